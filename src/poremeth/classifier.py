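"""Per-read log-likelihood-ratio classification of methylation sites.

Each site window carries up to four modification-hypothesis sequence
variants (ref1 none, ref2 all CpGs methylated, ref3 6mA-containing,
ref4 both).  The calling statistic on one read is

    LLR = sum_{i in meth-side refs} log L(S_i | e, Theta)
        - sum_{j in unmeth-side refs} log L(S_j | e, Theta)

with {ref2, ref4} vs {ref1, ref3} for CpG methylation and {ref3, ref4} vs
{ref1, ref2} for 6mA; the sums degenerate to single-hypothesis ratios for
windows lacking the other mark.  Likelihoods come from the signal HMM; for
multi-component entries the maximum-density component per event stands in
for the max over trained parameter sets.  LLRs are natural logs.

Calls: CpG llr >= +1.5 -> methylated, llr <= -1.5 -> unmethylated, the dead
zone in between -> no_call; a 50-bp adenine window llr >= 8 (low stringency)
or >= 32 (high) -> contains_6mA, else non_6mA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alphabet import SiteWindow, make_reference_variants, segment_read
from .event_hmm import (
    EventSequence,
    HmmConfig,
    ReadScaling,
    fit_read_scaling,
    forward_loglik,
)
from .pore_model import PoreModel

CALL_METHYLATED = "methylated"
CALL_UNMETHYLATED = "unmethylated"
CALL_CONTAINS_6MA = "contains_6mA"
CALL_NON_6MA = "non_6mA"
CALL_NONE = "no_call"


@dataclass(frozen=True)
class Thresholds:
    """LLR decision boundaries (natural log), inclusive at the boundary."""

    cpg_meth: float = 1.5
    cpg_unmeth: float = -1.5
    ada_low: float = 8.0
    ada_high: float = 32.0

    def __post_init__(self) -> None:
        if not self.cpg_meth > self.cpg_unmeth:
            raise ValueError("cpg_meth must exceed cpg_unmeth")
        if not self.ada_high >= self.ada_low:
            raise ValueError("ada_high must be >= ada_low")


@dataclass
class MethylationCall:
    """One per-read, per-window call."""

    read_id: str
    window: SiteWindow
    llr: float | None
    call: str
    n_hypotheses_used: int = 0
    reason: str | None = None  # populated for no_calls


class NoEventsError(ValueError):
    """No events overlap the window's k-mer support."""


def _window_events(
    events: EventSequence, window: SiteWindow, k: int
) -> EventSequence | None:
    """Subsequence of events assigned to k-mers overlapping the window,
    plus k-1 flanking k-mers each side (the window's context span)."""
    lo = window.context.coordinate_offset
    hi = lo + len(window.context) - k  # last k-mer start within the context
    sel = [
        ev
        for ev in events.events
        if ev.ref_kmer_index is not None and lo <= ev.ref_kmer_index <= hi
    ]
    if not sel:
        return None
    return EventSequence(
        read_id=events.read_id,
        strand=events.strand,
        events=sel,
        ref_start=lo,
        contig=events.contig,
    )


def _hypothesis_logliks(
    window: SiteWindow,
    events: EventSequence,
    model: PoreModel,
    scaling: ReadScaling,
    cfg: HmmConfig,
    k: int,
) -> dict[str, float]:
    sub = _window_events(events, window, k)
    if sub is None:
        raise NoEventsError(
            f"no events overlap window {window.chrom}:{window.ref_start}-{window.ref_end}"
        )
    variants = make_reference_variants(window, k=k)
    return {
        name: forward_loglik(sub, var.kmer_keys(k), model, scaling, cfg)
        for name, var in variants.items()
    }


def llr_cpg(
    window: SiteWindow,
    events: EventSequence,
    model: PoreModel,
    scaling: ReadScaling,
    cfg: HmmConfig | None = None,
) -> tuple[float, int]:
    """CpG-methylation LLR of one window on one read.

    Returns (llr, n_hypotheses): four hypotheses when the window also
    contains adenines ((ref2 + ref4) - (ref1 + ref3)), else the plain
    ref2 - ref1 ratio.
    """
    if window.kind != "cpg_substring":
        raise ValueError(f"expected a cpg_substring window, got {window.kind!r}")
    cfg = cfg or HmmConfig()
    ll = _hypothesis_logliks(window, events, model, scaling, cfg, model.k)
    if "ref3" in ll:
        return (ll["ref2"] + ll["ref4"]) - (ll["ref1"] + ll["ref3"]), 4
    return ll["ref2"] - ll["ref1"], 2


def llr_6ma(
    window: SiteWindow,
    events: EventSequence,
    model: PoreModel,
    scaling: ReadScaling,
    cfg: HmmConfig | None = None,
) -> tuple[float, int]:
    """6mA-containment LLR of one 50-bp window on one read.

    The window is classified as containing methylated adenine(s) or not —
    never per-adenine.  Hypothesis roles mirror ``llr_cpg``:
    (ref3 + ref4) - (ref1 + ref2), degenerating to ref3 - ref1 for
    CpG-free windows.
    """
    if window.kind != "adenine_window":
        raise ValueError(f"expected an adenine_window, got {window.kind!r}")
    cfg = cfg or HmmConfig()
    ll = _hypothesis_logliks(window, events, model, scaling, cfg, model.k)
    if "ref2" in ll:
        return (ll["ref3"] + ll["ref4"]) - (ll["ref1"] + ll["ref2"]), 4
    return ll["ref3"] - ll["ref1"], 2


def call(
    llr: float,
    kind: str,
    thresholds: Thresholds | None = None,
    stringency: str = "low",
) -> str:
    """Categorical call from a finite LLR.  Boundaries are inclusive."""
    if llr is None or math.isnan(llr):
        raise ValueError("LLR is NaN; cannot call")
    th = thresholds or Thresholds()
    if kind == "cpg_substring":
        if llr >= th.cpg_meth:
            return CALL_METHYLATED
        if llr <= th.cpg_unmeth:
            return CALL_UNMETHYLATED
        return CALL_NONE
    if kind == "adenine_window":
        if stringency not in ("low", "high"):
            raise ValueError(f"stringency must be low or high, got {stringency!r}")
        tau = th.ada_low if stringency == "low" else th.ada_high
        return CALL_CONTAINS_6MA if llr >= tau else CALL_NON_6MA
    raise ValueError(f"unknown window kind {kind!r}")


def call_read(
    events: EventSequence,
    ref_seq: str,
    model: PoreModel,
    cfg: HmmConfig | None = None,
    thresholds: Thresholds | None = None,
    stringency: str = "low",
    scaling: ReadScaling | None = None,
    window_size: int = 50,
) -> list[MethylationCall]:
    """All site calls of one event-aligned read.

    Fits the read scaling from its event labels (unless supplied), segments
    the read's reference span into CpG substrings and adenine windows, and
    emits one call per window.  A window without event support becomes a
    no_call; one bad window never aborts the read.
    """
    cfg = cfg or HmmConfig()
    thresholds = thresholds or Thresholds()
    k = model.k
    if scaling is None:
        labels = events.ref_kmers
        if labels is None:
            labels = [
                ref_seq[ev.ref_kmer_index : ev.ref_kmer_index + k]
                if ev.ref_kmer_index is not None
                else None
                for ev in events.events
            ]
        scaling = fit_read_scaling(events, labels, model)
    read_start = events.ref_start
    read_end = max(
        ev.ref_kmer_index for ev in events.events if ev.ref_kmer_index is not None
    ) + k
    windows = segment_read(
        ref_seq, read_start, read_end, k=k, window_size=window_size, chrom=events.contig
    )
    calls: list[MethylationCall] = []
    for win in windows:
        llr_fn = llr_cpg if win.kind == "cpg_substring" else llr_6ma
        try:
            value, n_hyp = llr_fn(win, events, model, scaling, cfg)
        except NoEventsError as err:
            calls.append(
                MethylationCall(
                    read_id=events.read_id,
                    window=win,
                    llr=None,
                    call=CALL_NONE,
                    reason=str(err),
                )
            )
            continue
        calls.append(
            MethylationCall(
                read_id=events.read_id,
                window=win,
                llr=value,
                call=call(value, win.kind, thresholds, stringency),
                n_hypotheses_used=n_hyp,
            )
        )
    return calls


def calls_to_table(calls: list[MethylationCall]):
    """Per-read call table (nanopolish-style): one row per window call."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            (
                c.read_id,
                c.window.chrom,
                c.window.ref_start,
                c.window.ref_end,
                c.window.kind,
                float("nan") if c.llr is None else c.llr,
                c.call,
                c.n_hypotheses_used,
                ";".join(str(p) for p in c.window.cpg_positions),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "chrom",
            "start",
            "end",
            "kind",
            "llr",
            "call",
            "n_hypotheses",
            "cpg_positions",
        ],
    )
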