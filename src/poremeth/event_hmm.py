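"""Event-to-k-mer hidden Markov model over nanopore signal.

Given the ordered current events of one read and a candidate reference
sequence S, the HMM computes P(e_1..e_n | S, Theta): each k-mer of S
contributes a block of states — *match* (Gaussian emission from the pore
model, self-transition allowed so a k-mer may emit several events), *bad*
(broadened Gaussian absorbing outlier events), and silent *skip* moves that
jump k-mers without emitting; *softclip* states with a flat emission absorb
unaligned leading/trailing events.

Per-read signal is related to the reference model through a shift/scale/
variance-scale triple (a, b, d): an event for k-mer k is modelled as
N(a + b*mu_k, (d*sigma_k)^2).  (a, b) come from ordinary least squares of
event means against model means; d is the root mean squared
sigma-standardised residual.

State semantics (shared by the forward pass, Viterbi, and the exhaustive
test oracle):

- Emitting states: PRE (leading softclip), M_j / B_j for k-mer j in 0..K-1,
  POST (trailing softclip).
- Initial: PRE with probability p_softclip; else enter block j with the
  truncated geometric weight p_skip^j * (1-p_skip) (j < K-1; the tail mass
  p_skip^(K-1) folds into the last block), split (1-p_bad)/p_bad between
  M_j and B_j.
- From PRE: stay with p_stay, else enter blocks as above.
- From M_j: stay with p_stay; the move mass (1-p_stay) reaches block
  j' = j+1+s with weight p_skip^s * (1-p_skip); mass skipping past the last
  block goes to POST.  B_j moves identically with mass 1 (no stay).
- POST is absorbing.
- Emissions: M_j from the pore-model entry of k-mer j (max-density
  component by default, mixture-marginal optionally); B_j the same with
  sd multiplied by bad_sd_factor; PRE/POST a flat density constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pore_model import PoreModel

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
D_MIN = 0.01  # floor on the variance scale; avoids degenerate zero-variance fits


class InsufficientDataError(ValueError):
    """Too few labelled events to fit per-read scaling."""


class DegenerateDesignError(ValueError):
    """The scaling regression design is singular (all model means equal)."""


@dataclass
class Event:
    """One segmented current event attributed to a single k-mer dwell."""

    mean_current: float  # pA
    stdv: float = 0.0
    duration: float = 0.0
    ref_kmer_index: int | None = None  # reference start of the labelled k-mer

    def __post_init__(self) -> None:
        if not self.mean_current > 0:
            raise ValueError(f"event mean current must be positive, got {self.mean_current}")


@dataclass
class EventSequence:
    """Ordered events of one read, anchored to the forward reference strand."""

    read_id: str
    strand: str
    events: list[Event]
    ref_start: int = 0
    contig: str = "."
    ref_kmers: list[str | None] | None = None  # optional per-event k-mer labels

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError(f"read {self.read_id!r} has no events")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def means(self) -> np.ndarray:
        return np.array([e.mean_current for e in self.events])


@dataclass(frozen=True)
class ReadScaling:
    """Read-specific shift (a, pA), scale (b) and variance scale (d)."""

    a: float
    b: float
    d: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"scale b must be positive, got {self.b}")
        if not self.d > 0:
            raise ValueError(f"variance scale d must be positive, got {self.d}")


IDENTITY_SCALING = ReadScaling(a=0.0, b=1.0, d=1.0)


@dataclass
class HmmConfig:
    """Transition and softclip constants of the signal HMM.

    The defaults follow squiggle-HMM convention; every acceptance property
    holds for any fixed constants in (0, 1).
    """

    p_stay: float = 0.1
    p_skip: float = 0.01
    p_bad: float = 0.001
    softclip_emission: float = 1e-3  # flat density per pA
    p_softclip: float = 0.05
    bad_sd_factor: float = 10.0
    component_mode: str = "max"  # "max" | "marginal"

    def __post_init__(self) -> None:
        for name in ("p_stay", "p_skip", "p_bad", "p_softclip"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.p_stay + self.p_skip + self.p_bad >= 1.0:
            raise ValueError("p_stay + p_skip + p_bad must be < 1")
        if self.component_mode not in ("max", "marginal"):
            raise ValueError(f"unknown component_mode {self.component_mode!r}")


def fit_read_scaling(
    events: EventSequence,
    labels: Sequence[str | None],
    model: PoreModel,
    min_events: int = 30,
) -> ReadScaling:
    """Least-squares fit of the read's (a, b, d) against labelled k-mers.

    (a, b) solve e_i ~= a + b*mu_k(i) by OLS over events whose label exists
    in the model; d is the RMS of sigma-standardised residuals, floored at
    0.01.  Multi-component entries contribute their first component.
    """
    if len(labels) != len(events):
        raise ValueError("labels must be parallel to events")
    e, mu, sigma = [], [], []
    for ev, lab in zip(events.events, labels):
        if lab is None or lab not in model:
            continue
        comp = model[lab][0]
        e.append(ev.mean_current)
        mu.append(comp.mean)
        sigma.append(comp.sd)
    if len(e) < min_events:
        raise InsufficientDataError(
            f"read {events.read_id!r}: {len(e)} labelled events, need >= {min_events}"
        )
    e_arr, mu_arr, s_arr = np.array(e), np.array(mu), np.array(sigma)
    if np.ptp(mu_arr) == 0:
        raise DegenerateDesignError(
            f"read {events.read_id!r}: all model means identical; cannot fit scale"
        )
    design = np.column_stack([np.ones_like(mu_arr), mu_arr])
    (a, b), *_ = np.linalg.lstsq(design, e_arr, rcond=None)
    resid = (e_arr - a - b * mu_arr) / s_arr
    d = max(float(np.sqrt(np.mean(resid**2))), D_MIN)
    return ReadScaling(a=float(a), b=float(b), d=d)


def emission_logpdf(
    event: Event,
    kmer_or_class: str,
    model: PoreModel,
    scaling: ReadScaling = IDENTITY_SCALING,
    cfg: HmmConfig | None = None,
) -> float:
    """log N(e; a + b*mu, (d*sigma)^2) under the entry's best component."""
    mode = (cfg or HmmConfig()).component_mode
    entry = model[kmer_or_class]
    lps = []
    for comp in entry:
        s = scaling.d * comp.sd
        z = (event.mean_current - (scaling.a + scaling.b * comp.mean)) / s
        lps.append(-0.5 * z * z - math.log(s) - LOG_SQRT_2PI)
    if mode == "max" or len(entry) == 1:
        return max(lps)
    return float(
        np.logaddexp.reduce([math.log(c.weight) + lp for c, lp in zip(entry, lps)])
    )


def _emission_matrices(
    means: np.ndarray,
    keys: Sequence[str],
    model: PoreModel,
    scaling: ReadScaling,
    cfg: HmmConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """(emit_match, emit_bad) of shape (n_events, K), fully vectorised."""
    K = len(keys)
    cmax = max(len(model[key]) for key in keys)
    mu = np.full((K, cmax), np.nan)
    sd = np.full((K, cmax), np.nan)
    w = np.zeros((K, cmax))
    for j, key in enumerate(keys):
        for c, comp in enumerate(model[key]):
            mu[j, c], sd[j, c], w[j, c] = comp.mean, comp.sd, comp.weight
    center = scaling.a + scaling.b * mu  # (K, cmax)
    mask = ~np.isnan(mu)
    out = []
    for scale in (scaling.d * sd, scaling.d * sd * cfg.bad_sd_factor):
        z = (means[:, None, None] - center[None]) / scale[None]
        lp = -0.5 * z * z - np.log(scale)[None] - LOG_SQRT_2PI
        lp = np.where(mask[None], lp, -np.inf)
        if cfg.component_mode == "max" or cmax == 1:
            out.append(lp.max(axis=2))
        else:
            logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
            from scipy.special import logsumexp

            out.append(logsumexp(lp + logw[None], axis=2))
    return out[0], out[1]


def _log(x: float) -> float:
    return math.log(x) if x > 0 else -math.inf


def _entry_logweights(K: int, cfg: HmmConfig) -> np.ndarray:
    """log of the truncated geometric entry distribution over blocks."""
    if cfg.p_skip == 0.0:
        lw = np.full(K, -np.inf)
        lw[0] = 0.0
        return lw
    lw = np.arange(K) * _log(cfg.p_skip) + _log(1.0 - cfg.p_skip)
    lw[K - 1] = (K - 1) * _log(cfg.p_skip)  # tail mass folds into last block
    return lw


def _forward_viterbi(
    events: EventSequence,
    keys: Sequence[str],
    model: PoreModel,
    scaling: ReadScaling,
    cfg: HmmConfig,
    viterbi: bool,
):
    """Shared DP core.  Returns final state scores and (for Viterbi)
    backpointers.  The geometric skip chain is evaluated exactly — never
    truncated — via a cumulative log-sum (or running-max) scan.

    State ids for backpointers: 0 = PRE, 1+2j = M_j, 2+2j = B_j,
    2K+1 = POST.
    """
    K = len(keys)
    n = len(events)
    EM, EB = _emission_matrices(events.means, keys, model, scaling, cfg)
    lsc = _log(cfg.softclip_emission)
    l_stay, l_move = _log(cfg.p_stay), _log(1.0 - cfg.p_stay)
    l_skip, l_noskip = _log(cfg.p_skip), _log(1.0 - cfg.p_skip)
    l_bad, l_good = _log(cfg.p_bad), _log(1.0 - cfg.p_bad)
    l_entry = _entry_logweights(K, cfg)
    jarr = np.arange(K)
    POST = 2 * K + 1

    aPre = _log(cfg.p_softclip) + lsc
    enter = _log(1.0 - cfg.p_softclip) + l_entry
    aM = enter + l_good + EM[0]
    aB = enter + l_bad + EB[0]
    aPost = -np.inf

    bp = np.full((n, 2 * K + 2), -1, dtype=np.int64) if viterbi else None

    for t in range(1, n):
        if viterbi:
            m_out = aM + l_move
            out = np.maximum(m_out, aB)
            out_state = np.where(m_out >= aB, 1 + 2 * jarr, 2 + 2 * jarr)
            # running max of out[j] + (j'-j-1)*l_skip over j < j'
            if cfg.p_skip > 0:
                u = out - jarr * l_skip
                cm = np.maximum.accumulate(u)
                src = np.maximum.accumulate(np.where(u >= cm, jarr, -1))
                g = np.concatenate([[-np.inf], jarr * l_skip + cm])
                g_src = np.concatenate([[-1], src])
            else:
                g = np.concatenate([[-np.inf], out])
                g_src = np.concatenate([[-1], jarr])
            g_state = np.where(g_src >= 0, out_state[np.maximum(g_src, 0)], -1)

            inc_pre = aPre + l_move + l_entry
            inc_blk = g[:K] + l_noskip
            from_pre = inc_pre >= inc_blk
            inc = np.where(from_pre, inc_pre, inc_blk)
            inc_state = np.where(from_pre, 0, g_state[:K])

            stay_m = aM + l_stay
            cand_m = inc + l_good
            m_stay = stay_m >= cand_m
            nM = np.where(m_stay, stay_m, cand_m)
            bp[t, 1 : 2 * K + 1 : 2] = np.where(m_stay, 1 + 2 * jarr, inc_state)
            nB = inc + l_bad
            bp[t, 2 : 2 * K + 1 : 2] = inc_state
            tail = g[K]
            if aPost >= tail:
                nPost, bp[t, POST] = aPost, POST
            else:
                nPost, bp[t, POST] = tail, g_state[K]
            bp[t, 0] = 0
        else:
            out = np.logaddexp(aM + l_move, aB)
            if cfg.p_skip > 0:
                u = out - jarr * l_skip
                c = np.logaddexp.accumulate(u)
                g = np.concatenate([[-np.inf], jarr * l_skip + c])
            else:
                g = np.concatenate([[-np.inf], out])
            inc = np.logaddexp(aPre + l_move + l_entry, g[:K] + l_noskip)
            nM = np.logaddexp(aM + l_stay, inc + l_good)
            nB = inc + l_bad
            nPost = np.logaddexp(aPost, g[K])

        aPre = aPre + l_stay + lsc
        aM = nM + EM[t]
        aB = nB + EB[t]
        aPost = nPost + lsc

    scores = np.concatenate([[aPre], np.ravel(np.column_stack([aM, aB])), [aPost]])
    return scores, bp


def forward_loglik(
    events: EventSequence,
    keys: Sequence[str],
    model: PoreModel,
    scaling: ReadScaling = IDENTITY_SCALING,
    cfg: HmmConfig | None = None,
) -> float:
    """log P(e_1..e_n | S, Theta): the log-sum over all legal state paths.

    ``keys`` are the pore-model lookup keys of the K = len(S)-k+1 k-mers of
    the candidate sequence, in order.
    """
    cfg = cfg or HmmConfig()
    if not keys:
        raise ValueError("candidate sequence yields no k-mers")
    from scipy.special import logsumexp

    scores, _ = _forward_viterbi(events, keys, model, scaling, cfg, viterbi=False)
    return float(logsumexp(scores))


@dataclass
class ViterbiAlignment:
    """Maximum-probability state path of one read against one sequence."""

    log_prob: float
    #: per-event (state, kmer_index): state in {"match", "bad", "softclip"};
    #: kmer_index is None for softclip events.
    assignments: list[tuple[str, int | None]] = field(default_factory=list)


def viterbi_align(
    events: EventSequence,
    keys: Sequence[str],
    model: PoreModel,
    scaling: ReadScaling = IDENTITY_SCALING,
    cfg: HmmConfig | None = None,
) -> ViterbiAlignment:
    """Single best state path; its log-probability never exceeds the forward
    log-likelihood, and k-mer assignments are monotone in signal time."""
    cfg = cfg or HmmConfig()
    if not keys:
        raise ValueError("candidate sequence yields no k-mers")
    K = len(keys)
    scores, bp = _forward_viterbi(events, keys, model, scaling, cfg, viterbi=True)
    state = int(np.argmax(scores))
    log_prob = float(scores[state])
    n = len(events)
    path = np.empty(n, dtype=np.int32)
    for t in range(n - 1, -1, -1):
        path[t] = state
        state = bp[t, state]

    def decode(s: int) -> tuple[str, int | None]:
        if s == 0 or s == 2 * K + 1:
            return ("softclip", None)
        j, kind = divmod(s - 1, 2)
        return ("match" if kind == 0 else "bad", j)

    return ViterbiAlignment(log_prob=log_prob, assignments=[decode(int(s)) for s in path])


# --- eventalign-style TSV I/O -------------------------------------------------

EVENTALIGN_COLUMNS = [
    "contig",
    "position",
    "reference_kmer",
    "read_id",
    "strand",
    "event_index",
    "event_level_mean",
    "event_stdv",
    "event_length",
]


def read_eventalign(path) -> list[EventSequence]:
    """Parse an eventalign-dialect TSV into per-read event sequences.

    One row per measured event; ``position`` is the 0-based reference start
    of the labelled k-mer.  Extra columns are tolerated.  Rows of one read
    must be contiguous and in signal order (event_index ascending).
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENTALIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"eventalign table missing columns {sorted(missing)}")
    reads: list[EventSequence] = []
    for read_id, grp in df.groupby("read_id", sort=False):
        grp = grp.sort_values("event_index", kind="stable")
        events = [
            Event(
                mean_current=float(r.event_level_mean),
                stdv=float(r.event_stdv),
                duration=float(r.event_length),
                ref_kmer_index=int(r.position),
            )
            for r in grp.itertuples()
        ]
        reads.append(
            EventSequence(
                read_id=str(read_id),
                strand=str(grp.strand.iloc[0]),
                events=events,
                ref_start=int(grp.position.min()),
                contig=str(grp.contig.iloc[0]),
                ref_kmers=[str(k) for k in grp.reference_kmer],
            )
        )
    return reads


def write_eventalign(reads: list[EventSequence], path) -> None:
    rows = []
    for rd in reads:
        for i, ev in enumerate(rd.events):
            rows.append(
                (
                    rd.contig,
                    ev.ref_kmer_index,
                    rd.ref_kmers[i] if rd.ref_kmers else ".",
                    rd.read_id,
                    rd.strand,
                    i,
                    ev.mean_current,
                    ev.stdv,
                    ev.duration,
                )
            )
    pd.DataFrame(rows, columns=EVENTALIGN_COLUMNS).to_csv(path, sep="\t", index=False)
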