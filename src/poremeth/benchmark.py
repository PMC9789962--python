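"""End-to-end benchmark harness: train on the four simulated library
conditions, call fresh reads, and score classification against the
simulator's truth.

The evaluation mirrors how signal-space callers are benchmarked on real
data: positives come from treated libraries (CpG-methyltransferase or
adenine-methyltransferase amplicons), negatives from the untreated library.
CpG positives require every CpG of the window methylated on the molecule —
the joint all-or-none call has no defined truth on mixed windows.  6mA
positives are treatment-level: every adenine window of a treated read
counts, including windows the partial labelling reaction happened to miss —
on real data the molecule truth is unknowable, and it is exactly this
missed-label fraction that makes short windows harder to call than long
ones.

Problem sizes are scaled to a single CPU: an 800-bp reference at ~26x
training coverage per condition (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import call_read, calls_to_table
from .pore_model import PoreModel, synthetic_pore_model
from .simulator import (
    ReferenceTruth,
    SimConfig,
    simulate_reads,
    simulate_reference,
    simulate_training_conditions,
)
from .training import TrainingConfig, train


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), ties sharing average ranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(scores))
    s = scores[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s[j + 1] == s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EndToEndResult:
    cpg_auc: float
    ada_auc: float  # 50-bp windows
    ada_auc_by_window: dict[int, float]
    n_cpg_pos: int
    n_cpg_neg: int
    n_ada_pos: int
    n_ada_neg: int
    trained_entries: int
    model: PoreModel | None = field(repr=False, default=None)
    reference: ReferenceTruth | None = field(repr=False, default=None)
    config: SimConfig | None = field(repr=False, default=None)


def run_end_to_end(
    seed: int,
    k: int = 6,
    ref_length: int = 800,
    n_train_reads: int = 60,
    train_read_length: int = 350,
    n_test_reads: int = 35,
    test_read_length: int = 500,
    outer_rounds: int = 5,
    window_sizes: tuple[int, ...] = (12, 24, 50, 100),
) -> EndToEndResult:
    """Train from scratch on simulated conditions, then score fresh reads."""
    cfg = SimConfig(seed=seed, ref_length=ref_length, k=k)
    rng = np.random.default_rng(cfg.seed)
    ref = simulate_reference(cfg, rng)
    base = synthetic_pore_model(k)
    datasets = simulate_training_conditions(
        ref, base, cfg, n_train_reads, train_read_length, rng
    )
    trained = train(datasets, base, TrainingConfig(outer_rounds=outer_rounds))
    n_trained = sum(1 for p in trained.provenance.values() if p == "trained")

    test_reads, truths = {}, {}
    for tag in ("unmodified", "mCpG", "6mA"):
        reads, truth, _ = simulate_reads(
            ref, base, cfg, n_test_reads, test_read_length, rng,
            condition=tag, footprint=False,
        )
        test_reads[tag], truths[tag] = reads, truth

    def _calls(reads, window_size):
        tabs = [
            calls_to_table(call_read(ev, ref.sequence, trained, window_size=window_size))
            for ev in reads
        ]
        return pd.concat(tabs, ignore_index=True)

    calls50 = {tag: _calls(test_reads[tag], 50) for tag in test_reads}
    merged = {
        tag: calls50[tag].merge(
            truths[tag], on=["read_id", "chrom", "start", "end", "kind"]
        )
        for tag in test_reads
    }

    # CpG ROC: fully methylated substrings (treated) vs untreated substrings
    pos = merged["mCpG"]
    pos = pos[
        (pos.kind == "cpg_substring")
        & (pos.n_cpg > 0)
        & (pos.n_modified_cpg == pos.n_cpg)
        & pos.llr.notna()
    ]
    neg = merged["unmodified"]
    neg = neg[(neg.kind == "cpg_substring") & neg.llr.notna()]
    cpg_auc = rank_auc(
        np.r_[np.ones(len(pos)), np.zeros(len(neg))], np.r_[pos.llr, neg.llr]
    )
    n_cpg = (len(pos), len(neg))

    # 6mA ROC per window length: treated-library windows vs untreated
    ada_auc_by_window: dict[int, float] = {}
    n_ada = (0, 0)
    for ws in window_sizes:
        mp = merged["6mA"] if ws == 50 else _calls(test_reads["6mA"], ws)
        mn = merged["unmodified"] if ws == 50 else _calls(test_reads["unmodified"], ws)
        p = mp[(mp.kind == "adenine_window") & mp.llr.notna()]
        n = mn[(mn.kind == "adenine_window") & mn.llr.notna()]
        ada_auc_by_window[ws] = rank_auc(
            np.r_[np.ones(len(p)), np.zeros(len(n))], np.r_[p.llr, n.llr]
        )
        if ws == 50:
            n_ada = (len(p), len(n))

    return EndToEndResult(
        cpg_auc=cpg_auc,
        ada_auc=ada_auc_by_window[50],
        ada_auc_by_window=ada_auc_by_window,
        n_cpg_pos=n_cpg[0],
        n_cpg_neg=n_cpg[1],
        n_ada_pos=n_ada[0],
        n_ada_neg=n_ada[1],
        trained_entries=n_trained,
        model=trained,
        reference=ref,
        config=cfg,
    )
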