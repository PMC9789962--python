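"""Haplotype-resolved methylation statistics.

Reads carrying haplotype tags (from upstream phasing) are grouped per
region; regions with combined read coverage >= 20 are analysed.
Allele-specific CpG methylation uses a two-sided Fisher exact test on the
2x2 table of methylated/unmethylated call counts by haplotype.
Allele-specific 6mA enrichment uses a window bootstrap: reads of each
allele are segmented into non-overlapping 250-bp windows flagged as
6mA-containing or not; each of 100 bootstrap replications samples 30
windows with replacement per allele and records the positives; the pooled
replication counts form a 2x2 table tested two-sided by Fisher.  P-values
are Benjamini-Hochberg corrected; a region is significant when p < 0.01 at
a 10% target FDR (q <= 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

MIN_COVERAGE = 20
DEFAULT_BOOTSTRAP_WINDOWS = 30
DEFAULT_BOOTSTRAP_REPS = 100
BOOTSTRAP_WINDOW_SIZE = 250
ALPHA = 0.01
TARGET_FDR = 0.10


@dataclass
class HaplotypedRegion:
    """Per-region call collections split by haplotype.

    For the CpG test, ``hap*_meth`` / ``hap*_unmeth`` are call counts.
    For the 6mA bootstrap, ``hap*_windows`` are per-window boolean flags
    (True = window harbours 6mA) over the allele's 250-bp segmentation.
    """

    region: str
    coverage: int
    hap1_meth: int = 0
    hap1_unmeth: int = 0
    hap2_meth: int = 0
    hap2_unmeth: int = 0
    hap1_windows: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    hap2_windows: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


@dataclass
class AllelicResult:
    region: str
    test: str  # "cpg_fisher" | "ada_bootstrap"
    statistic: float
    p_value: float
    q_value: float | None = None
    significant: bool = False
    skipped: str | None = None


def fisher_cpg(region: HaplotypedRegion) -> AllelicResult:
    """Two-sided Fisher exact test of methylation counts by haplotype."""
    if region.coverage < MIN_COVERAGE:
        return AllelicResult(
            region.region, "cpg_fisher", float("nan"), float("nan"),
            skipped=f"coverage {region.coverage} < {MIN_COVERAGE}",
        )
    h1 = region.hap1_meth + region.hap1_unmeth
    h2 = region.hap2_meth + region.hap2_unmeth
    if h1 == 0 or h2 == 0:
        return AllelicResult(
            region.region, "cpg_fisher", float("nan"), float("nan"),
            skipped="a haplotype has no informative calls",
        )
    table = [
        [region.hap1_meth, region.hap1_unmeth],
        [region.hap2_meth, region.hap2_unmeth],
    ]
    odds, p = fisher_exact(table, alternative="two-sided")
    return AllelicResult(region.region, "cpg_fisher", float(odds), float(p))


def bootstrap_6ma(
    region: HaplotypedRegion,
    n_windows: int = DEFAULT_BOOTSTRAP_WINDOWS,
    n_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
) -> AllelicResult:
    """Window-bootstrap test of allele-specific 6mA enrichment.

    Per replication, ``n_windows`` windows are drawn with replacement from
    each allele's window set and the 6mA-positives counted; counts pooled
    over all replications form the 2x2 Fisher table.  Deterministic given
    the seed.  Alleles offering fewer than ``n_windows`` windows are
    skipped rather than sampled with shortfall.
    """
    if region.coverage < MIN_COVERAGE:
        return AllelicResult(
            region.region, "ada_bootstrap", float("nan"), float("nan"),
            skipped=f"coverage {region.coverage} < {MIN_COVERAGE}",
        )
    w1, w2 = np.asarray(region.hap1_windows), np.asarray(region.hap2_windows)
    if w1.size < n_windows or w2.size < n_windows:
        return AllelicResult(
            region.region, "ada_bootstrap", float("nan"), float("nan"),
            skipped=f"fewer than {n_windows} windows on an allele",
        )
    rng = np.random.default_rng(seed)
    pos = np.zeros(2, dtype=int)
    total = n_reps * n_windows
    for arm, w in enumerate((w1, w2)):
        draws = rng.integers(0, w.size, size=(n_reps, n_windows))
        pos[arm] = int(w[draws].sum())
    table = [[pos[0], total - pos[0]], [pos[1], total - pos[1]]]
    odds, p = fisher_exact(table, alternative="two-sided")
    return AllelicResult(region.region, "ada_bootstrap", float(odds), float(p))


def correct_and_select(
    results: list[AllelicResult],
    alpha: float = ALPHA,
    target_fdr: float = TARGET_FDR,
) -> list[AllelicResult]:
    """Benjamini-Hochberg q-values plus the significance gate.

    Skipped results (NaN p) are passed through untouched and excluded from
    the correction.  Significant iff p < alpha and q <= target_fdr.
    """
    tested = [r for r in results if not np.isnan(r.p_value)]
    if tested:
        _, q_values, _, _ = multipletests(
            [r.p_value for r in tested], method="fdr_bh"
        )
        for r, q in zip(tested, q_values):
            r.q_value = float(q)
            r.significant = (r.p_value < alpha) and (r.q_value <= target_fdr)
    return results


def results_to_bed(results: list[AllelicResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        chrom, coords = (r.region.split(":") + ["0-0"])[:2] if ":" in r.region else (r.region, "0-0")
        start, _, end = coords.partition("-")
        rows.append(
            (
                chrom,
                int(start or 0),
                int(end or 0),
                r.test,
                r.statistic,
                r.p_value,
                r.q_value,
                r.significant,
                r.skipped or "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "test", "odds_ratio", "p", "q", "significant", "skipped"],
    )
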