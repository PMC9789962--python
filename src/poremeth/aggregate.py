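"""Aggregation of per-read calls into genomic summaries.

Per-CpG methylation frequencies (bedMethyl-style), binned counts of
6mA-positive windows (bedGraph-style), nonspecific-antibody (IgG)
background correction

    R_f = R_s - sf * R_b,    sf = C_s / C_i

where R_s / R_b count 6mA-containing windows in the target and IgG data and
C_s / C_i are the matching coverage depths, plus the within-read distance
distribution between adjacent 6mA-positive windows (the accessible-linker
signature of nucleosome footprints).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import CALL_CONTAINS_6MA, CALL_METHYLATED, CALL_UNMETHYLATED


class CoverageError(ValueError):
    """IgG coverage is zero; the scaling factor is undefined."""


def site_frequencies(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG-site methylation frequencies from per-read substring calls.

    A substring call applies jointly to every CpG it covers, so each CpG
    position listed in ``cpg_positions`` inherits the call.  no_calls are
    excluded from both counts; sites with no informative call are omitted.
    Output is ordered by (chrom, start).
    """
    counts: dict[tuple[str, int], list[int]] = {}
    sub = calls[calls.kind == "cpg_substring"]
    for row in sub.itertuples():
        if row.call not in (CALL_METHYLATED, CALL_UNMETHYLATED):
            continue
        if not isinstance(row.cpg_positions, str) or not row.cpg_positions:
            continue
        for pos_s in row.cpg_positions.split(";"):
            key = (row.chrom, int(pos_s))
            c = counts.setdefault(key, [0, 0])
            c[0 if row.call == CALL_METHYLATED else 1] += 1
    rows = [
        (chrom, pos, pos + 2, m, u, m / (m + u), m + u)
        for (chrom, pos), (m, u) in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_methylated",
            "n_unmethylated",
            "frequency",
            "coverage",
        ],
    )


def methylation_category(frequency: float) -> str:
    """Frequency bins: high >= 70%, intermediate 30-70%, low < 30%."""
    if frequency >= 0.7:
        return "high"
    if frequency >= 0.3:
        return "intermediate"
    return "low"


def background_correct(
    R_s: float, R_b: float, C_s: float, C_i: float, region: str = "."
) -> tuple[float, float]:
    """(sf, R_f) with sf = C_s/C_i and R_f = max(R_s - sf*R_b, 0).

    A negative corrected count is floored at zero (counts below background
    carry no signal).
    """
    if C_i == 0:
        raise CoverageError(f"region {region!r}: IgG coverage is zero")
    sf = C_s / C_i
    return sf, max(R_s - sf * R_b, 0.0)


def window_counts(calls: pd.DataFrame, bin_size: int = 2500) -> pd.DataFrame:
    """Count 6mA-positive windows per genomic bin (0-based tiling).

    A window is attributed to the bin containing its start coordinate.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    pos = calls[(calls.kind == "adenine_window") & (calls.call == CALL_CONTAINS_6MA)]
    if pos.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "count"])
    binned = (
        pos.assign(bin=(pos.start // bin_size) * bin_size)
        .groupby(["chrom", "bin"])
        .size()
        .reset_index(name="count")
    )
    binned["start"] = binned.pop("bin")
    binned["end"] = binned.start + bin_size
    return binned[["chrom", "start", "end", "count"]].sort_values(
        ["chrom", "start"], ignore_index=True
    )


def cpm(counts: np.ndarray | pd.Series, total_reads: int) -> np.ndarray:
    """Counts-per-million normalisation against the library's read total."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / total_reads


def linker_length_distribution(calls: pd.DataFrame) -> np.ndarray:
    """Distances between adjacent 6mA-positive windows within single reads.

    Distances are between window midpoints of consecutive positives on the
    same read; reads with fewer than two positives contribute nothing.
    """
    pos = calls[(calls.kind == "adenine_window") & (calls.call == CALL_CONTAINS_6MA)]
    dists: list[float] = []
    for _, grp in pos.groupby("read_id", sort=False):
        mids = np.sort((grp.start.to_numpy() + grp.end.to_numpy()) / 2.0)
        if mids.size >= 2:
            dists.extend(np.diff(mids))
    return np.array(dists)


def frequencies_to_bedmethyl(freq: pd.DataFrame) -> str:
    """Render per-site frequencies as bedMethyl text."""
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\tCpG\t{r.coverage}\t+"
        f"\t{r.start}\t{r.end}\t0,0,0\t{r.coverage}\t{round(100 * r.frequency)}"
        for r in freq.itertuples()
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def counts_to_bedgraph(binned: pd.DataFrame, value_col: str = "count") -> str:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{getattr(r, value_col)}"
        for r in binned.itertuples()
    ]
    return "\n".join(lines) + ("\n" if lines else "")
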