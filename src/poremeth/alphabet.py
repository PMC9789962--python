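"""Expanded six-letter nucleotide alphabet for joint 5mC/6mA calling.

The standard DNA alphabet {A, C, G, T} is extended with M (5-methylcytosine,
restricted to CpG context) and Z (N6-methyladenine).  A 6-mer over this
alphabet keys one emission distribution in the pore model; because partial
adenine labelling makes the exact Z placement within a k-mer unknowable,
k-mers differing only by A/Z substitutions are pooled into a single
equivalence class (the "k-bar" class).

This module owns the alphabet rules: enumeration, validity (M must be part
of a CpG), class collapsing, construction of the four modification-hypothesis
sequence variants for a site, and segmentation of a read's reference span
into testable site windows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

ALPHABET = "ACGTMZ"
STANDARD = "ACGT"

#: Suffix appended to a collapsed base k-mer to form the label of a
#: 6mA-carrying class in pore-model tables.
CLASS_6MA_SUFFIX = "+6mA"


class AlphabetError(ValueError):
    """A string violates the six-letter alphabet or its validity rules."""


class KmerEnumeration(NamedTuple):
    count: int
    kmers: Iterator[str]


@dataclass(frozen=True)
class KmerClass:
    """Equivalence class of k-mers pooled over A/Z substitutions.

    ``base_kmer`` is the k-mer with every Z replaced by A (letters over
    {A,C,G,T,M}); ``has_6mA`` records whether any member carries Z.
    """

    base_kmer: str
    has_6mA: bool

    @property
    def label(self) -> str:
        return self.base_kmer + CLASS_6MA_SUFFIX if self.has_6mA else self.base_kmer


@dataclass
class ModSequence:
    """A reference-anchored sequence over {A,C,G,T,M,Z}.

    ``coordinate_offset`` is the 0-based reference position of the first
    letter; minus-strand reads are represented on the forward strand.
    """

    letters: str
    coordinate_offset: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        bad = set(self.letters) - set(ALPHABET)
        if bad:
            raise AlphabetError(f"illegal letters {sorted(bad)!r} in sequence")
        if self.strand not in "+-":
            raise AlphabetError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return len(self.letters)


@dataclass
class SiteWindow:
    """A testable site on a read: a CpG substring or a 50-bp adenine window.

    ``ref_start``/``ref_end`` delimit the tested interval (0-based,
    half-open).  ``context`` covers every k-mer overlapping the interval
    plus k-1 flanking k-mers on each side, so hypothesis likelihoods are
    computable without further reference access.  ``cpg_positions`` are the
    reference coordinates of the C of each CpG inside the interval;
    ``adenine_positions`` likewise for adenines inside the interval.
    """

    kind: str  # "cpg_substring" | "adenine_window"
    ref_start: int
    ref_end: int
    context: ModSequence
    cpg_positions: tuple[int, ...] = ()
    adenine_positions: tuple[int, ...] = ()
    chrom: str = "."

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def n_adenine(self) -> int:
        return len(self.adenine_positions)


@dataclass
class HypothesisVariant:
    """One modification hypothesis (ref1..ref4) rendered as pore-model keys.

    ``letters`` substitutes M for the hypothesised methylated CpG cytosines;
    ``six_ma_kmer_starts`` lists context-relative k-mer start offsets whose
    emission is looked up under the 6mA-carrying class.
    """

    name: str
    letters: str
    coordinate_offset: int
    six_ma_kmer_starts: frozenset[int] = field(default_factory=frozenset)

    def kmer_keys(self, k: int) -> list[str]:
        """Pore-model lookup key for every k-mer of the variant, in order."""
        keys = []
        for i in range(len(self.letters) - k + 1):
            kmer = self.letters[i : i + k]
            if i in self.six_ma_kmer_starts and "A" in kmer:
                keys.append(kmer + CLASS_6MA_SUFFIX)
            else:
                keys.append(kmer)
        return keys


def enumerate_alphabet(k: int, letters: str = ALPHABET) -> KmerEnumeration:
    """Count and lazily enumerate all length-``k`` strings over ``letters``.

    With the full six-letter alphabet and k=6 this yields 6^6 = 46,656
    strings, of which the {A,C,G,T} restriction contributes 4,096.
    """
    if not 1 <= k <= 8:
        raise AlphabetError(f"k must be in [1, 8], got {k}")
    count = len(letters) ** k
    kmers = ("".join(p) for p in itertools.product(letters, repeat=k))
    return KmerEnumeration(count, kmers)


def is_valid_kmer(kmer: str) -> bool:
    """Whether a six-letter k-mer is a legal methylation context.

    M denotes a methylated CpG cytosine, so an M must be immediately
    followed by G.  An M at the final position is valid: its G lies in the
    next k-mer.  Any M followed by A, C, T, Z or M marks the k-mer invalid.
    """
    bad = set(kmer) - set(ALPHABET)
    if bad:
        raise AlphabetError(f"illegal letters {sorted(bad)!r} in k-mer {kmer!r}")
    for i, ch in enumerate(kmer[:-1]):
        if ch == "M" and kmer[i + 1] != "G":
            return False
    return True


def collapse_to_class(kmer: str) -> KmerClass:
    """Collapse a valid k-mer to its A/Z equivalence class."""
    if not is_valid_kmer(kmer):
        raise AlphabetError(f"invalid k-mer {kmer!r}")
    return KmerClass(base_kmer=kmer.replace("Z", "A"), has_6mA="Z" in kmer)


def _cpg_starts(seq: str, start: int = 0) -> list[int]:
    """0-based positions (offset by ``start``) of the C of each CpG."""
    return [start + i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


def _adenine_positions(seq: str, start: int = 0) -> list[int]:
    return [start + i for i, ch in enumerate(seq) if ch == "A"]


def make_reference_variants(window: SiteWindow, k: int = 6) -> dict[str, HypothesisVariant]:
    """Build the modification-hypothesis variants ref1..ref4 for a window.

    ref1: unmodified.  ref2: every CpG cytosine inside the tested interval
    replaced by M (a joint hypothesis over all CpGs at once).  ref3: every
    k-mer overlapping an adenine inside the interval evaluated under its
    6mA-carrying class.  ref4: both.  Degenerate windows (no CpG or no
    adenine) omit the hypotheses that would duplicate others.
    """
    ctx = window.context
    if window.n_cpg == 0 and window.n_adenine == 0:
        raise AlphabetError("window contains neither CpG nor adenine; nothing to test")

    letters = ctx.letters
    off = ctx.coordinate_offset

    meth_letters = list(letters)
    for pos in window.cpg_positions:
        i = pos - off
        if not (0 <= i < len(letters)) or letters[i] != "C":
            raise AlphabetError(f"CpG position {pos} does not index a C in the context")
        meth_letters[i] = "M"
    meth_letters = "".join(meth_letters)

    # k-mer starts (context-relative) overlapping any adenine inside the interval
    flagged: set[int] = set()
    n_kmers = len(letters) - k + 1
    for pos in window.adenine_positions:
        i = pos - off
        for s in range(max(0, i - k + 1), min(n_kmers, i + 1)):
            flagged.add(s)
    flagged = frozenset(flagged)

    variants = {"ref1": HypothesisVariant("ref1", letters, off)}
    if window.n_cpg:
        variants["ref2"] = HypothesisVariant("ref2", meth_letters, off)
    if window.n_adenine:
        variants["ref3"] = HypothesisVariant("ref3", letters, off, flagged)
    if window.n_cpg and window.n_adenine:
        variants["ref4"] = HypothesisVariant("ref4", meth_letters, off, flagged)
    return variants


def segment_read(
    ref_seq: str,
    read_start: int,
    read_end: int,
    k: int = 6,
    window_size: int = 50,
    flank: int = 10,
    chrom: str = ".",
) -> list[SiteWindow]:
    """Segment a read's reference span into CpG substrings and adenine windows.

    CpG substrings: maximal clusters of CpGs separated by fewer than
    ``flank`` CpG-free bases, padded by ``flank`` bases beyond the outermost
    CpG on each side; clusters whose padded interval leaves the read span
    are dropped (the flank guarantee cannot be met).  Adenine windows:
    non-overlapping ``window_size``-bp tiles anchored at ``read_start``;
    a terminal remainder shorter than ``window_size`` is dropped.  The two
    families may overlap each other; tiles never overlap among themselves.

    ``ref_seq`` is the full forward-strand reference (0-based indexing).
    """
    span_seq = ref_seq[read_start:read_end]
    cpgs = _cpg_starts(span_seq, read_start)
    windows: list[SiteWindow] = []

    def _context(lo: int, hi: int) -> ModSequence:
        c_lo = max(read_start, lo - 2 * (k - 1))
        c_hi = min(read_end, hi + 2 * (k - 1))
        return ModSequence(ref_seq[c_lo:c_hi], coordinate_offset=c_lo)

    # --- CpG substrings: cluster then pad ---
    clusters: list[list[int]] = []
    for p in cpgs:
        # previous CpG occupies [q, q+2); CpG-free gap is p - (q + 2)
        if clusters and p - (clusters[-1][-1] + 2) < flank:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    for cl in clusters:
        lo, hi = cl[0] - flank, cl[-1] + 2 + flank
        if lo < read_start or hi > read_end:
            continue  # flank guarantee unmeetable at read edge
        ctx = _context(lo, hi)
        windows.append(
            SiteWindow(
                kind="cpg_substring",
                ref_start=lo,
                ref_end=hi,
                context=ctx,
                cpg_positions=tuple(cl),
                adenine_positions=tuple(
                    p for p in _adenine_positions(ctx.letters, ctx.coordinate_offset)
                    if lo <= p < hi
                ),
                chrom=chrom,
            )
        )

    # --- adenine windows: fixed tiling from the read start ---
    for lo in range(read_start, read_end - window_size + 1, window_size):
        hi = lo + window_size
        tile = ref_seq[lo:hi]
        adas = _adenine_positions(tile, lo)
        if not adas:
            continue
        windows.append(
            SiteWindow(
                kind="adenine_window",
                ref_start=lo,
                ref_end=hi,
                context=_context(lo, hi),
                cpg_positions=tuple(_cpg_starts(tile, lo)),
                adenine_positions=tuple(adas),
                chrom=chrom,
            )
        )
    return windows


def windows_to_bed(windows: list[SiteWindow]) -> str:
    """Render site windows as BED6 text (kind in the name field)."""
    lines = [
        f"{w.chrom}\t{w.ref_start}\t{w.ref_end}\t{w.kind}\t0\t+"
        for w in windows
    ]
    return "\n".join(lines) + ("\n" if lines else "")
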