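"""Seeded simulation of event-aligned nanopore reads with known truth.

The generator emulates the data this caller consumes: a reference sequence
with controllable CpG density, four training-library conditions (untreated
PCR; near-complete CpG methylation, completeness 0.962; partial adenine
methylation; both), and antibody-footprint-style reads in which adenine
labelling is confined to accessible linkers between protected nucleosome
footprints.  Events follow the signal model of the caller itself: an event
for k-mer k on a read with distortion (a, b, d) is drawn from
N(a + b*(mu_k + shift), (d*sigma_k)^2), where the shift is nonzero only for
modified k-mers; stays duplicate events and skips drop k-mers at configured
rates.

Modified-k-mer shifts are deterministic per k-mer: magnitude
``shift_sigma`` * sigma_k scaled by a positional decay that peaks when the
modified base sits mid-k-mer, with a stable hash choosing the sign.  All
randomness flows through one integer-seeded numpy Generator, so every
output is bit-reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .alphabet import segment_read
from .event_hmm import Event, EventSequence
from .pore_model import PoreModel
from .training import TrainingRead, condition_keys

MSSSI_COMPLETENESS = 0.962  # CpG methylation completeness of the treated library


@dataclass
class SimConfig:
    """Study conditions of the simulation.

    Signal distortions: per read a ~ N(0, s_a), b ~ N(1, s_b),
    d ~ N(1, s_d) truncated positive.  ``shift_sigma`` is the separation of
    modified from unmodified k-mer means in units of sigma_k (peak, before
    positional decay).  ``hia5_label_prob`` is the per-adenine labelling
    probability of the partial-methylation conditions; in footprint reads
    labelling applies only inside accessible linkers.
    """

    seed: int
    ref_length: int = 20_000
    gc_content: float = 0.41
    cpg_density: float = 0.02  # CpG starts per bp
    cpg_meth_prob: float = 0.5  # endogenous per-site 5mC probability
    msssi_completeness: float = MSSSI_COMPLETENESS
    hia5_label_prob: float = 0.4
    nucleosome_size: int = 147
    linker_size: int = 30
    s_a: float = 2.0  # pA
    s_b: float = 0.02
    s_d: float = 0.05
    p_stay: float = 0.1
    p_skip: float = 0.01
    shift_sigma: float = 3.0
    positional_decay: bool = True
    event_stdv: float = 1.0
    event_duration: float = 0.002
    k: int = 6


@dataclass
class ReferenceTruth:
    """A simulated reference with its genomic truth tracks."""

    sequence: str
    chrom: str = "sim1"
    methylated_cpgs: frozenset[int] = frozenset()  # positions of the methylated C
    accessible: tuple[tuple[int, int], ...] = ()  # linker intervals, half-open

    @property
    def cpg_positions(self) -> list[int]:
        s = self.sequence
        return [i for i in range(len(s) - 1) if s[i : i + 2] == "CG"]


def _positional_decay(positions: tuple[int, ...], k: int) -> float:
    """Shift attenuation: strongest for mid-k-mer modifications."""
    center = (k - 1) / 2.0
    return max(1.0 - abs(p - center) / k for p in positions)


def kmer_shift(
    mod_letters: str, sigma_k: float, shift_sigma: float, positional_decay: bool = True
) -> float:
    """Signed true mean shift (pA) of a modified k-mer.

    Each modified position (M or Z) contributes shift_sigma * sigma_k,
    scaled (optionally) by a positional decay that peaks mid-k-mer; the
    sign per k-mer comes from a stable hash of the unmodified parent, so
    the same k-mer always shifts the same way.
    """
    k = len(mod_letters)
    mods = tuple(i for i, ch in enumerate(mod_letters) if ch in "MZ")
    if not mods:
        return 0.0
    parent = mod_letters.replace("M", "C").replace("Z", "A")
    sign = 1.0 if hashlib.sha256(parent.encode()).digest()[0] % 2 == 0 else -1.0
    if positional_decay:
        decay = sum(_positional_decay((p,), k) for p in mods) / len(mods)
    else:
        decay = 1.0
    return sign * shift_sigma * sigma_k * decay * len(mods) ** 0.5


def simulate_reference(cfg: SimConfig, rng: np.random.Generator | None = None) -> ReferenceTruth:
    """Random reference with the requested GC content and CpG density.

    CpGs are planted (or broken) after the iid draw until the realised
    density is within 5% of the request; accessible linkers alternate with
    protected footprints starting from a random phase.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    L = cfg.ref_length
    p = np.array(
        [
            (1 - cfg.gc_content) / 2,
            cfg.gc_content / 2,
            cfg.gc_content / 2,
            (1 - cfg.gc_content) / 2,
        ]
    )
    letters = np.array(list("ACGT"))[rng.choice(4, size=L, p=p)]
    target = int(round(cfg.cpg_density * L))
    for _ in range(20):
        starts = np.where((letters[:-1] == "C") & (letters[1:] == "G"))[0]
        diff = target - starts.size
        if abs(diff) <= max(1, int(0.05 * target)):
            break
        if diff > 0:
            cand = rng.choice(L - 1, size=2 * diff, replace=False)
            for i in cand[:diff]:
                letters[i], letters[i + 1] = "C", "G"
        else:
            drop = rng.choice(starts, size=-diff, replace=False)
            letters[drop + 1] = "A"
    seq = "".join(letters)

    cpgs = [i for i in range(L - 1) if seq[i : i + 2] == "CG"]
    meth = frozenset(
        int(pos) for pos in cpgs if rng.random() < cfg.cpg_meth_prob
    )
    accessible = []
    pos = int(rng.integers(0, cfg.nucleosome_size + cfg.linker_size))
    while pos < L:
        lo, hi = pos, min(pos + cfg.linker_size, L)
        accessible.append((lo, hi))
        pos = hi + cfg.nucleosome_size
    return ReferenceTruth(
        sequence=seq, methylated_cpgs=meth, accessible=tuple(accessible)
    )


def _molecule_letters(
    ref: ReferenceTruth,
    start: int,
    end: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    condition: str,
    footprint: bool,
) -> str:
    """Render one molecule's true modification state over [start, end)."""
    letters = list(ref.sequence[start:end])
    if condition in ("mCpG", "both"):
        for i in range(len(letters) - 1):
            if (
                letters[i] == "C"
                and letters[i + 1] == "G"
                and rng.random() < cfg.msssi_completeness
            ):
                letters[i] = "M"
    elif condition == "endogenous":
        for pos in ref.methylated_cpgs:
            i = pos - start
            if 0 <= i < len(letters) - 1:
                letters[i] = "M"
    if condition in ("6mA", "both", "endogenous"):
        if footprint:
            allowed = np.zeros(len(letters), dtype=bool)
            for lo, hi in ref.accessible:
                lo, hi = max(lo, start), min(hi, end)
                if lo < hi:
                    allowed[lo - start : hi - start] = True
        else:
            allowed = np.ones(len(letters), dtype=bool)
        for i, ch in enumerate(letters):
            if ch == "A" and allowed[i] and rng.random() < cfg.hia5_label_prob:
                letters[i] = "Z"
    return "".join(letters)


def simulate_read_events(
    molecule: str,
    ref_start: int,
    read_id: str,
    model: PoreModel,
    cfg: SimConfig,
    rng: np.random.Generator,
    scaling_override: tuple[float, float, float] | None = None,
) -> EventSequence:
    """Generate the event sequence of one molecule.

    Walks the molecule's k-mers in order; each k-mer is skipped with
    p_skip, otherwise emits one event plus geometrically many stays.  The
    eventalign-style labels carry the unmodified reference k-mer, as a real
    aligner would.
    """
    k = model.k
    if scaling_override is not None:
        a, b, d = scaling_override
    else:
        a = rng.normal(0.0, cfg.s_a)
        b = abs(rng.normal(1.0, cfg.s_b))
        d = abs(rng.normal(1.0, cfg.s_d))
        d = max(d, 0.05)
    events: list[Event] = []
    kmers: list[str] = []
    for j in range(len(molecule) - k + 1):
        if rng.random() < cfg.p_skip:
            continue
        mod_kmer = molecule[j : j + k]
        parent = mod_kmer.replace("M", "C").replace("Z", "A")
        comp = model[parent][0]
        mean = comp.mean + kmer_shift(
            mod_kmer, comp.sd, cfg.shift_sigma, cfg.positional_decay
        )
        n_events = 1
        while rng.random() < cfg.p_stay:
            n_events += 1
        for _ in range(n_events):
            e = rng.normal(a + b * mean, d * comp.sd)
            events.append(
                Event(
                    mean_current=max(e, 1e-3),
                    stdv=cfg.event_stdv,
                    duration=cfg.event_duration,
                    ref_kmer_index=ref_start + j,
                )
            )
            kmers.append(parent)
    if not events:  # pathological skip run; emit the first k-mer once
        comp = model[molecule[:k].replace("M", "C").replace("Z", "A")][0]
        events = [
            Event(
                mean_current=max(rng.normal(a + b * comp.mean, d * comp.sd), 1e-3),
                stdv=cfg.event_stdv,
                duration=cfg.event_duration,
                ref_kmer_index=ref_start,
            )
        ]
        kmers = [molecule[:k].replace("M", "C").replace("Z", "A")]
    return EventSequence(
        read_id=read_id,
        strand="+",
        events=events,
        ref_start=ref_start,
        contig="sim1",
        ref_kmers=kmers,
    )


def window_truth(
    molecule: str,
    ref_start: int,
    read_id: str,
    ref: ReferenceTruth,
    k: int = 6,
    window_size: int = 50,
) -> pd.DataFrame:
    """Per-window modification truth of one molecule, using the same
    segmentation as the caller (joins on read_id/start/end/kind)."""
    end = ref_start + len(molecule)
    windows = segment_read(
        ref.sequence, ref_start, end, k=k, window_size=window_size, chrom=ref.chrom
    )
    rows = []
    for w in windows:
        seg = molecule[w.ref_start - ref_start : w.ref_end - ref_start]
        n_mod_cpg = sum(
            1 for pos in w.cpg_positions if molecule[pos - ref_start] == "M"
        )
        n_z = seg.count("Z")
        if w.kind == "cpg_substring":
            truth = n_mod_cpg > 0
        else:
            truth = n_z > 0
        rows.append(
            (
                read_id, ref.chrom, w.ref_start, w.ref_end, w.kind, truth,
                len(w.cpg_positions), n_mod_cpg, n_z,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "chrom", "start", "end", "kind", "truth",
            "n_cpg", "n_modified_cpg", "n_z",
        ],
    )


def simulate_reads(
    ref: ReferenceTruth,
    model: PoreModel,
    cfg: SimConfig,
    n_reads: int,
    read_length: int,
    rng: np.random.Generator | None = None,
    condition: str = "endogenous",
    footprint: bool = True,
    hap_meth_probs: tuple[float, float] | None = None,
    return_molecules: bool = False,
):
    """Simulate labelled reads: (events, per-window truth, haplotags).

    ``condition`` "endogenous" draws footprint-style reads with the
    genomic 5mC truth; the four training tags (unmodified/mCpG/6mA/both)
    emulate the treated PCR libraries (no footprint, no endogenous truth).
    ``hap_meth_probs`` optionally makes 5mC allele-specific: reads are
    split over two haplotypes whose CpGs methylate with the given
    per-allele probabilities (overriding the genomic truth).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    L = len(ref.sequence)
    reads, truths, haps = [], [], []
    molecules: dict[str, tuple[int, str]] = {}
    for i in range(n_reads):
        start = int(rng.integers(0, max(L - read_length, 1)))
        end = min(start + read_length, L)
        read_id = f"read{i:05d}"
        hap = int(rng.integers(1, 3))
        local_cfg = cfg
        local_ref = ref
        if hap_meth_probs is not None:
            # per-allele methylation: redraw site truth at the allele rate
            p_meth = hap_meth_probs[hap - 1]
            meth = frozenset(
                pos
                for pos in ref.cpg_positions
                if start <= pos < end and rng.random() < p_meth
            )
            local_ref = replace(ref, methylated_cpgs=meth)
        molecule = _molecule_letters(
            local_ref, start, end, local_cfg, rng, condition, footprint
        )
        reads.append(
            simulate_read_events(molecule, start, read_id, model, cfg, rng)
        )
        truths.append(window_truth(molecule, start, read_id, local_ref, k=cfg.k))
        haps.append((read_id, hap))
        molecules[read_id] = (start, molecule)
    truth_df = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=["read_id", "chrom", "start", "end", "kind", "truth"])
    )
    hap_df = pd.DataFrame(haps, columns=["read_id", "haplotype"])
    if return_molecules:
        return reads, truth_df, hap_df, molecules
    return reads, truth_df, hap_df


def simulate_training_conditions(
    ref: ReferenceTruth,
    model: PoreModel,
    cfg: SimConfig,
    n_reads_per_condition: int,
    read_length: int,
    rng: np.random.Generator | None = None,
) -> dict[str, list[TrainingRead]]:
    """The four training libraries as condition-tagged training reads.

    PCR amplicons carry no marks; the treated libraries follow the
    configured CpG completeness and partial adenine labelling, genome-wide
    (no footprint — naked DNA).  Keys are rendered per condition so the
    k-bar pooling happens exactly as with real partially labelled data.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    datasets: dict[str, list[TrainingRead]] = {}
    for tag in ("unmodified", "mCpG", "6mA", "both"):
        reads, _, _ = simulate_reads(
            ref,
            model,
            cfg,
            n_reads_per_condition,
            read_length,
            rng=rng,
            condition=tag,
            footprint=False,
        )
        datasets[tag] = [
            TrainingRead(
                events=ev,
                keys=condition_keys(
                    ref.sequence[ev.ref_start : ev.ref_start + _span(ev, cfg.k)],
                    tag,
                    k=cfg.k,
                ),
            )
            for ev in reads
        ]
        # keep read ids unique across conditions
        for ev in reads:
            ev.read_id = f"{tag}:{ev.read_id}"
    return datasets


def _span(events: EventSequence, k: int) -> int:
    last = max(e.ref_kmer_index for e in events.events if e.ref_kmer_index is not None)
    return last - events.ref_start + k


def reference_to_fasta(ref: ReferenceTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.chrom}\n")
        for i in range(0, len(ref.sequence), 80):
            fh.write(ref.sequence[i : i + 80] + "\n")


def truth_to_bed(ref: ReferenceTruth, path) -> None:
    """Truth tracks as BED: methylated CpGs and accessible linkers."""
    with open(path, "w") as fh:
        for pos in sorted(ref.methylated_cpgs):
            fh.write(f"{ref.chrom}\t{pos}\t{pos + 2}\tmCpG\t0\t+\n")
        for lo, hi in ref.accessible:
            fh.write(f"{ref.chrom}\t{lo}\t{hi}\taccessible\t0\t+\n")
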