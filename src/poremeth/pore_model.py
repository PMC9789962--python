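"""Per-k-mer Gaussian emission models ("pore models").

A pore model maps each k-mer — or pooled A/Z class — to one or more Gaussian
components describing the event current expected while that k-mer dwells in
the pore.  Unmodified k-mers have a single component (the ONT-style
reference model N(mu_k, sigma_k^2)); trained modified classes may carry a
mixture.  The on-disk dialect is a TSV with one row per component.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field

from .alphabet import CLASS_6MA_SUFFIX, STANDARD, enumerate_alphabet, is_valid_kmer

_WEIGHT_TOL = 1e-9


class ModelFormatError(ValueError):
    """A pore-model table violates the dialect or its invariants."""


@dataclass(frozen=True)
class EmissionComponent:
    """One Gaussian component of a k-mer's emission distribution (pA)."""

    mean: float
    sd: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ModelFormatError(f"sd must be positive, got {self.sd}")
        if not 0.0 <= self.weight <= 1.0 + _WEIGHT_TOL:
            raise ModelFormatError(f"weight must be in [0,1], got {self.weight}")


@dataclass
class PoreModel:
    """Map from k-mer/class label to ordered emission components."""

    k: int
    entries: dict[str, list[EmissionComponent]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> list[EmissionComponent]:
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(f"k-mer/class {key!r} absent from pore model") from None

    def set_entry(
        self, key: str, components: list[EmissionComponent], provenance: str
    ) -> None:
        total = sum(c.weight for c in components)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ModelFormatError(
                f"component weights for {key!r} sum to {total}, expected 1"
            )
        self.entries[key] = list(components)
        self.provenance[key] = provenance

    def copy(self) -> "PoreModel":
        return PoreModel(
            k=self.k,
            entries={k: list(v) for k, v in self.entries.items()},
            provenance=dict(self.provenance),
        )


_COLUMNS = ["kmer", "component_index", "level_mean", "level_stdv", "weight", "provenance"]


def save_model(model: PoreModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for key in sorted(model.entries):
            for idx, comp in enumerate(model.entries[key]):
                fh.write(
                    f"{key}\t{idx}\t{comp.mean:.6f}\t{comp.sd:.6f}"
                    f"\t{comp.weight:.6f}\t{model.provenance.get(key, 'trained')}\n"
                )


def load_model(path) -> PoreModel:
    """Load a pore-model TSV; round-trips ``save_model`` bit-exactly."""
    raw: dict[str, dict[int, EmissionComponent]] = {}
    prov: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_COLUMNS)] != _COLUMNS:
            raise ModelFormatError(
                f"unexpected header {header!r}; expected columns {_COLUMNS}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            kmer, idx_s, mean_s, sd_s, w_s, p = parts[:6]
            idx = int(idx_s)
            if kmer in raw and idx in raw[kmer]:
                raise ModelFormatError(
                    f"duplicate (kmer, component_index) = ({kmer!r}, {idx}) at line {lineno}"
                )
            sd = float(sd_s)
            if sd <= 0:
                raise ModelFormatError(f"non-positive sd {sd} at line {lineno}")
            raw.setdefault(kmer, {})[idx] = EmissionComponent(
                mean=float(mean_s), sd=sd, weight=float(w_s)
            )
            prov[kmer] = p
    if not raw:
        raise ModelFormatError("empty pore-model file")
    k = len(next(iter(raw)).replace(CLASS_6MA_SUFFIX, ""))
    model = PoreModel(k=k)
    for kmer, comps in raw.items():
        ordered = [comps[i] for i in sorted(comps)]
        if sorted(comps) != list(range(len(comps))):
            raise ModelFormatError(f"component indices for {kmer!r} are not 0..n-1")
        model.set_entry(kmer, ordered, prov[kmer])
    return model


def _parent_key(target: str) -> str:
    """Unmodified four-letter parent of a modified k-mer or class label."""
    base = target.removesuffix(CLASS_6MA_SUFFIX)
    return base.replace("M", "C").replace("Z", "A")


def initialize_methylated_model(
    base: PoreModel, targets: set[str] | list[str], sd_increase: float = 2.0
) -> PoreModel:
    """Seed modified entries from their unmodified parents.

    Each target keeps the parent's mean and gets its sd increased by
    ``sd_increase`` pA (default 2), weight 1.  Base entries are untouched.
    """
    model = base.copy()
    for target in sorted(targets):
        parent = _parent_key(target)
        if parent not in base:
            raise KeyError(
                f"parent {parent!r} of target {target!r} absent from base model"
            )
        ref = base[parent][0]
        model.set_entry(
            target,
            [EmissionComponent(mean=ref.mean, sd=ref.sd + sd_increase, weight=1.0)],
            provenance="initialized",
        )
    return model


def modified_lexicon(base: PoreModel) -> set[str]:
    """Every modified k-mer/class key derivable from the base model.

    Covers A-containing classes of each four-letter k-mer, all valid
    M-containing k-mers whose unmethylated parent the base model knows, and
    their doubly modified (M + 6mA) classes.
    """
    keys: set[str] = set()
    for parent in base.entries:
        if set(parent) <= set(STANDARD) and "A" in parent:
            keys.add(parent + CLASS_6MA_SUFFIX)
    for tup in itertools.product("ACGTM", repeat=base.k):
        s = "".join(tup)
        if "M" not in s or not is_valid_kmer(s):
            continue
        if s.replace("M", "C") in base:
            keys.add(s)
            if "A" in s:
                keys.add(s + CLASS_6MA_SUFFIX)
    return keys


def complete_model(base: PoreModel, sd_increase: float = 2.0) -> PoreModel:
    """Base model plus seeded entries for whatever part of the modified
    lexicon it lacks; entries already present (e.g. trained) are kept."""
    missing = {k for k in modified_lexicon(base) if k not in base}
    return initialize_methylated_model(base, missing, sd_increase)


def component_logpdf(
    comp: EmissionComponent, transformed_event: float, variance_scale: float
) -> float:
    """log N(e'; mu_j, (variance_scale * sigma_j)^2)."""
    s = variance_scale * comp.sd
    z = (transformed_event - comp.mean) / s
    return -0.5 * z * z - math.log(s) - 0.5 * math.log(2.0 * math.pi)


def best_component(
    entry: list[EmissionComponent], transformed_event: float, variance_scale: float
) -> EmissionComponent:
    """Component maximising the Gaussian density of a transformed event.

    Ties break deterministically toward the lowest component index.
    """
    best = entry[0]
    best_lp = component_logpdf(best, transformed_event, variance_scale)
    for comp in entry[1:]:
        lp = component_logpdf(comp, transformed_event, variance_scale)
        if lp > best_lp:
            best, best_lp = comp, lp
    return best


def synthetic_pore_model(k: int = 6, mean_range=(70.0, 130.0), sd_range=(1.2, 2.5)) -> PoreModel:
    """Deterministic synthetic pore model over the four-letter k-mers.

    Not an ONT model: per-k-mer means and sds are derived from a stable hash
    of the k-mer string, spread uniformly over realistic pA ranges.  Used by
    the simulator and the test-suite so no proprietary model file is needed.
    """
    model = PoreModel(k=k)
    lo, hi = mean_range
    slo, shi = sd_range
    _, kmers = enumerate_alphabet(k, STANDARD)
    for kmer in kmers:
        digest = hashlib.sha256(kmer.encode()).digest()
        u1 = int.from_bytes(digest[:8], "big") / 2**64
        u2 = int.from_bytes(digest[8:16], "big") / 2**64
        model.set_entry(
            kmer,
            [EmissionComponent(mean=lo + u1 * (hi - lo), sd=slo + u2 * (shi - slo))],
            provenance="ont_reference",
        )
    return model
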