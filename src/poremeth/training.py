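"""EM training of emission parameters from condition-labelled event data.

Training data come from four library conditions: untreated PCR amplicons
(no modification), CpG-methyltransferase-treated (near-complete 5mC in CpG
context), adenine-methyltransferase-treated (partial 6mA), and both.
Partial adenine labelling means events of an A-containing k-mer are a
mixture over modification states, so each modified k-mer (or pooled A/Z
class) is fitted with a Gaussian mixture by EM:

  E-step   gamma_{i,j} = w_j phi_j(e'_i) / sum_j w_j phi_j(e'_i)
  M-step   w_j = mean_i gamma_{i,j}
           mu_j = sum_i gamma_{i,j} e'_i / sum_i gamma_{i,j}
           sigma_j^2 = sum_i gamma_{i,j} ((e'_i - mu_j) b_i/d_i)^2 / sum_i gamma_{i,j}

where e'_i = (e_i - a_i)/b_i is the shift/scale-transformed event and
phi_j is N(mu_j, ((d_i/b_i) sigma_j)^2) — the per-event variance factor
d_i/b_i is the read-level value of the read that produced event i.

Fits are run from a grid of initialisations (means mu_k, mu_k +- 5,
mu_k +- 10; sds sigma_k, sigma_k + 1; weights fixed per component count);
parameters are assigned to the modified entry only when the converged
estimates are consistent across at least half the grid.  The whole
procedure wraps in an outer loop that re-aligns events to k-mers by
Viterbi under the current model, for a fixed number of rounds (default 5).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabet import CLASS_6MA_SUFFIX, collapse_to_class
from .event_hmm import (
    EventSequence,
    HmmConfig,
    InsufficientDataError,
    ReadScaling,
    fit_read_scaling,
    viterbi_align,
)
from .pore_model import (
    EmissionComponent,
    PoreModel,
    _parent_key,
    initialize_methylated_model,
    modified_lexicon,
)

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: canonical condition tags and their treatment aliases
CONDITIONS = {
    "unmodified": "unmodified",
    "PCR": "unmodified",
    "mCpG": "mCpG",
    "M.SssI": "mCpG",
    "6mA": "6mA",
    "Hia5": "6mA",
    "both": "both",
    "M.SssI+Hia5": "both",
}


class ConfigurationError(ValueError):
    pass


@dataclass
class TrainingConfig:
    mean_init_offsets: tuple[float, ...] = (5.0, -5.0, 10.0, -10.0)
    sd_init_offsets: tuple[float, ...] = (0.0, 1.0)
    weight_inits: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: {
            2: (0.95, 0.05),
            3: (0.5, 0.3, 0.2),
            4: (0.25, 0.25, 0.25, 0.25),
        }
    )
    max_em_iterations: int = 1000
    outer_rounds: int = 5
    convergence_tol: float = 1e-3  # pA, on max |delta mu|
    consistency_tol: float = 1.0  # pA, grid-agreement and ref-mean matching
    #: components below this mixture weight are not assignable: the
    #: methylated fraction of every training library is large by design
    #: (96.2% CpG completeness; tens of percent per adenine class), so a
    #: near-empty component is an outlier cluster, not the mark
    assignment_weight_floor: float = 0.1
    min_events_per_component: int = 10
    sd_collapse: float = 0.05  # pA; a narrower component is dropped
    weight_collapse: float = 0.01
    sd_init_increase: float = 2.0  # pA added to sd when seeding modified entries
    max_components: int = 4

    def __post_init__(self) -> None:
        if self.max_em_iterations < 1:
            raise ConfigurationError("max_em_iterations must be >= 1")
        if self.outer_rounds < 1:
            raise ConfigurationError("outer_rounds must be >= 1")


@dataclass
class MixtureFit:
    """Result of one EM run: components as (weight, mean, sd) triples."""

    components: list[tuple[float, float, float]]
    responsibilities: np.ndarray  # (n_events, n_components); rows sum to 1
    converged: bool
    n_events: int
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def means(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.components])


def collect_transformed_events(
    aligned_reads: Iterable[tuple[EventSequence, Sequence[str | None]]],
    scalings: dict[str, ReadScaling],
    collapse: bool = True,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pool shift/scale-transformed events per k-mer or A/Z class.

    Each aligned event contributes (e'_i, d_i/b_i) to exactly one key; raw
    labels containing Z are collapsed to their class label so e.g. TZCACG
    and TACZCG pool together.
    """
    pools: dict[str, tuple[list[float], list[float]]] = {}
    for events, labels in aligned_reads:
        if events.read_id not in scalings:
            raise KeyError(f"no scaling fitted for read {events.read_id!r}")
        sc = scalings[events.read_id]
        varfac = sc.d / sc.b
        for ev, lab in zip(events.events, labels):
            if lab is None:
                continue
            key = lab
            if collapse and "Z" in lab and not lab.endswith(CLASS_6MA_SUFFIX):
                key = collapse_to_class(lab).label
            e_t, v = pools.setdefault(key, ([], []))
            e_t.append((ev.mean_current - sc.a) / sc.b)
            v.append(varfac)
    return {
        key: (np.array(vals), np.array(facs)) for key, (vals, facs) in pools.items()
    }


def fit_gmm(
    values: np.ndarray,
    variance_factors: np.ndarray,
    means_init: Sequence[float],
    sds_init: Sequence[float],
    weights_init: Sequence[float],
    max_iterations: int = 1000,
    tol: float = 1e-3,
    sd_collapse: float = 0.05,
    weight_collapse: float = 0.01,
) -> MixtureFit:
    """EM fit of a Gaussian mixture with per-event variance factors.

    The observed-data log-likelihood is non-decreasing across iterations
    (standard EM guarantee; the per-event factors d_i/b_i are known
    constants, not fitted).  A component collapsing below ``sd_collapse``
    pA or ``weight_collapse`` weight is dropped and the rest renormalised.
    """
    x = np.asarray(values, dtype=float)
    vf = np.asarray(variance_factors, dtype=float)
    n = x.size
    n_comp = len(means_init)
    if n < 10 * n_comp:
        raise InsufficientDataError(
            f"{n} events for a {n_comp}-component mixture; need >= {10 * n_comp}"
        )
    mu = np.array(means_init, dtype=float)
    sd = np.array(sds_init, dtype=float)
    w = np.array(weights_init, dtype=float)
    w = w / w.sum()

    trace: list[float] = []
    converged = False
    gamma = np.full((n, mu.size), 1.0 / mu.size)
    for _ in range(max_iterations):
        # E-step: log w_j + log N(x_i; mu_j, (vf_i sd_j)^2)
        scale = vf[:, None] * sd[None, :]
        z = (x[:, None] - mu[None, :]) / scale
        log_num = np.log(w)[None, :] - 0.5 * z * z - np.log(scale) - LOG_SQRT_2PI
        shift = log_num.max(axis=1)
        expnum = np.exp(log_num - shift[:, None])
        log_den = shift + np.log(expnum.sum(axis=1))
        trace.append(float(log_den.sum()))
        gamma = expnum / expnum.sum(axis=1, keepdims=True)

        # M-step
        nk = gamma.sum(axis=0)
        new_w = nk / n
        new_mu = (gamma * x[:, None]).sum(axis=0) / nk
        resid = (x[:, None] - new_mu[None, :]) / vf[:, None]
        new_sd = np.sqrt((gamma * resid**2).sum(axis=0) / nk)

        keep = (new_sd >= sd_collapse) & (new_w >= weight_collapse)
        if not keep.all():
            if not keep.any():
                keep[np.argmax(new_w)] = True
            mu, sd, w = new_mu[keep], np.maximum(new_sd[keep], sd_collapse), new_w[keep]
            w = w / w.sum()
            gamma = gamma[:, keep]
            gamma = gamma / gamma.sum(axis=1, keepdims=True)
            continue

        delta = np.max(np.abs(new_mu - mu))
        mu, sd, w = new_mu, new_sd, new_w
        if delta < tol:
            converged = True
            break

    return MixtureFit(
        components=[(float(wi), float(mi), float(si)) for wi, mi, si in zip(w, mu, sd)],
        responsibilities=gamma,
        converged=converged,
        n_events=n,
        loglik_trace=trace,
    )


def _fit_gmm_grid(
    values: np.ndarray,
    variance_factors: np.ndarray,
    grid: list[tuple[tuple[float, ...], tuple[float, ...], tuple[float, ...]]],
    cfg: TrainingConfig,
) -> list[MixtureFit]:
    """Run EM from every grid initialisation at once (vectorised over the
    grid axis).  Numerically identical to per-init :func:`fit_gmm` on
    well-behaved pools; collapsing components are masked to zero weight in
    place (the dense equivalent of drop-and-renormalise), and grid points
    leave the batch as they converge."""
    x = np.asarray(values, dtype=float)
    vf = np.asarray(variance_factors, dtype=float)
    n = x.size
    G = len(grid)
    c = len(grid[0][0])
    mu = np.array([g[0] for g in grid])  # (G, c)
    sd = np.array([g[1] for g in grid])
    w = np.array([g[2] for g in grid])
    w = w / w.sum(axis=1, keepdims=True)

    conv = np.zeros(G, dtype=bool)
    gamma = np.full((G, n, c), 1.0 / c)
    active = np.arange(G)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for _ in range(cfg.max_em_iterations):
            amu, asd, aw = mu[active], sd[active], w[active]
            scale = vf[None, :, None] * asd[:, None, :]
            z = (x[None, :, None] - amu[:, None, :]) / scale
            log_num = np.log(aw)[:, None, :] - 0.5 * z * z - np.log(scale) - LOG_SQRT_2PI
            shift = log_num.max(axis=2, keepdims=True)
            expnum = np.where(np.isfinite(log_num), np.exp(log_num - shift), 0.0)
            agamma = expnum / expnum.sum(axis=2, keepdims=True)
            nk = agamma.sum(axis=1)  # (g, c)
            new_w = nk / n
            new_mu = (agamma * x[None, :, None]).sum(axis=1) / nk
            resid = (x[None, :, None] - new_mu[:, None, :]) / vf[None, :, None]
            new_sd = np.sqrt((agamma * resid**2).sum(axis=1) / nk)

            # in-batch collapse handling: a dying component gets weight 0
            # (excluded from the next E-step) and the rest renormalise —
            # the dense equivalent of drop-and-renormalise
            dead = (
                ~np.isfinite(new_mu)
                | ~np.isfinite(new_sd)
                | (new_sd < cfg.sd_collapse)
                | (new_w < cfg.weight_collapse)
            )
            all_dead = dead.all(axis=1)
            if all_dead.any():
                keep = np.argmax(np.where(np.isfinite(new_w), new_w, -1.0), axis=1)
                dead[all_dead, keep[all_dead]] = False
            was_alive = aw > 0
            new_w = np.where(dead, 0.0, np.where(np.isfinite(new_w), new_w, 0.0))
            new_w = new_w / new_w.sum(axis=1, keepdims=True)
            new_mu = np.where(dead | ~was_alive, amu, new_mu)
            new_sd = np.where(dead | ~was_alive, asd, np.maximum(new_sd, cfg.sd_collapse))

            delta = np.where(new_w > 0, np.abs(new_mu - amu), 0.0).max(axis=1)
            newly_dead = (dead & was_alive).any(axis=1)
            done = (delta < cfg.convergence_tol) & ~newly_dead
            mu[active], sd[active], w[active] = new_mu, new_sd, new_w
            gamma[active] = agamma
            conv[active] |= done
            active = active[~done]
            if active.size == 0:
                break

    fits: list[MixtureFit] = []
    for g in range(G):
        alive = w[g] > 0
        resp = gamma[g][:, alive]
        resp = resp / np.maximum(resp.sum(axis=1, keepdims=True), 1e-300)
        fits.append(
            MixtureFit(
                components=[
                    (float(w[g, j]), float(mu[g, j]), float(sd[g, j]))
                    for j in np.flatnonzero(alive)
                ],
                responsibilities=resp,
                converged=bool(conv[g]),
                n_events=n,
            )
        )
    return fits


def initialization_grid(
    ref_mean: float, ref_sd: float, n_components: int, cfg: TrainingConfig
) -> list[tuple[tuple[float, ...], tuple[float, ...], tuple[float, ...]]]:
    """(means, sds, weights) triples spanning the stated initialisation grid.

    The first component starts at the reference mean; the others take
    distinct offsets from {+-5, +-10} pA; all sds start at sigma_k or
    sigma_k + 1; weights are fixed by component count.
    """
    if n_components not in cfg.weight_inits:
        raise ConfigurationError(f"no weight initialisation for {n_components} components")
    weights = cfg.weight_inits[n_components]
    grid = []
    for offs in itertools.combinations(cfg.mean_init_offsets, n_components - 1):
        means = (ref_mean,) + tuple(ref_mean + o for o in offs)
        for ds in cfg.sd_init_offsets:
            grid.append((means, tuple(ref_sd + ds for _ in means), weights))
    return grid


def _fits_agree(a: MixtureFit, b: MixtureFit, tol: float) -> bool:
    ma, mb = np.sort(a.means), np.sort(b.means)
    return ma.size == mb.size and bool(np.all(np.abs(ma - mb) <= tol))


def assign_parameters(
    fits: Sequence[MixtureFit],
    reference: EmissionComponent,
    class_kind: str,
    consistency_tol: float = 1.0,
    weight_floor: float = 0.1,
) -> tuple[list[EmissionComponent] | None, bool]:
    """Pick trained parameters for a modified entry from grid fits.

    Converged fits are grouped by agreement of their sorted means within
    ``consistency_tol``; a group covering at least half of all grid points
    is required.  Two-component entries receive the component whose mean
    departs furthest from the reference; pooled-class entries receive every
    component whose mean differs from the reference, with weights
    renormalised.  Components carrying less than ``weight_floor`` of the
    mixture are not assignable (they model stray events, never the mark,
    whose fraction is large in every training library); if no component
    clears the floor the restriction is waived.  Returns (components,
    trained); (None, False) marks the entry untrained (it keeps its seeded
    values).
    """
    if not fits:
        return None, False
    if class_kind not in ("two_component", "multi_component"):
        raise ConfigurationError(f"unknown class kind {class_kind!r}")
    converged = [f for f in fits if f.converged]
    best_group: list[MixtureFit] = []
    for f in converged:
        group = [g for g in converged if _fits_agree(f, g, consistency_tol)]
        if len(group) > len(best_group):
            best_group = group
    if len(best_group) < 0.5 * len(fits):
        return None, False
    rep = best_group[0]
    eligible = [c for c in rep.components if c[0] >= weight_floor] or list(rep.components)

    if class_kind == "two_component":
        dev = [abs(m - reference.mean) for _, m, _ in eligible]
        _, m, s = eligible[int(np.argmax(dev))]
        return [EmissionComponent(mean=m, sd=s, weight=1.0)], True

    kept = [
        (wi, mi, si)
        for wi, mi, si in eligible
        if abs(mi - reference.mean) > consistency_tol
    ]
    if not kept:
        return None, False
    total = sum(wi for wi, _, _ in kept)
    return (
        [EmissionComponent(mean=m, sd=s, weight=wi / total) for wi, m, s in kept],
        True,
    )


# --- condition-specific reference rendering ----------------------------------


def condition_keys(ref_letters: str, condition: str, k: int = 6) -> list[str]:
    """Pore-model keys of each k-mer of a training read's reference span,
    rendered under the library condition (CpG C -> M; A-containing k-mers
    under their 6mA class)."""
    cond = CONDITIONS.get(condition)
    if cond is None:
        raise ConfigurationError(f"unknown condition {condition!r}")
    letters = list(ref_letters)
    if cond in ("mCpG", "both"):
        for i in range(len(letters) - 1):
            if letters[i] == "C" and letters[i + 1] == "G":
                letters[i] = "M"
    seq = "".join(letters)
    keys = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if cond in ("6mA", "both") and "A" in kmer:
            keys.append(kmer + CLASS_6MA_SUFFIX)
        else:
            keys.append(kmer)
    return keys


@dataclass
class TrainingRead:
    """One training read: its events plus condition-rendered reference keys."""

    events: EventSequence
    keys: list[str]


def _n_components_for(key: str, cfg: TrainingConfig) -> tuple[int, str]:
    base = key.removesuffix(CLASS_6MA_SUFFIX)
    if not key.endswith(CLASS_6MA_SUFFIX):
        return 2, "two_component"  # methylated-CpG k-mer: meth + residual unmeth
    m = base.count("A")
    n = min(1 + (2**m - 1), cfg.max_components)
    return n, ("two_component" if n == 2 else "multi_component")


def _scaling_labels(read: TrainingRead, base: PoreModel) -> list[str | None]:
    """Per-event labels usable for scaling: unmodified-parent k-mers of
    positions that the condition leaves unmodified; falls back to all
    parents when too few survive."""
    strict: list[str | None] = []
    loose: list[str | None] = []
    for ev in read.events.events:
        cond_key = None
        if ev.ref_kmer_index is not None:
            j = ev.ref_kmer_index - read.events.ref_start
            if 0 <= j < len(read.keys):
                cond_key = read.keys[j]
        parent = _parent_key(cond_key) if cond_key else None
        loose.append(parent)
        strict.append(parent if (cond_key is not None and cond_key == parent) else None)
    if sum(lab is not None for lab in strict) >= 30:
        return strict
    return loose


def train(
    datasets: dict[str, list[TrainingRead]],
    base_model: PoreModel,
    cfg: TrainingConfig | None = None,
    hmm_cfg: HmmConfig | None = None,
) -> PoreModel:
    """Full training loop: seed modified entries, then alternate Viterbi
    realignment and grid EM for ``cfg.outer_rounds`` rounds.

    ``datasets`` maps a condition tag (unmodified / mCpG / 6mA / both, or
    their treatment aliases) to training reads.  The returned model carries
    the final round's assignments; entries without a consistent fit keep
    their seeded (sd + 2) values and provenance "initialized".
    """
    cfg = cfg or TrainingConfig()
    hmm_cfg = hmm_cfg or HmmConfig()
    if not datasets:
        raise ConfigurationError("no training datasets supplied")
    for tag in datasets:
        if tag not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {tag!r}")

    targets = {k for k in modified_lexicon(base_model) if k not in base_model}
    model = initialize_methylated_model(base_model, targets, cfg.sd_init_increase)

    scalings: dict[str, ReadScaling] = {}
    for reads in datasets.values():
        for read in reads:
            scalings[read.events.read_id] = fit_read_scaling(
                read.events, _scaling_labels(read, base_model), base_model
            )

    for _ in range(cfg.outer_rounds):
        # Alignment model: modified entries additionally carry their parent's
        # reference component, because under partial labelling the events at
        # a class position are a mixture of modified and unmodified states —
        # a modified-only entry would misalign the unmodified majority.
        align_model = model.copy()
        for key in targets:
            if model.provenance.get(key) != "trained":
                continue
            parent = _parent_key(key)
            comps = list(model[key]) + [base_model[parent][0]]
            n = len(comps)
            align_model.set_entry(
                key,
                [EmissionComponent(c.mean, c.sd, 1.0 / n) for c in comps],
                "trained",
            )
        aligned = []
        for reads in datasets.values():
            for read in reads:
                aln = viterbi_align(
                    read.events, read.keys, align_model, scalings[read.events.read_id], hmm_cfg
                )
                labels = [
                    read.keys[j] if state == "match" else None
                    for state, j in aln.assignments
                ]
                aligned.append((read.events, labels))
        pools = collect_transformed_events(aligned, scalings)

        for key, (values, vfacs) in pools.items():
            if key in base_model:
                continue  # unmodified entries keep their reference parameters
            parent = _parent_key(key)
            if parent not in base_model:
                continue
            ref = base_model[parent][0]
            n_comp, kind = _n_components_for(key, cfg)
            # the component-count guess bows to the data: small pools get
            # fewer components rather than no fit at all
            n_comp = min(n_comp, values.size // cfg.min_events_per_component)
            if n_comp < 2:
                continue
            grid = initialization_grid(ref.mean, ref.sd, n_comp, cfg)
            fits = _fit_gmm_grid(values, vfacs, grid, cfg)
            components, trained = assign_parameters(
                fits, ref, kind, cfg.consistency_tol, cfg.assignment_weight_floor
            )
            if trained and components is not None:
                model.set_entry(key, components, "trained")
    return model
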