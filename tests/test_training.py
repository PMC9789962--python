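"""EM mixture training: recovery, monotonicity, consistency-based
assignment, and the outer Viterbi-retraining loop."""

import numpy as np
import pytest

from poremeth.event_hmm import EventSequence, Event, InsufficientDataError, ReadScaling
from poremeth.pore_model import EmissionComponent, synthetic_pore_model
from poremeth.training import (
    MixtureFit,
    TrainingConfig,
    TrainingRead,
    assign_parameters,
    collect_transformed_events,
    condition_keys,
    fit_gmm,
    initialization_grid,
    train,
)
from poremeth.simulator import SimConfig, simulate_reference, simulate_training_conditions


def _two_component_sample(rng, n=5000, mu=(80.0, 86.0), sd=(2.0, 2.0), w=(0.5, 0.5)):
    comp = rng.choice(len(w), size=n, p=w)
    x = rng.normal(np.take(mu, comp), np.take(sd, comp))
    return x, np.ones(n)


class TestFitGmm:
    def test_two_component_recovery(self, rng):
        """Means recovered within 0.3 pA and weights within 0.05 of truth
        at n=5000 and 3 sigma separation; the fit coincides with an
        independent EM implementation (sklearn) on the same sample."""
        from sklearn.mixture import GaussianMixture

        x, vf = _two_component_sample(rng)
        fit = fit_gmm(x, vf, means_init=(80.0, 85.0), sds_init=(2.0, 2.0),
                      weights_init=(0.95, 0.05))
        means = np.sort(fit.means)
        ws = [w for w, _, _ in sorted(fit.components, key=lambda c: c[1])]
        assert means[0] == pytest.approx(80.0, abs=0.3)
        assert means[1] == pytest.approx(86.0, abs=0.3)
        assert ws[0] == pytest.approx(0.5, abs=0.05)
        gm = GaussianMixture(
            2, means_init=[[80.0], [85.0]], tol=1e-8, max_iter=2000, reg_covar=0.0
        ).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        assert means == pytest.approx(gm.means_.ravel()[order], abs=2e-2)
        assert ws == pytest.approx(gm.weights_[order], abs=5e-3)

    def test_loglik_monotone_every_iteration(self, rng):
        x, vf = _two_component_sample(rng, n=2000)
        fit = fit_gmm(x, vf, (80.0, 90.0), (2.0, 3.0), (0.95, 0.05))
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-7).all()

    def test_responsibilities_rows_sum_to_one(self, rng):
        x, vf = _two_component_sample(rng, n=500)
        fit = fit_gmm(x, vf, (80.0, 86.0), (2.0, 2.0), (0.5, 0.5))
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0)

    def test_single_gaussian_data_degenerates(self, rng):
        x = rng.normal(100.0, 2.0, size=3000)
        fit = fit_gmm(x, np.ones_like(x), (100.0, 105.0), (2.0, 2.0), (0.95, 0.05))
        means = np.sort(fit.means)
        weights = [w for w, _, _ in fit.components]
        assert (means[-1] - means[0] < 0.5) or (min(weights) < 0.05) or len(means) == 1

    def test_heteroscedastic_variance_factors_respected(self, rng):
        """Events from reads with large d/b are down-weighted: sigma is
        estimated on the b/d-rescaled residuals."""
        n = 4000
        vf = rng.choice([1.0, 2.0], size=n)
        x = rng.normal(100.0, 2.0 * vf)
        fit = fit_gmm(x, vf, (100.0, 105.0), (2.0, 2.0), (0.95, 0.05))
        sds = [s for _, _, s in fit.components]
        assert max(sds) < 3.0  # pooled naive sd would be ~3.2

    def test_too_few_events_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gmm(np.ones(15), np.ones(15), (1.0, 2.0), (1.0, 1.0), (0.5, 0.5))

    def test_partial_methylation_weight_recovery(self, rng):
        """True methylated fraction 0.5 is recovered within 0.1."""
        x, vf = _two_component_sample(rng, mu=(100.0, 106.0), w=(0.5, 0.5))
        fit = fit_gmm(x, vf, (100.0, 105.0), (2.0, 2.0), (0.95, 0.05))
        w_meth = [w for w, m, _ in fit.components if abs(m - 106.0) < 1.0]
        assert w_meth and w_meth[0] == pytest.approx(0.5, abs=0.1)


class TestAssignment:
    def _fit(self, comps, converged=True):
        return MixtureFit(
            components=comps,
            responsibilities=np.ones((10, len(comps))) / len(comps),
            converged=converged,
            n_events=10,
        )

    def test_two_component_picks_larger_deviation(self):
        ref = EmissionComponent(100.0, 2.0)
        fits = [self._fit([(0.96, 106.1, 2.4), (0.04, 100.0, 2.0)]) for _ in range(4)]
        comps, trained = assign_parameters(fits, ref, "two_component")
        assert trained
        assert comps[0].mean == pytest.approx(106.1) and comps[0].sd == pytest.approx(2.4)
        assert comps[0].weight == 1.0

    def test_near_empty_outlier_component_not_assigned(self):
        """A 2-event stray cluster far from the reference must not win over
        the majority methylated component."""
        ref = EmissionComponent(70.9, 1.5)
        fits = [self._fit([(0.95, 66.3, 1.4), (0.05, 77.3, 1.2)]) for _ in range(4)]
        comps, trained = assign_parameters(fits, ref, "two_component")
        assert trained and comps[0].mean == pytest.approx(66.3)

    def test_multi_component_drops_reference_mean(self):
        ref = EmissionComponent(100.0, 2.0)
        fits = [
            self._fit([(0.4, 100.1, 2.0), (0.35, 105.9, 2.2), (0.25, 111.8, 2.5)])
            for _ in range(4)
        ]
        comps, trained = assign_parameters(fits, ref, "multi_component")
        assert trained
        assert sorted(c.mean for c in comps) == pytest.approx([105.9, 111.8])
        assert sum(c.weight for c in comps) == pytest.approx(1.0)

    def test_no_convergent_fit_leaves_untrained(self):
        ref = EmissionComponent(100.0, 2.0)
        fits = [self._fit([(0.5, 90.0, 2.0), (0.5, 110.0, 2.0)], converged=False)] * 4
        comps, trained = assign_parameters(fits, ref, "two_component")
        assert not trained and comps is None

    def test_inconsistent_grid_leaves_untrained(self):
        ref = EmissionComponent(100.0, 2.0)
        fits = [
            self._fit([(0.5, 100.0, 2.0), (0.5, 103.0 + 5 * i, 2.0)])
            for i in range(4)
        ]
        comps, trained = assign_parameters(fits, ref, "two_component")
        assert not trained

    def test_label_switching_invariance(self):
        ref = EmissionComponent(100.0, 2.0)
        a = [self._fit([(0.95, 100.0, 2.0), (0.05, 106.0, 2.4)]) for _ in range(4)]
        b = [self._fit([(0.05, 106.0, 2.4), (0.95, 100.0, 2.0)]) for _ in range(4)]
        comps_a, _ = assign_parameters(a, ref, "two_component")
        comps_b, _ = assign_parameters(b, ref, "two_component")
        assert comps_a == comps_b


class TestCollect:
    def _events(self, read_id, means, start=0):
        return EventSequence(
            read_id=read_id, strand="+",
            events=[Event(m, ref_kmer_index=start + i) for i, m in enumerate(means)],
            ref_start=start,
        )

    def test_shift_scale_transform(self):
        ev = self._events("r1", [110.0])
        pools = collect_transformed_events(
            [(ev, ["ACG"])], {"r1": ReadScaling(10.0, 1.0, 1.0)}
        )
        assert pools["ACG"][0][0] == pytest.approx(100.0)

    def test_pooling_across_reads_keeps_variance_factors(self):
        e1, e2 = self._events("r1", [100.0]), self._events("r2", [100.0])
        pools = collect_transformed_events(
            [(e1, ["ACG"]), (e2, ["ACG"])],
            {"r1": ReadScaling(0, 1.0, 1.0), "r2": ReadScaling(0, 1.0, 2.0)},
        )
        assert sorted(pools["ACG"][1]) == [1.0, 2.0]

    def test_z_labels_collapse_to_class(self):
        e1, e2 = self._events("r1", [100.0]), self._events("r2", [100.0])
        pools = collect_transformed_events(
            [(e1, ["TZC"]), (e2, ["TAC"])],
            {"r1": ReadScaling(0, 1, 1), "r2": ReadScaling(0, 1, 1)},
        )
        assert "TZC" not in pools
        assert len(pools["TAC+6mA"][0]) == 1 and len(pools["TAC"][0]) == 1

    def test_missing_scaling_rejected(self):
        with pytest.raises(KeyError):
            collect_transformed_events([(self._events("r1", [100.0]), ["ACG"])], {})


class TestConditionKeys:
    def test_mcpg_renders_m(self):
        assert condition_keys("TACGT", "mCpG", k=3) == ["TAM", "AMG", "MGT"]

    def test_hia5_flags_adenine_kmers(self):
        assert condition_keys("TACGT", "6mA", k=3) == ["TAC+6mA", "ACG+6mA", "CGT"]

    def test_both_combines(self):
        assert condition_keys("TACGT", "both", k=3) == ["TAM+6mA", "AMG+6mA", "MGT"]

    def test_unknown_condition_rejected(self):
        from poremeth.training import ConfigurationError

        with pytest.raises(ConfigurationError):
            condition_keys("TACGT", "banana", k=3)


class TestInitializationGrid:
    def test_grid_spans_stated_offsets(self):
        cfg = TrainingConfig()
        grid = initialization_grid(100.0, 2.0, 2, cfg)
        first_means = {g[0] for g in grid}
        assert (100.0, 105.0) in first_means and (100.0, 90.0) in first_means
        sds = {g[1] for g in grid}
        assert (2.0, 2.0) in sds and (3.0, 3.0) in sds
        assert all(g[2] == (0.95, 0.05) for g in grid)

    def test_weight_inits_match_component_count(self):
        cfg = TrainingConfig()
        assert all(g[2] == (0.5, 0.3, 0.2) for g in initialization_grid(100, 2, 3, cfg))
        assert all(
            g[2] == (0.25, 0.25, 0.25, 0.25)
            for g in initialization_grid(100, 2, 4, cfg)
        )


@pytest.fixture(scope="module")
def small_training_run():
    """A complete (scaled-down) training run at k=3 shared by the loop tests."""
    model = synthetic_pore_model(3)
    cfg = SimConfig(seed=5, ref_length=900, k=3, cpg_density=0.03)
    rng = np.random.default_rng(cfg.seed)
    ref = simulate_reference(cfg, rng)
    datasets = simulate_training_conditions(ref, model, cfg, 30, 300, rng)
    trained = train(datasets, model, TrainingConfig(outer_rounds=2))
    return model, cfg, ref, trained


class TestTrainLoop:
    def test_unmodified_entries_untouched(self, small_training_run):
        base, _, _, trained = small_training_run
        for key, comps in base.entries.items():
            assert trained[key] == comps

    def test_mcpg_dataset_recovers_uniform_shift(self):
        """Training on a CpG-methylated library with a uniform true shift
        recovers trained M-entry means with MAE < 0.5 pA."""
        from poremeth.simulator import kmer_shift

        model = synthetic_pore_model(3)
        cfg = SimConfig(
            seed=9, ref_length=900, k=3, cpg_density=0.04, positional_decay=False
        )
        rng = np.random.default_rng(cfg.seed)
        ref = simulate_reference(cfg, rng)
        ds = simulate_training_conditions(ref, model, cfg, 50, 300, rng)
        trained = train(
            {"mCpG": ds["mCpG"], "unmodified": ds["unmodified"]},
            model,
            TrainingConfig(outer_rounds=2),
        )
        errors = []
        for key, comps in trained.entries.items():
            if trained.provenance.get(key) != "trained" or "M" not in key:
                continue
            if key.endswith("+6mA"):
                continue
            ref_comp = model[key.replace("M", "C")][0]
            truth = ref_comp.mean + kmer_shift(
                key, ref_comp.sd, cfg.shift_sigma, positional_decay=False
            )
            errors.append(min(abs(c.mean - truth) for c in comps))
        assert len(errors) >= 10
        assert np.mean(errors) < 0.5

    def test_recovers_adenine_class_shifts(self, small_training_run):
        """Trained single-adenine (centre-position) class means land within
        1 pA of the simulator's true shifted means on average; edge-position
        classes, whose decayed shifts overlap the reference more, stay
        within the shift scale."""
        from poremeth.simulator import kmer_shift

        base, cfg, _, trained = small_training_run
        center, edge = [], []
        for key, comps in trained.entries.items():
            if trained.provenance.get(key) != "trained" or not key.endswith("+6mA"):
                continue
            parent = key.removesuffix("+6mA")
            if parent.count("A") != 1 or "M" in parent:
                continue
            ref_comp = base[parent][0]
            truth = ref_comp.mean + kmer_shift(
                parent.replace("A", "Z"), ref_comp.sd, cfg.shift_sigma
            )
            err = min(abs(c.mean - truth) for c in comps)
            (center if parent[1] == "A" else edge).append(err)
        assert len(center) >= 5 and len(edge) >= 5
        assert np.mean(center) < 1.0
        assert np.mean(edge) < 2.5

    def test_untrained_entries_keep_seeded_values(self, small_training_run):
        base, _, _, trained = small_training_run
        seeded = [
            key
            for key, prov in trained.provenance.items()
            if prov == "initialized"
        ]
        for key in seeded[:20]:
            parent = key.removesuffix("+6mA").replace("M", "C").replace("Z", "A")
            assert trained[key][0].mean == base[parent][0].mean
            assert trained[key][0].sd == base[parent][0].sd + 2.0
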