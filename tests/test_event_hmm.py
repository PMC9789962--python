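"""Signal-HMM tests: scaling fit, emissions, forward/Viterbi vs an
exhaustive path-enumeration oracle."""

import itertools
import math

import numpy as np
import pytest

from poremeth.event_hmm import (
    DegenerateDesignError,
    Event,
    EventSequence,
    HmmConfig,
    InsufficientDataError,
    ReadScaling,
    emission_logpdf,
    fit_read_scaling,
    forward_loglik,
    viterbi_align,
)
from poremeth.pore_model import EmissionComponent, PoreModel

from conftest import make_events


# --- independent oracle -------------------------------------------------------
# Re-derives the documented state semantics from scratch: emitting states are
# PRE, (j, m), (j, b), POST; initial/transition probabilities are computed
# directly and all state sequences are enumerated.


def _oracle_states(K):
    return ["PRE", "POST"] + [(j, kind) for j in range(K) for kind in "mb"]


def _oracle_entry(K, cfg):
    w = [cfg.p_skip**j * (1 - cfg.p_skip) for j in range(K)]
    w[K - 1] = cfg.p_skip ** (K - 1)
    return w


def _oracle_init(state, K, cfg):
    entry = _oracle_entry(K, cfg)
    if state == "PRE":
        return cfg.p_softclip
    if state == "POST":
        return 0.0
    j, kind = state
    p = (1 - cfg.p_softclip) * entry[j]
    return p * (cfg.p_bad if kind == "b" else 1 - cfg.p_bad)


def _oracle_trans(s, s2, K, cfg):
    entry = _oracle_entry(K, cfg)
    if s == "POST":
        return 1.0 if s2 == "POST" else 0.0
    if s == "PRE":
        if s2 == "PRE":
            return cfg.p_stay
        if s2 == "POST":
            return 0.0
        j, kind = s2
        p = (1 - cfg.p_stay) * entry[j]
        return p * (cfg.p_bad if kind == "b" else 1 - cfg.p_bad)
    j, kind = s
    move = (1 - cfg.p_stay) if kind == "m" else 1.0
    if s2 == "PRE":
        return 0.0
    if s2 == s and kind == "m":
        return cfg.p_stay
    if s2 == "POST":
        return move * cfg.p_skip ** (K - 1 - j)
    j2, kind2 = s2
    if j2 <= j:
        return 0.0
    w = cfg.p_skip ** (j2 - j - 1) * (1 - cfg.p_skip)
    return move * w * (cfg.p_bad if kind2 == "b" else 1 - cfg.p_bad)


def _oracle_emit(state, e, keys, model, scaling, cfg):
    if state in ("PRE", "POST"):
        return cfg.softclip_emission
    j, kind = state
    factor = 1.0 if kind == "m" else cfg.bad_sd_factor
    best = -np.inf
    for comp in model[keys[j]]:
        s = scaling.d * comp.sd * factor
        z = (e - (scaling.a + scaling.b * comp.mean)) / s
        best = max(best, math.exp(-0.5 * z * z) / (s * math.sqrt(2 * math.pi)))
    return best


def oracle_path_probs(events, keys, model, scaling, cfg):
    """Probability of every state sequence; returns (sum, max)."""
    K = len(keys)
    states = _oracle_states(K)
    means = [ev.mean_current for ev in events.events]
    total, best = 0.0, 0.0
    for path in itertools.product(states, repeat=len(means)):
        p = _oracle_init(path[0], K, cfg) * _oracle_emit(
            path[0], means[0], keys, model, scaling, cfg
        )
        for t in range(1, len(path)):
            if p == 0.0:
                break
            p *= _oracle_trans(path[t - 1], path[t], K, cfg) * _oracle_emit(
                path[t], means[t], keys, model, scaling, cfg
            )
        total += p
        best = max(best, p)
    return total, best


def _model_from_means(means, sd=2.0, k=1):
    m = PoreModel(k=k)
    for i, mu in enumerate(means):
        m.set_entry(f"K{i}", [EmissionComponent(mu, sd)], "ont_reference")
    return m


IDENT = ReadScaling(0.0, 1.0, 1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_kmers,n_events,seed", [
        (1, 1, 0), (1, 3, 1), (2, 2, 2), (2, 4, 3), (3, 3, 4),
        (3, 5, 5), (4, 4, 6), (4, 6, 7), (2, 6, 8), (4, 2, 9),
    ])
    def test_forward_and_viterbi_match_enumeration(self, n_kmers, n_events, seed):
        """Forward equals the sum, Viterbi the max, over all enumerated
        state paths, within 1e-9 (relative, in log space)."""
        rng = np.random.default_rng(seed)
        mus = rng.uniform(70, 130, size=n_kmers)
        model = _model_from_means(mus)
        keys = [f"K{i}" for i in range(n_kmers)]
        events = make_events(rng.uniform(70, 130, size=n_events))
        cfg = HmmConfig(p_stay=0.15, p_skip=0.05, p_bad=0.01, p_softclip=0.1)
        total, best = oracle_path_probs(events, keys, model, IDENT, cfg)
        assert forward_loglik(events, keys, model, IDENT, cfg) == pytest.approx(
            math.log(total), abs=1e-9
        )
        aln = viterbi_align(events, keys, model, IDENT, cfg)
        assert aln.log_prob == pytest.approx(math.log(best), abs=1e-9)

    def test_viterbi_never_exceeds_forward(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_kmers = int(rng.integers(1, 5))
            model = _model_from_means(rng.uniform(70, 130, size=n_kmers))
            keys = [f"K{i}" for i in range(n_kmers)]
            events = make_events(rng.uniform(70, 130, size=int(rng.integers(1, 7))))
            cfg = HmmConfig()
            assert viterbi_align(events, keys, model, IDENT, cfg).log_prob <= (
                forward_loglik(events, keys, model, IDENT, cfg) + 1e-12
            )

    def test_zero_skip_probability_is_handled(self):
        model = _model_from_means([90.0, 110.0])
        events = make_events([90.0, 110.0])
        cfg = HmmConfig(p_stay=0.1, p_skip=0.0, p_bad=0.01, p_softclip=0.0)
        total, best = oracle_path_probs(events, ["K0", "K1"], model, IDENT, cfg)
        assert forward_loglik(events, ["K0", "K1"], model, IDENT, cfg) == pytest.approx(
            math.log(total), abs=1e-9
        )


class TestForward:
    def test_single_kmer_single_event_reduces_to_emission(self, toy_model):
        cfg = HmmConfig(p_stay=0, p_skip=0, p_bad=0, p_softclip=0)
        events = make_events([100.0])
        assert forward_loglik(events, ["ACG"], toy_model, IDENT, cfg) == pytest.approx(
            emission_logpdf(events.events[0], "ACG", toy_model)
        )

    def test_shift_equivariance(self):
        """Likelihood is invariant to moving a shift between the read
        scaling and the model means."""
        model_a = _model_from_means([90.0, 100.0, 120.0])
        model_b = _model_from_means([100.0, 110.0, 130.0])
        keys = ["K0", "K1", "K2"]
        events = make_events([92.0, 103.0, 118.0])
        cfg = HmmConfig()
        ll_a = forward_loglik(events, keys, model_a, ReadScaling(10.0, 1.0, 1.0), cfg)
        ll_b = forward_loglik(events, keys, model_b, IDENT, cfg)
        assert ll_a == pytest.approx(ll_b, abs=1e-9)

    def test_true_sequence_beats_disrupted_sequence(self):
        """The generating sequence outscores one whose k-mer means are
        shifted by 3 sigma at two positions, in >= 95% of replicates."""
        rng = np.random.default_rng(42)
        sd = 2.0
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            mus = rng.uniform(70, 130, size=4)
            true_model = _model_from_means(mus, sd=sd)
            shifted = mus.copy()
            shifted[1] += 3 * sd
            shifted[2] -= 3 * sd
            alt_model = _model_from_means(shifted, sd=sd)
            keys = [f"K{i}" for i in range(4)]
            events = make_events(rng.normal(mus, sd))
            cfg = HmmConfig()
            if forward_loglik(events, keys, true_model, IDENT, cfg) > forward_loglik(
                events, keys, alt_model, IDENT, cfg
            ):
                wins += 1
        assert wins >= 0.95 * n_rep

    def test_bad_state_absorbs_outlier(self):
        """Appending an outlier explained by the bad state costs less
        than replacing a matched event with that outlier."""
        model = _model_from_means([90.0, 100.0, 110.0])
        keys = ["K0", "K1", "K2"]
        cfg = HmmConfig()
        base = [90.0, 100.0, 110.0]
        ll_clean = forward_loglik(make_events(base), keys, model, IDENT, cfg)
        ll_extra = forward_loglik(make_events(base + [300.0]), keys, model, IDENT, cfg)
        ll_replaced = forward_loglik(
            make_events([90.0, 300.0, 110.0]), keys, model, IDENT, cfg
        )
        assert ll_clean - ll_extra < ll_clean - ll_replaced


class TestViterbi:
    def test_noiseless_identity_alignment(self):
        model = _model_from_means([80.0, 100.0, 120.0])
        keys = ["K0", "K1", "K2"]
        events = make_events([80.0, 100.0, 120.0])
        aln = viterbi_align(events, keys, model, IDENT, HmmConfig())
        assert [a for a in aln.assignments] == [("match", 0), ("match", 1), ("match", 2)]

    def test_duplicated_event_uses_stay(self):
        model = _model_from_means([80.0, 100.0, 120.0])
        keys = ["K0", "K1", "K2"]
        events = make_events([80.0, 100.0, 100.0, 120.0])
        aln = viterbi_align(events, keys, model, IDENT, HmmConfig())
        assert aln.assignments == [
            ("match", 0), ("match", 1), ("match", 1), ("match", 2)
        ]

    def test_assignments_monotone(self):
        rng = np.random.default_rng(3)
        model = _model_from_means(rng.uniform(70, 130, size=4))
        keys = [f"K{i}" for i in range(4)]
        events = make_events(rng.uniform(70, 130, size=8))
        aln = viterbi_align(events, keys, model, IDENT, HmmConfig())
        ks = [j for _, j in aln.assignments if j is not None]
        assert ks == sorted(ks)


class TestReadScaling:
    def test_perfect_fit_recovers_identity(self, toy_model):
        keys = sorted(toy_model.entries)[:40]
        means = [toy_model[k][0].mean for k in keys]
        events = make_events(means)
        sc = fit_read_scaling(events, keys, toy_model)
        assert sc.a == pytest.approx(0.0, abs=1e-8)
        assert sc.b == pytest.approx(1.0, abs=1e-10)
        assert sc.d == 0.01  # zero-residual fit clamps at the floor

    def test_recovers_known_distortion(self, toy_model, rng):
        """(a, b, d) = (10, 1.05, 1.2) recovered within (0.5 pA, 0.01, 0.1)
        from 500 simulated events."""
        keys = list(rng.choice(sorted(toy_model.entries), size=500))
        mu = np.array([toy_model[k][0].mean for k in keys])
        sd = np.array([toy_model[k][0].sd for k in keys])
        e = rng.normal(10.0 + 1.05 * mu, 1.2 * sd)
        events = make_events(np.maximum(e, 1.0))
        sc = fit_read_scaling(events, keys, toy_model)
        assert sc.a == pytest.approx(10.0, abs=0.5)
        assert sc.b == pytest.approx(1.05, abs=0.01)
        assert sc.d == pytest.approx(1.2, abs=0.1)

    def test_insufficient_events_rejected(self, toy_model):
        keys = sorted(toy_model.entries)[:10]
        events = make_events([toy_model[k][0].mean for k in keys])
        with pytest.raises(InsufficientDataError):
            fit_read_scaling(events, keys, toy_model)

    def test_degenerate_design_rejected(self):
        model = _model_from_means([100.0] * 1)
        events = make_events([100.0] * 40)
        with pytest.raises(DegenerateDesignError):
            fit_read_scaling(events, ["K0"] * 40, model)


class TestEmission:
    def test_closed_form_value(self):
        model = _model_from_means([100.0], sd=2.0)
        lp = emission_logpdf(Event(100.0), "K0", model)
        assert lp == pytest.approx(math.log(1.0 / (2.0 * math.sqrt(2 * math.pi))))

    def test_monotone_decay_from_center(self):
        model = _model_from_means([100.0], sd=2.0)
        lps = [emission_logpdf(Event(100.0 + delta), "K0", model) for delta in (0, 1, 2, 5)]
        assert lps == sorted(lps, reverse=True)
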