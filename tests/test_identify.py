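import numpy as np
import pytest

from oracles import brute_force_sdtw_cost
from squigtail.identify import (
    build_reference,
    classify_cohort,
    classify_read,
    subsequence_dtw,
    znormalize,
)
from squigtail.simulate import SimConfig, preset, simulate_cohort, simulate_read


class TestZnormalize:
    def test_closed_form(self):
        out = znormalize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_idempotent(self, rng):
        x = znormalize(rng.normal(size=50))
        np.testing.assert_allclose(znormalize(x), x, atol=1e-12)

    @pytest.mark.parametrize("bad", [[5.0, 5.0, 5.0], [1.0]])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            znormalize(np.array(bad))


class TestSubsequenceDtw:
    def test_exact_subsequence_costs_zero(self, rng):
        target = rng.normal(size=30)
        query = target[10:18].copy()
        m = subsequence_dtw(query, target)
        assert m.cost == 0
        assert (m.start_idx, m.end_idx) == (10, 18)

    def test_hand_checkable_span(self):
        m = subsequence_dtw(np.zeros(2), np.array([5.0, 5.0, 0.0, 0.0, 5.0]))
        assert m.cost == 0
        assert (m.start_idx, m.end_idx) == (2, 4)

    def test_path_monotone_and_cost_nonnegative(self, rng):
        q, t = rng.normal(size=8), rng.normal(size=20)
        m = subsequence_dtw(q, t)
        assert m.cost >= 0
        qs, ts = zip(*m.path)
        assert all(b - a in (0, 1) for a, b in zip(qs, qs[1:]))
        assert all(b - a in (0, 1) for a, b in zip(ts, ts[1:]))
        assert m.path[0][0] == 0 and m.path[-1][0] == len(q) - 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(777)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            m_len = int(rng.integers(n, 11))
            q = rng.normal(size=n)
            t = rng.normal(size=m_len)
            got = subsequence_dtw(q, t)
            expected = brute_force_sdtw_cost(q, t)
            assert got.cost == pytest.approx(expected, abs=1e-10)

    def test_growing_target_never_increases_cost(self, rng):
        q = rng.normal(size=6)
        core = np.concatenate([q, rng.normal(size=3)])
        prev = np.inf
        target = core
        for _ in range(4):
            cost = subsequence_dtw(q, target).cost
            assert cost <= prev + 1e-12
            prev = cost
            target = np.concatenate([rng.normal(size=2), target, rng.normal(size=2)])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            subsequence_dtw(np.array([]), np.ones(3))


class TestClassifyRead:
    def test_infinite_threshold_matches_everything(self, pore_model):
        cohort = simulate_cohort(5, "control", SimConfig(seed=2), pore_model)
        ref = build_reference(preset("mrna1273")[0].body_seq, pore_model)
        results = classify_cohort([r for r, _ in cohort], ref, threshold=np.inf)
        assert all(r.is_match for r in results)

    def test_noiseless_vaccine_read_low_cost(self, pore_model):
        # event-averaging blends samples across state boundaries, leaving a
        # structural cost floor (~0.16/step) even without noise; the match
        # must sit clearly below the threshold and the negative class (~0.45)
        arch, _ = preset("mrna1273")
        read, _ = simulate_read(arch, SimConfig(seed=3, noise_sd_pA=0), pore_model)
        ref = build_reference(arch.body_seq, pore_model)
        res = classify_read(read, ref)
        assert res.is_match and res.match.cost_per_step < 0.2

    def test_reference_longer_than_read_gives_reason_code(self, pore_model):
        arch, _ = preset("mrna1273")
        read, _ = simulate_read(arch, SimConfig(seed=3), pore_model)
        ref = np.tile(build_reference(arch.body_seq, pore_model), 20)
        res = classify_read(read, ref)
        assert not res.is_match and res.reason == "reference_longer_than_read"

    def test_cohort_separation_at_default_threshold(self, pore_model):
        ref = build_reference(preset("mrna1273")[0].body_seq, pore_model)
        pos = simulate_cohort(40, "mrna1273", SimConfig(seed=21), pore_model)
        neg = simulate_cohort(40, "control", SimConfig(seed=22), pore_model)
        pos_res = classify_cohort([r for r, _ in pos], ref)
        neg_res = classify_cohort([r for r, _ in neg], ref)
        assert np.mean([r.is_match for r in pos_res]) >= 0.95
        assert np.mean([r.is_match for r in neg_res]) <= 0.05

    def test_cost_nondecreasing_in_noise(self, pore_model):
        arch, _ = preset("mrna1273")
        ref = build_reference(arch.body_seq, pore_model)
        means = []
        for noise in (0.5, 1.5, 3.0):
            cohort = simulate_cohort(10, arch, SimConfig(seed=31, noise_sd_pA=noise), pore_model)
            res = classify_cohort([r for r, _ in cohort], ref)
            means.append(np.mean([r.match.cost_per_step for r in res]))
        assert means[0] <= means[1] <= means[2]
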