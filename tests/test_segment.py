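import collections

import numpy as np
import pytest

from oracles import brute_force_viterbi
from squigtail._kernels import viterbi_kernel
from squigtail.segment import (
    QC_PASS,
    SegmentationModel,
    call_cohort,
    call_tail,
    estimate_read_rate,
    pentamer_fraction,
    segment_composite_tail,
    viterbi_segment,
)
from squigtail.simulate import SimConfig, preset, simulate_cohort, simulate_read


@pytest.fixture(scope="module")
def pentamer_model(pore_model):
    return SegmentationModel.from_pore_model(pore_model, mode="pentamer")


@pytest.fixture(scope="module")
def composite_model(pore_model):
    return SegmentationModel.from_pore_model(pore_model, mode="composite")


class TestViterbi:
    def test_matches_exhaustive_enumeration_on_toy_chains(self):
        rng = np.random.default_rng(424242)
        for _ in range(40):
            T = int(rng.integers(2, 13))
            S = int(rng.integers(2, 5))
            log_emit = rng.normal(size=(T, S))
            trans = rng.uniform(0.1, 1.0, size=(S, S))
            # left-to-right structure with some forbidden transitions
            trans[np.tril_indices(S, -1)] = 0.0
            with np.errstate(divide="ignore"):
                log_trans = np.where(trans > 0, np.log(trans), -np.inf)
            log_start = np.full(S, -np.inf)
            log_start[0] = 0.0
            path, ll = viterbi_kernel(log_emit, log_trans, log_start)
            best_ll, _ = brute_force_viterbi(log_emit, log_trans, log_start)
            assert ll == pytest.approx(best_ll, abs=1e-9)
            # the returned path must achieve the reported likelihood
            check = log_start[path[0]] + log_emit[0, path[0]]
            for t in range(1, T):
                check += log_trans[path[t - 1], path[t]] + log_emit[t, path[t]]
            assert check == pytest.approx(ll, abs=1e-9)

    @pytest.mark.parametrize("preset_name,mode", [("mrna1273", "pentamer"), ("bnt162b2", "composite")])
    def test_noiseless_boundaries_match_ground_truth(self, pore_model, preset_name, mode):
        arch, _ = preset(preset_name)
        cfg = SimConfig(dwell_dispersion=0, noise_sd_pA=0, seed=1)
        read, truth = simulate_read(arch, cfg, pore_model)
        model = SegmentationModel.from_pore_model(pore_model, mode=mode, noise_sd_pA=0.5)
        call = call_cohort([read], model, len(arch.body_seq))[0]
        for state, span in truth.boundaries.items():
            got = call.boundaries[state]
            assert abs(got[0] - span[0]) <= 2 and abs(got[1] - span[1]) <= 2

    def test_default_noise_boundaries_close_to_truth(self, pore_model, pentamer_model):
        # the poly(A)/transcript edge carries the stochastic dwell of the
        # k-1 hidden junction nucleotides (sd ~ 26 samples at default
        # dispersion), so per-read errors are bounded distributionally
        arch, _ = preset("mrna1273")
        cohort = simulate_cohort(20, arch, SimConfig(seed=17), pore_model)
        calls = call_cohort([r for r, _ in cohort], pentamer_model, len(arch.body_seq))
        errors = []
        for (read, truth), call in zip(cohort, calls):
            for state in ("adapter", "pentamer", "polya", "transcript"):
                t_span = truth.boundaries[state]
                g_span = call.boundaries[state]
                errors.append(abs(g_span[0] - t_span[0]))
                errors.append(abs(g_span[1] - t_span[1]))
        errors = np.array(errors)
        assert np.quantile(errors, 0.9) <= 50
        assert errors.max() <= 150


class TestReadRate:
    def test_rate_arithmetic(self):
        rate, ok = estimate_read_rate(43 * 300, 300, 3012.0)
        assert ok and rate == pytest.approx(3012 / 43, rel=1e-12)

    def test_out_of_range_and_empty_body(self):
        assert estimate_read_rate(10, 300, 3012.0)[1] is False  # absurdly fast
        assert estimate_read_rate(0, 300, 3012.0)[1] is False

    def test_dispersion_zero_recovers_configured_rate(self, pore_model, pentamer_model):
        arch, _ = preset("mrna1273")
        read, _ = simulate_read(arch, SimConfig(seed=2, dwell_dispersion=0), pore_model)
        call = call_cohort([read], pentamer_model, len(arch.body_seq))[0]
        assert call.read_rate_nt_per_s == pytest.approx(70.0, rel=0.01)

    def test_default_noise_cohort_rates_within_5_percent(self, pore_model, pentamer_model):
        arch, _ = preset("mrna1273")
        cohort = simulate_cohort(50, arch, SimConfig(seed=19), pore_model)
        calls = call_cohort([r for r, _ in cohort], pentamer_model, len(arch.body_seq))
        rates = np.array([c.read_rate_nt_per_s for c in calls])
        assert np.mean(np.abs(rates - 70.0) / 70.0 < 0.05) >= 0.9


class TestTailCalls:
    def test_qc_totality_and_noiseless_pass(self, pore_model, pentamer_model):
        arch, _ = preset("mrna1273")
        cohort = simulate_cohort(10, arch, SimConfig(seed=23, noise_sd_pA=0), pore_model)
        calls = call_cohort([r for r, _ in cohort], pentamer_model, len(arch.body_seq))
        assert all(c.qc_tag == QC_PASS for c in calls)
        tags = collections.Counter(c.qc_tag for c in calls)
        assert sum(tags.values()) == len(calls)

    def test_median_tail_recovery_mrna1273(self, pore_model, pentamer_model):
        arch, _ = preset("mrna1273")
        cohort = simulate_cohort(60, arch, SimConfig(seed=29), pore_model)
        calls = call_cohort([r for r, _ in cohort], pentamer_model, len(arch.body_seq))
        est = [c.polya_length_nt for c in calls if c.qc_tag == QC_PASS]
        assert np.median(est) == pytest.approx(100.0, abs=5.0)

    def test_composite_noiseless_exact(self, pore_model):
        arch, _ = preset("bnt162b2")
        cfg = SimConfig(dwell_dispersion=0, noise_sd_pA=0, seed=1)
        read, _ = simulate_read(arch, cfg, pore_model)
        model = SegmentationModel.from_pore_model(pore_model, mode="composite", noise_sd_pA=0.5)
        call = segment_composite_tail(read, model, 70.0)
        np.testing.assert_allclose(call.segment_lengths_nt, (30, 10, 70), atol=0.5)
        assert call.polya_length_nt == pytest.approx(100.0, abs=1.0)

    def test_single_tail_under_composite_model_reports_no_linker(self, pore_model, composite_model):
        arch, _ = preset("mrna1273")
        # pentamer off so the simple tail is the only non-body structure
        read, _ = simulate_read(arch, SimConfig(seed=5), pore_model, with_pentamer=False)
        call = call_cohort([read], composite_model, len(arch.body_seq))[0]
        assert call.segment_lengths_nt[1] == 0.0 and call.segment_lengths_nt[2] == 0.0
        assert call.polya_length_nt == pytest.approx(100.0, abs=5.0)

    def test_ladder_linearity_and_recovery(self, pore_model):
        model = SegmentationModel.from_pore_model(pore_model, mode="simple")
        cohort = simulate_cohort(70, "ladder", SimConfig(seed=37), pore_model)
        calls = call_cohort([r for r, _ in cohort], model, 150)
        by_truth = collections.defaultdict(list)
        for (_, truth), call in zip(cohort, calls):
            by_truth[truth.true_tail_nt].append(call.polya_length_nt)
        medians = {k: float(np.median(v)) for k, v in by_truth.items()}
        for true_len, med in medians.items():
            assert abs(med - true_len) <= max(3.0, 0.05 * true_len)
        # doubling the tail doubles the estimate (within dispersion noise)
        assert medians[60] / medians[30] == pytest.approx(2.0, rel=0.1)
        assert medians[90] / medians[45] == pytest.approx(2.0, rel=0.1)


class TestPentamer:
    def test_fraction_arithmetic(self, pore_model, pentamer_model):
        arch, _ = preset("mrna1273")
        cohort = simulate_cohort(4, arch, SimConfig(seed=3, pentamer_fraction=0.25), pore_model)
        calls = call_cohort([r for r, _ in cohort], pentamer_model, len(arch.body_seq))
        assert pentamer_fraction(calls) == pytest.approx(0.25)

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            pentamer_fraction([])

    def test_detector_operating_point(self, pore_model, pentamer_model):
        arch, _ = preset("mrna1273")
        cohort = simulate_cohort(80, arch, SimConfig(seed=7, pentamer_fraction=0.5), pore_model)
        calls = call_cohort([r for r, _ in cohort], pentamer_model, len(arch.body_seq))
        truth = np.array([t.pentamer for _, t in cohort])
        det = np.array([c.pentamer_detected for c in calls])
        assert det[truth].mean() >= 0.95  # sensitivity
        assert 1 - det[~truth].mean() >= 0.95  # specificity
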