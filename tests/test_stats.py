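import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_bh
from squigtail.stats import (
    AVOGADRO,
    TailDistribution,
    Thresholds,
    bh_adjust,
    copies_per_cell,
    estimate_thresholds,
    kw_bh_per_transcript,
    molecules_from_mass,
    standard_curve_quant,
    summarize_distribution,
)


class TestSummarize:
    def test_hand_count(self):
        d = TailDistribution("x", np.array([80.0, 90.0, 100.0, 120.0]))
        s = summarize_distribution(d, Thresholds(85, 115))
        assert (s.median, s.frac_shortened, s.frac_elongated) == (95.0, 0.25, 0.25)
        assert s.frac_unchanged == 0.5

    def test_degenerate_distribution(self):
        d = TailDistribution("x", np.full(5, 100.0))
        s = summarize_distribution(d, Thresholds(85, 115))
        assert s.median == 100.0 and s.frac_unchanged == 1.0

    def test_fractions_sum_to_one(self, rng):
        for _ in range(20):
            d = TailDistribution("x", rng.gamma(5, 20, size=50))
            s = summarize_distribution(d, Thresholds(85, 115))
            assert s.frac_shortened + s.frac_unchanged + s.frac_elongated == pytest.approx(1.0)

    def test_pentamer_subset_rule(self):
        d = TailDistribution(
            "x", np.array([50.0, 60.0, 200.0, 210.0]), pentamer=np.array([0, 0, 1, 1], bool)
        )
        s = summarize_distribution(d, Thresholds(85, 115))
        assert s.n == 2 and s.median == 55.0  # only pentamer-lacking reads

    def test_empty_eligible_subset_rejected(self):
        d = TailDistribution("x", np.array([100.0]), pentamer=np.array([True]))
        with pytest.raises(ValueError):
            summarize_distribution(d, Thresholds(85, 115))


class TestThresholds:
    def test_uniform_grid_quantiles(self):
        d = TailDistribution("crude", np.arange(101, dtype=float))
        t = estimate_thresholds(d)
        assert (t.lo, t.hi) == (20.0, 80.0)

    def test_constant_distribution_rejected(self):
        with pytest.raises(ValueError):
            estimate_thresholds(TailDistribution("crude", np.full(20, 100.0)))

    def test_too_few_reads_rejected(self):
        with pytest.raises(ValueError):
            estimate_thresholds(TailDistribution("crude", np.arange(5, dtype=float)))

    def test_crude_cohort_brackets_median(self, rng):
        # crude-vaccine-like spread around the 100-nt design tail
        lengths = np.clip(rng.normal(100, 18, size=400), 0, None)
        t = estimate_thresholds(TailDistribution("crude", lengths))
        assert t.lo < np.median(lengths) < t.hi

    def test_presets(self):
        assert Thresholds.preset("drs_mrna1273") == Thresholds(85, 115, "drs_mrna1273")
        assert Thresholds.preset("cdna_bnt162b2").lo == 50
        with pytest.raises(ValueError):
            Thresholds(100, 100)


class TestBH:
    def test_closed_form_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_matches_step_up_definition(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), brute_force_bh(pvals), atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=10)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1) and np.all(q >= p)

    def test_constant_vector_is_fixed_point(self):
        p = np.full(6, 0.37)
        np.testing.assert_allclose(bh_adjust(p), p, atol=1e-12)


class TestKruskalWallis:
    def test_identical_samples_not_significant(self):
        data = list(np.tile([1.0, 2.0, 3.0, 4.0], 5))
        res = kw_bh_per_transcript({"tx": {"a": data, "b": data, "c": data}})
        assert len(res) == 1
        assert res[0].p_value == pytest.approx(1.0, abs=0.05)
        assert not res[0].significant

    def test_low_count_condition_excluded_from_family(self, rng):
        big = {"a": list(rng.normal(100, 10, 30)), "b": list(rng.normal(100, 10, 30))}
        small = {"a": list(rng.normal(100, 10, 19)), "b": list(rng.normal(100, 10, 30))}
        res = kw_bh_per_transcript({"tested": big, "undersampled": small})
        assert [r.transcript for r in res] == ["tested"]

    def test_fewer_than_two_conditions_rejected(self):
        with pytest.raises(ValueError):
            kw_bh_per_transcript({"tx": {"only": [1.0] * 25}})

    def test_power_for_20nt_shift(self):
        rng = np.random.default_rng(99)
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(100, 10, 50)
            b = rng.normal(120, 10, 50)
            res = kw_bh_per_transcript({"tx": {"a": list(a), "b": list(b)}})
            hits += res[0].significant
        assert hits / reps >= 0.95


class TestQuantification:
    def test_avogadro_identity(self):
        # one molar mass' worth of grams -> Avogadro's number of molecules
        assert molecules_from_mass(1e3 * 1e18, 1.0) == pytest.approx(AVOGADRO)

    def test_zero_mass(self):
        assert molecules_from_mass(0, 1321.81) == 0

    def test_detection_limit_molecule_count(self):
        # 10 ag per ng of total RNA at 5 ng input = 50 ag of a 1321.81 kDa mRNA
        assert molecules_from_mass(50, 1321.81) == pytest.approx(22.78, abs=0.05)

    def test_invalid_molar_mass(self):
        with pytest.raises(ValueError):
            molecules_from_mass(10, 0)

    def test_copies_per_cell(self):
        assert copies_per_cell(1000, 8) == 125


class TestStandardCurve:
    @staticmethod
    def perfect_series():
        # 10x dilutions at 100% efficiency: delta-Ct = log2(10) per step
        copies = [1e7 / 10**i for i in range(6)]
        cts = [10 + np.log2(10) * i for i in range(6)]
        return list(zip(cts, copies))

    def test_perfect_series_recovered_exactly(self):
        pts = self.perfect_series()
        for ct, copies in pts:
            res = standard_curve_quant(pts, ct)
            assert res.copies == pytest.approx(copies, rel=1e-9)
            assert not res.extrapolated

    def test_extrapolation_flagged(self):
        res = standard_curve_quant(self.perfect_series(), 40.0)
        assert res.extrapolated

    def test_noisy_series_within_25_percent(self):
        rng = np.random.default_rng(5)
        pts = [(ct + rng.normal(0, 0.2), c) for ct, c in self.perfect_series()]
        for ct, copies in self.perfect_series():
            res = standard_curve_quant(pts, ct)
            assert abs(res.copies - copies) / copies <= 0.25

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            standard_curve_quant([(10, 1e6), (13.3, 1e5)], 11)
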