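"""End-to-end evaluation runs on simulated cohorts with known truth.

Each function simulates a cohort under the study conditions (vaccine
architecture presets, default noise), runs the full measurement path
(segmentation, rate estimation, duration-to-length conversion) and returns
the summary quantity the design value predicts.  These are the recovery
experiments the package's validation rests on; the test suite and the
reproduction script both call them.
"""

from __future__ import annotations


import numpy as np

from .pore_model import load_default_model
from .segment import SegmentationModel, call_cohort, pentamer_fraction
from .simulate import (
    LADDER_LENGTHS,
    SimConfig,
    apply_preset_overrides,
    preset,
    simulate_cohort,
)
from .stats import TailDistribution


def _simulate_and_call(preset_name: str, n: int, seed: int, mode: str):
    model = load_default_model()
    arch, overrides = preset(preset_name)
    cfg = apply_preset_overrides(SimConfig(seed=seed), overrides)
    cohort = simulate_cohort(n, arch, cfg, model)
    seg_model = SegmentationModel.from_pore_model(model, mode=mode)
    calls = call_cohort([r for r, _ in cohort], seg_model, len(arch.body_seq))
    return cohort, calls


def median_tail_mrna1273(n: int = 500, seed: int = 0) -> dict:
    """Median estimated tail length of a simulated mRNA-1273 cohort
    (design value: the ~100-nt intact tail)."""
    _, calls = _simulate_and_call("mrna1273", n, seed, "pentamer")
    est = [c.polya_length_nt for c in calls if c.qc_tag == "PASS"]
    return {"value": float(np.median(est)), "n": len(est)}


def composite_segment_medians(n: int = 300, seed: int = 0) -> dict:
    """Median recovered (proximal polyA, linker, distal polyA) lengths for
    the BNT162b2 composite tail (design values 30/10/70)."""
    _, calls = _simulate_and_call("bnt162b2", n, seed, "composite")
    segs = np.array([c.segment_lengths_nt for c in calls if c.qc_tag == "PASS"])
    med = np.median(segs, axis=0)
    return {
        "polya_proximal": float(med[0]),
        "linker": float(med[1]),
        "polya_distal": float(med[2]),
        "n": int(segs.shape[0]),
    }


def pentamer_lacking_percent(n: int = 1000, seed: int = 0) -> dict:
    """Percentage of reads lacking the terminal pentamer in a simulated
    crude-vaccine cohort (design: ~20% lacking)."""
    _, calls = _simulate_and_call("mrna1273_crude", n, seed, "pentamer")
    frac = pentamer_fraction(calls)
    n_pass = sum(c.qc_tag == "PASS" for c in calls)
    return {"value": 100.0 * (1.0 - frac), "n": n_pass}


def ladder_medians(n_per_standard: int = 100, seed: int = 0) -> dict:
    """Median estimated tail length per spike-in ladder standard."""
    n = n_per_standard * len(LADDER_LENGTHS)
    cohort, calls = _simulate_and_call("ladder", n, seed, "simple")
    by_truth: dict[int, list[float]] = {length: [] for length in LADDER_LENGTHS}
    for (_, truth), call in zip(cohort, calls):
        if call.qc_tag == "PASS":
            by_truth[truth.true_tail_nt].append(call.polya_length_nt)
    return {
        "medians": {length: float(np.median(v)) for length, v in by_truth.items()},
        "n": n,
    }


def readenylation_median_shift(n: int = 500, seed: int = 0) -> dict:
    """Difference of estimated median tail lengths (pentamer-lacking reads)
    between a re-adenylated cohort and its baseline (design: ~24 nt)."""

    def median_lacking(preset_name: str, s: int) -> float:
        _, calls = _simulate_and_call(preset_name, n, s, "pentamer")
        passed = [c for c in calls if c.qc_tag == "PASS"]
        dist = TailDistribution(
            preset_name,
            np.array([c.polya_length_nt for c in passed]),
            pentamer=np.array([c.pentamer_detected for c in passed]),
        )
        return float(np.median(dist.eligible_lengths()))

    base = median_lacking("mrna1273_crude", seed)
    elevated = median_lacking("mrna1273_readenylated", seed + 1)
    return {"value": elevated - base, "baseline": base, "elongated": elevated, "n": 2 * n}
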