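"""Tail-length statistics: summaries, classification thresholds,
per-transcript tests, and absolute-quantification arithmetic.

Poly(A) length distributions are not normal, so all summaries are
median-based.  Reads are classified as shortened (deadenylated) or
elongated (re-adenylated) against fixed thresholds that were chosen close
to the 0.2/0.8 quantiles of crude vaccine RNA; named presets carry the
published operating values for each platform/vaccine combination, and
``estimate_thresholds`` recomputes quantile-based ones from a crude
distribution.

For the mRNA-1273 convention, summaries describe the *processed* tail
population -- reads lacking the terminal pentamer -- whereas BNT162b2
summaries use all reads; :class:`TailDistribution` applies the rule
automatically when pentamer flags are present.

Per-transcript comparisons use the Kruskal-Wallis test (tie-corrected,
chi-square approximation) with Benjamini-Hochberg adjustment across the
transcripts that pass the >=20-reads-per-condition filter; a transcript is
significant when its adjusted p is below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

AVOGADRO = 6.02214076e23

#: Published classification thresholds (lo, hi) in nt.
PRESET_THRESHOLDS = {
    "drs_mrna1273": (85.0, 115.0),
    "drs_bnt162b2": (95.0, 125.0),
    "cdna_mrna1273": (80.0, 110.0),
    "cdna_bnt162b2": (50.0, 80.0),
}


@dataclass(frozen=True)
class Thresholds:
    lo: float
    hi: float
    provenance: str = "estimated"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"thresholds must satisfy lo < hi, got ({self.lo}, {self.hi})")

    @classmethod
    def preset(cls, name: str) -> "Thresholds":
        lo, hi = PRESET_THRESHOLDS[name]
        return cls(lo, hi, provenance=name)


@dataclass
class TailDistribution:
    """Per-condition tail lengths, with optional per-read pentamer flags."""

    condition: str
    lengths: np.ndarray
    pentamer: np.ndarray | None = None  # bool flags, aligned with lengths

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        if np.any(self.lengths < 0):
            raise ValueError("tail lengths must be >= 0")
        if self.pentamer is not None:
            self.pentamer = np.asarray(self.pentamer, dtype=bool)
            if self.pentamer.shape != self.lengths.shape:
                raise ValueError("pentamer flags must align with lengths")

    def eligible_lengths(self) -> np.ndarray:
        """Pentamer-lacking subset when flags are present (processed-tail
        convention), otherwise all reads."""
        if self.pentamer is None:
            return self.lengths
        return self.lengths[~self.pentamer]


@dataclass
class DistributionSummary:
    condition: str
    n: int
    median: float
    frac_shortened: float
    frac_unchanged: float
    frac_elongated: float


@dataclass
class TranscriptTailTest:
    transcript: str
    n_per_condition: dict[str, int]
    p_value: float
    p_adjusted: float
    significant: bool


def summarize_distribution(d: TailDistribution, t: Thresholds) -> DistributionSummary:
    """Median plus shortened/unchanged/elongated fractions of the eligible
    subset; fractions sum to 1."""
    x = d.eligible_lengths()
    if x.size == 0:
        raise ValueError(f"no eligible reads in condition {d.condition!r}")
    frac_short = float(np.mean(x < t.lo))
    frac_long = float(np.mean(x > t.hi))
    return DistributionSummary(
        condition=d.condition,
        n=int(x.size),
        median=float(np.median(x)),
        frac_shortened=frac_short,
        frac_unchanged=1.0 - frac_short - frac_long,
        frac_elongated=frac_long,
    )


def estimate_thresholds(crude: TailDistribution) -> Thresholds:
    """0.2/0.8 linear-interpolation quantiles of a crude-vaccine
    distribution (the quantile basis of the published presets)."""
    x = crude.eligible_lengths()
    if x.size < 10:
        raise ValueError("need at least 10 eligible reads to estimate thresholds")
    lo, hi = np.quantile(x, [0.2, 0.8])
    return Thresholds(float(lo), float(hi), provenance="estimated")


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kw_bh_per_transcript(
    tables: Mapping[str, Mapping[str, Sequence[float]]],
    min_reads: int = 20,
    alpha: float = 0.05,
) -> list[TranscriptTailTest]:
    """Kruskal-Wallis p per transcript with >= ``min_reads`` in every
    condition, BH-adjusted over the tested transcripts only.

    ``tables`` maps transcript -> condition -> tail lengths.  Transcripts
    failing the read-count filter are excluded from testing and from the BH
    family entirely.
    """
    if not tables:
        raise ValueError("no transcripts provided")
    n_conditions = {len(conds) for conds in tables.values()}
    if min(n_conditions) < 2:
        raise ValueError("need at least 2 conditions per transcript")

    tested: list[tuple[str, dict[str, int], float]] = []
    for transcript, conds in tables.items():
        counts = {c: len(v) for c, v in conds.items()}
        if min(counts.values()) < min_reads:
            continue
        groups = [np.asarray(v, dtype=np.float64) for v in conds.values()]
        if all(np.all(g == groups[0][0]) for g in groups):
            p = 1.0  # all observations identical: no evidence of any shift
        else:
            p = float(sps.kruskal(*groups).pvalue)
        tested.append((transcript, counts, p))
    if not tested:
        return []
    padj = bh_adjust([p for _, _, p in tested])
    return [
        TranscriptTailTest(
            transcript=name,
            n_per_condition=counts,
            p_value=p,
            p_adjusted=float(q),
            significant=bool(q < alpha),
        )
        for (name, counts, p), q in zip(tested, padj)
    ]


def molecules_from_mass(mass_ag: float, molar_mass_kda: float) -> float:
    """Molecule count from a mass in attograms and a molar mass in kDa.

    10 ag/ng sensitivity at 5 ng input (50 ag) of a 1321.81 kDa mRNA is
    ~22.8 molecules.
    """
    if molar_mass_kda <= 0:
        raise ValueError("molar mass must be > 0")
    if mass_ag < 0:
        raise ValueError("mass must be >= 0")
    return mass_ag * 1e-18 / (molar_mass_kda * 1e3) * AVOGADRO


def copies_per_cell(molecules: float, n_cells: float) -> float:
    """Plain division; assumes 100% recovery through sorting, RNA isolation
    and cDNA synthesis (no hidden corrections)."""
    if n_cells <= 0:
        raise ValueError("cell count must be > 0")
    return molecules / n_cells


@dataclass
class QuantResult:
    copies: float
    extrapolated: bool
    slope: float
    intercept: float


def standard_curve_quant(
    dilution_points: Sequence[tuple[float, float]], query_ct: float
) -> QuantResult:
    """Absolute quantification from a qPCR dilution series.

    Fits log10(copies) linear in Ct over ``(Ct, known_copies)`` pairs and
    inverts at ``query_ct``; the result is flagged when the query lies
    outside the fitted Ct range.
    """
    if len(dilution_points) < 3:
        raise ValueError("need at least 3 dilution points")
    ct = np.array([p[0] for p in dilution_points], dtype=np.float64)
    copies = np.array([p[1] for p in dilution_points], dtype=np.float64)
    if np.any(copies <= 0):
        raise ValueError("known copy numbers must be > 0")
    fit = sps.linregress(ct, np.log10(copies))
    value = 10 ** (fit.slope * query_ct + fit.intercept)
    extrapolated = not (ct.min() <= query_ct <= ct.max())
    return QuantResult(
        copies=float(value),
        extrapolated=bool(extrapolated),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
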