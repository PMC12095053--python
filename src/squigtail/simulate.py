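"""Synthetic direct-RNA-sequencing squiggle generator with ground truth.

Direct RNA sequencing captures the 3' end of the molecule first: the stored
trace begins with the sequencing adapter, then the terminal pentamer when
present, then the 3'-most poly(A) segment, and finally the transcript body
in 3'->5' order.  The simulator reproduces the read architectures of the
two COVID-19 mRNA vaccines and of calibration spike-ins:

* ``mrna1273``   -- ~100-nt poly(A) tail terminated by the mPsiCmPsiAG
  pentamer (written UCUAG; all U residues in the vaccine are
  N1-methyl-pseudouridine, represented by the pore-model shift);
* ``bnt162b2``   -- composite tail of 30 A, a 10-nt non-A linker, 70 A;
* ``ladder``     -- spike-in standards with defined tails of
  10/15/30/45/60/90/120 A;
* ``mrna1273_crude``        -- crude vaccine, 80% of reads carry the pentamer;
* ``mrna1273_readenylated`` -- tail elongated by 24 A, most reads lacking the
  pentamer (the re-adenylated state observed in macrophages);
* ``control``    -- unrelated transcript body, used as the negative class for
  read identification.

Emission convention: each nucleotide emits the pore-model level of the
5-mer window *ending* at that base (clamped at the 5' start of the
sequence).  Junction blur therefore falls on the 5'-ward segment, the
terminal pentamer occupies exactly five distinct non-A states, and every
junction into a poly(A) segment carries a fixed (k-1)-state footprint that
the decoder can correct deterministically.  Ground-truth sample boundaries
follow per-nucleotide architecture labels, so a 100-nt tail at 3012 Hz and
70 nt/s spans round(100*3012/70) = 4303 samples when dwell dispersion is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .pore_model import (
    ADAPTER_MEAN_PA,
    PoreModel,
    encode_sequence,
    load_default_model,
)

LADDER_LENGTHS = (10, 15, 30, 45, 60, 90, 120)
READENYLATION_NT = 24
PENTAMER_RNA = "UCUAG"
BNT_LINKER_SEQ = "GCAUAUGACU"

# Segment labels, in capture (time) order for a full read.
SEG_ADAPTER = "adapter"
SEG_PENTAMER = "pentamer"
SEG_POLYA = "polya"
SEG_LINKER = "linker"
SEG_POLYA2 = "polya2"
SEG_TRANSCRIPT = "transcript"


def random_rna(length: int, seed: int) -> str:
    """Deterministic synthetic transcript body (uniform over A/C/G/U)."""
    rng = np.random.default_rng(seed)
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))


@dataclass(frozen=True)
class TailSegment:
    kind: str  # "polyA" | "linker"
    length_nt: int
    linker_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("polyA", "linker"):
            raise ValueError(f"unknown tail segment kind {self.kind!r}")
        if self.length_nt < 0:
            raise ValueError("segment length must be >= 0")
        if self.kind == "linker" and len(self.linker_seq) != self.length_nt:
            raise ValueError("linker_seq length must equal length_nt")


@dataclass(frozen=True)
class ReadArchitecture:
    """One read layout: adapter -> [pentamer] -> tail segments -> body.

    ``tail_segments`` are given 5'->3' and must alternate polyA/linker,
    starting and ending with polyA (a single polyA is allowed).
    ``body_seq`` is the transcript body, 5'->3'.
    """

    name: str
    adapter_len_nt: int
    pentamer_seq: str  # "" or a 5-mer such as UCUAG
    tail_segments: tuple[TailSegment, ...]
    body_seq: str

    def __post_init__(self) -> None:
        if self.adapter_len_nt < 0:
            raise ValueError("adapter_len_nt must be >= 0")
        if self.pentamer_seq and len(self.pentamer_seq) != 5:
            raise ValueError("pentamer_seq must be empty or 5 nt")
        segs = self.tail_segments
        if not segs or segs[0].kind != "polyA" or segs[-1].kind != "polyA":
            raise ValueError("tail_segments must start and end with polyA")
        for prev, cur in zip(segs, segs[1:]):
            if prev.kind == cur.kind:
                raise ValueError("tail_segments must alternate polyA/linker")

    @property
    def total_polya_nt(self) -> int:
        return sum(s.length_nt for s in self.tail_segments if s.kind == "polyA")

    def with_polya_length(self, length_nt: int) -> "ReadArchitecture":
        """Replace the length of a single-polyA tail (used for draws)."""
        if len(self.tail_segments) != 1:
            raise ValueError("tail-length draws require a single-polyA architecture")
        return replace(self, tail_segments=(TailSegment("polyA", int(length_nt)),))


@dataclass(frozen=True)
class TailLengthDistribution:
    """Per-read tail length draw: architecture preset value, point mass,
    Gaussian, or the deterministic spike-in ladder cycle."""

    kind: str = "preset"  # preset | point | normal | ladder
    value: float | None = None
    sd: float | None = None
    values: tuple[int, ...] = LADDER_LENGTHS

    def draw(self, index: int, rng: np.random.Generator, preset_nt: int) -> int:
        if self.kind == "preset":
            return preset_nt
        if self.kind == "point":
            return int(round(self.value if self.value is not None else preset_nt))
        if self.kind == "normal":
            mean = self.value if self.value is not None else preset_nt
            return max(0, int(round(rng.normal(mean, self.sd or 0.0))))
        if self.kind == "ladder":
            return int(self.values[index % len(self.values)])
        raise ValueError(f"unknown tail length distribution {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    sample_rate_hz: float = 3012.0
    mean_rate_nt_per_s: float = 70.0
    dwell_dispersion: float = 0.3  # CV of the per-nt dwell
    noise_sd_pA: float = 1.5
    pentamer_fraction: float = 1.0
    tail_distribution: TailLengthDistribution = TailLengthDistribution()
    modified: bool = True  # emit with the mPsi current shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0 or self.mean_rate_nt_per_s <= 0:
            raise ValueError("sample_rate_hz and mean_rate_nt_per_s must be > 0")
        if not 0.0 <= self.pentamer_fraction <= 1.0:
            raise ValueError("pentamer_fraction must be in [0, 1]")
        if self.dwell_dispersion < 0 or self.noise_sd_pA < 0:
            raise ValueError("dispersion and noise must be >= 0")

    @property
    def mean_dwell_samples(self) -> float:
        return self.sample_rate_hz / self.mean_rate_nt_per_s


@dataclass
class RawRead:
    """One read's current trace in capture (3'->5') order."""

    read_id: str
    samples: np.ndarray
    sample_rate_hz: float


@dataclass
class GroundTruth:
    read_id: str
    preset: str
    true_tail_nt: int
    pentamer: bool
    boundaries: dict[str, tuple[int, int]]  # label -> [start, end) samples
    segment_lengths_nt: tuple[int, ...]  # tail segments, 5'->3'
    rate_nt_per_s: float


def squiggle_from_sequence(seq: str, model: PoreModel, modified: bool = False) -> np.ndarray:
    """Expected current levels for a sequence, one per k-mer, 5'->3'.

    With ``modified`` on, levels of U-containing k-mers are offset by the
    model's ``mod_shift_pA``; all others are unchanged.
    """
    if len(seq) < model.k:
        raise ValueError(f"sequence shorter than k={model.k}")
    enc = encode_sequence(seq)
    weights = 4 ** np.arange(model.k - 1, -1, -1, dtype=np.int64)
    codes = np.convolve(enc, weights[::-1], mode="valid")  # k-mer codes, 5'->3'
    return model.shifted_means(modified)[codes]


def _per_nt_levels(seq: str, model: PoreModel, modified: bool) -> np.ndarray:
    """One level per nucleotide: the k-mer window ending at that base,
    clamped at the 5' start."""
    states = squiggle_from_sequence(seq, model, modified)
    idx = np.clip(np.arange(len(seq)) - (model.k - 1), 0, len(states) - 1)
    return states[idx]


def _segment_runs(labels_time: Sequence[str]) -> list[tuple[str, int, int]]:
    runs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(labels_time) + 1):
        if i == len(labels_time) or labels_time[i] != labels_time[start]:
            runs.append((labels_time[start], start, i))
            start = i
    return runs


def _dwells(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Integer per-nt dwells.  Dispersion 0 uses cumulative rounding so a
    run of n nucleotides spans exactly round(n * mean_dwell) samples."""
    d = cfg.mean_dwell_samples
    if cfg.dwell_dispersion == 0:
        edges = np.round(np.arange(n + 1) * d).astype(np.int64)
        return np.diff(edges)
    cv = cfg.dwell_dispersion
    shape = 1.0 / (cv * cv)
    raw = rng.gamma(shape, d / shape, size=n)
    return np.maximum(1, np.round(raw)).astype(np.int64)


def simulate_read(
    arch: ReadArchitecture,
    cfg: SimConfig,
    model: PoreModel | None = None,
    rng: np.random.Generator | None = None,
    read_id: str = "read_00000",
    with_pentamer: bool | None = None,
    tail_index: int = 0,
) -> tuple[RawRead, GroundTruth]:
    """Simulate one squiggle plus exact ground truth.

    ``with_pentamer`` overrides the architecture's pentamer (used by
    :func:`simulate_cohort` to realise the pentamer fraction); ``tail_index``
    feeds deterministic distributions such as the ladder cycle.
    """
    model = model or load_default_model()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    carry_pentamer = bool(arch.pentamer_seq) if with_pentamer is None else with_pentamer
    if carry_pentamer and not arch.pentamer_seq:
        raise ValueError("architecture has no pentamer_seq to carry")

    segments = arch.tail_segments
    if len(segments) == 1 and cfg.tail_distribution.kind != "preset":
        length = cfg.tail_distribution.draw(tail_index, rng, segments[0].length_nt)
        segments = (TailSegment("polyA", length),)

    # sequence 5'->3': body + tail + optional pentamer
    seq_parts = [arch.body_seq]
    nt_labels: list[str] = [SEG_TRANSCRIPT] * len(arch.body_seq)
    polya_seen = 0
    n_polya = sum(1 for s in segments if s.kind == "polyA")
    seg_lengths = tuple(s.length_nt for s in segments)
    for seg in segments:
        if seg.kind == "polyA":
            polya_seen += 1
            # time order reverses sequence order: the 3'-most polyA is decoded
            # first and is labelled "polya"; an earlier (5'-ward) polyA in a
            # composite tail becomes "polya2".
            label = SEG_POLYA if polya_seen == n_polya else SEG_POLYA2
            seq_parts.append("A" * seg.length_nt)
        else:
            label = SEG_LINKER
            seq_parts.append(seg.linker_seq)
        nt_labels.extend([label] * seg.length_nt)
    if carry_pentamer:
        seq_parts.append(arch.pentamer_seq)
        nt_labels.extend([SEG_PENTAMER] * len(arch.pentamer_seq))
    seq = "".join(seq_parts)

    levels_seq = _per_nt_levels(seq, model, cfg.modified)
    # capture order: 3' end first
    levels_time = levels_seq[::-1]
    labels_time = [SEG_ADAPTER] * arch.adapter_len_nt + nt_labels[::-1]
    levels_time = np.concatenate([np.full(arch.adapter_len_nt, ADAPTER_MEAN_PA), levels_time])

    # dwells per contiguous segment run so noiseless sample accounting is exact
    runs = _segment_runs(labels_time)
    dwell_parts = [_dwells(end - start, cfg, rng) for _, start, end in runs]
    dwells = np.concatenate(dwell_parts) if dwell_parts else np.zeros(0, dtype=np.int64)

    samples = np.repeat(levels_time, dwells)
    if cfg.noise_sd_pA > 0:
        samples = samples + rng.normal(0.0, cfg.noise_sd_pA, size=samples.size)

    edges = np.concatenate([[0], np.cumsum(dwells)])
    boundaries: dict[str, tuple[int, int]] = {}
    for label, start, end in runs:
        boundaries[label] = (int(edges[start]), int(edges[end]))
    truth = GroundTruth(
        read_id=read_id,
        preset=arch.name,
        true_tail_nt=sum(s.length_nt for s in segments if s.kind == "polyA"),
        pentamer=carry_pentamer,
        boundaries=boundaries,
        segment_lengths_nt=seg_lengths,
        rate_nt_per_s=cfg.mean_rate_nt_per_s,
    )
    read = RawRead(read_id=read_id, samples=samples.astype(np.float32), sample_rate_hz=cfg.sample_rate_hz)
    return read, truth


def simulate_cohort(
    n: int,
    arch: ReadArchitecture | str,
    cfg: SimConfig,
    model: PoreModel | None = None,
) -> list[tuple[RawRead, GroundTruth]]:
    """Simulate ``n`` reads; exactly round(n * pentamer_fraction) carry the
    pentamer, assigned deterministically under the config seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(arch, str):
        arch, overrides = preset(arch)
        cfg = apply_preset_overrides(cfg, overrides)
    model = model or load_default_model()
    rng = np.random.default_rng(cfg.seed)
    if arch.pentamer_seq:
        n_pent = int(round(n * cfg.pentamer_fraction))
        order = rng.permutation(n)
        pent_mask = np.zeros(n, dtype=bool)
        pent_mask[order[:n_pent]] = True
    else:
        pent_mask = np.zeros(n, dtype=bool)
    out = []
    for i in range(n):
        read, truth = simulate_read(
            arch,
            cfg,
            model,
            rng=rng,
            read_id=f"{arch.name}_{i:05d}",
            with_pentamer=bool(pent_mask[i]),
            tail_index=i,
        )
        out.append((read, truth))
    return out


# ---------------------------------------------------------------------------
# Presets

_BODY_MRNA1273 = random_rna(300, seed=101)
_BODY_BNT162B2 = random_rna(300, seed=202)
_BODY_CONTROL = random_rna(300, seed=303)
_BODY_LADDER = random_rna(150, seed=404)

CRUDE_PENTAMER_FRACTION = 0.8  # crude vaccine: ~20% of reads lack the pentamer
READENYLATED_PENTAMER_FRACTION = 0.25


def preset(name: str) -> tuple[ReadArchitecture, dict]:
    """Named architecture plus recommended SimConfig overrides."""
    if name == "mrna1273":
        arch = ReadArchitecture(
            name, 30, PENTAMER_RNA, (TailSegment("polyA", 100),), _BODY_MRNA1273
        )
        return arch, {"pentamer_fraction": 1.0}
    if name == "mrna1273_crude":
        arch = ReadArchitecture(
            name, 30, PENTAMER_RNA, (TailSegment("polyA", 100),), _BODY_MRNA1273
        )
        return arch, {"pentamer_fraction": CRUDE_PENTAMER_FRACTION}
    if name == "mrna1273_readenylated":
        arch = ReadArchitecture(
            name,
            30,
            PENTAMER_RNA,
            (TailSegment("polyA", 100 + READENYLATION_NT),),
            _BODY_MRNA1273,
        )
        return arch, {"pentamer_fraction": READENYLATED_PENTAMER_FRACTION}
    if name == "bnt162b2":
        arch = ReadArchitecture(
            name,
            30,
            "",
            (
                TailSegment("polyA", 30),
                TailSegment("linker", 10, BNT_LINKER_SEQ),
                TailSegment("polyA", 70),
            ),
            _BODY_BNT162B2,
        )
        return arch, {"pentamer_fraction": 0.0}
    if name == "ladder":
        arch = ReadArchitecture(name, 30, "", (TailSegment("polyA", 45),), _BODY_LADDER)
        return arch, {
            "pentamer_fraction": 0.0,
            "tail_distribution": TailLengthDistribution(kind="ladder"),
        }
    if name == "control":
        arch = ReadArchitecture(name, 30, "", (TailSegment("polyA", 100),), _BODY_CONTROL)
        return arch, {"pentamer_fraction": 0.0}
    raise ValueError(f"unknown preset {name!r}")


PRESET_NAMES = (
    "mrna1273",
    "mrna1273_crude",
    "mrna1273_readenylated",
    "bnt162b2",
    "ladder",
    "control",
)


def apply_preset_overrides(cfg: SimConfig, overrides: dict) -> SimConfig:
    """Fill preset-recommended fields, but never clobber a field the caller
    has explicitly moved away from its default."""
    defaults = SimConfig()
    effective = {
        key: value
        for key, value in overrides.items()
        if getattr(cfg, key) == getattr(defaults, key)
    }
    return replace(cfg, **effective)
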