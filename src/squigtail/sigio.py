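"""On-disk formats: the signal container, ground-truth and tail tables.

Signal container layout (one directory per cohort)::

    cohort_dir/
      metadata.tsv        read_id, sample_rate_hz, preset, seed
      ground_truth.tsv    read_id, true_tail_nt, pentamer, seg_lengths, seg_boundaries
      signals/<read_id>.npy   float32 current trace, capture order

Traces round-trip bit-exactly.  Tail tables are TSV with a versioned
header comment; the column set extends the nanopolish-polya convention
with pentamer/composite fields.  An optional single-read FAST5-style HDF5
writer is provided for interoperability with signal-file tooling; POD5
import is not available in this build and reports a clear message.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .segment import TailCall
from .simulate import GroundTruth, RawRead

logger = logging.getLogger("squigtail")

TAIL_TABLE_VERSION = "squigtail_tail_table_v1"
TAIL_TABLE_COLUMNS = [
    "read_id",
    "qc_tag",
    "adapter_start",
    "pentamer_start",
    "polya_start",
    "linker_start",
    "polya2_start",
    "transcript_start",
    "read_rate",
    "polya_length",
    "pentamer_detected",
    "seg_lengths",
]
_REQUIRED_COLUMNS = set(TAIL_TABLE_COLUMNS)


def write_signal_container(
    path: str | Path,
    cohort: list[tuple[RawRead, GroundTruth]],
    preset: str = "",
    seed: int = 0,
) -> Path:
    path = Path(path)
    (path / "signals").mkdir(parents=True, exist_ok=True)
    meta_rows = []
    truth_rows = []
    for read, truth in cohort:
        np.save(path / "signals" / f"{read.read_id}.npy", read.samples.astype(np.float32))
        meta_rows.append(
            {
                "read_id": read.read_id,
                "sample_rate_hz": read.sample_rate_hz,
                "preset": truth.preset or preset,
                "seed": seed,
            }
        )
        truth_rows.append(
            {
                "read_id": truth.read_id,
                "true_tail_nt": truth.true_tail_nt,
                "pentamer": truth.pentamer,
                "seg_lengths": json.dumps(list(truth.segment_lengths_nt)),
                "seg_boundaries": json.dumps(truth.boundaries),
            }
        )
    pd.DataFrame(meta_rows).to_csv(path / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(path / "ground_truth.tsv", sep="\t", index=False)
    return path


def read_signal_container(path: str | Path) -> list[tuple[RawRead, GroundTruth | None]]:
    """Load a cohort; errors name the read whose array file is missing.

    An empty/uninitialised directory yields an empty cohort with a warning.
    """
    path = Path(path)
    meta_path = path / "metadata.tsv"
    if not meta_path.exists():
        logger.warning("no metadata.tsv under %s; returning empty cohort", path)
        return []
    meta = pd.read_csv(meta_path, sep="\t")
    truth_path = path / "ground_truth.tsv"
    truths: dict[str, GroundTruth] = {}
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t")
        for row in tdf.itertuples():
            truths[row.read_id] = GroundTruth(
                read_id=row.read_id,
                preset="",
                true_tail_nt=int(row.true_tail_nt),
                pentamer=bool(row.pentamer),
                boundaries={k: tuple(v) for k, v in json.loads(row.seg_boundaries).items()},
                segment_lengths_nt=tuple(json.loads(row.seg_lengths)),
                rate_nt_per_s=float("nan"),
            )
    out = []
    for row in meta.itertuples():
        arr_path = path / "signals" / f"{row.read_id}.npy"
        if not arr_path.exists():
            raise FileNotFoundError(f"missing signal array for read {row.read_id!r}: {arr_path}")
        samples = np.load(arr_path)
        truth = truths.get(row.read_id)
        if truth is not None:
            truth.preset = row.preset
        out.append((RawRead(row.read_id, samples, float(row.sample_rate_hz)), truth))
    return out


def write_tail_table(calls: list[TailCall], path: str | Path, config_hash: str = "") -> Path:
    if not calls:
        raise ValueError("cannot write an empty tail table")
    rows = []
    for c in calls:
        b = c.boundaries

        def start(state: str) -> int:
            return b[state][0] if state in b else -1

        rows.append(
            {
                "read_id": c.read_id,
                "qc_tag": c.qc_tag,
                "adapter_start": start("adapter"),
                "pentamer_start": start("pentamer"),
                "polya_start": start("polya"),
                "linker_start": start("linker"),
                "polya2_start": start("polya2"),
                "transcript_start": start("transcript"),
                "read_rate": round(c.read_rate_nt_per_s, 3),
                "polya_length": round(c.polya_length_nt, 3),
                "pentamer_detected": c.pentamer_detected,
                "seg_lengths": json.dumps([round(x, 3) for x in c.segment_lengths_nt]),
            }
        )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {TAIL_TABLE_VERSION}")
        if config_hash:
            fh.write(f" config={config_hash}")
        fh.write("\n")
        pd.DataFrame(rows, columns=TAIL_TABLE_COLUMNS).to_csv(fh, sep="\t", index=False)
    return path


def read_tail_table(path: str | Path) -> pd.DataFrame:
    """Read a tail table; extra columns are ignored with a warning, missing
    required columns raise naming them."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"tail table {path} is missing columns: {sorted(missing)}")
    extra = [c for c in df.columns if c not in _REQUIRED_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown tail-table columns: {extra}")
        df = df[TAIL_TABLE_COLUMNS]
    return df


def calls_from_table(df: pd.DataFrame) -> list[TailCall]:
    calls = []
    for row in df.itertuples():
        calls.append(
            TailCall(
                read_id=row.read_id,
                polya_length_nt=float(row.polya_length),
                pentamer_detected=bool(row.pentamer_detected),
                segment_lengths_nt=tuple(json.loads(row.seg_lengths)),
                read_rate_nt_per_s=float(row.read_rate),
                qc_tag=row.qc_tag,
            )
        )
    return calls


def write_fast5(path: str | Path, read: RawRead) -> Path:
    """Write a minimal single-read FAST5-style HDF5 file (raw signal plus
    sampling rate), for hand-off to signal-level tooling."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        grp = fh.create_group(f"read_{read.read_id}")
        raw = grp.create_group("Raw")
        raw.create_dataset("Signal", data=read.samples.astype(np.float32))
        raw.attrs["read_id"] = read.read_id
        chan = grp.create_group("channel_id")
        chan.attrs["sampling_rate"] = float(read.sample_rate_hz)
    return path


def read_fast5(path: str | Path) -> RawRead:
    import h5py

    with h5py.File(path, "r") as fh:
        keys = list(fh.keys())
        grp = fh[keys[0]]
        samples = np.asarray(grp["Raw/Signal"])
        read_id = grp["Raw"].attrs["read_id"]
        rate = float(grp["channel_id"].attrs["sampling_rate"])
    return RawRead(str(read_id), samples, rate)


def read_pod5(path: str | Path):  # pragma: no cover - availability notice
    raise ImportError(
        "POD5 import requires the 'pod5' package, which is not installed; "
        "convert to the native signal container or FAST5 instead"
    )
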