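"""Generate the synthetic 5-mer pore-model table shipped with squigtail.

The table is drawn once from a fixed seed and frozen into
``src/squigtail/data/pore_model_synthetic_5mer.tsv``.  It is a synthetic
stand-in for a chemistry model, constructed so the segmentation problem is
well posed:

* levels ~ Normal(97, 11) pA clipped to [72, 128], per-k-mer sd ~ U(1.5, 3.0);
* the homopolymer AAAAA level is pinned at 108.9 pA (direct-RNA scale);
* generation-time acceptance criterion: every junction k-mer of the terminal
  pentamer (UCUAG in poly(A) context) and of the composite-tail linker
  (GCAUAUGACU in poly(A) context), with the default +4 pA mPsi shift on
  U-containing k-mers, must sit at least 5 pA away from the AAAAA level so
  that poly(A) boundaries are identifiable in principle.  Seeds are scanned
  upward from a fixed start until the criterion holds; the chosen seed is
  recorded in the table header.

Run from the repository root:  python scripts/make_pore_model.py
"""

from pathlib import Path
import sys

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from squigtail.pore_model import PoreModel, encode_kmer  # noqa: E402

K = 5
POLYA_LEVEL = 108.9
MOD_SHIFT = 4.0
MIN_SEP = 5.0
PENTAMER = "UCUAG"
LINKER = "GCAUAUGACU"
OUT = Path(__file__).resolve().parents[1] / "src" / "squigtail" / "data" / "pore_model_synthetic_5mer.tsv"


def junction_kmers() -> list[str]:
    """k-mers a decoder must separate from poly(A): all windows over the
    pentamer and linker embedded in A context."""
    kmers = []
    for insert in (PENTAMER, LINKER):
        ctx = "A" * (K - 1) + insert + "A" * (K - 1)
        for i in range(len(ctx) - K + 1):
            kmer = ctx[i : i + K]
            if set(kmer) != {"A"}:
                kmers.append(kmer)
    return sorted(set(kmers))


def build(seed: int) -> tuple[PoreModel, float]:
    rng = np.random.default_rng(seed)
    means = np.clip(rng.normal(97.0, 11.0, 4 ** K), 72.0, 128.0)
    sds = rng.uniform(1.5, 3.0, 4 ** K)
    means[encode_kmer("A" * K)] = POLYA_LEVEL
    sds[encode_kmer("A" * K)] = 1.5
    model = PoreModel(k=K, means=means, sds=sds, mod_shift_pA=MOD_SHIFT)
    sep = min(
        abs(model.level(kmer, modified=True)[0] - POLYA_LEVEL)
        for kmer in junction_kmers()
    )
    return model, sep


def main() -> None:
    seed = 20210
    while True:
        model, sep = build(seed)
        if sep >= MIN_SEP:
            break
        seed += 1
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        fh.write(f"# synthetic 5-mer pore model, seed={seed}, min junction separation={sep:.2f} pA\n")
    with open(OUT, "a"):
        pass
    # append the table after the header comment
    tmp = OUT.with_suffix(".tmp")
    model.to_tsv(tmp)
    with open(OUT, "a") as out, open(tmp) as src:
        out.write(src.read())
    tmp.unlink()
    print(f"seed={seed} min_junction_separation={sep:.2f} pA -> {OUT}")


if __name__ == "__main__":
    main()
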