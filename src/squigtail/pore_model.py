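"""k-mer current-level model for direct RNA squiggle prediction.

A pore model maps every k-mer over {A, C, G, U} to the expected picoampere
current (mean, sd) while that k-mer occupies the pore.  The default model
shipped with the package is a synthetic 5-mer Gaussian table generated once
from a fixed seed (``scripts/make_pore_model.py``); it is deliberately not a
vendor chemistry table, so all algorithms are exercised against a fully
self-contained model.  Two conventions carry over from real direct RNA
chemistry scales: the homopolymer-A level is pinned near 109 pA and the
sequencing adapter is modelled as a distinct low constant level (~76 pA),
giving the adapter/poly(A) contrast that tail segmentation exploits.

N1-methyl-pseudouridine (mPsi) substitution perturbs the recorded current;
the model represents this as an additive ``mod_shift_pA`` applied to every
U-containing k-mer when modified mode is on.  ``mod_shift_pA = 0``
reproduces the unmodified model exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Constant emission level of the sequencing adapter (pA).  The adapter is a
#: DNA/leader segment with chemistry unrelated to the RNA k-mer table, so it
#: is modelled as its own level rather than derived from the table.
ADAPTER_MEAN_PA = 76.0
ADAPTER_SD_PA = 1.2

DEFAULT_MOD_SHIFT_PA = 4.0


def encode_kmer(kmer: str) -> int:
    """Base-4 encoding of a k-mer over {A,C,G,U} (A=0 ... U=3)."""
    code = 0
    for base in kmer:
        try:
            code = code * 4 + _BASE_INDEX[base]
        except KeyError:
            raise ValueError(f"invalid base {base!r} in k-mer {kmer!r}") from None
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def encode_sequence(seq: str) -> np.ndarray:
    """Integer-encode a nucleotide string, raising on the first bad char."""
    arr = np.empty(len(seq), dtype=np.int64)
    for i, base in enumerate(seq):
        idx = _BASE_INDEX.get(base)
        if idx is None:
            raise ValueError(
                f"invalid character {base!r} at position {i}; expected one of {BASES}"
            )
        arr[i] = idx
    return arr


@dataclass
class PoreModel:
    """k-mer -> (mean_pA, sd_pA) table plus the mPsi modification shift.

    Arrays are indexed by :func:`encode_kmer`.  ``u_mask[code]`` is True when
    the k-mer contains at least one U; those levels receive ``mod_shift_pA``
    in modified mode.
    """

    k: int
    means: np.ndarray
    sds: np.ndarray
    mod_shift_pA: float = DEFAULT_MOD_SHIFT_PA
    u_mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = 4 ** self.k
        if self.means.shape != (n,) or self.sds.shape != (n,):
            raise ValueError(f"model table must cover all {n} {self.k}-mers")
        if not np.all(self.sds > 0):
            raise ValueError("all k-mer sds must be positive")
        u_digit = _BASE_INDEX["U"]
        mask = np.zeros(n, dtype=bool)
        codes = np.arange(n)
        for _ in range(self.k):
            mask |= codes % 4 == u_digit
            codes //= 4
        self.u_mask = mask

    def shifted_means(self, modified: bool) -> np.ndarray:
        """Expected levels with the modification shift applied (or not)."""
        if not modified or self.mod_shift_pA == 0:
            return self.means
        out = self.means.copy()
        out[self.u_mask] += self.mod_shift_pA
        return out

    def level(self, kmer: str, modified: bool = False) -> tuple[float, float]:
        code = encode_kmer(kmer)
        mean = float(self.means[code])
        if modified and self.u_mask[code]:
            mean += self.mod_shift_pA
        return mean, float(self.sds[code])

    @classmethod
    def from_tsv(cls, path: str | Path, mod_shift_pA: float = DEFAULT_MOD_SHIFT_PA) -> "PoreModel":
        """Load a ``kmer<TAB>mean_pA<TAB>sd_pA`` table."""
        kmers: list[str] = []
        means: list[float] = []
        sds: list[float] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("kmer"):
                    continue
                kmer, mean, sd = line.split("\t")
                kmers.append(kmer)
                means.append(float(mean))
                sds.append(float(sd))
        k = len(kmers[0])
        n = 4 ** k
        if len(kmers) != n:
            raise ValueError(f"expected {n} {k}-mers, found {len(kmers)}")
        mean_arr = np.empty(n)
        sd_arr = np.empty(n)
        for kmer, mean, sd in zip(kmers, means, sds):
            code = encode_kmer(kmer)
            mean_arr[code] = mean
            sd_arr[code] = sd
        return cls(k=k, means=mean_arr, sds=sd_arr, mod_shift_pA=mod_shift_pA)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tmean_pA\tsd_pA\n")
            for code in range(4 ** self.k):
                fh.write(
                    f"{decode_kmer(code, self.k)}\t{self.means[code]:.3f}\t{self.sds[code]:.3f}\n"
                )


_default_model: PoreModel | None = None


def load_default_model(mod_shift_pA: float = DEFAULT_MOD_SHIFT_PA) -> PoreModel:
    """Load (and cache) the synthetic 5-mer table shipped with the package."""
    global _default_model
    if _default_model is None or _default_model.mod_shift_pA != mod_shift_pA:
        ref = importlib.resources.files("squigtail.data") / "pore_model_synthetic_5mer.tsv"
        with importlib.resources.as_file(ref) as path:
            _default_model = PoreModel.from_tsv(path, mod_shift_pA=mod_shift_pA)
    return _default_model
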