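"""SNP polarity recoding between coding schemes.

A biallelic SNP can be coded with either allele as 1; the choice (its
"polarity") is arbitrary in the raw data but consequential for biplots.
Schemes supported:

* ``rare1``   — minor allele coded 1 (every SNP frequency of 1 <= 0.5),
* ``common1`` — major allele coded 1,
* ``vcf:<id>`` — the named reference individual reads 0 at every SNP,
* ``random_mixed`` — each SNP's polarity flipped independently with a
  given probability (seeded),
* ``explicit`` — a user-supplied flip mask.

Flipping a SNP complements its column (x -> 1-x, or 2-x for diploid
codes); applying the same mask twice is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotype_io import GenotypeMatrix, GenotypeError

__all__ = [
    "PolarityMask",
    "allele1_frequencies",
    "individual_means",
    "recode",
    "apply_mask",
    "recode_diploid_rare2",
]

TIE_TOL = 1e-12  # frequencies within this of 0.5 are ties and left untouched


@dataclass(frozen=True)
class PolarityMask:
    """Per-SNP flip indicators; True complements that SNP's column."""

    flip: np.ndarray
    snp_ids: tuple[str, ...]

    def __post_init__(self):
        f = np.asarray(self.flip, dtype=bool)
        object.__setattr__(self, "flip", f)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        if f.ndim != 1 or f.shape[0] != len(self.snp_ids):
            raise GenotypeError("flip mask length must equal SNP count")

    @property
    def n_flipped(self) -> int:
        return int(self.flip.sum())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, f in zip(self.snp_ids, self.flip):
                fh.write(f"{sid}\t{int(f)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, snp_ids: tuple[str, ...] | None = None) -> "PolarityMask":
        ids: list[str] = []
        flips: list[bool] = []
        with open(path) as fh:
            for ln in fh:
                if not ln.strip():
                    continue
                sid, f = ln.rstrip("\r\n").split("\t")
                ids.append(sid)
                flips.append(bool(int(f)))
        mask = cls(np.array(flips, dtype=bool), tuple(ids))
        if snp_ids is not None and mask.snp_ids != tuple(snp_ids):
            raise GenotypeError("flip mask SNP ids do not match the matrix")
        return mask


def allele1_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of the allele coded 1 (the SNP column mean)."""
    if matrix.ploidy_mode != "binary":
        raise GenotypeError("allele-1 frequencies require binary (0/1) coding; convert diploid data first")
    return matrix.values.mean(axis=0)


def individual_means(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-Individual frequency of the allele coded 1 (the row mean)."""
    if matrix.ploidy_mode != "binary":
        raise GenotypeError("individual means require binary (0/1) coding")
    return matrix.values.mean(axis=1)


def apply_mask(matrix: GenotypeMatrix, mask: PolarityMask, coding: str = "mixed") -> GenotypeMatrix:
    """Complement the columns flagged by ``mask`` (an involution)."""
    if mask.flip.shape[0] != matrix.n_snps:
        raise GenotypeError("mask length does not match SNP count")
    top = 2 if matrix.ploidy_mode == "diploid" else 1
    out = matrix.values.copy()
    out[:, mask.flip] = top - out[:, mask.flip]
    return matrix.with_values(out, coding=coding)


def recode(
    matrix: GenotypeMatrix,
    scheme: str,
    seed: int | None = None,
    flip_probability: float = 0.5,
    mask: PolarityMask | None = None,
) -> tuple[GenotypeMatrix, PolarityMask]:
    """Recode SNP polarities under a named scheme.

    Returns the recoded matrix and the mask of SNPs that were complemented.
    Scheme names: ``rare1``, ``common1``, ``vcf:<individual_id>``,
    ``random_mixed`` (requires ``seed``), ``explicit`` (requires ``mask``).
    SNPs whose allele-1 frequency is exactly 0.5 are ties: rare1/common1
    leave them untouched.
    """
    if matrix.ploidy_mode != "binary":
        raise GenotypeError("recode operates on binary (0/1) matrices")
    freqs = allele1_frequencies(matrix)

    if scheme == "rare1":
        flip = freqs > 0.5 + TIE_TOL
        tag = "rare1"
    elif scheme == "common1":
        flip = freqs < 0.5 - TIE_TOL
        tag = "common1"
    elif scheme.startswith("vcf:"):
        ref_id = scheme[4:]
        try:
            ref_row = matrix.individual_ids.index(ref_id)
        except ValueError:
            raise GenotypeError(f"reference individual {ref_id!r} not in matrix") from None
        flip = matrix.values[ref_row, :] == 1
        tag = f"vcf:{ref_id}"
    elif scheme == "random_mixed":
        if seed is None:
            raise GenotypeError("random_mixed requires an explicit seed")
        if not 0.0 <= flip_probability <= 1.0:
            raise GenotypeError("flip_probability must be in [0, 1]")
        rng = np.random.default_rng(seed)
        flip = rng.random(matrix.n_snps) < flip_probability
        tag = "mixed"
    elif scheme == "explicit":
        if mask is None:
            raise GenotypeError("explicit scheme requires a PolarityMask")
        flip = mask.flip
        tag = "mixed"
    else:
        raise GenotypeError(f"unknown coding scheme {scheme!r}")

    pmask = PolarityMask(np.asarray(flip, dtype=bool), matrix.snp_ids)
    return apply_mask(matrix, pmask, coding=tag), pmask


def recode_diploid_rare2(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, PolarityMask]:
    """Orient 0/1/2 codes so the rarest homozygote is 2 per SNP.

    Heterozygotes (1) are unchanged; SNPs whose two homozygote counts tie
    are left untouched.
    """
    if matrix.ploidy_mode != "diploid":
        raise GenotypeError("recode_diploid_rare2 requires diploid (0/1/2) mode")
    n2 = (matrix.values == 2).sum(axis=0)
    n0 = (matrix.values == 0).sum(axis=0)
    flip = n2 > n0
    pmask = PolarityMask(flip, matrix.snp_ids)
    return apply_mask(matrix, pmask, coding="rare1"), pmask
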