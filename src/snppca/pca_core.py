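"""Centering/standardization transforms, SVD, and scaled component scores.

Six transforms are supported prior to PCA of an Individuals-x-SNPs matrix:

========================  ====================================================
variant                   matrix decomposed
========================  ====================================================
``snp_centered``          D minus per-SNP (column) means
``individual_centered``   D minus per-Individual (row) means
``double_centered``       D - mu_r - mu_c + mu  (the SxI interaction matrix)
``snp_standardized``      SNP-centered, each SNP scaled to unit SD (n-1)
``individual_standardized`` Individual-centered, rows scaled to unit SD (n-1)
``grand_mean_centered``   D - mu
========================  ====================================================

Double-centered PCA (DC-PCA) decomposes the pure interaction matrix; its
components are interaction principal components (IPCs).  The model for a
datum is ``D_rc = mu_r + mu_c - mu + sum_n lambda_n gamma_rn delta_cn + rho_rc``
with unit eigenvectors gamma (Individuals) and delta (SNPs).  Scores are,
by default, eigenvectors scaled by sqrt(lambda) on both axes so the product
of an Individual score and a SNP score estimates their interaction directly.

Degrees of freedom for multiplicative components follow the Gollob rule:
``p + n - 1 - 2k`` for the k-th component of a double-centered p x n
matrix, with one more df per uncentered axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .genotype_io import GenotypeMatrix, GenotypeError

__all__ = [
    "VARIANTS",
    "VARIANT_ALIASES",
    "TransformedMatrix",
    "PCAResult",
    "transform",
    "decompose",
    "pca",
    "component_df",
    "source_df",
    "reconstruct",
]

VARIANTS = (
    "snp_centered",
    "individual_centered",
    "double_centered",
    "snp_standardized",
    "individual_standardized",
    "grand_mean_centered",
)

# short CLI aliases
VARIANT_ALIASES = {
    "dc": "double_centered",
    "snpc": "snp_centered",
    "indc": "individual_centered",
    "snps": "snp_standardized",
    "inds": "individual_standardized",
    "gm": "grand_mean_centered",
}


def canonical_variant(name: str) -> str:
    v = VARIANT_ALIASES.get(name, name)
    if v not in VARIANTS:
        raise GenotypeError(f"unknown PCA variant {name!r}")
    return v


@dataclass(frozen=True)
class TransformedMatrix:
    """A genotype matrix after one of the six transforms.

    Means (and SDs for standardized variants) of the source matrix are
    retained so the additive part of the model can be reconstructed.
    """

    values: np.ndarray
    variant: str
    individual_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    grand_mean: float
    individual_means: np.ndarray
    snp_means: np.ndarray
    snp_sd: np.ndarray | None = None
    individual_sd: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def total_ss(self) -> float:
        return float(np.sum(self.values**2))


@dataclass(frozen=True)
class PCAResult:
    """Truncated SVD of a transformed matrix with ANOVA bookkeeping.

    ``individual_eigenvectors`` (R x k) and ``snp_eigenvectors`` (C x k)
    are unit vectors; ``singular_values`` descend.  Component sum of
    squares is the squared singular value; dfs follow the Gollob rule for
    the source variant.
    """

    variant: str
    k: int
    singular_values: np.ndarray
    individual_eigenvectors: np.ndarray
    snp_eigenvectors: np.ndarray
    individual_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    total_ss: float
    component_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.component_names == ():
            prefix = "IPC" if self.variant == "double_centered" else "PC"
            object.__setattr__(
                self, "component_names", tuple(f"{prefix}{i + 1}" for i in range(self.k))
            )

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.individual_eigenvectors.shape[0]

    @property
    def n_snps(self) -> int:
        return self.snp_eigenvectors.shape[0]

    @property
    def component_ss(self) -> np.ndarray:
        return self.singular_values**2

    @property
    def component_dfs(self) -> np.ndarray:
        return np.array(
            [component_df(self.n_snps, self.n_individuals, i + 1, self.variant) for i in range(self.k)]
        )

    @property
    def source_df(self) -> int:
        return source_df(self.n_snps, self.n_individuals, self.variant)

    @property
    def residual_ss(self) -> float:
        return float(self.total_ss - self.component_ss.sum())

    @property
    def residual_df(self) -> int:
        return int(self.source_df - self.component_dfs.sum())

    # -- scores -----------------------------------------------------------
    def scores(
        self,
        axis: Literal["individuals", "snps"],
        scaling: Literal["symmetric_sqrt", "axis_principal"] = "symmetric_sqrt",
    ) -> np.ndarray:
        """Component scores for one axis.

        ``symmetric_sqrt`` (default) multiplies unit eigenvectors of both
        axes by sqrt(lambda), so products of paired scores estimate
        interactions directly.  ``axis_principal`` multiplies the requested
        axis by lambda itself, optimizing inter-point distances for a
        monoplot of that axis.
        """
        vec = self.individual_eigenvectors if axis == "individuals" else self.snp_eigenvectors
        if scaling == "symmetric_sqrt":
            return vec * np.sqrt(self.singular_values)
        if scaling == "axis_principal":
            return vec * self.singular_values
        raise GenotypeError(f"unknown scaling {scaling!r}")

    def rank1_matrix(self, component: int) -> np.ndarray:
        """lambda_n * gamma_n * delta_n^T for one component (0-based)."""
        lam = self.singular_values[component]
        g = self.individual_eigenvectors[:, component]
        d = self.snp_eigenvectors[:, component]
        return lam * np.outer(g, d)


# ---------------------------------------------------------------------------
# transforms


def transform(matrix: GenotypeMatrix | np.ndarray, variant: str, ids=None) -> TransformedMatrix:
    """Apply one of the six transforms prior to SVD."""
    variant = canonical_variant(variant)
    if isinstance(matrix, GenotypeMatrix):
        values = matrix.values.astype(float)
        ind_ids, snp_ids = matrix.individual_ids, matrix.snp_ids
    else:
        values = np.asarray(matrix, dtype=float)
        if ids is not None:
            ind_ids, snp_ids = tuple(ids[0]), tuple(ids[1])
        else:
            r, c = values.shape
            ind_ids = tuple(f"ind{i + 1:04d}" for i in range(r))
            snp_ids = tuple(f"snp{j + 1:04d}" for j in range(c))

    mu = float(values.mean())
    mu_r = values.mean(axis=1)
    mu_c = values.mean(axis=0)
    snp_sd = individual_sd = None

    if variant == "snp_centered":
        out = values - mu_c
    elif variant == "individual_centered":
        out = values - mu_r[:, None]
    elif variant == "double_centered":
        out = values - mu_r[:, None] - mu_c + mu
    elif variant == "grand_mean_centered":
        out = values - mu
    elif variant == "snp_standardized":
        snp_sd = values.std(axis=0, ddof=1)
        zero = np.flatnonzero(snp_sd == 0.0)
        if zero.size:
            raise GenotypeError(
                f"SNP {snp_ids[zero[0]]!r} has zero standard deviation; "
                "snp_standardized is undefined (drop monomorphic SNPs first)"
            )
        out = (values - mu_c) / snp_sd
    elif variant == "individual_standardized":
        individual_sd = values.std(axis=1, ddof=1)
        zero = np.flatnonzero(individual_sd == 0.0)
        if zero.size:
            raise GenotypeError(
                f"Individual {ind_ids[zero[0]]!r} has zero standard deviation; "
                "individual_standardized is undefined"
            )
        out = (values - mu_r[:, None]) / individual_sd[:, None]
    else:  # pragma: no cover - canonical_variant guards
        raise GenotypeError(variant)

    return TransformedMatrix(
        values=out,
        variant=variant,
        individual_ids=ind_ids,
        snp_ids=snp_ids,
        grand_mean=mu,
        individual_means=mu_r,
        snp_means=mu_c,
        snp_sd=snp_sd,
        individual_sd=individual_sd,
    )


def rank_bound(R: int, C: int, variant: str) -> int:
    """Maximum number of nonzero singular values after a transform."""
    variant = canonical_variant(variant)
    if variant == "double_centered":
        return min(R - 1, C - 1)
    if variant in ("snp_centered", "snp_standardized"):
        return min(R - 1, C)
    if variant in ("individual_centered", "individual_standardized"):
        return min(R, C - 1)
    return min(R, C)  # grand_mean_centered


def decompose(tm: TransformedMatrix, k: int) -> PCAResult:
    """SVD of a transformed matrix, retaining ``k`` components.

    Sign convention: each component is oriented (jointly on both axes, so
    all reconstructed products are unchanged) so that the SNP-eigenvector
    entry of largest magnitude is positive.
    """
    R, C = tm.shape
    bound = rank_bound(R, C, tm.variant)
    if not 1 <= k <= bound:
        raise GenotypeError(f"k={k} outside [1, {bound}] for variant {tm.variant}")
    U, s, Vt = np.linalg.svd(tm.values, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k, :]
    V = Vt.T
    # deterministic joint sign convention
    for n in range(k):
        j = int(np.argmax(np.abs(V[:, n])))
        if V[j, n] < 0:
            V[:, n] = -V[:, n]
            U[:, n] = -U[:, n]
    return PCAResult(
        variant=tm.variant,
        k=k,
        singular_values=s,
        individual_eigenvectors=U,
        snp_eigenvectors=V,
        individual_ids=tm.individual_ids,
        snp_ids=tm.snp_ids,
        total_ss=tm.total_ss,
    )


def pca(matrix: GenotypeMatrix | np.ndarray, variant: str, k: int) -> PCAResult:
    """Convenience: ``decompose(transform(matrix, variant), k)``."""
    return decompose(transform(matrix, variant), k)


# ---------------------------------------------------------------------------
# degrees of freedom


def component_df(p: int, n: int, k: int, variant: str) -> int:
    """Gollob df of the k-th multiplicative component (p SNPs, n Individuals)."""
    variant = canonical_variant(variant)
    if k < 1:
        raise GenotypeError("component index k must be >= 1")
    if variant == "double_centered":
        df = p + n - 1 - 2 * k
    elif variant == "grand_mean_centered":
        df = p + n + 1 - 2 * k
    else:  # singly centered or standardized
        df = p + n - 2 * k
    if df <= 0:
        raise GenotypeError(f"component {k} has nonpositive df for a {p}x{n} matrix")
    return df


def source_df(p: int, n: int, variant: str) -> int:
    """df of the matrix each variant decomposes (p SNPs, n Individuals)."""
    variant = canonical_variant(variant)
    if variant == "double_centered":
        return (p - 1) * (n - 1)
    if variant in ("snp_centered", "snp_standardized"):
        return p * (n - 1)
    if variant in ("individual_centered", "individual_standardized"):
        return n * (p - 1)
    return p * n - 1  # grand_mean_centered


def reconstruct(res: PCAResult, k: int) -> np.ndarray:
    """Rank-k least-squares estimate sum_{n<=k} lambda_n gamma_n delta_n^T."""
    if not 0 <= k <= res.k:
        raise GenotypeError(f"k={k} exceeds the {res.k} retained components")
    if k == 0:
        return np.zeros((res.n_individuals, res.n_snps))
    U = res.individual_eigenvectors[:, :k]
    V = res.snp_eigenvectors[:, :k]
    return (U * res.singular_values[:k]) @ V.T
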