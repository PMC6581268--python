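"""Seeded synthetic genotype matrices with known structure.

Two generators cover the structures the rest of the package is built to
display:

* ``diagonal_band_matrix`` — a 0/1 matrix with ones along a diagonal band,
  the signature of a single environmental/causal gradient.  Its DC-PCA
  biplot shows the classic arch (horseshoe) distortion, and its CA1
  arrangement recovers the band.
* ``structured_bernoulli`` — independent Bernoulli entries whose success
  probability carries additive SNP-main, Individual-main, and
  multiplicative interaction structure with requested shares of the total
  sum of squares, for exercising the three-source ANOVA decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix, GenotypeError
from .snp_coding import recode

__all__ = ["diagonal_band_matrix", "structured_bernoulli", "BernoulliTruth"]

CLAMP_EPS = 0.02  # Bernoulli probabilities clamped to [eps, 1-eps]


def diagonal_band_matrix(
    n_individuals: int,
    n_snps: int,
    band_width: int = 3,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """A banded 0/1 matrix driven by a single gradient, rare=1 coded.

    Entry (r, c) is 1 when the normalized column position is within half
    the band width (in column units) of the row's band center; the center
    is the row's own normalized position, clamped away from the matrix
    edges so every row carries a full-width band (edge truncation would
    otherwise exaggerate the involution of the arch).  Each entry is then
    flipped independently with probability ``noise_rate``, and the result
    is recoded rare=1 so downstream CA/biplot conventions hold.
    """
    if n_individuals < 2 or n_snps < 2:
        raise GenotypeError("need at least 2 individuals and 2 SNPs")
    if band_width < 1:
        raise GenotypeError("band_width must be >= 1")
    if not 0.0 <= noise_rate < 0.5:
        raise GenotypeError("noise_rate must be in [0, 0.5)")
    r = (np.arange(n_individuals) + 0.5) / n_individuals
    c = (np.arange(n_snps) + 0.5) / n_snps
    half = band_width / (2.0 * n_snps)  # half-width on the normalized scale
    center = np.clip(r, half, 1.0 - half)
    values = (np.abs(center[:, None] - c[None, :]) <= half).astype(np.int64)
    if noise_rate > 0:
        rng = np.random.default_rng(seed)
        flips = rng.random(values.shape) < noise_rate
        values = np.where(flips, 1 - values, values)
    # guard degenerate all-constant rows/columns introduced by tiny bands
    if values.sum() == 0:
        raise GenotypeError("band too narrow: matrix is all zeros")
    gm = GenotypeMatrix(
        values,
        tuple(f"ind{i + 1:04d}" for i in range(n_individuals)),
        tuple(f"snp{j + 1:04d}" for j in range(n_snps)),
        coding="unknown",
    )
    recoded, _ = recode(gm, "rare1")
    return recoded


@dataclass(frozen=True)
class BernoulliTruth:
    """Generating parameters behind a structured Bernoulli matrix."""

    base: float
    individual_effects: np.ndarray  # a_r
    snp_effects: np.ndarray  # b_c
    interaction_row: np.ndarray  # g, one row per rank-1 term
    interaction_col: np.ndarray  # h, one row per rank-1 term
    probabilities: np.ndarray
    clamped_fraction: float


def structured_bernoulli(
    n_individuals: int,
    n_snps: int,
    share_snp: float = 0.0,
    share_individual: float = 0.0,
    share_interaction: float | tuple[float, ...] = 0.0,
    base: float = 0.5,
    seed: int = 0,
    max_clamped: float = 0.10,
) -> tuple[GenotypeMatrix, BernoulliTruth]:
    """Bernoulli 0/1 matrix with controllable three-source structure.

    Entries are Bernoulli(pi_rc) with
    ``pi_rc = clamp(base + a_r + b_c + sum_t g_tr * h_tc, eps, 1 - eps)``;
    ``share_interaction`` may be a single share (one rank-1 interaction
    term) or a tuple of shares, one per term, giving an interaction of
    higher rank with well-separated singular values.
    Because the binomial variance lost where pi moves away from ``base``
    exactly offsets the systematic variance gained, the expected total sum
    of squares is ``R*C*base*(1-base)`` whatever the effects; each source's
    systematic SS is scaled to the requested share of that total.  Effect
    vectors are balanced sign patterns (half positive, half negative, in
    seeded random order) of constant magnitude, which spreads the
    systematic variance as flat as possible and so maximizes the feasible
    share range before probabilities saturate.  Requested shares are
    targets in expectation, not exact realizations; binomial noise lands
    almost entirely in the interaction SS, so the realized interaction
    share sits far above its requested systematic share.
    """
    int_shares = tuple(np.atleast_1d(share_interaction).astype(float))
    if share_snp < 0 or share_individual < 0 or any(s < 0 for s in int_shares):
        raise GenotypeError("shares must be nonnegative")
    s_tot = share_snp + share_individual + sum(int_shares)
    if s_tot >= 1.0:
        raise GenotypeError("shares must sum to less than 1")
    if not CLAMP_EPS < base < 1 - CLAMP_EPS:
        raise GenotypeError(f"base rate must lie in ({CLAMP_EPS}, {1 - CLAMP_EPS})")
    R, C = n_individuals, n_snps
    if R < 2 or C < 2:
        raise GenotypeError("need at least 2 individuals and 2 SNPs")
    rng = np.random.default_rng(seed)
    cell_var = base * (1 - base)  # expected total SS is R*C*cell_var

    def signs(n: int) -> np.ndarray:
        s = np.ones(n)
        s[: n // 2] = -1.0
        rng.shuffle(s)
        return s - s.mean()  # exact zero mean (handles odd n)

    # C*sum(a^2) = share*R*C*cell_var  =>  |a| = sqrt(share*cell_var)
    a = signs(R) * np.sqrt(share_individual * cell_var)
    b = signs(C) * np.sqrt(share_snp * cell_var)
    # per term: sum(g^2)*sum(h^2) = share*R*C*cell_var  =>  |g_r h_c| = sqrt(share*cell_var)
    g = np.stack([signs(R) * (s * cell_var) ** 0.25 for s in int_shares]) if int_shares else np.zeros((0, R))
    h = np.stack([signs(C) * (s * cell_var) ** 0.25 for s in int_shares]) if int_shares else np.zeros((0, C))

    pi = base + a[:, None] + b[None, :] + g.T @ h
    clamped = (pi < CLAMP_EPS) | (pi > 1 - CLAMP_EPS)
    frac = float(clamped.mean())
    if frac > max_clamped:
        raise GenotypeError(
            f"infeasible shares: clamping saturates {frac:.1%} of cells (> {max_clamped:.0%})"
        )
    pi = np.clip(pi, CLAMP_EPS, 1 - CLAMP_EPS)
    values = (rng.random((R, C)) < pi).astype(np.int64)
    gm = GenotypeMatrix(
        values,
        tuple(f"ind{i + 1:04d}" for i in range(R)),
        tuple(f"snp{j + 1:04d}" for j in range(C)),
        coding="unknown",
    )
    truth = BernoulliTruth(
        base=base,
        individual_effects=a,
        snp_effects=b,
        interaction_row=g,
        interaction_col=h,
        probabilities=pi,
        clamped_fraction=frac,
    )
    return gm, truth
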