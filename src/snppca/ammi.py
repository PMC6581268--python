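"""Additive Main effects and Multiplicative Interaction (AMMI) model.

AMMI fits grand mean + Individual main effects + SNP main effects by
ANOVA, and the SNP-by-Individual interaction by PCA of the double-centered
matrix.  Its multiplicative part is therefore identical to DC-PCA; the
difference is that AMMI retains the main effects rather than discarding
them.  The AMMI1 biplot plots main effects (means) on the abscissa and the
IPC1 score on the ordinate, so it displays main and interaction effects
without confounding them; its two axes carry different kinds of
information and are exempt from the equal-axis-scale rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, GenotypeError
from .anova_tables import AnovaTable, dc_pca_anova
from .pca_core import PCAResult, decompose, transform

__all__ = ["AMMIModel", "fit_ammi", "ammi1_coordinates"]


@dataclass(frozen=True)
class AMMIModel:
    grand_mean: float
    individual_means: np.ndarray
    snp_means: np.ndarray
    interaction: PCAResult  # DC-PCA of the same matrix
    k: int
    source_values: np.ndarray | None = None

    @property
    def individual_effects(self) -> np.ndarray:
        return self.individual_means - self.grand_mean

    @property
    def snp_effects(self) -> np.ndarray:
        return self.snp_means - self.grand_mean

    def predict(self, k: int | None = None) -> np.ndarray:
        """Expected values: mu + a_r + b_c + first-k multiplicative terms."""
        from .pca_core import reconstruct

        k = self.k if k is None else k
        additive = self.individual_means[:, None] + self.snp_means[None, :] - self.grand_mean
        return additive + reconstruct(self.interaction, k)

    def anova(self) -> AnovaTable:
        """ANOVA table of the fit — identical to the DC-PCA table."""
        if self.source_values is None:
            raise GenotypeError("model was built without its source matrix")
        return dc_pca_anova(self.source_values, self.k)


def fit_ammi(matrix, k: int) -> AMMIModel:
    """Fit the AMMI model with ``k`` multiplicative interaction terms."""
    values = matrix.values.astype(float) if isinstance(matrix, GenotypeMatrix) else np.asarray(matrix, float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise GenotypeError("AMMI needs at least a 2x2 matrix")
    tm = transform(values, "double_centered")
    res = decompose(tm, k)
    return AMMIModel(
        grand_mean=tm.grand_mean,
        individual_means=tm.individual_means,
        snp_means=tm.snp_means,
        interaction=res,
        k=k,
        source_values=values,
    )


def ammi1_coordinates(model: AMMIModel) -> tuple[pd.DataFrame, dict]:
    """Point coordinates for the AMMI1 biplot.

    Returns a DataFrame with columns (id, panel, abscissa, ordinate) —
    abscissa is the mean frequency of the allele coded 1 (row/column
    mean), ordinate the IPC1 score — plus metadata: the grand-mean
    reference line and the share of SxI interaction SS captured by the
    ordinate.  The abscissa captures 100% of both main effects and 0% of
    the interaction.
    """
    if model.k < 1:
        raise GenotypeError("AMMI1 needs at least one multiplicative term")
    res = model.interaction
    ind_scores = res.scores("individuals")[:, 0]
    snp_scores = res.scores("snps")[:, 0]
    pts = pd.DataFrame(
        {
            "id": list(res.individual_ids) + list(res.snp_ids),
            "panel": ["individuals"] * res.n_individuals + ["snps"] * res.n_snps,
            "abscissa": np.concatenate([model.individual_means, model.snp_means]),
            "ordinate": np.concatenate([ind_scores, snp_scores]),
        }
    )
    sxi_ss = res.total_ss  # the double-centered matrix IS the SxI interaction
    meta = {
        "grand_mean": model.grand_mean,
        "ordinate_component": res.component_names[0],
        "ipc1_share_of_sxi": float(res.component_ss[0] / sxi_ss) if sxi_ss > 0 else 0.0,
        "abscissa_share_of_main_effects": 1.0,
        "abscissa_share_of_sxi": 0.0,
        "equal_scale": False,
    }
    return pts, meta
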