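"""Three-source ANOVA, the DC-PCA ANOVA table, and augmented ANOVA tables.

An Individuals-x-SNPs matrix is a two-way factorial, so its corrected total
sum of squares splits orthogonally into SNP main effects, Individual main
effects, and SNP-by-Individual (SxI) interaction effects.  DC-PCA then
partitions the SxI interaction into multiplicative components.

When PCA is instead applied to a matrix that still contains main effects
(every variant other than double-centered), each component mixes main and
interaction information.  The augmented ANOVA table quantifies the mixture:
each component's rank-1 expected-value matrix (lambda_n gamma_n delta_n^T)
is itself subjected to ANOVA, splitting the component's sum of squares into
the portions attributable to each retained source.  The residual matrix
(source minus all retained rank-1 terms) is partitioned the same way.

Portions always sum to their row's SS.  For the singly-centered and
standardized variants the portion *columns* also sum to the source SS,
because every retained singular vector has exactly zero mean on the
centered axis, which makes the per-component main-effect projections
mutually orthogonal.  Grand-mean-centered PCA lacks that property: its
rank-1 terms can carry nonzero grand means and non-orthogonal main-effect
projections, so only row closure holds there, and an explicit "Mean"
portion column keeps it exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, GenotypeError
from .pca_core import (
    PCAResult,
    canonical_variant,
    component_df,
    decompose,
    reconstruct,
    source_df,
    transform,
)

__all__ = [
    "AnovaTable",
    "AugmentedAnovaTable",
    "three_source_anova",
    "dc_pca_anova",
    "augmented_anova",
    "classify_pc_outcomes",
]


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, GenotypeMatrix):
        return matrix.values.astype(float)
    return np.asarray(matrix, dtype=float)


@dataclass(frozen=True)
class AnovaTable:
    """Ordered (source, df, SS) rows with indentation levels for subtotals."""

    table: pd.DataFrame  # columns: source, df, ss, level

    def ss(self, source: str) -> float:
        return float(self.table.set_index("source").loc[source, "ss"])

    def df(self, source: str) -> int:
        return int(self.table.set_index("source").loc[source, "df"])

    @property
    def sources(self) -> list[str]:
        return list(self.table["source"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_text(self) -> str:
        """Human-readable table with SS at 3 decimal places."""
        lines = []
        for _, row in self.table.iterrows():
            indent = "  " * int(row.get("level", 0))
            lines.append(f"{indent}{row['source']:<14}{int(row['df']):>10}{row['ss']:>16.3f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return self.table.to_json(orient="records")


@dataclass(frozen=True)
class AugmentedAnovaTable(AnovaTable):
    """An ANOVA table whose component rows carry per-source SS portions."""

    portion_columns: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# core SS partitions


def _partition(values: np.ndarray) -> dict[str, float]:
    """Uncorrected decomposition of sum(M^2) into mean/SNPs/Individuals/SxI."""
    R, C = values.shape
    mu = values.mean()
    mu_r = values.mean(axis=1)
    mu_c = values.mean(axis=0)
    ss_mean = R * C * mu**2
    ss_snp = R * float(np.sum((mu_c - mu) ** 2))
    ss_ind = C * float(np.sum((mu_r - mu) ** 2))
    ss_tot = float(np.sum(values**2))
    ss_int = ss_tot - ss_mean - ss_snp - ss_ind
    return {"Mean": ss_mean, "SNPs": ss_snp, "Individuals": ss_ind, "SxI": ss_int}


def three_source_anova(matrix) -> AnovaTable:
    """Corrected-total ANOVA into SNP main, Individual main, and SxI effects."""
    values = _as_array(matrix)
    R, C = values.shape
    if R < 2 or C < 2:
        raise GenotypeError("ANOVA needs at least a 2x2 matrix")
    p = _partition(values)
    total = p["SNPs"] + p["Individuals"] + p["SxI"]
    rows = [
        ("Total", R * C - 1, total, 0),
        ("SNPs", C - 1, p["SNPs"], 1),
        ("Individuals", R - 1, p["Individuals"], 1),
        ("SxI", (R - 1) * (C - 1), p["SxI"], 1),
    ]
    return AnovaTable(pd.DataFrame(rows, columns=["source", "df", "ss", "level"]))


def dc_pca_anova(matrix, k: int) -> AnovaTable:
    """Three-source table with the SxI row split into IPC1..IPCk + Residual."""
    values = _as_array(matrix)
    base = three_source_anova(values)
    res = decompose(transform(values, "double_centered"), k)
    R, C = values.shape
    rows = list(base.table.itertuples(index=False, name=None))
    for n in range(k):
        rows.append((f"IPC{n + 1}", component_df(C, R, n + 1, "double_centered"), float(res.component_ss[n]), 2))
    rows.append(("Residual", res.residual_df, res.residual_ss, 2))
    return AnovaTable(pd.DataFrame(rows, columns=["source", "df", "ss", "level"]))


_RETAINED = {
    "snp_centered": ("Individuals", "SxI"),
    "snp_standardized": ("Individuals", "SxI"),
    "individual_centered": ("SNPs", "SxI"),
    "individual_standardized": ("SNPs", "SxI"),
    "grand_mean_centered": ("Mean", "SNPs", "Individuals", "SxI"),
}

_COMBINED_NAME = {
    "snp_centered": "I&SxI",
    "snp_standardized": "I&SxI",
    "individual_centered": "S&SxI",
    "individual_standardized": "S&SxI",
    "grand_mean_centered": "All",
}


def _restricted_portions(values: np.ndarray, retained: tuple[str, ...]) -> dict[str, float]:
    """Partition sum(M^2) over the retained sources only.

    Sources a variant centered away are exactly zero for its retained
    singular vectors; their numerical residue is folded into SxI so each
    row closes exactly to its SS.
    """
    p = _partition(values)
    total = float(np.sum(values**2))
    out = {s: p[s] for s in retained if s != "SxI"}
    out["SxI"] = total - sum(out.values())
    return out


def augmented_anova(matrix, variant: str, k: int) -> AnovaTable:
    """Augmented ANOVA table for one PCA variant.

    For ``double_centered`` the plain DC-PCA table is returned: every IPC
    is pure interaction, so there is nothing to augment.  Otherwise each
    component row and the residual row carry portion columns for the
    sources the variant retains; the grand-mean-centered variant retains a
    ``Mean`` portion as well because its rank-1 matrices can have a
    nonzero grand mean.
    """
    variant = canonical_variant(variant)
    values = _as_array(matrix)
    R, C = values.shape
    if variant == "double_centered":
        return dc_pca_anova(values, k)

    retained = _RETAINED[variant]
    tm = transform(values, variant)
    res = decompose(tm, k)
    base = _partition(values)
    total_corr = base["SNPs"] + base["Individuals"] + base["SxI"]

    portion_cols = list(retained)
    rows: list[dict] = []

    def add(source, df, ss, level, portions=None):
        row = {"source": source, "df": df, "ss": ss, "level": level}
        for col in portion_cols:
            row[col] = np.nan if portions is None else portions.get(col, 0.0)
        rows.append(row)

    combined_portions = _restricted_portions(tm.values, retained)
    if variant == "snp_centered":
        add("Total", R * C - 1, total_corr, 0)
        add("SNPs", C - 1, base["SNPs"], 1)
        add(_COMBINED_NAME[variant], source_df(C, R, variant), tm.total_ss, 1, combined_portions)
    elif variant == "individual_centered":
        add("Total", R * C - 1, total_corr, 0)
        add("Individuals", R - 1, base["Individuals"], 1)
        add(_COMBINED_NAME[variant], source_df(C, R, variant), tm.total_ss, 1, combined_portions)
    elif variant == "grand_mean_centered":
        # the grand-mean-centered matrix IS the corrected total
        add(_COMBINED_NAME[variant], source_df(C, R, variant), tm.total_ss, 0, combined_portions)
    else:
        # standardized variants: the decomposed matrix lives on a rescaled
        # axis, so raw-scale Total/main rows would not nest; report only
        # the standardized-scale rows
        add(_COMBINED_NAME[variant], source_df(C, R, variant), tm.total_ss, 0, combined_portions)

    for n in range(res.k):
        t = res.rank1_matrix(n)
        add(
            res.component_names[n],
            component_df(C, R, n + 1, variant),
            float(res.component_ss[n]),
            2,
            _restricted_portions(t, retained),
        )
    resid = tm.values - reconstruct(res, res.k)
    add("Residual", res.residual_df, res.residual_ss, 2, _restricted_portions(resid, retained))

    frame = pd.DataFrame(rows, columns=["source", "df", "ss", "level", *portion_cols])
    return AugmentedAnovaTable(frame, portion_columns=tuple(portion_cols))


def classify_pc_outcomes(table: AugmentedAnovaTable, components=("PC1", "PC2"), mixed_threshold: float = 0.2) -> dict[str, str]:
    """Label components as main-dominated, interaction-dominated, or mixed.

    A component is "mixed" when the minority portion exceeds
    ``mixed_threshold`` of its SS (default 20%); otherwise it is dominated
    by whichever portion is larger.  Main-effect portions (everything but
    SxI) are pooled.
    """
    if not isinstance(table, AugmentedAnovaTable) or not table.portion_columns:
        raise GenotypeError("classification requires an augmented table")
    idx = table.table.set_index("source")
    out: dict[str, str] = {}
    for comp in components:
        if comp not in idx.index:
            raise GenotypeError(f"component {comp!r} not in table")
        row = idx.loc[comp]
        sxi = float(row["SxI"])
        main = float(sum(row[c] for c in table.portion_columns if c != "SxI"))
        ss = float(row["ss"])
        minority = min(main, sxi) / ss if ss > 0 else 0.0
        if minority > mixed_threshold:
            out[comp] = "mixed"
        elif main >= sxi:
            out[comp] = "main-dominated"
        else:
            out[comp] = "interaction-dominated"
    return out
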