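"""Biplots, AMMI1 plots, and arranged-matrix heatmaps.

Conventions enforced here: component-vs-component plots draw a dashed
origin crosshair at (0, 0) and use the *same data scale* on both axes
(points far from the origin mean large interactions, and distances only
mean anything if a data unit has the same physical length both ways);
axis labels carry the percent of the decomposed source's sum of squares
each component captures.  AMMI1 plots carry a vertical reference line at
the grand mean and are exempt from the equal-scale rule because their two
axes hold different kinds of information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeError
from .ammi import AMMIModel, ammi1_coordinates
from .pca_core import PCAResult
from .structure_groups import GroupScheme

__all__ = [
    "BiplotSpec",
    "build_biplot",
    "axis_scale_ratio",
    "classify_scale_ratio",
    "render_biplot",
    "render_heatmap",
]

_SOURCE_NAME = {
    "double_centered": "SxI",
    "snp_centered": "I&SxI",
    "snp_standardized": "I&SxI (std)",
    "individual_centered": "S&SxI",
    "individual_standardized": "S&SxI (std)",
    "grand_mean_centered": "Total",
}


@dataclass(frozen=True)
class BiplotSpec:
    points: pd.DataFrame  # id, panel, x, y, group, marker
    layout: str  # "single_panel" or "two_panel"
    x_label: str
    y_label: str
    equal_scale: bool
    origin_crosshair: bool
    reference_vlines: tuple[float, ...] = ()
    palette: dict[str, str] = field(default_factory=dict)
    labeled_ids: tuple[str, ...] = ()
    title: str = ""

    def coords_tsv(self, path: str | Path) -> None:
        self.points.to_csv(path, sep="\t", index=False)


def build_biplot(
    result: PCAResult | AMMIModel,
    scheme: GroupScheme | None = None,
    axes: tuple[int, int] | str = (1, 2),
    layout: str = "auto",
    labeled_ids: tuple[str, ...] = (),
) -> BiplotSpec:
    """Assemble biplot geometry and labeling for a PCA result or AMMI model.

    ``axes`` is a 1-based component pair, or the string ``"ammi1"`` (the
    default when given an AMMIModel).  Group colors come from ``scheme``
    when provided.  Layout ``auto`` uses two panels above 2000 points.
    """
    if isinstance(result, AMMIModel) or axes == "ammi1":
        if not isinstance(result, AMMIModel):
            raise GenotypeError("axes='ammi1' requires an AMMIModel")
        pts, meta = ammi1_coordinates(result)
        pts = pts.rename(columns={"abscissa": "x", "ordinate": "y"})
        x_label = "Mean frequency of allele coded 1"
        pct = meta["ipc1_share_of_sxi"] * 100.0
        y_label = f"{meta['ordinate_component']} ({pct:.1f}% of SxI)"
        equal_scale = False
        vlines = (meta["grand_mean"],)
        crosshair = False
    else:
        i, j = axes
        if not (1 <= i <= result.k and 1 <= j <= result.k):
            raise GenotypeError(f"components {axes} not retained (k={result.k})")
        ind = result.scores("individuals")
        snp = result.scores("snps")
        pts = pd.DataFrame(
            {
                "id": list(result.individual_ids) + list(result.snp_ids),
                "panel": ["individuals"] * result.n_individuals + ["snps"] * result.n_snps,
                "x": np.concatenate([ind[:, i - 1], snp[:, i - 1]]),
                "y": np.concatenate([ind[:, j - 1], snp[:, j - 1]]),
            }
        )
        src = _SOURCE_NAME[result.variant]
        pct = result.component_ss / result.total_ss * 100.0
        names = result.component_names
        x_label = f"{names[i - 1]} ({pct[i - 1]:.1f}% of {src})"
        y_label = f"{names[j - 1]} ({pct[j - 1]:.1f}% of {src})"
        equal_scale = True
        vlines = ()
        crosshair = True

    if scheme is not None:
        ind_map = scheme.individual_groups.as_dict()
        snp_map = scheme.snp_groups.as_dict()
        pts["group"] = [
            ind_map.get(i, "?") if p == "individuals" else snp_map.get(i, "?")
            for i, p in zip(pts["id"], pts["panel"])
        ]
        palette = dict(scheme.palette)
    else:
        pts["group"] = pts["panel"]
        palette = {"individuals": "black", "snps": "tab:blue"}
    pts["marker"] = np.where(pts["panel"] == "individuals", "^", ".")

    if layout == "auto":
        layout = "two_panel" if len(pts) > 2000 else "single_panel"
    if layout not in ("single_panel", "two_panel"):
        raise GenotypeError(f"unknown layout {layout!r}")

    return BiplotSpec(
        points=pts,
        layout=layout,
        x_label=x_label,
        y_label=y_label,
        equal_scale=equal_scale,
        origin_crosshair=crosshair,
        reference_vlines=vlines,
        palette=palette,
        labeled_ids=tuple(labeled_ids),
    )


def axis_scale_ratio(
    x_extent: float, y_extent: float, x_length: float, y_length: float
) -> float:
    """Ratio (>= 1) of the two axes' data-units-per-physical-length scales."""
    if x_extent <= 0 or y_extent <= 0 or x_length <= 0 or y_length <= 0:
        raise GenotypeError("axis extents and lengths must be positive")
    sx = x_extent / x_length
    sy = y_extent / y_length
    return float(max(sx, sy) / min(sx, sy))


def classify_scale_ratio(ratio: float) -> str:
    """correct (<=1.01), slight (<=1.1), faulty (<=2), substantial (>2)."""
    if ratio < 1.0:
        raise GenotypeError("ratio is defined as larger/shorter scale, >= 1")
    if ratio <= 1.01:
        return "correct"
    if ratio <= 1.1:
        return "slight"
    if ratio <= 2.0:
        return "faulty"
    return "substantial"


# ---------------------------------------------------------------------------
# rendering (matplotlib, deterministic: no jitter, fixed ordering)


def _panels(spec: BiplotSpec):
    if spec.layout == "two_panel":
        return [("individuals",), ("snps",)]
    return [("individuals", "snps")]


def render_biplot(spec: BiplotSpec, path: str | Path, dpi: int = 150) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    matplotlib.rcParams["svg.hashsalt"] = "snppca"  # reproducible SVG ids
    import matplotlib.pyplot as plt

    panels = _panels(spec)
    fig, axs = plt.subplots(1, len(panels), figsize=(6 * len(panels), 6))
    axs = np.atleast_1d(axs)
    for ax, panel_set in zip(axs, panels):
        sub = spec.points[spec.points["panel"].isin(panel_set)]
        for (grp, mk), block in sub.groupby(["group", "marker"], sort=True):
            ax.scatter(
                block["x"],
                block["y"],
                s=14,
                marker=mk,
                c=spec.palette.get(grp, "gray"),
                label=str(grp),
                linewidths=0,
            )
        for iid in spec.labeled_ids:
            hit = sub[sub["id"] == iid]
            for _, row in hit.iterrows():
                ax.annotate(iid, (row["x"], row["y"]), fontsize=7)
        if spec.origin_crosshair:
            ax.axhline(0.0, ls="--", lw=0.7, c="gray")
            ax.axvline(0.0, ls="--", lw=0.7, c="gray")
        for x in spec.reference_vlines:
            ax.axvline(x, ls="-", lw=0.9, c="gray")
        if spec.equal_scale:
            ax.set_aspect("equal", adjustable="datalim")
        ax.set_xlabel(spec.x_label)
        ax.set_ylabel(spec.y_label)
        ax.legend(fontsize=7, loc="best")
        ax.set_title(", ".join(panel_set))
    if spec.title:
        fig.suptitle(spec.title)
    fig.tight_layout()
    meta = {"Date": None} if str(path).endswith(".svg") else None
    fig.savefig(path, dpi=dpi, metadata=meta)
    plt.close(fig)


def render_heatmap(values: np.ndarray, path: str | Path, dpi: int = 150, title: str = "") -> None:
    """Two-tone heatmap of a 0/1 matrix: 1 dark, 0 light."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap(["#cfe3f5", "#0b3d91"])  # light blue 0, dark blue 1
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.imshow(np.asarray(values), cmap=cmap, aspect="auto", interpolation="nearest")
    ax.set_xlabel("SNPs (CA1 order)")
    ax.set_ylabel("Individuals (CA1 order)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
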