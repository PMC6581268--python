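"""Coherent group/color schemes for both panels of a biplot.

Two complementary routes give Individuals and SNPs a unified color scheme:

* expert transfer — given expert group labels for the Individuals, each
  SNP is assigned the group in which its rare (coded-1) allele reaches the
  highest frequency;
* automated CA1 quantiles — both axes are cut into k contiguous,
  near-equal blocks along the ranked CA1 order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, GroupAssignment, GenotypeError

__all__ = [
    "GroupScheme",
    "snp_groups_from_individual_groups",
    "quantile_groups_by_order",
    "ca1_quantile_scheme",
    "expert_scheme",
    "label_anomalies",
    "EXPERT_PALETTE",
    "QUANTILE_PALETTE_5",
]

EXPERT_PALETTE = ("green", "blue", "red")
QUANTILE_PALETTE_5 = ("darkgreen", "lightgreen", "black", "pink", "red")


@dataclass(frozen=True)
class GroupScheme:
    individual_groups: GroupAssignment
    snp_groups: GroupAssignment
    provenance: str  # "expert_transfer" or "ca1_quantile"
    palette: dict[str, str] = field(default_factory=dict)

    def palette_json(self) -> str:
        return json.dumps(self.palette, indent=2)


def snp_groups_from_individual_groups(
    matrix: GenotypeMatrix, groups: GroupAssignment
) -> tuple[GroupAssignment, list[str]]:
    """Transfer expert Individual groups to SNPs by argmax rare-allele frequency.

    For each SNP the within-group frequency of the allele coded 1 is
    computed and the SNP joins the group where that frequency is highest.
    Ties go to the largest group, then to the lexicographically first
    name; tied SNP ids are returned alongside the assignment.
    """
    if groups.axis != "individuals":
        raise GenotypeError("expected a group assignment over individuals")
    groups.check_against(matrix)
    if matrix.coding not in ("rare1", "unknown"):
        warnings.warn(
            f"expert transfer expects rare=1 coding; matrix is coded {matrix.coding!r}",
            stacklevel=2,
        )
    lab_of = groups.as_dict()
    names = sorted(set(groups.labels))
    rows_by_group = {
        g: [i for i, iid in enumerate(matrix.individual_ids) if lab_of[iid] == g] for g in names
    }
    for g, rows in rows_by_group.items():
        if not rows:
            raise GenotypeError(f"group {g!r} has no members")
    sizes = {g: len(rows) for g, rows in rows_by_group.items()}
    # within-group allele-1 frequency per SNP, groups in sorted name order
    freq = np.stack([matrix.values[rows_by_group[g], :].mean(axis=0) for g in names])

    labels: list[str] = []
    ties: list[str] = []
    for j, sid in enumerate(matrix.snp_ids):
        col = freq[:, j]
        best = col.max()
        cand = [names[i] for i in np.flatnonzero(col == best)]
        if len(cand) > 1:
            ties.append(sid)
            cand.sort(key=lambda g: (-sizes[g], g))
        labels.append(cand[0])
    return GroupAssignment(matrix.snp_ids, tuple(labels), axis="snps"), ties


def quantile_groups_by_order(
    order: np.ndarray | list,
    k: int,
    item_ids: tuple[str, ...] | None = None,
    axis: str = "individuals",
    group_names: tuple[str, ...] | None = None,
) -> GroupAssignment:
    """Cut an ordering into k contiguous blocks of floor(N/k), remainder last.

    ``order`` is a permutation (positions of items along the CA1 axis).
    Returned labels follow the *original* item order, so the assignment
    lines up with the matrix axes.
    """
    order = np.asarray(order)
    n = order.shape[0]
    if not 2 <= k <= n:
        raise GenotypeError(f"group count k={k} must be in [2, {n}]")
    base = n // k
    sizes = [base] * k
    sizes[-1] += n - base * k
    if group_names is None:
        group_names = tuple(f"G{i + 1}" for i in range(k))
    labels_along_order = np.repeat(group_names, sizes)
    labels = np.empty(n, dtype=object)
    labels[order] = labels_along_order
    if item_ids is None:
        prefix = "ind" if axis == "individuals" else "snp"
        item_ids = tuple(f"{prefix}{i + 1:04d}" for i in range(n))
    return GroupAssignment(tuple(item_ids), tuple(labels), axis=axis)


def ca1_quantile_scheme(arranged, k: int = 5) -> GroupScheme:
    """Automated GroupScheme: k CA1-order quantile groups on both axes."""
    from .correspondence import ArrangedMatrix

    if not isinstance(arranged, ArrangedMatrix):
        raise GenotypeError("expected an ArrangedMatrix")
    names = tuple(f"G{i + 1}" for i in range(k))
    ind = quantile_groups_by_order(
        arranged.row_order, k, item_ids=arranged.source.individual_ids, axis="individuals", group_names=names
    )
    snp = quantile_groups_by_order(
        arranged.col_order, k, item_ids=arranged.source.snp_ids, axis="snps", group_names=names
    )
    palette = dict(zip(names, QUANTILE_PALETTE_5 if k == 5 else _cycle_palette(k)))
    return GroupScheme(ind, snp, provenance="ca1_quantile", palette=palette)


def expert_scheme(matrix: GenotypeMatrix, groups: GroupAssignment) -> GroupScheme:
    """Expert GroupScheme: given Individual groups, transfer them to SNPs."""
    snp_groups, _ = snp_groups_from_individual_groups(matrix, groups)
    names = sorted(set(groups.labels))
    palette = dict(zip(names, EXPERT_PALETTE if len(names) <= 3 else _cycle_palette(len(names))))
    return GroupScheme(groups, snp_groups, provenance="expert_transfer", palette=palette)


def _cycle_palette(k: int) -> tuple[str, ...]:
    base = ("green", "blue", "red", "orange", "purple", "brown", "teal", "magenta")
    return tuple(base[i % len(base)] for i in range(k))


def label_anomalies(
    expert: GroupAssignment, order: np.ndarray, window: int = 10
) -> list[tuple[str, str, str]]:
    """Items whose expert label disagrees with their CA1 neighborhood.

    For each item, the majority expert label among its ``window`` nearest
    neighbors along the CA1 order (excluding itself) is computed; items
    whose own label differs are reported as (item_id, own_label,
    neighborhood_majority).  A report to prompt review, not a claim.
    """
    order = np.asarray(order)
    n = order.shape[0]
    labels = np.asarray(expert.labels, dtype=object)
    ids = expert.item_ids
    pos_labels = labels[order]  # labels along the CA1 axis
    out: list[tuple[str, str, str]] = []
    for pos in range(n):
        lo = max(0, pos - window)
        hi = min(n, pos + window + 1)
        neigh = np.concatenate([pos_labels[lo:pos], pos_labels[pos + 1 : hi]])
        if neigh.size == 0:
            continue
        vals, counts = np.unique(neigh, return_counts=True)
        majority = vals[np.argmax(counts)]
        own = pos_labels[pos]
        if own != majority and counts.max() > neigh.size / 2:
            out.append((ids[order[pos]], str(own), str(majority)))
    return out
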