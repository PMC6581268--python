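"""Reading, validating and writing biallelic genotype matrices.

The internal orientation is fixed: Individuals in rows, SNPs in columns.
Files laid out the other way around are transposed on entry.  Entries are
0/1 in binary (haploid/inbred-line) mode or 0/1/2 in diploid mode, with the
heterozygote coded 1.  Missing values are a hard error by default because
every downstream analysis assumes a complete matrix; an explicit opt-in
flag performs per-SNP mean imputation (rounded back to the code set) as a
clearly marked extension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GroupAssignment",
    "ValidationReport",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_group_assignment",
    "write_group_assignment",
    "shift_codes",
    "validate",
]

_MISSING_TOKENS = {"", "NA", "N/A", "NAN", ".", "-", "?"}

_DELIMS = {"tsv": "\t", "csv": ",", "whitespace": None}


class GenotypeError(ValueError):
    """Raised for malformed genotype input."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """A complete biallelic genotype matrix, Individuals x SNPs.

    ``coding`` records the polarity convention of the 0/1 codes:
    ``rare1`` (minor allele coded 1), ``common1``, ``mixed``,
    ``vcf:<individual_id>`` (the named reference individual reads 0
    everywhere) or ``unknown``.
    """

    values: np.ndarray
    individual_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    coding: str = "unknown"
    ploidy_mode: str = "binary"  # "binary" (0/1) or "diploid" (0/1/2)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise GenotypeError("genotype matrix must be two-dimensional")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(np.equal(np.mod(v, 1), 0)):
                raise GenotypeError("genotype matrix entries must be integers")
            v = v.astype(np.int64)
        object.__setattr__(self, "values", v.astype(np.int64))
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        r, c = v.shape
        if r < 2 or c < 2:
            raise GenotypeError(f"need at least 2 Individuals and 2 SNPs, got {r}x{c}")
        if len(self.individual_ids) != r:
            raise GenotypeError("individual_ids length does not match row count")
        if len(self.snp_ids) != c:
            raise GenotypeError("snp_ids length does not match column count")
        for axis_name, ids in (("individual", self.individual_ids), ("snp", self.snp_ids)):
            if len(set(ids)) != len(ids):
                raise GenotypeError(f"duplicate {axis_name} identifiers")
        allowed = {0, 1} if self.ploidy_mode == "binary" else {0, 1, 2}
        if self.ploidy_mode not in ("binary", "diploid"):
            raise GenotypeError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        observed = set(np.unique(self.values).tolist())
        if not observed <= allowed:
            raise GenotypeError(
                f"entries {sorted(observed - allowed)} outside the "
                f"{self.ploidy_mode} value set {sorted(allowed)}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, coding: str | None = None) -> "GenotypeMatrix":
        return replace(self, values=values, coding=self.coding if coding is None else coding)

    def transposed(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            values=self.values.T,
            individual_ids=self.snp_ids,
            snp_ids=self.individual_ids,
            coding=self.coding,
            ploidy_mode=self.ploidy_mode,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.individual_ids), columns=list(self.snp_ids))


@dataclass(frozen=True)
class GroupAssignment:
    """Group labels for one axis of a genotype matrix."""

    item_ids: tuple[str, ...]
    labels: tuple[str, ...]
    axis: str  # "individuals" or "snps"

    def __post_init__(self):
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.item_ids) != len(self.labels):
            raise GenotypeError("item_ids and labels must be parallel")
        if self.axis not in ("individuals", "snps"):
            raise GenotypeError(f"axis must be 'individuals' or 'snps', got {self.axis!r}")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise GenotypeError("duplicate item_ids in group assignment")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.item_ids, self.labels))

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def check_against(self, matrix: GenotypeMatrix) -> None:
        ids = matrix.individual_ids if self.axis == "individuals" else matrix.snp_ids
        missing = set(self.item_ids) - set(ids)
        if missing:
            raise GenotypeError(f"group items not present in matrix {self.axis}: {sorted(missing)[:5]}")
        unlabeled = set(ids) - set(self.item_ids)
        if unlabeled:
            raise GenotypeError(f"unlabeled {self.axis}: {sorted(unlabeled)[:5]}")


@dataclass
class ValidationReport:
    n_individuals: int
    n_snps: int
    monomorphic_snps: list[str]
    duplicate_individual_ids: list[str] = field(default_factory=list)
    duplicate_snp_ids: list[str] = field(default_factory=list)
    value_set_violations: int = 0
    n_missing: int = 0

    @property
    def n_violations(self) -> int:
        return (
            self.value_set_violations
            + self.n_missing
            + len(self.duplicate_individual_ids)
            + len(self.duplicate_snp_ids)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_individuals": self.n_individuals,
                "n_snps": self.n_snps,
                "monomorphic_snps": self.monomorphic_snps,
                "duplicate_individual_ids": self.duplicate_individual_ids,
                "duplicate_snp_ids": self.duplicate_snp_ids,
                "value_set_violations": self.value_set_violations,
                "n_missing": self.n_missing,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# reading / writing


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _split(line: str, delim: str | None) -> list[str]:
    return line.split() if delim is None else line.rstrip("\r\n").split(delim)


def sniff_dialect(path: str | Path) -> str:
    """Guess the delimiter of a genotype text file from its first line."""
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "tsv"
    if "," in first:
        return "csv"
    return "whitespace"


def read_genotype_matrix(
    path: str | Path,
    dialect: str = "auto",
    orientation: str = "individuals_in_rows",
    coding: str = "unknown",
    ploidy_mode: str = "binary",
    impute_missing: bool = False,
) -> GenotypeMatrix:
    """Read a delimited genotype table.

    A non-numeric first row is treated as column identifiers, and a
    non-numeric first column as row identifiers; otherwise identifiers are
    generated (ind0001.../snp0001...).  ``orientation='snps_in_rows'``
    transposes on entry so the returned matrix is always Individuals x SNPs.
    Missing-value tokens are a hard error unless ``impute_missing`` is set,
    in which case each missing cell gets its SNP's rounded mean.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = sniff_dialect(path)
    if dialect not in _DELIMS:
        raise GenotypeError(f"unknown dialect {dialect!r}")
    delim = _DELIMS[dialect]

    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() != ""]
    if not lines:
        raise GenotypeError(f"{path}: empty file")
    rows = [_split(ln, delim) for ln in lines]

    widths = {len(r) for r in rows[1:]} if len(rows) > 1 else {len(rows[0])}
    if len(widths) != 1:
        raise GenotypeError(f"{path}: non-rectangular table (row widths {sorted(widths)})")

    # header detection: first data cell of first row non-numeric => header row
    has_header = not _is_number(rows[0][-1])
    body = rows[1:] if has_header else rows
    has_row_ids = len(body) > 0 and not _is_number(body[0][0])
    # a header row may or may not carry a leading corner cell
    ncol = len(body[0]) - (1 if has_row_ids else 0)

    if has_header:
        header = rows[0]
        if len(header) == ncol + 1 and has_row_ids:
            col_ids = header[1:]
        elif len(header) == ncol:
            col_ids = header
        else:
            raise GenotypeError(f"{path}: header width {len(header)} does not match table width")
        col_ids = [str(x) for x in col_ids]
    else:
        col_ids = None

    row_ids: list[str] | None = [] if has_row_ids else None
    cells: list[list[str]] = []
    for r in body:
        if has_row_ids:
            row_ids.append(r[0])  # type: ignore[union-attr]
            cells.append(r[1:])
        else:
            cells.append(r)

    nrow = len(cells)
    values = np.empty((nrow, ncol), dtype=float)
    missing_mask = np.zeros((nrow, ncol), dtype=bool)
    for i, row in enumerate(cells):
        if len(row) != ncol:
            raise GenotypeError(
                f"{path}: non-rectangular table (row {i + 1} has {len(row)} cells, expected {ncol})"
            )
        for j, tok in enumerate(row):
            t = tok.strip()
            if t.upper() in _MISSING_TOKENS:
                if not impute_missing:
                    rid = row_ids[i] if row_ids else f"row {i + 1}"
                    cid = col_ids[j] if col_ids else f"column {j + 1}"
                    raise GenotypeError(f"{path}: missing value at ({rid}, {cid})")
                missing_mask[i, j] = True
                values[i, j] = np.nan
                continue
            try:
                x = float(t)
            except ValueError:
                rid = row_ids[i] if row_ids else f"row {i + 1}"
                cid = col_ids[j] if col_ids else f"column {j + 1}"
                raise GenotypeError(f"{path}: non-numeric cell {t!r} at ({rid}, {cid})") from None
            if x != int(x):
                rid = row_ids[i] if row_ids else f"row {i + 1}"
                cid = col_ids[j] if col_ids else f"column {j + 1}"
                raise GenotypeError(f"{path}: non-integer cell {t!r} at ({rid}, {cid})")
            values[i, j] = x

    if impute_missing and missing_mask.any():
        # SNP-mean imputation on the file's column axis (per-SNP only after
        # orientation is resolved below for snps_in_rows files the columns
        # are individuals, so impute after transposition instead)
        pass

    if orientation == "snps_in_rows":
        values = values.T
        missing_mask = missing_mask.T
        row_ids, col_ids = col_ids, row_ids
    elif orientation != "individuals_in_rows":
        raise GenotypeError(f"unknown orientation {orientation!r}")

    if impute_missing and missing_mask.any():
        for j in range(values.shape[1]):
            col = values[:, j]
            m = np.isnan(col)
            if m.all():
                raise GenotypeError(f"{path}: SNP column {j + 1} entirely missing")
            col[m] = round(float(np.nanmean(col)))

    r, c = values.shape
    individual_ids = tuple(row_ids) if row_ids else tuple(f"ind{i + 1:04d}" for i in range(r))
    snp_ids = tuple(col_ids) if col_ids else tuple(f"snp{j + 1:04d}" for j in range(c))
    return GenotypeMatrix(values.astype(np.int64), individual_ids, snp_ids, coding=coding, ploidy_mode=ploidy_mode)


def write_genotype_matrix(matrix: GenotypeMatrix, path: str | Path, dialect: str = "tsv") -> None:
    if dialect not in _DELIMS:
        raise GenotypeError(f"unknown dialect {dialect!r}")
    delim = _DELIMS[dialect] or " "
    with open(path, "w") as fh:
        fh.write("id" + delim + delim.join(matrix.snp_ids) + "\n")
        for rid, row in zip(matrix.individual_ids, matrix.values):
            fh.write(rid + delim + delim.join(str(int(x)) for x in row) + "\n")


def read_group_assignment(path: str | Path, axis: str) -> GroupAssignment:
    """Read a two-column TSV (item id, group label)."""
    ids: list[str] = []
    labels: list[str] = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            parts = ln.rstrip("\r\n").split("\t")
            if len(parts) != 2:
                raise GenotypeError(f"{path}: expected two tab-separated columns, got {ln!r}")
            ids.append(parts[0])
            labels.append(parts[1])
    return GroupAssignment(tuple(ids), tuple(labels), axis=axis)


def write_group_assignment(groups: GroupAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, lab in zip(groups.item_ids, groups.labels):
            fh.write(f"{i}\t{lab}\n")


# ---------------------------------------------------------------------------
# code shifting and validation


def shift_codes(matrix: GenotypeMatrix, mapping: dict[int, int]) -> GenotypeMatrix:
    """Relabel genotype codes via a bijective mapping (e.g. {1: 0, 2: 1})."""
    observed = set(np.unique(matrix.values).tolist())
    missing = observed - set(mapping)
    if missing:
        raise GenotypeError(f"mapping does not cover observed codes {sorted(missing)}")
    if len(set(mapping.values())) != len(mapping):
        raise GenotypeError("mapping is not a bijection")
    out = matrix.values.copy()
    for src, dst in mapping.items():
        out[matrix.values == src] = dst
    return matrix.with_values(out)


def validate(matrix: "GenotypeMatrix | pd.DataFrame", ploidy_mode: str = "binary") -> ValidationReport:
    """Report monomorphic SNPs, duplicate identifiers, missing cells and
    value-set violations (reporting only — never raises).

    Accepts a :class:`GenotypeMatrix` (whose constructor already enforces
    the hard invariants) or a raw Individuals-x-SNPs DataFrame, for which
    the softer problems a constructor would reject are merely reported.
    """
    if isinstance(matrix, GenotypeMatrix):
        frame = matrix.to_frame()
        ploidy_mode = matrix.ploidy_mode
    else:
        frame = matrix
    top = 2 if ploidy_mode == "diploid" else 1
    allowed = set(range(top + 1))
    vals = frame.to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    finite = vals[~np.isnan(vals)]
    violations = int(np.sum(~np.isin(finite, list(allowed))))
    col_means = np.nanmean(vals, axis=0)
    mono = [str(sid) for sid, m in zip(frame.columns, col_means) if m == 0.0 or m == float(top)]
    return ValidationReport(
        n_individuals=frame.shape[0],
        n_snps=frame.shape[1],
        monomorphic_snps=mono,
        duplicate_individual_ids=_dups([str(x) for x in frame.index]),
        duplicate_snp_ids=_dups([str(x) for x in frame.columns]),
        value_set_violations=violations,
        n_missing=n_missing,
    )


def _dups(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in ids:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out
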