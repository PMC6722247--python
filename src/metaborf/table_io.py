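"""Abundance-table container, file I/O, minimum-observed imputation and log transform.

The single currency of the pipeline is the :class:`MetaboliteTable`: a
subjects x metabolites matrix of raw area counts (non-negative, arbitrary
units, NaN = missing / not detected) together with a binary group label per
subject and per-metabolite annotations (mass, retention index, platform).

The canonical file layout mirrors metabolomics vendor exports: metabolites
as rows, subjects as columns, a two-row header (subject identifiers, then
group labels), and leading annotation columns
``metabolite_id, mass, retention_index, platform``. Empty cells are missing
values. TSV is the default; CSV is accepted by extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["mass", "retention_index", "platform"]
_GROUP_ROW_SENTINEL = "group"


class TableFormatError(ValueError):
    """Malformed abundance-table file; message carries row/column coordinates."""


@dataclass
class MetaboliteTable:
    """Subjects x metabolites abundance matrix with labels and annotations.

    Attributes
    ----------
    abundances
        DataFrame indexed by subject id, columns = metabolite ids; values
        are raw area counts (>= 0) or NaN for missing.
    group_labels
        Series indexed by subject id with exactly two distinct labels
        (e.g. ``resistant`` / ``control``).
    annotations
        DataFrame indexed by metabolite id with columns
        ``mass`` (Da), ``retention_index``, ``platform``.
    """

    abundances: pd.DataFrame
    group_labels: pd.Series
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- shape accessors -------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def n_subjects(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.abundances.shape[1]

    @property
    def groups(self) -> list:
        """The distinct group labels in order of first appearance."""
        return list(dict.fromkeys(self.group_labels))

    def validate(self) -> None:
        ab = self.abundances
        if ab.index.duplicated().any():
            dup = ab.index[ab.index.duplicated()][0]
            raise TableFormatError(f"duplicate subject identifier: {dup!r}")
        if ab.columns.duplicated().any():
            dup = ab.columns[ab.columns.duplicated()][0]
            raise TableFormatError(f"duplicate metabolite identifier: {dup!r}")
        if not ab.index.equals(self.group_labels.index):
            raise TableFormatError("group_labels index does not match subject ids")
        if not ab.columns.equals(self.annotations.index):
            raise TableFormatError("annotations index does not match metabolite ids")
        vals = ab.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            si, mi = np.argwhere(vals < 0)[0]
            raise TableFormatError(
                f"negative abundance at subject {ab.index[si]!r}, metabolite {ab.columns[mi]!r}"
            )
        all_missing = np.all(np.isnan(vals), axis=0)
        if all_missing.any():
            mid = ab.columns[int(np.argmax(all_missing))]
            raise TableFormatError(f"metabolite {mid!r} has zero observed values")

    def require_two_groups(self) -> tuple:
        groups = self.groups
        if len(groups) != 2:
            raise TableFormatError(
                f"classification requires exactly two group labels, found {groups!r}"
            )
        return tuple(groups)

    def restrict_metabolites(self, metabolite_ids: list[str]) -> "MetaboliteTable":
        """Sub-table with the given metabolites, preserving their order as passed."""
        return MetaboliteTable(
            abundances=self.abundances.loc[:, metabolite_ids].copy(),
            group_labels=self.group_labels.copy(),
            annotations=self.annotations.loc[metabolite_ids].copy(),
        )

    def matrix(self) -> np.ndarray:
        return self.abundances.to_numpy(dtype=float)


@dataclass
class ImputedTable(MetaboliteTable):
    """A MetaboliteTable with no missing cells.

    ``provenance_mask`` marks exactly the cells that were filled by
    imputation; ``log_transformed`` records whether abundances are on the
    natural-log scale.
    """

    provenance_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.provenance_mask is None:
            self.provenance_mask = pd.DataFrame(
                False, index=self.abundances.index, columns=self.abundances.columns
            )
        if self.abundances.isna().any().any():
            raise TableFormatError("ImputedTable must not contain missing values")

    def restrict_metabolites(self, metabolite_ids: list[str]) -> "ImputedTable":
        return ImputedTable(
            abundances=self.abundances.loc[:, metabolite_ids].copy(),
            group_labels=self.group_labels.copy(),
            annotations=self.annotations.loc[metabolite_ids].copy(),
            provenance_mask=self.provenance_mask.loc[:, metabolite_ids].copy(),
            log_transformed=self.log_transformed,
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_table(table: MetaboliteTable, path: str | Path, orient: str = "metabolites") -> None:
    """Write a table in the canonical delimited layout.

    ``orient="metabolites"`` (default) puts metabolites on rows;
    ``orient="subjects"`` flips the matrix (subjects as rows, one header
    row of metabolite ids and a trailing ``group`` column).
    """
    path = Path(path)
    sep = _sep_for(path)
    if orient not in ("metabolites", "subjects"):
        raise ValueError(f"unknown orient {orient!r}")
    with open(path, "w", encoding="utf-8") as fh:
        if orient == "metabolites":
            header = ["metabolite_id", *ANNOTATION_COLUMNS, *map(str, table.subject_ids)]
            fh.write(sep.join(header) + "\n")
            group_row = [_GROUP_ROW_SENTINEL, "", "", "",
                         *[str(table.group_labels[s]) for s in table.subject_ids]]
            fh.write(sep.join(group_row) + "\n")
            for mid in table.metabolite_ids:
                ann = table.annotations.loc[mid]
                col = table.abundances[mid]
                cells = [str(mid), _fmt(ann["mass"]), _fmt(ann["retention_index"]),
                         str(ann["platform"]),
                         *[_fmt(col[s]) for s in table.subject_ids]]
                fh.write(sep.join(cells) + "\n")
        else:
            header = ["subject_id", "group", *map(str, table.metabolite_ids)]
            fh.write(sep.join(header) + "\n")
            for sid in table.subject_ids:
                row = table.abundances.loc[sid]
                cells = [str(sid), str(table.group_labels[sid]),
                         *[_fmt(row[m]) for m in table.metabolite_ids]]
                fh.write(sep.join(cells) + "\n")


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    if isinstance(v, float):
        return np.format_float_positional(v, trim="0")
    return str(v)


def read_table(path: str | Path, orient: str = "metabolites") -> MetaboliteTable:
    """Read an abundance table from the canonical layout.

    Empty cells are parsed as missing. Malformed headers, duplicate
    identifiers, negative abundances and non-numeric cells raise
    :class:`TableFormatError` with row/column coordinates.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip("\r\n")]
    if orient == "subjects":
        return _read_subject_rows(lines, sep)
    if orient != "metabolites":
        raise ValueError(f"unknown orient {orient!r}")

    if len(lines) < 3:
        raise TableFormatError("file must have two header rows and at least one metabolite row")
    header = lines[0].split(sep)
    if header[:4] != ["metabolite_id", *ANNOTATION_COLUMNS]:
        raise TableFormatError(
            f"row 1: expected leading columns metabolite_id, {', '.join(ANNOTATION_COLUMNS)}; "
            f"got {header[:4]!r}"
        )
    subject_ids = header[4:]
    if not subject_ids:
        raise TableFormatError("row 1: no subject columns found")
    group_row = lines[1].split(sep)
    if group_row[0] != _GROUP_ROW_SENTINEL:
        raise TableFormatError(f"row 2: expected first cell {_GROUP_ROW_SENTINEL!r}, got {group_row[0]!r}")
    labels = group_row[4:]
    if len(labels) != len(subject_ids):
        raise TableFormatError(
            f"row 2: {len(labels)} group labels for {len(subject_ids)} subjects"
        )

    metabolite_ids, ann_rows, data_rows = [], [], []
    for r, line in enumerate(lines[2:], start=3):
        cells = line.split(sep)
        if len(cells) != 4 + len(subject_ids):
            raise TableFormatError(
                f"row {r}: expected {4 + len(subject_ids)} cells, got {len(cells)}"
            )
        mid = cells[0]
        metabolite_ids.append(mid)
        ann_rows.append({
            "mass": _parse_number(cells[1], r, "mass", allow_missing=True),
            "retention_index": _parse_number(cells[2], r, "retention_index", allow_missing=True),
            "platform": cells[3],
        })
        vals = []
        for c, cell in enumerate(cells[4:]):
            v = _parse_number(cell, r, f"subject column {subject_ids[c]!r}", allow_missing=True)
            vals.append(v)
        data_rows.append(vals)

    abundances = pd.DataFrame(
        np.asarray(data_rows, dtype=float).T, index=pd.Index(subject_ids, name="subject_id"),
        columns=pd.Index(metabolite_ids, name="metabolite_id"),
    )
    annotations = pd.DataFrame(ann_rows, index=abundances.columns)
    group_labels = pd.Series(labels, index=abundances.index, name="group")
    return MetaboliteTable(abundances, group_labels, annotations)


def _read_subject_rows(lines: list[str], sep: str) -> MetaboliteTable:
    header = lines[0].split(sep)
    if header[:2] != ["subject_id", "group"]:
        raise TableFormatError("row 1: expected leading columns subject_id, group")
    metabolite_ids = header[2:]
    sids, labels, rows = [], [], []
    for r, line in enumerate(lines[1:], start=2):
        cells = line.split(sep)
        if len(cells) != 2 + len(metabolite_ids):
            raise TableFormatError(f"row {r}: expected {2 + len(metabolite_ids)} cells")
        sids.append(cells[0])
        labels.append(cells[1])
        rows.append([
            _parse_number(c, r, f"metabolite column {metabolite_ids[i]!r}", allow_missing=True)
            for i, c in enumerate(cells[2:])
        ])
    abundances = pd.DataFrame(
        np.asarray(rows, dtype=float), index=pd.Index(sids, name="subject_id"),
        columns=pd.Index(metabolite_ids, name="metabolite_id"),
    )
    annotations = pd.DataFrame(
        {"mass": np.nan, "retention_index": np.nan, "platform": ""}, index=abundances.columns
    )
    return MetaboliteTable(abundances, pd.Series(labels, index=abundances.index, name="group"),
                           annotations)


def _parse_number(cell: str, row: int, col: str, allow_missing: bool) -> float:
    cell = cell.strip()
    if cell == "" or cell.upper() in ("NA", "NAN"):
        if allow_missing:
            return np.nan
        raise TableFormatError(f"row {row}, {col}: missing value not allowed here")
    try:
        return float(cell)
    except ValueError:
        raise TableFormatError(f"row {row}, {col}: non-numeric cell {cell!r}") from None


# ---------------------------------------------------------------------------
# imputation and transformation
# ---------------------------------------------------------------------------

def impute_minimum(table: MetaboliteTable) -> ImputedTable:
    """Replace each missing cell with its metabolite's minimum observed value.

    This is the detection-limit convention for untargeted metabolomics:
    values absent because they fell below the platform's sensitivity are
    stood in for by the lowest level at which the metabolite was seen.
    The returned ``provenance_mask`` marks exactly the imputed cells;
    observed values are never altered. Idempotent.
    """
    ab = table.abundances
    mask = ab.isna()
    filled = ab.fillna(ab.min(axis=0, skipna=True))
    return ImputedTable(
        abundances=filled,
        group_labels=table.group_labels.copy(),
        annotations=table.annotations.copy(),
        provenance_mask=mask,
        log_transformed=getattr(table, "log_transformed", False),
    )


def log_transform(table: ImputedTable, offset: float = 0.0) -> ImputedTable:
    """Elementwise natural log of the (imputed) abundances.

    Raw area counts span orders of magnitude; the log scale controls for
    outliers and scale differences before distance computations. Zeros are
    refused rather than silently shifted: pass an explicit ``offset`` to
    assert positivity.
    """
    if table.log_transformed:
        raise ValueError("table is already log-transformed")
    vals = table.abundances + offset
    if (vals.to_numpy() <= 0).any():
        bad = vals.columns[(vals <= 0).any(axis=0)][0]
        raise ValueError(
            f"metabolite {bad!r} has a non-positive abundance; supply an explicit "
            "positivity offset to log_transform rather than relying on silent handling"
        )
    return ImputedTable(
        abundances=np.log(vals),
        group_labels=table.group_labels.copy(),
        annotations=table.annotations.copy(),
        provenance_mask=table.provenance_mask.copy(),
        log_transformed=True,
    )
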