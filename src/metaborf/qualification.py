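"""Pre-processing filter defining the qualified metabolite profile.

A metabolite qualifies for classification when it is observed (non-missing
before imputation) in at least ``presence_min`` of the subjects of *each*
group and its relative standard deviation (RSD, sample SD over mean,
computed on imputed raw abundances pooled across all subjects) is at least
``rsd_min``. The presence rule removes metabolites too sparse to inform a
classifier; the RSD rule removes near-constant ones. Defaults are the
conventional 80% presence and 15% RSD.

Both thresholds are inclusive (>=). The RSD scope (pooled vs per-group)
and evaluation stage (pre vs post imputation) are configurable because the
convention varies between labs; pooled post-imputation is the default since
the classifier consumes the imputed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .table_io import ImputedTable, MetaboliteTable, impute_minimum


@dataclass
class QualificationReport:
    """Per-metabolite presence fractions and RSD with pass/fail verdicts."""

    records: pd.DataFrame  # index metabolite_id; presence per group, rsd, qualified
    presence_min: float
    rsd_min: float

    @property
    def n_qualified(self) -> int:
        return int(self.records["qualified"].sum())

    @property
    def qualified_ids(self) -> list[str]:
        return list(self.records.index[self.records["qualified"]])

    def to_tsv(self, path: str | Path) -> None:
        out = self.records.copy()
        out["qualified"] = out["qualified"].astype(int)
        out.to_csv(path, sep="\t")


def presence_fractions(table: MetaboliteTable) -> pd.DataFrame:
    """Fraction of non-missing values per metabolite within each group.

    Evaluated on the pre-imputation missingness pattern; columns are named
    ``presence_<group>`` for the table's two groups.
    """
    g1, g2 = table.require_two_groups()
    out = {}
    for g in (g1, g2):
        members = table.group_labels == g
        if members.sum() == 0:
            raise ValueError(f"group {g!r} has zero subjects")
        out[f"presence_{g}"] = table.abundances.loc[members.to_numpy()].notna().mean(axis=0)
    return pd.DataFrame(out)


def relative_standard_deviation(values) -> float:
    """Sample SD (n-1 denominator) divided by the mean. Unitless."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("RSD requires at least 2 values")
    if np.isnan(v).any():
        raise ValueError("RSD is computed on imputed values; missing values present")
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"RSD undefined for non-positive mean ({mean})")
    return float(v.std(ddof=1) / mean)


def qualify(
    table: MetaboliteTable,
    presence_min: float = 0.80,
    rsd_min: float = 0.15,
    rsd_scope: str = "pooled",
    rsd_on: str = "imputed",
) -> tuple[QualificationReport, MetaboliteTable]:
    """Apply the presence/RSD filter; return the report and the qualified sub-table.

    ``rsd_scope``: "pooled" (RSD across all subjects) or "per_group" (both
    groups must individually clear ``rsd_min``). ``rsd_on``: "imputed"
    (default) or "observed" (RSD over non-missing values only).
    Metabolite order of the qualified table preserves the input order.
    """
    if rsd_scope not in ("pooled", "per_group"):
        raise ValueError(f"unknown rsd_scope {rsd_scope!r}")
    if rsd_on not in ("imputed", "observed"):
        raise ValueError(f"unknown rsd_on {rsd_on!r}")

    pres = presence_fractions(table)
    if rsd_on == "imputed" and not isinstance(table, ImputedTable):
        basis = impute_minimum(table).abundances
    else:
        basis = table.abundances

    g1, g2 = table.require_two_groups()
    rsd = pd.Series(index=table.abundances.columns, dtype=float)
    for mid in table.metabolite_ids:
        col = basis[mid]
        if rsd_scope == "pooled":
            rsd[mid] = _rsd_allow_missing(col, rsd_on)
        else:
            rsd[mid] = min(
                _rsd_allow_missing(col[(table.group_labels == g).to_numpy()], rsd_on)
                for g in (g1, g2)
            )

    qualified = (
        (pres.iloc[:, 0] >= presence_min)
        & (pres.iloc[:, 1] >= presence_min)
        & (rsd >= rsd_min)
    )
    records = pres.copy()
    records["rsd"] = rsd
    records["qualified"] = qualified
    report = QualificationReport(records=records, presence_min=presence_min, rsd_min=rsd_min)
    kept = table.restrict_metabolites(report.qualified_ids)
    return report, kept


def _rsd_allow_missing(col: pd.Series, rsd_on: str) -> float:
    v = col.to_numpy(dtype=float)
    if rsd_on == "observed":
        v = v[~np.isnan(v)]
    if v.size < 2:
        return np.nan
    return relative_standard_deviation(v)
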