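"""Synthetic case/control metabolomics tables with known ground truth.

The generator emulates the data regime of a small untargeted serum
metabolomics study: ~759 metabolites measured on 15 cases and 15 controls,
strictly positive right-skewed raw area counts (log-normal), left-censored
missingness (low values fall below the detection limit), a handful of
group-discriminative metabolites with modest fold changes, and correlated
metabolite blocks standing in for shared-pathway structure.

Every downstream stage (qualification, forest refinement, tuning, PCA,
clustering) has a parameter-recovery test built on these tables, because
the planted structure — which metabolites discriminate, which belong to a
block — is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import substream_rng
from .table_io import MetaboliteTable, write_table

CASE_LABEL = "resistant"
CONTROL_LABEL = "control"

# substream family tags (see _seeds): blocks, loose metabolites
_STREAM_BLOCK = 1
_STREAM_LOOSE = 2


class ConfigurationError(ValueError):
    """Invalid SyntheticConfig; message names the offending field."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults reproduce the target regime: a 15 + 15 cohort measured on 759
    metabolites, ~30 discriminative metabolites with a 2-fold (1 log2 unit)
    shift, ten 15-member correlated pathway blocks, log-normal area counts
    around e^13 ≈ 4.4e5 with unit log-SD, and 10% left-censoring.
    """

    n_case: int = 15
    n_control: int = 15
    n_metabolites: int = 759
    n_informative: int = 30
    log2_fold_change: float = 1.0
    n_blocks: int = 10
    block_size: int = 15
    block_rho: float = 0.6
    base_log_mean: float = 13.0
    base_log_sd: float = 1.0
    missing_quantile: float = 0.10
    seed: int = 0
    informative_in_blocks: bool = False
    effect_direction: str = "split"  # "split": alternate up/down; "up": all elevated

    def __post_init__(self) -> None:
        if self.effect_direction not in ("split", "up"):
            raise ConfigurationError(
                f"effect_direction must be 'split' or 'up', got {self.effect_direction!r}"
            )

    def validate(self) -> None:
        for name in ("n_case", "n_control", "n_metabolites"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_informative", "n_blocks", "block_size"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_informative > self.n_metabolites:
            raise ConfigurationError(
                f"n_informative ({self.n_informative}) exceeds n_metabolites ({self.n_metabolites})"
            )
        if self.n_blocks * self.block_size > self.n_metabolites:
            raise ConfigurationError(
                f"n_blocks x block_size ({self.n_blocks * self.block_size}) exceeds "
                f"n_metabolites ({self.n_metabolites})"
            )
        if not (0.0 <= self.block_rho < 1.0):
            raise ConfigurationError(f"block_rho must be in [0, 1), got {self.block_rho}")
        if not (0.0 <= self.missing_quantile < 1.0):
            raise ConfigurationError(
                f"missing_quantile must be in [0, 1), got {self.missing_quantile}"
            )
        if self.base_log_sd <= 0:
            raise ConfigurationError(f"base_log_sd must be > 0, got {self.base_log_sd}")
        if (not self.informative_in_blocks
                and self.n_blocks * self.block_size + self.n_informative > self.n_metabolites):
            raise ConfigurationError(
                "n_informative does not fit outside the correlated blocks; set "
                "informative_in_blocks=True or reduce counts"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic table."""

    informative_ids: frozenset[str]
    block_assignments: dict[str, int | None] = field(hash=False)

    @property
    def block_labels(self) -> dict[str, int]:
        return {m: b for m, b in self.block_assignments.items() if b is not None}


def generate_table(config: SyntheticConfig) -> tuple[MetaboliteTable, GroundTruth]:
    """Draw one synthetic cohort.

    Log abundances follow a multivariate normal with block-diagonal
    correlation (``block_rho`` within blocks, zero elsewhere); informative
    metabolites get a mean shift of ``log2_fold_change * ln(2)`` in cases;
    abundances are exponentiated; per metabolite, observed values strictly
    below the ``missing_quantile`` empirical quantile are censored to
    missing. Each block and each loose metabolite draws from its own seed
    substream, so the output is invariant to generation order and fully
    determined by ``config``.
    """
    config.validate()
    n = config.n_case + config.n_control
    p = config.n_metabolites
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_case] = True

    # column layout: blocks first, informative at the tail (kept disjoint
    # from blocks unless informative_in_blocks)
    in_block = config.n_blocks * config.block_size
    block_of = np.full(p, -1, dtype=int)
    for b in range(config.n_blocks):
        block_of[b * config.block_size : (b + 1) * config.block_size] = b
    informative = np.zeros(p, dtype=bool)
    if config.n_informative:
        if config.informative_in_blocks:
            informative[:config.n_informative] = True
        else:
            informative[p - config.n_informative :] = True

    z = np.empty((n, p))
    rho = config.block_rho
    for b in range(config.n_blocks):
        rng = substream_rng(config.seed, _STREAM_BLOCK, b)
        shared = rng.standard_normal(n)[:, None]
        indep = rng.standard_normal((n, config.block_size))
        cols = slice(b * config.block_size, (b + 1) * config.block_size)
        z[:, cols] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
    for j in range(in_block, p):
        rng = substream_rng(config.seed, _STREAM_LOOSE, j)
        z[:, j] = rng.standard_normal(n)

    log_ab = config.base_log_mean + config.base_log_sd * z
    # discriminative metabolites differ by log2FC * ln 2 between the groups,
    # placed symmetrically around the base mean (cases +half, controls -half)
    # so each group carries its own signature, as in real cohorts where the
    # reference level sits between the groups. By default half the effects
    # are elevated and half reduced in cases, mirroring real panels where
    # both directions occur (a one-directional, case-only shift would be
    # invisible to rank-based subject distances).
    shift = config.log2_fold_change * np.log(2.0)
    inf_idx = np.flatnonzero(informative)
    signs = np.ones(inf_idx.size)
    if config.effect_direction == "split":
        signs[1::2] = -1.0
    for rank, j in enumerate(inf_idx):
        log_ab[is_case, j] += signs[rank] * shift / 2.0
        log_ab[~is_case, j] -= signs[rank] * shift / 2.0
    abundances = np.exp(log_ab)

    # left-censoring: per metabolite, drop values below its own empirical
    # quantile — the detection-limit behaviour that motivates
    # minimum-observed imputation downstream
    if config.missing_quantile > 0:
        cutoffs = np.quantile(abundances, config.missing_quantile, axis=0)
        abundances = np.where(abundances < cutoffs[None, :], np.nan, abundances)

    metabolite_ids = [f"M{j + 1:04d}" for j in range(p)]
    subject_ids = [f"{'R' if is_case[i] else 'C'}{i + 1:03d}" for i in range(n)]
    labels = pd.Series(
        np.where(is_case, CASE_LABEL, CONTROL_LABEL),
        index=pd.Index(subject_ids, name="subject_id"), name="group",
    )
    ann_rng = substream_rng(config.seed, 3)
    annotations = pd.DataFrame(
        {
            "mass": np.round(ann_rng.uniform(80.0, 900.0, size=p), 4),
            "retention_index": np.round(ann_rng.uniform(500.0, 4000.0, size=p), 1),
            "platform": ann_rng.choice(
                ["GC/MS", "LC/MS Pos", "LC/MS Neg", "LC/MS Polar"], size=p
            ),
        },
        index=pd.Index(metabolite_ids, name="metabolite_id"),
    )
    table = MetaboliteTable(
        abundances=pd.DataFrame(abundances, index=labels.index, columns=annotations.index),
        group_labels=labels,
        annotations=annotations,
    )
    truth = GroundTruth(
        informative_ids=frozenset(np.asarray(metabolite_ids)[informative]),
        block_assignments={
            m: (int(block_of[j]) if block_of[j] >= 0 else None)
            for j, m in enumerate(metabolite_ids)
        },
    )
    return table, truth


def truth_sidecar_path(table_path: str | Path) -> Path:
    p = Path(table_path)
    return p.with_name(p.stem + ".truth.tsv")


def write_fixture(table: MetaboliteTable, truth: GroundTruth, path: str | Path) -> None:
    """Persist a synthetic table plus its ground-truth sidecar.

    The table round-trips losslessly through ``table_io.read_table``; the
    sidecar is a TSV of (metabolite_id, informative flag, block label).
    """
    write_table(table, path)
    side = truth_sidecar_path(path)
    with open(side, "w", encoding="utf-8") as fh:
        fh.write("metabolite_id\tinformative\tblock\n")
        for mid in table.metabolite_ids:
            block = truth.block_assignments.get(mid)
            fh.write(
                f"{mid}\t{int(mid in truth.informative_ids)}\t"
                f"{'' if block is None else block}\n"
            )


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype={"metabolite_id": str})
    informative = frozenset(df.loc[df["informative"] == 1, "metabolite_id"])
    blocks = {
        row.metabolite_id: (None if pd.isna(row.block) else int(row.block))
        for row in df.itertuples()
    }
    return GroundTruth(informative_ids=informative, block_assignments=blocks)
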