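"""Forest-size hyperparameter tuning.

Two scans over a half-magnitude grid of forest sizes (10^0 … 10^6 by
default):

* **stability scan** (qualified profile): at each size, grow replicate
  forests and extract each one's prospective refined profile (top 5% by
  MDA). Profile instability across replicates is summarised by the mean
  pairwise Hamming distance between membership indicator vectors (= size
  of the symmetric difference of member sets), the number of distinct
  metabolites appearing across the replicate profiles, and a
  rank-consistency statistic (mean pairwise Spearman correlation of MDA
  scores over the union of members — this package's formalization of
  "rank consistency", reported alongside the primary two statistics).

* **CV scan** (refined profile): at each size, replicate stratified
  k-fold cross-validations; per-forest accuracy is the mean over folds,
  and the scan records the mean and SD of those accuracies across
  replicates.

The forest size is then chosen to maximize accuracy while minimizing its
spread: among sizes whose mean accuracy is within a tolerance of the
maximum, take the one with the smallest SD (remaining ties: the smallest
size). Larger forests stabilize both the profile membership and the
accuracy; the scans make the convergence visible and the choice auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._seeds import spawn_seeds
from .forest import ForestSpec, cross_validate
from .profiling import RefinedProfile, run_replicates, select_refined

_STREAM_SIZE = 23
_STREAM_CV = 29


@dataclass(frozen=True)
class ForestSizeGrid:
    """Tree counts round(10^e) for e = min_exponent … max_exponent in half steps."""

    sizes: tuple[int, ...]

    @classmethod
    def default(cls, max_exponent: float = 6.0, step: float = 0.5) -> "ForestSizeGrid":
        if max_exponent < 0:
            raise ValueError("max_exponent must be >= 0")
        exponents = np.arange(0.0, max_exponent + 1e-9, step)
        sizes = tuple(int(np.floor(10.0**e + 0.5)) for e in exponents)
        return cls(sizes=sizes)

    def __post_init__(self) -> None:
        if not self.sizes:
            raise ValueError("empty grid")
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("grid sizes must be strictly increasing")
        if self.sizes[0] < 1:
            raise ValueError("grid sizes must be >= 1")

    def __iter__(self):
        return iter(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)


def forest_size_grid(max_exponent: float = 6.0, step: float = 0.5) -> ForestSizeGrid:
    """The canonical grid: 1, 3, 10, 32, …, 10^max_exponent."""
    return ForestSizeGrid.default(max_exponent=max_exponent, step=step)


def profile_hamming(a: RefinedProfile | set, b: RefinedProfile | set, universe) -> int:
    """Hamming distance between two profiles' membership indicator vectors.

    Equals the cardinality of the symmetric difference of the member sets;
    members must lie inside ``universe``.
    """
    sa = set(a.member_ids) if isinstance(a, RefinedProfile) else set(a)
    sb = set(b.member_ids) if isinstance(b, RefinedProfile) else set(b)
    uni = set(universe)
    stray = (sa | sb) - uni
    if stray:
        raise ValueError(f"profile members outside the universe: {sorted(stray)[:3]!r}")
    return len(sa ^ sb)


@dataclass
class StabilityScan:
    """Per-size replicate-profile stability statistics, profiles retained for audit."""

    records: pd.DataFrame  # index size; mean_pairwise_hamming, n_unique_members, rank_consistency
    profiles: dict[int, list[RefinedProfile]]
    profile_size: int

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t")


@dataclass
class CvScan:
    """Per-size replicate CV accuracies (mean and SD across replicates)."""

    records: pd.DataFrame  # index size; accuracy_mean, accuracy_sd
    replicate_accuracies: dict[int, list[float]]
    fold_accuracies: dict[int, list[list[float]]]

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t")


def stability_scan(
    x_qualified,
    y,
    grid: ForestSizeGrid,
    n_replicates: int = 10,
    top_fraction: float = 0.05,
    base_seed: int = 0,
    class_labels: tuple | None = None,
) -> StabilityScan:
    """Replicate prospective refined profiles per forest size and score their agreement.

    Deterministic given ``base_seed``; each size gets its own derived seed
    family so truncating the grid does not perturb the sizes that remain.
    """
    rows = []
    profiles: dict[int, list[RefinedProfile]] = {}
    psize = None
    for size in grid:
        ens = run_replicates(
            x_qualified, y, n_trees=size, n_replicates=n_replicates,
            base_seed=spawn_seeds(base_seed, 1, stream=_STREAM_SIZE + size)[0],
            class_labels=class_labels,
        )
        profs = [
            select_refined(
                ReplicateView(ens.results[i], ens.feature_ids), top_fraction
            )
            for i in range(n_replicates)
        ]
        profiles[size] = profs
        psize = len(profs[0])
        hams = [
            profile_hamming(profs[i], profs[j], ens.feature_ids)
            for i in range(n_replicates) for j in range(i + 1, n_replicates)
        ]
        members_union: set = set()
        for p in profs:
            members_union |= set(p.member_ids)
        rows.append({
            "size": size,
            "mean_pairwise_hamming": float(np.mean(hams)) if hams else 0.0,
            "n_unique_members": len(members_union),
            "rank_consistency": _rank_consistency(ens, sorted(members_union)),
        })
    records = pd.DataFrame(rows).set_index("size")
    return StabilityScan(records=records, profiles=profiles, profile_size=int(psize))


class ReplicateView:
    """A one-replicate ensemble view, so per-replicate profiles reuse select_refined."""

    def __init__(self, result, feature_ids):
        self.results = [result]
        self.feature_ids = list(feature_ids)
        self.n_replicates = 1
        self.best_index = 0


def _rank_consistency(ens, union_members: list[str]) -> float:
    """Mean pairwise Spearman correlation of replicate MDA scores over the union."""
    if len(union_members) < 2 or ens.n_replicates < 2:
        return float("nan")
    import warnings

    scores = [r.mda.loc[union_members].to_numpy() for r in ens.results]
    cors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant MDA vectors at tiny forest sizes
        for i in range(len(scores)):
            for j in range(i + 1, len(scores)):
                rho = spearmanr(scores[i], scores[j]).statistic
                if np.isnan(rho):
                    rho = 0.0
                cors.append(rho)
    return float(np.mean(cors))


def cv_scan(
    x_refined,
    y,
    grid: ForestSizeGrid,
    n_replicates: int = 10,
    folds: int = 5,
    base_seed: int = 0,
    class_labels: tuple | None = None,
) -> CvScan:
    """Replicate k-fold CV accuracy (mean over folds) per forest size."""
    rows = []
    rep_accs: dict[int, list[float]] = {}
    fold_accs: dict[int, list[list[float]]] = {}
    for size in grid:
        seeds = spawn_seeds(base_seed, n_replicates, stream=_STREAM_CV + size)
        accs, per_fold = [], []
        for s in seeds:
            cv = cross_validate(
                x_refined, y,
                ForestSpec(n_trees=size, seed=s, class_labels=class_labels),
                folds=folds, seed=s,
            )
            accs.append(cv.mean_accuracy)
            per_fold.append(cv.fold_accuracies)
        rep_accs[size] = accs
        fold_accs[size] = per_fold
        rows.append({
            "size": size,
            "accuracy_mean": float(np.mean(accs)),
            "accuracy_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        })
    records = pd.DataFrame(rows).set_index("size")
    return CvScan(records=records, replicate_accuracies=rep_accs, fold_accuracies=fold_accs)


def choose_forest_size(scan: CvScan, tolerance: float | None = None) -> int:
    """Pick the forest size maximizing accuracy and minimizing its spread.

    Among sizes whose mean accuracy is within ``tolerance`` of the best,
    return the one with minimal accuracy SD; remaining ties break to the
    smallest size. The default tolerance is one standard error of the
    best size's replicate accuracies.
    """
    rec = scan.records
    if rec.empty:
        raise ValueError("empty CV scan")
    best_mean = rec["accuracy_mean"].max()
    if tolerance is None:
        best_size = rec["accuracy_mean"].idxmax()
        reps = scan.replicate_accuracies[best_size]
        tolerance = (
            float(np.std(reps, ddof=1) / np.sqrt(len(reps))) if len(reps) > 1 else 0.0
        )
    eligible = rec[rec["accuracy_mean"] >= best_mean - tolerance]
    eligible = eligible.sort_values(["accuracy_sd"], kind="stable")
    min_sd = eligible["accuracy_sd"].iloc[0]
    winners = eligible[eligible["accuracy_sd"] == min_sd]
    return int(winners.index.min())
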