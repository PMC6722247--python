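"""Two-round random-forest feature refinement.

Round one trains a set of replicate forests (same data, distinct seeds) on
the qualified profile; the best replicate by OOB error supplies the MDA
ranking, and the metabolites in the highest 5% of its scores form the
refined profile. Round two refits a smaller forest on the refined profile
alone, yielding the OOB confusion matrix and accuracy reported for the
final classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import spawn_seeds
from .forest import ForestResult, ForestSpec, train_forest

_STREAM_REPLICATES = 11


@dataclass
class ReplicateEnsemble:
    """Replicate forests trained on identical data with distinct seeds."""

    results: list[ForestResult]
    feature_ids: list[str]

    @property
    def n_replicates(self) -> int:
        return len(self.results)

    @property
    def oob_errors(self) -> list[float]:
        return [r.oob_error for r in self.results]

    @property
    def best_index(self) -> int:
        """Index of the lowest-OOB-error replicate; ties go to the lowest index."""
        errs = self.oob_errors
        return int(np.argmin(errs))  # argmin returns the first minimum


@dataclass
class RefinedProfile:
    """The top-MDA metabolite subset selected from the best replicate."""

    member_ids: list[str]  # descending MDA order
    mda_scores: pd.Series  # indexed by member id, same order
    source_replicate: int
    top_fraction: float

    def __len__(self) -> int:
        return len(self.member_ids)

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame({
            "rank": np.arange(1, len(self.member_ids) + 1),
            "metabolite_id": self.member_ids,
            "mda": self.mda_scores.to_numpy(),
        })
        out.to_csv(path, sep="\t", index=False)


def profile_size(n_features: int, top_fraction: float = 0.05) -> int:
    """Number of refined-profile members: ceil(top_fraction * p), so 594 -> 30."""
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    return max(1, math.ceil(top_fraction * n_features))


def run_replicates(
    x,
    y,
    n_trees: int,
    n_replicates: int = 10,
    base_seed: int = 0,
    features_per_split: int | str = "default",
    class_labels: tuple | None = None,
) -> ReplicateEnsemble:
    """Train ``n_replicates`` forests on the same data with derived seeds.

    Replication quantifies the stability of the MDA ranking: unique but
    similarly-performing models should nominate overlapping profiles.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    seeds = spawn_seeds(base_seed, n_replicates, stream=_STREAM_REPLICATES)
    feature_ids = list(x.columns) if isinstance(x, pd.DataFrame) else [
        f"f{j}" for j in range(np.asarray(x).shape[1])
    ]
    results = [
        train_forest(
            x, y,
            ForestSpec(n_trees=n_trees, features_per_split=features_per_split,
                       seed=s, class_labels=class_labels),
        )
        for s in seeds
    ]
    return ReplicateEnsemble(results=results, feature_ids=feature_ids)


def select_refined(ensemble: ReplicateEnsemble, top_fraction: float = 0.05) -> RefinedProfile:
    """Refined profile = top ceil(top_fraction * p) features by MDA of the best replicate.

    The best replicate has minimal OOB error (ties to the lowest replicate
    index); MDA ties at the cut go to the lower original feature index.
    """
    if ensemble.n_replicates == 0:
        raise ValueError("empty ensemble")
    best = ensemble.best_index
    result = ensemble.results[best]
    k = profile_size(len(ensemble.feature_ids), top_fraction)
    members = result.top_features(k)
    return RefinedProfile(
        member_ids=members,
        mda_scores=result.mda.loc[members],
        source_replicate=best,
        top_fraction=top_fraction,
    )


def refit_refined(
    x_refined,
    y,
    n_trees: int = 1000,
    seed: int = 0,
    features_per_split: int | str = "default",
    class_labels: tuple | None = None,
) -> ForestResult:
    """Round-two forest on the refined profile; returns OOB confusion and error."""
    spec = ForestSpec(n_trees=n_trees, features_per_split=features_per_split,
                      seed=seed, class_labels=class_labels)
    return train_forest(x_refined, y, spec)
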