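"""End-to-end orchestration: read → impute → qualify → refine → tune → project → cluster.

``run_pipeline`` executes the whole workflow deterministically from a
:class:`PipelineConfig` whose defaults are the full-scale study settings
(10^6-tree qualified forests, 10^3-tree refined forests, 10 replicates,
5-fold CV, the 10^0–10^6 tuning grid, linkage thresholds 0.73 / 0.60).
Desk-scale runs truncate the grid and shrink the forests through the same
code path; ``validate_config`` estimates when a configuration is too heavy
for interactive use.

Beyond the standard two-round procedure, the pipeline reports an *honest nested-CV
accuracy*: feature selection is repeated inside each training fold before
the fold's accuracy is measured. Selecting features on all subjects and
then estimating OOB accuracy on those same subjects — as the two-round
design does — is optimistic; reporting both numbers side by side
makes the optimism measurable instead of hidden.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seeds import spawn_seeds
from .clustering import (average_linkage, cluster_both_axes, correlation_distance_matrix,
                         cut_at_threshold)
from .forest import ForestSpec, train_forest
from .profiling import profile_size, refit_refined, run_replicates, select_refined
from .projection import pca, separation_ratio
from .qualification import qualify
from .table_io import MetaboliteTable, impute_minimum, log_transform, read_table
from .tuning import choose_forest_size, cv_scan, forest_size_grid, stability_scan

log = logging.getLogger("metaborf")

_S_REPL, _S_REFIT, _S_STAB, _S_CV, _S_NESTED = 1, 2, 3, 4, 5


@dataclass
class PipelineConfig:
    """All knobs of the workflow; defaults are the full-scale study settings."""

    input_path: str | None = None
    output_dir: str | None = None
    presence_min: float = 0.80
    rsd_min: float = 0.15
    top_fraction: float = 0.05
    qualified_trees: int = 1_000_000
    refined_trees: int = 1_000
    replicates: int = 10
    folds: int = 5
    grid_max_exponent: float = 6.0
    grid_step: float = 0.5
    data_matrix_threshold: float = 0.73
    correlation_matrix_threshold: float = 0.60
    correlation_mode: str = "profile"
    pca_k_override: int | None = None
    run_tuning: bool = False
    nested_cv: bool = True
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_config(config: PipelineConfig, table: MetaboliteTable | None = None) -> list[str]:
    """Human-readable configuration issues (empty list = clean)."""
    issues: list[str] = []
    for name, lo, hi in [("presence_min", 0.0, 1.0), ("rsd_min", 0.0, None),
                         ("top_fraction", 0.0, 1.0)]:
        v = getattr(config, name)
        if v < lo or (hi is not None and v > hi):
            issues.append(f"{name}={v} outside [{lo}, {hi}]")
    for name in ("qualified_trees", "refined_trees", "replicates", "folds"):
        if getattr(config, name) < 1:
            issues.append(f"{name} must be >= 1")
    if config.folds < 2:
        issues.append("folds must be >= 2 for cross-validation")
    if table is not None:
        counts = table.group_labels.value_counts()
        if counts.min() < config.folds:
            issues.append(
                f"folds={config.folds} infeasible: smallest group has {counts.min()} subjects"
            )
    if config.run_tuning and config.grid_max_exponent > 4.0:
        total = sum(forest_size_grid(config.grid_max_exponent, config.grid_step))
        issues.append(
            f"tuning grid to 10^{config.grid_max_exponent:g} replays ~"
            f"{config.replicates * total:.1e} trees; truncate with grid_max_exponent "
            "for desk-scale use (the scan trends are already converged by 10^4)"
        )
    return issues


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    n_subjects: int
    n_metabolites: int
    n_qualified: int
    refined_profile_size: int
    refined_members: list[str]
    replicate_oob_errors: list[float]
    best_replicate: int
    qualified_oob_error: float
    refined_oob_error: float
    refined_confusion: list[list[int]]
    refined_cv_accuracy_mean: float | None
    nested_cv_accuracy: float | None
    chosen_forest_size: int | None
    pca_qualified_k: int
    pca_qualified_variance: float
    pca_refined_k: int
    pca_refined_variance: float
    pca_separation_qualified: float
    pca_separation_refined: float
    data_matrix_clusters: int
    data_matrix_multimember: int
    correlation_matrix_clusters: int
    correlation_matrix_multimember: int
    subject_split_matches_groups: bool
    config: dict
    seed: int
    version: str = __version__

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_jsonify)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(
    config: PipelineConfig, table: MetaboliteTable | None = None
) -> RunReport:
    """Execute every stage in order; deterministic given ``config.seed``.

    ``table`` may be passed directly (e.g. a synthetic cohort); otherwise
    ``config.input_path`` is read. When ``config.output_dir`` is set, all
    per-stage exports (TSV reports, Newick dendrograms, the JSON report,
    optional plots) are written there.
    """
    issues = validate_config(config, table)
    hard = [i for i in issues if "must" in i or "outside" in i or "infeasible" in i]
    if hard:
        raise ValueError("invalid configuration: " + "; ".join(hard))

    if table is None:
        if config.input_path is None:
            raise ValueError("either a table or config.input_path is required")
        table = read_table(config.input_path)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    labels = tuple(table.groups)
    log.info("input: %d subjects x %d metabolites, groups %s",
             table.n_subjects, table.n_metabolites, labels)

    # impute + qualify -----------------------------------------------------
    imputed = impute_minimum(table)
    report_q, _ = qualify(table, config.presence_min, config.rsd_min)
    qualified_imp = imputed.restrict_metabolites(report_q.qualified_ids)
    log.info("qualification: %d of %d metabolites qualified",
             report_q.n_qualified, table.n_metabolites)
    if outdir:
        report_q.to_tsv(outdir / "qualification.tsv")

    # round-one replicate forests + refinement ----------------------------
    x_qual = qualified_imp.abundances
    y = table.group_labels
    ens = run_replicates(
        x_qual, y, n_trees=config.qualified_trees, n_replicates=config.replicates,
        base_seed=spawn_seeds(config.seed, 1, stream=_S_REPL)[0], class_labels=labels,
    )
    profile = select_refined(ens, config.top_fraction)
    log.info("refined profile: %d members from replicate %d (OOB error %.4f)",
             len(profile), profile.source_replicate, ens.results[ens.best_index].oob_error)
    if outdir:
        profile.to_tsv(outdir / "refined_profile.tsv")

    # round-two forest on the refined profile ------------------------------
    x_ref = x_qual.loc[:, profile.member_ids]
    refined_forest = refit_refined(
        x_ref, y, n_trees=config.refined_trees,
        seed=spawn_seeds(config.seed, 1, stream=_S_REFIT)[0], class_labels=labels,
    )
    if outdir:
        refined_forest.to_tsv(outdir / "refined_forest_mda.tsv")
        refined_forest.confusion.to_csv(outdir / "refined_confusion.tsv", sep="\t")

    # tuning scans (optional: a long batch run at full scale) --------------
    chosen_size = None
    cv_mean = None
    if config.run_tuning:
        grid = forest_size_grid(config.grid_max_exponent, config.grid_step)
        stab = stability_scan(
            x_qual, y, grid, n_replicates=config.replicates,
            top_fraction=config.top_fraction,
            base_seed=spawn_seeds(config.seed, 1, stream=_S_STAB)[0], class_labels=labels,
        )
        scan = cv_scan(
            x_ref, y, grid, n_replicates=config.replicates, folds=config.folds,
            base_seed=spawn_seeds(config.seed, 1, stream=_S_CV)[0], class_labels=labels,
        )
        chosen_size = choose_forest_size(scan)
        cv_mean = float(scan.records.loc[chosen_size, "accuracy_mean"])
        if outdir:
            stab.to_tsv(outdir / "stability_scan.tsv")
            scan.to_tsv(outdir / "cv_scan.tsv")
        log.info("tuning: chose forest size %d (CV accuracy %.3f)", chosen_size, cv_mean)

    # honest nested-CV diagnostic ------------------------------------------
    nested_acc = None
    if config.nested_cv:
        nested_acc = nested_cv_accuracy(
            x_qual, y, labels,
            selection_trees=min(config.qualified_trees, 10_000),
            refined_trees=config.refined_trees,
            top_fraction=config.top_fraction, folds=config.folds,
            seed=spawn_seeds(config.seed, 1, stream=_S_NESTED)[0],
        )
        log.info("nested-CV accuracy (selection inside folds): %.3f vs refined OOB %.3f",
                 nested_acc, refined_forest.oob_accuracy)

    # PCA of both profiles --------------------------------------------------
    log_qual = log_transform(qualified_imp)
    log_ref = log_qual.restrict_metabolites(profile.member_ids)
    proj_q = pca(log_qual.abundances)
    proj_r = pca(log_ref.abundances, k_override=config.pca_k_override)
    if outdir:
        proj_q.export(outdir / "pca_qualified")
        proj_r.export(outdir / "pca_refined")

    # dual-matrix hierarchical clustering ----------------------------------
    x_items = log_ref.abundances.T  # metabolites x subjects
    met_dend, subj_dend = cluster_both_axes(x_items)
    data_cut = cut_at_threshold(met_dend, config.data_matrix_threshold)
    corr_dend = average_linkage(
        correlation_distance_matrix(x_items, mode=config.correlation_mode)
    )
    corr_cut = cut_at_threshold(corr_dend, config.correlation_matrix_threshold)
    subj_two = cut_at_threshold(
        subj_dend, _two_cluster_threshold(subj_dend)
    )
    split_matches = _partition_matches_groups(subj_two.assignments, y)
    if outdir:
        met_dend.to_newick(outdir / "metabolite_dendrogram.nwk")
        subj_dend.to_newick(outdir / "subject_dendrogram.nwk")
        corr_dend.to_newick(outdir / "correlation_dendrogram.nwk")
        data_cut.to_tsv(outdir / "data_matrix_clusters.tsv")
        corr_cut.to_tsv(outdir / "correlation_matrix_clusters.tsv")
    if config.make_plots and outdir:
        _write_plots(outdir, proj_q, proj_r, y, log_ref, met_dend, subj_dend)

    report = RunReport(
        n_subjects=table.n_subjects,
        n_metabolites=table.n_metabolites,
        n_qualified=report_q.n_qualified,
        refined_profile_size=len(profile),
        refined_members=list(profile.member_ids),
        replicate_oob_errors=[float(e) for e in ens.oob_errors],
        best_replicate=profile.source_replicate,
        qualified_oob_error=float(ens.results[ens.best_index].oob_error),
        refined_oob_error=float(refined_forest.oob_error),
        refined_confusion=refined_forest.confusion.to_numpy().tolist(),
        refined_cv_accuracy_mean=cv_mean,
        nested_cv_accuracy=nested_acc,
        chosen_forest_size=chosen_size,
        pca_qualified_k=proj_q.k_selected,
        pca_qualified_variance=float(proj_q.variance_captured),
        pca_refined_k=proj_r.k_selected,
        pca_refined_variance=float(proj_r.variance_captured),
        pca_separation_qualified=separation_ratio(proj_q.scores_all, y),
        pca_separation_refined=separation_ratio(proj_r.scores_all, y),
        data_matrix_clusters=data_cut.n_clusters,
        data_matrix_multimember=data_cut.n_multimember,
        correlation_matrix_clusters=corr_cut.n_clusters,
        correlation_matrix_multimember=corr_cut.n_multimember,
        subject_split_matches_groups=split_matches,
        config={k: v for k, v in asdict(config).items()},
        seed=config.seed,
    )
    if outdir:
        report.to_json(outdir / "run_report.json")
    return report


def nested_cv_accuracy(
    x_qualified: pd.DataFrame,
    y: pd.Series,
    labels: tuple,
    selection_trees: int,
    refined_trees: int,
    top_fraction: float,
    folds: int,
    seed: int,
) -> float:
    """CV accuracy with MDA feature selection repeated inside each training fold.

    The unbiased counterpart of the two-round design: the held-out
    subjects never influence which metabolites are selected.
    """
    from sklearn.model_selection import StratifiedKFold

    y_arr = y.to_numpy()
    y_enc = np.asarray([list(labels).index(v) for v in y_arr])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) & 0x7FFFFFFF)
    fold_seeds = spawn_seeds(seed, folds, stream=51)
    accs = []
    k = profile_size(x_qualified.shape[1], top_fraction)
    for f, (tr, te) in enumerate(skf.split(x_qualified, y_enc)):
        x_tr = x_qualified.iloc[tr]
        sel = train_forest(
            x_tr, y_arr[tr],
            ForestSpec(n_trees=selection_trees, seed=fold_seeds[f], class_labels=labels),
        )
        members = sel.top_features(k)
        preds = _forest_predict(
            x_tr.loc[:, members], y_arr[tr], x_qualified.iloc[te].loc[:, members],
            refined_trees, fold_seeds[f] + 1, labels,
        )
        accs.append(float(np.mean(preds == y_arr[te])))
    return float(np.mean(accs))


def _forest_predict(x_train, y_train, x_test, n_trees, seed, labels):
    from .forest import _grow_forest, _prepare_xy

    X, y_enc, labs, _ = _prepare_xy(x_train, y_train, labels)
    Xt = np.ascontiguousarray(np.asarray(x_test, dtype=np.float32))
    mtry = ForestSpec(n_trees=n_trees).resolve_mtry(X.shape[1])
    _v, _c, eval_votes, _m, _mq, _n = _grow_forest(
        X, y_enc, n_trees, mtry, int(seed) & 0x7FFFFFFF, Xt, False
    )
    pred = np.where(eval_votes[:, 0] >= eval_votes[:, 1], 0, 1)
    return np.asarray([labs[p] for p in pred])


def _two_cluster_threshold(dend) -> float:
    """A threshold strictly between the last two merge heights (2-cluster cut)."""
    heights = dend.merge_heights
    if len(heights) < 2:
        return float(heights[-1]) / 2.0
    return float((heights[-1] + heights[-2]) / 2.0)


def _partition_matches_groups(assignments: pd.Series, y: pd.Series) -> bool:
    tab = pd.crosstab(assignments, y.loc[assignments.index])
    if tab.shape != (2, 2):
        return False
    return bool(min(np.trace(tab.to_numpy()), np.trace(np.fliplr(tab.to_numpy())))
                == 0)


def _write_plots(outdir: Path, proj_q, proj_r, y, log_ref, met_dend, subj_dend) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), constrained_layout=True)
    for ax, proj, title in [(axes[0], proj_q, "Qualified profile"),
                            (axes[1], proj_r, "Refined profile")]:
        for g, marker in zip(dict.fromkeys(y), "o^"):
            pts = proj.scores_all.loc[(y == g).to_numpy()]
            ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], marker=marker, label=str(g), alpha=0.8)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title(title)
        ax.legend()
    fig.savefig(outdir / "pca_scores.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 6), constrained_layout=True)
    mat = log_ref.abundances.T  # metabolites x subjects
    row_order = met_dend.leaf_order
    col_order = subj_dend.leaf_order
    z = (mat - mat.to_numpy().mean()) / mat.to_numpy().std()
    im = ax.imshow(z.iloc[row_order, :].iloc[:, col_order], aspect="auto", cmap="RdBu_r")
    ax.set_xlabel("subjects")
    ax.set_ylabel("metabolites")
    fig.colorbar(im, ax=ax, label="z(log abundance)")
    fig.savefig(outdir / "heatmap.png", dpi=120)
    plt.close(fig)
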