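"""Random-forest classification engine: OOB error, MDA importance, k-fold CV.

This is the computational core of the pipeline. Each tree is grown on a
bootstrap sample of size n drawn with replacement; at each node a random
subset of ``features_per_split`` candidate features is examined and the
best Gini-impurity split taken; trees grow to purity (minimum node size 1).
A subject's out-of-bag (OOB) prediction is the majority vote of the trees
whose bootstrap sample excluded it, giving an internal error estimate
without a held-out set. Mean decrease accuracy (MDA) for feature f is the
mean over trees of (the tree's OOB accuracy) minus (its OOB accuracy after
permuting f within the tree's OOB set) — permutation importance in raw
accuracy-fraction units.

The tree grower is a numba kernel rather than a wrapper around an
off-the-shelf forest because the tuning stage replays forests of up to
10^4–10^6 trees on 30-subject cohorts, a regime where per-tree Python
overhead dominates; the kernel also gives exact control over the OOB
bookkeeping, per-tree permutation MDA and the documented tie-breaks.
Agreement with an independent reference forest is asserted in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ._seeds import spawn_seeds

NEVER_OOB = "never-oob"


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _predict_node(node_feat, node_thr, node_left, node_right, node_class, x_row):
    node = 0
    while node_feat[node] >= 0:
        if x_row[node_feat[node]] <= node_thr[node]:
            node = node_left[node]
        else:
            node = node_right[node]
    return node_class[node]


@njit(cache=True)
def _grow_forest(X, y, n_trees, mtry, seed, X_eval, compute_mda):
    """Grow a forest, accumulating OOB votes, eval-set votes and MDA sums.

    Returns (votes n x 2, oob_count n, eval_votes m x 2, mda_sum p,
    mda_sq_sum p, n_mda_trees). MDA sums are over trees with >= 1 OOB
    subject; features unused by a tree contribute 0 for that tree.
    """
    n, p = X.shape
    n_eval = X_eval.shape[0]
    votes = np.zeros((n, 2), dtype=np.int64)
    oob_count = np.zeros(n, dtype=np.int64)
    eval_votes = np.zeros((n_eval, 2), dtype=np.int64)
    mda_sum = np.zeros(p, dtype=np.float64)
    mda_sq_sum = np.zeros(p, dtype=np.float64)
    n_mda_trees = 0

    max_nodes = 2 * n + 1
    node_feat = np.empty(max_nodes, dtype=np.int64)
    node_thr = np.empty(max_nodes, dtype=np.float64)
    node_left = np.empty(max_nodes, dtype=np.int64)
    node_right = np.empty(max_nodes, dtype=np.int64)
    node_class = np.empty(max_nodes, dtype=np.int64)

    samples = np.empty(n, dtype=np.int64)
    buf = np.empty(n, dtype=np.int64)
    stack_node = np.empty(max_nodes, dtype=np.int64)
    stack_lo = np.empty(max_nodes, dtype=np.int64)
    stack_hi = np.empty(max_nodes, dtype=np.int64)
    perm = np.empty(p, dtype=np.int64)
    in_bag = np.empty(n, dtype=np.int64)
    oob_idx = np.empty(n, dtype=np.int64)
    used = np.empty(p, dtype=np.uint8)

    np.random.seed(seed)

    for _t in range(n_trees):
        # bootstrap sample of size n, with replacement
        in_bag[:] = 0
        for i in range(n):
            j = np.random.randint(0, n)
            samples[i] = j
            in_bag[j] += 1
        n_oob = 0
        for i in range(n):
            if in_bag[i] == 0:
                oob_idx[n_oob] = i
                n_oob += 1

        # grow the tree (explicit stack; nodes appended breadth-on-demand)
        used[:] = 0
        n_nodes = 1
        sp = 0
        stack_node[0] = 0
        stack_lo[0] = 0
        stack_hi[0] = n
        sp = 1
        while sp > 0:
            sp -= 1
            node = stack_node[sp]
            lo = stack_lo[sp]
            hi = stack_hi[sp]
            m = hi - lo
            c1 = 0
            for k in range(lo, hi):
                c1 += y[samples[k]]
            c0 = m - c1
            if c0 == 0 or c1 == 0 or m < 2:
                node_feat[node] = -1
                node_class[node] = 1 if c1 > c0 else 0  # tie -> first class
                continue

            # choose best Gini split among mtry non-constant candidate
            # features, drawn without replacement in random order; if all
            # candidates are constant keep drawing (same convention as the
            # reference implementations)
            for j in range(p):
                perm[j] = j
            for j in range(p - 1, 0, -1):
                r = np.random.randint(0, j + 1)
                tmp = perm[j]
                perm[j] = perm[r]
                perm[r] = tmp

            best_score = 1e18
            best_feat = -1
            best_thr = 0.0
            n_valid = 0
            for j in range(p):
                f = perm[j]
                # find min/max to skip constant features cheaply
                fmin = X[samples[lo], f]
                fmax = fmin
                for k in range(lo + 1, hi):
                    v = X[samples[k], f]
                    if v < fmin:
                        fmin = v
                    elif v > fmax:
                        fmax = v
                if fmax <= fmin:
                    continue
                n_valid += 1
                # sort node samples by feature value (insertion sort: m is tiny)
                for k in range(m):
                    buf[k] = samples[lo + k]
                for a in range(1, m):
                    key = buf[a]
                    kv = X[key, f]
                    b = a - 1
                    while b >= 0 and X[buf[b], f] > kv:
                        buf[b + 1] = buf[b]
                        b -= 1
                    buf[b + 1] = key
                # scan split points between distinct values
                nl1 = 0
                for k in range(m - 1):
                    nl1 += y[buf[k]]
                    vk = X[buf[k], f]
                    vk1 = X[buf[k + 1], f]
                    if vk1 <= vk:
                        continue
                    nl = k + 1
                    nr = m - nl
                    nl0 = nl - nl1
                    nr1 = c1 - nl1
                    nr0 = c0 - nl0
                    # weighted children Gini x m (lower is better)
                    score = (nl - (nl0 * nl0 + nl1 * nl1) / nl) + (
                        nr - (nr0 * nr0 + nr1 * nr1) / nr
                    )
                    if score < best_score:
                        best_score = score
                        best_feat = f
                        best_thr = 0.5 * (vk + vk1)
                if n_valid >= mtry and best_feat >= 0:
                    break

            if best_feat < 0:
                node_feat[node] = -1
                node_class[node] = 1 if c1 > c0 else 0
                continue

            # stable partition around the threshold
            nl = 0
            for k in range(lo, hi):
                if X[samples[k], best_feat] <= best_thr:
                    buf[nl] = samples[k]
                    nl += 1
            nr = nl
            for k in range(lo, hi):
                if X[samples[k], best_feat] > best_thr:
                    buf[nr] = samples[k]
                    nr += 1
            for k in range(m):
                samples[lo + k] = buf[k]

            node_feat[node] = best_feat
            node_thr[node] = best_thr
            used[best_feat] = 1
            node_left[node] = n_nodes
            node_right[node] = n_nodes + 1
            stack_node[sp] = n_nodes
            stack_lo[sp] = lo
            stack_hi[sp] = lo + nl
            stack_node[sp + 1] = n_nodes + 1
            stack_lo[sp + 1] = lo + nl
            stack_hi[sp + 1] = hi
            sp += 2
            n_nodes += 2

        # OOB votes
        for k in range(n_oob):
            i = oob_idx[k]
            pred = _predict_node(node_feat, node_thr, node_left, node_right, node_class, X[i])
            votes[i, pred] += 1
            oob_count[i] += 1

        # eval-set votes
        for k in range(n_eval):
            pred = _predict_node(
                node_feat, node_thr, node_left, node_right, node_class, X_eval[k]
            )
            eval_votes[k, pred] += 1

        # per-tree permutation MDA over the tree's OOB set
        if compute_mda and n_oob > 0:
            n_mda_trees += 1
            Xo = np.empty((n_oob, p), dtype=X.dtype)
            for k in range(n_oob):
                Xo[k] = X[oob_idx[k]]
            correct = 0
            for k in range(n_oob):
                pred = _predict_node(
                    node_feat, node_thr, node_left, node_right, node_class, Xo[k]
                )
                if pred == y[oob_idx[k]]:
                    correct += 1
            acc0 = correct / n_oob
            col = np.empty(n_oob, dtype=X.dtype)
            for f in range(p):
                if used[f] == 0:
                    continue
                for k in range(n_oob):
                    col[k] = Xo[k, f]
                # Fisher-Yates permutation of the feature within the OOB set
                for k in range(n_oob - 1, 0, -1):
                    r = np.random.randint(0, k + 1)
                    tmp = Xo[k, f]
                    Xo[k, f] = Xo[r, f]
                    Xo[r, f] = tmp
                correct_p = 0
                for k in range(n_oob):
                    pred = _predict_node(
                        node_feat, node_thr, node_left, node_right, node_class, Xo[k]
                    )
                    if pred == y[oob_idx[k]]:
                        correct_p += 1
                d = acc0 - correct_p / n_oob
                mda_sum[f] += d
                mda_sq_sum[f] += d * d
                for k in range(n_oob):
                    Xo[k, f] = col[k]

    return votes, oob_count, eval_votes, mda_sum, mda_sq_sum, n_mda_trees


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForestSpec:
    """Forest hyperparameters.

    ``features_per_split="default"`` uses floor(sqrt(p)), the standard
    classification setting. ``class_labels`` fixes the label order used
    for vote tie-breaking (ties go to the first label); by default the
    order of first appearance in y.
    """

    n_trees: int
    features_per_split: int | str = "default"
    seed: int = 0
    class_labels: tuple | None = None

    def resolve_mtry(self, p: int) -> int:
        if self.features_per_split == "default":
            return max(1, int(np.sqrt(p)))
        m = int(self.features_per_split)
        if not 1 <= m <= p:
            raise ValueError(f"features_per_split must be in [1, {p}], got {m}")
        return m


@dataclass
class ForestResult:
    """One trained forest's OOB summary and per-feature importance."""

    spec: ForestSpec
    class_labels: tuple
    oob_predictions: list  # per-subject predicted label, or NEVER_OOB
    oob_error: float
    confusion: pd.DataFrame  # 2x2 true x predicted counts over OOB-voted subjects
    mda: pd.Series  # per-feature mean decrease accuracy (accuracy fraction units)
    mda_scaled: pd.Series  # mda / (SD over trees / sqrt(n trees)); z-score variant
    oob_counts: np.ndarray  # per-subject number of trees for which it was OOB

    @property
    def oob_accuracy(self) -> float:
        return 1.0 - self.oob_error

    def top_features(self, k: int, scaled: bool = False) -> list[str]:
        """The k highest-importance feature ids, ties broken by input order."""
        scores = (self.mda_scaled if scaled else self.mda).to_numpy()
        order = np.argsort(-scores, kind="stable")[:k]
        return [self.mda.index[i] for i in sorted(order, key=lambda i: (-scores[i], i))]

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"mda": self.mda, "mda_scaled": self.mda_scaled})
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def _prepare_xy(x, y, class_labels):
    if isinstance(x, pd.DataFrame):
        feature_ids = list(x.columns)
        X = np.ascontiguousarray(x.to_numpy(dtype=np.float32))
    else:
        X = np.ascontiguousarray(np.asarray(x, dtype=np.float32))
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("x must be a subjects x features matrix with >= 2 subjects")
    if np.isnan(X).any():
        raise ValueError("x contains missing values; impute before training")
    y_arr = np.asarray(pd.Series(y).to_numpy())
    if len(y_arr) != X.shape[0]:
        raise ValueError("y length does not match number of subjects")
    labels = tuple(class_labels) if class_labels else tuple(dict.fromkeys(y_arr.tolist()))
    if len(set(y_arr.tolist())) != 2 or len(labels) != 2:
        raise ValueError(f"exactly two classes required, got {sorted(set(y_arr.tolist()))!r}")
    y_enc = np.asarray([labels.index(v) for v in y_arr], dtype=np.int64)
    return X, y_enc, labels, feature_ids


def train_forest(
    x, y, spec: ForestSpec, compute_importance: bool = True
) -> ForestResult:
    """Train a forest and summarise its out-of-bag behaviour.

    Deterministic given ``spec.seed``. Subjects never out of bag (possible
    at very small n_trees) are reported as :data:`NEVER_OOB` and excluded
    from the OOB error denominator, so the error stays defined across the
    whole 10^0–10^6 forest-size grid.
    """
    if spec.n_trees < 1:
        raise ValueError(f"n_trees must be >= 1, got {spec.n_trees}")
    X, y_enc, labels, feature_ids = _prepare_xy(x, y, spec.class_labels)
    mtry = spec.resolve_mtry(X.shape[1])
    empty_eval = np.empty((0, X.shape[1]), dtype=np.float32)
    votes, oob_count, _ev, mda_sum, mda_sq_sum, n_mda = _grow_forest(
        X, y_enc, spec.n_trees, mtry, int(spec.seed) & 0x7FFFFFFF, empty_eval,
        compute_importance,
    )
    preds, confusion, oob_error = _summarise_oob(votes, oob_count, y_enc, labels)
    if compute_importance and n_mda > 0:
        mda = mda_sum / n_mda
        var = np.maximum(mda_sq_sum / n_mda - mda**2, 0.0)
        se = np.sqrt(var / n_mda)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(se > 0, mda / se, 0.0)
    else:
        mda = np.zeros(len(feature_ids))
        scaled = np.zeros(len(feature_ids))
    return ForestResult(
        spec=spec,
        class_labels=labels,
        oob_predictions=preds,
        oob_error=oob_error,
        confusion=confusion,
        mda=pd.Series(mda, index=feature_ids, name="mda"),
        mda_scaled=pd.Series(scaled, index=feature_ids, name="mda_scaled"),
        oob_counts=oob_count,
    )


def _summarise_oob(votes, oob_count, y_enc, labels):
    preds = []
    conf = np.zeros((2, 2), dtype=int)
    for i in range(len(y_enc)):
        if oob_count[i] == 0:
            preds.append(NEVER_OOB)
            continue
        pred = 0 if votes[i, 0] >= votes[i, 1] else 1  # tie -> first label
        preds.append(labels[pred])
        conf[y_enc[i], pred] += 1
    total = conf.sum()
    oob_error = float(1.0 - np.trace(conf) / total) if total else np.nan
    confusion = pd.DataFrame(conf, index=pd.Index(labels, name="true"),
                             columns=pd.Index(labels, name="predicted"))
    return preds, confusion, oob_error


@dataclass
class CvResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    folds: int


def cross_validate(
    x, y, spec: ForestSpec, folds: int = 5, seed: int | None = None
) -> CvResult:
    """Stratified k-fold cross-validated accuracy of the forest.

    ``seed`` drives the fold shuffle and the per-fold forest seeds
    (defaults to ``spec.seed``); held-out predictions are forest majority
    votes with ties to the first class label.
    """
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    X, y_enc, labels, _ = _prepare_xy(x, y, spec.class_labels)
    counts = np.bincount(y_enc, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects; cannot stratify into {folds} folds"
        )
    seed = spec.seed if seed is None else seed
    fold_seeds = spawn_seeds(seed, folds, stream=101)
    mtry = spec.resolve_mtry(X.shape[1])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) & 0x7FFFFFFF)
    accs = []
    for f, (tr, te) in enumerate(skf.split(X, y_enc)):
        _v, _c, eval_votes, _m, _mq, _n = _grow_forest(
            np.ascontiguousarray(X[tr]), y_enc[tr], spec.n_trees, mtry,
            fold_seeds[f], np.ascontiguousarray(X[te]), False,
        )
        pred = np.where(eval_votes[:, 0] >= eval_votes[:, 1], 0, 1)
        accs.append(float(np.mean(pred == y_enc[te])))
    return CvResult(fold_accuracies=accs, mean_accuracy=float(np.mean(accs)), folds=folds)
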