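"""Stepwise one-vs-one SVM protocol with ADASYN balancing.

The protocol, end to end:

1. **ADASYN balancing** — each class is oversampled to a common target by
   density-weighted interpolation between same-class neighbors (k = 5),
   so hard-to-learn minority samples (those with many other-class
   neighbors) receive more synthetic siblings.  Balancing happens once,
   before selection and cross-validation; synthetic siblings may then
   cross folds, which makes fold accuracies optimistic — that is a
   property of the protocol, not corrected here.
2. **Stepwise (floating) selection per class pair** — alternating
   forward addition, backward removal and SVM-parameter re-optimization,
   each step driven by stratified k-fold CV accuracy, until a full cycle
   no longer improves the best accuracy.
3. **One-vs-one multiclass CV (MCV)** — the 21 pairwise models vote per
   test sample; ties break toward the larger summed decision margin,
   then the smaller class index.
4. **Multi-restart evaluation** — the row order is reshuffled per
   restart, selection is rerun, and the restart with the best mean MCV
   accuracy over repeated fold partitions is reported.
5. **Model-family comparison** — families of feature subsets are
   evaluated and compared against a control family with Dunnett's
   many-to-one test, using Monte-Carlo critical values for max |t|.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .io import CLASS_LABELS, feature_columns

__all__ = [
    "DEFAULT_GRID",
    "FEATURE_FAMILIES",
    "PairModel",
    "PairwiseModelSet",
    "EvaluationResult",
    "adasyn_balance",
    "pair_cv_accuracy",
    "stepwise_select",
    "ssvm",
    "mcv",
    "evaluate",
    "dunnett_critical_value",
    "compare_model_families",
]

#: SVM parameter grid W: kernel x cost, linear before RBF, costs ascending.
#: RBF gamma is 1/m with m the number of selected features (sklearn "auto").
DEFAULT_GRID: tuple[tuple[str, float], ...] = tuple(
    (kernel, cost) for kernel in ("linear", "rbf") for cost in (0.1, 1.0, 10.0, 100.0)
)

_CF = tuple(f"f{i}" for i in range(1, 40))
_PF1 = ("f40", "f41", "f42", "f43")
_PF2 = ("f44",)
_PF3 = ("f45", "f46")

#: The eight model families compared in the protocol.
FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "Cf": _CF,
    "Cf+Pf.1": _CF + _PF1,
    "Cf+Pf.2": _CF + _PF2,
    "Cf+Pf.3": _CF + _PF3,
    "Cf+Pf.1+Pf.2": _CF + _PF1 + _PF2,
    "Cf+Pf.1+Pf.3": _CF + _PF1 + _PF3,
    "Cf+Pf.2+Pf.3": _CF + _PF2 + _PF3,
    "Pf.A": _CF + _PF1 + _PF2 + _PF3,
}


@dataclass
class PairModel:
    """Selected model for one class pair."""

    classes: tuple[str, str]
    features: list[str]
    kernel: str
    cost: float
    accuracy: float  # AM, CV accuracy (%) at selection time


@dataclass
class PairwiseModelSet:
    """One selected model per class pair (round-robin over the classes)."""

    models: dict[tuple[str, str], PairModel]


@dataclass
class EvaluationResult:
    """Multi-restart evaluation summary for one model family."""

    restart_means: list[float]          # Mk per restart
    best_index: int                     # d
    best_accuracies: list[float]        # Bd, one accuracy per MCV repeat
    best_models: PairwiseModelSet
    average: float
    sd: float


def _class_sort_key(label: str):
    try:
        return (0, CLASS_LABELS.index(label))
    except ValueError:
        return (1, label)


def _ordered_classes(y) -> list[str]:
    return sorted(set(y), key=_class_sort_key)


# ---------------------------------------------------------------------------
# ADASYN
# ---------------------------------------------------------------------------

def adasyn_balance(
    table: pd.DataFrame,
    per_class_target: int,
    seed: int,
    k: int = 5,
) -> pd.DataFrame:
    """Oversample every class to exactly ``per_class_target`` rows.

    Original rows are preserved verbatim (first, in input order).  Each
    synthetic row is a convex combination x_i + lambda (x_z - x_i) of a
    minority sample and one of its k same-class nearest neighbors; the
    number of synthetics seeded at x_i follows ADASYN's density weighting
    (the fraction of other-class samples among x_i's k nearest neighbors
    in the full data), allocated by largest remainder so the target is
    met exactly.  Classes smaller than k+1 fall back to random same-class
    pair interpolation with a warning.
    """
    if "label" not in table.columns:
        raise ValueError("table has no label column")
    cols = feature_columns(table)
    counts = table["label"].value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least two samples")
    if per_class_target < counts.max():
        raise ValueError("per_class_target must be >= the largest class size")

    rng = np.random.default_rng(seed)
    X_all = table[cols].to_numpy(dtype=np.float64)
    y_all = table["label"].to_numpy()

    nn_all = NearestNeighbors(n_neighbors=min(k + 1, len(table)))
    nn_all.fit(X_all)

    synth_frames = [table]
    for label in _ordered_classes(y_all):
        idx = np.flatnonzero(y_all == label)
        G = per_class_target - idx.size
        if G <= 0:
            continue
        Xc = X_all[idx]
        if idx.size < k + 1:
            warnings.warn(
                f"class {label} smaller than k+1; falling back to random-pair interpolation"
            )
            a = rng.integers(idx.size, size=G)
            b = (a + 1 + rng.integers(idx.size - 1, size=G)) % idx.size
            lam = rng.random((G, 1))
            synth = Xc[a] + lam * (Xc[b] - Xc[a])
        else:
            # Density weights from neighborhoods in the full data.
            _, nbrs = nn_all.kneighbors(Xc)
            nbrs = nbrs[:, 1:]  # drop self
            r = (y_all[nbrs] != label).mean(axis=1)
            weights = r / r.sum() if r.sum() > 0 else np.full(idx.size, 1.0 / idx.size)
            g = _largest_remainder(weights * G, G)
            # Same-class neighbor structure for interpolation partners.
            nn_c = NearestNeighbors(n_neighbors=min(k + 1, idx.size)).fit(Xc)
            _, cn = nn_c.kneighbors(Xc)
            cn = cn[:, 1:]
            rows = []
            for i, gi in enumerate(g):
                if gi == 0:
                    continue
                partners = cn[i][rng.integers(cn.shape[1], size=gi)]
                lam = rng.random((gi, 1))
                rows.append(Xc[i] + lam * (Xc[partners] - Xc[i]))
            synth = np.vstack(rows) if rows else np.empty((0, len(cols)))
        frame = pd.DataFrame(synth, columns=cols)
        frame["label"] = label
        if "id" in table.columns:
            frame["id"] = [f"{label}_synth_{j}" for j in range(len(frame))]
        synth_frames.append(frame[table.columns.intersection(frame.columns)])

    out = pd.concat(synth_frames, ignore_index=True)
    return out


def _largest_remainder(raw: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing exactly to ``total`` (largest remainder)."""
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# Cross-validated SVM accuracy
# ---------------------------------------------------------------------------

def _make_svc(kernel: str, cost: float) -> SVC:
    return SVC(kernel=kernel, C=cost, gamma="auto")


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, kernel: str, cost: float, folds: int, seed: int
) -> float:
    """Stratified k-fold CV accuracy (%) of a binary/multiclass SVC."""
    min_class = np.bincount(pd.factorize(y)[0]).min()
    if folds > min_class:
        warnings.warn(f"reducing folds from {folds} to {min_class}")
        folds = int(min_class)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    correct = 0
    for train, test in skf.split(X, y):
        clf = _make_svc(kernel, cost).fit(X[train], y[train])
        correct += int((clf.predict(X[test]) == y[test]).sum())
    return 100.0 * correct / len(y)


def pair_cv_accuracy(
    table: pd.DataFrame,
    pair: tuple[str, str],
    features: list[str],
    params: tuple[str, float],
    folds: int = 10,
    seed: int = 0,
) -> float:
    """CV accuracy (%) of a two-class SVM on the given features/parameters."""
    if not features:
        raise ValueError("feature subset must be non-empty")
    sub = table[table["label"].isin(pair)]
    if sub["label"].nunique() < 2:
        raise ValueError(f"both classes of {pair} must be present")
    X = sub[list(features)].to_numpy(dtype=np.float64)
    y = sub["label"].to_numpy()
    return _cv_accuracy(X, y, params[0], params[1], folds, seed)


# ---------------------------------------------------------------------------
# Stepwise (floating) selection
# ---------------------------------------------------------------------------

def stepwise_select(
    table: pd.DataFrame,
    pair: tuple[str, str],
    candidates: list[str] | None = None,
    grid: tuple[tuple[str, float], ...] = DEFAULT_GRID,
    folds: int = 10,
    seed: int = 0,
) -> PairModel:
    """Floating forward/backward feature selection with parameter tuning.

    Cycles of (forward additions, backward removals, grid re-optimization)
    run until a full cycle leaves the best CV accuracy AM unchanged.
    Ties break toward the smaller feature index, then the earlier grid
    entry (linear before RBF, smaller cost first).  At least one feature
    is always selected.
    """
    sub = table[table["label"].isin(pair)].reset_index(drop=True)
    if sub["label"].nunique() < 2:
        raise ValueError(f"both classes of {pair} must be present")
    cols = candidates if candidates is not None else feature_columns(table)
    if not cols:
        raise ValueError("no candidate features")
    X_full = sub[list(cols)].to_numpy(dtype=np.float64)
    y = sub["label"].to_numpy()
    col_index = {c: i for i, c in enumerate(cols)}

    def cv(feats: list[str], kernel: str, cost: float) -> float:
        X = X_full[:, [col_index[f] for f in feats]]
        return _cv_accuracy(X, y, kernel, cost, folds, seed)

    selected: list[str] = []
    kernel, cost = grid[0]
    am = -np.inf

    updated = True
    while updated:
        updated = False
        # Forward: keep adding the best feature while it strictly improves AM
        # (the very first feature is added unconditionally).
        while True:
            best_f, best_ac = None, -np.inf
            for f in cols:
                if f in selected:
                    continue
                ac = cv(selected + [f], kernel, cost)
                if ac > best_ac:
                    best_f, best_ac = f, ac
            if best_f is None:
                break
            if best_ac > am or not selected:
                selected.append(best_f)
                am = best_ac
                updated = True
            else:
                break
        # Backward: remove features while a removal strictly improves AM.
        while len(selected) > 1:
            best_f, best_ac = None, -np.inf
            for f in selected:
                rest = [c for c in selected if c != f]
                ac = cv(rest, kernel, cost)
                if ac > best_ac:
                    best_f, best_ac = f, ac
            if best_ac > am:
                selected.remove(best_f)
                am = best_ac
                updated = True
            else:
                break
        # Parameter re-optimization over the grid (first best wins ties).
        best_params, best_ac = None, -np.inf
        for kern, c in grid:
            ac = cv(selected, kern, c)
            if ac > best_ac:
                best_params, best_ac = (kern, c), ac
        if best_ac > am:
            kernel, cost = best_params
            am = best_ac
            updated = True

    return PairModel(
        classes=tuple(pair), features=selected, kernel=kernel, cost=cost,
        accuracy=float(am),
    )


def ssvm(
    table: pd.DataFrame,
    candidates: list[str] | None = None,
    grid: tuple[tuple[str, float], ...] = DEFAULT_GRID,
    folds: int = 10,
    seed: int = 0,
) -> PairwiseModelSet:
    """Stepwise selection for every class pair (round-robin)."""
    classes = _ordered_classes(table["label"])
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    models = {}
    for pair in itertools.combinations(classes, 2):
        models[pair] = stepwise_select(
            table, pair, candidates=candidates, grid=grid, folds=folds,
            seed=int(rng.integers(2**31)),
        )
    return PairwiseModelSet(models)


# ---------------------------------------------------------------------------
# One-vs-one multiclass CV
# ---------------------------------------------------------------------------

def mcv(
    table: pd.DataFrame,
    models: PairwiseModelSet,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Multiclass CV accuracy (%) by one-vs-one majority voting.

    Per fold, each pairwise model is retrained on the training rows of its
    two classes with its selected features/parameters; test rows take the
    majority class over the 21 votes, ties resolved by the larger summed
    decision-function margin, then the smaller class index.
    """
    classes = _ordered_classes(table["label"])
    pairs = list(itertools.combinations(classes, 2))
    missing = [p for p in pairs if p not in models.models]
    if missing:
        raise ValueError(f"model set does not cover pairs {missing}")

    y = table["label"].to_numpy()
    min_class = pd.Series(y).value_counts().min()
    if folds > min_class:
        warnings.warn(f"reducing folds from {folds} to {min_class}")
        folds = int(min_class)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    class_pos = {c: i for i, c in enumerate(classes)}

    correct = 0
    for train, test in skf.split(np.zeros(len(y)), y):
        votes = np.zeros((len(test), len(classes)), dtype=int)
        margins = np.zeros((len(test), len(classes)))
        for pair in pairs:
            pm = models.models[pair]
            tr_rows = table.iloc[train]
            tr = tr_rows[tr_rows["label"].isin(pair)]
            Xtr = tr[pm.features].to_numpy(dtype=np.float64)
            ytr = tr["label"].to_numpy()
            clf = _make_svc(pm.kernel, pm.cost).fit(Xtr, ytr)
            Xte = table.iloc[test][pm.features].to_numpy(dtype=np.float64)
            pred = clf.predict(Xte)
            dec = np.abs(clf.decision_function(Xte))
            for row, (p, m) in enumerate(zip(pred, dec)):
                votes[row, class_pos[p]] += 1
                margins[row, class_pos[p]] += m
        for row, true in enumerate(y[test]):
            vmax = votes[row].max()
            tied = np.flatnonzero(votes[row] == vmax)
            if len(tied) > 1:
                mmax = margins[row, tied].max()
                tied = tied[margins[row, tied] == mmax]
            winner = classes[int(tied[0])]  # smallest class index last
            correct += int(winner == true)
    return 100.0 * correct / len(y)


# ---------------------------------------------------------------------------
# Multi-restart evaluation and family comparison
# ---------------------------------------------------------------------------

def evaluate(
    table: pd.DataFrame,
    family: list[str] | tuple[str, ...] | None = None,
    restarts: int = 40,
    mcv_repeats: int = 50,
    folds: int = 10,
    seed: int = 0,
) -> EvaluationResult:
    """Multi-restart SSVM evaluation of one model family.

    Per restart the rows are reshuffled, selection reruns on the family's
    features, and the mean MCV accuracy over ``mcv_repeats`` distinct fold
    partitions is recorded; the restart with the best mean is reported
    with its repeat-level accuracies.
    """
    feats = list(family) if family is not None else feature_columns(table)
    feats = [f for f in feats if f in table.columns]
    if not feats:
        raise ValueError("family has no features present in the table")
    rng = np.random.default_rng(seed)

    restart_means: list[float] = []
    all_accs: list[list[float]] = []
    all_models: list[PairwiseModelSet] = []
    for _ in range(restarts):
        perm = rng.permutation(len(table))
        shuffled = table.iloc[perm].reset_index(drop=True)
        models = ssvm(
            shuffled, candidates=feats, folds=folds, seed=int(rng.integers(2**31))
        )
        accs = [
            mcv(shuffled, models, folds=folds, seed=int(rng.integers(2**31)))
            for _ in range(mcv_repeats)
        ]
        restart_means.append(float(np.mean(accs)))
        all_accs.append(accs)
        all_models.append(models)

    d = int(np.argmax(restart_means))
    bd = all_accs[d]
    return EvaluationResult(
        restart_means=restart_means,
        best_index=d,
        best_accuracies=bd,
        best_models=all_models[d],
        average=float(np.mean(bd)),
        sd=float(np.std(bd, ddof=1)) if len(bd) > 1 else 0.0,
    )


def dunnett_critical_value(
    n_groups: int,
    n_per_group: int,
    alpha: float = 0.05,
    draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo critical value of the many-to-one max-|t| statistic.

    Simulates the null directly from the sampling distributions of the
    group means (normal) and the pooled variance (chi-squared), which is
    exact for normal data.  With two groups this reduces to the two-sided
    two-sample t critical value.
    """
    if n_groups < 2 or n_per_group < 2:
        raise ValueError("need >= 2 groups of >= 2 observations")
    rng = np.random.default_rng(seed)
    m = n_groups - 1
    df = n_groups * (n_per_group - 1)
    means = rng.standard_normal((draws, n_groups)) / np.sqrt(n_per_group)
    s2 = rng.chisquare(df, size=draws) / df
    t = (means[:, 1:] - means[:, :1]) / np.sqrt(s2[:, None] * 2.0 / n_per_group)
    max_abs_t = np.abs(t).max(axis=1)
    return float(np.quantile(max_abs_t, 1.0 - alpha))


def compare_model_families(
    table: pd.DataFrame,
    families: dict[str, tuple[str, ...]] | None = None,
    control: str = "Cf",
    alpha: float = 0.05,
    restarts: int = 40,
    mcv_repeats: int = 50,
    folds: int = 10,
    seed: int = 0,
    mc_draws: int = 100_000,
) -> pd.DataFrame:
    """Evaluate families and Dunnett-test each against the control.

    Test statistics use the pooled variance over all families' accuracy
    sets; the critical value comes from :func:`dunnett_critical_value`.
    Returns one row per family with average, SD and the significance flag.
    """
    families = dict(families) if families is not None else dict(FEATURE_FAMILIES)
    if control not in families:
        raise ValueError(f"control family {control!r} not among families")

    rng = np.random.default_rng(seed)
    # Common random numbers: every family is evaluated under the same
    # shuffles and fold partitions, so identical families score identically
    # and between-family differences are not masked by seed noise.
    eval_seed = int(rng.integers(2**31))
    results: dict[str, EvaluationResult] = {}
    for name, feats in families.items():
        results[name] = evaluate(
            table, feats, restarts=restarts, mcv_repeats=mcv_repeats,
            folds=folds, seed=eval_seed,
        )

    names = list(families)
    sets = {n: np.asarray(results[n].best_accuracies) for n in names}
    n_rep = len(sets[control])
    pooled = np.mean([sets[n].var(ddof=1) for n in names])
    crit = dunnett_critical_value(
        len(names), n_rep, alpha=alpha, draws=mc_draws,
        seed=int(rng.integers(2**31)),
    )

    rows = []
    for name in names:
        if name == control:
            t = np.nan
            sig = False
        else:
            diff = sets[name].mean() - sets[control].mean()
            denom = np.sqrt(pooled * 2.0 / n_rep)
            t = float(diff / denom) if denom > 0 else (0.0 if diff == 0 else np.inf)
            sig = bool(abs(t) > crit)
        rows.append({
            "family": name,
            "average": float(sets[name].mean()),
            "sd": float(sets[name].std(ddof=1)),
            "t_vs_control": t,
            "significant": sig,
            "selected_features": {
                "/".join(p): results[name].best_models.models[p].features
                for p in results[name].best_models.models
            },
        })
    out = pd.DataFrame(rows)
    out.attrs["critical_value"] = crit
    out.attrs["alpha"] = alpha
    return out
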