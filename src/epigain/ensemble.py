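"""Dual-ensemble SNP ranking: repeated stratified CV, tuning and consensus.

Two tree-ensemble learners — a bagged random forest ranked by Gini (impurity
decrease) importance and a gradient boosting machine ranked by
improvement-weighted split importance — are run through the same harness:
stratified k-fold cross-validation repeated several times per fold, a
parameter-grid search scored by average CV accuracy (AUC breaks ties), and
per-SNP importances averaged over all folds x repeats then min-max
normalised.  The two normalised rankings are combined by a consensus rule:
either a diagonal threshold on the sum of normalised scores (the "separating
line" between the jointly-high-scoring cluster and the rest) or the
intersection of each method's top-k.

The tree learners themselves come from scikit-learn behind the
:class:`LearnerAdapter` contract; the harness never touches tree internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from .genotype import GenotypeMatrix, Phenotype
from .relief import ImportanceTable

__all__ = [
    "LearnerAdapter",
    "RandomForestAdapter",
    "GBMAdapter",
    "OracleAdapter",
    "MajorityAdapter",
    "ParamGrid",
    "RF_GRID",
    "GBM_GRID",
    "CVReport",
    "stratified_kfold",
    "repeated_cv",
    "average_cv_accuracy",
    "cv_auc",
    "tune",
    "aggregate_importance",
    "consensus_select",
]


# ---------------------------------------------------------------------------
# Adapters


class LearnerAdapter:
    """Contract a learner must satisfy to run in the CV harness.

    ``fit`` returns an opaque fitted model; ``predict_proba`` maps it to
    per-sample case probabilities in [0, 1]; ``importance`` to a non-negative
    per-SNP score vector of length n_snps.
    """

    name: str = "base"

    def fit(self, X: np.ndarray, y: np.ndarray, params: dict, seed: int):
        raise NotImplementedError

    def predict_proba(self, model, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def importance(self, model) -> np.ndarray:
        raise NotImplementedError


class _SklearnAdapter(LearnerAdapter):
    def predict_proba(self, model, X):
        proba = model.predict_proba(X)
        case_col = list(model.classes_).index(1)
        return proba[:, case_col]

    def importance(self, model):
        return np.asarray(model.feature_importances_, dtype=float)


class RandomForestAdapter(_SklearnAdapter):
    """Bagged forest; params: ntree, mtry (clamped to n_snps with a warning)."""

    name = "rf"

    def fit(self, X, y, params, seed):
        mtry = int(params.get("mtry", max(1, int(np.sqrt(X.shape[1])))))
        if mtry > X.shape[1]:
            import warnings

            warnings.warn(f"mtry={mtry} > n_snps={X.shape[1]}; clamping")
            mtry = X.shape[1]
        model = RandomForestClassifier(
            n_estimators=int(params.get("ntree", 500)),
            max_features=mtry,
            criterion="gini",
            random_state=seed,
            n_jobs=1,
        )
        return model.fit(X, y)


class GBMAdapter(_SklearnAdapter):
    """Boosted trees; params: n_trees, interaction_depth, shrinkage.

    Fixed settings follow common GBM defaults for GWAS-scale tabular data:
    minimum 10 samples per leaf and 0.5 subsampling per tree.
    """

    name = "gbm"

    def fit(self, X, y, params, seed):
        model = GradientBoostingClassifier(
            n_estimators=int(params.get("n_trees", 100)),
            max_depth=int(params.get("interaction_depth", 1)),
            learning_rate=float(params.get("shrinkage", 0.1)),
            min_samples_leaf=10,
            subsample=0.5,
            random_state=seed,
        )
        return model.fit(X, y)


class OracleAdapter(LearnerAdapter):
    """Test double that memorises the full label vector and predicts it exactly."""

    name = "oracle"

    def __init__(self, labels: np.ndarray):
        self.labels = np.asarray(labels)

    def fit(self, X, y, params, seed):
        return None

    def predict_proba(self, model, X):
        # X carries the original sample index in its last column (see
        # repeated_cv's index pass-through used only by test adapters).
        return self.labels[X[:, -1].astype(int)].astype(float)

    def importance(self, model):
        return np.zeros(1)


class MajorityAdapter(LearnerAdapter):
    """Test double predicting the training majority class probability for all."""

    name = "majority"

    def fit(self, X, y, params, seed):
        return float(np.mean(y))

    def predict_proba(self, model, X):
        return np.full(X.shape[0], model)

    def importance(self, model):
        return np.zeros(1)


# ---------------------------------------------------------------------------
# Grids


@dataclass
class ParamGrid:
    """Cartesian parameter grid; each axis is a name -> list of values."""

    axes: dict[str, list]

    def cells(self) -> list[dict]:
        names = list(self.axes)
        return [dict(zip(names, combo)) for combo in product(*self.axes.values())]


RF_GRID = ParamGrid({"mtry": [100, 200, 300, 500, 1000], "ntree": [500, 1000, 2000]})
GBM_GRID = ParamGrid({
    "n_trees": [100, 500, 1000, 2000],
    "interaction_depth": [1, 2, 10],
    "shrinkage": [0.001, 0.01, 0.1],
})


@dataclass
class CVReport:
    """Grid-search results: per-cell average CV accuracy/AUC and the winner."""

    cells: list[dict]
    accuracy: list[float]
    auc: list[float]
    winner: dict = field(default_factory=dict)

    def pick_winner(self) -> dict:
        # max accuracy; ties -> higher AUC, then first in grid order
        best = 0
        for i in range(1, len(self.cells)):
            if (self.accuracy[i], self.auc[i]) > (self.accuracy[best], self.auc[best]):
                best = i
        self.winner = self.cells[best]
        return self.winner

    def write(self, path) -> None:
        keys = sorted({k for c in self.cells for k in c})
        with open(path, "w") as fh:
            fh.write("\t".join(keys) + "\tcv_accuracy\tcv_auc\twinner\n")
            for c, acc, auc in zip(self.cells, self.accuracy, self.auc):
                row = [str(c.get(k, "")) for k in keys]
                fh.write("\t".join(row) + f"\t{acc:.6g}\t{auc:.6g}"
                         f"\t{int(c == self.winner)}\n")


# ---------------------------------------------------------------------------
# CV machinery


def _derive_seed(master: int, *parts: int) -> int:
    """Deterministic per-(fold, repeat, cell) seed via a SeedSequence spawn key."""
    return int(np.random.SeedSequence([master & 0x7FFFFFFF, *parts]).generate_state(1)[0]
               & 0x7FFFFFFF)


def stratified_kfold(phen: Phenotype, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """k disjoint test index sets with per-fold class balance within 1 sample."""
    y = phen.labels
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for pos, sample in enumerate(idx):
            folds[pos % k].append(int(sample))
    return [np.array(sorted(f), dtype=int) for f in folds]


def repeated_cv(
    g: GenotypeMatrix,
    phen: Phenotype,
    adapter: LearnerAdapter,
    params: dict,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Stratified k-fold CV with ``repeats`` fits per fold.

    Returns (per-sample correct fraction over the repeats of its test fold,
    per-sample mean case probability, list of importance vectors from every
    fit).  Classification threshold is 0.5 on the case probability.
    """
    X = g.genotypes.astype(np.float64)
    y = np.asarray(phen.labels, dtype=int)
    n = X.shape[0]
    # index pass-through column so test doubles can identify samples; real
    # learners see it as one extra constant-importance feature stripped below
    Xi = np.hstack([X, np.arange(n, dtype=float)[:, None]])
    use_index = isinstance(adapter, (OracleAdapter,))

    folds = stratified_kfold(phen, k=k, seed=_derive_seed(seed, 0))
    frac_correct = np.full(n, np.nan)
    mean_prob = np.full(n, np.nan)
    importances: list[np.ndarray] = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xtr = Xi[train_idx] if use_index else X[train_idx]
        Xte = Xi[test_idx] if use_index else X[test_idx]
        probs = np.zeros((repeats, test_idx.size))
        for r in range(repeats):
            fit_seed = _derive_seed(seed, 1, f, r)
            try:
                model = adapter.fit(Xtr, y[train_idx], params, fit_seed)
            except Exception as exc:  # noqa: BLE001 - contract: name the failure site
                raise RuntimeError(
                    f"adapter {adapter.name!r} failed at fold {f}, repeat {r}: {exc}"
                ) from exc
            probs[r] = adapter.predict_proba(model, Xte)
            imp = np.asarray(adapter.importance(model), dtype=float)
            if imp.shape[0] == g.n_snps:
                importances.append(imp)
        pred = (probs >= 0.5).astype(int)
        frac_correct[test_idx] = (pred == y[test_idx]).mean(axis=0)
        mean_prob[test_idx] = probs.mean(axis=0)
    return frac_correct, mean_prob, importances


def average_cv_accuracy(frac_correct: np.ndarray) -> float:
    """Mean of the per-sample correct fractions."""
    v = np.asarray(frac_correct, dtype=float)
    if np.isnan(v).any():
        raise ValueError("per-sample fractions contain NaN (sample never tested)")
    return float(v.mean())


def cv_auc(mean_prob: np.ndarray, phen: Phenotype) -> float:
    """Rank-based (Mann-Whitney) AUC of pooled per-sample mean probabilities."""
    y = phen.labels
    if not phen.both_classes_present():
        raise ValueError("AUC undefined for a single-class phenotype")
    p = np.asarray(mean_prob, dtype=float)
    pos = p[y == 1]
    neg = p[y == 0]
    # concordant pairs + half ties, computed via midranks
    from scipy.stats import rankdata

    ranks = rankdata(p)
    auc = (ranks[y == 1].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    return float(auc)


def tune(
    g: GenotypeMatrix,
    phen: Phenotype,
    adapter: LearnerAdapter,
    grid: ParamGrid,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CVReport:
    """Exhaustive grid search scored by average CV accuracy (AUC tie-break)."""
    cells = grid.cells()
    if not cells:
        raise ValueError("empty parameter grid")
    accs: list[float] = []
    aucs: list[float] = []
    for cell in cells:
        frac, prob, _ = repeated_cv(g, phen, adapter, cell, k=k, repeats=repeats,
                                    seed=seed)
        accs.append(average_cv_accuracy(frac))
        aucs.append(cv_auc(prob, phen))
    report = CVReport(cells, accs, aucs)
    report.pick_winner()
    return report


def aggregate_importance(importances: list[np.ndarray],
                         snp_ids: list[str], method: str) -> ImportanceTable:
    """Mean importance over all fits, min-max normalised to [0, 1]."""
    if not importances:
        raise ValueError("no importance vectors to aggregate")
    lengths = {v.shape[0] for v in importances}
    if lengths != {len(snp_ids)}:
        raise ValueError("importance vector length mismatch")
    mean = np.mean(np.vstack(importances), axis=0)
    lo, hi = mean.min(), mean.max()
    norm = np.zeros_like(mean) if hi == lo else (mean - lo) / (hi - lo)
    return ImportanceTable(list(snp_ids), norm, method=method)


def consensus_select(
    rf: ImportanceTable,
    gbm: ImportanceTable,
    rule: str = "diagonal",
    t: float = 1.0,
    k: int | None = None,
) -> set[str]:
    """Consensus SNP selection from two normalised importance tables.

    ``rule='diagonal'``: select SNPs with normalised_rf + normalised_gbm >= t
    (the separating line drawn across the joint score scatter).
    ``rule='top_k'``: intersection of each method's top-k ranks.
    """
    if list(rf.snp_ids) != list(gbm.snp_ids):
        raise ValueError("importance tables must share the same snp_ids")
    if rule == "diagonal":
        total = rf.scores + gbm.scores
        return {rf.snp_ids[i] for i in np.flatnonzero(total >= t)}
    if rule == "top_k":
        if k is None or k < 1:
            raise ValueError("top_k rule requires k >= 1")
        return set(rf.ranking()[:k]) & set(gbm.ranking()[:k])
    raise ValueError(f"unknown consensus rule {rule!r}")
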