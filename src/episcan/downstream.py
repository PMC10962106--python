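"""Downstream uses of a 2D scan: two-locus haplogroups and phenotype
classification with selected 1D + 2D features.

The prediction harness mirrors a marker-assisted selection workflow: the
sample is split 50/50, scans and feature selection run on the training half
only, and classifiers predict quantile-binned phenotype classes on the held
-out half.  The informativeness of true epistatic features is measured by
pairing every run against an identical run where the 2D features are
replaced by randomly sampled pairs (``2D_random``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .interactions import TermKey, n_pairs, pair_to_index, index_to_pair
from .simdata import GenotypeMatrix

__all__ = [
    "TwoLocusGroups",
    "PredictionRun",
    "two_locus_groups",
    "quantile_classes",
    "split_train_test",
    "build_feature_table",
    "sample_random_pairs",
    "classifier_registry",
    "evaluate_classifiers",
    "prediction_study",
    "compare_true_vs_random",
]


@dataclass
class TwoLocusGroups:
    """Phenotype values partitioned by the joint genotype at a SNP pair."""

    i: int
    j: int
    cells: dict[tuple[int, int], np.ndarray]
    marginal_i: dict[int, np.ndarray]
    marginal_j: dict[int, np.ndarray]

    def summary(self) -> pd.DataFrame:
        rows = []
        for (a, b), vals in sorted(self.cells.items()):
            rows.append(
                {
                    "dosage_i": a,
                    "dosage_j": b,
                    "count": len(vals),
                    "mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "median": float(np.median(vals)) if len(vals) else np.nan,
                    "q25": float(np.quantile(vals, 0.25)) if len(vals) else np.nan,
                    "q75": float(np.quantile(vals, 0.75)) if len(vals) else np.nan,
                }
            )
        return pd.DataFrame(rows)


def two_locus_groups(X: GenotypeMatrix, Y: np.ndarray, i: int, j: int) -> TwoLocusGroups:
    """Partition individuals by (dosage_i, dosage_j); empty cells get count 0."""
    if not 0 <= i < j < X.p:
        raise ValueError(f"need 0 <= i < j < p, got ({i}, {j})")
    y = np.asarray(Y, dtype=float)
    if y.shape[0] != X.n:
        raise ValueError("phenotype length mismatch")
    xi = X.values[:, i]
    xj = X.values[:, j]
    lv = range(X.ploidy + 1)
    cells = {(a, b): y[(xi == a) & (xj == b)] for a in lv for b in lv}
    return TwoLocusGroups(
        i=i,
        j=j,
        cells=cells,
        marginal_i={a: y[xi == a] for a in lv},
        marginal_j={b: y[xj == b] for b in lv},
    )


def quantile_classes(Y: np.ndarray, n_classes: int) -> np.ndarray:
    """Rank phenotypes into 3 or 5 empirical-quantile classes.

    Class boundaries are the c/k quantiles; a value exactly on a boundary
    goes to the lower class.
    """
    if n_classes not in (3, 5):
        raise ValueError("n_classes must be 3 or 5")
    y = np.asarray(Y, dtype=float)
    if np.unique(y).size < n_classes:
        raise ValueError("fewer distinct phenotype values than classes")
    cuts = np.quantile(y, [c / n_classes for c in range(1, n_classes)])
    return (y[:, None] > cuts[None, :]).sum(axis=1).astype(int)


def split_train_test(
    n: int,
    fraction: float = 0.5,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test split; stratified when labels given."""
    if n < 4:
        raise ValueError("need at least 4 individuals to split")
    from sklearn.model_selection import train_test_split

    idx = np.arange(n)
    train, test = train_test_split(
        idx,
        train_size=fraction,
        random_state=seed,
        shuffle=True,
        stratify=None if labels is None else np.asarray(labels),
    )
    return np.sort(train), np.sort(test)


def build_feature_table(
    X: GenotypeMatrix, top1d: Sequence[TermKey], top2d: Sequence[TermKey]
) -> np.ndarray:
    """n x (k1 + k2) matrix: dosage columns then pair product columns."""
    keys = list(top1d) + list(top2d)
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate term keys in the feature request")
    for k in top1d:
        if k.kind != "single":
            raise ValueError("top1d must contain single-SNP keys")
    for k in top2d:
        if k.kind != "pair":
            raise ValueError("top2d must contain pair keys")
    V = X.values.astype(float)
    cols = [V[:, k.i] if k.kind == "single" else V[:, k.i] * V[:, k.j] for k in keys]
    return np.column_stack(cols) if cols else np.empty((X.n, 0))


def sample_random_pairs(
    p: int, k: int, exclude: Sequence[TermKey] = (), seed: int = 0
) -> list[TermKey]:
    """Uniform sample of k distinct pairs outside ``exclude``."""
    excl = {pair_to_index(t.i, t.j, p) for t in exclude if t.kind == "pair"}
    total = n_pairs(p)
    if k > total - len(excl):
        raise ValueError(f"cannot sample {k} pairs from {total - len(excl)} available")
    rng = np.random.default_rng(seed)
    if total <= 10**6:
        avail = np.setdiff1d(np.arange(total), np.fromiter(excl, dtype=int, count=len(excl)))
        chosen = rng.choice(avail, size=k, replace=False)
    else:  # rejection sampling for huge landscapes
        chosen_set: set[int] = set()
        while len(chosen_set) < k:
            c = int(rng.integers(0, total))
            if c not in excl and c not in chosen_set:
                chosen_set.add(c)
        chosen = np.fromiter(chosen_set, dtype=int, count=k)
    return sorted(TermKey.pair(*index_to_pair(int(c), p)) for c in chosen)


@dataclass
class PredictionRun:
    model: str
    phenotype: str
    n_classes: int
    n_features: int
    feature_mode: str  # "1D+2D" | "1D+2D_random"
    max_f1: float
    per_class_f1: list[float] = field(default_factory=list)
    confusion: list[list[int]] = field(default_factory=list)

    def key(self) -> tuple:
        return (self.model, self.phenotype, self.n_classes, self.n_features)


def classifier_registry(seed: int = 0, small: bool = True) -> dict:
    """Default registry of standard classifier families.

    ``small=True`` keeps each model cheap (documented desk-scale defaults);
    the registry is a plain dict and can be extended or replaced.
    """
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    reg = {
        "logistic": LogisticRegression(max_iter=500, random_state=seed),
        "lasso": LogisticRegression(
            solver="saga", l1_ratio=1.0, C=0.5, max_iter=500, random_state=seed
        ),
        "elasticnet": LogisticRegression(
            solver="saga", l1_ratio=0.5, C=0.5, max_iter=300, random_state=seed
        ),
        "svm": SVC(kernel="rbf", C=1.0, random_state=seed),
        "random_forest": RandomForestClassifier(
            n_estimators=100 if small else 400, random_state=seed
        ),
        "gradient_boosting": GradientBoostingClassifier(
            n_estimators=50 if small else 200, random_state=seed
        ),
        "mlp": MLPClassifier(
            hidden_layer_sizes=(32,) if small else (128, 64),
            max_iter=300, random_state=seed,
        ),
    }
    return reg


def evaluate_classifiers(
    features: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    models: dict | None = None,
    phenotype: str = "trait",
    feature_mode: str = "1D+2D",
    n_features_label: int | None = None,
) -> list[PredictionRun]:
    """Fit each model on the train half, score per-class F1 on the test half.

    The reported statistic is the maximum per-class (one-vs-rest) F1 — the
    best-predicted class.  Degenerate single-class training labels skip the
    model with a warning.
    """
    from sklearn.metrics import confusion_matrix, f1_score
    from sklearn.preprocessing import StandardScaler

    y = np.asarray(labels)
    models = models if models is not None else classifier_registry()
    runs: list[PredictionRun] = []
    scaler = StandardScaler().fit(features[train_idx])
    ftr = scaler.transform(features[train_idx])
    fte = scaler.transform(features[test_idx])
    n_classes = int(np.unique(y).size)
    nf = features.shape[1] if n_features_label is None else n_features_label
    for name, model in models.items():
        if np.unique(y[train_idx]).size < 2:
            import warnings

            warnings.warn(f"single-class training labels; skipping {name}")
            continue
        import copy

        est = copy.deepcopy(model)
        est.fit(ftr, y[train_idx])
        pred = est.predict(fte)
        per_class = f1_score(y[test_idx], pred, average=None, labels=np.unique(y))
        runs.append(
            PredictionRun(
                model=name,
                phenotype=phenotype,
                n_classes=n_classes,
                n_features=nf,
                feature_mode=feature_mode,
                max_f1=float(np.max(per_class)),
                per_class_f1=[float(v) for v in per_class],
                confusion=confusion_matrix(
                    y[test_idx], pred, labels=np.unique(y)
                ).tolist(),
            )
        )
    return runs


def prediction_study(
    X: GenotypeMatrix,
    Y: np.ndarray,
    n_classes: int = 5,
    n_1d: int = 30,
    n_2d: int = 30,
    models: dict | None = None,
    seed: int = 0,
    solver_config=None,
    phenotype: str = "trait",
) -> dict:
    """Train/test phenotype-classification study with true vs random 2D features.

    The sample is split 50/50 stratified by quantile class.  The 1D and 2D
    scans and the feature selection run on the training half only; the
    held-out half is used exclusively for scoring.  Returns a dict with the
    paired runs, the selected keys and the split (for leak auditing).
    """
    from .pipeline import run_2d
    from .solver import SolverConfig, seed_for

    y = np.asarray(Y, dtype=float)
    labels = quantile_classes(y, n_classes)
    train, test = split_train_test(X.n, 0.5, seed=seed, labels=labels)
    X_train = GenotypeMatrix(
        X.values[train], X.markers, [X.individuals[i] for i in train], X.ploidy
    )
    cfg = solver_config or SolverConfig(dtype="float32", debias=True)
    em = run_2d(X_train, y[train], cfg.with_seed(seed_for(seed, "scan")))
    top1d = [k for k in em.top(len(em)) if k.kind == "single"][:n_1d]
    top2d = em.pairs_only().top(n_2d)
    rnd2d = sample_random_pairs(X.p, n_2d, exclude=top2d, seed=seed_for(seed, "rnd"))
    runs = {}
    for mode, pairs in (("1D+2D", top2d), ("1D+2D_random", rnd2d)):
        feats = build_feature_table(X, top1d, pairs)
        runs[mode] = evaluate_classifiers(
            feats, labels, train, test,
            models=models, phenotype=phenotype, feature_mode=mode,
            n_features_label=n_1d + n_2d,
        )
    table, frac = compare_true_vs_random(runs["1D+2D"], runs["1D+2D_random"])
    return {
        "runs": runs,
        "paired": table,
        "fraction_improved": frac,
        "top1d": top1d,
        "top2d": top2d,
        "random2d": rnd2d,
        "train_idx": train,
        "test_idx": test,
    }


def compare_true_vs_random(
    runs_2d: Sequence[PredictionRun], runs_random: Sequence[PredictionRun]
) -> tuple[pd.DataFrame, float]:
    """Pair runs by (model, phenotype, classes, features); fraction improved.

    Returns the paired table and the fraction of pairs where the true-2D
    run strictly beats its random-2D control on max F1.
    """
    import warnings

    by_key = {r.key(): r for r in runs_random}
    rows = []
    for r in runs_2d:
        ctrl = by_key.get(r.key())
        if ctrl is None:
            warnings.warn(f"no paired control for {r.key()}; excluded")
            continue
        rows.append(
            {
                "model": r.model,
                "phenotype": r.phenotype,
                "n_classes": r.n_classes,
                "n_features": r.n_features,
                "f1_2d": r.max_f1,
                "f1_random": ctrl.max_f1,
                "improved": r.max_f1 > ctrl.max_f1,
            }
        )
    table = pd.DataFrame(rows)
    frac = float(table["improved"].mean()) if len(table) else float("nan")
    return table, frac
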