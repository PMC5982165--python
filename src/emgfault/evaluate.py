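"""Seven-setting SVM movement classification and the three-factor ANOVA.

An 18-class (rest + 17 movements) one-vs-all RBF-kernel SVM is trained and
tested under the complementary repetition k-fold scheme (all C(6,3) = 20
train/test partitions of the six repetitions), with a majority vote over the
last three window predictions as post-processing.  The seven settings:

    1  clean train / clean test (reference)
    2  clean train / contaminated test
    3  retrain and test without the channels the SFTD marks for removal
    4  clean train / TVARMA-reconstructed test
    5  retrain: TVARMA reconstruction in train and test
    6  clean train / TVK-reconstructed test
    7  retrain: TVK reconstruction in train and test

Per-cell mean accuracies feed a fixed-effects full-factorial three-way ANOVA
(classification setting x contaminant x channel case) with per-group 95%
confidence intervals for multiple comparisons (two means differ significantly
when their intervals are disjoint).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sstats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import feature_columns

__all__ = [
    "FoldScheme",
    "ClassifierModel",
    "EvaluationResult",
    "AnovaModel",
    "enumerate_kfolds",
    "train_classifier",
    "majority_vote",
    "predict_stream",
    "run_setting",
    "anova3",
    "DEFAULT_GRID",
    "COARSE_GRID",
]

#: grid-search ranges (cost, kernel width) for the per-subject search
DEFAULT_GRID = {
    "C": [2.0**k for k in range(-3, 8, 2)],
    "gamma": [2.0**k for k in range(-7, 4, 2)],
}
#: coarse desk-scale grid used by the study harness
COARSE_GRID = {"C": [2.0**-3, 2.0**2, 2.0**7], "gamma": [2.0**-7, 2.0**-4, 2.0**-1]}


@dataclass(frozen=True)
class FoldScheme:
    """All complementary train/test repetition partitions."""

    partitions: tuple  # ((train_tuple, test_tuple), ...)

    def __len__(self) -> int:
        return len(self.partitions)

    def __getitem__(self, i):
        return self.partitions[i]

    def __iter__(self):
        return iter(self.partitions)


def enumerate_kfolds(n_repetitions: int = 6, n_train: int = 3) -> FoldScheme:
    """All C(n_repetitions, n_train) partitions, lexicographic in the train triple."""
    if not 0 < n_train < n_repetitions:
        raise ValueError("need 0 < n_train < n_repetitions")
    reps = tuple(range(1, n_repetitions + 1))
    parts = []
    for train in itertools.combinations(reps, n_train):
        test = tuple(r for r in reps if r not in train)
        parts.append((train, test))
    return FoldScheme(partitions=tuple(parts))


@dataclass
class ClassifierModel:
    """One-vs-all RBF SVM with feature scaling; argmax of decision values."""

    pipeline: Pipeline
    classes: np.ndarray
    columns: list
    meta: dict = field(default_factory=dict)

    def decision_values(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(self._as_array(X))

    def predict_raw(self, X) -> np.ndarray:
        d = self.decision_values(X)
        if d.ndim == 1:  # two-class edge case
            return self.classes[(d > 0).astype(int)]
        return self.classes[np.argmax(d, axis=1)]

    def _as_array(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.columns].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)


def train_classifier(
    features: pd.DataFrame,
    seed: int = 0,
    columns: list | None = None,
    C: float | None = None,
    gamma: float | None = None,
    grid: dict | None = None,
    cv: int = 3,
) -> ClassifierModel:
    """Fit the movement classifier on a feature table.

    When ``C``/``gamma`` are given they are used directly; otherwise an inner
    ``cv``-fold grid search over ``grid`` (default: the full cost/width
    ranges) picks them.  Raises on a single-class training set.
    """
    if columns is None:
        n_channels = sum(1 for c in features.columns if c.endswith("_mav"))
        columns = feature_columns(n_channels)
    X = features[columns].to_numpy(dtype=float)
    y = features["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")

    def build(Cv, gv):
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("ovr", OneVsRestClassifier(SVC(kernel="rbf", C=Cv, gamma=gv))),
            ]
        )

    if C is not None and gamma is not None:
        model = build(C, gamma)
        model.fit(X, y)
        best = {"C": C, "gamma": gamma}
    else:
        if grid is None:
            grid = DEFAULT_GRID
        search = GridSearchCV(
            build(1.0, "scale"),
            {"ovr__estimator__C": grid["C"], "ovr__estimator__gamma": grid["gamma"]},
            cv=cv,
            n_jobs=1,
        )
        search.fit(X, y)
        model = search.best_estimator_
        best = {
            "C": search.best_params_["ovr__estimator__C"],
            "gamma": search.best_params_["ovr__estimator__gamma"],
        }
    return ClassifierModel(
        pipeline=model,
        classes=model.named_steps["ovr"].classes_,
        columns=columns,
        meta={"seed": seed, "params": best},
    )


def majority_vote(raw: np.ndarray) -> np.ndarray:
    """Mode of the last three raw predictions per window.

    The first windows use the available history; a three-way tie falls back
    to the current window's raw prediction.
    """
    raw = np.asarray(raw)
    out = raw.copy()
    for i in range(len(raw)):
        lo = max(0, i - 2)
        window = raw[lo : i + 1]
        vals, counts = np.unique(window, return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        if len(winners) == 1:
            out[i] = winners[0]
        else:
            out[i] = raw[i]
    return out


def predict_stream(model: ClassifierModel, test_features: pd.DataFrame) -> np.ndarray:
    """Raw per-window argmax predictions post-processed by majority voting."""
    raw = model.predict_raw(test_features)
    return majority_vote(raw)


@dataclass
class EvaluationResult:
    """Per-fold accuracies and confusion matrices for one evaluation."""

    rows: pd.DataFrame  # columns: setting, fold, accuracy (%)
    confusions: dict  # fold index -> (classes, matrix)

    @property
    def mean_accuracy(self) -> float:
        return float(self.rows["accuracy"].mean())


SETTING_BUNDLES = {
    1: ("clean", "clean"),
    2: ("clean", "contaminated"),
    3: ("clean", "contaminated"),  # with removal-flagged channels dropped
    4: ("clean", "tvarma"),
    5: ("tvarma", "tvarma"),
    6: ("clean", "tvk"),
    7: ("tvk", "tvk"),
}


def run_setting(
    setting: int,
    bundles: dict,
    folds,
    removed_channels: tuple = (),
    C: float | None = None,
    gamma: float | None = None,
    grid: dict | None = None,
    all_classes: np.ndarray | None = None,
) -> EvaluationResult:
    """Evaluate one classification setting over the given folds.

    ``bundles`` maps {'clean', 'contaminated', 'tvarma', 'tvk'} to feature
    tables of the same window grid.  ``removed_channels`` (1-based ids) is
    honoured only for setting 3.  Accuracy is the percentage of correctly
    classified test windows after majority voting.
    """
    if setting not in SETTING_BUNDLES:
        raise ValueError("setting must be 1..7")
    train_key, test_key = SETTING_BUNDLES[setting]
    for key in (train_key, test_key):
        if key not in bundles or bundles[key] is None:
            raise ValueError(f"missing feature bundle {key!r} for setting {setting}")
    train_tab, test_tab = bundles[train_key], bundles[test_key]

    n_channels = sum(1 for c in train_tab.columns if c.endswith("_mav"))
    cols = feature_columns(n_channels)
    if setting == 3 and removed_channels:
        drop = {f"ch{c}_" for c in removed_channels}
        cols = [c for c in cols if not any(c.startswith(d) for d in drop)]

    rows = []
    confusions = {}
    for k, (train_reps, test_reps) in enumerate(folds):
        tr = train_tab[train_tab["fold_repetition"].isin(train_reps)]
        te = test_tab[test_tab["fold_repetition"].isin(test_reps)]
        model = train_classifier(tr, columns=cols, C=C, gamma=gamma, grid=grid)
        pred = predict_stream(model, te)
        truth = te["label"].to_numpy()
        acc = 100.0 * float(np.mean(pred == truth))
        rows.append({"setting": setting, "fold": k, "accuracy": acc})
        labels = (
            all_classes
            if all_classes is not None
            else np.unique(np.concatenate([truth, pred]))
        )
        confusions[k] = (labels, confusion_matrix(truth, pred, labels=labels))
    return EvaluationResult(rows=pd.DataFrame(rows), confusions=confusions)


# ---------------------------------------------------------------------------
# three-factor full-factorial ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaModel:
    """Fixed-effects three-way ANOVA with per-group confidence intervals."""

    table: pd.DataFrame  # sum_sq, df, F, PR(>F) per effect + Residual
    effects: dict  # factor -> Series of level effects (mean - grand mean)
    grand_mean: float
    mse: float
    df_resid: float
    data: pd.DataFrame
    factors: tuple
    response: str

    def group_intervals(self, factor: str, alpha: float = 0.05) -> pd.DataFrame:
        """Per-level mean and (1-alpha) interval based on the pooled MSE."""
        g = self.data.groupby(factor)[self.response]
        means, counts = g.mean(), g.count()
        half = sstats.t.ppf(1 - alpha / 2, self.df_resid) * np.sqrt(
            self.mse / counts
        )
        return pd.DataFrame(
            {"mean": means, "lower": means - half, "upper": means + half}
        )

    def significantly_different(
        self, factor: str, level_a, level_b, alpha: float = 0.05
    ) -> bool:
        """Disjoint-interval multiple-comparison test between two levels."""
        ci = self.group_intervals(factor, alpha)
        a, b = ci.loc[level_a], ci.loc[level_b]
        return bool(a["upper"] < b["lower"] or b["upper"] < a["lower"])


def anova3(
    data: pd.DataFrame,
    response: str = "accuracy",
    factors: tuple = ("setting", "contaminant", "case"),
) -> AnovaModel:
    """Full-factorial three-way fixed-effects ANOVA.

    Requires a complete factorial with at least two replicates per cell.
    Sums of squares are sequential (Type I), which for a balanced design
    coincide with the classical factorial decomposition and partition the
    total sum of squares exactly.
    """
    a, b, c = factors
    counts = data.groupby(list(factors), observed=True)[response].count()
    n_cells = (
        data[a].nunique() * data[b].nunique() * data[c].nunique()
    )
    if len(counts) < n_cells:
        raise ValueError("missing cells: design must be a full factorial")
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per cell")
    df = data.rename(columns={response: "_y", a: "_a", b: "_b", c: "_c"})
    model = smf.ols("_y ~ C(_a) * C(_b) * C(_c)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    rename = {
        "C(_a)": a,
        "C(_b)": b,
        "C(_c)": c,
        "C(_a):C(_b)": f"{a}:{b}",
        "C(_a):C(_c)": f"{a}:{c}",
        "C(_b):C(_c)": f"{b}:{c}",
        "C(_a):C(_b):C(_c)": f"{a}:{b}:{c}",
    }
    table = table.rename(index=rename)
    grand = float(data[response].mean())
    effects = {
        f: data.groupby(f, observed=True)[response].mean() - grand for f in factors
    }
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    return AnovaModel(
        table=table,
        effects=effects,
        grand_mean=grand,
        mse=mse,
        df_resid=float(table.loc["Residual", "df"]),
        data=data[[a, b, c, response]].copy(),
        factors=factors,
        response=response,
    )
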