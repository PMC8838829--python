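"""Group statistics, 1-D binary classification, repeated cross-validation,
and score-table aggregation.

Statistics layer: per-feature one-way ANOVA with Tukey HSD post hoc letters
across the three severity groups, and Spearman rank correlation of each
feature against the ordinal severity score (0 normal, 1 moderate, 2 severe).

Classification layer: each feature is used alone (1-D) to separate normal
(label 0, negative) from wooden-breast (labels 1 and 2 pooled, positive)
fillets with one of five classical models (LDA, QDA, decision tree, RBF SVM,
k-nearest neighbors), evaluated by 10-repeated stratified 5-fold
cross-validation with four metrics: overall accuracy (OACC), balanced
accuracy (BACC), F1 and the Matthews correlation coefficient (MCC).

Aggregation layer: marginal means (row / column / block-subtotal / grand)
over score grids, reported to three decimals with half-up rounding, mirroring
how published benchmark tables for this technique summarize their cells.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateFitError, IncompleteGridError

MODEL_NAMES = ("LDA", "QDA", "DT", "SVM", "KNN")
METRIC_NAMES = ("OACC", "BACC", "F1", "MCC")


# --------------------------------------------------------------------------
# binary metrics
# --------------------------------------------------------------------------

def binary_metrics(y_true, y_pred) -> dict[str, float]:
    """OACC, BACC, F1 and MCC for binary labels with 1 = wooden breast.

    All four are computed from the confusion matrix directly; an undefined
    (zero-denominator) MCC or F1 is reported as 0.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + tn + fp + fn
    oacc = (tp + tn) / n if n else 0.0
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    tnr = tn / (tn + fp) if (tn + fp) else 0.0
    bacc = 0.5 * (tpr + tnr)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"OACC": oacc, "BACC": bacc, "F1": f1, "MCC": float(mcc)}


# --------------------------------------------------------------------------
# 1-D classifiers
# --------------------------------------------------------------------------

def _make_model(model_name: str, random_state: int = 0):
    if model_name == "LDA":
        return LinearDiscriminantAnalysis()
    if model_name == "QDA":
        return QuadraticDiscriminantAnalysis()
    if model_name == "DT":
        return DecisionTreeClassifier(max_depth=3, random_state=random_state)
    if model_name == "SVM":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0))
    if model_name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown model name: {model_name!r}")


def fit_predict_1d(model_name: str, train: tuple, test) -> np.ndarray:
    """Fit a named classifier on a single feature and predict test labels."""
    x_train, y_train = train
    x_train = np.asarray(x_train, float).reshape(-1, 1)
    y_train = np.asarray(y_train).astype(int)
    if np.unique(y_train).size < 2:
        raise DegenerateFitError("training split contains a single class")
    model = _make_model(model_name)
    model.fit(x_train, y_train)
    x_test = np.asarray(test, float).reshape(-1, 1)
    return model.predict(x_test)


def repeated_cv(
    values,
    labels,
    model_name: str,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
    level: str = "repeat",
) -> dict[str, float]:
    """Repeated stratified k-fold CV of a 1-D classifier.

    ``level='repeat'`` (default) pools the out-of-fold predictions of each
    repeat, scores them once, and averages the per-repeat scores;
    ``level='fold'`` scores each fold and averages over all folds.
    A fold whose training split lost a class triggers a re-stratification
    with a fresh shuffle rather than proceeding silently.
    """
    x = np.asarray(values, float).ravel()
    y = np.asarray(labels).astype(int)
    if x.size != y.size:
        raise ValueError("values and labels must have equal length")
    if np.unique(y).size < 2:
        raise DegenerateFitError("need both classes for cross-validation")
    if x.size < folds:
        raise ValueError("need at least as many samples as folds")
    if level not in ("repeat", "fold"):
        raise ValueError("level must be 'repeat' or 'fold'")

    rng = np.random.default_rng(seed)
    per_repeat: list[dict[str, float]] = []
    fold_scores: list[dict[str, float]] = []
    for _ in range(repeats):
        for _attempt in range(10):
            rs = int(rng.integers(0, 2**31 - 1))
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            splits = list(skf.split(x.reshape(-1, 1), y))
            if all(np.unique(y[tr]).size == 2 for tr, _ in splits):
                break
        else:
            raise DegenerateFitError("could not stratify folds with both classes")
        y_pred = np.empty_like(y)
        for tr, te in splits:
            pred = fit_predict_1d(model_name, (x[tr], y[tr]), x[te])
            y_pred[te] = pred
            if level == "fold":
                fold_scores.append(binary_metrics(y[te], pred))
        per_repeat.append(binary_metrics(y, y_pred))
    source = per_repeat if level == "repeat" else fold_scores
    return {m: float(np.mean([s[m] for s in source])) for m in METRIC_NAMES}


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

@dataclass
class FeatureGroupStats:
    feature: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    anova_f: float
    anova_p: float
    tukey_letters: dict[str, str]
    tukey_pvalues: dict[tuple[str, str], float]
    spearman_rho: float
    spearman_p: float


@dataclass
class GroupStatsResult:
    per_feature: dict[str, FeatureGroupStats] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for f, s in self.per_feature.items():
            row = {"feature": f, "anova_F": s.anova_f, "anova_p": s.anova_p,
                   "spearman_rho": s.spearman_rho, "spearman_p": s.spearman_p}
            for g in s.group_means:
                row[f"mean_{g}"] = s.group_means[g]
                row[f"sd_{g}"] = s.group_sds[g]
                row[f"letters_{g}"] = s.tukey_letters[g]
            rows.append(row)
        return pd.DataFrame(rows).set_index("feature")


def _compact_letters(groups: list, means: dict, nonsig_pairs: list[tuple]) -> dict:
    """Compact letter display: maximal cliques of the non-significance graph,
    lettered in order of decreasing best group mean."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(nonsig_pairs)
    cliques = sorted(nx.find_cliques(g), key=lambda c: -max(means[m] for m in c))
    letters: dict = {grp: "" for grp in groups}
    for letter, clique in zip("abcdefghij", cliques):
        for grp in clique:
            letters[grp] += letter
    return {grp: "".join(sorted(s)) for grp, s in letters.items()}


def group_statistics(table: pd.DataFrame, alpha: float = 0.05) -> GroupStatsResult:
    """Per-feature ANOVA + Tukey letters + Spearman rho against the label.

    ``table`` is a feature table with a ``label`` column of ordinal scores.
    """
    if "label" not in table.columns:
        raise ValueError("feature table must contain a 'label' column")
    labels = table["label"].to_numpy()
    groups = sorted(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups for ANOVA")
    counts = [np.sum(labels == g) for g in groups]
    if min(counts) < 2:
        raise ValueError("need at least two samples per group")

    result = GroupStatsResult()
    for feat in [c for c in table.columns if c != "label"]:
        x = table[feat].to_numpy(float)
        by_group = [x[labels == g] for g in groups]
        f_stat, p = stats.f_oneway(*by_group)
        tuk = pairwise_tukeyhsd(x, labels, alpha=alpha)
        pair_p: dict[tuple, float] = {}
        nonsig = []
        for (g1, g2), pv, rej in zip(
            [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]],
            tuk.pvalues,
            tuk.reject,
        ):
            pair_p[(g1, g2)] = float(pv)
            if not rej:
                nonsig.append((g1, g2))
        means = {g: float(v.mean()) for g, v in zip(groups, by_group)}
        sds = {g: float(v.std(ddof=1)) for g, v in zip(groups, by_group)}
        rho, rho_p = stats.spearmanr(x, labels)
        result.per_feature[feat] = FeatureGroupStats(
            feature=feat,
            group_means=means,
            group_sds=sds,
            anova_f=float(f_stat),
            anova_p=float(p),
            tukey_letters=_compact_letters(list(groups), means, nonsig),
            tukey_pvalues=pair_p,
            spearman_rho=float(rho),
            spearman_p=float(rho_p),
        )
    return result


# --------------------------------------------------------------------------
# score-grid aggregation
# --------------------------------------------------------------------------

def round3(x: float) -> float:
    """Round to three decimals with half-up ties, as used for reporting.

    The value is first snapped to nine decimals so that exact decimal ties
    computed in binary floating point (e.g. 3.894 / 4 = 0.97349999...) still
    round half-up the way their decimal arithmetic would.
    """
    snapped = Decimal(repr(float(x))).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    return float(snapped.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _check_complete(cells: pd.DataFrame) -> None:
    if cells.isna().any().any():
        missing = [(i, c) for i in cells.index for c in cells.columns if pd.isna(cells.at[i, c])]
        raise IncompleteGridError(f"score grid has missing cells: {missing[:5]}")


@dataclass
class AggregateReport:
    cells: pd.DataFrame
    row_means: pd.Series
    col_means: pd.Series
    block_col_means: pd.DataFrame | None
    grand_mean: float

    def rendered(self) -> pd.DataFrame:
        """Cells plus marginals, all rounded to 3 decimals (half-up)."""
        out = self.cells.copy().map(round3)
        out["MEAN"] = self.row_means.map(round3)
        if self.block_col_means is not None:
            for block, row in self.block_col_means.iterrows():
                out.loc[f"Avg. subtotal ({block})"] = list(row.map(round3)) + [np.nan]
        out.loc["Average Total"] = list(self.col_means.map(round3)) + [round3(self.grand_mean)]
        return out

    def to_text(self) -> str:
        return self.rendered().to_string(float_format=lambda v: f"{v:.3f}")


def aggregate_report(
    cells: pd.DataFrame,
    row_blocks: dict[str, list[str]] | None = None,
) -> AggregateReport:
    """Marginal means over a complete score grid.

    ``row_blocks`` optionally names disjoint groups of rows (e.g. sideview
    image features vs instrumental features) whose per-column subtotal means
    are reported alongside row means, column means and the grand mean.
    """
    cells = cells.astype(float)
    _check_complete(cells)
    row_means = cells.mean(axis=1)
    col_means = cells.mean(axis=0)
    block_means = None
    if row_blocks:
        missing = [r for rows in row_blocks.values() for r in rows if r not in cells.index]
        if missing:
            raise IncompleteGridError(f"block rows absent from grid: {missing}")
        block_means = pd.DataFrame(
            {name: cells.loc[rows].mean(axis=0) for name, rows in row_blocks.items()}
        ).T
    return AggregateReport(
        cells=cells,
        row_means=row_means,
        col_means=col_means,
        block_col_means=block_means,
        grand_mean=float(cells.to_numpy().mean()),
    )


# --------------------------------------------------------------------------
# bundled reference score tables
# --------------------------------------------------------------------------

def _load_data_csv(name: str, **kw) -> pd.DataFrame:
    ref = importlib.resources.files("filletbend").joinpath("data", name)
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#", **kw)


def load_reference_scores_by_classifier() -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Previously reported per-feature x per-classifier mean CV scores,
    with the sideview-vs-instrument row blocks used for subtotals."""
    df = _load_data_csv("reference_scores_by_classifier.csv")
    blocks = {
        name: list(sub["feature"]) for name, sub in df.groupby("block", sort=False)
    }
    cells = df.set_index("feature").drop(columns="block")
    return cells, blocks


def load_reference_svm_scores() -> pd.DataFrame:
    """Previously reported SVM scores per feature and metric."""
    return _load_data_csv("reference_svm_scores_by_metric.csv").set_index("feature")


def load_reference_linespeed_scores() -> pd.DataFrame:
    """Previously reported sideview-feature scores per metric and line speed
    (long format: feature, metric, fpm, score)."""
    return _load_data_csv("reference_linespeed_scores.csv")


def load_reference_group_stats() -> pd.DataFrame:
    """Previously reported per-feature group means/SDs and Spearman rho."""
    return _load_data_csv("reference_feature_group_stats.csv").set_index("feature")
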