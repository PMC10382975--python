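"""Downstream analysis of a protein quantity matrix.

Covers the three standard steps of a two-class biomarker cohort
analysis:

* **Missing-value profiling** — per-protein and per-sample counts of
  absent quantities and the overall missing fraction.
* **Differential expression** — per-protein two-sided Welch t-test on
  log2 abundances with Benjamini-Hochberg adjustment; a protein is
  called up/down when the adjusted p-value is below ``p_threshold``
  (default 0.01) and |log2 fold change| exceeds ``lfc_threshold``
  (default 1, i.e. a two-fold change).
* **Hyperparameter grid search** — a gradient-boosted tree classifier
  (XGBoost) trained for every combination of learning rate (eta),
  subsample fraction, gamma and number of top-ranked protein features,
  repeated over several random internal-validation splits of the
  training set. Models reaching perfect accuracy and AUC on the
  internal validation set are then evaluated on the held-out test set.
  With the default grids (eta 0.2-0.3 step 0.05, subsample 0.8-1 step
  0.05, gamma 0.05-0.2 step 0.05, features 5-20 step 1, 10 iterations)
  the search enumerates 3*5*4*16*10 = 9,600 models.

Feature ranking and per-protein median imputation are computed inside
each training fold only, so no information leaks from validation or
test samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.metrics import accuracy_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ValidationError


@dataclass
class QuantMatrix:
    """Samples × proteins abundance table with a class label per sample.

    ``data`` holds positive abundances on the linear scale with NaN for
    missing cells; ``labels`` is indexed like ``data`` rows.
    """

    data: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.data.index)
        if self.labels.isna().any():
            raise ValidationError("every sample needs a class label")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.data.shape[1]

    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QuantMatrix":
        """First column sample id, second column label, rest proteins;
        empty cells are missing."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] < 2:
            raise FormatError(f"{path}: need a label column plus >= 1 protein column")
        labels = df.iloc[:, 0].astype(str)
        data = df.iloc[:, 1:].astype(float)
        return cls(data=data, labels=labels.rename("label"))

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat([self.labels.rename("label"), self.data], axis=1)
        out.to_csv(path, sep="\t", float_format="%.10g", na_rep="")


@dataclass
class MissingProfile:
    per_protein: pd.Series
    per_sample: pd.Series
    n_missing: int
    fraction: float


def missing_profile(m: QuantMatrix) -> MissingProfile:
    """Count absent cells by protein and by sample."""
    if m.data.empty:
        raise ValidationError("empty quantity matrix")
    mask = m.data.isna()
    return MissingProfile(
        per_protein=mask.sum(axis=0),
        per_sample=mask.sum(axis=1),
        n_missing=int(mask.values.sum()),
        fraction=float(mask.values.mean()),
    )


def _resolve_classes(m: QuantMatrix, class1: str | None, class2: str | None) -> tuple[str, str]:
    classes = m.classes()
    if class1 is None and class2 is None:
        if len(classes) != 2:
            raise ValidationError(
                f"need exactly 2 classes (got {classes}); pass class1/class2 explicitly"
            )
        # fold change reported as second class over first in sorted order
        # (e.g. tumor over benign)
        class1, class2 = classes[1], classes[0]
    if class1 == class2 or class1 not in classes or class2 not in classes:
        raise ValidationError(f"invalid class pair ({class1!r}, {class2!r})")
    return class1, class2


def differential_expression(
    m: QuantMatrix,
    class1: str | None = None,
    class2: str | None = None,
    p_threshold: float = 0.01,
    lfc_threshold: float = 1.0,
    already_log2: bool = False,
) -> pd.DataFrame:
    """Welch t-test differential expression with BH adjustment.

    Returns one row per protein: ``log2_fold_change`` (class1 mean minus
    class2 mean on the log2 scale, pairwise-complete observations),
    ``raw_p``, ``adjusted_p`` and ``status`` in {up, down, ns,
    untested}. Proteins with fewer than two observed values in either
    class are reported ``untested`` and excluded from the BH family.
    """
    class1, class2 = _resolve_classes(m, class1, class2)
    values = m.data if already_log2 else np.log2(m.data)
    g1 = values[m.labels == class1]
    g2 = values[m.labels == class2]
    rows = []
    for prot in values.columns:
        x1 = g1[prot].dropna().to_numpy()
        x2 = g2[prot].dropna().to_numpy()
        if len(x1) < 2 or len(x2) < 2:
            rows.append((prot, np.nan, np.nan, False))
            continue
        lfc = float(x1.mean() - x2.mean())
        if np.ptp(x1) == 0 and np.ptp(x2) == 0 and x1.mean() == x2.mean():
            p = 1.0  # identical constant groups: no evidence of change
        else:
            p = float(stats.ttest_ind(x1, x2, equal_var=False).pvalue)
        rows.append((prot, lfc, p, True))
    table = pd.DataFrame(
        rows, columns=["protein", "log2_fold_change", "raw_p", "tested"]
    ).set_index("protein")
    tested = table["tested"]
    adjusted = pd.Series(np.nan, index=table.index)
    if tested.any():
        adjusted[tested] = multipletests(
            table.loc[tested, "raw_p"].to_numpy(), method="fdr_bh"
        )[1]
    table["adjusted_p"] = adjusted
    status = pd.Series("ns", index=table.index)
    sig = tested & (table["adjusted_p"] < p_threshold)
    status[sig & (table["log2_fold_change"] > lfc_threshold)] = "up"
    status[sig & (table["log2_fold_change"] < -lfc_threshold)] = "down"
    status[~tested] = "untested"
    table["status"] = status
    return table.drop(columns="tested")


def rank_features(
    m: QuantMatrix,
    class1: str | None = None,
    class2: str | None = None,
    method: str = "univariate_auc",
    seed: int = 0,
    already_log2: bool = False,
) -> list[str]:
    """Order proteins by discriminative strength between two classes.

    ``univariate_auc`` ranks by |AUC - 0.5| of each protein alone
    (observed values only); ``model_importance`` ranks by the gain
    importance of a single gradient-boosted model on the median-imputed
    matrix. Ties break on protein id, so the order is deterministic.
    """
    class1, class2 = _resolve_classes(m, class1, class2)
    mask = m.labels.isin([class1, class2])
    y = (m.labels[mask] == class1).astype(int)
    data = m.data[mask]
    if method == "univariate_auc":
        scores = {}
        for prot in data.columns:
            obs = data[prot].dropna()
            yo = y.loc[obs.index]
            if yo.nunique() < 2 or len(obs) == 0:
                scores[prot] = 0.0
                continue
            scores[prot] = abs(roc_auc_score(yo, obs) - 0.5)
        return sorted(data.columns, key=lambda p: (-scores[p], p))
    if method == "model_importance":
        X = data.fillna(data.median())
        booster = xgb.XGBClassifier(
            n_estimators=50,
            max_depth=3,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
        booster.fit(X.to_numpy(), y.to_numpy())
        gain = booster.feature_importances_
        scores = dict(zip(data.columns, gain))
        return sorted(data.columns, key=lambda p: (-scores[p], p))
    raise ValueError(f"unknown ranking method {method!r}")


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grids and internal-validation scheme.

    Defaults enumerate eta 0.2-0.3 step 0.05 (3 values), subsample
    0.8-1 step 0.05 (5), gamma 0.05-0.2 step 0.05 (4), number of
    features 5-20 step 1 (16) over 10 internal-validation iterations:
    9,600 models in total. A model is *selected* when its internal
    validation accuracy and AUC both equal ``selection_acc`` /
    ``selection_auc`` (1.0 by default).
    """

    eta_values: tuple[float, ...] = (0.2, 0.25, 0.3)
    subsample_values: tuple[float, ...] = (0.8, 0.85, 0.9, 0.95, 1.0)
    gamma_values: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2)
    n_features_values: tuple[int, ...] = tuple(range(5, 21))
    n_validation_iterations: int = 10
    validation_size: int = 40
    selection_acc: float = 1.0
    selection_auc: float = 1.0
    n_boost_rounds: int = 30
    max_depth: int = 6
    ranking_method: str = "univariate_auc"

    def __post_init__(self) -> None:
        for name in ("eta_values", "subsample_values", "gamma_values", "n_features_values"):
            if not getattr(self, name):
                raise ValidationError(f"{name} must be non-empty")
        if self.n_validation_iterations < 1 or self.validation_size < 1:
            raise ValidationError("iterations and validation_size must be >= 1")

    @property
    def n_models(self) -> int:
        return (
            len(self.eta_values)
            * len(self.subsample_values)
            * len(self.gamma_values)
            * len(self.n_features_values)
            * self.n_validation_iterations
        )


@dataclass
class GridSearchResult:
    results: pd.DataFrame
    n_models: int
    selected: pd.DataFrame = field(default_factory=pd.DataFrame)
    train_samples: list[str] = field(default_factory=list)
    test_samples: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_models": self.n_models,
            "n_selected": int(len(self.selected)),
            "mean_validation_acc": float(self.results["val_acc"].mean()),
            "mean_validation_auc": float(self.results["val_auc"].mean()),
            "mean_test_acc_selected": (
                float(self.selected["test_acc"].mean()) if len(self.selected) else float("nan")
            ),
            "mean_test_auc_selected": (
                float(self.selected["test_auc"].mean()) if len(self.selected) else float("nan")
            ),
        }


def _split_indices(
    rng: np.random.Generator, index: pd.Index, n_test: int
) -> tuple[pd.Index, pd.Index]:
    order = rng.permutation(len(index))
    test = index[np.sort(order[:n_test])]
    train = index[np.sort(order[n_test:])]
    return train, test


def _safe_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    if len(np.unique(y_true)) < 2:
        return float("nan")
    return float(roc_auc_score(y_true, y_score))


def grid_search(
    m: QuantMatrix,
    spec: GridSpec = GridSpec(),
    test_size: int = 41,
    seed: int = 0,
    class1: str | None = None,
    class2: str | None = None,
    already_log2: bool = False,
) -> GridSearchResult:
    """Enumerate and evaluate the full hyperparameter grid.

    The cohort is split once into training and held-out test sets
    (``test_size`` samples). For each of ``spec.n_validation_iterations``
    iterations an internal validation set of ``spec.validation_size``
    samples is drawn from the training set; features are ranked and
    medians for imputation computed on the remaining fit samples only.
    One model is trained per (eta, subsample, gamma, n_features)
    combination and iteration; accuracy and AUC are recorded on the
    internal validation set, and models meeting the selection rule are
    additionally scored on the test set. Fixing ``seed`` makes the whole
    procedure (splits, rankings, model metrics) reproducible.
    """
    class1, class2 = _resolve_classes(m, class1, class2)
    mask = m.labels.isin([class1, class2])
    data = m.data[mask]
    if not already_log2:
        data = np.log2(data)
    y_all = (m.labels[mask] == class1).astype(int)
    n = len(data)
    if test_size >= n or test_size < 1:
        raise ValidationError(f"test_size {test_size} infeasible for {n} samples")
    if spec.validation_size >= n - test_size:
        raise ValidationError(
            f"validation_size {spec.validation_size} must be below the "
            f"training-set size {n - test_size}"
        )
    max_feat = max(spec.n_features_values)
    if max_feat > data.shape[1]:
        raise ValidationError(
            f"grid requests {max_feat} features but matrix has {data.shape[1]} proteins"
        )

    rng = np.random.default_rng(seed)
    train_idx, test_idx = _split_indices(rng, data.index, test_size)
    y_test = y_all.loc[test_idx].to_numpy()

    records: list[dict] = []
    for iteration in range(spec.n_validation_iterations):
        val_order = rng.permutation(len(train_idx))
        val_idx = train_idx[np.sort(val_order[: spec.validation_size])]
        fit_idx = train_idx[np.sort(val_order[spec.validation_size :])]
        fit_data = data.loc[fit_idx]
        fit_qm = QuantMatrix(
            data=fit_data, labels=m.labels.loc[fit_idx]
        )
        ranking = rank_features(
            fit_qm, class1=class1, class2=class2,
            method=spec.ranking_method, seed=seed, already_log2=True,
        )
        medians = fit_data.median()
        y_fit = y_all.loc[fit_idx].to_numpy()
        y_val = y_all.loc[val_idx].to_numpy()
        for n_features in spec.n_features_values:
            feats = ranking[:n_features]
            X_fit = fit_data[feats].fillna(medians[feats]).to_numpy()
            X_val = data.loc[val_idx, feats].fillna(medians[feats]).to_numpy()
            X_test = data.loc[test_idx, feats].fillna(medians[feats]).to_numpy()
            dfit = xgb.DMatrix(X_fit, label=y_fit)
            dval = xgb.DMatrix(X_val)
            dtest = xgb.DMatrix(X_test)
            for eta in spec.eta_values:
                for subsample in spec.subsample_values:
                    for gamma in spec.gamma_values:
                        params = {
                            "objective": "binary:logistic",
                            "eta": eta,
                            "subsample": subsample,
                            "gamma": gamma,
                            "max_depth": spec.max_depth,
                            # exact greedy splits: midpoint thresholds
                            # behave sanely on small cohorts
                            "tree_method": "exact",
                            "nthread": 1,
                            "seed": seed,
                            "verbosity": 0,
                        }
                        booster = xgb.train(
                            params, dfit, num_boost_round=spec.n_boost_rounds
                        )
                        val_score = booster.predict(dval)
                        val_pred = (val_score >= 0.5).astype(int)
                        val_acc = float(accuracy_score(y_val, val_pred))
                        val_auc = _safe_auc(y_val, val_score)
                        selected = (
                            val_acc >= spec.selection_acc
                            and val_auc >= spec.selection_auc
                        )
                        rec = {
                            "iteration": iteration,
                            "eta": eta,
                            "subsample": subsample,
                            "gamma": gamma,
                            "n_features": n_features,
                            "val_acc": val_acc,
                            "val_auc": val_auc,
                            "selected": selected,
                            "test_acc": np.nan,
                            "test_auc": np.nan,
                        }
                        if selected:
                            test_score = booster.predict(dtest)
                            test_pred = (test_score >= 0.5).astype(int)
                            rec["test_acc"] = float(accuracy_score(y_test, test_pred))
                            rec["test_auc"] = _safe_auc(y_test, test_score)
                        records.append(rec)
    results = pd.DataFrame(records)
    assert len(results) == spec.n_models
    return GridSearchResult(
        results=results,
        n_models=len(results),
        selected=results[results["selected"]].reset_index(drop=True),
        train_samples=list(train_idx),
        test_samples=list(test_idx),
    )
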