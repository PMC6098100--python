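"""The meta-classifier layer.

The screening model scores a (species pair, ANN topology) record by a linear
discriminant over the 24 entropy features:

    S = sum_k a_k * Sh_ki  +  sum_k b_k * Sh_kj
      + sum_k c_k * dSh_k  +  sum_k d_k * annSh_k  +  e0

and predicts "this topology will classify this pair correctly" iff S >= 0.
:func:`reference_linear_model` freezes the published five-feature coefficient
set; :func:`fit_lda` fits the same form from a meta-table by linear
discriminant analysis; :func:`classifier_menu` provides the nonlinear
alternatives (Bayesian, tree, ensemble, perceptron and deep fully-connected
families) behind one fit/predict_score contract.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .dataset import FEATURES_ANN, FEATURES_BSI, FEATURES_D, FEATURES_I, FEATURES_J, FEATURES_MT
from .entropy import K_MAX_DEFAULT

__all__ = [
    "LinearNetNetModel",
    "reference_linear_model",
    "fit_lda",
    "MenuClassifier",
    "classifier_menu",
]

_NK = K_MAX_DEFAULT + 1


@dataclass
class LinearNetNetModel:
    """25-parameter linear screening model in the layout above.

    ``coef_i``/``coef_j``/``coef_d``/``coef_ann`` each hold six coefficients
    (k = 0..5); ``intercept`` is the free term e0.  ``fitted_stats`` carries
    n, chi2 (Bartlett's approximation from Wilks' lambda) and p when the
    model was fitted, or the published values for the frozen reference.
    """

    coef_i: np.ndarray
    coef_j: np.ndarray
    coef_d: np.ndarray
    coef_ann: np.ndarray
    intercept: float
    fitted_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("coef_i", "coef_j", "coef_d", "coef_ann"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (_NK,):
                raise ValueError(f"{name} must have {_NK} entries")
            setattr(self, name, arr)
        self.intercept = float(self.intercept)

    @property
    def coefficients(self) -> pd.Series:
        """All 24 slope coefficients, indexed by feature name."""
        return pd.Series(
            np.concatenate([self.coef_i, self.coef_j, self.coef_d, self.coef_ann]),
            index=FEATURES_MT,
        )

    def score(self, record: Union[pd.DataFrame, pd.Series, dict]) -> Union[float, np.ndarray]:
        """Discriminant score S for one record or a whole table."""
        if isinstance(record, (pd.Series, dict)):
            rec = pd.Series(record)
            missing = [f for f in FEATURES_MT if f not in rec.index]
            if missing:
                raise KeyError(f"record is missing features: {missing}")
            x = rec[FEATURES_MT].to_numpy(dtype=float)
            return float(x @ self.coefficients.to_numpy() + self.intercept)
        missing = [f for f in FEATURES_MT if f not in record.columns]
        if missing:
            raise KeyError(f"table is missing features: {missing}")
        x = record[FEATURES_MT].to_numpy(dtype=float)
        return x @ self.coefficients.to_numpy() + self.intercept

    def predict(self, record) -> Union[int, np.ndarray]:
        """Class decision at the discriminant boundary S >= 0."""
        s = self.score(record)
        if np.isscalar(s):
            return int(s >= 0)
        return (s >= 0).astype(int)

    def predict_score(self, features: pd.DataFrame) -> np.ndarray:
        """Monotone score for AUROC-style ranking (the raw discriminant S)."""
        return np.asarray(self.score(features), dtype=float)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        names = (
            [f"a_{k}" for k in range(_NK)]
            + [f"b_{k}" for k in range(_NK)]
            + [f"c_{k}" for k in range(_NK)]
            + [f"d_{k}" for k in range(_NK)]
        )
        values = np.concatenate([self.coef_i, self.coef_j, self.coef_d, self.coef_ann])
        out = {name: float(v) for name, v in zip(names, values)}
        out["e0"] = self.intercept
        if self.fitted_stats:
            out["fitted_stats"] = {k: v for k, v in self.fitted_stats.items()}
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "LinearNetNetModel":
        return cls(
            coef_i=[d[f"a_{k}"] for k in range(_NK)],
            coef_j=[d[f"b_{k}"] for k in range(_NK)],
            coef_d=[d[f"c_{k}"] for k in range(_NK)],
            coef_ann=[d[f"d_{k}"] for k in range(_NK)],
            intercept=d["e0"],
            fitted_stats=d.get("fitted_stats", {}),
        )

    @classmethod
    def load(cls, path) -> "LinearNetNetModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def reference_linear_model() -> LinearNetNetModel:
    """The published five-feature linear screening model, frozen.

    Nonzero terms: -42.38*Sh_0i + 15.69*Sh_3i - 44.95*Sh_0j + 13.79*Sh_3j
    - 0.014*annSh_3 - 0.8263.  The difference features dSh_k carry no weight.
    Fitted statistics are carried verbatim as published (n = 235,540,
    chi2 = 56,326.2, p < 0.001); they are an artifact of the original fit,
    not recomputed here.
    """
    coef_i = np.zeros(_NK)
    coef_j = np.zeros(_NK)
    coef_ann = np.zeros(_NK)
    coef_i[0], coef_i[3] = -42.38, 15.69
    coef_j[0], coef_j[3] = -44.95, 13.79
    coef_ann[3] = -0.014
    return LinearNetNetModel(
        coef_i=coef_i,
        coef_j=coef_j,
        coef_d=np.zeros(_NK),
        coef_ann=coef_ann,
        intercept=-0.8263,
        fitted_stats={"n": 235_540, "chi2": 56_326.2, "p": "<0.001"},
    )


# ---------------------------------------------------------------------------
# LDA fitting
# ---------------------------------------------------------------------------

def _wilks_stats(x: np.ndarray, y: np.ndarray) -> dict:
    """Wilks' lambda and Bartlett's chi-square approximation for a 2-class LDA.

    Exactly collinear features (the dSh_k columns are Sh_ki - Sh_kj by
    construction) make the raw scatter matrices singular, so the statistic is
    computed on the full-rank principal subspace of the total scatter; the
    effective dimension enters Bartlett's correction and the degrees of
    freedom.
    """
    n = x.shape[0]
    g = 2
    centered = x - x.mean(axis=0)
    total = centered.T @ centered
    evals, evecs = np.linalg.eigh(total)
    keep = evals > max(evals.max(), 1.0) * 1e-10
    basis = evecs[:, keep]
    z = centered @ basis
    p_eff = z.shape[1]
    within = np.zeros((p_eff, p_eff))
    for cls in np.unique(y):
        zc = z[y == cls]
        within += (zc - zc.mean(axis=0)).T @ (zc - zc.mean(axis=0))
    sign_w, logdet_w = np.linalg.slogdet(within)
    sign_t, logdet_t = np.linalg.slogdet(z.T @ z)
    if sign_w <= 0 or sign_t <= 0:
        return {"n": int(n), "wilks_lambda": np.nan, "chi2": np.nan, "p": np.nan}
    log_lambda = logdet_w - logdet_t
    chi2 = -(n - 1 - (p_eff + g) / 2.0) * log_lambda
    df = p_eff * (g - 1)
    return {
        "n": int(n),
        "wilks_lambda": float(np.exp(log_lambda)),
        "chi2": float(chi2),
        "df": df,
        "p": float(stats.chi2.sf(chi2, df)),
    }


def fit_lda(
    train: pd.DataFrame,
    features: Sequence[str] = tuple(FEATURES_MT),
    label: str = "meta_label",
    priors: Optional[Sequence[float]] = (0.5, 0.5),
) -> LinearNetNetModel:
    """Fit the linear screening model by two-class LDA on a meta-table.

    Equal priors by default (pass ``priors=None`` for empirical ones).  If
    the pooled within-class covariance is singular (e.g. duplicated feature
    columns), the fit falls back to a ridge-regularized (shrinkage) solver
    with a warning.  The returned coefficients are mapped into the standard
    24 + 1 layout; features outside ``features`` get coefficient zero.
    """
    features = list(features)
    missing = [f for f in features if f not in train.columns]
    if missing:
        raise ValueError(f"training table is missing features: {missing}")
    x = train[features].to_numpy(dtype=float)
    y = train[label].to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, found {classes}")
    if len(y) < len(features) + 2:
        raise ValueError("too few rows to fit the discriminant")

    within = np.zeros((x.shape[1], x.shape[1]))
    for cls in classes:
        xc = x[y == cls]
        within += (xc - xc.mean(axis=0)).T @ (xc - xc.mean(axis=0))
    if np.linalg.matrix_rank(within) < x.shape[1]:
        warnings.warn(
            "singular within-class covariance; refitting with ridge shrinkage",
            stacklevel=2,
        )
        lda = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=1e-3, priors=priors
        )
    else:
        lda = LinearDiscriminantAnalysis(solver="svd", priors=priors)
    lda.fit(x, y)

    coef = pd.Series(0.0, index=FEATURES_MT)
    coef[features] = lda.coef_[0]
    model = LinearNetNetModel(
        coef_i=coef[FEATURES_I].to_numpy(),
        coef_j=coef[FEATURES_J].to_numpy(),
        coef_d=coef[FEATURES_D].to_numpy(),
        coef_ann=coef[FEATURES_ANN].to_numpy(),
        intercept=float(lda.intercept_[0]),
        fitted_stats=_wilks_stats(x, y),
    )
    return model


# ---------------------------------------------------------------------------
# Classifier menu
# ---------------------------------------------------------------------------

class MenuClassifier:
    """A named meta-classifier conforming to fit/predict_score."""

    def __init__(self, name: str, estimator):
        self.name = name
        self._est = estimator
        self._columns: Optional[list[str]] = None

    def fit(self, features: pd.DataFrame, labels: np.ndarray) -> "MenuClassifier":
        self._columns = list(features.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._est.fit(features.to_numpy(), np.asarray(labels))
        return self

    def predict_score(self, features: pd.DataFrame) -> np.ndarray:
        if self._columns is not None:
            features = features[self._columns]
        x = features.to_numpy()
        if hasattr(self._est, "predict_proba"):
            return self._est.predict_proba(x)[:, 1]
        return self._est.decision_function(x)

    def predict(self, features: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_score(features) >= threshold).astype(int)


def classifier_menu(
    seed: int = 0,
    deep_n: int = 200,
    deep_epochs: int = 50,
) -> dict[str, Callable[[], MenuClassifier]]:
    """Builders for the meta-classifier families, keyed by short name.

    Covers: linear discriminant baseline, logistic regression, naive Bayes,
    decision tree (decision-table surrogate), random forest (500 trees),
    bagging over trees and over perceptrons, boosting, multilayer perceptrons
    with one and two hidden layers, and a deep fully-connected net with the
    n - 2n - n hidden shape (default n = 200, tanh, Adam).  Hyperparameters
    follow the original study's settings where an sklearn equivalent exists;
    the deep net's training budget defaults to 50 epochs for desk runs and
    is configurable.
    """
    def mlp(hidden, max_iter=500, **kw):
        return MLPClassifier(
            hidden_layer_sizes=hidden,
            max_iter=max_iter,
            random_state=seed,
            **kw,
        )

    builders: dict[str, Callable[[], MenuClassifier]] = {
        "lda": lambda: MenuClassifier("lda", LinearDiscriminantAnalysis()),
        "logistic": lambda: MenuClassifier(
            "logistic", LogisticRegression(max_iter=1000, random_state=seed)
        ),
        "naive_bayes": lambda: MenuClassifier("naive_bayes", GaussianNB()),
        "decision_tree": lambda: MenuClassifier(
            "decision_tree", DecisionTreeClassifier(random_state=seed)
        ),
        "random_forest": lambda: MenuClassifier(
            "random_forest",
            RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1),
        ),
        "bagging_tree": lambda: MenuClassifier(
            "bagging_tree",
            BaggingClassifier(
                DecisionTreeClassifier(random_state=seed),
                n_estimators=10,
                random_state=seed,
            ),
        ),
        "bagging_mlp": lambda: MenuClassifier(
            "bagging_mlp",
            BaggingClassifier(
                mlp((13,), max_iter=200), n_estimators=10, random_state=seed
            ),
        ),
        "adaboost": lambda: MenuClassifier(
            "adaboost", AdaBoostClassifier(n_estimators=10, random_state=seed)
        ),
        "mlp_1h": lambda: MenuClassifier("mlp_1h", mlp((13,))),
        "mlp_2h": lambda: MenuClassifier("mlp_2h", mlp((18, 9))),
        "deep_fc": lambda: MenuClassifier(
            "deep_fc",
            mlp(
                (deep_n, deep_n * 2, deep_n),
                max_iter=deep_epochs,
                activation="tanh",
                solver="adam",
                batch_size="auto",
                alpha=1e-3,
            ),
        ),
    }
    return builders


def build_classifier(name: str, **menu_kwargs) -> MenuClassifier:
    """Instantiate one menu classifier by name."""
    menu = classifier_menu(**menu_kwargs)
    if name not in menu:
        raise KeyError(f"unknown classifier {name!r}; choose from {sorted(menu)}")
    return menu[name]()
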