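"""Occurrence models: five algorithms behind one fit/predict/response-curve contract.

Algorithms
----------
GLM     binomial regression with linear + quadratic terms per covariate
        (statsmodels).
GAM     binomial additive model with penalized B-spline smooths per covariate
        (statsmodels GLMGam).
MAXENT  the penalised-regression form of maximum entropy: L1-regularised
        logistic regression of presences against background, with background
        rows reweighted so total background weight equals total presence
        weight, on linear + quadratic + hinge features.
BRT     gradient-boosted classification trees (scikit-learn), trees chosen by
        an internal holdout.
RF      random forest (scikit-learn); probability = fraction of votes.

Covariates are z-scored inside GLM/GAM/MAXENT; the tree methods see raw
values. Every prediction is clamped to [0, 1] by construction of the link or
vote fraction.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from statsmodels.gam.api import BSplines, GLMGam

from .errors import DegenerateFitError, SchemaError
from .occurrence import covariate_columns

ALGORITHM_IDS = ("GLM", "GAM", "MAXENT", "BRT", "RF")

_SERIAL_FORMAT_VERSION = 1

#: Documented hyperparameter defaults, overridable per AlgorithmSpec.
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "GLM": {},
    "GAM": {"df": 6, "degree": 3, "alpha": 0.01},
    "MAXENT": {"C": 1.0, "n_hinge": 6, "use_quadratic": False, "max_iter": 5000},
    "BRT": {
        "max_depth": 3,
        "learning_rate": 0.01,
        "n_estimators": 1000,
        "validation_fraction": 0.2,
        "n_iter_no_change": 20,
    },
    "RF": {"n_estimators": 500},
}


@dataclass(frozen=True)
class AlgorithmSpec:
    """Which algorithm to fit, with hyperparameters and a seed for stochastic fitters."""

    id: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.id not in ALGORITHM_IDS:
            raise SchemaError(f"unknown algorithm {self.id!r}; expected {ALGORITHM_IDS}")

    def resolved_hyperparameters(self) -> dict[str, Any]:
        out = dict(DEFAULT_HYPERPARAMETERS[self.id])
        out.update(self.hyperparameters)
        return out


@dataclass
class ResponseCurve:
    """Partial response: probability along one covariate, others held fixed."""

    variable: str
    grid: np.ndarray
    probability: np.ndarray
    reference_values: dict[str, float]

    def half_max_crossing(self) -> float | None:
        """Covariate value where the curve first falls to half its maximum,
        searching rightward from the maximum (the declining limb). Linear
        interpolation between grid points; None if the curve never drops
        that far."""
        p = self.probability
        i0 = int(np.argmax(p))
        half = p[i0] / 2.0
        for i in range(i0 + 1, len(p)):
            if p[i] <= half:
                x0, x1 = self.grid[i - 1], self.grid[i]
                p0, p1 = p[i - 1], p[i]
                if p1 == p0:
                    return float(x1)
                return float(x0 + (half - p0) * (x1 - x0) / (p1 - p0))
        return None


# -- internal fitters ---------------------------------------------------------


class _Standardizer:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)  # constant columns map to 0

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


class _GlmFitter:
    """Binomial GLM with linear + quadratic terms on z-scored covariates."""

    def __init__(self, hp: dict, seed: int):
        del hp, seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.std = _Standardizer(X)
        z = self.std(X)
        design = sm.add_constant(np.column_stack([z, z**2]), has_constant="add")
        self.result = sm.GLM(y, design, family=sm.families.Binomial()).fit()

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = self.std(X)
        design = sm.add_constant(np.column_stack([z, z**2]), has_constant="add")
        return np.asarray(self.result.predict(design))

    def quadratic_coefficients(self) -> np.ndarray:
        """Coefficients of the squared terms, in covariate order."""
        k = (len(self.result.params) - 1) // 2
        return np.asarray(self.result.params[1 + k:])


class _GamFitter:
    """Binomial additive model, penalized B-spline smooth per covariate.

    Covariates are z-scored; prediction clips inputs to the training range
    (the spline basis is undefined beyond its knots, so extrapolation is
    constant at the edge value).
    """

    def __init__(self, hp: dict, seed: int):
        self.df = int(hp["df"])
        self.degree = int(hp["degree"])
        self.alpha = float(hp["alpha"])

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.std = _Standardizer(X)
        z = self.std(X)
        # smooth only the non-constant covariates
        self.smooth_idx = [j for j in range(z.shape[1]) if np.ptp(z[:, j]) > 0]
        self.zmin = z.min(axis=0)
        self.zmax = z.max(axis=0)
        if not self.smooth_idx:
            design = np.ones((len(y), 1))
            self.result = sm.GLM(y, design, family=sm.families.Binomial()).fit()
            self.basis = None
            return
        zs = z[:, self.smooth_idx]
        k = zs.shape[1]
        self.basis = BSplines(zs, df=[self.df] * k, degree=[self.degree] * k)
        model = GLMGam(
            y, smoother=self.basis, alpha=[self.alpha] * k,
            family=sm.families.Binomial(),
        )
        self.result = model.fit()

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = np.clip(self.std(X), self.zmin, self.zmax)
        if self.basis is None:
            return np.asarray(self.result.predict(np.ones((len(z), 1))))
        return np.asarray(self.result.predict(exog_smooth=z[:, self.smooth_idx]))


class _MaxentFitter:
    """Presence/background maximum entropy as L1-penalised logistic regression.

    Features per z-scored covariate: linear plus forward/reverse hinges at
    `n_hinge` interior quantile knots (a quadratic term can be enabled via
    `use_quadratic`; hinge features already provide smooth curvature and an
    unconstrained quadratic degrades threshold-shaped responses). Background
    (zero-response) rows are reweighted so their total weight equals the
    total presence weight, matching the presence/background contrast of
    maximum-entropy density estimation.
    """

    def __init__(self, hp: dict, seed: int):
        self.C = float(hp["C"])
        self.n_hinge = int(hp["n_hinge"])
        self.use_quadratic = bool(hp["use_quadratic"])
        self.max_iter = int(hp["max_iter"])
        self.seed = seed

    def _features(self, z: np.ndarray) -> np.ndarray:
        cols = [z, z**2] if self.use_quadratic else [z]
        for j in range(z.shape[1]):
            for knot in self.knots[j]:
                cols.append(np.maximum(0.0, z[:, j] - knot)[:, None])
                cols.append(np.maximum(0.0, knot - z[:, j])[:, None])
        return np.column_stack(cols)

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.std = _Standardizer(X)
        z = self.std(X)
        qs = np.linspace(0, 1, self.n_hinge + 2)[1:-1]
        self.knots = [np.quantile(z[:, j], qs) for j in range(z.shape[1])]
        F = self._features(z)
        n1 = int(y.sum())
        n0 = len(y) - n1
        w = np.where(y == 1, 1.0, n1 / n0)
        self.clf = LogisticRegression(
            l1_ratio=1.0, C=self.C, solver="liblinear",
            max_iter=self.max_iter, random_state=self.seed,
        )
        self.clf.fit(F, y, sample_weight=w)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(self._features(self.std(X)))[:, 1]


class _SklearnProbaFitter:
    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.clf.predict_proba(X)
        if proba.shape[1] == 1:  # degenerate: single class seen (guarded earlier)
            return np.full(len(X), float(self.clf.classes_[0]))
        return proba[:, 1]


class _BrtFitter(_SklearnProbaFitter):
    def __init__(self, hp: dict, seed: int):
        self.clf = GradientBoostingClassifier(
            max_depth=hp["max_depth"],
            learning_rate=hp["learning_rate"],
            n_estimators=hp["n_estimators"],
            validation_fraction=hp["validation_fraction"],
            n_iter_no_change=hp["n_iter_no_change"],
            random_state=seed,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.clf.fit(X, y)


class _RfFitter(_SklearnProbaFitter):
    def __init__(self, hp: dict, seed: int):
        self.clf = RandomForestClassifier(
            n_estimators=hp["n_estimators"], random_state=seed, n_jobs=1
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.clf.fit(X, y)


_FITTERS = {
    "GLM": _GlmFitter,
    "GAM": _GamFitter,
    "MAXENT": _MaxentFitter,
    "BRT": _BrtFitter,
    "RF": _RfFitter,
}


@dataclass
class SdmModel:
    """A fitted occurrence model mapping covariate vectors to probability."""

    spec: AlgorithmSpec
    covariates: list[str]
    training_means: dict[str, float]
    training_ranges: dict[str, tuple[float, float]]
    n_presence: int
    n_absence: int
    _fitter: Any = field(repr=False, default=None)

    format_version: int = _SERIAL_FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        """Serialise the fitted model (self-describing versioned archive)."""
        payload = {
            "format_version": self.format_version,
            "algorithm": self.spec.id,
            "model": self,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SdmModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != _SERIAL_FORMAT_VERSION:
            raise SchemaError(
                f"unsupported model format version {payload.get('format_version')!r}"
            )
        return payload["model"]


def fit(spec: AlgorithmSpec, table: pd.DataFrame) -> SdmModel:
    """Fit one algorithm to a feature table (response column + covariates)."""
    if "response" not in table.columns:
        raise SchemaError("feature table has no 'response' column")
    covs = covariate_columns(table)
    if not covs:
        raise SchemaError("feature table has no covariate columns")
    X = table[covs].to_numpy(dtype=float)
    y = table["response"].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise SchemaError("covariates contain non-finite values")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise SchemaError("response must be binary 0/1")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateFitError(
            f"single-class response (presences={n1}, zeros={n0})"
        )
    fitter = _FITTERS[spec.id](spec.resolved_hyperparameters(), spec.seed)
    fitter.fit(X, y)
    return SdmModel(
        spec=spec,
        covariates=covs,
        training_means={c: float(m) for c, m in zip(covs, X.mean(axis=0))},
        training_ranges={
            c: (float(lo), float(hi))
            for c, lo, hi in zip(covs, X.min(axis=0), X.max(axis=0))
        },
        n_presence=n1,
        n_absence=n0,
        _fitter=fitter,
    )


def predict(model: SdmModel, covariates: pd.DataFrame) -> np.ndarray:
    """Probability of occurrence per row; always in [0, 1]."""
    missing = [c for c in model.covariates if c not in covariates.columns]
    if missing:
        raise SchemaError(f"prediction input missing covariate(s): {missing}")
    X = covariates[model.covariates].to_numpy(dtype=float)
    p = np.asarray(model._fitter.predict(X), dtype=float)
    return np.clip(p, 0.0, 1.0)


def response_curve(model: SdmModel, variable: str, n_grid: int = 100) -> ResponseCurve:
    """Partial response along one covariate, the others held at training means."""
    if variable not in model.covariates:
        raise SchemaError(
            f"unknown variable {variable!r}; model covariates are {model.covariates}"
        )
    lo, hi = model.training_ranges[variable]
    grid = np.linspace(lo, hi, n_grid)
    frame = pd.DataFrame(
        {c: np.full(n_grid, model.training_means[c]) for c in model.covariates}
    )
    frame[variable] = grid
    prob = predict(model, frame)
    refs = {c: model.training_means[c] for c in model.covariates if c != variable}
    return ResponseCurve(variable, grid, prob, refs)
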