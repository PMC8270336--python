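"""Second-order response-surface model: OLS fit, ANOVA, optimum location.

The model is the full 15-term quadratic in the four coded factors

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2

fit by ordinary least squares on coded (-1..+1) variables.  The ANOVA uses
partial (Type-III) sums of squares obtained by reduced-model refits, and
splits the residual into lack-of-fit and pure error using replicated runs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import stats

from .design import DesignTable, FactorSpec, code_point, decode_point
from .errors import InvalidBoundsError, SingularDesignError

__all__ = [
    "QuadraticModel",
    "AnovaRow",
    "AnovaTable",
    "OptimumResult",
    "fit_quadratic",
    "predict",
    "anova",
    "r_squared",
    "optimize_on_cube",
    "absolute_error",
]

#: Interaction index pairs in fixed coefficient order AB, AC, AD, BC, BD, CD.
INTERACTION_PAIRS: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations(range(4), 2)
)

_LETTERS = "ABCD"


def term_labels() -> list[str]:
    """Labels of the 15 columns in model-matrix order."""
    lin = list(_LETTERS)
    inter = [f"{_LETTERS[i]}{_LETTERS[j]}" for i, j in INTERACTION_PAIRS]
    quad = [f"{c}^2" for c in _LETTERS]
    return ["Intercept"] + lin + inter + quad


def design_matrix(coded: np.ndarray) -> np.ndarray:
    """Expand coded points (n, 4) into the 15-column quadratic model matrix."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    cols = [np.ones(coded.shape[0])]
    cols += [coded[:, i] for i in range(4)]
    cols += [coded[:, i] * coded[:, j] for i, j in INTERACTION_PAIRS]
    cols += [coded[:, i] ** 2 for i in range(4)]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Fitted second-order polynomial on coded variables."""

    b0: float
    b_lin: np.ndarray    # (4,)   A, B, C, D
    b_int: np.ndarray    # (6,)   AB, AC, AD, BC, BD, CD
    b_quad: np.ndarray   # (4,)   A^2 .. D^2
    factors: tuple[FactorSpec, ...]

    def __post_init__(self) -> None:
        self.b_lin = np.asarray(self.b_lin, dtype=float)
        self.b_int = np.asarray(self.b_int, dtype=float)
        self.b_quad = np.asarray(self.b_quad, dtype=float)

    @property
    def coefficients(self) -> np.ndarray:
        """All 15 coefficients in model-matrix order."""
        return np.concatenate([[self.b0], self.b_lin, self.b_int, self.b_quad])

    @classmethod
    def from_coefficients(cls, beta, factors) -> "QuadraticModel":
        beta = np.asarray(beta, dtype=float)
        return cls(
            b0=float(beta[0]),
            b_lin=beta[1:5],
            b_int=beta[5:11],
            b_quad=beta[11:15],
            factors=tuple(factors),
        )

    def predict(self, coded) -> np.ndarray | float:
        """Evaluate the polynomial at coded points (extrapolation allowed)."""
        coded = np.asarray(coded, dtype=float)
        scalar = coded.ndim == 1
        out = design_matrix(coded) @ self.coefficients
        return float(out[0]) if scalar else out

    def predict_natural(self, natural) -> np.ndarray | float:
        return self.predict(code_point(natural, self.factors))

    def is_extrapolating(self, coded, tol: float = 1e-9) -> bool:
        """True when any coordinate lies outside the coded [-1, 1] cube."""
        return bool(np.any(np.abs(np.asarray(coded, dtype=float)) > 1 + tol))

    def to_dict(self) -> dict:
        labels = term_labels()
        return {
            "coefficients": dict(zip(labels, map(float, self.coefficients))),
            "factors": [
                {
                    "name": f.name,
                    "unit": f.unit,
                    "low": f.low,
                    "center": f.center,
                    "high": f.high,
                }
                for f in self.factors
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QuadraticModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        beta = [payload["coefficients"][k] for k in term_labels()]
        factors = tuple(FactorSpec(**f) for f in payload["factors"])
        return cls.from_coefficients(beta, factors)


@dataclass
class AnovaRow:
    source: str
    ss: float | None
    df: int | None
    ms: float | None = None
    f: float | None = None
    p: float | None = None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    ss_total: float
    df_total: int
    factor_names: list[str] = field(default_factory=list)

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "Source": r.source,
                "Sum of Squares": r.ss,
                "df": r.df,
                "Mean Square": r.ms,
                "F-value": r.f,
                "p-value": r.p,
            }
            for r in self.rows
        ]
        recs.append(
            {
                "Source": "Cor Total",
                "Sum of Squares": self.ss_total,
                "df": self.df_total,
                "Mean Square": None,
                "F-value": None,
                "p-value": None,
            }
        )
        return pd.DataFrame(recs)


@dataclass
class OptimumResult:
    """An argmax point in both unit systems, with its predicted response."""

    coded: np.ndarray
    natural: np.ndarray
    predicted: float
    method: str
    history: np.ndarray | None = None  # best-so-far trace for iterative methods

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coded": [float(v) for v in self.coded],
            "natural": [float(v) for v in self.natural],
            "predicted": float(self.predicted),
        }


def _check_design(design: DesignTable) -> tuple[np.ndarray, np.ndarray]:
    mask = design.has_response
    if int(mask.sum()) < 15:
        raise SingularDesignError(
            ["<underdetermined: fewer than 15 measured runs>"]
        )
    return design.coded[mask], design.response[mask]


def _aliased_columns(X: np.ndarray) -> list[str]:
    # greedy forward scan: a column that does not raise the rank is aliased
    labels = term_labels()
    aliased, kept = [], np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            aliased.append(labels[j])
    return aliased


def fit_quadratic(design: DesignTable) -> QuadraticModel:
    """OLS fit of the full quadratic to the design's measured responses."""
    coded, y = _check_design(design)
    X = design_matrix(coded)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(_aliased_columns(X))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return QuadraticModel.from_coefficients(beta, design.factors)


def predict(model: QuadraticModel, coded) -> np.ndarray | float:
    """Functional alias for :meth:`QuadraticModel.predict`."""
    return model.predict(coded)


def _pure_error(coded: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Within-group SS over replicated design points and its df."""
    keys = [tuple(np.round(row, 10)) for row in coded]
    groups: dict[tuple, list[float]] = {}
    for key, val in zip(keys, y):
        groups.setdefault(key, []).append(val)
    ss, df = 0.0, 0
    for vals in groups.values():
        if len(vals) > 1:
            arr = np.asarray(vals)
            ss += float(((arr - arr.mean()) ** 2).sum())
            df += len(vals) - 1
    return ss, df


def anova(model: QuadraticModel, design: DesignTable) -> AnovaTable:
    """Type-III ANOVA with replicate-based lack-of-fit decomposition.

    Each of the 14 non-intercept terms gets a partial sum of squares: the
    increase in residual SS when that single term is dropped from the full
    model and the reduced model is refit.  The Model row tests all 14 terms
    jointly.  When no replicated runs exist the lack-of-fit/pure-error rows
    are reported as unavailable (None), never as zero.
    """
    coded, y = _check_design(design)
    X = design_matrix(coded)
    n = len(y)
    beta = model.coefficients
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_model = ss_tot - ss_res
    df_model, df_res = 14, n - 15
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    rows = [
        AnovaRow(
            "Model",
            ss_model,
            df_model,
            ss_model / df_model,
            (ss_model / df_model) / ms_res,
            float(stats.f.sf((ss_model / df_model) / ms_res, df_model, df_res)),
        )
    ]
    labels = term_labels()
    for j in range(1, 15):
        Xr = np.delete(X, j, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rr = y - Xr @ br
        ss_j = float(rr @ rr) - ss_res
        f_j = (ss_j / 1.0) / ms_res
        rows.append(
            AnovaRow(
                labels[j], ss_j, 1, ss_j, f_j, float(stats.f.sf(f_j, 1, df_res))
            )
        )
    rows.append(AnovaRow("Residual", ss_res, df_res, ms_res))

    ss_pe, df_pe = _pure_error(coded, y)
    if df_pe > 0:
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        ms_pe = ss_pe / df_pe
        ms_lof = ss_lof / df_lof if df_lof > 0 else np.nan
        f_lof = ms_lof / ms_pe if df_lof > 0 and ms_pe > 0 else None
        p_lof = (
            float(stats.f.sf(f_lof, df_lof, df_pe)) if f_lof is not None else None
        )
        rows.append(AnovaRow("Lack of Fit", ss_lof, df_lof, ms_lof, f_lof, p_lof))
        rows.append(AnovaRow("Pure Error", ss_pe, df_pe, ms_pe))
    else:
        rows.append(AnovaRow("Lack of Fit", None, None))
        rows.append(AnovaRow("Pure Error", None, None))

    return AnovaTable(
        rows=rows,
        ss_total=ss_tot,
        df_total=n - 1,
        factor_names=list(design.factor_names),
    )


def r_squared(model: QuadraticModel, design: DesignTable) -> tuple[float, float]:
    """(R^2, adjusted R^2); NaN for a constant response (SS_total == 0)."""
    coded, y = _check_design(design)
    X = design_matrix(coded)
    resid = y - X @ model.coefficients
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return float("nan"), float("nan")
    n, p = len(y), 15
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (ss_res / (n - p)) / (ss_tot / (n - 1)) if n > p else float("nan")
    return r2, adj


def _as_bounds(bounds) -> tuple[np.ndarray, np.ndarray]:
    if bounds is None:
        lo, hi = -np.ones(4), np.ones(4)
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
    if lo.shape != (4,) or hi.shape != (4,) or np.any(lo >= hi):
        raise InvalidBoundsError(f"invalid box: lo={lo}, hi={hi}")
    return lo, hi


def optimize_on_cube(
    model: QuadraticModel,
    bounds=None,
    objective=None,
) -> OptimumResult:
    """Deterministic box-constrained maximization of the fitted surface.

    Runs Nelder-Mead local ascent from every point of the 3^4 lattice
    {lo, mid, hi}^4, with iterates clipped to the box; ties within 1e-9 are
    broken by the smallest coded Euclidean norm.  An arbitrary ``objective``
    over coded 4-vectors may be substituted for the model's own predictor
    (used to optimize ANN surrogates with the same machinery).
    """
    lo, hi = _as_bounds(bounds)
    fun = model.predict if objective is None else objective

    def neg(x):
        return -float(fun(np.clip(x, lo, hi)))

    starts = [
        np.array(p)
        for p in itertools.product(*[(lo[i], (lo[i] + hi[i]) / 2, hi[i]) for i in range(4)])
    ]
    best_x, best_v = None, -np.inf
    for x0 in starts:
        res = sp_optimize.minimize(
            neg,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        x = np.clip(res.x, lo, hi)
        v = float(fun(x))
        if v > best_v + 1e-9 or (
            abs(v - best_v) <= 1e-9
            and best_x is not None
            and np.linalg.norm(x) < np.linalg.norm(best_x)
        ):
            best_x, best_v = x, v
    natural = decode_point(best_x, model.factors)
    return OptimumResult(
        coded=best_x, natural=natural, predicted=best_v, method="RSM"
    )


def absolute_error(prediction: float, experiment: float) -> float:
    """|prediction - experiment| (symmetric by construction)."""
    return abs(float(prediction) - float(experiment))
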