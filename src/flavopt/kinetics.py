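"""First-order extraction kinetics.

Under a first-order (Fick's-first-law) model the transform
``y = ln(C_inf / (C_inf - C))`` is linear in time with slope k (the rate
constant) and intercept ``ln(C_inf / (C_inf - C0))``.  The module fits that
line by OLS and, alternatively, a sigmoid directly to the concentration data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sp_optimize

from .errors import ParseError, TransformDomainError

__all__ = [
    "KineticSeries",
    "KineticFit",
    "transform",
    "inverse_transform",
    "fit_first_order",
    "fit_nonlinear",
    "pick_equilibrium",
]


@dataclass
class KineticSeries:
    """Time-concentration series with initial and equilibrium concentrations."""

    times: np.ndarray
    concentrations: np.ndarray
    c0: float
    c_inf: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ParseError("times and concentrations differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ParseError("times must be strictly increasing")


@dataclass
class KineticFit:
    k: float                     # rate constant, per min
    intercept: float             # ln(C_inf / (C_inf - C0)) under the model
    r2: float
    nonlinear: dict | None = None   # y0/xc/W/A + form label, when fit
    diagnostics: dict = field(default_factory=dict)


def transform(series: KineticSeries) -> tuple[np.ndarray, np.ndarray]:
    """(times, ln[C_inf / (C_inf - C)]) — the linearizing transform."""
    c = series.concentrations
    bad = np.nonzero(c >= series.c_inf)[0]
    if bad.size:
        raise TransformDomainError(
            f"concentration at t={series.times[bad[0]]:g} reaches or exceeds "
            f"the equilibrium concentration {series.c_inf:g}"
        )
    return series.times, np.log(series.c_inf / (series.c_inf - c))


def inverse_transform(y, c_inf: float) -> np.ndarray:
    """Map transformed values back to concentrations (inverse of transform)."""
    return c_inf * (1.0 - np.exp(-np.asarray(y, dtype=float)))


def fit_first_order(series: KineticSeries) -> KineticFit:
    """OLS of the transformed values on time; the slope is k."""
    t, y = transform(series)
    if len(t) < 2:
        raise ParseError("need at least two time points")
    k, intercept = np.polyfit(t, y, 1)
    resid = y - (k * t + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return KineticFit(k=float(k), intercept=float(intercept), r2=r2)


def _boltzmann(t, y0, xc, w, a):
    # y0: baseline as t -> +inf; a: amplitude (value at -inf is y0 + a)
    return y0 + a / (1.0 + np.exp((t - xc) / w))


def fit_nonlinear(series: KineticSeries, form: str = "boltzmann") -> KineticFit:
    """Direct least-squares sigmoid fit to the concentration data.

    The default form is a Boltzmann sigmoid
    ``C(t) = y0 + A / (1 + exp((t - xc) / W))`` parameterized by
    (y0, xc, W, A); fitting uses deterministic multi-start Levenberg-
    Marquardt style least squares, and a non-converged fit is flagged in the
    diagnostics with residuals still reported.
    """
    if form != "boltzmann":
        raise ParseError(f"unknown nonlinear form {form!r}")
    t = series.times
    c = series.concentrations
    span = float(np.ptp(c))
    t_span = float(np.ptp(t))
    if span == 0:
        lin = fit_first_order(series)
        lin.nonlinear = {
            "form": form, "y0": float(c[0]), "xc": float(np.median(t)),
            "W": t_span or 1.0, "A": 0.0,
        }
        lin.diagnostics["nonlinear_converged"] = False
        lin.diagnostics["nonlinear_note"] = "constant series; degenerate fit"
        return lin

    starts = [
        (float(c.max()), float(np.median(t)), -t_span / 4.0, -span),
        (float(c.max()), float(t[0]), -t_span / 2.0, -span),
        (float(c.min()), float(np.median(t)), t_span / 4.0, span),
        (float(c.mean()), float(t[-1]), -t_span, -2.0 * span),
    ]

    def residuals(p):
        return _boltzmann(t, *p) - c

    best = None
    for p0 in starts:
        try:
            sol = sp_optimize.least_squares(
                residuals, p0, method="lm", max_nfev=5000
            )
        except Exception:
            continue
        cost = float(sol.cost)
        if best is None or cost < best[0]:
            best = (cost, sol)
    lin = fit_first_order(series)
    const_sse = float(((c - c.mean()) ** 2).sum())
    if best is None:
        lin.diagnostics["nonlinear_converged"] = False
        return lin
    cost, sol = best
    y0, xc, w, a = (float(v) for v in sol.x)
    sse = float(sol.fun @ sol.fun)
    converged = bool(sol.success)
    if sse > const_sse:
        # fall back to the constant model so the sigmoid never fits worse
        y0, xc, w, a = float(c.mean()), float(np.median(t)), t_span or 1.0, 0.0
        sse, converged = const_sse, False
    lin.nonlinear = {"form": form, "y0": y0, "xc": xc, "W": w, "A": a}
    lin.diagnostics["nonlinear_converged"] = converged and sse <= const_sse + 1e-12
    lin.diagnostics["nonlinear_sse"] = sse
    lin.diagnostics["constant_model_sse"] = const_sse
    return lin


def pick_equilibrium(times, concentrations, rule: str = "last") -> float:
    """Equilibrium-concentration heuristic; default: final time point."""
    c = np.asarray(concentrations, dtype=float)
    if rule == "last":
        return float(c[-1])
    if rule == "max":
        return float(c.max())
    raise ParseError(f"unknown equilibrium rule {rule!r}")
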