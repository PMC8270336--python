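"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of a :class:`SyntheticSpec`: the same spec
always yields bit-identical output, and zero-noise output is exactly
invertible by the corresponding fitting operation.  Every generator draws
from its own pseudo-random stream split from the spec seed via a fixed
spawn key, so adding draws to one generator never perturbs another:

==================  =========
generator           spawn key
==================  =========
gen_bbd_response        (1,)
gen_kinetic_series      (2,)
gen_standard_curve      (3,)
gen_assay               (4,)
gen_dominant_factor     (5,)
==================  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import AssayMeasurement
from .datasets import extraction_factors
from .design import DesignTable, build_bbd
from .kinetics import KineticSeries

__all__ = [
    "SyntheticSpec",
    "DEFAULT_QUADRATIC_COEF",
    "gen_bbd_response",
    "gen_kinetic_series",
    "gen_standard_curve_points",
    "gen_assay_measurements",
    "gen_dominant_factor",
]

#: Default ground-truth coefficients for the synthetic quadratic surface, in
#: model-matrix order (intercept, 4 linear, 6 interaction, 4 quadratic).
#: They equal the published refit of the packaged 29-run experiment, so the
#: zero-noise surface predicts 10.30 at the coded origin.
DEFAULT_QUADRATIC_COEF = np.array(
    [
        10.30,
        0.81, 0.40, -1.47, 1.15,
        -1.43, -1.53, -0.048, 0.20, -1.23, -0.59,
        -0.68, -1.55, -3.50, -3.03,
    ]
)

#: Default first-order kinetic parameters: rate constant (per min) and the
#: transformed-line intercept, as published for the reference experiment.
DEFAULT_KINETIC_PARAMS = {"k": 0.01372, "intercept": -0.6274, "c_inf": 5.0}

#: Default calibration line (absorbance per mg/mL, absorbance offset).
DEFAULT_CURVE_PARAMS = {"slope": 5.0629, "intercept": 0.1885}


@dataclass
class SyntheticSpec:
    """What to generate, with known ground truth.

    ``kind`` is one of ``bbd``, ``kinetic``, ``standard_curve``, ``assay``,
    ``dominant_factor``.  ``true_params`` overrides generator defaults.
    """

    kind: str
    true_params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    n: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self, spawn_key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(spawn_key,))
        )


def _quadratic_surface(coded: np.ndarray, beta: np.ndarray) -> np.ndarray:
    from .rsm import design_matrix

    return design_matrix(coded) @ beta


def gen_bbd_response(spec: SyntheticSpec) -> DesignTable:
    """29-run BBD whose response is a known quadratic plus Gaussian noise.

    Center replicates share the same mean by construction (identical coded
    point); with ``noise_sd == 0`` an OLS refit recovers the coefficients
    exactly.
    """
    rng = spec.rng(1)
    beta = np.asarray(
        spec.true_params.get("coefficients", DEFAULT_QUADRATIC_COEF), dtype=float
    )
    n_center = int(spec.true_params.get("n_center", 5))
    design = build_bbd(extraction_factors(), n_center=n_center)
    mean = _quadratic_surface(design.coded, beta)
    noise = rng.normal(0.0, spec.noise_sd, size=design.n_runs) if spec.noise_sd else 0.0
    return design.with_response(mean + noise)


def gen_kinetic_series(spec: SyntheticSpec) -> KineticSeries:
    """Time-concentration series from the first-order model.

    ``C(t) = C_inf * (1 - exp(-(k t + a0)))`` where a0 is the transformed-line
    intercept; Gaussian noise is clipped below ``C_inf`` to keep the
    log-transform defined.
    """
    rng = spec.rng(2)
    params = {**DEFAULT_KINETIC_PARAMS, **spec.true_params}
    k, a0, c_inf = params["k"], params["intercept"], params["c_inf"]
    times = np.asarray(
        spec.true_params.get("times", np.arange(10.0, 131.0, 10.0)), dtype=float
    )
    mean = c_inf * (1.0 - np.exp(-(k * times + a0)))
    c = mean + (rng.normal(0.0, spec.noise_sd, size=len(times)) if spec.noise_sd else 0.0)
    cap = c_inf - 1e-9 * max(abs(c_inf), 1.0)
    c = np.minimum(c, cap)
    c0 = c_inf * (1.0 - np.exp(-a0))
    return KineticSeries(times=times, concentrations=c, c0=c0, c_inf=c_inf)


def gen_standard_curve_points(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Calibration dilution series: 6 points over 0..0.1 mg/mL by default."""
    rng = spec.rng(3)
    params = {**DEFAULT_CURVE_PARAMS, **spec.true_params}
    n = spec.n or 6
    conc = np.linspace(0.0, spec.true_params.get("c_max", 0.1), n)
    absorb = params["slope"] * conc + params["intercept"]
    if spec.noise_sd:
        absorb = absorb + rng.normal(0.0, spec.noise_sd, size=n)
    return conc, absorb


def _true_efficiency(conc: np.ndarray, emax: float, half: float) -> np.ndarray:
    # saturating monotone curve through the origin
    return emax * conc / (conc + half)


def gen_assay_measurements(spec: SyntheticSpec) -> list[AssayMeasurement]:
    """Dilution ladder of scavenging measurements with a monotone true curve.

    Absorbances are constructed so the published efficiency formulas recover
    the true curve exactly at zero noise.
    """
    rng = spec.rng(4)
    assay = spec.true_params.get("assay", "dpph")
    emax = float(spec.true_params.get("emax", 90.0))
    half = float(spec.true_params.get("half", 0.03))
    n = spec.n or 10
    conc = np.linspace(0.01, 0.1, n)
    eff = _true_efficiency(conc, emax, half)
    out = []
    for c, e in zip(conc, eff):
        if assay == "hydroxyl":
            ap, ab = 0.2, 1.0
            a_s = ap + (ab - ap) * e / 100.0
            vals = np.array([ap, a_s, ab])
            if spec.noise_sd:
                vals = np.abs(vals + rng.normal(0.0, spec.noise_sd, size=3))
            out.append(
                AssayMeasurement(
                    assay=assay,
                    blank=vals[0],
                    sample_control=vals[1],
                    experimental_control=vals[2],
                    concentration=float(c),
                )
            )
        else:
            a0, a2 = 0.8, 0.05
            a1 = a2 + a0 * (1.0 - e / 100.0)
            vals = np.array([a0, a1, a2])
            if spec.noise_sd:
                vals = np.abs(vals + rng.normal(0.0, spec.noise_sd, size=3))
            out.append(
                AssayMeasurement(
                    assay=assay,
                    blank=vals[0],
                    sample_control=vals[1],
                    experimental_control=vals[2],
                    concentration=float(c),
                )
            )
    return out


def gen_dominant_factor(spec: SyntheticSpec) -> DesignTable:
    """BBD response where one factor's linear effect is 10x the others'."""
    rng = spec.rng(5)
    dominant = int(spec.true_params.get("dominant", 2))
    base = float(spec.true_params.get("base_effect", 0.5))
    beta = np.zeros(15)
    beta[0] = 10.0
    beta[1:5] = base
    beta[1 + dominant] = 10.0 * base
    design = build_bbd(extraction_factors(), n_center=5)
    mean = _quadratic_surface(design.coded, beta)
    noise = rng.normal(0.0, spec.noise_sd, size=design.n_runs) if spec.noise_sd else 0.0
    return design.with_response(mean + noise)
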