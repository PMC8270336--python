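"""Packaged example datasets.

The package ships the published 29-run Box-Behnken extraction experiment
(four factors, five center replicates), the trained-network weight table of
the same study, and its optimum-validation table.  All three are plain CSV
under ``flavopt/data`` and load through :mod:`importlib.resources`, so they
work from zipped installs too.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .design import DesignTable, FactorSpec, read_design

__all__ = [
    "extraction_factors",
    "load_extraction_design",
    "load_validation_table",
    "load_ann_weight_frame",
]


def extraction_factors() -> tuple[FactorSpec, ...]:
    """Factor specs of the packaged extraction experiment.

    The material-liquid ratio is parameterized by its denominator — mL of
    solvent per g of material — so "1:15" sits at the high level (+1).
    """
    return (
        FactorSpec("time_min", "min", 20.0, 30.0, 40.0),
        FactorSpec("ethanol_pct", "%", 50.0, 60.0, 70.0),
        FactorSpec("solvent_ml_per_g", "mL/g", 5.0, 10.0, 15.0),
        FactorSpec("power_w", "W", 60.0, 120.0, 180.0),
    )


def _data_path(name: str):
    return resources.files("flavopt.data").joinpath(name)


def load_extraction_design() -> DesignTable:
    """The 29-run BBD with measured extraction efficiencies (%)."""
    with resources.as_file(_data_path("bbd_runs.csv")) as path:
        return read_design(path, factors=extraction_factors())


def load_validation_table() -> pd.DataFrame:
    """Optimum-validation rows: conditions, experiment and prediction (%)."""
    with resources.as_file(_data_path("validation_runs.csv")) as path:
        return pd.read_csv(path)


def load_ann_weight_frame() -> pd.DataFrame:
    """Raw weight table (10 hidden neurons) as published.

    Note: the published table's input-bias column is symmetric about zero and
    its layer-weight column repeats values; it is used as-is.
    """
    with resources.as_file(_data_path("ann_weights.csv")) as path:
        return pd.read_csv(path)


def response_bounds(design: DesignTable) -> tuple[float, float]:
    """(min, max) of the measured responses, ignoring missing values."""
    resp = design.response[design.has_response]
    return float(np.min(resp)), float(np.max(resp))
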