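import numpy as np
import pytest

from flavopt import datasets
from flavopt.design import FactorSpec, build_bbd


@pytest.fixture(scope="session")
def extraction_design():
    """The packaged 29-run experiment (session-scoped; treat as read-only)."""
    return datasets.load_extraction_design()


@pytest.fixture(scope="session")
def extraction_model(extraction_design):
    from flavopt.rsm import fit_quadratic

    return fit_quadratic(extraction_design)


@pytest.fixture(scope="session")
def extraction_anova(extraction_model, extraction_design):
    from flavopt.rsm import anova

    return anova(extraction_model, extraction_design)


@pytest.fixture(scope="session")
def packaged_ann():
    """AnnModel built from the packaged published weight table."""
    from flavopt import ann

    design = datasets.load_extraction_design()
    lo, hi = datasets.response_bounds(design)
    return ann.load_weights(
        datasets.load_ann_weight_frame(),
        input_min=np.array([f.low for f in design.factors]),
        input_max=np.array([f.high for f in design.factors]),
        response_min=lo,
        response_max=hi,
    )


@pytest.fixture
def toy_factors():
    return tuple(
        FactorSpec.from_range(name, 0.0, 2.0) for name in ("x1", "x2", "x3", "x4")
    )


@pytest.fixture
def toy_bbd(toy_factors):
    return build_bbd(toy_factors, n_center=5)
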