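import numpy as np
import pytest

from isoassign import SyntheticConfig, simulate_study
from isoassign.grids import Grid


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across read-only tests."""
    return simulate_study(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def fitted(study):
    """Simple calibration + variance surface on the shared study."""
    from isoassign import fit_simple_calibration, predict_surface, total_variance_surface

    model = fit_simple_calibration(study.train, study.isoscape)
    predicted = predict_surface(model, base=study.isoscape)
    comps = total_variance_surface(
        model, base=study.isoscape, base_pred_var=study.base_variance
    )
    return model, predicted, comps


def make_grid(values, origin=(0.0, 5.0), cell=1.0, mask=None, role="isoscape"):
    values = np.asarray(values, dtype=float)
    return Grid(
        values=values,
        origin=origin,
        cell_size=(cell, cell),
        nodata_mask=mask,
        role=role,
    )


@pytest.fixture
def grid_factory():
    return make_grid
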