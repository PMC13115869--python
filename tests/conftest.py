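import numpy as np
import pytest

from phoswell import (
    Condition,
    ConcentrationSeries,
    Layout,
    TranswellGeometry,
    closed_form_concentrations,
)

TWELVE_HOURS = np.array([0.0, 4 * 3600.0, 8 * 3600.0, 12 * 3600.0])


@pytest.fixture
def geom() -> TranswellGeometry:
    return TranswellGeometry()


@pytest.fixture
def make_noiseless_series(geom):
    """Factory: exact closed-form well at a given Papp and dosing."""

    def _make(papp, c_a0=1.0, c_b0=0.1, times=TWELVE_HOURS, layout=Layout.MESO_BASOLATERAL):
        c_a, c_b = closed_form_concentrations(papp, geom, c_a0, c_b0, times)
        cond = Condition(
            layout=layout, apical_phosphate_mm=c_a0, basolateral_phosphate_mm=c_b0
        )
        return ConcentrationSeries(cond, "w1", times, np.atleast_1d(c_a), np.atleast_1d(c_b))

    return _make
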