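import numpy as np
import pytest
from hypothesis import settings

from synscreen.doseresponse import FourPLCurve, NormalizedCurveData

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def curve_data(
    curve: FourPLCurve,
    dmso_level: float | None = None,
    top_conc: float = 30000.0,
    dilution: float = 3.0,
    n_points: int = 10,
) -> NormalizedCurveData:
    """Noise-free normalized data generated exactly from a 4PL curve."""
    conc = np.sort(top_conc / dilution ** np.arange(n_points))
    resp = curve.predict(conc)
    dmso = curve.top if dmso_level is None else dmso_level
    return NormalizedCurveData(conc, resp, float(dmso), float(conc.max()))


@pytest.fixture
def reference_curve() -> FourPLCurve:
    """The worked closed-form example: bottom 0, top 300, EC50 1 uM, slope 1."""
    return FourPLCurve(0.0, 300.0, 1000.0, 1.0)
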