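import numpy as np
import pytest

from ddipk.profiles import ConcentrationTimeProfile


def make_profile(times, concs, blq=None, **kw):
    defaults = dict(
        subject_id="S1",
        analyte="probe",
        group="vehicle",
        dose=10.0,
        route="oral",
        conc_unit="ng/ml",
    )
    defaults.update(kw)
    return ConcentrationTimeProfile(
        times=np.asarray(times, dtype=float),
        concentrations=np.asarray(concs, dtype=float),
        blq_flags=None if blq is None else np.asarray(blq, dtype=bool),
        **defaults,
    )


@pytest.fixture
def monoexp_profile():
    """Pure monoexponential C(t) = 100 * exp(-0.5 t) at t = 1, 2, 4, 8 h."""
    t = np.array([1.0, 2.0, 4.0, 8.0])
    return make_profile(t, 100.0 * np.exp(-0.5 * t))
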