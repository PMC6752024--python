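import numpy as np
import pandas as pd
import pytest

from sedpep.kinetics import CalibrationCurve, SaturationAssay


@pytest.fixture
def calib():
    return CalibrationCurve(slope=2.0)


@pytest.fixture
def simple_assay():
    """Hand-built two-timepoint assay with dF=40 at every concentration."""
    concs = [0.0, 25.0, 50.0, 100.0, 200.0]
    records = pd.DataFrame({
        "conc_um": concs,
        "fluor_t0": [100.0] * len(concs),
        "fluor_t1": [140.0] * len(concs),
        "t0_h": [0.0] * len(concs),
        "t1_h": [3.0] * len(concs),
        "wet_mass_g": [0.5] * len(concs),
        "treatment": ["live"] * len(concs),
    })
    return SaturationAssay("Leu-AMC", 4.5, records, slurry_volume_ml=4.5)


def v0_table_from_law(vmax, km, concs=(25, 50, 75, 100, 200, 300), noise=None):
    """Exact (or noisy) v0 table straight from the Michaelis-Menten law."""
    concs = np.asarray(concs, dtype=float)
    v0 = vmax * concs / (km + concs)
    if noise is not None:
        v0 = v0 + noise
    return pd.DataFrame({"conc_um": concs, "v0": v0,
                         "treatment": ["live"] * concs.size})
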