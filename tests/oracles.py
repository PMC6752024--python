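"""Independent closed-form oracles used by the test suite.

These derivations never call the solver they check.
"""

import numpy as np


def single_g_sulfate_closed_form(z, params):
    """Exact steady-state sulfate profile for a single-G, no-AOM model.

    With one reactive fraction (partition fraction ~1), no Monod limitation
    (k_so4 = 0) and no methane oxidation, the porewater sulfate equation is
    linear with an exponential source:

        D C'' - u C' = q exp(-lam (z - z0)),   q = a k G0 / phi,  lam = k / u

    General solution C = c1 + c2 exp(u z / D) + A exp(-lam (z - z0)) with
    A = q / (lam (D lam + u)); the constants follow from C(z0) = C0 and
    C'(L) = 0.
    """
    a = (4.0 - params.ox_state) / 8.0
    phi = params.porosity
    d = params.ds_so4
    u = params.omega
    k = params.k1
    lam = k / u
    c_flux = (params.so4_flux_top + params.ch4_burial_bottom) / a
    g0 = params.f_partition * c_flux / u
    q = a * k * g0 / phi
    z0, bot = params.z_top, params.z_bottom
    big_a = q / (lam * (d * lam + u))
    c2 = big_a * lam * d / u * np.exp(-lam * (bot - z0)) * np.exp(-u / d * bot)
    c1 = params.so4_top - big_a - c2 * np.exp(u / d * z0)
    z = np.asarray(z, dtype=float)
    return c1 + c2 * np.exp(u / d * z) + big_a * np.exp(-lam * (z - z0))
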