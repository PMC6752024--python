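"""Steady-state 2-G reaction-transport model of sulfate and methane.

The organic-matter remineralization rate is parameterized with a two-fraction
(2-G) model: reactive organic carbon arriving at the top of the model domain
is split into a labile fraction G1 and a less reactive fraction G2, each
decaying first-order while being buried with the sediment at the
accumulation rate ``omega``.  Because solids advect without mixing below the
bioturbated layer, each fraction has the closed form

    G_i(z) = G_i(z_top) * exp(-k_i (z - z_top) / omega)

and the total carbon oxidation rate is r_c(z) = k1 G1(z) + k2 G2(z)
(micromol C per cm^3 bulk sediment per year).

Carbon oxidation is routed between sulfate reduction and methanogenesis with
a Monod switch on porewater sulfate; methane formed at depth diffuses upward
and is consumed by anaerobic oxidation of methane (AOM) against sulfate with
1:1 stoichiometry.  Both solutes obey the classical steady-state diagenetic
equation (diffusion with tortuosity correction, burial advection, reaction):

    phi Ds C'' - phi omega C' + phi sum(R) = 0

with measured concentrations fixed at the top of the domain and a
zero-gradient condition at the bottom.  The stoichiometric factor linking
carbon oxidation to sulfate consumption (or methane production) follows from
electron balance: carbon of mean oxidation state s releases (4 - s)
electrons per atom on oxidation to CO2, and sulfate accepts 8, so

    a = (4 - s) / 8    [mol SO4 (or CH4) per mol C].

Four parameters are adjustable against observed porewater profiles: k1, k2,
the partitioning fraction f of reactive carbon assigned to G1, and the AOM
rate constant k_aom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import least_squares

from .errors import CalibrationError, DomainError, SolverError
from .profiles import DepthProfile

__all__ = [
    "DiagenesisParams",
    "ModelSolution",
    "CalibrationResult",
    "stoichiometric_factor",
    "oc_flux_partition",
    "om_profile",
    "solve_solutes",
    "calibrate_model",
    "oc_oxidation_summary",
    "so4_budget",
    "ch4_budget",
]


def stoichiometric_factor(ox_state: float) -> float:
    """Mol sulfate consumed (or methane produced) per mol organic C oxidized.

    From electron balance: a = (4 - ox_state) / 8.  ``ox_state`` is the mean
    carbon oxidation state of the reactive organic matter (default -0.7 for
    estuarine OM; 0 recovers the textbook 2C : 1SO4 carbohydrate ratio).
    """
    if ox_state >= 4:
        raise DomainError("oxidation state >= 4 gives degenerate stoichiometry (a <= 0)")
    return (4.0 - ox_state) / 8.0


@dataclass
class DiagenesisParams:
    """Configuration of the 2-G sulfate/methane model.

    Rates are per year, lengths in cm, concentrations in mM
    (= micromol per cm^3 porewater).  ``k1 > k2 > 0`` orders the fractions by
    reactivity; ``f_partition`` is the fraction of the reactive carbon flux
    assigned to the labile pool.  ``so4_flux_top`` (micromol SO4 cm^-2 yr^-1)
    and ``ch4_burial_bottom`` (micromol CH4 cm^-2 yr^-1) anchor the reactive
    carbon flux via :func:`oc_flux_partition`.  Diffusivities ``d0_*`` are
    free-solution values at the in situ temperature; the effective
    diffusivity divides by the tortuosity correction theta^2 = 1 - 2 ln(phi).
    """

    k1: float = 0.08
    k2: float = 0.018
    f_partition: float = 0.5
    k_aom: float = 3.0          # mM^-1 yr^-1 (bimolecular form)
    omega: float = 0.3          # cm yr^-1 sediment accumulation
    porosity: float = 0.8
    d0_so4: float = 280.0       # cm^2 yr^-1 free solution, ~16 degC
    d0_ch4: float = 440.0
    z_top: float = 4.5
    z_bottom: float = 200.0
    so4_top: float = 12.0       # mM, measured upper-boundary value
    ch4_top: float = 0.0
    ox_state: float = -0.7
    k_so4: float = 0.1          # mM Monod half-saturation for SR vs methanogenesis
    so4_flux_top: float = 182.0  # micromol cm^-2 yr^-1
    ch4_burial_bottom: float = 15.0
    grid_step: float = 0.5      # cm
    aom_bimolecular: bool = True

    def __post_init__(self):
        if not (self.k1 > self.k2 > 0):
            raise DomainError("require k1 > k2 > 0")
        if not (0 < self.f_partition < 1):
            raise DomainError("f_partition must lie in (0, 1)")
        if self.k_aom < 0:
            raise DomainError("k_aom must be nonnegative")
        if not (0 < self.porosity < 1):
            raise DomainError("porosity must lie in (0, 1)")
        if self.z_top >= self.z_bottom:
            raise DomainError("z_top must be above z_bottom")
        if self.omega <= 0:
            raise DomainError("sedimentation rate omega must be positive")
        if self.so4_flux_top < 0 or self.ch4_burial_bottom < 0:
            raise DomainError("boundary fluxes must be nonnegative")
        stoichiometric_factor(self.ox_state)  # validates ox_state

    @property
    def tortuosity2(self) -> float:
        return 1.0 - 2.0 * np.log(self.porosity)

    @property
    def ds_so4(self) -> float:
        """Effective sediment diffusivity of sulfate (cm^2 yr^-1)."""
        return self.d0_so4 / self.tortuosity2

    @property
    def ds_ch4(self) -> float:
        return self.d0_ch4 / self.tortuosity2

    def grid(self) -> np.ndarray:
        n = int(round((self.z_bottom - self.z_top) / self.grid_step))
        return self.z_top + self.grid_step * np.arange(n + 1)


def oc_flux_partition(
    so4_flux_top: float,
    ch4_burial_bottom: float,
    ox_state: float = -0.7,
    f_partition: float = 0.5,
    omega: float = 0.3,
) -> tuple[float, float, float]:
    """Reactive organic-carbon flux and per-fraction boundary concentrations.

    Every mol of reactive C oxidized in the domain either consumes ``a`` mol
    sulfate (directly, or indirectly when its methane is re-oxidized by AOM)
    or leaves as ``a`` mol buried methane, so the reactive carbon flux across
    the top of the domain is (sulfate flux + methane burial) / a.  Boundary
    concentrations follow from flux continuity of the advecting solids:
    G_i(z_top) = f_i * C_flux / omega (micromol C per cm^3 bulk).

    Returns ``(c_flux_total, g1_top, g2_top)``.
    """
    if so4_flux_top < 0 or ch4_burial_bottom < 0:
        raise DomainError("fluxes must be nonnegative")
    a = stoichiometric_factor(ox_state)
    c_flux = so4_flux_top / a + ch4_burial_bottom / a
    g1_top = f_partition * c_flux / omega
    g2_top = (1.0 - f_partition) * c_flux / omega
    return c_flux, g1_top, g2_top


def om_profile(params: DiagenesisParams, z: np.ndarray | None = None):
    """Closed-form depth profiles of the two reactive carbon fractions.

    Solids advect at ``omega`` without mixing, so each fraction decays as
    ``exp(-k_i (z - z_top) / omega)`` from its boundary concentration.
    Returns ``(g1, g2)`` in micromol C per cm^3 bulk sediment.
    """
    if params.omega <= 0:
        raise DomainError("omega must be positive")
    if z is None:
        z = params.grid()
    z = np.asarray(z, dtype=float)
    _, g1_top, g2_top = oc_flux_partition(
        params.so4_flux_top, params.ch4_burial_bottom, params.ox_state,
        params.f_partition, params.omega,
    )
    dz = z - params.z_top
    g1 = g1_top * np.exp(-params.k1 * dz / params.omega)
    g2 = g2_top * np.exp(-params.k2 * dz / params.omega)
    return g1, g2


@dataclass
class ModelSolution:
    """Converged model state on the depth grid.

    Concentrations in mM; rates in micromol per cm^3 bulk per year.
    ``r_c = k1 g1 + k2 g2`` is total carbon oxidation; ``r_sr``/``r_mg`` are
    the sulfate-consuming and methane-producing routes (as SO4/CH4
    equivalents) and ``r_aom`` the anaerobic methane oxidation rate.
    """

    grid: np.ndarray
    so4: np.ndarray
    ch4: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    r_c: np.ndarray
    r_sr: np.ndarray
    r_mg: np.ndarray
    r_aom: np.ndarray
    residual: float
    iterations: int
    params: DiagenesisParams

    def so4_profile(self) -> DepthProfile:
        return DepthProfile(self.grid, self.so4, label="sulfate (mM)")

    def ch4_profile(self) -> DepthProfile:
        return DepthProfile(self.grid, self.ch4, label="methane (mM)")

    def oxidation_profile(self) -> DepthProfile:
        return DepthProfile(self.grid, self.r_c, label="OC oxidation (umol C cm-3 yr-1)")

    def sulfate_depletion_depth(self, threshold: float = 0.5) -> float:
        """Shallowest depth where sulfate first drops below ``threshold`` mM."""
        below = np.nonzero(self.so4 < threshold)[0]
        if below.size == 0:
            return np.nan
        i = below[0]
        if i == 0:
            return float(self.grid[0])
        # linear interpolation across the crossing
        z0, z1 = self.grid[i - 1], self.grid[i]
        c0, c1 = self.so4[i - 1], self.so4[i]
        return float(z0 + (c0 - threshold) / (c0 - c1) * (z1 - z0))


def _solve_tridiag(ds, omega, h, lin, src, c_top, n):
    """Solve D C'' - omega C' - lin*C + src = 0 on n+1 nodes.

    Node 0 is Dirichlet (c_top); node n uses a symmetric ghost for the
    zero-gradient condition.  ``lin`` and ``src`` are arrays over all nodes.
    """
    # banded matrix rows: [upper, diag, lower]
    ab = np.zeros((3, n + 1))
    rhs = np.zeros(n + 1)
    ab[1, 0] = 1.0
    rhs[0] = c_top
    alpha = ds / h**2
    beta = omega / (2 * h)
    # interior nodes 1..n-1
    ab[0, 2:] = alpha - beta            # super-diagonal (coef of C[i+1])
    ab[1, 1:] = -2 * alpha - lin[1:]    # diagonal
    ab[2, 0:-1] = alpha + beta          # sub-diagonal (coef of C[i-1])
    rhs[1:] = -src[1:]
    # bottom node: ghost C[n+1] = C[n-1] kills the advective derivative
    ab[2, n - 1] = 2 * alpha
    ab[1, n] = -2 * alpha - lin[n]
    # fix row 0 couplings
    ab[0, 1] = 0.0
    return solve_banded((1, 1), ab, rhs)


def _residual(params, so4, ch4, g1, g2):
    """Max-norm residual of the coupled nonlinear system, nondimensionalized."""
    h = params.grid_step
    phi = params.porosity
    a = stoichiometric_factor(params.ox_state)
    rc = params.k1 * g1 + params.k2 * g2
    m = so4 / (params.k_so4 + so4) if params.k_so4 > 0 else (so4 > 0).astype(float)
    aom = params.k_aom * ch4 * so4 if params.aom_bimolecular else params.k_aom * ch4
    f_so4 = np.zeros_like(so4)
    f_ch4 = np.zeros_like(ch4)

    def op(c, ds):
        out = np.zeros_like(c)
        out[1:-1] = (
            ds * (c[:-2] - 2 * c[1:-1] + c[2:]) / h**2
            - params.omega * (c[2:] - c[:-2]) / (2 * h)
        )
        out[-1] = ds * 2 * (c[-2] - c[-1]) / h**2
        return out

    f_so4 = op(so4, params.ds_so4) - a * rc * m / phi - aom
    f_ch4 = op(ch4, params.ds_ch4) + a * rc * (1 - m) / phi - aom
    f_so4[0] = f_ch4[0] = 0.0
    scale = max(params.so4_top, float(np.max(ch4, initial=0.0)), 1.0)
    norm = max(params.ds_so4, params.ds_ch4) * scale / h**2
    return float(max(np.max(np.abs(f_so4)), np.max(np.abs(f_ch4))) / norm)


def solve_solutes(
    params: DiagenesisParams,
    max_iter: int = 400,
    tol: float = 1e-8,
    relax: float = 0.9,
) -> ModelSolution:
    """Solve the coupled steady-state sulfate/methane system.

    Damped Picard iteration: each sweep solves sulfate then methane as
    linear tridiagonal problems, freezing the Monod switch at the previous
    sulfate field and taking the consumption terms semi-implicitly (linear
    in the solute being solved), which keeps iterates nonnegative.
    Convergence is declared when the nondimensional residual of the full
    nonlinear system falls below ``tol``.
    """
    z = params.grid()
    n = z.size - 1
    h = params.grid_step
    phi = params.porosity
    a = stoichiometric_factor(params.ox_state)
    g1, g2 = om_profile(params, z)
    rc = params.k1 * g1 + params.k2 * g2

    so4 = np.full(z.shape, params.so4_top, dtype=float)
    ch4 = np.full(z.shape, params.ch4_top, dtype=float)
    res_history = []
    res = np.inf
    for it in range(1, max_iter + 1):
        so4_old, ch4_old = so4, ch4
        # sulfate: SR linearized as (a rc / (phi (K + so4_old))) * so4 so that
        # consumption vanishes smoothly as sulfate is exhausted
        if params.k_so4 > 0:
            lin_sr = a * rc / (phi * (params.k_so4 + np.maximum(so4_old, 0.0)))
            src_so4 = np.zeros_like(z)
        else:
            lin_sr = np.zeros_like(z)
            src_so4 = -a * rc / phi
        lin_aom_so4 = (params.k_aom * np.maximum(ch4_old, 0.0)
                       if params.aom_bimolecular else np.zeros_like(z))
        src_aom_so4 = (np.zeros_like(z) if params.aom_bimolecular
                       else -params.k_aom * np.maximum(ch4_old, 0.0))
        so4_new = _solve_tridiag(
            params.ds_so4, params.omega, h,
            lin_sr + lin_aom_so4, src_so4 + src_aom_so4, params.so4_top, n,
        )
        so4 = np.maximum(so4_old + relax * (so4_new - so4_old), 0.0)

        m = so4 / (params.k_so4 + so4) if params.k_so4 > 0 else (so4 > 0).astype(float)
        src_mg = a * rc * (1 - m) / phi
        lin_aom_ch4 = (params.k_aom * so4 if params.aom_bimolecular
                       else np.full_like(z, params.k_aom))
        ch4_new = _solve_tridiag(
            params.ds_ch4, params.omega, h, lin_aom_ch4, src_mg, params.ch4_top, n,
        )
        ch4 = np.maximum(ch4_old + relax * (ch4_new - ch4_old), 0.0)

        res = _residual(params, so4, ch4, g1, g2)
        res_history.append(res)
        if res < tol:
            break
    else:
        raise SolverError(
            f"no convergence after {max_iter} sweeps (residual {res:.3e})",
            diagnostics={"residuals": res_history},
        )

    m = so4 / (params.k_so4 + so4) if params.k_so4 > 0 else (so4 > 0).astype(float)
    aom_pw = params.k_aom * ch4 * so4 if params.aom_bimolecular else params.k_aom * ch4
    return ModelSolution(
        grid=z, so4=so4, ch4=ch4, g1=g1, g2=g2,
        r_c=rc, r_sr=a * rc * m, r_mg=a * rc * (1 - m), r_aom=phi * aom_pw,
        residual=res, iterations=it, params=params,
    )


def _top_gradient(c: np.ndarray, h: float) -> float:
    """Second-order one-sided derivative at the top node."""
    return (-3 * c[0] + 4 * c[1] - c[2]) / (2 * h)


def so4_budget(sol: ModelSolution) -> dict:
    """Sulfate mass balance: flux in across z_top vs depth-integrated sinks.

    Fluxes are micromol cm^-2 yr^-1, positive downward.  At steady state
    (diffusive + advective influx at top) - (advective outflux at bottom)
    equals the depth-integrated sulfate reduction + AOM.
    """
    p = sol.params
    phi = p.porosity
    j_diff_top = -phi * p.ds_so4 * _top_gradient(sol.so4, p.grid_step)
    j_adv_top = phi * p.omega * sol.so4[0]
    j_adv_bottom = phi * p.omega * sol.so4[-1]
    consumed = float(np.trapezoid(sol.r_sr + sol.r_aom, sol.grid))
    influx = j_diff_top + j_adv_top - j_adv_bottom
    return {
        "j_diff_top": j_diff_top,
        "j_adv_top": j_adv_top,
        "j_adv_bottom": j_adv_bottom,
        "influx": influx,
        "integrated_consumption": consumed,
        "closure_rel_error": abs(influx - consumed) / max(abs(influx), 1e-30),
    }


def ch4_budget(sol: ModelSolution) -> dict:
    """Methane balance: net production vs burial at the bottom plus escape at the top."""
    p = sol.params
    phi = p.porosity
    j_top = -phi * p.ds_ch4 * _top_gradient(sol.ch4, p.grid_step) + phi * p.omega * sol.ch4[0]
    j_bottom = phi * p.omega * sol.ch4[-1]  # zero-gradient: burial only
    net_production = float(np.trapezoid(sol.r_mg - sol.r_aom, sol.grid))
    # steady state: j_bottom - j_top = net production
    lhs = j_bottom - j_top
    return {
        "j_top": j_top,
        "burial_bottom": j_bottom,
        "net_production": net_production,
        "closure_rel_error": abs(lhs - net_production) / max(abs(net_production), 1e-30),
    }


_FREE = ("k1", "k2", "f_partition", "k_aom")


def _pack(params: DiagenesisParams) -> np.ndarray:
    f = params.f_partition
    return np.array([np.log(params.k1), np.log(params.k2),
                     np.log(f / (1 - f)), np.log(max(params.k_aom, 1e-12))])


def _unpack(x: np.ndarray, base: DiagenesisParams) -> DiagenesisParams:
    k1, k2 = np.exp(x[0]), np.exp(x[1])
    if k1 <= k2:  # fractions are exchangeable; canonicalize k1 > k2
        k1, k2 = k2, k1
        x = x.copy()
        x[2] = -x[2]
    f = 1.0 / (1.0 + np.exp(-x[2]))
    f = min(max(f, 1e-6), 1 - 1e-6)
    if k1 <= k2:
        k1 = k2 * 1.0001
    return replace(base, k1=float(k1), k2=float(k2), f_partition=float(f),
                   k_aom=float(np.exp(x[3])))


@dataclass
class CalibrationResult:
    params: DiagenesisParams
    solution: ModelSolution
    sse: float
    standard_errors: dict
    n_solver_failures: int
    quality_warning: str | None = None


def calibrate_model(
    so4_obs: DepthProfile,
    ch4_obs: DepthProfile,
    params: DiagenesisParams | None = None,
    n_polish: int = 2,
    start_factors=(0.25, 1.0, 4.0),
    f_starts=(0.25, 0.5, 0.75),
    max_nfev: int = 60,
) -> CalibrationResult:
    """Fit {k1, k2, f_partition, k_aom} to observed porewater profiles.

    Minimizes the weighted sum of squared residuals between modeled and
    observed sulfate and methane (weights 1/sigma where the profiles carry
    errors, otherwise unit weights per solute scaled by the profile maximum
    so both solutes contribute comparably).  The four parameters are
    optimized on log (rate constants) / logit (partition fraction) scales
    with a multi-start strategy: a log-spaced 3^4 grid of starting points is
    ranked by forward-model SSE and the best ``n_polish`` are refined by
    trust-region least squares.  Approximate standard errors come from the
    Gauss-Newton covariance at the optimum, delta-method-transformed back to
    the natural scale.
    """
    if params is None:
        params = DiagenesisParams()
    for prof in (so4_obs, ch4_obs):
        if len(prof) < 6:
            raise DomainError("need at least 6 observations per solute")
        if prof.depths[0] < params.z_top - 1e-9 or prof.depths[-1] > params.z_bottom + 1e-9:
            raise DomainError("observed depths outside the model domain")

    def weight(prof: DepthProfile) -> np.ndarray:
        if prof.errors is not None and np.all(prof.errors > 0):
            return 1.0 / prof.errors
        scale = max(float(np.max(np.abs(prof.values))), 1e-12)
        return np.full(len(prof), 1.0 / scale)

    w_so4, w_ch4 = weight(so4_obs), weight(ch4_obs)
    failures = [0]

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            p = _unpack(x, params)
            sol = solve_solutes(p)
        except (SolverError, DomainError):
            failures[0] += 1
            return np.full(len(so4_obs) + len(ch4_obs), 1e3)
        so4_mod = np.interp(so4_obs.depths, sol.grid, sol.so4)
        ch4_mod = np.interp(ch4_obs.depths, sol.grid, sol.ch4)
        return np.concatenate([
            w_so4 * (so4_mod - so4_obs.values),
            w_ch4 * (ch4_mod - ch4_obs.values),
        ])

    x0 = _pack(params)
    starts = []
    for a1 in start_factors:
        for a2 in start_factors:
            for fs in f_starts:
                for a4 in start_factors:
                    x = x0.copy()
                    x[0] += np.log(a1)
                    x[1] += np.log(a2)
                    x[2] = np.log(fs / (1 - fs))
                    x[3] += np.log(a4)
                    starts.append(x)
    scored = sorted(starts, key=lambda x: float(np.sum(residuals(x) ** 2)))

    best = None
    for x_start in scored[:max(1, n_polish)]:
        try:
            fit = least_squares(residuals, x_start, method="trf",
                                xtol=1e-12, ftol=1e-12, max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None:
        raise CalibrationError(f"all calibration starts failed ({failures[0]} solver failures)")

    p_fit = _unpack(best.x, params)
    sol = solve_solutes(p_fit)
    sse = float(2 * best.cost)

    # Gauss-Newton covariance on the transformed scale
    se = {}
    try:
        jtj = best.jac.T @ best.jac
        dof = max(best.fun.size - best.x.size, 1)
        cov = np.linalg.pinv(jtj) * (2 * best.cost / dof)
        sd = np.sqrt(np.maximum(np.diag(cov), 0))
        f = p_fit.f_partition
        se = {
            "k1": p_fit.k1 * sd[0],
            "k2": p_fit.k2 * sd[1],
            "f_partition": f * (1 - f) * sd[2],
            "k_aom": p_fit.k_aom * sd[3],
        }
    except np.linalg.LinAlgError:
        se = {k: np.nan for k in _FREE}

    warning = None
    data_ss = float(np.sum((w_so4 * (so4_obs.values - so4_obs.values.mean())) ** 2)
                    + np.sum((w_ch4 * (ch4_obs.values - ch4_obs.values.mean())) ** 2))
    if data_ss > 0 and sse > 0.5 * data_ss:
        warning = ("model explains less than half the weighted variance of the "
                   "observations; profiles may be incompatible with a monotone "
                   "steady-state solution")
        warnings.warn(warning, stacklevel=2)
    return CalibrationResult(p_fit, sol, sse, se, failures[0], warning)


def oc_oxidation_summary(
    sol: ModelSolution, reference_depth: float = 4.5, query_depth: float = 82.5
) -> float:
    """Carbon oxidation rate at ``query_depth`` as % of the rate at ``reference_depth``."""
    for d in (reference_depth, query_depth):
        if d < sol.grid[0] - 1e-9 or d > sol.grid[-1] + 1e-9:
            raise DomainError(f"depth {d} outside model grid")
    r_ref = float(np.interp(reference_depth, sol.grid, sol.r_c))
    r_q = float(np.interp(query_depth, sol.grid, sol.r_c))
    if r_ref == 0:
        raise DomainError("reference oxidation rate is zero; ratio undefined")
    return 100.0 * r_q / r_ref
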