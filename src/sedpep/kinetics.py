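"""Fluorogenic peptidase assay reduction and Michaelis-Menten inference.

Assays incubate sediment slurry with AMC-linked peptide substrates; free AMC
released by enzymatic hydrolysis is fluorescent, so the hydrolysis rate v0
at substrate concentration S is the increase in fluorescence between two
quench timepoints, converted to concentration with a calibration curve and
normalized to wet sediment mass:

    v0 = (dF / slope) * slurry_volume_ml / wet_mass_g / elapsed_h
         [nmol AMC g^-1 wet sediment h^-1]

Saturation curves across S are fit to the Michaelis-Menten rate law
v0 = Vmax * S / (Km + S) by nonlinear least squares, with standard errors
from the local linearization at the optimum.  When a curve cannot be fit
(e.g. rates already saturated at the lowest concentrations), the mean v0 at
the highest substrate concentration substitutes for Vmax and no Km is
reported.

Summed Vmax over substrates at one depth is a proxy for the community's
total peptidolytic potential; its standard error is the quadrature sum of
the per-substrate fit errors.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigurationError, DomainError, InvalidDesignError
from .profiles import DepthProfile

__all__ = [
    "CalibrationCurve",
    "SaturationAssay",
    "KineticFit",
    "SimpleLinearFit",
    "RatioResult",
    "SubstrateComparison",
    "michaelis_menten",
    "compute_v0",
    "fit_michaelis_menten",
    "fit_assay",
    "vmax_proxy",
    "sum_vmax",
    "compare_substrates",
    "ratio_profile",
]

ASSAY_COLUMNS = ("conc_um", "fluor_t0", "fluor_t1", "t0_h", "t1_h", "wet_mass_g", "treatment")


def michaelis_menten(s, vmax, km):
    """Michaelis-Menten rate law v0 = Vmax S / (Km + S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


@dataclass
class CalibrationCurve:
    """Fluorescence-vs-AMC-concentration calibration.

    Only the slope enters rate computation (the intercept cancels in the
    fluorescence difference between timepoints); it is retained for
    record-keeping.
    """

    slope: float  # fluorescence units per uM AMC
    intercept: float = 0.0
    r_squared: float = float("nan")

    def __post_init__(self):
        if not self.slope > 0:
            raise ConfigurationError("calibration slope must be positive")


@dataclass
class SaturationAssay:
    """One substrate x depth set of paired-timepoint fluorescence readings.

    ``records`` columns: conc_um, fluor_t0, fluor_t1, t0_h, t1_h,
    wet_mass_g, treatment ('live' or 'killed' for autoclaved controls).
    """

    substrate_label: str
    depth_cm: float
    records: pd.DataFrame
    slurry_volume_ml: float = 4.5

    def __post_init__(self):
        missing = [c for c in ASSAY_COLUMNS if c not in self.records.columns]
        if missing:
            raise ConfigurationError(f"assay records missing columns: {missing}")
        r = self.records
        if not self.slurry_volume_ml > 0:
            raise DomainError("slurry volume must be positive")
        if (r["wet_mass_g"] <= 0).any():
            raise DomainError("wet sediment mass must be positive")
        if (r["conc_um"] < 0).any():
            raise DomainError("substrate concentrations must be nonnegative")
        if (r["t1_h"] <= r["t0_h"]).any():
            raise DomainError("second quench time must be after the first")
        if not set(r["treatment"]).issubset({"live", "killed"}):
            raise DomainError("treatment must be 'live' or 'killed'")


@dataclass
class KineticFit:
    """Estimated Michaelis-Menten parameters for one substrate x depth."""

    substrate_label: str
    depth_cm: float
    vmax: float
    vmax_se: float
    km: float | None
    km_se: float | None
    fit_ok: bool
    fallback_used: bool
    residual_sd: float
    n_points: int


def compute_v0(assay: SaturationAssay, calib: CalibrationCurve) -> pd.DataFrame:
    """Reduce paired fluorescence readings to hydrolysis rates.

    Returns a table (conc_um, v0 in nmol g^-1 h^-1, treatment,
    negative_drift flag).  Negative fluorescence drifts are preserved, not
    clipped, and flagged — they carry information about the noise floor.
    """
    if calib is None:
        raise ConfigurationError("a calibration curve is required")
    r = assay.records
    elapsed = (r["t1_h"] - r["t0_h"]).to_numpy(dtype=float)
    if np.any(elapsed <= 0):
        raise DomainError("elapsed incubation time must be positive")
    dfluor = (r["fluor_t1"] - r["fluor_t0"]).to_numpy(dtype=float)
    amc_um = dfluor / calib.slope  # uM AMC released in the slurry
    # uM * mL = nmol; normalize per g wet sediment per hour
    v0 = amc_um * assay.slurry_volume_ml / r["wet_mass_g"].to_numpy(dtype=float) / elapsed
    return pd.DataFrame({
        "conc_um": r["conc_um"].to_numpy(dtype=float),
        "v0": v0,
        "treatment": r["treatment"].to_numpy(),
        "negative_drift": dfluor < 0,
    })


def _subtract_killed(v0_table: pd.DataFrame) -> pd.DataFrame:
    """Optionally subtract matched killed-control rates from live rates.

    Autoclaved controls are retained qualitatively by default because
    autoclaving does not fully destroy mineral-stabilized enzymes; this
    helper serves users who want the quantitative correction anyway.
    """
    live = v0_table[v0_table["treatment"] == "live"].copy()
    killed = (v0_table[v0_table["treatment"] == "killed"]
              .groupby("conc_um")["v0"].mean())
    live["v0"] = live["v0"] - live["conc_um"].map(killed).fillna(0.0)
    return live


def fit_michaelis_menten(
    v0_table: pd.DataFrame,
    substrate_label: str = "",
    depth_cm: float = float("nan"),
    live_only: bool = True,
    subtract_killed: bool = False,
    km_floor_frac: float = 1e-6,
) -> KineticFit:
    """Nonlinear least-squares Michaelis-Menten fit of a v0 table.

    A 3x3 log-spaced multi-start grid around (Vmax0 = max v0, Km0 = median
    S) guards against poor starts.  If no start converges, or the optimum
    collapses to the Km >= 0 boundary (rates flat across the tested
    concentrations), the fallback rule applies: Vmax is the mean v0 at the
    highest substrate concentration and no Km is reported.
    """
    tab = v0_table
    if subtract_killed:
        tab = _subtract_killed(tab)
    elif live_only:
        tab = tab[tab["treatment"] == "live"]
    s = tab["conc_um"].to_numpy(dtype=float)
    v = tab["v0"].to_numpy(dtype=float)
    nonzero = np.unique(s[s > 0])
    if nonzero.size < 4:
        raise InvalidDesignError(
            f"need >= 4 distinct nonzero substrate concentrations, got {nonzero.size}"
        )
    mask = s > 0  # the zero-substrate blank anchors calibration, not the fit
    s_fit, v_fit = s[mask], v[mask]
    n = s_fit.size

    if np.allclose(v_fit, 0.0):
        return KineticFit(substrate_label, depth_cm, 0.0, float("nan"), None, None,
                          fit_ok=False, fallback_used=False,
                          residual_sd=0.0, n_points=n)

    vmax0 = max(float(np.max(v_fit)), 1e-12)
    km0 = float(np.median(s_fit))
    best = None
    for fv in (0.3, 1.0, 3.0):
        for fk in (0.3, 1.0, 3.0):
            try:
                popt, pcov = curve_fit(
                    michaelis_menten, s_fit, v_fit,
                    p0=[vmax0 * fv, km0 * fk],
                    bounds=([0.0, 0.0], [np.inf, np.inf]),
                    xtol=1e-10, ftol=1e-10, maxfev=2000,
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((michaelis_menten(s_fit, *popt) - v_fit) ** 2))
            if best is None or sse < best[2]:
                best = (popt, pcov, sse)

    s_max = float(np.max(s_fit))
    converged = best is not None
    if converged:
        (vmax, km), pcov, sse = best
        se = np.sqrt(np.diag(pcov))
        km_degenerate = (km < km_floor_frac * s_max) or not np.isfinite(se[1])
    if not converged or km_degenerate:
        at_max = v_fit[s_fit == s_max]
        vmax_fb = float(np.mean(at_max))
        se_fb = float(np.std(at_max, ddof=1) / np.sqrt(at_max.size)) if at_max.size > 1 else float("nan")
        return KineticFit(substrate_label, depth_cm, vmax_fb, se_fb, None, None,
                          fit_ok=False, fallback_used=True,
                          residual_sd=float("nan"), n_points=n)

    dof = max(n - 2, 1)
    return KineticFit(
        substrate_label, depth_cm,
        vmax=float(vmax), vmax_se=float(se[0]),
        km=float(km), km_se=float(se[1]),
        fit_ok=True, fallback_used=False,
        residual_sd=float(np.sqrt(sse / dof)), n_points=n,
    )


def vmax_proxy(
    v0_table: pd.DataFrame,
    substrate_label: str = "",
    depth_cm: float = float("nan"),
    conc_um: float = 400.0,
) -> KineticFit:
    """Single-concentration Vmax proxy for the reduced plate-reader schema.

    Noisier assay campaigns measure v0 only at one saturating concentration
    (400 uM); that rate stands in for Vmax and no Km is estimated.  Returned
    as a fallback-style :class:`KineticFit` so it aggregates transparently.
    """
    live = v0_table[v0_table["treatment"] == "live"]
    at = live[np.isclose(live["conc_um"], conc_um)]["v0"].to_numpy(dtype=float)
    if at.size == 0:
        raise InvalidDesignError(f"no live readings at {conc_um} uM")
    se = float(np.std(at, ddof=1) / np.sqrt(at.size)) if at.size > 1 else float("nan")
    return KineticFit(substrate_label, depth_cm, float(np.mean(at)), se, None, None,
                      fit_ok=False, fallback_used=True,
                      residual_sd=float("nan"), n_points=int(at.size))


def fit_assay(assay: SaturationAssay, calib: CalibrationCurve, **kwargs) -> KineticFit:
    """Convenience: reduce an assay to v0 and fit it in one step."""
    v0 = compute_v0(assay, calib)
    return fit_michaelis_menten(v0, substrate_label=assay.substrate_label,
                                depth_cm=assay.depth_cm, **kwargs)


@dataclass
class SummedVmax:
    """Total peptidolytic potential by depth, absolute and normalized."""

    profile: DepthProfile            # sum of Vmax over substrates, +- quadrature SE
    normalized: DepthProfile | None  # profile / value at reference depth
    reference_depth: float | None


def sum_vmax(fits, reference_depth: float | None = None) -> SummedVmax:
    """Sum fitted Vmax over substrates at each depth with propagated error.

    Fits flagged neither ok nor fallback are skipped with a warning.  When
    ``reference_depth`` is given (and present), a second profile normalized
    to the summed value at that depth is returned.
    """
    fits = list(fits)
    if not fits:
        raise DomainError("empty fit list")
    usable = [f for f in fits if f.fit_ok or f.fallback_used]
    if not usable:
        raise DomainError("no usable fits (all failed without fallback)")
    if len(usable) < len(fits):
        warnings.warn(f"dropping {len(fits) - len(usable)} failed fits", stacklevel=2)
    by_depth: dict[float, list[KineticFit]] = {}
    for f in usable:
        by_depth.setdefault(float(f.depth_cm), []).append(f)
    depths = np.array(sorted(by_depth))
    totals = np.array([sum(f.vmax for f in by_depth[d]) for d in depths])
    ses = np.array([
        np.sqrt(np.nansum([f.vmax_se**2 for f in by_depth[d]])) for d in depths
    ])
    profile = DepthProfile(depths, totals, ses, label="sum Vmax (nmol g-1 h-1)")

    normalized = None
    if reference_depth is not None:
        if not (depths[0] <= reference_depth <= depths[-1]):
            raise DomainError(f"reference depth {reference_depth} outside fitted range")
        ref = float(np.interp(reference_depth, depths, totals))
        if ref == 0:
            raise DomainError("summed Vmax at reference depth is zero")
        rel_err = np.sqrt(
            (ses / np.where(totals != 0, totals, np.nan)) ** 2
            + (float(np.interp(reference_depth, depths, ses)) / ref) ** 2
        )
        normalized = DepthProfile(
            depths, totals / ref, np.abs(totals / ref) * rel_err,
            label=f"sum Vmax relative to {reference_depth} cm",
        )
    return SummedVmax(profile, normalized, reference_depth)


def _compact_letters(groups: list[str], means: dict, nonsig) -> dict:
    """Compact letter display from a non-significance relation.

    Letters are maximal cliques of the graph whose edges join groups that
    are *not* significantly different; cliques (hence letters) are ordered
    from the group with the highest mean, ties broken alphabetically.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for a in groups:
        for b in groups:
            if a < b and nonsig(a, b):
                g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    order = sorted(groups, key=lambda x: (-means[x], x))
    rank = {name: i for i, name in enumerate(order)}
    cliques.sort(key=lambda c: (min(rank[m] for m in c), sorted(c)))
    letters = {name: "" for name in groups}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for member in clique:
            letters[member] += letter
    return {k: "".join(sorted(v)) for k, v in letters.items()}


@dataclass
class SubstrateComparison:
    """Group comparison of kinetic parameters across substrates."""

    vmax_letters: dict
    km_letters: dict
    vmax_anova_p: float
    km_kruskal_p: float
    excluded: list = field(default_factory=list)


def compare_substrates(fits, alpha: float = 0.05) -> SubstrateComparison:
    """Compare substrates on log10 Vmax (ANOVA + Tukey HSD) and Km
    (Kruskal-Wallis, Tukey HSD post hoc on log10 values).

    Substrates sharing a letter are not significantly different at ``alpha``.
    Groups with fewer than two observations are excluded with a warning.
    """
    rows = [(f.substrate_label, f.vmax, f.km) for f in fits if f.fit_ok]
    df = pd.DataFrame(rows, columns=["substrate", "vmax", "km"])
    if df["substrate"].nunique() < 2:
        raise InvalidDesignError("need >= 2 substrates with successful fits")

    def prepare(col):
        d = df[df[col] > 0][["substrate", col]].dropna()
        counts = d.groupby("substrate").size()
        small = sorted(counts[counts < 2].index)
        if small:
            warnings.warn(f"excluding substrates with <2 observations: {small}",
                          stacklevel=3)
            d = d[~d["substrate"].isin(small)]
        return d, small

    dv, excl_v = prepare("vmax")
    dk, excl_k = prepare("km")

    def letters_for(d, col):
        if d["substrate"].nunique() < 2:
            return {s: "a" for s in d["substrate"].unique()}, float("nan")
        logs = np.log10(d[col].to_numpy(dtype=float))
        labels = d["substrate"].to_numpy()
        groups = sorted(set(labels))
        samples = [logs[labels == g] for g in groups]
        if col == "vmax":
            p_global = float(stats.f_oneway(*samples).pvalue)
        else:
            p_global = float(stats.kruskal(*samples).pvalue)
        tk = pairwise_tukeyhsd(logs, labels, alpha=alpha)
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        sig = {
            frozenset((r["group1"], r["group2"])): bool(r["reject"])
            for _, r in res.iterrows()
        }
        means = {g: float(np.mean(logs[labels == g])) for g in groups}
        # when the global test is not significant, all groups share one letter
        if p_global >= alpha:
            return {g: "a" for g in groups}, p_global
        lets = _compact_letters(
            groups, means, lambda a, b: not sig.get(frozenset((a, b)), False)
        )
        return lets, p_global

    vmax_letters, p_anova = letters_for(dv, "vmax")
    km_letters, p_kw = letters_for(dk, "km")
    return SubstrateComparison(vmax_letters, km_letters, p_anova, p_kw,
                               excluded=sorted(set(excl_v) | set(excl_k)))


@dataclass
class SimpleLinearFit:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    p_value: float


@dataclass
class RatioResult:
    ratio: DepthProfile
    regression: SimpleLinearFit | None


def ratio_profile(numerator: DepthProfile, denominator: DepthProfile) -> RatioResult:
    """Per-depth ratio of two activity profiles with a linear depth trend.

    Errors propagate in relative quadrature; depths with a zero denominator
    are dropped with a warning.  An ordinary least-squares line of ratio on
    depth is fit when at least three depths survive.
    """
    if len(numerator) != len(denominator) or not np.allclose(
        numerator.depths, denominator.depths
    ):
        raise DomainError("profiles must share matched depths")
    keep = denominator.values != 0
    if not keep.all():
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} depths with zero denominator",
            stacklevel=2,
        )
    z = numerator.depths[keep]
    ratio = numerator.values[keep] / denominator.values[keep]
    err = None
    if numerator.errors is not None or denominator.errors is not None:
        rel_n = (numerator.errors[keep] / numerator.values[keep]
                 if numerator.errors is not None else 0.0)
        rel_d = (denominator.errors[keep] / denominator.values[keep]
                 if denominator.errors is not None else 0.0)
        err = np.abs(ratio) * np.sqrt(np.square(rel_n) + np.square(rel_d))
    prof = DepthProfile(z, ratio, err, label=f"{numerator.label}/{denominator.label}")

    if z.size < 3:
        warnings.warn("fewer than 3 depths; regression refused", stacklevel=2)
        return RatioResult(prof, None)
    x = np.column_stack([np.ones_like(z), z])
    beta, res_ss, *_ = np.linalg.lstsq(x, ratio, rcond=None)
    fitted = x @ beta
    dof = max(z.size - 2, 1)
    s2 = float(np.sum((ratio - fitted) ** 2)) / dof
    cov = s2 * np.linalg.inv(x.T @ x)
    slope, intercept = float(beta[1]), float(beta[0])
    slope_se = float(np.sqrt(cov[1, 1]))
    tss = float(np.sum((ratio - ratio.mean()) ** 2))
    r2 = 1.0 - float(np.sum((ratio - fitted) ** 2)) / tss if tss > 0 else 1.0
    tstat = slope / slope_se if slope_se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(tstat), dof)) if np.isfinite(tstat) else 0.0
    reg = SimpleLinearFit(slope, slope_se, intercept, float(np.sqrt(cov[0, 0])), r2, p)
    return RatioResult(prof, reg)
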