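"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the field campaign's data streams so the whole chain
— assay reduction, Michaelis-Menten fitting, diagenetic calibration, index
construction and the gene census — can be exercised and validated without
any external data:

* saturation assays: paired-timepoint fluorescence readings whose expected
  rates obey the Michaelis-Menten law, plus matched autoclaved controls
  retaining a small fraction of the live rate (autoclaving does not fully
  destroy mineral-stabilized enzymes);
* porewater sulfate/methane profiles: forward solutions of the 2-G
  reaction-transport model sampled at observation depths, plus noise;
* cell counts: log-linear decline through the measured anchor points
  (4.5e8 cells ml^-1 at 1.5 cmbsf, 7.4e7 at 82.5 cmbsf) with lognormal
  noise, since counts are strictly positive;
* degraded-OM activity ratios: the d-Phe/l-Phe and Orn/l-Phe aminopeptidase
  ratio trends (slopes 5.60e-3 and 2.26e-3 per cm, intercepts 0.146 and
  0.451) with additive noise;
* a secreted-peptidase gene table with fixed per-zone totals and a family
  composition dominated by gingipain-like C25 genes among SP-positives.

All generators take explicit integer seeds; none touches global random
state.  Zero noise followed by the matching inference stage returns the
ground truth (round-trip identity), which the test-suite exploits
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagenesis import DiagenesisParams, solve_solutes
from .errors import DomainError, InvalidDesignError
from .kinetics import SaturationAssay, michaelis_menten
from .profiles import DepthProfile

__all__ = [
    "KineticGroundTruth",
    "GeochemGroundTruth",
    "DEFAULT_CONCENTRATIONS",
    "gen_saturation_assay",
    "gen_porewater_profiles",
    "gen_core_tables",
    "gen_gene_table",
    "default_kinetic_truths",
    "CELL_ANCHORS",
    "RATIO_LINES",
    "ZONE_GENE_COUNTS",
]

#: The assay concentration ladder (uM) used in the single-cuvette campaign.
DEFAULT_CONCENTRATIONS = (0.0, 25.0, 50.0, 75.0, 100.0, 200.0, 300.0)

#: (depth_cm, cells per ml wet sediment) anchor points for the count profile.
CELL_ANCHORS = ((1.5, 4.5e8), (82.5, 7.4e7))

#: Depth-trend lines for the degraded-OM activity ratios:
#: ratio = slope * depth_cm + intercept.
RATIO_LINES = {
    "d_phe_l_phe": {"slope": 5.60e-3, "intercept": 0.146},
    "orn_l_phe": {"slope": 2.26e-3, "intercept": 0.451},
}

#: Per-zone secreted-peptidase gene totals used as census defaults.
ZONE_GENE_COUNTS = {"SRZ": 685, "SMTZ": 1994, "MRZ": 1060}


@dataclass
class KineticGroundTruth:
    """True kinetic parameters behind one synthetic saturation assay."""

    substrate_label: str
    depth_cm: float
    vmax_true: float            # nmol AMC g^-1 wet sed h^-1
    km_true: float              # uM
    noise_sd: float = 0.0       # rate units (nmol g^-1 h^-1)
    killed_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not self.vmax_true > 0:
            raise DomainError("vmax_true must be positive")
        if not self.km_true > 0:
            raise DomainError("km_true must be positive")
        if not (0 <= self.killed_fraction < 1):
            raise DomainError("killed_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be nonnegative")


def gen_saturation_assay(
    gt: KineticGroundTruth,
    concentrations=DEFAULT_CONCENTRATIONS,
    incubation_h: float = 3.0,
    calib_slope: float = 2.0,
    wet_mass_g: float = 0.5,
    slurry_volume_ml: float = 4.5,
    baseline_fluor: float = 50.0,
) -> SaturationAssay:
    """Simulate paired-timepoint fluorescence readings for one assay.

    For each concentration S the live hydrolysis rate is
    Vmax S / (Km + S) + N(0, noise_sd); a matched killed-control record
    retains ``killed_fraction`` of the noiseless live rate (plus its own
    noise draw).  Rates are converted back to fluorescence increments with
    the same unit chain the reduction stage inverts, so a zero-noise assay
    round-trips exactly.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise DomainError("substrate concentrations must be nonnegative")
    if np.unique(conc).size < 4:
        raise InvalidDesignError("need at least 4 distinct substrate concentrations")
    if incubation_h <= 0:
        raise DomainError("incubation time must be positive")
    rng = np.random.default_rng(gt.seed)

    rows = []
    for treatment, factor in (("live", 1.0), ("killed", gt.killed_fraction)):
        for s in conc:
            rate = michaelis_menten(s, gt.vmax_true, gt.km_true) * factor
            if gt.noise_sd > 0:
                rate = rate + rng.normal(0.0, gt.noise_sd)
            # invert the reduction: v0 [nmol/g/h] -> fluorescence increment
            dfluor = rate * calib_slope * wet_mass_g * incubation_h / slurry_volume_ml
            rows.append({
                "conc_um": s,
                "fluor_t0": baseline_fluor,
                "fluor_t1": baseline_fluor + dfluor,
                "t0_h": 0.0,
                "t1_h": incubation_h,
                "wet_mass_g": wet_mass_g,
                "treatment": treatment,
            })
    return SaturationAssay(
        substrate_label=gt.substrate_label,
        depth_cm=gt.depth_cm,
        records=pd.DataFrame(rows),
        slurry_volume_ml=slurry_volume_ml,
    )


#: Core sections were 3 cm thick and cores reached ~85 cm, so porewater
#: observations default to 3-cm midpoint spacing over the upper 85 cm.
DEFAULT_PROFILE_DEPTHS = tuple(np.arange(4.5, 85.0, 3.0))


@dataclass
class GeochemGroundTruth:
    """True model configuration behind synthetic porewater profiles.

    Noise is specified either as absolute standard deviations per solute
    (``profile_noise_sd_*``, in mM) or as a shared proportional level
    (``noise_rel``: sd_i = noise_rel * (|value_i| + 0.01 * profile max),
    the small floor standing in for the instrument detection limit).  If
    ``noise_rel`` is set it takes precedence.
    """

    params: DiagenesisParams = field(default_factory=DiagenesisParams)
    profile_noise_sd_so4: float = 0.0   # mM
    profile_noise_sd_ch4: float = 0.0   # mM
    noise_rel: float | None = None
    depths_cm: tuple = DEFAULT_PROFILE_DEPTHS
    seed: int = 0

    def __post_init__(self):
        d = np.asarray(self.depths_cm, dtype=float)
        if d.size < 2 or not np.all(np.diff(d) > 0):
            raise DomainError("depths must be strictly increasing")
        if d[0] < self.params.z_top - 1e-9 or d[-1] > self.params.z_bottom + 1e-9:
            raise DomainError("sample depths outside the model domain")


def gen_porewater_profiles(gt: GeochemGroundTruth):
    """Forward-model sulfate and methane profiles sampled with noise.

    Returns ``(so4, ch4)`` DepthProfiles in mM whose noiseless values equal
    the converged model solution at the sample depths; additive Gaussian
    noise per the configured standard deviations (absolute or proportional),
    seed-reproducible.  Solver non-convergence propagates as SolverError.
    """
    sol = solve_solutes(gt.params)
    depths = np.asarray(gt.depths_cm, dtype=float)
    rng = np.random.default_rng(gt.seed)
    out = []
    for values, sd_abs, label in (
        (np.interp(depths, sol.grid, sol.so4), gt.profile_noise_sd_so4, "sulfate (mM)"),
        (np.interp(depths, sol.grid, sol.ch4), gt.profile_noise_sd_ch4, "methane (mM)"),
    ):
        if gt.noise_rel is not None and gt.noise_rel > 0:
            scale = max(float(np.max(np.abs(values))), 1e-12)
            sd = gt.noise_rel * (np.abs(values) + 0.01 * scale)
        elif sd_abs > 0:
            sd = np.full(depths.size, sd_abs)
        else:
            sd = None
        if sd is not None:
            values = values + rng.normal(0.0, 1.0, depths.size) * sd
        out.append(DepthProfile(depths, values, sd, label=label))
    return tuple(out)


def gen_core_tables(
    seed: int,
    depth_grid,
    cell_noise_rel: float = 0.0,
    ratio_noise_sd: float = 0.0,
):
    """Cell-count profile and degraded-OM activity-ratio series.

    Cell counts log-linearly interpolate (and, off the anchor interval,
    extrapolate) the two measured anchors with multiplicative lognormal
    noise of log-sd ``cell_noise_rel``.  The two activity-ratio series
    follow their regression lines with additive Gaussian noise.

    Returns ``(cells, ratios)`` where ratios maps series name ->
    DepthProfile.
    """
    z = np.asarray(depth_grid, dtype=float)
    if not np.all(np.diff(z) > 0):
        raise DomainError("depth grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    (z0, n0), (z1, n1) = CELL_ANCHORS
    slope = (np.log10(n1) - np.log10(n0)) / (z1 - z0)
    cells = 10 ** (np.log10(n0) + slope * (z - z0))
    if cell_noise_rel > 0:
        cells = cells * np.exp(rng.normal(0.0, cell_noise_rel, z.size))
    cell_err = cells * cell_noise_rel if cell_noise_rel > 0 else None
    cells_profile = DepthProfile(z, cells, cell_err, label="cells ml-1 wet sediment")

    ratios = {}
    for name, line in RATIO_LINES.items():
        vals = line["slope"] * z + line["intercept"]
        if ratio_noise_sd > 0:
            vals = vals + rng.normal(0.0, ratio_noise_sd, z.size)
        err = np.full(z.size, ratio_noise_sd) if ratio_noise_sd > 0 else None
        ratios[name] = DepthProfile(z, vals, err, label=name)
    return cells_profile, ratios


# Family composition of the synthetic gene table.  Shares of SP-positive
# genes: gingipain-like C25 dominates; methionine aminopeptidases (M24) and
# zinc carboxypeptidases (M20) follow.
_SP_FAMILY_SHARES = {
    "C25": 0.43, "M24": 0.16, "M20": 0.15, "M28": 0.08, "S24": 0.05,
    "M50": 0.04, "M1": 0.03, "M3": 0.02, "M29": 0.02, "M61": 0.02,
}
_NONSP_FAMILY_SHARES = {
    "C25": 0.20, "M24": 0.14, "M20": 0.12, "M28": 0.12, "S8": 0.10,
    "S9": 0.08, "M16": 0.08, "C26": 0.06, "S33": 0.06, "M13": 0.04,
}
_SP_TOOLS = ("sp_predisi", "sp_predsignal", "sp_psort", "sp_signalp")


def _largest_remainder(total: int, shares: dict) -> dict:
    """Integer counts per key matching ``shares`` and summing to ``total``."""
    keys = list(shares)
    raw = np.array([shares[k] for k in keys], dtype=float)
    raw = raw / raw.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return dict(zip(keys, base))


def gen_gene_table(
    seed: int = 0,
    zone_counts: dict | None = None,
    sp_fraction: float = 0.40,
    tool_sensitivity: float = 0.6,
) -> pd.DataFrame:
    """Synthetic secreted-peptidase gene annotation table.

    Per-zone totals and family shares are deterministic (largest-remainder
    apportionment), so census arithmetic on the defaults is exact; the seed
    only randomizes which predictor tools flag each SP-positive gene (each
    SP gene is guaranteed at least one flag; additional tools fire with
    probability ``tool_sensitivity``) and the row order.
    """
    if zone_counts is None:
        zone_counts = dict(ZONE_GENE_COUNTS)
    rng = np.random.default_rng(seed)
    rows = []
    for zone, n_zone in zone_counts.items():
        n_sp = int(round(sp_fraction * n_zone))
        sp_fams = _largest_remainder(n_sp, _SP_FAMILY_SHARES)
        nonsp_fams = _largest_remainder(n_zone - n_sp, _NONSP_FAMILY_SHARES)
        i = 0
        for fam, n in sp_fams.items():
            for _ in range(n):
                flags = {t: bool(rng.random() < tool_sensitivity) for t in _SP_TOOLS}
                if not any(flags.values()):
                    flags[_SP_TOOLS[rng.integers(len(_SP_TOOLS))]] = True
                rows.append({"gene_id": f"{zone}_{i:05d}", "zone": zone,
                             "family": fam, **flags})
                i += 1
        for fam, n in nonsp_fams.items():
            for _ in range(n):
                rows.append({"gene_id": f"{zone}_{i:05d}", "zone": zone,
                             "family": fam, **{t: False for t in _SP_TOOLS}})
                i += 1
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


# Default substrate mix for a full synthetic kinetics campaign.  Shares of
# the summed hydrolysis potential and base half-saturation constants are
# chosen so that tripeptide endopeptidase substrates and Gly-AMC are fastest,
# Arg-AMC slowest, and Leu-AMC shows the weakest substrate affinity.
_SUBSTRATE_MIX = {
    # label: (share of summed Vmax, base Km in uM)
    "AAF-AMC": (0.28, 180.0),
    "Z-GGR-AMC": (0.26, 80.0),
    "Gly-AMC": (0.20, 150.0),
    "Leu-AMC": (0.12, 400.0),
    "Boc-VPR-AMC": (0.09, 70.0),
    "Arg-AMC": (0.05, 90.0),
}

#: Assayed depth horizons (cm) for the synthetic campaign and the summed
#: Vmax anchors (nmol g^-1 h^-1) at the reference and deepest horizons.
KINETIC_DEPTHS = (1.5, 4.5, 28.5, 58.5, 82.5)
SUM_VMAX_SURFACE = 9090.0   # at 4.5 cm
SUM_VMAX_DEEP = 1240.0      # at 82.5 cm


def default_kinetic_truths(seed: int = 0, noise_rel: float = 0.0) -> list[KineticGroundTruth]:
    """Ground-truth table for a full substrate x depth kinetics campaign.

    Summed Vmax declines log-linearly with depth through the two anchors
    (9.09 umol g^-1 h^-1 at 4.5 cm, 1.24 at 82.5 cm); per-substrate Vmax
    follows fixed shares of the sum, and Km declines linearly with depth
    (higher substrate affinity in deeper, more degraded organic matter).
    ``noise_rel`` sets each assay's noise_sd as a fraction of its true Vmax.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(_SUBSTRATE_MIX) * len(KINETIC_DEPTHS)) % (2**31)
    decay = np.log(SUM_VMAX_DEEP / SUM_VMAX_SURFACE) / (82.5 - 4.5)
    truths = []
    i = 0
    for depth in KINETIC_DEPTHS:
        total = SUM_VMAX_SURFACE * np.exp(decay * (depth - 4.5))
        km_factor = 1.4 - 0.8 * (depth - 1.5) / (82.5 - 1.5)  # 1.4 -> 0.6
        for label, (share, km_base) in _SUBSTRATE_MIX.items():
            vmax = share * total
            truths.append(KineticGroundTruth(
                substrate_label=label,
                depth_cm=depth,
                vmax_true=float(vmax),
                km_true=float(km_base * km_factor),
                noise_sd=float(noise_rel * vmax),
                seed=int(seeds[i]),
            ))
            i += 1
    return truths
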