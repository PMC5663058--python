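"""Synthetic vineyard campaign generator with known ground truth.

Emulates a single midday flight over a drip-irrigated vineyard under three
irrigation treatments — well-watered (W), cover crop (C) and drought (D) —
at the meteorological conditions of the emulated campaign (31.4 degC,
41.7 % RH, 0.91 m/s wind, 659.5 W/m2 shortwave). Per-plant canopy
conductances are drawn lognormally around treatment means of
0.15 / 0.04 / 0.02 mol m-2 s-1 (W/C/D); thermal scenes paint each canopy at
the forward energy-balance temperature for its true resistance, add Gaussian
sensor noise (0.05 K, the camera sensitivity class used in such campaigns),
and include wet/dry reference patches. Leaf stomatal conductance and stem
sap flow are noisy linear functions of true canopy conductance, and the
metabolome is a 60-metabolite matrix in which a small influential subset is
linearly linked to conductance (malate and myo-inositol positively, caffeate
and the flavonols negatively) over structured noise.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import MetaboliteMatrix
from .micromet import MetConditions, air_properties, resistance_set
from .scene import ROI, ThermalScene
from .thermal import R_GAS, forward_delta_t, model_reference_temps

__all__ = [
    "DEFAULT_TREATMENT_MEANS",
    "DEFAULT_INFLUENTIAL",
    "GroundTruth",
    "SceneLayout",
    "generate_met",
    "generate_design",
    "generate_true_conductance",
    "render_scene",
    "generate_physiology",
    "generate_metabolome",
]

#: Treatment-mean canopy conductances (mol m-2 s-1): watered, cover crop, drought.
DEFAULT_TREATMENT_MEANS = {"W": 0.15, "C": 0.04, "D": 0.02}

#: Influential metabolites and the sign of their link to conductance.
#: Malate (guard-cell osmoticum) and myo-inositol track conductance
#: positively; caffeate and the flavonol glycosides accumulate under stress,
#: hence link negatively.
DEFAULT_INFLUENTIAL = {
    "malate": 1.0,
    "myo-inositol": 1.0,
    "caffeate": -1.0,
    "quercetin-3-O-galactoside": -1.0,
    "kaempferol-3-O-galactoside": -1.0,
    "kaempferol-3-O-glucoside": -1.0,
}

# Background metabolite names typical of a grapevine leaf GC/LC-MS panel.
_BACKGROUND_NAMES = [
    "valine", "isoleucine", "threonine", "asparagine", "glutamine", "serine",
    "glycine", "lysine", "tyrosine", "tryptophan", "ornithine", "proline",
    "putrescine", "spermine", "GABA", "citrate", "isocitrate", "succinate",
    "fumarate", "pyruvate", "maleate", "glutarate", "glycerate",
    "butyric-acid", "erythronic-acid", "2-oxo-gulonic-acid", "ascorbate",
    "galactonic-acid-1-4-lactone", "galacturonic-acid", "glucuronic-acid",
    "glucose", "fructose", "sucrose", "maltose", "isomaltose", "ribose",
    "altrose", "galactinol", "raffinose", "trehalose", "phosphorate",
    "shikimate", "quinate", "caffeoylquinate", "quercetin-3-O-glucoside",
    "quercetin-3-O-glucuronide", "quercetin-3-O-rutinoside",
    "kaempferol-3-O-rutinoside", "myricetin-3-O-glucuronide",
    "myricetin-3-O-glucoside", "catechin", "epicatechin", "resveratrol",
    "coumarate",
]


@dataclass
class GroundTruth:
    """True per-plant state behind a synthetic campaign.

    ``plants`` has columns plant_id, treatment, g_mol (true canopy
    conductance, mol m-2 s-1), r_c (s m-1); ``influential`` maps each
    conductance-linked metabolite to its signed effect; ``met`` is the
    weather snapshot; ``seed`` the master seed.
    """

    plants: pd.DataFrame
    met: MetConditions
    seed: int
    influential: dict[str, float] = field(default_factory=dict)
    noise: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.plants.to_csv(path, index=False)


@dataclass(frozen=True)
class SceneLayout:
    """Row-structured scene geometry, mimicking a vineyard planted in rows.

    One row of canopies per treatment, ``patch``-pixel square canopies
    separated by ``gap`` pixels of soil; wet/dry reference targets in the top
    margin. Default pixel size 0.025 m (2.5 cm/pixel imagery).
    """

    patch: int = 12
    gap: int = 8
    margin: int = 18
    ref_size: int = 10
    pixel_size: float = 0.025


def generate_met(seed: int | None = None, jitter_sd: float = 0.0, **overrides) -> MetConditions:
    """Weather snapshot; defaults are the emulated flight conditions.

    ``jitter_sd`` adds relative Gaussian jitter (fraction of each default) to
    Ta/RH/u/SWR, seeded; overrides replace individual fields outright.
    """
    base = {"Ta": 31.4, "RH": 41.7, "u": 0.91, "SWR": 659.5, "P": 101325.0}
    base.update(overrides)
    if jitter_sd > 0.0:
        rng = np.random.default_rng(seed)
        for key in ("Ta", "RH", "u", "SWR"):
            base[key] = base[key] * (1.0 + jitter_sd * rng.standard_normal())
        base["RH"] = float(np.clip(base["RH"], 0.0, 100.0))
        base["u"] = max(base["u"], 0.0)
        base["SWR"] = max(base["SWR"], 0.0)
    return MetConditions(**base)


def generate_design(n_per_treatment: int = 6) -> pd.DataFrame:
    """Treatment assignment: W/C/D labels, default 6 plants each (n = 18)."""
    if n_per_treatment < 1:
        raise ValueError("n_per_treatment must be >= 1")
    rows = [
        {"plant_id": f"{t}{i + 1:02d}", "treatment": t}
        for t in ("W", "C", "D")
        for i in range(n_per_treatment)
    ]
    return pd.DataFrame(rows)


def generate_true_conductance(
    design: pd.DataFrame,
    treatment_means: dict[str, float] | None = None,
    cv: float = 0.4,
    seed: int = 0,
    met: MetConditions | None = None,
) -> GroundTruth:
    """Draw per-plant true conductances lognormally around treatment means.

    A lognormal with coefficient of variation ``cv`` keeps conductances
    positive and right-skewed; ``cv = 0`` puts every plant exactly at its
    treatment mean. True canopy resistance follows from the ideal-gas molar
    conversion r_c = P / (R T_K g_mol).
    """
    means = dict(DEFAULT_TREATMENT_MEANS if treatment_means is None else treatment_means)
    met = generate_met() if met is None else met
    rng = np.random.default_rng(seed)
    g = np.empty(len(design))
    for i, t in enumerate(design["treatment"]):
        m = means[t]
        if cv == 0.0:
            g[i] = m
        else:
            sigma2 = np.log1p(cv**2)
            mu = np.log(m) - sigma2 / 2.0
            g[i] = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
    r_c = met.P / (R_GAS * (met.Ta + 273.15) * g)
    plants = design.copy()
    plants["g_mol"] = g
    plants["r_c"] = r_c
    return GroundTruth(
        plants=plants, met=met, seed=seed, influential=dict(DEFAULT_INFLUENTIAL),
        noise={"conductance_cv": cv},
    )


def render_scene(
    truth: GroundTruth,
    met: MetConditions | None = None,
    layout: SceneLayout | None = None,
    sensor_noise_sd: float = 0.05,
    seed: int = 0,
    emissivity_canopy: float = 0.96,
    emissivity_reference: float = 0.95,
) -> ThermalScene:
    """Paint a brightness-temperature raster from the forward energy balance.

    Each canopy patch is painted at Ta + forward ΔT(r_c) for its plant's true
    resistance, wet/dry reference patches at the energy-balance reference
    temperatures, and the soil background hotter than the dry reference.
    Surface temperatures are converted to brightness through the graybody
    emissivity for the region type (so extraction, which inverts that
    correction, recovers the painted surface temperatures exactly at zero
    noise), then Gaussian sensor noise of ``sensor_noise_sd`` K is added.
    Plant and reference ROIs are attached to the returned scene.
    """
    met = truth.met if met is None else met
    layout = layout or SceneLayout()
    air = air_properties(met)
    res = resistance_set(met, emissivity=emissivity_canopy)
    refs = model_reference_temps(met.Ta, air, res)

    treatments = list(dict.fromkeys(truth.plants["treatment"]))
    per_row = {t: truth.plants[truth.plants["treatment"] == t] for t in treatments}
    n_cols = max(len(v) for v in per_row.values())
    step = layout.patch + layout.gap
    height = layout.margin + len(treatments) * step + layout.gap
    width = max(layout.gap + n_cols * step, 3 * (layout.ref_size + layout.gap))

    soil_K = refs.T_dry + 273.15 + 3.0  # bare soil runs hotter than the dry reference
    grid = np.full((height, width), soil_K * emissivity_canopy**0.25)
    rois: list[ROI] = []

    for row_i, t in enumerate(treatments):
        for col_i, plant in enumerate(per_row[t].itertuples()):
            Ts_K = met.Ta + forward_delta_t(plant.r_c, air, res) + 273.15
            r0 = layout.margin + row_i * step
            c0 = layout.gap + col_i * step
            rect = (r0, c0, r0 + layout.patch, c0 + layout.patch)
            grid[rect[0]:rect[2], rect[1]:rect[3]] = Ts_K * emissivity_canopy**0.25
            rois.append(ROI(name=plant.plant_id, kind="plant", rect=rect, treatment=t))

    for i, (kind, T) in enumerate((("wet", refs.T_wet), ("dry", refs.T_dry))):
        r0, c0 = 2, layout.gap + i * (layout.ref_size + layout.gap)
        rect = (r0, c0, r0 + layout.ref_size, c0 + layout.ref_size)
        grid[rect[0]:rect[2], rect[1]:rect[3]] = (T + 273.15) * emissivity_reference**0.25
        rois.append(ROI(name=f"{kind}_ref", kind=kind, rect=rect))

    if sensor_noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, sensor_noise_sd, size=grid.shape)

    return ThermalScene(
        grid=grid,
        pixel_size=layout.pixel_size,
        rois=rois,
        emissivity_canopy=emissivity_canopy,
        emissivity_reference=emissivity_reference,
    )


def generate_physiology(
    truth: GroundTruth,
    gs_slope: float = 1.0,
    gs_noise_sd: float | None = None,
    target_r2: float = 0.75,
    sap_slope: float = 0.23,
    sap_intercept: float = 0.005,
    sap_noise_sd: float | None = None,
    sap_target_r2: float = 0.78,
    sap_two_treatments: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Leaf stomatal conductance and stem sap flow linked to true g_c.

    g_s = gs_slope * g_c + eps, with the noise SD either given or calibrated
    from the realised conductance spread so the population R2 between g_c and
    g_s equals ``target_r2`` (R2 = var(signal) / (var(signal) + sd_eps^2));
    likewise for sap flow (l min-1 m-2). With ``sap_two_treatments`` sap flow
    is generated only for the W and D treatments, as when gauges are
    installed in only two treatments. Values are floored at a small positive
    number (a conductance measurement cannot be negative).
    """
    rng = np.random.default_rng(seed)
    g = truth.plants["g_mol"].to_numpy()

    def _calibrated_sd(signal: np.ndarray, r2: float) -> float:
        if not (0.0 < r2 < 1.0):
            raise ValueError("target R2 must lie in (0, 1)")
        return float(np.std(signal, ddof=1) * np.sqrt(1.0 / r2 - 1.0))

    sd_gs = _calibrated_sd(gs_slope * g, target_r2) if gs_noise_sd is None else gs_noise_sd
    gs = gs_slope * g + rng.normal(0.0, sd_gs, size=len(g))
    gs = np.maximum(gs, 1e-4)

    sap_signal = sap_slope * g + sap_intercept
    sd_sap = _calibrated_sd(sap_signal, sap_target_r2) if sap_noise_sd is None else sap_noise_sd
    sap = sap_signal + rng.normal(0.0, sd_sap, size=len(g))
    sap = np.maximum(sap, 1e-5)

    out = truth.plants[["plant_id", "treatment"]].copy()
    out["gs"] = gs
    out["sap_flow"] = sap
    if sap_two_treatments:
        out.loc[out["treatment"] == "C", "sap_flow"] = np.nan
    return out


def generate_metabolome(
    truth: GroundTruth,
    n_metabolites: int = 60,
    influential: dict[str, float] | None = None,
    effect_size: float = 1.0,
    noise_sd: float = 1.0 / 3.0,
    missing_rate: float = 0.02,
    correlation: float = 0.3,
    block_size: int = 6,
    baseline: float = 10.0,
    seed: int = 0,
) -> MetaboliteMatrix:
    """Plants x metabolites abundances with a conductance-linked subset.

    Influential metabolite j follows ``baseline + sign_j * effect_size * z +
    eps``, where z is the standardised true conductance and eps is Gaussian
    with SD ``noise_sd`` (defaults give signal-to-noise 3). The remaining
    metabolites are structured noise: blocks of ``block_size`` share a latent
    factor with inter-metabolite correlation ``correlation``, plus the same
    baseline offset so abundances stay positive (relative, dry-matter-basis
    scale). ``missing_rate`` of cells are then masked uniformly at random.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    if not (0.0 <= correlation < 1.0):
        raise ValueError("correlation must lie in [0, 1)")
    influential = dict(truth.influential if influential is None else influential)
    if len(influential) > n_metabolites:
        raise ValueError("more influential metabolites than total metabolites")

    n_bg = n_metabolites - len(influential)
    names_bg = list(_BACKGROUND_NAMES[:n_bg])
    names_bg += [f"metabolite_{i + 1:02d}" for i in range(n_bg - len(names_bg))]
    names = list(influential) + names_bg

    rng = np.random.default_rng(seed)
    g = truth.plants["g_mol"].to_numpy()
    z = (g - g.mean()) / g.std(ddof=1)
    n = len(g)

    X = np.empty((n, n_metabolites))
    for j, (_, sign) in enumerate(influential.items()):
        X[:, j] = baseline + sign * effect_size * z + rng.normal(0.0, noise_sd, n)
    k0 = len(influential)
    n_blocks = int(np.ceil(n_bg / block_size)) if n_bg else 0
    factors = rng.standard_normal((n, max(n_blocks, 1)))
    for j in range(n_bg):
        shared = np.sqrt(correlation) * factors[:, j // block_size]
        unique = np.sqrt(1.0 - correlation) * rng.standard_normal(n)
        X[:, k0 + j] = baseline + shared + unique

    values = pd.DataFrame(X, index=truth.plants["plant_id"].to_numpy(), columns=names)
    if missing_rate > 0.0:
        mask = rng.random(values.shape) < missing_rate
        # never blank out an entire metabolite
        for j in range(n_metabolites):
            if mask[:, j].all():
                mask[rng.integers(n), j] = False
        values = values.mask(mask)
    treatments = pd.Series(
        truth.plants["treatment"].to_numpy(), index=values.index, name="treatment"
    )
    return MetaboliteMatrix(values=values, treatments=treatments)
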