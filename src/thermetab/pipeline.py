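"""End-to-end orchestration: simulate or ingest, extract, model, report.

``run_full`` drives the whole analysis on a synthetic campaign: render a
thermal scene from known ground truth, extract canopy and reference
temperatures, compute thermal indices and invert the energy balance to
canopy conductance, benchmark conductance and indices against leaf-level
physiology, summarise treatments (ANOVA + Tukey letters, log2 fold-changes
vs the watered control), and link the metabolome to conductance with
cross-validated PLS and VIP ranking. Everything is deterministic given the
config seed; all tables are written as CSV, with optional PNG figures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import chemometrics as chem
from . import stats as tstats
from . import synthetic as syn
from .micromet import MetConditions, air_properties, resistance_set
from .scene import PlantThermalRecord, ThermalScene, extract_all
from .thermal import (
    ReferenceTemps,
    cwsi,
    i3_index,
    ig_index,
    invert_canopy_resistance,
    resistance_to_molar_conductance,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "conductance_table",
    "benchmark_regressions",
    "run_full",
]

log = logging.getLogger("thermetab")


@dataclass
class RunConfig:
    """Configuration for a full synthetic-campaign run.

    All simulation knobs default to the emulated study conditions: 18 plants
    in three treatments, treatment-mean conductances 0.15/0.04/0.02
    mol m-2 s-1, 0.05 K sensor noise, a 60-metabolite matrix with six
    influential metabolites at signal-to-noise 3, physiology noise calibrated
    for a population g_c-g_s R2 of 0.75.
    """

    seed: int = 0
    n_per_treatment: int = 6
    treatment_means: dict[str, float] = field(
        default_factory=lambda: dict(syn.DEFAULT_TREATMENT_MEANS)
    )
    conductance_cv: float = 0.4
    sensor_noise_sd: float = 0.05
    gs_target_r2: float = 0.75
    n_metabolites: int = 60
    effect_size: float = 1.0
    metabolite_noise_sd: float = 1.0 / 3.0
    missing_rate: float = 0.02
    metabolite_correlation: float = 0.3
    imputation: str = "iterative"
    max_comp: int = 10
    cv_scheme: str = "loo"
    alpha: float = 0.05
    emissivity_canopy: float = 0.96
    emissivity_reference: float = 0.95
    trim_fraction: float = 0.05
    met_overrides: dict[str, float] = field(default_factory=dict)
    outdir: str | None = None
    plots: bool = False

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_per_treatment < 2:
            raise ValueError("need >= 2 plants per treatment for inference")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.cv_scheme not in ("loo", "kfold"):
            raise ValueError(f"unknown CV scheme {self.cv_scheme!r}")
        if self.imputation not in ("iterative", "mean", "knn"):
            raise ValueError(f"unknown imputation method {self.imputation!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunResult:
    """Bundle of every table a full run produces."""

    config: RunConfig
    truth: syn.GroundTruth
    scene: ThermalScene
    refs: ReferenceTemps
    plant_table: pd.DataFrame
    regressions: pd.DataFrame
    treatment_summary: pd.DataFrame
    log2fc: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_variance: np.ndarray
    pls: dict[str, dict]


def conductance_table(
    records: list[PlantThermalRecord],
    refs: ReferenceTemps,
    met: MetConditions,
    emissivity: float = 0.96,
) -> pd.DataFrame:
    """Per-plant thermal indices and inverted canopy conductance.

    One row per plant: canopy and reference temperatures, CWSI/IG/I3,
    canopy-air difference, canopy resistance (s m-1), molar conductance
    (mol m-2 s-1) and the inversion quality flag.
    """
    air = air_properties(met)
    res = resistance_set(met, emissivity=emissivity)
    rows = []
    for rec in records:
        r_c, flag = invert_canopy_resistance(rec.Tc, met.Ta, air, res)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows.append(
                {
                    "plant_id": rec.plant_id,
                    "treatment": rec.treatment,
                    "Tc_C": rec.Tc,
                    "Twet_C": refs.T_wet,
                    "Tdry_C": refs.T_dry,
                    "CWSI": cwsi(rec.Tc, refs.T_wet, refs.T_dry),
                    "IG": ig_index(rec.Tc, refs.T_wet, refs.T_dry),
                    "I3": i3_index(rec.Tc, refs.T_wet, refs.T_dry),
                    "dT_K": rec.Tc - met.Ta,
                    "rc_s_m": r_c,
                    "gc_mol_m2_s": resistance_to_molar_conductance(r_c, met.Ta, met.P)
                    if r_c > 0
                    else np.inf,
                    "quality_flag": flag,
                }
            )
    return pd.DataFrame(rows)


def benchmark_regressions(
    table: pd.DataFrame,
    predictors: tuple[str, ...] = ("CWSI", "IG", "I3", "dT_K", "gc_mol_m2_s"),
    responses: tuple[str, ...] = ("gs", "sap_flow"),
) -> pd.DataFrame:
    """Ordinary least-squares benchmarking of thermal metrics vs physiology.

    For every (predictor, response) pair with at least three paired finite
    observations: slope, intercept, R2 and the regression p value. Pairs
    with too few observations are skipped with a warning.
    """
    rows = []
    for resp in responses:
        if resp not in table.columns:
            continue
        for pred in predictors:
            pair = table[[pred, resp]].replace([np.inf, -np.inf], np.nan).dropna()
            if len(pair) < 3:
                warnings.warn(
                    f"skipping {resp} ~ {pred}: only {len(pair)} paired observations",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            fit = sps.linregress(pair[pred], pair[resp])
            rows.append(
                {
                    "response": resp,
                    "predictor": pred,
                    "n": len(pair),
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r2": fit.rvalue**2,
                    "p": fit.pvalue,
                }
            )
    return pd.DataFrame(rows)


def _treatment_summary(
    table: pd.DataFrame, variables: list[str], alpha: float
) -> pd.DataFrame:
    """Table-1-style summary: mean +/- SE with Tukey letters per variable."""
    rows = []
    order = ["W", "C", "D"]
    for var in variables:
        try:
            comp = tstats.compare_treatments(
                table, table["treatment"], var, alpha=alpha, group_order=order
            )
        except ValueError as err:
            log.warning("treatment summary for %s skipped: %s", var, err)
            continue
        for g in comp.means.index:
            rows.append(
                {
                    "variable": var,
                    "treatment": g,
                    "mean": comp.means[g],
                    "sem": comp.sems[g],
                    "letters": comp.letters[g],
                    "anova_F": comp.F,
                    "anova_p": comp.p,
                }
            )
    return pd.DataFrame(rows)


def _metabolite_log2fc(
    matrix: chem.MetaboliteMatrix, alpha: float, control: str = "W"
) -> pd.DataFrame:
    """Significance-gated log2 fold-changes vs control for every metabolite."""
    df = matrix.values.copy()
    rows = []
    for met_name in df.columns:
        try:
            comp = tstats.compare_treatments(
                df, matrix.treatments, met_name, control=control, alpha=alpha,
                group_order=["W", "C", "D"],
            )
        except ValueError as err:
            log.warning("log2FC for %s skipped: %s", met_name, err)
            continue
        for r in comp.log2fc.itertuples():
            rows.append(
                {
                    "metabolite": met_name,
                    "treatment": r.treatment,
                    "log2fc": r.log2fc,
                    "significant": r.significant,
                    "anova_p": comp.p,
                }
            )
    return pd.DataFrame(rows)


def _fit_pls_block(
    X: pd.DataFrame, y: np.ndarray, cfg: RunConfig, cv_seed: int
) -> dict:
    cv = chem.cross_validate(
        X, y, max_comp=cfg.max_comp, scheme=cfg.cv_scheme, seed=cv_seed
    )
    model = chem.pls_fit(X, y, n_comp=cv.n_comp)
    vip = chem.vip_scores(model)
    return {"cv": cv, "model": model, "vip": vip}


def run_full(config: RunConfig) -> RunResult:
    """Execute the full synthetic campaign analysis (see module docstring)."""
    cfg = config
    master = np.random.default_rng(cfg.seed)
    sub = master.integers(2**31, size=6)

    log.info("stage: simulate (seed=%d)", cfg.seed)
    met = syn.generate_met(**cfg.met_overrides)
    design = syn.generate_design(cfg.n_per_treatment)
    truth = syn.generate_true_conductance(
        design, cfg.treatment_means, cv=cfg.conductance_cv, seed=int(sub[0]), met=met
    )
    scene = syn.render_scene(
        truth,
        met,
        sensor_noise_sd=cfg.sensor_noise_sd,
        seed=int(sub[1]),
        emissivity_canopy=cfg.emissivity_canopy,
        emissivity_reference=cfg.emissivity_reference,
    )

    log.info("stage: extract")
    records, refs = extract_all(scene, trim_fraction=cfg.trim_fraction)
    table = conductance_table(records, refs, met, emissivity=cfg.emissivity_canopy)

    log.info("stage: physiology + benchmarking")
    phys = syn.generate_physiology(
        truth, target_r2=cfg.gs_target_r2, seed=int(sub[2])
    )
    table = table.merge(phys, on=["plant_id", "treatment"], how="left")
    regressions = benchmark_regressions(table)

    log.info("stage: treatment statistics")
    summary = _treatment_summary(
        table, ["gc_mol_m2_s", "gs", "sap_flow", "Tc_C", "CWSI"], cfg.alpha
    )

    log.info("stage: metabolome")
    matrix = syn.generate_metabolome(
        truth,
        n_metabolites=cfg.n_metabolites,
        effect_size=cfg.effect_size,
        noise_sd=cfg.metabolite_noise_sd,
        missing_rate=cfg.missing_rate,
        correlation=cfg.metabolite_correlation,
        seed=int(sub[3]),
    )
    imputed = chem.impute_missing(matrix, method=cfg.imputation, seed=int(sub[4]))
    log2fc = _metabolite_log2fc(imputed, cfg.alpha)
    pca_scores, pca_var = chem.pca_overview(imputed.values, n_comp=5)

    log.info("stage: PLS / VIP")
    X = imputed.values
    responses = {
        "gc": table.set_index("plant_id")["gc_mol_m2_s"].reindex(X.index).to_numpy(),
        "gs": table.set_index("plant_id")["gs"].reindex(X.index).to_numpy(),
    }
    pls = {
        name: _fit_pls_block(X, y, cfg, cv_seed=int(sub[5]))
        for name, y in responses.items()
    }

    result = RunResult(
        config=cfg,
        truth=truth,
        scene=scene,
        refs=refs,
        plant_table=table,
        regressions=regressions,
        treatment_summary=summary,
        log2fc=log2fc,
        pca_scores=pca_scores,
        pca_variance=pca_var,
        pls=pls,
    )
    if cfg.outdir is not None:
        _write_outputs(result, Path(cfg.outdir))
    return result


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    cfg.to_yaml(outdir / "config.yaml")
    result.truth.to_csv(outdir / "ground_truth.csv")
    result.plant_table.to_csv(outdir / "plant_conductance.csv", index=False)
    result.regressions.to_csv(outdir / "benchmark_regressions.csv", index=False)
    result.treatment_summary.to_csv(outdir / "treatment_summary.csv", index=False)
    result.log2fc.to_csv(outdir / "metabolite_log2fc.csv", index=False)
    result.pca_scores.to_csv(outdir / "pca_scores.csv")
    pd.DataFrame(
        {"component": np.arange(1, len(result.pca_variance) + 1),
         "explained_variance_fraction": result.pca_variance}
    ).to_csv(outdir / "pca_variance.csv", index=False)
    for name, block in result.pls.items():
        block["cv"].to_frame().to_csv(outdir / f"pls_{name}_cv.csv", index=False)
        coef = block["model"].coefficients()
        vip = block["vip"]
        pd.DataFrame(
            {
                "metabolite": coef.index,
                "coefficient": coef.to_numpy(),
                "vip": vip.vip.reindex(coef.index).to_numpy(),
                "above_mean_vip": vip.above_mean.reindex(coef.index).to_numpy(),
            }
        ).to_csv(outdir / f"pls_{name}_coefficients.csv", index=False)
    (outdir / "run_summary.json").write_text(
        json.dumps(
            {
                "n_plants": int(len(result.plant_table)),
                "T_wet": result.refs.T_wet,
                "T_dry": result.refs.T_dry,
                "pls_n_comp": {k: int(v["cv"].n_comp) for k, v in result.pls.items()},
            },
            indent=1,
        )
    )
    if cfg.plots:
        _write_plots(result, outdir)


def _write_plots(result: RunResult, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.plant_table
    colors = {"W": "tab:green", "C": "tab:red", "D": "black"}

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for tr, grp in t.groupby("treatment"):
        ax.scatter(grp["gc_mol_m2_s"], grp["gs"], label=tr, color=colors.get(tr))
    ax.set_xlabel(r"$g_c$ (mol m$^{-2}$ s$^{-1}$)")
    ax.set_ylabel(r"$g_s$ (mol m$^{-2}$ s$^{-1}$)")
    ax.legend(title="treatment")
    fig.tight_layout()
    fig.savefig(outdir / "gc_vs_gs.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for name, block in result.pls.items():
        curve = block["cv"].to_frame()
        ax.plot(curve["n_comp"], curve["rmsep_adj"], marker="o", label=name)
    ax.set_xlabel("components")
    ax.set_ylabel("adjusted RMSEP")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "pls_cv_curves.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    sc = result.pca_scores
    for tr in colors:
        sel = result.truth.plants["treatment"].to_numpy() == tr
        ax.scatter(sc.iloc[sel, 0], sc.iloc[sel, 1], label=tr, color=colors[tr])
    ax.set_xlabel(f"PC1 ({result.pca_variance[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({result.pca_variance[1] * 100:.1f}%)")
    ax.legend(title="treatment")
    fig.tight_layout()
    fig.savefig(outdir / "pca_scores.png", dpi=120)
    plt.close(fig)
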