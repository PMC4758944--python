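"""Seeded synthetic-data generators emulating the three wet-lab instruments.

Each generator produces data with the statistical structure the matching
analysis stage assumes, so every pipeline is testable end-to-end without
instrument files:

* :func:`gen_dialysis` — two-chamber rapid equilibrium dialysis.  Protein
  stays behind the membrane in the sample chamber; ligand partitions until
  the free concentration is equal on both sides.  For each total load the
  generator solves the ligand mass balance for the free concentration
  under the chosen binding isotherm (bracketed root finding) and reports
  the two chamber concentrations, optionally with measurement noise
  applied to the chamber readouts (spectrophotometric noise acts on the
  measured concentrations, not the loads).

* :func:`gen_radial_scan` — sedimentation-equilibrium absorbance profiles
  from :func:`vlbind.sedimentation.predict_profile` plus noise.

* :func:`gen_tht` — sigmoidal (logistic) fibril-growth curves whose
  plateau is suppressed by a Hill dose-response,
  ``plateau(c) = A / (1 + (c/IC50)^h)``, with replicated seeded noise.

Identical seed and configuration give bit-identical output.  Presets
bundle the published parameter sets for the two study ligands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .binding_models import (
    BindingCurve,
    CooperativeParams,
    EquivalentNSParams,
    bound_cooperative,
    bound_equivalent_ns,
)
from .dialysis import DEFAULT_MONOMER_MASS_DA, DialysisExperiment, receptor_conc_uM
from .sedimentation import (
    DEFAULT_SOLVENT_DENSITY,
    DEFAULT_TEMPERATURE_K,
    RadialScan,
    SpeciesComponent,
    predict_profile,
)
from .tht import THT_DOSE_GRID_MM, ThTTimeCourse

__all__ = [
    "GeneratorConfig",
    "gen_dialysis",
    "gen_binding_curve",
    "gen_radial_scan",
    "gen_tht",
    "tht_plateau",
    "PRESETS",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducibility and noise settings shared by all generators."""

    seed: int = 0
    noise_model: str = "none"  # none | gaussian_absolute | gaussian_relative
    noise_scale: float = 0.0  # AU/μM for absolute, fraction for relative
    n_experiments: int = 1

    def __post_init__(self) -> None:
        if self.noise_model not in {"none", "gaussian_absolute", "gaussian_relative"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")
        if self.n_experiments < 1:
            raise ValueError("need at least one experiment")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(values: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if cfg.noise_model == "none" or cfg.noise_scale == 0.0:
        return values.copy()
    if cfg.noise_model == "gaussian_absolute":
        sd = np.full_like(values, cfg.noise_scale)
    else:
        sd = cfg.noise_scale * np.abs(values)
    return values + rng.normal(0.0, 1.0, size=values.shape) * sd


def _bound_function(model: str, params, adair: bool):
    if model == "cooperative":
        return lambda u: bound_cooperative(u, params, adair=adair)
    if model == "equivalent_ns":
        return lambda u: bound_equivalent_ns(u, params)
    raise ValueError(f"unknown model {model!r}")


def _equilibrate(total: float, bound_of_u, volume_ratio: float) -> tuple[float, float]:
    """Free and bound concentrations at dialysis equilibrium for one load.

    Solves the ligand mass balance
    ``(U + B(U))·V_s + U·V_r = total·(V_s + V_r)`` for the free
    concentration U, with ``volume_ratio = V_s / V_r``.
    """
    if total == 0.0:
        return 0.0, 0.0
    vs, vr = volume_ratio, 1.0

    def h(u: float) -> float:
        return (u + bound_of_u(u)) * vs + u * vr - total * (vs + vr)

    # h(0) = -total(vs+vr) < 0 and h(total) = B(total)·vs >= 0
    u = brentq(h, 0.0, total, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    return u, float(bound_of_u(u))


def gen_binding_curve(
    model: str,
    params,
    ligand_totals: np.ndarray,
    *,
    volume_ratio: float = 1.0,
    adair: bool = False,
    experiment_id: str = "",
) -> BindingCurve:
    """Noiseless (free, bound) curve at dialysis equilibrium for given loads."""
    bound_of_u = _bound_function(model, params, adair)
    pairs = [_equilibrate(float(t), bound_of_u, volume_ratio) for t in ligand_totals]
    free = np.array([p[0] for p in pairs])
    bound = np.array([p[1] for p in pairs])
    return BindingCurve(
        free=free, bound=bound, total=np.asarray(ligand_totals, float), experiment_id=experiment_id
    )


def gen_dialysis(
    model: str,
    params,
    protein_mg_ml: float,
    ligand_totals: np.ndarray,
    cfg: GeneratorConfig,
    *,
    monomer_mass_da: float = DEFAULT_MONOMER_MASS_DA,
    volume_ratio: float = 1.0,
    ligand_name: str = "ligand",
    adair: bool = False,
    id_prefix: str | None = None,
) -> list[DialysisExperiment]:
    """Simulate ``cfg.n_experiments`` independent dialysis experiments.

    The receptor concentration implied by ``protein_mg_ml`` overrides the
    ``r0`` stored in ``params`` so the simulated plate is internally
    consistent.  Noise is applied to the chamber concentrations
    (post-equilibrium), never to the loads.  Relative noise is modelled as
    a per-well multiplicative calibration/dilution error shared by the two
    chambers of a well (they are read in the same spectrophotometric run),
    so the bound-ligand difference inherits the nominal relative error;
    absolute noise is an independent photometric floor per chamber.
    """
    r0 = receptor_conc_uM(protein_mg_ml, model, monomer_mass_da)
    params = replace(params, r0=r0)
    totals = np.asarray(ligand_totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("ligand totals must be positive")

    curve = gen_binding_curve(model, params, totals, volume_ratio=volume_ratio, adair=adair)
    sample_true = curve.free + curve.bound
    reference_true = curve.free

    rng = cfg.rng()
    exps = []
    for i in range(cfg.n_experiments):
        if cfg.noise_model == "gaussian_relative" and cfg.noise_scale > 0:
            # shared per-well calibration error: chambers of one well scale together
            eps = 1.0 + rng.normal(0.0, cfg.noise_scale, size=totals.shape)
            sample = np.maximum(sample_true * eps, 0.0)
            reference = np.maximum(reference_true * eps, 0.0)
        else:
            sample = np.maximum(_apply_noise(sample_true, cfg, rng), 0.0)
            reference = np.maximum(_apply_noise(reference_true, cfg, rng), 0.0)
        series = np.column_stack([totals, sample, reference])
        exps.append(
            DialysisExperiment(
                experiment_id=f"{id_prefix or ligand_name}_exp{i:02d}",
                protein_mg_ml=protein_mg_ml,
                ligand_name=ligand_name,
                series=series,
                chamber_volume_ratio=volume_ratio,
            )
        )
    return exps


def gen_radial_scan(
    species: list[SpeciesComponent],
    rpm: float,
    r_range: tuple[float, float] = (6.9, 7.2),
    n_points: int = 120,
    cfg: GeneratorConfig = GeneratorConfig(),
    *,
    baseline: float = 0.05,
    solvent_density: float = DEFAULT_SOLVENT_DENSITY,
    temperature: float = DEFAULT_TEMPERATURE_K,
    wavelength: float = 500.0,
    ligand_name: str = "",
) -> RadialScan:
    """Simulate one sedimentation-equilibrium radial absorbance scan.

    Evaluates the multi-species exponential profile over ``n_points``
    radii and applies the configured noise.  Cell coordinates must lie in
    the physical rotor range [5.8, 7.3] cm.
    """
    lo, hi = r_range
    if not (5.8 <= lo < hi <= 7.3):
        raise ValueError("radial range must lie within [5.8, 7.3] cm")
    radii = np.linspace(lo, hi, n_points)
    profile = predict_profile(
        radii, species, baseline=baseline, solvent_density=solvent_density,
        rotor_rpm=rpm, temperature=temperature,
    )
    absorbance = _apply_noise(profile, cfg, cfg.rng())
    return RadialScan(
        radius=radii, absorbance=absorbance, rotor_rpm=rpm,
        temperature=temperature, wavelength=wavelength, ligand_name=ligand_name,
    )


def tht_plateau(conc_mM: float, control_plateau: float, ic50_mM: float, hill: float) -> float:
    """Hill dose-response plateau: A / (1 + (c/IC50)^h); halves at c = IC50."""
    if conc_mM == 0.0:
        return control_plateau
    return control_plateau / (1.0 + (conc_mM / ic50_mM) ** hill)


def gen_tht(
    dose_ic50: float,
    hill: float,
    growth: tuple[float, float, float] = (500.0, 20.0, 0.4),
    grid: np.ndarray = THT_DOSE_GRID_MM,
    n_replicates: int = 3,
    cfg: GeneratorConfig = GeneratorConfig(),
    *,
    t_max_h: float = 60.0,
    n_time: int = 121,
) -> list[ThTTimeCourse]:
    """Simulate a ThT dose grid with a ligand-free control.

    ``growth = (plateau AU, midpoint h, rate 1/h)`` defines the control
    logistic ``A / (1 + exp(−rate·(t − t50)))``; at ligand concentration c
    the plateau is scaled by the Hill factor ``1/(1 + (c/IC50)^hill)``.
    Each concentration (and the control, coded as c=0) is replicated
    ``n_replicates`` times with seeded noise.
    """
    if dose_ic50 <= 0 or hill <= 0:
        raise ValueError("IC50 and Hill coefficient must be positive")
    amp, t50, rate = growth
    time = np.linspace(0.0, t_max_h, n_time)
    shape = 1.0 / (1.0 + np.exp(-rate * (time - t50)))

    rng = cfg.rng()
    courses = []
    for conc in (0.0, *np.asarray(grid, dtype=float)):
        plateau = tht_plateau(conc, amp, dose_ic50, hill)
        clean = plateau * shape
        for rep in range(n_replicates):
            courses.append(
                ThTTimeCourse(
                    time=time,
                    fluorescence=np.maximum(_apply_noise(clean, cfg, rng), 0.0),
                    ligand_conc=conc,
                    replicate=rep,
                    is_control=(conc == 0.0),
                )
            )
    return courses


# ---------------------------------------------------------------------------
# Published parameter presets for the two study ligands

PRESETS: dict[str, dict] = {
    "methylene_blue": {
        "model": "cooperative",
        "params": CooperativeParams(k1=207.0, k2=21.0, r0=42.0),  # r0 overridden per protein load
        "protein_mg_ml": (0.5, 1.0),
        "ligand_totals": np.geomspace(1.0, 200.0, 12),
        "ligand_mw": 319.85,  # Da, free dye
        "auc": {
            "monomer_mw": DEFAULT_MONOMER_MASS_DA,
            "dimer_mw": 23_609.0,
            "rpms": (10_000, 14_000, 22_000, 35_000),
            "wavelength": 500.0,
        },
        "tht": {"ic50_mM": 0.15, "hill": 6.0},
        "n_experiments": 8,
    },
    "sulfasalazine": {
        "model": "equivalent_ns",
        # ns carries the published numeric value; see module docs on units
        "params": EquivalentNSParams(k1=698.0, ns=21.0, r0=424.0),
        "protein_mg_ml": (2.5, 5.0),
        "ligand_totals": np.geomspace(100.0, 5000.0, 12),
        "ligand_mw": 398.39,
        "auc": {
            "monomer_mw": DEFAULT_MONOMER_MASS_DA,
            "dimer_mw": 21_989.0,
            "rpms": (10_000, 14_000, 22_000),
            "wavelength": 420.0,
        },
        "tht": {"ic50_mM": 0.08, "hill": 6.0},
        "n_experiments": 6,
    },
}
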