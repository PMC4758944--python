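"""Sedimentation-equilibrium analysis of radial absorbance profiles.

At sedimentation equilibrium each ideal species adopts an exponential
radial concentration distribution in the centrifuge cell,

    A(r) = baseline + Σ_i a_i · exp[ σ_i · (r² − r_ref²) / 2 ],

with the reduced buoyant parameter

    σ_i = M_i (1 − v̄_i ρ) ω² / (R T)        [cm⁻²]

where M_i is the molar mass (g/mol), v̄ the partial specific volume (ml/g),
ρ the solvent density (g/ml), ω the rotor angular velocity (rad/s), R the
gas constant and T the temperature.  Fitting one or two exponential terms
to a scan yields apparent molecular weights; an apparent mass above the
dimer mass signals a multimer admixture, and a high-speed (meniscus
depletion) run clears heavy species from the inner cell so that any light
(monomeric) ligand-bound species would remain detectable near the meniscus.

Detection here is at the ligand's absorbance wavelength, so only
ligand-bound protein (plus free ligand) contributes signal.  Free ligand
(~320–400 Da) has a near-zero σ at these speeds and is absorbed into the
baseline term by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "RadialScan",
    "SpeciesComponent",
    "AUCFitResult",
    "MonomerCheckResult",
    "buoyant_sigma",
    "predict_profile",
    "fit_apparent_mw",
    "classify_oligomer",
    "meniscus_depletion_monomer_check",
    "read_scan_csv",
    "write_scan_csv",
    "R_GAS_CGS",
    "DEFAULT_V_BAR",
    "DEFAULT_SOLVENT_DENSITY",
    "DEFAULT_TEMPERATURE_K",
]

R_GAS_CGS = 8.31446261815324e7  # erg / (mol K); yields sigma in cm^-2
DEFAULT_V_BAR = 0.73  # ml/g, typical globular protein
DEFAULT_SOLVENT_DENSITY = 1.00  # g/ml, dilute aqueous buffer
DEFAULT_TEMPERATURE_K = 293.15  # equilibrium runs at 20 degC


@dataclass
class RadialScan:
    """One equilibrium absorbance-vs-radius profile with rotor conditions."""

    radius: np.ndarray  # cm, strictly increasing, meniscus -> base
    absorbance: np.ndarray  # AU
    rotor_rpm: float
    temperature: float = DEFAULT_TEMPERATURE_K  # K
    wavelength: float = 500.0  # nm
    ligand_name: str = ""

    def __post_init__(self) -> None:
        self.radius = np.asarray(self.radius, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.radius.ndim != 1 or self.radius.shape != self.absorbance.shape:
            raise ValueError("radius and absorbance must be 1-D arrays of equal length")
        if np.any(np.diff(self.radius) <= 0):
            raise ValueError("radii must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.rotor_rpm <= 0 or self.temperature <= 0:
            raise ValueError("rotor speed and temperature must be positive")

    @property
    def n_points(self) -> int:
        return self.radius.size


@dataclass(frozen=True)
class SpeciesComponent:
    """One ideal sedimenting species contributing an exponential term."""

    ref_absorbance: float  # AU at the reference radius
    molar_mass: float  # Da
    partial_specific_volume: float = DEFAULT_V_BAR  # ml/g
    label: str = "dimer_complex"

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")
        if self.label in {"monomer_complex", "dimer_complex", "multimer"} and not (
            0.5 < self.partial_specific_volume < 1.0
        ):
            raise ValueError("protein partial specific volume must lie in (0.5, 1.0) ml/g")


@dataclass
class AUCFitResult:
    """Result of fitting exponential species terms to one radial scan."""

    apparent_mw: float  # Da, dominant species
    apparent_mw_se: float  # Da
    baseline: float  # AU
    rss: float  # AU^2
    oligomer_state: str
    converged: bool = True
    species: tuple[SpeciesComponent, ...] = ()
    species_mw_se: tuple[float, ...] = ()


@dataclass
class MonomerCheckResult:
    """Outcome of the high-speed meniscus-depletion monomer search."""

    monomer_signal_fraction: float
    detectable: bool  # False when below the reporting floor
    floor: float
    fit: AUCFitResult


def buoyant_sigma(
    molar_mass: float,
    v_bar: float = DEFAULT_V_BAR,
    solvent_density: float = DEFAULT_SOLVENT_DENSITY,
    rotor_rpm: float = 22_000.0,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Reduced buoyant parameter σ = M(1 − v̄ρ)ω²/(RT), in cm⁻²."""
    omega = 2.0 * np.pi * rotor_rpm / 60.0
    return molar_mass * (1.0 - v_bar * solvent_density) * omega**2 / (R_GAS_CGS * temperature)


def predict_profile(
    radii: np.ndarray,
    species: list[SpeciesComponent],
    baseline: float = 0.0,
    solvent_density: float = DEFAULT_SOLVENT_DENSITY,
    rotor_rpm: float = 22_000.0,
    temperature: float = DEFAULT_TEMPERATURE_K,
    r_ref: float | None = None,
) -> np.ndarray:
    """Equilibrium absorbance profile of a species mixture.

    ``r_ref`` defaults to the first (meniscus-side) radius.  A species with
    v̄ρ = 1 is neutrally buoyant (flat contribution); v̄ρ > 1 with positive
    mass gives a negative σ (floating species) — permitted, but the caller
    should treat it as non-physical for proteins.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or radii.size == 0:
        raise ValueError("radii must be a non-empty 1-D array")
    if solvent_density <= 0:
        raise ValueError("solvent density must be positive")
    if r_ref is None:
        r_ref = float(radii[0])
    xi = (radii**2 - r_ref**2) / 2.0
    profile = np.full_like(radii, float(baseline))
    for sp in species:
        sigma = buoyant_sigma(
            sp.molar_mass, sp.partial_specific_volume, solvent_density, rotor_rpm, temperature
        )
        profile = profile + sp.ref_absorbance * np.exp(sigma * xi)
    return profile


def _sigma_to_mass(sigma: float, v_bar: float, rho: float, rpm: float, temp: float) -> float:
    return sigma / buoyant_sigma(1.0, v_bar, rho, rpm, temp)


def _init_single(scan: RadialScan, v_bar: float, rho: float) -> tuple[float, float, float]:
    """Crude (baseline, amplitude, mass) seed from the log-profile slope."""
    a = scan.absorbance
    baseline0 = float(a.min()) - 0.05 * float(np.ptp(a)) - 1e-6
    signal = a - baseline0
    xi = (scan.radius**2 - scan.radius[0] ** 2) / 2.0
    slope = np.polyfit(xi, np.log(np.maximum(signal, 1e-12)), 1)[0]
    mass0 = _sigma_to_mass(max(slope, 1e-3), v_bar, rho, scan.rotor_rpm, scan.temperature)
    mass0 = float(np.clip(mass0, 500.0, 5e6))
    return baseline0, float(signal[0]), mass0


def fit_apparent_mw(
    scan: RadialScan,
    n_species: int = 1,
    v_bar: float = DEFAULT_V_BAR,
    solvent_density: float = DEFAULT_SOLVENT_DENSITY,
    *,
    monomer_mw: float | None = None,
    tolerance: float = 0.10,
    fixed_masses: tuple[float | None, ...] | None = None,
) -> AUCFitResult:
    """Fit a one- or two-exponential species model to a radial scan.

    Amplitudes and molar masses are fitted in log-space with the baseline
    free on the natural scale.  ``fixed_masses`` pins individual species
    masses (None = floated), which the meniscus-depletion check uses to
    anchor one species at the monomer mass.  The oligomer label is assigned
    from the dominant species (largest integrated signal) when
    ``monomer_mw`` is given, otherwise left as ``"unclassified"``.
    """
    if n_species not in (1, 2):
        raise ValueError("n_species must be 1 or 2")
    if scan.n_points < 20:
        raise ValueError("need at least 20 radial points")
    if float(np.ptp(scan.absorbance)) < 1e-12:
        raise ValueError("flat profile: neutrally buoyant or empty cell; no mass information")

    if fixed_masses is None:
        fixed_masses = (None,) * n_species
    if len(fixed_masses) != n_species:
        raise ValueError("fixed_masses must have one entry per species")

    r = scan.radius
    a_obs = scan.absorbance
    xi = (r**2 - r[0] ** 2) / 2.0
    sigma_per_dalton = buoyant_sigma(1.0, v_bar, solvent_density, scan.rotor_rpm, scan.temperature)

    free_mass_idx = [i for i, m in enumerate(fixed_masses) if m is None]

    def unpack(theta):
        amps = np.exp(theta[:n_species])
        masses = np.array([m if m is not None else 0.0 for m in fixed_masses], dtype=float)
        for j, i in enumerate(free_mass_idx):
            masses[i] = np.exp(theta[n_species + j])
        baseline = theta[-1]
        return amps, masses, baseline

    def model(theta):
        amps, masses, baseline = unpack(theta)
        prof = np.full_like(xi, baseline)
        for amp, mass in zip(amps, masses):
            prof = prof + amp * np.exp(sigma_per_dalton * mass * xi)
        return prof

    def residuals(theta):
        return model(theta) - a_obs

    baseline0, amp0, mass0 = _init_single(scan, v_bar, solvent_density)
    mass_seeds: list[list[float]]
    if n_species == 1:
        mass_seeds = [[m] for m in (mass0, mass0 / 2, mass0 * 2, 12_000.0, 24_000.0)]
    else:
        mass_seeds = [
            [mass0 / 2, mass0],
            [mass0, 2 * mass0],
            [mass0 / 2, 2 * mass0],
            [12_000.0, 24_000.0],
        ]

    best = None
    for seed in mass_seeds:
        theta0 = np.concatenate(
            [
                np.log(np.full(n_species, max(amp0 / n_species, 1e-8))),
                [np.log(seed[i]) for i in free_mass_idx],
                [baseline0],
            ]
        )
        try:
            res = least_squares(
                residuals, theta0, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimisation starts failed")

    amps, masses, baseline = unpack(best.x)
    rss = float(2.0 * best.cost)
    n_params = best.x.size
    dof = max(scan.n_points - n_params, 1)

    se_theta = np.full(n_params, np.inf)
    try:
        cov = (rss / dof) * np.linalg.inv(best.jac.T @ best.jac)
        diag = np.diag(cov)
        with np.errstate(invalid="ignore"):
            se_theta = np.sqrt(np.where(diag >= 0, diag, np.nan))
    except np.linalg.LinAlgError:
        pass
    mass_se = np.zeros(n_species)
    for j, i in enumerate(free_mass_idx):
        s = se_theta[n_species + j]
        mass_se[i] = masses[i] * s if np.isfinite(s) else np.inf

    # dominant species by integrated (baseline-free) signal over the cell
    contributions = np.array(
        [
            np.trapezoid(amp * np.exp(sigma_per_dalton * mass * xi), r)
            for amp, mass in zip(amps, masses)
        ]
    )
    dominant = int(np.argmax(contributions))
    apparent_mw = float(masses[dominant])
    apparent_mw_se = float(mass_se[dominant])

    state = "unclassified"
    if monomer_mw is not None:
        state = classify_oligomer(apparent_mw, monomer_mw, tolerance)

    converged = bool(best.success and np.all(np.isfinite(masses)) and np.all(masses > 0))
    species = tuple(
        SpeciesComponent(
            ref_absorbance=float(amp),
            molar_mass=float(mass),
            partial_specific_volume=v_bar,
            label="fitted",
        )
        for amp, mass in zip(amps, masses)
    )
    return AUCFitResult(
        apparent_mw=apparent_mw,
        apparent_mw_se=apparent_mw_se,
        baseline=float(baseline),
        rss=rss,
        oligomer_state=state,
        converged=converged,
        species=species,
        species_mw_se=tuple(map(float, mass_se)),
    )


def classify_oligomer(
    apparent_mw: float,
    monomer_mw: float,
    tolerance: float = 0.10,
    trimer_bound_factor: float = 3.0,
) -> str:
    """Label an apparent molecular weight relative to the monomer mass.

    Within ``tolerance`` (fractional) of the monomer or dimer mass the
    corresponding state is returned, ties broken toward the lower state.
    Masses above the dimer band but below ``trimer_bound_factor × monomer``
    are labelled ``dimer_plus_multimer`` (a dimer population with a heavier
    admixture); anything heavier is ``multimer``.  A mass falling in the
    gap between the monomer and dimer bands is assigned to the nearer of
    the two, again preferring the lower state on a tie.
    """
    if monomer_mw <= 0:
        raise ValueError("monomer mass must be positive")
    if not 0 < tolerance < 0.5:
        raise ValueError("tolerance must lie in (0, 0.5)")
    dimer_mw = 2.0 * monomer_mw
    if abs(apparent_mw - monomer_mw) <= tolerance * monomer_mw:
        return "monomer"
    if abs(apparent_mw - dimer_mw) <= tolerance * dimer_mw:
        return "dimer"
    if apparent_mw > (1.0 + tolerance) * dimer_mw:
        if apparent_mw > trimer_bound_factor * monomer_mw:
            return "multimer"
        return "dimer_plus_multimer"
    # below the dimer band and outside the monomer band: nearest state
    return "monomer" if abs(apparent_mw - monomer_mw) <= abs(apparent_mw - dimer_mw) else "dimer"


def meniscus_depletion_monomer_check(
    scan_high_speed: RadialScan,
    monomer_mw: float,
    v_bar: float = DEFAULT_V_BAR,
    solvent_density: float = DEFAULT_SOLVENT_DENSITY,
    *,
    floor: float = 0.02,
) -> MonomerCheckResult:
    """Quantify the monomer share of signal in a high-speed depletion run.

    Fits a two-species model with one mass pinned at ``monomer_mw`` (the
    other floated, seeded at the dimer) and returns the fraction of the
    baseline-subtracted integrated signal carried by the pinned monomer
    term.  Fractions below ``floor`` are flagged as "no detectable
    monomer"; the high rotor speed is required because only then are the
    heavy species depleted from the meniscus region where a light species
    would stand out.
    """
    if scan_high_speed.rotor_rpm < 30_000:
        raise ValueError("meniscus-depletion analysis requires rotor speed >= 30,000 rpm")
    fit = fit_apparent_mw(
        scan_high_speed,
        n_species=2,
        v_bar=v_bar,
        solvent_density=solvent_density,
        monomer_mw=monomer_mw,
        fixed_masses=(monomer_mw, None),
    )
    r = scan_high_speed.radius
    xi = (r**2 - r[0] ** 2) / 2.0
    sigma_per_dalton = buoyant_sigma(
        1.0, v_bar, solvent_density, scan_high_speed.rotor_rpm, scan_high_speed.temperature
    )
    signals = np.array(
        [
            np.trapezoid(sp.ref_absorbance * np.exp(sigma_per_dalton * sp.molar_mass * xi), r)
            for sp in fit.species
        ]
    )
    total = float(signals.sum())
    frac = float(signals[0] / total) if total > 0 else 0.0
    return MonomerCheckResult(
        monomer_signal_fraction=frac, detectable=frac >= floor, floor=floor, fit=fit
    )


# ---------------------------------------------------------------------------
# I/O

SCAN_COLUMNS = ["radius_cm", "absorbance", "rpm", "temperature_K", "wavelength_nm"]


def read_scan_csv(path) -> RadialScan:
    """Read one radial scan from CSV (radius_cm, absorbance, rpm, temperature_K, wavelength_nm)."""
    df = pd.read_csv(path)
    missing = {"radius_cm", "absorbance", "rpm"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return RadialScan(
        radius=df["radius_cm"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
        rotor_rpm=float(df["rpm"].iloc[0]),
        temperature=float(df["temperature_K"].iloc[0]) if "temperature_K" in df else DEFAULT_TEMPERATURE_K,
        wavelength=float(df["wavelength_nm"].iloc[0]) if "wavelength_nm" in df else 500.0,
        ligand_name=str(df["ligand"].iloc[0]) if "ligand" in df else "",
    )


def write_scan_csv(scan: RadialScan, path) -> None:
    pd.DataFrame(
        {
            "radius_cm": scan.radius,
            "absorbance": scan.absorbance,
            "rpm": scan.rotor_rpm,
            "temperature_K": scan.temperature,
            "wavelength_nm": scan.wavelength,
            "ligand": scan.ligand_name,
        }
    ).to_csv(path, index=False)
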