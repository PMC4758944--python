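"""Equilibrium-dialysis pipeline: chamber measurements → binding constants.

In rapid equilibrium dialysis the protein is retained behind a low-cutoff
membrane (8 kDa here, far below the ~24 kDa V_L dimer) while the small
ligand equilibrates freely between the sample and reference chambers.  At
equilibrium the reference chamber reports the free ligand concentration [U]
and the excess in the sample chamber reports bound ligand
[B] = sample − reference.

The pipeline fits the two isotherms of :mod:`vlbind.binding_models` to
(U, B) pairs by unweighted nonlinear least squares, one fit per independent
experiment, then aggregates fitted constants across experiments as
mean ± SEM — the quantity conventionally reported as <K> (SEM) with N the
number of experiments.

Dissociation constants are fitted in log-space (positivity for free), with
a deterministic multistart over a log-spaced grid when no initial guess is
given.  Standard errors are asymptotic, from the Jacobian at the optimum,
mapped back to the natural scale by the delta method.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .binding_models import (
    BindingCurve,
    CooperativeParams,
    EquivalentNSParams,
    InsufficientDataError,
    bound_cooperative,
    bound_equivalent_ns,
)

__all__ = [
    "DialysisExperiment",
    "FitResult",
    "MultiExperimentSummary",
    "protein_molar_uM",
    "receptor_conc_uM",
    "bound_free_from_chambers",
    "fit_binding_model",
    "summarize_experiments",
    "read_dialysis_csv",
    "write_dialysis_csv",
    "fit_report_frame",
    "fit_report_json",
    "DEFAULT_MONOMER_MASS_DA",
]

# Typical immunoglobulin V_L domain monomer mass; configurable everywhere it
# is used because the exact construct mass varies between light chains.
DEFAULT_MONOMER_MASS_DA = 11_800.0

MODEL_PARAM_NAMES = {
    "cooperative": ("k1", "k2"),
    "equivalent_ns": ("k1", "ns"),
}


def protein_molar_uM(protein_mg_ml: float, monomer_mass_da: float = DEFAULT_MONOMER_MASS_DA) -> float:
    """Convert a protein mass concentration (mg/ml) to monomer μM."""
    if monomer_mass_da <= 0:
        raise ValueError("monomer mass must be positive")
    return protein_mg_ml / monomer_mass_da * 1e6


def receptor_conc_uM(
    protein_mg_ml: float,
    model: str,
    monomer_mass_da: float = DEFAULT_MONOMER_MASS_DA,
) -> float:
    """Receptor concentration r0 implied by the protein load, per model.

    The cooperative model's receptor is the V_L dimer (half the monomer
    concentration); the equivalent-sites model's r0 is the total
    specific-site concentration, two sites per dimer, i.e. numerically the
    monomer concentration.
    """
    monomer = protein_molar_uM(protein_mg_ml, monomer_mass_da)
    if model == "cooperative":
        return monomer / 2.0
    if model == "equivalent_ns":
        return monomer
    raise ValueError(f"unknown model {model!r}")


@dataclass
class DialysisExperiment:
    """One independent two-chamber dialysis experiment.

    ``series`` rows are (total_uM, sample_chamber_uM, reference_chamber_uM).
    The sample chamber holds the protein, so sample >= reference up to a
    noise tolerance.
    """

    experiment_id: str
    protein_mg_ml: float
    ligand_name: str
    series: np.ndarray  # shape (n, 3): total, sample, reference
    chamber_volume_ratio: float = 1.0

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        if self.series.ndim != 2 or self.series.shape[1] != 3:
            raise ValueError("series must have columns (total, sample, reference)")
        if np.any(self.series < 0):
            raise ValueError("concentrations must be non-negative")
        total, sample, reference = self.series.T
        # bound ligand accumulates on the protein side; allow measurement noise
        tol = 0.25 * (1.0 + reference)
        if np.any(sample < reference - tol):
            raise ValueError("sample chamber far below reference chamber: not an equilibrium state")
        if self.chamber_volume_ratio <= 0:
            raise ValueError("chamber volume ratio must be positive")

    def protein_molar(self, monomer_mass_da: float = DEFAULT_MONOMER_MASS_DA) -> float:
        """Protein monomer concentration in μM."""
        return protein_molar_uM(self.protein_mg_ml, monomer_mass_da)


@dataclass
class FitResult:
    """Outcome of a least-squares fit of one binding model to one experiment."""

    model: str
    params: dict[str, float]
    std_errors: dict[str, float]
    rss: float
    converged: bool
    n_points: int
    experiment_id: str = ""
    r0: float = 0.0

    def params_object(self):
        """Reconstruct the typed parameter object for the fitted model."""
        if self.model == "cooperative":
            return CooperativeParams(self.params["k1"], self.params["k2"], self.r0)
        return EquivalentNSParams(self.params["k1"], self.params["ns"], self.r0)


@dataclass
class MultiExperimentSummary:
    """Mean ± SEM of fitted constants across independent experiments."""

    model: str
    means: dict[str, float]
    sems: dict[str, float]
    n_experiments: int
    n_excluded: int = 0


def bound_free_from_chambers(exp: DialysisExperiment) -> BindingCurve:
    """Convert chamber concentrations to a (free, bound) binding curve.

    free = reference chamber; bound = sample − reference, floored at zero
    (small negative differences arise from measurement noise).
    """
    if exp.series.shape[0] == 0:
        raise InsufficientDataError("experiment has an empty series")
    total, sample, reference = exp.series.T
    free = reference
    bound = np.maximum(sample - reference, 0.0)
    return BindingCurve(free=free, bound=bound, experiment_id=exp.experiment_id)


def _model_predictor(model: str, r0: float, adair: bool):
    if model == "cooperative":

        def predict(u, theta):
            return bound_cooperative(u, CooperativeParams(theta[0], theta[1], r0), adair=adair)

    elif model == "equivalent_ns":

        def predict(u, theta):
            return bound_equivalent_ns(u, EquivalentNSParams(theta[0], theta[1], r0))

    else:
        raise ValueError(f"unknown model {model!r}")
    return predict


def _fit_predictor(model: str, r0: float, adair: bool, fit_r0: bool):
    """Predictor taking the full natural-scale parameter vector (optionally incl. r0)."""
    if not fit_r0:
        base = _model_predictor(model, r0, adair)
        return lambda u, theta: base(u, theta)

    def predict(u, theta):
        return _model_predictor(model, theta[2], adair)(u, theta[:2])

    return predict


def fit_binding_model(
    curves: list[BindingCurve] | BindingCurve,
    model: str,
    r0: float,
    *,
    init: tuple[float, ...] | None = None,
    fit_r0: bool = False,
    adair: bool = False,
    multistart: int = 5,
    experiment_id: str = "",
) -> FitResult:
    """Least-squares fit of one binding model to pooled (free, bound) points.

    Parameters are optimised in log-space (all are positive quantities).
    When ``init`` is omitted, a deterministic ``multistart × multistart``
    log-grid over [0.01, 100] × the median observed free concentration
    seeds the optimiser and the best run wins.  ``fit_r0=True`` adds r0 as
    a third free parameter; by default r0 is fixed at the value implied by
    the known protein load.

    Returns asymptotic standard errors from the Jacobian at the optimum;
    on a degenerate optimum (singular normal matrix) the affected errors
    are reported as ``inf`` rather than hidden.
    """
    if isinstance(curves, BindingCurve):
        curves = [curves]
    u = np.concatenate([c.free for c in curves])
    b = np.concatenate([c.bound for c in curves])
    names = list(MODEL_PARAM_NAMES[model])
    if fit_r0:
        names.append("r0")
    n_free = len(names)
    if u.size < n_free + 1:
        raise InsufficientDataError(
            f"need at least {n_free + 1} points to fit {n_free} parameters; got {u.size}"
        )
    if np.ptp(u) == 0:
        raise ValueError("degenerate data: all free concentrations identical")

    predict = _fit_predictor(model, r0, adair, fit_r0)

    def residuals(log_theta):
        return predict(u, np.exp(log_theta)) - b

    if init is not None:
        starts = [np.log(np.asarray(init, dtype=float))]
        if len(init) != n_free:
            raise ValueError(f"init must supply {n_free} values for {names}")
    else:
        med = float(np.median(u[u > 0])) if np.any(u > 0) else 1.0
        k_grid = np.log(np.geomspace(0.01 * med, 100.0 * med, multistart))
        starts = [np.array([a, c]) for a in k_grid for c in k_grid]
        if fit_r0:
            r0_seed = np.log(max(np.max(b), 1e-6))
            starts = [np.append(s, r0_seed) for s in starts]

    best = None
    for s in starts:
        try:
            res = least_squares(
                residuals, s, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimisation starts failed")

    theta = np.exp(best.x)
    rss = float(2.0 * best.cost)
    converged = bool(best.success and np.all(np.isfinite(theta)) and np.all(theta > 0))

    dof = max(u.size - n_free, 1)
    jtj = best.jac.T @ best.jac
    se_nat = np.full(n_free, np.inf)
    try:
        cov_log = (rss / dof) * np.linalg.inv(jtj)
        diag = np.diag(cov_log)
        with np.errstate(invalid="ignore"):
            se_log = np.sqrt(np.where(diag >= 0, diag, np.nan))
        se_nat = theta * se_log  # delta method for log-parameterised fit
        se_nat = np.where(np.isfinite(se_nat), se_nat, np.inf)
    except np.linalg.LinAlgError:
        pass  # identifiability failure: leave SEs infinite

    return FitResult(
        model=model,
        params=dict(zip(names, map(float, theta))),
        std_errors=dict(zip(names, map(float, se_nat))),
        rss=rss,
        converged=converged,
        n_points=int(u.size),
        experiment_id=experiment_id,
        r0=float(theta[2]) if fit_r0 else float(r0),
    )


def summarize_experiments(fits: list[FitResult]) -> MultiExperimentSummary:
    """Aggregate per-experiment fits as mean ± SEM per parameter.

    SEM is the sample standard deviation (ddof=1) divided by √n over the
    converged fits.  Non-converged fits are excluded and counted.  Fewer
    than two converged fits leave the SEM undefined, which is an error.
    """
    if not fits:
        raise InsufficientDataError("no fits supplied")
    models = {f.model for f in fits}
    if len(models) > 1:
        raise ValueError(f"cannot pool different models: {sorted(models)}")
    ok = [f for f in fits if f.converged]
    if len(ok) < 2:
        raise InsufficientDataError(
            f"need >= 2 converged fits for a defined SEM; got {len(ok)}"
        )
    names = list(ok[0].params)
    values = {n: np.array([f.params[n] for f in ok]) for n in names}
    means = {n: float(v.mean()) for n, v in values.items()}
    sems = {n: float(v.std(ddof=1) / math.sqrt(len(ok))) for n, v in values.items()}
    return MultiExperimentSummary(
        model=ok[0].model,
        means=means,
        sems=sems,
        n_experiments=len(ok),
        n_excluded=len(fits) - len(ok),
    )


# ---------------------------------------------------------------------------
# I/O

CSV_COLUMNS = ["experiment_id", "protein_mg_ml", "ligand", "total_uM", "sample_uM", "reference_uM"]


def read_dialysis_csv(path) -> list[DialysisExperiment]:
    """Read dialysis experiments from CSV with the canonical column layout."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    exps = []
    for exp_id, grp in df.groupby("experiment_id", sort=False):
        exps.append(
            DialysisExperiment(
                experiment_id=str(exp_id),
                protein_mg_ml=float(grp["protein_mg_ml"].iloc[0]),
                ligand_name=str(grp["ligand"].iloc[0]),
                series=grp[["total_uM", "sample_uM", "reference_uM"]].to_numpy(),
            )
        )
    return exps


def write_dialysis_csv(exps: list[DialysisExperiment], path) -> None:
    frames = []
    for e in exps:
        frames.append(
            pd.DataFrame(
                {
                    "experiment_id": e.experiment_id,
                    "protein_mg_ml": e.protein_mg_ml,
                    "ligand": e.ligand_name,
                    "total_uM": e.series[:, 0],
                    "sample_uM": e.series[:, 1],
                    "reference_uM": e.series[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def fit_report_frame(fits: list[FitResult], summary: MultiExperimentSummary | None = None) -> pd.DataFrame:
    """Tabular fit report: one row per experiment plus an optional mean row."""
    rows = []
    for f in fits:
        row = {"experiment_id": f.experiment_id, "model": f.model, "n_points": f.n_points,
               "rss": f.rss, "converged": f.converged, "r0_uM": f.r0}
        for k, v in f.params.items():
            row[k] = v
            row[f"se_{k}"] = f.std_errors[k]
        rows.append(row)
    if summary is not None:
        row = {"experiment_id": f"<mean of {summary.n_experiments}>", "model": summary.model}
        for k in summary.means:
            row[k] = summary.means[k]
            row[f"se_{k}"] = summary.sems[k]
        rows.append(row)
    return pd.DataFrame(rows)


def fit_report_json(fits: list[FitResult], summary: MultiExperimentSummary | None = None) -> str:
    payload = {
        "fits": [
            {
                "experiment_id": f.experiment_id,
                "model": f.model,
                "params": f.params,
                "std_errors": {k: (v if math.isfinite(v) else None) for k, v in f.std_errors.items()},
                "rss": f.rss,
                "converged": f.converged,
                "n_points": f.n_points,
                "r0_uM": f.r0,
            }
            for f in fits
        ]
    }
    if summary is not None:
        payload["summary"] = {
            "model": summary.model,
            "means": summary.means,
            "sems": summary.sems,
            "n_experiments": summary.n_experiments,
            "n_excluded": summary.n_excluded,
        }
    return json.dumps(payload, indent=2)
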