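"""Equilibrium binding models for ligands of the light-chain V_L dimer.

Immunoglobulin light-chain variable domains (V_L) form homo-dimers with a
hydrophobic cavity at the interface that accommodates small aromatic
ligands.  Equilibrium-dialysis experiments on such systems are summarised by
one of two classical isotherms, both expressed in dissociation constants
(μM):

* **Two positively cooperative sites** — sequential occupation of the dimer
  cavity, ``R + L ⇌ RL + L ⇌ RL₂`` with stepwise dissociation constants
  ``k1`` and ``k2``.  Positive cooperativity corresponds to ``k1 > k2``
  (the second ligand binds more tightly).  Free receptor follows

  ``[R] = r0 / (1 + U/k1 + U²/(k1·k2))``

  and bound ligand is tallied as

  ``B = (U·[R]/k1) · (1 + U/k2)``

  which counts the doubly-ligated species once (``B = [RL] + [RL₂]``).
  The standard Adair tally ``B = [RL] + 2·[RL₂]`` is available through the
  ``adair`` flag; see :func:`bound_cooperative`.

* **Two equivalent specific sites plus nonspecific binding** — a single
  site-class isotherm with an additional linear term,

  ``B = r0·U/(k1 + U) + ns·U``

  where ``ns`` is the nonspecific slope (stored dimensionless; reported
  data sheets sometimes quote it with μM units — the number is used as
  printed).

Scatchard-space diagnostics (``B/U`` against ``B``) discriminate the two
mechanisms by shape: concave (rising then falling) for positive
cooperativity, straight with slope ``−1/k1`` for a single site class, and
down-curving toward a positive asymptote when nonspecific binding follows
specific binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InsufficientDataError",
    "CooperativeParams",
    "EquivalentNSParams",
    "BindingCurve",
    "ScatchardCurve",
    "bound_cooperative",
    "bound_equivalent_ns",
    "free_receptor_cooperative",
    "scatchard_transform",
    "classify_scatchard_shape",
    "hill_coefficient",
    "read_binding_curves_csv",
    "write_binding_curves_csv",
]


class InsufficientDataError(ValueError):
    """Raised when a curve has too few usable points for an operation."""


def _as_nonneg_array(values, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


@dataclass(frozen=True)
class CooperativeParams:
    """Parameters of the two-site positively-cooperative model.

    Parameters
    ----------
    k1, k2
        Stepwise dissociation constants of the first and second binding
        event, μM.
    r0
        Total receptor (V_L dimer) concentration, μM.
    """

    k1: float
    k2: float
    r0: float

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.r0 < 0:
            raise ValueError("receptor concentration must be non-negative")

    @property
    def positive_cooperativity(self) -> bool:
        """True when the second site binds more tightly than the first."""
        return self.k1 > self.k2


@dataclass(frozen=True)
class EquivalentNSParams:
    """Parameters of the equivalent-sites-plus-nonspecific model.

    Parameters
    ----------
    k1
        Dissociation constant of the specific site class, μM.
    ns
        Nonspecific binding coefficient: the slope of the linear term,
        stored dimensionless.
    r0
        Total specific-site concentration (two sites per dimer), μM.
    """

    k1: float
    ns: float
    r0: float

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError("dissociation constant must be positive")
        if self.ns < 0:
            raise ValueError("nonspecific coefficient must be non-negative")
        if self.r0 < 0:
            raise ValueError("site concentration must be non-negative")


@dataclass
class BindingCurve:
    """Paired free/bound ligand concentrations from one binding experiment.

    ``free`` ([U]) and ``bound`` ([B]) are μM arrays of equal length;
    ``total`` ([L]) is optional and, where given, must satisfy
    ``free <= total`` up to a small noise tolerance.
    """

    free: np.ndarray
    bound: np.ndarray
    total: np.ndarray | None = None
    experiment_id: str = ""

    def __post_init__(self) -> None:
        self.free = _as_nonneg_array(self.free, "free")
        self.bound = _as_nonneg_array(self.bound, "bound")
        if self.free.shape != self.bound.shape:
            raise ValueError("free and bound must have equal length")
        if self.total is not None:
            self.total = _as_nonneg_array(self.total, "total")
            if self.total.shape != self.free.shape:
                raise ValueError("total must match free/bound length")
            tol = 1e-9 * (1.0 + np.abs(self.total))
            if np.any(self.free > self.total + tol):
                raise ValueError("free ligand cannot exceed total ligand")

    @property
    def n_points(self) -> int:
        return self.free.size


@dataclass
class ScatchardCurve:
    """Scatchard transform of a binding curve: x = [B], y = [B]/[U]."""

    x: np.ndarray
    y: np.ndarray
    shape_label: str = "indeterminate"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)


def free_receptor_cooperative(free, params: CooperativeParams) -> np.ndarray:
    """Free (unliganded) receptor concentration [R] at free ligand U.

    ``[R] = r0 / (1 + U/k1 + U²/(k1·k2))``; equals ``r0`` at U=0 and
    decreases monotonically with U.
    """
    u = _as_nonneg_array(free, "free")
    denom = 1.0 + u / params.k1 + u * u / (params.k1 * params.k2)
    return params.r0 / denom


def bound_cooperative(free, params: CooperativeParams, *, adair: bool = False):
    """Bound ligand under the two-site cooperative model.

    With ``adair=False`` (default) the doubly-ligated dimer contributes one
    ligand to the tally (``B = [RL] + [RL₂]``), giving a plateau of ``r0``;
    with ``adair=True`` it contributes two (``B = [RL] + 2·[RL₂]``, plateau
    ``2·r0``).

    Scalar input returns a scalar; arrays return arrays.
    """
    u = _as_nonneg_array(free, "free")
    r = free_receptor_cooperative(u, params)
    rl = u * r / params.k1
    rl2 = rl * u / params.k2
    b = rl + (2.0 * rl2 if adair else rl2)
    return b if np.ndim(free) else float(b[0])


def bound_equivalent_ns(free, params: EquivalentNSParams):
    """Bound ligand under the equivalent-sites-plus-nonspecific model.

    ``B = r0·U/(k1 + U) + ns·U``.  With ``ns=0`` the curve saturates at
    ``r0``; with ``ns>0`` it is asymptotically linear with slope ``ns``.
    """
    u = _as_nonneg_array(free, "free")
    b = params.r0 * u / (params.k1 + u) + params.ns * u
    return b if np.ndim(free) else float(b[0])


def scatchard_transform(curve: BindingCurve) -> ScatchardCurve:
    """Transform a binding curve into Scatchard space.

    Points with zero free ligand carry no ratio information and are dropped
    (their count is kept in ``n_dropped``).  Fewer than three usable points
    raise :class:`InsufficientDataError`.
    """
    usable = curve.free > 0
    n_dropped = int(np.sum(~usable))
    if np.sum(usable) < 3:
        raise InsufficientDataError(
            f"Scatchard transform needs >= 3 points with free > 0; "
            f"got {int(np.sum(usable))}"
        )
    b = curve.bound[usable]
    u = curve.free[usable]
    order = np.argsort(u)
    return ScatchardCurve(x=b[order], y=(b / u)[order], n_dropped=n_dropped)


def _window_slopes(x: np.ndarray, y: np.ndarray, width: int = 5) -> np.ndarray:
    """Local dy/dx from quadratic fits over sliding windows of `width` points."""
    n = x.size
    slopes = []
    for i in range(n - width + 1):
        xs = x[i : i + width]
        ys = y[i : i + width]
        xc = xs.mean()
        span = np.ptp(xs)
        if span == 0:
            continue
        coeffs = np.polyfit(xs - xc, ys, 2)
        # derivative of the quadratic at the window centre
        slopes.append(coeffs[1])
    return np.asarray(slopes)


def classify_scatchard_shape(s: ScatchardCurve, *, slope_rtol: float = 0.05) -> str:
    """Label the shape of a Scatchard curve.

    Returns one of ``cooperative`` (interior maximum: slope positive then
    negative), ``linear_single_site`` (constant negative slope within
    ``slope_rtol`` relative deviation), ``specific_plus_nonspecific``
    (monotone decrease flattening toward a positive asymptote), or
    ``indeterminate``.  Requires at least 5 points spanning a 10-fold range
    of free ligand; insufficient span yields ``indeterminate`` rather than
    an exception.
    """
    x, y = s.x, s.y
    if x.size < 5:
        return "indeterminate"
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(y > 0, x / y, np.nan)
    u = u[np.isfinite(u) & (u > 0)]
    if u.size < 5 or u.max() / u.min() < 10.0:
        return "indeterminate"

    slopes = _window_slopes(x, y)
    if slopes.size < 2:
        return "indeterminate"
    scale = np.max(np.abs(slopes))
    if scale == 0:
        return "indeterminate"
    tol = 0.02 * scale
    pos = slopes > tol
    neg = slopes < -tol

    if pos.any() and neg.any() and np.argmax(pos) < (len(slopes) - 1 - np.argmax(neg[::-1])):
        return "cooperative"
    if not pos.any() and neg.any():
        mean_slope = slopes.mean()
        if np.max(np.abs(slopes - mean_slope)) <= slope_rtol * abs(mean_slope):
            return "linear_single_site"
        # flattening toward a positive asymptote: slopes rise toward zero
        nondecreasing = np.all(np.diff(slopes) >= -tol)
        if nondecreasing and y[-1] > 0:
            return "specific_plus_nonspecific"
    return "indeterminate"


def hill_coefficient(params: CooperativeParams, *, adair: bool = False) -> float:
    """Hill coefficient at half-saturation, by finite differences.

    Estimated as the slope of ``log(B/(plateau − B))`` against ``log U`` at
    the free-ligand concentration where B equals half the plateau.  Values
    above 1 indicate positive cooperativity.
    """
    from scipy.optimize import brentq

    plateau = params.r0 * (2.0 if adair else 1.0)
    if plateau == 0:
        raise ValueError("undefined for r0 = 0")
    half = plateau / 2.0

    def f(log_u: float) -> float:
        return bound_cooperative(float(np.exp(log_u)), params, adair=adair) - half

    lo, hi = np.log(1e-8 * params.k2), np.log(1e8 * params.k1)
    log_u50 = brentq(f, lo, hi, xtol=1e-13)
    h = 1e-5

    def theta(log_u: float) -> float:
        b = bound_cooperative(float(np.exp(log_u)), params, adair=adair)
        return np.log(b / (plateau - b))

    return (theta(log_u50 + h) - theta(log_u50 - h)) / (2 * h)


def read_binding_curves_csv(path) -> list[BindingCurve]:
    """Read binding curves from CSV (experiment_id, total_uM, free_uM, bound_uM)."""
    df = pd.read_csv(path)
    required = {"experiment_id", "free_uM", "bound_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    curves = []
    for exp_id, grp in df.groupby("experiment_id", sort=False):
        total = grp["total_uM"].to_numpy() if "total_uM" in grp else None
        curves.append(
            BindingCurve(
                free=grp["free_uM"].to_numpy(),
                bound=grp["bound_uM"].to_numpy(),
                total=total,
                experiment_id=str(exp_id),
            )
        )
    return curves


def write_binding_curves_csv(curves: list[BindingCurve], path) -> None:
    """Write binding curves to CSV with the canonical column layout."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "experiment_id": c.experiment_id,
                    "total_uM": c.total if c.total is not None else np.nan,
                    "free_uM": c.free,
                    "bound_uM": c.bound,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
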