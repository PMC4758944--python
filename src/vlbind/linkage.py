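"""Thermodynamic linkage between V_L dimerization and ligand binding.

Light-chain variable domains equilibrate between amyloid-prone monomers
and folded homo-dimers, ``D ⇌ 2M`` with dissociation constant
``k_dim = [M]²/[D]`` (μM).  Ligand binds only the dimer (two stepwise
events, ``D + L ⇌ DL + L ⇌ DL₂``), so by linkage any ligand that binds the
dimer pulls protein out of the monomer pool: the free-monomer fraction is
a strictly non-increasing function of total ligand.  That fraction is the
proxy readout for amyloid propensity; the aggregation step itself is not
modelled.

Speciation is solved exactly: at fixed free ligand the protein mass
balance is a quadratic in free monomer (solved in closed form), and the
remaining ligand balance is a monotone scalar equation in free ligand,
bracketed on [0, l_total] and solved by Brent's method.

Ligand bookkeeping in the balance defaults to the standard Adair count
(``l_free + [DL] + 2[DL₂] = l_total``); a printed-form flag counts the
doubly-ligated dimer once, for consistency with the binding-isotherm
module's default tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .binding_models import CooperativeParams, EquivalentNSParams

__all__ = [
    "LinkageParams",
    "SpeciationState",
    "LinkageNumericalError",
    "solve_speciation",
    "monomer_fraction_curve",
]


class LinkageNumericalError(RuntimeError):
    """Raised when the speciation root-finder cannot bracket or converge."""


@dataclass(frozen=True)
class LinkageParams:
    """Coupled dimerization + dimer-binding equilibrium.

    Parameters
    ----------
    k_dim
        Dimer dissociation constant for D ⇌ 2M, [M]²/[D], μM.
    binding
        Dimer-site binding constants (:class:`CooperativeParams` or
        :class:`EquivalentNSParams`); the receptor concentration stored
        there is ignored — speciation fixes it from ``p_total``.
    p_total
        Total protein in monomer-equivalent units, μM.
    l_total
        Total ligand, μM.
    """

    k_dim: float
    binding: CooperativeParams | EquivalentNSParams
    p_total: float
    l_total: float

    def __post_init__(self) -> None:
        if self.k_dim <= 0:
            raise ValueError("k_dim must be positive")
        if self.p_total < 0 or self.l_total < 0:
            raise ValueError("totals must be non-negative")

    def stepwise_constants(self) -> tuple[float, float]:
        """Macroscopic stepwise dissociation constants (K1, K2) of the dimer.

        Cooperative parameters are already stepwise constants.  For the
        equivalent-sites model the per-site constant k1 maps to the
        macroscopic pair (k1/2, 2·k1) through the statistical factors of
        two identical independent sites; the nonspecific slope is a bulk
        partitioning term with no defined species and is excluded here.
        """
        b = self.binding
        if isinstance(b, CooperativeParams):
            return b.k1, b.k2
        return b.k1 / 2.0, 2.0 * b.k1


@dataclass
class SpeciationState:
    """Equilibrium concentrations (μM) of every species in the linkage model."""

    m: float  # free monomer
    d: float  # unliganded dimer
    dl: float  # singly-liganded dimer
    dl2: float  # doubly-liganded dimer
    l_free: float
    p_total: float
    l_total: float

    @property
    def monomer_fraction(self) -> float:
        """Free monomer as a fraction of total protein (monomer units)."""
        return self.m / self.p_total if self.p_total > 0 else 0.0

    @property
    def dimer_total(self) -> float:
        return self.d + self.dl + self.dl2


def _monomer_given_ligand(l: float, params: LinkageParams) -> tuple[float, float]:
    """Closed-form free monomer at fixed free ligand.

    Protein balance m + 2·(m²/k_dim)·φ(l) = p_total with binding factor
    φ(l) = 1 + l/K1 + l²/(K1·K2) is quadratic in m.
    """
    k1, k2 = params.stepwise_constants()
    phi = 1.0 + l / k1 + l * l / (k1 * k2)
    a = 2.0 * phi / params.k_dim
    p = params.p_total
    if p == 0:
        return 0.0, phi
    # positive root of a m^2 + m - p = 0, written to avoid cancellation
    m = 2.0 * p / (1.0 + np.sqrt(1.0 + 4.0 * a * p))
    return m, phi


def _species_at(l: float, params: LinkageParams) -> SpeciationState:
    k1, k2 = params.stepwise_constants()
    m, _ = _monomer_given_ligand(l, params)
    d = m * m / params.k_dim
    dl = d * l / k1
    dl2 = dl * l / k2
    return SpeciationState(
        m=m, d=d, dl=dl, dl2=dl2, l_free=l, p_total=params.p_total, l_total=params.l_total
    )


def solve_speciation(params: LinkageParams, *, adair: bool = True) -> SpeciationState:
    """Solve the coupled monomer–dimer–ligand equilibrium exactly.

    Satisfies the mass-action relations [M]²/[D] = k_dim,
    [D][L]/[DL] = K1, [DL][L]/[DL₂] = K2 together with the protein balance
    m + 2(d + dl + dl₂) = p_total and the ligand balance
    l_free + dl + 2·dl₂ = l_total (Adair count; the printed-form flag
    ``adair=False`` counts dl₂ once).  Both balances hold to 1e-9 relative
    at the returned state.
    """

    def ligand_bound(state: SpeciationState) -> float:
        return state.dl + (2.0 * state.dl2 if adair else state.dl2)

    if params.l_total == 0.0 or params.p_total == 0.0:
        state = _species_at(params.l_total if params.p_total == 0 else 0.0, params)
        if params.p_total == 0:
            state = SpeciationState(
                m=0.0, d=0.0, dl=0.0, dl2=0.0,
                l_free=params.l_total, p_total=0.0, l_total=params.l_total,
            )
        return state

    def g(l: float) -> float:
        state = _species_at(l, params)
        return l + ligand_bound(state) - params.l_total

    lo, hi = 0.0, params.l_total
    glo, ghi = g(lo), g(hi)
    if glo > 0 or ghi < 0:
        raise LinkageNumericalError(
            f"failed to bracket free ligand on [0, {params.l_total}]: g(0)={glo}, g(l_total)={ghi}"
        )
    l_free = brentq(g, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    state = _species_at(l_free, params)

    p_resid = abs(state.m + 2.0 * state.dimer_total - params.p_total) / max(params.p_total, 1e-300)
    l_resid = abs(state.l_free + ligand_bound(state) - params.l_total) / max(params.l_total, 1e-300)
    if p_resid > 1e-9 or l_resid > 1e-9:
        raise LinkageNumericalError(
            f"balance violation: protein {p_resid:.2e}, ligand {l_resid:.2e}"
        )
    return state


def monomer_fraction_curve(
    params: LinkageParams, l_grid: np.ndarray, *, adair: bool = True
) -> np.ndarray:
    """Free-monomer fraction at each total-ligand concentration of a grid.

    The grid must be sorted and non-negative; ``params.l_total`` is
    overridden point by point.  For a dimer-binding ligand the returned
    fractions are monotone non-increasing in total ligand.
    """
    from dataclasses import replace

    l_grid = np.asarray(l_grid, dtype=float)
    if np.any(l_grid < 0):
        raise ValueError("ligand grid must be non-negative")
    if np.any(np.diff(l_grid) < 0):
        raise ValueError("ligand grid must be sorted ascending")
    return np.array(
        [
            solve_speciation(replace(params, l_total=float(lt)), adair=adair).monomer_fraction
            for lt in l_grid
        ]
    )
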