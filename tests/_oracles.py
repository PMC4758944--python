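"""Independent brute-force oracles shared across test modules."""

import numpy as np


def linkage_grid_oracle(p, n_grid=600, *, adair=True):
    """Locate the coupled-equilibrium solution by brute-force grid scanning.

    Scans free ligand on [0, l_total]; at each ligand node picks the free
    monomer node on [0, p_total] minimising the protein-balance violation,
    then selects the ligand node minimising the ligand-balance violation.
    Uses only argmins over mass-action species evaluations — deliberately
    independent of the closed-form/brentq solver.
    """
    k1, k2 = p.stepwise_constants()
    m_grid = np.linspace(0.0, p.p_total, n_grid)
    l_grid = np.linspace(0.0, p.l_total, n_grid) if p.l_total > 0 else np.array([0.0])
    best = None
    for l in l_grid:
        d = m_grid**2 / p.k_dim
        dl = d * l / k1
        dl2 = dl * l / k2
        protein = np.abs(m_grid + 2.0 * (d + dl + dl2) - p.p_total)
        i = int(np.argmin(protein))
        ligand = abs(l + dl[i] + (2.0 if adair else 1.0) * dl2[i] - p.l_total)
        if best is None or ligand < best[0]:
            best = (ligand, float(m_grid[i]), float(l))
    return best[1], best[2]
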