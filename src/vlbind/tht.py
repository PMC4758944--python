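"""Thioflavin-T (ThT) fibril-formation assay summaries.

ThT fluorescence (440/480 nm ex/em) reports amyloid fibril mass: an
aggregating sample shows a sigmoidal rise to a plateau, while an inhibited
sample stays near baseline.  Because the ligands studied here absorb in
the ThT emission band, absolute fluorescence is not comparable across
conditions; the analysis therefore works with endpoint *ratios* against
the ligand-free control:

    inhibition_fraction(c) = 1 − endpoint(c) / endpoint(control)

The "effective concentration" of an inhibitor on a tested dose grid is the
smallest concentration whose inhibition fraction reaches a threshold
(default 0.90) with every larger tested concentration also above threshold
— a deliberately conservative, grid-restricted summary rather than an
interpolated IC value.  A lag-time (first crossing of a fraction of the
plateau) is reported per trace as a model-free kinetic summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ThTTimeCourse",
    "InhibitionSummary",
    "endpoint_summary",
    "effective_concentration",
    "lag_time",
    "summarize_inhibition",
    "read_tht_csv",
    "write_tht_csv",
    "THT_DOSE_GRID_MM",
]

# Standard tested dose grid, mM
THT_DOSE_GRID_MM = (1.0, 0.50, 0.25, 0.12, 0.05, 0.03)


@dataclass
class ThTTimeCourse:
    """One fluorescence-vs-time trace at a single ligand concentration."""

    time: np.ndarray  # h, strictly increasing
    fluorescence: np.ndarray  # AU
    ligand_conc: float  # mM
    replicate: int = 0
    is_control: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape or self.time.ndim != 1:
            raise ValueError("time and fluorescence must be 1-D arrays of equal length")
        if self.time.size < 10:
            raise ValueError("need at least 10 time points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")
        if self.ligand_conc < 0:
            raise ValueError("ligand concentration must be non-negative")


@dataclass
class InhibitionSummary:
    """Per-concentration endpoints, inhibition fractions and lag times."""

    concentrations: np.ndarray  # mM, ascending, excluding the control
    endpoints: np.ndarray  # mean plateau fluorescence, AU
    control_endpoint: float
    inhibition_fraction: np.ndarray  # clipped to [0, 1]
    lag_times: list[float | None]
    control_lag_time: float | None
    effective_conc: float | None
    threshold: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "concentrations_mM": list(map(float, self.concentrations)),
                "endpoints_AU": list(map(float, self.endpoints)),
                "control_endpoint_AU": self.control_endpoint,
                "inhibition_fraction": list(map(float, self.inhibition_fraction)),
                "lag_times_h": [None if t is None else float(t) for t in self.lag_times],
                "control_lag_time_h": self.control_lag_time,
                "effective_conc_mM": self.effective_conc,
                "threshold": self.threshold,
            },
            indent=2,
        )


def _trace_endpoint(course: ThTTimeCourse, tail_fraction: float) -> float:
    n_tail = max(1, int(round(tail_fraction * course.time.size)))
    return float(course.fluorescence[-n_tail:].mean())


def endpoint_summary(
    courses: list[ThTTimeCourse], tail_fraction: float = 0.10
) -> dict[float, float]:
    """Mean plateau fluorescence per ligand concentration.

    The endpoint of a trace is the mean of its final ``tail_fraction`` of
    time points; replicates at the same concentration are averaged.
    Replicates recorded on a different time grid than the first control
    are interpolated onto the control grid with a warning (the endpoint is
    a tail mean, so mild grid mismatch is benign).
    """
    if not courses:
        raise ValueError("no time courses supplied")
    controls = [c for c in courses if c.is_control]
    ref_time = controls[0].time if controls else courses[0].time

    by_conc: dict[float, list[float]] = {}
    for c in courses:
        course = c
        if c.time.size != ref_time.size or not np.allclose(c.time, ref_time):
            warnings.warn(
                f"time grid of replicate {c.replicate} at {c.ligand_conc} mM differs "
                "from the control grid; interpolating",
                stacklevel=2,
            )
            course = ThTTimeCourse(
                time=ref_time,
                fluorescence=np.interp(ref_time, c.time, c.fluorescence),
                ligand_conc=c.ligand_conc,
                replicate=c.replicate,
                is_control=c.is_control,
            )
        key = 0.0 if c.is_control else float(c.ligand_conc)
        by_conc.setdefault(key, []).append(_trace_endpoint(course, tail_fraction))
    return {conc: float(np.mean(vals)) for conc, vals in by_conc.items()}


def effective_concentration(
    inhibition: dict[float, float],
    grid: np.ndarray,
    threshold: float = 0.90,
) -> float | None:
    """Smallest grid concentration achieving sustained threshold inhibition.

    Returns the smallest tested concentration whose inhibition fraction is
    at or above ``threshold`` **and** for which every larger tested
    concentration also meets the threshold; ``None`` when no concentration
    qualifies.  Raising the threshold can only raise (or void) the answer.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    missing = [c for c in grid if float(c) not in inhibition]
    if missing:
        raise ValueError(f"grid concentrations without summaries: {missing}")
    ok = np.array([inhibition[float(c)] >= threshold for c in grid])
    # suffix-AND: qualified from this concentration upward
    sustained = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.nonzero(sustained)[0]
    return float(grid[idx[0]]) if idx.size else None


def lag_time(course: ThTTimeCourse, level: float = 0.5) -> float | None:
    """First time the trace crosses ``level × plateau``, linearly interpolated.

    The plateau is the mean of the final 10% of points.  Traces without a
    detectable growth phase (plateau not exceeding 5× the initial signal)
    or that never cross the level return ``None``.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    f = course.fluorescence
    plateau = _trace_endpoint(course, 0.10)
    initial = float(f[0])
    if plateau <= 5.0 * max(initial, 1e-12):
        return None
    target = level * plateau
    above = f >= target
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(course.time[0])
    t0, t1 = course.time[i - 1], course.time[i]
    f0, f1 = f[i - 1], f[i]
    if f1 == f0:
        return float(t1)
    return float(t0 + (target - f0) * (t1 - t0) / (f1 - f0))


def summarize_inhibition(
    courses: list[ThTTimeCourse],
    tail_fraction: float = 0.10,
    threshold: float = 0.90,
    grid: np.ndarray | None = None,
) -> InhibitionSummary:
    """Full assay summary: endpoints, inhibition fractions, lags, effective dose."""
    endpoints = endpoint_summary(courses, tail_fraction)
    if 0.0 not in endpoints:
        raise ValueError("no ligand-free control in the supplied courses")
    control_endpoint = endpoints[0.0]
    if control_endpoint <= 0:
        raise ValueError("control endpoint must be positive to define inhibition")
    concs = np.sort([c for c in endpoints if c > 0])
    if grid is None:
        grid = concs
    ep = np.array([endpoints[c] for c in concs])
    inhib = np.clip(1.0 - ep / control_endpoint, 0.0, 1.0)
    inhib_map = {float(c): float(v) for c, v in zip(concs, inhib)}

    def _first_lag(conc: float | None) -> float | None:
        matches = [
            c for c in courses if (c.is_control if conc is None else (not c.is_control and c.ligand_conc == conc))
        ]
        lags = [lag_time(c) for c in matches]
        finite = [t for t in lags if t is not None]
        return float(np.mean(finite)) if finite else None

    return InhibitionSummary(
        concentrations=concs,
        endpoints=ep,
        control_endpoint=control_endpoint,
        inhibition_fraction=inhib,
        lag_times=[_first_lag(float(c)) for c in concs],
        control_lag_time=_first_lag(None),
        effective_conc=effective_concentration(inhib_map, grid, threshold),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# I/O

THT_COLUMNS = ["time_h", "fluorescence", "ligand_mM", "replicate", "is_control"]


def read_tht_csv(path) -> list[ThTTimeCourse]:
    """Read ThT time courses from CSV (time_h, fluorescence, ligand_mM, replicate, is_control)."""
    df = pd.read_csv(path)
    missing = set(THT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    courses = []
    for (conc, rep, ctrl), grp in df.groupby(["ligand_mM", "replicate", "is_control"], sort=False):
        courses.append(
            ThTTimeCourse(
                time=grp["time_h"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                ligand_conc=float(conc),
                replicate=int(rep),
                is_control=bool(ctrl),
            )
        )
    return courses


def write_tht_csv(courses: list[ThTTimeCourse], path) -> None:
    frames = []
    for c in courses:
        frames.append(
            pd.DataFrame(
                {
                    "time_h": c.time,
                    "fluorescence": c.fluorescence,
                    "ligand_mM": c.ligand_conc,
                    "replicate": c.replicate,
                    "is_control": c.is_control,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
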