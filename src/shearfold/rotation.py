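"""Rotational dynamics and collapse analysis of multi-domain constructs.

Tracks the unit vector connecting the centres of mass of a peripheral
domain and the central one.  From it:

* the first-order orientational time correlation function
  c(τ) = ⟨R̂(t+τ)·R̂(t)⟩ averaged over all time origins, and its first
  zero crossing (linear interpolation; censored if it never crosses
  within the maximum lag);
* the unsigned angular velocity ω = |ΔR̂|/Δt projected on the shear
  (flow–gradient, XZ) plane;
* the theoretical rotational period of the Couette field, Tr = 4π/γ̇
  (vorticity γ̇/2);
* a collapse/extension scan: time-averaged inter-domain distances as a
  function of shear rate, classified against the low-shear baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import TrajectoryRecord
from .model import ConstructModel

__all__ = [
    "OrientationSeries", "TCFResult", "AngularVelocitySeries", "CollapseScan",
    "orientation_series", "orientation_tcf", "angular_velocity",
    "theory_rotation_period", "collapse_extension_scan", "domain_distance_series",
]


@dataclass
class OrientationSeries:
    times_ns: np.ndarray
    vectors: np.ndarray  # (F, 3), unit-normalized per frame

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero-length inter-domain vector")
        self.vectors = self.vectors / norms[:, None]


@dataclass
class TCFResult:
    lags_ns: np.ndarray
    c: np.ndarray
    first_zero_ns: float | None  # None = censored within max lag

    @property
    def censored(self) -> bool:
        return self.first_zero_ns is None


@dataclass
class AngularVelocitySeries:
    times_ns: np.ndarray
    omega_rad_per_ns: np.ndarray
    dt_ns: float

    @property
    def mean(self) -> float:
        return float(self.omega_rad_per_ns.mean())


@dataclass
class CollapseScan:
    table: pd.DataFrame  # columns: shear_rate, d12, d13, classification
    baseline_d12: float
    baseline_d13: float
    margin: float


def orientation_series(traj: TrajectoryRecord, model: ConstructModel,
                       peripheral: str, central: str) -> OrientationSeries:
    """Unit vectors from the peripheral to the central domain COM per frame."""
    ip = model.segment_indices(peripheral)
    ic = model.segment_indices(central)
    mp = model.masses()[ip][:, None]
    mc = model.masses()[ic][:, None]
    com_p = (traj.positions[:, ip] * mp).sum(1) / mp.sum()
    com_c = (traj.positions[:, ic] * mc).sum(1) / mc.sum()
    return OrientationSeries(times_ns=traj.times_ns.copy(),
                             vectors=com_c - com_p)


def orientation_tcf(series: OrientationSeries,
                    max_lag_ns: float | None = None) -> TCFResult:
    """c(τ) = ⟨R̂(t+τ)·R̂(t)⟩ over all overlapping time origins."""
    v = series.vectors
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 frames")
    dt = float(np.median(np.diff(series.times_ns)))
    max_k = n - 1
    if max_lag_ns is not None:
        max_k = min(max_k, int(round(max_lag_ns / dt)))
    lags = np.arange(max_k + 1) * dt
    c = np.empty(max_k + 1)
    c[0] = 1.0
    for k in range(1, max_k + 1):
        c[k] = float(np.mean(np.sum(v[k:] * v[:-k], axis=1)))
    first_zero = None
    sign = np.signbit(c)
    crossing = np.nonzero(sign[1:] != sign[:-1])[0]
    if len(crossing):
        k = int(crossing[0])
        # linear interpolation between the bracketing lags
        frac = c[k] / (c[k] - c[k + 1])
        first_zero = float(lags[k] + frac * dt)
    return TCFResult(lags_ns=lags, c=c, first_zero_ns=first_zero)


def angular_velocity(series: OrientationSeries,
                     plane: tuple[int, int] = (0, 2)) -> AngularVelocitySeries:
    """Unsigned per-step angular speed |ΔR̂|/Δt on the rotation plane.

    ``plane`` selects the two Cartesian components kept (defaults to XZ,
    the flow–gradient plane); for small displacements |ΔR̂|/|R̂| is the
    angular increment in radians.
    """
    v = series.vectors
    if len(v) < 2:
        raise ValueError("need at least 2 frames")
    dt = float(np.median(np.diff(series.times_ns)))
    dv = np.diff(v, axis=0)
    proj = dv[:, list(plane)]
    omega = np.linalg.norm(proj, axis=1) / dt
    return AngularVelocitySeries(times_ns=series.times_ns[1:].copy(),
                                 omega_rad_per_ns=omega, dt_ns=dt)


def theory_rotation_period(shear_rate: float) -> float:
    """Rotational period of the Couette field, Tr = 4π/γ̇ (same time units)."""
    if shear_rate <= 0:
        raise ValueError("rotation period undefined for zero shear rate")
    return 4.0 * np.pi / shear_rate


def domain_distance_series(traj: TrajectoryRecord, model: ConstructModel,
                           seg_a: str, seg_b: str) -> np.ndarray:
    ia = model.segment_indices(seg_a)
    ib = model.segment_indices(seg_b)
    ma = model.masses()[ia][:, None]
    mb = model.masses()[ib][:, None]
    com_a = (traj.positions[:, ia] * ma).sum(1) / ma.sum()
    com_b = (traj.positions[:, ib] * mb).sum(1) / mb.sum()
    return np.linalg.norm(com_a - com_b, axis=1)


def collapse_extension_scan(trajs_by_rate: dict[float, list[TrajectoryRecord]],
                            model: ConstructModel,
                            segments: tuple[str, str, str] = ("A1", "A2", "A3"),
                            margin: float = 0.5) -> CollapseScan:
    """Time-averaged inter-domain distances vs shear rate.

    Distances are averaged per trajectory first, then pooled per rate.
    The lowest scanned rate defines the collapsed baseline; a rate is
    classified ``extended/cyclic`` when either distance exceeds the
    baseline by at least ``margin`` (fractional, default 50%).
    """
    if len(trajs_by_rate) < 2:
        raise ValueError("scan needs at least 2 shear rates")
    s1, s2, s3 = segments
    rows = []
    for rate in sorted(trajs_by_rate):
        d12s, d13s = [], []
        for traj in trajs_by_rate[rate]:
            d12s.append(domain_distance_series(traj, model, s1, s2).mean())
            d13s.append(domain_distance_series(traj, model, s1, s3).mean())
        rows.append({"shear_rate": rate,
                     "d12": float(np.mean(d12s)), "d13": float(np.mean(d13s))})
    base_d12, base_d13 = rows[0]["d12"], rows[0]["d13"]
    for row in rows:
        extended = (row["d12"] > base_d12 * (1 + margin)
                    or row["d13"] > base_d13 * (1 + margin))
        row["classification"] = "extended/cyclic" if extended else "collapsed"
    return CollapseScan(table=pd.DataFrame(rows), baseline_d12=base_d12,
                        baseline_d13=base_d13, margin=margin)
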