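"""Structural observables on trajectories.

The central quantity is the *coordination number* of the cleavage-site
residue: the number of backbone sites (excluding the site's own) within a
probe radius (10 Å default) of any of its atoms.  A frame counts as
"exposed" when that number drops below a threshold; the first exposed frame
of a trajectory gives the first unfolding time, otherwise the run is
right-censored at its final time.

Also provided: the smooth native H-bond contact count

    C(t) = Σ_contacts 1 / (1 + exp{a (d(t) − d_ref)}),

per-β-strand-pair contact series, end-to-end distances, and the
moving-averaged tensile force  f̄ = ⟨k (d(t) − d0)⟩_τw  on an instrumented
terminal bond (reported in pN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import units
from .dynamics import TrajectoryRecord
from .model import ConstructModel, NativeHBondSet

__all__ = [
    "ExposureCriterion", "ContactSeries", "TensileSeries",
    "coordination_number", "exposure_time", "contact_count",
    "strand_pair_contacts", "end_to_end", "tensile_force_series",
    "exposure_scatter", "moving_average", "site_indices",
]


@dataclass
class ExposureCriterion:
    """Burial criterion for a site residue.

    ``threshold`` is representation-dependent: 50 backbone atoms for
    atomistic counting; for a coarse-grained model it is re-calibrated so
    that the native state sits safely above it (the toy-structure builders
    store the calibrated value).
    """

    site_residue_local: int = 111
    probe_radius: float = 10.0
    threshold: float = 50.0
    segment: str = "A2"

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe radius must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


@dataclass
class ContactSeries:
    strand_pair_label: str
    times_ns: np.ndarray
    contacts: np.ndarray
    n_catalogued: int


@dataclass
class TensileSeries:
    bond_index: int
    times_ns: np.ndarray
    force_pN: np.ndarray          # instantaneous k(d − d0), pN
    force_avg_pN: np.ndarray      # centered moving average over window_ns
    window_ns: float


def site_indices(model: ConstructModel,
                 criterion: ExposureCriterion) -> tuple[np.ndarray, np.ndarray]:
    """(site bead indices, counted backbone bead indices) for a criterion."""
    site = model.residue_bead_indices(criterion.segment,
                                      criterion.site_residue_local)
    counted = model.segment_backbone_indices(criterion.segment)
    counted = np.setdiff1d(counted, site)
    return site, counted


def coordination_number(frame: np.ndarray, site: np.ndarray,
                        counted: np.ndarray, probe_radius: float = 10.0) -> int:
    """Number of counted sites strictly within ``probe_radius`` of the site.

    A counted site contributes once if it lies within the radius of *any*
    site atom; the site's own atoms must already be excluded from
    ``counted``.
    """
    if len(site) == 0:
        raise ValueError("site has no atoms in this model")
    if len(counted) == 0:
        return 0
    d = cdist(np.asarray(frame)[counted], np.asarray(frame)[site])
    return int(np.sum(d.min(axis=1) < probe_radius))


def coordination_series(traj: TrajectoryRecord, model: ConstructModel,
                        criterion: ExposureCriterion) -> np.ndarray:
    site, counted = site_indices(model, criterion)
    return np.array([coordination_number(fr, site, counted,
                                         criterion.probe_radius)
                     for fr in traj.positions])


def exposure_time(traj: TrajectoryRecord, model: ConstructModel,
                  criterion: ExposureCriterion) -> tuple[str, float]:
    """First frame time with coordination below threshold, else censored.

    Returns ``("unfolded", τ)`` or ``("censored", final time)``.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    coord = coordination_series(traj, model, criterion)
    below = np.nonzero(coord < criterion.threshold)[0]
    if len(below):
        return "unfolded", float(traj.times_ns[below[0]])
    return "censored", float(traj.times_ns[-1])


def contact_count(frame: np.ndarray, hbond_set: NativeHBondSet,
                  labels: set[str] | None = None) -> float:
    """Smooth native-contact count of one frame.

    Each catalogued O···HN contact contributes 1/(1 + exp{a (d − d_ref)});
    a contact at its native distance contributes exactly 1/2.
    """
    frame = np.asarray(frame, float)
    total = 0.0
    a = hbond_set.smoothing_a
    for c in hbond_set.contacts:
        if labels is not None and c.strand_pair_label not in labels:
            continue
        d = float(np.linalg.norm(frame[c.donor_h] - frame[c.acceptor_o]))
        total += 1.0 / (1.0 + np.exp(a * (d - c.d_ref)))
    return total


def strand_pair_contacts(traj: TrajectoryRecord, hbond_set: NativeHBondSet,
                         labels: tuple[str, ...] | None = None,
                         ) -> dict[str, ContactSeries]:
    """Per-frame contact count split by β-strand-pair label."""
    if labels is None:
        labels = tuple(l for l in hbond_set.labels() if l != "other")
    if not labels:
        raise ValueError("hydrogen-bond set carries no strand-pair labels")
    out = {}
    for label in labels:
        n_cat = sum(c.strand_pair_label == label for c in hbond_set.contacts)
        series = np.array([contact_count(fr, hbond_set, labels={label})
                           for fr in traj.positions])
        out[label] = ContactSeries(label, traj.times_ns.copy(), series, n_cat)
    return out


def half_drop_time(series: ContactSeries, fraction: float = 0.5) -> float:
    """First time a contact series falls below ``fraction`` of its initial
    value; ``inf`` if it never does.  The reference is the first-frame
    value (native contacts sit at their half-logistic value ½ each, so the
    catalogue size itself is not the natural reference)."""
    ref = series.contacts[0]
    idx = np.nonzero(series.contacts < fraction * ref)[0]
    return float(series.times_ns[idx[0]]) if len(idx) else float("inf")


def end_to_end(frame: np.ndarray, segment_idx: np.ndarray,
               axis: int | None = None) -> float:
    """Distance between first and last backbone site of a segment.

    With ``axis`` given, the absolute projection of the end-to-end vector
    on that Cartesian axis is returned instead.
    """
    segment_idx = np.asarray(segment_idx, int)
    if len(segment_idx) < 2:
        raise ValueError("segment needs at least 2 sites")
    vec = np.asarray(frame)[segment_idx[-1]] - np.asarray(frame)[segment_idx[0]]
    if axis is not None:
        return float(abs(vec[axis]))
    return float(np.linalg.norm(vec))


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar mean, truncated (not padded) at the series edges."""
    values = np.asarray(values, float)
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    half = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def tensile_force_series(traj: TrajectoryRecord, model: ConstructModel,
                         terminal_bond: int = 0,
                         window_ns: float = 2.1) -> TensileSeries:
    """Instantaneous and moving-averaged stretch force on a terminal bond."""
    bond_idx = model.terminal_bonds[terminal_bond]
    bond = model.bonds[bond_idx]
    d = np.linalg.norm(traj.positions[:, bond.i] - traj.positions[:, bond.j],
                       axis=1)
    force = units.force_internal_to_pn(bond.k * (d - bond.r0))
    stride_ns = float(np.median(np.diff(traj.times_ns)))
    window = max(int(round(window_ns / stride_ns)), 0)
    if window < 2:
        raise ValueError(
            f"window {window_ns} ns shorter than 2 frames at stride {stride_ns} ns")
    return TensileSeries(bond_index=bond_idx, times_ns=traj.times_ns.copy(),
                         force_pN=force,
                         force_avg_pN=moving_average(force, window),
                         window_ns=window_ns)


def exposure_scatter(traj: TrajectoryRecord, model: ConstructModel,
                     cleavage: ExposureCriterion,
                     recognition_residues: tuple[int, int] = (118, 120),
                     ) -> tuple[pd.DataFrame, float]:
    """Joint cleavage/recognition-site exposure per frame.

    The recognition site is scored as the larger burial of its residues
    (both must be exposed).  Returns the per-frame table and the fraction
    of frames where the recognition site is exposed while the cleavage
    site is not — the ordering indicator: positive values mean recognition
    precedes cleavage exposure.
    """
    cleav = coordination_series(traj, model, cleavage)
    rec_series = []
    for res in recognition_residues:
        crit = ExposureCriterion(site_residue_local=res,
                                 probe_radius=cleavage.probe_radius,
                                 threshold=cleavage.threshold,
                                 segment=cleavage.segment)
        rec_series.append(coordination_series(traj, model, crit))
    rec = np.max(rec_series, axis=0)
    df = pd.DataFrame({"time_ns": traj.times_ns,
                       "coord_cleavage": cleav,
                       "coord_recognition": rec})
    ordered = np.mean((rec < cleavage.threshold) & (cleav >= cleavage.threshold))
    return df, float(ordered)
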