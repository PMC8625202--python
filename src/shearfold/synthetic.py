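"""Synthetic fixtures: every input the pipeline needs without downloads.

Provides seed-deterministic generators (each takes an explicit integer seed
feeding an independent :func:`numpy.random.default_rng` stream) for:

* first-passage samples from the exponential and inverse Gaussian laws,
  with optional right censoring;
* a Brownian-motion-with-drift first-passage oracle (Euler discretization)
  whose law is inverse Gaussian with μ = α/ν, λ = α²/σ²;
* a rigid dumbbell probe for the Couette rotational period Tr = 4π/γ̇;
* a toy β-hairpin PDB file (text) for structure-loading tests;
* a four-strand β-sheet with explicit O/HN pseudo-atom sites, a buried
  "cleavage-site" bead and a calibrated exposure threshold — the desk-scale
  stand-in for the A2 fold's central β-sheet;
* a three-blob elastic-network construct standing in for A1-L12-A2-L23-A3;
* an end-to-end demo pipeline (build → pull at several forces → exposure
  events → censored ML fits).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import units
from .dynamics import (CouetteField, DragCoupling, PullingProtocol, SimParams,
                       Simulation, TrajectoryRecord, run_pulling)
from .forces import compile_model
from .kinetics import (FirstPassageDataset, fit_bell, fit_exponential,
                       fit_ig_joint)
from .model import (Bead, ConstructModel, DomainModel, ElasticNetworkTerms,
                    GoTerms, HarmonicBond, LinkerForceField, NativeHBondSet,
                    NativePair,
                    build_elastic_network, build_go_model, derive_native_hbonds,
                    assemble_construct)
from .observables import ExposureCriterion, coordination_number, exposure_time, site_indices

__all__ = [
    "sample_exponential_censored", "sample_invgauss",
    "sample_invgauss_censored", "brownian_fpt_oracle",
    "make_rigid_dumbbell", "dumbbell_tumbling_period",
    "make_hairpin_pdb", "make_toy_sheet", "ToySheet",
    "make_three_blob_construct", "make_vwf_like_construct",
    "pull_toy_sheet", "three_blob_shear_run", "demo_pipeline",
    "TOY_GAMMA_FRICTION",
]


# ---------------------------------------------------------------------------
# first-passage samplers
# ---------------------------------------------------------------------------

def sample_exponential_censored(k: float, n: int, censor_time: float,
                                seed: int = 0,
                                condition: float | str = "exp",
                                ) -> FirstPassageDataset:
    """n exponential(k) draws, right-censored at ``censor_time``."""
    if k <= 0 or n < 1:
        raise ValueError("need k > 0 and n >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.exponential(1.0 / k, size=n)
    obs = draws[draws <= censor_time]
    cens = np.full(int(np.sum(draws > censor_time)), censor_time)
    return FirstPassageDataset(condition=condition, observed=obs, censored=cens)


def sample_invgauss(mu: float, lam: float, n: int, seed: int = 0) -> np.ndarray:
    """Inverse Gaussian draws by the Michael–Schucany–Haas transformation."""
    if mu <= 0 or lam <= 0:
        raise ValueError("mu and lambda must be positive")
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n) ** 2
    x = (mu + mu ** 2 * y / (2.0 * lam)
         - mu / (2.0 * lam) * np.sqrt(4.0 * mu * lam * y + mu ** 2 * y ** 2))
    u = rng.uniform(size=n)
    return np.where(u <= mu / (mu + x), x, mu ** 2 / x)


def sample_invgauss_censored(mu: float, lam: float, n: int,
                             censor_time: float, seed: int = 0,
                             condition: float | str = "ig",
                             ) -> FirstPassageDataset:
    draws = sample_invgauss(mu, lam, n, seed)
    obs = draws[draws <= censor_time]
    cens = np.full(int(np.sum(draws > censor_time)), censor_time)
    return FirstPassageDataset(condition=condition, observed=obs, censored=cens)


def brownian_fpt_oracle(alpha: float, nu: float, sigma: float,
                        dt: float | None = None, n: int = 1000,
                        seed: int = 0, max_time_factor: float = 200.0,
                        ) -> np.ndarray:
    """First-passage times of x(t+dt) = x(t) + ν dt + σ√dt ξ from 0 to α.

    Independent Euler walkers start at the reactant state x = 0 and are
    absorbed at x = α.  The default step keeps the drift per step at
    α/400 (well inside the α/100 coarseness bound); crossings are assigned
    to the midpoint of the crossing step, which removes the half-step
    recording bias of discrete monitoring.
    """
    if alpha <= 0 or sigma < 0 or n < 1:
        raise ValueError("need alpha > 0, sigma >= 0, n >= 1")
    if dt is None:
        dt = alpha / (400.0 * nu) if nu > 0 else (alpha / (20.0 * sigma)) ** 2
    if dt <= 0:
        raise ValueError("dt must be positive")
    if nu * dt > alpha / 10.0:
        warnings.warn("Euler step too coarse: nu*dt exceeds alpha/10")
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    times = np.full(n, np.nan)
    active = np.arange(n)
    t = 0.0
    sqdt = np.sqrt(dt)
    max_steps = int(max_time_factor * max(alpha / max(nu, 1e-12), 1.0) / dt)
    for _ in range(max_steps):
        t += dt
        x[active] += nu * dt + sigma * sqdt * rng.standard_normal(len(active))
        crossed = x[active] >= alpha
        if np.any(crossed):
            times[active[crossed]] = t - 0.5 * dt
            active = active[~crossed]
        if len(active) == 0:
            break
    return times[~np.isnan(times)]


# ---------------------------------------------------------------------------
# rigid dumbbell probe
# ---------------------------------------------------------------------------

def make_rigid_dumbbell(separation: float = 20.0, mass: float = 500.0,
                        k_bond: float = 1.0, tilt_deg: float = 45.0,
                        seed: int = 0) -> ConstructModel:
    """Two beads joined by one stiff bond, tilted in the XZ (shear) plane."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    th = np.radians(tilt_deg)
    half = 0.5 * separation * np.array([np.cos(th), 0.0, np.sin(th)])
    beads = [
        Bead(id=0, residue_local_index=1, residue_name="GLY",
             bead_role="backbone", position=-half, mass=mass),
        Bead(id=1, residue_local_index=2, residue_name="GLY",
             bead_role="backbone", position=half, mass=mass),
    ]
    return ConstructModel(
        beads=beads, segment_labels=["D", "D"],
        bonds=[HarmonicBond(0, 1, separation, k_bond)],
        metadata={"kind": "rigid_dumbbell", "seed": seed})


def dumbbell_tumbling_period(shear_rate_per_s: float, separation: float = 20.0,
                             mass: float = 500.0,
                             coupling_ratio: float = 0.02,
                             n_periods: float = 3.0, seed: int = 0,
                             ) -> tuple[float, float]:
    """Measured vs theoretical tumbling period of a dumbbell at T = 0.

    The dumbbell spins in the vorticity of the Couette field.  Friction is
    set weak relative to the shear rate (``γ/m = coupling_ratio · γ̇``) so
    angular momentum carries the rod through the flow-aligned orientation;
    it is started on the steady tumbling orbit (rigid rotation at the
    vorticity γ̇/2) and the period is read from the slope of the unwrapped
    bond-vector angle.  Returns ``(measured_ns, theory_ns)``.
    """
    gdot = units.shear_rate_si_to_internal(shear_rate_per_s)  # fs⁻¹
    if gdot <= 0:
        raise ValueError("shear rate must be positive")
    model = make_rigid_dumbbell(separation=separation, mass=mass, seed=seed)
    gamma = coupling_ratio * gdot * mass
    period_fs = 4.0 * np.pi / gdot
    dt = min(period_fs / 2000.0, 200.0)
    n_steps = int(n_periods * period_fs / dt)
    stride = max(n_steps // 4000, 1)
    params = SimParams(dt_bonded_fs=dt, dt_nonbonded_fs=dt, temperature_K=0.0,
                       seed=seed, n_steps=n_steps, record_stride=stride)
    field = CouetteField(shear_rate_per_s)
    sim = Simulation(model, params, field=field,
                     drag=DragCoupling(gamma_friction=gamma))
    # start on the tumbling orbit: rigid rotation at the vorticity γ̇/2
    # about ŷ, plus the local fluid velocity of the centre of mass
    omega = np.array([0.0, gdot / 2.0, 0.0])
    com = sim.x.mean(axis=0)
    for i in range(2):
        sim.v[i] = np.cross(omega, sim.x[i] - com)
    traj = sim.run()
    vec = traj.positions[:, 1] - traj.positions[:, 0]
    angle = np.unwrap(np.arctan2(vec[:, 2], vec[:, 0]))
    slope = np.polyfit(traj.times_ns, angle, 1)[0]  # rad/ns
    measured_ns = 2.0 * np.pi / abs(slope)
    theory_ns = period_fs * units.NS_PER_FS
    return measured_ns, theory_ns


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

_HAIRPIN_SEQ = ("ALA", "LEU", "SER", "VAL", "GLY", "GLY", "THR", "ILE",
                "ASP", "PHE")


def make_hairpin_pdb(n_res: int = 10) -> str:
    """PDB text of a synthetic two-strand β-hairpin (backbone + CB).

    Purely geometric: two antiparallel extended strands 4.8 Å apart joined
    by a turn, with N/CA/C/O backbone atoms and a CB sidechain atom for
    non-glycine residues.  Synthetic stand-in for a crystallographic file.
    """
    half = n_res // 2
    lines = []
    serial = 1
    for i in range(n_res):
        resname = _HAIRPIN_SEQ[i % len(_HAIRPIN_SEQ)]
        if i < half:
            ca = np.array([3.5 * i, 0.0, 0.0])
        else:
            ca = np.array([3.5 * (n_res - 1 - i), 0.0, 4.8])
        offs = {"N": (-1.2, 0.6, 0.0), "CA": (0.0, 0.0, 0.0),
                "C": (1.2, 0.6, 0.0), "O": (1.4, 1.8, 0.0)}
        for name, off in offs.items():
            x, y, z = ca + np.array(off)
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                f"{name[0]:>2s}")
            serial += 1
        if resname != "GLY":
            x, y, z = ca + np.array([0.0, -1.0, 1.1])
            lines.append(
                f"ATOM  {serial:5d}  CB {resname:>4s} A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass
class ToySheet:
    """Four-strand β-sheet fixture with everything its analyses need."""

    model: ConstructModel
    hbonds: NativeHBondSet
    criterion: ExposureCriterion
    strand_ranges: dict
    native_coordination: int
    extended_coordination: int


def make_toy_sheet(n_per_strand: int = 5, strand_spacing: float = 4.6,
                   ca_spacing: float = 3.5, site_offset: float = 1.1,
                   well_depth: float = 0.35, site_bond_k: float = 40.0,
                   probe_radius: float = 10.0,
                   interface_strength: tuple[float, float, float] = (1.7, 1.0, 0.55),
                   seed: int = 0) -> ToySheet:
    """Four antiparallel strands with explicit O/HN sites and a buried site.

    The chain runs bottom strand → top strand in a serpentine; the strands
    play the roles of the mechanically resistive β-sheet core (labels
    β1/β4/β5/β6, spatial order as in the native A2 sheet, C-terminus on
    β6).  Each residue carries a Cα bead plus carbonyl-O and amide-H
    pseudo-atom beads offset toward the neighbouring strands, so the native
    O···HN network across each strand interface sits well inside the 3 Å
    definition cutoff.  The "cleavage-site" bead is the middle residue of
    the β4-analog strand; its exposure threshold is calibrated midway
    between the native and the fully extended coordination number.

    ``interface_strength`` scales the native-well depth across the
    β1β4 / β4β5 / β5β6 interfaces, emulating the graded mechanical
    resistance of the native sheet (the short β6 edge strand unzips
    first, the β1β4 core last).
    """
    L = n_per_strand
    n_strands = 4
    beads: list[Bead] = []
    o_site, h_site = {}, {}  # residue -> bead index
    res = 0
    for s in range(n_strands):
        xs = range(L) if s % 2 == 0 else range(L - 1, -1, -1)
        for col in xs:
            res += 1
            pos = np.array([ca_spacing * col, 0.0, strand_spacing * s])
            beads.append(Bead(id=len(beads), residue_local_index=res,
                              residue_name="ALA", bead_role="backbone",
                              position=pos, mass=56.0))
            o_site[res] = len(beads)
            beads.append(Bead(id=len(beads), residue_local_index=res,
                              residue_name="ALA", bead_role="site_o",
                              position=pos + [0, 0, site_offset], mass=16.0))
            h_site[res] = len(beads)
            beads.append(Bead(id=len(beads), residue_local_index=res,
                              residue_name="ALA", bead_role="site_h",
                              position=pos - [0, 0, site_offset], mass=16.0))

    go = build_go_model(beads, native_cutoff=6.5, min_residue_separation=3,
                        well_depth=well_depth, kb=149.0)
    # grade cross-interface contact strength: β1β4 core > β4β5 > β5β6 edge
    strand_idx = {b.id: (b.residue_local_index - 1) // L for b in beads}
    graded = []
    for p in go.native_pairs:
        si, sj = sorted((strand_idx[p.i], strand_idx[p.j]))
        if sj == si + 1:
            factor = interface_strength[si]
        else:
            factor = 1.0
        graded.append(NativePair(p.i, p.j, p.r_native, p.well_depth * factor))
    go.native_pairs = graded
    # soften the site-attachment bonds and add orientation bonds so the
    # O/H pseudo-atoms follow their strand instead of swinging freely
    by_res = {b.residue_local_index: b for b in beads if b.bead_role == "backbone"}
    bonds = []
    for b in go.bonds:
        role_j = beads[b.j].bead_role
        if role_j in ("site_o", "site_h"):
            bonds.append(HarmonicBond(b.i, b.j, b.r0, site_bond_k))
        else:
            bonds.append(b)
    strand_of_res = lambda r: (r - 1) // L
    for r in range(1, res + 1):
        for site, nb in ((o_site[r], r + 1), (h_site[r], r - 1)):
            if 1 <= nb <= res and strand_of_res(nb) == strand_of_res(r):
                d = float(np.linalg.norm(beads[site].position
                                         - by_res[nb].position))
                bonds.append(HarmonicBond(*sorted((site, by_res[nb].id)),
                                          d, site_bond_k))

    model = ConstructModel(
        beads=beads, segment_labels=["A2"] * len(beads), bonds=bonds,
        angles=go.angles, torsions=go.torsions, native_pairs=go.native_pairs,
        excluded_volume_radius=go.nonnative_excluded_volume_radius,
        metadata={"kind": "toy_sheet", "n_per_strand": L, "seed": seed})

    strand_ranges = {"β1": (1, L), "β4": (L + 1, 2 * L),
                     "β5": (2 * L + 1, 3 * L), "β6": (3 * L + 1, 4 * L)}
    residues = list(range(1, res + 1))
    o_pos = np.array([beads[o_site[r]].position for r in residues])
    h_pos = np.array([beads[h_site[r]].position for r in residues])
    hbonds = derive_native_hbonds(
        residues, o_pos, h_pos, cutoff=3.0, strand_ranges=strand_ranges,
        o_site_index=[o_site[r] for r in residues],
        h_site_index=[h_site[r] for r in residues])

    # calibrate the exposure threshold: midway between the native and the
    # fully extended coordination of the buried site
    site_res = L + (L + 1) // 2  # middle of the β4-analog strand
    crit = ExposureCriterion(site_residue_local=site_res,
                             probe_radius=probe_radius, threshold=0.0,
                             segment="A2")
    site, counted = site_indices(model, crit)
    native_coord = coordination_number(model.positions(), site, counted,
                                       probe_radius)
    ext = _extended_positions(model)
    extended_coord = coordination_number(ext, site, counted, probe_radius)
    crit.threshold = 0.5 * (native_coord + extended_coord)
    if not extended_coord < crit.threshold < native_coord:
        raise RuntimeError("toy sheet burial calibration failed")
    return ToySheet(model=model, hbonds=hbonds, criterion=crit,
                    strand_ranges=strand_ranges,
                    native_coordination=native_coord,
                    extended_coordination=extended_coord)


def _extended_positions(model: ConstructModel) -> np.ndarray:
    """Lay the chain straight along +x at native bond lengths (sites offset)."""
    backbone = [b for b in model.beads if b.bead_role in ("backbone", "linker")]
    backbone.sort(key=lambda b: b.residue_local_index)
    bond_len = {}
    for bond in model.bonds:
        key = tuple(sorted((bond.i, bond.j)))
        bond_len[key] = bond.r0
    pos = np.zeros((model.n_beads, 3))
    x = 0.0
    prev = None
    xs = {}
    for b in backbone:
        if prev is not None:
            key = tuple(sorted((prev.id, b.id)))
            x += bond_len.get(key, 3.8)
        pos[b.id] = [x, 0.0, 0.0]
        xs[b.residue_local_index] = x
        prev = b
    for b in model.beads:
        if b.bead_role == "site_o":
            pos[b.id] = [xs[b.residue_local_index], 1.1, 0.0]
        elif b.bead_role == "site_h":
            pos[b.id] = [xs[b.residue_local_index], -1.1, 0.0]
    return pos


# ---------------------------------------------------------------------------
# multi-domain constructs
# ---------------------------------------------------------------------------

def _blob_beads(n: int = 10, radius: float = 3.2, half_gap: float = 1.6,
                mass: float = 100.0) -> list[Bead]:
    """Two stacked rings of beads: a compact, nearly rigid blob."""
    beads = []
    per_ring = (n + 1) // 2
    for i in range(n):
        ring, k = divmod(i, per_ring)
        ang = 2 * np.pi * (k + 0.5 * ring) / per_ring
        pos = np.array([radius * np.cos(ang), radius * np.sin(ang),
                        (2 * ring - 1) * half_gap])
        beads.append(Bead(id=i, residue_local_index=i + 1, residue_name="GLY",
                          bead_role="backbone", position=pos, mass=mass))
    return beads


def make_three_blob_construct(n_per_blob: int = 10,
                              linker_sequences: tuple[str, str] = ("GSAGT", "GSA"),
                              tilt_deg: float = 0.0,
                              seed: int = 0) -> ConstructModel:
    """Three elastic-network blobs chained by two short linkers.

    A desk-scale stand-in for the tri-domain construct; with
    ``tilt_deg`` the whole assembly is rotated in the XZ plane so an
    imposed shear exerts torque from the first step.
    """
    domains = []
    for _ in range(3):
        beads = _blob_beads(n_per_blob)
        domains.append(DomainModel(beads=beads,
                                   elastic=build_elastic_network(beads, 6.0, 5.0)))
    model = assemble_construct(domains, list(linker_sequences))
    model.metadata.update(kind="three_blob_construct", seed=seed)
    if tilt_deg:
        # positive tilt lifts the chain axis from +x toward +z, so an
        # imposed Couette flow (u_x = γ̇ z) rotates it back toward +x
        th = np.radians(tilt_deg)
        rot = np.array([[np.cos(th), 0.0, -np.sin(th)], [0.0, 1.0, 0.0],
                        [np.sin(th), 0.0, np.cos(th)]])
        centre = model.positions().mean(axis=0)
        for b in model.beads:
            b.position = (b.position - centre) @ rot.T + centre
    return model


_L12_SEQ = ("GSAGTPLSAQEPGSAGTPLSAQEPGSAGTPLSAQEPG")[:37]
_L23_SEQ = ("GSAGTPLSAQEPGSA")[:15]


def make_vwf_like_construct(n_per_blob: int = 10, seed: int = 0) -> ConstructModel:
    """Default tri-domain construct with the 37- and 15-residue linkers.

    The linker amino-acid sequences are placeholders of the correct
    lengths (the real inter-domain sequences are configurable upstream);
    the peripheral domains are synthetic elastic-network blobs.
    """
    return make_three_blob_construct(n_per_blob=n_per_blob,
                                     linker_sequences=(_L12_SEQ, _L23_SEQ),
                                     seed=seed)


def three_blob_shear_run(shear_rate_per_s: float, duration_over_sweep: float = 1.5,
                         tilt_deg: float = 135.0, temperature_K: float = 0.0,
                         dt_fs: float = 18.0, seed: int = 0,
                         model: ConstructModel | None = None,
                         ) -> tuple[ConstructModel, TrajectoryRecord]:
    """Shear run of the tilted three-blob construct, scaled to the sweep time.

    In the overdamped limit a rod tilted at 135° to the flow sweeps 90°
    (the first TCF zero) after a time 2/γ̇; the run length is that sweep
    time times ``duration_over_sweep``.  Returns the model and trajectory.
    """
    model = model or make_three_blob_construct(tilt_deg=tilt_deg, seed=seed)
    gdot = units.shear_rate_si_to_internal(shear_rate_per_s)
    if gdot <= 0:
        raise ValueError("shear rate must be positive")
    total_fs = duration_over_sweep * 2.0 / gdot
    n_steps = max(int(total_fs / dt_fs), 100)
    stride = max(n_steps // 1200, 1)
    params = SimParams(dt_bonded_fs=dt_fs, dt_nonbonded_fs=3 * dt_fs,
                       temperature_K=temperature_K, seed=seed,
                       n_steps=n_steps, record_stride=stride)
    com_z = float(model.positions()[:, 2].mean())
    field = CouetteField(shear_rate_per_s, reference_plane_z=com_z)
    sim = Simulation(model, params, field=field)
    return model, sim.run()


# ---------------------------------------------------------------------------
# demo pipeline
# ---------------------------------------------------------------------------

#: Friction used for the toy unfolding runs, amu fs⁻¹ per bead.  The drag
#: coefficient is the adjustable knob of the coupling scheme; this value
#: keeps the chain response fast enough that unfolding completes within
#: desk-scale runs while remaining strongly overdamped.
TOY_GAMMA_FRICTION = 0.3


def pull_toy_sheet(sheet: ToySheet, force_pN: float, seed: int,
                   n_steps: int = 25_000, dt_fs: float = 6.0,
                   gamma_friction: float = TOY_GAMMA_FRICTION,
                   temperature_K: float = 300.0, record_stride: int = 50,
                   ff=None) -> TrajectoryRecord:
    """Constant-force unfolding run of the toy sheet (N fixed, C pulled)."""
    params = SimParams(dt_bonded_fs=dt_fs, dt_nonbonded_fs=3 * dt_fs,
                       temperature_K=temperature_K, seed=seed,
                       n_steps=n_steps, record_stride=record_stride)
    protocol = PullingProtocol(force_pN=force_pN)
    return _run_pulling_compiled(sheet.model, params, protocol,
                                 ff or compile_model(sheet.model),
                                 gamma_friction=gamma_friction)


def demo_pipeline(seed: int = 0, out_dir: str | Path | None = None,
                  forces_pN: tuple[float, ...] = (250.0, 450.0, 700.0),
                  n_replicas: int = 6, n_steps: int = 30_000,
                  temperature_K: float = 300.0) -> dict:
    """Build the toy sheet, pull at several forces, fit both kinetic models.

    Returns a JSON-serializable report; with ``out_dir`` also writes
    ``events.csv``, ``fits.json`` and ``report.json``.  Deterministic for a
    fixed seed.
    """
    sheet = make_toy_sheet(seed=seed)
    ff = compile_model(sheet.model)
    datasets = []
    rows = []
    for fi, force in enumerate(forces_pN):
        obs, cens = [], []
        for rep in range(n_replicas):
            rep_seed = (seed * 100_003 + fi * 1009 + rep) % (2 ** 31)
            traj = pull_toy_sheet(sheet, force, rep_seed, n_steps=n_steps,
                                  temperature_K=temperature_K, ff=ff)
            status, t_ns = exposure_time(traj, sheet.model, sheet.criterion)
            (obs if status == "unfolded" else cens).append(t_ns)
            rows.append({"condition": force, "replicate": rep,
                         "time_ns": t_ns, "status": status})
        # guard against a zero first-frame time from an immediate unfolding
        obs = [max(t, 1e-6) for t in obs]
        datasets.append(FirstPassageDataset(condition=force, observed=obs,
                                            censored=cens))
    events = pd.DataFrame(rows)
    exp_fits = {ds.condition: fit_exponential(ds) for ds in datasets}
    if any(ds.n_observed for ds in datasets):
        ig_fit = fit_ig_joint(datasets, seed=seed)
        ig_params = {k: round(v, 6) for k, v in ig_fit.params.items()}
    else:
        ig_params = None
    mean_exposure = {}
    for ds in datasets:
        fit = exp_fits[ds.condition]
        mean_exposure[ds.condition] = (1.0 / fit.params["k"] if fit.success
                                       else float("inf"))
    fitted = [(f, exp_fits[f].params["k"]) for f in forces_pN
              if exp_fits[f].success]
    bell = None
    if len(fitted) >= 2:
        bp, r2 = fit_bell(np.array([f for f, _ in fitted]),
                          np.array([k for _, k in fitted]),
                          temperature_K=temperature_K)
        bell = {"k0_per_ns": bp.k0, "delta_x_A": bp.delta_x, "r_squared": r2}
    report = {
        "seed": seed,
        "forces_pN": list(forces_pN),
        "n_replicas": n_replicas,
        "mean_exposure_time_ns": {str(k): round(v, 6)
                                  for k, v in mean_exposure.items()},
        "exponential_rates_per_ns": {
            str(ds.condition): (round(exp_fits[ds.condition].params["k"], 6)
                                if exp_fits[ds.condition].success else None)
            for ds in datasets},
        "invgauss": ig_params,
        "bell": bell,
        "n_events": len(events),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        events.to_csv(out / "events.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
    return report


def _run_pulling_compiled(model: ConstructModel, params: SimParams,
                          protocol: PullingProtocol, ff,
                          gamma_friction: float | None = None,
                          ) -> TrajectoryRecord:
    """run_pulling with a shared compiled force field (skips recompilation)."""
    chain = [i for i, b in enumerate(model.beads)
             if b.bead_role in ("backbone", "linker")]
    pulled = chain[-1] if protocol.pulled_terminus == "C" else chain[0]
    fixed = chain[0] if protocol.fixed_terminus == "N" else chain[-1]
    mask = np.zeros(model.n_beads, bool)
    mask[fixed] = True
    fvec = (units.force_pn_to_internal(protocol.force_pN)
            * np.asarray(protocol.direction, float))

    def ext(x):
        f = np.zeros_like(x)
        f[pulled] = fvec
        return f

    drag = (DragCoupling(gamma_friction) if gamma_friction is not None
            else None)
    sim = Simulation(model, params, field=CouetteField(0.0),
                     external_force=ext, fixed_beads=mask, drag=drag, ff=ff)
    rec = sim.run()
    rec.metadata.update(force_pN=protocol.force_pN)
    return rec
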