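"""Vectorized evaluation of the coarse-grained potential.

A :class:`ConstructModel` is compiled once into flat index/parameter arrays;
energies and forces are then evaluated with numpy per call.  The potential
is split into a *bonded* part (harmonic bonds and elastic-network springs,
harmonic angles in degrees, periodic torsions) and a *nonbonded* part
(attractive 12-10 native wells, 12-6 hydrophobic/polar pairs, and a purely
repulsive excluded-volume term over all remaining pairs), matching the
multiple-time-stepping split of the integrator.
"""

from __future__ import annotations

import numpy as np

from .model import ConstructModel

__all__ = ["CompiledForceField", "compile_model"]

_DEG = 180.0 / np.pi


class CompiledForceField:
    def __init__(self, model: ConstructModel):
        n = model.n_beads
        self.n = n
        bonds = list(model.bonds) + list(model.springs)
        self.bond_idx = np.array([(b.i, b.j) for b in bonds], int).reshape(-1, 2)
        self.bond_r0 = np.array([b.r0 for b in bonds], float)
        self.bond_k = np.array([b.k for b in bonds], float)

        self.ang_idx = np.array([(a.i, a.j, a.k) for a in model.angles],
                                int).reshape(-1, 3)
        self.ang_t0 = np.array([a.theta0_deg for a in model.angles], float)
        self.ang_k = np.array([a.k_theta for a in model.angles], float)

        self.tor_idx = np.array([(t.i, t.j, t.k, t.l) for t in model.torsions],
                                int).reshape(-1, 4)
        self.tor_phi0 = np.radians(
            np.array([t.phi0_deg for t in model.torsions], float))
        self.tor_n = np.array([t.multiplicity for t in model.torsions], float)
        self.tor_k = np.array([t.k_phi for t in model.torsions], float)

        self.nat_idx = np.array([(p.i, p.j) for p in model.native_pairs],
                                int).reshape(-1, 2)
        self.nat_r0 = np.array([p.r_native for p in model.native_pairs], float)
        self.nat_eps = np.array([p.well_depth for p in model.native_pairs], float)

        self.hp_idx = np.array([(p.i, p.j) for p in model.hp_pairs],
                               int).reshape(-1, 2)
        self.hp_sig = np.array([p.contact_distance for p in model.hp_pairs], float)
        self.hp_eps = np.array([p.eps for p in model.hp_pairs], float)

        # excluded-volume candidates: all pairs ≥ 3 residues apart along the
        # chain that carry no explicit bonded/spring/native/HP term.
        # Residue ordinals run through the whole construct (local residue
        # numbering restarts per segment).
        resord = np.empty(n, int)
        count = -1
        prev = None
        for b_i, (bead, seg) in enumerate(zip(model.beads, model.segment_labels)):
            key = (seg, bead.residue_local_index)
            if key != prev:
                count += 1
                prev = key
            resord[b_i] = count
        excluded = np.zeros((n, n), bool)
        np.fill_diagonal(excluded, True)
        for arr in (self.bond_idx, self.nat_idx, self.hp_idx):
            if len(arr):
                excluded[arr[:, 0], arr[:, 1]] = True
                excluded[arr[:, 1], arr[:, 0]] = True
        for a in model.angles:
            excluded[a.i, a.k] = excluded[a.k, a.i] = True
        for t in model.torsions:
            excluded[t.i, t.l] = excluded[t.l, t.i] = True
        iu, ju = np.triu_indices(n, k=1)
        near = np.abs(resord[iu] - resord[ju]) < 3
        keep = ~excluded[iu, ju] & ~near
        self.rep_idx = np.stack([iu[keep], ju[keep]], axis=1)
        self.rep_sigma = model.excluded_volume_radius
        self.rep_eps = model.excluded_volume_eps


    def _scatter_add(self, f: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
        for c in range(3):
            f[:, c] += np.bincount(idx, weights=vals[:, c], minlength=self.n)

    # -- bonded -------------------------------------------------------------
    def bonded(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        f = np.zeros_like(x)
        e = 0.0
        if len(self.bond_idx):
            ri = x[self.bond_idx[:, 0]]
            rj = x[self.bond_idx[:, 1]]
            dv = ri - rj
            d = np.linalg.norm(dv, axis=1)
            dd = d - self.bond_r0
            e += float(0.5 * np.sum(self.bond_k * dd ** 2))
            fmag = (-self.bond_k * dd / np.maximum(d, 1e-12))[:, None] * dv
            self._scatter_add(f, self.bond_idx[:, 0], fmag)
            self._scatter_add(f, self.bond_idx[:, 1], -fmag)
        if len(self.ang_idx):
            e += self._angles(x, f)
        if len(self.tor_idx):
            e += self._torsions(x, f)
        return e, f

    def _angles(self, x: np.ndarray, f: np.ndarray) -> float:
        i, j, k = self.ang_idx.T
        u = x[i] - x[j]
        v = x[k] - x[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        theta = np.degrees(np.arccos(cos))
        dtheta = theta - self.ang_t0
        e = float(0.5 * np.sum(self.ang_k * dtheta ** 2))
        # dU/dθ_rad = kθ · Δθ_deg · (180/π)
        du = self.ang_k * dtheta * _DEG
        sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
        dthe_di = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
        dthe_dk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
        fi = -du[:, None] * dthe_di
        fk = -du[:, None] * dthe_dk
        self._scatter_add(f, i, fi)
        self._scatter_add(f, k, fk)
        self._scatter_add(f, j, -(fi + fk))
        return e

    def _torsions(self, x: np.ndarray, f: np.ndarray) -> float:
        i, j, k, l = self.tor_idx.T
        b1 = x[j] - x[i]
        b2 = x[k] - x[j]
        b3 = x[l] - x[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m1 = np.cross(n1, b2 / nb2[:, None])
        phi = np.arctan2(np.sum(m1 * n2, axis=1), np.sum(n1 * n2, axis=1))
        arg = self.tor_n * phi - self.tor_phi0
        e = float(np.sum(self.tor_k * (1.0 + np.cos(arg))))
        du = -self.tor_k * self.tor_n * np.sin(arg)  # dU/dφ
        sq1 = np.maximum(np.sum(n1 ** 2, axis=1), 1e-12)
        sq2 = np.maximum(np.sum(n2 ** 2, axis=1), 1e-12)
        # gradient of φ (atan2 convention above); validated against
        # finite differences in the test suite
        dphi_di = (nb2 / sq1)[:, None] * n1
        dphi_dl = (-nb2 / sq2)[:, None] * n2
        c12 = np.sum(b1 * b2, axis=1) / nb2 ** 2
        c32 = np.sum(b3 * b2, axis=1) / nb2 ** 2
        dphi_dj = (-(1.0 + c12))[:, None] * dphi_di + c32[:, None] * dphi_dl
        dphi_dk = -(dphi_di + dphi_dj + dphi_dl)
        self._scatter_add(f, i, -du[:, None] * dphi_di)
        self._scatter_add(f, j, -du[:, None] * dphi_dj)
        self._scatter_add(f, k, -du[:, None] * dphi_dk)
        self._scatter_add(f, l, -du[:, None] * dphi_dl)
        return e

    # -- nonbonded ----------------------------------------------------------
    def nonbonded(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        f = np.zeros_like(x)
        e = 0.0
        if len(self.nat_idx):
            e += self._pair_1210(x, f)
        if len(self.hp_idx):
            e += self._pair_126(x, f)
        if len(self.rep_idx):
            e += self._repulsion(x, f)
        return e, f

    def _pair_1210(self, x, f) -> float:
        i, j = self.nat_idx.T
        dv = x[i] - x[j]
        d = np.linalg.norm(dv, axis=1)
        s = self.nat_r0 / np.maximum(d, 1e-9)
        s10 = s ** 10
        s12 = s10 * s * s
        e = float(np.sum(self.nat_eps * (5.0 * s12 - 6.0 * s10)))
        # dU/dd = eps·60·(s¹⁰ − s¹²)/d ; F = −dU/dd · d̂
        du = self.nat_eps * 60.0 * (s10 - s12) / np.maximum(d, 1e-9)
        fv = (-du / np.maximum(d, 1e-9))[:, None] * dv
        self._scatter_add(f, i, fv)
        self._scatter_add(f, j, -fv)
        return e

    def _pair_126(self, x, f) -> float:
        i, j = self.hp_idx.T
        dv = x[i] - x[j]
        d = np.linalg.norm(dv, axis=1)
        s = self.hp_sig / np.maximum(d, 1e-9)
        s6 = s ** 6
        s12 = s6 ** 2
        e = float(np.sum(self.hp_eps * (s12 - 2.0 * s6)))
        du = self.hp_eps * 12.0 * (s6 - s12) / np.maximum(d, 1e-9)
        fv = (-du / np.maximum(d, 1e-9))[:, None] * dv
        self._scatter_add(f, i, fv)
        self._scatter_add(f, j, -fv)
        return e

    def _repulsion(self, x, f) -> float:
        i, j = self.rep_idx.T
        dv = x[i] - x[j]
        d = np.linalg.norm(dv, axis=1)
        inside = d < self.rep_sigma
        if not np.any(inside):
            return 0.0
        d = d[inside]
        dv = dv[inside]
        s = self.rep_sigma / np.maximum(d, 1e-9)
        s12 = s ** 12
        e = float(self.rep_eps * np.sum(s12 - 1.0))
        du = -12.0 * self.rep_eps * s12 / np.maximum(d, 1e-9)
        fv = (-du / np.maximum(d, 1e-9))[:, None] * dv
        self._scatter_add(f, i[inside], fv)
        self._scatter_add(f, j[inside], -fv)
        return e

    def energy_forces(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        eb, fb = self.bonded(x)
        en, fn = self.nonbonded(x)
        return eb + en, fb + fn


def compile_model(model: ConstructModel) -> CompiledForceField:
    """Flatten a model's term lists into arrays ready for the integrator."""
    return CompiledForceField(model)
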