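"""Coarse-grained model construction.

Builds multi-resolution bead models of protein domains and of the
A1-L12-A2-L23-A3 multi-domain construct:

* elastic-network domains — every native pair of sites within a spatial
  cutoff (default 6 Å) is restrained by a harmonic spring at its native
  distance (spring constant 5 kcal mol⁻¹ Å⁻² by default), keeping a folded
  domain near its crystal conformation;
* simplified one-bead-per-residue linker chains with harmonic bonds and
  angles, a periodic torsion, and a two-class (hydrophobic/polar)
  non-bonded potential;
* a structure-based (Gō-like) representation for domains that must be able
  to unfold: native geometry defines the bonded reference and an attractive
  12-10 well for every native pair, so the native state is the energy
  minimum but contacts are breakable under load;
* the catalogue of native backbone hydrogen bonds (O···HN within 3 Å in
  the reference structure) used for the smooth contact-count order
  parameter, labelled by β-strand pair.

Internally coordinates are Å, residue indices 1-based and pair lists are
stored with i < j.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Bead",
    "HarmonicBond",
    "HarmonicAngle",
    "PeriodicTorsion",
    "NativePair",
    "HPPair",
    "ElasticNetworkTerms",
    "LinkerForceField",
    "GoTerms",
    "DomainModel",
    "ConstructModel",
    "HBondContact",
    "NativeHBondSet",
    "ResidueNumbering",
    "load_ca_structure",
    "build_elastic_network",
    "build_linker_chain",
    "classify_hp",
    "build_go_model",
    "derive_native_hbonds",
    "assemble_construct",
    "map_residue_number",
]

# Average residue (in-chain) masses, Da.
RESIDUE_MASS = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16,
    "ASN": 114.10, "ASP": 115.09, "GLN": 128.13, "LYS": 128.17,
    "GLU": 129.12, "MET": 131.19, "HIS": 137.14, "PHE": 147.18,
    "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
}
BACKBONE_MASS = 56.04  # N + Cα + C' + O

ONE_TO_THREE = {
    "G": "GLY", "A": "ALA", "S": "SER", "P": "PRO", "V": "VAL", "T": "THR",
    "C": "CYS", "L": "LEU", "I": "ILE", "N": "ASN", "D": "ASP", "Q": "GLN",
    "K": "LYS", "E": "GLU", "M": "MET", "H": "HIS", "F": "PHE", "R": "ARG",
    "Y": "TYR", "W": "TRP",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# Hydrophobic residues: positive Kyte–Doolittle hydropathy. All others polar.
_HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "CYS"}


class ModelError(ValueError):
    """Raised for invalid model-construction inputs."""


# ---------------------------------------------------------------------------
# term containers
# ---------------------------------------------------------------------------

@dataclass
class Bead:
    """A single coarse-grained site.

    ``hp_class`` is ``"none"`` except for linker beads, which carry the
    two-letter hydrophobic/polar class used by the linker non-bonded
    potential.
    """

    id: int
    residue_local_index: int
    residue_name: str
    bead_role: str  # backbone | sidechain | linker | site_o | site_h
    position: np.ndarray
    mass: float = BACKBONE_MASS
    hp_class: str = "none"
    residue_global_index: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.residue_local_index < 1:
            raise ModelError("residue_local_index must be >= 1")
        if self.mass <= 0:
            raise ModelError("bead mass must be positive")
        if (self.hp_class != "none") != (self.bead_role == "linker"):
            raise ModelError("hp_class is set iff bead_role == 'linker'")


@dataclass(frozen=True)
class HarmonicBond:
    i: int
    j: int
    r0: float
    k: float  # kcal mol⁻¹ Å⁻²; U = ½ k (d − r0)²


@dataclass(frozen=True)
class HarmonicAngle:
    i: int
    j: int
    k: int
    theta0_deg: float
    k_theta: float  # kcal mol⁻¹ deg⁻²; U = ½ kθ (θ − θ0)², θ in degrees


@dataclass(frozen=True)
class PeriodicTorsion:
    i: int
    j: int
    k: int
    l: int
    phi0_deg: float
    multiplicity: int
    k_phi: float  # kcal mol⁻¹; U = kφ (1 + cos(nφ − φ0))


@dataclass(frozen=True)
class NativePair:
    """Attractive 12-10 well at the native distance (depth ``well_depth``)."""

    i: int
    j: int
    r_native: float
    well_depth: float


@dataclass(frozen=True)
class HPPair:
    """Linker non-bonded 12-6 pair with minimum −eps at ``contact_distance``."""

    i: int
    j: int
    contact_distance: float
    eps: float


@dataclass
class ElasticNetworkTerms:
    springs: list[HarmonicBond]
    cutoff: float


@dataclass
class LinkerForceField:
    """Parameters of the simplified one-bead-per-residue linker chain."""

    r0: float = 3.8
    kb: float = 149.0
    theta0: float = 110.0
    ktheta: float = 1.5e-3
    phi0: float = 180.0
    multiplicity: int = 2
    kphi: float = 1.0
    hp_pair_params: dict = field(default_factory=lambda: {
        "HH": (0.5, 6.0), "PP": (0.2, 6.0), "HP": (0.2, 6.0),
    })

    def __post_init__(self) -> None:
        if min(self.kb, self.ktheta, self.kphi) < 0:
            raise ModelError("linker force constants must be non-negative")


@dataclass
class GoTerms:
    bonds: list[HarmonicBond]
    angles: list[HarmonicAngle]
    torsions: list[PeriodicTorsion]
    native_pairs: list[NativePair]
    nonnative_excluded_volume_radius: float = 4.0


@dataclass
class DomainModel:
    """Beads plus whichever term set represents the domain."""

    beads: list[Bead]
    elastic: ElasticNetworkTerms | None = None
    go: GoTerms | None = None


@dataclass(frozen=True)
class HBondContact:
    donor_h: int       # index of the donor HN site in the coordinate array
    acceptor_o: int    # index of the acceptor O site
    donor_res: int
    acceptor_res: int
    d_ref: float
    strand_pair_label: str = "other"


@dataclass
class NativeHBondSet:
    contacts: list[HBondContact]
    smoothing_a: float = 0.5  # Å⁻¹
    cutoff: float = 3.0

    def __post_init__(self) -> None:
        if self.smoothing_a <= 0:
            raise ModelError("smoothing_a must be positive")
        for c in self.contacts:
            if c.d_ref > self.cutoff + 1e-12:
                raise ModelError(
                    f"contact {c.donor_res}-{c.acceptor_res} has d_ref "
                    f"{c.d_ref:.2f} beyond the {self.cutoff} Å definition cutoff")

    def labels(self) -> list[str]:
        return sorted({c.strand_pair_label for c in self.contacts})


@dataclass(frozen=True)
class ResidueNumbering:
    """Affine map from local (domain) to global (full-sequence) numbering."""

    global_start: int
    length: int


def map_residue_number(numbering: ResidueNumbering, local_index: int) -> int:
    """Global residue index of a 1-based local index.

    The vWf A2 numbering convention maps local residue 1 onto Tyr1605's
    position minus 110, i.e. local 111 (the cleavage-site tyrosine) onto
    global 1605 when ``global_start`` is 1495.
    """
    if not 1 <= local_index <= numbering.length:
        raise ModelError(
            f"local index {local_index} outside [1, {numbering.length}]")
    return numbering.global_start + local_index - 1


# ---------------------------------------------------------------------------
# the assembled construct
# ---------------------------------------------------------------------------

@dataclass
class ConstructModel:
    """A single coarse-grained chain with all its interaction terms.

    ``segment_labels`` assigns each bead to one of the construct segments
    (for the default vWf tri-domain construct: A1, L12, A2, L23, A3).
    ``terminal_bonds`` are indices into ``bonds`` of the two instrumented
    harmonic bonds joining the flexible central domain's termini to the
    linker ends; their stretch k(d − d0) is the tensile-force readout.
    """

    beads: list[Bead]
    segment_labels: list[str]
    bonds: list[HarmonicBond] = field(default_factory=list)
    angles: list[HarmonicAngle] = field(default_factory=list)
    torsions: list[PeriodicTorsion] = field(default_factory=list)
    springs: list[HarmonicBond] = field(default_factory=list)
    native_pairs: list[NativePair] = field(default_factory=list)
    hp_pairs: list[HPPair] = field(default_factory=list)
    terminal_bonds: list[int] = field(default_factory=list)
    excluded_volume_radius: float = 4.0
    excluded_volume_eps: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.segment_labels) != len(self.beads):
            raise ModelError("one segment label per bead required")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads], dtype=float)

    def segment_indices(self, label: str) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.segment_labels)
                        if s == label], dtype=int)
        if idx.size == 0:
            raise ModelError(
                f"no segment {label!r}; have {sorted(set(self.segment_labels))}")
        return idx

    def segment_backbone_indices(self, label: str) -> np.ndarray:
        idx = [i for i in self.segment_indices(label)
               if self.beads[i].bead_role in ("backbone", "linker")]
        return np.asarray(idx, dtype=int)

    def residue_bead_indices(self, label: str, residue_local: int) -> np.ndarray:
        idx = [i for i in self.segment_indices(label)
               if self.beads[i].residue_local_index == residue_local]
        if not idx:
            raise ModelError(f"residue {residue_local} absent from segment {label}")
        return np.asarray(idx, dtype=int)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        def bead_dict(b: Bead) -> dict:
            d = asdict(b)
            d["position"] = [float(x) for x in b.position]
            return d

        payload = {
            "units": {"length": "angstrom", "energy": "kcal/mol",
                      "mass": "amu", "angle": "degree"},
            "beads": [bead_dict(b) for b in self.beads],
            "segment_labels": self.segment_labels,
            "bonds": [asdict(t) for t in self.bonds],
            "angles": [asdict(t) for t in self.angles],
            "torsions": [asdict(t) for t in self.torsions],
            "springs": [asdict(t) for t in self.springs],
            "native_pairs": [asdict(t) for t in self.native_pairs],
            "hp_pairs": [asdict(t) for t in self.hp_pairs],
            "terminal_bonds": self.terminal_bonds,
            "excluded_volume_radius": self.excluded_volume_radius,
            "excluded_volume_eps": self.excluded_volume_eps,
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ConstructModel":
        d = json.loads(text)
        return cls(
            beads=[Bead(**b) for b in d["beads"]],
            segment_labels=d["segment_labels"],
            bonds=[HarmonicBond(**t) for t in d["bonds"]],
            angles=[HarmonicAngle(**t) for t in d["angles"]],
            torsions=[PeriodicTorsion(**t) for t in d["torsions"]],
            springs=[HarmonicBond(**t) for t in d["springs"]],
            native_pairs=[NativePair(**t) for t in d["native_pairs"]],
            hp_pairs=[HPPair(**t) for t in d["hp_pairs"]],
            terminal_bonds=list(d["terminal_bonds"]),
            excluded_volume_radius=d["excluded_volume_radius"],
            excluded_volume_eps=d["excluded_volume_eps"],
            metadata=d.get("metadata", {}),
        )

    def to_pdb(self) -> str:
        """Write beads as pseudo-atom ATOM records (segment in the chain field)."""
        seg_chain = {}
        lines = []
        for i, (b, seg) in enumerate(zip(self.beads, self.segment_labels)):
            chain = seg_chain.setdefault(seg, chr(ord("A") + len(seg_chain) % 26))
            name = {"backbone": "CA", "sidechain": "SC", "linker": "CA",
                    "site_o": "O", "site_h": "H"}.get(b.bead_role, "X")
            x, y, z = b.position
            lines.append(
                f"ATOM  {i + 1:5d} {name:^4s}{b.residue_name:>4s} {chain}"
                f"{b.residue_local_index % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def classify_hp(residue_name: str) -> str:
    """Two-class hydrophobic/polar assignment.

    A residue is hydrophobic (``"H"``) when its Kyte–Doolittle hydropathy is
    positive (Ala, Val, Leu, Ile, Met, Phe, Cys) and polar (``"P"``)
    otherwise.  Accepts one- or three-letter codes.
    """
    code = residue_name.strip().upper()
    if len(code) == 1:
        if code not in ONE_TO_THREE:
            raise ModelError(f"unknown residue code {residue_name!r}")
        code = ONE_TO_THREE[code]
    if code not in RESIDUE_MASS:
        raise ModelError(f"unknown residue code {residue_name!r}")
    return "H" if code in _HYDROPHOBIC else "P"


def load_ca_structure(pdb_text: str, chain: str = "A") -> list[Bead]:
    """Reduce a PDB chain to one Cα bead per residue plus a sidechain bead.

    The sidechain bead sits at the centroid of the side-chain heavy atoms and
    is absent for glycine.  Residue numbering from the file is preserved in
    ``residue_global_index``.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", io.StringIO(pdb_text))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain not in chains:
        raise ModelError(
            f"chain {chain!r} not found; available chains: {sorted(chains)}")

    backbone_names = {"N", "CA", "C", "O", "OXT"}
    beads: list[Bead] = []
    missing_ca: list[int] = []
    bead_id = 0
    local = 0
    for residue in chains[chain]:
        if residue.id[0] != " ":  # skip HETATM/water
            continue
        local += 1
        resname = residue.get_resname()
        if "CA" not in residue:
            missing_ca.append(residue.id[1])
            continue
        mass_sc = max(RESIDUE_MASS.get(resname, 110.0) - BACKBONE_MASS, 1.0)
        beads.append(Bead(
            id=bead_id, residue_local_index=local, residue_name=resname,
            bead_role="backbone", position=residue["CA"].coord.astype(float),
            mass=BACKBONE_MASS, residue_global_index=residue.id[1]))
        bead_id += 1
        side = [a.coord for a in residue
                if a.element != "H" and a.get_name() not in backbone_names]
        if side and resname != "GLY":
            beads.append(Bead(
                id=bead_id, residue_local_index=local, residue_name=resname,
                bead_role="sidechain",
                position=np.mean(np.asarray(side, dtype=float), axis=0),
                mass=mass_sc, residue_global_index=residue.id[1]))
            bead_id += 1
    if missing_ca:
        raise ModelError(f"residues with no Cα atom: {missing_ca}")
    if not beads:
        raise ModelError(f"chain {chain!r} contains no amino-acid residues")
    return beads


def build_elastic_network(beads: Sequence[Bead], cutoff: float = 6.0,
                          k_spring: float = 5.0) -> ElasticNetworkTerms:
    """Harmonic springs between all site pairs closer than ``cutoff``.

    Each spring's equilibrium length is the native inter-site distance, so
    the native configuration is the exact energy minimum of the network.
    """
    if len(beads) < 2:
        raise ModelError("elastic network needs at least 2 beads")
    pos = np.array([b.position for b in beads], dtype=float)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    iu, ju = np.triu_indices(len(beads), k=1)
    if np.all(dist[iu, ju] < 1e-9):
        raise ModelError("degenerate geometry: all beads coincident")
    springs = [
        HarmonicBond(int(i), int(j), float(dist[i, j]), float(k_spring))
        for i, j in zip(iu, ju) if dist[i, j] < cutoff
    ]
    return ElasticNetworkTerms(springs=springs, cutoff=float(cutoff))


def build_linker_chain(sequence: str, ff: LinkerForceField | None = None,
                       start_id: int = 0, origin: np.ndarray | None = None,
                       direction: np.ndarray | None = None):
    """One-bead-per-residue linker with bonds, angles, torsions and HP pairs.

    Beads are laid out on a near-straight line (a small zig-zag keeps
    torsions well defined) starting at ``origin`` along ``direction``.

    Returns ``(beads, bonds, angles, torsions, hp_pairs)``.
    """
    ff = ff or LinkerForceField()
    if len(sequence) < 2:
        raise ModelError("linker needs at least 2 residues")
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    direction = np.array([1.0, 0.0, 0.0]) if direction is None else (
        np.asarray(direction, float) / np.linalg.norm(direction))
    perp = np.array([0.0, 1.0, 0.0])
    if abs(direction @ perp) > 0.9:
        perp = np.array([0.0, 0.0, 1.0])
    perp = perp - (perp @ direction) * direction
    perp /= np.linalg.norm(perp)

    beads: list[Bead] = []
    for n, letter in enumerate(sequence):
        three = ONE_TO_THREE.get(letter.upper())
        if three is None:
            raise ModelError(f"unknown residue letter {letter!r} in linker")
        wiggle = 0.25 * perp * (-1) ** n
        beads.append(Bead(
            id=start_id + n, residue_local_index=n + 1, residue_name=three,
            bead_role="linker", position=origin + n * ff.r0 * direction + wiggle,
            mass=RESIDUE_MASS[three], hp_class=classify_hp(three)))

    ids = [b.id for b in beads]
    bonds = [HarmonicBond(ids[n], ids[n + 1], ff.r0, ff.kb)
             for n in range(len(ids) - 1)]
    angles = [HarmonicAngle(ids[n], ids[n + 1], ids[n + 2], ff.theta0, ff.ktheta)
              for n in range(len(ids) - 2)]
    torsions = [PeriodicTorsion(ids[n], ids[n + 1], ids[n + 2], ids[n + 3],
                                ff.phi0, ff.multiplicity, ff.kphi)
                for n in range(len(ids) - 3)]
    hp_pairs = []
    for a in range(len(beads)):
        for b in range(a + 3, len(beads)):
            key = "".join(sorted(beads[a].hp_class + beads[b].hp_class))
            key = {"HH": "HH", "PP": "PP", "HP": "HP"}[key]
            eps, dist = ff.hp_pair_params[key]
            hp_pairs.append(HPPair(ids[a], ids[b], dist, eps))
    return beads, bonds, angles, torsions, hp_pairs


def build_go_model(beads: Sequence[Bead], native_cutoff: float = 6.5,
                   min_residue_separation: int = 3, well_depth: float = 0.5,
                   kb: float = 149.0, ktheta: float = 1.5e-3,
                   kphi: float = 0.2,
                   excluded_volume_radius: float = 4.0) -> GoTerms:
    """Structure-based potential with the supplied conformation as native state.

    Bonded terms (consecutive-backbone bonds, angles, weak torsions, and
    attachment bonds for non-backbone sites) are harmonic/periodic at the
    native geometry.  Native pairs are all bead pairs at least
    ``min_residue_separation`` residues apart and closer than
    ``native_cutoff``; each receives a 12-10 well of depth ``well_depth``,
    the single stability knob of the model.
    """
    residues = sorted({b.residue_local_index for b in beads})
    if len(residues) < 4:
        raise ModelError("structure-based model needs at least 4 residues")
    backbone = [b for b in beads if b.bead_role in ("backbone", "linker")]
    backbone.sort(key=lambda b: b.residue_local_index)

    def d(a: Bead, b: Bead) -> float:
        return float(np.linalg.norm(a.position - b.position))

    bonds = [HarmonicBond(a.id, b.id, d(a, b), kb)
             for a, b in zip(backbone, backbone[1:])]
    by_res: dict[int, Bead] = {b.residue_local_index: b for b in backbone}
    for b in beads:
        if b.bead_role not in ("backbone", "linker"):
            bonds.append(HarmonicBond(
                *sorted((by_res[b.residue_local_index].id, b.id)),
                d(by_res[b.residue_local_index], b), kb))

    def angle_deg(a, b, c) -> float:
        u = a.position - b.position
        v = c.position - b.position
        cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))

    angles = [HarmonicAngle(a.id, b.id, c.id, angle_deg(a, b, c), ktheta)
              for a, b, c in zip(backbone, backbone[1:], backbone[2:])]
    def dihedral_deg(a, b, c, e) -> float:
        b1 = b.position - a.position
        b2 = c.position - b.position
        b3 = e.position - c.position
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        return float(np.degrees(np.arctan2(m1 @ n2, n1 @ n2)))

    # phi0 = native dihedral − 180° makes U = kφ(1 − cos(φ − φ_native)):
    # zero at the native geometry, positive elsewhere.
    torsions = [PeriodicTorsion(a.id, b.id, c.id, e.id,
                                dihedral_deg(a, b, c, e) - 180.0, 1, kphi)
                for a, b, c, e in zip(backbone, backbone[1:],
                                      backbone[2:], backbone[3:])]

    pairs = []
    blist = list(beads)
    for x in range(len(blist)):
        for y in range(x + 1, len(blist)):
            a, b = blist[x], blist[y]
            if abs(a.residue_local_index - b.residue_local_index) < min_residue_separation:
                continue
            dist = d(a, b)
            if dist < native_cutoff:
                pairs.append(NativePair(*sorted((a.id, b.id)), dist, well_depth))
    return GoTerms(bonds=bonds, angles=angles, torsions=torsions,
                   native_pairs=pairs,
                   nonnative_excluded_volume_radius=excluded_volume_radius)


def derive_native_hbonds(residue_index: Sequence[int], o_pos: np.ndarray,
                         h_pos: np.ndarray, cutoff: float = 3.0,
                         min_residue_separation: int = 2,
                         strand_ranges: dict[str, tuple[int, int]] | None = None,
                         o_site_index: Sequence[int] | None = None,
                         h_site_index: Sequence[int] | None = None,
                         smoothing_a: float = 0.5) -> NativeHBondSet:
    """Catalogue native backbone O···HN hydrogen bonds.

    ``o_pos[r]``/``h_pos[r]`` are the carbonyl-O and amide-H positions of
    residue ``residue_index[r]`` in the reference structure.  Every
    (acceptor O of residue i, donor HN of residue j) pair with
    |i − j| ≥ ``min_residue_separation`` and distance ≤ ``cutoff`` becomes a
    contact.  When both residues fall inside two β-strand ranges the contact
    is labelled with that strand pair (e.g. the vWf A2 defaults β1 3–10,
    β4 108–114, β5 129–136, β6 155–157 give labels β1β4/β4β5/β5β6);
    otherwise it is labelled ``other``.

    ``o_site_index``/``h_site_index`` optionally map each residue to the
    index of its O/H pseudo-atom in the coordinate array used for trajectory
    frames; they default to the row index.
    """
    if strand_ranges is None:
        strand_ranges = {"β1": (3, 10), "β4": (108, 114),
                         "β5": (129, 136), "β6": (155, 157)}
    order = list(strand_ranges)
    o_pos = np.asarray(o_pos, float)
    h_pos = np.asarray(h_pos, float)
    if o_pos.shape != h_pos.shape or o_pos.ndim != 2:
        raise ModelError("O and HN coordinate arrays must both be (n, 3)")
    n = len(residue_index)
    o_site_index = list(range(n)) if o_site_index is None else list(o_site_index)
    h_site_index = list(range(n)) if h_site_index is None else list(h_site_index)

    def strand_of(res: int) -> str | None:
        for name, (lo, hi) in strand_ranges.items():
            if lo <= res <= hi:
                return name
        return None

    contacts = []
    dist = np.sqrt(((o_pos[:, None, :] - h_pos[None, :, :]) ** 2).sum(-1))
    for a in range(n):           # acceptor O of residue a
        for dnr in range(n):     # donor HN of residue dnr
            ra, rd = residue_index[a], residue_index[dnr]
            if abs(ra - rd) < min_residue_separation:
                continue
            if dist[a, dnr] > cutoff:
                continue
            sa, sd = strand_of(ra), strand_of(rd)
            if sa and sd and sa != sd:
                lo, hi = sorted((sa, sd), key=order.index)
                label = f"{lo}{hi}"
            else:
                label = "other"
            contacts.append(HBondContact(
                donor_h=h_site_index[dnr], acceptor_o=o_site_index[a],
                donor_res=rd, acceptor_res=ra,
                d_ref=float(dist[a, dnr]), strand_pair_label=label))
    return NativeHBondSet(contacts=contacts, smoothing_a=smoothing_a,
                          cutoff=cutoff)


def rebuild_amide_hydrogens(n_pos: np.ndarray, ca_pos: np.ndarray,
                            c_prev_pos: np.ndarray,
                            nh_length: float = 1.0) -> np.ndarray:
    """Planar geometric reconstruction of amide H from N, Cα and preceding C'.

    H is placed along the external bisector of the Cα−N−C'(prev) angle in
    the peptide plane, ``nh_length`` Å from N.
    """
    n_pos = np.asarray(n_pos, float)
    u = n_pos - np.asarray(ca_pos, float)
    v = n_pos - np.asarray(c_prev_pos, float)
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    w = u + v
    w = w / np.linalg.norm(w, axis=-1, keepdims=True)
    return n_pos + nh_length * w


def assemble_construct(domains: Sequence[DomainModel],
                       linker_sequences: Sequence[str],
                       linker_ff: LinkerForceField | None = None,
                       terminal_bond_k: float = 149.0,
                       terminal_bond_d0: float | None = None,
                       segment_names: Sequence[str] = ("A1", "L12", "A2", "L23", "A3"),
                       ) -> ConstructModel:
    """Chain three domain models through two linkers into one construct.

    Segments are laid out head-to-tail along +x with near-linear linkers.
    The two harmonic bonds that join the central domain's termini to the
    linker ends are instrumented as ``terminal_bonds`` for the tensile-force
    readout; the outer junctions are plain bonds with the linker force
    constant.  Junction equilibrium lengths default to the assembled
    native distance so the initial configuration carries no stress
    (``terminal_bond_d0`` overrides this for the instrumented bonds).
    """
    if len(domains) != 3 or len(linker_sequences) != 2:
        raise ModelError("need 3 domain models and 2 linker sequences")
    ff = linker_ff or LinkerForceField()
    dom_names = [segment_names[0], segment_names[2], segment_names[4]]
    link_names = [segment_names[1], segment_names[3]]

    beads: list[Bead] = []
    labels: list[str] = []
    bonds: list[HarmonicBond] = []
    angles: list[HarmonicAngle] = []
    torsions: list[PeriodicTorsion] = []
    springs: list[HarmonicBond] = []
    native_pairs: list[NativePair] = []
    hp_pairs: list[HPPair] = []
    chain_ends: list[tuple[int, int]] = []  # (first, last backbone bead id)

    cursor = 0.0

    def add_domain(dom: DomainModel, name: str) -> None:
        nonlocal cursor
        offset = len(beads)
        pos = np.array([b.position for b in dom.beads])
        shift = np.array([cursor - pos[:, 0].min(), 0.0, 0.0])
        id_map = {}
        first = last = None
        for b in dom.beads:
            nb = Bead(id=len(beads), residue_local_index=b.residue_local_index,
                      residue_name=b.residue_name, bead_role=b.bead_role,
                      position=b.position + shift, mass=b.mass,
                      hp_class=b.hp_class,
                      residue_global_index=b.residue_global_index)
            id_map[b.id] = nb.id
            beads.append(nb)
            labels.append(name)
            if b.bead_role in ("backbone", "linker"):
                first = first if first is not None else nb.id
                last = nb.id
        n_declared = len(dom.beads)
        if len(id_map) != n_declared:
            raise ModelError(f"duplicate bead ids in segment {name}")
        chain_ends.append((first, last))
        for terms in (dom.elastic, dom.go):
            if terms is None:
                continue
            if isinstance(terms, ElasticNetworkTerms):
                springs.extend(HarmonicBond(id_map[s.i], id_map[s.j], s.r0, s.k)
                               for s in terms.springs)
            else:
                bonds.extend(HarmonicBond(id_map[t.i], id_map[t.j], t.r0, t.k)
                             for t in terms.bonds)
                angles.extend(HarmonicAngle(id_map[t.i], id_map[t.j],
                                            id_map[t.k], t.theta0_deg, t.k_theta)
                              for t in terms.angles)
                torsions.extend(PeriodicTorsion(
                    id_map[t.i], id_map[t.j], id_map[t.k], id_map[t.l],
                    t.phi0_deg, t.multiplicity, t.k_phi) for t in terms.torsions)
                native_pairs.extend(NativePair(
                    id_map[t.i], id_map[t.j], t.r_native, t.well_depth)
                    for t in terms.native_pairs)
        cursor = max(b.position[0] for b in beads[offset:]) + ff.r0

    def add_linker(seq: str, name: str) -> None:
        nonlocal cursor
        lb, lbo, lan, lto, lhp = build_linker_chain(
            seq, ff, start_id=len(beads), origin=np.array([cursor, 0.0, 0.0]))
        for b in lb:
            beads.append(b)
            labels.append(name)
        bonds.extend(lbo)
        angles.extend(lan)
        torsions.extend(lto)
        hp_pairs.extend(lhp)
        chain_ends.append((lb[0].id, lb[-1].id))
        cursor = lb[-1].position[0] + ff.r0

    add_domain(domains[0], dom_names[0])
    add_linker(linker_sequences[0], link_names[0])
    add_domain(domains[1], dom_names[1])
    add_linker(linker_sequences[1], link_names[1])
    add_domain(domains[2], dom_names[2])

    # junctions: A1–L12 and L23–A3 plain; L12–A2 and A2–L23 instrumented
    (a1_f, a1_l), (l12_f, l12_l), (a2_f, a2_l), (l23_f, l23_l), (a3_f, a3_l) = chain_ends

    def native_dist(i: int, j: int) -> float:
        return float(np.linalg.norm(beads[i].position - beads[j].position))

    bonds.append(HarmonicBond(a1_l, l12_f, native_dist(a1_l, l12_f), ff.kb))
    terminal_bonds = []
    for i, j in ((l12_l, a2_f), (a2_l, l23_f)):
        d0 = terminal_bond_d0 if terminal_bond_d0 is not None else native_dist(i, j)
        bonds.append(HarmonicBond(i, j, d0, terminal_bond_k))
        terminal_bonds.append(len(bonds) - 1)
    bonds.append(HarmonicBond(l23_l, a3_f, native_dist(l23_l, a3_f), ff.kb))

    return ConstructModel(
        beads=beads, segment_labels=labels, bonds=bonds, angles=angles,
        torsions=torsions, springs=springs, native_pairs=native_pairs,
        hp_pairs=hp_pairs, terminal_bonds=terminal_bonds,
        metadata={"segments": list(segment_names),
                  "linker_lengths": [len(s) for s in linker_sequences]})
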