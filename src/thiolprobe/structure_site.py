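"""Geometry kernels for active-site analysis of protein coordinates.

Interatomic distances and heavy-atom contact (hydrogen-bond) inventories,
rigid least-squares superposition (Kabsch, SVD with proper-rotation
correction) with RMSD, and Shrake-Rupley solvent-accessible surface areas
on a deterministic golden-spiral sphere lattice, plus the chain-pair
buried/interface area bookkeeping built on top of them.

PDB files are parsed with gemmi; for alternate conformations the highest
occupancy wins (ties broken by altloc letter). Author residue numbering is
kept verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

import gemmi

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ContactList",
    "DEFAULT_RADII",
    "read_pdb",
    "atom_distance",
    "find_contacts",
    "kabsch_superpose",
    "sasa",
    "chain_asa",
    "interface_area",
    "buried_area",
]

#: united-atom van der Waals radii (Angstrom) used for SASA; configurable.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.00,
}

WATER_RESNAMES = {"HOH", "WAT", "DOD"}


class MissingRadiusError(KeyError):
    """An element present in the model has no radius in the radii set."""


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    resnum: int
    resname: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""
    is_water: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


class StructureModel:
    """An ordered collection of atoms with chain/residue/atom selectors."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms = list(atoms)
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.resnum, a.atom_name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def select(
        self,
        chain: str | None = None,
        resnum: int | None = None,
        atom_name: str | None = None,
        resname: str | None = None,
        include_waters: bool = False,
    ) -> "StructureModel":
        out = [
            a for a in self.atoms
            if (chain is None or a.chain == chain)
            and (resnum is None or a.resnum == resnum)
            and (atom_name is None or a.atom_name == atom_name)
            and (resname is None or a.resname == resname)
            and (include_waters or not a.is_water)
        ]
        return StructureModel(out)

    def atom(self, chain: str, resnum: int, atom_name: str) -> AtomRecord:
        hits = [a for a in self.atoms
                if a.chain == chain and a.resnum == resnum and a.atom_name == atom_name]
        if not hits:
            raise KeyError(f"no atom {chain}:{resnum}:{atom_name}")
        return hits[0]

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms]).reshape(-1, 3)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def ca_atoms(self, chain: str | None = None) -> "StructureModel":
        return self.select(chain=chain, atom_name="CA")


def read_pdb(path, keep_waters: bool = True) -> StructureModel:
    """Parse ATOM/HETATM records; keep the highest-occupancy altloc."""
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for chain in st[0]:
        for res in chain:
            is_water = res.name in WATER_RESNAMES
            if is_water and not keep_waters:
                continue
            for atom in res:
                key = (chain.name, res.seqid.num, atom.name)
                rec = AtomRecord(
                    chain=chain.name,
                    resnum=res.seqid.num,
                    resname=res.name,
                    atom_name=atom.name,
                    element=atom.element.name.upper(),
                    x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                    occupancy=atom.occ,
                    altloc=atom.altloc.strip() if atom.altloc else "",
                    is_water=is_water,
                )
                if key not in best:
                    best[key] = rec
                    order.append(key)
                else:
                    old = best[key]
                    if rec.occupancy > old.occupancy or (
                        rec.occupancy == old.occupancy and rec.altloc < old.altloc
                    ):
                        best[key] = rec
    return StructureModel([best[k] for k in order])


def atom_distance(a: AtomRecord, b: AtomRecord) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(a.xyz - b.xyz))


ContactList = list[tuple[AtomRecord, AtomRecord, float]]


def find_contacts(
    atom: AtomRecord,
    model: StructureModel,
    cutoff: float = 4.0,
    exclude_same_residue: bool = True,
    elements: Iterable[str] = ("N", "O", "S"),
) -> ContactList:
    """Polar heavy atoms within ``cutoff`` of ``atom``, sorted by distance.

    The default 4.0 A heavy-atom criterion is a distance-only hydrogen-bond
    inventory (no angle test), appropriate when only donor-acceptor
    distances are reported.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if not any(a is atom or (a.chain, a.resnum, a.atom_name) ==
               (atom.chain, atom.resnum, atom.atom_name) for a in model):
        raise KeyError("query atom not found in model")
    wanted = {e.upper() for e in elements}
    out: ContactList = []
    for other in model:
        if other is atom:
            continue
        if (other.chain, other.resnum, other.atom_name) == \
           (atom.chain, atom.resnum, atom.atom_name):
            continue
        if exclude_same_residue and (other.chain, other.resnum) == (atom.chain, atom.resnum):
            continue
        if other.element not in wanted:
            continue
        d = atom_distance(atom, other)
        if d <= cutoff:
            out.append((atom, other, d))
    out.sort(key=lambda c: c[2])
    return out


def kabsch_superpose(
    coords_ref: np.ndarray, coords_mov: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired point sets.

    Returns (rotation R, translation t, rmsd) such that ``mov @ R.T + t``
    best fits ``ref`` in least squares. The SVD determinant correction
    enforces a proper rotation; all pairs enter, no outlier rejection.
    """
    P = np.asarray(coords_ref, dtype=float)
    Q = np.asarray(coords_mov, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"need matching (n, 3) arrays, got {P.shape} and {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc) < 2 or np.linalg.matrix_rank(Qc) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - Q.mean(axis=0) @ R.T
    diff = Qc @ R.T - Pc
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: dict[str, float] | None = None,
    include_waters: bool = False,
) -> np.ndarray:
    """Shrake-Rupley per-atom solvent-accessible surface areas (A^2).

    Each atom's solvent-expanded sphere (vdW + probe) is sampled on a fixed
    golden-spiral lattice; a sample point is accessible when outside every
    neighbouring expanded sphere. Hydrogens and waters are excluded by
    default. Deterministic for a fixed lattice size.
    """
    radii = radii or DEFAULT_RADII
    atoms = [a for a in model
             if (include_waters or not a.is_water) and a.element != "H"]
    if not atoms:
        return np.zeros(0)
    try:
        r = np.array([radii[a.element] for a in atoms]) + probe_radius
    except KeyError as exc:
        raise MissingRadiusError(f"no radius for element {exc.args[0]!r}") from None
    xyz = np.array([[a.x, a.y, a.z] for a in atoms])
    sphere = _golden_spiral(n_sphere_points)
    tree = cKDTree(xyz)
    max_r = r.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        neighbours = [j for j in tree.query_ball_point(xyz[i], r[i] + max_r)
                      if j != i]
        pts = xyz[i] + r[i] * sphere
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d2 = ((pts - xyz[j]) ** 2).sum(axis=1)
            accessible &= d2 > r[j] ** 2
        areas[i] = 4.0 * np.pi * r[i] ** 2 * accessible.mean()
    return areas


def chain_asa(model: StructureModel, chains: Iterable[str], **kwargs) -> float:
    """Total ASA (A^2) of the sub-model consisting of the given chains."""
    chains = set(chains)
    sub = StructureModel([a for a in model if a.chain in chains and not a.is_water])
    return float(sasa(sub, **kwargs).sum())


def buried_area(model: StructureModel, chain_a: str, chain_b: str, **kwargs) -> float:
    """ASA buried on forming the A:B pair: ASA_A + ASA_B - ASA_AB."""
    asa_a = chain_asa(model, [chain_a], **kwargs)
    asa_b = chain_asa(model, [chain_b], **kwargs)
    asa_ab = chain_asa(model, [chain_a, chain_b], **kwargs)
    return asa_a + asa_b - asa_ab


def interface_area(model: StructureModel, chain_a: str, chain_b: str, **kwargs) -> float:
    """Interface area = half the buried area of the chain pair."""
    return max(buried_area(model, chain_a, chain_b, **kwargs), 0.0) / 2.0
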