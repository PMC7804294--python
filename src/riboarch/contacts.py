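"""Inter-chain interface detection by solvent-accessible surface area (SASA) loss.

An interface between two chains is operationally defined as the SASA buried
upon complex formation:

    buried(A, B) = SASA(A alone) + SASA(B alone) - SASA(A and B together)

computed with a rolling probe of radius 1.4 Angstrom (water).  SASA is
evaluated with a Shrake-Rupley style numerical scheme using a deterministic
golden-spiral point construction, so results are machine-stable for a fixed
point count.  The buried-area convention is *total* (both sides summed), never
halved; this is recorded in the contact metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

#: van der Waals radii (Angstrom), Bondi-style element table.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "SE": 1.90, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "FE": 1.52, "MN": 1.61, "CA": 2.31,
    "NA": 2.27, "K": 2.75,
}

DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with author residue numbering preserved verbatim."""

    chain_id: str
    residue_index: int
    icode: str
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    vdw_radius: float

    @property
    def residue_key(self) -> tuple[str, str]:
        """(chain, author residue number with insertion code concatenated)."""
        return (self.chain_id, f"{self.residue_index}{self.icode}".strip())


class StructureAtoms:
    """Atoms of a structure grouped by chain, in deposition order."""

    def __init__(self, chains: dict[str, list[AtomRecord]]):
        self.chains = chains

    def __getitem__(self, chain_id: str) -> list[AtomRecord]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(f"chain {chain_id!r} not found; available: "
                           f"{sorted(self.chains)}") from None

    def __contains__(self, chain_id: str) -> bool:
        return chain_id in self.chains

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def atoms(self, chain_ids: Iterable[str] | None = None) -> list[AtomRecord]:
        ids = self.chain_ids if chain_ids is None else list(chain_ids)
        out: list[AtomRecord] = []
        for cid in ids:
            out.extend(self[cid])
        return out

    def n_atoms(self) -> int:
        return sum(len(v) for v in self.chains.values())


def read_structure(path: str | Path, fmt: str | None = None,
                   include_hetero: bool = False,
                   default_radius: float = DEFAULT_RADIUS) -> StructureAtoms:
    """Read a PDB or mmCIF file into chain-grouped :class:`AtomRecord` lists.

    Waters and (by default) ligand HETATM records are excluded; hydrogens are
    dropped; for alternate conformations the highest-occupancy conformer is
    kept.  Unknown elements fall back to ``default_radius`` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb" or (fmt is None and path.suffix.lower() in {".pdb", ".ent"}):
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc

    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]

    chains: dict[str, list[AtomRecord]] = {}
    for chain in model:
        records: list[AtomRecord] = []
        for res in chain:
            if res.name in WATER_NAMES or res.is_water():
                continue
            if res.het_flag == "H" and not include_hetero and not res.is_water():
                # keep hetero polymers (e.g. modified residues) only on request
                continue
            # altloc: keep highest-occupancy conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                el = atom.element.name.upper()
                radius = VDW_RADII.get(el)
                if radius is None:
                    log.warning("unknown element %r in %s %s%s; using default "
                                "radius %.2f", el, chain.name, res.seqid.num,
                                res.name, default_radius)
                    radius = default_radius
                records.append(AtomRecord(
                    chain_id=chain.name,
                    residue_index=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    residue_name=res.name,
                    atom_name=name,
                    element=el,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    vdw_radius=radius,
                ))
        if records:
            chains[chain.name] = records
    if not chains:
        raise ValueError(f"{path}: no polymer chains with atoms found")
    return StructureAtoms(chains)


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere directions (deterministic)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    per_atom_area: np.ndarray          # Angstrom^2, aligned with the input atom list
    per_residue_area: dict[tuple[str, str], float]
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom_area.sum())


def _sasa_from_directions(coords: np.ndarray, radii: np.ndarray, probe: float,
                          directions_for_atom) -> np.ndarray:
    """Shared occlusion kernel: per-atom exposed fraction times sphere area.

    ``directions_for_atom(i)`` yields unit vectors for atom ``i``; a surface
    point is exposed when it lies outside every neighbour's expanded sphere.
    """
    n = len(coords)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = float(expanded.max())
    areas = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        neighbours = [j for j in tree.query_ball_point(coords[i], ri + max_r)
                      if j != i and
                      np.linalg.norm(coords[j] - coords[i]) < ri + expanded[j]]
        sphere_area = 4.0 * math.pi * ri * ri
        if not neighbours:
            areas[i] = sphere_area
            continue
        ncoords = coords[neighbours]
        nrad = expanded[neighbours]
        exposed = 0
        total = 0
        for dirs in directions_for_atom(i):
            pts = coords[i] + dirs * ri
            d2 = ((pts[:, None, :] - ncoords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nrad * nrad)[None, :]).any(axis=1)
            exposed += int((~buried).sum())
            total += len(dirs)
        areas[i] = sphere_area * exposed / total
    return areas


def compute_sasa(atoms: Sequence[AtomRecord], probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS) -> SasaResult:
    """Numerical SASA of an atom set (deterministic golden-spiral points)."""
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for stable areas")
    if not atoms:
        raise ValueError("empty atom set")
    coords = np.array([a.position for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float)
    dirs = golden_spiral_points(n_points)
    per_atom = _sasa_from_directions(coords, radii, probe, lambda i: (dirs,))
    per_res: dict[tuple[str, str], float] = {}
    for a, area in zip(atoms, per_atom):
        per_res[a.residue_key] = per_res.get(a.residue_key, 0.0) + float(area)
    return SasaResult(per_atom, per_res, probe, n_points)


def sasa_montecarlo(atoms: Sequence[AtomRecord], probe: float = DEFAULT_PROBE,
                    n_points: int = 1_000_000, seed: int = 0,
                    chunk: int = 50_000) -> float:
    """Independent dense Monte-Carlo SASA (random directions), total area only.

    Reference oracle for the deterministic sampler; O(n_atoms * n_points).
    """
    coords = np.array([a.position for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float)
    rng = np.random.default_rng(seed)

    def directions(_i):
        done = 0
        while done < n_points:
            k = min(chunk, n_points - done)
            v = rng.normal(size=(k, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            done += k
            yield v

    per_atom = _sasa_from_directions(coords, radii, probe, directions)
    return float(per_atom.sum())


@dataclass
class InterfaceContact:
    """A detected chain-chain contact with per-residue buried areas."""

    chain_a: str
    chain_b: str
    buried_area_total: float     # Angstrom^2, both sides summed
    residues_a: list[tuple[str, float]]   # (residue key within chain, dSASA)
    residues_b: list[tuple[str, float]]
    convention: str = "total_both_sides"

    def swapped(self) -> "InterfaceContact":
        return InterfaceContact(self.chain_b, self.chain_a,
                                self.buried_area_total,
                                list(self.residues_b), list(self.residues_a),
                                self.convention)


def _min_gap(coords_a, radii_a, coords_b, radii_b) -> float:
    """Smallest surface-to-surface distance between two atom sets."""
    tree = cKDTree(coords_b)
    d, idx = tree.query(coords_a)
    gaps = d - radii_a - radii_b[idx]
    return float(gaps.min())


def detect_interfaces(structure: StructureAtoms,
                      chain_pairs: Sequence[tuple[str, str]] | None = None,
                      probe: float = DEFAULT_PROBE,
                      burial_tol: float = 0.1,
                      burial_tol_res: float = 0.1,
                      n_points: int = DEFAULT_N_POINTS) -> list[InterfaceContact]:
    """Detect all pairwise chain-chain interfaces by SASA difference.

    A contact is emitted iff the total buried area exceeds ``burial_tol``;
    interface residues are those losing more than ``burial_tol_res`` of SASA.
    """
    ids = structure.chain_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 chains to detect interfaces")
    if chain_pairs is None:
        chain_pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    for a, b in chain_pairs:
        structure[a], structure[b]  # raises KeyError with available chains

    iso: dict[str, SasaResult] = {}

    def isolated(cid: str) -> SasaResult:
        if cid not in iso:
            iso[cid] = compute_sasa(structure[cid], probe, n_points)
        return iso[cid]

    contacts: list[InterfaceContact] = []
    for ca, cb in chain_pairs:
        atoms_a, atoms_b = structure[ca], structure[cb]
        xa = np.array([a.position for a in atoms_a])
        xb = np.array([a.position for a in atoms_b])
        ra = np.array([a.vdw_radius for a in atoms_a])
        rb = np.array([a.vdw_radius for a in atoms_b])
        if _min_gap(xa, ra, xb, rb) >= 2.0 * probe:
            continue  # no atom pair close enough for the probe to be excluded
        sa, sb = isolated(ca), isolated(cb)
        together = compute_sasa(list(atoms_a) + list(atoms_b), probe, n_points)
        buried = sa.total + sb.total - together.total
        if buried <= burial_tol:
            continue

        def iface(iso_res, cid):
            out = []
            for (chain, res), area in iso_res.per_residue_area.items():
                d = area - together.per_residue_area.get((chain, res), 0.0)
                if d > burial_tol_res:
                    out.append((res, float(d)))
            return sorted(out, key=lambda t: t[0])

        contacts.append(InterfaceContact(
            chain_a=ca, chain_b=cb, buried_area_total=float(buried),
            residues_a=iface(sa, ca), residues_b=iface(sb, cb)))
    return contacts


def contacts_to_tsv(contacts: Sequence[InterfaceContact], path: str | Path) -> None:
    import pandas as pd
    rows = [{"chain_a": c.chain_a, "chain_b": c.chain_b,
             "buried_area": round(c.buried_area_total, 2),
             "n_iface_res_a": len(c.residues_a),
             "n_iface_res_b": len(c.residues_b)} for c in contacts]
    pd.DataFrame(rows, columns=["chain_a", "chain_b", "buried_area",
                                "n_iface_res_a", "n_iface_res_b"]
                 ).to_csv(path, sep="\t", index=False)


def contacts_to_json(contacts: Sequence[InterfaceContact], path: str | Path) -> None:
    import json
    data = [{"chain_a": c.chain_a, "chain_b": c.chain_b,
             "buried_area_total": c.buried_area_total,
             "convention": c.convention,
             "residues_a": c.residues_a, "residues_b": c.residues_b}
            for c in contacts]
    Path(path).write_text(json.dumps(data, indent=1))
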