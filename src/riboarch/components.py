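"""Ribosomal-protein anatomy: globular domains, extensions and their statuses.

An r-protein is decomposed into a compact globular domain (G) plus zero or
more *extensions* — elongated protrusions classified into five structural
categories (segment, mix, alpha-helix, loop, beta-hairpin) located at the N-
or C-terminus or internally.  Each component carries an evolutionary status:
U/B/A/E for whole proteins, and Ub/Ua/Ue/Ae (or ``inherited``) for extensions
acquired after the protein itself.  Components are consumed from curated
annotation tables; they are never inferred from structure here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import AtomRecord, StructureAtoms

KINDS = {"globular", "extension", "extra_domain", "non_protein"}
CATEGORIES = {"segment", "mix", "helix", "loop", "beta_hairpin"}
TERMINI = {"N", "C", "internal"}
PROTEIN_STATUSES = {"U", "B", "A", "E"}
EXTENSION_STATUSES = {"inherited", "Ub", "Ua", "Ue", "Ae"}

#: approximate atomic masses for the optional mass-weighted COM
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
               "P": 30.974, "S": 32.06, "SE": 78.97}


@dataclass
class ProteinComponent:
    """A globular domain, extension or extra domain of one r-protein."""

    protein_id: str
    chain: str
    component_kind: str                   # globular | extension | extra_domain
    category: str | None = None          # extension category
    terminus: str | None = None          # N | C | internal
    ranges: list[tuple[int, int]] = field(default_factory=list)
    status: str = "U"                     # U/B/A/E or Ub/Ua/Ue/Ae/inherited

    def __post_init__(self):
        if self.component_kind not in KINDS:
            raise ValueError(f"unknown component kind {self.component_kind!r}")
        if self.component_kind == "extension":
            if self.category not in CATEGORIES:
                raise ValueError(
                    f"{self.protein_id}: unknown extension category "
                    f"{self.category!r} (expected one of {sorted(CATEGORIES)})")
            if self.terminus not in TERMINI:
                raise ValueError(
                    f"{self.protein_id}: extension terminus must be one of "
                    f"{sorted(TERMINI)}, got {self.terminus!r}")
        elif self.category is not None or self.terminus is not None:
            raise ValueError(
                f"{self.protein_id}: category/terminus only valid on extensions")
        for start, end in self.ranges:
            if end < start:
                raise ValueError(
                    f"{self.protein_id}: inverted residue range ({start}, {end})")

    @property
    def label(self) -> str:
        """Short component label used in edge tables (G, ext:N-mix, ...)."""
        if self.component_kind == "globular":
            return "G"
        if self.component_kind == "extra_domain":
            return "dom"
        return f"ext:{self.terminus}-{self.category}"

    @property
    def length_aa(self) -> int:
        return sum(end - start + 1 for start, end in self.ranges)

    def covers(self, residue_index: int) -> bool:
        return any(start <= residue_index <= end for start, end in self.ranges)


def _check_overlaps(components: Sequence[ProteinComponent]) -> None:
    by_protein: dict[str, list[tuple[int, int, str]]] = {}
    for c in components:
        for start, end in c.ranges:
            by_protein.setdefault(c.protein_id, []).append((start, end, c.label))
    for pid, ranges in by_protein.items():
        ranges.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(ranges, ranges[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{pid}: overlapping residue ranges {l1}({s1}-{e1}) and "
                    f"{l2}({s2}-{e2})")


class ComponentAnnotation:
    """Per-chain component annotation for one kingdom's ribosome network."""

    def __init__(self, kingdom: str, components: Sequence[ProteinComponent],
                 non_protein_chains: Mapping[str, str] | None = None,
                 subunits: Mapping[str, str] | None = None,
                 source: str | None = None):
        self.kingdom = kingdom
        self.components = list(components)
        #: chain id -> molecule kind (rRNA, tRNA, mRNA) for non-protein chains
        self.non_protein_chains = dict(non_protein_chains or {})
        #: protein id -> SSU | LSU
        self.subunits = dict(subunits or {})
        self.source = source
        _check_overlaps(self.components)
        self._by_chain: dict[str, list[ProteinComponent]] = {}
        for c in self.components:
            self._by_chain.setdefault(c.chain, []).append(c)

    # -- lookups ---------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.components:
            seen.setdefault(c.protein_id, None)
        return list(seen)

    def protein_of_chain(self, chain: str) -> str | None:
        comps = self._by_chain.get(chain)
        return comps[0].protein_id if comps else None

    def components_of(self, protein_id: str) -> list[ProteinComponent]:
        return [c for c in self.components if c.protein_id == protein_id]

    def component_at(self, chain: str, residue_index: int) -> ProteinComponent | None:
        for c in self._by_chain.get(chain, []):
            if c.covers(residue_index):
                return c
        return None

    def protein_status(self, protein_id: str) -> str:
        for c in self.components_of(protein_id):
            if c.component_kind == "globular":
                return c.status
        comps = self.components_of(protein_id)
        if not comps:
            raise KeyError(f"unknown protein {protein_id!r}")
        return comps[0].status

    def component_status(self, component: ProteinComponent) -> str:
        """Effective evolutionary status of a component.

        Extensions marked ``inherited`` take their protein's status; acquired
        extensions keep their own label (Ub/Ua/Ue/Ae).
        """
        if component.component_kind == "extension" and component.status != "inherited":
            return component.status
        if component.component_kind == "extension":
            return self.protein_status(component.protein_id)
        return component.status

    def validate_against_structure(self, structure: StructureAtoms) -> None:
        named = {c.chain for c in self.components} | set(self.non_protein_chains)
        missing = sorted(ch for ch in named if ch not in structure)
        if missing:
            raise ValueError(
                f"annotation names chains absent from the structure: {missing}")


def _parse_ranges(text: str) -> list[tuple[int, int]]:
    ranges = []
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        start, end = part.split("-")
        ranges.append((int(start), int(end)))
    return ranges


ANNOTATION_COLUMNS = ["protein_id", "chain", "subunit", "component_kind",
                      "category", "terminus", "ranges", "status"]


def load_annotation(path: str | Path, kingdom: str | None = None) -> ComponentAnnotation:
    """Load a component annotation from TSV or JSON.

    TSV columns: protein_id, chain, subunit, component_kind, category,
    terminus, ranges (semicolon-separated ``start-end``), status.  Rows with
    component_kind ``non_protein`` mark rRNA/tRNA/mRNA chains.  The JSON
    equivalent nests the same fields under ``components``.
    """
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        kingdom = kingdom or data.get("kingdom", "?")
        rows = data["components"]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        kingdom = kingdom or "?"
        rows = df.to_dict("records")
    components, non_protein, subunits = [], {}, {}
    for row in rows:
        kind = row["component_kind"]
        if kind == "non_protein":
            non_protein[row["chain"]] = row["protein_id"]
            continue
        ranges = row["ranges"]
        if isinstance(ranges, str):
            ranges = _parse_ranges(ranges)
        else:
            ranges = [tuple(r) for r in ranges]
        components.append(ProteinComponent(
            protein_id=row["protein_id"], chain=row["chain"],
            component_kind=kind,
            category=(row.get("category") or None) or None,
            terminus=(row.get("terminus") or None) or None,
            ranges=ranges, status=row["status"]))
        if row.get("subunit"):
            subunits[row["protein_id"]] = row["subunit"]
    return ComponentAnnotation(kingdom, components, non_protein, subunits,
                               source=str(path))


def save_annotation(annotation: ComponentAnnotation, path: str | Path) -> None:
    rows = []
    for c in annotation.components:
        rows.append({
            "protein_id": c.protein_id, "chain": c.chain,
            "subunit": annotation.subunits.get(c.protein_id, ""),
            "component_kind": c.component_kind,
            "category": c.category or "", "terminus": c.terminus or "",
            "ranges": ";".join(f"{s}-{e}" for s, e in c.ranges),
            "status": c.status})
    for chain, kind in annotation.non_protein_chains.items():
        rows.append({"protein_id": kind, "chain": chain, "subunit": "",
                     "component_kind": "non_protein", "category": "",
                     "terminus": "", "ranges": "", "status": ""})
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False)


# -- centres of mass ------------------------------------------------------

def center_of_mass(atoms: Sequence[AtomRecord],
                   mass_weighted: bool = False) -> np.ndarray:
    """Centre of mass of an atom set.

    Geometric (unweighted) by default: mass weighting changes protein COMs
    negligibly and the unweighted form needs no element-mass table; pass
    ``mass_weighted=True`` to switch.
    """
    if len(atoms) == 0:
        raise ValueError("empty atom selection")
    coords = np.array([a.position for a in atoms], dtype=float)
    if not mass_weighted:
        return coords.mean(axis=0)
    w = np.array([ATOMIC_MASS.get(a.element, 12.011) for a in atoms])
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def protein_com(structure: StructureAtoms, annotation: ComponentAnnotation,
                protein_id: str, mass_weighted: bool = False) -> np.ndarray:
    """COM of a protein's globular domain(s); whole protein if it has none."""
    comps = annotation.components_of(protein_id)
    if not comps:
        raise KeyError(f"unknown protein {protein_id!r}")
    globular = [c for c in comps if c.component_kind == "globular"]
    chain = comps[0].chain
    atoms = structure[chain]
    if globular:
        selected = [a for a in atoms
                    if any(g.covers(a.residue_index) for g in globular)]
    else:
        selected = list(atoms)  # protein devoid of globular domain
    return center_of_mass(selected, mass_weighted)


# -- extension size statistics --------------------------------------------

def extension_size_stats(annotations: Mapping[str, ComponentAnnotation],
                         threshold_aa: int = 80) -> pd.DataFrame:
    """Per-kingdom fraction of extensions longer than ``threshold_aa``.

    Returns one row per kingdom with the fraction, counts, and a per-category
    size histogram (dict column).
    """
    rows = []
    for kingdom, ann in annotations.items():
        exts = [c for c in ann.components if c.component_kind == "extension"]
        if not exts:
            raise ValueError(f"kingdom {kingdom}: no extensions annotated")
        n_long = sum(1 for c in exts if c.length_aa > threshold_aa)
        hist: dict[str, list[int]] = {}
        for c in exts:
            hist.setdefault(c.category, []).append(c.length_aa)
        rows.append({"kingdom": kingdom, "n_extensions": len(exts),
                     "n_gt_threshold": n_long,
                     "fraction_gt_threshold": n_long / len(exts),
                     "sizes_by_category": hist})
    return pd.DataFrame(rows).set_index("kingdom")
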