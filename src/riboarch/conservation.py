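"""Sequence conservation under the 80% rule and aromatic-residue analysis.

A column of a within-kingdom alignment is *strictly* conserved when a single
residue occupies it in more than 80% of the sequences, and *similar*
conserved when a single physicochemical class (aromatic, basic, acidic,
polar, hydrophobic) does.  Gaps count in the denominator: a column that is
80%-identical among non-gap rows but half gapped is not conserved (the
stricter reading).  On top of the profiles we map conservation onto detected
interfaces, track the A->E acquisition of conserved aromatic residues, and
classify the pi-interaction motifs the aromatics engage in (pi-pi, cation-pi,
anion-pi, proline-pi) from ring-centroid geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .contacts import AtomRecord, InterfaceContact, StructureAtoms

log = logging.getLogger(__name__)

GAP_CHARS = {"-", ".", "X", "x"}

#: physicochemical classes; a partition of the 20 standard residues
AA_CLASSES: dict[str, str] = {}
for _cls, _aas in {
    "aromatic": "FYWH",
    "basic": "KR",
    "acidic": "DE",
    "polar": "STNQC",
    "hydrophobic": "AVLIMGP",
}.items():
    for _aa in _aas:
        AA_CLASSES[_aa] = _cls

AROMATIC = set("FYWH")


@dataclass
class ColumnConservation:
    consensus: str            # most frequent residue ('-' for all-gap columns)
    identity_fraction: float  # max single-residue frequency (gaps in denominator)
    top_class: str | None
    class_fraction: float
    strict_conserved: bool
    similar_conserved: bool
    all_gap: bool


@dataclass
class ConservationProfile:
    columns: list[ColumnConservation]
    n_sequences: int
    threshold: float

    def __len__(self) -> int:
        return len(self.columns)

    def strict_columns(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.strict_conserved]

    def similar_columns(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.similar_conserved]

    def conserved_aromatic(self, col: int, strict_only: bool = False) -> bool:
        c = self.columns[col]
        if c.strict_conserved and c.consensus in AROMATIC:
            return True
        return (not strict_only and c.similar_conserved
                and c.top_class == "aromatic")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "column": i, "consensus": c.consensus,
            "identity_fraction": c.identity_fraction,
            "top_class": c.top_class, "class_fraction": c.class_fraction,
            "strict_conserved": c.strict_conserved,
            "similar_conserved": c.similar_conserved,
            "all_gap": c.all_gap,
        } for i, c in enumerate(self.columns)])


def conservation_profile(msa, threshold: float = 0.80) -> ConservationProfile:
    """Per-column conservation of an aligned FASTA / MultipleSeqAlignment.

    ``msa`` may be a path, a Biopython alignment, or a list of equal-length
    strings.  Ragged alignments raise; all-gap columns are flagged and never
    conserved.
    """
    if isinstance(msa, (str, Path)):
        msa = AlignIO.read(str(msa), "fasta")
    seqs = [str(getattr(rec, "seq", rec)).upper() for rec in msa]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(seqs[0])
    ragged = [i for i, s in enumerate(seqs) if len(s) != length]
    if ragged:
        raise ValueError(f"ragged alignment: sequences {ragged} differ in "
                         f"length from the first ({length})")
    n = len(seqs)
    cols = []
    for j in range(length):
        residues = [s[j] for s in seqs]
        counts: dict[str, int] = {}
        class_counts: dict[str, int] = {}
        for r in residues:
            if r in GAP_CHARS:
                continue
            counts[r] = counts.get(r, 0) + 1
            cls = AA_CLASSES.get(r)
            if cls:
                class_counts[cls] = class_counts.get(cls, 0) + 1
        if not counts:
            cols.append(ColumnConservation("-", 0.0, None, 0.0, False, False,
                                           True))
            continue
        consensus = max(sorted(counts), key=counts.get)
        identity = counts[consensus] / n          # gaps in the denominator
        if class_counts:
            top_class = max(sorted(class_counts), key=class_counts.get)
            class_frac = class_counts[top_class] / n
        else:
            top_class, class_frac = None, 0.0
        cols.append(ColumnConservation(
            consensus=consensus, identity_fraction=identity,
            top_class=top_class, class_fraction=class_frac,
            strict_conserved=identity > threshold,
            similar_conserved=class_frac > threshold,
            all_gap=False))
    return ConservationProfile(cols, n, threshold)


# -- interface conservation ------------------------------------------------

@dataclass
class InterfaceConservation:
    fraction_strict_a: float
    fraction_similar_a: float
    fraction_strict_b: float
    fraction_similar_b: float
    fraction_strict: float        # combined over both sides
    fraction_similar: float
    unmapped: list[tuple[str, str]]


def interface_conservation(contact: InterfaceContact,
                           profiles: Mapping[str, ConservationProfile],
                           seq_map: Mapping[tuple[str, str], int],
                           ) -> InterfaceConservation:
    """Fraction of interface residues that are conserved, per side.

    ``profiles`` is keyed by chain id; ``seq_map`` maps (chain, residue key)
    to an alignment column.  Unmappable residues are excluded with a warning
    and listed in the result.
    """
    unmapped: list[tuple[str, str]] = []

    def side(chain: str, residues):
        strict = similar = total = 0
        if not residues:
            return 0, 0, 0
        prof = profiles[chain]
        for res, _ in residues:
            col = seq_map.get((chain, res))
            if col is None:
                unmapped.append((chain, res))
                continue
            total += 1
            c = prof.columns[col]
            strict += c.strict_conserved
            similar += c.similar_conserved
        return strict, similar, total

    sa, ma, ta = side(contact.chain_a, contact.residues_a)
    sb, mb, tb = side(contact.chain_b, contact.residues_b)
    if unmapped:
        log.warning("interface %s-%s: %d residue(s) not mappable to columns: %s",
                    contact.chain_a, contact.chain_b, len(unmapped), unmapped)

    def frac(k, t):
        return k / t if t else 0.0

    return InterfaceConservation(
        frac(sa, ta), frac(ma, ta), frac(sb, tb), frac(mb, tb),
        frac(sa + sb, ta + tb), frac(ma + mb, ta + tb), unmapped)


# -- aromatic acquisitions -------------------------------------------------

@dataclass
class AromaticAcquisition:
    column_e: int
    column_a: int
    consensus_e: str
    status: str                  # new_in_E | ancient | strengthened_similar_to_strict
    at_new_interface: bool = False


def aromatic_acquisitions(profile_a: ConservationProfile,
                          profile_e: ConservationProfile,
                          cross_map: Mapping[int, int] | None = None,
                          new_interface_columns_e: set[int] | None = None,
                          ) -> list[AromaticAcquisition]:
    """Track conserved aromatic residues across the A->E transition.

    ``cross_map`` maps E columns to A columns (identity when the two
    alignments share a coordinate system).  A column conserved-aromatic in E
    is *new_in_E* when its A counterpart is not conserved aromatic,
    *strengthened* when A was similar (class) but not strict and E is strict,
    and *ancient* otherwise.
    """
    if cross_map is None:
        if len(profile_a) != len(profile_e):
            raise ValueError("profiles differ in length; supply cross_map")
        cross_map = {i: i for i in range(len(profile_e))}
    out = []
    for col_e, c_e in enumerate(profile_e.columns):
        if not profile_e.conserved_aromatic(col_e):
            continue
        if col_e not in cross_map:
            raise ValueError(f"E column {col_e} missing from cross_map")
        col_a = cross_map[col_e]
        c_a = profile_a.columns[col_a]
        a_conserved_aromatic = profile_a.conserved_aromatic(col_a)
        a_similar_only = (c_a.similar_conserved and c_a.top_class == "aromatic"
                          and not c_a.strict_conserved)
        e_strict_aromatic = c_e.strict_conserved and c_e.consensus in AROMATIC
        if not a_conserved_aromatic:
            status = "new_in_E"
        elif a_similar_only and e_strict_aromatic:
            status = "strengthened_similar_to_strict"
        else:
            status = "ancient"
        out.append(AromaticAcquisition(
            column_e=col_e, column_a=col_a,
            consensus_e=c_e.consensus if c_e.consensus in AROMATIC else
            (c_e.top_class or ""),
            status=status,
            at_new_interface=bool(new_interface_columns_e
                                  and col_e in new_interface_columns_e)))
    return out


# -- pi interactions -------------------------------------------------------

RING_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}
PRO_RING = ["N", "CA", "CB", "CG", "CD"]
CATION_ATOMS = {"LYS": ["NZ"], "ARG": ["CZ"]}
ANION_ATOMS = {"ASP": ["CG"], "GLU": ["CD"]}


@dataclass
class PiCutoffs:
    """Centroid-based distance cutoffs (Angstrom), all configurable."""
    pi_pi: float = 7.0
    cation_pi: float = 6.0
    anion_pi: float = 5.5
    proline_pi: float = 6.0


@dataclass
class PiInteraction:
    aromatic: tuple[str, str, str]    # (chain, residue key, residue name)
    partner: tuple[str, str, str]
    interaction_class: str            # pi_pi | cation_pi | anion_pi | proline_pi
    centroid_distance: float
    intramolecular: bool


def _group_residues(atoms: Sequence[AtomRecord]):
    res: dict[tuple[str, str], list[AtomRecord]] = {}
    for a in atoms:
        res.setdefault(a.residue_key, []).append(a)
    return res


def _centroid(atoms: Sequence[AtomRecord], names: Sequence[str]):
    got = {a.atom_name: np.asarray(a.position) for a in atoms
           if a.atom_name in names}
    if len(got) < len(names):
        return None
    return np.mean([got[n] for n in names], axis=0)


def classify_pi_interactions(structure: StructureAtoms,
                             aromatics: Sequence[tuple[str, str]] | None = None,
                             cutoffs: PiCutoffs | None = None
                             ) -> list[PiInteraction]:
    """Classify pi-interaction partners of aromatic residues.

    ``aromatics`` restricts the scan to the given (chain, residue key) list;
    default is every F/Y/W/H residue.  Residues with incomplete rings are
    skipped with a warning.  pi-pi pairs are reported once, in deterministic
    (chain, residue) order.
    """
    cutoffs = cutoffs or PiCutoffs()
    residues = _group_residues(structure.atoms())

    rings: dict[tuple[str, str], tuple[str, np.ndarray]] = {}
    for key, atoms in residues.items():
        name = atoms[0].residue_name
        if name not in RING_ATOMS:
            continue
        if aromatics is not None and key not in set(aromatics):
            continue
        cen = _centroid(atoms, RING_ATOMS[name])
        if cen is None:
            log.warning("incomplete aromatic ring %s %s; skipped", *key)
            continue
        rings[key] = (name, cen)

    out: list[PiInteraction] = []
    seen_pi_pi: set[tuple] = set()
    for key, (name, cen) in sorted(rings.items()):
        for pkey, patoms in sorted(residues.items()):
            if pkey == key:
                continue
            pname = patoms[0].residue_name
            intra = pkey[0] == key[0]
            if pname in RING_ATOMS:
                ring = _centroid(patoms, RING_ATOMS[pname])
                if ring is None:
                    continue
                d = float(np.linalg.norm(cen - ring))
                if d <= cutoffs.pi_pi:
                    pair = tuple(sorted((key, pkey)))
                    if pair in seen_pi_pi:
                        continue
                    seen_pi_pi.add(pair)
                    a_key, b_key = pair
                    out.append(PiInteraction(
                        (a_key[0], a_key[1], residues[a_key][0].residue_name),
                        (b_key[0], b_key[1], residues[b_key][0].residue_name),
                        "pi_pi", d, intra))
            elif pname in CATION_ATOMS or pname in ANION_ATOMS:
                atom_names = (CATION_ATOMS.get(pname) or ANION_ATOMS[pname])
                pts = [np.asarray(a.position) for a in patoms
                       if a.atom_name in atom_names]
                if not pts:
                    continue
                d = min(float(np.linalg.norm(cen - p)) for p in pts)
                cls = "cation_pi" if pname in CATION_ATOMS else "anion_pi"
                cutoff = (cutoffs.cation_pi if cls == "cation_pi"
                          else cutoffs.anion_pi)
                if d <= cutoff:
                    out.append(PiInteraction(
                        (key[0], key[1], name), (pkey[0], pkey[1], pname),
                        cls, d, intra))
            elif pname == "PRO":
                ring = _centroid(patoms, PRO_RING)
                if ring is None:
                    continue
                d = float(np.linalg.norm(cen - ring))
                if d <= cutoffs.proline_pi:
                    out.append(PiInteraction(
                        (key[0], key[1], name), (pkey[0], pkey[1], pname),
                        "proline_pi", d, intra))
    return out


def distant_aromatic_approaches(structure: StructureAtoms, chain_a: str,
                                chain_b: str, max_dist: float = 10.0,
                                min_dist: float = 2.8) -> list[dict]:
    """Closest-approach scan for aromatic pairs that come near without contact.

    Reports aromatic residue pairs across two chains whose ring centroids lie
    within ``max_dist`` but beyond van-der-Waals contact (``min_dist``).
    """
    def rings(chain):
        out = {}
        for key, atoms in _group_residues(structure[chain]).items():
            name = atoms[0].residue_name
            if name in RING_ATOMS:
                cen = _centroid(atoms, RING_ATOMS[name])
                if cen is not None:
                    out[key] = (name, cen)
        return out

    ra, rb = rings(chain_a), rings(chain_b)
    hits = []
    for ka, (na, ca) in sorted(ra.items()):
        for kb, (nb, cb) in sorted(rb.items()):
            d = float(np.linalg.norm(ca - cb))
            if min_dist < d <= max_dist:
                hits.append({"residue_a": ka, "name_a": na,
                             "residue_b": kb, "name_b": nb,
                             "centroid_distance": d})
    return sorted(hits, key=lambda h: h["centroid_distance"])
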