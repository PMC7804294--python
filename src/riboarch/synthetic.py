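"""Seeded generators for every input the pipeline consumes, with ground truth.

Three families of fixtures:

* toy multi-chain structures (ideal poly-alanine helices) with designed
  contacts, written as both PDB and mmCIF;
* supplementary-style annotated interaction tables for the four evolutionary
  stages (universal core, B, A, E) with *planted* status-pair proportions,
  contact types, functional-centre fractions, core size, multiplicities,
  module structure, node geometry and extension-size distributions — the
  defaults are the study conditions (49-edge core; 58/19/12/9% B classes;
  47/19% + 35% Ua in A; 57% new-extension-mediated contacts and 11 new
  proteins in E; functional fractions 45/14/4/2%; 1%→10% extensions >80 aa);
* per-kingdom alignments with planted conserved columns, aromatic
  acquisitions and similar→strict strengthenings.

Every generator is fully determined by its seed and returns machine-readable
ground truth alongside the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .components import ComponentAnnotation, ProteinComponent, save_annotation
from .network import (CONTACT_TABLE_COLUMNS, FUNCTIONAL_SITE_KINDS,
                      canonical_status_pair)

# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5          # Angstrom per residue
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3

#: local atom offsets within a residue frame (idealised, not stereochemical)
_LOCAL_OFFSETS = {
    "N": (-1.20, -0.70, -0.55), "CA": (0.0, 0.0, 0.0),
    "C": (1.25, 0.60, 0.45), "O": (1.60, 1.75, 0.40),
    "CB": (0.55, -1.30, 0.55),
}
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass
class ToyChain:
    chain_id: str
    n_residues: int
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)


def _helix_coords(n_residues: int, offset) -> dict[tuple[int, str], np.ndarray]:
    out = {}
    off = np.asarray(offset, dtype=float)
    for i in range(n_residues):
        theta = math.radians(HELIX_TWIST * i)
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        ca = np.array([HELIX_RADIUS * c, HELIX_RADIUS * s, HELIX_RISE * i])
        for name, local in _LOCAL_OFFSETS.items():
            out[(i + 1, name)] = ca + rot @ np.asarray(local) + off
    return out


@dataclass
class ToyComplex:
    pdb_path: Path
    cif_path: Path
    chains: list[ToyChain]
    ground_truth: dict            # per pair: in_contact flag and min gap


def make_toy_complex(chains: Sequence[ToyChain], out_dir: str | Path,
                     name: str = "toy", probe: float = 1.4,
                     seed: int = 0) -> ToyComplex:
    """Write an ideal-helix complex as PDB and mmCIF with contact truth.

    Ground truth marks a chain pair as in contact when some inter-chain atom
    pair has a surface gap smaller than a probe diameter (2 * probe).  Chains
    placed so close that atoms clash raise an error.
    """
    import gemmi

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coords = {c.chain_id: _helix_coords(c.n_residues, c.offset) for c in chains}

    # ground truth from raw geometry (carbon/nitrogen/oxygen radii)
    from .contacts import VDW_RADII
    truth: dict = {"pairs": {}}
    ids = [c.chain_id for c in chains]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            gaps = []
            for (ra, na), xa in coords[a].items():
                for (rb, nb), xb in coords[b].items():
                    d = float(np.linalg.norm(xa - xb))
                    gap = d - VDW_RADII[_ELEMENT[na]] - VDW_RADII[_ELEMENT[nb]]
                    gaps.append(gap)
            min_gap = min(gaps)
            if min_gap < -1.0:
                raise ValueError(f"chains {a} and {b} overlap "
                                 f"(min surface gap {min_gap:.2f} A)")
            truth["pairs"][f"{a}-{b}"] = {
                "min_gap": min_gap, "in_contact": min_gap < 2.0 * probe}

    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for c in chains:
        chain = gemmi.Chain(c.chain_id)
        for i in range(1, c.n_residues + 1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i, " ")
            for atom_name in _LOCAL_OFFSETS:
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(_ELEMENT[atom_name])
                x, y, z = coords[c.chain_id][(i, atom_name)]
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = 1.0
                atom.b_iso = 20.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()

    pdb_path = out_dir / f"{name}.pdb"
    cif_path = out_dir / f"{name}.cif"
    st.write_pdb(str(pdb_path))
    st.make_mmcif_document().write_file(str(cif_path))
    return ToyComplex(pdb_path, cif_path, list(chains), truth)


def two_helix_complex(gap: float, out_dir: str | Path, n_residues: int = 11,
                      name: str | None = None) -> ToyComplex:
    """Two parallel helices whose closest surfaces are ``gap`` Angstrom apart.

    ``gap`` ~ 0-2 gives kissing helices; large gaps give separated chains.
    """
    # facing atoms are CA/CB shells at ~HELIX_RADIUS+1.3 A from each axis
    axis_sep = 2 * (HELIX_RADIUS + 1.3) + 2 * 1.7 + gap
    name = name or f"pair_gap{gap:g}".replace(".", "p").replace("-", "m")
    return make_toy_complex(
        [ToyChain("A", n_residues), ToyChain("B", n_residues, (axis_sep, 0, 0))],
        out_dir, name=name)


# ---------------------------------------------------------------------------
# ER graphs
# ---------------------------------------------------------------------------

def make_er_graph(n: int, m: int | None = None, p: float | None = None,
                  seed: int = 0) -> nx.Graph:
    """Erdos-Renyi sample: G(n, m) when ``m`` given, else G(n, p)."""
    if (m is None) == (p is None):
        raise ValueError("give exactly one of m (G(n,m)) or p (G(n,p))")
    if m is not None:
        return nx.gnm_random_graph(n, m, seed=seed)
    return nx.gnp_random_graph(n, p, seed=seed)


# ---------------------------------------------------------------------------
# annotated interaction networks
# ---------------------------------------------------------------------------

STAGES = ("ABE", "B", "A", "E")

_EXT_CATEGORIES = ["segment", "mix", "helix", "loop", "beta_hairpin"]
_EXT_TERMINI = ["N", "C", "internal"]


@dataclass
class NetworkStudySpec:
    """Planted study conditions; the defaults are the paper-scale conditions."""

    seed: int = 0
    # protein inventories
    n_universal_lsu: int = 17
    n_universal_ssu: int = 16
    n_bacterial: int = 21
    n_archaeal: int = 33
    n_eukaryotic: int = 11
    # universal core: 49 strictly conserved connections, 45% to functional sites
    core_pp_types: tuple[int, int, int] = (7, 10, 10)   # ext_ext, ext_G, G_G
    # new protein-protein contact class counts per transition
    b_classes: Mapping[str, int] = field(default_factory=lambda: {
        "U-B": 50, "B-B": 16, "Ub-U": 10, "Ub-B": 8, "Ub-Ub": 2})
    a_classes: Mapping[str, int] = field(default_factory=lambda: {
        "U-A": 93, "A-A": 38, "Ua-U": 24, "Ua-A": 26, "Ua-Ua": 19})
    e_classes: Mapping[str, int] = field(default_factory=lambda: {
        "Ue-U": 14, "Ue-A": 10, "Ue-E": 8, "Ue-Ue": 10,
        "Ae-A": 6, "Ae-E": 4, "Ae-Ae": 4,
        "U-E": 15, "A-E": 13, "E-E": 8, "U-A": 6})
    # contact-type quotas (ext_ext, ext_G, G_G) over new protein-protein rows
    b_types: tuple[int, int, int] = (12, 38, 36)
    a_types: tuple[int, int, int] = (45, 80, 75)
    e_types: tuple[int, int, int] = (39, 45, 14)
    # planted repeated protein pairs (multiple connections)
    multiplicity_pairs: Mapping[str, int] = field(default_factory=lambda: {
        "B": 2, "A": 3, "E": 5})
    # extension size distribution: fraction of extensions > 80 aa per stage
    long_fraction: Mapping[str, float] = field(default_factory=lambda: {
        "ABE": 0.01, "B": 0.03, "A": 0.05, "E": 0.10})
    max_new_contacts_per_protein: int = 6
    # proteins live in spatial neighbourhoods; new contacts form mostly
    # within a neighbourhood, giving the modular (non-random) architecture
    intra_cluster_bias: float = 0.97
    # geometry: COM length scale of each stage's new connections (Angstrom)
    stage_radius: Mapping[str, float] = field(default_factory=lambda: {
        "ABE": 10.0, "B": 45.0, "A": 75.0, "E": 140.0})


@dataclass
class _Ext:
    protein: str
    label: str
    category: str
    terminus: str
    acquisition: str        # ABE | B | A | E
    length: int


class SyntheticNetworkStudy:
    """Tables, annotations, coordinates and planted truth of one study."""

    def __init__(self, tables, annotations, coords, subunits, truth):
        self.tables: dict[str, pd.DataFrame] = tables
        self.annotations: dict[str, ComponentAnnotation] = annotations
        self.coords: dict[str, np.ndarray] = coords
        self.subunits: dict[str, str] = subunits
        self.truth: dict = truth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for stage, df in self.tables.items():
            df.to_csv(out / f"contacts_{stage}.tsv", sep="\t", index=False)
        for stage, ann in self.annotations.items():
            save_annotation(ann, out / f"annotation_{stage}.tsv")
        pd.DataFrame([{"node": k, "x": v[0], "y": v[1], "z": v[2]}
                      for k, v in sorted(self.coords.items())]
                     ).to_csv(out / "coords.tsv", sep="\t", index=False)
        (out / "ground_truth.json").write_text(
            json.dumps(self.truth, indent=1, default=str))


def _assign_types(classes: Sequence[tuple[str, str]],
                  quotas: tuple[int, int, int]) -> list[str]:
    """Assign ext_ext/ext_G/G_G to protein-protein rows respecting the quotas.

    Rows whose status tokens include an acquired-extension label (Ub/Ua/Ue/Ae)
    must involve an extension on that side; plain rows may use inherited
    extensions.  Raises on infeasible combinations.
    """
    ext_tokens = {"Ub", "Ua", "Ue", "Ae"}
    q_ee, q_eg, q_gg = quotas
    n_ext = [len([t for t in pair if t in ext_tokens]) for pair in classes]
    n_both = sum(1 for k in n_ext if k == 2)
    n_one = sum(1 for k in n_ext if k == 1)
    n_plain = sum(1 for k in n_ext if k == 0)
    if q_ee + q_eg + q_gg != len(classes):
        raise ValueError("type quotas do not sum to the number of contacts")
    if n_both > q_ee:
        raise ValueError("more double-extension classes than ext_ext quota")
    if q_gg > n_plain:
        raise ValueError("G_G quota exceeds plain-status contacts")
    a = min(n_one, q_ee - n_both)            # one-ext rows typed ext_ext
    e_plain = q_ee - n_both - a              # plain rows typed ext_ext
    if e_plain > n_plain - q_gg:
        raise ValueError("infeasible ext_ext quota")
    types = []
    used_one = used_plain_gg = used_plain_ee = 0
    for k in n_ext:
        if k == 2:
            types.append("ext_ext")
        elif k == 1:
            types.append("ext_ext" if used_one < a else "ext_G")
            used_one += 1
        else:
            if used_plain_gg < q_gg:
                types.append("G_G")
                used_plain_gg += 1
            elif used_plain_ee < e_plain:
                types.append("ext_ext")
                used_plain_ee += 1
            else:
                types.append("ext_G")
    return types


class _Builder:
    def __init__(self, spec: NetworkStudySpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.U = ([f"uL{i}" for i in range(1, spec.n_universal_lsu + 1)]
                  + [f"uS{i}" for i in range(1, spec.n_universal_ssu + 1)])
        nb_l = spec.n_bacterial - spec.n_bacterial // 2
        self.B = ([f"bL{i}" for i in range(1, nb_l + 1)]
                  + [f"bS{i}" for i in range(1, spec.n_bacterial - nb_l + 1)])
        na_l = spec.n_archaeal - spec.n_archaeal // 3
        self.A = ([f"eL{i}" for i in range(1, na_l + 1)]
                  + [f"eS{i}" for i in range(1, spec.n_archaeal - na_l + 1)])
        self.E = ([f"eL{i}" for i in range(na_l + 1,
                                           na_l + 1 + spec.n_eukaryotic - 3)]
                  + [f"eS{i}" for i in range(spec.n_archaeal - na_l + 1,
                                             spec.n_archaeal - na_l + 4)])
        self.stage_of = {p: "ABE" for p in self.U}
        self.stage_of.update({p: "B" for p in self.B})
        self.stage_of.update({p: "A" for p in self.A})
        self.stage_of.update({p: "E" for p in self.E})
        self.subunits = {p: ("LSU" if "L" in p else "SSU")
                         for p in self.stage_of}
        self.exts: dict[tuple[str, str], _Ext] = {}
        self.used_pairs: dict[str, set] = {s: set() for s in STAGES}
        self.cluster_of: dict[str, str] = {}
        self.uu_pairs_used: set[tuple[str, str]] = set()

    # -- extensions ------------------------------------------------------
    def _new_ext(self, protein: str, acquisition: str,
                 length: int | None = None) -> _Ext:
        existing = {lab for (p, lab) in self.exts if p == protein}
        combos = [(c, t) for t in _EXT_TERMINI for c in _EXT_CATEGORIES]
        order = self.rng.permutation(len(combos))
        for k in order:
            cat, term = combos[k]
            label = f"ext:{term}-{cat}"
            if label not in existing:
                break
        else:
            raise ValueError(f"extension inventory of {protein} exhausted")
        if length is None:
            length = int(self.rng.integers(15, 61))
        ext = _Ext(protein, label, cat, term, acquisition, length)
        self.exts[(protein, label)] = ext
        return ext

    def get_ext(self, protein: str, effective_status: str,
                force_new: bool = False) -> _Ext:
        """Extension of ``protein`` whose status reads ``effective_status``."""
        acquisition = {"Ub": "B", "Ua": "A", "Ue": "E", "Ae": "E"}.get(
            effective_status)
        if acquisition is None:   # plain token: inherited extension
            stage = self.stage_of[protein]
            acquisition = "ABE" if stage == "ABE" else stage
        if not force_new:
            for (p, _), ext in self.exts.items():
                if p == protein and ext.acquisition == acquisition:
                    return ext
        return self._new_ext(protein, acquisition)

    def pool(self, token: str) -> list[str]:
        return {"U": self.U, "B": self.B, "A": self.A, "E": self.E,
                "Ub": self.U, "Ua": self.U, "Ue": self.U, "Ae": self.A}[token]

    # -- rows ------------------------------------------------------------
    def _row(self, stage, pa, ca, sa, pb, cb, sb, ctype, excluded=False):
        return {"stage": stage, "protein_a": pa, "component_a": ca,
                "status_a": sa, "protein_b": pb, "component_b": cb,
                "status_b": sb,
                "status_pair": canonical_status_pair(sa, sb),
                "contact_type": ctype,
                "excluded_from_stats": excluded}

    def _component(self, protein, token, is_ext, force_new=False):
        if not is_ext:
            return "G", token
        ext = self.get_ext(protein, token, force_new=force_new)
        return ext.label, token

    def pp_row(self, stage, tokens, pair, ctype, force_new_side=None):
        (ta, tb), (pa, pb) = tokens, pair
        ext_tokens = {"Ub", "Ua", "Ue", "Ae"}
        if ctype == "ext_ext":
            ext_a = ext_b = True
        elif ctype == "G_G":
            ext_a = ext_b = False
        else:  # ext_G: the acquired-extension side if any, else side a
            ext_a = ta in ext_tokens or tb not in ext_tokens
            ext_b = not ext_a
            if tb in ext_tokens:
                ext_a, ext_b = False, True
        ca, sa = self._component(pa, ta, ext_a, force_new=force_new_side == "a")
        cb, sb = self._component(pb, tb, ext_b, force_new=force_new_side == "b")
        return self._row(stage, pa, ca, sa, pb, cb, sb, ctype)

    def funct_row(self, stage, protein, token, site, ctype):
        is_ext = ctype == "ext_funct"
        comp, status = self._component(protein, token, is_ext)
        return self._row(stage, protein, comp, status, site, "site", "funct",
                         ctype)

    # -- pair sampling ---------------------------------------------------
    def sample_pairs(self, stage, class_counts: Mapping[str, int],
                     parent_pairs: set, n_dups: int):
        """Pick protein pairs per class; returns rows of (tokens, pair, dup).

        New proteins of the stage are each guaranteed at least one contact;
        per-protein contact counts are capped; ``n_dups`` rows of the largest
        class reuse an earlier pair (planted multiple connections).
        """
        spec = self.spec
        cap = spec.max_new_contacts_per_protein
        degree: dict[str, int] = {}
        new_status = {"B": "B", "A": "A", "E": "E"}[stage]
        uncovered = set(self.pool(new_status))
        used = self.used_pairs[stage]
        used |= parent_pairs
        out = []
        # duplicated pairs live in the largest acquired-extension class: the
        # extra row then carries a fresh extension label, so the repeated
        # pair yields a distinct component-level contact (true multiplicity)
        ext_tokens = {"Ub", "Ua", "Ue", "Ae"}
        ext_classes = [k for k in class_counts
                       if set(k.split("-")) & ext_tokens]
        if n_dups and not ext_classes:
            raise ValueError(f"{stage}: multiplicity planting needs at least "
                             f"one acquired-extension contact class")
        largest = (max(ext_classes, key=lambda k: class_counts[k])
                   if ext_classes else None)
        for cls, count in class_counts.items():
            tokens = tuple(cls.split("-"))
            dups = n_dups if cls == largest else 0
            if dups >= count:
                raise ValueError(f"{stage}: more planted duplicates than "
                                 f"{cls} contacts")
            pairs = []
            for i in range(count - dups):
                pairs.append(self._pick_pair(tokens, used, degree, cap,
                                             uncovered, new_status))
            for i in range(count - dups):
                out.append((tokens, pairs[i], None))
            for i in range(dups):
                out.append((tokens, pairs[i], "a"))   # re-used pair, new comp
        return out

    def _pick_pair(self, tokens, used, degree, cap, uncovered, new_status):
        ta, tb = tokens
        pool_a, pool_b = self.pool(ta), self.pool(tb)
        bias = self.spec.intra_cluster_bias
        for relax in range(4):
            limit = cap * (relax + 1)
            eff_bias = bias if relax < 2 else 0.0
            for _ in range(400):
                if ta == new_status and uncovered:
                    a = sorted(uncovered)[int(self.rng.integers(len(uncovered)))]
                else:
                    a = pool_a[int(self.rng.integers(len(pool_a)))]
                if tb == new_status and uncovered - {a}:
                    rest = sorted(uncovered - {a})
                    b = rest[int(self.rng.integers(len(rest)))]
                else:
                    cands = [p for p in pool_b if p != a]
                    if self.rng.uniform() < eff_bias:
                        same = [p for p in cands if
                                self.cluster_of.get(p) == self.cluster_of.get(a)]
                        if same:
                            cands = same
                    b = cands[int(self.rng.integers(len(cands)))]
                if a == b:
                    continue
                pair = tuple(sorted((a, b)))
                if pair in used:
                    continue
                # a universal-universal pair used by any other lineage would
                # leak into the three-kingdom intersection: keep the planted
                # universal core exact by excluding it everywhere else
                both_u = a in self.stage_of and b in self.stage_of and \
                    self.stage_of[a] == "ABE" and self.stage_of[b] == "ABE"
                if both_u and pair in self.uu_pairs_used:
                    continue
                if degree.get(a, 0) >= limit or degree.get(b, 0) >= limit:
                    continue
                if both_u:
                    self.uu_pairs_used.add(pair)
                used.add(pair)
                degree[a] = degree.get(a, 0) + 1
                degree[b] = degree.get(b, 0) + 1
                # return in token order (side a matches the first token)
                uncovered.discard(a)
                uncovered.discard(b)
                return (a, b)
        raise ValueError(f"could not place a {ta}-{tb} pair "
                         f"(pools exhausted under the degree cap)")


def make_annotated_network(spec: NetworkStudySpec | int = 0
                           ) -> SyntheticNetworkStudy:
    """Generate the four-stage annotated interaction tables with ground truth.

    See :class:`NetworkStudySpec` for the planted conditions; an integer
    argument is taken as a seed with default conditions.
    """
    if isinstance(spec, int):
        spec = NetworkStudySpec(seed=spec)
    b = _Builder(spec)
    rng = b.rng
    rows: dict[str, list[dict]] = {s: [] for s in STAGES}

    # ---- universal core: 22 functional + 27 protein-protein edges -------
    lsu = [p for p in b.U if p.startswith("uL")]
    ssu = [p for p in b.U if p.startswith("uS")]
    site_plan = ([("PTC", p) for p in lsu[:10]]
                 + [("tunnel", p) for p in lsu[10:13]]
                 + [("mRNA", p) for p in ssu[:3]]
                 + [("tRNA_A", p) for p in ssu[3:5]]
                 + [("tRNA_P", p) for p in ssu[5:7]]
                 + [("tRNA_E", p) for p in ssu[7:9]])
    # spatial neighbourhoods: the PTC crown reaches into every neighbourhood
    # (the PTC sits centrally), the other sites anchor their own;
    # everything else is distributed at random
    sites6 = list(FUNCTIONAL_SITE_KINDS)
    for i, p in enumerate(lsu[:10]):
        b.cluster_of[p] = sites6[i % 6]
    for site, prot in site_plan[10:]:
        b.cluster_of[prot] = site
    for p in b.stage_of:
        if p not in b.cluster_of:
            b.cluster_of[p] = sites6[int(rng.integers(6))]

    for i, (site, prot) in enumerate(site_plan):
        ctype = "ext_funct" if i % 2 == 0 else "G_funct"
        rows["ABE"].append(b.funct_row("ABE", prot, "U", site, ctype))
        b.used_pairs["ABE"].add(tuple(sorted((prot, site))))
    # adjacencies between the functional centres themselves (the tRNAs reach
    # the PTC and the mRNA, the exit tunnel starts at the PTC): drawn in the
    # graphs but excluded from the connectivity statistics
    for sa, sb in [("mRNA", "tRNA_A"), ("mRNA", "tRNA_P"),
                   ("tRNA_A", "tRNA_P"), ("tRNA_P", "tRNA_E"),
                   ("PTC", "tRNA_A"), ("PTC", "tRNA_P"), ("PTC", "tunnel")]:
        rows["ABE"].append(b._row("ABE", sa, "site", "funct", sb, "site",
                                  "funct", "G_funct", excluded=True))
    # protein-protein core: attach every orphan protein inside its own
    # neighbourhood (inter-neighbourhood routing then runs through the PTC
    # crown), then neighbourhood-biased extras
    core_pairs = []
    attached = set(p for _, p in site_plan)
    for prot in b.U:
        if prot not in attached:
            same = sorted(p for p in attached
                          if b.cluster_of[p] == b.cluster_of[prot])
            cands = same or sorted(attached)
            partner = cands[int(rng.integers(len(cands)))]
            core_pairs.append((prot, partner))
            attached.add(prot)
    used = {tuple(sorted(p)) for p in core_pairs}
    n_extra = 27 - len(core_pairs)
    while n_extra > 0:
        pa = b.U[int(rng.integers(len(b.U)))]
        cands = [p for p in b.U
                 if p != pa and b.cluster_of[p] == b.cluster_of[pa]]
        if not cands or rng.uniform() >= spec.intra_cluster_bias:
            cands = [p for p in b.U if p != pa]
        pb = cands[int(rng.integers(len(cands)))]
        pair = tuple(sorted((pa, pb)))
        if pair in used:
            continue
        used.add(pair)
        core_pairs.append(pair)
        n_extra -= 1
    b.uu_pairs_used |= used
    n_ee, n_eg, n_gg = spec.core_pp_types
    if n_ee + n_eg + n_gg != len(core_pairs):
        raise ValueError("core type counts must sum to 27")
    core_types = ["ext_ext"] * n_ee + ["ext_G"] * n_eg + ["G_G"] * n_gg
    for (pa, pb), ctype in zip(core_pairs, core_types):
        rows["ABE"].append(b.pp_row("ABE", ("U", "U"), (pa, pb), ctype))
        b.used_pairs["ABE"].add(tuple(sorted((pa, pb))))
    core_pair_set = set(b.used_pairs["ABE"])

    # ---- designed functional contacts of the later stages ---------------
    bl = [p for p in b.B if p.startswith("bL")]
    bs = [p for p in b.B if p.startswith("bS")]
    b_funct = ([(p, "B", "PTC") for p in bl[:8]]
               + [(bl[8], "B", "tunnel"), (bl[9], "B", "tunnel"),
                  (bs[0], "B", "mRNA"), (bs[1], "B", "mRNA"),
                  (bs[2], "B", "tRNA_A"), (bs[3], "B", "tRNA_E")])
    # B proteins joining the PTC crown spread across the neighbourhoods too
    for i, (prot, _token, site) in enumerate(b_funct):
        b.cluster_of[prot] = sites6[i % 6] if site == "PTC" else site

    a_funct = [("eL15", "A", "PTC"), ("eL15", "A", "tunnel"),
               ("eL20", "A", "PTC"), ("eL20", "A", "tRNA_P"),
               ("eL18", "A", "tunnel"), ("eL18", "A", "tRNA_A"),
               ("uL7", "Ua", "tunnel"), ("uL8", "Ua", "mRNA")]
    e_funct = [("uL7", "Ue", "tRNA_E"), ("eL15", "A", "tRNA_P")]
    funct_plan = {"B": b_funct, "A": a_funct, "E": e_funct}
    funct_types = {"B": ["ext_funct", "G_funct"] * 7,
                   "A": ["G_funct"] * 4 + ["ext_funct"] * 4,
                   "E": ["ext_funct", "G_funct"]}

    # ---- per-transition protein-protein rows -----------------------------
    class_plans = {"B": spec.b_classes, "A": spec.a_classes,
                   "E": spec.e_classes}
    type_plans = {"B": spec.b_types, "A": spec.a_types, "E": spec.e_types}
    parent_of = {"B": core_pair_set, "A": core_pair_set, "E": None}
    for stage in ("B", "A", "E"):
        parent_pairs = (parent_of[stage] if parent_of[stage] is not None
                        else set(b.used_pairs["A"]))
        for prot, token, site in funct_plan[stage]:
            pair = tuple(sorted((prot, site)))
            if pair in parent_pairs or pair in b.used_pairs[stage]:
                raise ValueError(f"{stage}: functional contact {pair} "
                                 f"duplicates a parent contact")
            b.used_pairs[stage].add(pair)
        sampled = b.sample_pairs(stage, class_plans[stage], parent_pairs,
                                 spec.multiplicity_pairs.get(stage, 0))
        types = _assign_types([t for t, _, _ in sampled], type_plans[stage])
        for (tokens, pair, force), ctype in zip(sampled, types):
            rows[stage].append(b.pp_row(stage, tokens, pair, ctype,
                                        force_new_side=force))
        for (prot, token, site), ctype in zip(funct_plan[stage],
                                              funct_types[stage]):
            rows[stage].append(b.funct_row(stage, prot, token, site, ctype))

    # ---- compose the cumulative kingdom tables ---------------------------
    tables = {
        "ABE": pd.DataFrame(rows["ABE"]),
        "B": pd.DataFrame(rows["ABE"] + rows["B"]),
        "A": pd.DataFrame(rows["ABE"] + rows["A"]),
        "E": pd.DataFrame(rows["ABE"] + rows["A"] + rows["E"]),
    }
    cols = ["stage"] + CONTACT_TABLE_COLUMNS + ["excluded_from_stats"]
    tables = {k: v[cols] for k, v in tables.items()}

    # ---- extension padding for the size statistics -----------------------
    visible_stages = {"ABE": {"ABE"}, "B": {"ABE", "B"}, "A": {"ABE", "A"},
                      "E": {"ABE", "A", "E"}}
    stage_hosts = {"ABE": b.U, "B": b.B, "A": b.A, "E": b.A + b.E}
    ext_truth = {}
    for stage in STAGES:
        kingdoms_visible = visible_stages[stage]
        current = [e for e in b.exts.values()
                   if e.acquisition in kingdoms_visible]
        n_now = len([e for e in b.exts.values() if e.acquisition == stage])
        target_frac = spec.long_fraction[stage]
        # choose a stage total so the cumulative long fraction is exact
        denom = max(10, int(round(1 / target_frac)) if target_frac else 10)
        total_visible = len(current)
        total = -(-max(total_visible + 10, 100 if stage == "ABE" else 0)
                  // denom) * denom
        current_longs = sum(1 for e in current if e.length > 80)
        # grow the stage total until the padding can host the long quota
        while total - total_visible < int(round(total * target_frac)) - current_longs:
            total += denom
        n_pad = total - total_visible
        longs_needed = int(round(total * target_frac)) - current_longs
        if longs_needed < 0 or longs_needed > n_pad:
            raise ValueError(f"stage {stage}: cannot plant the long-extension "
                             f"fraction (need {longs_needed} of {n_pad} pads)")
        hosts = stage_hosts[stage]
        for i in range(n_pad):
            host = hosts[int(rng.integers(len(hosts)))]
            length = (int(rng.integers(85, 141)) if i < longs_needed else None)
            for _ in range(50):
                try:
                    b._new_ext(host, stage if stage != "ABE" else "ABE", length)
                    break
                except ValueError:
                    host = hosts[int(rng.integers(len(hosts)))]
            else:
                raise ValueError("could not place padding extension")
        visible = [e for e in b.exts.values()
                   if e.acquisition in kingdoms_visible]
        n_long = sum(1 for e in visible if e.length > 80)
        ext_truth[stage] = {"n_extensions": len(visible), "n_long": n_long,
                            "fraction_gt_80": n_long / len(visible)}

    # ---- per-kingdom annotations -----------------------------------------
    kingdom_proteins = {"ABE": b.U, "B": b.U + b.B, "A": b.U + b.A,
                        "E": b.U + b.A + b.E}
    annotations = {}
    for stage in STAGES:
        comps = []
        for prot in kingdom_proteins[stage]:
            pstage = b.stage_of[prot]
            status = {"ABE": "U", "B": "B", "A": "A", "E": "E"}[pstage]
            cursor = 1
            comps.append(ProteinComponent(prot, prot, "globular",
                                          ranges=[(cursor, cursor + 119)],
                                          status=status))
            cursor += 120
            for (p, label), ext in sorted(b.exts.items()):
                if p != prot or ext.acquisition not in visible_stages[stage]:
                    continue
                if ext.acquisition in ("ABE", pstage):
                    est = "inherited"
                else:
                    est = {("ABE", "B"): "Ub", ("ABE", "A"): "Ua",
                           ("ABE", "E"): "Ue", ("A", "E"): "Ae"}[
                               (pstage, ext.acquisition)]
                comps.append(ProteinComponent(
                    prot, prot, "extension", category=ext.category,
                    terminus=ext.terminus,
                    ranges=[(cursor, cursor + ext.length - 1)], status=est))
                cursor += ext.length
        annotations[stage] = ComponentAnnotation(stage, comps,
                                                 subunits=b.subunits)

    # ---- node geometry ----------------------------------------------------
    coords: dict[str, np.ndarray] = {}

    def rand_dir():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    r0 = spec.stage_radius["ABE"]
    for name in b.U + list(FUNCTIONAL_SITE_KINDS):
        coords[name] = rand_dir() * r0 * rng.uniform() ** (1 / 3)
    for stage in ("B", "A", "E"):
        d = spec.stage_radius[stage]
        pending = [p for p in kingdom_proteins[stage] if p not in coords]
        pairs = [tuple(sorted((r["protein_a"], r["protein_b"])))
                 for r in rows[stage]]
        for _ in range(len(pending) + 2):
            placed_any = False
            for pa, pb in pairs:
                for new, anchor in ((pa, pb), (pb, pa)):
                    if new not in coords and anchor in coords:
                        coords[new] = coords[anchor] + rand_dir() * d
                        placed_any = True
            if not placed_any:
                break
        still = [p for p in pending if p not in coords]
        if still:
            raise ValueError(f"stage {stage}: proteins without contacts or "
                             f"anchors: {still}")

    # ---- planted ground truth ---------------------------------------------
    def stage_new_pairs(stage, parent_stage):
        parent = {tuple(sorted((r["protein_a"], r["protein_b"])))
                  for r in tables[parent_stage].to_dict("records")}
        return {tuple(sorted((r["protein_a"], r["protein_b"])))
                for r in rows[stage]} - parent

    def mean_dist(pairs):
        return float(np.mean([np.linalg.norm(coords[a] - coords[b])
                              for a, b in pairs])) if pairs else float("nan")

    stage_pairs = {"ABE": core_pair_set,
                   "B": stage_new_pairs("B", "ABE"),
                   "A": stage_new_pairs("A", "ABE"),
                   "E": stage_new_pairs("E", "A")}

    def class_fracs(stage):
        pp = [r for r in rows[stage] if r["status_b"] != "funct"]
        counts = pd.Series([r["status_pair"] for r in pp]).value_counts()
        return {k: v / len(pp) for k, v in counts.items()}

    def type_fracs(stage):
        counts = pd.Series([r["contact_type"] for r in rows[stage]]
                           ).value_counts()
        return {k: v / len(rows[stage]) for k, v in counts.items()}

    new_ext_status = {"B": {"Ub"}, "A": {"Ua"}, "E": {"Ue", "Ae"}}
    truth = {
        "seed": spec.seed,
        "core_n_edges": len(core_pair_set),
        "core_functional_fraction": len(site_plan) / len(core_pair_set),
        "status_pair_fractions": {s: class_fracs(s) for s in ("B", "A", "E")},
        "contact_type_fractions": {s: type_fracs(s) for s in ("B", "A", "E")},
        "functional_fractions": {
            s: (sum(1 for r in rows[s] if r["status_b"] == "funct")
                / len(rows[s])) for s in ("B", "A", "E")},
        "ext_mediated_fractions": {
            s: (sum(1 for r in rows[s]
                    if {r["status_a"], r["status_b"]} & new_ext_status[s])
                / len(rows[s])) for s in ("B", "A", "E")},
        "n_new_contacts": {s: len(rows[s]) for s in ("B", "A", "E")},
        "n_new_proteins": {"B": len(b.B), "A": len(b.A), "E": len(b.E)},
        "multiplicities": {
            s: {" / ".join(pair): int(n) for pair, n in
                pd.Series([tuple(sorted((r["protein_a"], r["protein_b"])))
                           for r in tables[s].to_dict("records")]
                          ).value_counts().items() if n > 1}
            for s in STAGES},
        "bridge3_proteins": {"B": [], "A": [], "E": ["eL15", "uL7"]},
        "extension_sizes": ext_truth,
        "stage_mean_distances": {s: mean_dist(stage_pairs[s]) for s in STAGES},
        "n_new_edges": {s: len(stage_pairs[s]) for s in ("B", "A", "E")},
    }
    return SyntheticNetworkStudy(tables, annotations, coords, b.subunits,
                                 truth)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

_NON_AROMATIC = [a for a in "ACDEGIKLMNPQRSTV"]
_ALL_AA = list("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class MsaSpec:
    seed: int = 0
    n_sequences: int = 50
    length: int = 120
    n_strict: int = 10                 # conserved in both kingdoms, non-aromatic
    n_ancient_aromatic: int = 4        # strict aromatic in both
    n_new_aromatic: int = 6            # conserved aromatic in E only
    n_strengthened: int = 4            # similar-aromatic in A, strict in E
    conservation_level: float = 0.90
    gap_rate: float = 0.05


@dataclass
class SyntheticMsa:
    sequences_a: list[str]
    sequences_e: list[str]
    column_map: dict[int, int]        # E column -> A column (identity here)
    truth: dict

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for kingdom, seqs in (("A", self.sequences_a), ("E", self.sequences_e)):
            p = out / f"msa_{kingdom}.fasta"
            with open(p, "w") as fh:
                for i, s in enumerate(seqs):
                    fh.write(f">{kingdom}_seq{i:03d}\n{s}\n")
            paths.append(p)
        return tuple(paths)


def make_msa(spec: MsaSpec | int = 0) -> SyntheticMsa:
    """Aligned FASTA pair (archaeal, eukaryotic) with planted conservation.

    Planted column kinds: strictly conserved (both kingdoms), ancient
    aromatics (both), new-in-E aromatics (E only), and similar-to-strict
    strengthened aromatics (class-conserved in A, strictly conserved in E).
    Background columns are uniform random residues with gaps at ``gap_rate``.
    """
    if isinstance(spec, int):
        spec = MsaSpec(seed=spec)
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_sequences, spec.length
    n_planted = (spec.n_strict + spec.n_ancient_aromatic + spec.n_new_aromatic
                 + spec.n_strengthened)
    if L < n_planted:
        raise ValueError(f"alignment length {L} shorter than {n_planted} "
                         f"planted columns")
    cols = rng.permutation(L)
    strict_cols = sorted(int(c) for c in cols[:spec.n_strict])
    k = spec.n_strict
    ancient_cols = sorted(int(c) for c in cols[k:k + spec.n_ancient_aromatic])
    k += spec.n_ancient_aromatic
    new_cols = sorted(int(c) for c in cols[k:k + spec.n_new_aromatic])
    k += spec.n_new_aromatic
    strengthened_cols = sorted(int(c) for c in
                               cols[k:k + spec.n_strengthened])

    def background(rng):
        m = rng.choice(_ALL_AA, size=(n, L))
        gaps = rng.uniform(size=(n, L)) < spec.gap_rate
        m[gaps] = "-"
        return m

    def plant(m, col, consensus, level, rng, mixture=None):
        n_cons = int(math.ceil(level * n))
        order = rng.permutation(n)
        for idx in order[:n_cons]:
            if mixture is None:
                m[idx, col] = consensus
            else:
                m[idx, col] = mixture[int(rng.integers(len(mixture)))]
        for idx in order[n_cons:]:
            m[idx, col] = _NON_AROMATIC[int(rng.integers(len(_NON_AROMATIC)))]

    ma, me = background(rng), background(rng)
    lvl = spec.conservation_level
    for c in strict_cols:
        plant(ma, c, "L", lvl, rng)
        plant(me, c, "L", lvl, rng)
    for c in ancient_cols:
        plant(ma, c, "Y", lvl, rng)
        plant(me, c, "Y", lvl, rng)
    for c in new_cols:
        plant(me, c, "W", lvl, rng)          # A keeps background
    for c in strengthened_cols:
        plant(ma, c, None, lvl, rng, mixture=["F", "Y", "W"])  # class only
        plant(me, c, "F", lvl, rng)

    truth = {"strict_columns": strict_cols,
             "ancient_aromatic_columns": ancient_cols,
             "new_aromatic_columns": new_cols,
             "strengthened_columns": strengthened_cols,
             "conservation_level": lvl}
    return SyntheticMsa(["".join(r) for r in ma], ["".join(r) for r in me],
                        {i: i for i in range(L)}, truth)
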