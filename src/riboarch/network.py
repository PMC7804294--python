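"""Centre-of-mass network graphs of ribosomal proteins and functional sites.

Nodes are r-proteins (COM of the globular domain, or of the whole protein
when it has no globular domain) plus the six functional centres: the peptidyl
transferase centre (PTC), peptide exit tunnel, mRNA channel and the three
tRNA sites.  Component-level contacts between two proteins are aggregated
into a single undirected edge whose ``n_connections`` records the
multiplicity.  Edges are typed by the component kinds in contact (ext-ext,
ext-G, G-G, ext-funct, G-funct) and labelled by the evolutionary status pair
of the contacting components (U-B, Ub-U, Ua-Ua, ...).  tRNA-tRNA and
tRNA-mRNA connections are drawn but flagged as excluded from the statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import InterfaceContact, StructureAtoms
from .components import (ComponentAnnotation, ProteinComponent,
                         center_of_mass, protein_com)

FUNCTIONAL_SITE_KINDS = ("PTC", "tunnel", "mRNA", "tRNA_A", "tRNA_P", "tRNA_E")
CONTACT_TYPES = ("ext_ext", "ext_G", "G_G", "ext_funct", "G_funct")

#: canonical ordering of status tokens inside a status-pair label
_STATUS_ORDER = ["Ub", "Ua", "Ue", "Ae", "U", "B", "A", "E", "funct"]


def canonical_status_pair(status_a: str, status_b: str) -> str:
    """Order a status pair the way the field writes it (ext status first,
    universal before kingdom-specific): (B, U) -> 'U-B', (U, Ub) -> 'Ub-U'."""
    def rank(s: str) -> int:
        try:
            return _STATUS_ORDER.index(s)
        except ValueError:
            return len(_STATUS_ORDER)
    a, b = sorted((status_a, status_b), key=rank)
    return f"{a}-{b}"


@dataclass
class ComponentContact:
    """One component-level contact: the currency of the archaeology stats."""

    protein_a: str
    component_a: str       # component label: G, dom, ext:N-mix, ... or 'site'
    status_a: str          # U/B/A/E, Ub/Ua/Ue/Ae, or 'funct'
    protein_b: str
    component_b: str
    status_b: str
    contact_type: str      # one of CONTACT_TYPES
    buried_area: float = 0.0
    excluded_from_stats: bool = False

    def __post_init__(self):
        if self.contact_type not in CONTACT_TYPES:
            raise ValueError(f"unknown contact type {self.contact_type!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.protein_a, self.protein_b)))

    @property
    def status_pair(self) -> str:
        return canonical_status_pair(self.status_a, self.status_b)

    @property
    def involves_functional_site(self) -> bool:
        return "funct" in self.contact_type

    @property
    def key(self) -> tuple:
        """Identity used to match contacts across kingdoms."""
        sides = sorted([(self.protein_a, self.component_a),
                        (self.protein_b, self.component_b)])
        return (sides[0], sides[1])


class FunctionalSites:
    """Residue selections defining the functional centres.

    ``selections`` maps a site kind to a list of (chain, start, end) residue
    ranges in author numbering.
    """

    def __init__(self, selections: Mapping[str, Sequence[tuple[str, int, int]]]):
        unknown = set(selections) - set(FUNCTIONAL_SITE_KINDS)
        if unknown:
            raise ValueError(f"unknown functional site kinds: {sorted(unknown)}")
        self.selections = {k: [tuple(r) for r in v] for k, v in selections.items()}

    @classmethod
    def from_json(cls, path: str | Path) -> "FunctionalSites":
        return cls(json.loads(Path(path).read_text()))

    def site_of(self, chain: str, residue_index: int) -> str | None:
        for kind, ranges in self.selections.items():
            for c, start, end in ranges:
                if c == chain and start <= residue_index <= end:
                    return kind
        return None

    def com(self, structure: StructureAtoms, kind: str) -> np.ndarray:
        atoms = []
        for c, start, end in self.selections.get(kind, []):
            atoms.extend(a for a in structure[c]
                         if start <= a.residue_index <= end)
        return center_of_mass(atoms)


class RibosomeGraph:
    """Simple undirected COM graph with the full contact list attached."""

    def __init__(self, kingdom: str, graph: nx.Graph,
                 contacts: Sequence[ComponentContact]):
        self.kingdom = kingdom
        self.graph = graph
        self.contacts = list(contacts)

    # -- convenience -----------------------------------------------------
    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def protein_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("node_kind") == "protein"]

    def site_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("node_kind") == "functional_site"]

    def edge_pairs(self) -> set[tuple[str, str]]:
        """Unordered name pairs of non-excluded aggregated edges."""
        return {tuple(sorted((u, v))) for u, v, d in self.graph.edges(data=True)
                if not d.get("excluded_from_stats")}

    def stats_contacts(self) -> list[ComponentContact]:
        return [c for c in self.contacts if not c.excluded_from_stats]


def _aggregate(kingdom: str, contacts: Sequence[ComponentContact],
               coms: Mapping[str, np.ndarray] | None,
               node_kinds: Mapping[str, str],
               subunits: Mapping[str, str] | None = None) -> RibosomeGraph:
    g = nx.Graph()
    for node, kind in node_kinds.items():
        attrs = {"node_kind": kind, "functional_module": "none"}
        if kind == "functional_site":
            attrs["functional_site_kind"] = node
        if subunits and node in subunits:
            attrs["subunit"] = subunits[node]
        if coms is not None and node in coms:
            attrs["com"] = np.asarray(coms[node], dtype=float)
        g.add_node(node, **attrs)
    grouped: dict[tuple[str, str], list[ComponentContact]] = {}
    for c in contacts:
        if c.protein_a == c.protein_b:
            continue  # no self loops
        grouped.setdefault(c.pair, []).append(c)
    for (u, v), group in grouped.items():
        primary = max(group, key=lambda c: (c.buried_area, c.key))
        g.add_edge(u, v,
                   n_connections=len(group),
                   contact_type=primary.contact_type,
                   status_pair=primary.status_pair,
                   excluded_from_stats=all(c.excluded_from_stats for c in group))
    return RibosomeGraph(kingdom, g, contacts)


def _side_component(annotation: ComponentAnnotation, chain: str,
                    residues: Sequence[tuple[str, float]]) -> ProteinComponent:
    """Pick the component a contact side belongs to.

    When interface residues span both globular and extension parts, the side
    is classified by the region with the larger summed buried area; ties go
    to the extension (extensions are the object of study).
    """
    weight: dict[int, float] = {}
    comps = {}
    for res, dsasa in residues:
        idx = int("".join(ch for ch in res if ch.isdigit() or ch == "-"))
        comp = annotation.component_at(chain, idx)
        if comp is None:
            continue
        key = id(comp)
        comps[key] = comp
        weight[key] = weight.get(key, 0.0) + dsasa
    if not comps:
        raise ValueError(f"no annotated component covers the interface "
                         f"residues of chain {chain!r}")
    def sort_key(k):
        c = comps[k]
        return (weight[k], 1 if c.component_kind == "extension" else 0)
    return comps[max(comps, key=sort_key)]


def build_graph(contacts: Sequence[InterfaceContact],
                annotation: ComponentAnnotation,
                sites: FunctionalSites,
                structure: StructureAtoms) -> RibosomeGraph:
    """Build the COM network from chain-level interface contacts.

    Each chain-chain interface becomes one or more component-level contacts;
    contacts of a protein with residues inside a functional-site selection
    become protein-site edges.  Chains neither annotated as proteins nor
    covered by a site selection raise an error naming the chain.
    """
    node_kinds: dict[str, str] = {}
    coms: dict[str, np.ndarray] = {}
    for pid in annotation.protein_ids:
        node_kinds[pid] = "protein"
        coms[pid] = protein_com(structure, annotation, pid)
    for kind in sites.selections:
        node_kinds[kind] = "functional_site"
        coms[kind] = sites.com(structure, kind)

    def resolve(chain: str, residues):
        """-> list of (endpoint name, component label, status, is_site)."""
        pid = annotation.protein_of_chain(chain)
        if pid is not None:
            comp = _side_component(annotation, chain, residues)
            return [(pid, comp.label, annotation.component_status(comp), False)]
        hits: dict[str, None] = {}
        for res, _ in residues:
            idx = int("".join(ch for ch in res if ch.isdigit() or ch == "-"))
            kind = sites.site_of(chain, idx)
            if kind is not None:
                hits.setdefault(kind, None)
        if hits:
            return [(kind, "site", "funct", True) for kind in hits]
        if chain in annotation.non_protein_chains:
            return []  # e.g. rRNA stretch outside any functional site
        raise ValueError(f"contact touches unannotated chain {chain!r}")

    comp_contacts: list[ComponentContact] = []
    for ic in contacts:
        sides_a = resolve(ic.chain_a, ic.residues_a)
        sides_b = resolve(ic.chain_b, ic.residues_b)
        for name_a, comp_a, st_a, site_a in sides_a:
            for name_b, comp_b, st_b, site_b in sides_b:
                if name_a == name_b:
                    continue
                if site_a and site_b:
                    ctype = "G_funct"  # site-site links are drawn only
                    excluded = True
                elif site_a or site_b:
                    prot_comp = comp_b if site_a else comp_a
                    ctype = ("ext_funct" if prot_comp.startswith("ext")
                             else "G_funct")
                    excluded = False
                else:
                    ext_a = comp_a.startswith("ext")
                    ext_b = comp_b.startswith("ext")
                    ctype = ("ext_ext" if ext_a and ext_b else
                             "G_G" if not ext_a and not ext_b else "ext_G")
                    excluded = False
                comp_contacts.append(ComponentContact(
                    name_a, comp_a, st_a, name_b, comp_b, st_b, ctype,
                    buried_area=ic.buried_area_total,
                    excluded_from_stats=excluded))
    return _aggregate(annotation.kingdom, comp_contacts, coms, node_kinds,
                      annotation.subunits)


CONTACT_TABLE_COLUMNS = ["protein_a", "component_a", "status_a",
                         "protein_b", "component_b", "status_b",
                         "status_pair", "contact_type"]


def graph_from_contact_table(table: pd.DataFrame, kingdom: str,
                             coords: Mapping[str, np.ndarray] | None = None,
                             subunits: Mapping[str, str] | None = None) -> RibosomeGraph:
    """Build a RibosomeGraph from a supplementary-style interaction table.

    The table enumerates component-level contacts with per-side component
    labels and evolutionary statuses (see ``CONTACT_TABLE_COLUMNS``).
    """
    contacts = []
    node_kinds: dict[str, str] = {}
    for row in table.to_dict("records"):
        c = ComponentContact(
            protein_a=row["protein_a"], component_a=row["component_a"],
            status_a=row["status_a"], protein_b=row["protein_b"],
            component_b=row["component_b"], status_b=row["status_b"],
            contact_type=row["contact_type"],
            buried_area=float(row.get("buried_area", 0.0) or 0.0),
            excluded_from_stats=bool(row.get("excluded_from_stats", False)))
        contacts.append(c)
        for name, status in ((c.protein_a, c.status_a), (c.protein_b, c.status_b)):
            kind = ("functional_site" if name in FUNCTIONAL_SITE_KINDS
                    else "protein")
            node_kinds.setdefault(name, kind)
    return _aggregate(kingdom, contacts, coords, node_kinds, subunits)


def contact_table(graph: RibosomeGraph) -> pd.DataFrame:
    rows = [{"protein_a": c.protein_a, "component_a": c.component_a,
             "status_a": c.status_a, "protein_b": c.protein_b,
             "component_b": c.component_b, "status_b": c.status_b,
             "status_pair": c.status_pair, "contact_type": c.contact_type}
            for c in graph.contacts]
    return pd.DataFrame(rows, columns=CONTACT_TABLE_COLUMNS)


# -- distances ------------------------------------------------------------

def com_distances(graph: RibosomeGraph, top_k: int = 5):
    """Euclidean COM distance of every edge, plus a distribution summary."""
    g = graph.graph
    rows = []
    for u, v in g.edges:
        cu, cv = g.nodes[u].get("com"), g.nodes[v].get("com")
        if cu is None or cv is None:
            raise ValueError(f"edge ({u}, {v}): node without COM coordinates")
        d = float(np.linalg.norm(np.asarray(cu) - np.asarray(cv)))
        g.edges[u, v]["com_distance"] = d
        rows.append({"node_a": u, "node_b": v, "com_distance": d})
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "com_distance"])
    df = df.sort_values("com_distance", ascending=False).reset_index(drop=True)
    summary = {
        "mean": float(df["com_distance"].mean()) if len(df) else float("nan"),
        "max": float(df["com_distance"].max()) if len(df) else float("nan"),
        "largest_edges": df.head(top_k).to_dict("records"),
    }
    return df, summary


# -- functional modules ---------------------------------------------------

def assign_functional_modules(graph: RibosomeGraph) -> RibosomeGraph:
    """Label protein nodes by the functional centres they touch.

    One site category -> that module; two -> bridge_2; three or more ->
    bridge_3; a protein whose neighbours span both subunits (and touching no
    site) -> subunit_bridge; otherwise none.
    """
    g = graph.graph
    module_of_site = {"PTC": "PTC_module", "tunnel": "tunnel_module",
                      "mRNA": "mRNA_module", "tRNA_A": "tRNA_module",
                      "tRNA_P": "tRNA_module", "tRNA_E": "tRNA_module"}
    site_category = {"PTC": "PTC", "tunnel": "tunnel", "mRNA": "mRNA",
                     "tRNA_A": "tRNA", "tRNA_P": "tRNA", "tRNA_E": "tRNA"}
    for node, data in g.nodes(data=True):
        if data.get("node_kind") != "protein":
            continue
        cats = {site_category[nbr] for nbr in g.neighbors(node)
                if g.nodes[nbr].get("node_kind") == "functional_site"}
        if len(cats) == 1:
            site = next(nbr for nbr in g.neighbors(node)
                        if g.nodes[nbr].get("node_kind") == "functional_site")
            data["functional_module"] = module_of_site[site]
        elif len(cats) == 2:
            data["functional_module"] = "bridge_2"
        elif len(cats) >= 3:
            data["functional_module"] = "bridge_3"
        else:
            subunits = {g.nodes[nbr].get("subunit") for nbr in g.neighbors(node)
                        if g.nodes[nbr].get("node_kind") == "protein"}
            subunits.discard(None)
            own = data.get("subunit")
            spans = (subunits | ({own} if own else set())) >= {"SSU", "LSU"}
            data["functional_module"] = "subunit_bridge" if spans else "none"
    return graph


# -- export ----------------------------------------------------------------

def to_graphml(graph: RibosomeGraph, path: str | Path) -> None:
    g = nx.Graph()
    for n, d in graph.graph.nodes(data=True):
        attrs = {k: v for k, v in d.items() if k != "com"}
        com = d.get("com")
        if com is not None:
            attrs.update(x=float(com[0]), y=float(com[1]), z=float(com[2]))
        g.add_node(n, **{k: v for k, v in attrs.items() if v is not None})
    for u, v, d in graph.graph.edges(data=True):
        g.add_edge(u, v, **{k: (int(v2) if isinstance(v2, bool) else v2)
                            for k, v2 in d.items()})
    nx.write_graphml(g, str(path))


def to_node_link_json(graph: RibosomeGraph, path: str | Path) -> None:
    g = graph.graph.copy()
    for _, d in g.nodes(data=True):
        if "com" in d:
            d["com"] = [float(x) for x in d["com"]]
    data = nx.node_link_data(g, edges="links")
    Path(path).write_text(json.dumps(data, indent=1))
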