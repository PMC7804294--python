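"""Network archaeology: how the three kingdoms' interactomes diverged.

The universal (ABE) core is the set of connections present in all three
kingdom networks (identity by unified protein nomenclature).  Each transition
(ABE->B, ABE->A, A->E) is then characterised by its *new* contacts: the
component-level contacts of the child network absent from the parent.  New
contacts are broken down by the evolutionary-status pair of the contacting
components (U-B, B-B, Ub-U, ...), by contact type (ext-ext, ext-G, G-G,
ext-funct, G-funct), by involvement of functional centres, and by
coevolution: contacts whose two components were both acquired at the same
transition.

Denominators: status-pair fractions are over new protein-protein contacts;
the functional-centre fraction and contact-type fractions are over all new
contacts of the transition.  Both new-only and whole-network functional
fractions are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ComponentContact, RibosomeGraph

TRANSITIONS = ("ABE_to_B", "ABE_to_A", "A_to_E")

#: statuses that mark a component as acquired at a given transition
ACQUIRED_STATUSES = {
    "ABE_to_B": {"B", "Ub"},
    "ABE_to_A": {"A", "Ua"},
    "A_to_E": {"E", "Ue", "Ae"},
}

#: extension-acquisition statuses of each transition (for ext-mediated stats)
NEW_EXTENSION_STATUSES = {
    "ABE_to_B": {"Ub"},
    "ABE_to_A": {"Ua"},
    "A_to_E": {"Ue", "Ae"},
}


@dataclass
class CoreResult:
    """The strictly conserved (ABE) connection set."""

    edge_pairs: set[tuple[str, str]]
    n_edges: int                      # aggregated protein/site pair count
    contact_keys: set[tuple]
    n_contacts: int                   # component-level contact count

    def __post_init__(self):
        assert self.n_edges == len(self.edge_pairs)


def universal_core(graphs: Mapping[str, RibosomeGraph]) -> CoreResult:
    """Intersect the A, B and E networks into the universal core.

    Edge identity across kingdoms is the unordered pair of nomenclature
    names.  Both the aggregated-edge count (primary) and the component-level
    contact count are reported.
    """
    missing = {"A", "B", "E"} - set(graphs)
    if missing:
        raise ValueError(f"missing kingdom graph(s): {sorted(missing)}")
    pair_sets = [graphs[k].edge_pairs() for k in ("A", "B", "E")]
    pairs = set.intersection(*pair_sets)
    key_sets = [{c.key for c in graphs[k].stats_contacts()}
                for k in ("A", "B", "E")]
    keys = set.intersection(*key_sets)
    keys = {k for k in keys
            if tuple(sorted((k[0][0], k[1][0]))) in pairs}
    return CoreResult(pairs, len(pairs), keys, len(keys))


@dataclass
class TransitionStats:
    transition: str
    n_new_contacts: int
    n_new_edges: int                 # new protein/site *pairs*
    n_new_proteins: int
    status_pair_fractions: dict[str, float]   # over new protein-protein contacts
    contact_type_fractions: dict[str, float]  # over all new contacts
    functional_fraction: float                # over all new contacts
    ext_mediated_fraction: float   # new contacts touching a newly acquired ext
    coevolved_pairs: list[tuple[str, str]]
    new_contacts: list[ComponentContact] = field(repr=False, default_factory=list)

    def as_dict(self) -> dict:
        return {
            "transition": self.transition,
            "n_new_contacts": self.n_new_contacts,
            "n_new_edges": self.n_new_edges,
            "n_new_proteins": self.n_new_proteins,
            "status_pair_fractions": self.status_pair_fractions,
            "contact_type_fractions": self.contact_type_fractions,
            "functional_fraction": self.functional_fraction,
            "ext_mediated_fraction": self.ext_mediated_fraction,
            "n_coevolved_pairs": len(self.coevolved_pairs),
            "coevolved_pairs": [list(p) for p in self.coevolved_pairs],
        }


def _new_contacts(parent: RibosomeGraph, child: RibosomeGraph
                  ) -> list[ComponentContact]:
    parent_keys = {c.key for c in parent.stats_contacts()}
    return [c for c in child.stats_contacts() if c.key not in parent_keys]


def transition_stats(parent: RibosomeGraph, child: RibosomeGraph,
                     transition: str) -> TransitionStats:
    """Statistics of the contacts gained between ``parent`` and ``child``.

    New contacts include both connections of previously unlinked pairs and
    reinforcements (additional component contacts on an existing pair).
    """
    if transition not in TRANSITIONS:
        raise ValueError(f"unknown transition {transition!r}; "
                         f"expected one of {TRANSITIONS}")
    acquired = ACQUIRED_STATUSES[transition]
    new_ext = NEW_EXTENSION_STATUSES[transition]
    new = _new_contacts(parent, child)
    for c in new:
        for status in (c.status_a, c.status_b):
            if status not in {"U", "B", "A", "E", "Ub", "Ua", "Ue", "Ae",
                              "funct"}:
                raise ValueError(f"unknown evolutionary status {status!r} on "
                                 f"contact {c.pair}")
    new_pairs = {c.pair for c in new} - parent.edge_pairs()
    parent_proteins = set(parent.protein_nodes())
    new_proteins = [p for p in child.protein_nodes() if p not in parent_proteins]

    pp = [c for c in new if not c.involves_functional_site]
    status_fracs: dict[str, float] = {}
    if pp:
        counts = pd.Series([c.status_pair for c in pp]).value_counts()
        status_fracs = {k: v / len(pp) for k, v in counts.items()}
    type_fracs: dict[str, float] = {}
    if new:
        counts = pd.Series([c.contact_type for c in new]).value_counts()
        type_fracs = {k: v / len(new) for k, v in counts.items()}
    funct_frac = (sum(c.involves_functional_site for c in new) / len(new)
                  if new else 0.0)
    ext_med = (sum(1 for c in new
                   if {c.status_a, c.status_b} & new_ext) / len(new)
               if new else 0.0)
    coevolved = sorted({c.pair for c in new
                        if c.status_a in acquired and c.status_b in acquired})
    return TransitionStats(
        transition=transition,
        n_new_contacts=len(new),
        n_new_edges=len(new_pairs),
        n_new_proteins=len(new_proteins),
        status_pair_fractions=status_fracs,
        contact_type_fractions=type_fracs,
        functional_fraction=funct_frac,
        ext_mediated_fraction=ext_med,
        coevolved_pairs=coevolved,
        new_contacts=new,
    )


def functional_contact_fraction(graph: RibosomeGraph, new_only: bool = False,
                                parent: RibosomeGraph | None = None) -> float:
    """Fraction of (new) component-level contacts touching a functional site."""
    if new_only:
        if parent is None:
            raise ValueError("new_only=True requires a parent graph")
        contacts = _new_contacts(parent, graph)
    else:
        contacts = graph.stats_contacts()
    if not contacts:
        return 0.0
    return sum(c.involves_functional_site for c in contacts) / len(contacts)


def distance_trend(stages: Sequence[tuple[str, RibosomeGraph,
                                          RibosomeGraph | None]]
                   ) -> pd.DataFrame:
    """Mean COM distance of the edges added at each evolutionary stage.

    ``stages`` is an ordered list of (label, graph, parent-or-None); the
    first stage (the ancestral core) has no parent and contributes all of its
    edges.  Monotonicity of the means is reported, never asserted.
    """
    rows = []
    for label, graph, parent in stages:
        g = graph.graph
        if parent is None:
            pairs = graph.edge_pairs()
        else:
            pairs = graph.edge_pairs() - parent.edge_pairs()
        dists = []
        for u, v in pairs:
            cu, cv = g.nodes[u].get("com"), g.nodes[v].get("com")
            if cu is None or cv is None:
                raise ValueError(f"stage {label}: node without COM on edge "
                                 f"({u}, {v})")
            dists.append(float(np.linalg.norm(np.asarray(cu) - np.asarray(cv))))
        rows.append({
            "stage": label,
            "n_new_edges": len(dists),
            "mean_distance": float(np.mean(dists)) if dists else float("nan"),
            "undefined": not dists,
            "distances": dists,
        })
    return pd.DataFrame(rows, columns=["stage", "n_new_edges",
                                       "mean_distance", "undefined",
                                       "distances"])


def percent(x: float) -> int:
    """Round a fraction to a whole percentage, half away from zero."""
    import math
    return int(math.floor(abs(x) * 100.0 + 0.5)) * (1 if x >= 0 else -1)
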