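"""End-to-end orchestration: contacts -> network -> archaeology -> stats.

Two entry points:

* :func:`run_pipeline` consumes a declarative config (YAML/dict) pointing at
  per-kingdom inputs — either a structure file (contacts are then detected by
  SASA difference) or a precomputed supplementary-style interaction table —
  plus optional alignments, and writes graphs, per-transition reports and a
  single JSON summary.
* :func:`run_synthetic_study` generates the full planted fixture set with the
  default study conditions and runs the same analysis; this is the
  reproducible, download-free path exercised by the test-suite and the
  acceptance script.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import archaeology, conservation, graphstats, synthetic
from .archaeology import percent
from .components import extension_size_stats, load_annotation
from .contacts import detect_interfaces, read_structure
from .network import (FunctionalSites, RibosomeGraph,
                      assign_functional_modules, build_graph, com_distances,
                      graph_from_contact_table, to_graphml)

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


@dataclass
class KingdomInput:
    kingdom: str
    annotation: str
    structure: str | None = None
    sites: str | None = None
    contacts_table: str | None = None
    msa: str | None = None


@dataclass
class RunConfig:
    kingdoms: list[KingdomInput]
    out_dir: str = "riboarch_out"
    probe: float = 1.4
    burial_tol: float = 0.1
    conservation_threshold: float = 0.80
    extension_threshold_aa: int = 80
    null_samples: int = 499
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        kingdoms = [KingdomInput(**k) for k in data.pop("kingdoms")]
        cfg = cls(kingdoms=kingdoms, **data)
        for k in cfg.kingdoms:
            for attr in ("annotation", "structure", "sites",
                         "contacts_table", "msa"):
                p = getattr(k, attr)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"kingdom {k.kingdom}: {attr} "
                                            f"file {p} does not exist")
        return cfg


def _kingdom_graph(k: KingdomInput, cfg: RunConfig) -> RibosomeGraph:
    ann = load_annotation(k.annotation, kingdom=k.kingdom)
    if k.contacts_table:
        table = pd.read_csv(k.contacts_table, sep="\t")
        return graph_from_contact_table(table, k.kingdom,
                                        subunits=ann.subunits)
    if not (k.structure and k.sites):
        raise ValueError(f"kingdom {k.kingdom}: need either contacts_table "
                         f"or structure+sites")
    structure = read_structure(k.structure)
    ann.validate_against_structure(structure)
    sites = FunctionalSites.from_json(k.sites)
    contacts = detect_interfaces(structure, probe=cfg.probe,
                                 burial_tol=cfg.burial_tol)
    return build_graph(contacts, ann, sites, structure)


def _analyse(graphs: Mapping[str, RibosomeGraph],
             annotations: Mapping[str, Any],
             null_samples: int, alpha: float, seed: int,
             extension_threshold_aa: int = 80) -> dict:
    """Shared archaeology/graph-theory summary over the four stage graphs."""
    core = archaeology.universal_core(graphs)
    transitions = {
        "ABE_to_B": archaeology.transition_stats(graphs["ABE"], graphs["B"],
                                                 "ABE_to_B"),
        "ABE_to_A": archaeology.transition_stats(graphs["ABE"], graphs["A"],
                                                 "ABE_to_A"),
        "A_to_E": archaeology.transition_stats(graphs["A"], graphs["E"],
                                               "A_to_E"),
    }
    funct = {"universal": archaeology.functional_contact_fraction(graphs["ABE"]),
             "B_new": transitions["ABE_to_B"].functional_fraction,
             "A_new": transitions["ABE_to_A"].functional_fraction,
             "E_new": transitions["A_to_E"].functional_fraction}

    ext_stats = None
    if annotations:
        df = extension_size_stats(annotations,
                                  threshold_aa=extension_threshold_aa)
        ext_stats = {k: {"n_extensions": int(df.loc[k, "n_extensions"]),
                         "fraction_gt_threshold":
                             float(df.loc[k, "fraction_gt_threshold"])}
                     for k in df.index}

    have_coms = all("com" in d for _, d in graphs["E"].graph.nodes(data=True))
    trend = None
    if have_coms:
        trend_df = archaeology.distance_trend([
            ("ABE", graphs["ABE"], None), ("B", graphs["B"], graphs["ABE"]),
            ("A", graphs["A"], graphs["ABE"]), ("E", graphs["E"], graphs["A"])])
        trend = {row["stage"]: {"n_new_edges": int(row["n_new_edges"]),
                                "mean_distance": float(row["mean_distance"])}
                 for row in trend_df.to_dict("records")}

    centrality = {}
    er_tests = {}
    rng = np.random.default_rng(seed)
    for kingdom in ("B", "A", "E"):
        g = graphs[kingdom]
        report = graphstats.centralities(g, giant_component=True)
        centrality[kingdom] = {
            "bc_argmax": report.argmax["betweenness"],
            "ev_argmax": report.argmax["eigenvector"],
            "top_bc": report.ranking("betweenness")[:5]}
        results = graphstats.er_null_test(
            g, n_samples=null_samples, seed=int(rng.integers(0, 2**31 - 1)),
            alpha=alpha)
        er_tests[kingdom] = {
            "p_values": {r.statistic_name: r.empirical_p for r in results},
            "coherent_reject": graphstats.coherent_reject(results),
            "note": results[0].note}

    modules_e = assign_functional_modules(graphs["E"])
    bridge3 = sorted(n for n, d in modules_e.graph.nodes(data=True)
                     if d.get("functional_module") == "bridge_3")

    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "universal_core": {"n_edges": core.n_edges,
                           "n_contacts": core.n_contacts},
        "transitions": {k: v.as_dict() for k, v in transitions.items()},
        "functional_fractions": funct,
        "functional_fractions_pct": {k: percent(v) for k, v in funct.items()},
        "extension_size_stats": ext_stats,
        "distance_trend": trend,
        "centrality": centrality,
        "er_tests": er_tests,
        "bridge3_proteins_E": bridge3,
        "headline": _headline(core, transitions, funct, ext_stats, centrality),
    }
    return summary


def _headline(core, transitions, funct, ext_stats, centrality) -> dict:
    """The printed-statistics block: every number comparable to the study
    conditions, as whole percentages where the field prints percentages."""
    b = transitions["ABE_to_B"]
    a = transitions["ABE_to_A"]
    e = transitions["A_to_E"]
    ua_share = sum(v for k, v in a.status_pair_fractions.items() if "Ua" in k)
    out = {
        "universal_core_edges": core.n_edges,
        "b_new_UB_pct": percent(b.status_pair_fractions.get("U-B", 0.0)),
        "b_new_BB_pct": percent(b.status_pair_fractions.get("B-B", 0.0)),
        "b_new_UbU_pct": percent(b.status_pair_fractions.get("Ub-U", 0.0)),
        "b_new_UbB_pct": percent(b.status_pair_fractions.get("Ub-B", 0.0)),
        "a_new_UA_pct": percent(a.status_pair_fractions.get("U-A", 0.0)),
        "a_new_AA_pct": percent(a.status_pair_fractions.get("A-A", 0.0)),
        "a_new_Ua_share_pct": percent(ua_share),
        "e_new_ext_mediated_pct": percent(e.ext_mediated_fraction),
        "e_n_new_proteins": e.n_new_proteins,
        "funct_universal_pct": percent(funct["universal"]),
        "funct_B_pct": percent(funct["B_new"]),
        "funct_A_pct": percent(funct["A_new"]),
        "funct_E_pct": percent(funct["E_new"]),
        "e_ext_G_pct": percent(e.contact_type_fractions.get("ext_G", 0.0)),
        "e_ext_ext_pct": percent(e.contact_type_fractions.get("ext_ext", 0.0)),
        "bc_argmax": {k: centrality[k]["bc_argmax"] for k in centrality},
    }
    if ext_stats and "E" in ext_stats:
        out["e_ext_gt80_pct"] = percent(ext_stats["E"]["fraction_gt_threshold"])
        out["abe_ext_gt80_pct"] = percent(
            ext_stats["ABE"]["fraction_gt_threshold"])
    return out


def run_synthetic_study(seed: int = 0, null_samples: int = 499,
                        alpha: float = 0.05,
                        out_dir: str | Path | None = None,
                        msa: bool = True) -> dict:
    """Generate the default planted fixture set and run the full analysis.

    Returns the summary dict; also includes the generator's ground truth
    under ``"planted"`` for recovery checks, and a conservation block from
    the planted alignment pair when ``msa`` is true.
    """
    study = synthetic.make_annotated_network(synthetic.NetworkStudySpec(seed=seed))
    graphs = {
        stage: graph_from_contact_table(
            study.tables[stage], stage, coords=study.coords,
            subunits=study.subunits)
        for stage in synthetic.STAGES
    }
    summary = _analyse(graphs, study.annotations, null_samples, alpha, seed)
    summary["planted"] = study.truth

    if msa:
        msa_fixture = synthetic.make_msa(synthetic.MsaSpec(seed=seed))
        prof_a = conservation.conservation_profile(msa_fixture.sequences_a)
        prof_e = conservation.conservation_profile(msa_fixture.sequences_e)
        acq = conservation.aromatic_acquisitions(prof_a, prof_e,
                                                 msa_fixture.column_map)
        summary["conservation"] = {
            "n_strict_columns_E": len(prof_e.strict_columns()),
            "n_new_aromatic_E": sum(1 for x in acq if x.status == "new_in_E"),
            "n_ancient_aromatic": sum(1 for x in acq if x.status == "ancient"),
            "n_strengthened": sum(1 for x in acq
                                  if x.status == "strengthened_similar_to_strict"),
            "planted": msa_fixture.truth,
        }
    else:
        summary["conservation"] = {"skipped": True}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        study.write(out / "fixtures")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, default=_json_default))
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run the file-based pipeline; halts on stage failure with a labelled
    error, keeping partial outputs.  Missing alignments skip the conservation
    stage with an explicit marker."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graphs: dict[str, RibosomeGraph] = {}
    annotations = {}
    for k in config.kingdoms:
        try:
            graphs[k.kingdom] = _kingdom_graph(k, config)
            annotations[k.kingdom] = load_annotation(k.annotation,
                                                     kingdom=k.kingdom)
            to_graphml(graphs[k.kingdom], out / f"graph_{k.kingdom}.graphml")
        except Exception as exc:
            raise RuntimeError(f"[stage: contacts/network, kingdom "
                               f"{k.kingdom}] {exc}") from exc
    missing = {"ABE", "B", "A", "E"} - set(graphs)
    if missing:
        raise RuntimeError(f"[stage: archaeology] missing kingdom inputs: "
                           f"{sorted(missing)}")
    try:
        ann_with_ext = {k: a for k, a in annotations.items()
                        if any(c.component_kind == "extension"
                               for c in a.components)}
        summary = _analyse(graphs, ann_with_ext, config.null_samples,
                           config.alpha, config.seed,
                           config.extension_threshold_aa)
    except Exception as exc:
        raise RuntimeError(f"[stage: archaeology/graphstats] {exc}") from exc

    msas = {k.kingdom: k.msa for k in config.kingdoms if k.msa}
    if {"A", "E"} <= set(msas):
        try:
            prof_a = conservation.conservation_profile(
                msas["A"], config.conservation_threshold)
            prof_e = conservation.conservation_profile(
                msas["E"], config.conservation_threshold)
            acq = conservation.aromatic_acquisitions(prof_a, prof_e)
            summary["conservation"] = {
                "n_strict_columns_E": len(prof_e.strict_columns()),
                "n_new_aromatic_E": sum(1 for x in acq
                                        if x.status == "new_in_E"),
            }
        except Exception as exc:
            raise RuntimeError(f"[stage: conservation] {exc}") from exc
    else:
        summary["conservation"] = {"skipped": True,
                                   "reason": "A/E alignments not provided"}
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, default=_json_default))
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
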