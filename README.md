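# riboarch

Evolutionary archaeology of ribosomal protein (r-protein) interaction
networks.

Ribosomes from the three kingdoms of life share a universal core of
r-proteins whose filamentous extensions weave tiny protein–protein
interfaces into kingdom-specific interactomes.  `riboarch` implements the
full analysis chain for studying how these networks grew:

1. **Interface detection** — inter-chain contacts are defined by buried
   solvent-accessible surface area,
   `buried(A,B) = SASA(A) + SASA(B) − SASA(AB)`, computed with a
   deterministic Shrake–Rupley sampler (probe radius 1.4 Å, golden-spiral
   sphere points).
2. **Network construction** — an undirected graph whose nodes are the
   centres of mass of the globular domains (whole protein when no globular
   domain exists) plus the six functional centres (PTC, exit tunnel, mRNA
   channel, tRNA A/P/E sites); component-level contacts are aggregated into
   single edges carrying multiplicities and typed as ext–ext, ext–G, G–G,
   ext–funct or G–funct.
3. **Network archaeology** — the universal (ABE) core as the intersection of
   the three kingdom networks, and per-transition statistics (ABE→B, ABE→A,
   A→E) of new contacts broken down by the evolutionary status pair of the
   contacting components (U-B, B-B, Ub-U, …), contact type, functional-site
   involvement, coevolved pairs, and the centre-of-mass distance trend.
4. **Graph statistics** — degree, closeness, betweenness (BC) and
   eigenvector (EV) centralities, and a Monte-Carlo test of the Erdős–Rényi
   G(n, m) null with empirical p-values
   `p = (1 + #{null ≥ observed}) / (n_samples + 1)`.
5. **Conservation** — per-column alignment conservation under the 80% rule
   (strict identity and by amino-acid class), interface conservation
   mapping, tracking of newly conserved aromatic residues across the A→E
   transition, and geometric classification of π–π, cation-π, anion-π and
   proline-π motifs.
6. **Synthetic data** — seeded generators for every input (toy PDB/mmCIF
   complexes, annotated interaction tables with planted proportions,
   alignments with planted conserved columns), each returning machine-
   readable ground truth.

It is aimed at structural and systems biologists who want to recompute the
network statistics on their own structures/annotations, or to test network
inference machinery against fixtures with known ground truth.

## Worked example

Run the fully synthetic study (all inputs generated with planted ground
truth under the default study conditions) and print the headline numbers:

```sh
riboarch study --seed 1 --null-samples 499
```

```json
{
 "universal_core_edges": 49,
 "b_new_UB_pct": 58,
 "b_new_BB_pct": 19,
 "b_new_UbU_pct": 12,
 "b_new_UbB_pct": 9,
 "a_new_UA_pct": 47,
 "a_new_AA_pct": 19,
 "a_new_Ua_share_pct": 35,
 "e_new_ext_mediated_pct": 57,
 "e_n_new_proteins": 11,
 "funct_universal_pct": 45,
 "funct_B_pct": 14,
 "funct_A_pct": 4,
 "funct_E_pct": 2,
 "e_ext_G_pct": 45,
 "e_ext_ext_pct": 39,
 "bc_argmax": {"B": "PTC", "A": "PTC", "E": "PTC"},
 "e_ext_gt80_pct": 10,
 "abe_ext_gt80_pct": 1
}
```

Reading the output: the three kingdom networks share a 49-edge universal
core, 45% of whose connections involve functional centres.  At the ABE→B
transition 58% of new protein–protein contacts join universal and new
bacterial proteins (U-B) while bacterial-acquired extensions play a minor
role (12% Ub-U, 9% Ub-B); at ABE→A the archaeal extensions already mediate
35% of new contacts; at A→E most new contacts (57%) run through extensions
newly acquired by universal or archaeal proteins, only 11 new proteins
arrive, and connections to functional centres have fallen from 14% (B) to
2% (E).  The eukaryotic network is extension-dominated (45% ext–G, 39%
ext–ext) and 10% of its extensions exceed 80 residues (vs 1% in the core).
In all three kingdoms the betweenness-centrality maximum falls on the PTC
node, and the max-BC statistic rejects the Erdős–Rényi null.

Other entry points:

```sh
riboarch contacts structure.pdb --probe 1.4 --out contacts.tsv
riboarch network contacts_E.tsv annotation_E.tsv --kingdom E --out graph_E.graphml
riboarch stats contacts_E.tsv --null-samples 999 --seed 17
riboarch fixtures --kind complex --seed 0 --out fixtures/
riboarch run config.yaml
```

The same functionality is available as a library (`riboarch.contacts`,
`riboarch.network`, `riboarch.archaeology`, `riboarch.graphstats`,
`riboarch.conservation`, `riboarch.synthetic`, `riboarch.pipeline`).

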