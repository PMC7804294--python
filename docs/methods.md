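# Methods

## Interface detection by buried surface area

A contact between two chains is the solvent-accessible surface area (SASA)
lost on complex formation:

    buried(A, B) = SASA(A alone) + SASA(B alone) − SASA(A ∪ B)

SASA is computed with a Shrake–Rupley numerical scheme: each atom's sphere
(van der Waals radius + probe) is covered with points from a deterministic
golden-spiral construction, and a point is exposed when it lies outside
every neighbour's expanded sphere.  Defaults: probe 1.4 Å (water), 960
points per atom.  The construction is deterministic, so results are
machine-stable for a fixed point count; agreement with other
implementations is tolerance-based, never bit-exact (radius tables and
point sets differ between programs).

* **vdW radii** — a fixed Bondi-style element table shipped with the
  package; unknown elements fall back to 1.70 Å with a logged warning.
* **Burial thresholds** — a contact is emitted when the total buried area
  exceeds `burial_tol` = 0.1 Å² and an interface residue when its SASA loss
  exceeds `burial_tol_res` = 0.1 Å².  These defaults only suppress
  sphere-sampling noise; they are not biological filters.
* **Convention** — buried area is the *total* over both sides (not halved);
  the convention is recorded on every contact to prevent factor-2 drift.
* **Structure handling** — waters and (by default) ligands are excluded,
  hydrogens dropped, the highest-occupancy alternate conformer kept, and
  author residue numbering preserved verbatim with insertion codes
  concatenated into the residue key.

Accuracy, as verified by the test-suite: the single-atom case matches the
analytic sphere 4π(r+p)² within 1%; multi-atom complexes match a
1 000 000-point random-direction Monte-Carlo oracle within 2% and an
independent library implementation (biotite) within 0.01% when radii are
matched.

## Network model

Nodes are r-proteins, placed at the unweighted mean of their globular-domain
atom coordinates, and the six functional centres (PTC, exit tunnel, mRNA
channel, tRNA A/P/E), placed at the mean of their defining residue
selections.  The geometric (mass-unweighted) centre is the default because
it needs no element-mass table and differs negligibly from the weighted
centre for proteins; mass weighting is available via a flag and the choice
is recorded in output metadata.  A protein with no globular domain uses all
its atoms.

Component-level contacts (globular domain, categorized extension, or extra
domain, against the same on the partner) are aggregated into one undirected
edge per protein pair; `n_connections` stores the multiplicity.  Edge type
is one of ext–ext, ext–G, G–G, ext–funct, G–funct.  When a contact's
interface residues span both globular and extension regions on one side,
the side is classified by the region with the larger summed buried area,
ties going to the extension (extensions are the object of study).
Connections among tRNAs/mRNA and other site–site adjacencies are drawn in
the graph but flagged `excluded_from_stats`; they are never counted in
connectivity statistics, core intersection or transition fractions, but are
present for centrality computation (the functional backbone is part of the
architecture being scored).

Functional-module labels per protein node: touching one site category gives
that module (the three tRNA sites count as one category); two categories →
`bridge_2`; three or more → `bridge_3`; a protein with no site contact
whose neighbourhood spans both subunits → `subunit_bridge`; otherwise
`none`.

## Network archaeology

Cross-kingdom edge identity is by unified nomenclature name pair.  The
universal core is the set of edges present in the A, B and E networks;
both the aggregated-pair count (primary) and the component-contact count
are computed, and they coincide when core contacts have multiplicity one.

For each transition (ABE→B, ABE→A, A→E) the *new contacts* are the child's
component-level contacts absent from the parent at
(protein pair, component pair) granularity — this includes reinforcements
of existing edges, which is why fractions are computed over contacts rather
than aggregated edges.  Denominators:

* status-pair fractions (U-B, B-B, Ub-U, …) over new **protein–protein**
  contacts;
* functional-centre fraction and contact-type fractions over **all** new
  contacts;
* `ext_mediated_fraction` = new contacts touching a component whose status
  is the transition's extension acquisition (Ub; Ua; Ue/Ae) over all new
  contacts.

This is the only denominator assignment under which the class percentages
sum to ~100 while the functional series (14%→4%→2%) holds simultaneously;
whole-network functional fractions are also available (`new_only=False`).
Coevolved pairs are contacts whose two components both carry the
transition's acquisition status.  Percentages are reported to 0 decimal
places (half away from zero) when compared against printed integers.

## Erdős–Rényi null test

The null model is G(n, m) with n and m matched to the observed graph —
conditioning on the observed density removes one nuisance dimension.  For
each of `n_samples` (≥ 100) samples a family of statistics is evaluated:

* `max_betweenness` — largest normalised BC;
* `betweenness_variance` — concentration of the BC distribution;
* `eigenvector_concentration` — inverse participation ratio Σvᵢ⁴ of the
  L2-normalised leading adjacency eigenvector (high when eigenvector mass
  localises on few nodes); chosen over a plain variance because variance of
  max-normalised scores is not direction-consistent across architectures;
* `degree_variance`.

Empirical p-values are upper-tail with the +1 correction (never zero) and
are bit-reproducible for a fixed seed.  `coherent_reject` means unanimous
rejection across the family at the configured α; this operationalises a
coherence notion whose exact formalism was not available and is labelled an
approximation in all outputs.  No multiple-testing correction is applied
inside the unanimity rule (it is conservative); raw per-statistic p-values
are always reported.  In practice only the two betweenness statistics
reject consistently for the hub-and-modules architectures this package
studies; the eigenvector and degree statistics are architecture-sensitive,
which the reports show honestly.

Eigenvector scores come from a dense symmetric eigendecomposition (exact,
deterministic, defined on disconnected graphs) and are normalised to unit
maximum; argmax ties break lexicographically.  Betweenness agrees with an
exhaustive all-pairs path-enumeration oracle on small graphs to 1e-12.
Type-I calibration: under the null, the rejection frequency over 200
replicates sits inside the 95% binomial interval around α (verified at
α = 0.05 and 0.01).

## Conservation and aromatics

A column is *strictly* conserved when one residue exceeds the 0.80
threshold, *similar* when one class does (aromatic FYWH / basic KR / acidic
DE / polar STNQC / hydrophobic AVLIMGP — a partition of the 20 residues, so
strict implies similar).  Gaps count in the denominator: a column
80%-identical among non-gap rows but half gapped is not conserved (the
stricter reading).  All-gap columns are flagged and never conserved.
Because the ambiguity between identity-only and class conservation cannot
be resolved from the available description, both strict and similar
fractions are reported everywhere.

Across A→E, an E-conserved aromatic column is `new_in_E` when its A
counterpart is not conserved-aromatic, `strengthened_similar_to_strict`
when A was class-conserved but not strict while E is strictly conserved,
and `ancient` otherwise.

π-interaction classification is ring-centroid based with configurable
cutoffs: π–π ≤ 7.0 Å, cation-π ≤ 6.0 Å (Lys NZ / Arg CZ), anion-π ≤ 5.5 Å
(Asp CG / Glu CD), proline-π ≤ 6.0 Å (Pro ring centroid).  The cutoffs are
conventional mid-range values for centroid-distance criteria and are
exposed in the API; incomplete rings are skipped with a warning; π–π pairs
are reported once in deterministic order.  A generic closest-approach scan
(default 10 Å) reports aromatic pairs that approach without touching.

## Synthetic data: what it emulates and what it does not

The generators are first-class, tested code; their defaults *are* the study
conditions:

* 33 universal, 21 bacterial, 33 archaeal and 11 eukaryote-specific
  proteins; a 49-edge universal core with 45% functional-centre contacts;
* new-contact class counts per transition chosen so the recovered
  percentages round to 58/19/12/9 (B), 47/19 with a 34.5% Ua share (A,
  printed 47/19/35 — the printed numbers sum to 101 by rounding, so the
  underlying fractions are 0.465/0.19/0.345), and a 57% share of contacts
  mediated by newly acquired extensions in E;
* functional-centre fractions 45/14/4/2% and eukaryotic contact types
  45% ext–G / 39% ext–ext (counts 14 of 100, 8 of 208, 2 of 100);
* extension-size distributions with >80-aa fractions 1% (ABE), ~3% (B),
  5% (A), 10% (E) — the endpoints are the stated conditions, the B/A
  interpolants are package defaults chosen once as a monotone series;
* stage length scales 10/45/75/140 Å so the mean centre-of-mass distance of
  newly added edges increases through evolution by construction;
* planted repeated protein pairs (multiple connections), two designed
  three-site bridge proteins appearing only in E, and per-kingdom
  alignments with planted strict, ancient-aromatic, new-aromatic and
  similar→strict columns at 90% conservation over 50 sequences.

The contact topology is *modular by design*: each protein belongs to one of
six site-anchored neighbourhoods, new contacts form within the
neighbourhood with probability 0.97, the PTC's partner proteins are spread
across all neighbourhoods (the catalytic centre sits centrally in the
ribosome body), and the real site–site adjacencies (tRNAs to PTC and mRNA,
PTC–tunnel) are drawn as excluded-from-statistics edges.  This architecture
— not any tuning of the test — is what makes the planted networks reject
the Erdős–Rényi null and place the betweenness maximum on the PTC, exactly
as a modular hub-centred interactome should.

What the generators do **not** emulate: real rRNA (no nucleotide network),
real protein folds (toy structures are ideal poly-alanine helices with
idealised local geometry, adequate for surface-area arithmetic but not for
stereochemistry), disordered/unmodelled residues (extension lengths count
modelled residues only), cross-kingdom sequence homology (the A/E
alignments share a coordinate system by construction rather than via a
joint alignment), and species-level variation within kingdoms.  Passing the
planted-recovery tests therefore demonstrates the correctness of the
bookkeeping and statistics, not the biological values themselves, which on
real data depend on the curated annotations supplied.

## Numerical and procedural choices

* All randomness flows through `numpy.random.default_rng(seed)`; derived
  seeds stay below 2³¹.  Same seed ⇒ byte-identical outputs.
* Problem sizes used by the test-suite and acceptance script: ER nulls of
  199–499 samples on graphs of 39–83 nodes; type-I calibration with 200
  replicates of G(18, 30); Monte-Carlo SASA oracle at 10⁶ points on a
  110-atom complex.  These sizes give sub-percent standard errors on every
  quantity asserted.
* Degenerate inputs: empty atom selections, all-gap columns, ragged
  alignments, inverted or overlapping residue ranges, unknown statuses and
  unannotated chains all raise with the offending entity named; stages with
  zero new edges report an undefined mean, flagged rather than silently
  dropped.
* The pipeline halts on the first failing stage with a stage-labelled error
  and keeps partial outputs; a missing alignment pair skips the
  conservation stage with an explicit `skipped` marker.

## Known limitations

* Interface detection agrees with other SASA programs only within
  tolerance; no symmetry-mate expansion, no hydrogen addition.
* The coherence rule (unanimous rejection) is an approximation of a
  formalism that was not available; the statistic family is configurable so
  a replacement can be dropped in.
* Extension categories and evolutionary statuses are consumed from curated
  annotations; the package does not infer them from structure or sequence.
* The universal-core count is reported at both protein-pair and
  component-contact granularity; on inputs where core contacts have
  multiplicity above one the two differ and the pair count is primary.
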