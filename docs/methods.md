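# Methods

## Domain architectures and variant calling

A protein's architecture is the N→C ordered tuple of Pfam accessions of
its surviving domain hits. Hit resolution: hits overlapping by more than
`max_overlap_fraction` (default 0.5) of the shorter hit are in conflict;
conflicts are resolved greedily in order of quality — smaller e-value
first, ties broken by longer alignment, then lexicographic accession —
so the result is independent of input row order. 0.5 of the shorter hit
is the common Pfam post-processing heuristic; it is configurable because
clan-aware filtering pipelines differ. Versioned accessions
(`PF00403.28`) are stripped to the unversioned form at parse time, since
architecture signatures are defined over unversioned accessions.

Variant calling matches an architecture against the two signatures,
longest first, so a protein matching the 2-domain signature is never
also called 1-domain. Two modes are shipped:

* `EXACT` (default): the architecture must equal the signature. Proteins
  with three or more HMBD copies are left uncalled — only 1 and 2 copies
  define variants here.
* `SUBSEQUENCE`: the signature must occur as a contiguous run inside the
  architecture. Offered because real proteomes carry incidental extra
  domains; under this mode a triplicated-HMBD protein is called
  2-domain (the longest signature found).

EXACT is the default because the variant definitions are printed as full
architectures; whether proteins with extra domains should count is a
judgement call we expose rather than decide.

## Genomic context

The context unit is the co-directional strand run: starting at the focal
gene, extend left and right one gene at a time while the neighbour's
strand matches the focal strand, stopping at the first strand flip or
contig end. Strand is the sole criterion by default; an optional
`max_gap_bp` limit (intergenic distance = next.start − prev.end − 1)
exists because operon callers commonly bound gaps, but it is off by
default. Runs never cross contig boundaries (adjacency undefined there)
and circular contigs are not modelled. Non-coding features are dropped
at parse time with a logged count, so they neither join nor break runs;
whether intervening non-coding features should break adjacency is
genuinely open, and this choice makes the strand criterion exact over
protein-coding genes.

## FixI-like classification and cbb3 detection

A context is FIXI_LIKE iff the focal ATPase is the 1-domain variant and
at least `min_markers` (default 2) **distinct** cbb3-subunit markers lie
among the other members of its run. "At least 2" is the minimal reading
of "multiple"; it is a flag (`--min-markers`) so sensitivity can be
reported. Markers are matched primarily by gene label
(ccoN/ccoO/ccoP/ccoQ and the fixN/fixO/fixP/fixC synonyms); matching by
Pfam accession against member architectures is supported but no default
accession list is shipped — annotations vary and inventing one would
bake in errors. 2-domain ATPases are never FixI-like, whatever their
neighbourhood.

Genome-level cbb3-cluster presence (default mode `run`) requires a
co-directional run holding ≥ `min_markers` distinct markers, using the
same run semantics seeded at each marker gene; mode `anywhere` only
requires the markers to exist somewhere in the genome. Both are exposed
because the profile could plausibly be defined either way.

## Order-level aggregation and trees

Copy numbers are counted per genome and variant, then binned 0..7 with
everything ≥ 7 pooled into the top bin ("7+") — an 8-bin display scale;
the cap is configurable (`--max-copy-bin`). Per order we report the
proportion of genomes in each bin (each vector sums to 1 within 1e-9 by
construction) and the proportion of genomes with a cbb3 cluster. Output
is sorted by order name and invariant to genome input order.

Tree pruning retains a requested leaf set and collapses unary internal
nodes, summing their branch lengths onto the retained child edge
(dendropy's `retain_taxa` provides exactly this). Collapsing to a rank
replaces each maximal monophyletic set of same-taxon leaves with one
leaf named for the taxon. Non-monophyletic taxa are handled totally: the
largest clade keeps the bare name, further clades get `name_2`,
`name_3`, ... by decreasing size, with a logged warning. Branch lengths
are optional; without them pruning preserves topology only.

## Assay computations

* **Atoms per cell**: moles = c[mg/L] × V[L] / 1000 / M[g/mol];
  atoms = moles × N_A; divided by the cell count. N_A is fixed at the
  2019 SI value 6.02214076e23; molar mass is taken in g/mol with the
  unit stated explicitly because source formulas in this area are often
  typeset with garbled units.
* **TMPD activity**: Δc[mM] = ΔA520 / (ε·l); amount[μmol] = Δc × V[L] ×
  1000; activity = amount / Δt[min], reported per well of cells (default
  2.4e4). ε defaults to 6.1 mM⁻¹ cm⁻¹. The optical path defaults to
  0.29 cm — the approximate depth of 100 μl in a flat-bottom 96-well
  plate — and is a documented assumption, required config for any
  quantitative use. Negative ΔA is returned as-is with a warning rather
  than clipped, so blank-subtraction errors stay visible.
* **NADI**: dark staining with onset ≤ `fast_cutoff` (60 s) → NADI+;
  any staining with onset ≤ `slow_cutoff` (900 s = 15 min) → NADIslow;
  staining later than the slow cutoff, or none over a window covering
  it, → NADI−. A window shorter than the slow cutoff with no staining is
  returned as NADI_INDETERMINATE instead of being forced to NADI−.
  The 15-min slow cutoff follows the assay protocol description; a
  30-min reading also circulates, so both cutoffs are parameters.

## Synthetic data generator

The generator emulates the statistical structure of an order-stratified
genome panel, not its sequences: genomes are stranded gene lists on a
few contigs; strandedness of background genes follows a Markov flip
process (flip probability 0.15 per step); gene coordinates use a fixed
900 bp gene length and 100 bp intergenic gap (they matter only for
ordering and gap-limit tests). Default study conditions: 10 orders × 20
genomes, 2 contigs of 25–45 genes, copy-number distributions
(0.25, 0.55, 0.15, 0.05) for the 1-domain and (0.55, 0.30, 0.10, 0.05)
for the 2-domain variant over 0–3 copies, cbb3 clusters in 70% of
genomes, 80% of 1-domain ATPases co-localized with a cbb3 run, and a
10% decoy-architecture rate on background proteins.

Planting: each ATPase receives domain hits spelling its signature
exactly; a co-localized 1-domain ATPase is inserted into a run of three
distinct marker genes (ccoN/ccoO/ccoP) on one strand; an independent
standalone marker run is planted with probability `p_cbb3_cluster`;
genome-level cbb3 truth is "any marker run planted". Every planted block
is flanked by single opposite-strand insulator genes so blocks can never
merge into one run — the emitted truth therefore holds by construction,
and a noiseless pipeline run recovers it exactly. Decoy architectures
are drawn from a pool disjoint from the signatures, so they are inert
under both matching modes. Orders are monophyletic by construction in
the coalescent-style random tree (random pairwise joining with
exponential branch lengths); `scramble_orders` swaps leaves across
orders to exercise the non-monophyly path. Infeasible configurations
(contigs too short to host a planted run) fail before any output.

What the generator does **not** emulate: real Pfam hit-score noise,
partial/fragmented architectures, operon rearrangements, annotation
errors, assembly fragmentation biases, or non-coding structure. Passing
truth-recovery tests therefore demonstrates the pipeline's logic is
exact on clean input; it does not validate robustness to annotation
noise, which on real data is governed by the upstream domain scanning.

All randomness flows through one numpy PCG64 generator seeded from
`SimConfig.seed`; outputs are byte-identical across runs and platforms
for a fixed configuration.

## Problem sizes and determinism

The shipped tests run the pipeline end-to-end on panels of 12–200
genomes and a recovery study with one order of 500 genomes, where
recovered bin proportions are required to lie within 3·√(p(1−p)/500) of
the generative probabilities — the exact-binomial envelope at the
planted sample size. Fuzz checks compare the variant matcher and the
strand-run extractor against brute-force oracles on 10⁴ random
instances each. `scripts/acceptance.py` re-runs the default 200-genome
study from scratch for any seed and reports recovery percentages,
conservation error, tree leaf counts and the assay reference values.

## Known limitations

* Subfamily assignment (P1B1 vs P1B4 etc.) by sequence similarity is out
  of scope; classification is purely architectural.
* Marker identity relies on input gene labels unless an accession set is
  provided; unlabeled real annotations need a preceding annotation step.
* `genome_has_cbb3_cluster` counts distinct marker labels, so split
  operons on different contigs never count together in `run` mode.
* iTOL files are written as fixed-header text for iTOL's dataset
  importer; no interaction with the iTOL service is attempted.
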