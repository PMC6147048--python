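# Methods

## The trait model

Mo/W utilization is treated as a deterministic boolean function of an
organism's gene content, recovered from homology evidence.

**Homology filtering.** A hit from the 12-column tabular search output is
kept iff its e-value is at most `evalue_max` (default 0.01) and its
*query-side* alignment coverage, `(qend − qstart + 1) / query_length`,
is at least `coverage_min` (default 0.20). Coverage is computed on the
query because queries are full-length curated seed proteins whereas the
searched genomes may be fragmentary; the side is configurable. Full
query lengths travel in a companion length table since the tabular
dialect does not carry them.

**Ortholog assignment.** Each candidate protein is assigned to the
family of its best seed hit (maximal bit score; ties broken by lower
e-value, then lexicographically smaller id, so results are independent
of input order). Two vetoes apply: if the best hit is an *exclusion
seed* — a Mo-independent homolog such as NuoG (DMSOR-like) or NifE
(nitrogenase-like) — the protein is left unassigned; and if the top bit
score is shared by seeds of two families the protein is dropped as
ambiguous rather than guessed (such cases are resolved manually in real
annotation work, e.g. by gene neighborhood). Bidirectional best hits are
provided as a separate orthology primitive with the same ranking rule.
Note that tightening the e-value cutoff can *promote* new reciprocal
pairs (removing a one-sided best hit lets the runner-up become
reciprocal), so BBH sets at different cutoffs are compared per query,
not as subsets.

**Moco pathway rule.** The three biosynthesis steps are satisfied by
moaA∨moaC, moaD∨moaE∨moeB and moeA∨mogA respectively. The pathway is
called present when all three steps are satisfied *and* at least
`pathway_majority` of the seven key genes are present. "Most of the key
genes" is quantified here as a strict majority, ≥ 4 of 7 (configurable);
the per-step requirement alone would accept a 3-gene profile. The plant
bifunctional CNX1 seed carries the compound label `moeA+mogA` and
satisfies both metal-insertion genes at once.

**Utilization category.** `moco_trait` = pathway ∧ (≥ 1 enzyme-family
member among SO, XO, DMSOR, AOR, MOSC); `both` / `moco_only` /
`nif_only` / `none` follow from crossing it with nitrogenase presence.
AOR is W-specific but counted as a Moco enzyme by default because the
cofactor chemistry is shared; `include_aor_as_moco_enzyme=False` gives
the strict-Mo call. MOSC-only organisms count as enzyme-positive.
Organisms with the pathway but no enzyme, or enzymes but no pathway, are
tabulated as partial-trait ("orphan") classes crossed with nitrogenase.

**Transporters.** An ABC system is called present iff its
substrate-binding A subunit plus at least one membrane/ATPase (B/C)
subunit is found — the A subunit confers substrate specificity, so it
anchors the call. MOT1/MOT2 are single genes. ABC calls are restricted
to prokaryotes and MOT calls to eukaryotes.

**Richness.** An organism is molybdoprotein-rich iff its molybdoprotein
gene count strictly exceeds `rich_threshold` (default 20). Nitrogenase
genes are excluded from the count by default (configurable).

**Tungstoproteins.** Three ecology-based rules: (i) any AOR member;
(ii) FDH/ACH orthologs in strictly anaerobic (`oxygen_req ==
anaerobic`) bacteria; (iii) FWD orthologs in methanogenic archaea
(recognized by a "methano…" rank in the taxon path). DMSOR members
without a subfamily label cannot fire rules (ii)/(iii) and are logged.

## Domain fusions

Per-protein domain hits are tiled greedily by descending score (ties:
lower e-value, smaller start, then accession), accepting a hit iff it
overlaps every previously accepted hit by at most 10 residues — a
tolerance for the boundary jitter of real domain annotations
(configurable). A fusion event is a protein whose architecture couples
catalytic domains of exactly one molybdoprotein family with ≥ 1
non-catalytic partner; proteins spanning two families' catalytic domains
are logged and skipped. Partners recurring across ≥ 2 families are
flagged `multi_family`; partners with established functional links
(XDH FAD-binding subunit, nitrate reductase δ/γ, cysteine desulfurase)
are annotated as known rather than novel.

## Phylogenetics and HGT

Distances are uncorrected p-distances with pairwise deletion of gap
positions (a pair with no comparable site reports 0 with a warning —
p-distance is not guaranteed metric and is used only as NJ input). Trees
come from standard neighbor joining (Q-matrix minimization) with ties
broken on the lexicographically smallest pair of cluster keys and
negative branch-length estimates clamped at zero; the output is the
unrooted tree written with a trifurcating root. On additive matrices
this reconstructs the generating tree exactly, which the tests verify on
random 5–8-taxon trees and against an independent NJ implementation.

For HGT screening each gene tree is midpoint-rooted (the displayed trees
have no stated outgroup), the focal leaf's sister group is collected,
and its majority taxonomic class is taken (ties → "ambiguous"). A gene
*supports* transfer iff that class is definite and foreign; the organism
is flagged when ≥ `hgt_min_trees` genes agree (default 3 — the number of
concordant trees that constitutes a call is a package choice, as no
quantitative criterion is established). Optional column-resampling
bootstrap (100 replicates) reports the stability of a sister call but
does not gate flags by default.

## Environment association

For habitat (host-associated, aquatic, terrestrial, multiple,
specialized) and oxygen requirement (anaerobic, facultative,
microaerophilic, aerobic), per-category feature proportions are reported
at two decimals with exact Clopper–Pearson 95% intervals. Organisms with
unknown factor values are excluded from denominators, and the analysis
runs on bacteria only by default: archaeal sampling is heavily skewed
toward aquatic/anaerobic lifestyles and would confound the trend. A
two-proportion chi-square between categories is available as an
explicitly labeled extension; no hypothesis test is applied by default.
All percentages use decimal round-half-up so printed one-decimal values
are reproducible from integer counts.

## Synthetic communities

The generator emits metadata, per-organism hit tables, domain tables and
gene alignments whose downstream verdicts equal the ground truth by
construction:

- **Sizes and frequencies.** Defaults mirror the published census:
  256 archaea, 5,387 bacteria, 250 eukaryotes; trait-category weights
  per kingdom from the census's tabulated category counts; per-system
  transporter and per-family enzyme inclusion probabilities from the
  tabulated occurrence percentages.
- **Hits.** A present gene yields one hit with e-value ≤ `evalue_max`/10
  and coverage ≥ 2·`coverage_min` (comfortably inside the filter), so
  classification is noise-free. Decoy rows (20% of hits by default)
  always violate one threshold; an additional exerciser protein whose
  best passing hit is NuoG checks the exclusion rule on every run.
- **Molybdoproteome sizes** follow a negative binomial per kingdom
  (mean/shape 10/2 bacteria, 6/3 archaea, 5/5 eukaryotes), chosen so
  that roughly 8–10% of Mo-utilizing bacteria exceed the richness
  threshold while archaeal/eukaryotic maxima stay in the low twenties,
  matching the reported shape of the size distributions. Members are
  spread across the organism's present families with DMSOR weighted
  heaviest.
- **Orphans** are planted exactly: requested cell counts are carved from
  the sampled nif-only/none pools (falling back to trait-positive
  organisms if a pool is short, with truth updated accordingly).
- **HGT scenario.** Each gene's clades descend from mutated copies of a
  random ancestral protein (per-site substitution probability 0.05
  within clades, 0.35 between; no indels, so sequences are born aligned
  and p-distances are exact). When the transfer is on, the recipient's
  sequences derive from the donor clade's ancestor for all seven genes
  (five pathway genes plus a MOSC and an AOR gene, mirroring the
  reported co-transfer).
- **Factor surveys.** `habitat_survey` / `oxygen_survey` build
  bacteria-only communities with exactly n per category (default 2,000)
  and trait presence drawn from the configured conditional probabilities
  (defaults: terrestrial 0.9405 … host-associated 0.5630; aerobic
  0.7892 … anaerobic 0.50 — the two anchors are reported values, the
  middle categories are plausible intermediates consistent with the
  reported ordering).
- An optional per-gene `dropout` (default 0) emulates incompletely
  assembled genomes; truth keeps the intended labels, so dropout > 0 is
  the one setting where classification may legitimately miss.

What passing on synthetic data does *not* show: robustness to paralog
confusion, partial-length hits near the thresholds, annotation noise in
real domain tables, or alignment error — the generator produces none of
these by design.

## Problem sizes and determinism

The default test suite uses a 648-organism community (128/400/120), the
acceptance script the full 5,893-organism census structure plus two
18,000-organism surveys; both complete in well under a minute. All
randomness flows from a single integer seed through
`numpy.random.default_rng`; fixed seed and inputs give byte-identical
output tables.

## Known limitations

- NJ uses raw p-distances; no Jukes–Cantor/Kimura correction and no
  Bayesian confirmation of topologies.
- The orphan/decoy machinery models best-hit mistakes only through the
  exclusion-seed mechanism, not through realistic score distributions.
- Operon-adjacency evidence for HGT is not modeled; flags rest on tree
  concordance alone.
- Strain-level duplicates are not collapsed: each metadata row is one
  organism.
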