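# Methods

## Genome model

A genome is a set of linear chromosomes, each an ordered sequence of signed
blocks. Every block `b` carries two extremities, tail `(b, t)` and head
`(b, h)`; reading a chromosome left to right visits tail→head for `+b` and
head→tail for `−b`. Consecutive extremities form *adjacencies*; chromosome
ends are *telomeres*. Two genomes over the same blocks are compared through
their adjacency graph, whose components are cycles and paths.

All coordinates are 0-based half-open internally. Input tables may declare the
1-based fully-closed dialect (`one_inclusive`, the default, matching
genome-browser exports); conversion happens once at parse time and is
idempotent thereafter.

## msHSBs and EBRs

Pairwise synteny blocks (target species placed on reference coordinates with
an orientation sign) are filtered to a minimum reference length — default
300 kb, the resolution at which the source maps were drawn. The reference axis
is cut at the union of all species' block boundaries; a segment survives as
(part of) an msHSB only if every species covers it. Adjacent segments merge
when every species agrees on target chromosome, orientation, and target
contiguity within a tolerance equal to the resolution (the merge tolerance is
not dictated by the data model; tying it to the resolution means no breakpoint
observable at that resolution is erased). Segments still shorter than the
resolution after merging are dropped; ids run in reference order.

EBRs are the reference gaps between a species' adjacent blocks: different
target chromosomes → interchromosomal; same target chromosome with an
orientation flip or a target-order discontinuity (gap beyond the tolerance, or
order reversal) → intrachromosomal. The EBR is the *maximal* gap interval —
zero-width when blocks abut — rather than a midpoint guess; window assignment
downstream decides pointing. An EBR is lineage-specific when no other species
has a reciprocally overlapping EBR; the default overlap rule is "any shared
base pair" (abutting intervals stay distinct, a zero-width breakpoint overlaps
an interval containing it), with a configurable reciprocal fraction because
"the same EBR" across species is not otherwise well defined.

## DCJ distance and scenarios

The event model is double-cut-and-join (2-break): one operation cuts up to two
adjacencies and rejoins the four ends, uniformly encoding inversions,
reciprocal translocations, fusions and fissions. The distance is the closed
form `N − (C + I/2)` (blocks, adjacency-graph cycles, odd paths). Consequences
accepted with the model: a transposition costs two operations, and for
unoriented components a pure-inversion scenario can exceed the DCJ length — in
that case the optimal mixed scenario is reported and the circular-excision
steps are flagged on the events.

Scenario extraction is the standard greedy: every adjacency of the target
missing from the current genome is a distance-reducing join; candidates are
ranked to (1) immediately reabsorb circular intermediates, (2) prefer
inversions, with the lexicographically smallest extremity as the final
tie-break, and trailing telomere cuts clear the remainder. The ranking makes
scenarios deterministic, which the reuse tallies require. Event types are read
off the chromosome structure at application time (1→1 linear = inversion,
2→2 = translocation, 2→1 = fusion, 1→2 = fission/excision).

A genome equals its reverse complement: a whole-chromosome flip has no
adjacency signature, zero distance, and an empty scenario. Orientation
evidence for blocks that form chromosomes on their own is therefore handled
separately: a block whose orientation differs in a single species is flagged
`orientation_unknown`; two or more disagreeing species count it as a true
inversion (`count_whole_block_inversions`).

## Ancestral reconstruction

For every adjacency observed in any leaf, presence/absence is scored at each
internal node by unit-cost small parsimony, computed with the inside/outside
dynamic program so each node knows whether presence is *mandatory* (in every
most-parsimonious labeling), *optional* (in some), or excluded. Mandatory
adjacencies, then optional ones ranked by leaf support, are chained greedily
under two constraints — each extremity used once, no chain closed into a
circle — and the chains are the node's CARs. Dropped candidates are recorded
as conflicts.

A deliberate asymmetry of the data must be acknowledged: differences between
the outgroup and the rest that map to the two root-incident branches cannot be
polarised by parsimony (either placement costs one event). Optional-rank
ordering by leaf support resolves these ties reproducibly; how often they are
resolved *correctly* depends on how many events the short root-adjacent branch
carries, which is why recovery is validated by simulation rather than assumed.

The parsimony initialisation is then polished by a median-style local search:
each internal node is re-proposed from the adjacencies of its tree neighbours
(two children and parent), ranked by vote count then leaf support, and the
proposal is accepted only if it lowers the summed DCJ distance to the
neighbours — with equal-cost proposals accepted when they raise the total leaf
support of the node's adjacencies. Both objectives are bounded and strictly
improving, so the sweep terminates (default at most 10 rounds, typically 2–3).
The support tie-break also stabilises the reconstruction across leaf subsets,
which the leave-one-out robustness report measures.

Per-branch event summaries run the DCJ scenario between the reconstructed
parent and child; rates divide by branch length in million years (a
zero-length branch with events reports an infinity sentinel and a warning).
Deeper ancestors that the outgroup cannot reach directly are inferred only
when the two flanking arrangements agree up to chromosome order and flips
(`infer_deeper_ancestor`), otherwise "undetermined".

Reconstruction can be restricted to block subsets per reference chromosome
group, each group with its own outgroup, via the pipeline's
`chromosome_groups` configuration — the pattern used when different outgroups
cover different chromosome classes.

## Breakpoint reuse

Segment ends are msHSB extremities (two per block). Scenarios from the common
ancestor to each leaf are concatenated per lineage; an extremity's usage count
is the number of events whose broken ends include it. An end is *involved* if
used at least once; *reused across lineages* if used in two or more lineages;
*reused in any sense* if additionally a single lineage used it twice.
Percentages are reported over involved ends, rounded to one decimal, matching
the published convention (e.g. 100/421 = 23.8%, 214/421 = 50.8%).

## Recombination association

Genetic-map markers give cM positions; each window boundary's genetic position
is linearly interpolated between flanking markers and the window rate is
ΔcM/ΔMb. Windows not fully inside the marker span have no rate and are
excluded. Decreasing genetic positions are clamped isotonically with a
warning. Window size defaults to 1 Mb, non-overlapping, tiling each chromosome
(terminal remainder kept).

Windows are flagged by EBR midpoint (default) or any-overlap — both offered
because the original window assignment rule is not recorded. The two classes
are compared twice: a two-sided Wilcoxon rank-sum test with continuity
correction (the normal-approximation path of R's `wilcox.test`, the method
named in the source analysis; the reported `W` is the first-sample U
statistic), and a randomisation test that draws `|flagged|` windows without
replacement from all rated windows `n_iter` times (default 10,000) and reports
the one-sided fraction of draws whose mean reaches the observed flagged-class
mean (direction configurable; resolution 1/n_iter; bit-reproducible given the
seed).

## Chromosome-number correlation

Ordinary least squares of interchromosomal-change counts on |n − 40| over the
species with a published haploid number (species marked "?" are silently
excluded, as are any explicitly excluded names). The bundled 21-species table
carries both the total (macro- and micro-) and the micro-only change columns;
the total column is the regression default because it is the one that
reproduces the published R² pair (0.3 with all 15 species, 0.7 with the
ostrich outlier removed), verified against a closed-form Pearson computation.

## Enrichment

Gene families are collapsed to one representative per (chromosome, family) —
lexicographically smallest gene id — so tandem arrays cannot mimic functional
clustering. For each term with at least one gene on a chromosome, the p-value
is the upper hypergeometric tail (probability of at least the observed count
in the chromosome's collapsed gene set drawn from the collapsed universe).
Benjamini–Hochberg q-values are computed per chromosome by default, mirroring
per-chromosome uploads to enrichment services; a `global` scope re-adjusts
across all (chromosome, term) pairs. Results are tiered: *significant*
(p < 0.05 and q ≤ 0.05), *suggestive* (p < 0.05 only). Per-chromosome FDR
controls error within a chromosome but not genome-wide — under a global null
with ~40 chromosomes, the chance of at least one significant pair somewhere is
large — so genome-wide questions (including the calibration studies here)
should use, and the calibration tests do use, the global scope.

## Synthetic generator

The generator defines the study conditions; its defaults are fixed and the
tests run against them.

- **Root karyotype:** 10 macrochromosomes of 6–12 blocks (1–10 Mb each) and 30
  microchromosomes of 1–3 blocks (1–5 Mb each) — haploid 40, 2n = 80, around
  150 blocks and a ~0.7 Gb genome, the typical avian configuration in
  miniature. Every block is at least 300 kb so the resolution filter is
  non-destructive at defaults.
- **Tree:** the packaged six-species tree with splits at 100 (palaeognath/
  neognath), 65 (galloanseran), 54 (passerine/parrot) and 30 (chicken/turkey)
  million years. The Galloanserae–Neoaves split is not anchored by the study's
  dates; it is placed at 95 MY so the tree is ultrametric at depth 100 with no
  zero-length internal branch.
- **Events:** per branch, counts are Poisson(rate × MY) per type with default
  rates (events/MY) inversion 0.12, translocation 0.010, fusion 0.005, fission
  0.005 — inversion-dominated with rare interchromosomal change, totalling
  0.14/MY so the 30–100 MY branches expect roughly 5–15 events each. A uniform
  per-branch count override (`events_per_branch_range`) exists for controlled
  designs. Whole-chromosome flips are excluded (no adjacency signature);
  micro–micro interchromosomal pairs are down-weighted (factor 0.1) so a
  default run yields at most a couple of micro–micro events. With probability
  `breakpoint_reuse_prob` (default 0.1) an inversion endpoint reuses a
  previously broken extremity, seeding the reuse statistics. More than 10×
  as many events as blocks on one branch is rejected as degenerate.
- **Replay invariant:** applying the event log from the root reproduces every
  leaf exactly (asserted on every generated history).
- **Emitted tables:** each leaf is re-expressed as maximal runs contiguous and
  co-oriented in both the leaf and the chosen reference leaf, with synthetic
  target coordinates laid cumulatively — the same shape as browser-exported
  pairwise maps. Zero-width EBRs at true breakpoints follow by construction.
- **Genetic maps:** per-Mb window rates are log-normal (median ~2.5 cM/Mb,
  σ = 0.5, the scale of published chicken maps); `hotspot_coupling > 0`
  multiplies rates in windows holding a true breakpoint by (1 + coupling).
  Markers every 250 kb carry the cumulative cM; because the spacing divides
  the window size, interpolation recovers window rates exactly.
- **Annotations:** 120 genes per reference chromosome, two uniform terms each
  from a vocabulary of 30; ~15% of genes share a family with a same-chromosome
  neighbour (exercising collapse); a designated (chromosome, term) pair gains
  the seeded term with probability (enrichment − 1) × 2/n_terms, i.e. a
  five-fold seeded density at the default check.
- **Random streams** are spawned per purpose (events vs map vs annotations)
  from the single seed, so changing one knob leaves the other outputs fixed.

What the generator does *not* emulate: assembly gaps and scaffold
fragmentation, orientation-unknown scaffolds, missing per-species coverage
(every species covers the whole reference), sequence-level detail,
duplications and indels, and non-uniform breakpoint landscapes beyond the
reuse mechanism. Passing tests therefore certify the algorithms under clean,
fully-observed maps, not robustness to assembly artefacts.

## Validation studies and sizes

Run by the test suite and `scripts/acceptance.py` (sizes chosen as desk-scale
defaults; the acceptance script uses the `--seed` argument for every stream):

- **DCJ engine:** exhaustive agreement with a breadth-first-search oracle over
  single-DCJ moves for every arrangement pair with ≤ 5 blocks and ≤ 2 linear
  chromosomes (reduced by relabelling invariance to canonical sources per
  chromosome-size partition; ~15k pairs), plus scenario-length equality and
  exact replay. The script reports the ≤ 4-block slice (~1.1k pairs).
- **Ancestral recovery:** 100 histories (50 in the script) at default rates
  and reuse 0.1: ≥ 95% of true root adjacencies recovered (measured ~97%) and
  aggregate inferred events within ±10% of truth (measured +1–4%).
- **Leave-one-out:** every single-species exclusion retains ≥ 90% of the root
  ancestor's adjacencies (measured minimum ~94%, mean ~99%).
- **Randomisation test:** under the null (i.i.d. rates, random flags; 200
  windows, 20 flagged, 400 draws) the rejection rate at 0.05 lies in
  [0.03, 0.07] over 1,000 replicates; with hotspot coupling 5 the test rejects
  in ≥ 80% of replicates (measured 100%).
- **Enrichment:** with null annotations, no FDR-significant pair genome-wide
  in ≥ 95% of replicates; a five-fold seeded pair is significant in ≥ 95%
  (measured ~97–100%). Both under the global FDR scope, per the rationale
  above.

## Known limitations

- Root-adjacent ambiguity: differences between the outgroup and the ingroup
  ancestor are unpolarisable at the root by parsimony; accuracy there degrades
  as the root-adjacent branches accumulate events.
- Convergent breakpoint reuse erodes per-adjacency parsimony; the median
  refinement compensates only partially at high reuse probabilities.
- The EBR caller works at the block resolution: rearrangements entirely inside
  one block, and EBR classes distinguishable only below the merge tolerance,
  are invisible.
- The Wilcoxon p-value uses the normal approximation with continuity
  correction even at small window counts, for fidelity to the named method
  rather than small-sample exactness.
- `sorting_scenario` reports DCJ-optimal scenarios; when a pure-inversion
  explanation would be longer (unoriented components), counts are minimal DCJ
  counts, flagged, not inversion counts.
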