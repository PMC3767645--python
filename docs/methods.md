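# Methods

## The analysis

`diffmark` compares two single-library ChIP-seq experiments for a broad
histone mark (the motivating design is H3K9me2 in wild-type versus
Dicer-null mouse embryonic stem cells) without replicates or an input
control. The procedure is:

1. **Tag ingest.** Aligned tags are read from BED or SAM. "Uniquely
   mapping" is operationalized as mapped records with MAPQ ≥ `mapq_min`
   (default 20), plus NH == 1 when an NH tag is present. MAPQ is a portable
   proxy for uniqueness across aligners; duplicates are kept, since neither
   library carries UMIs and a broad mark legitimately stacks tags. All
   internal coordinates are 0-based half-open.
2. **Windowing.** The genome is tiled into fixed-width windows (default
   100 bp; the terminal window of each chromosome is truncated). Each tag
   is assigned to the single window containing its midpoint
   ⌊(start+end)/2⌋. The midpoint rule makes window counts conserve the
   library size exactly, an invariant asserted throughout the test suite;
   the plausible alternatives (5′-end assignment, overlap-weighting) differ
   negligibly at 100 bp against ~36 bp tags but lose either conservation or
   integrality.
3. **Normalization.** Per-window densities (count / actual window width,
   tags per bp — densities rather than counts so truncated terminal windows
   do not distort the quantiles) are quantile-normalized: the reference
   distribution is the row-wise mean of the column-sorted matrix, and each
   value is replaced by the reference value at its within-column rank. Ties
   receive the mean of the reference over the tied rank span. The tie rule
   is essential for window counts, which are small integers massively tied
   at zero; it deliberately trades the classical exact invariants
   (identical sorted columns, idempotence — which the tests assert on
   tie-free data, where they hold to machine precision) for stable
   behaviour on tied data. Zeros map to the reference minimum (averaged
   over the zero block), preserving the zero-heavy structure.
   `cpm` (counts per million) and `none` are offered for sensitivity
   analysis only.
4. **Per-window test.** With one library per condition the only exact
   null available is conditional: given a window total n = a + b, the
   condition-B count is Binomial(n, π₀) with π₀ = N_B/(N_A+N_B) from the
   library sizes. Two-sided p-values use tail doubling with the observed
   point included in each tail, capped at 1 — a simple convention that an
   enumeration oracle can verify exactly. The test runs on **raw counts**;
   the reported effect size `delta` is the difference of
   quantile-normalized densities (B − A), so the effect scale is
   depth-free while the p-value remains exact. Windows with a + b = 0 are
   untestable and are excluded both from testing and from the
   Benjamini–Hochberg multiplicity count m (keeping them would inflate m
   with nulls that can never reject).
5. **FDR and selection.** Benjamini–Hochberg step-up q-values; windows
   with q < 0.001 (default) are selected and given a direction by the sign
   of `delta`. Zero-delta windows are never selected.
6. **Segmentation.** A greedy linear pass merges selected windows on the
   same chromosome with the same direction when the gap between them is at
   most `max_gap_windows` × window width (default 1, i.e. one
   non-significant window may be bridged). Opposite directions never
   merge. Regions with fewer than `min_windows` constituents are dropped
   (default 1 = keep all). This greedy pass provably equals the transitive
   closure of the pairwise mergeable relation, which is how the tests
   verify it; HMM or change-point segmentation would be a different,
   heavier design and is out of scope.
7. **Annotation.** Each feature (CpG island, promoter, exon, …) is
   labelled `higher_in_B` / `higher_in_A` / `mixed` / `unchanged` by the
   directions of regions it overlaps (≥ 1 bp, half-open). Directional
   percentages are computed **over differential features only** (label ≠
   unchanged). The per-class occupation ratio is a tag-level statistic
   computed before windowing: tags whose midpoint falls in the class's
   union-merged intervals, scaled per million library tags, condition B
   over condition A. Union-merging prevents double counting of overlapping
   annotations within a class; classes are independent summaries, so a tag
   inside both an island and a promoter counts once in each.

## The synthetic-data generator

`diffmark simulate` emulates the two-library design: tag start positions
follow a homogeneous per-bp Poisson law at `background_rate × depth_scale`,
and within a planted subset of CpG islands condition B's rate is multiplied
by `enrich_fold` (implemented by Poisson superposition, so expected counts
over any interval are exactly rate × length × fold). Tags are fixed-length
intervals (default 36 bp, a classic short-read length) clipped at
chromosome ends, with uniform random strand. Features are placed uniformly
at random, non-overlapping within a class (the sorted-spacings
construction), allocated to chromosomes proportionally to length.

Defaults: a 2 × 1 Mb genome, 100 islands of 500 bp, 50 promoters of 1 kb,
200 exons of 200 bp, background 0.01 tags/bp per library (≈ 20 k tags per
library — the genome-wide tag density of a typical early-generation
mammalian ChIP-seq library), `frac_planted` 0.5, `enrich_fold` 4, equal
depths. Everything is deterministic given `seed`; the two conditions and
the layout draw from independent seeded substreams so adding a condition
never perturbs another.

The generator does **not** model fragment-size distributions, PCR
duplicates, mappability or GC bias, or an input library. Passing recovery
tests therefore demonstrate the statistical machinery on idealized Poisson
data, not robustness to real-library artefacts.

## Power and the choice of effect sizes in the tests

At the default background of 0.01 tags/bp, a 100 bp window carries about
one tag per library. The conditional binomial's smallest attainable
two-sided p-value at window total n is 2·(1/2)ⁿ (equal depths), so a
window needs n ≥ 15 with an extreme split before p < 10⁻⁴ — far beyond
what a fold-4 enrichment over a Poisson(1) background produces. A planted
fold of 4 at this depth is therefore essentially undetectable per-window at
q < 0.001, and the suite's recovery check under those conditions documents
exactly that. The strong-enrichment integration test instead plants fold
60 — the occupation fold change actually observed at CpG islands in the
motivating comparison — at which every planted island is recovered with
no false island calls. The acceptance script uses the same fold-60
conditions. Detecting modest folds at low depth requires wider windows,
deeper libraries, or region-level aggregation, all of which are available
as parameters but are not the defaults.

## Numerical and degenerate-case choices

* p-values and q-values are exact to machine precision; no continuity
  corrections.
* BH is computed with a vectorized stable sort + right-to-left cumulative
  minimum; tied p-values share a q-value by construction.
* `select_windows` applies a strict inequality (q < threshold).
* An empty tag file for either condition aborts the run with the input
  named; an empty feature class yields an undefined (NaN) occupation ratio
  and "not applicable" directional percentages rather than zeros.
* Single-column matrices pass through normalization unchanged with a
  warning; non-finite values are rejected.
* The pipeline is single-process and deterministic: identical inputs and
  config give byte-identical outputs, and the run manifest records the
  config, package version and SHA-256 of every input.

## Known limitations

* One library per condition means the test captures only sampling noise,
  not biological variability; q-values are exact under the conditional
  null but optimistic about replication.
* Quantile normalization assumes the two samples share a global density
  distribution; a genuinely genome-wide gain of signal in one condition
  would be partly normalized away.
* Segmentation operates on significant windows only; sub-threshold
  windows inside a broad domain can split regions when
  `max_gap_windows` is small.
* The directional percentages depend on the feature catalogs supplied;
  no gene-ontology or pathway interpretation is performed.
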