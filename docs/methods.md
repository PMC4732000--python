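# Methods

## Scope and data model

The pipeline operates on four kinds of input: per-species gene annotations
(GFF3, gene features only; 1-based inclusive on disk, 0-based half-open in
memory), tabular homology hits (BLAST outfmt-6 columns; only qseqid,
sseqid, pident, evalue, bitscore are consumed), a curated seed list of
functionally characterized nodulation genes (published/legacy id, species,
name), and expression matrices (rows = genes; columns = tissue atlas plus
paired `<timepoint>_IN` / `<timepoint>_UN` root-hair samples). A gene's
point position for all windowed analyses is the integer midpoint
`floor((start + end) / 2)`; a single point per gene keeps window membership
unambiguous for genes longer than a window step.

## Seed re-anchoring (catalog)

Hits are kept iff `evalue < 1e-12` **and** `bitscore > 100`, both strict;
"score" is the bit score, the conventional reading of a BLAST score
threshold. Each seed gene is assigned the subject of its maximum-score
surviving hit, ties broken by higher percent identity, then
lexicographically smallest subject id — best-hit assignment is this
package's decision (multiple-hit resolution is otherwise underdetermined),
and the tie-break makes it deterministic. Seeds with no surviving hit are
reported `unmapped` and excluded from all downstream stages rather than
aborting the run: an unmappable seed is a data problem, not a pipeline
error.

## Syntelog detection and group assembly (synteny)

Anchors (filtered hits whose both ids resolve to gene models) are chained
per chromosome pair in **rank space** — the gene's index in
start-coordinate order — rather than bp, which makes chaining insensitive
to gene-density differences between genomes. Chaining is greedy and
single-pass: anchors sorted by rank on genome A; a chain extends while the
next anchor advances by 1..`max_rank_gap` (default 10) ranks on A, by at
most `max_rank_gap` on B, and keeps B-ranks strictly monotone in the
direction (same/inverted) locked by the chain's first two anchors. A
non-extending anchor closes the chain and starts a new one, so blocks never
share anchors. Chains with fewer than `min_anchors` (default 3) are
discarded; syntelog pairs are exactly the anchors inside surviving blocks.
The greedy chainer is deliberately simple — it is verified against an
exhaustive enumeration of maximal monotone chains on small instances — and
is not a reimplementation of any published synteny tool; defaults are
declared, not inferred from prior work.

Ortholog/paralog groups are the connected components (networkx) of the
syntelog graph that contain at least one re-anchored seed gene; seed genes
are always nodes, so an unpaired seed yields a singleton group. Components
without a seed are counted and discarded. Within-species syntelog pairs are
allowed and contribute paralogy edges, which is how WGD pairs land inside
the same group as their orthologs. `group_id` is the lexicographically
smallest member, making output invariant under permutation of the pair
list.

## Expression classification

Fold-change is `(treated + pc) / (control + pc)` with pseudocount
`pc = 1.0` abundance unit by default (guards zero denominators in atlas
data; `pc = 0` gives the raw ratio and is what the noiseless recovery tests
use). Equal treated and control give fold-change 1 for any pseudocount,
including 0/0 for silent genes at `pc = 0`.

* **Root-hair induced**: fold-change > threshold (default 2, strict) at
  *any* paired time point; single-time-point induction is biologically
  expected, and an `all` mode exists.
* **Nodule-preferential**: nodule abundance versus the *maximum* of the
  other atlas tissues — the strictest reading of "preferential compared to
  other tissues"; the mean is available as an option.
* **Pattern**: `nodulation-restricted` if either call is true; `broad` if
  neither but the gene is above the detection floor (default 1.0) in ≥ 2
  atlas tissues; `silent` otherwise. A gene expressed in exactly one tissue
  with no call is classified silent — the boundary case is noted here
  because a plausible alternative reading would treat "silent" as strictly
  all-below-floor; the ≥ 2-tissue rule for broad is kept primary.

Calls lift to groups by an any-member rule per species. Cross-species
sharing is a full Venn partition over the species list (each group counted
in exactly the subset of species where it is flagged; per-species totals
are conserved by construction). Shared-of-total percentages are rounded to
the nearest integer, half away from zero — the rounding that reproduces all
four count-derived reference percentages (11/32 → 34, 11/16 → 69, 4/18 →
22, 4/14 → 29). For the reference counts, 4 of 27 gives 15%, not the 11%
sometimes quoted alongside them; the package reproduces the count-derived
value and leaves the discrepancy as such.

## Chromosomal clustering test (density)

Window presets follow genome size: 10 Mb windows / 1 Mb step for *G. max*,
6 / 0.6 for *P. vulgaris*, 5 / 0.5 for *L. japonicus* and *M. truncatula*;
unknown species require an explicit override. Windows start at 0, step,
2·step, … up to the chromosome end; truncated terminal windows are kept
(dropping them would silently ignore chromosome ends), and per-Mb density
over the actual truncated length is reported alongside raw counts.

Z-scores standardize the **raw counts** per chromosome,
`z = (c − u)/st`, with `u` the mean and `st` the *sample* (n−1) standard
deviation of that chromosome's window counts (the population variant is a
parameter). Counts rather than per-Mb density feed the z-scores because a
single stray gene in a 1-Mb truncated terminal window would otherwise be as
extreme as a ten-gene cluster in a full window; with equal-length windows
the two are identical. Constant tracks (or < 2 windows) are flagged
degenerate, get all-zero z, and can never be called enriched.

**Null model.** Nodulation *labels* are redistributed: `n_nodulation`
positions are drawn without replacement from the chromosome's full
gene-point set, preserving the genome's gene-position landscape (a
uniform-bp null would conflate nodulation-gene clustering with plain gene
clustering). Each of `n_permutations` (default 1000) replicates is
re-counted and re-normalized exactly like the observed track.

**Test.** The observed window-z distribution is compared with the pooled
null z distribution by the two-sample KS statistic
`D = sup |ECDF_obs − ECDF_null|`. Overlapping sliding windows make
neighbouring z values strongly autocorrelated (window/step = 10 here), so
treating the ~40–80 windows as independent KS samples would be badly
anti-conservative — a chromosome carries roughly `length/window` ≈ 4
independent windows' worth of information. The reported p-value is
therefore **permutation-calibrated**: the observed D is ranked among the D
of each null replicate against the same pool,
`p = (1 + #{D_i ≥ D_obs}) / (n_permutations + 1)`, which is exact under the
null by exchangeability. The uncalibrated asymptotic KS p (effective size
`n_a·n_b/(n_a+n_b)`, Kolmogorov tail) is available as
`p_method="asymptotic"`.

A significant KS distance alone is direction-blind (depletion would also
shift the distribution), so **enriched** additionally requires the observed
maximum window *count* to exceed the 0.99 quantile of the per-replicate
maximum counts — a familywise max test. The guard works on counts, not z:
per-chromosome standardization caps a genuinely clustered chromosome's own
maximum z at `sqrt((n_windows − k)/k)` (the cluster inflates its own
standard deviation), which sits *below* the null's typical maxima — a
z-scale guard would veto exactly the signal it should confirm. On the count
scale the test is conservative where it should be: a chromosome carrying
one nodulation gene can never beat the null maximum of one.

The standalone `ks_two_sample` uses an exact lattice-path p-value
(dynamic-programming path count under the no-ties model, verified against
an independent implementation to machine precision) when
`min(n_a, n_b) ≤ 10`, the asymptotic tail otherwise. The D statistic is
computed from right- and left-limit ECDF evaluations at one sample's
points, which is exact in the presence of ties.

No multiple-testing correction is applied across chromosomes by default
(matching the analysis design this pipeline reproduces); the per-chromosome
permutation p-values are emitted, so any correction can be applied
downstream.

## Synthetic data: what it emulates, and what it does not

The generator plants every signal the pipeline is meant to recover, under a
single integer seed (three independent sub-streams for annotations,
homology and expression, so each artifact is reproducible in isolation).

Default study conditions (all configurable): four species named after the
study species so the window presets apply — a WGD carrier with 8
chromosomes (1600 genes), and 5/4/3-chromosome species with 1000/800/600
genes; 40-Mb chromosomes; gene lengths uniform in 0.6–1.4 × 3 kb, placed
non-overlapping (cluster genes by sorted-uniform packing inside the span,
the rest by rejection sampling — the simplest null consistent with the
random-redistribution comparison); 12 seed ortholog groups; 10 of 12
nodulation genes inside a 2-Mb cluster per cluster chromosome (the WGD
species carries a second, duplicated cluster on another chromosome; the
two paralogs of every group sit on distinct chromosomes); leftover
nodulation genes are deterministically spread over distinct non-cluster
chromosomes. The cluster span holds only cluster genes, so cluster gene
order and rank adjacency are identical across species and the planted
collinear blocks are unambiguous — with background genes interleaved into
the span, rank offsets can cross between genomes and a greedy chainer may
strand a true pair in a sub-minimum fragment, making "exact recovery"
ill-posed rather than merely hard.

Homology output: every true ortholog/paralog pair gets a hit passing the
strict filter, embedded in a collinear run of `genes_per_block` (default 5)
anchors whose flanks connect non-nodulation neighbours at matching rank
offsets; seed-less decoy blocks (default 2) exercise the discarding of
unanchored components; decoy hits (default 25) are drawn adjacent to the
filter thresholds — the first two sit exactly on the boundaries
(evalue = 1e-12; score = 100) — and always fail the strict filter.

Expression: planted groups cycle through three labels (induced +
preferential / induced only / preferential only); per species a group may
lose its planted effect with probability `divergence_fraction` (default
0.25), giving the cross-species overlap statistics realistic structure; a
fraction (default 0.25) of WGD duplicate copies is reassigned a flat
"broad" profile, emulating expression sub-functionalization after
duplication; 5% of background genes are silent. Before noise the planted
contrasts are exact (inoculated = 4 × mock at every time point;
nodule = 3 × other tissues); multiplicative log-normal noise with a
configured CV (default 0 — the recovery contracts are stated at zero
noise) multiplies every value, keeping abundances positive.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: nucleotide sequences and alignment artifacts,
synteny decay and small-scale rearrangements inside blocks, tandem
duplications, gene-density variation along chromosomes (background
placement is uniform), platform effects and normalization differences
between expression atlases, and dependence structure between tissues. The
pipeline's recovery being exact at zero noise is a correctness statement
about the implementation, not a power claim for real genomes.

## Numerical and reproducibility choices

* Seeds: one top-level integer; stages derive seeds as
  `SeedSequence([seed, crc32(stage_name)])`, so stage-level reruns match
  full runs and nothing depends on Python's randomized string hashing.
  All derived seeds stay below 2³¹.
* Degenerate inputs: constant or too-short density tracks are flagged and
  excluded from enrichment rather than erroring; empty hit tables, empty
  truth and seedless components are all legal and covered by tests.
* Percent rounding: half away from zero (`floor(x + 0.5)` for positive x) —
  Python's bankers' rounding would break the reference percentages.
* TSV round-trips use pandas with `float_precision="round_trip"`.
* Test problem sizes: the shared test fixture is a two-species, 40-Mb
  genome (640 + 480 genes); the acceptance checks run the four-species
  default genome with 1000 permutations per chromosome and a 100-chromosome
  null study at 200 permutations (p resolution 1/201 against alpha 0.05) —
  the full suite completes in a few seconds.

## Known limitations

* The greedy chainer can split a block at a crossing anchor instead of
  skipping it; adequate for planted-block recovery and verified against
  exhaustive search, but not a general-purpose synteny caller (no gap
  scoring, no Ks dating, no dot plots).
* Enrichment power depends on the cluster-to-window geometry; clusters
  holding fewer than ~5 genes, or windows a large fraction of the
  chromosome, leave the max-count guard without resolution (by design — it
  is then honest about having no evidence).
* The exact KS p-value assumes continuous data; with heavy ties it is an
  approximation (the permutation calibration used by the enrichment call
  does not have this problem).
* Group-level statistics exclude genes outside any ortholog group; they are
  still present in the per-gene calls table.
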