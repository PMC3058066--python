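# Methods

This note documents the statistical procedures implemented in `cnveval`,
the conventions and numerical choices behind them, what the synthetic
cohort generator does and does not emulate, and the known limitations.

## Coordinates, overlap and matching

All intervals are 0-based half-open (BED convention), in memory and on
disk. The matching primitive asks whether a query segment is re-found in a
target set: a target of compatible type matches when the overlap fraction
is **strictly greater** than the threshold θ. Two denominators are
supported:

* `query` mode (default) — overlap / length(query). The concordance and
  sensitivity tables are asymmetric (a short call inside a long reference
  counts as found), which is the convention those tables need.
* `reciprocal` mode — min over both directions, for symmetric region
  comparisons.

Gains and losses are discriminated (`type_policy="strict"`) by default;
`"collapse"` ignores the type, for reference experiments that do not
distinguish insertion from duplication. Matching is independent per query:
one target may match many queries. Overlapping same-type segments within
one (sample, program, array) are kept as-is; `merge_same_type_segments`
unions them explicitly, because merging changes counts and should never
happen silently. Sex chromosomes receive no special handling. Indexed
matching uses per-chromosome interval trees; the test suite holds it equal
to a brute-force all-pairs oracle.

## Concordance statistics

* **Stability**: mean over all *ordered* pairs (A, B) of distinct
  replicate arrays of the fraction of A's segments matched in B. Ordered
  and unordered means coincide up to labelling; ordered is used because
  the pair rates are themselves asymmetric. Pairs whose query array has no
  segments are excluded from the mean and counted.
* **Mendelian inconsistency**: per trio, the fraction of offspring
  segments matched by a same-type segment in father **or** mother
  ("not detected in both parents" is read as *detected in neither*: an
  inherited CNV comes from one parent, so a single parental match
  demonstrates consistency). Offspring with zero segments are excluded and
  counted. The conventional threshold grid is {0, 0.5, 0.8}.
* **Similarity / sensitivity / specificity**: per shared sample, fraction
  of the query program's segments matched by the other side; the report
  carries both the per-sample mean (`value`) and the pooled fraction
  (`extra["pooled"]`), and labels which averaging was used.
* **Pooled overlap ratio**: sample identity ignored, all segments pooled —
  the whole-cohort analogue used when comparing a population call set
  against an external region list. Commonality strata are produced by
  pre-filtering through the clustering selectors.
* Empty denominators are never coerced to 0 or 1; the statistic is flagged
  undefined, excluded from means, and the exclusion is counted. This
  avoids biasing rates in sparse subsets.

## Region clustering

Boundary estimates jitter by a few probes between individuals, so two
segments describe the same population variant when both boundaries agree
at array resolution: |Δ probe rank(start)| ≤ k **and** |Δ probe
rank(end)| ≤ k, with k = 20 probes by default. The probe rank of a
position is the count of probes at or before it in the supplied probe map;
the unit is probes, not bp, because probe spacing varies along the genome.
Components under single linkage become regions (single linkage is the
natural reading of "segments within k probes are the same region"); the
consensus interval is the member-wise median start/end with ties broken
toward the smaller coordinate — robust to outlier jitter, and idempotent:
re-clustering consensus intervals reproduces the partition. Gains and
losses never co-cluster. Sorted processing makes the result independent of
input order.

Commonality selectors: *Common1* re-clusters the per-program regions with
the same linkage rule and keeps merged clusters backed by ≥ 2 programs;
*Common2* keeps anchor-program regions with ≥ 5 individuals that link to at
least one region of another program. Clustering can be run per program or
on the pooled cohort; both entry points exist. Stratification "more than k
individuals" is a strict inequality.

## Breakpoint-flank characterisation

Each region contributes two windows, ±w around its start and ±w around its
end (w ∈ {500, 800, 1000} bp), clipped at chromosome ends (clips are
recorded; windows of short CNVs may overlap each other, which is allowed).
The wide windows reflect that array probes are sparse: the reported
boundary is only a probe-resolution estimate of the true breakpoint.

Repeat containment categories per CNV: segmental duplication in **both**
windows; any interspersed repeat (LINE ∪ SINE ∪ LTR) in both windows
("ALL"); `only_LINE/only_SINE/only_LTR` — interspersed repeats in both
windows *and* that class is the only interspersed class present in either
window (this is the reading under which the three "only" columns partition
a subset of ALL); and the union category (segdup ∪ interspersed in both
windows). The null is a random region set matched in lengths and count:
one uniformly placed interval per observed CNV, chromosome drawn with
probability proportional to its length, optional exclusion rejection,
deterministic given a seed.

Score tracks are stepwise (bedGraph semantics); the window statistic is
the length-weighted mean over covered bases, uncovered bases excluded and
coverage reported. Start and end windows are summarised separately, as
mean-of-per-CNV-means.

CpG-island counting uses a permutation test because no parametric form is
assumed: observed = number of features intersecting any CNV window; null =
the same count on length-matched random draws; two-sided
p = (1 + #{null at least as extreme}) / (n_perm + 1), extremeness measured
as absolute deviation from the null mean. The reported direction is the
sign of the observed deviation. Under a null generator the p-values are
super-uniform (verified in the suite).

Microhomology: distinct k-mers shared by the two flank sequences
(uppercased; k-mers containing N excluded), with positions. The relevant
null space is the 4ᵏ k-mer universe (1024 at k = 5) — with kilobase
windows, shared pentamers are expected by chance, which is why flank k-mer
sharing alone is not evidence of a microhomology mechanism at array
resolution.

## Array QC

Quantile normalisation replaces each array's sorted intensities by the
across-array mean at each rank; ties receive the mean over their rank
range (implemented as linear interpolation of the reference distribution
at average ranks), which preserves rank order and makes the operation
idempotent. Log2 ratios are taken against a reference profile (typically a
panel mean); the per-array noise metric is the sample SD (n−1) of those
ratios. Cohort filtering removes a sample when its CNV count strictly
exceeds the per-program ceiling for any program; the default ceilings are
the conventional 250 (PennCNV), 400 (Birdseye), 500 (Canary), 100
(DNAcopy), 100 (CGHseg). Call rate is an externally supplied covariate —
genotype calling is out of scope.

## Synthetic cohort generator

The generator is the package's test bed: it produces every input format
with known parameters so each statistic can be checked by recovery.

Default world (chosen as a desk-scale caricature of a SNP-array cohort
study; all tunable in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| genome | 3 chromosomes × 20 Mb | large enough for ~100s of disjoint regions |
| probe spacing | 2 kb mean (uniform jitter) | sparse-array regime; probe rank ≠ bp |
| true regions | 120, log-normal lengths, median 50 kb, σ = 0.6 | array-detectable CNV length scale |
| gain fraction | 0.4 | losses slightly preponderant |
| population frequency | Uniform(0.02, 0.30) | polymorphic regions, as in a control cohort |
| cohort | 20 unrelated + 8 trios; 5 samples × 5 replicate arrays | mirrors the replicate-set and trio design of array evaluations |
| de novo rate | 0 per offspring | germline CNV mutation rates (~1e-6–1e-4/gamete) are negligible at this size |
| programs | three observers with detection p = 0.9/0.9/0.8, jitter SD 2/2/4 probes, false rate 2–3 per array | spread between HMM-like and segmentation-like callers |
| repeat classes | segdup/LINE/SINE/LTR/simple repeat backgrounds; breakpoint placement probability 0.33/0.20/0.03/0.05/0 | reproduces the observed ordering: strong segdup and LINE breakpoint association, weak SINE/LTR |
| conservation track | steps of 1 kb, N(70, 8) clipped to [0,100], −20 inside breakpoint flanks | CNV flanks less conserved than random |
| recombination track | steps of 50 kb, N(1.17, 0.4) | no breakpoint association (null track) |
| CpG features | density 2e-5/bp, length 500 bp, keep-probability 0.5 inside breakpoint flanks | mild depletion near breakpoints |
| array noise | per-array log2-ratio SD ~ U(0.08, 0.12); false-call rate × (SD/mid)² | ties the QC metric to CNV-count inflation |

Mechanics worth knowing:

* True regions are placed on probe indices, disjoint with a ≥ 60-probe
  gap, so clustering has unambiguous truth. Calls snap to probe positions;
  boundary jitter is a rounded Gaussian offset in probe *ranks*, so the
  20-probe clustering rule is exercised on its own scale.
* Each annotation class draws one Bernoulli(q_b) per true region; on
  success an element is placed in **both** breakpoint flanks (within
  ±200 bp of the breakpoint). The both-window containment of the CNV set
  therefore estimates q_b + (1 − q_b)·p², where p is the background
  per-window hit probability 1 − exp(−density·(2w + element length)).
* False calls are rejected away from true regions so recovery expectations
  stay clean; carriers, transmission and detection are all seeded from one
  `SeedSequence` — identical seeds give byte-identical fixtures.

What the generator does **not** emulate: LRR/BAF signal structure, probe-
level intensity waves, genotype clusters, segmental biases of real
callers, overlapping/nested true CNVs, population structure, or sex
chromosomes' copy-number baseline. Passing recovery tests therefore shows
the statistics are implemented correctly, not that any particular real
caller achieves these rates.

## Pipeline and problem sizes

`run_pipeline` chains simulate → QC (count filter applied by default) →
evaluation tables → per-program clustering and Common1/Common2 → pooled
overlap strata → flank enrichment/score summaries → CpG permutation, and
renders each table as machine TSV plus fixed-width text with percentages
to one decimal. Reports embed the seed, a config hash and the tool
version, and no timestamps, so reruns are byte-identical. In the simulated
setting the ground-truth regions serve as the reference standard for the
sensitivity and pooled-overlap tables.

The suite and the acceptance script run on worlds of 50–300 regions and
cohorts of ≤ 60 samples with permutation counts of 100–1000; these sizes
give binomial standard errors comfortably inside the tested tolerances
while keeping a full run in seconds. The statistics themselves are
indexed (interval trees, sorted-array sweeps) and scale to cohort sizes
far beyond the defaults.

## Known limitations

* The overlap denominator of the published "> 80%" concordance rule is not
  standardised across studies; both readings are first-class here
  (`mode="query"` default, `mode="reciprocal"` available) and results
  should state which was used.
* Region consensus coordinates are member medians; other conventions
  (union, intersection) would shift flank windows by up to the jitter
  scale.
* The permutation p-value is exchangeable-null and slightly conservative
  (it uses the null-sample mean as the centre of extremeness).
* `Common2`'s anchor-program default ("PennCNV-like") matches the
  generator's program naming; real call sets must name their own anchor.
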