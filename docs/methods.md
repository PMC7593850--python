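# Methods

## Problem and scope

`picomethyl` reimplements the downstream portion of a whole-genome bisulfite
sequencing (WGBS) analysis of the green alga *Picochlorum soloecismus*, a
haploid biofuel candidate species whose genome carries sparse but dynamic
5-methylcytosine (5mC): roughly 12% methylation at CpG sites and well under
1% at CHG/CHH sites, with global CpG hypomethylation under nitrogen
starvation and site-specific responses to the DNA-methyltransferase
inhibitor 5-aza-2′-deoxycytidine (5AZA). The pipeline starts from
per-cytosine bisulfite counts (MethylDackel-style bedGraphs); read
alignment, methylation extraction, methyltransferase gene mining, phenotype
assays and KEGG orthology computation are out of scope. An externally
computed gene→KO table can be joined, but never produced, here.

## Site catalog and context classification

Every cytosine on both strands is enumerated from the genome FASTA. A
site's context is read 5′→3′ on its own strand: the next base G gives CpG;
C‑H‑G gives CHG; C‑H‑H gives CHH, with H ∈ {A, T, C}. Reverse-strand
cytosines are forward-strand Gs whose downstream window lies at decreasing
coordinates, complemented. CpG needs one downstream base; CHG/CHH need two.
A cytosine whose needed bases run off the contig end or touch an N is
classified `ambiguous`: it stays in the catalog but is excluded from
per-context totals and from calling, and the exclusion count is logged. N
never matches H. Coordinates are 0-based half-open internally; GFF3 I/O
converts to 1-based inclusive, bedGraph I/O stays 0-based.

On the published assembly the catalog comprises 1,014,486 CpG + 1,316,811
CHG + 4,430,371 CHH sites over 15.2 Mb — about 44% of the genome. The
genome length used for percent summaries defaults to the FASTA total; a
config override exists because the source reports both 15.6 Mb and 15.2 Mb
for the assembly, and 15,200,000 is used for replication summaries.

## Calling and validation

The methylation ratio of a site is n_meth / (n_meth + n_unmeth) — reads
reporting C over reads reporting C or T. Ratios are always recomputed from
counts; the bedGraph percent column is advisory (disagreements > 0.5
percentage points are logged, counts win). A call is *validated* when its
coverage is ≥ 20 (configurable; the boundary is kept, coverage = 20 is
retained) and its position exists in the catalog, from which it inherits
strand and context; context reassignments and all drops are tallied by
reason.

The per-sample, per-context **methylation fraction** is the unweighted mean
of validated site ratios. The read-weighted pooled ratio
Σn_meth/Σcoverage is available as an option; the unweighted mean is the
default because the published per-sample table reads as a site-level mean.
Percent summaries that replicate printed values round half-up to one
decimal; internal values keep full precision. The **genome-wide percent**
weights each context's mean fraction by the catalog's context total:
100 × Σ_c (mean_c × total_c) / genome length.

Ratio histograms use 0.1-wide bins with the final bin closed at 1.0;
ratios below 0.05 are dropped first, since the mass of fully unmethylated
cytosines would otherwise dominate every panel. The bimodality summary
reports strict fractions below 0.2 and above 0.8 and the inclusive
[0.4, 0.6] band.

## Genomic features and density

Gene bodies are the annotated gene spans (introns included). Promoters and
terminators are fixed 500 bp flanks 5′ and 3′ of the gene (strand-aware),
truncated at contig edges; zero-length truncations are dropped and logged.
Flanks are placed purely by distance and may overlap neighboring gene
bodies — no truncation at neighbors. The intergenic region (IGR) is the
per-contig complement of the union of the other three classes, so the four
classes tile every base (overlaps allowed, gaps impossible by
construction). A site inside overlapping features counts once per
containing feature, and site strand is ignored for assignment. Per-feature
density is 1000 × count/length (sites per kb); class-level mean ± SD is
reported with zero-count features excluded by default (the inclusive
variant is computable). The published absolute CpG densities
(4.95/5.83/6.39/5.86 sites/kb for gene bodies/promoters/terminators/IGR)
depend on the real assembly and are documented expected outputs of a
full-data run, not desk-reproducible test targets.

## Differential methylation

Each site covered ≥ 20X in **every** sample of a comparison is tested with
the classical equal-variance two-sample Student's t on the replicate
ratios (df = nA + nB − 2, two-sided p). Retained sites satisfy
p ≤ threshold **and** |Δ| ≥ 0.1 with Δ = mean(B) − mean(A); both boundaries
inclusive, matching a literal reading of "changes less than 0.1 and greater
than −0.1 were not considered". Direction is hypo for Δ < 0. The
time-course comparison is Day 4 vs Day 10 controls at p < 0.01; drug
comparisons are control vs 5AZA per day at p < 0.05, with per-day
direction counts and percents normalized to that day's retained total.
Persistence partitions one day's retained sites by their fate in a later
day: persistent (same direction), reversed, or resolved (absent).

Numerical conventions: replicate ratios that are constant in both groups
give p = 1 when equal and p = 0 (flagged `degenerate`) when unequal —
ratio data saturate at 0/1, and this keeps the behavior deterministic
without epsilon inflation. Constancy is detected by max = min, not
variance = 0, which round-off can miss. No multiple-testing correction is
applied by default (matching the raw-p design); Benjamini–Hochberg q
values are available behind a flag. The filter order
coverage → test → effect does not change the retained set, since the
filters are conjunctive.

## Annotation

Differential sites map to every containing feature (multi-row output; no
priority rule, because none is documented for the original figures).
KO joins keep, per gene, the assignment with the smallest E-value at or
below 1e-24, ties broken by lexicographic KO id for determinism. Augmented
GFF3 export writes each site as a 1-bp `methylation_site` record with the
ratio in the score column and context/Δ/p/direction in the attributes, one
file per timepoint × condition, round-trippable by a strict reader.

## Synthetic data generator

The simulator is first-class, tested code and defines the study conditions
for every statistical check.

**Genome.** i.i.d. bases at GC 0.44 over two contigs totalling 100 kb by
default — a deliberate ~150× scale-down of the 15.2 Mb assembly so the
full design runs in minutes on one CPU; the catalog still holds ~9,500 CpG
sites, enough for distributional checks. Forty non-overlapping genes of
0.6–2 kb with ≥ 200 bp spacing approximate the real gene density (roughly
one gene per 2.5 kb).

**Methylome.** Per context, site truths are drawn from a three-component
Beta mixture (low/mid/high). CpG defaults: weights (0.83, 0.10, 0.07) with
the high component Beta(45, 5) centered at 0.9, the mid component
Beta(5, 5), and the low component's Beta(0.3, b) solved so the mixture mean
is exactly 0.121 — reproducing the observed bimodality (~83% of sites
< 0.2, ~7% > 0.8). CHG/CHH use almost-all-low mixtures with thin high
tails and means 0.008/0.009 (few methylated sites, heavily methylated
where present).

**Effects.** Planted deltas compose additively and clip to [0, 1] (clips
logged). Defaults mirror the study's qualitative findings: (1) gradual
starvation hypomethylation in *both* arms — 150 heavily methylated CpG
sites (truth 0.5–0.95) ramp linearly from day 4 to a day-10 delta drawn
from U[−0.36, −0.10], the published effect-size range; (2) drug-specific
early hypomethylation, 100 sites on days 4–6; (3) drug-specific late
hypermethylation, 150 low/moderate sites on days 7–10, emulating the
drug's loss of efficacy once division stops. Site counts are the published
headline counts rescaled to the 100 kb genome, sized so recall and
precision have usable denominators.

**Observation model.** Coverage is Poisson(50) per site (the published
median coverage ≈ 50; a negative-binomial option adds overdispersion), and
n_meth ~ Binomial(coverage, p_obs) with p_obs = p_true + (1 − p_true)·ε,
ε = 0.005 by default — binomial thinning with bisulfite non-conversion
only. No over-conversion of methylated C, no sequencing-error term, no
spatial autocorrelation of truths, no PCR or M-bias artifacts: passing
tests therefore demonstrate correctness of the counting, filtering and
testing logic under the assumed site-wise model, not robustness to real
alignment artifacts. One visible consequence: observed CHG/CHH sample
means (~1.4%) sit above the truth means (0.8/0.9%) by roughly ε, exactly
as the observation model predicts.

Determinism: every stage derives its generator from the master seed with
fixed stream keys (genome/truth/effects, and per-sample keys from day,
treatment and replicate), so a (config, seed) pair yields a byte-identical
file tree.

## Calibration and power checks

The headline differential counts of the original study (e.g. 1102 hypo /
41 hyper across the time course) require the deposited reads and assembly,
so the pipeline is accepted on properties instead: exact agreement of the
filter chain with an independent brute-force implementation on experiments
under 5,000 sites; a pure-null Gaussian simulation whose rejection count
at p < 0.01 must fall inside the exact binomial 99% interval over 10,000
sites; and recall of planted hypomethylation (400 sites per cell) that is
non-decreasing across coverage {20, 50, 100}X and |Δ| {0.1, 0.2, 0.3}. At
20X mean coverage the every-sample ≥ 20X eligibility rule removes most
sites — recall near zero there is the honest consequence of the published
filter, not a defect.

## Known limitations

- Site-wise independence everywhere: no DMR aggregation, no smoothing, no
  beta-binomial dispersion modeling.
- The t-test treats the 3 replicate ratios as the unit of analysis
  (read-level counts are not modeled), which is the reading most
  consistent with the source description.
- The printed per-sample table carries sequencing metrics (read pairs,
  mapping efficiency, unique CpGs, coverage) that are never recomputed.
- One unresolved inconsistency in the source is preserved as-is: 699,653
  vs 944,940 called CpG sites quoted for the same sample in different
  places; both appear in fixtures and no reconciliation is attempted.
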