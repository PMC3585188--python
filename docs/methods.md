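# Methods

This note records the statistical conventions, numerical choices and known
limitations behind each stage of the pipeline.

## Haplotype definition and sequence variability

Haplotype identity is strict string equality after upper-casing: a sequence
containing `N` or another ambiguity code is a distinct haplotype from any
resolved sequence. The published software chain this pipeline mirrors gives
no policy for ambiguity codes; strict equality is the only choice that is
reproducible without call-quality information. Haplotypes are numbered
`H1, H2, …` in first-appearance order, walking populations in popmap order —
the numbering of any particular published dataset is not reconstructible from
sequences alone, so published tables are matched by incidence structure, not
by label.

Site tallies exclude alignment columns containing a gap in any sequence
(the target data class has no indels) and drop ambiguous characters per site.
A site is polymorphic when ≥2 distinct bases are observed and
parsimony-informative when ≥2 bases each occur in ≥2 sequences. Transition /
transversion class counts (C–T, A–G, transversion pairs) are tallied for
two-state sites only; a triallelic site has no unique class and is counted
as polymorphic but unclassed.

Numt screening flags any sequence whose conceptual translation (invertebrate
mitochondrial code, NCBI table 5, user-chosen frame) contains an internal
stop codon, and any sequence containing an alignment gap. It is a screen,
not a proof: a numt without stops in the sequenced fragment passes.

## Distances, diversity, Φst

K2P distances use only sites that are unambiguous and ungapped in both
members of a pair; the population-level distance is the mean over all
between-population pairs and its SE is the standard deviation of that mean
over bootstrap replicates that resample alignment columns with replacement
(1,000 replicates by default). Saturated pairs (log argument ≤ 0) raise an
error rather than returning a truncated value.

Nei's between-population mean pairwise differences are reported raw
(uncorrected) by default, matching the "between populations" convention of
the tables this pipeline mirrors; net divergence d_xy − (K_x+K_y)/2 is an
option. Permutation p-values everywhere use the (count+1)/(replicates+1)
estimator, which cannot return zero.

Pairwise Fst is the distance-based Φst of a two-population AMOVA. The number
of differing sites between two sequences is used directly as the squared
inter-individual distance δ² (the Excoffier/Arlequin convention for
haplotypic sequence data). A haplotype-identity mode (δ² ∈ {0,1}) gives the
frequency-only statistic. Negative estimates are reported as computed;
the all-identical case raises an undefined-statistic error. Gene flow uses
the haploid transform N_m = (1−Fst)/(2Fst), infinite at Fst ≤ 0 (serialised
as `inf`), appropriate for mitochondrial data.

## Hierarchical AMOVA

The three-level partition follows the nested expectation equations of
Excoffier, Smouse & Quattro (1992): SSD terms are block sums of δ² divided by
twice the block size; Vc = SSD(within-pop)/(N−P); Vb and Va come from the
standard n′, n″, n‴ coefficients for unbalanced designs. Negative components
are not truncated, and percentages are computed on the signed components
(they always sum to 100). When every population is its own group the
among-populations-within-groups level is empty (df 0, Vb = 0) and F_CT
collapses to the pairwise Φst.

Permutation layers: F_CT permutes whole populations among groups, F_SC
permutes individuals among populations within their group, F_ST permutes
individuals among all populations. F_CT permutations operate on the 14×14
population-pair sum matrix and are therefore effectively free; the
individual-level layers recompute that matrix per replicate through an
indicator-matrix product.

An optional K2P (plain or gamma-corrected, Jin & Nei 1990) distance mode is
provided for rate-variable data; the gamma shape is a user parameter because
estimating it is out of scope here. Covariate-based groupings bin populations
with the left-open convention (t_{i−1}, t_i], lowest bin closed at the
minimum, so each boundary value is assigned exactly once. The grouping search
ranks candidates by descending F_CT, then ascending p_CT, then input order;
all candidates share one permutation seed so their p-values are comparable
and exact duplicates tie deterministically.

## Median-joining network

The network starts from the minimum spanning network at tolerance ε (a pair
is linked iff its distance is within ε of its Kruskal joining level; ε = 0 by
default, matching common practice). Iteratively, for every triplet forming a
connected subgraph of the current feasible network, the per-site majority
consensus is a candidate median vector; per round all novel medians with
connection cost within ε of the round minimum are added, until closure
(three-way site ties take the first parent in sorted node order, and a
64-round cap guards termination). Cleanup removes, iteratively, median nodes
of degree ≤ 2 whose deletion leaves every observed-to-observed shortest-path
length unchanged. Character weights are uniform. Node sizes are individual
counts when the haplotype table carries counts, otherwise incidence counts;
median nodes have size 0. Outgroup rooting is exposed as nearest-observed-
node attachment of a supplied outgroup sequence — where the outgroup is
equidistant from several nodes the attachment is not a stable inference.

## Ordination

Nonmetric MDS minimises stress by SMACOF with isotonic (weak-monotone)
regression on the dissimilarity ranks, starting from the classical Torgerson
configuration plus random restarts (4 by default; best configuration kept;
all restarts seeded). Reported diagnostics are Kruskal stress-1
√(Σ(d̂−disparity)²/Σd̂²) and RSQ, the squared Pearson correlation between
disparities and configuration distances. SPSS ALSCAL — the tool behind the
published (stress, RSQ) pair this mirrors — minimises S-stress instead, so
those published diagnostics are plausibility references, not reproduction
targets. Stress-1 is invariant to scaling, rotation and reflection of the
input/solution; two points embed exactly with stress 0. The cluster readout
is complete-linkage on the embedded Euclidean distances — a reading aid, not
a claim of equivalence to any particular clustering used elsewhere.

## Rank correlations

Kendall's τ-b with tie correction and Spearman's ρ on mid-ranks, both
two-tailed, via scipy (exact Kendall enumeration for small untied samples,
tie-adjusted normal approximation otherwise; Spearman p by the t
approximation with n−2 df). These conventions reproduce the published
R_shr correlation row from the embedded summary tables to the printed
precision for the port, infestation and freight-turnover columns. The
published GDP column (τ = 0.384, ρ = 0.523) is *not* reproducible from the
published GDP values themselves (they give 0.408/0.545); the package reports
what the inputs give. Constant vectors raise an undefined-statistic error.

## Synthetic data generator

The generator emulates the survey design: 14 demes × 10 haploid individuals,
1,200 bp at A+T fraction 0.732, substitution classes C–T : A–G : A–T
weighted 40 : 20 : 5. Genealogies are per-deme Kingman coalescents (msprime,
haploid, one tree per deme) hanging off a small shared ancestral pool;
mutations are Poisson on branches and toggle a site within its class pair,
so segregating sites reproduce the configured class mix. Defaults, chosen
once for realism against the survey's summary statistics: θ = 3 expected
within-deme pairwise differences (the survey's K range), founder-lineage
divergence stem_θ = 1, pool divergence 1.5 across 8 pool haplotypes.

Human-mediated transport is a per-individual replacement of the haplotype by
a verbatim copy from a donor deme. Both sides of the exchange are coupled to
the covariate: donors are drawn proportionally to their coupling covariate
(freight turnover by default), and a deme at covariate rank u ∈ [0,1]
imports each individual with probability m^(1+k(1−u)), k = 3 by default.
Every deme's import probability is 0 at m = 0 and 1 at m = 1; in between,
high-activity demes engage in exchange first, reflecting that trade volume
drives both import and export. A uniform import probability was considered
and rejected: it floods low-covariate demes with covariate-blind sharing, so
the recoverable association between R_shr and the covariate saturates and
then degrades as m grows, which contradicts the dose–response behaviour the
knob exists to create. Verbatim copying (no further mutation) models recent
transport producing identical haplotypes in distant demes.

Covariates are synthetic: log-normal freight turnover and GDP (correlated),
binary port/infestation flags tied to the covariate ranks with 20% noise.
The generator has no recombination, selection, spatial kernels or
epidemiology; passing tests demonstrate that the statistics recover planted
structure of this simple kind, not that they would resolve demographic
subtleties in real data. Per-population haplotype frequencies behind the
published incidence table were never published, so the fixture supports
incidence-based indices (R_shr, shared/private counts) but not K, π, D_hap
or Fst reproduction — and the tests do not pretend otherwise.

All randomness flows from explicit seeds (numpy SeedSequence derivation;
transport uses a dedicated substream with constant per-individual
consumption, so the imported set at a smaller m is a subset of the set at a
larger m for the same seed — which also makes dose–response experiments
efficient via common random numbers).

## Problem sizes used by the test-suite experiments

Oracle equivalence checks run 100+ random two-population toys (3–6
individuals, ≤20 sites). The AMOVA null-calibration experiment uses 200
replicates of 14 demes × 6 individuals × 400 bp with 99 permutations each;
the transport dose–response experiment uses the full survey shape
(14 × 10 × 1,200 bp) at m ∈ {0, 0.1, 0.25, 0.5} with 50 common seeds per
level. These sizes are the package's chosen experiment designs; the
underlying properties are size-independent.

## Known limitations

- AMOVA significance and variance components from any particular published
  dataset require the individual-level sequences and the gamma shape used,
  neither of which is published for the motivating survey; the pipeline
  checks structural properties (df bookkeeping, percentage closure, null
  calibration, oracle equivalence) instead of chasing those table values.
- The median-joining cleanup rule (shortest-path-preserving deletion of
  low-degree medians) is one reasonable reading of "delete obsolete median
  vectors"; different network software disagrees on borderline medians.
- The NMDS stress surface is multimodal; with few restarts a slightly
  suboptimal embedding is possible. Restarts and seeds are exposed.
- K2P saturation is raised, not imputed; extremely divergent inputs are the
  caller's problem to model with a better distance.
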