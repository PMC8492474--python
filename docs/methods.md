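# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices a maintainer would need to know.

## The generative model

A person carries one germline proofreading genotype. Each clonal epithelial
unit (intestinal crypt, endometrial gland) descends from a recent ancestral
stem cell; sequencing the unit at ~30× reads out that ancestor's mutation
set at VAF ≈ 0.5 (heterozygous, clonal). Somatic burden accumulates
linearly with age at a genotype-dependent per-year rate:

| genotype | SBS/yr | ID/yr | signature mixture (defaults) |
|---|---|---|---|
| POLE L424V | 331 | 13 | SBS10a .45, SBS10b .35, SBS28 .05, SBS1 .05, SBS5 .10 |
| POLD1 S478N | 152 | 44 | SBS10c .62, SBS1 .12, SBS5 .26 |
| POLD1 L474P / D316N | 58 | 12 | SBS10c .20, SBS1 .25, SBS5 .55 |
| wild type | 49 | 1 | SBS1 .35, SBS5 .65 |

Endometrial glands use 148 (POLE L424V) vs 29 (wild type) SBS/yr. The
polymerase mixtures put the excess over the wild-type clock on the
polymerase signatures and keep the SBS1/SBS5 clock share near the absolute
wild-type rate; the exact split within the polymerase group is a modelling
choice. Indel channel mixtures are dominated by 1-bp T insertions at T
homopolymers (ID1-like) in carriers.

Between-patient rate heterogeneity is a lognormal multiplier with 10%
coefficient of variation where it is applied. It is applied to the POLE
L424V cohort, where between-individual rate differences are an observed
feature; carriers of the same POLD1 mutation, and healthy individuals,
accumulate at similar rates and are simulated with Poisson noise only.
This matters quantitatively: with a 4-patient cohort, a 10% multiplicative
rate CV alone moves the fitted slope by ~17% RMS, because slope
heterogeneity is amplified by age leverage in a random-intercept fit.

**Phylogeny.** Crypt lineages within a person separate during early
development, so the trunk (conception → MRCA of the sampled crypts) is
short: the MRCA time is drawn uniformly below `split_age_max` (default 0.5
years; configurable up to 10). Internal splits follow shortly after
(exponential spacing, mean 0.5 years); the remaining lifetime accrues on
the terminal branches. Mutation counts per branch are Poisson(rate ×
branch duration); each mutation's generating signature is drawn from the
mixture weights exactly, and its channel within the signature is reweighted
by the reference's trinucleotide availability, then placed uniformly at a
site with that context (drawing the signature first keeps label
proportions equal to the configured weights, which availability reweighting
of the pooled spectrum would distort).

**Reads.** Depth is Poisson(coverage) per site and sample (negative
binomial optional via `depth_dispersion`); variant reads are
Binomial(depth, 0.5 × cell fraction) in carriers. Sequencing-error false
positives are injected as context-independent sites at 10⁻⁶/bp with 1–2
supporting reads. Clean calls carry alignment score ≥ 140 and clipped
median 0; germline SNPs are flagged by the panel-of-normals with 95%
sensitivity (the residue is what the binomial test must catch).

**Embryonic mutations.** A mutation arising at division k is carried by a
2⁻ᵏ cell fraction. We parameterise bulk-blood VAF directly as 2⁻ᵏ per
division (division 1 → 0.5, division 2 → 0.25), absorbing the
heterozygosity factor into the division index; each crypt carries the
mutation independently with probability equal to the cell fraction, and is
clonal for it when it does. Maternal inheritance exposes the zygote to the
defective polymerase from division 1 (the protein is present in the ovum
cytoplasm); paternal inheritance applies clock-only signatures until
zygotic genome activation (`zga_divisions`, default 3). Per-division counts
default to 3 clock SBS, 12 polymerase-active SBS and 2.5 T-insertions per
cell per division — chosen so carriers show tens of called embryonic
mutations, the scale seen in bulk-blood calls.

**Duplex counts.** Interrogated trinucleotide totals are multinomial over
genome composition × a 32-vector bias profile (restriction-digest bias);
substitution counts are Poisson with per-channel per-base rates.

**Reference genomes.** Random sequence at 40% GC with single-CDS,
non-overlapping genes. CDS intervals are overwritten with stop-free codons
so nonsense classes are well defined, using per-gene lognormal codon-usage
weights (σ = 0.8) — this gives genes heterogeneous trinucleotide
composition, which is what makes a uniform-rate dN/dS expectation visibly
wrong under a polymerase spectrum. Replication-strand annotation alternates
leading/lagging in fixed 50-kb segments. Coordinates are 0-based half-open
internally, 1-based in VCF.

What the generator does **not** emulate: alignment artifacts beyond flag
fields (cruciform structures, overlapping read pairs are pass-through QC
booleans), copy-number and structural variation, real human genome
composition (CpG depletion, isochores), extended (penta-nucleotide)
context effects, and mutation-rate covariates such as replication timing
or chromatin. Passing tests therefore demonstrate the statistics are
implemented correctly and recover known parameters under the stated model,
not that thresholds tuned for real low-input libraries are optimal.

## Filtering

The exact binomial germline test uses the lower tail of
Binomial(NR, 0.5) on counts aggregated over all samples of a patient
(~340× at ten crypts): heterozygous germline variants sit at VAF 0.5,
somatic mutations confined to a subset of crypts fall far below.
Sidedness and α are not externally fixed; we use the lower tail with
α = 10⁻⁵ (a Bonferroni-scale default, configurable). The exact tail
p-value of a discrete statistic is super-uniform under the null
(conservative); a `mid_p` option (tail minus half the point mass) is
provided and is the calibrated, approximately Uniform(0,1) version —
classification uses the exact tail.

The beta-binomial filter fixes the mean at the pooled VAF and maximises
the likelihood over the overdispersion ρ on log₁₀ρ ∈ [−6, −0.05] (grid
scan + bounded golden-section refinement). Germline variants have
consistent per-crypt VAFs (ρ at the lower bound); genuine somatic
mutations present in some crypts and absent in others are strongly
overdispersed; ρ > 0.1 ⇒ genuine. Degenerate inputs (all-zero or all-ref
counts) pin ρ at the lower bound.

A known limitation follows from the aggregate test: a somatic mutation
carried by *every* sampled crypt at VAF 0.5 is indistinguishable from a
germline heterozygote. This is why the short developmental trunk matters;
with a multi-year trunk the filter would necessarily discard truncal
somatic mutations.

## Phylogeny

Characters are binary and irreversible (a somatic mutation arises once and
is never lost), so the parsimony cost of a character on a rooted tree is
the number of maximal clades whose leaves all carry it. Exhaustive
enumeration of rooted topologies is used up to 7 leaves (10,395 trees);
beyond that, NNI hill-climbing from an average-linkage start with 10 random
restarts. Bootstrap support is the percentage of column resamples whose
re-search recovers each clade.

Branch assignment maximises a per-mutation binomial likelihood: leaves
below the candidate branch expect VAF 0.5 × purity (purity default 1),
other leaves the error VAF ε = 0.01. Ties break toward the most terminal
branch, which avoids inflating truncal counts. The likelihood is a
declared reconstruction, validated by recovery (≥ 99.9% of mutations map
to their generating branch on clean simulations).

## Signatures

Catalogs use the standard 96-channel pyrimidine-centred convention
(substitution-major ordering, flanks lexicographic); indels use a reduced
24-channel scheme (1-bp ins/del × T/other × homopolymer run length 1–5+,
plus multi-bp and unclassified aggregates) because the headline indel
phenomenon is the single ID1-type channel.

De novo extraction is KL-NMF (multiplicative updates) with restarts;
restart components are pooled, clustered by cosine distance, and k is
chosen at the reconstruction-error elbow gated by restart stability: an
extra component must cut the median KL residual by ≥ 15% (absorbing pure
multinomial noise gains ~8%) and cluster consistently (silhouette ≥ 0.3).
Extraction input drops units under 100 SBS and subsamples units above
2,500 (seeded, without replacement); refitting uses full counts.

Constrained refitting minimises generalized KL divergence with fixed
signature profiles by multiplicative updates on the exposures only;
signatures outside a unit's whitelist are exactly zero. Whitelists
implement the per-patient restriction (only signatures found in that
patient are refitted; the SBS10d-type restriction to specific units is a
config input).

The shipped signature profiles are **synthetic stand-ins** constructed in
`refsigs.py` — peaked at the channels by which each process is recognised
(e.g. SBS10c: C>A at ACC/CCA/CCT/TCA/TCT) with a uniform floor. All
recovery claims are relative to these planted profiles.

Replication strand bias counts each mutation on the template strand of its
pyrimidine-centred representation within leading/lagging annotation
intervals, with per-channel exact binomial tests; inverting the annotation
negates every log₂ ratio exactly.

## Rates and mutational age

The per-genotype rate is the fixed age slope of `burden ~ age` with a
patient random intercept, fitted by REML (random slope available via
config). A free intercept is fitted: burden at age 0 is the embryonic
count, not zero. Numerics: the response is standardised before fitting
(burdens reach 10⁴ while variance parameters are optimised near unit
scale) and the best finite-likelihood fit across lbfgs/bfgs/powell is
kept — the lbfgs path can diverge (infinite REML objective with a spurious
slope) when the between-patient variance estimate hits the zero boundary.
The 95% CI is Wald with a t quantile at df = patients − 2; with 7-patient
cohorts the normal quantile undercovers (~86% empirical vs 95% nominal).
Single-patient data fall back to OLS with a warning.

Mutational age = chronological age × rate(carrier)/rate(wild type),
computed per mutation class and per region (genome-wide or coding). The
genome-vs-coding polymerase-signature contrast is a two-sided Wilcoxon
signed-rank on paired per-unit fractions, exact for small n.

## Duplex burden correction

f_i = t_i/Σt per trinucleotide (32 pyrimidine-centred contexts), computed
separately for the genome and the experiment; r_i = f_i^g/f_i^e;
s′_ij = s_ij·r_i; β′ = Σs′/Σt. The β′ denominator uses the
experimentally interrogated totals t^e: the substitution counts arise from
those bases and r_i reprojects composition only, making β′ exactly
invariant to library size (both numerator and denominator scale together).
The choice is switchable in the data structure (both totals are kept).
Contexts never interrogated get r = 0 with a warning; interrogated counts
at such a context are contradictory and raise. The correction is
identifiable only when per-context rates vary: under a per-site-uniform
rate both raw and corrected burdens equal the true rate in expectation,
and the recovery analysis therefore uses context-concentrated rate
profiles; at the assay's interrogated-base scale (10⁸–10⁹), the corrected
burden recovers the genome-mean rate to ~1–2% while the raw burden errs by
tens of percent under 2–4× digestion bias.

## Embryonic calling

SBS are retained at VAF ≥ 0.15, indels at VAF ≥ 0.10 (inclusive bounds;
the laxer indel calling warrants the lower threshold). Signature
attribution fits exactly {SBS1, SBS5, SBS10a, SBS10b, SBS28} and reports
polymerase (10a+10b+28) vs clock (1+5) counts, flagged unreliable below
10 SBS. T-insertion counting requires a 1-bp T insertion whose anchor or
following reference base is T. The inheritance test is a two-sided
Mann–Whitney on polymerase-attributed counts, exact when both groups are
small and untied.

## Selection

Expected counts per gene and impact class come from exhaustive enumeration:
every possible substitution at every CDS position is weighted by
spectrum[channel]/genome-count[context] — the per-site rate implied by a
genome-wide 96-channel spectrum — and classified by the standard codon
table (stop-gain ⇒ nonsense, stop-loss ⇒ missense, frameshift indels ⇒
nonsense for testing; splice = ±2 bp of a CDS boundary). Trinucleotide
context is the default (pentanucleotide is out of scope). The synonymous
class calibrates the neutral rate scale; each protein-altering class is
tested per gene against a negative binomial whose dispersion is shared
across genes within the class (estimated by an intercept-only NB
regression with log-expected offset; Poisson fallback under 20 genes or
when no overdispersion is found). Per-gene class p-values (NB upper tails)
are combined with Fisher's method and BH-corrected across genes;
q < 0.05 ⇒ under positive selection. Hypermutator caps are applied first:
samples above 5,000 coding mutations are excluded and per-gene per-sample
counts truncate at 20.

Driver annotation applies rules in priority order — truncating in a
recessively acting gene, known activating hotspot, 'likely oncogenic'
database annotation — after restricting to the tissue-appropriate panel
(colorectal list for intestine, pan-cancer list otherwise); hotspot and
oncogenic tables are configuration inputs. The case/control driver-burden
comparison is a continuity-corrected Pearson chi-squared on the 2×2 table.

## Problem sizes

Default desk scale: 100–800 kb references (the full default is 10 Mb with
200 genes; analyses and tests use smaller slices), 40–200 genes for
selection, cohorts of 4–7 patients with 6–16 crypts, 25–50 replicate
cohorts for recovery statements, 10⁸–3×10⁸ interrogated bases for duplex
recovery. These sizes keep every analysis reproducible on a laptop while
leaving recovery criteria statistically meaningful.

## Known limitations

* The branch-assignment likelihood and the ρ-filter search strategy are
  declared reconstructions validated only on simulation.
* The NB GLM parameterisation of the selection test is a dndscv-style
  offset regression; other parameterisations could differ in small-sample
  tails.
* The parsimony search is heuristic above 7 leaves; bootstrap under NNI
  re-search can understate support on noisy matrices.
* Synthetic signature profiles are qualitative mimics; cosine thresholds
  in tests say nothing about separability of the true COSMIC vectors.
* The mixed model assumes Poisson-scale residuals are approximately
  normal, which is fine at burdens ≫ 100 but untested below.
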