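# Methods

## The scientific setting

Mismatch-repair-deficient (MMRd) colorectal and endometrial cancers divide
by mechanism: loss of mismatch *recognition* (MutSα: MSH2/MSH6 — "dMutSα")
or of mismatch *correction* (MutLα: MLH1/PMS2, usually MLH1 promoter
silencing — "dMutLα"). dMutSα tumours show an excess of CpG>TpG mutations,
the C>T changes at NCG trinucleotides that dominate the clock-like
signature SBS1. Two hypotheses compete: the excess reflects unrepaired
spontaneous 5-methylcytosine deamination (replication-independent, so
strand-neutral), or unrepaired replication errors (biased toward the
leading strand). The package implements the quantitative machinery of that
argument: spectrum construction, subtype classification, signature
refitting, the admixture reconstitution scan, replication/transcription
strand asymmetry, and feature-binned mutation rates — exercised end to end
on synthetic cohorts whose generative truth is known, because the original
patient-level data sits in an access-controlled research environment.

## Conventions

- 96 channels in the conventional COSMIC order (substitution blocks C>A,
  C>G, C>T, T>A, T>C, T>G; 5' base outer loop, 3' base inner). Purine
  reference calls (G>*, A>*) are reverse-complemented onto the pyrimidine
  channel.
- VCF positions 1-based; all interval tracks 0-based half-open. A mutation
  at position p overlaps [s, e) iff s <= p-1 < e, implemented in exactly
  one predicate.
- Only FILTER == PASS records enter any analysis; no additional QUAL/depth
  filtering. Multi-allelic records split one row per alt. Mutations whose
  trinucleotide context contains N are dropped with a logged count.
- Chromosome names are normalised by stripping "chr"; a post-normalisation
  mismatch raises rather than silently producing zero overlap.

## Subtype classification

MMRd requires MSI-positivity (an upstream call, consumed as input) AND
tumour mutation burden strictly greater than 10 coding mutations/Mb.
Pathogenicity is likewise an input annotation. The rule order is:
polymerase-proofreading (POLE/POLD1) exclusion; PMS2 → uncertain
(pseudogene ambiguity); blocklist and subclonality filtering; biallelic
MSH2/MSH6 → dMutSα; biallelic MLH1 → dMutLα-mutation (either with a Lynch_
prefix when a hit is germline); mono-allelic hits or missing copy-number
data → uncertain; no hit at all → dMutLα with presumed MLH1 methylation.
Contradictory biallelic evidence in both arms routes to uncertain.

The zygosity test compares observed alt/ref read counts with the
heterozygous and homozygous expectations under a diploid-contamination
model (expected het VAF ρ/(ρ·CN + 2(1−ρ)), hom VAF ρ·CN/(ρ·CN + 2(1−ρ)),
CN defaulting to 2), each as a 1-df χ² at α = 0.05. Model VAFs are clamped
into [0.01, 0.99] — a sequencing-error floor without which the homozygous
model at purity 1 expects zero reference reads and the statistic is
undefined. A variant whose het model is rejected from below is subclonal
and excluded from hit counting; rejected from above with a fitting hom
model it counts as two hits; if neither model fits, the conservative call
is heterozygous-with-warning, which protects against false biallelic
(hence false dMutSα/dMutLα) assignments. A copy-number-loss annotation
riding on a subclonal variant is retained as one hit: the copy-number
observation does not depend on the variant's read support. Two somatic
hits in one gene are treated as biallelic without phasing, flagged in the
audit trail. The blocklist ships with the three recurrent MSH6
frameshifts arising in hypermutable repeats (p.Ile245fs, p.Thr1085fs,
p.Thr1102fs) and is extensible; blocklisted variants never contribute
hits, which is what prevents MLH1-silenced tumours from being
misclassified as dMutSα. MBD4/TDG/UDG biallelic status is computed with
the same two-hit logic but reported as annotation only.

## Signature refitting and de novo extraction

Refitting is non-negative least squares of a 96-channel spectrum on the
reference columns, followed by backward pruning: repeatedly drop the
signature whose removal costs the least reconstruction cosine, as long as
that cost is below 0.01. The threshold suppresses spurious low-activity
assignments and is configurable. Burdens are the coefficients rescaled to
the spectrum total; activity is burden over total; prevalence is burden
strictly greater than zero after pruning.

De novo extraction runs KL-objective multiplicative-update NMF
(scikit-learn) from `replicates` random initialisations, column-normalises
each run, matches columns across runs to the best-objective run by greedy
cosine pairing, and averages matched columns into a renormalised
consensus; exposures are NNLS-refit against the consensus and rescaled to
per-sample totals. k is user-fixed (default 2, mirroring the two-signature
comparison the study performs); model-selection over k and the resampling
machinery of the original extraction tool are intentionally out of scope.
Recovery of two generating signatures at cosine >= 0.95 requires cohorts
containing near-pure samples; with exposures confined well inside (0, 1)
the NMF cone is not identified at the true endpoints, which is a property
of the model, not the implementation.

## The admixture scan

Restricted to the four CpG>TpG channels (A/C/G/T[C>T]G), as signatures
overlap too much elsewhere. Given base and target four-channel counts and
a candidate signature's renormalised four-channel proportions, the scan
evaluates cosine(base + a·props, target) on a 301-point grid from 0 to
3× the base total, then sharpens the best bracket by golden-section search
to 1e-3 of the grid span. Ties on a flat curve resolve to the smallest
addition (parsimony). The implied mixture fraction a/(base + a) is
scale-free because cosine is; the default grid covers fractions up to
0.75, and larger targets need an explicitly wider grid. Cohort spectra
default to summed counts across tumours (per-tumour means are available);
the bundled SBS1 proportions are ACG 0.416, CCG 0.243, GCG 0.217,
TCG 0.124.

## Strand asymmetry

All strand logic reasons about where the mutated pyrimidine sits: C>T
calls carry it on the plus strand, G>A calls on the minus strand.
Transcription: inside genes annotated on exactly one strand, the call is
"coding" when the pyrimidine lies on the sense strand, else "template";
ambiguous or intergenic positions are excluded. Replication: 20-kb regions
carry left/right-replicating labels; under the default convention a
plus-strand pyrimidine in a left-replicating region is "leading" (the
convention lives in one flag-invertible predicate, and outputs record
which convention produced them). Per-sample log2(leading/lagging) ratios
use medians and IQR for summaries; a zero on either strand makes the
sample's ratio missing rather than infinite. The admixture corollary —
expected log2 under a fraction f of strand-neutral mutations — is the
closed form E = log2((f/2 + (1−f)p)/(f/2 + (1−f)(1−p))) with
p = 2^b/(1+2^b): identity at f = 0, zero at f = 1, strictly decreasing
between. At b = 0.172 and f = 0.39 it evaluates to ≈ 0.105; the
observed-vs-expected comparison can be made per-tumour-then-median or at
the cohort level, and both are provided because the original computation
order is not recoverable from the published medians alone.

## Feature binning

N_x counts plus-strand CG dinucleotides whose track value falls in bin x;
M_x counts the CpG>TpG mutations at such sites (for G>A calls the track is
looked up at the C, one base 5'). Rates are M_x/(N_x/1e6). Bins are
half-open with the top bin closed; edges default to deciles of the
observed track values since no canonical edges exist for the toy tracks.
Trends use the Jonckheere–Terpstra test per group (one-sided, increasing),
and per-sample unweighted OLS slopes of rate on bin midpoint are compared
between groups by rank-sum.

## Statistics

scipy/statsmodels provide rank-sum (exact below combined n = 20 without
ties, tie-corrected normal approximation with continuity correction
otherwise), signed-rank (zeros dropped; exact for small untied samples),
Fisher's exact test, the χ² goodness-of-fit, and Benjamini–Hochberg.
Jonckheere–Terpstra is implemented here: JT = Σ_{i<j} U_ij, null mean
(N² − Σnᵢ²)/4, tie-corrected variance, normal approximation, with full
permutation enumeration below 10 observations and a degenerate p = 1 when
all values tie. Defaults are two-sided and every result records method,
sidedness and sample sizes.

## The synthetic study

Genome: i.i.d. bases at 40% GC, thinned to a CpG dinucleotide density of
0.02/bp (toy scale keeps per-context site pools in the tens of thousands);
two chromosomes of 2 Mb. Tracks: per-CpG methylation from a 70/30 mixture
of Beta(8,2) and Beta(1.5,8) (the bimodal, mostly-methylated pattern of
normal colon); replication timing uniform per 10-kb tile; genes of 30 kb
alternating strand with 20-kb gaps; replication direction alternating
left/right per 20-kb tile with 5% of tiles dropped (unassigned); exome and
kataegis region sets for the restriction operations.

Cohort: per-group sample counts 20 dMutLα / 10 dMutSα / 4 MMRp with
log-normal per-tumour burdens (median 5×10⁴, σ = 0.25). Group spectra are
signature mixtures; the dMutLα mixture follows the published median
activities (SBS1 6.4%, SBS5 16.4%, SBS26 9.3%, SBS44 21.5%, small SBS15,
flat remainder), which puts its CpG>TpG activity near 15% and, after
spiking, the dMutSα activity near 24% — the observed contrast. The dMutSα
group adds an SBS1-proportional CpG>TpG spike sized to f = 0.39 of that
group's CpG>TpG mutations, the decomposition reported for the real
cohorts. Replication-derived (non-spike) C>T mutations realise a
leading-strand bias of log2 = 0.172 via the orientation/region-class of
the sampled site; spike mutations are strand-neutral. CpG>TpG placement
weight is (1 + γ·methylation)(1 + δ·lateness) with γ = 3 and δ = 1 —
strong enough to mirror the several-fold rate gradient across methylation
deciles seen in tumours. Placement is without replacement per sample, so
no site is hit twice in a tumour. Every mutation's generative labels
(signature of origin, spike membership, intended strand) go to a truth
table, enabling truth-stratified checks such as "spike-only mutations show
no strand bias".

The MMR-variant generator emits read counts binomially at the
zygosity-model VAF given each tumour's purity (depth ~ Poisson(80)),
builds second hits as two somatic variants, variant + copy-loss,
homozygous somatic, or germline + somatic, plants blocklisted MSH6
frameshifts in 30% of presumed-methylation tumours, and adds occasional
subclonal decoys — exercising every guard in the classifier.

### What the generator does not emulate

Indels and DBS beyond raw carriage; kataegis clustering; chromatin- or
sequence-covariate structure beyond the methylation/RT weights; realistic
chromosome counts and lengths; copy-number variation in the mutation
placement; sample contamination and mapping artefacts. Passing tests
therefore demonstrate internal consistency of the method chain under its
own generative assumptions — parameter recovery, not biological
validation on real cohorts.

## Problem sizes and determinism

Default end-to-end runs use the toy scale above (~1.7 M mutations per
cohort), chosen so a full simulate-write-read-scan pass completes in about
a minute and a half on one CPU and the whole test suite in well under a
minute of simulation time; power-style checks (trend detection across 50
replicates) use a reduced single-chromosome configuration (400 kb, 3
samples, 8×10³ mutations) that preserves the effects being tested.
Everything is deterministic under (seed, config); the acceptance script
derives its five replicate seeds from the single --seed argument.
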