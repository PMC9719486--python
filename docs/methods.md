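# Methods

`hairline` models and analyses a sequencing run from a heavily degraded,
largely single-stranded DNA source — the regime seen in sun-exposed ancient
hair — where the molecules are ultra-short (post-filter median 25 bp),
deamination damage is high in the read interior (~10%) but only modestly
elevated at the 5' terminus (~15%) and suppressed at the 3' terminus (~1%),
and endogenous content is a fraction of a percent of raw reads.

## Degradation model

A cytosine at 1-based position `i` of an `L` bp molecule is read as T with
probability

    d(i, L) = (a5 * exp(-lam5 * (i-1)) + c) * (1 - b3 * exp(-mu3 * (L-i)))

Defaults: `a5 = 0.05`, `lam5 = 0.5 /bp`, `c = 0.10`, `b3 = 0.90`,
`mu3 = 1.0 /bp`, flat sequencing-error probability `eps = 0.001`.  These
give `d(1, ·) ~ 0.15`, `d(10, ·) ~ 0.10` and a last-base rate of ~0.01,
the three observable anchors of the damage pattern.  The functional form is
phenomenological: a decaying 5' excess on an interior plateau, times a 3'
suppression factor; whether the 3' suppression is library chemistry or
biology is left open and not modelled mechanistically.  Because the
single-stranded protocol converts each strand independently, all
deamination appears as C->T in read orientation; the complementary G->A
channel exists only at the sequencing-error floor, and the damage profiler
tallies it as a protocol diagnostic.

## Fragment lengths

Endogenous molecule lengths are a three-component mixture: 0.50
shifted-exponential(shift 14 bp, scale 3 bp) for the ultra-short bulk, 0.45
shifted-exponential(shift 24 bp, scale 1 bp) for a steep just-over-cutoff
shoulder, and 0.05 lognormal(ln 42, 0.35) for the long tail that carries
the interior-damage signal; lengths are rounded and clamped at 10 bp.  The
parameters were chosen once so that (a) the median after the >= 25 bp
filter is 25 bp and (b) essentially no mass sits below 14 bp, where the 3'
suppression term would depress the marginal position-10 damage rate away
from its ~10% anchor.  Modern contaminants are lognormal(ln 60, 0.40) —
long, undamaged molecules.  Survival functions of all components are
available in closed form (scipy), which the scenario calibration and the
contamination estimator rely on.

## Library simulation and scenarios

Each raw read is endogenous, contaminant or environmental.  Endogenous and
contaminant molecules are sliced uniformly from the nuclear/mitochondrial
compartments of a synthetic reference (chromosome chosen proportional to
length, strand uniform, minus strand = reverse complement); environmental
reads come from a decoy compartment and never map to the target.
Scenarios:

- `hair_25bp` / `hair_30bp` — the two length-cutoff regimes of the deep
  shotgun run.  The scenario parameter is the contaminant share among
  **aligned fragments passing the scenario's cutoff** (0.1% at 25 bp, 47.3%
  at 30 bp), since that is the quantity a substitution-based contamination
  estimator is run on.  The raw-molecule share is solved by inverting each
  component's effective yield = length survival x mapper acceptance, where
  acceptance is a Poisson-count model of per-read mismatches against the
  mismatch cap (below).  One library genuinely reproduces both printed
  regimes qualitatively: raising the cutoff enriches the long undamaged
  contaminants.
- `hair_mtnuc` — mitochondrial share 0.615, solved so the
  coverage-normalised mt/nuc read ratio is ~200 on the 2 Mb + 16 kb toy
  genome.  Kept separate from the contamination scenarios so that
  PCR-duplicate collapse on the tiny mito does not distort their
  composition.
- `shotgun` — raw sequencing regime: endogenous fraction 0.00231 with
  endogenous lengths conditioned on >= 25 bp, so that the pipeline's
  endogenous content (filtered mapped / raw) recovers 0.231% up to mapper
  losses (~2-4%).

Capture enrichment is modelled as independent Bernoulli retention with
probability `logistic(slope * (L - L0)) * exp(-penalty * n_deamination)` —
longer and less-damaged molecules are preferentially retained, which
reproduces the observed drop of terminal damage rates in captured data.

## Toy mapper

`align.map_reads` is a deterministic seed-and-extend mapper: exact 13-mer
seeds, ungapped extension, a candidate passes when mismatches <=
`ceil(0.06 * L)`, unique best score -> MQ 37, ties -> MQ 0.  It is
deliberately minimal — two-valued mapping quality is all the MQ >= 30 gate
needs — and is *not* an emulation of a production aligner.  Reads shorter
than 13 bp are unmappable.  The per-read acceptance probability is also
available in closed form (`mapping_acceptance_probability`): mismatch
counts are approximated as Poisson with rate summed from the damage curve
at reference-C positions (C fraction = GC/2) plus the flat error rate.
This closed form is what couples the scenario definitions and the
contamination estimator to the mapping stage.

## Contamination estimation

Each aligned read is scored under an endogenous component (deamination at
reference-C positions following `d(i, L)`, plus error) and a contaminant
component (error only), and the contaminant fraction `rho` maximises the
concave mixture log-likelihood; the SE comes from the observed Fisher
information, with a one-sided profile-likelihood SE and an explicit
boundary flag when the optimum is within 1e-4 of 0 or 1 (so a "0.1 +/- 0.3"
style result is reported as a bounded estimate, never a negative one).
Only reference-C positions enter: all other positions contribute equal
factors to both components.

Two estimator grades exist:

- **Substitution-only** (default; all the `read_loglik` contract defines).
  Caveat: when the two sources have different length distributions, long
  reads carry both more reference-C information and a higher contaminant
  share, so the optimum is an information-weighted share that can sit well
  above the count-weighted one (+6 points at the 30 bp cutoff scenario).
- **Full generative** (used when the fragment-length models are supplied):
  each component additionally includes `log P(length | component,
  survived the pipeline)`, normalised by the component's effective yield
  when `max_mismatch_frac` is set.  This is consistent for the
  count-weighted contaminant share among the reads analysed.

The hidden-state machinery of full ancient-DNA contamination likelihoods
(overhang states, contiguous single/double-stranded tracts) is not
reproduced; an independent-sites mixture is exact for this simulator and a
documented simplification for real data.  Self-calibration (estimating the
damage curve from the same library's empirical profile, 3-position
smoothing) is supported and tested; because contaminant reads dilute the
profile by roughly `1 - rho`, the self-calibrated estimate detects but
underestimates contamination — supplying an external damage curve is
preferred whenever one exists.

## Length-cutoff rule

`cutoff.spurious_rate` measures, by simulation against the target index,
the MQ >= 30 alignment rate of non-target reads of a fixed length (random
GC-matched sequence by default, decoy-genome slices optionally).
`cutoff_report` tabulates, per candidate cutoff: surviving read count,
median length, 5' position-1 damage, the contamination MLE with SE, and
the spurious fraction.  `choose_cutoff` formalises the trade-off the study
states but does not formalise: the smallest cutoff with
`rho + 2*SE <= 0.05` and spurious fraction `<= 0.10` (both configurable).
The toy spurious rates are properties of the 3 Mb toy index and are not
expected to match genome-scale figures.

## Genotyping

Pseudo-haploid calling: pileup at panel SNPs gated at BQ >= 30 and
MQ >= 30, bases matching neither panel allele discarded, then one passing
allelic base drawn uniformly at random per site (per-base, not
per-read-then-base), stored as a homozygous diploid code for EIGENSTRAT
compatibility (genotype = copies of the reference allele; 9 = missing).
No damage-aware site filtering is applied by default.

## f-statistics, jackknife, PCA

- Outgroup-f3(A, B; O) = mean (a-o)(b-o) over SNPs where all three have
  data; no heterozygosity normalisation or small-sample correction
  (outgroup mode).  A 1000-SNP floor guards sparse-sample reports and is
  relaxable for unit-scale inputs.
- f4(A, B; C, D) = mean (a-b)(c-d); |Z| > 3 is the significance
  convention.
- Standard errors use the weighted block jackknife over chromosomes with
  block sizes = per-chromosome usable SNP counts: with `h_k = n/m_k`,
  pseudo-values `tau_k = h_k*theta - (h_k-1)*theta_{-k}`,
  `SE^2 = (1/g) sum (tau_k - theta_J)^2 / (h_k - 1)`.
- PCA standardises modern genotypes per SNP by mean `mu_j` and
  `sqrt(p_j(1-p_j))`, `p_j = mu_j/2`, mean-imputes missing entries, drops
  monomorphic SNPs, and decomposes by SVD (per-PC sign fixed by making the
  largest-|loading| entry positive).  Sparse samples are placed by least
  squares on their non-missing SNPs; pseudo-haploid 0/2 coding is unbiased
  for the projection because its per-SNP mean equals the diploid mean.
  Error bars are the take-one-chromosome-out jackknife in which only the
  projection is refit; the basis is never refit, because refitting would
  change the meaning of every coordinate (the alternative reading of
  "deleting each chromosome of the genotype data" is noted and not
  implemented).  No outlier-removal iterations and no score shrinkage are
  applied: the synthetic panels are clean by construction.

## Synthetic panel

A star-shaped Balding–Nichols model: ancestral reference-allele frequency
`~ U(0.05, 0.95)` per SNP; each population drifts independently with its
own `F` (default 0.05, Hudson-type Fst between two such populations ~ F);
diploid genotypes binomial; an outgroup fixed at the ancestral allele with
divergence flips (default 0.1); two pseudo-haploid ancient samples drawn
from configurable source populations with i.i.d. missingness (default
0.5).  SNPs carry chromosome labels 1..22 (round-robin), which are the
jackknife blocks.  Because every population drifts independently from one
ancestor, f4(anc1, anc2; X, O) is zero in expectation for *any* pair of
ancients unless X shares drift with one of their sources — detection power
therefore exists only for X chosen as a source population, and at F = 0.05
with 5000 SNPs the signal (F * E[p(1-p)] ~ 0.009) is below ~2 jackknife
SE; the power property is exercised at F = 0.15 where the expected |Z| is
~5.  What passing tests show: estimator calibration and level/power under
the stated generative model.  What they do not show: robustness to LD (no
linkage is simulated), to reference bias, to admixture graphs deeper than
a star, or to real capture chemistry.

## Numerical and size choices

Tests and the acceptance script scale the study down to what the pipeline
analyses comfortably on one core: a 2 Mb nuclear + 16 kb mito + 1 Mb decoy
toy genome, 5e5-read damage profiling runs, ~2e5 informative reads for the
contamination scenarios, 1e6 raw reads for the endogenous-content run, and
5000-SNP panels with 20-replicate level/power checks.  The contamination
MLE uses bounded Brent search polished by Newton steps (tolerance 1e-6,
concave objective); mixture likelihood evaluations work on log-ratios with
explicit large-|llr| branches; empty pileups, missing compartments and
single-block jackknives raise explicit errors rather than returning
silent zeros.  All randomness flows through per-call
`numpy.random.default_rng(seed)` generators; every simulation function is
a pure function of its inputs and seed.
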