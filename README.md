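# hairline

Analysis pipeline for **ultra-short, interior-damaged ancient DNA from
single-stranded sequencing libraries** — the regime found in mummified hair
from hot, arid environments, where heat denatures DNA to single strands,
fragments are extraordinarily short (median ~25 bp after filtering), C→T
deamination runs at ~10% through the read *interior* (versus ~1% in typical
bone-derived data) yet only ~15% at the 5′ terminus, and endogenous
molecules are ~0.2% of raw reads.

The package provides, as a tested library plus a `hairline` CLI:

- a **generative model** of such a sequencing run: synthetic references
  with nuclear/mitochondrial/environmental compartments, mixture
  fragment-length models, a parametric damage curve
  `d(i,L) = (a₅·e^(−λ₅(i−1)) + c)·(1 − b₃·e^(−μ₃(L−i)))`, modern-contaminant
  and environmental reads, capture bias, and per-read truth tables;
- a deterministic **toy mapper** (seed-and-extend, ungapped, MQ ∈ {0, 37}),
  the study's length/BQ/MQ **filters**, PCR-duplicate removal and
  coverage-normalised **mt/nuc statistics**;
- **damage profiling**: position-specific C→T and G→A rates from both read
  ends, length statistics, nuclear-vs-mito comparison;
- **contamination estimation** by a two-component per-read likelihood
  mixture conditioned on the deamination curve, with Fisher/profile SEs and
  boundary handling;
- the **read-length cutoff exploration**: simulated spurious-alignment
  rates per length, a per-cutoff report, and the dual-threshold safe-cutoff
  rule (smallest cutoff with ρ̂ + 2·SE ≤ 5% contamination and ≤ 10%
  spurious alignments);
- **pseudo-haploid genotype calling** at panel SNPs with EIGENSTRAT I/O;
- **population-genetic statistics**: outgroup-f3 = mean (a−o)(b−o),
  f4 = mean (a−b)(c−d) with the |Z| > 3 convention, the weighted block
  jackknife over chromosomes for standard errors, and least-squares PCA
  projection of sparse ancient samples with take-one-chromosome-out error
  bars;
- a **Balding–Nichols panel simulator** with an outgroup and a cladal pair
  of pseudo-haploid ancient samples, so every statistic is testable against
  known truth.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and known limitations.

## Worked example

Simulate the deep-shotgun regime at its preferred 25 bp cutoff, map,
profile damage and estimate contamination:

```bash
hairline simulate library --scenario hair_25bp --n-reads 400000 --out run25 --seed 7
hairline align   --ref run25/reference.fa --fastq run25/reads.fq \
                 --min-length 25 --min-mq 30 --no-dedup --out run25/aln.sam
hairline damage  --sam run25/aln.sam --ref run25/reference.fa --out-prefix run25/damage
hairline contam  --sam run25/aln.sam --ref run25/reference.fa
```

which prints

```
wrote 400000 reads (scenario hair_25bp, seed 7) to run25
mapped 125351 reads (nuclear 122888, mito 2463, mt/nuc 2.51) -> run25/aln.sam
5' pos1 C->T 0.1434; median length 25
{
  "rho": 0.0,
  "se": 9.025397925167692e-05,
  "loglik": -216654.90669750742,
  "n": 125023,
  "boundary": true
}
```

Reading: of 400k raw reads, 125,351 map at ≥25 bp and MQ ≥ 30; the 5′
position-1 C→T rate of 14.3% is the authenticity signal (the self-profiled
curve is slightly diluted relative to the generative 15%); the median
mapped length is 25 bp; and the mixture MLE for the contaminant fraction
sits on the ρ = 0 boundary with a one-sided profile SE — the same shape of
result as a "0.1 ± 0.3%" report, never a negative estimate.

Population-genetic checks on a simulated panel (four populations, an
outgroup, and two pseudo-haploid ancient samples from the same source):

```bash
hairline simulate panel --out panel --seed 11
hairline f4  --panel panel --a Pop0 --b Pop1 --x Pop2
hairline pca --panel panel --project panel.ancient --pcs 2
```

```
f4(Pop0,Pop1;Pop2,Outgroup) = -0.000325 +/- 0.001118 (Z=-0.29, ns)
Ancient_0: PC1=-3.6623+/-2.4720, PC2=20.2967+/-3.1606 (2445 SNPs)
Ancient_1: PC1=-4.2406+/-2.8204, PC2=21.2680+/-2.1786 (2519 SNPs)
```

The f4 test does not reject cladality (|Z| < 3), and the two ~50%-missing
ancient samples project to mutually consistent coordinates, with
take-one-chromosome-out jackknife error bars.

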