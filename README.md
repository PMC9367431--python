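# genomesurvey

A whole-genome **survey** characterises a genome from low-cost short reads
before any serious assembly exists: how big is it, how error-ridden are the
reads, how heterozygous and repeat-rich is the genome, what do the draft
contigs look like, which microsatellites could serve as markers, what does
the mitogenome contain, and what does PSMC say about the population's
history.  `genomesurvey` implements that analysis chain as a tested Python
library — aimed at people building or auditing survey pipelines for
non-model organisms (the defaults mirror a small marine fish) — together
with a simulator that generates every input *with known truth*, so each
stage carries a parameter-recovery test instead of a screenshot.

## What it computes

**K-mer spectrum estimates** (`genomesurvey.kmer`).  Reads are decomposed
into canonical k-mers (lexicographic min of k-mer and reverse complement,
odd k).  With N_kmer the total k-mer volume and C_kmer the post-error-peak
depth of the histogram:

    G_size         = N_kmer / C_kmer
    Error rate     = volume(depth 1) / N_kmer
    Revised G_size = G_size x (1 - Error rate)

Heterozygosity comes from a two-component Poisson mixture (means C/2 and C)
fitted to the spectrum by non-negative least squares: with alpha the
half-depth component's share of k-mer volume, the per-base rate is
`r = 1 - (1 - alpha)^(1/k)`.  The repeat ratio is the non-error volume at
depths >= 1.5 x C.  A continuous-coverage refinement of C (`refine_peak`)
removes the integer-mode quantisation from all three estimates.

**SSR census** (`genomesurvey.ssr`).  Maximal perfect tandem repeats of
period 2-6 with MISA-style thresholds (6/5/5/5/5 minimum copies), motif
phase preserved, compound merging of loci separated by <= 100 bp, and the
survey-table summary (totals, per-period percentages, density per Mb).

**Assembly metrics** (`genomesurvey.assembly`).  N50/N90 (smallest length
whose cumulative coverage reaches 50%/90%), totals, GC% excluding ambiguous
bases, scaffold-to-contig splitting on N runs, and a windowed GC-vs-depth
table using k-mer multiplicities as the depth proxy.

**Mitogenome census** (`genomesurvey.mito`).  Feature counts by type
(PCG/tRNA/rRNA/control region) and strand (heavy/light), base composition,
and start/stop codons of the 13 protein-coding genes under the vertebrate
mitochondrial code — including incomplete stops (T/TA) completed by
polyadenylation.

**PSMC scaling** (`genomesurvey.psmc`).  Parses PSMC text output (RD/TR/RS
blocks, last round) and converts coalescent units to natural ones:
`N0 = theta0 / (4 u s)`, `Ne_k = N0 lambda_k`, `years_k = 2 N0 t_k g`
(defaults u = 2.5e-8 per site per generation, s = 100 bp, g = 1 year), plus
median/quantile envelopes over bootstrap replicates.

**Simulator** (`genomesurvey.simulate`).  Diploid genomes with exact block
duplications and per-base SNP heterozygosity, uniform-coverage substitution-
error reads, planted SSR arrays with guaranteed-maximal flanks, a 16,532 bp
circular mitogenome fixture with the canonical 13/22/2/1 layout, and PSMC
output generated from a known Ne trajectory.  Everything is byte-
deterministic under its seed.

## Worked example

```sh
python examples/kmer_spectrum_survey.py
```

simulates a 500 kb diploid genome (heterozygosity 0.47%, repeats 32.6%) at
30x with 0.1% read errors and inverts the 19-mer spectrum:

```
k-mer volume (N_kmer):     13,200,000
peak depth (C_kmer):       25 (refined 26.07)
error rate:                1.84%
revised genome size:       0.497 Mb  (truth 0.500 Mb)
heterozygosity:            0.569%  (truth 0.470%)
repeat ratio:              28.89%  (truth 32.60%)
```

The error rate is per *k-mer* (a 0.1% per-base rate corrupts
`1-(1-0.001)^19 ~ 1.88%` of 19-mers); the refined peak is the fitted k-mer
coverage `30 x (150-19+1)/150 = 26.4`.  The other examples
(`ssr_census.py`, `assembly_stats.py`, `mito_census.py`,
`psmc_scaling.py`, `full_survey.py`) each exercise one stage the same way.

There is also a thin CLI:

```sh
survey simulate --length 100000 --seed 1 --out-dir scratch/sim
survey kspec --reads scratch/sim/reads.fastq --k 19
survey ssr --fasta scratch/sim/genome.fasta --out scratch/ssr
survey run --out-dir scratch/full        # whole pipeline, one report bundle
```

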