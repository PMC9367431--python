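# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
decisions a maintainer would want written down.

## K-mer spectrum model

Reads are decomposed into canonical k-mers: the lexicographic minimum of
each k-window and its reverse complement, with k odd (an even k admits
self-reverse-complementary palindromes whose canonical form is ambiguous).
In the 2-bit A<C<G<T encoding the lexicographic minimum coincides with the
numeric minimum, so counting is a vectorised shift/or over the encoded read
stream; windows containing N are skipped and depths beyond 10,000 accumulate
in a cap bin.  Counting is in-memory and comfortable up to tens of millions
of k-mers; it is deliberately not a disk-based multi-threaded counter.

The histogram records *species* (distinct k-mers) per depth; *volume* is
depth x species.  The estimators:

* **Error rate** = volume(1) / N_kmer.  Under a substitution-only error
  model almost every erroneous k-mer is unique, so depth-1 volume is the
  error mass.  This is a per-k-mer rate: a per-base rate e corrupts
  `1-(1-e)^k` of k-mers, which is what the estimator recovers and what the
  parameter-recovery test asserts (±20% at e = 0.001, k = 19).
* **Peak (C_kmer)**.  The species curve is smoothed with a window-3 moving
  average (edge-corrected); the error region is its initial descending
  stretch (empty when the curve starts by rising, e.g. error-free input);
  the peak is the raw-species argmax strictly beyond it, ties to the
  smaller depth.  A curve that only descends has no post-error peak and is
  an error.
* **Continuous coverage refinement.**  The integer mode is quantised and,
  because a read contributes ~`L-k+1` correlated windows, its sampling
  noise is far larger than Poisson counting statistics — the mode wobbles
  ±1 between runs.  The true k-mer coverage `c (L-k+1)/L` (26.4 at c = 30,
  L = 150, k = 19) is recovered by fitting the two-Poisson mixture below
  with a *continuous* mean via bounded scalar minimisation (mode ± 3).
  `estimate_spectrum` uses the refined coverage for genome size,
  heterozygosity and repeat ratio; `find_peak` keeps the integer contract.
  With refinement, genome-size recovery error drops from 1.5-5.6% to
  <0.3% across seeds.
* **Genome size** G = N_kmer / C; revised G multiplies by (1 - error rate),
  algebraically `(N_kmer - volume(1)) / C`.
* **Heterozygosity.**  K-mers spanning a heterozygous site exist in one
  haplotype only and pile up at half coverage, two distinct species per
  affected locus.  Species counts over depths [C/4, 1.5C] are fitted by
  non-negative least squares to `A1 Poisson(C/2) + A2 Poisson(C)`.  The
  half-depth component's share of k-mer *volume*, `alpha = A1/(A1+2 A2)`,
  equals the fraction of k-mer loci containing a het site (the species
  share would double-count the two variants), and inverts to the per-base
  rate `r = 1-(1-alpha)^(1/k)`.  The accuracy contract is parameter
  recovery on simulated truth (±30% over r in 0.002-0.01, strictly
  monotone), not any published organism value.
* **Repeat ratio** = volume at depths >= round(1.5 C) over non-error
  volume.  1.5C splits the single-copy peak from the 2x-and-up repeat
  peaks; it is a documented heuristic, adequate for exact-duplication
  repeats, and recovers a planted 30% repeat fraction within a few points.

## SSR mining

Maximal perfect tandem runs of period 2-6 are found per period from the
`s[i] == s[i+p]` match array; trailing partial copies are excluded from
count and coordinates; N breaks every run.  A motif whose minimal period is
shorter than the search period is classified at the shorter period, and
period-1 (homopolymer) runs are never reported.  Overlaps across periods
are resolved greedily — longer span wins, ties prefer smaller period then
smaller start — so e.g. an (AT) run is never double-reported through its
(ATAT) reading.  Default thresholds are 6 copies for dinucleotides and 5
for periods 3-6; compound merging joins records separated by <= 100 bp (the
de facto interruption default of MISA-style tools), lowercasing the
interruption in the standardized string.  Motif phase is preserved (AC and
CA are different motifs) because survey reports tabulate them separately;
`canonical_motif` is available to collapse phase/strand classes.  The
scanner is validated record-for-record against an exhaustive brute-force
enumerator on a corpus that mixes uniform, two-letter-alphabet and
motif-run-injected sequences.

Census statistics count perfect SSRs (compound constituents included in the
per-period totals and in the compound count), and density is
`total / (length/1e6)`.

## Assembly metrics

Nxx is the smallest length L such that sequences of length >= L cover xx%
of the total (descending sort + cumulative sum).  GC% excludes ambiguous
bases from the denominator.  Contigs are obtained by splitting scaffolds on
runs of >= 1 N — the simplest defensible convention; there is no minimum
gap or contig length.  The GC-depth table pairs non-overlapping windows
(default 500 bp; windows > 50% N skipped) with the mean multiplicity of the
canonical k-mers starting in the window, a depth proxy that avoids read
alignment entirely.

## Mitogenome census

Coordinates are 1-based inclusive on a circular genome; a feature may wrap
the origin (end < start with a wrap flag), and extraction honours wrap and
strand (reverse complement for light-strand features).  Start codon = first
3 nt of the CDS; the stop is the trailing 1-3 nt after whole codons,
classified *incomplete* when shorter than 3 (completed to TAA by
polyadenylation in vivo).  AGA/AGG count as conventional mitochondrial
stops alongside TAA/TAG (vertebrate mitochondrial code, translation
table 2).  Annotations are read from a 6-column TSV dialect or GenBank flat
files (CDS -> PCG, D-loop/misc_feature -> control region; origin-spanning
join locations -> wrap flag).

## PSMC scaling

Only the output contract of PSMC is implemented — parsing the text dialect
(last RD block's TR and RS lines) and the plotting mathematics
`N0 = theta0/(4 u s)`, `Ne_k = N0 lambda_k`, `years_k = 2 N0 t_k g` — never
the HMM/EM inference itself.  Defaults u = 2.5e-8 per site per generation
and g = 1 year are the standard small-fish settings; the bin size s
defaults to 100 (the consensus-input convention of the upstream tool) and
is exposed because published analyses rarely state it.  Bootstrap
replicates are step-interpolated onto the union time grid (no new Ne level
is invented) before pointwise median and 2.5/97.5% quantiles.

## Simulator: what it emulates, and what it does not

The generator's defaults are the survey conditions the package is tested
under: 500 kb diploid genome, heterozygosity 0.47%, repeat fraction 32.6%,
150 bp single-end reads at 30x pooled coverage.  The read error default of
0.001 per base is a generic short-read figure, chosen once, not a library
measurement.  Design choices:

* Repeats are *exact block duplications*: the repeat fraction of the genome
  is laid out as pairs of identical units (default 500 bp) interleaved with
  unique chunks, so the duplicated-sequence share of the genome equals the
  nominal fraction and the spectrum gains a clean 2x peak.  Real repeats
  diverge, nest and come in high-copy families; the recovery tests
  therefore validate the estimator's logic, not its behaviour on real
  repeat landscapes.
* Substitution-only errors (no indels), matching what depth-1 error
  estimation assumes; constant placeholder base qualities (QC is out of
  scope).
* Single-end reads suffice: no stage uses pairing, so insert-size modelling
  is omitted.
* Planted SSR arrays get flank bases adjusted so no array can extend by one
  period, and the background generator suppresses spontaneous tandems above
  3 copies — the "non-repetitive flank" condition under which exact
  coordinate recovery is guaranteed.
* The mitogenome fixture is synthetic: canonical vertebrate gene order and
  feature counts, random inter-feature sequence, planted start/stop codons
  (COI GTG, ATP6 ATA, 11x ATG; seven conventional stops — 2x TAA, 3x TAG,
  2x AGA — and six incomplete).  It validates census/codon logic, not
  annotation transfer from real data.
* PSMC fixtures encode the truth trajectory exactly (earlier EM rounds,
  when emitted, are perturbed so last-round selection is observable);
  round-tripping is exact to floating precision, so the 1e-9 tolerance in
  tests checks the scaling algebra, not statistical error.

Passing tests therefore demonstrate correct inversion of the package's own
generative model at desk scale (hundreds of kb); they do not demonstrate
robustness to real library artefacts (coverage bias, indels, diverged
repeats, contamination).

## Problem sizes and numerics

Recovery tests simulate 500 kb genomes at 30x (13.2M 19-mers, a few seconds
each); the pipeline determinism check runs 100 kb at 20x twice.  These
sizes give the estimators enough statistics that the asserted tolerances
hold with wide margin across seeds.  NNLS (scipy) is used for all mixture
amplitude fits — it cannot fail to converge on these small systems — and
bounded scalar minimisation for the continuous coverage.  Ties everywhere
break deterministically (smaller depth, smaller period, smaller start), and
every generator and pipeline stage is byte-deterministic under its seed;
report hashes exclude only the output directory path.

## Known limitations

* In-memory k-mer counting: not suitable for full sequencing libraries
  (tens of Gb); feed a precomputed two-column histogram instead.
* The heterozygosity model assumes a diploid with a single het peak at C/2;
  polyploids and very high heterozygosity (haplotype-split main peak) are
  out of scope.
* The repeat threshold 1.5C undercounts repeats whose copy number is
  amplified in only one haplotype and overcounts high-coverage tails.
* GC-depth uses k-mer multiplicity, which saturates on repeats, unlike
  alignment depth.
* PSMC preprocessing (fq2psmcfa/splitfa) and the -t/-p/-N inference
  options are recorded as metadata only; inference is delegated to the
  published tool.
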