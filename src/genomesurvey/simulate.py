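"""Synthetic survey inputs with known truth.

Every downstream stage of the survey pipeline gets a parameter-recovery test
from this module: a diploid genome with controlled heterozygosity and repeat
content, uniform-coverage substitution-error reads, planted microsatellite
arrays, a circular mitochondrial fixture with the canonical vertebrate
13 PCG / 22 tRNA / 2 rRNA / 1 control-region layout, and PSMC text output
generated from a known Ne trajectory.

Default truth values mirror a typical small-fish survey genome: per-base
heterozygosity 0.47%, repeat fraction 32.6%, 150 bp reads at 30x pooled
coverage.  The read error default of 0.1% is a generic short-read figure,
not tied to any particular library.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .mito import CONVENTIONAL_STOPS, MitoAnnotation, MitoFeature
from .ssr import minimal_period

__all__ = [
    "SimParams",
    "DiploidGenome",
    "ReadSet",
    "PlantedSSR",
    "MitoFixture",
    "PsmcTruth",
    "simulate_diploid_genome",
    "simulate_reads",
    "plant_ssrs",
    "random_dna",
    "make_mito_fixture",
    "make_psmc_output",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


@dataclass
class SimParams:
    """Truth parameters of one synthetic diploid genome."""

    genome_length: int = 500_000
    het_rate: float = 0.0047
    repeat_fraction: float = 0.326
    repeat_unit_length: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.het_rate <= 0.05:
            raise ValueError(f"het_rate must be in [0, 0.05], got {self.het_rate}")
        if not 0.0 <= self.repeat_fraction <= 0.9:
            raise ValueError(f"repeat_fraction must be in [0, 0.9], got {self.repeat_fraction}")
        if self.repeat_unit_length <= 0:
            raise ValueError("repeat_unit_length must be positive")
        if self.genome_length < self.repeat_unit_length:
            raise ValueError("genome_length must be >= repeat_unit_length")


@dataclass
class DiploidGenome:
    """Two haplotypes plus the truth needed by recovery tests."""

    hap1: str
    hap2: str
    het_sites: List[int]  # 1-based positions where hap1 != hap2
    ssr_truth: List["PlantedSSR"] = field(default_factory=list)
    repeat_intervals: List[Tuple[int, int]] = field(default_factory=list)  # 1-based inclusive
    params: Optional[SimParams] = None

    def __post_init__(self) -> None:
        if len(self.hap1) != len(self.hap2):
            raise ValueError("haplotypes must have equal length")

    @property
    def length(self) -> int:
        return len(self.hap1)


@dataclass
class ReadSet:
    reads: List[Tuple[str, str, str]]  # (id, sequence, quality)
    read_length: int
    coverage: float
    error_rate: float

    def sequences(self) -> List[str]:
        return [seq for _, seq, _ in self.reads]


@dataclass
class PlantedSSR:
    """Truth record of one planted microsatellite array (1-based inclusive)."""

    motif: str
    repeats: int
    start: int
    end: int


def simulate_diploid_genome(params: SimParams) -> DiploidGenome:
    """Build a diploid genome with exact duplicated blocks and SNP het sites.

    The repeat fraction of the genome is laid out as pairs of identical
    blocks of ``repeat_unit_length`` interleaved with unique chunks, so the
    duplicated-sequence share of the genome equals ``repeat_fraction`` and
    the expected k-mer spectrum gains a clean 2x repeat peak.  Haplotype 2 is
    haplotype 1 with independent per-base substitutions at ``het_rate``.
    """
    rng = np.random.default_rng(params.seed)
    L = params.genome_length
    unit = params.repeat_unit_length
    n_units = int(round(params.repeat_fraction * L / (2 * unit)))
    while n_units > 0 and 2 * n_units * unit > L:
        n_units -= 1
    uniq_len = L - 2 * n_units * unit

    units = [rng.integers(0, 4, size=unit, dtype=np.int8) for _ in range(n_units)]
    n_chunks = 2 * n_units + 1
    base = uniq_len // n_chunks
    sizes = np.full(n_chunks, base, dtype=np.int64)
    sizes[: uniq_len - base * n_chunks] += 1
    order = rng.permutation(np.repeat(np.arange(n_units), 2)) if n_units else np.empty(0, int)

    parts: List[np.ndarray] = []
    repeat_intervals: List[Tuple[int, int]] = []
    pos = 0
    for i in range(n_chunks):
        chunk = rng.integers(0, 4, size=int(sizes[i]), dtype=np.int8)
        parts.append(chunk)
        pos += chunk.size
        if i < len(order):
            u = units[order[i]]
            parts.append(u)
            repeat_intervals.append((pos + 1, pos + u.size))
            pos += u.size
    hap1 = np.concatenate(parts) if parts else np.empty(0, np.int8)
    assert hap1.size == L

    mask = rng.random(L) < params.het_rate
    hap2 = hap1.copy()
    n_mut = int(mask.sum())
    if n_mut:
        hap2[mask] = (hap2[mask] + rng.integers(1, 4, size=n_mut, dtype=np.int8)) % 4
    het_sites = (np.flatnonzero(mask) + 1).tolist()

    return DiploidGenome(
        hap1=_to_str(hap1),
        hap2=_to_str(hap2),
        het_sites=het_sites,
        repeat_intervals=repeat_intervals,
        params=params,
    )


def simulate_reads(
    genome: DiploidGenome,
    coverage: float,
    read_length: int = 150,
    error_rate: float = 0.001,
    seed: int = 0,
) -> ReadSet:
    """Uniform single-end reads pooled over both haplotypes and strands.

    The read count is ``round(coverage * genome_length / read_length)``;
    substitution errors are i.i.d. per base (no indels), matching what
    depth-1 k-mer error estimation assumes.
    """
    if coverage <= 0:
        raise ValueError(f"coverage must be positive, got {coverage}")
    L = genome.length
    if read_length > L:
        raise ValueError("read_length must be <= genome_length")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * L / read_length))

    enc = np.full(256, 0, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        enc[ord(b)] = i
    haps = [
        enc[np.frombuffer(genome.hap1.encode(), np.uint8)],
        enc[np.frombuffer(genome.hap2.encode(), np.uint8)],
    ]
    hap_choice = rng.integers(0, 2, size=n_reads)
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)

    mat = np.empty((n_reads, read_length), dtype=np.int8)
    win = starts[:, None] + np.arange(read_length)[None, :]
    for h in (0, 1):
        rows = hap_choice == h
        mat[rows] = haps[h][win[rows]]
    rev = strands == 1
    mat[rev] = 3 - mat[rev, ::-1]
    if error_rate > 0:
        errmask = rng.random((n_reads, read_length)) < error_rate
        n_err = int(errmask.sum())
        if n_err:
            mat[errmask] = (mat[errmask] + rng.integers(1, 4, size=n_err, dtype=np.int8)) % 4

    qual = "I" * read_length
    byte_mat = _BASES[mat]
    reads = [
        (f"read_{i:07d}", byte_mat[i].tobytes().decode("ascii"), qual)
        for i in range(n_reads)
    ]
    return ReadSet(reads=reads, read_length=read_length, coverage=coverage, error_rate=error_rate)


def random_dna(length: int, seed: int = 0, max_tandem: int = 3) -> str:
    """Random DNA with tandem runs suppressed below SSR-detection range.

    When ``max_tandem`` is set, any perfect tandem of a 1-6 bp unit with more
    than ``max_tandem`` copies is broken by point changes, giving the
    "non-repetitive flank" background that guarantees planted arrays stay
    maximal and unmerged.
    """
    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 4, size=length, dtype=np.int8)
    if max_tandem is None or length < 2:
        return _to_str(arr)
    for _ in range(50):
        dirty: List[int] = []
        for p in range(1, 7):
            if length <= p:
                continue
            eq = arr[:-p] == arr[p:]
            padded = np.concatenate([[False], eq, [False]])
            d = np.diff(padded.astype(np.int8))
            run_starts = np.flatnonzero(d == 1)
            run_ends = np.flatnonzero(d == -1)  # exclusive
            for a, b in zip(run_starts, run_ends):
                copies = ((b - a) + p) // p
                if copies > max_tandem:
                    dirty.append(int(a + (b - a) // 2))
        if not dirty:
            return _to_str(arr)
        for mid in dirty:
            arr[mid] = (arr[mid] + rng.integers(1, 4)) % 4
    return _to_str(arr)  # pragma: no cover - suppression converges quickly


def plant_ssrs(
    sequence: str,
    spec: Sequence[Tuple[str, int, int]],
    seed: int = 0,
    min_gap: int = 30,
) -> Tuple[str, List[PlantedSSR]]:
    """Insert perfect SSR arrays at non-overlapping random positions.

    ``spec`` lists (motif, repeats, copies) triples; motifs must have minimal
    period 2-6.  Arrays are inserted (sequence grows) at positions at least
    ``min_gap`` apart, and the immediately flanking bases are adjusted so no
    array can extend by another period.  Truth coordinates are returned
    1-based inclusive in the output sequence.
    """
    expanded: List[Tuple[str, int]] = []
    for motif, repeats, copies in spec:
        motif = motif.upper()
        p = len(motif)
        if not 2 <= p <= 6:
            raise ValueError(f"motif period must be 2-6, got {motif!r}")
        if minimal_period(motif) != p:
            raise ValueError(f"motif {motif!r} is a repetition of a shorter unit")
        if repeats < 2 or copies < 1:
            raise ValueError("repeats must be >= 2 and copies >= 1")
        expanded.extend([(motif, repeats)] * copies)

    rng = np.random.default_rng(seed)
    n = len(expanded)
    if n == 0:
        return sequence, []
    L = len(sequence)
    if (n + 1) * min_gap >= L:
        raise ValueError(f"cannot place {n} arrays with min_gap={min_gap} in {L} bp")
    positions = None
    for _ in range(1000):
        cand = np.sort(rng.integers(min_gap, L - min_gap, size=n))
        if n == 1 or np.all(np.diff(cand) >= min_gap):
            positions = cand
            break
    if positions is None:
        raise ValueError(f"cannot place {n} non-overlapping arrays in {L} bp")
    order = rng.permutation(n)

    pieces: List[str] = []
    truth: List[PlantedSSR] = []
    prev = 0
    offset = 0
    for pos, which in zip(positions, order):
        motif, repeats = expanded[which]
        array = motif * repeats
        left = sequence[prev:pos]
        # block single-base extension of the planted run into the flanks
        if left and left[-1] == motif[-1]:
            left = left[:-1] + _different_base(motif[-1], rng)
        pieces.append(left)
        start = offset + len(left) + 1
        pieces.append(array)
        truth.append(PlantedSSR(motif=motif, repeats=repeats, start=start, end=start + len(array) - 1))
        offset = start + len(array) - 1
        prev = pos
        if prev < L and sequence[prev] == motif[0]:
            pieces.append(_different_base(motif[0], rng))
            offset += 1
            prev += 1
    pieces.append(sequence[prev:])
    return "".join(pieces), truth


def _different_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


# ---------------------------------------------------------------------------
# Mitochondrial fixture
# ---------------------------------------------------------------------------

_STOP_CODONS = sorted(CONVENTIONAL_STOPS)
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in CONVENTIONAL_STOPS
]

# (name, body codon count, start codon, stop string); stop strings of length
# 1-2 are incomplete stops completed by polyadenylation in vivo
_PCG_PLAN: List[Tuple[str, int, str, str]] = [
    ("ND1", 320, "ATG", "TAG"),
    ("ND2", 345, "ATG", "TA"),
    ("COI", 515, "GTG", "T"),
    ("COII", 228, "ATG", "AGA"),
    ("ATP8", 54, "ATG", "TAA"),
    ("ATP6", 226, "ATA", "TAA"),
    ("COIII", 260, "ATG", "T"),
    ("ND3", 115, "ATG", "TAG"),
    ("ND4L", 97, "ATG", "TA"),
    ("ND4", 459, "ATG", "AGA"),
    ("ND5", 611, "ATG", "T"),
    ("ND6", 172, "ATG", "TAG"),
    ("CYTB", 379, "ATG", "TA"),
]

_LIGHT_TRNAS = {"trnQ", "trnA", "trnN", "trnC", "trnY", "trnS1", "trnE", "trnP"}

# canonical vertebrate mitochondrial gene order
_GENE_ORDER: List[Tuple[str, str]] = [
    ("trnF", "tRNA"),
    ("rrnS", "rRNA"),
    ("trnV", "tRNA"),
    ("rrnL", "rRNA"),
    ("trnL2", "tRNA"),
    ("ND1", "PCG"),
    ("trnI", "tRNA"),
    ("trnQ", "tRNA"),
    ("trnM", "tRNA"),
    ("ND2", "PCG"),
    ("trnW", "tRNA"),
    ("trnA", "tRNA"),
    ("trnN", "tRNA"),
    ("trnC", "tRNA"),
    ("trnY", "tRNA"),
    ("COI", "PCG"),
    ("trnS1", "tRNA"),
    ("trnD", "tRNA"),
    ("COII", "PCG"),
    ("trnK", "tRNA"),
    ("ATP8", "PCG"),
    ("ATP6", "PCG"),
    ("COIII", "PCG"),
    ("trnG", "tRNA"),
    ("ND3", "PCG"),
    ("trnR", "tRNA"),
    ("ND4L", "PCG"),
    ("ND4", "PCG"),
    ("trnH", "tRNA"),
    ("trnS2", "tRNA"),
    ("trnL1", "tRNA"),
    ("ND5", "PCG"),
    ("ND6", "PCG"),
    ("trnE", "tRNA"),
    ("CYTB", "PCG"),
    ("trnT", "tRNA"),
    ("trnP", "tRNA"),
    ("CR", "CR"),
]

_TRNA_LEN = 70
_RRNS_LEN = 950
_RRNL_LEN = 1680
MITO_TOTAL_LENGTH = 16_532


@dataclass
class MitoFixture:
    """Synthetic circular mitogenome with its annotation and codon truth."""

    sequence: str
    annotation: MitoAnnotation
    translation_table: int  # NCBI table id (2 = vertebrate mitochondrial)
    expected_codons: Dict[str, Tuple[str, str, str]]  # name -> (start, stop, stop_class)


def _random_cds(rng: np.random.Generator, n_body: int, start: str, stop: str) -> str:
    idx = rng.integers(0, len(_SAFE_CODONS), size=n_body)
    body = "".join(_SAFE_CODONS[i] for i in idx)
    return start + body + stop


def make_mito_fixture(seed: int = 0) -> MitoFixture:
    """Synthetic 16,532 bp circular mitogenome, vertebrate layout.

    13 PCGs / 22 tRNAs / 2 rRNAs / 1 control region in the canonical gene
    order; ND6 and eight tRNAs (Q, A, N, C, Y, S1, E, P) sit on the light
    strand.  COI starts with GTG, ATP6 with ATA, the rest with ATG; seven
    PCGs carry conventional stops (ATP6/ATP8 TAA, ND1/ND3/ND6 TAG,
    COII/ND4 AGA) and six end in incomplete stops (T or TA).
    """
    rng = np.random.default_rng(seed)
    pcg_plan = {name: (nb, start, stop) for name, nb, start, stop in _PCG_PLAN}

    gene_seqs: Dict[str, str] = {}
    for name, nb, start, stop in _PCG_PLAN:
        gene_seqs[name] = _random_cds(rng, nb, start, stop)
    for name, ftype in _GENE_ORDER:
        if ftype == "tRNA":
            gene_seqs[name] = _to_str(rng.integers(0, 4, size=_TRNA_LEN, dtype=np.int8))
    gene_seqs["rrnS"] = _to_str(rng.integers(0, 4, size=_RRNS_LEN, dtype=np.int8))
    gene_seqs["rrnL"] = _to_str(rng.integers(0, 4, size=_RRNL_LEN, dtype=np.int8))

    fixed = sum(len(gene_seqs[n]) for n, t in _GENE_ORDER if t != "CR")
    cr_len = MITO_TOTAL_LENGTH - fixed
    if cr_len < 200:
        raise RuntimeError("control region squeezed out; adjust gene plan")
    gene_seqs["CR"] = _to_str(rng.integers(0, 4, size=cr_len, dtype=np.int8))

    parts: List[str] = []
    features: List[MitoFeature] = []
    pos = 1
    expected: Dict[str, Tuple[str, str, str]] = {}
    for name, ftype in _GENE_ORDER:
        seq = gene_seqs[name]
        strand = "H"
        if name == "ND6" or name in _LIGHT_TRNAS:
            strand = "L"
        genomic = seq.translate(_COMPLEMENT)[::-1] if strand == "L" else seq
        parts.append(genomic)
        features.append(
            MitoFeature(
                name=name,
                ftype=ftype,
                strand=strand,
                start=pos,
                end=pos + len(seq) - 1,
            )
        )
        if ftype == "PCG":
            _, start_codon, stop = pcg_plan[name]
            cls = "incomplete" if len(stop) < 3 else "conventional"
            expected[name] = (start_codon, stop, cls)
        pos += len(seq)

    sequence = "".join(parts)
    assert len(sequence) == MITO_TOTAL_LENGTH
    annotation = MitoAnnotation(genome_length=len(sequence), features=features)
    return MitoFixture(
        sequence=sequence,
        annotation=annotation,
        translation_table=2,
        expected_codons=expected,
    )


# ---------------------------------------------------------------------------
# PSMC truth and text output
# ---------------------------------------------------------------------------


@dataclass
class PsmcTruth:
    """Known trajectory in PSMC's own parameterisation.

    ``intervals`` are (t_k in 2*N0 generations, lambda_k relative size)
    with t_0 = 0; u, s, g are the scaling constants used when converting to
    natural units.
    """

    theta0: float
    intervals: List[Tuple[float, float]]
    u: float = 2.5e-8
    s: float = 100.0
    g: float = 1.0
    rho0: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("need at least one interval")
        times = [t for t, _ in self.intervals]
        if times[0] != 0.0:
            raise ValueError("t_0 must be 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("t_k must be strictly increasing")
        if any(lam <= 0 for _, lam in self.intervals):
            raise ValueError("lambda_k must be positive")
        if self.rho0 is None:
            self.rho0 = self.theta0 / 5.0  # psmc's -r5 initial theta/rho ratio

    @property
    def n0(self) -> float:
        return self.theta0 / (4.0 * self.u * self.s)

    def ne_trajectory(self) -> Tuple[np.ndarray, np.ndarray]:
        """Truth (years, Ne) arrays under this truth's own constants."""
        n0 = self.n0
        t = np.array([tk for tk, _ in self.intervals])
        lam = np.array([lk for _, lk in self.intervals])
        return 2.0 * n0 * t * self.g, n0 * lam


def make_psmc_output(truth: PsmcTruth, n_rounds: int = 1) -> str:
    """Emit PSMC-dialect text (RD/TR/RS blocks) encoding ``truth``.

    The final round carries the truth exactly; earlier rounds (when
    ``n_rounds > 1``) are perturbed so last-round selection is observable.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    lines: List[str] = [
        "CC\tsynthetic PSMC output (genomesurvey.simulate.make_psmc_output)",
        "MM\tpattern:4+25*2+4+6",
    ]
    for r in range(n_rounds):
        final = r == n_rounds - 1
        factor = 1.0 if final else 0.8 + 0.2 * r / max(n_rounds - 1, 1)
        lines.append(f"RD\t{r}")
        lines.append(f"TR\t{truth.theta0:.10e}\t{truth.rho0:.10e}")
        for k, (t, lam) in enumerate(truth.intervals):
            lines.append(f"RS\t{k}\t{t:.10e}\t{lam * factor:.10e}\t0.0000")
        lines.append("//")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_fastq(readset: ReadSet, path) -> None:
    """Plain FASTQ with the constant placeholder quality string."""
    with open(path, "w") as fh:
        for rid, seq, qual in readset.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
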