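"""Canonical k-mer counting and spectrum-based genome survey estimates.

A genome survey estimates genome size, sequencing error rate, heterozygosity
and repeat content from the depth histogram of canonical k-mers in unassembled
short reads.  The central quantities are

* ``N_kmer`` — the total number of valid k-mer windows (the "volume"),
* ``C_kmer`` — the depth of the main histogram peak, a proxy for k-mer
  coverage, and
* ``G_size = N_kmer / C_kmer`` — the genome-size estimate, revised to
  ``G_size * (1 - error_rate)`` after attributing depth-1 k-mers to
  sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "KmerHistogram",
    "SpectrumEstimates",
    "KmerIndex",
    "NoPeakError",
    "EstimationError",
    "count_kmers",
    "build_kmer_index",
    "load_histogram",
    "save_histogram",
    "find_peak",
    "refine_peak",
    "estimate_error_rate",
    "estimate_genome_size",
    "estimate_heterozygosity",
    "estimate_repeat_ratio",
    "estimate_spectrum",
]

#: depths beyond this accumulate in the cap bin, keeping histograms bounded
DEPTH_CAP = 10_000

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


class NoPeakError(ValueError):
    """Raised when a histogram has no peak beyond the error region."""


class EstimationError(RuntimeError):
    """Raised when a spectrum estimator cannot produce a value."""


@dataclass
class KmerHistogram:
    """Depth -> number of distinct canonical k-mers observed at that depth.

    ``volume(d) = d * species(d)`` is the number of k-mer windows carried by
    depth ``d``; ``n_kmer`` (the sum of volumes) equals the total number of
    valid k-mer windows counted, provided no depth exceeded :data:`DEPTH_CAP`.
    """

    k: int
    species: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_k(self.k)
        for d, n in self.species.items():
            if d < 1 or n < 0:
                raise ValueError(f"invalid histogram entry {d} -> {n}")

    def volume(self, depth: int) -> int:
        return depth * self.species.get(depth, 0)

    @property
    def n_kmer(self) -> int:
        return sum(d * n for d, n in self.species.items())

    @property
    def n_species(self) -> int:
        return sum(self.species.values())

    @property
    def max_depth(self) -> int:
        return max(self.species) if self.species else 0

    def dense_species(self) -> np.ndarray:
        """Species counts as an array indexed by depth (index 0 unused)."""
        out = np.zeros(self.max_depth + 1, dtype=np.int64)
        for d, n in self.species.items():
            out[d] = n
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerHistogram):
            return NotImplemented
        prune = lambda m: {d: n for d, n in m.items() if n}
        return self.k == other.k and prune(self.species) == prune(other.species)


@dataclass
class SpectrumEstimates:
    """Bundle of survey estimates derived from one k-mer histogram."""

    k: int
    c_kmer: int
    c_kmer_refined: float
    n_kmer: int
    error_rate: float
    g_size: float
    revised_g_size: float
    het_rate: float
    repeat_ratio: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "k": self.k,
            "c_kmer": self.c_kmer,
            "c_kmer_refined": round(self.c_kmer_refined, 4),
            "n_kmer": self.n_kmer,
            "error_rate": self.error_rate,
            "g_size": self.g_size,
            "revised_g_size": self.revised_g_size,
            "het_rate": self.het_rate,
            "repeat_ratio": self.repeat_ratio,
        }


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd (canonical form is ill-defined for palindromes): {k}")
    if not 1 <= k <= 31:
        raise ValueError(f"k out of supported range [1, 31]: {k}")


def _encode_sequences(seqs: Iterable[str]) -> np.ndarray:
    """Concatenate sequences into one int8 array with -1 separators."""
    parts = []
    sep = np.array([-1], dtype=np.int8)
    for s in seqs:
        parts.append(_ENCODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)])
        parts.append(sep)
    if not parts:
        return np.empty(0, dtype=np.int8)
    return np.concatenate(parts)


def _canonical_codes(vals: np.ndarray, k: int) -> np.ndarray:
    """2-bit codes of canonical k-mers for every valid window in ``vals``.

    ``vals`` holds 0..3 for A,C,G,T and negative values for N/separators;
    windows containing a negative value are dropped.  The canonical form is
    the lexicographic minimum of a k-mer and its reverse complement, which
    for the 2-bit A<C<G<T encoding coincides with the numeric minimum.
    """
    n = vals.shape[0]
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    v = vals.astype(np.int64)
    invalid = v < 0
    v = np.where(invalid, 0, v)
    fwd = np.zeros(m, dtype=np.int64)
    rc = np.zeros(m, dtype=np.int64)
    for j in range(k):
        w = v[j : j + m]
        fwd = (fwd << 2) | w
        rc |= (3 - w) << (2 * j)
    csum = np.concatenate([[0], np.cumsum(invalid)])
    bad = (csum[k:] - csum[:m]) > 0
    return np.minimum(fwd, rc)[~bad].astype(np.uint64)


def _all_codes(reads: Iterable[str], k: int) -> np.ndarray:
    _check_k(k)
    # non-ACGT characters (N and any IUPAC ambiguity code) break windows
    return _canonical_codes(_encode_sequences(reads), k)


def count_kmers(reads: Iterable[str], k: int) -> KmerHistogram:
    """Count canonical k-mers in ``reads`` and return their depth histogram.

    Every window of ``k`` consecutive non-N bases contributes one count to its
    canonical k-mer; windows containing N are skipped.  Depths above
    :data:`DEPTH_CAP` are folded into the cap bin.
    """
    codes = _all_codes(reads, k)
    if codes.size == 0:
        return KmerHistogram(k=k, species={})
    _, counts = np.unique(codes, return_counts=True)
    counts = np.minimum(counts, DEPTH_CAP)
    depths, species = np.unique(counts, return_counts=True)
    return KmerHistogram(k=k, species={int(d): int(s) for d, s in zip(depths, species)})


@dataclass
class KmerIndex:
    """Multiplicity lookup for canonical k-mers (sorted codes + counts)."""

    k: int
    codes: np.ndarray
    counts: np.ndarray

    def depths(self, sequence: str) -> np.ndarray:
        """Multiplicity of the canonical k-mer starting at each position.

        Positions whose window contains an N (or runs off the end) are
        returned as NaN.
        """
        n = len(sequence)
        out = np.full(max(n - self.k + 1, 0), np.nan)
        if out.size == 0:
            return out
        vals = _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
        m = n - self.k + 1
        v = vals.astype(np.int64)
        invalid = v < 0
        v = np.where(invalid, 0, v)
        fwd = np.zeros(m, dtype=np.int64)
        rc = np.zeros(m, dtype=np.int64)
        for j in range(self.k):
            w = v[j : j + m]
            fwd = (fwd << 2) | w
            rc |= (3 - w) << (2 * j)
        csum = np.concatenate([[0], np.cumsum(invalid)])
        ok = (csum[self.k :] - csum[:m]) == 0
        canon = np.minimum(fwd, rc).astype(np.uint64)
        pos = np.searchsorted(self.codes, canon)
        pos = np.minimum(pos, len(self.codes) - 1)
        hit = self.codes[pos] == canon
        vals_out = np.where(hit, self.counts[pos], 0).astype(float)
        out[ok] = vals_out[ok]
        return out

    def histogram(self) -> KmerHistogram:
        capped = np.minimum(self.counts, DEPTH_CAP)
        depths, species = np.unique(capped, return_counts=True)
        return KmerHistogram(k=self.k, species={int(d): int(s) for d, s in zip(depths, species)})


def build_kmer_index(reads: Iterable[str], k: int) -> KmerIndex:
    """Count canonical k-mers, keeping the full code -> multiplicity map."""
    codes = _all_codes(reads, k)
    uniq, counts = np.unique(codes, return_counts=True)
    return KmerIndex(k=k, codes=uniq, counts=counts)


def save_histogram(hist: KmerHistogram, path: str | Path) -> None:
    """Write the two-column ``depth count`` text dialect, ascending depth."""
    with open(path, "w") as fh:
        for d in sorted(hist.species):
            fh.write(f"{d}\t{hist.species[d]}\n")


def load_histogram(path: str | Path, k: int = 19) -> KmerHistogram:
    """Read a two-column ``depth count`` histogram (jellyfish/kmerfreq style)."""
    species: Dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
            try:
                d, n = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
            species[d] = species.get(d, 0) + n
    return KmerHistogram(k=k, species=species)


def _smoothed_species(hist: KmerHistogram) -> np.ndarray:
    dense = hist.dense_species().astype(float)
    # window-3 moving average with edge-corrected window sizes
    sm = np.convolve(dense[1:], np.ones(3), mode="same")
    norm = np.convolve(np.ones(dense.size - 1), np.ones(3), mode="same")
    return np.concatenate([[0.0], sm / norm])  # keep depth-indexing


def find_peak(hist: KmerHistogram) -> int:
    """Main-peak depth of the spectrum, past the low-depth error region.

    The species curve is smoothed with a window-3 moving average; the error
    region is its initial descending stretch, ending at the first local
    minimum (depth 1 itself when the curve starts by rising, i.e. there is
    no error peak).  The peak is the depth with the largest raw species
    count strictly beyond that boundary; ties break toward the smaller
    depth.  A curve that only descends has no post-error peak.
    """
    if not hist.species:
        raise NoPeakError("empty histogram")
    dmax = hist.max_depth
    if dmax < 3:
        raise NoPeakError("histogram too narrow to contain a post-error peak")
    sm = _smoothed_species(hist)
    first_min = 1
    while first_min < dmax and sm[first_min + 1] < sm[first_min]:
        first_min += 1
    if first_min == dmax:
        raise NoPeakError("species curve is monotone decreasing; no post-error peak")
    dense = hist.dense_species()
    region = dense[first_min + 1 :]
    if region.size == 0 or region.max() == 0:
        raise NoPeakError("no k-mer species beyond the error region")
    return int(first_min + 1 + int(np.argmax(region)))


def _mixture_window(hist: KmerHistogram, peak: float) -> Tuple[np.ndarray, np.ndarray]:
    """Depths [peak/4, 1.5*peak] and their species counts (zero-padded)."""
    lo = max(2, int(round(peak / 4)))
    hi = int(round(1.5 * peak))
    dense = hist.dense_species().astype(float)
    if hi >= dense.size:
        dense = np.concatenate([dense, np.zeros(hi + 1 - dense.size)])
    depths = np.arange(lo, hi + 1)
    return depths, dense[lo : hi + 1]


def _mixture_fit(depths: np.ndarray, y: np.ndarray, lam: float) -> Tuple[float, float, float]:
    """NNLS amplitudes (half-depth, full-depth) and SSE at coverage ``lam``."""
    basis = np.column_stack(
        [stats.poisson.pmf(depths, lam / 2.0), stats.poisson.pmf(depths, lam)]
    )
    (a_half, a_full), _ = nnls(basis, y)
    resid = y - basis @ np.array([a_half, a_full])
    return a_half, a_full, float(resid @ resid)


def refine_peak(hist: KmerHistogram, peak: int, halfwidth: float = 3.0) -> float:
    """Sub-integer k-mer coverage by a continuous two-Poisson mixture fit.

    The true k-mer coverage ``c * (L_read - k + 1) / L_read`` is rarely an
    integer, and the sampled mode wobbles by +/-1; fitting the mixture of
    half-depth (heterozygous) and full-depth (homozygous) Poisson components
    with a continuous mean recovers the coverage with far less quantisation
    error than the mode itself, which matters directly for
    ``G = N_kmer / C_kmer``.
    """
    from scipy.optimize import minimize_scalar

    depths, y = _mixture_window(hist, peak)
    if y.sum() == 0:
        return float(peak)
    res = minimize_scalar(
        lambda lam: _mixture_fit(depths, y, lam)[2],
        bounds=(max(2.0, peak - halfwidth), peak + halfwidth),
        method="bounded",
    )
    return float(res.x)


def estimate_error_rate(hist: KmerHistogram) -> float:
    """Fraction of k-mer volume at depth 1, attributed to sequencing error."""
    n = hist.n_kmer
    if n == 0:
        return 0.0
    return hist.volume(1) / n


def estimate_genome_size(hist: KmerHistogram, peak: float) -> Tuple[float, float]:
    """Genome size ``G = N_kmer / C_kmer`` and its error-revised value.

    ``peak`` may be the integer mode from :func:`find_peak` or the refined
    coverage from :func:`refine_peak`.  The revision multiplies by
    ``1 - error_rate``, which is algebraically identical to
    ``(N_kmer - volume(1)) / C_kmer``.
    """
    if peak < 2:
        raise ValueError(f"peak depth must be >= 2, got {peak}")
    # a refined (fractional) coverage may sit just past the last occupied bin
    if peak > hist.max_depth + 1:
        raise ValueError(f"peak {peak} outside histogram depth range")
    n = hist.n_kmer
    g = n / peak
    revised = (n - hist.volume(1)) / peak
    return g, revised


def estimate_heterozygosity(hist: KmerHistogram, peak: float, k: int | None = None) -> float:
    """Per-base heterozygosity from the half-depth spectrum component.

    In a diploid, k-mers spanning a heterozygous site occur on one haplotype
    only and pile up at half the homozygous coverage.  A two-component
    Poisson mixture with fixed means ``peak/2`` and ``peak`` is fitted to the
    species counts over depths ``[peak/4, 1.5*peak]`` by non-negative least
    squares.  With alpha the half-depth component's share of k-mer volume
    (each het locus yields two half-depth species, so the volume share equals
    the fraction of het k-mer loci), the per-base rate is recovered through
    ``r = 1 - (1 - alpha)**(1/k)``.
    """
    if k is None:
        k = hist.k
    if peak < 4:
        raise ValueError(f"peak depth must be >= 4 for the mixture fit, got {peak}")
    depths, y = _mixture_window(hist, peak)
    try:
        a_half, a_full, _ = _mixture_fit(depths, y, float(peak))
    except Exception as exc:  # pragma: no cover - nnls is robust in practice
        raise EstimationError(f"mixture fit failed: {exc}") from exc
    if a_half + a_full <= 0:
        raise EstimationError("mixture fit degenerate: no species mass in the fit window")
    alpha = a_half / (a_half + 2.0 * a_full)
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


def estimate_repeat_ratio(hist: KmerHistogram, peak: float) -> float:
    """Share of non-error k-mer volume at depths >= 1.5x the main peak.

    Repetitive sequence produces k-mers at integer multiples of the
    homozygous coverage; 1.5x the peak splits the single-copy peak from the
    2x-and-up repeat peaks.
    """
    if peak < 2:
        raise ValueError(f"peak depth must be >= 2, got {peak}")
    thr = int(round(1.5 * peak))
    denom = hist.n_kmer - hist.volume(1)
    if denom <= 0:
        return 0.0
    num = sum(d * n for d, n in hist.species.items() if d >= thr)
    return num / denom


def estimate_spectrum(hist: KmerHistogram, k: int | None = None) -> SpectrumEstimates:
    """Run the full estimator chain on one histogram."""
    if k is None:
        k = hist.k
    peak = find_peak(hist)
    c = refine_peak(hist, peak)
    err = estimate_error_rate(hist)
    g, revised = estimate_genome_size(hist, c)
    het = estimate_heterozygosity(hist, c, k) if peak >= 4 else float("nan")
    rep = estimate_repeat_ratio(hist, c)
    return SpectrumEstimates(
        k=k,
        c_kmer=peak,
        c_kmer_refined=c,
        n_kmer=hist.n_kmer,
        error_rate=err,
        g_size=g,
        revised_g_size=revised,
        het_rate=het,
        repeat_ratio=rep,
    )
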