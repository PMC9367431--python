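"""Assembly summary statistics: N50/N90, GC content, contig splitting, GC-depth.

These are the draft-assembly numbers a genome survey tabulates: total
length/number, longest sequence, Nxx lengths (smallest length L such that
sequences of length >= L cover xx% of the assembly) and GC percentage, at
both scaffold and contig level (contigs obtained by splitting scaffolds on
N runs).  The GC-depth table pairs windowed GC content with mean canonical
k-mer multiplicity, the scatter used to screen for contamination and
coverage bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

from .kmer import KmerIndex

__all__ = [
    "AssemblyMetrics",
    "GCDepthPoint",
    "nxx",
    "assembly_metrics",
    "scaffold_to_contigs",
    "gc_depth_table",
    "read_fasta",
    "write_fasta",
]

SeqInput = Union[str, Path, Iterable[Tuple[str, str]]]


@dataclass
class AssemblyMetrics:
    total_length: int
    total_number: int
    max_length: int
    n50: int
    n90: int
    gc_percent: float


@dataclass
class GCDepthPoint:
    seq_id: str
    window_start: int  # 1-based
    gc_percent: float
    mean_depth: float


def read_fasta(source: SeqInput) -> List[Tuple[str, str]]:
    """Normalise a FASTA path or (id, sequence) iterable to a record list."""
    if isinstance(source, (str, Path)):
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(source), "fasta")]
    return [(sid, seq.upper()) for sid, seq in source]


def write_fasta(records: Iterable[Tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping (default 60 columns)."""
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def nxx(lengths: Sequence[int], x: float) -> int:
    """Nxx length: smallest L with cumulative length of sequences >= L
    covering at least x% of the total (descending-sort convention)."""
    if len(lengths) == 0:
        raise ValueError("nxx of an empty length list is undefined")
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    target = x / 100.0 * arr.sum()
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, target, side="left"))
    return int(arr[idx])


def _gc_count(seq: str) -> Tuple[int, int]:
    """(G+C, A+C+G+T) counts; ambiguous bases excluded from both."""
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc, acgt


def assembly_metrics(source: SeqInput) -> AssemblyMetrics:
    """Survey-table metrics for one assembly (scaffold or contig set)."""
    records = read_fasta(source)
    if not records:
        raise ValueError("empty FASTA: no sequences to summarise")
    lengths = [len(seq) for _, seq in records]
    gc = acgt = 0
    for _, seq in records:
        g, a = _gc_count(seq)
        gc += g
        acgt += a
    return AssemblyMetrics(
        total_length=sum(lengths),
        total_number=len(lengths),
        max_length=max(lengths),
        n50=nxx(lengths, 50),
        n90=nxx(lengths, 90),
        gc_percent=100.0 * gc / acgt if acgt else 0.0,
    )


def scaffold_to_contigs(source: SeqInput) -> List[Tuple[str, str]]:
    """Split each scaffold on runs of one or more N into contigs.

    Non-empty pieces keep input order with ``_ctg<i>`` suffixed ids; non-N
    bases are conserved exactly.
    """
    out: List[Tuple[str, str]] = []
    for sid, seq in read_fasta(source):
        pieces = [p for p in seq.split("N") if p]
        if len(pieces) == 1 and pieces[0] == seq:
            out.append((sid, seq))
        else:
            for i, piece in enumerate(pieces, 1):
                out.append((f"{sid}_ctg{i}", piece))
    return out


def gc_depth_table(
    source: SeqInput,
    index: KmerIndex,
    window: int = 500,
) -> List[GCDepthPoint]:
    """Windowed GC%% vs mean k-mer depth over an assembly.

    For each non-overlapping window the GC percentage (ambiguous bases
    excluded) is paired with the mean multiplicity, in ``index``, of the
    canonical k-mers starting in the window.  Windows with more than 50% N
    are skipped.
    """
    if window < index.k:
        raise ValueError(f"window ({window}) must be >= k ({index.k})")
    points: List[GCDepthPoint] = []
    for sid, seq in read_fasta(source):
        depths = index.depths(seq)
        for w0 in range(0, len(seq), window):
            chunk = seq[w0 : w0 + window]
            if len(chunk) < index.k:
                continue
            if chunk.count("N") > 0.5 * len(chunk):
                continue
            gc, acgt = _gc_count(chunk)
            d = depths[w0 : min(w0 + window, depths.size)]
            d = d[~np.isnan(d)]
            points.append(
                GCDepthPoint(
                    seq_id=sid,
                    window_start=w0 + 1,
                    gc_percent=100.0 * gc / acgt if acgt else 0.0,
                    mean_depth=float(d.mean()) if d.size else 0.0,
                )
            )
    return points
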