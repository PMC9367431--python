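"""Perfect and compound microsatellite (SSR) mining and census statistics.

Finds maximal perfect tandem repeats of 2-6 bp motifs (MISA-style thresholds:
at least 6 copies for dinucleotides, 5 for tri- through hexanucleotides),
merges neighbouring loci separated by a short interruption into compound
records, and tabulates the census a survey paper reports: totals, per-period
and per-motif percentages, density per Mb.

Motif phase is preserved: AC and CA arrays are counted separately, matching
how survey reports list them.  ``canonical_motif`` is available for callers
who want phase/strand classes collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "SSRRecord",
    "SSRSummary",
    "DEFAULT_MIN_REPEATS",
    "find_ssrs",
    "merge_compound",
    "summarize_ssrs",
    "canonical_motif",
    "minimal_period",
]

DEFAULT_MIN_REPEATS: Dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SSRRecord:
    """One microsatellite locus (perfect, or compound after merging).

    Coordinates are 1-based inclusive.  For perfect records
    ``end - start + 1 == len(motif) * repeats``; compound records span their
    constituents and keep them in ``constituents``.
    """

    seq_id: str
    index: int  # 1-based running number within the sequence
    ssr_type: str  # p2..p6 for perfect records, c for compound
    motif: str  # as it occurs in sequence (phase preserved); "" for compound
    repeats: int
    start: int
    end: int
    standardized: str  # e.g. "(AC)6" or "(AC)6tt(GA)5"
    constituents: List["SSRRecord"] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SSRSummary:
    """Census of an SSR run over a sequence set (survey Table-2 style)."""

    sequences_examined: int
    total_length: int
    total_ssrs: int
    sequences_with_ssr: int
    sequences_with_more_than_one_ssr: int
    compound_ssrs: int
    density_per_mb: float
    type_counts: Dict[str, int]
    type_percentages: Dict[str, float]
    motif_percentages: Dict[int, Dict[str, float]]


def minimal_period(motif: str) -> int:
    """Length of the shortest unit whose repetition equals ``motif``."""
    n = len(motif)
    for q in range(1, n + 1):
        if n % q == 0 and motif == motif[:q] * (n // q):
            return q
    return n  # pragma: no cover - q == n always matches


def canonical_motif(motif: str) -> str:
    """Smallest rotation of the motif or its reverse complement."""
    rc = motif.translate(_COMPLEMENT)[::-1]
    rotations = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(rotations)


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq


def _maximal_runs(seq: str, period: int) -> Iterable[Tuple[int, int, str]]:
    """Yield (start0, repeats, motif) for maximal perfect runs of ``period``.

    A run is a maximal stretch where ``seq[i] == seq[i+period]`` (both
    non-N); partial trailing copies are truncated.  ``start0`` is 0-based.
    """
    n = len(seq)
    i = 0
    limit = n - period
    while i < limit:
        if seq[i] != seq[i + period] or seq[i] == "N":
            i += 1
            continue
        j = i
        while j < limit and seq[j] == seq[j + period] and seq[j] != "N":
            j += 1
        # matches cover i..j-1; run spans i .. j-1+period
        run_len = (j - i) + period
        repeats = run_len // period
        if repeats >= 2:
            yield i, repeats, seq[i : i + period]
        i = j + 1


def find_ssrs(
    sequence: str,
    min_repeats: Optional[Mapping[int, int]] = None,
    seq_id: str = "seq",
) -> List[SSRRecord]:
    """Find perfect SSRs of period 2-6 in one sequence.

    Returns maximal perfect tandem runs whose motif's minimal period equals
    the record's period (so e.g. an (ATAT) candidate is classified as AT, and
    homopolymer runs are never reported).  Overlapping candidates of
    different periods are resolved greedily: longer span wins, ties prefer
    the smaller period, then the smaller start.  N breaks every run.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    seq = _validate_sequence(sequence)
    candidates: List[Tuple[int, int, int, int, str]] = []  # (-span, period, start0, end0, motif)
    for period in sorted(min_repeats):
        if not 2 <= period <= 6:
            raise ValueError(f"SSR search supports periods 2-6 only, got {period}")
        for start0, repeats, motif in _maximal_runs(seq, period):
            if repeats < min_repeats[period]:
                continue
            if minimal_period(motif) != period:
                continue
            span = period * repeats
            candidates.append((-span, period, start0, start0 + span - 1, motif))
    candidates.sort()
    accepted: List[Tuple[int, int, int, str, int]] = []  # (start0, end0, period, motif, repeats)
    occupied: List[Tuple[int, int]] = []
    for negspan, period, s0, e0, motif in candidates:
        if any(s0 <= oe and e0 >= os_ for os_, oe in occupied):
            continue
        occupied.append((s0, e0))
        accepted.append((s0, e0, period, motif, (-negspan) // period))
    accepted.sort()
    records = []
    for idx, (s0, e0, period, motif, repeats) in enumerate(accepted, 1):
        records.append(
            SSRRecord(
                seq_id=seq_id,
                index=idx,
                ssr_type=f"p{period}",
                motif=motif,
                repeats=repeats,
                start=s0 + 1,
                end=e0 + 1,
                standardized=f"({motif}){repeats}",
            )
        )
    return records


def merge_compound(
    records: Sequence[SSRRecord],
    max_interruption: int = 100,
    sequence: Optional[str] = None,
) -> List[SSRRecord]:
    """Merge neighbouring SSRs separated by <= ``max_interruption`` bp.

    Consecutive perfect records on the same sequence whose gap is at most
    ``max_interruption`` become one compound (type ``c``) record spanning
    both, with the interruption lowercased in the standardized string (or
    rendered as ``n``s when the sequence is not supplied).  Other records
    pass through unchanged; indices are renumbered by position.
    """
    by_seq: Dict[str, List[SSRRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.seq_id, []).append(rec)
    out: List[SSRRecord] = []
    for seq_id in by_seq:
        recs = sorted(by_seq[seq_id], key=lambda r: r.start)
        groups: List[List[SSRRecord]] = []
        for rec in recs:
            if groups and rec.start - groups[-1][-1].end - 1 <= max_interruption:
                groups[-1].append(rec)
            else:
                groups.append([rec])
        for idx, group in enumerate(groups, 1):
            if len(group) == 1:
                rec = group[0]
                out.append(
                    SSRRecord(
                        seq_id=rec.seq_id,
                        index=idx,
                        ssr_type=rec.ssr_type,
                        motif=rec.motif,
                        repeats=rec.repeats,
                        start=rec.start,
                        end=rec.end,
                        standardized=rec.standardized,
                    )
                )
                continue
            parts = [group[0].standardized]
            for prev, nxt in zip(group, group[1:]):
                gap = nxt.start - prev.end - 1
                if sequence is not None:
                    filler = sequence[prev.end : nxt.start - 1].lower()
                else:
                    filler = "n" * gap
                parts.append(filler)
                parts.append(nxt.standardized)
            out.append(
                SSRRecord(
                    seq_id=seq_id,
                    index=idx,
                    ssr_type="c",
                    motif="",
                    repeats=0,
                    start=group[0].start,
                    end=group[-1].end,
                    standardized="".join(parts),
                    constituents=list(group),
                )
            )
    out.sort(key=lambda r: (r.seq_id, r.start))
    return out


def _perfect_constituents(records: Iterable[SSRRecord]) -> Tuple[List[SSRRecord], int]:
    perfect: List[SSRRecord] = []
    in_compound = 0
    for rec in records:
        if rec.ssr_type == "c":
            perfect.extend(rec.constituents)
            in_compound += len(rec.constituents)
        else:
            perfect.append(rec)
    return perfect, in_compound


def summarize_ssrs(
    records: Sequence[SSRRecord],
    sequences_examined: int,
    total_length: int,
) -> SSRSummary:
    """Tabulate the SSR census over a sequence set.

    ``records`` may be the raw ``find_ssrs`` output or the ``merge_compound``
    output; compound records contribute their perfect constituents to the
    per-period totals and to the "present in compound formation" count.
    """
    if total_length <= 0:
        raise ValueError(f"total_length must be positive, got {total_length}")
    perfect, compound_ssrs = _perfect_constituents(records)
    type_counts = {f"p{p}": 0 for p in range(2, 7)}
    motif_counts: Dict[int, Dict[str, int]] = {p: {} for p in range(2, 7)}
    per_seq: Dict[str, int] = {}
    for rec in perfect:
        type_counts[rec.ssr_type] += 1
        period = len(rec.motif)
        motif_counts[period][rec.motif] = motif_counts[period].get(rec.motif, 0) + 1
        per_seq[rec.seq_id] = per_seq.get(rec.seq_id, 0) + 1
    total = len(perfect)
    type_pct = {t: (100.0 * c / total if total else 0.0) for t, c in type_counts.items()}
    motif_pct = {
        p: {m: 100.0 * c / total for m, c in sorted(counts.items())}
        for p, counts in motif_counts.items()
        if total
    }
    return SSRSummary(
        sequences_examined=sequences_examined,
        total_length=total_length,
        total_ssrs=total,
        sequences_with_ssr=len(per_seq),
        sequences_with_more_than_one_ssr=sum(1 for c in per_seq.values() if c > 1),
        compound_ssrs=compound_ssrs,
        density_per_mb=total / (total_length / 1e6),
        type_counts=type_counts,
        type_percentages=type_pct,
        motif_percentages=motif_pct if total else {p: {} for p in range(2, 7)},
    )
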