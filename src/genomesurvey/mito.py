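"""Circular mitochondrial genome census: features, strands, codons, composition.

A vertebrate mitogenome is a ~16.5 kb closed circle carrying 13 protein-coding
genes (PCGs), 22 tRNAs, 2 rRNAs and 1 control region (D-loop), most on the
heavy (H) strand with ND6 and a handful of tRNAs on the light (L) strand.
This module reads an annotation (6-column TSV or GenBank flat file), counts
features by type and strand, extracts CDSs honouring strand and origin wrap,
and classifies start and stop codons — including the incomplete stops (T/TA,
completed to TAA by polyadenylation) typical of mitochondrial transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

from Bio import SeqIO

__all__ = [
    "MitoFeature",
    "MitoAnnotation",
    "FeatureCensus",
    "GeneCodons",
    "CodonReport",
    "CONVENTIONAL_STOPS",
    "FEATURE_TYPES",
    "read_annotation",
    "write_annotation_tsv",
    "feature_census",
    "extract_feature_sequence",
    "codon_report",
    "composition",
]

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "CR")

#: vertebrate mitochondrial stop codons (translation table 2)
CONVENTIONAL_STOPS = {"TAA", "TAG", "AGA", "AGG"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MitoFeature:
    name: str
    ftype: str  # PCG | tRNA | rRNA | CR
    strand: str  # H | L
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive; < start only when wraps_origin
    wraps_origin: bool = False


@dataclass
class MitoAnnotation:
    """Feature table of one circular genome, 1-based inclusive coordinates."""

    genome_length: int
    features: List[MitoFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            self._validate(f)

    def _validate(self, f: MitoFeature) -> None:
        if f.ftype not in FEATURE_TYPES:
            raise ValueError(f"{f.name}: unknown feature type {f.ftype!r}")
        if f.strand not in ("H", "L"):
            raise ValueError(f"{f.name}: strand must be H or L, got {f.strand!r}")
        L = self.genome_length
        if not (1 <= f.start <= L and 1 <= f.end <= L):
            raise ValueError(f"{f.name}: coordinates {f.start}-{f.end} outside 1..{L}")
        if not f.wraps_origin and f.start > f.end:
            raise ValueError(f"{f.name}: start > end without wraps_origin flag")

    def pcgs(self) -> List[MitoFeature]:
        return [f for f in self.features if f.ftype == "PCG"]


@dataclass
class FeatureCensus:
    by_type: Dict[str, int]
    by_strand: Dict[str, int]


@dataclass
class GeneCodons:
    name: str
    start_codon: str
    stop_codon: str  # 1-3 nt
    stop_class: str  # conventional | incomplete


@dataclass
class CodonReport:
    genes: List[GeneCodons]

    def by_gene(self) -> Dict[str, GeneCodons]:
        return {g.name: g for g in self.genes}


_TSV_HEADER = ["name", "type", "strand", "start", "end", "wraps_origin"]


def write_annotation_tsv(ann: MitoAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#genome_length={ann.genome_length}\n")
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for f in ann.features:
            fh.write(
                f"{f.name}\t{f.ftype}\t{f.strand}\t{f.start}\t{f.end}\t"
                f"{int(f.wraps_origin)}\n"
            )


def _read_annotation_tsv(path: str | Path) -> MitoAnnotation:
    genome_length = None
    features: List[MitoFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#genome_length="):
                genome_length = int(line.split("=", 1)[1])
                continue
            if line.startswith("#") or line.split("\t")[0] == "name":
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            features.append(
                MitoFeature(
                    name=fields[0],
                    ftype=fields[1],
                    strand=fields[2],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    wraps_origin=bool(int(fields[5])),
                )
            )
    if genome_length is None:
        raise ValueError(f"{path}: missing '#genome_length=' header line")
    return MitoAnnotation(genome_length=genome_length, features=features)


def _read_annotation_genbank(path: str | Path) -> MitoAnnotation:
    record = SeqIO.read(str(path), "genbank")
    type_map = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}
    features: List[MitoFeature] = []
    for feat in record.features:
        if feat.type in type_map:
            ftype = type_map[feat.type]
        elif feat.type in ("D-loop", "misc_feature"):
            ftype = "CR"
        else:
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("product", [None])[0]
            or ftype
        )
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        wraps = len(parts) > 1 and int(parts[0].start) == 0 and int(parts[-1].end) == len(record.seq)
        if wraps:
            start = int(parts[-1].start) + 1
            end = int(parts[0].end)
        else:
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
        strand = "L" if feat.location.strand == -1 else "H"
        features.append(MitoFeature(name, ftype, strand, start, end, wraps))
    return MitoAnnotation(genome_length=len(record.seq), features=features)


def read_annotation(path: str | Path) -> MitoAnnotation:
    """Read a feature table from the 6-column TSV dialect or a GenBank file."""
    with open(path) as fh:
        head = fh.read(256)
    if head.startswith("LOCUS"):
        return _read_annotation_genbank(path)
    return _read_annotation_tsv(path)


def feature_census(ann: MitoAnnotation) -> FeatureCensus:
    """Counts of features by type (PCG/tRNA/rRNA/CR) and by strand (H/L)."""
    by_type = {t: 0 for t in FEATURE_TYPES}
    by_strand = {"H": 0, "L": 0}
    for f in ann.features:
        by_type[f.ftype] += 1
        by_strand[f.strand] += 1
    return FeatureCensus(by_type=by_type, by_strand=by_strand)


def extract_feature_sequence(sequence: str, feature: MitoFeature) -> str:
    """Feature sequence honouring origin wrap and strand (revcomp for L)."""
    seq = sequence.upper()
    if feature.wraps_origin:
        raw = seq[feature.start - 1 :] + seq[: feature.end]
    else:
        raw = seq[feature.start - 1 : feature.end]
    if feature.strand == "L":
        raw = raw.translate(_COMPLEMENT)[::-1]
    return raw


def codon_report(sequence: str, ann: MitoAnnotation) -> CodonReport:
    """Start/stop codons of every protein-coding gene.

    The stop is the trailing 1-3 nt left after whole codons: a full final
    codon for CDS lengths divisible by 3, otherwise the 1-2 nt overhang,
    classified as an incomplete stop.
    """
    genes: List[GeneCodons] = []
    for f in ann.pcgs():
        cds = extract_feature_sequence(sequence, f)
        if len(cds) < 6:
            raise ValueError(f"{f.name}: CDS shorter than 6 nt ({len(cds)})")
        overhang = len(cds) % 3
        stop = cds[-3:] if overhang == 0 else cds[-overhang:]
        genes.append(
            GeneCodons(
                name=f.name,
                start_codon=cds[:3],
                stop_codon=stop,
                stop_class="incomplete" if overhang else "conventional",
            )
        )
    return CodonReport(genes=genes)


def composition(sequence: str) -> Tuple[int, float, float]:
    """(length, GC%, AT%) with percentages over unambiguous bases."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    if denom == 0:
        return len(seq), 0.0, 0.0
    return len(seq), 100.0 * gc / denom, 100.0 * at / denom
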