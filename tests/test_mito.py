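"""Mitochondrial census tests: annotation I/O, strand/wrap extraction, codons."""

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from genomesurvey import mito
from genomesurvey.mito import (
    MitoAnnotation,
    MitoFeature,
    codon_report,
    composition,
    extract_feature_sequence,
    feature_census,
    read_annotation,
    write_annotation_tsv,
)


class TestAnnotationIO:
    def test_tsv_round_trip(self, tmp_path, mito_fixture):
        path = tmp_path / "ann.tsv"
        write_annotation_tsv(mito_fixture.annotation, path)
        back = read_annotation(path)
        assert back == mito_fixture.annotation

    def test_fixture_has_38_features(self, mito_fixture):
        assert len(mito_fixture.annotation.features) == 38  # 13 + 22 + 2 + 1

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="outside"):
            MitoAnnotation(100, [MitoFeature("x", "PCG", "H", 1, 200)])
        with pytest.raises(ValueError, match="wraps_origin"):
            MitoAnnotation(100, [MitoFeature("x", "PCG", "H", 50, 10)])
        with pytest.raises(ValueError, match="strand"):
            MitoAnnotation(100, [MitoFeature("x", "PCG", "+", 1, 10)])

    def test_genbank_reader(self, tmp_path):
        seq = Seq("ATGAAACCCGGGTTTTAAACGTACGTACGTGGGCCCAAATTTACGT" * 4)
        rec = SeqRecord(seq, id="toy", annotations={"molecule_type": "DNA"})
        rec.features = [
            SeqFeature(FeatureLocation(0, 21, strand=1), type="CDS",
                       qualifiers={"gene": ["ND1"]}),
            SeqFeature(FeatureLocation(30, 100, strand=-1), type="tRNA",
                       qualifiers={"product": ["trnQ"]}),
            SeqFeature(FeatureLocation(100, 120, strand=1), type="rRNA",
                       qualifiers={"gene": ["rrnS"]}),
            SeqFeature(CompoundLocation([FeatureLocation(170, len(seq), strand=1),
                                         FeatureLocation(0, 10, strand=1)]),
                       type="D-loop"),
        ]
        path = tmp_path / "toy.gb"
        SeqIO.write([rec], path, "genbank")
        ann = read_annotation(path)
        by_name = {f.name: f for f in ann.features}
        assert by_name["ND1"].ftype == "PCG" and by_name["ND1"].start == 1
        assert by_name["ND1"].end == 21
        assert by_name["trnQ"].strand == "L"
        assert by_name["rrnS"].ftype == "rRNA"
        cr = [f for f in ann.features if f.ftype == "CR"][0]
        assert cr.wraps_origin and cr.start == 171 and cr.end == 10


class TestCensus:
    def test_fixture_census(self, mito_fixture):
        census = feature_census(mito_fixture.annotation)
        assert census.by_type == {"PCG": 13, "tRNA": 22, "rRNA": 2, "CR": 1}
        assert census.by_strand == {"H": 29, "L": 9}

    def test_empty_annotation(self):
        census = feature_census(MitoAnnotation(100, []))
        assert census.by_type == {"PCG": 0, "tRNA": 0, "rRNA": 0, "CR": 0}
        assert census.by_strand == {"H": 0, "L": 0}

    def test_reordering_invariance(self, mito_fixture):
        ann = mito_fixture.annotation
        shuffled = MitoAnnotation(ann.genome_length, list(reversed(ann.features)))
        assert feature_census(shuffled) == feature_census(ann)


class TestExtraction:
    def test_light_strand_is_reverse_complement(self):
        # 18-nt toy CDS on the light strand, hand reverse-complemented
        cds = "ATGAAACCCGGGTTTTAA"
        genome = "TTTT" + str(Seq(cds).reverse_complement()) + "GGGG"
        feat = MitoFeature("toy", "PCG", "L", 5, 22)
        assert extract_feature_sequence(genome, feat) == cds

    def test_wrapped_feature_equals_rotation(self, mito_fixture):
        seq = mito_fixture.sequence
        L = len(seq)
        shift = 1000  # rotate so late features wrap the origin
        rotated = seq[-shift:] + seq[:-shift]
        for f in mito_fixture.annotation.features:
            ns = f.start + shift
            ne = f.end + shift
            wraps = ns <= L < ne
            nf = MitoFeature(f.name, f.ftype, f.strand,
                             (ns - 1) % L + 1, (ne - 1) % L + 1, wraps_origin=wraps)
            assert extract_feature_sequence(rotated, nf) == extract_feature_sequence(seq, f)


class TestCodonReport:
    def test_fixture_codons(self, mito_fixture):
        report = codon_report(mito_fixture.sequence, mito_fixture.annotation)
        by_gene = report.by_gene()
        assert len(by_gene) == 13
        for name, (start, stop, cls) in mito_fixture.expected_codons.items():
            g = by_gene[name]
            assert g.start_codon == start
            assert g.stop_codon == stop
            assert g.stop_class == cls

    def test_start_matches_biopython_translation_frame(self, mito_fixture):
        # the reported start codon is the first codon of the strand-aware CDS
        ann = mito_fixture.annotation
        report = codon_report(mito_fixture.sequence, ann).by_gene()
        for f in ann.pcgs():
            cds = extract_feature_sequence(mito_fixture.sequence, f)
            trimmed = cds[: 3 * (len(cds) // 3)]
            aa = str(Seq(trimmed).translate(table=2))
            assert report[f.name].start_codon == trimmed[:3]
            assert "*" not in aa[:-1]  # no internal stops in the fixture CDSs

    def test_incomplete_stop_definition(self):
        # CDS length = 1 mod 3 ending in T -> stop "T", incomplete
        genome = "ATG" + "AAA" * 3 + "T"
        ann = MitoAnnotation(len(genome), [MitoFeature("g", "PCG", "H", 1, len(genome))])
        g = codon_report(genome, ann).genes[0]
        assert g.stop_codon == "T" and g.stop_class == "incomplete"

    def test_short_cds_rejected(self):
        ann = MitoAnnotation(10, [MitoFeature("g", "PCG", "H", 1, 4)])
        with pytest.raises(ValueError, match="shorter"):
            codon_report("ACGTACGTAC", ann)


class TestComposition:
    def test_all_a(self):
        length, gc, at = composition("AAAA")
        assert (length, gc, at) == (4, 0.0, 100.0)

    def test_hand_count(self):
        assert composition("ATGC")[1] == pytest.approx(50.0)

    def test_gc_plus_at_is_100(self, mito_fixture):
        _, gc, at = composition(mito_fixture.sequence)
        assert gc + at == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composition("")
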