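"""End-to-end survey orchestration: config, stages, deterministic report.

``run_survey`` wires the stages together: (optionally) simulate inputs with
known truth, estimate the k-mer spectrum quantities, census SSRs, compute
assembly metrics and the GC-depth table, census the mitogenome, and scale a
PSMC trajectory.  All TSV/JSON outputs are byte-identical for identical
config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import yaml

from . import assembly as asm
from . import kmer, mito, psmc, simulate, ssr

log = logging.getLogger("genomesurvey")

__all__ = ["SurveyConfig", "run_survey"]

STAGES = ("simulate", "kspec", "ssr", "asmstats", "mito", "psmc")


@dataclass
class SurveyConfig:
    """Survey run parameters.

    Defaults follow the standard survey parameterisation: k = 19, SSR
    minimum repeats 6/5/5/5/5 for periods 2-6, compound-merge interruption
    100 bp, u = 2.5e-8 per site per generation, generation time 1 year,
    PSMC bin size 100 bp.
    """

    # analysis parameters
    k: int = 19
    min_repeats: Dict[int, int] = field(default_factory=lambda: dict(ssr.DEFAULT_MIN_REPEATS))
    max_interruption: int = 100
    window: int = 500
    u: float = 2.5e-8
    s: float = 100.0
    g: float = 1.0
    seed: int = 0
    # simulation parameters (used when no input paths are given)
    genome_length: int = 500_000
    het_rate: float = 0.0047
    repeat_fraction: float = 0.326
    repeat_unit_length: int = 500
    coverage: float = 30.0
    read_length: int = 150
    error_rate: float = 0.001
    # optional real inputs
    reads_fastq: Optional[str] = None
    histogram: Optional[str] = None
    assembly_fasta: Optional[str] = None
    mito_fasta: Optional[str] = None
    mito_annotation: Optional[str] = None
    psmc_file: Optional[str] = None
    # control
    out_dir: str = "survey_out"
    skip: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.min_repeats = {int(k): int(v) for k, v in self.min_repeats.items()}
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in skip: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _read_fastq_sequences(path: str | Path) -> List[str]:
    seqs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                seqs.append(line.strip().upper())
    return seqs


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _ssr_rows(records: Sequence[ssr.SSRRecord]) -> List[List]:
    return [
        [r.seq_id, r.index, r.ssr_type, r.standardized, r.length, r.start, r.end]
        for r in records
    ]


def run_survey(config: SurveyConfig) -> Dict:
    """Run the survey pipeline and write the report bundle to out_dir.

    Returns the report dict (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"config_hash": config.config_hash(), "seed": config.seed}
    t_start = time.time()

    def active(stage: str) -> bool:
        return stage not in config.skip

    # ------------------------------------------------------------------ inputs
    reads: Optional[List[str]] = None
    assembly_records = None
    mito_seq = None
    mito_ann = None
    psmc_text = None

    simulated = active("simulate") and not (config.reads_fastq or config.histogram)
    if simulated:
        t0 = time.time()
        params = simulate.SimParams(
            genome_length=config.genome_length,
            het_rate=config.het_rate,
            repeat_fraction=config.repeat_fraction,
            repeat_unit_length=config.repeat_unit_length,
            seed=config.seed,
        )
        genome = simulate.simulate_diploid_genome(params)
        readset = simulate.simulate_reads(
            genome,
            coverage=config.coverage,
            read_length=config.read_length,
            error_rate=config.error_rate,
            seed=config.seed + 1,
        )
        asm.write_fasta([("hap1", genome.hap1)], out / "genome_hap1.fasta")
        simulate.write_fastq(readset, out / "reads.fastq")
        reads = readset.sequences()
        assembly_records = [("hap1", genome.hap1)]
        fixture = simulate.make_mito_fixture(seed=config.seed)
        asm.write_fasta([("mito", fixture.sequence)], out / "mito.fasta")
        mito.write_annotation_tsv(fixture.annotation, out / "mito_annotation.tsv")
        mito_seq, mito_ann = fixture.sequence, fixture.annotation
        truth = simulate.PsmcTruth(
            theta0=0.01,
            intervals=_default_psmc_intervals(),
            u=config.u,
            s=config.s,
            g=config.g,
        )
        psmc_text = simulate.make_psmc_output(truth, n_rounds=3)
        (out / "psmc.out").write_text(psmc_text)
        report["simulate"] = {
            "genome_length": genome.length,
            "het_sites": len(genome.het_sites),
            "repeat_blocks": len(genome.repeat_intervals),
            "reads": len(readset.reads),
        }
        log.info("simulate stage done in %.1fs", time.time() - t0)

    if config.reads_fastq:
        reads = _read_fastq_sequences(config.reads_fastq)
    if config.assembly_fasta:
        assembly_records = asm.read_fasta(config.assembly_fasta)
    if config.mito_fasta:
        mito_seq = asm.read_fasta(config.mito_fasta)[0][1]
    if config.mito_annotation:
        mito_ann = mito.read_annotation(config.mito_annotation)
    if config.psmc_file:
        psmc_text = Path(config.psmc_file).read_text()

    # ------------------------------------------------------------------ kspec
    index = None
    if active("kspec"):
        t0 = time.time()
        if config.histogram:
            hist = kmer.load_histogram(config.histogram, k=config.k)
        elif reads is not None:
            index = kmer.build_kmer_index(reads, config.k)
            hist = index.histogram()
        else:
            raise ValueError("kspec stage needs reads_fastq, histogram, or simulation")
        kmer.save_histogram(hist, out / "kmer_histogram.tsv")
        est = kmer.estimate_spectrum(hist, config.k)
        report["spectrum"] = est.as_dict()
        with open(out / "spectrum.json", "w") as fh:
            json.dump(est.as_dict(), fh, indent=2, sort_keys=True)
        log.info("kspec stage done in %.1fs", time.time() - t0)

    # ------------------------------------------------------------------ ssr
    if active("ssr"):
        if assembly_records is None:
            raise ValueError("ssr stage needs assembly_fasta or simulation")
        t0 = time.time()
        all_records: List[ssr.SSRRecord] = []
        merged_all: List[ssr.SSRRecord] = []
        for sid, seq in assembly_records:
            recs = ssr.find_ssrs(seq, config.min_repeats, seq_id=sid)
            all_records.extend(recs)
            merged_all.extend(ssr.merge_compound(recs, config.max_interruption, sequence=seq))
        total_len = sum(len(seq) for _, seq in assembly_records)
        summary = ssr.summarize_ssrs(merged_all, len(assembly_records), total_len)
        _write_tsv(
            out / "ssr_records.tsv",
            ["ID", "SSR nr.", "SSR type", "SSR", "size", "start", "end"],
            _ssr_rows(merged_all),
        )
        report["ssr"] = {
            "sequences_examined": summary.sequences_examined,
            "total_ssrs": summary.total_ssrs,
            "sequences_with_ssr": summary.sequences_with_ssr,
            "sequences_with_more_than_one_ssr": summary.sequences_with_more_than_one_ssr,
            "compound_ssrs": summary.compound_ssrs,
            "density_per_mb": summary.density_per_mb,
            "type_percentages": summary.type_percentages,
        }
        _write_tsv(
            out / "ssr_summary.tsv",
            ["statistic", "value"],
            [
                ["Total number of sequences examined", summary.sequences_examined],
                ["Total size of examined sequences (bp)", summary.total_length],
                ["Total number of identified SSRs", summary.total_ssrs],
                ["Number of SSR containing sequences", summary.sequences_with_ssr],
                ["Number of sequences containing more than 1 SSR",
                 summary.sequences_with_more_than_one_ssr],
                ["Number of SSRs present in compound formation", summary.compound_ssrs],
                ["SSR density per Mb", f"{summary.density_per_mb:.2f}"],
            ],
        )
        log.info("ssr stage done in %.1fs", time.time() - t0)

    # ------------------------------------------------------------------ asmstats
    if active("asmstats"):
        if assembly_records is None:
            raise ValueError("asmstats stage needs assembly_fasta or simulation")
        t0 = time.time()
        scaff = asm.assembly_metrics(assembly_records)
        contigs = asm.assembly_metrics(asm.scaffold_to_contigs(assembly_records))
        rows = []
        for label, m in (("Contig", contigs), ("Scaffold", scaff)):
            rows.append([label, m.total_length, m.total_number, m.max_length,
                         m.n50, m.n90, f"{m.gc_percent:.2f}"])
        _write_tsv(
            out / "assembly_metrics.tsv",
            ["level", "total_length_bp", "total_number", "max_length_bp",
             "n50_bp", "n90_bp", "gc_percent"],
            rows,
        )
        report["assembly"] = {
            "scaffold": asdict(scaff),
            "contig": asdict(contigs),
        }
        if index is not None:
            points = asm.gc_depth_table(assembly_records, index, window=config.window)
            _write_tsv(
                out / "gc_depth.tsv",
                ["seq_id", "window_start", "gc_percent", "mean_depth"],
                [[p.seq_id, p.window_start, f"{p.gc_percent:.2f}", f"{p.mean_depth:.3f}"]
                 for p in points],
            )
            report["assembly"]["gc_depth_windows"] = len(points)
        log.info("asmstats stage done in %.1fs", time.time() - t0)

    # ------------------------------------------------------------------ mito
    if active("mito"):
        if mito_seq is None or mito_ann is None:
            raise ValueError("mito stage needs mito_fasta + mito_annotation or simulation")
        t0 = time.time()
        census = mito.feature_census(mito_ann)
        codons = mito.codon_report(mito_seq, mito_ann)
        length, gc, at = mito.composition(mito_seq)
        _write_tsv(
            out / "mito_codons.tsv",
            ["gene", "start_codon", "stop_codon", "stop_class"],
            [[g.name, g.start_codon, g.stop_codon, g.stop_class] for g in codons.genes],
        )
        report["mito"] = {
            "length": length,
            "gc_percent": gc,
            "at_percent": at,
            "by_type": census.by_type,
            "by_strand": census.by_strand,
        }
        log.info("mito stage done in %.1fs", time.time() - t0)

    # ------------------------------------------------------------------ psmc
    if active("psmc"):
        if psmc_text is None:
            raise ValueError("psmc stage needs psmc_file or simulation")
        t0 = time.time()
        res = psmc.parse_psmc_output(psmc_text)
        traj = psmc.scale_trajectory(res, u=config.u, s=config.s, g=config.g)
        _write_tsv(
            out / "ne_trajectory.tsv",
            ["years", "ne"],
            [[f"{y:.6g}", f"{n:.6g}"] for y, n in zip(traj.years, traj.ne)],
        )
        report["psmc"] = {
            "n0": res.theta0 / (4 * config.u * config.s),
            "segments": len(res.segments),
            "round_index": res.round_index,
        }
        log.info("psmc stage done in %.1fs", time.time() - t0)

    report["stages_run"] = [s for s in STAGES if active(s)]
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("survey complete in %.1fs", time.time() - t_start)
    return report


def _default_psmc_intervals() -> List:
    """Bottleneck-and-recovery shape: large ancestral size, glacial crash,
    partial post-glacial recovery (in PSMC's 2N0-scaled units)."""
    ts = [0.0, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0]
    lams = [0.6, 0.8, 0.4, 0.2, 0.3, 0.7, 1.0, 1.2, 1.0]
    return list(zip(ts, lams))
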