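"""Assembly summary metrics and the scaffold -> contig decomposition.

Builds a toy scaffold set with N gaps, reports the survey-table metrics
(total length/number, max, N50, N90, GC%) at both levels.
"""

from genomesurvey import simulate
from genomesurvey.assembly import assembly_metrics, scaffold_to_contigs

rng_seqs = [simulate.random_dna(n, seed=i) for i, n in
            enumerate([40_000, 25_000, 12_000, 6_000, 2_500])]
# join some pieces with N gaps to make scaffolds
scaffolds = [
    ("scaf1", rng_seqs[0] + "N" * 100 + rng_seqs[2]),
    ("scaf2", rng_seqs[1]),
    ("scaf3", rng_seqs[3] + "N" * 20 + rng_seqs[4]),
]

for label, records in (("Scaffold", scaffolds),
                       ("Contig", scaffold_to_contigs(scaffolds))):
    m = assembly_metrics(records)
    print(f"{label:9s} total={m.total_length:>7,} bp  n={m.total_number}  "
          f"max={m.max_length:>7,}  N50={m.n50:>7,}  N90={m.n90:>7,}  "
          f"GC={m.gc_percent:.2f}%")

print()
print("N50 is the smallest length L such that sequences >= L cover half the")
print("assembly; splitting on N runs always yields more, shorter contigs.")
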