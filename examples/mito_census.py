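"""Census a circular mitochondrial genome: features, strands, codons.

Uses the synthetic vertebrate-layout fixture (13 protein-coding genes,
22 tRNAs, 2 rRNAs, 1 control region; ND6 and eight tRNAs on the light
strand) and reports what a survey paper tabulates.
"""

from genomesurvey import simulate
from genomesurvey.mito import codon_report, composition, feature_census

fixture = simulate.make_mito_fixture(seed=0)
census = feature_census(fixture.annotation)
length, gc, at = composition(fixture.sequence)
report = codon_report(fixture.sequence, fixture.annotation)

print(f"genome length: {length:,} bp   GC {gc:.2f}%   AT {at:.2f}%")
print(f"features by type:   {census.by_type}")
print(f"features by strand: {census.by_strand}")
print()
print(f"{'gene':7s} {'start':6s} {'stop':5s} class")
for g in report.genes:
    print(f"{g.name:7s} {g.start_codon:6s} {g.stop_codon:5s} {g.stop_class}")
print()
print("COI starts with GTG and ATP6 with ATA (the rest ATG); stops shorter")
print("than 3 nt are incomplete and completed to TAA by polyadenylation.")
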