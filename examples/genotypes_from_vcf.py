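"""Extract panel genotypes from a VCF matched on the ID column.

Alleles are taken exactly as written on the forward strand; a record whose
REF/ALT are outside the panel's allele domain is rejected rather than
strand-flipped, which is the only safe policy for C/G SNPs.
"""

import tempfile

from tgskit import Panel, SnpDefinition, read_vcf_genotypes

VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP01\tP02
1\t100\trs2010963\tG\tC\t.\tPASS\t.\tGT\t1/1\t0/1
1\t200\trs1042713\tA\tG\t.\tPASS\t.\tGT\t0/1\t./.
1\t300\trs9999999\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/0
"""

panel = Panel(
    snps=(
        SnpDefinition(rsid="rs2010963", gene="VEGF", effect_allele="C", other_allele="G"),
        SnpDefinition(rsid="rs1042713", gene="ADRB2", effect_allele="G", other_allele="A"),
    )
)

with tempfile.NamedTemporaryFile("w", suffix=".vcf") as fh:
    fh.write(VCF)
    fh.flush()
    genotypes = read_vcf_genotypes(fh.name, panel)

for sample, calls in genotypes.items():
    print(sample, calls)
# P01 is CC at rs2010963 (ALT homozygote) and AG at rs1042713; P02's missing
# GT at rs1042713 leaves that rsid absent, and the non-panel rs9999999
# record is ignored entirely.
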