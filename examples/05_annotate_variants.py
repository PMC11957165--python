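"""Annotate a VCF with splice delta scores.

The fixture VCF carries engineered variants: a SNP destroying a donor GT, a
SNP destroying an acceptor AG, a SNP completing a planted cryptic donor, an
intergenic SNP, an over-long deletion (both excluded by rule) and a benign
mid-intron deletion. Each accepted variant gets four delta scores (acceptor
/donor gain/loss) with delta positions relative to the variant (negative =
upstream).
"""

import tempfile
from pathlib import Path

from spliceworks.fixtures import FixtureSpec, generate_genome, generate_vcf, make_mock_scorer
from spliceworks.variant import annotate_vcf

workdir = Path(tempfile.mkdtemp())
genome = generate_genome(FixtureSpec(seed=10), workdir / "genome")
vcf_in = workdir / "variants.vcf"
records = generate_vcf(genome, vcf_in, seed=10)

counts = annotate_vcf(vcf_in, genome.fasta_path, genome.gff_path,
                      [make_mock_scorer()], workdir / "annotated.vcf")
print(f"annotated {counts['annotated']} variants; skipped {counts['skipped']}")

effects = {f"var{i + 1}": r["effect"] for i, r in enumerate(records)}
for line in (workdir / "annotated.vcf").read_text().splitlines():
    if line.startswith("#"):
        continue
    f = line.split("\t")
    info = f[7] if "SPLICE_DELTA" in f[7] else "(passthrough)"
    print(f"{f[2]:5s} {effects[f[2]]:22s} {info}")
# INFO format: gene|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL.
# The donor-loss SNP shows DS_DL near 1 at DP_DL = -1 (the donor sits one
# base upstream of the mutated G of its GT dinucleotide).
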