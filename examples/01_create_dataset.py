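"""Build train/test tensors from a genome + annotation.

Generates a small synthetic genome (multi-exon genes on both strands with
GT-AG introns, pseudogene decoys, paralog pairs), then runs the full
create-data path: biotype filtering, canonical transcript selection,
splice-site labeling, 5,000-nt-core segmentation and HDF5 archiving.
"""

import tempfile
from pathlib import Path

from spliceworks.archive import read_archive
from spliceworks.dataprep import SplitSpec, create_datasets
from spliceworks.fixtures import FixtureSpec, generate_genome

workdir = Path(tempfile.mkdtemp())
genome = generate_genome(FixtureSpec(seed=10), workdir / "genome")
print(f"genome: {len(genome.chromosomes)} chromosomes, "
      f"{sum(g.biotype == 'protein_coding' for g in genome.genes)} protein-coding genes, "
      f"{len(genome.sites)} planted splice sites")

result = create_datasets(
    genome.fasta_path, genome.gff_path, workdir / "datasets",
    split=SplitSpec(method="human"),  # chr1/3/5 held out, chr2/4/6 train
    flank=400,
)
print(f"train genes: {result['train_genes']}, test genes: {result['test_genes']}")

examples, meta = read_archive(result["train_path"])
ex = examples[0]
print(f"first gene {ex.gene_id}: X {ex.x.shape} (segments x 5000+flank x 4), "
      f"Y {ex.y.shape} (segments x core x 3)")
print(f"archive flank: {meta['flank']} nt; "
      f"donor labels in first gene: {int(ex.y[..., 2].sum())}")
# Each segment's 5,000-nt core carries the labels; the flank on each side
# only provides sequence context, so label cores tile the gene exactly.
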