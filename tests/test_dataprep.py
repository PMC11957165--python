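"""Annotation parsing, labeling, segmentation, splitting and archiving."""

import numpy as np
import pytest

from spliceworks.alignment import ExactLocalAligner
from spliceworks.archive import read_archive, write_archive
from spliceworks.dataprep import (
    CORE,
    GeneLocus,
    SegmentedExample,
    SplitSpec,
    Transcript,
    create_datasets,
    encode_sequence,
    extract_gene_sequence,
    filter_pseudogenes,
    label_splice_sites,
    local_exons,
    parse_annotation,
    remove_paralogs,
    reverse_complement,
    segment_gene,
    select_canonical,
    split_dataset,
)

GFF_MIXED = """##gff-version 3
##sequence-region chrA 1 10000
chrA\tsrc\tgene\t101\t800\t.\t+\t.\tID=gA;gene_biotype=protein_coding
chrA\tsrc\tmRNA\t101\t800\t.\t+\t.\tID=gA.t1;Parent=gA
chrA\tsrc\texon\t101\t300\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
chrA\tsrc\texon\t601\t800\t.\t+\t.\tID=gA.t1.e2;Parent=gA.t1
chrA\tsrc\tgene\t2001\t2500\t.\t+\t.\tID=gB;gene_biotype=lncRNA
chrA\tsrc\tlnc_RNA\t2001\t2500\t.\t+\t.\tID=gB.t1;Parent=gB
chrA\tsrc\texon\t2001\t2500\t.\t+\t.\tID=gB.t1.e1;Parent=gB.t1
chrA\tsrc\tpseudogene\t3001\t3400\t.\t+\t.\tID=gC;gene_biotype=processed_pseudogene
chrA\tsrc\tpseudogenic_transcript\t3001\t3400\t.\t+\t.\tID=gC.t1;Parent=gC
chrA\tsrc\texon\t3001\t3400\t.\t+\t.\tID=gC.t1.e1;Parent=gC.t1
"""


@pytest.fixture(scope="module")
def mixed_gff(tmp_path_factory):
    p = tmp_path_factory.mktemp("gff") / "mixed.gff3"
    p.write_text(GFF_MIXED)
    return p


class TestParseAnnotation:
    def test_biotype_filter_keeps_only_protein_coding(self, mixed_gff):
        loci = parse_annotation(mixed_gff, biotype_filter="protein-coding")
        assert [l.id for l in loci] == ["gA"]
        assert loci[0].start == 101 and loci[0].end == 800  # 1-based inclusive

    def test_all_filter_includes_noncoding(self, mixed_gff):
        loci = parse_annotation(mixed_gff, biotype_filter="all")
        assert {l.id for l in loci} == {"gA", "gB", "gC"}

    def test_empty_gff(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("##gff-version 3\n")
        assert parse_annotation(p, biotype_filter="all") == []

    def test_unreadable_file_is_fatal(self, tmp_path):
        with pytest.raises(Exception):
            parse_annotation(tmp_path / "missing.gff3")


class TestPseudogeneFilter:
    @pytest.mark.parametrize("biotype,feature,removed", [
        ("processed_pseudogene", "gene", True),
        ("transcribed_pseudogene", "gene", True),
        ("pseudogene", "gene", True),
        ("protein_coding", "gene", False),
        ("protein_coding", "pseudogene", True),  # third-column feature type
        ("unknown", "gene", False),  # missing attribute => keep
    ])
    def test_rules(self, biotype, feature, removed):
        locus = GeneLocus(id="g", chrom="c", strand="+", start=1, end=10,
                          biotype=biotype, feature_type=feature)
        kept = filter_pseudogenes([locus])
        assert (len(kept) == 0) == removed


class TestSelectCanonical:
    def test_longest_wins(self):
        locus = GeneLocus(id="g", chrom="c", strand="+", start=1, end=3000, transcripts=[
            Transcript("T1", [(1, 1000)]),
            Transcript("T2", [(1, 500), (2000, 2500)]),
        ])
        assert select_canonical(locus).id == "T2"  # span 2,500 beats 1,000

    def test_tie_breaks_to_smallest_id(self):
        locus = GeneLocus(id="g", chrom="c", strand="+", start=1, end=1000, transcripts=[
            Transcript("T2", [(1, 1000)]),
            Transcript("T1", [(1, 1000)]),
        ])
        assert select_canonical(locus).id == "T1"

    def test_no_transcripts_skipped(self):
        locus = GeneLocus(id="g", chrom="c", strand="+", start=1, end=10)
        assert select_canonical(locus) is None


class TestEncoding:
    @pytest.mark.parametrize("seq,expected", [
        ("A", [[1, 0, 0, 0]]),
        ("N", [[0, 0, 0, 0]]),
        ("ACGTN", [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1], [0, 0, 0, 0]]),
        ("acgu", [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]]),
    ])
    def test_onehot_rows(self, seq, expected):
        assert encode_sequence(seq).tolist() == expected

    def test_ambiguity_codes_are_zero_rows(self):
        assert encode_sequence("RYKMSWBDHV-").sum() == 0


class TestLabeling:
    def test_two_exon_transcript_gets_one_donor_one_acceptor(self):
        #        exon1      intron        exon2
        seq = "CCCCCCCCAG" + "GTAAGT" + "TT" * 10 + "TTCAGG" + "CCCCCCCCC"
        exons = [(0, 10), (10 + 6 + 20 + 6, len(seq))]
        track = label_splice_sites(exons, seq)
        assert track[:, 2].sum() == 1 and track[:, 1].sum() == 1
        assert track[9, 2] == 1          # last exonic base of exon 1
        assert track[exons[1][0], 1] == 1  # first exonic base of exon 2

    def test_single_exon_all_none(self):
        track = label_splice_sites([(0, 50)], "A" * 50)
        assert (track == [1, 0, 0]).all()

    @pytest.mark.parametrize("first2,last2,n_labels", [
        ("GT", "AG", 2), ("GC", "AG", 2), ("AT", "AC", 2), ("CT", "AC", 0),
    ])
    def test_canonical_only_motif_gate(self, first2, last2, n_labels):
        intron = first2 + "A" * 26 + last2
        seq = "C" * 20 + intron + "G" * 20
        exons = [(0, 20), (20 + len(intron), len(seq))]
        track = label_splice_sites(exons, seq, canonical_only=True)
        assert int((track[:, 1:] == 1).sum()) == n_labels

    def test_exon_outside_sequence_is_fatal(self):
        with pytest.raises(ValueError):
            label_splice_sites([(0, 100)], "ACGT")

    def test_strand_symmetry(self, genome):
        """Labeling a minus-strand gene equals labeling the reverse-complement
        plus-strand construction with the same exon structure."""
        g = next(g for g in genome.genes if g.strand == "-" and g.donors_local)
        track = label_splice_sites(g.local_exons, g.sense_seq)
        # same structure planted on the plus strand: identical sense labels
        track_plus = label_splice_sites(g.local_exons, reverse_complement(
            reverse_complement(g.sense_seq)))
        assert (track == track_plus).all()
        donors = np.nonzero(track[:, 2] == 1)[0].tolist()
        assert donors == sorted(g.donors_local)


class TestSegmentation:
    def test_worked_example_22000(self):
        L = 22000
        x = encode_sequence("A" * L)
        y = np.tile([1, 0, 0], (L, 1)).astype(np.uint8)
        ex = segment_gene(x, y, flank=10000)
        assert ex.x.shape == (5, 15000, 4)
        assert ex.y.shape == (5, 5000, 3)
        # final segment holds 2,000 real nucleotides in its core
        real = (ex.y[4].sum(axis=1) > 0).sum()
        assert real == 2000
        assert ex.x[4, 5000 + 2000 :].sum() == 0  # features padded beyond them

    @pytest.mark.parametrize("L,n_seg,last_real", [
        (5000, 1, 5000), (5001, 2, 1), (1, 1, 1), (12345, 3, 2345),
    ])
    def test_segment_count_law(self, L, n_seg, last_real):
        x = encode_sequence("C" * L)
        y = np.tile([1, 0, 0], (L, 1)).astype(np.uint8)
        ex = segment_gene(x, y, flank=32)
        assert ex.x.shape[0] == n_seg
        assert (ex.y[-1].sum(axis=1) > 0).sum() == last_real
        total_real = sum((ex.y[i].sum(axis=1) > 0).sum() for i in range(n_seg))
        assert total_real == L

    def test_core_reconstruction_roundtrip(self, rng):
        L = 7321
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        x = encode_sequence(seq)
        y = np.tile([1, 0, 0], (L, 1)).astype(np.uint8)
        y[100] = [0, 0, 1]
        y[6000] = [0, 1, 0]
        ex = segment_gene(x, y, flank=32)
        rebuilt = np.concatenate([ex.y[i] for i in range(ex.y.shape[0])])[:L]
        assert (rebuilt == y).all()

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            segment_gene(np.zeros((0, 4)), np.zeros((0, 3)))


class TestSplit:
    def _locus(self, chrom):
        return GeneLocus(id=f"g_{chrom}", chrom=chrom, strand="+", start=1, end=10)

    def test_human_split_fixed_lists(self):
        loci = [self._locus("chr1"), self._locus("chr2"), self._locus("chrX")]
        train, test = split_dataset(loci, SplitSpec(method="human"))
        assert [l.chrom for l in test] == ["chr1"]
        assert {l.chrom for l in train} == {"chr2", "chrX"}

    def test_unlisted_chromosome_excluded(self):
        loci = [self._locus("chrM")]
        train, test = split_dataset(loci, SplitSpec(method="human"))
        assert train == [] and test == []

    def test_random_single_chromosome_all_train(self):
        loci = [self._locus("c1")]
        train, test = split_dataset(loci, SplitSpec(method="random"), {"c1": 1000})
        assert len(train) == 1 and test == []

    def test_random_greedy_accumulation_10_equal(self):
        lengths = {f"c{i}": 1000 for i in range(10)}
        loci = [self._locus(c) for c in lengths]
        train, test = split_dataset(loci, SplitSpec(method="random", ratio=0.8), lengths)
        assert len(train) == 8 and len(test) == 2

    def test_random_split_deterministic(self):
        lengths = {f"c{i}": 1000 + i for i in range(7)}
        loci = [self._locus(c) for c in lengths]
        a = split_dataset(loci, SplitSpec(method="random", seed=3), lengths)
        b = split_dataset(loci, SplitSpec(method="random", seed=3), lengths)
        assert [l.id for l in a[0]] == [l.id for l in b[0]]


class TestParalogRemoval:
    def _loci_seqs(self, rng, n=3, length=400):
        seqs = {}
        loci = []
        for i in range(n):
            s = "".join("ACGT"[j] for j in rng.integers(0, 4, length))
            loci.append(GeneLocus(id=f"t{i}", chrom="c", strand="+", start=1, end=length))
            seqs[f"t{i}"] = s
        return loci, seqs

    def test_identical_sequence_removed_random_kept(self, rng):
        loci, seqs = self._loci_seqs(rng)
        train = [seqs["t0"]]
        kept = remove_paralogs(loci, seqs, train, ExactLocalAligner())
        assert {l.id for l in kept} == {"t1", "t2"}

    def test_thresholds_are_conjunctive(self):
        class OneHit:
            def __init__(self, identity, coverage):
                self.hit = (identity, coverage)

            def align(self, query, targets):
                from spliceworks.alignment import AlignmentHit
                return [AlignmentHit(*self.hit)]

        locus = [GeneLocus(id="t", chrom="c", strand="+", start=1, end=10)]
        kept = remove_paralogs(locus, {"t": "ACGT"}, ["ACGT"], OneHit(0.9, 0.5))
        assert len(kept) == 1  # fails coverage threshold
        kept = remove_paralogs(locus, {"t": "ACGT"}, ["ACGT"], OneHit(0.9, 0.9))
        assert kept == []

    def test_idempotent(self, rng):
        loci, seqs = self._loci_seqs(rng, n=4)
        train = [seqs["t0"], seqs["t1"][:200]]
        aligner = ExactLocalAligner()
        once = remove_paralogs(loci, seqs, train, aligner)
        twice = remove_paralogs(once, seqs, train, aligner)
        assert [l.id for l in once] == [l.id for l in twice]

    def test_diverged_copy_removed(self, rng):
        """A ~5% diverged full-length copy exceeds both 80% thresholds."""
        loci, seqs = self._loci_seqs(rng, n=1)
        copy = list(seqs["t0"])
        for i in rng.choice(len(copy), size=20, replace=False):
            copy[i] = "ACGT"[("ACGT".index(copy[i]) + 1) % 4]
        kept = remove_paralogs(loci, seqs, ["".join(copy)], ExactLocalAligner())
        assert kept == []


class TestArchive:
    def _examples(self, n, rng):
        out = []
        for i in range(n):
            x = rng.random((2, 132, 4)).astype(np.float32)
            y = np.zeros((2, 100, 3), dtype=np.uint8)
            y[:, :, 0] = 1
            out.append(SegmentedExample(gene_id=f"g{i}", x=x, y=y))
        return out

    def test_batch_partition_250_genes(self, tmp_path, rng):
        path = tmp_path / "a.h5"
        write_archive(path, self._examples(250, rng), flank=32)
        import h5py

        with h5py.File(path) as fh:
            assert fh.attrs["n_batches"] == 3
            sizes = [fh[f"ids{b}"].shape[0] for b in range(3)]
        assert sizes == [100, 100, 50]

    @pytest.mark.parametrize("n", [1, 7])
    def test_roundtrip_lossless(self, tmp_path, rng, n):
        path = tmp_path / "a.h5"
        examples = self._examples(n, rng)
        write_archive(path, examples, flank=32)
        back, meta = read_archive(path)
        assert meta["flank"] == 32
        assert [e.gene_id for e in back] == [e.gene_id for e in examples]
        for a, b in zip(examples, back):
            assert (a.y == b.y).all()
            assert np.array_equal(a.x, b.x)

    def test_empty_archive_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_archive(tmp_path / "a.h5", [], flank=32)

    def test_corrupt_archive_fatal(self, tmp_path):
        p = tmp_path / "bad.h5"
        p.write_bytes(b"not an hdf5 file")
        with pytest.raises(OSError):
            read_archive(p)


class TestCreateDataParalogPath:
    def test_minimap2_backend_removes_cross_split_paralogs(self, tmp_path):
        """With paralog pairs split across train/test chromosomes, the
        minimap2-backed filter drops every test gene whose near-identical
        partner sits in the training set."""
        from spliceworks.fixtures import FixtureSpec, generate_genome

        fx = generate_genome(FixtureSpec(paralog_fraction=0.3), tmp_path / "fx")
        res = create_datasets(fx.fasta_path, fx.gff_path, tmp_path / "ds",
                              split=SplitSpec(method="human"), flank=32,
                              remove_paralogs_flag=True)
        test_chroms = {"chr1", "chr3", "chr5"}
        expected_removed = {
            g.id for g in fx.genes
            if g.paralog_of and g.chrom in test_chroms
        } | {
            g.paralog_of for g in fx.genes
            if g.paralog_of and g.chrom not in test_chroms
        }
        kept = {ex.gene_id for ex in read_archive(res["test_path"])[0]}
        assert expected_removed and not (expected_removed & kept)


class TestFixtureClosure:
    def test_labels_equal_generator_ground_truth(self, genome):
        """The full create-data labeling path recovers every planted site."""
        import pyfaidx

        fasta = pyfaidx.Fasta(str(genome.fasta_path))
        loci = parse_annotation(genome.gff_path, biotype_filter="protein-coding")
        assert loci, "fixture produced no protein-coding loci"
        for locus in loci:
            tr = select_canonical(locus)
            seq = extract_gene_sequence(fasta, locus)
            track = label_splice_sites(local_exons(locus, tr), seq)
            truth = genome.sites_for_gene(locus.id)
            donors = {s.local_pos for s in truth if s.site_type == "donor"}
            acceptors = {s.local_pos for s in truth if s.site_type == "acceptor"}
            assert set(np.nonzero(track[:, 2] == 1)[0].tolist()) == donors
            assert set(np.nonzero(track[:, 1] == 1)[0].tolist()) == acceptors

    def test_label_conservation(self, genome):
        """Donor count == acceptor count == intron count per gene."""
        for g in genome.genes:
            if g.biotype != "protein_coding":
                continue
            track = label_splice_sites(g.local_exons, g.sense_seq)
            n_introns = len(g.local_exons) - 1
            assert int(track[:, 2].sum()) == n_introns
            assert int(track[:, 1].sum()) == n_introns
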