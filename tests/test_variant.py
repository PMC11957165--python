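"""Variant validation, indel realignment, delta scores, VCF annotation."""

import numpy as np
import pytest

from spliceworks.variant import (
    GeneIndex,
    annotate_vcf,
    build_ref_alt,
    delta_scores,
    realign_alt,
    score_variant,
    validate_variant,
)


@pytest.fixture(scope="module")
def gene_index(genome_module):
    return GeneIndex.from_gff(genome_module.gff_path)


@pytest.fixture(scope="module")
def genome_module(tmp_path_factory):
    from spliceworks.fixtures import FixtureSpec, generate_genome

    return generate_genome(FixtureSpec(), tmp_path_factory.mktemp("vfix"))


class TestValidate:
    def test_intergenic_variant_skipped(self, genome_module, gene_index):
        seq = genome_module.chromosomes["chr1"]
        g0 = min((g for g in genome_module.genes if g.chrom == "chr1"),
                 key=lambda g: g.start)
        pos0 = g0.start - 1 - 50
        _, reason = validate_variant("chr1", pos0, seq[pos0], "A", gene_index, seq,
                                     flank=80)
        assert reason == "outside_gene"

    def test_long_deletion_skipped(self, genome_module, gene_index):
        g = next(g for g in genome_module.genes if g.biotype == "protein_coding")
        seq = genome_module.chromosomes[g.chrom]
        pos0 = g.start + 10
        ref = seq[pos0 : pos0 + 151]
        _, reason = validate_variant(g.chrom, pos0, ref, ref[0], gene_index, seq,
                                     flank=80, distance=50)
        assert reason == "deletion_too_long"  # 150 > 2 x 50

    def test_boundary_deletion_accepted(self, genome_module, gene_index):
        g = next(g for g in genome_module.genes if g.biotype == "protein_coding"
                 and g.end - g.start > 400)
        seq = genome_module.chromosomes[g.chrom]
        pos0 = g.start + 150
        ref = seq[pos0 : pos0 + 101]  # deletion of exactly 100 = 2 x distance
        gene, reason = validate_variant(g.chrom, pos0, ref, ref[0], gene_index, seq,
                                        flank=80, distance=50)
        assert reason is None and gene.id == g.id

    def test_mid_gene_snp_accepted(self, genome_module, gene_index):
        g = next(g for g in genome_module.genes if g.biotype == "protein_coding")
        seq = genome_module.chromosomes[g.chrom]
        pos0 = (g.start + g.end) // 2
        gene, reason = validate_variant(g.chrom, pos0, seq[pos0], "A" if seq[pos0] != "A" else "C",
                                        gene_index, seq, flank=80)
        assert reason is None

    def test_near_chromosome_end_skipped(self, gene_index, genome_module):
        g = min((g for g in genome_module.genes if g.chrom == "chr1"),
                key=lambda g: g.start)
        seq = genome_module.chromosomes["chr1"]
        # inside a gene but closer than flank to the chromosome start
        if g.start - 1 < 5000:  # fixture genes sit well inside, so fake flank
            _, reason = validate_variant("chr1", g.start + 5, seq[g.start + 5], "A",
                                         gene_index, seq, flank=g.start + 100)
            assert reason == "near_chrom_end"

    def test_ref_mismatch_skipped(self, genome_module, gene_index):
        g = next(g for g in genome_module.genes if g.biotype == "protein_coding")
        seq = genome_module.chromosomes[g.chrom]
        pos0 = (g.start + g.end) // 2
        wrong = "A" if seq[pos0] != "A" else "C"
        _, reason = validate_variant(g.chrom, pos0, wrong, "G", gene_index, seq, flank=80)
        assert reason == "ref_mismatch"


class TestBuildRefAlt:
    SEQ = "".join("ACGT"[i] for i in np.random.default_rng(0).integers(0, 4, 2000))

    def test_snp_windows(self):
        ref_seq, alt_seq = build_ref_alt(self.SEQ, 1000, self.SEQ[1000], "T"
                                         if self.SEQ[1000] != "T" else "A",
                                         distance=50, flank=80)
        assert len(ref_seq) == 2 * (50 + 40) + 1 == len(alt_seq)
        diff = [i for i, (a, b) in enumerate(zip(ref_seq, alt_seq)) if a != b]
        assert diff == [90]  # exactly the center position

    def test_deletion_shortens_alt(self):
        ref = self.SEQ[1000:1003]
        ref_seq, alt_seq = build_ref_alt(self.SEQ, 1000, ref, ref[0], 50, 80)
        assert len(alt_seq) == len(ref_seq) - 2

    def test_insertion_lengthens_alt(self):
        ref = self.SEQ[1000]
        ref_seq, alt_seq = build_ref_alt(self.SEQ, 1000, ref, ref + "GGG", 50, 80)
        assert len(alt_seq) == len(ref_seq) + 3


class TestRealign:
    def test_snp_identity(self):
        scores = np.arange(101, dtype=float)
        out = realign_alt(scores, 1, 1, 50)
        assert np.array_equal(out, scores)

    def test_deletion_masks_deleted_slots(self):
        scores = np.arange(99, dtype=float)  # 2-nt deletion: alt 2 shorter
        out = realign_alt(scores, 3, 1, 50)
        assert len(out) == 101
        assert np.isnan(out[51]) and np.isnan(out[52])
        assert out[50] == scores[50] and out[53] == scores[51]
        assert np.isnan(out).sum() == 2

    def test_insertion_collapses_by_max(self):
        scores = np.zeros(104)  # 3-nt insertion: alt 3 longer
        scores[50:54] = [1.0, 7.0, 2.0, 3.0]  # anchor + inserted bases
        scores[54] = 5.0
        out = realign_alt(scores, 1, 4, 50)
        assert len(out) == 101
        assert out[50] == 7.0  # max over anchor + insertion
        assert out[51] == 5.0


class TestDeltaScores:
    def test_identical_arrays_all_zero(self):
        a = np.random.default_rng(1).random(101)
        d = np.random.default_rng(2).random(101)
        ann = delta_scores(a, a.copy(), d, d.copy())
        assert (ann.ds_ag, ann.ds_al, ann.ds_dg, ann.ds_dl) == (0, 0, 0, 0)

    def test_hand_example_acceptor_gain(self):
        a_ref = np.full(101, 0.1)
        a_alt = a_ref.copy()
        a_alt[50 + 3] = 0.8
        d = np.zeros(101)
        ann = delta_scores(a_ref, a_alt, d, d.copy())
        assert ann.ds_ag == pytest.approx(0.7)
        assert ann.dp_ag == 3

    def test_window_size_law(self, mock_scorer, genome):
        g = next(g for g in genome.genes if g.strand == "+" and g.donors_local)
        seq = genome.chromosomes[g.chrom]
        pos0 = g.local_to_genomic(g.donors_local[0] + 1)
        ann = score_variant(seq, pos0, seq[pos0], "C", mock_scorer, distance=50,
                            strand="+", gene=g.id)
        # comparison window covers exactly 2*50+1 = 101 offsets
        assert all(-50 <= dp <= 50 for dp in
                   (ann.dp_ag, ann.dp_al, ann.dp_dg, ann.dp_dl))
        assert ann.ds_dl > 0.9 and ann.dp_dl == -1

    def test_gain_loss_symmetry_random_arrays(self, rng):
        """Swapping ref and alt swaps gains and losses exactly (1,000 draws)."""
        for _ in range(1000):
            a_ref, a_alt = rng.random((2, 101))
            d_ref, d_alt = rng.random((2, 101))
            fwd = delta_scores(a_ref, a_alt, d_ref, d_alt)
            rev = delta_scores(a_alt, a_ref, d_alt, d_ref)
            assert fwd.ds_ag == rev.ds_al and fwd.ds_al == rev.ds_ag
            assert fwd.ds_dg == rev.ds_dl and fwd.ds_dl == rev.ds_dg
            assert fwd.dp_ag == rev.dp_al and fwd.dp_dg == rev.dp_dl

    def test_scores_clipped_and_positions_bounded(self, rng):
        for _ in range(50):
            arrs = rng.random((4, 101))
            ann = delta_scores(*arrs)
            for v in (ann.ds_ag, ann.ds_al, ann.ds_dg, ann.ds_dl):
                assert 0.0 <= v <= 1.0
            for dp in (ann.dp_ag, ann.dp_al, ann.dp_dg, ann.dp_dl):
                assert -50 <= dp <= 50

    def test_tie_breaks_to_smallest_absolute_then_upstream(self):
        a_ref = np.zeros(101)
        a_alt = np.zeros(101)
        a_alt[50 - 4] = a_alt[50 + 4] = 0.6  # tie at offsets -4 and +4
        d = np.zeros(101)
        ann = delta_scores(a_ref, a_alt, d, d.copy())
        assert ann.dp_ag == -4

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            delta_scores(np.array([]), np.array([]), np.array([]), np.array([]))


@pytest.fixture(scope="module")
def annotated(genome, fixture_vcf, mock_scorer, tmp_path_factory):
    vcf_path, records = fixture_vcf
    out = tmp_path_factory.mktemp("annot") / "out.vcf"
    counts = annotate_vcf(vcf_path, genome.fasta_path, genome.gff_path,
                          [mock_scorer], out)
    return out, records, counts


class TestAnnotateVcf:
    def _info(self, out, var_id):
        for line in out.read_text().splitlines():
            if line.startswith("#"):
                continue
            f = line.split("\t")
            if f[2] == var_id:
                return f[7]
        raise AssertionError(f"{var_id} not in output")

    def test_skips_and_annotations_counted(self, annotated):
        _, records, counts = annotated
        expected_skips = sum(r["effect"].startswith("skip") for r in records)
        assert sum(counts["skipped"].values()) == expected_skips
        assert counts["annotated"] == len(records) - expected_skips

    def test_skipped_variants_pass_through_unannotated(self, annotated):
        out, records, _ = annotated
        for i, r in enumerate(records):
            if r["effect"].startswith("skip"):
                assert "SPLICE_DELTA" not in self._info(out, f"var{i + 1}")

    def test_engineered_effects_detected(self, annotated):
        out, records, _ = annotated
        for i, r in enumerate(records):
            info = self._info(out, f"var{i + 1}")
            if not r["effect"].startswith(("donor", "acceptor", "benign")):
                continue
            payload = info.split("SPLICE_DELTA=")[1].split(",")[0].split("|")
            ds_ag, ds_al, ds_dg, ds_dl = map(float, payload[1:5])
            if r["effect"] == "donor_loss":
                assert ds_dl > 0.9 and ds_dl > ds_dg
            elif r["effect"] == "donor_gain":
                assert ds_dg > 0.9 and ds_dg > ds_dl
            elif r["effect"] == "acceptor_loss":
                assert ds_al > 0.9
            elif r["effect"] == "benign_indel":
                assert max(ds_ag, ds_al, ds_dg, ds_dl) < 0.1

    def test_header_declares_info_key(self, annotated):
        out, _, _ = annotated
        header = [l for l in out.read_text().splitlines() if l.startswith("##INFO")]
        assert any("SPLICE_DELTA" in l for l in header)

    def test_empty_vcf_body_gives_header_only(self, genome, mock_scorer, tmp_path):
        src = tmp_path / "empty.vcf"
        src.write_text("##fileformat=VCFv4.2\n"
                       "##contig=<ID=chr1,length=1000>\n"
                       "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        out = tmp_path / "out.vcf"
        counts = annotate_vcf(src, genome.fasta_path, genome.gff_path,
                              [mock_scorer], out)
        assert counts["annotated"] == 0
        assert all(l.startswith("#") for l in out.read_text().splitlines())
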