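"""Genome + annotation preprocessing into labeled training tensors.

Converts FASTA sequences and GFF3/GTF annotations into one-hot encoded,
segmented examples with per-base splice-site labels, applying the biotype,
pseudogene, paralog and chromosome-split rules, and writes them to HDF5
archives (see :mod:`spliceworks.archive`).

Coordinate conventions: annotation intervals are 1-based inclusive (as in
GFF); all internal tracks are 0-based; minus-strand genes are
reverse-complemented so every downstream step sees the sense strand.
Splice-site label positions: the donor is labeled at the last exonic base of
the upstream exon, the acceptor at the first exonic base of the downstream
exon (sense-strand coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import ParalogAligner

logger = logging.getLogger(__name__)

__all__ = [
    "GeneLocus",
    "Transcript",
    "SegmentedExample",
    "SplitSpec",
    "HUMAN_TRAIN_CHROMS",
    "HUMAN_TEST_CHROMS",
    "PSEUDOGENE_BIOTYPES",
    "CANONICAL_INTRON_MOTIFS",
    "parse_annotation",
    "filter_pseudogenes",
    "select_canonical",
    "encode_sequence",
    "decode_sequence",
    "reverse_complement",
    "label_splice_sites",
    "segment_gene",
    "split_dataset",
    "remove_paralogs",
    "extract_gene_sequence",
    "local_exons",
    "create_datasets",
]

# Fixed human chromosome split (training vs held-out test chromosomes).
HUMAN_TRAIN_CHROMS = frozenset(
    {"2", "4", "6", "8", "10", "11", "12", "13", "14", "15", "16", "17",
     "18", "19", "20", "21", "22", "X", "Y"}
)
HUMAN_TEST_CHROMS = frozenset({"1", "3", "5", "7", "9"})

PSEUDOGENE_BIOTYPES = frozenset(
    {"pseudogene", "transcribed_pseudogene", "processed_pseudogene"}
)

# Allowed (first-2, last-2) intronic dinucleotides under --canonical-only:
# U2-type GT-AG and GC-AG, U12-type GT-AG and AT-AC.
CANONICAL_INTRON_MOTIFS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})

CORE = 5000  # prediction-core width of one segment

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


@dataclass
class Transcript:
    """A transcript as an ordered list of genomic exon intervals.

    Exons are 1-based inclusive ``(start, end)`` tuples, non-overlapping and
    sorted in genomic coordinates. ``length`` is the genomic span of the
    transcript (first exon start to last exon end), the quantity used for
    canonical-transcript selection.
    """

    id: str
    exons: list[tuple[int, int]]

    def __post_init__(self):
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"transcript {self.id}: exon start {s} > end {e}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"transcript {self.id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s + 1


@dataclass
class GeneLocus:
    id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    biotype: str = "unknown"
    feature_type: str = "gene"
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentedExample:
    """One gene's stacked feature and label segments.

    ``x`` has shape ``(n_segments, CORE + flank, 4)`` and ``y`` has shape
    ``(n_segments, CORE, 3)`` with pad label rows all-zero.
    """

    gene_id: str
    x: np.ndarray
    y: np.ndarray


@dataclass
class SplitSpec:
    """Chromosome-level train/test split.

    ``human`` uses the fixed chromosome lists; ``random`` shuffles
    chromosomes with ``seed`` and greedily accumulates them (by length) into
    the training set until at least ``ratio`` of the total length is
    covered, assigning the remainder to test.
    """

    method: str = "human"
    ratio: float = 0.8
    seed: int = 10
    train_chroms: frozenset = HUMAN_TRAIN_CHROMS
    test_chroms: frozenset = HUMAN_TEST_CHROMS

    def __post_init__(self):
        if self.method not in {"human", "random"}:
            raise ValueError(f"unknown split method {self.method!r}")
        if not 0.0 < self.ratio < 1.0:
            raise ValueError(f"split ratio must be in (0,1), got {self.ratio}")


# ---------------------------------------------------------------------------
# annotation parsing
# ---------------------------------------------------------------------------

_GENE_FEATURES = {"gene", "pseudogene"}
_TRANSCRIPT_FEATURES = {"mRNA", "transcript", "pseudogenic_transcript", "lnc_RNA"}


def _attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def parse_annotation(gff_path, biotype_filter: str = "protein-coding") -> list[GeneLocus]:
    """Parse a GFF3/GTF file into gene loci.

    ``biotype_filter`` is ``"protein-coding"`` (keep only genes whose
    biotype is protein_coding) or ``"all"``. Records with a malformed
    hierarchy (e.g. an exon whose parent transcript is missing) are rejected
    with a logged warning rather than aborting the parse.
    """
    import gffutils

    if biotype_filter not in {"protein-coding", "all"}:
        raise ValueError(f"biotype_filter must be 'protein-coding' or 'all', got {biotype_filter!r}")
    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:", merge_strategy="create_unique",
            keep_order=True, force=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    loci: list[GeneLocus] = []
    for ftype in _GENE_FEATURES:
        for gene in db.features_of_type(ftype):
            biotype = _attr(gene, "gene_biotype", "biotype") or (
                "pseudogene" if ftype == "pseudogene" else "unknown"
            )
            if biotype_filter == "protein-coding" and biotype != "protein_coding":
                continue
            transcripts: list[Transcript] = []
            for tr in db.children(gene, level=1):
                if tr.featuretype not in _TRANSCRIPT_FEATURES:
                    continue
                exons = [(e.start, e.end) for e in db.children(tr, featuretype="exon")]
                if not exons:
                    logger.warning("transcript %s of gene %s has no exons; rejected", tr.id, gene.id)
                    continue
                try:
                    transcripts.append(Transcript(id=tr.id, exons=exons))
                except ValueError as exc:
                    logger.warning("rejecting transcript %s: %s", tr.id, exc)
            locus = GeneLocus(
                id=gene.id, chrom=gene.seqid, strand=gene.strand,
                start=gene.start, end=gene.end, biotype=biotype,
                feature_type=gene.featuretype, transcripts=transcripts,
            )
            bad = [t for t in locus.transcripts
                   if t.span[0] < locus.start or t.span[1] > locus.end]
            for t in bad:
                logger.warning("transcript %s extends outside gene %s; rejected", t.id, gene.id)
                locus.transcripts.remove(t)
            loci.append(locus)
    return loci


def filter_pseudogenes(loci: list[GeneLocus]) -> list[GeneLocus]:
    """Drop loci that are pseudogenes by feature type or biotype."""
    kept = []
    for locus in loci:
        if locus.feature_type == "pseudogene" or locus.biotype in PSEUDOGENE_BIOTYPES:
            logger.info("removing pseudogene locus %s (%s)", locus.id, locus.biotype)
            continue
        kept.append(locus)
    return kept


def select_canonical(locus: GeneLocus) -> Transcript | None:
    """Longest transcript; ties broken by lexicographically smallest id."""
    if not locus.transcripts:
        logger.warning("gene %s has no transcripts; skipped", locus.id)
        return None
    return min(locus.transcripts, key=lambda t: (-t.length, t.id))


# ---------------------------------------------------------------------------
# sequence handling
# ---------------------------------------------------------------------------

_ENCODE_LUT = np.zeros((256, 4), dtype=np.float32)
for _i, _base in enumerate("ACGT"):
    _ENCODE_LUT[ord(_base), _i] = 1.0
    _ENCODE_LUT[ord(_base.lower()), _i] = 1.0
_ENCODE_LUT[ord("U")] = _ENCODE_LUT[ord("T")]
_ENCODE_LUT[ord("u")] = _ENCODE_LUT[ord("t")]


def encode_sequence(seq: str) -> np.ndarray:
    """One-hot encode: A/C/G/T(U) are unit rows, anything else a zero row."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[codes].copy()


def decode_sequence(onehot: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`; zero rows decode to ``N``."""
    bases = np.array(list("ACGT"))
    out = np.full(onehot.shape[0], "N", dtype="<U1")
    hot = onehot.sum(axis=1) > 0.5
    out[hot] = bases[onehot[hot].argmax(axis=1)]
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_gene_sequence(fasta, locus: GeneLocus) -> str:
    """Uppercased sense-strand sequence of the locus span.

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> indexable
    sequence). Soft-masked lowercase bases are uppercased before encoding.
    """
    seq = str(fasta[locus.chrom][locus.start - 1 : locus.end]).upper()
    if locus.strand == "-":
        seq = reverse_complement(seq)
    return seq


def local_exons(locus: GeneLocus, transcript: Transcript) -> list[tuple[int, int]]:
    """Exon intervals in 0-based half-open gene-local sense coordinates."""
    out = []
    for s, e in transcript.exons:
        if locus.strand == "+":
            out.append((s - locus.start, e - locus.start + 1))
        else:
            out.append((locus.end - e, locus.end - s + 1))
    return sorted(out)


# class row encodings for the label track
LABEL_NONE = np.array([1, 0, 0], dtype=np.uint8)
LABEL_ACCEPTOR = np.array([0, 1, 0], dtype=np.uint8)
LABEL_DONOR = np.array([0, 0, 1], dtype=np.uint8)


def label_splice_sites(
    exons: list[tuple[int, int]],
    gene_seq: str,
    canonical_only: bool = False,
) -> np.ndarray:
    """Per-base label track over the sense-strand gene sequence.

    ``exons`` are 0-based half-open sense-local intervals, sorted 5'->3'.
    One donor is labeled at the last exonic base upstream of each intron and
    one acceptor at the first exonic base downstream of it. With
    ``canonical_only``, introns whose terminal dinucleotides fall outside
    the U2/U12 motif set (GT-AG, GC-AG, AT-AC) produce no labels.

    Raises ``ValueError`` if an exon lies outside the sequence (fatal for
    the gene).
    """
    length = len(gene_seq)
    exons = sorted(exons)
    for s, e in exons:
        if s < 0 or e > length or s >= e:
            raise ValueError(f"exon [{s},{e}) outside gene sequence of length {length}")
    track = np.tile(LABEL_NONE, (length, 1))
    for (_, e1), (s2, _) in zip(exons, exons[1:]):
        intron_start, intron_end = e1, s2  # 0-based half-open intron
        if intron_end - intron_start < 4:
            logger.warning("intron [%d,%d) shorter than 4 nt; unlabeled", intron_start, intron_end)
            continue
        if canonical_only:
            first2 = gene_seq[intron_start : intron_start + 2]
            last2 = gene_seq[intron_end - 2 : intron_end]
            if (first2, last2) not in CANONICAL_INTRON_MOTIFS:
                continue
        track[e1 - 1] = LABEL_DONOR      # last exonic base of upstream exon
        track[s2] = LABEL_ACCEPTOR       # first exonic base of downstream exon
    return track


def segment_gene(onehot: np.ndarray, labels: np.ndarray, flank: int = 10000) -> SegmentedExample:
    """Tile a gene into windows of ``CORE + flank`` with disjoint 5,000-nt cores.

    Window *w* covers sense-local positions ``[w*5000 - flank/2,
    w*5000 + 5000 + flank/2)``; out-of-gene positions are padded (zero
    feature rows, all-zero label rows). ``n_segments = ceil(L / 5000)``.
    """
    if flank % 2 != 0:
        raise ValueError(f"flank must be even, got {flank}")
    length = onehot.shape[0]
    if length == 0:
        raise ValueError("zero-length gene")
    if labels.shape[0] != length:
        raise ValueError(f"feature length {length} != label length {labels.shape[0]}")
    n_seg = -(-length // CORE)
    half = flank // 2
    win = CORE + flank
    x = np.zeros((n_seg, win, 4), dtype=np.float32)
    y = np.zeros((n_seg, CORE, 3), dtype=np.uint8)
    for w in range(n_seg):
        core_start = w * CORE
        src_lo = max(0, core_start - half)
        src_hi = min(length, core_start + CORE + half)
        x[w, src_lo - (core_start - half) : src_hi - (core_start - half)] = onehot[src_lo:src_hi]
        core_hi = min(length, core_start + CORE)
        y[w, : core_hi - core_start] = labels[core_start:core_hi]
    return SegmentedExample(gene_id="", x=x, y=y)


# ---------------------------------------------------------------------------
# dataset splitting and paralog removal
# ---------------------------------------------------------------------------

def normalize_chrom(name: str) -> str:
    n = name.removeprefix("chr").removeprefix("Chr").removeprefix("CHR")
    return n.upper() if n.lower() in {"x", "y"} else n


def split_dataset(
    loci: list[GeneLocus],
    spec: SplitSpec,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[GeneLocus], list[GeneLocus]]:
    """Assign loci to (train, test) by chromosome.

    ``human`` uses the fixed lists; chromosomes on neither list are excluded
    with a warning. ``random`` requires ``chrom_lengths`` and performs the
    seeded greedy length-accumulation split.
    """
    if spec.method == "human":
        train, test = [], []
        for locus in loci:
            c = normalize_chrom(locus.chrom)
            if c in spec.train_chroms:
                train.append(locus)
            elif c in spec.test_chroms:
                test.append(locus)
            else:
                logger.warning("chromosome %s not in train or test list; gene %s excluded",
                               locus.chrom, locus.id)
        return train, test

    if chrom_lengths is None:
        raise ValueError("random split requires chromosome lengths")
    chroms = sorted(chrom_lengths)
    rng = np.random.default_rng(spec.seed)
    order = [chroms[i] for i in rng.permutation(len(chroms))]
    total = sum(chrom_lengths.values())
    train_set: set[str] = set()
    acc = 0
    for c in order:
        if acc < spec.ratio * total:
            train_set.add(c)
            acc += chrom_lengths[c]
    train = [l for l in loci if l.chrom in train_set]
    test = [l for l in loci if l.chrom in chrom_lengths and l.chrom not in train_set]
    dropped = [l for l in loci if l.chrom not in chrom_lengths]
    for l in dropped:
        logger.warning("chromosome %s has no recorded length; gene %s excluded", l.chrom, l.id)
    return train, test


def remove_paralogs(
    test_loci: list[GeneLocus],
    test_seqs: dict[str, str],
    train_seqs: list[str],
    aligner: ParalogAligner,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> list[GeneLocus]:
    """Drop test loci whose DNA aligns to any training sequence with
    identity > ``min_identity`` and query coverage > ``min_coverage``."""
    kept = []
    removed = 0
    for locus in test_loci:
        hits = aligner.align(test_seqs[locus.id], train_seqs)
        if any(h.identity > min_identity and h.coverage > min_coverage for h in hits):
            removed += 1
            logger.info("removing paralogous test gene %s", locus.id)
            continue
        kept.append(locus)
    logger.info("paralog filter removed %d / %d test genes", removed, len(test_loci))
    return kept


# ---------------------------------------------------------------------------
# full create-data pipeline
# ---------------------------------------------------------------------------

def _build_example(locus: GeneLocus, fasta, flank: int, canonical_only: bool) -> SegmentedExample | None:
    tr = select_canonical(locus)
    if tr is None:
        return None
    seq = extract_gene_sequence(fasta, locus)
    try:
        labels = label_splice_sites(local_exons(locus, tr), seq, canonical_only)
    except ValueError as exc:
        logger.error("gene %s: %s; skipped", locus.id, exc)
        return None
    ex = segment_gene(encode_sequence(seq), labels, flank=flank)
    ex.gene_id = locus.id
    return ex


def create_datasets(
    fasta_path,
    gff_path,
    output_dir,
    biotype: str = "protein-coding",
    split: SplitSpec | None = None,
    flank: int = 10000,
    canonical_only: bool = False,
    remove_paralogs_flag: bool = False,
    aligner: ParalogAligner | None = None,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
    write_fasta: bool = False,
) -> dict:
    """FASTA + GFF -> train/test HDF5 archives; returns paths and counts."""
    import pyfaidx

    from .archive import write_archive

    split = split or SplitSpec()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    fasta = pyfaidx.Fasta(str(fasta_path))
    chrom_lengths = {name: len(fasta[name]) for name in fasta.keys()}

    loci = parse_annotation(gff_path, biotype_filter=biotype)
    train_loci, test_loci = split_dataset(loci, split, chrom_lengths)
    test_loci = filter_pseudogenes(test_loci)

    if remove_paralogs_flag:
        if aligner is None:
            from .alignment import Minimap2Aligner

            aligner = Minimap2Aligner()
        test_seqs = {l.id: extract_gene_sequence(fasta, l) for l in test_loci}
        train_seqs = [extract_gene_sequence(fasta, l) for l in train_loci]
        test_loci = remove_paralogs(test_loci, test_seqs, train_seqs, aligner,
                                    min_identity, min_coverage)

    meta = {
        "split_method": split.method,
        "canonical_only": int(canonical_only),
        "label_convention": "donor=last exonic base upstream; acceptor=first exonic base downstream",
    }
    result = {"train_genes": len(train_loci), "test_genes": len(test_loci)}
    for name, loci_part in (("train", train_loci), ("test", test_loci)):
        examples = []
        for locus in loci_part:
            ex = _build_example(locus, fasta, flank, canonical_only)
            if ex is not None:
                examples.append(ex)
        path = output_dir / f"dataset_{name}.h5"
        if examples:
            write_archive(path, examples, flank=flank, metadata=meta)
            result[f"{name}_path"] = path
        else:
            logger.warning("no %s examples produced; archive not written", name)
        result[f"{name}_examples"] = len(examples)
        if write_fasta:
            fa_out = output_dir / f"genes_{name}.fa"
            with open(fa_out, "w") as fh:
                for locus in loci_part:
                    fh.write(f">{locus.id}\n{extract_gene_sequence(fasta, locus)}\n")
            result[f"{name}_fasta"] = fa_out
    return result
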