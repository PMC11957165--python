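"""Deterministic synthetic genomes, annotations, variants and a mock scorer.

The generator plants multi-exon protein-coding gene loci on both strands of
small chromosomes, with canonical GT-AG (optionally GC-AG / AT-AC /
noncanonical) introns, pseudogene decoys and paralog pairs, and emits
standard FASTA / GFF3 / VCF plus ground-truth tables, so the whole pipeline
is testable end-to-end with no downloads. With ``strong_consensus`` every
splice site carries a fixed extended consensus (donor ``CAG|GTAAGT``,
acceptor ``TTTTTC AG|G`` with a polypyrimidine run), giving learnability
tests signal comparable to real sites; spurious exact-consensus matches in
the random background are scrubbed so planted sites are the only perfect
motifs.

The mock scorer is a deterministic position-weight matcher satisfying the
scorer contract (simplex rows, output length ``n - cl``): probability
> 0.9 at exact planted-consensus matches and < 0.1 everywhere else, with
the canonical GT/AG dinucleotide weighted highest so motif-critical bases
dominate mutagenesis profiles. It stands in for a trained network in
predict / variant / mutagenesis tests.

Background sequence is uniform i.i.d. over ACGT; real base composition,
repeats and intron-length distributions are deliberately not modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .dataprep import decode_sequence, reverse_complement
from .nn.core import softmax

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "PlannedGene",
    "Site",
    "FixtureGenome",
    "generate_genome",
    "MockScorer",
    "make_mock_scorer",
    "generate_vcf",
    "DONOR_CONSENSUS",
    "ACCEPTOR_CONSENSUS",
]

# Extended splice-site consensus strings. Offsets are relative to the
# labeled site: donor offset 0 = last exonic base (string index 2), so the
# intron starts at string index 3; acceptor offset 0 = first exonic base
# (string index 8), so the intron ends at string index 7.
DONOR_OFFSET0 = 2
ACCEPTOR_OFFSET0 = 8
DONOR_CONSENSUS = {
    "GT-AG": "CAGGTAAGT",
    "GC-AG": "CAGGCAAGT",
    "AT-AC": "CAGATATCC",
    "noncanonical": "CAGCTAAGT",  # CT..AC introns: never labeled canonical
}
ACCEPTOR_CONSENSUS = {
    "GT-AG": "TTTTTCAGG",
    "GC-AG": "TTTTTCAGG",
    "AT-AC": "TTTTTCACG",
    "noncanonical": "TTTTTCACG",
}
# mock-scorer match weights: canonical dinucleotide positions count triple
DONOR_WEIGHTS = np.array([1, 1, 1, 3, 3, 1, 1, 1, 1], dtype=float)
ACCEPTOR_WEIGHTS = np.array([1, 1, 1, 1, 1, 1, 3, 3, 1], dtype=float)


@dataclass
class FixtureSpec:
    """Generation parameters; the defaults are the standard desk-scale
    study conditions used throughout the test suite."""

    seed: int = 10
    n_chromosomes: int = 6
    n_genes: int = 20
    exon_count: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (150, 400)
    intergenic: tuple[int, int] = (300, 800)
    minus_strand_fraction: float = 0.5
    pseudogene_fraction: float = 0.1
    paralog_fraction: float = 0.1
    paralog_divergence: float = 0.05
    motif_mix: dict = field(default_factory=lambda: {"GT-AG": 1.0})
    strong_consensus: bool = True
    plant_cryptic: bool = True

    def __post_init__(self):
        for name in ("exon_length", "intron_length", "intergenic"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.exon_length[0] < 12 or self.intron_length[0] < 40:
            raise ValueError("exons must be >= 12 nt and introns >= 40 nt "
                             "so planted motifs cannot collide")
        for frac in (self.minus_strand_fraction, self.pseudogene_fraction,
                     self.paralog_fraction, self.paralog_divergence):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fractions must be in [0,1], got {frac}")
        total = sum(self.motif_mix.values())
        if total <= 0:
            raise ValueError("motif_mix must have positive total weight")
        unknown = set(self.motif_mix) - set(DONOR_CONSENSUS)
        if unknown:
            raise ValueError(f"unknown motif classes: {sorted(unknown)}")


class Site(NamedTuple):
    chrom: str
    pos: int  # 0-based genomic position of the labeled base
    strand: str
    site_type: str  # donor | acceptor
    gene: str
    motif_class: str
    local_pos: int  # 0-based sense-local position within the gene


@dataclass
class PlannedGene:
    id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive genomic
    end: int
    biotype: str
    sense_seq: str
    local_exons: list[tuple[int, int]]  # 0-based half-open, sense-local
    motif_classes: list[str]
    donors_local: list[int]
    acceptors_local: list[int]
    cryptic_donors_local: list[int] = field(default_factory=list)
    paralog_of: str | None = None

    def local_to_genomic(self, local: int) -> int:
        """Map a sense-local 0-based position to a 0-based plus-strand position."""
        if self.strand == "+":
            return self.start - 1 + local
        return self.end - 1 - local


@dataclass
class FixtureGenome:
    spec: FixtureSpec
    chromosomes: dict[str, str]
    genes: list[PlannedGene]
    sites: list[Site]
    fasta_path: Path | None = None
    gff_path: Path | None = None
    truth_path: Path | None = None

    def sites_for_gene(self, gene_id: str) -> list[Site]:
        return [s for s in self.sites if s.gene == gene_id]


def _random_seq(rng, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode()


def _write_motif(seq: list, pos: int, motif: str) -> None:
    for i, ch in enumerate(motif):
        seq[pos + i] = ch


def _plan_gene(rng, spec: FixtureSpec, gene_id: str) -> PlannedGene:
    """Sense-strand gene body with planted splice motifs (coords filled later)."""
    n_exons = int(rng.integers(spec.exon_count[0], spec.exon_count[1] + 1))
    exon_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, size=n_exons)
    intron_lens = rng.integers(spec.intron_length[0], spec.intron_length[1] + 1, size=n_exons - 1)
    classes = list(spec.motif_mix)
    weights = np.array([spec.motif_mix[c] for c in classes], dtype=float)
    weights /= weights.sum()
    motif_classes = [classes[i] for i in rng.choice(len(classes), size=n_exons - 1, p=weights)]

    length = int(exon_lens.sum() + intron_lens.sum())
    seq = list(_to_str(_random_seq(rng, length)))
    exons: list[tuple[int, int]] = []
    donors, acceptors, cryptic = [], [], []
    cursor = 0
    for i, el in enumerate(exon_lens):
        exons.append((cursor, cursor + int(el)))
        cursor += int(el)
        if i < n_exons - 1:
            il = int(intron_lens[i])
            mclass = motif_classes[i]
            donor_local = cursor - 1           # last exonic base
            acceptor_local = cursor + il       # first exonic base downstream
            if spec.strong_consensus:
                _write_motif(seq, donor_local - DONOR_OFFSET0, DONOR_CONSENSUS[mclass])
                _write_motif(seq, acceptor_local - ACCEPTOR_OFFSET0, ACCEPTOR_CONSENSUS[mclass])
            else:
                don = DONOR_CONSENSUS[mclass]
                _write_motif(seq, donor_local + 1, don[DONOR_OFFSET0 + 1 : DONOR_OFFSET0 + 3])
                acc = ACCEPTOR_CONSENSUS[mclass]
                _write_motif(seq, acceptor_local - 2, acc[ACCEPTOR_OFFSET0 - 2 : ACCEPTOR_OFFSET0])
            if spec.plant_cryptic and il >= 60:
                # a donor consensus dead at the +2 position (GT -> GA); one
                # substitution away from firing
                dead = list(DONOR_CONSENSUS["GT-AG"])
                dead[DONOR_OFFSET0 + 2] = "A"
                mid = cursor + il // 2
                _write_motif(seq, mid - DONOR_OFFSET0, "".join(dead))
                cryptic.append(mid)
            donors.append(donor_local)
            acceptors.append(acceptor_local)
            cursor += il
    return PlannedGene(
        id=gene_id, chrom="", strand="+", start=0, end=0,
        biotype="protein_coding", sense_seq="".join(seq),
        local_exons=exons, motif_classes=motif_classes,
        donors_local=donors, acceptors_local=acceptors,
        cryptic_donors_local=cryptic,
    )


def _mutate_copy(rng, gene: PlannedGene, rate: float, new_id: str) -> PlannedGene:
    seq = np.frombuffer(gene.sense_seq.encode(), dtype=np.uint8).copy()
    # splice motifs stay intact in the copy (conserved, as in real paralogs)
    protected = np.zeros(len(seq), dtype=bool)
    for d in gene.donors_local:
        protected[d - DONOR_OFFSET0 : d - DONOR_OFFSET0 + 9] = True
    for a in gene.acceptors_local:
        protected[a - ACCEPTOR_OFFSET0 : a - ACCEPTOR_OFFSET0 + 9] = True
    hits = np.nonzero((rng.random(len(seq)) < rate) & ~protected)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != seq[i]]
        seq[i] = choices[int(rng.integers(0, 3))]
    return PlannedGene(
        id=new_id, chrom="", strand="+", start=0, end=0,
        biotype="protein_coding", sense_seq=seq.tobytes().decode(),
        local_exons=list(gene.local_exons), motif_classes=list(gene.motif_classes),
        donors_local=list(gene.donors_local), acceptors_local=list(gene.acceptors_local),
        cryptic_donors_local=[], paralog_of=gene.id,
    )


def _scrub_spurious(chrom: list, protected: np.ndarray, rng) -> None:
    """Mutate one base of any exact GT-AG consensus occurring outside
    planted (protected) intervals, so planted sites stay the only perfect
    matches on this strand's text in either orientation."""
    patterns = [DONOR_CONSENSUS["GT-AG"], ACCEPTOR_CONSENSUS["GT-AG"]]
    patterns += [reverse_complement(p) for p in patterns]
    for _ in range(10):  # rescan; a substitution could create a new match
        text = "".join(chrom)
        dirty = False
        for pat in patterns:
            start = text.find(pat)
            while start != -1:
                span = np.arange(start, start + len(pat))
                if not protected[span].any():
                    k = start + len(pat) // 2
                    old = chrom[k]
                    chrom[k] = "ACGT"[(("ACGT".index(old)) + 1 + int(rng.integers(0, 3))) % 4]
                    dirty = True
                start = text.find(pat, start + 1)
        if not dirty:
            return
    logger.warning("spurious-motif scrub did not converge")


def generate_genome(spec: FixtureSpec, output_dir=None) -> FixtureGenome:
    """Build the synthetic genome; optionally write FASTA/GFF3/truth TSV.

    Identical specs (including seed) produce byte-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    n_pseudo = int(round(spec.pseudogene_fraction * spec.n_genes))
    n_paralog = int(round(spec.paralog_fraction * spec.n_genes))

    base_genes = [_plan_gene(rng, spec, f"gene{i + 1:03d}") for i in range(spec.n_genes)]
    paralogs = [
        _mutate_copy(rng, base_genes[i], spec.paralog_divergence, f"{base_genes[i].id}_par")
        for i in range(min(n_paralog, len(base_genes)))
    ]
    pseudos = []
    for i in range(n_pseudo):
        length = int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
        pseudos.append(PlannedGene(
            id=f"pseudo{i + 1:03d}", chrom="", strand="+", start=0, end=0,
            biotype="processed_pseudogene",
            sense_seq=_to_str(_random_seq(rng, length)),
            local_exons=[(0, length)], motif_classes=[],
            donors_local=[], acceptors_local=[],
        ))

    # layout: base genes round-robin across chromosomes; each paralog on the
    # chromosome after its source so splits can separate the pair
    placements: dict[str, list[PlannedGene]] = {
        f"chr{c + 1}": [] for c in range(spec.n_chromosomes)
    }
    names = list(placements)
    for i, g in enumerate(base_genes):
        placements[names[i % len(names)]].append(g)
    for i, g in enumerate(paralogs):
        src_idx = i % len(names)
        placements[names[(src_idx + 1) % len(names)]].append(g)
    for i, g in enumerate(pseudos):
        placements[names[i % len(names)]].append(g)

    chromosomes: dict[str, str] = {}
    sites: list[Site] = []
    genes: list[PlannedGene] = []
    for chrom_name, members in placements.items():
        parts: list[str] = []
        protected_spans: list[tuple[int, int]] = []
        cursor = 0
        for g in members:
            gap = int(rng.integers(spec.intergenic[0], spec.intergenic[1] + 1))
            parts.append(_to_str(_random_seq(rng, gap)))
            cursor += gap
            g.chrom = chrom_name
            minus = (g.biotype == "protein_coding"
                     and rng.random() < spec.minus_strand_fraction)
            g.strand = "-" if minus else "+"
            body = reverse_complement(g.sense_seq) if minus else g.sense_seq
            g.start = cursor + 1
            g.end = cursor + len(body)
            parts.append(body)
            protected_spans.append((cursor, cursor + len(body)))
            cursor += len(body)
            genes.append(g)
        tail = int(rng.integers(spec.intergenic[0], spec.intergenic[1] + 1))
        parts.append(_to_str(_random_seq(rng, tail)))
        chrom = list("".join(parts))
        protected = np.zeros(len(chrom), dtype=bool)
        for lo, hi in protected_spans:
            protected[lo:hi] = True
        _scrub_spurious(chrom, protected, rng)
        chromosomes[chrom_name] = "".join(chrom)

    for g in genes:
        for d, mclass in zip(g.donors_local, g.motif_classes):
            sites.append(Site(g.chrom, g.local_to_genomic(d), g.strand, "donor",
                              g.id, mclass, d))
        for a, mclass in zip(g.acceptors_local, g.motif_classes):
            sites.append(Site(g.chrom, g.local_to_genomic(a), g.strand, "acceptor",
                              g.id, mclass, a))

    fixture = FixtureGenome(spec=spec, chromosomes=chromosomes, genes=genes, sites=sites)
    if output_dir is not None:
        _write_fixture(fixture, Path(output_dir))
    return fixture


def _write_fixture(fx: FixtureGenome, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fx.fasta_path = out / "genome.fa"
    with open(fx.fasta_path, "w") as fh:
        for name, seq in fx.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    fx.gff_path = out / "annotation.gff3"
    with open(fx.gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in fx.chromosomes.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in fx.genes:
            attrs = f"ID={g.id};gene_biotype={g.biotype}"
            fh.write(f"{g.chrom}\tfixture\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            tid = f"{g.id}.t1"
            fh.write(f"{g.chrom}\tfixture\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={tid};Parent={g.id}\n")
            for j, (ls, le) in enumerate(g.local_exons):
                if g.strand == "+":
                    s, e = g.start + ls, g.start + le - 1
                else:
                    s, e = g.end - le + 1, g.end - ls
                fh.write(f"{g.chrom}\tfixture\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={tid}.e{j + 1};Parent={tid}\n")
    fx.truth_path = out / "truth_sites.tsv"
    with open(fx.truth_path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tsite_type\tgene\tmotif_class\tlocal_pos\n")
        for s in fx.sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.site_type}\t{s.gene}\t"
                     f"{s.motif_class}\t{s.local_pos}\n")


# ---------------------------------------------------------------------------
# mock scorer
# ---------------------------------------------------------------------------

class MockScorer:
    """Deterministic consensus-matching scorer.

    A position's donor (acceptor) logit is ``hi_logit`` when the weighted
    9-mer around it matches the planted consensus exactly, and
    ``slope * match_fraction + base`` otherwise; the non-splice logit is 0.
    With the defaults an exact match scores ~0.997 and the best possible
    near-miss stays below 0.1.
    """

    def __init__(self, cl: int = 80, hi_logit: float = 6.0,
                 slope: float = 3.0, base: float = -5.0) -> None:
        if cl % 2 != 0:
            raise ValueError(f"cl must be even, got {cl}")
        if cl // 2 < max(DONOR_OFFSET0, len(DONOR_CONSENSUS["GT-AG"]) - DONOR_OFFSET0,
                         ACCEPTOR_OFFSET0, len(ACCEPTOR_CONSENSUS["GT-AG"]) - ACCEPTOR_OFFSET0):
            raise ValueError("cl too small for the consensus window")
        self.cl = cl
        self.hi_logit = hi_logit
        self.slope = slope
        self.base = base

    def _match(self, codes: np.ndarray, consensus: str, offset0: int,
               weights: np.ndarray) -> np.ndarray:
        length = codes.shape[0]
        score = np.zeros(length)
        pos = np.arange(length)
        for i, ch in enumerate(consensus):
            idx = pos + (i - offset0)
            valid = (idx >= 0) & (idx < length)
            hit = np.zeros(length)
            hit[valid] = (codes[idx[valid]] == ord(ch)) * weights[i]
            score += hit
        return score / weights.sum()

    def score_sequence(self, seq: str) -> np.ndarray:
        codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        m_d = self._match(codes, DONOR_CONSENSUS["GT-AG"], DONOR_OFFSET0, DONOR_WEIGHTS)
        m_a = self._match(codes, ACCEPTOR_CONSENSUS["GT-AG"], ACCEPTOR_OFFSET0, ACCEPTOR_WEIGHTS)

        def logit(m: np.ndarray) -> np.ndarray:
            return np.where(np.isclose(m, 1.0), self.hi_logit, self.slope * m + self.base)

        logits = np.stack([np.zeros(len(codes)), logit(m_a), logit(m_d)], axis=1)
        half = self.cl // 2
        return softmax(logits[half : len(codes) - half], axis=-1)

    def score_batch(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[None]
        n, length, _ = x.shape
        if length <= self.cl:
            raise ValueError(f"input length {length} must exceed cl={self.cl}")
        out = np.empty((n, length - self.cl, 3))
        for i in range(n):
            out[i] = self.score_sequence(decode_sequence(x[i]))
        return out

    # SpliceScorer-compatible aliases
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.score_batch(x)


def make_mock_scorer(cl: int = 80, hi_logit: float = 6.0,
                     slope: float = 3.0, base: float = -5.0) -> MockScorer:
    return MockScorer(cl=cl, hi_logit=hi_logit, slope=slope, base=base)


# ---------------------------------------------------------------------------
# variant fixtures
# ---------------------------------------------------------------------------

def generate_vcf(fixture: FixtureGenome, output_path, seed: int = 10) -> list[dict]:
    """Write a VCF of engineered variants plus an effects side table.

    Records include a donor-destroying SNP, an acceptor-destroying SNP, a
    cryptic-donor-creating SNP, an intergenic SNP, an over-long deletion
    and a benign mid-intron deletion, each tagged with its intended effect
    class (returned, and written next to the VCF as TSV).
    """
    rng = np.random.default_rng(seed)
    records: list[dict] = []

    def base_at(chrom: str, pos0: int) -> str:
        return fixture.chromosomes[chrom][pos0]

    def other_base(b: str, rng=rng) -> str:
        choices = [c for c in "ACGT" if c != b]
        return choices[int(rng.integers(0, 3))]

    plus_genes = [g for g in fixture.genes
                  if g.strand == "+" and g.biotype == "protein_coding" and g.donors_local]

    if plus_genes:
        g = plus_genes[0]
        # destroy the donor GT: mutate the G at local donor+1
        pos0 = g.local_to_genomic(g.donors_local[0] + 1)
        ref = base_at(g.chrom, pos0)
        records.append({"chrom": g.chrom, "pos": pos0 + 1, "ref": ref,
                        "alt": other_base(ref), "effect": "donor_loss", "gene": g.id})
        # destroy the acceptor AG: mutate the A at local acceptor-2
        pos0 = g.local_to_genomic(g.acceptors_local[0] - 2)
        ref = base_at(g.chrom, pos0)
        records.append({"chrom": g.chrom, "pos": pos0 + 1, "ref": ref,
                        "alt": other_base(ref), "effect": "acceptor_loss", "gene": g.id})
    cryptic_genes = [g for g in plus_genes if g.cryptic_donors_local]
    if cryptic_genes:
        g = cryptic_genes[0]
        # restore the dead GT of the planted cryptic donor (+2 base A -> T)
        pos0 = g.local_to_genomic(g.cryptic_donors_local[0] + 2)
        records.append({"chrom": g.chrom, "pos": pos0 + 1, "ref": base_at(g.chrom, pos0),
                        "alt": "T", "effect": "donor_gain", "gene": g.id})
    if fixture.genes:
        g0 = min(fixture.genes, key=lambda g: (g.chrom, g.start))
        chrom = g0.chrom
        pos0 = max(0, g0.start - 1 - 100)
        records.append({"chrom": chrom, "pos": pos0 + 1, "ref": base_at(chrom, pos0),
                        "alt": other_base(base_at(chrom, pos0)),
                        "effect": "skip_outside_gene", "gene": ""})
    if plus_genes:
        g = max(plus_genes, key=lambda g: g.end - g.start)
        mid = g.local_to_genomic((g.end - g.start) // 2)
        seq = fixture.chromosomes[g.chrom]
        ref = seq[mid : mid + 151]
        records.append({"chrom": g.chrom, "pos": mid + 1, "ref": ref, "alt": ref[0],
                        "effect": "skip_deletion_too_long", "gene": g.id})
        # benign 2-nt deletion in the middle of an intron, away from motifs
        g2 = plus_genes[0]
        intron_mid = (g2.donors_local[0] + g2.acceptors_local[0]) // 2 + 20
        pos0 = g2.local_to_genomic(intron_mid)
        ref = fixture.chromosomes[g2.chrom][pos0 : pos0 + 3]
        records.append({"chrom": g2.chrom, "pos": pos0 + 1, "ref": ref, "alt": ref[0],
                        "effect": "benign_indel", "gene": g2.id})

    output_path = Path(output_path)
    records.sort(key=lambda r: (r["chrom"], r["pos"]))
    with open(output_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in fixture.chromosomes.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, r in enumerate(records):
            fh.write(f"{r['chrom']}\t{r['pos']}\tvar{i + 1}\t{r['ref']}\t{r['alt']}\t.\t.\t.\n")
    with open(output_path.with_suffix(".effects.tsv"), "w") as fh:
        fh.write("id\tchrom\tpos\tref\talt\teffect\tgene\n")
        for i, r in enumerate(records):
            fh.write(f"var{i + 1}\t{r['chrom']}\t{r['pos']}\t{r['ref']}\t{r['alt']}\t"
                     f"{r['effect']}\t{r['gene']}\n")
    return records
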