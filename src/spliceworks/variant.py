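"""Variant splice-impact annotation: delta scores and delta positions.

For each variant, reference and alternate sequences spanning the variant
plus ``distance + flank/2`` context per side are scored; the acceptor and
donor probability arrays over the ``2*distance + 1`` comparison window are
differenced to yield four delta scores:

    DS_AG = max(a_alt - a_ref)    acceptor gain
    DS_AL = max(a_ref - a_alt)    acceptor loss
    DS_DG = max(d_alt - d_ref)    donor gain
    DS_DL = max(d_ref - d_alt)    donor loss

each with a delta position (the offset of the maximum relative to the
variant; negative = upstream). Negative maxima are clipped to 0 in the
reported scores (the signed value is kept for debugging). For indels the
alternate score array is realigned to the reference frame: positions inside
a deletion are masked out of the comparison, and scores over an insertion
are collapsed onto the anchor slot by maximum.

Variants are excluded (skipped with a reason, not fatal) when they fall
outside annotated genes, lie closer than ``flank`` to a chromosome end,
delete more than ``2*distance`` bases, or mismatch the reference genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataprep import encode_sequence, parse_annotation, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "DeltaAnnotation",
    "GeneIndex",
    "validate_variant",
    "build_ref_alt",
    "realign_alt",
    "delta_scores",
    "score_variant",
    "annotate_vcf",
    "DEFAULT_DISTANCE",
]

DEFAULT_DISTANCE = 50
INFO_KEY = "SPLICE_DELTA"


@dataclass
class DeltaAnnotation:
    """Four clipped delta scores, their signed values, and delta positions."""

    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    dp_ag: int
    dp_al: int
    dp_dg: int
    dp_dl: int
    signed: dict = field(default_factory=dict)
    gene: str = ""

    def info_string(self) -> str:
        return (
            f"{self.gene}|{self.ds_ag:.2f}|{self.ds_al:.2f}|{self.ds_dg:.2f}|"
            f"{self.ds_dl:.2f}|{self.dp_ag}|{self.dp_al}|{self.dp_dg}|{self.dp_dl}"
        )


class GeneIndex:
    """Gene intervals per chromosome for variant-in-gene lookups."""

    def __init__(self, loci) -> None:
        self._by_chrom: dict[str, list] = {}
        for locus in loci:
            self._by_chrom.setdefault(locus.chrom, []).append(locus)

    @classmethod
    def from_gff(cls, gff_path, biotype: str = "protein-coding") -> "GeneIndex":
        return cls(parse_annotation(gff_path, biotype_filter=biotype))

    def lookup(self, chrom: str, pos0: int):
        """First gene whose span contains the 0-based position, else None."""
        for locus in self._by_chrom.get(chrom, []):
            if locus.start - 1 <= pos0 < locus.end:
                return locus
        return None


def validate_variant(
    chrom: str,
    pos0: int,
    ref: str,
    alt: str,
    genes: GeneIndex,
    chrom_seq: str,
    flank: int,
    distance: int = DEFAULT_DISTANCE,
):
    """Accept or skip one variant; returns (gene_or_None, reason).

    ``reason`` is None on acceptance, else one of ``outside_gene``,
    ``near_chrom_end``, ``deletion_too_long``, ``ref_mismatch``.
    """
    gene = genes.lookup(chrom, pos0)
    if gene is None:
        return None, "outside_gene"
    if pos0 < flank or pos0 + len(ref) > len(chrom_seq) - flank:
        return None, "near_chrom_end"
    if len(ref) - len(alt) > 2 * distance:
        return None, "deletion_too_long"
    if chrom_seq[pos0 : pos0 + len(ref)].upper() != ref.upper():
        return None, "ref_mismatch"
    return gene, None


def build_ref_alt(
    chrom_seq: str,
    pos0: int,
    ref: str,
    alt: str,
    distance: int,
    flank: int,
) -> tuple[str, str]:
    """Reference and alternate windows centered on the variant.

    The reference window spans ``pos0 ± (distance + flank/2)`` (length
    ``2*(distance + flank/2) + 1``); the alternate window substitutes the
    alt allele, so its length differs by ``len(alt) - len(ref)``.
    """
    half = distance + flank // 2
    lo, hi = pos0 - half, pos0 + half + 1
    left = "N" * max(0, -lo) + chrom_seq[max(0, lo) : pos0]
    right = chrom_seq[pos0 : min(len(chrom_seq), hi)] + "N" * max(0, hi - len(chrom_seq))
    ref_seq = (left + right).upper()
    alt_seq = (left + alt + right[len(ref) :]).upper()
    return ref_seq, alt_seq


def realign_alt(alt_scores: np.ndarray, ref_len: int, alt_len: int, distance: int) -> np.ndarray:
    """Map alternate-window scores onto the 2*distance+1 reference frame.

    SNP/MNP: identity. Insertion: the anchor slot takes the max over the
    anchor plus inserted positions. Deletion: slots of deleted bases become
    NaN (masked from the comparison).
    """
    width = 2 * distance + 1
    center = distance
    dlen = alt_len - ref_len
    out = np.full((width,) + alt_scores.shape[1:], np.nan)
    if dlen == 0:
        return alt_scores[:width].astype(float)
    if dlen > 0:  # insertion
        out[:center] = alt_scores[:center]
        out[center] = alt_scores[center : center + dlen + 1].max(axis=0)
        out[center + 1 :] = alt_scores[center + dlen + 1 : width + dlen]
        return out
    # deletion: ref positions center+1 .. center-dlen have no alt counterpart
    out[: center + 1] = alt_scores[: center + 1]
    out[center - dlen + 1 :] = alt_scores[center + 1 : width + dlen]
    return out


def _max_with_position(diff: np.ndarray, distance: int) -> tuple[float, int]:
    """Maximum of a (possibly NaN-masked) difference array and its offset.

    Ties go to the smallest absolute offset, then upstream (negative).
    """
    offsets = np.arange(-distance, distance + 1)
    finite = np.isfinite(diff)
    if not finite.any():
        raise ValueError("empty comparison window")
    vals = diff[finite]
    offs = offsets[finite]
    best = vals.max()
    cands = offs[vals == best]
    pos = min(cands, key=lambda o: (abs(o), o))
    return float(best), int(pos)


def delta_scores(
    a_ref: np.ndarray,
    a_alt: np.ndarray,
    d_ref: np.ndarray,
    d_alt: np.ndarray,
    distance: int | None = None,
    gene: str = "",
) -> DeltaAnnotation:
    """Four delta scores/positions from aligned score arrays.

    Arrays cover the comparison window of ``2*distance + 1`` positions
    (NaN marks masked slots). Reported scores are clipped to [0, 1]; the
    signed maxima are retained in ``signed``.
    """
    width = len(a_ref)
    if width == 0:
        raise ValueError("empty comparison window")
    if distance is None:
        distance = (width - 1) // 2
    ag, dp_ag = _max_with_position(a_alt - a_ref, distance)
    al, dp_al = _max_with_position(a_ref - a_alt, distance)
    dg, dp_dg = _max_with_position(d_alt - d_ref, distance)
    dl, dp_dl = _max_with_position(d_ref - d_alt, distance)
    return DeltaAnnotation(
        ds_ag=max(ag, 0.0), ds_al=max(al, 0.0), ds_dg=max(dg, 0.0), ds_dl=max(dl, 0.0),
        dp_ag=dp_ag, dp_al=dp_al, dp_dg=dp_dg, dp_dl=dp_dl,
        signed={"ag": ag, "al": al, "dg": dg, "dl": dl},
        gene=gene,
    )


def _score_window(seq: str, scorers, strand: str) -> np.ndarray:
    """Mean class probabilities over a window, in genomic orientation."""
    s = reverse_complement(seq) if strand == "-" else seq
    x = encode_sequence(s)[None]
    mean = None
    for scorer in scorers:
        p = scorer.score_batch(x)[0]
        mean = p if mean is None else mean + p
    mean /= len(scorers)
    if strand == "-":
        mean = mean[::-1]
    return mean


def score_variant(
    chrom_seq: str,
    pos0: int,
    ref: str,
    alt: str,
    scorers,
    distance: int = DEFAULT_DISTANCE,
    strand: str = "+",
    gene: str = "",
) -> DeltaAnnotation:
    """Score one accepted variant with an ensemble of scorers."""
    scorers = scorers if isinstance(scorers, (list, tuple)) else [scorers]
    cls = {s.cl for s in scorers}
    if len(cls) != 1:
        raise ValueError(f"ensemble members disagree on flank/cropping: {sorted(cls)}")
    flank = cls.pop()
    ref_seq, alt_seq = build_ref_alt(chrom_seq, pos0, ref, alt, distance, flank)
    p_ref = _score_window(ref_seq, scorers, strand)  # (2*distance+1, 3)
    p_alt_raw = _score_window(alt_seq, scorers, strand)
    p_alt = realign_alt(p_alt_raw, len(ref), len(alt), distance)
    return delta_scores(
        p_ref[:, 1].astype(float), p_alt[:, 1],
        p_ref[:, 2].astype(float), p_alt[:, 2],
        distance=distance, gene=gene,
    )


def annotate_vcf(
    vcf_in,
    fasta_path,
    gff_path,
    scorers,
    output_path,
    distance: int = DEFAULT_DISTANCE,
) -> dict:
    """Annotate a VCF with delta scores; skipped variants pass through.

    Adds an INFO field ``SPLICE_DELTA`` =
    gene|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL per accepted
    variant. Returns counts of annotated and skipped records by reason.
    """
    import pyfaidx
    from cyvcf2 import VCF, Writer

    scorers = scorers if isinstance(scorers, (list, tuple)) else [scorers]
    flank = scorers[0].cl
    fasta = pyfaidx.Fasta(str(fasta_path))
    chrom_cache: dict[str, str] = {}
    genes = GeneIndex.from_gff(gff_path)

    vcf = VCF(str(vcf_in))
    vcf.add_info_to_header({
        "ID": INFO_KEY, "Number": ".", "Type": "String",
        "Description": "Splice delta annotation: "
                       "gene|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL",
    })
    writer = Writer(str(output_path), vcf)
    counts = {"annotated": 0, "skipped": {}}
    for rec in vcf:
        chrom = rec.CHROM
        if chrom not in chrom_cache:
            if chrom in fasta.keys():
                chrom_cache[chrom] = str(fasta[chrom][:]).upper()
            else:
                chrom_cache[chrom] = ""
        seq = chrom_cache[chrom]
        annotations = []
        for alt in rec.ALT:
            gene, reason = validate_variant(
                chrom, rec.POS - 1, rec.REF, alt, genes, seq, flank, distance
            )
            if reason is not None:
                counts["skipped"][reason] = counts["skipped"].get(reason, 0) + 1
                logger.info("variant %s:%d %s>%s skipped (%s)", chrom, rec.POS, rec.REF, alt, reason)
                continue
            ann = score_variant(seq, rec.POS - 1, rec.REF, alt, scorers,
                                distance, gene.strand, gene.id)
            annotations.append(ann.info_string())
        if annotations:
            rec.INFO[INFO_KEY] = ",".join(annotations)
            counts["annotated"] += 1
        writer.write_record(rec)
    writer.close()
    vcf.close()
    return counts
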