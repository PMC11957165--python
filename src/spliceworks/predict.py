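"""Genome-scale prediction: chunking, windowing, ensembling, BED output.

Long targets are split into memory-bounded chunks (default at most
1,500,000 bases) whose junctions overlap by ``flank/2``; on reassembly each
chunk reports its share of the overlap so every target position receives
exactly one probability triplet. Within a chunk, windows of ``5000 +
flank`` with disjoint 5,000-nt cores tile the sequence, N-padded at the
chunk ends and for a short final core. Ensemble prediction averages the
outputs of several scorers sharing one flanking configuration. Sites whose
probability exceeds a threshold (default 0.5, strict) are written to donor
and acceptor BED6 files, in genomic coordinates when the target carries
them (0-based half-open, minus-strand positions mapped back to the plus
strand) and sequence-relative otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataprep import CORE, encode_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "PredictTarget",
    "PredictionTrack",
    "Chunk",
    "plan_chunks",
    "window_chunk",
    "ensemble_predict",
    "predict_track",
    "write_bed",
    "predict_fasta",
    "SPLIT_THRESHOLD",
]

SPLIT_THRESHOLD = 1_500_000
DEFAULT_THRESHOLD = 0.5


@dataclass
class PredictTarget:
    """A sequence to predict on, optionally anchored to genomic coordinates.

    ``start``/``end`` are 0-based half-open plus-strand coordinates; when
    they are unset the target is a raw sequence and BED output is
    sequence-relative. ``sequence`` is always the sense strand.
    """

    id: str
    sequence: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "+"

    def __post_init__(self):
        if self.chrom is not None and (self.end - self.start) != len(self.sequence):
            raise ValueError(
                f"target {self.id}: span length {self.end - self.start} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class PredictionTrack:
    """Per-position class probabilities over a target, with provenance."""

    target: PredictTarget
    probabilities: np.ndarray  # (len(target.sequence), 3)
    n_models: int
    flank: int
    n_chunks: int


@dataclass
class Chunk:
    start: int  # chunk span in target coordinates, 0-based half-open
    end: int
    report_start: int  # the sub-span this chunk contributes to the track
    report_end: int


def plan_chunks(length: int, split_threshold: int = SPLIT_THRESHOLD, flank: int = 10000) -> list[Chunk]:
    """Tile a target into chunks of at most ``split_threshold`` bases.

    Adjacent chunks overlap by ``flank/2``; each half of an overlap is
    reported by the chunk for which it is interior, so reassembly covers
    every position exactly once.
    """
    if flank % 2 != 0:
        raise ValueError(f"flank must be even, got {flank}")
    if length <= split_threshold:
        return [Chunk(0, length, 0, length)]
    overlap = flank // 2
    step = split_threshold - overlap
    if step <= 0:
        raise ValueError("split_threshold must exceed flank/2")
    starts = list(range(0, length - overlap, step))
    chunks: list[Chunk] = []
    prev_boundary = 0
    for i, s in enumerate(starts):
        e = min(s + split_threshold, length)
        if i == len(starts) - 1:
            boundary = length
        else:
            boundary = starts[i + 1] + overlap // 2
        chunks.append(Chunk(s, e, prev_boundary, boundary))
        prev_boundary = boundary
    return chunks


def window_chunk(chunk_seq: str, flank: int, core: int = CORE) -> list[str]:
    """Split a chunk into windows of ``core + flank`` with disjoint cores.

    Window *w* carries ``flank/2`` context per side of its core; positions
    outside the chunk are filled with ``N``. The number of windows is
    ``ceil(len / core)`` and the model output for each window covers its
    core, so the concatenated outputs trimmed to the chunk length cover the
    chunk exactly.
    """
    if flank % 2 != 0:
        raise ValueError(f"flank must be even, got {flank}")
    length = len(chunk_seq)
    if length == 0:
        raise ValueError("empty chunk")
    half = flank // 2
    n_win = -(-length // core)
    windows = []
    for w in range(n_win):
        lo = w * core - half
        hi = w * core + core + half
        left_pad = max(0, -lo)
        right_pad = max(0, hi - length)
        body = chunk_seq[max(0, lo) : min(length, hi)]
        windows.append("N" * left_pad + body + "N" * right_pad)
    return windows


def _check_scorers(scorers) -> int:
    cls = {s.cl for s in scorers}
    if len(cls) != 1:
        raise ValueError(f"ensemble members disagree on flank/cropping: {sorted(cls)}")
    return cls.pop()


def ensemble_predict(windows: list[str] | np.ndarray, scorers, batch_size: int = 32) -> np.ndarray:
    """Mean of member predictions over a batch of equal-length windows.

    Returns ``(n_windows, window_length - cl, 3)``; the result is
    independent of ``batch_size``.
    """
    if not scorers:
        raise ValueError("need at least one scorer")
    _check_scorers(scorers)
    if isinstance(windows, np.ndarray):
        x = windows
    else:
        x = np.stack([encode_sequence(w) for w in windows])
    out = None
    for i in range(0, x.shape[0], batch_size):
        xb = x[i : i + batch_size]
        mean = None
        for scorer in scorers:
            p = scorer.score_batch(xb)
            mean = p if mean is None else mean + p
        mean /= len(scorers)
        if out is None:
            out = np.empty((x.shape[0],) + mean.shape[1:], dtype=mean.dtype)
        out[i : i + batch_size] = mean
    return out


def predict_track(
    target: PredictTarget,
    scorers,
    split_threshold: int = SPLIT_THRESHOLD,
    batch_size: int = 32,
    core: int = CORE,
) -> PredictionTrack:
    """Full chunk -> window -> ensemble -> reassemble pipeline for one target."""
    scorers = list(scorers) if not hasattr(scorers, "cl") else [scorers]
    cl = _check_scorers(scorers)
    flank = cl  # window of core+flank yields exactly `core` outputs
    seq = target.sequence.upper()
    chunks = plan_chunks(len(seq), split_threshold, flank)
    pieces = []
    for chunk in chunks:
        windows = window_chunk(seq[chunk.start : chunk.end], flank, core)
        probs = ensemble_predict(windows, scorers, batch_size)
        track = probs.reshape(-1, 3)[: chunk.end - chunk.start]
        pieces.append(track[chunk.report_start - chunk.start : chunk.report_end - chunk.start])
    full = np.concatenate(pieces)
    assert full.shape[0] == len(seq)
    return PredictionTrack(
        target=target, probabilities=full, n_models=len(scorers),
        flank=flank, n_chunks=len(chunks),
    )


def _bed_rows(track: PredictionTrack, class_index: int, threshold: float) -> list[str]:
    target = track.target
    probs = track.probabilities[:, class_index]
    rows = []
    for i in np.nonzero(probs > threshold)[0]:
        if target.chrom is None:
            chrom, pos, strand = target.id, int(i), "."
        else:
            chrom, strand = target.chrom, target.strand
            pos = target.start + int(i) if strand == "+" else target.end - 1 - int(i)
        rows.append((chrom, pos, f"{chrom}\t{pos}\t{pos + 1}\t{target.id}\t{probs[i]:.6f}\t{strand}"))
    rows.sort(key=lambda r: (r[0], r[1]))
    return [r[2] for r in rows]


def write_bed(
    tracks: list[PredictionTrack] | PredictionTrack,
    output_dir,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[Path, Path]:
    """Emit donor and acceptor BED6 files for sites scoring above threshold."""
    if isinstance(tracks, PredictionTrack):
        tracks = [tracks]
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    donor_path = output_dir / "donor.bed"
    acceptor_path = output_dir / "acceptor.bed"
    with open(acceptor_path, "w") as fa, open(donor_path, "w") as fd:
        for track in tracks:
            for line in _bed_rows(track, 1, threshold):
                fa.write(line + "\n")
            for line in _bed_rows(track, 2, threshold):
                fd.write(line + "\n")
    return donor_path, acceptor_path


def targets_from_fasta(fasta_path, annotation_gff=None, biotype: str = "protein-coding") -> list[PredictTarget]:
    """Build prediction targets: whole FASTA records, or annotated gene loci
    (sense-strand sequence with genomic anchoring) when a GFF is given."""
    import pyfaidx

    fasta = pyfaidx.Fasta(str(fasta_path))
    targets: list[PredictTarget] = []
    if annotation_gff is None:
        for name in fasta.keys():
            targets.append(PredictTarget(id=name, sequence=str(fasta[name][:]).upper()))
        return targets
    from .dataprep import extract_gene_sequence, parse_annotation

    for locus in parse_annotation(annotation_gff, biotype_filter=biotype):
        targets.append(PredictTarget(
            id=locus.id, sequence=extract_gene_sequence(fasta, locus),
            chrom=locus.chrom, start=locus.start - 1, end=locus.end,
            strand=locus.strand,
        ))
    return targets


def predict_fasta(
    fasta_path,
    scorers,
    output_dir,
    annotation_gff=None,
    threshold: float = DEFAULT_THRESHOLD,
    split_threshold: int = SPLIT_THRESHOLD,
    batch_size: int = 32,
    store_tracks: bool = False,
) -> dict:
    """Predict every target in a FASTA file and write BED outputs.

    With ``store_tracks`` the per-base probability tracks are additionally
    saved to an HDF5 archive (the streaming default writes only BED).
    """
    targets = targets_from_fasta(fasta_path, annotation_gff)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    tracks = []
    h5 = None
    if store_tracks:
        import h5py

        h5 = h5py.File(output_dir / "tracks.h5", "w")
    n_sites = 0
    try:
        for target in targets:
            track = predict_track(target, scorers, split_threshold, batch_size)
            tracks.append(track)
            if h5 is not None:
                h5.create_dataset(target.id, data=track.probabilities, compression="gzip")
    finally:
        if h5 is not None:
            h5.close()
    donor_path, acceptor_path = write_bed(tracks, output_dir, threshold)
    n_sites = sum(
        int((t.probabilities[:, 1:] > threshold).sum()) for t in tracks
    )
    return {
        "donor_bed": donor_path,
        "acceptor_bed": acceptor_path,
        "n_targets": len(targets),
        "n_sites": n_sites,
    }
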