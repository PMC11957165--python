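"""Pairwise DNA aligner backends for paralog detection.

The paralog filter only needs, for a query sequence against a set of target
sequences, the best local hits expressed as ``(identity, coverage)`` where
identity = matching bases / alignment block length and coverage = aligned
query span / query length. Two backends implement that contract:

* :class:`Minimap2Aligner` — shells out to the ``minimap2`` executable with
  the assembly-to-assembly preset tolerating ~20% divergence; suited to
  gene-length and chromosome-length sequences.
* :class:`ExactLocalAligner` — exact dynamic-programming local alignment
  (Smith-Waterman via Bio.Align.PairwiseAligner); exhaustive and intended
  for short test fixtures and as an independent oracle.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import NamedTuple, Protocol, Sequence

__all__ = ["AlignmentHit", "ParalogAligner", "ExactLocalAligner", "Minimap2Aligner"]


class AlignmentHit(NamedTuple):
    identity: float
    coverage: float


class ParalogAligner(Protocol):
    def align(self, query: str, targets: Sequence[str]) -> list[AlignmentHit]:
        """Best local hit of ``query`` against each target (may be empty)."""
        ...


class ExactLocalAligner:
    """Exact Smith-Waterman local alignment (affine gaps).

    Identity counts matched columns over all alignment columns (including
    gap columns); coverage is the aligned query span over the query length.
    """

    def __init__(self, match: float = 2.0, mismatch: float = -1.0,
                 open_gap: float = -4.0, extend_gap: float = -0.5) -> None:
        from Bio import Align

        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.match_score = match
        self._aligner.mismatch_score = mismatch
        self._aligner.open_gap_score = open_gap
        self._aligner.extend_gap_score = extend_gap

    def align(self, query: str, targets: Sequence[str]) -> list[AlignmentHit]:
        hits: list[AlignmentHit] = []
        q = query.upper()
        for target in targets:
            t = target.upper()
            if self._aligner.score(t, q) <= 0:
                continue
            # co-optimal alignment counts can overflow; take the first path only
            aln = next(iter(self._aligner.align(t, q)))
            counts = aln.counts()
            block = counts.identities + counts.mismatches + counts.gaps
            if block == 0:
                continue
            qspan = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
            hits.append(AlignmentHit(counts.identities / block, qspan / len(q)))
        return hits


class Minimap2Aligner:
    """minimap2-backed aligner (PAF output, divergent-assembly preset).

    Parses matches / alignment-block-length (PAF columns 10/11) as identity
    and the aligned query fraction as coverage; reports the best hit per
    target sequence.
    """

    def __init__(self, preset: str = "asm20", executable: str = "minimap2") -> None:
        self.preset = preset
        self.executable = executable
        if shutil.which(executable) is None:
            raise RuntimeError(f"{executable!r} not found on PATH")

    def align(self, query: str, targets: Sequence[str]) -> list[AlignmentHit]:
        with tempfile.TemporaryDirectory() as tmp:
            qpath = Path(tmp) / "query.fa"
            tpath = Path(tmp) / "targets.fa"
            qpath.write_text(f">q\n{query}\n")
            with open(tpath, "w") as fh:
                for i, t in enumerate(targets):
                    fh.write(f">t{i}\n{t}\n")
            proc = subprocess.run(
                [self.executable, "-x", self.preset, "-c", str(tpath), str(qpath)],
                capture_output=True, text=True,
            )
            if proc.returncode != 0:
                raise RuntimeError(f"minimap2 failed: {proc.stderr.strip()}")
            best: dict[str, AlignmentHit] = {}
            for line in proc.stdout.splitlines():
                f = line.split("\t")
                if len(f) < 12:
                    continue
                qlen, qstart, qend = int(f[1]), int(f[2]), int(f[3])
                matches, block = int(f[9]), int(f[10])
                if block == 0 or qlen == 0:
                    continue
                hit = AlignmentHit(matches / block, (qend - qstart) / qlen)
                prev = best.get(f[5])
                if prev is None or hit.identity * hit.coverage > prev.identity * prev.coverage:
                    best[f[5]] = hit
            return list(best.values())
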