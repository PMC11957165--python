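"""HDF5 dataset archives.

An archive stores the segmented examples of a dataset in batch groups, each
concatenating the segment tensors of up to 100 genes along the first axis:
datasets ``X{i}`` (float32, one-hot features) and ``Y{i}`` (uint8 labels),
plus per-batch gene ids and per-gene segment counts so examples can be
reconstructed losslessly. Root attributes record the flanking size, the
encoding version and any split metadata.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .dataprep import SegmentedExample

__all__ = ["write_archive", "read_archive", "read_metadata", "BATCH_GENES", "ENCODING_VERSION"]

BATCH_GENES = 100  # genes concatenated per batch group
ENCODING_VERSION = 1


def write_archive(
    path,
    examples: list[SegmentedExample],
    flank: int,
    metadata: dict | None = None,
    batch_genes: int = BATCH_GENES,
) -> None:
    if not examples:
        raise ValueError("cannot write an archive with no examples")
    win = examples[0].x.shape[1]
    for ex in examples:
        if ex.x.shape[1] != win:
            raise ValueError("heterogeneous window sizes in archive; "
                             "all examples must share one flanking configuration")
    with h5py.File(path, "w") as fh:
        fh.attrs["flank"] = flank
        fh.attrs["encoding_version"] = ENCODING_VERSION
        for k, v in (metadata or {}).items():
            fh.attrs[k] = v
        n_batches = -(-len(examples) // batch_genes)
        fh.attrs["n_batches"] = n_batches
        for b in range(n_batches):
            chunk = examples[b * batch_genes : (b + 1) * batch_genes]
            fh.create_dataset(f"X{b}", data=np.concatenate([ex.x for ex in chunk]),
                              compression="gzip", compression_opts=1)
            fh.create_dataset(f"Y{b}", data=np.concatenate([ex.y for ex in chunk]),
                              compression="gzip", compression_opts=1)
            fh.create_dataset(f"ids{b}", data=np.array([ex.gene_id for ex in chunk], dtype="S"))
            fh.create_dataset(f"nseg{b}", data=np.array([ex.x.shape[0] for ex in chunk]))


def read_archive(path) -> tuple[list[SegmentedExample], dict]:
    """Read an archive back into per-gene examples plus its metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    examples: list[SegmentedExample] = []
    try:
        with h5py.File(path, "r") as fh:
            meta = dict(fh.attrs)
            for b in range(int(meta["n_batches"])):
                x = fh[f"X{b}"][...]
                y = fh[f"Y{b}"][...]
                ids = [s.decode() for s in fh[f"ids{b}"][...]]
                nseg = fh[f"nseg{b}"][...]
                offsets = np.concatenate([[0], np.cumsum(nseg)])
                for gid, lo, hi in zip(ids, offsets[:-1], offsets[1:]):
                    examples.append(SegmentedExample(gene_id=gid, x=x[lo:hi], y=y[lo:hi]))
    except OSError as exc:
        raise OSError(f"corrupt or unreadable archive {path}: {exc}") from exc
    return examples, meta


def read_metadata(path) -> dict:
    with h5py.File(path, "r") as fh:
        return dict(fh.attrs)
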