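"""Fixed-width sliding-frame loci and spanning-read depth selection.

A frame is a fixed-width genomic interval (default 40 bp) that defines one
haplotyping locus. Frames tile each contig start-to-start at ``frame_distance``
(default 40, i.e. contiguous and non-overlapping); a trailing interval shorter
than ``frame_size`` is dropped so every locus has identical width.

Coordinates are 0-based half-open throughout; BED output uses the same
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam


@dataclass(frozen=True, order=True)
class FrameLocus:
    contig: str
    start: int  # 0-based inclusive
    end: int    # exclusive

    @property
    def locus_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"

    @classmethod
    def from_id(cls, locus_id: str) -> "FrameLocus":
        contig, span = locus_id.rsplit(":", 1)
        start, end = span.split("-")
        return cls(contig, int(start), int(end))


def define_frames(reference_lengths: Mapping[str, int], frame_size: int = 40,
                  frame_distance: int = 40) -> list[FrameLocus]:
    """Tile every contig with frames of ``frame_size`` bp, ``frame_distance``
    apart start-to-start; drop any trailing partial frame."""
    if frame_size < 1:
        raise ValueError(f"frame_size must be >= 1, got {frame_size}")
    if frame_distance < frame_size:
        raise ValueError(
            f"frame_distance ({frame_distance}) must be >= frame_size ({frame_size})")
    frames = []
    for contig, length in reference_lengths.items():
        if length is None or length < 0:
            raise ValueError(f"unknown length for contig {contig!r}")
        start = 0
        while start + frame_size <= length:
            frames.append(FrameLocus(contig, start, start + frame_size))
            start += frame_distance
    return frames


def _read_spans(read: pysam.AlignedSegment, start: int, end: int,
                min_mapq: int) -> bool:
    """True iff the read fully spans [start, end), has mapq >= min_mapq, and
    carries no insertion/deletion/skip operation overlapping the frame."""
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.mapping_quality < min_mapq:
        return False
    if read.reference_start > start or read.reference_end is None or read.reference_end < end:
        return False
    ref_pos = read.reference_start
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X consume both
            ref_pos += length
        elif op in (2, 3):  # D, N consume reference; overlap with frame disqualifies
            if ref_pos < end and ref_pos + length > start:
                return False
            ref_pos += length
        elif op == 1:  # I consumes query only; breakpoint inside frame disqualifies
            if start < ref_pos < end:
                return False
        # S/H/P consume no reference and cannot fall inside a spanned frame
    return True


def spanning_depth(frame: FrameLocus, alignments: pysam.AlignmentFile | Iterable,
                   min_mapq: int = 30) -> int:
    """Count reads that completely span the frame at mapq >= ``min_mapq``."""
    if isinstance(alignments, pysam.AlignmentFile):
        try:
            reads = alignments.fetch(frame.contig, frame.start, frame.end)
        except ValueError:  # no index (plain SAM): stream from the top instead
            alignments.reset()
            reads = (r for r in alignments if r.reference_name == frame.contig)
    else:
        reads = alignments
    return sum(1 for r in reads if _read_spans(r, frame.start, frame.end, min_mapq))


def depth_matrix(frames: Sequence[FrameLocus], sam_paths: Mapping[str, str | Path],
                 min_mapq: int = 30) -> pd.DataFrame:
    """Spanning-read depth per (frame, sample) as a loci x samples DataFrame.

    Streams each SAM once: every read is credited to the frames it fully
    spans, which is far cheaper than a per-frame fetch for dense tilings.
    """
    frame_index: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for i, f in enumerate(frames):
        frame_index.setdefault(f.contig, ([], [], []))
        starts, ends, idx = frame_index[f.contig]
        starts.append(f.start)
        ends.append(f.end)
        idx.append(i)
    frame_index = {c: (np.asarray(s), np.asarray(e), np.asarray(i))
                   for c, (s, e, i) in frame_index.items()}

    samples = sorted(sam_paths)
    depth = np.zeros((len(frames), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        with pysam.AlignmentFile(str(sam_paths[sample]), check_sq=False) as sam:
            for read in sam:
                if read.is_unmapped or read.mapping_quality < min_mapq:
                    continue
                contig = read.reference_name
                if contig not in frame_index:
                    continue
                starts, ends, idx = frame_index[contig]
                # candidate frames entirely inside the read's aligned span
                lo = np.searchsorted(starts, read.reference_start)
                hi = np.searchsorted(ends, read.reference_end, side="right")
                for k in range(lo, hi):
                    if _read_spans(read, int(starts[k]), int(ends[k]), 0):
                        depth[idx[k], j] += 1
    return pd.DataFrame(depth, index=[f.locus_id for f in frames], columns=samples)


def select_loci(frames: Sequence[FrameLocus], depths: pd.DataFrame,
                min_depth: int = 8, completeness: float = 0.9) -> list[FrameLocus]:
    """Retain frames where the fraction of samples with spanning depth
    >= ``min_depth`` is strictly greater than ``completeness``."""
    if depths.shape[1] == 0:
        raise ValueError("select_loci requires at least one sample")
    frac = (depths >= min_depth).mean(axis=1)
    keep = set(frac.index[frac > completeness])
    return [f for f in frames if f.locus_id in keep]


def write_bed(frames: Sequence[FrameLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.locus_id}\n")


def read_bed(path: str | Path) -> list[FrameLocus]:
    frames = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            frames.append(FrameLocus(parts[0], int(parts[1]), int(parts[2])))
    return frames
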