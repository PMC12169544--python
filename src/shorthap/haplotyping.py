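"""Read-backed short-haplotype calling within sliding frames.

For each frame (locus) and sample, every read that completely spans the
frame contributes one haplotype string: its base at each SNP position of the
locus, in coordinate order. Reads with indels overlapping the frame, mapq
below threshold, or partial overlap contribute nothing; read orientation is
ignored. Haplotype read counts are converted to percent frequencies of the
per-cell total and thresholded into discrete diploid dosages using frequency
interval bounds (default 15/15/85/85): below the noise floor (-f 10) a
haplotype is absent; frequency < 15 -> dosage 0; 15..85 -> 1; > 85 -> 2.

A diploid cell is *correct* when its dosages sum to 2. Loci are retained
when strictly more than 90% of samples have data and strictly more than 90%
of those cells are correct; incorrect cells inside retained loci are masked
to missing so no downstream statistic sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from shorthap.frames import FrameLocus, _read_spans
from shorthap.variants import SnpRecord

Cell = dict[str, int]  # haplotype string -> dosage (or read count)


@dataclass
class HaplotypeCountTable:
    """Read counts per haplotype per (locus, sample)."""

    entries: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)
    loci: list[str] = field(default_factory=list)

    def counts(self, locus_id: str, sample: str) -> dict[str, int]:
        return self.entries.get((locus_id, sample), {})


@dataclass
class DosageMatrix:
    """Discrete haplotype dosages per (locus, sample); ploidy-2 cells.

    A cell is either a dict haplotype -> dosage in {1, 2} (dosage-0 entries
    omitted) or None for missing. ``calls`` is keyed (locus_id, sample).
    """

    calls: dict[tuple[str, str], Cell | None] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)
    loci: list[str] = field(default_factory=list)
    ploidy: int = 2

    def cell(self, locus_id: str, sample: str) -> Cell | None:
        return self.calls.get((locus_id, sample))

    def subset_loci(self, loci: Sequence[str]) -> "DosageMatrix":
        keep = set(loci)
        return DosageMatrix(
            calls={k: v for k, v in self.calls.items() if k[0] in keep},
            samples=list(self.samples), loci=[l for l in self.loci if l in keep],
            ploidy=self.ploidy)

    def n_haplotypes(self) -> int:
        """Distinct (locus, haplotype) alleles observed across all samples."""
        seen = set()
        for (locus, _s), cell in self.calls.items():
            if cell:
                seen.update((locus, h) for h in cell)
        return len(seen)

    def to_frame(self) -> pd.DataFrame:
        """Long-to-wide table: rows (locus, haplotype), columns samples."""
        rows = {}
        for (locus, sample), cell in self.calls.items():
            if cell is None:
                continue
            for hap, dose in cell.items():
                rows.setdefault((locus, hap), {})[sample] = dose
        df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=self.samples)
        df.index = pd.MultiIndex.from_tuples(df.index, names=["locus", "haplotype"])
        return df.sort_index()

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame().reset_index()
        df.to_csv(path, sep="\t", index=False, float_format="%g")

    @classmethod
    def read_tsv(cls, path: str | Path, loci: Sequence[str] | None = None) -> "DosageMatrix":
        """Round-trip reader for :meth:`write_tsv` output.

        Note: a TSV cannot distinguish a missing cell from dosage zero at a
        locus where the sample has no listed haplotype; cells with no entry
        at any haplotype of the locus are read back as missing.
        """
        df = pd.read_csv(path, sep="\t", dtype={"locus": str, "haplotype": str})
        samples = [c for c in df.columns if c not in ("locus", "haplotype")]
        calls: dict[tuple[str, str], Cell | None] = {}
        loci_seen = list(dict.fromkeys(df["locus"]))
        for locus, grp in df.groupby("locus", sort=False):
            for s in samples:
                cell = {hap: int(v) for hap, v in zip(grp["haplotype"], grp[s])
                        if pd.notna(v) and int(v) > 0}
                calls[(locus, s)] = cell if cell else None
        return cls(calls=calls, samples=samples,
                   loci=list(loci) if loci is not None else loci_seen)


def extract_haplotypes(locus: FrameLocus, snp_positions: Sequence[int],
                       alignments: pysam.AlignmentFile | Iterable,
                       min_mapq: int = 30) -> dict[str, int]:
    """Haplotype-string read counts for one (locus, sample).

    ``snp_positions`` are 0-based reference positions, sorted, inside the
    frame. With no SNPs the locus is monomorphic and every spanning read
    contributes the single haplotype ``"ref"``.
    """
    positions = list(snp_positions)
    if any(p < locus.start or p >= locus.end for p in positions):
        raise ValueError(f"SNP positions outside frame {locus.locus_id}")
    if sorted(positions) != positions:
        raise ValueError("snp_positions must be sorted")
    if isinstance(alignments, pysam.AlignmentFile):
        try:
            reads = alignments.fetch(locus.contig, locus.start, locus.end)
        except ValueError:
            alignments.reset()
            reads = (r for r in alignments if r.reference_name == locus.contig)
    else:
        reads = alignments
    counts: dict[str, int] = {}
    for read in reads:
        if not _read_spans(read, locus.start, locus.end, min_mapq):
            continue
        hap = _read_haplotype(read, positions)
        if hap is not None:
            counts[hap] = counts.get(hap, 0) + 1
    return counts


def _read_haplotype(read: pysam.AlignedSegment, positions: Sequence[int]) -> str | None:
    if not positions:
        return "ref"
    seq = read.query_sequence
    if read.cigartuples is not None and len(read.cigartuples) == 1 and \
            read.cigartuples[0][0] == 0:
        # full-length match: index the query directly
        offset = read.reference_start
        return "".join(seq[p - offset] for p in positions)
    lookup = {rpos: qpos for qpos, rpos in read.get_aligned_pairs(matches_only=True)}
    bases = []
    for p in positions:
        q = lookup.get(p)
        if q is None:
            return None
        bases.append(seq[q])
    return "".join(bases)


def call_dosage(counts: Mapping[str, int], min_read_count: int = 8,
                min_freq_pct: float = 10.0,
                bounds: tuple[float, float, float, float] = (15, 15, 85, 85),
                ploidy: int = 2) -> Cell | None:
    """Convert haplotype read counts into discrete dosages, or None (missing).

    Frequencies are percentages of the total cell read count, including
    sub-threshold haplotypes (no renormalization after the noise floor).
    With the default coincident bounds (15,15,85,85) every frequency maps to
    a dosage; with separated bounds a frequency inside an undefined gap makes
    the whole cell missing.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative read counts")
    if list(bounds) != sorted(bounds) or not all(0 <= b <= 100 for b in bounds):
        raise ValueError(f"bounds must be non-decreasing within [0, 100]: {bounds}")
    total = sum(counts.values())
    if total < min_read_count:
        return None
    cell: Cell = {}
    for hap, c in counts.items():
        freq = 100.0 * c / total
        if freq < min_freq_pct:
            continue
        if freq < bounds[0]:
            dose = 0
        elif bounds[1] <= freq <= bounds[2]:
            dose = 1
        elif freq > bounds[3]:
            dose = ploidy
        else:
            return None  # frequency inside an undefined gap: no confident call
        if dose > 0:
            cell[hap] = dose
    return cell


def correctness_flag(cell: Cell | None, ploidy: int = 2) -> bool:
    """True iff the cell is non-missing and its dosages sum to the ploidy."""
    return cell is not None and sum(cell.values()) == ploidy


def build_dosage_matrix(loci: Sequence[FrameLocus],
                        snps_per_locus: Mapping[str, Sequence[SnpRecord]],
                        sam_paths: Mapping[str, str | Path],
                        min_mapq: int = 30, min_read_count: int = 8,
                        min_freq_pct: float = 10.0,
                        bounds: tuple[float, float, float, float] = (15, 15, 85, 85),
                        ploidy: int = 2) -> tuple[HaplotypeCountTable, DosageMatrix]:
    """Extract haplotype counts and call dosages for all (locus, sample) cells.

    Streams each sample's alignment file once, assigning every read to the
    frames it fully spans.
    """
    samples = sorted(sam_paths)
    by_contig: dict[str, list[FrameLocus]] = {}
    for f in loci:
        by_contig.setdefault(f.contig, []).append(f)
    for c in by_contig:
        by_contig[c].sort()
    positions = {f.locus_id: sorted(r.position - 1 for r in snps_per_locus.get(f.locus_id, []))
                 for f in loci}
    starts_arr = {c: np.asarray([f.start for f in fr]) for c, fr in by_contig.items()}

    table = HaplotypeCountTable(samples=samples, loci=[f.locus_id for f in loci])
    for sample in samples:
        with pysam.AlignmentFile(str(sam_paths[sample]), check_sq=False) as sam:
            for read in sam:
                if read.is_unmapped or read.mapping_quality < min_mapq:
                    continue
                frames = by_contig.get(read.reference_name)
                if not frames:
                    continue
                starts = starts_arr[read.reference_name]
                lo = int(np.searchsorted(starts, read.reference_start))
                for f in frames[lo:]:
                    if f.end > read.reference_end:
                        break
                    if not _read_spans(read, f.start, f.end, 0):
                        continue
                    hap = _read_haplotype(read, positions[f.locus_id])
                    if hap is None:
                        continue
                    key = (f.locus_id, sample)
                    cell = table.entries.setdefault(key, {})
                    cell[hap] = cell.get(hap, 0) + 1

    matrix = DosageMatrix(samples=samples, loci=[f.locus_id for f in loci], ploidy=ploidy)
    for f in loci:
        for sample in samples:
            counts = table.entries.get((f.locus_id, sample), {})
            matrix.calls[(f.locus_id, sample)] = call_dosage(
                counts, min_read_count=min_read_count, min_freq_pct=min_freq_pct,
                bounds=bounds, ploidy=ploidy)
    return table, matrix


def filter_loci(matrix: DosageMatrix, completeness: float = 0.9,
                correctness: float = 0.9) -> tuple[list[str], DosageMatrix]:
    """Retain loci passing completeness AND correctness, masking bad cells.

    A locus is retained iff the fraction of samples with a non-missing cell
    is strictly greater than ``completeness`` and the fraction of non-missing
    cells whose dosages sum to the ploidy is strictly greater than
    ``correctness``. In the returned matrix, incorrect cells of retained loci
    are set missing.
    """
    if not matrix.calls:
        raise ValueError("empty dosage matrix")
    n_samples = len(matrix.samples)
    retained: list[str] = []
    filtered = DosageMatrix(samples=list(matrix.samples), ploidy=matrix.ploidy)
    for locus in matrix.loci:
        cells = [matrix.calls.get((locus, s)) for s in matrix.samples]
        present = [c for c in cells if c is not None]
        if not present or len(present) / n_samples <= completeness:
            continue
        correct = sum(correctness_flag(c, matrix.ploidy) for c in present)
        if correct / len(present) <= correctness:
            continue
        retained.append(locus)
        for s, c in zip(matrix.samples, cells):
            ok = correctness_flag(c, matrix.ploidy)
            filtered.calls[(locus, s)] = c if ok else None
    filtered.loci = retained
    return retained, filtered


def het_fraction(matrix: DosageMatrix, sample: str) -> float | None:
    """Fraction of this sample's non-missing correct cells carrying >= 2
    distinct haplotypes; None when the sample has no usable data."""
    n_data = 0
    n_het = 0
    for locus in matrix.loci:
        cell = matrix.calls.get((locus, sample))
        if not correctness_flag(cell, matrix.ploidy):
            continue
        n_data += 1
        if sum(1 for d in cell.values() if d >= 1) >= 2:
            n_het += 1
    return n_het / n_data if n_data else None
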