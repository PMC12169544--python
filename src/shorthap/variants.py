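"""Bi-allelic SNP handling: VCF ingest/output, GATK-style hard filters,
singleton detection, locus subsetting, and a naive pileup caller used on
synthetic alignments.

Genotypes are coded per sample as 0 (hom-ref), 1 (het), 2 (hom-alt), or -1
(missing). Only bi-allelic single-nucleotide records are kept on ingest;
indel and multi-allelic records are dropped with a counted log message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from shorthap.frames import FrameLocus

logger = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: GATK-style hard-filter thresholds: annotation -> (comparison, cutoff).
#: A record fails if any PRESENT annotation violates its rule; absent
#: annotations never fail a record.
DEFAULT_HARD_FILTERS: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "SOR": (">", 3.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -8.0),
}


@dataclass
class SnpRecord:
    contig: str
    position: int  # 1-based, VCF convention
    ref: str
    alt: str
    genotypes: np.ndarray  # int8 per sample in sample order
    annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.key}: only single-nucleotide alleles allowed")
        if self.ref == self.alt:
            raise ValueError(f"{self.key}: ref and alt alleles are identical")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.position}"


def read_vcf(path: str | Path) -> tuple[list[SnpRecord], list[str]]:
    """Load bi-allelic SNP records; drop indels/multi-allelics with a count."""
    records: list[SnpRecord] = []
    dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                dropped += 1
                continue
            gts = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                gts[i] = int(sum(gt))
            annotations = {}
            for key in DEFAULT_HARD_FILTERS:
                if key in rec.info:
                    v = rec.info[key]
                    try:
                        annotations[key] = float(v[0] if isinstance(v, tuple) else v)
                    except (TypeError, ValueError) as exc:
                        raise ValueError(
                            f"malformed {key} annotation at {rec.chrom}:{rec.pos}") from exc
            records.append(SnpRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0],
                                     gts, annotations))
    if dropped:
        logger.info("dropped %d non-bi-allelic/indel records on ingest", dropped)
    return records, samples


def write_vcf(records: Sequence[SnpRecord], samples: Sequence[str],
              contig_lengths: Mapping[str, int], path: str | Path,
              fail_reasons: Mapping[str, list[str]] | None = None) -> None:
    """Write records as VCF v4.2; FILTER carries fail reasons where given."""
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    for key in DEFAULT_HARD_FILTERS:
        header.info.add(key, 1, "Float", f"{key} site annotation")
        header.filters.add(key, None, None, f"Failed {key} hard filter")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    gt_map = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(contig=r.contig, start=r.position - 1,
                                 alleles=(r.ref, r.alt))
            for key, v in r.annotations.items():
                rec.info[key] = v
            reasons = (fail_reasons or {}).get(r.key)
            if reasons:
                for reason in reasons:
                    rec.filter.add(reason)
            else:
                rec.filter.add("PASS")
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = gt_map[int(r.genotypes[i])]
            vcf.write(rec)


def apply_hard_filters(records: Iterable[SnpRecord],
                       thresholds: Mapping[str, tuple[str, float]] | None = None,
                       ) -> tuple[list[SnpRecord], dict[str, list[str]]]:
    """Split records into retained and failed; failures name violated keys.

    A record fails when any present annotation violates its threshold;
    records missing an annotation pass that annotation's test.
    """
    thresholds = dict(DEFAULT_HARD_FILTERS if thresholds is None else thresholds)
    retained: list[SnpRecord] = []
    reasons: dict[str, list[str]] = {}
    for rec in records:
        violated = []
        for key, (op, cutoff) in thresholds.items():
            if key not in rec.annotations:
                continue
            v = rec.annotations[key]
            if not isinstance(v, (int, float)) or not np.isfinite(v):
                raise ValueError(f"malformed {key} annotation in record {rec.key}")
            if (op == "<" and v < cutoff) or (op == ">" and v > cutoff):
                violated.append(key)
        if violated:
            reasons[rec.key] = violated
        else:
            retained.append(rec)
    return retained, reasons


def find_singletons(records: Iterable[SnpRecord]) -> set[str]:
    """Record keys heterozygous in exactly one sample and homozygous-identical
    in every other sample with data."""
    singletons = set()
    for rec in records:
        g = rec.genotypes[rec.genotypes != MISSING]
        if np.count_nonzero(g == HET) != 1:
            continue
        others = g[g != HET]
        if others.size == 0 or np.all(others == others[0]):
            singletons.add(rec.key)
    return singletons


def subset_to_loci(records: Iterable[SnpRecord],
                   loci: Sequence[FrameLocus]) -> list[SnpRecord]:
    """Keep records whose 1-based position falls inside a retained frame
    (frames are 0-based half-open)."""
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for f in loci:
        by_contig.setdefault(f.contig, ([], []))
        by_contig[f.contig][0].append(f.start)
        by_contig[f.contig][1].append(f.end)
    by_contig = {c: (np.sort(np.asarray(s)), np.asarray(e)[np.argsort(np.asarray(s))])
                 for c, (s, e) in by_contig.items()}
    out = []
    for rec in records:
        if rec.contig not in by_contig:
            continue
        starts, ends = by_contig[rec.contig]
        pos0 = rec.position - 1
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i >= 0 and pos0 < ends[i]:
            out.append(rec)
    return out


def snps_by_locus(records: Sequence[SnpRecord],
                  loci: Sequence[FrameLocus]) -> dict[str, list[SnpRecord]]:
    """Group records by the locus containing them (empty lists included)."""
    grouped: dict[str, list[SnpRecord]] = {f.locus_id: [] for f in loci}
    frames_sorted: dict[str, list[FrameLocus]] = {}
    for f in loci:
        frames_sorted.setdefault(f.contig, []).append(f)
    for contig in frames_sorted:
        frames_sorted[contig].sort()
    for rec in sorted(records, key=lambda r: (r.contig, r.position)):
        frames = frames_sorted.get(rec.contig, [])
        pos0 = rec.position - 1
        starts = [f.start for f in frames]
        i = int(np.searchsorted(np.asarray(starts), pos0, side="right")) - 1
        if i >= 0 and pos0 < frames[i].end:
            grouped[frames[i].locus_id].append(rec)
    return grouped


def naive_pileup_caller(sam_paths: Mapping[str, str | Path], reference: Mapping[str, str],
                        min_depth: int = 8, min_alt_fraction: float = 0.2,
                        min_mapq: int = 30) -> tuple[list[SnpRecord], list[str]]:
    """Call bi-allelic SNPs from per-sample pileups.

    A site is emitted when at least two alleles each reach ``min_alt_fraction``
    of some sample's pileup (at depth >= ``min_depth``). Per-sample genotypes
    follow majority composition: het when both the ref and alt allele reach
    ``min_alt_fraction`` of the sample's ref+alt reads. Annotations are
    synthesized as pass-like constants.

    Stands in for a full haplotype-based caller when the inputs are synthetic
    alignments with exact positions.
    """
    samples = sorted(sam_paths)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    # counts[sample][contig] -> 4 x L array of base counts
    counts: dict[str, dict[str, np.ndarray]] = {}
    for sample in samples:
        counts[sample] = {}
        with pysam.AlignmentFile(str(sam_paths[sample]), check_sq=False) as sam:
            per_contig = {c: np.zeros((4, len(seq)), dtype=np.int32)
                          for c, seq in reference.items()}
            for read in sam:
                if read.is_unmapped or read.mapping_quality < min_mapq:
                    continue
                arr = per_contig.get(read.reference_name)
                if arr is None:
                    continue
                seq = read.query_sequence
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    b = base_idx.get(seq[qpos])
                    if b is not None:
                        arr[b, rpos] += 1
            counts[sample] = per_contig

    records: list[SnpRecord] = []
    pass_annotations = {"QD": 20.0, "FS": 1.0, "SOR": 1.0, "MQ": 60.0, "MQRankSum": 0.0}
    for contig, seq in reference.items():
        stacked = np.stack([counts[s][contig] for s in samples])  # S x 4 x L
        depths = stacked.sum(axis=1)  # S x L
        with np.errstate(invalid="ignore", divide="ignore"):
            fracs = stacked / depths[:, None, :]
        ok = depths >= min_depth  # S x L
        qualifies = (fracs >= min_alt_fraction) & ok[:, None, :]  # S x 4 x L
        n_alleles = qualifies.any(axis=0).sum(axis=0)  # L
        for pos in np.flatnonzero(n_alleles >= 2):
            ref_base = seq[pos]
            ref_i = base_idx.get(ref_base)
            if ref_i is None:
                continue
            totals = stacked[:, :, pos].sum(axis=0)
            order = [i for i in np.argsort(-totals) if qualifies[:, i, pos].any()]
            alt_candidates = [i for i in order if i != ref_i]
            if not alt_candidates or ref_i not in order:
                continue
            alt_i = alt_candidates[0]
            gts = np.full(len(samples), MISSING, dtype=np.int8)
            for si in range(len(samples)):
                d = stacked[si, ref_i, pos] + stacked[si, alt_i, pos]
                if depths[si, pos] < min_depth or d == 0:
                    continue
                f_alt = stacked[si, alt_i, pos] / d
                if f_alt >= min_alt_fraction and (1 - f_alt) >= min_alt_fraction:
                    gts[si] = HET
                else:
                    gts[si] = HOM_ALT if f_alt > 0.5 else HOM_REF
            records.append(SnpRecord(contig, int(pos) + 1, ref_base, "ACGT"[alt_i],
                                     gts, dict(pass_annotations)))
    return records, samples
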