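"""Pairwise Jaccard Inverse Distance (JID) between samples from the discrete
haplotype dosage table, with locus-bootstrap replicate matrices.

Each sample's profile is its set of present (locus, haplotype) items
(dosage >= 1); dosage magnitude does not weight the computation. For a pair,
only loci where BOTH samples carry a non-missing correct call enter the
comparison (pairwise-complete). J = |A ∩ B| / |A ∪ B| over those items and
JID = 1 − J, so 0 means identical haplotype profiles and 1 means fully
disjoint ones.

Bootstrap replicates resample loci with replacement to the original locus
count; resampled copies of a locus count as distinct items, which makes each
replicate a plain re-weighting of per-locus intersection/union tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from shorthap.haplotyping import DosageMatrix, correctness_flag


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with a zero diagonal."""

    samples: list[str]
    values: np.ndarray  # n x n float, NaN where undefined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample list")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.samples.index(a), self.samples.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(samples=list(df.index), values=df.to_numpy(dtype=float))


def _pair_tallies(matrix: DosageMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-locus intersection and union item counts for every sample pair.

    Returns (inter, union) arrays of shape (n_loci, n_pairs) where pairs are
    enumerated in upper-triangle order, and the locus list. JID for any locus
    subset is then 1 − sum(inter) / sum(union) over that subset.
    """
    samples = matrix.samples
    loci = matrix.loci
    n = len(samples)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    inter = np.zeros((len(loci), len(pairs)), dtype=np.int32)
    union = np.zeros((len(loci), len(pairs)), dtype=np.int32)
    for li, locus in enumerate(loci):
        sets = []
        for s in samples:
            cell = matrix.calls.get((locus, s))
            if correctness_flag(cell, matrix.ploidy):
                sets.append(frozenset(h for h, d in cell.items() if d >= 1))
            else:
                sets.append(None)
        for pi, (i, j) in enumerate(pairs):
            a, b = sets[i], sets[j]
            if a is None or b is None:
                continue
            inter[li, pi] = len(a & b)
            union[li, pi] = len(a | b)
    return inter, union, list(loci)


def jid(sample_a: str, sample_b: str, matrix: DosageMatrix) -> float:
    """Jaccard Inverse Distance between two samples; NaN if no shared loci."""
    for s in (sample_a, sample_b):
        if s not in matrix.samples:
            raise KeyError(f"unknown sample {s!r}")
    if sample_a == sample_b:
        return 0.0
    inter_total = 0
    union_total = 0
    for locus in matrix.loci:
        ca = matrix.calls.get((locus, sample_a))
        cb = matrix.calls.get((locus, sample_b))
        if not (correctness_flag(ca, matrix.ploidy) and correctness_flag(cb, matrix.ploidy)):
            continue
        a = {h for h, d in ca.items() if d >= 1}
        b = {h for h, d in cb.items() if d >= 1}
        inter_total += len(a & b)
        union_total += len(a | b)
    if union_total == 0:
        return float("nan")
    return 1.0 - inter_total / union_total


def jid_matrix(matrix: DosageMatrix) -> DistanceMatrix:
    """All-pairs JID; symmetric with an exactly-zero diagonal."""
    inter, union, _ = _pair_tallies(matrix)
    return _matrix_from_tallies(matrix.samples, inter.sum(axis=0), union.sum(axis=0))


def _matrix_from_tallies(samples: list[str], inter: np.ndarray,
                         union: np.ndarray) -> DistanceMatrix:
    n = len(samples)
    values = np.zeros((n, n))
    pi = 0
    for i in range(n):
        for j in range(i + 1, n):
            if union[pi] > 0:
                d = 1.0 - inter[pi] / union[pi]
            else:
                d = float("nan")
            values[i, j] = values[j, i] = d
            pi += 1
    return DistanceMatrix(samples=list(samples), values=values)


def bootstrap_jid(matrix: DosageMatrix, n_reps: int = 200,
                  seed: int = 0) -> list[DistanceMatrix]:
    """Locus-bootstrap replicate JID matrices (deterministic given seed)."""
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    inter, union, loci = _pair_tallies(matrix)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        draw = rng.integers(0, len(loci), size=len(loci))
        out.append(_matrix_from_tallies(matrix.samples,
                                        inter[draw].sum(axis=0),
                                        union[draw].sum(axis=0)))
    return out


def group_jid_summary(dm: DistanceMatrix,
                      labels: dict[str, tuple[str, str]]) -> dict[str, float]:
    """Mean JID within subpopulations, between subpopulations of one species,
    and between species, given (species, subpop) labels per sample."""
    within_sub, between_sub, between_species = [], [], []
    n = len(dm.samples)
    for i in range(n):
        for j in range(i + 1, n):
            v = dm.values[i, j]
            if not np.isfinite(v):
                continue
            sp_i, sub_i = labels[dm.samples[i]]
            sp_j, sub_j = labels[dm.samples[j]]
            if sp_i != sp_j:
                between_species.append(v)
            elif sub_i != sub_j:
                between_sub.append(v)
            else:
                within_sub.append(v)
    return {
        "within_subpop": float(np.mean(within_sub)) if within_sub else float("nan"),
        "between_subpop": float(np.mean(between_sub)) if between_sub else float("nan"),
        "between_species": float(np.mean(between_species)) if between_species else float("nan"),
    }
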