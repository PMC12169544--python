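"""Population-genetic estimators on bi-allelic SNP genotypes.

Implements the classical Nei / Nei–Chesser sample-size-corrected estimators
of observed heterozygosity (Ho), within-population gene diversity (Hs),
inbreeding coefficient (FIS = 1 − Ho/Hs), Nei pairwise FST on the
ratio-of-averages convention, windowed nucleotide diversity (pi), and a
genotype PCA on 0/1/2-coded calls.

Genotype matrices are samples x loci int arrays coded 0/1/2 with −1 missing
(the coding of :mod:`shorthap.variants`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from shorthap.variants import MISSING, SnpRecord


def genotype_matrix(records: Sequence[SnpRecord]) -> np.ndarray:
    """Stack per-record genotype vectors into a samples x loci array."""
    if not records:
        return np.zeros((0, 0), dtype=np.int8)
    return np.stack([r.genotypes for r in records], axis=1)


def _locus_stats(geno: np.ndarray, pops: Sequence[np.ndarray]):
    """Per-locus Ho, Hs per population plus allele frequencies.

    ``geno`` is samples x loci; ``pops`` a list of index arrays. Yields, per
    population, masked arrays over loci: Ho, Hs, n (genotyped diploids) and
    alt-allele frequency p. Loci with < 2 genotyped samples in a population
    are masked for that population.
    """
    out = []
    for idx in pops:
        g = geno[idx]  # n_pop x loci
        present = g != MISSING
        n = present.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(n > 0, (g == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
            p = np.where(n > 0, np.where(present, g, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
            # Nei–Chesser: Hs = n/(n-1) * (1 - p^2 - q^2 - Ho/(2n))
            hs = np.where(n > 1,
                          n / (n - 1) * (1 - p**2 - (1 - p)**2 - ho / (2 * n)),
                          np.nan)
        valid = n >= 2
        out.append({"ho": np.where(valid, ho, np.nan),
                    "hs": np.where(valid, hs, np.nan),
                    "p": np.where(valid, p, np.nan),
                    "n": np.where(valid, n, np.nan)})
    return out


def het_stats(geno: np.ndarray, samples: Sequence[str],
              assignment: Mapping[str, str]) -> pd.DataFrame:
    """Per-population Ho, Hs (Nei–Chesser corrected) and FIS = 1 − Ho/Hs.

    Population values are means over polymorphic loci with defined values
    (monomorphic loci, where Hs = 0, are skipped).
    """
    pops = sorted(set(assignment[s] for s in samples))
    idx = {p: np.asarray([i for i, s in enumerate(samples) if assignment[s] == p])
           for p in pops}
    stats = _locus_stats(geno, [idx[p] for p in pops])
    rows = []
    for p, st in zip(pops, stats):
        defined = np.isfinite(st["hs"]) & (st["hs"] > 0)
        ho = float(np.nanmean(np.where(defined, st["ho"], np.nan))) if defined.any() else np.nan
        hs = float(np.nanmean(np.where(defined, st["hs"], np.nan))) if defined.any() else np.nan
        fis = 1.0 - ho / hs if defined.any() and hs > 0 else np.nan
        rows.append({"population": p, "Ho": ho, "Hs": hs, "FIS": fis,
                     "n_loci": int(defined.sum())})
    return pd.DataFrame(rows).set_index("population")


def windowed_pi(records: Sequence[SnpRecord], window_size: int = 50_000,
                ) -> tuple[pd.DataFrame, float]:
    """Nucleotide diversity per non-overlapping window, and its unweighted
    mean over windows containing at least one SNP.

    Per site, pi = 2 * c_ref * c_alt / (n (n−1)) over non-missing allele
    counts; a window's value is the sum over its sites divided by
    ``window_size``. Windows are anchored at position 0 of each contig.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    acc: dict[tuple[str, int], float] = {}
    for rec in records:
        g = rec.genotypes[rec.genotypes != MISSING]
        n = 2 * g.size
        if n < 2:
            continue
        c_alt = int(g.sum())
        c_ref = n - c_alt
        pi_site = 2.0 * c_ref * c_alt / (n * (n - 1))
        win = (rec.position - 1) // window_size
        acc[(rec.contig, win)] = acc.get((rec.contig, win), 0.0) + pi_site
    rows = [{"contig": c, "window_start": w * window_size,
             "window_end": (w + 1) * window_size, "pi": v / window_size}
            for (c, w), v in sorted(acc.items())]
    df = pd.DataFrame(rows, columns=["contig", "window_start", "window_end", "pi"])
    mean_pi = float(df["pi"].mean()) if len(df) else float("nan")
    return df, mean_pi


def pi_by_population(records: Sequence[SnpRecord], samples: Sequence[str],
                     assignment: Mapping[str, str],
                     window_size: int = 50_000) -> dict[str, float]:
    """Mean windowed pi computed separately within each population."""
    out = {}
    for pop in sorted(set(assignment[s] for s in samples)):
        keep = [i for i, s in enumerate(samples) if assignment[s] == pop]
        sub = [SnpRecord(r.contig, r.position, r.ref, r.alt,
                         r.genotypes[keep], r.annotations) for r in records]
        _, out[pop] = windowed_pi(sub, window_size)
    return out


def pairwise_neifst(geno: np.ndarray, samples: Sequence[str],
                    assignment: Mapping[str, str]) -> pd.DataFrame:
    """Nei (1987) pairwise FST = (Ht − Hs) / Ht with Nei–Chesser corrections,
    averaged over loci as a ratio of averages; symmetric, zero diagonal."""
    pops = sorted(set(assignment[s] for s in samples))
    idx = {p: np.asarray([i for i, s in enumerate(samples) if assignment[s] == p])
           for p in pops}
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            value = _nei_fst_pair(geno, idx[a], idx[b])
            fst.loc[a, b] = fst.loc[b, a] = value
    return fst


def _nei_fst_pair(geno: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float:
    if len(ia) < 2 or len(ib) < 2:
        return float("nan")
    sa, sb = _locus_stats(geno, [ia, ib])
    ok = np.isfinite(sa["hs"]) & np.isfinite(sb["hs"])
    if not ok.any():
        return float("nan")
    hs = (sa["hs"] + sb["hs"]) / 2.0
    ho = (sa["ho"] + sb["ho"]) / 2.0
    p_bar = (sa["p"] + sb["p"]) / 2.0
    with np.errstate(invalid="ignore"):
        n_harm = 2.0 / (1.0 / sa["n"] + 1.0 / sb["n"])  # harmonic mean of pop sizes
        ht = 1 - p_bar**2 - (1 - p_bar)**2 + hs / (2 * n_harm) - ho / (4 * n_harm)
    m_hs = float(np.nanmean(np.where(ok, hs, np.nan)))
    m_ht = float(np.nanmean(np.where(ok, ht, np.nan)))
    return (m_ht - m_hs) / m_ht if m_ht > 0 else float("nan")


@dataclass
class PCAResult:
    coordinates: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    samples: list[str]


def genotype_pca(geno: np.ndarray, samples: Sequence[str],
                 n_components: int | None = None, center: bool = True,
                 scale: bool = False) -> PCAResult:
    """PCA on the 0/1/2 genotype matrix with mean imputation of missing calls.

    Columns are centered (and optionally scaled to unit variance); the
    decomposition is the eigendecomposition of the sample covariance, via
    sklearn's exact SVD solver.
    """
    if geno.shape[0] < 2:
        raise ValueError("genotype_pca requires at least 2 samples")
    X = geno.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    return PCAResult(coordinates=coords,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     samples=list(samples))
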