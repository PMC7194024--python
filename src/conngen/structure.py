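"""Genomic relationship matrices, PCA, IBS population tree, FST scan.

The GRM follows the two classic marker-based constructions with observed
allele frequencies: a global scaling ``G = Z Z' / (2 sum p_j q_j)``
(method 1) and a per-SNP variance standardisation
``G = (1/m) sum_j z_j z_j' / (2 p_j q_j)`` (method 2), where
``Z = M - 2p`` and missing calls are mean-imputed to ``2 p_j``.

The per-SNP FST between two populations is the Weir-Cockerham
variance-components estimator (sample-size weighted, heterozygosity
corrected); the naive frequency-ratio form
``(p1 - p2)^2 / (4 pbar qbar)`` is available behind a flag.  SNPs with
FST above the mean plus three standard deviations are flagged as
candidate selection signatures.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import MISSING, GenotypeDataset, align_alleles
from .qc import allele_frequencies


@dataclasses.dataclass
class GRMatrix:
    """Symmetric genomic relationship matrix with its construction metadata."""

    values: np.ndarray
    method: int
    snp_count: int
    sample_ids: list[str]
    n_imputed_calls: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclasses.dataclass
class PCAResult:
    """Eigenvalues (descending), variance fractions, and sample coordinates."""

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    coordinates: pd.DataFrame  # samples x components


@dataclasses.dataclass
class PopTree:
    """Hierarchical population tree from average-IBS distances."""

    labels: list[str]
    distance: pd.DataFrame
    linkage_matrix: np.ndarray
    newick: str

    def merge_order(self) -> list[tuple[frozenset, frozenset, float]]:
        """Pairs of leaf-label sets merged at each step, with heights."""
        clusters = {i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        out = []
        k = len(self.labels)
        for row_idx, (a, b, h, _) in enumerate(self.linkage_matrix):
            fa, fb = clusters[int(a)], clusters[int(b)]
            out.append((fa, fb, float(h)))
            clusters[k + row_idx] = fa | fb
        return out


@dataclasses.dataclass
class FstResult:
    """Per-SNP FST with the mean + 3 SD outlier call."""

    table: pd.DataFrame  # id, chrom, pos, fst
    mean: float
    sd: float
    weighted_mean: float  # ratio of summed variance components
    threshold: float
    outliers: pd.DataFrame
    selected_mean: float
    selected_sd: float
    estimator: str


def _standardised_genotypes(data: GenotypeDataset):
    calls = data.calls.astype(np.float64)
    miss = data.calls == MISSING
    freqs = allele_frequencies(data)
    p = freqs["freq_a1"].to_numpy()
    calls[miss] = np.take(2.0 * p, np.nonzero(miss)[1])
    z = calls - 2.0 * p
    return z, p, int(miss.sum())


def grm(data: GenotypeDataset, method: int = 1) -> GRMatrix:
    """VanRaden-style genomic relationship matrix (observed frequencies).

    Method 2 requires all SNPs polymorphic (its per-SNP denominator is
    ``2 p_j q_j``); monomorphic SNPs raise ``ValueError``.
    """
    if method not in (1, 2):
        raise ValueError("method must be 1 or 2")
    z, p, n_imputed = _standardised_genotypes(data)
    two_pq = 2.0 * p * (1.0 - p)
    if method == 1:
        denom = two_pq.sum()
        if denom <= 0:
            raise ValueError("all SNPs monomorphic: GRM undefined")
        g = (z @ z.T) / denom
    else:
        if (two_pq <= 0).any():
            bad = data.variants["id"].values[two_pq <= 0][0]
            raise ValueError(f"monomorphic SNP {bad!r}: method-2 GRM requires pre-filtering")
        zs = z / np.sqrt(two_pq)
        g = (zs @ zs.T) / data.n_variants
    g = (g + g.T) / 2.0
    return GRMatrix(g, method, data.n_variants, list(data.samples["id"].values), n_imputed)


def pca(g: GRMatrix, k: int = 10) -> PCAResult:
    """Top-k eigendecomposition of a (symmetric) GRM.

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalues; variance fractions use the full spectrum (negative
    eigenvalues floored at zero).  Each component's largest-magnitude
    loading is made positive for reproducible orientation.
    """
    values = g.values
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    k = min(k, values.shape[0])
    eigval, eigvec = np.linalg.eigh(values)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    clipped = np.clip(eigval, 0.0, None)
    fractions = clipped / clipped.sum() if clipped.sum() > 0 else clipped
    coords = eigvec[:, :k] * np.sqrt(clipped[:k])
    for comp in range(coords.shape[1]):
        j = np.argmax(np.abs(eigvec[:, comp]))
        if eigvec[j, comp] < 0:
            coords[:, comp] *= -1
    coord_df = pd.DataFrame(
        coords, index=g.sample_ids, columns=[f"PC{c+1}" for c in range(k)]
    )
    return PCAResult(eigval, fractions, coord_df)


def population_tree(
    data: GenotypeDataset,
    subsample: int | None = None,
    seed: int = 0,
    linkage_method: str = "complete",
) -> PopTree:
    """Hierarchical tree over populations from 1 - (average IBS) distances.

    Cross-population average IBS sharing is computed over all between-
    population sample pairs (optionally on a seeded per-population
    subsample) and clustered agglomeratively; the tree is serialised as a
    Newick string with branch lengths from the merge heights.
    """
    from .diversity import ibs_distance

    pops = data.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    if subsample is not None:
        rng = np.random.default_rng(seed)
        keep = []
        pop_arr = data.samples["population"].to_numpy()
        for pop in pops:
            idx = np.flatnonzero(pop_arr == pop)
            take = rng.choice(idx, size=min(subsample, idx.size), replace=False)
            keep.extend(sorted(take))
        data = data.subset(sample_idx=np.array(sorted(keep)))
    sim, _ = ibs_distance(data)
    pop_arr = data.samples["population"].to_numpy()
    k = len(pops)
    dist = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            block = sim.values[np.ix_(pop_arr == pops[a], pop_arr == pops[b])]
            dist[a, b] = dist[b, a] = 1.0 - np.nanmean(block)
    link = linkage(squareform(dist, checks=False), method=linkage_method)
    newick = _linkage_to_newick(link, pops)
    return PopTree(pops, pd.DataFrame(dist, index=pops, columns=pops), link, newick)


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = link[i - n]
        branch_a = h - heights[int(a)]
        branch_b = h - heights[int(b)]
        return f"({node(int(a))}:{branch_a / 2:.6g},{node(int(b))}:{branch_b / 2:.6g})"

    for row_idx, (a, b, h, _) in enumerate(link):
        heights[n + row_idx] = h
    return node(n + len(link) - 1) + ";"


def _pop_counts(data: GenotypeDataset):
    calls = data.calls
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)  # individuals called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(called, calls, 0).sum(axis=0) / (2.0 * n), np.nan)
        h = np.where(n > 0, (calls == 1).sum(axis=0) / n, np.nan)
    return n, p, h


def fst_scan(
    data_a: GenotypeDataset,
    data_b: GenotypeDataset,
    estimator: str = "weir-cockerham",
) -> FstResult:
    """Per-SNP two-population FST with mean + 3 SD outlier calling.

    Variants are matched by id and allele-aligned first.  SNPs
    monomorphic across both populations jointly are skipped.  The
    ``weir-cockerham`` estimator is the variance-components form (may dip
    slightly below zero); ``frequency-ratio`` is the plain
    ``(p1 - p2)^2 / (4 pbar qbar)``.
    """
    a, b, _ = align_alleles(data_a, data_b)
    n1, p1, h1 = _pop_counts(a)
    n2, p2, h2 = _pop_counts(b)
    valid = (n1 > 1) & (n2 > 1) & np.isfinite(p1) & np.isfinite(p2)
    pbar_all = np.where(
        valid, (2 * n1 * p1 + 2 * n2 * p2) / np.maximum(2 * n1 + 2 * n2, 1), np.nan
    )
    valid &= (pbar_all > 0) & (pbar_all < 1)  # jointly monomorphic -> skipped

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        comp_a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1.0)
        )
        comp_b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4.0 * nbar)
        )
        comp_c = hbar / 2.0
        total = comp_a + comp_b + comp_c
        if estimator == "weir-cockerham":
            fst = np.where(valid & (total != 0), comp_a / total, np.nan)
        elif estimator == "frequency-ratio":
            fst = np.where(
                valid, (p1 - p2) ** 2 / (4.0 * pbar * (1.0 - pbar)), np.nan
            )
        else:
            raise ValueError(f"unknown estimator {estimator!r}")

    keep = np.isfinite(fst)
    table = pd.DataFrame(
        {
            "id": a.variants["id"].values[keep],
            "chrom": a.variants["chrom"].values[keep],
            "pos": a.variants["pos"].values[keep],
            "fst": fst[keep],
        }
    )
    mean = float(table["fst"].mean())
    sd = float(table["fst"].std(ddof=0))
    if estimator == "weir-cockerham":
        weighted = float(np.nansum(comp_a[keep]) / np.nansum(total[keep]))
    else:
        weighted = mean
    threshold = mean + 3.0 * sd
    outliers = table[table["fst"] > threshold].reset_index(drop=True)
    return FstResult(
        table=table,
        mean=mean,
        sd=sd,
        weighted_mean=weighted,
        threshold=threshold,
        outliers=outliers,
        selected_mean=float(outliers["fst"].mean()) if len(outliers) else np.nan,
        selected_sd=float(outliers["fst"].std(ddof=0)) if len(outliers) else np.nan,
        estimator=estimator,
    )
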