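"""Two-locus linkage disequilibrium, LD decay, and gametic-phase consistency.

For two diallelic loci with alleles A/a and B/b (A and B being each SNP's
A1 allele), the disequilibrium is ``D = f(AB) - f(A) f(B)`` and

    r^2 = D^2 / (f(A) f(a) f(B) f(b)),      r_signed = sign(D) sqrt(r^2).

Haplotype frequencies come from direct counting when phase is known and
from the Hill-type EM over the double-heterozygote ambiguity otherwise.

LD decay is summarised over 20 distance bins: below 0.01 Mb, 0.01-0.10 Mb
in 0.01 steps, 0.1-1.0 Mb in 0.1 steps, and an open bin above 1.0 Mb;
bins are half-open ``(lower, upper]`` and a bin is reported only when it
holds at least ``min_pairs`` pair estimates.

The consistency of gametic phase between two populations is the Pearson
correlation of ``r_signed`` over SNP pairs shared by both, overall and
per distance bin; it predicts how well marker-QTL associations transfer
across populations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, align_alleles

_EM_TOL = 1e-10
_EM_MAX_ITER = 1000


@dataclasses.dataclass
class LDPair:
    """LD summary for one SNP pair on a single chromosome."""

    snp_i: str
    snp_j: str
    distance_bp: int
    d: float
    r2: float
    r_signed: float


@dataclasses.dataclass
class BinScheme:
    """Distance bins for LD decay; default is the 20-bin panel scheme."""

    edges_mb: np.ndarray  # interior upper edges, ascending; top bin open
    min_pairs: int = 50

    @classmethod
    def default20(cls, min_pairs: int = 50) -> "BinScheme":
        edges = np.r_[np.arange(0.01, 0.101, 0.01), np.arange(0.2, 1.01, 0.1)]
        return cls(edges_mb=np.round(edges, 10), min_pairs=min_pairs)

    @property
    def n_bins(self) -> int:
        return self.edges_mb.size + 1

    @property
    def labels(self) -> list[str]:
        e = self.edges_mb
        lab = [f"<{e[0]:g}"]
        lab += [f"{a:g}-{b:g}" for a, b in zip(e[:-1], e[1:])]
        lab.append(f">{e[-1]:g}")
        return lab

    def assign(self, distance_bp) -> np.ndarray:
        """0-based bin index per distance; bins are half-open (lower, upper]."""
        edges_bp = self.edges_mb * 1e6
        return np.searchsorted(edges_bp, np.asarray(distance_bp, dtype=float), side="left")


@dataclasses.dataclass
class LDDecayTable:
    """Per-bin mean r^2 plus the adjacent-SNP summary statistics."""

    table: pd.DataFrame  # bin, label, n_pairs, mean_r2, reported
    adjacent_mean_dist_mb: float
    adjacent_sd_dist_mb: float
    adjacent_mean_r2: float
    adjacent_sd_r2: float
    n_pairs_total: int


@dataclasses.dataclass
class PhaseConsistencyTable:
    """Pearson correlation of signed r between two populations."""

    table: pd.DataFrame  # bin, label, n_pairs, correlation
    overall_correlation: float
    n_shared_pairs: int


# -- haplotype frequencies ----------------------------------------------------


def haplotype_frequencies(data: GenotypeDataset, i: int, j: int):
    """Frequencies (f_AB, f_Ab, f_aB, f_ab) for SNP indices ``i`` and ``j``.

    Counts haplotypes directly on phased data; otherwise runs EM over the
    double-heterozygote ambiguity (converged when successive ``f(AB)``
    estimates differ by less than 1e-10, at most 1000 iterations).
    Returns ``None`` when fewer than two individuals are called at both
    SNPs or either SNP is monomorphic in the pairwise-complete subset.
    """
    gi, gj = data.calls[:, i], data.calls[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        return None
    if data.phased:
        hi = data.haplotypes[ok, :, i].ravel().astype(float)
        hj = data.haplotypes[ok, :, j].ravel().astype(float)
        f_ab_ = np.mean(hi * hj)
        f_a = hi.mean()
        f_b = hj.mean()
        if f_a in (0.0, 1.0) or f_b in (0.0, 1.0):
            return None
        f_ab = f_ab_
        f_aB = f_b - f_ab
        f_Ab = f_a - f_ab
        f_ab0 = 1.0 - f_ab - f_aB - f_Ab
        return f_ab, f_Ab, f_aB, f_ab0
    counts = _pair_counts(gi[ok], gj[ok])
    freqs = _em_single(counts)
    return freqs


def _pair_counts(gi, gj) -> np.ndarray:
    """3x3 genotype-pair counts, axes = copies of A1 at SNP i and j."""
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (gi.astype(int), gj.astype(int)), 1)
    return counts


def _em_single(counts: np.ndarray):
    c = counts.astype(float)
    n2 = 2.0 * c.sum()
    f_a = (2 * c[2].sum() + c[1].sum()) / n2
    f_b = (2 * c[:, 2].sum() + c[:, 1].sum()) / n2
    if f_a in (0.0, 1.0) or f_b in (0.0, 1.0):
        return None
    f = np.array([f_a * f_b, f_a * (1 - f_b), (1 - f_a) * f_b, (1 - f_a) * (1 - f_b)])
    n_dh = c[1, 1]
    base_ab = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    base_Ab = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    base_aB = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    base_ab0 = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    for _ in range(_EM_MAX_ITER):
        denom = f[0] * f[3] + f[1] * f[2]
        x = 0.5 if denom == 0 else f[0] * f[3] / denom
        new = np.array(
            [
                base_ab + x * n_dh,
                base_Ab + (1 - x) * n_dh,
                base_aB + (1 - x) * n_dh,
                base_ab0 + x * n_dh,
            ]
        ) / n2
        if abs(new[0] - f[0]) < _EM_TOL:
            f = new
            break
        f = new
    return tuple(f)


def ld_from_freqs(freqs) -> tuple[float, float, float]:
    """(D, r^2, r_signed) from (f_AB, f_Ab, f_aB, f_ab)."""
    f_ab, f_Ab, f_aB, f_ab0 = freqs
    f_a = f_ab + f_Ab
    f_b = f_ab + f_aB
    d = f_ab - f_a * f_b
    denom = f_a * (1 - f_a) * f_b * (1 - f_b)
    if denom <= 0:
        return d, np.nan, np.nan
    r2 = d * d / denom
    return d, r2, np.sign(d) * np.sqrt(r2)


def ld_pair(data: GenotypeDataset, i: int, j: int) -> LDPair | None:
    """LD between SNP indices ``i`` and ``j`` (must share a chromosome)."""
    vi, vj = data.variants.iloc[i], data.variants.iloc[j]
    if str(vi["chrom"]) != str(vj["chrom"]):
        raise ValueError("LD is only defined within a chromosome")
    freqs = haplotype_frequencies(data, i, j)
    if freqs is None:
        return None
    d, r2, rs = ld_from_freqs(freqs)
    return LDPair(vi["id"], vj["id"], int(abs(vj["pos"] - vi["pos"])), d, r2, rs)


# -- vectorised pairwise r ----------------------------------------------------


def intrachromosomal_pairs(data: GenotypeDataset, max_distance_bp: float):
    """Index arrays (ii, jj) of all same-chromosome pairs within a distance."""
    chrom = data.variants["chrom"].astype(str).to_numpy()
    pos = data.variants["pos"].to_numpy()
    ii_parts, jj_parts = [], []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        order = np.argsort(p, kind="stable")
        idx, p = idx[order], p[order]
        hi = np.searchsorted(p, p + max_distance_bp, side="right")
        for k in range(idx.size):
            if hi[k] > k + 1:
                ii_parts.append(np.full(hi[k] - k - 1, idx[k]))
                jj_parts.append(idx[k + 1 : hi[k]])
    if not ii_parts:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(ii_parts), np.concatenate(jj_parts)


def signed_r_pairs(
    data: GenotypeDataset, ii, jj, max_missing_rate: float = 0.5
) -> np.ndarray:
    """Signed r for many SNP pairs at once; NaN where LD is undefined.

    Uses haplotype counting on phased data and vectorised EM otherwise.
    Pairs whose pairwise-complete subset keeps less than half the samples
    are skipped (NaN).
    """
    if data.phased and (data.calls == MISSING).sum() == 0:
        h = data.haplotypes.reshape(data.n_samples * 2, data.n_variants).astype(np.float64)
        f_a = h[:, ii].mean(axis=0)
        f_b = h[:, jj].mean(axis=0)
        f_ab = np.einsum("ni,ni->i", h[:, ii], h[:, jj]) / h.shape[0]
        d = f_ab - f_a * f_b
        denom = f_a * (1 - f_a) * f_b * (1 - f_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, d / np.sqrt(denom), np.nan)
        return r
    return _signed_r_em(data, ii, jj, max_missing_rate)


def _signed_r_em(data, ii, jj, max_missing_rate):
    calls = data.calls
    n = calls.shape[0]
    a = calls[:, ii]
    b = calls[:, jj]
    ok = (a != MISSING) & (b != MISSING)
    n_ok = ok.sum(axis=0).astype(float)
    code = np.where(ok, a * 3 + b, 9)
    counts = np.zeros((9, ii.size), dtype=np.float64)
    for v in range(9):
        counts[v] = (code == v).sum(axis=0)
    c = counts.reshape(3, 3, -1)
    n2 = 2.0 * n_ok
    with np.errstate(invalid="ignore", divide="ignore"):
        f_a = (2 * c[2].sum(axis=0) + c[1].sum(axis=0)) / n2
        f_b = (2 * c[:, 2].sum(axis=0) + c[:, 1].sum(axis=0)) / n2
    valid = (n_ok >= 2) & (n_ok >= (1 - max_missing_rate) * n)
    valid &= (f_a > 0) & (f_a < 1) & (f_b > 0) & (f_b < 1)

    f_ab = f_a * f_b
    f_Ab = f_a * (1 - f_b)
    f_aB = (1 - f_a) * f_b
    f_ab0 = (1 - f_a) * (1 - f_b)
    n_dh = c[1, 1]
    base_ab = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    base_Ab = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    base_aB = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    base_ab0 = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        for _ in range(_EM_MAX_ITER):
            denom = f_ab * f_ab0 + f_Ab * f_aB
            x = np.where(denom > 0, f_ab * f_ab0 / np.where(denom > 0, denom, 1.0), 0.5)
            new_ab = (base_ab + x * n_dh) / n2
            delta = np.nanmax(np.abs(new_ab - f_ab)) if new_ab.size else 0.0
            f_ab = new_ab
            f_Ab = (base_Ab + (1 - x) * n_dh) / n2
            f_aB = (base_aB + (1 - x) * n_dh) / n2
            f_ab0 = (base_ab0 + x * n_dh) / n2
            if delta < _EM_TOL:
                break
        d = f_ab - f_a * f_b
        var = f_a * (1 - f_a) * f_b * (1 - f_b)
        r = np.where(valid & (var > 0), d / np.sqrt(np.where(var > 0, var, 1.0)), np.nan)
    return r


# -- decay table and phase consistency ----------------------------------------


def ld_decay(
    data: GenotypeDataset,
    scheme: BinScheme | None = None,
    max_distance_bp: float = 5e6,
) -> LDDecayTable:
    """Binned LD decay plus adjacent-SNP distance and r^2 summaries."""
    scheme = scheme or BinScheme.default20()
    ii, jj = intrachromosomal_pairs(data, max_distance_bp)
    pos = data.variants["pos"].to_numpy()
    dist = np.abs(pos[jj] - pos[ii])
    r = signed_r_pairs(data, ii, jj)
    r2 = r * r
    keep = np.isfinite(r2)
    bins = scheme.assign(dist[keep])
    r2k = r2[keep]

    rows = []
    for b in range(scheme.n_bins):
        sel = bins == b
        n_pairs = int(sel.sum())
        reported = n_pairs >= scheme.min_pairs
        rows.append(
            {
                "bin": b + 1,
                "label": scheme.labels[b],
                "n_pairs": n_pairs,
                "mean_r2": float(r2k[sel].mean()) if reported else np.nan,
                "reported": reported,
            }
        )

    adj_ii, adj_jj, adj_dist = _adjacent_pairs(data)
    adj_r = signed_r_pairs(data, adj_ii, adj_jj)
    adj_r2 = adj_r * adj_r
    fin = np.isfinite(adj_r2)
    return LDDecayTable(
        table=pd.DataFrame(rows),
        adjacent_mean_dist_mb=float(adj_dist.mean() / 1e6) if adj_dist.size else np.nan,
        adjacent_sd_dist_mb=float(adj_dist.std() / 1e6) if adj_dist.size else np.nan,
        adjacent_mean_r2=float(adj_r2[fin].mean()) if fin.any() else np.nan,
        adjacent_sd_r2=float(adj_r2[fin].std()) if fin.any() else np.nan,
        n_pairs_total=int(keep.sum()),
    )


def _adjacent_pairs(data: GenotypeDataset):
    chrom = data.variants["chrom"].astype(str).to_numpy()
    pos = data.variants["pos"].to_numpy()
    ii, jj = [], []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        ii.append(idx[:-1])
        jj.append(idx[1:])
    ii = np.concatenate(ii) if ii else np.empty(0, dtype=int)
    jj = np.concatenate(jj) if jj else np.empty(0, dtype=int)
    return ii, jj, np.abs(pos[jj] - pos[ii])


def phase_consistency(
    data_a: GenotypeDataset,
    data_b: GenotypeDataset,
    scheme: BinScheme | None = None,
    max_distance_bp: float = 5e6,
    min_pairs_per_bin: int = 3,
) -> PhaseConsistencyTable:
    """Correlation of signed r between two populations over shared pairs.

    Variants are matched by id and allele-aligned (A1/A2 swaps flipped)
    before computing r in each population; only pairs with a defined r in
    both populations enter the correlations.
    """
    scheme = scheme or BinScheme.default20()
    a, b, _ = align_alleles(data_a, data_b)
    ii, jj = intrachromosomal_pairs(a, max_distance_bp)
    pos = a.variants["pos"].to_numpy()
    dist = np.abs(pos[jj] - pos[ii])
    r_a = signed_r_pairs(a, ii, jj)
    r_b = signed_r_pairs(b, ii, jj)
    ok = np.isfinite(r_a) & np.isfinite(r_b)
    r_a, r_b, dist = r_a[ok], r_b[ok], dist[ok]
    bins = scheme.assign(dist)

    rows = []
    for k in range(scheme.n_bins):
        sel = bins == k
        n_pairs = int(sel.sum())
        corr = _pearson(r_a[sel], r_b[sel]) if n_pairs >= min_pairs_per_bin else np.nan
        rows.append(
            {"bin": k + 1, "label": scheme.labels[k], "n_pairs": n_pairs, "correlation": corr}
        )
    overall = _pearson(r_a, r_b) if r_a.size >= min_pairs_per_bin else np.nan
    return PhaseConsistencyTable(pd.DataFrame(rows), overall, int(r_a.size))


def _pearson(x, y) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])
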