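"""Heterozygosity, MAF spectra, IBS distance, ROH detection, inbreeding.

Four inbreeding estimators are provided:

* ``F_E`` -- excess of homozygosity, ``(O_hom - E_hom) / (m - E_hom)``
  with the small-sample-corrected HWE expectation
  ``E_hom = sum_j [1 - 2 p_j q_j * A_j / (A_j - 1)]`` (``A_j`` = called
  allele count at SNP j);
* ``F_G`` -- diagonal of the genomic relationship matrix (method 1,
  observed frequencies) minus one;
* ``F_ROH`` -- fraction of the autosomal SNP-covered genome inside runs
  of homozygosity;
* ``F_PED`` -- pedigree inbreeding by the Meuwissen-Luo recursion over
  the numerator relationship matrix diagonal (linear memory, founders
  unrelated and non-inbred).

ROH detection follows the classic sliding-window scan: 50-SNP windows
with at most one heterozygous and a bounded number of missing calls vote
for each SNP; SNPs hit by at least 5% of their windows form candidate
runs, which are then split at large gaps and filtered on SNP count,
length and density.  The minimum SNP count that keeps chance runs below
a false-positive rate ``alpha`` is

    ceil( ln(alpha / (n_snps * n_individuals)) / ln(1 - mean_het) ).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .io import AUTOSOMES, MISSING, GenotypeDataset, Pedigree
from .qc import allele_frequencies


# -- heterozygosity and MAF spectrum ------------------------------------------


@dataclasses.dataclass
class HetStats:
    """Observed (per-individual) and expected (per-SNP) heterozygosity."""

    ho_per_individual: pd.Series
    he_per_snp: pd.Series
    mean_ho: float
    sd_ho: float
    mean_he: float
    sd_he: float


def heterozygosity(data: GenotypeDataset) -> HetStats:
    """Ho per individual over its called SNPs; He = 2pq per SNP.

    Individuals with no called genotype get ``NaN`` Ho.
    """
    calls = data.calls
    called = calls != MISSING
    n_called = called.sum(axis=1)
    n_het = (calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, n_het / n_called, np.nan)
    p = allele_frequencies(data)["freq_a1"].to_numpy()
    he = 2.0 * p * (1.0 - p)
    ho_s = pd.Series(ho, index=data.samples["id"].values, name="Ho")
    he_s = pd.Series(he, index=data.variants["id"].values, name="He")
    return HetStats(
        ho_s,
        he_s,
        float(np.nanmean(ho)) if ho.size else np.nan,
        float(np.nanstd(ho)) if ho.size else np.nan,
        float(np.nanmean(he)) if he.size else np.nan,
        float(np.nanstd(he)) if he.size else np.nan,
    )


MAF_BIN_EDGES = np.round(np.r_[0.01, np.arange(0.05, 0.501, 0.05)], 10)


def maf_spectrum(data: GenotypeDataset):
    """Polymorphic proportion (MAF > 0.01) and the 10-bin MAF histogram.

    Bins are half-open ``(lower, upper]`` with edges 0.01, 0.05, 0.10,
    ..., 0.50; monomorphic and sub-0.01 SNPs fall outside the histogram.
    """
    maf = allele_frequencies(data)["maf"].to_numpy()
    maf = maf[np.isfinite(maf)]
    polymorphic = float((maf > 0.01).mean()) if maf.size else np.nan
    idx = np.searchsorted(MAF_BIN_EDGES, maf, side="left")
    counts = np.array([(idx == b + 1).sum() for b in range(10)])
    labels = [
        f"{a:g}-{b:g}" for a, b in zip(MAF_BIN_EDGES[:-1], MAF_BIN_EDGES[1:])
    ]
    hist = pd.DataFrame({"bin": np.arange(1, 11), "label": labels, "n_snps": counts})
    return polymorphic, hist


# -- IBS distance -------------------------------------------------------------


def ibs_distance(data: GenotypeDataset):
    """Pairwise IBS sharing D_ST and the distance matrix 1 - D_ST.

    ``D_ST = (IBS2 + 0.5 * IBS1) / m`` over jointly called SNPs, which
    equals the mean of ``1 - |g_i - g_j| / 2``.  Returns
    ``(similarity, distance)`` DataFrames indexed by sample id; pairs with
    no jointly called SNP get ``NaN``.
    """
    x = data.calls.astype(np.float64)
    x[data.calls == MISSING] = np.nan
    n = data.n_samples
    sim = np.empty((n, n))
    for i in range(n):
        diff = np.abs(x - x[i])  # NaN propagates joint missingness
        with np.errstate(invalid="ignore"):
            sim[i] = np.nanmean(1.0 - diff / 2.0, axis=1)
    np.fill_diagonal(sim, 1.0)
    ids = data.samples["id"].values
    sim_df = pd.DataFrame(sim, index=ids, columns=ids)
    return sim_df, 1.0 - sim_df


# -- runs of homozygosity -----------------------------------------------------


@dataclasses.dataclass
class ROHParams:
    """Sliding-window ROH scan parameters (panel-scan defaults)."""

    window_snps: int = 50
    max_het_in_window: int = 1
    max_missing_in_window: int = 5
    hit_rate_threshold: float = 0.05
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0
    alpha: float = 0.05
    min_snps: int | None = None  # None -> derived from the false-positive rule

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclasses.dataclass
class ROHSegment:
    """One homozygous tract of one individual."""

    individual: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    het_calls_inside: int
    missing_inside: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def roh_min_snps(n_snps: int, n_individuals: int, mean_het: float, alpha: float = 0.05) -> int:
    """Minimum SNPs per ROH keeping chance homozygous runs below ``alpha``.

    ``ceil( ln(alpha / (n_snps * n_individuals)) / ln(1 - mean_het) )``.
    """
    if not 0 < mean_het < 1:
        raise ValueError("mean_het must be strictly between 0 and 1")
    return math.ceil(math.log(alpha / (n_snps * n_individuals)) / math.log(1.0 - mean_het))


def roh_scan(data: GenotypeDataset, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH segments on autosomes for every individual.

    Deterministic; invariant to individual order and to allele relabeling
    (homozygosity is symmetric in the allele codes).
    """
    params = params or ROHParams()
    min_snps = params.min_snps
    if min_snps is None:
        mean_het = heterozygosity(data).mean_ho
        min_snps = roh_min_snps(data.n_variants, data.n_samples, mean_het, params.alpha)

    chrom = data.variants["chrom"].astype(str).to_numpy()
    pos = data.variants["pos"].to_numpy()
    segments: list[ROHSegment] = []
    for c in [c for c in pd.unique(chrom) if c in AUTOSOMES]:
        idx = np.flatnonzero(chrom == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        p = pos[idx]
        for i, iid in enumerate(data.samples["id"].values):
            g = data.calls[i, idx]
            segments.extend(
                _scan_chromosome(iid, c, g, p, params, min_snps)
            )
    return segments


def _scan_chromosome(iid, chrom, g, pos, params: ROHParams, min_snps):
    length = g.size
    w = params.window_snps
    if length < w:
        return []
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    ones = np.ones(w)
    het_in_win = np.convolve(het, ones, mode="valid")  # length L - w + 1
    mis_in_win = np.convolve(mis, ones, mode="valid")
    ok_win = (het_in_win <= params.max_het_in_window) & (
        mis_in_win <= params.max_missing_in_window
    )
    # per-SNP: number of ok windows containing it / number of windows containing it
    hits = np.convolve(ok_win.astype(np.float64), ones, mode="full")[: length]
    denom = np.convolve(np.ones(ok_win.size), ones, mode="full")[: length]
    eligible = hits / denom >= params.hit_rate_threshold

    segments = []
    gap_bp = params.max_gap_kb * 1000.0
    for a, b in _runs(eligible):
        for s, e in _split_at_gaps(pos, a, b, gap_bp):
            seg = _trim_and_check(iid, chrom, g, pos, s, e, params, min_snps)
            if seg is not None:
                segments.append(seg)
    return segments


def _runs(mask: np.ndarray):
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, mask.size - 1]
    return [(a, b) for a, b in zip(starts, ends) if mask[a]]


def _split_at_gaps(pos, a, b, gap_bp):
    cuts = np.flatnonzero(np.diff(pos[a : b + 1]) > gap_bp)
    starts = np.r_[a, a + cuts + 1]
    ends = np.r_[a + cuts, b]
    return list(zip(starts, ends))


def _trim_and_check(iid, chrom, g, pos, s, e, params: ROHParams, min_snps):
    # ends must sit on called homozygous SNPs
    while s <= e and g[s] in (1, MISSING):
        s += 1
    while e >= s and g[e] in (1, MISSING):
        e -= 1
    if e <= s:
        return None
    n = e - s + 1
    length_kb = (pos[e] - pos[s]) / 1000.0
    if n < min_snps or length_kb < params.min_length_kb:
        return None
    if length_kb / n > params.max_density_kb_per_snp:
        return None
    het_inside = int((g[s : e + 1] == 1).sum())
    mis_inside = int((g[s : e + 1] == MISSING).sum())
    return ROHSegment(iid, str(chrom), int(pos[s]), int(pos[e]), n, het_inside, mis_inside)


#: length categories (Mb) used for the ROH length-distribution report
ROH_LENGTH_CATEGORIES = ((1.0, 2.5), (2.5, 5.0), (5.0, 10.0), (10.0, np.inf))


def roh_summary(segments: list[ROHSegment], data: GenotypeDataset) -> pd.DataFrame:
    """Per-population ROH descriptives: segment counts, lengths, density.

    One row per population with mean [min-max] of per-individual segment
    count (nSEG) and total length (Kbi), per-segment length (Kb), SNPs per
    segment (nSNP), density (kb per SNP) and proportion of homozygous
    calls inside segments (phom).
    """
    seg_by_ind: dict[str, list[ROHSegment]] = {}
    for s in segments:
        seg_by_ind.setdefault(s.individual, []).append(s)
    rows = []
    pops = data.samples.set_index("id")["population"]
    for pop in data.populations:
        ids = [i for i in pops.index[pops == pop]]
        segs = [s for i in ids for s in seg_by_ind.get(i, [])]
        n_seg = np.array([len(seg_by_ind.get(i, [])) for i in ids])
        kbi = np.array([sum(s.length_kb for s in seg_by_ind.get(i, [])) for i in ids])
        kb = np.array([s.length_kb for s in segs])
        nsnp = np.array([s.n_snps for s in segs])
        dens = np.array([s.length_kb / s.n_snps for s in segs])
        phom = np.array(
            [(s.n_snps - s.het_calls_inside - s.missing_inside) / s.n_snps for s in segs]
        )
        rows.append(
            {
                "population": pop,
                "n_individuals": len(ids),
                "n_total": len(segs),
                "nSEG_mean": n_seg.mean() if n_seg.size else 0.0,
                "nSEG_min": int(n_seg.min()) if n_seg.size else 0,
                "nSEG_max": int(n_seg.max()) if n_seg.size else 0,
                "Kbi_mean": kbi.mean() if kbi.size else 0.0,
                "Kbi_min": kbi.min() if kbi.size else 0.0,
                "Kbi_max": kbi.max() if kbi.size else 0.0,
                "Kb_mean": kb.mean() if kb.size else np.nan,
                "Kb_min": kb.min() if kb.size else np.nan,
                "Kb_max": kb.max() if kb.size else np.nan,
                "nSNP_mean": nsnp.mean() if nsnp.size else np.nan,
                "density_mean": dens.mean() if dens.size else np.nan,
                "phom_mean": phom.mean() if phom.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def roh_length_categories(segments: list[ROHSegment]) -> pd.DataFrame:
    """Proportion of segments per length category (1-2.5, 2.5-5, 5-10, >10 Mb)."""
    lengths_mb = np.array([s.length_kb / 1000.0 for s in segments])
    rows = []
    for lo, hi in ROH_LENGTH_CATEGORIES:
        sel = (lengths_mb > lo) & (lengths_mb <= hi)
        label = f">{lo:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}"
        rows.append(
            {
                "category_mb": label,
                "n_segments": int(sel.sum()),
                "proportion": float(sel.mean()) if lengths_mb.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


# -- inbreeding estimators ----------------------------------------------------


def inbreeding_excess_hom(data: GenotypeDataset) -> pd.Series:
    """Excess-homozygosity inbreeding F_E per individual."""
    calls = data.calls
    called = calls != MISSING
    freqs = allele_frequencies(data)
    p = freqs["freq_a1"].to_numpy()
    alleles = 2.0 * freqs["n_called"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(alleles > 1, alleles / (alleles - 1.0), np.nan)
    e_hom_snp = 1.0 - 2.0 * p * (1.0 - p) * corr
    usable = called & np.isfinite(e_hom_snp)[None, :]
    o_hom = ((calls == 0) | (calls == 2)) & usable
    e_hom = usable @ np.nan_to_num(e_hom_snp)
    m = usable.sum(axis=1)
    denom = m - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (o_hom.sum(axis=1) - e_hom) / denom, np.nan)
    return pd.Series(f, index=data.samples["id"].values, name="F_E")


def inbreeding_grm(data: GenotypeDataset) -> pd.Series:
    """F_G = diag(G) - 1 with G built by VanRaden method 1 (observed freqs)."""
    from .structure import grm  # local import avoids a module cycle

    g = grm(data, method=1)
    return pd.Series(
        np.diag(g.values) - 1.0, index=data.samples["id"].values, name="F_G"
    )


def inbreeding_roh(
    segments: list[ROHSegment], data: GenotypeDataset
) -> pd.Series:
    """F_ROH per individual: ROH-covered length over the autosomal span.

    The denominator is the SNP-covered span (first to last SNP) summed
    over autosomes present in the dataset.
    """
    chrom = data.variants["chrom"].astype(str).to_numpy()
    pos = data.variants["pos"].to_numpy()
    total = 0.0
    for c in pd.unique(chrom):
        if c in AUTOSOMES:
            p = pos[chrom == c]
            total += float(p.max() - p.min())
    covered = dict.fromkeys(data.samples["id"].values, 0.0)
    for s in segments:
        if s.individual in covered:
            covered[s.individual] += s.end_bp - s.start_bp
    f = np.array([covered[i] / total if total > 0 else np.nan for i in covered])
    return pd.Series(f, index=list(covered), name="F_ROH")


def inbreeding_pedigree(pedigree: Pedigree) -> pd.Series:
    """Pedigree inbreeding F per individual via the Meuwissen-Luo recursion.

    Computes each diagonal of the numerator relationship matrix by tracing
    the individual's ancestor tree with path coefficients, in linear
    memory; founders (unknown parents) are unrelated and non-inbred.
    Exactly matches the full tabular-method diagonal.
    """
    pedigree.validate()
    order, sire, dam = pedigree.parent_arrays()
    n = len(order)
    f = np.zeros(n)
    d = np.zeros(n)  # within-family segregation variance coefficient
    for i in range(n):
        s, t = sire[i], dam[i]
        fs = f[s] if s >= 0 else 0.0
        ft = f[t] if t >= 0 else 0.0
        if s >= 0 and t >= 0:
            d[i] = 0.5 - 0.25 * (fs + ft)
        elif s >= 0 or t >= 0:
            d[i] = 0.75 - 0.25 * (fs if s >= 0 else ft)
        else:
            d[i] = 1.0
        if s < 0 or t < 0:
            f[i] = 0.0
            continue
        # a_ii = sum over ancestors j of L_ij^2 * d_j, with L the path matrix
        coeff = np.zeros(i + 1)
        coeff[i] = 1.0
        a_ii = 0.0
        for j in range(i, -1, -1):
            c = coeff[j]
            if c == 0.0:
                continue
            a_ii += c * c * d[j]
            if sire[j] >= 0:
                coeff[sire[j]] += 0.5 * c
            if dam[j] >= 0:
                coeff[dam[j]] += 0.5 * c
        f[i] = a_ii - 1.0
    return pd.Series(f, index=order, name="F_PED")
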