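"""SNP quality control and VIF-based LD pruning.

Filters are applied sequentially in a fixed order so the per-criterion
removal report is unambiguous:

1. unknown/duplicated positions and sex-linked SNPs,
2. minor allele frequency,
3. call rate,
4. Hardy-Weinberg exact test.

The Hardy-Weinberg test is the genotype-conditional two-sided exact test
(summing the probabilities of all heterozygote counts no more probable
than the observed one), evaluated with a log-space recurrence so it stays
stable for sample sizes in the tens of thousands.

LD pruning mirrors the classic sliding-window variance-inflation-factor
procedure: within each 50-SNP window the SNP whose genotype is best
predicted by the others (largest VIF = 1/(1 - R^2)) is removed until all
VIFs fall at or below the threshold, then the window advances by 5 SNPs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import MISSING, SEX_CHROMOSOMES, UNKNOWN_CHROMOSOME, GenotypeDataset


@dataclasses.dataclass
class QCThresholds:
    """SNP filtering thresholds; defaults follow common HD-panel practice."""

    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-15
    drop_sex_chromosomes: bool = True
    drop_unknown_or_duplicate_positions: bool = True

    def __post_init__(self):
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 <= self.call_rate_min <= 1:
            raise ValueError("call_rate_min must be in [0, 1]")
        if not 0 < self.hwe_p_min <= 1:
            raise ValueError("hwe_p_min must be in (0, 1]")


@dataclasses.dataclass
class QCReport:
    """Per-criterion removal counts for sequentially applied filters."""

    removed_by_position: int
    removed_by_maf: int
    removed_by_call_rate: int
    removed_by_hwe: int
    remaining: int

    @property
    def total_input(self) -> int:
        return (
            self.removed_by_position
            + self.removed_by_maf
            + self.removed_by_call_rate
            + self.removed_by_hwe
            + self.remaining
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "remaining": [self.remaining],
                "removed_position": [self.removed_by_position],
                "removed_maf": [self.removed_by_maf],
                "removed_call_rate": [self.removed_by_call_rate],
                "removed_hwe": [self.removed_by_hwe],
            }
        )


@dataclasses.dataclass
class PruneParams:
    """Sliding-window VIF pruning parameters (window/step/threshold)."""

    window_snps: int = 50
    step_snps: int = 5
    vif_max: float = 2.0
    ridge: float = 1e-8

    def __post_init__(self):
        if not self.window_snps > self.step_snps > 0:
            raise ValueError("require window_snps > step_snps > 0")
        if self.vif_max < 1:
            raise ValueError("vif_max must be >= 1")


def allele_frequencies(data: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP A1 frequency, MAF, and call counts.

    The frequency is ``(2 * n_hom_A1 + n_het) / (2 * n_called)``; SNPs with
    no called genotype get ``NaN`` frequencies (they fall to the call-rate
    filter downstream).
    """
    calls = data.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    a1_count = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, a1_count / (2.0 * n_called), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame(
        {
            "id": data.variants["id"].values,
            "freq_a1": freq,
            "maf": maf,
            "n_called": n_called,
            "call_rate": n_called / max(data.n_samples, 1),
        }
    )


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more probable than the observed one.
    Degenerate tables (monomorphic or empty) return 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("empty genotype table")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0
    log_probs = _hwe_log_probs(n, rare)
    obs_idx = n_het // 2 if rare % 2 == 0 else (n_het - 1) // 2
    total = logsumexp(log_probs)
    # include every outcome with probability <= observed (tolerating rounding)
    keep = log_probs <= log_probs[obs_idx] + 1e-12
    return float(min(1.0, np.exp(logsumexp(log_probs[keep]) - total)))


def _hwe_log_probs(n: int, rare: int) -> np.ndarray:
    """Unnormalised log-probabilities over heterozygote counts.

    Heterozygote counts share the parity of the rare-allele count ``rare``
    and run from ``rare % 2`` to ``min(rare, 2n - rare)``.  Entry ``i``
    corresponds to ``n_het = rare % 2 + 2 i``.  Uses the standard ratio
    recurrence in log space, anchored at the largest term.
    """
    het_min = rare % 2
    het_max = min(rare, 2 * n - rare)
    hets = np.arange(het_min, het_max + 1, 2)
    logs = np.zeros(hets.size)
    for i in range(1, hets.size):
        h = hets[i]  # moving from h-2 to h hets
        hom_r = (rare - h) // 2  # rare homozygotes at h hets
        hom_c = n - h - hom_r
        # P(h) / P(h-2) = 4 * (hom_r + 1) * (hom_c + 1) / (h * (h - 1))
        logs[i] = logs[i - 1] + (
            np.log(4.0) + np.log(hom_r + 1.0) + np.log(hom_c + 1.0) - np.log(h) - np.log(h - 1.0)
        )
    return logs - logs.max()


def hwe_pvalues(data: GenotypeDataset) -> np.ndarray:
    """Exact HWE p-value for every SNP (missing calls excluded per SNP)."""
    calls = data.calls
    n_hom1 = (calls == 2).sum(axis=0)
    n_het = (calls == 1).sum(axis=0)
    n_hom2 = (calls == 0).sum(axis=0)
    out = np.ones(data.n_variants)
    for j in range(data.n_variants):
        if n_hom1[j] + n_het[j] + n_hom2[j] > 0:
            out[j] = hwe_exact_test(int(n_hom1[j]), int(n_het[j]), int(n_hom2[j]))
    return out


def apply_qc(data: GenotypeDataset, thresholds: QCThresholds | None = None):
    """Apply the sequential SNP filters; return (filtered dataset, report).

    Run on a single population's dataset for within-population QC, or on a
    merged dataset for pooled-mode QC (where the HWE test acts on the
    pooled genotype table, Wahlund effect included).
    """
    thresholds = thresholds or QCThresholds()
    m = data.n_variants
    alive = np.ones(m, dtype=bool)
    chrom = data.variants["chrom"].astype(str).to_numpy()

    pos_mask = np.zeros(m, dtype=bool)
    if thresholds.drop_sex_chromosomes:
        pos_mask |= np.isin(chrom, SEX_CHROMOSOMES)
    if thresholds.drop_unknown_or_duplicate_positions:
        pos_mask |= chrom == UNKNOWN_CHROMOSOME
        key = pd.Series(list(zip(chrom, data.variants["pos"])))
        pos_mask |= key.duplicated(keep=False).to_numpy()  # both copies removed
    removed_position = int(pos_mask.sum())
    alive &= ~pos_mask

    freqs = allele_frequencies(data)
    maf = freqs["maf"].to_numpy()
    with np.errstate(invalid="ignore"):
        maf_mask = alive & (maf < thresholds.maf_min)
    removed_maf = int(maf_mask.sum())
    alive &= ~maf_mask

    call_rate = freqs["call_rate"].to_numpy()
    cr_mask = alive & (call_rate < thresholds.call_rate_min)
    removed_cr = int(cr_mask.sum())
    alive &= ~cr_mask

    removed_hwe = 0
    if thresholds.hwe_p_min > 0:
        idx = np.flatnonzero(alive)
        sub = data.subset(variant_idx=idx)
        pvals = hwe_pvalues(sub)
        hwe_bad = idx[pvals < thresholds.hwe_p_min]
        removed_hwe = int(hwe_bad.size)
        alive[hwe_bad] = False

    report = QCReport(removed_position, removed_maf, removed_cr, removed_hwe, int(alive.sum()))
    return data.subset(variant_idx=np.flatnonzero(alive)), report


def per_population_qc(data: GenotypeDataset, thresholds: QCThresholds | None = None):
    """Run within-population QC; returns ``{population: (dataset, report)}``."""
    return {
        pop: apply_qc(data.for_population(pop), thresholds) for pop in data.populations
    }


def ld_prune(data: GenotypeDataset, params: PruneParams | None = None) -> np.ndarray:
    """Greedy sliding-window VIF pruning; returns kept variant indices.

    Monomorphic SNPs are skipped in the window regressions and never cause
    the removal of others.  Near-singular windows are regularised with a
    tiny ridge term.  Ties on the maximal VIF are broken toward the SNP
    with lower MAF, then toward the later input position (the earlier SNP
    survives).  Deterministic given the input order.
    """
    params = params or PruneParams()
    maf = allele_frequencies(data)["maf"].to_numpy()
    calls = data.calls.astype(float)
    calls[data.calls == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(calls), np.nan, calls), axis=0)
    filled = np.where(np.isnan(calls), col_mean, calls)
    variance = filled.var(axis=0)

    keep = np.ones(data.n_variants, dtype=bool)
    chrom = data.variants["chrom"].astype(str).to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < idx.size:
            window = idx[start : start + params.window_snps]
            active = window[keep[window] & (variance[window] > 0)]
            _prune_window(filled, active, maf, params, keep)
            if start + params.window_snps >= idx.size:
                break
            start += params.step_snps
    return np.flatnonzero(keep)


def _prune_window(filled, active, maf, params: PruneParams, keep) -> None:
    active = list(active)
    while len(active) >= 2:
        x = filled[:, active]
        r = np.corrcoef(x, rowvar=False)
        r[np.diag_indices_from(r)] += params.ridge
        try:
            vif = np.diag(np.linalg.inv(r))
        except np.linalg.LinAlgError:
            r[np.diag_indices_from(r)] += 1e-6
            vif = np.diag(np.linalg.inv(r))
        worst = vif.max()
        if worst <= params.vif_max:
            break
        tied = np.flatnonzero(vif >= worst * (1 - 1e-9))
        # lower MAF first, then later input position: earlier SNP survives
        order = sorted(tied, key=lambda k: (maf[active[k]], -active[k]))
        victim = active[order[0]]
        keep[victim] = False
        active.remove(victim)
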