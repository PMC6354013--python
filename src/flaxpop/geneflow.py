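"""Wild-to-cultivated gene-flow tests on four-population SNP panels.

Implements the delta-f subset machinery (loci whose wild-north minus
wild-south frequency difference exceeds a threshold, higher in the north),
Rosenberg's informativeness-for-assignment I_a, the subset-mean-F_ST
resampling test against randomly drawn subsets of equal size, the f3
admixture statistic with a delete-one-locus jackknife, and the
shared-elevation fraction (how often a wild-north-elevated locus is also
cultivated-north-elevated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differentiation import fst_locus

__all__ = [
    "DeltaFSubset",
    "ResampleTestResult",
    "delta_f_subsets",
    "informativeness_ia",
    "informativeness_per_locus",
    "subset_fst_resample_test",
    "f3_statistic",
    "shared_elevation_fraction",
]


@dataclass(frozen=True)
class DeltaFSubset:
    """Loci with f_wildNorth - f_wildSouth above a threshold (north higher)."""

    threshold: float
    loci: tuple
    delta_f: tuple

    def __len__(self):
        return len(self.loci)


@dataclass(frozen=True)
class ResampleTestResult:
    """One-sided upper resampling test of a subset's mean F_ST."""

    observed_mean_fst: float
    null_mean: float
    null_sd: float
    null_q05: float
    null_q95: float
    n_resamples: int
    p_value: float
    seed: int | None


def delta_f_subsets(
    f_wild_north,
    f_wild_south,
    loci=None,
    thresholds=(0.5, 0.4, 0.3),
) -> list[DeltaFSubset]:
    """One subset per threshold of loci differentially high in the wild north.

    Membership requires f_wildN - f_wildS strictly greater than the
    threshold; loci with a missing frequency in either population are
    excluded.  Subsets nest: the 0.5 subset is contained in 0.4, which is
    contained in 0.3.
    """
    f_n = np.asarray(f_wild_north, dtype=float)
    f_s = np.asarray(f_wild_south, dtype=float)
    if f_n.shape != f_s.shape:
        raise ValueError("wild north/south frequency arrays differ in shape")
    if loci is None:
        loci = np.arange(len(f_n))
    loci = np.asarray(loci)
    if len(loci) == 0:
        raise ValueError("no loci shared between the wild populations")
    delta = f_n - f_s
    valid = np.isfinite(delta)
    out = []
    for thr in thresholds:
        sel = valid & (delta > thr)
        out.append(
            DeltaFSubset(
                threshold=float(thr),
                loci=tuple(loci[sel]),
                delta_f=tuple(delta[sel]),
            )
        )
    return out


def informativeness_per_locus(freqs: np.ndarray) -> np.ndarray:
    """Rosenberg informativeness for assignment, I_n, per biallelic locus.

    ``freqs`` has shape (loci, populations) holding the focal-allele
    frequency in each population; the complementary allele is implied.  Per
    locus,

        I_n = sum_alleles [ -pbar ln pbar + sum_pops (p_pop ln p_pop) / K ]

    with the convention 0*ln(0) = 0 and pbar the unweighted mean across the
    K populations.
    """
    p = np.atleast_2d(np.asarray(freqs, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    k = p.shape[1]

    def xlogx(v):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = v * np.log(v)
        return np.where(v == 0.0, 0.0, out)

    total = np.zeros(p.shape[0])
    for allele in (p, 1.0 - p):
        pbar = allele.mean(axis=1)
        total += -xlogx(pbar) + xlogx(allele).sum(axis=1) / k
    return total


def informativeness_ia(freqs) -> float:
    """Mean informativeness-for-assignment over loci (see per-locus form)."""
    return float(informativeness_per_locus(freqs).mean())


def subset_fst_resample_test(
    subset_indices,
    x_cult_north,
    n_cult_north,
    x_cult_south,
    n_cult_south,
    n_resamples: int = 100000,
    seed: int | None = None,
) -> ResampleTestResult:
    """Test whether a locus subset shows elevated cultivated N/S F_ST.

    The observed statistic is the mean uncorrected F_ST between cultivated
    north and south over the subset loci; the null distribution is the same
    statistic over ``n_resamples`` random subsets of equal size drawn
    without replacement from all loci.  p = (1 + #{null >= observed}) /
    (n_resamples + 1), so the smallest achievable p is 1/(n_resamples+1).
    """
    subset_indices = np.asarray(subset_indices, dtype=int)
    if len(subset_indices) == 0:
        raise ValueError("subset is empty")
    fst = fst_locus(x_cult_north, n_cult_north, x_cult_south, n_cult_south,
                    corrected=False)
    fst = np.asarray(fst, dtype=float)
    n_loci = len(fst)
    k = len(subset_indices)
    if k > n_loci / 2:
        import warnings

        warnings.warn(
            "subset covers more than half the panel; the resampling null degenerates",
            stacklevel=2,
        )
    observed = float(np.nanmean(fst[subset_indices]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        pick = rng.choice(n_loci, size=k, replace=False)
        null[i] = np.nanmean(fst[pick])
    p = (1.0 + float((null >= observed).sum())) / (n_resamples + 1.0)
    return ResampleTestResult(
        observed_mean_fst=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        null_q05=float(np.quantile(null, 0.05)),
        null_q95=float(np.quantile(null, 0.95)),
        n_resamples=n_resamples,
        p_value=p,
        seed=seed,
    )


def f3_statistic(
    x_target,
    n_target,
    x_src_a,
    n_src_a,
    x_src_b,
    n_src_b,
    bias_correction: bool = True,
) -> tuple[float, float]:
    """f3(target; A, B) with a delete-one-locus jackknife z-score.

    Per locus f3 = (pT - pA)(pT - pB); with ``bias_correction`` the
    target's sampling term pT(1-pT)/(nT - 1) is subtracted, removing the
    upward bias from finite target sample size.  A significantly negative
    f3 indicates the target is admixed between sources related to A and B.
    Refuses panels with fewer than 30 loci (jackknife unstable).
    """
    pt = np.asarray(x_target, float) / np.asarray(n_target, float)
    pa = np.asarray(x_src_a, float) / np.asarray(n_src_a, float)
    pb = np.asarray(x_src_b, float) / np.asarray(n_src_b, float)
    nt = np.asarray(n_target, float)
    valid = np.isfinite(pt) & np.isfinite(pa) & np.isfinite(pb)
    pt, pa, pb, nt = pt[valid], pa[valid], pb[valid], nt[valid]
    n_loci = len(pt)
    if n_loci < 30:
        raise ValueError(f"need >= 30 loci for a stable jackknife, got {n_loci}")
    per_locus = (pt - pa) * (pt - pb)
    if bias_correction:
        per_locus = per_locus - pt * (1.0 - pt) / (nt - 1.0)
    f3 = float(per_locus.mean())
    total = per_locus.sum()
    jack = (total - per_locus) / (n_loci - 1)  # delete-one means
    se = np.sqrt((n_loci - 1) / n_loci * ((jack - jack.mean()) ** 2).sum())
    if se > 0:
        z = f3 / se
    else:
        z = 0.0 if f3 == 0 else math.copysign(math.inf, f3)
    return f3, float(z)


def shared_elevation_fraction(f_cult_north, f_cult_south, subset_indices) -> float:
    """Fraction of subset loci elevated in the cultivated north.

    Counts strict f_cultN > f_cultS over the subset; ties are excluded from
    the denominator.  Returns nan when the subset is empty or all ties.
    """
    subset_indices = np.asarray(subset_indices, dtype=int)
    if len(subset_indices) == 0:
        return float("nan")
    f_n = np.asarray(f_cult_north, dtype=float)[subset_indices]
    f_s = np.asarray(f_cult_south, dtype=float)[subset_indices]
    valid = np.isfinite(f_n) & np.isfinite(f_s) & (f_n != f_s)
    if valid.sum() == 0:
        return float("nan")
    return float((f_n[valid] > f_s[valid]).mean())
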