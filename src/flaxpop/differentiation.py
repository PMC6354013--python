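"""Population differentiation: per-SNP F_ST, trimmed-likelihood outlier
detection, diagonal-Gaussian 2D allele-frequency-spectrum probability maps,
and latitudinal logistic cline fitting.

F_ST uses the Weir & Cockerham (1984) variance-component estimator applied
to allele counts (no within-individual heterozygosity term, appropriate for
pooled allele counts from highly selfing material).  The "uncorrected"
variant drops the finite-sample terms, which keeps it non-negative and
suits the trimmed scaled-chi-square likelihood used to model the neutral
F_ST distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import SNPPanel

__all__ = [
    "fst_locus",
    "fst_outlier_scan",
    "OutlierScanError",
    "AFS2D",
    "afs2d_fit",
    "afs2d_pvalue",
    "heatmap_grid",
    "ClineFit",
    "SeparationError",
    "logistic_cline",
]

SQRT2 = np.sqrt(2.0)


class OutlierScanError(RuntimeError):
    """The outlier scan cannot proceed (degenerate input or failed fit)."""


class SeparationError(RuntimeError):
    """Logistic fit failed due to complete separation of the outcome."""


def fst_locus(x_n, n_n, x_s, n_s, corrected: bool = True):
    """Two-population Weir & Cockerham F_ST from allele counts.

    Parameters are the focal-allele count and total allele count in each
    population; all four broadcast, so arrays give per-locus values.  With
    ``corrected=True`` the finite-sample variance-component terms are kept;
    with ``corrected=False`` the infinite-sample limit

        theta = s2 / (s2 + pbar*qbar - s2/2)

    is returned, which is non-negative by construction.  A locus
    monomorphic in the pooled sample yields nan.
    """
    x1 = np.asarray(x_n, dtype=float)
    n1 = np.asarray(n_n, dtype=float)
    x2 = np.asarray(x_s, dtype=float)
    n2 = np.asarray(n_s, dtype=float)
    x1, n1, x2, n2 = np.broadcast_arrays(x1, n1, x2, n2)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need at least 2 allele calls per population")
    p1 = x1 / n1
    p2 = x2 / n2
    nbar = (n1 + n2) / 2.0
    ntot = n1 + n2
    nc = ntot - (n1**2 + n2**2) / ntot  # r - 1 = 1 in the denominator
    pbar = (x1 + x2) / ntot
    qbar = 1.0 - pbar
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # r - 1 = 1
    with np.errstate(invalid="ignore", divide="ignore"):
        if corrected:
            a = (nbar / nc) * (s2 - (pbar * qbar - s2 / 2.0) / (nbar - 1.0))
            b = (nbar / (nbar - 1.0)) * (pbar * qbar - s2 / 2.0)
            theta = a / (a + b)
        else:
            theta = s2 / (s2 + pbar * qbar - s2 / 2.0)
    theta = np.where((pbar <= 0.0) | (pbar >= 1.0), np.nan, theta)
    return float(theta) if theta.ndim == 0 else theta


def expected_heterozygosity(x_n, n_n, x_s, n_s):
    """Pooled-sample expected heterozygosity 2*pbar*(1-pbar)."""
    pbar = (np.asarray(x_n, float) + np.asarray(x_s, float)) / (
        np.asarray(n_n, float) + np.asarray(n_s, float)
    )
    return 2.0 * pbar * (1.0 - pbar)


def _trimmed_chi2_fit(core: np.ndarray, lo: float, hi: float,
                      n_below: int = 0, n_above: int = 0,
                      likelihood: str = "censored"):
    """ML fit of F_ST*df/mu ~ chi2_df to a trimmed sample.

    ``likelihood="censored"`` keeps the trimmed tails as censored counts
    (``n_below`` values known only to lie below ``lo``, ``n_above`` above
    ``hi``), which anchors the fitted tail mass to the observed trim
    fractions; ``"truncated"`` conditions on the core range and ignores the
    tails entirely.
    """
    mean = core.mean()
    var = core.var()
    df0 = max(0.2, 2.0 * mean**2 / var) if var > 0 else 1.0

    def negloglik(params):
        log_df, log_mu = params
        df = np.exp(log_df)
        mu = np.exp(log_mu)
        scale = df / mu
        z = core * scale
        logpdf = stats.chi2.logpdf(z, df) + np.log(scale)
        cdf_lo = stats.chi2.cdf(lo * scale, df)
        sf_hi = stats.chi2.sf(hi * scale, df)
        if likelihood == "censored":
            ll = logpdf.sum()
            if n_below:
                if cdf_lo <= 0:
                    return 1e12
                ll += n_below * np.log(cdf_lo)
            if n_above:
                if sf_hi <= 0:
                    return 1e12
                ll += n_above * np.log(sf_hi)
            return -ll
        norm = 1.0 - cdf_lo - sf_hi
        if norm <= 0 or not np.isfinite(norm):
            return 1e12
        return -(logpdf.sum() - len(core) * np.log(norm))

    res = optimize.minimize(
        negloglik,
        x0=[np.log(df0), np.log(mean)],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
    )
    if not res.success:
        raise OutlierScanError(f"trimmed chi-square fit did not converge: {res.message}")
    df, mu = np.exp(res.x)
    return float(df), float(mu)


def fst_outlier_scan(
    panel: SNPPanel,
    north: str = "north",
    south: str = "south",
    trim: float = 0.05,
    he_min: float = 0.10,
    q_threshold: float = 0.05,
    likelihood: str = "censored",
) -> pd.DataFrame:
    """Scan a two-population SNP panel for F_ST outliers.

    Loci with pooled expected heterozygosity below ``he_min`` are dropped;
    the central portion of the uncorrected F_ST distribution (after
    symmetric trimming of the lowest and highest ``trim`` quantiles) is fit
    by maximum likelihood with a scaled chi-square model
    ``F_ST * df / mu ~ chi2(df)``; by default the trimmed tails enter the
    likelihood as censored counts, which pins the fitted tail mass to the
    observed trim fractions (``likelihood="truncated"`` instead conditions
    on the core range, as in plain truncated ML).  Each
    retained locus then gets a right-tail p-value from the fitted null and
    a Benjamini-Hochberg q-value; outliers are flagged at
    ``q < q_threshold``.

    Returns a DataFrame indexed by locus with frequencies, counts, both
    F_ST variants, He, p, q and the outlier flag; the fitted (df, mu) are
    stored in ``DataFrame.attrs``.
    """
    x = panel.x
    n = panel.n
    if north not in x.columns or south not in x.columns:
        raise KeyError(f"panel lacks populations {north!r}/{south!r}")
    xn, nn = x[north].values, n[north].values
    xs, ns = x[south].values, n[south].values
    he = expected_heterozygosity(xn, nn, xs, ns)
    fst_unc = fst_locus(xn, nn, xs, ns, corrected=False)
    fst_cor = fst_locus(xn, nn, xs, ns, corrected=True)

    retained = (he >= he_min) & np.isfinite(fst_unc)
    if retained.sum() < 50:
        raise OutlierScanError(
            f"only {int(retained.sum())} loci pass the He filter; need >= 50"
        )
    values = fst_unc[retained]
    if np.allclose(values, values[0]):
        raise OutlierScanError("degenerate F_ST distribution: no spread across loci")

    lo, hi = np.quantile(values, [trim, 1.0 - trim])
    in_core = (values >= lo) & (values <= hi) & (values > 0)
    core = values[in_core]
    if len(core) < 50:
        raise OutlierScanError("too few positive F_ST values in the trimmed core")
    df_fit, mu_fit = _trimmed_chi2_fit(
        core,
        max(lo, core.min()),
        hi,
        n_below=int((values < max(lo, core.min())).sum()),
        n_above=int((values > hi).sum()),
        likelihood=likelihood,
    )

    p = np.full(len(fst_unc), np.nan)
    p[retained] = stats.chi2.sf(fst_unc[retained] * df_fit / mu_fit, df_fit)
    q = np.full(len(fst_unc), np.nan)
    q[retained] = multipletests(p[retained], method="fdr_bh")[1]

    with np.errstate(invalid="ignore", divide="ignore"):
        out = pd.DataFrame(
            {
                "f_north": xn / nn,
                "f_south": xs / ns,
                "n_north": nn.astype(int),
                "n_south": ns.astype(int),
                "he": he,
                "fst_uncorrected": fst_unc,
                "fst_corrected": fst_cor,
                "retained": retained,
                "p_value": p,
                "q_value": q,
                "outlier": (q < q_threshold) & retained,
            },
            index=panel.x.index,
        )
    out.attrs["df"] = df_fit
    out.attrs["mu"] = mu_fit
    return out


# ---------------------------------------------------------------------------
# 2D allele frequency spectrum
# ---------------------------------------------------------------------------


@dataclass
class AFS2D:
    """Diagonal-Gaussian fit of a two-population allele-frequency spectrum.

    Each locus contributes a point (f_north, f_south); its position along
    the spectrum diagonal is m = (f_N + f_S)/2 and its signed perpendicular
    distance d = (f_N - f_S)/sqrt(2).  Per bin of m the mean and standard
    deviation of d are estimated, and interpolated linearly between bin
    centers (constant beyond the outer centers).
    """

    bin_centers: np.ndarray
    mu_d: np.ndarray
    sigma_d: np.ndarray
    n_per_bin: np.ndarray
    interpolated_bins: list = field(default_factory=list)

    def params_at(self, m):
        m = np.asarray(m, dtype=float)
        mu = np.interp(m, self.bin_centers, self.mu_d)
        sigma = np.interp(m, self.bin_centers, self.sigma_d)
        return mu, sigma


def diagonal_coordinates(f_north, f_south):
    """(m, d): midpoint along the diagonal, signed perpendicular distance."""
    f_n = np.asarray(f_north, dtype=float)
    f_s = np.asarray(f_south, dtype=float)
    return (f_n + f_s) / 2.0, (f_n - f_s) / SQRT2


def afs2d_fit(f_north, f_south, n_bins: int = 10) -> AFS2D:
    """Fit per-bin Gaussians of the perpendicular spread of the 2D spectrum.

    Bins partition m in [0, 1].  Empty or single-point bins get parameters
    interpolated from their neighbours and are reported in
    ``interpolated_bins``.  Raises if every occupied bin is degenerate
    (all sigma = 0), which happens when f_north equals f_south exactly at
    every locus.
    """
    m, d = diagonal_coordinates(f_north, f_south)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(m, edges) - 1, 0, n_bins - 1)
    mu = np.full(n_bins, np.nan)
    sigma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = d[idx == b]
        counts[b] = len(sel)
        if len(sel) >= 2:
            mu[b] = sel.mean()
            sigma[b] = sel.std(ddof=1)
    occupied = ~np.isnan(mu)
    if not occupied.any():
        raise OutlierScanError("no bin holds >= 2 loci; cannot fit the spectrum")
    if np.all(sigma[occupied] == 0.0):
        raise OutlierScanError(
            "degenerate spectrum: f_north = f_south at every locus (all sigma = 0); "
            "the perpendicular Gaussian model needs spread"
        )
    interpolated = [int(b) for b in range(n_bins) if not occupied[b]]
    if interpolated:
        good = np.where(occupied)[0]
        mu = np.interp(np.arange(n_bins), good, mu[good])
        sigma = np.interp(np.arange(n_bins), good, sigma[good])
        warnings.warn(
            f"bins {interpolated} had <2 loci; parameters interpolated",
            stacklevel=2,
        )
    return AFS2D(centers, mu, sigma, counts, interpolated)


def afs2d_pvalue(afs: AFS2D, f_north, f_south):
    """Two-sided Gaussian tail probability of a frequency combination.

    p = 2 * (1 - Phi(|d - mu_d(m)| / sigma_d(m))), capped at 1; nan where
    the local sigma is zero.
    """
    m, d = diagonal_coordinates(f_north, f_south)
    mu, sigma = afs.params_at(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(d - mu) / sigma
        p = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    p = np.where(np.asarray(sigma) == 0.0, np.nan, p)
    return float(p) if p.ndim == 0 else p


def heatmap_grid(afs: AFS2D, resolution: int = 101) -> pd.DataFrame:
    """Evaluate the spectrum p-value on a grid over the unit square.

    Rows index f_north and columns f_south, both on a uniform grid of
    ``resolution`` points in [0, 1]; suitable for external heat-map
    plotting (serialize with ``DataFrame.to_csv(sep='\\t')``).
    """
    grid = np.linspace(0.0, 1.0, resolution)
    f_n, f_s = np.meshgrid(grid, grid, indexing="ij")
    p = afs2d_pvalue(afs, f_n.ravel(), f_s.ravel()).reshape(resolution, resolution)
    return pd.DataFrame(p, index=np.round(grid, 6), columns=np.round(grid, 6))


# ---------------------------------------------------------------------------
# latitudinal cline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClineFit:
    """Logistic regression of allele presence on latitude."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    wald_p: float
    curve: pd.DataFrame  # latitude, fitted probability at 0.1 degree steps


def logistic_cline(presence, latitude) -> ClineFit:
    """Fit P(presence) ~ logistic(latitude) by maximum likelihood (IRLS).

    ``presence`` is binary per sample.  Raises :class:`SeparationError` on
    complete separation (including all-0/all-1 outcomes), advising a
    penalized fit instead.  The Wald p-value tests the latitude slope.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(presence, dtype=float)
    lat = np.asarray(latitude, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("presence must be binary 0/1")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise SeparationError(
            "need at least 2 of each outcome; fit is degenerate "
            "(consider a penalized logistic fit)"
        )
    # complete separation: a latitude threshold classifies perfectly
    order = np.argsort(lat)
    ys = y[order]
    if np.all(np.diff(ys) >= 0) or np.all(np.diff(ys) <= 0):
        raise SeparationError(
            "complete separation of presence by latitude; use a penalized fit"
        )
    X = sm.add_constant(lat)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    except PerfectSeparationError as exc:
        raise SeparationError(
            "complete separation detected; use a penalized fit"
        ) from exc
    if not fit.converged:
        raise RuntimeError("logistic fit did not converge within 100 iterations")
    intercept, slope = fit.params
    se_int, se_slope = fit.bse
    wald_p = float(fit.pvalues[1])
    grid = np.arange(np.floor(lat.min() * 10), np.ceil(lat.max() * 10) + 1) / 10.0
    prob = 1.0 / (1.0 + np.exp(-(intercept + slope * grid)))
    curve = pd.DataFrame({"latitude": grid, "probability": prob})
    return ClineFit(
        intercept=float(intercept),
        slope=float(slope),
        intercept_se=float(se_int),
        slope_se=float(se_slope),
        wald_p=wald_p,
        curve=curve,
    )
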