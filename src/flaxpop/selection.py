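"""Selection-coefficient estimation from pairs of dated allele frequencies.

The model is the deterministic single-locus viability-selection recursion
with inbreeding in the sense of Wright's F: each generation the genotype
frequencies are built from the current allele frequency p and F,

    D_AA = p^2 + F p q,   H = 2 p q (1 - F),   R = q^2 + F p q,

fitnesses are {1, 1, 1-s} when the focal (beneficial) allele is dominant
and {1, 1-s, 1-s} when it is recessive, and

    p' = (w_AA D_AA + 0.5 w_Aa H) / w_bar.

Given two dated binomial observations of the focal allele, ``estimate_s``
inverts this recursion by bisection over s; sampling error is propagated
by drawing the start/stop frequencies from Beta posteriors (uniform prior:
Beta(x+1, n-x+1)) and re-estimating per draw.

The relation between the selection differential k and the selection
coefficient is s = 1 - 1/(1 - k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DatedFrequencySeries

__all__ = [
    "SelectionModel",
    "SelectionEstimate",
    "InfeasibleTrajectoryError",
    "s_from_k",
    "k_from_s",
    "forward_frequency",
    "estimate_s",
    "beta_bounds",
    "latitude_series",
]

S_BRACKET = (-0.5, 0.5)  # bisection bracket; realistic |s| is ~1e-3..1e-1


class InfeasibleTrajectoryError(ValueError):
    """The requested frequency change cannot be produced by any s in range."""


@dataclass(frozen=True)
class SelectionModel:
    """Mating/trait settings for the deterministic selection recursion.

    Parameters
    ----------
    inbreeding_f
        Wright's F in [0, 1]; under selfing rate sigma = 1 - t the
        equilibrium value is (1 - t) / (1 + t).
    dominance
        ``"dominant"`` or ``"recessive"`` for the focal (selected) allele.
    trait_mode
        ``"allele_frequency"`` (observations are allele frequencies) or
        ``"phenotype_frequency"`` (observations are carrier/homozygote
        phenotype frequencies, converted via the genotype model).
    generation_time
        Years per generation; flax is annual, so the default is 1.
    """

    inbreeding_f: float = 0.9
    dominance: str = "dominant"
    trait_mode: str = "allele_frequency"
    generation_time: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must lie in [0, 1]")
        if self.dominance not in ("dominant", "recessive"):
            raise ValueError("dominance must be 'dominant' or 'recessive'")
        if self.trait_mode not in ("allele_frequency", "phenotype_frequency"):
            raise ValueError("unknown trait_mode")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")


@dataclass(frozen=True)
class SelectionEstimate:
    """Point estimate of s with Monte-Carlo bounds and run settings."""

    s_hat: float
    ci_low: float
    ci_high: float
    k_hat: float
    generations: int
    draws: int
    seed: int | None
    infeasible_fraction: float = 0.0
    reliable: bool = True


def s_from_k(k):
    """s = 1 - 1/(1 - k), the printed relation between differential and coefficient."""
    k = np.asarray(k, dtype=float)
    if np.any(k == 1.0):
        raise ZeroDivisionError("k = 1 leaves s undefined")
    out = 1.0 - 1.0 / (1.0 - k)
    return float(out) if out.ndim == 0 else out


def k_from_s(s):
    """Inverse of :func:`s_from_k` (the relation is an involution)."""
    return s_from_k(s)


def phenotype_to_allele_frequency(pheno_freq, model: SelectionModel):
    """Convert an observed phenotype frequency to an allele frequency.

    Dominant trait: the phenotype counts carriers, P = D_AA + H; recessive:
    homozygotes only, P = D_AA.  Solved under the model's F for p in [0,1]
    (monotone in p, solved numerically).
    """
    pheno = np.atleast_1d(np.asarray(pheno_freq, dtype=float))
    f = model.inbreeding_f

    def carriers(p):
        q = 1.0 - p
        d_aa = p * p + f * p * q
        h = 2 * p * q * (1.0 - f)
        return d_aa + h if model.dominance == "dominant" else d_aa

    out = np.empty_like(pheno)
    for i, target in enumerate(pheno):
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if carriers(mid) < target:
                lo = mid
            else:
                hi = mid
        out[i] = 0.5 * (lo + hi)
    return out if out.shape != (1,) else float(out[0])


def forward_frequency(p0, s, generations: int, model: SelectionModel):
    """Deterministic allele frequency after ``generations`` of selection.

    Vectorized: ``p0`` and ``s`` broadcast together; the recursion runs the
    same number of generations for every element.  The result is clamped to
    [0, 1] against round-off.
    """
    scalar = np.isscalar(p0) and np.isscalar(s)
    p = np.atleast_1d(np.asarray(p0, dtype=float))
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    p, s_arr = np.broadcast_arrays(p, s_arr)
    p = p.astype(float).copy()
    f = model.inbreeding_f
    dominant = model.dominance == "dominant"
    for _ in range(int(generations)):
        q = 1.0 - p
        d_aa = p * p + f * p * q
        h = 2.0 * p * q * (1.0 - f)
        r = q * q + f * p * q
        if dominant:
            w_aa, w_het, w_rr = 1.0, 1.0, 1.0 - s_arr
        else:
            w_aa, w_het, w_rr = 1.0, 1.0 - s_arr, 1.0 - s_arr
        wbar = w_aa * d_aa + w_het * h + w_rr * r
        p = (w_aa * d_aa + 0.5 * w_het * h) / wbar
        np.clip(p, 0.0, 1.0, out=p)
    if scalar:
        return float(p[0])
    return p


def _invert(p_start, p_stop, generations: int, model: SelectionModel,
            tol: float = 1e-12, max_iter: int = 100):
    """Vectorized bisection for s with forward(p_start, s, G) = p_stop.

    Returns an array of s values with nan where the trajectory is
    infeasible (p_start absorbing, or p_stop outside the bracket's reach).
    The forward map is monotone increasing in s.
    """
    p_start = np.atleast_1d(np.asarray(p_start, dtype=float))
    p_stop = np.atleast_1d(np.asarray(p_stop, dtype=float))
    p_start, p_stop = np.broadcast_arrays(p_start, p_stop)
    lo = np.full(p_start.shape, S_BRACKET[0] + 1e-9)
    hi = np.full(p_start.shape, S_BRACKET[1] - 1e-9)
    f_lo = forward_frequency(p_start, lo, generations, model) - p_stop
    f_hi = forward_frequency(p_start, hi, generations, model) - p_stop
    feasible = (f_lo <= 0) & (f_hi >= 0)
    # absorbing start with a different stop can never be reached
    feasible &= ~(((p_start == 0.0) | (p_start == 1.0)) & (p_stop != p_start))
    same = np.isclose(p_start, p_stop, rtol=0, atol=0)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = forward_frequency(p_start, mid, generations, model) - p_stop
        go_up = f_mid < 0
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
        if np.all((hi - lo) < tol):
            break
    s = 0.5 * (lo + hi)
    s = np.where(same, 0.0, s)
    s = np.where(feasible, s, np.nan)
    return s


def estimate_s(
    series: DatedFrequencySeries,
    model: SelectionModel,
    draws: int = 10000,
    level: float = 0.95,
    seed: int | None = None,
) -> SelectionEstimate:
    """Estimate s between the first (oldest) and last observation of a series.

    The point estimate is the unique root of
    ``forward_frequency(p_start, s, G) = p_stop`` over the bracket
    (-0.5, 0.5); G is the number of generations separating the two dates.
    Bounds come from :func:`beta_bounds`.
    """
    (p_start, p_stop), gens = _series_endpoints(series, model)
    if p_start in (0.0, 1.0) and p_stop != p_start:
        raise InfeasibleTrajectoryError(
            f"start frequency {p_start} is absorbing; cannot reach {p_stop}"
        )
    s = _invert(p_start, p_stop, gens, model)
    s_hat = float(s[0])
    if np.isnan(s_hat):
        raise InfeasibleTrajectoryError(
            f"no s in {S_BRACKET} moves {p_start} to {p_stop} in {gens} generations"
        )
    lo, hi, infeasible_frac = _beta_bounds_arrays(series, model, draws, level, seed)
    return SelectionEstimate(
        s_hat=s_hat,
        ci_low=lo,
        ci_high=hi,
        k_hat=k_from_s(s_hat),
        generations=gens,
        draws=draws,
        seed=seed,
        infeasible_fraction=infeasible_frac,
        reliable=infeasible_frac <= 0.5,
    )


def _series_endpoints(series: DatedFrequencySeries, model: SelectionModel):
    dates = series.dates_bp
    delta_years = dates[0] - dates[-1]
    gens = max(1, int(round(delta_years / model.generation_time)))
    p = series.freq
    if model.trait_mode == "phenotype_frequency":
        p = np.array([phenotype_to_allele_frequency(v, model) for v in p])
    return (float(p[0]), float(p[-1])), gens


def beta_bounds(
    series: DatedFrequencySeries,
    model: SelectionModel,
    draws: int = 10000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo bounds on s from Beta sampling distributions.

    Draws p_start ~ Beta(x1+1, n1-x1+1) and p_stop ~ Beta(x2+1, n2-x2+1)
    independently (a binomial process with a uniform prior), re-estimates s
    per draw and reports the empirical (1-level)/2 and 1-(1-level)/2
    quantiles.  Infeasible draws are skipped; when more than half of the
    draws are infeasible the bounds are flagged unreliable (nan returned).
    """
    lo, hi, frac = _beta_bounds_arrays(series, model, draws, level, seed)
    return lo, hi


def _beta_bounds_arrays(series, model, draws, level, seed):
    rng = np.random.default_rng(seed)
    x1, n1 = series.x[0], series.n[0]
    x2, n2 = series.x[-1], series.n[-1]
    gens = _series_endpoints(series, model)[1]
    p_start = rng.beta(x1 + 1, n1 - x1 + 1, size=draws)
    p_stop = rng.beta(x2 + 1, n2 - x2 + 1, size=draws)
    if model.trait_mode == "phenotype_frequency":
        p_start = np.array([phenotype_to_allele_frequency(v, model) for v in p_start])
        p_stop = np.array([phenotype_to_allele_frequency(v, model) for v in p_stop])
    s = _invert(p_start, p_stop, gens, model)
    ok = ~np.isnan(s)
    infeasible_frac = 1.0 - ok.mean()
    if infeasible_frac > 0.5:
        return float("nan"), float("nan"), infeasible_frac
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(s[ok], [alpha, 1.0 - alpha])
    return float(lo), float(hi), infeasible_frac


def latitude_series(
    band_frequencies,
    arrival_dates,
    model: SelectionModel | None = None,
) -> list[DatedFrequencySeries]:
    """Build consecutive-band dated series pairs from latitudinal frequencies.

    Parameters
    ----------
    band_frequencies
        DataFrame with columns ``lat_min, lat_max, x, n`` (one row per
        latitude band, any order; bands are sorted south to north).
    arrival_dates
        DataFrame with columns ``lat_min, lat_max, date_bp`` mapping each
        band to the arrival date of agriculture.

    Returns the list of two-point series for consecutive band pairs
    (southern first, i.e. older date first); bands with n = 0 are skipped
    with a warning.
    """
    import warnings

    import pandas as pd

    freq = pd.DataFrame(band_frequencies).sort_values("lat_min").reset_index(drop=True)
    dates = pd.DataFrame(arrival_dates)
    merged = freq.merge(dates, on=["lat_min", "lat_max"], how="left")
    if merged["date_bp"].isna().any():
        missing = merged.loc[merged["date_bp"].isna(), ["lat_min", "lat_max"]]
        raise ValueError(f"no arrival date for bands:\n{missing}")
    keep = merged["n"] > 0
    if not keep.all():
        warnings.warn("skipping latitude bands with n = 0", stacklevel=2)
        merged = merged[keep].reset_index(drop=True)
    out = []
    for i in range(len(merged) - 1):
        a, b = merged.iloc[i], merged.iloc[i + 1]
        if a["date_bp"] == b["date_bp"]:
            warnings.warn(
                f"bands {a['lat_min']} and {b['lat_min']} share a date; skipped",
                stacklevel=2,
            )
            continue
        out.append(
            DatedFrequencySeries(
                dates_bp=[a["date_bp"], b["date_bp"]],
                x=[a["x"], b["x"]],
                n=[a["n"], b["n"]],
                latitudes=[0.5 * (a["lat_min"] + a["lat_max"]),
                           0.5 * (b["lat_min"] + b["lat_max"])],
            )
        )
    return out
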