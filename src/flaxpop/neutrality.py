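"""Sequence diversity summaries, neutrality tests and two-locus LD.

Implements, on haplotype alignments: Watterson/pairwise diversity, allele
(haplotype) collapsing, Tajima's D, Fu & Li's starred D*/F* (and the
outgroup D/F variants), the Ramos-Onsins & Rozas R2 statistic, and the
correlation coefficient r of the classical two-locus disequilibrium D.

Conventions
-----------
* complete deletion: any alignment column containing a gap ``-`` or an
  ``N`` in any sequence is excluded before computing statistics;
* statistics that are undefined when there is no segregating variation
  (S = 0) return ``nan``, never 0;
* the number of mutations eta is taken equal to the number of segregating
  sites (infinite-sites convention; multi-hit columns are rare in the
  short gene fragments this targets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HaplotypeAlignment

__all__ = [
    "DiversityStats",
    "NeutralityResult",
    "TwoLocusCounts",
    "collapse_alleles",
    "diversity_stats",
    "tajimas_d",
    "fu_li_star",
    "fu_li_outgroup",
    "ramos_onsins_r2",
    "ld_r",
    "neutrality_report",
    "neutrality_pvalues",
]

NA = float("nan")


def _clean_matrix(alignment: HaplotypeAlignment) -> np.ndarray:
    """Alignment matrix after complete deletion of gap/N columns."""
    mat = alignment.matrix()
    keep = ~((mat == "-") | (mat == "N")).any(axis=0)
    return mat[:, keep]


def _site_allele_counts(mat: np.ndarray):
    """Yield per-site arrays of allele counts (only observed alleles)."""
    for j in range(mat.shape[1]):
        _, counts = np.unique(mat[:, j], return_counts=True)
        yield counts


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


@dataclass(frozen=True)
class DiversityStats:
    """Summary of within-locus diversity for one alignment."""

    n: int
    S: int
    pi: float
    theta_w: float
    singletons: int
    haplotype_count: int


@dataclass(frozen=True)
class NeutralityResult:
    """The four neutrality statistics; nan marks an undefined value."""

    tajima_d: float
    fu_li_d_star: float
    fu_li_f_star: float
    r2: float


@dataclass
class TwoLocusCounts:
    """Observed two-locus haplotype-combination proportions.

    ``j11, j12, j21, j22`` are the observed proportions of the allele
    combinations (p1 p2), (p1 q2), (q1 p2) and (q1 q2); the marginals are
    derived from them.
    """

    j11: float
    j12: float
    j21: float
    j22: float

    def __post_init__(self):
        props = np.array([self.j11, self.j12, self.j21, self.j22], dtype=float)
        if (props < 0).any():
            raise ValueError("proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {props.sum()}")

    @property
    def p1(self) -> float:
        return self.j11 + self.j12

    @property
    def q1(self) -> float:
        return self.j21 + self.j22

    @property
    def p2(self) -> float:
        return self.j11 + self.j21

    @property
    def q2(self) -> float:
        return self.j12 + self.j22

    def swap_locus1(self) -> "TwoLocusCounts":
        """Exchange the allele labels of the first locus."""
        return TwoLocusCounts(self.j21, self.j22, self.j11, self.j12)


# ---------------------------------------------------------------------------
# core summaries
# ---------------------------------------------------------------------------


def _summaries(mat: np.ndarray):
    """(n, S, pi, singleton count, per-sequence singleton loads)."""
    n = mat.shape[0]
    S = 0
    pi_sum = 0.0
    eta_s = 0
    u = np.zeros(n)  # singleton mutations carried by each sequence
    pairs = n * (n - 1) / 2.0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) < 2:
            continue
        S += 1
        pi_sum += (counts[:, None] * counts[None, :]).sum() - (counts**2).sum()
        for a, c in zip(alleles, counts):
            if c == 1:
                eta_s += 1
                u[np.argmax(col == a)] += 1
    pi = pi_sum / 2.0 / pairs if pairs else 0.0
    return n, S, pi, eta_s, u


def diversity_stats(alignment: HaplotypeAlignment) -> DiversityStats:
    """n, segregating sites, pi, Watterson's theta, singletons, haplotypes."""
    mat = _clean_matrix(alignment)
    n, S, pi, eta_s, _ = _summaries(mat)
    a1 = _harmonic(n)
    theta_w = S / a1 if a1 > 0 else NA
    return DiversityStats(
        n=n,
        S=S,
        pi=pi,
        theta_w=theta_w,
        singletons=eta_s,
        haplotype_count=len(collapse_alleles(alignment)),
    )


def collapse_alleles(alignment: HaplotypeAlignment) -> list[tuple[str, list[str]]]:
    """Group sequences into alleles, treating N as a wildcard.

    Two sequences belong to the same allele when they agree at every site
    where neither carries an N.  Assignment is greedy in file order against
    a per-allele consensus whose N positions are filled in as members
    resolve them.  Returned groups are labelled ``allele_1 ...`` ordered by
    descending size, ties broken by first occurrence.
    """
    groups: list[dict] = []  # {"consensus": list[str], "members": [ids]}
    for sid, seq in alignment.records:
        chars = list(seq)
        placed = False
        for g in groups:
            cons = g["consensus"]
            ok = all(
                a == b or a == "N" or b == "N" for a, b in zip(cons, chars)
            )
            if ok:
                g["consensus"] = [
                    b if a == "N" else a for a, b in zip(cons, chars)
                ]
                g["members"].append(sid)
                placed = True
                break
        if not placed:
            groups.append({"consensus": chars, "members": [sid]})
    order = sorted(
        range(len(groups)), key=lambda i: (-len(groups[i]["members"]), i)
    )
    return [
        (f"allele_{rank + 1}", groups[i]["members"])
        for rank, i in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------


def tajimas_d(alignment: HaplotypeAlignment) -> float:
    """Tajima's D = (pi - theta_W) / sqrt(V-hat); nan when S = 0."""
    mat = _clean_matrix(alignment)
    n, S, pi, _, _ = _summaries(mat)
    if S == 0:
        return NA
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    num = pi - S / a1
    if var <= 0:
        # at n = 2 the variance coefficients vanish but pi = S = theta_w,
        # so D is the degenerate 0, not undefined
        return 0.0 if num == 0 else NA
    return num / math.sqrt(var)


def _fu_li_coefficients(n: int):
    a = _harmonic(n)
    b = _harmonic(n, 2)
    a_next = a + 1.0 / n
    if n == 2:
        c = 1.0
    else:
        c = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    if n == 2:
        d = 2.0
    else:
        d = c + (n - 2) / (n - 1) ** 2 + 2.0 / (n - 1) * (
            1.5 - (2 * a_next - 3) / (n - 2) - 1.0 / n
        )
    return a, b, a_next, c, d


def fu_li_star(alignment: HaplotypeAlignment) -> tuple[float, float]:
    """Fu & Li's D* and F* (no outgroup; singletons by minor count = 1).

    Uses the corrected coefficient expressions that standard popgen
    software adopted after the original report; nan when S = 0.
    """
    mat = _clean_matrix(alignment)
    n, S, pi, eta_s, _ = _summaries(mat)
    if S == 0 or n < 3:
        return NA, NA
    eta = float(S)
    a, b, a_next, c, d = _fu_li_coefficients(n)

    nn = float(n)
    v_d = (
        (nn / (nn - 1)) ** 2 * b
        + a**2 * d
        - 2 * nn * a * (a + 1) / (nn - 1) ** 2
    ) / (a**2 + b)
    u_d = nn / (nn - 1) * (a - nn / (nn - 1)) - v_d
    denom_d = u_d * eta + v_d * eta**2
    d_star = (
        NA
        if denom_d <= 0
        else ((nn / (nn - 1)) * eta - a * eta_s) / math.sqrt(denom_d)
    )

    v_f = (
        (2 * nn**3 + 110 * nn**2 - 255 * nn + 153) / (9 * nn**2 * (nn - 1))
        + 2 * (nn - 1) * a / nn**2
        - 8 * b / nn
    ) / (a**2 + b)
    u_f = (
        (4 * nn**2 + 19 * nn + 3 - 12 * (nn + 1) * a_next)
        / (3 * nn * (nn - 1))
    ) / a - v_f
    denom_f = u_f * eta + v_f * eta**2
    f_star = (
        NA
        if denom_f <= 0
        else (pi - (nn - 1) / nn * eta_s) / math.sqrt(denom_f)
    )
    return d_star, f_star


def fu_li_outgroup(
    alignment: HaplotypeAlignment, outgroup_id: str
) -> tuple[float, float]:
    """Fu & Li's D and F proper, polarizing singletons with an outgroup.

    The outgroup sequence is removed from the ingroup sample; external
    mutations eta_e are sites where exactly one ingroup sequence carries a
    state different from the outgroup's.
    """
    records = [r for r in alignment.records if r[0] != outgroup_id]
    out = [seq for sid, seq in alignment.records if sid == outgroup_id]
    if not out:
        raise ValueError(f"outgroup {outgroup_id!r} not in alignment")
    if len(records) < 3:
        raise ValueError("outgroup variants need at least 3 ingroup sequences")
    mat_full = alignment.matrix()
    ids = alignment.sample_ids
    out_idx = ids.index(outgroup_id)
    in_idx = [i for i in range(len(ids)) if i != out_idx]
    keep = ~((mat_full == "-") | (mat_full == "N")).any(axis=0)
    mat = mat_full[:, keep]
    ing = mat[in_idx]
    outg = mat[out_idx]

    n, S, pi, _, _ = _summaries(ing)
    if S == 0 or n < 3:
        return NA, NA
    eta = float(S)
    eta_e = 0
    for j in range(ing.shape[1]):
        col = ing[:, j]
        derived = col != outg[j]
        if derived.sum() == 1 and len(np.unique(col)) >= 2:
            eta_e += 1
    a, b, a_next, c, d = _fu_li_coefficients(n)
    nn = float(n)
    v_d = 1 + a**2 / (b + a**2) * (c - (nn + 1) / (nn - 1))
    u_d = a - 1 - v_d
    denom_d = u_d * eta + v_d * eta**2
    d_val = NA if denom_d <= 0 else (eta - a * eta_e) / math.sqrt(denom_d)

    v_f = (c + 2 * (nn**2 + nn + 3) / (9 * nn * (nn - 1)) - 2.0 / (nn - 1)) / (
        a**2 + b
    )
    u_f = (
        1
        + (nn + 1) / (3 * (nn - 1))
        - 4 * (nn + 1) / (nn - 1) ** 2 * (a_next - 2 * nn / (nn + 1))
    ) / a - v_f
    denom_f = u_f * eta + v_f * eta**2
    f_val = NA if denom_f <= 0 else (pi - eta_e) / math.sqrt(denom_f)
    return d_val, f_val


def ramos_onsins_r2(alignment: HaplotypeAlignment) -> float:
    """Ramos-Onsins & Rozas R2; nan when S = 0.

    R2 = sqrt((1/n) sum_i (U_i - k/2)^2) / S where U_i is the number of
    singleton mutations carried by sequence i and k the mean number of
    pairwise differences.
    """
    mat = _clean_matrix(alignment)
    n, S, pi, _, u = _summaries(mat)
    if S == 0:
        return NA
    return math.sqrt(np.mean((u - pi / 2.0) ** 2)) / S


def ld_r(counts: TwoLocusCounts) -> float:
    """Correlation coefficient r of the two-locus disequilibrium D.

    r = (j11*j22 - j12*j21) / sqrt(p1*p2*q1*q2), where the numerator equals
    the classical D = j11 - p1*p2.  Returns nan (with no exception) when a
    locus is monomorphic, where the coefficient is undefined.
    """
    p1, q1, p2, q2 = counts.p1, counts.q1, counts.p2, counts.q2
    denom = p1 * q1 * p2 * q2
    if denom <= 0:
        return NA  # monomorphic locus: correlation undefined
    d = counts.j11 * counts.j22 - counts.j12 * counts.j21
    return d / math.sqrt(denom)


# ---------------------------------------------------------------------------
# reports and significance
# ---------------------------------------------------------------------------


def neutrality_report(alignment: HaplotypeAlignment) -> pd.Series:
    """All four tests plus diversity summaries as one table row."""
    stats = diversity_stats(alignment)
    d_star, f_star = fu_li_star(alignment)
    return pd.Series(
        {
            "n": stats.n,
            "S": stats.S,
            "pi": stats.pi,
            "theta_w": stats.theta_w,
            "singletons": stats.singletons,
            "haplotype_count": stats.haplotype_count,
            "tajima_d": tajimas_d(alignment),
            "fu_li_d_star": d_star,
            "fu_li_f_star": f_star,
            "r2": ramos_onsins_r2(alignment),
        }
    )


def neutrality_pvalues(
    alignment: HaplotypeAlignment, reps: int = 10000, seed: int | None = None
) -> pd.Series:
    """Two-sided empirical p-values from a fixed-S coalescent null.

    Simulates ``reps`` neutral coalescent genealogies at the observed sample
    size, placing exactly the observed number of segregating sites on each
    (multinomially by branch length), and compares each statistic's observed
    value with its simulated distribution.
    """
    from .synthetic import _coalescent_tree_mutations, _alignment_from_mutations

    mat = _clean_matrix(alignment)
    n, S, _, _, _ = _summaries(mat)
    if S == 0:
        return pd.Series(
            {"tajima_d": NA, "fu_li_d_star": NA, "fu_li_f_star": NA, "r2": NA}
        )
    rng = np.random.default_rng(seed)
    obs = {
        "tajima_d": tajimas_d(alignment),
        "fu_li_d_star": fu_li_star(alignment)[0],
        "fu_li_f_star": fu_li_star(alignment)[1],
        "r2": ramos_onsins_r2(alignment),
    }
    sims = {k: [] for k in obs}
    for _ in range(reps):
        branches = _coalescent_tree_mutations(n, rng)
        lengths = np.array([ln for ln, _ in branches])
        probs = lengths / lengths.sum()
        muts = rng.multinomial(S, probs)
        carriers = []
        for m, (_, members) in zip(muts, branches):
            carriers.extend([members] * int(m))
        aln = _alignment_from_mutations(n, carriers)
        sims["tajima_d"].append(tajimas_d(aln))
        ds, fs = fu_li_star(aln)
        sims["fu_li_d_star"].append(ds)
        sims["fu_li_f_star"].append(fs)
        sims["r2"].append(ramos_onsins_r2(aln))
    out = {}
    for k, v in obs.items():
        null = np.array(sims[k], dtype=float)
        null = null[~np.isnan(null)]
        if math.isnan(v) or len(null) == 0:
            out[k] = NA
            continue
        lo = (null <= v).sum()
        hi = (null >= v).sum()
        out[k] = min(1.0, 2.0 * (1 + min(lo, hi)) / (len(null) + 1))
    return pd.Series(out)
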