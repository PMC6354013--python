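"""Seed-deterministic synthetic-data generators for every pipeline stage.

These emulate the statistical structure the analyses assume: neutral
single-population haplotype alignments (Kingman coalescent with
infinite-sites mutation), multi-population biallelic SNP panels with
controllable drift (Balding-Nichols), allele-frequency trajectories under
selection with partial selfing (Wright-Fisher with dynamic inbreeding),
a four-population wild/cultivated scenario with optional wild-north to
cultivated-north gene flow, and Mendelian selfed-progeny segregation at
unlinked hemizygous transgene loci.

Every generator takes a seed (or numpy Generator) and is reproducible;
scenario generators record their ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HaplotypeAlignment, SNPPanel
from .selection import SelectionModel, forward_frequency

__all__ = [
    "WFTrajectory",
    "ScenarioPanel",
    "equilibrium_inbreeding",
    "wright_fisher_selfing",
    "balding_nichols_panel",
    "neutral_coalescent_alignment",
    "geneflow_scenario",
    "selfing_t2_segregation",
]


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def equilibrium_inbreeding(outcrossing_t: float) -> float:
    """Equilibrium Wright's F under selfing rate 1 - t: F = (1-t)/(1+t)."""
    if not 0.0 <= outcrossing_t <= 1.0:
        raise ValueError("outcrossing rate must lie in [0, 1]")
    return (1.0 - outcrossing_t) / (1.0 + outcrossing_t)


@dataclass
class WFTrajectory:
    """A simulated allele-frequency trajectory with its parameters."""

    frequencies: np.ndarray  # length generations + 1, starts at p0
    N: int
    s: float
    outcrossing_t: float
    dominance: str
    seed: int | None

    @property
    def final(self) -> float:
        return float(self.frequencies[-1])


def wright_fisher_selfing(
    N: int,
    p0: float,
    s: float,
    outcrossing_t: float,
    dominance: str = "dominant",
    generations: int = 100,
    seed=None,
    initial_f: float | None = None,
) -> WFTrajectory:
    """Forward Wright-Fisher simulation under partial selfing and selection.

    Each generation: genotype frequencies are built from the current allele
    frequency and inbreeding coefficient F (equilibrium-style construction),
    viability selection is applied exactly as in the deterministic model
    (:func:`flaxpop.selection.forward_frequency`), N individuals are
    resampled multinomially by genotype, and F is updated by the partial
    selfing recursion F' = (1 - t)(1 + F)/2.  F starts at its equilibrium
    value (1-t)/(1+t) unless ``initial_f`` is given.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    rng = _rng(seed)
    f = equilibrium_inbreeding(outcrossing_t) if initial_f is None else initial_f
    dominant = dominance == "dominant"
    if dominance not in ("dominant", "recessive"):
        raise ValueError("dominance must be 'dominant' or 'recessive'")
    p = float(p0)
    traj = [p]
    for _ in range(int(generations)):
        if p in (0.0, 1.0):
            traj.append(p)
            continue
        q = 1.0 - p
        d_aa = p * p + f * p * q
        h = 2.0 * p * q * (1.0 - f)
        r = q * q + f * p * q
        if dominant:
            w = np.array([1.0, 1.0, 1.0 - s])
        else:
            w = np.array([1.0, 1.0 - s, 1.0 - s])
        geno = np.array([d_aa, h, r]) * w
        geno = geno / geno.sum()
        counts = rng.multinomial(N, geno)
        p = (2.0 * counts[0] + counts[1]) / (2.0 * N)
        f = (1.0 - outcrossing_t) * (1.0 + f) / 2.0
        traj.append(p)
    return WFTrajectory(
        frequencies=np.array(traj),
        N=N,
        s=s,
        outcrossing_t=outcrossing_t,
        dominance=dominance,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def balding_nichols_panel(
    n_loci: int,
    f_divergence: float,
    n_pops: int = 2,
    sample_sizes=None,
    seed=None,
    pop_names=None,
    ancestral_range=(0.05, 0.95),
) -> tuple[SNPPanel, pd.DataFrame]:
    """Draw a multi-population SNP panel under the Balding-Nichols model.

    Ancestral frequencies are uniform on ``ancestral_range``; each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral p with divergence parameter F; observed counts are binomial
    at the stated allele sample sizes (default 100 per population).

    Returns the panel and a truth table (ancestral and realized per-pop
    frequencies).
    """
    if not 0.0 < f_divergence < 1.0:
        raise ValueError("f_divergence must lie in (0, 1)")
    rng = _rng(seed)
    if sample_sizes is None:
        sample_sizes = [100] * n_pops
    if pop_names is None:
        pop_names = [f"pop{i+1}" for i in range(n_pops)]
    p_anc = rng.uniform(*ancestral_range, size=n_loci)
    ratio = (1.0 - f_divergence) / f_divergence
    freqs = np.empty((n_loci, n_pops))
    x = np.empty((n_loci, n_pops), dtype=int)
    n = np.empty((n_loci, n_pops), dtype=int)
    for k in range(n_pops):
        freqs[:, k] = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
        n[:, k] = sample_sizes[k]
        x[:, k] = rng.binomial(sample_sizes[k], freqs[:, k])
    loci = [f"locus_{j+1}" for j in range(n_loci)]
    panel = SNPPanel(
        pd.DataFrame(x, index=loci, columns=pop_names),
        pd.DataFrame(n, index=loci, columns=pop_names),
        max_n=pd.Series(dict(zip(pop_names, sample_sizes))),
    )
    truth = pd.DataFrame(
        {"p_ancestral": p_anc, **{pop_names[k]: freqs[:, k] for k in range(n_pops)}},
        index=loci,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# coalescent alignments
# ---------------------------------------------------------------------------


def _coalescent_tree_mutations(n: int, rng) -> list[tuple[float, frozenset]]:
    """Simulate one Kingman genealogy; return branches as (length, members).

    Each entry is one branch: its total length (in units of 2N generations)
    and the set of sample indices descending from it.
    """
    active = [frozenset([i]) for i in range(n)]
    lengths = {lineage: 0.0 for lineage in active}
    branches: list[tuple[float, frozenset]] = []
    k = n
    while k > 1:
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        for lineage in active:
            lengths[lineage] += t
        i, j = rng.choice(k, size=2, replace=False)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        branches.append((lengths.pop(a), a))
        branches.append((lengths.pop(b), b))
        merged = a | b
        active = [x for x in active if x is not a and x is not b]
        active.append(merged)
        lengths[merged] = 0.0
        k -= 1
    return branches


def _alignment_from_mutations(n: int, carrier_sets) -> HaplotypeAlignment:
    """Binary infinite-sites alignment: ancestral 'A', derived 'T' columns."""
    n_sites = len(carrier_sets)
    if n_sites == 0:
        # keep a valid (monomorphic, length-1) alignment when no mutation fell
        mat = np.full((n, 1), "A", dtype="U1")
    else:
        mat = np.full((n, n_sites), "A", dtype="U1")
        for j, members in enumerate(carrier_sets):
            mat[list(members), j] = "T"
    return HaplotypeAlignment(
        (f"hap_{i+1}", "".join(mat[i])) for i in range(n)
    )


def neutral_coalescent_alignment(
    n_samples: int, theta: float, seed=None
) -> HaplotypeAlignment:
    """Neutral single-population coalescent alignment under infinite sites.

    Inter-coalescent times are exponential with rate k(k-1)/2 (time in
    units of 2N generations); mutations fall on each branch as
    Poisson(theta/2 * length) and become biallelic A/T columns.  The
    expected number of segregating sites is theta * sum_{i<n} 1/i.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = _rng(seed)
    branches = _coalescent_tree_mutations(n_samples, rng)
    carriers = []
    for length, members in branches:
        m = rng.poisson(theta / 2.0 * length)
        carriers.extend([members] * int(m))
    # random site order so adjacent columns carry no tree signal
    order = rng.permutation(len(carriers)) if carriers else []
    carriers = [carriers[i] for i in order]
    return _alignment_from_mutations(n_samples, carriers)


# ---------------------------------------------------------------------------
# four-population gene-flow scenario
# ---------------------------------------------------------------------------


@dataclass
class ScenarioPanel:
    """A wildN/wildS/cultN/cultS panel with its generating truth."""

    panel: SNPPanel
    truth: pd.DataFrame  # per-locus true frequencies per population
    spiked_loci: tuple
    params: dict = field(default_factory=dict)

    @property
    def freq(self) -> pd.DataFrame:
        return self.panel.freq()


def geneflow_scenario(
    n_loci: int = 3000,
    divergence_f: float = 0.05,
    migration_m: float = 0.1,
    migration_generations: int = 20,
    spike_count: int = 3,
    sample_sizes=(56, 56, 62, 62),
    seed=None,
    founder_n: int = 50,
    wf_n: int = 500,
    spike_shift: float = 0.4,
) -> ScenarioPanel:
    """Simulate the wild/cultivated four-population design.

    Wild north and south diverge from a common ancestor by Balding-Nichols
    drift (parameter ``divergence_f``).  Both cultivated populations are
    founded from the wild south through a bottleneck of ``founder_n``
    diploid founders, then drift at size ``wf_n`` for
    ``migration_generations`` generations, during which the cultivated
    north receives migrants from the wild north at rate ``migration_m`` per
    generation (the cultivated south receives none).  ``spike_count`` loci
    get a deterministic frequency boost of ``spike_shift`` (clipped) in the
    wild north before founding and in the cultivated north at the end --
    analogues of a northern-adapted allele rising on both backgrounds.

    Populations are ordered (wildN, wildS, cultN, cultS); ``sample_sizes``
    are allele counts drawn binomially from the true frequencies.
    """
    rng = _rng(seed)
    pops = ["wildN", "wildS", "cultN", "cultS"]
    if len(sample_sizes) != 4:
        raise ValueError("sample_sizes must give allele counts for 4 populations")
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    ratio = (1.0 - divergence_f) / divergence_f
    f_wild_n = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
    f_wild_s = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
    spiked = tuple(rng.choice(n_loci, size=spike_count, replace=False)) if spike_count else ()
    spiked_arr = np.array(spiked, dtype=int)
    if spike_count:
        f_wild_n[spiked_arr] = np.clip(f_wild_n[spiked_arr] + spike_shift, 0.0, 1.0)

    def bottleneck(freq):
        return rng.binomial(2 * founder_n, freq) / (2.0 * founder_n)

    f_cult_n = bottleneck(f_wild_s)
    f_cult_s = bottleneck(f_wild_s)
    for _ in range(int(migration_generations)):
        f_cult_n = (1.0 - migration_m) * f_cult_n + migration_m * f_wild_n
        f_cult_n = rng.binomial(2 * wf_n, f_cult_n) / (2.0 * wf_n)
        f_cult_s = rng.binomial(2 * wf_n, f_cult_s) / (2.0 * wf_n)
    if spike_count:
        f_cult_n[spiked_arr] = np.clip(f_cult_n[spiked_arr] + spike_shift, 0.0, 1.0)

    true_f = np.column_stack([f_wild_n, f_wild_s, f_cult_n, f_cult_s])
    x = np.empty((n_loci, 4), dtype=int)
    n = np.empty((n_loci, 4), dtype=int)
    for k in range(4):
        n[:, k] = sample_sizes[k]
        x[:, k] = rng.binomial(sample_sizes[k], true_f[:, k])
    loci = [f"locus_{j+1}" for j in range(n_loci)]
    panel = SNPPanel(
        pd.DataFrame(x, index=loci, columns=pops),
        pd.DataFrame(n, index=loci, columns=pops),
        max_n=pd.Series(dict(zip(pops, sample_sizes))),
    )
    truth = pd.DataFrame(true_f, index=loci, columns=pops)
    truth["p_ancestral"] = p_anc
    return ScenarioPanel(
        panel=panel,
        truth=truth,
        spiked_loci=spiked,
        params={
            "n_loci": n_loci,
            "divergence_f": divergence_f,
            "migration_m": migration_m,
            "migration_generations": migration_generations,
            "spike_count": spike_count,
            "spike_shift": spike_shift,
            "founder_n": founder_n,
            "wf_n": wf_n,
            "sample_sizes": tuple(sample_sizes),
        },
    )


# ---------------------------------------------------------------------------
# Mendelian transgene segregation
# ---------------------------------------------------------------------------


def selfing_t2_segregation(
    n_transgene_loci: int,
    n_progeny: int,
    seed=None,
) -> tuple[int, int, float]:
    """Selfed progeny of a parent hemizygous at L unlinked transgene loci.

    Each progeny receives, independently per locus, the Mendelian selfing
    genotype mix (1/4 homozygous carrier, 1/2 hemizygous, 1/4 null); a
    carrier holds at least one transgene allele at at least one locus.
    Returns (carriers, non-carriers, expected_ratio) where the analytic
    expected carrier : non-carrier ratio is (4^L - 1) : 1.
    """
    if n_transgene_loci < 1:
        raise ValueError("need at least one transgene locus")
    if n_progeny < 1:
        raise ValueError("need at least one progeny")
    rng = _rng(seed)
    # transgene allele count per (progeny, locus): Binomial(2, 1/2), i.e.
    # 1/4 homozygous carrier, 1/2 hemizygous, 1/4 null
    allele_counts = rng.binomial(2, 0.5, size=(n_progeny, n_transgene_loci))
    carrier = (allele_counts >= 1).any(axis=1)
    carriers = int(carrier.sum())
    non_carriers = n_progeny - carriers
    expected_ratio = float(4**n_transgene_loci - 1)
    return carriers, non_carriers, expected_ratio


def wf_deterministic_limit(
    p0: float, s: float, outcrossing_t: float, dominance: str, generations: int
) -> np.ndarray:
    """Deterministic trajectory the Wright-Fisher model converges to.

    Uses the viability recursion with F fixed at the selfing equilibrium
    (1-t)/(1+t); the stochastic model's mean approaches this as N grows.
    """
    model = SelectionModel(
        inbreeding_f=equilibrium_inbreeding(outcrossing_t), dominance=dominance
    )
    out = [p0]
    p = p0
    for _ in range(generations):
        p = forward_frequency(p, s, 1, model)
        out.append(p)
    return np.array(out)
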