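"""Readers, writers and core containers for the pipeline's external formats.

Formats handled here are deliberately plain-text: FASTA haplotype
alignments, STRUCTURE-style genotype matrices (missing data coded ``-9``),
tab-separated frequency/metadata/dated-frequency tables and a small YAML
run configuration.  Everything downstream (neutrality tests, selection
estimation, differentiation scans, gene-flow tests) consumes the containers
defined in this module.

Conventions
-----------
* all tables are UTF-8, tab-delimited, decimal point ``.``;
* dates are canonically years BP (before 1950); calendar years are
  converted as ``BP = 1950 - year``;
* samples are assigned to the ``north``/``south`` group by a configurable
  split parallel, 40 degrees N by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "FormatError",
    "SampleRecord",
    "HaplotypeAlignment",
    "SNPPanel",
    "DatedFrequencySeries",
    "RunConfig",
    "assign_group",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_structure_genotypes",
    "read_frequency_table",
    "write_frequency_table",
    "read_sample_metadata",
    "read_dated_frequencies",
    "write_dated_frequencies",
]

MISSING_CODE = -9
DEFAULT_SPLIT_LATITUDE = 40.0
DEFAULT_PRESENCE_THRESHOLD = 0.80

VALID_RESIDUES = set("ACGTN-")


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


class AlignmentError(FormatError):
    """Sequences cannot form a valid alignment (e.g. unequal lengths)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested analysis."""


def assign_group(latitude: float, split: float = DEFAULT_SPLIT_LATITUDE) -> str:
    """Assign ``north``/``south`` by latitude relative to a split parallel.

    Latitudes at or above the split are northern; below are southern.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    return "north" if latitude >= split else "south"


@dataclass(frozen=True)
class SampleRecord:
    """One accession: identifier, wild/cultivated status and location."""

    sample_id: str
    species: str  # "wild" or "cultivated"
    latitude: float
    longitude: float | None = None
    group: str = "unassigned"

    def __post_init__(self):
        if self.species not in ("wild", "cultivated"):
            raise ValueError(f"species must be wild/cultivated, got {self.species!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.group not in ("north", "south", "unassigned"):
            raise ValueError(f"unknown group {self.group!r}")

    def with_group(self, split: float = DEFAULT_SPLIT_LATITUDE) -> "SampleRecord":
        return SampleRecord(
            self.sample_id,
            self.species,
            self.latitude,
            self.longitude,
            assign_group(self.latitude, split),
        )


class HaplotypeAlignment:
    """An aligned set of haplotype sequences over ``{A, C, G, T, -, N}``.

    Parameters
    ----------
    records
        Iterable of ``(sample_id, sequence)`` pairs.  Lowercase residues are
        mapped to uppercase; all sequences must share one length and ids
        must be unique.
    """

    def __init__(self, records):
        records = [(str(sid), str(seq).upper()) for sid, seq in records]
        if len(records) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        length = len(records[0][1])
        ids = set()
        for sid, seq in records:
            if len(seq) != length:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - VALID_RESIDUES
            if bad:
                raise AlignmentError(f"sequence {sid!r} has invalid residues {bad}")
            if sid in ids:
                raise AlignmentError(f"duplicate sample_id {sid!r}")
            ids.add(sid)
        self.records = records
        self.length = length

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def matrix(self) -> np.ndarray:
        """Return the alignment as an (n, length) array of single characters."""
        return np.array([list(seq) for _, seq in self.records], dtype="U1")

    def __eq__(self, other):
        return isinstance(other, HaplotypeAlignment) and self.records == other.records

    def __repr__(self):
        return f"HaplotypeAlignment(n={self.n}, length={self.length})"


def read_fasta_alignment(path) -> HaplotypeAlignment:
    """Read a FASTA file as a haplotype alignment (file order preserved)."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return HaplotypeAlignment(records)


def write_fasta_alignment(alignment: HaplotypeAlignment, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in alignment.records
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# SNP panels
# ---------------------------------------------------------------------------


@dataclass
class SNPPanel:
    """Per-locus biallelic allele counts for one or more populations.

    ``x`` holds the focal-allele count (global minor allele unless the
    generator polarized otherwise) and ``n`` the total number of called
    alleles, both indexed by locus with one column per population.
    ``max_n`` is the number of allele calls possible per population when
    nothing is missing; it drives the presence filter.
    """

    x: pd.DataFrame
    n: pd.DataFrame
    max_n: pd.Series | None = None
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD

    def __post_init__(self):
        if list(self.x.columns) != list(self.n.columns):
            raise ValueError("x and n must have identical population columns")
        if not self.x.index.equals(self.n.index):
            raise ValueError("x and n must have identical locus indices")
        if self.x.index.has_duplicates:
            raise ValueError("duplicate locus ids")
        if ((self.x.values < 0) | (self.x.values > self.n.values)).any():
            raise ValueError("require 0 <= x <= n at every (locus, population)")

    @property
    def populations(self) -> list[str]:
        return list(self.x.columns)

    @property
    def loci(self) -> list:
        return list(self.x.index)

    @property
    def n_loci(self) -> int:
        return len(self.x.index)

    def freq(self) -> pd.DataFrame:
        """Allele frequencies x/n; NaN where a population has no calls."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.x.values / self.n.values
        return pd.DataFrame(f, index=self.x.index, columns=self.x.columns)

    def filter_presence(self, threshold: float | None = None) -> "SNPPanel":
        """Drop loci genotyped in less than ``threshold`` of possible calls.

        Requires ``max_n``.  Idempotent: filtering a filtered panel changes
        nothing.
        """
        if threshold is None:
            threshold = self.presence_threshold
        if self.max_n is None:
            raise ValueError("presence filtering needs max_n (calls when complete)")
        total_possible = float(self.max_n.sum())
        frac = self.n.sum(axis=1) / total_possible
        keep = frac >= threshold
        return SNPPanel(
            self.x.loc[keep].copy(),
            self.n.loc[keep].copy(),
            self.max_n,
            threshold,
        )


def read_structure_genotypes(
    path,
    ploidy: int = 2,
    rows_per_individual: str | int = "auto",
    has_pop_column: bool = True,
    header: bool = False,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    apply_presence_filter: bool = True,
) -> SNPPanel:
    """Read a STRUCTURE-format genotype matrix into a :class:`SNPPanel`.

    The dialect is whitespace-delimited with one or two rows per individual
    (two-row files carry one allele row per chromosome set), first column
    the sample id, optionally a second column with an integer/str
    population label, then genotype codes; missing data are ``-9``.
    Columns beyond id/population before the genotypes are not supported.

    With ``rows_per_individual="auto"`` the layout is inferred: repeated
    consecutive sample ids mean two-row.

    Counts: per locus the *global minor* allele over the pooled sample is
    counted as ``x``; missing calls are excluded from both ``x`` and ``n``.
    Loci genotyped in fewer than ``presence_threshold`` of possible allele
    calls are dropped (disable with ``apply_presence_filter=False``).
    """
    lines = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            if raw.strip():
                lines.append(raw.split())
    if header and lines:
        lines = lines[1:]
    if not lines:
        raise FormatError(f"{path}: empty STRUCTURE file")

    widths = {len(row) for row in lines}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")

    if rows_per_individual == "auto":
        two_row = any(
            lines[i][0] == lines[i + 1][0] for i in range(0, len(lines) - 1, 2)
        ) and len(lines) % 2 == 0
        rows_per_individual = 2 if two_row else 1
    rows_per_individual = int(rows_per_individual)
    if rows_per_individual not in (1, 2):
        raise ValueError("rows_per_individual must be 1, 2 or 'auto'")

    meta_cols = 2 if has_pop_column else 1
    geno_width = widths.pop() - meta_cols
    if geno_width <= 0:
        raise FormatError(f"{path}: no genotype columns")

    if rows_per_individual == 1:
        if geno_width % ploidy:
            raise FormatError(
                f"{path}: {geno_width} genotype columns not divisible by ploidy {ploidy}"
            )
        n_loci = geno_width // ploidy
    else:
        if len(lines) % 2:
            raise FormatError(f"{path}: odd row count for a two-row file")
        n_loci = geno_width

    def parse_codes(tokens):
        try:
            return [int(t) for t in tokens]
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer allele code: {exc}") from None

    individuals = []  # (sample_id, pop, array (ploidy, n_loci))
    if rows_per_individual == 1:
        for row in lines:
            sid = row[0]
            pop = row[1] if has_pop_column else "pop1"
            codes = np.array(parse_codes(row[meta_cols:]), dtype=int)
            geno = codes.reshape(n_loci, ploidy).T
            individuals.append((sid, pop, geno))
    else:
        for i in range(0, len(lines), 2):
            r1, r2 = lines[i], lines[i + 1]
            if r1[0] != r2[0]:
                raise FormatError(
                    f"{path}: two-row file but rows {i} and {i+1} have different ids"
                )
            sid = r1[0]
            pop = r1[1] if has_pop_column else "pop1"
            geno = np.array(
                [parse_codes(r1[meta_cols:]), parse_codes(r2[meta_cols:])], dtype=int
            )
            individuals.append((sid, pop, geno))

    pops = sorted({pop for _, pop, _ in individuals}, key=str)
    all_geno = np.stack([g for _, _, g in individuals])  # (n_ind, ploidy, n_loci)
    pop_of = np.array([pop for _, pop, _ in individuals])

    # global minor allele per locus over pooled, non-missing calls
    loci = [f"locus_{j+1}" for j in range(n_loci)]
    x = np.zeros((n_loci, len(pops)), dtype=int)
    n = np.zeros((n_loci, len(pops)), dtype=int)
    flat = all_geno.reshape(-1, n_loci)  # (n_ind*ploidy, n_loci)
    for j in range(n_loci):
        calls = flat[:, j]
        observed = calls[calls != MISSING_CODE]
        alleles, counts = np.unique(observed, return_counts=True)
        if len(alleles) > 2:
            raise FormatError(f"{path}: locus {loci[j]} has >2 alleles: {alleles}")
        if len(alleles) == 0:
            minor = None
        elif len(alleles) == 1:
            minor = None  # monomorphic: x stays 0
        else:
            order = np.lexsort((alleles, counts))  # least frequent, ties by code
            minor = alleles[order[0]]
        for k, pop in enumerate(pops):
            sel = all_geno[pop_of == pop, :, j].ravel()
            obs = sel[sel != MISSING_CODE]
            n[j, k] = len(obs)
            if minor is not None:
                x[j, k] = int((obs == minor).sum())

    max_n = pd.Series(
        {pop: int((pop_of == pop).sum()) * ploidy for pop in pops}, name="max_n"
    )
    panel = SNPPanel(
        pd.DataFrame(x, index=loci, columns=pops),
        pd.DataFrame(n, index=loci, columns=pops),
        max_n,
        presence_threshold,
    )
    if apply_presence_filter:
        panel = panel.filter_presence()
    return panel


def read_frequency_table(path) -> SNPPanel:
    """Read a long-format TSV (locus_id, pop, x, n) into a :class:`SNPPanel`."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus_id", "pop", "x", "n"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    x = df.pivot(index="locus_id", columns="pop", values="x")
    n = df.pivot(index="locus_id", columns="pop", values="n")
    if x.isna().any().any():
        raise FormatError(f"{path}: incomplete locus x population table")
    return SNPPanel(x.astype(int), n.astype(int))


def write_frequency_table(panel: SNPPanel, path) -> None:
    rows = []
    for locus in panel.loci:
        for pop in panel.populations:
            rows.append(
                {
                    "locus_id": locus,
                    "pop": pop,
                    "x": int(panel.x.loc[locus, pop]),
                    "n": int(panel.n.loc[locus, pop]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path, split: float = DEFAULT_SPLIT_LATITUDE) -> list[SampleRecord]:
    """Read a metadata TSV (sample_id, species, latitude[, longitude]).

    Groups are assigned from latitude via the split parallel.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "species", "latitude"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    out = []
    for _, row in df.iterrows():
        lon = float(row["longitude"]) if "longitude" in df.columns and pd.notna(row.get("longitude")) else None
        out.append(
            SampleRecord(
                str(row["sample_id"]), str(row["species"]), float(row["latitude"]), lon
            ).with_group(split)
        )
    return out


# ---------------------------------------------------------------------------
# Dated allele-frequency series
# ---------------------------------------------------------------------------


@dataclass
class DatedFrequencySeries:
    """Dated binomial observations (years BP, successes x, samples n) of one allele.

    Stored oldest first (dates strictly decreasing in BP, i.e. forward in
    time).  ``latitudes`` is optional and parallel to the observations.
    """

    dates_bp: np.ndarray
    x: np.ndarray
    n: np.ndarray
    latitudes: np.ndarray | None = None
    allele: str = "allele"

    def __post_init__(self):
        self.dates_bp = np.asarray(self.dates_bp, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if len(self.dates_bp) < 2:
            raise InsufficientDataError("a dated series needs at least 2 observations")
        if ((self.x < 0) | (self.x > self.n)).any():
            raise ValueError("require 0 <= x <= n at every observation")
        order = np.argsort(-self.dates_bp, kind="stable")
        self.dates_bp = self.dates_bp[order]
        self.x = self.x[order]
        self.n = self.n[order]
        if self.latitudes is not None:
            self.latitudes = np.asarray(self.latitudes, dtype=float)[order]
        if len(np.unique(self.dates_bp)) != len(self.dates_bp):
            raise ValueError("dates must be distinct")

    @property
    def freq(self) -> np.ndarray:
        return self.x / self.n

    def __len__(self):
        return len(self.dates_bp)


def read_dated_frequencies(path) -> DatedFrequencySeries:
    """Read a dated-frequency TSV.

    The date column must be named ``date_bp`` (years before 1950) or
    ``date_ce`` (calendar years, converted as BP = 1950 - year); the other
    required columns are ``x`` and ``n``, with optional ``latitude``.
    """
    df = pd.read_csv(path, sep="\t")
    if "date_bp" in df.columns:
        dates = df["date_bp"].astype(float).values
    elif "date_ce" in df.columns:
        dates = 1950.0 - df["date_ce"].astype(float).values
    else:
        raise FormatError(f"{path}: need a 'date_bp' or 'date_ce' column")
    if not {"x", "n"} <= set(df.columns):
        raise FormatError(f"{path}: need 'x' and 'n' columns")
    lat = df["latitude"].astype(float).values if "latitude" in df.columns else None
    return DatedFrequencySeries(dates, df["x"].values, df["n"].values, lat)


def write_dated_frequencies(series: DatedFrequencySeries, path) -> None:
    df = pd.DataFrame(
        {"date_bp": series.dates_bp, "x": series.x.astype(int), "n": series.n.astype(int)}
    )
    if series.latitudes is not None:
        df["latitude"] = series.latitudes
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS: dict[str, object] = {
    "split_latitude": DEFAULT_SPLIT_LATITUDE,  # parallel separating north/south
    "presence_threshold": DEFAULT_PRESENCE_THRESHOLD,  # min fraction of called alleles
    "he_min": 0.10,  # minimum pooled expected heterozygosity for the outlier scan
    "trim": 0.05,  # symmetric trim fraction for the F_ST null fit
    "n_bins": 10,  # diagonal bins for the 2D spectrum fit
    "delta_f_thresholds": [0.5, 0.4, 0.3],
    "n_resamples": 100000,  # subsets drawn for the gene-flow null
    "draws": 10000,  # Monte-Carlo draws for selection bounds
    "generation_time": 1.0,  # years per generation (flax is annual)
    "inbreeding_f": 0.9,
    "dominance": "dominant",
    "seed": 0,
    "out": None,
}


@dataclass
class RunConfig:
    """Key-value run settings with documented defaults; unknown keys rejected."""

    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.settings) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_CONFIG_DEFAULTS)
        merged.update(self.settings)
        self.settings = merged

    def __getitem__(self, key):
        return self.settings[key]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls(data)

    @classmethod
    def defaults(cls) -> "RunConfig":
        return cls({})
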