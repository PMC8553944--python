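"""Core in-memory containers shared across the pipeline arms.

Genotypes are held as an integer matrix of minor-allele dosages (0/1/2, -1
for missing) with per-locus and per-individual metadata; OTU tables as a
pandas counts frame (rows = OTUs, columns = samples) plus sample metadata
and a pairwise-similarity match list; SST fields as xarray DataArrays with
a monthly time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from ._utils import MISSING


@dataclass
class FilterReport:
    """Record of one quality-control stage."""

    stage: str
    loci_before: int
    loci_after: int
    individuals_before: int
    individuals_after: int
    missing_fraction_after: float
    removed_loci: list = field(default_factory=list)
    removed_individuals: list = field(default_factory=list)
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.loci_after > self.loci_before:
            raise ValueError("loci_after exceeds loci_before")
        if self.individuals_after > self.individuals_before:
            raise ValueError("individuals_after exceeds individuals_before")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "loci_before": self.loci_before,
            "loci_after": self.loci_after,
            "individuals_before": self.individuals_before,
            "individuals_after": self.individuals_after,
            "missing_fraction_after": self.missing_fraction_after,
            "removed_loci": list(map(str, self.removed_loci)),
            "removed_individuals": list(map(str, self.removed_individuals)),
            "detail": self.detail,
        }


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, coded as minor-allele dosage.

    ``calls`` is int8 with values {0, 1, 2} and -1 for missing.  ``sites``
    assigns each individual to a sampling site (the unit of population
    structure downstream).  ``locus_meta`` carries per-locus mean coverage;
    heterozygosity and allele frequency are recomputed on demand so they
    stay in sync with filtering.
    """

    calls: np.ndarray
    locus_ids: np.ndarray
    individual_ids: np.ndarray
    sites: np.ndarray
    locus_meta: pd.DataFrame = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.sites = np.asarray(self.sites, dtype=object)
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype calls must be in {0, 1, 2, missing}")
        if self.calls.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError("calls shape does not match id vectors")
        if len(self.sites) != len(self.individual_ids):
            raise ValueError("one site label per individual required")
        if self.locus_meta is None:
            self.locus_meta = pd.DataFrame(index=pd.Index(self.locus_ids, name="locus"))
        if "coverage" not in self.locus_meta.columns:
            self.locus_meta = self.locus_meta.assign(coverage=np.nan)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def locus_call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=1)

    def missing_fraction(self) -> float:
        return float(1.0 - self.observed().mean()) if self.calls.size else 0.0

    def allele_freq(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Minor-allele frequency per locus over ``mask``-ed individuals."""
        calls = self.calls if mask is None else self.calls[mask]
        obs = calls != MISSING
        n = obs.sum(axis=0)
        dose = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose / (2.0 * n), np.nan)

    def het_obs(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Observed heterozygote fraction per locus."""
        calls = self.calls if mask is None else self.calls[mask]
        obs = calls != MISSING
        n = obs.sum(axis=0)
        het = (calls == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    def site_masks(self) -> dict:
        """Ordered mapping site label -> boolean individual mask."""
        return {s: self.sites == s for s in pd.unique(self.sites)}

    def subset(self, ind_mask=None, locus_mask=None) -> "GenotypeMatrix":
        ind_mask = np.ones(self.n_individuals, bool) if ind_mask is None else np.asarray(ind_mask)
        locus_mask = np.ones(self.n_loci, bool) if locus_mask is None else np.asarray(locus_mask)
        return GenotypeMatrix(
            calls=self.calls[np.ix_(ind_mask, locus_mask)],
            locus_ids=self.locus_ids[locus_mask],
            individual_ids=self.individual_ids[ind_mask],
            sites=self.sites[ind_mask],
            locus_meta=self.locus_meta.loc[locus_mask].copy(),
            provenance=list(self.provenance),
        )


@dataclass
class OutlierScanResult:
    """Neutral/outlier partition from the trimmed chi-square scan."""

    locus_ids: np.ndarray
    fst: np.ndarray
    fst_no_corr: np.ndarray
    het: np.ndarray
    df_inferred: float
    fst_bar: float
    pvalues: np.ndarray
    qvalues: np.ndarray
    neutral_ids: np.ndarray
    outlier_ids: np.ndarray
    excluded_low_het_ids: np.ndarray

    def __post_init__(self):
        tested = set(self.neutral_ids) | set(self.outlier_ids)
        if tested != set(self.locus_ids) - set(self.excluded_low_het_ids):
            raise ValueError("neutral and outlier sets must partition tested loci")


@dataclass
class PairwiseStatMatrix:
    """Symmetric per-site-pair differentiation statistics."""

    statistic: str
    sites: list
    estimates: np.ndarray
    ci_lo: np.ndarray = None
    ci_hi: np.ndarray = None
    pvalues: np.ndarray = None
    pvalues_adj: np.ndarray = None
    adjust_method: str = ""
    shift_constant: float = 0.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.estimates = np.asarray(self.estimates, float)
        k = len(self.sites)
        if self.estimates.shape != (k, k):
            raise ValueError("estimates must be square over sites")
        if not np.allclose(self.estimates, self.estimates.T, equal_nan=True):
            raise ValueError("estimates must be symmetric")

    def to_long(self) -> pd.DataFrame:
        rows = []
        k = len(self.sites)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "site_a": self.sites[i],
                        "site_b": self.sites[j],
                        "statistic": self.statistic,
                        "estimate": self.estimates[i, j],
                        "ci_lo": None if self.ci_lo is None else self.ci_lo[i, j],
                        "ci_hi": None if self.ci_hi is None else self.ci_hi[i, j],
                        "p": None if self.pvalues is None else self.pvalues[i, j],
                        "p_adj": None if self.pvalues_adj is None else self.pvalues_adj[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class MigrationNetwork:
    """Directed relative-migration rates on [0, 1].

    ``rates[i, j]`` is the relative migration from ``sites[i]`` into
    ``sites[j]``; the diagonal is NaN.  After normalization the maximum
    off-diagonal entry equals 1 whenever any rate is positive.
    """

    sites: list
    rates: np.ndarray
    basis: str
    n_boot: int = 0
    significant_asymmetry: np.ndarray = None
    asym_ci_lo: np.ndarray = None
    asym_ci_hi: np.ndarray = None

    def __post_init__(self):
        self.rates = np.asarray(self.rates, float)
        k = len(self.sites)
        if self.rates.shape != (k, k):
            raise ValueError("rates must be square over sites")

    def to_long(self) -> pd.DataFrame:
        rows = []
        k = len(self.sites)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append(
                    {
                        "source": self.sites[i],
                        "receiving": self.sites[j],
                        "relative_migration": self.rates[i, j],
                        "significant_asymmetry": None
                        if self.significant_asymmetry is None
                        else bool(self.significant_asymmetry[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class OTUTable:
    """OTU read counts with sample metadata and a similarity match list.

    ``counts``: DataFrame, rows = OTU ids, columns = sample ids.
    ``sample_meta``: DataFrame indexed by sample id with ``group`` and
    ``is_control`` columns.  ``match_list``: DataFrame with columns
    (otu_a, otu_b, pct_identity); similarity is treated as symmetric.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    match_list: pd.DataFrame = None
    otu_meta: pd.DataFrame = None
    log: list = field(default_factory=list)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if "is_control" not in self.sample_meta.columns:
            self.sample_meta = self.sample_meta.assign(is_control=False)
        if self.match_list is None:
            self.match_list = pd.DataFrame(columns=["otu_a", "otu_b", "pct_identity"])

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def control_samples(self) -> list:
        meta = self.sample_meta.loc[self.counts.columns]
        return list(meta.index[meta["is_control"].astype(bool)])

    def biological_samples(self) -> list:
        meta = self.sample_meta.loc[self.counts.columns]
        return list(meta.index[~meta["is_control"].astype(bool)])

    def groups(self) -> pd.Series:
        """Group label per biological sample."""
        return self.sample_meta.loc[self.biological_samples(), "group"]

    def copy_with(self, counts=None, **kw) -> "OTUTable":
        return OTUTable(
            counts=self.counts.copy() if counts is None else counts,
            sample_meta=self.sample_meta.copy(),
            match_list=self.match_list.copy(),
            otu_meta=None if self.otu_meta is None else self.otu_meta.copy(),
            log=list(self.log) + list(kw.pop("extra_log", [])),
        )


@dataclass
class SSTGrid:
    """Monthly sea-surface temperature field with provenance labels."""

    data: xr.DataArray  # dims (time, lat, lon), degrees C
    provenance: str = "observed"  # "observed" or a model name
    scenario: str = "observed"  # observed | historical_GHG | RCP4.5 | RCP8.5

    def __post_init__(self):
        if tuple(self.data.dims) != ("time", "lat", "lon"):
            raise ValueError("SST data must have dims (time, lat, lon)")
        t = pd.DatetimeIndex(self.data.time.values)
        steps = (t.year[1:] - t.year[:-1]) * 12 + (t.month[1:] - t.month[:-1])
        if len(t) > 1 and not (steps == 1).all():
            raise ValueError("time axis must be strictly monthly and contiguous")
        finite = self.data.values[np.isfinite(self.data.values)]
        if finite.size and (finite.min() < -5 or finite.max() > 45):
            raise ValueError("temperatures outside physical bounds (-5, 45) C")

    @property
    def years(self) -> tuple:
        t = pd.DatetimeIndex(self.data.time.values)
        return int(t.year.min()), int(t.year.max())
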