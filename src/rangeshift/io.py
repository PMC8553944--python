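"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as a CSV trio (calls with 0/1/2/NA, locus metadata,
site assignments); OTU tables as tab-separated counts in the USEARCH
otutab dialect plus a sample-metadata CSV and a 3-column match list;
SST fields as NetCDF with dims (time, lat, lon).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from ._utils import MISSING
from .datatypes import GenotypeMatrix, MigrationNetwork, OTUTable, PairwiseStatMatrix, SSTGrid


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, outdir, prefix: str = "genotypes") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls = pd.DataFrame(
        g.calls.astype(float), index=g.individual_ids, columns=g.locus_ids
    ).replace(MISSING, np.nan)
    paths = {
        "calls": outdir / f"{prefix}.csv",
        "loci": outdir / f"{prefix}_loci.csv",
        "sites": outdir / f"{prefix}_sites.csv",
    }
    calls.to_csv(paths["calls"], float_format="%.0f")
    meta = g.locus_meta.copy()
    meta["het_obs"] = g.het_obs()
    p = g.allele_freq()
    meta["maf"] = np.fmin(p, 1 - p)
    meta.to_csv(paths["loci"])
    pd.DataFrame({"individual": g.individual_ids, "site": g.sites}).to_csv(
        paths["sites"], index=False
    )
    return paths


def read_genotypes(calls_csv, loci_csv=None, sites_csv=None) -> GenotypeMatrix:
    calls = pd.read_csv(calls_csv, index_col=0)
    mat = calls.to_numpy(float)
    mat = np.where(np.isnan(mat), MISSING, mat).astype(np.int8)
    locus_meta = None
    if loci_csv is not None:
        locus_meta = pd.read_csv(loci_csv, index_col=0)
        locus_meta = locus_meta.loc[calls.columns]
    if sites_csv is not None:
        s = pd.read_csv(sites_csv).set_index("individual")["site"]
        sites = s.loc[calls.index].to_numpy(object)
    else:
        sites = np.array(["all"] * len(calls), dtype=object)
    return GenotypeMatrix(
        calls=mat,
        locus_ids=calls.columns.to_numpy(object),
        individual_ids=calls.index.to_numpy(object),
        sites=sites,
        locus_meta=locus_meta,
    )


def read_vcf(path, sites: dict | None = None) -> GenotypeMatrix:
    """Import biallelic sites from a VCF, mapping GT to minor-allele
    dosage.  ``sites`` maps sample name -> site label."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=np.int8)
        dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING).astype(np.int8)
        rows.append(dose)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    calls = np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    site_labels = np.array(
        [sites.get(s, "all") if sites else "all" for s in samples], dtype=object
    )
    return GenotypeMatrix(
        calls=calls,
        locus_ids=np.array(ids, dtype=object),
        individual_ids=np.array(samples, dtype=object),
        sites=site_labels,
    )


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

def write_otu_table(t: OTUTable, outdir, prefix: str = "otus") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}.tsv",
        "samples": outdir / f"{prefix}_samples.csv",
        "matches": outdir / f"{prefix}_matchlist.tsv",
    }
    counts = t.counts.copy()
    counts.index.name = "#OTU ID"
    counts.to_csv(paths["counts"], sep="\t")
    t.sample_meta.to_csv(paths["samples"])
    t.match_list.to_csv(paths["matches"], sep="\t", index=False, header=False)
    return paths


def read_otu_table(counts_tsv, samples_csv=None, matchlist_tsv=None) -> OTUTable:
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    if samples_csv is not None:
        meta = pd.read_csv(samples_csv, index_col=0)
    else:
        meta = pd.DataFrame(
            {"group": "all", "is_control": False}, index=counts.columns
        )
    match = None
    if matchlist_tsv is not None:
        match = pd.read_csv(
            matchlist_tsv, sep="\t", header=None,
            names=["otu_a", "otu_b", "pct_identity"],
        )
    return OTUTable(counts=counts, sample_meta=meta, match_list=match)


# ---------------------------------------------------------------------------
# pairwise matrices / networks / distances
# ---------------------------------------------------------------------------

def write_stat_matrix(m: PairwiseStatMatrix, path) -> None:
    m.to_long().to_csv(path, index=False)


def read_distance_matrix(path) -> pd.DataFrame:
    d = pd.read_csv(path, index_col=0)
    d.columns = d.columns.astype(str)
    d.index = d.index.astype(str)
    return d


def write_network(net: MigrationNetwork, csv_path=None, json_path=None) -> None:
    long = net.to_long()
    if csv_path is not None:
        long.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "basis": net.basis,
            "n_boot": net.n_boot,
            "nodes": list(map(str, net.sites)),
            "edges": [
                {
                    "source": str(r["source"]),
                    "receiving": str(r["receiving"]),
                    "weight": None if pd.isna(r["relative_migration"]) else float(r["relative_migration"]),
                    "significant_asymmetry": r["significant_asymmetry"],
                }
                for _, r in long.iterrows()
            ],
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# SST
# ---------------------------------------------------------------------------

def write_sst(g: SSTGrid, path) -> None:
    ds = g.data.to_dataset(name="sst")
    ds["sst"].attrs.update(
        {"units": "degC", "standard_name": "sea_surface_temperature"}
    )
    ds.attrs.update({"provenance": g.provenance, "scenario": g.scenario})
    ds.to_netcdf(path, engine="scipy")


def read_sst(path) -> SSTGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds["sst"].load()
    return SSTGrid(
        data=da,
        provenance=ds.attrs.get("provenance", "observed"),
        scenario=ds.attrs.get("scenario", "observed"),
    )
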