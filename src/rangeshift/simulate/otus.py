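"""Dietary OTU-table simulation with planted curation ground truth.

Each sample's read counts are Dirichlet-multinomial draws from a
group-specific composition.  On top of the core community the generator
plants, with exact bookkeeping:

* indicator OTUs present only (and abundantly) in a configured group
  combination — ground truth for indicator-species analysis;
* parent-daughter error pairs: the daughter's counts are a fixed fraction
  of its parent's in every sample, with a high-identity match-list entry,
  so curation must merge exactly these;
* decoy pairs: similar by identity but occupying disjoint sample sets, so
  co-occurrence-based curation must never merge them;
* control contaminants: OTUs that receive >= 2 reads in every extraction/
  PCR control sample;
* low-read OTUs whose table-wide total stays below the minimum-read
  threshold.

The returned table carries the truth as ``.truth``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._utils import sub_rng
from ..datatypes import OTUTable


@dataclass
class OTUSimSpec:
    groups: list = field(default_factory=lambda: ["tropical_A", "tropical_B", "temperate"])
    n_samples_per_group: int = 8
    n_otus: int = 200
    indicator_map: dict = field(default_factory=dict)  # otu_id -> tuple of groups
    n_daughter_errors: int = 0
    control_contaminant_ids: list | int = 0
    n_controls: int = 2
    n_decoy_pairs: int = 0
    n_low_read_otus: int = 0
    read_depth_range: tuple = (35000, 60000)
    concentration: float = 150.0
    daughter_ratio_range: tuple = (0.05, 0.2)
    seed: int | None = None

    def __post_init__(self):
        if self.n_daughter_errors > self.n_otus:
            raise ValueError("n_daughter_errors cannot exceed n_otus")
        for otu, combo in self.indicator_map.items():
            if not combo:
                raise ValueError(f"indicator {otu} maps to an empty group combination")
            unknown = set(combo) - set(self.groups)
            if unknown:
                raise ValueError(f"indicator {otu} references unknown groups {unknown}")


def _otu_id(i: int) -> str:
    return f"OTU_{i + 1:05d}"


def simulate_otu_table(spec: OTUSimSpec) -> OTUTable:
    rng = sub_rng(spec.seed, "otus")
    n_base = spec.n_otus - spec.n_daughter_errors
    if n_base < 1:
        raise ValueError("no base OTUs left after daughters")
    base_ids = [_otu_id(i) for i in range(n_base)]
    daughter_ids = [_otu_id(n_base + i) for i in range(spec.n_daughter_errors)]
    all_ids = base_ids + daughter_ids

    # --- role assignment over base OTUs ------------------------------------
    indicator_ids = list(spec.indicator_map)
    unknown = set(indicator_ids) - set(base_ids)
    if unknown:
        raise ValueError(f"indicator ids outside the base OTU range: {sorted(unknown)}")
    reserved = set(indicator_ids)

    def take(k: int) -> list:
        picked = [o for o in reversed(base_ids) if o not in reserved][:k]
        if len(picked) < k:
            raise ValueError("not enough base OTUs for the requested roles")
        reserved.update(picked)
        return picked

    low_read = take(spec.n_low_read_otus)
    if isinstance(spec.control_contaminant_ids, int):
        contaminants = take(spec.control_contaminant_ids)
    else:
        contaminants = list(spec.control_contaminant_ids)
        reserved.update(contaminants)
    decoys = [tuple(take(2)) for _ in range(spec.n_decoy_pairs)]

    # --- composition weights ------------------------------------------------
    w = rng.lognormal(0.0, 1.0, n_base)
    w_series = pd.Series(w, index=base_ids)
    w_series[low_read] = 0.0  # planted directly, outside the composition
    mean_w = float(w_series[w_series > 0].mean())
    for otu in indicator_ids:
        w_series[otu] = mean_w * rng.uniform(15, 30)
    for a, b in decoys:
        w_series[b] = w_series[a]  # equal abundance by construction

    # parents must be reliably abundant in every sample
    candidates = [
        o for o in base_ids
        if o not in reserved and w_series[o] >= np.quantile(w_series[w_series > 0], 0.75)
    ]
    if spec.n_daughter_errors and not candidates:
        raise ValueError("no eligible parent OTUs for daughters")
    parents = (
        list(rng.choice(candidates, spec.n_daughter_errors, replace=True))
        if spec.n_daughter_errors
        else []
    )
    ratios = rng.uniform(*spec.daughter_ratio_range, spec.n_daughter_errors)

    # --- per-sample draws ---------------------------------------------------
    samples, groups_col, is_control = [], [], []
    counts = {}
    for gname in spec.groups:
        for s in range(spec.n_samples_per_group):
            sid = f"{gname}_s{s + 1:02d}"
            samples.append(sid)
            groups_col.append(gname)
            is_control.append(False)
            wg = w_series.copy()
            for otu, combo in spec.indicator_map.items():
                if gname not in combo:
                    wg[otu] = 0.0
            alpha = wg.to_numpy() * spec.concentration / max(wg.sum(), 1e-12)
            gam = rng.gamma(np.maximum(alpha, 0.0))
            theta = gam / gam.sum()
            depth = int(rng.integers(spec.read_depth_range[0], spec.read_depth_range[1] + 1))
            counts[sid] = rng.multinomial(depth, theta)
    mat = pd.DataFrame(counts, index=base_ids)

    # guarantee indicator presence throughout its combination
    for otu, combo in spec.indicator_map.items():
        for sid, gname in zip(samples, groups_col):
            if gname in combo and mat.at[otu, sid] == 0:
                mat.at[otu, sid] = 5

    # decoys occupy disjoint halves of the sample set
    half = len(samples) // 2
    for a, b in decoys:
        mat.loc[a, samples[half:]] = 0
        mat.loc[b, samples[:half]] = 0

    # low-read OTUs: a handful of reads, total < 10
    for otu in low_read:
        total = int(rng.integers(1, 10))
        picks = rng.choice(len(samples), size=min(total, 3), replace=False)
        alloc = rng.multinomial(total, np.full(len(picks), 1 / len(picks)))
        for jx, c in zip(picks, alloc):
            mat.at[otu, samples[jx]] = int(c)

    # daughters mirror their parents at a fixed sub-unit ratio
    match_rows = []
    merges = {}
    for did, pid, ratio in zip(daughter_ids, parents, ratios):
        prow = mat.loc[pid].to_numpy()
        # errors arise from abundant templates: seed the daughter only in
        # samples where the parent is solidly present, so co-occurrence
        # survives downstream subsampling
        child = np.where(prow >= 20, np.floor(prow * ratio), 0).astype(int)
        if child.sum() == 0 and prow.max() >= 2:
            child[int(prow.argmax())] = 1  # keep the error OTU observable
        mat.loc[did] = child
        merges[did] = pid
        match_rows.append((did, pid, float(rng.uniform(93.0, 99.8))))
    for a, b in decoys:
        match_rows.append((a, b, float(rng.uniform(86.0, 95.0))))
    # sub-threshold similarities that curation must ignore
    free = [o for o in base_ids if o not in reserved]
    for _ in range(min(30, len(free) // 2)):
        a, b = rng.choice(free, 2, replace=False)
        match_rows.append((a, b, float(rng.uniform(60.0, 80.0))))

    mat = mat.loc[all_ids]

    # controls: silent except for the planted contaminants
    control_ids = [f"control_{c + 1}" for c in range(spec.n_controls)]
    for cid in control_ids:
        col = pd.Series(0, index=mat.index)
        for otu in contaminants:
            col[otu] = 2 + int(rng.poisson(6))
        mat[cid] = col
        samples.append(cid)
        groups_col.append("control")
        is_control.append(True)

    table = OTUTable(
        counts=mat,
        sample_meta=pd.DataFrame(
            {"group": groups_col, "is_control": is_control},
            index=pd.Index(samples, name="sample"),
        ),
        match_list=pd.DataFrame(match_rows, columns=["otu_a", "otu_b", "pct_identity"]),
    )
    table.truth = {
        "merges": merges,
        "contaminants": contaminants,
        "low_read": low_read,
        "decoy_pairs": decoys,
        "indicator_map": dict(spec.indicator_map),
        "n_base": n_base,
    }
    return table
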