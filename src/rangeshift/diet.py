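"""Dietary OTU-table curation and community statistics.

Curation runs in a fixed, logged order: depth normalization (rarefaction
to a common read count), co-occurrence curation of erroneous daughter
OTUs, removal of OTUs detected in extraction/PCR controls, and a
minimum-total-read filter.  Community structure is then tested on
Bray-Curtis dissimilarities: nMDS ordination, PERMANOVA (location),
PERMDISP (dispersion), and indicator-species analysis over group
combinations with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._utils import adjust_pvalues, perm_pvalue, sub_rng
from .datatypes import OTUTable


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def normalize_depth(t: OTUTable, depth: int = 30000, seed: int | None = None) -> OTUTable:
    """Rarefy every biological sample to exactly ``depth`` reads by
    sampling without replacement (one draw per seed); samples below the
    depth are dropped with a warning.  Control samples pass unchanged."""
    rng = sub_rng(seed, "rarefy")
    counts = t.counts.copy()
    controls = set(t.control_samples())
    dropped = []
    for sid in t.biological_samples():
        col = counts[sid].to_numpy(np.int64)
        total = int(col.sum())
        if total < depth:
            dropped.append(sid)
        elif total > depth:
            counts[sid] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        warnings.warn(f"samples below depth {depth} dropped: {dropped}")
        counts = counts.drop(columns=dropped)
    if not [c for c in counts.columns if c not in controls]:
        raise ValueError("all biological samples fall below the normalization depth")
    out = t.copy_with(counts=counts)
    out.log.append({"stage": "normalize_depth", "depth": depth, "dropped_samples": dropped})
    return out


def lulu_curate(
    t: OTUTable,
    min_match: float = 84.0,
    min_cooccurrence: float = 0.95,
    min_ratio: float = 1.0,
    ratio_type: str = "min",
):
    """Merge likely erroneous daughter OTUs into abundant, similar,
    co-occurring parents (post-clustering curation).

    OTUs are ranked by decreasing total abundance; walking down the
    ranking, an OTU is merged into a retained higher-ranked OTU when (i)
    their match-list identity is >= ``min_match``, (ii) the fraction of
    the daughter's samples in which the parent is also present is >=
    ``min_cooccurrence``, and (iii) the parent/daughter abundance ratio
    over samples where both occur is >= ``min_ratio`` (``ratio_type``
    'min' or 'avg').  Merged counts are added to the parent.  Returns
    (curated table, merge log).  Candidate pairs without a similarity
    record are skipped.
    """
    counts = t.counts.copy()
    sim = {}
    for _, row in t.match_list.iterrows():
        a, b, pid = row["otu_a"], row["otu_b"], float(row["pct_identity"])
        sim[(a, b)] = max(pid, sim.get((a, b), 0.0))
        sim[(b, a)] = max(pid, sim.get((b, a), 0.0))

    totals = counts.sum(axis=1)
    order = totals.sort_values(ascending=False, kind="mergesort").index.tolist()
    retained = []
    merges = []
    merged_into = {}
    mat = counts.to_numpy(np.int64)
    row_of = {o: i for i, o in enumerate(counts.index)}
    for otu in order:
        d = mat[row_of[otu]]
        d_occ = d > 0
        n_occ = int(d_occ.sum())
        best = None
        for parent in retained:
            pid = sim.get((otu, parent))
            if pid is None or pid < min_match:
                continue
            p_row = mat[row_of[parent]]
            if n_occ == 0:
                continue
            both = d_occ & (p_row > 0)
            cooc = both.sum() / n_occ
            if cooc < min_cooccurrence:
                continue
            if both.any():
                ratios = p_row[both] / d[both]
                ratio = ratios.min() if ratio_type == "min" else ratios.mean()
            else:
                ratio = 0.0
            if ratio < min_ratio:
                continue
            cand = (cooc, totals[parent], parent)
            if best is None or cand[:2] > best[:2]:
                best = cand
        if best is None:
            retained.append(otu)
        else:
            parent = best[2]
            mat[row_of[parent]] += d
            merged_into[otu] = parent
            merges.append(
                {"daughter": otu, "parent": parent,
                 "pct_identity": sim[(otu, parent)], "cooccurrence": best[0]}
            )
    keep = [o for o in counts.index if o not in merged_into]
    curated = pd.DataFrame(mat, index=counts.index, columns=counts.columns).loc[keep]
    merge_log = pd.DataFrame(merges, columns=["daughter", "parent", "pct_identity", "cooccurrence"])
    out = t.copy_with(counts=curated)
    out.log.append({"stage": "lulu_curate", "n_merged": len(merges)})
    return out, merge_log


def remove_control_otus(t: OTUTable, min_control_reads: int = 2):
    """Remove OTUs reaching ``min_control_reads`` reads in any control
    sample, then drop the control samples themselves.  Returns
    (table, removed ids)."""
    controls = t.control_samples()
    if not controls:
        warnings.warn("no control samples: contamination filter is a no-op")
        return t.copy_with(), []
    flagged = t.counts[controls].max(axis=1) >= min_control_reads
    removed = list(t.counts.index[flagged])
    counts = t.counts.loc[~flagged].drop(columns=controls)
    out = t.copy_with(counts=counts)
    out.log.append({"stage": "remove_control_otus", "removed": removed})
    return out, removed


def min_read_filter(t: OTUTable, min_total: int = 10) -> OTUTable:
    """Drop OTUs whose table-wide read total is below ``min_total``."""
    keep = t.counts.sum(axis=1) >= min_total
    out = t.copy_with(counts=t.counts.loc[keep])
    out.log.append({"stage": "min_read_filter", "removed": int((~keep).sum())})
    return out


def curate(t: OTUTable, depth: int = 30000, seed: int | None = None, **kw):
    """Full curation cascade in the fixed order; returns
    (table, merge log, removed contaminant ids)."""
    t1 = normalize_depth(t, depth=depth, seed=seed)
    t2, merge_log = lulu_curate(
        t1, min_match=kw.get("min_match", 84.0),
        min_cooccurrence=kw.get("min_cooccurrence", 0.95),
        min_ratio=kw.get("min_ratio", 1.0),
    )
    t3, removed = remove_control_otus(t2, kw.get("min_control_reads", 2))
    t4 = min_read_filter(t3, kw.get("min_total", 10))
    return t4, merge_log, removed


# ---------------------------------------------------------------------------
# community statistics
# ---------------------------------------------------------------------------

def bray_curtis(t: OTUTable, use_relative: bool = True) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between biological samples, on relative
    abundances by default."""
    samples = t.biological_samples()
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    X = t.counts[samples].to_numpy(float).T
    if use_relative:
        totals = X.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("sample with zero reads")
        X = X / totals
    d = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(d, index=samples, columns=samples)


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    n_starts: int = 50,
    max_iter: int = 500,
    seed: int | None = None,
):
    """Non-metric MDS (Kruskal stress-1 with monotone regression and
    random restarts).  Returns (coordinates DataFrame, stress)."""
    from sklearn.manifold import MDS

    dm = np.asarray(d, float)
    n = dm.shape[0]
    if k >= n:
        raise ValueError("embedding dimension must be below the sample count")
    rs = None if seed is None else int(sub_rng(seed, "nmds").integers(0, 2**31 - 1))
    model = MDS(
        n_components=k, metric="precomputed", metric_mds=False,
        n_init=n_starts, max_iter=max_iter, random_state=rs,
        normalized_stress=True, eps=1e-9, init="random",
    )
    coords = model.fit_transform(dm)
    idx = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    cols = [f"nmds{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=idx, columns=cols), float(model.stress_)


@dataclass
class CommunityTestResult:
    test: str
    df: int
    pseudo_f: float
    r2: float | None
    p: float
    n_permutations: int
    seed: int | None = None


def _gower_center(dm: np.ndarray) -> np.ndarray:
    a = -0.5 * dm**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _group_codes(groups, index) -> tuple:
    s = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    if index is not None:
        s = s.loc[index]
    codes, uniques = pd.factorize(s.to_numpy())
    return codes, list(uniques)


def permanova(
    d: pd.DataFrame,
    groups,
    n_perm: int = 100000,
    seed: int | None = None,
) -> CommunityTestResult:
    """One-way PERMANOVA: pseudo-F from the Gower-centered distance
    matrix, R^2 = SS_between / SS_total, p by free permutation of sample
    labels."""
    dm = np.asarray(d, float)
    codes, uniques = _group_codes(groups, d.index if isinstance(d, pd.DataFrame) else None)
    n, k = len(codes), len(uniques)
    sizes = np.bincount(codes, minlength=k)
    if k < 2:
        raise ValueError("need at least two groups")
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")
    G = _gower_center(dm)
    ss_total = np.trace(G)
    f_den_df = n - k
    f_num_df = k - 1

    def pseudo_f(lab):
        Z = np.eye(k)[lab]
        sa = ((Z.T @ G @ Z).diagonal() / sizes).sum()
        return sa, (sa / f_num_df) / ((ss_total - sa) / f_den_df)

    sa_obs, f_obs = pseudo_f(codes)
    rng = sub_rng(seed, "permanova")
    n_ge = 0
    block = 512
    done = 0
    Z0 = np.eye(k)
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        Y = Z0[codes[perms]]  # (b, n, k)
        T = np.einsum("ij,bjg->big", G, Y)
        sa = (np.einsum("big,big->bg", Y, T) / sizes).sum(axis=1)
        f_perm = (sa / f_num_df) / ((ss_total - sa) / f_den_df)
        n_ge += int((f_perm >= f_obs - 1e-12).sum())
        done += b
    return CommunityTestResult(
        test="PERMANOVA", df=f_num_df, pseudo_f=float(f_obs),
        r2=float(sa_obs / ss_total), p=perm_pvalue(n_ge, n_perm),
        n_permutations=n_perm, seed=seed,
    )


def _pcoa(dm: np.ndarray):
    """Principal coordinates; returns (real-axis coords, imaginary-axis
    coords) from positive and negative eigenvalues respectively."""
    G = _gower_center(dm)
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-8 * max(abs(vals).max(), 1.0)
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def _spatial_median(x: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld algorithm for the geometric median."""
    c = x.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(x - c, axis=1)
        if (dist < tol).any():
            return c
        w = 1.0 / dist
        c_new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(c_new - c) < tol:
            return c_new
        c = c_new
    return c


def permdisp(
    d: pd.DataFrame,
    groups,
    n_perm: int = 100000,
    seed: int | None = None,
    center: str = "median",
) -> CommunityTestResult:
    """Homogeneity of multivariate dispersions (PERMDISP2).

    Samples are embedded by principal coordinates (negative eigenvalues
    kept as imaginary axes whose squared distances subtract); each
    sample's distance to its group center (spatial median by default,
    centroid optionally) is computed, and the one-way ANOVA F on those
    distances is tested by permuting them among groups.
    """
    dm = np.asarray(d, float)
    codes, uniques = _group_codes(groups, d.index if isinstance(d, pd.DataFrame) else None)
    n, k = len(codes), len(uniques)
    sizes = np.bincount(codes, minlength=k)
    if k < 2:
        raise ValueError("need at least two groups")
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")
    real, imag = _pcoa(dm)
    z = np.empty(n)
    for gidx in range(k):
        m = codes == gidx
        if center == "median":
            c_r = _spatial_median(real[m])
            c_i = imag[m].mean(axis=0) if imag.size else np.zeros(imag.shape[1])
        elif center == "centroid":
            c_r = real[m].mean(axis=0)
            c_i = imag[m].mean(axis=0) if imag.size else np.zeros(imag.shape[1])
        else:
            raise ValueError("center must be 'median' or 'centroid'")
        d2 = ((real[m] - c_r) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[m] - c_i) ** 2).sum(axis=1)
        z[m] = np.sqrt(np.maximum(d2, 0.0))

    Z0 = np.eye(k)[codes]  # (n, k) group indicator

    def anova_f(zz):
        # zz: (..., n); one-way ANOVA F on distances-to-center
        gsum = zz @ Z0
        gmean = gsum / sizes
        grand = zz.mean(axis=-1, keepdims=True)
        ssb = (sizes * (gmean - grand) ** 2).sum(axis=-1)
        sst = ((zz - grand) ** 2).sum(axis=-1)
        ssw = sst - ssb
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (ssb / (k - 1)) / (ssw / (n - k))
        return np.where(ssw == 0, np.where(ssb > 0, np.inf, 0.0), f)

    f_obs = float(anova_f(z[None, :])[0])
    rng = sub_rng(seed, "permdisp")
    n_ge = 0
    block = 2048
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        zp = z[np.argsort(rng.random((b, n)), axis=1)]
        n_ge += int((anova_f(zp) >= f_obs - 1e-12).sum())
        done += b
    return CommunityTestResult(
        test="PERMDISP", df=k - 1, pseudo_f=float(f_obs), r2=None,
        p=perm_pvalue(int(n_ge), n_perm), n_permutations=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# indicator species analysis
# ---------------------------------------------------------------------------

def _combos(k: int, combinations: bool):
    singles = [(i,) for i in range(k)]
    if not combinations:
        return singles
    out = []
    for size in range(1, k + 1):
        out.extend(itertools.combinations(range(k), size))
    return out


def _indval_stats(X, occ, codes, sizes, combos):
    """IndVal (group-size corrected) for every OTU x combination.

    Specificity uses group means so unequal group sizes do not bias it:
    A_C = sum of group-mean abundances within C over the total across
    groups.  Fidelity B_C is the occurrence fraction within C.
    """
    k = len(sizes)
    gm = np.stack([X[:, codes == gdx].mean(axis=1) for gdx in range(k)], axis=1)
    go = np.stack([occ[:, codes == gdx].sum(axis=1) for gdx in range(k)], axis=1)
    tot = gm.sum(axis=1)
    stats = np.zeros((X.shape[0], len(combos)))
    for ci, combo in enumerate(combos):
        sel = list(combo)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = gm[:, sel].sum(axis=1) / tot
        b = go[:, sel].sum(axis=1) / sizes[sel].sum()
        stats[:, ci] = np.sqrt(np.where(tot > 0, a, 0.0) * b)
    return stats


def indval(
    t: OTUTable,
    groups=None,
    combinations: bool = True,
    n_perm: int = 100000,
    adjust: str = "BH",
    seed: int | None = None,
) -> pd.DataFrame:
    """Indicator value analysis over group combinations.

    For each OTU the best-scoring combination of groups is reported with
    IndVal = sqrt(specificity * fidelity); the p-value is the permutation
    probability that the best combination's statistic is matched or
    exceeded when group labels are shuffled, adjusted across OTUs
    (Benjamini-Hochberg by default).  OTUs absent everywhere get
    statistic 0 and are flagged.
    """
    samples = t.biological_samples()
    if groups is None:
        groups = t.groups()
    codes, uniques = _group_codes(groups, pd.Index(samples))
    k = len(uniques)
    if k < 2:
        raise ValueError("need at least two groups")
    X = t.counts[samples].to_numpy(float)
    occ = X > 0
    sizes = np.bincount(codes, minlength=k)
    combos = _combos(k, combinations)
    stats = _indval_stats(X, occ, codes, sizes, combos)
    best_idx = stats.argmax(axis=1)
    best_stat = stats[np.arange(len(best_idx)), best_idx]
    absent = ~occ.any(axis=1)

    rng = sub_rng(seed, "indval")
    n_ge = np.zeros(X.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        s = _indval_stats(X, occ, perm, sizes, combos)
        n_ge += s[np.arange(len(best_idx)), best_idx] >= best_stat - 1e-12
    pvals = (n_ge + 1) / (n_perm + 1)
    pvals[absent] = np.nan
    padj = adjust_pvalues(pvals, adjust)
    out = pd.DataFrame(
        {
            "best_combination": [
                "+".join(str(uniques[gdx]) for gdx in combos[bi]) for bi in best_idx
            ],
            "indval": np.where(absent, 0.0, best_stat),
            "p": pvals,
            "p_adj": padj,
            "absent_everywhere": absent,
        },
        index=t.counts.index,
    )
    return out
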