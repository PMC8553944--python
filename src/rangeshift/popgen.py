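"""Diversity and differentiation statistics with resampling inference.

The differentiation workhorse is the Weir & Cockerham (1984) variance
component estimator: per biallelic locus the among-population (a),
among-individual (b) and within-individual (c) components are computed
from sample sizes, allele frequencies and heterozygote fractions, and the
multilocus estimate is the ratio of summed components sum(a)/sum(a+b+c).
Nei's G_st and Jost's D come from total and mean within-population
expected heterozygosities.  Confidence intervals bootstrap over loci;
pairwise p-values are the bootstrap probability that the estimate is <= 0,
adjusted across pairs with the Benjamini-Yekutieli FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._utils import MISSING, adjust_pvalues, perm_pvalue, sub_rng
from .datatypes import GenotypeMatrix, PairwiseStatMatrix


# ---------------------------------------------------------------------------
# per-population locus summaries
# ---------------------------------------------------------------------------

def pop_locus_stats(g: GenotypeMatrix, masks: dict):
    """Per population x locus: sample size, allele frequency, het fraction.

    Returns (sites, n, p, h) with arrays of shape (n_pops, n_loci); entries
    with no genotyped individuals are NaN (n = 0).
    """
    sites = list(masks)
    r, L = len(sites), g.n_loci
    n = np.zeros((r, L))
    p = np.full((r, L), np.nan)
    h = np.full((r, L), np.nan)
    for k, s in enumerate(sites):
        calls = g.calls[masks[s]]
        obs = calls != MISSING
        nk = obs.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, np.where(obs, calls, 0).sum(axis=0) / (2.0 * nk), np.nan)
            h[k] = np.where(nk > 0, (calls == 1).sum(axis=0) / np.maximum(nk, 1), np.nan)
    return sites, n, p, h


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray, corrected: bool = True):
    """Weir-Cockerham per-locus variance components (a, b, c).

    ``corrected=False`` drops the finite-sample corrections in a and b;
    that uncorrected form feeds the outlier-scan null fit, where the
    sampling inflation is absorbed by the inferred degrees of freedom.
    Loci where any population has no data are returned as NaN.
    """
    n = np.asarray(n, float)
    r = n.shape[0]
    valid = (n > 0).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n.mean(axis=0)
        n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        if corrected:
            a = n_bar / n_c * (s2 - (inner - h_bar / 4) / (n_bar - 1))
            b = n_bar / (n_bar - 1) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        else:
            a = n_bar / n_c * s2
            b = inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        c = h_bar / 2
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def wc_multilocus(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Multilocus theta as the ratio of summed components."""
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if not ok.any() or denom == 0:
        return np.nan
    return float(a[ok].sum() / denom)


def wc_fst_pair(g: GenotypeMatrix, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Multilocus Weir-Cockerham F_st between two individual masks."""
    sub = {"a": mask_a, "b": mask_b}
    _, n, p, h = pop_locus_stats(g, sub)
    return wc_multilocus(*wc_components(n, p, h))


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _rarefied_richness(minor: np.ndarray, total: np.ndarray, size: int) -> np.ndarray:
    """Expected allele count per locus when ``size`` gene copies are drawn.

    Exact hypergeometric form: each allele contributes
    1 - C(N - c, g) / C(N, g) where c is its copy count.
    """
    out = np.zeros(minor.shape)
    for c in (minor, total - minor):
        with np.errstate(invalid="ignore"):
            miss = np.where(
                total - c >= size,
                np.exp(_log_comb(total - c, size) - _log_comb(total, size)),
                0.0,
            )
        out += 1.0 - miss
    return out


def _diversity_point(calls: np.ndarray, raref_size: int):
    """(mean Ho, mean He, mean rarefied richness) for one population block."""
    obs = calls != MISSING
    n = obs.sum(axis=0)
    poly = n > 0
    dose = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dose / (2.0 * n)
        ho = (calls == 1).sum(axis=0) / n
    he = 2 * p * (1 - p)
    ar = _rarefied_richness(dose.astype(float), (2 * n).astype(float), raref_size)
    return (
        float(np.nanmean(np.where(poly, ho, np.nan))),
        float(np.nanmean(np.where(poly, he, np.nan))),
        float(np.nanmean(np.where(poly, ar, np.nan))),
    )


def diversity_stats(
    g: GenotypeMatrix,
    pops: dict | None = None,
    n_perm: int = 10000,
    ci: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-site mean observed/expected heterozygosity and rarefied allelic
    richness, with bootstrap (resampled individuals) confidence intervals.

    Richness is rarefied to the smallest per-locus allele count across
    populations by the exact hypergeometric formula, so values lie in
    [1, 2] for biallelic loci.  Populations of size 1 are excluded with a
    warning.
    """
    masks = g.site_masks() if pops is None else pops
    masks = dict(masks)
    for s in list(masks):
        if masks[s].sum() < 2:
            warnings.warn(f"population {s!r} has <2 individuals; excluded")
            del masks[s]
    if not masks:
        raise ValueError("no population with >=2 individuals")
    raref = min(
        int(np.min(2 * (g.calls[m] != MISSING).sum(axis=0))) for m in masks.values()
    )
    raref = max(raref, 2)
    rng = sub_rng(seed, "diversity")
    alpha = (1 - ci) / 2
    rows = []
    for s, m in masks.items():
        block = g.calls[m]
        ho, he, ar = _diversity_point(block, raref)
        reps = np.empty((n_perm, 3))
        for b in range(n_perm):
            idx = rng.integers(0, block.shape[0], block.shape[0])
            reps[b] = _diversity_point(block[idx], raref)
        lo = np.quantile(reps, alpha, axis=0)
        hi = np.quantile(reps, 1 - alpha, axis=0)
        rows.append(
            {
                "site": s,
                "n": int(m.sum()),
                "Ho": ho, "Ho_lo": lo[0], "Ho_hi": hi[0],
                "He": he, "He_lo": lo[1], "He_hi": hi[1],
                "allelic_richness": ar, "AR_lo": lo[2], "AR_hi": hi[2],
            }
        )
    return pd.DataFrame(rows).set_index("site")


# ---------------------------------------------------------------------------
# pairwise differentiation
# ---------------------------------------------------------------------------

def _bootstrap_ratio(num: np.ndarray, den: np.ndarray, n_boot: int, ci: float, rng):
    """Bootstrap loci; returns (lo, hi, p_le_zero) for a ratio-of-sums stat."""
    ok = np.isfinite(num) & np.isfinite(den)
    num, den = num[ok], den[ok]
    L = num.size
    if L < 2:
        return np.nan, np.nan, np.nan
    alpha = (1 - ci) / 2
    thetas = np.empty(n_boot)
    for start in range(0, n_boot, 2000):
        stop = min(start + 2000, n_boot)
        idx = rng.integers(0, L, (stop - start, L))
        d = den[idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            thetas[start:stop] = num[idx].sum(axis=1) / d
    thetas = thetas[np.isfinite(thetas)]
    if thetas.size == 0:
        return np.nan, np.nan, np.nan
    lo, hi = np.quantile(thetas, [alpha, 1 - alpha])
    p = perm_pvalue(int((thetas <= 0).sum()), thetas.size)
    return float(lo), float(hi), float(p)


def pairwise_fst(
    g: GenotypeMatrix,
    pops: dict | None = None,
    n_boot: int = 10000,
    ci: float = 0.95,
    adjust: str = "BY",
    seed: int | None = None,
) -> PairwiseStatMatrix:
    """Pairwise multilocus Weir-Cockerham F_st with locus-bootstrap CIs.

    The p-value for a pair is the bootstrap probability of an estimate
    <= 0; p-values are adjusted across pairs (Benjamini-Yekutieli by
    default).  Pairs sharing <2 informative loci are flagged unreliable.
    """
    masks = g.site_masks() if pops is None else pops
    sites = list(masks)
    k = len(sites)
    if k < 2:
        raise ValueError("need at least two populations")
    rng = sub_rng(seed, "pairwise_fst")
    est = np.zeros((k, k))
    lo = np.zeros((k, k))
    hi = np.zeros((k, k))
    pv = np.full((k, k), np.nan)
    flags = {}
    _, n_all, p_all, h_all = pop_locus_stats(g, masks)
    for i in range(k):
        for j in range(i + 1, k):
            n = n_all[[i, j]]
            p = p_all[[i, j]]
            h = h_all[[i, j]]
            a, b, c = wc_components(n, p, h)
            den = a + b + c
            ok = np.isfinite(den) & (den != 0)
            if ok.sum() < 2:
                flags[(sites[i], sites[j])] = "unreliable: <2 informative loci"
                est[i, j] = est[j, i] = np.nan
                continue
            theta = float(a[ok].sum() / den[ok].sum())
            est[i, j] = est[j, i] = theta
            l, hh, pp = _bootstrap_ratio(a, den, n_boot, ci, rng)
            lo[i, j] = lo[j, i] = l
            hi[i, j] = hi[j, i] = hh
            pv[i, j] = pv[j, i] = pp
    iu = np.triu_indices(k, 1)
    padj = np.full((k, k), np.nan)
    padj_flat = adjust_pvalues(pv[iu], adjust)
    padj[iu] = padj_flat
    padj[(iu[1], iu[0])] = padj_flat
    return PairwiseStatMatrix(
        statistic="F_st", sites=sites, estimates=est, ci_lo=lo, ci_hi=hi,
        pvalues=pv, pvalues_adj=padj, adjust_method=adjust, flags=flags,
    )


def _gst_jostd_locus(n, p):
    """Per-locus Nei G_st and Jost's D from population frequencies.

    H_S is the unweighted mean of within-population expected
    heterozygosities, H_T the expected heterozygosity of the pooled mean
    frequency (Nei 1973, no sample-size correction); D carries the
    n/(n-1) population-number scaling.
    """
    r = n.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        hs = np.nanmean(2 * p * (1 - p), axis=0)
        p_bar = np.nanmean(p, axis=0)
        ht = 2 * p_bar * (1 - p_bar)
        gst = np.where(ht > 0, (ht - hs) / ht, np.nan)
        d = np.where(hs < 1, (ht - hs) / (1 - hs) * r / (r - 1), np.nan)
    return gst, d, hs, ht


def pairwise_gst_jostd(
    g: GenotypeMatrix,
    pops: dict | None = None,
    n_iter: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
):
    """Pairwise multilocus Nei G_st and Jost's D with locus-bootstrap CIs.

    Multilocus values use the ratio-of-averages form (mean H_S and H_T
    across loci, then the statistic).  Returns (gst_matrix, d_matrix).
    """
    masks = g.site_masks() if pops is None else pops
    sites = list(masks)
    k = len(sites)
    if k < 2:
        raise ValueError("need at least two populations")
    rng = sub_rng(seed, "gst_jostd")
    _, n_all, p_all, _ = pop_locus_stats(g, masks)
    mats = {
        "G_st": (np.zeros((k, k)), np.zeros((k, k)), np.zeros((k, k))),
        "Jost_D": (np.zeros((k, k)), np.zeros((k, k)), np.zeros((k, k))),
    }
    flags = {}
    alpha = (1 - ci) / 2
    for i in range(k):
        for j in range(i + 1, k):
            n = n_all[[i, j]]
            p = p_all[[i, j]]
            _, _, hs, ht = _gst_jostd_locus(n, p)
            ok = np.isfinite(hs) & np.isfinite(ht)
            if not ok.any() or np.nansum(ht[ok]) == 0:
                flags[(sites[i], sites[j])] = "undefined: H_T = 0 at all loci"
                for key in mats:
                    mats[key][0][i, j] = mats[key][0][j, i] = np.nan
                continue
            hs, ht = hs[ok], ht[ok]

            def stat(hs_m, ht_m):
                g_ = (ht_m - hs_m) / ht_m if ht_m > 0 else np.nan
                d_ = (ht_m - hs_m) / (1 - hs_m) * 2 if hs_m < 1 else np.nan
                return g_, d_

            g0, d0 = stat(hs.mean(), ht.mean())
            idx = rng.integers(0, hs.size, (n_iter, hs.size))
            reps = np.array([stat(hs[ix].mean(), ht[ix].mean()) for ix in idx])
            for col, key in enumerate(("G_st", "Jost_D")):
                e, l, h_ = mats[key]
                e[i, j] = e[j, i] = (g0, d0)[col]
                vals = reps[:, col]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    l[i, j] = l[j, i] = np.quantile(vals, alpha)
                    h_[i, j] = h_[j, i] = np.quantile(vals, 1 - alpha)
    out = []
    for key in ("G_st", "Jost_D"):
        e, l, h_ = mats[key]
        out.append(
            PairwiseStatMatrix(statistic=key, sites=sites, estimates=e,
                               ci_lo=l, ci_hi=h_, flags=flags)
        )
    return tuple(out)


def shift_nonnegative(m: PairwiseStatMatrix) -> PairwiseStatMatrix:
    """Add a constant so the minimum off-diagonal estimate is 0.

    Presentation-only transform for visualisation; inference fields are
    carried over untouched and the constant is recorded.
    """
    k = len(m.sites)
    iu = np.triu_indices(k, 1)
    vals = m.estimates[iu]
    finite = vals[np.isfinite(vals)]
    const = float(-finite.min()) if finite.size and finite.min() < 0 else 0.0
    est = m.estimates.copy()
    if const > 0:
        est[iu] = est[iu] + const
        est[(iu[1], iu[0])] = est[iu]
    return PairwiseStatMatrix(
        statistic=m.statistic, sites=m.sites, estimates=est,
        ci_lo=m.ci_lo, ci_hi=m.ci_hi, pvalues=m.pvalues,
        pvalues_adj=m.pvalues_adj, adjust_method=m.adjust_method,
        shift_constant=const, flags=dict(m.flags),
    )


# ---------------------------------------------------------------------------
# isolation by distance
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    layer: str = ""
    n_excluded: int = 0


def mantel_ibd(
    stat: PairwiseStatMatrix,
    distances: pd.DataFrame,
    n_perm: int = 100000,
    seed: int | None = None,
    layer: str = "",
) -> MantelResult:
    """Mantel test of linearized differentiation against distance.

    F_st is linearized as F_st/(1-F_st); the statistic is the Pearson
    correlation over off-diagonal pairs and the p-value comes from
    permuting the site labels of the distance matrix, one-sided against
    the isolation-by-distance alternative (r > 0).  Entries with
    F_st = 1 linearize to infinity and are excluded with a warning.
    """
    sites = list(stat.sites)
    d = distances.loc[sites, sites].to_numpy(float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    k = len(sites)
    iu = np.triu_indices(k, 1)
    fst = stat.estimates[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        lin = fst / (1 - fst)
    bad = ~np.isfinite(lin)
    n_excluded = int(bad.sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} pair(s) with F_st = 1 excluded from Mantel test")
    keep = ~bad

    def corr(y):
        x, yy = lin[keep], y[keep]
        if x.size < 3 or x.std() == 0 or yy.std() == 0:
            return np.nan
        return float(np.corrcoef(x, yy)[0, 1])

    r_obs = corr(d[iu])
    rng = sub_rng(seed, "mantel")
    perms = np.array([rng.permutation(k) for _ in range(n_perm)])
    y_perm = d[perms[:, iu[0]], perms[:, iu[1]]]  # (n_perm, n_pairs)
    x = lin[keep]
    yp = y_perm[:, keep]
    xc = x - x.mean()
    ypc = yp - yp.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (ypc @ xc) / (np.sqrt((ypc**2).sum(axis=1)) * np.sqrt((xc**2).sum()))
    n_ge = int((r_perm >= r_obs - 1e-12).sum())
    return MantelResult(
        r=r_obs, p=perm_pvalue(n_ge, n_perm), n_permutations=n_perm,
        layer=layer, n_excluded=n_excluded,
    )
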