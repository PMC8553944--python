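"""SNP quality-control cascade and F_st outlier scan.

The cascade runs in a fixed order: per-locus filters (call rate, coverage
bounds, heterozygosity ceiling, minor-allele-frequency floor), then
monomorphic-locus/individual removal iterated to a fixed point, then
exact Hardy-Weinberg and composite-LD pruning voted across populations,
and finally the neutral/outlier partition.  Every stage appends a
FilterReport to the matrix provenance so the count sequence can be
audited on any input.

The outlier scan follows the OutFLANK logic: per-locus F_st is computed
without the finite-sample correction, a scaled chi-square null is fitted
by maximum likelihood to the two-sided-trimmed distribution (inferring
the effective degrees of freedom), and right-tail p-values are converted
to q-values by the Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from ._utils import MISSING, adjust_pvalues
from .datatypes import FilterReport, GenotypeMatrix, OutlierScanResult
from .popgen import pop_locus_stats, wc_components


def _report(stage, g_before, g_after, removed_loci, removed_inds, detail=None):
    return FilterReport(
        stage=stage,
        loci_before=g_before.n_loci,
        loci_after=g_after.n_loci,
        individuals_before=g_before.n_individuals,
        individuals_after=g_after.n_individuals,
        missing_fraction_after=g_after.missing_fraction(),
        removed_loci=list(removed_loci),
        removed_individuals=list(removed_inds),
        detail=detail or {},
    )


# ---------------------------------------------------------------------------
# stage 1: per-locus filters
# ---------------------------------------------------------------------------

def filter_loci(
    g: GenotypeMatrix,
    call_rate: float = 0.95,
    cov_min: float = 20,
    cov_max: float = 200,
    het_max: float = 0.75,
    maf_min: float = 0.05,
):
    """Sequential per-locus filters: call rate >= ``call_rate``, mean
    coverage within (``cov_min``, ``cov_max``) inclusive, observed
    heterozygosity <= ``het_max``, and folded MAF >= ``maf_min``.

    Bounds are read as strict removal criteria ("coverage <20x and
    >200x", "heterozygosity >0.75", "rare (allele frequency <0.05)"), so
    a locus exactly at a bound is retained.  Removal counts are recorded
    per criterion in application order.
    """
    keep = np.ones(g.n_loci, bool)
    removed = {}

    cr = g.locus_call_rate()
    hit = keep & (cr < call_rate)
    removed["call_rate"] = list(g.locus_ids[hit])
    keep &= ~hit

    cov = g.locus_meta["coverage"].to_numpy(float)
    hit = keep & ((cov < cov_min) | (cov > cov_max))
    removed["coverage"] = list(g.locus_ids[hit])
    keep &= ~hit

    het = g.het_obs()
    hit = keep & (het > het_max)
    removed["heterozygosity"] = list(g.locus_ids[hit])
    keep &= ~hit

    p = g.allele_freq()
    maf = np.fmin(p, 1 - p)
    hit = keep & (maf < maf_min)
    removed["maf"] = list(g.locus_ids[hit])
    keep &= ~hit

    if not keep.any():
        raise ValueError("all loci filtered out")
    out = g.subset(locus_mask=keep)
    all_removed = [x for lst in removed.values() for x in lst]
    rep = _report("locus_filters", g, out, all_removed, [],
                  detail={k: len(v) for k, v in removed.items()})
    out.provenance.append(rep)
    return out, rep


# ---------------------------------------------------------------------------
# stage 2: monomorphic loci and low-call individuals, to a fixed point
# ---------------------------------------------------------------------------

def _monomorphic_mask(g: GenotypeMatrix) -> np.ndarray:
    p = g.allele_freq()
    return ~np.isfinite(p) | (p <= 0) | (p >= 1)


def filter_individuals_monomorphic(g: GenotypeMatrix, ind_call_rate: float = 0.90):
    """Drop monomorphic loci and individuals genotyped below
    ``ind_call_rate``; iterate because individual removal can fix a
    previously polymorphic locus."""
    cur = g
    removed_loci, removed_inds = [], []
    while True:
        mono = _monomorphic_mask(cur)
        if mono.any():
            removed_loci.extend(cur.locus_ids[mono])
            cur = cur.subset(locus_mask=~mono)
        low = cur.individual_call_rate() < ind_call_rate
        if low.all():
            raise ValueError("all individuals dropped by call-rate filter")
        if low.any():
            removed_inds.extend(cur.individual_ids[low])
            cur = cur.subset(ind_mask=~low)
            continue
        if not _monomorphic_mask(cur).any():
            break
    if cur.n_loci == 0:
        raise ValueError("all loci filtered out as monomorphic")
    rep = _report("monomorphic_individuals", g, cur, removed_loci, removed_inds)
    cur.provenance.append(rep)
    return cur, rep


# ---------------------------------------------------------------------------
# stage 3: Hardy-Weinberg and linkage-disequilibrium pruning
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Classic exact conditional HWE test (Levene/Haldane; mid-p off).

    Enumerates all heterozygote counts compatible with the observed
    allele counts and sums the probabilities of outcomes no more likely
    than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_alt + n_het  # alt allele count
    n_a = min(n_a, 2 * n - n_a)  # fold to the minor allele
    hets = np.arange(n_a % 2, n_a + 1, 2)
    hom_min = (n_a - hets) // 2
    hom_maj = n - hets - hom_min
    valid = hom_maj >= 0
    hets, hom_min, hom_maj = hets[valid], hom_min[valid], hom_maj[valid]
    logp = (
        hets * np.log(2)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_min + 1)
        - gammaln(hom_maj + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs_het = min(n_het, n_a)  # folding keeps the het count
    p_obs = prob[hets == n_het].item() if (hets == n_het).any() else 0.0
    return float(prob[prob <= p_obs + 1e-12].sum())


def _ld_r2(calls: np.ndarray):
    """Composite genotypic r^2 on dosages with pairwise-complete calls."""
    X = np.ma.masked_equal(calls.astype(float), MISSING)
    r = np.ma.corrcoef(X, rowvar=False)
    obs = (~np.ma.getmaskarray(X)).astype(int)
    n_pair = obs.T @ obs
    return np.asarray(r.filled(np.nan)) ** 2, n_pair


def hwe_ld_filter(
    g: GenotypeMatrix,
    pops: dict | None = None,
    alpha: float = 0.05,
    min_pops: int = 2,
    ld_r2: float = 0.8,
    min_pop_size: int = 5,
):
    """Remove loci out of HWE and prune locus pairs in LD, each judged
    significant (after Bonferroni within population) in >= ``min_pops``
    populations.

    LD uses the composite genotypic r^2 (squared Pearson correlation of
    dosages) with a chi-square test n*r^2 ~ chi2(1); a pair additionally
    needs r^2 >= ``ld_r2``.  Of a pruned pair the member with the lower
    call rate is removed (ties: lower MAF, then the lexicographically
    later id).  Populations with fewer than ``min_pop_size`` genotyped
    individuals are excluded from voting.
    """
    masks = g.site_masks() if pops is None else pops
    voting = {}
    skipped = []
    for s, m in masks.items():
        if m.sum() >= min_pop_size:
            voting[s] = m
        else:
            skipped.append(s)
    if skipped:
        warnings.warn(f"populations below minimum size excluded from voting: {skipped}")
    if len(voting) < 2:
        raise ValueError("need >=2 populations large enough for HWE/LD voting")

    L = g.n_loci
    # --- HWE votes ---------------------------------------------------------
    hwe_votes = np.zeros(L, int)
    for s, m in voting.items():
        calls = g.calls[m]
        obs = calls != MISSING
        tested = []
        pvals = []
        for j in range(L):
            c = calls[obs[:, j], j]
            if c.size == 0:
                continue
            counts = [(c == 0).sum(), (c == 1).sum(), (c == 2).sum()]
            if counts[1] + min(counts[0], counts[2]) == 0 and (counts[0] == 0 or counts[2] == 0):
                continue  # monomorphic in this population: untestable
            tested.append(j)
            pvals.append(hwe_exact_pvalue(*counts))
        if tested:
            thr = alpha / len(tested)
            for j, p in zip(tested, pvals):
                if p < thr:
                    hwe_votes[j] += 1
    hwe_out = hwe_votes >= min_pops
    removed_hwe = list(g.locus_ids[hwe_out])
    cur = g.subset(locus_mask=~hwe_out)

    # --- LD votes ----------------------------------------------------------
    L2 = cur.n_loci
    pair_votes = np.zeros((L2, L2), int)
    n_pairs = L2 * (L2 - 1) // 2
    for s, m in voting.items():
        r2, n_pair = _ld_r2(cur.calls[m])
        with np.errstate(invalid="ignore"):
            chi2 = n_pair * r2
            pv = stats.chi2.sf(chi2, 1)
        sig = (pv < alpha / max(n_pairs, 1)) & (r2 >= ld_r2)
        sig &= np.isfinite(r2)
        np.fill_diagonal(sig, False)
        pair_votes += sig.astype(int)

    call_rate = cur.locus_call_rate()
    p = cur.allele_freq()
    maf = np.fmin(p, 1 - p)
    alive = np.ones(L2, bool)
    removed_ld = []
    ii, jj = np.where(np.triu(pair_votes >= min_pops, 1))
    for i, j in zip(ii, jj):
        if not (alive[i] and alive[j]):
            continue
        key_i = (call_rate[i], maf[i], str(cur.locus_ids[j]))  # higher key survives
        key_j = (call_rate[j], maf[j], str(cur.locus_ids[i]))
        drop = i if key_i < key_j else j
        alive[drop] = False
        removed_ld.append(cur.locus_ids[drop])
    out = cur.subset(locus_mask=alive)
    rep = _report(
        "hwe_ld", g, out, removed_hwe + removed_ld, [],
        detail={"hwe_removed": len(removed_hwe), "ld_removed": len(removed_ld),
                "populations_excluded": skipped},
    )
    out.provenance.append(rep)
    return out, rep


# ---------------------------------------------------------------------------
# stage 4: outlier scan
# ---------------------------------------------------------------------------

def _trimmed_chisq_fit(x: np.ndarray, trim: float):
    """ML fit of a scaled chi-square to the two-sided-trimmed sample.

    The model is x ~ (mean/df) * chi2(df) truncated to the observed trim
    window; both the mean and the effective df are free.
    """
    lo, hi = np.quantile(x, [trim, 1 - trim])
    kept = x[(x >= lo) & (x <= hi)]
    if kept.size < 10:
        raise ValueError("too few loci left after trimming")

    def nll(params):
        log_df, log_mean = params
        df, mean = np.exp(log_df), np.exp(log_mean)
        scale = mean / df
        logpdf = stats.chi2.logpdf(kept / scale, df) - np.log(scale)
        norm = stats.chi2.cdf(hi / scale, df) - stats.chi2.cdf(lo / scale, df)
        if norm <= 0 or not np.isfinite(norm):
            return 1e12
        return -(logpdf.sum() - kept.size * np.log(norm))

    mean0 = kept.mean()
    var0 = max(kept.var(), 1e-12)
    df0 = max(2 * mean0**2 / var0, 0.5)
    res = optimize.minimize(
        nll, [np.log(df0), np.log(mean0)], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    df_hat, mean_hat = np.exp(res.x)
    return float(df_hat), float(mean_hat)


def outflank_scan(
    g: GenotypeMatrix,
    pops: dict | None = None,
    trim: float = 0.05,
    min_het: float = 0.1,
    fdr: float = 0.05,
) -> OutlierScanResult:
    """Neutral/outlier partition of loci from the trimmed chi-square null.

    Loci with pooled expected heterozygosity below ``min_het`` are
    excluded from the fit and the test.  Returns disjoint neutral and
    outlier id sets over the tested loci.
    """
    masks = g.site_masks() if pops is None else pops
    if len(masks) < 2:
        raise ValueError("need at least two populations")
    if g.n_loci < 200:
        warnings.warn("fewer than 200 loci: the null fit may be unstable")
    _, n, p, h = pop_locus_stats(g, masks)
    a, b, c = wc_components(n, p, h, corrected=True)
    an, bn, cn = wc_components(n, p, h, corrected=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / (a + b + c)
        fst_nc = an / (an + bn + cn)
        n_tot = n.sum(axis=0)
        p_bar = np.nansum(n * p, axis=0) / n_tot
    het = 2 * p_bar * (1 - p_bar)

    testable = np.isfinite(fst_nc) & np.isfinite(het)
    low_het = testable & (het < min_het)
    kept = testable & ~low_het
    if not kept.any():
        raise ValueError("no testable loci: all excluded by the heterozygosity mask")
    vals = fst_nc[kept]
    if np.ptp(vals) < 1e-12:
        raise ValueError("degenerate F_st distribution: all values equal")

    df_hat, mean_hat = _trimmed_chisq_fit(vals, trim)
    pvals = np.full(g.n_loci, np.nan)
    pvals[kept] = stats.chi2.sf(fst_nc[kept] * df_hat / mean_hat, df_hat)
    qvals = np.full(g.n_loci, np.nan)
    qvals[kept] = adjust_pvalues(pvals[kept], "BH")

    outlier = kept & (qvals < fdr)
    neutral = kept & ~outlier
    excluded = ~kept
    return OutlierScanResult(
        locus_ids=g.locus_ids,
        fst=fst,
        fst_no_corr=fst_nc,
        het=het,
        df_inferred=df_hat,
        fst_bar=mean_hat,
        pvalues=pvals,
        qvalues=qvals,
        neutral_ids=g.locus_ids[neutral],
        outlier_ids=g.locus_ids[outlier],
        excluded_low_het_ids=g.locus_ids[excluded],
    )


def run_qc_cascade(g: GenotypeMatrix, pops: dict | None = None, **kw):
    """Full four-stage cascade; returns (filtered matrix, reports, scan)."""
    g1, r1 = filter_loci(g, **{k: v for k, v in kw.items()
                               if k in {"call_rate", "cov_min", "cov_max", "het_max", "maf_min"}})
    g2, r2 = filter_individuals_monomorphic(g1, kw.get("ind_call_rate", 0.90))
    g3, r3 = hwe_ld_filter(g2, pops=None, alpha=kw.get("alpha", 0.05),
                           min_pops=kw.get("min_pops", 2), ld_r2=kw.get("ld_r2", 0.8))
    scan = outflank_scan(g3, pops=None, trim=kw.get("trim", 0.05),
                         min_het=kw.get("min_het", 0.1), fdr=kw.get("fdr", 0.05))
    return g3, [r1, r2, r3], scan
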