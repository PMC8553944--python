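"""Directional relative-migration networks with bootstrap asymmetry tests.

For every ordered pair of populations a hypothetical pooled population is
built as the equal-weight mean of the pair's allele frequencies.  The
genetic differentiation of each member from that pool is converted into a
directional migration proxy by a monotone island-model transform, and the
whole directed matrix is divided by its maximum, giving relative rates on
[0, 1].  Asymmetry per pair is judged by bootstrapping individuals within
populations and asking whether the bootstrap interval of
m[i->j] - m[j->i] excludes zero.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._utils import MISSING, sub_rng
from .datatypes import GenotypeMatrix, MigrationNetwork

_EPS = 1e-6


def _pair_stat(p_a: np.ndarray, p_b: np.ndarray, basis: str) -> float:
    """Multilocus differentiation between two frequency vectors
    (ratio-of-averages over loci); basis 'gst', 'd' or 'nm'."""
    ok = np.isfinite(p_a) & np.isfinite(p_b)
    if not ok.any():
        return np.nan
    pa, pb = p_a[ok], p_b[ok]
    hs = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2
    pm = (pa + pb) / 2
    ht = 2 * pm * (1 - pm)
    hs_bar, ht_bar = hs.mean(), ht.mean()
    if basis in ("gst", "nm"):
        return (ht_bar - hs_bar) / ht_bar if ht_bar > 0 else np.nan
    if basis == "d":
        return (ht_bar - hs_bar) / (1 - hs_bar) * 2 if hs_bar < 1 else np.nan
    raise ValueError(f"unknown basis {basis!r}")


def _raw_rate(stat: float, basis: str) -> float:
    """Monotone decreasing transform of differentiation into a migration
    proxy; negative values are truncated to zero."""
    if not np.isfinite(stat):
        return np.nan
    stat = max(stat, _EPS)
    if basis in ("gst", "nm"):
        rate = (1.0 / stat - 1.0) / 4.0  # island-model Nm from G_st
    else:
        rate = (1.0 - stat) / stat
    return max(rate, 0.0)


def directional_rates(p: np.ndarray, basis: str = "gst", normalize: bool = True) -> np.ndarray:
    """Directed matrix m[i, j] = relative migration from deme i into j.

    ``p`` holds per-population allele frequencies, shape (n_pops, n_loci).
    For each ordered pair the pair's pooled population is built and the
    directional differentiation is converted into a rate.  Heavy
    immigration raises the receiver's heterozygosity; because the mean
    member-pool heterozygosity gap is symmetric within a pair, that extra
    diversity is the entire directional signal.  It lowers the G_st-type
    differentiation of the receiver from the pool (larger H_T
    denominator) but lowers the Jost-D differentiation of the *source*
    (larger 1 - H_S denominator on the other side), so the G_st/Nm bases
    read the receiver-pool statistic and the D basis the source-pool
    statistic; the two readings order every pair identically.
    """
    k = p.shape[0]
    m = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            pool = (p[i] + p[j]) / 2
            member = p[i] if basis == "d" else p[j]
            m[i, j] = _raw_rate(_pair_stat(member, pool, basis), basis)
    if normalize:
        top = np.nanmax(m)
        if np.isfinite(top) and top > 0:
            m = m / top
    return m


def _pop_freqs(calls_by_pop: list) -> np.ndarray:
    out = []
    for calls in calls_by_pop:
        obs = calls != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out.append(np.where(n > 0, np.where(obs, calls, 0).sum(axis=0) / (2.0 * n), np.nan))
    return np.asarray(out)


def relative_migration(
    g: GenotypeMatrix,
    pops: dict | None = None,
    basis: str = "gst",
) -> MigrationNetwork:
    """Directional relative-migration network, normalized to max 1."""
    basis = basis.lower().replace("_st", "st").replace("jost_", "")
    masks = g.site_masks() if pops is None else pops
    sites = list(masks)
    if len(sites) < 2:
        raise ValueError("need at least two populations")
    calls_by_pop = [g.calls[masks[s]] for s in sites]
    p = _pop_freqs(calls_by_pop)
    # a pair sharing no polymorphic loci cannot be scored
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            ok = np.isfinite(p[i]) & np.isfinite(p[j])
            if not ok.any() or not ((p[i][ok] != p[i][ok][0]).any() or (p[j][ok] != p[j][ok][0]).any()):
                warnings.warn(f"pair ({sites[i]}, {sites[j]}) shares no polymorphic loci; excluded")
    rates = directional_rates(p, basis)
    return MigrationNetwork(sites=sites, rates=rates, basis=basis)


def asymmetry_test(
    net: MigrationNetwork,
    g: GenotypeMatrix,
    pops: dict | None = None,
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> MigrationNetwork:
    """Bootstrap individuals within populations and flag ordered pairs
    whose m[i->j] - m[j->i] interval excludes zero at level ``alpha``."""
    if n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap asymmetry intervals are unstable")
    masks = g.site_masks() if pops is None else pops
    sites = net.sites
    if list(masks) != list(sites):
        masks = {s: masks[s] for s in sites}
    calls_by_pop = [g.calls[masks[s]] for s in sites]
    rng = sub_rng(seed, "migration_boot")
    k = len(sites)
    diffs = np.empty((n_boot, k, k))
    for b in range(n_boot):
        res = []
        for calls in calls_by_pop:
            idx = rng.integers(0, calls.shape[0], calls.shape[0])
            res.append(calls[idx])
        m = directional_rates(_pop_freqs(res), net.basis)
        diffs[b] = m - m.T
    lo = np.nanquantile(diffs, alpha / 2, axis=0)
    hi = np.nanquantile(diffs, 1 - alpha / 2, axis=0)
    sig = (lo > 0) | (hi < 0)
    np.fill_diagonal(sig, False)
    return MigrationNetwork(
        sites=sites, rates=net.rates, basis=net.basis, n_boot=n_boot,
        significant_asymmetry=sig, asym_ci_lo=lo, asym_ci_hi=hi,
    )
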