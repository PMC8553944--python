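"""Shared helpers: seeded sub-generators and multiple-testing wrappers."""

from __future__ import annotations

import zlib

import numpy as np
from statsmodels.stats.multitest import multipletests

MISSING = -1  # sentinel for a missing genotype call


def sub_rng(seed: int | None, label: str) -> np.random.Generator:
    """Return a labeled child generator of one global seed.

    Each pipeline stage draws from its own stream so that adding draws in
    one stage never perturbs another.  The child seed is derived from the
    (seed, label) pair, so results are bit-reproducible.
    """
    if seed is None:
        return np.random.default_rng()
    tag = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def adjust_pvalues(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Benjamini–Hochberg ('BH'), Benjamini–Yekutieli ('BY') or Bonferroni."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return out
    key = {"BH": "fdr_bh", "BY": "fdr_by", "bonferroni": "bonferroni"}[method]
    out[ok] = multipletests(p[ok], method=key)[1]
    return out


def perm_pvalue(n_extreme: int, n_perm: int) -> float:
    """Permutation p with the +1 correction; respects the 1/(n_perm+1) floor."""
    return (n_extreme + 1) / (n_perm + 1)
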