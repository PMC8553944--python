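"""Independent brute-force oracles used to validate the implementations.

These are deliberately written in plain scalar style, straight from the
defining formulas, and share no code with the package.
"""

import math

import numpy as np

MISSING = -1


def wc_fst_bruteforce(calls_by_pop):
    """Multilocus Weir-Cockerham theta by direct per-locus summation.

    calls_by_pop: list of (n_ind, n_loci) integer arrays with -1 missing.
    Returns sum(a) / sum(a + b + c) over loci with complete information.
    """
    n_loci = calls_by_pop[0].shape[1]
    r = len(calls_by_pop)
    sum_a = 0.0
    sum_abc = 0.0
    for l in range(n_loci):
        ns, ps, hs = [], [], []
        ok = True
        for pop in calls_by_pop:
            col = [c for c in pop[:, l] if c != MISSING]
            if len(col) == 0:
                ok = False
                break
            ns.append(len(col))
            ps.append(sum(col) / (2.0 * len(col)))
            hs.append(sum(1 for c in col if c == 1) / len(col))
        if not ok:
            continue
        n_bar = sum(ns) / r
        n_c = (r * n_bar - sum(n**2 for n in ns) / (r * n_bar)) / (r - 1)
        p_bar = sum(n * p for n, p in zip(ns, ps)) / (r * n_bar)
        s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
        h_bar = sum(n * h for n, h in zip(ns, hs)) / (r * n_bar)
        if n_bar <= 1:
            continue
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
        if math.isfinite(a + b + c):
            sum_a += a
            sum_abc += a + b + c
    return sum_a / sum_abc


def hwe_exact_bruteforce(n_aa, n_ab, n_bb):
    """Exact conditional HWE p-value by full enumeration of genotype
    configurations with the observed allele counts."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    probs = {}
    for het in range(min(na, nb) + 1):
        if (na - het) % 2:
            continue
        haa = (na - het) // 2
        hbb = (nb - het) // 2
        if haa < 0 or hbb < 0 or haa + het + hbb != n:
            continue
        logp = (
            het * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(haa + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hbb + 1)
        )
        probs[het] = logp
    mx = max(probs.values())
    weights = {h: math.exp(lp - mx) for h, lp in probs.items()}
    total = sum(weights.values())
    p_obs = weights[n_ab] / total
    return sum(w for w in weights.values() if w / total <= p_obs + 1e-12) / total


def diversity_bruteforce(calls):
    """(mean Ho, mean He) across loci for one population, plain loops."""
    n_loci = calls.shape[1]
    hos, hes = [], []
    for l in range(n_loci):
        col = [c for c in calls[:, l] if c != MISSING]
        if not col:
            continue
        p = sum(col) / (2.0 * len(col))
        hos.append(sum(1 for c in col if c == 1) / len(col))
        hes.append(2 * p * (1 - p))
    return float(np.mean(hos)), float(np.mean(hes))


def bray_curtis_bruteforce(x, y):
    x = np.asarray(x, float) / np.sum(x)
    y = np.asarray(y, float) / np.sum(y)
    return float(np.abs(x - y).sum() / (x + y).sum())
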