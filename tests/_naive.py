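"""Independent brute-force oracles used by the tests.

Everything here is written as straight-line loops against the definitions,
deliberately sharing no code with the package, so that agreement between
the two routes is evidence of correctness.
"""

from __future__ import annotations

import math

import numpy as np

from iodoscreen.screen_model import Role


def naive_trimmean(values, proportion=0.5):
    """Spreadsheet TRIMMEAN by explicit sort-and-slice."""
    vals = sorted(values)
    n = len(vals)
    k = int(n * proportion / 2)  # excluded per tail
    kept = vals[k:n - k] if k > 0 else vals
    return sum(kept) / len(kept)


def naive_delta_yfp(wells, cycles_used=4, trim=0.5):
    """Straight-line reimplementation of the %YFP -> S_IQM -> S_IQMW ->
    delta-YFP chain with plain loops and dicts.  Returns address -> dYFP."""
    usable = [w for w in wells if w.yfp0 > 0 and len(w.yfp_cycles) >= 1]
    pct = {}
    for w in usable:
        c = min(cycles_used, len(w.yfp_cycles))
        yfp4 = w.yfp_cycles[c - 1]
        pct[w.address] = (w.yfp0 - yfp4) / w.yfp0 * 100.0

    plates = sorted({a.plate_id for a in pct})
    mu_iq = {}
    for p in plates:
        mu_iq[p] = naive_trimmean([v for a, v in pct.items() if a.plate_id == p], trim)
    s_iqm = {a: v / mu_iq[a.plate_id] for a, v in pct.items()}

    positions = sorted({a.position for a in s_iqm})
    mu_iqw = {}
    for pos in positions:
        mu_iqw[pos] = naive_trimmean(
            [v for a, v in s_iqm.items() if a.position == pos], trim)
    s_iqmw = {a: v / mu_iqw[a.position] for a, v in s_iqm.items()}

    dmso_vals = [s_iqmw[w.address] for w in usable if w.role is Role.DMSO_CONTROL]
    mean_dmso = sum(dmso_vals) / len(dmso_vals)
    sd = math.sqrt(sum((v - mean_dmso) ** 2 for v in dmso_vals) / (len(dmso_vals) - 1))

    dmso_by_plate = {}
    for w in usable:
        if w.role is Role.DMSO_CONTROL:
            dmso_by_plate.setdefault(w.address.plate_id, []).append(s_iqmw[w.address])
    plate_dmso_mean = {p: sum(v) / len(v) for p, v in dmso_by_plate.items()}

    return {a: (s_iqmw[a] - plate_dmso_mean[a.plate_id]) / sd for a in s_iqmw}


def dense_grid_auc(doses, responses, n_grid=200001):
    """Numerically integrate the piecewise-linear curve through the
    zero-clipped responses on a very fine log10-dose grid."""
    x = np.log10(np.asarray(doses, dtype=float))
    y = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    grid = np.linspace(x.min(), x.max(), n_grid)
    return float(np.trapezoid(np.interp(grid, x, y), grid))


def naive_concordance(score, label):
    """All-pairs Mann-Whitney concordance with ties counted one half."""
    score = list(map(float, score))
    label = list(map(bool, label))
    pos = [s for s, y in zip(score, label) if y]
    neg = [s for s, y in zip(score, label) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_fisher_two_sided(table):
    """Two-sided Fisher exact p by enumerating all tables with the observed
    margins and summing hypergeometric probabilities <= P(observed)
    (relative tolerance 1 + 1e-7, the convention R and scipy share)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(m, k):
        return math.lgamma(m + 1) - math.lgamma(k + 1) - math.lgamma(m - k + 1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return math.exp(log_comb(r1, x) + log_comb(r2, c1 - x) - log_comb(n, c1))

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1.0 + 1e-7):
            total += px
    return min(total, 1.0)


def naive_breslow_loglik(beta, covariate, time, event):
    """Cox partial log-likelihood with Breslow tie handling, double loop."""
    n = len(time)
    ll = 0.0
    for i in range(n):
        if not event[i]:
            continue
        risk_sum = 0.0
        for j in range(n):
            if time[j] >= time[i]:
                risk_sum += math.exp(beta * covariate[j])
        ll += beta * covariate[i] - math.log(risk_sum)
    return ll


def naive_youden_best_j(score, label):
    """Max Youden J over an exhaustive fine scan of thresholds."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(label, dtype=bool)
    candidates = np.concatenate([[s.min() - 1.0], np.sort(np.unique(s)),
                                 (np.sort(np.unique(s))[:-1]
                                  + np.sort(np.unique(s))[1:]) / 2.0])
    best = -np.inf
    for t in candidates:
        pred = s > t
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        best = max(best, sens + spec - 1.0)
    return float(best)
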