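"""Independent brute-force oracles used only by the tests.

Everything here is written from the definitions, gene by gene and step by
step, deliberately not sharing code with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def _average_ranks(values):
    """1-based ranks with ties averaged, computed from first principles."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_pair_oracle(obs, ref, n_obs, n_ref, log_ratio_trim=0.3, abundance_trim=0.05):
    """Pairwise TMM factor from the published definition, by explicit loops."""
    m_vals, a_vals, weights = [], [], []
    for o, r in zip(obs, ref):
        po, pr = o / n_obs, r / n_ref
        if po <= 0 or pr <= 0:
            continue
        m_vals.append(math.log2(po / pr))
        a_vals.append((math.log2(po) + math.log2(pr)) / 2.0)
        weights.append((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    if not m_vals or max(abs(m) for m in m_vals) < 1e-6:
        return 1.0
    n = len(m_vals)
    lo_m = math.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = _average_ranks(m_vals)
    rank_a = _average_ranks(a_vals)
    num = den = 0.0
    kept = False
    for i in range(n):
        if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
            num += m_vals[i] / weights[i]
            den += 1.0 / weights[i]
            kept = True
    if not kept:
        return 1.0
    return 2.0 ** (num / den)


def tmm_factors_oracle(matrix):
    """Full TMM: reference column by upper quartile, pairwise factors,
    geometric-mean rescaling. ``matrix`` is a genes x samples array-like."""
    x = [list(map(float, row)) for row in matrix]
    n_samples = len(x[0])
    libs = [sum(row[j] for row in x) for j in range(n_samples)]
    f75 = [
        float(np.quantile([row[j] for row in x], 0.75)) / libs[j] for j in range(n_samples)
    ]
    mean_f75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda j: (abs(f75[j] - mean_f75), j))
    factors = [
        tmm_pair_oracle(
            [row[j] for row in x], [row[ref] for row in x], libs[j], libs[ref]
        )
        for j in range(n_samples)
    ]
    log_mean = sum(math.log(f) for f in factors) / n_samples
    return [f / math.exp(log_mean) for f in factors]


def logcpm_oracle(matrix, factors, prior):
    """Direct evaluation of the prior-augmented logCPM formula."""
    x = [list(map(float, row)) for row in matrix]
    n_samples = len(x[0])
    libs = [sum(row[j] for row in x) * factors[j] for j in range(n_samples)]
    mean_lib = sum(libs) / n_samples
    out = []
    for row in x:
        out_row = []
        for j in range(n_samples):
            prior_s = prior * libs[j] / mean_lib
            out_row.append(math.log2((row[j] + prior_s) / (libs[j] + 2 * prior_s) * 1e6))
        out.append(out_row)
    return out


def filter_oracle(matrix, factors, min_cpm=0.5, min_samples=4):
    """Per-gene exhaustive check of the CPM filter; returns retained row indices."""
    x = [list(map(float, row)) for row in matrix]
    n_samples = len(x[0])
    libs = [sum(row[j] for row in x) * factors[j] for j in range(n_samples)]
    retained = []
    for i, row in enumerate(x):
        qualifying = sum(1 for j in range(n_samples) if row[j] / libs[j] * 1e6 >= min_cpm)
        if qualifying >= min_samples:
            retained.append(i)
    return retained


def pearson_oracle(x, y):
    """Product-moment correlation and two-sided t-transform p-value."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, p


def summarize_oracle(x_naive, x_pain, x_treat, change_min=0.10, near_naive_max=0.15, rf_cut=1.0):
    """Exhaustive per-gene computation of every transcriptome summary.

    x_naive / x_pain: dicts gene -> value; x_treat: dict treatment -> dict.
    Returns a nested dict of the statistics on the percent scale.
    """
    genes = list(x_naive)
    pct_c = {}
    changed = []
    for g in genes:
        pct_c[g] = (x_pain[g] - x_naive[g]) / x_naive[g] * 100.0
        if abs(pct_c[g]) >= change_min * 100.0:
            changed.append(g)
    out = {
        "pct_changed": 100.0 * len(changed) / len(genes),
        "n_changed": len(changed),
        "up_share": (
            100.0 * sum(1 for g in changed if pct_c[g] > 0) / len(changed)
            if changed
            else None
        ),
        "down_share": (
            100.0 * sum(1 for g in changed if pct_c[g] < 0) / len(changed)
            if changed
            else None
        ),
        "treatments": {},
    }
    for t, xs in x_treat.items():
        rf = {}
        cscs = {}
        undefined = 0
        for g in changed:
            denom = x_pain[g] - x_naive[g]
            if denom == 0:
                undefined += 1
                continue
            rf[g] = (x_pain[g] - xs[g]) / denom
            cscs[g] = (xs[g] - x_naive[g]) / x_naive[g] * 100.0
        n_def = len(rf)
        out["treatments"][t] = {
            "n_rf_defined": n_def,
            "n_rf_undefined": undefined,
            "pct_recovered_le_one": (
                100.0 * sum(1 for g in rf if rf[g] <= rf_cut) / n_def if n_def else None
            ),
            "pct_recovered_unit_interval": (
                100.0 * sum(1 for g in rf if 0.0 <= rf[g] <= rf_cut) / n_def
                if n_def
                else None
            ),
            "pct_near_naive": (
                100.0 * sum(1 for g in cscs if abs(cscs[g]) <= near_naive_max * 100.0) / n_def
                if n_def
                else None
            ),
        }
    return out
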