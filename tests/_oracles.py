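"""Independent brute-force oracles used by the test suite.

Deliberately written in plain Python (explicit loops, ``math`` module, no
shared helpers from the package) so they cannot inherit a bug from the
implementations they check.
"""

from __future__ import annotations

import itertools
import math


def brute_abs_cosine(x, y, features):
    dot = sum(x[f] * y[f] for f in features)
    nx = math.sqrt(sum(x[f] ** 2 for f in features))
    ny = math.sqrt(sum(y[f] ** 2 for f in features))
    if nx == 0 or ny == 0:
        return 0.0
    return min(1.0, abs(dot) / (nx * ny))


def brute_soft_threshold(c, midpoint=0.75, steepness=30.0):
    return 1.0 / (1.0 + math.exp(-steepness * (c - midpoint)))


def brute_coexpr_components(gene, features, dataset, training, params, discarded=frozenset()):
    """Two explicit loops over the positive and negative partners."""
    x = {g: list(dataset.x_lr[i]) for i, g in enumerate(dataset.gene_ids)}
    c_pos = 0.0
    for p in training.positives:
        if p == gene:
            continue
        c = brute_abs_cosine(x[gene], x[p], features)
        c_pos += brute_soft_threshold(c, params.sigmoid_midpoint, params.sigmoid_steepness)
    c_neg = 0.0
    for n in training.negatives:
        if n == gene or n in discarded:
            continue
        c = brute_abs_cosine(x[gene], x[n], features)
        c_neg += brute_soft_threshold(c, params.sigmoid_midpoint, params.sigmoid_steepness)
    return c_pos, c_neg


def brute_ess(gene, features, dataset, training, params):
    c_pos, c_neg = brute_coexpr_components(gene, features, dataset, training, params)
    n = len(set(features))
    if n == 0:
        return 0.0
    alpha = n / (n + params.alpha_halfsize)
    return alpha * c_pos / (c_pos + params.beta * c_neg + 1e-12)


def brute_hypergeom_tail(universe_size, successes, draws, overlap):
    """P(X >= overlap) by enumerating every size-``draws`` subset."""
    universe = list(range(universe_size))
    success_set = set(range(successes))
    total = 0
    hits = 0
    for subset in itertools.combinations(universe, draws):
        total += 1
        if len(success_set.intersection(subset)) >= overlap:
            hits += 1
    return hits / total


def brute_rank_products_fdr(control, test):
    """Exhaustive-permutation rank-product FDR, up and down, per gene.

    ``control``/``test`` are lists of per-gene replicate lists.  Returns
    (log_ratio, fdr_up, fdr_down) with the same conventions as the
    implementation contract: average ranks for ties, the null enumerated
    over every way to assign the pooled replicate columns to the control
    group, FDR = expected null hits at the observed statistic over the
    observed rank, clamped to [0, 1].
    """
    n_genes = len(control)
    k_c = len(control[0])
    k_t = len(test[0])

    def ranks(values, reverse):
        # average ranks; rank 1 = first in sort order
        order = sorted(range(len(values)), key=lambda i: values[i], reverse=reverse)
        r = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    def rank_product(ctrl_cols, test_cols, pooled):
        log_up = [0.0] * n_genes
        log_down = [0.0] * n_genes
        n_pairs = 0
        for ci in ctrl_cols:
            for ti in test_cols:
                fc = [pooled[g][ti] / pooled[g][ci] for g in range(n_genes)]
                up = ranks(fc, reverse=True)
                down = ranks(fc, reverse=False)
                for g in range(n_genes):
                    log_up[g] += math.log(up[g])
                    log_down[g] += math.log(down[g])
                n_pairs += 1
        rp_up = [math.exp(v / n_pairs) for v in log_up]
        rp_down = [math.exp(v / n_pairs) for v in log_down]
        return rp_up, rp_down

    pooled = [list(control[g]) + list(test[g]) for g in range(n_genes)]
    n_cols = k_c + k_t
    obs_up, obs_down = rank_product(list(range(k_c)), list(range(k_c, n_cols)), pooled)

    null_up = []
    null_down = []
    n_datasets = 0
    for ctrl_cols in itertools.combinations(range(n_cols), k_c):
        test_cols = [c for c in range(n_cols) if c not in ctrl_cols]
        nu, nd = rank_product(list(ctrl_cols), test_cols, pooled)
        null_up.extend(nu)
        null_down.extend(nd)
        n_datasets += 1

    def fdr(obs, null):
        out = []
        for g in range(n_genes):
            exp_hits = sum(1 for v in null if v <= obs[g]) / n_datasets
            rank_obs = sum(1 for v in obs if v <= obs[g])
            out.append(min(1.0, exp_hits / rank_obs))
        return out

    log_ratio = [
        math.log2(
            (sum(test[g]) / k_t) / (sum(control[g]) / k_c)
        )
        for g in range(n_genes)
    ]
    return log_ratio, fdr(obs_up, null_up), fdr(obs_down, null_down)


def brute_fbeta(tp, fp, fn, beta):
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    if beta * beta * r + p == 0:
        return 0.0
    return (1 + beta * beta) * p * r / (beta * beta * r + p)
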