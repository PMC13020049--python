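"""Independent oracles shared by the test suite.

Everything here is deliberately naive (dense linear algebra, double loops,
explicit enumeration) and independent of the library code paths it checks.
"""

import itertools

import numpy as np

import phenoprop as pp


def dense_pagerank(network, seeds, damping, weighted=True):
    """Direct linear-system solution of x = d·Pᵀx + (1−d)r."""
    n = network.n_nodes
    W = network.adjacency.toarray().astype(float)
    if not weighted:
        W = (W > 0).astype(float)
    P = W / W.sum(axis=1, keepdims=True)  # row-stochastic
    r = np.zeros(n)
    idx = network.indices_of(sorted(set(seeds)))
    r[idx] = 1.0 / len(idx)
    return np.linalg.solve(np.eye(n) - damping * P.T, (1.0 - damping) * r)


def random_er_network(rng, n, p=0.06):
    """Connected-ish random weighted graph (a spanning path guarantees
    every node has an edge)."""
    genes = [f"N{i:03d}" for i in range(n)]
    edges = [(genes[i], genes[i + 1], float(rng.uniform(0.4, 1.0)))
             for i in range(n - 1)]
    for i in range(n):
        for j in range(i + 2, n):
            if rng.random() < p:
                edges.append((genes[i], genes[j], float(rng.uniform(0.4, 1.0))))
    return pp.InteractionNetwork.from_edges(edges)


def concordance_auroc(y, s):
    """Brute-force pairwise concordance with half-credit for ties."""
    y = np.asarray(y, dtype=bool)
    s = np.asarray(s, dtype=float)
    total = conc = 0.0
    for i in np.flatnonzero(y):
        for j in np.flatnonzero(~y):
            total += 1
            if s[i] > s[j]:
                conc += 1
            elif s[i] == s[j]:
                conc += 0.5
    return conc / total


def sweep_pr_auc(y, s):
    """Step-integral average precision from an explicit threshold sweep."""
    y = np.asarray(y, dtype=int)
    s = np.asarray(s, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    s = s[order]
    n_pos = y.sum()
    tp = fp = 0
    area = 0.0
    prev_recall = 0.0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # process tied scores together
            j += 1
        tp += y[i:j].sum()
        fp += (j - i) - y[i:j].sum()
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def sweep_partial_auroc(y, s, max_fpr=0.05):
    """Brute-force partial ROC area with McClish standardization."""
    y = np.asarray(y, dtype=int)
    s = np.asarray(s, dtype=float)
    thresholds = np.unique(s)[::-1]
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    fprs, tprs = [0.0], [0.0]
    for t in thresholds:
        pred = s >= t
        tprs.append((pred & (y == 1)).sum() / n_pos)
        fprs.append((pred & (y == 0)).sum() / n_neg)
    fprs, tprs = np.array(fprs), np.array(tprs)
    # interpolate the ROC curve at max_fpr, then trapezoid over [0, max_fpr]
    keep = fprs <= max_fpr
    xs = fprs[keep].tolist()
    ys = tprs[keep].tolist()
    if xs[-1] < max_fpr:
        nxt = np.searchsorted(fprs, max_fpr)
        x0, x1 = fprs[nxt - 1], fprs[nxt]
        y0, y1 = tprs[nxt - 1], tprs[nxt]
        ys.append(y0 + (y1 - y0) * (max_fpr - x0) / (x1 - x0))
        xs.append(max_fpr)
    area = np.trapezoid(ys, xs)
    min_area = 0.5 * max_fpr ** 2
    max_area = max_fpr
    return 0.5 * (1.0 + (area - min_area) / (max_area - min_area))


def exact_ranksum_greater_p(x, y):
    """Exact one-sided (greater) rank-sum p-value by full enumeration.

    Enumerates every assignment of the combined sample into groups of the
    observed sizes; feasible only for tiny inputs.
    """
    from scipy.stats import rankdata

    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    n1 = len(x)
    obs = ranks[:n1].sum()
    count = total = 0
    for subset in itertools.combinations(range(len(combined)), n1):
        total += 1
        if ranks[list(subset)].sum() >= obs:
            count += 1
    return count / total
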