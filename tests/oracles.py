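"""Independent brute-force oracles used by the test suite.

Every function here is a direct, loop-level transcription of the
defining formula, kept deliberately naive and separate from the package
implementation it checks.
"""

import numpy as np


def mtd_oracle(data: np.ndarray, w: int) -> np.ndarray:
    """Triple-loop MTD: windowed mean of standardised derivative products."""
    t, n = data.shape
    d = np.empty((t - 1, n))
    for u in range(1, t):
        d[u - 1] = data[u] - data[u - 1]
    sigma = d.std(axis=0)
    n_win = (t - 1) - w + 1
    out = np.zeros((n, n, n_win))
    for k, s in enumerate(range(n_win)):
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for u in range(s, s + w):
                    acc += d[u, i] * d[u, j] / (sigma[i] * sigma[j])
                out[i, j, k] = acc / w
    return out


def signed_modularity_oracle(w: np.ndarray, partition: np.ndarray, gamma: float) -> float:
    """Direct double-sum of the asymmetric signed modularity formula."""
    n = w.shape[0]
    wp = np.where(w > 0, w, 0.0).copy()
    wn = np.where(w < 0, -w, 0.0).copy()
    np.fill_diagonal(wp, 0.0)
    np.fill_diagonal(wn, 0.0)
    vp, vn = wp.sum(), wn.sum()
    sp, sn = wp.sum(axis=1), wn.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if partition[i] != partition[j]:
                continue
            q += (wp[i, j] - gamma * sp[i] * sp[j] / vp) / vp
            if vn > 0:
                q -= (wn[i, j] - gamma * sn[i] * sn[j] / vn) / (vp + vn)
    return q


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1 :]
        yield [[first]] + smaller


def all_partition_labelings(n):
    """Every partition of n nodes as a label vector."""
    for blocks in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for m, block in enumerate(blocks):
            for i in block:
                labels[i] = m + 1
        yield labels


def module_degree_z_oracle(w: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Loop evaluation of the within-module degree z-score (positive weights)."""
    n = w.shape[0]
    wp = np.where(w > 0, w, 0.0).copy()
    np.fill_diagonal(wp, 0.0)
    kappa = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if partition[j] == partition[i]:
                kappa[i] += wp[i, j]
    z = np.zeros(n)
    for m in np.unique(partition):
        members = np.flatnonzero(partition == m)
        mu = kappa[members].mean()
        sd = kappa[members].std()
        if sd > 0:
            z[members] = (kappa[members] - mu) / sd
    return z


def participation_oracle(w: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Loop evaluation of the participation coefficient (positive weights)."""
    n = w.shape[0]
    wp = np.where(w > 0, w, 0.0).copy()
    np.fill_diagonal(wp, 0.0)
    mods = np.unique(partition)
    b = np.zeros(n)
    for i in range(n):
        ki = wp[i].sum()
        if ki == 0:
            continue
        acc = 0.0
        for m in mods:
            kis = wp[i, partition == m].sum()
            acc += (kis / ki) ** 2
        b[i] = 1.0 - acc
    return b


def fdr_bh_oracle(pvals: np.ndarray, q: float) -> np.ndarray:
    """Brute-force BH: scan all candidate thresholds p_(k) <= k q / m."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject
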