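"""Independent brute-force reference implementations used by the test suite.

These deliberately naive O(n^2)-style routines re-derive the same quantities
as the package's optimised code paths and are kept free of any shared logic
with them.
"""

import numpy as np


def brute_force_bursts(times, rate_threshold=5, window_s=1000e-6, min_photons=50):
    """Per-photon centred-window count, qualifying runs split at window gaps."""
    n = times.size
    qualify = np.zeros(n, dtype=bool)
    for i in range(n):
        qualify[i] = np.sum(np.abs(times - times[i]) <= window_s / 2) >= rate_threshold
    runs, start = [], None
    for i in range(n + 1):
        q = qualify[i] if i < n else False
        if q and start is not None and times[i] - times[i - 1] > window_s:
            if i - start >= min_photons:
                runs.append((start, i))
            start = i
            continue
        if q and start is None:
            start = i
        elif not q and start is not None:
            if i - start >= min_photons:
                runs.append((start, i))
            start = None
    return runs


def brute_force_multitau(counts, bin_width_s, n_per_level=16, max_lag_s=None):
    """Direct correlator on the same coarsened traces as the multi-tau scheme."""
    x = np.asarray(counts, dtype=float)
    lags, gs = [], []
    width, level = bin_width_s, 0
    while True:
        ks = (range(1, n_per_level + 1) if level == 0
              else range(n_per_level // 2 + 1, n_per_level + 1))
        done = False
        for k in ks:
            if k >= x.size or (max_lag_s is not None and k * width > max_lag_s):
                done = True
                break
            left, right = x[: x.size - k], x[k:]
            num = 0.0
            for i in range(left.size):       # deliberately naive per-lag loop
                num += left[i] * right[i]
            num /= left.size
            lags.append(k * width * 1e3)
            gs.append(num / (left.mean() * right.mean()) - 1.0)
        if done:
            break
        n2 = (x.size // 2) * 2
        x = x[:n2:2] + x[1:n2:2]
        width *= 2.0
        level += 1
        if x.size < n_per_level + 1:
            break
    return np.asarray(lags), np.asarray(gs)


def brute_force_chain_clusters(frame, topology, box, cutoff=7.0):
    """Union-find over all chain pairs with an explicit bead-pair scan."""
    n_res, n_chains = topology.n_res, topology.n_chains
    pos = frame.reshape(n_chains, n_res, 3)
    parent = list(range(n_chains))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for a in range(n_chains):
        for b in range(a + 1, n_chains):
            touching = False
            for i in range(n_res):
                for j in range(n_res):
                    d = pos[a, i] - pos[b, j]
                    if box > 0:
                        d = d - box * np.round(d / box)
                    if np.dot(d, d) < cutoff**2:
                        touching = True
                        break
                if touching:
                    break
            if touching:
                parent[find(a)] = find(b)
    roots = [find(c) for c in range(n_chains)]
    groups = {}
    for c, r in enumerate(roots):
        groups.setdefault(r, []).append(c)
    return {frozenset(g) for g in groups.values()}
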