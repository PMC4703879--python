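"""Event-driven structured-coalescent kernel.

Simulates genealogies for two populations (W, D) plus their ancestor under a
piecewise-constant demography and accumulates, for every branch, its length
into the joint-SFS cell indexed by the branch's number of descendant tips in
each population.  Expected mutation counts per cell are mu * L * E[length],
so this one kernel serves both the expected joint SFS (normalised branch
lengths) and exact SFS sampling (Poisson draws on summed lengths).

The demography is passed as parallel per-interval arrays; interval ``b``
spans ``[times[b], times[b+1])`` in generations before present.  After the
interval flagged ``merged`` all D lineages live in W (the ancestor), and the
wrapper zeroes migration there.  Migration rates are backwards-in-time
per-lineage movement probabilities per generation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event budget per tree, as a multiple of sample size (guards non-coalescing
# parameterisations such as m=0 with merged never reached)
_EVENT_FACTOR = 10_000


@njit(cache=True)
def _simulate_branch_lengths(
    seed,
    n_trees,
    n_w,
    n_d,
    times,
    size_w,
    size_d,
    mig_wd,
    mig_dw,
    merged,
    out,
):  # pragma: no cover - exercised via wrappers
    np.random.seed(seed)
    n = n_w + n_d
    tot_nodes = 2 * n - 1
    desc_w = np.empty(tot_nodes, np.int64)
    desc_d = np.empty(tot_nodes, np.int64)
    birth = np.empty(tot_nodes, np.float64)
    idx_w = np.empty(n, np.int64)
    idx_d = np.empty(n, np.int64)
    max_events = _EVENT_FACTOR * n
    n_intervals = times.shape[0]

    for _ in range(n_trees):
        for i in range(n_w):
            idx_w[i] = i
            desc_w[i] = 1
            desc_d[i] = 0
            birth[i] = 0.0
        for i in range(n_d):
            j = n_w + i
            idx_d[i] = j
            desc_w[j] = 0
            desc_d[j] = 1
            birth[j] = 0.0
        k_w = n_w
        k_d = n_d
        b = 0
        t = 0.0
        if merged[0] == 1 and k_d > 0:
            for i in range(k_d):
                idx_w[k_w + i] = idx_d[i]
            k_w += k_d
            k_d = 0
        node = n
        events = 0
        while k_w + k_d > 1:
            events += 1
            if events > max_events:
                return 1
            r_cw = k_w * (k_w - 1) / (4.0 * size_w[b])
            r_cd = k_d * (k_d - 1) / (4.0 * size_d[b])
            r_mw = k_w * mig_wd[b]
            r_md = k_d * mig_dw[b]
            rate = r_cw + r_cd + r_mw + r_md
            if rate <= 0.0:
                if b + 1 >= n_intervals:
                    return 1
                t = times[b + 1]
                b += 1
                if merged[b] == 1 and k_d > 0:
                    for i in range(k_d):
                        idx_w[k_w + i] = idx_d[i]
                    k_w += k_d
                    k_d = 0
                continue
            dt = np.random.exponential(1.0 / rate)
            if b + 1 < n_intervals and t + dt >= times[b + 1]:
                t = times[b + 1]
                b += 1
                if merged[b] == 1 and k_d > 0:
                    for i in range(k_d):
                        idx_w[k_w + i] = idx_d[i]
                    k_w += k_d
                    k_d = 0
                continue
            t += dt
            u = np.random.random() * rate
            if u < r_cw:
                i = np.random.randint(0, k_w)
                j = np.random.randint(0, k_w - 1)
                if j >= i:
                    j += 1
                a = idx_w[i]
                c = idx_w[j]
                out[desc_w[a], desc_d[a]] += t - birth[a]
                out[desc_w[c], desc_d[c]] += t - birth[c]
                desc_w[node] = desc_w[a] + desc_w[c]
                desc_d[node] = desc_d[a] + desc_d[c]
                birth[node] = t
                if i > j:
                    i, j = j, i
                idx_w[i] = node
                idx_w[j] = idx_w[k_w - 1]
                k_w -= 1
                node += 1
            elif u < r_cw + r_cd:
                i = np.random.randint(0, k_d)
                j = np.random.randint(0, k_d - 1)
                if j >= i:
                    j += 1
                a = idx_d[i]
                c = idx_d[j]
                out[desc_w[a], desc_d[a]] += t - birth[a]
                out[desc_w[c], desc_d[c]] += t - birth[c]
                desc_w[node] = desc_w[a] + desc_w[c]
                desc_d[node] = desc_d[a] + desc_d[c]
                birth[node] = t
                if i > j:
                    i, j = j, i
                idx_d[i] = node
                idx_d[j] = idx_d[k_d - 1]
                k_d -= 1
                node += 1
            elif u < r_cw + r_cd + r_mw:
                i = np.random.randint(0, k_w)
                a = idx_w[i]
                idx_w[i] = idx_w[k_w - 1]
                k_w -= 1
                idx_d[k_d] = a
                k_d += 1
            else:
                i = np.random.randint(0, k_d)
                a = idx_d[i]
                idx_d[i] = idx_d[k_d - 1]
                k_d -= 1
                idx_w[k_w] = a
                k_w += 1
    return 0


def branch_length_matrix(seed, n_trees, n_w, n_d, arrays):
    """Summed branch lengths (generations) per joint-SFS cell over n_trees.

    ``arrays`` is the tuple produced by DemographicModel.to_kernel_arrays().
    Cell (i, j) holds the total length of branches ancestral to exactly i of
    the n_w W tips and j of the n_d D tips.
    """
    times, size_w, size_d, mig_wd, mig_dw, merged = arrays
    out = np.zeros((n_w + 1, n_d + 1), dtype=np.float64)
    status = _simulate_branch_lengths(
        np.uint32(seed % (2**32)),
        int(n_trees),
        int(n_w),
        int(n_d),
        times,
        size_w,
        size_d,
        mig_wd,
        mig_dw,
        merged,
        out,
    )
    if status != 0:
        raise RuntimeError(
            "coalescent did not complete within the event budget; "
            "check that the demography lets all lineages reach a common "
            "ancestral population (e.g. m=0 requires a finite divergence time)"
        )
    return out
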