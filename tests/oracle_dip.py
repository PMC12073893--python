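"""Exact dip via linear programming, used to fuzz the fast algorithm.

dip(F_n) = min over unimodal CDFs G of sup_x |F_n(x) - G(x)|.

Work on distinct values v_1..v_K with cumulative counts c_j (F_n(v_j) = c_j/n).
A unimodal G is convex left of its mode, concave right of it, and continuous
everywhere except for an optional atom at the mode.  Band constraints at v_j
for a continuous point: c_j/n - d <= g_j <= c_{j-1}/n + d.  Mode cases:
  * atom at v_j: split g_j into left/right limits, convex chords end at the
    left limit, concave chords start at the right limit;
  * mode in the open gap (v_j, v_{j+1}): two extreme placements (just right
    of v_j / just left of v_{j+1}) give the weakest constraint sets.
The dip is the min over all cases of the LP optimum of d.
"""
import numpy as np
from scipy.optimize import linprog


def dip_lp(values):
    x = np.sort(np.asarray(values, float))
    n = x.size
    if n == 1 or x[0] == x[-1]:
        return 0.0
    v, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts) / n           # F at each distinct value
    cl = c - counts / n                 # F left-limits
    K = v.size
    best = np.inf
    # mode in gap j (between v_j and v_{j+1}), 0-based: j = -1..K-1; variants
    for j in range(-1, K):
        for conv_end in (j + 1, j + 2):     # number of leading points convex
            val = _solve_gap(v, c, cl, conv_end)
            if val is not None:
                best = min(best, val)
    # atom at v_j
    for j in range(K):
        val = _solve_atom(v, c, cl, j)
        if val is not None:
            best = min(best, val)
    return best


def _shape_rows(nv, v, idxs, gmap, concave):
    """Second-difference rows over consecutive point triples in idxs."""
    A, b = [], []
    for t in range(len(idxs) - 2):
        i0, i1, i2 = idxs[t], idxs[t + 1], idxs[t + 2]
        dx1 = v[i1] - v[i0]
        dx2 = v[i2] - v[i1]
        row = np.zeros(nv)
        # convex: (g2-g1)dx1 - (g1-g0)dx2 >= 0
        row[gmap[t]] = -dx2
        row[gmap[t + 1]] = dx1 + dx2
        row[gmap[t + 2]] = -dx1
        # row holds -(convexity expression); convex wants expr >= 0
        A.append(-row if concave else row)
        b.append(0.0)
    return A, b


def _base_lp(K):
    nv = K + 2          # g_0..g_{K-1}, extra slot (atom right limit), d
    c_obj = np.zeros(nv)
    c_obj[-1] = 1.0
    return nv, c_obj


def _solve_gap(v, c, cl, conv_end):
    K = v.size
    nv, c_obj = _base_lp(K)
    d_i = nv - 1
    A, b = [], []
    for i in range(K):  # band
        row = np.zeros(nv); row[i] = -1; row[d_i] = -1
        A.append(row); b.append(-c[i])
        row = np.zeros(nv); row[i] = 1; row[d_i] = -1
        A.append(row); b.append(cl[i])
    for i in range(K - 1):  # monotone
        row = np.zeros(nv); row[i] = 1; row[i + 1] = -1
        A.append(row); b.append(0.0)
    ce = min(max(conv_end, 0), K)
    conv_idx = list(range(ce))
    # the concave chain starts at the last convex point: the chord across the
    # mode gap is bounded by the secant from that point
    conc_idx = list(range(max(ce - 1, 0), K))
    a2, b2 = _shape_rows(nv, v, conv_idx, conv_idx, concave=False)
    A += a2; b += b2
    a2, b2 = _shape_rows(nv, v, conc_idx, conc_idx, concave=True)
    A += a2; b += b2
    bounds = [(0.0, 1.0)] * (nv - 1) + [(0.0, 1.0)]
    res = linprog(c_obj, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds, method="highs")
    return res.fun if res.success else None


def _solve_atom(v, c, cl, j):
    K = v.size
    nv, c_obj = _base_lp(K)
    d_i = nv - 1
    gr = nv - 2          # right limit of G at the mode atom v_j; g_j is the left limit
    A, b = [], []
    for i in range(K):
        if i == j:
            # left limit vs F left-limit; right limit vs F value
            row = np.zeros(nv); row[i] = 1; row[d_i] = -1
            A.append(row); b.append(cl[i])
            row = np.zeros(nv); row[gr] = -1; row[d_i] = -1
            A.append(row); b.append(-c[i])
            row = np.zeros(nv); row[gr] = 1; row[d_i] = -1
            A.append(row); b.append(c[i])
        else:
            row = np.zeros(nv); row[i] = -1; row[d_i] = -1
            A.append(row); b.append(-c[i])
            row = np.zeros(nv); row[i] = 1; row[d_i] = -1
            A.append(row); b.append(cl[i])
    # monotone: ... g_{j-1} <= g_j <= gr <= g_{j+1} ...
    order = list(range(0, j + 1)) + [gr] + list(range(j + 1, K))
    for t in range(len(order) - 1):
        row = np.zeros(nv); row[order[t]] = 1; row[order[t + 1]] = -1
        A.append(row); b.append(0.0)
    # convex through points 0..j (g_j = left limit), concave through
    # (v_j, gr), v_{j+1}, ..., v_{K-1}
    conv_pts = list(range(j + 1))
    a2, b2 = _shape_rows(nv, v, conv_pts, conv_pts, concave=False)
    A += a2; b += b2
    conc_pts = [j] + list(range(j + 1, K))
    gmap = [gr] + list(range(j + 1, K))
    a2, b2 = _shape_rows(nv, v, conc_pts, gmap, concave=True)
    A += a2; b += b2
    bounds = [(0.0, 1.0)] * nv
    res = linprog(c_obj, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds, method="highs")
    return res.fun if res.success else None
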