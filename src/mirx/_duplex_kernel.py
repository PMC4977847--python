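"""Numba kernel for the intermolecular duplex dynamic program.

State ``E[i, j]`` is the minimum free energy of a duplex whose 3'-most miRNA
pair is (miRNA position ``i``, target position ``j``), including one helix-end
penalty at the duplex start.  The duplex is antiparallel: earlier miRNA
positions pair with later target positions, so predecessors of (i, j) are
cells (i2, j2) with i2 < i and j2 > j.  Gaps between consecutive pairs are a
stack (0/0), a bulge (one-sided) or an internal loop (two-sided), with
length-linear penalties and optional hard caps.
"""

import numpy as np
from numba import njit

INF = 1e18


@njit(cache=False)
def duplex_dp(mir, tgt, pair_index, stack, bulge_base, bulge_slope,
              loop_base, loop_slope, end_pen, max_bulge, max_loop):
    m = mir.shape[0]
    n = tgt.shape[0]
    E = np.full((m, n), INF)
    bt = np.full((m, n, 2), -1, dtype=np.int32)
    gap_cap = max_bulge if max_bulge > max_loop else max_loop
    for i in range(m):
        for j in range(n):
            q = pair_index[mir[i], tgt[j]]
            if q < 0:
                continue
            best = end_pen  # open a new helix at this pair
            bi = -1
            bj = -1
            i_lo = i - 1 - gap_cap
            if i_lo < 0:
                i_lo = 0
            j_hi = j + 2 + gap_cap
            if j_hi > n:
                j_hi = n
            for i2 in range(i - 1, i_lo - 1, -1):
                a = i - i2 - 1
                for j2 in range(j + 1, j_hi):
                    e2 = E[i2, j2]
                    if e2 >= INF * 0.5:
                        continue
                    b = j2 - j - 1
                    if a == 0 and b == 0:
                        pen = stack[pair_index[mir[i2], tgt[j2]], q]
                    elif b == 0:
                        if a > max_bulge:
                            continue
                        pen = bulge_base + bulge_slope * a
                    elif a == 0:
                        if b > max_bulge:
                            continue
                        pen = bulge_base + bulge_slope * b
                    else:
                        if a > max_loop or b > max_loop:
                            continue
                        pen = loop_base + loop_slope * (a + b)
                    cand = e2 + pen
                    if cand < best:
                        best = cand
                        bi = i2
                        bj = j2
            E[i, j] = best
            bt[i, j, 0] = bi
            bt[i, j, 1] = bj
    return E, bt
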