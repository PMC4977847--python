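"""Exhaustive reference implementations used for validation.

`enumerate_duplex_mfe` scores every admissible non-crossing intermolecular
pairing by explicit recursion over structures (no memoization), so it is an
independent check on the dynamic program.  Only practical for short
sequences (roughly |miRNA| <= 10, |window| <= 12).
"""

from __future__ import annotations

import math

from .energy import PAIR_ORDER, EnergyModel, default_energy_model


def enumerate_duplex_mfe(mirna_seq: str, window: str,
                         model: EnergyModel | None = None,
                         caps: dict | None = None) -> float:
    """Minimum energy over all non-empty non-crossing antiparallel pairings.

    Returns ``math.inf`` when no admissible pair exists.
    """
    model = model or default_energy_model()
    m, n = len(mirna_seq), len(window)
    big = m + n
    max_bulge = big if caps is None or caps.get("max_bulge") is None \
        else caps["max_bulge"]
    max_loop = big if caps is None or caps.get("max_loop") is None \
        else caps["max_loop"]
    pidx = [[-1] * n for _ in range(m)]
    for i in range(m):
        for j in range(n):
            pq = mirna_seq[i] + window[j]
            if pq in PAIR_ORDER:
                pidx[i][j] = PAIR_ORDER.index(pq)
    end = model.helix_end_penalty
    best = math.inf

    def extend(i0: int, j0: int, p0: int, acc: float):
        nonlocal best
        for i in range(i0 + 1, m):
            a = i - i0 - 1
            for j in range(j0 - 1, -1, -1):
                p = pidx[i][j]
                if p < 0:
                    continue
                b = j0 - j - 1
                if a == 0 and b == 0:
                    pen = model.stack[p0, p]
                elif b == 0:
                    if a > max_bulge:
                        continue
                    pen = model.bulge_penalty(a)
                elif a == 0:
                    if b > max_bulge:
                        continue
                    pen = model.bulge_penalty(b)
                else:
                    if a > max_loop or b > max_loop:
                        continue
                    pen = model.internal_loop_penalty(a, b)
                e = acc + pen
                if e + end < best:
                    best = e + end
                extend(i, j, p, e)

    for i in range(m):
        for j in range(n):
            p = pidx[i][j]
            if p < 0:
                continue
            if 2 * end < best:
                best = 2 * end
            extend(i, j, p, end)
    return best
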