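"""Independent straight-line transcription of the four model steps.

Deliberately written as one flat function per quantity, with no reuse of
the package's code paths, to serve as the equivalence oracle in tests.
"""

import math


def uptake_oracle(si, sj, ai, di, aj, dj, ri, rj):
    """Piecewise uptake of nutrient i given supplies of i and j."""
    sj_net = sj - rj
    if sj_net < 0.0:
        sj_net = 0.0
    if si < ri + sj_net * aj / di:
        return si
    if si > ri + sj_net * (2.0 * dj / ai - aj / di):
        return ri + sj_net * dj / ai
    if sj_net == 0.0:
        return min(si, ri)
    num = (si - ri - sj_net * aj / di) ** 2
    den = sj_net * (dj / ai - aj / di)
    return si - 0.25 * num / den


def yield_range_oracle(u, a, d, r):
    if u <= r:
        return 0.0, 0.0
    return a * (u - r), d * (u - r)


def pair_yield_oracle(ui, ai, di, ri, yja, yjd, ykd, ymax):
    m = min(yjd, ykd, ymax)
    if m <= yja:
        return yja
    lo = yja / di
    hi = m / ai
    if hi <= lo:
        return yja
    x = ui - ri
    if x < lo:
        x = lo
    if x > hi:
        x = hi
    t = (x - lo) / (hi - lo)
    return yja + 2.0 * (m - yja) * t - (m - yja) * t * t


def ultimate_yield_oracle(sn, sp, sk, a, d, r, ymax, combine="min"):
    """Full chain on one supply triple; coefficient dicts keyed N/P/K."""
    s = {"N": sn, "P": sp, "K": sk}
    names = ("N", "P", "K")
    pair_u = {}
    for i in names:
        for j in names:
            if i == j:
                continue
            pair_u[(i, j)] = uptake_oracle(
                s[i], s[j], a[i], d[i], a[j], d[j], r[i], r[j]
            )
    u = {}
    for i in names:
        vals = [pair_u[(i, j)] for j in names if j != i]
        u[i] = min(vals) if combine == "min" else sum(vals) / len(vals)
    ranges = {i: yield_range_oracle(u[i], a[i], d[i], r[i]) for i in names}
    for i in names:
        if u[i] <= r[i]:
            return 0.0, u
    total = 0.0
    for i in names:
        for j in names:
            if i == j:
                continue
            k = next(x for x in names if x not in (i, j))
            total += pair_yield_oracle(
                u[i], a[i], d[i], r[i],
                ranges[j][0], ranges[j][1], ranges[k][1], ymax,
            )
    yu = total / 6.0
    if yu < 0.0:
        yu = 0.0
    if yu > ymax:
        yu = ymax
    return yu, u
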