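"""Independent straight-line reimplementation of the scoring chain.

Deliberately shares no code with the package: plain floats, explicit loops,
written directly from the algorithm's step list.  Used only as a
cross-check oracle in tests.
"""

import math


def oracle_owod(values, targets, acceptables):
    """Score one record; ``values``/``targets``/``acceptables`` are aligned lists."""
    n = len(values)
    ndtc = []
    ndta = []
    entropies = []
    for c, t, a in zip(values, targets, acceptables):
        dtc = math.sqrt((t - c) ** 2)
        dta = math.sqrt((t - a) ** 2)
        n_tc = dtc / a * 100.0
        n_ta = dta / a * 100.0
        ndtc.append(n_tc)
        ndta.append(n_ta)
        tot = n_tc + n_ta
        if tot > 0:
            rtc = n_tc / tot
            rta = n_ta / tot
        else:
            rtc = rta = 0.5
        h = 0.0
        if rtc > 0:
            h -= rtc * math.log2(rtc)
        if rta > 0:
            h -= rta * math.log2(rta)
        entropies.append(h)

    ep = 1.0  # balanced two-class prior
    ig = sum(entropies) / n
    gain = ep - ig
    ratios = [h / gain for h in entropies]
    s = sum(ratios)
    if s > 0:
        weights = [r / s for r in ratios]
    else:
        weights = [1.0 / n] * n

    wd = [w * abs(n_ta - n_tc) for w, n_tc, n_ta in zip(weights, ndtc, ndta)]
    lo = min(wd)
    hi = max(wd)
    if hi - lo <= 1e-12:
        nwd = [0.5] * n
    else:
        nwd = [(x - lo) / (hi - lo) for x in wd]
    return sum(nwd) / n
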