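"""Independent literal transcriptions of the five statistics.

Pure-Python, per-gene, list-based implementations used as oracles
against the vectorized package code.  Deliberately numpy-free except
for input coercion; medians/quantiles are hand-written.
"""

from __future__ import annotations

import math


def clean(values):
    return [float(v) for v in values if not math.isnan(float(v))]


def median_(values):
    v = sorted(values)
    n = len(v)
    if n == 0:
        raise ValueError("median of empty list")
    mid = n // 2
    if n % 2:
        return v[mid]
    return (v[mid - 1] + v[mid]) / 2.0


def type7_quantile(values, p):
    """Linear interpolation between order statistics at h = (n-1)p."""
    v = sorted(values)
    n = len(v)
    if n == 0:
        raise ValueError("quantile of empty list")
    h = (n - 1) * p
    lo = math.floor(h)
    frac = h - lo
    if lo + 1 >= n:
        return v[-1]
    return v[lo] + frac * (v[lo + 1] - v[lo])


def mad_(values):
    med = median_(values)
    return 1.4826 * median_([abs(x - med) for x in values])


def cutoff_(values):
    q75 = type7_quantile(values, 0.75)
    q25 = type7_quantile(values, 0.25)
    return q75 + (q75 - q25)


def t_oracle(normal, disease):
    normal, disease = clean(normal), clean(disease)
    n1, n2 = len(normal), len(disease)
    if n1 < 2 or n2 < 2:
        return None
    m1 = sum(normal) / n1
    m2 = sum(disease) / n2
    ss = sum((x - m1) ** 2 for x in normal) + sum((x - m2) ** 2 for x in disease)
    s2 = ss / (n1 + n2 - 2)
    if s2 <= 0:
        return None
    return (m2 - m1) / (math.sqrt(s2) * math.sqrt(1.0 / n1 + 1.0 / n2))


def copa_oracle(normal, disease, r=90):
    normal, disease = clean(normal), clean(disease)
    if not normal or not disease:
        return None
    allv = normal + disease
    med = median_(allv)
    mad = mad_(allv)
    if mad <= 0:
        return None
    z = [(x - med) / mad for x in disease]
    return type7_quantile(z, r / 100.0)


def os_oracle(normal, disease):
    normal, disease = clean(normal), clean(disease)
    if not normal or not disease:
        return None
    allv = normal + disease
    med = median_(allv)
    mad = mad_(allv)
    if mad <= 0:
        return None
    b = cutoff_(allv)
    return sum((x - med) / mad for x in disease if x > b)


def ort_oracle(normal, disease):
    normal, disease = clean(normal), clean(disease)
    if len(normal) < 2 or not disease:
        return None
    med1 = median_(normal)
    med2 = median_(disease)
    centred = [x - med1 for x in normal] + [x - med2 for x in disease]
    mad_star = 1.4826 * median_([abs(c) for c in centred])
    if mad_star <= 0:
        return None
    b_normal = cutoff_(normal)
    return sum((x - med1) / mad_star for x in disease if x > b_normal)


def gti_group_oracle(values, b):
    values = clean(values)
    if not values:
        raise ValueError("empty group")
    if b <= 0:
        return None
    above = [v for v in values if v > b]
    if not above:
        return 0.0
    mean_above = sum(above) / len(above)
    return 100.0 * (len(above) / len(values)) * ((mean_above - b) / b)


def gti_oracle(normal, disease):
    normal, disease = clean(normal), clean(disease)
    if not normal or not disease:
        return None
    b = cutoff_(normal + disease)
    if b <= 0:
        return None
    return gti_group_oracle(disease, b) - gti_group_oracle(normal, b)


ORACLES = {
    "t": t_oracle,
    "copa": copa_oracle,
    "os": os_oracle,
    "ort": ort_oracle,
    "gti": gti_oracle,
}


def spearman_oracle(x, y):
    """Rank-then-Pearson with average ranks for ties."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
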