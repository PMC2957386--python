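"""Explicit-enumeration one-way ANOVA oracle, independent of the package.

Computes SSW/SSB by double loops over the raw ratings and pools SI kappa
dummy-by-dummy; used to cross-check the package's streaming estimators.
"""

from __future__ import annotations


def oracle_components(units):
    allv = [float(x) for u in units for x in u]
    n = len(allv)
    k = len(units)
    grand = sum(allv) / n
    ssw = 0.0
    for u in units:
        m = sum(u) / len(u)
        for x in u:
            ssw += (x - m) ** 2
    ssb = 0.0
    for u in units:
        m = sum(u) / len(u)
        ssb += len(u) * (m - grand) ** 2
    ms_within = ssw / (n - k)
    ms_between = ssb / (k - 1)
    n0 = (n - sum(len(u) ** 2 for u in units) / n) / (k - 1)
    raw = (ms_between - ms_within) / n0
    return {
        "ms_within": ms_within,
        "ms_between": ms_between,
        "n0": n0,
        "sigma2_article": max(0.0, raw),
        "sigma2_error": ms_within,
        "truncated": raw < 0,
    }


def oracle_icc(units):
    c = oracle_components(units)
    den = c["sigma2_article"] + c["sigma2_error"]
    return None if den == 0 else c["sigma2_article"] / den


def oracle_si(units, categories):
    num = 0.0
    den = 0.0
    for cat in categories:
        c = oracle_components(
            [[1.0 if x == cat else 0.0 for x in u] for u in units]
        )
        num += c["sigma2_article"]
        den += c["sigma2_article"] + c["sigma2_error"]
    return None if den == 0 else num / den
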