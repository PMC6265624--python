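"""Brute-force reference implementations used only by the test suite.

Each function is written directly from the defining algebra, independent
of the package's vectorised code paths.
"""

import math


def brute_mh_log_or(cells):
    """Mantel-Haenszel pooled log OR from a list of (a, b, c, d) rows."""
    num = den = 0.0
    for a, b, c, d in cells:
        n = a + b + c + d
        num += a * d / n
        den += b * c / n
    return math.log(num / den)


def brute_dl_mu_tau(effects):
    """DerSimonian-Laird pooled mean and tau^2 from per-study effects."""
    y = [e.log_or for e in effects]
    v = [e.se * e.se for e in effects]
    w = [1.0 / vi for vi in v]
    sw = sum(w)
    mu_fixed = sum(wi * yi for wi, yi in zip(w, y)) / sw
    q = sum(wi * (yi - mu_fixed) ** 2 for wi, yi in zip(w, y))
    tau2 = max(0.0, (q - (len(y) - 1)) / (sw - sum(wi * wi for wi in w) / sw))
    ws = [1.0 / (vi + tau2) for vi in v]
    return sum(wi * yi for wi, yi in zip(ws, y)) / sum(ws), tau2


def brute_kendall(x, y):
    """Kendall tau-b and its tie-corrected normal z by explicit counting of
    concordant, discordant and tied pairs."""
    n = len(x)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            prod = (x[j] - x[i]) * (y[j] - y[i])
            if prod > 0:
                concordant += 1
            elif prod < 0:
                discordant += 1
    s = concordant - discordant

    def tie_groups(v):
        from collections import Counter

        return [c for c in Counter(v).values() if c > 1]

    tx, ty = tie_groups(x), tie_groups(y)
    n0 = n * (n - 1) / 2
    n1 = sum(t * (t - 1) / 2 for t in tx)
    n2 = sum(t * (t - 1) / 2 for t in ty)
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    tau = s / denom if denom > 0 else float("nan")
    var_s = (
        n * (n - 1) * (2 * n + 5)
        - sum(t * (t - 1) * (2 * t + 5) for t in tx)
        - sum(t * (t - 1) * (2 * t + 5) for t in ty)
    ) / 18.0
    var_s += (
        sum(t * (t - 1) for t in tx) * sum(t * (t - 1) for t in ty)
    ) / (2.0 * n * (n - 1))
    if n > 2:
        var_s += (
            sum(t * (t - 1) * (t - 2) for t in tx)
            * sum(t * (t - 1) * (t - 2) for t in ty)
        ) / (9.0 * n * (n - 1) * (n - 2))
    z = s / math.sqrt(var_s) if var_s > 0 else 0.0
    return tau, z
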