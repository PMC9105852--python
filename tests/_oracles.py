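"""Independent oracles used by the tests.

These deliberately avoid the library code paths they check: the tone-curve
oracle is scalar pure-Python arithmetic (no numpy, no LUT), and the
statistical oracles compute the Student-t machinery from the t statistic and
the regularized incomplete beta function rather than via scipy.stats test
routines.
"""

import math

from scipy.special import betainc

#: two-sided 97.5% Student-t quantile at 9 degrees of freedom (from R qt(0.975, 9))
T_975_DF9 = 2.2621571627982049


def tone_oracle(curve_type: int, f: int, fmax: int, t=None, gamma=None) -> int:
    """Scalar real-arithmetic evaluation + round-half-away + clip."""
    ct = int(curve_type)
    if ct == 0:
        g = float(f)
    elif ct == 1:
        g = 0.0 if f < t else float(f)
    elif ct == 2:
        g = 0.0 if f < t else fmax * (f - t) / (fmax - t)
    elif ct == 3:
        g = fmax * (f / fmax) ** (1.0 / gamma)
    elif ct == 4:
        g = float(fmax - f)
    elif ct == 5:
        g = float(fmax - f) if f < t else 0.0
    elif ct == 6:
        g = fmax * (1.0 - f / t) if f < t else 0.0
    elif ct == 7:
        g = fmax * ((fmax - f) / fmax) ** (1.0 / gamma)
    else:
        raise ValueError(ct)
    return min(max(math.floor(g + 0.5), 0), fmax)


def t_ci_halfwidth(values) -> float:
    """95% CI half-width for a 10-value sample, closed form."""
    n = len(values)
    assert n == 10, "frozen quantile is for df=9"
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return T_975_DF9 * math.sqrt(var) / math.sqrt(n)


def paired_t(a, b):
    """Paired two-sided t-test via the incomplete-beta tail formula."""
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t_stat = mean / math.sqrt(var / n)
    nu = n - 1
    p = betainc(nu / 2.0, 0.5, nu / (nu + t_stat**2))
    return t_stat, float(p)
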