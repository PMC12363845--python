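"""Independent direct-formula oracles used to cross-check the mixture models.

These re-derive each model from its printed formula with straight loops and
no shared code with the package implementation.
"""

from __future__ import annotations

import itertools
import math


def oracle_add(intensities):
    return sum(intensities)


def oracle_sc(intensities):
    return max(intensities)


def oracle_euc(intensities):
    return math.sqrt(sum(i * i for i in intensities))


def oracle_vec(intensities, cos_alpha):
    """Returns None when the radicand is negative (undefined intensity)."""
    s = sum(i * i for i in intensities)
    for a, b in itertools.combinations(intensities, 2):
        s += 2.0 * a * b * cos_alpha
    return math.sqrt(s) if s >= 0 else None


def oracle_u(intensities, cos_alpha):
    s = sum(i * i for i in intensities)
    n = len(intensities)
    for k in range(2, n + 1):
        for subset in itertools.combinations(intensities, k):
            prod = 1.0
            for v in subset:
                prod *= v
            s += 2.0 * cos_alpha * prod ** (1.0 / k)
    return math.sqrt(s) if s >= 0 else None


def oracle_cb(a_values, conc_over_ec50, fmax):
    num = sum(a * r for a, r in zip(a_values, conc_over_ec50))
    den = 1.0 + sum(conc_over_ec50)
    return fmax * num / den


def oracle_hill(imax, ec50, n, c):
    if c == 0:
        return 0.0
    return imax * c**n / (c**n + ec50**n)


def oracle_pri(components, alpha):
    """components: iterable of (imax, ec50, n, concentration); zero-conc skipped."""
    total = 0.0
    for imax, ec50, n, c in components:
        if c > 0:
            total += math.exp(oracle_hill(imax, ec50, n, alpha * c))
    return math.log(total)
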