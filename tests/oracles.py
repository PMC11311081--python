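"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exact rational arithmetic, O(n^2)
window enumeration, high-precision decimals — and shares no code with the
package internals it checks.
"""

from decimal import Decimal, getcontext
from fractions import Fraction
from math import factorial

import numpy as np

from rohscan.datamodel import MISSING


def hwe_exact_pvalue_rational(n_AA: int, n_Ab: int, n_bb: int) -> Fraction:
    """Two-sided HWE exact p-value by full enumeration in exact rationals.

    Conditional on allele counts, P(het=h) for each feasible h; the
    p-value sums probabilities <= the observed table's probability.
    """
    n = n_AA + n_Ab + n_bb
    nA = 2 * n_AA + n_Ab
    nB = 2 * n_bb + n_Ab

    def prob(h: int) -> Fraction:
        a = (nA - h) // 2
        b = (nB - h) // 2
        num = factorial(n) * 2**h * factorial(nA) * factorial(nB)
        den = factorial(a) * factorial(h) * factorial(b) * factorial(2 * n)
        return Fraction(num, den)

    # h must share parity with nA (and hence with nB: they sum to 2n)
    feasible = [h for h in range(min(nA, nB) + 1) if (nA - h) % 2 == 0]
    probs = {h: prob(h) for h in feasible}
    assert sum(probs.values()) == 1
    p_obs = probs[n_Ab]
    return sum(p for p in probs.values() if p <= p_obs)


def brute_force_roh(calls, bp, *, min_snps, min_length_bp, max_het, max_missing, max_gap_bp):
    """All maximal qualifying homozygous windows on one chromosome of one
    individual, by O(n^2) enumeration.

    A window [i, j] qualifies if both ends are homozygous calls, every
    adjacent gap is <= max_gap_bp, and the het/missing counts respect the
    allowances.  Windows passing the SNP-count and length floors are kept,
    then any window contained in another kept window is dropped.
    """
    calls = np.asarray(calls)
    bp = np.asarray(bp)
    n = calls.size
    is_hom = (calls == 0) | (calls == 2)
    qualifying = []
    for i in range(n):
        if not is_hom[i]:
            continue
        het = miss = 0
        for j in range(i, n):
            if j > i and bp[j] - bp[j - 1] > max_gap_bp:
                break
            if calls[j] == 1:
                het += 1
            elif calls[j] == MISSING:
                miss += 1
            if het > max_het or miss > max_missing:
                break
            if not is_hom[j]:
                continue
            if j - i + 1 >= min_snps and bp[j] - bp[i] >= min_length_bp:
                qualifying.append((i, j, het, miss))
    maximal = [
        w
        for w in qualifying
        if not any(
            (o[0] <= w[0] and w[1] <= o[1] and o != w) for o in qualifying
        )
    ]
    return sorted(maximal)


def min_snp_count_decimal(n_s, n_i, alpha, mean_het, prec=60):
    """Eq-style minimum SNP count at 60-digit precision."""
    getcontext().prec = prec
    l = (Decimal(alpha) / (Decimal(n_s) * Decimal(n_i))).ln() / (
        Decimal(1) - Decimal(mean_het)
    ).ln()
    ceil_l = int(l) + (0 if l == int(l) else 1)
    return max(1, ceil_l)
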