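"""Independent reference implementations used only to check the package.

These are deliberately naive: exact rational arithmetic and direct
formula transcriptions, written before (and kept independent of) the
log-gamma / vectorised production code.
"""

from fractions import Fraction
from math import comb, erfc, sqrt


def ac_conditional_pmf(k: int, x: int, N1: int, N2: int) -> Fraction:
    """Exact P(k | x) = q^k (x+k)! / (x! k! (1+q)^(x+k+1)) with q = N2/N1."""
    q = Fraction(N2, N1)
    return q**k * comb(x + k, k) / (1 + q) ** (x + k + 1)


def ac_pvalue_exact(x: int, N1: int, y: int, N2: int, tail: str = "two_sided") -> float:
    """Brute-force Audic-Claverie tail probability in exact rational arithmetic."""
    lower = sum(ac_conditional_pmf(k, x, N1, N2) for k in range(0, y + 1))
    upper = 1 - sum(ac_conditional_pmf(k, x, N1, N2) for k in range(0, y))
    if tail == "enriched_in_1":
        return float(min(lower, Fraction(1)))
    if tail == "enriched_in_2":
        return float(min(upper, Fraction(1)))
    return float(min(Fraction(1), 2 * min(lower, upper)))


def two_proportion_exact(x1: int, N1: int, x2: int, N2: int) -> tuple[float, float]:
    """Textbook pooled z statistic, evaluated in rational arithmetic up to the sqrt."""
    pooled = Fraction(x1 + x2, N1 + N2)
    var = pooled * (1 - pooled) * (Fraction(1, N1) + Fraction(1, N2))
    if var == 0:
        return 0.0, 1.0
    z = float(Fraction(x1, N1) - Fraction(x2, N2)) / sqrt(float(var))
    p = erfc(abs(z) / sqrt(2.0))
    return z, min(1.0, p)


def welch_t_exact(a, b) -> tuple[float, float]:
    """Welch t and Welch-Satterthwaite df from the closed-form definitions."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def np_shannon_direct(counts) -> float:
    """Chao-Shen estimator transcribed directly from its definition."""
    from math import log

    N = sum(counts)
    n1 = sum(1 for c in counts if c == 1)
    C = 1.0 - n1 / N
    total = 0.0
    for c in counts:
        if c == 0:
            continue
        p = C * c / N
        if p <= 0 or p >= 1:
            continue
        total += -p * log(p) / (1.0 - (1.0 - p) ** N)
    return total


def theta_yc_direct(a, b) -> float:
    num = sum(ai * bi for ai, bi in zip(a, b))
    den = sum(ai * ai for ai in a) + sum(bi * bi for bi in b) - num
    return num / den


def pd_traversal_oracle(tree, names) -> float:
    """Union branch length via an independent per-leaf ancestor-path walk."""
    names = set(names)
    seen_edges = set()
    total = 0.0
    for tip in tree.tips():
        if tip.name not in names:
            continue
        node = tip
        while node.parent is not None:
            key = id(node)
            if key in seen_edges:
                break
            seen_edges.add(key)
            total += node.length or 0.0
            node = node.parent
    return total
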