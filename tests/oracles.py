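"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: exact rational
arithmetic for the count-test and hypergeometric tails, and naive
string scanning / all-pairs Hamming comparison for windows and mapping.
"""

from fractions import Fraction
from math import comb

ANCHOR = "CATG"
TAG_LEN = 21


def ac_pvalue_exact(x: int, y: int, N1: int, N2: int) -> Fraction:
    """Two-sided Audic-Claverie p by direct rational summation.

    P(y'|x) = C(x+y', y') r^y' / (1+r)^(x+y'+1) with r = N2/N1; both tails
    include the observed y; p = min(1, 2 min(lower, upper)).
    """
    r = Fraction(N2, N1)

    def pmf(yp: int) -> Fraction:
        return comb(x + yp, yp) * r**yp / (1 + r) ** (x + yp + 1)

    lower = sum(pmf(yp) for yp in range(y + 1))
    upper = 1 - sum(pmf(yp) for yp in range(y))
    return min(Fraction(1), 2 * min(lower, upper))


def hypergeom_upper_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact enumeration."""
    denom = comb(N, n)
    total = Fraction(0)
    for kp in range(k, min(K, n) + 1):
        total += Fraction(comb(K, kp) * comb(N - K, n - kp), denom)
    return min(Fraction(1), total)


def naive_windows(sequence: str) -> list[tuple[int, str]]:
    """Every CATG occurrence with >= 17 following bases, by position scan."""
    out = []
    for i in range(len(sequence) - 3):
        if sequence[i : i + 4] == ANCHOR and i + TAG_LEN <= len(sequence):
            out.append((i, sequence[i : i + TAG_LEN]))
    return out


def hamming(a: str, b: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def brute_force_map(tag: str, windows: list[tuple[str, str]]) -> tuple[str, str | None]:
    """All-pairs Hamming mapping of one tag against (tag21, gene_id) windows.

    Exact matches take precedence over 1-mismatch matches; a mismatch is
    only allowed in the 17 variable bases (anchor fixed).  Returns
    (status, gene_id or None) with status in {unambiguous, ambiguous,
    unknown}.
    """
    exact = {g for w, g in windows if w == tag}
    if exact:
        genes = exact
    else:
        genes = set()
        for w, g in windows:
            if w[:4] == tag[:4] and hamming(w[4:], tag[4:]) == 1:
                genes.add(g)
    if len(genes) == 1:
        return "unambiguous", next(iter(genes))
    if genes:
        return "ambiguous", None
    return "unknown", None
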