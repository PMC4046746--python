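"""TPM normalization and two-library differential-expression statistics.

Expression is normalized to TPM (transcripts per million *clean* tags):
``tpm = count / total_clean * 1e6``.  Significance of a per-gene count
difference between two libraries is assessed with the Audic-Claverie exact
test for unreplicated count data: conditioning on the count ``x`` observed
in library 1 (size ``N1``), the count ``y`` in library 2 (size ``N2``)
follows

    P(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1))

which is a negative binomial with ``x+1`` successes and success probability
``N1/(N1+N2)``.  Tail probabilities are evaluated through the regularized
incomplete beta function, exact to double precision for counts far beyond
10^5 where naive summation of the series would be impractical.  Multiple
testing is controlled with Benjamini-Hochberg; genes are called
differentially expressed at FDR <= 0.001 and |log2 ratio| >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .mapping import GeneCounts

DEFAULT_FDR_MAX = 0.001
DEFAULT_MIN_ABS_LOG2 = 1.0


def tpm_normalize(counts, total_clean: int):
    """Counts to transcripts-per-million-clean-tags.

    The denominator is the library's total *clean* tags, not its mapped
    tags, so TPMs across genes sum to 1e6 times the unambiguously mapped
    fraction of the library.
    """
    if total_clean < 1:
        raise ValueError("total_clean must be >= 1")
    if isinstance(counts, GeneCounts):
        counts = counts.counts
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    tpm = arr / total_clean * 1e6
    if isinstance(counts, pd.Series):
        return pd.Series(tpm, index=counts.index)
    return tpm


def audic_claverie_pmf(x, y, N1: int, N2: int):
    """P(y | x) of the Audic-Claverie conditional law, in log space.

    The two-sided p-value is exchange-symmetric under (x, N1) <-> (y, N2)
    only up to tie terms of this magnitude, because the observed value is
    included in both tails.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    log_r = np.log(N2) - np.log(N1)
    log_1pr = np.log1p(N2 / N1)
    lp = (
        y * log_r
        + special.gammaln(x + y + 1.0)
        - special.gammaln(x + 1.0)
        - special.gammaln(y + 1.0)
        - (x + y + 1.0) * log_1pr
    )
    return np.exp(lp)


def _ac_tails(x, y, N1, N2):
    """Lower and upper tail of the Audic-Claverie conditional law.

    Both tails include the observed value y.  Vectorized over x, y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    q = N1 / (N1 + N2)  # success probability of the negative binomial
    # P(Y <= y) = I_q(x+1, y+1);  P(Y >= y) = 1 - P(Y <= y-1)
    lower = special.betainc(x + 1.0, y + 1.0, q)
    upper = np.where(y > 0, 1.0 - special.betainc(x + 1.0, np.maximum(y, 1.0), q), 1.0)
    return lower, upper


def audic_claverie_p(x, y, N1: int, N2: int):
    """Two-sided Audic-Claverie p-value for counts x (lib 1) and y (lib 2).

    p = min(1, 2 * min(P(Y <= y | x), P(Y >= y | x))); ties at the observed
    value are included in both tails, so x == y with N1 == N2 gives p = 1.
    Accepts scalars or arrays (vectorized over genes).
    """
    if N1 < 1 or N2 < 1:
        raise ValueError("library sizes must be >= 1")
    xa = np.asarray(x)
    ya = np.asarray(y)
    if (xa < 0).any() or (ya < 0).any():
        raise ValueError("counts must be non-negative")
    lower, upper = _ac_tails(xa, ya, N1, N2)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if np.isscalar(x) and np.isscalar(y) else p


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def log2_ratio(count_treat, count_ctrl, N_treat: int, N_ctrl: int, zero_floor: float = 1.0):
    """log2 of the treatment/control TPM ratio, with a zero-count floor.

    A zero count is floored at ``zero_floor`` tag-equivalents (default 1)
    before TPM conversion so the ratio stays finite; a gene with zero in
    BOTH libraries has no meaningful ratio and returns NaN (rendered "-").
    Vectorized over counts.
    """
    t = np.asarray(count_treat, dtype=float)
    c = np.asarray(count_ctrl, dtype=float)
    if (t < 0).any() or (c < 0).any():
        raise ValueError("counts must be non-negative")
    both_zero = (t == 0) & (c == 0)
    tf = np.maximum(t, zero_floor)
    cf = np.maximum(c, zero_floor)
    ratio = np.log2((tf / N_treat) / (cf / N_ctrl))
    ratio = np.where(both_zero, np.nan, ratio)
    if np.isscalar(count_treat) and np.isscalar(count_ctrl):
        return float(ratio)
    return ratio


def de_table(
    ctrl: GeneCounts,
    treat: GeneCounts,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
    zero_floor: float = 1.0,
) -> pd.DataFrame:
    """Full per-gene differential-expression table for one comparison.

    Columns: gene_id, x (control count), y (treatment count), tpm1, tpm2,
    log2_ratio (treatment/control), p_value, fdr, significant.  Gene order
    follows the control count index; both GeneCounts must share it.
    """
    if not ctrl.counts.index.equals(treat.counts.index):
        raise ValueError("control and treatment gene indexes differ")
    x = ctrl.counts.to_numpy()
    y = treat.counts.to_numpy()
    N1, N2 = ctrl.total_clean, treat.total_clean
    p = audic_claverie_p(x, y, N1, N2)
    fdr = bh_fdr(p)
    lr = log2_ratio(y, x, N2, N1, zero_floor=zero_floor)
    significant = (fdr <= fdr_max) & ~np.isnan(lr) & (np.abs(lr) >= min_abs_log2)
    return pd.DataFrame(
        {
            "gene_id": ctrl.counts.index,
            "x": x,
            "y": y,
            "tpm1": tpm_normalize(x, N1),
            "tpm2": tpm_normalize(y, N2),
            "log2_ratio": lr,
            "p_value": p,
            "fdr": fdr,
            "significant": significant,
        }
    )


def call_degs(
    results: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
) -> tuple[list[str], list[str]]:
    """Split a DE table into up- and down-regulated gene lists.

    A gene is called iff fdr <= fdr_max AND |log2_ratio| >= min_abs_log2;
    genes with an undefined ratio (zero in both libraries) are never
    significant.  Returns (up, down) as gene-id lists.
    """
    lr = results["log2_ratio"]
    ok = (results["fdr"] <= fdr_max) & lr.notna()
    up = results.loc[ok & (lr >= min_abs_log2), "gene_id"].tolist()
    down = results.loc[ok & (lr <= -min_abs_log2), "gene_id"].tolist()
    return up, down


@dataclass(frozen=True)
class PhaseCall:
    gene_id: str
    phase: str  # "phase1" | "phase2" | "phase3" | "none"
    up_flags: tuple[bool, bool, bool]  # at 1 h, 5 h, 24 h


def classify_phase(
    up_1h: set[str] | list[str],
    up_5h: set[str] | list[str],
    up_24h: set[str] | list[str],
    genes: list[str] | None = None,
) -> list[PhaseCall]:
    """Classify genes by the earliest timepoint of significant up-regulation.

    Phase 1 (early rapid response): already up at 1 h.  Phase 2 (early slow
    response): first up at 5 h.  Phase 3 (late response): first up at 24 h.
    Genes never called up are "none".  All three call sets must come from
    comparisons against the same control.
    """
    s1, s5, s24 = set(up_1h), set(up_5h), set(up_24h)
    if genes is None:
        genes = sorted(s1 | s5 | s24)
    calls = []
    for g in genes:
        flags = (g in s1, g in s5, g in s24)
        if flags[0]:
            phase = "phase1"
        elif flags[1]:
            phase = "phase2"
        elif flags[2]:
            phase = "phase3"
        else:
            phase = "none"
        calls.append(PhaseCall(g, phase, flags))
    return calls


def format_ratio(value: float, decimals: int = 2) -> str:
    """Render a log2 ratio, using '-' for the undefined (both-zero) case."""
    return "-" if value is None or np.isnan(value) else f"{value:.{decimals}f}"
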