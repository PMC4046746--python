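"""Hypergeometric term enrichment of DEG sets and annotation coverage.

A term (e.g. a metabolic pathway) is tested for over-representation among
differentially expressed genes against the annotated background: with N
background genes carrying at least one term, K of them annotated to the
term, and n annotated DEGs of which k carry the term, the enrichment
p-value is the exact upper hypergeometric tail P(X >= k).  The background
is the set of genes with at least one annotation — not the whole reference
— and the DEG denominator is likewise restricted to annotated DEGs.
Q-values are Benjamini-Hochberg over the terms tested in one comparison;
terms with Q <= 0.05 are flagged significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

DEFAULT_Q_MAX = 0.05


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) into a gene -> terms map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_col, term_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        out.setdefault(gene, set()).add(term)
    return out


def hypergeom_enrich(
    deg_genes,
    annotation: dict[str, set[str]],
    background=None,
    term_names: dict[str, str] | None = None,
    q_max: float = DEFAULT_Q_MAX,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every term among the DEGs.

    ``background`` defaults to all genes possessing >= 1 term in
    ``annotation``; the DEG set is intersected with it.  Returns one row
    per term with the k/n/K/N contingency, percentages at 2 dp, exact
    p-value, BH q-value and significance flag, sorted by (q, p).
    """
    if background is None:
        background = set(annotation)
    else:
        background = {g for g in background if annotation.get(g)}
    degs = set(deg_genes) & background
    n, N = len(degs), len(background)

    term_bg: dict[str, int] = {}
    term_deg: dict[str, int] = {}
    for gene in background:
        for term in annotation[gene]:
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in degs:
                term_deg[term] = term_deg.get(term, 0) + 1

    rows = []
    for term, K in sorted(term_bg.items()):
        if K == 0:
            warnings.warn(f"term {term!r} has no background genes; skipped")
            continue
        k = term_deg.get(term, 0)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "pct_deg": round(100.0 * k / n, 2) if n else 0.0,
                "pct_bg": round(100.0 * K / N, 2),
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "n", "K", "N", "pct_deg", "pct_bg", "p_value"],
    )
    return qvalue_adjust(df, q_max=q_max)


def qvalue_adjust(rows: pd.DataFrame, q_max: float = DEFAULT_Q_MAX) -> pd.DataFrame:
    """Attach BH q-values and the Q <= q_max significance flag; sort by (q, p)."""
    df = rows.copy()
    if len(df) == 0:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] <= q_max
    return df.sort_values(["q_value", "p_value"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class CoverageRow:
    source: str
    n_annotated: int
    n_total: int

    @property
    def percentage(self) -> float:
        return round(100.0 * self.n_annotated / self.n_total, 2)


def coverage_report(annotated_sets: dict[str, "set[str] | int"], n_total: int) -> pd.DataFrame:
    """Annotation coverage per source as a percentage of the reference.

    ``annotated_sets`` maps a source name to either the set of annotated
    gene ids or directly to an annotated-gene count.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    rows = []
    for source, genes in annotated_sets.items():
        n = genes if isinstance(genes, int) else len(genes)
        row = CoverageRow(source, n, n_total)
        rows.append((source, n, n_total, row.percentage))
    return pd.DataFrame(rows, columns=["source", "n_annotated", "n_total", "percentage"])


def write_enrichment_tsv(df: pd.DataFrame, path) -> None:
    """Table-style TSV: term, k (pct of DEGs), K (pct of background), p, q, flag."""
    out = pd.DataFrame(
        {
            "term_id": df["term_id"],
            "term_name": df["term_name"],
            "k_degs": [f"{k} ({p:.2f}%)" for k, p in zip(df["k"], df["pct_deg"])],
            "K_background": [f"{K} ({p:.2f}%)" for K, p in zip(df["K"], df["pct_bg"])],
            "p_value": df["p_value"].map("{:.3e}".format),
            "q_value": df["q_value"].map("{:.3e}".format),
            "significant": df["significant"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
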