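"""Hypergeometric enrichment and set-overlap tests.

Used for functional-term enrichment of gene selections (background = all
expressed genes) and for overlap tests between gene/eQTL sets from the two
maternal environments.  The overlap percentage is reported relative to the
union of the two sets.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_test(
    selection, term_sets: dict[str, set], background
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of a selection against term sets.

    For each term with K annotated genes in the background of size N,
    p = P(X >= k) where k of the n selected genes carry the term; BH
    adjustment across terms.
    """
    background = set(background)
    selection = set(selection)
    stray = selection - background
    if stray:
        raise ValueError(f"selection not contained in background: {sorted(stray)[:5]}")
    n_bg, n_sel = len(background), len(selection)
    rows = []
    for term, genes in term_sets.items():
        in_bg = set(genes) & background
        k = len(in_bg & selection)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(in_bg), n_sel))
        rows.append((term, n_bg, len(in_bg), n_sel, k, p))
    out = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p"]).set_index("term")
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def overlap_test(set_a, set_b, universe) -> dict[str, float]:
    """Hypergeometric overlap test between two sets within a universe.

    Returns N, K (=|A|), n (=|B|), k (=|A & B|), the upper-tail p, and the
    overlap as a percentage of the union |A & B| / |A | B| * 100.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    for name, s in (("A", a), ("B", b)):
        if not s <= universe:
            raise ValueError(f"set {name} not contained in the universe")
    k = len(a & b)
    union = len(a | b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    return {
        "N": len(universe),
        "K": len(a),
        "n": len(b),
        "k": k,
        "p": p,
        "overlap_pct": union_overlap_pct(k, len(a), len(b)),
    }


def union_overlap_pct(n_overlap: int, n_a: int, n_b: int) -> float:
    """Overlap percentage of the union: k / (|A| + |B| - k) * 100."""
    union = n_a + n_b - n_overlap
    if union <= 0:
        return 0.0
    return 100.0 * n_overlap / union
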