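"""Genetic architecture statistics: broad-sense heritability and transgression.

Both statistics contrast the RIL population with replicated measurements of
the two parental lines, per maternal environment:

* Broad-sense heritability H2 = (V_RIL - V_e) / V_RIL, where V_RIL is the
  sample variance over RILs and V_e the pooled variance of the parental
  replicates (an upper-bound estimate of the genetic variance fraction).
* Transgression counts RILs whose trait value falls strictly beyond
  [min parental mean - 3*sigma, max parental mean + 3*sigma], with sigma the
  pooled parental standard deviation; an excess indicates antagonistic
  multi-locus architecture.

Significance uses a per-transcript permutation null: values are reshuffled
over the line designations (group sizes preserved), the statistic is
recomputed ``n_perm`` times, and the rank-th highest permuted value (by
default the 50th of 1000, the FDR = 0.05 convention) is the threshold; the
observed statistic is significant iff strictly greater.

Sample variances use the n-1 denominator throughout.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .xpr import ExpressionMatrix


def heritability(ril_values, parent_a_values, parent_b_values) -> dict[str, float]:
    """H2 = (V_RIL - V_e)/V_RIL with V_e the pooled parental variance.

    Returns ``{"v_ril", "v_e", "h2"}``; ``h2`` is NaN when V_RIL is zero
    (undefined) and may be negative — it is reported as computed, never
    clipped.
    """
    r = np.asarray(ril_values, float)
    a = np.asarray(parent_a_values, float)
    b = np.asarray(parent_b_values, float)
    if len(r) < 2 or len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 RILs and >= 2 replicates per parent")
    v_ril = float(np.var(r, ddof=1))
    v_e = _pooled_var(a, b)
    h2 = (v_ril - v_e) / v_ril if v_ril > 0 else float("nan")
    return {"v_ril": v_ril, "v_e": v_e, "h2": h2}


def _pooled_var(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    return float(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    )


def transgression(ril_values, parent_a_values, parent_b_values) -> dict[str, float]:
    """Count RILs strictly beyond the parental means +- 3 pooled SDs.

    The lower bound is set by the parental line with the lowest mean minus
    3*sigma, the upper by the highest mean plus 3*sigma.  With sigma = 0 the
    bounds collapse onto the parental means; the count is still computed and
    ``degenerate`` is flagged.
    """
    r = np.asarray(ril_values, float)
    a = np.asarray(parent_a_values, float)
    b = np.asarray(parent_b_values, float)
    if len(r) < 2 or len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 RILs and >= 2 replicates per parent")
    sigma = float(np.sqrt(_pooled_var(a, b)))
    lo = min(a.mean(), b.mean()) - 3.0 * sigma
    hi = max(a.mean(), b.mean()) + 3.0 * sigma
    n = int(((r < lo) | (r > hi)).sum())
    return {
        "lower": lo,
        "upper": hi,
        "sigma": sigma,
        "n_transgressive": n,
        "degenerate": sigma == 0.0,
    }


def permutation_threshold(
    statistic: Callable[[np.ndarray, np.ndarray, np.ndarray], float],
    ril_values,
    parent_a_values,
    parent_b_values,
    n_perm: int = 1000,
    rank: int = 50,
    rng=None,
) -> float:
    """Rank-th highest of ``n_perm`` permuted statistics.

    Values are pooled over RILs and parental replicates, randomly reassigned
    to the line designations (same group sizes), and the statistic is
    recomputed; the default 50th highest of 1000 is the FDR = 0.05
    convention for these scans.
    """
    if n_perm < rank:
        raise ValueError("n_perm must be >= rank")
    rng = np.random.default_rng(rng)
    pooled = np.concatenate(
        [np.asarray(ril_values, float), np.asarray(parent_a_values, float),
         np.asarray(parent_b_values, float)]
    )
    n_r, n_a = len(ril_values), len(parent_a_values)
    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, len(pooled))).copy(), axis=1)
    stats_ = np.array(
        [
            statistic(row[:n_r], row[n_r : n_r + n_a], row[n_r + n_a :])
            for row in perms
        ]
    )
    return float(np.partition(stats_, -rank)[-rank])


def _split(meta: pd.DataFrame, treatment: str):
    sub = meta[meta["treatment"] == treatment]
    rils = sub.index[~sub["is_parent"]]
    pa = sub.index[sub["is_parent"] & (sub["line"] == "MM")]
    pb = sub.index[sub["is_parent"] & (sub["line"] == "PI")]
    if len(rils) < 2 or len(pa) < 2 or len(pb) < 2:
        raise ValueError(f"treatment {treatment!r} lacks RILs or parental replicates")
    return rils, pa, pb


def _perm_stats_matrix(values: np.ndarray, n_r: int, n_a: int, n_perm: int, rng, kind: str):
    """Permuted statistics for one gene, vectorized over permutations."""
    perms = rng.permuted(np.broadcast_to(values, (n_perm, len(values))).copy(), axis=1)
    r = perms[:, :n_r]
    a = perms[:, n_r : n_r + n_a]
    b = perms[:, n_r + n_a :]
    na, nb = a.shape[1], b.shape[1]
    v_a = np.var(a, axis=1, ddof=1)
    v_b = np.var(b, axis=1, ddof=1)
    v_e = ((na - 1) * v_a + (nb - 1) * v_b) / (na + nb - 2)
    if kind == "h2":
        v_r = np.var(r, axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (v_r - v_e) / v_r
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    sigma = np.sqrt(v_e)
    lo = np.minimum(m_a, m_b) - 3.0 * sigma
    hi = np.maximum(m_a, m_b) + 3.0 * sigma
    return ((r < lo[:, None]) | (r > hi[:, None])).sum(axis=1).astype(float)


def _scan(
    em: ExpressionMatrix,
    treatment: str,
    kind: str,
    layer: str,
    n_perm: int,
    rank: int,
    seed,
) -> pd.DataFrame:
    if n_perm < rank:
        raise ValueError("n_perm must be >= rank")
    rils, pa, pb = _split(em.samples, treatment)
    y = em.layers[layer]
    r_m = y[rils].to_numpy(float)
    a_m = y[pa].to_numpy(float)
    b_m = y[pb].to_numpy(float)
    n_r, n_a = r_m.shape[1], a_m.shape[1]
    rng = np.random.default_rng(seed)

    rows = []
    for gi, gene in enumerate(em.genes):
        r, a, b = r_m[gi], a_m[gi], b_m[gi]
        values = np.concatenate([r, a, b])
        perm = _perm_stats_matrix(values, n_r, n_a, n_perm, rng, kind)
        perm = np.nan_to_num(perm, nan=-np.inf)
        thr = float(np.partition(perm, -rank)[-rank])
        if kind == "h2":
            res = heritability(r, a, b)
            obs = res["h2"]
            sig = bool(np.isfinite(obs) and obs > thr)
            rows.append((gene, treatment, res["v_ril"], res["v_e"], obs, thr, sig))
        else:
            res = transgression(r, a, b)
            obs = res["n_transgressive"]
            rows.append(
                (gene, treatment, res["lower"], res["upper"], obs, thr, obs > thr)
            )
    if kind == "h2":
        cols = ["gene", "treatment", "v_ril", "v_e", "h2", "threshold", "significant"]
    else:
        cols = ["gene", "treatment", "lower", "upper", "n_transgressive", "threshold",
                "significant"]
    return pd.DataFrame(rows, columns=cols).set_index("gene")


def heritability_scan(
    em: ExpressionMatrix,
    treatment: str,
    layer: str = "tpm_log",
    n_perm: int = 1000,
    rank: int = 50,
    seed=None,
) -> pd.DataFrame:
    """Per-gene H2 with per-transcript permutation thresholds for one
    treatment; see module docstring for the null construction."""
    return _scan(em, treatment, "h2", layer, n_perm, rank, seed)


def transgression_scan(
    em: ExpressionMatrix,
    treatment: str,
    layer: str = "tpm_log",
    n_perm: int = 1000,
    rank: int = 50,
    seed=None,
) -> pd.DataFrame:
    """Per-gene transgression counts with permutation thresholds."""
    return _scan(em, treatment, "transgression", layer, n_perm, rank, seed)
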