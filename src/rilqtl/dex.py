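"""Differential mRNA-abundance linear models.

Two models on log2-TPM values:

* :func:`test_treatment` — per gene, a one-factor model ``tpm_log ~ treatment``
  over all samples of both maternal environments (RILs plus parental
  replicates), F-tested and Bonferroni-corrected.
* :func:`test_parental_gxe` — on parental replicates only, the two-factor
  model ``tpm_log ~ treatment + line + treatment:line``; each term is
  F-tested and Benjamini-Hochberg-adjusted per term, with overall
  significance judged at the most stringent of the three realized FDR=0.05
  thresholds.

Sign conventions (documented in the output): a positive treatment effect
means higher abundance under HP; a positive line effect means higher in the
MM parent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .xpr import ExpressionMatrix


def _anova_two_group(y: np.ndarray, grp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA of genes x samples `y` on a boolean group.

    Returns (effect = mean(True group) - mean(False group), F, p) with
    df = (1, n-2).  Genes with zero total variance get effect 0 and p 1.
    """
    n = y.shape[1]
    n1, n0 = int(grp.sum()), int((~grp).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be represented")
    m1 = y[:, grp].mean(axis=1)
    m0 = y[:, ~grp].mean(axis=1)
    m = y.mean(axis=1)
    ssb = n1 * (m1 - m) ** 2 + n0 * (m0 - m) ** 2
    sst = ((y - m[:, None]) ** 2).sum(axis=1)
    ssw = sst - ssb
    df2 = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / df2)
    p = stats.f.sf(f, 1, df2)
    effect = m1 - m0
    flat = sst <= 1e-300
    effect[flat], p[flat], f[flat] = 0.0, 1.0, 0.0
    # perfect separation: ssw == 0 but ssb > 0
    p = np.where(np.isnan(p) & ~flat, 0.0, p)
    return effect, f, p


def test_treatment(em: ExpressionMatrix, layer: str = "tpm_log", alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene treatment (HP vs LN) F-test with Bonferroni correction.

    Uses every sample in the matrix — RILs and parental replicates of both
    environments.  Effect = mean(HP) - mean(LN) in log2 units.
    """
    y = em.layers[layer].to_numpy(float)
    grp = (em.samples["treatment"] == "HP").to_numpy()
    effect, f, p = _anova_two_group(y, grp)
    m = len(em.genes)
    p_adj = np.minimum(p * m, 1.0)
    neg = -np.log10(np.clip(p, 1e-300, None))
    cutoff = bonferroni_threshold(m, alpha)
    return pd.DataFrame(
        {
            "term": "T",
            "effect": effect,
            "F": f,
            "p": p,
            "p_adj": p_adj,
            "neg_log10_p": neg,
            "significant": neg > cutoff,
        },
        index=em.genes,
    )


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """-log10(p) cutoff of the Bonferroni correction: -log10(alpha / m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / m))


def test_parental_gxe(
    em: ExpressionMatrix, layer: str = "tpm_log", alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Two-factor model T + L + TxL on the parental replicates.

    Per gene and term, a 1-df F test from the least-squares fit with
    sum-to-zero (+-1/2) coding, so effects read as log2 differences:
    treatment = HP - LN, line = MM - PI, interaction = difference of the
    line effect between treatments.  BH adjustment runs per term; the
    realized -log10(p) threshold of each term at FDR ``alpha`` is returned,
    and ``significant`` uses the most stringent of the three.
    """
    parents = em.sample_ids(parents=True)
    meta = em.samples.loc[parents]
    cells = meta.groupby(["treatment", "line"]).size()
    if len(cells) < 4:
        raise ValueError("need all four treatment x line cells of parental data")

    y = em.layers[layer][parents].to_numpy(float)
    t = np.where(meta["treatment"] == "HP", 0.5, -0.5)
    l = np.where(meta["line"] == "MM", 0.5, -0.5)
    x = np.column_stack([np.ones_like(t), t, l, t * l])
    n, k = x.shape
    if n <= k:
        raise ValueError("need more parental samples than model terms")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # genes x 4
    resid = y - beta @ x.T
    df2 = n - k
    sigma2 = (resid**2).sum(axis=1) / df2
    terms = {"T": 1, "L": 2, "TxL": 3}
    rows = []
    for term, idx in terms.items():
        se2 = sigma2 * xtx_inv[idx, idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = beta[:, idx] ** 2 / se2
        p = stats.f.sf(f, 1, df2)
        p = np.where(np.isnan(p), 1.0, p)
        _, p_bh, _, _ = multipletests(p, method="fdr_bh")
        rows.append(
            pd.DataFrame(
                {
                    "term": term,
                    "effect": beta[:, idx],
                    "F": f,
                    "p": p,
                    "p_adj": p_bh,
                    "neg_log10_p": -np.log10(np.clip(p, 1e-300, None)),
                },
                index=em.genes,
            )
        )
    res = pd.concat(rows)

    thresholds: dict[str, float] = {}
    for term in terms:
        sub = res[res["term"] == term]
        sig = sub[sub["p_adj"] <= alpha]
        # realized threshold: largest raw p still called at FDR alpha
        thresholds[term] = (
            float(-np.log10(max(sig["p"].max(), 1e-300))) if len(sig) else float("inf")
        )
    finite = [v for v in thresholds.values() if np.isfinite(v)]
    thresholds["overall"] = max(finite) if finite else float("inf")
    res["significant"] = res["neg_log10_p"] > thresholds["overall"]
    return res, thresholds
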