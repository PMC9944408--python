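"""Single-marker eQTL mapping with permutation-based FDR under dependency.

Per treatment, every transcript's log2-TPM values over the RILs are
regressed on the genotype code at every marker (one-factor least squares;
the F test gives a -log10(p) profile per transcript).  Multiple testing is
controlled by remapping line-permuted expression ``n_perm`` times (default
10) and choosing the smallest -log10(p) cutoff on a 0.1-step grid whose
false/real discovery ratio satisfies the dependency-aware bound

    FDS / RDS <= (m0 / m) * q * log(m),        m0 = m - RDS,

where RDS is the number of transcripts whose profile maximum exceeds the
cutoff in the real data, FDS the mean of the same count over permutations,
m the number of transcripts, and log the natural logarithm.

Peaks above the threshold become eQTL records (one per chromosome per
transcript) with a 1.5-drop confidence interval, and are classified cis or
trans: trans requires the peak at least 1 Mb from the gene and the gene
outside the confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .snpmap import GenotypeMatrix, MarkerMap

MAX_NEG_LOG10_P = 300.0


def marker_scan(gm: GenotypeMatrix, traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regress every trait (gene) on every marker.

    ``traits`` is genes x lines (columns must be a subset of ``gm`` lines —
    RILs only; parental replicates are the caller's responsibility to
    exclude).  Returns ``(neg_log10_p, effect)``, both genes x markers;
    effect = mean(MM) - mean(PI), so positive means the MM allele raises
    abundance.  Markers with a single genotype class get score 0 and effect
    NaN; lines with NA genotype are dropped marker-wise.
    """
    lines = list(traits.columns)
    x_all = gm.codes.loc[lines].to_numpy(float)  # lines x markers
    y = traits.to_numpy(float)  # genes x lines
    n_genes, n_lines = y.shape
    n_markers = x_all.shape[1]

    neg = np.zeros((n_genes, n_markers))
    eff = np.full((n_genes, n_markers), np.nan)

    na_mask = np.isnan(x_all)
    clean = ~na_mask.any(axis=0)

    def _fill(cols: np.ndarray, x: np.ndarray, yy: np.ndarray) -> None:
        """OLS slope F-test of yy (genes x n) on each column of x (n x k)."""
        n = x.shape[0]
        if n < 3:
            return
        xc = x - x.mean(axis=0, keepdims=True)
        sxx = (xc**2).sum(axis=0)
        poly = sxx <= 0
        yc = yy - yy.mean(axis=1, keepdims=True)
        sxy = yc @ xc  # genes x k
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx
            ssr = beta * sxy
            sst = (yc**2).sum(axis=1, keepdims=True)
            sse = np.maximum(sst - ssr, 0.0)
            f = ssr * (n - 2) / sse
        p = stats.f.sf(f, 1, n - 2)
        p = np.where(np.isnan(p) & (ssr > 0), 0.0, p)
        p = np.where(np.isnan(p), 1.0, p)
        score = np.minimum(-np.log10(np.clip(p, 1e-300, None)), MAX_NEG_LOG10_P)
        score[:, poly] = 0.0
        e = -beta  # genotype code PI=1: positive effect = MM up
        e[:, poly] = np.nan
        neg[:, cols] = score
        eff[:, cols] = e

    if clean.any():
        _fill(np.flatnonzero(clean), x_all[:, clean], y)
    for j in np.flatnonzero(~clean):
        ok = ~na_mask[:, j]
        if ok.sum() < 3:
            continue
        _fill(np.array([j]), x_all[ok][:, [j]], y[:, ok])

    markers = gm.codes.columns
    idx = traits.index
    return (
        pd.DataFrame(neg, index=idx, columns=markers),
        pd.DataFrame(eff, index=idx, columns=markers),
    )


def map_transcript(gm: GenotypeMatrix, trait: pd.Series, mm: MarkerMap) -> pd.DataFrame:
    """Profile of one transcript: marker, chrom, pos, -log10(p), effect."""
    neg, eff = marker_scan(gm, trait.to_frame().T.astype(float))
    tab = mm.table.loc[gm.codes.columns]
    return pd.DataFrame(
        {
            "chrom": tab["chrom"].to_numpy(),
            "pos_bp": tab["pos_bp"].to_numpy(),
            "neg_log10_p": neg.iloc[0].to_numpy(),
            "effect": eff.iloc[0].to_numpy(),
        },
        index=tab.index,
    )


@dataclass
class EqtlThreshold:
    """Chosen genome-wide -log10(p) cutoff and its discovery accounting.

    ``cutoff`` is None when no grid point satisfies the bound ("no
    significant eQTLs").  ``grid`` records RDS/FDS/bound per candidate
    cutoff.
    """

    treatment: str
    q: float
    m: int
    grid: pd.DataFrame
    cutoff: float | None

    @property
    def significant(self) -> bool:
        return self.cutoff is not None


def fdr_bound_rhs(m: int, rds: int, q: float = 0.05, log_base: str = "e") -> float:
    """Right side of the dependency bound: (m0/m) * q * log(m), m0 = m - RDS."""
    log_m = np.log(m) if log_base == "e" else np.log10(m)
    return (m - rds) / m * q * float(log_m)


def fdr_threshold(
    real_max: pd.Series,
    perm_max: np.ndarray,
    q: float = 0.05,
    grid_step: float = 0.1,
    log_base: str = "e",
    treatment: str = "",
    m: int | None = None,
) -> EqtlThreshold:
    """Choose the -log10(p) cutoff from real and permuted profile maxima.

    ``real_max``: per-transcript maximum -log10(p); ``perm_max``: n_perm x
    transcripts matrix of the same under line permutation.  Candidate
    cutoffs descend on a ``grid_step`` grid; the chosen cutoff is the
    smallest with RDS > 0 whose FDS/RDS respects the bound.
    """
    m = int(m if m is not None else len(real_max))
    obs = real_max.to_numpy(float)
    top = max(obs.max(), perm_max.max() if perm_max.size else 0.0)
    grid = np.round(np.arange(grid_step, top + grid_step, grid_step), 10)

    rows = []
    for c in grid:
        rds = int((obs > c).sum())
        fds = float((perm_max > c).sum(axis=1).mean()) if perm_max.size else 0.0
        rhs = fdr_bound_rhs(m, rds, q, log_base)
        ok = rds > 0 and fds / rds <= rhs
        rows.append((c, rds, fds, rhs, ok))
    grid_df = pd.DataFrame(rows, columns=["cutoff", "rds", "fds", "bound_rhs", "satisfied"])
    satisfied = grid_df[grid_df["satisfied"]]
    cutoff = float(satisfied["cutoff"].iloc[0]) if len(satisfied) else None
    return EqtlThreshold(treatment=treatment, q=q, m=m, grid=grid_df, cutoff=cutoff)


def permuted_maxima(
    gm: GenotypeMatrix, traits: pd.DataFrame, n_perm: int = 10, seed=None
) -> np.ndarray:
    """Profile maxima after jointly permuting the line labels, n_perm times.

    One reshuffle of the line order is applied to all transcripts per
    permutation, preserving co-expression between transcripts.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, len(traits)))
    cols = np.asarray(traits.columns)
    for i in range(n_perm):
        shuffled = traits.copy()
        shuffled.columns = cols[rng.permutation(len(cols))]
        shuffled = shuffled[cols]
        neg, _ = marker_scan(gm, shuffled)
        out[i] = neg.to_numpy().max(axis=1)
    return out


def peak_and_interval(
    neg: pd.DataFrame,
    eff: pd.DataFrame,
    mm: MarkerMap,
    threshold: float,
    drop: float = 1.5,
) -> pd.DataFrame:
    """Extract eQTL records: one per chromosome per transcript above threshold.

    Peak = leftmost argmax marker on the chromosome; the confidence interval
    is the contiguous run of markers around the peak scoring >= peak - drop.
    Each marker genotypes a window of SNPs covering a physical span, so the
    interval is reported as [leftmost marker's span start, rightmost marker's
    span end] (falling back to marker point positions when no spans are
    recorded).
    """
    tab = mm.table.loc[neg.columns]
    chrom_arr = tab["chrom"].to_numpy()
    pos_arr = tab["pos_bp"].to_numpy(float)
    left_arr = (
        tab["span_start_bp"].to_numpy(float)
        if "span_start_bp" in tab.columns else pos_arr
    )
    right_arr = (
        tab["span_end_bp"].to_numpy(float)
        if "span_end_bp" in tab.columns else pos_arr
    )
    cm_arr = tab["cm"].to_numpy(float)
    records = []
    for chrom in tab["chrom"].unique():
        cols = np.flatnonzero(chrom_arr == chrom)
        sub = neg.iloc[:, cols].to_numpy()
        pos_c, cm_c = pos_arr[cols], cm_arr[cols]
        left_c, right_c = left_arr[cols], right_arr[cols]
        maxima = sub.max(axis=1)
        for gi in np.flatnonzero(maxima > threshold):
            s = sub[gi]
            pk = int(np.argmax(s))  # leftmost on ties
            lo = pk
            while lo > 0 and s[lo - 1] >= s[pk] - drop:
                lo -= 1
            hi = pk
            while hi < len(s) - 1 and s[hi + 1] >= s[pk] - drop:
                hi += 1
            e = eff.iloc[gi, cols[pk]]
            records.append(
                (
                    neg.index[gi],
                    chrom,
                    pos_c[pk],
                    cm_c[pk],
                    float(s[pk]),
                    float(e) if np.isfinite(e) else np.nan,
                    left_c[lo],
                    right_c[hi],
                    neg.columns[cols[pk]],
                )
            )
    return pd.DataFrame(
        records,
        columns=[
            "gene", "chrom", "peak_bp", "peak_cm", "neg_log10_p", "effect",
            "ci_left_bp", "ci_right_bp", "peak_marker",
        ],
    )


def classify_eqtl(records: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Label each record cis or trans.

    trans requires (i) the peak at least 1 Mb from the gene — distance from
    the nearest gene edge, infinite across chromosomes — and (ii) the gene
    interval outside the peak's confidence interval.  Everything else is
    cis.  Unannotated genes get type NA with a warning.
    """
    types = []
    for _, rec in records.iterrows():
        g = rec["gene"]
        if g not in annotation.index:
            warnings.warn(f"gene {g} missing from annotation; type set to NA")
            types.append(pd.NA)
            continue
        ann = annotation.loc[g]
        if ann["chrom"] != rec["chrom"]:
            types.append("trans")
            continue
        start, end, pk = float(ann["start"]), float(ann["end"]), float(rec["peak_bp"])
        dist = 0.0 if start <= pk <= end else min(abs(pk - start), abs(pk - end))
        in_ci = not (end < rec["ci_left_bp"] or start > rec["ci_right_bp"])
        types.append("trans" if dist >= 1e6 and not in_ci else "cis")
    out = records.copy()
    out["type"] = types
    return out


def eqtl_scan(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    traits: pd.DataFrame,
    treatment: str = "",
    n_perm: int = 10,
    q: float = 0.05,
    grid_step: float = 0.1,
    threshold: float | None = None,
    seed=None,
) -> tuple[pd.DataFrame, EqtlThreshold, pd.DataFrame, pd.DataFrame]:
    """Full per-treatment scan: profiles, FDR threshold, eQTL records.

    ``threshold`` overrides the permutation-derived cutoff (used when
    harmonizing treatments at the most stringent of their two cutoffs).
    Returns ``(records_without_type, threshold_object, neg_log10_p, effect)``.
    """
    neg, eff = marker_scan(gm, traits)
    perm = permuted_maxima(gm, traits, n_perm=n_perm, seed=seed)
    thr_obj = fdr_threshold(
        neg.max(axis=1), perm, q=q, grid_step=grid_step, treatment=treatment
    )
    use = threshold if threshold is not None else thr_obj.cutoff
    if use is None:
        empty = peak_and_interval(neg.iloc[0:0], eff.iloc[0:0], mm, 0.0)
        return empty, thr_obj, neg, eff
    records = peak_and_interval(neg, eff, mm, use)
    return records, thr_obj, neg, eff
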