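"""Genetic-map construction from RNA-seq-derived SNP calls.

A biparental RIL population is genotyped from SNPs segregating between the
two parental lines (here called MM and PI after the Moneymaker x
S. pimpinellifolium cross the toolkit was designed around, but any biparental
cross fits).  The workflow is:

1. :func:`filter_consistent_snps` — keep sites where the parental replicates
   are internally consistent, the parents differ, and every RIL has a call.
2. :func:`call_bin_genotypes` — slide a 100-SNP window (step 1) along each
   chromosome and call the most likely parental genotype per RIL per window;
   the window's marker position is the mean position of its member SNPs.
3. :func:`collapse_unique_markers` — merge consecutive markers with identical
   genotype columns, yielding the unique markers usable for mapping.
4. :func:`count_recombinations` / :func:`build_cm_map` — count genotype
   switches between consecutive informative markers per line and convert
   per-interval recombination fractions into centimorgan positions.

Genotype codes are numeric throughout: ``0.0`` = MM allele, ``1.0`` = PI
allele, ``NaN`` = no call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MM = 0.0
PI = 1.0

CODE_LABELS = {MM: "MM", PI: "PI"}


@dataclass
class SnpTable:
    """Per-site alleles plus per-sample allele calls.

    ``sites`` is indexed by site id with columns ``chrom``, ``pos`` (1-based
    bp), ``ref`` and ``alt`` (the two alleles; after parental filtering also
    ``mm_allele``/``pi_allele``).  ``calls`` shares the site index; its
    columns are sample ids and its values allele indices (``0.0`` ref /
    ``1.0`` alt, ``NaN`` missing).  Once ``parent_coded`` is True the indices
    mean MM/PI rather than ref/alt.
    """

    sites: pd.DataFrame
    calls: pd.DataFrame
    parent_coded: bool = False

    def __post_init__(self) -> None:
        if not self.sites.index.equals(self.calls.index):
            raise ValueError("sites and calls must share an index")
        order = self.sites.sort_values(["chrom", "pos"], kind="stable").index
        if not order.equals(self.sites.index):
            self.sites = self.sites.loc[order]
            self.calls = self.calls.loc[order]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class GenotypeMatrix:
    """Lines x markers genotype codes (0=MM, 1=PI, NaN=no call).

    ``prob_mm`` (same shape) holds the fraction of informative member SNPs
    supporting the MM allele; the reported code always has probability
    >= 0.5.
    """

    codes: pd.DataFrame
    prob_mm: pd.DataFrame | None = None

    @property
    def lines(self) -> list[str]:
        return list(self.codes.index)

    @property
    def markers(self) -> list[str]:
        return list(self.codes.columns)


@dataclass
class MarkerMap:
    """Marker coordinates: physical (bp) and genetic (cM).

    ``table`` is indexed by marker id with columns ``chrom``, ``pos_bp``
    (mean position of member SNPs), ``cm`` (NaN until :func:`build_cm_map`),
    ``n_snps`` and ``snp_first``/``snp_last`` (ids of the first and last
    member SNP; window membership is contiguous by construction).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tab = self.table
        for chrom, sub in tab.groupby("chrom", sort=False):
            if not sub["pos_bp"].is_monotonic_increasing:
                raise ValueError(f"markers on {chrom} not sorted by position")

    def loc_of(self, marker: str) -> tuple[str, float]:
        row = self.table.loc[marker]
        return row["chrom"], float(row["pos_bp"])


def filter_consistent_snps(
    raw: SnpTable,
    mm_samples: list[str],
    pi_samples: list[str],
    ril_samples: list[str],
) -> SnpTable:
    """Retain sites informative for genotyping the RILs.

    A site is kept when (i) all replicates of each parent agree internally,
    (ii) the two parents carry different alleles, and (iii) every RIL has a
    non-missing call.  RIL calls are then re-coded to 0=MM / 1=PI and the
    parental alleles recorded per site.
    """
    if not mm_samples or not pi_samples:
        raise ValueError("need at least one replicate per parent")
    if not ril_samples:
        raise ValueError("need at least one RIL sample")

    mm_calls = raw.calls[mm_samples].to_numpy(float)
    pi_calls = raw.calls[pi_samples].to_numpy(float)
    ril_calls = raw.calls[ril_samples].to_numpy(float)

    mm_ok = (~np.isnan(mm_calls)).all(axis=1) & (mm_calls == mm_calls[:, [0]]).all(axis=1)
    pi_ok = (~np.isnan(pi_calls)).all(axis=1) & (pi_calls == pi_calls[:, [0]]).all(axis=1)
    differ = mm_calls[:, 0] != pi_calls[:, 0]
    complete = (~np.isnan(ril_calls)).all(axis=1)
    keep = mm_ok & pi_ok & differ & complete

    if not keep.any():
        warnings.warn("no consistent SNPs retained", stacklevel=2)

    sites = raw.sites.loc[keep].copy()
    mm_allele_idx = mm_calls[keep, 0]
    # re-code RIL calls: matches MM parent allele -> 0, else -> 1
    coded = (ril_calls[keep] != mm_allele_idx[:, None]).astype(float)
    coded[np.isnan(ril_calls[keep])] = np.nan
    calls = pd.DataFrame(coded, index=sites.index, columns=ril_samples)

    allele_cols = sites[["ref", "alt"]].to_numpy()
    rows = np.arange(len(sites))
    sites["mm_allele"] = allele_cols[rows, mm_allele_idx.astype(int)]
    sites["pi_allele"] = allele_cols[rows, 1 - mm_allele_idx.astype(int)]
    return SnpTable(sites=sites, calls=calls, parent_coded=True)


def _sliding_sum(x: np.ndarray, width: int) -> np.ndarray:
    """Sum over a width-`width` window sliding with step 1 along axis 0."""
    c = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    return c[width:] - c[:-width]


def call_bin_genotypes(
    snps: SnpTable,
    bin_size: int = 100,
    min_informative_frac: float = 0.1,
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Call per-RIL genotypes in sliding windows of ``bin_size`` SNPs.

    Per window and line, the genotype probability is the fraction of
    non-missing member-SNP calls matching MM; the reported code is the
    majority allele, NA on an exact tie or when fewer than
    ``min_informative_frac`` of member SNPs are informative.  Chromosomes
    with fewer than ``bin_size`` SNPs yield a single window over all their
    SNPs.  The window slides with step 1; redundant markers are removed
    later by :func:`collapse_unique_markers`.
    """
    if not snps.parent_coded:
        raise ValueError("SNP table must be parent-coded (run filter_consistent_snps)")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")

    code_blocks, prob_blocks, rows = [], [], []
    for chrom, sub in snps.sites.groupby("chrom", sort=False):
        calls = snps.calls.loc[sub.index].to_numpy(float)
        pos = sub["pos"].to_numpy(float)
        width = min(bin_size, len(sub))
        informative = (~np.isnan(calls)).astype(float)
        is_mm = (calls == MM).astype(float)

        n_inf = _sliding_sum(informative, width)
        n_mm = _sliding_sum(is_mm, width)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_mm = np.where(n_inf > 0, n_mm / np.maximum(n_inf, 1), np.nan)
        codes = np.full_like(p_mm, np.nan)
        codes[p_mm > 0.5] = MM
        codes[p_mm < 0.5] = PI
        codes[n_inf < min_informative_frac * width] = np.nan

        mean_pos = _sliding_sum(pos[:, None], width)[:, 0] / width
        site_ids = sub.index.to_numpy()
        n_bins = len(mean_pos)
        for b in range(n_bins):
            rows.append(
                (
                    f"{chrom}_m{b + 1:05d}",
                    chrom,
                    mean_pos[b],
                    pos[b],
                    pos[b + width - 1],
                    np.nan,
                    width,
                    site_ids[b],
                    site_ids[b + width - 1],
                )
            )
        code_blocks.append(codes)
        prob_blocks.append(p_mm)

    marker_tab = pd.DataFrame(
        rows,
        columns=["marker", "chrom", "pos_bp", "span_start_bp", "span_end_bp",
                 "cm", "n_snps", "snp_first", "snp_last"],
    ).set_index("marker")
    codes = pd.DataFrame(
        np.concatenate(code_blocks).T, index=snps.samples, columns=marker_tab.index
    )
    prob = pd.DataFrame(
        np.concatenate(prob_blocks).T, index=snps.samples, columns=marker_tab.index
    )
    return GenotypeMatrix(codes=codes, prob_mm=prob), MarkerMap(marker_tab)


def collapse_unique_markers(
    gm: GenotypeMatrix, mm: MarkerMap
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Merge consecutive markers whose genotype columns are identical.

    Two adjacent markers merge when every line carries the same code at both
    (NA matching NA).  The merged marker sits at the mean position of its
    members and keeps the first member's id.  Idempotent.
    """
    tab = mm.table.loc[gm.codes.columns]
    codes = gm.codes.to_numpy(float)
    sig = np.nan_to_num(codes, nan=-1.0)

    chroms = tab["chrom"].to_numpy()
    new_block = np.ones(len(tab), dtype=bool)
    if len(tab) > 1:
        same_col = (sig[:, 1:] == sig[:, :-1]).all(axis=0)
        same_chrom = chroms[1:] == chroms[:-1]
        new_block[1:] = ~(same_col & same_chrom)
    block_id = np.cumsum(new_block) - 1

    keep_idx = np.flatnonzero(new_block)
    pos = tab["pos_bp"].to_numpy(float)
    merged_pos = np.bincount(block_id, weights=pos) / np.bincount(block_id)
    # member accounting survives repeated collapsing (idempotence)
    prior = (
        tab["n_bins_merged"].to_numpy(float)
        if "n_bins_merged" in tab.columns
        else np.ones(len(tab))
    )
    n_members = np.bincount(block_id, weights=prior).astype(int)
    last_idx = np.r_[keep_idx[1:] - 1, len(tab) - 1]

    out_tab = tab.iloc[keep_idx].copy()
    out_tab["pos_bp"] = merged_pos
    out_tab["n_snps"] = [
        tab["n_snps"].iloc[i : j + 1].sum() for i, j in zip(keep_idx, last_idx)
    ]
    out_tab["snp_last"] = tab["snp_last"].to_numpy()[last_idx]
    if "span_end_bp" in tab.columns:
        out_tab["span_end_bp"] = tab["span_end_bp"].to_numpy()[last_idx]
    out_tab["n_bins_merged"] = n_members

    out_codes = gm.codes.iloc[:, keep_idx].copy()
    out_codes.columns = out_tab.index
    out_prob = None
    if gm.prob_mm is not None:
        prob = gm.prob_mm.to_numpy(float)
        merged_prob = np.empty((prob.shape[0], len(keep_idx)))
        for b, (i, j) in enumerate(zip(keep_idx, last_idx)):
            merged_prob[:, b] = np.nanmean(prob[:, i : j + 1], axis=1)
        out_prob = pd.DataFrame(merged_prob, index=gm.codes.index, columns=out_tab.index)
    return GenotypeMatrix(codes=out_codes, prob_mm=out_prob), MarkerMap(out_tab)


def count_recombinations(
    gm: GenotypeMatrix, mm: MarkerMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count genotype switches between consecutive informative markers.

    A recombination is a change of code between consecutive non-NA markers
    of the same chromosome (NA markers are skipped).  Returns a lines x
    chromosomes count table and a long table of breakpoint intervals
    ``(line, chrom, left_bp, right_bp)`` delimited by the flanking informative
    markers.
    """
    tab = mm.table.loc[gm.codes.columns]
    lines = gm.codes.index
    chrom_list = tab["chrom"].unique()
    counts = pd.DataFrame(0, index=lines, columns=chrom_list, dtype=int)
    bp_rows: list[tuple] = []

    for chrom in chrom_list:
        cols = tab.index[tab["chrom"] == chrom]
        codes = gm.codes[cols].to_numpy(float)
        pos = tab.loc[cols, "pos_bp"].to_numpy(float)
        for li, line in enumerate(lines):
            v = codes[li]
            ok = ~np.isnan(v)
            if not ok.any():
                warnings.warn(f"line {line} has no informative marker on {chrom}")
                continue
            vv, pp = v[ok], pos[ok]
            switch = np.flatnonzero(vv[1:] != vv[:-1])
            counts.loc[line, chrom] = len(switch)
            for s in switch:
                bp_rows.append((line, chrom, pp[s], pp[s + 1]))

    breakpoints = pd.DataFrame(bp_rows, columns=["line", "chrom", "left_bp", "right_bp"])
    return counts, breakpoints


def build_cm_map(
    gm: GenotypeMatrix, mm: MarkerMap, map_function: str = "morgan"
) -> MarkerMap:
    """Fill genetic (cM) positions from inter-marker recombination fractions.

    Between adjacent markers, r = (# lines whose codes differ, both non-NA) /
    (# lines informative at both); the cM increment is 100*r (``morgan``,
    default) or the Haldane-corrected -50*ln(1-2r) (``haldane``); genetic
    position is the per-chromosome cumulative sum starting at 0.
    """
    if len(gm.codes) < 2:
        raise ValueError("need >= 2 lines to estimate recombination fractions")
    if map_function not in ("morgan", "haldane"):
        raise ValueError(f"unknown map function {map_function!r}")

    tab = mm.table.loc[gm.codes.columns].copy()
    cm = np.zeros(len(tab))
    codes = gm.codes.to_numpy(float)
    chroms = tab["chrom"].to_numpy()
    for j in range(1, len(tab)):
        if chroms[j] != chroms[j - 1]:
            continue  # new chromosome restarts at 0
        a, b = codes[:, j - 1], codes[:, j]
        both = ~np.isnan(a) & ~np.isnan(b)
        n = int(both.sum())
        if n == 0:
            warnings.warn(
                f"no informative lines between {tab.index[j - 1]} and {tab.index[j]}"
            )
            r = 0.0
        else:
            r = float((a[both] != b[both]).sum()) / n
        if map_function == "haldane":
            inc = -50.0 * np.log(max(1.0 - 2.0 * min(r, 0.4999), 1e-12))
        else:
            inc = 100.0 * r
        cm[j] = cm[j - 1] + inc
    tab["cm"] = cm
    return MarkerMap(tab)


def allele_frequency_profile(gm: GenotypeMatrix) -> pd.Series:
    """Per-marker frequency of the PI allele among non-NA calls.

    The genome-wide profile reveals segregation distortion: in a biparental
    RIL population every marker is expected near 0.5.
    """
    codes = gm.codes.to_numpy(float)
    n_pi = (codes == PI).sum(axis=0)
    n_inf = (~np.isnan(codes)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_inf > 0, n_pi / np.maximum(n_inf, 1), np.nan)
    return pd.Series(freq, index=gm.codes.columns, name="pi_freq")
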