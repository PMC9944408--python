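"""Trans-band detection: Poisson enrichment of trans-eQTL peaks in 2-Mb bins.

Trans-eQTL peaks are assigned to a fixed 2-Mb genomic grid.  Under the null
of an even genome-wide distribution the per-bin count is Poisson with rate
lambda = (total trans-eQTLs) / (number of bins in the universe); a bin is
enriched when the upper-tail probability P(X >= observed) falls below a
conservative cutoff (default 1e-4).  Runs of enriched bins — tolerating up
to one non-enriched bin in between — merge into a single trans-band, whose
counts are split by allele direction (+: MM allele raises the targets,
-: PI allele raises them).

The default bin universe is the set of 2-Mb bins that contain at least one
genetic marker (trans-eQTL peaks can only fall where markers exist);
``all_bins=True`` switches to every bin of the physical genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .snpmap import MarkerMap


def bin_universe(
    mm: MarkerMap,
    bin_size: float = 2e6,
    all_bins: bool = False,
    chrom_lengths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """The 2-Mb bins over which the Poisson rate is computed.

    Marker-bearing bins by default; with ``all_bins`` every bin up to each
    chromosome's length (``chrom_lengths`` required, else inferred from the
    last marker).
    """
    rows = []
    for chrom, sub in mm.table.groupby("chrom", sort=False):
        if all_bins:
            length = (chrom_lengths or {}).get(chrom, float(sub["pos_bp"].max()))
            idxs = np.arange(int(np.ceil(length / bin_size)))
        else:
            idxs = np.unique((sub["pos_bp"].to_numpy(float) // bin_size).astype(int))
        for i in idxs:
            rows.append((chrom, int(i), i * bin_size, (i + 1) * bin_size))
    return pd.DataFrame(rows, columns=["chrom", "bin", "start_bp", "end_bp"])


def bin_trans_eqtls(
    records: pd.DataFrame,
    universe: pd.DataFrame,
    bin_size: float = 2e6,
    treatment: str = "",
) -> pd.DataFrame:
    """Count trans-eQTL peaks per bin and attach the Poisson upper-tail p.

    ``records`` must already be classified trans.  Every peak is assigned to
    the bin containing its peak position; counts split by effect sign
    (n_plus: effect > 0, the MM allele raises the target).  p = P(X >= k)
    under Poisson(lambda), lambda = total / number of universe bins.
    """
    out = universe.copy()
    out.insert(0, "treatment", treatment)
    out[["n_trans", "n_plus", "n_minus"]] = 0
    if len(records):
        key = pd.MultiIndex.from_frame(out[["chrom", "bin"]])
        rec_bin = (records["peak_bp"].to_numpy(float) // bin_size).astype(int)
        rec_key = pd.MultiIndex.from_arrays([records["chrom"], rec_bin])
        plus = records["effect"].to_numpy(float) > 0
        counts = pd.Series(1, index=rec_key).groupby(level=[0, 1]).sum()
        counts_p = pd.Series(plus.astype(int), index=rec_key).groupby(level=[0, 1]).sum()
        out["n_trans"] = counts.reindex(key, fill_value=0).to_numpy()
        out["n_plus"] = counts_p.reindex(key, fill_value=0).to_numpy()
        out["n_minus"] = out["n_trans"] - out["n_plus"]
    lam = out["n_trans"].sum() / len(out) if len(out) else 0.0
    out["lambda"] = lam
    out["p"] = stats.poisson.sf(out["n_trans"] - 1, lam)
    return out


def poisson_min_count(lam: float, p_cut: float = 1e-4) -> int:
    """Smallest count k with P(X >= k) < p_cut under Poisson(lam)."""
    return int(stats.poisson.isf(p_cut, lam)) + 1


def call_and_merge(
    bins: pd.DataFrame,
    p_cut: float = 1e-4,
    max_gap: int = 1,
    records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge runs of enriched bins into trans-bands.

    Significant bins (p < p_cut) on the same chromosome merge when separated
    by at most ``max_gap`` non-significant grid bins.  Band bounds run from
    the first to the last significant bin; totals include every universe bin
    in that span.  With ``records`` given, member gene ids are collected per
    band.
    """
    bands = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.sort_values("bin")
        sig_bins = sub.loc[sub["p"] < p_cut, "bin"].to_numpy()
        if len(sig_bins) == 0:
            continue
        run_start = [sig_bins[0]]
        run_end = [sig_bins[0]]
        for b in sig_bins[1:]:
            if b - run_end[-1] - 1 <= max_gap:
                run_end[-1] = b
            else:
                run_start.append(b)
                run_end.append(b)
        for s, e in zip(run_start, run_end):
            span = sub[(sub["bin"] >= s) & (sub["bin"] <= e)]
            start_bp = float(span["start_bp"].iloc[0])
            end_bp = float(span["end_bp"].iloc[-1])
            members: list[str] = []
            if records is not None and len(records):
                in_band = (
                    (records["chrom"] == chrom)
                    & (records["peak_bp"] >= start_bp)
                    & (records["peak_bp"] < end_bp)
                )
                members = sorted(records.loc[in_band, "gene"].unique())
            bands.append(
                (
                    chrom,
                    start_bp,
                    end_bp,
                    len(span),
                    int((span["p"] < p_cut).sum()),
                    int(span["n_trans"].sum()),
                    int(span["n_plus"].sum()),
                    int(span["n_minus"].sum()),
                    ";".join(members),
                )
            )
    out = pd.DataFrame(
        bands,
        columns=[
            "chrom", "start_bp", "end_bp", "n_bins", "n_sig_bins",
            "n_eqtls", "n_plus", "n_minus", "genes",
        ],
    )
    if len(out):
        out.insert(0, "band", [f"TB{i + 1}" for i in range(len(out))])
    else:
        out.insert(0, "band", pd.Series(dtype=str))
    return out
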