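"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from rilqtl import simdata, snpmap, xpr


@pytest.fixture(scope="session")
def small_cfg():
    return simdata.SimulationConfig(
        n_snps=2400, n_genes=200, n_rils_hp=30, n_rils_ln=30,
        hotspots=[simdata.Hotspot(chrom="chr03", pos_bp=40e6, n_targets=20,
                                  treatment="LN")],
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_population(small_cfg):
    return simdata.simulate_population(small_cfg)


@pytest.fixture(scope="session")
def small_expression(small_cfg, small_population):
    _, truth_gm, truth = small_population
    return simdata.simulate_expression(truth_gm, truth, small_cfg)


@pytest.fixture(scope="session")
def small_expression_normed(small_cfg, small_population, small_expression):
    _, _, truth = small_population
    em = xpr.ExpressionMatrix(
        counts=small_expression.counts.copy(), samples=small_expression.samples
    )
    em = xpr.compute_tpm(em, simdata.gene_annotation(truth))
    em = xpr.transform(em)
    return xpr.transform(xpr.filter_expressed(em))


def toy_snp_table(rows, samples, chrom="chr01"):
    """Build a tiny SnpTable from a list of (pos, ref, alt, calls...) rows."""
    sites = pd.DataFrame(
        [(f"s{i}", chrom, r[0], r[1], r[2]) for i, r in enumerate(rows)],
        columns=["site", "chrom", "pos", "ref", "alt"],
    ).set_index("site")
    calls = pd.DataFrame(
        [r[3:] for r in rows], index=sites.index, columns=samples, dtype=float
    )
    return snpmap.SnpTable(sites=sites, calls=calls)


def genotype_matrix(codes, lines=None, markers=None, chrom="chr01", positions=None):
    """GenotypeMatrix + MarkerMap from a lines x markers array of codes."""
    codes = np.asarray(codes, float)
    lines = lines or [f"L{i}" for i in range(codes.shape[0])]
    markers = markers or [f"m{j}" for j in range(codes.shape[1])]
    positions = positions if positions is not None else (np.arange(codes.shape[1]) + 1.0) * 1e5
    gm = snpmap.GenotypeMatrix(
        codes=pd.DataFrame(codes, index=lines, columns=markers)
    )
    tab = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, str) else list(chrom),
            "pos_bp": positions,
            "cm": np.nan,
            "n_snps": 1,
            "snp_first": markers,
            "snp_last": markers,
        },
        index=pd.Index(markers, name="marker"),
    )
    return gm, snpmap.MarkerMap(tab)
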