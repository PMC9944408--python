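"""End-to-end orchestration of the RIL eQTL analysis.

Stages (each treatment analyzed independently, compared only at reporting
time): SNP filtering -> bin genotyping -> genetic map -> TPM normalization
and expression filter -> treatment / parental GxE models -> heritability and
transgression scans -> eQTL mapping with permutation FDR -> cis/trans
classification -> trans-band detection -> cross-environment overlaps.

All randomness flows from one seed through fixed per-stage sub-seeds, so
stages re-run in isolation reproducibly.  :func:`run_synthetic` wires the
synthetic generator straight into the analysis; :func:`run_all` starts from
files on disk.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dex, enrich, eqtl, genarch, hotspot, io, simdata, snpmap, xpr

log = logging.getLogger("rilqtl")

_STAGE_SEED = {"arch_hp": 11, "arch_ln": 12, "eqtl_hp": 21, "eqtl_ln": 22,
               "tg_hp": 31, "tg_ln": 32}


@dataclass
class AnalysisParams:
    """Per-stage analysis parameters with the defaults of the study design."""

    bin_size: int = 100          # SNPs per genotyping window
    min_informative_frac: float = 0.1
    n_perm_arch: int = 1000      # permutations for H2/transgression thresholds
    rank: int = 50               # 50th highest of 1000 = FDR 0.05 convention
    n_perm_eqtl: int = 10
    q: float = 0.05
    grid_step: float = 0.1
    harmonize: bool = True       # analyze both treatments at the stricter cutoff
    p_cut: float = 1e-4          # Poisson trans-band bin threshold
    trans_bin: float = 2e6
    max_gap: int = 1
    all_bins: bool = False
    seed: int = 0


@dataclass
class RunConfig:
    """File-based run configuration (see ``run_all``).

    SNP-table columns whose names start with ``mm_parent``/``pi_parent`` are
    taken as parental replicates; all other columns are RIL lines.
    """

    snp_table: str
    counts: str
    metadata: str
    annotation: str
    out_dir: str
    term_sets: str | None = None
    mm_parent: str = "MM"
    pi_parent: str = "PI"
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = AnalysisParams(**raw.pop("params", {}))
        return cls(params=params, **raw)


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def _sub_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) % (2**31), _STAGE_SEED[stage]])


def genotype_stage(
    snps: snpmap.SnpTable,
    mm_samples: list[str],
    pi_samples: list[str],
    ril_samples: list[str],
    params: AnalysisParams,
) -> dict:
    """SNP filter -> window genotypes -> unique markers -> cM map."""
    t0 = _stage("genotype")
    filtered = snpmap.filter_consistent_snps(snps, mm_samples, pi_samples, ril_samples)
    gm_raw, mm_raw = snpmap.call_bin_genotypes(
        filtered, bin_size=params.bin_size,
        min_informative_frac=params.min_informative_frac,
    )
    gm, marker_map = snpmap.collapse_unique_markers(gm_raw, mm_raw)
    rec_counts, breakpoints = snpmap.count_recombinations(gm, marker_map)
    marker_map = snpmap.build_cm_map(gm, marker_map)
    freqs = snpmap.allele_frequency_profile(gm)
    log.info("genotype stage done in %.1fs", time.perf_counter() - t0)
    return {
        "snps_retained": filtered,
        "genotypes": gm,
        "marker_map": marker_map,
        "recombination_counts": rec_counts,
        "breakpoints": breakpoints,
        "pi_freq": freqs,
        "n_markers_raw": len(gm_raw.markers),
    }


def expression_stage(em: xpr.ExpressionMatrix, annotation: pd.DataFrame) -> xpr.ExpressionMatrix:
    _stage("expression")
    em = xpr.compute_tpm(em, annotation)
    em = xpr.transform(em)
    out = xpr.filter_expressed(em)
    if len(out.genes) == 0:
        raise RuntimeError("filter_expressed removed every gene; check input counts")
    # ratios relative to the retained analysis set
    return xpr.transform(out)


def _ril_traits(em: xpr.ExpressionMatrix, treatment: str) -> pd.DataFrame:
    """tpm_log of the treatment's RILs, columns renamed to line ids."""
    samples = em.sample_ids(treatment=treatment, parents=False)
    traits = em.layers["tpm_log"][samples].copy()
    traits.columns = em.samples.loc[samples, "line"].to_numpy()
    return traits


def eqtl_stage(
    gm: snpmap.GenotypeMatrix,
    marker_map: snpmap.MarkerMap,
    em: xpr.ExpressionMatrix,
    annotation: pd.DataFrame,
    params: AnalysisParams,
) -> dict:
    """Per-treatment eQTL scans, optional threshold harmonization, cis/trans
    classification and trans-band detection."""
    _stage("eqtl")
    scans = {}
    for env in ("HP", "LN"):
        traits = _ril_traits(em, env)
        records, thr, neg, eff = eqtl.eqtl_scan(
            gm, marker_map, traits, treatment=env,
            n_perm=params.n_perm_eqtl, q=params.q, grid_step=params.grid_step,
            seed=_sub_seed(params.seed, f"eqtl_{env.lower()}"),
        )
        scans[env] = {"threshold": thr, "neg": neg, "eff": eff}

    cutoffs = [scans[e]["threshold"].cutoff for e in ("HP", "LN")]
    harmonized = None
    if params.harmonize and all(c is not None for c in cutoffs):
        harmonized = max(cutoffs)

    out = {"harmonized_cutoff": harmonized}
    for env in ("HP", "LN"):
        thr = scans[env]["threshold"]
        use = harmonized if harmonized is not None else thr.cutoff
        if use is None:
            records = eqtl.peak_and_interval(
                scans[env]["neg"].iloc[0:0], scans[env]["eff"].iloc[0:0],
                marker_map, 0.0,
            )
        else:
            records = eqtl.peak_and_interval(
                scans[env]["neg"], scans[env]["eff"], marker_map, use
            )
        records = eqtl.classify_eqtl(records, annotation)
        records.insert(0, "treatment", env)
        trans = records[records["type"] == "trans"]
        universe = hotspot.bin_universe(
            marker_map, bin_size=params.trans_bin, all_bins=params.all_bins
        )
        bins = hotspot.bin_trans_eqtls(
            trans, universe, bin_size=params.trans_bin, treatment=env
        )
        bands = hotspot.call_and_merge(
            bins, p_cut=params.p_cut, max_gap=params.max_gap, records=trans
        )
        out[env] = {
            "records": records,
            "threshold": thr,
            "used_cutoff": use,
            "bins": bins,
            "bands": bands,
        }
    return out


def architecture_stage(em: xpr.ExpressionMatrix, params: AnalysisParams) -> dict:
    """Heritability and transgression scans per treatment."""
    _stage("architecture")
    out = {}
    for env in ("HP", "LN"):
        out[env] = {
            "heritability": genarch.heritability_scan(
                em, env, n_perm=params.n_perm_arch, rank=params.rank,
                seed=_sub_seed(params.seed, f"arch_{env.lower()}"),
            ),
            "transgression": genarch.transgression_scan(
                em, env, n_perm=params.n_perm_arch, rank=params.rank,
                seed=_sub_seed(params.seed, f"tg_{env.lower()}"),
            ),
        }
    return out


def summarize_overlaps(eqtl_results: dict, arch_results: dict, genes) -> dict:
    """Cross-environment overlap report (counts, union percentages, p)."""
    genes = set(genes)

    def _records_sets(kind):
        return {
            env: set(
                eqtl_results[env]["records"]
                .loc[eqtl_results[env]["records"]["type"] == kind, "gene"]
            )
            for env in ("HP", "LN")
        }

    out = {}
    for kind in ("cis", "trans"):
        s = _records_sets(kind)
        out[kind] = enrich.overlap_test(s["HP"], s["LN"], genes)
    for stat in ("heritability", "transgression"):
        sets = {
            env: set(
                arch_results[env][stat].index[arch_results[env][stat]["significant"]]
            )
            for env in ("HP", "LN")
        }
        out[stat] = enrich.overlap_test(sets["HP"], sets["LN"], genes)
    return out


def _manifest(geno: dict, em: xpr.ExpressionMatrix, arch: dict, eq: dict,
              overlaps: dict, params: AnalysisParams) -> dict:
    man = {
        "params": asdict(params),
        "n_snps_retained": geno["snps_retained"].n_sites,
        "n_markers_raw": geno["n_markers_raw"],
        "n_markers_unique": len(geno["genotypes"].markers),
        "total_recombinations": int(geno["recombination_counts"].to_numpy().sum()),
        "n_genes_expressed": int(len(em.genes)),
        "harmonized_cutoff": eq["harmonized_cutoff"],
    }
    for env in ("HP", "LN"):
        rec = eq[env]["records"]
        n_cis = int((rec["type"] == "cis").sum())
        n_trans = int((rec["type"] == "trans").sum())
        man[env] = {
            "eqtl_cutoff": eq[env]["threshold"].cutoff,
            "used_cutoff": eq[env]["used_cutoff"],
            "n_eqtls": int(len(rec)),
            "n_cis": n_cis,
            "n_trans": n_trans,
            "n_genes_with_eqtl": int(rec["gene"].nunique()),
            "n_trans_bands": int(len(eq[env]["bands"])),
            "n_trans_in_bands": int(eq[env]["bands"]["n_eqtls"].sum()),
            "n_heritable": int(arch[env]["heritability"]["significant"].sum()),
            "n_transgressive": int(arch[env]["transgression"]["significant"].sum()),
        }
        assert man[env]["n_eqtls"] == n_cis + n_trans
    man["overlaps"] = {k: v for k, v in overlaps.items()}
    return man


def run_synthetic(
    sim_cfg: simdata.SimulationConfig,
    params: AnalysisParams | None = None,
    out_dir=None,
) -> dict:
    """Full pipeline on a simulated population; returns all stage results.

    With ``out_dir`` set, every tabular output plus a JSON manifest is
    written there.
    """
    params = params or AnalysisParams()
    snps, truth_gm, truth = simdata.simulate_population(sim_cfg)
    em = simdata.simulate_expression(truth_gm, truth, sim_cfg)
    annotation = simdata.gene_annotation(truth)
    mm_samples = [c for c in snps.samples if c.startswith("MM_")]
    pi_samples = [c for c in snps.samples if c.startswith("PI_")]
    rils = [c for c in snps.samples if c not in mm_samples + pi_samples]

    results = _run_core(snps, mm_samples, pi_samples, rils, em, annotation, params)
    results["truth"] = truth
    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def run_all(config: RunConfig) -> dict:
    """File-based pipeline; writes all outputs and the manifest to
    ``config.out_dir`` and returns the in-memory results."""
    p = config.params
    snps = io.read_snp_table(config.snp_table)
    em = io.read_expression(config.counts, config.metadata)
    annotation = io.read_gene_annotation(config.annotation)
    mm_samples = [c for c in snps.samples if c.startswith(config.mm_parent)]
    pi_samples = [c for c in snps.samples if c.startswith(config.pi_parent)]
    rils = [c for c in snps.samples if c not in mm_samples + pi_samples]
    results = _run_core(snps, mm_samples, pi_samples, rils, em, annotation, p)
    _write_outputs(results, Path(config.out_dir))
    return results


def _run_core(snps, mm_samples, pi_samples, rils, em, annotation, params) -> dict:
    geno = genotype_stage(snps, mm_samples, pi_samples, rils, params)
    em = expression_stage(em, annotation)
    arch = architecture_stage(em, params)
    eq = eqtl_stage(geno["genotypes"], geno["marker_map"], em, annotation, params)
    overlaps = summarize_overlaps(eq, arch, em.genes)
    manifest = _manifest(geno, em, arch, eq, overlaps, params)
    return {
        "genotype": geno,
        "expression": em,
        "architecture": arch,
        "eqtl": eq,
        "overlaps": overlaps,
        "manifest": manifest,
        "annotation": annotation,
    }


def _write_outputs(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    geno = results["genotype"]
    io.write_marker_map(geno["marker_map"], out_dir / "marker_map.tsv")
    io.write_genotype_matrix(geno["genotypes"], out_dir / "genotypes.tsv")
    io.write_breakpoints_bed(geno["breakpoints"], out_dir / "breakpoints.bed")
    geno["pi_freq"].to_csv(out_dir / "pi_allele_freq.tsv", sep="\t")
    em = results["expression"]
    for layer in ("tpm", "tpm_log", "tpm_rat"):
        io.write_layer(em, layer, out_dir / f"{layer}.tsv")
    de = dex.test_treatment(em)
    de.to_csv(out_dir / "de_treatment.tsv", sep="\t", index_label="gene")
    gxe, gxe_thresholds = dex.test_parental_gxe(em)
    gxe.to_csv(out_dir / "de_parental_gxe.tsv", sep="\t", index_label="gene")
    for env in ("HP", "LN"):
        arch = results["architecture"][env]
        arch["heritability"].to_csv(
            out_dir / f"heritability_{env}.tsv", sep="\t", index_label="gene"
        )
        arch["transgression"].to_csv(
            out_dir / f"transgression_{env}.tsv", sep="\t", index_label="gene"
        )
        eq = results["eqtl"][env]
        eq["records"].to_csv(out_dir / f"eqtl_{env}.tsv", sep="\t", index=False)
        eq["bins"].to_csv(out_dir / f"trans_bins_{env}.tsv", sep="\t", index=False)
        eq["bands"].to_csv(out_dir / f"trans_bands_{env}.tsv", sep="\t", index=False)
        if len(eq["bands"]):
            io.write_bands_bed(eq["bands"], out_dir / f"trans_bands_{env}.bed")
    manifest = dict(results["manifest"])
    manifest["gxe_thresholds"] = {
        k: (None if not np.isfinite(v) else v) for k, v in gxe_thresholds.items()
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
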