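"""Synthetic RIL population and expression generator with known ground truth.

The generator emulates the post-alignment inputs of a two-environment
genetical-genomics experiment on a biparental RIL population: RIL genomes
are homozygous mosaics of the two parental genomes delimited by
Poisson-distributed crossovers (mean two per chromosome, biased toward the
distal chromosome arms), parental SNPs are biallelic and replicate-
consistent, and gene expression is built from a linear effect model on the
log2 scale — local (cis) effects at the gene's own locus, environment-
specific trans-hotspots, treatment and genotype-by-treatment terms, and
Gaussian residual noise — observed through negative-binomial counts.

Every simulated effect is recorded in :class:`SimTruth`, so downstream
stages (genetic map, heritability, eQTL mapping, hotspot detection) can be
tested as parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snpmap import MM, PI, GenotypeMatrix, MarkerMap, SnpTable
from .xpr import ExpressionMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class Hotspot:
    """A pleiotropic trans-acting locus.

    ``treatment`` restricts the hotspot's activity to one maternal
    environment (``"HP"``/``"LN"``) or both (``None``).  Each of the
    ``n_targets`` randomly chosen target genes receives an effect of
    ``effect_size`` whose sign favours the MM allele with probability
    ``frac_mm_up`` (positive sign = MM allele raises abundance, matching the
    sign convention of the eQTL output).
    """

    chrom: str
    pos_bp: float
    n_targets: int = 50
    effect_size: float = 1.0
    treatment: str | None = None
    frac_mm_up: float = 0.8


def _default_hotspots() -> list[Hotspot]:
    # one hotspot exclusive to each maternal environment, placed on the
    # distal arm (LN) and pericentromere (HP) like the dominant bands the
    # design emulates
    return [
        Hotspot(chrom="chr03", pos_bp=58e6, n_targets=50, effect_size=1.0,
                treatment="LN", frac_mm_up=0.9),
        Hotspot(chrom="chr06", pos_bp=33e6, n_targets=50, effect_size=1.0,
                treatment="HP", frac_mm_up=0.2),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical config (incl. seed) gives
    bit-identical outputs.

    Population sizes default to the study design the generator emulates:
    49 RILs in the high-phosphorus (HP) environment, 52 in the low-nitrogen
    (LN) environment, 3 parental replicates per line per environment, and a
    mean of two crossovers per RIL per chromosome on 12 chromosomes.
    """

    n_chromosomes: int = 12
    chrom_length_bp: float = 65e6
    n_rils_hp: int = 49
    n_rils_ln: int = 52
    n_parent_reps: int = 3
    n_snps: int = 6000
    n_genes: int = 1000
    mean_crossovers_per_chrom: float = 2.0
    arm_bias: float = 0.8  # fraction of crossovers forced into distal thirds
    snp_missing_rate: float = 0.0
    # optional segregation distortion: (chromosome, target PI frequency)
    distortion: tuple[str, float] | None = None
    # effect model
    cis_fraction: float = 0.3
    cis_effect_size: float = 1.0
    hotspots: list[Hotspot] = field(default_factory=_default_hotspots)
    treatment_fraction: float = 0.2
    treatment_effect_size: float = 1.0
    gxe_fraction: float = 0.05
    gxe_effect_size: float = 1.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    residual_sd: float = 0.3
    nb_dispersion: float = 0.01
    library_size: float = 2e6
    gene_length_range: tuple[int, int] = (500, 5000)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_chromosomes=self.n_chromosomes,
            n_parent_reps=self.n_parent_reps,
            n_snps=self.n_snps,
            n_genes=self.n_genes,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_rils_hp < 0 or self.n_rils_ln < 0 or self.n_rils_hp + self.n_rils_ln < 2:
            raise ValueError("need at least 2 RILs in total")
        if self.chrom_length_bp <= 0:
            raise ValueError("chromosome length must be positive")
        if self.mean_crossovers_per_chrom < 0:
            raise ValueError("mean crossovers must be >= 0")
        if not 0.0 <= self.arm_bias <= 1.0:
            raise ValueError("arm_bias must be in [0, 1]")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    @property
    def ril_ids(self) -> list[str]:
        return [f"RIL{i + 1:03d}" for i in range(self.n_rils_hp + self.n_rils_ln)]


@dataclass
class SimTruth:
    """Ground truth of a simulated population.

    ``crossovers``: long table (line, chrom, pos_bp); ``start_codes``:
    lines x chromosomes matrix of the leftmost parental allele; ``genes``:
    per-gene truth (position, length, baseline, cis/treatment/GxE effects);
    ``hotspot_targets``: (gene, hotspot index, signed effect); ``ril_env``:
    environment assignment of each RIL.
    """

    crossovers: pd.DataFrame
    start_codes: pd.DataFrame
    genes: pd.DataFrame
    hotspots: list[Hotspot]
    hotspot_targets: pd.DataFrame
    ril_env: pd.Series

    @property
    def n_crossovers(self) -> int:
        return len(self.crossovers)

    def genotype_at(self, chrom: str, pos: float) -> pd.Series:
        """True genotype code (0=MM, 1=PI) of every RIL at a locus."""
        start = self.start_codes[chrom]
        out = start.copy().astype(float)
        xo = self.crossovers[self.crossovers["chrom"] == chrom]
        for line, sub in xo.groupby("line"):
            flips = int((sub["pos_bp"].to_numpy() <= pos).sum())
            if flips % 2:
                out.loc[line] = PI if start.loc[line] == MM else MM
        return out

    def zeroed(self) -> "SimTruth":
        """Copy with all genetic/treatment/GxE effects set to zero."""
        genes = self.genes.copy()
        genes[["cis_effect", "treatment_effect", "gxe_effect"]] = 0.0
        return SimTruth(
            crossovers=self.crossovers,
            start_codes=self.start_codes,
            genes=genes,
            hotspots=[],
            hotspot_targets=self.hotspot_targets.iloc[0:0],
            ril_env=self.ril_env,
        )


def _draw_crossover_positions(rng, k: int, length: float, arm_bias: float) -> np.ndarray:
    """Uniform positions, a fraction `arm_bias` forced into the distal thirds."""
    if k == 0:
        return np.empty(0)
    in_arm = rng.random(k) < arm_bias
    pos = rng.uniform(0, length, size=k)
    arm = rng.uniform(0, 2 * length / 3, size=k)
    arm = np.where(arm < length / 3, arm, arm + length / 3)  # [0,L/3) U [2L/3,L)
    return np.sort(np.where(in_arm, arm, pos))


def _simulate_mosaics(cfg: SimulationConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    rils = cfg.ril_ids
    xo_rows = []
    start = pd.DataFrame(index=rils, columns=cfg.chromosomes, dtype=float)
    for chrom in cfg.chromosomes:
        distort = cfg.distortion is not None and cfg.distortion[0] == chrom
        if distort:
            p_target = cfg.distortion[1]
            locus = cfg.chrom_length_bp / 2
        for line in rils:
            while True:
                k = rng.poisson(cfg.mean_crossovers_per_chrom)
                pos = _draw_crossover_positions(rng, k, cfg.chrom_length_bp, cfg.arm_bias)
                a0 = MM if rng.random() < 0.5 else PI
                if not distort:
                    break
                # rejection step: keep PI carriers at the distortion locus,
                # thin MM carriers so the locus reaches the target frequency
                flips = int((pos <= locus).sum())
                allele = a0 if flips % 2 == 0 else (PI if a0 == MM else MM)
                hi, lo = max(p_target, 1 - p_target), min(p_target, 1 - p_target)
                favored = PI if p_target >= 0.5 else MM
                if allele == favored or rng.random() < lo / hi:
                    break
            start.loc[line, chrom] = a0
            for p in pos:
                xo_rows.append((line, chrom, p))
    xo = pd.DataFrame(xo_rows, columns=["line", "chrom", "pos_bp"])
    return xo, start


def _genotypes_at_positions(
    xo: pd.DataFrame, start: pd.DataFrame, chrom: str, positions: np.ndarray
) -> np.ndarray:
    """Codes (lines x positions) for one chromosome; rows follow start.index."""
    out = np.empty((len(start), len(positions)))
    sub = xo[xo["chrom"] == chrom]
    by_line = {line: g["pos_bp"].to_numpy() for line, g in sub.groupby("line")}
    for i, line in enumerate(start.index):
        bp = np.sort(by_line.get(line, np.empty(0)))
        flips = np.searchsorted(bp, positions, side="left")
        a0 = start.loc[line, chrom]
        out[i] = np.where(flips % 2 == 0, a0, PI if a0 == MM else MM)
    return out


def simulate_population(cfg: SimulationConfig) -> tuple[SnpTable, GenotypeMatrix, SimTruth]:
    """Simulate RIL mosaics, a SNP-call table, and the gene-effect truth.

    Returns the raw SNP table (parental replicates + all RILs, allele-index
    calls with configurable missingness), the noise-free true genotype
    matrix at every SNP site, and the :class:`SimTruth` record.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    xo, start = _simulate_mosaics(cfg, rng)

    # SNP sites: evenly split across chromosomes, uniform positions
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1

    mm_samples = [f"MM_rep{r + 1}" for r in range(cfg.n_parent_reps)]
    pi_samples = [f"PI_rep{r + 1}" for r in range(cfg.n_parent_reps)]
    rils = cfg.ril_ids

    site_rows, call_blocks, truth_blocks, marker_rows = [], [], [], []
    for chrom, n_c in zip(cfg.chromosomes, per_chrom):
        pos = np.sort(rng.integers(1, int(cfg.chrom_length_bp), size=int(n_c)))
        ref = rng.integers(0, 4, size=int(n_c))
        alt = (ref + rng.integers(1, 4, size=int(n_c))) % 4
        truth = _genotypes_at_positions(xo, start, chrom, pos.astype(float))
        # which allele index carries the MM allele at each site (random phase)
        mm_is_ref = rng.random(int(n_c)) < 0.5
        calls = np.where(mm_is_ref[None, :], truth, 1.0 - truth)
        if cfg.snp_missing_rate > 0:
            miss = rng.random(calls.shape) < cfg.snp_missing_rate
            calls = np.where(miss, np.nan, calls)
        parent_mm = np.where(mm_is_ref, 0.0, 1.0)
        parent_pi = 1.0 - parent_mm
        block = np.column_stack(
            [np.tile(parent_mm[:, None], len(mm_samples)),
             np.tile(parent_pi[:, None], len(pi_samples)),
             calls.T]
        )
        for i in range(int(n_c)):
            site_rows.append((f"{chrom}_s{i + 1:05d}", chrom, int(pos[i]),
                              _BASES[ref[i]], _BASES[alt[i]]))
        call_blocks.append(block)
        truth_blocks.append(truth)
        marker_rows += [(f"{chrom}_s{i + 1:05d}", chrom, float(pos[i]))
                        for i in range(int(n_c))]

    sites = pd.DataFrame(site_rows, columns=["site", "chrom", "pos", "ref", "alt"])
    sites = sites.set_index("site")
    calls = pd.DataFrame(np.vstack(call_blocks), index=sites.index,
                         columns=mm_samples + pi_samples + rils)
    snp_table = SnpTable(sites=sites, calls=calls)

    truth_codes = pd.DataFrame(
        np.hstack(truth_blocks), index=rils, columns=sites.index
    )
    truth_gm = GenotypeMatrix(codes=truth_codes)

    genes = _simulate_gene_truth(cfg, rng)
    hs_targets = _assign_hotspot_targets(cfg, genes, rng)
    env = pd.Series(
        ["HP"] * cfg.n_rils_hp + ["LN"] * cfg.n_rils_ln, index=rils, name="env"
    )
    truth = SimTruth(
        crossovers=xo, start_codes=start, genes=genes,
        hotspots=list(cfg.hotspots), hotspot_targets=hs_targets, ril_env=env,
    )
    return snp_table, truth_gm, truth


def _simulate_gene_truth(cfg: SimulationConfig, rng) -> pd.DataFrame:
    n = cfg.n_genes
    chrom = rng.choice(cfg.chromosomes, size=n)
    length = rng.integers(*cfg.gene_length_range, size=n)
    start = rng.integers(1, int(cfg.chrom_length_bp) - int(cfg.gene_length_range[1]), size=n)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    cis = np.zeros(n)
    is_cis = rng.random(n) < cfg.cis_fraction
    sign = rng.choice([-1.0, 1.0], size=n)
    cis[is_cis] = (sign * cfg.cis_effect_size)[is_cis]
    treat = np.zeros(n)
    is_t = rng.random(n) < cfg.treatment_fraction
    treat[is_t] = (rng.choice([-1.0, 1.0], size=n) * cfg.treatment_effect_size)[is_t]
    gxe = np.zeros(n)
    is_g = rng.random(n) < cfg.gxe_fraction
    gxe[is_g] = (rng.choice([-1.0, 1.0], size=n) * cfg.gxe_effect_size)[is_g]
    genes = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + length - 1,
            "strand": rng.choice(["+", "-"], size=n),
            "length": length,
            "baseline": baseline,
            "cis_effect": cis,
            "treatment_effect": treat,
            "gxe_effect": gxe,
        },
        index=pd.Index([f"gene{i + 1:05d}" for i in range(n)], name="gene"),
    )
    return genes.sort_values(["chrom", "start"], kind="stable")


def _assign_hotspot_targets(cfg: SimulationConfig, genes: pd.DataFrame, rng) -> pd.DataFrame:
    rows = []
    for h_idx, hs in enumerate(cfg.hotspots):
        if hs.chrom not in cfg.chromosomes:
            raise ValueError(f"hotspot on unknown chromosome {hs.chrom!r}")
        # targets drawn among genes not on the hotspot chromosome so the
        # induced eQTLs are unambiguously trans
        pool = genes.index[genes["chrom"] != hs.chrom]
        if hs.n_targets > len(pool):
            raise ValueError("hotspot has more targets than available genes")
        targets = rng.choice(pool, size=hs.n_targets, replace=False)
        # positive effect = MM allele raises abundance; genotype code PI=1,
        # so the coefficient on the code is the negated effect
        signs = np.where(rng.random(hs.n_targets) < hs.frac_mm_up, 1.0, -1.0)
        for g, s in zip(targets, signs):
            rows.append((g, h_idx, s * hs.effect_size))
    return pd.DataFrame(rows, columns=["gene", "hotspot", "effect"])


def _sample_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for env in ("HP", "LN"):
        for parent in ("MM", "PI"):
            for r in range(cfg.n_parent_reps):
                rows.append((f"{parent}_{env}_rep{r + 1}", parent, env, True, r + 1))
    for line, env in zip(
        cfg.ril_ids, ["HP"] * cfg.n_rils_hp + ["LN"] * cfg.n_rils_ln
    ):
        rows.append((f"{line}_{env}", line, env, False, 1))
    return pd.DataFrame(
        rows, columns=["sample", "line", "treatment", "is_parent", "replicate"]
    ).set_index("sample")


def simulate_expression(
    truth_gm: GenotypeMatrix, truth: SimTruth, cfg: SimulationConfig
) -> ExpressionMatrix:
    """Draw a count matrix from the latent log2 effect model.

    Latent log2 expression per gene and sample = baseline + cis effect x
    genotype at the gene's locus + active hotspot effects x genotype at the
    hotspot + treatment term (+ for HP) + GxE term + N(0, residual_sd).
    Counts are negative-binomial around TPM-consistent means (expected reads
    proportional to abundance x gene length, scaled to the library size).
    Parental replicates share their line's genotype and differ only through
    the residual and counting noise.
    """
    for hs in truth.hotspots:
        if hs.chrom not in truth.start_codes.columns:
            raise ValueError(f"hotspot references unknown chromosome {hs.chrom!r}")
    if not truth.hotspot_targets.empty and not (
        truth.hotspot_targets["gene"].isin(truth.genes.index).all()
    ):
        raise ValueError("hotspot target references unknown gene")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))
    meta = _sample_metadata(cfg)
    genes = truth.genes
    n_s = len(meta)

    is_parent = meta["is_parent"].to_numpy(bool)
    line_arr = meta["line"].to_numpy()

    def locus_codes(chrom: str, pos: float) -> np.ndarray:
        """Genotype code of every sample at a locus (parents are pure)."""
        ril_codes = truth.genotype_at(chrom, pos)
        out = np.where(line_arr == "PI", PI, MM)
        out[~is_parent] = ril_codes.loc[line_arr[~is_parent]].to_numpy()
        return out

    env_sign = np.where(meta["treatment"].to_numpy() == "HP", 0.5, -0.5)

    latent = np.tile(genes["baseline"].to_numpy()[:, None], (1, n_s))
    # cis + GxE at the gene's own locus (effect sign: + = MM allele up)
    active = genes.index[(genes["cis_effect"] != 0) | (genes["gxe_effect"] != 0)]
    for g in active:
        row = genes.loc[g]
        x = locus_codes(row["chrom"], float(row["start"]))
        gi = genes.index.get_loc(g)
        latent[gi] += -row["cis_effect"] * x
        latent[gi] += -row["gxe_effect"] * x * env_sign
    # treatment main effect (+ = higher in HP)
    latent += genes["treatment_effect"].to_numpy()[:, None] * env_sign[None, :]
    # hotspots, active only in their environment
    for h_idx, hs in enumerate(truth.hotspots):
        x = locus_codes(hs.chrom, hs.pos_bp)
        if hs.treatment is None:
            mask = np.ones(n_s)
        else:
            mask = (meta["treatment"].to_numpy() == hs.treatment).astype(float)
        tgt = truth.hotspot_targets[truth.hotspot_targets["hotspot"] == h_idx]
        for _, t in tgt.iterrows():
            gi = genes.index.get_loc(t["gene"])
            latent[gi] += -t["effect"] * x * mask
    latent += rng.normal(0.0, cfg.residual_sd, size=latent.shape)

    # counts: expected reads ~ abundance x length, scaled to library size
    weight = (2.0 ** latent) * genes["length"].to_numpy()[:, None]
    mu = weight / weight.sum(axis=0, keepdims=True) * cfg.library_size
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=genes.index, columns=meta.index)
    return ExpressionMatrix(counts=counts_df, samples=meta)


def simulate_null(cfg: SimulationConfig) -> ExpressionMatrix:
    """Expression independent of genotype: all genetic and GxE effects zero,
    everything else (treatment term, residual and counting noise) as in
    :func:`simulate_expression`."""
    _, truth_gm, truth = simulate_population(cfg)
    null_truth = truth.zeroed()
    # keep the treatment main effect: the null concerns genetic effects only
    null_truth.genes["treatment_effect"] = truth.genes["treatment_effect"]
    return simulate_expression(truth_gm, null_truth, cfg)


def gene_annotation(truth: SimTruth) -> pd.DataFrame:
    """Gene annotation table (chrom, start, end, strand, length) from truth."""
    return truth.genes[["chrom", "start", "end", "strand", "length"]].copy()
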