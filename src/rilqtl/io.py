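"""File formats: TSV tables, minimal VCF, GFF3 annotation, BED intervals.

All tabular artifacts round-trip through plain TSV.  SNP tables can also be
exchanged as minimal VCF (CHROM/POS/REF/ALT + GT per sample), read back via
cyvcf2; gene annotation can come from GFF3 (via gffutils) or TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .snpmap import GenotypeMatrix, MarkerMap, SnpTable
from .xpr import ExpressionMatrix, validate_annotation


# --- SNP tables ------------------------------------------------------------

def write_snp_table(snps: SnpTable, path) -> None:
    wide = snps.sites.join(snps.calls)
    wide.to_csv(path, sep="\t", index_label="site")


def read_snp_table(path, parent_coded: bool = False) -> SnpTable:
    wide = pd.read_csv(path, sep="\t").set_index("site")
    site_cols = [c for c in ("chrom", "pos", "ref", "alt", "mm_allele", "pi_allele")
                 if c in wide.columns]
    sites = wide[site_cols]
    calls = wide.drop(columns=site_cols).astype(float)
    return SnpTable(sites=sites, calls=calls, parent_coded=parent_coded)


def write_vcf(snps: SnpTable, path) -> None:
    """Minimal VCF 4.2: GT per sample, REF/ALT from the site table."""
    samples = snps.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in snps.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        calls = snps.calls.to_numpy(float)
        for i, (site, row) in enumerate(snps.sites.iterrows()):
            gts = []
            for v in calls[i]:
                gts.append("./." if np.isnan(v) else f"{int(v)}/{int(v)}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{site}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> SnpTable:
    """Read a biallelic VCF into a SnpTable (homozygous GT -> allele index)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    site_rows, call_rows = [], []
    for i, var in enumerate(vcf):
        site_id = var.ID or f"{var.CHROM}_s{i + 1:05d}"
        site_rows.append((site_id, var.CHROM, var.POS, var.REF, var.ALT[0]))
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing; het treated as no call
        g = var.gt_types
        row = np.where(g == 0, 0.0, np.where(g == 2, 1.0, np.nan))
        call_rows.append(row)
    sites = pd.DataFrame(
        site_rows, columns=["site", "chrom", "pos", "ref", "alt"]
    ).set_index("site")
    calls = pd.DataFrame(call_rows, index=sites.index, columns=samples)
    return SnpTable(sites=sites, calls=calls)


# --- genotype matrix and marker map ---------------------------------------

def write_genotype_matrix(gm: GenotypeMatrix, path) -> None:
    out = gm.codes.replace({0.0: "MM", 1.0: "PI"}).fillna("NA")
    out.to_csv(path, sep="\t", index_label="line")


def read_genotype_matrix(path) -> GenotypeMatrix:
    raw = pd.read_csv(path, sep="\t").set_index("line")
    codes = raw.replace({"MM": 0.0, "PI": 1.0, "NA": np.nan}).astype(float)
    return GenotypeMatrix(codes=codes)


def write_marker_map(mm: MarkerMap, path) -> None:
    mm.table.to_csv(path, sep="\t", index_label="marker")


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t").set_index("marker"))


def write_breakpoints_bed(breakpoints: pd.DataFrame, path) -> None:
    """Breakpoint intervals as BED (0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": breakpoints["chrom"],
            "start": (breakpoints["left_bp"].astype(float) - 1).clip(lower=0).astype(int),
            "end": breakpoints["right_bp"].astype(float).astype(int),
            "name": breakpoints["line"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_bands_bed(bands: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": bands["chrom"],
            "start": bands["start_bp"].astype(int),
            "end": bands["end_bp"].astype(int),
            "name": bands["band"],
            "score": bands["n_eqtls"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


# --- expression ------------------------------------------------------------

def write_counts(em: ExpressionMatrix, path) -> None:
    em.counts.to_csv(path, sep="\t", index_label="gene")


def write_sample_metadata(em: ExpressionMatrix, path) -> None:
    em.samples.to_csv(path, sep="\t", index_label="sample")


def read_expression(counts_path, metadata_path) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t").set_index("gene")
    meta = pd.read_csv(metadata_path, sep="\t").set_index("sample")
    meta["is_parent"] = meta["is_parent"].astype(bool)
    return ExpressionMatrix(counts=counts[meta.index], samples=meta)


def write_layer(em: ExpressionMatrix, layer: str, path) -> None:
    em.layers[layer].to_csv(path, sep="\t", index_label="gene")


# --- annotation ------------------------------------------------------------

def read_gene_annotation(path, gff_id_attribute: str = "ID") -> pd.DataFrame:
    """Gene annotation from GFF3 or TSV (chrom, start, end, strand, length)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path, gff_id_attribute)
    return validate_annotation(pd.read_csv(path, sep="\t").set_index("gene"))


def _read_gff3(path: Path, id_attribute: str) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get(id_attribute, [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand,
                     feat.end - feat.start + 1))
    ann = pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "strand", "length"]
    ).set_index("gene")
    return validate_annotation(ann)


def read_term_sets(path) -> dict[str, set]:
    """Gene-term pair TSV (columns gene, term) -> {term: {genes}}."""
    pairs = pd.read_csv(path, sep="\t")
    return {term: set(sub["gene"]) for term, sub in pairs.groupby("term")}
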