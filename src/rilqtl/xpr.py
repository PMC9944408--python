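"""Expression normalization: TPM, log/ratio transforms, filtering, PCA.

Counts are length-normalized to transcripts per million (TPM) and then
carried through two transforms used by all downstream statistics:

* ``tpm_log``:  log2(TPM + 1), the scale for linear models, heritability and
  eQTL mapping;
* ``tpm_rat``:  log2(TPM / per-gene mean TPM), a per-gene ratio-to-mean used
  for sample-level PCA.

Genes are retained only when detected (TPM > 0) in every sample of the
analysis set, which also guarantees ``tpm_rat`` is finite everywhere after
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["line", "treatment", "is_parent", "replicate"]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression container.

    ``counts`` is a genes x samples integer DataFrame; ``samples`` is indexed
    by sample id with columns ``line``, ``treatment`` (HP/LN), ``is_parent``
    (bool) and ``replicate``.  Derived layers (``tpm``, ``tpm_log``,
    ``tpm_rat``) live in ``layers`` with the same shape as ``counts``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    layers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns: {missing}")
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("counts columns must match sample metadata index")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def sample_ids(self, treatment: str | None = None, parents: bool | None = None):
        sel = pd.Series(True, index=self.samples.index)
        if treatment is not None:
            sel &= self.samples["treatment"] == treatment
        if parents is not None:
            sel &= self.samples["is_parent"] == parents
        return self.samples.index[sel]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.loc[genes],
            samples=self.samples,
            layers={k: v.loc[genes] for k, v in self.layers.items()},
        )


def read_gene_annotation_tsv(path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene, chrom, start, end, strand, length)."""
    ann = pd.read_csv(path, sep="\t").set_index("gene")
    return validate_annotation(ann)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if (ann["start"] > ann["end"]).any():
        bad = ann.index[ann["start"] > ann["end"]].tolist()
        raise ValueError(f"annotation start > end for: {bad[:5]}")
    if "length" not in ann.columns:
        ann = ann.assign(length=ann["end"] - ann["start"] + 1)
    if (ann["length"] <= 0).any():
        raise ValueError("non-positive gene lengths in annotation")
    return ann


def compute_tpm(em: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Add the TPM layer: (count/length) scaled to one million per sample."""
    lengths = annotation["length"].reindex(em.genes)
    if lengths.isna().any():
        missing = em.genes[lengths.isna()].tolist()
        raise ValueError(f"no annotated length for genes: {missing[:5]}")
    totals = em.counts.sum(axis=0)
    dead = totals.index[totals == 0].tolist()
    if dead:
        raise ValueError(f"sample(s) with all-zero counts: {dead}")
    rate = em.counts.div(lengths, axis=0)
    em.layers["tpm"] = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return em


def transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Add ``tpm_log`` and ``tpm_rat`` layers.

    ``tpm_rat`` uses the arithmetic mean of TPM over all samples currently in
    the matrix; entries for genes with any zero TPM are non-finite and must
    be removed by :func:`filter_expressed` before use.
    """
    tpm = em.layers["tpm"]
    em.layers["tpm_log"] = np.log2(tpm + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        em.layers["tpm_rat"] = np.log2(tpm.div(tpm.mean(axis=1), axis=0))
    return em


def filter_expressed(em: ExpressionMatrix) -> ExpressionMatrix:
    """Keep genes with TPM_log > 0 (i.e. TPM > 0) in every sample."""
    tpm = em.layers["tpm"]
    keep = (tpm > 0).all(axis=1)
    return em.subset_genes(em.genes[keep])


def pca_samples(em: ExpressionMatrix, layer: str = "tpm_rat"):
    """Sample-level PCA on the chosen layer (centered, unscaled).

    Returns ``(coordinates, variance_fractions)``: coordinates is a samples x
    components DataFrame, variance fractions sum to 1 over all components.
    """
    from sklearn.decomposition import PCA

    x = em.layers[layer].to_numpy(float).T  # samples x genes
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not np.isfinite(x).all():
        raise ValueError(f"layer {layer!r} has non-finite entries; filter first")
    pca = PCA(n_components=None)
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=em.counts.columns, columns=cols),
        pd.Series(pca.explained_variance_ratio_, index=cols, name="var_frac"),
    )
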