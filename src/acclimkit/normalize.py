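"""Contig abundance filtering, size-factor normalization, and sample QC.

Normalization uses the median-of-ratios estimator: for sample ``j``,

    s_j = median_g  count[g, j] / ( prod_k count[g, k] )^(1/n)

taken over genes with strictly positive counts in every sample (the
geometric mean is otherwise zero). Size factors are identifiable only up
to a common scale; no rescaling is applied here, callers comparing
against external factors should fix a gauge (e.g. geometric mean 1).

Outlier screening mirrors the field's visual PCA check with an explicit
rule: robust z-scores (median/MAD) of the first two principal-component
scores of log-transformed samples, flagged above a threshold. Flagging
and removal are separate calls so the decision stays explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CountMatrix, ExperimentDesign, NormalizedMatrix, ValidationError

_MAD_SCALE = 1.4826  # consistency constant: MAD -> SD under normality


@dataclass(frozen=True)
class FilterReport:
    """Per-gene record of the abundance filter decision."""

    table: pd.DataFrame = field(repr=False)  # mean, sd, passed_mean, passed_sd, kept

    @property
    def kept_genes(self) -> pd.Index:
        return self.table.index[self.table["kept"]]


@dataclass(frozen=True)
class OutlierReport:
    """PCA scores, robust z-scores and flags per sample."""

    table: pd.DataFrame = field(repr=False)  # pc1, pc2, z_pc1, z_pc2, flagged
    z_threshold: float
    n_components: int = 2

    @property
    def flagged(self) -> pd.Index:
        return self.table.index[self.table["flagged"]]


def filter_contigs(counts: CountMatrix, min_mean: float = 5.0) -> tuple[CountMatrix, FilterReport]:
    """Keep genes with mean count > ``min_mean`` and sample SD < mean.

    Both inequalities are strict. The SD is the sample (n-1) standard
    deviation, so at least two samples are required.
    """
    if counts.shape[1] < 2:
        raise ValidationError("abundance filter needs >=2 samples (SD undefined)")
    arr = counts.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    passed_mean = mean > min_mean
    passed_sd = sd < mean
    kept = passed_mean & passed_sd
    report = FilterReport(
        pd.DataFrame(
            {
                "mean": mean,
                "sd": sd,
                "passed_mean": passed_mean,
                "passed_sd": passed_sd,
                "kept": kept,
            },
            index=counts.gene_ids,
        )
    )
    if kept.sum() < 2:
        raise ValidationError(
            f"fewer than 2 genes pass the abundance filter (kept {int(kept.sum())})"
        )
    return CountMatrix(counts.values.loc[kept]), report


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, one positive real per sample."""
    arr = counts.values.to_numpy(dtype=float)
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise ValidationError(
            "no gene has strictly positive counts in all samples; size factors "
            "are undefined — consider filtering low-abundance genes first"
        )
    sub = arr[eligible]
    log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_gm)
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def normalize(counts: CountMatrix, sf: pd.Series) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    missing = set(counts.sample_ids) - set(sf.index)
    if missing:
        raise ValidationError(f"size factors missing for samples: {sorted(missing)[:5]}")
    sf = sf.reindex(counts.sample_ids).astype(float)
    vals = counts.values.div(sf, axis=1)
    return NormalizedMatrix(vals, sf)


def log_transform(norm: NormalizedMatrix | pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(value + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    vals = norm.values if isinstance(norm, NormalizedMatrix) else norm
    return np.log2(vals + pseudocount)


def flag_outlier_samples(
    norm: NormalizedMatrix,
    design: ExperimentDesign | None = None,
    z_threshold: float = 3.0,
    pseudocount: float = 1.0,
) -> OutlierReport:
    """Flag samples far from the bulk on the first two PCs.

    The matrix is log2(x+pc) transformed, genes are centered, and sample
    scores on PC1/PC2 are converted to robust z-scores
    ``|score - median| / (1.4826 * MAD)``; a sample is flagged when either
    z exceeds ``z_threshold``. The design argument is accepted for column
    alignment only — flagging never looks at the factors.
    """
    vals = norm.values
    if design is not None:
        vals = vals.loc[:, design.sample_ids]
    if vals.shape[1] < 3:
        raise ValidationError("outlier PCA needs >=3 samples")
    logx = np.log2(vals.to_numpy(dtype=float) + pseudocount)
    centered = logx - logx.mean(axis=1, keepdims=True)  # center each gene
    if not np.any(centered != 0):
        raise ValidationError("matrix has zero variance; PCA undefined")
    # samples as observations: SVD of (samples x genes)
    u, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    scores = u[:, :2] * s[:2]
    if scores.shape[1] < 2:  # degenerate rank-1 case
        scores = np.column_stack([scores[:, 0], np.zeros(scores.shape[0])])
    z = np.empty_like(scores)
    for k in range(2):
        med = np.median(scores[:, k])
        mad = np.median(np.abs(scores[:, k] - med))
        denom = _MAD_SCALE * mad
        if denom == 0:
            z[:, k] = np.where(scores[:, k] == med, 0.0, np.inf)
        else:
            z[:, k] = np.abs(scores[:, k] - med) / denom
    flagged = (z > z_threshold).any(axis=1)
    table = pd.DataFrame(
        {
            "pc1": scores[:, 0],
            "pc2": scores[:, 1],
            "z_pc1": z[:, 0],
            "z_pc2": z[:, 1],
            "flagged": flagged,
        },
        index=vals.columns,
    )
    return OutlierReport(table, z_threshold=float(z_threshold))


def drop_samples(counts: CountMatrix, sample_ids) -> CountMatrix:
    """Remove the given samples from a count matrix."""
    drop = set(sample_ids)
    keep = [s for s in counts.sample_ids if s not in drop]
    return CountMatrix(counts.values.loc[:, keep])
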