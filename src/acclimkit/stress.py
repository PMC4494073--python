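"""Heat-stress response, cluster resampling nulls, and dampening metrics.

The per-gene heat-stress response is the log2 fold change between
stressed and nonstressed arms of a stratum,

    log2fc_g = log2( (mean stressed_g + pc) / (mean nonstressed_g + pc) ),

on normalized (linear-scale) expression with a small pseudocount pc
guarding zero means. A cluster's response is tested against a resampling
null: the mean response of the cluster is compared with the means of
randomly drawn gene sets of the same size from the filtered background,
giving an empirical two-sided p-value and a central 95% envelope.

Transcriptional dampening is quantified by regressing acclimated
responses on control responses through the origin: a slope below 1 (with
a gene-resampling bootstrap interval excluding 1) means acclimated
colonies mount a proportionally smaller transcriptional response.
Mechanism classification separates "dampening" (muted response with an
unchanged baseline) from "frontloading" (baseline already shifted before
acute stress, with reduced further induction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign, NormalizedMatrix, ValidationError


@dataclass(frozen=True)
class ClusterNullResult:
    """Resampling-null test of one cluster's mean response."""

    label: str
    observed: float
    null_samples: np.ndarray = field(repr=False)
    p_value: float
    envelope: tuple[float, float]
    n_draws: int

    @property
    def null_mean(self) -> float:
        return float(self.null_samples.mean())


@dataclass(frozen=True)
class DampeningResult:
    """Through-origin slope of acclimated vs control responses."""

    slope: float
    ci_low: float
    ci_high: float
    ratio: float  # mean|acclimated| / mean|control|
    dampened: bool
    n_genes: int
    n_bootstrap: int


def _stratum_mask(design: ExperimentDesign, stratum) -> pd.Series:
    if stratum is None:
        return pd.Series(True, index=design.sample_ids)
    if isinstance(stratum, str):
        return design.mask(stratum)
    mask = pd.Series(np.asarray(stratum, dtype=bool), index=design.sample_ids)
    return mask


def gene_log2fc(
    norm: NormalizedMatrix | pd.DataFrame,
    design: ExperimentDesign,
    stratum=None,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene stressed-vs-nonstressed log2 fold change within a stratum.

    ``stratum`` may be None (all samples), a design query string such as
    ``"day == 11 and treatment == 'control29'"``, or a boolean mask.
    """
    vals = norm.values if isinstance(norm, NormalizedMatrix) else norm
    mask = _stratum_mask(design, stratum)
    cond = design.table["condition"]
    stressed = design.sample_ids[mask & (cond == "stressed")]
    nonstressed = design.sample_ids[mask & (cond == "nonstressed")]
    if len(stressed) == 0 or len(nonstressed) == 0:
        raise ValidationError(
            f"stratum needs both arms: {len(stressed)} stressed, "
            f"{len(nonstressed)} nonstressed"
        )
    ms = vals.loc[:, stressed].mean(axis=1)
    mn = vals.loc[:, nonstressed].mean(axis=1)
    out = np.log2((ms + pseudocount) / (mn + pseudocount))
    out.name = "log2fc"
    return out


def cluster_null_test(
    log2fc: pd.Series,
    cluster_genes,
    background_genes=None,
    n_draws: int = 1000,
    seed: int | None = 0,
    label: str = "cluster",
) -> ClusterNullResult:
    """Compare a cluster's mean response with same-size random gene sets.

    Draws are without replacement from the background (default: all genes
    in ``log2fc``). The two-sided p-value is centered on the null mean:
    p = (1 + #{|null_b - mean| >= |observed - mean|}) / (n_draws + 1).
    """
    if n_draws < 999:
        raise ValidationError(f"n_draws must be >= 999, got {n_draws}")
    background = (
        log2fc.index if background_genes is None else pd.Index(background_genes)
    )
    cluster = pd.Index(cluster_genes)
    if not set(cluster) <= set(background):
        raise ValidationError("cluster must be a subset of the background")
    k, n = len(cluster), len(background)
    if k > n:
        raise ValidationError(f"cluster size {k} exceeds background size {n}")
    if k == 0:
        raise ValidationError("empty cluster")
    bg = log2fc.loc[background].to_numpy(dtype=float)
    observed = float(log2fc.loc[cluster].mean())
    rng = np.random.default_rng(seed)
    # without-replacement draws via row-wise argpartition of random keys
    keys = rng.random((n_draws, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null = bg[idx].mean(axis=1)
    center = null.mean()
    exceed = np.abs(null - center) >= np.abs(observed - center) - 1e-15
    p = (1 + int(exceed.sum())) / (n_draws + 1)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return ClusterNullResult(
        label=label,
        observed=observed,
        null_samples=null,
        p_value=float(p),
        envelope=(float(lo), float(hi)),
        n_draws=n_draws,
    )


def through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x with no intercept: sum(xy)/sum(x^2)."""
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValidationError("all control responses are zero; slope undefined")
    return float(np.dot(x, y) / denom)


def dampening_index(
    log2fc_control: pd.Series,
    log2fc_acclimated: pd.Series,
    n_bootstrap: int = 1000,
    seed: int | None = 0,
) -> DampeningResult:
    """Quantify dampening as the through-origin slope of acclimated on control.

    Also reports the ratio of mean absolute responses. Dampening is
    declared when the slope is below 1 and the gene-resampling bootstrap
    95% interval excludes 1.
    """
    common = log2fc_control.index.intersection(log2fc_acclimated.index)
    if len(common) != len(log2fc_control) or len(common) != len(log2fc_acclimated):
        raise ValidationError("control and acclimated responses must share a gene set")
    x = log2fc_control.loc[common].to_numpy(dtype=float)
    y = log2fc_acclimated.loc[common].to_numpy(dtype=float)
    slope = through_origin_slope(x, y)
    mean_abs_x = np.abs(x).mean()
    ratio = float(np.abs(y).mean() / mean_abs_x) if mean_abs_x > 0 else np.nan
    rng = np.random.default_rng(seed)
    n = x.size
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        take = rng.integers(0, n, size=n)
        xb = x[take]
        denom = np.dot(xb, xb)
        boot[b] = np.dot(xb, y[take]) / denom if denom > 0 else np.nan
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    dampened = bool(slope < 1.0 and hi < 1.0)
    return DampeningResult(
        slope=slope,
        ci_low=float(lo),
        ci_high=float(hi),
        ratio=ratio,
        dampened=dampened,
        n_genes=int(n),
        n_bootstrap=int(n_bootstrap),
    )


def classify_mechanism(
    baseline_control: pd.Series,
    baseline_acclimated: pd.Series,
    stressed_control: pd.Series,
    stressed_acclimated: pd.Series,
    tau_baseline: float = 0.5,
    tau_response: float = 0.25,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Label each gene ``dampening``, ``frontloading`` or ``none``.

    Inputs are per-gene mean normalized expression for the four arms
    (baseline = nonstressed). All comparisons happen in log2 units:

    * baseline shift  Dbase = |log2 baseline_acclimated - log2 baseline_control|
    * per-arm response r_arm = log2 stressed_arm - log2 baseline_arm

    ``frontloading``: baseline shifted (Dbase > tau_baseline) and the
    acclimated response magnitude is smaller than control's.
    ``dampening``: baseline unchanged (Dbase <= tau_baseline) and the
    acclimated response magnitude is smaller by more than tau_response.
    Everything else: ``none``.
    """
    idx = baseline_control.index
    for ser in (baseline_acclimated, stressed_control, stressed_acclimated):
        if not ser.index.equals(idx):
            raise ValidationError("all four arm means must share one gene index")

    def _log2(s):
        return np.log2(s.to_numpy(dtype=float) + pseudocount)

    b_ctrl, b_acc = _log2(baseline_control), _log2(baseline_acclimated)
    s_ctrl, s_acc = _log2(stressed_control), _log2(stressed_acclimated)
    d_base = np.abs(b_acc - b_ctrl)
    resp_ctrl = s_ctrl - b_ctrl
    resp_acc = s_acc - b_acc
    muted = np.abs(resp_acc) < np.abs(resp_ctrl)
    labels = np.full(idx.size, "none", dtype=object)
    labels[(d_base > tau_baseline) & muted] = "frontloading"
    labels[
        (d_base <= tau_baseline)
        & (np.abs(resp_acc) < np.abs(resp_ctrl) - tau_response)
    ] = "dampening"
    return pd.Series(labels, index=idx, name="mechanism")


def arm_means(
    norm: NormalizedMatrix | pd.DataFrame,
    design: ExperimentDesign,
    treatment_query: str,
    stressed_stratum: str | None = "day in (7, 11)",
    baseline_stratum: str | None = None,
) -> tuple[pd.Series, pd.Series]:
    """(baseline, stressed) per-gene mean expression for one treatment arm.

    The stressed arm defaults to the post-onset days (7 and 11), when
    acclimation-dependent stress responses are expected; the baseline
    (nonstressed) arm defaults to all days, since a baseline shift is a
    property of the acclimation regime rather than one time point and the
    wider pool stabilizes the mean for high-dispersion genes.
    """
    vals = norm.values if isinstance(norm, NormalizedMatrix) else norm
    base_q = f"({treatment_query}) and condition == 'nonstressed'"
    stress_q = f"({treatment_query}) and condition == 'stressed'"
    if baseline_stratum:
        base_q += f" and ({baseline_stratum})"
    if stressed_stratum:
        stress_q += f" and ({stressed_stratum})"
    baseline_ids = design.subset(base_q).sample_ids
    stressed_ids = design.subset(stress_q).sample_ids
    if len(baseline_ids) == 0 or len(stressed_ids) == 0:
        raise ValidationError(
            f"no samples for arm {treatment_query!r} "
            f"(strata: stressed {stressed_stratum!r}, baseline {baseline_stratum!r})"
        )
    return (
        vals.loc[:, baseline_ids].mean(axis=1),
        vals.loc[:, stressed_ids].mean(axis=1),
    )
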