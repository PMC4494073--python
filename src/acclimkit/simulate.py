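"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the factorial acclimation experiment: a 144-sample
design (3 acclimation regimes x 6 colonies per batch x 4 days x
stressed/nonstressed branches), negative-binomial read counts with
per-sample size factors, and planted gene modules whose heat-stress
responses depend on acclimation treatment:

* ``up_dampened`` / ``down_dampened`` — genes induced/repressed by acute
  heat stress, with the response multiplied by a dampening factor
  d in [0, 1] in acclimated treatments once acclimation has taken hold
  (days 7 and 11 by default). Both acclimated regimes share identical
  parameters, encoding the stable-vs-variable null.
* ``frontloaded`` — baseline expression shifted up in acclimated
  colonies before stress, with the same muted further induction.
* ``background_de`` — stress-responsive in every treatment alike, the
  large backdrop of generic heat-stress genes.

All module genes also receive a day-2 expression spike shared across
treatments, mimicking transplantation stress. A separate operation
multiplies a random subset of genes in chosen samples to recreate the
nine-sample technical-artifact pattern that PCA screening must catch.

The log2 mean model for gene g in sample s is

    mu[g, s] = b_g + colony[g, c(s)] + spike_g * 1[day = 2]
               + delta_g * 1[acclimated] + beta_g * 1[stressed] * m(g, s)

with m(g, s) = d for dampened/frontloaded genes in acclimated treatments
at or after the onset day, else 1; counts are NB with mean
sf_s * 2^mu[g, s] and gene-wise dispersion phi_g (variance
mean + phi * mean^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    ACCLIMATED_TREATMENTS,
    CountMatrix,
    DAYS,
    ExperimentDesign,
    TREATMENTS,
    ValidationError,
    canonical_design,
)
from .phenotype import DEFAULT_CHL_COEFFICIENTS

#: Relative spectral shape used to invert the chlorophyll equation.
_ABS_SHAPE = np.array([0.05, 0.10, 1.00, 0.02])


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic experiment; the defaults are the study
    conditions every simulation-based check runs under."""

    seed: int
    n_genes: int = 2000
    n_up_dampened: int = 100
    n_down_dampened: int = 600
    n_frontloaded: int = 100
    n_background_de: int = 800
    beta_up: float = 1.5           # log2 stress response of induced module
    beta_down: float = -1.5        # log2 stress response of repressed module
    beta_background_range: tuple[float, float] = (0.5, 2.0)  # |beta|, random sign
    dampening: float = 0.4         # d for both acclimated treatments
    dampening_onset_day: int = 7
    baseline_shift: float = 1.0    # delta (log2) for frontloaded genes
    baseline_log2_range: tuple[float, float] = (3.0, 9.0)
    dispersion_range: tuple[float, float] = (0.01, 0.5)  # log-uniform
    size_factor_range: tuple[float, float] = (0.5, 2.0)  # log-uniform
    sigma_colony: float = 0.2      # SD of per-gene colony effects (log2)
    spike_day2: float = 0.5        # log2 spike for module genes at day 2
    # design
    treatments: tuple[str, ...] = TREATMENTS
    days: tuple[int, ...] = DAYS
    colonies_per_treatment: int = 6
    # phenotype
    chl_baseline: dict = field(
        default_factory=lambda: {
            "control29": 1.5,
            "stable31": 2.25,
            "variable29_33": 2.25,
        }
    )  # nonstressed chl density, ug/cm^2
    retained: dict = field(
        default_factory=lambda: {
            "control29": 0.4,
            "stable31": 0.7,
            "variable29_33": 0.7,
        }
    )  # planted retained chlorophyll fraction (days >= 2)
    sigma_fraction: float = 0.05
    sigma_density: float = 0.1     # log-normal sigma on baseline density
    area_range: tuple[float, float] = (10.0, 30.0)  # branch area, cm^2
    wax_slope: float = 25.0        # cm^2 per g of second-dip weight gain
    wax_intercept: float = 0.0
    weight_noise_sd: float = 0.0005  # g
    absorbance_noise_sd: float = 0.002
    extract_volume_ml: float = 3.0
    standards_areas: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0)

    def __post_init__(self) -> None:
        n_mod = (
            self.n_up_dampened
            + self.n_down_dampened
            + self.n_frontloaded
            + self.n_background_de
        )
        if n_mod > self.n_genes:
            raise ValidationError(
                f"module sizes sum to {n_mod} > n_genes {self.n_genes}"
            )
        if not 0 <= self.dampening <= 1:
            raise ValidationError(f"dampening must be in [0, 1], got {self.dampening}")

    @classmethod
    def scaled(cls, seed: int, n_genes: int, **overrides) -> "GeneratorConfig":
        """Default study conditions at a different gene count: module sizes
        keep their default proportions (5% up-dampened, 30% down-dampened,
        5% frontloaded, 40% background DE)."""
        base = cls(seed=seed)
        ratio = n_genes / base.n_genes
        cfg = replace(
            base,
            n_genes=n_genes,
            n_up_dampened=int(round(base.n_up_dampened * ratio)),
            n_down_dampened=int(round(base.n_down_dampened * ratio)),
            n_frontloaded=int(round(base.n_frontloaded * ratio)),
            n_background_de=int(round(base.n_background_de * ratio)),
        )
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def null(cls, seed: int, n_genes: int = 500, **overrides) -> "GeneratorConfig":
        """No planted effects anywhere: no modules, no colony clustering,
        no day-2 spike. Under this configuration every sample of a
        condition is exchangeable, which is the regime where permutation
        p-values are exactly valid."""
        base = cls(
            seed=seed,
            n_genes=n_genes,
            n_up_dampened=0,
            n_down_dampened=0,
            n_frontloaded=0,
            n_background_de=0,
            sigma_colony=0.0,
            spike_day2=0.0,
        )
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth behind one simulated count matrix."""

    genes: pd.DataFrame = field(repr=False)    # baseline_log2, dispersion, module, beta, dampening, baseline_shift, spike
    samples: pd.DataFrame = field(repr=False)  # size_factor, outlier
    mean_matrix: pd.DataFrame = field(repr=False)  # model means (pre-NB noise)
    config: GeneratorConfig = field(repr=False)


def simulate_design(config: GeneratorConfig) -> ExperimentDesign:
    """Factorial design for the configured treatments/days/colonies.

    Defaults give the canonical 144-sample layout.
    """
    return canonical_design(
        treatments=config.treatments,
        days=config.days,
        colonies_per_treatment=config.colonies_per_treatment,
    )


def _gene_table(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    width = max(4, len(str(n)))
    ids = pd.Index([f"g{str(i).zfill(width)}" for i in range(1, n + 1)], name="gene_id")
    module = np.full(n, "none", dtype=object)
    lo = 0
    for name, size in (
        ("up_dampened", config.n_up_dampened),
        ("down_dampened", config.n_down_dampened),
        ("frontloaded", config.n_frontloaded),
        ("background_de", config.n_background_de),
    ):
        module[lo : lo + size] = name
        lo += size
    baseline = rng.uniform(*config.baseline_log2_range, size=n)
    log_lo, log_hi = np.log(config.dispersion_range[0]), np.log(config.dispersion_range[1])
    dispersion = np.exp(rng.uniform(log_lo, log_hi, size=n))
    beta = np.zeros(n)
    beta[module == "up_dampened"] = config.beta_up
    beta[module == "down_dampened"] = config.beta_down
    beta[module == "frontloaded"] = config.beta_up
    n_bg = int((module == "background_de").sum())
    mag = rng.uniform(*config.beta_background_range, size=n_bg)
    sign = rng.choice([-1.0, 1.0], size=n_bg)
    beta[module == "background_de"] = mag * sign
    dampened = np.isin(module, ("up_dampened", "down_dampened", "frontloaded"))
    d = np.where(dampened, config.dampening, 1.0)
    delta = np.where(module == "frontloaded", config.baseline_shift, 0.0)
    spike = np.where(dampened, config.spike_day2, 0.0)
    return pd.DataFrame(
        {
            "baseline_log2": baseline,
            "dispersion": dispersion,
            "module": module,
            "beta_stress": beta,
            "dampening": d,
            "baseline_shift": delta,
            "spike_day2": spike,
        },
        index=ids,
    )


def model_mean_matrix(
    design: ExperimentDesign,
    genes: pd.DataFrame,
    size_factors: pd.Series,
    colony_effects: pd.DataFrame,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Expected counts sf_s * 2^mu[g, s] under the generator's mean model."""
    tab = design.table
    stressed = (tab["condition"] == "stressed").to_numpy()
    acclimated = tab["treatment"].isin(ACCLIMATED_TREATMENTS).to_numpy()
    day2 = (tab["day"] == 2).to_numpy()
    onset = (tab["day"] >= config.dampening_onset_day).to_numpy()
    modulated = np.isin(
        genes["module"].to_numpy(), ("up_dampened", "down_dampened", "frontloaded")
    )
    d = genes["dampening"].to_numpy()[:, None]
    mult = np.where(
        modulated[:, None] & (acclimated & onset)[None, :], d, 1.0
    )
    mu = (
        genes["baseline_log2"].to_numpy()[:, None]
        + colony_effects.loc[genes.index, tab["colony_id"]].to_numpy()
        + genes["spike_day2"].to_numpy()[:, None] * day2[None, :]
        + genes["baseline_shift"].to_numpy()[:, None] * acclimated[None, :]
        + genes["beta_stress"].to_numpy()[:, None] * stressed[None, :] * mult
    )
    mean = size_factors.to_numpy()[None, :] * np.exp2(mu)
    return pd.DataFrame(mean, index=genes.index, columns=design.sample_ids)


def simulate_counts(
    design: ExperimentDesign, config: GeneratorConfig
) -> tuple[CountMatrix, SimulationTruth]:
    """Draw a negative-binomial count matrix and return it with its truth."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config, rng)
    tab = design.table
    sf_lo, sf_hi = np.log(config.size_factor_range[0]), np.log(config.size_factor_range[1])
    sf = pd.Series(
        np.exp(rng.uniform(sf_lo, sf_hi, size=design.n_samples)),
        index=design.sample_ids,
        name="size_factor",
    )
    colonies = pd.Index(sorted(tab["colony_id"].unique()))
    colony_effects = pd.DataFrame(
        rng.normal(0.0, config.sigma_colony, size=(config.n_genes, colonies.size)),
        index=genes.index,
        columns=colonies,
    )
    mean = model_mean_matrix(design, genes, sf, colony_effects, config)
    m = mean.to_numpy()
    phi = genes["dispersion"].to_numpy()[:, None]
    if np.all(phi < 1e-8):
        counts = rng.poisson(m)
    else:
        size = 1.0 / np.maximum(phi, 1e-8)
        p = size / (size + m)
        counts = rng.negative_binomial(size, p)
    cm = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=genes.index, columns=design.sample_ids)
    )
    samples = pd.DataFrame({"size_factor": sf, "outlier": False})
    truth = SimulationTruth(genes=genes, samples=samples, mean_matrix=mean, config=config)
    return cm, truth


def inject_outliers(
    counts: CountMatrix,
    sample_ids: Sequence[str],
    scale: float = 10.0,
    fraction_genes: float = 0.3,
    seed: int | None = 0,
) -> CountMatrix:
    """Multiply a random gene subset by ``scale`` in the chosen samples.

    Recreates a tank-level technical artifact; with an empty sample list
    or scale 1 the matrix is returned unchanged.
    """
    if scale <= 0:
        raise ValidationError(f"scale must be > 0, got {scale}")
    missing = set(sample_ids) - set(counts.sample_ids)
    if missing:
        raise ValidationError(f"unknown sample(s): {sorted(missing)[:5]}")
    if not len(sample_ids) or scale == 1.0:
        return CountMatrix(counts.values.copy())
    rng = np.random.default_rng(seed)
    n_genes = counts.shape[0]
    n_hit = int(round(fraction_genes * n_genes))
    hit = rng.choice(n_genes, size=n_hit, replace=False)
    vals = counts.values.copy()
    cols = [vals.columns.get_loc(s) for s in sample_ids]
    block = vals.iloc[hit, cols].to_numpy(dtype=float) * scale
    vals.iloc[hit, cols] = np.round(block).astype(np.int64)
    return CountMatrix(vals)


def artifact_tank_samples(design: ExperimentDesign, day: int = 2) -> list[str]:
    """Stressed day-``day`` samples from the first tank of each treatment.

    In the canonical design this is nine samples, three per treatment —
    the layout of the experimental artifact the QC stage must flag.
    """
    tab = design.table
    first_tanks = {
        trt: sorted(tab.loc[tab["treatment"] == trt, "tank_id"].unique())[0]
        for trt in tab["treatment"].unique()
    }
    mask = (
        (tab["day"] == day)
        & (tab["condition"] == "stressed")
        & (tab["tank_id"] == tab["treatment"].map(first_tanks))
    )
    return list(tab.index[mask])


def simulate_phenotype(
    design: ExperimentDesign, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate phenotype records, calibration standards, and truth.

    Densities follow planted treatment-level baselines and retained
    fractions (day 0 uses the control fraction for every treatment — the
    transplantation artifact); absorbances are obtained by inverting the
    chlorophyll equation, and wax weights by inverting the planted area
    calibration. With all noise terms at zero the measurement pipeline
    reproduces the planted densities exactly.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 77]).generate_state(1)[0]
    )
    coef = np.asarray(DEFAULT_CHL_COEFFICIENTS)
    shape_gain = float(_ABS_SHAPE @ coef)
    tab = design.table
    rows, truth_rows = [], []
    for (colony, day), grp in tab.groupby(["colony_id", "day"], sort=True):
        trt = grp["treatment"].iloc[0]
        base_density = config.chl_baseline[trt] * np.exp(
            rng.normal(0.0, config.sigma_density)
        )
        planted_fraction = (
            config.retained["control29"] if day == 0 else config.retained[trt]
        )
        fraction = max(
            planted_fraction + rng.normal(0.0, config.sigma_fraction), 0.01
        )
        truth_rows.append(
            {
                "colony_id": colony,
                "day": day,
                "treatment": trt,
                "nonstressed_density": base_density,
                "retained_fraction": fraction,
            }
        )
        for sid, row in grp.iterrows():
            density = base_density * (fraction if row["condition"] == "stressed" else 1.0)
            area = rng.uniform(*config.area_range)
            total = density * area
            conc = total / config.extract_volume_ml
            absorb = _ABS_SHAPE * (conc / shape_gain)
            absorb = np.maximum(
                absorb + rng.normal(0.0, config.absorbance_noise_sd, size=4), 0.0
            )
            dw2 = (area - config.wax_intercept) / config.wax_slope
            w0 = rng.uniform(4.0, 6.0)
            w1 = w0 + 1.3 * dw2
            w2 = w1 + dw2 + rng.normal(0.0, config.weight_noise_sd)
            rows.append(
                {
                    "sample_id": sid,
                    "a632": absorb[0],
                    "a649": absorb[1],
                    "a665": absorb[2],
                    "a696": absorb[3],
                    "volume_ml": config.extract_volume_ml,
                    "w0": w0,
                    "w1": w1,
                    "w2": max(w2, w1),
                    "true_density": density,
                    "true_area": area,
                }
            )
    records = pd.DataFrame(rows).set_index("sample_id").loc[design.sample_ids]
    standards = pd.DataFrame(
        {
            "weight_gain": [
                (a - config.wax_intercept) / config.wax_slope
                + rng.normal(0.0, config.weight_noise_sd)
                for a in config.standards_areas
            ],
            "area": list(config.standards_areas),
        }
    )
    truth = pd.DataFrame(truth_rows).set_index(["colony_id", "day"])
    return records, standards, truth


def correlated_blocks(
    n_samples: int,
    block_sizes: Sequence[int],
    rho: float = 0.8,
    n_noise_genes: int = 0,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian expression with planted equicorrelated co-expression blocks.

    Genes in block b are x = sqrt(rho) * f_b + sqrt(1-rho) * eps with a
    shared per-sample factor f_b, giving pairwise correlation ``rho``
    within blocks and 0 between; ``n_noise_genes`` independent genes are
    appended. Returns the matrix and the true membership labels.
    """
    if not 0 <= rho < 1:
        raise ValidationError(f"rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, size in enumerate(block_sizes, start=1):
        f = rng.standard_normal(n_samples)
        eps = rng.standard_normal((size, n_samples))
        rows.append(np.sqrt(rho) * f[None, :] + np.sqrt(1 - rho) * eps)
        labels += [f"block_{b}"] * size
    if n_noise_genes:
        rows.append(rng.standard_normal((n_noise_genes, n_samples)))
        labels += ["none"] * n_noise_genes
    arr = np.vstack(rows)
    ids = pd.Index([f"g{str(i).zfill(4)}" for i in range(1, arr.shape[0] + 1)], name="gene_id")
    expr = pd.DataFrame(arr, index=ids, columns=[f"s{j}" for j in range(n_samples)])
    return expr, pd.Series(labels, index=ids, name="block")


def planted_effect_matrix(
    design: ExperimentDesign,
    n_genes: int = 500,
    n_true: int = 50,
    effect: float = 1.5,
    noise_sd: float = 0.5,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.Index]:
    """Gaussian log-expression testbed with a planted treatment effect.

    The first ``n_true`` genes are shifted by ``effect`` log2 units in the
    acclimated treatments; the rest are pure noise. Returns the matrix and
    the true-positive gene index, for power/FDR checks of the per-gene
    ANOVA without count-model noise.
    """
    rng = np.random.default_rng(seed)
    n = design.n_samples
    arr = rng.normal(5.0, noise_sd, size=(n_genes, n))
    acclimated = design.table["treatment"].isin(ACCLIMATED_TREATMENTS).to_numpy()
    arr[:n_true, acclimated] += effect
    ids = pd.Index(
        [f"g{str(i).zfill(4)}" for i in range(1, n_genes + 1)], name="gene_id"
    )
    expr = pd.DataFrame(arr, index=ids, columns=design.sample_ids)
    return expr, ids[:n_true]
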