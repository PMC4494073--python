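"""Chlorophyll-a bleaching phenotype: quantification and testing.

Chlorophyll a is quantified spectrophotometrically from absorbances at
four wavelengths of a 95%-ethanol extract. The concentration (ug/ml) is
a linear combination of the four optical densities; the default
coefficients are a published quadrachromatic equation for chlorophyll a
in ethanol, applied to A632, A649, A665 and A696 (study protocols
sometimes list 655 nm in place of 665 nm; the coefficients here are for
the 665 nm reading and are fully user-overridable). Total chlorophyll is
concentration times extract volume (default 3 ml).

Branch surface area comes from the wax-dip method: a branch is dipped in
melted wax twice and weighed after each dip; the second-dip weight gain
(the first dip seals the porous skeleton) is proportional to surface
area and is calibrated against standards of known area by ordinary least
squares. Bleaching resistance is the retained chlorophyll fraction —
area-normalized chlorophyll density of the stressed branch divided by
its paired nonstressed branch — tested with the same permutation ANOVA
engine as the expression analyses (treatment, day, interaction), with
day 0 excluded by default as a transplantation artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentDesign, ValidationError
from .permtest import permutation_anova

#: Quadrachromatic chl-a coefficients (ug/ml per OD) for 95% ethanol,
#: ordered as (A632, A649, A665, A696).
DEFAULT_CHL_COEFFICIENTS = (0.0604, -4.5224, 13.2969, -1.7453)

ABSORBANCE_COLUMNS = ("a632", "a649", "a665", "a696")


@dataclass(frozen=True)
class AreaStandardCurve:
    """OLS calibration of surface area against wax weight gain."""

    slope: float
    intercept: float
    r_squared: float
    n_standards: int


def chlorophyll_a(
    absorbances,
    coefficients=DEFAULT_CHL_COEFFICIENTS,
    volume: float = 3.0,
) -> float:
    """Total chlorophyll a (ug) from a 4-wavelength absorbance vector.

    concentration (ug/ml) = dot(coefficients, absorbances); total is
    concentration x extract volume (ml). Linear in both arguments; a
    negative result is reported as-is (it signals absorbances outside the
    equation's calibration range).
    """
    a = np.asarray(absorbances, dtype=float)
    c = np.asarray(coefficients, dtype=float)
    if a.shape[-1] != 4 or c.shape != (4,):
        raise ValidationError("need exactly 4 absorbances and 4 coefficients")
    if (a < 0).any():
        raise ValidationError("absorbances must be >= 0")
    if volume <= 0:
        raise ValidationError(f"extract volume must be > 0, got {volume}")
    return float(a @ c * volume) if a.ndim == 1 else a @ c * volume


def fit_area_curve(standards: pd.DataFrame | np.ndarray) -> AreaStandardCurve:
    """Fit area ~ weight gain by OLS over calibration standards.

    ``standards`` has two columns: weight gain (g) and known area (cm^2).
    Needs >= 3 standards with distinct weight gains.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("standards must be (weight_gain, area) pairs")
    if arr.shape[0] < 3:
        raise ValidationError(f"need >=3 standards, got {arr.shape[0]}")
    dw, area = arr[:, 0], arr[:, 1]
    if np.unique(dw).size < 2:
        raise ValidationError("standards need at least two distinct weight gains")
    res = stats.linregress(dw, area)
    return AreaStandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_standards=arr.shape[0],
    )


def branch_area(w1: float, w2: float, curve: AreaStandardCurve) -> float:
    """Surface area (cm^2) from the second-dip weight gain w2 - w1."""
    if w2 < w1:
        raise ValidationError(f"w2 ({w2}) must be >= w1 ({w1})")
    area = curve.slope * (w2 - w1) + curve.intercept
    if area <= 0:
        raise ValidationError(
            f"predicted area {area:.4g} cm^2 is not positive (dw={w2 - w1:.4g})"
        )
    return float(area)


def chlorophyll_density_table(
    records: pd.DataFrame,
    curve: AreaStandardCurve,
    coefficients=DEFAULT_CHL_COEFFICIENTS,
) -> pd.DataFrame:
    """Compute chl totals, areas and densities for a phenotype table.

    ``records`` is indexed by sample_id with absorbance columns
    ``a632, a649, a665, a696``, ``volume_ml`` and wax weights
    ``w0, w1, w2`` (bare, first dip, second dip).
    """
    missing = [c for c in (*ABSORBANCE_COLUMNS, "volume_ml", "w1", "w2") if c not in records.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    a = records.loc[:, list(ABSORBANCE_COLUMNS)].to_numpy(dtype=float)
    conc = a @ np.asarray(coefficients, dtype=float)
    total = conc * records["volume_ml"].to_numpy(dtype=float)
    areas = np.array(
        [branch_area(w1, w2, curve) for w1, w2 in zip(records["w1"], records["w2"])]
    )
    out = records.copy()
    out["chl_total_ug"] = total
    out["area_cm2"] = areas
    out["chl_density"] = total / areas
    return out


def retained_fraction(
    densities: pd.DataFrame, design: ExperimentDesign
) -> pd.DataFrame:
    """Stressed/nonstressed chlorophyll-density ratio per colony and day.

    ``densities`` must contain a ``chl_density`` column indexed by
    sample_id. Returns one row per (colony, day) with the treatment
    carried along; the ratio may exceed 1.
    """
    tab = design.table.join(densities["chl_density"], how="inner")
    rows = []
    for (colony, day), grp in tab.groupby(["colony_id", "day"], sort=True):
        stressed = grp.loc[grp["condition"] == "stressed", "chl_density"]
        nonstressed = grp.loc[grp["condition"] == "nonstressed", "chl_density"]
        if stressed.empty or nonstressed.empty:
            continue
        denom = float(nonstressed.mean())
        if denom == 0:
            raise ValidationError(
                f"nonstressed chlorophyll density is zero for colony {colony!r}, day {day}"
            )
        rows.append(
            {
                "colony_id": colony,
                "day": day,
                "treatment": grp["treatment"].iloc[0],
                "stressed_density": float(stressed.mean()),
                "nonstressed_density": denom,
                "retained_fraction": float(stressed.mean()) / denom,
            }
        )
    if not rows:
        raise ValidationError("no colony has both stressed and nonstressed branches")
    return pd.DataFrame(rows).set_index(["colony_id", "day"])


def phenotype_anova(
    values: pd.Series,
    factors: pd.DataFrame,
    exclude_day0: bool = True,
    n_permutations: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> pd.Series:
    """Permutational treatment x day ANOVA (with interaction) on phenotypes.

    ``values`` holds one real per observational unit (colony-day);
    ``factors`` supplies aligned ``treatment`` and ``day`` columns. Day-0
    rows are dropped by default (transplantation artifact).
    """
    if not values.index.equals(factors.index):
        raise ValidationError("values and factors must share an index")
    keep = factors["day"] != 0 if exclude_day0 else pd.Series(True, index=factors.index)
    vals, fac = values[keep], factors[keep]
    # reuse the expression engine through a minimal synthetic design
    from .design import CONDITIONS, ExperimentDesign as _ED

    df = pd.DataFrame(
        {
            "colony_id": [str(i) for i in range(len(fac))],
            "tank_id": "na",
            "batch": 1,
            "treatment": fac["treatment"].to_numpy(),
            "day": fac["day"].to_numpy(dtype=int),
            "condition": CONDITIONS[0],
        },
        index=pd.Index([f"obs{i}" for i in range(len(fac))], name="sample_id"),
    )
    dsn = _ED(df)
    y = pd.Series(vals.to_numpy(dtype=float), index=dsn.sample_ids)
    return permutation_anova(
        y,
        dsn,
        interaction=True,
        n_permutations=n_permutations,
        seed=seed,
        exhaustive=exhaustive,
    )
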