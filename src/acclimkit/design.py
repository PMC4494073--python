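"""Experimental-design and count-matrix data model, plus tabular I/O.

The experiment this package targets is a factorial thermal-acclimation
design: coral colonies are held under one of three acclimation regimes
(ambient ``control29``, stable elevated ``stable31``, or diurnally
fluctuating ``variable29_33``), sampled after 0, 2, 7 or 11 days of
acclimation, and each sampled branch is either put through an acute heat
stress (``stressed``) or held at ambient temperature (``nonstressed``).
Two collection batches supply the early (days 0, 2) and late (days 7, 11)
time points. The canonical layout is 3 treatments x 6 colonies per batch
x 4 days x 2 conditions = 144 samples.

All tabular data are plain delimiter-separated text with a header row;
matrices carry gene ids in the first column and sample ids in the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TREATMENTS = ("control29", "stable31", "variable29_33")
CONDITIONS = ("stressed", "nonstressed")
ACCLIMATED_TREATMENTS = ("stable31", "variable29_33")
DAYS = (0, 2, 7, 11)

#: Columns a design table must provide, in canonical order.
DESIGN_COLUMNS = (
    "sample_id",
    "colony_id",
    "tank_id",
    "batch",
    "treatment",
    "day",
    "condition",
)


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample-level factor table.

    Wraps a DataFrame indexed by ``sample_id`` with columns ``colony_id``,
    ``tank_id``, ``batch``, ``treatment``, ``day`` and ``condition``.
    Tank and batch are recorded for provenance but are not part of any
    model matrix in this package.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in DESIGN_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        if df.index.name != "sample_id":
            raise ValidationError("design table must be indexed by sample_id")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample_id(s): {dups}")
        bad_trt = sorted(set(df["treatment"]) - set(TREATMENTS))
        if bad_trt:
            raise ValidationError(
                f"unknown treatment level(s) {bad_trt}; allowed: {list(TREATMENTS)}"
            )
        bad_cond = sorted(set(df["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValidationError(
                f"unknown condition level(s) {bad_cond}; allowed: {list(CONDITIONS)}"
            )
        if not pd.api.types.is_integer_dtype(df["day"]):
            raise ValidationError("day must be integer")
        if not pd.api.types.is_integer_dtype(df["batch"]):
            raise ValidationError("batch must be integer")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def subset(self, mask) -> "ExperimentDesign":
        """Return a design restricted to samples where ``mask`` holds.

        ``mask`` may be a boolean vector aligned to the design, a query
        string evaluated against the factor columns (e.g. ``"day == 11"``),
        or an iterable of sample ids.
        """
        df = self.table
        if isinstance(mask, str):
            sub = df.query(mask)
        elif isinstance(mask, (pd.Series, np.ndarray, list)) and len(mask) == len(df) and (
            pd.api.types.is_bool_dtype(pd.Series(mask))
        ):
            sub = df.loc[np.asarray(mask, dtype=bool)]
        else:
            sub = df.loc[list(mask)]
        return ExperimentDesign(sub.copy())

    def mask(self, expr: str) -> pd.Series:
        """Boolean Series over samples for a query expression."""
        out = pd.Series(False, index=self.table.index)
        out.loc[self.table.query(expr).index] = True
        return out


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample matrix of nonnegative integer read counts."""

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(
                f"count matrix needs >=2 genes and >=2 samples, got {df.shape}"
            )
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated gene id(s): {dups}")
        if df.columns.duplicated().any():
            raise ValidationError("duplicated sample columns")
        if not all(pd.api.types.is_integer_dtype(t) for t in df.dtypes):
            raise ValidationError("counts must be integers")
        if (df.to_numpy() < 0).any():
            g, s = np.argwhere(df.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def align_to(self, design: ExperimentDesign) -> "CountMatrix":
        """Reorder columns to match ``design``; error on mismatch."""
        missing = set(design.sample_ids) - set(self.sample_ids)
        extra = set(self.sample_ids) - set(design.sample_ids)
        if missing or extra:
            raise ValidationError(
                "count matrix and design sample ids do not match "
                f"(missing from matrix: {sorted(missing)[:5]}, "
                f"unknown to design: {sorted(extra)[:5]})"
            )
        return CountMatrix(self.values.loc[:, design.sample_ids])

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(gene_ids)])


@dataclass(frozen=True)
class NormalizedMatrix:
    """Size-factor-normalized expression with the factors retained.

    Invariant: ``values[g, s] * size_factors[s] == counts[g, s]`` up to
    floating tolerance for the matrix it was derived from.
    """

    values: pd.DataFrame = field(repr=False)
    size_factors: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.size_factors.index):
            raise ValidationError("size factors must be indexed by the sample columns")
        sf = self.size_factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(sf)) or np.any(sf <= 0):
            raise ValidationError("size factors must be finite and > 0")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("normalized values must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def canonical_design(
    treatments: tuple[str, ...] = TREATMENTS,
    days: tuple[int, ...] = DAYS,
    colonies_per_treatment: int = 6,
) -> ExperimentDesign:
    """Build the canonical factorial design.

    Days 0 and 2 come from collection batch 2 and days 7 and 11 from
    batch 1; each batch has its own set of ``colonies_per_treatment``
    colonies per treatment, split over two replicate tanks. Every colony
    contributes a stressed and a nonstressed branch at each of its days.
    The defaults give the full 144-sample layout.
    """
    rows = []
    for trt in treatments:
        for day in days:
            batch = 2 if day in (0, 2) else 1
            for k in range(1, colonies_per_treatment + 1):
                tank = 1 if k <= (colonies_per_treatment + 1) // 2 else 2
                colony = f"{trt}.b{batch}.c{k}"
                for cond in CONDITIONS:
                    short = "hs" if cond == "stressed" else "ns"
                    rows.append(
                        {
                            "sample_id": f"{colony}.d{day}.{short}",
                            "colony_id": colony,
                            "tank_id": f"{trt}.t{tank}",
                            "batch": batch,
                            "treatment": trt,
                            "day": day,
                            "condition": cond,
                        }
                    )
    df = pd.DataFrame(rows).set_index("sample_id")
    return ExperimentDesign(df)


def read_counts(path, delimiter: str = "\t") -> CountMatrix:
    """Read a gene x sample integer count matrix.

    First column holds gene ids, header row holds sample ids.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    for col in df.columns:
        ser = df[col]
        if not pd.api.types.is_integer_dtype(ser):
            # accept floats that are exact integers (e.g. "3.0"), reject rest
            arr = ser.to_numpy()
            if not np.issubdtype(arr.dtype, np.number):
                bad = ser[pd.to_numeric(ser, errors="coerce").isna()].index[0]
                raise FormatError(
                    f"non-numeric count in column {col!r}, row {bad!r} of {path}"
                )
            if not np.allclose(arr, np.round(arr)):
                bad = ser[np.abs(arr - np.round(arr)) > 0].index[0]
                raise FormatError(
                    f"non-integer count in column {col!r}, row {bad!r} of {path}"
                )
            df[col] = np.round(arr).astype(np.int64)
    return CountMatrix(df)


def read_design(path, delimiter: str | None = None) -> ExperimentDesign:
    """Read a sample design table (TSV by default, CSV accepted)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=delimiter)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} missing design columns: {missing}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return ExperimentDesign(df)


def write_table(table, path, delimiter: str = "\t") -> None:
    """Write a tabular result as delimiter-separated text.

    Accepts DataFrames and the package's matrix/design wrappers; writes
    a header row with the index as the first column, full float precision
    so write -> read round-trips to 1e-12 or better.
    """
    if isinstance(table, (CountMatrix, NormalizedMatrix)):
        df = table.values
    elif isinstance(table, ExperimentDesign):
        df = table.table
    elif isinstance(table, pd.Series):
        df = table.to_frame()
    else:
        df = table
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_table(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep=delimiter, index_col=0)


def read_normalized(values_path, size_factor_path, delimiter: str = "\t") -> NormalizedMatrix:
    vals = read_table(values_path, delimiter)
    sf = read_table(size_factor_path, delimiter).iloc[:, 0]
    sf = sf.reindex(vals.columns)
    return NormalizedMatrix(vals, sf)
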