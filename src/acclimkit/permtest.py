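"""Permutation-based tests: two-factor ANOVA, two-group tests, BH-FDR.

The per-gene model is a fixed-effects linear model with categorical
acclimation treatment and day, no interaction (an interaction term is
available for the cluster-eigengene and phenotype analyses). Term F
statistics use Type-II sums of squares — each main effect is adjusted
for the other — so the tests are invariant to factor order in mildly
unbalanced designs such as the post-outlier-removal layout:

    SS_A = RSS(1 + B) - RSS(1 + A + B)
    F_A  = (SS_A / df_A) / (RSS_full / df_resid)

Significance comes from unrestricted permutation of the response vector
against the fixed design (Manly-style), which is exact under the global
exchangeable null. One shared permutation stream is applied to every
gene so a run is reproducible from a single seed and the genome-wide
null is exchangeable across genes. Empirical p-values use the add-one
estimator p = (1 + #{F_perm >= F_obs}) / (B + 1), hence the floor
1/(B+1); with exhaustive enumeration p = #{F_perm >= F_obs} / n_perm
over all permutations (the identity included).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign, ValidationError

_REL_TOL = 1e-9  # SS below this fraction of total variation counts as zero
_CMP_SLACK = 1e-12  # relative slack when counting F_perm >= F_obs


def _one_hot(codes: np.ndarray) -> np.ndarray:
    levels, idx = np.unique(codes, return_inverse=True)
    out = np.zeros((codes.shape[0], levels.shape[0]))
    out[np.arange(codes.shape[0]), idx] = 1.0
    return out


def _basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank by SVD tolerance)."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0:
        return u[:, :0]
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps))
    return u[:, :rank]


@dataclass(frozen=True)
class _TwoFactorModel:
    """Precomputed projection bases for a two-factor layout."""

    q_a: np.ndarray      # span{1, A}
    q_b: np.ndarray      # span{1, B}
    q_main: np.ndarray   # span{1, A, B}
    q_full: np.ndarray   # full model (main effects, or cell means if interaction)
    df: dict
    terms: tuple
    n: int

    @classmethod
    def build(cls, factor_a, factor_b, interaction: bool, names=("treatment", "day")):
        a = np.asarray(factor_a)
        b = np.asarray(factor_b)
        n = a.shape[0]
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            raise ValidationError(
                f"both factors need >=2 observed levels "
                f"({names[0]}: {np.unique(a).size}, {names[1]}: {np.unique(b).size})"
            )
        ones = np.ones((n, 1))
        da, db = _one_hot(a), _one_hot(b)
        q_a = _basis(np.hstack([ones, da]))
        q_b = _basis(np.hstack([ones, db]))
        q_main = _basis(np.hstack([ones, da, db]))
        terms = names
        if interaction:
            cell = _one_hot(np.char.add(a.astype(str), np.char.add("||", b.astype(str))))
            q_full = _basis(cell)
            terms = (*names, f"{names[0]}_x_{names[1]}")
        else:
            q_full = q_main
        r_a, r_b = q_a.shape[1], q_b.shape[1]
        r_main, r_full = q_main.shape[1], q_full.shape[1]
        df = {
            names[0]: r_main - r_b,
            names[1]: r_main - r_a,
            "resid": n - r_full,
        }
        if interaction:
            df[f"{names[0]}_x_{names[1]}"] = r_full - r_main
        if df["resid"] <= 0:
            raise ValidationError("saturated design: no residual degrees of freedom")
        return cls(q_a, q_b, q_main, q_full, df, terms, n)

    def f_stats(self, Y: np.ndarray) -> dict:
        """Term F statistics for each row of Y (genes x samples).

        Rows must be centered (the centering is permutation-invariant and
        makes the zero-variation tolerance exact for constant responses).
        """
        total = np.einsum("ij,ij->i", Y, Y)
        fit_a = np.einsum("ij,ij->i", Y @ self.q_a, Y @ self.q_a)
        fit_b = np.einsum("ij,ij->i", Y @ self.q_b, Y @ self.q_b)
        fit_main = np.einsum("ij,ij->i", Y @ self.q_main, Y @ self.q_main)
        fit_full = (
            fit_main
            if self.q_full is self.q_main
            else np.einsum("ij,ij->i", Y @ self.q_full, Y @ self.q_full)
        )
        rss_full = total - fit_full
        tol = _REL_TOL * np.maximum(total, np.finfo(float).tiny)
        ss = {
            self.terms[0]: fit_main - fit_b,
            self.terms[1]: fit_main - fit_a,
        }
        if len(self.terms) == 3:
            ss[self.terms[2]] = fit_full - fit_main
        out = {}
        resid_zero = rss_full <= tol
        for term in self.terms:
            s = np.maximum(ss[term], 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (s / self.df[term]) / (rss_full / self.df["resid"])
            f = np.where(s <= tol, 0.0, np.where(resid_zero, np.inf, f))
            out[term] = f
        return out


def _iter_permutations(n, n_permutations, seed, exhaustive, within=None):
    """Yield permutation index arrays (identity included when exhaustive)."""
    if exhaustive:
        if within is not None:
            raise ValidationError("exhaustive enumeration with restricted shuffling not supported")
        if math.factorial(n) > 500_000:
            raise ValidationError(f"exhaustive enumeration infeasible for n={n}")
        for p in itertools.permutations(range(n)):
            yield np.asarray(p)
        return
    rng = np.random.default_rng(seed)
    if within is None:
        for _ in range(n_permutations):
            yield rng.permutation(n)
    else:
        within = np.asarray(within)
        groups = [np.flatnonzero(within == lv) for lv in np.unique(within)]
        base = np.arange(n)
        for _ in range(n_permutations):
            perm = base.copy()
            for g in groups:
                perm[g] = g[rng.permutation(g.size)]
            yield perm


def permutation_anova(
    data,
    design: ExperimentDesign,
    terms: tuple[str, str] = ("treatment", "day"),
    interaction: bool = False,
    n_permutations: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
    permute_within: str | None = None,
) -> pd.DataFrame:
    """Two-factor permutational ANOVA for each row of ``data``.

    ``data`` is a DataFrame (genes x samples, columns matching the design)
    or a single per-sample Series. Returns a DataFrame with ``F_<term>``
    and ``p_<term>`` columns plus ``n_permutations``. Set
    ``exhaustive=True`` on small designs to enumerate all n! response
    permutations instead of sampling; ``permute_within`` restricts the
    shuffle to levels of one design factor.
    """
    squeeze = isinstance(data, pd.Series)
    df = data.to_frame().T if squeeze else data
    if not set(design.sample_ids) <= set(df.columns):
        raise ValidationError("data columns do not cover the design samples")
    df = df.loc[:, design.sample_ids]
    Y = df.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=1, keepdims=True)
    if not exhaustive and n_permutations < 99:
        raise ValidationError(
            f"need >=99 permutations for usable resolution, got {n_permutations}"
        )
    model = _TwoFactorModel.build(
        design.table[terms[0]].to_numpy(),
        design.table[terms[1]].to_numpy(),
        interaction,
        names=terms,
    )
    f_obs = model.f_stats(Y)
    counts = {t: np.zeros(Y.shape[0], dtype=np.int64) for t in model.terms}
    thresh = {
        t: np.where(np.isfinite(f_obs[t]), f_obs[t] * (1 - _CMP_SLACK) - _CMP_SLACK, f_obs[t])
        for t in model.terms
    }
    within = design.table[permute_within].to_numpy() if permute_within else None
    n_done = 0
    for perm in _iter_permutations(
        model.n, n_permutations, seed, exhaustive, within=within
    ):
        f_perm = model.f_stats(Y[:, perm])
        for t in model.terms:
            counts[t] += f_perm[t] >= thresh[t]
        n_done += 1
    out = {}
    for t in model.terms:
        out[f"F_{t}"] = f_obs[t]
        if exhaustive:
            out[f"p_{t}"] = counts[t] / n_done
        else:
            out[f"p_{t}"] = (1 + counts[t]) / (n_done + 1)
    res = pd.DataFrame(out, index=df.index)
    res["n_permutations"] = n_done
    return res.iloc[0] if squeeze else res


def fit_two_factor_f(y: pd.Series, design: ExperimentDesign) -> tuple[float, float]:
    """Observed (F_treatment, F_day) for one response vector.

    Constant responses give (0, 0); a perfectly separating term with zero
    residual gives the +inf sentinel.
    """
    y = y.loc[design.sample_ids]
    model = _TwoFactorModel.build(
        design.table["treatment"].to_numpy(),
        design.table["day"].to_numpy(),
        interaction=False,
    )
    yv = y.to_numpy(dtype=float)[None, :]
    f = model.f_stats(yv - yv.mean())
    return float(f["treatment"][0]), float(f["day"][0])


def permutation_pvalues(
    norm_log: pd.DataFrame,
    design: ExperimentDesign,
    n_permutations: int = 999,
    seed: int | None = 0,
    permute_within: str | None = None,
) -> pd.DataFrame:
    """Per-gene treatment/day permutation ANOVA with BH q-values.

    Expects log-scale normalized expression (genes x samples). Returns the
    gene test table: F, permutation p and BH q per term.
    """
    res = permutation_anova(
        norm_log,
        design,
        n_permutations=n_permutations,
        seed=seed,
        permute_within=permute_within,
    )
    for term in ("treatment", "day"):
        res[f"q_{term}"] = bh_fdr(res[f"p_{term}"].to_numpy())
    cols = [
        "F_treatment", "F_day", "p_treatment", "p_day",
        "q_treatment", "q_day", "n_permutations",
    ]
    return res[cols]


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1, returned in the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_significant(table: pd.DataFrame, term: str = "treatment", alpha: float = 0.01) -> pd.Index:
    """Genes with q_term <= alpha (inclusive)."""
    if term not in ("treatment", "day"):
        raise ValueError(f"term must be 'treatment' or 'day', got {term!r}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    col = f"q_{term}"
    return table.index[table[col] <= alpha]


def two_group_test(
    norm_log: pd.DataFrame,
    design: ExperimentDesign,
    group_a,
    group_b,
    n_permutations: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Per-gene permutation test of |mean(A) - mean(B)| in log space.

    ``group_a``/``group_b`` are design query strings (e.g.
    ``"treatment == 'stable31' and day in (7, 11)"``) or explicit sample-id
    lists; the groups must be disjoint with >=2 samples each. Group labels
    are permuted over the pooled samples; BH q-values are appended.
    """
    ids_a = list(design.subset(group_a).sample_ids) if isinstance(group_a, str) else list(group_a)
    ids_b = list(design.subset(group_b).sample_ids) if isinstance(group_b, str) else list(group_b)
    if set(ids_a) & set(ids_b):
        raise ValidationError("groups must be disjoint")
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError(
            f"each group needs >=2 samples (got {len(ids_a)} and {len(ids_b)})"
        )
    pooled = ids_a + ids_b
    Y = norm_log.loc[:, pooled].to_numpy(dtype=float)
    n_a, n = len(ids_a), len(pooled)

    def stat(idx_a: np.ndarray) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        mask[idx_a] = True
        return np.abs(Y[:, mask].mean(axis=1) - Y[:, ~mask].mean(axis=1))

    obs = stat(np.arange(n_a))
    thresh = obs * (1 - _CMP_SLACK) - _CMP_SLACK
    count = np.zeros(Y.shape[0], dtype=np.int64)
    if exhaustive:
        n_done = 0
        for combo in itertools.combinations(range(n), n_a):
            count += stat(np.asarray(combo)) >= thresh
            n_done += 1
        p = count / n_done
    else:
        if n_permutations < 99:
            raise ValidationError("need >=99 permutations")
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            count += stat(rng.permutation(n)[:n_a]) >= thresh
        n_done = n_permutations
        p = (1 + count) / (n_done + 1)
    out = pd.DataFrame(
        {"stat": obs, "p": p, "q": bh_fdr(p), "n_permutations": n_done},
        index=norm_log.index,
    )
    return out
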