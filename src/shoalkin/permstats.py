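"""Permutation-based one-way and two-way factorial ANOVA.

Classical F statistics are computed from sequential (Type I) sums of squares
on the linear factorial model; p-values come from permutation rather than
the F distribution, so no normality assumption is needed — appropriate for
small, possibly unbalanced behavioral designs (a handful of replicate
shoals per cell).

* One-way models permute the raw response labels; all distinct label
  arrangements are enumerated exhaustively when there are at most 20,000 of
  them (the p-value is then exact), otherwise Monte Carlo with a fixed,
  seeded number of draws.
* Multi-factor terms use the Freedman–Lane scheme: the residuals of the
  reduced model excluding the tested term are permuted, added back to the
  reduced-model fit, and the term's F is recomputed on the reconstructed
  response.

The term order (factor A, factor B, interaction) is fixed; with equal cell
sizes sequential SS coincides with Type III.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorialDataset",
    "TermResult",
    "StatResult",
    "anova_f",
    "permutation_anova",
    "within_speed_sweep",
    "EXHAUSTIVE_LIMIT",
]

EXHAUSTIVE_LIMIT = 20_000


@dataclass
class FactorialDataset:
    """Response values with one or two categorical factors."""

    y: np.ndarray
    a: np.ndarray
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.a = np.asarray(self.a)
        if self.b is not None:
            self.b = np.asarray(self.b)
            if self.b.shape != self.y.shape:
                raise ValueError("b must match y in length")
        if self.a.shape != self.y.shape:
            raise ValueError("a must match y in length")
        if np.unique(self.a).size < 2:
            raise ValueError("factor A needs at least 2 levels")
        if self.y.size < 4:
            raise ValueError("too few observations")


@dataclass(frozen=True)
class TermResult:
    f: float
    df: int
    p: float | None = None


@dataclass
class StatResult:
    """F statistics and permutation p-values per model term."""

    terms: dict[str, TermResult]
    m_permutations: int
    seed: int | None
    method: str
    df_resid: int


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _dummies(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummies (reference level dropped)."""
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, 1:]).astype(float)


def _design_blocks(ds: FactorialDataset, model: str) -> list[tuple[str, np.ndarray]]:
    n = ds.y.size
    blocks = [("intercept", np.ones((n, 1)))]
    da = _dummies(ds.a)
    if model == "one_way":
        blocks.append(("A", da))
        return blocks
    if model != "two_way_interaction":
        raise ValueError(f"unknown model {model!r}")
    if ds.b is None:
        raise ValueError("two-way model requires factor B")
    db = _dummies(ds.b)
    inter = (da[:, :, None] * db[:, None, :]).reshape(n, -1)
    blocks.append(("A", da))
    blocks.append(("B", db))
    blocks.append(("A:B", inter))
    return blocks


def _sequential_qr(blocks: list[tuple[str, np.ndarray]]):
    """Orthonormal bases of the sequential column spans.

    Returns (names, q_blocks, dfs, q_full): ``q_blocks[k]`` spans the part of
    term k orthogonal to all preceding terms, so ``||q_blocks[k].T y||^2`` is
    the sequential SS of that term.  Rank-deficient columns are dropped.
    """
    names, q_blocks, dfs = [], [], []
    q_cols: list[np.ndarray] = []
    tol = 1e-10
    for name, X in blocks:
        added = []
        for j in range(X.shape[1]):
            v = X[:, j].astype(float)
            for q in q_cols:
                v = v - q * np.dot(q, v)
            # second pass for numerical orthogonality
            for q in q_cols:
                v = v - q * np.dot(q, v)
            nv = np.linalg.norm(v)
            if nv > tol * max(1.0, np.linalg.norm(X[:, j])):
                v = v / nv
                q_cols.append(v)
                added.append(v)
        if name != "intercept":
            names.append(name)
            q_blocks.append(np.column_stack(added) if added else np.zeros((X.shape[0], 0)))
            dfs.append(len(added))
    q_full = np.column_stack(q_cols)
    return names, q_blocks, dfs, q_full


def _f_stats(y: np.ndarray, names, q_blocks, dfs, q_full) -> tuple[dict[str, TermResult], int, float]:
    n = y.size
    ss_terms = [float(np.sum((qb.T @ y) ** 2)) if qb.shape[1] else 0.0 for qb in q_blocks]
    rss = float(np.dot(y, y) - np.sum((q_full.T @ y) ** 2))
    df_resid = n - q_full.shape[1]
    if df_resid <= 0:
        raise ValueError("degenerate design: no residual degrees of freedom")
    mse = rss / df_resid
    out = {}
    for name, ss, df in zip(names, ss_terms, dfs):
        if df == 0:
            out[name] = TermResult(np.nan, 0)
        elif mse <= 1e-12 * max(1.0, float(np.dot(y, y)) / n):
            out[name] = TermResult(np.inf, df)
        else:
            out[name] = TermResult((ss / df) / mse, df)
    return out, df_resid, mse


def anova_f(dataset: FactorialDataset, model: str = "one_way") -> dict[str, TermResult]:
    """Sequential-SS F statistic per term ('A', 'B', 'A:B' as applicable)."""
    blocks = _design_blocks(dataset, model)
    names, q_blocks, dfs, q_full = _sequential_qr(blocks)
    out, _, _ = _f_stats(dataset.y, names, q_blocks, dfs, q_full)
    return out


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _n_arrangements(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _distinct_assignments(counts: Sequence[int], pool: tuple[int, ...]) -> Iterator[list[np.ndarray]]:
    """All distinct partitions of ``pool`` indices into groups of given sizes."""
    if len(counts) == 1:
        yield [np.asarray(pool, dtype=int)]
        return
    first, rest = counts[0], counts[1:]
    for chosen in combinations(pool, first):
        remaining = tuple(i for i in pool if i not in chosen)
        for tail in _distinct_assignments(rest, remaining):
            yield [np.asarray(chosen, dtype=int)] + tail


def _one_way_f_from_groups(y: np.ndarray, groups: list[np.ndarray], sst: float, grand: float) -> float:
    n = y.size
    k = len(groups)
    ssb = -grand * grand / n
    for g in groups:
        s = float(y[g].sum())
        ssb += s * s / g.size
    ssw = sst - ssb
    if ssw <= 1e-12 * max(sst, 1.0):
        return np.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def permutation_anova(
    dataset: FactorialDataset,
    model: str = "one_way",
    m_permutations: int = 4999,
    seed: int = 0,
) -> StatResult:
    """Permutation p-values for every term of the factorial model.

    One-way: raw-label permutation, exhaustive when the number of distinct
    arrangements is at most 20,000 (exact p = proportion of arrangements
    with F at least the observed, the identity included), Monte Carlo
    otherwise with ``p = (exceedances + 1) / (m + 1)``.  Two-way: each term
    by Freedman–Lane residual permutation against its reduced model.
    Deterministic given (dataset, model, m_permutations, seed).
    """
    if m_permutations < 99:
        raise ValueError("m_permutations must be at least 99")
    blocks = _design_blocks(dataset, model)
    names, q_blocks, dfs, q_full = _sequential_qr(blocks)
    y = dataset.y
    observed, df_resid, _ = _f_stats(y, names, q_blocks, dfs, q_full)
    rng = np.random.default_rng(seed)
    rel_eps = 1e-9

    if model == "one_way":
        f_obs = observed["A"].f
        levels = np.unique(dataset.a)
        masks = [np.nonzero(dataset.a == lv)[0] for lv in levels]
        counts = [g.size for g in masks]
        grand = float(y.sum())
        sst = float(np.dot(y, y)) - grand * grand / y.size
        n_arr = _n_arrangements(dataset.a)
        thresh = f_obs * (1.0 - rel_eps) if np.isfinite(f_obs) else np.inf
        if n_arr <= EXHAUSTIVE_LIMIT:
            count = 0
            for groups in _distinct_assignments(counts, tuple(range(y.size))):
                f = _one_way_f_from_groups(y, groups, sst, grand)
                if f >= thresh or (np.isinf(f) and np.isinf(f_obs)):
                    count += 1
            p = count / n_arr
            method, m_eff = "exhaustive", n_arr
        else:
            count = 0
            for _ in range(m_permutations):
                perm = rng.permutation(y.size)
                groups = []
                start = 0
                for c in counts:
                    groups.append(perm[start : start + c])
                    start += c
                f = _one_way_f_from_groups(y, groups, sst, grand)
                if f >= thresh or (np.isinf(f) and np.isinf(f_obs)):
                    count += 1
            p = (count + 1) / (m_permutations + 1)
            method, m_eff = "monte_carlo", m_permutations
        terms = {"A": TermResult(f_obs, observed["A"].df, p)}
        return StatResult(terms, m_eff, seed, method, df_resid)

    # two-way: Freedman–Lane per term
    block_map = dict(blocks)
    reduced_spec = {
        "A": ["intercept", "B"],
        "B": ["intercept", "A"],
        "A:B": ["intercept", "A", "B"],
    }
    n = y.size
    terms: dict[str, TermResult] = {}
    for ti, name in enumerate(names):
        f_obs = observed[name].f
        df_t = observed[name].df
        if df_t == 0:
            terms[name] = TermResult(np.nan, 0, np.nan)
            continue
        xr = np.column_stack([block_map[b] for b in reduced_spec[name]])
        qr, _ = np.linalg.qr(xr)
        fitted = qr @ (qr.T @ y)
        resid = y - fitted
        perms = np.stack([rng.permutation(n) for _ in range(m_permutations)])
        ystar = fitted[None, :] + resid[perms]  # (m, n)
        qt = q_blocks[ti]
        ss_t = np.sum((ystar @ qt) ** 2, axis=1)
        rss = np.sum(ystar * ystar, axis=1) - np.sum((ystar @ q_full) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fstar = (ss_t / df_t) / (rss / df_resid)
        fstar = np.where(rss <= 1e-12, np.inf, fstar)
        if np.isinf(f_obs):
            count = int(np.sum(np.isinf(fstar)))
        else:
            count = int(np.sum(fstar >= f_obs * (1.0 - rel_eps)))
        p = (count + 1) / (m_permutations + 1)
        terms[name] = TermResult(f_obs, df_t, p)
    return StatResult(terms, m_permutations, seed, "freedman_lane", df_resid)


# ---------------------------------------------------------------------------
# study-level sweep
# ---------------------------------------------------------------------------

def within_speed_sweep(
    table: pd.DataFrame,
    variables: Sequence[str],
    model: str = "two_way_interaction",
    speed_col: str = "speed_bl_s",
    a_col: str = "stage",
    b_col: str = "treatment_temp_c",
    m_permutations: int = 4999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation ANOVA of each variable within each flow speed.

    Speeds are tested separately because shoals are re-measured across
    speeds (not independent) and not all speeds are shared by all stages.
    Speeds where only one level of the tested factor is present are skipped
    with a logged reason.  No multiple-testing correction is applied to the
    significance flags; a Benjamini–Hochberg column is emitted alongside
    for transparency.
    """
    import logging

    log = logging.getLogger(__name__)
    rows = []
    counter = 0
    for var in variables:
        for speed in sorted(table[speed_col].unique()):
            sub = table[(table[speed_col] == speed) & table[var].notna()]
            if sub[a_col].nunique() < 2:
                log.warning(
                    "skipping %s at %s BL/s: single %s level", var, speed, a_col
                )
                continue
            use_model = model
            if model == "two_way_interaction" and sub[b_col].nunique() < 2:
                use_model = "one_way"
            ds = FactorialDataset(
                y=sub[var].to_numpy(),
                a=sub[a_col].to_numpy(),
                b=sub[b_col].to_numpy() if use_model != "one_way" else None,
            )
            counter += 1
            res = permutation_anova(
                ds, use_model, m_permutations, seed=int((seed + 7919 * counter) % (2**31 - 1))
            )
            for term, tr in res.terms.items():
                rows.append(
                    {
                        "variable": var,
                        "speed_bl_s": speed,
                        "term": term,
                        "F": tr.f,
                        "df": tr.df,
                        "p_perm": tr.p,
                        "m": res.m_permutations,
                        "seed": res.seed,
                        "n_obs": len(sub),
                        "significant": bool(tr.p is not None and tr.p <= alpha),
                    }
                )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = _benjamini_hochberg(out["p_perm"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values; NaN entries (untestable terms) stay NaN."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.size, np.nan)
    ok = np.nonzero(~np.isnan(p))[0]
    n = ok.size
    if n == 0:
        return out
    order = ok[np.argsort(p[ok])]
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out[order] = np.minimum(adj, 1.0)
    return out
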