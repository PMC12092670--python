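"""Resampling statistics: permutation tests, Bonferroni, bootstrap, letters.

The two-sample permutation test uses the difference of group means as its
statistic and two-sided p-values. When the number of distinct label
assignments C(n_a + n_b, n_a) is small enough, the test enumerates all of
them exactly; otherwise it Monte-Carlo samples permutations and applies
the add-one rule p = (1 + #{|T*| >= |T_obs|}) / (n_perm + 1), which keeps
p >= 1/(n_perm + 1) and never returns zero.

Multi-group comparisons are summarized with a compact letter display built
by the insert-and-absorb algorithm: groups share at least one letter
exactly when their pairwise difference is not significant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError

#: comparisons with at most this many distinct assignments run exhaustively
EXHAUSTIVE_LIMIT = 100_000

#: relative tolerance when comparing |T*| against |T_obs| (float-tie guard)
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_two_sided: float
    n_permutations: int
    mode: str  # "exhaustive" | "monte-carlo"
    seed: int | None


def _group_statistic(values: np.ndarray, n_a: int, statistic: str) -> float:
    if statistic == "mean":
        return float(values[:n_a].mean() - values[n_a:].mean())
    if statistic == "median":
        return float(np.median(values[:n_a]) - np.median(values[n_a:]))
    raise ConfigError(f"unknown permutation statistic {statistic!r}")


def permutation_test_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 100_000,
    seed: int | None = None,
    statistic: str = "mean",
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> PermutationResult:
    """Two-sample, two-sided permutation test on the mean difference.

    Exhaustive when C(|a|+|b|, |a|) <= ``exhaustive_limit``; Monte-Carlo
    with the add-one rule otherwise (``seed`` required in that mode for
    reproducibility; None falls back to seed 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    n_a = a.size
    t_obs = _group_statistic(pooled, n_a, statistic)
    threshold = abs(t_obs) * (1.0 - _TIE_EPS) - _TIE_EPS

    n_total = math.comb(pooled.size, n_a)
    if n_total <= exhaustive_limit:
        count = 0
        idx_all = np.arange(pooled.size)
        for combo in itertools.combinations(idx_all, n_a):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(combo)] = True
            t = _group_statistic(np.concatenate([pooled[mask], pooled[~mask]]), n_a, statistic)
            if abs(t) >= threshold:
                count += 1
        return PermutationResult(
            statistic=t_obs,
            p_two_sided=count / n_total,
            n_permutations=n_total,
            mode="exhaustive",
            seed=None,
        )

    rng = np.random.Generator(np.random.PCG64(0 if seed is None else seed))
    count = 0
    # chunked vectorized permutations to bound memory at large n_perm
    chunk = max(1, min(n_perm, 20_000_000 // max(pooled.size, 1)))
    done = 0
    if statistic == "mean":
        total = pooled.sum()
        n_b = pooled.size - n_a
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perm = rng.permuted(np.broadcast_to(pooled, (m, pooled.size)), axis=1)
            sum_a = perm[:, :n_a].sum(axis=1)
            t = sum_a / n_a - (total - sum_a) / n_b
            count += int((np.abs(t) >= threshold).sum())
            done += m
    else:
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(_group_statistic(perm, n_a, statistic)) >= threshold:
                count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(
        statistic=t_obs,
        p_two_sided=p,
        n_permutations=n_perm,
        mode="monte-carlo",
        seed=0 if seed is None else seed,
    )


def bonferroni_adjust(pvals: Sequence[float]) -> list[float]:
    """Bonferroni correction: p_i -> min(1, p_i * m), order preserved."""
    pvals = list(pvals)
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    m = len(pvals)
    return [min(1.0, p * m) for p in pvals]


_STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda x: float(np.mean(x)),
    "median": lambda x: float(np.median(x)),
    "cv": lambda x: float(np.std(x, ddof=1) / np.mean(x)),
}


@dataclass(frozen=True)
class BootstrapResult:
    statistic: str
    values: np.ndarray
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def bootstrap_statistic(
    sample: Sequence[float],
    statistic: str = "mean",
    n_boot: int = 10_000,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> BootstrapResult:
    """Nonparametric bootstrap distribution with a percentile CI.

    Resamples with replacement at the original sample size; supported
    statistics: mean, median, cv (sample SD over mean).
    """
    if statistic not in _STATISTICS:
        raise ConfigError(
            f"unknown statistic {statistic!r}; expected one of {sorted(_STATISTICS)}"
        )
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("bootstrap requires a sample of size >= 2")
    rng = np.random.Generator(np.random.PCG64(seed))
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    draws = x[idx]
    if statistic == "mean":
        values = draws.mean(axis=1)
    elif statistic == "median":
        values = np.median(draws, axis=1)
    else:
        values = draws.std(axis=1, ddof=1) / draws.mean(axis=1)
    lo, hi = np.percentile(values, ci)
    return BootstrapResult(
        statistic=statistic,
        values=values,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
    )


def bootstrap_pairs(
    c1: np.ndarray,
    c2: np.ndarray,
    func: Callable[[np.ndarray, np.ndarray], tuple[float, float]],
    n_boot: int = 1000,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> dict[str, tuple[float, float]]:
    """Percentile CIs for the paired-cell noise statistics (eta2_ext,
    eta2_int); resamples cells (pairs) with replacement."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    rng = np.random.Generator(np.random.PCG64(seed))
    n = c1.size
    ext = np.empty(n_boot)
    intr = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ext[k], intr[k] = func(c1[idx], c2[idx])
    return {
        "eta2_ext": tuple(float(v) for v in np.percentile(ext, ci)),
        "eta2_int": tuple(float(v) for v in np.percentile(intr, ci)),
    }


def compact_letter_display(
    groups: Sequence[str], significant: np.ndarray | Sequence[Sequence[bool]]
) -> dict[str, str]:
    """Compact letter display via insert-and-absorb.

    Parameters
    ----------
    groups : sequence of group names (defines letter assignment order).
    significant : square symmetric boolean matrix, True where the pair
        differs significantly; diagonal must be False.

    Two groups share at least one letter iff their pair is not
    significant. Deterministic given group order.
    """
    sig = np.asarray(significant, dtype=bool)
    k = len(groups)
    if sig.shape != (k, k):
        raise ValueError(f"significance matrix must be {k}x{k}, got {sig.shape}")
    if not np.array_equal(sig, sig.T):
        raise ValueError("significance matrix must be symmetric")
    if sig.diagonal().any():
        raise ValueError("significance matrix diagonal must be False")

    # columns are member sets; start with one column holding every group
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_columns: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    a = col - {j}
                    b = col - {i}
                    new_columns.extend([a, b])
                else:
                    new_columns.append(col)
            # absorb: drop columns contained in another column
            columns = []
            for col in new_columns:
                if any(col < other for other in new_columns):
                    continue
                if col not in columns:
                    columns.append(col)

    letters = "abcdefghijklmnopqrstuvwxyz"
    if len(columns) > len(letters):
        raise ValueError("more letter columns than available letters")
    # order columns by their smallest member for a stable letter assignment
    columns.sort(key=lambda col: sorted(col))
    out = {}
    for gi, name in enumerate(groups):
        out[str(name)] = "".join(
            letters[ci] for ci, col in enumerate(columns) if gi in col
        )
    return out


def pairwise_group_comparison(
    table: pd.DataFrame,
    group_col: str,
    value_col: str,
    n_perm: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "mean",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """All pairwise permutation tests with Bonferroni adjustment + letters.

    Returns the pairwise table (group_a, group_b, statistic, p_raw, p_adj,
    significant) and the compact letter display over the adjusted p-values.
    """
    groups = list(dict.fromkeys(table[group_col].astype(str)))
    samples = {
        g: table.loc[table[group_col].astype(str) == g, value_col].to_numpy(dtype=float)
        for g in groups
    }
    pairs = list(itertools.combinations(range(len(groups)), 2))
    rows = []
    for idx, (gi, gj) in enumerate(pairs):
        res = permutation_test_two_sample(
            samples[groups[gi]], samples[groups[gj]],
            n_perm=n_perm, seed=seed + idx, statistic=statistic,
        )
        rows.append((groups[gi], groups[gj], res.statistic, res.p_two_sided, res.mode))
    p_adj = bonferroni_adjust([r[3] for r in rows])
    sig = np.zeros((len(groups), len(groups)), dtype=bool)
    for (gi, gj), adj in zip(pairs, p_adj):
        sig[gi, gj] = sig[gj, gi] = adj < alpha
    letters = compact_letter_display(groups, sig)
    out = pd.DataFrame(
        rows, columns=["group_a", "group_b", "statistic", "p_raw", "mode"]
    )
    out["p_adj"] = p_adj
    out["significant"] = [p < alpha for p in p_adj]
    return out, letters
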