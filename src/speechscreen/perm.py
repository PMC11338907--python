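"""Permutation tests of per-feature group mean differences.

For each feature the observed statistic is the absolute difference of the
two group means (two-sided default).  Group labels are shuffled preserving
group sizes; when the total number of distinct label arrangements is at most
``EXHAUSTIVE_LIMIT`` the null distribution is enumerated exactly, otherwise
``n_perm`` random permutations are drawn and the empirical p-value uses the
add-one correction (1 + #{permuted >= observed}) / (n_perm + 1), so a
sampled p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import ALL_FEATURE_COLUMNS, TASKS

EXHAUSTIVE_LIMIT = 20_000

#: Relative tolerance when comparing permuted statistics to the observed one,
#: so exact ties under floating-point arithmetic count as "at least as extreme".
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class PermutationResult:
    feature: str
    mean_group_a: float
    mean_group_b: float
    observed_stat: float
    p_empirical: float
    n_permutations: int
    exhaustive: bool
    seed: int | None


def _stat(mean_a: float, mean_b: float, alternative: str) -> float:
    d = mean_a - mean_b
    return abs(d) if alternative == "two-sided" else d


def perm_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    feature: str = "",
    force_sampled: bool = False,
) -> PermutationResult:
    """Permutation test of the difference in group means.

    Exhaustive enumeration replaces sampling when the number of label
    arrangements C(n_a + n_b, n_a) is at most ``EXHAUSTIVE_LIMIT``;
    ``force_sampled`` disables the exhaustive path (used to validate that
    the sampled estimator converges to the exact p-value).
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    observed = _stat(a.mean(), b.mean(), alternative)
    tol = _TIE_RTOL * max(abs(observed), np.abs(pooled).max(), 1.0)

    total = comb(n, na)
    if total <= EXHAUSTIVE_LIMIT and not force_sampled:
        csum = pooled.sum()
        hits = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            stat = _stat(sa / na, (csum - sa) / (n - na), alternative)
            if stat >= observed - tol:
                hits += 1
        return PermutationResult(
            feature, float(a.mean()), float(b.mean()), float(observed),
            hits / total, total, True, seed,
        )

    rng = np.random.default_rng(seed)
    # vectorized label shuffles: each row of `order` is one permutation
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_a = pooled[order[:, :na]].mean(axis=1)
    perm_b = pooled[order[:, na:]].mean(axis=1)
    if alternative == "two-sided":
        stats = np.abs(perm_a - perm_b)
    else:
        stats = perm_a - perm_b
    hits = int(np.sum(stats >= observed - tol))
    p = (1 + hits) / (n_perm + 1)
    return PermutationResult(
        feature, float(a.mean()), float(b.mean()), float(observed),
        p, n_perm, False, seed,
    )


def perm_test_table(
    table: pd.DataFrame,
    task: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    features: Sequence[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One permutation test per feature for a screening task.

    ``task`` is ``"HC_vs_AD"`` or ``"HC_vs_CI"`` (CI pools AD and MCI).
    Group means are reported on the natural, un-normalized scale.  With
    ``bh_correct`` a Benjamini-Hochberg adjusted column is appended (off by
    default: per-feature reporting).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    impaired = TASKS[task]
    feats = list(features) if features is not None else [
        c for c in ALL_FEATURE_COLUMNS if c in table.columns
    ]
    groups = set(table["group"])
    if "HC" not in groups or not groups.intersection(impaired):
        raise ValueError(f"table lacks the groups required by {task}")
    mask_a = table["group"] == "HC"
    mask_b = table["group"].isin(impaired)

    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(feats))]

    rows = []
    for feat, child in zip(feats, child_seeds):
        res = perm_test(
            table.loc[mask_a, feat].to_numpy(),
            table.loc[mask_b, feat].to_numpy(),
            n_perm=n_perm,
            seed=child,
            alternative=alternative,
            feature=feat,
        )
        rows.append(
            {
                "feature": feat,
                "mean_HC": res.mean_group_a,
                f"mean_{'AD' if task == 'HC_vs_AD' else 'CI'}": res.mean_group_b,
                "observed_stat": res.observed_stat,
                "p_empirical": res.p_empirical,
                "n_permutations": res.n_permutations,
                "exhaustive": res.exhaustive,
            }
        )
    out = pd.DataFrame(rows)
    if bh_correct:
        out["p_bh"] = benjamini_hochberg(out["p_empirical"].to_numpy())
    return out


def difference_table(
    table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Combined report: per-group means plus both tasks' empirical p-values."""
    res_ad = perm_test_table(table, "HC_vs_AD", n_perm, seed, alternative, features)
    res_ci = perm_test_table(table, "HC_vs_CI", n_perm, None if seed is None else seed + 1,
                             alternative, features)
    out = res_ad[["feature", "mean_HC", "mean_AD"]].copy()
    out["mean_CI"] = res_ci["mean_CI"]
    out["p_HC_vs_AD"] = res_ad["p_empirical"]
    out["p_HC_vs_CI"] = res_ci["p_empirical"]
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
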