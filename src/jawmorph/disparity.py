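"""Morphofunctional disparity: sum of variances with resampling tests.

Disparity of a group is the sum over ordination axes of the sample (ddof=1)
variance of its members' scores — the trace of the members' covariance
matrix. Computed over ALL retained PCo axes it equals total variance and is
invariant to the orthogonal basis, so it matches the same sum taken on the
z-corrected characters directly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .biomech import StandardizedMatrix
from .ordination import OrdinationResult


class DisparityError(ValueError):
    pass


def _coords_frame(coords) -> pd.DataFrame:
    if isinstance(coords, OrdinationResult):
        return coords.coordinates
    if isinstance(coords, StandardizedMatrix):
        return coords.values
    return pd.DataFrame(coords)


def sum_of_variances(coords, member_ids=None) -> float:
    """Sum over axes of the sample variance of the members' scores."""
    frame = _coords_frame(coords)
    if member_ids is not None:
        frame = frame.loc[list(member_ids)]
    if len(frame) < 2:
        raise DisparityError(
            f"disparity undefined for a group of {len(frame)} member(s)")
    return float(frame.to_numpy(dtype=float).var(axis=0, ddof=1).sum())


def bootstrap_disparity(coords, member_ids=None, n_bootstrap: int = 1000,
                        seed: int | None = None) -> dict:
    """Bootstrap the sum of variances; 2.5/97.5-percentile CI."""
    frame = _coords_frame(coords)
    if member_ids is not None:
        frame = frame.loc[list(member_ids)]
    n = len(frame)
    if n < 3:
        raise DisparityError("bootstrap needs >= 3 members")
    X = frame.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    boot = X[idx].var(axis=1, ddof=1).sum(axis=-1)
    return {
        "observed": float(X.var(axis=0, ddof=1).sum()),
        "distribution": boot,
        "ci_low": float(np.percentile(boot, 2.5)),
        "ci_high": float(np.percentile(boot, 97.5)),
        "n": n,
        "n_bootstrap": n_bootstrap,
        "seed": seed,
    }


def disparity_permutation_test(coords, ids_A, ids_B, n_permutations: int = 9999,
                               seed: int | None = None, *,
                               exhaustive_limit: int = 100_000) -> dict:
    """Two-tailed permutation test of a difference in sum of variances.

    Pools both groups, re-splits at the original sizes, and compares
    |SoV(A*) - SoV(B*)| with the observed |difference|. Exhaustive over all
    splits when their number is small, Monte Carlo with the
    (count + 1)/(n + 1) rule otherwise.
    """
    ids_A, ids_B = list(ids_A), list(ids_B)
    if set(ids_A) & set(ids_B):
        raise ValueError(f"overlapping groups: {sorted(set(ids_A) & set(ids_B))}")
    frame = _coords_frame(coords)
    A = frame.loc[ids_A].to_numpy(dtype=float)
    B = frame.loc[ids_B].to_numpy(dtype=float)
    nA, nB = len(A), len(B)
    if min(nA, nB) < 2:
        raise DisparityError("both groups need >= 2 members")
    # canonical pooled order (sorted ids): permuted splits are invariant to
    # swapping A and B and to the callers' id ordering
    pooled = frame.loc[sorted(ids_A) + sorted(ids_B)].sort_index().to_numpy(dtype=float)
    n = nA + nB

    def delta(idx_a_mask: np.ndarray) -> float:
        a = pooled[idx_a_mask]
        b = pooled[~idx_a_mask]
        return float(a.var(axis=0, ddof=1).sum() - b.var(axis=0, ddof=1).sum())

    d_obs = float(A.var(axis=0, ddof=1).sum() - B.var(axis=0, ddof=1).sum())
    tol = 1e-12 * max(1.0, abs(d_obs))

    # |delta| over a split does not depend on which side is called A, so
    # permuted splits always draw the smaller size: swap-invariant p
    k = min(nA, nB)
    total = math.comb(n, k)
    if total <= min(exhaustive_limit, n_permutations + 1):
        count = 0
        for combo in itertools.combinations(range(n), k):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            if abs(delta(mask)) >= abs(d_obs) - tol:
                count += 1
        p = count / total
        n_done, exhaustive = total, True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            mask = np.zeros(n, dtype=bool)
            mask[perm[:k]] = True
            if abs(delta(mask)) >= abs(d_obs) - tol:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        n_done, exhaustive = n_permutations, False

    return {"observed_difference": d_obs, "p": p, "n_A": nA, "n_B": nB,
            "n_permutations": n_done, "exhaustive": exhaustive, "seed": seed}


def disparity_wilcoxon_matrix(bootstrap_distributions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise rank-sum tests between per-group bootstrap SoV distributions.

    Bonferroni-corrected over the number of pairs. Caution: bootstrap
    replicates are pseudo-replicates, which makes these p-values
    anti-conservative; prefer :func:`disparity_permutation_test` for
    inference.
    """
    groups = sorted(bootstrap_distributions)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    lengths = {len(np.asarray(v)) for v in bootstrap_distributions.values()}
    if len(lengths) != 1:
        raise ValueError("bootstrap distributions must have equal length")
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        da = np.asarray(bootstrap_distributions[a], dtype=float)
        db = np.asarray(bootstrap_distributions[b], dtype=float)
        if np.array_equal(np.sort(da), np.sort(db)):
            stat, p = float(len(da) * len(db) / 2), 1.0
        else:
            stat, p = mannwhitneyu(da, db, alternative="two-sided",
                                   method="asymptotic")
            stat, p = float(stat), float(p)
        rows.append({"group_A": a, "group_B": b, "statistic": stat,
                     "p_raw": p, "p_bonferroni": min(1.0, p * m)})
    return pd.DataFrame(rows)


def group_disparity_table(coords, labels, n_bootstrap: int = 1000,
                          seed: int | None = None, *,
                          min_group_size: int = 3) -> tuple[pd.DataFrame, dict]:
    """Per-group SoV with bootstrap CIs; under-sized groups are flagged."""
    frame = _coords_frame(coords)
    labels = np.asarray(list(labels))
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rows, dists = [], {}
    for g, child in zip(sorted(set(labels)),
                        ss.spawn(len(set(labels)))):
        ids = list(frame.index[labels == g])
        if len(ids) < min_group_size:
            rows.append({"group": g, "n": len(ids), "sum_of_variances": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "skipped": True})
            continue
        if len(ids) < 3:  # SoV defined, bootstrap is not
            rows.append({"group": g, "n": len(ids),
                         "sum_of_variances": sum_of_variances(frame, ids),
                         "ci_low": np.nan, "ci_high": np.nan, "skipped": False})
            continue
        boot = bootstrap_disparity(frame, ids, n_bootstrap,
                                   seed=int(child.generate_state(1)[0] % 2**31))
        dists[g] = boot["distribution"]
        rows.append({"group": g, "n": len(ids),
                     "sum_of_variances": boot["observed"],
                     "ci_low": boot["ci_low"], "ci_high": boot["ci_high"],
                     "skipped": False})
    return pd.DataFrame(rows), dists
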