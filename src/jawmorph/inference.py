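"""Group-separation inference: PERMANOVA and jackknifed LDA.

PERMANOVA follows the standard distance-based pseudo-F construction: with
squared inter-point distances, SS_total = sum_{i<j} d_ij^2 / n, SS_within is
the analogous sum restricted to same-group pairs divided by group size, and

    F = (SS_between / (g - 1)) / (SS_within / (n - g)).

The null distribution comes from permuting the group labels. When the number
of distinct label arrangements is small the test enumerates all of them and
reports the exact p; otherwise it Monte-Carlo samples permutations and uses
the (count + 1) / (n_permutations + 1) rule so p is never zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .biomech import StandardizedMatrix
from .ordination import OrdinationResult, euclidean_distances

logger = logging.getLogger("jawmorph")

#: Groups below this size are excluded from inferential tests by default.
DEFAULT_MIN_GROUP_SIZE = 3

EXHAUSTIVE_LIMIT = 100_000


class GroupSizeError(ValueError):
    pass


def _squared_distance_matrix(data, ids=None) -> tuple[np.ndarray, list[str]]:
    """Coerce coordinates / standardized matrix / DistanceMatrix to D^2."""
    if isinstance(data, DistanceMatrix):
        return np.asarray(data.data, dtype=float) ** 2, list(data.ids)
    if isinstance(data, OrdinationResult):
        data = data.coordinates
    if isinstance(data, StandardizedMatrix):
        data = data.values
    if isinstance(data, pd.DataFrame):
        dm = euclidean_distances(data)
        return np.asarray(dm.data) ** 2, list(dm.ids)
    X = np.asarray(data, dtype=float)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    return sq, [str(i) for i in (ids if ids is not None else range(len(X)))]


def _ss_within(D2: np.ndarray, label_codes: np.ndarray, group_sizes: np.ndarray) -> float:
    ss = 0.0
    for g, n_g in enumerate(group_sizes):
        idx = np.flatnonzero(label_codes == g)
        ss += D2[np.ix_(idx, idx)].sum() / (2.0 * n_g)
    return ss


def _pseudo_F(D2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    n = len(codes)
    g = len(sizes)
    ss_total = D2.sum() / (2.0 * n)
    ss_within = _ss_within(D2, codes, sizes)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def _n_arrangements(sizes: np.ndarray) -> int:
    n = int(sizes.sum())
    count = math.factorial(n)
    for s in sizes:
        count //= math.factorial(int(s))
    return count


def _iter_arrangements(n: int, sizes: np.ndarray):
    """Yield every distinct assignment of n items into labelled groups."""
    codes = np.empty(n, dtype=int)

    def rec(remaining: tuple[int, ...], group: int):
        if group == len(sizes) - 1:
            codes[list(remaining)] = group
            yield codes
            return
        for chosen in itertools.combinations(remaining, int(sizes[group])):
            codes[list(chosen)] = group
            rest = tuple(i for i in remaining if i not in set(chosen))
            yield from rec(rest, group + 1)

    yield from rec(tuple(range(n)), 0)


def adjust_pvalues(p_raw, method: str) -> np.ndarray:
    """Multiplicity adjustment: ``"bonferroni"`` or ``"bh"`` (step-up FDR)."""
    p = np.asarray(p_raw, dtype=float)
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_raw: float
    n_permutations: int
    seed: int | None
    groups_tested: list[str]
    df_between: int
    df_within: int
    exhaustive: bool = False


def permanova_oneway(data, labels, n_permutations: int | str = 9999,
                     seed: int | None = None, *,
                     min_group_size: int = 2,
                     exhaustive_limit: int = EXHAUSTIVE_LIMIT) -> PermanovaResult:
    """One-way PERMANOVA of group-centroid separation.

    ``data`` may be a coordinate matrix (DataFrame / ndarray / ordination
    result / standardized matrix) or a pre-computed DistanceMatrix.
    ``n_permutations="exhaustive"`` forces full enumeration (error if the
    arrangement count exceeds ``exhaustive_limit``); an integer count
    auto-switches to enumeration when it is cheaper than sampling.
    """
    D2, _ = _squared_distance_matrix(data)
    labels = np.asarray(list(labels))
    if len(labels) != D2.shape[0]:
        raise ValueError("labels length does not match number of specimens")
    group_names, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    if len(group_names) < 2:
        raise GroupSizeError("need >= 2 groups")
    if sizes.min() < min_group_size:
        small = group_names[sizes < min_group_size]
        raise GroupSizeError(
            f"group(s) below minimum size {min_group_size}: {list(small)}")
    n, g = len(codes), len(group_names)
    if D2.sum() <= 0:
        raise ValueError("zero total sum of squares: all specimens identical")

    F_obs = _pseudo_F(D2, codes, sizes)
    total = _n_arrangements(sizes)
    force_exhaustive = n_permutations == "exhaustive"
    if force_exhaustive and total > exhaustive_limit:
        raise ValueError(f"{total} arrangements exceed the exhaustive limit")
    exhaustive = force_exhaustive or total <= min(
        exhaustive_limit, (n_permutations if not force_exhaustive else 0) + 1)

    tol = 1e-12 * max(1.0, abs(F_obs) if math.isfinite(F_obs) else 1.0)
    if exhaustive:
        count = sum(
            _pseudo_F(D2, arrangement, sizes) >= F_obs - tol
            for arrangement in _iter_arrangements(n, sizes))
        p = count / total
        n_perm_done = total
    else:
        rng = np.random.default_rng(seed)
        # canonical scheme: permute the sorted code vector, so the sampled
        # null arrangements do not depend on specimen order or label names
        base = np.sort(codes)
        count = 0
        for _ in range(int(n_permutations)):
            perm = rng.permutation(base)
            if _pseudo_F(D2, perm, sizes) >= F_obs - tol:
                count += 1
        p = (count + 1) / (int(n_permutations) + 1)
        n_perm_done = int(n_permutations)

    return PermanovaResult(
        pseudo_F=F_obs, p_raw=p, n_permutations=n_perm_done, seed=seed,
        groups_tested=[str(gn) for gn in group_names],
        df_between=g - 1, df_within=n - g, exhaustive=exhaustive)


def permanova_pairwise(data, labels, n_permutations: int = 9999,
                       seed: int | None = None, *,
                       min_group_size: int = DEFAULT_MIN_GROUP_SIZE) -> pd.DataFrame:
    """All unordered pairwise PERMANOVAs with Bonferroni and BH columns.

    Pairs with an under-sized member are recorded as skipped (NaN results);
    the correction multiplier counts only the tests actually run.
    """
    D2, ids = _squared_distance_matrix(data)
    labels = np.asarray(list(labels))
    group_names = sorted(set(labels))
    rows = []
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = iter(ss.generate_state(len(group_names) * len(group_names)))
    for a, b in itertools.combinations(group_names, 2):
        mask = (labels == a) | (labels == b)
        sub_seed = int(next(child_seeds) % (2 ** 31))
        na, nb = int((labels == a).sum()), int((labels == b).sum())
        if min(na, nb) < min_group_size:
            logger.warning("pairwise PERMANOVA %s vs %s skipped: group below "
                           "minimum size %d", a, b, min_group_size)
            rows.append({"group_A": a, "group_B": b, "n_A": na, "n_B": nb,
                         "pseudo_F": np.nan, "p_raw": np.nan, "skipped": True})
            continue
        idx = np.flatnonzero(mask)
        res = permanova_oneway(
            DistanceMatrix(np.sqrt(D2[np.ix_(idx, idx)]),
                           ids=[ids[i] for i in idx]),
            labels[mask], n_permutations, seed=sub_seed,
            min_group_size=min(min_group_size, 2))
        rows.append({"group_A": a, "group_B": b, "n_A": na, "n_B": nb,
                     "pseudo_F": res.pseudo_F, "p_raw": res.p_raw,
                     "skipped": False})
    table = pd.DataFrame(rows)
    tested = ~table["skipped"]
    table["p_bonferroni"] = np.nan
    table["p_bh"] = np.nan
    if tested.any():
        p = table.loc[tested, "p_raw"].to_numpy()
        table.loc[tested, "p_bonferroni"] = adjust_pvalues(p, "bonferroni")
        table.loc[tested, "p_bh"] = adjust_pvalues(p, "bh")
    return table


# ---------------------------------------------------------------------------
# Jackknifed (leave-one-out) LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaResult:
    confusion_matrix: pd.DataFrame     # true labels (rows) x predicted (cols)
    overall_jackknife_rate: float
    per_class_rates: pd.Series
    feature_set: str
    excluded_classes: list[str] = field(default_factory=list)


def _fit_lda(X, y, priors):
    try:
        clf = LinearDiscriminantAnalysis(solver="svd", priors=priors)
        clf.fit(X, y)
        return clf
    except np.linalg.LinAlgError:
        # near-singular pooled covariance: ridge-style shrinkage fallback
        logger.warning("LDA svd solver failed; retrying with lsqr + shrinkage")
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto",
                                         priors=priors)
        clf.fit(X, y)
        return clf


def lda_jackknife(X, labels, feature_set: str = "characters", *,
                  min_class_size: int = DEFAULT_MIN_GROUP_SIZE) -> LdaResult:
    """Leave-one-out linear discriminant classification with equal priors.

    ``X``: standardized character matrix or PCo scores (``feature_set`` is a
    recorded tag, not a dispatcher). Classes below ``min_class_size`` are
    excluded with a logged warning.
    """
    if isinstance(X, StandardizedMatrix):
        X = X.values
    if isinstance(X, OrdinationResult):
        X = X.coordinates
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(list(labels))
    classes, counts = np.unique(y, return_counts=True)
    excluded = [str(c) for c, n in zip(classes, counts) if n < min_class_size]
    if excluded:
        logger.warning("LDA excluding under-sized class(es): %s", excluded)
        keep = ~np.isin(y, excluded)
        Xa, y = Xa[keep], y[keep]
        classes = np.unique(y)
    if len(classes) < 2:
        raise GroupSizeError("need >= 2 classes of sufficient size for LDA")
    priors = np.full(len(classes), 1.0 / len(classes))

    preds = np.empty(len(y), dtype=object)
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < len(classes):
            # the held-out point was the last member of its class
            preds[i] = "__unclassifiable__"
            continue
        clf = _fit_lda(Xa[mask], y[mask], priors)
        preds[i] = clf.predict(Xa[i][None, :])[0]

    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, preds):
        if p in cm.columns:
            cm.loc[t, p] += 1
    per_class = pd.Series(np.diag(cm) / np.bincount(
        np.searchsorted(classes, y), minlength=len(classes)), index=classes)
    overall = float(np.trace(cm) / len(y))
    return LdaResult(confusion_matrix=cm, overall_jackknife_rate=overall,
                     per_class_rates=per_class, feature_set=feature_set,
                     excluded_classes=excluded)
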