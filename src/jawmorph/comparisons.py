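"""Univariate trait comparisons across clades and guilds.

Morphological metrics: size (ML, compared on a log10 scale by default),
robustness (MSL/ML, MSD/ML, CPD/ML) and relative largest-tooth size (TI).
Functional metrics: relative adductor insertion length (maL/ML, the input-
force proxy), force transmission at the largest tooth (ltMA) and jaw-opening
speed (oMA). Pairwise Welch t-tests and rank-sum tests are Bonferroni
corrected within each metric's family of pairwise comparisons.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, ttest_ind

from .biomech import character_table, zscore_matrix
from .io import AssemblageTable

logger = logging.getLogger("jawmorph")

MORPHOLOGICAL_METRICS: tuple[str, ...] = ("ML", "MSL/ML", "MSD/ML", "CPD/ML", "TI")
FUNCTIONAL_METRICS: tuple[str, ...] = ("maL/ML", "ltMA", "oMA")
DEFAULT_METRICS: tuple[str, ...] = MORPHOLOGICAL_METRICS + FUNCTIONAL_METRICS


def metric_table(table: AssemblageTable, *, log_size: bool = True) -> pd.DataFrame:
    """Specimens x metrics frame; ML is log10(mm) when ``log_size``."""
    chars = character_table(table)
    out = chars[list(DEFAULT_METRICS)].copy()
    if log_size:
        out["ML"] = np.log10(out["ML"])
    return out


def _ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Rank-sum test: exact for small tie-free samples, else asymptotic."""
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 12 and no_ties) else "asymptotic"
    stat, p = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(stat), float(p)


def pairwise_metric_tests(table: AssemblageTable,
                          metrics=DEFAULT_METRICS,
                          grouping: str = "clade", *,
                          min_group_size: int = 3,
                          log_size: bool = True) -> pd.DataFrame:
    """Welch t and rank-sum for every metric and group pair.

    Bonferroni multiplier = number of pairs actually tested for that metric.
    """
    values = metric_table(table, log_size=log_size)
    labels = np.asarray(table.labels(grouping))
    groups = sorted(set(labels))
    rows = []
    for metric in metrics:
        col = values[metric].to_numpy(dtype=float)
        tested = []
        for a, b in itertools.combinations(groups, 2):
            xa = col[(labels == a) & ~np.isnan(col)]
            xb = col[(labels == b) & ~np.isnan(col)]
            if min(len(xa), len(xb)) < min_group_size:
                logger.warning("%s: %s vs %s skipped (group below %d)",
                               metric, a, b, min_group_size)
                rows.append({"metric": metric, "group_A": a, "group_B": b,
                             "test": "t", "statistic": np.nan, "p_raw": np.nan,
                             "skipped": True})
                rows.append({"metric": metric, "group_A": a, "group_B": b,
                             "test": "wilcoxon", "statistic": np.nan,
                             "p_raw": np.nan, "skipped": True})
                continue
            t_stat, t_p = ttest_ind(xa, xb, equal_var=False)
            w_stat, w_p = _ranksum(xa, xb)
            rows.append({"metric": metric, "group_A": a, "group_B": b,
                         "test": "t", "statistic": float(t_stat),
                         "p_raw": float(t_p), "skipped": False})
            rows.append({"metric": metric, "group_A": a, "group_B": b,
                         "test": "wilcoxon", "statistic": w_stat,
                         "p_raw": w_p, "skipped": False})
            tested.append((a, b))
        m = len(tested)
        for row in rows:
            if row["metric"] == metric and not row["skipped"]:
                row["p_bonferroni"] = min(1.0, row["p_raw"] * m)
    out = pd.DataFrame(rows)
    if "p_bonferroni" not in out.columns:
        out["p_bonferroni"] = np.nan
    out.attrs["grouping_system"] = grouping
    return out


def standardized_metric_matrix(table: AssemblageTable,
                               metrics=DEFAULT_METRICS,
                               row_order=None, *,
                               log_size: bool = True) -> pd.DataFrame:
    """Species x metric matrix, z-standardized by column (heatmap input).

    ``row_order``: explicit specimen-id order (e.g. an informal phylogeny);
    defaults to table order. Values are identical under any row order.
    """
    values = metric_table(table, log_size=log_size)[list(metrics)]
    std = zscore_matrix(values).values
    if row_order is not None:
        missing = [r for r in row_order if r not in std.index]
        if missing:
            raise KeyError(f"row_order names absent from the table: {missing}")
        std = std.loc[list(row_order)]
    return std
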