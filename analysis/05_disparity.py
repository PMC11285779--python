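"""Quantify morphofunctional disparity.

Sum-of-variances disparity per clade and per guild (bootstrap CIs),
Bonferroni-corrected rank-sum comparisons of the bootstrap distributions,
and within-group permutation tests of disparity change between the two
time bins.
"""

from pathlib import Path

import numpy as np

from jawmorph import (disparity_permutation_test, disparity_wilcoxon_matrix,
                      euclidean_distances, group_disparity_table, pcoa,
                      read_specimen_table, standardized_characters)
from jawmorph.io import TIME_BINS

SEED = 20240515
OUT = Path("results")


def main() -> None:
    table = read_specimen_table(OUT / "specimens.csv")
    coords = pcoa(euclidean_distances(standardized_characters(table))).coordinates
    ids = np.asarray(table.ids())
    bins = np.asarray(table.labels("time_bin"))

    for system in ("clade", "guild"):
        labels = table.labels(system)
        disp, dists = group_disparity_table(coords, labels, 1000,
                                            seed=SEED)
        disp.to_csv(OUT / f"disparity_{system}.csv", index=False)
        print(f"[{system}] sum-of-variances disparity:")
        for _, row in disp[~disp["skipped"]].iterrows():
            print(f"  {row['group']:<18} n={row['n']:>2} "
                  f"SoV={row['sum_of_variances']:.2f} "
                  f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]")
        if len(dists) >= 2:
            wil = disparity_wilcoxon_matrix(dists)
            wil.to_csv(OUT / f"disparity_wilcoxon_{system}.csv", index=False)

        glabels = np.asarray(labels)
        for g in sorted(set(glabels)):
            a = list(ids[(glabels == g) & (bins == TIME_BINS[0])])
            b = list(ids[(glabels == g) & (bins == TIME_BINS[1])])
            if min(len(a), len(b)) < 3:
                continue
            res = disparity_permutation_test(coords, a, b, 9999, seed=SEED)
            print(f"  {g} {TIME_BINS[0]} vs {TIME_BINS[1]}: "
                  f"dSoV = {res['observed_difference']:+.2f}, p = {res['p']:.4g}")


if __name__ == "__main__":
    main()
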