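"""Build the PCoA morphospace.

Euclidean distances on the z-corrected characters, classical scaling, and
2-D morphospace scatter plots (PCo1-2, 1-3, 2-3) coloured by clade and by
guild. Prints the variance explained by the leading axes.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from jawmorph import (euclidean_distances, pcoa, read_specimen_table,
                      standardized_characters)

OUT = Path("results")
FIG = OUT / "figures"


def scatter(coords, labels, pair, ax):
    for group in sorted(set(labels)):
        sel = [lab == group for lab in labels]
        ax.scatter(coords.loc[sel, pair[0]], coords.loc[sel, pair[1]],
                   label=group, s=18)
    ax.set_xlabel(pair[0])
    ax.set_ylabel(pair[1])


def main() -> None:
    FIG.mkdir(parents=True, exist_ok=True)
    table = read_specimen_table(OUT / "specimens.csv")
    res = pcoa(euclidean_distances(standardized_characters(table)))
    res.coordinates.to_csv(OUT / "pco_scores.csv", index_label="specimen_id")
    pd.DataFrame({"eigenvalue": res.eigenvalues,
                  "variance_explained": res.variance_explained},
                 index=res.coordinates.columns).to_csv(
        OUT / "pco_eigenvalues.csv", index_label="axis")
    pct = 100 * res.variance_explained
    print("variance explained by PCo1-3: "
          + " / ".join(f"{v:.1f}%" for v in pct[:3])
          + f" (cumulative {pct[:3].sum():.1f}%)")

    for system in ("clade", "guild"):
        labels = table.labels(system)
        fig, axes = plt.subplots(1, 3, figsize=(15, 4.2))
        for ax, pair in zip(axes, (("PCo1", "PCo2"), ("PCo1", "PCo3"),
                                   ("PCo2", "PCo3"))):
            scatter(res.coordinates, labels, pair, ax)
        axes[-1].legend(fontsize=7, loc="best")
        fig.suptitle(f"Morphofunctional morphospace by {system}")
        fig.tight_layout()
        fig.savefig(FIG / f"morphospace_{system}.png", dpi=150)
        plt.close(fig)
    print(f"scatter plots in {FIG}/")


if __name__ == "__main__":
    main()
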