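"""End-to-end pipeline: characters -> ordination -> inference -> disparity
-> trait comparisons, under one seeded config, with a hashed manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomech import character_table, standardized_characters
from .comparisons import pairwise_metric_tests, standardized_metric_matrix
from .disparity import (disparity_permutation_test, group_disparity_table,
                        disparity_wilcoxon_matrix)
from .inference import (GroupSizeError, lda_jackknife, permanova_oneway,
                        permanova_pairwise)
from .io import (AssemblageTable, TIME_BINS, read_specimen_table,
                 write_specimen_table)
from .ordination import euclidean_distances, pcoa
from .simulate import SimulationConfig, simulate_assemblage

logger = logging.getLogger("jawmorph")


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str | Path = "results"
    input_path: str | Path | None = None          # CSV; None -> simulate
    simulation: SimulationConfig | None = None
    groupings: tuple[str, ...] = ("clade", "guild")
    merge_pierce: bool = False
    time_bin_comparisons: bool = True
    n_permutations: int = 9999
    n_bootstrap: int = 1000
    min_group_size: int = 3

    def resolve_groupings(self) -> tuple[str, ...]:
        if self.merge_pierce:
            return tuple("guild_merged" if g == "guild" else g
                         for g in self.groupings)
        return self.groupings


def _load(config: PipelineConfig) -> AssemblageTable:
    if config.input_path is not None:
        return read_specimen_table(config.input_path)
    sim = config.simulation or SimulationConfig(seed=config.seed)
    return simulate_assemblage(sim)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _permanova_json(res) -> dict:
    return {"pseudo_F": res.pseudo_F, "p_raw": res.p_raw,
            "n_permutations": res.n_permutations, "seed": res.seed,
            "groups": res.groups_tested, "df_between": res.df_between,
            "df_within": res.df_within, "exhaustive": res.exhaustive}


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write CSV outputs plus a manifest; return a summary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seedseq = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % 2**31)
                   for name, s in zip(
                       ("permanova", "pairwise", "disparity", "timebins"),
                       seedseq.spawn(4))}

    table = _load(config)
    write_specimen_table(table, outdir / "specimens.csv")

    chars = character_table(table)
    chars.to_csv(outdir / "characters.csv", index_label="specimen_id")
    std = standardized_characters(table)
    std.values.to_csv(outdir / "characters_standardized.csv",
                      index_label="specimen_id")
    (outdir / "standardization.json").write_text(json.dumps({
        "column_means": std.column_means.to_dict(),
        "column_sds": std.column_sds.to_dict()}, indent=2))

    dm = euclidean_distances(std)
    ord_res = pcoa(dm)
    ord_res.coordinates.to_csv(outdir / "pco_scores.csv",
                               index_label="specimen_id")
    pd.DataFrame({"eigenvalue": ord_res.eigenvalues,
                  "variance_explained": ord_res.variance_explained},
                 index=ord_res.coordinates.columns).to_csv(
        outdir / "pco_eigenvalues.csv", index_label="axis")

    summary: dict = {
        "n_specimens": len(table),
        "provenance": table.provenance,
        "variance_explained": ord_res.variance_explained.tolist(),
        "permanova": {}, "pairwise": {}, "disparity": {}, "lda": {},
        "time_bins": {},
    }

    coords = ord_res.coordinates
    for grouping in config.resolve_groupings():
        labels = table.labels(grouping)
        tag = grouping.replace("_", "-")
        try:
            res = permanova_oneway(coords, labels, config.n_permutations,
                                   seed=stage_seeds["permanova"],
                                   min_group_size=config.min_group_size)
            summary["permanova"][grouping] = _permanova_json(res)
        except GroupSizeError as err:
            logger.warning("one-way PERMANOVA (%s) skipped: %s", grouping, err)
            summary["permanova"][grouping] = {"skipped": str(err)}

        pw = permanova_pairwise(coords, labels, config.n_permutations,
                                seed=stage_seeds["pairwise"],
                                min_group_size=config.min_group_size)
        pw.to_csv(outdir / f"permanova_pairwise_{tag}.csv", index=False)
        summary["pairwise"][grouping] = {
            "n_tested": int((~pw["skipped"]).sum()),
            "n_significant_bonferroni": int((pw["p_bonferroni"] < 0.05).sum()),
        }

        disp, dists = group_disparity_table(
            coords, labels, config.n_bootstrap, seed=stage_seeds["disparity"],
            min_group_size=config.min_group_size)
        disp.to_csv(outdir / f"disparity_{tag}.csv", index=False)
        if len(dists) >= 2:
            wil = disparity_wilcoxon_matrix(dists)
            wil.to_csv(outdir / f"disparity_wilcoxon_{tag}.csv", index=False)
        summary["disparity"][grouping] = {
            row["group"]: row["sum_of_variances"]
            for _, row in disp.iterrows() if not row["skipped"]}

        try:
            lda = lda_jackknife(std, labels, feature_set="characters",
                                min_class_size=config.min_group_size)
            lda.confusion_matrix.to_csv(outdir / f"lda_confusion_{tag}.csv")
            summary["lda"][grouping] = {
                "overall_jackknife_rate": lda.overall_jackknife_rate,
                "excluded_classes": lda.excluded_classes}
        except GroupSizeError as err:
            logger.warning("LDA (%s) skipped: %s", grouping, err)
            summary["lda"][grouping] = {"skipped": str(err)}

        cmp_table = pairwise_metric_tests(table, grouping=grouping,
                                          min_group_size=config.min_group_size)
        cmp_table.to_csv(outdir / f"metric_tests_{tag}.csv", index=False)

    heat = standardized_metric_matrix(table)
    heat.to_csv(outdir / "metric_heatmap_matrix.csv",
                index_label="specimen_id")

    if config.time_bin_comparisons:
        bins = set(table.labels("time_bin"))
        if all(b in bins for b in TIME_BINS):
            summary["time_bins"] = _time_bin_comparisons(
                table, coords, config, seed=stage_seeds["timebins"])
        else:
            missing = [b for b in TIME_BINS if b not in bins]
            logger.warning("time-bin comparisons skipped: no %s records",
                           missing)
            summary["time_bins"] = {"skipped": f"missing bins {missing}"}

    files = sorted(p for p in outdir.iterdir() if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "jawmorph_version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "n_permutations": config.n_permutations,
        "n_bootstrap": config.n_bootstrap,
        "groupings": list(config.resolve_groupings()),
        "provenance": table.provenance,
        "files": {p.name: _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    default=float))
    summary["manifest"] = manifest
    return summary


def _time_bin_comparisons(table, coords, config, seed) -> dict:
    """Within-group disparity comparisons across the two time bins."""
    out = {}
    bins = np.asarray(table.labels("time_bin"))
    ids = np.asarray(table.ids())
    for grouping in ("clade", "guild"):
        glabels = np.asarray(table.labels(grouping))
        for g in sorted(set(glabels)):
            ids_a = list(ids[(glabels == g) & (bins == TIME_BINS[0])])
            ids_b = list(ids[(glabels == g) & (bins == TIME_BINS[1])])
            if min(len(ids_a), len(ids_b)) < config.min_group_size:
                continue
            res = disparity_permutation_test(
                coords, ids_a, ids_b, config.n_permutations, seed=seed)
            out[f"{g} {TIME_BINS[0]} vs {TIME_BINS[1]}"] = {
                "observed_difference": res["observed_difference"],
                "p": res["p"], "n_A": res["n_A"], "n_B": res["n_B"]}
    return out
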