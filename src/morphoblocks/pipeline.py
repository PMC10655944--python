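"""End-to-end orchestration of the full morphometric analysis.

One call (or the ``run-all`` CLI subcommand) takes raw landmark files plus a
metadata table — or a synthetic-data recipe — and runs the complete chain:
per-specimen symmetrization of the paired views, generalized Procrustes
superimposition per view, centroid-size ANOVAs, per-view and integrated PCA,
MANOVAs over every grouping (one-way, pairwise with Bonferroni, and the
sex-by-block factorial), cross-validated discriminant analyses, Mahalanobis
distance matrices with permutation significance and neighbor-joining
phenograms, and the Mantel test of morphometric against geographic distances.

All tables land as CSV, trees as Newick, and a machine-readable manifest
records parameters, seeds and output inventory.  Randomness is controlled by
one master seed, split per consumer with ``numpy.random.SeedSequence.spawn``
so every stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discriminant import select_pc_subset
from .distances_trees import (
    geographic_matrix,
    mahalanobis_matrix,
    mantel_test,
    neighbor_joining,
    permutation_significance,
    write_newick,
)
from .io_tps import (
    MorphometricDataset,
    assemble_dataset,
    read_pair_map,
    read_specimen_table,
    read_tps,
    write_specimen_table,
    write_tps,
)
from .procrustes import gpa
from .shape_stats import (
    anova_tukey,
    factorial_manova,
    join_views,
    pairwise_manova,
    shape_pca,
    wilks_manova,
)
from .symmetry import symmetrize_dataset
from .synthetic_data import SimulationParams, simulate_dataset

log = logging.getLogger("morphoblocks")

GROUPINGS = ("sex", "block", "karyotype", "pair1", "pair2", "major_group")


@dataclass
class PipelineConfig:
    """Run configuration; load from YAML with :func:`load_config`."""

    output_dir: str = "morphoblocks_out"
    seed: int = 0
    simulate: dict | None = None          # SimulationParams overrides
    tps_files: dict[str, str] = field(default_factory=dict)
    metadata: str | None = None
    pair_map: str | None = None
    groupings: tuple[str, ...] = GROUPINGS
    pca_variance: float = 0.95
    lda_strategy: str = "forward"
    lda_max_pcs: int = 12
    n_perm: int = 999
    run_mantel: bool = True


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "groupings" in raw:
        raw["groupings"] = tuple(raw["groupings"])
    return PipelineConfig(**raw)


def grouping_labels(dataset: MorphometricDataset, ids, grouping: str):
    """Label vector for a named grouping variable.

    ``major_group`` merges blocks A+B and C+D, the two clusters separated by
    the natural barrier in the middle of the species range.
    """
    recs = [dataset.records[i] for i in ids]
    if grouping == "sex":
        return np.array([r.sex for r in recs])
    if grouping == "block":
        return np.array([r.block for r in recs])
    if grouping == "karyotype":
        return np.array([r.diploid_2n for r in recs])
    if grouping in ("pair1", "pair2"):
        vals = [getattr(r, grouping) for r in recs]
        if any(v is None for v in vals):
            raise ValueError(f"grouping {grouping}: missing states")
        return np.array(vals)
    if grouping == "major_group":
        return np.array(["AB" if r.block in "AB" else "CD" for r in recs])
    raise ValueError(f"unknown grouping {grouping!r}")


def _load_dataset(cfg: PipelineConfig):
    if cfg.simulate is not None:
        overrides = dict(cfg.simulate)
        overrides.setdefault("seed", cfg.seed)
        params = SimulationParams(**overrides)
        dataset, truth = simulate_dataset(params)
        return dataset, truth
    if not cfg.tps_files or cfg.metadata is None:
        raise ValueError("config must give either 'simulate' or "
                         "'tps_files' plus 'metadata'")
    configs = {view: read_tps(path, view)
               for view, path in cfg.tps_files.items()}
    records = read_specimen_table(cfg.metadata)
    pair_maps = read_pair_map(cfg.pair_map) if cfg.pair_map else {}
    return assemble_dataset(configs, records, pair_maps), None


def _usable_groups(labels: np.ndarray, min_n: int = 2):
    vals, counts = np.unique(labels, return_counts=True)
    keep = vals[counts >= min_n]
    return np.isin(labels, keep), len(keep)


def run_full_analysis(config: PipelineConfig | Mapping[str, Any] | str | Path,
                      ) -> dict[str, Any]:
    """Execute the whole pipeline; returns the manifest dictionary.

    Any stage failure aborts with the stage name in the exception message;
    outputs written so far stay on disk next to a ``FAILED`` marker file.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    elif isinstance(config, PipelineConfig):
        cfg = config
    else:
        cfg = PipelineConfig(**dict(config))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(cfg.seed)
    child_seeds = iter(seed_seq.spawn(64))

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "stages": [],
        "outputs": [],
        "counts": {},
    }

    def emit_csv(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        manifest["outputs"].append(name)

    stage = "load"
    try:
        dataset, _truth = _load_dataset(cfg)
        manifest["stages"].append(stage)
        views = list(dataset.views)
        ids = list(dataset.complete_ids)
        manifest["counts"]["n_specimens"] = len(ids)
        if cfg.simulate is not None:
            for view in views:
                write_tps(out / f"landmarks_{view}.tps",
                          [dataset.configurations[(i, view)] for i in ids])
                manifest["outputs"].append(f"landmarks_{view}.tps")
            write_specimen_table(out / "specimens.csv",
                                 [dataset.records[i] for i in ids])
            manifest["outputs"].append("specimens.csv")

        stage = "symmetrize"
        dataset = symmetrize_dataset(dataset)
        manifest["stages"].append(stage)

        stage = "gpa"
        gpa_results = {}
        for view in views:
            res = gpa([dataset.configurations[(i, view)] for i in ids])
            gpa_results[view] = res
            sizes = pd.DataFrame({"specimen_id": res.ids,
                                  "centroid_size": res.centroid_sizes})
            emit_csv(f"centroid_sizes_{view}.csv", sizes)
        manifest["stages"].append(stage)

        stage = "size_anova"
        anova_rows = []
        for view in views:
            res = gpa_results[view]
            for grouping in ("sex", "block", "karyotype", "pair1", "pair2"):
                if grouping not in cfg.groupings:
                    continue
                labels = grouping_labels(dataset, res.ids, grouping)
                mask, n_groups = _usable_groups(labels)
                if n_groups < 2:
                    continue
                F, p, tukey = anova_tukey(res.centroid_sizes[mask],
                                          labels[mask])
                anova_rows.append({"view": view, "grouping": grouping,
                                   "F": F, "p": p})
                emit_csv(f"tukey_{grouping}_{view}.csv", tukey)
        emit_csv("anova_size.csv", pd.DataFrame(anova_rows))
        manifest["stages"].append(stage)

        stage = "pca"
        spaces = {}
        for view in views:
            res = gpa_results[view]
            spaces[view] = shape_pca(res.tangent, source_view=view,
                                     ids=res.ids)
            frame = pd.DataFrame(
                spaces[view].scores,
                columns=[f"PC{i + 1}" for i in range(spaces[view].d)],
            )
            frame.insert(0, "specimen_id", list(res.ids))
            emit_csv(f"pca_scores_{view}.csv", frame)
        integrated = join_views([spaces[v] for v in views])
        frame = pd.DataFrame(
            integrated.scores,
            columns=[f"PC{i + 1}" for i in range(integrated.d)],
        )
        frame.insert(0, "specimen_id", ids)
        emit_csv("pca_scores_integrated.csv", frame)
        spaces["integrated"] = integrated
        manifest["stages"].append(stage)

        stage = "manova"
        manova_rows = []
        for space_name, space in spaces.items():
            d_keep = space.n_components_for(cfg.pca_variance)
            scores = space.scores[:, :d_keep]
            sp_ids = space.ids if space.ids else tuple(ids)
            for grouping in cfg.groupings:
                labels = grouping_labels(dataset, sp_ids, grouping)
                mask, n_groups = _usable_groups(labels)
                if n_groups < 2:
                    continue
                n_eff = int(mask.sum())
                d_use = min(d_keep, max(1, n_eff - n_groups - 1))
                res = wilks_manova(scores[mask][:, :d_use], labels[mask],
                                   term=grouping)
                manova_rows.append({"space": space_name,
                                    "grouping": grouping, "d_used": d_use,
                                    "wilks_lambda": res.wilks_lambda,
                                    "F": res.F, "df1": res.df1,
                                    "df2": res.df2, "p": res.p})
                if n_groups > 2:
                    pw = pairwise_manova(scores[mask][:, :d_use],
                                         labels[mask])
                    emit_csv(f"manova_pairwise_{grouping}_{space_name}.csv",
                             pw)
                    if space_name == "integrated":
                        manifest["counts"][
                            f"n_pairwise_{grouping}"] = len(pw)
        emit_csv("manova_oneway.csv", pd.DataFrame(manova_rows))

        factorial_rows = []
        if {"sex", "block"} <= set(cfg.groupings):
            for space_name, space in spaces.items():
                d_keep = space.n_components_for(cfg.pca_variance)
                sp_ids = space.ids if space.ids else tuple(ids)
                sex = grouping_labels(dataset, sp_ids, "sex")
                block = grouping_labels(dataset, sp_ids, "block")
                n_cells = len(np.unique(sex)) * len(np.unique(block))
                d_use = min(d_keep, max(1, len(sp_ids) - n_cells - 1))
                for res in factorial_manova(space.scores[:, :d_use], sex,
                                            block, names=("sex", "block")):
                    factorial_rows.append({
                        "space": space_name, "term": res.term,
                        "wilks_lambda": res.wilks_lambda, "F": res.F,
                        "df1": res.df1, "df2": res.df2, "p": res.p,
                    })
            emit_csv("manova_factorial_sex_block.csv",
                     pd.DataFrame(factorial_rows))
        manifest["stages"].append(stage)

        stage = "lda"
        lda_rows = []
        for grouping in cfg.groupings:
            space = spaces["integrated"]
            labels = grouping_labels(dataset, ids, grouping)
            mask, n_groups = _usable_groups(labels)
            if n_groups < 2:
                continue
            d_cand = min(cfg.lda_max_pcs, space.d)
            subset, report = select_pc_subset(
                space.scores[mask][:, :d_cand], labels[mask],
                strategy=cfg.lda_strategy,
            )
            emit_csv(f"lda_confusion_{grouping}.csv",
                     report.confusion_frame().reset_index(names="true"))
            emit_csv(f"lda_posteriors_{grouping}.csv", report.posteriors)
            lda_rows.append({
                "grouping": grouping,
                "selected_pcs": " ".join(str(s + 1) for s in subset),
                "overall_pct": report.overall_pct,
                **{f"pct_{g}": p for g, p in
                   zip(report.groups, report.per_group_pct)},
            })
        emit_csv("lda_summary.csv", pd.DataFrame(lda_rows))
        manifest["stages"].append(stage)

        stage = "distances"
        mantel_rows = []
        for space_name in list(views) + ["integrated"]:
            space = spaces[space_name]
            sp_ids = space.ids if space.ids else tuple(ids)
            labels = grouping_labels(dataset, sp_ids, "karyotype")
            mask, n_groups = _usable_groups(labels)
            d_keep = space.n_components_for(cfg.pca_variance)
            n_min = int(np.unique(labels[mask],
                                  return_counts=True)[1].min())
            d_use = min(d_keep, max(1, n_min - 1))
            scores = space.scores[mask][:, :d_use]
            dm = mahalanobis_matrix(scores, labels[mask])
            emit_csv(f"mahalanobis_{space_name}.csv",
                     dm.to_frame().reset_index(names="karyotype"))
            sig = permutation_significance(
                scores, labels[mask], n_perm=cfg.n_perm,
                seed=np.random.default_rng(next(child_seeds)),
            )
            emit_csv(f"mahalanobis_significance_{space_name}.csv", sig)
            if n_groups >= 3:
                tree = neighbor_joining(dm)
                tree_path = out / f"nj_{space_name}.nwk"
                tree_path.write_text(write_newick(tree) + "\n")
                manifest["outputs"].append(tree_path.name)

            if cfg.run_mantel and space_name != "integrated":
                recs = [dataset.records[i]
                        for i, m in zip(sp_ids, mask) if m]
                for level, lab in (("karyotype",
                                    [r.diploid_2n for r in recs]),
                                   ("block", [r.block for r in recs])):
                    if not all(r.has_coordinates for r in recs) \
                            or len(set(lab)) < 4:
                        log.info("Mantel skipped for %s/%s: missing "
                                 "coordinates or too few groups",
                                 space_name, level)
                        continue
                    if level == "karyotype":
                        dm_level = dm
                    else:
                        lab_arr = np.asarray(lab)
                        n_min_b = int(np.unique(lab_arr,
                                      return_counts=True)[1].min())
                        d_b = min(d_keep, max(1, n_min_b - 1))
                        dm_level = mahalanobis_matrix(
                            space.scores[mask][:, :d_b], lab_arr)
                    geo = geographic_matrix(
                        lab, [r.lat for r in recs], [r.lon for r in recs],
                    )
                    r_val, p_val = mantel_test(
                        dm_level, geo, n_perm=cfg.n_perm,
                        seed=np.random.default_rng(next(child_seeds)),
                    )
                    mantel_rows.append({"view": space_name, "level": level,
                                        "r": r_val, "p": p_val,
                                        "n_perm": cfg.n_perm})
        if mantel_rows:
            emit_csv("mantel.csv", pd.DataFrame(mantel_rows))
        manifest["stages"].append(stage)
    except Exception as e:
        (out / "FAILED").write_text(f"stage {stage}: {e}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
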