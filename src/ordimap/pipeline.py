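"""End-to-end pipeline: simulate/ingest → select → correlate → ordinate → maps.

One :class:`RunConfig` drives the whole analysis; every stage writes plain
TSV/JSON outputs to the run directory and the run ends with a manifest
listing each file with a content hash, the parameters, the seed and the
wall-clock time.  Stage parameter defaults are the study's printed values
(FDR 1% at 80% confidence, |FC| > 5, |R| > 0.9 screen, 1.6-SD ellipses,
±0.15 median-shift threshold, 50 regression dimensions, mirSVR ≤ −0.1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariate_diagnostics as cdx
from . import diffexpr, matrix_io, synthetic_data, thematic
from .correlation import distribution_profile, pairwise_matrix
from .matrix_io import MIRNA, MRNA
from .ordination import classical_scaling_svd, kruskal_nmds, sammon_mapping, to_distance

log = logging.getLogger("ordimap")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration for a full run.

    Exactly one of ``simulation`` (a StudyConfig) or ``inputs`` (paths to
    the expression matrices and auxiliary tables) must be provided.
    """

    out_dir: str | Path = "ordimap_run"
    simulation: synthetic_data.StudyConfig | None = None
    inputs: dict[str, str] | None = None
    rng_seed: int = 0

    fdr_target: float = 0.01
    confidence: float = 0.80
    n_permutations: int = 1000
    fc_threshold: float = 5.0
    run_selection: bool = True

    covariate_name: str = "necrosis"
    screen_threshold: float = 0.9

    mds_method: str = "svd"          # svd | sammon | kruskal
    k_map: int = 3
    k_regression: int = 50

    shift_threshold: float = 0.15
    ellipse_scale: float = 1.6
    density_bandwidth: float = 0.1
    density_grid: int = 64
    mirsvr_cutoff: float = -0.1

    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise PipelineError(
                "config: provide exactly one of a simulation block or input paths"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "necrosis_grades" in sim:
                sim["necrosis_grades"] = tuple(sim["necrosis_grades"])
            sim = synthetic_data.StudyConfig(**sim)
        return cls(simulation=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(paths: dict[str, str]):
    ann = matrix_io.GeneAnnotationTable.from_tsv(paths["annotations"])
    species = ann.species_series()
    case = matrix_io.read_expression(paths["case_matrix"], species)
    ctrl = matrix_io.read_expression(paths["control_matrix"], species)
    samples = matrix_io.SampleTable.from_tsv(paths["samples"])
    targets = matrix_io.TargetTable.from_tsv(paths["targets"])
    seeds = matrix_io.SeedTable.from_tsv(paths["seeds"])
    return case, ctrl, samples, ann, targets, seeds


def run_full(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    stage = "setup"
    try:
        # ---------------------------------------------------- simulate/ingest
        stage = "ingest"
        if config.simulation is not None:
            cfg = dataclasses.replace(config.simulation, rng_seed=config.rng_seed)
            log.info("simulating study bundle (seed=%d)", cfg.rng_seed)
            bundle = synthetic_data.generate_study(cfg)
            files.update(synthetic_data.write_bundle(bundle, out / "bundle"))
            case, ctrl = bundle.case_matrix, bundle.control_matrix
            samples, ann = bundle.samples, bundle.annotations
            targets, seeds = bundle.targets, bundle.seeds
        else:
            bundle = None
            case, ctrl, samples, ann, targets, seeds = _load_inputs(config.inputs)

        necrosis = samples.necrosis(case.sample_ids)

        # --------------------------------------------------------- select
        stage = "select"
        if config.run_selection:
            merged_all = pd.concat([case.values, ctrl.values], axis=1)
            labels = ["case"] * case.shape[1] + ["control"] * ctrl.shape[1]
            selected: list[str] = []
            fc_all: dict[str, float] = {}
            for tag in (MIRNA, MRNA):
                ids = [g for g in case.gene_ids if case.species[g] == tag]
                sub = matrix_io.ExpressionMatrix(merged_all.loc[ids], case.species.loc[ids])
                sel = diffexpr.permutation_f_select(
                    sub,
                    labels,
                    fdr_target=config.fdr_target,
                    confidence=config.confidence,
                    n_permutations=config.n_permutations,
                    rng_seed=config.rng_seed,
                )
                fc = {
                    g: diffexpr.signed_fold_change(
                        case.values.loc[g].to_numpy(), ctrl.values.loc[g].to_numpy()
                    )
                    for g in ids
                }
                fc_all.update(fc)
                if tag == MRNA:
                    kept = diffexpr.fold_change_filter(sel, fc, config.fc_threshold)
                else:
                    kept = sel.selected_ids
                log.info("%s: %d/%d selected", tag, len(kept), len(ids))
                selected.extend(kept)
            sel_table = pd.DataFrame(
                {
                    "species": case.species.loc[selected],
                    "fold_change": [fc_all[g] for g in selected],
                },
                index=pd.Index(selected, name="gene_id"),
            )
            files["selection"] = out / "selection.tsv"
            sel_table.to_csv(files["selection"], sep="\t")
            # keep original order (miRNAs first)
            keep = [g for g in case.gene_ids if g in set(selected)]
            if len([g for g in keep if case.species[g] == MIRNA]) < 2 or len(
                [g for g in keep if case.species[g] == MRNA]
            ) < 2:
                raise PipelineError("selection kept too few genes to continue")
            case = matrix_io.filter_rows(case, keep)
            ctrl = matrix_io.filter_rows(ctrl, keep)

        # ------------------------------------------------------ correlate
        stage = "correlate"
        assoc_case = pairwise_matrix(
            case, covariate=necrosis, covariate_name=config.covariate_name
        )
        assoc_ctrl = pairwise_matrix(ctrl)
        files["assoc_case"] = out / "assoc_case.tsv"
        files["assoc_control"] = out / "assoc_control.tsv"
        assoc_case.to_tsv(files["assoc_case"])
        assoc_ctrl.to_tsv(files["assoc_control"])
        # also the raw (unadjusted) case matrix for the Fig-1-style diagnostics
        assoc_case_raw = pairwise_matrix(case)
        profiles = {
            "case_simple": distribution_profile(assoc_case_raw),
            "case_partial": distribution_profile(assoc_case),
            "control_simple": distribution_profile(assoc_ctrl),
        }
        files["tau_profiles"] = out / "tau_profiles.json"
        with open(files["tau_profiles"], "w") as fh:
            json.dump(
                {
                    name: {
                        "bimodality_coefficient": p.bimodality_coefficient,
                        "is_bimodal": bool(p.is_bimodal),
                        "n_values": p.n_values,
                    }
                    for name, p in profiles.items()
                },
                fh,
                indent=2,
            )

        # ------------------------------------------------------ covariate
        stage = "covariate"
        screen = cdx.covariate_screen(case, necrosis, threshold=config.screen_threshold)
        correction = cdx.zero_covariate_expression(case, necrosis)
        agreement_raw = cdx.cross_condition_agreement(
            ctrl.values.mean(axis=1), case.values.mean(axis=1)
        )
        agreement_corr = cdx.cross_condition_agreement(
            ctrl.values.mean(axis=1), correction.intercepts
        )
        diag = correction.table.copy()
        diag["covariate_r"] = screen.r
        diag["flagged"] = diag.index.isin(screen.flagged_ids)
        files["covariate_diagnostics"] = out / "covariate_diagnostics.tsv"
        diag.to_csv(files["covariate_diagnostics"], sep="\t")

        # ------------------------------------------------------- ordinate
        stage = "ordinate"
        k = min(max(config.k_map, config.k_regression), len(case.gene_ids) - 1)
        method = {"svd": classical_scaling_svd, "sammon": sammon_mapping, "kruskal": kruskal_nmds}[
            config.mds_method
        ]
        ord_case = method(to_distance(assoc_case), k)
        ord_ctrl = method(to_distance(assoc_ctrl), k)
        files["coords_case"] = out / "coords_case.tsv"
        files["coords_control"] = out / "coords_control.tsv"
        ord_case.to_tsv(files["coords_case"])
        ord_ctrl.to_tsv(files["coords_control"])

        # ----------------------------------------------------------- maps
        stage = "maps"
        report: dict = {
            "tau_profiles": {
                name: {"bimodality_coefficient": p.bimodality_coefficient, "is_bimodal": bool(p.is_bimodal)}
                for name, p in profiles.items()
            },
            "covariate": {
                "flagged_fraction": screen.flagged_fraction,
                "agreement_raw_vs_control": agreement_raw,
                "agreement_corrected_vs_control": agreement_corr,
            },
        }

        ann_classes = ann.table.loc[case.gene_ids, "functional_class"]
        ellipses = thematic.class_ellipses(
            ord_case, ann_classes, n_dims=min(config.k_map, k), scale=config.ellipse_scale
        )
        report["ellipses"] = {
            label: {"center": e.center.tolist(), "semi_axes": e.semi_axes().tolist()}
            for label, e in ellipses.items()
        }

        coords2 = ord_case.coords_array(2)
        is_mir = (ord_case.species == MIRNA).to_numpy()
        m = 3 * config.density_bandwidth
        extent = (
            coords2[:, 0].min() - m,
            coords2[:, 0].max() + m,
            coords2[:, 1].min() - m,
            coords2[:, 1].max() + m,
        )
        dens_mir = thematic.kernel_density_field(
            coords2[is_mir], config.density_grid, config.density_bandwidth, extent
        )
        dens_mrna = thematic.kernel_density_field(
            coords2[~is_mir], config.density_grid, config.density_bandwidth, extent
        )
        report["density_complementarity"] = thematic.complementarity_score(dens_mir, dens_mrna)

        shift = thematic.median_correlation_shift(
            assoc_case, assoc_ctrl, threshold=config.shift_threshold
        )
        files["median_shift"] = out / "median_shift.tsv"
        shift.table.to_csv(files["median_shift"], sep="\t")
        report["median_shift"] = {
            "decreased": shift.decreased_ids,
            "increased": shift.increased_ids,
        }

        good = targets.good_pairs(config.mirsvr_cutoff)
        present = good.table[
            good.table["mirna_id"].isin(case.gene_ids)
            & good.table["mrna_id"].isin(case.gene_ids)
        ].reset_index(drop=True)
        if len(present):
            good = matrix_io.TargetTable(present)
            tp = thematic.target_pair_analysis(
                ord_case, assoc_case, good, n_dims=min(config.k_map, k)
            )
            report["target_pairs"] = dataclasses.asdict(tp)
            n_dims = min(config.k_regression, k)
            if len(good) <= n_dims + 1:
                n_dims = max(1, len(good) - 2)
                warnings.warn(
                    f"too few target pairs for {config.k_regression} regression "
                    f"dimensions; reduced to {n_dims}",
                    stacklevel=2,
                )
            reg = thematic.mirsvr_distance_regression(ord_case, good, n_dims=n_dims)
            report["mirsvr_regression"] = {
                "r_squared": reg.r_squared,
                "f_pvalue": reg.f_pvalue,
                "n_pairs": reg.n_pairs,
                "n_dims": reg.n_dims,
            }
        else:
            report["target_pairs"] = None
            report["mirsvr_regression"] = None

        sg = thematic.seed_group_partition(seeds)
        report["seed_groups"] = {
            "n_groups": sg.n_groups,
            "n_singletons": sg.n_singletons,
            "groups": sg.groups,
        }

        files["thematic_report"] = out / "thematic_report.json"
        with open(files["thematic_report"], "w") as fh:
            json.dump(report, fh, indent=2, default=float)

        if config.make_plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            ax = thematic.plot_ordination_map(ord_case, ann_classes, config.ellipse_scale)
            files["map_plot"] = out / "map_case.png"
            ax.figure.savefig(files["map_plot"], dpi=150)
            plt.close(ax.figure)
            ax = thematic.plot_density_field(dens_mrna)
            files["density_plot"] = out / "density_mrna_case.png"
            ax.figure.savefig(files["density_plot"], dpi=150)
            plt.close(ax.figure)
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {
        "seed": config.rng_seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("inputs", "out_dir")
        },
        "files": {name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in files.items()},
        "wall_clock_s": round(time.time() - t0, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
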