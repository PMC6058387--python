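"""End-to-end orchestration: simulate -> preprocess -> EWAS x 2 fractions
-> meta-analysis -> deconvolution -> report, plus the sorted-vs-bulk
power comparison.

Everything is deterministic given the config seed; a JSON manifest
recording versions, seed, thresholds and per-stage probe counts is
written next to the result tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconvolution import estimate_proportions, select_reference_markers
from .diffmeth import (
    RegressionSpec,
    call_ct_dmcgs,
    celltype_ttest,
    classify_direction,
    region_distribution,
    run_ewas,
)
from .errors import ConfigError
from .io_formats import (
    write_beta_matrix,
    write_probe_annotation,
    write_results_table,
    write_sample_sheet,
)
from .meta_analysis import combine_cell_types, hierarchical_cluster_check, top_k_overlap
from .preprocess import (
    compute_principal_components,
    correlate_pcs_with_covariates,
    filter_probes_by_detection,
    quantile_normalize,
)
from .synthetic import generate_bulk_cohort, generate_sorted_cohort, make_default_design

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults mirror the standard analysis
    (detection p 0.01, |delta| >= 0.20, Bonferroni alpha 0.05, 600 markers,
    top-1000 / top-200 rankings)."""

    seed: int = 0
    n_probes: int = 5000
    n_per_fraction: int = 40
    n_bulk: int = 40
    detection_threshold: float = 0.01
    delta_min: float = 0.20
    alpha: float = 0.05
    k_markers: int = 600
    top_k: int = 1000
    top_k_meta: int = 200
    normalize: bool = True
    n_components: int = 4
    aging_controls_only: bool = True
    include_pc1: bool = True
    design_params: dict = field(default_factory=dict)
    outdir: str = "ctewas_run"

    def __post_init__(self):
        if not 0 < self.detection_threshold <= 1:
            raise ConfigError("detection_threshold must be in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.delta_min < 0 or self.delta_min > 1:
            raise ConfigError("delta_min must be in [0, 1]")
        if min(self.k_markers, self.top_k, self.top_k_meta) < 1:
            raise ConfigError("k_markers/top_k/top_k_meta must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline into ``config.outdir``; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "ctewas",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "design_params"
        },
        "design_params": config.design_params,
        "stages": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        s = stage("simulate")
        design = make_default_design(config.n_probes, config.seed, **config.design_params)
        beta, sheet, annotation = generate_sorted_cohort(design, config.n_per_fraction)
        bulk, bulk_sheet = generate_bulk_cohort(design, config.n_bulk)
        write_beta_matrix(beta, out / "sorted_beta.tsv")
        write_sample_sheet(sheet, out / "sorted_samples.tsv")
        write_beta_matrix(bulk, out / "bulk_beta.tsv")
        write_sample_sheet(bulk_sheet, out / "bulk_samples.tsv")
        write_probe_annotation(annotation, out / "probe_annotation.tsv")
        design.truth_table().to_csv(out / "ground_truth.tsv", sep="\t")
        s["n_probes"] = int(beta.shape[0])
        s["n_sorted_samples"] = int(beta.shape[1])
        s["n_bulk_samples"] = int(bulk.shape[1])

        s = stage("preprocess")
        filtered = filter_probes_by_detection(beta, None, config.detection_threshold)
        s["probes_in"], s["probes_after_detection"] = int(beta.shape[0]), int(filtered.shape[0])
        work = quantile_normalize(filtered) if config.normalize else filtered
        pcs = compute_principal_components(work, config.n_components)
        pcs.scores.to_csv(out / "pc_scores.tsv", sep="\t")
        correlate_pcs_with_covariates(pcs, sheet).to_csv(
            out / "pc_covariate_associations.tsv", sep="\t", index=False
        )
        s["explained_variance"] = [float(v) for v in pcs.explained_variance]

        s = stage("ct_dmcgs")
        tests = celltype_ttest(work, sheet)
        called = call_ct_dmcgs(tests, annotation, config.delta_min, config.alpha)
        write_results_table(tests, out / "celltype_ttest.tsv", annotation)
        called.to_csv(out / "ct_dmcgs.tsv", sep="\t")
        region_distribution(called.index, annotation, tests.index).to_csv(
            out / "ct_dmcg_regions.tsv", sep="\t"
        )
        s["n_tested"], s["n_called"] = int(len(tests)), int(len(called))

        s = stage("ewas")
        tables = {}
        for fraction in ("neuron", "glia"):
            for mode, spec in (
                ("aging", RegressionSpec.aging(fraction, config.aging_controls_only)),
                ("braak", RegressionSpec.braak(fraction)),
            ):
                if not config.include_pc1:
                    spec = dataclasses.replace(
                        spec, covariates=tuple(c for c in spec.covariates if c != "pc1")
                    )
                tbl = run_ewas(work, sheet, pcs, spec)
                tables[(mode, fraction)] = tbl
                write_results_table(tbl, out / f"ewas_{mode}_{fraction}.tsv", annotation)
        s["n_probes_tested"] = int(len(tables[("aging", "neuron")]))
        k = min(config.top_k, config.n_probes)
        for fraction in ("neuron", "glia"):
            tbl = tables[("aging", fraction)]
            top = tbl.index[tbl["rank"] <= k]
            classify_direction(work, sheet, top, "aging").to_csv(
                out / f"aging_{fraction}_directions.tsv", sep="\t"
            )

        s = stage("meta")
        meta = combine_cell_types(tables[("braak", "neuron")], tables[("braak", "glia")])
        write_results_table(meta, out / "meta_braak.tsv", annotation)
        k = min(config.top_k, config.n_probes)
        overlaps = {
            "aging_neuron_vs_glia": top_k_overlap(
                tables[("aging", "neuron")], tables[("aging", "glia")], k
            ),
            "braak_neuron_vs_glia": top_k_overlap(
                tables[("braak", "neuron")], tables[("braak", "glia")], k
            ),
        }
        pd.DataFrame(
            [(name, *counts) for name, counts in overlaps.items()],
            columns=["comparison", "n_common", "n_only_a", "n_only_b"],
        ).to_csv(out / "topk_overlaps.tsv", sep="\t", index=False)
        s["overlaps"] = {name: list(c) for name, c in overlaps.items()}
        top_meta = meta.index[meta["rank"] <= min(config.top_k_meta, len(meta))]
        check = hierarchical_cluster_check(work.loc[top_meta], sheet)
        check.labels.rename("cluster").to_csv(out / "cluster_labels.tsv", sep="\t")
        s["cluster_perfect_celltype_split"] = check.perfect_split

        s = stage("deconvolve")
        panel = select_reference_markers(work, sheet, k=min(config.k_markers, len(work)))
        panel.reference.to_csv(out / "reference_panel.tsv", sep="\t", index_label="probe_id")
        props = estimate_proportions(bulk, panel)
        props.to_csv(out / "bulk_proportions.tsv", sep="\t")
        s["n_markers"] = int(len(panel.markers))
        if "true_neuron_prop" in bulk_sheet.columns:
            err = props["w_neuron"] - bulk_sheet["true_neuron_prop"]
            s["neuron_prop_rmse"] = float(np.sqrt((err**2).mean()))
    except Exception as exc:  # annotate the failing stage, then re-raise
        done = list(manifest["stages"])
        raise type(exc)(f"pipeline stage {done[-1] if done else '?'!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def power_comparison(
    design=None,
    n_donors: int = 30,
    n_probes: int = 4000,
    seeds=range(10),
    alpha: float = 0.05,
    design_params: dict | None = None,
) -> pd.DataFrame:
    """Detection power for planted Braak effects: sorted versus bulk.

    For each seed a sorted cohort and a bulk cohort with matched donor
    numbers are generated from the same design (``n_donors`` samples per
    sorted fraction and ``n_donors`` bulk samples).  Power is scored per
    planted effect instance -- a (probe, cell fraction) pair with a
    nonzero Braak effect: sorted power is the fraction of instances
    reaching Bonferroni significance at ``alpha`` in the EWAS of the
    fraction carrying the effect; bulk power counts the same instances in
    the bulk Braak regression.  Returns one row per seed with the overall
    powers and the per-effect-class breakdown (effects in neurons / in
    glia).
    """
    rows = []
    for seed in seeds:
        if design is None:
            d = make_default_design(n_probes, int(seed), **(design_params or {}))
        else:
            d = replace(design, seed=int(seed))
        planted_n = d.braak_effect_neuron != 0
        planted_g = d.braak_effect_glia != 0
        if not (planted_n | planted_g).any():
            raise ConfigError("design has no planted Braak effects")
        beta, sheet, _ = generate_sorted_cohort(d, n_donors)
        bulk, bulk_sheet = generate_bulk_cohort(d, n_donors)
        tbl = {
            "neuron": run_ewas(beta, sheet, None, RegressionSpec("braak", "neuron", ("age", "sex"))),
            "glia": run_ewas(beta, sheet, None, RegressionSpec("braak", "glia", ("age", "sex"))),
            "bulk": run_ewas(bulk, bulk_sheet, None, RegressionSpec("braak", "bulk", ("age", "sex"))),
        }
        hits = {
            name: (t["bonferroni_p"] < alpha).reindex(d.probe_ids).to_numpy()
            for name, t in tbl.items()
        }
        # one instance per (probe, fraction) carrying an effect
        sorted_inst = np.concatenate([hits["neuron"][planted_n], hits["glia"][planted_g]])
        bulk_inst = np.concatenate([hits["bulk"][planted_n], hits["bulk"][planted_g]])
        rows.append(
            {
                "seed": int(seed),
                "n_planted": int(planted_n.sum() + planted_g.sum()),
                "power_sorted": float(sorted_inst.mean()),
                "power_bulk": float(bulk_inst.mean()),
                "power_sorted_neuron": float(hits["neuron"][planted_n].mean()),
                "power_sorted_glia": float(hits["glia"][planted_g].mean()),
                "power_bulk_neuron": float(hits["bulk"][planted_n].mean()),
                "power_bulk_glia": float(hits["bulk"][planted_g].mean()),
            }
        )
    out = pd.DataFrame(rows)
    out["power_diff"] = out["power_sorted"] - out["power_bulk"]
    return out
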