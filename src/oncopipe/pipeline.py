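"""End-to-end driver: simulate every assay, analyze it, write a run manifest.

A single global seed fans out to per-stage child seeds by stable hashing of
the stage name, so stages stay decoupled: changing one stage's parameters
never perturbs another stage's random stream. The manifest records the
configuration, per-stage seeds, and a SHA-256 checksum of every output file,
making a full run reproducible and checksum-comparable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, grmetrics, synergy, synth, trajectory, xenograft
from .io import sha256_file, write_json, write_table

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "ALL_STAGES"]

ALL_STAGES = ("simulate", "gr", "synergy", "flow", "qpcr", "tgi", "trajectory",
              "survival")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    out_dir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage name(s): {sorted(unknown)}; "
                             f"valid stages are {list(ALL_STAGES)}")
        unknown_blocks = set(self.params) - set(ALL_STAGES)
        if unknown_blocks:
            raise ValueError(f"unknown parameter block(s): {sorted(unknown_blocks)}")
        for block, value in self.params.items():
            if not isinstance(value, dict):
                raise ValueError(f"parameter block {block!r} must be a mapping")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(out_dir=raw.get("out_dir", "."), seed=int(raw.get("seed", 0)),
                   stages=tuple(raw.get("stages", ALL_STAGES)),
                   params=raw.get("params", {}))

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump({
            "out_dir": self.out_dir, "seed": self.seed,
            "stages": list(self.stages), "params": self.params}))
        return path


def _default_plate_spec(seed: int, **overrides) -> synth.PlateSpec:
    cell_lines = ("LINE_A", "LINE_B")
    drugs = ("gedatolisib", "everolimus")
    gr_params = {
        ("LINE_A", "gedatolisib"): (-0.5, 20.0, 1.0),
        ("LINE_A", "everolimus"): (0.3, 500.0, 1.2),
        ("LINE_B", "gedatolisib"): (-0.3, 60.0, 1.5),
        ("LINE_B", "everolimus"): (0.5, 1500.0, 1.0),
    }
    kwargs = dict(cell_lines=cell_lines, drugs=drugs,
                  doubling_time_h={"LINE_A": 24.0, "LINE_B": 40.0},
                  gr_params=gr_params, noise_cv=0.05, seed=seed)
    kwargs.update(overrides)
    return synth.PlateSpec(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    skipped = [s for s in ALL_STAGES if s not in config.stages]
    seeds = {s: stage_seed(config.seed, s) for s in ALL_STAGES}

    def record(path):
        outputs[str(Path(path).relative_to(out))] = sha256_file(path)

    sim = "simulate" in config.stages
    plates = combo = xeno = cohort = None
    flow_panel = None

    if sim:
        plates = synth.gen_dose_response(
            _default_plate_spec(seeds["simulate"], **config.params.get("simulate", {}).get("plate", {})))
        record(write_table(plates, out / "plates.tsv"))
        combo = synth.gen_combination(dm_a=50.0, m_a=1.2, dm_b=200.0, m_b=1.0,
                                      interaction=0.6,
                                      doses=[(20, 80), (40, 160), (60, 240), (80, 320)],
                                      noise_cv=0.0, seed=seeds["simulate"])
        record(write_table(combo, out / "combination.tsv"))
        xeno = synth.gen_xenograft(
            arms=[("vehicle", 10, 0.08, 0.0), ("gedatolisib", 10, 0.08, 0.05),
                  ("combo", 10, 0.08, 0.075)],
            noise_cv=0.1, seed=seeds["simulate"])
        record(write_table(xeno, out / "xenograft.tsv"))
        cohort = synth.gen_expression_cohort(synth.CohortSpec(
            seed=seeds["simulate"], **config.params.get("simulate", {}).get("cohort", {})))
        record(write_table(cohort.counts.reset_index(names="gene"), out / "counts.tsv"))
        record(write_table(cohort.samples.reset_index(drop=True), out / "samples.tsv"))
        record(write_table(cohort.genes.reset_index(drop=True), out / "genes.tsv"))
        record(write_json({"pseudotime": cohort.truth["pseudotime"],
                           "loadings": cohort.truth["loadings"]},
                          out / "cohort_truth.json"))
        ctrl, treat, unstained, ct = synth.gen_assay_panel(seed=seeds["simulate"],
                                                           ct_effects={"PGR": -1.0})
        flow_panel = (ctrl, treat, unstained)
        record(write_table(ctrl, out / "flow_control.tsv"))
        record(write_table(treat, out / "flow_treated.tsv"))
        record(write_table(ct, out / "ct_table.tsv"))
        record(write_json(unstained, out / "unstained_medians.json"))

    if "gr" in config.stages:
        if plates is None:
            raise ValueError("gr stage requires the simulate stage (missing plates)")
        gr_table, metrics = grmetrics.analyze_plates(plates)
        record(write_table(gr_table, out / "gr_table.tsv"))
        record(write_table(metrics, out / "gr_metrics.tsv"))

    if "synergy" in config.stages:
        if combo is None:
            raise ValueError("synergy stage requires the simulate stage")
        fit_a, fit_b, ci = synergy.analyze_combination(combo)
        record(write_table(ci, out / "combination_index.tsv"))
        record(write_json({"drug_a": vars(fit_a), "drug_b": vars(fit_b)},
                          out / "median_effect_fits.json"))

    if "flow" in config.stages:
        if flow_panel is None:
            raise ValueError("flow stage requires the simulate stage")
        ctrl, treat, unstained = flow_panel
        summary = assays.flow_summarize(treat, ctrl, unstained,
                                        seed=seeds["flow"])
        pct = {ch: assays.percent_inhibition(v)[0]
               for ch, v in summary["mfi_norm"].items()}
        pct["edu"] = assays.percent_inhibition(summary["edu_norm"])[0]
        record(write_json({"normalized": {"edu": summary["edu_norm"],
                                          **summary["mfi_norm"]},
                           "percent_inhibition": pct}, out / "flow_summary.json"))

    if "qpcr" in config.stages:
        ct = pd.read_csv(out / "ct_table.tsv", sep="\t")
        rel = assays.ddct_expression(ct, target="PGR", control_condition="control")
        record(write_table(rel.drop(columns="flagged_samples"), out / "qpcr_ddct.tsv"))

    if "tgi" in config.stages:
        if xeno is None:
            raise ValueError("tgi stage requires the simulate stage")
        day = float(config.params.get("tgi", {}).get("day", 25))
        record(write_table(xenograft.arm_summary(xeno), out / "arm_summary.tsv"))
        record(write_table(xenograft.tgi(xeno, day=day, control_arm="vehicle"),
                           out / "tgi.tsv"))
        record(write_table(xenograft.body_weight_change(xeno),
                           out / "body_weight.tsv"))
        record(write_json(xenograft.group_compare(xeno, day=day,
                                                  control_arm="vehicle"),
                          out / "group_compare.json"))

    traj_model = None
    logmat = None
    if "trajectory" in config.stages:
        if cohort is None:
            raise ValueError("trajectory stage requires the simulate stage")
        tp = config.params.get("trajectory", {})
        logmat, sf = trajectory.preprocess_counts(cohort.counts, cohort.genes)
        adjusted = trajectory.remove_batch(logmat, cohort.samples["batch"],
                                           cohort.samples["grade"])
        n_perm = int(tp.get("dsc_permutations", 200))
        diag_before = trajectory.dsc(logmat, cohort.samples["batch"],
                                     n_perm=n_perm, seed=seeds["trajectory"])
        diag_after = trajectory.dsc(adjusted, cohort.samples["batch"],
                                    n_perm=n_perm, seed=seeds["trajectory"])
        pca = trajectory.pca_embed(adjusted,
                                   n_top_iqr=int(tp.get("n_top_iqr", 2000)),
                                   n_pc=int(tp.get("n_pc", 5)))
        seed_cluster = str(cohort.samples["grade"].sort_values().iloc[0])
        traj_model = trajectory.infer_trajectory(pca.embedding,
                                                 cohort.samples["grade"],
                                                 seed_cluster=seed_cluster)
        corr = trajectory.pseudotime_correlation(adjusted, traj_model.pseudotime,
                                                 seed=seeds["trajectory"])
        record(write_table(corr.reset_index(drop=True), out / "pseudotime_correlation.tsv"))
        record(write_table(traj_model.pseudotime.rename("pseudotime")
                           .rename_axis("sample").reset_index(),
                           out / "pseudotime.tsv"))
        record(write_json({
            "dsc_before": diag_before.dsc, "dsc_after": diag_after.dsc,
            "dsc_p_before": diag_before.p_perm, "dsc_p_after": diag_after.p_perm,
            "variance_explained_5pc": float(pca.variance_ratio[:5].sum()),
            "mst_edges": traj_model.mst_edges,
            "cluster_order": traj_model.cluster_order,
            "converged": traj_model.converged,
            "curve": traj_model.curve}, out / "trajectory_model.json"))
        # preranked GSEA on planted modules: top positive-loading genes in the
        # filtered matrix form a truth set, a matched random set is the control
        loadings = cohort.truth["loadings"].reindex(corr.index)
        planted = loadings[loadings >= 0.5].index.tolist()
        rng = np.random.default_rng(seeds["trajectory"])
        if len(planted) >= 5:
            random_set = list(rng.choice(corr.index.to_numpy(),
                                         size=len(planted), replace=False))
            gsea = trajectory.gsea_preranked(
                corr["median_r"].dropna(),
                {"planted_module": planted, "random_set": random_set},
                n_perm=int(tp.get("gsea_permutations", 500)),
                seed=seeds["trajectory"])
            record(write_table(gsea, out / "gsea.tsv"))

    if "survival" in config.stages:
        if cohort is None:
            raise ValueError("survival stage requires the simulate stage")
        if logmat is None:
            logmat, _ = trajectory.preprocess_counts(cohort.counts, cohort.genes)
        loadings = cohort.truth["loadings"].reindex(logmat.index).fillna(0.0)
        gene = loadings.abs().idxmax()
        report = trajectory.km_twogroup(logmat.loc[gene],
                                        cohort.samples["survival_time"],
                                        cohort.samples["event"])
        record(write_json({"gene": gene, "n": report["n"],
                           "n_events": report["n_events"],
                           "logrank_stat": report["logrank_stat"],
                           "p": report["p"]}, out / "survival.json"))

    manifest = {
        "config": {"seed": config.seed, "stages": list(config.stages),
                   "params": config.params},
        "stage_seeds": {s: seeds[s] for s in config.stages},
        "skipped_stages": skipped,
        "outputs": dict(sorted(outputs.items())),
    }
    write_json(manifest, out / "manifest.json")
    return manifest
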