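"""End-to-end pipeline wiring: simulate -> quantify -> classify ->
phenotype -> associate (cohort, senescence, mouse).

``run_pipeline`` executes the enabled stages in dependency order,
writes every output as TSV into the run directory and records a
machine-readable ``manifest.json`` (semantic config hash, seed, stage
status and per-file row counts).  Reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import associate, classify, phenotype, quantify, synthetic
from .config import PipelineConfig

logger = logging.getLogger("circaging")

__all__ = ["run_pipeline", "StageFailure"]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def _write(frame: pd.DataFrame, outdir: Path, name: str, manifest_files: dict) -> None:
    path = outdir / name
    frame.to_csv(path, sep="\t", index=False)
    manifest_files[name] = int(len(frame))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all enabled stages; returns the run directory.

    On stage failure the partial outputs are kept and the manifest marks
    the failure point before the exception is re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages_cfg = config["stages"]
    manifest = {
        "config_hash": config.semantic_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}

    order = ["simulate", "quantify", "classify", "phenotype", "associate", "senescence", "mouse"]
    try:
        for stage in order:
            if not stages_cfg.get(stage, False):
                manifest["stages"][stage] = {"status": "skipped", "files": {}}
                logger.info("[%s] skipped", stage)
                continue
            files: dict[str, int] = {}
            logger.info("[%s] running", stage)
            try:
                _STAGE_FUNCS[stage](config, state, outdir, files)
            except Exception as exc:  # noqa: BLE001 - manifest must record the failure
                manifest["stages"][stage] = {"status": "failed", "error": str(exc), "files": files}
                raise StageFailure(stage, exc) from exc
            manifest["stages"][stage] = {"status": "ok", "files": files}
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, state: dict, outdir: Path, files: dict) -> None:
    seed = config.seed
    pool_cfg = synthetic.PoolSimConfig(seed=seed, **config["pool_sim"])
    table, truth = synthetic.simulate_pool_counts(pool_cfg)
    state["junction_counts"] = table
    state["pool_truth"] = truth
    _write(table, outdir, "junction_counts.tsv", files)
    gt = pd.DataFrame(
        {
            "circ_id": sorted(truth.class_of),
            "class_label": [truth.class_of[c] for c in sorted(truth.class_of)],
            "planted_log2_fc": [truth.planted_fc.get(c, np.nan) for c in sorted(truth.class_of)],
        }
    )
    _write(gt, outdir, "ground_truth_classes.tsv", files)

    cohort_params = dict(config["cohort_sim"])
    planted_beta = cohort_params.pop("planted_pls_beta")
    cohort_cfg = synthetic.CohortSimConfig(
        seed=seed + 1,
        planted_effects={"circPLS01": ("PLS", planted_beta)},
        **cohort_params,
    )
    records, expression, cohort_truth = synthetic.simulate_cohort(cohort_cfg)
    state["cohort"] = records
    state["expression"] = expression
    state["cohort_truth"] = cohort_truth
    _write(records, outdir, "cohort.tsv", files)
    _write(expression.reset_index(), outdir, "expression.tsv", files)


def _stage_quantify(config: PipelineConfig, state: dict, outdir: Path, files: dict) -> None:
    table = state.get("junction_counts")
    if table is None:
        path = config["inputs.junction_counts"]
        if not path:
            raise ValueError("no junction counts: enable simulate or set inputs.junction_counts")
        table = pd.read_csv(path, sep="\t")
        state["junction_counts"] = table
    profiles = quantify.compute_bpm_all(
        table, canonical_per_gene_once=config["quantify.canonical_per_gene_once"]
    )
    state["profiles"] = profiles
    rows = []
    for lib, prof in profiles.items():
        for circ, bpm in prof.bpm.items():
            rows.append(
                {
                    "library_id": lib,
                    "circ_id": circ,
                    "bsj_reads": int(prof.bsj_reads[circ]),
                    "bpm": bpm,
                    "denominator": prof.denominator,
                }
            )
    _write(pd.DataFrame(rows), outdir, "bpm_profiles.tsv", files)
    min_reads = config["quantify.min_bsj_reads"]
    presence = {
        pool: quantify.call_presence(profiles[lib], min_reads)
        for pool, lib in synthetic.TREATED_LIBRARIES.items()
        if lib in profiles
    }
    state["presence"] = presence
    pres_rows = [
        {"pool": pool, "circ_id": circ}
        for pool, ids in presence.items()
        for circ in sorted(ids)
    ]
    _write(pd.DataFrame(pres_rows), outdir, "presence.tsv", files)


def _stage_classify(config: PipelineConfig, state: dict, outdir: Path, files: dict) -> None:
    presence = state["presence"]
    profiles = state["profiles"]
    table = classify.partition_classes(
        presence.get("young", set()),
        presence.get("old", set()),
        profiles.get("young_treated"),
        profiles.get("old_treated"),
    )
    state["class_table"] = table
    _write(table, outdir, "class_table.tsv", files)
    counts = classify.class_counts(table)
    counts_frame = pd.DataFrame(
        [{"class_label": k, "n": v} for k, v in counts.items()]
        + [{"class_label": "total", "n": int(len(table))}]
    )
    _write(counts_frame, outdir, "class_counts.tsv", files)
    candidates = classify.select_candidates(table, config["classify.k_per_class"])
    state["candidates"] = candidates
    _write(candidates, outdir, "candidates.tsv", files)

    hosts_frames = []
    for pool, lib in synthetic.TREATED_LIBRARIES.items():
        if lib not in profiles:
            continue
        genes = classify.top_decile_hosts(
            profiles[lib], top_fraction=config["classify.top_fraction"]
        )
        hosts_frames.append(pd.DataFrame({"pool": pool, "host_gene": genes}))
    if hosts_frames:
        _write(pd.concat(hosts_frames, ignore_index=True), outdir, "top_decile_hosts.tsv", files)

    gmt_path = config["inputs.gene_sets"]
    if gmt_path:
        gene_sets = classify.read_gmt(gmt_path)
        universe = set()
        for lib in synthetic.TREATED_LIBRARIES.values():
            if lib in profiles and profiles[lib].hosts is not None:
                universe |= set(profiles[lib].hosts)
        for frame in hosts_frames:
            pool = frame["pool"].iloc[0]
            results = classify.enrich_gene_sets(frame["host_gene"], gene_sets, universe)
            enr = pd.DataFrame(
                [
                    {
                        "set_id": r.set_id,
                        "k": r.k,
                        "q": r.q,
                        "m": r.m,
                        "N": r.N,
                        "p_two_sided": r.p_two_sided,
                        "p_adjusted": r.p_adjusted,
                        "leading_genes": ",".join(r.leading_genes),
                    }
                    for r in results
                ]
            )
            _write(enr, outdir, f"enrichment_{pool}.tsv", files)


def _stage_phenotype(config: PipelineConfig, state: dict, outdir: Path, files: dict) -> None:
    records = state.get("cohort")
    if records is None:
        path = config["inputs.cohort"]
        if not path:
            raise ValueError("no cohort table: enable simulate or set inputs.cohort")
        records = pd.read_csv(path, sep="\t")
        state["cohort"] = records
    pls = phenotype.compute_pls(records)
    state["pls"] = pls
    _write(pls, outdir, "pls.tsv", files)


def _stage_associate(config: PipelineConfig, state: dict, outdir: Path, files: dict) -> None:
    records = state["cohort"]
    expression = state.get("expression")
    if expression is None:
        path = config["inputs.expression"]
        if not path:
            raise ValueError("no expression matrix: enable simulate or set inputs.expression")
        expression = pd.read_csv(path, sep="\t").set_index("participant_id")
        state["expression"] = expression
    pls = state["pls"].set_index(records.index)["pls"]
    alpha = config["associate.alpha"]
    overrides = config["associate.orientation_overrides"]
    n_tests = expression.shape[1]
    results = []
    outcomes = {
        "PLS": pls,
        "age": records["age"],
        "grip_cross_sectional": records["grip_fu3"],
        "grip_longitudinal": records["grip_fu4"],
    }
    for outcome_name, outcome in outcomes.items():
        covariates, _ = phenotype.build_covariates(
            records, outcome="age" if outcome_name == "age" else outcome_name
        )
        for circ in expression.columns:
            expr = expression[circ]
            expr.index = records.index
            results.append(
                associate.fit_phenotype_association(
                    expr,
                    outcome,
                    covariates,
                    circ_id=circ,
                    outcome_name=outcome_name,
                    orientation=overrides.get(outcome_name),
                    alpha=alpha,
                    n_tests=n_tests,
                )
            )
    frame = associate.association_results_frame(results)
    state["associations"] = frame
    _write(frame, outdir, "associations.tsv", files)


def _default_senescence_shifts(config: PipelineConfig, state: dict) -> dict:
    """Planted shifts for the selected candidates: the configured shift
    for the first ``n_shifted`` candidate/cell-type pairs, 0 elsewhere."""
    candidates = state.get("candidates")
    if candidates is not None:
        circ_ids = list(candidates["circ_id"])
    else:
        circ_ids = [f"cand{i:02d}" for i in range(15)]
    shift = config["senescence_sim.shift_ct"]
    n_shifted = int(config["senescence_sim.n_shifted"])
    rng = np.random.default_rng(config.seed + 7)
    shifts = {}
    pairs = [(c, ct) for c in circ_ids for ct in synthetic.CELL_TYPES]
    shifted = set(
        rng.choice(len(pairs), size=min(n_shifted, len(pairs)), replace=False).tolist()
    )
    for i, pair in enumerate(pairs):
        shifts[pair] = shift if i in shifted else 0.0
    return shifts


def _stage_senescence(config: PipelineConfig, state: dict, outdir: Path, files: dict) -> None:
    path = config["inputs.senescence_qpcr"]
    if path:
        matrix = pd.read_csv(path, sep="\t")
    else:
        shifts = _default_senescence_shifts(config, state)
        matrix, truth = synthetic.simulate_senescence_qpcr(shifts, seed=config.seed + 3)
        state["senescence_truth"] = truth
        _write(matrix, outdir, "senescence_qpcr.tsv", files)
    all_results = []
    for cell in sorted(matrix["cell_type"].unique()):
        all_results.extend(associate.senescence_compare(matrix, cell_type=cell))
    frame = pd.DataFrame(
        [
            {
                "circ_id": r.circ_id,
                "cell_type": r.cell_type,
                "median_early": r.median_early,
                "median_late": r.median_late,
                "q1_early": r.iqr_early[0],
                "q3_early": r.iqr_early[1],
                "q1_late": r.iqr_late[0],
                "q3_late": r.iqr_late[1],
                "p": r.p,
                "expressed": r.expressed,
            }
            for r in all_results
        ]
    )
    state["senescence_results"] = frame
    _write(frame, outdir, "senescence_results.tsv", files)
    n_dys, n_expr, pct = associate.count_dysregulated(frame, alpha=config["associate.alpha"])
    summary = pd.DataFrame(
        [{"n_dysregulated": n_dys, "n_expressed": n_expr, "percent": pct}]
    )
    _write(summary, outdir, "senescence_summary.tsv", files)


def _stage_mouse(config: PipelineConfig, state: dict, outdir: Path, files: dict) -> None:
    path = config["inputs.mouse_panel"]
    if path:
        panel = pd.read_csv(path, sep="\t")
    else:
        candidates = state.get("candidates")
        if candidates is not None:
            conserved = list(candidates["circ_id"].head(4))
        else:
            conserved = [f"cons{i}" for i in range(4)]
        slope = config["mouse_sim.planted_young_spleen_slope"]
        slopes = {}
        for i, circ in enumerate(conserved):
            slopes[(circ, "spleen", "young")] = slope if i == 0 else 0.0
            slopes[(circ, "spleen", "old")] = 0.0
            if i < 2:  # two of four also detected in muscle
                slopes[(circ, "muscle", "young")] = 0.0
                slopes[(circ, "muscle", "old")] = 0.0
        panel, truth = synthetic.simulate_mouse_panel(
            planted_slopes=slopes,
            seed=config.seed + 5,
            n_animals_per_group=int(config["mouse_sim.n_animals_per_group"]),
        )
        state["mouse_truth"] = truth
        _write(panel, outdir, "mouse_panel.tsv", files)
    n_circ = panel.loc[
        ~panel["assay_id"].isin(associate.MOUSE_REFERENCE_ASSAYS), "assay_id"
    ].nunique()
    results = []
    tissue_col: list[str] = []
    for tissue in sorted(panel["tissue"].unique()):
        for stratum in ("all", "young", "old"):
            res = associate.mouse_lifespan_association(
                panel,
                tissue,
                stratum=stratum,
                alpha=config["associate.alpha"],
                n_tests=max(n_circ, 1),
            )
            results.extend(res)
            tissue_col.extend([tissue] * len(res))
    frame = associate.association_results_frame(results)
    frame.insert(1, "tissue", tissue_col)
    state["mouse_results"] = frame
    _write(frame, outdir, "mouse_associations.tsv", files)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "classify": _stage_classify,
    "phenotype": _stage_phenotype,
    "associate": _stage_associate,
    "senescence": _stage_senescence,
    "mouse": _stage_mouse,
}
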