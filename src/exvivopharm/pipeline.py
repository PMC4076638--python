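"""End-to-end pipeline runner: simulation -> scoring -> classification ->
expression -> synergy -> report, driven by one :class:`RunConfig`."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bliss, classify, expression, ihc, synthetic
from .config import RunConfig
from .io import read_table, write_table

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    import zlib

    seq = np.random.SeedSequence([cfg.seed, zlib.crc32(stage.encode())])
    return int(seq.generate_state(1, dtype=np.uint64)[0] % (2**31))


def run_simulate(cfg: RunConfig, outdir: Path) -> dict:
    cp = synthetic.CohortParams(**cfg.cohort.model_dump(), seed=_stage_seed(cfg, "cohort"))
    cohort = synthetic.generate_cohort(cp)
    write_table(cohort.cases_frame(), outdir / "cohort_cases.csv")
    write_table(cohort.observations_frame(), outdir / "ihc_observations.csv")
    write_table(cohort.truth_frame(), outdir / "truth_labels.csv")

    ep_kwargs = cfg.expression.model_dump()
    ep_kwargs.pop("efficiency")
    ep_kwargs.pop("max_missing_fraction")
    ep = synthetic.ExpressionParams(**ep_kwargs, seed=_stage_seed(cfg, "expression"))
    ct = synthetic.generate_ct_table(cohort.reveal_all(), ep)
    write_table(ct, outdir / "ct_table.csv")

    pp_kwargs = {k: v for k, v in cfg.plate.model_dump().items() if v is not None}
    pp = synthetic.PlateParams(**pp_kwargs, seed=_stage_seed(cfg, "plate"))
    plate = synthetic.generate_dose_matrix(pp)
    write_table(plate.to_table(), outdir / "plate.csv")
    logger.info("simulated %d cases, %d IHC observations, %d Ct wells, %d plate wells",
                len(cohort.cases), len(cohort.observations), len(ct), len(plate.wells))
    return {"n_cases": len(cohort.cases)}


def _trajectories(obs: pd.DataFrame) -> dict[tuple[str, str, str], ihc.MarkerTrajectory]:
    out = {}
    for (case_id, marker, arm), group in obs.groupby(["case_id", "marker", "arm"]):
        observations = [
            ihc.IHCObservation(
                case_id=str(r.case_id),
                marker=str(r.marker),
                arm=str(r.arm),
                time_h=float(r.time_h),
                percent_positive=float(r.percent_positive),
                intensity=None if pd.isna(r.intensity) or r.intensity == "" else int(r.intensity),
            )
            for r in group.itertuples(index=False)
        ]
        out[(str(case_id), str(marker), str(arm))] = ihc.MarkerTrajectory.from_observations(observations)
    return out


def run_score(cfg: RunConfig, outdir: Path) -> dict:
    obs = read_table(outdir / "ihc_observations.csv",
                     ["case_id", "marker", "arm", "time_h", "percent_positive"])
    trajs = _trajectories(obs)
    rows, gi_rows = [], []
    for (case_id, marker, arm), traj in trajs.items():
        norm = ihc.normalize_to_baseline(traj)
        for t, raw, n in zip(traj.times_h, traj.scores, norm.scores):
            rows.append({"case_id": case_id, "marker": marker, "arm": arm,
                         "time_h": t, "score": raw, "normalized": n})
    for (case_id, marker, arm), traj in trajs.items():
        if marker != "Ki67":
            continue
        casp = trajs.get((case_id, "CASP3", arm))
        if casp is None:
            continue
        gi = ihc.growth_index(traj, casp)
        for t, g in zip(gi.times_h, gi.gi):
            gi_rows.append({"case_id": case_id, "arm": arm, "time_h": t, "gi": g})
    write_table(pd.DataFrame(rows), outdir / "trajectories.csv")
    write_table(pd.DataFrame(gi_rows), outdir / "growth_index.csv")
    return {"n_trajectories": len(trajs)}


def run_classify(cfg: RunConfig, outdir: Path) -> dict:
    traj = read_table(outdir / "trajectories.csv",
                      ["case_id", "marker", "arm", "time_h", "normalized"])
    ki = traj[traj["marker"] == "Ki67"]
    calls = []
    for case_id, group in ki.groupby("case_id"):
        arms = {}
        for arm, sub in group.groupby("arm"):
            sub = sub.sort_values("time_h")
            arms[arm] = ihc.MarkerTrajectory(
                case_id=str(case_id), marker="Ki67", arm=str(arm),
                times_h=tuple(sub["time_h"]), scores=tuple(sub["normalized"]),
            )
        if "doxo" not in arms or "vehicle" not in arms:
            logger.warning("case %s lacks a treatment or control arm; skipped", case_id)
            continue
        if cfg.classify.denominator == "t0":
            shared = sorted(set(arms["doxo"].times_h))
            t_final = cfg.classify.final_time or shared[-1]
            rel = arms["doxo"].at(t_final)
        else:
            rel = classify.relative_ki67(arms["doxo"], arms["vehicle"], cfg.classify.final_time)
        calls.append(classify.ResponseCall(
            case_id=str(case_id), relative_ki67_final=rel, call=classify.classify_response(rel),
        ))
    calls_frame = pd.DataFrame([vars(c) for c in calls])
    write_table(calls_frame, outdir / "response_calls.csv")

    summary: dict = {
        "n_responder": int((calls_frame["call"] == "Responder").sum()),
        "n_nonresponder": int((calls_frame["call"] == "NonResponder").sum()),
    }
    if cfg.use_clinical_fixture:
        cases = classify.load_clinical_fixture()
    else:
        cases = classify.parse_clinical_table(read_table(outdir / "cohort_cases.csv"))
        lookup = {c.case_id: c.call for c in calls}
        cases = [
            classify.TumorCase(**{**vars(c), "doxo_class": lookup.get(c.case_id, "Unknown")})
            for c in cases
        ]
    try:
        assoc = classify.association_screen([c for c in cases if c.doxo_class != "Unknown"])
        write_table(assoc, outdir / "associations.csv")
        ki_row = assoc[assoc["feature"] == "ki67_diagnosis_mean"].iloc[0]
        summary["ki67_mean_responder"] = float(ki_row["mean_responder"])
        summary["ki67_mean_nonresponder"] = float(ki_row["mean_nonresponder"])
    except classify.ClassificationError as exc:
        logger.warning("association screen skipped: %s", exc)
    return summary


def run_expression(cfg: RunConfig, outdir: Path) -> dict:
    ct = read_table(outdir / "ct_table.csv", list(expression.CT_COLUMNS))
    rq = expression.relative_quantity(ct, efficiency=cfg.expression.efficiency)
    refs = [g for g in cfg.expression.reference_genes if g in rq.index]
    if len(refs) < 2:
        raise expression.ExpressionError(f"reference genes missing from card: {cfg.expression.reference_genes}")
    ref_rq = rq.loc[refs]
    stability = expression.genorm_stability(ref_rq)
    nf = expression.normalization_factor(ref_rq)
    matrix = expression.normalize_card(
        rq.drop(index=refs), nf, stability, cfg.expression.max_missing_fraction
    )
    if matrix.dropped_genes:
        logger.info("dropped %d genes missing in >%.0f%% of samples",
                    len(matrix.dropped_genes), 100 * cfg.expression.max_missing_fraction)
    classes = ct.drop_duplicates("sample_id").set_index("sample_id")["class"]
    diff = expression.differential_panel(matrix, classes)
    write_table(matrix.values.reset_index(), outdir / "normalized_matrix.csv")
    write_table(stability.rename_axis("gene").reset_index(), outdir / "reference_stability.csv")
    write_table(diff, outdir / "differential.csv")
    return {"top_gene": str(diff.iloc[0]["gene"]), "top_gene_fdr": float(diff.iloc[0]["fdr"])}


def run_synergy(cfg: RunConfig, outdir: Path) -> dict:
    table = read_table(outdir / "plate.csv", list(bliss.PLATE_COLUMNS))
    plate = bliss.DoseMatrixPlate.from_table(table)
    grid = bliss.synergy_matrix(plate)
    write_table(grid.to_frame(), outdir / "bliss_grid.csv")
    summary = bliss.combination_summary(grid, delta=cfg.synergy.delta)
    if cfg.synergy.plot:
        _plot_heatgrid(grid, outdir / "bliss_heatgrid.png")
    write_table(pd.DataFrame([summary]), outdir / "synergy_summary.csv")
    return summary


def _plot_heatgrid(grid: bliss.BlissGrid, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid.excess, origin="lower", cmap="RdBu_r", vmin=-0.5, vmax=0.5)
    ax.set_xticks(range(len(grid.doses_b)), [f"{d:g}" for d in grid.doses_b], rotation=45)
    ax.set_yticks(range(len(grid.doses_a)), [f"{d:g}" for d in grid.doses_a])
    ax.set_xlabel(f"{grid.drug_b} dose")
    ax.set_ylabel(f"{grid.drug_a} dose")
    fig.colorbar(im, label="excess over independence")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_report(cfg: RunConfig, outdir: Path, stage_results: dict) -> dict:
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(stage_results, indent=2, sort_keys=True))
    lines = ["pipeline summary", "================"]
    for stage, result in stage_results.items():
        lines.append(f"[{stage}]")
        for key, value in result.items():
            lines.append(f"  {key} = {value}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return {"summary": str(summary_path)}


_RUNNERS = {
    "simulate": run_simulate,
    "score": run_score,
    "classify": run_classify,
    "expression": run_expression,
    "synergy": run_synergy,
}


def run_pipeline(cfg: RunConfig, stages=None) -> dict:
    """Run the requested stages in canonical order; returns per-stage results.

    Writes ``manifest.json`` (resolved config + seed + artifact list) so
    every output is reproducible from the manifest alone.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or cfg.stages)
    results: dict = {}
    for stage in [s for s in ("simulate", "score", "classify", "expression", "synergy") if s in stages]:
        results[stage] = _RUNNERS[stage](cfg, outdir)
    if "report" in stages:
        results["report"] = run_report(cfg, outdir, results)
    manifest = {
        "config": cfg.model_dump(),
        "stages_run": stages,
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=list))
    return results
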