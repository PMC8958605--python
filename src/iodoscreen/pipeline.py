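"""End-to-end orchestration with reproducibility manifests.

Composes the stages — simulate/read a screen, normalize and call hits, QC
with per-plate Z' factors, dose-response ranking, uptake quantification,
risk-score modelling — under a single root seed, and records a run manifest
(config snapshot, input digests, seed, per-stage counts) so that a run can
be reproduced byte-for-byte.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .dose_quantify import summarize_dose_table, uptake_fold_table
from .hts_scoring import call_hits, plate_z_factors, score_screen
from .recurrence_risk import (
    build_risk_model,
    multivariate_adjusted,
    stratify_by_risk,
    COVARIATE_COLUMNS,
)
from .screen_model import (
    KineticWell,
    Role,
    ScreenConfig,
    ScreenValidationError,
    read_screen,
    validate_layout,
    write_results,
    write_screen,
)
from .synthetic_data import (
    CohortSimSpec,
    FourPLParams,
    ScreenSimSpec,
    simulate_cohort,
    simulate_dose_response,
    simulate_screen,
    simulate_uptake,
)

logger = logging.getLogger("iodoscreen")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_QC = 3


def file_digest(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    seed: int
    version: str = __version__
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat())

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class PrimaryScreenResult:
    hits: pd.DataFrame
    qc: pd.DataFrame
    manifest: RunManifest
    exit_code: int


def run_primary_screen(
    config: ScreenConfig,
    screen_path: Union[str, Path],
    out_results: Optional[Union[str, Path]] = None,
    require_qc_pass: bool = False,
) -> PrimaryScreenResult:
    """Read, validate, normalize and score one screen file.

    Writes the per-well results TSV when ``out_results`` is given and
    returns the ranked hit table, the per-plate QC table (Z', mu_IQ, DMSO
    SD) and a manifest.  Exit code 2 flags validation errors, 3 a QC
    failure when ``require_qc_pass`` demands every plate pass Z' > 0.5.
    """
    manifest = RunManifest(seed=config.rng_seed, config=dict(config.__dict__))
    manifest.input_digests[str(screen_path)] = file_digest(screen_path)
    wells = read_screen(screen_path)
    manifest.stage_counts["wells_in"] = len(wells)

    findings = validate_layout(wells)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        for f in errors:
            logger.error("run_primary_screen: %s", f.message)
        raise ScreenValidationError("; ".join(f.message for f in errors))

    normalized, stats = score_screen(wells, config)
    manifest.stage_counts["wells_scored"] = len(normalized)
    manifest.stage_counts["wells_excluded"] = len(wells) - len(normalized)
    ranked = call_hits(normalized, config)
    manifest.stage_counts["drugs"] = len(ranked)
    manifest.stage_counts["hits"] = int(sum(w.hit for w in ranked))
    hit_drugs = {w.drug_id for w in ranked if w.hit}
    for w in normalized:
        w.hit = w.drug_id in hit_drugs

    zs = plate_z_factors(wells, cycle=config.cycles_used)
    qc = pd.DataFrame([
        {"plate": p,
         "z_factor": zs[p].z_factor if p in zs else np.nan,
         "z_suitable": zs[p].suitable if p in zs else None,
         "mu_iq": stats.mu_iq_per_plate.get(p, np.nan)}
        for p in sorted(stats.mu_iq_per_plate)
    ])
    qc.attrs["dmso_sd"] = stats.dmso_sd
    qc.attrs["n_dmso"] = stats.n_dmso

    exit_code = EXIT_OK
    if require_qc_pass and not bool(qc["z_suitable"].fillna(False).all()):
        bad = qc.loc[~qc["z_suitable"].fillna(False), "plate"].tolist()
        logger.error("run_primary_screen: plates failing Z' > 0.5: %s", bad)
        exit_code = EXIT_QC

    if out_results is not None:
        write_results(normalized, out_results)

    hits = pd.DataFrame([
        {"drug_id": w.drug_id, "delta_yfp": w.delta_yfp,
         "viability": w.viability, "hit": w.hit}
        for w in ranked
    ])
    return PrimaryScreenResult(hits=hits, qc=qc, manifest=manifest,
                               exit_code=exit_code)


def run_end_to_end_demo(seed: int = 1, out_dir: Optional[Union[str, Path]] = None) -> dict:
    """Generate a full synthetic study and run every stage on it.

    Simulates a 15-plate primary screen, scores it and calls hits; runs a
    small secondary dose-response panel, an uptake experiment and a
    recurrence cohort with a 13-gene risk model; returns a report dict and,
    when ``out_dir`` is given, writes the tables plus a human-readable
    report and the manifest.
    """
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    report: dict = {"seed": seed}
    manifest = RunManifest(seed=seed)

    # --- primary screen ---
    spec = ScreenSimSpec(seed=child())
    wells, truth = simulate_screen(spec)
    config = ScreenConfig(rng_seed=seed)
    normalized, stats = score_screen(wells, config)
    ranked = call_hits(normalized, config)
    zs = plate_z_factors(wells)
    hits = [w for w in ranked if w.hit]
    truth_active = truth.set_index("drug_id")["is_active"]
    called = {w.drug_id for w in hits}
    active_ids = set(truth_active[truth_active].index)
    viable_active = set(
        truth[(truth.is_active) & (truth.viability >= config.viability_floor)]["drug_id"])
    report["screen"] = {
        "n_wells": len(wells),
        "n_drugs": len(ranked),
        "n_hits": len(hits),
        "n_true_active": len(active_ids),
        "sensitivity_viable_actives": (
            len(called & viable_active) / len(viable_active) if viable_active else np.nan),
        "min_plate_z_factor": min(a.z_factor for a in zs.values()),
        "dmso_sd": stats.dmso_sd,
        "top_hits": [(w.drug_id, round(w.delta_yfp, 2)) for w in hits[:10]],
    }
    manifest.stage_counts["screen_wells"] = len(wells)
    manifest.stage_counts["screen_hits"] = len(hits)

    # --- secondary dose-response panel ---
    doses = np.geomspace(0.1, 50.0, 10)
    panel = []
    true_ec50 = {}
    for i in range(5):
        ec50 = float(rng.uniform(0.5, 10.0))
        drug = f"HIT_{i + 1:02d}"
        true_ec50[drug] = ec50
        params = FourPLParams(bottom=0.0, top=float(rng.uniform(2.0, 4.0)),
                              ec50=ec50, hill=float(rng.uniform(0.8, 2.0)))
        panel.append(simulate_dose_response(params, doses, noise_cv=0.05,
                                            seed=child(), drug_id=drug))
    dose_table = pd.concat(panel, ignore_index=True)
    dose_summary = summarize_dose_table(dose_table)
    report["dose_response"] = {
        "n_drugs": len(dose_summary),
        "ranking": dose_summary[["drug_id", "delta_auc", "ec50_uM"]]
        .round(3).to_dict("records"),
        "true_ec50": {k: round(v, 3) for k, v in true_ec50.items()},
    }

    # --- radioiodide uptake ---
    uptake = simulate_uptake(n_replicates=6, true_fold=4.3, seed=child())
    folds = uptake_fold_table(uptake)
    report["uptake"] = folds.round(3).to_dict("records")

    # --- recurrence risk model ---
    cspec = CohortSimSpec(n_patients=600, seed=child())
    cohort, true_beta = simulate_cohort(cspec)
    model = build_risk_model(cohort, cspec.genes)
    strat = stratify_by_risk(model, cohort)
    adj = multivariate_adjusted(
        (model.scores(cohort) > model.group_cutoff).astype(float),
        cohort[COVARIATE_COLUMNS], cohort["time"], cohort["event"])
    report["risk_model"] = {
        "n_patients": len(cohort),
        "n_events": int(cohort["event"].sum()),
        "score_auc": round(model.auc, 3),
        "high_vs_low_hr": round(strat.hazard_ratio, 3),
        "logrank_p": float(strat.logrank_p),
        "adjusted_risk_hr": round(float(adj["risk_high"]["hr"]), 3),
        "adjusted_risk_p": float(adj["risk_high"]["p"]),
        "true_causal_beta": {g: b for g, b in true_beta.items() if b != 0},
        "fitted_beta": {g: round(float(b), 3)
                        for g, b in zip(model.genes, model.beta)},
    }
    manifest.stage_counts["cohort_patients"] = len(cohort)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_screen(wells, out / "screen.csv")
        truth.to_csv(out / "screen_truth.tsv", sep="\t", index=False)
        write_results(normalized, out / "screen_results.tsv")
        dose_table.to_csv(out / "dose_response.csv", index=False)
        dose_summary.to_csv(out / "dose_summary.tsv", sep="\t", index=False)
        uptake.to_csv(out / "uptake.csv", index=False)
        folds.to_csv(out / "uptake_folds.tsv", sep="\t", index=False)
        cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
        with open(out / "risk_model.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        with open(out / "report.txt", "w") as fh:
            fh.write(format_report(report))
        manifest.write(out / "manifest.json")
    return report


def format_report(report: dict) -> str:
    """Render the demo report for humans."""
    s = report["screen"]
    lines = [
        f"iodoscreen end-to-end demo (seed {report['seed']})",
        "=" * 50,
        "",
        "Primary screen",
        f"  wells: {s['n_wells']}, drugs: {s['n_drugs']}, hits: {s['n_hits']} "
        f"(true actives: {s['n_true_active']})",
        f"  sensitivity among viable actives: {s['sensitivity_viable_actives']:.2%}",
        f"  min plate Z': {s['min_plate_z_factor']:.3f}   "
        f"screen DMSO SD: {s['dmso_sd']:.4f}",
        "  top hits (drug, dYFP): "
        + ", ".join(f"{d}={v}" for d, v in s["top_hits"][:5]),
        "",
        "Secondary dose-response (dAUC ranking)",
    ]
    for row in report["dose_response"]["ranking"]:
        t = report["dose_response"]["true_ec50"].get(row["drug_id"])
        lines.append(f"  {row['drug_id']}: dAUC={row['delta_auc']}, "
                     f"EC50={row['ec50_uM']} uM (true {t})")
    lines.append("")
    lines.append("Radioiodide uptake")
    for row in report["uptake"]:
        lines.append(f"  {row['condition']}: fold={row['fold_uptake']} "
                     f"+/- {row['sem']} (NIS-specific: {row['nis_specific']})")
    r = report["risk_model"]
    lines += [
        "",
        "Recurrence risk model",
        f"  n={r['n_patients']} patients, {r['n_events']} events",
        f"  risk-score AUC: {r['score_auc']}",
        f"  high vs low HR: {r['high_vs_low_hr']} (log-rank p={r['logrank_p']:.2e})",
        f"  covariate-adjusted risk HR: {r['adjusted_risk_hr']} "
        f"(p={r['adjusted_risk_p']:.2e})",
        "",
    ]
    return "\n".join(lines)
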