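"""Config-driven orchestration of the whole analysis.

Reads or generates a cohort, applies exclusions, computes burden panels and
outcome labels, runs the group comparisons and ROC analyses, and writes four
report tables (cohort characteristics, burdens by outcome, burdens by arm,
ROC results) plus a machine-readable JSON bundle.  All randomness flows from
the single top-level ``seed``; the JSON embeds the seed and a hash of the
config so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .burden_metrics import AnalysisConfig, BurdenPanel, burden_panel
from .outcomes import label_renal_impairment
from .stats_suite import StatsError, roc_table, route_and_compare
from .synthetic_cohort import ChannelParams, CohortSpec, generate_cohort
from .trace_model import PatientRecord, apply_exclusions, read_cohort, write_cohort

log = logging.getLogger("oxiburden")

CONFIG_VERSION = 1


@dataclass
class PipelineResult:
    output_dir: Path
    report: dict
    paths: dict[str, Path]


def _build_spec(synthetic: dict, seed: int) -> CohortSpec:
    synthetic = dict(synthetic or {})
    channel_fields = {}
    for ch in ("renal", "cerebral", "peripheral"):
        if ch in synthetic:
            default = getattr(CohortSpec(), ch)
            channel_fields[ch] = dataclasses.replace(default, **synthetic.pop(ch))
    return CohortSpec(seed=seed, **synthetic, **channel_fields)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _safe_compare(groups: dict[str, np.ndarray], kind: str, variable: str) -> dict:
    try:
        cmp = route_and_compare(groups, kind, variable=variable)
        return {
            "variable": variable,
            "test": cmp.test,
            "p_value": cmp.p_value,
            **{f"summary_{g}": s for g, s in cmp.summaries.items()},
        }
    except StatsError as exc:
        log.warning("comparison skipped for %s: %s", variable, exc)
        return {"variable": variable, "test": "skipped", "p_value": None, "note": str(exc)}


def _comparison_table(
    variables: dict[str, tuple[str, dict[str, np.ndarray]]]
) -> list[dict]:
    return [
        _safe_compare(groups, kind, name)
        for name, (kind, groups) in variables.items()
    ]


def _split(values: np.ndarray, mask: np.ndarray, names: tuple[str, str]) -> dict:
    return {names[0]: values[mask], names[1]: values[~mask]}


def run_pipeline(config: dict | str | Path) -> PipelineResult:
    """Run the full analysis described by a config mapping or YAML file."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if config.get("version", CONFIG_VERSION) != CONFIG_VERSION:
        raise ValueError(f"unsupported config version {config.get('version')}")
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("output_dir", "oxiburden_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis_cfg = AnalysisConfig(**config.get("analysis", {}))
    outcome_cfg = config.get("outcome", {})
    threshold_frac = float(outcome_cfg.get("threshold_frac", 0.10))
    window_days = int(outcome_cfg.get("window_days", 7))

    cohort_cfg = config.get("cohort", {}) or {}
    rejected_rows: list[dict] = []
    if "input_dir" in cohort_cfg:
        log.info("reading cohort from %s", cohort_cfg["input_dir"])
        read = read_cohort(cohort_cfg["input_dir"])
        records = read.records
        rejected_rows = [
            {"patient_id": r.patient_id, "stage": "validation", "reason": r.reason}
            for r in read.rejected
        ]
    else:
        spec = _build_spec(cohort_cfg.get("synthetic", {}), seed)
        log.info("generating synthetic cohort of n=%d (seed %d)", spec.n_patients, seed)
        records = generate_cohort(spec)
        if config.get("write_cohort", True):
            write_cohort(records, out_dir / "cohort")

    analysable, excluded = apply_exclusions(records)
    rejected_rows += [
        {"patient_id": rec.patient_id, "stage": "exclusion", "reason": reason}
        for rec, reason in excluded
    ]
    log.info("%d analysable, %d excluded", len(analysable), len(excluded))
    if len(analysable) < 4:
        raise ValueError("fewer than 4 analysable records; nothing to analyse")

    panels: list[BurdenPanel] = [burden_panel(r, analysis_cfg) for r in analysable]
    labels = [
        label_renal_impairment(
            r.creatinine, threshold_frac, window_days, patient_id=r.patient_id
        )
        for r in analysable
    ]
    impaired = np.array([l.impaired for l in labels])
    on_pump = np.array([r.arm == "on_pump" for r in analysable])

    burdens_df = pd.DataFrame(
        [row for p in panels for row in p.as_rows()]
    )
    outcomes_df = pd.DataFrame(
        [
            {
                "patient_id": l.patient_id,
                "impaired": l.impaired,
                "max_relative_rise": l.max_relative_rise,
                "day_of_max": l.day_of_max,
            }
            for l in labels
        ]
    )

    # predictor matrix: baselines, every burden, preoperative creatinine
    predictor_cols: dict[str, np.ndarray] = {}
    for ch in ("renal_mean", "cerebral", "peripheral"):
        vals = [
            p.baselines[ch].value if ch in p.baselines else np.nan for p in panels
        ]
        predictor_cols[f"{ch}_baseline"] = np.array(vals)
    burden_keys = sorted({k for p in panels for k in p.burdens})
    for key in burden_keys:
        predictor_cols[key] = np.array(
            [p.burdens[key].aut if key in p.burdens else np.nan for p in panels]
        )
    predictor_cols["preop_creatinine"] = np.array(
        [r.creatinine.baseline_value for r in analysable]
    )

    group_names_outcome = ("impaired", "not_impaired")
    group_names_arm = ("on_pump", "off_pump")

    # Table 1 analogue: demographics / intraoperative characteristics
    t1_vars: dict[str, tuple[str, dict]] = {}
    for cov, kind in (("age", "continuous"), ("duration_min", "continuous"), ("n_grafts", "continuous")):
        vals = np.array([r.covariates.get(cov, np.nan) for r in analysable])
        if np.isnan(vals).all():
            continue
        t1_vars[cov] = (kind, _split(vals, impaired, group_names_outcome))
    t1_vars["on_pump"] = (
        "categorical",
        _split(on_pump.astype(float), impaired, group_names_outcome),
    )
    t1_vars["preop_creatinine"] = (
        "continuous",
        _split(predictor_cols["preop_creatinine"], impaired, group_names_outcome),
    )
    table1 = _comparison_table(t1_vars)

    def _burden_comparisons(mask: np.ndarray, names: tuple[str, str]) -> list[dict]:
        rows = []
        for name, vals in predictor_cols.items():
            if name == "preop_creatinine":
                continue
            ok = ~np.isnan(vals)
            rows.append(
                _safe_compare(
                    {names[0]: vals[ok & mask], names[1]: vals[ok & ~mask]},
                    "continuous",
                    name,
                )
            )
        return rows

    table2 = _burden_comparisons(impaired, group_names_outcome)
    table3 = _burden_comparisons(on_pump, group_names_arm)

    # Table 4 analogue: ROC of every predictor vs renal impairment
    n_pos, n_neg = int(impaired.sum()), int((~impaired).sum())
    table4: list[dict] = []
    roc_skipped = None
    if n_pos >= 2 and n_neg >= 2:
        complete = {
            k: v for k, v in predictor_cols.items() if not np.isnan(v).any()
        }
        dropped = sorted(set(predictor_cols) - set(complete))
        if dropped:
            log.warning("ROC predictors with missing values dropped: %s", dropped)
        for s in roc_table(complete, impaired.astype(int)):
            table4.append(
                {
                    "predictor": s.predictor,
                    "auroc": s.auroc,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "p_value": s.p_value,
                    "optimal_cutoff": s.optimal_cutoff,
                    "sensitivity": s.sensitivity,
                    "specificity": s.specificity,
                    "degenerate": s.degenerate,
                }
            )
    else:
        roc_skipped = (
            f"ROC stage skipped: {n_pos} impaired / {n_neg} non-impaired "
            "(need at least 2 per class)"
        )
        log.warning(roc_skipped)

    n_tests = sum(
        1 for row in table1 + table2 + table3 if row.get("p_value") is not None
    ) + len(table4)

    report = {
        "config_version": CONFIG_VERSION,
        "seed": seed,
        "config_hash": _config_hash(config),
        "n_records": len(records),
        "n_analysable": len(analysable),
        "n_excluded": len(excluded),
        "n_impaired": n_pos,
        "n_not_impaired": n_neg,
        "renal_bilateral_spearman": {
            "mean": float(
                np.mean([p.renal_spearman for p in panels if p.renal_spearman is not None])
            )
            if any(p.renal_spearman is not None for p in panels)
            else None,
            "n_bilateral": sum(p.renal_spearman is not None for p in panels),
        },
        "table1_characteristics": table1,
        "table2_burden_by_outcome": table2,
        "table3_burden_by_arm": table3,
        "table4_roc": table4,
        "roc_skipped": roc_skipped,
        "n_statistical_tests": n_tests,
        "multiple_testing_correction": "none",
    }

    paths = {}
    for name, df in (
        ("burdens", burdens_df),
        ("outcomes", outcomes_df),
        ("exclusions", pd.DataFrame(rejected_rows, columns=["patient_id", "stage", "reason"])),
        ("table1_characteristics", pd.DataFrame(table1)),
        ("table2_burden_by_outcome", pd.DataFrame(table2)),
        ("table3_burden_by_arm", pd.DataFrame(table3)),
        ("table4_roc", pd.DataFrame(table4)),
    ):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    paths["report"] = report_path
    log.info("report written to %s", report_path)
    return PipelineResult(output_dir=out_dir, report=report, paths=paths)
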