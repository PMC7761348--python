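"""End-to-end orchestration and table rendering.

``run_pipeline`` wires the stages together: simulate a labelled cohort,
render one noisy phantom study per simulated patient, quantify every study
back to joint uptake ratios, and run the full statistics battery, writing
three CSV tables (group comparison per area; AUC comparison of the uptake
ratio against each reader's visual grading; diagnostic performance at the
Youden-optimal cutoff) plus a JSON manifest recording seeds, versions and
row counts.

Formatting follows the reporting conventions of the field's tables: ratios
to 2 decimals, AUC and p-values to 3, percentages to 1 (half away from
zero).  Areas where only one class is present are emitted with NA cells
rather than failing the run.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .diagstats import (
    DiagnosticPerformance,
    SingleClassError,
    auc_mann_whitney,
    bonferroni_threshold,
    ccc,
    compare_groups,
    delong_paired_test,
    exact_agreement,
    round_half_away,
    weighted_kappa,
    youden_optimal_cutoff,
)
from .joint_schema import AREAS
from .phantom import CohortSpec, PhantomSpec, render_phantom, simulate_cohort
from .quantify import quantify_study

logger = logging.getLogger("scintiquant")

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "quantify_simulated_cohort",
    "evaluate_cohort",
    "render_table1",
    "render_table2",
    "render_table3",
]

AREA_LABELS = {
    "shoulder": "Shoulder",
    "sternoclavicular": "Sternoclavicular",
    "elbow": "Elbow",
    "knee": "Knee",
    "sacroiliac": "Sacroiliac",
    "ankle": "Ankle",
    "tarsal": "Tarsal",
    "mtp": "MTP",
    "toe_ip": "Toe IP",
    "wrist": "Wrist",
    "thumb_ip": "Thumb IP",
    "mcp": "MCP",
    "hand_pip": "PIP",
    "hand_dip": "DIP",
}


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    seed: int = 0
    out_dir: str = "report"
    cohort: Optional[CohortSpec] = None
    score_col: str = "ratio_quantified"
    alpha: float = 0.05
    comparisons_per_area: int = 3  # ratio vs reader1, ratio vs reader2, reader1 vs reader2
    render_images: bool = True
    group_test: str = "mann-whitney"


# ---------------------------------------------------------------------------
# formatting helpers


def _fmt(x, nd) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{round_half_away(float(x), nd):.{nd}f}"


def _fmt_p(p) -> str:
    if p is None or (isinstance(p, float) and not np.isfinite(p)):
        return "NA"
    return "<0.001" if p < 0.001 else f"{round_half_away(p, 3):.3f}"


def _mean_sd(values) -> str:
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return "NA"
    return f"{_fmt(v.mean(), 2)} ± {_fmt(v.std(ddof=1) if len(v) > 1 else 0.0, 2)}"


def _metric_ci(m) -> str:
    if m.value is None:
        return "NA"
    return f"{_fmt(m.value, 1)} ({_fmt(m.ci_low, 1)}–{_fmt(m.ci_high, 1)})"


# ---------------------------------------------------------------------------
# image round-trip for a simulated cohort


def quantify_simulated_cohort(
    cohort: pd.DataFrame, seed: int, min_renderable_ratio: float = 0.05
) -> pd.DataFrame:
    """Render one noisy phantom study per simulated patient and quantify it.

    Adds a ``ratio_quantified`` column: the uptake ratio recovered from the
    Poisson-noisy images, the pipeline's end-to-end measured score.  True
    ratios below ``min_renderable_ratio`` are rendered at that floor (a
    hotspot cannot be darker than the soft-tissue background allows).
    """
    out = cohort.copy()
    out["ratio_quantified"] = np.nan
    for k, (pid, grp) in enumerate(out.groupby("patient_id", sort=True)):
        targets = {
            r.joint_id: max(float(r.true_ratio), min_renderable_ratio)
            for r in grp.itertuples(index=False)
            if not r.excluded
        }
        exclusions = frozenset(grp.loc[grp["excluded"], "joint_id"])
        spec = PhantomSpec(
            patient_id=str(pid),
            target_ratios=targets,
            poisson_noise=True,
            seed=seed + k,
            exclusions=exclusions,
        )
        study = render_phantom(spec)
        measured = {
            m.joint_id: m.ratio
            for m in quantify_study(study.bundle, study.rois)
            if m.status == "measured"
        }
        idx = grp.index
        out.loc[idx, "ratio_quantified"] = [
            measured.get(j, np.nan) for j in grp["joint_id"]
        ]
    return out


# ---------------------------------------------------------------------------
# statistics over a cohort table


def _included(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort.loc[~cohort["excluded"]]


def evaluate_cohort(
    cohort: pd.DataFrame,
    score_col: str = "ratio_reader1",
    alpha: float = 0.05,
    comparisons_per_area: int = 3,
    group_test: str = "mann-whitney",
) -> dict:
    """Run the full statistics battery on a per-joint cohort table.

    Returns a nested dict: reader agreement (weighted kappa, exact agreement,
    CCC of the two readers' ratios), per-area and total group comparisons,
    AUC comparisons of the score against each reader's grades (DeLong), and
    diagnostic performance at the Youden-optimal cutoff.
    """
    for col in ("area", "excluded", "affected", score_col):
        if col not in cohort.columns:
            raise PipelineError(f"cohort table is missing required column {col!r}")
    df = _included(cohort)
    df = df.loc[df[score_col].notna()]

    g1 = df["grade_reader1"].astype(int).to_numpy()
    g2 = df["grade_reader2"].astype(int).to_numpy()
    agreement = {
        "weighted_kappa": weighted_kappa(g1, g2, weights="linear"),
        "exact_agreement_pct": exact_agreement(g1, g2),
        "ccc_ratio": ccc(df["ratio_reader1"].to_numpy(), df["ratio_reader2"].to_numpy()),
        "n": int(len(df)),
    }

    per_area: dict[str, dict] = {}
    for name in [a.name for a in AREAS] + ["Total"]:
        sub = df if name == "Total" else df.loc[df["area"] == name]
        per_area[name] = _evaluate_block(sub, score_col, alpha, group_test)

    threshold = bonferroni_threshold(alpha, comparisons_per_area)
    return {
        "agreement": agreement,
        "per_area": per_area,
        "bonferroni_threshold": threshold,
        "score_col": score_col,
    }


def _evaluate_block(sub: pd.DataFrame, score_col: str, alpha: float, group_test: str) -> dict:
    labels = sub["affected"].astype(bool).to_numpy()
    scores = sub[score_col].to_numpy(dtype=float)
    block: dict = {
        "n": int(len(sub)),
        "n_affected": int(labels.sum()),
        "n_nonaffected": int((~labels).sum()),
        "ratio_affected": scores[labels],
        "ratio_nonaffected": scores[~labels],
    }
    try:
        block["p_group"] = compare_groups(scores[labels], scores[~labels], method=group_test)
    except (SingleClassError, ValueError):
        block["p_group"] = None
    try:
        block["roc_ratio"] = auc_mann_whitney(scores, labels, alpha)
        block["youden"] = youden_optimal_cutoff(scores, labels, alpha)
        for r in (1, 2):
            grades = sub[f"grade_reader{r}"].to_numpy(dtype=float)
            block[f"roc_reader{r}"] = auc_mann_whitney(grades, labels, alpha)
            delta, z, p = delong_paired_test(scores, grades, labels)
            block[f"p_vs_reader{r}"] = p
            block[f"delta_auc_reader{r}"] = delta
    except SingleClassError:
        block["roc_ratio"] = None
        block["youden"] = None
        for r in (1, 2):
            block[f"roc_reader{r}"] = None
            block[f"p_vs_reader{r}"] = None
            block[f"delta_auc_reader{r}"] = None
    return block


# ---------------------------------------------------------------------------
# table rendering


def _rows_to_csv(rows: list[dict], columns: list[str]) -> str:
    return pd.DataFrame(rows, columns=columns).to_csv(index=False)


def render_table1(results: dict) -> str:
    """Group sizes and uptake ratios of affected vs nonaffected joints per area."""
    rows = []
    for name, block in results["per_area"].items():
        label = AREA_LABELS.get(name, name)
        n = block["n"]
        na, nn = block["n_affected"], block["n_nonaffected"]
        rows.append(
            {
                "joint": label,
                "n": n,
                "uptake_ratio": _mean_sd(np.concatenate([block["ratio_affected"], block["ratio_nonaffected"]])) if n else "NA",
                "affected_n_pct": f"{na} ({_fmt(100.0 * na / n, 1)}%)" if n else "NA",
                "affected_ratio": _mean_sd(block["ratio_affected"]) if na else "NA",
                "nonaffected_n_pct": f"{nn} ({_fmt(100.0 * nn / n, 1)}%)" if n else "NA",
                "nonaffected_ratio": _mean_sd(block["ratio_nonaffected"]) if nn else "NA",
                "p_value": _fmt_p(block["p_group"]),
            }
        )
    return _rows_to_csv(
        rows,
        [
            "joint",
            "n",
            "uptake_ratio",
            "affected_n_pct",
            "affected_ratio",
            "nonaffected_n_pct",
            "nonaffected_ratio",
            "p_value",
        ],
    )


def _roc_ci(roc) -> str:
    if roc is None:
        return "NA"
    return f"{_fmt(roc.auc, 3)} ({_fmt(roc.ci_low, 3)}–{_fmt(roc.ci_high, 3)})"


def render_table2(results: dict) -> str:
    """AUC of the uptake ratio vs each reader's visual grading, DeLong p."""
    rows = []
    for name, block in results["per_area"].items():
        rows.append(
            {
                "joint": AREA_LABELS.get(name, name),
                "auc_uptake_ratio": _roc_ci(block["roc_ratio"]),
                "auc_reader1": _roc_ci(block["roc_reader1"]),
                "p_vs_reader1": _fmt_p(block["p_vs_reader1"]),
                "auc_reader2": _roc_ci(block["roc_reader2"]),
                "p_vs_reader2": _fmt_p(block["p_vs_reader2"]),
            }
        )
    return _rows_to_csv(
        rows,
        [
            "joint",
            "auc_uptake_ratio",
            "auc_reader1",
            "p_vs_reader1",
            "auc_reader2",
            "p_vs_reader2",
        ],
    )


def render_table3(results: dict) -> str:
    """Diagnostic performance of the uptake ratio at the Youden cutoff."""
    rows = []
    for name, block in results["per_area"].items():
        perf: Optional[DiagnosticPerformance] = block["youden"]
        if perf is None:
            rows.append(
                {
                    "joint": AREA_LABELS.get(name, name),
                    "cutoff": "NA",
                    "sensitivity_pct": "NA",
                    "specificity_pct": "NA",
                    "ppv_pct": "NA",
                    "npv_pct": "NA",
                    "accuracy_pct": "NA",
                }
            )
            continue
        rows.append(
            {
                "joint": AREA_LABELS.get(name, name),
                "cutoff": _fmt(perf.cutoff, 2),
                "sensitivity_pct": _metric_ci(perf.sensitivity),
                "specificity_pct": _metric_ci(perf.specificity),
                "ppv_pct": _metric_ci(perf.ppv),
                "npv_pct": _metric_ci(perf.npv),
                "accuracy_pct": _fmt(perf.accuracy.value, 1),
            }
        )
    return _rows_to_csv(
        rows,
        [
            "joint",
            "cutoff",
            "sensitivity_pct",
            "specificity_pct",
            "ppv_pct",
            "npv_pct",
            "accuracy_pct",
        ],
    )


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: RunConfig) -> str:
    """Simulate, quantify and evaluate one cohort; write tables + manifest.

    Deterministic under a fixed config: identical seeds give byte-identical
    tables.  Returns the output directory path.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    spec = config.cohort if config.cohort is not None else CohortSpec(seed=config.seed)
    logger.info("simulating cohort: %d patients, seed %d", spec.n_patients, spec.seed)
    cohort = simulate_cohort(spec)

    score_col = config.score_col
    if config.render_images:
        logger.info("rendering and quantifying %d phantom studies", spec.n_patients)
        cohort = quantify_simulated_cohort(cohort, seed=config.seed + 10_000)
    elif score_col == "ratio_quantified":
        score_col = "ratio_reader1"

    cohort_path = os.path.join(config.out_dir, "cohort.csv")
    cohort.to_csv(cohort_path, index=False)

    logger.info("evaluating cohort (score column %r)", score_col)
    results = evaluate_cohort(
        cohort,
        score_col=score_col,
        alpha=config.alpha,
        comparisons_per_area=config.comparisons_per_area,
        group_test=config.group_test,
    )

    tables = {
        "table1_group_comparison.csv": render_table1(results),
        "table2_auc_comparison.csv": render_table2(results),
        "table3_diagnostic_performance.csv": render_table3(results),
    }
    for fname, text in tables.items():
        with open(os.path.join(config.out_dir, fname), "w", encoding="utf-8") as fh:
            fh.write(text)

    n_total = len(cohort)
    n_excluded = int(cohort["excluded"].sum())
    manifest = {
        "tool": "scintiquant",
        "version": __version__,
        "seed": config.seed,
        "cohort_seed": spec.seed,
        "n_patients": spec.n_patients,
        "score_col": score_col,
        "alpha": config.alpha,
        "bonferroni_threshold": results["bonferroni_threshold"],
        "rows": {
            "joints_total": n_total,
            "joints_excluded": n_excluded,
            "joints_measured": n_total - n_excluded,
        },
        "agreement": {
            "weighted_kappa": results["agreement"]["weighted_kappa"].statistic,
            "exact_agreement_pct": results["agreement"]["exact_agreement_pct"],
            "ccc_ratio": results["agreement"]["ccc_ratio"].statistic,
        },
        "outputs": sorted(tables) + ["cohort.csv"],
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("report written to %s", config.out_dir)
    return config.out_dir
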