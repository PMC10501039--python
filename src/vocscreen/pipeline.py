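"""Pipeline orchestration and report rendering.

``run_all`` executes the full analysis — simulate (or load) the peak and
cohort tables, extract differential VOCs, fit the quadratic discriminant
on the significant panel, evaluate single-marker and combined-index ROC
curves, and correlate indices with the cohort scores — persisting
intermediate artifacts and a JSON + text report.  Reports are
deterministic functions of the config and seed (no timestamps), so
re-running a config reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, calibration as cal
from .diff_extraction import BiomarkerSet, FilterCriteria, extract_differential
from .discriminant import evaluate_training, expand_polynomial, fit_qda
from .exceptions import ConfigError, VocscreenError
from .peak_model import (
    CohortTable,
    group_summary,
    read_cohort_table,
    read_peak_table,
    write_cohort_table,
    write_peak_table,
)
from .screening_index import combined_index, correlate_index, roc
from .synthetic_data import default_calibration, generate

logger = logging.getLogger("vocscreen")

__all__ = ["PipelineConfig", "RunReport", "run_all", "load_config"]

# cohort scores each combined index is correlated against
INDEX_SCORE_MAP = {
    "two_voc": ("kihon_cl", "dskc_self"),
    "three_voc": ("dskc_self", "sds", "grid_hamd"),
}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 2015
    simulate: bool = True
    peak_table_path: str | None = None
    cohort_table_path: str | None = None
    out_dir: str = "vocscreen_out"
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    features: tuple[str, ...] | None = None  # None -> significant set
    two_voc_members: tuple[str, ...] = cal.COMBINED_TWO
    three_voc_members: tuple[str, ...] = cal.COMBINED_THREE
    strict_members: bool = True  # members must be combination-eligible
    exclude_subjects_for_hamd: tuple[str, ...] = ()
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate and (self.peak_table_path or self.cohort_table_path):
            raise ConfigError("choose either simulate or input paths, not both")
        if not self.simulate and not (self.peak_table_path and self.cohort_table_path):
            raise ConfigError("need peak and cohort table paths when not simulating")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML key-value file."""
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh) or {}
    crit_kwargs = raw.pop("criteria", {}) or {}
    criteria = FilterCriteria(**crit_kwargs)
    for key in ("features", "two_voc_members", "three_voc_members",
                "exclude_subjects_for_hamd"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(criteria=criteria, **raw)


@dataclass
class RunReport:
    config_hash: str
    version: str
    cohort_summary: list[dict]
    differential_table: pd.DataFrame
    coefficients: dict
    discriminant: dict
    auc_table: list[dict]
    correlations: list[dict]
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "cohort_summary": self.cohort_summary,
            "differential_table": self.differential_table.to_dict(orient="records"),
            "coefficients": self.coefficients,
            "discriminant": self.discriminant,
            "auc_table": self.auc_table,
            "correlations": self.correlations,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)


def _fmt_p(p: float) -> str:
    return "< 0.0001" if p < 0.0001 else f"{p:.4f}"


def _fmt_area(a: float) -> str:
    return f"{a:,.0f}"


def differential_frame(biomarkers: BiomarkerSet) -> pd.DataFrame:
    """Machine-readable differential table (full precision, one row per
    nominated VOC)."""
    rows = []
    for d in biomarkers.nominated:
        s = d.summary
        rows.append(
            {
                "voc_id": d.voc_id,
                "name": d.species.name,
                "retention_time_min": d.species.retention_time,
                "quantifier_mz": d.quantifier_mz,
                "mean_control": s.mean_control,
                "sem_control": s.sem_control,
                "mean_positive": s.mean_positive,
                "sem_positive": s.sem_positive,
                "fold": s.fold,
                "p_two_tailed": s.p_two_tailed,
                "p_one_tailed": s.p_one_tailed,
                "filters_passed": "+".join(sorted(d.passed_filters)),
                "significant": d.significant,
            }
        )
    return pd.DataFrame(rows)


def cohort_summary_rows(cohort: CohortTable) -> list[dict]:
    rows = []
    for row in cal.COHORT_CALIBRATION:
        var = row.variable
        pos = cohort.scores(var, "positive").dropna().to_numpy(dtype=float)
        ctrl = cohort.scores(var, "control").dropna().to_numpy(dtype=float)
        if ctrl.size == 0:  # e.g. clinician-rated score, cases only
            rows.append(
                {
                    "variable": var,
                    "mean_positive": float(pos.mean()),
                    "mean_control": None,
                    "fold": None,
                    "p_two_tailed": None,
                }
            )
            continue
        summ = group_summary({"control": ctrl, "positive": pos}, var)
        d = summ.as_dict()
        rows.append(d)
    return rows


def run_all(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and persist artifacts under
    ``config.out_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hash_src = replace(config, out_dir="", log_level="")
    cfg_hash = hashlib.sha256(repr(hash_src).encode()).hexdigest()[:16]
    warnings_log: list[str] = []

    # --- stage: data ----------------------------------------------------
    try:
        if config.simulate:
            gen = default_calibration(seed=config.seed)
            table, cohort = generate(gen)
        else:
            table = read_peak_table(config.peak_table_path)
            cohort = read_cohort_table(config.cohort_table_path)
    except VocscreenError as exc:
        raise VocscreenError(f"stage 'data': {exc}") from exc
    logger.info("stage=data subjects=%d species=%d", len(table.subject_ids), len(table.species))
    write_peak_table(table, out / "peak_table.tsv")
    write_cohort_table(cohort, out / "cohort_table.csv")

    # --- stage: extract -------------------------------------------------
    try:
        biomarkers = extract_differential(table, config.criteria)
    except VocscreenError as exc:
        raise VocscreenError(f"stage 'extract': {exc}") from exc
    diff_df = differential_frame(biomarkers)
    diff_df.to_csv(out / "differential_vocs.tsv", sep="\t", index=False)
    logger.info(
        "stage=extract nominated=%d significant=%d",
        len(biomarkers.nominated),
        len(biomarkers.significant),
    )

    # --- stage: discriminate -------------------------------------------
    features = config.features or biomarkers.ids("significant")
    coefficients: dict = {}
    discr: dict = {}
    if features:
        try:
            model = fit_qda(table, features)
            coeffs = expand_polynomial(model)
            report = evaluate_training(model, table)
        except VocscreenError as exc:
            raise VocscreenError(f"stage 'discriminate': {exc}") from exc
        coefficients = {
            "feature_ids": list(coeffs.feature_ids),
            "a0": coeffs.a0,
            "a": list(map(float, coeffs.a)),
            "C": [list(map(float, row)) for row in coeffs.C],
        }
        discr = report.as_dict()
        (out / "discriminant.json").write_text(
            json.dumps({"coefficients": coefficients, "report": discr}, indent=2)
        )
        logger.info(
            "stage=discriminate features=%d prob_pos=%.1f prob_ctrl=%.1f",
            len(features),
            report.probability_positive,
            report.probability_control,
        )
    else:
        warnings_log.append("no significant biomarkers; discriminant stage skipped")

    # --- stage: roc -----------------------------------------------------
    labels = list(table.subjects["group"])
    auc_rows = []
    for d in biomarkers.significant:
        r = roc(table.quantifier_areas(d.voc_id).to_numpy(), labels)
        auc_rows.append({"marker": d.voc_id, "kind": "single", "auc": r.auc,
                         "orientation_flipped": r.orientation_flipped})
    eligible = set(biomarkers.ids("combination_eligible"))
    indices: dict[str, Any] = {}
    for name, members in (
        ("three_voc", config.three_voc_members),
        ("two_voc", config.two_voc_members),
    ):
        if not members:
            warnings_log.append(f"empty member list for {name}; skipped")
            continue
        if config.strict_members and not set(members) <= eligible:
            warnings_log.append(
                f"{name} members {sorted(set(members) - eligible)} not "
                "combination-eligible; index skipped"
            )
            continue
        idx = combined_index(table, members)
        indices[name] = idx
        r = roc(idx.values.to_numpy(), labels)
        auc_rows.append({"marker": "+".join(members), "kind": name, "auc": r.auc,
                         "orientation_flipped": r.orientation_flipped})
    pd.DataFrame(auc_rows).to_csv(out / "auc_table.tsv", sep="\t", index=False)
    logger.info("stage=roc curves=%d", len(auc_rows))

    # --- stage: correlate ----------------------------------------------
    corr_rows = []
    for name, idx in indices.items():
        for score_name in INDEX_SCORE_MAP.get(name, ()):
            exclude = (
                config.exclude_subjects_for_hamd if score_name == "grid_hamd" else ()
            )
            try:
                res = correlate_index(idx, cohort, score_name, exclude_subjects=exclude)
            except VocscreenError as exc:
                warnings_log.append(f"correlate {name} vs {score_name}: {exc}")
                continue
            corr_rows.append(
                {
                    "index": name,
                    "score": score_name,
                    "n": res["n"],
                    "pearson_r": res["pearson"].r,
                    "pearson_p": res["pearson"].p_value,
                    "strength": res["pearson"].strength,
                    "spearman_r": res["spearman"].r,
                    "quadratic": res["quadratic"].as_dict(),
                    "cubic": res["cubic"].as_dict(),
                    "quadratic_formula": res["quadratic"].formula(),
                    "cubic_formula": res["cubic"].formula(),
                }
            )
    logger.info("stage=correlate pairs=%d", len(corr_rows))

    report = RunReport(
        config_hash=cfg_hash,
        version=__version__,
        cohort_summary=cohort_summary_rows(cohort),
        differential_table=diff_df,
        coefficients=coefficients,
        discriminant=discr,
        auc_table=auc_rows,
        correlations=corr_rows,
        warnings=warnings_log,
    )
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(render_text_report(report))
    return report


def render_text_report(report: RunReport) -> str:
    """Human-readable rendering: thousands-separated areas, 4-decimal
    p-values with '< 0.0001' below threshold, folds at 2 d.p."""
    lines = [f"vocscreen {report.version}  (config {report.config_hash})", ""]
    lines.append("Cohort summary")
    for row in report.cohort_summary:
        if row.get("mean_control") is None:
            lines.append(f"  {row['variable']:<20} positive mean {row['mean_positive']:.3f} (controls n.d.)")
            continue
        lines.append(
            f"  {row['variable']:<20} control {row['mean_control']:.3f} "
            f"positive {row['mean_positive']:.3f} fold {row['fold']:.2f} "
            f"p {_fmt_p(row['p_two_tailed'])}"
        )
    lines.append("")
    lines.append("Differential VOCs (quantifier-ion areas)")
    for _, r in report.differential_table.iterrows():
        star = " *" if r["significant"] else ""
        lines.append(
            f"  {r['voc_id']:<22} m/z {int(r['quantifier_mz']):>3} "
            f"control {_fmt_area(r['mean_control']):>12} "
            f"positive {_fmt_area(r['mean_positive']):>12} "
            f"fold {r['fold']:.2f} p(two) {_fmt_p(r['p_two_tailed'])} "
            f"p(one) {_fmt_p(r['p_one_tailed'])}{star}"
        )
    if report.coefficients:
        lines.append("")
        lines.append("Quadratic discriminant")
        lines.append(f"  features: {', '.join(report.coefficients['feature_ids'])}")
        lines.append(f"  a0 = {report.coefficients['a0']:.4g}")
        prob = report.discriminant["discriminant_probability_percent"]
        err = report.discriminant["error_percent"]
        lines.append(
            f"  discriminant probability: positive {prob['positive']:.3f}% "
            f"control {prob['control']:.3f}%  error {err['positive']:.3f}%/"
            f"{err['control']:.3f}%"
        )
        lines.append(f"  Box's M p = {_fmt_p(report.discriminant['box_m']['p_value'])}")
    lines.append("")
    lines.append("ROC")
    for row in report.auc_table:
        lines.append(f"  {row['marker']:<40} AUC {row['auc']:.4f}")
    if report.correlations:
        lines.append("")
        lines.append("Index-score correlations")
        for row in report.correlations:
            lines.append(
                f"  {row['index']} vs {row['score']:<12} r = {row['pearson_r']:.3f} "
                f"({row['strength']}) p {_fmt_p(row['pearson_p'])} n={row['n']}"
            )
            lines.append(f"    quadratic: {row['quadratic_formula']}")
            lines.append(f"    cubic:     {row['cubic_formula']}")
    if report.warnings:
        lines.append("")
        lines.append("Warnings")
        lines += [f"  - {w}" for w in report.warnings]
    lines.append("")
    return "\n".join(lines)
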