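"""File I/O, run configuration and end-to-end pipeline orchestration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import regimen_crosstab, summarize_groups, two_way_anova_tukey
from .model import CensoredTrajectoryMixture
from .selection import Thresholds, TrajectoryGroupSelector
from .simulate import StudyDesign, GeneratingModel, default_design, default_generating_model, generate_cohort

logger = logging.getLogger("gbtm")

__all__ = ["RunConfig", "read_long_csv", "write_long_csv", "run_pipeline", "config_hash"]

REQUIRED_COLUMNS = ("subject_id", "day", "value")


def read_long_csv(path) -> pd.DataFrame:
    """Read a long-format measurement table (subject_id, day, value, ...).

    Days are parsed as integers and values as floats, with row-numbered
    errors on unparseable entries; extra columns (latent_group, regimen,
    channel labels) are carried through untouched and never consumed by
    estimation.
    """
    table = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    for col, caster in (("day", "integer"), ("value", "float")):
        parsed = pd.to_numeric(table[col], errors="coerce")
        bad = parsed.isna() & table[col].notna()
        if bad.any() or table[col].isna().any():
            row = int(np.argmax((bad | table[col].isna()).to_numpy()))
            raise ValueError(f"{path}: non-numeric '{col}' at data row {row + 1}")
        table[col] = parsed.astype(int) if caster == "integer" else parsed.astype(float)
    return table


def write_long_csv(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run; round-trips losslessly via YAML."""

    input_csv: str | None = None      # if None, a cohort is simulated
    seed: int = 0
    k_min: int = 1
    k_max: int = 4
    order: int = 2
    lower_bound: float = 0.0
    n_starts: int = 8
    bin_width: int = 5
    alpha: float = 0.05
    membership_min: float = 0.10
    pvalue_max: float = 0.1
    bpp_min: float = 0.95
    delta_bic: float = 10.0
    out_dir: str = "gbtm_run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _float_fmt(x):
    return "%.10g" % x if isinstance(x, float) else x


def _write_tsv(frame: pd.DataFrame, path: Path, index=False):
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Simulate or load a cohort, select the group number, fit, classify and
    compare groups; write every stage table plus a provenance log.

    Returns the artifact paths keyed by stage. Deterministic given the
    config (seed included), so two identical configs give identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    chash = config_hash(config)
    provenance = {"seed": config.seed, "config_hash": chash}

    stage = "load"
    try:
        if config.input_csv:
            data = read_long_csv(config.input_csv)
        else:
            stage = "simulate"
            data = generate_cohort(default_design(seed=config.seed), default_generating_model())
            path = out / "cohort.csv"
            write_long_csv(data, path)
            artifacts["cohort"] = path
        logger.info("%s: %d rows, %d subjects", stage, len(data), data["subject_id"].nunique())

        stage = "scan"
        selector = TrajectoryGroupSelector(
            k_min=config.k_min, k_max=config.k_max, order=config.order,
            membership_min=config.membership_min, pvalue_max=config.pvalue_max,
            bpp_min=config.bpp_min, delta_bic=config.delta_bic,
            n_starts=config.n_starts, random_state=config.seed)
        selector.fit(data)
        report = selector.report_
        scan_frame = report.to_frame()
        _write_tsv(scan_frame, out / "selection.tsv")
        (out / "selection.json").write_text(json.dumps({
            **provenance,
            "selected_k": report.selected_k,
            "delta_bic_vs_k1": report.delta_bic_vs_k1,
            "homogeneity_rejected": report.homogeneity_rejected,
            "warnings": report.warnings,
            "candidates": scan_frame.to_dict(orient="records"),
        }, indent=2))
        artifacts["selection"] = out / "selection.json"
        logger.info("scan: selected k=%d (delta BIC vs k=1: %s)",
                    report.selected_k, report.delta_bic_vs_k1)

        stage = "fit"
        best: CensoredTrajectoryMixture = selector.best_estimator_
        result = best.result_
        _write_tsv(best.params_table_, out / "estimates.tsv")
        (out / "fit_report.json").write_text(json.dumps({
            **provenance,
            "k": result.spec.k,
            "orders": list(result.spec.orders),
            "loglik": result.loglik,
            "bic_obs": result.bic_obs,
            "bic_subj": result.bic_subj,
            "aic": result.aic,
            "n_obs": result.n_obs,
            "n_subjects": result.n_subjects,
            "n_params": result.n_params,
            "sigma": result.params.sigma,
            "membership_pct": [100 * w for w in result.params.pi],
            "coefficients": [list(b) for b in result.params.beta],
            "converged": result.converged,
            "n_iter": result.n_iter,
            "n_starts_used": result.n_starts_used,
        }, indent=2))
        artifacts["fit"] = out / "fit_report.json"

        stage = "classify"
        probs = best.predict_proba(data)
        assignments = best.predict(data)
        posterior_table = probs.copy()
        posterior_table["assignment"] = assignments
        _write_tsv(posterior_table, out / "posteriors.tsv", index=True)
        artifacts["posteriors"] = out / "posteriors.tsv"

        stage = "compare"
        summary = summarize_groups(data, assignments, bin_width=config.bin_width)
        _write_tsv(summary, out / "binned_summary.tsv")
        artifacts["summary"] = out / "binned_summary.tsv"
        if best.spec_.k >= 2:
            comparison = two_way_anova_tukey(data, assignments,
                                             bin_width=config.bin_width, alpha=config.alpha)
            _write_tsv(comparison.anova, out / "anova.tsv")
            _write_tsv(comparison.tukey, out / "tukey.tsv")
            if best.spec_.k >= 3:
                _write_tsv(comparison.phases, out / "phases.tsv")
            artifacts["comparison"] = out / "anova.tsv"
        if "regimen" in data.columns:
            regimens = data.groupby("subject_id")["regimen"].first()
            crosstab = regimen_crosstab(assignments, regimens)
            _write_tsv(crosstab, out / "regimen_crosstab.tsv", index=True)
            artifacts["crosstab"] = out / "regimen_crosstab.tsv"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps({
        **provenance,
        "config": asdict(config),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }, indent=2))
    artifacts["run_log"] = out / "run_log.json"
    return artifacts
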