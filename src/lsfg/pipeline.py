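"""End-to-end orchestration: simulate a cohort, analyse it, write report tables.

:func:`run_pipeline` reproduces the study's Results structure on synthetic
data: a cohort table, a per-index repeatability table (COV/ICC per condition),
association tables (each index vs age and vs pulse pressure amplitude, using
the per-subject mean of the dilated scans), paired condition comparisons, sex
comparisons, and the scan success-rate chi-square.  All randomness flows from
the single top-level seed; a run log records the seed, the configuration hash
and every configuration-controlled analysis choice actually used.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as st
from .config import PipelineConfig
from .io import write_cohort_csv
from .synthetic import simulate_cohort

__all__ = [
    "INDEX_COLUMNS",
    "run_pipeline",
    "repeatability_table",
    "association_table",
    "paired_table",
    "sex_table",
    "success_table",
    "subject_means",
    "write_report",
]

# the 11 reported indices, in study order
INDEX_COLUMNS = ["MA", "MV", "MT", "BOT", "BOS", "Skew", "ATI", "RR", "FR", "FAI", "RI"]


def complete_matrix(cohort: pd.DataFrame, index: str, condition: str) -> np.ndarray:
    """Subjects × repeats matrix for one index, complete cases only."""
    sub = cohort[(cohort["condition"] == condition) & cohort["scan_success"]]
    wide = sub.pivot(index="subject_id", columns="repeat", values=index).dropna()
    return wide.to_numpy(dtype=float)


def subject_means(cohort: pd.DataFrame, condition: str = "dilated") -> pd.DataFrame:
    """Per-subject mean of successful scans in one condition, plus covariates.

    Mirrors the study convention of averaging the repeated dilated scans
    before any age/sex analysis.  PPA is computed on demand from SBP/DBP.
    """
    ok = cohort[(cohort["condition"] == condition) & cohort["scan_success"]]
    means = ok.groupby("subject_id")[INDEX_COLUMNS].mean()
    covars = cohort.groupby("subject_id")[["age", "sbp", "dbp", "hr", "iop"]].first()
    sex = cohort.groupby("subject_id")["sex"].first()
    out = means.join(covars).join(sex)
    out["ppa"] = out["sbp"] - out["dbp"]
    return out.reset_index()


def repeatability_table(cohort: pd.DataFrame, icc_form: str = "icc3") -> pd.DataFrame:
    """COV (%) and ICC per index per condition (complete cases)."""
    rows = []
    for condition in ("undilated", "dilated"):
        for index in INDEX_COLUMNS:
            m = complete_matrix(cohort, index, condition)
            res = st.intraclass_correlation(m, form=icc_form, index_name=index)
            rows.append({
                "condition": condition,
                "index": index,
                "cov_percent": round(res.cov, 1),
                "icc": round(res.icc, 3),
                "n_subjects": res.n_subjects,
                "n_repeats": res.n_repeats,
            })
    return pd.DataFrame(rows)


def association_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and p of each index vs age and vs PPA (dilated-scan means)."""
    means = subject_means(cohort, "dilated")
    rows = []
    for covariate in ("age", "ppa"):
        for index in INDEX_COLUMNS:
            res = st.association(means[covariate].to_numpy(),
                                 means[index].to_numpy())
            rows.append({
                "covariate": covariate,
                "index": index,
                "r": round(res.r, 3),
                "p": res.p,
                "slope": res.slope,
                "intercept": res.intercept,
                "n": res.n,
            })
    return pd.DataFrame(rows)


def paired_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test per index: undilated vs dilated per-subject means."""
    before = subject_means(cohort, "undilated").set_index("subject_id")
    after = subject_means(cohort, "dilated").set_index("subject_id")
    common = before.index.intersection(after.index)
    rows = []
    for index in INDEX_COLUMNS:
        a = before.loc[common, index].to_numpy()
        b = after.loc[common, index].to_numpy()
        res = st.paired_comparison(a, b)
        rows.append({
            "index": index,
            "mean_before": round(res.mean_a, 2),
            "mean_after": round(res.mean_b, 2),
            "mean_difference": round(res.mean_difference, 3),
            "t": res.t,
            "p": res.p,
            "n": len(common),
        })
    return pd.DataFrame(rows)


def sex_table(cohort: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Independent t-test per index: male vs female (dilated-scan means)."""
    means = subject_means(cohort, "dilated")
    male = means[means["sex"] == "male"]
    female = means[means["sex"] == "female"]
    rows = []
    for index in INDEX_COLUMNS:
        res = st.group_comparison(male[index].to_numpy(),
                                  female[index].to_numpy(), welch=welch)
        rows.append({
            "index": index,
            "mean_male": round(res.mean_a, 2),
            "mean_female": round(res.mean_b, 2),
            "t": res.t,
            "p": res.p,
        })
    return pd.DataFrame(rows)


def success_table(cohort: pd.DataFrame, yates: bool = False) -> pd.DataFrame:
    """Scan success rates per condition and the 2×2 chi-square between them."""
    und = cohort[cohort["condition"] == "undilated"]
    dil = cohort[cohort["condition"] == "dilated"]
    res = st.success_rate_test(int(und["scan_success"].sum()), len(und),
                               int(dil["scan_success"].sum()), len(dil),
                               yates=yates)
    return pd.DataFrame([{
        "success_undilated": int(und["scan_success"].sum()),
        "total_undilated": len(und),
        "rate_undilated_percent": res.rate_a,
        "success_dilated": int(dil["scan_success"].sum()),
        "total_dilated": len(dil),
        "rate_dilated_percent": res.rate_b,
        "chi2": res.chi2,
        "p": res.p,
    }])


def run_pipeline(
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> dict[str, pd.DataFrame]:
    """Simulate → analyse → report.  Deterministic given the config seed.

    Returns the report tables; when ``out_dir`` is given they are also
    written as CSV together with the cohort table and a JSON run log.
    """
    cfg = config or PipelineConfig()
    cohort = simulate_cohort(cfg.n_per_cell, cfg.repeats, cfg.seed,
                             cfg.generator, cfg.waveform)
    tables = {
        "cohort": cohort,
        "repeatability": repeatability_table(cohort, cfg.stats.icc_form),
        "association": association_table(cohort),
        "condition_comparison": paired_table(cohort),
        "sex_comparison": sex_table(cohort, cfg.stats.welch),
        "success_rate": success_table(cohort, cfg.stats.yates),
    }
    if out_dir is not None:
        write_report(tables, out_dir, cfg)
    return tables


def write_report(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: Optional[PipelineConfig] = None,
) -> list[Path]:
    """Write every table as CSV plus a run log with seed and config hash."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out / f"{name}.csv"
        if name == "cohort":
            write_cohort_csv(table, path)
        else:
            table.to_csv(path, index=False, encoding="utf-8")
        written.append(path)
    if config is not None:
        log = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_per_cell": config.n_per_cell,
            "repeats": config.repeats,
            "choices": {
                "bot_level": config.waveform.bot_level,
                "skew_scale": config.waveform.skew_scale,
                "n_phase_bins": config.waveform.n_phase_bins,
                "icc_form": config.stats.icc_form,
                "yates": config.stats.yates,
                "welch": config.stats.welch,
                "map_formula": config.stats.map_formula,
            },
        }
        log_path = out / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2), encoding="utf-8")
        written.append(log_path)
    return written
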