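"""Readers, validation and the end-to-end analysis pipeline.

CSV dialect throughout: UTF-8, comma-separated, ``.`` decimal, header row
mandatory.  Times are months since symptom onset; date-based inputs
(``assessment_date`` plus a per-patient ``onset_date``) are converted at
1 month = 365.25 / 12 days.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as _model
from . import munix as _munix
from . import stats as _stats
from .exceptions import SchemaError
from .model import (FULL_SCORE, classify_aggressiveness, classify_phase,
                    compute_rd50)

__all__ = [
    "DAYS_PER_MONTH",
    "PipelineConfig",
    "read_alsfrs",
    "read_munix",
    "read_patients",
    "run_pipeline",
]

DAYS_PER_MONTH = 365.25 / 12.0

_ALSFRS_COLS = ("patient_id", "months_since_onset", "alsfrs_r_total")
_MUNIX_COLS = ("patient_id", "months_since_onset", "muscle", "side",
               "cmap_mv", "munix")


@dataclass
class PipelineConfig:
    """Paths, constants and options of the fit -> munix -> analyze pipeline."""

    alsfrs_path: Path
    munix_path: Path
    out_dir: Path
    patients_path: Path | None = None
    strata: str = "phase"                 # phase | aggressiveness | group
    alpha: float = _stats.ALPHA
    posthoc: str = "dunn"
    seed: int = 0
    phase_bounds: tuple = _model.PHASE_BOUNDS
    tier_bounds: tuple = _model.TIER_BOUNDS
    variables: tuple = ("munix", "cmap_mv", "musix_uv")

    def digest(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _require_columns(df, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _months_from_dates(df, patients, path):
    if patients is None or "onset_date" not in patients.columns:
        raise SchemaError(
            f"{path}: has assessment_date but no patients table with onset_date")
    onset = patients.set_index("patient_id")["onset_date"]
    onset = pd.to_datetime(onset, format="ISO8601")
    dates = pd.to_datetime(df["assessment_date"], format="ISO8601")
    mapped = df["patient_id"].map(onset)
    if mapped.isna().any():
        bad = df.loc[mapped.isna(), "patient_id"].unique()
        raise SchemaError(f"{path}: no onset date for patient(s) {list(bad)[:5]}")
    return (dates - mapped).dt.days / DAYS_PER_MONTH


def read_alsfrs(path, patients: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a long-format ALSFRS-R table.

    Either ``months_since_onset`` or ``assessment_date`` (with a patients
    table carrying ISO-8601 ``onset_date``) must be present.  Row-level
    violations (score outside 0-48, negative or non-finite time) are
    collected and raised together with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("patient_id", "alsfrs_r_total"), path)
    if "months_since_onset" not in df.columns:
        _require_columns(df, ("assessment_date",), path)
        df["months_since_onset"] = _months_from_dates(df, patients, path)

    errors = []
    t = pd.to_numeric(df["months_since_onset"], errors="coerce")
    score = pd.to_numeric(df["alsfrs_r_total"], errors="coerce")
    for idx in df.index:
        line = idx + 2  # header is line 1
        if not np.isfinite(t[idx]) or t[idx] < 0:
            errors.append(f"line {line}: invalid months_since_onset "
                          f"{df.loc[idx, 'months_since_onset']!r}")
        if not np.isfinite(score[idx]) or not 0 <= score[idx] <= FULL_SCORE:
            errors.append(f"line {line}: ALSFRS-R total outside [0, 48]: "
                          f"{df.loc[idx, 'alsfrs_r_total']!r}")
    if errors:
        raise SchemaError(f"{path}: validation failed", errors)
    df["months_since_onset"] = t
    df["alsfrs_r_total"] = score
    return df[list(_ALSFRS_COLS)]


def read_munix(path) -> pd.DataFrame:
    """Read and validate a long-format MUNIX table (munix may be empty)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _MUNIX_COLS, path)
    errors = []
    t = pd.to_numeric(df["months_since_onset"], errors="coerce")
    cmap = pd.to_numeric(df["cmap_mv"], errors="coerce")
    valid_muscles = {m.name for m in _munix.Muscle}
    for idx in df.index:
        line = idx + 2
        if not np.isfinite(t[idx]) or t[idx] < 0:
            errors.append(f"line {line}: invalid months_since_onset")
        if str(df.loc[idx, "muscle"]).upper() not in valid_muscles:
            errors.append(f"line {line}: unknown muscle "
                          f"{df.loc[idx, 'muscle']!r}")
        if np.isfinite(cmap[idx]) and cmap[idx] < 0:
            errors.append(f"line {line}: negative CMAP")
    if errors:
        raise SchemaError(f"{path}: validation failed", errors)
    df["months_since_onset"] = t
    return df[list(_MUNIX_COLS)]


def read_patients(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("patient_id",), path)
    return df


def read_cohort(alsfrs_path, munix_path, patients_path=None):
    """Read the full cohort; returns (alsfrs, munix, patients-or-None)."""
    patients = read_patients(patients_path) if patients_path else None
    return (read_alsfrs(alsfrs_path, patients), read_munix(munix_path),
            patients)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _stratify(fits, munix_first, patients):
    """Attach rd50-at-measurement, phase and aggressiveness to measurements."""
    meas = munix_first[munix_first["analysis_flag"]].copy()
    fitted = fits.set_index("patient_id")
    rd50, phase, tier = [], [], []
    for r in meas.itertuples(index=False):
        if r.patient_id in fitted.index:
            d50 = fitted.loc[r.patient_id, "d50"]
            v = compute_rd50(d50, r.months_since_onset)
            rd50.append(v)
            phase.append(classify_phase(v).value)
            tier.append(classify_aggressiveness(d50).value)
        else:
            rd50.append(np.nan)
            phase.append(None)
            tier.append(None)
    meas["rd50_at_measurement"] = rd50
    meas["phase"] = phase
    meas["aggressiveness"] = tier
    if patients is not None and "group" in patients.columns:
        meas = meas.merge(patients[["patient_id", "group"]], on="patient_id",
                          how="left")
    else:
        meas["group"] = "als"
    return meas


def _comparison_table(meas, stratum_col, variables, posthoc):
    """One row per variable x muscle x pairwise contrast."""
    rows = []
    for muscle in sorted(meas["muscle"].unique()):
        sub = meas[meas["muscle"] == muscle]
        for var in variables:
            by = {lab: grp[var].to_numpy()
                  for lab, grp in sub.groupby(stratum_col, observed=True)
                  if len(grp)}
            if len(by) < 2:
                continue
            res = _stats.compare_groups(by, posthoc=posthoc)
            for pw in res.pairwise.itertuples(index=False):
                rows.append({
                    "muscle": muscle, "variable": var,
                    "stratification": stratum_col,
                    "omnibus_H": res.statistic, "omnibus_p": res.pvalue,
                    "group1": pw.group1, "group2": pw.group2,
                    "z": pw.z, "p_raw": pw.p_raw, "p_adj": pw.p_adj,
                })
    return pd.DataFrame(rows)


def _summary_table(meas, stratum_col, variables):
    rows = []
    for (stratum, muscle), grp in meas.groupby([stratum_col, "muscle"],
                                               observed=True):
        row = {"stratum": stratum, "muscle": muscle, "n": len(grp)}
        for var in variables:
            s = _stats.summarize(grp[var])
            if s:
                row[f"{var}_median"], row[f"{var}_q25"], row[f"{var}_q75"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig):
    """Fit, preprocess, stratify and compare; write the report bundle.

    Outputs under ``config.out_dir``: ``fits.csv``, ``excluded.csv``,
    ``munix_processed.csv``, ``summary_<strata>.csv``,
    ``comparisons_<strata>.csv``, ``dropout.csv``, ``report.md`` and
    ``pipeline_log.txt``.  Deterministic given inputs and seed; every
    fitted patient lands in exactly one phase and one tier stratum.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"pipeline seed={cfg.seed} config_hash={cfg.digest()}"]

    alsfrs, munix_raw, patients = read_cohort(
        cfg.alsfrs_path, cfg.munix_path, cfg.patients_path)
    log_lines.append(f"read: {alsfrs['patient_id'].nunique()} ALSFRS-R "
                     f"patients, {len(munix_raw)} MUNIX rows")

    als_ids = None
    if patients is not None and "group" in patients.columns:
        als_ids = set(patients.loc[patients["group"] == "als", "patient_id"])
        alsfrs = alsfrs[alsfrs["patient_id"].isin(als_ids)]

    fits, excluded = _model.fit_cohort(alsfrs)
    n_in = alsfrs["patient_id"].nunique()
    assert n_in == len(fits) + len(excluded), "exclusion accounting broken"
    log_lines.append(f"fit: {len(fits)} fitted, {len(excluded)} excluded "
                     f"({'; '.join(excluded['reason'].unique()) or 'none'})")

    processed = _munix.process_measurements(munix_raw)
    selected = _munix.select_first_measurements(processed)
    log_lines.append(f"munix: {int(selected['analysis_flag'].sum())} analysis "
                     f"records, {int(processed['imputed'].sum())} imputed rows")

    meas = _stratify(fits, selected, patients)
    fitted_meas = meas.dropna(subset=["rd50_at_measurement"])

    stratum_col = {"phase": "phase", "aggressiveness": "aggressiveness",
                   "group": "group"}[cfg.strata]
    frame = meas if stratum_col == "group" else fitted_meas

    summary = _summary_table(frame, stratum_col, cfg.variables)
    comparisons = _comparison_table(frame, stratum_col, cfg.variables,
                                    cfg.posthoc)
    dropout = _munix.dropout_rate(
        fitted_meas.rename(columns={"phase": "stratum"}), "stratum")
    log_lines.append(f"analyze: strata={cfg.strata} "
                     f"{len(comparisons)} pairwise contrasts")

    fits.to_csv(out / "fits.csv", index=False)
    excluded.to_csv(out / "excluded.csv", index=False)
    processed.to_csv(out / "munix_processed.csv", index=False)
    summary.to_csv(out / f"summary_{cfg.strata}.csv", index=False)
    comparisons.to_csv(out / f"comparisons_{cfg.strata}.csv", index=False)
    dropout.to_csv(out / "dropout.csv", index=False)

    report = _render_report(cfg, fits, summary, comparisons, dropout)
    (out / "report.md").write_text(report)
    (out / "pipeline_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "fits": fits, "excluded": excluded, "measurements": meas,
        "summary": summary, "comparisons": comparisons, "dropout": dropout,
        "out_dir": out,
    }


def _render_report(cfg, fits, summary, comparisons, dropout):
    lines = ["# d50track analysis report", ""]
    if len(fits):
        s = _stats.summarize(fits["d50"])
        lines += [f"Fitted patients: {len(fits)}",
                  f"D50 median (IQR): {s[0]:.1f} ({s[1]:.1f}-{s[2]:.1f}) months",
                  ""]
    lines += [f"## Stratified medians ({cfg.strata})", "",
              summary.to_string(index=False) if len(summary) else "(empty)", "",
              "## Pairwise comparisons", "",
              comparisons.to_string(index=False) if len(comparisons) else "(empty)",
              "", "## Floor-imputation (drop-out) by phase", "",
              dropout.to_string(index=False) if len(dropout) else "(empty)", ""]
    return "\n".join(lines)
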