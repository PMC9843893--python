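"""Cohort-level diagnostic report assembly and rendering.

A report summarises one evaluated cohort: per-analysis sensitivity /
specificity / accuracy with exact CIs, likelihood ratios, AUCs where scores
are available, the (3D, 2D) cross-tab with per-cell likelihood ratios, and
size-stratified sensitivities with the trend p-value.

The canonical tabular input is a *calls table* with columns
``study_id, truth, call3d, call2d`` plus optional ``call_combined,
call_series, call_parallel, score3d, area2d, score_combined, stratum`` —
so published contingency data can be evaluated without any images.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .errors import ConfigurationError

_CALL_COLUMNS = {
    "3d": "call3d",
    "2d": "call2d",
    "combined": "call_combined",
    "series": "call_series",
    "parallel": "call_parallel",
}
_SCORE_COLUMNS = {"3d": "score3d", "2d": "area2d", "combined": "score_combined"}


def _as_bool(col: pd.Series) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy()
    return col.astype(str).str.strip().str.lower().isin(
        {"1", "true", "positive", "+", "pos"}).to_numpy()


def _interval_dict(est: dx.IntervalEstimate) -> dict:
    return {"point": est.point, "lower": est.lower, "upper": est.upper,
            "method": est.method}


def build_report(calls: pd.DataFrame) -> dict:
    """Compute the full diagnostic report from a calls table."""
    if "truth" not in calls or "call3d" not in calls or "call2d" not in calls:
        raise ConfigurationError("calls table needs truth, call3d, call2d columns")
    truth = _as_bool(calls["truth"])
    if truth.all() or not truth.any():
        raise ConfigurationError("cohort must contain both classes")
    call3d = _as_bool(calls["call3d"])
    call2d = _as_bool(calls["call2d"])

    df = calls.copy()
    if "call_series" not in df:
        df["call_series"] = call3d & call2d
    if "call_parallel" not in df:
        df["call_parallel"] = call3d | call2d

    report: dict = {"n_cases": int(truth.sum()),
                    "n_controls": int((~truth).sum()),
                    "analyses": {}}
    for name, col in _CALL_COLUMNS.items():
        if col not in df:
            continue
        counts = dx.ConfusionCounts.from_calls(_as_bool(df[col]), truth)
        entry: dict = {"counts": asdict(counts)}
        entry.update({k: _interval_dict(v)
                      for k, v in dx.accuracy_metrics(counts).items()})
        lr_pos, lr_neg = dx.likelihood_ratios(counts)
        entry["lr_positive"] = _interval_dict(lr_pos)
        entry["lr_negative"] = _interval_dict(lr_neg)
        score_col = _SCORE_COLUMNS.get(name)
        if score_col and score_col in df and df[score_col].notna().all():
            entry["auc"] = _interval_dict(
                dx.roc_auc(df[score_col].to_numpy(dtype=float), truth.astype(int)))
        report["analyses"][name] = entry

    tab = dx.CrossTab.from_calls(call3d, call2d, truth)
    report["crosstab"] = {"pc": list(tab.pc), "control": list(tab.control),
                          "likelihood_ratios": {
                              k: _interval_dict(v)
                              for k, v in dx.stratum_likelihood_ratios(tab).items()}}

    if "stratum" in df:
        strata = df.loc[truth & df["stratum"].notna(), "stratum"]
        if strata.nunique() >= 2:
            by_stratum = {}
            for name, col in _CALL_COLUMNS.items():
                if col not in df:
                    continue
                sub = df.loc[truth & df["stratum"].notna()]
                det = sub.groupby("stratum")[col].apply(
                    lambda s: int(_as_bool(s).sum())).to_dict()
                tot = sub.groupby("stratum").size().to_dict()
                per, p_trend = dx.size_stratified_sensitivity(det, tot)
                by_stratum[name] = {
                    "sensitivity": {k: _interval_dict(v) for k, v in per.items()},
                    "p_trend": p_trend,
                }
            report["size_stratified"] = by_stratum
    return report


def format_report(report: dict) -> str:
    """Human-readable table: one row per analysis, LR cross-tab below."""
    lines = [f"Cohort: {report['n_cases']} cases / {report['n_controls']} controls",
             "",
             f"{'analysis':<10}{'sens':>22}{'spec':>22}{'acc':>22}"
             f"{'AUC':>22}{'LR+':>22}{'LR-':>22}"]

    def fmt(e: dict | None, nd=3) -> str:
        if e is None:
            return f"{'-':>22}"
        return f"{e['point']:.{nd}f} ({e['lower']:.{nd}f}-{e['upper']:.{nd}f})".rjust(22)

    def fmt_lr(e: dict | None) -> str:
        if e is None:
            return f"{'-':>22}"
        return f"{e['point']:.2f} ({e['lower']:.2f}-{e['upper']:.2f})".rjust(22)

    for name, entry in report["analyses"].items():
        lines.append(f"{name:<10}" + fmt(entry.get("sensitivity"))
                     + fmt(entry.get("specificity")) + fmt(entry.get("accuracy"))
                     + fmt(entry.get("auc")) + fmt_lr(entry.get("lr_positive"))
                     + fmt_lr(entry.get("lr_negative")))

    tab = report.get("crosstab")
    if tab:
        lines += ["", "Cross-tab (3D call, 2D call):",
                  f"{'cell':<10}{'PC':>8}{'control':>10}{'LR':>24}"]
        for i, cell in enumerate(("3d+2d+", "3d+2d-", "3d-2d+", "3d-2d-")):
            lr = tab["likelihood_ratios"][cell]
            lines.append(f"{cell:<10}{tab['pc'][i]:>8}{tab['control'][i]:>10}"
                         + fmt_lr(lr).rjust(24))
    if "size_stratified" in report:
        lines += ["", "Sensitivity by tumor size:"]
        for name, entry in report["size_stratified"].items():
            parts = [f"{k} {v['point']:.3f} ({v['lower']:.3f}-{v['upper']:.3f})"
                     for k, v in entry["sensitivity"].items()]
            lines.append(f"  {name:<10}" + "; ".join(parts)
                         + f"  Ptrend={entry['p_trend']:.2g}")
    return "\n".join(lines)


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
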