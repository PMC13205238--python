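"""Tabular report rendering for pipeline results.

A :class:`ReportBundle` flattens a :class:`~aslt.shelf_life.PipelineResult`
into five data frames — primary fits, secondary fits on b(T), the
shelf-life table, the t-threshold Arrhenius fit, and the per-temperature
predictions — plus run metadata, and writes them as CSVs, one JSON bundle,
and an optional Markdown summary. Rendering is deterministic: the same
result and metadata regenerate byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .shelf_life import PipelineResult

_STAGE_FILES = {
    "primary_table": "primary_fits.csv",
    "secondary_table": "secondary_fits.csv",
    "shelf_life_table": "shelf_life.csv",
    "arrhenius_t80": "arrhenius_t80.csv",
    "predictions": "predictions.csv",
}


def input_digest(path) -> str:
    """Short SHA-256 digest of an input file, for run provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class ReportBundle:
    primary_table: pd.DataFrame
    secondary_table: pd.DataFrame
    shelf_life_table: pd.DataFrame
    arrhenius_t80: pd.DataFrame
    predictions: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def build_report(result: PipelineResult, metadata: dict | None = None) -> ReportBundle:
    """Flatten every pipeline stage into tidy tables."""
    primary_rows = []
    for T, fits in sorted(result.primary_fits.items()):
        selected = result.selected.get(T)
        for fit in fits:
            primary_rows.append(
                {
                    "temperature_C": T,
                    "model": fit.model,
                    "k1": fit.k1,
                    "k2": fit.k2,
                    "b": fit.b,
                    "n": fit.n,
                    "c0": fit.c0,
                    "r2": fit.metrics.r2,
                    "mse": fit.metrics.mse,
                    "rmse": fit.metrics.rmse,
                    "selected": selected is fit,
                    "non_degrading": fit.non_degrading,
                }
            )

    secondary_rows = []
    if result.arrhenius_b is not None:
        a = result.arrhenius_b
        secondary_rows.append(
            {
                "model": "arrhenius",
                "ea_kj_mol": a.ea_kj_mol,
                "se_ea_kj_mol": a.se_ea_kj_mol,
                "pre_exponential": a.pre_exponential,
                "k3": None,
                "tc_C": None,
                "r2": a.r2,
                "mse": None,
                "rmse": None,
                "n_points": a.n_points,
                "equation": f"b(T) = {a.pre_exponential:.4g} * exp({a.slope:.4f} / (T + 273.15))",
            }
        )
    if result.log_logistic_b is not None:
        ll = result.log_logistic_b
        secondary_rows.append(
            {
                "model": "log_logistic",
                "ea_kj_mol": None,
                "se_ea_kj_mol": None,
                "pre_exponential": None,
                "k3": ll.k3,
                "tc_C": ll.tc,
                "r2": ll.metrics.r2,
                "mse": ll.metrics.mse,
                "rmse": ll.metrics.rmse,
                "n_points": ll.n_points,
                "equation": f"b(T) = ln(1 + exp({ll.k3:.5f} * (T - {ll.tc:.2f})))",
            }
        )

    shelf_rows = []
    if result.shelf_life_table is not None:
        for r in result.shelf_life_table.rows:
            shelf_rows.append(
                {
                    "temperature_C": r.temperature_c,
                    "b": r.b,
                    "n": r.n,
                    "t_threshold_days": r.t_threshold_days,
                    "t_threshold_days_rounded": r.t_threshold_days_rounded,
                    "threshold_fraction": result.shelf_life_table.threshold_fraction,
                }
            )

    t80_rows = []
    pred_rows = []
    if result.shelf_life_prediction is not None:
        p = result.shelf_life_prediction
        t80_rows.append(
            {
                "slope": p.arrhenius.slope,
                "intercept": p.arrhenius.intercept,
                "ea_kj_mol": p.arrhenius.ea_kj_mol,
                "pre_exponential": p.arrhenius.pre_exponential,
                "r2": p.arrhenius.r2,
                "equation": f"ln t = {p.arrhenius.slope:.1f}/(T+273.15) + {p.arrhenius.intercept:.4f}",
            }
        )
        for row in p.predictions:
            pred_rows.append(
                {
                    "temperature_C": row.temperature_c,
                    "t_threshold_days": row.t_threshold_days,
                    "t_threshold_days_rounded": row.t_threshold_days_rounded,
                    "extrapolated": row.extrapolated,
                }
            )

    meta = {"package_version": __version__}
    meta.update(metadata or {})
    if result.errors:
        meta["stage_errors"] = {k: str(v) for k, v in result.errors.items()}
    return ReportBundle(
        primary_table=pd.DataFrame(primary_rows),
        secondary_table=pd.DataFrame(secondary_rows),
        shelf_life_table=pd.DataFrame(shelf_rows),
        arrhenius_t80=pd.DataFrame(t80_rows),
        predictions=pd.DataFrame(pred_rows),
        metadata=meta,
    )


def write_report(bundle: ReportBundle, out_dir, markdown: bool = True) -> Path:
    """Write stage CSVs, report.json, and (optionally) report.md to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"metadata": bundle.metadata}
    for attr, fname in _STAGE_FILES.items():
        df: pd.DataFrame = getattr(bundle, attr)
        df.to_csv(out / fname, index=False)
        payload[attr] = df.to_dict(orient="records")
    (out / "report.json").write_text(json.dumps(payload, indent=2, default=str) + "\n")
    if markdown:
        (out / "report.md").write_text(render_markdown(bundle))
    return out


def render_markdown(bundle: ReportBundle) -> str:
    """Human-readable Markdown summary of all five tables."""
    parts = ["# Accelerated shelf-life report\n"]
    for key, value in sorted(bundle.metadata.items()):
        parts.append(f"- **{key}**: {value}")
    parts.append("")
    titles = {
        "primary_table": "Primary kinetic fits",
        "secondary_table": "Secondary models on b(T)",
        "shelf_life_table": "Shelf life at the retention threshold",
        "arrhenius_t80": "Arrhenius fit of the shelf life",
        "predictions": "Predicted shelf life at target temperatures",
    }
    for attr, title in titles.items():
        df: pd.DataFrame = getattr(bundle, attr)
        parts.append(f"\n## {title}\n")
        if df.empty:
            parts.append("_not computed_")
        else:
            parts.append("```\n" + df.to_string(index=False) + "\n```")
    return "\n".join(parts) + "\n"
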