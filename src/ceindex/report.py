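"""Human- and machine-readable outputs of one assessment run.

The headline artifact is the score matrix — rows are services, columns are
sites, each cell printed as ``I/S%`` (service score to one decimal,
sustainability as a signed whole percent, ``–`` for undefined) — plus tidy
CSV exports of every intermediate: reference points, trend CIs, per-cell
factor scores (radar-chart data), a countermeasure digest, and a structured
log of every flag raised.
"""
from __future__ import annotations

import math
import re
from pathlib import Path

import pandas as pd

from .errors import UnknownPairError
from .pipeline import AssessmentResult, CellResult
from .pr import factor_diagnostics

NA_MARK = "–"  # en dash, the print convention for omitted cells


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def format_cell(I: float, S: float) -> str:
    """``I/S%`` with I to one decimal and S as a signed integer percent."""
    if _is_na(I):
        return f"{NA_MARK}/{NA_MARK}"
    left = f"{I:.1f}"
    if _is_na(S):
        return f"{left}/{NA_MARK}"
    return f"{left}/{round(S * 100):+d}%"


_CELL_RE = re.compile(r"^(?P<I>[^/]+)/(?P<S>.+)$")


def parse_cell(cell: str) -> tuple[float, float]:
    """Inverse of :func:`format_cell` to printed precision (NaN for ``–``)."""
    m = _CELL_RE.match(cell.strip())
    if not m:
        raise ValueError(f"unparseable cell {cell!r}")
    i_txt, s_txt = m.group("I"), m.group("S")
    I = math.nan if i_txt == NA_MARK else float(i_txt)
    if s_txt == NA_MARK:
        S = math.nan
    else:
        S = float(s_txt.rstrip("%")) / 100.0
    return I, S


def score_matrix(result: AssessmentResult) -> pd.DataFrame:
    """The printed score table: services x sites of ``I/S%`` cells."""
    cfg = result.config
    data = {}
    for site_id in cfg.site_ids:
        col = []
        for service_id in cfg.service_ids:
            s = result.cells[(site_id, service_id)].scores
            col.append(format_cell(s.I, s.S))
        data[site_id] = col
    return pd.DataFrame(data, index=pd.Index(cfg.service_ids, name="service_id"))


def tidy_scores(result: AssessmentResult) -> pd.DataFrame:
    """Long-format export of every score-cell field."""
    rows = []
    for (site_id, service_id), cell in result.cells.items():
        s = cell.scores
        rows.append({
            "site_id": site_id,
            "service_id": service_id,
            "X_eval": cell.X_eval,
            "X_R": cell.ref.X_R,
            "x": s.x,
            "T": s.T,
            "T_lower": s.T_lower,
            "T_upper": s.T_upper,
            "PR": s.PR,
            "x_F": s.x_F,
            "I": s.I,
            "S": s.S,
            "flags": "|".join(s.flags),
        })
    return pd.DataFrame(rows)


def reference_table(result: AssessmentResult) -> pd.DataFrame:
    rows = []
    for service_id, ref in result.reference_points.items():
        rows.append({
            "service_id": service_id,
            "X_R": ref.X_R,
            "source_site": ref.source_site if ref.source_site else "",
            "source_year": ref.source_year if ref.source_year else "",
            "window_first": ref.window[0],
            "window_last": ref.window[1],
            "override": ref.override,
        })
    return pd.DataFrame(rows)


def trend_table(result: AssessmentResult) -> pd.DataFrame:
    """The trend scores and their 95% CIs for every cell (machine form of
    the error-range figure)."""
    rows = []
    for (site_id, service_id), cell in result.cells.items():
        t = cell.trend
        rows.append({
            "site_id": site_id,
            "service_id": service_id,
            "T": t.T,
            "T_lower": t.T_lower,
            "T_upper": t.T_upper,
            "slope": t.slope_t,
            "se": t.se,
            "n_points": t.n_points,
            "flags": "|".join(t.flags),
        })
    return pd.DataFrame(rows)


def radar_data(cell: CellResult) -> pd.DataFrame:
    """factor_id, score for one cell — plottable as a radar chart."""
    return pd.DataFrame(
        [{"factor_id": fs.factor_id,
          "score": math.nan if fs.score is None else fs.score,
          "basis": fs.basis}
         for fs in cell.factor_scores]
    )


def countermeasure_digest(result: AssessmentResult) -> pd.DataFrame:
    """Per site: services declining under present conditions (S < 0) and
    the pressure factors behind them, worst first."""
    rows = []
    for (site_id, service_id), cell in result.cells.items():
        s = cell.scores.S
        if _is_na(s) or s >= 0:
            continue
        negative = factor_diagnostics(cell.factor_scores, threshold=0.0)
        rows.append({
            "site_id": site_id,
            "service_id": service_id,
            "S": s,
            "negative_factors": "|".join(negative),
        })
    return pd.DataFrame(
        rows, columns=["site_id", "service_id", "S", "negative_factors"]
    )


def flags_log(result: AssessmentResult) -> pd.DataFrame:
    rows = []
    for (site_id, service_id), cell in result.cells.items():
        for fl in cell.scores.flags:
            rows.append({"site_id": site_id, "service_id": service_id, "flag": fl})
    return pd.DataFrame(rows, columns=["site_id", "service_id", "flag"])


def explain(result: AssessmentResult, site_id: str, service_id: str) -> str:
    """Audit trail of one cell: every intermediate from raw values to S."""
    cell = result.cell(site_id, service_id)  # raises UnknownPairError
    s = cell.scores
    t = cell.trend
    lines = [
        f"cell ({site_id}, {service_id})",
        f"window: {cell.ref.window[0]}-{cell.ref.window[1]}",
        "",
        "observations retained (year, X, x=X/X_R):",
    ]
    for _, row in cell.retained.iterrows():
        lines.append(f"  {int(row['year'])}  X={row['value']:g}  x={row['x']:.6g}")
    if len(cell.excluded):
        lines.append("observations excluded as outliers:")
        for _, row in cell.excluded.iterrows():
            lines.append(f"  {int(row['year'])}  X={row['value']:g}")
    src = (f" (site {cell.ref.source_site}, year {cell.ref.source_year})"
           if cell.ref.source_site else " (user-supplied override)")
    lines += [
        "",
        f"reference point X_R = {cell.ref.X_R:g}{src}",
        f"evaluation-year value X = "
        f"{'missing' if cell.X_eval is None else f'{cell.X_eval:g}'}",
        f"present status x = {'NA' if _is_na(s.x) else f'{s.x:.6g}'}",
        "",
        f"trend: slope t = {t.slope_t:.6g}/yr, se = {t.se:.6g}, "
        f"n = {t.n_points}",
        f"  T = 5t = {t.T:.6g}, 95% CI [{t.T_lower:.6g}, {t.T_upper:.6g}] "
        f"(bounds 5t ± 15se, clamped to [-1, 1])",
        "",
        "factor scores:",
    ]
    if cell.factor_scores:
        for fs in cell.factor_scores:
            val = "NA (unknown state)" if fs.score is None else f"{fs.score:+.3g}"
            lines.append(f"  {fs.factor_id}: {val}  [{fs.basis}]")
    else:
        lines.append("  (no conceptual model declared: PR not evaluated)")
    pr_txt = "NA -> 0 used in projection" if _is_na(s.PR) else f"{s.PR:+.6g}"
    beta = result.config.assessment.beta
    lines += [
        f"PR = {pr_txt}",
        "",
        f"beta = {beta:g}",
        f"future status x_F = (1 + beta*T + (1-beta)*PR) * x = "
        f"{'NA' if _is_na(s.x_F) else f'{s.x_F:.6g}'}",
    ]
    if "CLAMPED_FUTURE" in s.flags:
        pr_eff = 0.0 if _is_na(s.PR) else s.PR
        raw = (1 + beta * s.T + (1 - beta) * pr_eff) * s.x
        lines.append(f"  (raw projection {raw:.6g} clamped to 1)")
    lines += [
        f"service score I = (x + x_F)/2 = "
        f"{'NA' if _is_na(s.I) else f'{s.I:.6g}'}",
        f"sustainability S = (x_F - x)/x = "
        f"{'NA' if _is_na(s.S) else f'{s.S:+.6g}'} "
        f"({format_cell(s.I, s.S).split('/')[1]})",
        f"flags: {', '.join(s.flags) if s.flags else 'none'}",
    ]
    return "\n".join(lines) + "\n"


def write_reports(result: AssessmentResult, out_dir) -> dict[str, Path]:
    """Write all report artifacts into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    matrix = score_matrix(result)
    paths["score_matrix"] = out / "score_matrix.csv"
    matrix.to_csv(paths["score_matrix"], lineterminator="\n")

    for name, df in (
        ("scores", tidy_scores(result)),
        ("reference_points", reference_table(result)),
        ("trend_ci", trend_table(result)),
        ("countermeasures", countermeasure_digest(result)),
        ("flags", flags_log(result)),
    ):
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False, float_format="%.12g",
                  lineterminator="\n")

    radar_dir = out / "radar"
    radar_dir.mkdir(exist_ok=True)
    for (site_id, service_id), cell in result.cells.items():
        p = radar_dir / f"{site_id}__{service_id}.csv"
        radar_data(cell).to_csv(p, index=False, float_format="%.12g",
                                lineterminator="\n")
    paths["radar_dir"] = radar_dir
    return paths
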