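"""Dashboard outputs: per-question, per-domain and total results as CSV, JSON
and a static HTML page.

Every number in the rendered tables is re-derived from the scorecards before
rendering (templates never compute); display values are rounded to one
decimal place at this layer only.  CSV and JSON outputs are byte-identical
for identical inputs; the HTML differs only in its generation timestamp.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from .aggregation import BenchmarkView, ScoreCard, card_to_dict
from .change import PairedChangeResult

#: cautions shown under every rendered dashboard
CAVEATS = [
    "Aggregated scores smooth over much of the nuance and detail in the "
    "underlying responses.",
    "Below-average results may reflect factors outside the organisation's "
    "control, such as system interoperability and governance.",
    "Organisation size and structure can mediate scores: the same activities "
    "may be implemented differently in large and small organisations.",
    "Scores incorporate the subjective judgement of whoever completed the tool.",
]


@dataclass
class DashboardBundle:
    """Everything a rendered dashboard is built from."""

    cards: list[ScoreCard]
    views: list[BenchmarkView] = field(default_factory=list)
    change: Optional[PairedChangeResult] = None
    provenance: dict = field(default_factory=dict)


def _total_frame(bundle: DashboardBundle) -> pd.DataFrame:
    rows = []
    views = {(v.org_id, v.timepoint): v for v in bundle.views}
    for c in bundle.cards:
        row = {
            "org_id": c.org_id,
            "timepoint": c.timepoint,
            "total": c.total,
            "objective_summary": c.objective_summary,
            "subjective_summary": c.subjective_summary,
            "n_scored": c.n_scored,
        }
        v = views.get((c.org_id, c.timepoint))
        if v is not None:
            row["delta_vs_reference"] = v.total_delta
            row["percentile"] = v.percentile_total
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["org_id", "timepoint"]).reset_index(drop=True)


def _question_frame(bundle: DashboardBundle) -> pd.DataFrame:
    rows = []
    for c in bundle.cards:
        for qid, qs in sorted(c.question_scores.items()):
            rows.append({
                "org_id": c.org_id,
                "timepoint": c.timepoint,
                "question_id": qid,
                "objective": qs.objective,
                "subjective": qs.subjective,
                "total": qs.total,
                "unanswered": qs.flags.unanswered,
            })
    return pd.DataFrame(rows).sort_values(
        ["org_id", "timepoint", "question_id"]).reset_index(drop=True)


def _domain_frame(bundle: DashboardBundle) -> pd.DataFrame:
    rows = []
    for c in bundle.cards:
        for domain, score in sorted(c.domain_scores.items()):
            rows.append({
                "org_id": c.org_id,
                "timepoint": c.timepoint,
                "domain": domain,
                "score": score,
            })
    return pd.DataFrame(rows).sort_values(
        ["org_id", "timepoint", "domain"]).reset_index(drop=True)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # one-decimal display rounding happens here, never upstream
    df.to_csv(path, index=False, float_format="%.1f", lineterminator="\n")


def build_dashboard(cards: list[ScoreCard],
                    views: Optional[list[BenchmarkView]] = None,
                    change: Optional[PairedChangeResult] = None,
                    out_dir: str | Path = "dashboard",
                    provenance: Optional[dict] = None) -> dict[str, Path]:
    """Write total.csv, questions.csv, domains.csv, dashboard.json and
    dashboard.html under ``out_dir``; returns the paths written.

    Raises ``ValueError`` (writing nothing) on an empty cohort.
    """
    if not cards:
        raise ValueError("cannot build a dashboard from an empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = DashboardBundle(cards=cards, views=list(views or []), change=change,
                             provenance=dict(provenance or {}))

    total_df = _total_frame(bundle)
    question_df = _question_frame(bundle)
    domain_df = _domain_frame(bundle)

    paths = {
        "total": out_dir / "total.csv",
        "questions": out_dir / "questions.csv",
        "domains": out_dir / "domains.csv",
        "json": out_dir / "dashboard.json",
        "html": out_dir / "dashboard.html",
    }
    _write_csv(total_df, paths["total"])
    _write_csv(question_df, paths["questions"])
    _write_csv(domain_df, paths["domains"])

    payload = {
        "provenance": bundle.provenance,
        "scorecards": [card_to_dict(c) for c in bundle.cards],
        "benchmarks": [asdict(v) for v in bundle.views],
        "change": asdict(change) if change is not None else None,
        "caveats": CAVEATS,
    }
    paths["json"].write_text(
        json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8")

    paths["html"].write_text(_render_html(bundle, total_df, question_df, domain_df),
                             encoding="utf-8")
    return paths


def _render_html(bundle: DashboardBundle, total_df: pd.DataFrame,
                 question_df: pd.DataFrame, domain_df: pd.DataFrame) -> str:
    fmt = {c: (lambda v: f"{v:.1f}") for c in
           ["total", "objective_summary", "subjective_summary", "objective",
            "subjective", "score", "delta_vs_reference", "percentile"]}

    def table(df: pd.DataFrame) -> str:
        return df.to_html(index=False, border=0, formatters={
            k: v for k, v in fmt.items() if k in df.columns})

    change_html = ""
    if bundle.change is not None:
        ch = bundle.change
        change_html = (
            f"<h2>Change between timepoints ({ch.metric})</h2>"
            f"<p>n = {ch.n} paired organisations; mean {ch.mean_t1:.1f} &rarr; "
            f"{ch.mean_t2:.1f} (difference {ch.mean_diff:+.2f}, 95% CI "
            f"{ch.ci_95[0]:.2f} to {ch.ci_95[1]:.2f}); paired t = "
            f"{ch.t_statistic:.2f}, df = {ch.df}, two-sided p = "
            f"{ch.p_two_sided:.3f}.</p>")

    provenance = dict(bundle.provenance)
    provenance["generated_at"] = datetime.now(timezone.utc).isoformat()
    prov_html = "".join(f"<li>{k}: {v}</li>" for k, v in sorted(provenance.items()))
    caveats_html = "".join(f"<li>{c}</li>" for c in CAVEATS)

    return f"""<!DOCTYPE html>
<html lang="en">
<head><meta charset="utf-8"><title>P3C-OCT dashboard</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 2em; }}
th, td {{ padding: 0.3em 0.8em; border-bottom: 1px solid #ccc; text-align: left; }}
footer {{ color: #555; font-size: 0.9em; margin-top: 3em; }}
</style></head>
<body>
<h1>P3C-OCT results dashboard</h1>
<h2>Total scores (out of 20)</h2>
{table(total_df)}
<h2>Domain scores (out of 20)</h2>
{table(domain_df)}
<h2>Per-question scores</h2>
{table(question_df)}
{change_html}
<footer>
<h3>Reading these scores</h3>
<ul>{caveats_html}</ul>
<h3>Provenance</h3>
<ul>{prov_html}</ul>
</footer>
</body>
</html>
"""
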