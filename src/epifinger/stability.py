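"""Heat-stability calls and combined recognition reports.

Each analyte (protein or epitope label) is measured per serum under an
unroasted reference (UR) and a set of roasting conditions (LTLT: 142 °C
for 30/50 min; HTST: 200 °C for 8/10 min). The retention ratio is the
worst-case signal retention, min over roasted conditions of
signal / UR signal; an analyte is heat-labile for a serum when that ratio
falls below the labile cutoff (default 0.5), and sera disagreeing about
an analyte are flagged as discordant.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

UR = "UR"
DEFAULT_CONDITIONS = ("UR", "142C/30min", "142C/50min", "200C/8min", "200C/10min")
HEAT_STABLE = "heat-stable"
HEAT_LABILE = "heat-labile"


def classify_stability(
    signals: pd.DataFrame,
    labile_cutoff: float = 0.5,
    reference_condition: str = UR,
) -> pd.DataFrame:
    """Per analyte x serum stability labels from per-condition signals.

    ``signals`` columns: analyte, condition, serum, signal (adjusted fold).
    Returns one row per analyte x serum with retention_ratio, label, and a
    per-analyte ``discordant`` flag set when sera disagree on the label.
    """
    if not 0 < labile_cutoff < 1:
        raise ValueError("labile_cutoff must be in (0, 1)")
    required = {"analyte", "condition", "serum", "signal"}
    if missing := required - set(signals.columns):
        raise ValueError(f"signals table missing columns {sorted(missing)}")
    rows = []
    for (analyte, serum), grp in signals.groupby(["analyte", "serum"], sort=True):
        by_cond = grp.set_index("condition")["signal"]
        if reference_condition not in by_cond.index:
            raise ValueError(f"no {reference_condition} signal for {analyte}/{serum}")
        ur = float(by_cond[reference_condition])
        if ur <= 0:
            raise ValueError(f"non-positive {reference_condition} signal for {analyte}/{serum}")
        roasted = by_cond.drop(reference_condition)
        if roasted.empty:
            raise ValueError(f"no roasted conditions for {analyte}/{serum}")
        ratio = float((roasted / ur).min())
        rows.append(
            {
                "analyte": analyte,
                "serum": serum,
                "retention_ratio": ratio,
                "label": HEAT_LABILE if ratio < labile_cutoff else HEAT_STABLE,
            }
        )
    calls = pd.DataFrame(rows)
    discord = calls.groupby("analyte")["label"].nunique() > 1
    calls["discordant"] = calls["analyte"].map(discord)
    return calls


def build_reports(
    epitope_table: pd.DataFrame,
    array_summaries: pd.DataFrame | None,
    stability_calls: pd.DataFrame | None,
    sera: list[str] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Combined recognition report: one row per epitope.

    ``epitope_table`` needs columns antigen_id, label, sera (';'-joined
    serum ids). Array summaries (columns id, adjusted, positive — id equal
    to the epitope label) and stability calls are joined where present;
    epitopes without array data keep empty array columns. Stability calls
    whose analytes match no epitope's antigen or label raise an error
    listing the orphans.
    """
    report = epitope_table.copy()
    if sera is None:
        sera = sorted(
            {s for cell in report["sera"] for s in str(cell).split(";") if s}
        )
    for s in sera:
        report[f"ngs_{s}"] = report["sera"].map(
            lambda cell, s=s: s in str(cell).split(";")
        )
    if array_summaries is not None and len(array_summaries):
        arr = array_summaries.set_index("id")
        report["array_adjusted"] = report["label"].map(arr["adjusted"])
        report["array_positive"] = report["label"].map(arr["positive"])
    else:
        report["array_adjusted"] = np.nan
        report["array_positive"] = pd.NA
    if stability_calls is not None and len(stability_calls):
        known = set(report["antigen_id"]) | set(report["label"])
        orphans = sorted(set(stability_calls["analyte"]) - known)
        if orphans:
            raise ValueError(f"stability analytes match no epitope: {orphans}")
        lab = (
            stability_calls.groupby("analyte")["label"]
            .agg(lambda v: "/".join(sorted(set(v))))
        )
        report["stability"] = (
            report["antigen_id"].map(lab).fillna(report["label"].map(lab))
        )
    else:
        report["stability"] = pd.NA

    lines = ["Epitope recognition report", "=" * 60]
    for _, r in report.iterrows():
        ngs = ",".join(s for s in sera if r.get(f"ngs_{s}", False))
        arr_txt = (
            f"array {r['array_adjusted']:.2f}x"
            f" ({'positive' if r['array_positive'] else 'negative'})"
            if pd.notna(r.get("array_positive"))
            else "array n/a"
        )
        stab = r["stability"] if pd.notna(r["stability"]) else "n.d."
        lines.append(
            f"{r['antigen_id']:>12} {r['label']:<28} NGS[{ngs}] {arr_txt}; {stab}"
        )
    return report, "\n".join(lines)


def write_report(
    report: pd.DataFrame, text: str,
    tsv_path: str | os.PathLike, txt_path: str | os.PathLike,
) -> None:
    report.to_csv(tsv_path, sep="\t", index=False)
    with open(txt_path, "w") as fh:
        fh.write(text + "\n")
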