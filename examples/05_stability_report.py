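"""Classify heat stability from per-condition array signals and build the
combined recognition report.

Signals are fold-over-water intensities per analyte x roasting condition
x serum: unroasted (UR) as reference, two LTLT conditions (142 C for
30/50 min) and two HTST conditions (200 C for 8/10 min). An analyte is
heat-labile for a serum when its worst-case retention (min roasted/UR)
drops below 0.5; sera that disagree are flagged discordant.
"""

import pandas as pd

from epifinger import build_reports, classify_stability
from epifinger.stability import DEFAULT_CONDITIONS

rows = []
profiles = {
    # analyte: (serum, UR fold, per-condition retention)
    "Cor a 9":  [("R1", 12.0, [1.0, 0.95, 0.9, 0.9]), ("R2", 9.0, [1.0, 0.9, 0.85, 0.8])],
    "Cor a 1":  [("R1", 8.0, [0.6, 0.4, 0.2, 0.1]), ("R2", 7.0, [0.5, 0.45, 0.3, 0.2])],
    "Cor a 14": [("R1", 6.0, [0.8, 0.6, 0.45, 0.4]), ("R2", 6.5, [0.9, 0.85, 0.8, 0.75])],
}
for analyte, sera in profiles.items():
    for serum, ur, ret in sera:
        rows.append({"analyte": analyte, "condition": "UR", "serum": serum, "signal": ur})
        for cond, r in zip(DEFAULT_CONDITIONS[1:], ret):
            rows.append({"analyte": analyte, "condition": cond, "serum": serum,
                         "signal": ur * r})

calls = classify_stability(pd.DataFrame(rows), labile_cutoff=0.5)
print(calls.round(3).to_string(index=False))

epitopes = pd.DataFrame({
    "antigen_id": ["Cor a 9", "Cor a 9", "Cor a 1", "Cor a 14"],
    "start": [63, 183, 124, 46],
    "end": [72, 194, 127, 54],
    "label": ["63-DHNDQQFQCA", "183-NNYANQLDENPR", "124-kgdHEINaee",
              "45-eSCREQAQRQqnl"],
    "n_support": [5, 4, 3, 4],
    "sera": ["R1;R2", "R1", "R1;R2", "R1"],
})
report, text = build_reports(epitopes, None, calls)
print("\n" + text)

# 'retention_ratio' is min over roasted conditions of signal/UR; a ratio
# below the cutoff in any condition marks the analyte heat-labile for
# that serum, and discordant=True mirrors sera disagreeing on the call.
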