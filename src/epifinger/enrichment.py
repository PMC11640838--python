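"""Per-peptide enrichment statistics across selection rounds.

For each peptide present in the selected round, the fold change of its
pseudocounted frequency relative to a reference round is computed together
with a one-sided exact binomial tail p-value (is the selected-round count
larger than expected under the reference-round frequency?) and a
Benjamini-Hochberg adjusted q-value. A peptide is called enriched when
q <= alpha and fold >= fold_min.
"""

from __future__ import annotations

import os

import numpy as np

import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .processing import PeptideCountTable

DEFAULT_ALPHA = 0.05
DEFAULT_FOLD_MIN = 3.0
DEFAULT_PSEUDOCOUNT = 0.5


def score_enrichment(
    table_ref: PeptideCountTable,
    table_sel: PeptideCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    alpha: float = DEFAULT_ALPHA,
    fold_min: float = DEFAULT_FOLD_MIN,
) -> pd.DataFrame:
    """Score every peptide of the selected round against the reference round.

    Returns a DataFrame with columns peptide, count_ref, count_sel,
    total_ref, total_sel, fold, p, q, enriched, sorted by ascending p.

    fold = ((count_sel + pc) / (total_sel + pc)) / ((count_ref + pc) / (total_ref + pc));
    p = P(X >= count_sel) with X ~ Binomial(total_sel, pseudocounted
    reference frequency); q = BH over all peptides of the selected round.
    """
    sel = table_sel.table
    if len(sel) == 0:
        return pd.DataFrame(
            columns=[
                "peptide", "count_ref", "count_sel", "total_ref", "total_sel",
                "fold", "p", "q", "enriched",
            ]
        )
    total_ref = table_ref.accepted_reads
    total_sel = table_sel.accepted_reads
    if total_ref <= 0 or total_sel <= 0:
        raise ValueError("both rounds need accepted reads")
    ref_counts = dict(zip(table_ref.table["peptide"], table_ref.table["count"]))
    out = sel[["peptide", "count"]].rename(columns={"count": "count_sel"}).copy()
    out["count_ref"] = out["peptide"].map(ref_counts).fillna(0).astype(int)
    out["total_ref"] = total_ref
    out["total_sel"] = total_sel
    f_ref = (out["count_ref"] + pseudocount) / (total_ref + pseudocount)
    f_sel = (out["count_sel"] + pseudocount) / (total_sel + pseudocount)
    out["fold"] = f_sel / f_ref
    # one-sided exact binomial upper tail, P(X >= count_sel); the tail is
    # mathematically positive, so clamp float underflow away from 0

    out["p"] = np.clip(
        binom.sf(out["count_sel"] - 1, total_sel, f_ref.clip(upper=1.0)),
        np.finfo(float).tiny, 1.0,
    )
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched"] = (out["q"] <= alpha) & (out["fold"] >= fold_min)
    out = out[
        [
            "peptide", "count_ref", "count_sel", "total_ref", "total_sel",
            "fold", "p", "q", "enriched",
        ]
    ]
    return out.sort_values(["p", "peptide"], kind="stable").reset_index(drop=True)


def select_enriched(
    records: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fold_min: float = DEFAULT_FOLD_MIN,
) -> list[str]:
    """Peptides with q <= alpha and fold >= fold_min, by descending fold."""
    if len(records) == 0:
        return []
    hit = records[(records["q"] <= alpha) & (records["fold"] >= fold_min)]
    hit = hit.sort_values(["fold", "peptide"], ascending=[False, True], kind="stable")
    return list(hit["peptide"])


def write_enrichment_tsv(records: pd.DataFrame, path: str | os.PathLike) -> None:
    records.to_csv(path, sep="\t", index=False)
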