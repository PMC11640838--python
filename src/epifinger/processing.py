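"""Curation of paired phage-display reads into per-round peptide counts.

Pipeline: merge each read pair on its best ungapped overlap (disagreements
resolved by the higher base quality), gate on whole-read mean quality,
validate the merged insert against the library codon structure, translate,
and aggregate identical peptides into a count table. Reads that deviate
from the library grammar are tallied by rejection reason, never silently
dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .scheme import (
    CODON_VIOLATION,
    FLANK_MISMATCH,
    LOW_QUALITY,
    STOP_CODON,
    PeptideLibraryScheme,
)

REJECT_REASONS = (FLANK_MISMATCH, CODON_VIOLATION, STOP_CODON, LOW_QUALITY)
NO_OVERLAP = "no_overlap"

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MergedRead:
    dna: str
    mean_quality: float
    overlap_len: int


@dataclass
class PeptideCountTable:
    """Curated unique-peptide counts for one selection round."""

    round_id: int
    table: pd.DataFrame  # columns: peptide, count, frequency
    total_reads: int
    rejected: dict[str, int]

    @property
    def accepted_reads(self) -> int:
        return int(self.table["count"].sum())

    def frequency_of(self, peptide: str) -> float:
        hit = self.table.loc[self.table["peptide"] == peptide, "frequency"]
        return float(hit.iloc[0]) if len(hit) else 0.0

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.table.copy()
        out.insert(0, "round", self.round_id)
        out.to_csv(path, sep="\t", index=False)


def merge_pair(
    fwd: str,
    rev: str,
    fwd_qual: np.ndarray | list[int],
    rev_qual: np.ndarray | list[int],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | str:
    """Merge a read pair on the best ungapped overlap.

    The reverse read is reverse-complemented and slid along the forward
    read; for every admissible offset the overlap's match count is scored
    and the offset with most matches wins (ties: longer overlap). Bases
    disagreeing inside the overlap take the call with the higher Phred
    quality. Returns the rejection reason string if no offset has overlap
    >= min_overlap with mismatch fraction <= max_mismatch_frac.
    """
    if not fwd or not rev:
        raise ValueError("empty read")
    rc = rev.translate(_COMP)[::-1]
    rcq = np.asarray(rev_qual, dtype=np.int16)[::-1]
    fq = np.asarray(fwd_qual, dtype=np.int16)
    fa = np.frombuffer(fwd.encode(), dtype="S1")
    ra = np.frombuffer(rc.encode(), dtype="S1")
    nf, nr = len(fa), len(ra)

    best = None  # (matches, overlap, offset)
    # offset = position of rc's first base relative to fwd's first base;
    # negative offsets would imply the insert shorter than the rev read
    for off in range(-(nr - 1), nf):
        lo_f, hi_f = max(0, off), min(nf, off + nr)
        ov = hi_f - lo_f
        if ov < min_overlap:
            continue
        seg_f = fa[lo_f:hi_f]
        seg_r = ra[lo_f - off:hi_f - off]
        matches = int((seg_f == seg_r).sum())
        if (ov - matches) / ov > max_mismatch_frac:
            continue
        cand = (matches, ov, -abs(off))
        if best is None or cand > best[:3]:
            best = (matches, ov, -abs(off), off)
    if best is None:
        return NO_OVERLAP
    off = best[3]

    start = min(0, off)
    end = max(nf, off + nr)
    n = end - start
    out = np.zeros(n, dtype="S1")
    outq = np.zeros(n, dtype=np.int16)
    # forward read contributes first, reverse fills / overrides on quality
    out[-start:nf - start] = fa
    outq[-start:nf - start] = fq
    r_lo = off - start
    r_seg = slice(r_lo, r_lo + nr)
    r_only = outq[r_seg] == 0
    take_rev = r_only | (rcq > outq[r_seg])
    # on a disagreement keep the higher-quality base; on agreement keep the
    # base and the higher of the two qualities
    agree = out[r_seg] == ra
    out[r_seg] = np.where(take_rev, ra, out[r_seg])
    outq[r_seg] = np.where(agree, np.maximum(outq[r_seg], rcq),
                           np.where(take_rev, rcq, outq[r_seg]))
    return MergedRead(
        dna=out.tobytes().decode(),
        mean_quality=float(outq.mean()),
        overlap_len=best[1],
    )


def validate_structure(dna: str, scheme: PeptideLibraryScheme) -> str | None:
    """Pass (None) or rejection reason for a merged insert. See scheme.validate."""
    return scheme.validate(dna)


def translate_and_count(
    merged: list[MergedRead | str],
    scheme: PeptideLibraryScheme,
    round_id: int = 0,
    min_mean_quality: float = 20.0,
) -> PeptideCountTable:
    """Curate merged reads into a unique-peptide count table.

    Merge rejections (strings) and reads failing the mean-quality gate or
    the codon-structure validation are tallied under their reason;
    surviving reads are translated and aggregated.
    """
    rejected = {r: 0 for r in REJECT_REASONS}
    rejected[NO_OVERLAP] = 0
    counts: dict[str, int] = {}
    total = 0
    for m in merged:
        total += 1
        if isinstance(m, str):
            rejected[m] = rejected.get(m, 0) + 1
            continue
        if m.mean_quality < min_mean_quality:
            rejected[LOW_QUALITY] += 1
            continue
        reason = scheme.validate(m.dna)
        if reason is not None:
            rejected[reason] += 1
            continue
        pep = scheme.translate(m.dna)
        counts[pep] = counts.get(pep, 0) + 1
    accepted = sum(counts.values())
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["peptide", "count"],
    )
    table["frequency"] = table["count"] / accepted if accepted else 0.0
    return PeptideCountTable(
        round_id=round_id, table=table, total_reads=total, rejected=rejected
    )


def process_fastq_pair(
    fwd_path: str | os.PathLike,
    rev_path: str | os.PathLike,
    scheme: PeptideLibraryScheme,
    round_id: int = 0,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    min_mean_quality: float = 20.0,
) -> PeptideCountTable:
    """File-level convenience wrapper: paired FASTQ -> PeptideCountTable."""
    merged: list[MergedRead | str] = []
    with open(fwd_path) as fh1, open(rev_path) as fh2:
        for rec1, rec2 in zip(
            SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq"), strict=True
        ):
            merged.append(
                merge_pair(
                    str(rec1.seq),
                    str(rec2.seq),
                    rec1.letter_annotations["phred_quality"],
                    rec2.letter_annotations["phred_quality"],
                    min_overlap=min_overlap,
                    max_mismatch_frac=max_mismatch_frac,
                )
            )
    return translate_and_count(
        merged, scheme, round_id=round_id, min_mean_quality=min_mean_quality
    )


def process_simulation(
    sim,
    round_id: int,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    min_mean_quality: float = 20.0,
) -> PeptideCountTable:
    """Curate one round of an in-memory SelectionSim without FASTQ files."""
    merged: list[MergedRead | str] = []
    for _rid, fwd, rev, q in sim.reads(round_id):
        quals = [q] * len(fwd)
        merged.append(
            merge_pair(
                fwd, rev, quals, [q] * len(rev),
                min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac,
            )
        )
    return translate_and_count(
        merged, sim.scheme, round_id=round_id, min_mean_quality=min_mean_quality
    )
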