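"""Mapping enriched peptides onto antigens and calling linear epitopes.

Peptides are aligned to each antigen by seeded, ungapped extension: every
shared k-mer nominates a diagonal, and on each diagonal the reported hit
is the window that (a) contains at least one run of >= k consecutive
matches, (b) has identity >= min_identity, and (c) maximizes the number of
matching residues — tie-broken by shortest span, then leftmost start.
Per-residue pile-up of hits from distinct peptides then yields epitope
calls: maximal runs of residues supported by >= min_support peptides,
rendered in the field's mixed-case notation ("124-kgdHEINaee": uppercase
core = residues meeting the support threshold, lowercase = flanking
context, the leading number = 1-based position of the first printed
residue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SeedHit:
    peptide: str
    antigen_id: str
    peptide_offset: int  # 1-based start on the peptide
    antigen_start: int   # 1-based start on the antigen
    span: int
    identities: int


@dataclass
class EpitopeCall:
    antigen_id: str
    start: int  # 1-based first core residue
    core: str
    flank_left: str
    flank_right: str
    n_support: int
    sera: tuple[str, ...] = ()
    supporting_peptides: tuple[str, ...] = ()

    @property
    def end(self) -> int:
        return self.start + len(self.core) - 1

    @property
    def label(self) -> str:
        printed_start = self.start - len(self.flank_left)
        return f"{printed_start}-{self.flank_left.lower()}{self.core.upper()}{self.flank_right.lower()}"


def render_label(call: EpitopeCall) -> str:
    return call.label


def parse_label(label: str, antigen_id: str = "", n_support: int = 0) -> EpitopeCall:
    """Inverse of EpitopeCall.label (position + mixed-case core/flank string)."""
    pos_str, seq = label.split("-", 1)
    printed_start = int(pos_str)
    i = 0
    while i < len(seq) and seq[i].islower():
        i += 1
    j = len(seq)
    while j > i and seq[j - 1].islower():
        j -= 1
    core = seq[i:j]
    if not core or not core.isupper():
        raise ValueError(f"label {label!r} has no uppercase core")
    return EpitopeCall(
        antigen_id=antigen_id,
        start=printed_start + i,
        core=core,
        flank_left=seq[:i].upper(),
        flank_right=seq[j:].upper(),
        n_support=n_support,
    )


# ---------------------------------------------------------------------------
# seeded ungapped alignment


def _best_window_on_diagonal(
    match: np.ndarray, k: int, min_identity: float
) -> tuple[int, int, int] | None:
    """Best (start, length, identities) window of a 0/1 match vector.

    Admissible windows contain >= k consecutive matches and have identity
    >= min_identity; best = max identities, then shortest, then leftmost.
    """
    n = len(match)
    if n < k:
        return None
    # positions where a k-run of matches starts
    run = np.convolve(match, np.ones(k, dtype=int), mode="valid") == k
    if not run.any():
        return None
    csum = np.concatenate([[0], np.cumsum(match)])
    run_start = np.nonzero(run)[0]
    best = None
    for i in range(n):
        # earliest seed run that could sit inside a window starting at i
        for j in range(i + k - 1, n):
            ident = csum[j + 1] - csum[i]
            length = j + 1 - i
            if ident / length < min_identity:
                continue
            # window must contain a full k-run
            lo = np.searchsorted(run_start, i)
            if lo >= len(run_start) or run_start[lo] + k - 1 > j:
                continue
            cand = (ident, -length, -i)
            if best is None or cand > best[:3]:
                best = (ident, -length, -i, i, length)
    if best is None:
        return None
    return best[3], best[4], best[0]


def seed_and_extend(
    peptide: str,
    antigen_seq: str,
    antigen_id: str = "",
    k: int = 4,
    min_identity: float = 0.7,
) -> list[SeedHit]:
    """Ungapped peptide-vs-antigen hits seeded by shared k-mers.

    Only diagonals carrying at least one exact shared k-mer are examined;
    each contributes at most one hit (the best admissible window, see
    module docstring). Returns an empty list when no k-mer is shared.
    """
    if k > len(peptide):
        raise ValueError("k longer than peptide")
    index: dict[str, list[int]] = {}
    for i in range(len(antigen_seq) - k + 1):
        index.setdefault(antigen_seq[i:i + k], []).append(i)
    diagonals = set()
    for p in range(len(peptide) - k + 1):
        for a in index.get(peptide[p:p + k], ()):
            diagonals.add(a - p)
    hits = []
    pep = np.frombuffer(peptide.encode(), dtype="S1")
    ant = np.frombuffer(antigen_seq.encode(), dtype="S1")
    for d in sorted(diagonals):
        # overlap of the peptide with the antigen along diagonal d
        p_lo = max(0, -d)
        p_hi = min(len(pep), len(ant) - d)
        if p_hi - p_lo < k:
            continue
        match = (pep[p_lo:p_hi] == ant[p_lo + d:p_hi + d]).astype(int)
        best = _best_window_on_diagonal(match, k, min_identity)
        if best is None:
            continue
        start, length, ident = best
        hits.append(
            SeedHit(
                peptide=peptide,
                antigen_id=antigen_id,
                peptide_offset=p_lo + start + 1,
                antigen_start=p_lo + d + start + 1,
                span=length,
                identities=ident,
            )
        )
    return hits


def map_peptides(
    peptides: list[str],
    antigens: dict[str, str],
    k: int = 4,
    min_identity: float = 0.7,
) -> list[SeedHit]:
    """seed_and_extend of every peptide against every antigen."""
    hits = []
    for pep in peptides:
        for aid, seq in antigens.items():
            hits.extend(seed_and_extend(pep, seq, aid, k=k, min_identity=min_identity))
    return hits


# ---------------------------------------------------------------------------
# pile-up epitope calling


def pileup_and_call(
    hits: list[SeedHit],
    antigens: dict[str, str],
    min_support: int = 3,
    min_core_len: int = 4,
    flank: int = 3,
    serum_id: str = "",
) -> list[EpitopeCall]:
    """Call epitopes for one serum from the per-residue peptide pile-up.

    Support at a residue = number of distinct peptides with a hit covering
    it; maximal runs with support >= min_support and length >= min_core_len
    become cores, printed with up to ``flank`` lowercase context residues
    each side (clipped at antigen ends).
    """
    calls: list[EpitopeCall] = []
    by_antigen: dict[str, list[SeedHit]] = {}
    for h in hits:
        by_antigen.setdefault(h.antigen_id, []).append(h)
    for aid in sorted(by_antigen):
        seq = antigens[aid]
        cover: dict[str, np.ndarray] = {}
        for h in by_antigen[aid]:
            mask = cover.setdefault(h.peptide, np.zeros(len(seq), dtype=bool))
            mask[h.antigen_start - 1:h.antigen_start - 1 + h.span] = True
        support = np.sum(list(cover.values()), axis=0) if cover else np.zeros(len(seq))
        above = support >= min_support
        i = 0
        while i < len(seq):
            if not above[i]:
                i += 1
                continue
            j = i
            while j < len(seq) and above[j]:
                j += 1
            if j - i >= min_core_len:
                lo = max(0, i - flank)
                hi = min(len(seq), j + flank)
                supporters = tuple(
                    sorted(p for p, m in cover.items() if m[i:j].any())
                )
                calls.append(
                    EpitopeCall(
                        antigen_id=aid,
                        start=i + 1,
                        core=seq[i:j],
                        flank_left=seq[lo:i],
                        flank_right=seq[j:hi],
                        n_support=int(support[i:j].max()),
                        sera=(serum_id,) if serum_id else (),
                        supporting_peptides=supporters,
                    )
                )
            i = j
    calls.sort(key=lambda c: (c.antigen_id, c.start))
    return calls


# ---------------------------------------------------------------------------
# cross-serum consensus and cross-species conservation


def consensus_across_sera(
    calls_by_serum: dict[str, list[EpitopeCall]],
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Group epitopes whose cores overlap across sera (transitive closure).

    Two calls on the same antigen belong to the same shared epitope when
    their cores overlap by >= min_overlap residues; grouping is the
    connected components of this overlap graph. Returns one row per group
    with per-serum detection flags (columns ``serum_<id>``).
    """
    if len(calls_by_serum) < 2:
        raise ValueError("need calls from at least two sera")
    flat = [
        (serum, call)
        for serum, calls in calls_by_serum.items()
        for call in calls
    ]
    parent = list(range(len(flat)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            ci, cj = flat[i][1], flat[j][1]
            if ci.antigen_id != cj.antigen_id:
                continue
            ov = min(ci.end, cj.end) - max(ci.start, cj.start) + 1
            if ov >= min_overlap:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(flat)):
        groups.setdefault(find(i), []).append(i)
    sera = sorted(calls_by_serum)
    rows = []
    for members in groups.values():
        calls = [flat[i][1] for i in members]
        present = {flat[i][0] for i in members}
        start = min(c.start for c in calls)
        end = max(c.end for c in calls)
        row = {
            "antigen_id": calls[0].antigen_id,
            "start": start,
            "end": end,
            "n_sera": len(present),
            "labels": ";".join(sorted({c.label for c in calls})),
        }
        for s in sera:
            row[f"serum_{s}"] = s in present
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(["antigen_id", "start"], kind="stable")
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class ConservationScore:
    epitope_label: str
    homolog_id: str
    identity_fraction: float
    homolog_start: int  # 1-based best placement
    aligned_window: str


def conservation(
    call: EpitopeCall | str,
    homolog_seq: str,
    homolog_id: str = "",
    label: str = "",
) -> ConservationScore:
    """Best ungapped placement of an epitope core on a homolog sequence."""
    core = call.core if isinstance(call, EpitopeCall) else call
    if not core:
        raise ValueError("empty epitope core")
    if len(homolog_seq) < len(core):
        raise ValueError("homolog shorter than epitope core")
    c = np.frombuffer(core.encode(), dtype="S1")
    h = np.frombuffer(homolog_seq.encode(), dtype="S1")
    best_ident, best_off = -1, 0
    for off in range(len(h) - len(c) + 1):
        ident = int((c == h[off:off + len(c)]).sum())
        if ident > best_ident:
            best_ident, best_off = ident, off
    return ConservationScore(
        epitope_label=(
            call.label if isinstance(call, EpitopeCall) else (label or core)
        ),
        homolog_id=homolog_id,
        identity_fraction=best_ident / len(core),
        homolog_start=best_off + 1,
        aligned_window=homolog_seq[best_off:best_off + len(core)],
    )


def epitope_table(calls: list[EpitopeCall]) -> pd.DataFrame:
    """Tabular report: one row per call with label and serum flags."""
    rows = [
        {
            "antigen_id": c.antigen_id,
            "start": c.start,
            "end": c.end,
            "label": c.label,
            "n_support": c.n_support,
            "sera": ";".join(c.sera),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["antigen_id", "start", "end", "label", "n_support", "sera"]
    )
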