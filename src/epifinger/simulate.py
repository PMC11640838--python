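"""Ground-truthed simulation of antigens and phage-display selection rounds.

The generator emulates the sequencing input of a two-round selection: a
naive random-peptide pool, a set of "spiked" peptides overlapping planted
epitopes whose frequency is multiplied by an enrichment factor each round,
multinomial sampling at a given depth, and fully-overlapping paired reads
with substitution errors. Every read traces back to a truth record.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scheme import PeptideLibraryScheme, _revcomp

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# antigens


def gen_antigens(
    n: int,
    length: int,
    epitope_fragments: list[str],
    seed: int,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Random protein antigens with epitope fragments embedded at known sites.

    Fragments are distributed round-robin over the ``n`` antigens and placed
    at non-overlapping uniform-random offsets in an otherwise uniform-random
    amino-acid background. Returns the FASTA records and an embedding map
    with 1-based start coordinates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for frag in epitope_fragments:
        if len(frag) > length:
            raise ValueError(
                f"fragment {frag!r} (len {len(frag)}) longer than antigen length {length}"
            )
        if set(frag) - set(AA_ALPHABET):
            raise ValueError(f"fragment {frag!r} contains non-standard residues")
    rng = np.random.default_rng(seed)
    seqs = [
        list(rng.choice(list(AA_ALPHABET), size=length)) for _ in range(n)
    ]
    rows = []
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for i, frag in enumerate(epitope_fragments):
        ai = i % n
        flen = len(frag)
        for _attempt in range(1000):
            start0 = int(rng.integers(0, length - flen + 1))
            window = (start0, start0 + flen)
            if all(window[1] <= a or window[0] >= b for a, b in occupied[ai]):
                break
        else:
            raise ValueError(
                f"could not place fragment {frag!r} without overlap in antigen {ai}"
            )
        occupied[ai].append(window)
        seqs[ai][start0:start0 + flen] = list(frag)
        rows.append(
            {"antigen_id": f"antigen_{ai+1}", "fragment": frag, "start": start0 + 1}
        )
    records = [
        SeqRecord(Seq("".join(s)), id=f"antigen_{i+1}", description="synthetic antigen")
        for i, s in enumerate(seqs)
    ]
    embedding = pd.DataFrame(rows, columns=["antigen_id", "fragment", "start"])
    return records, embedding


def write_fasta(records: list[SeqRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# selection rounds


@dataclass(frozen=True)
class SpikePlan:
    """One planted epitope: where it sits and how strongly it enriches."""

    antigen_id: str
    epitope_start: int  # 1-based residue index on the antigen
    epitope_length: int
    enrichment_factor_per_round: float
    n_distinct_peptides: int

    def __post_init__(self):
        if self.enrichment_factor_per_round < 1:
            raise ValueError("enrichment_factor_per_round must be >= 1")
        if self.epitope_start < 1 or self.epitope_length < 1:
            raise ValueError("epitope window must be positive and 1-based")


@dataclass
class SelectionSim:
    """In-memory result of a simulated selection experiment.

    ``truth`` has one row per (round, peptide) with sampled count and the
    model frequency; ``peptide_dna`` maps each pool peptide to the single
    insert DNA it was encoded with.
    """

    scheme: PeptideLibraryScheme
    truth: pd.DataFrame
    peptide_dna: dict[str, str]
    frequencies: pd.DataFrame  # peptide x round model frequencies
    error_rate: float
    seed: int
    _read_seed: int = field(default=0)

    @property
    def rounds(self) -> list[int]:
        return sorted(self.truth["round"].unique())

    def counts(self, round_id: int) -> pd.DataFrame:
        sub = self.truth[(self.truth["round"] == round_id) & (self.truth["count"] > 0)]
        return sub[["peptide", "count"]].reset_index(drop=True)

    def reads(self, round_id: int, quality: int = 37):
        """Yield (read_id, fwd_dna, rev_dna, qual) tuples for one round.

        Forward read = insert, reverse read = its reverse complement
        (full overlap); independent substitution errors on each mate.
        """
        rng = np.random.default_rng((self._read_seed, round_id))
        sub = self.truth[self.truth["round"] == round_id]
        i = 0
        for peptide, count in zip(sub["peptide"], sub["count"]):
            dna = self.peptide_dna[peptide]
            for _ in range(int(count)):
                fwd = _mutate(dna, self.error_rate, rng)
                rev = _mutate(_revcomp(dna), self.error_rate, rng)
                yield f"r{round_id}_{i}", fwd, rev, quality
                i += 1

    def write_fastq(self, outdir: str | os.PathLike, prefix: str = "sim") -> dict:
        """Write per-round paired FASTQ files; returns {round: (fwd, rev)} paths."""
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for r in self.rounds:
            f1 = os.path.join(outdir, f"{prefix}_round{r}_R1.fastq")
            f2 = os.path.join(outdir, f"{prefix}_round{r}_R2.fastq")
            with open(f1, "w") as fh1, open(f2, "w") as fh2:
                for rid, fwd, rev, q in self.reads(r):
                    qs = chr(q + 33)
                    fh1.write(f"@{rid}/1\n{fwd}\n+\n{qs * len(fwd)}\n")
                    fh2.write(f"@{rid}/2\n{rev}\n+\n{qs * len(rev)}\n")
            paths[r] = (f1, f2)
        return paths


def _mutate(dna: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0:
        return dna
    arr = np.frombuffer(dna.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if len(hits) == 0:
        return dna
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        alt = bases[bases != arr[i]]
        arr[i] = alt[rng.integers(3)]
    return arr.tobytes().decode()


def _spike_peptides(
    spike: SpikePlan,
    antigen_seq: str,
    n_codons: int,
    min_core_overlap: int,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Peptides carrying a window of the epitope, padded with random residues.

    Returns (peptide, epitope_overlap_start_on_antigen) pairs. Each peptide
    contains a contiguous antigen window of at least ``min_core_overlap``
    residues overlapping the epitope, at a random offset inside the peptide.
    """
    epi0 = spike.epitope_start - 1
    epi1 = epi0 + spike.epitope_length
    if epi1 > len(antigen_seq):
        raise ValueError("epitope window outside antigen")
    out = []
    for _ in range(spike.n_distinct_peptides):
        core_len = min(n_codons, max(min_core_overlap, spike.epitope_length))
        core_len = min(core_len, spike.epitope_length)
        # random sub-window of the epitope of core_len residues
        cstart = epi0 + int(rng.integers(0, spike.epitope_length - core_len + 1))
        core = antigen_seq[cstart:cstart + core_len]
        pad = n_codons - core_len
        left = int(rng.integers(0, pad + 1))
        flanks = rng.choice(list(AA_ALPHABET), size=pad)
        pep = "".join(flanks[:left]) + core + "".join(flanks[left:])
        out.append((pep, cstart + 1))
    return out


def simulate_count_tables(
    n_peptides: int,
    depth: int,
    seed: int,
    enrichment_factors: dict[int, float] | None = None,
    n_rounds: int = 2,
    peptide_length: int = 12,
):
    """Count-level selection simulation (no reads rendered).

    The same frequency model as gen_selection_reads — uniform naive pool,
    per-round multiplication of spiked peptides' frequencies by their
    enrichment factor, multinomial sampling — applied directly at the
    count level. ``enrichment_factors`` maps peptide pool indices to
    per-round factors. Returns (tables, spiked_peptides): one curated-style
    PeptideCountTable per round and the spiked peptide strings.
    """
    from .processing import PeptideCountTable

    rng = np.random.default_rng(seed)
    peptides = []
    seen = set()
    while len(peptides) < n_peptides:
        pep = "".join(rng.choice(list(AA_ALPHABET), size=peptide_length))
        if pep not in seen:
            seen.add(pep)
            peptides.append(pep)
    factors = np.ones(n_peptides)
    for idx, f in (enrichment_factors or {}).items():
        factors[idx] = f
    naive = np.full(n_peptides, 1.0 / n_peptides)
    tables = []
    for r in range(n_rounds + 1):
        w = naive * factors ** r
        freqs = w / w.sum()
        counts = rng.multinomial(depth, freqs)
        nz = counts > 0
        table = pd.DataFrame(
            {"peptide": np.array(peptides)[nz], "count": counts[nz]}
        ).sort_values(["count", "peptide"], ascending=[False, True], kind="stable")
        table["frequency"] = table["count"] / counts.sum()
        tables.append(
            PeptideCountTable(
                round_id=r,
                table=table.reset_index(drop=True),
                total_reads=int(counts.sum()),
                rejected={},
            )
        )
    spiked = [peptides[i] for i in (enrichment_factors or {})]
    return tables, spiked


def gen_selection_reads(
    scheme: PeptideLibraryScheme,
    antigens: list[SeqRecord],
    spikes: list[SpikePlan],
    depth_per_round: int | list[int],
    error_rate: float,
    seed: int,
    n_rounds: int = 2,
    n_background_peptides: int = 1000,
    min_core_overlap: int = 6,
) -> SelectionSim:
    """Simulate naive + selection rounds of a peptide phage display.

    Round 0 is the naive pool: ``n_background_peptides`` random peptides
    plus the spiked peptides, all at uniform frequency. In round r a spiked
    peptide's frequency is multiplied by ``enrichment_factor_per_round**r``
    and the pool renormalized; counts are multinomial at the round's depth.
    """
    if error_rate < 0 or error_rate >= 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    depths = (
        [int(depth_per_round)] * (n_rounds + 1)
        if np.isscalar(depth_per_round)
        else list(depth_per_round)
    )
    if len(depths) != n_rounds + 1 or any(d < 1 for d in depths):
        raise ValueError("need a positive depth for each round incl. naive")

    rng = np.random.default_rng(seed)
    by_id = {rec.id: str(rec.seq) for rec in antigens}

    peptides: list[str] = []
    meta: list[dict] = []
    seen: set[str] = set()
    for si, spike in enumerate(spikes):
        if spike.antigen_id not in by_id:
            raise ValueError(f"unknown antigen {spike.antigen_id!r}")
        for pep, ov_start in _spike_peptides(
            spike, by_id[spike.antigen_id], scheme.n_codons, min_core_overlap, rng
        ):
            if pep in seen:
                continue
            seen.add(pep)
            peptides.append(pep)
            meta.append(
                {
                    "spike_index": si,
                    "antigen_id": spike.antigen_id,
                    "overlap_start": ov_start,
                    "enrichment_factor": spike.enrichment_factor_per_round,
                }
            )
    aa_table = scheme.codons_for_aa()
    encodable = sorted(aa_table)
    n_spiked = len(peptides)
    while len(peptides) < n_spiked + n_background_peptides:
        pep = "".join(rng.choice(encodable, size=scheme.n_codons))
        if pep in seen:
            continue
        seen.add(pep)
        peptides.append(pep)
        meta.append(
            {
                "spike_index": -1,
                "antigen_id": "",
                "overlap_start": 0,
                "enrichment_factor": 1.0,
            }
        )

    factors = np.array([m["enrichment_factor"] for m in meta])
    naive = np.full(len(peptides), 1.0 / len(peptides))
    freq_rows = {}
    truth_rows = []
    for r in range(n_rounds + 1):
        w = naive * factors ** r
        freqs = w / w.sum()
        freq_rows[r] = freqs
        counts = rng.multinomial(depths[r], freqs)
        for pep, m, f, c in zip(peptides, meta, freqs, counts):
            truth_rows.append(
                {
                    "round": r,
                    "peptide": pep,
                    "count": int(c),
                    "frequency": f,
                    "spike_index": m["spike_index"],
                    "antigen_id": m["antigen_id"],
                    "overlap_start": m["overlap_start"],
                }
            )
    truth = pd.DataFrame(truth_rows)
    frequencies = pd.DataFrame(
        freq_rows, index=pd.Index(peptides, name="peptide")
    )
    peptide_dna = {pep: scheme.encode_peptide(pep, rng) for pep in peptides}
    return SelectionSim(
        scheme=scheme,
        truth=truth,
        peptide_dna=peptide_dna,
        frequencies=frequencies,
        error_rate=error_rate,
        seed=seed,
        _read_seed=int(rng.integers(2**31)),
    )
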