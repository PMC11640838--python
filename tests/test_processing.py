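"""Read merging and curation into peptide count tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epifinger import (
    MergedRead,
    gen_antigens,
    gen_selection_reads,
    merge_pair,
    process_simulation,
    translate_and_count,
)
from epifinger.processing import NO_OVERLAP
from epifinger.scheme import _revcomp


def q(n, val=30):
    return [val] * n


def merge_oracle(fwd, rev, min_overlap, max_mismatch_frac):
    """Enumerate every offset of rc(rev) against fwd; best = most matches,
    then longest overlap. Independent of the implementation's vectorization."""
    rc = _revcomp(rev)
    best = None
    for off in range(-(len(rc) - 1), len(fwd)):
        lo = max(0, off)
        hi = min(len(fwd), off + len(rc))
        ov = hi - lo
        if ov < min_overlap:
            continue
        matches = sum(fwd[i] == rc[i - off] for i in range(lo, hi))
        if (ov - matches) / ov > max_mismatch_frac:
            continue
        cand = (matches, ov, -abs(off), off)
        if best is None or cand[:3] > best[:3]:
            best = cand
    return best


class TestMergePair:
    def test_exact_reverse_complement_gives_identity(self):
        insert = "ACGTACGTGGATCCTTAA"
        m = merge_pair(insert, _revcomp(insert), q(18), q(18), min_overlap=10)
        assert isinstance(m, MergedRead)
        assert m.dna == insert
        assert m.overlap_len == len(insert)

    def test_min_overlap_boundary(self):
        fwd = "ACGTACGTACGTACGTACGT"  # 20 nt
        rev = _revcomp(fwd[-10:])     # overlaps last 10 exactly
        ok = merge_pair(fwd, rev, q(20), q(10), min_overlap=10)
        assert isinstance(ok, MergedRead) and ok.overlap_len == 10
        rej = merge_pair(fwd, rev, q(20), q(10), min_overlap=11)
        assert rej == NO_OVERLAP

    def test_disagreement_resolved_by_quality(self):
        insert = "ACGTACGTACGTACGTACGT"
        rev_seq = list(_revcomp(insert))
        # corrupt the base of the reverse read covering insert position 5
        pos = len(insert) - 1 - 5
        rev_seq[pos] = "G" if rev_seq[pos] != "G" else "C"
        rev = "".join(rev_seq)
        hi_fwd = merge_pair(insert, rev, q(20, 40), q(20, 10), min_overlap=10)
        assert hi_fwd.dna == insert  # fwd Q40 beats rev Q10
        hi_rev = merge_pair(insert, rev, q(20, 10), q(20, 40), min_overlap=10)
        assert hi_rev.dna != insert
        assert hi_rev.dna[5] == _revcomp(rev)[5]

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1))
    def test_offset_choice_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(18, 40))
        insert = "".join(rng.choice(list("ACGT"), size=n))
        k = int(rng.integers(12, n + 1))
        rev = _revcomp(insert[-k:])
        # sprinkle up to 2 errors into the reverse read
        rev = list(rev)
        for _ in range(int(rng.integers(0, 3))):
            i = int(rng.integers(len(rev)))
            rev[i] = "ACGT"[int(rng.integers(4))]
        rev = "".join(rev)
        got = merge_pair(insert, rev, q(n), q(k), min_overlap=8,
                         max_mismatch_frac=0.25)
        want = merge_oracle(insert, rev, 8, 0.25)
        if want is None:
            assert got == NO_OVERLAP
        else:
            assert isinstance(got, MergedRead)
            assert got.overlap_len == want[1]

    def test_empty_read_raises(self):
        with pytest.raises(ValueError):
            merge_pair("", "ACGT", [], q(4))


class TestTranslateAndCount:
    def test_aggregation_and_frequencies(self, scheme, rng):
        var = scheme.random_variable_dna(rng)
        var2 = scheme.random_variable_dna(rng)
        mk = lambda v: MergedRead(scheme.flank5 + v + scheme.flank3, 35.0, 40)
        table = translate_and_count([mk(var), mk(var), mk(var2)], scheme)
        assert table.total_reads == 3
        counts = dict(zip(table.table["peptide"], table.table["count"]))
        assert sorted(counts.values(), reverse=True) == [2, 1]
        freqs = sorted(table.table["frequency"], reverse=True)
        assert freqs == pytest.approx([2 / 3, 1 / 3])

    def test_synonymous_codons_aggregate(self, scheme):
        pep = "A" * scheme.n_codons
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(99)
        d1, d2 = scheme.encode_peptide(pep, rng1), scheme.encode_peptide(pep, rng2)
        assert d1 != d2  # different codon choices
        table = translate_and_count(
            [MergedRead(d1, 35, 40), MergedRead(d2, 35, 40)], scheme
        )
        assert len(table.table) == 1
        assert table.table.loc[0, "count"] == 2

    def test_rejection_reasons_conserve_reads(self, scheme, rng):
        good = MergedRead(
            scheme.flank5 + scheme.random_variable_dna(rng) + scheme.flank3, 35, 40
        )
        bad_flank = MergedRead("A" * scheme.insert_length, 35, 40)
        low_q = MergedRead(good.dna, 10.0, 40)
        table = translate_and_count([good, bad_flank, low_q, NO_OVERLAP], scheme)
        assert table.accepted_reads + sum(table.rejected.values()) == 4
        assert table.rejected["flank_mismatch"] == 1
        assert table.rejected["low_quality"] == 1
        assert table.rejected[NO_OVERLAP] == 1


class TestRoundTrip:
    def test_error_free_simulation_recovers_truth_exactly(self, scheme):
        records, _ = gen_antigens(1, 80, [], seed=2)
        sim = gen_selection_reads(
            scheme, records, [], 1500, 0.0, seed=8, n_background_peptides=300
        )
        table = process_simulation(sim, 0)
        truth = sim.counts(0)
        got = dict(zip(table.table["peptide"], table.table["count"]))
        want = dict(zip(truth["peptide"], truth["count"]))
        assert got == want
        assert all(v == 0 for v in table.rejected.values())

    def test_mismatch_tolerance_monotonicity(self, scheme):
        """Raising max_mismatch_frac never decreases the accepted count."""
        records, _ = gen_antigens(1, 80, [], seed=2)
        sim = gen_selection_reads(
            scheme, records, [], 400, 0.02, seed=8, n_background_peptides=100
        )
        accepted = []
        for frac in (0.0, 0.05, 0.15, 0.3):
            merged = [
                merge_pair(f, r, q(len(f)), q(len(r)), 20, frac)
                for _i, f, r, _q in sim.reads(1)
            ]
            accepted.append(
                sum(1 for m in merged if isinstance(m, MergedRead))
            )
        assert accepted == sorted(accepted)
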