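"""Seeded ungapped alignment, epitope calling, consensus, conservation."""

import numpy as np
import pytest

from epifinger import (
    EpitopeCall,
    conservation,
    consensus_across_sera,
    parse_label,
    pileup_and_call,
    seed_and_extend,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def best_window_oracle(peptide, antigen, k, min_identity):
    """Exhaustive offset/window scan: for every diagonal and every window,
    keep the admissible window (contains a k-run of matches, identity >=
    min_identity) maximizing identities, tie-broken shortest then leftmost.
    Returns {diagonal: (pep_start0, ant_start0, length, identities)}."""
    out = {}
    for d in range(-(len(peptide) - 1), len(antigen)):
        p_lo, p_hi = max(0, -d), min(len(peptide), len(antigen) - d)
        if p_hi - p_lo < k:
            continue
        match = [peptide[i] == antigen[i + d] for i in range(p_lo, p_hi)]
        best = None
        n = len(match)
        for i in range(n):
            for j in range(i + k, n + 1):
                window = match[i:j]
                ident = sum(window)
                if ident / (j - i) < min_identity:
                    continue
                has_run = any(
                    all(window[t:t + k]) for t in range(len(window) - k + 1)
                )
                if not has_run:
                    continue
                cand = (ident, -(j - i), -i)
                if best is None or cand > best[:3]:
                    best = (ident, -(j - i), -i, i, j - i)
        if best is not None:
            i, length = best[3], best[4]
            out[d] = (p_lo + i, p_lo + d + i, length, best[0])
    return out


class TestSeedAndExtend:
    def test_exact_substring_full_identity(self):
        antigen = "MKT" + "DHNDQQFQCA" + "LVRS"
        hits = seed_and_extend("DHNDQQFQCA", antigen, "a1")
        assert len(hits) == 1
        h = hits[0]
        assert (h.antigen_start, h.span, h.identities) == (4, 10, 10)

    def test_single_central_mismatch_spans_full_window(self):
        antigen = "WWWW" + "DHNDAQFQCA" + "WWWW"  # Q->A at window position 5
        hits = seed_and_extend("DHNDQQFQCA", antigen, k=4, min_identity=0.8)
        assert len(hits) == 1
        assert (hits[0].span, hits[0].identities) == (10, 9)

    def test_no_shared_kmer_gives_empty(self):
        assert seed_and_extend("AAAA", "WWWWWWWW", k=4) == []

    def test_k_longer_than_peptide_rejected(self):
        with pytest.raises(ValueError):
            seed_and_extend("AAA", "AAAAAA", k=4)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan_on_random_pairs(self, seed):
        """Implementation (seeded diagonals + prefix sums) vs the exhaustive
        offset/window oracle, on random pairs with planted similarity."""
        rng = np.random.default_rng(seed)
        for _ in range(60):
            ant = "".join(rng.choice(AA, size=int(rng.integers(30, 80))))
            if rng.random() < 0.6:  # plant a mutated window of the antigen
                a0 = int(rng.integers(0, len(ant) - 12))
                pep = list(ant[a0:a0 + 12])
                for _m in range(int(rng.integers(0, 3))):
                    pep[int(rng.integers(12))] = str(rng.choice(AA))
                pep = "".join(pep)
            else:
                pep = "".join(rng.choice(AA, size=12))
            got = {
                (h.peptide_offset - 1, h.antigen_start - 1, h.span, h.identities)
                for h in seed_and_extend(pep, ant, k=4, min_identity=0.7)
            }
            want = set(best_window_oracle(pep, ant, 4, 0.7).values())
            assert got == want


class TestPileupAndCall:
    def test_three_full_cover_peptides_one_core(self):
        antigen = {"a1": "W" * 62 + "DHNDQQFQCA" + "W" * 10}
        peptides = ["XX" + "DHNDQQFQCA", "DHNDQQFQCA" + "YY", "Y" + "DHNDQQFQCA" + "X"]
        hits = [
            h for p in peptides for h in seed_and_extend(p, antigen["a1"], "a1")
        ]
        calls = pileup_and_call(hits, antigen, min_support=3, serum_id="R1")
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.core) == (63, "DHNDQQFQCA")
        assert c.label == "60-wwwDHNDQQFQCAwww"

    def test_support_run_length_scan(self):
        """Support pattern 2,3,3,3,2 with min_support=3 -> middle 3 only.

        Oracle: the core is the maximal run of residues covered by >= 3
        distinct peptides, computed here by construction of the hits.
        """
        from epifinger.mapping import SeedHit

        antigen = {"a1": "ABCDEFGHIK".replace("B", "N")}  # any 10-mer
        seq = antigen["a1"]
        mk = lambda pep, start, span: SeedHit(pep, "a1", 1, start, span, span)
        hits = [
            mk("p1", 3, 5),  # covers 3-7
            mk("p2", 3, 5),
            mk("p3", 4, 3),  # covers 4-6
        ]
        calls = pileup_and_call(hits, antigen, min_support=3, min_core_len=3)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (4, 6)
        assert calls[0].core == seq[3:6]

    def test_insufficient_support_no_calls(self):
        antigen = {"a1": "W" * 30 + "DHNDQQFQCA" + "W" * 5}
        hits = seed_and_extend("DHNDQQFQCA", antigen["a1"], "a1")
        assert pileup_and_call(hits, antigen, min_support=3) == []

    def test_flank_clipped_at_antigen_ends(self):
        antigen = {"a1": "DHNDQQFQCA" + "W" * 6}
        peptides = [f"{x}{'DHNDQQFQCA'}{y}" for x, y in
                    [("C", "W"), ("L", "M"), ("V", "S")]]
        hits = [h for p in peptides for h in seed_and_extend(p, antigen["a1"], "a1")]
        calls = pileup_and_call(hits, antigen, min_support=3)
        assert calls and calls[0].flank_left == ""
        assert calls[0].label.startswith("1-")


class TestLabels:
    @pytest.mark.parametrize("seed", range(20))
    def test_label_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        core = "".join(rng.choice(AA, size=int(rng.integers(4, 16))))
        fl = "".join(rng.choice(AA, size=int(rng.integers(0, 4))))
        fr = "".join(rng.choice(AA, size=int(rng.integers(0, 4))))
        call = EpitopeCall(
            antigen_id="a1", start=int(rng.integers(1, 300)), core=core,
            flank_left=fl, flank_right=fr, n_support=3,
        )
        back = parse_label(call.label, antigen_id="a1", n_support=3)
        assert (back.start, back.core, back.flank_left, back.flank_right) == (
            call.start, call.core, call.flank_left, call.flank_right
        )

    def test_table1_style_label_parses(self):
        call = parse_label("124-kgdHEINaee")
        assert (call.start, call.core) == (127, "HEIN")
        assert (call.flank_left, call.flank_right) == ("KGD", "AEE")


class TestConsensus:
    def mk(self, antigen, start, core_len, serum):
        return EpitopeCall(
            antigen_id=antigen, start=start, core="A" * core_len,
            flank_left="", flank_right="", n_support=3, sera=(serum,),
        )

    def test_overlapping_cores_grouped(self):
        out = consensus_across_sera(
            {"R1": [self.mk("a1", 124, 10, "R1")],
             "R2": [self.mk("a1", 126, 6, "R2")]},
            min_overlap=4,
        )
        assert len(out) == 1
        assert out.loc[0, "serum_R1"] and out.loc[0, "serum_R2"]
        assert out.loc[0, "n_sera"] == 2

    def test_disjoint_cores_stay_separate(self):
        out = consensus_across_sera(
            {"R1": [self.mk("a1", 10, 6, "R1")],
             "R2": [self.mk("a1", 40, 6, "R2")]},
        )
        assert len(out) == 2
        assert (out["n_sera"] == 1).all()

    def test_transitive_closure_matches_brute_force_components(self):
        """Pairwise-overlap graph components vs brute-force BFS."""
        rng = np.random.default_rng(4)
        sera = {f"S{s}": [
            self.mk("a1", int(rng.integers(1, 120)), int(rng.integers(4, 12)), f"S{s}")
            for _ in range(6)
        ] for s in range(3)}
        out = consensus_across_sera(sera, min_overlap=4)
        flat = [(s, c) for s, calls in sera.items() for c in calls]
        # brute-force connected components
        n = len(flat)
        adj = [[False] * n for _ in range(n)]
        for i in range(n):
            for j in range(n):
                ci, cj = flat[i][1], flat[j][1]
                ov = min(ci.end, cj.end) - max(ci.start, cj.start) + 1
                adj[i][j] = i != j and ov >= 4
        seen, n_comp = set(), 0
        for s0 in range(n):
            if s0 in seen:
                continue
            n_comp += 1
            stack = [s0]
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                stack.extend(v for v in range(n) if adj[u][v])
        assert len(out) == n_comp

    def test_requires_two_sera(self):
        with pytest.raises(ValueError):
            consensus_across_sera({"R1": []})


class TestConservation:
    def test_identical_window_scores_one(self):
        hom = "LLL" + "NNYANQLDENPR" + "KKK"
        sc = conservation("NNYANQLDENPR", hom, "homolog1")
        assert sc.identity_fraction == 1.0
        assert sc.homolog_start == 4

    def test_two_substitutions_scanned_over_all_offsets(self):
        core = "NNYANQLDENPR"
        window = "NNYAAQLDENPK"  # 2 substitutions
        hom = "GG" + window + "GG"
        sc = conservation(core, hom)
        # oracle: scan every offset by hand
        best = max(
            sum(a == b for a, b in zip(core, hom[o:o + len(core)]))
            for o in range(len(hom) - len(core) + 1)
        )
        assert best == 10
        assert sc.identity_fraction == pytest.approx(10 / 12)

    def test_unrelated_homolog_low_identity(self):
        rng = np.random.default_rng(1)
        core = "NNYANQLDENPR"
        hom = "".join(rng.choice([a for a in AA], size=200))
        sc = conservation(core, hom)
        assert sc.identity_fraction <= 0.5

    def test_short_homolog_rejected(self):
        with pytest.raises(ValueError):
            conservation("NNYANQLDENPR", "SHORT")
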