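"""Map enriched peptides onto antigens and call epitopes.

Runs the full in-memory pipeline for two synthetic sera that share one
planted epitope, then forms the cross-serum consensus — the analogue of
reporting which epitopes are seen by both animals.
"""

import epifinger as ef

antigens, _ = ef.gen_antigens(1, 160, [], seed=3)
seqs = {r.id: str(r.seq) for r in antigens}

# two sera: both react with the window at 40, each has one private epitope
plans = {
    "R1": [ef.SpikePlan("antigen_1", 40, 10, 8.0, 5),
           ef.SpikePlan("antigen_1", 90, 10, 8.0, 5)],
    "R2": [ef.SpikePlan("antigen_1", 40, 10, 8.0, 5),
           ef.SpikePlan("antigen_1", 130, 10, 8.0, 5)],
}
calls_by_serum = {}
for serum, spikes in plans.items():
    sim = ef.gen_selection_reads(
        ef.DEFAULT_SCHEME, antigens, spikes, 8000, 0.002,
        seed=100 + len(serum), n_background_peptides=500,
    )
    t0, t2 = ef.process_simulation(sim, 0), ef.process_simulation(sim, 2)
    enriched = ef.select_enriched(ef.score_enrichment(t0, t2))
    hits = ef.map_peptides(enriched, seqs)
    calls = ef.pileup_and_call(hits, seqs, serum_id=serum)
    calls_by_serum[serum] = calls
    print(f"{serum}: {len(enriched)} enriched peptides ->",
          [c.label for c in calls])

consensus = ef.consensus_across_sera(calls_by_serum)
print("\ncross-serum consensus (epitopes grouped when cores overlap >= 4):")
print(consensus.to_string(index=False))

# Labels follow the mixed-case convention: uppercase = core residues
# covered by >= 3 distinct peptides, lowercase = flanking context, and the
# leading number is the 1-based position of the first printed residue.
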