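"""Ground-truth validation experiments.

Each function runs one stage (or the whole pipeline) on synthetic data
from the generators and measures how well the known truth is recovered.
They return plain dicts of measured quantities and are used both by the
test suite and by scripts that summarize pipeline performance. Problem
sizes are arguments with defaults matching the package's standard study
conditions (two selection rounds, read depth 10^4, quadruplicate spots).
"""

from __future__ import annotations

import tempfile

import numpy as np
import pandas as pd

from .arrayquant import GridTransform, detect_grid, quantify_image
from .enrichment import score_enrichment, select_enriched
from .gal import make_layout
from .mapping import consensus_across_sera, map_peptides, pileup_and_call
from .processing import process_fastq_pair, process_simulation
from .simulate import SpikePlan, gen_antigens, gen_selection_reads, simulate_count_tables
from .simulate_image import gen_array_image
from .stability import DEFAULT_CONDITIONS, HEAT_LABILE, HEAT_STABLE, classify_stability


def _sub(seed: int, k: int) -> int:
    return int(np.random.default_rng((seed, k)).integers(2**31))


# ---------------------------------------------------------------------------
# curation


def curation_roundtrip(
    seed: int,
    depth: int = 10_000,
    error_rate: float = 0.0,
    n_background_peptides: int = 1000,
    via_fastq: bool = True,
) -> dict:
    """Simulate error-free selection reads, curate them, compare to truth.

    With error_rate 0 every read must survive curation and the recovered
    per-round peptide counts must equal the generator's truth table
    exactly. Returns the number of reads processed and discrepancies.
    """
    antigens, _ = gen_antigens(2, 150, [], seed=_sub(seed, 1))
    spikes = [SpikePlan("antigen_1", 40, 10, 5.0, 3)]
    sim = gen_selection_reads(
        sim_scheme(), antigens, spikes, depth, error_rate, _sub(seed, 2),
        n_background_peptides=n_background_peptides,
    )
    n_reads = 0
    n_discrepancies = 0
    for r in sim.rounds:
        if via_fastq:
            with tempfile.TemporaryDirectory() as d:
                paths = {r: sim.write_fastq(d, prefix=f"r{r}")[r]}
                table = process_fastq_pair(*paths[r], sim.scheme, round_id=r)
        else:
            table = process_simulation(sim, r)
        n_reads += table.total_reads
        got = dict(zip(table.table["peptide"], table.table["count"]))
        truth = sim.counts(r)
        want = dict(zip(truth["peptide"], truth["count"]))
        n_discrepancies += sum(
            1 for k in set(got) | set(want) if got.get(k, 0) != want.get(k, 0)
        )
        n_discrepancies += sum(table.rejected.values())
    return {
        "n_reads": n_reads,
        "n_rounds": len(sim.rounds),
        "n_discrepancies": n_discrepancies,
        "exact": n_discrepancies == 0,
    }


def sim_scheme():
    from .scheme import DEFAULT_SCHEME

    return DEFAULT_SCHEME


# ---------------------------------------------------------------------------
# enrichment calibration


def enrichment_calibration(
    seed: int,
    n_reps: int = 20,
    n_peptides: int = 1000,
    depth: int = 10_000,
    spike_factor: float = 5.0,
    n_spikes: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Type-I control under the no-spike null and power on spiked pools.

    Count-level simulations drawn from the generator's frequency model:
    ``n_reps`` null pools (no enrichment) give the flagged fraction, and
    ``n_reps`` spiked pools (``n_spikes`` peptides at ``spike_factor`` per
    round) give the sensitivity.
    """
    null_fracs = []
    for rep in range(n_reps):
        tables, _ = simulate_count_tables(
            n_peptides, depth, _sub(seed, 100 + rep)
        )
        rec = score_enrichment(tables[0], tables[2], alpha=alpha)
        null_fracs.append(rec["enriched"].sum() / max(len(rec), 1))
    hits = misses = 0
    for rep in range(n_reps):
        factors = {i: spike_factor for i in range(n_spikes)}
        tables, spiked = simulate_count_tables(
            n_peptides, depth, _sub(seed, 200 + rep), enrichment_factors=factors
        )
        rec = score_enrichment(tables[0], tables[2], alpha=alpha)
        flagged = set(select_enriched(rec, alpha=alpha))
        hits += sum(p in flagged for p in spiked)
        misses += sum(p not in flagged for p in spiked)
    null_fracs = np.asarray(null_fracs, dtype=float)
    se = float(null_fracs.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return {
        "n_reps": n_reps,
        "null_flagged_fraction": float(null_fracs.mean()),
        "null_flagged_se": se,
        "sensitivity": hits / max(hits + misses, 1),
    }


# ---------------------------------------------------------------------------
# epitope recovery (full pipeline)


def epitope_recovery(
    seed: int,
    n_replicates: int = 4,
    n_sera: int = 2,
    n_antigens: int = 2,
    antigen_length: int = 170,
    epitopes_per_set: int = 10,
    epitope_length: int = 10,
    depth: int = 10_000,
    error_rate: float = 0.002,
    factor: float = 8.0,
    peptides_per_epitope: int = 5,
    n_background_peptides: int = 800,
    tolerance: int = 2,
) -> dict:
    """End-to-end planted-epitope recovery over replicate antigen sets.

    Per replicate: random antigens with ``epitopes_per_set`` planted
    epitope windows (a subset planted in every serum), per-serum selection
    reads, curation, enrichment, mapping, and pile-up calling. An epitope
    counts as recovered for a serum when a call on the right antigen has
    both boundaries within ``tolerance`` residues of the planted window; a
    call matching no planted window is a false call. Cross-serum consensus
    must group the epitopes planted in several sera.
    """
    starts = np.arange(epitopes_per_set // n_antigens) * 30 + 20
    recovered = planted = 0
    false_calls = []
    consensus_hits = consensus_total = 0
    for rep in range(n_replicates):
        rs = _sub(seed, 300 + rep)
        antigens, _ = gen_antigens(n_antigens, antigen_length, [], seed=rs)
        ant_seqs = {r.id: str(r.seq) for r in antigens}
        windows = [
            (f"antigen_{a+1}", int(s), int(s) + epitope_length - 1)
            for a in range(n_antigens)
            for s in starts
        ][:epitopes_per_set]
        # first `n_shared` windows are planted in every serum
        n_shared = max(2, epitopes_per_set // 3)
        per_serum_windows = {}
        for s in range(n_sera):
            own = [
                w for i, w in enumerate(windows)
                if i < n_shared or i % n_sera == s
            ]
            per_serum_windows[f"S{s+1}"] = own
        calls_by_serum = {}
        for s, (serum, own) in enumerate(per_serum_windows.items()):
            spikes = [
                SpikePlan(aid, start, epitope_length, factor, peptides_per_epitope)
                for aid, start, _end in own
            ]
            sim = gen_selection_reads(
                sim_scheme(), antigens, spikes, depth, error_rate,
                _sub(seed, 400 + rep * 10 + s),
                n_background_peptides=n_background_peptides,
            )
            t0 = process_simulation(sim, 0)
            t2 = process_simulation(sim, 2)
            enriched = select_enriched(score_enrichment(t0, t2))
            hits = map_peptides(enriched, ant_seqs)
            calls = pileup_and_call(hits, ant_seqs, serum_id=serum)
            calls_by_serum[serum] = calls
            matched_calls = set()
            for aid, start, end in own:
                planted += 1
                ok = [
                    i for i, c in enumerate(calls)
                    if c.antigen_id == aid
                    and abs(c.start - start) <= tolerance
                    and abs(c.end - end) <= tolerance
                ]
                if ok:
                    recovered += 1
                    matched_calls.update(ok)
            false_calls.append(len(calls) - len(matched_calls))
        shared = windows[:n_shared]
        cons = consensus_across_sera(calls_by_serum)
        for aid, start, end in shared:
            consensus_total += 1
            hit = cons[
                (cons["antigen_id"] == aid)
                & (cons["start"] <= end)
                & (cons["end"] >= start)
                & (cons["n_sera"] >= 2)
            ]
            if len(hit):
                consensus_hits += 1
    return {
        "n_replicates": n_replicates,
        "n_planted": planted,
        "recovered_fraction": recovered / planted,
        "false_calls_per_set": float(np.mean(false_calls)),
        "max_false_calls_per_set": int(np.max(false_calls)),
        "consensus_recovered_fraction": (
            consensus_hits / consensus_total if consensus_total else 1.0
        ),
    }


# ---------------------------------------------------------------------------
# array quantification


def _demo_array(seed: int, n_peptides: int = 18):
    rng = np.random.default_rng(seed)
    ids = [f"pep_{i:03d}" for i in range(n_peptides)]
    layout = make_layout(ids)
    intensities = {
        pid: float(np.exp(rng.uniform(np.log(5000), np.log(40000)))) for pid in ids
    }
    intensities["water"] = 2000.0
    return layout, intensities


def array_end_to_end(
    seed: int,
    noise_frac: float = 0.02,
    transform: GridTransform = GridTransform(0.4, 2.0, -1.5),
) -> dict:
    """Measured fold-over-water vs generator truth, noiseless and noisy.

    The noiseless scan must reproduce the truth folds exactly (the
    segmentation captures each spot's full quantized support); with
    Gaussian noise of ``noise_frac`` times the median spot amplitude the
    folds must stay close. Outlier spots are planted and must be fenced.
    """
    layout, intensities = _demo_array(_sub(seed, 7))
    prof_area = np.pi * layout.spot_radius**2  # rough per-spot pixel count
    med_amp = float(np.median(list(intensities.values()))) / prof_area
    out = {}
    for label, noise_sd in (("noiseless", 0.0), ("noisy", noise_frac * med_amp)):
        img, truth = gen_array_image(
            layout, intensities, _sub(seed, 8), transform=transform,
            noise_sd=noise_sd, outlier_fraction=0.1, outlier_factor=8.0,
        )
        result = quantify_image(img, layout)
        tf = truth.group_fold_truth(layout).set_index("id")["true_fold"]
        mf = result.summaries.set_index("id")["adjusted"]
        rel = ((mf - tf).abs() / tf).max()
        out[f"{label}_max_rel_fold_error"] = float(rel)
        out[f"{label}_max_abs_fold_error"] = float((mf - tf).abs().max())
    out["n_peptides"] = len(tf)
    return out


def grid_recovery(
    seed: int,
    n_transforms: int = 100,
    max_rotation: float = 1.0,
    max_shift: float = 4.0,
) -> dict:
    """Worst-case grid-pose recovery error over random transforms."""
    layout, intensities = _demo_array(_sub(seed, 9))
    rng = np.random.default_rng(_sub(seed, 10))
    rot_err = []
    shift_err = []
    for i in range(n_transforms):
        tr = GridTransform(
            float(rng.uniform(-max_rotation, max_rotation)),
            float(rng.uniform(-max_shift, max_shift)),
            float(rng.uniform(-max_shift, max_shift)),
        )
        img, _ = gen_array_image(
            layout, intensities, _sub(seed, 1000 + i), transform=tr,
            noise_sd=0.0, outlier_fraction=0.0,
        )
        got = detect_grid(img, layout)
        rot_err.append(abs(got.rotation - tr.rotation))
        shift_err.append(max(abs(got.dx - tr.dx), abs(got.dy - tr.dy)))
    return {
        "n_transforms": n_transforms,
        "max_rotation_error_deg": float(np.max(rot_err)),
        "max_shift_error_px": float(np.max(shift_err)),
    }


# ---------------------------------------------------------------------------
# stability


def stability_recovery(
    seed: int,
    n_analytes: int = 40,
    labile_cutoff: float = 0.5,
    margin: float = 0.05,
) -> dict:
    """Label recovery on planted retention ratios and scale invariance.

    Ratios are drawn outside cutoff +/- margin; one roasted condition is
    set exactly at UR * ratio (the worst case), the others above it.
    Accuracy must be exact outside the margin; labels must survive a
    random positive per-analyte rescaling.
    """
    rng = np.random.default_rng(_sub(seed, 11))
    rows = []
    truth_labels = {}
    for i in range(n_analytes):
        analyte = f"P{i:02d}"
        while True:
            ratio = float(rng.uniform(0.0, 1.2))
            if abs(ratio - labile_cutoff) > margin:
                break
        truth_labels[analyte] = HEAT_LABILE if ratio < labile_cutoff else HEAT_STABLE
        ur = float(rng.uniform(2, 20))
        worst = int(rng.integers(0, 4))
        for j, cond in enumerate(DEFAULT_CONDITIONS[1:]):
            r = ratio if j == worst else float(ratio + rng.uniform(0, 1))
            rows.append(
                {"analyte": analyte, "condition": cond, "serum": "R1",
                 "signal": ur * r}
            )
        rows.append(
            {"analyte": analyte, "condition": "UR", "serum": "R1", "signal": ur}
        )
    sig = pd.DataFrame(rows)
    calls = classify_stability(sig, labile_cutoff=labile_cutoff)
    acc = float(
        np.mean([truth_labels[a] == l for a, l in zip(calls["analyte"], calls["label"])])
    )
    scaled = sig.copy()
    scale = {a: float(rng.uniform(0.01, 100)) for a in truth_labels}
    scaled["signal"] = [
        s * scale[a] for a, s in zip(scaled["analyte"], scaled["signal"])
    ]
    calls2 = classify_stability(scaled, labile_cutoff=labile_cutoff)
    invariant = bool((calls["label"].to_numpy() == calls2["label"].to_numpy()).all())
    return {
        "n_analytes": n_analytes,
        "label_accuracy": acc,
        "scale_invariant": invariant,
    }
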