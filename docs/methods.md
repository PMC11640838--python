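# Methods

This note documents the models, defaults and numerical conventions of the
`epifinger` pipeline, and what the synthetic generators do and do not
emulate.

## Display-library grammar and curation

A library insert is `flank5 + 3·n_codons variable bases + flank3`. The
default scheme uses 12 NNK codons (N = any base, K = G/T) between 18-nt
constant flanks — a typical naive-library design; the real library behind
any given experiment is configurable via `PeptideLibraryScheme` (YAML
serializable), including the degenerate pattern per codon position and
the amber policy. Under NNK the only reachable stop codon is amber (TAG),
which supE hosts read through as Gln; `amber_policy="suppress_to_Q"` is
therefore the default and `"reject"` treats TAG as a stop.

Curation is deliberately conservative:

- **Merging**: the reverse read is reverse-complemented and slid along
  the forward read; the offset maximizing the number of agreeing bases
  wins (ties: longer overlap, then smaller |offset|). Disagreements take
  the base with the higher Phred quality; agreements keep the higher
  quality. Pairs with best overlap < `min_overlap` (20) or mismatch
  fraction > `max_mismatch_frac` (0.1) are rejected. No indel handling:
  the generator and the curation model substitution errors only, which
  keeps codon-structure validation the sole curation gate.
- **Quality gate**: whole-read mean Phred < 20 rejects; no positional
  trimming, because inserts are short and fully overlapped.
- **Structure validation**: flanks must match exactly (a flank error
  implies an unreliable variable region), every codon must lie in its
  degenerate class, and non-suppressed stops reject. Rejections are
  tallied by reason (`flank_mismatch`, `codon_violation`, `stop_codon`,
  `low_quality`), so accepted + rejected = total always holds.

## Enrichment statistic

The method literature for statistical mimotope enrichment varies; this
package uses an exact one-sided binomial tail because selection-round
counts are often small enough that asymptotic tests misbehave. With
pseudocount c = 0.5 (finite folds when a peptide is absent from the
reference round):

- `fold = ((k_sel+c)/(N_sel+c)) / ((k_ref+c)/(N_ref+c))`
- `p = P(X ≥ k_sel)`, `X ~ Binomial(N_sel, (k_ref+c)/(N_ref+c))`,
  clamped away from 0 at the smallest positive float (the tail is
  mathematically positive; this keeps the `α = 0 ⇒ nothing selected`
  invariant).
- `q` = Benjamini–Hochberg over all peptides present in the selected
  round; enriched ⇔ `q ≤ α` (0.05) and `fold ≥ fold_min` (3).

The reference/selected rounds are configurable; the default compares the
naive pool to round 2. Calibration on no-spike multinomial nulls (1000
peptides, depth 10⁴) flags well under 5 % of peptides; spikes with
per-round factor ≥ 5 are recovered with sensitivity ≈ 1. The test treats
the reference frequencies as known, which is slightly anticonservative
when reference counts are small — the fold floor absorbs this in
practice.

## Epitope mapping

Alignment is ungapped only: mimotopes are short and the motif similarity
being sought is local. Every k-mer (k = 4) shared between peptide and
antigen nominates a diagonal; on each diagonal the reported hit is the
window that (a) contains at least one run of ≥ k consecutive matches,
(b) has identity ≥ `min_identity` (0.7), and (c) maximizes the number of
matches — tie-broken by shortest span, then leftmost. Maximizing matches
rather than span prevents windows from absorbing mismatch flanks, which
would otherwise drag epitope cores sideways; the definition is exactly
brute-forceable and is verified against an exhaustive offset/window scan.

Epitope calling: per-residue support = number of distinct peptides whose
hit covers the residue; maximal runs with support ≥ `min_support` (3) and
length ≥ `min_core_len` (4) become cores. Labels print `flank` (3)
lowercase context residues each side, clipped at the antigen ends, with
the leading number the 1-based position of the first printed residue —
e.g. `124-kgdHEINaee`. The uppercase/lowercase semantics (uppercase =
support-defined core) is this package's own rendering convention for the
notation; labels round-trip through `parse_label`. Defaults reflect
typical core spans of ~4–16 residues; all are keyword arguments.

Cross-serum consensus groups calls on the same antigen whose cores
overlap by ≥ `min_overlap` (4) residues, taking connected components of
the overlap graph (so transitivity can chain A–B–C). Conservation of a
core in a homolog is the best ungapped placement's identity fraction.

## Array quantification

- **Grid detection**: the nominal GAL grid may be rotated (±2°) and
  shifted (±8 px by default). The score of a candidate pose is the mean
  smoothed-image intensity sampled at the transformed spot centers
  (Gaussian σ = 2 px, bilinear sampling); a coarse grid over
  (rotation, dx, dy) is refined by Nelder–Mead on cubic-spline sampling.
  Rotation pivots on the image center; the generator shares this
  convention. If the best pose's score does not exceed the median pose
  score by 2 % (relative contrast), the image is declared gridless —
  on blank images every pose scores alike. Recovery on synthetic scans
  is ~10⁻³ px and ~10⁻³ degrees, far inside the 0.5 px / 0.1° envelope
  the tests require.
- **Segmentation**: seeds = window pixels > seeding threshold, mask =
  pixels > masking threshold (defaults: block background median + 6σ and
  + 3σ, σ = 1.4826·MAD of the block's non-spot pixels); the segment is
  the 4-connected geodesic dilation of the seeds under the mask iterated
  to fixpoint (binary morphological reconstruction), restricted to a
  disk search window of 1.6× the spot radius. Empty seeds flag the spot.
  The implementation is verified pixel-exact against an independent
  flood-fill oracle and against `skimage.morphology.reconstruction`.
- **Totals**: corrected total = Σ(pixel − block background median) over
  the segment; negative sums clamp to 0 with a flag; pixels at 65535
  flag saturation. The block background excludes disks of 2× the spot
  radius around every (transformed) spot center.
- **Replicate fences**: quadruples are filtered with Q1/Q3 by linear
  interpolation at positions 1 + 0.25(n−1), 1 + 0.75(n−1) on the sorted
  values (the numpy `linear` convention) and Tukey fences at 1.5×IQR,
  bounds inclusive. The convention is oracle-tested, including the
  worked case (98, 100, 102, 500) → {98, 100, 102}.
- **Normalization**: the water baseline is the median of all water-spot
  corrected totals after the same fences; adjusted intensity =
  median(retained) / water baseline; `positive` ⇔ adjusted ≥ `pos_fold`
  (3). A non-positive water baseline is an error. Two-wavelength scans
  are handled by running the pipeline once per channel image.

Pixel coordinates are 0-based (row, col); x = column, y = row.

## Stability classification

Retention ratio = min over roasted conditions of signal/UR. The worst
condition defines the call so that loss under *any* roasting regime marks
lability. The labile cutoff (0.5, i.e. ≥ 50 % signal loss) is an explicit
modeling choice — published stability calls are qualitative — and is a
parameter. Classification is scale-invariant by construction (ratios),
which the tests verify under random positive rescaling. Condition names
are free-form strings; the defaults name an unroasted reference, 142 °C
for 30/50 min (LTLT) and 200 °C for 8/10 min (HTST).

## Synthetic generators and what they (don't) emulate

- **Antigens**: uniform-random residue background with epitope fragments
  embedded at recorded non-overlapping positions. No real protein
  composition bias or domain structure.
- **Selection rounds**: a fixed pool (default 1000 background peptides +
  spiked peptides, uniform naive frequencies); in round r a spiked
  peptide's frequency is multiplied by `enrichment_factor^r` and the pool
  renormalized; counts are multinomial at the round depth; reads carry
  one fixed codon-level encoding per peptide, full overlap between mates,
  i.i.d. substitution errors. Not modeled: phage propagation fitness and
  amplification bias, indels, quality-score structure, chimeras — so
  passing round-trips show correctness of the curation logic, not
  robustness to every real-world artifact.
- **Scans**: spots are flat-top disks (radius − 2 px) with Gaussian edge
  falloff (σ = 1 px, truncated at radius + 2 px), scaled to a requested
  total flux; per-block integer background; optional Gaussian noise;
  ~5–10 % outlier spots at 8× their group intensity (at most one per
  quadruple, so fences can reject them); water spots carry a small
  positive buffer-autofluorescence signal so fold-over-water is
  well-defined. The truth table records the *realized* totals (quantized
  pre-noise flux summed over each spot's compact support), which makes
  the noiseless end-to-end identity exact despite uint16 quantization.
  Not modeled: scanner PMT/laser physics, comet tails, spatial gradients
  within a block.

Determinism: every generator takes a seed and uses
`numpy.random.default_rng`; identical seeds give byte-identical FASTA,
FASTQ and TIFF outputs.

## Validation problem sizes

The validation experiments (`epifinger.validation`, also driven by
`scripts/acceptance.py`) use: curation round-trip at depth 10⁴ per round
(3 rounds, via FASTQ files); enrichment calibration with 20 null and 20
spiked pools (1000 peptides, depth 10⁴, factor 5); planted-epitope
recovery over 4 replicate antigen sets × 2 sera (10 epitope windows per
set, 5 peptides each, factor 8, error rate 0.002, ±2-residue matching);
500 random 32×32 segmentation windows; 10⁴ random fence quadruples; one
noiseless and one 2 %-noise scan with planted outliers; 100 random grid
poses; 40 planted retention ratios. These sizes give each measured rate
a resolution well below its pass/fail margin while keeping the whole
suite fast on a single CPU.

## Known limitations

- Enrichment ignores clonal phage fitness and between-serum batch
  effects (out of scope).
- Mapping is strictly linear/ungapped; conformational epitopes are not
  inferable.
- The grid model is rigid (rotation + translation); no affine/nonlinear
  print distortion.
- The recognition report joins on exact analyte/label identifiers; fuzzy
  matching is deliberately absent (orphans raise with a list).
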