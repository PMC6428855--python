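# Methods

## Random-region extraction

Reads are 75-bp single-end amplicons of an 80-nt library, so the 19-nt 3'
constant flank is only partially observable (at most 14 nt when the 5'
flank starts at position 0). Extraction therefore anchors on the 18-nt 5'
flank, searched at offsets 0–2 to tolerate slight synthesis slippage, at a
Hamming distance of at most `max_mismatch_fw` (default 2 — tolerant but
unambiguous on an 18-mer, where random matches at distance ≤2 are
vanishingly rare). The best (lowest-distance, then leftmost) hit anchors the
next 43 nt as the random region. The 3' flank is checked only over whatever
overlap the read provides, and only when at least `min_rv_overlap` (default
8) bases are visible, allowing `max_mismatch_rv` (default 1) mismatches.
Regions containing N are rejected rather than corrected: counting integrity
is preferred over yield, since every downstream statistic is a copy count.
Rejections carry one of four reasons (`no_fw`, `short`, `ambiguous_base`,
`bad_rv`), checked in that order.

Index demultiplexing assumes a 5' prefix index; other layouts are
configuration. The index table is validated at construction: all indexes
one length, pairwise Hamming distance strictly greater than twice the
mismatch allowance, so every assignment within the allowance is unique.
Unassigned reads are kept in an `undetermined` bin with the prefix intact.

## Enrichment statistics

"Unique sequences" is genuinely ambiguous in common usage, so both readings
are implemented: the *distinct* fraction (#distinct / total copies, the
default) and the *singleton* fraction (#count-1 sequences / #distinct).
Composition defaults to copy-weighted, describing the sequenced population
rather than the sequence repertoire. Copy-number classes use the fixed
edges 10/100/1000/10000 with boundary counts in the lower class. Overlap
between libraries defaults to the union denominator.

Amplification folds are defined on *frequencies*, not raw copy numbers, so
that differing sequencing depths between cycles cancel; a pseudocount
(default 0.5 copies, applied to both numerator and denominator counts and
totals) keeps folds finite when a sequence is absent in the earlier cycle.

The optional Hamming denoiser is an abundance-greedy parent/child merge:
processing parents in descending count order (ties lexicographic), any
sequence within `max_dist` of a parent holding at least `min_parent_ratio`
times its count is absorbed. It is a transparent stand-in for proprietary
pattern-grouping tools, off by default, and conserves total copies.

## Candidate selection

Two tracks. *Abundant*: final-cycle frequency above 0.5%, ranked by
frequency. *Low-frequency rescue*: remaining sequences whose log2-fold
profile has cosine similarity ≥ 0.8 to the centroid profile of the top-10
abundant sequences and whose final fold is ≥ 1 (still enriching), ranked by
similarity. Cosine on log2-folds makes the comparison scale-free: a rare
sequence enriching in the same rounds as the winners scores 1 regardless of
its absolute level. All ties break lexicographically, so the output is a
pure function of the inputs. The tumour/kidney ratio is the
pseudocount-adjusted frequency ratio at a matched cycle; below 1 flags
clearance-biased sequences, and a sequence absent from both pools returns
an explicitly uninformative ratio of 1.

## The campaign simulator

One cycle is modelled at the molecule level:

1. **Injection** — a multinomial draw of `injected_copies[round]` molecules
   from the current library frequencies. The schedule is the tapering
   5, 2, 1, 0.5 then 0.1 nmol over ten cycles, scaled by `injection_unit`
   (default 1e8 molecules per nmol). The unit keeps even the smallest
   injection (0.1 nmol → 1e7 molecules) at or above the largest sequencing
   depth, preserving the real campaign's ordering in which injected amounts
   (~6e13 molecules) dwarf read counts (≤1.2e7): sampling noise should
   enter at the sequencer and the tissue, not at injection.
2. **Tissue partition** — each molecule of species *i* is captured by the
   tumour with probability `capture_fraction · w_i` (`w_i = exp(s_i)`,
   clipped at 1; capture_fraction default 0.05), else cleared through the
   kidney with probability `clearance_fraction · k_i` (default 0.2), else
   lost. Capture *linear* in `w` is deliberate: it makes expected tumour
   frequencies follow exact replicator dynamics, which both the closed-form
   tests and the estimator rely on. Molecule counts are conserved exactly
   at every round. No quantitative clearance physiology is claimed: kidney
   weights are free synthetic parameters.
3. **PCR** — tumour counts grow by `(1+e_i)^pcr_cycles` with per-species
   efficiency `e_i ~ U(0.8, 1)` and multiplicative log-normal noise
   (σ = 0.05), stochastically rounded. `pcr_cycles` defaults to 6, the
   low-cycle regime used when re-amplifying selections to limit bias; the
   per-species efficiency spread then contributes a persistent
   ±~0.2/round growth difference — the known caveat that abundance can
   reflect PCR preference rather than binding.
4. **Sequencing** — a multinomial draw at the configured depth (default
   2e5/round, the low end of real campaign depths), then i.i.d. per-base
   substitution errors (exact model: Binomial count of error-bearing reads,
   conditioned-Binomial substitutions per read).

Kidney captures are sequenced directly (multinomial at the same depth cap)
without a PCR layer: the partition analytics operate on frequency ratios,
where a shared PCR layer cancels in expectation, and omitting it keeps the
kidney channel an undistorted readout of clearance. Desk-scale defaults are
1e4 species (full 1e15 diversity is explicitly not simulated) and all
randomness flows from one seeded generator, so identical seeds give
byte-identical campaigns.

## Selection-coefficient estimation

For each sequence with ≥3 cycles of nonzero frequency, the slope of
log(frequency) against round is fit by least squares (optionally weighted
by √copies, approximating inverse-variance weights for log counts); the
mean slope across estimated sequences is subtracted, giving relative
fitness per round on the natural-log scale of `w = exp(s)`.

Identifiability: the observed per-round growth of species *i* is
`s_i + pcr_cycles · log(1 + e_i)` plus noise. PCR preference is therefore
perfectly confounded with tissue selection in any trajectory-based
estimator; with the default efficiency spread this caps the rank
correlation between true `s` and its estimate at roughly 0.92–0.95 even at
high depth. The parameter-recovery checks measure exactly this: rank
recovery with the confound present.

The planted-candidate recovery experiment uses spike-ins with *fully
specified* parameters (s = 2.0, k = 1, e = 0.9 nominal) rather than only a
raised `s` with lottery-drawn efficiency: twenty identically selected
species with efficiencies spread over U(0.8, 1) end a ten-round campaign
spread over a ~500-fold frequency range for reasons unrelated to selection,
which would test the PCR lottery, not candidate selection. Fixing the
spike-ins' nuisance parameters makes the recovery figure interpretable as
selection detection; the confounded setting is covered by the
rank-recovery check above.

## Imaging quantification

Normalisation follows the planar-FRI convention: subtract the camera's
intrinsic background (scalar dark level or per-pixel dark frame — both
accepted), clip negatives to zero (ROI means are computed after clipping),
and rescale to a common exposure time. In-vivo ratios subtract the
pre-injection ROI mean (the animal's autofluorescence) using the identical
mask on the t0 frame; ex-vivo ratios use a muscle reference with no t0
subtraction. A non-positive reference mean yields a flagged degenerate
result, never a silent infinity. The group comparison is the pooled-SD
unpaired t-test (one-way-ANOVA residual SD, pairwise t on N − k degrees of
freedom), which reduces exactly to the classic two-sample pooled t-test at
k = 2. ROI masks are supplied, not segmented: the workflow they model is
hand-drawn ROIs.

The synthetic image generator plants Gaussian blobs on a flat
autofluorescence background with i.i.d. Gaussian noise. It emulates the
*arithmetic* of the analysis (background, exposure, autofluorescence,
ROI means), not the physics — no depth-dependent attenuation, scatter,
animal-to-animal variation or ROI mis-registration — so passing recovery
tests validate the computation, not biological effect sizes.

## qPCR and library arithmetic

Standard curves fit Cq against log10(quantity) by least squares, averaging
replicate wells per quantity first; efficiency is `10^(−1/slope) − 1`, and
a non-negative slope marks the curve invalid. Quantification inverts the
fit; stability is the percentage of the t=0 quantity, flagged (not capped)
above 100%.

Molecular weight uses the standard average deoxynucleotide-monophosphate
residue masses (A 313.21, C 289.18, G 329.21, T 304.20 Da) with a 61.96 Da
terminal correction for the 5'-OH/3'-OH ends; downstream uses round to
whole kDa, so the choice of terminal convention is non-critical. Diversity
from an injected amount is `nmol · 1e-9 · N_A` with its order of magnitude.

## Test and problem sizes

Oracle-equivalence suites run on ≤1e3-element instances against literal
brute-force reimplementations. Simulation-based checks use 20–2000 species
at depths 3e3–1e6 and 1–10 rounds; the rank-recovery experiment uses 1000
species at depth 1e6 for 10 rounds. These sizes keep the full suite in the
seconds-to-minutes range while staying inside the regime the statistics are
designed for.

## Known limitations

- The simulator's tissue model is a one-parameter capture weight; no
  pharmacokinetics, spatial structure, or immune clearance.
- The Hamming denoiser is a pragmatic greedy merge, not a reproduction of
  any published pattern-clustering algorithm.
- Selection and PCR preference are unidentifiable from trajectories alone;
  estimates are relative fitness including PCR effects.
- The fold definition intentionally deviates from a literal
  "change of copy numbers" by using frequencies, removing depth effects.
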