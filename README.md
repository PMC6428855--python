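# selexseed

Analytics for **in-vivo SELEX** campaigns — the iterative selection of DNA
aptamer libraries in live animals — with a ground-truth campaign simulator
that makes every stage testable at desk scale.

An in-vivo selection injects an ssDNA library (here an 80-nt design: an
18-nt forward flank, a 43-nt random region, and a 19-nt reverse flank) into
tumour-bearing animals, recovers tissue-bound molecules, re-amplifies them
and repeats for ten cycles. Sequencing each cycle's population turns the
campaign into time-series data. This package provides the informatics around
that data:

- **Ingest** — phred+33 FASTQ parsing, index demultiplexing (prefix indexes,
  mismatch-tolerant, ambiguity-safe), constant-flank anchoring and 43-nt
  random-region extraction from 75-bp single-end reads, counted pools as TSV.
- **Enrichment metrics** — distinct/singleton fractions, per-position base
  composition, copy-number class spectra (≤10, 11–100, 101–1000, 1001–10000,
  >10000 copies), cross-library overlap, per-sequence trajectories with
  amplification folds, and an optional Hamming-distance denoiser.
- **Candidate selection** — two-track ranking: sequences above a final-cycle
  frequency threshold (default 0.5%), plus rare sequences whose log2-fold
  profile matches the abundant winners (cosine similarity to the top-N
  centroid); tumour/kidney partition ratios flag clearance-biased sequences.
- **Simulator** — a molecule-level model of a 10-cycle campaign (multinomial
  injection under the tapering 5/2/1/0.5/0.1-nmol schedule, per-species
  tumour capture `w = exp(s)` and kidney clearance, per-species PCR
  efficiency with noise, multinomial sequencing with per-base errors),
  with an estimator that recovers relative selection coefficients as the
  centred slope of log-frequency against round.
- **Imaging** — planar fluorescence ratio quantification: camera-background
  subtraction, exposure normalisation, pre-injection autofluorescence
  subtraction via the identical ROI, tumour/healthy and tumour/muscle
  ratios, pooled-SD pairwise t-tests.
- **Quant** — qPCR standard curves (Cq vs log10 quantity, amplification
  efficiency), absolute quantification, serum-stability percentages, ssDNA
  molecular weight and injected-amount diversity arithmetic.

The expected tumour dynamics follow replicator selection,
`f_i' = f_i w_i / Σ_j f_j w_j`, so a two-species pool with weight ratio λ
obeys `f_r = f_0 λ^r / (f_0 λ^r + 1 − f_0)` — the closed form the simulator
and estimator are tested against.

## Worked example

```python
import selexseed as sx
from scipy.stats import spearmanr

cfg = sx.SimConfig(n_species=1_000, rounds=10, sigma_s=0.5,
                   sequencing_depth=1_000_000, seed=11)
sim = sx.run_campaign(cfg)
trajectories = sx.build_trajectories(sim.tumour_pools)
s_hat = sx.estimate_selection_coefficients(trajectories, depth_aware=True)
truth = {s: sp.s for s, sp in sim.ground_truth.items()}
rho = spearmanr([truth[s] for s in s_hat], [s_hat[s] for s in s_hat]).statistic
print(f"Spearman(true s, estimated s) = {rho:.3f}")
```

prints

```
Spearman(true s, estimated s) = 0.932
```

meaning the per-round selection ranking of all 1000 species is recovered
almost perfectly from the sequenced trajectories alone; the residual gap is
dominated by per-species PCR-efficiency bias, which no trajectory-based
estimator can separate from tissue selection. The `examples/` directory has
one short script per capability (ingest, enrichment metrics, candidate
ranking, selection recovery, imaging ratios, qPCR quantification), each
printing the numbers it computes. A thin `selexseed` CLI wraps the same
functions (`selexseed extract|metrics|candidates|simulate|imgratio|qpcr`).

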