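"""Synthetic in-vivo SELEX campaign simulator with known ground truth.

The model is a minimal molecule-level account of one selection cycle:

1. *Injection* — a fixed number of molecules is drawn multinomially from the
   current library's frequencies, following the tapering schedule
   (5, 2, 1, 0.5 then 0.1 nmol-equivalents over ten cycles).
2. *Tissue partition* — each injected molecule of species *i* is captured by
   the tumour with probability ``capture_fraction * w_i`` where
   ``w_i = exp(s_i)`` is the species' selection weight; a non-captured
   molecule is cleared through the kidney with probability
   ``clearance_fraction * k_i``, otherwise it is lost. Capture linear in
   ``w`` makes expected tumour frequencies follow replicator dynamics
   ``f_i' = f_i w_i / sum_j f_j w_j``, which the estimator inverts.
3. *PCR* — tumour counts grow by ``(1 + e_i)^pcr_cycles`` with per-species
   efficiency ``e_i`` and multiplicative log-normal noise, so consistently
   PCR-favoured species enrich for reasons unrelated to tissue binding.
4. *Sequencing* — a multinomial sample at the configured depth, with
   optional i.i.d. per-base substitution errors.

All randomness flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .design import DEFAULT_DESIGN, LibraryDesign
from .enrichment import Trajectory
from .pools import SamplePool

NUCLEOTIDES = np.array(list("ACGT"))

#: Injection schedule in nmol: 5, 2, 1, 0.5 then 0.1 from cycle 5 on.
INJECTION_SCHEDULE_NMOL = (5.0, 2.0, 1.0, 0.5, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1)


@dataclass
class SimSpecies:
    """Ground-truth parameters for one library species.

    ``s`` is the tumour selection coefficient (capture weight ``exp(s)``),
    ``k`` the kidney clearance weight (> 0), ``e`` the per-cycle PCR
    efficiency in (0.5, 1].
    """

    sequence: str
    s: float
    k: float
    e: float

    @property
    def w(self) -> float:
        return math.exp(self.s)

    def __post_init__(self) -> None:
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError(f"clearance weight must be finite and > 0, got {self.k}")
        if not 0.5 < self.e <= 1.0:
            raise ValueError(f"PCR efficiency must be in (0.5, 1], got {self.e}")


@dataclass
class SimConfig:
    """Desk-scale campaign configuration.

    ``injection_unit`` converts the nmol schedule into molecule counts
    (molecules per nmol at desk scale); ``sequencing_depth`` may be a single
    depth or one per round. Defaults emulate the sequenced-depth low end of
    a real campaign (~1.5e5 reads/cycle) at 1e4 species.
    """

    n_species: int = 10_000
    rounds: int = 10
    random_len: int = 43
    injection_schedule_nmol: tuple[float, ...] = INJECTION_SCHEDULE_NMOL
    # molecules per nmol at desk scale; keeps even the smallest injection
    # (0.1 nmol -> 1e7 molecules) at or above the largest sequencing depth,
    # matching the real campaign where injected amounts dwarf read counts
    injection_unit: float = 1e8
    capture_fraction: float = 0.05
    clearance_fraction: float = 0.2
    pcr_cycles: int = 6
    sigma_pcr: float = 0.05
    sequencing_depth: int | tuple[int, ...] = 200_000
    per_base_error_rate: float = 0.0
    sigma_s: float = 0.5
    k_log_sigma: float = 0.5
    e_range: tuple[float, float] = (0.8, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            raise ValueError("per_base_error_rate must be in [0, 1]")
        if not 0.0 <= self.capture_fraction <= 1.0:
            raise ValueError("capture_fraction must be in [0, 1]")
        if not 0.0 <= self.clearance_fraction <= 1.0:
            raise ValueError("clearance_fraction must be in [0, 1]")
        for d in self.depth_per_round():
            if d < 1_000:
                raise ValueError("sequencing depth must be >= 1e3 per round")
        if len(self.injection_schedule_nmol) < self.rounds:
            raise ValueError("injection schedule shorter than the number of rounds")

    def depth_per_round(self) -> tuple[int, ...]:
        if isinstance(self.sequencing_depth, (int, np.integer)):
            return tuple([int(self.sequencing_depth)] * self.rounds)
        depths = tuple(int(d) for d in self.sequencing_depth)
        if len(depths) < self.rounds:
            raise ValueError("per-round sequencing_depth shorter than rounds")
        return depths

    def injected_copies(self, round_index: int) -> int:
        """Molecules injected at 1-based ``round_index``."""
        return int(round(self.injection_schedule_nmol[round_index - 1] * self.injection_unit))


@dataclass
class RoundResult:
    tumour_pool: SamplePool
    kidney_pool: SamplePool
    injected: int
    captured_tumour: int
    captured_kidney: int
    lost: int


@dataclass
class SimResult:
    """Full campaign output with ground truth.

    ``tumour_pools[0]`` is the initial library (every species one copy);
    ``tumour_pools[r]`` for r >= 1 and ``kidney_pools[r-1]`` are the
    sequenced tumour/kidney populations of cycle r.
    """

    tumour_pools: list[SamplePool]
    kidney_pools: list[SamplePool]
    ground_truth: dict[str, SimSpecies]
    rounds_accounting: list[RoundResult]
    config: SimConfig


class ExtinctionError(RuntimeError):
    pass


def _random_sequences(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out), length))
        for row in batch:
            seq = "".join(NUCLEOTIDES[row])
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
    return out


def make_initial_pool(
    n_species: int,
    random_len: int,
    rng: np.random.Generator | int,
    sigma_s: float = 0.5,
    k_log_sigma: float = 0.5,
    e_range: tuple[float, float] = (0.8, 1.0),
) -> tuple[SamplePool, dict[str, SimSpecies]]:
    """Draw the naive library: distinct random sequences, one copy each.

    Species parameters are drawn ``s ~ Normal(0, sigma_s)``,
    ``k ~ LogNormal(0, k_log_sigma)``, ``e ~ Uniform(*e_range)``.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sequences = _random_sequences(n_species, random_len, rng)
    s = rng.normal(0.0, sigma_s, size=n_species) if sigma_s > 0 else np.zeros(n_species)
    k = rng.lognormal(0.0, k_log_sigma, size=n_species) if k_log_sigma > 0 else np.ones(n_species)
    e = rng.uniform(*e_range, size=n_species)
    species = {
        seq: SimSpecies(sequence=seq, s=float(si), k=float(ki), e=float(ei))
        for seq, si, ki, ei in zip(sequences, s, k, e)
    }
    pool = SamplePool(counts={seq: 1 for seq in sequences}, library="SIM", cycle=0, tissue="tumour")
    return pool, species


def _stochastic_round(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    floor = np.floor(values)
    frac = values - floor
    return (floor + (rng.random(values.shape) < frac)).astype(np.int64)


def apply_sequencing_error(
    counts: Mapping[str, int], error_rate: float, rng: np.random.Generator
) -> dict[str, int]:
    """Apply i.i.d. per-base substitution errors to a counted pool.

    For each copy group the number of error-bearing reads is Binomial with
    per-read probability ``1 - (1 - error_rate)^L``; each such read gets a
    Binomial(L, error_rate) number of substitutions conditioned to be >= 1,
    at distinct random positions.
    """
    if error_rate == 0:
        return dict(counts)
    out: dict[str, int] = {}
    for seq, n in counts.items():
        L = len(seq)
        p_any = 1.0 - (1.0 - error_rate) ** L
        n_err = int(rng.binomial(n, p_any))
        if n - n_err:
            out[seq] = out.get(seq, 0) + (n - n_err)
        for _ in range(n_err):
            n_sub = 0
            while n_sub == 0:  # conditioned on >= 1 substitution
                n_sub = int(rng.binomial(L, error_rate))
            positions = rng.choice(L, size=n_sub, replace=False)
            bases = list(seq)
            for pos in positions:
                alternatives = [b for b in "ACGT" if b != bases[pos]]
                bases[pos] = alternatives[rng.integers(0, 3)]
            mutant = "".join(bases)
            out[mutant] = out.get(mutant, 0) + 1
    return out


def _sequence_sample(
    counts: dict[str, int],
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
    cycle: int,
    tissue: str,
) -> SamplePool:
    sequences = list(counts)
    n = np.array([counts[s] for s in sequences], dtype=float)
    draws = rng.multinomial(depth, n / n.sum())
    sampled = {s: int(c) for s, c in zip(sequences, draws) if c > 0}
    sampled = apply_sequencing_error(sampled, error_rate, rng)
    return SamplePool(counts=sampled, library="SIM", cycle=cycle, tissue=tissue)


def simulate_round(
    pool: SamplePool,
    species: Mapping[str, SimSpecies],
    config: SimConfig,
    round_index: int,
    rng: np.random.Generator,
) -> RoundResult:
    """One selection cycle: inject, partition, amplify, sequence.

    ``round_index`` is 1-based. Molecule conservation holds exactly:
    captured_tumour + captured_kidney + lost == injected.
    """
    if not pool.counts:
        raise ExtinctionError("input pool is empty")
    sequences = list(pool.counts)
    n = np.array([pool.counts[s] for s in sequences], dtype=float)
    w = np.array([species[s].w for s in sequences])
    k = np.array([species[s].k for s in sequences])
    e = np.array([species[s].e for s in sequences])

    injected = rng.multinomial(config.injected_copies(round_index), n / n.sum())

    p_tumour = np.minimum(config.capture_fraction * w, 1.0)
    tumour = rng.binomial(injected, p_tumour)
    remaining = injected - tumour
    p_kidney = np.minimum(config.clearance_fraction * k, 1.0)
    kidney = rng.binomial(remaining, p_kidney)
    lost = remaining - kidney

    if tumour.sum() == 0:
        raise ExtinctionError(
            f"tumour capture extinct at round {round_index}; "
            "raise capture_fraction or the injected amount"
        )

    # PCR: per-species efficiency with multiplicative log-normal noise
    gain = (1.0 + e) ** config.pcr_cycles
    if config.sigma_pcr > 0:
        gain = gain * rng.lognormal(0.0, config.sigma_pcr, size=gain.shape)
    amplified = _stochastic_round(tumour * gain, rng)
    amp_counts = {s: int(c) for s, c in zip(sequences, amplified) if c > 0}
    if not amp_counts:
        raise ExtinctionError(f"amplified pool empty at round {round_index}")

    depth = config.depth_per_round()[round_index - 1]
    tumour_pool = _sequence_sample(
        amp_counts, depth, config.per_base_error_rate, rng, cycle=round_index, tissue="tumour"
    )
    kidney_counts = {s: int(c) for s, c in zip(sequences, kidney) if c > 0}
    if kidney_counts:
        kidney_pool = _sequence_sample(
            kidney_counts,
            min(depth, int(sum(kidney_counts.values()))),
            config.per_base_error_rate,
            rng,
            cycle=round_index,
            tissue="kidney",
        )
    else:
        kidney_pool = SamplePool(counts={}, library="SIM", cycle=round_index, tissue="kidney")

    return RoundResult(
        tumour_pool=tumour_pool,
        kidney_pool=kidney_pool,
        injected=int(injected.sum()),
        captured_tumour=int(tumour.sum()),
        captured_kidney=int(kidney.sum()),
        lost=int(lost.sum()),
    )


def run_campaign(
    config: SimConfig,
    mutate_species: Callable[[dict[str, SimSpecies]], None] | None = None,
    fastq_dir: str | Path | None = None,
    design: LibraryDesign | None = None,
) -> SimResult:
    """Run a full multi-round campaign, reproducibly from ``config.seed``.

    ``mutate_species`` may adjust ground-truth parameters (e.g. plant known
    high-selection species) before the first round. With ``fastq_dir`` set,
    each tumour pool is also written as an indexed error-free FASTQ for
    end-to-end ingest testing.
    """
    rng = np.random.default_rng(config.seed)
    pool0, species = make_initial_pool(
        config.n_species,
        config.random_len,
        rng,
        sigma_s=config.sigma_s,
        k_log_sigma=config.k_log_sigma,
        e_range=config.e_range,
    )
    if mutate_species is not None:
        mutate_species(species)

    tumour_pools = [pool0]
    kidney_pools: list[SamplePool] = []
    accounting: list[RoundResult] = []
    pool = pool0
    for r in range(1, config.rounds + 1):
        result = simulate_round(pool, species, config, r, rng)
        tumour_pools.append(result.tumour_pool)
        kidney_pools.append(result.kidney_pool)
        accounting.append(result)
        pool = result.tumour_pool

    sim = SimResult(
        tumour_pools=tumour_pools,
        kidney_pools=kidney_pools,
        ground_truth=species,
        rounds_accounting=accounting,
        config=config,
    )
    if fastq_dir is not None:
        emit_campaign_fastq(sim, fastq_dir, design=design)
    return sim


def replicator_expectation(
    freqs: Sequence[float], weights: Sequence[float], rounds: int
) -> np.ndarray:
    """Expected frequency trajectory under pure selection.

    Iterates ``f_i' = f_i w_i / sum_j f_j w_j`` for ``rounds`` cycles — the
    deterministic expectation of the simulator with all noise terms off.
    For two species with weight ratio lambda this has the closed form
    ``f_r = f_0 lambda^r / (f_0 lambda^r + 1 - f_0)``.
    """
    f = np.asarray(freqs, dtype=float).copy()
    w = np.asarray(weights, dtype=float)
    if not np.isclose(f.sum(), 1.0):
        raise ValueError("frequencies must sum to 1")
    for _ in range(rounds):
        f = f * w
        f /= f.sum()
    return f


def estimate_selection_coefficients(
    trajectories: Mapping[str, Trajectory],
    depth_aware: bool = False,
    min_cycles: int = 3,
) -> dict[str, float]:
    """Recover relative selection coefficients from frequency trajectories.

    For each sequence with >= ``min_cycles`` cycles of nonzero frequency,
    the slope of log(frequency) against round is fit by least squares
    (weighted by copy number when ``depth_aware``, approximating
    inverse-variance weights for log counts); the mean slope across
    estimated sequences is subtracted, leaving relative fitness per round
    on the natural-log scale of ``w = exp(s)``.
    """
    slopes: dict[str, float] = {}
    for seq, traj in trajectories.items():
        cycles = np.asarray(traj.cycles, dtype=float)
        freqs = np.asarray(traj.frequencies, dtype=float)
        copies = np.asarray(traj.copies, dtype=float)
        mask = freqs > 0
        if mask.sum() < min_cycles:
            continue
        x, y = cycles[mask], np.log(freqs[mask])
        if depth_aware:
            weights = np.sqrt(copies[mask])  # polyfit weights ~ 1/sigma
            slope = np.polyfit(x, y, 1, w=weights)[0]
        else:
            slope = np.polyfit(x, y, 1)[0]
        slopes[seq] = float(slope)
    if not slopes:
        return {}
    mean_slope = float(np.mean(list(slopes.values())))
    return {seq: slope - mean_slope for seq, slope in slopes.items()}


# ---------------------------------------------------------------------------
# FASTQ emission for end-to-end ingest tests


def make_index_set(
    n: int = 12, length: int = 6, min_dist: int = 4, seed: int = 7_919
) -> list[str]:
    """Greedy deterministic set of well-separated index sequences.

    Pairwise Hamming distance is at least ``min_dist`` (> 2 so one-mismatch
    demultiplexing is unambiguous).
    """
    from .design import hamming

    rng = np.random.default_rng(seed)
    indexes: list[str] = []
    while len(indexes) < n:
        cand = "".join(NUCLEOTIDES[rng.integers(0, 4, size=length)])
        if all(hamming(cand, ix) >= min_dist for ix in indexes):
            indexes.append(cand)
    return indexes


DEFAULT_INDEXES = make_index_set()


def pool_to_fastq(
    pool: SamplePool,
    path: str | Path,
    index: str,
    design: LibraryDesign | None = None,
    read_len: int = 75,
) -> None:
    """Write a pool as error-free FASTQ reads: index + flanked region.

    Each read is the index prefix followed by the amplicon sense strand
    (forward flank + region + reverse flank) truncated to ``read_len``
    bases, one read per copy, all bases at phred 37.
    """
    design = design or DEFAULT_DESIGN
    with open(path, "w") as fh:
        read_no = 0
        for seq in sorted(pool.counts):
            body = (design.fw_flank + seq + design.rv_flank_sense)[:read_len]
            record = index + body
            qual = "F" * len(record)
            for _ in range(pool.counts[seq]):
                read_no += 1
                fh.write(f"@sim_c{pool.cycle}_{read_no}\n{record}\n+\n{qual}\n")


def emit_campaign_fastq(
    sim: SimResult, outdir: str | Path, design: LibraryDesign | None = None
) -> dict[str, str]:
    """Write every tumour pool as indexed FASTQ; returns index → file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index_map: dict[str, str] = {}
    for pool in sim.tumour_pools:
        index = DEFAULT_INDEXES[pool.cycle % len(DEFAULT_INDEXES)]
        path = outdir / f"tumour_cycle{pool.cycle}.fastq"
        pool_to_fastq(pool, path, index=index, design=design)
        index_map[index] = str(path)
    return index_map
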