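"""Round-by-round enrichment analytics of a SELEX campaign.

The statistics here describe how a sequenced DNA population changes across
selection cycles: the shrinking share of distinct sequences, shifts in
per-position nucleotide composition, the copy-number class spectrum, overlap
between libraries, and per-sequence abundance trajectories with their
amplification folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .pools import SamplePool

NUCLEOTIDES = "ACGT"

#: Upper edges of the copy-number classes; the last class is open-ended.
COPY_NUMBER_BIN_EDGES = (10, 100, 1000, 10000)
COPY_NUMBER_BIN_LABELS = ("<=10", "11-100", "101-1000", "1001-10000", ">10000")


def unique_fraction(pool: SamplePool, mode: Literal["distinct", "singleton"] = "distinct") -> float:
    """Share of unique sequences in a pool.

    ``distinct``: number of distinct sequences over total copies — the
    fraction of the sequenced population made of different molecules, which
    declines as selection concentrates copies. ``singleton``: fraction of
    distinct sequences observed exactly once.
    """
    if not pool.counts:
        raise ValueError("unique_fraction of an empty pool is undefined")
    if mode == "distinct":
        return pool.n_distinct / pool.total_copies
    if mode == "singleton":
        singletons = sum(1 for n in pool.counts.values() if n == 1)
        return singletons / pool.n_distinct
    raise ValueError(f"mode must be 'distinct' or 'singleton', got {mode!r}")


@dataclass
class CompositionMatrix:
    """Per-position nucleotide frequencies over the random region.

    ``freqs`` is a 4 x L array with rows in A, C, G, T order; each column
    sums to 1.
    """

    freqs: np.ndarray
    weighting: Literal["by_copies", "by_distinct"]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape[0] != 4:
            raise ValueError("composition matrix must have 4 rows (A,C,G,T)")

    @property
    def length(self) -> int:
        return self.freqs.shape[1]


def nucleotide_composition(
    pool: SamplePool, weighting: Literal["by_copies", "by_distinct"] = "by_copies"
) -> CompositionMatrix:
    """Positional base composition of a pool.

    ``by_copies`` weights each sequence by its copy number (describes the
    sequenced population); ``by_distinct`` counts each distinct sequence
    once (describes the sequence repertoire).
    """
    if not pool.counts:
        raise ValueError("composition of an empty pool is undefined")
    lengths = {len(s) for s in pool.counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths: {sorted(lengths)}")
    L = lengths.pop()
    base_index = {b: i for i, b in enumerate(NUCLEOTIDES)}
    tally = np.zeros((4, L), dtype=float)
    for seq, count in pool.counts.items():
        w = count if weighting == "by_copies" else 1
        for pos, base in enumerate(seq):
            tally[base_index[base], pos] += w
    return CompositionMatrix(freqs=tally / tally.sum(axis=0, keepdims=True), weighting=weighting)


@dataclass
class CopyNumberBinning:
    """Copy-number class spectrum of one cycle's population.

    ``distinct_per_bin``: number of distinct sequences whose copy number
    falls in each class (<=10, 11-100, 101-1000, 1001-10000, >10000).
    ``copy_share_per_bin``: fraction of all sequenced copies carried by each
    class; a growing top class signals strong enrichment.
    """

    distinct_per_bin: tuple[int, int, int, int, int]
    copy_share_per_bin: tuple[float, float, float, float, float]
    labels: tuple[str, ...] = COPY_NUMBER_BIN_LABELS


def _bin_index(count: int) -> int:
    for i, edge in enumerate(COPY_NUMBER_BIN_EDGES):
        if count <= edge:
            return i
    return len(COPY_NUMBER_BIN_EDGES)


def bin_by_copy_number(pool: SamplePool) -> CopyNumberBinning:
    """Group a pool's sequences into the five copy-number classes.

    Boundary counts (10, 100, 1000, 10000) fall in the lower class of each
    pair.
    """
    if not pool.counts:
        raise ValueError("cannot bin an empty pool")
    distinct = [0] * 5
    copies = [0] * 5
    for count in pool.counts.values():
        i = _bin_index(count)
        distinct[i] += 1
        copies[i] += count
    total = pool.total_copies
    return CopyNumberBinning(
        distinct_per_bin=tuple(distinct),  # type: ignore[arg-type]
        copy_share_per_bin=tuple(c / total for c in copies),  # type: ignore[arg-type]
    )


def pool_overlap(
    pool_a: SamplePool,
    pool_b: SamplePool,
    denominator: Literal["union", "A", "B"] = "union",
) -> float:
    """Fraction of distinct sequences shared between two pools."""
    if not pool_a.counts or not pool_b.counts:
        raise ValueError("pool_overlap of an empty pool is undefined")
    set_a, set_b = set(pool_a.counts), set(pool_b.counts)
    shared = len(set_a & set_b)
    if denominator == "union":
        return shared / len(set_a | set_b)
    if denominator == "A":
        return shared / len(set_a)
    if denominator == "B":
        return shared / len(set_b)
    raise ValueError(f"denominator must be 'union', 'A' or 'B', got {denominator!r}")


@dataclass
class Trajectory:
    """One sequence's abundance across selection cycles.

    ``folds[i]`` is the amplification fold from ``cycles[i]`` to
    ``cycles[i+1]``: the ratio of pseudocount-adjusted frequencies, so it is
    finite and positive even when the sequence is absent in the earlier
    cycle. Folds are on frequencies, not raw copies, so differing sequencing
    depths between cycles cancel.
    """

    sequence: str
    cycles: tuple[int, ...]
    copies: tuple[int, ...]
    frequencies: tuple[float, ...]
    folds: tuple[float, ...]

    @property
    def final_frequency(self) -> float:
        return self.frequencies[-1]

    @property
    def max_fold(self) -> float:
        return max(self.folds)

    @property
    def max_fold_transition(self) -> tuple[int, int]:
        i = int(np.argmax(self.folds))
        return (self.cycles[i], self.cycles[i + 1])

    def log2_fold_profile(self) -> np.ndarray:
        return np.log2(np.asarray(self.folds))


def build_trajectories(
    pools: Sequence[SamplePool],
    min_total_copies: int = 1,
    pseudocount: float = 0.5,
) -> dict[str, Trajectory]:
    """Per-sequence trajectories across an ordered series of cycle pools.

    Every sequence present in at least one pool (and with at least
    ``min_total_copies`` copies summed over the series) gets a trajectory;
    its frequency is 0 in cycles where it is absent. Fold from cycle c to
    c+1 is ``((n_{c+1}+pc)/(N_{c+1}+pc)) / ((n_c+pc)/(N_c+pc))``.
    """
    if len(pools) < 2:
        raise ValueError("need at least two cycle pools to build trajectories")
    cycles = [p.cycle for p in pools]
    if any(b <= a for a, b in zip(cycles, cycles[1:])):
        raise ValueError(f"cycles must be strictly increasing, got {cycles}")
    totals = [p.total_copies for p in pools]
    all_sequences: set[str] = set()
    for p in pools:
        all_sequences.update(p.counts)

    trajectories: dict[str, Trajectory] = {}
    for seq in all_sequences:
        copies = [p.counts.get(seq, 0) for p in pools]
        if sum(copies) < min_total_copies:
            continue
        freqs = [n / N if N else 0.0 for n, N in zip(copies, totals)]
        folds = []
        for (n0, N0), (n1, N1) in zip(zip(copies, totals), zip(copies[1:], totals[1:])):
            f0 = (n0 + pseudocount) / (N0 + pseudocount)
            f1 = (n1 + pseudocount) / (N1 + pseudocount)
            folds.append(f1 / f0)
        trajectories[seq] = Trajectory(
            sequence=seq,
            cycles=tuple(cycles),
            copies=tuple(copies),
            frequencies=tuple(freqs),
            folds=tuple(folds),
        )
    return trajectories


def cluster_by_hamming(
    pool: SamplePool, max_dist: int = 1, min_parent_ratio: float = 10.0
) -> SamplePool:
    """Greedy Hamming-distance denoising of a pool (optional, default off).

    Any sequence within ``max_dist`` of a sequence holding at least
    ``min_parent_ratio`` times its count is merged into that parent (counts
    added). Parents are processed in descending count order, ties broken
    lexicographically — the classic abundance-greedy parent/child merge used
    to absorb likely PCR/sequencing error progeny. A transparent stand-in
    for proprietary pattern-grouping tools, not a reproduction of one.
    """
    from .design import hamming

    order = sorted(pool.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    merged: dict[str, int] = {}
    absorbed: set[str] = set()
    for seq, count in order:
        if seq in absorbed:
            continue
        merged[seq] = count
        for child, child_count in order:
            if child == seq or child in absorbed or child in merged:
                continue
            if merged[seq] >= min_parent_ratio * child_count and hamming(seq, child) <= max_dist:
                merged[seq] += child_count
                absorbed.add(child)
    return SamplePool(
        counts=merged, library=pool.library, cycle=pool.cycle, tissue=pool.tissue
    )
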