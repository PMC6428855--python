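"""Counted sequence pools: the per-(library, cycle, tissue) populations.

A pool is a multiset of extracted random-region sequences with copy counts —
the unit on which every enrichment statistic downstream operates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .design import DNA_ALPHABET

LIBRARIES = ("D3", "D3P", "SIM")
TISSUES = ("tumour", "kidney", "none")


@dataclass
class SamplePool:
    """Copy-counted population of random-region sequences for one sample.

    ``counts`` maps each distinct sequence to its (positive) copy number;
    ``total_copies`` is the number of molecules sequenced, i.e. the sum of
    the counts.
    """

    counts: dict[str, int]
    library: str = "SIM"
    cycle: int = 0
    tissue: str = "none"

    def __post_init__(self) -> None:
        if self.library not in LIBRARIES:
            raise ValueError(f"library must be one of {LIBRARIES}, got {self.library!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if not 0 <= self.cycle <= 10:
            raise ValueError(f"cycle must be in 0..10, got {self.cycle}")
        lengths = {len(s) for s in self.counts}
        if len(lengths) > 1:
            raise ValueError(f"mixed sequence lengths in pool: {sorted(lengths)}")
        for seq, n in self.counts.items():
            if n < 1:
                raise ValueError(f"count for {seq} must be >= 1, got {n}")
            if not set(seq) <= DNA_ALPHABET:
                raise ValueError(f"sequence {seq!r} contains non-ACGT characters")

    @property
    def total_copies(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def frequency(self, sequence: str) -> float:
        """Relative abundance of ``sequence`` (0 if absent)."""
        total = self.total_copies
        return self.counts.get(sequence, 0) / total if total else 0.0

    def frequencies(self) -> dict[str, float]:
        total = self.total_copies
        return {s: n / total for s, n in self.counts.items()}

    def __len__(self) -> int:
        return self.n_distinct

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SamplePool):
            return NotImplemented
        return (
            self.counts == other.counts
            and self.library == other.library
            and self.cycle == other.cycle
            and self.tissue == other.tissue
        )


def build_pool(
    sequences: Iterable[str],
    library: str = "SIM",
    cycle: int = 0,
    tissue: str = "none",
) -> SamplePool:
    """Tally a stream of equal-length sequences into a :class:`SamplePool`."""
    counts = Counter(sequences)
    return SamplePool(counts=dict(counts), library=library, cycle=cycle, tissue=tissue)


def _ranked_frame(pool: SamplePool) -> pd.DataFrame:
    # rank 1 = highest copy number; ties broken lexicographically
    items = sorted(pool.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = pool.total_copies
    return pd.DataFrame(
        {
            "sequence": [s for s, _ in items],
            "count": [n for _, n in items],
            "frequency": [n / total for _, n in items],
            "rank": range(1, len(items) + 1),
        }
    )


def write_pool(pool: SamplePool, path: str | Path) -> None:
    """Write a pool as TSV (sequence, count, frequency, rank), ranked by count."""
    df = _ranked_frame(pool)
    with open(path, "w") as fh:
        fh.write(f"# library={pool.library}\tcycle={pool.cycle}\ttissue={pool.tissue}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_pool(path: str | Path) -> SamplePool:
    """Read a pool written by :func:`write_pool`; inverse up to metadata."""
    path = Path(path)
    meta = {"library": "SIM", "cycle": 0, "tissue": "none"}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                key, _, value = token.partition("=")
                if key in meta:
                    meta[key] = int(value) if key == "cycle" else value
        else:
            fh.seek(0)
        try:
            df = pd.read_csv(fh, sep="\t", dtype={"sequence": str, "count": int})
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"malformed pool TSV {path}: {exc}") from exc
    for col in ("sequence", "count"):
        if col not in df.columns:
            raise ValueError(f"malformed pool TSV {path}: missing column {col!r}")
    counts = dict(zip(df["sequence"], df["count"].astype(int)))
    return SamplePool(counts=counts, **meta)  # type: ignore[arg-type]


def write_pool_fasta(pool: SamplePool, path: str | Path) -> None:
    """Write a pool as FASTA with ``>rank-count`` headers (rank order)."""
    df = _ranked_frame(pool)
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f">{row.rank}-{row.count}\n{row.sequence}\n")
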