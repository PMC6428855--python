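"""FASTQ ingest: parsing, index demultiplexing and random-region extraction.

Reads are 75-bp single-end amplicon reads of an 80-nt library, so only part
of the 3' constant flank is observable; extraction anchors on the 5' flank
and checks the 3' flank over whatever overlap the read length allows.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import DNA_ALPHABET, LibraryDesign, hamming


@dataclass(frozen=True)
class Read:
    """One sequencing read: id, bases over {A,C,G,T,N} and phred scores."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id}: empty sequence")
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.bases)} != "
                f"quality length {len(self.quals)}"
            )


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a phred+33 FASTQ file in file order.

    Raises ``ValueError`` with an (approximate) line number on a malformed
    record.
    """
    path = Path(path)
    n_records = 0
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ record near line {4 * n_records + 1}: {exc}"
                ) from exc
            n_records += 1
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: malformed FASTQ record near line {4 * (n_records - 1) + 1}: "
                    f"sequence/quality length mismatch"
                )
            yield Read(
                id=title.split()[0] if title else title,
                bases=seq.upper(),
                quals=tuple(ord(c) - 33 for c in qual),
            )


UNDETERMINED = "undetermined"


@dataclass
class DemuxResult:
    """Demultiplexed reads per sample plus assignment counts."""

    by_sample: dict[str, list[Read]]
    counts: dict[str, int]


class IndexTable:
    """Validated index → sample-id map for prefix demultiplexing.

    All indexes must share one length and be pairwise separated by a Hamming
    distance greater than ``2 * max_mismatch`` so that assignment within
    ``max_mismatch`` is unambiguous.
    """

    def __init__(self, indexes: Mapping[str, str], max_mismatch: int = 1):
        if not indexes:
            raise ValueError("empty index table")
        lengths = {len(ix) for ix in indexes}
        if len(lengths) != 1:
            raise ValueError(f"index sequences have mixed lengths: {sorted(lengths)}")
        for ix in indexes:
            if not set(ix) <= DNA_ALPHABET:
                raise ValueError(f"index {ix!r} contains non-ACGT characters")
        keys = list(indexes)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if hamming(a, b) <= 2 * max_mismatch:
                    raise ValueError(
                        f"ambiguous index table: {a} and {b} are within "
                        f"2*max_mismatch={2 * max_mismatch} mismatches"
                    )
        self.indexes = dict(indexes)
        self.index_len = lengths.pop()
        self.max_mismatch = max_mismatch

    def assign(self, read_prefix: str) -> str | None:
        """Sample id for the read prefix, or None if nothing is close enough."""
        for ix, sample in self.indexes.items():
            if hamming(ix, read_prefix) <= self.max_mismatch:
                return sample
        return None


def demultiplex(
    reads: Iterable[Read],
    index_table: Mapping[str, str] | IndexTable,
    max_mismatch: int = 1,
) -> DemuxResult:
    """Assign reads to samples by their index prefix and strip the prefix.

    Reads matching no index within ``max_mismatch`` go to the
    ``"undetermined"`` bin with the prefix left intact.
    """
    table = (
        index_table
        if isinstance(index_table, IndexTable)
        else IndexTable(index_table, max_mismatch)
    )
    by_sample: dict[str, list[Read]] = {s: [] for s in table.indexes.values()}
    by_sample[UNDETERMINED] = []
    for read in reads:
        prefix = read.bases[: table.index_len]
        sample = table.assign(prefix) if len(prefix) == table.index_len else None
        if sample is None:
            by_sample[UNDETERMINED].append(read)
        else:
            by_sample[sample].append(
                Read(read.id, read.bases[table.index_len :], read.quals[table.index_len :])
            )
    counts = {s: len(rs) for s, rs in by_sample.items()}
    return DemuxResult(by_sample=by_sample, counts=counts)


class RejectionReason(str, Enum):
    NO_FW = "no_fw"
    BAD_RV = "bad_rv"
    SHORT = "short"
    AMBIGUOUS_BASE = "ambiguous_base"


@dataclass(frozen=True)
class Rejection:
    reason: RejectionReason
    read_id: str


def extract_random_region(
    read: Read,
    design: LibraryDesign,
    max_mismatch_fw: int = 2,
    min_rv_overlap: int = 8,
    max_mismatch_rv: int = 1,
) -> str | Rejection:
    """Extract the random region from one read, or reject with a reason.

    The forward flank is searched at offsets 0..2 (allowing slight synthesis
    slippage) at Hamming distance <= ``max_mismatch_fw``; the best (lowest
    distance, then leftmost) hit anchors the region. If at least
    ``min_rv_overlap`` bases of the reverse flank are observable after the
    region they must agree within ``max_mismatch_rv``. Regions containing N
    are rejected, not corrected.
    """
    fw = design.fw_flank
    best: tuple[int, int] | None = None  # (distance, start)
    for start in range(0, 3):
        window = read.bases[start : start + len(fw)]
        if len(window) < len(fw):
            break
        d = hamming(window, fw)
        if d <= max_mismatch_fw and (best is None or d < best[0]):
            best = (d, start)
    if best is None:
        return Rejection(RejectionReason.NO_FW, read.id)
    region_start = best[1] + len(fw)
    region = read.bases[region_start : region_start + design.random_len]
    if len(region) < design.random_len:
        return Rejection(RejectionReason.SHORT, read.id)
    if "N" in region:
        return Rejection(RejectionReason.AMBIGUOUS_BASE, read.id)
    tail = read.bases[region_start + design.random_len :]
    overlap = min(len(tail), len(design.rv_flank_sense))
    if overlap >= min_rv_overlap:
        if hamming(tail[:overlap], design.rv_flank_sense[:overlap]) > max_mismatch_rv:
            return Rejection(RejectionReason.BAD_RV, read.id)
    return region


@dataclass
class ExtractionResult:
    regions: list[str]
    rejections: list[Rejection]

    def rejection_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for rej in self.rejections:
            tally[rej.reason.value] = tally.get(rej.reason.value, 0) + 1
        return tally


def extract_all(
    reads: Iterable[Read],
    design: LibraryDesign,
    max_mismatch_fw: int = 2,
    min_rv_overlap: int = 8,
    max_mismatch_rv: int = 1,
) -> ExtractionResult:
    """Run :func:`extract_random_region` over a stream of reads."""
    regions: list[str] = []
    rejections: list[Rejection] = []
    for read in reads:
        out = extract_random_region(read, design, max_mismatch_fw, min_rv_overlap, max_mismatch_rv)
        if isinstance(out, Rejection):
            rejections.append(out)
        else:
            regions.append(out)
    return ExtractionResult(regions=regions, rejections=rejections)
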