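"""Candidate aptamer ranking from enrichment trajectories.

Two tracks mirror how in-vivo SELEX screens are assembled: the *abundant*
track takes everything above a final-cycle frequency threshold (default
0.5%), ranked by frequency; the *low_frequency* track rescues rare
sequences whose amplification-fold profile looks like that of the abundant
winners — operationalised as cosine similarity of log2-fold vectors against
the centroid profile of the top-N abundant sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .enrichment import Trajectory
from .pools import SamplePool


@dataclass
class CandidateRecord:
    sequence: str
    track: str  # "abundant" | "low_frequency"
    final_frequency: float
    max_fold: float
    max_fold_transition: tuple[int, int]
    profile_similarity: float
    tumour_kidney_ratio: float | None = None


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def select_candidates(
    trajectories: Mapping[str, Trajectory],
    freq_threshold: float = 0.005,
    similarity_threshold: float = 0.8,
    top_n_reference: int = 10,
) -> list[CandidateRecord]:
    """Rank sequences for screening by abundance and fold-profile similarity.

    Returns the abundant track (final frequency > ``freq_threshold``, by
    descending frequency) followed by the low-frequency track (cosine
    similarity of the log2-fold profile to the centroid of the top
    ``top_n_reference`` abundant profiles >= ``similarity_threshold`` and a
    last fold >= 1, by descending similarity). All ties break
    lexicographically on the sequence, so the list is deterministic.
    """
    for traj in trajectories.values():
        if len(traj.cycles) < 2:
            raise ValueError("every trajectory needs at least two cycles")

    abundant = sorted(
        (t for t in trajectories.values() if t.final_frequency > freq_threshold),
        key=lambda t: (-t.final_frequency, t.sequence),
    )
    reference = abundant[:top_n_reference]
    if reference:
        centroid = np.mean([t.log2_fold_profile() for t in reference], axis=0)
    else:
        warnings.warn(
            "no sequence exceeds the frequency threshold; "
            "low-frequency track is empty (no reference profile)",
            stacklevel=2,
        )
        centroid = None

    records = [
        CandidateRecord(
            sequence=t.sequence,
            track="abundant",
            final_frequency=t.final_frequency,
            max_fold=t.max_fold,
            max_fold_transition=t.max_fold_transition,
            profile_similarity=_cosine(t.log2_fold_profile(), centroid)
            if centroid is not None
            else 1.0,
        )
        for t in abundant
    ]

    if centroid is not None:
        abundant_set = {t.sequence for t in abundant}
        low_track = []
        for t in trajectories.values():
            if t.sequence in abundant_set:
                continue
            sim = _cosine(t.log2_fold_profile(), centroid)
            if sim >= similarity_threshold and t.folds[-1] >= 1:
                low_track.append((sim, t))
        low_track.sort(key=lambda st: (-st[0], st[1].sequence))
        records.extend(
            CandidateRecord(
                sequence=t.sequence,
                track="low_frequency",
                final_frequency=t.final_frequency,
                max_fold=t.max_fold,
                max_fold_transition=t.max_fold_transition,
                profile_similarity=sim,
            )
            for sim, t in low_track
        )
    return records


@dataclass
class PartitionRatio:
    """Tumour/kidney frequency ratio for one sequence.

    A ratio below 1 flags a clearance-biased sequence (more abundant in the
    kidney than in the tumour); ``uninformative`` marks sequences absent
    from both pools, for which the ratio defaults to 1.
    """

    sequence: str
    ratio: float
    tumour_frequency: float
    kidney_frequency: float
    uninformative: bool = False

    def __float__(self) -> float:
        return self.ratio


def tumour_kidney_ratio(
    tumour_pool: SamplePool,
    kidney_pool: SamplePool,
    sequence: str,
    pseudocount: float = 0.5,
) -> PartitionRatio:
    """Pseudocount-adjusted frequency ratio of a sequence, tumour over kidney."""
    nt, Nt = tumour_pool.counts.get(sequence, 0), tumour_pool.total_copies
    nk, Nk = kidney_pool.counts.get(sequence, 0), kidney_pool.total_copies
    if nt == 0 and nk == 0:
        return PartitionRatio(sequence, 1.0, 0.0, 0.0, uninformative=True)
    ft = (nt + pseudocount) / (Nt + pseudocount)
    fk = (nk + pseudocount) / (Nk + pseudocount)
    return PartitionRatio(sequence, ft / fk, nt / Nt if Nt else 0.0, nk / Nk if Nk else 0.0)
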