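"""qPCR standard-curve quantification and closed-form library arithmetic.

Covers the molecular bookkeeping around a SELEX campaign: log-linear
Cq-vs-quantity standard curves with amplification efficiency, absolute
quantification of recovered aptamer, serum-stability percentages, ssDNA
molecular weight (with optional PEG moiety) and library diversity from an
injected molar amount.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

AVOGADRO = 6.02214076e23

#: Average masses (Da) of deoxynucleotide-monophosphate residues in a chain.
RESIDUE_MASS_DA = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
#: Terminal correction (Da): net effect of the 5'-OH / 3'-OH chain ends.
TERMINAL_CORRECTION_DA = 61.96


@dataclass
class StandardCurve:
    """Log-linear qPCR calibration: Cq = slope * log10(quantity) + intercept.

    ``efficiency = 10^(-1/slope) - 1`` equals 1 for perfect doubling
    (slope -1/log10(2) ~ -3.32 Cq per decade). A positive slope marks an
    invalid curve.
    """

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10 ** (-1 / self.slope) - 1

    @property
    def valid(self) -> bool:
        return self.slope < 0


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Cq against log10(quantity in fmol).

    Replicate Cq measurements of the same quantity are averaged before
    fitting. Requires >= 3 distinct positive quantities.
    """
    by_quantity: dict[float, list[float]] = {}
    for quantity, cq in standards:
        if quantity <= 0:
            raise ValueError(f"standard quantity must be positive, got {quantity}")
        by_quantity.setdefault(float(quantity), []).append(float(cq))
    if len(by_quantity) < 3:
        raise ValueError("need at least 3 distinct standard quantities")
    x = np.log10(np.array(sorted(by_quantity)))
    y = np.array([np.mean(by_quantity[q]) for q in sorted(by_quantity)])
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=float(slope), intercept=float(intercept), r_squared=r_squared)


def quantify(curve: StandardCurve, cq: float) -> float:
    """Quantity (fmol) from a Cq value: ``10^((Cq - intercept) / slope)``."""
    if not curve.valid:
        raise ValueError("invalid standard curve (non-negative slope)")
    return 10 ** ((cq - curve.intercept) / curve.slope)


@dataclass
class StabilitySeries:
    """Percent full-length aptamer over incubation time; 100% at t = 0."""

    timepoints_h: tuple[float, ...]
    percent_full_length: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints_h) != len(self.percent_full_length):
            raise ValueError("timepoints and percentages must have the same length")
        if self.timepoints_h and self.timepoints_h[0] == 0 and self.percent_full_length[0] != 100:
            raise ValueError("percent at t=0 is 100 by definition")


def stability_fraction(quant_t: float, quant_0: float) -> tuple[float, bool]:
    """Percent of full-length material remaining: ``100 * q_t / q_0``.

    Returns ``(percent, flagged)``; percentages above 100 (quantification
    noise) are reported as-is but flagged.
    """
    if quant_0 <= 0:
        raise ValueError("t=0 quantity must be positive")
    if quant_t < 0:
        raise ValueError("quantity cannot be negative")
    percent = 100.0 * quant_t / quant_0
    return percent, percent > 100.0


def stability_series(
    timepoints_h: Sequence[float], quantities_fmol: Sequence[float]
) -> StabilitySeries:
    """Build a stability series from qPCR quantities, normalised to t = 0."""
    if not timepoints_h or timepoints_h[0] != 0:
        raise ValueError("series must start at t = 0")
    q0 = quantities_fmol[0]
    percents = [stability_fraction(q, q0)[0] for q in quantities_fmol]
    percents[0] = 100.0
    return StabilitySeries(tuple(timepoints_h), tuple(percents))


def ssdna_molecular_weight(
    length_nt: int,
    composition: Mapping[str, int] | str = "equimolar",
    peg_kda: float = 0.0,
) -> float:
    """Molecular weight of an ssDNA (kDa), optionally with a PEG moiety.

    Sums average residue masses (A 313.21, C 289.18, G 329.21, T 304.20 Da)
    over the chain, applies the 61.96 Da terminal correction, and adds
    ``peg_kda``. ``composition='equimolar'`` assumes equal base shares (the
    expectation for a random library); an explicit base-count map must sum
    to ``length_nt``.
    """
    if length_nt < 1:
        raise ValueError("length must be >= 1")
    if peg_kda < 0:
        raise ValueError("peg_kda cannot be negative")
    if composition == "equimolar":
        mean_mass = sum(RESIDUE_MASS_DA.values()) / 4
        chain = length_nt * mean_mass
    else:
        if sum(composition.values()) != length_nt:
            raise ValueError("composition counts must sum to length_nt")
        chain = sum(RESIDUE_MASS_DA[b] * n for b, n in composition.items())
    return (chain - TERMINAL_CORRECTION_DA) / 1000.0 + peg_kda


def base_content(sequence: str, base: str) -> float:
    """Percent of ``sequence`` made of ``base`` (e.g. G-richness)."""
    if not sequence:
        raise ValueError("empty sequence")
    if base not in "ACGT":
        raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
    return 100.0 * sequence.count(base) / len(sequence)


def diversity_from_amount(nmol: float) -> tuple[float, float]:
    """Molecule count and order of magnitude in an injected molar amount.

    For a library with one copy per sequence this bounds the sequence
    diversity: ``count = nmol * 1e-9 * N_A``; the order is
    ``10^floor(log10(count))``.
    """
    if nmol <= 0:
        raise ValueError("amount must be positive")
    count = nmol * 1e-9 * AVOGADRO
    order = 10.0 ** math.floor(math.log10(count))
    return count, order
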