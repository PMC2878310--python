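"""Peptide and protein ratio computation with recursive outlier elimination.

A peptide observed at several charge states yields one light/heavy area
ratio per charge state; these merge into a single peptide ratio by a
weighted mean (weight = light + heavy area by default: bigger combined
signal, more reliable ratio). A protein's ratio is the arithmetic mean
of its unique peptides' ratios after recursively eliminating outliers:

* round 1 — keep ratios within median(m) +/- sqrt(m);
* later rounds — keep ratios within mean(A) +/- sqrt(A) of the
  survivors; repeat until the survivor set stops changing (or one
  survivor remains).

Intervals are closed; a round that would eliminate everything instead
keeps the single ratio closest to the round's centre, so a non-empty
input always has at least one survivor. The procedure terminates in at
most len(ratios) rounds because each non-final round strictly shrinks
the survivor set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import InsufficientDataError, InvalidAreaError

__all__ = [
    "ChargeStateQuant",
    "PeptideQuant",
    "ProteinQuant",
    "EliminationRound",
    "peptide_ratio",
    "combine_charge_states",
    "protein_ratio",
    "relative_error",
]


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


@dataclass
class ChargeStateQuant:
    """Light/heavy areas and ratio for one charge state of one peptide."""

    charge: int
    light_area: float
    heavy_area: float
    ratio: float | None = None
    weight: float = 0.0
    accepted: bool = True

    @classmethod
    def from_areas(
        cls, charge: int, light_area: float, heavy_area: float, accepted: bool = True
    ) -> "ChargeStateQuant":
        return cls(
            charge=charge,
            light_area=light_area,
            heavy_area=heavy_area,
            ratio=peptide_ratio(light_area, heavy_area),
            weight=light_area + heavy_area,
            accepted=accepted,
        )


@dataclass
class PeptideQuant:
    """All charge states of one peptide and their combined ratio."""

    peptide: str
    protein: str
    charge_states: list[ChargeStateQuant] = field(default_factory=list)
    combined_ratio: float | None = None

    def combine(self) -> float | None:
        self.combined_ratio = combine_charge_states(
            [(cs.ratio, cs.weight) for cs in self.charge_states if cs.accepted]
        )
        return self.combined_ratio


@dataclass
class EliminationRound:
    """Audit record of one outlier-elimination round."""

    number: int
    center_kind: str  # "median" (round 1) or "mean"
    center: float
    low: float
    high: float
    eliminated: list[float]
    survivors: list[float]


@dataclass
class ProteinQuant:
    """Peptide ratios of one protein and the outlier-pruned mean."""

    protein: str
    peptide_ratios: list[float]
    surviving_ratios: list[float]
    final_ratio: float
    rounds: list[EliminationRound]


def peptide_ratio(light_area: float, heavy_area: float) -> float | None:
    """Light/heavy area ratio; ``None`` (undefined, not zero) when heavy = 0."""
    if light_area < 0 or heavy_area < 0:
        raise InvalidAreaError(
            f"areas must be >= 0, got light={light_area}, heavy={heavy_area}"
        )
    if heavy_area == 0:
        return None
    return light_area / heavy_area


def combine_charge_states(entries: Sequence[tuple[float | None, float]]) -> float | None:
    """Weighted arithmetic mean of per-charge-state ratios.

    Entries are ``(ratio, weight)``; undefined ratios and non-positive
    weights are skipped. Returns ``None`` when nothing is usable — the
    peptide is unquantifiable, which is an outcome, not an error.
    """
    num = den = 0.0
    for ratio, weight in entries:
        if ratio is None or weight <= 0:
            continue
        num += weight * ratio
        den += weight
    if den == 0.0:
        return None
    return num / den


def protein_ratio(ratios: Sequence[float], protein: str = "") -> ProteinQuant:
    """Aggregate peptide ratios into one protein ratio, pruning outliers.

    See the module docstring for the recursion. All input ratios must be
    defined and > 0; an empty input raises
    :class:`InsufficientDataError`. Deterministic and independent of
    input order.
    """
    vals = [float(r) for r in ratios]
    if not vals:
        raise InsufficientDataError(f"no quantified peptides for protein {protein!r}")
    if any(not (r > 0) or math.isnan(r) for r in vals):
        raise ValueError("all peptide ratios must be defined and > 0")

    survivors = sorted(vals)
    rounds: list[EliminationRound] = []
    number = 0
    while True:
        number += 1
        if number == 1:
            center = _median(survivors)
            kind = "median"
        else:
            center = sum(survivors) / len(survivors)
            kind = "mean"
        half = math.sqrt(center)
        low, high = center - half, center + half
        kept = [r for r in survivors if low <= r <= high]
        if not kept:  # guarantee >= 1 survivor: keep the ratio nearest the centre
            kept = [min(survivors, key=lambda r: (abs(r - center), r))]
        eliminated = _difference(survivors, kept)
        rounds.append(
            EliminationRound(
                number=number,
                center_kind=kind,
                center=center,
                low=low,
                high=high,
                eliminated=eliminated,
                survivors=list(kept),
            )
        )
        if len(kept) == len(survivors) or len(kept) == 1:
            survivors = kept
            break
        survivors = kept

    return ProteinQuant(
        protein=protein,
        peptide_ratios=vals,
        surviving_ratios=survivors,
        final_ratio=sum(survivors) / len(survivors),
        rounds=rounds,
    )


def _difference(before: list[float], after: list[float]) -> list[float]:
    out = list(before)
    for r in after:
        out.remove(r)
    return out


def relative_error(estimated: float, expected: float) -> float:
    """Accuracy metric in percent: 100 * |estimated - expected| / expected."""
    if expected <= 0:
        raise ValueError(f"expected ratio must be > 0, got {expected}")
    return 100.0 * abs(estimated - expected) / expected
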