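"""Carbon-isotope diet reconstruction and C3/C4 end-member mixing.

Bioapatite d13C exceeds diet d13C by a taxon-level enrichment factor
(default +9.9 per mil for rodent bone).  Diet values are interpreted against
two plant end-members (C3 mean -27, C4 mean -13 per mil) by linear mixing.
CAM plants are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .core import SpecimenRecord, sample_sd
from .errors import InvalidInputError

log = logging.getLogger(__name__)

#: Raw mixing fractions outside this band raise the out-of-range flag, so
#: that e.g. subcanopy C3 diets (below the C3 mean) flag instead of being
#: clamped silently.
CLIP_TOLERANCE = 0.05


@dataclass(frozen=True)
class DietModel:
    """Scalar enrichment plus C3/C4 end-member means, all per mil vs VPDB."""

    enrichment: float = 9.9
    c3_endmember: float = -27.0
    c4_endmember: float = -13.0

    def __post_init__(self) -> None:
        if not (self.c4_endmember > self.c3_endmember):
            raise InvalidInputError("c4_endmember must exceed c3_endmember")
        if not (0.0 <= self.enrichment <= 20.0):
            raise InvalidInputError("enrichment must lie in [0, 20] per mil")


DEFAULT_MODEL = DietModel()


def apatite_to_diet(d13C_apatite: float, model: DietModel = DEFAULT_MODEL) -> float:
    """Diet d13C implied by a bioapatite d13C value (pure shift)."""
    return d13C_apatite - model.enrichment


def c4_fraction(
    d13C_diet: float, model: DietModel = DEFAULT_MODEL
) -> tuple[float, bool]:
    """Two-end-member C4 fraction of a diet d13C value.

    Returns ``(fraction, flagged)`` where the fraction is clipped to [0, 1]
    and ``flagged`` is True when the raw value falls outside
    ``[-CLIP_TOLERANCE, 1 + CLIP_TOLERANCE]``.
    """
    raw = (d13C_diet - model.c3_endmember) / (model.c4_endmember - model.c3_endmember)
    flagged = raw < -CLIP_TOLERANCE or raw > 1.0 + CLIP_TOLERANCE
    return min(1.0, max(0.0, raw)), flagged


@dataclass(frozen=True)
class DietGroupSummary:
    species: str
    n: int
    diet_mean: float
    diet_sd: float | None
    diet_min: float
    diet_max: float
    c4_fraction_of_mean: float
    flagged: bool


def diet_summary(
    records: Iterable[SpecimenRecord],
    model: DietModel = DEFAULT_MODEL,
) -> list[DietGroupSummary]:
    """Per-species diet reconstruction from apatite d13C records.

    Records without d13C are skipped; species without any d13C data are
    omitted with a logged notice.  Output is sorted by species name.
    """
    by_species: dict[str, list[float]] = {}
    skipped: dict[str, int] = {}
    for rec in records:
        if rec.d13C is None:
            skipped[rec.species] = skipped.get(rec.species, 0) + 1
            continue
        by_species.setdefault(rec.species, []).append(
            apatite_to_diet(rec.d13C, model)
        )
    for species, n_missing in skipped.items():
        if species not in by_species:
            log.info("diet_summary: species %r omitted (%d records lack d13C)",
                     species, n_missing)

    out = []
    for species in sorted(by_species):
        diets = by_species[species]
        mean = sum(diets) / len(diets)
        frac, flagged = c4_fraction(mean, model)
        out.append(
            DietGroupSummary(
                species=species,
                n=len(diets),
                diet_mean=mean,
                diet_sd=sample_sd(diets),
                diet_min=min(diets),
                diet_max=max(diets),
                c4_fraction_of_mean=frac,
                flagged=flagged,
            )
        )
    return out
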