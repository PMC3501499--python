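"""Domain types for isotope measurements and carbonate-phosphate offset arithmetic.

All oxygen values are per mil vs VSMOW, carbon values per mil vs VPDB.
The carbonate-phosphate offset sign convention is fixed project-wide as
``CO3 - PO4`` (positive, typically 9-11 per mil for rodent bioapatite).
Missing isotope fields are ``None``, never sentinel numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .errors import (
    EmptySelectionError,
    InvalidInputError,
    MissingDataError,
)

Family = Literal["arvicolid", "murid", "other"]
Tissue = Literal["incisor", "M1", "M2", "M3", "bone"]
Side = Literal["left", "right", "both", "unknown"]
AgeClass = Literal["juvenile", "adult", "unknown"]

TISSUES: tuple[str, ...] = ("incisor", "M1", "M2", "M3", "bone")
TOOTH_TISSUES: tuple[str, ...] = ("incisor", "M1", "M2", "M3")
MOLAR_TISSUES: tuple[str, ...] = ("M1", "M2", "M3")
FAMILIES: tuple[str, ...] = ("arvicolid", "murid", "other")

#: Sanity windows for flagging (never dropping) implausible values, per mil.
D18O_SANITY = (0.0, 50.0)
D13C_SANITY = (-40.0, 10.0)


@dataclass(frozen=True)
class SpecimenRecord:
    """One skeletal-tissue measurement of one individual.

    At least one of ``d18O_co3``, ``d18O_po4``, ``d13C`` must be present.
    ``flags`` collects sanity-window violations; flagged records stay in the
    dataset and are only excluded by explicit exclusion lists.
    """

    specimen_id: str
    species: str
    family: str = "other"
    tissue: str = "incisor"
    side: str | None = None
    d18O_co3: float | None = None
    d18O_po4: float | None = None
    d13C: float | None = None
    age_class: str | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.d18O_co3 is None and self.d18O_po4 is None and self.d13C is None:
            raise InvalidInputError(
                f"record ({self.specimen_id}, {self.tissue}): at least one "
                "isotope value is required"
            )
        if self.family not in FAMILIES:
            raise InvalidInputError(
                f"record ({self.specimen_id}, {self.tissue}): unknown family "
                f"{self.family!r}"
            )
        if self.tissue not in TISSUES:
            raise InvalidInputError(
                f"record ({self.specimen_id}, {self.tissue}): unknown tissue"
            )
        object.__setattr__(
            self, "flags", tuple(self.flags) + tuple(self._sanity_flags())
        )

    def _sanity_flags(self) -> list[str]:
        flags = []
        for name, value, (lo, hi) in (
            ("d18O_co3", self.d18O_co3, D18O_SANITY),
            ("d18O_po4", self.d18O_po4, D18O_SANITY),
            ("d13C", self.d13C, D13C_SANITY),
        ):
            if value is not None and not (lo <= value <= hi):
                flags.append(f"{name}_out_of_sanity_window")
        return flags

    @property
    def key(self) -> tuple[str, str]:
        """Unique key within a dataset: (specimen_id, tissue)."""
        return (self.specimen_id, self.tissue)

    def value(self, variable: str) -> float | None:
        if variable not in ("d18O_co3", "d18O_po4", "d13C"):
            raise InvalidInputError(f"unknown isotope variable {variable!r}")
        return getattr(self, variable)


@dataclass(frozen=True)
class OffsetEstimate:
    """Carbonate-minus-phosphate offset statistics for a set of paired values.

    ``sd_offset`` is the n-1 sample SD and is ``None`` when only one pair is
    available.
    """

    n_pairs: int
    mean_offset: float
    sd_offset: float | None
    per_pair: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise InvalidInputError("OffsetEstimate requires n_pairs >= 1")
        if self.n_pairs == 1 and self.sd_offset is not None:
            raise InvalidInputError("sd_offset must be absent when n_pairs == 1")
        if self.sd_offset is not None and self.sd_offset < 0:
            raise InvalidInputError("sd_offset must be non-negative")
        check = sum(o for (_, _, o) in self.per_pair) / len(self.per_pair)
        if abs(check - self.mean_offset) > 1e-9:
            raise InvalidInputError(
                "mean_offset inconsistent with per_pair offsets"
            )


def delta_from_ratios(r_sample: float, r_standard: float) -> float:
    """Per-mil delta value from sample and standard isotope ratios.

    delta = (r_sample / r_standard - 1) * 1000
    """
    if not (r_sample > 0):
        raise InvalidInputError(f"r_sample must be > 0, got {r_sample!r}")
    if not (r_standard > 0):
        raise InvalidInputError(f"r_standard must be > 0, got {r_standard!r}")
    return (r_sample / r_standard - 1.0) * 1000.0


def pairwise_offset(co3: float | None, po4: float | None, *,
                    record: SpecimenRecord | None = None) -> float:
    """Carbonate-minus-phosphate offset for one paired measurement."""
    if co3 is None or po4 is None:
        which = "d18O_co3" if co3 is None else "d18O_po4"
        where = f" on record {record.key}" if record is not None else ""
        raise MissingDataError(f"{which} missing{where}")
    return co3 - po4


def sample_sd(values: Sequence[float]) -> float | None:
    """n-1 sample standard deviation; ``None`` for fewer than two values."""
    n = len(values)
    if n < 2:
        return None
    m = sum(values) / n
    return math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))


def estimate_offset(
    records: Iterable[SpecimenRecord],
    group_by: str | Sequence[str] | None = None,
) -> OffsetEstimate:
    """Estimate the CO3-PO4 offset over records carrying both oxygen values.

    Parameters
    ----------
    records
        Any iterable of :class:`SpecimenRecord`.
    group_by
        Optional tissue name (or collection of tissue names); only matching
        tissues enter the estimate.
    """
    if group_by is None:
        tissues = None
    elif isinstance(group_by, str):
        tissues = {group_by}
    else:
        tissues = set(group_by)

    per_pair: list[tuple[str, str, float]] = []
    for rec in records:
        if tissues is not None and rec.tissue not in tissues:
            continue
        if rec.d18O_co3 is None or rec.d18O_po4 is None:
            continue
        per_pair.append(
            (rec.specimen_id, rec.tissue, pairwise_offset(rec.d18O_co3, rec.d18O_po4))
        )
    if not per_pair:
        raise EmptySelectionError(
            "no records carry both d18O_co3 and d18O_po4"
            + (f" for tissues {sorted(tissues)}" if tissues else "")
        )
    offsets = [o for (_, _, o) in per_pair]
    return OffsetEstimate(
        n_pairs=len(per_pair),
        mean_offset=sum(offsets) / len(offsets),
        sd_offset=sample_sd(offsets),
        per_pair=tuple(per_pair),
    )


def co3_to_po4(
    d18O_co3: float,
    offset: float,
    offset_sd: float | None = None,
    input_sd: float | None = None,
) -> float | tuple[float, float]:
    """Convert a carbonate delta to its phosphate equivalent.

    Returns ``d18O_co3 - offset``; when both an input SD and an offset SD are
    supplied, returns ``(value, sd)`` with first-order propagation under
    independence: ``sd = sqrt(input_sd**2 + offset_sd**2)``.
    """
    if not math.isfinite(offset):
        raise InvalidInputError("offset must be finite")
    value = d18O_co3 - offset
    if offset_sd is not None or input_sd is not None:
        var = (input_sd or 0.0) ** 2 + (offset_sd or 0.0) ** 2
        return value, math.sqrt(var)
    return value


def po4_to_co3(d18O_po4: float, offset: float) -> float:
    """Inverse of :func:`co3_to_po4` for the same offset."""
    if not math.isfinite(offset):
        raise InvalidInputError("offset must be finite")
    return d18O_po4 + offset


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used in all rendered tables."""
    factor = 10.0 ** ndigits
    scaled = value * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor
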