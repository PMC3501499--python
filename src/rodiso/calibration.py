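"""Registry and application of linear phosphate/local-water calibration lines.

Equations are stored exactly in the published form

    d18O_LW = (d18O_PO4 - a) / b

and the forward map ``a + b * d18O_LW`` is derived algebraically, not stored
separately.  The registry ships with the three published rodent equations;
users may register additional lines at run time.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .core import (
    SpecimenRecord,
    TOOTH_TISSUES,
    co3_to_po4,
    sample_sd,
)
from .errors import (
    EmptySelectionError,
    InvalidInputError,
    NotFoundError,
    RegistryConflictError,
)


class TissueMismatchWarning(UserWarning):
    """Equation tissue basis disagrees with the tissues being reconstructed.

    A warning, not an error: mismatched comparisons are legitimate (and
    instructive) but systematically biased because teeth and bone integrate
    different formation windows.
    """


@dataclass(frozen=True)
class CalibrationEquation:
    """A named linear relation d18O_LW = (d18O_PO4 - a) / b."""

    name: str
    intercept_a: float
    slope_b: float
    tissue_basis: str  # bone | tooth | mixed
    taxa: tuple[str, ...] = ()
    valid_lw_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.slope_b == 0:
            raise InvalidInputError(f"calibration {self.name!r}: slope_b must be nonzero")
        if self.tissue_basis not in ("bone", "tooth", "mixed"):
            raise InvalidInputError(
                f"calibration {self.name!r}: tissue_basis must be bone/tooth/mixed"
            )

    def matches_tissue(self, tissue: str) -> bool:
        if self.tissue_basis == "mixed":
            return True
        basis = "tooth" if tissue in TOOTH_TISSUES else "bone"
        return basis == self.tissue_basis


#: Extrapolation caveat for the laboratory-rat line: its calibration range
#: does not cover the local-water regime of temperate field sites.  The bound
#: is configurable because no numeric range was published.
LUZ_KOLODNY_LW_RANGE = (-4.0, 10.0)


def _builtin_equations() -> list[CalibrationEquation]:
    eqs = []
    with resources.files("rodiso.data").joinpath("calibrations.csv").open(
        encoding="utf-8"
    ) as fh:
        for row in csv.DictReader(fh):
            eqs.append(
                CalibrationEquation(
                    name=row["name"],
                    intercept_a=float(row["intercept_a"]),
                    slope_b=float(row["slope_b"]),
                    tissue_basis=row["tissue_basis"],
                    taxa=tuple(row["taxa"].split(";")) if row["taxa"] else (),
                    valid_lw_range=(
                        LUZ_KOLODNY_LW_RANGE
                        if row["name"] == "luz_kolodny_1985"
                        else None
                    ),
                )
            )
    return eqs


class CalibrationRegistry:
    """Mutable mapping of equation name -> :class:`CalibrationEquation`."""

    def __init__(self, equations: Iterable[CalibrationEquation] | None = None):
        self._by_name: dict[str, CalibrationEquation] = {}
        for eq in equations if equations is not None else _builtin_equations():
            self.register(eq)

    def register(self, eq: CalibrationEquation) -> None:
        if eq.name in self._by_name:
            raise RegistryConflictError(
                f"calibration {eq.name!r} is already registered"
            )
        self._by_name[eq.name] = eq

    def get(self, name: str) -> CalibrationEquation:
        try:
            return self._by_name[name]
        except KeyError:
            raise NotFoundError(
                f"unknown calibration {name!r}; known: {sorted(self._by_name)}"
            ) from None

    def names(self) -> list[str]:
        return sorted(self._by_name)

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)


_DEFAULT_REGISTRY: CalibrationRegistry | None = None


def registry() -> CalibrationRegistry:
    """The process-wide default registry (built-in equations plus additions)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = CalibrationRegistry()
    return _DEFAULT_REGISTRY


def get_equation(name: str) -> CalibrationEquation:
    return registry().get(name)


def to_local_water(
    eq: CalibrationEquation, d18O_po4: float, *, warn_extrapolation: bool = True
) -> float:
    """Invert the calibration line: local-water delta from a phosphate delta."""
    if not math.isfinite(d18O_po4):
        raise InvalidInputError("d18O_po4 must be finite")
    lw = (d18O_po4 - eq.intercept_a) / eq.slope_b
    if (
        warn_extrapolation
        and eq.valid_lw_range is not None
        and not (eq.valid_lw_range[0] <= lw <= eq.valid_lw_range[1])
    ):
        warnings.warn(
            f"{eq.name}: reconstructed water {lw:.2f} lies outside the "
            f"calibrated range {eq.valid_lw_range}; extrapolation",
            UserWarning,
            stacklevel=2,
        )
    return lw


def from_local_water(eq: CalibrationEquation, d18O_lw: float) -> float:
    """Forward map: phosphate delta predicted for a local-water delta."""
    if not math.isfinite(d18O_lw):
        raise InvalidInputError("d18O_lw must be finite")
    return eq.intercept_a + eq.slope_b * d18O_lw


@dataclass(frozen=True)
class WaterReconstruction:
    """Result of inverting a calibration line over a set of records."""

    equation: str
    d18O_lw: float
    sd: float | None
    n_records: int
    n_converted_from_co3: int
    mean_po4: float
    tissue_warning: bool
    extrapolation: bool = False
    notes: tuple[str, ...] = field(default_factory=tuple)


def reconstruct_water(
    records: Iterable[SpecimenRecord],
    eq: CalibrationEquation,
    offset: float,
    offset_sd: float | None = None,
    tissue_filter: Sequence[str] | None = None,
) -> WaterReconstruction:
    """Reconstruct local-water d18O from a set of records via one equation.

    Measured phosphate values are used when present; otherwise carbonate
    values are converted with the supplied CO3-PO4 offset.  Records are
    averaged with equal weight, the mean is inverted through ``eq``, and a
    :class:`TissueMismatchWarning` is emitted when the equation's tissue
    basis disagrees with any selected tissue.

    The returned ``sd`` propagates the between-record sample SD together
    with the offset SD (applied to the converted fraction), divided by |b|.
    """
    tissues = set(tissue_filter) if tissue_filter is not None else None
    po4_values: list[float] = []
    n_converted = 0
    used_tissues: set[str] = set()
    for rec in records:
        if tissues is not None and rec.tissue not in tissues:
            continue
        if rec.d18O_po4 is not None:
            po4_values.append(rec.d18O_po4)
        elif rec.d18O_co3 is not None:
            po4_values.append(co3_to_po4(rec.d18O_co3, offset))
            n_converted += 1
        else:
            continue
        used_tissues.add(rec.tissue)
    if not po4_values:
        raise EmptySelectionError(
            "no records with oxygen data"
            + (f" for tissues {sorted(tissues)}" if tissues else "")
        )

    mismatch = any(not eq.matches_tissue(t) for t in used_tissues)
    if mismatch:
        warnings.warn(
            f"{eq.name} is {eq.tissue_basis}-based but the selection includes "
            f"tissues {sorted(used_tissues)}: tissue-formation-time bias likely",
            TissueMismatchWarning,
            stacklevel=2,
        )

    mean_po4 = sum(po4_values) / len(po4_values)
    lw = to_local_water(eq, mean_po4, warn_extrapolation=False)
    extrapolated = eq.valid_lw_range is not None and not (
        eq.valid_lw_range[0] <= lw <= eq.valid_lw_range[1]
    )

    spread = sample_sd(po4_values)
    sd = None
    if spread is not None or offset_sd is not None:
        conv_frac = n_converted / len(po4_values)
        var = (spread or 0.0) ** 2 + conv_frac * (offset_sd or 0.0) ** 2
        sd = math.sqrt(var) / abs(eq.slope_b)

    notes = []
    if n_converted:
        notes.append(
            f"{n_converted}/{len(po4_values)} values converted from d18O_co3 "
            f"with offset {offset:g}"
        )
    return WaterReconstruction(
        equation=eq.name,
        d18O_lw=lw,
        sd=sd,
        n_records=len(po4_values),
        n_converted_from_co3=n_converted,
        mean_po4=mean_po4,
        tissue_warning=mismatch,
        extrapolation=extrapolated,
        notes=tuple(notes),
    )
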