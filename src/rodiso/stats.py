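"""Community-level summaries, paired tissue offsets and inferential tests.

The test statistics (one-way ANOVA, Tukey HSD, tie-corrected Kruskal-Wallis)
are computed from their classical decompositions; only the reference
distributions (F, studentized range, chi-square) come from scipy.  Sample
SDs use the n-1 denominator throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats as _sps

from .core import (
    MOLAR_TISSUES,
    SpecimenRecord,
    TOOTH_TISSUES,
    sample_sd,
)
from .errors import (
    DegenerateVarianceError,
    EmptySelectionError,
    InvalidInputError,
)

log = logging.getLogger(__name__)

_VARIABLES = ("d18O_co3", "d18O_po4", "d13C")
_GROUP_FIELDS = ("species", "tissue", "family", "age_class")


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD/range of one variable within one group of records."""

    group_key: tuple
    n: int
    mean: float
    sd: float | None
    min: float
    max: float

    @property
    def range_width(self) -> float:
        return self.max - self.min


@dataclass(frozen=True)
class PairedOffsetReport:
    """Per-specimen offsets between two tissues of the same individual."""

    tissue_a: str
    tissue_b: str
    variable: str
    pairs: tuple[tuple[str, str, str, float], ...]  # (specimen, tissue_a, tissue_b, offset)
    offset_sd_by_species: Mapping[str, float | None]

    @property
    def n_positive(self) -> int:
        return sum(1 for (_, _, _, o) in self.pairs if o > 0)

    @property
    def proportion_positive(self) -> float:
        return self.n_positive / len(self.pairs)


def _check_variable(variable: str) -> None:
    if variable not in _VARIABLES:
        raise InvalidInputError(
            f"unknown variable {variable!r}; expected one of {_VARIABLES}"
        )


def summarize(
    records: Iterable[SpecimenRecord],
    group_by: str | Sequence[str] = ("species", "tissue"),
    variable: str = "d18O_co3",
) -> list[GroupSummary]:
    """Group records and summarise one isotope variable per group.

    Missing values are excluded (count logged); groups with no data are
    omitted.  Output order is sorted by group key.
    """
    _check_variable(variable)
    fields = (group_by,) if isinstance(group_by, str) else tuple(group_by)
    for f in fields:
        if f not in _GROUP_FIELDS:
            raise InvalidInputError(f"cannot group by {f!r}")

    groups: dict[tuple, list[float]] = {}
    n_missing = 0
    for rec in records:
        value = rec.value(variable)
        if value is None:
            n_missing += 1
            continue
        key = tuple(getattr(rec, f) for f in fields)
        groups.setdefault(key, []).append(value)
    if n_missing:
        log.info("summarize: %d records lack %s and were excluded",
                 n_missing, variable)

    out = []
    for key in sorted(groups, key=lambda k: tuple(str(x) for x in k)):
        vals = groups[key]
        out.append(
            GroupSummary(
                group_key=key,
                n=len(vals),
                mean=sum(vals) / len(vals),
                sd=sample_sd(vals),
                min=min(vals),
                max=max(vals),
            )
        )
    return out


def paired_tissue_offsets(
    records: Iterable[SpecimenRecord],
    tissue_a: str,
    tissue_b: str,
    variable: str = "d18O_co3",
) -> PairedOffsetReport:
    """Offsets ``value(tissue_a) - value(tissue_b)`` per specimen.

    Only specimens measured in both tissues enter; the species-level SD of
    the offsets is reported alongside.
    """
    _check_variable(variable)
    by_specimen: dict[str, dict[str, float]] = {}
    species_of: dict[str, str] = {}
    for rec in records:
        value = rec.value(variable)
        if value is None or rec.tissue not in (tissue_a, tissue_b):
            continue
        by_specimen.setdefault(rec.specimen_id, {})[rec.tissue] = value
        species_of[rec.specimen_id] = rec.species

    pairs = []
    offsets_by_species: dict[str, list[float]] = {}
    for sid in sorted(by_specimen):
        vals = by_specimen[sid]
        if tissue_a in vals and tissue_b in vals:
            off = vals[tissue_a] - vals[tissue_b]
            pairs.append((sid, tissue_a, tissue_b, off))
            offsets_by_species.setdefault(species_of[sid], []).append(off)
    if not pairs:
        raise EmptySelectionError(
            f"no specimens measured in both {tissue_a!r} and {tissue_b!r}"
        )
    return PairedOffsetReport(
        tissue_a=tissue_a,
        tissue_b=tissue_b,
        variable=variable,
        pairs=tuple(pairs),
        offset_sd_by_species={
            sp: sample_sd(offs) for sp, offs in sorted(offsets_by_species.items())
        },
    )


@dataclass(frozen=True)
class IntraJawRange:
    specimen_id: str
    n_teeth: int
    overall_range: float          # across all available teeth (I1, M1-M3)
    molar_range: float | None     # across M1-M3 only, None if < 2 molars


def intra_jaw_ranges(
    records: Iterable[SpecimenRecord],
    variable: str = "d18O_co3",
) -> list[IntraJawRange]:
    """Per-specimen max-min ranges over tooth tissues.

    Specimens with fewer than two measured teeth are skipped with a notice.
    """
    _check_variable(variable)
    teeth: dict[str, dict[str, float]] = {}
    for rec in records:
        value = rec.value(variable)
        if value is None or rec.tissue not in TOOTH_TISSUES:
            continue
        teeth.setdefault(rec.specimen_id, {})[rec.tissue] = value

    out = []
    for sid in sorted(teeth):
        vals = teeth[sid]
        if len(vals) < 2:
            log.info("intra_jaw_ranges: specimen %r has <2 teeth, skipped", sid)
            continue
        all_vals = list(vals.values())
        molars = [v for t, v in vals.items() if t in MOLAR_TISSUES]
        out.append(
            IntraJawRange(
                specimen_id=sid,
                n_teeth=len(vals),
                overall_range=max(all_vals) - min(all_vals),
                molar_range=(max(molars) - min(molars)) if len(molars) >= 2 else None,
            )
        )
    return out


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float


def _validate_groups(groups: Sequence[Sequence[float]], min_n: int = 2) -> None:
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) < min_n:
            raise InvalidInputError(f"group {i} has fewer than {min_n} values")


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within with p from the F distribution.  Zero pooled
    within-group variance raises :class:`DegenerateVarianceError` rather than
    returning an infinite statistic.
    """
    _validate_groups(groups)
    if all(len(set(g)) == 1 for g in groups):
        # exact check: float noise in the mean must not disguise degeneracy
        raise DegenerateVarianceError(
            "zero within-group variance; F is undefined"
        )
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n_total
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(
        sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups
    )
    df_between = k - 1
    df_within = n_total - k
    if ss_within <= 0:
        raise DegenerateVarianceError(
            "zero within-group variance; F is undefined"
        )
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(_sps.f.sf(f, df_between, df_within))
    return AnovaResult(
        f_statistic=f,
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        ss_between=ss_between,
        ss_within=ss_within,
    )


@dataclass(frozen=True)
class TukeyPair:
    group_i: int
    group_j: int
    difference: float      # mean_i - mean_j
    q_statistic: float
    p_adjusted: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adjusted < alpha


def tukey_hsd(groups: Sequence[Sequence[float]]) -> list[TukeyPair]:
    """All-pairs Tukey HSD with the Tukey-Kramer unequal-n convention.

    For each pair (i, j): SE = sqrt(MSW/2 * (1/n_i + 1/n_j)),
    q = |mean_i - mean_j| / SE, adjusted p from the studentized range
    distribution with k groups and the ANOVA within-group df.
    """
    anova = one_way_anova(groups)
    k = len(groups)
    msw = anova.ss_within / anova.df_within
    means = [sum(g) / len(g) for g in groups]
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(msw / 2.0 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            diff = means[i] - means[j]
            q = abs(diff) / se
            p = float(_sps.studentized_range.sf(q, k, anova.df_within))
            out.append(
                TukeyPair(
                    group_i=i,
                    group_j=j,
                    difference=diff,
                    q_statistic=q,
                    p_adjusted=min(1.0, p),
                )
            )
    return out


@dataclass(frozen=True)
class KruskalResult:
    h_statistic: float
    df: int
    p_value: float
    tie_correction: float


def _midranks(values: Sequence[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for idx in order[i:j + 1]:
            ranks[idx] = mid
        i = j + 1
    return ranks


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis rank test with the standard tie correction.

    H = [12/(N(N+1)) * sum(R_g^2 / n_g) - 3(N+1)] / C where
    C = 1 - sum(t^3 - t)/(N^3 - N) over tie groups of size t; p-value from
    the chi-square approximation with k-1 df.
    """
    _validate_groups(groups, min_n=1)
    pooled = [x for g in groups for x in g]
    n_total = len(pooled)
    if len(set(pooled)) == 1:
        raise DegenerateVarianceError("all values tied; H is undefined")
    ranks = _midranks(pooled)

    h = 0.0
    start = 0
    for g in groups:
        r_sum = sum(ranks[start:start + len(g)])
        h += r_sum ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)

    tie_sizes: dict[float, int] = {}
    for x in pooled:
        tie_sizes[x] = tie_sizes.get(x, 0) + 1
    correction = 1.0 - sum(t ** 3 - t for t in tie_sizes.values()) / (
        n_total ** 3 - n_total
    )
    h /= correction
    df = len(groups) - 1
    return KruskalResult(
        h_statistic=h,
        df=df,
        p_value=float(_sps.chi2.sf(h, df)),
        tie_correction=correction,
    )


def flag_outliers(values: Sequence[float], k: float = 3.0) -> list[bool]:
    """Flag values far from the group median, leave-one-out scaled.

    A value is flagged when ``|x - median| > k * SD(remaining values)``.
    Flags only — nothing is removed; exclusion is an explicit, separate step.
    """
    n = len(values)
    if n < 3:
        raise InvalidInputError("flag_outliers requires at least 3 values")
    if math.isinf(k):
        return [False] * n  # rule disabled
    med = float(_sps.scoreatpercentile(values, 50))
    flags = []
    for i, x in enumerate(values):
        rest = [v for j, v in enumerate(values) if j != i]
        sd = sample_sd(rest)
        flags.append(sd is not None and abs(x - med) > k * sd)
    return flags
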