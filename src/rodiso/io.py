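"""Canonical dataset CSV reading/writing, bundled fixtures, report bundle.

Canonical dataset format: UTF-8, comma-delimited, LF line endings, header

    specimen_id,species,family,tissue,side,d18O_co3,d18O_po4,d13C,age_class

with empty string for missing values and ``.`` as decimal separator.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import calibration as _calibration
from . import diet as _diet
from . import samplesize as _samplesize
from . import stats as _stats
from .core import (
    OffsetEstimate,
    SpecimenRecord,
    estimate_offset,
    round_half_away,
)
from .errors import EmptySelectionError, FormatError, RodisoError

log = logging.getLogger(__name__)

HEADER = [
    "specimen_id", "species", "family", "tissue", "side",
    "d18O_co3", "d18O_po4", "d13C", "age_class",
]
_NUMERIC = ("d18O_co3", "d18O_po4", "d13C")


@dataclass
class Dataset:
    """A list of specimen records plus provenance and explicit exclusions."""

    records: list[SpecimenRecord]
    provenance: str = ""
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.key in seen:
                raise FormatError(
                    f"duplicate (specimen_id, tissue) pair {rec.key}"
                )
            seen.add(rec.key)
        for sid, tissue, _reason in self.exclusions:
            if (sid, tissue) not in seen:
                raise FormatError(
                    f"exclusion references unknown record ({sid}, {tissue})"
                )

    def active_records(self) -> list[SpecimenRecord]:
        """Records minus the explicit exclusion list."""
        excluded = {(sid, tissue) for sid, tissue, _ in self.exclusions}
        return [r for r in self.records if r.key not in excluded]

    def __len__(self) -> int:
        return len(self.records)


def read_dataset(path: str | Path, strict: bool = False) -> Dataset:
    """Read a canonical dataset CSV.

    In strict mode, sanity-window violations are errors; otherwise the
    offending records are flagged and kept.
    """
    path = Path(path)
    records: list[SpecimenRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header") from None
        if header != HEADER:
            missing = [c for c in HEADER if c not in header]
            raise FormatError(
                f"{path}: header mismatch; missing columns {missing}"
                if missing else f"{path}: header columns out of order"
            )
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != len(HEADER):
                raise FormatError(f"{path}:{lineno}: expected {len(HEADER)} fields")
            fields = dict(zip(HEADER, (cell.strip() for cell in row)))
            numeric: dict[str, float | None] = {}
            for col in _NUMERIC:
                raw = fields[col]
                if raw == "":
                    numeric[col] = None
                    continue
                try:
                    numeric[col] = float(raw)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: unparseable {col} value {raw!r}"
                    ) from None
            rec = SpecimenRecord(
                specimen_id=fields["specimen_id"],
                species=fields["species"],
                family=fields["family"] or "other",
                tissue=fields["tissue"],
                side=fields["side"] or None,
                d18O_co3=numeric["d18O_co3"],
                d18O_po4=numeric["d18O_po4"],
                d13C=numeric["d13C"],
                age_class=fields["age_class"] or None,
            )
            if rec.flags:
                if strict:
                    raise FormatError(
                        f"{path}:{lineno}: sanity-window violation {rec.flags}"
                    )
                log.warning("%s:%d: flagged record %s: %s",
                            path, lineno, rec.key, rec.flags)
            records.append(rec)
    if not records:
        log.warning("%s: valid header but no records", path)
    return Dataset(records=records, provenance=str(path))


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return str(value)
    return str(value)


def write_dataset(dataset: Dataset | Iterable[SpecimenRecord], path: str | Path) -> None:
    """Write records in the canonical CSV format (LF endings)."""
    records = dataset.records if isinstance(dataset, Dataset) else list(dataset)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(HEADER)
        for rec in records:
            writer.writerow([
                rec.specimen_id, rec.species, rec.family, rec.tissue,
                rec.side or "", _fmt(rec.d18O_co3), _fmt(rec.d18O_po4),
                _fmt(rec.d13C), rec.age_class or "",
            ])


def fixture_path(name: str):
    """Path-like handle to a bundled fixture CSV (context-manager free)."""
    return resources.files("rodiso.data").joinpath(name)


def load_fixture(name: str = "table3_arvicola.csv") -> Dataset:
    """Load a bundled record-level fixture as a Dataset."""
    with resources.as_file(fixture_path(name)) as p:
        ds = read_dataset(p)
    ds.provenance = f"bundled fixture {name}"
    return ds


def load_summary_fixture(name: str) -> pd.DataFrame:
    """Load a bundled species-by-tissue summary table."""
    with fixture_path(name).open(encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_bootstrap_counts_fixture() -> pd.DataFrame:
    """Published bootstrap count table (long format, lower-bound flags)."""
    with fixture_path("table4_bootstrap_counts.csv").open(encoding="utf-8") as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# Full report bundle
# ---------------------------------------------------------------------------

#: Fallback carbonate-phosphate offset (mean, sd) used when the input
#: dataset itself has no paired CO3/PO4 measurements.
FALLBACK_OFFSET = (10.9, 0.8)


def run_full_report(
    dataset: Dataset,
    out_dir: str | Path,
    *,
    seed: int = 0,
    n_replicates: int = _samplesize.DEFAULT_REPLICATES,
    n_repeats: int = _samplesize.DEFAULT_REPEATS,
    diet_model: _diet.DietModel | None = None,
) -> dict[str, Path]:
    """Run every pipeline stage on a dataset and write tidy CSV outputs.

    Stages: per-group summaries, offset estimation, water reconstruction
    against every registered calibration, diet summary, incisor-bone paired
    offsets, and the bootstrap sample-size procedure per (species, tissue)
    group.  A stage failure aborts the bundle, removes partial outputs and
    re-raises with the stage named.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = dataset.active_records()
    written: dict[str, Path] = {}
    log_lines = [f"seed={seed}", f"n_records={len(records)}",
                 f"provenance={dataset.provenance}"]

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False, lineterminator="\n")
        written[name] = path

    stage = "summaries"
    try:
        rows = []
        for variable in _NUMERIC:
            try:
                groups = _stats.summarize(records, ("species", "tissue"), variable)
            except EmptySelectionError:
                continue
            for g in groups:
                rows.append({
                    "species": g.group_key[0], "tissue": g.group_key[1],
                    "variable": variable, "n": g.n, "mean": g.mean,
                    "sd": g.sd, "min": g.min, "max": g.max,
                    "range_width": g.range_width,
                })
        _write("summaries.csv", pd.DataFrame(rows))

        stage = "offset_estimation"
        try:
            offset_est: OffsetEstimate | None = estimate_offset(records)
        except EmptySelectionError:
            offset_est = None
        if offset_est is not None:
            offset_mean, offset_sd = offset_est.mean_offset, offset_est.sd_offset
            log_lines.append(
                f"offset: estimated from {offset_est.n_pairs} pairs, "
                f"mean={round_half_away(offset_mean)} sd={offset_sd}"
            )
            _write("offsets.csv", pd.DataFrame(
                [{"specimen_id": s, "tissue": t, "offset": o}
                 for (s, t, o) in offset_est.per_pair]
            ))
        else:
            offset_mean, offset_sd = FALLBACK_OFFSET
            log_lines.append(
                "offset: no paired CO3/PO4 data in input; using fallback "
                f"{FALLBACK_OFFSET}"
            )

        stage = "water_reconstruction"
        import warnings as _warnings
        recon_rows = []
        for eq in _calibration.registry():
            for tissues, label in ((("incisor", "M1", "M2", "M3"), "tooth"),
                                   (("bone",), "bone")):
                try:
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore")
                        recon = _calibration.reconstruct_water(
                            records, eq, offset_mean, offset_sd, tissues)
                except EmptySelectionError:
                    continue
                if recon.n_converted_from_co3:
                    log_lines.append(
                        f"calibration {eq.name}/{label}: {recon.notes[0]}")
                recon_rows.append({
                    "equation": eq.name, "tissue_class": label,
                    "d18O_lw": recon.d18O_lw, "sd": recon.sd,
                    "n": recon.n_records,
                    "n_converted_from_co3": recon.n_converted_from_co3,
                    "tissue_warning": recon.tissue_warning,
                    "extrapolation": recon.extrapolation,
                })
        _write("calibration.csv", pd.DataFrame(recon_rows))

        stage = "diet"
        diet_rows = []
        for row in _diet.diet_summary(records, diet_model or _diet.DEFAULT_MODEL):
            diet_rows.append({
                "species": row.species, "n": row.n,
                "diet_mean": row.diet_mean, "diet_sd": row.diet_sd,
                "diet_min": row.diet_min, "diet_max": row.diet_max,
                "c4_fraction": row.c4_fraction_of_mean, "flag": row.flagged,
            })
        _write("diet.csv", pd.DataFrame(diet_rows))

        stage = "paired_offsets"
        try:
            paired = _stats.paired_tissue_offsets(records, "incisor", "bone")
            _write("paired_offsets.csv", pd.DataFrame(
                [{"specimen_id": s, "tissue_a": a, "tissue_b": b, "offset": o}
                 for (s, a, b, o) in paired.pairs]
            ))
            log_lines.append(
                f"incisor-bone: {paired.n_positive}/{len(paired.pairs)} "
                "specimens with higher incisor values"
            )
        except EmptySelectionError:
            log_lines.append("incisor-bone: no complete pairs")

        stage = "bootstrap"
        boot_rows, minn_rows = [], []
        for variable in ("d18O_co3",):
            groups = _stats.summarize(records, ("species", "tissue"), variable)
            for g in groups:
                if g.n < 3 or g.sd is None or g.sd == 0:
                    continue
                values = [
                    r.value(variable) for r in records
                    if (r.species, r.tissue) == g.group_key
                    and r.value(variable) is not None
                ]
                res = _samplesize.bootstrap_min_sample_size(
                    values, n_replicates=n_replicates, n_repeats=n_repeats,
                    seed=seed, group_key=(*g.group_key, variable),
                )
                for n_sub, count in sorted(res.counts.items()):
                    boot_rows.append({
                        "species": g.group_key[0], "tissue": g.group_key[1],
                        "variable": variable, "n_sub": n_sub, "count": count,
                    })
                minn_rows.append({
                    "species": g.group_key[0], "tissue": g.group_key[1],
                    "variable": variable,
                    "min_n_95": res.min_n_for_95,
                    "min_n_99": res.min_n_for_99,
                })
        _write("bootstrap.csv", pd.DataFrame(boot_rows))
        _write("minimum_n.csv", pd.DataFrame(minn_rows))

        stage = "run_log"
        log_path = out_dir / "run_log.txt"
        log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        written["run_log.txt"] = log_path
    except RodisoError as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise RodisoError(f"report stage {stage!r} failed: {exc}") from exc
    return written
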