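"""Empirical minimum-sample-size estimation by repeated subsampling.

For a group of n measured values, and for every subsample size ``n_sub``
from 2 to n-1, draw ``n_replicates`` random subsamples (without replacement
within a subsample), count how many subsample means fall within +/- one
full-sample SD of the full-sample mean, and average that count over
``n_repeats`` independent evaluations.  The smallest ``n_sub`` whose
averaged count reaches 95% (or 99%) of the replicates is the minimum
adequate sample size for that group.

Notes on conventions (all configurable):

* subsamples are drawn *without* replacement within a subsample — a
  "subsample" is a set of distinct specimens; a with-replacement bootstrap
  mode exists behind ``with_replacement=True`` for sensitivity analysis;
* repeated identical subsamples across replicates are allowed (independent
  draws);
* the +/- 1 SD window uses the n-1 sample SD and is boundary-inclusive,
  which makes the zero-variance case well defined (every count equals
  ``n_replicates``, flagged degenerate);
* one master seed spawns an independent substream per (n_sub, repeat), so
  results are reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import sample_sd
from .errors import InsufficientDataError

DEFAULT_REPLICATES = 1000
DEFAULT_REPEATS = 100


@dataclass(frozen=True)
class BootstrapResult:
    """Averaged within-1-sigma counts for every subsample size of one group."""

    group_key: tuple
    n_full: int
    full_mean: float
    full_sd: float
    counts: Mapping[int, float]       # n_sub -> average count over repeats
    n_replicates: int
    n_repeats: int
    degenerate: bool = False

    def min_n(self, confidence: float) -> int | None:
        """Smallest n_sub whose averaged count reaches confidence * replicates."""
        threshold = confidence * self.n_replicates
        for n_sub in sorted(self.counts):
            if self.counts[n_sub] >= threshold:
                return n_sub
        return None

    @property
    def min_n_for_95(self) -> int | None:
        return self.min_n(0.95)

    @property
    def min_n_for_99(self) -> int | None:
        return self.min_n(0.99)


def _counts_one_repeat(
    values: np.ndarray,
    n_sub: int,
    n_replicates: int,
    lo: float,
    hi: float,
    rng: np.random.Generator,
    with_replacement: bool,
) -> int:
    n = values.size
    if with_replacement:
        idx = rng.integers(0, n, size=(n_replicates, n_sub))
    else:
        # vectorised draw-without-replacement: rank random keys per row
        keys = rng.random((n_replicates, n))
        idx = np.argpartition(keys, n_sub - 1, axis=1)[:, :n_sub]
    means = values[idx].mean(axis=1)
    return int(np.count_nonzero((means >= lo) & (means <= hi)))


def bootstrap_min_sample_size(
    values: Sequence[float],
    n_replicates: int = DEFAULT_REPLICATES,
    n_repeats: int = DEFAULT_REPEATS,
    sigma_multiplier: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
    group_key: tuple = (),
    with_replacement: bool = False,
) -> BootstrapResult:
    """Run the subsampling procedure for one group of values.

    Raises :class:`InsufficientDataError` for fewer than 3 values.  A
    zero-variance group short-circuits: every count is ``n_replicates``
    (inclusive window boundary) and the result is flagged degenerate.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 values, got {n}"
        )
    full_mean = float(arr.mean())
    full_sd = sample_sd([float(v) for v in arr])
    assert full_sd is not None

    sub_sizes = range(2, n)
    if full_sd == 0.0:
        return BootstrapResult(
            group_key=group_key,
            n_full=n,
            full_mean=full_mean,
            full_sd=0.0,
            counts={k: float(n_replicates) for k in sub_sizes},
            n_replicates=n_replicates,
            n_repeats=n_repeats,
            degenerate=True,
        )

    lo = full_mean - sigma_multiplier * full_sd
    hi = full_mean + sigma_multiplier * full_sd

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    counts: dict[int, float] = {}
    for n_sub in sub_sizes:
        # one independent substream per (n_sub, repeat)
        per_repeat = []
        repeat_seeds = np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=ss.spawn_key + (n_sub,)
        ).spawn(n_repeats)
        for rep_seed in repeat_seeds:
            rng = np.random.default_rng(rep_seed)
            per_repeat.append(
                _counts_one_repeat(arr, n_sub, n_replicates, lo, hi, rng,
                                   with_replacement)
            )
        counts[n_sub] = float(np.mean(per_repeat))

    return BootstrapResult(
        group_key=group_key,
        n_full=n,
        full_mean=full_mean,
        full_sd=full_sd,
        counts=counts,
        n_replicates=n_replicates,
        n_repeats=n_repeats,
    )


@dataclass(frozen=True)
class MinimumNRow:
    group_key: tuple
    confidence: float
    min_n: int | None


def minimum_n_report(
    results: Sequence[BootstrapResult], confidence: float
) -> list[MinimumNRow]:
    """Minimum adequate n per group at the given confidence level.

    ``min_n`` is None when no subsample size reaches the threshold.
    """
    if not (0.0 < confidence <= 1.0):
        raise ValueError("confidence must lie in (0, 1]")
    return [
        MinimumNRow(
            group_key=res.group_key,
            confidence=confidence,
            min_n=res.min_n(confidence),
        )
        for res in results
    ]


def minimum_n_from_counts(
    counts: Mapping[int, float],
    confidence: float,
    n_replicates: int = DEFAULT_REPLICATES,
    lower_bounds: Mapping[int, bool] | None = None,
) -> int | None:
    """Minimum adequate n_sub from an externally tabulated count table.

    ``lower_bounds`` marks counts published as ">x" cells: the true integer
    count is at least x + 1, and the comparison uses that bound.
    """
    threshold = confidence * n_replicates
    for n_sub in sorted(counts):
        value = counts[n_sub]
        if lower_bounds and lower_bounds.get(n_sub):
            value += 1
        if value >= threshold:
            return n_sub
    return None
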