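"""Percentile-rank normalization of raw completion times.

Raw completion times are positively skewed, so they are first converted
to performance percentiles (midpoint rank: slower observations count
against you, ties share credit) and then mapped onto the familiar
scaled-score metric (mean 10, SD 3, range 1-19) through the standard
normal quantile.  Faster completion earns a higher scaled score, so the
percentile direction is reversed relative to the raw times.

A :class:`ConversionTable` freezes that mapping as contiguous raw-time
bins so individuals can be scored later without the training sample.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort_io import Subtest

__all__ = [
    "ScaledBin",
    "ConversionTable",
    "performance_percentiles",
    "percentile_to_scaled",
    "scaled_anchor_percentile",
    "build_conversion_table",
    "raw_to_scaled",
    "round_half_away",
    "DegenerateDistributionError",
]

SCALED_MIN = 1
SCALED_MAX = 19
SCALED_MEAN = 10.0
SCALED_SD = 3.0


class DegenerateDistributionError(ValueError):
    """Raised when the raw-score distribution has no spread."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero.

    Python's built-in round() rounds halves to even, which would map a
    percentile landing exactly between two scaled scores inconsistently
    with ordinary clinical rounding.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class ScaledBin:
    """One conversion-table row: raw seconds in [low, high] -> scaled.

    ``low``/``high`` are inclusive integer bounds; ``None`` opens the bin
    to -inf / +inf at the extremes.
    """

    low: int | None
    high: int | None
    scaled: int

    def contains(self, raw: float) -> bool:
        lo = -math.inf if self.low is None else self.low
        hi = math.inf if self.high is None else self.high
        return lo <= raw <= hi


@dataclass(frozen=True)
class ConversionTable:
    """Ordered raw-time bins with scaled-score and percentile anchors.

    Bins are stored fastest first (highest scaled score first); scaled
    values strictly decrease as raw time increases.  ``anchors`` maps a
    scaled score to the percentile printed alongside it (the percentile
    of the normal round-point, 100*Phi((s-10)/3)).
    """

    subtest: Subtest
    bins: tuple[ScaledBin, ...]
    anchors: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("conversion table needs at least one bin")
        prev_high: int | None = None
        prev_scaled: int | None = None
        for i, b in enumerate(self.bins):
            if not (SCALED_MIN <= b.scaled <= SCALED_MAX):
                raise ValueError(f"scaled {b.scaled} outside [1, 19]")
            if i == 0:
                if b.low is not None:
                    raise ValueError("fastest bin must be open below")
            else:
                if b.low is None or prev_high is None or b.low != prev_high + 1:
                    raise ValueError(
                        f"bins not contiguous at scaled {b.scaled}: "
                        f"low={b.low}, previous high={prev_high}"
                    )
                assert prev_scaled is not None
                if b.scaled >= prev_scaled:
                    raise ValueError("scaled must strictly decrease with raw time")
            if b.low is not None and b.high is not None and b.low > b.high:
                raise ValueError(f"empty bin [{b.low}, {b.high}]")
            prev_high, prev_scaled = b.high, b.scaled
        if self.bins[-1].high is not None:
            raise ValueError("slowest bin must be open above")

    def lookup(self, raw: float) -> int:
        if raw <= 0:
            raise ValueError(f"raw time must be positive, got {raw}")
        for b in self.bins:
            if b.contains(raw):
                return b.scaled
        # only reachable for non-integer raw falling between integer bins;
        # assign the slower (lower-scaled) neighbour, the conservative read
        for b in self.bins:
            if b.low is not None and raw < b.low:
                continue
            return b.scaled
        return self.bins[-1].scaled

    @property
    def available_scaled(self) -> tuple[int, ...]:
        return tuple(b.scaled for b in self.bins)

    def bin_for_scaled(self, scaled: int) -> ScaledBin:
        for b in self.bins:
            if b.scaled == scaled:
                return b
        raise KeyError(f"{self.subtest}: no conversion bin for scaled score {scaled}")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "subtest": self.subtest.value,
            "bins": [{"low": b.low, "high": b.high, "scaled": b.scaled} for b in self.bins],
            "anchors": {str(k): v for k, v in self.anchors.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ConversionTable":
        return cls(
            subtest=Subtest(data["subtest"]),
            bins=tuple(
                ScaledBin(low=b["low"], high=b["high"], scaled=b["scaled"])
                for b in data["bins"]
            ),
            anchors={int(k): float(v) for k, v in data.get("anchors", {}).items()},
        )

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "ConversionTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


def performance_percentiles(raw_times: Sequence[float]) -> dict[float, float]:
    """Midpoint-rank performance percentiles of raw completion times.

    For a raw value v with f ties and c observations strictly slower,
    percentile(v) = 100 * (c + f/2) / N.  Faster times receive higher
    percentiles.  The frequency-weighted mean percentile is always 50.
    """
    times = np.asarray(list(raw_times), dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 observations")
    values, counts = np.unique(times, return_counts=True)
    if values.size < 2:
        raise DegenerateDistributionError("all raw times identical")
    n = times.size
    # values are sorted ascending (fastest first); slower-than counts come
    # from the suffix sums of the frequency vector
    slower = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0]])
    pct = 100.0 * (slower + counts / 2.0) / n
    return {float(v): float(p) for v, p in zip(values, pct)}


def percentile_to_scaled(p: float) -> int:
    """Map a performance percentile to the scaled-score metric.

    clip(round_half_away(10 + 3 * Phi^-1(p/100)), 1, 19).  The 50th
    percentile maps to 10 and the 99th to 17.
    """
    if not (0.0 < p < 100.0):
        raise ValueError(f"percentile must be in (0, 100), got {p}")
    z = stats.norm.ppf(p / 100.0)
    return int(np.clip(round_half_away(SCALED_MEAN + SCALED_SD * z), SCALED_MIN, SCALED_MAX))


def scaled_anchor_percentile(scaled: int) -> float:
    """Percentile anchor printed next to a scaled score: 100*Phi((s-10)/3).

    Rounded to one decimal in the tails (outside roughly the 2nd-98th
    percentile) and to an integer elsewhere, matching how such tables are
    conventionally printed.
    """
    p = 100.0 * stats.norm.cdf((scaled - SCALED_MEAN) / SCALED_SD)
    return round(p, 1) if (p < 2.0 or p > 98.0) else float(round(p))


def build_conversion_table(
    raw_times: Sequence[float],
    subtest: Subtest,
    *,
    min_n: int = 50,
) -> ConversionTable:
    """Build a raw->scaled conversion table from a normative sample.

    Every observed raw value gets the scaled score of its midpoint-rank
    percentile; consecutive raw values sharing a scaled score are merged
    into one bin, and the extreme bins are opened to +-inf.  Raw times
    are treated as integer seconds.
    """
    times = [int(t) for t in raw_times]
    if len(times) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(times)}")
    pct = performance_percentiles(times)
    values = sorted(pct)  # ascending raw time = descending scaled
    assignments = [(v, percentile_to_scaled(pct[v])) for v in values]
    bins: list[ScaledBin] = []
    cur_scaled = assignments[0][1]
    cur_low = assignments[0][0]
    cur_high = assignments[0][0]
    for v, s in assignments[1:]:
        if s == cur_scaled:
            cur_high = v
        else:
            bins.append(ScaledBin(int(cur_low), int(cur_high), cur_scaled))
            cur_scaled, cur_low, cur_high = s, v, v
    bins.append(ScaledBin(int(cur_low), int(cur_high), cur_scaled))
    # open the extremes and fill inter-bin gaps (unobserved raw values
    # join the slower neighbour)
    opened = []
    for i, b in enumerate(bins):
        low = None if i == 0 else bins[i - 1].high + 1  # type: ignore[operator]
        high = None if i == len(bins) - 1 else b.high
        opened.append(ScaledBin(low, high, b.scaled))
    anchors = {b.scaled: scaled_anchor_percentile(b.scaled) for b in opened}
    return ConversionTable(subtest=subtest, bins=tuple(opened), anchors=anchors)


def raw_to_scaled(table: ConversionTable, raw: float) -> int:
    """Look up the scaled score of a raw completion time."""
    return table.lookup(raw)
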