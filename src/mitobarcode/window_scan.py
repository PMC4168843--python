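"""Sliding-window K2P divergence between two aligned genomes.

Windows are defined on alignment columns: gap columns stay in the
coordinate frame but are excluded from the counts by pairwise deletion.
Full windows start at 0, step, 2*step, ...; when the full windows do not
already reach the end of the alignment a trailing partial window is
appended and flagged (mitochondrial genomes are circular, so the tail is
still informative; wrap-around windows are not modeled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .distances import (
    DEFAULT_MIN_SITES,
    SiteCounts,
    encode_sequence,
    k2p_distance,
)
from .errors import BoundsError, EmptyResultError, ParameterError
from .seqio import RegionAnnotation, SequenceRecord, write_tsv

DEFAULT_WINDOW = 500
DEFAULT_STEP = 25


@dataclass(frozen=True)
class WindowPoint:
    """One window of the divergence track."""

    start: int
    end: int
    n: int
    ts: int
    tv: int
    d: float  # K2P distance; NaN when missing; +inf when saturated
    partial: bool = False

    @property
    def missing(self) -> bool:
        return math.isnan(self.d)


@dataclass
class WindowTrack:
    window_size: int
    step: int
    min_sites: int
    points: list[WindowPoint]

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)

    def values(self) -> np.ndarray:
        return np.array([p.d for p in self.points])

    def argmax_window(self) -> WindowPoint:
        finite = [p for p in self.points if math.isfinite(p.d)]
        if not finite:
            raise EmptyResultError("no window has a finite divergence")
        return max(finite, key=lambda p: (p.d, -p.start))

    def to_tsv(self, path) -> None:
        rows = [
            (p.start, p.end, p.n, p.ts, p.tv,
             "" if p.missing else f"{p.d:.8g}",
             "partial" if p.partial else ("missing" if p.missing else "ok"))
            for p in self.points
        ]
        write_tsv(rows, path, header=("start", "end", "n", "ts", "tv", "d", "flag"))

    def to_bedgraph(self, path, chrom: str = "chrM") -> None:
        with Path(path).open("w") as fh:
            fh.write(f'track type=bedGraph name="k2p_divergence"\n')
            for p in self.points:
                if math.isfinite(p.d):
                    fh.write(f"{chrom}\t{p.start}\t{p.end}\t{p.d:.8g}\n")


@dataclass
class RegionDivergence:
    """Divergence summary for one annotated region.

    ``d_region`` is the K2P distance computed once over exactly the
    region's columns; ``mean_window_d`` averages the track windows fully
    inside the region (None when no window fits). Both are reported because
    a "mean divergence" for a region can reasonably denote either.
    """

    region: RegionAnnotation
    d_region: float
    n: int
    ts: int
    tv: int
    mean_window_d: Optional[float]


def _as_sequence(genome: Union[str, SequenceRecord]) -> str:
    return genome.sequence if isinstance(genome, SequenceRecord) else genome


def _prefix_counts(a: str, b: str):
    ca, cb = encode_sequence(a), encode_sequence(b)
    comparable = (ca >= 0) & (cb >= 0)
    diff = comparable & (ca != cb)
    ts = diff & ((ca ^ cb) == 2)
    tv = diff & ~ts
    # prefix sums with a leading 0 so counts over [s, e) are cum[e] - cum[s]
    zero = np.zeros(1, dtype=np.int64)
    return (
        np.concatenate([zero, np.cumsum(comparable)]),
        np.concatenate([zero, np.cumsum(ts)]),
        np.concatenate([zero, np.cumsum(tv)]),
    )


def _interval_counts(cums, start: int, end: int) -> SiteCounts:
    cn, cts, ctv = cums
    return SiteCounts(
        n=int(cn[end] - cn[start]),
        ts=int(cts[end] - cts[start]),
        tv=int(ctv[end] - ctv[start]),
    )


def _window_point(cums, start, end, min_sites, partial=False) -> WindowPoint:
    counts = _interval_counts(cums, start, end)
    if counts.n < max(min_sites, 1):
        d = math.nan
    else:
        d = k2p_distance(counts)
    return WindowPoint(start=start, end=end, n=counts.n, ts=counts.ts,
                       tv=counts.tv, d=d, partial=partial)


def sliding_window_divergence(
    genome_a: Union[str, SequenceRecord],
    genome_b: Union[str, SequenceRecord],
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_sites: int = DEFAULT_MIN_SITES,
) -> WindowTrack:
    """K2P divergence in sliding windows along a 2-genome alignment."""
    a, b = _as_sequence(genome_a), _as_sequence(genome_b)
    if len(a) != len(b):
        raise ParameterError("genomes must be aligned to equal length")
    length = len(a)
    if window_size > length:
        raise ParameterError(
            f"window_size {window_size} exceeds alignment length {length}"
        )
    if step < 1 or window_size < 1:
        raise ParameterError("window_size and step must be >= 1")

    cums = _prefix_counts(a, b)
    points = []
    start = 0
    while start + window_size <= length:
        points.append(_window_point(cums, start, start + window_size, min_sites))
        start += step
    if points[-1].end < length:
        # trailing partial window so the track covers the whole alignment
        points.append(_window_point(cums, start, length, min_sites, partial=True))
    return WindowTrack(window_size=window_size, step=step,
                       min_sites=min_sites, points=points)


def region_divergence(
    genome_a: Union[str, SequenceRecord],
    genome_b: Union[str, SequenceRecord],
    regions: Sequence[RegionAnnotation],
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_sites: int = DEFAULT_MIN_SITES,
    track: Optional[WindowTrack] = None,
) -> list[RegionDivergence]:
    """Per-region K2P divergence plus the mean over fully-contained windows."""
    a, b = _as_sequence(genome_a), _as_sequence(genome_b)
    if len(a) != len(b):
        raise ParameterError("genomes must be aligned to equal length")
    length = len(a)
    for r in regions:
        if r.end > length:
            raise BoundsError(
                f"region {r.name!r} [{r.start}, {r.end}) exceeds alignment length {length}"
            )
    cums = _prefix_counts(a, b)
    if track is None and window_size <= length:
        track = sliding_window_divergence(a, b, window_size, step, min_sites)

    out = []
    for r in regions:
        counts = _interval_counts(cums, r.start, r.end)
        d = math.nan if counts.n == 0 else k2p_distance(counts)
        mean_wd: Optional[float] = None
        if track is not None:
            inside = [
                p.d for p in track.points
                if not p.partial and p.start >= r.start and p.end <= r.end
                and math.isfinite(p.d)
            ]
            if inside:
                mean_wd = float(np.mean(inside))
        out.append(RegionDivergence(region=r, d_region=d, n=counts.n,
                                    ts=counts.ts, tv=counts.tv,
                                    mean_window_d=mean_wd))
    return out


def rank_regions(
    region_divergences: Iterable[RegionDivergence],
    category_filter: Optional[set[str]] = frozenset({"coding"}),
) -> list[RegionDivergence]:
    """Regions ordered by descending divergence (ties by start coordinate).

    Regions whose divergence is undefined (NaN) sort last; saturated
    regions (+inf) sort first. ``category_filter=None`` keeps everything.
    """
    pool = [
        rd for rd in region_divergences
        if category_filter is None or rd.region.category in category_filter
    ]
    if not pool:
        raise EmptyResultError("no regions remain after category filtering")

    def key(rd: RegionDivergence):
        d = rd.d_region
        return (-d if not math.isnan(d) else math.inf, rd.region.start)

    return sorted(pool, key=key)


def write_region_ranking(ranked: Sequence[RegionDivergence], path) -> None:
    rows = [
        (
            rd.region.name, rd.region.start, rd.region.end, rd.region.category,
            rd.n, rd.ts, rd.tv,
            "" if math.isnan(rd.d_region) else f"{rd.d_region:.8g}",
            "" if rd.mean_window_d is None else f"{rd.mean_window_d:.8g}",
        )
        for rd in ranked
    ]
    write_tsv(rows, path, header=(
        "region", "start", "end", "category", "n", "ts", "tv",
        "d_region", "mean_window_d",
    ))
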