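"""Sliding-window runs-of-homozygosity (ROH) detection and segment algebra.

The detector follows the classical SNP-count sliding-window scheme used for
autozygosity mapping on array-density marker grids:

1. every window of ``window_snp`` consecutive markers is scored homozygous
   when it contains at most ``window_het`` heterozygous and at most
   ``window_missing`` missing calls;
2. each marker's hit rate is the fraction of windows spanning it that are
   homozygous — near chromosome ends the denominator is the number of
   windows that actually span the marker, which is fewer than in the
   interior;
3. a marker is "in ROH state" when its hit rate reaches
   ``window_threshold``;
4. maximal runs of in-state markers become candidate segments, split
   wherever adjacent markers are more than ``gap_kb`` apart;
5. candidates are emitted if they contain at least ``min_snp`` markers,
   span at least ``min_kb``, and have at most ``density_kb`` kilobases per
   marker.

Segment bounds are the physical positions of the first and last in-state
marker (not window edges), and lengths are ``end - start`` on 1-based
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from ._util import chrom_sort_key, round_half_up
from .core import GeneInterval, Interval, MarkerGrid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH parameters (defaults are the classical array-density set).

    ``window_kb`` records the nominal physical window span; the window is
    defined by marker count, so this value is unused unless
    ``enforce_window_kb`` is set, in which case windows physically longer
    than ``window_kb`` are never scored homozygous.
    """

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 100
    min_kb: float = 1000.0
    density_kb: float = 50.0
    gap_kb: float = 1000.0
    window_kb: float = 5000.0
    enforce_window_kb: bool = False

    def __post_init__(self) -> None:
        if min(self.window_snp, self.min_snp) < 1:
            raise ValueError("window_snp and min_snp must be positive")
        if min(self.min_kb, self.density_kb, self.gap_kb, self.window_kb) <= 0:
            raise ValueError("kb parameters must be positive")
        if self.window_het < 0 or self.window_missing < 0:
            raise ValueError("window tolerances must be non-negative")
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must be in (0, 1]")


def segment_size_mb(start: int, end: int) -> float:
    """Physical segment size in Mb, rounded half-up to 2 decimals."""
    if end <= start:
        raise ValueError(f"end ({end}) must exceed start ({start})")
    return round_half_up((end - start) / 1e6, 2)


@dataclass(frozen=True)
class ROHSegment:
    """A contiguous autozygous interval in one sample (1-based, bp)."""

    chrom: str
    start: int
    end: int
    n_snp: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def size_mb(self) -> float:
        return segment_size_mb(self.start, self.end)


def detect_roh(grid: MarkerGrid, sample_id: str, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect runs of homozygosity for one sample on one chromosome grid.

    Deterministic. A grid shorter than one window yields an empty result
    with a logged warning rather than an error.
    """
    params = params or ROHParams()
    if sample_id not in grid.genotypes:
        raise KeyError(f"sample {sample_id!r} not in grid for {grid.chrom}")
    calls = grid.genotypes[sample_id]
    n = calls.size
    w = params.window_snp
    if n < w:
        log.warning(
            "grid %s has %d markers, fewer than one %d-marker window; no ROH called",
            grid.chrom, n, w,
        )
        return []

    het = (calls == 1).astype(np.int32)
    miss = (calls == -1).astype(np.int32)
    kernel = np.ones(w, dtype=np.int32)
    het_in_window = np.convolve(het, kernel, mode="valid")
    miss_in_window = np.convolve(miss, kernel, mode="valid")
    hom_window = (het_in_window <= params.window_het) & (
        miss_in_window <= params.window_missing
    )
    if params.enforce_window_kb:
        span = grid.positions[w - 1 :] - grid.positions[: n - w + 1]
        hom_window &= span <= params.window_kb * 1000

    # Marker j is spanned by windows starting in [j-w+1, j] clipped to [0, W).
    n_windows = n - w + 1
    cum = np.concatenate(([0], np.cumsum(hom_window.astype(np.int64))))
    idx = np.arange(n)
    lo = np.clip(idx - w + 1, 0, n_windows - 1)
    hi = np.minimum(idx, n_windows - 1)
    hits = cum[hi + 1] - cum[lo]
    spanning = hi - lo + 1
    in_state = hits / spanning >= params.window_threshold

    return _emit_segments(grid, sample_id, in_state, params)


def _emit_segments(
    grid: MarkerGrid, sample_id: str, in_state: np.ndarray, params: ROHParams
) -> list[ROHSegment]:
    positions = grid.positions
    segments: list[ROHSegment] = []
    runs = _runs_of_true(in_state)
    gap_bp = params.gap_kb * 1000
    for run_start, run_end in runs:  # inclusive marker indices
        # split at large inter-marker gaps
        piece_start = run_start
        for j in range(run_start, run_end):
            if positions[j + 1] - positions[j] > gap_bp:
                _maybe_emit(segments, grid, sample_id, piece_start, j, params)
                piece_start = j + 1
        _maybe_emit(segments, grid, sample_id, piece_start, run_end, params)
    return segments


def _maybe_emit(segments, grid, sample_id, i0: int, i1: int, params: ROHParams) -> None:
    n_snp = i1 - i0 + 1
    start = int(grid.positions[i0])
    end = int(grid.positions[i1])
    length = end - start
    if n_snp < params.min_snp:
        return
    if length < params.min_kb * 1000:
        return
    if length / n_snp > params.density_kb * 1000:
        return
    segments.append(
        ROHSegment(chrom=grid.chrom, start=start, end=end, n_snp=n_snp, sample_id=sample_id)
    )


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# Segment algebra
# ---------------------------------------------------------------------------


def _overlaps(a, b) -> bool:
    """At least 1 bp shared on 1-based inclusive coordinates, same chromosome."""
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def shared_segments(a: Sequence, b: Sequence) -> list[Interval]:
    """Pairwise intersections of overlapping segments from two segment lists.

    Empty intersections are dropped; results are sorted by (chrom, start).
    Inputs may be ROHSegments or bare Intervals.
    """
    out: list[Interval] = []
    for sa in a:
        for sb in b:
            if _overlaps(sa, sb):
                out.append(
                    Interval(
                        chrom=sa.chrom,
                        start=max(sa.start, sb.start),
                        end=min(sa.end, sb.end),
                    )
                )
    out.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start, s.end))
    return out


def exclude_overlapping(case_segments: Sequence, parent_segments: Sequence) -> list:
    """Drop any case segment sharing >= 1 bp with any parent segment.

    Whole-segment removal, not trimming: a case segment touched anywhere by
    a parental run of homozygosity is not case-exclusive.
    """
    return [
        seg
        for seg in case_segments
        if not any(_overlaps(seg, p) for p in parent_segments)
    ]


def annotate_genes(
    segments: Sequence, genes: Iterable[GeneInterval]
) -> dict[object, list[str]]:
    """Map each segment to the gene names it overlaps by at least 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        # store 1-based inclusive intervals as half-open [start, end+1)
        trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end + 1, gene.name)
    annotated: dict[object, list[str]] = {}
    for seg in segments:
        tree = trees.get(seg.chrom)
        hits = sorted(iv.data for iv in tree.overlap(seg.start, seg.end + 1)) if tree else []
        annotated[seg] = hits
    return annotated
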