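"""Coarse experimental occupancy tracks and their per-bp interpolation.

Nucleosome maps derived from sequencing are commonly deposited at a fixed
coarse resolution (10-bp bins for the CD4+ T-cell maps this package was
designed around).  This module parses such tracks from bedGraph or wiggle
text and upsamples them to per-base-pair occupancy by natural cubic spline
through the bin midpoints, splitting at data gaps and never extrapolating
beyond the outermost knots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .occupancy import OccupancyTrack

logger = logging.getLogger(__name__)

__all__ = ["CoarseTrack", "read_coarse_track", "spline_interpolate"]


class TrackParseError(ValueError):
    pass


@dataclass
class CoarseTrack:
    """Binned signal on one sequence: sorted, non-overlapping bins.

    starts/ends are 0-based half-open bin coordinates; values are the
    reads-derived occupancy per bin (nonnegative reals).
    """

    seq_id: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts, ends and values must have equal length")
        if len(self.starts):
            if (self.ends <= self.starts).any():
                bad = int(np.argmax(self.ends <= self.starts))
                raise ValueError(
                    f"empty or inverted bin at {self.seq_id}:"
                    f"{self.starts[bad]}-{self.ends[bad]}"
                )
            if (self.starts[1:] < self.ends[:-1]).any():
                bad = int(np.argmax(self.starts[1:] < self.ends[:-1]))
                raise ValueError(
                    f"overlapping bins at {self.seq_id}:"
                    f"{self.starts[bad]}-{self.ends[bad]} and "
                    f"{self.starts[bad + 1]}-{self.ends[bad + 1]}"
                )

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def bin_size(self) -> int | None:
        """Common bin width, or None when widths differ."""
        if not len(self.starts):
            return None
        widths = np.unique(self.ends - self.starts)
        return int(widths[0]) if len(widths) == 1 else None

    @property
    def midpoints(self) -> np.ndarray:
        """Knot abscissae: each bin's value is anchored at its midpoint."""
        return (self.starts + self.ends) / 2.0


def read_coarse_track(path: str | Path, fmt: str | None = None) -> list[CoarseTrack]:
    """Parse a bedGraph or wiggle file into per-sequence coarse tracks.

    ``fmt`` is "bedgraph", "wiggle", or None to sniff: files whose first
    data-bearing line starts with fixedStep/variableStep/track type=wiggle
    parse as wiggle, anything else as bedGraph.  Unsorted input is sorted
    with a logged warning; overlapping bins raise.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if fmt is None:
        fmt = "bedgraph"
        for ln in lines:
            s = ln.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith(("fixedStep", "variableStep")) or (
                s.startswith("track") and "wiggle" in s
            ):
                fmt = "wiggle"
            break
    if fmt == "bedgraph":
        records = _parse_bedgraph(lines)
    elif fmt == "wiggle":
        records = _parse_wiggle(lines)
    else:
        raise ValueError(f"unknown track format: {fmt!r}")

    tracks = []
    for seq_id in sorted(records):
        starts, ends, values = (np.asarray(x) for x in zip(*records[seq_id]))
        order = np.argsort(starts, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            logger.warning("%s: bins for %s were unsorted; sorting", path.name, seq_id)
            starts, ends, values = starts[order], ends[order], values[order]
        tracks.append(CoarseTrack(seq_id, starts, ends, values))
    return tracks


def _parse_bedgraph(lines: list[str]) -> dict[str, list[tuple[int, int, float]]]:
    records: dict[str, list[tuple[int, int, float]]] = {}
    for num, ln in enumerate(lines, 1):
        s = ln.strip()
        if not s or s.startswith(("#", "track", "browser")):
            continue
        fields = s.split()
        if len(fields) < 4:
            raise TrackParseError(f"line {num}: expected 4 bedGraph columns, got {len(fields)}")
        try:
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise TrackParseError(f"line {num}: {exc}") from None
        records.setdefault(chrom, []).append((start, end, value))
    return records


def _parse_wiggle(lines: list[str]) -> dict[str, list[tuple[int, int, float]]]:
    records: dict[str, list[tuple[int, int, float]]] = {}
    mode = None  # ("fixed", chrom, next_start0, step, span) | ("variable", chrom, span)
    for num, ln in enumerate(lines, 1):
        s = ln.strip()
        if not s or s.startswith(("#", "track", "browser")):
            continue
        if s.startswith("fixedStep"):
            kv = _wig_keyvals(s, num)
            try:
                chrom = kv["chrom"]
                start0 = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv["step"])
            except KeyError as exc:
                raise TrackParseError(f"line {num}: fixedStep missing {exc}") from None
            span = int(kv.get("span", step))
            mode = ["fixed", chrom, start0, step, span]
            continue
        if s.startswith("variableStep"):
            kv = _wig_keyvals(s, num)
            if "chrom" not in kv:
                raise TrackParseError(f"line {num}: variableStep missing chrom")
            mode = ["variable", kv["chrom"], int(kv.get("span", 1))]
            continue
        if mode is None:
            raise TrackParseError(f"line {num}: data before any wiggle declaration")
        if mode[0] == "fixed":
            _, chrom, start0, step, span = mode
            try:
                value = float(s)
            except ValueError:
                raise TrackParseError(f"line {num}: expected a value, got {s!r}") from None
            records.setdefault(chrom, []).append((start0, start0 + span, value))
            mode[2] = start0 + step
        else:
            _, chrom, span = mode
            fields = s.split()
            if len(fields) != 2:
                raise TrackParseError(f"line {num}: expected 'position value', got {s!r}")
            try:
                pos0 = int(fields[0]) - 1
                value = float(fields[1])
            except ValueError as exc:
                raise TrackParseError(f"line {num}: {exc}") from None
            records.setdefault(chrom, []).append((pos0, pos0 + span, value))
    return records


def _wig_keyvals(line: str, num: int) -> dict[str, str]:
    out = {}
    for token in line.split()[1:]:
        if "=" not in token:
            raise TrackParseError(f"line {num}: malformed wiggle declaration token {token!r}")
        k, v = token.split("=", 1)
        out[k] = v
    return out


def spline_interpolate(track: CoarseTrack, min_spline_knots: int = 4) -> OccupancyTrack:
    """Upsample a coarse track to per-bp values by natural cubic spline.

    Knots sit at bin midpoints.  Bins separated by more than one bin width
    break the track into independent runs, so no curve bridges a data gap.
    Runs with fewer than ``min_spline_knots`` knots fall back to linear
    interpolation (with a logged warning).  Positions outside the outermost
    knots of each run are left undefined: no extrapolation.
    """
    if len(track) == 0:
        return OccupancyTrack(track.seq_id, 0, np.empty(0), "experimental", {"source": "spline"})
    mids = track.midpoints
    widths = track.ends - track.starts
    # a gap larger than the local bin width separates runs
    breaks = np.flatnonzero(track.starts[1:] - track.ends[:-1] > widths[:-1])
    run_bounds = np.concatenate([[0], breaks + 1, [len(track)]])

    origin = int(np.ceil(mids[0]))
    last = int(np.floor(mids[-1]))
    values = np.full(max(last - origin + 1, 0), np.nan)

    for a, b in zip(run_bounds[:-1], run_bounds[1:]):
        x, y = mids[a:b], track.values[a:b]
        lo, hi = int(np.ceil(x[0])), int(np.floor(x[-1]))
        if hi < lo:
            continue
        pos = np.arange(lo, hi + 1)
        if len(x) >= min_spline_knots:
            f = CubicSpline(x, y, bc_type="natural")
            vals = f(pos)
        elif len(x) >= 2:
            logger.warning(
                "%s: run of %d knots < %d; using linear interpolation",
                track.seq_id, len(x), min_spline_knots,
            )
            vals = np.interp(pos, x, y)
        else:
            vals = np.full(len(pos), y[0])
        values[lo - origin : hi - origin + 1] = vals
    return OccupancyTrack(
        track.seq_id,
        origin,
        values,
        "experimental",
        {"source": "spline", "boundary": "natural", "knots": "bin-midpoints"},
    )
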