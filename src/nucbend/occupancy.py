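"""Boltzmann nucleosome formation potential and per-bp occupancy.

The deformation energy ``E_j`` of the placement whose dyad is at position
``j`` becomes a formation potential ``S_j = exp(-beta * E_j)`` (``beta = 1``
by default: energies are in arbitrary units, so the inverse temperature is
absorbed).  Occupancy ``O_j`` is the mean of the formation potentials over
an ``l``-bp window centred at ``j`` (``l = 51`` by default), and normalized
occupancy is the natural-log ratio ``log(O_j / <O>)`` against a reference
mean, either supplied or computed over the defined positions at hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .elastic import BendingGeometry, EnergyModel, StepParamTable

__all__ = [
    "BoltzmannConfig",
    "OccupancyTrack",
    "formation_potential",
    "potential_profile",
    "occupancy_profile",
    "normalize_occupancy",
    "write_bedgraph",
]


@dataclass(frozen=True)
class BoltzmannConfig:
    """beta: inverse-temperature factor (unitless); smoothing_window: odd bp count."""

    beta: float = 1.0
    smoothing_window: int = 51
    #: if True, occupancy is reported only where the full smoothing window
    #: holds defined potentials; otherwise edge windows are truncated.
    require_full_window: bool = False

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be an odd positive integer")


@dataclass
class OccupancyTrack:
    """Per-base-pair signal over one sequence.

    values[k] is the signal at genomic position origin + k (0-based);
    NaN marks undefined positions.  kind is one of "potential",
    "occupancy", "normalized", "experimental".  metadata records the
    parameters that produced the track.
    """

    seq_id: str
    origin: int
    values: np.ndarray
    kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> int:
        return self.origin + len(self.values)

    def value_at(self, pos: int) -> float:
        """Signal at absolute position ``pos``; NaN outside the track."""
        k = pos - self.origin
        if 0 <= k < len(self.values):
            return float(self.values[k])
        return float("nan")

    def slice(self, start: int, end: int) -> np.ndarray:
        """Values over [start, end) in absolute coordinates; NaN-padded."""
        out = np.full(end - start, np.nan)
        lo = max(start, self.origin)
        hi = min(end, self.end)
        if lo < hi:
            out[lo - start : hi - start] = self.values[lo - self.origin : hi - self.origin]
        return out


def formation_potential(E, cfg: BoltzmannConfig | None = None):
    """Boltzmann weight ``S = exp(-beta * E)``; NaN energies stay NaN.

    Accepts scalars or arrays. S lies in (0, 1] for nonnegative energies
    and decreases monotonically in E.
    """
    beta = (cfg or BoltzmannConfig()).beta
    return np.exp(-beta * np.asarray(E, dtype=float)) if np.ndim(E) else float(np.exp(-beta * E))


def potential_profile(
    sequence: str,
    table: StepParamTable | None = None,
    geom: BendingGeometry | None = None,
    cfg: BoltzmannConfig | None = None,
    seq_id: str = "seq",
    model: EnergyModel | None = None,
) -> OccupancyTrack:
    """Formation potential S at every scoreable dyad position of ``sequence``."""
    cfg = cfg or BoltzmannConfig()
    model = model or EnergyModel(table, geom)
    if len(sequence) < model.geom.contact_len:
        raise ValueError(
            f"sequence of {len(sequence)} bp is shorter than "
            f"contact_len={model.geom.contact_len}"
        )
    E = model.sliding_energy(sequence)
    S = np.exp(-cfg.beta * E)
    return OccupancyTrack(
        seq_id=seq_id,
        origin=0,
        values=S,
        kind="potential",
        metadata={"beta": cfg.beta, **_geom_meta(model.geom)},
    )


def occupancy_profile(
    sequence: str,
    table: StepParamTable | None = None,
    geom: BendingGeometry | None = None,
    cfg: BoltzmannConfig | None = None,
    seq_id: str = "seq",
    model: EnergyModel | None = None,
) -> OccupancyTrack:
    """Per-bp occupancy: mean formation potential over the smoothing window.

    The window is truncated near sequence ends (or near runs of ambiguous
    bases) to the defined potentials it contains; a position with no
    defined potential in its window is NaN.  With
    ``cfg.require_full_window`` set, only full windows are reported.
    """
    cfg = cfg or BoltzmannConfig()
    model = model or EnergyModel(table, geom)
    S_track = potential_profile(sequence, cfg=cfg, seq_id=seq_id, model=model)
    S = S_track.values
    l = cfg.smoothing_window
    kernel = np.ones(l)
    defined = np.isfinite(S)
    sums = np.convolve(np.where(defined, S, 0.0), kernel, mode="same")
    counts = np.convolve(defined.astype(float), kernel, mode="same")
    counts_int = np.rint(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        O = np.where(counts_int >= 1, sums / np.maximum(counts_int, 1), np.nan)
    if cfg.require_full_window:
        O = np.where(counts_int >= l, O, np.nan)
    return OccupancyTrack(
        seq_id=seq_id,
        origin=0,
        values=O,
        kind="occupancy",
        metadata={
            "beta": cfg.beta,
            "smoothing_window": l,
            "require_full_window": cfg.require_full_window,
            **_geom_meta(model.geom),
        },
    )


def normalize_occupancy(
    track: OccupancyTrack, reference_mean: float | str = "auto"
) -> OccupancyTrack:
    """Natural-log ratio of occupancy to a reference mean.

    ``reference_mean="auto"`` uses the mean of the track's defined values;
    pass a precomputed positive number to normalize against a wider set
    (e.g. the mean over all analysed sequences).  Missing stays missing.
    """
    vals = track.values
    defined = np.isfinite(vals)
    if reference_mean == "auto":
        if not defined.any():
            raise ValueError("cannot auto-normalize a track with no defined values")
        ref = float(vals[defined].mean())
    else:
        ref = float(reference_mean)
    if not (ref > 0):
        raise ValueError(f"reference mean must be positive, got {ref}")
    if (vals[defined] <= 0).any():
        raise ValueError("occupancy values must be positive to normalize")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(defined, np.log(vals / ref), np.nan)
    meta = dict(track.metadata)
    meta.update({"log_base": "e", "reference_mean": ref})
    return OccupancyTrack(track.seq_id, track.origin, out, "normalized", meta)


def write_bedgraph(
    tracks: Iterable[OccupancyTrack] | Mapping[str, OccupancyTrack] | OccupancyTrack,
    path: str | Path,
    precision: int = 6,
) -> None:
    """Write per-bp tracks as bedGraph, merging runs of equal value.

    Track metadata (beta, smoothing window, log base, geometry) is recorded
    in header comment lines.  NaN positions are omitted.
    """
    if isinstance(tracks, OccupancyTrack):
        tracks = [tracks]
    elif isinstance(tracks, Mapping):
        tracks = list(tracks.values())
    else:
        tracks = list(tracks)
    with open(path, "w") as fh:
        for tr in tracks:
            meta = " ".join(f"{k}={v}" for k, v in sorted(tr.metadata.items()))
            fh.write(f"# nucbend kind={tr.kind} seq_id={tr.seq_id} {meta}\n")
        for tr in tracks:
            vals = np.round(tr.values, precision)
            n = len(vals)
            k = 0
            while k < n:
                if not np.isfinite(vals[k]):
                    k += 1
                    continue
                j = k + 1
                while j < n and np.isfinite(vals[j]) and vals[j] == vals[k]:
                    j += 1
                fh.write(
                    f"{tr.seq_id}\t{tr.origin + k}\t{tr.origin + j}\t{vals[k]:.{precision}g}\n"
                )
                k = j


def _geom_meta(geom: BendingGeometry) -> dict:
    return {
        "alpha_total": geom.alpha_total,
        "omega": geom.omega,
        "core_len": geom.core_len,
        "contact_len": geom.contact_len,
    }
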