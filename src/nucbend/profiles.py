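"""Stranded feature intervals and anchor-aligned occupancy metaprofiles.

Features are pseudogene-like intervals carrying group labels (transcribed /
nontranscribed; processed / duplicated) and per-feature attributes (GC
content, identity to the parent gene, divergence, family).  A metaprofile
averages a per-bp signal across features as a function of the offset from
a transcription-oriented anchor: at a start anchor positive offsets point
into the feature body, at an end anchor positive offsets point away from
it, and minus-strand features contribute their signal reversed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .occupancy import OccupancyTrack

logger = logging.getLogger(__name__)

__all__ = ["Feature", "FeatureSet", "MetaProfile", "read_features", "aggregate"]

ATTRIBUTE_COLUMNS = [
    "transcription_status",
    "biotype",
    "gc_content",
    "identity",
    "divergence",
    "family_id",
]

_CORE_COLUMNS = ["seq_id", "start", "end", "feature_id", "strand"]


@dataclass(frozen=True)
class Feature:
    """One stranded interval (0-based half-open) with optional attributes."""

    seq_id: str
    start: int
    end: int
    feature_id: str
    strand: str
    transcription_status: str | None = None
    biotype: str | None = None
    gc_content: float = float("nan")
    identity: float = float("nan")
    divergence: float = float("nan")
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"feature {self.feature_id}: start must be < end "
                f"({self.start} >= {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def anchor_position(self, anchor: str) -> int:
        """Genomic coordinate of the transcription-oriented anchor base.

        The biological start of a minus-strand feature is its highest
        coordinate (end - 1); its biological end is the interval start.
        """
        if anchor not in ("start", "end"):
            raise ValueError(f"anchor must be 'start' or 'end', got {anchor!r}")
        if self.strand == "+":
            return self.start if anchor == "start" else self.end - 1
        return self.end - 1 if anchor == "start" else self.start


class FeatureSet:
    """A collection of features, backed by a DataFrame for vector work."""

    def __init__(self, features: Iterable[Feature] | pd.DataFrame):
        if isinstance(features, pd.DataFrame):
            df = features.copy()
            for col in _CORE_COLUMNS:
                if col not in df.columns:
                    raise ValueError(f"feature frame missing required column {col!r}")
            for col in ATTRIBUTE_COLUMNS:
                if col not in df.columns:
                    df[col] = np.nan
            self._features = [
                Feature(
                    seq_id=row.seq_id,
                    start=int(row.start),
                    end=int(row.end),
                    feature_id=str(row.feature_id),
                    strand=row.strand,
                    transcription_status=_none_if_na(row.transcription_status),
                    biotype=_none_if_na(row.biotype),
                    gc_content=_float_or_nan(row.gc_content),
                    identity=_float_or_nan(row.identity),
                    divergence=_float_or_nan(row.divergence),
                    family_id=_none_if_na(row.family_id),
                )
                for row in df.itertuples(index=False)
            ]
        else:
            self._features = list(features)
        ids = [f.feature_id for f in self._features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self):
        return iter(self._features)

    def __getitem__(self, i) -> Feature:
        return self._features[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seq_id": f.seq_id,
                    "start": f.start,
                    "end": f.end,
                    "feature_id": f.feature_id,
                    "strand": f.strand,
                    "transcription_status": f.transcription_status,
                    "biotype": f.biotype,
                    "gc_content": f.gc_content,
                    "identity": f.identity,
                    "divergence": f.divergence,
                    "family_id": f.family_id,
                }
                for f in self._features
            ]
        )

    def write_bed(self, bed_path: str | Path, attrs_path: str | Path | None = None) -> None:
        """Write BED6 plus an optional attribute TSV keyed by feature_id."""
        df = self.to_frame()
        bed = df[["seq_id", "start", "end", "feature_id"]].copy()
        bed["score"] = 0
        bed["strand"] = df["strand"]
        bed.to_csv(bed_path, sep="\t", header=False, index=False)
        if attrs_path is not None:
            df[["feature_id", *ATTRIBUTE_COLUMNS]].to_csv(attrs_path, sep="\t", index=False)


def _none_if_na(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v) else str(v)


def _float_or_nan(v) -> float:
    try:
        return float(v)
    except (TypeError, ValueError):
        return float("nan")


def read_features(bed_path: str | Path, attributes_tsv_path: str | Path | None = None) -> FeatureSet:
    """Load stranded intervals from BED6 and join per-feature attributes.

    The BED must have at least 6 columns (strand is required).  The TSV is
    keyed by feature_id; BED features absent from it carry missing
    attributes (with a logged warning); duplicate ids are an error.
    """
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str, 3: str},
    )
    if bed.shape[1] < 6:
        raise ValueError(
            f"{bed_path}: BED must have >= 6 columns (strand required), got {bed.shape[1]}"
        )
    df = bed.iloc[:, [0, 1, 2, 3, 5]].copy()
    df.columns = _CORE_COLUMNS
    if attributes_tsv_path is not None:
        attrs = pd.read_csv(attributes_tsv_path, sep="\t", dtype={"feature_id": str})
        if "feature_id" not in attrs.columns:
            raise ValueError(f"{attributes_tsv_path}: attribute TSV must have a feature_id column")
        if attrs["feature_id"].duplicated().any():
            dupes = attrs.loc[attrs["feature_id"].duplicated(), "feature_id"].tolist()
            raise ValueError(f"duplicate feature_id(s) in attribute TSV: {dupes}")
        unmatched = set(df["feature_id"]) - set(attrs["feature_id"])
        if unmatched:
            logger.warning(
                "%d feature(s) lack attribute rows: %s",
                len(unmatched),
                ", ".join(sorted(unmatched)[:5]),
            )
        keep = ["feature_id"] + [c for c in ATTRIBUTE_COLUMNS if c in attrs.columns]
        df = df.merge(attrs[keep], on="feature_id", how="left")
    return FeatureSet(df)


@dataclass
class MetaProfile:
    """Mean signal per offset from an anchor, with per-offset counts.

    Offsets are transcription-oriented base pairs (negative = upstream of a
    start anchor / inside the body at an end anchor).  mean_signal is NaN
    wherever n_observations is 0.
    """

    anchor: str
    offsets: np.ndarray
    mean_signal: np.ndarray
    n_observations: np.ndarray
    group: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "group": self.group if self.group is not None else "all",
                "mean": self.mean_signal,
                "n": self.n_observations,
            }
        )

    def argmin_offset(self) -> int:
        """Offset of the minimum of the mean profile (NaN-aware)."""
        if not np.isfinite(self.mean_signal).any():
            raise ValueError("profile has no defined positions")
        return int(self.offsets[np.nanargmin(self.mean_signal)])


def aggregate(
    tracks: Mapping[str, OccupancyTrack] | OccupancyTrack,
    features: FeatureSet,
    anchor: str = "start",
    flank: int = 1000,
    group_by: str | None = None,
) -> list[MetaProfile]:
    """Average a per-bp signal across features around a stranded anchor.

    For each feature the window [anchor - flank, anchor + flank] is read in
    transcription orientation (minus-strand windows reversed), windows
    running off the track contribute NaN at the missing offsets, and the
    per-offset mean and count are taken over features with defined signal.
    With ``group_by`` set to a Feature attribute name (e.g.
    "transcription_status"), one profile per group value is returned,
    ordered by group label; otherwise a single ungrouped profile.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if isinstance(tracks, OccupancyTrack):
        tracks = {tracks.seq_id: tracks}
    offsets = np.arange(-flank, flank + 1)
    width = len(offsets)

    def new_acc():
        return (np.zeros(width), np.zeros(width, dtype=int))

    accs: dict[str | None, tuple[np.ndarray, np.ndarray]] = {}
    for feat in features:
        track = tracks.get(feat.seq_id)
        if track is None:
            continue
        a = feat.anchor_position(anchor)
        window = track.slice(a - flank, a + flank + 1)
        if feat.strand == "-":
            window = window[::-1]
        group = getattr(feat, group_by) if group_by else None
        if group_by and group is None:
            group = "unknown"
        sums, counts = accs.setdefault(group, new_acc())
        defined = np.isfinite(window)
        sums[defined] += window[defined]
        counts += defined

    out = []
    for group in sorted(accs, key=lambda g: (g is None, str(g))):
        sums, counts = accs[group]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out.append(
            MetaProfile(
                anchor=anchor,
                offsets=offsets.copy(),
                mean_signal=mean,
                n_observations=counts,
                group=group,
            )
        )
    return out


def profiles_to_frame(profiles: Iterable[MetaProfile]) -> pd.DataFrame:
    """Stack metaprofiles into one tidy frame (offset, group, mean, n)."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
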