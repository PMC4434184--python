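"""Per-feature mean occupancy and family-level correlation statistics.

Pseudogene families (many degenerate copies of one parent gene) allow the
chromatin response to sequence decay to be read out as within-family rank
correlations: for each family, the Spearman correlation between the mean
nucleosome occupancy of each member and a member attribute (GC content,
identity to the parent, divergence) is computed, and the cohort is
summarized by how many families reach significance, how many of those are
positive, and the mean significant coefficient.  A one-way ANOVA on
per-feature mean occupancy between groups (e.g. transcribed vs
nontranscribed) is also provided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .occupancy import OccupancyTrack
from .profiles import Feature, FeatureSet

__all__ = [
    "CorrelationResult",
    "FamilySummary",
    "CohortSummary",
    "mean_feature_occupancy",
    "feature_occupancy_table",
    "family_correlations",
    "summarize_cohort",
    "cohort_table",
    "group_anova",
]

#: attribute columns correlated against occupancy, in reporting order
DEFAULT_CORRELATES = ("gc_content", "identity", "divergence")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_pairs: int
    tested: bool
    significant: bool

    @property
    def sign(self) -> int:
        if not self.tested or self.rho == 0:
            return 0
        return 1 if self.rho > 0 else -1


@dataclass
class FamilySummary:
    """Spearman results for one family: (correlate, kind) -> CorrelationResult."""

    family_id: str
    n_members: int
    results: dict[tuple[str, str], CorrelationResult] = field(default_factory=dict)


@dataclass
class CohortSummary:
    """Cohort-level roll-up for one correlate and one occupancy kind."""

    correlate: str
    kind: str
    n_families_tested: int
    n_significant: int
    n_significant_positive: int
    mean_significant_rho: float  # NaN when nothing is significant

    def __post_init__(self) -> None:
        if not (
            0 <= self.n_significant_positive <= self.n_significant <= self.n_families_tested
        ):
            raise ValueError("inconsistent cohort counts")


def mean_feature_occupancy(
    track: OccupancyTrack,
    feature: Feature,
    min_length: int | None = None,
) -> float:
    """Mean of the defined per-bp values within the feature interval.

    NaN when nothing is defined or when the feature is shorter than
    ``min_length``.  Sequence-based prediction needs a full contact window,
    so predicted occupancy is conventionally computed with
    ``min_length=contact_len`` (129 bp): shorter features are excluded
    rather than scored from partial windows.
    """
    if min_length is not None and feature.length < min_length:
        return float("nan")
    vals = track.slice(feature.start, feature.end)
    defined = np.isfinite(vals)
    if not defined.any():
        return float("nan")
    return float(vals[defined].mean())


def feature_occupancy_table(
    features: FeatureSet,
    tracks_by_kind: Mapping[str, Mapping[str, OccupancyTrack]],
    min_length_by_kind: Mapping[str, int | None] | None = None,
) -> pd.DataFrame:
    """Per-feature attributes plus one mean-occupancy column per kind.

    ``tracks_by_kind`` maps an occupancy kind (e.g. "predicted",
    "experimental") to per-seq_id tracks; the output frame has one
    ``occ_<kind>`` column per kind, NaN where the feature is unscoreable.
    """
    min_length_by_kind = min_length_by_kind or {}
    df = features.to_frame()
    for kind, tracks in tracks_by_kind.items():
        min_len = min_length_by_kind.get(kind)
        col = []
        for feat in features:
            track = tracks.get(feat.seq_id)
            col.append(
                mean_feature_occupancy(track, feat, min_length=min_len)
                if track is not None
                else float("nan")
            )
        df[f"occ_{kind}"] = col
    return df


def _spearman(
    x: np.ndarray, y: np.ndarray, p_method: str, rng: np.random.Generator | None
) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    p_method "t" uses the large-sample t approximation; "permutation"
    resamples pairings (exhaustively for n <= 7, otherwise 10000 draws).
    """
    if p_method == "t":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if p_method != "permutation":
        raise ValueError(f"unknown p_method {p_method!r}")
    n = len(x)
    rho_obs = float(stats.spearmanr(x, y).statistic)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if n <= 7:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        rng = rng or np.random.default_rng()
        perms = [rng.permutation(n) for _ in range(10000)]
    null = np.array([np.corrcoef(rx, ry[p])[0, 1] for p in perms])
    p = float(np.mean(np.abs(null) >= abs(rho_obs) - 1e-12))
    return rho_obs, p


def family_correlations(
    data: pd.DataFrame,
    occupancy_cols: Mapping[str, str] | None = None,
    correlates: Sequence[str] = DEFAULT_CORRELATES,
    min_family_size: int = 5,
    alpha: float = 0.05,
    p_method: str = "t",
    rng: np.random.Generator | None = None,
) -> list[FamilySummary]:
    """Within-family Spearman correlations of occupancy vs attributes.

    ``data`` has one row per feature with a ``family_id`` column, the
    correlate columns, and the occupancy columns named in
    ``occupancy_cols`` (kind -> column; default any ``occ_*`` columns).
    Rows with a missing correlate or occupancy are dropped pairwise.  A
    family/correlate/kind cell with fewer than ``min_family_size`` usable
    pairs, or a zero-variance correlate or occupancy, is reported untested.
    Significance is ``p < alpha``, two-sided, uncorrected.
    """
    if occupancy_cols is None:
        occupancy_cols = {
            c[len("occ_"):]: c for c in data.columns if c.startswith("occ_")
        }
    if not occupancy_cols:
        raise ValueError("no occupancy columns found or specified")
    if "family_id" not in data.columns:
        raise ValueError("data must have a family_id column")

    out = []
    for family_id, sub in data.groupby("family_id", sort=True, dropna=True):
        summary = FamilySummary(family_id=str(family_id), n_members=len(sub))
        for kind, occ_col in occupancy_cols.items():
            for correlate in correlates:
                x = sub[correlate].to_numpy(dtype=float)
                y = sub[occ_col].to_numpy(dtype=float)
                keep = np.isfinite(x) & np.isfinite(y)
                x, y = x[keep], y[keep]
                n = len(x)
                if n < min_family_size or len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                    res = CorrelationResult(
                        rho=float("nan"), p_value=float("nan"),
                        n_pairs=n, tested=False, significant=False,
                    )
                else:
                    rho, p = _spearman(x, y, p_method, rng)
                    res = CorrelationResult(
                        rho=rho, p_value=p, n_pairs=n,
                        tested=True, significant=bool(p < alpha),
                    )
                summary.results[(correlate, kind)] = res
        out.append(summary)
    return out


def summarize_cohort(
    summaries: Iterable[FamilySummary], correlate: str, kind: str
) -> CohortSummary:
    """Counts of tested / significant / significant-positive families and
    the mean of the significant coefficients (NaN when none)."""
    tested = sig = pos = 0
    sig_rhos = []
    for s in summaries:
        res = s.results.get((correlate, kind))
        if res is None or not res.tested:
            continue
        tested += 1
        if res.significant:
            sig += 1
            sig_rhos.append(res.rho)
            if res.sign > 0:
                pos += 1
    return CohortSummary(
        correlate=correlate,
        kind=kind,
        n_families_tested=tested,
        n_significant=sig,
        n_significant_positive=pos,
        mean_significant_rho=float(np.mean(sig_rhos)) if sig_rhos else float("nan"),
    )


def cohort_table(
    summaries: Sequence[FamilySummary],
    kinds: Sequence[str],
    correlates: Sequence[str] = DEFAULT_CORRELATES,
) -> pd.DataFrame:
    """One row per occupancy kind, one column per correlate, cells of the
    form "sig/tested (R=mean_sig_rho, n_pos+)" — the cohort report layout."""
    rows = {}
    for kind in kinds:
        row = {}
        for correlate in correlates:
            c = summarize_cohort(summaries, correlate, kind)
            mean_str = "NA" if math.isnan(c.mean_significant_rho) else f"{c.mean_significant_rho:.3f}"
            row[correlate] = (
                f"{c.n_significant}/{c.n_families_tested} "
                f"(R={mean_str}, {c.n_significant_positive}+)"
            )
        rows[kind] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(correlates)]


def group_anova(
    values: Sequence[float] | np.ndarray,
    groups: Sequence[str],
) -> tuple[float, float]:
    """One-way ANOVA of per-feature means across groups: returns (F, p).

    Rows with missing values are dropped; every remaining group must have
    >= 2 members and there must be >= 2 groups.  Identical constant groups
    return F = 0, p = 1 (no between-group variance).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 members each")
    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    if ss_between == 0:
        return 0.0, 1.0
    F, p = stats.f_oneway(*samples)
    return float(F), float(p)
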