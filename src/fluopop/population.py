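"""Subpopulation analysis of calcium-transient features.

Cells are summarized by two features — spike count per recording and
Ca2+max (maximum dF/F0) — and partitioned into four activity classes:
hyperactive, moderate, low and silent. The control condition is clustered
with k-means (k=4); the clusters are named by axis-aligned activity
boundaries; and those control-derived boundaries then classify cells from
treated conditions, so that condition contrasts are expressed as shifts in
subpopulation percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .assays import kruskal_wallis

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityClass",
    "ClassBoundaries",
    "ClusterModel",
    "SubpopulationProfile",
    "classify_cell",
    "classify_table",
    "cluster_features",
    "name_clusters",
    "derive_boundaries",
    "subsample_profiles",
    "summarize_profiles",
    "compare_conditions",
]


class ActivityClass(str, Enum):
    """The four activity classes, with their conventional plot colors."""

    HYPERACTIVE = "hyperactive"
    MODERATE = "moderate"
    LOW = "low"
    SILENT = "silent"

    @property
    def color(self) -> str:
        return _CLASS_COLORS[self]


_CLASS_COLORS = {
    ActivityClass.HYPERACTIVE: "red",
    ActivityClass.MODERATE: "green",
    ActivityClass.LOW: "black",
    ActivityClass.SILENT: "cyan",
}

#: Classes in decreasing order of activity.
CLASS_ORDER = (
    ActivityClass.HYPERACTIVE,
    ActivityClass.MODERATE,
    ActivityClass.LOW,
    ActivityClass.SILENT,
)


@dataclass(frozen=True)
class ClassBoundaries:
    """Axis-aligned thresholds separating the activity classes.

    Parameters
    ----------
    spike_thr : float
        Spike count per 600 s recording above which a cell is hyperactive
        (strictly greater than; default 6, i.e. ">6 spikes in 10 min").
    amp_thr : float
        Ca2+max (dF/F0) above which a spiking, non-hyperactive cell is
        moderately active (default 0.5).
    silent_max_spikes : float
        Largest spike count still considered silent (default 0).
    """

    spike_thr: float = 6.0
    amp_thr: float = 0.5
    silent_max_spikes: float = 0.0

    def __post_init__(self) -> None:
        if not (self.spike_thr > 0 and self.amp_thr > 0):
            raise ValueError("spike_thr and amp_thr must be positive")

    def to_dict(self) -> dict:
        return {
            "spike_thr": self.spike_thr,
            "amp_thr": self.amp_thr,
            "silent_max_spikes": self.silent_max_spikes,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassBoundaries":
        return cls(**{k: float(d[k]) for k in ("spike_thr", "amp_thr", "silent_max_spikes")})


def classify_cell(
    spike_count: float, ca_max: float, boundaries: ClassBoundaries | None = None
) -> ActivityClass:
    """Assign one activity class to a (spike count, Ca2+max) pair.

    The rule reads the boundary definitions literally: more than
    ``spike_thr`` spikes is hyperactive regardless of amplitude; otherwise
    a spiking cell with Ca2+max above ``amp_thr`` is moderate; otherwise a
    cell with at most ``silent_max_spikes`` spikes is silent, and anything
    left is low-activity. Total on finite non-negative inputs.
    """
    if boundaries is None:
        boundaries = ClassBoundaries()
    if not (np.isfinite(spike_count) and np.isfinite(ca_max)):
        raise ValueError("features must be finite")
    if spike_count < 0 or ca_max < 0:
        raise ValueError("features must be non-negative")
    if spike_count > boundaries.spike_thr:
        return ActivityClass.HYPERACTIVE
    if ca_max > boundaries.amp_thr and spike_count >= 1:
        return ActivityClass.MODERATE
    if spike_count <= boundaries.silent_max_spikes:
        return ActivityClass.SILENT
    return ActivityClass.LOW


def classify_table(
    features: pd.DataFrame, boundaries: ClassBoundaries | None = None
) -> pd.Series:
    """Classify every row of a feature table; returns a Series of ActivityClass."""
    return features.apply(
        lambda r: classify_cell(r["spike_count"], r["ca_max"], boundaries), axis=1
    )


@dataclass
class ClusterModel:
    """A fitted k-means model on min-max scaled (spike_count, ca_max).

    ``centroids`` are stored in raw feature units; ``scaling`` holds the
    per-feature (min, max) used to map features to [0, 1] before fitting.
    """

    k: int
    centroids: np.ndarray  # k x 2, raw units (spike_count, ca_max)
    scaling: tuple[tuple[float, float], tuple[float, float]]
    assignments: np.ndarray  # cell -> cluster index
    cell_ids: list
    inertia: float
    seed: int
    n_restarts: int
    naming: dict[int, ActivityClass] = field(default_factory=dict)

    def scale(self, features: np.ndarray) -> np.ndarray:
        """Map raw feature rows into the [0, 1] space the model was fit in."""
        lo = np.array([s[0] for s in self.scaling])
        span = np.array([s[1] - s[0] for s in self.scaling])
        span[span == 0] = 1.0
        return (np.asarray(features, dtype=float) - lo) / span

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment in scaled space."""
        scaled = self.scale(features)
        scaled_centroids = self.scale(self.centroids)
        d2 = ((scaled[:, None, :] - scaled_centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def cluster_features(
    features: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterModel:
    """K-means clustering of (spike_count, ca_max), min-max scaled to [0, 1].

    Uses k-means++ initialization with ``n_restarts`` restarts and keeps
    the lowest within-cluster sum of squares. If the table holds fewer
    distinct feature points than ``k``, ``k`` is reduced with a warning.
    """
    X = features[["spike_count", "ca_max"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(X) < k:
        raise ValueError(f"need at least k={k} cells, got {len(X)}")
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < k:
        logger.warning(
            "only %d distinct feature points; reducing k from %d", n_distinct, k
        )
        k = n_distinct
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    safe_span = np.where(span > 0, span, 1.0)
    Xs = (X - lo) / safe_span
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed
    ).fit(Xs)
    centroids_raw = km.cluster_centers_ * safe_span + lo
    return ClusterModel(
        k=k,
        centroids=centroids_raw,
        scaling=((float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1]))),
        assignments=km.labels_.copy(),
        cell_ids=list(features["cell_id"]),
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def name_clusters(
    model: ClusterModel, boundaries: ClassBoundaries | None = None
) -> dict[int, ActivityClass]:
    """Map each cluster index to an activity class via its centroid.

    Each centroid (in raw feature units) is classified with
    :func:`classify_cell`. Because centroids have fractional spike counts,
    the low-activity pair usually both classify as LOW; duplicates within
    the {LOW, SILENT} pair are split by centroid spike count (lower one
    becomes SILENT). Duplicates elsewhere are kept with a logged warning —
    e.g. if every centroid exceeds the spike threshold, every cluster is
    legitimately hyperactive.
    """
    if boundaries is None:
        boundaries = ClassBoundaries()
    named = {
        i: classify_cell(max(c[0], 0.0), max(c[1], 0.0), boundaries)
        for i, c in enumerate(model.centroids)
    }
    low_pair = [
        i for i, cls in named.items() if cls in (ActivityClass.LOW, ActivityClass.SILENT)
    ]
    if len(low_pair) == 2:
        lo_first = sorted(low_pair, key=lambda i: model.centroids[i][0])
        named[lo_first[0]] = ActivityClass.SILENT
        named[lo_first[1]] = ActivityClass.LOW
    elif len(low_pair) > 2:
        logger.warning(
            "%d clusters map to the low-activity pair; resolving by centroid order",
            len(low_pair),
        )
        ordered = sorted(low_pair, key=lambda i: (model.centroids[i][0], model.centroids[i][1]))
        named[ordered[0]] = ActivityClass.SILENT
        for i in ordered[1:]:
            named[i] = ActivityClass.LOW
    counts: dict[ActivityClass, int] = {}
    for cls in named.values():
        counts[cls] = counts.get(cls, 0) + 1
    for cls, n in counts.items():
        if n > 1:
            logger.warning("%d clusters named %s (ambiguous separation)", n, cls.value)
    model.naming = named
    return named


def derive_boundaries(
    model: ClusterModel, named_mapping: Mapping[int, ActivityClass] | None = None,
    features: pd.DataFrame | None = None,
) -> ClassBoundaries:
    """Data-driven boundaries between the named control clusters.

    spike_thr is the midpoint between the largest spike count seen in
    MODERATE-named clusters and the smallest in HYPERACTIVE-named clusters;
    amp_thr the midpoint between the MODERATE minimum and the LOW maximum
    Ca2+max. When a class is missing the corresponding default (6 spikes,
    0.5 dF/F0) is used with a warning. If ``features`` is omitted the
    per-cell extrema are unavailable and centroid coordinates are used.
    """
    if named_mapping is None:
        named_mapping = model.naming or name_clusters(model)
    defaults = ClassBoundaries()

    if features is not None:
        X = features[["spike_count", "ca_max"]].to_numpy(dtype=float)
        assign = model.predict(X)
    else:
        X = model.centroids
        assign = np.arange(model.k)
    by_class: dict[ActivityClass, np.ndarray] = {}
    for cls in ActivityClass:
        idx = [i for i in range(len(assign)) if named_mapping.get(assign[i]) == cls]
        by_class[cls] = X[idx] if idx else np.empty((0, 2))

    hyper, moder, low = (
        by_class[ActivityClass.HYPERACTIVE],
        by_class[ActivityClass.MODERATE],
        by_class[ActivityClass.LOW],
    )
    if len(hyper) and len(moder):
        spike_thr = float((moder[:, 0].max() + hyper[:, 0].min()) / 2)
    else:
        logger.warning("hyperactive or moderate cluster missing; spike_thr falls back to %g",
                       defaults.spike_thr)
        spike_thr = defaults.spike_thr
    if len(moder) and len(low):
        amp_thr = float((low[:, 1].max() + moder[:, 1].min()) / 2)
    else:
        logger.warning("moderate or low cluster missing; amp_thr falls back to %g",
                       defaults.amp_thr)
        amp_thr = defaults.amp_thr
    if spike_thr <= 0:
        spike_thr = defaults.spike_thr
    if amp_thr <= 0:
        amp_thr = defaults.amp_thr
    out = ClassBoundaries(spike_thr=spike_thr, amp_thr=amp_thr,
                          silent_max_spikes=defaults.silent_max_spikes)
    logger.info("derived boundaries: spike_thr=%.3f amp_thr=%.3f", spike_thr, amp_thr)
    return out


@dataclass(frozen=True)
class SubpopulationProfile:
    """Percent of cells in each activity class for one (sub)sample."""

    sample_id: str
    condition_label: str
    percent: Mapping[ActivityClass, float]

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {total}, expected 100")

    def as_row(self) -> dict:
        row = {"sample_id": self.sample_id, "condition": self.condition_label}
        row.update({f"pct_{c.value}": self.percent[c] for c in CLASS_ORDER})
        return row


def _profile_from_classes(
    classes: Sequence[ActivityClass], sample_id: str, condition: str
) -> SubpopulationProfile:
    n = len(classes)
    pct = {
        c: 100.0 * sum(1 for x in classes if x == c) / n for c in ActivityClass
    }
    # force an exact 100 sum against float round-off
    drift = 100.0 - sum(pct.values())
    if drift != 0.0:
        largest = max(pct, key=pct.get)
        pct[largest] += drift
    return SubpopulationProfile(sample_id, condition, pct)


def subsample_profiles(
    features: pd.DataFrame,
    boundaries: ClassBoundaries | None = None,
    fraction: float = 0.6,
    sample_size: int | None = 90,
    n_repeats: int = 5,
    seed: int = 0,
    condition_label: str | None = None,
) -> list[SubpopulationProfile]:
    """Repeated random subsampling into subpopulation percentage profiles.

    Draws ``n_repeats`` samples without replacement (size ``sample_size``
    if given, else ``round(fraction * n)``), classifies each draw with the
    boundaries, and returns one percentage profile per draw. An explicit
    ``sample_size`` takes precedence over ``fraction``.
    """
    n = len(features)
    size = sample_size if sample_size is not None else int(round(fraction * n))
    if size > n:
        raise ValueError(f"sample size {size} exceeds population {n}")
    if size < 1:
        raise ValueError("sample size must be >= 1")
    condition = condition_label or str(features.get("condition", pd.Series(["?"])).iloc[0])
    rng = np.random.default_rng(seed)
    classes_all = list(classify_table(features, boundaries))
    profiles = []
    for rep in range(n_repeats):
        idx = rng.choice(n, size=size, replace=False)
        drawn = [classes_all[i] for i in idx]
        profiles.append(
            _profile_from_classes(drawn, sample_id=f"{condition}_rep{rep + 1}", condition=condition)
        )
    return profiles


def summarize_profiles(profiles: Sequence[SubpopulationProfile]) -> pd.DataFrame:
    """Mean and SEM of each class percentage across a set of profiles."""
    rows = pd.DataFrame([p.as_row() for p in profiles])
    out = []
    for c in CLASS_ORDER:
        col = rows[f"pct_{c.value}"]
        sem = float(col.std(ddof=1) / np.sqrt(len(col))) if len(col) > 1 else 0.0
        out.append({"class": c.value, "mean_pct": float(col.mean()), "sem_pct": sem,
                    "n": len(col)})
    return pd.DataFrame(out)


def compare_conditions(
    profiles_by_condition: Mapping[str, Sequence[SubpopulationProfile]],
    activity_class: ActivityClass,
) -> tuple[float, float]:
    """Kruskal-Wallis test on one class percentage across conditions.

    The replication unit is the subsample profile: for each condition the
    per-repeat percentages of ``activity_class`` form one group, and the
    groups are compared with the tie-corrected rank test. Returns (H, p).
    """
    if len(profiles_by_condition) < 2:
        raise ValueError("need at least two conditions")
    groups = []
    for cond, profiles in profiles_by_condition.items():
        if len(profiles) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 profiles")
        groups.append([p.percent[activity_class] for p in profiles])
    return kruskal_wallis(groups)
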