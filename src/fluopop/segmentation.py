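"""PCA-based segmentation of cells from a time-lapse fluorescence stack.

Active cells reveal themselves through temporal variance: after centering
each pixel's time series, the leading principal components of the
(frames x pixels) matrix concentrate the coordinated fluorescence
fluctuations of cells, while background pixels carry only noise. The
root-sum-of-squares of the top-component spatial loadings gives an
"activity image" that is thresholded and split into connected components
to yield one labelled footprint per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)

__all__ = [
    "Movie",
    "LabelMask",
    "segment_movie_pca",
    "segment_movie_variance",
    "extract_traces",
    "match_rois",
]


@dataclass
class Movie:
    """A frames x height x width stack with a fixed frame interval (s)."""

    data: np.ndarray
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("movie must be 3-D (frames x height x width)")
        if self.data.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMask:
    """Integer label image (0 background, 1..n cells) with an ROI table."""

    labels: np.ndarray
    roi_table: pd.DataFrame  # label, area_px, centroid_row, centroid_col

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


def _roi_table(labels: np.ndarray) -> pd.DataFrame:
    ids = np.arange(1, labels.max() + 1)
    if ids.size == 0:
        return pd.DataFrame(columns=["label", "area_px", "centroid_row", "centroid_col"])
    areas = ndimage.sum_labels(np.ones_like(labels), labels, ids)
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=float), labels, ids)
    return pd.DataFrame(
        {
            "label": ids,
            "area_px": areas.astype(int),
            "centroid_row": [c[0] for c in centroids],
            "centroid_col": [c[1] for c in centroids],
        }
    )


def _activity_to_mask(
    activity: np.ndarray, threshold_method, min_area: int, max_area: int
) -> LabelMask:
    """Threshold an activity image and extract size-filtered components."""
    if activity.max() <= 0 or np.allclose(activity, activity.flat[0]):
        labels = np.zeros(activity.shape, dtype=np.int32)
        return LabelMask(labels, _roi_table(labels))
    if threshold_method == "otsu":
        # threshold in log space: cell activity spans an order of magnitude
        # between dim and bright cells, and Otsu on the raw image splits
        # bright cells from (dim cells + background); the log compresses
        # the cell tail so the cell/background valley dominates. Working in
        # log space also keeps the binary mask invariant to intensity
        # rescaling of the movie.
        log_act = np.log(activity + 1e-9 * activity.max())
        thr = np.exp(threshold_otsu(log_act))
    elif isinstance(threshold_method, float):
        if not 0 < threshold_method < 1:
            raise ValueError("quantile threshold must be in (0, 1)")
        thr = np.quantile(activity, threshold_method)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = activity > thr
    comps = cc_label(binary, connectivity=2)
    labels = np.zeros_like(comps, dtype=np.int32)
    next_id = 0
    for i in range(1, comps.max() + 1):
        area = int((comps == i).sum())
        if min_area <= area <= max_area:
            next_id += 1
            labels[comps == i] = next_id
    logger.info("segmentation: %d components, %d kept after size filter [%d, %d]",
                comps.max(), next_id, min_area, max_area)
    return LabelMask(labels, _roi_table(labels))


def segment_movie_pca(
    movie: Movie,
    n_components: int | None = None,
    threshold_method="otsu",
    min_area: int = 20,
    max_area: int = 2000,
) -> LabelMask:
    """Segment active cells via principal components of pixel time series.

    Each pixel's time course is centered; the SVD of the resulting
    (frames x pixels) matrix gives temporal components with spatial
    loading maps. The activity image is the pixelwise root-sum-of-squares
    of the top ``n_components`` loadings (scaled by their singular
    values), thresholded (Otsu by default, or a quantile in (0, 1)), and
    connected components (8-connectivity) within [min_area, max_area]
    pixels are relabelled 1..n.

    With ``n_components=None`` the number of components is the smaller of
    10 and the count needed to explain 90% of the temporal variance. An
    all-constant movie yields an empty mask, not an error.
    """
    n_frames, h, w = movie.shape
    if n_components is not None and not 1 <= n_components <= n_frames:
        raise ValueError(f"n_components must be in [1, {n_frames}]")
    X = movie.data.reshape(n_frames, h * w)
    Xc = X - X.mean(axis=0, keepdims=True)
    if not Xc.any():
        labels = np.zeros((h, w), dtype=np.int32)
        return LabelMask(labels, _roi_table(labels))
    # economy SVD: frames << pixels, so U is frames x frames
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if n_components is None:
        var = s**2
        cum = np.cumsum(var) / var.sum()
        n_components = min(10, int(np.searchsorted(cum, 0.90) + 1))
    loadings = s[:n_components, None] * vt[:n_components]  # k x pixels
    activity = np.sqrt((loadings**2).sum(axis=0)).reshape(h, w)
    return _activity_to_mask(activity, threshold_method, min_area, max_area)


def segment_movie_variance(
    movie: Movie,
    threshold_method="otsu",
    min_area: int = 20,
    max_area: int = 2000,
) -> LabelMask:
    """Fallback segmentation from the per-pixel temporal standard deviation.

    Same thresholding and size filtering as the PCA path; useful as a
    sanity check since it needs no component count.
    """
    activity = movie.data.std(axis=0)
    return _activity_to_mask(activity, threshold_method, min_area, max_area)


def extract_traces(movie: Movie, mask: LabelMask):
    """Mean intensity over each labelled footprint, per frame.

    Returns a :class:`~fluopop.traces.TraceSet` whose rows follow
    ascending label order; an empty mask yields an empty trace set
    (0 x n_frames).
    """
    from .traces import TraceSet  # local import to avoid a cycle

    if mask.labels.shape != movie.shape[1:]:
        raise ValueError("mask dimensions do not match movie frames")
    ids = np.arange(1, mask.labels.max() + 1)
    n_frames = movie.n_frames
    raw = np.empty((ids.size, n_frames))
    flat_labels = mask.labels.ravel()
    for t in range(n_frames):
        raw[:, t] = ndimage.mean(movie.data[t].ravel(), flat_labels, ids) if ids.size else []
    return TraceSet(
        cell_ids=[int(i) for i in ids],
        raw=raw if ids.size else np.empty((0, n_frames)),
        frame_interval=movie.frame_interval,
    )


def match_rois(
    predicted_mask: LabelMask, true_mask: LabelMask, iou_min: float = 0.5
) -> pd.DataFrame:
    """Greedy one-to-one matching of predicted to true footprints by IoU.

    All (true, predicted) pairs with positive overlap are sorted by
    descending IoU and matched greedily; pairs below ``iou_min`` stay
    unmatched. Returns a table (true_id, pred_id, iou) with pred_id = -1
    and iou = 0 for unmatched true cells.
    """
    if predicted_mask.labels.shape != true_mask.labels.shape:
        raise ValueError("masks must share dimensions")
    pred = predicted_mask.labels
    true = true_mask.labels
    n_pred, n_true = int(pred.max()), int(true.max())
    pred_areas = np.bincount(pred.ravel(), minlength=n_pred + 1)
    true_areas = np.bincount(true.ravel(), minlength=n_true + 1)
    both = (pred > 0) & (true > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        joint = pred[both].astype(np.int64) * (n_true + 1) + true[both]
        uniq, counts = np.unique(joint, return_counts=True)
        for u, c in zip(uniq, counts):
            pairs[(int(u // (n_true + 1)), int(u % (n_true + 1)))] = int(c)
    candidates = []
    for (p, t), inter in pairs.items():
        union = pred_areas[p] + true_areas[t] - inter
        candidates.append((inter / union, t, p))
    candidates.sort(reverse=True)
    matched_t: dict[int, tuple[int, float]] = {}
    used_p: set[int] = set()
    for iou, t, p in candidates:
        if iou < iou_min:
            break
        if t in matched_t or p in used_p:
            continue
        matched_t[t] = (p, iou)
        used_p.add(p)
    rows = []
    for t in range(1, n_true + 1):
        p, iou = matched_t.get(t, (-1, 0.0))
        rows.append({"true_id": t, "pred_id": p, "iou": iou})
    return pd.DataFrame(rows)
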