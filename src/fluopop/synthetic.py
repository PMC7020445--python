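"""Ground-truthed synthetic data with the population structure the
analysis assumes.

The generator emulates a mixed retinal culture imaged with a cytosolic
calcium indicator: a population of four activity classes (hyperactive,
moderate, low, silent), Poisson-timed transients with a fast rise and
exponential decay sampled every 10 s for 600 s, multiplicative
photobleaching with a smooth quadratic trend, additive Gaussian noise,
and — optionally — a movie with spatially disjoint disc footprints.
Companion generators produce qPCR Ct tables and viability plates with
known folds / percentages, so every downstream computation has an exact
oracle.

Condition presets shift the class mix the way chemically mimicked hypoxia
does: more hyperactive and moderate cells, fewer low-activity cells, and
a higher hyperactive amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .population import ActivityClass
from .segmentation import LabelMask, Movie, _roi_table
from .traces import TraceSet

__all__ = [
    "ClassParams",
    "SimulationConfig",
    "CellGroundTruth",
    "SyntheticDataset",
    "preset",
    "simulate_population",
    "simulate_movie",
    "simulate_qpcr",
    "simulate_viability",
    "ConfigError",
    "GeometryError",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GeometryError(RuntimeError):
    """Cell footprints cannot be placed in the requested geometry."""


@dataclass(frozen=True)
class ClassParams:
    """Per-class event statistics: expected events per recording and the
    normal amplitude distribution of a single transient (dF/F0 units)."""

    spike_rate: float
    amp_mean: float
    amp_sd: float
    #: optional (lo, hi) band for the event count: the Poisson draw is
    #: conditioned to lie inside it, guaranteeing the class occupies its
    #: defining spike-count range ("class-separated" fixtures)
    count_range: tuple[int, int] | None = None


#: Control-condition class parameters. Rates are events per 600 s
#: recording; amplitudes are dF/F0. Chosen so the classes straddle the
#: classification boundaries (>6 spikes hyperactive; Ca2+max 0.5).
CONTROL_CLASS_PARAMS: dict[ActivityClass, ClassParams] = {
    ActivityClass.HYPERACTIVE: ClassParams(12.0, 0.9, 0.15),
    ActivityClass.MODERATE: ClassParams(3.0, 0.8, 0.15),
    ActivityClass.LOW: ClassParams(3.0, 0.3, 0.08),
    ActivityClass.SILENT: ClassParams(0.0, 0.0, 0.0),
}

CONTROL_PROPORTIONS: dict[ActivityClass, float] = {
    ActivityClass.HYPERACTIVE: 0.10,
    ActivityClass.MODERATE: 0.30,
    ActivityClass.LOW: 0.40,
    ActivityClass.SILENT: 0.20,
}

HYPOXIA_PROPORTIONS: dict[ActivityClass, float] = {
    ActivityClass.HYPERACTIVE: 0.25,
    ActivityClass.MODERATE: 0.40,
    ActivityClass.LOW: 0.25,
    ActivityClass.SILENT: 0.10,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the population simulator.

    Defaults follow the acquisition protocol (frame every 10 s, 60 frames
    = 600 s) and the control-condition presets. ``bleach_coeffs`` are the
    (b, c) of the multiplicative trend 1 + b t + c t^2, matching the
    quadratic form the correction stage fits.
    """

    n_cells: int = 160
    frame_interval: float = 10.0
    n_frames: int = 60
    class_proportions: Mapping[ActivityClass, float] = field(
        default_factory=lambda: dict(CONTROL_PROPORTIONS)
    )
    class_params: Mapping[ActivityClass, ClassParams] = field(
        default_factory=lambda: dict(CONTROL_CLASS_PARAMS)
    )
    decay_tau: float = 15.0
    rise_frames: int = 1
    f0_baseline: float = 100.0
    bleach_coeffs: tuple[float, float] = (-4e-4, 1e-7)
    noise_sd: float = 2.0
    seed: int = 0
    condition_label: str = "control"
    #: interpret class_proportions as the exact composition of the
    #: population (largest-remainder rounding, shuffled order) rather
    #: than per-cell sampling probabilities; keeps same-config replicate
    #: populations compositionally identical
    exact_composition: bool = True

    def __post_init__(self) -> None:
        vals = [
            self.frame_interval, self.decay_tau, self.f0_baseline,
            self.noise_sd, *self.bleach_coeffs,
            *self.class_proportions.values(),
        ]
        for p in self.class_params.values():
            vals += [p.spike_rate, p.amp_mean, p.amp_sd]
        if not all(math.isfinite(v) for v in vals):
            raise ConfigError("configuration contains non-finite values")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ConfigError("class proportions must be >= 0")
        for p in self.class_params.values():
            if p.spike_rate < 0 or p.amp_sd < 0:
                raise ConfigError("rates and amplitude sds must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def preset(condition: str, n_cells: int = 160, seed: int = 0, **overrides) -> SimulationConfig:
    """Named condition presets.

    "control" uses the default class mix; "hypoxia" raises the
    hyperactive and moderate fractions (10/30 -> 25/40%), lowers the
    low-activity and silent fractions, and raises the hyperactive
    amplitude mean from 0.9 to 1.2 — the direction of the reported shift
    under a chemical hypoxia mimic.
    """
    if condition == "control":
        cfg = SimulationConfig(n_cells=n_cells, seed=seed, condition_label="control")
    elif condition == "hypoxia":
        params = dict(CONTROL_CLASS_PARAMS)
        params[ActivityClass.HYPERACTIVE] = ClassParams(12.0, 1.2, 0.15)
        cfg = SimulationConfig(
            n_cells=n_cells,
            seed=seed,
            condition_label="hypoxia",
            class_proportions=dict(HYPOXIA_PROPORTIONS),
            class_params=params,
        )
    elif condition == "active":
        # all-active mix for movie/segmentation fixtures: silent cells have
        # no temporal signature and are invisible to activity-based
        # segmentation by construction
        params = {
            ActivityClass.HYPERACTIVE: ClassParams(12.0, 0.9, 0.15, count_range=(7, 10**6)),
            ActivityClass.MODERATE: ClassParams(4.0, 0.8, 0.15, count_range=(2, 8)),
            ActivityClass.LOW: ClassParams(4.0, 0.4, 0.08, count_range=(2, 8)),
            ActivityClass.SILENT: ClassParams(0.0, 0.0, 0.0),
        }
        cfg = SimulationConfig(
            n_cells=n_cells, seed=seed, condition_label="control",
            class_proportions={
                ActivityClass.HYPERACTIVE: 0.3, ActivityClass.MODERATE: 0.4,
                ActivityClass.LOW: 0.3, ActivityClass.SILENT: 0.0,
            },
            class_params=params, noise_sd=0.0, bleach_coeffs=(0.0, 0.0),
        )
    elif condition == "detection":
        # spike-detection benchmark: every event amplitude >= 0.5 (mean 0.8,
        # sd 0.08), dF/F0 noise 0.05 (noise_sd 5 on a baseline of 100),
        # no bleaching so the detector is measured in isolation
        params = {
            ActivityClass.HYPERACTIVE: ClassParams(12.0, 0.8, 0.08),
            ActivityClass.MODERATE: ClassParams(3.0, 0.8, 0.08),
            ActivityClass.LOW: ClassParams(3.0, 0.8, 0.08),
            ActivityClass.SILENT: ClassParams(0.0, 0.0, 0.0),
        }
        cfg = SimulationConfig(
            n_cells=n_cells, seed=seed, condition_label="control",
            class_params=params, noise_sd=5.0, bleach_coeffs=(0.0, 0.0),
        )
    elif condition == "separated":
        # classes conditioned to their defining spike-count bands, so the
        # generating class is recoverable from the features by construction
        params = {
            ActivityClass.HYPERACTIVE: ClassParams(12.0, 0.9, 0.15, count_range=(7, 10**6)),
            ActivityClass.MODERATE: ClassParams(3.0, 0.9, 0.12, count_range=(1, 6)),
            ActivityClass.LOW: ClassParams(3.0, 0.25, 0.05, count_range=(1, 6)),
            ActivityClass.SILENT: ClassParams(0.0, 0.0, 0.0),
        }
        cfg = SimulationConfig(
            n_cells=n_cells, seed=seed, condition_label="control",
            class_params=params,
        )
    else:
        raise ConfigError(f"unknown preset {condition!r}")
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class CellGroundTruth:
    """Per-cell truth the recovery tests score against."""

    cell_id: int
    true_class: ActivityClass
    true_spike_times: np.ndarray  # frame indices, strictly increasing
    true_amplitudes: np.ndarray  # dF/F0 units
    footprint: np.ndarray | None = None  # (n_px, 2) pixel coords, movies only


@dataclass
class SyntheticDataset:
    """A simulated recording: config, per-cell truth, traces, optional movie."""

    config: SimulationConfig
    ground_truth: list[CellGroundTruth]
    traces: TraceSet
    dff_true: np.ndarray  # noiseless, bleach-free dF/F0 (cells x frames)
    movie: Movie | None = None
    true_mask: LabelMask | None = None

    @property
    def condition_label(self) -> str:
        return self.config.condition_label

    def true_features(self) -> pd.DataFrame:
        """Ground-truth (spike count, Ca2+max) per cell."""
        rows = []
        for gt, dff in zip(self.ground_truth, self.dff_true):
            rows.append(
                {
                    "cell_id": gt.cell_id,
                    "true_class": gt.true_class.value,
                    "true_spike_count": int(gt.true_spike_times.size),
                    "true_ca_max": float(max(dff.max(), 0.0)),
                }
            )
        return pd.DataFrame(rows)


def _draw_spike_frames(rng: np.random.Generator, k: int, n_frames: int) -> np.ndarray:
    """k spike frames uniform without replacement in [2, n_frames - 2],
    with a minimum separation of 2 frames (gap >= 2)."""
    lo, hi = 2, n_frames - 2
    if k == 0:
        return np.empty(0, dtype=int)
    # map distinct sorted draws y_1 < ... < y_k to x_i = y_i + (i - 1),
    # turning gaps >= 1 into gaps >= 2
    upper = hi - (k - 1)
    y = np.sort(rng.choice(np.arange(lo, upper + 1), size=k, replace=False))
    return y + np.arange(k)


def _composition(classes: list, probs: np.ndarray, n: int) -> list:
    """Largest-remainder apportionment of n cells to the class fractions."""
    exact = probs * n
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    for idx in np.argsort(-(exact - counts))[:short]:
        counts[idx] += 1
    out = []
    for cls, c in zip(classes, counts):
        out.extend([cls] * int(c))
    return out


def _max_events(n_frames: int) -> int:
    lo, hi = 2, n_frames - 2
    return max(0, (hi - lo) // 2 + 1)


def _event_kernel(dff: np.ndarray, frame: int, amp: float, cfg: SimulationConfig) -> None:
    """Add one transient in place: linear rise over rise_frames ending at
    the spike frame, then exponential decay with time constant decay_tau."""
    n = dff.size
    t_idx = np.arange(frame, n)
    dff[frame:] += amp * np.exp(-(t_idx - frame) * cfg.frame_interval / cfg.decay_tau)
    for j in range(1, cfg.rise_frames):
        f = frame - j
        if f >= 0:
            dff[f] += amp * (cfg.rise_frames - j) / cfg.rise_frames


def simulate_population(
    config: SimulationConfig | None = None, seed: int | None = None
) -> SyntheticDataset:
    """Simulate a mixed population of cells as traces plus ground truth.

    Each cell draws an activity class from the configured proportions and
    a spike count from Poisson(class rate) (0 for amplitude-free
    classes); spike frames are uniform with a 2-frame minimum separation
    and amplitudes are normal per class (floored at a small positive
    value). The raw trace is
    ``f0 * (1 + dF/F0) * (1 + b t + c t^2) + N(0, noise_sd)``,
    so bleaching is exactly the quadratic form the correction stage fits.
    Fully reproducible given (config, seed); ``seed`` overrides
    ``config.seed`` when given.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    classes = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in classes], dtype=float)
    t = np.arange(cfg.n_frames) * cfg.frame_interval
    bleach = 1.0 + cfg.bleach_coeffs[0] * t + cfg.bleach_coeffs[1] * t**2
    max_k = _max_events(cfg.n_frames)

    if cfg.exact_composition:
        cell_classes = _composition(classes, probs, cfg.n_cells)
        rng.shuffle(cell_classes)
    else:
        cell_classes = [classes[rng.choice(len(classes), p=probs)]
                        for _ in range(cfg.n_cells)]

    ground_truth: list[CellGroundTruth] = []
    dff_true = np.zeros((cfg.n_cells, cfg.n_frames))
    raw = np.empty((cfg.n_cells, cfg.n_frames))
    for i in range(cfg.n_cells):
        cls = cell_classes[i]
        params = cfg.class_params[cls]
        k = 0
        if params.spike_rate > 0 and params.amp_mean > 0:
            k = min(int(rng.poisson(params.spike_rate)), max_k)
            if params.count_range is not None:
                lo_k, hi_k = params.count_range
                hi_k = min(hi_k, max_k)
                for _ in range(1000):
                    if lo_k <= k <= hi_k:
                        break
                    k = min(int(rng.poisson(params.spike_rate)), max_k)
                k = int(np.clip(k, lo_k, hi_k))
        frames = _draw_spike_frames(rng, k, cfg.n_frames)
        amps = np.maximum(rng.normal(params.amp_mean, params.amp_sd, size=k), 0.01)
        for f, a in zip(frames, amps):
            _event_kernel(dff_true[i], int(f), float(a), cfg)
        clean = cfg.f0_baseline * (1.0 + dff_true[i]) * bleach
        noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_frames) if cfg.noise_sd > 0 else 0.0
        raw[i] = np.maximum(clean + noise, 0.0)
        ground_truth.append(
            CellGroundTruth(
                cell_id=i + 1,
                true_class=cls,
                true_spike_times=frames,
                true_amplitudes=amps,
            )
        )
    traces = TraceSet(
        cell_ids=[g.cell_id for g in ground_truth],
        raw=raw,
        frame_interval=cfg.frame_interval,
        condition_label=cfg.condition_label,
    )
    return SyntheticDataset(
        config=cfg, ground_truth=ground_truth, traces=traces, dff_true=dff_true
    )


def simulate_movie(
    dataset: SyntheticDataset,
    height: int = 256,
    width: int = 256,
    cell_radius: int = 5,
    noise_sd: float = 0.0,
    background_level: float = 10.0,
    margin: float = 3.0,
    seed: int = 0,
    max_tries: int = 20_000,
) -> tuple[Movie, LabelMask]:
    """Render a dataset as a movie of disc-shaped, non-overlapping cells.

    Footprint centers are drawn uniformly, rejecting any center within
    ``2 * cell_radius + margin`` of an existing one; every pixel of a
    footprint carries its cell's trace value plus independent Gaussian
    pixel noise, and background pixels carry ``background_level`` plus
    noise. Returns the movie and the ground-truth label mask (label i for
    cell i in dataset order); the dataset's ground truth gains the placed
    footprints.
    """
    n_cells = dataset.traces.n_cells
    rng = np.random.default_rng(seed)
    r = cell_radius
    if n_cells > 0 and (height < 2 * r + 2 or width < 2 * r + 2):
        raise GeometryError("image too small for the requested cell radius")
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise GeometryError(
                f"could not place {n_cells} non-overlapping cells in "
                f"{height}x{width} after {max_tries} tries"
            )
        tries += 1
        cr = int(rng.integers(r + 1, height - r - 1))
        cc = int(rng.integers(r + 1, width - r - 1))
        if all((cr - pr) ** 2 + (cc - pc) ** 2 > (2 * r + margin) ** 2 for pr, pc in centers):
            centers.append((cr, cc))

    labels = np.zeros((height, width), dtype=np.int32)
    yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
    disc = yy**2 + xx**2 <= r**2
    for i, (cr, cc) in enumerate(centers):
        patch = labels[cr - r : cr + r + 1, cc - r : cc + r + 1]
        patch[disc] = i + 1
        dataset.ground_truth[i].footprint = np.argwhere(labels == i + 1)

    n_frames = dataset.traces.n_frames
    data = np.full((n_frames, height, width), float(background_level))
    for i in range(n_cells):
        mask_i = labels == i + 1
        data[:, mask_i] = dataset.traces.raw[i][:, None]
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    data = np.maximum(data, 0.0)
    movie = Movie(data=data, frame_interval=dataset.traces.frame_interval)
    true_mask = LabelMask(labels, _roi_table(labels))
    dataset.movie = movie
    dataset.true_mask = true_mask
    return movie, true_mask


def simulate_qpcr(
    true_fold_per_gene: Mapping[str, float],
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "ACTB",
    control_condition: str = "control",
    treated_condition: str = "hypoxia",
    reference_ct: float = 17.0,
    target_base_ct: float = 26.0,
) -> pd.DataFrame:
    """Ct table with known fold changes, for the 2^-ddCt round trip.

    The reference gene has a constant Ct per condition; each target
    gene's control Ct sits at ``target_base_ct`` and the treated Ct is
    lowered by log2(true fold), both plus N(0, ct_noise_sd) per
    replicate. Returns a tidy table (gene, condition, replicate, ct).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for g, f in true_fold_per_gene.items():
        if not (f > 0 and math.isfinite(f)):
            raise ValueError(f"fold for {g!r} must be positive and finite")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in (control_condition, treated_condition):
        for rep in range(1, n_replicates + 1):
            rows.append(
                {"gene": reference_gene, "condition": cond, "replicate": rep,
                 "ct": reference_ct}
            )
    for gene, fold in true_fold_per_gene.items():
        for cond in (control_condition, treated_condition):
            shift = -math.log2(fold) if cond == treated_condition else 0.0
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {"gene": gene, "condition": cond, "replicate": rep,
                     "ct": target_base_ct + shift + noise}
                )
    return pd.DataFrame(rows)


def simulate_viability(
    true_percent_per_dose: Mapping[float, float],
    blank_abs: float = 0.1,
    control_abs: float = 1.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    n_blanks: int = 3,
) -> pd.DataFrame:
    """Absorbance plate with known per-dose viability percentages.

    Treated absorbance = blank + (percent / 100) * (control - blank)
    + N(0, noise_sd). Returns a well table (well, dose_um, absorbance,
    role) with blank and control wells included.
    """
    if control_abs <= blank_abs:
        raise ValueError("control absorbance must exceed blank absorbance")
    for d, p in true_percent_per_dose.items():
        if not (0.0 <= p <= 120.0):
            raise ValueError(f"viability percent for dose {d} out of range: {p}")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for _ in range(n_blanks):
        well += 1
        rows.append({"well": f"W{well:02d}", "dose_um": 0.0,
                     "absorbance": blank_abs, "role": "blank"})
    for _ in range(n_replicates):
        well += 1
        rows.append({"well": f"W{well:02d}", "dose_um": 0.0,
                     "absorbance": control_abs, "role": "control"})
    for dose, pct in true_percent_per_dose.items():
        base = blank_abs + (pct / 100.0) * (control_abs - blank_abs)
        for _ in range(n_replicates):
            well += 1
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({"well": f"W{well:02d}", "dose_um": float(dose),
                         "absorbance": base + noise, "role": "treated"})
    return pd.DataFrame(rows)
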