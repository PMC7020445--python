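"""Statistical utilities for the companion assays and condition tests.

Covers the nonparametric machinery used throughout (tie-corrected
Kruskal-Wallis, Jarque-Bera normality, 10-90% box-plot summaries) and the
two plate/tube computations: relative gene expression by 2^-ddCt with a
housekeeping reference, and blank-subtracted Alamar-blue viability
expressed as percent of control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "kruskal_wallis",
    "jarque_bera",
    "box_summary",
    "BoxSummary",
    "FoldChangeResult",
    "fold_change_ddct",
    "viability_percent",
    "ALPHA",
]

#: Significance level used throughout.
ALPHA = 0.05


def _kw_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H for a list of 1-D arrays."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction: divide by 1 - sum(t^3 - t) / (n^3 - n)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0  # every pooled value identical
    return h / tie


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    p_method: str = "asymptotic",
    n_permutations: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Kruskal-Wallis rank test across two or more groups.

    Parameters
    ----------
    groups : sequence of samples
        At least two non-empty groups, total n >= 3.
    p_method : {"asymptotic", "permutation"}
        "asymptotic" takes p from the chi-square distribution with
        (#groups - 1) degrees of freedom; "permutation" estimates p by
        shuffling group membership ``n_permutations`` times, which is the
        better-calibrated choice at very small n.

    Returns
    -------
    (H, p). When every pooled value is identical the test is degenerate
    and (0.0, 1.0) is returned.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be non-empty")
    n = sum(a.size for a in arrs)
    if n < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(arrs)
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    h = _kw_statistic(arrs)
    df = len(arrs) - 1
    if p_method == "asymptotic":
        p = float(stats.chi2.sf(h, df))
    elif p_method == "permutation":
        # H depends on the data only through the pooled ranks, so shuffling
        # group membership is equivalent to shuffling the rank vector; the
        # tie-correction factor is permutation-invariant
        rng = np.random.default_rng(seed)
        sizes = np.array([a.size for a in arrs])
        ranks = stats.rankdata(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
        perm = rng.permuted(
            np.broadcast_to(ranks, (n_permutations, n)).copy(), axis=1
        )
        edges = np.concatenate([[0], np.cumsum(sizes)])
        term = np.zeros(n_permutations)
        for j in range(sizes.size):
            term += perm[:, edges[j] : edges[j + 1]].sum(axis=1) ** 2 / sizes[j]
        h_null = (12.0 / (n * (n + 1)) * term - 3 * (n + 1)) / tie
        p = (np.count_nonzero(h_null >= h - 1e-12) + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return float(h), float(p)


def jarque_bera(sample: Sequence[float]) -> tuple[float, float]:
    """Jarque-Bera normality test from sample skewness and kurtosis.

    JB = n/6 * (S^2 + (K - 3)^2 / 4) with S the sample skewness and K the
    (non-excess) kurtosis; p comes from chi-square with 2 df. Requires
    n >= 8; a zero-variance sample is degenerate and rejected.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError("Jarque-Bera needs n >= 8")
    if np.var(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    n = x.size
    s = stats.skew(x, bias=True)
    k = stats.kurtosis(x, fisher=False, bias=True)
    jb = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
    return float(jb), float(stats.chi2.sf(jb, 2))


@dataclass(frozen=True)
class BoxSummary:
    """Box-plot summary: median, quartiles, and 10-90% whiskers."""

    median: float
    q1: float
    q3: float
    p10: float
    p90: float
    n: int

    def __post_init__(self) -> None:
        if not (self.p10 <= self.q1 <= self.median <= self.q3 <= self.p90):
            raise ValueError("percentiles out of order")


def box_summary(sample: Sequence[float]) -> BoxSummary:
    """Order-statistic percentiles (linear interpolation convention)."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    p10, q1, med, q3, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    return BoxSummary(float(med), float(q1), float(q3), float(p10), float(p90), int(x.size))


@dataclass(frozen=True)
class FoldChangeResult:
    """Relative expression of one gene: mean 2^-ddCt fold +/- SEM."""

    gene: str
    fold: float
    sem: float
    n_replicates: int
    per_replicate_folds: tuple[float, ...] = ()


def fold_change_ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_condition: str,
    treated_condition: str,
) -> FoldChangeResult:
    """Relative quantification by the 2^-ddCt method.

    For each replicate, dCt = Ct(target) - Ct(reference); each treated
    replicate's ddCt is its dCt minus the mean control dCt, and the fold
    is 2^-ddCt. The result is the mean fold across treated replicates with
    its SEM (SEM computed on the per-replicate folds).

    ``ct_table`` needs columns gene, condition, replicate, ct.
    """
    required = {"gene", "condition", "replicate", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")

    def _dcts(condition: str) -> np.ndarray:
        sub = ct_table[ct_table["condition"] == condition]
        tgt = sub[sub["gene"] == target_gene].set_index("replicate")["ct"]
        ref = sub[sub["gene"] == reference_gene].set_index("replicate")["ct"]
        if tgt.empty or ref.empty:
            raise ValueError(
                f"{target_gene} or {reference_gene} missing in condition {condition!r}"
            )
        missing = set(tgt.index) - set(ref.index)
        if missing:
            raise ValueError(
                f"replicate(s) {sorted(missing)} of {target_gene} in {condition!r} "
                f"have no {reference_gene} pairing"
            )
        return (tgt - ref.loc[tgt.index]).to_numpy(dtype=float)

    dct_control = _dcts(control_condition)
    dct_treated = _dcts(treated_condition)
    ddct = dct_treated - dct_control.mean()
    folds = np.power(2.0, -ddct)
    sem = float(stats.sem(folds)) if folds.size > 1 else 0.0
    return FoldChangeResult(
        gene=target_gene,
        fold=float(folds.mean()),
        sem=sem,
        n_replicates=int(folds.size),
        per_replicate_folds=tuple(float(f) for f in folds),
    )


def viability_percent(plate: pd.DataFrame) -> pd.DataFrame:
    """Blank-subtracted viability as percent of control, per dose.

    percent = 100 * (A_treated - mean A_blank) / (mean A_control - mean A_blank)
    computed per treated well, then averaged within each dose with its SEM.
    ``plate`` needs columns well, dose_um, absorbance, role (blank /
    control / treated). Controls are 100% by construction.
    """
    required = {"dose_um", "absorbance", "role"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate must have columns {sorted(required)}")
    blanks = plate.loc[plate["role"] == "blank", "absorbance"]
    controls = plate.loc[plate["role"] == "control", "absorbance"]
    if blanks.empty or controls.empty:
        raise ValueError("plate needs at least one blank and one control well")
    blank = float(blanks.mean())
    control = float(controls.mean())
    if control <= blank:
        raise ValueError("control absorbance must exceed blank absorbance")
    treated = plate[plate["role"] == "treated"].copy()
    treated["percent"] = 100.0 * (treated["absorbance"] - blank) / (control - blank)
    rows = []
    for dose, grp in treated.groupby("dose_um"):
        vals = grp["percent"].to_numpy(dtype=float)
        sem = float(stats.sem(vals)) if vals.size > 1 else 0.0
        rows.append({"dose_um": float(dose), "percent": float(vals.mean()),
                     "sem": sem, "n_wells": int(vals.size)})
    return pd.DataFrame(rows).sort_values("dose_um").reset_index(drop=True)
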