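"""Luciferase-assay fold changes, ATP calibration, and growth-curve timing.

The reverse fructose-1-kinase reaction (F-1,6-BP + ADP -> F-1-P + ATP) is
read out by coupling ATP formation to luciferase luminescence.  Activity
is expressed as the fold-increase of the enzyme signal over buffer-only
controls, with first-order error propagation on the ratio of means; a
log-log linear ATP standard curve maps luminescence back to apparent ATP.
Concentration dependence across the substrate series is assessed with a
Spearman rank correlation and a seeded permutation p-value.

Growth phenotypes are summarized by the time a culture first crosses
half of its maximum OD600 (t-half) and by delays, i.e. differences of
t-half between a test strain and a reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FoldChange",
    "GrowthMetrics",
    "TrendResult",
    "fold_change",
    "AtpCalibration",
    "atp_calibration",
    "concentration_trend",
    "half_max_time",
    "growth_delay",
]


@dataclass(frozen=True)
class FoldChange:
    substrate_mM: float
    fold: float
    sd: float | None
    n_replicates: int


@dataclass(frozen=True)
class GrowthMetrics:
    max_od: float
    t_half_h: float | None   # None when the half-max crossing is unreachable
    label: str = ""


@dataclass(frozen=True)
class TrendResult:
    rho: float
    p_value: float
    monotone_increase: bool
    n_permutations: int


def fold_change(condition, control, substrate_mM: float = float("nan")) -> FoldChange:
    """Fold-increase of a condition over buffer-only controls.

    ``fold = mean(condition) / mean(control)``; the SD follows first-order
    propagation for a ratio,
    ``fold * sqrt((sd_c/mean_c)^2 + (sd_0/mean_0)^2)`` with the replicate
    SDs.  With a single replicate on either side the SD is reported as
    None rather than a fabricated zero.
    """
    cond = np.asarray(condition, dtype=float)
    ctrl = np.asarray(control, dtype=float)
    if cond.size < 1 or ctrl.size < 1:
        raise ValueError("need at least one replicate per side")
    mc, m0 = cond.mean(), ctrl.mean()
    if m0 <= 0:
        raise ValueError("control mean must be positive")
    fold = mc / m0
    if cond.size > 1 and ctrl.size > 1:
        sd_c = cond.std(ddof=1)
        sd_0 = ctrl.std(ddof=1)
        sd = fold * math.sqrt((sd_c / mc) ** 2 + (sd_0 / m0) ** 2)
    else:
        sd = None
    return FoldChange(substrate_mM=substrate_mM, fold=fold, sd=sd, n_replicates=cond.size)


def fold_change_table(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-substrate fold changes from a tidy plate table.

    Expects columns ``substrate_mM, luminescence`` plus buffer controls
    marked with ``substrate_mM`` NaN or a boolean ``is_control`` column.
    When a ``replicate_set`` column marks independent experiments, the
    reported fold is the mean of per-experiment folds and the SD is their
    spread, matching how averages over independent replicates are
    reported.
    """
    df = plate.copy()
    if "is_control" in df.columns:
        ctrl_mask = df["is_control"].astype(bool)
    else:
        ctrl_mask = df["substrate_mM"].isna()
    if not ctrl_mask.any():
        raise ValueError("no buffer-only control rows found")
    sets = df["replicate_set"] if "replicate_set" in df.columns else pd.Series(0, index=df.index)
    rows = []
    for s, grp in df[~ctrl_mask].groupby("substrate_mM", sort=True):
        per_set = []
        for rs, sub in grp.groupby(sets.loc[grp.index]):
            ctl = df[ctrl_mask & (sets == rs)]["luminescence"].to_numpy()
            if ctl.size == 0:
                ctl = df[ctrl_mask]["luminescence"].to_numpy()
            per_set.append(fold_change(sub["luminescence"].to_numpy(), ctl, s))
        folds = np.array([f.fold for f in per_set])
        if len(per_set) > 1:
            sd = float(folds.std(ddof=1))
        else:
            sd = per_set[0].sd
        rows.append(
            {
                "substrate_mM": s,
                "fold": float(folds.mean()),
                "sd": sd,
                "n_experiments": len(per_set),
                "n_replicates": int(sum(f.n_replicates for f in per_set)),
            }
        )
    return pd.DataFrame(rows)


class AtpCalibration(RegressorMixin, BaseEstimator):
    """Log-log linear ATP standard curve with an inverse map.

    Fits ``log10(signal) = intercept + slope * log10(conc)`` on the
    calibration points; :meth:`inverse` maps luminescence back to
    apparent ATP concentration (mM) and flags extrapolation outside the
    calibrated concentration range.

    Attributes
    ----------
    slope_, intercept_ : fitted log-log line.
    r2_ : coefficient of determination in log space.
    range_mM_ : (min, max) calibrated concentration range.
    """

    def __init__(self, force_slope: float | None = None):
        self.force_slope = force_slope

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        sig = np.asarray(y, dtype=float).ravel()
        if conc.size < 3:
            raise ValueError("need >= 3 calibration points")
        if np.any(conc <= 0) or np.any(sig <= 0):
            raise ValueError("concentrations and signals must be positive")
        if conc.max() / conc.min() < 10:
            raise ValueError("calibration points must span at least a decade")
        lx, ly = np.log10(conc), np.log10(sig)
        if self.force_slope is None:
            slope, intercept = np.polyfit(lx, ly, 1)
        else:
            slope = float(self.force_slope)
            intercept = float(np.mean(ly - slope * lx))
        pred = intercept + slope * lx
        ss_res = float(np.sum((ly - pred) ** 2))
        ss_tot = float(np.sum((ly - ly.mean()) ** 2))
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.range_mM_ = (float(conc.min()), float(conc.max()))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Expected luminescence at the given concentrations (mM)."""
        check_is_fitted(self, "slope_")
        conc = np.asarray(X, dtype=float).ravel()
        return 10.0 ** (self.intercept_ + self.slope_ * np.log10(conc))

    def inverse(self, signal):
        """Apparent ATP (mM) for a luminescence reading.

        Returns ``(conc_mM, extrapolated)``; ``extrapolated`` marks
        readings mapping outside the calibrated range.
        """
        check_is_fitted(self, "slope_")
        sig = np.asarray(signal, dtype=float)
        if np.any(sig <= 0):
            raise ValueError("signal must be positive")
        conc = 10.0 ** ((np.log10(sig) - self.intercept_) / self.slope_)
        lo, hi = self.range_mM_
        return conc, (conc < lo) | (conc > hi)


def atp_calibration(points) -> AtpCalibration:
    """Fit the standard curve from (conc_mM, luminescence) pairs."""
    pts = np.asarray(points, dtype=float)
    return AtpCalibration().fit(pts[:, 0], pts[:, 1])


def concentration_trend(
    folds,
    substrate=None,
    n_permutations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TrendResult:
    """Spearman trend of fold change versus substrate concentration.

    The p-value is a one-sided permutation p-value for a positive rank
    correlation (seeded, ``(r+1)/(n+1)`` estimator); ``monotone_increase``
    is the test decision at level ``alpha``.
    """
    f = np.asarray([x.fold if isinstance(x, FoldChange) else x for x in folds], dtype=float)
    if substrate is None:
        substrate = [x.substrate_mM for x in folds]
    s = np.asarray(substrate, dtype=float)
    if f.size < 4:
        raise ValueError("need >= 4 substrate levels")
    if np.allclose(f, f[0]):
        raise ValueError("constant folds: correlation undefined")
    rho = float(stats.spearmanr(s, f).statistic)
    # Permutation null, vectorized on centered ranks (Spearman = Pearson
    # on ranks, and permutation preserves the rank norms).
    rs = stats.rankdata(s) - (s.size + 1) / 2.0
    rf = stats.rankdata(f) - (f.size + 1) / 2.0
    denom = np.linalg.norm(rs) * np.linalg.norm(rf)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(rf, (n_permutations, 1)), axis=1)
    null = perms @ rs / denom
    count = int(np.sum(null >= rho - 1e-12))
    p = (count + 1) / (n_permutations + 1)
    return TrendResult(
        rho=rho,
        p_value=float(p),
        monotone_increase=bool(p <= alpha and rho > 0),
        n_permutations=n_permutations,
    )


def half_max_time(time_h, od, label: str = "", smooth: int = 3) -> GrowthMetrics:
    """Time to half-maximal OD600 of one growth curve.

    The series is median-smoothed (window ``smooth``) to resist
    single-point spikes; the maximum of the smoothed series defines the
    plateau, and t-half is the first crossing of half that maximum,
    located by linear interpolation between the flanking samples.  The
    crossing must be upward: a series that already starts at or above
    half of its maximum never grew through half-max inside the window,
    so the metric is marked unreachable (``t_half_h`` None) rather than
    fabricated.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size != y.size or t.size < 5:
        raise ValueError("need >= 5 aligned time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if np.all(y <= 0):
        raise ValueError("all-zero (or negative) OD series")
    ys = median_filter(y, size=smooth, mode="nearest")
    max_od = float(ys.max())
    target = max_od / 2.0
    if ys[0] >= target:
        # no upward crossing exists: the series never grew from below
        # half-max within the observation window
        return GrowthMetrics(max_od=max_od, t_half_h=None, label=label)
    j = int(np.argmax(ys >= target))
    # linear interpolation between the flanking samples
    t_half = t[j - 1] + (target - ys[j - 1]) / (ys[j] - ys[j - 1]) * (t[j] - t[j - 1])
    return GrowthMetrics(max_od=max_od, t_half_h=float(t_half), label=label)


def growth_delay(test: GrowthMetrics, reference: GrowthMetrics) -> float | None:
    """Delay of the test strain: t-half(test) - t-half(reference), in h.

    Negative values (test faster than reference) are preserved; if either
    t-half is unreachable the delay is None.
    """
    if test.t_half_h is None or reference.t_half_h is None:
        return None
    return test.t_half_h - reference.t_half_h
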