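"""End-to-end recovery studies on synthetic data.

Each function simulates data at stated study conditions, runs the
corresponding analysis stage, and returns the recovered quantity, so
the pipeline's headline numbers (shared Kd, ladder masses, coverage,
growth delays) can be recomputed from scratch in one call.  These are
the computations behind ``scripts/acceptance.py``.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from . import assay, binding, clustering, simulate, volumetry

__all__ = [
    "kd_recovery",
    "eq2_eq1_limit_gap",
    "afm_roundtrip_error",
    "exhaustive_partition",
    "clustering_oracle_agreement",
    "bootstrap_coverage",
    "growth_delay_recovery",
    "fold_change_recovery",
]


def kd_recovery(
    true_kd: float,
    seed: int,
    n_curves: int = 10,
    noise_sd: float = 0.02,
    dt_range=(0.5e-9, 5e-9),
) -> tuple[float, binding.GlobalBindingFit]:
    """Simulate titrations at a known Kd and refit globally.

    Default conditions: ten depleting-model curves, immobilized
    concentrations spanning 0.5-5 nM, plateau noise 2% of amplitude.
    Returns ``(recovered_kd_M, fit)``.
    """
    spec = simulate.TitrationSimSpec(
        true_kd=true_kd, n_curves=n_curves, noise_sd=noise_sd, dt_range=dt_range, seed=seed
    )
    curves, _ = simulate.gen_titration(spec)
    fit = binding.fit_global(curves)
    return fit.kd_, fit


def eq2_eq1_limit_gap(kd: float = 2.0e-9, dt_over_kd: float = 1e-4, n_points: int = 601) -> float:
    """Max relative gap between the depleting and hyperbolic models.

    Evaluated over three decades either side of Kd at ``DT = Kd * 1e-4``;
    in this limit the quadratic model must collapse onto the hyperbola.
    """
    x = np.linspace(np.log10(kd) - 3, np.log10(kd) + 3, n_points)
    y1 = binding.eq1_signal(x, kd, c=0.0, ymax=1.0)
    y2 = binding.eq2_signal(x, kd, dt=dt_over_kd * kd, c=0.0, ymax=1.0)
    return float(np.max(np.abs(y2 - y1) / np.maximum(np.abs(y1), 1e-300)))


def afm_roundtrip_error(seed: int = 0, n_peaks: int = 60) -> float:
    """Max relative mass error of the noiseless AFM chain.

    Peaks are generated at the reference-ladder masses with zero
    measurement noise; the volumetry chain (elliptic-cylinder volume,
    adjacent-DNA subtraction, specific-volume conversion) must return
    each particle's true mass to numerical precision.
    """
    spec = simulate.AfmSimSpec(seed=seed, n_peaks=n_peaks, noise_cv=0.0, dna_bound_fraction=0.5)
    peaks = simulate.gen_afm_peaks(spec)
    est = volumetry.AfmMassEstimator().fit()
    out = est.transform(peaks)
    return float(np.max(np.abs(out["mass_da"] - out["true_mass_da"]) / out["true_mass_da"]))


def exhaustive_partition(values, k: int):
    """Brute-force minimal-WCSS contiguous partition (oracle).

    Enumerates every way to place k-1 split points in the sorted values
    and returns ``(best_wcss, boundaries)``.  Exponential; for small n
    only.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    best, best_bounds = np.inf, None
    for splits in combinations(range(1, n), k - 1):
        bounds = (0,) + splits + (n,)
        wcss = 0.0
        for i, j in zip(bounds[:-1], bounds[1:]):
            seg = v[i:j]
            wcss += float(np.sum((seg - seg.mean()) ** 2))
        if wcss < best:
            best, best_bounds = wcss, bounds
    return best, best_bounds


def clustering_oracle_agreement(seed: int = 0, n_instances: int = 100) -> float:
    """Fraction of random instances where the DP matches brute force.

    Instances have n <= 15 observations and k <= 4 classes; agreement is
    equality of the minimal WCSS to within round-off.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(4, 16))
        k = int(rng.integers(1, min(4, n) + 1))
        v = rng.normal(0.0, 10.0, size=n) + rng.choice([0.0, 30.0, 60.0], size=n)
        res = clustering.cluster_1d(v, k)
        wcss_oracle, _ = exhaustive_partition(v, k)
        if np.isclose(res.wcss, wcss_oracle, rtol=1e-9, atol=1e-7):
            agree += 1
    return agree / n_instances


def bootstrap_coverage(
    seed: int = 0,
    n_reps: int = 200,
    true_kd: float = 2.0e-9,
    n_curves: int = 4,
    noise_sd: float = 0.02,
    n_boot: int = 80,
) -> float:
    """Coverage of the 95% parametric-bootstrap Kd interval.

    Repeatedly simulates titration sets at 2% noise, fits globally,
    builds the percentile interval, and reports the fraction of
    replicates whose interval contains the true Kd.
    """
    covered = 0
    for r in range(n_reps):
        spec = simulate.TitrationSimSpec(
            true_kd=true_kd, n_curves=n_curves, noise_sd=noise_sd, seed=seed * 100_003 + r
        )
        curves, _ = simulate.gen_titration(spec)
        fit = binding.fit_global(curves, n_starts=3)
        lo, hi, _ = binding.bootstrap_ci(fit, curves, n_boot=n_boot, seed=seed * 7 + r)
        if lo <= true_kd <= hi:
            covered += 1
    return covered / n_reps


def growth_delay_recovery(shifts_h=(0.5, 1.3, 1.7, 3.3, 3.4, 3.8), seed: int = 0, noise_sd: float = 0.01):
    """Recover injected half-max delays from noisy logistic pairs.

    For each shift, a reference and a lag-shifted curve are simulated at
    the 30-min sampling interval and OD noise ``noise_sd``; returns the
    array of recovered delays (h), in the order of ``shifts_h``.
    """
    out = []
    for i, d in enumerate(shifts_h):
        ref_spec = simulate.GrowthSimSpec(midpoint_h=8.0, noise_sd=noise_sd, seed=seed * 1000 + 2 * i)
        tst_spec = simulate.GrowthSimSpec(
            midpoint_h=8.0 + d, noise_sd=noise_sd, seed=seed * 1000 + 2 * i + 1
        )
        t0, od0, _ = simulate.gen_growth(ref_spec)
        t1, od1, _ = simulate.gen_growth(tst_spec)
        m0 = assay.half_max_time(t0, od0, label="ref")
        m1 = assay.half_max_time(t1, od1, label="test")
        out.append(assay.growth_delay(m1, m0))
    return np.asarray(out, dtype=float)


def fold_change_recovery(seed: int = 0, true_top_fold: float = 3.0):
    """Recover the top-substrate fold change from a simulated plate.

    The plate uses a saturating fold function reaching ``true_top_fold``
    at the highest substrate level; returns ``(recovered_fold, sd)``.
    """
    fold_fn = lambda s: 1.0 + (true_top_fold - 1.0) * s / 15.0
    spec = simulate.PlateSimSpec(seed=seed, fold_fn=fold_fn)
    plate, _ = simulate.gen_luminescence(spec)
    table = assay.fold_change_table(plate)
    top = table.loc[table["substrate_mM"].idxmax()]
    return float(top["fold"]), float(top["sd"]) if top["sd"] is not None else None
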