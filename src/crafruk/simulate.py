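"""Synthetic-data generators with known ground truth.

No raw study data are deposited for the titrations, AFM measurements, or
plate/growth assays, so every analysis stage in this package is exercised
against simulated inputs whose ground truth is known exactly:

* BLI titration plateaus follow the quadratic ligand-depletion model with
  one shared dissociation constant and per-curve baseline, amplitude, and
  effective immobilized concentration, plus additive Gaussian noise
  scaled to each curve's amplitude.
* AFM peaks are drawn from a mixture of populations at specified true
  masses; each particle's true volume is decomposed into an elliptic
  cylinder under a lognormal aspect model, adjacent-DNA volume is added
  for DNA-bound particles, and lognormal measurement noise perturbs each
  dimension.
* Growth curves are logistic with configurable midpoint and noise.
* Plate assays produce replicate luminescence per substrate level, buffer
  controls, and an ATP calibration series.

All generators derive their random stream from a single integer seed via
fixed per-generator substream offsets, so adding one generator never
reshuffles another, and a fixed seed reproduces tables byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import volumetry
from .binding import TitrationCurve, eq2_signal

__all__ = [
    "TitrationSimSpec",
    "AfmSimSpec",
    "GrowthSimSpec",
    "PlateSimSpec",
    "gen_titration",
    "gen_afm_peaks",
    "gen_growth",
    "gen_luminescence",
]

# Fixed substream offsets; one per generator.
_STREAM = {"titration": 0, "afm": 1, "growth": 2, "plate": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM[stream],)))


def _require(cond: bool, fieldname: str, msg: str):
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


def _default_titrant_grid():
    return np.logspace(-11, -6, 12)


@dataclass(frozen=True)
class TitrationSimSpec:
    """Conditions for simulated equilibrium titrations.

    Defaults reproduce the study conditions of the global-fit experiment:
    ten curves sharing a true Kd of 2.0e-9 M, per-curve immobilized
    concentrations spanning 0.5-5 nM, and plateau noise of 2% of each
    curve's amplitude.
    """

    true_kd: float = 2.0e-9
    n_curves: int = 10
    dt_range: tuple[float, float] = (0.5e-9, 5e-9)
    titrant_grid: np.ndarray = field(default_factory=_default_titrant_grid)
    c_range: tuple[float, float] = (0.0, 0.2)
    ymax_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 0.02   # fraction of each curve's Ymax
    n: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _require(self.true_kd > 0, "true_kd", "must be positive")
        _require(self.n_curves >= 1, "n_curves", "must be >= 1")
        _require(0 < self.dt_range[0] <= self.dt_range[1], "dt_range", "must be positive and ordered")
        grid = np.asarray(self.titrant_grid, dtype=float)
        _require(grid.size >= 4, "titrant_grid", "needs >= 4 concentrations")
        _require(np.all(grid > 0), "titrant_grid", "must be strictly positive")
        _require(np.all(np.diff(grid) > 0), "titrant_grid", "must be sorted increasing")
        object.__setattr__(self, "titrant_grid", grid)
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.n > 0, "n", "must be positive")


def gen_titration(spec: TitrationSimSpec):
    """Simulate titration curves under the depleting model.

    Returns ``(curves, truth)``: a list of :class:`TitrationCurve` and a
    DataFrame with each curve's true c, Ymax, DT and the shared Kd.
    """
    rng = _rng(spec.seed, "titration")
    x = np.log10(spec.titrant_grid)
    # Deterministic log-spaced DT grid guarantees the requested span.
    if spec.n_curves == 1:
        dts = np.array([spec.dt_range[0]])
    else:
        dts = np.logspace(
            np.log10(spec.dt_range[0]), np.log10(spec.dt_range[1]), spec.n_curves
        )
    curves, rows = [], []
    for i in range(spec.n_curves):
        c = rng.uniform(*spec.c_range)
        ymax = rng.uniform(*spec.ymax_range)
        clean = eq2_signal(x, spec.true_kd, dts[i], c, ymax, spec.n)
        y = clean + rng.normal(0.0, spec.noise_sd * ymax, size=x.size)
        cid = f"curve_{i:02d}"
        curves.append(TitrationCurve(curve_id=cid, x=x, y=y, dt_hint=float(dts[i])))
        rows.append({"curve_id": cid, "true_kd_M": spec.true_kd, "c": c, "ymax": ymax, "dt_M": float(dts[i])})
    return curves, pd.DataFrame(rows)


def titration_frame(curves) -> pd.DataFrame:
    """Tidy CSV-ready table (curve_id, conc_M, signal, DT_hint_M)."""
    parts = []
    for c in curves:
        parts.append(
            pd.DataFrame(
                {
                    "curve_id": c.curve_id,
                    "conc_M": 10.0 ** c.x,
                    "signal": c.y,
                    "DT_hint_M": c.dt_hint,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def _default_mix():
    lad = volumetry.reference_ladder()
    return [
        (lad.entries["Cra homodimer"], 0.4),
        (lad.entries["(dimer)2 Cra-FruK"], 0.4),
        (lad.entries["(dimer)3 Cra-FruK-Cra"], 0.2),
    ]


@dataclass(frozen=True)
class AfmSimSpec:
    """Conditions for simulated AFM particle populations.

    The default mixture places particles at the homodimer,
    dimer-of-dimers, and trimer-of-dimers ladder masses, roughly matching
    the relative abundances seen for DNA-bound complexes.  Geometry
    defaults give peaks a few nm tall and tens of nm wide, and adjacent
    dsDNA ~0.5 nm tall and ~6 nm wide at half-height.
    """

    populations: tuple = field(default_factory=lambda: tuple(_default_mix()))
    n_peaks: int = 60
    height_mean_nm: float = 2.0
    height_cv: float = 0.2          # lognormal spread of peak height
    aspect_mean: float = 1.3        # w_long / w_orth
    aspect_cv: float = 0.15
    noise_cv: float = 0.0           # fractional measurement noise per dimension
    dna_bound_fraction: float = 1.0
    dna_height_nm: float = 0.5
    dna_width_nm: float = 6.0
    dna_cv: float = 0.1
    specific_volume: float = volumetry.SPECIFIC_VOLUME_ML_PER_G
    seed: int = 0

    def __post_init__(self):
        fracs = np.array([f for _, f in self.populations], dtype=float)
        masses = np.array([m for m, _ in self.populations], dtype=float)
        _require(np.all(masses > 0), "populations", "masses must be positive")
        _require(abs(fracs.sum() - 1.0) < 1e-9, "populations", "mixing fractions must sum to 1")
        _require(self.n_peaks >= 1, "n_peaks", "must be >= 1")
        for name in ("height_mean_nm", "aspect_mean", "dna_height_nm", "dna_width_nm"):
            _require(getattr(self, name) > 0, name, "must be positive")
        _require(0 <= self.dna_bound_fraction <= 1, "dna_bound_fraction", "must be in [0, 1]")
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")


def _lognormal(rng, mean, cv, size=None):
    if cv == 0:
        return np.full(size if size is not None else (), mean, dtype=float)
    sigma = np.sqrt(np.log1p(cv * cv))
    mu = np.log(mean) - 0.5 * sigma * sigma
    return rng.lognormal(mu, sigma, size=size)


def gen_afm_peaks(spec: AfmSimSpec) -> pd.DataFrame:
    """Simulate an AFM measurement sheet with true-mass labels.

    For each particle a true protein volume is computed from the drawn
    population mass via the specific-volume constant; DNA-bound particles
    get adjacent-DNA measurements whose cylindrical-segment volume is
    added to the deposited volume before the geometric decomposition.
    Columns match the measurement-sheet reader plus ``true_mass_da``.
    """
    rng = _rng(spec.seed, "afm")
    masses = np.array([m for m, _ in spec.populations])
    fracs = np.array([f for _, f in spec.populations])
    pop = rng.choice(masses.size, size=spec.n_peaks, p=fracs)
    true_mass = masses[pop]
    v_protein = volumetry.mw_to_volume(true_mass, spec.specific_volume)

    bound = rng.random(spec.n_peaks) < spec.dna_bound_fraction
    h_dna = _lognormal(rng, spec.dna_height_nm, spec.dna_cv, spec.n_peaks)
    w_dna = _lognormal(rng, spec.dna_width_nm, spec.dna_cv, spec.n_peaks)
    v_dna = np.where(bound, volumetry.dna_segment_volume(h_dna, w_dna), 0.0)
    v_total = v_protein + v_dna

    h = _lognormal(rng, spec.height_mean_nm, spec.height_cv, spec.n_peaks)
    aspect = _lognormal(rng, spec.aspect_mean, spec.aspect_cv, spec.n_peaks)
    # Decompose V = pi*h*(w_long/2)*(w_orth/2) with w_long = aspect*w_orth.
    w_orth = np.sqrt(4.0 * v_total / (np.pi * h * aspect))
    w_long = aspect * w_orth

    noise = lambda: _lognormal(rng, 1.0, spec.noise_cv, spec.n_peaks)
    df = pd.DataFrame(
        {
            "peak_id": [f"peak_{i:03d}" for i in range(spec.n_peaks)],
            "h_nm": h * noise(),
            "w_long_nm": w_long * noise(),
            "w_orth_nm": w_orth * noise(),
            "dna_bound": bound,
            "h_dna_nm": np.where(bound, h_dna * noise(), np.nan),
            "w_dna_nm": np.where(bound, w_dna * noise(), np.nan),
            "true_mass_da": true_mass,
        }
    )
    return df


@dataclass(frozen=True)
class GrowthSimSpec:
    """Logistic growth-curve simulation (OD600 vs time).

    Defaults mirror the plate-reader layout of the growth assays:
    readings every 30 min over 22 h, carrying capacity around 1 OD.
    """

    capacity: float = 1.0
    rate: float = 0.8            # 1/h
    midpoint_h: float = 8.0
    interval_h: float = 0.5
    horizon_h: float = 22.0
    od0: float = 0.025           # inoculum baseline OD
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        _require(self.capacity > 0, "capacity", "must be positive")
        _require(self.rate > 0, "rate", "must be positive")
        _require(self.interval_h > 0, "interval_h", "must be positive")
        _require(self.horizon_h >= self.interval_h, "horizon_h", "must cover at least one interval")
        _require(self.horizon_h > self.midpoint_h, "horizon_h", "must exceed the midpoint")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


def gen_growth(spec: GrowthSimSpec):
    """Simulate one growth series; returns (time_h, od, true_midpoint_h)."""
    rng = _rng(spec.seed, "growth")
    t = np.arange(0.0, spec.horizon_h + spec.interval_h / 2, spec.interval_h)
    clean = spec.od0 + spec.capacity / (1.0 + np.exp(-spec.rate * (t - spec.midpoint_h)))
    od = clean + rng.normal(0.0, spec.noise_sd, size=t.size)
    # a plate reader never reports negative optical density
    return t, np.clip(od, 0.0, None), spec.midpoint_h


def _default_substrates():
    return (0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 15.0)


def _default_fold(s):
    # Saturating concentration dependence reaching ~3-fold at the top
    # of the substrate range.
    return 1.0 + 2.0 * s / (s + 2.0)


@dataclass(frozen=True)
class PlateSimSpec:
    """Luciferase plate simulation: substrate series, controls, ATP ladder.

    Defaults follow the assay layout: triplicate technical replicates per
    substrate level over 0.1-15 mM, buffer-only controls, and an ATP
    calibration series spanning 0.03-4 mM.
    """

    substrates_mM: tuple = field(default_factory=_default_substrates)
    n_replicates: int = 3
    fold_fn: object = None               # callable substrate -> true fold
    control_mean: float = 1000.0
    control_sd: float = 50.0
    atp_points_mM: tuple = (0.03, 0.1, 0.3, 1.0, 4.0)
    atp_gain: float = 5000.0             # luminescence per mM (slope-1 log-log)
    atp_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.control_mean > 0, "control_mean", "must be positive")
        _require(self.control_sd >= 0, "control_sd", "must be >= 0")
        _require(self.atp_gain > 0, "atp_gain", "must be positive")
        _require(all(s > 0 for s in self.substrates_mM), "substrates_mM", "must be positive")
        if self.fold_fn is None:
            object.__setattr__(self, "fold_fn", _default_fold)


def gen_luminescence(spec: PlateSimSpec):
    """Simulate one plate; returns (plate_frame, atp_frame).

    The plate frame is tidy (substrate_mM, replicate, luminescence,
    is_control); condition wells have mean ``fold_fn(s) * control_mean``
    with the control's coefficient of variation.
    """
    rng = _rng(spec.seed, "plate")
    rows = []
    cv = spec.control_sd / spec.control_mean
    for r in range(spec.n_replicates):
        rows.append(
            {
                "substrate_mM": np.nan,
                "replicate": r,
                "luminescence": rng.normal(spec.control_mean, spec.control_sd),
                "is_control": True,
            }
        )
    for s in spec.substrates_mM:
        mean = spec.fold_fn(s) * spec.control_mean
        for r in range(spec.n_replicates):
            rows.append(
                {
                    "substrate_mM": s,
                    "replicate": r,
                    "luminescence": rng.normal(mean, cv * mean),
                    "is_control": False,
                }
            )
    plate = pd.DataFrame(rows)
    atp = pd.DataFrame(
        {
            "atp_mM": spec.atp_points_mM,
            "luminescence": [
                spec.atp_gain * a * _lognormal(rng, 1.0, spec.atp_noise_cv)
                for a in spec.atp_points_mM
            ],
        }
    )
    return plate, atp
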