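"""Synthetic chronotopic lattices and 4-D BOLD timeseries.

The generator plants a known duration-preference topography: per-voxel
Gaussian duration tuning (preferred duration mu*, spread sigma*) arranged
linearly along an anterior-posterior lattice axis, with an "anterior
short" gradient mirroring the rostro-caudal progression the analysis is
designed to detect.  BOLD is generated with the same offset-locked
convention the analysis assumes: a tuned neural impulse at each stimulus
offset, convolved with the canonical HRF, sampled at the TR, plus
baseline, a slow sinusoidal drift, and white noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .design import ScanGrid
from .hrf import HRFKernel, canonical_hrf


@dataclass
class TruthMap:
    """Planted per-voxel ground truth on a lattice.

    ``mu_star``/``sigma_star`` are the preferred duration and tuning spread
    in seconds, ``amplitude`` the evoked response gain, ``baseline`` the
    mean signal.  ``gradient_axis`` is the lattice axis along which mu*
    progresses; ``border_low``/``border_high`` are the anterior and
    posterior border coordinates (voxel units) along that axis.
    """

    shape: tuple[int, ...]
    voxel_size: float
    mu_star: np.ndarray
    sigma_star: np.ndarray
    amplitude: np.ndarray
    baseline: np.ndarray
    gradient_axis: int = 0
    border_low: float = 0.0
    border_high: float = 0.0
    gradient: str = "anterior_short"

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coordinate_mm(self) -> np.ndarray:
        """Per-voxel coordinate along the gradient axis, in mm."""
        idx = np.indices(self.shape)[self.gradient_axis]
        return idx * self.voxel_size

    def geometry(self):
        """Border geometry with the posterior border as reference (D1)."""
        from .topography import BorderGeometry
        return BorderGeometry(axis=self.gradient_axis,
                              d1_border=self.border_high * self.voxel_size,
                              d2_border=self.border_low * self.voxel_size,
                              voxel_size=self.voxel_size)


@dataclass(frozen=True)
class NoiseSpec:
    white_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_period: float = 240.0   # >= 120 s so the high-pass can remove it
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be positive")


@dataclass
class BehaviorSummary:
    accuracy: dict[float, float]
    cv: dict[float, float]
    overall_accuracy: float = field(default=np.nan)


def make_truth_chronomap(shape: tuple[int, ...] = (20, 20, 4),
                         duration_range: tuple[float, float] = (0.2, 1.0),
                         sigma_star: float = 0.3,
                         gradient: str = "anterior_short",
                         seed: int = 0,
                         jitter: float = 0.0,
                         amplitude: float = 1.0,
                         baseline: float = 100.0,
                         voxel_size: float = 2.0) -> TruthMap:
    """Plant a linear duration-preference gradient on a voxel lattice.

    ``anterior_short`` places the shortest preferred duration at lattice
    index 0 (the anterior border) increasing linearly to the posterior
    border; ``anterior_long`` is the reverse; ``shuffled`` permutes mu*
    across voxels, destroying the topography while keeping the mu*
    distribution.  ``jitter`` adds zero-mean Gaussian scatter (seconds) to
    mu*, clipped to the duration range.
    """
    if gradient not in ("anterior_short", "anterior_long", "shuffled"):
        raise ValueError(f"unknown gradient {gradient!r}")
    lo, hi = duration_range
    if lo > hi:
        raise ValueError("duration_range must be ordered")
    if lo == hi:
        warnings.warn("degenerate duration range: all mu* equal")
    rng = np.random.default_rng(seed)
    axis = 0
    n = shape[axis]
    frac = np.indices(shape)[axis] / max(n - 1, 1)
    if gradient == "anterior_long":
        frac = 1.0 - frac
    mu = lo + frac * (hi - lo)
    if jitter > 0:
        mu = np.clip(mu + rng.normal(0.0, jitter, size=shape), lo, hi)
    if gradient == "shuffled":
        mu = rng.permutation(mu.ravel()).reshape(shape)
    return TruthMap(shape=tuple(shape), voxel_size=voxel_size,
                    mu_star=mu, sigma_star=np.full(shape, sigma_star),
                    amplitude=np.full(shape, amplitude),
                    baseline=np.full(shape, baseline),
                    gradient_axis=axis, border_low=0.0,
                    border_high=float(n - 1), gradient=gradient)


def _tuned_impulses(events: pd.DataFrame, scan: ScanGrid,
                    include_s2: bool, s2_gain: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(durations, impulse matrix n_volumes x n_durations with event gains)."""
    rows = []
    for _, ev in events.iterrows():
        if ev["role"] == "S1":
            gain = 1.0
        elif ev["role"] == "S2" and include_s2:
            gain = s2_gain
        else:
            continue
        offset = float(ev["onset"]) + float(ev["duration"])
        rows.append((round(float(ev["duration_label"]), 9), offset, gain))
    durations = np.unique([r[0] for r in rows])
    impulses = np.zeros((scan.n_volumes, len(durations)))
    lookup = {d: j for j, d in enumerate(durations)}
    for dur, offset, gain in rows:
        vol = scan.volume_of(offset)
        if vol >= scan.n_volumes:
            raise ValueError("scan shorter than the last event")
        impulses[vol, lookup[dur]] += gain
    return durations, impulses


def simulate_bold(truth: TruthMap, events: pd.DataFrame, scan: ScanGrid,
                  noise: NoiseSpec | None = None,
                  include_s2: bool = True, s2_gain: float = 0.5,
                  hrf: HRFKernel | None = None) -> np.ndarray:
    """Generate one run of 4-D BOLD (shape = lattice + time).

    Per voxel v, each stimulus offset with presented duration d contributes
    a neural impulse of height amplitude_v * exp(-(d - mu*_v)^2 /
    (2 sigma*_v^2)) (S2 impulses scaled by ``s2_gain`` when enabled); the
    impulse train is convolved with the canonical HRF on the TR grid and
    added to baseline, sinusoidal drift, and white noise.
    """
    last = (events["onset"] + events["duration"]).max()
    if last > scan.duration + 1e-9:
        raise ValueError("scan shorter than the last event")
    if hrf is None:
        hrf = canonical_hrf(scan.tr)
    durations, impulses = _tuned_impulses(events, scan, include_s2, s2_gain)
    # convolved unit regressor per presented duration: n_volumes x n_durations
    reg = np.column_stack([np.convolve(impulses[:, j], hrf.values)[: scan.n_volumes]
                           for j in range(impulses.shape[1])])
    mu = truth.mu_star.reshape(-1, 1)
    sig = truth.sigma_star.reshape(-1, 1)
    weights = np.exp(-((durations[None, :] - mu) ** 2) / (2.0 * sig ** 2))
    signal = truth.amplitude.reshape(-1, 1) * (weights @ reg.T)
    signal += truth.baseline.reshape(-1, 1)
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        t = np.arange(scan.n_volumes) * scan.tr
        if noise.drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi, size=(truth.n_voxels, 1))
            signal += noise.drift_amplitude * np.sin(
                2 * np.pi * t[None, :] / noise.drift_period + phase)
        if noise.white_sd > 0:
            signal += rng.normal(0.0, noise.white_sd,
                                 size=(truth.n_voxels, scan.n_volumes))
    return signal.reshape(*truth.shape, scan.n_volumes)


def simulate_behavior(design: pd.DataFrame, sensitivity: float,
                      seed: int = 0) -> BehaviorSummary:
    """Noisy-comparison behavioral model for paired S1/S2 trials.

    A trial is judged correctly with probability Phi(sensitivity *
    |dT| / T), where T is the standard duration and dT the
    standard-comparison difference: chance at zero sensitivity, perfect in
    the high-sensitivity limit.  The per-condition coefficient of variation
    comes from perceived durations drawn with scalar-timing noise
    sd = T / (1 + sensitivity).
    """
    rng = np.random.default_rng(seed)
    s1 = design[design["role"] == "S1"].set_index("trial_index")
    s2 = design[design["role"] == "S2"].set_index("trial_index")
    trials = s1.join(s2, lsuffix="_s1", rsuffix="_s2", how="inner")
    if trials.empty:
        raise ValueError("design has no paired S1/S2 trials")
    d1 = trials["duration_label_s1"].to_numpy(float)
    d2 = trials["duration_label_s2"].to_numpy(float)
    if "pair_id_s1" in trials.columns and trials["pair_id_s1"].notna().all():
        standard = np.minimum(d1, d2)   # comparison = 1.5 x standard
        condition = standard
    else:
        standard = d1                   # S1 is the standard
        condition = d1
    delta = np.abs(d2 - d1)
    p_correct = ndtr(sensitivity * delta / standard)
    correct = rng.random(len(trials)) < p_correct
    accuracy, cv = {}, {}
    for cond in np.unique(np.round(condition, 9)):
        sel = np.isclose(condition, cond)
        accuracy[float(cond)] = float(np.mean(correct[sel]))
        perceived = rng.normal(cond, cond / (1.0 + sensitivity),
                               size=max(int(sel.sum()), 2))
        cv[float(cond)] = float(np.std(perceived, ddof=1) / cond)
    return BehaviorSummary(accuracy=accuracy, cv=cv,
                           overall_accuracy=float(np.mean(correct)))
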