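"""Event-timeline construction for the two duration-mapping paradigms.

Experiment 1 is a slow event-related duration-discrimination design: on each
trial a first grating (S1, one of four durations) is followed, after a
jittered interstimulus interval, by a comparison grating (S2) and a 2-s
response cue.  Experiment 2 is a cyclic design tailored to population
receptive field mapping: 44-s cycles of ten standard/comparison duration
pairs presented in ascending or descending order with no jitter.

Event tables are plain :class:`pandas.DataFrame` objects with columns
``onset, duration, duration_label, role, trial_index, cycle, pair_id`` (all
times in seconds on a 0-based run clock).  ``duration_label`` is the nominal
stimulus duration used as the condition identifier downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the four first-stimulus durations of experiment 1 (seconds)
EXP1_DURATIONS = (0.2, 0.4, 0.6, 1.0)
#: grating orientations crossed with duration in experiment 1 (degrees)
EXP1_ORIENTATIONS = (36, 72, 108, 144)
#: Weber ratio of the experiment-1 comparison stimulus
EXP1_WEBER_RATIO = 0.4

#: the ten (standard, comparison) duration pairs of experiment 2 (seconds)
EXP2_PAIRS = (
    (0.2, 0.3), (0.4, 0.6), (0.6, 0.9), (0.8, 1.2), (1.0, 1.5),
    (1.2, 1.8), (1.4, 2.1), (1.6, 2.4), (1.8, 2.7), (2.0, 3.0),
)
EXP2_CYCLE_SECONDS = 44.0
EXP2_INTRA_TRIAL_VERTICAL = 1.37
EXP2_INTER_CYCLE_VERTICAL = 2.03
EXP2_VOLUMES_PER_CYCLE = 22

RESPONSE_CUE_SECONDS = 2.0

EVENT_COLUMNS = ["onset", "duration", "duration_label", "role",
                 "trial_index", "cycle", "pair_id"]


@dataclass(frozen=True)
class ScanGrid:
    """Sampling grid of one functional run.

    Parameters
    ----------
    tr : float
        Effective sampling interval in seconds (one volume per ``tr``).
    n_volumes : int
        Number of volumes acquired in the run.
    run_id : int
        Index of the run within the session.
    direction : {"ascending", "descending", "none"}
        Cycle ordering for cyclic designs, "none" otherwise.
    """

    tr: float
    n_volumes: int
    run_id: int = 0
    direction: str = "none"

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_volumes <= 0:
            raise ValueError("n_volumes must be positive")
        if self.direction not in ("ascending", "descending", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def duration(self) -> float:
        """Run length in seconds."""
        return self.tr * self.n_volumes

    def volume_of(self, time_s: float) -> int:
        """0-based index of the volume containing ``time_s``."""
        return int(np.floor(time_s / self.tr))


def _finalize(rows: list[dict]) -> pd.DataFrame:
    events = pd.DataFrame(rows)
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            events[col] = np.nan
    events = events[EVENT_COLUMNS + [c for c in events.columns
                                     if c not in EVENT_COLUMNS]]
    events = events.sort_values("onset", kind="stable").reset_index(drop=True)
    return events


def _check_events(events: pd.DataFrame, scan: ScanGrid) -> None:
    onsets = events["onset"].to_numpy()
    offsets = onsets + events["duration"].to_numpy()
    if (onsets < 0).any():
        raise ValueError("negative event onset")
    if offsets.max() > scan.duration + 1e-9:
        raise ValueError("events extend past the end of the run")
    if len(np.unique(np.round(onsets, 6))) != len(onsets):
        raise ValueError("duplicate event onsets")


def build_exp1_design(n_runs: int, seed: int) -> list[tuple[pd.DataFrame, ScanGrid]]:
    """Build experiment-1 runs: 16 trials, one per (duration, orientation).

    Each trial presents S1 (0.2/0.4/0.6/1 s), a uniform interstimulus
    interval in {4.00, 4.08, ..., 5.20} s, S2 at S1 x (1 +/- 0.4), and a 2-s
    response cue.  Trial order is shuffled per run.  Runs are sampled on a
    1.368-s grid, 169 volumes each.

    Returns a list of ``(events, scan)`` pairs, one per run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    isi_choices = np.round(np.arange(4.00, 5.20 + 1e-9, 0.08), 2)
    iti_choices = np.round(np.arange(3.00, 4.48 + 1e-9, 0.08), 2)
    runs = []
    for run_id in range(n_runs):
        combos = list(itertools.product(EXP1_DURATIONS, EXP1_ORIENTATIONS))
        rng.shuffle(combos)
        rows: list[dict] = []
        t = 2.0  # lead-in before the first trial
        for trial, (s1, ori) in enumerate(combos):
            s2 = round(s1 * (1 + EXP1_WEBER_RATIO * rng.choice([-1.0, 1.0])), 6)
            isi = float(rng.choice(isi_choices))
            rows.append(dict(onset=round(t, 6), duration=s1, duration_label=s1,
                             role="S1", trial_index=trial, orientation=ori))
            s2_onset = t + s1 + isi
            rows.append(dict(onset=round(s2_onset, 6), duration=s2,
                             duration_label=s2, role="S2", trial_index=trial,
                             orientation=float(rng.choice(EXP1_ORIENTATIONS))))
            cue_onset = s2_onset + s2
            rows.append(dict(onset=round(cue_onset, 6),
                             duration=RESPONSE_CUE_SECONDS,
                             duration_label=RESPONSE_CUE_SECONDS,
                             role="response_cue", trial_index=trial))
            t = cue_onset + RESPONSE_CUE_SECONDS + float(rng.choice(iti_choices))
        scan = ScanGrid(tr=1.368, n_volumes=169, run_id=run_id)
        events = _finalize(rows)
        _check_events(events, scan)
        runs.append((events, scan))
    return runs


def _order_matrix(n_pairs: int, n_cycles: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced standard-first assignment: entry (p, c) is 1 if pair p leads
    with the standard in cycle c.  A permuted checkerboard keeps exactly
    half the pairs standard-first in every cycle and balances each pair
    across cycles."""
    base = (np.add.outer(np.arange(n_pairs), np.arange(n_cycles)) % 2).astype(bool)
    return base[rng.permutation(n_pairs)][:, rng.permutation(n_cycles)]


def build_exp2_design(direction: str, n_cycles: int,
                      seed: int) -> tuple[pd.DataFrame, ScanGrid]:
    """Build one experiment-2 run of ``n_cycles`` 44-s cycles.

    Each cycle presents the ten (T, 1.5 T) pairs, short-to-long (ascending)
    or long-to-short (descending).  Within a trial the standard/comparison
    order is randomized with exactly five standard-first trials per cycle;
    S1 and S2 are back to back and followed by a 1.37-s vertical-orientation
    interval.  A 2.03-s vertical inter-cycle interval plus a vertical pad
    brings every cycle to exactly 44 s (22 volumes at TR = 2 s).
    """
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    std_first = _order_matrix(len(EXP2_PAIRS), n_cycles, rng)
    rows: list[dict] = []
    trial_counter = 0
    for cycle in range(n_cycles):
        t = cycle * EXP2_CYCLE_SECONDS
        order = range(len(EXP2_PAIRS))
        if direction == "descending":
            order = reversed(list(order))
        for p in order:
            std, cmp_ = EXP2_PAIRS[p]
            first, second = (std, cmp_) if std_first[p, cycle] else (cmp_, std)
            rows.append(dict(onset=round(t, 6), duration=first,
                             duration_label=first, role="S1",
                             trial_index=trial_counter, cycle=cycle,
                             pair_id=p + 1))
            rows.append(dict(onset=round(t + first, 6), duration=second,
                             duration_label=second, role="S2",
                             trial_index=trial_counter, cycle=cycle,
                             pair_id=p + 1))
            t = t + first + second
            rows.append(dict(onset=round(t, 6),
                             duration=EXP2_INTRA_TRIAL_VERTICAL,
                             duration_label=EXP2_INTRA_TRIAL_VERTICAL,
                             role="vertical", trial_index=trial_counter,
                             cycle=cycle, pair_id=p + 1))
            t += EXP2_INTRA_TRIAL_VERTICAL
            trial_counter += 1
        rows.append(dict(onset=round(t, 6), duration=EXP2_INTER_CYCLE_VERTICAL,
                         duration_label=EXP2_INTER_CYCLE_VERTICAL,
                         role="vertical", cycle=cycle))
        t += EXP2_INTER_CYCLE_VERTICAL
        pad = (cycle + 1) * EXP2_CYCLE_SECONDS - t
        if pad > 1e-9:
            rows.append(dict(onset=round(t, 6), duration=round(pad, 6),
                             duration_label=round(pad, 6), role="vertical",
                             cycle=cycle))
    scan = ScanGrid(tr=2.0, n_volumes=EXP2_VOLUMES_PER_CYCLE * n_cycles,
                    run_id=0, direction=direction)
    events = _finalize(rows)
    _check_events(events, scan)
    return events, scan


def enumerate_s1_durations(events: pd.DataFrame) -> np.ndarray:
    """Unique sorted S1 duration labels (standards and comparisons pooled).

    For a full experiment-2 run this is the 17-duration set
    {0.2, 0.3, 0.4, 0.6, ..., 2.7, 3}.
    """
    s1 = events.loc[events["role"] == "S1", "duration_label"]
    if s1.empty:
        raise ValueError("event table contains no S1 events")
    return np.unique(np.round(s1.to_numpy(float), 9))
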