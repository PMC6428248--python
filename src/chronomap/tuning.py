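"""Duration-tuning analysis of labeled clusters.

The cluster timecourse is normalized by subtracting and dividing each
voxel's baseline (its mean signal across runs), averaging over voxels and
then over runs, and dividing by the standard deviation of the
voxel-averaged trace — so the normalized trace has unit SD by
construction.  Responses are read out at a fixed lag (the second volume
after the S1 offset), profiled relative to each cluster's preferred
duration (PD), and compared between PD, PD+-1 and PD+-2 conditions with
signed-rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import EXP2_PAIRS, ScanGrid

DEFAULT_LAG_VOLUMES = 2


@dataclass
class NormalizedTrace:
    values: np.ndarray          # run-averaged, unit-SD trace
    per_run: np.ndarray         # n_runs x n_volumes, same scaling
    n_runs: int
    n_voxels: int
    baseline_def: str = "grand_mean"


def normalize_bold(runs, voxels=None,
                   baseline: str = "grand_mean") -> NormalizedTrace:
    """Normalize a cluster's BOLD signal to a unit-SD percent-change trace.

    ``runs`` is a list of per-run arrays with time last (4-D volumes with a
    ``voxels`` boolean mask, or 2-D voxel-by-time arrays).  Per voxel the
    baseline MB is its mean signal across all runs (``baseline=
    "timepoint"`` instead uses the per-timepoint mean across runs); the
    percent-change traces (x - MB)/MB are averaged over voxels, then over
    runs, and scaled by the SD of that average.
    """
    if not isinstance(runs, (list, tuple)):
        runs = [runs]
    mats = []
    for r in runs:
        r = np.asarray(r, float)
        if voxels is not None:
            r = r[np.asarray(voxels, bool)]
        if r.ndim != 2:
            r = r.reshape(-1, r.shape[-1])
        mats.append(r)
    if mats[0].shape[0] == 0:
        raise ValueError("cluster contains no voxels")
    stack = np.stack(mats)                       # runs x voxels x time
    if baseline == "grand_mean":
        mb = stack.mean(axis=(0, 2), keepdims=True)
    elif baseline == "timepoint":
        mb = stack.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown baseline definition {baseline!r}")
    if np.any(mb == 0):
        raise ValueError("zero baseline: cannot normalize")
    rel = (stack - mb) / mb
    per_run = rel.mean(axis=1)                   # runs x time
    mean_trace = per_run.mean(axis=0)
    sd = float(np.std(mean_trace))
    if sd == 0:
        raise ValueError("zero-variance trace: cannot normalize")
    return NormalizedTrace(values=mean_trace / sd, per_run=per_run / sd,
                           n_runs=stack.shape[0], n_voxels=stack.shape[1],
                           baseline_def=baseline)


@dataclass
class ConditionResponses:
    mean: dict[float, float]           # duration -> mean response
    counts: dict[float, int]
    missing: list[float] = field(default_factory=list)


def extract_response(trace: NormalizedTrace, events, scan,
                     lag_volumes: int = DEFAULT_LAG_VOLUMES
                     ) -> ConditionResponses:
    """Sample the normalized trace ``lag_volumes`` after each S1 offset.

    ``events``/``scan`` may be lists matching ``trace.per_run`` rows.
    Events whose lagged index falls past the run end are dropped with a
    warning.  Responses are averaged within S1 duration condition.
    """
    events_list = events if isinstance(events, (list, tuple)) else [events]
    scans = scan if isinstance(scan, (list, tuple)) else [scan]
    if len(events_list) != trace.per_run.shape[0]:
        raise ValueError("number of event tables does not match runs")
    samples: dict[float, list[float]] = {}
    for row, (ev, sc) in enumerate(zip(events_list, scans)):
        s1 = ev[ev["role"] == "S1"]
        for _, e in s1.iterrows():
            vol = sc.volume_of(float(e["onset"]) + float(e["duration"]))
            idx = vol + lag_volumes
            if idx >= sc.n_volumes:
                warnings.warn("lagged sample beyond run end; event dropped")
                continue
            dur = round(float(e["duration_label"]), 9)
            samples.setdefault(dur, []).append(float(trace.per_run[row, idx]))
    mean = {d: float(np.mean(v)) for d, v in sorted(samples.items())}
    counts = {d: len(v) for d, v in sorted(samples.items())}
    return ConditionResponses(mean=mean, counts=counts)


def group_durations_to_pairs(responses: dict[float, float],
                             counts: dict[float, int] | None = None
                             ) -> dict[int, float]:
    """Collapse the 17 presented durations onto the 10 trial-type pairs.

    Each duration contributes to every pair it occurs in (0.6, 1.2 and
    1.8 s belong to two pairs), weighted by its occurrence count.
    """
    out: dict[int, float] = {}
    for pid, pair in enumerate(EXP2_PAIRS, start=1):
        vals, ws = [], []
        for d in pair:
            key = round(d, 9)
            if key in responses:
                vals.append(responses[key])
                ws.append(counts.get(key, 1) if counts else 1)
        if vals:
            out[pid] = float(np.average(vals, weights=ws))
    return out


@dataclass
class TuningProfile:
    """clusters x conditions matrix of (optionally PD-normalized) responses."""

    matrix: pd.DataFrame               # index: cluster PD, columns: conditions
    pd_index: dict[float, int]         # cluster PD -> column rank of its PD
    normalized_to_pd: bool = False
    grouping: str | None = None


def tuning_profile(responses: dict[float, dict[float, float]],
                   grouping: bool = False,
                   normalize: str = "pd",
                   counts: dict[float, dict[float, int]] | None = None
                   ) -> TuningProfile:
    """Build a cluster-by-condition tuning profile.

    ``responses`` maps each cluster's preferred duration to its
    per-condition mean responses.  With ``grouping`` the 17 presented
    durations collapse to the 10 trial-type pairs first (and each
    cluster's PD becomes the pair containing it).  ``normalize="pd"``
    divides each cluster's row by its response at PD, so the profile is 1
    at PD by construction; ``normalize="none"`` keeps raw normalized
    responses.
    """
    rows: dict[float, dict] = {}
    pd_index: dict[float, int] = {}
    for cluster_pd, resp in responses.items():
        key = round(float(cluster_pd), 9)
        if grouping:
            cnt = counts.get(cluster_pd) if counts else None
            row = group_durations_to_pairs(resp, cnt)
            conds = sorted(row)
            pd_cond = next(pid for pid, pair in enumerate(EXP2_PAIRS, 1)
                           if any(np.isclose(key, d) for d in pair))
        else:
            row = {round(float(d), 9): v for d, v in resp.items()}
            conds = sorted(row)
            pd_cond = key
        if pd_cond not in row:
            raise ValueError(f"cluster PD {cluster_pd} has no response")
        if normalize == "pd":
            ref = row[pd_cond]
            if ref == 0:
                raise ValueError("zero response at the preferred duration")
            row = {c: v / ref for c, v in row.items()}
        elif normalize != "none":
            raise ValueError(f"unknown normalization {normalize!r}")
        rows[key] = row
        pd_index[key] = conds.index(pd_cond)
    matrix = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    matrix = matrix[sorted(matrix.columns)]
    # recompute rank positions on the full condition list
    pd_index = {}
    cols = list(matrix.columns)
    for cluster_pd in matrix.index:
        if grouping:
            pd_cond = next(pid for pid, pair in enumerate(EXP2_PAIRS, 1)
                           if any(np.isclose(cluster_pd, d) for d in pair))
        else:
            pd_cond = cluster_pd
        pd_index[float(cluster_pd)] = cols.index(pd_cond)
    return TuningProfile(matrix=matrix, pd_index=pd_index,
                         normalized_to_pd=normalize == "pd",
                         grouping="pairs" if grouping else None)


@dataclass
class PDComparison:
    p_pd_vs_pd1: float | None
    p_pd_vs_pd2: float | None
    n: int
    flagged: str | None = None


def _neighbor_table(profile: TuningProfile) -> np.ndarray:
    """Per cluster: [response at PD, mean at PD+-1, mean at PD+-2] (rank
    scale, truncated at the profile ends; NaN where no neighbor exists)."""
    mat = profile.matrix.to_numpy(float)
    rows = []
    for row, j in enumerate(profile.pd_index.values()):
        entry = [mat[row, j], np.nan, np.nan]
        for k in (1, 2):
            vals = [mat[row, jj] for jj in (j - k, j + k)
                    if 0 <= jj < mat.shape[1] and np.isfinite(mat[row, jj])]
            if vals:
                entry[k] = float(np.mean(vals))
        rows.append(entry)
    return np.array(rows).reshape(-1, 3)


def compare_pd_groups(profiles, scheme: str = "pairwise_pd",
                      min_n: int = 5) -> PDComparison:
    """Signed-rank comparison of responses at PD vs neighboring durations.

    ``profiles`` is one :class:`TuningProfile` or a list pooled over
    subjects; each cluster contributes one paired observation.
    ``pairwise_pd`` tests PD vs PD+-1 and PD vs PD+-2 (one-sided, PD
    greater — enhancement at and near the preferred duration, suppression
    farther away); ``union`` tests mean(PD, PD+-1) vs PD+-2.
    """
    if isinstance(profiles, TuningProfile):
        profiles = [profiles]
    table = np.concatenate([_neighbor_table(p) for p in profiles])
    if scheme == "union":
        near = np.nanmean(table[:, :2], axis=1)
        pairs1 = pairs2 = np.column_stack([near, table[:, 2]])
    elif scheme == "pairwise_pd":
        pairs1 = table[:, [0, 1]]
        pairs2 = table[:, [0, 2]]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    pairs1 = pairs1[np.isfinite(pairs1).all(axis=1)]
    pairs2 = pairs2[np.isfinite(pairs2).all(axis=1)]
    n = min(len(pairs1), len(pairs2))
    if n < min_n:
        return PDComparison(None, None, n, "insufficient observations")

    def sr(pairs):
        d = pairs[:, 0] - pairs[:, 1]
        d = d[d != 0]
        if len(d) == 0:
            return None
        return float(stats.wilcoxon(d, alternative="greater").pvalue)

    return PDComparison(p_pd_vs_pd1=sr(pairs1), p_pd_vs_pd2=sr(pairs2), n=n)


def cycle_timecourse(trace: NormalizedTrace, scan,
                     cycle_len_volumes: int = 22) -> np.ndarray:
    """Mean single-cycle waveform of a cyclic run.

    Each run's trace is reshaped into cycles; cycles from descending runs
    are time-reversed to match ascending ones; all cycles are averaged.
    ``scan`` may be a list matching ``trace.per_run``.
    """
    scans = scan if isinstance(scan, (list, tuple)) else [scan]
    if len(scans) != trace.per_run.shape[0]:
        raise ValueError("number of scans does not match runs")
    cycles = []
    for row, sc in enumerate(scans):
        series = trace.per_run[row]
        if len(series) % cycle_len_volumes != 0:
            raise ValueError("run length not divisible by cycle length")
        chunk = series.reshape(-1, cycle_len_volumes)
        if sc.direction == "descending":
            chunk = chunk[:, ::-1]
        cycles.append(chunk)
    return np.concatenate(cycles).mean(axis=0)
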