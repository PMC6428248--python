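"""End-to-end orchestration of the chronotopic-mapping pipeline.

File-based stage functions (used by the command-line interface) plus
in-memory conveniences for simulation studies.  A working directory holds
one simulated session: ``bold_run##.nii``, ``events_run##.tsv``, the truth
map, ``scans.json``, and the stage outputs (label maps, JSON reports).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .design import (EXP1_DURATIONS, ScanGrid, build_exp1_design,
                     build_exp2_design, enumerate_s1_durations)
from .glm import build_design_matrix, fit_glm, winner_take_all
from .hrf import canonical_hrf
from .maps import LabelMap
from .prf import prf_map
from .qc import venous_check_glm, venous_check_prf
from .simulate import NoiseSpec, TruthMap, make_truth_chronomap, simulate_bold
from .topography import quantify_topography, test_slopes
from .tuning import (compare_pd_groups, extract_response, normalize_bold,
                     tuning_profile)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2,
                                     sort_keys=True))


def build_designs(cfg: dict) -> list[tuple[pd.DataFrame, ScanGrid]]:
    seed = int(cfg["seed"])
    if cfg["experiment"] == "exp1":
        return build_exp1_design(int(cfg["design"]["exp1_n_runs"]), seed)
    runs = []
    for i, direction in enumerate(("ascending", "descending")):
        ev, sc = build_exp2_design(direction,
                                   int(cfg["design"]["exp2_n_cycles"]),
                                   seed + i)
        runs.append((ev, dataclasses.replace(sc, run_id=i)))
    return runs


def duration_range_for(cfg: dict) -> tuple[float, float]:
    rng = cfg["simulate"].get("duration_range")
    if rng:
        return float(rng[0]), float(rng[1])
    return (0.2, 1.0) if cfg["experiment"] == "exp1" else (0.2, 3.0)


def simulate_session(cfg: dict, outdir) -> dict:
    """Generate and write a full synthetic session; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = cfg["simulate"]
    seed = int(cfg["seed"])
    truth = make_truth_chronomap(
        shape=tuple(sim["shape"]), duration_range=duration_range_for(cfg),
        sigma_star=float(sim["sigma_star"]), gradient=sim["gradient"],
        seed=seed + 1, amplitude=float(sim["amplitude"]),
        baseline=float(sim["baseline"]), voxel_size=float(sim["voxel_size"]))
    runs = build_designs(cfg)
    scans_meta = []
    for i, (events, scan) in enumerate(runs):
        noise = NoiseSpec(white_sd=float(sim["white_sd"]),
                          drift_amplitude=float(sim["drift_amplitude"]),
                          drift_period=float(sim["drift_period"]),
                          seed=seed + 100 + i)
        bold = simulate_bold(truth, events, scan, noise,
                             include_s2=bool(sim["include_s2"]))
        cio.save_volume(outdir / f"bold_run{i:02d}.nii", bold,
                        truth.voxel_size)
        cio.write_events(outdir / f"events_run{i:02d}.tsv", events)
        scans_meta.append(dict(tr=scan.tr, n_volumes=scan.n_volumes,
                               run_id=i, direction=scan.direction))
    cio.save_truth_map(outdir / "truth", truth)
    _write_json(outdir / "scans.json", dict(runs=scans_meta))
    manifest = dict(config_hash=cio.config_hash(cfg), seed=seed,
                    experiment=cfg["experiment"], n_runs=len(runs))
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def _load_session(workdir):
    workdir = Path(workdir)
    meta = json.loads((workdir / "scans.json").read_text())
    scans, events, bolds = [], [], []
    for m in meta["runs"]:
        i = int(m["run_id"])
        scans.append(ScanGrid(tr=float(m["tr"]), n_volumes=int(m["n_volumes"]),
                              run_id=i, direction=m["direction"]))
        events.append(cio.read_events(workdir / f"events_run{i:02d}.tsv"))
        data, _ = cio.load_volume(workdir / f"bold_run{i:02d}.nii")
        bolds.append(data)
    return bolds, events, scans


def glm_label_map(bolds, events_list, scans, t_threshold: float = 3.13,
                  hp_cutoff_hz: float = 0.0083, min_cluster_size: int = 0,
                  voxel_size: float = 1.0) -> LabelMap:
    """GLM + winner-take-all route: multi-run OLS, per-duration contrasts,
    t-threshold labeling."""
    hrf = canonical_hrf(scans[0].tr)
    designs = [build_design_matrix(ev, sc, hrf, hp_cutoff_hz=hp_cutoff_hz)
               for ev, sc in zip(events_list, scans)]
    _, tmap = fit_glm(bolds, designs)
    durations = np.array([float(n.split("_", 1)[1])
                          for n in tmap.contrast_names])
    order = np.argsort(durations)
    tmap.t = tmap.t[..., order]
    tmap.contrast_names = [tmap.contrast_names[j] for j in order]
    return winner_take_all(tmap, durations[order], threshold=t_threshold,
                           min_cluster_size=min_cluster_size,
                           voxel_size=voxel_size)


def run_glm_map(workdir, cfg: dict) -> LabelMap:
    bolds, events_list, scans = _load_session(workdir)
    voxel_size = float(cfg["simulate"]["voxel_size"])
    labels = glm_label_map(bolds, events_list, scans,
                           t_threshold=float(cfg["glm"]["t_threshold"]),
                           hp_cutoff_hz=float(cfg["glm"]["hp_cutoff_hz"]),
                           min_cluster_size=int(cfg["glm"]["min_cluster_size"]),
                           voxel_size=voxel_size)
    cio.save_label_map(Path(workdir) / "glm", labels)
    return labels


def run_prf_map(workdir, cfg: dict) -> LabelMap:
    bolds, events_list, scans = _load_session(workdir)
    start, stop, step = cfg["prf"]["sigma_grid"]
    sigma_grid = np.round(np.arange(start, stop + 1e-9, step), 6)
    mask = np.ones(bolds[0].shape[:-1], bool)
    labels, mu, sigma, r2 = prf_map(
        bolds, mask, events_list, scans, sigma_grid=sigma_grid,
        refine=bool(cfg["prf"]["refine"]),
        r2_threshold=float(cfg["prf"]["r2_threshold"]))
    labels.voxel_size = float(cfg["simulate"]["voxel_size"])
    workdir = Path(workdir)
    cio.save_label_map(workdir / "prf", labels)
    for name, arr in (("mu", mu), ("sigma", sigma), ("r2", r2)):
        cio.save_volume(workdir / f"prf_{name}.nii", np.nan_to_num(arr),
                        labels.voxel_size)
    fits = pd.DataFrame(dict(
        voxel=[tuple(c) for c in np.argwhere(mask)],
        mu=mu[mask], sigma=sigma[mask], r2=r2[mask],
        included=np.isfinite(labels.label[mask])))
    fits.to_csv(workdir / "prf_fits.tsv", sep="\t", index=False)
    return labels


def _label_stem(workdir, cfg) -> str:
    return str(Path(workdir) / ("glm" if cfg["experiment"] == "exp1"
                                else "prf"))


def run_topography(workdir, cfg: dict) -> dict:
    labels = cio.load_label_map(_label_stem(workdir, cfg))
    truth = cio.load_truth_map(Path(workdir) / "truth")
    report = quantify_topography(
        labels, truth.geometry(), split_at=cfg["topography"]["split_at"],
        bin_width=float(cfg["topography"]["bin_width_mm"]))
    payload = report.to_dict()
    _write_json(Path(workdir) / "topography.json", payload)
    return payload


def run_tuning(workdir, cfg: dict) -> dict:
    bolds, events_list, scans = _load_session(workdir)
    labels = cio.load_label_map(_label_stem(workdir, cfg))
    lag = int(cfg["tuning"]["lag_volumes"])
    responses, counts = {}, {}
    for dur in labels.present_labels():
        cluster = labels.mask_of(dur)
        trace = normalize_bold(bolds, voxels=cluster)
        resp = extract_response(trace, events_list, scans, lag_volumes=lag)
        responses[float(dur)] = resp.mean
        counts[float(dur)] = resp.counts
    grouping = cfg["experiment"] == "exp2"
    profile = tuning_profile(responses, grouping=grouping,
                             normalize="none" if grouping else "pd",
                             counts=counts)
    comparison = compare_pd_groups(profile)
    workdir = Path(workdir)
    profile.matrix.to_csv(workdir / "tuning_profile.tsv", sep="\t")
    payload = dict(comparison=comparison, grouping=profile.grouping,
                   normalized_to_pd=profile.normalized_to_pd)
    _write_json(workdir / "tuning.json", payload)
    return _jsonable(payload)


def run_qc(workdir, cfg: dict) -> dict:
    workdir = Path(workdir)
    labels = cio.load_label_map(_label_stem(workdir, cfg))
    if cfg["experiment"] == "exp1":
        bolds, _, _ = _load_session(workdir)
        intensity = np.mean(np.concatenate(bolds, axis=-1), axis=-1)
        report = venous_check_glm(
            labels.stat, intensity, mask=labels.labeled,
            z_thresh=float(cfg["qc"]["z_threshold"]),
            intensity_quantile=float(cfg["qc"]["intensity_quantile"]))
    else:
        fits = pd.read_csv(workdir / "prf_fits.tsv", sep="\t")
        report = venous_check_prf(
            fits, sigma_thresh=float(cfg["qc"]["sigma_threshold"]))
    report.table.to_csv(workdir / "qc_table.tsv", sep="\t", index=False)
    payload = dict(n_flagged=report.n_flagged, summary=report.summary)
    _write_json(workdir / "qc.json", payload)
    return payload


def run_report(workdir) -> dict:
    """Collate the stage JSON outputs into a single run summary."""
    workdir = Path(workdir)
    summary = {}
    for name in ("manifest", "topography", "tuning", "qc"):
        path = workdir / f"{name}.json"
        if path.exists():
            summary[name] = json.loads(path.read_text())
    _write_json(workdir / "run_summary.json", summary)
    return summary


# --------------------------------------------------------------------------
# in-memory simulation-study helpers

def simulate_subject_labelmap(seed: int, shape=(12, 12, 1), n_runs: int = 2,
                              gradient: str = "anterior_short",
                              sigma_star: float = 0.2, white_sd: float = 0.5,
                              drift_amplitude: float = 0.5,
                              voxel_size: float = 2.0,
                              t_threshold: float = 3.13
                              ) -> tuple[LabelMap, TruthMap]:
    """One synthetic subject through the GLM winner-take-all route."""
    truth = make_truth_chronomap(shape=shape, duration_range=(0.2, 1.0),
                                 sigma_star=sigma_star, gradient=gradient,
                                 seed=seed, voxel_size=voxel_size)
    runs = build_exp1_design(n_runs, seed + 1)
    bolds = []
    for i, (events, scan) in enumerate(runs):
        noise = NoiseSpec(white_sd=white_sd, drift_amplitude=drift_amplitude,
                          seed=seed + 100 + i)
        bolds.append(simulate_bold(truth, events, scan, noise))
    labels = glm_label_map(bolds, [ev for ev, _ in runs],
                           [sc for _, sc in runs], t_threshold=t_threshold,
                           voxel_size=voxel_size)
    return labels, truth


def wta_recovery_study(seed: int, n_runs: int = 18, shape=(20, 20, 4),
                       sigma_star: float = 0.15,
                       t_threshold: float = 3.13) -> dict:
    """Noise-free label-recovery check for the GLM winner-take-all route.

    Simulates a full multi-run session (S2 responses included) and reports
    the fraction of suprathreshold voxels labeled with the duration
    nearest their planted preferred duration.
    """
    labels, truth = simulate_subject_labelmap(
        seed, shape=shape, n_runs=n_runs, sigma_star=sigma_star,
        white_sd=0.0, drift_amplitude=0.0, t_threshold=t_threshold)
    durs = np.asarray(EXP1_DURATIONS)
    nearest = durs[np.argmin(np.abs(truth.mu_star[..., None] - durs), axis=-1)]
    m = labels.labeled
    correct = float(np.mean(np.isclose(labels.label[m], nearest[m])))
    return dict(fraction_correct=correct, n_labeled=int(m.sum()),
                n_voxels=int(labels.label.size))


def prf_recovery_study(n_voxels: int = 300, white_sd: float = 0.0,
                       seed: int = 0, n_cycles: int = 10,
                       sigma_star: float = 0.5, refine: bool = True) -> dict:
    """Parameter-recovery check for the duration pRF stage.

    Simulates ``n_voxels`` tuned voxels through one ascending and one
    descending cyclic run (no S2 responses, so the generated signal lies
    in the model family) and fits the pRF; reports recovery errors and
    goodness of fit.
    """
    ev1, sc1 = build_exp2_design("ascending", n_cycles, seed)
    ev2, sc2 = build_exp2_design("descending", n_cycles, seed + 1)
    truth = make_truth_chronomap(shape=(n_voxels,), duration_range=(0.2, 3.0),
                                 sigma_star=sigma_star, seed=seed + 2)
    bolds = []
    for i, (ev, sc) in enumerate(((ev1, sc1), (ev2, sc2))):
        ns = (NoiseSpec(white_sd=white_sd, seed=seed + 10 + i)
              if white_sd > 0 else None)
        bolds.append(simulate_bold(truth, ev, sc, ns, include_s2=False))
    mask = np.ones(truth.shape, bool)
    _, mu, sigma, r2 = prf_map(bolds, mask, [ev1, ev2], [sc1, sc2],
                               refine=refine)
    err = np.abs(mu - truth.mu_star)
    return dict(median_abs_error=float(np.median(err)),
                max_abs_error=float(np.nanmax(err)),
                min_r2=float(np.nanmin(r2)), mean_r2=float(np.nanmean(r2)),
                mu=mu, sigma=sigma, r2=r2, truth=truth)


def calibrate_white_sd(target_r2: float = 0.3, n_voxels: int = 40,
                       seed: int = 0, n_iter: int = 8) -> float:
    """White-noise level whose pilot-fit mean R^2 matches ``target_r2``.

    Bisection on log noise SD using small pilot recovery studies (mean R^2
    is monotone decreasing in noise).
    """
    lo, hi = np.log(0.05), np.log(20.0)
    for _ in range(n_iter):
        mid = (lo + hi) / 2
        r2 = prf_recovery_study(n_voxels=n_voxels, white_sd=float(np.exp(mid)),
                                seed=seed, refine=False)["mean_r2"]
        if r2 > target_r2:
            lo = mid
        else:
            hi = mid
    return float(np.exp((lo + hi) / 2))


def cohort_slope_test(n_subjects: int, seed: int,
                      gradient: str = "anterior_short", **subject_kwargs):
    """Slope-sign test over one cohort of simulated subjects.

    Returns ``(slope_test, slopes)``; subjects whose label map has fewer
    than two labeled durations contribute no slope.
    """
    from .topography import fit_wrd_slope, wrd_by_label

    slopes = []
    for s in range(n_subjects):
        labels, truth = simulate_subject_labelmap(seed + 1000 * s,
                                                  gradient=gradient,
                                                  **subject_kwargs)
        if len(labels.present_labels()) < 2:
            continue
        wrd = wrd_by_label(labels, truth.geometry())
        slopes.append(fit_wrd_slope(wrd.items()).slope_rank)
    return test_slopes(slopes), slopes


def topography_cohort_study(n_cohorts: int, seed: int, n_subjects: int = 10,
                            gradient: str = "anterior_short",
                            alpha: float = 0.05, **subject_kwargs) -> dict:
    """Replicate cohorts of simulated subjects and report how often the
    negative-slope test rejects at ``alpha``."""
    rejections = 0
    for c in range(n_cohorts):
        st, _ = cohort_slope_test(n_subjects, seed + 100_000 * (c + 1),
                                  gradient=gradient, **subject_kwargs)
        rejections += st.p_value < alpha
    return dict(rejection_fraction=rejections / n_cohorts,
                n_cohorts=n_cohorts, n_subjects=n_subjects)
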