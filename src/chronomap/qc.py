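"""Venous-artifact diagnostics.

Draining veins can masquerade as strongly duration-selective tissue.  Two
checks mirror the analysis stages: GLM-based maps are screened for voxels
combining a very high z score with very low mean signal intensity; pRF
maps are screened for tuning functions with an abnormally wide spread
(all genuine fits in this paradigm have sigma < 1 s), alongside a check
that fitted sigma shows no systematic dependence on mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_Z_THRESHOLD = 8.0
DEFAULT_INTENSITY_QUANTILE = 0.05
DEFAULT_SIGMA_THRESHOLD = 1.0


@dataclass
class QCReport:
    table: pd.DataFrame                 # per-voxel diagnostics + flag column
    n_flagged: int
    summary: dict = field(default_factory=dict)


def venous_check_glm(zmap: np.ndarray, mean_intensity: np.ndarray,
                     z_thresh: float = DEFAULT_Z_THRESHOLD,
                     intensity_quantile: float = DEFAULT_INTENSITY_QUANTILE,
                     mask: np.ndarray | None = None) -> QCReport:
    """Flag voxels with z > ``z_thresh`` AND intensity strictly below the
    given quantile of in-mask intensity."""
    zmap = np.asarray(zmap, float)
    mean_intensity = np.asarray(mean_intensity, float)
    if zmap.shape != mean_intensity.shape:
        raise ValueError("z map and intensity map are not aligned")
    if mask is None:
        mask = np.isfinite(zmap) & np.isfinite(mean_intensity)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    z = zmap[mask]
    inten = mean_intensity[mask]
    cutoff = float(np.quantile(inten, intensity_quantile))
    flags = (z > z_thresh) & (inten < cutoff)
    table = pd.DataFrame(dict(voxel=[tuple(c) for c in np.argwhere(mask)],
                              z=z, mean_intensity=inten, flagged=flags))
    return QCReport(table=table, n_flagged=int(flags.sum()),
                    summary=dict(intensity_cutoff=cutoff,
                                 z_threshold=float(z_thresh)))


def venous_check_prf(fits: pd.DataFrame,
                     sigma_thresh: float = DEFAULT_SIGMA_THRESHOLD) -> QCReport:
    """Flag included pRF fits with sigma >= ``sigma_thresh`` and report the
    Kendall correlation between sigma and mu across included voxels.

    ``fits`` needs columns ``mu``, ``sigma`` and ``included``.
    """
    fits = pd.DataFrame(fits)
    included = fits[fits["included"].astype(bool)]
    if len(included) < 2:
        raise ValueError("need at least 2 included voxels")
    flags = included["sigma"].to_numpy(float) >= sigma_thresh
    sig = included["sigma"].to_numpy(float)
    mu = included["mu"].to_numpy(float)
    if np.all(sig == sig[0]) or np.all(mu == mu[0]):
        tau, p = None, None
        note = "constant input: sigma-mu correlation undefined"
    else:
        tau_, p_ = stats.kendalltau(sig, mu)
        tau, p, note = float(tau_), float(p_), None
    table = included.assign(flagged=flags)
    return QCReport(table=table, n_flagged=int(flags.sum()),
                    summary=dict(sigma_threshold=float(sigma_thresh),
                                 sigma_mu_tau=tau, sigma_mu_p=p, note=note))
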