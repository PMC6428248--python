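"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: standard canonical double-gamma parameters: response peak 6 s,
#: undershoot peak 16 s, unit dispersions, 6:1 peak-to-undershoot ratio
DEFAULT_HRF_PARAMS = dict(peak_delay=6.0, undershoot_delay=16.0,
                          peak_dispersion=1.0, undershoot_dispersion=1.0,
                          ratio=6.0)


@dataclass(frozen=True)
class HRFKernel:
    """Sampled hemodynamic impulse response, peak-normalized to 1."""

    sample_times: np.ndarray
    values: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def tr(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])


def canonical_hrf(tr: float, duration: float = 32.0,
                  **params: float) -> HRFKernel:
    """Canonical double-gamma HRF sampled every ``tr`` seconds.

    The kernel is the difference of two gamma densities (peak at ~5 s,
    undershoot at ~15 s, 6:1 amplitude ratio) over a 32-s support,
    normalized to unit peak.  ``duration`` shorter than 16 s would truncate
    the undershoot and is rejected.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < 16.0:
        raise ValueError("kernel support shorter than 16 s truncates the "
                         "undershoot")
    p = dict(DEFAULT_HRF_PARAMS, **params)
    t = np.arange(0.0, duration + tr / 2, tr)
    peak = stats.gamma.pdf(t, p["peak_delay"] / p["peak_dispersion"],
                           scale=p["peak_dispersion"])
    under = stats.gamma.pdf(t, p["undershoot_delay"] / p["undershoot_dispersion"],
                            scale=p["undershoot_dispersion"])
    values = peak - under / p["ratio"]
    values = values / values.max()
    return HRFKernel(sample_times=t, values=values, params=p)
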