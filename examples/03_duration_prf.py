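"""Fit the 1-D duration population receptive field model and recover the
planted tuning parameters.

Each voxel's predicted response is the overlap of a Gaussian over
duration (preferred duration mu, spread sigma) with the presented-duration
profile, convolved with the canonical HRF; fitting is a grid search plus
Nelder-Mead refinement, keeping voxels with R^2 > 0.1.
"""

import numpy as np

from chronomap import build_exp2_design, make_truth_chronomap, simulate_bold
from chronomap.prf import prf_map

ev_asc, sc_asc = build_exp2_design("ascending", 10, seed=3)
ev_desc, sc_desc = build_exp2_design("descending", 10, seed=4)
truth = make_truth_chronomap(shape=(10, 10, 1), duration_range=(0.2, 3.0),
                             sigma_star=0.5, seed=5)
bolds = [simulate_bold(truth, ev, sc, include_s2=False)
         for ev, sc in ((ev_asc, sc_asc), (ev_desc, sc_desc))]
labels, mu, sigma, r2 = prf_map(bolds, np.ones(truth.shape, bool),
                                [ev_asc, ev_desc], [sc_asc, sc_desc])
err = np.abs(mu - truth.mu_star)
print(f"included {int(labels.labeled.sum())}/{mu.size} voxels (R^2 > 0.1)")
print(f"median |mu_hat - mu*| = {np.median(err):.2e} s, "
      f"median sigma_hat = {np.nanmedian(sigma):.3f} s "
      f"(planted sigma* = 0.5 s), min R^2 = {np.nanmin(r2):.4f}")
print("Noise-free recovery is exact up to the optimizer tolerance because "
      "the generator and the model share the offset-locked convention.")
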