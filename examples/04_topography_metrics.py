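"""Quantify the spatial progression of a duration-preference map and test
it across a cohort of simulated subjects.

The weighted relative distance (wRD) of each duration cluster from the
posterior border should decrease with preferred duration when the map is
chronotopic; a one-sided signed-rank test across subjects rejects a zero
slope.
"""

from chronomap.pipeline import cohort_slope_test, simulate_subject_labelmap
from chronomap.topography import (fit_wrd_slope, preferred_duration_profile,
                                  weighted_centroids, wrd_by_label)

labels, truth = simulate_subject_labelmap(seed=21, shape=(16, 10, 2))
geom = truth.geometry()
wrd = wrd_by_label(labels, geom)
print("wRD from the posterior border, by preferred duration:")
for dur, val in sorted(wrd.items()):
    print(f"  {dur:.1f} s -> wRD = {val:.4f}")
slopes = fit_wrd_slope(wrd.items(), split_at=1.0)
print(f"slope per duration rank: {slopes.slope_rank:+.4f} "
      "(negative = shorter durations sit farther from the posterior border)")

rd, pd_ = preferred_duration_profile(labels, geom)
print(f"preferred-duration profile ({len(pd_)} reduced bins): "
      + ", ".join(f"{r:.2f}->{p:.2f}s" for r, p in zip(rd, pd_)))
cents = weighted_centroids(labels)
print("weighted centroids (mm along the progression axis):",
      {f"{d:g}s": round(float(c.position_mm[0]), 2)
       for d, c in sorted(cents.items())})

test, cohort_slopes = cohort_slope_test(n_subjects=10, seed=99)
print(f"cohort of 10 subjects: signed-rank p = {test.p_value:.4g} "
      f"({test.n_used} slopes, alternative '{test.alternative}')")
print("p < 0.05 confirms a consistent negative wRD slope, i.e. a "
      "chronotopic progression across the cohort.")
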