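"""Build the two stimulus designs and check their printed arithmetic.

The slow event-related design presents 4 first-stimulus durations x 4
orientations once per run; the cyclic design presents ten duration pairs
(standard T, comparison 1.5 T) in 44-s cycles, which together expose 17
unique first-stimulus durations.
"""

from chronomap import (build_exp1_design, build_exp2_design,
                       enumerate_s1_durations)

runs = build_exp1_design(n_runs=18, seed=1)
events, scan = runs[0]
print(f"event-related design: {len(runs)} runs x {scan.n_volumes} volumes "
      f"@ {scan.tr} s -> {sum(s.n_volumes for _, s in runs)} volumes total")
print(f"  first run: {(events.role == 'S1').sum()} trials, S1 durations "
      f"{sorted(map(float, events[events.role == 'S1'].duration_label.unique()))}")

events2, scan2 = build_exp2_design("ascending", n_cycles=10, seed=1)
durations = enumerate_s1_durations(events2)
print(f"cyclic design: {scan2.n_volumes} volumes @ {scan2.tr} s, "
      f"{events2['cycle'].nunique()} cycles of 44 s")
print(f"  {len(durations)} unique S1 durations: {list(map(float, durations))}")
print("Each count above is fixed by the paradigm itself; the 17 durations "
      "arise because comparisons (1.5 T) interleave with standards (T).")
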