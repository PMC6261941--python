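"""Generate one participant's flanker session and summarise behaviour.

Builds the counterbalanced 1088-trial design, simulates it with the
multistage diffusion generator (post-error boundary increase, drift
decrease and flanker suppression are on by default), and prints accuracy,
median RT, the interference effect and the three post-error summaries.
"""

from flankerddm import (GeneratorSpec, generate_behavior,
                        generate_task_design, posterror_summaries)

design = generate_task_design(1088, seed=1)
beh = generate_behavior(design, GeneratorSpec(seed=1))

ok = ~beh["miss"]
cong = beh[ok & beh["congruent"]]
incong = beh[ok & ~beh["congruent"]]
interference = (incong.loc[incong["correct"], "rt_ms"].median()
                - cong.loc[cong["correct"], "rt_ms"].median())

print(f"trials: {len(beh)}, misses: {int(beh['miss'].sum())}")
print(f"accuracy  congruent: {cong['correct'].mean():.3f}   "
      f"incongruent: {incong['correct'].mean():.3f}")
print(f"median RT congruent: {cong.loc[cong['correct'], 'rt_ms'].median():.0f} ms   "
      f"incongruent: {incong.loc[incong['correct'], 'rt_ms'].median():.0f} ms")
print(f"interference effect: {interference:.0f} ms")

s = posterror_summaries(beh)
print(f"post-error slowing (PES): {s.pes_ms:.0f} ms  "
      f"(positive = slower after errors)")
print(f"post-error interference reduction (PERI): {s.peri_ms:.0f} ms")
print(f"post-error accuracy increase (PIA): {s.pia:.3f}  "
      f"(incongruent trials)")
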