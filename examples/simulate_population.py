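"""Generate a seeded virtual sole population and inspect its calibration.

Builds the default 44-fish market-weight population (body weight truncated
normal on 178.77-456.32 g, allometric lengths, analytic true fillet
volumes) and prints the descriptive statistics the generator is calibrated
to reproduce.
"""

import numpy as np

import filletvol as fv

config = fv.PopulationConfig(seed=7)
population = fv.generate_population(config)
frame = fv.population_to_frame(population)

print(f"{len(population)} virtual fish (seed={config.seed})\n")
for col in ["body_weight_g", "total_length_mm", "fillet_volume_cm3",
            "fillet_yield_pct"]:
    s = fv.summarize(frame[col].to_numpy())
    print(f"{col:20s} mean {s.mean:7.2f}  sd {s.sd:6.2f}  "
          f"range [{s.minimum:7.2f}, {s.maximum:7.2f}]  CV {s.cv:5.1f}%")

v = frame["fillet_volume_cm3"].to_numpy()
print(f"\nMean true fillet volume {v.mean():.2f} cm^3 — the generator is "
      "calibrated so a large population averages ~49.1 cm^3, the published "
      "mean of the real trial; fillet-yield CV ~9.6% mirrors the published "
      "dispersion.")
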