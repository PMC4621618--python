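"""Where in the gonad do germ cells die?  Single-step vs multistep death.

Runs the scripted steady-flow column through the RAS-activation region for
both death mechanisms at full-scale parameters and prints the axial death
histogram.  Single-step death (constant hazard while RAS-active) spreads
deaths evenly along the zone; the multistep mechanism (cells must shrink
through ~8 quanta before dying) concentrates deaths at the bend end --
which is where apoptotic corpses are actually observed, the argument for a
multistep shrinking mechanism.
"""

import numpy as np
from scipy import stats

from germsim.hybrid import preset, zone_transit_experiment

EDGES = np.linspace(0.0, 20.0, 6)      # the RAS zone spans 20 um

for preset_name in ("wildtype", "multistep_death"):
    cfg = preset(preset_name)
    res = zone_transit_experiment(cfg, n_cells=800, zone_length=20.0,
                                  cell_diameter=2.0, transit_time=360000.0,
                                  dt=60.0, seed=2)
    deaths = res["deaths"]
    counts, _ = np.histogram(deaths, bins=EDGES)
    chi2, p = stats.chisquare(counts)
    print(f"{cfg.death_mode:12s}: {len(deaths)} deaths "
          f"({100 * res['fraction_died']:.0f}% of transits), "
          f"mean axial {deaths.mean():.1f} um")
    print(f"  per-fifth counts {counts.tolist()}  "
          f"uniformity chi2={chi2:.1f} p={p:.2e}")
print("\nAxial 0 = distal edge of the RAS zone, 20 = the bend. "
      "Uniform deaths fit the single-step model; the observed pile-up at "
      "the bend fits the multistep (shrink-then-die) model.")
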