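"""Mini friction sweep: outcome of the young model across low mu_s.

Runs a reduced sweep (low end of the friction grid, 2 trials per value)
and prints the outcome table plus the slip threshold mu_s_slip — the
largest friction coefficient at which slip-induced falls still occur.
The full protocol uses the 25-value grid with 5 trials (125 trials per
model); see scripts/acceptance.py for that scale.
"""

import numpy as np

from gaitfall import run_sweep

grid = np.round(np.arange(1, 8) * 0.05, 10)   # 0.05 .. 0.35
sweep = run_sweep("young", trials_per_mu=2, base_seed=1, grid=grid,
                  progress=False)

counts = (sweep.table.groupby(["mu_s", "outcome"]).size()
          .unstack(fill_value=0))
print(counts.to_string())
ms = sweep.mu_s_slip
print(f"\nmu_s_slip = {ms if ms is not None else 'none (no slip falls)'}")
print("below this friction level the model slips and falls after the "
      "friction switch at 5 m; above it the gait survives")
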