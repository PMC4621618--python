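"""Full-scale germline: one founder, 21 simulated days.  SLOW (nightly).

This is the full-size organ run behind the headline emergent numbers: the
gonad fills from a single distal founder to on the order of a thousand
germ cells, the first 150 oocytes reaching maturation are fertilised and
removed (after which the tube blocks), and colouring the population at 3.5
days lets one measure how long a single lineage takes to dominate the
distal tip (of order two to three weeks -- thermal mixing of the mitotic
pool is what delays clonal dominance).

Expect many hours of wall time on one CPU; run it as a batch job:

    python examples/full_run.py --seed 1 --out scratch/full_run
"""

import argparse
import json
from pathlib import Path

from germsim.hybrid import System, preset, write_events_ndjson, zone_contains
from germsim.lineage import LineageTree

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("scratch/full_run"))
parser.add_argument("--days", type=float, default=21.0)
args = parser.parse_args()

config = preset("wildtype", seed=args.seed,
                duration=args.days * 86400.0, init="founder",
                trajectory_interval=3600.0)
system = System(config)
system.run(progress=True)

args.out.mkdir(parents=True, exist_ok=True)
events = system.events_dataframe()
write_events_ndjson(events, args.out / "events.ndjson")
system.trajectory_dataframe().to_csv(args.out / "trajectory.csv", index=False)

tree = LineageTree.from_events(events, run_end=system.clock)
(args.out / "lineage.nwk").write_text(tree.to_newick() + "\n")

t_color = 3.5 * 86400.0
delta = config.zone_for("DELTA")
dominance = tree.distal_tip_dominance_time(
    system.trajectory_dataframe(), lambda pos: zone_contains(delta, pos),
    t_color)
summary = dict(
    final_cells=system.n_cells,
    fertilizations=system.fert_count,
    generation_separation=tree.max_generation_separation(system.clock * 0.99),
    dominance_days=(dominance / 86400.0 if dominance else None),
)
(args.out / "summary.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
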