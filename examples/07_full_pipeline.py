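"""The whole analysis in one call: profiling through network inference.

Writes every stage table plus a machine-readable report.json under out/;
rerunning with the same config reproduces the report byte for byte.
"""

import json
import tempfile
from pathlib import Path

from pcnsl_immune import RSFParams, RunConfig, SimulationConfig, run_pipeline, simulate_cohort

cohort, _ = simulate_cohort(SimulationConfig(n_samples=100, beta=1.0, seed=61))

out = Path(tempfile.mkdtemp()) / "run"
cfg = RunConfig(out_dir=out, seed=61, rsf_params=RSFParams(n_trees=20, seed=61),
                n_cutoff_variants=3)
report = run_pipeline(cfg, cohort=cohort)

print("Stages completed:", ", ".join(report["stages"]))
print("\nMedian-split hazard ratios per panel score:")
for name, payload in report["stages"]["median_split_survival"].items():
    lo, hi = payload["ci95"]
    print(f"  {name:12} HR = {payload['hr']:.2f} ({lo:.2f}-{hi:.2f}), "
          f"log-rank p = {payload['logrank_p']:.3f}")

quad = report["stages"]["quadrants"]
print("\nQuadrant counts:", quad["counts"])
net = report["stages"]["network"]
print(f"Network: {net['n_edges']} edges, rho = {net['rho']}, hubs = {len(net['hubs'])}")

print("\nOutputs written to", out)
print(json.dumps(sorted(p.name for p in out.iterdir()), indent=2))
print("\nThe planted Inhibitory-score hazard surfaces as the largest HR above;")
print("report.json records every seed and threshold for exact reproduction.")
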