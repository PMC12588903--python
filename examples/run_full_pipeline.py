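"""Run the full evaluation pipeline end-to-end on synthetic data.

Executes qualification, chemometric classification, dose-response tiering,
marker selection, combination analysis and chromaticity correlation in one
call, writing one artifact per stage plus a manifest with content hashes
(fixed seed => byte-identical rerun).
"""

import json
from pathlib import Path

from pmtox import PipelineConfig, run_pipeline

out_dir = Path("scratch/pipeline_demo")
cfg = PipelineConfig(out_dir=out_dir, seed=1, n_permutations=200)
manifest = run_pipeline(cfg)

print(f"pipeline wrote {len(manifest['artifacts'])} artifacts to {out_dir}:")
for name, info in manifest["artifacts"].items():
    print(f"  {name:<24s} {info['path']}")

diag = json.loads((out_dir / "oplsda_diagnostics.json").read_text())
print(f"\nOPLS-DA ({diag['groups'][0]} vs {diag['groups'][1]}): "
      f"R2Y={diag['r2y']:.3f} Q2={diag['q2']:.3f}, "
      f"permutation valid={diag['permutation_valid']}")
tiers = (out_dir / "toxicity_tiers.csv").read_text().strip().splitlines()
print("\ntoxicity tiers per group (group, IC50, tier):")
for line in tiers[1:]:
    g, ic50, _, _, _, tier = line.split(",")
    print(f"  group {g}: IC50 {float(ic50):.0f} ug/mL -> {tier}")
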