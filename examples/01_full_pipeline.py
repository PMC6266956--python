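"""Run the six-stage switch-gene pipeline on a simulated two-condition dataset.

The simulated matrix plants three co-expressed modules (up-regulated in
condition A) and 20 down-regulated regulators anti-correlated with
module 1 — the signature switch genes carry.  The pipeline should
rediscover those regulators from the expression values alone.
"""

import tempfile
from pathlib import Path

from swimnet import PipelineConfig, run_pipeline
from swimnet.synthetic import SimulationConfig, generate_expression

config = SimulationConfig(seed=1)
matrix, truth = generate_expression(config)
outdir = Path(tempfile.mkdtemp(prefix="swim_run_"))

summary = run_pipeline(PipelineConfig(seed=1), matrix, outdir)

print(f"outputs written to {outdir}\n")
for key, value in summary["counts"].items():
    print(f"{key:>18} = {value}")

regulators = set(truth.loc[truth["is_regulator"], "gene_id"])
found = set(summary["switch_genes"])
print(f"\nplanted regulators recovered: {len(found & regulators)}/{len(regulators)}")
print(f"false switch calls:           {len(found - regulators)}")
print(
    "\nEach switch gene is a fight-club hub (negative APCC) in region R4 "
    "(z_g < 2.5, K_pi > 0.8): a node anti-correlated with its neighbors "
    "that links mostly outside its own module — the profile of a repressed "
    "master regulator of the condition transition."
)
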