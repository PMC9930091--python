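"""End-to-end demo: phantoms for both formulations, full report bundle.

Runs the complete pipeline (tube + brain phantoms for the low- and high-
concentration formulations, calibration, T1 mapping, segmentation, release
kinetics, mesh size, IVIVR) and prints the summary. Writes CSV tables and
summary.json under ./gelmri_demo_out. Takes a few minutes on one CPU.

Equivalent shell command:  gelmri run-all --outdir gelmri_demo_out --seed 1
"""

import json

from gelmri.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(outdir="gelmri_demo_out", seed=1, make_plots=True)
summary = run_pipeline(config)

print(json.dumps({k: v for k, v in summary.items() if k != "results"}, indent=2))
print("\nTables and plots written to", config.outdir)
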