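"""Run the whole pipeline on a simulated study, end to end.

preprocess -> topics -> regress -> kano -> report, one seed throughout;
all artifacts land in ./pipeline_demo with a digest manifest.
"""

import json
from pathlib import Path

import numpy as np

from kanosat.pipeline import PipelineConfig, run_pipeline
from kanosat.simulate import GeneratorConfig, generate_full_study

sat_vec = np.array([0.1, 0.1] + [0.9] * 10)  # themes 0-1 planted as dissatisfiers
gen = GeneratorConfig(n_docs=4000, vocab_size=500, doc_length_mean=40,
                      topic_separation=0.9, satisfaction_prob=sat_vec, seed=2)
dataset, truth = generate_full_study(gen)

config = PipelineConfig(out_dir="pipeline_demo", seed=2, k=12,
                        n_iterations=200, burn_in=100, min_doc_freq=2)
manifest = run_pipeline(config, dataset=dataset)

for stage in manifest["stages"]:
    print(f"{stage['stage']:<11} {stage['seconds']:>6.2f}s  "
          f"{', '.join(stage['outputs'])}")
out = Path("pipeline_demo")
print("\nkano counts :", json.loads((out / "kano_counts.json").read_text()))
print("summary     :", json.loads((out / "summary.json").read_text()))
# The kano counts should recover the planted 2-dissatisfier /
# 10-satisfier structure (at this reduced n, occasionally one theme
# lands in 'unclassified'; the tested n=20,000 run is exact).
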