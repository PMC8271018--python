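"""Run the end-to-end pipeline on synthetic data via the orchestration API.

Equivalent to `hubwire run --seed 1 --out demo_run` with a small config;
every stage writes tidy TSVs and a provenance manifest under the run
directory.
"""

import json

from hubwire.pipeline import RunConfig, run_pipeline

config = RunConfig(
    out_dir="demo_run",
    seed=1,
    options={
        "simulate": {"n_nodes": 60, "n_subjects": 10},
        "connectome": {"density": 0.15},
        "richclub": {"n_null": 50},
        "herit": {"max_edges": 20, "n_mz_pairs": 60, "n_dz_pairs": 40,
                  "n_mz_sibs": 30, "n_dz_sibs": 20, "models": ["AE", "CE", "E"]},
        "cge": {"n_genes": 150},
        "enrich": {"n_iter": 1000, "n_random_sets": 15},
        "optimize": {"n_per_round": 10, "n_rounds": 3},
    },
)
ctx = run_pipeline(config)
print(json.dumps(ctx["summary"], indent=2))
print(
    "\nOutputs (curves, fits, manifest with seeds and file digests) are "
    "under demo_run/; rerunning with the same seed reproduces them byte "
    "for byte."
)
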