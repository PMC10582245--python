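"""Discriminate clones of one cultivar from a diverged cultivar.

Simulates a small cohort — two clone samples of cultivar A plus one sample
of cultivar B at 1% per-base divergence, each sequenced as two PCR
duplicates — then runs the full pipeline (stringent filter, reference
construction, exact-matching-rate comparison) and prints the similarity
matrix and group summaries.
"""

import tempfile

from idnaseq import FilterConfig
from idnaseq.pipeline import run_pipeline
from idnaseq.simulate import CultivarNode, SampleSpec, SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_loci=150,
    cultivar_tree=[CultivarNode("A"), CultivarNode("B", "A", 0.01)],
    samples=[
        SampleSpec("A-garden1", "A"),
        SampleSpec("A-garden2", "A"),
        SampleSpec("B-1", "B"),
    ],
    depth_mean=25.0,
    rng_seed=42,
)

with tempfile.TemporaryDirectory() as tmp:
    manifest, _ = simulate_cohort(config, f"{tmp}/sim")
    matrix, summaries = run_pipeline(
        manifest,
        FilterConfig(adapters=(config.adapter,)),
        f"{tmp}/out",
        heatmap=False,
    )
    print("similarity matrix (rows = query, columns = target):")
    print(matrix.to_frame().round(3).to_string())
    print()
    for s in summaries:
        print(f"{s.group:20s} n={s.n_pairs:2d} mean={s.mean:.3f} sd={s.sd:.3f}")

print()
print("Clone pairs score ~1.0 (every reference read of one clone is seen in")
print("the other); the diverged cultivar scores far lower — only loci with")
print("no substitution over the 150 sequenced bases can match exactly.")
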