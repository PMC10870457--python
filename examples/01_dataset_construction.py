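"""Build a benchmark dataset from proteins + site annotations.

Generates a small synthetic proteome with planted crotonylation sites,
extracts a 29-mer window around every lysine of the annotated proteins,
removes redundant windows (>40% identity), and makes the species-stratified
7:3 train/test split.
"""

from kcrnet import (
    GeneratorConfig,
    build_samples,
    deduplicate,
    generate,
    species_stratified_split,
)

proteins, annotations, truth = generate(GeneratorConfig(n_proteins=100, seed=7))
samples = build_samples(proteins, annotations)
kept = deduplicate(samples, identity_threshold=0.40)
split = species_stratified_split(kept, ratio=0.7, seed=7)

n_pos = sum(s.label for s in kept)
print(f"proteins: {len(proteins)}  annotated Kcr sites: {len(annotations)}")
print(f"windows: {len(samples)}  after dedup: {len(kept)} ({n_pos} positive)")
print(f"train: {len(split.train)}  test: {len(split.test)}")
print(f"example window: {kept[0].window}  label={kept[0].label}  species={kept[0].species}")
# Every window is 29 residues with the candidate K at the center; the label
# marks whether that exact (protein, position) pair was an annotated site.
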