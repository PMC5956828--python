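"""Generate the synthetic study conditions: a labeled reference set of
feature-space clusters, one tumor slide and one never-trained novel slide.

The reference emulates what a fine-tuned classifier's hidden layer produces
for its training tiles: one isotropic Gaussian cluster per tissue class,
every pair of cluster means at least 10 within-class standard deviations
apart. Each slide is a mixture of lesional tiles (one tumor cluster) and
non-lesional background tiles, with per-tile class probabilities derived
from the same geometry.
"""

import embedclass as ec

config = ec.FixtureConfig(tiles_per_class_range=(60, 60), seed=3)
reference = ec.make_reference_set(config)
print(f"reference set: {len(reference)} tiles, "
      f"{reference['label'].nunique()} classes, "
      f"{len([c for c in reference.columns if c.startswith('f')])}-d features")

slide = ec.make_slide(config, truth_class=8, n_lesional=60, n_background=20, seed=11)
gated = [t for t in slide.tiles if t.p_lesional > 0.85]
print(f"tumor slide '{slide.slide_id}': truth={slide.truth_class}, "
      f"{len(slide.tiles)} tiles of which {len(gated)} read as lesional (>85%)")

novel = ec.make_novel_slide(config, n_tiles=60, seed=12)
gated_novel = [t for t in novel.tiles if t.p_lesional > 0.85]
print(f"novel slide '{novel.slide_id}': truth={novel.truth_class}, "
      f"{len(gated_novel)}/{len(novel.tiles)} tiles read as lesional")
print("the novel tumor passes the lesional gate yet belongs to no trained class —")
print("exactly the open-set case the map-based classifier must flag, not misdiagnose")
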