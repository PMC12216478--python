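"""Extract and fuse features from the three CNN backbone families.

Each backbone maps an image to its global-average-pooled activations;
fusion concatenates the three vectors into one representation.
"""

from dermpipe.features import FeatureScaler, default_backbones, extract_fused, fuse
from dermpipe.synthetic import DatasetSpec, generate_dataset

dataset = generate_dataset(DatasetSpec(n_classes=3, class_counts=(5, 5, 5), seed=0))
backbones = default_backbones(seed=0, input_size=64)
for bb in backbones:
    vec = bb.extract(dataset[0].image)
    print(f"{bb.spec.family:22s} -> {len(vec):3d} features")

fused = fuse([bb.extract(dataset[0].image) for bb in backbones])
print(f"{'fused':22s} -> {len(fused):3d} features (sum of the three)")

matrix = extract_fused(backbones, [d.image for d in dataset])
z = FeatureScaler().fit_transform(matrix)
print(f"feature matrix {matrix.shape}; standardized per-feature mean "
      f"{z.mean():.2e}, variance {z.var(axis=0).mean():.3f}")
# The standardized fused matrix is what the conditional-VAE classifier consumes.
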