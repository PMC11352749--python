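"""Conditional-GAN augmentation validated by a denoising autoencoder.

Trains the fidelity autoencoder on a quarter of the real training set,
trains the conditional GAN with the autoencoder attached, then samples
class-labelled synthetic subjects and inspects how real they look.
"""

import numpy as np

from fcgan import (AeSpec, CganSpec, FixtureConfig, extract_features,
                   fidelity_score, generate_synthetic, make_dataset,
                   stratified_split, train_autoencoder, train_cgan)

series, pheno = make_dataset(FixtureConfig(seed=7))
features = extract_features(series, pheno)
plan = stratified_split(features, test_fraction=0.3, seed=7)
train = features.subset_by_ids(plan.members("train"))
print(f"training set: {len(train)} subjects x {train.dim} features")

# desk-scale profile: widths at 1% of the full-scale architecture
ae = train_autoencoder(train, AeSpec(feature_dim=train.dim, scale=0.01,
                                     epochs=300, seed=7))
print(f"autoencoder loss: {ae.loss_trace[0]:.4f} (first epoch) -> "
      f"{ae.loss_trace[-1]:.4f} (last)")

cgan = train_cgan(train, CganSpec(feature_dim=train.dim, scale=0.01,
                                  epochs=300, seed=7), ae=ae)
print(f"generated-batch fidelity (reconstruction error through the AE): "
      f"{cgan.fidelity_trace[0]:.4f} (epoch 1) -> {cgan.fidelity_trace[-1]:.4f}"
      f" (final); lower = closer to the real distribution")

synth = generate_synthetic(cgan, n_per_class=1000, seed=7)
print(f"sampled {len(synth)} synthetic subjects "
      f"({synth.labels.count('ASD')} ASD / {synth.labels.count('HC')} HC)")

rng = np.random.default_rng(0)
noise = rng.uniform(-1, 1, size=(500, train.dim))
print(f"fidelity: real train {fidelity_score(ae, train):.4f} | "
      f"synthetic {fidelity_score(ae, synth):.4f} | "
      f"uniform noise {fidelity_score(ae, noise):.4f}")

# class conditioning: each synthetic class centroid should sit nearer the
# matching real class centroid
y_real, y_syn = train.label_ints(), synth.label_ints()
for cls, name in ((0, "HC"), (1, "ASD")):
    c_syn = synth.values[y_syn == cls].mean(axis=0)
    d_same = np.linalg.norm(c_syn - train.values[y_real == cls].mean(axis=0))
    d_other = np.linalg.norm(c_syn - train.values[y_real != cls].mean(axis=0))
    print(f"{name} centroid: {d_same:.3f} to matching class, "
          f"{d_other:.3f} to the other ({'ok' if d_same < d_other else 'off'})")
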