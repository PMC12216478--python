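"""Train the conditional VAE on class-separated features and classify.

The classifier evaluates the CVAE objective (reconstruction + KL) under
every candidate class and picks the argmin — the class under which the
observed features are most probable.
"""

import numpy as np

from dermpipe.cvae import CVAE, CVAEConfig

rng = np.random.default_rng(3)
k, n, d = 3, 300, 8
means = rng.normal(0, 4.0, (k, d))
y = np.repeat(np.arange(k), n // k)
x = means[y] + rng.normal(0, 1.0, (n, d))
idx = np.random.default_rng(0).permutation(n)
train, test = idx[:240], idx[240:]

model = CVAE(d, k, CVAEConfig(latent_dim=4, hidden_dim=32, epochs=50, seed=0))
history = model.fit(x[train], y[train])
print(f"training loss: {history[0]['total']:.2f} (epoch 1) -> "
      f"{history[-1]['total']:.2f} (epoch {len(history)})")

label, scores = model.classify(x[test[0]])
print(f"one held-out sample: per-class objectives {np.round(scores, 2)} "
      f"-> class {label} (true {y[test[0]]})")

acc = (model.predict(x[test]) == y[test]).mean()
print(f"held-out accuracy on {len(test)} samples: {acc:.3f}")
# Lower objective = better fit; with well-separated classes the argmin rule
# recovers the labels almost perfectly.
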