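"""Tune CVAE hyperparameters with the hippopotamus optimizer.

The optimizer searches (log10 learning rate, latent dim, batch size,
dropout) minimizing minus the validation macro precision; the default
configuration is always evaluated too, so the result never regresses.
"""

from dermpipe.pipeline import PipelineConfig, tune_hyperparameters

config = PipelineConfig(
    seed=3,
    input_size=32,
    ho_pop_size=6,
    ho_max_iter=4,
    tune_epochs=10,
    dataset={"count_factor": 0.05, "image_size": 32},
)
out = tune_hyperparameters(config, verbose=True)

print(f"\ndefault validation macro precision: {out['default_validation_precision']:.3f}")
print(f"tuned   validation macro precision: {out['validation_precision']:.3f}")
print(f"fitness evaluations used: {out['n_evaluations']}")
print("\nsearch trace (best objective = minus precision, non-increasing):")
print(out["trace"].to_string(index=False))
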