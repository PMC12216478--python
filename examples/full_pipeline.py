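"""Run the whole privacy-preserving classification pipeline on synthetic data.

Generates an imbalanced 9-class synthetic lesion dataset, encrypts and
decrypts every image (verifying the bit-exact round trip), extracts fused
backbone features, trains the conditional VAE, and reports per-class and
macro metrics on 80:20 and 70:30 stratified splits.
"""

from dermpipe.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(seed=7)
result = run_pipeline(config, verbose=True)

print("\nmacro metrics (%, per split and phase):")
print(result.summary().to_string())
# "accuracy" is the one-vs-rest per-class accuracy averaged over classes, so
# it sits high even when precision/recall show room; macro F-measure is the
# balanced summary to watch.  Rerunning with the same seed reproduces this
# table bit for bit.
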