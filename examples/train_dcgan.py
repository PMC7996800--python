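"""Train a desk-scale DCGAN on one synthetic class and dump milestone grids.

Trains the adversarial pair on the non-cancer class only (one GAN per class is
the intended usage) for 50 epochs at reduced channel widths, writing a 16-image
sample grid at epochs 10/25/50 plus the per-epoch loss history CSV under
./scratch_gan_demo.  The printed losses are cross-entropies in nats: at the
adversarial equilibrium the generator loss approaches ln 2 ~ 0.69 and the
total discriminator loss approaches 2 ln 2 ~ 1.39.
"""

import numpy as np

from cystaug import GanTrainConfig, SyntheticDatasetConfig, generate_dataset, train_gan
from cystaug.gan import DESK_GEN_CHANNELS

dataset = generate_dataset(
    SyntheticDatasetConfig(per_class_counts=(90, 0, 0, 0), master_seed=1)
)
non_cancer = dataset.subset(np.flatnonzero(dataset.labels == 0))

config = GanTrainConfig(
    epochs=50, batch_size=32, channels=DESK_GEN_CHANNELS, seed=0, milestones=(10, 25, 50)
)
generator, history = train_gan(non_cancer, config, out_dir="scratch_gan_demo")

print(history.tail(5).round(3).to_string(index=False))
samples = generator.generate(8, seed=7)
print(f"\ngenerated {samples.shape[0]} images, "
      f"mean pixel {samples.mean():.3f} (real data mean {non_cancer.images.mean():.3f})")
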