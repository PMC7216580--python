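"""Train a reduced conditional VAE and generate methylomes per cancer type.

The full-scale architecture (500/250 hidden nodes, 125 latent variables,
10,000 epochs) targets 10,000-CpG chunks of a real 450K matrix; here a
scaled-down configuration trains in seconds on a 200-CpG synthetic
fixture.  After training, changing only the condition fed to the decoder
steers generation toward that cancer type's methylation profile.
"""

import numpy as np

import methgen as mg

spec = mg.SyntheticSpec(
    n_conditions=4, n_cpgs=200, n_samples_per_condition=150,
    mean_separation=0.3, seed=42,
)
matrix, labels, truth = mg.generate_ground_truth(spec)

config = mg.CVAEConfig(
    encoder_hidden=(64, 32),  # full scale: (500, 250)
    latent_dim=16,            # full scale: 125
    learning_rate=1e-3,
    epochs=500,               # full scale: 10000
    batch_size=50,
    seed=42,
)
state = mg.train_cvae(mg.chunk_cpgs(matrix, 10000), labels, config)
trace = state.loss_traces[0]
print(f"negative ELBO per sample: {trace[0]:.1f} (epoch 1) -> "
      f"{trace[-1]:.1f} (epoch {len(trace)})")

for cond in labels.vocabulary:
    generated = mg.generate(state, cond, n_samples=100, seed=7)
    gmean = generated.values.mean(axis=0)
    true = truth.params_for(cond)
    tmean = (true["alpha"] / (true["alpha"] + true["beta"])).to_numpy()
    print(f"{cond}: mean abs error of generated per-CpG means vs truth = "
          f"{np.abs(gmean - tmean).mean():.3f}")
print("(errors well below the 0.3 between-condition separation mean the")
print(" model generates the requested type, not a generic average)")
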