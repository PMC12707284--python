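"""Train the desk-scale trunk on the toy world, then design sequences.

The toy world ties each residue's amino acid to its local backbone geometry
through a fixed descriptor table, so a model that reads the structure can in
principle recover every position.  We train briefly, then sample sequences
for a held-out backbone with the 10-step flow sampler and report how many
native positions each design recovers (chance level: 0.05).
"""

from backflow.design_metrics import sequence_recovery
from backflow.flow import SamplerConfig, design_sequences
from backflow.synthetic_data import ToyWorldConfig, make_toy_backbone, make_toy_dataset
from backflow.training import TrainConfig, train
from backflow.trunk import TrunkConfig, TrunkModel

data = make_toy_dataset(120, ToyWorldConfig(), seed=11)
model = TrunkModel(TrunkConfig.toy(seed=5))
result = train(model, data, TrainConfig(max_steps=150, seed=7))
print(f"training loss: {result.loss_curve[0]:.3f} -> {result.loss_curve[-1]:.3f} "
      f"(uniform baseline ln 20 = 3.00)")

held_out = make_toy_backbone(40, "hairpin", seed=999)
cfg = SamplerConfig(n_steps=10, temperature=0.1, seed=1)
designs = design_sequences(held_out, model, 3, cfg)
print(f"native: {held_out.sequence}")
for seq, score in zip(designs.sequences, designs.scores):
    rec = sequence_recovery(seq, held_out.sequence)
    print(f"design: {seq}  recovery={rec:.2f}  mean_logp={score:.2f}")
# each design is produced in 10 parallel unmasking steps regardless of length;
# recovery near 1.0 means the model has learned the geometry->sequence rule
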