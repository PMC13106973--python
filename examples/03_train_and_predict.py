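"""Train the network on synthetic complexes and predict.

A deliberately small demonstration: two-phase training (affinity + FAPE +
torsion losses, then violation fine-tuning) on 8 toy records, followed by
prediction — an affinity score, a binder call, and an all-atom peptide
model.  Runs in a few minutes on one CPU.
"""

import numpy as np

from pmhcnet import fixtures as fx
from pmhcnet import training as tr
from pmhcnet.network import Model, ModelConfig

train = fx.make_toy_dataset(8, fx.FixtureSpec(seed=11))
model = Model(ModelConfig(seed=0, mhc_blocks=1, cross_blocks=2, pep_blocks=2))
config = tr.TrainConfig(seed=0, max_epochs_phase1=500, max_epochs_phase2=500)

# overfit protocol: the validation stream is the training set itself
model = tr.fit(model, train, train, config, check_disjoint=False)

rmsds = [tr.ca_rmsd_to_truth(model, b) for b in train]
mses = [(model.predict(b).score - b.affinity) ** 2 for b in train]
print(f"training-set mean peptide CA-RMSD: {np.mean(rmsds):.2f} A "
      f"(started near 9 A: the peptide initializes at the groove center)")
print(f"training-set affinity MSE: {np.mean(mses):.4f} on the 0-1 scale")

b = train[0]
res = model.predict(b)
print(f"{b.pep_seq}: score {res.score:.3f} "
      f"({'binder' if res.binder else 'non-binder'}), "
      f"true target {b.affinity:.3f}")
print(f"predicted model: {int(res.atom_mask.sum())} heavy atoms, "
      f"omega angles all near 180 (trans): "
      f"{np.round(res.torsions.angles_deg[1:, 2], 1)}")
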