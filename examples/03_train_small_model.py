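"""Train a small Siamese model on phantoms and watch it learn.

Uses a deliberately tiny setup (16x24x24 hemispheres, 4 features, a few
epochs) so the script finishes in about a minute on one CPU.  The training
recipe is the real one: balanced epochs, random affine+elastic
augmentation of the full volume before splitting, hybrid BCE+CCE loss with
label smoothing, and the warm-up cosine learning-rate schedule.

Run:  python examples/03_train_small_model.py
"""

from collascore import PhantomSpec, generate_dataset
from collascore.network import save_checkpoint
from collascore.pipeline import reduced_backbone
from collascore.training import TrainingConfig, evaluate_accuracy, train_model

spec = PhantomSpec(shape=(16, 24, 24))
train_samples, _ = generate_dataset(n_per_class=8, seed=11, spec=spec)
test_samples, _ = generate_dataset(n_per_class=4, seed=22, spec=spec)

config = TrainingConfig(
    epochs=8,          # full model uses ~100; phantoms converge much faster
    overlap=2,         # hemisphere overlap scaled to this grid
    alpha=0.3,         # 0.7*BCE(dichotomized) + 0.3*CCE(4-class)
    smoothing=0.2,
    eval_every=2,
)

model, log = train_model(
    train_samples,
    config,
    seed=0,
    val_samples=test_samples,
    backbone=reduced_backbone(4),
)

print(log.to_string(index=False))
acc = evaluate_accuracy(model, test_samples, config)
print(f"\nheld-out multiclass accuracy: {acc:.3f} (chance = 0.25)")
print(f"model parameters           : {model.n_parameters()}")

save_checkpoint(model, "small_model.npz", metadata=model.train_metadata)
print("checkpoint written to small_model.npz")
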