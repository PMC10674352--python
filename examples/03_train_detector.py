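"""Train the improved U-Net on a small synthetic benchmark and score it.

Uses a reduced problem (4 scenes of 160x160, width-8 model, 25 epochs) so
the example finishes in well under a minute on a laptop CPU; the full
benchmark lives in `redtidenet.benchmark`.
"""

from redtidenet.evaluation import confusion_on_patches, metrics
from redtidenet.networks import ModelConfig, build_improved_unet
from redtidenet.synthetic import SyntheticSceneParams, generate_benchmark
from redtidenet.training import TrainConfig, train

dataset = generate_benchmark(
    n_train_scenes=3,
    n_test_scenes=1,
    params=SyntheticSceneParams(height=160, width=160),
    seed=7,
)
print(f"dataset: {len(dataset)} patches of "
      f"{dataset.patch_size}x{dataset.patch_size}x{dataset.num_channels} "
      f"({(dataset.split == 'train').sum()} train / {(dataset.split == 'test').sum()} test)")

model = build_improved_unet(ModelConfig(in_channels=7, base_width=8), seed=0)
model, history = train(model, dataset, TrainConfig(epochs=25, batch_size=25, seed=0))
print("validation F1 by epoch:", [round(f, 2) for f in history.val_f1])

report = metrics(confusion_on_patches(model, dataset, split="test")).rounded()
print(f"\nheld-out scene: accuracy {report.accuracy}%, precision {report.precision}%, "
      f"recall {report.recall}%, F1 {report.f1}")
print("Accuracy counts all valid pixels; precision/recall score the red-tide",
      "class; F1 is their harmonic mean on the 0-1 scale.")
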