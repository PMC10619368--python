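"""Leave-one-subject-out transfer with a finetuning-data sweep.

Trains a group model on four of five synthetic subjects and evaluates on the
fifth: zero-shot (fraction 0), and after finetuning on increasing fractions
of the held-out subject's training trials.  Accuracy at fraction 0 shows how
much the group model transfers with no target-subject data; the curve shows
how quickly a little subject-specific data closes the gap.
"""

from groupdecode import (
    GeneratorConfig, TrainConfig, WaveNetConfig, generate_dataset, loso_run,
    standardize_per_channel, stratified_split,
)

seed = 0
dataset, _, _ = generate_dataset(GeneratorConfig(seed=seed))
split = stratified_split(dataset, (4, 1), seed=seed)
dataset, _ = standardize_per_channel(dataset, split.train_indices)

model_config = WaveNetConfig(
    n_channels=24, n_timepoints=128, n_classes=8, n_conv_layers=3,
    fc_hidden=64, embedding_size=10, n_subjects=5, dropout=0.2,
)
group_cfg = TrainConfig(learning_rate=1e-3, batch_size=120, n_epochs=40, seed=seed)
ft_cfg = TrainConfig(learning_rate=1e-3, batch_size=48, n_epochs=15, seed=seed)

table, _ = loso_run(dataset, left_out=4, fractions=[0.0, 0.25, 0.5, 1.0],
                    model_config=model_config, group_config=group_cfg,
                    finetune_config=ft_cfg, split=split)
print("accuracy on the left-out subject (chance 0.125):")
print(table.to_string(index=False))
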