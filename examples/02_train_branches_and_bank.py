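"""Train the 12 per-lead residual branches and cache a multi-level feature bank.

Each lead's branch is a residual network of 17 convolutional basic units
trained as a 7-way classifier (6 MI subcategories + healthy control).  The
bank caches globally averaged activations at the even levels plus the top
level, so the architecture search never has to retrain a branch.
"""

from evombn import generate_beat_dataset
from evombn.branch_network import (DESK_SCHEDULE, DESK_WIDTH_PLAN,
                                   build_feature_bank, train_all_branches)
from evombn.leads import CLASS_ORDER

dataset = generate_beat_dataset(29, CLASS_ORDER, n_patients=21, noise_sd=0.05,
                                seed=11)
print(f"dataset: {len(dataset)} beats, classes {dataset.class_set}")

nets, histories = train_all_branches(dataset, DESK_WIDTH_PLAN, DESK_SCHEDULE,
                                     seed=11)
print(f"trained 12 branches (desk profile: width {DESK_WIDTH_PLAN[0]}, "
      f"{DESK_SCHEDULE.epochs} epochs); lead II loss per epoch: "
      + ", ".join(f"{l:.3f}" for l in histories[1]))
print(f"conv layers per branch: {nets[0].conv_layer_count()}")

bank = build_feature_bank(nets, dataset)
print(f"feature bank: {bank.n_beats} beats x 12 leads x levels {bank.level_set}")
print(f"lead V1 level-17 feature block shape: {bank.get(6, 17).shape}")
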