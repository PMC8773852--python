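"""Per-lead residual 1-D convolutional branches and the cached feature bank.

Each of the 12 leads gets its own branch: a residual network of exactly 17
convolutional *basic units* (convolution -> batch normalization -> ReLU).
Unit 1 is a kernel-7 stem; units 2..17 form 8 residual blocks of two kernel-3
units each, with temporal stride 2 at units 5, 9 and 13 and parameter-free
shortcuts (subsample + zero-padded channels), so a census of convolutional
layers in any built branch is exactly 17.  The activation after any unit
l in 1..17 can be tapped and globally average-pooled to give that lead's
level-l feature vector.

Branches are trained separately, one per lead, as 7-way classifiers (the six
MI subcategories plus HC) purely as a feature-learning strategy; afterwards
their pooled activations at the even levels and the top level are cached in a
:class:`FeatureBank` so that architecture search never retrains a branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import BeatDataset
from .nn import (BatchNorm1d, Conv1d, GlobalAvgPool1d, Linear, ReLU,
                 SGDMomentum, ShortcutA, softmax_weighted_ce)
from .nn.losses import weighted_ce_loss  # noqa: F401  (re-exported: the loss
# is part of this module's training surface)

N_UNITS = 17
#: Levels cached for architecture search: even indices plus the top level.
DEFAULT_LEVEL_SET = (2, 4, 6, 8, 10, 12, 14, 16, 17)
#: Channel widths of the full-scale training profile.
FULL_WIDTH_PLAN = (32,) * 4 + (64,) * 4 + (128,) * 4 + (256,) * 5
#: Slim widths for laptop-scale runs and the test suite.
DESK_WIDTH_PLAN = (16,) * 17
STRIDE_UNITS = (5, 9, 13)


@dataclass
class TrainSchedule:
    """SGD-with-momentum schedule for branch training.

    The full-scale profile is lr0 = 0.1 divided by 10 every 10 epochs,
    momentum 0.9, batch 128, 30 epochs.
    """

    lr0: float = 0.1
    decay_every: int = 10
    momentum: float = 0.9
    batch: int = 128
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if min(self.lr0, self.decay_every, self.momentum, self.batch) <= 0:
            raise ValueError("schedule values must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def lr_at(self, epoch: int) -> float:
        """Learning rate in effect at 0-based ``epoch``."""
        return self.lr0 * 10.0 ** (-(epoch // self.decay_every))


DESK_SCHEDULE = TrainSchedule(lr0=0.05, decay_every=10, momentum=0.9, batch=32, epochs=5)


class _Unit:
    """conv -> BN (ReLU applied by the caller, after any residual add)."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng):
        self.conv = Conv1d(in_ch, out_ch, kernel, stride, rng)
        self.bn = BatchNorm1d(out_ch)

    def forward(self, x, train):
        return self.bn.forward(self.conv.forward(x, train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(dy))

    @property
    def layers(self):
        return [self.conv, self.bn]


class _ResBlock:
    """Two basic units with a shortcut from the block input to the second."""

    def __init__(self, in_ch, ch_a, ch_b, stride_a, stride_b, rng):
        self.unit_a = _Unit(in_ch, ch_a, 3, stride_a, rng)
        self.relu_a = ReLU()
        self.unit_b = _Unit(ch_a, ch_b, 3, stride_b, rng)
        self.shortcut = ShortcutA(in_ch, ch_b, stride_a * stride_b)
        self.relu_b = ReLU()

    def forward(self, x, train):
        a = self.relu_a.forward(self.unit_a.forward(x, train), train)
        b = self.unit_b.forward(a, train)
        out = self.relu_b.forward(b + self.shortcut.forward(x, train), train)
        return a, out  # taps for the block's first and second unit

    def backward(self, dout):
        ds = self.relu_b.backward(dout)
        dx_short = self.shortcut.backward(ds)
        da = self.unit_b.backward(ds)
        dx_main = self.unit_a.backward(self.relu_a.backward(da))
        return dx_main + dx_short

    @property
    def layers(self):
        return self.unit_a.layers + self.unit_b.layers

    @property
    def convs(self):
        return [self.unit_a.conv, self.unit_b.conv]


class BranchNet:
    """One lead's residual branch of 17 basic units plus a training head."""

    def __init__(self, width_plan=DESK_WIDTH_PLAN, n_classes: int = 7, seed: int = 0,
                 stem_kernel: int = 7):
        width_plan = tuple(int(w) for w in width_plan)
        if len(width_plan) != N_UNITS:
            raise ValueError(f"width_plan must have {N_UNITS} entries")
        self.width_plan = width_plan
        self.n_classes = n_classes
        self.seed = seed
        rng = np.random.default_rng(seed)

        self.stem = _Unit(1, width_plan[0], stem_kernel, 1, rng)
        self.stem_relu = ReLU()
        self.blocks = []
        in_ch = width_plan[0]
        for j in range(8):
            ua, ub = 2 + 2 * j, 3 + 2 * j  # 1-based unit indices
            sa = 2 if ua in STRIDE_UNITS else 1
            sb = 2 if ub in STRIDE_UNITS else 1
            blk = _ResBlock(in_ch, width_plan[ua - 1], width_plan[ub - 1], sa, sb, rng)
            self.blocks.append(blk)
            in_ch = width_plan[ub - 1]
        self.gap = GlobalAvgPool1d()
        self.head = Linear(width_plan[-1], n_classes, rng)
        self._taps = None

    # ------------------------------------------------------------- structure
    def conv_layers(self):
        convs = [self.stem.conv]
        for blk in self.blocks:
            convs.extend(blk.convs)
        return convs

    def conv_layer_count(self) -> int:
        return len(self.conv_layers())

    @property
    def layers(self):
        out = self.stem.layers[:]
        for blk in self.blocks:
            out.extend(blk.layers)
        out.append(self.head)
        return out

    # --------------------------------------------------------------- forward
    def forward_units(self, x: np.ndarray, train: bool = False, upto: int = N_UNITS):
        """Activations after units 1..upto; ``x`` is (N, 1, 256)."""
        taps = [self.stem_relu.forward(self.stem.forward(x, train), train)]
        h = taps[0]
        for blk in self.blocks:
            if len(taps) >= upto:
                break
            a, h = blk.forward(h, train)
            taps.extend([a, h])
        return taps[:max(upto, 1)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Class logits from the training head."""
        taps = self.forward_units(x, train)
        self._taps = taps
        pooled = self.gap.forward(taps[-1], train)
        return self.head.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.gap.backward(self.head.backward(dlogits))
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        self.stem.backward(self.stem_relu.backward(d))

    def features(self, x: np.ndarray, level: int) -> np.ndarray:
        """Time-pooled feature after unit ``level`` (eval mode, untrained OK)."""
        if not 1 <= level <= N_UNITS:
            raise ValueError("level must be in 1..17")
        taps = self.forward_units(x, train=False, upto=level)
        return taps[level - 1].mean(axis=2)

    def feature_dim(self, level: int) -> int:
        return self.width_plan[level - 1]

    def param_checksum(self) -> float:
        """Sum of all parameter values; cheap frozen-weights fingerprint."""
        return float(sum(p.sum() for lay in self.layers for p in lay.params.values()))


def build_branch(width_plan=DESK_WIDTH_PLAN, n_classes: int = 7, seed: int = 0) -> BranchNet:
    return BranchNet(width_plan, n_classes, seed)


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency weights: w_i = N_total / (c * N_i).

    Balanced classes give all-ones; rarer classes get strictly larger weights.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 1):
        raise ValueError("every class must have at least one sample")
    return counts.sum() / (counts.size * counts)


def train_branch(net: BranchNet, lead_index: int, dataset: BeatDataset,
                 schedule: TrainSchedule = DESK_SCHEDULE):
    """Train one branch on its lead only, with weighted CE and the SGD schedule.

    Returns ``(net, loss_history)`` where the history holds the mean minibatch
    loss of each epoch.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    classes = tuple(dataset.class_set)
    labels = dataset.labels
    y_idx = np.array([classes.index(l) for l in labels])
    counts = np.array([max(int((y_idx == i).sum()), 1) for i in range(len(classes))])
    w = class_weights(counts)
    x = dataset.X[:, lead_index, :][:, None, :]
    onehot = np.eye(len(classes))[y_idx]

    rng = np.random.default_rng(schedule.seed)
    opt = SGDMomentum(net.layers, lr=schedule.lr0, momentum=schedule.momentum)
    history = []
    n = x.shape[0]
    for epoch in range(schedule.epochs):
        opt.lr = schedule.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, schedule.batch):
            idx = order[start: start + schedule.batch]
            logits = net.forward(x[idx], train=True)
            loss, dz = softmax_weighted_ce(logits, onehot[idx], w)
            net.backward(dz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return net, history


def train_all_branches(dataset: BeatDataset, width_plan=DESK_WIDTH_PLAN,
                       schedule: TrainSchedule = DESK_SCHEDULE, seed: int = 0):
    """Build and train the 12 per-lead branches; returns (nets, histories)."""
    nets, hists = [], []
    n_classes = len(dataset.class_set)
    for lead in range(12):
        net = BranchNet(width_plan, n_classes=n_classes, seed=seed + lead)
        sched = TrainSchedule(schedule.lr0, schedule.decay_every, schedule.momentum,
                              schedule.batch, schedule.epochs, seed=schedule.seed + lead)
        net, h = train_branch(net, lead, dataset, sched)
        nets.append(net)
        hists.append(h)
    return nets, hists


def extract_features(net: BranchNet, dataset: BeatDataset, lead_index: int,
                     level: int, batch: int = 256) -> np.ndarray:
    """Pooled level-``level`` features of one lead for every beat."""
    x = dataset.X[:, lead_index, :][:, None, :]
    chunks = [net.features(x[i: i + batch], level) for i in range(0, x.shape[0], batch)]
    return np.concatenate(chunks, axis=0)


@dataclass
class FeatureBank:
    """Cached per-lead, per-level pooled features for every beat.

    Keyed by ``(lead, level)`` with leads 0..11 in conventional order; aligned
    ``labels`` and ``patient_ids`` allow patient-wise splitting downstream.
    """

    features: dict = field(default_factory=dict)
    labels: np.ndarray = field(default_factory=lambda: np.array([]))
    patient_ids: np.ndarray = field(default_factory=lambda: np.array([]))
    level_set: tuple = DEFAULT_LEVEL_SET
    class_set: tuple = ()

    @property
    def n_beats(self) -> int:
        return len(self.labels)

    def get(self, lead: int, level: int) -> np.ndarray:
        key = (int(lead), int(level))
        if key not in self.features:
            raise KeyError(f"feature bank has no entry for lead {lead}, level {level}")
        return self.features[key]

    def subset(self, mask) -> "FeatureBank":
        idx = np.arange(self.n_beats)[mask]
        return FeatureBank(
            features={k: v[idx] for k, v in self.features.items()},
            labels=self.labels[idx], patient_ids=self.patient_ids[idx],
            level_set=self.level_set, class_set=self.class_set)

    def relabel(self, mapping: dict, class_set: tuple) -> "FeatureBank":
        labels = np.array([mapping.get(l, l) for l in self.labels])
        return FeatureBank(features=self.features, labels=labels,
                           patient_ids=self.patient_ids, level_set=self.level_set,
                           class_set=class_set)

    # ------------------------------------------------------------------ I/O
    def save(self, path) -> None:
        """Persist as compressed arrays plus a JSON manifest."""
        arrays = {f"lead{lead}_level{level}": v
                  for (lead, level), v in self.features.items()}
        manifest = {"level_set": list(self.level_set),
                    "class_set": list(self.class_set),
                    "keys": [[int(l), int(v)] for l, v in self.features]}
        np.savez_compressed(path, labels=self.labels, patient_ids=self.patient_ids,
                            manifest=np.frombuffer(
                                json.dumps(manifest).encode(), dtype=np.uint8),
                            **arrays)

    @classmethod
    def load(cls, path) -> "FeatureBank":
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(bytes(z["manifest"]).decode())
            features = {(l, v): z[f"lead{l}_level{v}"] for l, v in manifest["keys"]}
            return cls(features=features, labels=z["labels"],
                       patient_ids=z["patient_ids"],
                       level_set=tuple(manifest["level_set"]),
                       class_set=tuple(manifest["class_set"]))


def build_feature_bank(nets, dataset: BeatDataset,
                       level_set=DEFAULT_LEVEL_SET, batch: int = 256) -> FeatureBank:
    """Extract and cache features for every (lead, level, beat) triple.

    One forward pass per lead and batch serves all requested levels.
    """
    if len(nets) != 12:
        raise ValueError("need one trained branch per lead (12)")
    level_set = tuple(int(l) for l in level_set)
    feats = {}
    for lead, net in enumerate(nets):
        x = dataset.X[:, lead, :][:, None, :]
        pooled = {lv: [] for lv in level_set}
        for i in range(0, x.shape[0], batch):
            taps = net.forward_units(x[i: i + batch], train=False)
            for lv in level_set:
                pooled[lv].append(taps[lv - 1].mean(axis=2))
        for lv in level_set:
            feats[(lead, lv)] = np.concatenate(pooled[lv], axis=0)
    return FeatureBank(features=feats, labels=dataset.labels,
                       patient_ids=dataset.patient_ids,
                       level_set=tuple(int(l) for l in level_set),
                       class_set=tuple(dataset.class_set))
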