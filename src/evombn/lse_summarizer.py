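"""Lead Squeeze-and-Excitation (LSE) summarizer.

The LSE block fuses the 12 per-lead feature vectors selected by a genome:

* **squeeze** — each lead's pooled feature vector ``y_i`` is averaged to a
  scalar ``u_i``, giving ``u`` in R^12;
* **excite** — two fully-connected layers gate the leads,
  ``e = sigmoid(W2 relu(W1 u))`` with ``W1`` in R^(12/r x 12) and ``W2`` in
  R^(12 x 12/r); the reduction factor defaults to r = 1;
* **scale** — ``o_i = e_i * y_i`` re-weights each lead's features;
* **classify** — a fully-connected layer over the concatenated scaled
  features produces class probabilities (softmax) or a positive-class
  probability (sigmoid, binary mode).

Excitation is computed per beat, so ``e`` is input-dependent attention.
Forcing ``e = 1`` reduces the block exactly to the conventional
concatenation + fully-connected summarizer, which is how the ablation
baseline is realized.  The block is trained with Adam on the weighted
cross-entropy loss; bias terms are zero-initialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .branch_network import FeatureBank, class_weights
from .nn import Adam
from .nn.losses import sigmoid, sigmoid_weighted_ce, softmax, softmax_weighted_ce

N_LEADS = 12


@dataclass
class LSEConfig:
    epochs: int = 30
    batch: int = 32
    lr: float = 1e-2
    r: int = 1
    seed: int = 0
    force_excitation: float | None = None  # 1.0 -> plain concat+FC ablation head

    def __post_init__(self):
        if N_LEADS % self.r != 0:
            raise ValueError("reduction factor r must divide 12")
        if self.epochs < 0 or self.batch < 1 or self.lr <= 0:
            raise ValueError("invalid training configuration")


class LSEModel:
    """Squeeze/excitation weights plus the final fully-connected classifier."""

    def __init__(self, genome, feature_dims, classes, class_mode: str = "multiclass",
                 r: int = 1, seed: int = 0, positive_class: str | None = None):
        if N_LEADS % r != 0:
            raise ValueError("reduction factor r must divide 12")
        if class_mode not in ("multiclass", "binary"):
            raise ValueError("class_mode must be 'multiclass' or 'binary'")
        if len(feature_dims) != N_LEADS:
            raise ValueError("need one feature dimension per lead")
        self.genome = tuple(int(g) for g in genome)
        self.feature_dims = tuple(int(d) for d in feature_dims)
        self.classes = tuple(classes)
        self.class_mode = class_mode
        self.positive_class = positive_class
        self.r = r
        hidden = N_LEADS // r
        d_total = sum(self.feature_dims)
        n_out = 1 if class_mode == "binary" else len(self.classes)
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": rng.normal(0, np.sqrt(2.0 / N_LEADS), size=(hidden, N_LEADS)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0, np.sqrt(2.0 / hidden), size=(N_LEADS, hidden)),
            "b2": np.zeros(N_LEADS),
            "Wc": rng.normal(0, np.sqrt(1.0 / d_total), size=(n_out, d_total)),
            "bc": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._offsets = np.concatenate([[0], np.cumsum(self.feature_dims)])


def squeeze(ys) -> np.ndarray:
    """Per-lead global average: list of 12 (n, d_i) arrays -> (n, 12)."""
    if len(ys) != N_LEADS:
        raise ValueError("expected feature vectors for 12 leads")
    cols = []
    for y in ys:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[1] == 0:
            raise ValueError("cannot squeeze an empty feature vector")
        cols.append(y.mean(axis=1))
    return np.stack(cols, axis=1)


def excite(u: np.ndarray, model: LSEModel) -> np.ndarray:
    """e = sigmoid(W2 relu(W1 u)); componentwise in (0, 1)."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[1] != N_LEADS:
        raise ValueError("u must have 12 components")
    h = np.maximum(u @ model.params["W1"].T + model.params["b1"], 0.0)
    return sigmoid(h @ model.params["W2"].T + model.params["b2"])


def scale(ys, e: np.ndarray):
    """o_i = e_i * y_i, elementwise per lead."""
    e = np.atleast_2d(np.asarray(e, dtype=float))
    if e.shape[1] != N_LEADS:
        raise ValueError("e must have 12 components")
    return [e[:, i: i + 1] * np.atleast_2d(ys[i]) for i in range(N_LEADS)]


def classify(os_, model: LSEModel) -> np.ndarray:
    """Final fully-connected map over the concatenated scaled features."""
    xcat = np.concatenate([np.atleast_2d(o) for o in os_], axis=1)
    if xcat.shape[1] != model._offsets[-1]:
        raise ValueError("concatenated feature length does not match classifier")
    z = xcat @ model.params["Wc"].T + model.params["bc"]
    if model.class_mode == "binary":
        return sigmoid(z[:, 0])
    return softmax(z)


def _forward(model: LSEModel, ys, force_excitation=None):
    u = squeeze(ys)
    if force_excitation is None:
        h_pre = u @ model.params["W1"].T + model.params["b1"]
        h = np.maximum(h_pre, 0.0)
        e = sigmoid(h @ model.params["W2"].T + model.params["b2"])
    else:
        h_pre = h = None
        e = np.full((u.shape[0], N_LEADS), float(force_excitation))
    os_ = scale(ys, e)
    xcat = np.concatenate(os_, axis=1)
    z = xcat @ model.params["Wc"].T + model.params["bc"]
    cache = (u, h_pre, h, e, xcat, ys)
    return z, cache


def _backward(model: LSEModel, dz, cache, learn_excitation=True):
    u, h_pre, h, e, xcat, ys = cache
    g = model.grads
    g["Wc"] = dz.T @ xcat
    g["bc"] = dz.sum(axis=0)
    dxcat = dz @ model.params["Wc"]
    if not learn_excitation or h is None:
        for k in ("W1", "b1", "W2", "b2"):
            g[k] = np.zeros_like(model.params[k])
        return
    de = np.empty_like(e)
    off = model._offsets
    for i in range(N_LEADS):
        do_i = dxcat[:, off[i]: off[i + 1]]
        de[:, i] = (do_i * ys[i]).sum(axis=1)
    de_pre = de * e * (1.0 - e)
    g["W2"] = de_pre.T @ h
    g["b2"] = de_pre.sum(axis=0)
    dh = de_pre @ model.params["W2"]
    dh_pre = dh * (h_pre > 0)
    g["W1"] = dh_pre.T @ u
    g["b1"] = dh_pre.sum(axis=0)


def _bank_features(bank: FeatureBank, genome, mask=None):
    ys = []
    for lead in range(N_LEADS):
        level = int(genome[lead])
        if level not in bank.level_set:
            raise ValueError(f"genome level {level} absent from feature bank")
        y = bank.get(lead, level)
        ys.append(y if mask is None else y[mask])
    return ys


def train_lse(bank: FeatureBank, genome, config: LSEConfig, *,
              classes=None, class_mode: str = "multiclass",
              positive_class: str | None = None):
    """Train an LSE block on the bank features selected by ``genome``.

    In binary mode the target is ``label == positive_class``.  Returns
    ``(model, loss_history)``; with ``epochs = 0`` the freshly initialized
    model is returned untouched.
    """
    classes = tuple(classes) if classes is not None else tuple(bank.class_set)
    ys = _bank_features(bank, genome)
    dims = [y.shape[1] for y in ys]
    model = LSEModel(genome, dims, classes, class_mode=class_mode, r=config.r,
                     seed=config.seed, positive_class=positive_class)
    labels = bank.labels
    if class_mode == "binary":
        if positive_class is None:
            raise ValueError("binary mode needs a positive_class")
        targets = (labels == positive_class).astype(float)
        counts = np.array([max(int((targets == 0).sum()), 1),
                           max(int((targets == 1).sum()), 1)])
        w = class_weights(counts)  # [w_neg, w_pos]
    else:
        y_idx = np.array([classes.index(l) for l in labels])
        counts = np.array([max(int((y_idx == i).sum()), 1) for i in range(len(classes))])
        w = class_weights(counts)
        onehot = np.eye(len(classes))[y_idx]

    rng = np.random.default_rng(config.seed)
    opt = Adam([model], lr=config.lr)
    history = []
    n = labels.size
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch):
            idx = order[start: start + config.batch]
            batch_ys = [y[idx] for y in ys]
            z, cache = _forward(model, batch_ys, config.force_excitation)
            if class_mode == "binary":
                loss, dz1 = sigmoid_weighted_ce(z[:, 0], targets[idx], w[0], w[1])
                dz = dz1[:, None]
            else:
                loss, dz = softmax_weighted_ce(z, onehot[idx], w)
            _backward(model, dz, cache,
                      learn_excitation=config.force_excitation is None)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict_proba(model: LSEModel, bank: FeatureBank, genome=None, mask=None,
                  force_excitation=None) -> np.ndarray:
    """Class probabilities for every (selected) beat in the bank."""
    genome = model.genome if genome is None else genome
    ys = _bank_features(bank, genome, mask)
    z, _ = _forward(model, ys, force_excitation)
    if model.class_mode == "binary":
        return sigmoid(z[:, 0])
    return softmax(z)


def mean_excitations(model: LSEModel, bank: FeatureBank, genome=None,
                     mask=None) -> np.ndarray:
    """Per-lead mean excitation over the given beats; each value in (0, 1)."""
    genome = model.genome if genome is None else genome
    ys = _bank_features(bank, genome, mask)
    if ys[0].shape[0] == 0:
        raise ValueError("cannot average excitations over an empty beat set")
    e = excite(squeeze(ys), model)
    return e.mean(axis=0)
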