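"""The two classifier subsystems, class balancing and ensembling.

Subsystem 1 feeds the zero-padded beat-feature matrix through three
pre-activation residual blocks (channel widths 32 -> 64 -> 128, max
pooling after the first two only) into a bidirectional-RNN encoder and
decoder with a softmax head. The residual block follows

    out = f(x) + x,   f(x) = W2^T ReLU(BN(W1^T ReLU(BN(x))))

and the BiRNN runs a tanh recurrence in each direction,

    h_fwd[t] = tanh(W x[t] + V h_fwd[t-1] + b)        t = 1..T
    h_bwd[t] = tanh(W' x[t] + V' h_bwd[t+1] + b')     t = T..1
    y[t]     = U [h_fwd[t], h_bwd[t]] + b_y

Subsystem 2 is a compact convolutional spectrogram classifier trained on
224x224x3 Mel-spectrogram images with SpecAugment-style masking and a
freeze-then-unfreeze schedule (head only, then the full network); a
plug-in hook accepts any external model honouring the same input
contract. Both train with decoupled-weight-decay Adam, He-normal
initialization, cross-entropy, early stopping and best-checkpoint
retention. SMOTE equalizes class counts by interpolating minority
samples between nearest minority neighbours. The ensemble is a convex
combination of the two subsystems' class-probability vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from . import nn
from .synthetic import LABEL_NEGATIVE, LABEL_POSITIVE

# class index 0 is the positive class; argmax ties therefore resolve
# toward the positive label
CLASS_ORDER = (LABEL_POSITIVE, LABEL_NEGATIVE)


def encode_labels(labels) -> np.ndarray:
    return np.asarray([CLASS_ORDER.index(l) for l in labels], dtype=int)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 32
    epochs: int = 25
    head_epochs: int = 5          # phase-1 (frozen encoder) epochs, subsystem 2
    patience: int = 10            # early stopping on validation loss
    val_fraction: float = 0.15
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ------------------------------------------------------------------ SMOTE

def smote_oversample(X, y, k: int = 5, seed: int = 0):
    """Equalize class counts by synthetic minority interpolation.

    Each synthetic point is x + u * (x_nn - x) with u ~ U(0, 1) and x_nn
    one of the k nearest minority neighbours of x. Original rows are
    preserved (and come first, in order); already-balanced input is
    returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    if np.all(counts == target):
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = target - cnt
        if need == 0:
            continue
        if cnt < 2:
            raise ValueError(f"minority class {cls!r} has fewer than 2 samples")
        k_eff = k
        if cnt <= k:
            k_eff = cnt - 1
            warnings.warn(f"k reduced to {k_eff} for class {cls!r}")
        pts = X[y == cls]
        nbr = NearestNeighbors(n_neighbors=k_eff + 1).fit(pts)
        _, nn_idx = nbr.kneighbors(pts)
        nn_idx = nn_idx[:, 1:]  # drop self
        base = rng.integers(0, cnt, size=need)
        pick = rng.integers(0, k_eff, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        a = pts[base]
        b = pts[nn_idx[base, pick]]
        new_X.append(a + u[:, None] * (b - a))
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)


# ------------------------------------------------------------ SpecAugment

def spec_augment(img: np.ndarray, n_time_masks: int = 2, n_freq_masks: int = 2,
                 mask_width: int = 20, seed: int = 0) -> np.ndarray:
    """Mask random time (column) and frequency (row) bands with the image
    mean; each band spans exactly ``mask_width`` cells."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape[:2]
    if mask_width >= min(h, w):
        raise ValueError("mask_width must be smaller than both dimensions")
    out = img.copy()
    fill = img.mean()
    rng = np.random.default_rng(seed)
    for _ in range(n_time_masks):
        start = int(rng.integers(0, w - mask_width + 1))
        out[:, start:start + mask_width] = fill
    for _ in range(n_freq_masks):
        start = int(rng.integers(0, h - mask_width + 1))
        out[start:start + mask_width, :] = fill
    return out


# ------------------------------------------------------ network components

class ResNetBlock1d:
    """Pre-activation residual block at constant channel width."""

    def __init__(self, rng, channels: int, kernel: int = 2):
        self.bn1 = nn.BatchNorm(channels)
        self.conv1 = nn.Conv1d(rng, channels, channels, kernel)
        self.bn2 = nn.BatchNorm(channels)
        self.conv2 = nn.Conv1d(rng, channels, channels, kernel)

    def __call__(self, x):
        f = self.conv2(nn.relu(self.bn2(self.conv1(nn.relu(self.bn1(x))))))
        return f + x

    def set_training(self, flag):
        self.bn1.training = flag
        self.bn2.training = flag

    def params(self):
        return (self.bn1.params() + self.conv1.params()
                + self.bn2.params() + self.conv2.params())


def resnet_block_forward(x: np.ndarray, block: ResNetBlock1d) -> np.ndarray:
    """Inference-mode residual block application (running BN statistics).

    ``x`` is (batch, channels, length); raises on a channel mismatch.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3 or x.shape[1] != block.conv1.w.data.shape[1]:
        raise ValueError(
            f"expected (batch, {block.conv1.w.data.shape[1]}, length), "
            f"got {x.shape}")
    block.set_training(False)
    return block(nn.Tensor(x)).data


class BiRNN:
    """Bidirectional tanh RNN with a linear read-out of [h_fwd, h_bwd]."""

    def __init__(self, rng, d_in: int, hidden: int, d_out: int):
        self.hidden = hidden
        self.w_f = nn.Tensor(nn.he_normal(rng, (d_in, hidden), d_in), requires_grad=True)
        self.v_f = nn.Tensor(nn.he_normal(rng, (hidden, hidden), hidden), requires_grad=True)
        self.b_f = nn.Tensor(np.zeros(hidden), requires_grad=True)
        self.w_b = nn.Tensor(nn.he_normal(rng, (d_in, hidden), d_in), requires_grad=True)
        self.v_b = nn.Tensor(nn.he_normal(rng, (hidden, hidden), hidden), requires_grad=True)
        self.b_b = nn.Tensor(np.zeros(hidden), requires_grad=True)
        self.u = nn.Tensor(nn.he_normal(rng, (2 * hidden, d_out), 2 * hidden),
                           requires_grad=True)
        self.b_y = nn.Tensor(np.zeros(d_out), requires_grad=True)

    def hidden_states(self, xs):
        """xs: list of (batch, d_in) tensors; returns (fwd, bwd) lists."""
        t_len = len(xs)
        batch = xs[0].data.shape[0]
        h = nn.Tensor(np.zeros((batch, self.hidden)))
        fwd = []
        for t in range(t_len):
            h = nn.tanh(nn.matmul(xs[t], self.w_f) + nn.matmul(h, self.v_f) + self.b_f)
            fwd.append(h)
        h = nn.Tensor(np.zeros((batch, self.hidden)))
        bwd = [None] * t_len
        for t in range(t_len - 1, -1, -1):
            h = nn.tanh(nn.matmul(xs[t], self.w_b) + nn.matmul(h, self.v_b) + self.b_b)
            bwd[t] = h
        return fwd, bwd

    def __call__(self, xs):
        fwd, bwd = self.hidden_states(xs)
        return [nn.matmul(nn.concat([f, b], axis=1), self.u) + self.b_y
                for f, b in zip(fwd, bwd)]

    def params(self):
        return [self.w_f, self.v_f, self.b_f, self.w_b, self.v_b, self.b_b,
                self.u, self.b_y]


def birnn_forward(seq: np.ndarray, rnn: BiRNN):
    """Run one sequence (T, d_in) through the BiRNN.

    Returns ``(outputs, h_fwd, h_bwd)`` as (T, d_out) / (T, hidden) arrays.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("sequence must be (T, d_in) with T >= 1")
    xs = [nn.Tensor(seq[t][None, :]) for t in range(seq.shape[0])]
    fwd, bwd = rnn.hidden_states(xs)
    ys = [nn.matmul(nn.concat([f, b], axis=1), rnn.u) + rnn.b_y
          for f, b in zip(fwd, bwd)]
    stack = lambda ts: np.stack([t.data[0] for t in ts])
    return stack(ys), stack(fwd), stack(bwd)


# ------------------------------------------------------------- subsystem 1

class Subsystem1Model:
    """ResNet feature extractor -> BiRNN encoder -> BiRNN decoder -> softmax."""

    def __init__(self, seed: int = 0, n_classes: int = 2, seq_len: int = 16,
                 hidden: int = 32):
        rng = np.random.default_rng(seed)
        self.seq_len = seq_len
        self.n_classes = n_classes
        self.lift1 = nn.Conv1d(rng, 5, 32, 2)
        self.block1 = ResNetBlock1d(rng, 32)
        self.lift2 = nn.Conv1d(rng, 32, 64, 2)
        self.block2 = ResNetBlock1d(rng, 64)
        self.lift3 = nn.Conv1d(rng, 64, 128, 2)
        self.block3 = ResNetBlock1d(rng, 128)
        self.encoder = BiRNN(rng, 128, hidden, hidden)
        self.decoder = BiRNN(rng, hidden, hidden, n_classes)
        # zero-init the decoder read-out so training starts from the
        # uniform softmax
        self.decoder.u.data[:] = 0.0
        self.feat_mean = np.zeros(5)
        self.feat_std = np.ones(5)
        self.training = True

    def set_training(self, flag):
        self.training = flag
        for b in (self.block1, self.block2, self.block3):
            b.set_training(flag)

    def fit_normalizer(self, mats):
        stacked = np.concatenate([m for m in mats], axis=0)
        self.feat_mean = stacked.mean(axis=0)
        self.feat_std = np.maximum(stacked.std(axis=0), 1e-9)

    def prepare(self, mats) -> np.ndarray:
        """Pad/truncate N x 5 matrices to (batch, 5, seq_len), standardized."""
        out = np.zeros((len(mats), 5, self.seq_len))
        for i, m in enumerate(mats):
            m = (np.asarray(m, dtype=float) - self.feat_mean) / self.feat_std
            n = min(m.shape[0], self.seq_len)
            out[i, :, :n] = m[:n].T
        return out

    def logits(self, x: np.ndarray) -> nn.Tensor:
        t = nn.Tensor(x)
        t = self.block1(self.lift1(t))
        t = nn.maxpool1d(t, 2)
        t = self.block2(self.lift2(t))
        t = nn.maxpool1d(t, 2)
        t = self.block3(self.lift3(t))
        seq = [t[:, :, i] for i in range(t.data.shape[2])]
        enc = self.encoder(seq)
        dec = self.decoder(enc)
        total = dec[0]
        for y in dec[1:]:
            total = total + y
        return nn.mul(total, nn.Tensor(1.0 / len(dec)))

    def predict_proba(self, mats) -> np.ndarray:
        self.set_training(False)
        return nn.softmax(self.logits(self.prepare(mats)), axis=1).data

    def predict(self, mats) -> np.ndarray:
        return self.predict_proba(mats).argmax(axis=1)

    def params(self):
        ps = self.lift1.params() + self.block1.params()
        ps += self.lift2.params() + self.block2.params()
        ps += self.lift3.params() + self.block3.params()
        ps += self.encoder.params() + self.decoder.params()
        return ps


# ------------------------------------------------------------- subsystem 2

class Subsystem2Model:
    """Compact convolutional spectrogram classifier (224x224x3 input).

    The input contract matches the spectrogram stage exactly, so any
    external pretrained spectrogram model taking the same input can be
    plugged into the pipeline in its place.
    """

    # frequency is pooled 8x but time only 2x (28 x 112 grid): beats are
    # ~0.8 s apart, so coarser time bins could not localize the QRS for
    # Grad-CAM at all
    POOL_H = 8
    POOL_W = 2

    def __init__(self, seed: int = 0, n_classes: int = 2):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.conv1 = nn.Conv2d(rng, 1, 8, 3)
        self.conv2 = nn.Conv2d(rng, 8, 16, 3)
        grid_h = 224 // self.POOL_H // 4
        # head reads time-averaged conv features (channel x frequency):
        # the class signature is a spectral profile that may occur at any
        # beat, and time pooling is what lets Grad-CAM localize evidence
        self.head = nn.Linear(rng, 16 * grid_h, n_classes)
        # zero-init head: start at the uniform softmax instead of large
        # confidently-wrong logits
        self.head.w.data[:] = 0.0
        self.in_mean = 0.0
        self.in_std = 1.0

    @classmethod
    def _pool(cls, imgs) -> np.ndarray:
        arr = np.asarray(imgs, dtype=float)
        if arr.ndim == 3:
            arr = arr[None]
        gray = arr.mean(axis=3)
        b, h, w = gray.shape
        return gray.reshape(b, h // cls.POOL_H, cls.POOL_H,
                            w // cls.POOL_W, cls.POOL_W).mean(axis=(2, 4))

    def fit_normalizer(self, imgs):
        # per-frequency-row standardization: rows differ in energy by
        # orders of magnitude, so row scaling is needed for optimization,
        # while the within-row time structure that localizes the QRS in
        # Grad-CAM maps is preserved
        pooled = self._pool(imgs)
        self.in_mean = pooled.mean(axis=(0, 2), keepdims=True)[0]
        self.in_std = np.maximum(pooled.std(axis=(0, 2), keepdims=True)[0],
                                 0.1 * pooled.std())

    def prepare(self, imgs) -> np.ndarray:
        """(batch, 224, 224, 3) -> (batch, 1, 28, 112), standardized."""
        pooled = self._pool(imgs)
        return ((pooled - self.in_mean) / self.in_std)[:, None, :, :]

    def _forward(self, t: nn.Tensor):
        a1 = nn.relu(self.conv1(t))
        p1 = nn.maxpool2d(a1, 2)                   # 14 x 56
        a2 = nn.relu(self.conv2(p1))               # Grad-CAM target layer
        p2 = nn.maxpool2d(a2, 2)                   # 7 x 28
        tavg = nn.mul(nn.tsum(p2, axis=3), nn.Tensor(1.0 / p2.data.shape[3]))
        flat = nn.reshape(tavg, (tavg.data.shape[0], -1))
        return self.head(flat), a2

    def logits(self, x: np.ndarray) -> nn.Tensor:
        return self._forward(nn.Tensor(x))[0]

    def logits_with_activation(self, x: np.ndarray):
        t = nn.Tensor(x, requires_grad=True)
        logits, act = self._forward(t)
        return logits, act

    def predict_proba(self, imgs) -> np.ndarray:
        return nn.softmax(self.logits(self.prepare(imgs)), axis=1).data

    def predict(self, imgs) -> np.ndarray:
        return self.predict_proba(imgs).argmax(axis=1)

    def encoder_params(self):
        return self.conv1.params() + self.conv2.params()

    def head_params(self):
        return self.head.params()

    def params(self):
        return self.encoder_params() + self.head_params()

    def set_training(self, flag):  # no BN layers; kept for interface parity
        pass


def params_state(model) -> list[np.ndarray]:
    return [p.data.copy() for p in model.params()]


def load_params_state(model, state) -> None:
    for p, s in zip(model.params(), state):
        p.data = s.copy()


# --------------------------------------------------------------- training

def _stratified_holdout(y, fraction, seed):
    from .evaluation import stratified_split

    return stratified_split(y, test_fraction=fraction, seed=seed)


def _run_training(model, prepare_batch, X_train, y_train, X_val, y_val,
                  optimizer, cfg: TrainConfig, epochs: int, rng,
                  history: dict, augment=None, restore_best=True):
    n = len(X_train)
    best_val = history.get("best_val_loss", np.inf)
    best_state = history.get("_best_state") or params_state(model)
    stale = 0
    for _ in range(epochs):
        model.set_training(True)
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = [X_train[i] for i in idx]
            if augment is not None:
                xb = [augment(x, int(rng.integers(0, 2 ** 31 - 1))) for x in xb]
            yb = y_train[idx]
            logits = model.logits(prepare_batch(xb))
            loss = nn.cross_entropy(logits, yb)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            hits += int((logits.data.argmax(axis=1) == yb).sum())
        model.set_training(False)
        val_logits = model.logits(prepare_batch(list(X_val)))
        val_loss = float(nn.cross_entropy(val_logits, y_val).data)
        val_acc = float((val_logits.data.argmax(axis=1) == y_val).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(hits / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = params_state(model)
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    history["best_val_loss"] = best_val
    history["_best_state"] = best_state
    if restore_best:
        load_params_state(model, best_state)
        del history["_best_state"]
    return model


def train_subsystem1(feature_matrices, labels, cfg: TrainConfig | None = None):
    """Train the ResNet+BiRNN subsystem on N x 5 feature matrices.

    Labels are class-name strings; SMOTE balances the (flattened)
    training matrices before fitting. Returns ``(model, history)``.
    """
    cfg = cfg or TrainConfig()
    y = encode_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    model = Subsystem1Model(seed=cfg.seed, n_classes=cfg.n_classes)
    tr_idx, val_idx = _stratified_holdout(y, cfg.val_fraction, cfg.seed)
    pad = model.seq_len
    flat = np.stack([_pad_flat(m, pad) for m in feature_matrices])
    Xb, yb = smote_oversample(flat[tr_idx], y[tr_idx], seed=cfg.seed)
    mats_tr = [x.reshape(pad, 5) for x in Xb]
    mats_val = [_pad_flat(feature_matrices[i], pad).reshape(pad, 5)
                for i in val_idx]
    model.fit_normalizer(mats_tr)
    optimizer = nn.AdamW(model.params(), lr=cfg.learning_rate,
                         weight_decay=cfg.weight_decay)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    rng = np.random.default_rng(cfg.seed)
    _run_training(model, model.prepare, mats_tr, yb, mats_val, y[val_idx],
                  optimizer, cfg, cfg.epochs, rng, history)
    return model, history


def _pad_flat(m, n_rows):
    m = np.asarray(m, dtype=float)
    out = np.zeros((n_rows, m.shape[1]))
    k = min(n_rows, m.shape[0])
    out[:k] = m[:k]
    return out.ravel()


def train_subsystem2(images, labels, cfg: TrainConfig | None = None,
                     external_model=None):
    """Two-phase training of the spectrogram classifier.

    Phase 1 updates only the classification head (encoder frozen); phase
    2 fine-tunes everything. SpecAugment masking is applied to training
    batches only. ``external_model`` may supply any object honouring the
    Subsystem2Model interface (the pretrained-transformer plug-in hook).
    """
    cfg = cfg or TrainConfig(learning_rate=2e-5, batch_size=16, epochs=50)
    y = encode_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    model = external_model or Subsystem2Model(seed=cfg.seed, n_classes=cfg.n_classes)
    tr_idx, val_idx = _stratified_holdout(y, cfg.val_fraction, cfg.seed)
    X_tr = [images[i] for i in tr_idx]
    X_val = [images[i] for i in val_idx]
    model.fit_normalizer(X_tr)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    rng = np.random.default_rng(cfg.seed)

    def augment(img, seed):
        # mild masking: the synthetic class contrast is subtle, so wide
        # mean-filled bands would swamp it
        return spec_augment(img, n_time_masks=1, n_freq_masks=1,
                            mask_width=8, seed=seed)

    head_epochs = min(cfg.head_epochs, cfg.epochs)
    opt1 = nn.AdamW(model.head_params(), lr=cfg.learning_rate,
                    weight_decay=cfg.weight_decay)
    _run_training(model, model.prepare, X_tr, y[tr_idx], X_val, y[val_idx],
                  opt1, cfg, head_epochs, rng, history, augment=augment,
                  restore_best=head_epochs == cfg.epochs)
    if cfg.epochs > head_epochs:
        opt2 = nn.AdamW(model.params(), lr=cfg.learning_rate,
                        weight_decay=cfg.weight_decay)
        _run_training(model, model.prepare, X_tr, y[tr_idx], X_val, y[val_idx],
                      opt2, cfg, cfg.epochs - head_epochs, rng, history,
                      augment=augment)
    return model, history


# --------------------------------------------------------------- ensemble

@dataclass(frozen=True)
class EnsembleWeights:
    w1: float = 0.5
    w2: float = 0.5

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("ensemble weights must be non-negative")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("ensemble weights must sum to 1")


def ensemble_predict(p1: np.ndarray, p2: np.ndarray,
                     w: EnsembleWeights = EnsembleWeights()):
    """Weighted aggregation p = w1*p1 + w2*p2; returns (labels, probs).

    Argmax ties resolve toward index 0, the positive class.
    """
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    p2 = np.atleast_2d(np.asarray(p2, dtype=float))
    if p1.shape != p2.shape:
        raise ValueError("probability arrays must share the same class set")
    p = w.w1 * p1 + w.w2 * p2
    return p.argmax(axis=1), p


def fit_ensemble_weights(p1, p2, y_true, steps: int = 21) -> EnsembleWeights:
    """Grid-search w1 on [0, 1] maximizing validation accuracy."""
    best, best_acc = 0.5, -1.0
    for w1 in np.linspace(0.0, 1.0, steps):
        labels, _ = ensemble_predict(p1, p2, EnsembleWeights(w1, 1.0 - w1))
        acc = float((labels == y_true).mean())
        if acc > best_acc:
            best, best_acc = w1, acc
    return EnsembleWeights(best, 1.0 - best)
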