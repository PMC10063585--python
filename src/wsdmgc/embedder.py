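"""Deep metric embedding network with a classification head.

A small shared-weight network maps each grayscale patch to a
d-dimensional, L2-normalised embedding f(x); a linear head on top of the
embedding produces class probabilities q(f(x)). Image inputs go through
a convolutional trunk (3x3 conv + ReLU + 2x2 max-pool blocks, then fully
connected layers); plain feature vectors use a fully connected trunk.
Training minimises

    L = L_M + lambda1 * L_C + lambda2 * ||W||_F^2

where L_M is the hinged triplet loss (mean over batch-hard mined
triplets), L_C the cross-entropy of the head on the labeled batch, and
the Frobenius term sums the squared entries of every weight tensor
(biases excluded). Optimisation is SGD with momentum; all gradients are
computed analytically (finite-difference checked in the test suite) and
the whole stack is plain NumPy, deterministic given the seed.

Triplets are mined online and batch-hard: mini-batches are composed so
that every class contributes up to K samples plus extra random
negatives, and within the batch each anchor takes its farthest same-class
sample as positive and its nearest other-class sample as negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .config import RunConfig
from .datasets import DataValidationError, SampleSet


class EmbedderError(ValueError):
    pass


# ---------------------------------------------------------------------------
# loss functions (public, array-level)
# ---------------------------------------------------------------------------

@dataclass
class TripletBatch:
    """Index triplets (anchor, positive, negative) into an embedding matrix."""

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=np.int64)
        self.positives = np.asarray(self.positives, dtype=np.int64)
        self.negatives = np.asarray(self.negatives, dtype=np.int64)
        if not (len(self.anchors) == len(self.positives) == len(self.negatives)):
            raise EmbedderError("triplet index arrays must have equal length")

    def __len__(self) -> int:
        return len(self.anchors)


def triplet_loss(embeddings: np.ndarray, batch: TripletBatch, alpha: float,
                 hinge: bool = True) -> float:
    """Mean triplet loss max(||f_a-f_p||^2 - ||f_a-f_n||^2 + alpha, 0).

    ``hinge=False`` drops the max(., 0) and reproduces the literal
    (unbounded-below) sum; the hinged form is the default because only it
    is consistent with the margin constraint the loss is meant to enforce.
    """
    if len(batch) == 0:
        raise EmbedderError("empty triplet batch")
    F = np.asarray(embeddings, dtype=np.float64)
    d_ap = np.sum((F[batch.anchors] - F[batch.positives]) ** 2, axis=1)
    d_an = np.sum((F[batch.anchors] - F[batch.negatives]) ** 2, axis=1)
    terms = d_ap - d_an + alpha
    if hinge:
        terms = np.maximum(terms, 0.0)
    return float(terms.mean())


def contrastive_loss(pairs: list[tuple[int, int, int]], embeddings: np.ndarray,
                     m: float) -> float:
    """Siamese contrastive loss (1/2N) sum[Y*D^2 + (1-Y)*max(m-D, 0)^2].

    ``pairs`` is a list of (i, j, Y) with Y=1 for a matched (same-class)
    pair and Y=0 for a mismatched pair; D is the Euclidean distance
    between the embeddings of i and j.
    """
    if len(pairs) == 0:
        raise EmbedderError("empty pair list")
    F = np.asarray(embeddings, dtype=np.float64)
    total = 0.0
    for i, j, Y in pairs:
        D = float(np.linalg.norm(F[i] - F[j]))
        total += Y * D * D + (1 - Y) * max(m - D, 0.0) ** 2
    return total / (2 * len(pairs))


def total_loss(L_M: float, L_C: float, frobenius_sq: float,
               lambda1: float, lambda2: float) -> float:
    """Combined objective L_M + lambda1*L_C + lambda2*||W||_F^2."""
    out = L_M + lambda1 * L_C + lambda2 * frobenius_sq
    if not np.isfinite(out):
        raise EmbedderError("total loss is not finite")
    return float(out)


# ---------------------------------------------------------------------------
# online batch-hard triplet mining
# ---------------------------------------------------------------------------

def batch_hard_triplets(embeddings: np.ndarray,
                        labels: np.ndarray) -> TripletBatch:
    """Batch-hard mining within one mini-batch.

    For every anchor with at least one same-class partner and one
    other-class sample in the batch, select the farthest positive and the
    nearest negative (squared Euclidean distance). Ties break toward the
    lowest index. Anchors whose class has no second member are skipped.
    """
    F = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels)
    n = len(y)
    sq = np.sum(F * F, axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (F @ F.T), 0.0)
    same = y[:, None] == y[None, :]
    anchors, positives, negatives = [], [], []
    for a in range(n):
        pos_mask = same[a].copy()
        pos_mask[a] = False
        neg_mask = ~same[a]
        if not pos_mask.any() or not neg_mask.any():
            continue
        p = int(np.flatnonzero(pos_mask)[np.argmax(D2[a, pos_mask])])
        neg_idx = np.flatnonzero(neg_mask)
        nn = int(neg_idx[np.argmin(D2[a, neg_mask])])
        anchors.append(a)
        positives.append(p)
        negatives.append(nn)
    if not anchors:
        raise EmbedderError("no class with >= 2 members in the batch; "
                            "cannot form any triplet")
    return TripletBatch(np.array(anchors), np.array(positives),
                        np.array(negatives))


def compose_batch(labels: np.ndarray, samples_per_class: int,
                  extra_negatives: int, rng: np.random.Generator) -> np.ndarray:
    """Mini-batch indices: up to K samples from every class + random extras."""
    y = np.asarray(labels)
    chosen: list[np.ndarray] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = min(samples_per_class, members.size)
        chosen.append(rng.choice(members, size=k, replace=False))
    idx = np.concatenate(chosen)
    if extra_negatives > 0 and len(y) > 0:
        extras = rng.choice(len(y), size=min(extra_negatives, len(y)),
                            replace=False)
        idx = np.concatenate([idx, extras])  # duplicates allowed as extras
    return idx


def mine_triplets(embeddings: np.ndarray, labels: np.ndarray,
                  plan: tuple[int, int] = (4, 8),
                  seed: int = 0) -> TripletBatch:
    """Compose one mini-batch and mine batch-hard triplets within it.

    ``plan`` is (samples per class K, extra random negatives). Returned
    indices refer to the full ``embeddings`` matrix.
    """
    rng = np.random.default_rng(seed)
    idx = compose_batch(labels, plan[0], plan[1], rng)
    sub = batch_hard_triplets(np.asarray(embeddings)[idx],
                              np.asarray(labels)[idx])
    return TripletBatch(idx[sub.anchors], idx[sub.positives],
                        idx[sub.negatives])


# ---------------------------------------------------------------------------
# layers (NumPy, analytic gradients)
# ---------------------------------------------------------------------------

class _Layer:
    """Forward/backward layer; ``params``/``grads`` are parallel lists."""

    params: list[np.ndarray]
    weight_ix: tuple[int, ...] = ()   # which params count toward ||W||_F^2

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(_Layer):
    weight_ix = (0,)

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = [rng.normal(0, np.sqrt(2.0 / d_in), size=(d_in, d_out)),
                       np.zeros(d_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, g):
        self.grads[0][:] = self._x.T @ g
        self.grads[1][:] = g.sum(axis=0)
        return g @ self.params[0].T


class ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Conv3x3(_Layer):
    """3x3 same-padding convolution via im2col; kernel stored (C_in*9, C_out)."""

    weight_ix = (0,)

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * 9
        self.c_in, self.c_out = c_in, c_out
        self.params = [rng.normal(0, np.sqrt(2.0 / fan_in),
                                  size=(fan_in, c_out)),
                       np.zeros(c_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _im2col(self, x):
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # (B, C, H, W, 3, 3) windows -> (B*H*W, C*9)
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * 9)
        return col

    def forward(self, x, train):
        self._shape = x.shape
        b, c, h, w = x.shape
        self._col = self._im2col(x)
        out = self._col @ self.params[0] + self.params[1]
        return out.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g):
        b, c, h, w = self._shape
        gflat = g.transpose(0, 2, 3, 1).reshape(b * h * w, self.c_out)
        self.grads[0][:] = self._col.T @ gflat
        self.grads[1][:] = gflat.sum(axis=0)
        dcol = (gflat @ self.params[0].T).reshape(b, h, w, c, 3, 3)
        dxp = np.zeros((b, c, h + 2, w + 2))
        for dy in range(3):
            for dx in range(3):
                dxp[:, :, dy:dy + h, dx:dx + w] += \
                    dcol[:, :, :, :, dy, dx].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]


class MaxPool2(_Layer):
    def forward(self, x, train):
        b, c, h, w = x.shape
        self._shape = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2) \
              .transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, g):
        b, c, h, w = self._shape
        out = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(out, self._arg[..., None], g[..., None], axis=-1)
        return out.reshape(b, c, h // 2, w // 2, 2, 2) \
                  .transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)


class Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

@dataclass
class EmbedderParams:
    """The trained network: architecture descriptor, trunk layers, head.

    The trunk output is L2-normalised to the unit sphere; ``head_W`` /
    ``head_b`` map the normalised embedding to class logits. ``input_mean``
    (the training-set mean) is subtracted from inputs before the trunk —
    stored with the weights so embedding is self-contained.
    """

    architecture: dict
    layers: list[_Layer]
    head_W: np.ndarray
    head_b: np.ndarray
    input_mean: np.ndarray

    @property
    def input_shape(self) -> tuple[int, ...]:
        return tuple(self.architecture["input_shape"])

    @property
    def embed_dim(self) -> int:
        return int(self.architecture["embed_dim"])

    @property
    def n_classes(self) -> int:
        return self.head_W.shape[1]

    def frobenius_sq(self) -> float:
        """Sum of squared entries of all weight tensors (biases excluded)."""
        total = float(np.sum(self.head_W * self.head_W))
        for layer in self.layers:
            for i in layer.weight_ix:
                total += float(np.sum(layer.params[i] ** 2))
        return total

    def copy(self) -> "EmbedderParams":
        import copy as _copy

        new_layers = []
        for layer in self.layers:
            l2 = object.__new__(type(layer))
            _Layer.__init__(l2)
            l2.__dict__.update({k: v for k, v in layer.__dict__.items()
                                if not k.startswith("_")})
            l2.params = [p.copy() for p in layer.params]
            l2.grads = [np.zeros_like(p) for p in layer.params]
            new_layers.append(l2)
        return EmbedderParams(_copy.deepcopy(self.architecture), new_layers,
                              self.head_W.copy(), self.head_b.copy(),
                              self.input_mean.copy())


def init_params(input_shape: tuple[int, ...], config: RunConfig,
                n_classes: int, rng: np.random.Generator,
                input_mean: np.ndarray | None = None) -> EmbedderParams:
    """Build the default architecture for the given input shape.

    Images (H, W) get the convolutional trunk
    ``[conv3x3(8) relu pool2] x3 -> FC hidden -> FC d``; flat feature
    vectors get ``FC hidden -> FC d``. Both end L2-normalised.
    """
    layers: list[_Layer] = []
    if len(input_shape) == 2:
        h, w = input_shape
        channels = tuple(config.conv_channels)
        c_in = 1
        for c_out in channels:
            if h < 2 or w < 2:
                break
            layers += [Conv3x3(c_in, c_out, rng), ReLU(), MaxPool2()]
            c_in, h, w = c_out, h // 2, w // 2
        layers.append(Flatten())
        d_in = c_in * h * w
        arch = {"input_shape": list(input_shape), "conv_channels": channels,
                "hidden_dims": list(config.hidden_dims),
                "embed_dim": config.embed_dim}
    else:
        d_in = int(np.prod(input_shape))
        arch = {"input_shape": list(input_shape), "conv_channels": (),
                "hidden_dims": list(config.hidden_dims),
                "embed_dim": config.embed_dim}
    for d_out in config.hidden_dims:
        layers += [Dense(d_in, d_out, rng), ReLU()]
        d_in = d_out
    layers.append(Dense(d_in, config.embed_dim, rng))
    head_W = rng.normal(0, np.sqrt(1.0 / config.embed_dim),
                        size=(config.embed_dim, n_classes))
    if input_mean is None:
        input_mean = np.zeros(input_shape)
    return EmbedderParams(arch, layers, head_W, np.zeros(n_classes), input_mean)


def _as_input(params: EmbedderParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    shape = params.input_shape
    if X.shape[1:] != shape:
        if X.ndim == 2 and int(np.prod(shape)) == X.shape[1]:
            X = X.reshape(len(X), *shape)
        else:
            raise EmbedderError(f"input shape {X.shape[1:]} does not match "
                                f"network input {shape}")
    X = X - params.input_mean
    if len(shape) == 2:
        X = X[:, None, :, :]      # single channel
    return X


def _forward(params: EmbedderParams, X: np.ndarray, train: bool = False):
    h = _as_input(params, X)
    for layer in params.layers:
        h = layer.forward(h, train)
    z = h
    norms = np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)
    return z / norms, (z, norms)


def _backward(params: EmbedderParams, cache, dF: np.ndarray) -> None:
    """Backprop dLoss/dF through the normalisation and the trunk layers.

    Parameter gradients are left on each layer's ``grads``.
    """
    z, norms = cache
    F = z / norms
    g = (dF - np.sum(dF * F, axis=1, keepdims=True) * F) / norms
    for layer in reversed(params.layers):
        g = layer.backward(g)


def embed(samples: SampleSet | np.ndarray, params: EmbedderParams) -> np.ndarray:
    """Embed all samples; rows are unit-norm d-vectors aligned with input order."""
    X = samples.X if isinstance(samples, SampleSet) else np.asarray(samples)
    F, _ = _forward(params, X)
    return F


def classify(samples: SampleSet | np.ndarray,
             params: EmbedderParams) -> tuple[np.ndarray, np.ndarray]:
    """Classifier-head predictions.

    Returns (labels, confidence): per-sample argmax of the softmax head
    over the embedding (ties toward the lowest class id, numpy argmax
    semantics) and the corresponding maximum probability.
    """
    F = embed(samples, params)
    logits = F @ params.head_W + params.head_b
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p.argmax(axis=1), p.max(axis=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _metric_loss_and_grad(F: np.ndarray, y: np.ndarray, config: RunConfig,
                          ) -> tuple[float, np.ndarray]:
    """L_M and dL_M/dF for the configured metric loss on one batch."""
    n = len(y)
    dF = np.zeros_like(F)
    if config.loss == "triplet":
        batch = batch_hard_triplets(F, y)
        a, p, nn = batch.anchors, batch.positives, batch.negatives
        d_ap = np.sum((F[a] - F[p]) ** 2, axis=1)
        d_an = np.sum((F[a] - F[nn]) ** 2, axis=1)
        terms = d_ap - d_an + config.alpha_margin
        if config.hinge:
            active = terms > 0
            loss = float(np.maximum(terms, 0.0).mean())
        else:
            active = np.ones_like(terms, dtype=bool)
            loss = float(terms.mean())
        w = 1.0 / len(terms)
        for t in np.flatnonzero(active):
            dF[a[t]] += w * 2.0 * (F[nn[t]] - F[p[t]])
            dF[p[t]] += w * (-2.0) * (F[a[t]] - F[p[t]])
            dF[nn[t]] += w * 2.0 * (F[a[t]] - F[nn[t]])
        return loss, dF
    # contrastive: all within-batch pairs
    ii, jj = np.triu_indices(n, k=1)
    if len(ii) == 0:
        raise EmbedderError("batch too small for contrastive pairs")
    diff = F[ii] - F[jj]
    D = np.linalg.norm(diff, axis=1)
    Y = (y[ii] == y[jj]).astype(np.float64)
    m = config.contrastive_margin
    hinge = np.maximum(m - D, 0.0)
    N = len(ii)
    loss = float(np.sum(Y * D * D + (1 - Y) * hinge ** 2) / (2 * N))
    # matched: d/df_i = (f_i-f_j)/N ; mismatched active: -(m-D)/(N*D) (f_i-f_j)
    coef = np.where(Y == 1, 1.0 / N,
                    np.where((hinge > 0) & (D > 1e-12),
                             -hinge / (N * np.maximum(D, 1e-12)), 0.0))
    g = coef[:, None] * diff
    np.add.at(dF, ii, g)
    np.add.at(dF, jj, -g)
    return loss, dF


def _loss_and_grads(params: EmbedderParams, Xb: np.ndarray, yb: np.ndarray,
                    config: RunConfig) -> dict:
    """Forward + backward for one mini-batch; gradients left on layers.

    Returns the loss components plus the head gradients.
    """
    F, cache = _forward(params, Xb, train=True)
    L_M, dF = _metric_loss_and_grad(F, yb, config)

    logits = F @ params.head_W + params.head_b
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    B = len(yb)
    L_C = float(-np.mean(np.log(np.maximum(p[np.arange(B), yb], 1e-300))))
    dlogits = p.copy()
    dlogits[np.arange(B), yb] -= 1.0
    dlogits /= B
    g_head_W = config.lambda1 * (F.T @ dlogits) + 2 * config.lambda2 * params.head_W
    g_head_b = config.lambda1 * dlogits.sum(axis=0)
    dF = dF + config.lambda1 * (dlogits @ params.head_W.T)

    _backward(params, cache, dF)
    for layer in params.layers:
        for i in layer.weight_ix:
            layer.grads[i] += 2 * config.lambda2 * layer.params[i]

    frob = params.frobenius_sq()
    return {"loss": total_loss(L_M, L_C, frob, config.lambda1, config.lambda2),
            "L_M": L_M, "L_C": L_C, "frobenius_sq": frob,
            "g_head_W": g_head_W, "g_head_b": g_head_b}


class _SGD:
    """SGD with momentum and global-norm gradient clipping.

    Clipping guards the batch-hard triplet objective against the rare
    large step that collapses every embedding onto a single point (a
    fixed point the gradient cannot leave).
    """

    def __init__(self, params: EmbedderParams, lr: float, momentum: float,
                 clip: float = 5.0):
        self.lr, self.mu, self.clip = lr, momentum, clip
        self.v = [[np.zeros_like(p) for p in layer.params]
                  for layer in params.layers]
        self.vh = [np.zeros_like(params.head_W), np.zeros_like(params.head_b)]

    def step(self, params: EmbedderParams, g_head_W, g_head_b):
        sq = float(np.sum(g_head_W ** 2) + np.sum(g_head_b ** 2))
        for layer in params.layers:
            for g in layer.grads:
                sq += float(np.sum(g * g))
        scale = min(1.0, self.clip / max(np.sqrt(sq), 1e-12))
        for layer, vs in zip(params.layers, self.v):
            for i, p in enumerate(layer.params):
                vs[i] = self.mu * vs[i] - self.lr * scale * layer.grads[i]
                p += vs[i]
        self.vh[0] = self.mu * self.vh[0] - self.lr * scale * g_head_W
        self.vh[1] = self.mu * self.vh[1] - self.lr * scale * g_head_b
        params.head_W += self.vh[0]
        params.head_b += self.vh[1]


def fit_embedder(labeled: SampleSet | tuple[np.ndarray, np.ndarray],
                 config: RunConfig,
                 init: EmbedderParams | None = None,
                 epochs: int | None = None,
                 n_classes: int | None = None,
                 max_steps_per_epoch: int = 12,
                 ) -> tuple[EmbedderParams, pd.DataFrame]:
    """Train the embedding network on the labeled samples.

    Parameters may be warm-started from ``init`` (used by the outer
    propagation loop, with a reduced epoch count). Returns the trained
    parameters and a per-epoch history frame with columns
    ``epoch, loss, L_M, L_C``.
    """
    if isinstance(labeled, SampleSet):
        X = labeled.X[labeled.labeled]
        y = labeled.y[labeled.labeled]
        n_cls = n_classes or labeled.n_classes
    else:
        X, y = labeled
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        n_cls = n_classes or (int(y.max()) + 1 if len(y) else 0)
    if len(X) == 0:
        raise DataValidationError("labeled set is empty")
    if len(np.unique(y)) < 2:
        raise DataValidationError(
            "labeled set must contain at least 2 classes (no negatives exist)")
    if np.max(np.bincount(y)) < 2:
        raise DataValidationError(
            "some class must have >= 2 labeled samples (no positives exist)")

    if init is None and config.restarts > 1:
        # batch-hard training has high run-to-run variance: train a few
        # independent cold starts and keep the best by training loss,
        # vetoing collapsed runs (labeled-set silhouette near zero means
        # every embedding sits in one blob regardless of class)
        from .metrics import silhouette as _silhouette

        runs = []
        for r in range(config.restarts):
            sub = config.replace(restarts=1,
                                 seed=(config.seed + r * 50021) % (2 ** 31))
            cand, hist = fit_embedder((X, y), sub, epochs=epochs,
                                      n_classes=n_cls,
                                      max_steps_per_epoch=max_steps_per_epoch)
            F, _ = _forward(cand, X)
            _, sil = _silhouette(F, y)
            runs.append((float(hist["loss"].min()), sil, cand, hist))
        sil_max = max(r[1] for r in runs)
        ok = [r for r in runs if r[1] >= 0.5 * sil_max] or runs
        best = min(ok, key=lambda r: r[0])
        return best[2], best[3]

    rng = np.random.default_rng(config.seed)
    if init is None:
        params = init_params(X.shape[1:], config, n_cls, rng,
                             input_mean=X.mean(axis=0))
    else:
        params = init.copy()
    opt = _SGD(params, config.learning_rate, config.momentum)

    epochs = epochs if epochs is not None else config.epochs
    batch_size = (config.samples_per_class * len(np.unique(y))
                  + config.extra_negatives)
    n_batches = max(1, min(int(np.ceil(len(X) / batch_size)),
                           max_steps_per_epoch))
    rows = []
    best_loss = np.inf
    best_params = params
    lr0 = config.learning_rate
    for epoch in range(epochs):
        # cosine decay to 5% of the base rate: batch-hard training is
        # unstable at a constant rate once the margin is nearly satisfied
        opt.lr = lr0 * (0.05 + 0.95 * 0.5 *
                        (1 + np.cos(np.pi * epoch / max(1, epochs - 1))))
        stats = []
        for _ in range(n_batches):
            idx = compose_batch(y, config.samples_per_class,
                                config.extra_negatives, rng)
            out = _loss_and_grads(params, X[idx], y[idx], config)
            opt.step(params, out["g_head_W"], out["g_head_b"])
            stats.append(out)
        rows.append({"epoch": epoch,
                     **{k: float(np.mean([s[k] for s in stats]))
                        for k in ("loss", "L_M", "L_C")}})
        # early-stopping snapshot: keep the best-mean-loss parameters, so a
        # late training collapse cannot destroy an already good embedding
        if rows[-1]["loss"] < best_loss:
            best_loss = rows[-1]["loss"]
            best_params = params.copy()
    return best_params, pd.DataFrame(rows)
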