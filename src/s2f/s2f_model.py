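"""Sequence-to-expression surrogate model and training loop.

A small convolutional trunk with a position-resolved readout stands in,
at desk scale, for a large pre-trained sequence model.  The prediction
head follows the pooled-embedding design: trunk -> global average pooling
over positions -> covariate concatenation -> LayerNorm -> Linear(hidden)
-> ReLU -> Linear(1), yielding one scalar per individual.

Training uses AdamW with linear warm-up over the first 10% of optimizer
steps to the peak learning rate followed by cosine decay to 0, gradient
accumulation to reach the effective batch size, a composite loss
(alpha * MSE + (1 - alpha) * mean squared error of pairwise differences),
best-checkpoint selection on validation loss and early stopping.

The multi-gene scheme shares one head across genes, drops covariates and
uses the pairwise term only, so per-gene expression offsets do not
matter and unseen genes can be evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._nn import AdamW, Conv1d, GELU, Layer, LayerNorm, Linear, Param, PosReadout, ReLU, lr_schedule


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class TrunkConfig:
    """Convolutional trunk specification.

    ``conv_channels``/``kernels``/``dilations`` define a stack of
    Conv -> GELU blocks; with ``input_skip`` the raw one-hot channels are
    concatenated back onto the trunk output before the position-resolved
    readout (``readout_channels`` output channels).  An empty conv stack
    plus the readout gives a purely positional (affine-capacity) trunk.
    """

    conv_channels: tuple[int, ...] = (16,)
    kernels: tuple[int, ...] = (7,)
    dilations: tuple[int, ...] = (1,)
    input_skip: bool = True
    readout_channels: int = 32
    readout_init_scale: float = 0.01

    def __post_init__(self) -> None:
        if not (len(self.conv_channels) == len(self.kernels) == len(self.dilations)):
            raise ValueError("conv_channels, kernels and dilations must align")


#: the deeper dilated stack; selectable for larger-scale runs
DEEP_TRUNK = TrunkConfig(
    conv_channels=(64, 64, 128, 128),
    kernels=(7, 5, 5, 3),
    dilations=(1, 2, 4, 8),
)


@dataclass
class ModelConfig:
    """Model + optimisation hyperparameters (desk-scale defaults)."""

    length: int = 4096
    n_covariates: int = 0
    mode: str = "single"  # "single" (covariates) | "multi" (no covariates)
    trunk: TrunkConfig = field(default_factory=TrunkConfig)
    head_hidden: int = 512
    alpha: float = 0.5
    lr_peak: float = 2e-3
    warmup_frac: float = 0.1
    batch_size: int = 8
    accum_steps: int = 8  # effective batch = batch_size * accum_steps
    epochs: int = 30
    weight_decay: float = 0.02
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if not (0.0 <= self.warmup_frac < 1.0):
            raise ValueError("warmup fraction must be in [0, 1)")
        if self.mode not in ("single", "multi"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "multi" and self.n_covariates:
            raise ValueError("multi-gene mode does not take covariates")


@dataclass
class GeneData:
    """Training bundle for one gene: encodings, covariates, phenotype, split."""

    encodings: np.ndarray  # (n, L, 4) float32
    expression: np.ndarray  # (n,)
    covariates: np.ndarray | None  # (n, c) or None
    split: np.ndarray  # (n,) labels in {train, val, test}

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.split == label)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def composite_loss(pred: np.ndarray, obs: np.ndarray, alpha: float) -> float:
    """alpha * MSE + (1 - alpha) * mean over unique pairs (i < j) of
    [(pred_i - pred_j) - (obs_i - obs_j)]^2.

    The pairwise term is invariant to a constant shift of the
    predictions; it is computed in closed form via sums rather than by
    enumerating pairs.
    """
    loss, _ = composite_loss_grad(pred, obs, alpha)
    return loss


def composite_loss_grad(pred: np.ndarray, obs: np.ndarray,
                        alpha: float) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the predictions."""
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have the same shape")
    B = pred.shape[0]
    r = pred - obs
    mse = float(np.mean(r * r))
    dmse = 2.0 * r / B
    if alpha == 1.0:
        return mse, alpha * dmse
    if B < 2:
        raise ValueError("pairwise term needs a batch of at least 2")
    # sum_{i<j} (r_i - r_j)^2 = B * sum r^2 - (sum r)^2
    sr = r.sum()
    pair = (B * float(np.dot(r, r)) - sr * sr) * 2.0 / (B * (B - 1))
    dpair = 4.0 * (B * r - sr) / (B * (B - 1))
    loss = alpha * mse + (1.0 - alpha) * pair
    grad = alpha * dmse + (1.0 - alpha) * dpair
    return float(loss), grad


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class ExpressionPredictor:
    """Trunk + pooled-embedding head producing one scalar per individual."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        t = config.trunk
        self.conv_blocks: list[Layer] = []
        in_ch = 4
        for ch, k, d in zip(t.conv_channels, t.kernels, t.dilations):
            self.conv_blocks.append(Conv1d(in_ch, ch, k, dilation=d, rng=rng))
            self.conv_blocks.append(GELU())
            in_ch = ch
        readout_in = in_ch + (4 if t.input_skip and t.conv_channels else 0)
        if not t.conv_channels:
            readout_in = 4
        self.readout = PosReadout(readout_in, t.readout_channels, config.length,
                                  rng=rng, scale=t.readout_init_scale)
        feat = t.readout_channels + config.n_covariates
        self.norm = LayerNorm(feat)
        self.hidden = Linear(feat, config.head_hidden, rng=rng)
        self.act = ReLU()
        self.out = Linear(config.head_hidden, 1, rng=rng)
        # target / covariate standardisation, set by the trainer
        self.y_center = 0.0
        self.y_scale = 1.0
        self.cov_center = np.zeros(config.n_covariates, dtype=np.float32)
        self.cov_scale = np.ones(config.n_covariates, dtype=np.float32)

    # -- parameter plumbing -------------------------------------------------

    def layers(self) -> list[Layer]:
        return [*self.conv_blocks, self.readout, self.norm,
                self.hidden, self.act, self.out]

    def params(self) -> list[Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def get_state(self) -> list[np.ndarray]:
        return [p.v.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.v[...] = v

    # -- forward / backward -------------------------------------------------

    def _check_inputs(self, enc: np.ndarray, cov: np.ndarray | None) -> None:
        if enc.ndim != 3 or enc.shape[1] != self.config.length or enc.shape[2] != 4:
            raise ValueError(
                f"encoding shape {enc.shape} incompatible with (B, {self.config.length}, 4)"
            )
        if self.config.mode == "multi":
            if cov is not None:
                raise ValueError("covariates supplied in multi-gene mode")
        else:
            if cov is None and self.config.n_covariates:
                raise ValueError("single-gene mode requires covariates")
            if cov is not None and cov.shape[1] != self.config.n_covariates:
                raise ValueError("covariate dimension mismatch")

    def forward(self, enc: np.ndarray, cov: np.ndarray | None) -> np.ndarray:
        """Standardised-scale forward pass (training units)."""
        self._check_inputs(enc, cov)
        x = np.ascontiguousarray(enc, dtype=np.float32)
        h = x
        for layer in self.conv_blocks:
            h = layer.forward(h)
        if self.conv_blocks and self.config.trunk.input_skip:
            h = np.concatenate([x, h], axis=2)
            self._skip = True
        else:
            self._skip = False
        z = self.readout.forward(h)
        if cov is not None and self.config.n_covariates:
            zc = (cov.astype(np.float32) - self.cov_center) / self.cov_scale
            z = np.concatenate([z, zc], axis=1)
        z = self.norm.forward(z)
        z = self.hidden.forward(z)
        z = self.act.forward(z)
        z = self.out.forward(z)
        return z[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        dz = dpred[:, None].astype(np.float32)
        dz = self.out.backward(dz)
        dz = self.act.backward(dz)
        dz = self.hidden.backward(dz)
        dz = self.norm.backward(dz)
        k = self.config.trunk.readout_channels
        dz = dz[:, :k]  # covariate columns carry no trainable upstream params
        dh = self.readout.backward(dz)
        if self._skip:
            dh = dh[:, :, 4:]
        for layer in reversed(self.conv_blocks):
            dh = layer.backward(dh)

    # -- inference ----------------------------------------------------------

    def predict_batch(self, enc: np.ndarray, cov: np.ndarray | None = None,
                      chunk: int = 256) -> np.ndarray:
        """Predictions in phenotype units, chunked over the batch."""
        self._check_inputs(enc, cov)
        outs = []
        for lo in range(0, enc.shape[0], chunk):
            hi = lo + chunk
            c = cov[lo:hi] if cov is not None else None
            outs.append(self.forward(enc[lo:hi], c))
        raw = np.concatenate(outs) if outs else np.zeros(0)
        return raw.astype(np.float64) * self.y_scale + self.y_center

    def predict(self, encoding, covariates: np.ndarray | None = None) -> float:
        """Single-individual prediction; accepts a PersonalEncoding or array."""
        mat = getattr(encoding, "matrix", encoding)
        cov = None if covariates is None else np.atleast_2d(covariates)
        return float(self.predict_batch(mat[None], cov)[0])


@dataclass
class AffineModel:
    """f(x) = sum_{p,c} w[p,c] x[p,c] + b — the analytic oracle model.

    Exposes the same ``predict_batch`` interface as the trained surrogate
    so ISM and variant-effect routines treat both uniformly.
    """

    weights: np.ndarray  # (L, 4)
    bias: float = 0.0

    def predict_batch(self, enc: np.ndarray, cov: np.ndarray | None = None) -> np.ndarray:
        return np.einsum("blc,lc->b", enc.astype(np.float64), self.weights) + self.bias

    def predict(self, encoding, covariates=None) -> float:
        mat = getattr(encoding, "matrix", encoding)
        return float(self.predict_batch(mat[None])[0])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _standardise_targets(model: ExpressionPredictor, y_train: np.ndarray,
                         cov_train: np.ndarray | None) -> None:
    model.y_center = float(y_train.mean())
    model.y_scale = float(y_train.std()) or 1.0
    if cov_train is not None and cov_train.shape[1]:
        model.cov_center = cov_train.mean(axis=0).astype(np.float32)
        scale = cov_train.std(axis=0)
        scale[scale == 0] = 1.0
        model.cov_scale = scale.astype(np.float32)


def _val_loss(model: ExpressionPredictor, enc, y, cov, alpha: float) -> float:
    pred_std = []
    for lo in range(0, enc.shape[0], 256):
        c = cov[lo:lo + 256] if cov is not None else None
        pred_std.append(model.forward(enc[lo:lo + 256], c))
    pred = np.concatenate(pred_std)
    y_std = (y - model.y_center) / model.y_scale
    return composite_loss(pred, y_std, alpha)


def train_single_gene(data: GeneData, config: ModelConfig) -> tuple[ExpressionPredictor, dict]:
    """Train one single-gene model; returns (best model, history).

    Fully seeded: parameter init and batch shuffling derive from
    ``config.seed``.  The checkpoint with the lowest validation loss is
    restored before returning; training stops early after
    ``config.patience`` epochs without improvement.
    """
    if config.mode != "single":
        raise ValueError("train_single_gene requires mode='single'")
    tr, va = data.indices("train"), data.indices("val")
    if len(tr) == 0 or len(va) == 0:
        raise ValueError("train and validation splits must be non-empty")
    model = ExpressionPredictor(config)
    cov = None if data.covariates is None else np.asarray(data.covariates, dtype=np.float32)
    _standardise_targets(model, data.expression[tr], cov[tr] if cov is not None else None)
    history = _fit(
        model,
        batches=[(data.encodings, data.expression, cov, tr, va)],
        config=config,
        alpha=config.alpha,
    )
    return model, history


def train_multi_gene(datasets: dict[str, GeneData], config: ModelConfig) -> tuple[ExpressionPredictor, dict]:
    """Joint training over genes with a shared head and pairwise-only loss.

    Every batch contains individuals from a single gene; covariates are
    rejected; the loss is the pairwise-difference term alone, so per-gene
    expression offsets are ignored and evaluation on genes absent from
    training is supported.
    """
    if len(datasets) < 2:
        raise ValueError("multi-gene training needs at least 2 genes")
    if config.mode != "multi":
        raise ValueError("train_multi_gene requires mode='multi'")
    for gene, d in datasets.items():
        if d.covariates is not None:
            raise ValueError(f"covariates supplied for gene {gene} in multi-gene mode")
    model = ExpressionPredictor(config)
    # centre each gene's expression by its own training mean so the
    # pairwise loss is exactly invariant to per-gene offsets, then share
    # one pooled scale
    centred = {
        g: d.expression - d.expression[d.indices("train")].mean()
        for g, d in datasets.items()
    }
    pooled = np.concatenate([centred[g][d.indices("train")] for g, d in datasets.items()])
    model.y_center = 0.0
    model.y_scale = float(pooled.std()) or 1.0
    batches = [
        (d.encodings, centred[g], None, d.indices("train"), d.indices("val"))
        for g, d in datasets.items()
    ]
    history = _fit(model, batches=batches, config=config, alpha=0.0)
    return model, history


def _fit(model: ExpressionPredictor, batches, config: ModelConfig, alpha: float) -> dict:
    """Shared epoch loop over one or more (per-gene) data sources."""
    rng = np.random.default_rng(config.seed + 1)
    opt = AdamW(model.params(), betas=(0.9, 0.999), weight_decay=config.weight_decay)

    # enumerate homogeneous micro-batches once to size the schedule
    def epoch_plan():
        plan = []
        for src, (enc, y, cov, tr, va) in enumerate(batches):
            order = rng.permutation(tr)
            for lo in range(0, len(order), config.batch_size):
                idx = order[lo:lo + config.batch_size]
                if len(idx) >= 2 or alpha == 1.0:
                    plan.append((src, idx))
        perm = rng.permutation(len(plan))
        return [plan[i] for i in perm]

    micro_per_epoch = sum(
        len(range(0, len(tr), config.batch_size)) for _, _, _, tr, _ in batches
    )
    steps_per_epoch = max(1, math.ceil(micro_per_epoch / config.accum_steps))
    total_steps = steps_per_epoch * config.epochs

    history = {"train_loss": [], "val_loss": [], "lr": []}
    best = (np.inf, model.get_state())
    bad_epochs = 0
    opt_step = 0
    for epoch in range(config.epochs):
        plan = epoch_plan()
        opt.zero_grad()
        micro = 0
        losses = []
        for src, idx in plan:
            enc, y, cov, _, _ = batches[src]
            c = cov[idx] if cov is not None else None
            pred = model.forward(enc[idx], c)
            y_std = (y[idx] - model.y_center) / model.y_scale
            loss, dpred = composite_loss_grad(pred, y_std, alpha)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, micro-batch {micro} "
                    f"(lr={lr_schedule(opt_step, total_steps, config.lr_peak, config.warmup_frac):.3g})"
                )
            model.backward(dpred / config.accum_steps)
            losses.append(loss)
            micro += 1
            if micro % config.accum_steps == 0:
                lr = lr_schedule(opt_step, total_steps, config.lr_peak, config.warmup_frac)
                opt.step(lr=lr)
                opt.zero_grad()
                opt_step += 1
        if micro % config.accum_steps:
            lr = lr_schedule(opt_step, total_steps, config.lr_peak, config.warmup_frac)
            opt.step(lr=lr)
            opt.zero_grad()
            opt_step += 1

        val = np.mean([
            _val_loss(model, enc[va], y[va], cov[va] if cov is not None else None, alpha)
            for enc, y, cov, _, va in batches
        ])
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val))
        history["lr"].append(lr_schedule(opt_step, total_steps, config.lr_peak, config.warmup_frac))
        if val < best[0] - 1e-9:
            best = (float(val), model.get_state())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    model.set_state(best[1])
    history["best_val_loss"] = best[0]
    return history
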