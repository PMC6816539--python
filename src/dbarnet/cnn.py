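"""U-Net post-processing of low-pass D-bar images, implemented in numpy.

The post-processor ``G_Theta`` maps a blurred D-bar reconstruction to a
sharp conductivity image on the same grid.  Two variants are used: a plain
multiscale encoder--decoder for the thoracic (high-prior) task, and the same
topology with a residual connection (``output = input + correction``) for
the generic low-prior task.  Both use 5x5 convolution kernels and four
max-pool levels.  Training minimizes the squared-l2 loss

    Theta* = argmin_Theta sum_n || G_Theta(sigma_DB_n) - sigma_n ||_2^2

with Adam (initial learning rate 1e-4, batch size 16), monitored on a
held-out validation split (~5% of the training set).

All layers (convolution via im2col/BLAS, 2x2 max pooling, nearest-neighbor
upsampling, ReLU) carry hand-written forward/backward passes in float32;
the implementation is deliberately dependency-free so the full pipeline
runs on a plain scientific-Python stack.  Channel widths, activations and
padding are configurable through :class:`ArchitectureSpec`; defaults are
desk-scale (they train in minutes on one CPU).

Robustness probes: :func:`adversarial_perturbation` runs gradient ascent on
``||G(x + d) - G(x)||^2 - alpha ||d||^2`` to exhibit input perturbations
that maximally change the output, and :func:`garbage_test` feeds the
network structured noise to expose what image prior it has internalized.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ContractViolation

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "NetworkParams",
    "build_network",
    "train",
    "predict",
    "adversarial_perturbation",
    "garbage_test",
    "save_checkpoint",
    "load_checkpoint",
]

_F32 = np.float32


# ---------------------------------------------------------------------------
# layers (NHWC layout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, kh*kw*C) patches with zero 'same' padding."""
    B, H, W, C = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.zeros((B, H + 2 * ph, W + 2 * pw, C), dtype=x.dtype)
    xp[:, ph:ph + H, pw:pw + W, :] = x
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(B, H, W, kh, kw, C),
        strides=(s[0], s[1], s[2], s[1], s[2], s[3]), writeable=False)
    return view.reshape(B * H * W, kh * kw * C)


def _conv2d(x, W, b, return_cols: bool = False):
    B, H, Wd, Cin = x.shape
    kh, kw, _, Cout = W.shape
    cols = _im2col(x, kh, kw)
    y = cols @ W.reshape(kh * kw * Cin, Cout)
    if b is not None:
        y += b
    y = y.reshape(B, H, Wd, Cout)
    return (y, cols) if return_cols else y


def _conv2d_backward(cols, in_shape, W, dy):
    """Gradients (dx, dW, db) of a same-padded convolution.

    ``cols`` are the im2col patches cached from the forward pass.
    """
    B, H, Wd, Cin = in_shape
    kh, kw, _, Cout = W.shape
    dym = dy.reshape(B * H * Wd, Cout)
    dW = (cols.T @ dym).reshape(kh, kw, Cin, Cout)
    db = dym.sum(axis=0)
    # dx: full correlation of dy with the flipped kernel
    Wflip = W[::-1, ::-1].transpose(0, 1, 3, 2).copy()  # (kh, kw, Cout, Cin)
    dx = _conv2d(dy, Wflip, None)
    return dx, dW, db


def _maxpool(x):
    B, H, W, C = x.shape
    xr = x.reshape(B, H // 2, 2, W // 2, 2, C)
    flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(B, H // 2, W // 2, C, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _maxpool_backward(dy, idx, in_shape):
    B, H, W, C = in_shape
    flat = np.zeros((B, H // 2, W // 2, C, 4), dtype=dy.dtype)
    np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
    xr = flat.reshape(B, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return xr.reshape(B, H, W, C)


def _upsample(x):
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample_backward(dy):
    B, H, W, C = dy.shape
    return dy.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """U-Net topology: 5x5 kernels, four pooling levels, skip connections.

    ``residual`` selects the low-prior variant (output = input +
    correction, final layer zero-initialized so the net starts at the
    identity).  ``base_channels`` is the width of the top level; widths
    double at each of the ``pool_levels`` coarser scales.  Skip connections
    are additive (a 1x1 projection aligns channel counts after upsampling),
    activations are ReLU, padding is zero.
    """

    kernel_size: int = 5
    pool_levels: int = 4
    residual: bool = False
    base_channels: int = 16

    def __post_init__(self):
        if self.pool_levels < 1:
            raise ConfigurationError("need at least one pooling level")
        if self.kernel_size % 2 != 1:
            raise ConfigurationError("kernel size must be odd")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")

    def channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.pool_levels + 1)]

    def check_input(self, n: int):
        if n % 2**self.pool_levels:
            raise ConfigurationError(
                f"grid size {n} not divisible by 2^{self.pool_levels}")


@dataclass
class TrainingConfig:
    """Optimization settings (Adam, squared-l2 loss)."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    iterations: int = 2000
    validation_fraction: float = 0.05
    seed: int = 0
    checkpoint_every: int = 200

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch size must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ConfigurationError("validation fraction must be in (0, 1)")


@dataclass
class NetworkParams:
    """Learnable parameters of ``G_Theta`` plus training-state metadata."""

    spec: ArchitectureSpec
    weights: dict[str, np.ndarray]
    seed: int = 0
    iteration: int = 0
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.spec, {k: v.copy() for k, v in self.weights.items()},
                             self.seed, self.iteration,
                             list(self.train_loss), list(self.val_loss))


def _he_init(rng, shape):
    fan_in = int(np.prod(shape[:-1]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_F32)


def build_network(spec: ArchitectureSpec, seed: int = 0,
                  final_zero_init: bool = False) -> NetworkParams:
    """Deterministically initialized parameters for the given topology.

    He-normal filters.  With ``final_zero_init`` the output layer starts at
    zero, which makes the residual variant exactly the identity map (at the
    cost of blocking gradient flow to earlier layers for the first steps;
    off by default).
    """
    rng = np.random.default_rng(seed)
    k = spec.kernel_size
    ch = spec.channels()
    w: dict[str, np.ndarray] = {}
    cin = 1
    for lev, c in enumerate(ch):
        w[f"enc{lev}_W"] = _he_init(rng, (k, k, cin, c))
        w[f"enc{lev}_b"] = np.zeros(c, dtype=_F32)
        cin = c
    for lev in range(spec.pool_levels - 1, -1, -1):
        cup, c = ch[lev + 1], ch[lev]
        w[f"proj{lev}_W"] = _he_init(rng, (1, 1, cup, c))
        w[f"proj{lev}_b"] = np.zeros(c, dtype=_F32)
        w[f"dec{lev}_W"] = _he_init(rng, (k, k, c, c))
        w[f"dec{lev}_b"] = np.zeros(c, dtype=_F32)
    w["out_W"] = _he_init(rng, (k, k, ch[0], 1))
    w["out_b"] = np.zeros(1, dtype=_F32)
    if spec.residual:
        # start near the identity so early predictions stay sane
        w["out_W"] *= 0.1
    if final_zero_init:
        w["out_W"][:] = 0.0
    return NetworkParams(spec, w, seed=seed)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _forward(params: NetworkParams, x: np.ndarray, want_cache: bool = False):
    """``x``: (B, n, n) float32.  Returns (y, cache)."""
    spec = params.spec
    w = params.weights
    spec.check_input(x.shape[-1])
    h = x[..., None].astype(_F32)
    cache = {} if want_cache else None

    def conv(name, inp):
        if want_cache:
            y, cols = _conv2d(inp, w[f"{name}_W"], w[f"{name}_b"], return_cols=True)
            cache[f"{name}_cols"] = cols
            cache[f"{name}_shape"] = inp.shape
            return y
        return _conv2d(inp, w[f"{name}_W"], w[f"{name}_b"])

    skips = []
    for lev in range(spec.pool_levels + 1):
        pre = conv(f"enc{lev}", h)
        act = np.maximum(pre, 0.0)
        if want_cache:
            cache[f"enc{lev}_pre"] = pre
        if lev < spec.pool_levels:
            skips.append(act)
            h, idx = _maxpool(act)
            if want_cache:
                cache[f"pool{lev}_idx"] = idx
                cache[f"pool{lev}_shape"] = act.shape
        else:
            h = act
    for lev in range(spec.pool_levels - 1, -1, -1):
        up = _upsample(h)
        proj = conv(f"proj{lev}", up)
        merged = proj + skips[lev]
        pre = conv(f"dec{lev}", merged)
        act = np.maximum(pre, 0.0)
        if want_cache:
            cache[f"dec{lev}_pre"] = pre
        h = act
    y = conv("out", h)[..., 0]
    if spec.residual:
        y = y + x.astype(_F32)
    return y, cache


def _backward(params: NetworkParams, cache: dict, dy: np.ndarray):
    """Gradients of a scalar loss w.r.t. weights and the input image."""
    spec = params.spec
    w = params.weights
    grads: dict[str, np.ndarray] = {}
    d = dy[..., None].astype(_F32)
    dx_res = dy.astype(_F32) if spec.residual else 0.0

    def conv_bwd(name, dout):
        dx, gW, gb = _conv2d_backward(cache[f"{name}_cols"],
                                      cache[f"{name}_shape"],
                                      w[f"{name}_W"], dout)
        grads[f"{name}_W"] = gW
        grads[f"{name}_b"] = gb
        return dx

    d = conv_bwd("out", d)
    dskips = {}
    for lev in range(spec.pool_levels):
        d = d * (cache[f"dec{lev}_pre"] > 0)
        d = conv_bwd(f"dec{lev}", d)
        dskips[lev] = d  # additive skip: gradient flows to the encoder too
        d = conv_bwd(f"proj{lev}", d)
        d = _upsample_backward(d)
    for lev in range(spec.pool_levels, -1, -1):
        if lev < spec.pool_levels:
            d = _maxpool_backward(d, cache[f"pool{lev}_idx"],
                                  cache[f"pool{lev}_shape"])
            d = d + dskips[lev]
        d = d * (cache[f"enc{lev}_pre"] > 0)
        d = conv_bwd(f"enc{lev}", d)
    dx = d[..., 0] + dx_res
    return grads, dx


def predict(params: NetworkParams, x: np.ndarray,
            floor: float | None = 1e-3) -> np.ndarray:
    """Apply ``G_Theta``; accepts (n, n) or (B, n, n), order preserved.

    Outputs are clipped below at ``floor`` (conductivities are positive;
    pass ``floor=None`` for the raw network output).
    """
    x = np.asarray(x, dtype=_F32)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim != 3 or x.shape[1] != x.shape[2]:
        raise ContractViolation("input must be square image(s)")
    outs = []
    for start in range(0, x.shape[0], 64):
        y, _ = _forward(params, x[start:start + 64])
        outs.append(y)
    y = np.concatenate(outs, axis=0)
    if floor is not None:
        y = np.maximum(y, floor)
    return y[0] if single else y


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, weights, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            weights[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def _loss_and_grad(params, x, y):
    pred, cache = _forward(params, x, want_cache=True)
    diff = pred - y.astype(_F32)
    loss = float(np.mean(np.sum(diff**2, axis=(1, 2))))
    dy = (2.0 / x.shape[0]) * diff
    grads, _ = _backward(params, cache, dy)
    return loss, grads


def train(inputs: np.ndarray, targets: np.ndarray,
          spec: ArchitectureSpec | None = None,
          config: TrainingConfig | None = None,
          params: NetworkParams | None = None) -> NetworkParams:
    """Train ``G_Theta`` on paired images (D-bar reconstruction, truth).

    ``inputs`` and ``targets``: (N, n, n) on a common grid.  A disjoint
    validation split of ``config.validation_fraction`` is held out and its
    loss logged at every checkpoint.  Deterministic given ``config.seed``
    (split, initialization, batch order).  Raises on divergence, carrying
    the last finite checkpoint.
    """
    config = config or TrainingConfig()
    spec = spec or ArchitectureSpec()
    inputs = np.asarray(inputs, dtype=_F32)
    targets = np.asarray(targets, dtype=_F32)
    if inputs.shape != targets.shape or inputs.ndim != 3:
        raise ContractViolation("inputs/targets must be matching (N, n, n) stacks")
    rng = np.random.default_rng(config.seed)
    N = inputs.shape[0]
    n_val = max(1, int(round(config.validation_fraction * N)))
    perm = rng.permutation(N)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if params is None:
        params = build_network(spec, seed=config.seed)
    opt = _Adam(params.weights, config.learning_rate)
    last_good = params.copy()
    for it in range(config.iterations):
        batch = rng.choice(tr_idx, size=min(config.batch_size, tr_idx.size),
                           replace=False)
        loss, grads = _loss_and_grad(params, inputs[batch], targets[batch])
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at iteration {it}; last good checkpoint "
                f"at iteration {last_good.iteration}")
        opt.step(params.weights, grads)
        params.iteration = it + 1
        params.train_loss.append(loss)
        if (it + 1) % config.checkpoint_every == 0 or it + 1 == config.iterations:
            vp = predict(params, inputs[val_idx], floor=None)
            vloss = float(np.mean(np.sum((vp - targets[val_idx])**2, axis=(1, 2))))
            params.val_loss.append((it + 1, vloss))
            last_good = params.copy()
    return params


# ---------------------------------------------------------------------------
# robustness probes
# ---------------------------------------------------------------------------

def adversarial_perturbation(params: NetworkParams, x: np.ndarray,
                             alpha: float = 1.0, steps: int = 200,
                             step_size: float = 1e-2, max_step: float = 0.1,
                             snapshot_fractions=(0.1, 1.0)):
    """Gradient ascent on ``||G(x+d) - G(x)||^2 - alpha ||d||^2`` from d=0.

    The ascent moves along the *normalized* gradient with a backtracked,
    capped step, which keeps the objective trace non-decreasing and the
    perturbation magnitude controlled (for a piecewise-linear network the
    objective is unbounded above whenever the local gain exceeds
    ``sqrt(alpha)``, so an uncapped ascent diverges).  Returns
    ``(snapshots, trace)``: perturbations at the requested fractions of the
    ascent (early = "small", late = "large"), and the objective per step.
    """
    if alpha <= 0:
        raise ConfigurationError("alpha must be positive")
    x = np.asarray(x, dtype=_F32)
    if x.ndim == 2:
        x = x[None]
    y0, _ = _forward(params, x)
    delta = np.zeros_like(x)

    def objective(d):
        yd, cache = _forward(params, x + d, want_cache=True)
        diff = yd - y0
        val = float(np.sum(diff.astype(np.float64) ** 2)
                    - alpha * np.sum(d.astype(np.float64) ** 2))
        return val, diff, cache

    obj, diff, cache = objective(delta)
    trace = [obj]
    snaps = {}
    marks = sorted(set(max(1, int(round(f * steps))) for f in snapshot_fractions))
    step = step_size
    for it in range(1, steps + 1):
        _, dx = _backward(params, cache, 2.0 * diff)
        grad = dx - 2.0 * alpha * delta
        gnorm = float(np.linalg.norm(grad))
        if gnorm == 0.0:
            # objective and gradient both vanish at d = 0: seed the ascent
            grad = np.full_like(delta, 1.0)
            gnorm = float(np.linalg.norm(grad))
        direction = grad / gnorm
        accepted = False
        for _ in range(20):
            cand = delta + step * direction
            val, diff_c, cache_c = objective(cand)
            if val >= obj:
                delta, obj, diff, cache = cand, val, diff_c, cache_c
                accepted = True
                step = min(step * 1.2, max_step)
                break
            step *= 0.5
        trace.append(obj)
        if it in marks:
            snaps[it] = delta.copy()
        if not accepted:
            # stationary point: keep the trace flat for the remaining steps
            for jt in marks:
                if jt >= it and jt not in snaps:
                    snaps[jt] = delta.copy()
            trace.extend([obj] * (steps - it))
            break
    snapshots = [snaps[m] for m in marks if m in snaps]
    return snapshots, np.asarray(trace)


def garbage_test(params: NetworkParams, noise_spec: str, shape: tuple,
                 rng: np.random.Generator,
                 input_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Feed the network structured noise and return its outputs.

    ``noise_spec``: ``"uniform"`` draws noise spanning exactly the given
    ``input_range`` (the range of the training D-bar images);
    ``"gaussian"`` draws zero-mean Gaussian noise (includes negative
    values, i.e. outside the training range).
    """
    lo, hi = input_range
    if noise_spec == "uniform":
        x = rng.uniform(lo, hi, size=shape)
    elif noise_spec == "gaussian":
        scale = max(abs(hi - lo) / 2.0, 1e-6)
        x = rng.normal(0.0, scale, size=shape)
    else:
        raise ConfigurationError("noise_spec must be 'uniform' or 'gaussian'")
    return predict(params, x.astype(_F32), floor=None)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(params: NetworkParams, path: str):
    meta = dict(spec=asdict(params.spec), seed=params.seed,
                iteration=params.iteration,
                val_loss=params.val_loss)
    np.savez(path, __meta__=json.dumps(meta), **params.weights)


def load_checkpoint(path: str) -> NetworkParams:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        weights = {k: data[k] for k in data.files if k != "__meta__"}
    spec = ArchitectureSpec(**meta["spec"])
    p = NetworkParams(spec, weights, seed=meta["seed"],
                      iteration=meta["iteration"])
    p.val_loss = [tuple(v) for v in meta["val_loss"]]
    return p
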