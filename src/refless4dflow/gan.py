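"""Reference-encoding prediction: 3D U-Net generator, conditional adversarial
and velocity-weighted training, and fold-ensembled inference.

The task is image-to-image translation: map the six real/imaginary channels
of the three motion encodings to the two real/imaginary channels of the
(missing) reference encoding.  Two training strategies are provided:

* ``adversarial`` — the U-Net is the generator of a conditional GAN; a
  patch-wise convolutional discriminator sees the six conditioning channels
  concatenated with real or generated reference channels, and the generator
  loss is the sum of an L1 term and a binary cross-entropy (with logits) term
  for the generated image to be classified as real.
* ``velocity_weighted`` — no discriminator; the L1 loss is weighted per voxel
  by the homogeneous velocity weighting of :mod:`refless4dflow.weighting`.

Networks are width/depth-configurable so toy instances train on a CPU; the
defaults of :class:`TrainConfig` record the full-scale protocol, while
:class:`ReferencePredictor` (the scikit-learn-style estimator) defaults to a
desk-scale configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from . import nn
from .nn.losses import l1_loss, weighted_l1_loss, bce_with_logits
from .recon import EncodingSet, normalize_and_centralize, reconstruct_velocity
from .weighting import VelocityHistogram, velocity_histogram, compute_weights

IN_CHANNELS = 6      # (real, imag) x 3 motion encodings
OUT_CHANNELS = 2     # (real, imag) of the reference encoding


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """U-Net shape; ``depth`` counts resolution levels (full scale: 5)."""

    depth: int = 5
    base_channels: int = 8
    norm: str = "none"              # "none" | "instance"
    activation: str = "relu"        # "relu" | "leaky_relu"

    def __post_init__(self) -> None:
        if self.norm not in ("none", "instance"):
            raise ValueError("norm must be 'none' or 'instance'")
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError("activation must be 'relu' or 'leaky_relu'")


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Patch-wise convolutional classifier (full scale: 4 layers)."""

    n_layers: int = 4
    base_channels: int = 8
    conditioned: bool = True        # input = 6 conditioning + 2 reference channels


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol; defaults record the full-scale recipe
    (64x64x32 patches, batch 8, 2500 adversarial / 8000 weighted epochs,
    AdamW at 0.002 held for 1000 / 4000 epochs then linearly decayed to 0,
    5-fold cross-validation)."""

    mode: str = "adversarial"       # "adversarial" | "velocity_weighted"
    patch_size: tuple[int, int, int] = (64, 64, 32)
    batch_size: int = 8
    epochs: int = 2500
    lr: float = 0.002
    lr_constant_epochs: int = 1000
    weight_decay: float = 0.01
    l1_weight: float = 1.0
    adv_weight: float = 1.0
    folds: int = 5
    dev_interval: int = 50
    augment_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("adversarial", "velocity_weighted"):
            raise ValueError("mode must be 'adversarial' or 'velocity_weighted'")
        if self.epochs < self.lr_constant_epochs:
            raise ValueError("epochs must be >= lr_constant_epochs")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Constant at cfg.lr up to lr_constant_epochs, then linear decay to 0."""
    if epoch <= cfg.lr_constant_epochs:
        return cfg.lr
    span = cfg.epochs - cfg.lr_constant_epochs
    return cfg.lr * max(0.0, 1.0 - (epoch - cfg.lr_constant_epochs) / span)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _block(cin: int, cout: int, cfg: GeneratorConfig, rng) -> nn.Sequential:
    act = nn.ReLU if cfg.activation == "relu" else nn.LeakyReLU
    layers: list[nn.Layer] = []
    for c_in in (cin, cout):
        layers.append(nn.Conv3d(c_in, cout, 3, rng=rng))
        if cfg.norm == "instance":
            layers.append(nn.InstanceNorm3d(cout))
        layers.append(act())
    return nn.Sequential(*layers)


class UNet3D(nn.Layer):
    """Encoder-decoder with skip connections over ``depth`` resolution levels."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator | None = None,
                 in_channels: int = IN_CHANNELS, out_channels: int = OUT_CHANNELS):
        rng = rng or np.random.default_rng()
        self.config = config
        self.depth = config.depth
        chans = [config.base_channels * 2 ** i for i in range(config.depth)]
        self.enc_channels = chans[:-1]
        self.enc_blocks, self.pools, self.ups, self.dec_blocks = [], [], [], []
        cin = in_channels
        for c in chans[:-1]:
            self.enc_blocks.append(_block(cin, c, config, rng))
            self.pools.append(nn.AvgPool3d())
            cin = c
        self.bottleneck = _block(cin, chans[-1], config, rng)
        for i in range(config.depth - 1):
            c_up = chans[i + 1]
            self.ups.append(nn.Upsample3d())
            self.dec_blocks.append(_block(chans[i] + c_up, chans[i], config, rng))
        self.final = nn.Conv3d(chans[0], out_channels, 1, rng=rng)

    def parameters(self):
        ps = []
        for blk in self.enc_blocks:
            ps += blk.parameters()
        ps += self.bottleneck.parameters()
        for blk in self.dec_blocks:
            ps += blk.parameters()
        ps += self.final.parameters()
        return ps

    def check_shape(self, spatial: tuple[int, int, int]) -> None:
        f = 2 ** (self.depth - 1)
        if any(s % f or s < f for s in spatial):
            raise ValueError(
                f"spatial shape {spatial} must be divisible by {f} for depth "
                f"{self.depth}")

    def forward(self, x):
        self.check_shape(x.shape[2:])
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for i in reversed(range(self.depth - 1)):
            x = self.ups[i].forward(x)
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec_blocks[i].forward(x)
        return self.final.forward(x)

    def backward(self, grad):
        grad = self.final.backward(grad)
        skip_grads = [None] * (self.depth - 1)
        for i in range(self.depth - 1):
            grad = self.dec_blocks[i].backward(grad)
            c = self.enc_channels[i]
            skip_grads[i] = grad[:, :c]
            grad = self.ups[i].backward(grad[:, c:])
        grad = self.bottleneck.backward(grad)
        for i in reversed(range(self.depth - 1)):
            grad = self.pools[i].backward(grad)
            grad = grad + skip_grads[i]
            grad = self.enc_blocks[i].backward(grad)
        return grad


class PatchDiscriminator(nn.Layer):
    """Convolutional classifier emitting a patch-wise real/fake logit map."""

    def __init__(self, config: DiscriminatorConfig,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.config = config
        cin = IN_CHANNELS + OUT_CHANNELS if config.conditioned else OUT_CHANNELS
        layers: list[nn.Layer] = []
        c = config.base_channels
        for _ in range(config.n_layers):
            layers += [nn.Conv3d(cin, c, 3, rng=rng), nn.LeakyReLU(0.2),
                       nn.AvgPool3d()]
            cin, c = c, min(2 * c, 8 * config.base_channels)
        layers.append(nn.Conv3d(cin, 1, 3, rng=rng))
        self.net = nn.Sequential(*layers)

    def parameters(self):
        return self.net.parameters()

    def forward(self, x):
        return self.net.forward(x)

    def backward(self, grad):
        return self.net.backward(grad)


# ---------------------------------------------------------------------------
# training data handling
# ---------------------------------------------------------------------------

@dataclass
class TrainingSubject:
    """Preprocessed volumes of one subject, ready for patch sampling.

    ``inputs``: (6, T, X, Y, Z) motion-encoding real/imag channels (order
    enc1_re, enc1_im, enc2_re, enc2_im, enc3_re, enc3_im);
    ``target``: (2, T, X, Y, Z) reference real/imag;
    ``weights``: optional (T, X, Y, Z) per-voxel loss weights.
    """

    inputs: np.ndarray
    target: np.ndarray
    weights: np.ndarray | None = None
    subject_id: str = ""


def encoding_set_to_arrays(es: EncodingSet) -> tuple[np.ndarray, np.ndarray]:
    """Split a (preprocessed) EncodingSet into network input/target stacks."""
    inputs = np.empty((6,) + es.real.shape[1:])
    inputs[0::2] = es.real[1:4]
    inputs[1::2] = es.imag[1:4]
    target = np.stack([es.real[0], es.imag[0]])
    return inputs, target


def make_training_subjects(encoding_sets: list[EncodingSet], mode: str,
                           subject_ids: list[str] | None = None
                           ) -> tuple[list[TrainingSubject], VelocityHistogram | None]:
    """Preprocess raw encoding sets and, for the weighted mode, attach
    homogeneous velocity weights (speed bins from the 4-point reconstruction
    of the raw data, M = preprocessed reference magnitude)."""
    speeds = []
    prepped = []
    for es in encoding_sets:
        pre = normalize_and_centralize(es)
        prepped.append(pre)
        if mode == "velocity_weighted":
            vf = reconstruct_velocity(es)
            speeds.append(np.sqrt((vf.v ** 2).sum(axis=0)))
    hist = None
    if mode == "velocity_weighted":
        venc = encoding_sets[0].venc_m_s
        hist = velocity_histogram(np.concatenate([s.ravel() for s in speeds]), venc)
    subjects = []
    for i, pre in enumerate(prepped):
        inputs, target = encoding_set_to_arrays(pre)
        weights = None
        if hist is not None:
            mag = np.abs(target[0] + 1j * target[1])
            weights = compute_weights(hist, speeds[i], mag)
        sid = subject_ids[i] if subject_ids else f"sub{i:03d}"
        subjects.append(TrainingSubject(inputs=inputs, target=target,
                                        weights=weights, subject_id=sid))
    return subjects, hist


def sample_patch(subject: TrainingSubject, patch_size: tuple[int, int, int],
                 rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Draw one (input, target, weights) patch from a uniform timeframe and
    uniform spatial origin."""
    shape = subject.inputs.shape[2:]
    if any(p > s for p, s in zip(patch_size, shape)):
        raise ValueError(f"patch {patch_size} exceeds volume {shape}")
    t = int(rng.integers(subject.inputs.shape[1]))
    org = tuple(int(rng.integers(s - p + 1)) for s, p in zip(shape, patch_size))
    sl = tuple(slice(o, o + p) for o, p in zip(org, patch_size))
    x = subject.inputs[(slice(None), t) + sl]
    y = subject.target[(slice(None), t) + sl]
    w = subject.weights[(t,) + sl] if subject.weights is not None else None
    return x, y, w


def augment(volumes: np.ndarray, rng: np.random.Generator,
            p_flip: float = 0.5, p_rotate: float = 0.5, p_zoom: float = 0.5,
            max_angle_deg: float = 10.0, zoom_range: tuple[float, float] = (0.9, 1.1)
            ) -> np.ndarray:
    """Random rotation, per-axis flips and isotropic zoom of a (C, X, Y, Z)
    channel stack; all channels transform identically, applied before patch
    selection.  With all probabilities zero this is the identity."""
    out = volumes
    if p_rotate > 0 and rng.random() < p_rotate:
        angle = rng.uniform(-max_angle_deg, max_angle_deg)
        axes = [(1, 2), (1, 3), (2, 3)][int(rng.integers(3))]
        if angle != 0.0:
            out = ndimage.rotate(out, angle, axes=axes, reshape=False, order=1,
                                 mode="nearest")
    for axis in (1, 2, 3):
        if p_flip > 0 and rng.random() < p_flip:
            out = np.flip(out, axis=axis)
    if p_zoom > 0 and rng.random() < p_zoom:
        z = rng.uniform(*zoom_range)
        if z != 1.0:
            out = _zoom_keep_shape(out, z)
    return np.ascontiguousarray(out)


def _zoom_keep_shape(vol: np.ndarray, factor: float) -> np.ndarray:
    zoomed = ndimage.zoom(vol, (1.0, factor, factor, factor), order=1,
                          mode="nearest")
    out = np.zeros_like(vol)
    src, dst = [slice(None)], [slice(None)]
    for s_out, s_in in zip(vol.shape[1:], zoomed.shape[1:]):
        if s_in >= s_out:
            o = (s_in - s_out) // 2
            src.append(slice(o, o + s_out))
            dst.append(slice(None))
        else:
            o = (s_out - s_in) // 2
            src.append(slice(None))
            dst.append(slice(o, o + s_in))
    out[tuple(dst)] = zoomed[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# public loss surface
# ---------------------------------------------------------------------------

def generator_loss(pred: np.ndarray, target: np.ndarray,
                   disc_logits_on_fake: np.ndarray | None = None,
                   weights: np.ndarray | None = None,
                   mode: str = "adversarial",
                   l1_weight: float = 1.0, adv_weight: float = 1.0) -> float:
    """Generator objective value.

    Adversarial mode: l1_weight * mean|pred - target| + adv_weight *
    BCE-with-logits(disc logits on the fake, label=real).  Weighted mode:
    sum w|pred - target| / sum w, no adversarial term.
    """
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes disagree")
    if mode == "velocity_weighted":
        if weights is None:
            raise ValueError("weighted mode needs weights")
        value, _ = weighted_l1_loss(pred, target, weights)
        return value
    if disc_logits_on_fake is None:
        raise ValueError("adversarial mode needs discriminator logits")
    l1_val, _ = l1_loss(pred, target)
    adv_val, _ = bce_with_logits(disc_logits_on_fake, 1.0)
    return l1_weight * l1_val + adv_weight * adv_val


def discriminator_loss(logits_real: np.ndarray, logits_fake: np.ndarray) -> float:
    """0.5 * [BCE(logits_real, real) + BCE(logits_fake, fake)]."""
    if np.shape(logits_real) != np.shape(logits_fake):
        raise ValueError("logit shapes disagree")
    r, _ = bce_with_logits(logits_real, 1.0)
    f, _ = bce_with_logits(logits_fake, 0.0)
    return 0.5 * (r + f)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class ReferencePredictor(BaseEstimator):
    """Scikit-learn-style estimator predicting the reference encoding.

    ``fit`` takes a list of raw :class:`EncodingSet` (with an acquired
    reference at index 0) or prebuilt :class:`TrainingSubject` objects and
    trains one U-Net per cross-validation fold; ``predict`` takes an
    :class:`EncodingSet` and returns the fold-averaged 2-channel reference in
    the preprocessed space, shape (2, T, X, Y, Z).

    Defaults are desk-scale (CPU); pass the :class:`TrainConfig` /
    :class:`GeneratorConfig` values for the full-scale recipe.
    """

    def __init__(self, mode: str = "adversarial", depth: int = 3,
                 base_channels: int = 8, norm: str = "none",
                 activation: str = "relu", disc_layers: int = 2,
                 disc_channels: int = 8,
                 patch_size: tuple[int, int, int] = (16, 16, 16),
                 batch_size: int = 4, epochs: int = 100, lr: float = 0.002,
                 lr_constant_epochs: int = 50, weight_decay: float = 0.01,
                 l1_weight: float = 1.0, adv_weight: float = 1.0,
                 folds: int = 1, dev_interval: int = 10,
                 augment_prob: float = 0.0, tile_overlap: int = 8,
                 seed: int = 0):
        self.mode = mode
        self.depth = depth
        self.base_channels = base_channels
        self.norm = norm
        self.activation = activation
        self.disc_layers = disc_layers
        self.disc_channels = disc_channels
        self.patch_size = patch_size
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr = lr
        self.lr_constant_epochs = lr_constant_epochs
        self.weight_decay = weight_decay
        self.l1_weight = l1_weight
        self.adv_weight = adv_weight
        self.folds = folds
        self.dev_interval = dev_interval
        self.augment_prob = augment_prob
        self.tile_overlap = tile_overlap
        self.seed = seed

    # -- configuration plumbing -------------------------------------------
    def _train_config(self) -> TrainConfig:
        return TrainConfig(mode=self.mode, patch_size=tuple(self.patch_size),
                           batch_size=self.batch_size, epochs=self.epochs,
                           lr=self.lr, lr_constant_epochs=self.lr_constant_epochs,
                           weight_decay=self.weight_decay,
                           l1_weight=self.l1_weight, adv_weight=self.adv_weight,
                           folds=self.folds, dev_interval=self.dev_interval,
                           augment_prob=self.augment_prob, seed=self.seed)

    def _generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(depth=self.depth, base_channels=self.base_channels,
                               norm=self.norm, activation=self.activation)

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        if isinstance(X[0], EncodingSet):
            subjects, hist = make_training_subjects(list(X), self.mode)
        else:
            subjects, hist = list(X), None
        if self.mode == "velocity_weighted" and subjects[0].weights is None:
            raise ValueError("velocity_weighted mode needs subjects with weights")
        cfg = self._train_config()
        self.histogram_ = hist
        self.models_ = []
        self.history_ = []
        n = len(subjects)
        folds = max(1, min(cfg.folds, n))
        root = np.random.SeedSequence(cfg.seed)
        fold_seeds = [int(c.generate_state(1)[0] % 2 ** 31) for c in root.spawn(folds)]
        for k in range(folds):
            if folds == 1 or n == 1:
                train_idx = list(range(n))
                dev_idx = list(range(n))
            else:
                dev_idx = list(range(k, n, folds))
                train_idx = [i for i in range(n) if i not in dev_idx]
            model, hist_k = self._fit_fold(
                [subjects[i] for i in train_idx], [subjects[i] for i in dev_idx],
                cfg, fold_seeds[k])
            self.models_.append(model)
            self.history_.append(hist_k)
        return self

    def _fit_fold(self, train_subjects, dev_subjects, cfg: TrainConfig, seed: int):
        rng = np.random.default_rng(seed)
        gen = UNet3D(self._generator_config(), rng=rng)
        gen.check_shape(cfg.patch_size)
        opt_g = nn.AdamW(gen.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        disc = opt_d = None
        if cfg.mode == "adversarial":
            disc = PatchDiscriminator(
                DiscriminatorConfig(n_layers=self.disc_layers,
                                    base_channels=self.disc_channels), rng=rng)
            opt_d = nn.AdamW(disc.parameters(), lr=cfg.lr,
                             weight_decay=cfg.weight_decay)
        history = {"epoch": [], "gen_loss": [], "disc_loss": [], "lr": [],
                   "dev_epoch": [], "dev_mae": [], "dev_mse": []}
        self._record_dev(gen, dev_subjects, -1, history)
        for epoch in range(cfg.epochs):
            lr = lr_schedule(epoch, cfg)
            opt_g.lr = lr
            if opt_d is not None:
                opt_d.lr = lr
            order = rng.permutation(len(train_subjects))
            ep_gen, ep_disc, n_batches = 0.0, 0.0, 0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xs, ys, ws = [], [], []
                for i in idx:
                    sub = train_subjects[i]
                    x, y, w = self._draw(sub, cfg, rng)
                    xs.append(x)
                    ys.append(y)
                    ws.append(w)
                x = np.stack(xs)
                y = np.stack(ys)
                w = np.stack(ws)[:, None] if ws[0] is not None else None
                g_val, d_val = self._step(gen, disc, opt_g, opt_d, x, y, w, cfg)
                if not np.isfinite(g_val):
                    raise RuntimeError(f"NaN/inf generator loss at epoch {epoch}")
                ep_gen += g_val
                ep_disc += d_val
                n_batches += 1
            history["epoch"].append(epoch)
            history["gen_loss"].append(ep_gen / n_batches)
            history["disc_loss"].append(ep_disc / n_batches if disc else np.nan)
            history["lr"].append(lr)
            if (epoch + 1) % cfg.dev_interval == 0 or epoch == cfg.epochs - 1:
                self._record_dev(gen, dev_subjects, epoch, history)
        return gen, history

    def _draw(self, sub: TrainingSubject, cfg: TrainConfig, rng):
        if cfg.augment_prob > 0 and rng.random() < cfg.augment_prob:
            t = int(rng.integers(sub.inputs.shape[1]))
            chans = [sub.inputs[:, t], sub.target[:, t]]
            if sub.weights is not None:
                chans.append(sub.weights[None, t])
            stacked = augment(np.concatenate(chans, axis=0), rng)
            w3 = stacked[8] if sub.weights is not None else None
            tmp = TrainingSubject(inputs=stacked[None, :6].swapaxes(0, 1),
                                  target=stacked[None, 6:8].swapaxes(0, 1),
                                  weights=w3[None] if w3 is not None else None)
            return sample_patch(tmp, cfg.patch_size, rng)
        return sample_patch(sub, cfg.patch_size, rng)

    def _step(self, gen, disc, opt_g, opt_d, x, y, w, cfg: TrainConfig):
        # generator update
        opt_g.zero_grad()
        pred = gen.forward(x)
        if cfg.mode == "velocity_weighted":
            val, grad = weighted_l1_loss(pred, y, np.broadcast_to(w, pred.shape))
            gen.backward(grad)
            opt_g.step()
            return val, 0.0
        logits_fake = disc.forward(np.concatenate([x, pred], axis=1))
        l1_val, g_l1 = l1_loss(pred, y)
        adv_val, g_z = bce_with_logits(logits_fake, 1.0)
        g_fake_in = disc.backward(cfg.adv_weight * g_z)   # pollutes disc grads,
        grad_pred = cfg.l1_weight * g_l1 + g_fake_in[:, IN_CHANNELS:]
        gen.backward(grad_pred)
        opt_g.step()
        # discriminator update (zero_grad clears the pollution above)
        opt_d.zero_grad()
        logits_real = disc.forward(np.concatenate([x, y], axis=1))
        r_val, g_r = bce_with_logits(logits_real, 1.0)
        disc.backward(0.5 * g_r)
        logits_fake2 = disc.forward(np.concatenate([x, pred], axis=1))
        f_val, g_f = bce_with_logits(logits_fake2, 0.0)
        disc.backward(0.5 * g_f)
        opt_d.step()
        return cfg.l1_weight * l1_val + cfg.adv_weight * adv_val, 0.5 * (r_val + f_val)

    def _record_dev(self, gen, dev_subjects, epoch, history):
        errs_abs, errs_sq, n = 0.0, 0.0, 0
        for sub in dev_subjects:
            pred = _predict_subject(gen, sub.inputs, None, self.tile_overlap)
            d = pred - sub.target
            errs_abs += np.abs(d).sum()
            errs_sq += (d ** 2).sum()
            n += d.size
        history["dev_epoch"].append(epoch)
        history["dev_mae"].append(errs_abs / n)
        history["dev_mse"].append(errs_sq / n)

    # -- inference ---------------------------------------------------------
    def predict(self, X: EncodingSet) -> np.ndarray:
        if not hasattr(self, "models_") or not self.models_:
            raise ValueError("estimator is not fitted")
        es = normalize_and_centralize(X)
        inputs, _ = encoding_set_to_arrays(es)
        return predict_reference(self.models_, inputs, tile=None,
                                 overlap=self.tile_overlap)


# ---------------------------------------------------------------------------
# inference helpers and functional wrappers
# ---------------------------------------------------------------------------

def _forward_tiled(model: UNet3D, vol: np.ndarray,
                   tile: tuple[int, int, int] | None = None,
                   overlap: int = 8) -> np.ndarray:
    """Full-volume inference of a (C, X, Y, Z) stack.

    With ``tile=None`` the whole volume goes through in one pass (cropping to
    the largest shape the pyramid accepts, then padding back).  A smaller
    ``tile`` bounds memory: tiles overlap and only interior regions are kept.
    """
    shape = vol.shape[1:]
    f = 2 ** (model.depth - 1)
    if tile is None:
        tile = shape
    tile = tuple(min((t // f) * f, (s // f) * f) for t, s in zip(tile, shape))
    if any(t < f for t in tile):
        raise ValueError(f"volume/tile {shape} too small for depth {model.depth}")
    if all(t >= s for t, s in zip(tile, shape)):
        return model.forward(vol[None])[0]
    # margin m is trimmed from each interior tile face; steps of t - 2m make
    # the kept regions abut exactly, so with m >= the network's receptive-
    # field radius the tiled result matches untiled inference in the interior
    out = np.zeros((OUT_CHANNELS,) + shape)
    starts, margins = [], []
    for t, s in zip(tile, shape):
        m = min(overlap, (t - 1) // 2) if t < s else 0
        step = t - 2 * m
        st = list(range(0, max(s - t, 0) + 1, step))
        if st[-1] != s - t:
            st.append(s - t)
        starts.append(st)
        margins.append(m)
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                org = (sx, sy, sz)
                sl = tuple(slice(o, o + t) for o, t in zip(org, tile))
                pred = model.forward(vol[(slice(None),) + sl][None])[0]
                keep_src, keep_dst = [slice(None)], [slice(None)]
                for o, t, s, m in zip(org, tile, shape, margins):
                    lo = 0 if o == 0 else m
                    hi = t if o + t == s else t - m
                    keep_src.append(slice(lo, hi))
                    keep_dst.append(slice(o + lo, o + hi))
                out[tuple(keep_dst)] = pred[tuple(keep_src)]
    return out


def _predict_subject(model: UNet3D, inputs: np.ndarray,
                     tile: tuple[int, int, int] | None = None,
                     overlap: int = 8) -> np.ndarray:
    """(6, T, X, Y, Z) inputs -> (2, T, X, Y, Z) prediction, per timeframe."""
    T = inputs.shape[1]
    out = np.empty((OUT_CHANNELS, T) + inputs.shape[2:])
    for t in range(T):
        out[:, t] = _forward_tiled(model, inputs[:, t], tile, overlap)
    return out


def predict_reference(models: list[UNet3D], inputs: np.ndarray,
                      tile: tuple[int, int, int] | None = None,
                      overlap: int = 8) -> np.ndarray:
    """Fold-ensembled reference prediction: arithmetic mean over models of the
    per-model 2-channel outputs."""
    if not models:
        raise ValueError("model ensemble is empty")
    acc = None
    for m in models:
        p = _predict_subject(m, inputs, tile, overlap)
        acc = p if acc is None else acc + p
    return acc / len(models)


def train(encoding_sets: list[EncodingSet], config: TrainConfig,
          generator: GeneratorConfig | None = None,
          discriminator: DiscriminatorConfig | None = None
          ) -> tuple[list[UNet3D], list[dict]]:
    """Functional wrapper over :class:`ReferencePredictor`."""
    gcfg = generator or GeneratorConfig()
    dcfg = discriminator or DiscriminatorConfig()
    est = ReferencePredictor(
        mode=config.mode, depth=gcfg.depth, base_channels=gcfg.base_channels,
        norm=gcfg.norm, activation=gcfg.activation, disc_layers=dcfg.n_layers,
        disc_channels=dcfg.base_channels, patch_size=config.patch_size,
        batch_size=config.batch_size, epochs=config.epochs, lr=config.lr,
        lr_constant_epochs=config.lr_constant_epochs,
        weight_decay=config.weight_decay, l1_weight=config.l1_weight,
        adv_weight=config.adv_weight, folds=config.folds,
        dev_interval=config.dev_interval, augment_prob=config.augment_prob,
        seed=config.seed)
    est.fit(encoding_sets)
    return est.models_, est.history_


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, models: list[UNet3D], seed: int,
                    extra: dict | None = None) -> None:
    """Single-file .npz checkpoint with the architecture, seed and weights."""
    cfg = asdict(models[0].config)
    meta = {"generator": cfg, "seed": seed, "n_folds": len(models),
            "extra": extra or {}}
    arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for k, m in enumerate(models):
        for i, p in enumerate(m.parameters()):
            arrays[f"fold{k}_p{i}"] = p.value
    np.savez(Path(path), **arrays)


def load_checkpoint(path: str | Path) -> tuple[list[UNet3D], dict]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        gcfg = GeneratorConfig(**meta["generator"])
        models = []
        for k in range(meta["n_folds"]):
            m = UNet3D(gcfg, rng=np.random.default_rng(0))
            for i, p in enumerate(m.parameters()):
                p.value = np.array(data[f"fold{k}_p{i}"])
                p.grad = np.zeros_like(p.value)
            models.append(m)
    return models, meta
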