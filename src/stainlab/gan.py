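"""Pix2Pix conditional GAN for virtual CD3 staining.

A U-Net generator translates an encoded H&E patch (G = eosin,
B = hematoxylin, R empty) into the full three-channel image whose R
channel carries the blurred CD3+ signal.  A conditional patch
discriminator scores (input, candidate) pairs as a spatial map — 30x30
for 256x256 patches.  Four losses drive training:

* LOSS 1 — mean absolute difference between generated and truth image,
  weighted by ``lambda_l1`` (100);
* LOSS 2 — soft IoU loss on the CD3 (R) channel, weighted by a
  scheduled ``lambda_iou`` (e.g. 100 for 300 epochs, then 250);
* LOSS 3 — generator adversarial BCE against an all-ones target map;
* LOSS 4 — discriminator BCE: real pair vs ones plus fake pair vs
  zeros.

Inputs live in [-0.5, 0.5] (images in [0, 1] shifted down by 0.5); the
generator's scaled-tanh output is bounded by the same range and shifted
back to [0, 1] at inference.

:class:`Pix2PixTranslator` wraps the whole thing as a scikit-learn
style estimator (``fit(X, Y)`` / ``predict(X)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .config import SAME_SECTION_SCHEDULE
from .nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, LeakyReLU, ReLU, ScaledTanh, Sequential

__all__ = [
    "GanBundle",
    "LossReport",
    "UNetGenerator",
    "build_generator",
    "build_discriminator",
    "build_gan",
    "normalize_input",
    "rescale_output",
    "loss_l1",
    "loss_iou",
    "loss_adversarial",
    "train",
    "infer",
    "Pix2PixTranslator",
]


# ---------------------------------------------------------------------------
# Range mapping


def normalize_input(patch: np.ndarray) -> np.ndarray:
    """Map [0, 1] image values onto the model range [-0.5, 0.5]."""
    patch = np.asarray(patch)
    if patch.min() < -1e-9 or patch.max() > 1 + 1e-9:
        raise ValueError("normalize_input expects values in [0, 1]")
    return patch - 0.5


def rescale_output(patch: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`normalize_input`."""
    return np.asarray(patch) + 0.5


# ---------------------------------------------------------------------------
# Architectures


class UNetGenerator:
    """U-Net with skip connections and a scaled-tanh output.

    ``depth = log2(patch_size)`` stride-2 encoder blocks shrink the
    patch to 1x1; mirrored transposed-conv decoder blocks restore it,
    each consuming the concatenation of the previous decoder output and
    the matching encoder skip.  Encoder filters double per level, capped
    at ``8 * base_filters``.
    """

    def __init__(self, patch_size=256, base_filters=64, in_ch=3, out_ch=3, rng=None, dtype=np.float64):
        depth = int(np.log2(patch_size))
        if 2**depth != patch_size:
            raise ValueError("patch_size must be a power of two")
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.enc_ch = [min(base_filters * 2**i, base_filters * 8) for i in range(depth)]
        self.downs: list[Sequential] = []
        c_prev = in_ch
        for i, c in enumerate(self.enc_ch):
            layers = [Conv2d(c_prev, c, rng=rng)]
            if 0 < i < depth - 1:  # no norm on the outermost or the 1x1 bottleneck
                layers.append(BatchNorm2d(c))
            layers.append(LeakyReLU(0.2))
            self.downs.append(Sequential(*layers))
            c_prev = c
        self.ups: list[Sequential] = [None] * depth
        for i in range(depth - 1, 0, -1):
            c_in = self.enc_ch[i] if i == depth - 1 else 2 * self.enc_ch[i]
            self.ups[i] = Sequential(
                ConvTranspose2d(c_in, self.enc_ch[i - 1], rng=rng),
                BatchNorm2d(self.enc_ch[i - 1]),
                ReLU(),
            )
        self.ups[0] = Sequential(ConvTranspose2d(2 * self.enc_ch[0], out_ch, rng=rng), ScaledTanh(0.5))
        self._to_dtype(dtype)

    def _to_dtype(self, dtype):
        for blk in self.downs + self.ups:
            for layer in blk.layers:
                for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                    if hasattr(layer, attr):
                        setattr(layer, attr, getattr(layer, attr).astype(dtype))
                for attr in ("dW", "db", "dgamma", "dbeta"):
                    if hasattr(layer, attr):
                        setattr(layer, attr, getattr(layer, attr).astype(dtype))

    def params(self):
        out = []
        for j, blk in enumerate(self.downs):
            out.extend((f"d{j}.{n}", v, g) for n, v, g in blk.params())
        for j, blk in enumerate(self.ups):
            out.extend((f"u{j}.{n}", v, g) for n, v, g in blk.params())
        return out

    def zero_grad(self):
        for _, _, g in self.params():
            g[...] = 0.0

    def set_mode(self, train):
        for blk in self.downs + self.ups:
            blk.set_mode(train)

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for blk in self.downs:
            h = blk.forward(h)
            skips.append(h)
        u = skips[-1]
        for i in range(self.depth - 2, -1, -1):
            u = self.ups[i + 1].forward(u)
            u = np.concatenate([u, skips[i]], axis=1)
        self._nskips = len(skips)
        return self.ups[0].forward(u)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        du = self.ups[0].backward(dout)
        dskips = [None] * self.depth
        for i in range(self.depth - 1):
            c = self.enc_ch[i]
            du_u, dskips[i] = du[:, :c], du[:, c:]
            du = self.ups[i + 1].backward(du_u)
        g = du  # gradient w.r.t. the bottleneck skip
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                g = g + dskips[i]
            g = self.downs[i].backward(g)
        return g

    def __call__(self, x):
        return self.forward(x)


def build_generator(patch_size=256, base_filters=64, in_ch=3, out_ch=3, seed=0, dtype=np.float64):
    """U-Net generator mapping a [-0.5, 0.5] patch to a (-0.5, 0.5) patch."""
    return UNetGenerator(patch_size, base_filters, in_ch, out_ch, np.random.default_rng(seed), dtype)


def build_discriminator(patch_size=256, base_filters=64, in_ch=6, seed=0, dtype=np.float64):
    """Conditional patch discriminator (the published Pix2Pix layout).

    Three stride-2 and two stride-1 4x4 conv blocks: a 256x256
    (input, candidate) pair yields a 30x30 logit map; a 64x64 pair
    yields 6x6.  Apply a sigmoid to read probabilities.
    """
    if patch_size < 24:
        raise ValueError("the discriminator layout needs patches of at least 24 pixels")
    rng = np.random.default_rng(seed)
    b = base_filters
    net = Sequential(
        Conv2d(in_ch, b, stride=2, rng=rng),
        LeakyReLU(0.2),
        Conv2d(b, 2 * b, stride=2, rng=rng),
        BatchNorm2d(2 * b),
        LeakyReLU(0.2),
        Conv2d(2 * b, 4 * b, stride=2, rng=rng),
        BatchNorm2d(4 * b),
        LeakyReLU(0.2),
        Conv2d(4 * b, 8 * b, stride=1, rng=rng),
        BatchNorm2d(8 * b),
        LeakyReLU(0.2),
        Conv2d(8 * b, 1, stride=1, rng=rng),
    )
    for layer in net.layers:
        for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var", "dW", "db", "dgamma", "dbeta"):
            if hasattr(layer, attr):
                setattr(layer, attr, getattr(layer, attr).astype(dtype))
    return net


# ---------------------------------------------------------------------------
# Losses


def loss_l1(generated: np.ndarray, truth: np.ndarray) -> float:
    """LOSS 1: mean absolute difference over all pixels and channels."""
    generated, truth = np.asarray(generated), np.asarray(truth)
    if generated.shape != truth.shape:
        raise ValueError("shape mismatch")
    return float(np.abs(generated - truth).mean())


def _l1_grad(generated, truth):
    return np.sign(generated - truth) / generated.size


_IOU_EPS = 1e-6


def loss_iou(generated_r: np.ndarray, truth_r: np.ndarray, eps: float = _IOU_EPS) -> float:
    """LOSS 2: soft IoU loss, 1 - (sum ab + eps) / (sum a + sum b - sum ab + eps).

    Inputs are continuous masks in [0, 1]; on binary masks this equals
    1 - |A n B| / |A u B| up to ``eps``.
    """
    a, b = np.asarray(generated_r, float), np.asarray(truth_r, float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.min() < 0 or b.min() < 0:
        raise ValueError("soft IoU expects non-negative values in [0, 1]")
    inter = float((a * b).sum())
    union = float(a.sum() + b.sum() - inter)
    return 1.0 - (inter + eps) / (union + eps)


def _iou_grad(a, b, eps=_IOU_EPS):
    inter = (a * b).sum()
    union = a.sum() + b.sum() - inter
    return -(b * (union + eps) - (inter + eps) * (1.0 - b)) / (union + eps) ** 2


def loss_adversarial(score_map: np.ndarray, target: str) -> float:
    """LOSS 3/4 building block: mean BCE of a sigmoid score map vs a
    constant all-ones or all-zeros target map."""
    s = np.asarray(score_map, float)
    if s.min() <= 0 or s.max() >= 1:
        raise ValueError("scores must lie strictly inside (0, 1); apply a sigmoid first")
    if target == "ones":
        return float(-np.log(s).mean())
    if target == "zeros":
        return float(-np.log1p(-s).mean())
    raise ValueError("target must be 'ones' or 'zeros'")


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _bce_logits(z: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Numerically stable mean BCE-from-logits and its gradient."""
    loss = float((np.logaddexp(0.0, z) - target * z).mean())
    grad = (_sigmoid(z) - target) / z.size
    return loss, grad


# ---------------------------------------------------------------------------
# Bundle and training


@dataclass
class LossReport:
    epoch: int
    loss1: float
    loss2: float
    loss3: float
    loss4: float
    lambda_iou: float
    gen_total: float


@dataclass
class GanBundle:
    generator: UNetGenerator
    discriminator: Sequential
    lambda_l1: float = 100.0
    lambda_iou: float = 100.0
    opt_g: Adam = None
    opt_d: Adam = None
    epoch: int = 0
    seed: int = 0


def build_gan(
    patch_size=256,
    gen_filters=64,
    disc_filters=64,
    lambda_l1=100.0,
    lr=2e-4,
    beta1=0.5,
    seed=0,
    dtype=np.float64,
) -> GanBundle:
    gen = build_generator(patch_size, gen_filters, seed=seed, dtype=dtype)
    disc = build_discriminator(patch_size, disc_filters, seed=seed + 1, dtype=dtype)
    return GanBundle(
        generator=gen,
        discriminator=disc,
        lambda_l1=lambda_l1,
        opt_g=Adam(gen, lr=lr, beta1=beta1),
        opt_d=Adam(disc, lr=lr, beta1=beta1),
        seed=seed,
    )


def _schedule_lambda(schedule, epoch: int) -> float:
    """lambda_iou for a 1-based epoch under a [(n_epochs, value), ...] schedule."""
    e = epoch
    for n, v in schedule:
        if e <= n:
            return float(v)
        e -= n
    return float(schedule[-1][1])


def train(
    bundle: GanBundle,
    X: np.ndarray,
    Y: np.ndarray,
    schedule=SAME_SECTION_SCHEDULE,
    batch_size: int = 350,
    rng: np.random.Generator | None = None,
) -> tuple[GanBundle, list[LossReport]]:
    """Alternating generator/discriminator optimization.

    ``X``/``Y`` are NHWC patches in [0, 1]; X is the inference-style
    input (R channel zero), Y the truth image.  The generator objective
    is LOSS3 + lambda_l1 * LOSS1 + lambda_iou * LOSS2, with lambda_iou
    following the schedule.  Deterministic for a fixed rng seed under
    single-threaded execution.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(X) != len(Y):
        raise ValueError("X and Y must pair up")
    rng = rng or np.random.default_rng(bundle.seed)
    if batch_size > len(X):
        warnings.warn(f"batch size {batch_size} exceeds dataset size {len(X)}; clamping")
        batch_size = len(X)
    dtype = bundle.generator.downs[0].layers[0].W.dtype
    Xc = np.ascontiguousarray(normalize_input(X).transpose(0, 3, 1, 2), dtype=dtype)
    Yc = np.ascontiguousarray(normalize_input(Y).transpose(0, 3, 1, 2), dtype=dtype)

    G, D = bundle.generator, bundle.discriminator
    n_epochs_total = sum(n for n, _ in schedule)
    history: list[LossReport] = []
    for _ in range(n_epochs_total):
        bundle.epoch += 1
        lam_iou = _schedule_lambda(schedule, bundle.epoch)
        bundle.lambda_iou = lam_iou
        order = rng.permutation(len(Xc))
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            x, y = Xc[idx], Yc[idx]

            # --- discriminator step (LOSS 4)
            fake = G.forward(x)
            z_real = D.forward(np.concatenate([x, y], axis=1))
            l_real, dz_real = _bce_logits(z_real, 1.0)
            D.backward(dz_real)
            z_fake = D.forward(np.concatenate([x, fake], axis=1))
            l_fake, dz_fake = _bce_logits(z_fake, 0.0)
            D.backward(dz_fake)
            bundle.opt_d.step()
            bundle.opt_d.zero_grad()
            loss4 = l_real + l_fake

            # --- generator step (LOSS 3 + lambda_l1 * LOSS 1 + lambda_iou * LOSS 2)
            fake = G.forward(x)
            z_fake = D.forward(np.concatenate([x, fake], axis=1))
            loss3, dz = _bce_logits(z_fake, 1.0)
            dpair = D.backward(dz)
            D.zero_grad()  # D was only a conduit here
            dfake = dpair[:, x.shape[1] :].copy()

            l1 = loss_l1(fake, y)
            dfake += bundle.lambda_l1 * _l1_grad(fake, y)

            a = fake[:, 0] + 0.5  # model range -> [0, 1], R channel only
            b = y[:, 0] + 0.5
            l2 = loss_iou(a, b)
            dfake[:, 0] += lam_iou * _iou_grad(a, b)

            G.backward(dfake)
            bundle.opt_g.step()
            bundle.opt_g.zero_grad()

            sums += (l1, l2, loss3, loss4)
            n_batches += 1
        m = sums / n_batches
        history.append(
            LossReport(
                epoch=bundle.epoch,
                loss1=m[0],
                loss2=m[1],
                loss3=m[2],
                loss4=m[3],
                lambda_iou=lam_iou,
                gen_total=m[2] + bundle.lambda_l1 * m[0] + lam_iou * m[1],
            )
        )
    return bundle, history


def infer(bundle: GanBundle, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Generate virtual staining for encoded G/B patches.

    Input NHWC patches in [0, 1] with an all-zero R channel; output the
    generator's full three-channel prediction rescaled to [0, 1].
    """
    X = np.asarray(X)
    single = X.ndim == 3
    if single:
        X = X[None]
    if np.any(X[..., 0] != 0):
        warnings.warn("inference input has a nonzero R channel (information leak)")
    dtype = bundle.generator.downs[0].layers[0].W.dtype
    outs = []
    for start in range(0, len(X), batch_size):
        x = np.ascontiguousarray(
            normalize_input(X[start : start + batch_size]).transpose(0, 3, 1, 2), dtype=dtype
        )
        out = bundle.generator.forward(x)
        outs.append(rescale_output(out).transpose(0, 2, 3, 1))
    out = np.clip(np.concatenate(outs, axis=0), 0.0, 1.0)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Estimator


class Pix2PixTranslator(BaseEstimator):
    """Pix2Pix virtual-staining model with a scikit-learn interface.

    Parameters mirror the training recipe; defaults are the desk-scale
    configuration (64x64 patches, thin networks).  Use
    :meth:`full_scale` for the published 256x256 setup.

    Attributes (after ``fit``)
    --------------------------
    generator_ : trained U-Net generator
    discriminator_ : trained patch discriminator
    history_ : list of per-epoch :class:`LossReport`
    n_epochs_ : total epochs trained
    """

    def __init__(
        self,
        patch_size: int = 64,
        gen_filters: int = 16,
        disc_filters: int = 16,
        schedule=((20, 100.0), (10, 250.0)),
        lambda_l1: float = 100.0,
        batch_size: int = 16,
        lr: float = 2e-4,
        beta1: float = 0.5,
        dtype: str = "float32",
        random_state: int = 0,
    ):
        self.patch_size = patch_size
        self.gen_filters = gen_filters
        self.disc_filters = disc_filters
        self.schedule = schedule
        self.lambda_l1 = lambda_l1
        self.batch_size = batch_size
        self.lr = lr
        self.beta1 = beta1
        self.dtype = dtype
        self.random_state = random_state

    @classmethod
    def full_scale(cls, section: str = "same", random_state: int = 0) -> "Pix2PixTranslator":
        """The published configuration (256x256, base 64 filters, batch 350)."""
        from .config import SERIAL_SECTION_SCHEDULE

        schedule = SAME_SECTION_SCHEDULE if section == "same" else SERIAL_SECTION_SCHEDULE
        return cls(
            patch_size=256,
            gen_filters=64,
            disc_filters=64,
            schedule=schedule,
            batch_size=350,
            random_state=random_state,
        )

    def _validate(self, X, name):
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[1] != self.patch_size or X.shape[2] != self.patch_size or X.shape[3] != 3:
            raise ValueError(
                f"{name} must have shape (n, {self.patch_size}, {self.patch_size}, 3), got {X.shape}"
            )
        return X

    def fit(self, X, Y):
        X = self._validate(X, "X")
        Y = self._validate(Y, "Y")
        bundle = build_gan(
            patch_size=self.patch_size,
            gen_filters=self.gen_filters,
            disc_filters=self.disc_filters,
            lambda_l1=self.lambda_l1,
            lr=self.lr,
            beta1=self.beta1,
            seed=self.random_state,
            dtype=np.dtype(self.dtype).type,
        )
        rng = np.random.default_rng(self.random_state)
        bundle, history = train(
            bundle, X, Y, schedule=self.schedule, batch_size=self.batch_size, rng=rng
        )
        self.bundle_ = bundle
        self.generator_ = bundle.generator
        self.discriminator_ = bundle.discriminator
        self.history_ = history
        self.n_epochs_ = bundle.epoch
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "bundle_"):
            raise RuntimeError("fit must be called before predict")
        X = self._validate(X, "X")
        return infer(self.bundle_, X)

    def save(self, outdir) -> None:
        """Write weights as an NPZ archive plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        if not hasattr(self, "bundle_"):
            raise RuntimeError("fit must be called before save")
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        arrays = {f"g:{n}": v for n, v, _ in self.generator_.params()}
        arrays.update({f"d:{n}": v for n, v, _ in self.discriminator_.params()})
        np.savez(outdir / "weights.npz", **arrays)
        meta = {"params": self.get_params(), "n_epochs": self.n_epochs_}
        (outdir / "model.json").write_text(json.dumps(meta, indent=2, default=list))

    @classmethod
    def load(cls, outdir) -> "Pix2PixTranslator":
        import json
        from pathlib import Path

        outdir = Path(outdir)
        meta = json.loads((outdir / "model.json").read_text())
        params = meta["params"]
        params["schedule"] = tuple(tuple(t) for t in params["schedule"])
        est = cls(**params)
        bundle = build_gan(
            patch_size=est.patch_size,
            gen_filters=est.gen_filters,
            disc_filters=est.disc_filters,
            lambda_l1=est.lambda_l1,
            lr=est.lr,
            beta1=est.beta1,
            seed=est.random_state,
            dtype=np.dtype(est.dtype).type,
        )
        with np.load(outdir / "weights.npz") as arrays:
            for n, v, _ in bundle.generator.params():
                v[...] = arrays[f"g:{n}"]
            for n, v, _ in bundle.discriminator.params():
                v[...] = arrays[f"d:{n}"]
        est.bundle_ = bundle
        est.generator_ = bundle.generator
        est.discriminator_ = bundle.discriminator
        est.history_ = []
        est.n_epochs_ = meta["n_epochs"]
        return est
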