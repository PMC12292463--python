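"""Asymmetric pixel-shuffle-downsampling blind-spot network (AP-BSN).

The denoiser is trained on single noisy slices, with no clean targets. Three
ideas make that possible:

* **Blind-spot network (BSN).** Every output pixel is predicted from a
  receptive field that structurally excludes the corresponding input pixel,
  so reproducing the input's noise at that pixel is impossible and the L1
  self-reconstruction loss drives the network towards the (locally smooth)
  signal. The exclusion is architectural: each branch starts with a centrally
  masked convolution (3x3 or 5x5) followed by dilated convolutions whose tap
  offsets can never sum back to zero (dilation 2 behind the 3x3 mask, 3
  behind the 5x5 mask).
* **Pixel-shuffle downsampling (PD).** MRI noise is spatially correlated, so
  a blind spot of one pixel is not blind enough. PD rearranges the image into
  an s x s mosaic of subsampled images; at stride s the nearest neighbours of
  a mosaic pixel are s pixels apart in the original image, which breaks the
  short-range noise correlation the BSN assumption requires.
* **Asymmetry.** A large stride (5) is used during training for full noise
  decorrelation, and a small stride (2) at inference to preserve detail,
  followed by T passes of random-replacement refinement: a random fraction of
  the estimate's pixels is reset to the original noisy values, the PD-BSN
  path is re-run, and the pass outputs are averaged.

The module follows a Model/Results layout: :class:`BlindSpotDenoiser` holds
the training slices and configuration, ``fit()`` runs the self-supervised
optimisation and returns :class:`DenoiserResults`, which performs inference
and serialises to a single-file checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import nn
from .series import DynamicSeries, NoisyImage

__all__ = [
    "BSNConfig",
    "PDConfig",
    "TrainConfig",
    "BlindSpotDenoiser",
    "DenoiserResults",
    "pd_downsample",
    "pd_inverse",
    "bsn_forward",
    "train_self_supervised",
    "denoise_apbsn",
]


@dataclass(frozen=True)
class BSNConfig:
    """Architecture of the blind-spot network.

    Defaults are the desk-scale configuration (32 channels, 4 dilated blocks
    per branch); the branch kernel sizes and dilation rates are the fixed part
    of the design and must stay paired (masked 3x3 with dilation 2, masked 5x5
    with dilation 3) for the blind spot to hold.
    """

    branch_kernels: tuple[int, int] = (3, 5)
    dilations: tuple[int, int] = (2, 3)
    n_dilated_blocks: int = 4
    channels: int = 32
    n_tail_convs: int = 2

    def __post_init__(self) -> None:
        if any(k % 2 == 0 for k in self.branch_kernels):
            raise ValueError("branch kernel sizes must be odd")
        if any(d < 1 for d in self.dilations):
            raise ValueError("dilations must be >= 1")
        for k, d in zip(self.branch_kernels, self.dilations):
            if d < (k + 1) // 2:
                raise ValueError(
                    f"dilation {d} too small for masked kernel {k}: blind spot would leak"
                )
        if self.channels < 8:
            raise ValueError("channels must be >= 8")
        if self.n_dilated_blocks < 1 or self.n_tail_convs < 1:
            raise ValueError("block counts must be >= 1")


@dataclass(frozen=True)
class PDConfig:
    """Pixel-shuffle strides and random-replacement refinement settings."""

    stride_train: int = 5
    stride_test: int = 2
    refine_T: int = 16
    refine_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.stride_train > self.stride_test >= 1:
            raise ValueError("require stride_train > stride_test >= 1")
        if self.refine_T < 0:
            raise ValueError("refine_T must be >= 0")
        if not 0.0 < self.refine_fraction < 1.0:
            raise ValueError("refine_fraction must be in (0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    learning_rate: float = 1e-3
    patch_size: int = 40
    batch_size: int = 4
    optimizer: str = "adam"
    steps_per_epoch: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


# ---------------------------------------------------------------------------
# pixel-shuffle downsampling

def pd_downsample(image: np.ndarray, s: int) -> np.ndarray:
    """Rearrange ``image`` into an s x s mosaic of subsampled images.

    Sub-image (a, b) of the mosaic holds the pixels at positions congruent to
    (a, b) mod s. Bijective; dimensions must be divisible by ``s``.
    """
    if s < 1:
        raise ValueError("stride must be >= 1")
    image = np.asarray(image)
    H, W = image.shape
    if H % s or W % s:
        raise ValueError(f"image dims {image.shape} not divisible by stride {s}")
    h, w = H // s, W // s
    return image.reshape(h, s, w, s).transpose(1, 0, 3, 2).reshape(H, W)


def pd_inverse(mosaic: np.ndarray, s: int) -> np.ndarray:
    """Exact inverse of :func:`pd_downsample`."""
    if s < 1:
        raise ValueError("stride must be >= 1")
    mosaic = np.asarray(mosaic)
    H, W = mosaic.shape
    if H % s or W % s:
        raise ValueError(f"mosaic dims {mosaic.shape} not divisible by stride {s}")
    h, w = H // s, W // s
    return mosaic.reshape(s, h, s, w).transpose(1, 0, 3, 2).reshape(H, W)


def _pad_to_multiple(image: np.ndarray, s: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad so both dims are divisible by ``s``; return original shape."""
    H, W = image.shape
    ph = (-H) % s
    pw = (-W) % s
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw)), mode="reflect")
    return image, (H, W)


def _pd_split(image: np.ndarray, s: int) -> np.ndarray:
    """(H, W) -> (s*s, 1, H/s, W/s): the s^2 downsampled replicas as a batch.

    The network processes each replica separately so that convolutions never
    straddle the seams between sub-images (adjacent replicas hold nearly the
    same image, so a tiled mosaic would put large artificial discontinuities
    through the middle of the field of view).
    """
    H, W = image.shape
    h, w = H // s, W // s
    return np.ascontiguousarray(
        image.reshape(h, s, w, s).transpose(1, 3, 0, 2).reshape(s * s, 1, h, w))


def _pd_merge(batch: np.ndarray, s: int, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`_pd_split` for a (s*s, h, w) stack."""
    H, W = shape
    h, w = H // s, W // s
    return np.ascontiguousarray(
        batch.reshape(s, s, h, w).transpose(2, 0, 3, 1).reshape(H, W))


# ---------------------------------------------------------------------------
# network assembly

def _build_network(cfg: BSNConfig, rng: np.random.Generator) -> nn.Sequential:
    C = cfg.channels

    def branch(kernel: int, dilation: int) -> nn.Sequential:
        layers = [nn.Conv2d(C, C, kernel, mask_center=True, rng=rng), nn.ReLU()]
        for _ in range(cfg.n_dilated_blocks):
            inner = nn.Sequential(
                nn.Conv2d(C, C, 1, rng=rng), nn.ReLU(),
                nn.Conv2d(C, C, 3, dilation=dilation, rng=rng), nn.ReLU(),
                nn.Conv2d(C, C, 1, rng=rng),
            )
            layers.append(nn.Residual(inner))
        return nn.Sequential(*layers)

    (k1, k2), (d1, d2) = cfg.branch_kernels, cfg.dilations
    tail: list = [nn.Conv2d(2 * C, C, 1, rng=rng), nn.ReLU()]
    for _ in range(cfg.n_tail_convs - 1):
        tail += [nn.Conv2d(C, C, 1, rng=rng), nn.ReLU()]
    tail.append(nn.Conv2d(C, 1, 1, rng=rng))
    return nn.Sequential(
        nn.Conv2d(1, C, 1, rng=rng),
        nn.Concat2(branch(k1, d1), branch(k2, d2)),
        *tail,
    )


def _robust_scale(image: np.ndarray) -> float:
    scale = float(np.percentile(image, 99.9))
    if scale <= 0:
        scale = float(np.abs(image).max())
    return max(scale, 1e-6)


def _as_pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, NoisyImage) else np.asarray(img, dtype=np.float32)


# ---------------------------------------------------------------------------
# model / results

class BlindSpotDenoiser:
    """Self-supervised denoising model over a set of noisy 2D slices.

    Parameters
    ----------
    images
        Sequence of 2D arrays or :class:`NoisyImage` (background-subtracted
        noisy slices). Each slice is normalised by its own robust
        (99.9th-percentile) scale before entering the network.
    bsn_config, pd_config
        Architecture and pixel-shuffle settings; defaults are the desk-scale
        configuration.
    """

    def __init__(self, images, bsn_config: BSNConfig | None = None,
                 pd_config: PDConfig | None = None):
        self.images = [_as_pixels(im) for im in images]
        if not self.images:
            raise ValueError("need at least one training slice")
        self.bsn_config = bsn_config or BSNConfig()
        self.pd_config = pd_config or PDConfig()

    @classmethod
    def from_series(cls, series: DynamicSeries, timepoint: int,
                    bsn_config: BSNConfig | None = None,
                    pd_config: PDConfig | None = None) -> "BlindSpotDenoiser":
        """Build the model from every coronal slice of one timepoint."""
        vol = series.volume(timepoint)
        return cls(list(vol), bsn_config=bsn_config, pd_config=pd_config)

    def fit(self, train_config: TrainConfig | None = None) -> "DenoiserResults":
        """Run the self-supervised optimisation.

        Each step draws a batch of random patches, pixel-shuffles them at the
        training stride, and minimises the L1 distance between the network
        output and the mosaic itself. The blind spot makes this
        non-degenerate: the identity solution is structurally unavailable.
        """
        cfg = train_config or TrainConfig()
        s = self.pd_config.stride_train
        if cfg.patch_size % s:
            raise ValueError("patch_size must be divisible by stride_train")
        rng = np.random.default_rng(cfg.seed)
        net = _build_network(self.bsn_config, rng)
        opt = nn.Adam(net, lr=cfg.learning_rate)

        # normalise once; pad any slice smaller than the patch
        P = cfg.patch_size
        slices = []
        for img in self.images:
            norm = img / _robust_scale(img)
            ph, pw = max(0, P - norm.shape[0]), max(0, P - norm.shape[1])
            if ph or pw:
                norm = np.pad(norm, ((0, ph), (0, pw)), mode="reflect")
            slices.append(norm.astype(np.float32))

        steps = cfg.steps_per_epoch or max(1, int(np.ceil(len(slices) / cfg.batch_size)))
        loss_history = []
        for epoch in range(cfg.epochs):
            epoch_losses = []
            for _ in range(steps):
                replicas = []
                for b in range(cfg.batch_size):
                    img = slices[rng.integers(len(slices))]
                    i = rng.integers(img.shape[0] - P + 1)
                    j = rng.integers(img.shape[1] - P + 1)
                    replicas.append(_pd_split(img[i:i + P, j:j + P], s))
                batch = np.concatenate(replicas, axis=0)
                pred = net.forward(batch)
                resid = pred - batch
                loss = float(np.abs(resid).mean())
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                net.backward(np.sign(resid).astype(np.float32) / resid.size)
                opt.step()
                epoch_losses.append(loss)
            loss_history.append(float(np.mean(epoch_losses)))

        fingerprint = {
            "seed": cfg.seed,
            "epochs": cfg.epochs,
            "n_slices": len(self.images),
            "data_hash": _data_hash(self.images),
        }
        return DenoiserResults(net, self.bsn_config, self.pd_config, cfg,
                               loss_history, fingerprint)


def _data_hash(images) -> str:
    import hashlib

    h = hashlib.sha256()
    for img in images:
        h.update(np.ascontiguousarray(img, dtype=np.float32).tobytes())
    return h.hexdigest()[:16]


class DenoiserResults:
    """Trained blind-spot denoiser: parameters, diagnostics and inference."""

    def __init__(self, net, bsn_config: BSNConfig, pd_config: PDConfig,
                 train_config: TrainConfig, loss_history, fingerprint):
        self.net = net
        self.bsn_config = bsn_config
        self.pd_config = pd_config
        self.train_config = train_config
        self.loss_history = list(loss_history)
        self.fingerprint = dict(fingerprint)

    # -- raw network --------------------------------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        """One blind-spot forward pass on a raw 2D array (no PD, no scaling)."""
        image = np.asarray(image, dtype=np.float32)
        if not np.all(np.isfinite(image)):
            raise ValueError("non-finite input")
        out = self.net.forward(image[None, None])
        return out[0, 0]

    # -- AP-BSN inference ---------------------------------------------------
    def denoise(self, y, seed: int = 0, refine_T: int | None = None) -> np.ndarray:
        """AP-BSN estimate of the clean image behind noisy slice ``y``.

        PD at the (small) test stride, blind-spot forward pass, inverse PD;
        then ``refine_T`` random-replacement passes whose outputs are
        averaged. Deterministic given ``seed``.
        """
        y = _as_pixels(y)
        T = self.pd_config.refine_T if refine_T is None else refine_T
        s = self.pd_config.stride_test
        scale = _robust_scale(y)
        yn = (y / scale).astype(np.float32)

        def run(img: np.ndarray) -> np.ndarray:
            padded, (H, W) = _pad_to_multiple(img, s)
            out = self.net.forward(_pd_split(padded, s))
            return _pd_merge(out[:, 0], s, padded.shape)[:H, :W]

        base = run(yn)
        if T == 0:
            return (base * scale).astype(np.float32)
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(base)
        for _ in range(T):
            replace = rng.random(yn.shape) < self.pd_config.refine_fraction
            acc += run(np.where(replace, yn, base))
        return (acc / T * scale).astype(np.float32)

    def pnp_denoise(self, y, config=None):
        """PnP-ADMM restoration with this denoiser as the image prior."""
        from .pnp import pnp_denoise

        return pnp_denoise(y, self, config)

    # -- reporting ----------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.net.params()))

    def summary(self) -> str:
        lines = [
            "Blind-spot denoiser (AP-BSN) - self-supervised fit",
            "=" * 52,
            f"channels: {self.bsn_config.channels}   "
            f"dilated blocks/branch: {self.bsn_config.n_dilated_blocks}",
            f"branch kernels: {self.bsn_config.branch_kernels}   "
            f"dilations: {self.bsn_config.dilations}",
            f"PD stride train/test: {self.pd_config.stride_train}/"
            f"{self.pd_config.stride_test}   refinement T: {self.pd_config.refine_T}",
            f"parameters: {self.n_parameters}",
            f"epochs: {len(self.loss_history)}   seed: {self.fingerprint.get('seed')}",
            f"training slices: {self.fingerprint.get('n_slices')} "
            f"(hash {self.fingerprint.get('data_hash')})",
            f"L1 loss: first epoch {self.loss_history[0]:.5f} -> "
            f"final epoch {self.loss_history[-1]:.5f}",
        ]
        return "\n".join(lines)

    # -- checkpointing ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state())}
        header = {
            "bsn_config": asdict(self.bsn_config),
            "pd_config": asdict(self.pd_config),
            "train_config": asdict(self.train_config),
            "loss_history": self.loss_history,
            "fingerprint": self.fingerprint,
        }
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DenoiserResults":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
        bsn_cfg = BSNConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in header["bsn_config"].items()})
        pd_cfg = PDConfig(**header["pd_config"])
        tr_cfg = TrainConfig(**header["train_config"])
        net = _build_network(bsn_cfg, np.random.default_rng(0))
        net.load_state(arrays)
        return cls(net, bsn_cfg, pd_cfg, tr_cfg,
                   header["loss_history"], header["fingerprint"])


# ---------------------------------------------------------------------------
# functional wrappers

def bsn_forward(model: DenoiserResults, image: np.ndarray) -> np.ndarray:
    """Raw blind-spot network forward pass (no PD, no intensity scaling)."""
    return model.forward(image)


def train_self_supervised(slices, cfg: TrainConfig | None = None,
                          bsn: BSNConfig | None = None,
                          pd: PDConfig | None = None) -> DenoiserResults:
    return BlindSpotDenoiser(slices, bsn_config=bsn, pd_config=pd).fit(cfg)


def denoise_apbsn(model: DenoiserResults, y, seed: int = 0) -> np.ndarray:
    return model.denoise(y, seed=seed)
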