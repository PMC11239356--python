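"""RGB training-image encoding and tile preparation.

An H&E image and its per-nucleus CD3 labels become a three-channel
training image: R = Gaussian-blurred CD3+ signal (dilated CD3+ nucleus
footprints), G = eosin channel, B = hematoxylin channel, all in [0, 1].
Images are zero-padded to a multiple of the patch size and cut into
non-overlapping 256x256 tiles; tiles whose CD3 stain area is below 10%
are flagged (excluded), and the kept tiles are split 90/10 into train
and held-out sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import hed_from_rgb, separate_stains

from .config import PipelineConfig
from .labeling import dilate_mask
from .simulate import CD3_POS


@dataclass
class TileSet:
    """Tiles of one encoded source image plus their metadata."""

    tiles: np.ndarray          # (n, patch, patch, 3) float in [0, 1]
    origins: np.ndarray        # (n, 2) top-left (row, col) in the source
    flagged: np.ndarray        # (n,) bool, True = excluded (CD3 area < 10%)
    cd3_fracs: np.ndarray      # (n,) CD3 stain area fraction per tile
    source_id: str = ""

    def kept(self) -> np.ndarray:
        return np.flatnonzero(~self.flagged)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tile": np.arange(len(self.tiles)),
                "source_id": self.source_id,
                "origin_row": self.origins[:, 0],
                "origin_col": self.origins[:, 1],
                "flagged": self.flagged,
                "cd3_frac": self.cd3_fracs,
            }
        )


def _minmax01(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi <= lo:
        return np.zeros_like(channel, dtype=float)
    return (channel - lo) / (hi - lo)


def deconvolve_he(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unmix H&E into (hematoxylin, eosin) channels, min-max scaled to [0, 1].

    Uses the standard published H&E-DAB stain matrix; per-image min-max
    normalization absorbs staining-intensity differences between images.
    A uniform input (zero dynamic range) yields all-zero channels with a
    warning.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an RGB image, got shape {rgb.shape}")
    stains = separate_stains(rgb, hed_from_rgb)
    hema, eosin = stains[..., 0], stains[..., 1]
    if hema.max() <= hema.min() or eosin.max() <= eosin.min():
        warnings.warn("uniform image: stain channels have zero dynamic range")
    return _minmax01(hema), _minmax01(eosin)


def blur_cd3(mask: np.ndarray, kernel: int = 101, sigma: float = 11.875) -> np.ndarray:
    """Spread a binary CD3 mask with a Gaussian while keeping peaks centered.

    Convolves with a truncated Gaussian (window = ``kernel``) and
    rescales so the global maximum equals 1; an empty mask stays zero.
    """
    if kernel % 2 == 0:
        raise ValueError("kernel size must be odd")
    mask = np.asarray(mask, dtype=float)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    radius = (kernel - 1) // 2
    out = ndi.gaussian_filter(mask, sigma=sigma, truncate=radius / sigma, mode="constant")
    peak = out.max()
    return out / peak if peak > 0 else out


def build_cd3_mask(
    labels: pd.DataFrame, nuclei: np.ndarray, dilation_size: int = 5
) -> np.ndarray:
    """Binary CD3 stain mask: CD3+ nucleus footprints, square-dilated."""
    nuclei = np.asarray(nuclei)
    ids = set(labels["id"].tolist())
    present = set(np.unique(nuclei).tolist()) - {0}
    missing = sorted(ids - present)
    if missing:
        raise ValueError(f"label ids absent from nuclear mask: {missing}")
    pos_ids = labels.loc[labels["label"] == CD3_POS, "id"].to_numpy()
    mask = np.isin(nuclei, pos_ids) & (nuclei > 0)
    return dilate_mask(mask.astype(np.uint8), dilation_size)


def encode_image(
    he_rgb: np.ndarray,
    labels: pd.DataFrame,
    nuclei: np.ndarray,
    cfg: PipelineConfig | None = None,
    inference: bool = False,
    return_mask: bool = False,
):
    """Stack (R = blurred CD3 signal, G = eosin, B = hematoxylin) in [0, 1].

    With ``inference=True`` the R channel is all zero regardless of the
    labels (the model fills it in).  ``return_mask=True`` also returns
    the binary pre-blur CD3 mask used for tile flagging.
    """
    cfg = cfg or PipelineConfig()
    hema, eosin = deconvolve_he(he_rgb)
    cd3_mask = build_cd3_mask(labels, nuclei, cfg.dilation_size)
    if inference:
        red = np.zeros_like(hema)
    else:
        red = blur_cd3(cd3_mask, cfg.blur_kernel, cfg.blur_sigma)
    encoded = np.stack([red, eosin, hema], axis=-1)
    if return_mask:
        return encoded, cd3_mask
    return encoded


def pad_and_tile(image: np.ndarray, patch: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad bottom/right to a multiple of ``patch`` and tile row-major.

    Returns ``(tiles, origins)`` with ``ceil(H/patch) * ceil(W/patch)``
    non-overlapping tiles; origins are top-left (row, col) coordinates
    in the padded (= unpadded, for interior tiles) frame.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("image must be at least 1x1")
    nh, nw = -(-h // patch), -(-w // patch)
    pad = [(0, nh * patch - h), (0, nw * patch - w)] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad, mode="constant")
    tiles, origins = [], []
    for i in range(nh):
        for j in range(nw):
            tiles.append(padded[i * patch : (i + 1) * patch, j * patch : (j + 1) * patch])
            origins.append((i * patch, j * patch))
    return np.stack(tiles), np.asarray(origins)


def stitch_tiles(tiles: np.ndarray, origins: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Reassemble tiles at their origins and crop to ``shape`` (lossless)."""
    patch = tiles.shape[1]
    h = origins[:, 0].max() + patch
    w = origins[:, 1].max() + patch
    out = np.zeros((h, w) + tiles.shape[3:], dtype=tiles.dtype)
    for tile, (r, c) in zip(tiles, origins):
        out[r : r + patch, c : c + patch] = tile
    return out[: shape[0], : shape[1]]


def flag_tiles(cd3_mask_tiles: np.ndarray, min_frac: float = 0.10) -> np.ndarray:
    """Flag (exclude) tiles whose CD3 stain area fraction is below ``min_frac``.

    The fraction is computed on the binary pre-blur CD3 mask; a tile at
    exactly the boundary is kept ("at least 10%").
    """
    tiles = np.asarray(cd3_mask_tiles)
    fracs = tiles.reshape(len(tiles), -1).astype(bool).mean(axis=1)
    return fracs < min_frac


def cd3_area_fractions(cd3_mask_tiles: np.ndarray) -> np.ndarray:
    tiles = np.asarray(cd3_mask_tiles)
    return tiles.reshape(len(tiles), -1).astype(bool).mean(axis=1)


def split_tiles(
    n_or_indices, train_frac: float = 0.90, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/held-out partition of kept tile indices.

    Train size is ``round(train_frac * n)``; deterministic per seed.
    """
    if np.isscalar(n_or_indices):
        indices = np.arange(int(n_or_indices))
    else:
        indices = np.asarray(n_or_indices)
    n = len(indices)
    if n == 0:
        raise ValueError("cannot split an empty tile set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    return np.sort(indices[perm[:n_train]]), np.sort(indices[perm[n_train:]])


def encode_and_tile(
    he_rgb: np.ndarray,
    labels: pd.DataFrame,
    nuclei: np.ndarray,
    cfg: PipelineConfig | None = None,
    source_id: str = "",
) -> TileSet:
    """Full encoding path for one image: encode, tile, and flag."""
    cfg = cfg or PipelineConfig()
    encoded, mask = encode_image(he_rgb, labels, nuclei, cfg, return_mask=True)
    tiles, origins = pad_and_tile(encoded, cfg.patch_size)
    mask_tiles, _ = pad_and_tile(mask, cfg.patch_size)
    return TileSet(
        tiles=tiles,
        origins=origins,
        flagged=flag_tiles(mask_tiles, cfg.flag_min_frac),
        cd3_fracs=cd3_area_fractions(mask_tiles),
        source_id=source_id,
    )
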