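"""Ground-truth CD3 label derivation and cross-section label transfer.

The same-section route thresholds the CD3 fluorescence channel, dilates
the binary mask to capture the membranous signal around each nucleus,
and labels every nucleus that intersects the mask as CD3+.  The
chromogenic route first unmixes an H-DAB RGB image with the
Ruifrok-Johnston stain matrix and thresholds the DAB channel.  For
serial sections, CD3+ cells found on the marker section are transferred
to the nearest nuclei of the H&E section by greedy one-to-one centroid
matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import hdx_from_rgb, separate_stains
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .simulate import CD3_NEG, CD3_POS, SyntheticSection, truth_mask

__all__ = [
    "binarize_marker",
    "segment_nuclei",
    "dilate_mask",
    "label_nuclei_by_marker",
    "transfer_labels",
    "deconvolve_hdab",
    "derive_labels_mihc",
    "derive_labels_ihc",
    "nucleus_centroids",
]


def binarize_marker(channel: np.ndarray, threshold: int) -> np.ndarray:
    """Binary marker mask: pixel positive iff intensity >= threshold.

    The inclusive rule follows the chromogenic convention ("values at
    the threshold and above are positive"); the fluorescence threshold
    of 50 is applied with the same rule.
    """
    channel = np.asarray(channel)
    if channel.ndim != 2:
        raise ValueError(f"expected a 2D channel, got shape {channel.shape}")
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return (channel >= threshold).astype(np.uint8)


def segment_nuclei(
    image: np.ndarray | SyntheticSection,
    mode: str = "fluor",
    min_distance: int = 5,
) -> np.ndarray:
    """Segment nuclei into a labeled mask (0 background, 1..K nuclei).

    ``mode='truth'`` takes a :class:`SyntheticSection` and returns the
    generator's exact elliptical footprints keyed by cell id.  The other
    modes run a simple default segmenter — global Otsu threshold, hole
    filling, connected components, and a distance-transform watershed to
    split touching blobs — on the DAPI channel (``fluor``) or on the
    hematoxylin channel of an H&E RGB image (``he``).
    """
    if mode == "truth":
        if not isinstance(image, SyntheticSection):
            raise TypeError("mode='truth' requires a SyntheticSection")
        return truth_mask(image)

    if isinstance(image, SyntheticSection):
        image = image.dapi if mode == "fluor" else image.he_rgb
    image = np.asarray(image)
    if mode == "he":
        if image.ndim != 3 or image.shape[-1] != 3:
            raise ValueError("mode='he' expects an RGB image")
        from .encoding import deconvolve_he

        channel = deconvolve_he(image)[0] * 255
    elif mode == "fluor":
        if image.ndim != 2:
            raise ValueError("mode='fluor' expects a 2D channel")
        channel = image.astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if channel.max() == channel.min():
        return np.zeros(channel.shape, dtype=np.int32)
    # Otsu mislocates the cut when foreground covers well under 1% of the
    # image (it then splits the background); floor it at half the peak.
    cut = max(threshold_otsu(channel), 0.5 * channel.max())
    binary = channel > cut
    if not binary.any():
        return np.zeros(channel.shape, dtype=np.int32)
    binary = ndi.binary_fill_holes(binary)
    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(distance, min_distance=min_distance, labels=binary)
    markers = np.zeros(channel.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        return ndi.label(binary)[0].astype(np.int32)
    labels = watershed(-distance, markers, mask=binary)
    return labels.astype(np.int32)


def dilate_mask(mask: np.ndarray, size: int = 5) -> np.ndarray:
    """Morphological dilation with a size x size square structuring element."""
    if size < 1 or size % 2 == 0:
        raise ValueError("size must be an odd integer >= 1")
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    out = ndi.binary_dilation(mask.astype(bool), structure=np.ones((size, size), bool))
    return out.astype(np.uint8)


def _table(ids, rows, cols, labels, matched=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=np.int64),
            "row": np.asarray(rows, dtype=float),
            "col": np.asarray(cols, dtype=float),
            "label": list(labels),
            "matched_source_id": (
                pd.array(matched, dtype="Int64") if matched is not None else pd.array([pd.NA] * len(ids), dtype="Int64")
            ),
        }
    )


def nucleus_centroids(nuclei: np.ndarray) -> pd.DataFrame:
    """Per-nucleus centroids (id, row, col) from a labeled mask."""
    nuclei = np.asarray(nuclei)
    ids = np.unique(nuclei)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return pd.DataFrame({"id": pd.array([], dtype=np.int64), "row": [], "col": []})
    coms = ndi.center_of_mass(np.ones_like(nuclei), nuclei, ids)
    coms = np.atleast_2d(np.asarray(coms, dtype=float))
    return pd.DataFrame({"id": ids.astype(np.int64), "row": coms[:, 0], "col": coms[:, 1]})


def label_nuclei_by_marker(
    nuclei: np.ndarray, marker: np.ndarray, rule: str = "any_overlap"
) -> pd.DataFrame:
    """Label each nucleus by its overlap with a binary marker mask.

    ``any_overlap``: CD3+ iff the nucleus intersects the marker mask at
    all (logical AND nonempty).  ``majority``: CD3+ iff strictly more
    than half of the nucleus area overlaps the marker.
    """
    nuclei = np.asarray(nuclei)
    marker = np.asarray(marker)
    if nuclei.shape != marker.shape:
        raise ValueError(f"shape mismatch: nuclei {nuclei.shape} vs marker {marker.shape}")
    if rule not in ("any_overlap", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    cents = nucleus_centroids(nuclei)
    ids = cents["id"].to_numpy()
    if len(ids) == 0:
        return _table([], [], [], [])
    marker_b = marker.astype(bool)
    nmax = int(nuclei.max())
    overlap = np.bincount(nuclei[marker_b].ravel(), minlength=nmax + 1)
    area = np.bincount(nuclei.ravel(), minlength=nmax + 1)
    if rule == "any_overlap":
        pos = overlap[ids] > 0
    else:
        pos = overlap[ids] > 0.5 * area[ids]
    labels = np.where(pos, CD3_POS, CD3_NEG)
    return _table(ids, cents["row"], cents["col"], labels)


def transfer_labels(
    source: pd.DataFrame, target_nuclei: np.ndarray, max_dist: float | None = None
) -> pd.DataFrame:
    """Transfer CD3+ labels from a source section onto target nuclei.

    Each CD3+ source cell is matched to the nearest target-nucleus
    centroid (Euclidean), one-to-one, greedily in ascending distance
    order; ties break on the target centroid's (row, col) and then the
    source centroid's (row, col), so the result is independent of the
    source row order.  Matches farther than ``max_dist`` (if set) are
    discarded.  Unmatched target nuclei are CD3-.
    """
    targets = nucleus_centroids(target_nuclei)
    n_t = len(targets)
    labels = np.array([CD3_NEG] * n_t, dtype=object)
    matched = np.full(n_t, -1, dtype=np.int64)
    if n_t and source is not None and len(source):
        pos = source[source["label"] == CD3_POS]
        if len(pos):
            src_xy = pos[["row", "col"]].to_numpy(float)
            src_id = pos["id"].to_numpy()
            tgt_xy = targets[["row", "col"]].to_numpy(float)
            d = np.sqrt(((src_xy[:, None, :] - tgt_xy[None, :, :]) ** 2).sum(-1))
            pairs = sorted(
                (
                    (d[i, j], tgt_xy[j, 0], tgt_xy[j, 1], src_xy[i, 0], src_xy[i, 1], i, j)
                    for i in range(len(pos))
                    for j in range(n_t)
                ),
                key=lambda t: t[:5],
            )
            used_s: set[int] = set()
            used_t: set[int] = set()
            for dist, *_rest, i, j in pairs:
                if max_dist is not None and dist > max_dist:
                    break
                if i in used_s or j in used_t:
                    continue
                used_s.add(i)
                used_t.add(j)
                labels[j] = CD3_POS
                matched[j] = src_id[i]
                if len(used_s) == len(pos):
                    break
    out = _table(targets["id"], targets["row"], targets["col"], labels)
    out["matched_source_id"] = pd.array(
        [m if m >= 0 else pd.NA for m in matched], dtype="Int64"
    )
    return out


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask).astype(bool) * 255).astype(np.uint8))


def deconvolve_hdab(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unmix an H-DAB RGB image into hematoxylin and DAB channels (0-255).

    Uses the published Ruifrok-Johnston H-DAB stain matrix; each channel
    is min-max rescaled to 0-255 per image.  A channel with (near-)zero
    dynamic range maps to all zeros: without the guard, an image that
    contains no DAB at all would have its numerical unmixing residue
    stretched across the full 0-255 range.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an RGB image, got shape {rgb.shape}")
    stains = separate_stains(rgb, hdx_from_rgb)

    def _rescale(ch: np.ndarray, min_od: float = 0.02) -> np.ndarray:
        lo, hi = ch.min(), ch.max()
        if hi - lo < min_od:
            return np.zeros_like(ch)
        return (ch - lo) / (hi - lo) * 255.0

    return _rescale(stains[..., 0]), _rescale(stains[..., 1])


def derive_labels_mihc(
    cd3_channel: np.ndarray,
    nuclei: np.ndarray,
    threshold: int = 50,
    dilation_size: int = 5,
    smooth_sigma: float = 0.0,
) -> pd.DataFrame:
    """Same-section ground truth from a CD3 fluorescence channel.

    Threshold (>= 50 by default) -> square dilation (5) to capture the
    membranous signal -> any-overlap labeling against the nuclear mask.
    ``smooth_sigma`` optionally pre-smooths the channel before
    thresholding.
    """
    channel = np.asarray(cd3_channel, dtype=float)
    if smooth_sigma > 0:
        channel = ndi.gaussian_filter(channel, smooth_sigma)
    mask = binarize_marker(channel, threshold)
    mask = dilate_mask(mask, dilation_size)
    return label_nuclei_by_marker(nuclei, mask, rule="any_overlap")


def derive_labels_ihc(
    ihc_rgb: np.ndarray,
    he_nuclei: np.ndarray,
    dab_threshold: int = 100,
    dilation_size: int = 5,
    transfer: bool = False,
    max_dist: float | None = None,
    ihc_nuclei: np.ndarray | None = None,
) -> pd.DataFrame:
    """Ground truth from a chromogenic H-DAB IHC image.

    Deconvolve -> threshold the DAB channel (>= 100) -> dilate ->
    any-overlap labeling.  With ``transfer=True`` the labels are first
    derived on the IHC section's own nuclei (``ihc_nuclei``) and then
    transferred to ``he_nuclei`` by nearest-centroid matching, as for a
    serial-section pair.
    """
    if dab_threshold > 255:
        # Unreachable threshold: nothing is positive.
        return label_nuclei_by_marker(he_nuclei, np.zeros(np.asarray(he_nuclei).shape, np.uint8))
    _, dab = deconvolve_hdab(ihc_rgb)
    mask = dilate_mask(binarize_marker(dab.astype(np.uint8), dab_threshold), dilation_size)
    if not transfer:
        return label_nuclei_by_marker(he_nuclei, mask, rule="any_overlap")
    if ihc_nuclei is None:
        raise ValueError("transfer=True requires ihc_nuclei")
    source = label_nuclei_by_marker(ihc_nuclei, mask, rule="any_overlap")
    return transfer_labels(source, he_nuclei, max_dist=max_dist)
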