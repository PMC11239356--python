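"""Synthetic paired-section tissue simulator.

Generates small tissue sections populated with elliptical nuclei, a
configurable fraction of which are CD3+ T-cells carrying a membranous
(annular) CD3 signal.  Each section is rendered into the three image
modalities the label-derivation pipeline consumes:

* a DAPI-like fluorescence nuclear channel,
* a CD3 fluorescence channel (annuli around CD3+ nuclei),
* an H&E brightfield RGB rendering (and, on demand, a chromogenic
  H-DAB IHC rendering).

``make_serial`` simulates an adjacent ("serial") tissue section: the
same cell population subjected to a rigid offset, per-cell Gaussian
jitter, random cell dropout and random unmatched new cells.  This is
the in-silico counterpart of deriving ground-truth marker labels from
a physically adjacent 4 um section, where cell-to-cell correspondence
with the H&E section is imperfect.

Every cell's footprint is a closed-form ellipse, so downstream mask
operations (overlap labeling, dilation, decoding) are exactly
checkable against geometry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.color import combine_stains, rgb_from_hed

CD3_POS = "CD3_POS"
CD3_NEG = "CD3_NEG"

#: Fluorescence signal level painted on nuclei / CD3 annuli (0-255).
SIGNAL_LEVEL = 200
#: Upper bound of the uniform background noise floor on fluorescence
#: channels; kept well below the marker threshold of 50 so noise never
#: flips a label.
NOISE_MAX = 20

# Optical-density stain concentrations used by the brightfield renderers.
_HEMATOXYLIN_NUCLEUS = 0.85
_HEMATOXYLIN_BACKGROUND = 0.05
_EOSIN_BACKGROUND = 0.30
_EOSIN_NUCLEUS = 0.10
_DAB_ANNULUS = 0.9

# Annulus geometry: the membranous CD3 ring spans these multiples of the
# nuclear ellipse (inner edge just inside the membrane, ~2-3 px wide at
# the default nuclear scale).
_RING_INNER = 0.80
_RING_OUTER = 1.30


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap on the canvas."""


@dataclass
class Cell:
    """One nucleus: elliptical footprint plus a marker label."""

    id: int
    centroid: tuple[float, float]  # (row, col), 0-based pixels
    axes: tuple[float, float]      # (semi-major, semi-minor), pixels
    angle: float                   # radians, major axis vs column axis
    label: str                     # CD3_POS or CD3_NEG

    def footprint(self, shape: tuple[int, int], scale: float = 1.0) -> np.ndarray:
        """Boolean mask of the (optionally scaled) ellipse on a canvas."""
        return _ellipse_mask(shape, self.centroid, self.axes, self.angle, scale)


@dataclass
class SerialParams:
    """Corruption model for a simulated adjacent section."""

    offset: tuple[float, float] = (8.0, 8.0)
    jitter_sigma: float = 3.0
    p_drop: float = 0.25
    p_new: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_drop <= 1.0 and 0.0 <= self.p_new <= 1.0):
            raise ValueError("p_drop and p_new must lie in [0, 1]")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass
class SyntheticSection:
    """A cell population plus its rendered image channels."""

    cells: list[Cell]
    canvas: tuple[int, int]
    dapi: np.ndarray
    cd3: np.ndarray
    he_rgb: np.ndarray
    provenance: str = "SAME"
    serial_params: SerialParams | None = None
    seed: int = 0
    morphology_cue: bool = True

    @property
    def n_cd3_pos(self) -> int:
        return sum(1 for c in self.cells if c.label == CD3_POS)

    def truth_table(self):
        """Cell truth as a pandas DataFrame (id,row,col,...,label)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": [c.id for c in self.cells],
                "row": [c.centroid[0] for c in self.cells],
                "col": [c.centroid[1] for c in self.cells],
                "semi_major": [c.axes[0] for c in self.cells],
                "semi_minor": [c.axes[1] for c in self.cells],
                "angle": [c.angle for c in self.cells],
                "label": [c.label for c in self.cells],
            }
        )


def _ellipse_mask(shape, centroid, axes, angle, scale=1.0) -> np.ndarray:
    """Rasterize an ellipse with pixel-center semantics."""
    h, w = shape
    a, b = axes[0] * scale, axes[1] * scale
    r0, c0 = centroid
    rad = int(np.ceil(max(a, b))) + 1
    rlo, rhi = max(0, int(r0) - rad), min(h, int(r0) + rad + 2)
    clo, chi = max(0, int(c0) - rad), min(w, int(c0) + rad + 2)
    out = np.zeros(shape, dtype=bool)
    if rlo >= rhi or clo >= chi:
        return out
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    ca, sa = np.cos(angle), np.sin(angle)
    u = dc * ca + dr * sa
    v = -dc * sa + dr * ca
    out[rlo:rhi, clo:chi] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def _sample_axes(rng: np.random.Generator, label: str, cue: bool) -> tuple[float, float, float]:
    """Semi-axes and orientation for one nucleus.

    With the morphology cue enabled, CD3+ cells are drawn smaller and
    rounder (lymphocyte-like); without it, geometry is sampled from the
    same distribution regardless of label, so the H&E rendering carries
    no information about CD3 status.
    """
    if cue and label == CD3_POS:
        a = rng.uniform(3.5, 4.5)
        b = a * rng.uniform(0.9, 1.0)
    else:
        a = rng.uniform(6.0, 8.5)
        b = a * rng.uniform(0.55, 0.75)
    angle = rng.uniform(0, np.pi)
    return a, b, angle


def _place_cells(
    n_cells: int,
    frac_cd3: float,
    canvas: tuple[int, int],
    rng: np.random.Generator,
    morphology_cue: bool,
    min_gap: float,
    min_dist: float | None,
    max_attempts_per_cell: int = 400,
) -> list[Cell]:
    h, w = canvas
    n_pos = int(round(n_cells * frac_cd3))
    labels = np.array([CD3_POS] * n_pos + [CD3_NEG] * (n_cells - n_pos))
    rng.shuffle(labels)

    cells: list[Cell] = []
    positions = np.empty((0, 2))
    majors = np.empty((0,))
    budget = max_attempts_per_cell * max(n_cells, 1)
    for i, label in enumerate(labels):
        a, b, angle = _sample_axes(rng, label, morphology_cue)
        placed = False
        while budget > 0:
            budget -= 1
            r = rng.uniform(a, h - 1 - a)
            c = rng.uniform(a, w - 1 - a)
            if len(cells):
                d = np.hypot(positions[:, 0] - r, positions[:, 1] - c)
                req = majors + a + min_gap if min_dist is None else np.full_like(majors, min_dist)
                if np.any(d < req):
                    continue
            cells.append(Cell(id=i + 1, centroid=(r, c), axes=(a, b), angle=angle, label=str(label)))
            positions = np.vstack([positions, [r, c]])
            majors = np.append(majors, a)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{n_cells} on a {h}x{w} canvas "
                f"after exhausting the rejection-sampling budget"
            )
    return cells


def _render_fluorescence(cells, canvas, rng) -> tuple[np.ndarray, np.ndarray]:
    """DAPI (all nuclei) and CD3 (annuli of CD3+ cells) channels, uint8."""
    h, w = canvas
    dapi = rng.integers(0, NOISE_MAX + 1, size=(h, w)).astype(np.float64)
    cd3 = rng.integers(0, NOISE_MAX + 1, size=(h, w)).astype(np.float64)
    for cell in cells:
        fp = cell.footprint(canvas)
        level = SIGNAL_LEVEL + rng.uniform(-20, 20)
        dapi[fp] = level
        if cell.label == CD3_POS:
            ring = cell.footprint(canvas, _RING_OUTER) & ~cell.footprint(canvas, _RING_INNER)
            cd3[ring] = SIGNAL_LEVEL + rng.uniform(-20, 20)
    return dapi.astype(np.uint8), cd3.astype(np.uint8)


def render_he(section: SyntheticSection) -> np.ndarray:
    """Render a brightfield H&E RGB image (uint8) of a section.

    Nuclei absorb mostly hematoxylin, background mostly eosin; the
    image is produced through the standard optical-density model so the
    published H&E deconvolution matrix separates the two stains.  The
    rendering depends only on cell geometry, never on the CD3 label, so
    the only possible H&E cue to CD3 status is the morphological one
    injected at generation time.
    """
    h, w = section.canvas
    nuc = np.zeros((h, w), dtype=bool)
    for cell in section.cells:
        nuc |= cell.footprint(section.canvas)
    hema = np.where(nuc, _HEMATOXYLIN_NUCLEUS, _HEMATOXYLIN_BACKGROUND)
    eos = np.where(nuc, _EOSIN_NUCLEUS, _EOSIN_BACKGROUND)
    stains = np.stack([hema, eos, np.zeros_like(hema)], axis=-1)
    rgb = combine_stains(stains, rgb_from_hed)
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)


def render_ihc(section: SyntheticSection) -> np.ndarray:
    """Render a chromogenic H-DAB IHC RGB image (uint8).

    All nuclei receive a hematoxylin counterstain; CD3+ cells get a
    DAB-brown membranous annulus, separable by the H-DAB deconvolution
    matrix.
    """
    h, w = section.canvas
    nuc = np.zeros((h, w), dtype=bool)
    ring = np.zeros((h, w), dtype=bool)
    for cell in section.cells:
        nuc |= cell.footprint(section.canvas)
        if cell.label == CD3_POS:
            ring |= cell.footprint(section.canvas, _RING_OUTER) & ~cell.footprint(
                section.canvas, _RING_INNER
            )
    hema = np.where(nuc, _HEMATOXYLIN_NUCLEUS, _HEMATOXYLIN_BACKGROUND)
    dab = np.where(ring, _DAB_ANNULUS, 0.0)
    stains = np.stack([hema, np.zeros_like(hema), dab], axis=-1)
    rgb = combine_stains(stains, rgb_from_hed)
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)


def generate_section(
    n_cells: int = 150,
    frac_cd3: float = 0.2,
    canvas: tuple[int, int] = (512, 512),
    seed: int = 0,
    morphology_cue: bool = True,
    min_gap: float = 6.0,
    min_dist: float | None = None,
) -> SyntheticSection:
    """Generate a same-section synthetic tissue section.

    Parameters
    ----------
    n_cells : number of nuclei to place.
    frac_cd3 : fraction labeled CD3+; the positive count is exactly
        ``round(n_cells * frac_cd3)``, assigned to random cells.
    canvas : (height, width) in pixels.
    seed : RNG seed; identical seeds give byte-identical sections.
    morphology_cue : if True, CD3+ nuclei are smaller and rounder in
        every geometric rendering (the learnable H&E cue).  If False,
        geometry is label-independent and the H&E image carries no CD3
        information.
    min_gap : minimal gap (pixels) between centroids beyond the sum of
        the two semi-major axes; keeps nuclei and their membranous CD3
        rings from touching neighbouring nuclei.
    min_dist : if given, overrides the adaptive rule with a fixed
        minimal centroid distance (used to build "well separated"
        sections).
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not 0.0 <= frac_cd3 <= 1.0:
        raise ValueError("frac_cd3 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cells = _place_cells(n_cells, frac_cd3, canvas, rng, morphology_cue, min_gap, min_dist)
    dapi, cd3 = _render_fluorescence(cells, canvas, rng)
    section = SyntheticSection(
        cells=cells,
        canvas=canvas,
        dapi=dapi,
        cd3=cd3,
        he_rgb=np.zeros((*canvas, 3), np.uint8),
        provenance="SAME",
        seed=seed,
        morphology_cue=morphology_cue,
    )
    section.he_rgb = render_he(section)
    return section


def make_serial(section: SyntheticSection, params: SerialParams) -> SyntheticSection:
    """Simulate the adjacent (serial) section of an existing section.

    Each cell is dropped independently with probability ``p_drop``;
    retained cells keep their id (preserving correspondence) and move by
    the rigid ``offset`` plus independent Gaussian jitter.  Unmatched new
    cells appear at rate ``p_new`` per retained cell, with labels drawn
    at the original section's CD3+ fraction.  Cells whose centroid
    leaves the canvas are treated as dropped.
    """
    rng = np.random.default_rng(params.seed)
    h, w = section.canvas
    retained: list[Cell] = []
    for cell in section.cells:
        if rng.random() < params.p_drop:
            continue
        dr = params.offset[0] + rng.normal(0, params.jitter_sigma) if params.jitter_sigma else params.offset[0]
        dc = params.offset[1] + rng.normal(0, params.jitter_sigma) if params.jitter_sigma else params.offset[1]
        r, c = cell.centroid[0] + dr, cell.centroid[1] + dc
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            continue
        retained.append(dataclasses.replace(cell, centroid=(r, c)))

    frac_pos = section.n_cd3_pos / len(section.cells) if section.cells else 0.0
    n_new = rng.binomial(len(retained), params.p_new) if params.p_new > 0 else 0
    next_id = max((c.id for c in section.cells), default=0) + 1
    for k in range(n_new):
        label = CD3_POS if rng.random() < frac_pos else CD3_NEG
        a, b, angle = _sample_axes(rng, label, section.morphology_cue)
        r = rng.uniform(a, h - 1 - a)
        c = rng.uniform(a, w - 1 - a)
        retained.append(Cell(id=next_id + k, centroid=(r, c), axes=(a, b), angle=angle, label=label))

    dapi, cd3 = _render_fluorescence(retained, section.canvas, rng)
    serial = SyntheticSection(
        cells=retained,
        canvas=section.canvas,
        dapi=dapi,
        cd3=cd3,
        he_rgb=np.zeros((*section.canvas, 3), np.uint8),
        provenance="SERIAL",
        serial_params=params,
        seed=params.seed,
        morphology_cue=section.morphology_cue,
    )
    serial.he_rgb = render_he(serial)
    return serial


def truth_mask(section: SyntheticSection) -> np.ndarray:
    """Exact labeled nuclear mask (0 background, cell id elsewhere).

    Later cells overwrite earlier ones on the (rare) overlapping pixels;
    with default placement, footprints are disjoint.
    """
    out = np.zeros(section.canvas, dtype=np.int32)
    for cell in section.cells:
        out[cell.footprint(section.canvas)] = cell.id
    return out


def write_section(section: SyntheticSection, outdir: str | Path) -> dict:
    """Write channels as 8-bit TIFFs, cell truth as CSV, params as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "dapi.tif", section.dapi)
    tifffile.imwrite(outdir / "cd3.tif", section.cd3)
    tifffile.imwrite(outdir / "he.tif", section.he_rgb)
    section.truth_table().to_csv(outdir / "cells.csv", index=False)
    meta = {
        "canvas": list(section.canvas),
        "provenance": section.provenance,
        "seed": int(section.seed),
        "morphology_cue": bool(section.morphology_cue),
        "n_cells": len(section.cells),
        "n_cd3_pos": section.n_cd3_pos,
        "serial_params": dataclasses.asdict(section.serial_params) if section.serial_params else None,
    }
    (outdir / "section.json").write_text(json.dumps(meta, indent=2))
    return meta


def read_section(indir: str | Path) -> SyntheticSection:
    """Read a section previously written by :func:`write_section`."""
    import pandas as pd

    indir = Path(indir)
    meta = json.loads((indir / "section.json").read_text())
    df = pd.read_csv(indir / "cells.csv")
    cells = [
        Cell(
            id=int(r.id),
            centroid=(float(r.row), float(r.col)),
            axes=(float(r.semi_major), float(r.semi_minor)),
            angle=float(r.angle),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]
    sp = meta.get("serial_params")
    return SyntheticSection(
        cells=cells,
        canvas=tuple(meta["canvas"]),
        dapi=tifffile.imread(indir / "dapi.tif"),
        cd3=tifffile.imread(indir / "cd3.tif"),
        he_rgb=tifffile.imread(indir / "he.tif"),
        provenance=meta["provenance"],
        serial_params=SerialParams(**{**sp, "offset": tuple(sp["offset"])}) if sp else None,
        seed=meta["seed"],
        morphology_cue=meta["morphology_cue"],
    )
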