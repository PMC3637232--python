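"""Region-of-interest handling for mass / normal-tissue prototypes.

This module turns raw digitized mammogram-like images plus free-hand lesion
annotations into fixed-size optical-density patches ("prototypes"):

1. decode the Freeman chain code tracing a lesion boundary,
2. find the smallest *centered* square enclosing it (lesions whose centered
   square would stick out of the image are discarded),
3. convert gray levels to optical densities using the scanner's calibration
   curve (linear or logarithmic response), and
4. resize the square patch bilinearly to the working sizes (32/64 px).

Conventions (fixed so that encoder, decoder and tests agree):

* coordinates are 0-based ``(row, col)`` with row increasing downward;
* Freeman directions: 0=E, 1=SE, 2=S, 3=SW, 4=W, 5=NW, 6=N, 7=NE, i.e.
  codes 0..7 step clockwise on screen;
* boxes are half-open ``[row0, row0+side) x [col0, col0+side)``;
* the centered square origin is ``floor(center - (side-1)/2)`` per axis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Freeman direction -> (drow, dcol), clockwise starting East.
FREEMAN_STEPS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)

#: Sentinel returned by :func:`bounding_square` for lesions too close to an edge.
DISCARD = None


@dataclass(frozen=True)
class GrayImage:
    """Raw digitized image: non-negative integers up to ``max_gray``."""

    pixels: np.ndarray
    max_gray: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("GrayImage requires a 2-D pixel array")
        if px.min() < 0 or px.max() > self.max_gray:
            raise ValueError("pixel values outside [0, max_gray]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ChainCodeAnnotation:
    """Lesion boundary: start pixel plus Freeman direction string."""

    start: tuple[int, int]
    codes: tuple[int, ...]
    label: str  # 'malignant' | 'benign'

    def __post_init__(self) -> None:
        codes = tuple(int(c) for c in self.codes)
        if any(c < 0 or c > 7 for c in codes):
            raise ValueError("Freeman codes must be in 0..7")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "start", (int(self.start[0]), int(self.start[1])))


@dataclass(frozen=True)
class Prototype:
    """One square optical-density patch with its provenance labels."""

    patch: np.ndarray
    label: str       # 'mass' | 'normal'
    pathology: str   # 'malignant' | 'benign' | 'normal'
    site: str
    source_case: str

    def __post_init__(self) -> None:
        p = np.asarray(self.patch, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("prototype patch must be square")
        if (self.pathology in ("malignant", "benign")) != (self.label == "mass"):
            raise ValueError("pathology/label mismatch")
        object.__setattr__(self, "patch", p)


def decode_chain_code(
    ann: ChainCodeAnnotation, image_shape: tuple[int, int] | None = None
) -> list[tuple[int, int]]:
    """Replay a Freeman chain code into the ordered list of boundary pixels.

    The path starts at ``ann.start``; each code moves one pixel. If
    ``image_shape`` is given, a step leaving the image raises ``ValueError``.
    """
    r, c = ann.start
    path = [(r, c)]
    for code in ann.codes:
        dr, dc = FREEMAN_STEPS[code]
        r, c = r + dr, c + dc
        if image_shape is not None:
            if not (0 <= r < image_shape[0] and 0 <= c < image_shape[1]):
                raise ValueError(f"chain code leaves image bounds at ({r}, {c})")
        path.append((r, c))
    return path


def bounding_square(
    boundary: Sequence[tuple[int, int]], image_shape: tuple[int, int]
) -> tuple[int, int, int] | None:
    """Smallest square centered on the boundary's bounding box, or ``DISCARD``.

    The side equals the larger dimension of the axis-aligned bounding box and
    the square is centered on the box center (ties broken toward smaller
    indices).  Returns ``DISCARD`` (None) when the centered square would
    extend past any image edge — such lesions cannot be taken "centred in a
    square without stretching" and are dropped.
    """
    if len(boundary) == 0:
        raise ValueError("empty boundary")
    rows = np.fromiter((p[0] for p in boundary), dtype=int)
    cols = np.fromiter((p[1] for p in boundary), dtype=int)
    r0b, r1b = int(rows.min()), int(rows.max())
    c0b, c1b = int(cols.min()), int(cols.max())
    side = max(r1b - r0b + 1, c1b - c0b + 1)
    center_r = (r0b + r1b) / 2.0
    center_c = (c0b + c1b) / 2.0
    row0 = int(np.floor(center_r - (side - 1) / 2.0))
    col0 = int(np.floor(center_c - (side - 1) / 2.0))
    H, W = image_shape
    if row0 < 0 or col0 < 0 or row0 + side > H or col0 + side > W:
        return DISCARD
    return (row0, col0, side)


def to_optical_density(img: "GrayImage | np.ndarray", profile) -> np.ndarray:
    """Map gray levels to optical densities via the scanner calibration curve.

    linear response:       od = cal_a + cal_b * g
    logarithmic response:  od = cal_a + cal_b * log10(max(g, 1))

    Gray level 0 is clamped to 1 under the logarithmic response (the log is
    otherwise undefined; film OD saturates there anyway).
    """
    g = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    g = g.astype(float)
    if profile.response == "linear":
        return profile.cal_a + profile.cal_b * g
    if profile.response == "logarithmic":
        return profile.cal_a + profile.cal_b * np.log10(np.maximum(g, 1.0))
    raise ValueError(f"unknown scanner response {profile.response!r}")


def resize_bilinear(patch: np.ndarray, target: int) -> np.ndarray:
    """Resize a square patch with separable bilinear interpolation.

    Uses a corner-aligned sampling grid: output sample ``i`` lies at input
    coordinate ``i * (S-1) / (T-1)``, so the four corner values are preserved
    and constant / affine intensity surfaces are reproduced exactly.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square")
    if patch.shape[0] < 2:
        raise ValueError("patch side must be >= 2")
    if target < 2:
        raise ValueError("target size must be >= 2")
    S = patch.shape[0]
    coords = np.linspace(0.0, S - 1.0, target)
    rr, cc = np.meshgrid(coords, coords, indexing="ij")
    return ndimage.map_coordinates(patch, [rr, cc], order=1, mode="nearest")


def extract_prototypes(
    cases: Iterable,
    profiles: Mapping[str, object],
    sizes: Sequence[int] = (32, 64),
    normal_per_case: int = 2,
    size_range: tuple[int, int] = (24, 56),
    seed: int = 0,
) -> dict[int, list[Prototype]]:
    """Cut mass and normal-tissue prototypes from a set of cases.

    Mass prototypes come from the centered bounding square of each decoded
    annotation (the DISCARD rule applies); normal prototypes are random
    squares fully inside annotation-free images, with sides drawn uniformly
    over ``size_range`` — mirroring normal tissue captured "with sizes
    ranging randomly from the smallest to the largest" mass sizes.  Each
    patch is converted to optical density and then resized to every
    requested size.

    Returns a dict mapping size -> list of :class:`Prototype`.
    """
    lo, hi = size_range
    if lo < 8:
        raise ValueError("minimum prototype size must be >= 8")
    rng = np.random.default_rng(seed)
    out: dict[int, list[Prototype]] = {int(s): [] for s in sizes}
    n_discarded = 0
    for i, case in enumerate(cases):
        profile = profiles[case.site]
        img = case.image
        H, W = img.shape
        case_id = f"{case.site}-{i:05d}"
        if case.annotations:
            for ann in case.annotations:
                boundary = decode_chain_code(ann, image_shape=img.shape)
                box = bounding_square(boundary, img.shape)
                if box is DISCARD:
                    n_discarded += 1
                    continue
                r0, c0, side = box
                od = to_optical_density(img.pixels[r0:r0 + side, c0:c0 + side], profile)
                for s in sizes:
                    out[int(s)].append(Prototype(
                        patch=resize_bilinear(od, int(s)), label="mass",
                        pathology=ann.label, site=case.site, source_case=case_id))
        else:
            if H < lo or W < lo:
                logger.warning("normal image %s smaller than %d px; skipped", case_id, lo)
                continue
            for _ in range(normal_per_case):
                side = int(rng.integers(lo, min(hi, H, W) + 1))
                r0 = int(rng.integers(0, H - side + 1))
                c0 = int(rng.integers(0, W - side + 1))
                od = to_optical_density(img.pixels[r0:r0 + side, c0:c0 + side], profile)
                for s in sizes:
                    out[int(s)].append(Prototype(
                        patch=resize_bilinear(od, int(s)), label="normal",
                        pathology="normal", site=case.site, source_case=case_id))
    if n_discarded:
        logger.info("discarded %d border-adjacent mass annotations", n_discarded)
    return out


# ---------------------------------------------------------------------------
# File formats: 16-bit binary PGM and the plain-text overlay annotation format
# ---------------------------------------------------------------------------

def write_pgm(path: "str | Path", img: GrayImage) -> None:
    """Write a binary (P5) PGM; 16-bit big-endian when max_gray > 255."""
    px = img.pixels
    header = f"P5\n{px.shape[1]} {px.shape[0]}\n{img.max_gray}\n".encode("ascii")
    dtype = ">u2" if img.max_gray > 255 else "u1"
    Path(path).write_bytes(header + px.astype(dtype).tobytes())


def read_pgm(path: "str | Path") -> GrayImage:
    """Read a binary (P5) PGM written by :func:`write_pgm`."""
    raw = Path(path).read_bytes()
    m = re.match(rb"P5\s+(?:#[^\n]*\n\s*)*(\d+)\s+(\d+)\s+(\d+)\s", raw)
    if m is None:
        raise ValueError(f"{path}: not a binary PGM")
    w, h, maxg = (int(m.group(k)) for k in (1, 2, 3))
    dtype = ">u2" if maxg > 255 else "u1"
    px = np.frombuffer(raw[m.end():], dtype=dtype, count=h * w).reshape(h, w)
    return GrayImage(px.astype(np.int64), maxg)


def write_overlay(path: "str | Path", site: str,
                  annotations: Sequence[ChainCodeAnnotation]) -> None:
    """Write annotations as an overlay-like plain-text file."""
    lines = [f"SITE {site}"]
    for ann in annotations:
        digits = "".join(str(c) for c in ann.codes)
        lines.append(f"LESION {ann.label} START {ann.start[0]} {ann.start[1]} "
                     f"CHAIN {digits}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_overlay(path: "str | Path") -> tuple[str, list[ChainCodeAnnotation]]:
    """Parse an overlay file back into (site, annotations)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("SITE "):
        raise ValueError(f"{path}: missing SITE header")
    site = lines[0].split(None, 1)[1]
    anns = []
    for ln in lines[1:]:
        parts = ln.split()
        if parts[0] != "LESION" or parts[2] != "START" or parts[5] != "CHAIN":
            raise ValueError(f"{path}: malformed overlay line: {ln!r}")
        codes = tuple(int(ch) for ch in parts[6]) if len(parts) > 6 else ()
        anns.append(ChainCodeAnnotation(start=(int(parts[3]), int(parts[4])),
                                        codes=codes, label=parts[1]))
    return site, anns
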