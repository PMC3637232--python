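"""Synthetic multi-site mammogram-like data.

The classifier-robustness protocol needs image data from several "clinics"
whose digitizers differ (resolution, linear vs logarithmic optical-density
response, gray-level noise) and whose class mixes are badly imbalanced.  This
module generates such data end to end:

* textured normal-tissue backgrounds in optical-density (OD) units,
* parametric masses covering the four shape classes (round, oval, lobulated,
  irregular) and three margin classes (circumscribed, ill-defined,
  spiculated), with a controllable OD contrast,
* Freeman chain-code tracing of each mass boundary (the annotation format),
* digitization through a per-site scanner model (inverse calibration curve,
  Gaussian gray-level noise, clipping, integer quantization).

A single ``effect`` knob scales mass contrast, giving controllable class
separability: at ``effect = 0`` masses are invisible and downstream
classification collapses to chance.

The default site roster (:data:`DEFAULT_SITE_COUNTS`) mirrors a four-scanner
screening archive: three linear scanners and one logarithmic, at 42–50 um,
with one site ("dba") contributing zero benign lesions and a large majority
of the normal tissue — the configuration under which cross-site robustness
is expected to degrade most.

Every operation is a pure function of its arguments, including ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .io_roi import (
    FREEMAN_STEPS,
    ChainCodeAnnotation,
    GrayImage,
    write_overlay,
    write_pgm,
)

MASS_SHAPES = ("round", "oval", "lobulated", "irregular")
MASS_MARGINS = ("circumscribed", "ill_defined", "spiculated")

#: Radial reach of the intensity profile beyond the mask radius, per margin.
_MARGIN_REACH = {"circumscribed": 1.0, "ill_defined": 1.5, "spiculated": 1.9}


@dataclass(frozen=True)
class ScannerProfile:
    """One site's digitizer: resolution, OD response and calibration.

    The calibration curve maps gray level to optical density:
    ``od = cal_a + cal_b * g`` (linear) or
    ``od = cal_a + cal_b * log10(g)`` (logarithmic);
    :func:`digitize` applies its inverse.  ``noise_sd`` is the gray-level
    noise standard deviation added at digitization.
    """

    name: str
    resolution_um: float
    response: str  # 'linear' | 'logarithmic'
    cal_a: float
    cal_b: float
    max_gray: int = 4095
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.response not in ("linear", "logarithmic"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.cal_b == 0:
            raise ValueError("cal_b must be nonzero")
        if self.max_gray < 255:
            raise ValueError("max_gray must be >= 255")


@dataclass(frozen=True)
class MassSpec:
    """Geometry and intensity of one synthetic mass."""

    shape: str
    margin: str
    diameter_px: int
    contrast: float  # OD elevation of the mass core over background
    center: tuple[int, int]

    def __post_init__(self) -> None:
        if self.shape not in MASS_SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.margin not in MASS_MARGINS:
            raise ValueError(f"unknown margin {self.margin!r}")
        if self.diameter_px <= 4:
            raise ValueError("diameter_px must exceed 4")
        if self.contrast < 0:
            raise ValueError("contrast must be non-negative")


@dataclass(frozen=True)
class SyntheticCase:
    """One generated image with its annotations and ground truth."""

    image: GrayImage
    annotations: tuple[ChainCodeAnnotation, ...]
    site: str
    truth: tuple[str, ...]
    seed: int


def generate_background(height: int, width: int, texture_scale: float,
                        mean_od: float, seed: int,
                        texture_sd: float = 0.18) -> np.ndarray:
    """Textured normal-tissue background in OD units.

    Low-pass-filtered Gaussian white noise: white noise is smoothed with a
    Gaussian of sigma ``texture_scale`` px and scaled analytically so the
    field's standard deviation is ~``texture_sd`` (a 2-D Gaussian kernel has
    sum of squares 1/(4*pi*sigma^2), so the amplitude gain is
    ``texture_sd * 2 * sigma * sqrt(pi)``).
    """
    if height < 32 or width < 32:
        raise ValueError("background must be at least 32x32")
    if texture_scale <= 0:
        raise ValueError("texture_scale must be positive")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(white, texture_scale, mode="reflect")
    gain = texture_sd * 2.0 * texture_scale * np.sqrt(np.pi)
    return mean_od + gain * smooth


def _radius_profile(spec: MassSpec, theta: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Angular radius function r(theta), normalized so max(r) = diameter/2."""
    R = spec.diameter_px / 2.0
    if spec.shape == "round":
        return np.full_like(theta, R)
    if spec.shape == "oval":
        b = 0.6 * R
        phi = rng.uniform(0.0, np.pi)
        psi = theta - phi
        return R * b / np.sqrt((b * np.cos(psi)) ** 2 + (R * np.sin(psi)) ** 2)
    if spec.shape == "lobulated":
        k = int(rng.integers(3, 6))
        phi = rng.uniform(0.0, 2 * np.pi)
        amp = 0.25
        return R * (1.0 + amp * np.sin(k * theta + phi)) / (1.0 + amp)
    # irregular: smooth random perturbation over harmonics 2..6
    f = np.ones_like(theta)
    for k in range(2, 7):
        f += rng.uniform(0.0, 0.12) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return R * f / f.max()


def mass_reach(spec: MassSpec) -> float:
    """Radial extent (px) of the mass's intensity footprint."""
    return (spec.diameter_px / 2.0) * _MARGIN_REACH[spec.margin]


def render_mass(spec: MassSpec, background: np.ndarray,
                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Add a parametric mass to an OD background; return (image, mask).

    The mask is the star-convex region ``r <= r(theta)`` (8-connected and
    simply connected for round/oval shapes).  The OD elevation peaks at
    ``contrast`` in the core and falls off with a margin-dependent width:
    sharp at the mask edge for circumscribed margins, a wide ramp reaching
    1.5x the radius for ill-defined margins, and a sharp core plus radial
    spikes for spiculated margins.
    """
    H, W = background.shape
    r0, c0 = spec.center
    reach = mass_reach(spec)
    if (r0 - reach < 0 or c0 - reach < 0
            or r0 + reach > H - 1 or c0 + reach > W - 1):
        raise ValueError("mass footprint exceeds image bounds")
    rng = np.random.default_rng(seed)
    rows = np.arange(H)[:, None] - r0
    cols = np.arange(W)[None, :] - c0
    rr = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols)
    radius = _radius_profile(spec, theta, rng)
    u = rr / np.maximum(radius, 1e-9)  # normalized radius: mask is u <= 1
    mask = u <= 1.0

    if spec.margin == "circumscribed":
        elev = np.clip((1.0 - u) / 0.15, 0.0, 1.0)
    elif spec.margin == "ill_defined":
        elev = np.clip((1.5 - u) / 1.0, 0.0, 1.0)
    else:  # spiculated: sharp core + radial spikes
        core = np.clip((1.0 - u) / 0.2, 0.0, 1.0)
        n_spikes = int(rng.integers(6, 13))
        spike_angles = rng.uniform(0.0, 2 * np.pi, size=n_spikes)
        ang_sd = 0.06
        spikes = np.zeros_like(u)
        for a in spike_angles:
            d = np.angle(np.exp(1j * (theta - a)))
            ridge = np.exp(-0.5 * (d / ang_sd) ** 2)
            taper = np.clip((1.9 - u) / 0.9, 0.0, 1.0) * (u > 0.5)
            spikes = np.maximum(spikes, 0.6 * ridge * taper)
        elev = np.maximum(core, spikes)

    return background + spec.contrast * elev, mask


def trace_chain_code(mask: np.ndarray,
                     label: str = "malignant") -> ChainCodeAnnotation:
    """Encode the outer boundary of a mask as a clockwise Freeman chain code.

    Moore-neighbor tracing over the 8-neighborhood, starting at the
    topmost-then-leftmost foreground pixel; decoding the result with
    :func:`icamam.io_roi.decode_chain_code` reproduces the traced boundary
    pixel sequence exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_comp = ndimage.label(mask, structure=np.ones((3, 3)))[1]
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} components; exactly one required")
    pixels = np.argwhere(mask)
    start = tuple(pixels[np.lexsort((pixels[:, 1], pixels[:, 0]))[0]])
    start = (int(start[0]), int(start[1]))
    if len(pixels) == 1:
        return ChainCodeAnnotation(start=start, codes=(), label=label)

    H, W = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < H and 0 <= c < W and mask[r, c]

    codes: list[int] = []
    cur = start
    # For the topmost-leftmost start every neighbor checked before East is
    # background, so beginning the scan at North reproduces a clockwise trace.
    scan_from = 6
    first_move = None
    for _ in range(8 * mask.size):  # hard guard; tracing terminates well before
        for k in range(8):
            d = (scan_from + k) % 8
            nr, nc = cur[0] + FREEMAN_STEPS[d][0], cur[1] + FREEMAN_STEPS[d][1]
            if fg(nr, nc):
                if cur == start and first_move is not None and d == first_move:
                    return ChainCodeAnnotation(start=start, codes=tuple(codes),
                                               label=label)
                codes.append(d)
                if first_move is None:
                    first_move = d
                cur = (nr, nc)
                scan_from = (d + 6) % 8
                break
        else:  # isolated pixel cannot occur here (single component, size > 1)
            break
    return ChainCodeAnnotation(start=start, codes=tuple(codes), label=label)


def digitize(od_image: np.ndarray, profile: ScannerProfile,
             seed: int) -> GrayImage:
    """Simulate a scanner: invert the calibration curve, add noise, quantize.

    linear:       g = (od - cal_a) / cal_b
    logarithmic:  g = 10 ** ((od - cal_a) / cal_b)

    Gaussian gray-level noise of sd ``noise_sd`` is added, then values are
    clipped to [0, max_gray] and rounded to integers.
    """
    od = np.asarray(od_image, dtype=float)
    if profile.response == "linear":
        g = (od - profile.cal_a) / profile.cal_b
    else:
        g = np.power(10.0, (od - profile.cal_a) / profile.cal_b)
    if not np.all(np.isfinite(g)):
        raise ValueError("optical densities outside invertible range")
    if g.min() < -0.5 or g.max() > profile.max_gray + 0.5:
        raise ValueError(
            f"optical densities map outside [0, {profile.max_gray}] "
            f"for scanner {profile.name!r}")
    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, profile.noise_sd, size=g.shape)
    g = np.clip(np.rint(g), 0, profile.max_gray).astype(np.int64)
    return GrayImage(g, profile.max_gray)


# ---------------------------------------------------------------------------
# Site-level dataset generation
# ---------------------------------------------------------------------------

# Shape/margin mixes per pathology.  Malignant masses skew toward irregular
# shapes and spiculated margins with higher OD contrast; benign masses toward
# round/oval circumscribed masses with subtler contrast.
_SHAPE_MIX = {
    "malignant": (("irregular", 0.5), ("lobulated", 0.3), ("round", 0.1), ("oval", 0.1)),
    "benign": (("round", 0.4), ("oval", 0.4), ("lobulated", 0.2)),
}
_MARGIN_MIX = {
    "malignant": (("spiculated", 0.6), ("ill_defined", 0.3), ("circumscribed", 0.1)),
    "benign": (("circumscribed", 0.7), ("ill_defined", 0.3)),
}
_CONTRAST_RANGE = {"malignant": (0.50, 0.90), "benign": (0.30, 0.60)}


def _choice(rng: np.random.Generator, mix) -> str:
    names = [m[0] for m in mix]
    probs = np.array([m[1] for m in mix])
    return str(rng.choice(names, p=probs / probs.sum()))


def generate_site_dataset(
    profile: ScannerProfile,
    n_malignant: int,
    n_benign: int,
    n_normal: int,
    effect: float = 1.0,
    seed: int = 0,
    image_size: int = 128,
    diameter_range: tuple[int, int] = (24, 56),
    texture_scale: float = 6.0,
    mean_od: float = 1.5,
    texture_sd: float = 0.18,
) -> list[SyntheticCase]:
    """Generate one site's cases: annotated mass images plus normal images.

    Each mass case carries exactly one annotated mass whose diameter is drawn
    uniformly over ``diameter_range``; ``effect`` scales the OD contrast of
    every mass (``effect = 0`` makes masses invisible).  Counts may be
    arbitrarily imbalanced, including ``n_benign = 0``.
    """
    for n in (n_malignant, n_benign, n_normal):
        if n < 0:
            raise ValueError("counts must be non-negative")
    if effect < 0:
        raise ValueError("effect must be non-negative")
    rng = np.random.default_rng(seed)
    cases: list[SyntheticCase] = []
    jobs = (["malignant"] * n_malignant + ["benign"] * n_benign
            + ["normal"] * n_normal)
    for pathology in jobs:
        case_seed = int(rng.integers(0, 2**31))
        crng = np.random.default_rng(case_seed)
        bg = generate_background(image_size, image_size, texture_scale,
                                 mean_od, case_seed, texture_sd)
        if pathology == "normal":
            img = digitize(bg, profile, case_seed + 1)
            cases.append(SyntheticCase(image=img, annotations=(),
                                       site=profile.name, truth=(),
                                       seed=case_seed))
            continue
        diameter = int(crng.integers(diameter_range[0], diameter_range[1] + 1))
        margin = _choice(crng, _MARGIN_MIX[pathology])
        shape = _choice(crng, _SHAPE_MIX[pathology])
        lo, hi = _CONTRAST_RANGE[pathology]
        contrast = effect * crng.uniform(lo, hi)
        reach = (diameter / 2.0) * _MARGIN_REACH[margin]
        c_mid = image_size / 2.0
        jitter = max(0.0, min(8.0, c_mid - reach - 1.0))
        center = (int(round(c_mid + crng.uniform(-jitter, jitter))),
                  int(round(c_mid + crng.uniform(-jitter, jitter))))
        spec = MassSpec(shape=shape, margin=margin, diameter_px=diameter,
                        contrast=contrast, center=center)
        od, mask = render_mass(spec, bg, case_seed + 2)
        ann = trace_chain_code(mask, label=pathology)
        img = digitize(od, profile, case_seed + 3)
        cases.append(SyntheticCase(image=img, annotations=(ann,),
                                   site=profile.name, truth=(pathology,),
                                   seed=case_seed))
    return cases


# ---------------------------------------------------------------------------
# Default multi-site study roster
# ---------------------------------------------------------------------------

#: Four digitizer profiles: three linear, one logarithmic, 42-50 um.
#: Calibration coefficients follow the film-scanner convention that higher
#: gray level means lower optical density (negative slope).
DEFAULT_PROFILES: tuple[ScannerProfile, ...] = (
    ScannerProfile("howtek960", 43.5, "linear", 3.789, -0.00094568, 4095, 6.0),
    ScannerProfile("howtek850", 43.5, "linear", 3.96, -0.00099, 4095, 4.0),
    ScannerProfile("dba", 42.0, "logarithmic", 4.469, -0.9298, 65535, 40.0),
    ScannerProfile("lumisys", 50.0, "linear", 4.07, -0.00107, 4095, 5.0),
)

#: Per-site case counts (n_malignant, n_benign, n_normal_images), mirroring a
#: four-clinic archive at ~1/8 scale: one dominant site for normals ("dba")
#: with zero benign lesions, two small sites, one large balanced site.  With
#: two normal prototypes cut per normal image this yields ~630 prototypes.
DEFAULT_SITE_COUNTS: Mapping[str, tuple[int, int, int]] = {
    "howtek960": (43, 60, 20),
    "howtek850": (13, 19, 26),
    "dba": (13, 0, 104),
    "lumisys": (80, 62, 20),
}

#: Slight per-site differences in mean background OD (breast-density /
#: film-stock variation between clinics).
DEFAULT_SITE_MEAN_OD: Mapping[str, float] = {
    "howtek960": 1.45, "howtek850": 1.50, "dba": 1.60, "lumisys": 1.55,
}


def generate_study(
    effect: float = 1.0,
    seed: int = 0,
    counts: Mapping[str, tuple[int, int, int]] | None = None,
    profiles: Sequence[ScannerProfile] | None = None,
) -> tuple[list[SyntheticCase], dict[str, ScannerProfile]]:
    """Generate the full multi-site study; returns (cases, profiles-by-name)."""
    profiles = tuple(profiles) if profiles is not None else DEFAULT_PROFILES
    counts = dict(counts) if counts is not None else dict(DEFAULT_SITE_COUNTS)
    by_name = {p.name: p for p in profiles}
    unknown = set(counts) - set(by_name)
    if unknown:
        raise ValueError(f"counts reference undefined sites: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cases: list[SyntheticCase] = []
    for name in counts:
        n_mal, n_ben, n_norm = counts[name]
        site_seed = int(rng.integers(0, 2**31))
        mean_od = DEFAULT_SITE_MEAN_OD.get(name, 1.5)
        cases.extend(generate_site_dataset(
            by_name[name], n_mal, n_ben, n_norm, effect=effect,
            seed=site_seed, mean_od=mean_od))
    return cases, by_name


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------

def write_profiles_yaml(path: "str | Path",
                        profiles: Sequence[ScannerProfile]) -> None:
    data = {p.name: {"resolution_um": p.resolution_um, "response": p.response,
                     "cal_a": p.cal_a, "cal_b": p.cal_b,
                     "max_gray": p.max_gray, "noise_sd": p.noise_sd}
            for p in profiles}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_profiles_yaml(path: "str | Path") -> dict[str, ScannerProfile]:
    data = yaml.safe_load(Path(path).read_text())
    return {name: ScannerProfile(name=name, **vals) for name, vals in data.items()}


def write_dataset(out_dir: "str | Path", cases: Sequence[SyntheticCase],
                  profiles: Mapping[str, ScannerProfile]) -> None:
    """Write cases as PGM images + overlay files + a profiles YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_profiles_yaml(out / "profiles.yml", list(profiles.values()))
    for i, case in enumerate(cases):
        stem = f"{case.site}_{i:05d}"
        write_pgm(out / f"{stem}.pgm", case.image)
        write_overlay(out / f"{stem}.overlay", case.site, case.annotations)


def read_dataset(in_dir: "str | Path") -> tuple[list[SyntheticCase],
                                                dict[str, ScannerProfile]]:
    """Read back a dataset written by :func:`write_dataset`."""
    from .io_roi import read_overlay, read_pgm  # local import keeps api tidy

    in_dir = Path(in_dir)
    profiles = read_profiles_yaml(in_dir / "profiles.yml")
    cases = []
    for pgm in sorted(in_dir.glob("*.pgm")):
        site, anns = read_overlay(pgm.with_suffix(".overlay"))
        img = read_pgm(pgm)
        cases.append(SyntheticCase(image=img, annotations=tuple(anns),
                                   site=site,
                                   truth=tuple(a.label for a in anns), seed=-1))
    return cases, profiles
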