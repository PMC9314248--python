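"""Synthetic multi-magnification slide cohort with known ground truth.

Real interstitial-pneumonia slide cohorts are institutional and cannot be
redistributed, so every downstream stage of the pipeline is exercised on
procedurally generated slides instead. A slide is a patchwork of rectangular
texture regions; each texture class (a stand-in for a microscopic finding
such as dense fibrosis or a fibroblastic focus) is oriented band-pass noise
over a base colour, cheap to generate, seedable, and separable by a small
CNN. Case-level structure mirrors the statistical design of a biopsy cohort:

* a per-case composition vector ``x`` (area fraction of each texture class)
  drawn from a Dirichlet prior that differs between two latent disease
  groups,
* a binary diagnosis label (``uip_label``) drawn from a logistic model
  ``P(UIP=1|x) = sigmoid(w.x + b)``,
* a survival time ``min(E, horizon)`` with ``E ~ Exponential(h0 * exp(beta.x))``
  and administrative censoring at the follow-up horizon.

Slides are emitted at three magnification levels named ``20x`` (base),
``5x`` (base / 4) and ``2.5x`` (base / 8); the lower levels are exact block
downsamples of the base level, as in a scanner pyramid. Optional per-slide
stain jitter perturbs colour channels uniformly across a slide without
touching the ground-truth mask, emulating staining/scanner variation between
specimens.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.special import expit

__all__ = [
    "TextureClass", "SyntheticCohortConfig", "CaseTruth", "Slide",
    "default_texture_classes", "make_texture", "make_slide", "make_cohort",
    "write_cohort", "tile_true_labels", "LEVEL_FACTORS",
]

#: magnification name -> downsample factor relative to the base level
LEVEL_FACTORS = {"20x": 1, "5x": 4, "2.5x": 8}

# histology-flavoured base colours, pairwise mean-RGB distance > 60
_PALETTES = [
    (210, 140, 170),   # eosin pink
    (130, 110, 190),   # hematoxylin purple
    (235, 205, 160),   # pale tan
    (120, 170, 150),   # grey-green
    (180, 185, 110),   # olive
    (150, 100, 100),   # dull red-brown
    (90, 140, 200),    # blue-grey
    (240, 240, 235),   # near-white (airspace-like)
]


@dataclasses.dataclass(frozen=True)
class TextureClass:
    class_id: int
    name: str
    palette: tuple            # base RGB, 0-255
    orientation: float        # band orientation, degrees
    frequency: float          # cycles / pixel
    noise_amplitude: float    # 0..1; 0 gives a constant image

    def __post_init__(self):
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        if not 0.0 <= self.noise_amplitude <= 1.0:
            raise ValueError("noise_amplitude must lie in [0, 1]")


# orientation (deg) and band frequency (cycles/px) per class; class 0 — the
# rare decisive finding's stand-in — gets the strongest, most distinctive
# banding so that its identity is carried by structure, not just colour
_ORIENTATIONS = [30.0, 120.0, 60.0, 150.0, 0.0, 90.0, 45.0, 135.0]
_FREQUENCIES = [0.28, 0.10, 0.18, 0.06, 0.14, 0.22, 0.08, 0.24]


def default_texture_classes(n_classes: int = 4, noise_amplitude: float = 0.6
                            ) -> list[TextureClass]:
    """Texture classes with well-separated base colours and band structure."""
    if not 1 <= n_classes <= len(_PALETTES):
        raise ValueError(f"n_classes must be in [1, {len(_PALETTES)}]")
    out = []
    for i in range(n_classes):
        out.append(TextureClass(
            class_id=i,
            name=f"texture_{i}",
            palette=_PALETTES[i],
            orientation=_ORIENTATIONS[i],
            frequency=_FREQUENCIES[i],
            noise_amplitude=noise_amplitude,
        ))
    return out


def make_texture(texture_class: TextureClass, size: int, seed: int) -> np.ndarray:
    """Render one texture patch as (size, size, 3) uint8.

    Deterministic given (class parameters, seed). The signal is an oriented
    sinusoidal band plus smoothed white noise, both scaled by the class noise
    amplitude and added to the base colour as a luminance modulation, so the
    patch mean colour stays close to the palette.
    """
    if size < 32:
        raise ValueError("texture size must be >= 32 pixels")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, texture_class.class_id])
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    theta = np.deg2rad(texture_class.orientation)
    phase = 2 * np.pi * texture_class.frequency * (xx * np.cos(theta) + yy * np.sin(theta))
    band = np.sin(phase + rng.uniform(0, 2 * np.pi)).astype(np.float32)
    noise = rng.standard_normal((size, size)).astype(np.float32)
    # cheap smoothing: two passes of a 3-tap box filter along each axis
    for axis in (0, 1):
        noise = (np.roll(noise, 1, axis) + noise + np.roll(noise, -1, axis)) / 3.0
    signal = texture_class.noise_amplitude * (0.65 * band + 0.6 * noise)
    base = np.asarray(texture_class.palette, dtype=np.float32)
    img = base[None, None, :] + 90.0 * signal[:, :, None]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclasses.dataclass
class Slide:
    """One synthetic slide: image pyramid + base-level ground-truth mask."""
    slide_id: str
    case_id: str
    levels: dict              # level name -> (H, W, 3) uint8 array
    mask: np.ndarray          # base-level (H, W) int mask of class_ids
    composition: np.ndarray   # area fraction per class, from the mask


def _quantize_composition(composition: np.ndarray, n_regions: int) -> np.ndarray:
    """Largest-remainder allocation of regions to classes."""
    raw = composition * n_regions
    counts = np.floor(raw).astype(int)
    short = n_regions - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _block_downsample(img: np.ndarray, factor: int) -> np.ndarray:
    h, w = img.shape[:2]
    img = img[:h - h % factor, :w - w % factor]
    blocks = img.reshape(h // factor, factor, w // factor, factor, -1)
    return np.rint(blocks.mean(axis=(1, 3))).astype(np.uint8)


def make_slide(composition: Sequence[float], classes: Sequence[TextureClass],
               layout_seed: int, base_size: int = 256, region_grid: int = 4,
               stain_jitter: float = 0.0, slide_id: str = "slide",
               case_id: str = "case") -> Slide:
    """Assemble a pyramidal slide from rectangular texture regions.

    The base level is a ``region_grid x region_grid`` patchwork whose class
    area shares match ``composition`` up to one region quantum; lower levels
    are exact block downsamples. Stain jitter, when non-zero, applies one
    per-slide multiplicative colour gain and brightness offset to every
    level, leaving the mask untouched.
    """
    composition = np.asarray(composition, dtype=float)
    if abs(composition.sum() - 1.0) > 1e-6:
        raise ValueError("composition must sum to 1")
    if len(composition) != len(classes):
        raise ValueError("composition length must match class count")
    if base_size % (region_grid * max(LEVEL_FACTORS.values())) != 0:
        raise ValueError("base_size must be divisible by region_grid and level factors")

    rng = np.random.default_rng(int(layout_seed) & 0x7FFFFFFF)
    n_regions = region_grid * region_grid
    counts = _quantize_composition(composition, n_regions)
    region_classes = np.repeat(np.arange(len(classes)), counts)
    rng.shuffle(region_classes)

    rs = base_size // region_grid
    base = np.empty((base_size, base_size, 3), dtype=np.uint8)
    mask = np.empty((base_size, base_size), dtype=np.int32)
    for idx, cid in enumerate(region_classes):
        r, c = divmod(idx, region_grid)
        tex = make_texture(classes[cid], rs, seed=int(rng.integers(2**31)))
        base[r * rs:(r + 1) * rs, c * rs:(c + 1) * rs] = tex
        mask[r * rs:(r + 1) * rs, c * rs:(c + 1) * rs] = classes[cid].class_id

    if stain_jitter > 0:
        gain = 1.0 + rng.uniform(-stain_jitter, stain_jitter, size=3)
        offset = rng.uniform(-stain_jitter, stain_jitter) * 90.0
        base = np.clip(base.astype(np.float32) * gain + offset, 0, 255).astype(np.uint8)

    levels = {name: (base if f == 1 else _block_downsample(base, f))
              for name, f in LEVEL_FACTORS.items()}
    area = np.bincount(mask.ravel(), minlength=len(classes)) / mask.size
    return Slide(slide_id=slide_id, case_id=case_id, levels=levels,
                 mask=mask, composition=area)


@dataclasses.dataclass
class SyntheticCohortConfig:
    n_cases: int = 100
    classes: Sequence[TextureClass] = None
    composition_prior: np.ndarray = None     # (n_groups, n_classes) Dirichlet alphas
    uip_logit_weights: np.ndarray = None     # w over class proportions
    uip_intercept: float = -2.5
    cox_log_hr: np.ndarray = None            # beta over class proportions
    baseline_hazard: float = 1.0 / 6000.0    # events/day
    censor_horizon: float = 1825.0           # days (~5 years of follow-up)
    stain_jitter: float = 0.35               # hue/brightness amplitude; 0 disables
    base_size: int = 256
    region_grid: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.classes is None:
            self.classes = default_texture_classes(4)
        k = len(self.classes)
        if self.composition_prior is None:
            # class 0 plays the "rare but decisive" finding (a fibroblastic-
            # focus stand-in): present in the UIP-like group (0), nearly
            # absent in the other; the common classes are shared background
            self.composition_prior = np.array(
                [[2.0, 5.0, 3.0, 2.0][:k] if k <= 4 else [2.0] + [4.0] * (k - 1),
                 [0.2, 5.0, 3.0, 2.0][:k] if k <= 4 else [0.2] + [4.0] * (k - 1)])
        if self.uip_logit_weights is None:
            self.uip_logit_weights = np.zeros(k)
            self.uip_logit_weights[0] = 25.0
        if self.cox_log_hr is None:
            self.cox_log_hr = np.array([4.0, -1.0, 0.0, 0.0][:k] if k <= 4
                                       else [4.0] + [0.0] * (k - 1))
        self.composition_prior = np.atleast_2d(np.asarray(self.composition_prior, float))
        self.uip_logit_weights = np.asarray(self.uip_logit_weights, float)
        self.cox_log_hr = np.asarray(self.cox_log_hr, float)
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if self.censor_horizon <= 0 or self.baseline_hazard <= 0:
            raise ValueError("censor_horizon and baseline_hazard must be > 0")
        for vec in (self.uip_logit_weights, self.cox_log_hr):
            if vec.shape != (k,):
                raise ValueError("weight vectors must match the class count")
        if self.composition_prior.shape[1] != k:
            raise ValueError("composition_prior must match the class count")


@dataclasses.dataclass
class CaseTruth:
    case_id: str
    true_composition: np.ndarray
    uip_label: int
    survival_time: float
    event: int


def make_cohort(config: SyntheticCohortConfig):
    """Draw a full cohort: slides (one per case) plus the CaseTruth table.

    Returns ``(slides, truth_df)`` where ``truth_df`` has one row per case
    with the true composition, diagnosis label and censored survival time.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.classes)
    n_groups = config.composition_prior.shape[0]
    slides, rows = [], []
    for i in range(config.n_cases):
        case_id = f"case_{i:04d}"
        g = int(rng.integers(n_groups))
        x = rng.dirichlet(config.composition_prior[g])
        slide = make_slide(
            x, config.classes, layout_seed=int(rng.integers(2**31)),
            base_size=config.base_size, region_grid=config.region_grid,
            stain_jitter=config.stain_jitter,
            slide_id=f"{case_id}_s0", case_id=case_id)
        # the achievable (region-quantised) composition is the ground truth
        x_true = slide.composition
        logit = float(config.uip_logit_weights @ x_true + config.uip_intercept)
        uip = int(rng.random() < expit(logit))
        rate = config.baseline_hazard * np.exp(float(config.cox_log_hr @ x_true))
        e_time = rng.exponential(1.0 / rate)
        event = int(e_time <= config.censor_horizon)
        t = min(e_time, config.censor_horizon)
        slides.append(slide)
        rows.append({"case_id": case_id, "group": g,
                     **{f"prop_{c.name}": x_true[j] for j, c in enumerate(config.classes)},
                     "uip_label": uip, "time_days": t, "event": event})
    truth = pd.DataFrame(rows)
    return slides, truth


def write_cohort(slides: list, truth: pd.DataFrame, outdir: str | Path) -> Path:
    """Write slides (per-level PNG + mask PNG), truth CSV and manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in slides:
        for level, img in s.levels.items():
            p = outdir / f"{s.slide_id}_{level.replace('.', '_')}.png"
            Image.fromarray(img).save(p)
        mp = outdir / f"{s.slide_id}_mask.png"
        Image.fromarray(s.mask.astype(np.uint8)).save(mp)
        manifest.append({"slide_id": s.slide_id, "case_id": s.case_id,
                         "levels": sorted(s.levels)})
    truth.to_csv(outdir / "case_truth.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def tile_true_labels(slide: Slide, tiles, level: str, tile_size: int) -> np.ndarray:
    """Majority ground-truth class for each tile, from the base-level mask."""
    f = LEVEL_FACTORS[level]
    labels = np.empty(len(tiles), dtype=np.int64)
    for i, t in enumerate(tiles):
        y0, x0 = t.origin_y * f, t.origin_x * f
        patch = slide.mask[y0:y0 + tile_size * f, x0:x0 + tile_size * f]
        labels[i] = np.bincount(patch.ravel()).argmax()
    return labels
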