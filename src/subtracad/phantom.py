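"""Synthetic sequential-mammogram cohort generator with ground truth.

Emulates a two-round screening cohort: per patient, CC and MLO views of a
prior (always mass-free) and a recent round.  The breast is a half-ellipse
anchored on the chest-wall edge; fibroglandular texture is band-pass
filtered noise whose amplitude grows with BI-RADS density class a→d, so
dense breasts hide masses the way they do in practice.  Between rounds a
smooth random displacement field (positioning/compression stand-in), a
global intensity drift, and additive Gaussian noise are applied; the exact
field is recorded so registration recovery can be scored against it.

Recent-round masses follow the radiological shape prior: benign masses are
near-circular with smooth margins (low-order Fourier boundary
perturbation), malignant ones are spiculated and irregular (high-frequency
boundary spikes).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .core import (
    DENSITY_CLASSES,
    DegenerateGeometryError,
    DeformationField,
    Mammogram,
)
from .io import write_image, write_mask
from .register import warp

#: fibroglandular texture amplitude per BI-RADS density class
DENSITY_TEXTURE_AMPLITUDE = {"a": 0.02, "b": 0.045, "c": 0.075, "d": 0.11}

#: cohort composition of the emulated study population
DEFAULT_DENSITY_WEIGHTS = {"a": 0.11, "b": 0.45, "c": 0.39, "d": 0.05}
DEFAULT_CLASS_MIX = {"normal": 0.35, "benign": 0.15, "malignant": 0.50}

MANIFEST_HEADER = [
    "patient_id",
    "view",
    "round",
    "image_path",
    "mask_path",
    "label",
    "density",
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic screening cohort."""

    n_patients: int = 100
    views: tuple[str, ...] = ("CC", "MLO")
    n_rounds: int = 2
    density_weights: dict = field(default_factory=lambda: dict(DEFAULT_DENSITY_WEIGHTS))
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    image_shape: tuple[int, int] = (256, 208)
    deformation_magnitude: float = 6.0  # max |displacement|, pixels
    noise_sigma: float = 0.01  # additive noise, intensity units in [0,1]
    mass_contrast: float = 0.25  # peak mass brightness above local tissue
    mass_radius_range: tuple[float, float] = (7.0, 12.0)
    #: masses inserted per view; benign patients present several small
    #: findings per exam while malignant ones typically show a single new
    #: mass, which keeps the cohort's mass-level class counts near parity
    masses_per_view: dict = field(default_factory=lambda: {"benign": 3, "malignant": 1})
    intensity_drift: float = 0.04  # max |multiplicative gain - 1| between rounds
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_rounds != 2:
            raise ValueError("only two screening rounds (prior, recent) are supported")
        if min(self.image_shape) < 64:
            raise ValueError("image_shape dims must be >= 64")
        if abs(sum(self.density_weights.values()) - 1.0) > 1e-9:
            raise ValueError("density_weights must sum to 1")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if set(self.density_weights) != set(DENSITY_CLASSES):
            raise ValueError(f"density_weights must cover classes {DENSITY_CLASSES}")
        if set(self.class_mix) != {"normal", "benign", "malignant"}:
            raise ValueError("class_mix must cover normal/benign/malignant")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    deformation: dict  # (view) -> DeformationField applied prior->recent
    mass_masks: dict  # (view) -> list of binary masks on the recent image grid
    mass_labels: list  # benign | malignant, one per inserted mass
    density_class: str
    breast_masks: dict  # (view, round) -> binary breast mask
    patient_label: str  # normal | benign | malignant


def _breast_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    rows, cols = shape
    center_row = rows / 2 + rng.uniform(-0.05, 0.05) * rows
    semi_r = rows * rng.uniform(0.38, 0.46)
    semi_c = cols * rng.uniform(0.68, 0.80)
    rr, cc = np.mgrid[0:rows, 0:cols]
    ellipse = ((rr - center_row) / semi_r) ** 2 + (cc / semi_c) ** 2
    return ellipse <= 1.0


def _anatomy(
    shape: tuple[int, int], density: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free base anatomy for one view: (image, breast mask)."""
    mask = _breast_mask(shape, rng)
    dist = distance_transform_edt(mask)
    dmax = max(dist.max(), 1.0)
    # dome-shaped base brightness, brighter toward the breast interior
    base = 0.28 + 0.22 * np.sqrt(dist / dmax)

    white = rng.standard_normal(shape)
    texture = gaussian_filter(white, 1.5) - gaussian_filter(white, 6.0)
    texture /= max(texture.std(), 1e-12)
    # fibroglandular tissue occupies the inner breast
    inner = dist > 0.25 * dmax
    img = base + DENSITY_TEXTURE_AMPLITUDE[density] * texture * inner
    img = np.clip(img, 0.0, 1.0) * mask
    return img, mask


def _random_field(
    shape: tuple[int, int],
    magnitude: float,
    rng: np.random.Generator,
    n_bumps: int = 3,
) -> DeformationField:
    """Smooth random displacement field with max magnitude ``magnitude``."""
    rows, cols = shape
    disp = np.zeros((2, rows, cols))
    if magnitude > 0:
        rr, cc = np.mgrid[0:rows, 0:cols]
        for _ in range(n_bumps):
            r0 = rng.uniform(0.2, 0.8) * rows
            c0 = rng.uniform(0.1, 0.7) * cols
            sigma = rng.uniform(0.12, 0.22) * min(rows, cols)
            bump = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
            direction = rng.standard_normal(2)
            direction /= np.linalg.norm(direction)
            amp = rng.uniform(0.4, 1.0)
            disp[0] += amp * direction[0] * bump
            disp[1] += amp * direction[1] * bump
        peak = np.hypot(disp[0], disp[1]).max()
        if peak > 0:
            disp *= magnitude / peak
    return DeformationField(disp, provenance="phantom ground truth")


def _mass_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    label: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize a mass boundary r(θ) around ``center``.

    Benign: low-order smooth perturbation; malignant: high-frequency
    spicules giving an irregular, star-like margin.
    """
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr, dc = rr - center[0], cc - center[1]
    theta = np.arctan2(dr, dc)
    if label == "benign":
        orders = (2, 3)
        amps = rng.uniform(0.03, 0.08, size=len(orders))
    else:
        orders = tuple(range(6, 13, 2))
        amps = rng.uniform(0.18, 0.32, size=len(orders))
    phases = rng.uniform(0, 2 * np.pi, size=len(orders))
    boundary = np.ones_like(theta)
    for k, a, p in zip(orders, amps, phases):
        boundary = boundary + a * np.cos(k * theta + p)
    return np.hypot(dr, dc) <= radius * boundary


def _place_masses(
    recent: np.ndarray,
    breast: np.ndarray,
    labels: Sequence[str],
    cfg: CohortConfig,
    rng: np.random.Generator,
    max_retries: int = 150,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Insert one mass per label into the recent image; returns masks."""
    out = recent.copy()
    masks: list[np.ndarray] = []
    r_lo, r_hi = cfg.mass_radius_range
    # centers deep enough that the full (spiculated) boundary stays clear of
    # the skin line and of the peripheral-removal band of the detector
    depth = distance_transform_edt(breast)
    if labels and 1.2 * r_hi >= depth.max():
        raise DegenerateGeometryError(
            f"breast region (max depth {depth.max():.0f} px) cannot contain "
            f"a mass of radius up to {r_hi:.0f} px"
        )
    # small breasts (small images) cannot offer the full margin; cap the
    # requirement at a fraction of the deepest point so placement stays
    # feasible at any configured scale
    min_depth = min(1.4 * r_hi + 22.0, 0.6 * float(depth.max()))
    candidates = np.argwhere(depth > min_depth)
    if candidates.size == 0:
        candidates = np.argwhere(depth > 1.6 * r_hi)
    placed_centers: list[tuple[float, float, float]] = []  # (row, col, radius)
    for label in labels:
        if candidates.size == 0:
            raise DegenerateGeometryError("breast region too small to host a mass")
        radius = rng.uniform(r_lo, r_hi)
        placed = False
        # two phases: generous spacing first, then the minimum spacing
        # that still keeps detected components from merging
        for spacing_scale, spacing_pad in ((1.4, 12.0), (1.1, 6.0)):
            for _ in range(max_retries):
                center = candidates[rng.integers(len(candidates))]
                too_close = any(
                    np.hypot(center[0] - r0, center[1] - c0)
                    < spacing_scale * (radius + r0_rad) + spacing_pad
                    for r0, c0, r0_rad in placed_centers
                )
                if too_close:
                    continue
                mask = _mass_mask(recent.shape, tuple(center), radius, label, rng)
                mask &= breast
                if mask.sum() < 10:
                    continue
                if any((mask & m).any() for m in masks):
                    continue
                # soft radial brightness profile on top of local tissue
                dist_in = distance_transform_edt(mask)
                profile = (dist_in / max(dist_in.max(), 1.0)) ** 0.5
                out = out + cfg.mass_contrast * (0.45 + 0.55 * profile) * mask
                masks.append(mask)
                placed_centers.append((float(center[0]), float(center[1]), radius))
                placed = True
                break
            if placed:
                break
        if not placed:
            raise DegenerateGeometryError(
                f"could not place a {label} mass after {2 * max_retries} retries"
            )
    return np.clip(out, 0.0, 1.0), masks


def draw_patient_label(class_mix: dict, rng: np.random.Generator) -> str:
    keys = ("normal", "benign", "malignant")
    return str(rng.choice(keys, p=[class_mix[k] for k in keys]))


def draw_density(density_weights: dict, rng: np.random.Generator) -> str:
    return str(
        rng.choice(DENSITY_CLASSES, p=[density_weights[k] for k in DENSITY_CLASSES])
    )


def generate_patient(
    config: CohortConfig,
    patient_id: str,
    rng_state,
    patient_label: Optional[str] = None,
    density: Optional[str] = None,
) -> tuple[list[Mammogram], GroundTruth]:
    """Generate all views/rounds for one patient plus ground truth.

    ``rng_state`` may be an int seed or a ``numpy.random.Generator``.  The
    prior round is always mass-free; benign/malignant patients receive one
    mass per view in the recent round (a "new mass" presentation).
    """
    config.validate()
    rng = np.random.default_rng(rng_state)
    if patient_label is None:
        patient_label = draw_patient_label(config.class_mix, rng)
    if density is None:
        density = draw_density(config.density_weights, rng)

    images: list[Mammogram] = []
    deformations: dict = {}
    mass_masks: dict = {}
    breast_masks: dict = {}
    mass_labels: list[str] = []

    for view in config.views:
        anatomy, breast = _anatomy(config.image_shape, density, rng)
        field_gt = _random_field(config.image_shape, config.deformation_magnitude, rng)
        recent_clean = warp(anatomy, field_gt)
        recent_breast = warp(breast.astype(float), field_gt) > 0.5

        if patient_label in ("benign", "malignant"):
            labels = [patient_label] * config.masses_per_view.get(patient_label, 1)
        else:
            labels = []
        recent_clean, masks = _place_masses(
            recent_clean, recent_breast, labels, config, rng
        )
        if view == config.views[0]:
            mass_labels = list(labels)

        gain = 1.0 + rng.uniform(-config.intensity_drift, config.intensity_drift)
        recent_clean = np.clip(recent_clean * gain, 0.0, 1.0)

        prior = np.clip(
            anatomy + config.noise_sigma * rng.standard_normal(config.image_shape),
            0.0,
            1.0,
        )
        recent = np.clip(
            recent_clean + config.noise_sigma * rng.standard_normal(config.image_shape),
            0.0,
            1.0,
        )

        images.append(Mammogram(prior, patient_id, view, "prior"))
        images.append(Mammogram(recent, patient_id, view, "recent"))
        deformations[view] = field_gt
        mass_masks[view] = masks
        breast_masks[(view, "prior")] = breast
        breast_masks[(view, "recent")] = recent_breast

    truth = GroundTruth(
        deformation=deformations,
        mass_masks=mass_masks,
        mass_labels=mass_labels,
        density_class=density,
        breast_masks=breast_masks,
        patient_label=patient_label,
    )
    return images, truth


def generate_cohort(config: CohortConfig, out_dir) -> Path:
    """Write a full cohort to ``out_dir`` and return the manifest path.

    Layout: ``images/<patient>_<view>_<round>.png`` (16-bit),
    ``masks/<patient>_<view>_mass.png`` (8-bit 0/255, union of masses in the
    recent round), and ``manifest.csv``.
    """
    config.validate()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    rows = []
    for i, seed in enumerate(seeds):
        pid = f"P{i:03d}"
        images, truth = generate_patient(config, pid, np.random.default_rng(seed))
        for img in images:
            name = f"{pid}_{img.view}_{img.round}.png"
            path = out_dir / "images" / name
            write_image(path, img.pixels)
            mask_path = ""
            if img.round == "recent" and truth.mass_masks[img.view]:
                union = np.zeros(config.image_shape, dtype=bool)
                for m in truth.mass_masks[img.view]:
                    union |= m
                mask_path = str(Path("masks") / f"{pid}_{img.view}_mass.png")
                write_mask(out_dir / mask_path, union)
            rows.append(
                {
                    "patient_id": pid,
                    "view": img.view,
                    "round": img.round,
                    "image_path": str(Path("images") / name),
                    "mask_path": mask_path,
                    "label": truth.patient_label,
                    "density": truth.density_class,
                }
            )

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_HEADER)
        writer.writeheader()
        writer.writerows(rows)
    return manifest
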