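"""Synthetic low-SNR micrograph generator with exact ground truth.

Emulates the regime that makes cryo-EM picking hard — many roughly circular,
similarly sized particles, densely packed over a slowly varying background,
buried in heavy additive noise, with unannotated contamination blobs exerting
false-positive pressure. It does NOT model CTF oscillations, radiation
damage, ice gradients or real projection structure; passing tests on this
data demonstrate that the detector machinery works, not that it matches
published performance on real micrographs.

Particles are dark-on-light (protein appears dark at negative defocus); a
polarity flag flips this. Every micrograph is a pure function of
``(config, seed, index)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .geometry import Box, box_to_pixels
from .io_formats import (
    AnnotationRecord,
    AnnotationSet,
    ImageInfo,
    MicrographRecord,
    PickedParticle,
    standardize,
    write_coco,
    write_micrograph,
    write_star,
)

logger = logging.getLogger(__name__)

#: Peak particle depth relative to background; noise_sigma is relative to this.
PARTICLE_CONTRAST = 1.0

#: Soft-edge width of the rendered disks, pixels.
EDGE_WIDTH = 1.2


@dataclass(frozen=True)
class SimConfig:
    """Benchmark defaults: 128 px frames, 8±2 px particle radius, 5–15
    particles at ≥12 px center separation, noise at 0.8x particle contrast,
    two contamination distractors."""

    image_size: int = 128
    n_particles: tuple[int, int] = (5, 15)
    radius_mean: float = 8.0
    radius_jitter: float = 2.0
    min_center_separation: float = 12.0
    noise_sigma: float = 0.8
    n_distractors: int = 2
    seed: int = 0
    dark_particles: bool = True
    background_amplitude: float = 0.2

    def __post_init__(self):
        if self.min_center_separation < 0:
            raise ValueError("min_center_separation must be >= 0")
        if not self.radius_mean > self.radius_jitter >= 0:
            raise ValueError("need radius_mean > radius_jitter >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _rng_for(cfg: SimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, int(index)]))


def _soft_disk(size: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(xx - cx, yy - cy)
    return 1.0 / (1.0 + np.exp((dist - radius) / EDGE_WIDTH))


def _background(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    u = xx / size * 2 * np.pi
    v = yy / size * 2 * np.pi
    field = np.zeros((size, size))
    for _ in range(3):
        fx, fy = rng.uniform(0.5, 1.5, size=2)
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        field += rng.uniform(-1, 1) * np.cos(fx * u + px) * np.cos(fy * v + py)
    peak = np.abs(field).max()
    return amplitude * field / peak if peak > 0 else field


def generate_micrograph(cfg: SimConfig, index: int) -> tuple[MicrographRecord, AnnotationSet]:
    """Render micrograph ``index`` and its exact annotations.

    Centers are rejection-sampled to honor ``min_center_separation``; if
    placement stalls after ``10 * n`` attempts the micrograph simply carries
    fewer particles (logged). The ground-truth box of each particle is the
    tight square of side ``2 * radius`` around its center, always fully
    inside the frame. Distractor blobs never overlap an annotated box.
    """
    rng = _rng_for(cfg, index)
    size = cfg.image_size
    n_target = int(rng.integers(cfg.n_particles[0], cfg.n_particles[1] + 1))

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < n_target and attempts < 10 * n_target:
        attempts += 1
        r = rng.uniform(cfg.radius_mean - cfg.radius_jitter,
                        cfg.radius_mean + cfg.radius_jitter)
        margin = r + 1.0
        cx = rng.uniform(margin, size - margin)
        cy = rng.uniform(margin, size - margin)
        if all(np.hypot(cx - ox, cy - oy) >= cfg.min_center_separation
               for ox, oy in centers):
            centers.append((cx, cy))
            radii.append(r)
    if len(centers) < n_target:
        logger.info("micrograph %d: placed %d/%d particles after %d attempts",
                    index, len(centers), n_target, attempts)

    sign = -1.0 if cfg.dark_particles else 1.0
    clean = _background(size, cfg.background_amplitude, rng)
    for (cx, cy), r in zip(centers, radii):
        clean += sign * PARTICLE_CONTRAST * _soft_disk(size, cx, cy, r)

    # contamination blobs: larger, irregular, NOT annotated, kept clear of
    # every particle box
    for _ in range(cfg.n_distractors):
        for _attempt in range(50):
            extent = rng.uniform(1.5, 3.0) * cfg.radius_mean
            dx = rng.uniform(extent, size - extent)
            dy = rng.uniform(extent, size - extent)
            clear = all(
                max(abs(dx - cx), abs(dy - cy)) > extent + r + 1.0
                for (cx, cy), r in zip(centers, radii))
            if clear:
                theta = rng.uniform(0, np.pi)
                ax = extent
                ay = extent * rng.uniform(0.4, 0.9)
                yy, xx = np.mgrid[0:size, 0:size]
                xr = (xx - dx) * np.cos(theta) + (yy - dy) * np.sin(theta)
                yr = -(xx - dx) * np.sin(theta) + (yy - dy) * np.cos(theta)
                dist = np.sqrt((xr / ax) ** 2 + (yr / ay) ** 2) * extent
                blob = 1.0 / (1.0 + np.exp((dist - extent * 0.8) / (2 * EDGE_WIDTH)))
                clean += sign * 0.6 * PARTICLE_CONTRAST * blob
                break

    image = clean + rng.normal(0.0, cfg.noise_sigma * PARTICLE_CONTRAST, size=(size, size))

    name = f"sim_{index:05d}.mrc"
    record = MicrographRecord(image=standardize(image), micrograph_id=name,
                              width=size, height=size)
    annos = AnnotationSet()
    annos.images[name] = ImageInfo(id=index + 1, file_name=name, width=size, height=size)
    for (cx, cy), r in zip(centers, radii):
        annos.records.append(AnnotationRecord(
            micrograph_id=name,
            box=Box(cx=cx / size, cy=cy / size, w=2 * r / size, h=2 * r / size)))
    return record, annos


def generate_records(cfg: SimConfig, n_images: int, start_index: int = 0
                     ) -> tuple[list[MicrographRecord], AnnotationSet]:
    """In-memory dataset: ``n_images`` micrographs and their merged annotations."""
    records = []
    merged = AnnotationSet()
    for i in range(start_index, start_index + n_images):
        record, annos = generate_micrograph(cfg, i)
        records.append(record)
        merged.images.update(annos.images)
        merged.records.extend(annos.records)
    return records, merged


def split_of_index(index: int) -> str:
    """8:1:1 split by index hashing: residues 0–7 train, 8 val, 9 test."""
    residue = index % 10
    if residue < 8:
        return "train"
    return "val" if residue == 8 else "test"


def generate_dataset(cfg: SimConfig, n_images: int, out_dir: str | Path,
                     image_format: str = "mrc", write_truth_star: bool = True) -> Path:
    """Write micrographs, one COCO file, a split manifest and a truth .star."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    merged = AnnotationSet()
    splits: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    particles: list[PickedParticle] = []
    for i in range(n_images):
        record, annos = generate_micrograph(cfg, i)
        name = Path(record.micrograph_id).stem + "." + image_format
        info = next(iter(annos.images.values()))
        info.file_name = name
        merged.images[name] = info
        for r in annos.records:
            merged.records.append(replace(r, micrograph_id=name))
            pb = box_to_pixels(r.box, record.width, record.height)
            particles.append(PickedParticle(
                micrograph_name=name,
                x=(pb.x_min + pb.x_max) / 2.0,
                y=(pb.y_min + pb.y_max) / 2.0,
                score=1.0))
        write_micrograph(record.image, out_dir / name)
        splits[split_of_index(i)].append(name)
    write_coco(merged, out_dir / "annotations.json")
    with open(out_dir / "splits.json", "w") as fh:
        json.dump(splits, fh, indent=1, sort_keys=True)
    if write_truth_star:
        sizes = {n: (info.width, info.height) for n, info in merged.images.items()}
        write_star(particles, out_dir / "truth.star", image_sizes=sizes)
    logger.info("wrote %d micrographs (%d/%d/%d split) to %s", n_images,
                len(splits["train"]), len(splits["val"]), len(splits["test"]), out_dir)
    return out_dir


def measured_snr(record: MicrographRecord, annos: AnnotationSet,
                 cap: float = 1e6) -> float:
    """Empirical contrast-to-noise ratio of a simulated micrograph.

    Foreground is the core (inner 60 % radius) of each annotated particle;
    background is everything outside all annotated boxes. Returns
    |mean(bg) - mean(fg)| / sd(bg), capped.
    """
    boxes = annos.boxes_for(record.micrograph_id)
    if not boxes:
        raise ValueError("measured_snr needs at least one annotation")
    yy, xx = np.mgrid[0:record.height, 0:record.width]
    fg = np.zeros(record.image.shape, dtype=bool)
    in_box = np.zeros(record.image.shape, dtype=bool)
    for b in boxes:
        cx, cy = b.cx * record.width, b.cy * record.height
        r = b.w * record.width / 2.0
        dist = np.hypot(xx - cx, yy - cy)
        fg |= dist <= 0.6 * r
        in_box |= ((np.abs(xx - cx) <= r) & (np.abs(yy - cy) <= r))
    bg = ~in_box
    bg_sd = record.image[bg].std()
    if bg_sd == 0:
        return cap
    ratio = abs(record.image[bg].mean() - record.image[fg].mean()) / bg_sd
    return min(ratio, cap)
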