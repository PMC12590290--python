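"""Micrograph, COCO-annotation and STAR-coordinate I/O.

Conventions used throughout:

* Images are 2D float arrays, standardized per micrograph to zero mean and
  unit variance (with a variance floor so constant frames become all-zero).
* COCO boxes on disk are ``(x_min, y_min, w, h)`` in pixels; in memory every
  annotation is a normalized center-form :class:`~gtpick.geometry.Box`.
* STAR coordinates are particle CENTERS in original-micrograph pixel space,
  0-based with the origin at the top-left — the convention CryoSPARC's
  extract-from-coordinates expects. RELION display tools may assume a
  different origin; re-state this when importing elsewhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Box

logger = logging.getLogger(__name__)

STAR_COLUMNS = (
    "_rlnMicrographName",
    "_rlnCoordinateX",
    "_rlnCoordinateY",
    "_rlnAutopickFigureOfMerit",
)

PARTICLE_CATEGORY_ID = 1


@dataclass
class MicrographRecord:
    """One 2D grayscale micrograph plus identity and geometry metadata."""

    image: np.ndarray
    micrograph_id: str
    width: int
    height: int
    pixel_size: float | None = None
    source_path: str = ""

    def __post_init__(self):
        if self.image.shape != (self.height, self.width):
            raise ValueError(
                f"image shape {self.image.shape} does not match "
                f"(height={self.height}, width={self.width})")
        if not np.all(np.isfinite(self.image)):
            raise ValueError(f"non-finite intensities in {self.micrograph_id}")


@dataclass
class ImageInfo:
    id: int
    file_name: str
    width: int
    height: int


@dataclass
class AnnotationRecord:
    micrograph_id: str
    box: Box
    category_id: int = PARTICLE_CATEGORY_ID


@dataclass
class AnnotationSet:
    """Single-class particle annotations plus the micrograph index."""

    images: dict[str, ImageInfo] = field(default_factory=dict)
    records: list[AnnotationRecord] = field(default_factory=list)

    def boxes_for(self, micrograph_id: str) -> list[Box]:
        return [r.box for r in self.records if r.micrograph_id == micrograph_id]


@dataclass
class PickedParticle:
    """One picked particle center in ORIGINAL micrograph pixel space."""

    micrograph_name: str
    x: float
    y: float
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


# -- micrograph reading -------------------------------------------------------


def standardize(image: np.ndarray, variance_floor: float = 1e-8) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    centered = image - image.mean()
    sd = centered.std()
    if sd < variance_floor:
        return np.zeros_like(centered)
    return centered / sd


def _read_mrc(path: Path) -> tuple[np.ndarray, float | None]:
    import gemmi

    ccp4 = gemmi.read_ccp4_map(str(path))
    data = np.array(ccp4.grid, copy=True)
    data = np.squeeze(data)
    if data.ndim == 3:
        raise ValueError(
            f"{path.name}: multi-section stack ({data.shape[0]} sections); "
            "expected a single 2D micrograph")
    if data.ndim != 2:
        raise ValueError(f"{path.name}: expected 2D data, got shape {data.shape}")
    spacing = ccp4.grid.spacing
    pixel_size = float(spacing[0]) if spacing and spacing[0] > 0 else None
    return data, pixel_size


def read_micrograph(path: str | Path) -> MicrographRecord:
    """Read an MRC/PNG/TIFF micrograph, standardized to zero mean, unit sd."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    pixel_size = None
    if suffix in {".mrc", ".mrcs"}:
        data, pixel_size = _read_mrc(path)
    elif suffix in {".png", ".tif", ".tiff"}:
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path), dtype=np.float64)
        if data.ndim == 3:  # collapse color channels to luminance
            data = data.mean(axis=-1)
    else:
        raise ValueError(f"unsupported micrograph format: {path.suffix!r}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path.name}: non-finite pixel data")
    height, width = data.shape
    return MicrographRecord(
        image=standardize(data),
        micrograph_id=path.name,
        width=int(width),
        height=int(height),
        pixel_size=pixel_size,
        source_path=str(path),
    )


def write_micrograph(image: np.ndarray, path: str | Path) -> None:
    """Write a float image as MRC (float32), PNG (uint16) or TIFF (float32)."""
    path = Path(path)
    image = np.asarray(image)
    suffix = path.suffix.lower()
    if suffix in {".mrc", ".mrcs"}:
        import gemmi

        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(
            image[np.newaxis, :, :], dtype=np.float32))
        ccp4.update_ccp4_header()
        ccp4.write_ccp4_map(str(path))
    elif suffix == ".png":
        import imageio.v3 as iio

        lo, hi = float(image.min()), float(image.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        iio.imwrite(path, ((image - lo) * scale).astype(np.uint16))
    elif suffix in {".tif", ".tiff"}:
        import imageio.v3 as iio

        iio.imwrite(path, image.astype(np.float32))
    else:
        raise ValueError(f"unsupported micrograph format: {path.suffix!r}")


# -- COCO annotations ---------------------------------------------------------


def read_coco(json_path: str | Path) -> AnnotationSet:
    """Load COCO-style annotations, converting boxes to normalized center form.

    Boxes protruding beyond image bounds by more than one pixel are clamped
    to the frame with a warning; a single foreground category is enforced.
    """
    json_path = Path(json_path)
    with open(json_path) as fh:
        payload = json.load(fh)
    categories = payload.get("categories", [])
    if len(categories) > 1:
        raise ValueError("expected a single 'particle' category")
    images_by_id: dict[int, ImageInfo] = {}
    annos = AnnotationSet()
    for entry in payload.get("images", []):
        info = ImageInfo(id=int(entry["id"]), file_name=str(entry["file_name"]),
                         width=int(entry["width"]), height=int(entry["height"]))
        images_by_id[info.id] = info
        annos.images[info.file_name] = info
    n_clamped = 0
    for entry in payload.get("annotations", []):
        image_id = int(entry["image_id"])
        if image_id not in images_by_id:
            raise ValueError(f"annotation {entry.get('id')} references unknown image id {image_id}")
        info = images_by_id[image_id]
        x, y, w, h = (float(v) for v in entry["bbox"])
        if (x < -1.0 or y < -1.0 or x + w > info.width + 1.0 or y + h > info.height + 1.0):
            n_clamped += 1
        x0 = min(max(x, 0.0), info.width - 1.0)
        y0 = min(max(y, 0.0), info.height - 1.0)
        x1 = min(max(x + w, x0 + 1e-6), float(info.width))
        y1 = min(max(y + h, y0 + 1e-6), float(info.height))
        box = Box(cx=(x0 + x1) / 2.0 / info.width, cy=(y0 + y1) / 2.0 / info.height,
                  w=(x1 - x0) / info.width, h=(y1 - y0) / info.height)
        annos.records.append(AnnotationRecord(
            micrograph_id=info.file_name, box=box,
            category_id=int(entry.get("category_id", PARTICLE_CATEGORY_ID))))
    if n_clamped:
        logger.warning("%d boxes exceeded image bounds by >1 px and were clamped", n_clamped)
    logger.info("read %d annotations on %d images from %s",
                len(annos.records), len(annos.images), json_path)
    return annos


def write_coco(annos: AnnotationSet, out_path: str | Path) -> None:
    """Inverse of :func:`read_coco`; deterministic key ordering."""
    images = [
        {"id": info.id, "file_name": info.file_name,
         "width": info.width, "height": info.height}
        for info in sorted(annos.images.values(), key=lambda i: i.id)
    ]
    id_by_name = {info.file_name: info.id for info in annos.images.values()}
    annotations = []
    for i, record in enumerate(annos.records):
        info = annos.images[record.micrograph_id]
        w = record.box.w * info.width
        h = record.box.h * info.height
        x = record.box.cx * info.width - w / 2.0
        y = record.box.cy * info.height - h / 2.0
        annotations.append({
            "id": i + 1,
            "image_id": id_by_name[record.micrograph_id],
            "category_id": record.category_id,
            "bbox": [round(x, 6), round(y, 6), round(w, 6), round(h, 6)],
            "area": round(w * h, 6),
            "iscrowd": 0,
        })
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": PARTICLE_CATEGORY_ID, "name": "particle"}],
    }
    with open(out_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    logger.info("wrote %d annotations to %s", len(annotations), out_path)


# -- STAR coordinates ---------------------------------------------------------


def write_star(particles: list[PickedParticle], out_path: str | Path,
               image_sizes: dict[str, tuple[int, int]] | None = None) -> None:
    """Write picked centers as a RELION-style loop block.

    One data block, one loop, four columns (micrograph name, x, y, figure of
    merit); coordinates printed with six decimals. When ``image_sizes`` maps
    micrograph names to ``(width, height)``, out-of-bounds particles are
    rejected.
    """
    if image_sizes is not None:
        for p in particles:
            if p.micrograph_name not in image_sizes:
                raise ValueError(f"unknown micrograph {p.micrograph_name!r}")
            w, h = image_sizes[p.micrograph_name]
            if not (0.0 <= p.x < w and 0.0 <= p.y < h):
                raise ValueError(
                    f"particle at ({p.x}, {p.y}) outside {p.micrograph_name} ({w}x{h})")
    lines = ["", "data_particles", "", "loop_"]
    lines += [f"{name} #{i + 1}" for i, name in enumerate(STAR_COLUMNS)]
    for p in particles:
        lines.append(f"{p.micrograph_name} {p.x:.6f} {p.y:.6f} {p.score:.6f}")
    Path(out_path).write_text("\n".join(lines) + "\n")
    logger.info("wrote %d particles to %s", len(particles), out_path)


def read_star(path: str | Path) -> list[PickedParticle]:
    """Parse a STAR particle file written by :func:`write_star` (or RELION)."""
    columns: list[str] = []
    particles: list[PickedParticle] = []
    in_loop = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            columns, in_loop = [], False
            continue
        if line == "loop_":
            columns, in_loop = [], True
            continue
        if in_loop and line.startswith("_"):
            columns.append(line.split()[0])
            continue
        if in_loop and columns:
            values = line.split()
            if len(values) != len(columns):
                raise ValueError(f"malformed STAR row: {line!r}")
            row = dict(zip(columns, values))
            particles.append(PickedParticle(
                micrograph_name=row["_rlnMicrographName"],
                x=float(row["_rlnCoordinateX"]),
                y=float(row["_rlnCoordinateY"]),
                score=float(row.get("_rlnAutopickFigureOfMerit", 1.0)),
            ))
    return particles
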