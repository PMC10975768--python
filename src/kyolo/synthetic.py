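"""Synthetic sun-dried-kelp scene generator.

Emulates the statistical structure of aerial photographs of kelp drying on
sand, as seen from a camera 3-40 m overhead: a sandy textured background,
dark elongated strips (aspect ratio >= 3, gently curved) laid out densely
enough to overlap, greenish irregular debris that must NOT be labeled, and
collective labels — one enclosing box — for groups of strips whose boxes
overlap beyond a merge threshold, mirroring how indistinguishable
overlapping kelp is annotated in practice.

Visual realism is explicitly not the goal; the generator targets the
features that make this detection problem hard (elongation, density,
occlusion, unlabeled distractors, altitude-dependent object scale) so the
whole training and evaluation pipeline can be exercised and verified
without the original UAV imagery.

Every scene is a pure function of its spec (including the seed).
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from .boxes import BoundingBox, pairwise_iou

__all__ = [
    "SceneSpec", "LabeledScene", "generate_scene", "augment", "make_dataset",
    "write_labels", "read_labels_yolo", "read_labels_voc", "load_manifest",
    "ALTITUDE_REGIMES",
]

# Strip length as a fraction of image size per altitude regime. The camera
# flies 3-10 m (close), 10-25 m (medium) or 25-40 m (long); higher means
# smaller strips.
ALTITUDE_REGIMES = {
    "close": (0.28, 0.55),
    "medium": (0.12, 0.28),
    "long": (0.05, 0.12),
}


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic scene.

    size            square image side in pixels
    altitude        'close' | 'medium' | 'long' | 'mixed'
    n_strips        inclusive (min, max) number of kelp strips
    overlap_prob    probability a strip is dropped next to an existing one
                    (clustering induces overlap)
    merge_iou       box-IoU threshold above which overlapping strips share a
                    single collective label
    debris_rate     expected number of unlabeled debris blobs
    noise_level     std of the additive texture grain, in [0, 1] units
    seed            fixes all randomness
    """

    size: int = 640
    altitude: str = "mixed"
    n_strips: tuple[int, int] = (8, 20)
    overlap_prob: float = 0.5
    merge_iou: float = 0.4
    debris_rate: float = 3.0
    noise_level: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.altitude not in (*ALTITUDE_REGIMES, "mixed"):
            raise ValueError(f"unknown altitude regime {self.altitude!r}")
        if not (0 <= self.overlap_prob <= 1):
            raise ValueError("overlap_prob must be in [0, 1]")
        if not (0 < self.merge_iou <= 1):
            raise ValueError("merge_iou must be in (0, 1]")
        if self.n_strips[0] < 0 or self.n_strips[1] < self.n_strips[0]:
            raise ValueError("invalid strip count range")

    @classmethod
    def easy(cls, seed: int = 0, size: int = 640) -> "SceneSpec":
        """Large, well-separated strips: the benign end of the conditions."""
        return cls(size=size, altitude="close", n_strips=(2, 4),
                   overlap_prob=0.0, merge_iou=0.999, debris_rate=1.0,
                   noise_level=0.02, seed=seed)


@dataclass
class LabeledScene:
    """One rendered scene with its ground truth and provenance."""

    image: np.ndarray                  # (H, W, 3) uint8
    boxes: list[BoundingBox]           # normalized center-size, class 'kelp'
    spec: SceneSpec
    merged_groups: list[list[int]] = field(default_factory=list)  # strip ids per label
    skipped_strips: int = 0

    @property
    def size(self) -> int:
        return self.image.shape[0]

    def boxes_array(self) -> np.ndarray:
        if not self.boxes:
            return np.zeros((0, 4), dtype=np.float64)
        return np.stack([b.to_array() for b in self.boxes])


# -- rendering helpers ---------------------------------------------------------

def _polygon_mask(xs: np.ndarray, ys: np.ndarray, size: int) -> np.ndarray:
    """Rasterize a polygon into a boolean mask (half-open pixel grid)."""
    from skimage.draw import polygon
    rr, cc = polygon(np.clip(ys, 0, size - 1), np.clip(xs, 0, size - 1),
                     shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


def _sand_background(size: int, rng: np.random.Generator,
                     noise_level: float) -> np.ndarray:
    base = np.array([201.0, 182.0, 143.0])  # dry sand
    img = np.empty((size, size, 3), dtype=np.float64)
    low = ndimage.gaussian_filter(rng.normal(0, 1, (size, size)), sigma=size / 8)
    low = low / (np.abs(low).max() + 1e-9)
    grain = rng.normal(0, 1, (size, size))
    for c in range(3):
        img[..., c] = base[c] * (1 + 0.08 * low) + 255 * noise_level * grain
    return img


def _strip_polygon(cx: float, cy: float, length: float, width: float,
                   angle: float, curvature: float, n: int = 14):
    """Ribbon polygon along a curved centerline through (cx, cy)."""
    t = np.linspace(-0.5, 0.5, n)
    # quadratic bend perpendicular to the main axis
    along = t * length
    across = curvature * length * (t ** 2 - 0.25)
    ca, sa = math.cos(angle), math.sin(angle)
    mid_x = cx + along * ca - across * sa
    mid_y = cy + along * sa + across * ca
    # slight width taper toward the tips
    w = width * (0.65 + 0.35 * np.cos(t * math.pi))
    dx = np.gradient(mid_x)
    dy = np.gradient(mid_y)
    norm = np.hypot(dx, dy) + 1e-9
    nx, ny = -dy / norm, dx / norm
    xs = np.concatenate([mid_x + nx * w / 2, (mid_x - nx * w / 2)[::-1]])
    ys = np.concatenate([mid_y + ny * w / 2, (mid_y - ny * w / 2)[::-1]])
    return xs, ys


def _render_strip(img: np.ndarray, mask: np.ndarray,
                  rng: np.random.Generator) -> None:
    base = np.array([48.0, 56.0, 38.0]) + rng.normal(0, 6, 3)  # dark olive-brown
    shade = ndimage.gaussian_filter(rng.normal(0, 1, mask.shape), sigma=6)
    for c in range(3):
        img[..., c][mask] = base[c] * (1 + 0.15 * shade[mask])


def _render_debris(img: np.ndarray, mask: np.ndarray,
                   rng: np.random.Generator) -> None:
    base = np.array([96.0, 132.0, 74.0]) + rng.normal(0, 10, 3)  # green weed
    for c in range(3):
        img[..., c][mask] = base[c]


def _blob_polygon(cx: float, cy: float, r: float, rng: np.random.Generator,
                  n: int = 12):
    ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
    rad = r * rng.uniform(0.5, 1.3, n)
    return cx + rad * np.cos(ang), cy + rad * np.sin(ang)


def _merge_collective(boxes_px: list[tuple[float, float, float, float]],
                      merge_iou: float) -> list[list[int]]:
    """Union-find grouping of strip boxes by pairwise IoU above threshold."""
    n = len(boxes_px)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if n > 1:
        arr = np.array([[(x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1]
                        for x1, y1, x2, y2 in boxes_px])
        iou_m = pairwise_iou(arr, arr)
        for i in range(n):
            for j in range(i + 1, n):
                if iou_m[i, j] > merge_iou:
                    parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def generate_scene(spec: SceneSpec) -> LabeledScene:
    """Render one labeled scene; deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    img = _sand_background(size, rng, spec.noise_level)

    n_strips = int(rng.integers(spec.n_strips[0], spec.n_strips[1] + 1))
    strip_boxes: list[tuple[float, float, float, float]] = []
    centers: list[tuple[float, float]] = []
    skipped = 0
    margin = 2
    for _ in range(n_strips):
        placed = False
        for _attempt in range(10):
            regime = (spec.altitude if spec.altitude != "mixed"
                      else rng.choice(list(ALTITUDE_REGIMES)))
            lo, hi = ALTITUDE_REGIMES[regime]
            length = rng.uniform(lo, hi) * size
            aspect = rng.uniform(3.0, 8.0)
            width = max(2.0, length / aspect)
            if centers and rng.uniform() < spec.overlap_prob:
                bx, by = centers[int(rng.integers(len(centers)))]
                cx = bx + rng.normal(0, 0.25 * length)
                cy = by + rng.normal(0, 0.25 * length)
            else:
                cx = rng.uniform(0.1 * size, 0.9 * size)
                cy = rng.uniform(0.1 * size, 0.9 * size)
            angle = rng.uniform(0, math.pi)
            curvature = rng.uniform(-0.15, 0.15)
            xs, ys = _strip_polygon(cx, cy, length, width, angle, curvature)
            if (xs.min() < margin or ys.min() < margin
                    or xs.max() > size - margin or ys.max() > size - margin):
                continue
            mask = _polygon_mask(xs, ys, size)
            if not mask.any():
                continue
            _render_strip(img, mask, rng)
            rows = np.any(mask, axis=1)
            cols = np.any(mask, axis=0)
            y1, y2 = np.flatnonzero(rows)[[0, -1]]
            x1, x2 = np.flatnonzero(cols)[[0, -1]]
            strip_boxes.append((float(x1), float(y1), float(x2 + 1), float(y2 + 1)))
            centers.append((cx, cy))
            placed = True
            break
        if not placed:
            skipped += 1

    # unlabeled debris distractors
    n_debris = int(rng.poisson(spec.debris_rate))
    for _ in range(n_debris):
        r = rng.uniform(0.01, 0.03) * size
        cx = rng.uniform(r, size - r)
        cy = rng.uniform(r, size - r)
        xs, ys = _blob_polygon(cx, cy, r, rng)
        mask = _polygon_mask(xs, ys, size)
        if mask.any():
            _render_debris(img, mask, rng)

    groups = _merge_collective(strip_boxes, spec.merge_iou)
    boxes: list[BoundingBox] = []
    for g in groups:
        x1 = min(strip_boxes[i][0] for i in g)
        y1 = min(strip_boxes[i][1] for i in g)
        x2 = max(strip_boxes[i][2] for i in g)
        y2 = max(strip_boxes[i][3] for i in g)
        boxes.append(BoundingBox(((x1 + x2) / 2) / size, ((y1 + y2) / 2) / size,
                                 (x2 - x1) / size, (y2 - y1) / size))

    image = np.clip(img, 0, 255).astype(np.uint8)
    return LabeledScene(image=image, boxes=boxes, spec=spec,
                        merged_groups=groups, skipped_strips=skipped)


# -- augmentation --------------------------------------------------------------

def _rot90_box(b: BoundingBox) -> BoundingBox:
    # one clockwise quarter turn in normalized coordinates of a square image
    return BoundingBox(1.0 - b.cy, b.cx, b.h, b.w)


def augment(scene: LabeledScene, ops, seed: int = 0,
            arbitrary_rotation: bool = False) -> LabeledScene:
    """Apply augmentation ops from {additive_noise, random_rotation,
    random_masking}; deterministic per seed.

    Additive noise never touches labels. Rotation defaults to multiples of
    90 degrees so boxes transform exactly; ``arbitrary_rotation=True``
    rotates by a free angle and re-fits enclosing boxes. Masking paints
    random rectangles and drops labels whose visible area falls below 25%.
    """
    ops = list(ops)
    valid = {"additive_noise", "random_rotation", "random_masking"}
    if not ops:
        raise ValueError("at least one augmentation op required")
    if set(ops) - valid:
        raise ValueError(f"unknown ops {set(ops) - valid}")
    rng = np.random.default_rng(seed)
    img = scene.image.astype(np.float64)
    boxes = list(scene.boxes)
    size = scene.size

    if "additive_noise" in ops:
        img = img + rng.normal(0, 8.0, img.shape)

    if "random_rotation" in ops:
        if arbitrary_rotation:
            deg = float(rng.uniform(0, 360))
            img = ndimage.rotate(img, deg, axes=(1, 0), reshape=False,
                                 order=1, mode="nearest")
            rad = math.radians(deg)
            new_boxes = []
            for b in boxes:
                cs, sn = math.cos(rad), math.sin(rad)
                # rotate corners about the image center, re-fit the box
                x1, y1, x2, y2 = b.to_corners()
                corners = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]]) - 0.5
                rot = corners @ np.array([[cs, sn], [-sn, cs]]) + 0.5
                nx1, ny1 = rot.min(axis=0)
                nx2, ny2 = rot.max(axis=0)
                nx1, ny1 = max(nx1, 0.0), max(ny1, 0.0)
                nx2, ny2 = min(nx2, 1.0), min(ny2, 1.0)
                if nx2 - nx1 > 1e-3 and ny2 - ny1 > 1e-3:
                    new_boxes.append(BoundingBox.from_corners(nx1, ny1, nx2, ny2))
            boxes = new_boxes
        else:
            k = int(rng.integers(0, 4))
            for _ in range(k):
                img = np.rot90(img, k=-1, axes=(0, 1)).copy()  # clockwise
                boxes = [_rot90_box(b) for b in boxes]

    if "random_masking" in ops:
        masked = np.zeros((size, size), dtype=bool)
        n_rects = int(rng.integers(1, 4))
        for _ in range(n_rects):
            w = int(rng.uniform(0.1, 0.3) * size)
            h = int(rng.uniform(0.1, 0.3) * size)
            x = int(rng.integers(0, size - w))
            y = int(rng.integers(0, size - h))
            img[y:y + h, x:x + w] = 127.0
            masked[y:y + h, x:x + w] = True
        kept = []
        for b in boxes:
            x1, y1, x2, y2 = (np.array(b.to_corners()) * size).round().astype(int)
            x1, y1 = max(x1, 0), max(y1, 0)
            x2, y2 = min(x2, size), min(y2, size)
            area = max((x2 - x1) * (y2 - y1), 1)
            visible = 1.0 - masked[y1:y2, x1:x2].sum() / area
            if visible >= 0.25:
                kept.append(b)
        boxes = kept

    out = LabeledScene(image=np.clip(img, 0, 255).astype(np.uint8),
                       boxes=boxes, spec=scene.spec,
                       merged_groups=scene.merged_groups,
                       skipped_strips=scene.skipped_strips)
    return out


# -- label I/O -----------------------------------------------------------------

def write_labels(scene: LabeledScene, path, fmt: str = "yolo_txt",
                 image_name: str | None = None) -> None:
    """Write ground-truth labels as YOLO txt or Pascal VOC XML.

    YOLO txt: one "class cx cy w h" line per box, normalized, 6 decimals.
    VOC XML: 1-based integer pixel corners.
    """
    path = Path(path)
    for b in scene.boxes:
        x1, y1, x2, y2 = b.to_corners()
        if x1 < -1e-6 or y1 < -1e-6 or x2 > 1 + 1e-6 or y2 > 1 + 1e-6:
            raise ValueError(f"box {b} extends outside the unit square")
    if fmt == "yolo_txt":
        lines = [f"0 {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}" for b in scene.boxes]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "voc_xml":
        size = scene.size
        root = ET.Element("annotation")
        ET.SubElement(root, "filename").text = image_name or path.stem
        sz = ET.SubElement(root, "size")
        ET.SubElement(sz, "width").text = str(size)
        ET.SubElement(sz, "height").text = str(size)
        ET.SubElement(sz, "depth").text = "3"
        for b in scene.boxes:
            x1, y1, x2, y2 = b.to_corners()
            obj = ET.SubElement(root, "object")
            ET.SubElement(obj, "name").text = "kelp"
            ET.SubElement(obj, "difficult").text = "0"
            bb = ET.SubElement(obj, "bndbox")
            ET.SubElement(bb, "xmin").text = str(int(round(x1 * size)) + 1)
            ET.SubElement(bb, "ymin").text = str(int(round(y1 * size)) + 1)
            ET.SubElement(bb, "xmax").text = str(int(round(x2 * size)))
            ET.SubElement(bb, "ymax").text = str(int(round(y2 * size)))
        ET.ElementTree(root).write(path)
    else:
        raise ValueError(f"unknown label format {fmt!r}")


def read_labels_yolo(path) -> list[BoundingBox]:
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        _, cx, cy, w, h = parts[:5]
        boxes.append(BoundingBox(float(cx), float(cy), float(w), float(h)))
    return boxes


def read_labels_voc(path) -> tuple[list[BoundingBox], int]:
    """Returns (boxes normalized to the image size, image size)."""
    root = ET.parse(path).getroot()
    size = int(root.find("size/width").text)
    boxes = []
    for obj in root.findall("object"):
        bb = obj.find("bndbox")
        x1 = (int(bb.find("xmin").text) - 1) / size
        y1 = (int(bb.find("ymin").text) - 1) / size
        x2 = int(bb.find("xmax").text) / size
        y2 = int(bb.find("ymax").text) / size
        boxes.append(BoundingBox.from_corners(x1, y1, x2, y2))
    return boxes, size


# -- dataset construction ------------------------------------------------------

def make_dataset(n_images: int, out_dir, seed: int = 0,
                 spec: SceneSpec | None = None,
                 split: tuple[float, float, float] = (0.7, 0.2, 0.1),
                 write_voc: bool = False) -> dict:
    """Generate a train/val/test dataset and write a manifest YAML.

    Split sizes are round(n*0.7) / round(n*0.2) / remainder, the 7:2:1
    convention (2190 -> 1533/438/219). Returns the manifest dict; the
    manifest file lives at ``out_dir/manifest.yaml``.
    """
    if n_images < 10:
        raise ValueError("need at least 10 images for a 7:2:1 split")
    out = Path(out_dir)
    template = spec or SceneSpec()
    n_train = round(n_images * split[0])
    n_val = round(n_images * split[1])
    n_test = n_images - n_train - n_val
    sizes = {"train": n_train, "val": n_val, "test": n_test}
    rng = np.random.default_rng(seed)
    manifest = {"names": ["kelp"], "nc": 1, "seed": seed, "n_images": n_images}
    idx = 0
    for part, count in sizes.items():
        img_dir = out / "images" / part
        lbl_dir = out / "labels" / part
        img_dir.mkdir(parents=True, exist_ok=True)
        lbl_dir.mkdir(parents=True, exist_ok=True)
        for _ in range(count):
            scene_seed = int(rng.integers(0, 2 ** 31 - 1))
            scene = generate_scene(replace(template, seed=scene_seed))
            stem = f"img_{idx:05d}"
            Image.fromarray(scene.image).save(img_dir / f"{stem}.png")
            write_labels(scene, lbl_dir / f"{stem}.txt", "yolo_txt")
            if write_voc:
                write_labels(scene, lbl_dir / f"{stem}.xml", "voc_xml",
                             image_name=f"{stem}.png")
            idx += 1
        manifest[part] = str(img_dir)
    manifest["path"] = str(out)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def split_sizes(n: int, split=(0.7, 0.2, 0.1)) -> tuple[int, int, int]:
    """Split arithmetic used by :func:`make_dataset` (7:2:1 by default)."""
    n_train = round(n * split[0])
    n_val = round(n * split[1])
    return n_train, n_val, n - n_train - n_val


def load_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
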