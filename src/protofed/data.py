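"""Synthetic image datasets, train/test splitting and federated partitioning.

This module provides the data plumbing for simulating a multi-hospital
federated study on a single machine: a generator of class-structured
synthetic images (four classes emulating the glioma / meningioma /
pituitary / no-tumor folder layout of public brain-MRI classification
datasets), stratified train/test splitting, Dirichlet label-skew
partitioning across simulated clients, and an image-folder reader/writer
compatible with the usual one-directory-per-class layout.

All randomness is driven by explicit integer seeds; every operation is a
pure function of its inputs and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ImageSample",
    "LabeledDataset",
    "PartitionPlan",
    "generate_synthetic_dataset",
    "stratified_split",
    "dirichlet_partition",
    "read_image_folder",
    "write_image_folder",
    "augment_batch",
]


@dataclass(frozen=True)
class ImageSample:
    """A single labelled image.

    pixels is a 2-D (grayscale) or 3-channel float array with values in
    [0, 1]; label indexes the owning dataset's class_names.
    """

    pixels: np.ndarray
    label: int
    source_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or 3-channel")
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", p)


@dataclass
class LabeledDataset:
    """An ordered collection of ImageSamples sharing one image size."""

    samples: list[ImageSample]
    class_names: list[str]
    image_size: tuple[int, int]

    def __post_init__(self) -> None:
        c = len(self.class_names)
        for s in self.samples:
            if not 0 <= s.label < c:
                raise ValueError(f"label {s.label} outside [0, {c})")
            if s.pixels.shape[:2] != tuple(self.image_size):
                raise ValueError("sample image size mismatch")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    def pixel_array(self) -> np.ndarray:
        """Stack pixels into an (N, C, H, W) float64 array (C=1 for grayscale)."""
        arrs = []
        for s in self.samples:
            p = s.pixels
            if p.ndim == 2:
                p = p[None, :, :]
            else:
                p = np.moveaxis(p, -1, 0)
            arrs.append(p)
        return np.stack(arrs) if arrs else np.zeros((0, 1) + tuple(self.image_size))

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset(
            [self.samples[i] for i in indices], list(self.class_names), self.image_size
        )


@dataclass
class PartitionPlan:
    """Assignment of dataset indices to simulated clients.

    assignments maps client id -> sample indices; class_counts maps client
    id -> per-class counts n_k(c). Assignments are disjoint and cover the
    dataset exactly once.
    """

    n_clients: int
    assignments: dict[int, list[int]]
    class_counts: dict[int, np.ndarray]
    alpha: float = field(default=float("nan"))

    def client_sizes(self) -> dict[int, int]:
        return {k: len(v) for k, v in self.assignments.items()}


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------


def _head_mask(h: int, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.sqrt(((yy - cy) / (0.45 * h)) ** 2 + ((xx - cx) / (0.45 * w)) ** 2)
    return r, yy, xx


def _lesion_ellipse(yy, xx, cy, cx, ry, rx, theta):
    y0, x0 = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = (c * x0 + s * y0) / rx
    v = (-s * x0 + c * y0) / ry
    return u * u + v * v <= 1.0


def _render_sample(label: int, h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one image of the given class.

    Class motifs (on a dark elliptical "brain" disk with a radial shading
    gradient):
      0 — no lesion, faint cortical folds only;
      1 — solid bright round lesion of intermediate size near the centre;
      2 — thin, elongated bright bar at a random orientation, off-centre;
      3 — large bright ring with a hypointense core.
    The three lesion motifs differ both in shape and in total bright area,
    so they stay distinguishable after aggressive spatial pooling; pose,
    size and position are jittered per sample so the classifier must learn
    shape statistics rather than fixed pixel positions.
    """
    r, yy, xx = _head_mask(h, w)
    brain = r <= 1.0
    img = np.zeros((h, w))
    img[brain] = 0.35 * (1.0 - 0.3 * r[brain] ** 2)
    # faint folds shared by all classes
    folds = 0.02 * np.sin(yy / h * 6 * np.pi + rng.uniform(0, 2 * np.pi)) * np.sin(
        xx / w * 6 * np.pi + rng.uniform(0, 2 * np.pi)
    )
    img[brain] += folds[brain]

    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    scale = min(h, w)
    if label == 1:
        cy = cy0 + rng.uniform(-0.06, 0.06) * scale
        cx = cx0 + rng.uniform(-0.06, 0.06) * scale
        rad = rng.uniform(0.14, 0.17) * scale
        mask = _lesion_ellipse(yy, xx, cy, cx, rad, rad, 0.0)
        img[mask & brain] = 1.0
    elif label == 2:
        ang = rng.uniform(0, np.pi)
        off = rng.uniform(0.08, 0.14) * scale
        cy = cy0 + off * np.sin(ang)
        cx = cx0 + off * np.cos(ang)
        theta = rng.uniform(0, np.pi)
        mask = _lesion_ellipse(
            yy, xx, cy, cx, 0.04 * scale, 0.30 * scale, theta
        )
        img[mask & brain] = 1.0
    elif label == 3:
        cy = cy0 + rng.uniform(-0.05, 0.05) * scale
        cx = cx0 + rng.uniform(-0.05, 0.05) * scale
        r_out = rng.uniform(0.26, 0.30) * scale
        outer = _lesion_ellipse(yy, xx, cy, cx, r_out, r_out, 0.0)
        inner = _lesion_ellipse(yy, xx, cy, cx, 0.62 * r_out, 0.62 * r_out, 0.0)
        ring = outer & ~inner
        img[ring & brain] = 1.0
        img[inner & brain] = 0.12
    elif label >= 4:
        # extra classes beyond the four canonical motifs: bright bar at a
        # class-specific orientation
        theta = (label - 4) * np.pi / 7 + rng.uniform(-0.1, 0.1)
        mask = _lesion_ellipse(yy, xx, cy0, cx0, 0.04 * scale, 0.30 * scale, theta)
        img[mask & brain] = 0.85
    return img


def generate_synthetic_dataset(
    n_per_class: int,
    n_classes: int = 4,
    image_size: tuple[int, int] = (64, 64),
    noise_sd: float = 0.05,
    seed: int = 42,
) -> LabeledDataset:
    """Generate a balanced synthetic dataset with one structural motif per class.

    Exactly ``n_per_class`` samples are drawn for each of ``n_classes``
    classes; additive Gaussian pixel noise of standard deviation
    ``noise_sd`` is applied and the result clipped back to [0, 1]. The
    same arguments always produce a bit-identical dataset.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    h, w = image_size
    if h < 16 or w < 16:
        raise ValueError("image_size must be at least 16x16")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    names = ["no_tumor", "glioma", "meningioma", "pituitary"][:n_classes]
    names += [f"class_{i}" for i in range(len(names), n_classes)]
    samples: list[ImageSample] = []
    for c in range(n_classes):
        for i in range(n_per_class):
            img = _render_sample(c, h, w, rng)
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, size=img.shape)
            img = np.clip(img, 0.0, 1.0)
            samples.append(ImageSample(img, c, source_id=f"syn_{names[c]}_{i:04d}"))
    return LabeledDataset(samples, names, (h, w))


# ---------------------------------------------------------------------------
# splitting and partitioning
# ---------------------------------------------------------------------------


def stratified_split(
    dataset: LabeledDataset, train_frac: float, seed: int = 42
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split into train/test keeping per-class proportions.

    Each class contributes ``round(train_frac * class_count)`` samples to
    the training part; the remainder goes to the test part. Indices are
    permuted with the given seed, so the same seed yields the same split.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in range(dataset.n_classes):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        if idx.size < 2:
            raise ValueError(f"class {c} has fewer than 2 samples; cannot split")
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    train_idx.sort()
    test_idx.sort()
    return dataset.subset(train_idx), dataset.subset(test_idx)


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` items by ``proportions`` conserving the sum exactly."""
    quotas = proportions * total
    counts = np.floor(quotas).astype(np.int64)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quotas - counts))
        counts[order[:short]] += 1
    return counts


def dirichlet_partition(
    dataset: LabeledDataset,
    n_clients: int,
    alpha: float,
    seed: int = 42,
    min_per_client: int = 1,
    max_retries: int = 100,
) -> PartitionPlan:
    """Partition a dataset across clients with Dirichlet label skew.

    For every class c a proportion vector over the K clients is drawn from
    Dirichlet(alpha, ..., alpha) and the class's sample indices are split
    accordingly (largest-remainder rounding, so totals are conserved
    exactly). Small alpha yields strongly non-IID shards; large alpha
    approaches an IID split. Draws are repeated (up to ``max_retries``)
    until every client holds at least ``min_per_client`` samples.
    """
    if n_clients < 1:
        raise ValueError("n_clients must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if n_clients * min_per_client > len(dataset):
        raise ValueError(
            f"min_per_client={min_per_client} infeasible for "
            f"{n_clients} clients and {len(dataset)} samples"
        )
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    n_classes = dataset.n_classes
    for _ in range(max_retries):
        assignments: dict[int, list[int]] = {k: [] for k in range(n_clients)}
        class_counts = {k: np.zeros(n_classes, dtype=np.int64) for k in range(n_clients)}
        for c in range(n_classes):
            idx = np.flatnonzero(labels == c)
            if idx.size == 0:
                continue
            idx = rng.permutation(idx)
            props = rng.dirichlet(np.full(n_clients, alpha))
            counts = _largest_remainder(props, idx.size)
            start = 0
            for k in range(n_clients):
                assignments[k].extend(idx[start : start + counts[k]].tolist())
                class_counts[k][c] = counts[k]
                start += counts[k]
        if all(len(v) >= min_per_client for v in assignments.values()):
            for k in assignments:
                assignments[k].sort()
            return PartitionPlan(n_clients, assignments, class_counts, alpha)
    raise RuntimeError(
        f"could not satisfy min_per_client={min_per_client} for alpha={alpha} "
        f"within {max_retries} redraws"
    )


# ---------------------------------------------------------------------------
# image-folder I/O
# ---------------------------------------------------------------------------


def read_image_folder(
    path: str | Path,
    image_size: tuple[int, int] = (64, 64),
    grayscale: bool = True,
) -> LabeledDataset:
    """Read a one-directory-per-class image tree into a LabeledDataset.

    Class order is the lexicographic order of the subdirectory names.
    Images are resized to ``image_size`` and rescaled to [0, 1]. Empty
    class directories are skipped with a warning.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"{root} contains no class subdirectories")
    names: list[str] = []
    samples: list[ImageSample] = []
    exts = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
    for d in class_dirs:
        files = sorted(f for f in d.iterdir() if f.suffix.lower() in exts)
        if not files:
            warnings.warn(f"class directory {d.name} is empty; skipped")
            continue
        label = len(names)
        names.append(d.name)
        for f in files:
            try:
                with Image.open(f) as im:
                    im = im.convert("L" if grayscale else "RGB")
                    im = im.resize((image_size[1], image_size[0]), Image.BILINEAR)
                    arr = np.asarray(im, dtype=np.float64) / 255.0
            except Exception as exc:  # noqa: BLE001 - surfaced with the path
                raise OSError(f"cannot read image {f}: {exc}") from exc
            samples.append(ImageSample(arr, label, source_id=str(f)))
    if not names:
        raise ValueError(f"{root} has only empty class subdirectories")
    return LabeledDataset(samples, names, tuple(image_size))


def write_image_folder(dataset: LabeledDataset, path: str | Path) -> Path:
    """Write a dataset as PNG files in class subdirectories plus a manifest CSV."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    counters = dict.fromkeys(range(dataset.n_classes), 0)
    for s in dataset.samples:
        cname = dataset.class_names[s.label]
        cdir = root / cname
        cdir.mkdir(exist_ok=True)
        i = counters[s.label]
        counters[s.label] += 1
        fname = cdir / f"{cname}_{i:05d}.png"
        arr = np.clip(s.pixels * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(fname)
        rows.append((str(fname.relative_to(root)), s.label))
    manifest = root / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write("path,label\n")
        for p, lab in rows:
            fh.write(f"{p},{lab}\n")
    return root


# ---------------------------------------------------------------------------
# training-time augmentation
# ---------------------------------------------------------------------------


def augment_batch(
    x: np.ndarray,
    rng: np.random.Generator,
    max_rotation_deg: float = 15.0,
    max_zoom: float = 0.10,
    hflip: bool = True,
) -> np.ndarray:
    """Random rotation / horizontal flip / zoom applied per image.

    x has shape (N, C, H, W); returns an array of the same shape with
    values clipped to [0, 1]. Used only at training time.
    """
    out = np.empty_like(x)
    n = x.shape[0]
    for i in range(n):
        img = x[i]
        ang = rng.uniform(-max_rotation_deg, max_rotation_deg)
        img = ndimage.rotate(img, ang, axes=(1, 2), reshape=False, order=1, mode="nearest")
        z = 1.0 + rng.uniform(-max_zoom, max_zoom)
        zoomed = ndimage.zoom(img, (1.0, z, z), order=1, mode="nearest")
        img = _center_fit(zoomed, img.shape)
        if hflip and rng.random() < 0.5:
            img = img[:, :, ::-1]
        out[i] = np.clip(img, 0.0, 1.0)
    return out


def _center_fit(img: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Center-crop or pad a (C, H, W) image to the target shape."""
    c, h, w = shape
    ch, cw = img.shape[1], img.shape[2]
    out = np.zeros(shape, dtype=img.dtype)
    sy, sx = max((ch - h) // 2, 0), max((cw - w) // 2, 0)
    dy, dx = max((h - ch) // 2, 0), max((w - cw) // 2, 0)
    hh, ww = min(h, ch), min(w, cw)
    out[:, dy : dy + hh, dx : dx + ww] = img[:, sy : sy + hh, sx : sx + ww]
    return out
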