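"""Synthetic palm-vein image generation.

Near-infrared palm images show dark curvilinear vessels whose
cross-sections are approximately Gaussian, on a brighter background.  The
generator renders, per subject, a fixed *template* of smooth random-walk
vessel centerlines and then derives each sample by a small random rigid
perturbation (translation, rotation), a multiplicative gain, and additive
Gaussian noise — emulating the intra-class variation of repeated captures
of one palm.

Datasets are pure functions of :class:`SynthConfig` (same seed, same
pixels) and carry an enrollment/test split: the first half of each
subject's samples enrolls, the second half tests, mirroring the common
half/half verification protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SynthConfig",
    "GrayImage",
    "LabelledDataset",
    "make_subject_template",
    "make_dataset",
    "make_straight_vessel",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic palm-vein dataset.

    Intensities are floats in [0, 1]; geometric quantities are in pixels.
    """

    n_subjects: int = 50
    samples_per_subject: int = 12
    image_size: tuple[int, int] = (64, 64)
    n_vessels: int = 5
    vessel_sigma: float = 2.0          # Gaussian cross-section width (px)
    vessel_depth: float = 0.5          # intensity drop at the centerline
    background_level: float = 0.7
    noise_sd: float = 0.02             # additive Gaussian noise SD
    jitter_shift: float = 1.5          # max |translation| per axis (px)
    jitter_rot: float = 2.0            # max |rotation| (degrees)
    jitter_gain: float = 0.05          # max multiplicative intensity change
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.samples_per_subject < 1:
            raise ValueError("n_subjects and samples_per_subject must be positive")
        rows, cols = self.image_size
        if rows < 8 or cols < 8:
            raise ValueError(f"image_size {self.image_size} too small")
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be positive")
        if self.vessel_sigma <= 0:
            raise ValueError("vessel_sigma must be positive")
        if not 0.0 <= self.vessel_depth <= 1.0:
            raise ValueError("vessel_depth must lie in [0, 1]")
        if not 0.0 < self.background_level < 1.0:
            raise ValueError("background_level must lie in (0, 1)")
        for name in ("noise_sd", "jitter_shift", "jitter_rot", "jitter_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class GrayImage:
    """Single-channel intensity raster with subject/sample labels."""

    pixels: np.ndarray
    subject_id: int = -1
    sample_index: int = -1

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")


@dataclass
class LabelledDataset:
    """Images with subject labels and a disjoint enroll/test split."""

    images: list[GrayImage]
    split: list[str] = field(default_factory=list)  # "enroll" | "test" per image
    config: SynthConfig | None = None

    def subset(self, which: str) -> list[GrayImage]:
        return [im for im, s in zip(self.images, self.split) if s == which]

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([im.subject_id for im in self.images])


def _random_walk_centerline(
    rng: np.random.Generator,
    shape: tuple[int, int],
    step: float = 2.0,
    max_turn: float = 0.25,
) -> np.ndarray:
    """Smooth random-walk polyline through the frame, as (N, 2) xy points.

    Fixed step length with a bounded turning angle per step yields
    curvilinear, branching-free paths; the walk starts on a random frame
    edge heading inward and stops when it leaves the (slightly padded)
    frame.
    """
    rows, cols = shape
    edge = rng.integers(4)
    if edge == 0:      # left edge, heading right
        x, y, heading = 0.0, rng.uniform(0, rows - 1), rng.uniform(-0.6, 0.6)
    elif edge == 1:    # right edge, heading left
        x, y, heading = float(cols - 1), rng.uniform(0, rows - 1), np.pi + rng.uniform(-0.6, 0.6)
    elif edge == 2:    # top edge, heading down
        x, y, heading = rng.uniform(0, cols - 1), 0.0, np.pi / 2 + rng.uniform(-0.6, 0.6)
    else:              # bottom edge, heading up
        x, y, heading = rng.uniform(0, cols - 1), float(rows - 1), -np.pi / 2 + rng.uniform(-0.6, 0.6)

    pts = [(x, y)]
    max_steps = int(3 * (rows + cols) / step)
    for _ in range(max_steps):
        heading += rng.uniform(-max_turn, max_turn)
        x += step * np.cos(heading)
        y += step * np.sin(heading)
        pts.append((x, y))
        if not (-2 * step <= x <= cols - 1 + 2 * step and -2 * step <= y <= rows - 1 + 2 * step):
            break
    return np.asarray(pts)


def _distance_to_polyline(shape: tuple[int, int], pts: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to a polyline given as (N, 2) xy points."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)  # (M, 2)

    a = pts[:-1]                      # (S, 2) segment starts
    d = pts[1:] - a                   # (S, 2) segment vectors
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2[seg_len2 == 0] = 1.0

    # project each pixel onto each segment, clamp to [0, 1]
    diff = pix[:, None, :] - a[None, :, :]            # (M, S, 2)
    t = np.clip(np.einsum("msk,sk->ms", diff, d) / seg_len2, 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist2 = np.sum((pix[:, None, :] - closest) ** 2, axis=2)
    return np.sqrt(dist2.min(axis=1)).reshape(rows, cols)


def _render_vessels(
    shape: tuple[int, int],
    centerlines: list[np.ndarray],
    sigma: float,
    depth: float,
    background: float,
) -> np.ndarray:
    """Render dark Gaussian-profile ridges on a flat background.

    At perpendicular distance d from the nearest centerline the intensity
    drops by ``depth * exp(-d^2 / sigma^2)``; overlapping vessels take the
    deepest drop so single-vessel profiles stay exact.
    """
    drop = np.zeros(shape)
    for pts in centerlines:
        if len(pts) < 2:
            continue
        d = _distance_to_polyline(shape, pts)
        np.maximum(drop, depth * np.exp(-(d ** 2) / sigma ** 2), out=drop)
    return np.clip(background - drop, 0.0, 1.0)


def make_subject_template(config: SynthConfig, subject_id: int) -> GrayImage:
    """Deterministic vessel template for one subject.

    The template is the noise-free "true palm" of the subject: every
    sample in the dataset is a perturbed copy of it.
    """
    if not 0 <= subject_id < config.n_subjects:
        raise ValueError(f"subject_id {subject_id} outside [0, {config.n_subjects})")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_id]))
    lines = [_random_walk_centerline(rng, config.image_size) for _ in range(config.n_vessels)]
    pix = _render_vessels(
        config.image_size, lines, config.vessel_sigma, config.vessel_depth, config.background_level
    )
    return GrayImage(pix, subject_id=subject_id, sample_index=-1)


def make_straight_vessel(
    shape: tuple[int, int],
    normal_angle: float,
    sigma: float = 2.0,
    depth: float = 0.5,
    background: float = 0.7,
    offset: float = 0.0,
) -> np.ndarray:
    """Phantom with one straight vessel through the image center.

    ``normal_angle`` (radians) is the direction along which the intensity
    varies — the vessel centerline runs perpendicular to it.  The exact
    cross-section is ``background - depth * exp(-d^2 / sigma^2)`` with d
    the signed distance ``(x - xc) cos(a) + (y - yc) sin(a) - offset``.
    Used as ground truth for matched-filter orientation tests.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    dx = xx - (cols - 1) / 2.0
    dy = yy - (rows - 1) / 2.0
    d = dx * np.cos(normal_angle) + dy * np.sin(normal_angle) - offset
    return np.clip(background - depth * np.exp(-(d ** 2) / sigma ** 2), 0.0, 1.0)


def _perturb(
    template: np.ndarray, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """One sample: rigid jitter + gain + noise, bilinear, reflective border."""
    out = template
    angle = rng.uniform(-config.jitter_rot, config.jitter_rot)
    shift = rng.uniform(-config.jitter_shift, config.jitter_shift, size=2)
    gain = 1.0 + rng.uniform(-config.jitter_gain, config.jitter_gain)

    if angle != 0.0 or np.any(shift != 0.0):
        theta = np.deg2rad(angle)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        center = (np.asarray(template.shape) - 1) / 2.0
        # x_in = R @ (x_out - center) + center - shift
        off = center - rot @ center - shift
        out = ndimage.affine_transform(out, rot, offset=off, order=1, mode="reflect")

    out = out * gain
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def make_dataset(config: SynthConfig) -> LabelledDataset:
    """Full labelled dataset: per subject, perturbed copies of its template.

    The first half of each subject's samples is marked ``enroll``, the
    second half ``test``; ``samples_per_subject`` must be even for this
    half/half protocol.
    """
    if config.samples_per_subject % 2 != 0:
        raise ValueError("samples_per_subject must be even for the half/half split")
    images: list[GrayImage] = []
    split: list[str] = []
    half = config.samples_per_subject // 2
    for sid in range(config.n_subjects):
        template = make_subject_template(config, sid).pixels
        for k in range(config.samples_per_subject):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, sid, k, 1]))
            images.append(GrayImage(_perturb(template, config, rng), subject_id=sid, sample_index=k))
            split.append("enroll" if k < half else "test")
    return LabelledDataset(images=images, split=split, config=config)


# ---------------------------------------------------------------------------
# dataset I/O: <root>/<subject_id>/<sample_index>.png + manifest.json

def write_dataset(dataset: LabelledDataset, root: str | Path) -> Path:
    """Write a dataset as 8-bit PNGs plus a JSON manifest; returns the root."""
    import imageio.v3 as iio

    root = Path(root)
    entries = []
    for im, sp in zip(dataset.images, dataset.split):
        sub = root / str(im.subject_id)
        sub.mkdir(parents=True, exist_ok=True)
        rel = f"{im.subject_id}/{im.sample_index}.png"
        iio.imwrite(root / rel, np.round(im.pixels * 255).astype(np.uint8))
        entries.append(
            {"path": rel, "subject_id": im.subject_id, "sample_index": im.sample_index, "split": sp}
        )
    manifest = {"images": entries}
    if dataset.config is not None:
        cfg = asdict(dataset.config)
        cfg["image_size"] = list(cfg["image_size"])
        manifest["config"] = cfg
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root


def read_dataset(root: str | Path) -> LabelledDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    import imageio.v3 as iio

    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    images, split = [], []
    for e in manifest["images"]:
        pix = iio.imread(root / e["path"]).astype(float) / 255.0
        images.append(GrayImage(pix, subject_id=e["subject_id"], sample_index=e["sample_index"]))
        split.append(e["split"])
    config = None
    if "config" in manifest:
        cfg = dict(manifest["config"])
        cfg["image_size"] = tuple(cfg["image_size"])
        config = SynthConfig(**cfg)
    return LabelledDataset(images=images, split=split, config=config)
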