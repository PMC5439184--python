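"""Image-to-spike-train stimulus pipeline.

Grayscale patterns (pixel values 0-255) are mapped channel-by-channel to
Poisson spike trains with rates 0-50 Hz over a 0.5 s active window,
followed by a 0.5 s silent interval.  The module also provides the image
preprocessing used by the recognition protocols (edge detection to a line
drawing, downsampling, 20x20 -> 50x50 upscaling, pixel scrambling,
baseline-response normalization) and a generator of synthetic face-like
image sets so every experiment runs without external image databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, transform

from ._rng import stream_rng

__all__ = [
    "ImagePattern",
    "Stimulus",
    "preprocess_image",
    "upscale_pattern",
    "encode_image",
    "scramble_image",
    "normalize_image_set",
    "generate_synthetic_faces",
]


@dataclass
class ImagePattern:
    """A grayscale pattern with values in [0, 255] plus identity metadata."""

    pixels: np.ndarray
    label: str = ""
    item_id: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")

    @property
    def shape(self):
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ImagePattern":
        return ImagePattern(pixels, self.label, self.item_id)


@dataclass
class Stimulus:
    """Multichannel spike trains: 0.5 s active window + 0.5 s silence."""

    spike_times: List[np.ndarray]  # per channel, seconds
    active: float = 0.5
    silence: float = 0.5
    source_id: int = 0
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.spike_times)

    @property
    def duration(self) -> float:
        return self.active + self.silence

    def as_dict(self) -> Dict[int, np.ndarray]:
        return {c: t for c, t in enumerate(self.spike_times) if len(t)}

    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.spike_times))


def preprocess_image(raw, target_size, mode: str = "grayscale",
                     edge_threshold: float = 0.1) -> ImagePattern:
    """Convert a raw grayscale image to a network-sized pattern.

    ``edge`` mode converts to a line drawing first (Sobel gradient
    magnitude, normalized, thresholded at ``edge_threshold`` of the peak)
    to suppress shading, then downsamples with local averaging.  Output is
    clipped to [0, 255].
    """
    img = np.asarray(raw, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:  # collapse RGB
        img = img.mean(axis=2)
    if mode not in ("grayscale", "edge"):
        raise ValueError("mode must be 'grayscale' or 'edge'")
    if mode == "edge":
        grad = filters.sobel(img)
        peak = grad.max()
        if peak > 0:
            grad = grad / peak
            grad[grad < edge_threshold] = 0.0
        img = grad * 255.0
    h, w = (int(s) for s in target_size)
    out = transform.resize(img, (h, w), anti_aliasing=True, mode="reflect",
                           preserve_range=True)
    return ImagePattern(np.clip(out, 0.0, 255.0))


def upscale_pattern(pattern: ImagePattern | np.ndarray) -> ImagePattern:
    """Upscale a 20x20 pattern to 50x50: replicate each pixel into a 2x2
    block (40x40) and pad the right/bottom with void (zero) pixels."""
    px = pattern.pixels if isinstance(pattern, ImagePattern) else np.asarray(pattern, float)
    if px.shape != (20, 20):
        raise ValueError(f"expected a 20x20 pattern, got {px.shape}")
    up = np.kron(px, np.ones((2, 2)))
    out = np.zeros((50, 50))
    out[:40, :40] = up
    if isinstance(pattern, ImagePattern):
        return pattern.with_pixels(out)
    return ImagePattern(out)


def encode_image(pattern: ImagePattern | np.ndarray, f_max: float = 50.0,
                 active: float = 0.5, silence: float = 0.5, seed: int = 0,
                 regular: bool = False) -> Stimulus:
    """Encode a pattern as spike trains: rate = pixel/255 * f_max per channel.

    Channels follow ``pattern.ravel()`` order.  By default each channel is
    an independent seeded Poisson train over the active window; ``regular``
    produces evenly spaced trains at the same rates (used by single-synapse
    protocols that require fixed frequencies).
    """
    px = pattern.pixels if isinstance(pattern, ImagePattern) else np.asarray(pattern, float)
    rates = px.ravel() / 255.0 * f_max
    rng = stream_rng(seed, "stimulus/encode")
    trains: List[np.ndarray] = []
    for r in rates:
        if r <= 0:
            trains.append(np.empty(0))
            continue
        if regular:
            trains.append(np.arange(0.0, active, 1.0 / r))
            continue
        n = rng.poisson(r * active)
        trains.append(np.sort(rng.uniform(0.0, active, size=n)))
    sid = pattern.item_id if isinstance(pattern, ImagePattern) else 0
    return Stimulus(trains, active=active, silence=silence, source_id=sid,
                    seed=seed)


def scramble_image(pattern: ImagePattern | np.ndarray, seed: int = 0) -> ImagePattern:
    """Relocate every pixel to a new random position (seeded permutation)."""
    is_pat = isinstance(pattern, ImagePattern)
    px = pattern.pixels if is_pat else np.asarray(pattern, float)
    rng = stream_rng(seed, "stimulus/scramble")
    flat = px.ravel().copy()
    out = flat[rng.permutation(flat.size)].reshape(px.shape)
    if is_pat:
        res = pattern.with_pixels(out)
        res.label = f"scrambled:{pattern.label}" if pattern.label else "scrambled"
        return res
    return ImagePattern(out)


def normalize_image_set(images: Sequence[ImagePattern], probe,
                        tolerance: float = 0.02, max_iters: int = 20,
                        gain: float = 0.6) -> tuple[List[ImagePattern], dict]:
    """Equalize baseline network responses by adjusting mean pixel values.

    ``probe`` is a callable ``probe(images) -> responses`` that measures the
    baseline network response (spikes/s) of each image with plasticity
    disabled.  Each image's intensities are rescaled multiplicatively
    (zero/void pixels stay void, preserving line-drawing sparsity; values
    clipped to [0, 255]) until the largest deviation from the common mean
    response is within ``tolerance`` (relative).  Returns the adjusted
    images and a log with per-iteration responses and a convergence flag;
    images pinned at the intensity ceiling are flagged best-effort.
    """
    imgs = [im.with_pixels(im.pixels.copy()) for im in images]
    log = {"responses": [], "converged": False, "clipped": set()}
    if len(imgs) <= 1:
        log["converged"] = True
        return imgs, log
    for it in range(max_iters):
        resp = np.asarray(probe(imgs), dtype=float)
        log["responses"].append(resp)
        mean = resp.mean()
        if mean <= 0:
            break
        dev = np.abs(resp - mean) / mean
        if dev.max() <= tolerance:
            log["converged"] = True
            break
        for i, im in enumerate(imgs):
            factor = 1.0 + gain * (mean - resp[i]) / mean
            factor = min(max(factor, 0.5), 2.0)
            new = np.clip(im.pixels * factor, 0.0, 255.0)
            if factor > 1.0 and im.pixels.max() >= 254.5 and \
                    np.allclose(new, im.pixels):
                log["clipped"].add(i)
            imgs[i] = im.with_pixels(new)
    return imgs, log


def write_pgm(pattern: ImagePattern | np.ndarray, path) -> None:
    """Write a pattern as a plain (P2) PGM file."""
    px = pattern.pixels if isinstance(pattern, ImagePattern) else np.asarray(pattern)
    h, w = px.shape
    lines = [f"P2\n{w} {h}\n255"]
    for row in np.rint(px).astype(int):
        lines.append(" ".join(str(v) for v in row))
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def read_pgm(path) -> ImagePattern:
    """Read a grayscale image file (PGM/PNG/TIFF) as an ImagePattern."""
    from PIL import Image

    img = Image.open(path).convert("L")
    return ImagePattern(np.asarray(img, dtype=float))


def write_stimulus_text(stimulus: Stimulus, path) -> None:
    """Write spike trains as two-column text (channel, time_s)."""
    with open(path, "w") as f:
        f.write("# channel time_s\n")
        for c, times in enumerate(stimulus.spike_times):
            for t in times:
                f.write(f"{c} {t:.6f}\n")


def _smooth_field(rng: np.random.Generator, size, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=size), sigma, mode="wrap")
    f -= f.min()
    peak = f.max()
    return f / peak if peak > 0 else f


def generate_synthetic_faces(n_classes: int = 3, n_per_class: int = 10,
                             size=(20, 20), feature_spec: Optional[dict] = None,
                             seed: int = 0, edge_like: bool = True,
                             sparsity: float = 0.85,
                             item_noise: float = 0.8) -> List[ImagePattern]:
    """Generate classes of structured synthetic images ("faces").

    Each class is a smoothed random template; items add seeded
    item-specific perturbations, so within-class correlation exceeds
    between-class correlation by construction.  ``feature_spec`` may mark a
    binary feature block present only in designated classes, e.g.
    ``{"classes": [0], "region": (rows, cols) slices, "value": 255}`` (a
    "beard"-like patch).  ``edge_like`` turns patterns into sparse,
    high-contrast line-drawing-like images: only the intensity ridge above
    the ``sparsity`` quantile is kept (edge-detected photographs are mostly
    void pixels), with remaining intensities pushed toward the maximum.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    h, w = (int(s) for s in size)
    if h < 2 or w < 2:
        raise ValueError("degenerate image size")
    rng = stream_rng(seed, "stimulus/synthetic")
    sigma = max(1.0, min(h, w) / 8.0)
    out: List[ImagePattern] = []
    for c in range(n_classes):
        template = _smooth_field(rng, (h, w), sigma)
        for k in range(n_per_class):
            item = template + item_noise * _smooth_field(rng, (h, w), sigma / 2.0)
            item /= item.max()
            if edge_like:
                # a line drawing: keep only the ridge, high contrast
                keep = item >= np.quantile(item, sparsity)
                item = np.where(keep, np.sqrt(item), 0.0)
            px = item * 255.0
            if feature_spec and c in set(feature_spec.get("classes", ())):
                rows, cols = feature_spec.get(
                    "region", (slice(3 * h // 4, h), slice(w // 4, 3 * w // 4)))
                px[rows, cols] = feature_spec.get("value", 255.0)
            out.append(ImagePattern(np.clip(px, 0, 255),
                                    label=f"class{c}", item_id=c * n_per_class + k))
    return out
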