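"""Static-background estimation by per-pixel temporal mode.

The scene is assumed stationary and bright with dark flies moving over
it. Because each fly occupies any given pixel in only a small fraction
of frames, the most frequent intensity observed at a pixel over a
random sample of frames is the background intensity there. Ties are
broken toward the smallest intensity, which is deterministic and folds
static dark impurities into the background where the foreground
difference rule then cancels them.
"""

from __future__ import annotations

import numpy as np

from .config_io import FrameStream

__all__ = ["sample_frames", "temporal_mode", "estimate_background"]


def sample_frames(stream: FrameStream, n: int, seed: int = 0) -> np.ndarray:
    """Choose ``min(n, frame_count)`` distinct frame indices.

    Sampling is uniform without replacement and deterministic for a
    given seed; indices are returned sorted ascending. If the video has
    fewer than ``n`` frames, all frames are used.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    count = stream.frame_count
    if count == 0:
        raise ValueError("empty frame stream")
    if count <= n:
        return np.arange(count)
    rng = np.random.default_rng(seed)
    idx = rng.choice(count, size=n, replace=False)
    idx.sort()
    return idx


def temporal_mode(stream: FrameStream, indices: np.ndarray) -> np.ndarray:
    """Per-pixel most frequent intensity over the indexed frames.

    Returns a uint8 image of the same dimensions as the stream. Ties
    are broken by the smallest intensity.
    """
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("no frame indices given")
    h, w = stream.height, stream.width
    # histogram per pixel: (h*w, 256) counts, chunked over rows to bound memory
    bg = np.empty((h, w), dtype=np.uint8)
    chunk = max(1, int(4e7) // (w * 256))  # ~80 MB of uint16 counts per chunk
    frames = [stream.frame(int(i)) for i in indices]
    for r0 in range(0, h, chunk):
        r1 = min(h, r0 + chunk)
        counts = np.zeros(((r1 - r0) * w, 256), dtype=np.uint16)
        rows = np.arange((r1 - r0) * w)
        for f in frames:
            if f.shape != (h, w):
                raise ValueError(f"frame shape {f.shape} != stream shape {(h, w)}")
            counts[rows, f[r0:r1].ravel()] += 1
        # argmax returns the first (= smallest) index on ties
        bg[r0:r1] = counts.argmax(axis=1).astype(np.uint8).reshape(r1 - r0, w)
    return bg


def estimate_background(stream: FrameStream, n: int = 800, seed: int = 0) -> np.ndarray:
    """Sample frames and take their per-pixel temporal mode."""
    return temporal_mode(stream, sample_frames(stream, n, seed))
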