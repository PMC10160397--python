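"""Synthetic stimulus generation and frame I/O.

The generators emulate the model's simulated test videos on a 128 x 128
grid sampled every 33.3 ms: a centered dark square whose edge length
grows linearly until it fills the field at a known frame (looming; that
frame is the ground-truth "collision time"), its exact time reverse
(receding), and fixed-size blocks or bars translating at constant speed
along one of the 8 canonical directions.  Additive zero-mean Gaussian
noise can be applied at a requested SNR.

Objects are rasterized with exact partial-pixel (area) coverage, so
sub-pixel positions and edge lengths produce smoothly varying luminance
just as a camera integrating over pixel footprints would.

Coordinates follow the network's convention: direction 0 is rightward
and pi/2 is upward on screen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "StimulusSpec",
    "LuminanceSequence",
    "gen_looming",
    "gen_receding",
    "gen_translating",
    "generate",
    "add_gaussian_noise",
    "save_frames",
    "load_frames",
]

FRAME_INTERVAL = 0.0333  # seconds; metadata only


@dataclass
class StimulusSpec:
    """Parameters of one synthetic stimulus.

    kind : "looming", "receding" or "translate".
    grid : (H, W) pixel size.
    n_frames : sequence length (>= 3; the direction layer needs t-2).
    object_luminance, background_luminance : values in [0, 1] (dark object
        on a light background by default).
    start_size : initial square edge length (looming/receding), px.
    fill_frame : frame (1-based) at which the looming square fills the
        field; later frames are constant.  For receding, the schedule is
        the looming schedule reversed.
    direction : translation angle, one of {0, pi/4, ..., 7 pi/4}.
    speed : translation speed, px/frame.
    shape : "square" or "bar" (a bar is elongated perpendicular to the
        motion direction; axis-aligned directions only).
    size : object edge length (square) or bar thickness, px.
    noise_snr : optional SNR in dB; None or +inf disables noise.
    seed : RNG seed for the noise.
    """

    kind: str = "looming"
    grid: tuple[int, int] = (128, 128)
    n_frames: int = 60
    object_luminance: float = 0.0
    background_luminance: float = 1.0
    start_size: float = 6.0
    fill_frame: int = 40
    direction: float = 0.0
    speed: float = 1.0
    shape: str = "square"
    size: float = 11.0
    bar_length: float | None = None
    noise_snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("looming", "receding", "translate"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.n_frames < 3:
            raise ValueError("need n_frames >= 3")
        for name in ("object_luminance", "background_luminance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.kind in ("looming", "receding") and not 1 <= self.fill_frame <= self.n_frames:
            raise ValueError(f"fill_frame {self.fill_frame} outside 1..{self.n_frames}")
        if self.kind == "translate":
            if self.speed <= 0:
                raise ValueError("translation speed must be positive")
            if self.shape not in ("square", "bar"):
                raise ValueError(f"unknown object shape {self.shape!r}")

    def to_json(self) -> str:
        d = asdict(self)
        d["grid"] = list(self.grid)
        return json.dumps(d, indent=2)


@dataclass
class LuminanceSequence:
    """A T x H x W stack of luminance values in [0, 1]."""

    frames: np.ndarray
    frame_interval: float = FRAME_INTERVAL

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 3:
            raise ValueError("frames must be T x H x W with T >= 3")
        if self.frames.min() < 0.0 or self.frames.max() > 1.0:
            raise ValueError("luminance values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def _coverage_1d(n: int, lo: float, hi: float) -> np.ndarray:
    """Fraction of each unit pixel [k, k+1) covered by the interval [lo, hi]."""
    k = np.arange(n, dtype=float)
    return np.clip(np.minimum(k + 1.0, hi) - np.maximum(k, lo), 0.0, 1.0)


def _rect_frame(H: int, W: int, cx: float, cy: float, wx: float, wy: float,
                obj: float, bg: float) -> np.ndarray:
    """Rasterize an axis-aligned rectangle (center, widths) with area coverage.

    (cx, cy) are screen coordinates: cx rightward in [0, W], cy upward
    in [0, H] measured from the bottom edge.
    """
    cov_x = _coverage_1d(W, cx - wx / 2.0, cx + wx / 2.0)
    row_lo, row_hi = H - (cy + wy / 2.0), H - (cy - wy / 2.0)  # to top-down rows
    cov_y = _coverage_1d(H, row_lo, row_hi)
    cov = np.outer(cov_y, cov_x)
    return bg + (obj - bg) * cov


def _looming_edges(spec: StimulusSpec) -> np.ndarray:
    """Edge length per frame: linear growth to the full field at fill_frame."""
    H, W = spec.grid
    full = float(max(H, W))
    t = np.arange(1, spec.n_frames + 1, dtype=float)
    if spec.fill_frame == 1:
        edges = np.full(spec.n_frames, full)
    else:
        frac = np.clip((t - 1.0) / (spec.fill_frame - 1.0), 0.0, 1.0)
        edges = spec.start_size + (full - spec.start_size) * frac
    return edges


def gen_looming(spec: StimulusSpec) -> LuminanceSequence:
    """Centered dark square growing linearly until it fills the field.

    Frames at and after ``fill_frame`` are identical (the object "has
    collided"; the view no longer changes).
    """
    if spec.kind != "looming":
        raise ValueError("spec.kind must be 'looming'")
    H, W = spec.grid
    edges = _looming_edges(spec)
    frames = np.stack([
        _rect_frame(H, W, W / 2.0, H / 2.0, e, e,
                    spec.object_luminance, spec.background_luminance)
        for e in edges
    ])
    return LuminanceSequence(frames)


def gen_receding(spec: StimulusSpec) -> LuminanceSequence:
    """Time reverse of the looming geometry: the square shrinks."""
    if spec.kind != "receding":
        raise ValueError("spec.kind must be 'receding'")
    loom = gen_looming(StimulusSpec(**{**asdict(spec), "kind": "looming"}))
    return LuminanceSequence(loom.frames[::-1].copy())


def gen_translating(spec: StimulusSpec) -> LuminanceSequence:
    """Fixed-size object translating at constant speed along ``direction``.

    The trajectory is centered on the grid center; object pixels leaving
    the grid are clipped.  Raises if the object would exit the field
    before frame 3.
    """
    if spec.kind != "translate":
        raise ValueError("spec.kind must be 'translate'")
    theta_set = np.arange(8) * np.pi / 4.0
    if not np.any(np.isclose(spec.direction, theta_set)):
        raise ValueError(f"direction {spec.direction} not one of the 8 canonical angles")
    H, W = spec.grid
    ux, uy = np.cos(spec.direction), np.sin(spec.direction)
    travel = spec.speed * (spec.n_frames - 1)
    cx0, cy0 = W / 2.0 - ux * travel / 2.0, H / 2.0 - uy * travel / 2.0
    # keep the object fully on-grid at the start; if the trajectory is too
    # long it exits (clipped) near the end of the run instead
    if spec.shape == "square":
        cx0 = float(np.clip(cx0, spec.size / 2.0, W - spec.size / 2.0))
        cy0 = float(np.clip(cy0, spec.size / 2.0, H - spec.size / 2.0))
    if spec.shape == "bar":
        if abs(ux) > 1e-9 and abs(uy) > 1e-9:
            raise ValueError("bar stimuli support axis-aligned directions only")
        L = spec.bar_length if spec.bar_length is not None else 0.6 * (H if abs(ux) > 0 else W)
        wx, wy = (spec.size, L) if abs(ux) > 0 else (L, spec.size)
    else:
        wx = wy = spec.size
    frames = []
    for t in range(spec.n_frames):
        cx = cx0 + ux * spec.speed * t
        cy = cy0 + uy * spec.speed * t
        frames.append(_rect_frame(H, W, cx, cy, wx, wy,
                                  spec.object_luminance, spec.background_luminance))
        inside = (-wx / 2.0 < cx < W + wx / 2.0) and (-wy / 2.0 < cy < H + wy / 2.0)
        if t == 2 and not inside:
            raise ValueError("object exits the grid before frame 3; reduce speed")
    return LuminanceSequence(np.stack(frames))


def generate(spec: StimulusSpec) -> LuminanceSequence:
    """Dispatch on ``spec.kind`` and apply noise when requested."""
    gen = {"looming": gen_looming, "receding": gen_receding,
           "translate": gen_translating}[spec.kind]
    seq = gen(spec)
    if spec.noise_snr is not None and np.isfinite(spec.noise_snr):
        seq = add_gaussian_noise(seq, spec.noise_snr, spec.seed)
    return seq


def add_gaussian_noise(seq: LuminanceSequence, snr_db: float, seed: int) -> LuminanceSequence:
    """Additive zero-mean Gaussian noise at a requested SNR (dB).

    Signal power is the mean squared deviation of the frames from their
    temporal mean; the noise standard deviation is scaled so that
    ``10 log10(P_signal / P_noise) = snr_db``.  The noisy frames are
    clipped to [0, 1].  ``snr_db = +inf`` returns the input unchanged.
    """
    if np.isnan(snr_db) or snr_db == -np.inf:
        raise ValueError(f"snr_db must be finite or +inf, got {snr_db}")
    if snr_db == np.inf:
        return LuminanceSequence(seq.frames.copy(), seq.frame_interval)
    frames = seq.frames
    p_signal = float(np.mean((frames - frames.mean(axis=0)) ** 2))
    sigma = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = frames + rng.normal(0.0, sigma, size=frames.shape)
    return LuminanceSequence(np.clip(noisy, 0.0, 1.0), seq.frame_interval)


# ---------------------------------------------------------------------------
# frame I/O

_FRAME_EXTS = (".png", ".tif", ".tiff")
_LUMA = np.array([0.299, 0.587, 0.114])


def save_frames(seq: LuminanceSequence, path: str | Path,
                spec: StimulusSpec | None = None) -> Path:
    """Write a sequence as zero-padded 8-bit grayscale PNG frames.

    When a spec is given, a ``stimulus.json`` sidecar records it (the
    generator parameters are the ground truth of the stimulus).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(seq.frames, start=1):
        img = np.round(frame * 255.0).astype(np.uint8)
        iio.imwrite(path / f"frame_{t:04d}.png", img)
    if spec is not None:
        (path / "stimulus.json").write_text(spec.to_json())
    return path


def load_frames(path: str | Path) -> LuminanceSequence:
    """Read a directory of grayscale frames into a LuminanceSequence.

    Frames are taken in lexicographic filename order (use zero-padded
    numbering); RGB images are converted to grayscale with fixed luma
    weights; 8/16-bit integer images are normalized to [0, 1].
    """
    path = Path(path)
    files = sorted(f for f in path.iterdir()
                   if f.suffix.lower() in _FRAME_EXTS)
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF frames found in {path}")
    frames = []
    shape = None
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:
            img = img[..., :3] @ _LUMA
        if np.issubdtype(img.dtype, np.integer):
            img = img / float(np.iinfo(img.dtype).max)
        img = np.asarray(img, float)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"frame {f.name} has size {img.shape}, expected {shape}")
        frames.append(np.clip(img, 0.0, 1.0))
    return LuminanceSequence(np.stack(frames))
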