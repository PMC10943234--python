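"""Frame sequences and consecutive-frame similarity traces.

The pipeline's central signal is the *similarity score*: the squared
Pearson correlation (r²) between each pair of consecutive grayscale
frames of a fixed-camera video.  High scores mean the scene barely
changed (the animal is still); low scores mean motion.  A session of
``n`` frames yields ``n - 1`` scores, one per frame transition, ordered
in video time.  Score ``i`` spans frames ``(i, i + 1)``; downstream
durations are always ``run_length / fps``.

Grayscale conversion uses ITU-R BT.601 luma weights.  Degenerate
(zero-variance) frames are handled explicitly: two pixelwise-identical
constant frames score 1.0; a constant frame paired with anything else
scores 0.0, which the denoiser's outlier rule then catches as a
dropped-frame artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError, VideoDecodeError

__all__ = [
    "FrameSequence",
    "SimilarityTrace",
    "read_video",
    "frame_similarity",
    "compute_similarity_trace",
    "write_trace",
    "read_trace",
]

#: ITU-R BT.601 luma weights for RGB -> grayscale.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """An ordered stack of 2-D grayscale frames from one session.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Grayscale intensities, uniform scale within the sequence
        (either [0, 255] or [0, 1]).
    fps : float
        Frames per second (nominally 30 for the supported recordings).
    source_id : str
        Subject/session identifier propagated to every downstream
        artifact.
    """

    frames: np.ndarray
    fps: float = 30.0
    source_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InputError(
                f"frames must be a (n, h, w) array, got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise InputError("a frame sequence needs at least 2 frames")
        if not self.fps > 0:
            raise InputError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def crop(self, rect: tuple[int, int, int, int]) -> "FrameSequence":
        """Crop every frame to ``rect = (row0, row1, col0, col1)``.

        Provided because some recordings include regions outside the
        test cage; scoring the whole frame is the default.
        """
        r0, r1, c0, c1 = rect
        sub = self.frames[:, r0:r1, c0:c1]
        if sub.shape[1] < 1 or sub.shape[2] < 1:
            raise InputError(f"crop rectangle {rect} leaves no pixels")
        return FrameSequence(sub, fps=self.fps, source_id=self.source_id)


@dataclass
class SimilarityTrace:
    """Per-frame-pair similarity scores ordered in video time.

    ``scores[i]`` is the r² between frames ``i`` and ``i + 1``; all
    scores lie in [0, 1] and the trace has one fewer entry than the
    video has frames.
    """

    scores: np.ndarray
    fps: float = 30.0
    source_id: str = ""
    denoised: bool = False

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise InputError("scores must be a 1-D vector")
        if self.scores.size and (
            self.scores.min() < 0.0 or self.scores.max() > 1.0
        ):
            raise InputError("similarity scores must lie in [0, 1]")
        if not self.fps > 0:
            raise InputError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return self.scores.size

    @property
    def duration_s(self) -> float:
        return self.scores.size / self.fps

    def replace(self, scores: np.ndarray, denoised: bool | None = None) -> "SimilarityTrace":
        return SimilarityTrace(
            scores,
            fps=self.fps,
            source_id=self.source_id,
            denoised=self.denoised if denoised is None else denoised,
        )


def _to_grayscale(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        return frames[..., :3].astype(np.float64) @ LUMA_WEIGHTS
    if frames.ndim == 3:
        return frames.astype(np.float64)
    raise VideoDecodeError(f"unsupported frame array shape {frames.shape}")


def _downsample(frames: np.ndarray, max_dim: int) -> np.ndarray:
    h, w = frames.shape[1:3]
    longest = max(h, w)
    if longest <= max_dim:
        return frames
    from scipy.ndimage import zoom

    f = max_dim / longest
    return zoom(frames, (1.0, f, f), order=1)


def read_video(
    path: str | Path,
    fps_override: float | None = None,
    max_dim: int | None = None,
    crop: tuple[int, int, int, int] | None = None,
    source_id: str | None = None,
) -> FrameSequence:
    """Read a video or frame-stack file into a grayscale FrameSequence.

    Supports common containers (MP4/AVI via imageio's ffmpeg backend,
    when installed), multi-page TIFF stacks, and ``.npy``/``.npz`` frame
    arrays.  RGB content is converted with BT.601 luma weights.  ``fps``
    comes from container metadata when available, else defaults to 30;
    ``fps_override`` always wins.
    """
    path = Path(path)
    if not path.exists():
        raise VideoDecodeError(f"no such file: {path}")
    sid = source_id if source_id is not None else path.stem
    fps = None

    suffix = path.suffix.lower()
    if suffix == ".npy":
        frames = np.load(path)
    elif suffix == ".npz":
        with np.load(path) as z:
            frames = z["frames"]
            if "fps" in z:
                fps = float(z["fps"])
    elif suffix in (".tif", ".tiff"):
        import imageio.v3 as iio

        frames = np.asarray(iio.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    else:
        try:
            import imageio.v3 as iio

            frames = np.stack(list(iio.imiter(path)))
            try:
                meta = iio.immeta(path)
                fps = float(meta["fps"]) if "fps" in meta else None
            except Exception:
                fps = None
        except Exception as exc:  # decode failure or missing ffmpeg plugin
            raise VideoDecodeError(
                f"could not decode {path} ({exc}); MP4/AVI support requires "
                "imageio's ffmpeg backend — TIFF stacks and .npy arrays are "
                "always supported"
            ) from exc

    gray = _to_grayscale(np.asarray(frames))
    if gray.shape[0] < 2:
        raise InputError(f"{path} holds fewer than 2 frames")
    if max_dim is not None:
        gray = _downsample(gray, int(max_dim))
    seq = FrameSequence(
        gray,
        fps=float(fps_override if fps_override is not None else (fps or 30.0)),
        source_id=sid,
    )
    if crop is not None:
        seq = seq.crop(crop)
    return seq


def frame_similarity(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Similarity score between two frames: squared Pearson r of the
    flattened pixel vectors.

    Degenerate variance: both frames constant and pixelwise equal → 1.0;
    either frame constant otherwise → 0.0 (treated as a large change so
    the denoiser's outlier rule catches it).
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InputError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise InputError("frames need at least 2 pixels")
    av = a.ravel()
    bv = b.ravel()
    ac = av - av.mean()
    bc = bv - bv.mean()
    ssa = float(ac @ ac)
    ssb = float(bc @ bc)
    if ssa == 0.0 or ssb == 0.0:
        return 1.0 if np.array_equal(av, bv) else 0.0
    r = float(ac @ bc) / np.sqrt(ssa * ssb)
    return float(np.clip(r * r, 0.0, 1.0))


def compute_similarity_trace(seq: FrameSequence) -> SimilarityTrace:
    """Score every consecutive frame pair of a sequence.

    Vectorized equivalent of calling :func:`frame_similarity` on each
    pair; degenerate pairs fall back to the scalar rule.
    """
    X = seq.frames.reshape(seq.n_frames, -1).astype(np.float64)
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    cross = np.einsum("ij,ij->i", Xc[:-1], Xc[1:])
    denom2 = ss[:-1] * ss[1:]
    scores = np.zeros(seq.n_frames - 1)
    ok = denom2 > 0.0
    scores[ok] = np.clip(cross[ok] ** 2 / denom2[ok], 0.0, 1.0)
    for i in np.nonzero(~ok)[0]:
        scores[i] = frame_similarity(seq.frames[i], seq.frames[i + 1])
    return SimilarityTrace(scores, fps=seq.fps, source_id=seq.source_id)


# ---------------------------------------------------------------------------
# Trace CSV dialect: 2 columns (frame_index, score) + JSON sidecar.

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: SimilarityTrace, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a trace as a 2-column CSV with a JSON metadata sidecar."""
    path = Path(path)
    idx = np.arange(trace.scores.size)
    arr = np.column_stack([idx, trace.scores])
    header = "frame_index,score"
    np.savetxt(path, arr, fmt=["%d", "%.12g"], delimiter=",", header=header, comments="")
    meta = {
        "fps": trace.fps,
        "source_id": trace.source_id,
        "n_frames": int(trace.scores.size) + 1,
        "denoised": bool(trace.denoised),
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_trace(path: str | Path, fps: float | None = None) -> SimilarityTrace:
    """Read a trace CSV written by :func:`write_trace` (sidecar optional)."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    scores = data[:, 1]
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SimilarityTrace(
        scores,
        fps=float(fps if fps is not None else meta.get("fps", 30.0)),
        source_id=str(meta.get("source_id", path.stem)),
        denoised=bool(meta.get("denoised", False)),
    )
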