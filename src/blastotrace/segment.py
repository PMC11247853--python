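"""Per-frame area measurement of blastocyst time-lapse frames.

The measured quantities are the blastocoel-cavity area and the area enclosed
by the zona pellucida (ZP).  Both are reported in px² on a uniform frame grid
(one frame every ``frame_interval_min`` minutes, 10 min by default).  The
segmentation is a classical pipeline — intensity thresholding, morphology and
connected components — operating on frames where the ZP appears as a bright
annulus enclosing a trophectoderm ring and a darker cavity disc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "FrameMeasure",
    "AreaTrace",
    "segment_frame",
    "measure_stack",
    "infer_tB",
    "read_stack",
]

#: fraction of flagged frames above which a trace is unanalyzable
MAX_FLAGGED_FRACTION = 0.20

FLAG_OK = "ok"
FLAG_LOW_CONTRAST = "low_contrast"
FLAG_OFF_FRAME = "off_frame"


@dataclass
class FrameMeasure:
    """Areas measured on a single frame.

    ``cavity_area`` and ``zp_interior_area`` are NaN when the frame could not
    be measured (``quality_flag`` != "ok"); they are never zero-filled.
    """

    frame_index: int
    time_hpi: float
    cavity_area: float
    zp_interior_area: float
    zp_thickness: float
    quality_flag: str = FLAG_OK

    def __post_init__(self) -> None:
        if self.quality_flag == FLAG_OK:
            if not (0.0 <= self.cavity_area <= self.zp_interior_area * (1 + 1e-9)):
                raise ValueError(
                    f"cavity_area {self.cavity_area} outside "
                    f"[0, zp_interior_area={self.zp_interior_area}]"
                )
            if self.zp_thickness < 0:
                raise ValueError("zp_thickness must be >= 0")


@dataclass
class AreaTrace:
    """Cavity / ZP-interior area time series on a uniform frame grid.

    Missing frames (off-frame or low-contrast) carry NaN areas and a
    non-"ok" quality flag.  ``tSB_hpi`` / ``tB_hpi`` are optional
    morphokinetic annotations in hours post-insemination.
    """

    time_hpi: np.ndarray
    cavity_area: np.ndarray
    zp_interior_area: np.ndarray
    zp_thickness: np.ndarray
    quality_flag: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_interval_min: float = 10.0
    tSB_hpi: float | None = None
    tB_hpi: float | None = None

    def __post_init__(self) -> None:
        self.time_hpi = np.asarray(self.time_hpi, dtype=float)
        self.cavity_area = np.asarray(self.cavity_area, dtype=float)
        self.zp_interior_area = np.asarray(self.zp_interior_area, dtype=float)
        self.zp_thickness = np.asarray(self.zp_thickness, dtype=float)
        n = self.time_hpi.size
        if self.quality_flag is None:
            self.quality_flag = np.full(n, FLAG_OK, dtype=object)
        self.quality_flag = np.asarray(self.quality_flag, dtype=object)
        for name in ("cavity_area", "zp_interior_area", "zp_thickness", "quality_flag"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length {getattr(self, name).size} != {n}")
        if n >= 2:
            steps = np.diff(self.time_hpi)
            expected = self.frame_interval_min / 60.0
            if np.any(steps <= 0):
                raise ValueError("time_hpi must be strictly increasing")
            bad = np.where(np.abs(steps - expected) > 1e-6)[0]
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"non-uniform frame interval between frames {i} and {i + 1}: "
                    f"{steps[i] * 60:.3f} min (expected {self.frame_interval_min} min)"
                )
        # cavity must not exceed the ZP interior; tolerate <1% segmentation
        # overshoot by clamping, reject larger violations
        ok = self.quality_flag == FLAG_OK
        with np.errstate(invalid="ignore"):
            over = ok & (self.cavity_area > self.zp_interior_area)
        if np.any(over):
            rel = (self.cavity_area[over] - self.zp_interior_area[over]) / np.maximum(
                self.zp_interior_area[over], 1e-12
            )
            if np.any(rel >= 0.01):
                raise ValueError(
                    "cavity_area exceeds zp_interior_area by >= 1% on "
                    f"{int(np.sum(rel >= 0.01))} frame(s)"
                )
            warnings.warn(
                f"clamped cavity_area to zp_interior_area on {int(over.sum())} "
                "frame(s) (< 1% violation)",
                stacklevel=2,
            )
            self.cavity_area = np.minimum(self.cavity_area, self.zp_interior_area)

    @property
    def n_frames(self) -> int:
        return int(self.time_hpi.size)

    @property
    def flagged_fraction(self) -> float:
        return float(np.mean(self.quality_flag != FLAG_OK)) if self.n_frames else 1.0

    @property
    def analyzable(self) -> bool:
        """False when more than 20% of frames are flagged (mirrors the
        exclusion of embryos that moved out of view)."""
        return self.flagged_fraction <= MAX_FLAGGED_FRACTION

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(self.n_frames),
                "time_hpi": self.time_hpi,
                "cavity_area": self.cavity_area,
                "zp_interior_area": self.zp_interior_area,
                "zp_thickness": self.zp_thickness,
                "quality_flag": self.quality_flag,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# frame_interval_min={self.frame_interval_min}\n")
            if self.tSB_hpi is not None:
                fh.write(f"# tSB_hpi={self.tSB_hpi}\n")
            if self.tB_hpi is not None:
                fh.write(f"# tB_hpi={self.tB_hpi}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AreaTrace":
        meta: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = float(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
        return cls(
            time_hpi=df["time_hpi"].to_numpy(),
            cavity_area=df["cavity_area"].to_numpy(),
            zp_interior_area=df["zp_interior_area"].to_numpy(),
            zp_thickness=df["zp_thickness"].to_numpy(),
            quality_flag=df["quality_flag"].to_numpy(dtype=object),
            frame_interval_min=meta.get("frame_interval_min", 10.0),
            tSB_hpi=meta.get("tSB_hpi"),
            tB_hpi=meta.get("tB_hpi"),
        )


def _largest_cc(mask: np.ndarray) -> np.ndarray:
    lab = label(mask)
    if lab.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def segment_frame(
    image: np.ndarray, frame_index: int = 0, time_hpi: float = 0.0
) -> FrameMeasure:
    """Measure cavity and ZP-interior areas on one grayscale frame.

    The ZP is located as the largest bright connected annulus; its filled
    interior bounds the embryo.  The cavity is the largest dark component
    inside the ZP interior.  Frames with no usable contrast are flagged
    ``off_frame``; frames where the ZP cannot be localised are flagged
    ``low_contrast``.  Flagged frames report NaN areas.
    """
    img = np.asarray(image, dtype=float)
    missing = FrameMeasure(
        frame_index, time_hpi, np.nan, np.nan, np.nan, FLAG_OFF_FRAME
    )
    if img.ndim != 2:
        raise ValueError("segment_frame expects a single 2-D grayscale frame")
    if np.ptp(img) < 10.0:
        return missing

    # ZP annulus: brightest structure in the frame
    th_hi = 0.5 * (float(img.max()) + float(np.median(img)))
    zp = _largest_cc(img > th_hi)
    if zp.sum() < 50:
        return FrameMeasure(
            frame_index, time_hpi, np.nan, np.nan, np.nan, FLAG_LOW_CONTRAST
        )
    filled = ndimage.binary_fill_holes(zp)
    interior = filled & ~zp
    zp_interior_area = float(interior.sum())
    if zp_interior_area < 50:
        return FrameMeasure(
            frame_index, time_hpi, np.nan, np.nan, np.nan, FLAG_LOW_CONTRAST
        )
    # effective radii from areas; thickness = outer - inner
    r_out = np.sqrt(float(filled.sum()) / np.pi)
    r_in = np.sqrt(zp_interior_area / np.pi)
    thickness = max(r_out - r_in, 0.0)

    # cavity: dark component inside the ZP interior.  A near-uniform
    # interior is either all trophectoderm (no cavity) or all cavity (fully
    # expanded blastocyst); disambiguate by intensity against the
    # background / ZP anchors instead of thresholding noise.
    vals = img[interior]
    uniform = np.ptp(vals) < 20.0
    if not uniform:
        th = threshold_otsu(vals)
        lo, hi = vals[vals < th], vals[vals >= th]
        # an Otsu split of pure noise yields poorly separated classes
        uniform = (
            lo.size == 0
            or hi.size == 0
            or (hi.mean() - lo.mean()) < 3.0 * max(lo.std(), hi.std(), 1.0)
        )
    if uniform:
        bg_med = float(np.median(img[~filled]))
        zp_med = float(np.median(img[zp]))
        dark = float(np.median(vals)) < 0.5 * (bg_med + zp_med)
        cavity_area = zp_interior_area if dark else 0.0
    else:
        cavity = _largest_cc(interior & (img < th))
        cavity_area = float(cavity.sum())
    cavity_area = min(cavity_area, zp_interior_area)
    return FrameMeasure(frame_index, time_hpi, cavity_area, zp_interior_area, thickness)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a frame stack from a multi-page TIFF file or a directory of
    numbered PNG/TIFF frames.  Returns an (n_frames, H, W) array."""
    path = Path(path)
    if path.is_dir():
        from PIL import Image

        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        return np.stack([np.asarray(Image.open(p).convert("L")) for p in files])
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def measure_stack(
    stack: np.ndarray,
    time_hpi: np.ndarray,
    frame_interval_min: float = 10.0,
    tSB_hpi: float | None = None,
    tB_hpi: float | None = None,
) -> AreaTrace:
    """Segment every frame of an ordered stack into an :class:`AreaTrace`.

    Timestamps must lie on a uniform grid; a non-uniform interval is rejected
    with the offending pair reported.  Flagged frames are carried as NaN gaps;
    the trace's ``analyzable`` property is False when >20% are flagged.
    """
    stack = np.asarray(stack)
    time_hpi = np.asarray(time_hpi, dtype=float)
    if stack.shape[0] != time_hpi.size:
        raise ValueError("stack and time_hpi length mismatch")
    measures = [
        segment_frame(stack[i], frame_index=i, time_hpi=float(time_hpi[i]))
        for i in range(stack.shape[0])
    ]
    return AreaTrace(
        time_hpi=time_hpi,
        cavity_area=np.array([m.cavity_area for m in measures]),
        zp_interior_area=np.array([m.zp_interior_area for m in measures]),
        zp_thickness=np.array([m.zp_thickness for m in measures]),
        quality_flag=np.array([m.quality_flag for m in measures], dtype=object),
        frame_interval_min=frame_interval_min,
        tSB_hpi=tSB_hpi,
        tB_hpi=tB_hpi,
    )


def infer_tB(trace: AreaTrace, min_run: int = 3, eps: float = 1e-9) -> float | None:
    """Full-blastocyst time: the last frame before the ZP starts to thin.

    Returns the annotated tB unchanged when present.  Otherwise scans the
    ZP-thickness series for the first sustained decline (``min_run``
    consecutive strictly decreasing frames) and returns the time of the last
    frame before it.  Returns None (with no guessing) when no sustained
    thinning exists — the embryo is treated as never reaching full blastocyst.
    """
    if trace.tB_hpi is not None:
        return float(trace.tB_hpi)
    th = trace.zp_thickness
    t = trace.time_hpi
    ok = np.isfinite(th)
    idx = np.where(ok)[0]
    if idx.size < min_run + 1:
        return None
    th_f, t_f = th[idx], t[idx]
    dec = np.diff(th_f) < -eps
    run = 0
    for i, d in enumerate(dec):
        run = run + 1 if d else 0
        if run >= min_run:
            return float(t_f[i - min_run + 1])
    return None
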