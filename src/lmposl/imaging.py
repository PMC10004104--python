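"""Six-step 2-D OSL image-correction chain for LMP silicone-foil detectors.

The readout camera delivers 16-bit, single-channel, 1024x1024 frames.  A
processing session consists of, per detector, a stimulated *signal* frame, a
per-detector *background* frame and a *live-view* frame used to locate the
detector, plus shared white-light *flat-field* frames.  The chain applies,
in this fixed order:

1. sensor sensitivity-drift correction (divisive, ``1 + rate * t``),
2. per-detector background subtraction (clipped at zero),
3. detector localisation on the live view (30 % intensity-quantile
   threshold, largest connected component),
4. flat-field correction (gain = central-mean(flat) / flat),
5. spatial alignment: detector centre translated to pixel (512, 512), then
   rotated so the rim marker points "up",
6. extraction of the ROI statistic (mean / sd over a central circle,
   default radius 300 px).

Median filtering is deliberately absent everywhere: it biases the mean dose
inside the ROI.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

logger = logging.getLogger(__name__)

#: Standard acquisition frame size (pixels per side).
FRAME_SIZE = 1024
#: Default radius (px) of the central circle used for the ROI statistic.
DEFAULT_ROI_RADIUS = 300
#: Smallest connected component (px) accepted as a detector.
MIN_DETECTOR_AREA = 1000
#: Fraction of clipped pixels above which background subtraction logs a warning.
CLIP_WARN_FRACTION = 1e-3


class Role(str, enum.Enum):
    """Acquisition role of a frame within a session."""

    SIGNAL = "signal"
    BACKGROUND = "background"
    LIVEVIEW = "liveview"
    FLAT = "flat"


@dataclasses.dataclass
class DetectorImage:
    """A single camera frame plus acquisition metadata.

    Parameters
    ----------
    pixels
        Square 2-D array of non-negative intensities (ADU).  The standard
        acquisition format is 1024x1024 uint16; processing promotes to float.
    acquired_at
        Acquisition time in minutes relative to the first frame of the
        session (drives the sensitivity-drift correction).
    role
        One of :class:`Role`.
    detector_id
        Identifier of the foil shown in the frame (empty for shared frames
        such as flats).
    """

    pixels: np.ndarray
    acquired_at: float = 0.0
    role: Role = Role.SIGNAL
    detector_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"frame must be a square 2-D array, got shape {px.shape}")
        if px.size and float(px.min()) < 0:
            raise ValueError("pixel intensities must be non-negative")
        self.pixels = px
        self.role = Role(self.role)

    @property
    def frame_size(self) -> int:
        return self.pixels.shape[0]

    @property
    def centre_px(self) -> tuple[float, float]:
        """(x, y) pixel the alignment step targets: (512, 512) for 1024-frames."""
        c = self.frame_size // 2
        return float(c), float(c)

    def replace(self, **changes) -> "DetectorImage":
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass
class DetectorGeometry:
    """Detector disc found on a live-view frame.

    ``marker_angle`` is measured in degrees clockwise from image "up"
    (towards decreasing row index), in (-180, 180].
    """

    centre_x: float
    centre_y: float
    radius: float
    marker_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (-180.0 < self.marker_angle <= 180.0):
            self.marker_angle = _wrap_angle(self.marker_angle)


@dataclasses.dataclass
class OslSignal:
    """Scalar OSL statistic extracted from an aligned frame."""

    mean: float
    sd: float
    n_pixels: int
    roi_radius: float = DEFAULT_ROI_RADIUS


def _wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def disk_mask(n: int, cx: float, cy: float, radius: float) -> np.ndarray:
    """Boolean mask of pixels whose centres lie inside the given circle."""
    yy, xx = np.ogrid[:n, :n]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# step 1: sensitivity drift
# ---------------------------------------------------------------------------

def correct_drift(img: DetectorImage, rate: float) -> DetectorImage:
    """Remove the multiplicative sensor-sensitivity drift.

    The readout system gains sensitivity at roughly ``rate`` (fraction) per
    minute; a frame acquired ``t`` minutes after the session start is divided
    by ``1 + rate * t``.
    """
    if img.acquired_at < 0:
        raise ValueError(
            f"negative elapsed time ({img.acquired_at} min): session frames mis-ordered"
        )
    if rate < 0:
        raise ValueError("drift rate must be non-negative")
    factor = 1.0 + rate * img.acquired_at
    return img.replace(pixels=img.pixels / factor)


# ---------------------------------------------------------------------------
# step 2: background subtraction
# ---------------------------------------------------------------------------

def subtract_background(signal: DetectorImage, background: DetectorImage) -> DetectorImage:
    """Pixel-by-pixel subtraction of the per-detector background frame.

    Negative differences are clipped to zero so they cannot propagate into
    ROI means; a warning is logged when more than 0.1 % of pixels clip.
    """
    if signal.pixels.shape != background.pixels.shape:
        raise ValueError("signal and background frames differ in shape")
    if signal.detector_id != background.detector_id:
        raise ValueError(
            f"background pairing mismatch: signal {signal.detector_id!r} "
            f"vs background {background.detector_id!r}"
        )
    diff = signal.pixels.astype(float) - background.pixels.astype(float)
    clipped = float(np.mean(diff < 0))
    if clipped > CLIP_WARN_FRACTION:
        logger.debug(
            "background subtraction clipped %.2f%% of frame pixels for detector %s",
            100 * clipped, signal.detector_id,
        )
    return signal.replace(pixels=np.maximum(diff, 0.0))


def clipped_fraction(signal: DetectorImage, background: DetectorImage) -> float:
    """Fraction of pixels where the background exceeds the signal."""
    return float(np.mean(signal.pixels.astype(float) < background.pixels.astype(float)))


# ---------------------------------------------------------------------------
# step 3: detector localisation
# ---------------------------------------------------------------------------

def locate_detector(
    liveview: DetectorImage,
    quantile: float = 0.30,
    min_area: int = MIN_DETECTOR_AREA,
    opening_radius: int = 2,
    marker_band: tuple[float, float] = (0.80, 1.00),
    marker_bins: int = 36,
) -> DetectorGeometry:
    """Find the detector disc and its rim marker on a live-view frame.

    The frame is thresholded at the 30 % quantile of all its intensities
    (full frame); a small binary opening suppresses supra-threshold noise
    speckle, and the largest 4-connected component is taken as the detector.
    The marker angle is read from the minimum of the rim-band angular
    intensity profile (``marker_bins`` bins, parabolic sub-bin refinement).
    """
    px = liveview.pixels.astype(float)
    thr = float(np.quantile(px, quantile))
    mask = px > thr
    if opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(opening_radius))
    labels = measure.label(mask, connectivity=1)
    if labels.max() == 0:
        raise ValueError("no detector found: no contour separable above threshold")
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    best = int(np.argmax(areas))
    if areas[best] < min_area:
        raise ValueError(
            f"no detector found: largest component has {areas[best]} px < {min_area}"
        )
    ys, xs = np.nonzero(labels == best)
    cy, cx = float(ys.mean()), float(xs.mean())
    radius = math.sqrt(areas[best] / math.pi)
    angle = _marker_angle(px, cx, cy, radius, marker_band, marker_bins)
    return DetectorGeometry(centre_x=cx, centre_y=cy, radius=radius, marker_angle=angle)


def _marker_angle(
    px: np.ndarray,
    cx: float,
    cy: float,
    radius: float,
    band: tuple[float, float],
    n_bins: int,
) -> float:
    """Angular position (deg CW from up) of the rim-band intensity minimum."""
    n = px.shape[0]
    yy, xx = np.ogrid[:n, :n]
    dx, dy = xx - cx, yy - cy
    rho = np.hypot(dx, dy)
    annulus = (rho >= band[0] * radius) & (rho <= band[1] * radius)
    if not annulus.any():
        return 0.0
    # angle convention: 0 deg = up (-y), increasing clockwise on screen
    theta = np.degrees(np.arctan2(np.broadcast_to(dx, px.shape)[annulus],
                                  -np.broadcast_to(dy, px.shape)[annulus]))
    vals = px[annulus]
    width = 360.0 / n_bins
    idx = np.floor((theta + 180.0) / width).astype(int) % n_bins
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.inf)
    k = int(np.argmin(profile))
    y1, y2, y3 = profile[(k - 1) % n_bins], profile[k], profile[(k + 1) % n_bins]
    denom = y1 - 2.0 * y2 + y3
    shift = 0.5 * (y1 - y3) / denom if (np.isfinite(denom) and abs(denom) > 1e-12) else 0.0
    centre = -180.0 + (k + 0.5 + shift) * width
    return _wrap_angle(centre)


# ---------------------------------------------------------------------------
# step 4: flat-field correction
# ---------------------------------------------------------------------------

def flat_field_correct(
    signal: DetectorImage,
    flat: DetectorImage,
    roi_radius: float = DEFAULT_ROI_RADIUS,
    literal_gain: bool = False,
) -> DetectorImage:
    """Remove the multiplicative sensor/illumination non-uniformity.

    The gain map is the central-circle mean of the flat frame divided by the
    flat frame, so multiplying the signal by the gain cancels the vignette.
    ``literal_gain=True`` instead multiplies by the flat normalised to its
    central mean (the gain map inverted), which *imprints* rather than
    removes the pattern; it is kept as a switch for comparison with the
    alternative reading of the procedure.
    """
    if signal.pixels.shape != flat.pixels.shape:
        raise ValueError("signal and flat frames differ in shape")
    fl = flat.pixels.astype(float)
    n = fl.shape[0]
    cx, cy = signal.centre_px
    central = disk_mask(n, cx, cy, roi_radius)
    if np.any(fl[central] <= 0):
        raise ValueError("flat field contains non-positive pixels inside the central circle")
    norm = fl / float(fl[central].mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = norm if literal_gain else np.where(fl > 0, 1.0 / norm, 0.0)
    return signal.replace(pixels=signal.pixels.astype(float) * gain)


# ---------------------------------------------------------------------------
# step 5: spatial alignment
# ---------------------------------------------------------------------------

def align_detector(img: DetectorImage, geom: DetectorGeometry, order: int = 1) -> DetectorImage:
    """Translate the detector centre to (512, 512), then rotate the marker up.

    Both motions are composed into a single affine map (one bilinear
    interpolation pass); out-of-frame pixels are filled with zero.
    """
    cx_t, cy_t = img.centre_px  # alignment target
    theta = math.radians(geom.marker_angle)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    # inverse map, (row, col) ordering: p_in = C(theta) (p_out - target) + centre
    matrix = np.array([[cos_t, sin_t], [-sin_t, cos_t]])
    centre_in = np.array([geom.centre_y, geom.centre_x])
    target = np.array([cy_t, cx_t])
    offset = centre_in - matrix @ target
    out = ndimage.affine_transform(
        img.pixels.astype(float), matrix, offset=offset, order=order,
        mode="constant", cval=0.0,
    )
    return img.replace(pixels=np.maximum(out, 0.0))


# ---------------------------------------------------------------------------
# step 6: ROI statistic
# ---------------------------------------------------------------------------

def extract_osl(img: DetectorImage, roi_radius: float = DEFAULT_ROI_RADIUS) -> OslSignal:
    """Mean and standard deviation over the central circle of an aligned frame."""
    if roi_radius <= 0:
        raise ValueError("roi_radius must be positive")
    n = img.frame_size
    cx, cy = img.centre_px
    mask = disk_mask(n, cx, cy, roi_radius)
    vals = img.pixels[mask].astype(float)
    return OslSignal(
        mean=float(vals.mean()),
        sd=float(vals.std()),
        n_pixels=int(mask.sum()),
        roi_radius=float(roi_radius),
    )


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def process_stack(
    session: Sequence[DetectorImage],
    drift_rate: float = 0.1,
    roi_radius: float = DEFAULT_ROI_RADIUS,
    literal_gain: bool = False,
    locate_kwargs: Mapping | None = None,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Run the six-step chain over a whole session.

    Frames are grouped by ``detector_id``; each detector needs a signal, a
    background and a live-view frame.  Flat frames (any ``detector_id``) are
    shared: they are drift-corrected and averaged into a single gain source.
    A detector whose frames are missing or unprocessable yields a row with
    an ``error`` message; the rest of the session is still processed.

    Returns a DataFrame with one row per detector: the ROI statistic,
    geometry and correction-provenance columns.  ``exclude`` lists detector
    ids to flag as manually excluded (rows kept, ``excluded=True``).
    """
    locate_kwargs = dict(locate_kwargs or {})
    flats = [f for f in session if f.role is Role.FLAT]
    flat_img: DetectorImage | None = None
    if flats:
        corrected = [correct_drift(f, drift_rate).pixels for f in flats]
        flat_img = flats[0].replace(pixels=np.mean(corrected, axis=0))

    by_det: dict[str, dict[Role, DetectorImage]] = {}
    for frame in session:
        if frame.role is Role.FLAT:
            continue
        by_det.setdefault(frame.detector_id, {})[frame.role] = frame

    excluded = set(exclude)
    rows = []
    for det_id in sorted(by_det):
        group = by_det[det_id]
        row: dict = {"detector_id": det_id, "error": None, "excluded": det_id in excluded}
        try:
            for role in (Role.SIGNAL, Role.BACKGROUND, Role.LIVEVIEW):
                if role not in group:
                    raise KeyError(f"missing {role.value} frame for detector {det_id}")
            sig = correct_drift(group[Role.SIGNAL], drift_rate)
            bkg = correct_drift(group[Role.BACKGROUND], drift_rate)
            net = subtract_background(sig, bkg)
            geom = locate_detector(group[Role.LIVEVIEW], **locate_kwargs)
            # clip accounting over the detector disc, where it would bias the mean
            clip = sig.pixels < bkg.pixels
            disc = disk_mask(sig.frame_size, geom.centre_x, geom.centre_y, geom.radius)
            row["clipped_fraction"] = float(clip[disc].mean()) if disc.any() else 0.0
            if row["clipped_fraction"] > CLIP_WARN_FRACTION:
                logger.warning("detector %s: %.2f%% of disc pixels clipped in "
                               "background subtraction", det_id,
                               100 * row["clipped_fraction"])
            if flat_img is not None:
                net = flat_field_correct(net, flat_img, roi_radius=roi_radius,
                                         literal_gain=literal_gain)
            aligned = align_detector(net, geom)
            osl = extract_osl(aligned, roi_radius=roi_radius)
            row.update(
                mean=osl.mean, sd=osl.sd, n_pixels=osl.n_pixels,
                roi_radius=osl.roi_radius,
                centre_x=geom.centre_x, centre_y=geom.centre_y,
                radius=geom.radius, marker_angle=geom.marker_angle,
                acquired_at=group[Role.SIGNAL].acquired_at,
                drift_rate=drift_rate,
                flat_corrected=flat_img is not None,
                literal_gain=literal_gain,
            )
        except (KeyError, ValueError) as exc:
            row["error"] = str(exc)
            logger.warning("detector %s failed: %s", det_id, exc)
        rows.append(row)
    frame_cols = [
        "detector_id", "mean", "sd", "n_pixels", "roi_radius",
        "centre_x", "centre_y", "radius", "marker_angle", "acquired_at",
        "clipped_fraction", "drift_rate", "flat_corrected", "literal_gain",
        "excluded", "error",
    ]
    return pd.DataFrame(rows).reindex(columns=frame_cols)
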