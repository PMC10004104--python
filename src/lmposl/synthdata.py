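"""Synthetic readout sessions with the statistical structure the analysis assumes.

The generator renders complete camera sessions — per-foil signal,
background and live-view frames plus shared flat fields, for both the
proton irradiation and the Co-60 reference irradiation — so the whole
pipeline can be exercised closed-loop without any measured data.  A frame
is modelled as

    pixels = (1 + drift_rate * t)
             * [background + vignette(px) * jitter * signal_per_gray * dose * disc(px)]
             + read noise,                      (Poisson shot noise optional)

where the vignette acts on the collected light only — the sensor's
background offset is not an optical signal —

and quantised to 16 bits.  The disc carries a dim rim notch that serves as the
orientation marker; detector centre and rotation are randomised per
readout.  Per-frame multiplicative gain jitter (LED power / repositioning
variation between readouts, default sd 1.5 %) sets the foil-to-foil
scatter of the extracted ROI means at the few-percent level — with ~3x10^5
ROI pixels, per-pixel shot and read noise average away to ~0.01 % and
cannot produce that scatter.

Quenching enters at generation exactly where the analysis removes it: each
foil's proton frame is driven by ``true dose x eta(E_median)`` evaluated at
the foil's single attributed depth (an optional mode integrates eta over
the foil's WET to probe stopping-proton effects).  OSL response is linear
in dose over the simulated range, consistent with the material's broad
linear dose response.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import phantom, transport
from .efficiency import EfficiencyCurve, LMP_REFERENCE_CURVE
from .imaging import DetectorGeometry, DetectorImage, Role
from .transport import BeamModel, DepthDose, EnergySpectrumAtDepth

logger = logging.getLogger(__name__)

ADC_MAX = 65535


@dataclasses.dataclass(frozen=True)
class CameraModel:
    """Acquisition model of the CCD readout setup."""

    frame_size: int = 1024
    background_level: float = 100.0    # ADU
    read_noise_sd: float = 5.0         # ADU
    shot_noise: bool = True
    vignette_strength: float = 0.10    # fractional falloff at the frame corner
    drift_rate: float = 0.1            # sensitivity fraction per minute
    signal_per_gray: float = 250.0     # ADU per Gy of absorbed dose
    frame_gain_jitter_sd: float = 0.015
    disc_radius_px: float = 330.0
    marker_band: tuple[float, float] = (0.88, 0.98)  # fractions of disc radius
    marker_half_width_deg: float = 6.0
    marker_dim_factor: float = 0.55
    flat_level: float = 30000.0        # ADU of the white-light flat
    liveview_level: float = 8000.0     # ADU of the disc on a live view
    frame_interval_min: float = 0.1    # spacing of consecutive acquisitions

    def __post_init__(self) -> None:
        if not 0 <= self.vignette_strength < 0.5:
            raise ValueError("vignette_strength must lie in [0, 0.5)")
        if self.signal_per_gray <= 0:
            raise ValueError("signal_per_gray must be positive")
        if self.background_level < 0:
            raise ValueError("background level must be non-negative")

    def noiseless(self) -> "CameraModel":
        """Copy with every stochastic ingredient switched off."""
        return dataclasses.replace(self, read_noise_sd=0.0, shot_noise=False,
                                   frame_gain_jitter_sd=0.0)


@dataclasses.dataclass
class ScenarioSpec:
    """Study conditions of a closed-loop session."""

    beam: BeamModel = dataclasses.field(default_factory=BeamModel)
    layout: phantom.StackLayout = dataclasses.field(default_factory=phantom.reference_layout)
    efficiency: EfficiencyCurve = LMP_REFERENCE_CURVE
    entrance_dose_gy: float = 12.0
    gamma_dose_gy: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.entrance_dose_gy <= 0 or self.gamma_dose_gy <= 0:
            raise ValueError("doses must be positive")


def _vignette(n: int, strength: float) -> np.ndarray:
    if strength == 0:
        return np.ones((n, n))
    c = n // 2
    yy, xx = np.ogrid[:n, :n]
    r2 = ((xx - c) ** 2 + (yy - c) ** 2) / (2.0 * c**2)  # 1 at the corner
    return 1.0 - strength * r2


def _disc_with_marker(n: int, geom: DetectorGeometry, cam: CameraModel,
                      include_marker: bool) -> np.ndarray:
    yy, xx = np.ogrid[:n, :n]
    dx = xx - geom.centre_x
    dy = yy - geom.centre_y
    rho = np.hypot(dx, dy)
    disc = (rho <= geom.radius).astype(float)
    if include_marker:
        theta = np.degrees(np.arctan2(np.broadcast_to(dx, (n, n)),
                                      -np.broadcast_to(dy, (n, n))))
        delta = (theta - geom.marker_angle + 180.0) % 360.0 - 180.0
        band = ((rho >= cam.marker_band[0] * geom.radius)
                & (rho <= cam.marker_band[1] * geom.radius)
                & (np.abs(delta) <= cam.marker_half_width_deg))
        disc = np.where(band, cam.marker_dim_factor * disc, disc)
    return disc


def _digitise(expected: np.ndarray, cam: CameraModel,
              rng: np.random.Generator) -> np.ndarray:
    if cam.shot_noise:
        pixels = rng.poisson(np.maximum(expected, 0.0)).astype(float)
    else:
        pixels = expected.copy()
    if cam.read_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, cam.read_noise_sd, size=pixels.shape)
    pixels = np.clip(np.rint(pixels), 0, ADC_MAX)
    saturated = float(np.mean(pixels >= ADC_MAX))
    if saturated > 0.01:
        logger.warning("%.1f%% of pixels saturated at %d ADU", 100 * saturated, ADC_MAX)
    return pixels.astype(np.uint16)


def render_detector_frame(
    dose_gy: float,
    geom: DetectorGeometry,
    cam: CameraModel,
    acquired_at: float,
    seed: int | np.random.Generator,
    role: Role | str = Role.SIGNAL,
    detector_id: str = "",
    include_marker: bool = True,
    gain_jitter: float | None = None,
) -> DetectorImage:
    """Render one frame of a dosed detector (or a background frame at dose 0)."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cam.frame_size
    if gain_jitter is None:
        gain_jitter = (float(np.exp(rng.normal(0.0, cam.frame_gain_jitter_sd)))
                       if cam.frame_gain_jitter_sd > 0 else 1.0)
    signal = cam.signal_per_gray * dose_gy * _disc_with_marker(n, geom, cam, include_marker)
    expected = ((1.0 + cam.drift_rate * acquired_at)
                * (cam.background_level
                   + _vignette(n, cam.vignette_strength) * gain_jitter * signal))
    return DetectorImage(pixels=_digitise(expected, cam, rng),
                         acquired_at=acquired_at, role=Role(role),
                         detector_id=detector_id)


def render_liveview(geom: DetectorGeometry, cam: CameraModel, acquired_at: float,
                    rng: np.random.Generator, detector_id: str = "") -> DetectorImage:
    """Live-view frame: bright disc (with marker) used only for localisation."""
    n = cam.frame_size
    expected = (cam.background_level
                + _vignette(n, cam.vignette_strength)
                * cam.liveview_level * _disc_with_marker(n, geom, cam, True))
    return DetectorImage(pixels=_digitise(expected, cam, rng),
                         acquired_at=acquired_at, role=Role.LIVEVIEW,
                         detector_id=detector_id)


def render_flat(cam: CameraModel, acquired_at: float,
                rng: np.random.Generator) -> DetectorImage:
    """White-light flat-field frame: vignette over a uniform scene, no detector."""
    n = cam.frame_size
    expected = (cam.background_level
                + _vignette(n, cam.vignette_strength) * cam.flat_level)
    return DetectorImage(pixels=_digitise(expected, cam, rng),
                         acquired_at=acquired_at, role=Role.FLAT)


def random_geometry(cam: CameraModel, rng: np.random.Generator,
                    max_offset_px: float = 40.0) -> DetectorGeometry:
    """Random detector placement: centre near mid-frame, arbitrary rotation."""
    c = cam.frame_size // 2
    return DetectorGeometry(
        centre_x=c + rng.uniform(-max_offset_px, max_offset_px),
        centre_y=c + rng.uniform(-max_offset_px, max_offset_px),
        radius=cam.disc_radius_px,
        marker_angle=rng.uniform(-180.0, 180.0),
    )


@dataclasses.dataclass
class SessionBundle:
    """Frames of one closed-loop experiment plus the generating ground truth."""

    proton_frames: list[DetectorImage]
    gamma_frames: list[DetectorImage]
    truth: pd.DataFrame


def _foil_efficiency(curve: EfficiencyCurve, spec: EnergySpectrumAtDepth,
                     rel: transport.RangeEnergyRelation,
                     integrate_foil: bool) -> float:
    """eta driving a foil's proton frame.

    Default: the curve at the slab's median energy.  The integrating mode
    averages eta over the foil's WET (each surviving proton degraded
    through the foil, stopped protons weighted by the fraction of the foil
    they cross), probing the thick-detector caveat for stopping protons.
    """
    med, _ = transport.spectrum_summary(spec)
    if not integrate_foil:
        return float(curve(med))
    wet = phantom.FOIL_THICKNESS_MM * phantom.FOIL_WET
    steps = np.linspace(0.0, wet, 12)
    e = np.asarray(spec.energies, dtype=float)
    w = spec.weights if spec.weights is not None else np.ones_like(e)
    r = transport.range_from_energy(e, rel)
    etas = np.zeros_like(e)
    alive_frac = np.zeros_like(e)
    for i in range(len(steps) - 1):
        mid = 0.5 * (steps[i] + steps[i + 1])
        alive = r > mid
        e_mid = transport.energy_from_residual_range(np.maximum(r - mid, 0.0), rel)
        etas += np.where(alive, curve(e_mid), 0.0)
        alive_frac += alive
    keep = alive_frac > 0
    per_proton = np.where(keep, etas / np.maximum(alive_frac, 1), 0.0)
    return float(np.average(per_proton, weights=w))


def generate_session(
    scenario: ScenarioSpec,
    cam: CameraModel,
    depth_dose: DepthDose,
    spectra: Sequence[EnergySpectrumAtDepth],
    mapping: pd.DataFrame | None = None,
    rel: transport.RangeEnergyRelation = transport.DEFAULT_RELATION,
    integrate_foil: bool = False,
) -> SessionBundle:
    """Render the proton and Co-60 sessions for a full detector stack.

    ``depth_dose`` and ``spectra`` come from the transport surrogate scored
    at the stack's mapped slab centres (``mapping`` as produced by
    :func:`lmposl.phantom.map_detectors_to_grid`; recomputed here when
    omitted).  Ground truth per foil — true dose, spectral summary and the
    generating efficiency — is returned alongside the frames.
    """
    rng = np.random.default_rng(scenario.seed)
    if mapping is None:
        mapping = phantom.map_detectors_to_grid(scenario.layout, depth_dose.depth_mm)
    if len(spectra) != len(mapping):
        raise ValueError("one scored spectrum per detector is required")
    dd = depth_dose.normalized("entrance")
    rel_dose = dd.dose[mapping["grid_index"].to_numpy()]

    truth_rows = []
    proton_frames: list[DetectorImage] = [render_flat(cam, 0.0, rng)]
    gamma_frames: list[DetectorImage] = [render_flat(cam, 0.0, rng)]
    t_proton = t_gamma = cam.frame_interval_min
    for i, row in enumerate(mapping.itertuples(index=False)):
        spec = spectra[i]
        dose_true = scenario.entrance_dose_gy * float(rel_dose[i])
        if spec.is_empty or dose_true <= 0:
            eta = float("nan")
            dose_seen = 0.0
            e_med = e_iqr = float("nan")
        else:
            e_med, e_iqr = transport.spectrum_summary(spec)
            eta = _foil_efficiency(scenario.efficiency, spec, rel, integrate_foil)
            dose_seen = dose_true * eta
        geom_p = random_geometry(cam, rng)
        proton_frames.append(render_liveview(geom_p, cam, t_proton, rng, row.detector_id))
        proton_frames.append(render_detector_frame(
            dose_seen, geom_p, cam, t_proton, rng, Role.SIGNAL, row.detector_id))
        t_proton += cam.frame_interval_min
        proton_frames.append(render_detector_frame(
            0.0, geom_p, cam, t_proton, rng, Role.BACKGROUND, row.detector_id))
        t_proton += cam.frame_interval_min

        geom_g = random_geometry(cam, rng)
        gamma_frames.append(render_liveview(geom_g, cam, t_gamma, rng, row.detector_id))
        gamma_frames.append(render_detector_frame(
            scenario.gamma_dose_gy, geom_g, cam, t_gamma, rng, Role.SIGNAL,
            row.detector_id))
        t_gamma += cam.frame_interval_min
        gamma_frames.append(render_detector_frame(
            0.0, geom_g, cam, t_gamma, rng, Role.BACKGROUND, row.detector_id))
        t_gamma += cam.frame_interval_min

        truth_rows.append({
            "detector_id": row.detector_id,
            "depth_mm": row.depth_mm,
            "grid_index": row.grid_index,
            "depth_grid_mm": row.depth_grid_mm,
            "dose_true_gy": dose_true,
            "dose_seen_gy": dose_seen,
            "e_median": e_med,
            "e_iqr": e_iqr,
            "eta_true": eta,
        })
    return SessionBundle(proton_frames=proton_frames, gamma_frames=gamma_frames,
                         truth=pd.DataFrame(truth_rows))


def make_efficiency_observations(
    curve: EfficiencyCurve,
    e_median: Sequence[float],
    e_iqr: Sequence[float],
    noise_sd: float,
    rng: int | np.random.Generator,
    depths_mm: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Direct efficiency observations: curve(E) plus additive Gaussian noise."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    e = np.asarray(e_median, dtype=float)
    iqr = np.asarray(e_iqr, dtype=float)
    eta = np.asarray(curve(e), dtype=float) + rng.normal(0.0, noise_sd, size=e.shape)
    depths = np.full_like(e, np.nan) if depths_mm is None else np.asarray(depths_mm)
    return pd.DataFrame({
        "depth_mm": depths, "e_median": e, "e_iqr": iqr,
        "eta": eta, "eta_sd": np.full_like(e, noise_sd),
    })


def spectra_for_energy_span(
    beam: BeamModel,
    rel: transport.RangeEnergyRelation = transport.DEFAULT_RELATION,
    e_span: tuple[float, float] = (3.0, 58.0),
    n_depths: int = 40,
    n_protons: int = 20000,
    seed: int = 0,
) -> tuple[np.ndarray, list[EnergySpectrumAtDepth]]:
    """Scoring depths whose median energies span ``e_span``, with their spectra.

    Depths are placed at R(E_beam) - R(E_target) for targets on an even
    grid over the span, then scored with the transport surrogate.
    """
    targets = np.linspace(e_span[1], e_span[0], n_depths)
    r_beam = transport.range_from_energy(beam.mean_energy, rel)
    depths = np.maximum(r_beam - transport.range_from_energy(targets, rel), 0.0)
    _, spectra = transport.simulate_pristine(
        beam, rel, seed=seed, score_depths=depths, n_protons=n_protons)
    return depths, spectra
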