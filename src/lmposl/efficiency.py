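"""Relative luminescence efficiency: definition, composite model, fit, correction.

The relative luminescence efficiency of an OSL detector for protons is the
per-unit-dose light output relative to the same quantity under reference
Co-60 gamma irradiation,

    eta = (OSL_p / D_p) * (D_gamma / OSL_gamma),

which falls below unity at high ionisation density (low proton energy) —
the quenching effect.  Its energy dependence is modelled as a composite of
a step (logistic by default) and a weak linear term,

    eta(E) = A / (1 + exp(-(E - E0)/w)) + s*E + c,

where A is the step amplitude, E0 the threshold energy of the efficiency
drop, w the step width, s the residual slope above ~20 MeV and c an
optional intercept (fixed at 0 by default).  The model is fitted to
per-depth efficiency observations against the *median* kinetic energy of
the local proton spectrum, weighted by the inverse of the spectral IQR, in
the statsmodels idiom: :class:`QuenchingModel` holds the data,
``fit()`` returns a :class:`QuenchingResults` carrying estimates,
uncertainties and a ``summary()`` table.  Depth-wise dose correction
divides the measured dose by the modelled efficiency (floored to avoid
unbounded amplification beyond the range).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import transport

logger = logging.getLogger(__name__)

#: default lower bound applied to eta when correcting doses
DEFAULT_ETA_FLOOR = 0.05
#: default floor (MeV) applied to IQR values before weighting
DEFAULT_IQR_FLOOR = 0.1

PARAM_NAMES = ("amplitude", "center", "width", "slope", "intercept")


def _step_logistic(u: np.ndarray) -> np.ndarray:
    return special.expit(u)


def _step_erf(u: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + special.erf(u))


def _step_arctan(u: np.ndarray) -> np.ndarray:
    return 0.5 + np.arctan(u) / np.pi


STEP_SHAPES: Mapping[str, Callable[[np.ndarray], np.ndarray]] = {
    "logistic": _step_logistic,
    "erf": _step_erf,
    "arctan": _step_arctan,
}


@dataclasses.dataclass(frozen=True)
class EfficiencyCurve:
    """Parameter set of the composite step + linear efficiency model."""

    amplitude: float
    center: float          # MeV
    width: float = 1.0     # MeV
    slope: float = 0.0     # per MeV
    intercept: float = 0.0
    step_shape: str = "logistic"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.step_shape not in STEP_SHAPES:
            raise ValueError(f"unknown step shape {self.step_shape!r}")

    def __call__(self, energy_mev) -> np.ndarray | float:
        e = np.asarray(energy_mev, dtype=float)
        step = STEP_SHAPES[self.step_shape]((e - self.center) / self.width)
        eta = self.amplitude * step + self.slope * e + self.intercept
        return float(eta) if np.isscalar(energy_mev) else eta


#: reference parameterisation for LMP silicone foils (58.8 MeV ocular beam):
#: step amplitude 0.56, threshold 13.73 MeV, residual slope 0.0015 / MeV.
LMP_REFERENCE_CURVE = EfficiencyCurve(amplitude=0.56, center=13.73, width=1.0,
                                      slope=0.0015)


def model_eval(curve: EfficiencyCurve, energy_mev):
    """Evaluate the composite efficiency model at the given energies."""
    if np.any(np.asarray(energy_mev) < 0):
        raise ValueError("kinetic energy must be non-negative")
    return curve(energy_mev)


@dataclasses.dataclass(frozen=True)
class CalibrationPair:
    """Matched proton and Co-60 reference readouts of the same foil."""

    osl_proton: float   # ADU
    dose_proton: float  # Gy
    osl_gamma: float    # ADU
    dose_gamma: float   # Gy (reference irradiation, typically 60 Gy)

    def __post_init__(self) -> None:
        for name in ("osl_proton", "dose_proton", "osl_gamma", "dose_gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def relative_efficiency(cal: CalibrationPair) -> float:
    """eta = (OSL_p/D_p) * (D_gamma/OSL_gamma); scale-invariant in both units."""
    return (cal.osl_proton / cal.dose_proton) * (cal.dose_gamma / cal.osl_gamma)


@dataclasses.dataclass
class EfficiencyObservation:
    """One depth's efficiency measurement with its spectral summary."""

    depth_mm: float
    e_median: float
    e_iqr: float
    eta: float
    eta_sd: float = float("nan")


def observations_frame(obs: Iterable[EfficiencyObservation]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(o) for o in obs])


def efficiency_profile(
    dose_lmp_gy: Sequence[float],
    depths_mm: Sequence[float],
    reference: transport.DepthDose,
    spectra: Sequence[transport.EnergySpectrumAtDepth],
    entrance_dose_gy: float,
    entrance_window_mm: float = 5.0,
    dose_lmp_sd_gy: Sequence[float] | None = None,
    min_ref_fraction: float = 0.01,
) -> pd.DataFrame:
    """Per-depth efficiency: foil dose over the anchored reference dose.

    The foil doses are absolute (Gy, via the Co-60 calibration); the
    *relative* reference curve is anchored so that its mean over the first
    ``entrance_window_mm`` equals the delivered entrance dose, which
    preserves the absolute efficiency scale.  Depths whose spectrum is
    empty (beyond the beam range), or whose reference dose falls below
    ``min_ref_fraction`` of the entrance dose — where the foil signal is
    camera noise and the ratio is undefined within it — are dropped with
    a warning.
    """
    dose_lmp = np.asarray(dose_lmp_gy, dtype=float)
    depths = np.asarray(depths_mm, dtype=float)
    if dose_lmp.shape != depths.shape or len(spectra) != depths.size:
        raise ValueError("doses, depths and spectra must have matching lengths")
    sd = (np.full_like(dose_lmp, np.nan) if dose_lmp_sd_gy is None
          else np.asarray(dose_lmp_sd_gy, dtype=float))
    ref = reference.normalized("entrance", entrance_window_mm=entrance_window_mm)
    ref_dose = entrance_dose_gy * ref.at(depths)
    floor = min_ref_fraction * entrance_dose_gy
    rows = []
    for i, spec in enumerate(spectra):
        if ref_dose[i] <= floor or spec.is_empty or not np.isfinite(dose_lmp[i]):
            logger.warning("dropping depth %.2f mm: reference dose %.3g Gy "
                           "below threshold or spectrum empty", depths[i], ref_dose[i])
            continue
        med, iqr = transport.spectrum_summary(spec)
        eta = dose_lmp[i] / ref_dose[i]
        rows.append(EfficiencyObservation(
            depth_mm=float(depths[i]), e_median=med, e_iqr=iqr,
            eta=float(eta), eta_sd=float(sd[i] / ref_dose[i]),
        ))
    return observations_frame(rows)


class ConvergenceError(RuntimeError):
    """Raised when the weighted fit fails; carries the last iterate."""

    def __init__(self, message: str, last_params: np.ndarray):
        super().__init__(message)
        self.last_params = np.asarray(last_params)


class QuenchingModel:
    """Weighted composite step+linear efficiency model, statsmodels-style.

    Parameters
    ----------
    eta, energy
        Efficiency observations and the median kinetic energy (MeV) they
        are plotted against.
    iqr
        Spectral interquartile range per observation; drives the weights.
        ``None`` means unweighted.
    weight_mode
        ``"inverse_iqr"`` (default): weight w = 1 / max(IQR, iqr_floor) —
        broader local spectra count less.  ``"iqr"``: w = max(IQR, floor),
        the opposite reading, kept as a switch.
    step_shape
        "logistic" (default), "erf" or "arctan".
    fit_intercept
        Free the intercept c (default: fixed at 0).
    """

    def __init__(
        self,
        eta: Sequence[float],
        energy: Sequence[float],
        iqr: Sequence[float] | None = None,
        step_shape: str = "logistic",
        weight_mode: str = "inverse_iqr",
        iqr_floor: float = DEFAULT_IQR_FLOOR,
        fit_intercept: bool = False,
    ):
        eta = np.asarray(eta, dtype=float)
        energy = np.asarray(energy, dtype=float)
        if eta.shape != energy.shape:
            raise ValueError("eta and energy must have the same length")
        keep = np.isfinite(eta) & np.isfinite(energy)
        if iqr is not None:
            iqr = np.asarray(iqr, dtype=float)
            keep &= np.isfinite(iqr)
        self.eta = eta[keep]
        self.energy = energy[keep]
        self.iqr = None if iqr is None else iqr[keep]
        if self.eta.size < 5:
            raise ValueError("at least 5 finite observations are required")
        if step_shape not in STEP_SHAPES:
            raise ValueError(f"unknown step shape {step_shape!r}")
        self.step_shape = step_shape
        self.fit_intercept = bool(fit_intercept)
        if self.iqr is None:
            self.weights = np.ones_like(self.eta)
        elif weight_mode == "inverse_iqr":
            self.weights = 1.0 / np.maximum(self.iqr, iqr_floor)
        elif weight_mode == "iqr":
            self.weights = np.maximum(self.iqr, iqr_floor)
        else:
            raise ValueError(f"unknown weight mode {weight_mode!r}")

    @classmethod
    def from_observations(cls, obs: Iterable[EfficiencyObservation] | pd.DataFrame,
                          **kwargs) -> "QuenchingModel":
        df = obs if isinstance(obs, pd.DataFrame) else observations_frame(obs)
        return cls(eta=df["eta"].to_numpy(), energy=df["e_median"].to_numpy(),
                   iqr=df["e_iqr"].to_numpy() if "e_iqr" in df else None, **kwargs)

    from_dataframe = from_observations

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES if self.fit_intercept else PARAM_NAMES[:4]

    def _predict(self, params: np.ndarray, energy: np.ndarray) -> np.ndarray:
        a, e0, w, s = params[:4]
        c = params[4] if params.size > 4 else 0.0
        return a * STEP_SHAPES[self.step_shape]((energy - e0) / w) + s * energy + c

    def _start(self, start: Mapping[str, float] | None) -> np.ndarray:
        lo, hi = float(self.eta.min()), float(self.eta.max())
        mid_energy = float(self.energy[np.argmin(np.abs(self.eta - 0.5 * (lo + hi)))])
        defaults = {
            "amplitude": max(hi - lo, 0.1),
            "center": mid_energy,
            "width": 1.0,
            "slope": 1e-3,
            "intercept": 0.0,
        }
        if start:
            defaults.update(start)
        return np.array([defaults[name] for name in self.param_names])

    def fit(self, start: Mapping[str, float] | None = None,
            xtol: float = 1e-14, ftol: float = 1e-14, gtol: float = 1e-14,
            max_nfev: int = 20000) -> "QuenchingResults":
        p0 = self._start(start)
        e0_start = p0[1]
        below = int(np.sum(self.energy < e0_start))
        above = int(np.sum(self.energy > e0_start))
        if below == 0 or above == 0:
            raise ValueError(
                "centre unidentifiable: all observations lie on one side of the threshold"
            )
        sqrt_w = np.sqrt(self.weights)

        def residuals(params: np.ndarray) -> np.ndarray:
            return sqrt_w * (self._predict(params, self.energy) - self.eta)

        n_free = p0.size
        lower = np.full(n_free, -np.inf)
        upper = np.full(n_free, np.inf)
        lower[0], lower[1], lower[2] = 1e-9, 0.0, 1e-6  # A > 0, E0 >= 0, w > 0
        res = optimize.least_squares(residuals, p0, bounds=(lower, upper),
                                     xtol=xtol, ftol=ftol, gtol=gtol,
                                     max_nfev=max_nfev, method="trf")
        if not res.success:
            raise ConvergenceError(f"efficiency fit failed: {res.message}", res.x)
        chi2 = float(2.0 * res.cost)
        dof = self.eta.size - n_free
        redchi = chi2 / dof if dof > 0 else float("nan")
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * (chi2 / dof if dof > 0 else 1.0)
        except np.linalg.LinAlgError:
            cov = np.full((n_free, n_free), np.nan)
        return QuenchingResults(model=self, params=res.x.copy(), cov_params=cov,
                                chi2=chi2, redchi=redchi, nobs=int(self.eta.size))


@dataclasses.dataclass
class QuenchingResults:
    """Fit results: estimates, covariance, diagnostics, correction helpers."""

    model: QuenchingModel
    params: np.ndarray
    cov_params: np.ndarray
    chi2: float
    redchi: float
    nobs: int

    @property
    def param_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.model.param_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)),
                         index=self.model.param_names)

    @property
    def curve(self) -> EfficiencyCurve:
        p = self.param_series
        return EfficiencyCurve(
            amplitude=float(p["amplitude"]), center=float(p["center"]),
            width=float(p["width"]), slope=float(p["slope"]),
            intercept=float(p.get("intercept", 0.0)),
            step_shape=self.model.step_shape,
        )

    def predict(self, energy_mev) -> np.ndarray | float:
        return self.curve(energy_mev)

    def correct(self, dose, e_median, eta_floor: float = DEFAULT_ETA_FLOOR):
        return apply_correction(dose, e_median, self.curve, eta_floor=eta_floor)

    def summary(self) -> str:
        lines = [
            "Quenching efficiency model (composite %s step + linear)" % self.model.step_shape,
            "=" * 60,
            f"{'parameter':<12}{'estimate':>14}{'std err':>14}",
            "-" * 60,
        ]
        for name, est, se in zip(self.model.param_names, self.params,
                                 np.sqrt(np.diag(self.cov_params))):
            lines.append(f"{name:<12}{est:>14.5g}{se:>14.3g}")
        lines += [
            "-" * 60,
            f"n_obs = {self.nobs}   chi2 = {self.chi2:.4g}   "
            f"reduced chi2 = {self.redchi:.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, energies=None):
        """Observations and the fitted curve on one axis (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.errorbar(m.energy, m.eta, fmt="o", ms=4, label="observations")
        e = np.linspace(0.0, max(60.0, m.energy.max()), 400) if energies is None else energies
        ax.plot(e, self.curve(e), "-", label="fitted model")
        ax.set_xlabel("median kinetic energy (MeV)")
        ax.set_ylabel("relative efficiency")
        ax.legend()
        return ax


def fit_efficiency_model(
    obs: Iterable[EfficiencyObservation] | pd.DataFrame,
    start: Mapping[str, float] | None = None,
    **model_kwargs,
) -> QuenchingResults:
    """Convenience wrapper: build a :class:`QuenchingModel` and fit it."""
    return QuenchingModel.from_observations(obs, **model_kwargs).fit(start=start)


def compare_step_shapes(
    obs: Iterable[EfficiencyObservation] | pd.DataFrame,
    shapes: Sequence[str] = ("logistic", "erf", "arctan"),
    **model_kwargs,
) -> pd.DataFrame:
    """Fit each candidate step shape and tabulate the fit quality.

    A harness, not an automatic selector: the logistic shape stays the
    package default regardless of the outcome.
    """
    rows = []
    for shape in shapes:
        res = QuenchingModel.from_observations(obs, step_shape=shape,
                                               **model_kwargs).fit()
        row = {"step_shape": shape, "chi2": res.chi2, "redchi": res.redchi}
        row.update(res.param_series.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def apply_correction(
    dose,
    e_median,
    curve: EfficiencyCurve,
    eta_floor: float = DEFAULT_ETA_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Divide measured doses by the modelled efficiency at the local median energy.

    Returns ``(corrected, floored)``: the floor (default 0.05) bounds the
    amplification at distal depths where the model tends to zero; depths
    where it engaged are flagged, not dropped.
    """
    if eta_floor <= 0:
        raise ValueError("eta_floor must be positive")
    dose = np.asarray(dose, dtype=float)
    e = np.asarray(e_median, dtype=float)
    if dose.shape != e.shape:
        raise ValueError("dose and e_median must have the same shape")
    eta = np.asarray(curve(e), dtype=float)
    floored = eta < eta_floor
    corrected = dose / np.maximum(eta, eta_floor)
    return corrected, floored


def residual_range(energy_mev, rel: transport.RangeEnergyRelation = transport.DEFAULT_RELATION):
    """Residual range in mm water of a proton of the given kinetic energy."""
    return transport.range_from_energy(energy_mev, rel)
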