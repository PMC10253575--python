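"""Aortic stiffness measures: multi-plane (4D) PWV, two-plane (2D) PWV,
distensibility, and per-subject panel assembly.

PWV from many planes is obtained by regressing transit-time delay on
distance to the reference plane and inverting the slope: the delay carries
the measurement noise, so with delay as the response the ordinary
least-squares fit is unbiased, whereas regressing distance on noisy delays
suffers classical attenuation toward low velocities.  The alternative
orientation is available behind a flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (InsufficientDataError, InvalidArgumentError,
                     LowQualityError, NoSignalError, NonPhysiologicalFitError)
from .synthetic import AreaCurveSet, FlowCurveSet, PressureRecord, AorticCenterline
from .transit_time import plane_delays, upslope_xcorr_delay, wavelet_delay

__all__ = [
    "PWVFit",
    "StiffnessPanel",
    "pwv_from_delays",
    "pwv_two_plane",
    "distensibility",
    "subject_panel",
]


@dataclass(frozen=True)
class PWVFit:
    """Result of the distance-delay regression."""

    pwv: float                 # m/s
    n_planes_used: int
    residual_sd: float         # s
    rejected: tuple[int, ...]  # plane indices removed by the outlier pass
    intercept: float           # s, delay offset at the reference

    def __post_init__(self) -> None:
        if self.n_planes_used < 2:
            raise InvalidArgumentError("fit needs >= 2 planes")
        if not (np.isfinite(self.pwv) and self.pwv > 0):
            raise NonPhysiologicalFitError(f"PWV {self.pwv} not physiological")


def pwv_from_delays(arc_lengths_mm, delays_s,
                    orientation: str = "delay_on_distance",
                    outlier_sd: float = 2.5) -> PWVFit:
    """Fit PWV from per-plane transit delays to the most distal reference.

    Parameters
    ----------
    arc_lengths_mm : array
        Arc-length positions of the planes (mm); the last plane is the
        reference.
    delays_s : array
        Delay of the reference waveform relative to each plane (s), as
        produced by :func:`aortastiff.transit_time.plane_delays`; NaNs are
        treated as missing planes.
    orientation : str
        ``"delay_on_distance"`` (default): OLS of delay against distance,
        PWV = 1/slope.  ``"distance_on_delay"``: OLS of distance against
        delay, PWV = slope.
    outlier_sd : float
        One rejection pass removes planes with |residual| beyond this many
        residual SDs, then refits.
    """
    arcs = np.asarray(arc_lengths_mm, float)
    delays = np.asarray(delays_s, float)
    if arcs.shape != delays.shape:
        raise InvalidArgumentError("arc lengths and delays must align")
    dist_m = (arcs[-1] - arcs) / 1000.0   # distance to the distal reference
    ok = np.isfinite(delays)
    if ok.sum() < 2:
        raise InsufficientDataError("fewer than 2 valid (distance, delay) pairs")

    def _fit(mask):
        if orientation == "delay_on_distance":
            slope, icpt = np.polyfit(dist_m[mask], delays[mask], 1)
            res = delays[mask] - (icpt + slope * dist_m[mask])   # s
            pwv = 1.0 / slope if slope > 0 else -1.0
            return pwv, icpt, res
        elif orientation == "distance_on_delay":
            slope, icpt = np.polyfit(delays[mask], dist_m[mask], 1)
            res_m = dist_m[mask] - (icpt + slope * delays[mask])
            pwv = slope
            res = res_m / slope if slope > 0 else res_m
            return pwv, icpt, res
        raise InvalidArgumentError(f"unknown orientation {orientation!r}")

    pwv, icpt, res = _fit(ok)
    rejected: tuple[int, ...] = ()
    sd = float(res.std())
    if sd > 0:
        bad_local = np.abs(res) > outlier_sd * sd
        if bad_local.any() and (ok.sum() - bad_local.sum()) >= 2:
            idx_ok = np.where(ok)[0]
            rejected = tuple(int(i) for i in idx_ok[bad_local])
            mask = ok.copy()
            mask[list(rejected)] = False
            pwv, icpt, res = _fit(mask)
            ok = mask
    if not (np.isfinite(pwv) and pwv > 0):
        raise NonPhysiologicalFitError(
            "fitted slope is non-positive (wave appears to travel backward)")
    return PWVFit(pwv=float(pwv), n_planes_used=int(ok.sum()),
                  residual_sd=float(res.std()), rejected=rejected,
                  intercept=float(icpt))


def pwv_two_plane(aortic_length_mm: float, transit_time_s: float) -> float:
    """Two-plane PWV: centerline length between the ascending and descending
    measurement sites divided by the transit time, in m/s."""
    if aortic_length_mm <= 0:
        raise InvalidArgumentError("aortic length must be > 0")
    if transit_time_s <= 0:
        raise NonPhysiologicalFitError(
            f"transit time {transit_time_s} s not physiological")
    return (aortic_length_mm / 1000.0) / transit_time_s


def distensibility(areas_aa: AreaCurveSet, areas_da: AreaCurveSet,
                   pressure: PressureRecord) -> float:
    """Aortic distensibility, mean of the ascending and descending sites:
    D = (Amax - Amin) / (Amin * PP), reported in 10^-3 mmHg^-1."""
    pp = pressure.pp
    if pp <= 0:
        raise InvalidArgumentError("pulse pressure must be > 0")
    d_aa = (areas_aa.amax - areas_aa.amin) / (areas_aa.amin * pp)
    d_da = (areas_da.amax - areas_da.amin) / (areas_da.amin * pp)
    return 1e3 * 0.5 * (d_aa + d_da)


@dataclass
class StiffnessPanel:
    """The four per-subject stiffness measures with provenance.

    Missing measures are None, with the reason recorded in ``missing``.
    Provenance is ``"simulated-direct"`` for values passed through from the
    cohort simulator and ``"estimated-from-waveforms"`` for values computed
    from flow curves/areas.
    """

    cf_pwv: float | None = None
    pwv_2d: float | None = None
    pwv_4d: float | None = None
    distensibility: float | None = None
    provenance: dict[str, str] = field(default_factory=dict)
    missing: dict[str, str] = field(default_factory=dict)
    fit_4d: PWVFit | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {"cf_pwv": self.cf_pwv, "pwv_2d": self.pwv_2d,
                "pwv_4d": self.pwv_4d, "distensibility": self.distensibility}


def _two_plane_from_curves(curves: FlowCurveSet, centerline: AorticCenterline,
                           method: str) -> float:
    """2D PWV from the planes nearest the two cine-slice landmarks."""
    s_asc = centerline.landmark_arc_length("ascending_at_2D_slice")
    s_desc = centerline.landmark_arc_length("descending_at_2D_slice")
    i_asc = int(np.argmin(np.abs(curves.plane_arc_lengths - s_asc)))
    i_desc = int(np.argmin(np.abs(curves.plane_arc_lengths - s_desc)))
    if i_asc == i_desc:
        raise InsufficientDataError("2D-slice landmarks map to the same plane")
    length = float(curves.plane_arc_lengths[i_desc] - curves.plane_arc_lengths[i_asc])
    est = upslope_xcorr_delay if method == "xcorr" else wavelet_delay
    delay, _ = est(curves.flow[i_asc], curves.flow[i_desc], curves.time_axis)
    return pwv_two_plane(length, delay)


def subject_panel(flow_curves: FlowCurveSet | None = None,
                  areas_aa: AreaCurveSet | None = None,
                  areas_da: AreaCurveSet | None = None,
                  pressure: PressureRecord | None = None,
                  cf_pwv: float | None = None,
                  centerline: AorticCenterline | None = None,
                  method_4d: str = "wavelet",
                  method_2d: str = "xcorr") -> StiffnessPanel:
    """Assemble the four stiffness measures for one subject.

    Each measure is computed independently; failures are recorded as
    missing with a reason instead of aborting the subject (tonometry and
    segmentation failures occur in practice and subjects are analyzed with
    whatever measures remain).
    """
    panel = StiffnessPanel()

    if cf_pwv is not None:
        panel.cf_pwv = float(cf_pwv)
        panel.provenance["cf_pwv"] = "simulated-direct"
    else:
        panel.missing["cf_pwv"] = "no tonometry value supplied"

    if flow_curves is not None:
        try:
            res = plane_delays(flow_curves, method=method_4d)
            fit = pwv_from_delays(flow_curves.plane_arc_lengths, res.delays)
            panel.pwv_4d = fit.pwv
            panel.fit_4d = fit
            panel.provenance["pwv_4d"] = "estimated-from-waveforms"
        except (NoSignalError, LowQualityError, InsufficientDataError,
                NonPhysiologicalFitError) as exc:
            panel.missing["pwv_4d"] = str(exc)
        if centerline is not None:
            try:
                panel.pwv_2d = _two_plane_from_curves(flow_curves, centerline,
                                                      method_2d)
                panel.provenance["pwv_2d"] = "estimated-from-waveforms"
            except (NoSignalError, LowQualityError, InsufficientDataError,
                    NonPhysiologicalFitError) as exc:
                panel.missing["pwv_2d"] = str(exc)
        else:
            panel.missing["pwv_2d"] = "no centerline supplied"
    else:
        panel.missing["pwv_4d"] = "no flow curves supplied"
        panel.missing["pwv_2d"] = "no flow curves supplied"

    if areas_aa is not None and areas_da is not None and pressure is not None:
        try:
            panel.distensibility = distensibility(areas_aa, areas_da, pressure)
            panel.provenance["distensibility"] = "estimated-from-waveforms"
        except InvalidArgumentError as exc:
            panel.missing["distensibility"] = str(exc)
    else:
        panel.missing["distensibility"] = "areas or pressure not supplied"

    if all(v is None for v in panel.as_dict().values()):
        raise InsufficientDataError("no stiffness measure computable")
    return panel
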