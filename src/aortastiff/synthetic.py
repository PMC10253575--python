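"""Synthetic inputs for the aortic-stiffness pipeline.

Everything the analysis side consumes is generated here with known ground
truth: a 3D aortic centerline with the eight standard anatomical landmarks,
gamma-variate flow waveforms propagated along the centerline at a prescribed
pulse wave velocity (PWV), MRI-like temporal sampling (coarse acquisition
grid reconstructed to a fixed number of cardiac phases, additive Gaussian
noise at a stated SNR), cine-like systolic/diastolic lumen areas consistent
with a prescribed distensibility, central pressures, and full two-group
(CAD patients vs. matched controls) cohorts whose stiffness-measure
marginals and cross-measure correlations follow a configurable
:class:`CohortSpec` coupled by a Gaussian copula.

Units follow clinical convention throughout: time s, arc length mm, flow
mL/s, area mm^2, pressure mmHg, PWV m/s, distensibility 10^-3 mmHg^-1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.special import ndtr, ndtri
from scipy.stats import spearmanr

from .errors import CalibrationError, InvalidArgumentError

__all__ = [
    "LANDMARK_NAMES",
    "LANDMARK_FRACTIONS",
    "MEASURES",
    "POOLED_SPEARMAN_TARGETS",
    "AorticCenterline",
    "WaveformParams",
    "FlowCurveSet",
    "AreaCurveSet",
    "PressureRecord",
    "SubjectTruth",
    "NormalMarginal",
    "LogNormalMarginal",
    "CohortSpec",
    "default_cohort_spec",
    "make_centerline",
    "make_flow_waveform",
    "waveform_function",
    "propagate_waveform",
    "sample_and_noise",
    "make_area_and_pressure",
    "draw_cohort",
    "calibrate_copula",
    "simulate_subject_flow",
]

#: Anatomical landmarks in downstream order, aortic valve to coeliac trunk.
LANDMARK_NAMES = (
    "aortic_valve",
    "sinotubular_junction",
    "ascending_at_2D_slice",
    "brachiocephalic_bifurcation",
    "isthmus",
    "descending_at_2D_slice",
    "diaphragmatic_aorta",
    "coeliac_trunk",
)

#: Fractional arc-length positions of the landmarks; only ordering matters
#: downstream, the fractions are a fixed anatomical convention.
LANDMARK_FRACTIONS = (0.0, 0.04, 0.18, 0.30, 0.42, 0.55, 0.80, 1.0)

#: Canonical order of the four stiffness measures in copula vectors/matrices.
MEASURES = ("cf_pwv", "pwv_2d", "pwv_4d", "distensibility")

#: Pooled-cohort (both groups mixed) Spearman correlation targets used by
#: default when calibrating the within-group copula.
POOLED_SPEARMAN_TARGETS: dict[tuple[str, str], float] = {
    ("pwv_4d", "cf_pwv"): 0.66,
    ("pwv_4d", "pwv_2d"): 0.51,
    ("pwv_4d", "distensibility"): -0.33,
}

_NORM_Q75 = 0.6744897501960817  # standard normal 75th percentile


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AorticCenterline:
    """Ordered 3D aortic centerline (mm) with cumulative arc length and the
    eight standard anatomical landmarks mapped to point indices."""

    points: np.ndarray                 # (n, 3) mm
    cumulative_arc_length: np.ndarray  # (n,) mm, starts at 0
    landmarks: dict[str, int]

    def __post_init__(self) -> None:
        s = np.asarray(self.cumulative_arc_length, float)
        if s[0] != 0.0 or np.any(np.diff(s) <= 0):
            raise InvalidArgumentError(
                "cumulative_arc_length must start at 0 and be strictly increasing")
        if not 200.0 <= s[-1] <= 450.0:
            raise InvalidArgumentError(
                f"total centerline length {s[-1]:.1f} mm outside physiological "
                "bound [200, 450] mm")
        idx = [self.landmarks[name] for name in LANDMARK_NAMES]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InvalidArgumentError(
                "landmark indices must be strictly increasing in anatomical order")

    @property
    def total_length(self) -> float:
        return float(self.cumulative_arc_length[-1])

    def landmark_arc_length(self, name: str) -> float:
        """Arc-length position (mm) of a named landmark."""
        return float(self.cumulative_arc_length[self.landmarks[name]])


def make_centerline(total_length: float = 330.0, n_points: int = 200,
                    seed: int = 0) -> AorticCenterline:
    """Build a smooth candy-cane-shaped synthetic aortic centerline.

    The curve has an ascending limb, an arch with a slight out-of-plane
    bulge, and a longer descending limb; a small seeded low-order sinusoidal
    wobble makes each instance unique while keeping the arc length monotone.
    The returned polyline is rescaled so its arc length equals
    ``total_length`` exactly.

    Parameters
    ----------
    total_length : float
        Target arc length in mm, within the physiological bound [200, 450].
    n_points : int
        Number of points along the curve, at least 16.
    seed : int
        Seed for the wobble; identical seeds give identical curves.
    """
    if not 200.0 <= total_length <= 450.0:
        raise InvalidArgumentError(
            f"total_length {total_length} mm outside [200, 450]")
    if n_points < 16:
        raise InvalidArgumentError(f"n_points must be >= 16, got {n_points}")

    rng = default_rng(seed)
    # unit-scale shape: ascending limb height a, arch radius r, descending d
    a, r, d = 0.55, 0.33, 1.15
    seg = np.array([a, math.pi * r, d])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    L0 = cum[-1]
    s = np.linspace(0.0, L0, n_points)

    pts = np.empty((n_points, 3))
    for i, si in enumerate(s):
        if si <= cum[1]:                       # ascending, straight up
            pts[i] = (0.0, 0.0, si)
        elif si <= cum[2]:                     # arch, semicircle in x-z
            th = (si - cum[1]) / r             # 0..pi
            pts[i] = (r - r * math.cos(th), 0.12 * r * math.sin(th),
                      a + r * math.sin(th))
        else:                                  # descending, straight down
            pts[i] = (2 * r, 0.0, a - (si - cum[2]))

    # seeded smooth wobble, small enough to keep arc length monotone
    u = s / L0
    for axis in range(3):
        amp = rng.normal(0.0, 0.004, size=3)
        ph = rng.uniform(0.0, 2 * math.pi, size=3)
        for k in range(3):
            pts[:, axis] += amp[k] * np.sin((k + 1) * math.pi * u + ph[k])

    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0),
                                                          axis=1))])
    pts *= total_length / arc[-1]
    arc *= total_length / arc[-1]

    landmarks: dict[str, int] = {}
    prev = -1
    for name, frac in zip(LANDMARK_NAMES, LANDMARK_FRACTIONS):
        idx = int(np.argmin(np.abs(arc - frac * total_length)))
        idx = max(idx, prev + 1)
        landmarks[name] = idx
        prev = idx
    return AorticCenterline(points=pts, cumulative_arc_length=arc,
                            landmarks=landmarks)


# ---------------------------------------------------------------------------
# flow waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformParams:
    """Parameters of the gamma-variate aortic flow template.

    ``diastolic_fraction`` scales a delayed copy of the systolic pulse that
    stands in for the small early-diastolic forward-flow wave; zero disables
    it.  ``shape_alpha`` is the gamma-variate shape exponent (larger = more
    symmetric pulse).
    """

    cardiac_period: float = 1.0        # s
    peak_flow: float = 400.0           # mL/s
    time_to_peak: float = 0.15         # s
    upslope_duration: float = 0.10     # s
    diastolic_fraction: float = 0.1    # [0, 1)
    baseline_flow: float = 0.0         # mL/s
    shape_alpha: float = 3.0
    diastolic_delay_fraction: float = 0.35  # of cardiac_period

    def __post_init__(self) -> None:
        if self.cardiac_period <= 0:
            raise InvalidArgumentError("cardiac_period must be > 0")
        if not 0.0 < self.upslope_duration < self.time_to_peak < self.cardiac_period:
            raise InvalidArgumentError(
                "need 0 < upslope_duration < time_to_peak < cardiac_period")
        if not self.peak_flow > self.baseline_flow >= 0.0:
            raise InvalidArgumentError("need peak_flow > baseline_flow >= 0")
        if not 0.0 <= self.diastolic_fraction < 1.0:
            raise InvalidArgumentError("diastolic_fraction must be in [0, 1)")


def _gamma_pulse(t: np.ndarray, t_on: float, t_peak: float, alpha: float) -> np.ndarray:
    """Gamma-variate pulse, 0 before onset, peak value 1 at ``t_peak``."""
    x = (t - t_on) / (t_peak - t_on)
    with np.errstate(over="ignore"):
        out = np.where(x > 0, np.abs(x) ** alpha * np.exp(alpha * (1.0 - x)), 0.0)
    return out


def waveform_function(params: WaveformParams):
    """Return a callable Q(t) (mL/s) evaluating the periodic flow template
    at arbitrary times; times are wrapped modulo the cardiac period."""
    p = params

    def q(t):
        t = np.asarray(t, float) % p.cardiac_period
        t_on = p.time_to_peak - p.upslope_duration
        g = _gamma_pulse(t, t_on, p.time_to_peak, p.shape_alpha)
        if p.diastolic_fraction > 0:
            td = (t - p.diastolic_delay_fraction * p.cardiac_period) % p.cardiac_period
            g = g + p.diastolic_fraction * _gamma_pulse(
                td, t_on, p.time_to_peak, p.shape_alpha)
        return p.baseline_flow + (p.peak_flow - p.baseline_flow) * g

    return q


def make_flow_waveform(params: WaveformParams, time_axis: np.ndarray) -> np.ndarray:
    """Evaluate the flow template on ``time_axis`` (s, within one period)."""
    t = np.asarray(time_axis, float)
    if t.min() < 0.0 or t.max() > params.cardiac_period:
        raise InvalidArgumentError("time_axis must lie within one cardiac period")
    return waveform_function(params)(t)


@dataclass(frozen=True)
class FlowCurveSet:
    """Time-resolved flow-rate curves (mL/s) at ordered planes along the
    centerline.  ``effective_dt`` records the acquisition temporal
    resolution the curves carry (before any phase reconstruction)."""

    time_axis: np.ndarray           # (n_t,) s, uniform over one cycle
    plane_arc_lengths: np.ndarray   # (n_p,) mm, strictly increasing
    flow: np.ndarray                # (n_p, n_t) mL/s
    effective_dt: float             # s

    def __post_init__(self) -> None:
        t = np.asarray(self.time_axis, float)
        if t.size < 2:
            raise InvalidArgumentError("time_axis needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise InvalidArgumentError("time_axis must be uniform and increasing")
        arcs = np.asarray(self.plane_arc_lengths, float)
        if np.any(np.diff(arcs) <= 0):
            raise InvalidArgumentError("plane_arc_lengths must be strictly increasing")
        if self.flow.shape != (arcs.size, t.size):
            raise InvalidArgumentError(
                f"flow shape {self.flow.shape} does not match "
                f"({arcs.size} planes, {t.size} samples)")

    @property
    def n_planes(self) -> int:
        return self.flow.shape[0]

    @property
    def dt(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])

    @property
    def period(self) -> float:
        return float(self.time_axis.size * self.dt)


def propagate_waveform(waveform_fn, centerline: AorticCenterline,
                       n_planes: int, true_pwv: float, damping: float = 0.0,
                       *, period: float = 1.0, dt_dense: float = 0.001,
                       extent: tuple[float, float] = (0.0, 1.0)) -> FlowCurveSet:
    """Propagate a flow waveform along the centerline at a known PWV.

    Plane ``i`` at arc length ``d_i`` carries
    ``Q_i(t) = (1 - damping)^{d_i} * Q(t - d_i / PWV)`` evaluated on a dense
    uniform grid (``dt_dense`` <= 1 ms); delays wrap periodically within the
    cardiac cycle.

    Parameters
    ----------
    waveform_fn : callable
        Periodic flow template Q(t), e.g. from :func:`waveform_function`.
    n_planes : int
        Number of analysis planes, uniformly spaced in arc length over
        ``extent`` (fractions of total centerline length).  Protocols vary
        in whether planes stop at the diaphragm or extend to the coeliac
        trunk, so the extent is exposed; default is the full curve.
    true_pwv : float
        Ground-truth pulse wave velocity in m/s, within [2, 30].
    damping : float
        Per-mm fractional amplitude loss.
    """
    if not 2.0 <= true_pwv <= 30.0:
        raise InvalidArgumentError(f"true_pwv {true_pwv} m/s outside [2, 30]")
    if n_planes < 2:
        raise InvalidArgumentError("need at least 2 planes")
    if dt_dense > 0.001:
        raise InvalidArgumentError("dt_dense must be <= 1 ms")
    f0, f1 = extent
    if not 0.0 <= f0 < f1 <= 1.0:
        raise InvalidArgumentError("extent fractions must satisfy 0 <= f0 < f1 <= 1")

    n_t = int(round(period / dt_dense))
    t = np.arange(n_t) * period / n_t
    arcs = np.linspace(f0, f1, n_planes) * centerline.total_length
    flow = np.empty((n_planes, n_t))
    for i, d in enumerate(arcs):
        delay = (d / 1000.0) / true_pwv
        flow[i] = (1.0 - damping) ** d * waveform_fn(t - delay)
    return FlowCurveSet(time_axis=t, plane_arc_lengths=arcs, flow=flow,
                        effective_dt=period / n_t)


def sample_and_noise(curves: FlowCurveSet, effective_dt: float = 0.034,
                     n_phases: int = 50, snr_db: float = np.inf,
                     seed: int = 0) -> FlowCurveSet:
    """Emulate MRI temporal sampling and noise.

    Dense curves are sampled on the acquisition grid (``effective_dt``),
    linearly interpolated to ``n_phases`` uniform cardiac phases (view-
    sharing emulation: only the information loss of the coarse acquisition
    matters), then zero-mean Gaussian noise is added per plane with variance
    ``var(noise-free phase curve) / 10^(snr_db/10)``.
    """
    if effective_dt <= 0:
        raise InvalidArgumentError("effective_dt must be > 0")
    if n_phases < 8:
        raise InvalidArgumentError("n_phases must be >= 8")
    if np.isnan(snr_db):
        raise InvalidArgumentError("snr_db must not be NaN")

    period = curves.period
    t_acq = np.arange(0.0, period, effective_dt)
    t_ph = np.arange(n_phases) * period / n_phases
    rng = default_rng(seed)
    out = np.empty((curves.n_planes, n_phases))
    for i, row in enumerate(curves.flow):
        acq = np.interp(t_acq, curves.time_axis, row, period=period)
        tw = np.concatenate([t_acq, [t_acq[0] + period]])
        vw = np.concatenate([acq, [acq[0]]])
        clean = np.interp(t_ph, tw, vw)
        if np.isfinite(snr_db):
            sigma = math.sqrt(float(np.var(clean)) / 10.0 ** (snr_db / 10.0))
            clean = clean + rng.normal(0.0, sigma, n_phases)
        out[i] = clean
    return FlowCurveSet(time_axis=t_ph, plane_arc_lengths=curves.plane_arc_lengths,
                        flow=out, effective_dt=effective_dt)


# ---------------------------------------------------------------------------
# areas and pressures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AreaCurveSet:
    """Systolic (Amax) and diastolic (Amin) lumen areas (mm^2) at one site."""

    site: str   # "ascending" | "descending"
    amax: float
    amin: float

    def __post_init__(self) -> None:
        if self.site not in ("ascending", "descending"):
            raise InvalidArgumentError(f"unknown site {self.site!r}")
        if not self.amax >= self.amin > 0:
            raise InvalidArgumentError("need Amax >= Amin > 0")


@dataclass(frozen=True)
class PressureRecord:
    """Central systolic/diastolic pressures (mmHg); PP = SBP - DBP exactly."""

    central_sbp: float
    central_dbp: float

    def __post_init__(self) -> None:
        if not self.central_sbp > self.central_dbp > 0:
            raise InvalidArgumentError("need SBP > DBP > 0")

    @property
    def pp(self) -> float:
        return self.central_sbp - self.central_dbp


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth of one simulated subject.

    ``true_pwv`` is the propagation speed used when waveforms are simulated
    (it equals the drawn 4D PWV value); ``drawn`` holds the copula-coupled
    draws of all four stiffness measures, which double as the subject's
    measured panel in direct-draw (mode A) simulation.
    """

    subject_id: str
    group: str                      # "CAD" | "control"
    true_pwv: float                 # m/s
    true_distensibility: float      # 10^-3 mmHg^-1
    true_cf_pwv: float              # m/s
    pressure: PressureRecord
    heart_rate: float               # bpm
    drawn: dict[str, float] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("CAD", "control"):
            raise InvalidArgumentError(f"unknown group {self.group!r}")
        for v in (self.true_pwv, self.true_distensibility, self.true_cf_pwv):
            if not v > 0:
                raise InvalidArgumentError("stiffness values must be > 0")
        if self.group == "control" and self.covariates.get("infarcted_segments", 0):
            raise InvalidArgumentError("controls must have 0 infarcted segments")


def make_area_and_pressure(subject: SubjectTruth, amin_aa: float = 970.0,
                           amin_da: float = 560.0
                           ) -> tuple[AreaCurveSet, AreaCurveSet, PressureRecord]:
    """Generate lumen areas consistent with the subject's distensibility.

    Inverts D = dA/(Amin*PP): per site, ``dA = D * Amin * PP`` and
    ``Amax = Amin + dA`` with D the subject's true distensibility (shared by
    both sites), so the analysis-side distensibility recovers it exactly.
    Default diastolic areas correspond to typical ascending (~35 mm) and
    descending (~27 mm) aortic diameters.
    """
    if not (amin_aa > 0 and amin_da > 0):
        raise InvalidArgumentError("Amin values must be > 0")
    d = subject.true_distensibility * 1e-3   # mmHg^-1
    pp = subject.pressure.pp
    aa = AreaCurveSet("ascending", amin_aa + d * amin_aa * pp, amin_aa)
    da = AreaCurveSet("descending", amin_da + d * amin_da * pp, amin_da)
    return aa, da, subject.pressure


# ---------------------------------------------------------------------------
# cohort model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalMarginal:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise InvalidArgumentError("marginal SD must be > 0")

    def ppf(self, u):
        return self.mean + self.sd * ndtri(u)


@dataclass(frozen=True)
class LogNormalMarginal:
    """Log-normal marginal parameterized on the log scale; built from a
    printed median [IQR] summary via exact quantile matching of median and
    inter-quartile width."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidArgumentError("marginal sigma must be > 0")

    @classmethod
    def from_median_iqr(cls, median: float, q25: float, q75: float) -> "LogNormalMarginal":
        if not (0 < q25 < median < q75):
            raise InvalidArgumentError("need 0 < q25 < median < q75")
        sigma = math.asinh((q75 - q25) / (2.0 * median)) / _NORM_Q75
        return cls(mu=math.log(median), sigma=sigma)

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def ppf(self, u):
        return np.exp(self.mu + self.sigma * ndtri(u))


@dataclass
class CohortSpec:
    """Generative model of the two-group case-control cohort.

    ``marginals[group][measure]`` gives the marginal law of each stiffness
    measure (normal for the three PWVs, log-normal for distensibility);
    ``copula`` is the shared within-group Gaussian-copula correlation matrix
    in :data:`MEASURES` order.  ``aux[group]`` holds marginals of pressures,
    heart rate and covariates.
    """

    marginals: dict[str, dict[str, NormalMarginal | LogNormalMarginal]]
    copula: np.ndarray
    n_cad: int = 35
    n_control: int = 18
    aux: dict[str, dict[str, NormalMarginal | LogNormalMarginal]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        self.copula = np.asarray(self.copula, float)
        if self.n_cad < 2 or self.n_control < 2:
            raise InvalidArgumentError("group sizes must be >= 2")
        _validate_copula(self.copula, len(MEASURES))

    @property
    def n_total(self) -> int:
        return self.n_cad + self.n_control

    @property
    def proportion_patients(self) -> float:
        return self.n_cad / self.n_total


def _validate_copula(m: np.ndarray, k: int) -> None:
    if m.shape != (k, k):
        raise InvalidArgumentError(f"copula matrix must be {k}x{k}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise InvalidArgumentError("copula matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise InvalidArgumentError("copula matrix must have unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise InvalidArgumentError("copula matrix must be positive semi-definite")


def default_cohort_spec(copula: np.ndarray | None = None,
                        n_cad: int = 35, n_control: int = 18) -> CohortSpec:
    """The case-control study conditions: 35 CAD patients one year after
    myocardial infarction vs. 18 age/sex-matched controls, with the group
    marginal distributions of the four stiffness measures, central
    pressures, heart rate and covariates set to the published summaries."""
    marginals = {
        "CAD": {
            "cf_pwv": NormalMarginal(12.67, 2.86),
            "pwv_2d": NormalMarginal(10.97, 3.43),
            "pwv_4d": NormalMarginal(17.3, 4.04),
            "distensibility": LogNormalMarginal.from_median_iqr(1.71, 1.19, 2.17),
        },
        "control": {
            "cf_pwv": NormalMarginal(9.58, 1.13),
            "pwv_2d": NormalMarginal(8.01, 2.05),
            "pwv_4d": NormalMarginal(8.69, 2.54),
            "distensibility": LogNormalMarginal.from_median_iqr(1.77, 1.46, 2.70),
        },
    }
    aux = {
        "CAD": {
            "sbp": NormalMarginal(118.0, 12.5),
            "dbp": NormalMarginal(81.0, 10.6),
            "heart_rate": NormalMarginal(61.1, 8.8),
            "age": NormalMarginal(64.3, 11.7),
            "lvmi": LogNormalMarginal.from_median_iqr(66.5, 58.1, 78.9),
        },
        "control": {
            "sbp": NormalMarginal(116.0, 9.7),
            "dbp": NormalMarginal(82.9, 7.2),
            "heart_rate": NormalMarginal(67.3, 7.1),
            "age": NormalMarginal(62.0, 10.1),
            "lvmi": LogNormalMarginal.from_median_iqr(57.8, 52.11, 61.25),
        },
    }
    if copula is None:
        copula = np.eye(len(MEASURES))
    return CohortSpec(marginals=marginals, copula=copula,
                      n_cad=n_cad, n_control=n_control, aux=aux)


def _ppf_u(marginal, rng) -> float:
    u = min(max(rng.uniform(), 1e-12), 1.0 - 1e-12)
    return float(marginal.ppf(u))


def _draw_subject(rng, spec: CohortSpec, group: str, chol: np.ndarray,
                  subject_id: str) -> SubjectTruth:
    z = chol @ rng.standard_normal(len(MEASURES))
    u = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)
    drawn = {m: float(spec.marginals[group][m].ppf(ui))
             for m, ui in zip(MEASURES, u)}
    # PWVs are normal draws and can stray non-positive in principle; clamp
    # to a small physiological floor rather than rejecting the subject.
    for m in ("cf_pwv", "pwv_2d", "pwv_4d"):
        drawn[m] = max(drawn[m], 0.5)

    aux = spec.aux.get(group, {})
    sbp = dbp = 0.0
    for _ in range(100):
        sbp = _ppf_u(aux["sbp"], rng) if "sbp" in aux else 118.0
        dbp = _ppf_u(aux["dbp"], rng) if "dbp" in aux else 80.0
        if sbp - dbp >= 5.0 and dbp > 0:
            break
    else:
        dbp = max(sbp - 5.0, 1.0)
    hr = float(np.clip(_ppf_u(aux["heart_rate"], rng), 40.0, 120.0)) \
        if "heart_rate" in aux else 60.0

    cov: dict[str, float] = {}
    if "age" in aux:
        cov["age"] = float(np.clip(_ppf_u(aux["age"], rng), 30.0, 95.0))
    if "lvmi" in aux:
        cov["lvmi"] = _ppf_u(aux["lvmi"], rng)
    cov["infarcted_segments"] = (
        float(np.clip(round(rng.normal(3.0, 1.5)), 1, 17)) if group == "CAD" else 0.0)

    return SubjectTruth(
        subject_id=subject_id, group=group,
        true_pwv=drawn["pwv_4d"],
        true_distensibility=drawn["distensibility"],
        true_cf_pwv=drawn["cf_pwv"],
        pressure=PressureRecord(sbp, dbp),
        heart_rate=hr, drawn=drawn, covariates=cov)


def draw_cohort(spec: CohortSpec, seed: int = 0) -> list[SubjectTruth]:
    """Draw a full cohort: ``n_cad`` patients then ``n_control`` controls,
    each from its own child random stream of the root seed, with the four
    stiffness measures coupled by the within-group Gaussian copula and
    mapped through the group marginals."""
    _validate_copula(spec.copula, len(MEASURES))
    chol = np.linalg.cholesky(_nearest_psd(spec.copula) + 1e-12 * np.eye(len(MEASURES)))
    children = SeedSequence(seed).spawn(spec.n_total)
    subjects = []
    for i in range(spec.n_total):
        group = "CAD" if i < spec.n_cad else "control"
        rng = default_rng(children[i])
        subjects.append(_draw_subject(rng, spec, group, chol, f"s{i + 1:03d}"))
    return subjects


def _nearest_psd(m: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation-like PSD matrix
    (eigenvalue clipping followed by diagonal renormalization)."""
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    if w.min() >= eps:
        return m
    w = np.clip(w, eps, None)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    return r / np.outer(d, d)


def _pooled_spearman_mc(r: float, zbase: np.ndarray, n_cad: int,
                        marg_cad, marg_ctl) -> float:
    """Pooled (mixed-group) Spearman correlation of one measure pair for a
    within-group copula correlation ``r``, using common random numbers."""
    z1 = zbase[:, 0]
    z2 = r * zbase[:, 0] + math.sqrt(max(1.0 - r * r, 0.0)) * zbase[:, 1]
    u1 = np.clip(ndtr(z1), 1e-12, 1 - 1e-12)
    u2 = np.clip(ndtr(z2), 1e-12, 1 - 1e-12)
    x = np.empty_like(u1)
    y = np.empty_like(u2)
    x[:n_cad] = marg_cad[0].ppf(u1[:n_cad])
    y[:n_cad] = marg_cad[1].ppf(u2[:n_cad])
    x[n_cad:] = marg_ctl[0].ppf(u1[n_cad:])
    y[n_cad:] = marg_ctl[1].ppf(u2[n_cad:])
    return float(spearmanr(x, y).statistic)


def calibrate_copula(spec: CohortSpec,
                     targets: dict[tuple[str, str], float] | None = None,
                     n_mc: int = 20000, tol: float = 0.01,
                     seed: int = 0) -> np.ndarray:
    """Find the within-group copula matrix whose pooled-cohort Spearman
    correlations match the published mixed-group values.

    For each targeted measure pair, a scalar within-group copula correlation
    is found by monotone bisection so that the Monte-Carlo pooled (both
    groups mixed in case:control proportion) Spearman correlation lies
    within ``tol`` of the target; common random numbers make the objective
    a deterministic monotone function of the copula parameter.  Pairs
    without a target stay at 0; the assembled matrix is projected to the
    nearest PSD correlation matrix if needed.
    """
    if targets is None:
        targets = POOLED_SPEARMAN_TARGETS
    if n_mc < 10_000:
        raise InvalidArgumentError("n_mc must be >= 10000")
    for pair, t in targets.items():
        if not -1.0 < t < 1.0:
            raise InvalidArgumentError(f"target for {pair} must be in (-1, 1)")

    n_cad_mc = int(round(n_mc * spec.proportion_patients))
    out = np.eye(len(MEASURES))
    children = SeedSequence(seed).spawn(len(targets))
    for child, ((ma, mb), target) in zip(children, sorted(targets.items())):
        ia, ib = MEASURES.index(ma), MEASURES.index(mb)
        zbase = default_rng(child).standard_normal((n_mc, 2))
        marg_cad = (spec.marginals["CAD"][ma], spec.marginals["CAD"][mb])
        marg_ctl = (spec.marginals["control"][ma], spec.marginals["control"][mb])

        def f(r):
            return _pooled_spearman_mc(r, zbase, n_cad_mc, marg_cad, marg_ctl)

        lo, hi = -0.999, 0.999
        flo, fhi = f(lo), f(hi)
        if not flo - tol <= target <= fhi + tol:
            raise CalibrationError(
                f"pooled Spearman target {target:+.3f} for ({ma}, {mb}) is "
                f"unreachable; attainable range [{flo:+.3f}, {fhi:+.3f}]",
                attainable=(flo, fhi))
        r = 0.0
        for _ in range(40):
            r = 0.5 * (lo + hi)
            fr = f(r)
            if abs(fr - target) <= tol and hi - lo < 0.05:
                break
            if fr < target:
                lo = r
            else:
                hi = r
            if hi - lo < 1e-4:
                break
        out[ia, ib] = out[ib, ia] = r
    return _nearest_psd(out)


# ---------------------------------------------------------------------------
# per-subject waveform simulation (mode B)
# ---------------------------------------------------------------------------

def simulate_subject_flow(subject: SubjectTruth,
                          centerline: AorticCenterline | None = None,
                          n_planes: int = 40, effective_dt: float = 0.034,
                          n_phases: int = 50, snr_db: float = 20.0,
                          damping: float = 3e-4, seed: int = 0,
                          waveform_params: WaveformParams | None = None
                          ) -> FlowCurveSet:
    """Full forward model for one subject: propagate the flow template along
    the centerline at the subject's true PWV, then apply MRI-like sampling
    and noise.  The cardiac period follows the subject's heart rate."""
    if centerline is None:
        centerline = make_centerline(seed=seed)
    period = 60.0 / subject.heart_rate
    if waveform_params is None:
        waveform_params = WaveformParams(cardiac_period=period,
                                         time_to_peak=0.15 * period / 1.0,
                                         upslope_duration=0.10 * period / 1.0)
    else:
        waveform_params = replace(waveform_params, cardiac_period=period)
    fn = waveform_function(waveform_params)
    dense = propagate_waveform(fn, centerline, n_planes,
                               np.clip(subject.true_pwv, 2.0, 30.0),
                               damping=damping, period=period)
    return sample_and_noise(dense, effective_dt=effective_dt,
                            n_phases=n_phases, snr_db=snr_db, seed=seed)
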