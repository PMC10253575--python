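import numpy as np
import pytest

from aortastiff.synthetic import WaveformParams, waveform_function


@pytest.fixture(scope="session")
def waveform_params() -> WaveformParams:
    return WaveformParams()


@pytest.fixture(scope="session")
def flow_fn(waveform_params):
    return waveform_function(waveform_params)


@pytest.fixture(scope="session")
def dense_time(waveform_params):
    period = waveform_params.cardiac_period
    n = int(round(period / 0.001))
    return np.arange(n) * period / n


def dense_xcorr_delay(qa: np.ndarray, qb: np.ndarray, dt: float) -> float:
    """Independent delay oracle: peak of the circular cross-correlation on
    the (dense) grid, positive when qb lags qa."""
    n = qa.size
    a = qa - qa.mean()
    b = qb - qb.mean()
    r = np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n)
    k = int(np.argmax(r))
    period = n * dt
    return (k * dt + period / 2.0) % period - period / 2.0


def sample_phases(values_dense: np.ndarray, t_dense: np.ndarray,
                  eff_dt: float, n_phases: int, period: float) -> tuple:
    """Acquisition-grid sampling followed by linear phase interpolation,
    mirroring the generator's view-sharing emulation."""
    t_acq = np.arange(0.0, period, eff_dt)
    acq = np.interp(t_acq, t_dense, values_dense, period=period)
    t_ph = np.arange(n_phases) * period / n_phases
    tw = np.concatenate([t_acq, [t_acq[0] + period]])
    vw = np.concatenate([acq, [acq[0]]])
    return t_ph, np.interp(t_ph, tw, vw)
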