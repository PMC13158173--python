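"""Plane-wave beamforming: Stolt f-k migration and a delay-and-sum oracle.

For a single zero-angle plane-wave transmit, the two-way travel time to a
scatterer at (x0, z0) is ``(z0 + sqrt((x - x0)^2 + z0^2)) / c``.  In the
2-D Fourier domain this maps the data spectrum D(kx, f) onto the image
spectrum M(kx, kz) through the Stolt change of variables

    f(kx, kz) = c (kz^2 + kx^2) / (2 kz),      |kx| <= kz,

(with kx, kz in cycles/cm and f in MHz when c is in cm/us), so migration
reduces to a resampling of the temporal-frequency axis per lateral
wavenumber, scaled by the Jacobian (c/2)(1 - kx^2/kz^2).  The output depth
axis is z = c t / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rf_simulator import ChannelData, ProbeGeometry, _spectral_interp
from .units import sound_speed_cm_per_us


@dataclass
class BeamformedImage:
    """Beamformed RF on an (x, z) grid, one line per element position."""

    s: np.ndarray  # (n_lines, n_z) beamformed RF amplitude
    x_axis_cm: np.ndarray
    z_axis_cm: np.ndarray
    sound_speed_m_s: float
    probe: ProbeGeometry
    meta: dict | None = None

    def __post_init__(self) -> None:
        if self.s.shape != (self.x_axis_cm.size, self.z_axis_cm.size):
            raise ValueError("s must be shaped (n_lines, n_z)")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("beamformed image must be finite")

    @property
    def dz_cm(self) -> float:
        return float(self.z_axis_cm[1] - self.z_axis_cm[0])


def _validate(data: ChannelData, sound_speed_m_s: float) -> None:
    if sound_speed_m_s <= 0:
        raise ValueError("sound_speed must be > 0")
    dt = np.diff(data.time_axis_us)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("non-uniform time axis")


def fk_migrate(
    data: ChannelData,
    sound_speed_m_s: float = 1540.0,
    edge_taper_elements: int = 0,
) -> BeamformedImage:
    """Migrate zero-angle plane-wave channel data with Stolt's f-k method.

    Linear in the input; a point scatterer maps to a focal spot centered
    at its true location.  Time is zero-padded (factor 8, to keep the
    spectral resampling accurate) and the aperture is symmetrically
    zero-padded to the next power of two before the 2-D FFT; the f -> kz
    resampling uses cubic interpolation of the phase-demodulated spectrum.
    ``edge_taper_elements`` optionally cosine-tapers the outermost aperture
    columns (a depth-independent per-column gain, so intensity-decay
    estimates are unaffected); the default keeps the full aperture.
    """
    _validate(data, sound_speed_m_s)
    c = sound_speed_cm_per_us(sound_speed_m_s)
    probe = data.probe
    n_e, n_t = data.rf.shape
    dt = probe.dt_us
    pitch = probe.pitch_cm

    nt2 = int(2 ** np.ceil(np.log2(8 * n_t)))
    nx2 = int(2 ** np.ceil(np.log2(2 * n_e)))
    x_off = (nx2 - n_e) // 2

    apod = np.ones(n_e)
    m = int(edge_taper_elements)
    if m > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(m) + 1) / (m + 1)))
        apod[:m] = ramp
        apod[-m:] = ramp[::-1]

    padded = np.zeros((nx2, nt2))
    padded[x_off : x_off + n_e, :n_t] = data.rf * apod[:, None]

    # forward transforms: time then lateral
    D = np.fft.rfft(padded, axis=1)  # (nx2, nf) positive temporal freqs
    freqs = np.fft.rfftfreq(nt2, dt)  # MHz
    t0 = float(data.time_axis_us[0])
    # demodulate the bulk (record-center) phase so the spectrum varies
    # slowly across frequency bins; the exact phase is restored at the
    # interpolated frequencies (controls Stolt interpolation loss)
    t_c = n_t * dt / 2.0
    D *= np.exp(-2j * np.pi * freqs * (t0 - t_c))[None, :]
    D = np.fft.fft(D, axis=0)  # over elements -> kx
    kx = np.fft.fftfreq(nx2, pitch)  # cycles/cm

    # output depth grid mirrors the (padded) time grid via z = c t / 2
    dz = c * dt / 2.0
    n_kz_half = nt2 // 2 + 1
    kz = np.arange(n_kz_half) / (nt2 * dz)  # cycles/cm, kz >= 0

    M = np.zeros((nx2, n_kz_half), dtype=complex)
    f_max = freqs[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        for ix in range(nx2):
            kxi = kx[ix]
            f_map = c * (kz**2 + kxi**2) / (2.0 * kz)
            valid = (kz > np.abs(kxi)) & (f_map <= f_max)
            if not np.any(valid):
                continue
            fm = f_map[valid]
            vals = _spectral_interp(fm, freqs, D[ix])
            jac = (c / 2.0) * (1.0 - kxi**2 / kz[valid] ** 2)
            M[ix, valid] = vals * jac * np.exp(-2j * np.pi * fm * t_c)

    # inverse transforms: kx, then the real-signal half-spectrum trick in kz
    N = np.fft.ifft(M, axis=0)
    full = np.zeros((nx2, nt2), dtype=complex)
    full[:, :n_kz_half] = N
    full[:, 0] *= 0.5
    if nt2 % 2 == 0:
        full[:, n_kz_half - 1] *= 0.5
    img = 2.0 * np.real(np.fft.ifft(full, axis=1)) * nt2 / (nt2 * dz)

    s = img[x_off : x_off + n_e, :n_t]
    z_axis = c * data.time_axis_us / 2.0
    return BeamformedImage(
        s=np.ascontiguousarray(s),
        x_axis_cm=probe.element_positions_cm(),
        z_axis_cm=z_axis,
        sound_speed_m_s=sound_speed_m_s,
        probe=probe,
        meta={"method": "fk"},
    )


def das_beamform(
    data: ChannelData,
    sound_speed_m_s: float = 1540.0,
    f_number: float = 1.0,
) -> BeamformedImage:
    """Delay-and-sum beamformer for a zero-angle plane-wave transmit.

    Serves as an independent oracle for validating the f-k migration on
    point-scatterer scenes.  Receive aperture is limited by ``f_number``.
    """
    _validate(data, sound_speed_m_s)
    c = sound_speed_cm_per_us(sound_speed_m_s)
    probe = data.probe
    elem_x = probe.element_positions_cm()
    t = data.time_axis_us
    z_axis = c * t / 2.0
    n_lines = probe.n_elements
    s = np.zeros((n_lines, z_axis.size))
    zpos = np.maximum(z_axis, 1e-6)
    for ie in range(probe.n_elements):
        trace = data.rf[ie]
        dx = np.abs(elem_x[:, None] - elem_x[ie])  # (n_lines, 1)
        tau = (zpos[None, :] + np.hypot(dx, zpos[None, :])) / c
        contrib = np.interp(tau, t, trace, left=0.0, right=0.0)
        apod = dx <= zpos[None, :] / (2.0 * f_number)
        s += contrib * apod
    return BeamformedImage(
        s=s,
        x_axis_cm=elem_x,
        z_axis_cm=z_axis,
        sound_speed_m_s=sound_speed_m_s,
        probe=probe,
        meta={"method": "das"},
    )


def backscattered_intensity(image: BeamformedImage) -> np.ndarray:
    """Backscattered intensity: elementwise square of the beamformed RF."""
    return image.s**2
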