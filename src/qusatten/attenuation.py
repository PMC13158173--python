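"""Attenuation-coefficient estimation from beamformed plane-wave data.

Three estimators of the local attenuation slope alpha0 (Np/(cm.MHz)) are
implemented:

* **PWI** (reference-free): under the plane-wave model the ensemble
  backscattered intensity decays as ``I_r(z, f) = A^2 exp(-4 alpha(f) z)``,
  so ``alpha = -(1/4) d ln I_r / dz`` and, with frequency-linear
  attenuation, ``alpha0 = alpha / f``.  The broadband time-domain signal
  mixes frequencies: its log-intensity slope tracks ``-4 alpha0 fbar(z)``
  where ``fbar`` is the local spectral centroid, which downshifts with
  depth.  :func:`map_local_ac` therefore normalizes each window's slope by
  the centroid measured in that window (when ``f_eff`` is not forced),
  while :func:`estimate_ac_pwi` keeps the plain fixed-frequency contract.
* **SDM** (spectral difference): depth-slope of the log ratio of sample
  to reference power spectra, per frequency, offset by the known
  reference attenuation.
* **SLDM** (spectral log difference): the two-window version of SDM using
  only a proximal and a distal window.

All three are invariant to an overall gain of the RF data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .beamforming import BeamformedImage, backscattered_intensity
from .stats import GroupSummary

DEFAULT_DEPTH_RANGE_CM = (2.0, 5.7)  # near-field floor 2 cm; max usable 6.5 cm
MAX_DEPTH_CM = 6.5


@dataclass
class PWIEstimate:
    """Global plane-wave attenuation estimate with fit diagnostics."""

    alpha0: float  # Np/(cm.MHz)
    alpha_np_cm: float  # attenuation at f_eff, Np/cm
    f_eff_mhz: float
    slope: float  # d ln I / dz, Np-equivalent per cm
    r_squared: float
    n_samples: int


@dataclass
class ACMap:
    """Gridded local attenuation-slope estimates with window metadata."""

    alpha0: np.ndarray  # (n_x_windows, n_z_windows), Np/(cm.MHz)
    x_centers_cm: np.ndarray
    z_centers_cm: np.ndarray
    pixel_size_lambda: float
    overlap: float
    depth_range_cm: tuple[float, float]
    fit_r2: np.ndarray

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")


@dataclass
class SpectralEstimate:
    """Power spectral density of backscatter vs depth window."""

    S: np.ndarray  # (n_freqs, n_windows), >= 0
    freqs_mhz: np.ndarray
    window_centers_cm: np.ndarray
    band_mhz: tuple[float, float]

    def __post_init__(self) -> None:
        if np.any(self.S < 0):
            raise ValueError("power spectral density must be >= 0")


@dataclass
class ReferenceMedium:
    """Calibrated reference: known attenuation slope and matched sound speed."""

    alpha0_ref: float  # Np/(cm.MHz), frequency-linear law alpha_ref(f) = alpha0_ref * f
    spectra: SpectralEstimate
    sound_speed_m_s: float = 1540.0

    def check_sound_speed(self, sample_c_m_s: float) -> None:
        if abs(self.sound_speed_m_s - sample_c_m_s) > 0.01 * sample_c_m_s:
            raise ValueError(
                "reference sound speed must be within 1% of the sample's"
            )


@dataclass
class AlphaCurve:
    """Attenuation versus frequency, Np/cm."""

    freqs_mhz: np.ndarray
    alpha_np_cm: np.ndarray
    method: str = ""
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PWI
# ---------------------------------------------------------------------------


def estimate_ac_pwi(
    intensity: np.ndarray,
    z_axis_cm: np.ndarray,
    depth_range_cm: tuple[float, float] = DEFAULT_DEPTH_RANGE_CM,
    f_eff_mhz: float = 5.2,
    floor: float = 0.0,
) -> PWIEstimate:
    """Reference-free attenuation slope from an intensity-depth profile.

    Ordinary least squares of ``ln I_r`` on z over ``depth_range_cm``;
    the slope divided by -4 gives the attenuation in Np/cm at ``f_eff_mhz``
    and dividing by ``f_eff_mhz`` gives alpha0 in Np/(cm.MHz).  A 2-D
    intensity grid (lines x depth) is averaged laterally first.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim == 2:
        intensity = intensity.mean(axis=0)
    z_axis_cm = np.asarray(z_axis_cm, dtype=float)
    if intensity.shape != z_axis_cm.shape:
        raise ValueError("intensity and z_axis must align")
    z_lo, z_hi = depth_range_cm
    if z_lo < 0 or z_hi <= z_lo:
        raise ValueError("invalid depth range")
    sel = (z_axis_cm >= z_lo) & (z_axis_cm <= z_hi)
    if sel.sum() < 10:
        raise ValueError("fewer than 10 depth samples in range")
    z = z_axis_cm[sel]
    I = intensity[sel] + floor
    if np.any(I <= 0):
        raise ValueError(
            "nonpositive intensity in range: log undefined; pass a small "
            "positive `floor` (noise floor epsilon) to regularize"
        )
    lnI = np.log(I)
    slope, _intercept, r2 = _ols_line(z, lnI)
    alpha = -slope / 4.0
    return PWIEstimate(
        alpha0=alpha / f_eff_mhz,
        alpha_np_cm=alpha,
        f_eff_mhz=f_eff_mhz,
        slope=slope,
        r_squared=r2,
        n_samples=int(sel.sum()),
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xm = x.mean()
    ym = y.mean()
    dx = x - xm
    sxx = np.dot(dx, dx)
    slope = np.dot(dx, y - ym) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sst = np.dot(y - ym, y - ym)
    r2 = 1.0 - np.dot(resid, resid) / sst if sst > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def map_local_ac(
    image: BeamformedImage,
    pixel_size_lambda: float = 17.0,
    overlap: float = 0.95,
    f_eff_mhz: float | None = None,
    depth_range_cm: tuple[float, float] = DEFAULT_DEPTH_RANGE_CM,
    band_mhz: tuple[float, float] | None = None,
    r2_flag_threshold: float = 0.0,
    centroid_scope: str = "window",
) -> ACMap:
    """Local attenuation-slope map by windowed exponential regression.

    Square windows of side ``pixel_size_lambda`` wavelengths slide with
    the given ``overlap`` in both directions over ``depth_range_cm``.
    Within each window the intensity is averaged laterally (reducing the
    speckle log-bias), log-transformed, and regressed linearly on depth.
    With ``f_eff_mhz=None`` (default) each window's slope is divided by
    -4 times the spectral centroid measured in that window, which removes
    the depth-downshift bias of broadband data; passing a frequency fixes
    the normalization instead.  ``centroid_scope`` controls the centroid's
    footprint: ``"window"`` (default) measures it per window, which tracks
    lateral attenuation heterogeneity; ``"profile"`` pools it laterally per
    depth, which suppresses centroid-estimation noise and suits media known
    to be laterally uniform.  Windows with fit R^2 below
    ``r2_flag_threshold`` are set to NaN (flagged, excluded from ROI
    averages) rather than silently dropped.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    probe = image.probe
    lam = probe.wavelength_cm(image.sound_speed_m_s)
    pixel_cm = pixel_size_lambda * lam
    if pixel_cm < 2 * probe.pulse_length_cm(image.sound_speed_m_s):
        raise ValueError("pixel_size smaller than 2 pulse lengths: slope unidentifiable")

    dz = image.dz_cm
    pitch = probe.pitch_cm
    w_z = max(int(round(pixel_cm / dz)), 4)
    w_x = max(int(round(pixel_cm / pitch)), 1)
    hop_z = max(int(round(w_z * (1 - overlap))), 1)
    hop_x = max(int(round(w_x * (1 - overlap))), 1)

    z_lo, z_hi = depth_range_cm
    zsel = np.nonzero((image.z_axis_cm >= z_lo) & (image.z_axis_cm <= z_hi))[0]
    if zsel.size < w_z:
        raise ValueError("image not deep enough for one window beyond the near field")
    i0, i1 = zsel[0], zsel[-1] + 1

    s = image.s[:, i0:i1]
    z = image.z_axis_cm[i0:i1]
    n_x = s.shape[0]
    if n_x < w_x:
        raise ValueError("image narrower than one lateral window")

    intensity = s**2
    x_starts = np.arange(0, n_x - w_x + 1, hop_x)
    z_starts = np.arange(0, z.size - w_z + 1, hop_z)
    x_centers = image.x_axis_cm[x_starts + w_x // 2]
    z_centers = z[z_starts + w_z // 2]

    # lateral average per window start (cumulative-sum trick)
    csum = np.concatenate([np.zeros((1, z.size)), np.cumsum(intensity, axis=0)])
    lat = (csum[x_starts + w_x] - csum[x_starts]) / w_x  # (n_xw, n_z)
    eps = np.finfo(float).tiny
    lnI = np.log(lat + eps)

    # sliding-window OLS slope and R^2 along depth
    zw = z[:w_z]
    dzw = zw - zw.mean()
    sxx = np.dot(dzw, dzw)
    wins = sliding_window_view(lnI, w_z, axis=1)[:, z_starts, :]  # (n_xw, n_zw, w_z)
    slope = wins @ dzw / sxx
    mean = wins.mean(axis=2)
    sst = (wins**2).sum(axis=2) - w_z * mean**2
    ssr = slope**2 * sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssr / sst, 1.0)

    if f_eff_mhz is None:
        fbar = _window_centroids(s, dz, w_z, w_x, x_starts, z_starts,
                                 probe, image.sound_speed_m_s, band_mhz,
                                 scope=centroid_scope)
    else:
        fbar = np.full_like(slope, float(f_eff_mhz))

    alpha0 = -slope / (4.0 * fbar)
    alpha0 = np.where(r2 >= r2_flag_threshold, alpha0, np.nan)
    return ACMap(
        alpha0=alpha0,
        x_centers_cm=x_centers,
        z_centers_cm=z_centers,
        pixel_size_lambda=float(pixel_size_lambda),
        overlap=float(overlap),
        depth_range_cm=tuple(depth_range_cm),
        fit_r2=r2,
    )


def _window_centroids(s, dz, w_z, w_x, x_starts, z_starts, probe, c_m_s, band_mhz,
                      scope="window"):
    """Per-window spectral centroid (MHz) of the beamformed RF.

    Axial spatial frequency nu (cycles/cm) corresponds to temporal
    frequency f = nu * c / 2 through the z = c t / 2 mapping.
    """
    from .units import sound_speed_cm_per_us

    c = sound_speed_cm_per_us(c_m_s)
    if band_mhz is None:
        # cover essentially the whole (downshifted) pulse support: clipping
        # the low-frequency tail inflates the centroid and biases alpha low
        fc = probe.center_frequency_mhz
        band_mhz = (0.2 * fc, 1.85 * fc)
    taper = np.hanning(w_z)
    wins = sliding_window_view(s, w_z, axis=1)[:, z_starts, :]  # (n_x, n_zw, w_z)
    spec = np.fft.rfft(wins * taper, axis=2)
    psd = spec.real**2 + spec.imag**2  # (n_x, n_zw, n_f)
    if scope == "profile":
        # laterally pooled centroid profile, shared by all lateral windows
        psd_lat = np.broadcast_to(psd.sum(axis=0), (x_starts.size,) + psd.shape[1:])
    elif scope == "window":
        csum = np.concatenate([np.zeros((1,) + psd.shape[1:]), np.cumsum(psd, axis=0)])
        psd_lat = csum[x_starts + w_x] - csum[x_starts]  # (n_xw, n_zw, n_f)
    else:
        raise ValueError("centroid_scope must be 'window' or 'profile'")
    f_mhz = np.fft.rfftfreq(w_z, dz) * c / 2.0
    inband = (f_mhz >= band_mhz[0]) & (f_mhz <= band_mhz[1])
    p = psd_lat[:, :, inband]
    f = f_mhz[inband]
    tot = p.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fbar = (p @ f) / tot
    return np.where(tot > 0, fbar, probe.center_frequency_mhz)


# ---------------------------------------------------------------------------
# Spectra and reference-phantom methods
# ---------------------------------------------------------------------------


def power_spectrum_vs_depth(
    image: BeamformedImage,
    window_mm: float = 5.0,
    hop_mm: float | None = None,
    band_mhz: tuple[float, float] = (2.5, 8.0),
    lateral_slice: slice | None = None,
) -> SpectralEstimate:
    """Welch-style depth-resolved power spectral density.

    Hann-tapered periodograms per line and depth window, averaged over the
    lateral lines; the frequency axis is restricted to ``band_mhz``.
    """
    probe = image.probe
    window_cm = window_mm / 10.0
    if window_cm < 4 * probe.pulse_length_cm(image.sound_speed_m_s):
        raise ValueError("window shorter than 4 pulse lengths")
    if hop_mm is None:
        hop_mm = window_mm / 2.0
    dz = image.dz_cm
    w = int(round(window_cm / dz))
    hop = max(int(round(hop_mm / 10.0 / dz)), 1)
    s = image.s if lateral_slice is None else image.s[lateral_slice]
    n_z = s.shape[1]
    if n_z < w:
        raise ValueError("image shallower than one spectral window")
    starts = np.arange(0, n_z - w + 1, hop)
    taper = np.hanning(w)
    wins = sliding_window_view(s, w, axis=1)[:, starts, :]
    spec = np.fft.rfft(wins * taper, axis=2)
    psd = (spec.real**2 + spec.imag**2).mean(axis=0).T  # (n_f, n_windows)
    from .units import sound_speed_cm_per_us

    f_mhz = np.fft.rfftfreq(w, dz) * sound_speed_cm_per_us(image.sound_speed_m_s) / 2.0
    inband = (f_mhz >= band_mhz[0]) & (f_mhz <= band_mhz[1])
    centers = image.z_axis_cm[0] + (starts + w // 2) * dz
    return SpectralEstimate(
        S=psd[inband],
        freqs_mhz=f_mhz[inband],
        window_centers_cm=centers,
        band_mhz=tuple(band_mhz),
    )


def _check_grids(sample: SpectralEstimate, ref: SpectralEstimate) -> None:
    if sample.S.shape != ref.S.shape or not (
        np.allclose(sample.freqs_mhz, ref.freqs_mhz)
        and np.allclose(sample.window_centers_cm, ref.window_centers_cm)
    ):
        raise ValueError("sample and reference must share frequency axis and window grid")


def estimate_ac_sdm(sample: SpectralEstimate, reference: ReferenceMedium) -> AlphaCurve:
    """Spectral difference method: per-frequency attenuation from the
    depth slope of the log spectral ratio, offset by the reference law."""
    ref = reference.spectra
    _check_grids(sample, ref)
    if np.any(ref.S <= 0):
        raise ValueError("reference spectrum has non-positive values in band")
    if np.any(sample.S <= 0):
        raise ValueError("sample spectrum has non-positive values in band")
    ratio = np.log(sample.S / ref.S)  # (n_f, n_w)
    z = sample.window_centers_cm
    dzc = z - z.mean()
    sxx = np.dot(dzc, dzc)
    slopes = ratio @ dzc / sxx  # per frequency
    alpha = reference.alpha0_ref * sample.freqs_mhz - slopes / 4.0
    return AlphaCurve(sample.freqs_mhz, alpha, method="sdm")


def estimate_ac_sldm(
    sample: SpectralEstimate,
    reference: ReferenceMedium,
    z_proximal_cm: float,
    z_distal_cm: float,
) -> AlphaCurve:
    """Spectral log difference method: two-window (proximal/distal)
    variant of SDM."""
    ref = reference.spectra
    _check_grids(sample, ref)
    if z_proximal_cm == z_distal_cm:
        raise ValueError("proximal and distal depths must differ")
    if z_proximal_cm > z_distal_cm:
        raise ValueError("proximal window must be shallower than distal")
    z = sample.window_centers_cm
    tol = np.max(np.diff(z)) / 2 if z.size > 1 else np.inf
    ip = int(np.argmin(np.abs(z - z_proximal_cm)))
    idist = int(np.argmin(np.abs(z - z_distal_cm)))
    if abs(z[ip] - z_proximal_cm) > tol or abs(z[idist] - z_distal_cm) > tol:
        raise ValueError("requested depths are not on the window grid")
    if np.any(ref.S[:, [ip, idist]] <= 0) or np.any(sample.S[:, [ip, idist]] <= 0):
        raise ValueError("non-positive spectrum at the selected windows")
    lr_p = np.log(sample.S[:, ip] / ref.S[:, ip])
    lr_d = np.log(sample.S[:, idist] / ref.S[:, idist])
    alpha = reference.alpha0_ref * sample.freqs_mhz - (lr_d - lr_p) / (
        4.0 * (z[idist] - z[ip])
    )
    return AlphaCurve(sample.freqs_mhz, alpha, method="sldm")


def ac_slope(curve: AlphaCurve, band_mhz: tuple[float, float] | None = None) -> float:
    """Zero-intercept least-squares slope of alpha(f), in Np/(cm.MHz)."""
    f = curve.freqs_mhz
    a = curve.alpha_np_cm
    if band_mhz is not None:
        sel = (f >= band_mhz[0]) & (f <= band_mhz[1])
        f, a = f[sel], a[sel]
    if f.size == 0:
        raise ValueError("empty frequency band")
    return float(np.dot(f, a) / np.dot(f, f))


def roi_average_ac(acmap: ACMap, mask: np.ndarray, label: str = "") -> GroupSummary:
    """Mean / std / n of the local AC values under a binary mask.

    NaN pixels (flagged fits) are excluded; an empty mask is rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != acmap.alpha0.shape:
        raise ValueError("mask must match the AC map grid")
    vals = acmap.alpha0[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty mask (or all pixels flagged)")
    return GroupSummary(mean=float(vals.mean()), std=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                        n=int(vals.size), label=label)
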