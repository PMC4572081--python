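"""Gabor-filter front end: the model's stand-in for V1 simple cells.

A grayscale image is convolved with a bank of 2D Gabor wavelets tuned to
four spatial frequencies spanning four octaves (0.0625-0.5 cycles/pixel),
four orientations (0, 45, 90, 135 degrees) and quadrature phase (even /
odd symmetry).  The signed responses are zero-thresholded, with the
negated negative part kept as a separate anti-phase channel, emulating
ON/OFF simple-cell pairs.  Channel energies are then equalised across
frequency bands to compensate for the 1/f low-frequency bias of natural
images.

The network input volume uses the even (symmetric) kernel of each
frequency/orientation pair, so after rectification the input carries
4 frequencies x 4 orientations x 2 signs = 32 channels.  Odd kernels are
built alongside so the bank forms proper quadrature pairs.

No learning happens at this stage: the receptive fields are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "GaborParams",
    "GaborKernel",
    "FilterResponseVolume",
    "build_filter_bank",
    "apply_filter_bank",
    "rectify_split",
    "normalize_across_scales",
    "image_to_input_volume",
]

#: Default tuning of the bank (four octaves, four orientations).
DEFAULT_FREQUENCIES = (0.5, 0.25, 0.125, 0.0625)
DEFAULT_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class GaborParams:
    """Tuning parameters of the Gabor bank.

    Parameters
    ----------
    frequencies
        Spatial frequencies in cycles/pixel.  Must lie in (0, 0.5]
        (0.5 cycles/pixel is the Nyquist limit).
    orientations
        Filter orientations in degrees (direction of wave propagation is
        normal to the preferred bar orientation).
    aspect_ratio
        Elongation of the Gaussian envelope: the long axis (parallel to
        the excitatory/inhibitory boundaries) is ``aspect_ratio`` times
        the short axis.  Physiological estimates put this at 2:1.
    bandwidth_octaves
        Half-amplitude spatial-frequency bandwidth, in octaves; sets the
        envelope width along the propagation direction.  Simple cells
        show 1-1.5 octaves; we fix 1.5.
    """

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    aspect_ratio: float = 2.0
    bandwidth_octaves: float = 1.5

    def __post_init__(self) -> None:
        if len(self.frequencies) == 0 or len(self.orientations) == 0:
            raise ValueError("frequencies and orientations must be non-empty")
        for f in self.frequencies:
            if not (0.0 < f <= 0.5 + 1e-12):
                raise ValueError(
                    f"unsupported spatial frequency {f}: must be in (0, 0.5] cycles/pixel"
                )
        if self.aspect_ratio <= 0 or self.bandwidth_octaves <= 0:
            raise ValueError("aspect_ratio and bandwidth_octaves must be positive")

    def sigma_along(self, frequency: float) -> float:
        """Envelope sigma along the propagation axis for one frequency.

        Derived from the half-amplitude bandwidth ``b`` (octaves):
        ``sigma = sqrt(ln 2 / 2) / (pi f) * (2^b + 1) / (2^b - 1)``.
        """
        b = 2.0 ** self.bandwidth_octaves
        return np.sqrt(np.log(2.0) / 2.0) / (np.pi * frequency) * (b + 1.0) / (b - 1.0)


@dataclass(frozen=True)
class GaborKernel:
    """One kernel of the bank with its tuning metadata."""

    frequency: float
    orientation: float  # degrees
    phase: str  # "even" | "odd"
    array: np.ndarray = field(repr=False)


@dataclass
class FilterResponseVolume:
    """Rectified multi-channel filter responses (the network input layer).

    ``data`` has shape (n_channels, H, W) and is everywhere >= 0; the
    channel tuple ``(frequency, orientation, sign)`` identifies each
    plane.  For every (frequency, orientation) pair the +1 and -1 sign
    planes have disjoint support (a signed response is either excitatory
    or anti-phase, never both).
    """

    data: np.ndarray
    channels: list[tuple[float, float, int]]  # (frequency, orientation, sign)

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, H, W) matching channel metadata")

    @property
    def grid_dims(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def frequency_band(self, frequency: float) -> np.ndarray:
        """Indices of all channels at one spatial frequency."""
        return np.array(
            [i for i, (f, _, _) in enumerate(self.channels) if f == frequency]
        )

    def save(self, path) -> None:
        np.savez_compressed(
            path, data=self.data, channels=np.array(self.channels, dtype=float)
        )

    @classmethod
    def load(cls, path) -> "FilterResponseVolume":
        with np.load(path) as z:
            chans = [(float(f), float(o), int(s)) for f, o, s in z["channels"]]
            return cls(data=z["data"], channels=chans)


def _gabor_kernel(
    frequency: float, orientation_deg: float, phase: str, params: GaborParams,
    support: int | None,
) -> np.ndarray:
    sigma_x = params.sigma_along(frequency)  # along propagation
    sigma_y = params.aspect_ratio * sigma_x  # along bar (long axis)
    if support is None:
        support = int(np.ceil(3.0 * sigma_y))
    ax = np.arange(-support, support + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    theta = np.deg2rad(orientation_deg)
    # rotate so xr is the propagation axis
    xr = xx * np.cos(theta) + yy * np.sin(theta)
    yr = -xx * np.sin(theta) + yy * np.cos(theta)
    envelope = np.exp(-0.5 * ((xr / sigma_x) ** 2 + (yr / sigma_y) ** 2))
    carrier = 2.0 * np.pi * frequency * xr
    wave = np.cos(carrier) if phase == "even" else np.sin(carrier)
    k = envelope * wave
    # admissible wavelet: exactly zero mean
    k -= k.mean()
    # unit energy so responses are comparable across the bank before the
    # explicit across-scale normalization
    k /= np.linalg.norm(k)
    return k


def build_filter_bank(
    params: GaborParams | None = None, kernel_support: int | None = None
) -> list[GaborKernel]:
    """Construct the quadrature Gabor bank.

    Returns one even and one odd kernel per (frequency, orientation)
    pair, each mean-subtracted to exactly zero and normalised to unit
    energy.  ``kernel_support`` is the half-width in pixels; by default
    3 envelope sigmas of the long axis, which keeps the truncation error
    of the Gaussian below 1e-3 of peak.
    """
    params = params or GaborParams()
    bank: list[GaborKernel] = []
    for f in params.frequencies:
        for o in params.orientations:
            for phase in ("even", "odd"):
                bank.append(
                    GaborKernel(f, o, phase, _gabor_kernel(f, o, phase, params, kernel_support))
                )
    return bank


def apply_filter_bank(image: np.ndarray, bank: list[GaborKernel]) -> np.ndarray:
    """Convolve an image with every kernel of the bank.

    Returns the signed response volume with shape (len(bank), H, W).
    The image is extended by edge replication before convolving, so a
    uniform image yields zero response everywhere including the borders
    (zero padding would introduce a spurious luminance step at the frame
    edge that every image shares).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (grayscale) 2D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    out = np.empty((len(bank), *image.shape))
    for i, kern in enumerate(bank):
        half = kern.array.shape[0] // 2
        padded = np.pad(image, half, mode="edge")
        out[i] = fftconvolve(padded, kern.array, mode="valid")
    return out


def rectify_split(
    signed: np.ndarray, bank: list[GaborKernel]
) -> FilterResponseVolume:
    """Zero-threshold signed responses into positive / anti-phase channels.

    For each signed plane ``r`` the positive channel is ``max(r, 0)`` and
    the anti-phase channel is ``max(-r, 0)``, so ``pos - neg`` recovers
    ``r`` exactly and the two channels never overlap.
    """
    if signed.shape[0] != len(bank):
        raise ValueError("signed volume does not match bank size")
    data = np.empty((2 * len(bank), *signed.shape[1:]))
    channels: list[tuple[float, float, int]] = []
    for i, kern in enumerate(bank):
        data[2 * i] = np.maximum(signed[i], 0.0)
        data[2 * i + 1] = np.maximum(-signed[i], 0.0)
        channels.append((kern.frequency, kern.orientation, +1))
        channels.append((kern.frequency, kern.orientation, -1))
    return FilterResponseVolume(data=data, channels=channels)


def normalize_across_scales(volume: FilterResponseVolume) -> FilterResponseVolume:
    """Equalise response energy across frequency bands for this image.

    The band energy is the sum of squared rectified responses over all
    channels at one frequency; each band is rescaled so its energy
    equals the mean band energy.  All-zero bands are left at zero.
    Compensates for the low-frequency bias of natural images.
    """
    freqs = sorted({f for f, _, _ in volume.channels}, reverse=True)
    data = volume.data.copy()
    energies = np.array(
        [float(np.sum(data[volume.frequency_band(f)] ** 2)) for f in freqs]
    )
    nonzero = energies > 0
    if not np.any(nonzero):
        return FilterResponseVolume(data=data, channels=list(volume.channels))
    target = energies[nonzero].mean()
    for f, e in zip(freqs, energies):
        if e > 0:
            data[volume.frequency_band(f)] *= np.sqrt(target / e)
    return FilterResponseVolume(data=data, channels=list(volume.channels))


def image_to_input_volume(
    image: np.ndarray,
    params: GaborParams | None = None,
    bank: list[GaborKernel] | None = None,
    normalize: bool = True,
) -> FilterResponseVolume:
    """Full front-end pipeline: image -> rectified, scale-normalised volume.

    Uses the even (symmetric) kernel of each frequency/orientation pair,
    giving 4 x 4 x 2(sign) = 32 channels with the default bank.
    """
    if bank is None:
        bank = build_filter_bank(params)
    even = [k for k in bank if k.phase == "even"]
    signed = apply_filter_bank(image, even)
    vol = rectify_split(signed, even)
    if normalize:
        vol = normalize_across_scales(vol)
    return vol
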