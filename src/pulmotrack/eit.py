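"""Global and regional EIT variables, computed per breath from pixel frames.

Global variables are read off the lung-region impedance sum: end-expiratory
lung impedance (EELI, a surrogate for functional residual capacity) at the
start of inspiration and tidal impedance variation (TIV, a surrogate for
tidal volume) as the start-to-end-of-inspiration change.

Regional variables operate on the tidal image (per-pixel inspiratory
impedance change): the center of ventilation (impedance-weighted centroid in
% of the lung-region extent, 0 ventral / right to 100 dorsal / left), silent
spaces (pixels below 10 % of the maximum change, split at the CoV plane into
dependent and non-dependent — the subject is prone, so ventral is
dependent), and the share of ventilation in four equal-width ventro-dorsal
bands.

Negative per-pixel changes (out-of-phase pixels) are clipped to zero before
all regional ventilation measures; TIV itself is defined on the unclipped
global curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EITSequence

__all__ = [
    "TidalImage",
    "EITBreathFeatures",
    "global_signal",
    "breath_landmarks_eit",
    "tiv_eeli",
    "tidal_image",
    "center_of_ventilation",
    "silent_spaces",
    "regional_bands",
    "compute_breath_features",
]


@dataclass
class TidalImage:
    """Per-pixel inspiratory impedance change with the lung-region extent."""

    dz: np.ndarray  # (height, width), AU; meaningful inside mask only
    mask: np.ndarray  # boolean
    ventral_edge: int  # first mask row (most ventral)
    dorsal_edge: int  # last mask row
    right_edge: int  # first mask column (subject's right)
    left_edge: int  # last mask column

    @property
    def dz_clipped(self) -> np.ndarray:
        return np.where(self.mask, np.clip(self.dz, 0.0, None), 0.0)

    def extent_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates in % of the extent (y ventral->dorsal,
        x right->left); a single-row (or -column) extent maps to 50 %."""
        n_rows = self.dorsal_edge - self.ventral_edge + 1
        n_cols = self.left_edge - self.right_edge + 1
        rows = np.arange(self.mask.shape[0])
        cols = np.arange(self.mask.shape[1])
        y = (rows - self.ventral_edge + 0.5) / n_rows * 100.0
        x = (cols - self.right_edge + 0.5) / n_cols * 100.0
        return (
            np.broadcast_to(y[:, None], self.mask.shape),
            np.broadcast_to(x[None, :], self.mask.shape),
        )


@dataclass
class EITBreathFeatures:
    tiv: float  # AU
    eeli: float  # AU
    cov_vd: float  # % (0 ventral ... 100 dorsal)
    cov_rl: float  # % (0 right ... 100 left)
    nss: float  # % of lung pixels
    dss: float  # % of lung pixels
    dz_v: float  # % of total tidal impedance change
    dz_cv: float
    dz_cd: float
    dz_d: float


def global_signal(eit: EITSequence) -> np.ndarray:
    """Per-frame sum of pixel impedance inside the lung mask (AU)."""
    if not eit.lung_mask.any():
        raise ValueError("lung mask is empty")
    return eit.frames[:, eit.lung_mask].sum(axis=1)


def breath_landmarks_eit(
    signal: np.ndarray,
    frame_insp_guess: int,
    frame_breath_end: int,
    frame_rate: float,
    window_s: float = 0.5,
) -> tuple[int, int]:
    """Refine inspiration landmarks on the global impedance curve.

    The start of inspiration is the signal minimum in a +/- ``window_s``
    window around the flow-derived guess; the end of inspiration is the
    signal maximum within the breath.  Ties resolve to the earliest frame.
    """
    w = int(round(window_s * frame_rate))
    lo = max(0, frame_insp_guess - w)
    hi = min(len(signal) - 1, frame_insp_guess + w)
    if hi < lo:
        raise ValueError("landmark window is empty")
    fs = lo + int(np.argmin(signal[lo : hi + 1]))
    end = min(len(signal) - 1, frame_breath_end)
    if end <= fs:
        raise ValueError("landmark window is empty")
    fe = fs + int(np.argmax(signal[fs : end + 1]))
    return fs, fe


def tiv_eeli(signal: np.ndarray, frame_insp_start: int, frame_insp_end: int) -> tuple[float, float]:
    """(TIV, EELI) from the global curve at the inspiration landmarks."""
    eeli = float(signal[frame_insp_start])
    tiv = float(signal[frame_insp_end] - signal[frame_insp_start])
    return tiv, eeli


def tidal_image(eit: EITSequence, frame_insp_start: int, frame_insp_end: int) -> TidalImage:
    """Per-pixel end-minus-start-of-inspiration impedance change."""
    dz = (
        eit.frames[frame_insp_end].astype(float) - eit.frames[frame_insp_start].astype(float)
    )
    ridx, cidx = np.nonzero(eit.lung_mask)
    return TidalImage(
        dz=np.where(eit.lung_mask, dz, 0.0),
        mask=eit.lung_mask,
        ventral_edge=int(ridx.min()),
        dorsal_edge=int(ridx.max()),
        right_edge=int(cidx.min()),
        left_edge=int(cidx.max()),
    )


def center_of_ventilation(img: TidalImage) -> tuple[float, float]:
    """Ventilation-weighted centroid (CoV_VD, CoV_RL) in % of the extent.

    Returns (nan, nan) when the clipped tidal change is identically zero
    (center undefined, reported as missing).
    """
    w = img.dz_clipped
    total = w.sum()
    if total <= 0:
        return float("nan"), float("nan")
    y, x = img.extent_coords()
    return float((w * y).sum() / total), float((w * x).sum() / total)


def silent_spaces(img: TidalImage, cov_vd: float, threshold: float = 0.10) -> tuple[float, float]:
    """(NSS, DSS) in % of lung pixels.

    Silent pixels have a clipped tidal change strictly below ``threshold``
    of the maximum over the lung region.  The split plane is the horizontal
    CoV_VD height: pixels dorsal to it count as non-dependent (NSS), pixels
    ventral to or exactly on it as dependent (DSS; prone posture).
    """
    w = img.dz_clipped
    peak = w[img.mask].max()
    silent = img.mask & (w < threshold * peak)
    y, _ = img.extent_coords()
    n = img.mask.sum()
    nss = 100.0 * (silent & (y > cov_vd)).sum() / n
    dss = 100.0 * (silent & (y <= cov_vd)).sum() / n
    return float(nss), float(dss)


def regional_bands(img: TidalImage) -> tuple[float, float, float, float]:
    """Share of clipped tidal change in four equal-width ventro-dorsal bands.

    The lung-region extent is split into ventral / centro-ventral /
    centro-dorsal / dorsal quarters; each pixel belongs to the band holding
    its center.  Returns percentages of the total (nan if the total is 0).
    """
    w = img.dz_clipped
    total = w.sum()
    if total <= 0:
        return (float("nan"),) * 4
    y, _ = img.extent_coords()
    band = np.minimum(3, (y / 25.0).astype(int))
    shares = tuple(
        float(100.0 * w[img.mask & (band == b)].sum() / total) for b in range(4)
    )
    return shares


def compute_breath_features(
    eit: EITSequence,
    frame_insp_start: int,
    frame_insp_end: int,
    silent_threshold: float = 0.10,
) -> EITBreathFeatures:
    """All global and regional EIT variables for one breath."""
    g = global_signal(eit)
    tiv, eeli = tiv_eeli(g, frame_insp_start, frame_insp_end)
    img = tidal_image(eit, frame_insp_start, frame_insp_end)
    cov_vd, cov_rl = center_of_ventilation(img)
    if np.isnan(cov_vd):
        nss = dss = float("nan")
        bands = (float("nan"),) * 4
    else:
        nss, dss = silent_spaces(img, cov_vd, threshold=silent_threshold)
        bands = regional_bands(img)
    return EITBreathFeatures(
        tiv=tiv,
        eeli=eeli,
        cov_vd=cov_vd,
        cov_rl=cov_rl,
        nss=nss,
        dss=dss,
        dz_v=bands[0],
        dz_cv=bands[1],
        dz_cd=bands[2],
        dz_d=bands[3],
    )
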