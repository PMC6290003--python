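"""Sensitized-emission ratiometric FRET analysis.

Processing order is fixed: dark/flat-field correction, rolling-ball
background subtraction per channel, linear spectral de-mixing, punctum
segmentation on the corrected acceptor channel, then per-punctum FRET
index from summed corrected intensities.  Negative corrected intensities
are carried through and handled by the extreme-index filter rather than
clipped, so differences between arms stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from skimage.filters import gaussian
from skimage.restoration import rolling_ball

from ._segment import assign_to_local_maxima
from .flim_fret import SegmentationMap
from .presets import EPSILON_PRESETS, ROLLING_BALL_DIAMETER_PX


@dataclass
class MixingMatrix:
    """Forward spectral mixing operator with unit diagonal.

    ``eps_XY`` is the bleed of true channel Y into observed channel X,
    channel order (D, F, A): observed = M @ true.
    """

    eps_FD: float
    eps_AD: float
    eps_DF: float
    eps_AF: float
    eps_DA: float
    eps_FA: float

    def __post_init__(self) -> None:
        eps = [self.eps_FD, self.eps_AD, self.eps_DF, self.eps_AF, self.eps_DA, self.eps_FA]
        if any(e < 0 for e in eps):
            raise ValueError("cross-talk coefficients must be non-negative")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("mixing matrix is singular")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.eps_FD, self.eps_AD],
                [self.eps_DF, 1.0, self.eps_AF],
                [self.eps_DA, self.eps_FA, 1.0],
            ]
        )

    @classmethod
    def from_preset(cls, name: str) -> "MixingMatrix":
        try:
            return cls(**EPSILON_PRESETS[name])
        except KeyError:
            raise KeyError(
                f"unknown epsilon preset {name!r}; available: {sorted(EPSILON_PRESETS)}"
            ) from None

    @classmethod
    def identity(cls) -> "MixingMatrix":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class ChannelTriplet:
    """Three-channel acquisition: donor-exc/donor-em (D), donor-exc/
    acceptor-em (F), acceptor-exc/acceptor-em (A), plus calibration."""

    D_obs: np.ndarray
    F_obs: np.ndarray
    A_obs: np.ndarray
    dark_frame: np.ndarray = None  # type: ignore[assignment]
    flat_frames: dict = field(default_factory=dict)  # channel -> normalized flat
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in (self.D_obs, self.F_obs, self.A_obs)}
        if len(shapes) != 1:
            raise ValueError("channel images must share one shape")
        if self.dark_frame is None:
            self.dark_frame = np.zeros_like(np.asarray(self.D_obs, dtype=float))

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.D_obs).shape


@dataclass
class CorrectedTriplet:
    D_cor: np.ndarray
    F_cor: np.ndarray
    A_cor: np.ndarray


def flat_field_correct(raw: np.ndarray, dark: np.ndarray, flat_norm: np.ndarray) -> np.ndarray:
    """(raw - dark) / flat_norm, elementwise; ``flat_norm`` is the
    unit-mean calibration image.  Negative outputs are permitted."""
    raw = np.asarray(raw, dtype=float)
    dark = np.asarray(dark, dtype=float)
    flat_norm = np.asarray(flat_norm, dtype=float)
    if raw.shape != dark.shape or raw.shape != flat_norm.shape:
        raise ValueError("raw, dark and flat_norm shapes must match")
    if np.any(flat_norm == 0):
        raise ValueError("flat_norm contains zeros")
    return (raw - dark) / flat_norm


def rolling_ball_subtract(image: np.ndarray, diameter_px: float = ROLLING_BALL_DIAMETER_PX) -> np.ndarray:
    """Subtract a rolling-ball morphological background estimate."""
    if diameter_px < 3:
        raise ValueError("diameter_px must be >= 3")
    image = np.asarray(image, dtype=float)
    background = rolling_ball(image, radius=diameter_px / 2.0)
    return image - background


def unmix_channels(
    d: np.ndarray,
    f: np.ndarray,
    a: np.ndarray,
    mixing: MixingMatrix,
    interpretation: Literal["inverse", "literal"] = "inverse",
) -> CorrectedTriplet:
    """Linear spectral de-mixing of flat-fielded, background-subtracted
    channels.

    The default ``inverse`` interpretation treats the coefficient matrix as
    the forward mixing operator and solves corrected = M^-1 @ observed,
    which removes cross-talk and is exact on forward-simulated data.  The
    ``literal`` interpretation applies corrected = M @ observed as the
    matrix equation is typeset, provided for comparison only.
    """
    d = np.asarray(d, dtype=float)
    f = np.asarray(f, dtype=float)
    a = np.asarray(a, dtype=float)
    stacked = np.stack([d.ravel(), f.ravel(), a.ravel()])
    m = mixing.matrix
    if interpretation == "inverse":
        out = np.linalg.solve(m, stacked)
    elif interpretation == "literal":
        out = m @ stacked
    else:
        raise ValueError("interpretation must be 'inverse' or 'literal'")
    return CorrectedTriplet(
        D_cor=out[0].reshape(d.shape),
        F_cor=out[1].reshape(d.shape),
        A_cor=out[2].reshape(d.shape),
    )


def fret_index(d_cor, f_cor):
    """FRET index ``100 * F / (D + F)``; NaN where the denominator is 0.

    Scale invariant and unclamped -- out-of-range indices are a filter's
    concern, not this function's.
    """
    d_cor = np.asarray(d_cor, dtype=float)
    f_cor = np.asarray(f_cor, dtype=float)
    denom = d_cor + f_cor
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, 100.0 * f_cor / denom, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def segment_from_acceptor(
    a_cor: np.ndarray,
    background_region: np.ndarray,
    threshold_sd: float = 4.0,
    min_area: int = 9,
    blur_sigma: float = 3.0,
) -> SegmentationMap:
    """Segment puncta from the corrected acceptor channel.

    Threshold = mean + ``threshold_sd`` * SD over the supplied background
    region of the monolayer; supra-threshold pixels are split at intensity
    ridges of the blurred image by nearest-local-maximum assignment, and
    regions below ``min_area`` pixels are dropped.
    """
    a_cor = np.asarray(a_cor, dtype=float)
    background_region = np.asarray(background_region, dtype=bool)
    if background_region.shape != a_cor.shape:
        raise ValueError("background_region shape must match image")
    if not background_region.any():
        raise ValueError("background region is empty")
    bg = a_cor[background_region]
    thr = bg.mean() + threshold_sd * bg.std()
    mask = a_cor > thr
    surface = gaussian(a_cor, blur_sigma, preserve_range=True)
    labels = assign_to_local_maxima(surface, mask, min_area=min_area)
    return SegmentationMap(
        labels=labels,
        provenance="acceptor",
        params={"threshold_sd": threshold_sd, "min_area": min_area, "blur_sigma": blur_sigma},
    )


def lowest_decile_background(a_cor: np.ndarray) -> np.ndarray:
    """Convenience heuristic background mask (lowest-decile pixels).

    Never used implicitly; callers must opt in.
    """
    a_cor = np.asarray(a_cor, dtype=float)
    return a_cor <= np.quantile(a_cor, 0.10)


def analyze_ratiometric_image(
    triplet: ChannelTriplet,
    mixing: MixingMatrix,
    background_region: np.ndarray,
    min_total_a: float,
    rolling_ball_diameter_px: float = ROLLING_BALL_DIAMETER_PX,
    threshold_sd: float = 4.0,
    min_area: int = 9,
    manual_exclude_labels: set[int] | None = None,
    image_id: str = "image",
    apply_rolling_ball: bool = True,
) -> pd.DataFrame:
    """Full per-image sensitized-emission pipeline -> punctum table.

    Per punctum: I = 100 * sum(F_cor) / (sum(D_cor) + sum(F_cor)) over its
    pixels.  Flags: ``dim`` (sum(A_cor) < ``min_total_a``), ``extreme``
    (I outside [0, 100]) and ``manual_exclude`` (labels supplied from
    manual QC, never inferred).  Flagged puncta are excluded from
    summaries.
    """
    manual_exclude_labels = manual_exclude_labels or set()
    channels = {}
    for name, raw in (("D", triplet.D_obs), ("F", triplet.F_obs), ("A", triplet.A_obs)):
        flat = triplet.flat_frames.get(name)
        if flat is None:
            flat = np.ones(triplet.shape)
        img = flat_field_correct(raw, triplet.dark_frame, flat)
        if apply_rolling_ball:
            img = rolling_ball_subtract(img, rolling_ball_diameter_px)
        channels[name] = img
    corrected = unmix_channels(channels["D"], channels["F"], channels["A"], mixing)
    seg = segment_from_acceptor(
        corrected.A_cor, background_region, threshold_sd=threshold_sd, min_area=min_area
    )
    rows = []
    px = triplet.pixel_size_um
    for lab in range(1, seg.n_puncta + 1):
        pix = seg.labels == lab
        rr, cc = np.nonzero(pix)
        w = corrected.A_cor[pix]
        wsum = w.sum()
        weights = w / wsum if wsum > 0 else np.full(w.size, 1.0 / w.size)
        sum_d = float(corrected.D_cor[pix].sum())
        sum_f = float(corrected.F_cor[pix].sum())
        sum_a = float(wsum)
        idx = fret_index(sum_d, sum_f)
        flags = []
        if sum_a < min_total_a:
            flags.append("dim")
        if np.isnan(idx) or idx < 0.0 or idx > 100.0:
            flags.append("extreme")
        if lab in manual_exclude_labels:
            flags.append("manual_exclude")
        rows.append(
            {
                "image_id": image_id,
                "label": lab,
                "x_um": float(((cc + 0.5) * px * weights).sum()),
                "y_um": float(((rr + 0.5) * px * weights).sum()),
                "area_px": int(pix.sum()),
                "sumD": sum_d,
                "sumF": sum_f,
                "sumA": sum_a,
                "fret_index": float(idx),
                "flags": ";".join(flags),
            }
        )
    columns = [
        "image_id",
        "label",
        "x_um",
        "y_um",
        "area_px",
        "sumD",
        "sumF",
        "sumA",
        "fret_index",
        "flags",
    ]
    return pd.DataFrame(rows, columns=columns)
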