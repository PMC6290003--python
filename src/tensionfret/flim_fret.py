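"""FLIM-FRET analysis: punctum segmentation, Poisson maximum-likelihood
lifetime fitting, and FRET efficiency from donor lifetime shortening.

The decay model is a single exponential ``A * exp(-t / tau)`` fitted to the
photon-count histogram starting a fixed delay after the peak bin, which
keeps the instrument response and early autofluorescence out of the fit
window.  The amplitude is profiled out of the Poisson likelihood
analytically, leaving a deterministic bounded 1-D search in ``tau``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from skimage.filters import gaussian, threshold_otsu

from ._segment import assign_to_local_maxima
from .presets import FIT_START_OFFSET_NS

TAU_BOUNDS_NS = (0.1, 10.0)
# FWHM -> Gaussian sigma conversion used to turn the band-pass diameter
# range into difference-of-Gaussians scales.
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.355


@dataclass
class FLIMImage:
    """Per-pixel photon-arrival histograms plus calibration.

    ``photons`` is [row, col, time_bin] of non-negative counts;
    ``intensity`` is its sum over time bins.
    """

    photons: np.ndarray
    bin_width_ns: float
    pixel_size_um: float
    intensity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.photons = np.asarray(self.photons)
        if self.photons.ndim != 3:
            raise ValueError("photons must be a [y, x, time] 3-D array")
        if self.bin_width_ns <= 0:
            raise ValueError("bin_width_ns must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.photons < 0):
            raise ValueError("photon counts must be non-negative")
        summed = self.photons.sum(axis=2)
        if self.intensity is None:
            self.intensity = summed
        elif not np.array_equal(np.asarray(self.intensity), summed):
            raise ValueError("intensity does not match photon sum over time bins")

    @property
    def n_bins(self) -> int:
        return self.photons.shape[2]


@dataclass
class SegmentationMap:
    """Integer label image (0 = background) plus provenance."""

    labels: np.ndarray
    provenance: Literal["auto", "manual-masked", "acceptor"]
    params: dict

    @property
    def n_puncta(self) -> int:
        return int(self.labels.max())


@dataclass
class DecayFit:
    tau_ns: float
    amplitude: float
    photons_used: int
    fit_start_bin: int
    neg_log_likelihood: float
    converged: bool
    at_bound: bool = False


@dataclass
class BulkResult:
    fit: DecayFit
    fret_efficiency: float


def fret_efficiency(tau_da: float, tau_d: float):
    """FRET efficiency from donor lifetime shortening: ``1 - tau_da/tau_d``.

    No clamping is applied; out-of-range values are handled by downstream
    filters.
    """
    if np.any(np.asarray(tau_d) <= 0):
        raise ValueError("donor-only lifetime must be positive")
    return 1.0 - np.asarray(tau_da) / np.asarray(tau_d)


def _profiled_nll(tau: float, t: np.ndarray, counts: np.ndarray) -> float:
    # Poisson NLL with amplitude profiled out: A* = N / sum(exp(-t/tau)).
    shape = np.exp(-t / tau)
    s = shape.sum()
    n = counts.sum()
    # ll = N log(N/S) - sum(n_i t_i)/tau - N  (dropping count-only terms)
    return -(n * math.log(n / s) - float(np.dot(counts, t)) / tau - n)


def fit_decay_ml(
    counts: np.ndarray,
    bin_width_ns: float,
    offset_ns: float = FIT_START_OFFSET_NS,
    tau_bounds_ns: tuple[float, float] = TAU_BOUNDS_NS,
) -> DecayFit:
    """Maximum-likelihood mono-exponential fit to a photon-count histogram.

    The fit window starts at the first bin that is at least ``offset_ns``
    after the peak (first bin attaining the maximum count).  The Poisson
    likelihood of ``A * exp(-t/tau)`` is maximized over ``tau`` within
    ``tau_bounds_ns`` with the amplitude profiled out analytically, so the
    result is deterministic for a given histogram.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D histogram")
    if bin_width_ns <= 0:
        raise ValueError("bin_width_ns must be positive")
    if counts.sum() <= 0:
        raise ValueError("histogram contains no photons")

    peak = int(np.argmax(counts))  # first bin attaining the max
    start = peak + int(math.ceil(offset_ns / bin_width_ns - 1e-12))
    start = min(start, counts.size - 1)
    window = counts[start:]
    n_used = float(window.sum())
    t = (np.arange(start, counts.size) + 0.5) * bin_width_ns

    if n_used < 2:
        return DecayFit(
            tau_ns=float("nan"),
            amplitude=0.0,
            photons_used=int(n_used),
            fit_start_bin=start,
            neg_log_likelihood=float("nan"),
            converged=False,
        )

    res = minimize_scalar(
        _profiled_nll,
        bounds=tau_bounds_ns,
        args=(t, window),
        method="bounded",
        options={"xatol": 1e-7},
    )
    tau = float(res.x)
    amp = n_used / float(np.exp(-t / tau).sum())
    span = tau_bounds_ns[1] - tau_bounds_ns[0]
    at_bound = (
        tau - tau_bounds_ns[0] < 1e-4 * span or tau_bounds_ns[1] - tau < 1e-4 * span
    )
    return DecayFit(
        tau_ns=tau,
        amplitude=amp,
        photons_used=int(round(n_used)),
        fit_start_bin=start,
        neg_log_likelihood=float(res.fun),
        converged=bool(res.success),
        at_bound=at_bound,
    )


def segment_puncta_auto(
    intensity: np.ndarray,
    band_pass: tuple[float, float] = (3.0, 10.0),
    threshold_sd: float = 1.0,
    min_area: int = 9,
) -> SegmentationMap:
    """Automatic punctum segmentation of an intensity image.

    Difference-of-Gaussians band-pass tuned to the feature diameter range,
    global threshold at mean + ``threshold_sd`` * SD of the *filtered*
    image, then nearest-local-maximum basin assignment; basins smaller
    than ``min_area`` pixels are dropped.
    """
    intensity = np.asarray(intensity, dtype=float)
    d_min, d_max = band_pass
    if not d_min < d_max:
        raise ValueError("band_pass requires d_min < d_max")
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")

    sigma_small = d_min / _FWHM_TO_SIGMA
    sigma_large = d_max / _FWHM_TO_SIGMA
    filtered = gaussian(intensity, sigma_small, preserve_range=True) - gaussian(
        intensity, sigma_large, preserve_range=True
    )
    thr = filtered.mean() + threshold_sd * filtered.std()
    mask = filtered > thr
    labels = assign_to_local_maxima(filtered, mask, min_area=min_area)
    return SegmentationMap(
        labels=labels,
        provenance="auto",
        params={
            "band_pass": tuple(band_pass),
            "threshold_sd": threshold_sd,
            "min_area": min_area,
        },
    )


def segment_puncta_masked(
    intensity: np.ndarray,
    manual_mask: np.ndarray,
    blur_sigma: float = 3.0,
    min_area: int = 9,
) -> SegmentationMap:
    """Punctum segmentation restricted to a manually drawn junction mask.

    The image is Gaussian-blurred (default sigma 3 px); bright connected
    regions within the mask are isolated by an Otsu threshold on the
    blurred in-mask values, then split at intensity ridges by
    nearest-local-maximum assignment.
    """
    intensity = np.asarray(intensity, dtype=float)
    manual_mask = np.asarray(manual_mask, dtype=bool)
    if manual_mask.shape != intensity.shape:
        raise ValueError("manual_mask shape must match intensity")
    params = {"blur_sigma": blur_sigma, "min_area": min_area}
    if not manual_mask.any():
        return SegmentationMap(
            labels=np.zeros(intensity.shape, dtype=np.int32),
            provenance="manual-masked",
            params=params,
        )
    blurred = gaussian(intensity, blur_sigma, preserve_range=True)
    in_mask = blurred[manual_mask]
    if np.ptp(in_mask) == 0:
        bright = np.zeros_like(manual_mask)
    else:
        thr = threshold_otsu(in_mask)
        bright = manual_mask & (blurred > thr)
    labels = assign_to_local_maxima(blurred, bright, min_area=min_area)
    return SegmentationMap(labels=labels, provenance="manual-masked", params=params)


def _summed_decay(img: FLIMImage, pixel_mask: np.ndarray) -> np.ndarray:
    return img.photons[pixel_mask].sum(axis=0)


def analyze_flim_image(
    img: FLIMImage,
    seg: SegmentationMap,
    tau_d_ns: float,
    mode: Literal["per_punctum", "bulk"] = "per_punctum",
    min_photons: int = 1000,
    offset_ns: float = FIT_START_OFFSET_NS,
    image_id: str = "image",
):
    """Lifetime / FRET-efficiency analysis of a segmented FLIM image.

    ``bulk`` mode fits one decay to all photons within the segmentation
    mask and applies no exclusions.  ``per_punctum`` mode fits each
    punctum's summed decay and flags records with too few photons
    (< ``min_photons``) or extreme efficiency (E < 0 or E > 1); flagged
    records carry their values but are excluded from summaries.
    """
    if tau_d_ns <= 0:
        raise ValueError("tau_d_ns must be positive")
    labels = seg.labels
    if mode == "bulk":
        decay = _summed_decay(img, labels > 0)
        if decay.sum() <= 0:
            raise ValueError("no photons within the segmentation mask")
        fit = fit_decay_ml(decay, img.bin_width_ns, offset_ns=offset_ns)
        return BulkResult(fit=fit, fret_efficiency=float(fret_efficiency(fit.tau_ns, tau_d_ns)))

    rows = []
    for lab in range(1, int(labels.max()) + 1):
        pix = labels == lab
        n_pix = int(pix.sum())
        if n_pix == 0:
            continue
        decay = _summed_decay(img, pix)
        photons = int(decay.sum())
        rr, cc = np.nonzero(pix)
        # intensity-weighted centroid, physical units (pixel centers)
        w = img.intensity[pix].astype(float)
        w = w / w.sum() if w.sum() > 0 else np.full(n_pix, 1.0 / n_pix)
        y_um = float(((rr + 0.5) * img.pixel_size_um * w).sum())
        x_um = float(((cc + 0.5) * img.pixel_size_um * w).sum())
        flags = []
        tau = math.nan
        eff = math.nan
        if photons > 0:
            fit = fit_decay_ml(decay, img.bin_width_ns, offset_ns=offset_ns)
            if fit.converged:
                tau = fit.tau_ns
                eff = float(fret_efficiency(tau, tau_d_ns))
        if photons < min_photons:
            flags.append("low_photons")
        if not math.isnan(eff) and (eff < 0.0 or eff > 1.0):
            flags.append("extreme_value")
        rows.append(
            {
                "image_id": image_id,
                "label": lab,
                "x_um": x_um,
                "y_um": y_um,
                "area_px": n_pix,
                "photons": photons,
                "tau_ns": tau,
                "fret_efficiency": eff,
                "flags": ";".join(flags),
            }
        )
    columns = [
        "image_id",
        "label",
        "x_um",
        "y_um",
        "area_px",
        "photons",
        "tau_ns",
        "fret_efficiency",
        "flags",
    ]
    return pd.DataFrame(rows, columns=columns)


def included(table: pd.DataFrame) -> pd.DataFrame:
    """Rows with no exclusion flags set."""
    return table[table["flags"].fillna("") == ""]
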