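"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Generators produce TCSPC decay histograms, FLIM photon stacks, three-channel
bleed-through scenes, micropipette pull sequences and grouped FRET tables,
each with the statistical structure the downstream analysis assumes and a
ground-truth table for verification.  All randomness flows from explicit
integer seeds through ``numpy.random.default_rng``.

Defaults: 256 time bins over a 12.5 ns window (80 MHz-like repetition);
puncta are isotropic Gaussian intensity profiles truncated at 3 sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .flim_fret import FLIMImage
from .ratiometric_fret import ChannelTriplet, MixingMatrix
from .presets import PIXEL_SIZE_UM

DEFAULT_N_BINS = 256
DEFAULT_WINDOW_NS = 12.5


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------

@dataclass
class DecaySimParams:
    """Mono-exponential TCSPC decay simulation parameters."""

    lifetime_ns: float
    photon_budget: float
    n_bins: int = DEFAULT_N_BINS
    window_ns: float = DEFAULT_WINDOW_NS
    background_rate: float = 0.0  # expected photons per bin
    irf_sigma_ns: float = 0.0  # optional Gaussian IRF for robustness tests
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lifetime_ns <= 0:
            raise ValueError("lifetime_ns must be positive")
        if self.photon_budget < 1 or not math.isfinite(self.photon_budget):
            raise ValueError("photon_budget must be finite and >= 1")
        if self.n_bins < 16:
            raise ValueError("n_bins must be >= 16")
        if self.window_ns <= 0:
            raise ValueError("window_ns must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")

    @property
    def bin_width_ns(self) -> float:
        return self.window_ns / self.n_bins


def decay_bin_expectations(
    lifetime_ns: float,
    photon_budget: float,
    n_bins: int = DEFAULT_N_BINS,
    window_ns: float = DEFAULT_WINDOW_NS,
    background_rate: float = 0.0,
) -> np.ndarray:
    """Expected photon count per bin: the exponential integrated over each
    bin, normalized to the acquisition window, plus flat background."""
    edges = np.linspace(0.0, window_ns, n_bins + 1)
    tau = lifetime_ns
    cdf = 1.0 - np.exp(-edges / tau)
    probs = np.diff(cdf) / cdf[-1]
    return photon_budget * probs + background_rate


def simulate_decay(params: DecaySimParams, add_noise: bool = True) -> np.ndarray:
    """Simulate one TCSPC histogram.

    With ``add_noise`` the per-bin counts are independent Poisson draws
    around the bin expectations (or, when an IRF sigma is set, individual
    photon arrival times are sampled and jittered before histogramming).
    Without noise the exact expectation vector is returned.
    """
    expect = decay_bin_expectations(
        params.lifetime_ns,
        params.photon_budget,
        params.n_bins,
        params.window_ns,
        params.background_rate,
    )
    if not add_noise:
        return expect
    rng = np.random.default_rng(params.seed)
    if params.irf_sigma_ns > 0:
        n = rng.poisson(params.photon_budget)
        t = rng.exponential(params.lifetime_ns, size=n)
        t = t + rng.normal(0.0, params.irf_sigma_ns, size=n)
        t = t[(t >= 0) & (t < params.window_ns)]
        counts, _ = np.histogram(t, bins=params.n_bins, range=(0.0, params.window_ns))
        if params.background_rate > 0:
            counts = counts + rng.poisson(params.background_rate, size=params.n_bins)
        return counts.astype(np.int64)
    return rng.poisson(expect).astype(np.int64)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

@dataclass
class PunctumSpec:
    """One punctum: Gaussian profile at ``center_px`` (row, col), width
    ``sigma_px``, peak expected intensity, and a ground-truth value
    (lifetime in ns for FLIM scenes, FRET index for ratiometric ones)."""

    center_px: tuple[float, float]
    sigma_px: float
    peak: float
    value: float

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if self.peak < 0:
            raise ValueError("peak must be non-negative")


@dataclass
class SceneSpec:
    image_shape: tuple[int, int] = (64, 64)
    pixel_size_um: float = PIXEL_SIZE_UM["MDCK"]
    puncta: Sequence[PunctumSpec] = field(default_factory=list)
    background_level: float = 0.5
    background_lifetime_ns: float = 2.0
    noise_model: Literal["poisson", "gaussian", "none"] = "poisson"
    noise_sigma: float = 0.0  # for gaussian noise
    n_bins: int = 64
    window_ns: float = DEFAULT_WINDOW_NS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        h, w = self.image_shape
        for p in self.puncta:
            r, c = p.center_px
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"punctum center {p.center_px} outside image")

    @property
    def bin_width_ns(self) -> float:
        return self.window_ns / self.n_bins


def _render_puncta(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Render punctum amplitude maps.

    Returns (total amplitude image, owner label image with 0 = background,
    per-punctum amplitude maps).  Gaussian profiles are truncated at
    3 sigma; overlap of puncta with different ground-truth values is an
    error (ambiguous ownership).
    """
    h, w = spec.image_shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    total = np.zeros((h, w))
    owner = np.zeros((h, w), dtype=np.int32)
    amps = []
    for k, p in enumerate(spec.puncta, start=1):
        r0, c0 = p.center_px
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        amp = np.where(d2 <= (3.0 * p.sigma_px) ** 2, p.peak * np.exp(-d2 / (2.0 * p.sigma_px**2)), 0.0)
        footprint = amp > 0
        clash = footprint & (owner > 0)
        if clash.any():
            other = spec.puncta[owner[clash][0] - 1]
            if other.value != p.value:
                raise ValueError(
                    "overlapping puncta with different ground-truth values"
                )
        owner[footprint & (owner == 0)] = k
        total += amp
        amps.append(amp)
    return total, owner, amps


def _apply_scene_noise(image: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "poisson":
        return rng.poisson(image).astype(float)
    if spec.noise_model == "gaussian":
        return image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    if spec.noise_model == "none":
        return image.copy()
    raise ValueError(f"unknown noise model {spec.noise_model!r}")


@dataclass
class FLIMGroundTruth:
    table: pd.DataFrame  # label, row_px, col_px, sigma_px, lifetime_ns, expected_photons, n_pixels
    labels: np.ndarray  # owner label image


def simulate_flim_scene(spec: SceneSpec) -> tuple[FLIMImage, FLIMGroundTruth]:
    """Render a FLIM photon-count stack from a punctate scene.

    Every pixel owned by a punctum decays with that punctum's lifetime;
    background pixels decay with the background lifetime.  Counts are
    Poisson draws unless the spec disables noise.
    """
    h, w = spec.image_shape
    total, owner, amps = _render_puncta(spec)
    shape_cache: dict[float, np.ndarray] = {}

    def shape_for(tau: float) -> np.ndarray:
        if tau not in shape_cache:
            shape_cache[tau] = decay_bin_expectations(
                tau, 1.0, spec.n_bins, spec.window_ns
            )
        return shape_cache[tau]

    expect = np.zeros((h, w, spec.n_bins))
    if spec.background_level > 0:
        expect += spec.background_level * shape_for(spec.background_lifetime_ns)[None, None, :]
    for k, p in enumerate(spec.puncta, start=1):
        expect += amps[k - 1][:, :, None] * shape_for(p.value)[None, None, :]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "poisson":
        photons = rng.poisson(expect)
    elif spec.noise_model == "none":
        photons = expect
    else:
        raise ValueError("FLIM scenes support 'poisson' or 'none' noise")

    rows = []
    for k, p in enumerate(spec.puncta, start=1):
        pix = owner == k
        rows.append(
            {
                "label": k,
                "row_px": p.center_px[0],
                "col_px": p.center_px[1],
                "sigma_px": p.sigma_px,
                "lifetime_ns": p.value,
                "expected_photons": float(amps[k - 1][pix].sum()),
                "n_pixels": int(pix.sum()),
            }
        )
    truth = FLIMGroundTruth(
        table=pd.DataFrame(
            rows,
            columns=[
                "label", "row_px", "col_px", "sigma_px", "lifetime_ns",
                "expected_photons", "n_pixels",
            ],
        ),
        labels=owner,
    )
    img = FLIMImage(
        photons=photons, bin_width_ns=spec.bin_width_ns, pixel_size_um=spec.pixel_size_um
    )
    return img, truth


# ---------------------------------------------------------------------------
# Three-channel scenes
# ---------------------------------------------------------------------------

@dataclass
class FlatFieldModel:
    """Multiplicative vignette: flat, or radial quadratic falloff of the
    given strength; ``render`` returns the raw field, ``normalized`` the
    unit-mean calibration image."""

    kind: Literal["flat", "radial"] = "flat"
    strength: float = 0.3

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        if self.kind == "flat":
            return np.ones((h, w))
        rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        r2 = ((rows - (h - 1) / 2) ** 2 + (cols - (w - 1) / 2) ** 2)
        r2max = ((h - 1) / 2) ** 2 + ((w - 1) / 2) ** 2
        return 1.0 - self.strength * r2 / r2max

    def normalized(self, shape: tuple[int, int]) -> np.ndarray:
        v = self.render(shape)
        return v / v.mean()


@dataclass
class ThreeChannelGroundTruth:
    table: pd.DataFrame  # label, row_px, col_px, true_index, true_sumD/F/A, n_pixels
    labels: np.ndarray
    true_channels: tuple[np.ndarray, np.ndarray, np.ndarray]


def simulate_three_channel_scene(
    spec: SceneSpec,
    mixing: MixingMatrix,
    vignette: FlatFieldModel | None = None,
    dark_offset: float = 0.0,
    acceptor_gain: float = 1.0,
) -> tuple[ChannelTriplet, ThreeChannelGroundTruth]:
    """Forward-simulate a sensitized-emission acquisition.

    True channels are built from per-punctum brightness and FRET index
    (D = (1 - I/100) S, F = (I/100) S, A = gain * S); the observed triplet
    is ``M @ true`` per pixel, multiplied by the vignette, plus dark offset
    and noise.  The returned triplet carries the matching calibration
    frames so the analysis chain can undo exactly what was applied.
    """
    vignette = vignette or FlatFieldModel("flat")
    h, w = spec.image_shape
    total, owner, amps = _render_puncta(spec)

    d_true = np.full((h, w), float(spec.background_level))
    f_true = np.zeros((h, w))
    a_true = np.full((h, w), float(spec.background_level) * acceptor_gain)
    for k, p in enumerate(spec.puncta, start=1):
        frac = p.value / 100.0
        d_true += amps[k - 1] * (1.0 - frac)
        f_true += amps[k - 1] * frac
        a_true += amps[k - 1] * acceptor_gain

    stacked = np.stack([d_true.ravel(), f_true.ravel(), a_true.ravel()])
    mixed = mixing.matrix @ stacked
    v = vignette.render((h, w))
    rng = np.random.default_rng(spec.seed)
    observed = []
    for ch in mixed:
        img = ch.reshape(h, w) * v + dark_offset
        observed.append(_apply_scene_noise(img, spec, rng))

    flat_norm = vignette.normalized((h, w))
    triplet = ChannelTriplet(
        D_obs=observed[0],
        F_obs=observed[1],
        A_obs=observed[2],
        dark_frame=np.full((h, w), float(dark_offset)),
        flat_frames={"D": flat_norm, "F": flat_norm, "A": flat_norm},
        pixel_size_um=spec.pixel_size_um,
    )
    rows = []
    for k, p in enumerate(spec.puncta, start=1):
        pix = owner == k
        rows.append(
            {
                "label": k,
                "row_px": p.center_px[0],
                "col_px": p.center_px[1],
                "true_index": p.value,
                "true_sumD": float(d_true[pix].sum()),
                "true_sumF": float(f_true[pix].sum()),
                "true_sumA": float(a_true[pix].sum()),
                "n_pixels": int(pix.sum()),
            }
        )
    truth = ThreeChannelGroundTruth(
        table=pd.DataFrame(
            rows,
            columns=[
                "label", "row_px", "col_px", "true_index",
                "true_sumD", "true_sumF", "true_sumA", "n_pixels",
            ],
        ),
        labels=owner,
        true_channels=(d_true, f_true, a_true),
    )
    return triplet, truth


# ---------------------------------------------------------------------------
# Pull sequences
# ---------------------------------------------------------------------------

@dataclass
class TensionResponse:
    """Minimal monotone recoil-to-FRET response:
    delta_I = gain * min(d_r, window) * sin(alpha_r)^power."""

    gain_per_um: float = 1.0
    angle_power: float = 1.0
    window_um: float = 10.0

    def __call__(self, d_r_um: float, alpha_r_deg: float) -> float:
        s = math.sin(math.radians(alpha_r_deg))
        return self.gain_per_um * min(d_r_um, self.window_um) * s**self.angle_power


@dataclass
class PullSimSpec:
    base_scene: SceneSpec
    homography: np.ndarray
    recoil_fraction: float = 1.0
    junction_polyline: np.ndarray = None  # type: ignore[assignment]  # (n, 2) x,y um
    tension_response: TensionResponse = field(default_factory=TensionResponse)
    arm: Literal["TS", "ctrl"] = "TS"
    base_index: float = 50.0
    n_control_points: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.homography = np.asarray(self.homography, dtype=float)
        if self.homography.shape != (3, 3) or abs(np.linalg.det(self.homography)) < 1e-12:
            raise ValueError("homography must be an invertible 3x3 matrix")
        if not 0.0 <= self.recoil_fraction <= 1.0:
            raise ValueError("recoil_fraction must lie in [0, 1]")
        if self.junction_polyline is None:
            h, w = self.base_scene.image_shape
            px = self.base_scene.pixel_size_um
            mid = h / 2 * px
            self.junction_polyline = np.array([[0.0, mid], [w * px, mid]])
        self.junction_polyline = np.asarray(self.junction_polyline, dtype=float)


@dataclass
class PullSequence:
    tables: dict  # phase -> punctum table (image_id, label, x_um, y_um, fret_index, flags)
    control_points: tuple[np.ndarray, np.ndarray]  # pull-frame -> post-frame pairs
    truth: pd.DataFrame
    triplets: dict | None = None


def _apply_homography(h: np.ndarray, pts: np.ndarray) -> np.ndarray:
    hom = np.column_stack([pts, np.ones(len(pts))]) @ h.T
    return hom[:, :2] / hom[:, 2:3]


def _junction_direction_deg(polyline: np.ndarray, point: np.ndarray) -> float:
    """Orientation (deg) of the polyline segment nearest to ``point``."""
    best_d, best_deg = math.inf, 0.0
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        t = np.clip(np.dot(point - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        d = float(np.hypot(*(point - (a + t * ab))))
        if d < best_d:
            best_d = d
            best_deg = math.degrees(math.atan2(ab[1], ab[0]))
    return best_deg


def simulate_pull_sequence(
    spec: PullSimSpec,
    render_images: bool = False,
    mixing: MixingMatrix | None = None,
) -> PullSequence:
    """Simulate a pre/pull/post micropipette cycle.

    Punctum centres (material points) are warped by the homography for the
    pull phase and recover ``recoil_fraction`` of the deformation for the
    post phase, so d_r and the recoil direction have closed-form ground
    truth.  Sensor-arm puncta lose FRET index during the pull according to
    the tension response; control-arm puncta do not.  Control-point pairs
    are exact material correspondences between the pull and post frames.
    """
    from .recoil_tracking import acute_angle_deg  # local import avoids cycle

    scene = spec.base_scene
    px = scene.pixel_size_um
    centers_px = np.array([p.center_px for p in scene.puncta], dtype=float)
    if centers_px.size == 0:
        raise ValueError("pull simulation requires at least one punctum")
    # physical coords: x = (col + 0.5) * px, y = (row + 0.5) * px
    pre = np.column_stack([(centers_px[:, 1] + 0.5) * px, (centers_px[:, 0] + 0.5) * px])
    pull = _apply_homography(spec.homography, pre)
    post = pull + spec.recoil_fraction * (pre - pull)

    rows = []
    for i in range(len(pre)):
        vec = post[i] - pull[i]
        d_r = float(np.hypot(*vec))
        jdeg = _junction_direction_deg(spec.junction_polyline, pre[i])
        if d_r > 0:
            rdeg = math.degrees(math.atan2(vec[1], vec[0]))
            alpha = acute_angle_deg(rdeg, jdeg)
        else:
            alpha = 0.0
        base_i = scene.puncta[i].value if scene.puncta[i].value is not None else spec.base_index
        delta_i = spec.tension_response(d_r, alpha) if spec.arm == "TS" else 0.0
        rows.append(
            {
                "punctum": i,
                "arm": spec.arm,
                "x_pre": pre[i, 0], "y_pre": pre[i, 1],
                "x_pull": pull[i, 0], "y_pull": pull[i, 1],
                "x_post": post[i, 0], "y_post": post[i, 1],
                "d_r_um": d_r,
                "alpha_r_deg": alpha,
                "delta_index": delta_i,
                "index_pre": base_i,
                "index_pull": base_i - delta_i,
                "index_post": base_i,
            }
        )
    truth = pd.DataFrame(rows)

    tables = {}
    for phase, (xy, col) in {
        "pre": (pre, "index_pre"),
        "pull": (pull, "index_pull"),
        "post": (post, "index_post"),
    }.items():
        tables[phase] = pd.DataFrame(
            {
                "image_id": phase,
                "label": np.arange(1, len(pre) + 1),
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "fret_index": truth[col].to_numpy(),
                "flags": "",
            }
        )

    # control points: material grid points, exact pull->post correspondence
    h_px, w_px = scene.image_shape
    n_side = max(3, int(math.ceil(math.sqrt(spec.n_control_points))))
    gx = np.linspace(0.1, 0.9, n_side) * w_px * px
    gy = np.linspace(0.1, 0.9, n_side) * h_px * px
    grid = np.array([(x, y) for y in gy for x in gx])[: max(6, spec.n_control_points)]
    grid_pull = _apply_homography(spec.homography, grid)
    grid_post = grid_pull + spec.recoil_fraction * (grid - grid_pull)

    triplets = None
    if render_images:
        mixing = mixing or MixingMatrix.identity()
        triplets = {}
        for phase, (xy, col) in {
            "pre": (pre, "index_pre"),
            "pull": (pull, "index_pull"),
            "post": (post, "index_post"),
        }.items():
            puncta = []
            for i, p in enumerate(scene.puncta):
                r = xy[i, 1] / px - 0.5
                c = xy[i, 0] / px - 0.5
                if not (0 <= r < h_px and 0 <= c < w_px):
                    continue  # warped out of the field of view
                puncta.append(
                    PunctumSpec((r, c), p.sigma_px, p.peak, float(truth[col].iloc[i]))
                )
            phase_scene = SceneSpec(
                image_shape=scene.image_shape,
                pixel_size_um=px,
                puncta=puncta,
                background_level=scene.background_level,
                noise_model=scene.noise_model,
                noise_sigma=scene.noise_sigma,
                seed=spec.seed + {"pre": 1, "pull": 2, "post": 3}[phase],
            )
            triplets[phase], _ = simulate_three_channel_scene(phase_scene, mixing)

    return PullSequence(
        tables=tables,
        control_points=(grid_pull, grid_post),
        truth=truth,
        triplets=triplets,
    )


def make_junction_scene(
    n_puncta: int = 18,
    spacing_um: float = 1.5,
    junction_y_um: float = 12.0,
    image_shape: tuple[int, int] = (48, 48),
    pixel_size_um: float = 0.5,
    sigma_px: float = 1.2,
    peak: float = 80.0,
    base_index: float = 55.0,
    jitter_um: float = 0.0,
    seed: int = 0,
) -> tuple[SceneSpec, np.ndarray]:
    """Puncta strung along a horizontal cell-cell junction line.

    Returns the scene and the matching junction polyline (physical
    coordinates), the geometry recoil analysis expects.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    xs = (np.arange(n_puncta) - (n_puncta - 1) / 2) * spacing_um + w * pixel_size_um / 2
    puncta = []
    for x in xs:
        y = junction_y_um + (rng.normal(0.0, jitter_um) if jitter_um > 0 else 0.0)
        r = y / pixel_size_um - 0.5
        c = x / pixel_size_um - 0.5
        if 0 <= r < h and 0 <= c < w:
            puncta.append(PunctumSpec((r, c), sigma_px, peak, base_index))
    scene = SceneSpec(
        image_shape=image_shape,
        pixel_size_um=pixel_size_um,
        puncta=puncta,
        noise_model="none",
    )
    polyline = np.array([[0.0, junction_y_um], [w * pixel_size_um, junction_y_um]])
    return scene, polyline


# ---------------------------------------------------------------------------
# Grouped FRET tables
# ---------------------------------------------------------------------------

@dataclass
class GroupedTableSpec:
    n_images_per_arm: int = 20
    puncta_per_image: int = 30
    true_delta: float = 3.0  # ctrl minus sensor, index units
    image_sd: float = 2.0
    punctum_sd: float = 4.0
    ctrl_mean: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images_per_arm < 1 or self.puncta_per_image < 1:
            raise ValueError("counts must be >= 1")
        if self.image_sd < 0 or self.punctum_sd < 0:
            raise ValueError("SDs must be >= 0")


def simulate_grouped_fret_table(spec: GroupedTableSpec) -> pd.DataFrame:
    """Two-arm punctum table with per-image random intercepts.

    Sensor-arm mean is ``ctrl_mean - true_delta`` (tension lowers sensor
    FRET); each image draws an intercept N(0, image_sd^2) and each punctum
    N(arm mean + intercept, punctum_sd^2).  Columns: value,
    isTensionSensor, imageNumber (unique across arms).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    image_number = 0
    for arm, mean in (("ctrl", spec.ctrl_mean), ("TS", spec.ctrl_mean - spec.true_delta)):
        is_ts = int(arm == "TS")
        for _ in range(spec.n_images_per_arm):
            intercept = rng.normal(0.0, spec.image_sd)
            values = rng.normal(mean + intercept, spec.punctum_sd, size=spec.puncta_per_image)
            for v in values:
                rows.append(
                    {"value": v, "isTensionSensor": is_ts, "imageNumber": image_number}
                )
            image_number += 1
    return pd.DataFrame(rows, columns=["value", "isTensionSensor", "imageNumber"])
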