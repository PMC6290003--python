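"""Recoil tracking of puncta across pre/pull/post micropipette frames.

Geometry conventions: positions in micrometres, (x, y) = (col, row)
physical coordinates.  All slope arithmetic is carried out in angle
parametrization (atan2) so vertical junctions never produce infinities;
for finite slopes this is algebraically identical to the acute-angle
slope formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from skimage.transform import ProjectiveTransform

from .presets import (
    JUNCTION_MAX_SE_DEG,
    JUNCTION_MIN_POINTS,
    JUNCTION_NEIGHBOR_RADIUS_UM,
    MAX_RECOIL_WINDOW_UM,
    MIN_RECOIL_UM,
    ORIENTATION_SPLIT_DEG,
)

DEFAULT_MAX_DISP_UM = 15.0


@dataclass
class Homography:
    matrix: np.ndarray
    reprojection_rms: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        hom = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]


@dataclass
class Matching:
    pairs: list[tuple[int, int]]
    total_displacement: float
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)


def fit_projective_map(src: np.ndarray, dst: np.ndarray) -> Homography:
    """Least-squares projective map from control-point pairs (normalized
    DLT); at least 4 non-degenerate pairs required."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("control points must be matching (n, 2) arrays")
    if len(src) < 4:
        raise ValueError("at least 4 control-point pairs required")
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src, dst)
        if not tf or not np.all(np.isfinite(tf.params)):
            raise ValueError("degenerate control-point configuration")
    else:  # older scikit-image
        tf = ProjectiveTransform()
        if not tf.estimate(src, dst) or not np.all(np.isfinite(tf.params)):
            raise ValueError("degenerate control-point configuration")
    matrix = tf.params / tf.params[2, 2]
    h = Homography(matrix=matrix, reprojection_rms=0.0)
    resid = h.apply(src) - dst
    h.reprojection_rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return h


def match_puncta(a: np.ndarray, b: np.ndarray, max_disp_um: float = DEFAULT_MAX_DISP_UM) -> Matching:
    """Minimum-total-displacement one-to-one matching between point sets.

    Only pairs closer than ``max_disp_um`` are admissible; among all
    matchings using admissible pairs the result has maximum cardinality
    and, subject to that, minimum total Euclidean displacement.  Points
    without an admissible partner are left unmatched.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be positive")
    if a.size == 0 or b.size == 0:
        return Matching([], 0.0, list(range(len(a))), list(range(len(b))))
    dist = cdist(a, b)
    feasible = dist <= max_disp_um
    # A cost larger than any feasible matching total makes the solver
    # prefer fewer infeasible edges, i.e. maximum cardinality first.
    big = (min(len(a), len(b)) * max_disp_um + 1.0) * 10.0
    cost = np.where(feasible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    total = float(sum(dist[i, j] for i, j in pairs))
    return Matching(
        pairs=pairs,
        total_displacement=total,
        unmatched_a=[i for i in range(len(a)) if i not in matched_a],
        unmatched_b=[j for j in range(len(b)) if j not in matched_b],
    )


def compute_recoil(matching: Matching, pos_pull: np.ndarray, pos_post: np.ndarray) -> pd.DataFrame:
    """Recoil vector (post - pull) and distance d_r for each matched pair."""
    pos_pull = np.asarray(pos_pull, dtype=float)
    pos_post = np.asarray(pos_post, dtype=float)
    rows = []
    for i, j in matching.pairs:
        vec = pos_post[j] - pos_pull[i]
        rows.append(
            {
                "pull_id": i,
                "post_id": j,
                "x_pull": pos_pull[i, 0],
                "y_pull": pos_pull[i, 1],
                "x_post": pos_post[j, 0],
                "y_post": pos_post[j, 1],
                "recoil_dx": vec[0],
                "recoil_dy": vec[1],
                "d_r_um": float(np.hypot(*vec)),
            }
        )
    cols = [
        "pull_id", "post_id", "x_pull", "y_pull", "x_post", "y_post",
        "recoil_dx", "recoil_dy", "d_r_um",
    ]
    return pd.DataFrame(rows, columns=cols)


def link_to_pre(
    tracks: pd.DataFrame, matching_post_to_pre: Matching, pre_table: pd.DataFrame
) -> pd.DataFrame:
    """Attach pre-phase identity/position/FRET to tracks via the second
    (post -> pre) matching; tracks without a pre partner are flagged."""
    post_to_pre = dict(matching_post_to_pre.pairs)
    tracks = tracks.copy()
    pre_ids, xs, ys, frets, unlinked = [], [], [], [], []
    for post_id in tracks["post_id"]:
        pre_id = post_to_pre.get(int(post_id))
        if pre_id is None:
            pre_ids.append(-1)
            xs.append(np.nan)
            ys.append(np.nan)
            frets.append(np.nan)
            unlinked.append(True)
        else:
            row = pre_table.iloc[pre_id]
            pre_ids.append(pre_id)
            xs.append(row["x_um"])
            ys.append(row["y_um"])
            frets.append(row.get("fret_index", np.nan))
            unlinked.append(False)
    tracks["pre_id"] = pre_ids
    tracks["x_pre"] = xs
    tracks["y_pre"] = ys
    tracks["fret_pre"] = frets
    tracks["unlinked_pre"] = unlinked
    return tracks


def _robust_line_angle(points: np.ndarray, max_iter: int = 50) -> tuple[float, float]:
    """Robust (bisquare IRLS) line fit through 2-D points.

    Returns (angle_deg of the fitted line in [-90, 90), SE of that angle in
    degrees).  The fit runs in a frame rotated to the principal direction
    so near-vertical configurations are handled without infinities.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    # principal direction seeds the rotation
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    theta0 = math.atan2(vt[0, 1], vt[0, 0])
    rot = np.array(
        [[math.cos(-theta0), -math.sin(-theta0)], [math.sin(-theta0), math.cos(-theta0)]]
    )
    uv = centered @ rot.T
    u, v = uv[:, 0], uv[:, 1]
    n = len(u)

    w = np.ones(n)
    slope = 0.0
    prev_slope = None
    for _ in range(max_iter):
        sw = w.sum()
        ub = (w * u).sum() / sw
        vb = (w * v).sum() / sw
        duu = (w * (u - ub) ** 2).sum()
        if duu <= 0:
            break
        slope = (w * (u - ub) * (v - vb)).sum() / duu
        resid = v - (vb + slope * (u - ub))
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        # convergence is only meaningful once the weights have been applied
        if prev_slope is not None and abs(slope - prev_slope) < 1e-12:
            break
        prev_slope = slope
        if scale < 1e-12:
            break
        r = resid / (4.685 * scale)
        new_w = np.where(np.abs(r) < 1, (1 - r**2) ** 2, 0.0)
        if new_w.sum() < 2:  # degenerate re-weighting; keep previous weights
            break
        w = new_w

    sw = w.sum()
    ub = (w * u).sum() / sw
    vb = (w * v).sum() / sw
    duu = (w * (u - ub) ** 2).sum()
    resid = v - (vb + slope * (u - ub))
    dof = max(n - 2, 1)
    s2 = (w * resid**2).sum() / dof
    se_slope = math.sqrt(s2 / duu) if duu > 0 else math.inf
    # In the rotated frame the slope is ~0, so the delta-method angle SE is
    # se_slope / (1 + slope^2), converted to degrees.
    se_deg = math.degrees(se_slope / (1.0 + slope**2))
    angle_deg = math.degrees(theta0 + math.atan(slope))
    angle_deg = ((angle_deg + 90.0) % 180.0) - 90.0
    return angle_deg, se_deg


def junction_slope(
    punctum_xy: np.ndarray,
    all_xy: np.ndarray,
    radius_um: float = JUNCTION_NEIGHBOR_RADIUS_UM,
    min_points: int = JUNCTION_MIN_POINTS,
    max_se_deg: float = JUNCTION_MAX_SE_DEG,
) -> tuple[float, float, bool]:
    """Local cell-cell contact orientation at a punctum.

    Robust linear fit through the punctum and all neighbours within
    ``radius_um``.  Returns (contact angle deg, SE deg, reliable flag);
    the fit is unreliable with fewer than ``min_points`` points or an
    angle SE above ``max_se_deg``.
    """
    punctum_xy = np.asarray(punctum_xy, dtype=float)
    all_xy = np.atleast_2d(np.asarray(all_xy, dtype=float))
    d = np.hypot(*(all_xy - punctum_xy).T)
    local = all_xy[d <= radius_um]
    if len(local) < min_points:
        return math.nan, math.inf, False
    angle_deg, se_deg = _robust_line_angle(local)
    return angle_deg, se_deg, se_deg <= max_se_deg


def recoil_angle(m_r: float, m_c: float) -> float:
    """Acute angle (degrees, [0, 90]) between recoil and contact slopes."""
    return acute_angle_deg(math.degrees(math.atan(m_r)), math.degrees(math.atan(m_c)))


def acute_angle_deg(angle_a_deg: float, angle_b_deg: float) -> float:
    """Acute angle between two undirected lines given their angles."""
    d = abs(angle_a_deg - angle_b_deg) % 180.0
    return min(d, 180.0 - d)


def recoil_angle_from_vector(recoil_vec: np.ndarray, contact_angle_deg: float) -> float:
    """Acute angle between a recoil vector and the contact line; handles
    vertical recoil via atan2."""
    vec = np.asarray(recoil_vec, dtype=float)
    recoil_deg = math.degrees(math.atan2(vec[1], vec[0]))
    return acute_angle_deg(recoil_deg, contact_angle_deg)


def classify_orientation(alpha_r_deg: float, split_deg: float = ORIENTATION_SPLIT_DEG) -> str:
    """'parallel' iff the recoil angle is at most the split (default 45)."""
    if not 0.0 <= alpha_r_deg <= 90.0:
        raise ValueError("alpha_r_deg must lie in [0, 90]")
    return "parallel" if alpha_r_deg <= split_deg else "perpendicular"


def filter_tracks(
    tracks: pd.DataFrame,
    min_recoil_um: float = MIN_RECOIL_UM,
    max_dr_um: float = MAX_RECOIL_WINDOW_UM,
    neighbor_radius_um: float = 10.0,
    min_neighbors: int = 2,
    direction_tol_deg: float = 60.0,
) -> pd.DataFrame:
    """Set per-track exclusion flags.

    ``small_recoil`` (d_r below the inclusion minimum), ``out_of_window``
    (d_r above the analysis window), ``isolated`` (fewer than
    ``min_neighbors`` other tracks within ``neighbor_radius_um``) and
    ``direction_mismatch`` (recoil direction deviating more than
    ``direction_tol_deg`` from the mean of neighbouring recoils).
    Summaries downstream use unflagged tracks only.
    """
    tracks = tracks.copy()
    pos = tracks[["x_pull", "y_pull"]].to_numpy(dtype=float)
    vec = tracks[["recoil_dx", "recoil_dy"]].to_numpy(dtype=float)
    d_r = tracks["d_r_um"].to_numpy(dtype=float)
    n = len(tracks)

    small = d_r < min_recoil_um
    out = d_r > max_dr_um
    isolated = np.zeros(n, dtype=bool)
    mismatch = np.zeros(n, dtype=bool)
    if n:
        dist = cdist(pos, pos)
        np.fill_diagonal(dist, np.inf)
        for i in range(n):
            nb = np.flatnonzero(dist[i] <= neighbor_radius_um)
            if nb.size < min_neighbors:
                isolated[i] = True
                continue
            moving = nb[d_r[nb] > 0]
            if moving.size == 0 or d_r[i] == 0:
                continue
            mean_dir = (vec[moving] / d_r[moving, None]).mean(axis=0)
            if np.hypot(*mean_dir) < 1e-12:
                continue
            cosang = np.clip(
                np.dot(vec[i] / d_r[i], mean_dir / np.hypot(*mean_dir)), -1.0, 1.0
            )
            if math.degrees(math.acos(cosang)) > direction_tol_deg:
                mismatch[i] = True

    def join(*flag_sets):
        return [";".join(f for f, on in fs if on) for fs in zip(*flag_sets)] if flag_sets else []

    flags = []
    for i in range(n):
        active = []
        if isolated[i]:
            active.append("isolated")
        if mismatch[i]:
            active.append("direction_mismatch")
        if not tracks.iloc[i].get("slope_reliable", True):
            active.append("slope_unreliable")
        if small[i]:
            active.append("small_recoil")
        if out[i]:
            active.append("out_of_window")
        if tracks.iloc[i].get("unlinked_pre", False):
            active.append("unlinked_pre")
        flags.append(";".join(active))
    tracks["flags"] = flags
    return tracks


def build_tracks(
    pre_table: pd.DataFrame,
    pull_table: pd.DataFrame,
    post_table: pd.DataFrame,
    control_points: tuple[np.ndarray, np.ndarray] | None = None,
    max_disp_um: float = DEFAULT_MAX_DISP_UM,
    junction_radius_um: float = JUNCTION_NEIGHBOR_RADIUS_UM,
    min_slope_points: int = JUNCTION_MIN_POINTS,
    max_se_deg: float = JUNCTION_MAX_SE_DEG,
    min_recoil_um: float = MIN_RECOIL_UM,
    max_dr_um: float = MAX_RECOIL_WINDOW_UM,
    neighbor_radius_um: float = 10.0,
    min_neighbors: int = 2,
    direction_tol_deg: float = 60.0,
) -> pd.DataFrame:
    """End-to-end track construction from three punctum tables.

    Optional control points (pull -> post frame) drive an initial
    projective warp used only to aid the pull/post matching; recoil
    vectors are always computed from unwarped positions.  The junction
    orientation is fitted from post (relaxed) positions.
    """
    pos_pre = pre_table[["x_um", "y_um"]].to_numpy(dtype=float)
    pos_pull = pull_table[["x_um", "y_um"]].to_numpy(dtype=float)
    pos_post = post_table[["x_um", "y_um"]].to_numpy(dtype=float)

    match_pos = pos_pull
    if control_points is not None:
        h = fit_projective_map(*control_points)
        match_pos = h.apply(pos_pull)
    m1 = match_puncta(match_pos, pos_post, max_disp_um)
    tracks = compute_recoil(m1, pos_pull, pos_post)
    if tracks.empty:
        return tracks

    m2 = match_puncta(pos_post, pos_pre, max_disp_um)
    tracks = link_to_pre(tracks, m2, pre_table)
    tracks["fret_pull"] = pull_table["fret_index"].to_numpy()[tracks["pull_id"]]
    tracks["fret_post"] = post_table["fret_index"].to_numpy()[tracks["post_id"]]

    contact_deg, se_deg, reliable, alphas, orients = [], [], [], [], []
    for _, row in tracks.iterrows():
        p = np.array([row["x_post"], row["y_post"]])
        ang, se, ok = junction_slope(
            p, pos_post, radius_um=junction_radius_um,
            min_points=min_slope_points, max_se_deg=max_se_deg,
        )
        contact_deg.append(ang)
        se_deg.append(se)
        reliable.append(ok)
        if ok and row["d_r_um"] > 0:
            alpha = recoil_angle_from_vector(
                np.array([row["recoil_dx"], row["recoil_dy"]]), ang
            )
        else:
            alpha = math.nan
        alphas.append(alpha)
        orients.append(classify_orientation(alpha) if not math.isnan(alpha) else "")
    tracks["contact_angle_deg"] = contact_deg
    tracks["slope_se_deg"] = se_deg
    tracks["slope_reliable"] = reliable
    tracks["alpha_r_deg"] = alphas
    tracks["orientation"] = orients

    tracks = filter_tracks(
        tracks,
        min_recoil_um=min_recoil_um,
        max_dr_um=max_dr_um,
        neighbor_radius_um=neighbor_radius_um,
        min_neighbors=min_neighbors,
        direction_tol_deg=direction_tol_deg,
    )
    tracks.insert(0, "track_id", np.arange(len(tracks)))
    return tracks
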