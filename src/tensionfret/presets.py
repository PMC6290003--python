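"""Named calibration presets used throughout the pipeline.

Cross-talk coefficient sets are keyed by fluorophore pair; donor-only
lifetimes by construct/condition; photon minima and dim-punctum intensity
thresholds by sensor variant.  All values are overridable through run
configuration -- presets are conveniences, not hard-coded policy.
"""

from __future__ import annotations

# Cross-talk correction factors (unitless) for the two FRET pairs.
# eps_XY: bleed of true channel Y into observed channel X.
EPSILON_PRESETS: dict[str, dict[str, float]] = {
    "mTFP1-mEYFP": {
        "eps_FD": 4.9e-3,
        "eps_AD": 4.5e-4,
        "eps_DF": 0.62,
        "eps_AF": 0.092,
        "eps_DA": 2.4e-3,
        "eps_FA": 3.8e-3,
    },
    "YPet-mCherry": {
        "eps_FD": 2.4e-3,
        "eps_AD": 1.3e-4,
        "eps_DF": 0.29,
        "eps_AF": 0.056,
        "eps_DA": 0.038,
        "eps_FA": 0.13,
    },
}

# Mean donor-only lifetimes (ns), from matched acceptor-dark constructs.
DONOR_LIFETIME_NS: dict[str, float] = {
    "YPet-F40-mCherry": 2.94,
    "YPet-F40-mCherry-soft": 2.98,
    "YPet-FL-mCherry": 2.98,
    "mTFP1-F40-mEYFP": 2.52,
    "mTFP1-F40-mEYFP-drug": 2.55,
}

# Minimal photon count required for an individual punctum lifetime fit.
MIN_PHOTONS: dict[str, int] = {
    "DPII": 1000,
    "DPI": 175,
    "DPI-drug": 275,
}

# Dim-punctum threshold: minimum summed corrected acceptor intensity (a.u.).
MIN_TOTAL_ACCEPTOR_AU: dict[str, float] = {
    "DPI-TS": 5000.0,
    "DPII-TS": 2000.0,
}

# Lifetime fit start offset after the peak bin (ns).
FIT_START_OFFSET_NS: float = 0.56

# Rolling-ball background filter diameter (pixels).
ROLLING_BALL_DIAMETER_PX: int = 50

# Recoil analysis geometry defaults.
JUNCTION_NEIGHBOR_RADIUS_UM: float = 4.0
JUNCTION_MIN_POINTS: int = 3
JUNCTION_MAX_SE_DEG: float = 9.0
MIN_RECOIL_UM: float = 1.0
MAX_RECOIL_WINDOW_UM: float = 10.0
ORIENTATION_SPLIT_DEG: float = 45.0

# Default acquisition geometry (512 px fields).
PIXEL_SIZE_UM: dict[str, float] = {
    "MDCK": 70.85 / 512,
    "MEK": 61.51 / 512,
}
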