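"""Formats, table schemas, run configuration and stage chaining.

FLIM stacks are stored as multi-page TIFF (one page per time bin) with a
JSON sidecar carrying bin width and pixel size; punctum and track tables
are CSV against a versioned column schema.  ``run_pipeline`` chains
synthetic-data generation, FLIM analysis, recoil tracking and statistics
into reproducible, seeded runs with per-filter accounting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import presets
from .flim_fret import FLIMImage, analyze_flim_image, included, segment_puncta_auto
from .synthetic_scenes import (
    GroupedTableSpec,
    PullSimSpec,
    PunctumSpec,
    SceneSpec,
    make_junction_scene,
    simulate_flim_scene,
    simulate_grouped_fret_table,
    simulate_pull_sequence,
)
from .recoil_tracking import build_tracks
from .tension_stats import fit_grouped_difference

log = logging.getLogger("tensionfret")

SCHEMA_VERSION = 1

TABLE_SCHEMAS: dict[str, dict] = {
    "puncta_flim": {
        "required": [
            "image_id", "label", "x_um", "y_um", "area_px", "photons",
            "tau_ns", "fret_efficiency", "flags",
        ],
        "unique": ["image_id", "label"],
    },
    "puncta_se": {
        "required": [
            "image_id", "label", "x_um", "y_um", "area_px", "sumD", "sumF",
            "sumA", "fret_index", "flags",
        ],
        "unique": ["image_id", "label"],
    },
    "tracks": {
        "required": [
            "track_id", "x_pull", "y_pull", "x_post", "y_post", "d_r_um",
            "alpha_r_deg", "orientation", "flags",
        ],
        "unique": ["track_id"],
    },
    "grouped": {
        "required": ["value", "isTensionSensor", "imageNumber"],
        "unique": None,
    },
}


@dataclass
class ValidationReport:
    table_kind: str
    n_rows: int
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def write_flim_stack(path: str | Path, img: FLIMImage) -> Path:
    """Write a FLIM stack as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(np.asarray(img.photons), 2, 0)
    tifffile.imwrite(path, pages.astype(np.uint32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "bin_width_ns": img.bin_width_ns,
                "pixel_size_um": img.pixel_size_um,
                "n_bins": img.n_bins,
            }
        )
    )
    return path


def read_flim_stack(path: str | Path) -> FLIMImage:
    """Read a FLIM TIFF stack, validating sidecar metadata and page count."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("bin_width_ns", "pixel_size_um", "n_bins"):
        if key not in meta:
            raise ValueError(f"sidecar missing required key {key!r}")
    if meta["bin_width_ns"] <= 0:
        raise ValueError("sidecar bin_width_ns must be positive")
    if meta["pixel_size_um"] <= 0:
        raise ValueError("sidecar pixel_size_um must be positive")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != meta["n_bins"]:
        raise ValueError(
            f"page-count mismatch: sidecar expects {meta['n_bins']} time bins, "
            f"TIFF has {pages.shape[0]} pages"
        )
    photons = np.moveaxis(pages, 0, 2)
    return FLIMImage(
        photons=photons,
        bin_width_ns=float(meta["bin_width_ns"]),
        pixel_size_um=float(meta["pixel_size_um"]),
    )


def validate_table(table: pd.DataFrame | str | Path, kind: str) -> ValidationReport:
    """Check a table against the shared schema; returns a violation report."""
    if kind not in TABLE_SCHEMAS:
        raise KeyError(f"unknown table kind {kind!r}; known: {sorted(TABLE_SCHEMAS)}")
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    schema = TABLE_SCHEMAS[kind]
    report = ValidationReport(table_kind=kind, n_rows=len(table))
    missing = [c for c in schema["required"] if c not in table.columns]
    if missing:
        report.violations.append(f"missing columns: {missing}")
        return report
    if schema["unique"]:
        dup = table.duplicated(subset=schema["unique"])
        if dup.any():
            report.violations.append(
                f"duplicated keys {tuple(schema['unique'])} in {int(dup.sum())} rows"
            )
    if "alpha_r_deg" in table.columns:
        a = table["alpha_r_deg"].dropna()
        bad = a[(a < 0) | (a > 90)]
        if len(bad):
            report.violations.append(
                f"alpha_r_deg outside [0, 90] in {len(bad)} rows"
            )
    if "d_r_um" in table.columns:
        d = table["d_r_um"].dropna()
        if (d < 0).any():
            report.violations.append("negative recoil distances")
    for col in ("value", "fret_index", "fret_efficiency"):
        if col in table.columns:
            v = table[col].to_numpy(dtype=float)
            if np.isinf(v).any():
                report.violations.append(f"non-finite values in {col!r}")
    return report


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic run."""

    out_dir: str = "runs/demo"
    seed: int = 0
    fluorophore_preset: str = "mTFP1-mEYFP"
    donor_construct: str = "mTFP1-F40-mEYFP"
    min_photons: int = presets.MIN_PHOTONS["DPI"]
    band_pass: tuple[float, float] = (3.0, 10.0)
    threshold_sd: float = 1.0
    min_area: int = 9
    ci_level: float = 0.95
    # synthetic experiment design
    n_images_per_arm: int = 4
    puncta_per_image: int = 4
    true_delta_e: float = 0.05
    baseline_e: float = 0.25  # control-arm FRET efficiency
    image_shape: tuple[int, int] = (48, 48)
    punctum_peak: float = 120.0
    n_bins: int = 64
    # recoil stage
    pull_gain_per_um: float = 1.0
    min_recoil_um: float = presets.MIN_RECOIL_UM
    max_dr_um: float = presets.MAX_RECOIL_WINDOW_UM

    def __post_init__(self) -> None:
        if self.fluorophore_preset not in presets.EPSILON_PRESETS:
            raise ValueError(f"unknown fluorophore preset {self.fluorophore_preset!r}")
        if self.donor_construct not in presets.DONOR_LIFETIME_NS:
            raise ValueError(f"unknown donor construct {self.donor_construct!r}")
        for name in ("min_photons", "min_area", "n_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def tau_d_ns(self) -> float:
        return presets.DONOR_LIFETIME_NS[self.donor_construct]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("band_pass", "image_shape"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


STAGES = ("simulate", "flim", "recoil", "stats")
_STAGE_DEPS = {
    "simulate": [],
    "flim": ["flim_stacks"],
    "recoil": ["pull_tables"],
    "stats": ["puncta_flim"],
}


def _filter_accounting(table: pd.DataFrame) -> dict:
    flags = table["flags"].fillna("")
    counts: dict[str, int] = {}
    for f in flags:
        for name in filter(None, f.split(";")):
            counts[name] = counts.get(name, 0) + 1
    passed = int((flags == "").sum())
    acct = {
        "input_rows": len(table),
        "passed": passed,
        "flagged": len(table) - passed,
        "by_flag": counts,
    }
    assert acct["input_rows"] == acct["passed"] + acct["flagged"]
    return acct


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages of a synthetic end-to-end run.

    Stage artifacts and a structured JSON log (parameters, seeds, filter
    accounting) are written under ``config.out_dir``; runs are idempotent
    for a fixed seed.  A stage whose inputs are missing raises before any
    computation.
    """
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.out_dir)

    # dependency check up front
    available = set()
    for s in stages:
        if s == "simulate":
            available.update({"flim_stacks", "pull_tables", "grouped_table"})
        missing = [d for d in _STAGE_DEPS[s] if d not in available]
        for d in list(missing):
            if d == "flim_stacks" and (out / "stacks").exists():
                missing.remove(d)
            elif d == "pull_tables" and (out / "pull").exists():
                missing.remove(d)
            elif d == "puncta_flim" and (out / "puncta_flim.csv").exists():
                missing.remove(d)
        if missing:
            raise ValueError(f"stage {s!r} missing dependencies: {missing}")
        available.add({"flim": "puncta_flim", "recoil": "tracks", "stats": "results"}[s] if s != "simulate" else "simulate")

    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"config": asdict(config), "stages": {}, "seed": config.seed}
    rng = np.random.default_rng(config.seed)
    tau_d = config.tau_d_ns

    if "simulate" in stages:
        stack_dir = out / "stacks"
        stack_dir.mkdir(exist_ok=True)
        manifest = []
        for arm, e_true in (
            ("ctrl", config.baseline_e),
            ("TS", config.baseline_e - config.true_delta_e),  # tension lowers TS FRET
        ):
            tau_true = tau_d * (1.0 - e_true)
            for i in range(config.n_images_per_arm):
                h, w = config.image_shape
                spots = []
                for _ in range(config.puncta_per_image):
                    r = rng.uniform(6, h - 6)
                    c = rng.uniform(6, w - 6)
                    if all((r - s.center_px[0]) ** 2 + (c - s.center_px[1]) ** 2 > 144 for s in spots):
                        spots.append(PunctumSpec((r, c), 1.5, config.punctum_peak, tau_true))
                scene = SceneSpec(
                    image_shape=config.image_shape,
                    puncta=spots,
                    background_level=0.2,
                    n_bins=config.n_bins,
                    seed=int(rng.integers(2**31)),
                )
                img, _truth = simulate_flim_scene(scene)
                name = f"{arm}_{i:02d}.tif"
                write_flim_stack(stack_dir / name, img)
                manifest.append({"file": name, "arm": arm, "image": f"{arm}_{i:02d}"})
        pd.DataFrame(manifest).to_csv(stack_dir / "manifest.csv", index=False)

        # pull-sequence tables for the recoil stage
        pull_dir = out / "pull"
        pull_dir.mkdir(exist_ok=True)
        base, polyline = make_junction_scene(seed=int(rng.integers(2**31)))
        hmat = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 4.0], [0.0, 0.0, 1.0]])
        seq = simulate_pull_sequence(
            PullSimSpec(
                base_scene=base,
                homography=hmat,
                recoil_fraction=1.0,
                junction_polyline=polyline,
                seed=int(rng.integers(2**31)),
            )
        )
        for phase, tab in seq.tables.items():
            tab.to_csv(pull_dir / f"{phase}.csv", index=False)
        src, dst = seq.control_points
        pd.DataFrame(
            {"x_src": src[:, 0], "y_src": src[:, 1], "x_dst": dst[:, 0], "y_dst": dst[:, 1]}
        ).to_csv(pull_dir / "control_points.csv", index=False)
        seq.truth.to_csv(pull_dir / "truth.csv", index=False)

        grouped = simulate_grouped_fret_table(
            GroupedTableSpec(seed=int(rng.integers(2**31)))
        )
        grouped.to_csv(out / "grouped_table.csv", index=False)
        run_log["stages"]["simulate"] = {
            "n_stacks": len(manifest),
            "pull_puncta": len(seq.truth),
        }

    if "flim" in stages:
        stack_dir = out / "stacks"
        manifest = pd.read_csv(stack_dir / "manifest.csv")
        tables = []
        for _, row in manifest.iterrows():
            img = read_flim_stack(stack_dir / row["file"])
            seg = segment_puncta_auto(
                img.intensity,
                band_pass=config.band_pass,
                threshold_sd=config.threshold_sd,
                min_area=config.min_area,
            )
            tab = analyze_flim_image(
                img, seg, tau_d, mode="per_punctum",
                min_photons=config.min_photons, image_id=row["image"],
            )
            tab["arm"] = row["arm"]
            tables.append(tab)
        puncta = pd.concat(tables, ignore_index=True)
        puncta.to_csv(out / "puncta_flim.csv", index=False)
        run_log["stages"]["flim"] = _filter_accounting(puncta)

    if "recoil" in stages:
        pull_dir = out / "pull"
        tabs = {p: pd.read_csv(pull_dir / f"{p}.csv") for p in ("pre", "pull", "post")}
        cp = pd.read_csv(pull_dir / "control_points.csv")
        tracks = build_tracks(
            tabs["pre"], tabs["pull"], tabs["post"],
            control_points=(
                cp[["x_src", "y_src"]].to_numpy(),
                cp[["x_dst", "y_dst"]].to_numpy(),
            ),
            min_recoil_um=config.min_recoil_um,
            max_dr_um=config.max_dr_um,
        )
        tracks.to_csv(out / "tracks.csv", index=False)
        run_log["stages"]["recoil"] = _filter_accounting(tracks)

    if "stats" in stages:
        puncta = pd.read_csv(out / "puncta_flim.csv")
        ok = included(puncta.assign(flags=puncta["flags"].fillna("")))
        obs = pd.DataFrame(
            {
                "value": ok["fret_efficiency"] * 100.0,
                "isTensionSensor": (ok["arm"] == "TS").astype(int),
                "imageNumber": ok["image_id"],
            }
        )
        res = fit_grouped_difference(obs, ci_level=config.ci_level)
        results = pd.DataFrame(
            [
                {
                    "contrast": "delta_E_percent",
                    "estimate": res.delta,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "n_puncta": res.n_puncta,
                    "n_images": res.n_images,
                    "flags": ";".join(res.flags),
                }
            ]
        )
        results.to_csv(out / "results.csv", index=False)
        run_log["stages"]["stats"] = {
            "delta": res.delta,
            "ci": [res.ci_low, res.ci_high],
            "n_puncta": res.n_puncta,
            "n_images": res.n_images,
        }

    config.to_yaml(out / "config.yaml")
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=float))
    return run_log
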