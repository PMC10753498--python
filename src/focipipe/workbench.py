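"""Workbench: plate layouts, run configuration, pipeline composition,
screen-design utilities, file I/O and the command-line interface."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import click
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.segmentation import find_boundaries

from . import aggregate, coloc_frap, foci, nuclei, preprocess, score, synthetic_scenes
from .aggregate import QCRules, qc_position, summarize_track
from .foci import PRIMARY_FOCI, SECONDARY_FOCI, FociProfile, detect_foci
from .nuclei import (
    PERMISSIVE_THRESHOLDS,
    PRIMARY_SEGMENTATION,
    SECONDARY_SEGMENTATION,
    SegmentationProfile,
    filter_viable,
    segment_nuclei,
)
from .preprocess import CropSpec, correct_vignetting, crop_margins, power_loglog_slope, subtract_background
from .score import (
    DEFAULT_PSEUDOCOUNT,
    PositionResult,
    call_hits,
    control_stats,
    position_readout,
    summarize_sirna,
    zscore_positions,
)
from .synthetic_scenes import PlateDataset, SceneParams, ScenePosition, TimeLapse
from .tracking import build_tracks

__all__ = [
    "WellInfo",
    "PlateLayout",
    "AnalysisSettings",
    "RunConfig",
    "PositionAnalysis",
    "ScreenResult",
    "analyze_position",
    "run_screen",
    "run_pipeline",
    "render_overlay",
    "save_overlay",
    "sirna_final_concentration",
    "normalize_well",
    "main",
]

log = logging.getLogger(__name__)

ROLES = synthetic_scenes.WELL_ROLES


def normalize_well(well: str) -> str:
    """Normalize well ids to letter + 2-digit form (A1 -> A01)."""
    well = well.strip().upper()
    if len(well) < 2 or not well[0].isalpha() or not well[1:].isdigit():
        raise ValueError(f"malformed well id {well!r}")
    return f"{well[0]}{int(well[1:]):02d}"


@dataclass(frozen=True)
class WellInfo:
    sirna: str
    gene: str
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")


@dataclass
class PlateLayout:
    """Well -> siRNA assignment for one plate."""

    plate_id: str
    wells: dict[str, WellInfo] = field(default_factory=dict)

    def add(self, well: str, sirna: str, gene: str = "", role: str = "library") -> None:
        w = normalize_well(well)
        if w in self.wells:
            raise ValueError(f"duplicate well id {w}")
        self.wells[w] = WellInfo(sirna=sirna, gene=gene, role=role)

    def validate_for_scoring(self) -> None:
        n_neg = sum(1 for i in self.wells.values() if i.role == "sNEG1")
        if n_neg < 2:
            raise ValueError("layout needs >= 2 sNEG1 wells for scoring")

    def genes(self) -> dict[str, str]:
        return {i.sirna: i.gene for i in self.wells.values() if i.role != "empty"}

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        df = pd.read_csv(path, dtype=str).fillna("")
        required = {"well", "sirna", "role"}
        if not required.issubset(df.columns):
            raise ValueError(f"layout CSV must contain columns {sorted(required)}")
        plate_id = str(df["plate"].iloc[0]) if "plate" in df.columns and len(df) else "plate1"
        layout = cls(plate_id=plate_id)
        for _, row in df.iterrows():
            layout.add(
                row["well"],
                sirna=row["sirna"],
                gene=row.get("gene", ""),
                role=row["role"],
            )
        return layout

    def to_csv(self, path) -> None:
        rows = [
            {"plate": self.plate_id, "well": w, "sirna": i.sirna, "gene": i.gene, "role": i.role}
            for w, i in sorted(self.wells.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AnalysisSettings:
    """Every analysis parameter in one place, echoed to run metadata."""

    screen: str = "primary"                      # 'primary' | 'secondary'
    crop: Optional[CropSpec] = None              # None skips cropping
    background_smooth_fwhm: float = 6.0
    background_min_diameter: float = 15.0
    segmentation: SegmentationProfile = PRIMARY_SEGMENTATION
    foci_profile: FociProfile = PRIMARY_FOCI
    viability_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(PERMISSIVE_THRESHOLDS)
    )
    max_distance: float = 15.0
    min_persistence: int = 2
    gap_fill: str = "previous"
    qc_rules: QCRules = QCRules()
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @classmethod
    def for_screen(cls, screen: str, **overrides) -> "AnalysisSettings":
        if screen == "primary":
            base = cls(screen="primary", segmentation=PRIMARY_SEGMENTATION, foci_profile=PRIMARY_FOCI)
        elif screen == "secondary":
            base = cls(screen="secondary", segmentation=SECONDARY_SEGMENTATION, foci_profile=SECONDARY_FOCI)
        else:
            raise ValueError("screen must be 'primary' or 'secondary'")
        return replace(base, **overrides) if overrides else base


_RUNCONFIG_KEYS = {
    "screen",
    "input_dir",
    "output_dir",
    "layout_csv",
    "illumination_tiff",
    "seed",
    "crop",
    "viability_thresholds",
    "qc",
    "pseudocount",
    "up_threshold",
    "down_threshold",
}


@dataclass
class RunConfig:
    """Parsed run configuration (YAML); unknown keys are rejected."""

    screen: str = "primary"
    input_dir: str = "."
    output_dir: str = "out"
    layout_csv: str = "layout.csv"
    illumination_tiff: Optional[str] = None
    seed: int = 0
    crop: Optional[dict] = None
    viability_thresholds: Optional[dict] = None
    qc: Optional[dict] = None
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    up_threshold: float = 3.0
    down_threshold: float = -2.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_metadata(self) -> dict:
        return asdict(self)

    def settings(self) -> AnalysisSettings:
        overrides = {}
        if self.crop is not None:
            overrides["crop"] = CropSpec(**self.crop)
        if self.viability_thresholds is not None:
            thr = dict(PERMISSIVE_THRESHOLDS)
            thr.update(self.viability_thresholds)
            overrides["viability_thresholds"] = thr
        if self.qc is not None:
            qc = dict(self.qc)
            if "plls_range" in qc and qc["plls_range"] is not None:
                qc["plls_range"] = tuple(qc["plls_range"])
            overrides["qc_rules"] = QCRules(**qc)
        overrides["pseudocount"] = self.pseudocount
        return AnalysisSettings.for_screen(self.screen, **overrides)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PositionAnalysis:
    position_id: str
    readout: Optional[float]            # None when no tracks survived
    n_tracks: int
    qc: aggregate.PositionQC
    track_summaries: list[aggregate.TrackSummary]
    nuclei_table: pd.DataFrame
    foci_table: pd.DataFrame
    plls: list[float]


def analyze_position(
    frames: np.ndarray,
    settings: AnalysisSettings,
    illumination: Optional[np.ndarray] = None,
    frame_interval: float = 12.0,
    position_id: str = "pos",
) -> PositionAnalysis:
    """Run preprocess -> nuclei -> foci -> tracking -> aggregation on one
    time lapse (array of shape (T, H, W))."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("expected a (T, H, W) stack; channel-stacked input is rejected")
    per_frame_nuclei: list[list[nuclei.NucleusObject]] = []
    per_frame_foci: list[list[foci.FocusObject]] = []
    plls_vals: list[float] = []
    cell_counts: list[int] = []
    intensities: list[float] = []
    n_total_objects = 0
    n_kept_objects = 0
    nuc_rows = []
    foc_rows = []
    for t in range(frames.shape[0]):
        raw = frames[t]
        plls_vals.append(power_loglog_slope(raw))
        img = raw
        if illumination is not None:
            img = correct_vignetting(img, illumination)
        if settings.crop is not None:
            img = crop_margins(img, settings.crop)
        corrected, _bg = subtract_background(
            img,
            smooth_fwhm=settings.background_smooth_fwhm,
            min_diameter=settings.background_min_diameter,
        )
        objs = segment_nuclei(corrected, settings.segmentation, frame_index=t)
        kept, removed = filter_viable(objs, settings.segmentation, settings.viability_thresholds)
        n_total_objects += len(objs)
        n_kept_objects += len(kept)
        spots = detect_foci(corrected, kept, settings.foci_profile, frame_index=t)
        per_frame_nuclei.append(kept)
        per_frame_foci.append(spots)
        cell_counts.append(len(kept))
        intensities.append(float(np.mean([o.integrated_intensity for o in kept])) if kept else 0.0)
        for o in kept:
            nuc_rows.append(
                {
                    "frame": t,
                    "label": o.label,
                    "y": o.centroid[0],
                    "x": o.centroid[1],
                    "area": o.area,
                    "mean_intensity": o.mean_intensity,
                    "sd_intensity": o.sd_intensity,
                    "upper_quartile_intensity": o.upper_quartile_intensity,
                    "integrated_intensity": o.integrated_intensity,
                    "eccentricity": o.eccentricity,
                    "solidity": o.solidity,
                }
            )
        for f in spots:
            foc_rows.append(
                {
                    "frame": t,
                    "label": f.label,
                    "y": f.centroid[0],
                    "x": f.centroid[1],
                    "area": f.area,
                    "parent_nucleus": f.parent_nucleus,
                    "peak_intensity": f.peak_intensity,
                }
            )

    tracks = build_tracks(per_frame_nuclei, per_frame_foci, max_distance=settings.max_distance)
    summaries = [
        summarize_track(
            tr, frame_interval, min_persistence=settings.min_persistence, fill=settings.gap_fill
        )
        for tr in tracks
    ]
    filtered_ratio = (n_kept_objects / n_total_objects) if n_total_objects else 0.0
    qc = qc_position(
        position_id=position_id,
        n_tracks=len(tracks),
        integrated_intensities=intensities,
        cell_counts=cell_counts,
        plls_values=plls_vals,
        rules=settings.qc_rules,
        filtered_ratio=filtered_ratio,
    )
    readout = position_readout([s.mean_db_count for s in summaries]) if summaries else None
    log.info(
        "%s: %d nuclei (%d kept), %d foci, %d tracks, QC %s",
        position_id,
        n_total_objects,
        n_kept_objects,
        sum(len(f) for f in per_frame_foci),
        len(tracks),
        "pass" if qc.passed else f"FAIL {qc.failures}",
    )
    return PositionAnalysis(
        position_id=position_id,
        readout=readout,
        n_tracks=len(tracks),
        qc=qc,
        track_summaries=summaries,
        nuclei_table=pd.DataFrame(nuc_rows),
        foci_table=pd.DataFrame(foc_rows),
        plls=plls_vals,
    )


@dataclass
class ScreenResult:
    positions: pd.DataFrame     # per-position readouts and Z-scores
    sirna: pd.DataFrame         # per-siRNA mean Z, n, rank, hit class
    control_stats: dict

    def up_hits(self) -> list[str]:
        return list(self.sirna.loc[self.sirna["hit"] == "up", "sirna"])

    def down_hits(self) -> list[str]:
        return list(self.sirna.loc[self.sirna["hit"] == "down", "sirna"])


def _score_position_results(
    results: Sequence[PositionResult],
    pseudocount: float,
    up_threshold: float,
    down_threshold: float,
    genes: Optional[Mapping[str, str]] = None,
) -> ScreenResult:
    stats = control_stats(results, pseudocount=pseudocount)
    rows = zscore_positions(results, stats, pseudocount=pseudocount)
    table = summarize_sirna(rows[rows["role"] != "sNEG1"]) if not rows.empty else summarize_sirna(rows)
    table = call_hits(table, up_threshold=up_threshold, down_threshold=down_threshold, genes=genes)
    return ScreenResult(positions=rows, sirna=table, control_stats={k: asdict(v) for k, v in stats.items()})


def run_screen(
    dataset: PlateDataset,
    settings: AnalysisSettings,
    illumination: Optional[np.ndarray] = None,
    up_threshold: float = 3.0,
    down_threshold: float = -2.0,
    genes: Optional[Mapping[str, str]] = None,
) -> ScreenResult:
    """Analyze every rendered position of a dataset and score the plate."""
    results: list[PositionResult] = []
    for pos in dataset:
        if pos.timelapse is None:
            raise ValueError("dataset positions must be rendered (timelapse present)")
        pa = analyze_position(
            pos.timelapse.frames,
            settings,
            illumination=illumination,
            frame_interval=pos.timelapse.frame_interval,
            position_id=f"r{pos.replicate}/{pos.well}/p{pos.position}",
        )
        if pa.readout is None:
            log.warning("%s: zero tracks; position dropped", pa.position_id)
            continue
        results.append(
            PositionResult(
                replicate=pos.replicate,
                well=pos.well,
                position=pos.position,
                sirna=pos.sirna,
                role=pos.role,
                x=pa.readout,
                n_tracks=pa.n_tracks,
                qc_pass=pa.qc.passed,
            )
        )
    return _score_position_results(results, DEFAULT_PSEUDOCOUNT, up_threshold, down_threshold, genes)


def truth_position_results(
    dataset: PlateDataset,
    min_persistence: int = 2,
    fill: str = "previous",
) -> list[PositionResult]:
    """Position readouts computed from ground-truth focus counts.

    Bypasses pixel analysis: each cell's true count series goes through
    the same gap-closing / longest-run / mean readout path the image
    pipeline uses.  Dead and mitotic cells are excluded, mirroring the
    viability filter.
    """
    results = []
    for pos in dataset:
        vals = []
        dt = pos.params.frame_interval
        for cell in pos.truth.cells:
            if cell.viability in ("dead", "mitotic"):
                continue
            _, mean_count, _ = aggregate.summarize_counts(
                cell.counts(pos.truth.n_frames), dt, min_persistence=min_persistence, fill=fill
            )
            vals.append(mean_count)
        if not vals:
            continue
        results.append(
            PositionResult(
                replicate=pos.replicate,
                well=pos.well,
                position=pos.position,
                sirna=pos.sirna,
                role=pos.role,
                x=position_readout(vals),
                n_tracks=len(vals),
                qc_pass=True,
            )
        )
    return results


def score_truth_screen(
    dataset: PlateDataset,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    up_threshold: float = 3.0,
    down_threshold: float = -2.0,
    min_persistence: int = 2,
) -> ScreenResult:
    results = truth_position_results(dataset, min_persistence=min_persistence)
    return _score_position_results(results, pseudocount, up_threshold, down_threshold)


def run_pipeline(config: RunConfig) -> ScreenResult:
    """End-to-end run from a config: read TIFFs, analyze, score, write CSVs."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = PlateLayout.from_csv(in_dir / config.layout_csv)
    layout.validate_for_scoring()
    settings = config.settings()
    illum = None
    if config.illumination_tiff is not None:
        illum = tifffile.imread(in_dir / config.illumination_tiff).astype(float)

    results: list[PositionResult] = []
    tiffs = sorted(in_dir.glob("r*_*_p*.tif"))
    if not tiffs:
        raise FileNotFoundError(f"no position TIFFs (r<rep>_<well>_p<pos>.tif) in {in_dir}")
    for path in tiffs:
        rep_s, well, pos_s = path.stem.split("_")
        rep, posn = int(rep_s[1:]), int(pos_s[1:])
        well = normalize_well(well)
        info = layout.wells.get(well)
        if info is None or info.role == "empty":
            continue
        frames = tifffile.imread(path).astype(float)
        pa = analyze_position(
            frames, settings, illumination=illum, position_id=path.stem
        )
        pa.nuclei_table.to_csv(out_dir / f"{path.stem}_nuclei.csv", index=False)
        pa.foci_table.to_csv(out_dir / f"{path.stem}_foci.csv", index=False)
        if pa.readout is None:
            continue
        results.append(
            PositionResult(
                replicate=rep,
                well=well,
                position=posn,
                sirna=info.sirna,
                role=info.role,
                x=pa.readout,
                n_tracks=pa.n_tracks,
                qc_pass=pa.qc.passed,
            )
        )
    sr = _score_position_results(
        results, config.pseudocount, config.up_threshold, config.down_threshold, genes=layout.genes()
    )
    sr.positions.to_csv(out_dir / "positions.csv", index=False)
    sr.sirna.to_csv(out_dir / "sirna_scores.csv", index=False)
    meta = {"config": config.to_metadata(), "control_stats": sr.control_stats}
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    return sr


def render_overlay(
    frame: np.ndarray,
    kept_nuclei: Sequence[nuclei.NucleusObject],
    spots: Sequence[foci.FocusObject],
    removed_nuclei: Sequence[nuclei.NucleusObject] = (),
) -> np.ndarray:
    """Visual-QC overlay: foci-positive nuclei and focus rings in red,
    other kept nuclei in white; returns an RGB uint8 image."""
    lo, hi = float(frame.min()), float(frame.max())
    gray = np.zeros_like(frame) if hi == lo else (frame - lo) / (hi - lo)
    rgb = np.repeat((gray * 255).astype(np.uint8)[..., None], 3, axis=2)
    positive = {s.parent_nucleus for s in spots}

    def outline(objs, color):
        if not objs:
            return
        mask = np.zeros(frame.shape, dtype=bool)
        for o in objs:
            mask[o.coords[:, 0], o.coords[:, 1]] = True
        rgb[find_boundaries(mask, mode="inner")] = color

    outline([n for n in kept_nuclei if n.label not in positive], (255, 255, 255))
    outline([n for n in kept_nuclei if n.label in positive], (255, 0, 0))
    outline(list(removed_nuclei), (128, 128, 128))
    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    for s in spots:
        d2 = (yy - s.centroid[0]) ** 2 + (xx - s.centroid[1]) ** 2
        ring = (d2 >= 16) & (d2 <= 36)  # radius 4-6 px circle
        rgb[ring] = (255, 0, 0)
    return rgb


def save_overlay(path, frame, kept_nuclei, spots, removed_nuclei=()) -> None:
    iio.imwrite(Path(path), render_overlay(frame, kept_nuclei, spots, removed_nuclei))


# ---------------------------------------------------------------------------
# screen-design utility


def sirna_final_concentration(
    stock_conc: float,
    stock_vol: float,
    mix_vol: float,
    dilution_factor: float,
    dispensed_vol: float,
    medium_vol: float,
    ndigits: Optional[int] = 1,
) -> float:
    """Final per-well siRNA concentration (nM) for a reverse-transfection
    protocol: stock diluted into a mix, further diluted, a fixed volume
    dispensed per well and taken up in the final medium volume."""
    for name, v in (
        ("stock_conc", stock_conc),
        ("stock_vol", stock_vol),
        ("mix_vol", mix_vol),
        ("dilution_factor", dilution_factor),
        ("dispensed_vol", dispensed_vol),
        ("medium_vol", medium_vol),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    conc = stock_conc * stock_vol / mix_vol / dilution_factor * dispensed_vol / medium_vol
    return round(conc, ndigits) if ndigits is not None else conc


# ---------------------------------------------------------------------------
# CLI


@click.group()
def main():
    """High-content nuclear-foci screening toolkit."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


@main.command()
@click.option("--out", type=click.Path(), required=True, help="output directory")
@click.option("--seed", type=int, default=0)
@click.option("--wells", type=int, default=4, help="number of library wells")
@click.option("--positions", type=int, default=2)
@click.option("--replicates", type=int, default=1)
@click.option("--cells", type=int, default=10)
@click.option("--frames", type=int, default=10)
def simulate(out, seed, wells, positions, replicates, cells, frames):
    """Simulate a small plate: TIFF stacks, ground-truth and layout CSVs."""
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = PlateLayout(plate_id="sim1")
    for i in range(wells):
        layout.add(f"A{i + 1:02d}", sirna=f"LIB{i + 1}", gene=f"GENE{i + 1}", role="library")
    layout.add("H01", "sNEG1", role="sNEG1")
    layout.add("H02", "sNEG1", role="sNEG1")
    layout.add("H03", "sNEG1", role="sNEG1")
    layout.to_csv(out_dir / "layout.csv")
    base = SceneParams(
        image_shape=(256, 256),
        n_cells=cells,
        n_frames=frames,
        nucleus_radius_mean=20.0,
        noise_sd=0.004,
    )
    ds = synthetic_scenes.generate_plate(
        layout, base, n_positions=positions, seed=seed, n_replicates=replicates
    )
    truth_frames = []
    for pos in ds:
        stem = f"r{pos.replicate}_{pos.well}_p{pos.position}"
        tifffile.imwrite(
            out_dir / f"{stem}.tif", pos.timelapse.frames, photometric="minisblack"
        )
        df = pos.truth.to_frame()
        df.insert(0, "position", pos.position)
        df.insert(0, "well", pos.well)
        df.insert(0, "replicate", pos.replicate)
        truth_frames.append(df)
    pd.concat(truth_frames).to_csv(out_dir / "ground_truth.csv", index=False)
    click.echo(f"wrote {len(ds)} positions to {out_dir}")


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
def analyze(config_path):
    """Run the full pipeline from a YAML config."""
    sr = run_pipeline(RunConfig.from_yaml(config_path))
    click.echo(sr.sirna.to_string(index=False))


@main.command("score")
@click.option("--positions-csv", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--up", type=float, default=3.0)
@click.option("--down", type=float, default=-2.0)
@click.option("--pseudocount", type=float, default=DEFAULT_PSEUDOCOUNT)
def score_cmd(positions_csv, out, up, down, pseudocount):
    """Score a per-position readout CSV (replicate, well, position, sirna,
    role, x, n_tracks, qc_pass) into a per-siRNA table."""
    df = pd.read_csv(positions_csv)
    results = [
        PositionResult(
            replicate=int(r.replicate),
            well=str(r.well),
            position=int(r.position),
            sirna=str(r.sirna),
            role=str(r.role),
            x=float(r.x),
            n_tracks=int(r.n_tracks),
            qc_pass=bool(r.qc_pass),
        )
        for r in df.itertuples()
    ]
    sr = _score_position_results(results, pseudocount, up, down)
    sr.sirna.to_csv(out, index=False)
    click.echo(f"wrote {out}")


@main.command()
@click.option("--tiff", type=click.Path(exists=True), required=True, help="2-page TIFF: ch1, ch2")
@click.option("--ch2-threshold", type=float, default=0.0)
def coloc(tiff, ch2_threshold):
    """Manders M1 of channel 1 vs channel 2 for a two-channel TIFF."""
    stack = tifffile.imread(tiff).astype(float)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise click.ClickException("expected a 2-page (channel) TIFF")
    m1 = coloc_frap.manders_m1(stack[0], stack[1], ch2_threshold=ch2_threshold)
    click.echo(json.dumps({"M1": m1}))


@main.command()
@click.option("--csv", "csv_path", type=click.Path(exists=True), required=True, help="columns t,I")
@click.option("--out", type=click.Path(), default=None)
def frap(csv_path, out):
    """Normalize and fit a FRAP curve from a (t, I) CSV."""
    df = pd.read_csv(csv_path)
    t = df.iloc[:, 0].to_numpy(float)
    y = df.iloc[:, 1].to_numpy(float)
    bleach = int(np.searchsorted(t, 0.0))
    curve = synthetic_scenes.FrapCurve(times=t, intensities=y, bleach_index=bleach)
    fit = coloc_frap.fit_frap(coloc_frap.normalize_frap(curve))
    payload = json.dumps(asdict(fit), indent=2)
    if out:
        Path(out).write_text(payload)
    click.echo(payload)


@main.command()
@click.option("--results", type=click.Path(exists=True), required=True, help="sirna_scores.csv")
def report(results):
    """Print hit lists from a per-siRNA score table."""
    df = pd.read_csv(results)
    up = df[df["hit"] == "up"]["sirna"].tolist()
    down = df[df["hit"] == "down"]["sirna"].tolist()
    click.echo(json.dumps({"up_hits": up, "down_hits": down, "n_sirna": len(df)}))


@main.command()
@click.option("--stock-conc", type=float, required=True)
@click.option("--stock-vol", type=float, required=True)
@click.option("--mix-vol", type=float, required=True)
@click.option("--dilution-factor", type=float, default=1.0)
@click.option("--dispensed-vol", type=float, required=True)
@click.option("--medium-vol", type=float, required=True)
def conc(**kw):
    """Final per-well siRNA concentration (nM) for a transfection protocol."""
    click.echo(f"{sirna_final_concentration(**kw)} nM")


if __name__ == "__main__":
    main()
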