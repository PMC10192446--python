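"""End-to-end orchestration: simulate -> sample -> segment -> count -> estimate.

A :class:`RunConfig` captures every knob of a run (geometry, rendering,
counting method, seed) and is fully serializable to YAML; re-running a
persisted config reproduces all deterministic stages bit-identically.  Every
random stage draws its own child seed from the single run seed, and all
consumed seeds are echoed into the provenance log for forensic replay.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .counting import CountResult, count_disector, count_projection, counts_to_frame
from .errors import ConfigError
from .estimation import ScaffoldEstimate, scaffold_estimate
from .io import write_stack
from .sampling import (
    DEFAULT_FIELD_AREA_MM2,
    SamplingDesign,
    design_columns,
    points_in_column,
)
from .segmentation import (
    SegmentationModel,
    default_min_area_px,
    label_and_filter,
    max_project,
    segment,
    to_8bit,
)
from .simulate import (
    PointPattern,
    RenderConfig,
    ScaffoldSpec,
    generate_points,
    rasterize_projection,
    rasterize_sections,
    render_stack,
)

#: Seeding density (cells/ul) above which touching-nucleus watershed
#: splitting defaults to on (overlaps start to matter at the two highest
#: densities of the validation design: >= 250k cells per 500-ul scaffold).
SPLIT_DENSITY_THRESHOLD_PER_UL = 500.0


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulated-scaffold analysis."""

    seed: int = 0
    # scaffold
    scaffold_volume_ul: float = 500.0
    xy_extent_mm: tuple[float, float] = (15.6, 15.6)
    n_cells: int = 10_000
    pattern: str = "uniform"
    cluster_mean_offspring: float = 5.0
    cluster_sd_mm: float = 0.05
    # sampling design
    grid: tuple[int, int] = (3, 3)
    field_area_mm2: float = DEFAULT_FIELD_AREA_MM2
    n_sections: int = 30
    z_spacing_mm: float = 0.02
    # rendering
    pixel_size_um: float = 1.3
    background_level: float = 100.0
    blob_amplitude: float = 1200.0
    psf_sigma_xy_um: float = 3.0
    psf_sigma_z_um: float = 12.0
    noise_model: str = "gaussian"
    noise_sd: float = 80.0
    bit_depth: int = 16
    # counting
    method: str = "projection"  # "projection" | "disector"
    masks: str = "otsu"  # "model" | "otsu" | "ideal"
    model_path: str | None = None
    split_touching: bool | None = None  # None -> on above the density threshold
    min_area_px: int | None = None
    min_overlap_frac: float = 0.0
    # output
    out_dir: str | None = None
    write_stacks: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("projection", "disector"):
            raise ConfigError("method must be 'projection' or 'disector'")
        if self.masks not in ("model", "otsu", "ideal"):
            raise ConfigError("masks must be 'model', 'otsu' or 'ideal'")
        if self.masks == "model" and not self.model_path:
            raise ConfigError("masks='model' requires model_path")

    def scaffold_spec(self) -> ScaffoldSpec:
        return ScaffoldSpec(
            volume_ul=self.scaffold_volume_ul,
            xy_extent=tuple(self.xy_extent_mm),
            n_cells=self.n_cells,
            pattern=self.pattern,
            cluster_mean_offspring=self.cluster_mean_offspring,
            cluster_sd_mm=self.cluster_sd_mm,
        )

    def render_config(self) -> RenderConfig:
        return RenderConfig(
            pixel_size=self.pixel_size_um,
            background_level=self.background_level,
            blob_amplitude=self.blob_amplitude,
            psf_sigma_xy=self.psf_sigma_xy_um,
            psf_sigma_z=self.psf_sigma_z_um,
            noise_model=self.noise_model,
            noise_sd=self.noise_sd,
            bit_depth=self.bit_depth,
        )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["xy_extent_mm"] = list(d["xy_extent_mm"])
        d["grid"] = list(d["grid"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["xy_extent_mm"] = tuple(d["xy_extent_mm"])
        d["grid"] = tuple(d["grid"])
        return RunConfig(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["xy_extent_mm"] = list(d["xy_extent_mm"])
        d["grid"] = list(d["grid"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Everything a run produced, plus its provenance."""

    estimate: ScaffoldEstimate
    counts: list[CountResult]
    truth_counts: list[int]
    design: SamplingDesign
    points: PointPattern
    provenance: dict = field(default_factory=dict)


def _auto_split(config: RunConfig) -> bool:
    if config.split_touching is not None:
        return config.split_touching
    density = config.n_cells / config.scaffold_volume_ul
    return density >= SPLIT_DENSITY_THRESHOLD_PER_UL


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run one simulated scaffold through the full counting pipeline."""
    ss = np.random.SeedSequence(config.seed)
    n_cols = config.grid[0] * config.grid[1]
    children = ss.spawn(2 + n_cols)
    seed_points = int(children[0].generate_state(1)[0] % 2**31)
    seed_design = int(children[1].generate_state(1)[0] % 2**31)
    seeds_render = [
        int(c.generate_state(1)[0] % 2**31) for c in children[2:]
    ]

    scaffold = config.scaffold_spec()
    points = generate_points(scaffold, seed_points)
    design = design_columns(
        scaffold,
        grid=tuple(config.grid),
        field_area_mm2=config.field_area_mm2,
        n_sections=config.n_sections,
        z_spacing=config.z_spacing_mm,
        seed=seed_design,
    )

    model = None
    if config.masks == "model":
        model = SegmentationModel.load(config.model_path)
    rcfg = config.render_config()
    min_area = (
        config.min_area_px
        if config.min_area_px is not None
        else default_min_area_px(config.pixel_size_um)
    )
    split = _auto_split(config)
    nucleus_r_px = 5.0 / config.pixel_size_um

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    counts: list[CountResult] = []
    truth: list[int] = []
    for i, col in enumerate(design.columns):
        truth.append(points_in_column(points, col))
        if config.method == "projection":
            if config.masks == "ideal":
                mask = rasterize_projection(points, col, config.pixel_size_um)
            else:
                stack = render_stack(points, col, rcfg, seed=seeds_render[i])
                if out_dir and config.write_stacks:
                    write_stack(stack, out_dir / f"col_{col.column_id}.tif")
                proj = max_project(to_8bit(stack))
                fg = segment(
                    proj,
                    model=model,
                    threshold_fallback="otsu" if model is None else None,
                )
                mask = label_and_filter(
                    fg, min_area_px=min_area, split_touching=split,
                    nucleus_radius_px=nucleus_r_px,
                )
            counts.append(count_projection(mask, col))
        else:
            acq = col.with_lookup_section()
            if config.masks == "ideal":
                masks = rasterize_sections(points, acq, config.pixel_size_um)
            else:
                stack = render_stack(points, acq, rcfg, seed=seeds_render[i])
                if out_dir and config.write_stacks:
                    write_stack(stack, out_dir / f"col_{col.column_id}.tif")
                s8 = to_8bit(stack)
                masks = []
                for section in s8.voxels:
                    fg = segment(
                        section,
                        model=model,
                        threshold_fallback="otsu" if model is None else None,
                    )
                    lm = label_and_filter(fg, min_area_px=min_area)
                    lm.provenance = "section"
                    masks.append(lm)
            counts.append(
                count_disector(masks, col, min_overlap_frac=config.min_overlap_frac)
            )

    v_col = design.columns[0].volume_ul
    estimate = scaffold_estimate(counts, v_col, config.scaffold_volume_ul)

    provenance = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "seeds": {
            "points": seed_points,
            "design": seed_design,
            "render": seeds_render,
        },
        "method": config.method,
        "masks": config.masks,
        "split_touching": split,
        "min_area_px": min_area,
        "per_column_counts": [c.count for c in counts],
        "per_column_truth": truth,
    }

    if out_dir:
        design.to_csv(out_dir / "design.csv")
        points.to_csv(out_dir / "points.csv")
        counts_to_frame(counts).to_csv(out_dir / "counts.csv", index=False)
        estimate.to_frame(method=config.method).to_csv(
            out_dir / "estimate.csv", index=False
        )
        config.to_yaml(out_dir / "config.yaml")
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return PipelineReport(
        estimate=estimate,
        counts=counts,
        truth_counts=truth,
        design=design,
        points=points,
        provenance=provenance,
    )
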