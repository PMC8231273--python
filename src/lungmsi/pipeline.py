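"""End-to-end pipeline: generate → extract → normalize → threshold → spatial
statistics → group comparisons, with a reproducible run manifest.

Every numeric output is a deterministic function of the configuration (which
includes the seed): rerunning the pipeline with the same config reproduces
byte-identical tables and JSON.  The run manifest records the config hash,
seed, package version, per-file checksums and accumulated warnings (dropped
pixels, zero-reference pixels, outside-border pixels).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .groupstats import compare_clump_stats, compare_distance_bins
from .imzml import MSIDataset, write_msi
from .ionmap import (
    DEFAULT_TARGETS,
    IonImage,
    IonTarget,
    TissueMask,
    above_threshold_map,
    control_threshold,
    extract_ion_image,
    normalize_image,
    tissue_mask_from_heme,
)
from .spatial import (
    DEFAULT_BIN_EDGES_MM,
    alpha_hull_border,
    clump_summary,
    distance_profile,
    find_clumps,
    quartile_bin,
    zscore_section,
)
from .synthetic import GeneratorParams, generate_cohort

__all__ = ["PipelineConfig", "PipelineStageError", "run_full_pipeline", "render_maps"]

logger = logging.getLogger("lungmsi.pipeline")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and section id."""

    def __init__(self, stage: str, section_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on section {section_id!r}: {cause}")
        self.stage = stage
        self.section_id = section_id


@dataclass
class PipelineConfig:
    """Everything a run needs; hashable so the manifest can pin it."""

    targets: dict[str, IonTarget] = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    analyte: str = "budesonide"
    reference: str = "internal_standard"
    tissue_marker: str = "heme"
    threshold_quantile: float = 0.99
    tissue_min_fraction: float = 0.05
    connectivity: str = "8-neighbor"
    alpha_mm: float = 1.2  # 3 x pixel pitch
    bin_edges_mm: tuple[float, ...] = DEFAULT_BIN_EDGES_MM
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    n_per_group: int = 5
    seed: int = 0
    output_dir: str = "lungmsi_out"

    def validate(self) -> None:
        for role in (self.analyte, self.reference, self.tissue_marker):
            if role not in self.targets:
                raise ValueError(f"ion target {role!r} missing from the registry")
        if not 0 < self.threshold_quantile <= 1:
            raise ValueError("threshold_quantile must be in (0, 1]")
        if len(self.bin_edges_mm) < 2:
            raise ValueError("need at least two distance-bin edges")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["targets"] = {k: asdict(t) for k, t in self.targets.items()}
        d["bin_edges_mm"] = list(self.bin_edges_mm)
        d.pop("output_dir")  # where results land does not affect the numbers
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        targets = raw.pop("targets", None)
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if targets is not None:
            cfg.targets = {k: IonTarget(**v) for k, v in targets.items()}
        if gen is not None:
            gen["grid_shape"] = tuple(gen.get("grid_shape", (50, 125)))
            cfg.generator = GeneratorParams(**gen)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_raster_csv(path: Path, values: np.ndarray) -> None:
    pd.DataFrame(values).to_csv(path, index=False, header=False, float_format="%.8g")


def _write_border_txt(path: Path, rings: list[np.ndarray]) -> None:
    lines = []
    for i, ring in enumerate(rings):
        lines.append(f"# ring {i} ({len(ring)} vertices, mm)")
        lines.extend(f"{x:.6f}\t{y:.6f}" for x, y in ring)
    path.write_text("\n".join(lines) + "\n")


def _section_images(dataset: MSIDataset, config: PipelineConfig):
    """Extraction + normalization + masking for one section."""
    analyte = extract_ion_image(dataset, config.targets[config.analyte])
    reference = extract_ion_image(dataset, config.targets[config.reference])
    heme = extract_ion_image(dataset, config.targets[config.tissue_marker])
    mask = tissue_mask_from_heme(heme, min_fraction=config.tissue_min_fraction)
    normalized, dropped = normalize_image(analyte, reference)
    return normalized, mask, dropped


def run_full_pipeline(
    config: PipelineConfig,
    datasets: list[MSIDataset] | None = None,
    write_imzml: bool = False,
) -> dict:
    """Run the whole analysis and write the report bundle to ``output_dir``.

    ``datasets`` may carry a pre-loaded cohort (e.g. read back from imzML);
    otherwise a synthetic cohort is generated from the config.  Returns the
    summary dict that is also written to ``summary.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    sections_dir = out / "sections"
    sections_dir.mkdir(parents=True, exist_ok=True)

    t_start = time.perf_counter()
    if datasets is None:
        logger.info("generating cohort: %d per group + 2 controls", config.n_per_group)
        datasets = generate_cohort(config.n_per_group, config.seed, config.generator)
    if write_imzml:
        raw_dir = out / "imzml"
        raw_dir.mkdir(exist_ok=True)
        manifest_rows = []
        for ds in datasets:
            write_msi(ds, raw_dir / f"{ds.section_id}.imzML")
            manifest_rows.append(
                {"section_id": ds.section_id, "group": ds.group_label,
                 "path": f"imzml/{ds.section_id}.imzML"}
            )
        pd.DataFrame(manifest_rows).to_csv(out / "cohort_manifest.tsv", sep="\t", index=False)

    # --- stage 1: ion maps and tissue masks -------------------------------
    per_section: dict[str, dict] = {}
    images: dict[str, IonImage] = {}
    masks: dict[str, TissueMask] = {}
    for ds in datasets:
        t0 = time.perf_counter()
        try:
            normalized, mask, dropped = _section_images(ds, config)
        except Exception as exc:
            raise PipelineStageError("ion_mapping", ds.section_id, exc) from exc
        images[ds.section_id] = normalized
        masks[ds.section_id] = mask
        per_section[ds.section_id] = {
            "group": ds.group_label,
            "tissue_pixels": mask.n_pixels,
            "zero_reference_dropped": dropped,
        }
        logger.info("mapped %s (%.2fs)", ds.section_id, time.perf_counter() - t0)

    # --- stage 2: control-derived threshold -------------------------------
    control_ids = [ds.section_id for ds in datasets if ds.group_label == "CTRL"]
    threshold = None
    if control_ids:
        try:
            threshold = control_threshold(
                [images[i] for i in control_ids],
                [masks[i] for i in control_ids],
                config.threshold_quantile,
            )
        except Exception as exc:
            raise PipelineStageError("control_threshold", ",".join(control_ids), exc) from exc
        logger.info("control threshold (q=%g): %g", config.threshold_quantile, threshold)

    # --- stage 3: spatial statistics per section --------------------------
    profiles: dict[str, object] = {}
    for ds in datasets:
        sid = ds.section_id
        if ds.group_label == "CTRL":
            continue
        t0 = time.perf_counter()
        try:
            normalized, mask = images[sid], masks[sid]
            zimg = zscore_section(normalized, mask)
            qmap = quartile_bin(normalized, mask)
            clumps = find_clumps(qmap, config.connectivity)
            count, median_size = clump_summary(clumps)
            border = alpha_hull_border(mask, config.alpha_mm, normalized.pixel_pitch_um)
            q4 = qmap.pixels_in_quartile(4)
            profile = distance_profile(
                q4, border, normalized.pixel_pitch_um, config.bin_edges_mm
            )
            above = None
            if threshold is not None:
                above = int(
                    np.isfinite(above_threshold_map(normalized, mask, threshold).values).sum()
                )
        except Exception as exc:
            raise PipelineStageError("spatial_stats", sid, exc) from exc

        profiles[sid] = profile
        per_section[sid].update(
            {
                "clump_count": count,
                "clump_median_size_px": median_size,
                "above_threshold_pixels": above,
                "border_rings": len(border.rings),
                "border_length_mm": round(border.total_length_mm(), 6),
                "outside_border_pixels": profile.outside_border_count,
                "distance_bin_counts": [int(c) for c in profile.bin_counts],
                "distance_bin_fractions": [round(float(f), 8) for f in profile.bin_fractions],
            }
        )

        sdir = sections_dir
        _write_raster_csv(sdir / f"{sid}_intensity.csv", normalized.values)
        _write_raster_csv(sdir / f"{sid}_quartiles.csv", qmap.labels)
        pd.DataFrame(
            {"clump_id": range(1, len(clumps.clumps) + 1), "size_px": clumps.sizes}
        ).to_csv(sdir / f"{sid}_clumps.csv", index=False)
        _write_border_txt(sdir / f"{sid}_border.txt", border.rings)
        pd.DataFrame(
            {
                "bin_lo_mm": config.bin_edges_mm[:-1],
                "bin_hi_mm": config.bin_edges_mm[1:],
                "count": profile.bin_counts,
                "fraction": np.round(profile.bin_fractions, 8),
            }
        ).to_csv(sdir / f"{sid}_distance_profile.csv", index=False)
        logger.info("analyzed %s (%.2fs)", sid, time.perf_counter() - t0)

    # --- stage 4: group comparisons ---------------------------------------
    groups: dict[str, list[str]] = {}
    for ds in datasets:
        groups.setdefault(ds.group_label, []).append(ds.section_id)
    comparisons = []
    a_ids = groups.get("SF_BUD_1min", [])
    b_ids = groups.get("BUD_1min", [])
    if len(a_ids) >= 2 and len(b_ids) >= 2:
        try:
            stats_a = [
                (per_section[i]["clump_count"], per_section[i]["clump_median_size_px"])
                for i in a_ids
            ]
            stats_b = [
                (per_section[i]["clump_count"], per_section[i]["clump_median_size_px"])
                for i in b_ids
            ]
            cmp_count, cmp_size = compare_clump_stats(stats_a, stats_b)
            bin_cmps = compare_distance_bins(
                [profiles[i] for i in a_ids], [profiles[i] for i in b_ids]
            )
        except Exception as exc:
            raise PipelineStageError("group_stats", "SF_BUD_1min vs BUD_1min", exc) from exc
        for cmp_ in (cmp_count, cmp_size, *bin_cmps):
            comparisons.append(
                {
                    "statistic": cmp_.statistic_name,
                    "group_a": "SF_BUD_1min",
                    "group_b": "BUD_1min",
                    "n_a": len(cmp_.group_a_values),
                    "n_b": len(cmp_.group_b_values),
                    "rank_sum": cmp_.rank_sum,
                    "p_two_sided": cmp_.p_two_sided,
                    "method": cmp_.method,
                }
            )
        pd.DataFrame(comparisons).to_csv(out / "group_comparisons.csv", index=False)

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "threshold": threshold,
        "threshold_quantile": config.threshold_quantile,
        "groups": {g: sorted(ids) for g, ids in groups.items()},
        "sections": {k: per_section[k] for k in sorted(per_section)},
        "comparisons": comparisons,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline done in %.1fs", time.perf_counter() - t_start)
    return summary


def render_maps(output_dir: str | Path, section_id: str | None = None) -> list[Path]:
    """Render per-section rasters from a completed run: normalized-intensity
    map, Q2/Q4 overlay (grey/orange), and border overlay.  Returns the paths
    written (three per section)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    out = Path(output_dir)
    sections_dir = out / "sections"
    if not sections_dir.is_dir():
        raise FileNotFoundError(f"no sections/ directory under {out}; run the pipeline first")
    ids = (
        [section_id]
        if section_id
        else sorted(p.name[: -len("_intensity.csv")] for p in sections_dir.glob("*_intensity.csv"))
    )
    written: list[Path] = []
    render_dir = out / "maps"
    render_dir.mkdir(exist_ok=True)
    for sid in ids:
        ipath = sections_dir / f"{sid}_intensity.csv"
        qpath = sections_dir / f"{sid}_quartiles.csv"
        bpath = sections_dir / f"{sid}_border.txt"
        for p in (ipath, qpath, bpath):
            if not p.exists():
                raise FileNotFoundError(f"missing stage output {p.name} for section {sid}")
        intensity = pd.read_csv(ipath, header=None).to_numpy()
        quart = pd.read_csv(qpath, header=None).to_numpy()
        rings = _read_border_txt(bpath)

        fig, ax = plt.subplots(figsize=(6, 3))
        im = ax.imshow(intensity, origin="upper", interpolation="nearest")
        fig.colorbar(im, ax=ax, label="normalized intensity")
        ax.set_title(f"{sid}: normalized ion intensity")
        p1 = render_dir / f"{sid}_intensity.png"
        fig.savefig(p1, dpi=120, bbox_inches="tight")
        plt.close(fig)

        # Q2 grey, Q4 orange, everything else background
        overlay = np.zeros(quart.shape, dtype=int)
        overlay[quart == 2] = 1
        overlay[quart == 4] = 2
        cmap = ListedColormap(["white", "#9e9e9e", "#ff8c00"])
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.imshow(overlay, origin="upper", interpolation="nearest", cmap=cmap, vmin=0, vmax=2)
        ax.set_title(f"{sid}: 2nd (grey) / 4th (orange) quartiles")
        p2 = render_dir / f"{sid}_quartiles.png"
        fig.savefig(p2, dpi=120, bbox_inches="tight")
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(6, 3))
        ax.imshow(intensity, origin="upper", interpolation="nearest")
        pitch_mm = 0.4  # rendering scale only; rings are stored in mm
        for ring in rings:
            ax.plot(ring[:, 0] / pitch_mm, ring[:, 1] / pitch_mm, "r-", lw=1)
        ax.set_title(f"{sid}: tissue border (alpha hull)")
        p3 = render_dir / f"{sid}_border.png"
        fig.savefig(p3, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.extend([p1, p2, p3])
    return written


def _read_border_txt(path: Path) -> list[np.ndarray]:
    rings: list[np.ndarray] = []
    current: list[list[float]] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            if current:
                rings.append(np.asarray(current))
            current = []
        elif line.strip():
            x, y = line.split("\t")
            current.append([float(x), float(y)])
    if current:
        rings.append(np.asarray(current))
    return rings
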