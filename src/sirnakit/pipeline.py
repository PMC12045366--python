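"""Stage orchestration: design, screen, and imaging runs with provenance.

Each ``run_*`` function takes a validated config, chains the library
stages, writes tabular outputs plus a provenance JSON (config echo,
package version, seed) into the output directory, and returns the main
result table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import expression_analysis as ea
from . import imaging_quant as iq
from . import sirna_design as sd
from . import transcript_model as tm


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


@dataclass
class DesignConfig:
    targets_fasta: str
    structure_path: Optional[str] = None
    target_id: Optional[str] = None  # default: first transcript
    exclude_isoform_id: Optional[str] = None  # exclusive-site filter
    off_target_fasta: Optional[str] = None
    off_target_lncrna_fasta: Optional[str] = None
    ortholog_fastas: dict[str, str] = field(default_factory=dict)
    site_length: int = tm.DEFAULT_SITE_LENGTH
    rules: sd.DesignRules = field(default_factory=sd.DesignRules)
    out_dir: str = "design_out"

    def validate(self) -> None:
        if not Path(self.targets_fasta).exists():
            raise ConfigError(f"targets FASTA not found: {self.targets_fasta}")
        if self.structure_path and not Path(self.structure_path).exists():
            raise ConfigError(f"structure file not found: {self.structure_path}")
        for path in filter(None, [self.off_target_fasta,
                                  self.off_target_lncrna_fasta,
                                  *self.ortholog_fastas.values()]):
            if not Path(path).exists():
                raise ConfigError(f"input not found: {path}")
        if self.site_length < 8:
            raise ConfigError("site_length must be >= 8")


@dataclass
class ScreenConfig:
    plate_csv: str
    control_group: str = "NTC"
    control_stat: str = "mean"
    hit_threshold: float = 0.5
    fit_dose_response: bool = True
    out_dir: str = "screen_out"

    def validate(self) -> None:
        if not Path(self.plate_csv).exists():
            raise ConfigError(f"plate CSV not found: {self.plate_csv}")
        if self.control_stat not in {"mean", "median"}:
            raise ConfigError("control_stat must be 'mean' or 'median'")


@dataclass
class ImagingConfig:
    image_path: str
    masks_path: Optional[str] = None
    mask_names_path: Optional[str] = None
    segmentation_method: str = "otsu"
    min_area: int = iq.DEFAULT_MIN_AREA
    max_area: Optional[int] = None
    rolling_ball_radius: int = iq.DEFAULT_ROLLING_BALL_RADIUS
    positivity_strategy: str = "otsu_on_nucleus_means"
    intensity_stat: str = "mean_intensity"
    out_dir: str = "imaging_out"

    def validate(self) -> None:
        if not Path(self.image_path).exists():
            raise ConfigError(f"image not found: {self.image_path}")
        if self.masks_path and not Path(self.masks_path).exists():
            raise ConfigError(f"masks not found: {self.masks_path}")
        if self.intensity_stat not in {"mean_intensity", "median_intensity"}:
            raise ConfigError("intensity_stat must be mean_ or median_intensity")


def _config_dict(config) -> dict:
    def convert(value):
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            return {k: convert(v) for k, v in dataclasses.asdict(value).items()}
        return value

    return {k: convert(v) for k, v in dataclasses.asdict(config).items()}


def _write_provenance(out_dir: Path, stage: str, config, extra: dict) -> None:
    cfg = _config_dict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    record = {
        "stage": stage,
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        **extra,
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(record, indent=2, default=str)
    )


# ---------------------------------------------------------------------------


def run_design(config: DesignConfig) -> pd.DataFrame:
    """Enumerate, filter, score, rank, and annotate candidate sites."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    targets = tm.load_transcripts(config.targets_fasta, config.structure_path)
    target = (
        targets.get(config.target_id) if config.target_id
        else targets.transcripts[0]
    )
    sites = tm.enumerate_sites(target, config.site_length)
    n_enumerated = len(sites)
    if config.exclude_isoform_id:
        other = targets.get(config.exclude_isoform_id)
        sites = tm.isoform_exclusive_sites(sites, other)
    off_m = (
        tm.load_transcripts(config.off_target_fasta,
                            role=tm.SetRole.OFF_TARGET_MRNA)
        if config.off_target_fasta else None
    )
    off_l = (
        tm.load_transcripts(config.off_target_lncrna_fasta,
                            role=tm.SetRole.OFF_TARGET_LNCRNA)
        if config.off_target_lncrna_fasta else None
    )
    candidates = sd.rank_candidates(sites, config.rules, off_m, off_l)
    table = sd.candidates_to_frame(candidates)

    ortholog_sets = [
        tm.load_transcripts(path, role=tm.SetRole.ORTHOLOG, species=species)
        for species, path in sorted(config.ortholog_fastas.items())
    ]
    if ortholog_sets:
        site_by_key = {(c.site.start): c.site for c in candidates}
        conserved_flags = []
        for start in table["start"]:
            _, overall = tm.site_conservation(site_by_key[start], ortholog_sets)
            conserved_flags.append(overall)
        table["conserved_all_species"] = conserved_flags

    table.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    top = table[table["rank"].notna()].head(config.rules.top_n)
    top.to_csv(out_dir / "top_candidates.tsv", sep="\t", index=False)
    table.to_json(out_dir / "candidates.json", orient="records", indent=2)
    _write_provenance(out_dir, "design", config, {
        "n_sites_enumerated": n_enumerated,
        "n_sites_after_exclusive_filter": len(sites),
        "n_passing": int(table["passed"].sum()),
        "n_selected": int(len(top)),
    })
    return table


def run_screen(config: ScreenConfig) -> dict:
    """Normalize a plate, call hits, compute selectivity, fit potency."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    wells = ea.read_plate_csv(config.plate_csv)
    expressions = ea.normalize(wells, config.control_group, config.control_stat)
    frame = ea.expressions_to_frame(expressions)
    frame.to_csv(out_dir / "normalized.tsv", sep="\t", index=False)

    hits = ea.hit_call(expressions, config.hit_threshold)
    selectivity = ea.screen_selectivity(expressions)

    fits = {}
    if config.fit_dose_response:
        dosed = frame[frame["concentration"].notna()
                      & frame["group"].str.startswith("treated:")]
        for compound, grp in dosed.groupby(
            dosed["group"].str.split(":", n=1).str[1]
        ):
            if grp["concentration"].nunique() >= 4:
                fit = ea.fit_4pl(grp["concentration"], grp["value"])
                fits[str(compound)] = dataclasses.asdict(fit)

    results = {
        "hits": hits,
        "selectivity": [dataclasses.asdict(s) for s in selectivity],
        "fits": fits,
    }
    (out_dir / "screen_results.json").write_text(
        json.dumps(results, indent=2, default=str)
    )
    _write_provenance(out_dir, "screen", config, {
        "n_wells": len(wells),
        "n_hits": len(hits),
    })
    return results


def load_two_channel_image(
    image_path: str | Path,
    masks_path: Optional[str | Path] = None,
    mask_names_path: Optional[str | Path] = None,
) -> iq.TwoChannelImage:
    """Read a 2-channel TIFF/PNG stack plus optional labeled region mask."""
    import tifffile

    path = Path(image_path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        stack = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        stack = iio.imread(path)
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 3 and stack.shape[0] == 2:
        dapi, marker = stack[0], stack[1]
    elif stack.ndim == 3 and stack.shape[2] == 2:
        dapi, marker = stack[..., 0], stack[..., 1]
    else:
        raise ConfigError(
            f"expected a 2-channel image, got shape {stack.shape}"
        )
    region_masks = None
    if masks_path is not None:
        labeled = tifffile.imread(masks_path)
        names = {}
        if mask_names_path and Path(mask_names_path).exists():
            names = json.loads(Path(mask_names_path).read_text())
        region_masks = {
            names.get(str(v), f"region_{v}"): labeled == v
            for v in np.unique(labeled) if v != 0
        }
    return iq.TwoChannelImage(dapi=dapi, marker=marker,
                              region_masks=region_masks)


def run_imaging(config: ImagingConfig) -> pd.DataFrame:
    """Segment, background-correct, classify, and summarize per region."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    image = load_two_channel_image(
        config.image_path, config.masks_path, config.mask_names_path
    )
    results, provenance = iq.quantify_image(
        image,
        segmentation_method=config.segmentation_method,
        min_area=config.min_area,
        max_area=config.max_area,
        rolling_ball_radius=config.rolling_ball_radius,
        positivity_strategy=config.positivity_strategy,
        intensity_stat=config.intensity_stat,
    )
    table = iq.results_to_frame(results)
    table.to_csv(out_dir / "positivity.tsv", sep="\t", index=False)
    _write_provenance(out_dir, "imaging", config, provenance)
    return table
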