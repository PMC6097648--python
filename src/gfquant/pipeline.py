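"""End-to-end per-specimen analysis and batch group studies.

One specimen runs: read -> optional ROI crop -> top-hat agglomeration
removal on the fusion-protein (Brp) channel -> per-channel histogram
auto-threshold and binarization -> overlap, surface-proxy, medial
partition, dye-coupling window and colocalization measures.  A study maps
that over a manifest (or an in-memory synthetic study) and compares every
measure across groups with ANOVA plus Tukey-Kramer post-hoc tests.

Every threshold level, excluded-white count and mask voxel count is logged
per specimen for auditability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import phantom as phantom_mod
from .autothreshold import binarize, stack_histogram, threshold, METHODS
from .group_stats import StatsReport, anova_tukey
from .morph_filter import remove_agglomerations, rescale_contrast
from .quantify import (
    QuantSummary,
    colocalization,
    nb_coupling_area,
    overlap_volume,
    partition_medial,
    surface_area_proxy,
)
from .stack_io import BinaryMask, ChannelSet, crop_roi, load_specimen, read_manifest

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_specimen", "run_study", "summary_to_row", "MEASURES"]

CONFIG_SCHEMA_VERSION = 1

#: The per-channel method map the study was analyzed with.
DEFAULT_CHANNEL_METHODS = {
    "Brp": "intermodes",
    "nc82": "intermodes",
    "DA488": "default",
    "GF": "default",
    "NB": "default",
    "GFP": "default",
    "ShB": "renyi",
}

# channel aliases: the dendrite reference channel is the dye fill
_GF_ALIASES = ("GF", "DA488")

#: measure name -> channels it needs (region masks are checked separately)
MEASURES = {
    "az_on_gf_volume": ("Brp", "gf"),
    "gf_surface_area": ("gf",),
    "medial_surface_area": ("gf",),
    "az_on_medial_volume": ("Brp", "gf"),
    "nb_coupling_area": ("NB", "gf"),
    "shb_by_region": ("ShB", "Brp", "regions"),
}


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, JSON-serializable.

    Defaults are the published procedure: intermodes threshold for the Brp
    channel, the default/IsoData method for dye fill and Neurobiotin, Rényi
    entropy for ShakB; radius-3 top-hat; 5 μm medial boundary; 10 μm
    Neurobiotin window; contrast readjustment after the top-hat.
    """

    channel_methods: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_METHODS))
    tophat_radius: int = 3
    boundary_um: float = 5.0
    nb_window_um: float = 10.0
    rescale_after_tophat: bool = True
    ignore_white: bool = True
    measures: list | None = None  # None = every measure whose inputs exist
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {self.schema_version}")
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        if self.boundary_um <= 0 or self.nb_window_um <= 0:
            raise ValueError("boundary_um and nb_window_um must be positive")
        for chan, method in self.channel_methods.items():
            if method not in METHODS:
                raise ValueError(
                    f"channel {chan!r}: unknown threshold method {method!r}; "
                    f"supported: {sorted(METHODS)}"
                )
        if self.measures is not None:
            unknown = set(self.measures) - set(MEASURES)
            if unknown:
                raise ValueError(f"unknown measures {sorted(unknown)}; supported: {sorted(MEASURES)}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; allowed: {sorted(allowed)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _threshold_channel(config: PipelineConfig, channels: ChannelSet, name: str) -> BinaryMask:
    stack = channels[name]
    method = config.channel_methods.get(name, "default")
    if name == "Brp":
        stack = remove_agglomerations(stack, radius=config.tophat_radius)
        if config.rescale_after_tophat:
            stack = rescale_contrast(stack)
    hist = stack_histogram(stack, ignore_white=config.ignore_white)
    result = threshold(hist, method)
    mask = binarize(stack, result.level)
    logger.info(
        "channel %s: method=%s level=%d excluded_white=%d foreground=%d voxels",
        name, result.method, result.level, hist.excluded_white, mask.count(),
    )
    return mask


def run_specimen(
    config: PipelineConfig,
    channels: ChannelSet,
    roi_mask: BinaryMask | None = None,
    region_masks: Mapping[str, BinaryMask] | None = None,
    specimen_id: str = "",
    group: str = "",
) -> QuantSummary:
    """Run the full per-specimen analysis; returns a :class:`QuantSummary`.

    Measures whose input channels (or region masks) are absent are skipped
    when ``config.measures`` is None; if the config explicitly requests a
    measure that cannot be computed, the error lists what is computable.
    """
    if roi_mask is not None:
        channels = crop_roi(channels, roi_mask)
        logger.info("ROI crop: kept %d voxels", roi_mask.count())

    gf_name = next((n for n in _GF_ALIASES if n in channels), None)
    available = {
        "gf": gf_name is not None,
        "Brp": "Brp" in channels,
        "NB": "NB" in channels,
        "ShB": "ShB" in channels,
        "regions": bool(region_masks),
    }
    computable = [
        m for m, needs in MEASURES.items() if all(available.get(k, False) for k in needs)
    ]
    wanted = config.measures if config.measures is not None else computable
    impossible = [m for m in wanted if m not in computable]
    if impossible:
        raise ValueError(
            f"cannot compute {sorted(impossible)} (missing channels/masks); "
            f"computable measures: {sorted(computable)}"
        )

    masks: dict[str, BinaryMask] = {}

    def mask_for(name: str) -> BinaryMask:
        if name not in masks:
            real = gf_name if name == "gf" else name
            masks[name] = _threshold_channel(config, channels, real)
        return masks[name]

    summary = QuantSummary(specimen_id=specimen_id, group=group)
    if "az_on_gf_volume" in wanted:
        summary.az_on_gf_volume = overlap_volume(mask_for("Brp"), mask_for("gf"))
    if "gf_surface_area" in wanted:
        summary.gf_surface_area = surface_area_proxy(mask_for("gf"))
    if "medial_surface_area" in wanted or "az_on_medial_volume" in wanted:
        gf = mask_for("gf")
        if gf.voxels.any():
            medial, _core = partition_medial(gf, config.boundary_um)
            if "medial_surface_area" in wanted:
                summary.medial_surface_area = surface_area_proxy(medial)
            if "az_on_medial_volume" in wanted:
                summary.az_on_medial_volume = overlap_volume(mask_for("Brp"), medial)
        else:
            logger.warning("%s: empty dendrite mask, medial measures set to 0", specimen_id)
            if "medial_surface_area" in wanted:
                summary.medial_surface_area = 0.0
            if "az_on_medial_volume" in wanted:
                summary.az_on_medial_volume = 0.0
    if "nb_coupling_area" in wanted:
        gf = mask_for("gf")
        if gf.voxels.any():
            summary.nb_coupling_area = nb_coupling_area(mask_for("NB"), gf, config.nb_window_um)
        else:
            logger.warning("%s: empty dendrite mask, NB coupling set to 0", specimen_id)
            summary.nb_coupling_area = 0.0
    if "shb_by_region" in wanted:
        per_region = colocalization(mask_for("ShB"), mask_for("Brp"), region_masks)
        for region, rc in per_region.items():
            summary.shb_volume_by_region[region] = rc.shb_volume
            summary.shb_brp_overlap_by_region[region] = rc.overlap_volume
            summary.percent_shb_colocalized[region] = rc.percent_colocalized
    return summary


def _slug(region: str) -> str:
    return region.lower().replace("-", "_").replace(" ", "_")


def summary_to_row(summary: QuantSummary) -> dict:
    """Flatten a QuantSummary into one results-CSV row."""
    row = {
        "specimen_id": summary.specimen_id,
        "group": summary.group,
        "az_on_gf_volume": summary.az_on_gf_volume,
        "gf_surface_area": summary.gf_surface_area,
        "medial_surface_area": summary.medial_surface_area,
        "az_on_medial_volume": summary.az_on_medial_volume,
        "nb_coupling_area": summary.nb_coupling_area,
    }
    for region, v in summary.shb_volume_by_region.items():
        row[f"shb_volume_{_slug(region)}"] = v
    for region, v in summary.shb_brp_overlap_by_region.items():
        row[f"shb_brp_overlap_{_slug(region)}"] = v
    for region, v in summary.percent_shb_colocalized.items():
        row[f"pct_shb_coloc_{_slug(region)}"] = v
    return row


def run_study(
    config: PipelineConfig,
    study,
    results_csv=None,
    report_json=None,
):
    """Analyze every specimen of a study and compare groups per measure.

    ``study`` is either a manifest CSV path or an in-memory
    :class:`~gfquant.phantom.StudyData`.  Returns ``(results, reports)``
    where ``results`` is one row per specimen and ``reports`` maps each
    measure column to its :class:`~gfquant.group_stats.StatsReport`.
    """
    rows = []
    if isinstance(study, phantom_mod.StudyData):
        ids = [sp.specimen_id for sp in study.specimens]
        _check_duplicates(ids)
        for sp in study.specimens:
            channel_set, truth = study.realize(sp)
            summary = run_specimen(
                config, channel_set,
                region_masks=truth.region_masks,
                specimen_id=sp.specimen_id, group=sp.group,
            )
            rows.append(summary_to_row(summary))
    else:
        records = read_manifest(study)
        _check_duplicates([r.specimen_id for r in records])
        for rec in records:
            channel_set, masks = load_specimen(rec)
            roi = masks.pop("ROI", None)
            summary = run_specimen(
                config, channel_set,
                roi_mask=roi,
                region_masks=masks or None,
                specimen_id=rec.specimen_id, group=rec.group,
            )
            rows.append(summary_to_row(summary))

    results = pd.DataFrame(rows)
    measure_cols = [
        c for c in results.columns
        if c not in ("specimen_id", "group") and results[c].notna().any()
    ]
    reports: dict[str, StatsReport] = {}
    if results["group"].nunique() >= 2:
        for col in measure_cols:
            reports[col] = anova_tukey(results, value_col=col)
    if results_csv is not None:
        Path(results_csv).parent.mkdir(parents=True, exist_ok=True)
        results.to_csv(results_csv, index=False)
    if report_json is not None:
        Path(report_json).parent.mkdir(parents=True, exist_ok=True)
        with open(report_json, "w") as fh:
            json.dump({m: r.to_dict() for m, r in reports.items()}, fh, indent=2)
    return results, reports


def _check_duplicates(ids) -> None:
    dupes = sorted({i for i in ids if list(ids).count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate specimen_id values: {dupes}")
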