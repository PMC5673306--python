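"""File formats, run configuration and pipeline orchestration.

TIFF/OME-style multipage files are the only raster interchange format
(one page per polarization state / channel / timepoint); tabular outputs
are CSV and configurations YAML.  A run re-executed from its persisted
configuration and seed is bit-identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .emission import RatioPair
from .polscope import (
    PolStack,
    anisotropy_image,
    bleach_correct,
    CalibrationRefs,
    cortical_regions,
    locate_equator_poles,
    region_polarization,
    segment_cell,
)

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_pair",
    "load_refs",
    "save_refs",
    "run_polscope_pipeline",
]

LAYOUTS = ("polscope", "pair", "series")


def write_stack(path, stack: PolStack, metadata: dict | None = None):
    """Write a five-frame PolStack as a multipage TIFF with metadata."""
    meta = {
        "axes": "CYX",
        "layout": "polscope",
        "polarization_deg": [0, 45, 90, 135, 0],
        "pixel_size_um": stack.pixel_size_um,
    }
    if metadata:
        meta.update(metadata)
    tifffile.imwrite(path, stack.frames.astype(np.float32), metadata=meta)


def write_pair(path, pair: RatioPair, metadata: dict | None = None):
    meta = {
        "axes": "CYX",
        "layout": "pair",
        "channels": ["horizontal", "vertical"],
        "pixel_size_um": pair.pixel_size_um,
    }
    if metadata:
        meta.update(metadata)
    tifffile.imwrite(
        path,
        np.stack([pair.horizontal, pair.vertical]).astype(np.float32),
        metadata=meta,
    )


def _read_metadata(tif) -> dict:
    meta = {}
    try:
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is not None:
            meta = json.loads(desc.value)
    except (json.JSONDecodeError, AttributeError):
        pass
    return meta


def read_stack(path, layout: str, pixel_size_um: float | None = None):
    """Read a multipage TIFF as a typed image object.

    ``layout`` declares the page meaning: ``polscope`` (5 pages, one per
    excitation state) -> :class:`PolStack`; ``pair`` (2 pages: horizontal
    then vertical analyzer) -> :class:`RatioPair`; ``series`` (any page
    count) -> plain (T, H, W) array.  Pixel size is taken from the file
    metadata unless given explicitly.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = _read_metadata(tif)
    if data.ndim == 2:
        data = data[None]
    px = pixel_size_um or meta.get("pixel_size_um")
    if layout == "polscope":
        if data.shape[0] != 5:
            raise ValueError(
                f"polscope layout expects 5 pages (0,45,90,135,0 deg), got {data.shape[0]}"
            )
        if px is None:
            raise ValueError("pixel size missing from file metadata; pass pixel_size_um")
        return PolStack(data.astype(float), float(px))
    if layout == "pair":
        if data.shape[0] != 2:
            raise ValueError(f"pair layout expects 2 pages, got {data.shape[0]}")
        if px is None:
            raise ValueError("pixel size missing from file metadata; pass pixel_size_um")
        return RatioPair(data[0].astype(float), data[1].astype(float), float(px))
    return data.astype(float)


def save_refs(path, refs: CalibrationRefs):
    Path(path).write_text(
        yaml.safe_dump(
            {"p_plastic": refs.p_plastic, "p_stressfibers": refs.p_stressfibers}
        )
    )


def load_refs(path) -> CalibrationRefs:
    data = yaml.safe_load(Path(path).read_text())
    return CalibrationRefs(float(data["p_plastic"]), float(data["p_stressfibers"]))


@dataclass
class RunConfig:
    """Serializable description of one fixed-cell analysis run."""

    stack_path: str
    seed_x: float
    seed_y: float
    refs_path: str | None = None
    pixel_size_um: float | None = None
    cell_id: str = "cell"
    closing_radius_px: int = 5
    equator_window_um: float = 2.0
    pole_window_um: float = 16.0
    band_width_um: float = 0.64
    intensity_floor_fraction: float = 0.02
    out_dir: str = "."

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_polscope_pipeline(config: RunConfig) -> dict:
    """Full fixed-cell pipeline: stack -> per-region (normalized) p + QC.

    Stages: bleach correction, per-pixel anisotropy, seeded watershed
    segmentation, ellipse anchors, cortical band regions, region averages,
    optional calibration normalization.  Writes a per-region CSV, the p
    and azimuth images as a TIFF, and a QC JSON, all tagged with the
    configuration hash.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = load_refs(config.refs_path) if config.refs_path else None
    stack = read_stack(config.stack_path, "polscope", config.pixel_size_um)

    corrected = bleach_correct(stack)
    aniso = anisotropy_image(
        corrected,
        stack.pixel_size_um,
        intensity_floor=config.intensity_floor_fraction * float(corrected.max()),
    )
    mask, contour = segment_cell(
        stack.mean_image(),
        (config.seed_x, config.seed_y),
        closing_radius=config.closing_radius_px,
    )
    anchors = locate_equator_poles(contour)
    regions = cortical_regions(
        contour,
        anchors,
        stack.pixel_size_um,
        image_shape=mask.shape,
        equator_window_um=config.equator_window_um,
        pole_window_um=config.pole_window_um,
        band_width_um=config.band_width_um,
    )
    values = region_polarization(aniso, regions, refs)
    raw = region_polarization(aniso, regions, None)

    rows = []
    for name in ("equator_0", "equator_1", "pole_0", "pole_1", "equator", "pole"):
        rows.append(
            {
                "cell_id": config.cell_id,
                "region": name,
                "site": name.split("_")[0],
                "p": raw[name],
                "p_norm": values[name] if refs else np.nan,
                "n_pixels": int(regions[name].sum()) if name in regions else np.nan,
                "config_hash": config.config_hash(),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / f"regions_{config.cell_id}.csv", index=False)

    tifffile.imwrite(
        out_dir / f"anisotropy_{config.cell_id}.tif",
        np.stack(
            [aniso.p, np.nan_to_num(aniso.azimuth_deg, nan=-1.0), aniso.mean_intensity]
        ).astype(np.float32),
        metadata={"axes": "CYX", "channels": ["p", "azimuth_deg", "mean_intensity"]},
    )

    # intensity-independence QC: p vs mean intensity along the cortex band
    band = np.zeros(mask.shape, bool)
    for name in ("equator_0", "equator_1", "pole_0", "pole_1"):
        band |= regions[name]
    sel = band & aniso.mask
    if sel.sum() >= 3:
        corr = float(np.corrcoef(aniso.p[sel], aniso.mean_intensity[sel])[0, 1])
    else:
        corr = np.nan
    qc = {
        "config_hash": config.config_hash(),
        "axis_ratio": float(anchors.axis_ratio),
        "ambiguous_axes": bool(anchors.ambiguous),
        "mask_area_px": int(mask.sum()),
        "p_intensity_correlation": float(corr),
        "bleach_ratio": float(stack.frames[0].sum() / stack.frames[4].sum()),
    }
    (out_dir / f"qc_{config.cell_id}.json").write_text(json.dumps(qc, indent=2))
    return {"table": table, "qc": qc, "anchors": anchors, "regions": regions}
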