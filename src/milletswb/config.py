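"""Configuration I/O: variety parameter files and YAML run configs.

Crop parameter files are flat ``key = value`` text (``#`` comments); the
three packaged varieties -- ``kantana`` (landrace), ``kangara``
(improved) and ``agrigreen`` (hybrid) -- load by name. A run config is a
single YAML document with ``site``, ``soil``, ``crop`` and ``management``
blocks.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

from .crop import CropParameters, Management
from .errors import InvalidConfigError
from .soil import SoilLayer, SoilProfile
from .weather import SiteInfo

__all__ = [
    "PACKAGED_VARIETIES",
    "load_crop_parameters",
    "write_crop_parameters",
    "load_run_config",
]

PACKAGED_VARIETIES = ("kantana", "kangara", "agrigreen")

_FLOAT_FIELDS = {f.name for f in dataclasses.fields(CropParameters)
                 if f.name not in ("name", "k_s")}


def _parse_params_text(text: str, fallback_name: str) -> CropParameters:
    values: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidConfigError(f"line {lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "name":
            values["name"] = val
        elif key in _FLOAT_FIELDS:
            try:
                values[key] = float(val)
            except ValueError as exc:
                raise InvalidConfigError(
                    f"line {lineno}: bad number for {key!r}: {val!r}") from exc
        else:
            raise InvalidConfigError(f"line {lineno}: unknown parameter {key!r}")
    values.setdefault("name", fallback_name)
    try:
        return CropParameters(**values)  # type: ignore[arg-type]
    except TypeError as exc:
        raise InvalidConfigError(f"incomplete parameter file: {exc}") from exc


def load_crop_parameters(name_or_path: str | Path) -> CropParameters:
    """Load a variety by packaged name or from a parameter file path."""
    name = str(name_or_path)
    if name in PACKAGED_VARIETIES:
        text = (resources.files("milletswb.data")
                .joinpath(f"{name}.params").read_text())
        return _parse_params_text(text, name)
    path = Path(name_or_path)
    if not path.exists():
        raise InvalidConfigError(
            f"{name!r} is neither a packaged variety {PACKAGED_VARIETIES} "
            f"nor an existing file")
    return _parse_params_text(path.read_text(), path.stem)


def write_crop_parameters(params: CropParameters, path: str | Path) -> None:
    """Write a parameter file the loader reads back bit-identically."""
    lines = [f"name = {params.name}"]
    for fname in sorted(_FLOAT_FIELDS):
        lines.append(f"{fname} = {getattr(params, fname)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _build_soil(block: dict | None) -> SoilProfile:
    if not block:
        return SoilProfile.default()
    layers = block.get("layers")
    if layers:
        return SoilProfile([SoilLayer(
            thickness=float(l["thickness_m"]), fc=float(l["fc"]),
            pwp=float(l["pwp"]), theta=(float(l["theta"]) if "theta" in l else None),
            bulk_density=float(l.get("bulk_density", 1350.0))) for l in layers])
    return SoilProfile.default(
        n_layers=int(block.get("n_layers", 5)),
        thickness=float(block.get("thickness_m", 0.20)),
        fc=float(block.get("fc", 0.27)), pwp=float(block.get("pwp", 0.13)),
        bulk_density=float(block.get("bulk_density", 1350.0)))


def load_run_config(path: str | Path):
    """Load a YAML run config into (site, soil, crop, management)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise InvalidConfigError("run config must be a YAML mapping")
    site_block = doc.get("site") or {}
    site = SiteInfo(
        latitude=float(site_block.get("latitude", SiteInfo.latitude)),
        altitude=float(site_block.get("altitude", SiteInfo.altitude)),
        anemometer_height=float(site_block.get("anemometer_height", 2.0)))
    soil = _build_soil(doc.get("soil"))
    crop_block = doc.get("crop") or {}
    variety = crop_block.get("variety")
    if variety is None:
        raise InvalidConfigError("run config needs crop.variety")
    crop = load_crop_parameters(variety)
    mgmt_block = doc.get("management") or {}
    management = Management(
        mode=mgmt_block.get("mode", "weekly_refill"),
        first_irrigation_day=mgmt_block.get("first_irrigation_day"))
    return site, soil, crop, management
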