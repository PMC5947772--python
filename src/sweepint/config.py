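"""Typed keyword=value configuration for the pipeline stages.

Every stage has a schema of typed parameters with defaults; unknown keys are
rejected by name, and each resolved configuration records whether a value
came from the default, a config file or the command line (provenance).
Precedence: defaults < config file < command-line ``key=value`` pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field


class ConfigError(ValueError):
    pass


@dataclass
class ParamSpec:
    name: str
    type: type
    default: object
    help: str = ""


def _parse_value(spec: ParamSpec, raw):
    if isinstance(raw, str):
        if spec.type is bool:
            if raw.lower() in ("1", "true", "yes"):
                return True
            if raw.lower() in ("0", "false", "no"):
                return False
            raise ConfigError(f"cannot parse boolean {spec.name}={raw!r}")
        if spec.type in (tuple, list):
            return tuple(float(x) for x in raw.split(",") if x != "")
        if raw == "none":
            return None
        try:
            return spec.type(raw)
        except ValueError as exc:
            raise ConfigError(f"cannot parse {spec.name}={raw!r} as {spec.type.__name__}") from exc
    return raw


@dataclass
class Config:
    """Resolved parameter set with provenance per key."""

    schema: dict
    values: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @classmethod
    def resolve(cls, schema: list, overrides=(), config_file=None) -> "Config":
        by_name = {s.name: s for s in schema}
        cfg = cls(schema=by_name)
        for s in schema:
            cfg.values[s.name] = s.default
            cfg.provenance[s.name] = "default"
        if config_file is not None:
            with open(config_file) as fh:
                data = json.load(fh)
            for key, val in data.items():
                if key not in by_name:
                    raise ConfigError(f"unknown configuration key {key!r} in {config_file}")
                cfg.values[key] = _parse_value(by_name[key], val)
                cfg.provenance[key] = "file"
        for item in overrides:
            if "=" not in item:
                raise ConfigError(f"expected key=value, got {item!r}")
            key, _, raw = item.partition("=")
            if key not in by_name:
                raise ConfigError(f"unknown configuration key {key!r}")
            cfg.values[key] = _parse_value(by_name[key], raw)
            cfg.provenance[key] = "user"
        return cfg

    def __getitem__(self, key):
        return self.values[key]

    def to_dict(self) -> dict:
        return {
            k: {"value": _jsonable(v), "provenance": self.provenance[k]}
            for k, v in sorted(self.values.items())
        }


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    return v


SCHEMAS = {
    "simulate": [
        ParamSpec("cell", tuple, (30.0, 30.0, 30.0, 90.0, 90.0, 90.0), "unit cell (A, deg)"),
        ParamSpec("wavelength", float, 1.0, "wavelength (A)"),
        ParamSpec("distance", float, 120.0, "sample-detector distance (mm)"),
        ParamSpec("n_images", int, 90, "number of images"),
        ParamSpec("oscillation", float, 1.0, "oscillation per image (deg)"),
        ParamSpec("image_size", tuple, (450.0, 450.0), "detector raster (fast, slow)"),
        ParamSpec("pixel_size", tuple, (0.15, 0.15), "pixel size (mm)"),
        ParamSpec("background", float, 1.0, "flat background (counts/pixel)"),
        ParamSpec("n_spots", int, 500, "number of reflections to render (0 = all)"),
        ParamSpec("sigma_d", float, 0.05, "profile width on the detector (deg)"),
        ParamSpec("sigma_m", float, 0.1, "profile width over rotation (deg)"),
        ParamSpec("intensity_min", float, 10.0, "log-uniform intensity law lower bound"),
        ParamSpec("intensity_max", float, 1e5, "log-uniform intensity law upper bound"),
        ParamSpec("zinger_rate", float, 0.0, "zingers per image"),
        ParamSpec("ice_ring_d", tuple, (), "ice-ring resolutions (A)"),
        ParamSpec("ice_ring_strength", float, 0.0, "extra counts/pixel on rings"),
    ],
    "find_spots": [
        ParamSpec("sigma_b", float, 6.0, "dispersion-test significance"),
        ParamSpec("sigma_s", float, 3.0, "strong-pixel significance"),
        ParamSpec("gain", float, 1.0, "detector gain"),
        ParamSpec("global_threshold", float, 0.0, "absolute count threshold"),
        ParamSpec("kernel_half_size", int, 3, "local-window half size (px)"),
        ParamSpec("min_pixels", int, 3, "minimum pixels per spot"),
        ParamSpec("max_pixels", int, 10000, "maximum pixels per spot"),
        ParamSpec("connectivity", int, 6, "3D connectivity (6 or 26)"),
        ParamSpec("export_dispersion", bool, False, "write per-pixel dispersion maps"),
    ],
    "index": [
        ParamSpec("d_max", float, 200.0, "longest cell edge searched (A)"),
        ParamSpec("n_directions", int, 16384, "hemisphere sampling"),
        ParamSpec("grid_points", int, 256, "FFT grid points"),
        ParamSpec("tolerance", float, 0.3, "index-assignment tolerance"),
    ],
    "refine": [
        ParamSpec("free_blocks", tuple, (), "blocks to refine (empty = all)"),
        ParamSpec("max_iterations", int, 50, "LM iteration cap"),
        ParamSpec("outlier_cycles", int, 2, "outlier-rejection macro-cycles"),
    ],
    "integrate": [
        ParamSpec("background_method", str, "glm", "glm | mean | plane"),
        ParamSpec("grid_size", int, 9, "profile grid points per axis"),
        ParamSpec("n_sigma", float, 3.0, "profile extent multiplier"),
        ParamSpec("block_size", int, 16, "images per integration block"),
        ParamSpec("dmin", float, 0.0, "resolution limit (0 = detector edge)"),
        ParamSpec("apply_corrections", bool, False,
                  "multiply intensities by the LP and QE corrections"),
    ],
    "report": [
        ParamSpec("html", bool, True, "also write report.html"),
    ],
}
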