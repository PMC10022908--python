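"""Structured YAML run configuration with validation and round-tripping.

A run is described by four sections — ``phantom``, ``source``, ``transport``
and ``output`` — plus an optional ``materials`` section declaring custom
mixtures.  Unknown keys, unresolvable materials and non-positive dimensions
raise :class:`ConfigError` naming the offending key; every applied default
is logged at DEBUG level.  Units: lengths cm, energies keV, densities
g/cm^3.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .geometry import GeometryConfig, build_assembly, PhantomAssembly
from .materials import Material

__all__ = ["ConfigError", "RunConfig", "parse_config", "serialize_config"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


_PHANTOM_KEYS = {
    "footprint", "radius_cm", "box_width_cm", "box_depth_cm",
    "layer_thicknesses_cm", "layer_materials", "skin_thickness_cm",
    "include_skin", "skin_material", "plate_thickness_cm", "include_plates",
    "plate_material", "include_body", "body_material", "body_size_cm",
}
_SOURCE_KEYS = {"energy_keV", "sweep", "sid_cm", "beam"}
_TRANSPORT_KEYS = {
    "nps", "seed", "cutoff_keV", "batches", "repeats",
    "coherent", "incoherent_function", "mode",
}
_OUTPUT_KEYS = {"dir", "formats"}
_SWEEP_KEYS = {"start_keV", "stop_keV", "step_keV"}


@dataclass
class RunConfig:
    """Validated run parameters; geometry lives in the nested GeometryConfig."""

    geometry: GeometryConfig
    energy_keV: float | None = None
    sweep: tuple[float, float, float] | None = None  # start, stop, step
    beam: str = "cone"
    nps: int = 200_000
    seed: int = 1
    cutoff_keV: float = 1.0
    batches: int = 10
    repeats: int = 3
    coherent: bool = True
    incoherent_function: bool = False
    mode: str = "analog"
    output_dir: str = "results"
    output_formats: tuple[str, ...] = ("json", "csv")

    def build_assembly(self) -> PhantomAssembly:
        return build_assembly(self.geometry)

    def sweep_energies(self) -> list[float]:
        if self.sweep is None:
            raise ConfigError("no sweep section configured")
        start, stop, step = self.sweep
        n = int(round((stop - start) / step))
        return [start + i * step for i in range(n + 1)]


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _positive(value, key):
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{key} must be a number, got {value!r}") from None
    if v <= 0:
        raise ConfigError(f"{key} must be positive, got {v}")
    return v


def _parse_materials(section: dict) -> dict[str, Material]:
    out = {}
    for name, spec in section.items():
        if set(spec) - {"density", "fractions"}:
            raise ConfigError(f"unknown key(s) in materials.{name}")
        try:
            out[name] = Material.from_percent(
                name,
                {el: float(v) for el, v in spec["fractions"].items()},
                _positive(spec["density"], f"materials.{name}.density"),
            )
        except KeyError as exc:
            raise ConfigError(f"materials.{name} missing {exc}") from None
    return out


def parse_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML config file (or a pre-loaded mapping)."""
    if isinstance(source, (str, Path)) :
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys(raw, {"phantom", "source", "transport", "output", "materials"},
                "top level")

    materials = _parse_materials(raw.get("materials", {}))

    ph = raw.get("phantom", {})
    _check_keys(ph, _PHANTOM_KEYS, "phantom")
    geo_kwargs: dict = {"materials": materials}
    mapping = {
        "footprint": ("footprint", str),
        "radius_cm": ("radius", lambda v: _positive(v, "phantom.radius_cm")),
        "box_width_cm": ("box_width", lambda v: _positive(v, "phantom.box_width_cm")),
        "box_depth_cm": ("box_depth", lambda v: _positive(v, "phantom.box_depth_cm")),
        "skin_thickness_cm": ("skin_thickness",
                              lambda v: _positive(v, "phantom.skin_thickness_cm")),
        "include_skin": ("include_skin", bool),
        "skin_material": ("skin_material", str),
        "plate_thickness_cm": ("plate_thickness",
                               lambda v: _positive(v, "phantom.plate_thickness_cm")),
        "include_plates": ("include_plates", bool),
        "plate_material": ("plate_material", str),
        "include_body": ("include_body", bool),
        "body_material": ("body_material", str),
    }
    for key, (attr, conv) in mapping.items():
        if key in ph:
            geo_kwargs[attr] = conv(ph[key])
    if "layer_thicknesses_cm" in ph:
        ts = ph["layer_thicknesses_cm"]
        if len(ts) != 3:
            raise ConfigError("phantom.layer_thicknesses_cm needs exactly 3 values")
        geo_kwargs["layer_thicknesses"] = tuple(
            _positive(t, "phantom.layer_thicknesses_cm") for t in ts)
    if "layer_materials" in ph:
        lm = ph["layer_materials"]
        if len(lm) != 3:
            raise ConfigError("phantom.layer_materials needs exactly 3 names")
        geo_kwargs["layer_materials"] = tuple(str(m) for m in lm)
    if "body_size_cm" in ph:
        bs = ph["body_size_cm"]
        if len(bs) != 3:
            raise ConfigError("phantom.body_size_cm needs exactly 3 values")
        geo_kwargs["body_size"] = tuple(
            _positive(v, "phantom.body_size_cm") for v in bs)

    src = raw.get("source", {})
    _check_keys(src, _SOURCE_KEYS, "source")
    if "sid_cm" in src:
        geo_kwargs["sid"] = _positive(src["sid_cm"], "source.sid_cm")

    geometry = GeometryConfig(**geo_kwargs)
    # material names must resolve now, not at run time
    for name in (*geometry.layer_materials, geometry.skin_material,
                 geometry.plate_material, geometry.body_material):
        try:
            geometry.resolve(name)
        except ValueError as exc:
            raise ConfigError(str(exc)) from None

    cfg = RunConfig(geometry=geometry)
    defaults = {f.name: getattr(cfg, f.name) for f in dataclasses.fields(RunConfig)
                if f.name != "geometry"}

    if "energy_keV" in src:
        cfg.energy_keV = _positive(src["energy_keV"], "source.energy_keV")
    if "beam" in src:
        if src["beam"] not in ("cone", "pencil"):
            raise ConfigError(f"source.beam must be cone|pencil, got {src['beam']!r}")
        cfg.beam = src["beam"]
    if "sweep" in src:
        sw = src["sweep"]
        _check_keys(sw, _SWEEP_KEYS, "source.sweep")
        cfg.sweep = (
            _positive(sw.get("start_keV", 26.0), "source.sweep.start_keV"),
            _positive(sw.get("stop_keV", 36.0), "source.sweep.stop_keV"),
            _positive(sw.get("step_keV", 1.0), "source.sweep.step_keV"),
        )

    tr = raw.get("transport", {})
    _check_keys(tr, _TRANSPORT_KEYS, "transport")
    for key, attr, conv in (
        ("nps", "nps", int), ("seed", "seed", int),
        ("cutoff_keV", "cutoff_keV", lambda v: _positive(v, "transport.cutoff_keV")),
        ("batches", "batches", int), ("repeats", "repeats", int),
        ("coherent", "coherent", bool),
        ("incoherent_function", "incoherent_function", bool),
        ("mode", "mode", str),
    ):
        if key in tr:
            setattr(cfg, attr, conv(tr[key]))
    if cfg.nps <= 0 or cfg.batches < 2 or cfg.repeats < 1:
        raise ConfigError("transport.nps/batches/repeats out of range")
    if cfg.mode not in ("analog", "absorber"):
        raise ConfigError(f"transport.mode must be analog|absorber, got {cfg.mode!r}")

    out = raw.get("output", {})
    _check_keys(out, _OUTPUT_KEYS, "output")
    if "dir" in out:
        cfg.output_dir = str(out["dir"])
    if "formats" in out:
        cfg.output_formats = tuple(out["formats"])

    for name, default in defaults.items():
        if getattr(cfg, name) == default:
            log.debug("config: %s defaulted to %r", name, default)
    return cfg


def serialize_config(cfg: RunConfig, include_output: bool = True) -> str:
    """YAML text that :func:`parse_config` parses back to an equal config.

    ``include_output=False`` omits the output section, giving the canonical
    physics-relevant text used for provenance hashing.
    """
    g = cfg.geometry
    doc: dict = {
        "phantom": {
            "footprint": g.footprint,
            "radius_cm": g.radius,
            "skin_thickness_cm": g.skin_thickness,
            "box_width_cm": g.box_width,
            "box_depth_cm": g.box_depth,
            "layer_thicknesses_cm": list(g.layer_thicknesses),
            "layer_materials": list(g.layer_materials),
            "include_skin": g.include_skin,
            "skin_material": g.skin_material,
            "plate_thickness_cm": g.plate_thickness,
            "include_plates": g.include_plates,
            "plate_material": g.plate_material,
            "include_body": g.include_body,
            "body_material": g.body_material,
            "body_size_cm": list(g.body_size),
        },
        "source": {"sid_cm": g.sid, "beam": cfg.beam},
        "transport": {
            "nps": cfg.nps, "seed": cfg.seed, "cutoff_keV": cfg.cutoff_keV,
            "batches": cfg.batches, "repeats": cfg.repeats,
            "coherent": cfg.coherent,
            "incoherent_function": cfg.incoherent_function,
            "mode": cfg.mode,
        },
    }
    if include_output:
        doc["output"] = {"dir": cfg.output_dir,
                         "formats": list(cfg.output_formats)}
    if cfg.energy_keV is not None:
        doc["source"]["energy_keV"] = cfg.energy_keV
    if cfg.sweep is not None:
        doc["source"]["sweep"] = {
            "start_keV": cfg.sweep[0], "stop_keV": cfg.sweep[1],
            "step_keV": cfg.sweep[2],
        }
    if g.materials:
        doc["materials"] = {
            name: {
                "density": m.density,
                "fractions": {el: 100.0 * w for el, w in m.fractions.items()},
            } for name, m in g.materials.items()
        }
    return yaml.safe_dump(doc, sort_keys=False)
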