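"""YAML run configuration: input discovery, parameters, treatment maps.

A run config looks like::

    input:
      dir: plate/
      template: "{well}_f{frame}_{marker}.tif"
      markers: [DNA, Actin, Tubulin]
    segmentation:
      smoothing_sigma: 2.0
      h: null            # null = auto (5% of dynamic range)
      log_sigma: 5.0
      min_nucleus_area: 40
      min_cell_area: 100
      border_policy: keep
      channel_weights: {Actin: 0.5, Tubulin: 0.5}
    regions: {w_nb: 2, w_pn: 4, w_cb: 3}
    features:
      morphology: {regions: [cell_region, dna_region, nondna_region]}
      intensity:
        markers: [DNA]
        regions: [dna_region]
      ...
    profiling: {method: dprofile, control: Rluc, C: 1.0, standardize: true}
    treatments: {A01: Rluc, A02: gene1, ...}   # well -> treatment
    groups: {gene1: actin, ...}                # treatment -> group
    workers: 1
    seed: 0
    store: results.h5

The input ``template`` names one image file per (well, frame, marker) with
``{well}``, ``{frame}`` and ``{marker}`` placeholders; frames and wells are
discovered by scanning the input directory against the template.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import SegmentationParams


class ConfigError(ValueError):
    """Raised for an invalid or incomplete run configuration."""


DEFAULT_REGION_WIDTHS = {"w_nb": 2, "w_pn": 4, "w_cb": 3}


@dataclass
class RunConfig:
    """Validated run configuration (see module docstring for the schema)."""

    input_dir: Path = Path(".")
    template: str = "{well}_f{frame}_{marker}.tif"
    markers: list[str] = field(default_factory=list)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    region_widths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WIDTHS)
    )
    features: dict = field(default_factory=dict)
    profiling: dict = field(default_factory=dict)
    treatments: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    workers: int = 1
    seed: int = 0
    store: Path = Path("results.h5")
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if not isinstance(d, dict):
            raise ConfigError("config root must be a mapping")
        inp = d.get("input", {}) or {}
        markers = list(inp.get("markers", []))
        template = inp.get("template", "{well}_f{frame}_{marker}.tif")
        placeholders = {
            name for _, name, _, _ in string.Formatter().parse(template) if name
        }
        if not {"well", "frame", "marker"} <= placeholders:
            raise ConfigError(
                "input.template must contain {well}, {frame} and {marker} "
                f"placeholders; got {template!r}"
            )
        seg_block = dict(d.get("segmentation", {}) or {})
        try:
            seg = SegmentationParams(**seg_block)
        except TypeError as exc:
            raise ConfigError(f"bad segmentation block: {exc}") from exc
        widths = dict(DEFAULT_REGION_WIDTHS)
        widths.update(d.get("regions", {}) or {})
        unknown = set(widths) - set(DEFAULT_REGION_WIDTHS)
        if unknown:
            raise ConfigError(f"unknown region width keys: {sorted(unknown)}")
        workers = int(d.get("workers", 1))
        if workers < 1:
            raise ConfigError("workers must be >= 1")
        return cls(
            input_dir=Path(inp.get("dir", ".")),
            template=template,
            markers=markers,
            segmentation=seg,
            region_widths=widths,
            features=d.get("features", {}) or {},
            profiling=d.get("profiling", {}) or {},
            treatments=d.get("treatments", {}) or {},
            groups=d.get("groups", {}) or {},
            workers=workers,
            seed=int(d.get("seed", 0)),
            store=Path(d.get("store", "results.h5")),
            raw=d,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            try:
                data = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
        cfg = cls.from_dict(data or {})
        if not cfg.input_dir.is_absolute():
            cfg.input_dir = Path(path).parent / cfg.input_dir
        return cfg

    def to_yaml_text(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)

    # -- input discovery ---------------------------------------------------
    def discover_frames(self) -> list[tuple[str, int]]:
        """Scan the input directory for (well, frame) pairs with all markers.

        The template is converted to a regex; a frame is reported only if a
        file exists for every configured marker.
        """
        if not self.markers:
            raise ConfigError("input.markers must list at least one marker")
        pattern = re.escape(self.template)
        pattern = pattern.replace(re.escape("{well}"), r"(?P<well>[A-Za-z0-9]+)")
        pattern = pattern.replace(re.escape("{frame}"), r"(?P<frame>\d+)")
        pattern = pattern.replace(re.escape("{marker}"), r"(?P<marker>[A-Za-z0-9]+)")
        rx = re.compile(pattern + r"\Z")
        found: dict[tuple[str, int], set[str]] = {}
        for f in sorted(self.input_dir.iterdir()):
            m = rx.match(f.name)
            if m:
                key = (m.group("well"), int(m.group("frame")))
                found.setdefault(key, set()).add(m.group("marker"))
        frames = sorted(
            key for key, mk in found.items() if set(self.markers) <= mk
        )
        if not frames:
            raise ConfigError(
                f"no (well, frame) with all markers {self.markers} found in "
                f"{self.input_dir} using template {self.template!r}"
            )
        return frames

    def image_path(self, well: str, frame: int, marker: str) -> Path:
        return self.input_dir / self.template.format(
            well=well, frame=frame, marker=marker
        )
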