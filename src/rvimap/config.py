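"""Single-file experiment configuration for the command-line pipeline.

A YAML (or JSON) document describes geometry, tissue variant, pacing protocol,
recording grids, RVI settings and noise, with one master seed from which every
stochastic component derives its own seed deterministically.  The resolved
configuration is echoed into every output directory for provenance.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import geometry as G
from . import tissue as T

__all__ = ["ExperimentConfig", "component_seed"]


def component_seed(master: int, component: str) -> int:
    """Deterministic per-component seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(component.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentConfig:
    seed: int = 0
    outdir: str = "rvimap_out"
    geometry: dict = field(default_factory=dict)
    tissue: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    grids: list = field(default_factory=lambda: [{"kind": "high_density"}])
    rvi: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)

    _KEYS = ("seed", "outdir", "geometry", "tissue", "protocol", "grids",
             "rvi", "noise", "synthetic")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        unknown = set(d) - set(cls._KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def echo(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config_resolved.json", "w") as f:
            json.dump(self.to_dict(), f, indent=2, default=str)

    # -- component builders ------------------------------------------------
    def build_spec(self) -> G.InfarctSpec:
        g = dict(self.geometry)
        if "sheet_size" in g:
            g["sheet_size"] = tuple(g["sheet_size"])
        if "center" in g and g["center"] is not None:
            g["center"] = tuple(g["center"])
        if "isthmus_axis" in g:
            g["isthmus_axis"] = tuple(g["isthmus_axis"])
        return G.InfarctSpec(**g)

    def build_mesh(self) -> G.LabeledMesh:
        return G.build_idealized_infarct_sheet(self.build_spec())

    def build_params(self) -> T.TissueParams:
        cfg = dict(self.tissue)
        variant = cfg.pop("variant", "long_apd")
        calibrate = cfg.pop("calibrate", False)
        targets = cfg.pop("apd_targets", {"myo": 176.0, "bz": 229.0})
        params = T.TissueParams(**cfg)
        if calibrate:
            params = T.calibrate_ionic_params(targets, base=params)
        return T.make_bz_variant(params, variant)

    def build_protocol(self) -> T.PacingProtocol:
        return T.PacingProtocol(**self.protocol)

    def build_grids(self, mesh: G.LabeledMesh) -> dict[str, G.RecordingGrid]:
        grids: dict[str, G.RecordingGrid] = {}
        for k, spec in enumerate(self.grids):
            spec = dict(spec)
            kind = spec.pop("kind")
            name = spec.pop("name", f"{kind}_{k}")
            if kind == "high_density":
                grids[name] = G.high_density_grid(mesh, **spec)
            elif kind == "decapolar":
                grids[name] = G.place_decapolar(mesh, **spec)
            elif kind == "fan":
                grids[name] = G.place_fan(mesh, **spec)
            elif kind == "multipolar_random":
                spec.setdefault("seed", component_seed(self.seed, f"grid_{k}"))
                grids[name] = G.place_multipolar_random(mesh, **spec)
            else:
                raise ValueError(f"unknown grid kind {kind!r}")
        return grids

    def rvi_settings(self) -> tuple[list[str], list[float], float]:
        methods = list(self.rvi.get("methods", ["minimum"]))
        radii = [float(r) for r in self.rvi.get("radii", [4.0])]
        threshold = float(self.rvi.get("threshold", 50.0))
        return methods, radii, threshold
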