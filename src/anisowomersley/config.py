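"""Run configuration, result serialisation and the output manifest.

A run is described by a single JSON-compatible structured text file with
sections ``solver``, ``rheology``, ``scales``, ``ec`` and ``curvature``;
user files are overlaid on the package defaults, and the effective merged
config is always written beside a run's outputs so every artifact is
reproducible from its run directory alone.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .constitutive import (
    G0_DEFAULT,
    NU_ZZ_DEFAULT,
    OMEGA0_DEFAULT,
    RHO_BLOOD,
    AnisotropyRatios,
    PhysicalScales,
    scales_from_config,
)
from .forces import ECGeometry

log = logging.getLogger("anisowomersley")

#: Numeric formatting used for all CSV output (12 significant digits).
FLOAT_FORMAT = "%.12g"


@dataclass
class RunConfig:
    """Flat, JSON-round-trippable run configuration."""

    solver: dict = field(
        default_factory=lambda: {"N": 150, "Nt": 256, "harmonics": 6}
    )
    rheology: dict = field(
        default_factory=lambda: {"beta": 0.1, "gamma": 0.1, "delta": 1.0}
    )
    scales: dict = field(
        default_factory=lambda: {
            "rho": RHO_BLOOD,
            "nu_zz": NU_ZZ_DEFAULT,
            "R": 0.015,
            "omega0": OMEGA0_DEFAULT,
            "G0": G0_DEFAULT,
        }
    )
    ec: dict = field(default_factory=lambda: {"A_EC": 100e-12, "V_EC": 100e-18})
    curvature: dict = field(
        default_factory=lambda: {"kappa_low": 0.35, "kappa_high": 0.70, "mode": "bound"}
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        for section, values in data.items():
            if not hasattr(cfg, section):
                raise ValueError(f"unknown config section {section!r}")
            current = getattr(cfg, section)
            unknown = set(values) - set(current)
            if unknown:
                raise ValueError(f"unknown keys in {section!r}: {sorted(unknown)}")
            current.update(values)
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    # Typed views -----------------------------------------------------------
    def ratios(self) -> AnisotropyRatios:
        r = self.rheology
        return AnisotropyRatios(beta=r["beta"], gamma=r["gamma"], delta=r["delta"])

    def physical_scales(self) -> PhysicalScales:
        return scales_from_config(**self.scales)

    def ec_geometry(self) -> ECGeometry:
        return ECGeometry(**self.ec)


def write_results(tables: dict, run_dir, config: RunConfig | None = None) -> dict:
    """Write DataFrames/dicts deterministically and return a hashed manifest.

    ``tables`` maps file names (with .csv or .json suffix) to DataFrames or
    JSON-serialisable objects.  CSV numerics use 12 significant digits; the
    manifest records a sha256 content hash per artifact.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}}
    if config is not None:
        config.to_file(run_dir / "effective_config.json")
        tables = dict(tables)
    for name, obj in sorted(tables.items()):
        path = run_dir / name
        try:
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(path, index=False, float_format=FLOAT_FORMAT)
            else:
                with open(path, "w") as fh:
                    json.dump(obj, fh, indent=2, sort_keys=True)
                    fh.write("\n")
        except OSError as err:
            raise OSError(f"failed writing {path}: {err}") from err
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][name] = {"sha256": digest, "bytes": path.stat().st_size}
    if config is not None:
        p = run_dir / "effective_config.json"
        manifest["files"]["effective_config.json"] = {
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            "bytes": p.stat().st_size,
        }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote %d artifacts to %s", len(manifest["files"]), run_dir)
    return manifest
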