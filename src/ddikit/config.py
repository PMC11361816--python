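"""Run configuration and provenance stamping.

Every CLI run writes a manifest next to its outputs recording the
subcommand, the fully resolved parameters (after applying the precedence
CLI flag > config file > built-in default), SHA-256 checksums of all input
files, the seed and the package version — enough to reproduce the run.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    "contact_cutoff": 10.0,       # Angstrom, interface residue definition
    "disorder_threshold": 0.4,    # IUPred-style score above which a residue is disordered
    "plddt_cutoff": 80.0,         # order/disorder transition level
    "plddt_window": 10,           # residues averaged inside a boundary
    "zscore_cutoff": 4.47,        # z-score at 80% expected approval probability
    "n_random": 100,              # degree-preserving null networks
    "swap_factor": 10.0,          # attempted swaps per edge
}


def resolve_params(
    cli_values: Mapping[str, Any] | None = None,
    config_file: str | Path | None = None,
) -> dict[str, Any]:
    """Merge parameters with precedence CLI flag > config file > default.

    CLI values equal to ``None`` count as "not given".
    """
    resolved = dict(DEFAULTS)
    if config_file is not None:
        with open(config_file) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {config_file} must hold a mapping")
        resolved.update(loaded)
    for key, value in (cli_values or {}).items():
        if value is not None:
            resolved[key] = value
    return resolved


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per pipeline run."""

    subcommand: str
    parameters: dict[str, Any]
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    seed: int | None = None
    version: str = ""
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        subcommand: str,
        parameters: Mapping[str, Any],
        input_paths: Mapping[str, str | Path] | None = None,
        seed: int | None = None,
    ) -> "RunManifest":
        from . import __version__

        inputs = {
            name: _sha256(Path(p))
            for name, p in (input_paths or {}).items()
            if p is not None and Path(p).is_file()
        }
        return cls(
            subcommand=subcommand,
            parameters=dict(parameters),
            inputs=inputs,
            seed=seed,
            version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def checksum(self) -> str:
        """Checksum over the reproducible fields (timestamp excluded)."""
        payload = json.dumps(
            {
                "subcommand": self.subcommand,
                "parameters": self.parameters,
                "inputs": self.inputs,
                "seed": self.seed,
                "version": self.version,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(
                {
                    "subcommand": self.subcommand,
                    "parameters": self.parameters,
                    "inputs": self.inputs,
                    "seed": self.seed,
                    "version": self.version,
                    "timestamp": self.timestamp,
                    "checksum": self.checksum(),
                },
                fh,
                indent=2,
                default=str,
            )
            fh.write("\n")
        return path
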