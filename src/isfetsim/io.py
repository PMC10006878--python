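"""Tabular output and run manifests.

All tabular results go to RFC-4180 CSV with a header row, stable column
order, and full float precision (repr round-trip via scientific notation),
so a read-back reproduces the values bit-exactly. Every CLI invocation also
writes a YAML manifest: the echoed config, tool version, per-stage
diagnostics, and SHA-256 checksums of the output files — enough to re-run
the computation and verify the outputs byte for byte.
"""

from __future__ import annotations

import csv
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig, dump_config


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as round-trip-exact CSV (floats via repr)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(df.columns)
        for row in df.itertuples(index=False):
            w.writerow([repr(v) if isinstance(v, float) else v for v in row])
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sweep_csv(result, path: str | Path) -> Path:
    """Export a device SweepResult (see device module) as CSV."""
    return write_csv(result.to_frame(), path)


def write_profile_csv(state, path: str | Path) -> Path:
    """Export an electrolyte profile (y, potential, concentrations)."""
    return write_csv(state.to_frame(), path)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    cfg: RunConfig,
    command: str,
    outputs: list[Path],
    diagnostics: dict | None = None,
) -> Path:
    """Write the run manifest next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    def _plain(v):
        if isinstance(v, dict):
            return {k: _plain(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_plain(x) for x in v]
        if isinstance(v, np.integer):
            return int(v)
        if isinstance(v, np.floating):
            return float(v)
        return v

    manifest = {
        "tool": "isfetsim",
        "version": __version__,
        "command": command,
        "config": yaml.safe_load(dump_config(cfg)),
        "diagnostics": _plain(diagnostics or {}),
        "outputs": {str(p.name): sha256_file(p) for p in outputs},
    }
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path
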