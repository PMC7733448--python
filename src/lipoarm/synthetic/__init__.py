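"""Synthetic inputs: reference landscape, Langevin/umbrella sampling,
planted state schedules, and toy structural trajectories.

Everything the analysis stages consume can be generated here, determinis-
tically from a seed, so the whole pipeline is testable without molecular-
dynamics runs or downloads.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import WhamInputError
from ..wham import UmbrellaWindow
from .complexes import (HALLMARKS, ToyComplexSpec, default_toy_complex,
                        generate_release_trajectory)
from .landscape import (DEFAULT_KNOTS, ReferenceLandscape,
                        build_reference_landscape)
from .langevin import (HarmonicBias, LangevinConfig, generate_umbrella_windows,
                       simulate_langevin)
from .schedules import VARIANTS, StateSchedule, variant_schedule

__all__ = [
    "ReferenceLandscape", "build_reference_landscape", "DEFAULT_KNOTS",
    "LangevinConfig", "HarmonicBias", "simulate_langevin",
    "generate_umbrella_windows", "StateSchedule", "variant_schedule",
    "VARIANTS", "ToyComplexSpec", "default_toy_complex",
    "generate_release_trajectory", "HALLMARKS",
    "write_windows", "read_windows",
]


def write_windows(windows, directory, temperature: float = 300.0,
                  seed: int | None = None) -> Path:
    """Write umbrella windows as per-window CSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.csv"
        pd.DataFrame({"step": np.arange(w.n_samples), "d": w.samples}
                     ).to_csv(directory / fname, index=False)
        files.append(fname)
    manifest = {
        "centers": [w.center for w in windows],
        "spring_k": [w.spring_k for w in windows],
        "temperature": temperature,
        "seed": seed,
        "files": files,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_windows(manifest_path) -> tuple[list[UmbrellaWindow], dict]:
    """Read umbrella windows written by :func:`write_windows`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise WhamInputError(f"no such manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    windows = []
    for center, k, fname in zip(manifest["centers"], manifest["spring_k"],
                                manifest["files"]):
        df = pd.read_csv(manifest_path.parent / fname)
        windows.append(UmbrellaWindow(center=float(center), spring_k=float(k),
                                      samples=df["d"].to_numpy()))
    return windows, manifest
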