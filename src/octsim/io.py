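"""Text-file I/O for depth profiles and benchmark tables.

Profiles are written as tab-separated tables with a ``#``-prefixed YAML
metadata header echoing the full configuration, seed, per-run counters and
package version, so that a file can be reproduced bit-for-bit from its own
header.  Numbers are written with 17 significant digits (exact double
round-trip).
"""
from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import SimulationConfig
from .detection import DepthProfile

__all__ = ["write_profile", "read_profile"]

_FLOAT_FMT = "%.17g"


def write_profile(path: str | Path, profile: DepthProfile,
                  config: SimulationConfig | None = None,
                  extra_meta: dict[str, Any] | None = None) -> None:
    meta: dict[str, Any] = {"version": __version__, "model": profile.model}
    if config is not None:
        meta["config"] = config.to_dict()
    meta.update(profile.meta)
    if extra_meta:
        meta.update(extra_meta)
    header = yaml.safe_dump(meta, sort_keys=False).rstrip("\n")
    df = profile.to_dataframe()
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_profile(path: str | Path) -> DepthProfile:
    meta_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                meta_lines.append(line[1:].strip("\n").removeprefix(" "))
            else:
                break
    meta = yaml.safe_load("\n".join(meta_lines)) or {}
    df = pd.read_csv(path, sep="\t", comment="#")
    model = meta.pop("model", None)
    n = None
    config = meta.get("config")
    if config:
        n = float(config["medium"]["n"])
    depth_mm = df["depth_um"].to_numpy() * 1e-3
    return DepthProfile(
        bin_index=df["bin"].to_numpy(dtype=np.int64),
        opl_depth=df["opl_depth_um"].to_numpy() * 1e-3,
        physical_depth=depth_mm,
        intensity=df["intensity"].to_numpy(dtype=float),
        intensity_sq=df["intensity_sq"].to_numpy(dtype=float),
        n_contributing=df["n_photons"].to_numpy(dtype=np.int64),
        model=model,
        meta=meta,
    )
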