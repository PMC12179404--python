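"""Run configuration and reproducibility manifests.

A :class:`RunConfig` bundles the acquisition and analysis constants shared
across pipeline stages: the fMRI repetition time, the DCE sampling grid
(23 series of 16.78 s each, contrast injected at the end of series 2),
the 8-mm periventricular distance rule, the band-pass edges for the
BOLD-CSF coupling analysis, and the bootstrap/alpha settings of the
inference back end.  Every CLI stage records its config, seed and input
hashes in a JSON manifest so deterministic outputs are reproducible
bit-for-bit.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


@dataclass(frozen=True)
class RunConfig:
    """Shared pipeline constants.

    Parameters
    ----------
    seed:
        Base seed for every stochastic stage; recorded in all manifests.
    tr:
        fMRI repetition time in seconds.
    dce_series_count:
        Number of DCE image series (time samples).
    dce_series_duration:
        Duration of one DCE series in seconds (the sampling interval).
    injection_series_index:
        1-based series at whose end contrast is injected; the injection
        time is ``injection_series_index * dce_series_duration``.
    pv_distance_threshold:
        Lesion-to-ventricle distance (mm) at or below which a lesion is
        periventricular.
    bandpass:
        Low/high band-pass edges in Hz for coupling preprocessing.
    lag_window:
        Half-width of the cross-correlation lag window in seconds.
    bootstrap_n:
        Default bootstrap resamples for mediation / SEM intervals.
    alpha:
        Significance threshold.
    """

    seed: int = 0
    tr: float = 2.0
    dce_series_count: int = 23
    dce_series_duration: float = 16.78
    injection_series_index: int = 2
    pv_distance_threshold: float = 8.0
    bandpass: tuple[float, float] = (0.01, 0.1)
    lag_window: float = 20.0
    bootstrap_n: int = 5000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.dce_series_duration <= 0 or self.dce_series_count < 3:
            raise ValueError("DCE grid must have >=3 series of positive duration")
        if not (0 < self.injection_series_index < self.dce_series_count):
            raise ValueError("injection series must fall inside the acquisition")
        if self.pv_distance_threshold <= 0:
            raise ValueError("periventricular threshold must be positive")
        lo, hi = self.bandpass
        if not (0 < lo < hi):
            raise ValueError("bandpass edges must satisfy 0 < low < high")
        if self.lag_window <= 0 or self.bootstrap_n < 0:
            raise ValueError("lag_window must be positive and bootstrap_n >= 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def injection_time(self) -> float:
        """Injection time in seconds from the start of acquisition."""
        return self.injection_series_index * self.dce_series_duration

    def dce_time_grid(self):
        """Sample times (s): sample k is the end of series k+1."""
        import numpy as np

        return (np.arange(self.dce_series_count) + 1) * self.dce_series_duration

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_ini(cls, path: str | Path, section: str = "run") -> "RunConfig":
        """Load from a plain-text ``key = value`` config section."""
        parser = configparser.ConfigParser()
        read = parser.read(str(path))
        if not read:
            raise FileNotFoundError(path)
        if section not in parser:
            return cls()
        sec = parser[section]
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in sec:
                continue
            raw = sec[f.name]
            if f.name == "bandpass":
                lo, hi = (float(x) for x in raw.split(","))
                kwargs[f.name] = (lo, hi)
            elif f.type in ("int", int) or f.name in (
                "seed",
                "dce_series_count",
                "injection_series_index",
                "bootstrap_n",
            ):
                kwargs[f.name] = int(raw)
            else:
                kwargs[f.name] = float(raw)
        return cls(**kwargs)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: RunConfig,
    inputs: Sequence[str | Path] = (),
    extra: dict | None = None,
) -> dict:
    """Write a JSON manifest (config + seed + input hashes) next to outputs."""
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {str(p): sha256_file(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
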