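"""Full factorial study design and exposure-derived quantities.

The study crosses 2 systems x 5 X-ray exposure times x 6 light
conditions (five durations plus a no-light control) x 10 repeats,
yielding 600 acquisitions.  Each cell carries its own RNG seed derived
deterministically from the root seed and the cell's factor levels, so
any single cell can be re-rendered in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from itertools import product
from typing import TYPE_CHECKING

import pandas as pd

from .errors import ConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .config import RunConfig

__all__ = ["DesignCell", "Manifest", "build_manifest", "dose_area_product",
           "cell_seed"]

MANIFEST_COLUMNS = ("system", "exposure_time_s", "light_duration_s",
                    "repeat_index", "seed", "image_path")


@dataclass(frozen=True)
class DesignCell:
    """One factorial condition instance (a single acquisition)."""

    system: str
    exposure_time_s: float
    light_duration_s: float
    repeat_index: int
    seed: int
    image_path: str = ""


@dataclass(frozen=True)
class Manifest:
    """Ordered list of design cells plus the generating config hash."""

    cells: tuple[DesignCell, ...]
    config_hash: str

    def __len__(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "system": c.system,
                "exposure_time_s": c.exposure_time_s,
                "light_duration_s": c.light_duration_s,
                "repeat_index": c.repeat_index,
                "seed": c.seed,
                "image_path": c.image_path,
            }
            for c in self.cells
        ], columns=list(MANIFEST_COLUMNS))

    def with_paths(self, paths: list[str]) -> "Manifest":
        if len(paths) != len(self.cells):
            raise ValueError("one path per cell required")
        return Manifest(
            cells=tuple(replace(c, image_path=p)
                        for c, p in zip(self.cells, paths)),
            config_hash=self.config_hash,
        )


def cell_seed(root_seed: int, system: str, exposure_time_s: float,
              light_duration_s: float, repeat_index: int) -> int:
    """Deterministic 31-bit seed for one design cell.

    SHA-256 of the string
    ``"{root_seed}|{system}|{exposure:.6g}|{light:.6g}|{repeat}"``,
    first four bytes big-endian, reduced mod 2**31.
    """
    key = (f"{root_seed}|{system}|{exposure_time_s:.6g}|"
           f"{light_duration_s:.6g}|{repeat_index}")
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _check_unique(name: str, values) -> list:
    values = list(values)
    if len(set(values)) != len(values):
        raise ConfigError(f"duplicate {name} levels: {values}")
    return values


def build_manifest(config: "RunConfig") -> Manifest:
    """Enumerate every (system, exposure, light, repeat) combination
    exactly once, lexicographically ordered in that factor order."""
    from .config import config_hash  # deferred import, no cycle at module load

    systems = _check_unique("system", config.systems.keys())
    exposures = _check_unique("exposure time", config.exposure_times_s)
    lights = _check_unique("light duration", config.light_durations_s)
    repeats = range(1, config.n_repeats + 1)

    cells = tuple(
        DesignCell(
            system=s,
            exposure_time_s=e,
            light_duration_s=l,
            repeat_index=r,
            seed=cell_seed(config.root_seed, s, e, l, r),
        )
        for s, e, l, r in product(systems, exposures, lights, repeats)
    )
    return Manifest(cells=cells, config_hash=config_hash(config))


def dose_area_product(exposure_time_s: float, dap_rate: float) -> float:
    """Dose-area product (mGy cm^2) at fixed tube settings: exactly
    proportional to exposure time, ``dap_rate * exposure_time_s``."""
    if exposure_time_s <= 0:
        raise ValueError("exposure_time_s must be positive")
    if dap_rate <= 0:
        raise ValueError("dap_rate must be positive")
    return dap_rate * exposure_time_s
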