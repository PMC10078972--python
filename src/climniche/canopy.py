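"""Threshold coding of biome occupancy into the 3-state canopy character.

Each species' biome proportions (over its unique occurrence records) are
collapsed to two binary flags: occupying closed-canopy (forested) habitat
and occupying open-canopy (non-forested) habitat.  A flag is set when
strictly more than one third of unique records fall in biomes of that canopy
class.  The two flags combine into a composite state:

    (closed=1, open=0) -> "closed"    specialist of forested habitat
    (closed=1, open=1) -> "both"      generalist
    (closed=0, open=1) -> "open"      specialist of non-forested habitat

Because the two canopy classes partition the biomes, the flags cannot both
be zero.  Two schemes ship: ``primary`` (Mediterranean forests, woodlands &
scrub counted as closed) and ``mediterranean_open`` (the robustness variant
treating that biome as open).  The mapping lives in an editable YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "CanopyScheme",
    "load_scheme",
    "code_flags",
    "composite",
    "code_species",
    "THRESHOLD",
]

THRESHOLD = 1.0 / 3.0
STATES = ("closed", "both", "open")


@dataclass(frozen=True)
class CanopyScheme:
    """Mapping biome label -> canopy class ('closed' | 'open')."""

    name: str
    mapping: Mapping[str, str]

    def canopy_of(self, biome: str) -> str:
        if biome not in self.mapping:
            raise KeyError(f"biome {biome!r} not in scheme {self.name!r}")
        return self.mapping[biome]


def load_scheme(name: str = "primary", path: str | None = None) -> CanopyScheme:
    """Load a scheme from the packaged (or a user-supplied) YAML config."""
    if path is None:
        text = resources.files("climniche.data").joinpath("biome_canopy.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    mapping = dict(raw["primary"])
    if name == "primary":
        pass
    elif name in raw:
        mapping.update(raw[name])
    else:
        raise KeyError(f"no scheme {name!r} in config")
    return CanopyScheme(name=name, mapping=mapping)


def code_flags(
    biome_proportions: Mapping[str, float],
    scheme: CanopyScheme,
    threshold: float = THRESHOLD,
) -> tuple[int, int]:
    """Binary (closed_flag, open_flag) from a species' biome proportions.

    A flag is 1 iff the summed proportion of that canopy class strictly
    exceeds ``threshold`` (a share of exactly 1/3 does not count).
    """
    total = sum(biome_proportions.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"biome proportions sum to {total}, expected 1")
    closed_share = sum(
        p for b, p in biome_proportions.items() if scheme.canopy_of(b) == "closed"
    )
    open_share = sum(
        p for b, p in biome_proportions.items() if scheme.canopy_of(b) == "open"
    )
    closed_flag = int(closed_share > threshold)
    open_flag = int(open_share > threshold)
    if closed_flag == 0 and open_flag == 0:
        raise ValueError(
            "both canopy flags are zero; impossible when the two classes "
            "partition the biomes"
        )
    return closed_flag, open_flag


def composite(closed_flag: int, open_flag: int) -> str:
    """Composite 3-state canopy character from the two binary flags."""
    table = {(1, 0): "closed", (1, 1): "both", (0, 1): "open"}
    key = (int(closed_flag), int(open_flag))
    if key not in table:
        raise ValueError(f"invalid flag combination {key}")
    return table[key]


def code_species(
    biome_props: pd.DataFrame,
    scheme: CanopyScheme,
    threshold: float = THRESHOLD,
) -> pd.DataFrame:
    """Code every species in a species x biome proportion table.

    Returns a frame indexed by species with columns ``closed_flag``,
    ``open_flag``, ``state`` and the scheme name.
    """
    rows = {}
    for sp, row in biome_props.iterrows():
        props = {b: float(p) for b, p in row.items() if p > 0}
        c, o = code_flags(props, scheme, threshold)
        rows[sp] = {"closed_flag": c, "open_flag": o, "state": composite(c, o),
                    "scheme": scheme.name}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "species"
    return out
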