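"""Stimulus set construction and trial-list generation.

The experimental design uses 15 cubes organised in three subsets that share a
common middle cube (750 cm^3, 375 g, 0.5 g/cm^3):

* ``equal_density`` — weight grows linearly with volume at 0.5 g/cm^3, as for
  ordinary same-material objects;
* ``equal_weight`` — every cube weighs 375 g, so density falls with volume
  (classic size-weight-illusion stimuli);
* ``increasing_density`` — both weight and density grow with volume.

Cubes are paired exhaustively (same- and different-subset pairs, identical
cubes excluded), giving 105 unique pairs for the default set.  Pairs that
contain the middle cube enter the base trial list three times, all others
once (133 base entries); each entry is presented twice with left/right
positions swapped, for 266 trials per participant, in seeded random order
split evenly over two sessions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CubeSpec",
    "StimulusPair",
    "StimulusConfig",
    "MIDDLE_VOLUME",
    "MIDDLE_WEIGHT",
    "MIDDLE_DENSITY",
    "build_stimulus_set",
    "enumerate_pairs",
    "build_trial_list",
    "pair_id_for",
    "cubes_to_frame",
    "cubes_from_frame",
]

MIDDLE_VOLUME = 750.0
MIDDLE_WEIGHT = 375.0
MIDDLE_DENSITY = 0.5

#: order in which subsets are materialised; the middle cube is emitted once,
#: tagged ``shared_middle``.
_SUBSET_ORDER = ("equal_density", "equal_weight", "increasing_density")

VALID_SUBSETS = frozenset(_SUBSET_ORDER) | {"shared_middle"}


@dataclass(frozen=True)
class CubeSpec:
    """One physical stimulus cube.

    ``density * volume == weight`` is enforced to 1e-9 relative tolerance.
    """

    cube_id: str
    volume: float  # cm^3
    weight: float  # g
    density: float  # g/cm^3
    subset: str

    def __post_init__(self) -> None:
        if not (self.volume > 0 and self.weight > 0 and self.density > 0):
            raise ValueError(
                f"cube {self.cube_id!r}: volume, weight and density must be "
                f"strictly positive (got {self.volume}, {self.weight}, {self.density})"
            )
        if self.subset not in VALID_SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}")
        if abs(self.density * self.volume - self.weight) > 1e-9 * self.weight:
            raise ValueError(
                f"cube {self.cube_id!r}: density*volume = "
                f"{self.density * self.volume} != weight {self.weight}"
            )


@dataclass(frozen=True)
class StimulusPair:
    """An unordered pair of distinct cubes; ``pair_id`` is order-invariant."""

    cube_a: CubeSpec
    cube_b: CubeSpec
    pair_id: str

    def __post_init__(self) -> None:
        if self.cube_a.cube_id == self.cube_b.cube_id:
            raise ValueError("identical-stimulus pairs are excluded")

    def contains(self, cube_id: str) -> bool:
        return cube_id in (self.cube_a.cube_id, self.cube_b.cube_id)


def pair_id_for(id_a: str, id_b: str) -> str:
    """Order-invariant pair identifier: sorted cube ids joined by '|'."""
    return "|".join(sorted((id_a, id_b)))


@dataclass
class StimulusConfig:
    """Per-subset volume lists and density/weight rules for the cube set.

    Defaults reconstruct the published design: a 100 cm^3 volume grid with
    additional 50 cm^3 steps around the middle cube in the fixed-density
    subset, constant weight 375 g in the SWI subset (pairwise density ratios
    spanning 0.58-0.89), and densities linear through the middle cube in the
    increasing-density subset.
    """

    equal_density_volumes: tuple = (550, 650, 700, 750, 800, 850, 950)
    equal_density_value: float = MIDDLE_DENSITY
    equal_weight_volumes: tuple = (550, 650, 750, 850, 950)
    equal_weight_value: float = MIDDLE_WEIGHT
    increasing_density_volumes: tuple = (550, 650, 750, 850, 950)
    #: density change per cm^3 of volume; line passes through the middle cube
    increasing_density_slope: float = 0.00045

    def __post_init__(self) -> None:
        for name in (
            "equal_density_volumes",
            "equal_weight_volumes",
            "increasing_density_volumes",
        ):
            vols = getattr(self, name)
            if any(v <= 0 for v in vols):
                raise ValueError(f"{name}: volumes must be strictly positive")
            if MIDDLE_VOLUME not in [float(v) for v in vols]:
                raise ValueError(
                    f"{name}: every subset must contain the shared middle "
                    f"volume {MIDDLE_VOLUME} cm^3"
                )


_SUBSET_PREFIX = {
    "equal_density": "D",
    "equal_weight": "W",
    "increasing_density": "I",
    "shared_middle": "M",
}


def build_stimulus_set(config: StimulusConfig | None = None) -> list[CubeSpec]:
    """Construct the cube set; 15 cubes for the default configuration.

    The middle cube appears exactly once, tagged ``shared_middle``.
    """
    config = config or StimulusConfig()
    cubes: list[CubeSpec] = [
        CubeSpec(
            cube_id="M750",
            volume=MIDDLE_VOLUME,
            weight=MIDDLE_WEIGHT,
            density=MIDDLE_DENSITY,
            subset="shared_middle",
        )
    ]
    for subset in _SUBSET_ORDER:
        if subset == "equal_density":
            vols = config.equal_density_volumes
            dens = [config.equal_density_value] * len(vols)
        elif subset == "equal_weight":
            vols = config.equal_weight_volumes
            dens = [config.equal_weight_value / v for v in vols]
        else:
            vols = config.increasing_density_volumes
            dens = [
                MIDDLE_DENSITY + config.increasing_density_slope * (v - MIDDLE_VOLUME)
                for v in vols
            ]
        for v, d in zip(vols, dens):
            if float(v) == MIDDLE_VOLUME:
                continue  # shared middle emitted once above
            v = float(v)
            # keep the subset's defining quantity exact (constant weight in the
            # SWI subset), deriving the other from it
            if subset == "equal_weight":
                w = float(config.equal_weight_value)
                d = w / v
            else:
                d = float(d)
                w = d * v
            cubes.append(
                CubeSpec(
                    cube_id=f"{_SUBSET_PREFIX[subset]}{v:g}",
                    volume=v,
                    weight=w,
                    density=d,
                    subset=subset,
                )
            )
    ids = [c.cube_id for c in cubes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate cube ids in configuration: {ids}")
    return cubes


def enumerate_pairs(cubes: list[CubeSpec]) -> list[StimulusPair]:
    """All unordered pairs of distinct cubes: n(n-1)/2 pairs."""
    if len(cubes) < 2:
        raise ValueError("need at least two cubes to form pairs")
    ids = [c.cube_id for c in cubes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cube_ids")
    return [
        StimulusPair(a, b, pair_id_for(a.cube_id, b.cube_id))
        for a, b in itertools.combinations(cubes, 2)
    ]


def build_trial_list(
    pairs: list[StimulusPair],
    middle_id: str | None,
    seed: int,
    *,
    participant_id: str = "P01",
    n_sessions: int = 2,
) -> pd.DataFrame:
    """Randomised trial list for one participant.

    Base list: every pair once, plus each middle-containing pair twice more
    (middle pairs appear three times).  Each base entry yields two trials with
    left/right positions swapped.  The order is a seeded permutation; the
    first half of trials is session 1.  ``middle_id=None`` disables the
    middle-pair repetition.

    Returns a DataFrame with columns participant_id, session, trial_index,
    left_cube, right_cube, pair_id, presentation.
    """
    if middle_id is not None and not any(p.contains(middle_id) for p in pairs):
        raise ValueError(f"middle cube {middle_id!r} absent from pairs")
    base: list[StimulusPair] = []
    for p in pairs:
        base.append(p)
        if middle_id is not None and p.contains(middle_id):
            base.extend([p, p])

    rows = []
    for p in base:
        rows.append((p.cube_a.cube_id, p.cube_b.cube_id, p.pair_id, 1))
        rows.append((p.cube_b.cube_id, p.cube_a.cube_id, p.pair_id, 2))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    n = len(rows)
    per_session = int(np.ceil(n / n_sessions))
    records = []
    for idx, k in enumerate(order, start=1):
        left, right, pid, pres = rows[k]
        records.append(
            {
                "participant_id": participant_id,
                "session": 1 + (idx - 1) // per_session,
                "trial_index": idx,
                "left_cube": left,
                "right_cube": right,
                "pair_id": pid,
                "presentation": pres,
            }
        )
    return pd.DataFrame.from_records(records)


def cubes_to_frame(cubes: list[CubeSpec]) -> pd.DataFrame:
    """Serialise cubes with the stimuli.csv column contract."""
    return pd.DataFrame(
        {
            "cube_id": [c.cube_id for c in cubes],
            "subset": [c.subset for c in cubes],
            "volume_cm3": [c.volume for c in cubes],
            "weight_g": [c.weight for c in cubes],
            "density_g_cm3": [c.density for c in cubes],
        }
    )


def cubes_from_frame(frame: pd.DataFrame) -> list[CubeSpec]:
    """Inverse of :func:`cubes_to_frame`."""
    return [
        CubeSpec(
            cube_id=str(r.cube_id),
            volume=float(r.volume_cm3),
            weight=float(r.weight_g),
            density=float(r.density_g_cm3),
            subset=str(r.subset),
        )
        for r in frame.itertuples()
    ]
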