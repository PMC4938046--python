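"""Synthetic bee-choice data emulating the 2x2 flower-cue experiment.

Generates per-bee binary landing sequences under a logistic model with a
colony random intercept, matching the real experiment's structure: 57 bees
from 3 colonies in a cue-type (social bee model vs. non-social foam) by
prior reward-distribution (high-variance vs. no-variance) design, with
first-landing-on-a-cued-flower as the primary outcome and chance at 1/3
(4 cued flowers of 12).  Only the statistical structure of test-phase
outcomes is emulated — no flower geometry, bout timing, or training-phase
learning dynamics.

Default effect sizes are plausible values on the logit scale chosen to echo
the magnitude of the reported mixed-model fits; they parameterise the
generator and are never treated as ground truth for the real bees.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .stats import ChoiceRecord

__all__ = [
    "GeneratorConfig",
    "generate_choice_dataset",
    "write_choice_csv",
    "read_choice_csv",
]

#: group sizes keyed by (cue_type, distribution); cue_type 1 = social,
#: distribution 1 = no-variance.  57 bees total: 16 social/high-variance,
#: 17 social/no-variance, and the 24 non-social bees split 12/12.
DEFAULT_GROUP_SIZES = {(1, 0): 16, (1, 1): 17, (0, 0): 12, (0, 1): 12}

#: chance landing probability on the logit scale: logit(1/3)
LOGIT_CHANCE = math.log(0.5)

#: full-model effects (reference cell: non-social cue, high-variance).
#: Signs are oriented so that the social/high-variance cell sits above
#: chance and the remaining cells do not, the qualitative pattern the
#: design emulates; magnitudes echo reported mixed-model fits.
DEFAULT_FULL_EFFECTS = {
    "cue_type": 1.455,
    "distribution": -0.733,
    "interaction": -2.593,
}

#: per-cue distribution effects for the split parameterization
DEFAULT_SPLIT_EFFECTS = {"social": -3.125, "nonsocial": -0.696}


@dataclasses.dataclass
class GeneratorConfig:
    """Design and generative parameters for a synthetic choice dataset.

    ``parameterization`` selects how the linear predictor is built from the
    treatment cell: ``"full"`` uses cue, distribution and interaction
    effects relative to ``baseline_logit``; ``"split"`` applies a per-cue
    distribution effect only.  Landings within a bee are independent
    Bernoulli draws at the bee's probability.
    """

    group_sizes: dict[tuple[int, int], int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_colonies: int = 3
    colony_sd: float = 0.3
    baseline_logit: float = LOGIT_CHANCE
    parameterization: Literal["full", "split"] = "full"
    full_effects: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FULL_EFFECTS)
    )
    split_effects: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SPLIT_EFFECTS)
    )
    n_landings_per_bee: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = {tuple(k): int(v) for k, v in self.group_sizes.items()}
        for cell, size in self.group_sizes.items():
            if cell not in DEFAULT_GROUP_SIZES:
                raise ValueError(f"unknown treatment cell {cell!r}")
            if size < 1:
                raise ValueError(f"group size for {cell} must be positive, got {size}")
        if self.n_colonies < 1:
            raise ValueError("n_colonies must be >= 1")
        if self.colony_sd < 0:
            raise ValueError("colony_sd must be >= 0")
        if self.n_landings_per_bee < 1:
            raise ValueError("n_landings_per_bee must be >= 1")
        if self.parameterization not in ("full", "split"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")

    def linear_predictor(self, cue_type: int, distribution: int) -> float:
        """Fixed-effects logit for one treatment cell (no colony intercept)."""
        if self.parameterization == "full":
            return (
                self.baseline_logit
                + self.full_effects["cue_type"] * cue_type
                + self.full_effects["distribution"] * distribution
                + self.full_effects["interaction"] * cue_type * distribution
            )
        effect = self.split_effects["social" if cue_type else "nonsocial"]
        return self.baseline_logit + effect * distribution

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown generator keys: {', '.join(unknown)}")
        if "group_sizes" in data:
            data["group_sizes"] = {
                tuple(int(x) for x in key.split(",")): v
                for key, v in data["group_sizes"].items()
            }
        return cls(**data)


def generate_choice_dataset(config: GeneratorConfig) -> list[ChoiceRecord]:
    """Draw one synthetic dataset; deterministic for a fixed config and seed.

    Bees are assigned round-robin to colonies across the whole design (so
    the default 57 bees land 19/19/19), each colony gets one normal
    intercept on the logit scale, and every landing is an independent
    Bernoulli draw at the bee's inverse-logit probability.
    """
    rng = np.random.default_rng(config.seed)
    intercepts = rng.normal(0.0, config.colony_sd, size=config.n_colonies)
    records: list[ChoiceRecord] = []
    bee_index = 0
    for (cue, dist), size in sorted(config.group_sizes.items()):
        eta_cell = config.linear_predictor(cue, dist)
        for _ in range(size):
            colony = bee_index % config.n_colonies
            p = expit(eta_cell + intercepts[colony])
            landings = rng.binomial(1, p, size=config.n_landings_per_bee)
            records.append(
                ChoiceRecord(
                    bee_id=f"bee{bee_index + 1:04d}",
                    colony=f"colony{colony + 1}",
                    cue_type=cue,
                    distribution=dist,
                    landings=tuple(int(v) for v in landings),
                )
            )
            bee_index += 1
    return records


_LONG_COLUMNS = ["bee_id", "colony", "cue_type", "distribution", "landing_index", "landed_on_cued"]
_WIDE_COLUMNS = ["bee_id", "colony", "cue_type", "distribution", "first_choice_cued"]


def write_choice_csv(records: Iterable[ChoiceRecord], path) -> None:
    """Write records in long format, one row per landing (1-based index)."""
    rows = [
        {
            "bee_id": r.bee_id,
            "colony": r.colony,
            "cue_type": r.cue_type,
            "distribution": r.distribution,
            "landing_index": i + 1,
            "landed_on_cued": landed,
        }
        for r in records
        for i, landed in enumerate(r.landings)
    ]
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)


def _row_error(row: int, column: str, message: str) -> ValueError:
    return ValueError(f"row {row}, column {column!r}: {message}")


def _check_binary(frame: pd.DataFrame, column: str) -> None:
    for row, value in zip(frame.index, frame[column]):
        try:
            ok = int(value) in (0, 1) and float(value) == int(value)
        except (TypeError, ValueError):
            ok = False
        if not ok:
            # +2 converts frame position to 1-based file line beneath the header
            raise _row_error(int(row) + 2, column, f"expected 0 or 1, got {value!r}")


def read_choice_csv(path) -> list[ChoiceRecord]:
    """Read a choice CSV, accepting long (per landing) or wide (per bee) layout.

    The long layout has columns ``bee_id, colony, cue_type, distribution,
    landing_index, landed_on_cued``; the wide layout replaces the last two
    with ``first_choice_cued``.  Malformed values raise with the offending
    row and column.  ``write_choice_csv`` then ``read_choice_csv`` is the
    identity on record collections.
    """
    frame = pd.read_csv(path)
    columns = list(frame.columns)
    if set(_LONG_COLUMNS) <= set(columns):
        return _records_from_long(frame)
    if set(_WIDE_COLUMNS) <= set(columns):
        return _records_from_wide(frame)
    raise ValueError(
        f"unrecognised columns {columns}; expected {_LONG_COLUMNS} (long) "
        f"or {_WIDE_COLUMNS} (wide)"
    )


def _records_from_long(frame: pd.DataFrame) -> list[ChoiceRecord]:
    _check_binary(frame, "cue_type")
    _check_binary(frame, "distribution")
    _check_binary(frame, "landed_on_cued")
    for row, value in zip(frame.index, frame["landing_index"]):
        if not float(value) == int(value) or int(value) < 1:
            raise _row_error(int(row) + 2, "landing_index", f"expected positive integer, got {value!r}")
    records = []
    # sort=False keeps first-appearance order so a written file round-trips
    for bee_id, group in frame.groupby("bee_id", sort=False):
        group = group.sort_values("landing_index")
        expected = np.arange(1, len(group) + 1)
        if not np.array_equal(group["landing_index"].to_numpy(), expected):
            raise ValueError(
                f"bee {bee_id}: landing_index must run 1..{len(group)} without gaps"
            )
        for column in ("colony", "cue_type", "distribution"):
            if group[column].nunique() != 1:
                raise ValueError(f"bee {bee_id}: inconsistent values in column {column!r}")
        records.append(
            ChoiceRecord(
                bee_id=str(bee_id),
                colony=str(group["colony"].iloc[0]),
                cue_type=int(group["cue_type"].iloc[0]),
                distribution=int(group["distribution"].iloc[0]),
                landings=tuple(int(v) for v in group["landed_on_cued"]),
            )
        )
    return records


def _records_from_wide(frame: pd.DataFrame) -> list[ChoiceRecord]:
    _check_binary(frame, "cue_type")
    _check_binary(frame, "distribution")
    _check_binary(frame, "first_choice_cued")
    if frame["bee_id"].duplicated().any():
        dupes = frame.loc[frame["bee_id"].duplicated(), "bee_id"].tolist()
        raise ValueError(f"duplicated bee_id in wide layout: {dupes}")
    return [
        ChoiceRecord(
            bee_id=str(row.bee_id),
            colony=str(row.colony),
            cue_type=int(row.cue_type),
            distribution=int(row.distribution),
            landings=(int(row.first_choice_cued),),
        )
        for row in frame.itertuples()
    ]
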