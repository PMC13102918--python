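"""Twin-pair data containers, CSV I/O, and missingness coding.

The central container is :class:`TwinDataset`: an ordered collection of
twin pairs (MZ or DZ), each carrying one value per twin for one or more
traits.  Traits are either continuous (e.g. number of valid trials a
participant contributed to an experiment) or binary (1 = the participant's
data for an experiment is missing, 0 = valid data).  A value may be absent
(``NaN``): absent twins still contribute their co-twin's marginal
likelihood to the model fits.

The wide CSV interchange schema is ``pair_id, zygosity`` followed by
``<trait>_t1, <trait>_t2`` per trait; empty cells denote absent values.
Twin order within a pair is the file's column order and is preserved by
every order-specific statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataFormatError, TraitValueError, DegenerateInputError

ABSENT = float("nan")

MZ = "MZ"
DZ = "DZ"
ZYGOSITIES = (MZ, DZ)


def is_absent(x) -> bool:
    """True if ``x`` encodes a missing trait value."""
    if x is None:
        return True
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False


class SessionStatus(str, Enum):
    """Outcome of one experimental session, as logged by the testers."""

    VALID_DATA = "valid_data"
    POOR_DATA = "poor_data"
    NO_DATA_TECHNICAL = "no_data_technical"
    NO_DATA_CHILD = "no_data_child"
    NO_DATA_OTHER = "no_data_other"


@dataclass(frozen=True)
class TraitSpec:
    """Declares a trait's name, kind and admissible value range.

    ``kind`` is ``"continuous"`` (includes trial counts) or ``"binary"``.
    Binary traits always have range {0, 1}.
    """

    name: str
    kind: str
    valid_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise TraitValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "binary":
            object.__setattr__(self, "valid_range", (0.0, 1.0))
        elif self.valid_range is not None:
            lo, hi = self.valid_range
            if not lo <= hi:
                raise TraitValueError(
                    f"trait {self.name!r}: range lower bound {lo} > upper {hi}"
                )

    def check_value(self, x, row=None):
        """Validate one value; returns the value as float (NaN if absent)."""
        if is_absent(x):
            return ABSENT
        v = float(x)
        where = "" if row is None else f" (row {row})"
        if self.kind == "binary" and v not in (0.0, 1.0):
            raise TraitValueError(
                f"trait {self.name!r}: binary value {v!r} not in {{0, 1}}{where}"
            )
        if self.valid_range is not None:
            lo, hi = self.valid_range
            if not lo <= v <= hi:
                raise TraitValueError(
                    f"trait {self.name!r}: value {v} outside [{lo}, {hi}]{where}"
                )
        return v


@dataclass
class TwinPairRecord:
    """One twin pair: id, zygosity, and per-trait (twin1, twin2) values."""

    pair_id: str
    zygosity: str
    values: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.zygosity not in ZYGOSITIES:
            raise TraitValueError(
                f"pair {self.pair_id!r}: zygosity {self.zygosity!r} not in MZ/DZ"
            )
        for trait, pair in self.values.items():
            if len(pair) != 2:
                raise TraitValueError(
                    f"pair {self.pair_id!r}: trait {trait!r} needs exactly 2 values"
                )


class TwinDataset:
    """Ordered collection of twin pairs with declared trait metadata.

    Internally a wide :class:`pandas.DataFrame`; ``records`` materialises
    :class:`TwinPairRecord` objects on demand.
    """

    def __init__(self, records: Iterable[TwinPairRecord], trait_specs: Sequence[TraitSpec]):
        self.trait_specs = list(trait_specs)
        rows = []
        for rec in records:
            row = {"pair_id": rec.pair_id, "zygosity": rec.zygosity}
            for spec in self.trait_specs:
                v1, v2 = rec.values.get(spec.name, (ABSENT, ABSENT))
                row[f"{spec.name}_t1"] = spec.check_value(v1)
                row[f"{spec.name}_t2"] = spec.check_value(v2)
            rows.append(row)
        self._frame = pd.DataFrame(rows, columns=self._columns())
        self._validate()

    def _columns(self):
        cols = ["pair_id", "zygosity"]
        for spec in self.trait_specs:
            cols += [f"{spec.name}_t1", f"{spec.name}_t2"]
        return cols

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, trait_specs: Sequence[TraitSpec]) -> "TwinDataset":
        """Build a dataset from an already-wide frame (validated)."""
        ds = cls.__new__(cls)
        ds.trait_specs = list(trait_specs)
        missing = [c for c in ds._columns() if c not in frame.columns]
        if missing:
            raise DataFormatError(f"missing required column(s): {', '.join(missing)}")
        ds._frame = frame.loc[:, ds._columns()].reset_index(drop=True)
        ds._frame["pair_id"] = ds._frame["pair_id"].astype(str)
        for spec in ds.trait_specs:
            for j in (1, 2):
                col = f"{spec.name}_t{j}"
                ds._frame[col] = pd.to_numeric(ds._frame[col], errors="raise").astype(float)
                for row, v in enumerate(ds._frame[col].to_numpy()):
                    spec.check_value(v, row=row)
        ds._validate()
        return ds

    def _validate(self):
        zyg = self._frame["zygosity"]
        bad = ~zyg.isin(ZYGOSITIES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TraitValueError(
                f"row {row}: zygosity {zyg.iloc[row]!r} not in {ZYGOSITIES}"
            )
        if self._frame["pair_id"].duplicated().any():
            dup = self._frame.loc[self._frame["pair_id"].duplicated(), "pair_id"].iloc[0]
            raise DataFormatError(f"duplicate pair_id {dup!r}")

    # -- accessors -----------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The wide per-pair table (copy-on-write view; do not mutate)."""
        return self._frame

    @property
    def trait_names(self) -> list[str]:
        return [s.name for s in self.trait_specs]

    def trait_spec(self, name: str) -> TraitSpec:
        for s in self.trait_specs:
            if s.name == name:
                return s
        raise KeyError(f"unknown trait {name!r}")

    def __len__(self) -> int:
        return len(self._frame)

    def n_pairs(self, zygosity: str | None = None) -> int:
        if zygosity is None:
            return len(self._frame)
        return int((self._frame["zygosity"] == zygosity).sum())

    def pairs(self, trait: str, zygosity: str | None = None) -> np.ndarray:
        """Per-pair (twin1, twin2) values as an (n, 2) float array (NaN = absent)."""
        self.trait_spec(trait)
        df = self._frame
        if zygosity is not None:
            df = df[df["zygosity"] == zygosity]
        return df[[f"{trait}_t1", f"{trait}_t2"]].to_numpy(float)

    def individuals(self, trait: str) -> np.ndarray:
        """All twins' values for one trait, twin-1 block then twin-2 block."""
        arr = self.pairs(trait)
        return np.concatenate([arr[:, 0], arr[:, 1]])

    @property
    def records(self) -> list[TwinPairRecord]:
        out = []
        for _, row in self._frame.iterrows():
            values = {
                s.name: (row[f"{s.name}_t1"], row[f"{s.name}_t2"])
                for s in self.trait_specs
            }
            out.append(TwinPairRecord(str(row["pair_id"]), row["zygosity"], values))
        return out

    def with_trait_values(self, trait: str, values: np.ndarray) -> "TwinDataset":
        """Copy of the dataset with one trait's (n, 2) values replaced."""
        frame = self._frame.copy()
        frame[[f"{trait}_t1", f"{trait}_t2"]] = np.asarray(values, float)
        return TwinDataset.from_frame(frame, self.trait_specs)

    def equals(self, other: "TwinDataset") -> bool:
        """Field-by-field equality (absent values compare equal)."""
        if self.trait_specs != other.trait_specs:
            return False
        a, b = self._frame, other._frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        if not (a["pair_id"].tolist() == b["pair_id"].tolist()
                and a["zygosity"].tolist() == b["zygosity"].tolist()):
            return False
        for spec in self.trait_specs:
            for j in (1, 2):
                col = f"{spec.name}_t{j}"
                x, y = a[col].to_numpy(float), b[col].to_numpy(float)
                if not np.array_equal(x, y, equal_nan=True):
                    return False
        return True


# -- CSV I/O ----------------------------------------------------------


def read_pairs_csv(path, trait_specs: Sequence[TraitSpec]) -> TwinDataset:
    """Read a wide per-pair CSV into a :class:`TwinDataset`.

    Empty cells map to absent; values outside a trait's declared range
    raise :class:`TraitValueError` naming the row, trait and bounds.
    """
    frame = pd.read_csv(
        path, dtype={"pair_id": str, "zygosity": str}, float_precision="round_trip"
    )
    required = ["pair_id", "zygosity"] + [
        f"{s.name}_t{j}" for s in trait_specs for j in (1, 2)
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataFormatError(f"missing required column(s): {', '.join(missing)}")
    return TwinDataset.from_frame(frame, trait_specs)


def write_pairs_csv(dataset: TwinDataset, path) -> None:
    """Write a dataset in the ``read_pairs_csv`` schema (absent = empty cell)."""
    dataset.frame.to_csv(path, index=False, na_rep="")


# -- missingness coding ------------------------------------------------


def code_experiment_missingness(n_valid_trials, session_status, min_valid: int) -> int:
    """Code one experimental session as missing (1) or valid (0).

    A session is missing when no data was provided at all (for technical
    reasons, child-related reasons, or otherwise) or when fewer than
    ``min_valid`` trials passed the experiment's validity criteria.
    Sessions logged as lost to technical reasons are deliberately included
    and coded missing.
    """
    status = SessionStatus(session_status)
    if min_valid < 0:
        raise ValueError("min_valid must be >= 0")
    if status in (
        SessionStatus.NO_DATA_TECHNICAL,
        SessionStatus.NO_DATA_CHILD,
        SessionStatus.NO_DATA_OTHER,
    ):
        return 1
    if is_absent(n_valid_trials):
        raise DegenerateInputError(
            f"session with status {status.value!r} must carry a valid-trial count"
        )
    return 1 if float(n_valid_trials) < min_valid else 0


def read_session_log_csv(path, min_valid: Mapping[str, int]) -> TwinDataset:
    """Code a long-format session log into a binary missingness dataset.

    The log has one row per (pair, twin, experiment) with columns
    ``pair_id, zygosity, twin, experiment, status, n_valid_trials``;
    ``min_valid`` maps each experiment name to its valid-trial cut-off.
    Every experiment becomes a binary trait; with exactly three
    experiments a ``composite`` trait (missing anywhere) is added, with
    unlogged sessions counting as missing.
    """
    df = pd.read_csv(
        path,
        dtype={"pair_id": str, "zygosity": str, "experiment": str, "status": str},
    )
    required = ["pair_id", "zygosity", "twin", "experiment", "status", "n_valid_trials"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise DataFormatError(f"missing required column(s): {', '.join(missing_cols)}")
    experiments = sorted(min_valid)
    unknown = set(df["experiment"]) - set(experiments)
    if unknown:
        raise DataFormatError(f"experiment(s) without a cut-off: {sorted(unknown)}")

    codes: dict[tuple[str, int, str], int] = {}
    zyg: dict[str, str] = {}
    for _, row in df.iterrows():
        zyg.setdefault(row["pair_id"], row["zygosity"])
        codes[(row["pair_id"], int(row["twin"]), row["experiment"])] = (
            code_experiment_missingness(
                row["n_valid_trials"], row["status"], min_valid[row["experiment"]]
            )
        )

    with_composite = len(experiments) == 3
    specs = [TraitSpec(e, "binary") for e in experiments]
    if with_composite:
        specs.append(TraitSpec("composite", "binary"))
    records = []
    for pid in dict.fromkeys(df["pair_id"]):  # preserve file order
        values = {}
        for e in experiments:
            values[e] = tuple(
                float(codes[(pid, j, e)]) if (pid, j, e) in codes else ABSENT
                for j in (1, 2)
            )
        if with_composite:
            values["composite"] = tuple(
                float(make_composite([values[e][j] for e in experiments]))
                for j in (0, 1)
            )
        records.append(TwinPairRecord(pid, zyg[pid], values))
    return TwinDataset(records, specs)


def make_composite(per_experiment_codes) -> int:
    """Composite missingness: 1 iff any of exactly three experiments is missing.

    Absent per-experiment codes count as missing, since "did not provide
    valid data" covers non-participation.
    """
    codes = list(per_experiment_codes)
    if len(codes) != 3:
        raise ValueError(f"expected exactly 3 per-experiment codes, got {len(codes)}")
    coded = []
    for c in codes:
        if is_absent(c):
            coded.append(1)
        elif float(c) in (0.0, 1.0):
            coded.append(int(float(c)))
        else:
            raise TraitValueError(f"per-experiment code {c!r} not in {{0, 1}}")
    return 1 if any(coded) else 0
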