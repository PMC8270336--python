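"""Box-Behnken designs for four factors at three levels, and factor coding.

A four-factor Box-Behnken design (BBD) consists of 24 "edge" runs — every
unordered factor pair set to the four (+/-1, +/-1) sign combinations while the
remaining two factors sit at their centers — plus replicated center runs.
With five center replicates the design has 29 runs.

Coding maps natural factor settings onto the dimensionless interval
[-1, +1] via ``coded = (natural - center) / half_width`` where
``half_width = (high - low) / 2``.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateFactorError,
    ParseError,
    UnsupportedDesignError,
)

__all__ = [
    "FactorSpec",
    "DesignTable",
    "build_bbd",
    "code_point",
    "decode_point",
    "read_design",
    "write_design",
]

RESPONSE_COLUMN = "response"


@dataclass(frozen=True)
class FactorSpec:
    """A single experimental factor with its three working levels."""

    name: str
    unit: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise DegenerateFactorError(
                f"factor {self.name!r}: levels must satisfy low < center < high, "
                f"got ({self.low}, {self.center}, {self.high})"
            )

    @property
    def half_width(self) -> float:
        return (self.high - self.low) / 2.0

    def code(self, natural):
        """Natural units -> coded units."""
        return (np.asarray(natural, dtype=float) - self.center) / self.half_width

    def decode(self, coded):
        """Coded units -> natural units (exact inverse of :meth:`code`)."""
        return np.asarray(coded, dtype=float) * self.half_width + self.center

    @classmethod
    def from_range(cls, name: str, low: float, high: float, unit: str = "") -> "FactorSpec":
        return cls(name=name, unit=unit, low=low, center=(low + high) / 2.0, high=high)


@dataclass
class DesignTable:
    """A designed experiment: factor metadata, coded settings and responses.

    ``coded`` is an (n_runs, n_factors) array; ``response`` is an (n_runs,)
    array with NaN marking runs that have not been measured.  Natural settings
    are always derived from the coded matrix and factor specs rather than
    stored redundantly.
    """

    factors: tuple[FactorSpec, ...]
    coded: np.ndarray
    response: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        if self.response is None:
            self.response = np.full(self.coded.shape[0], np.nan)
        self.response = np.asarray(self.response, dtype=float)
        if self.coded.shape != (len(self.response), len(self.factors)):
            raise ParseError(
                f"shape mismatch: coded {self.coded.shape}, "
                f"{len(self.response)} responses, {len(self.factors)} factors"
            )

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def natural(self) -> np.ndarray:
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_width for f in self.factors])
        return self.coded * halves + centers

    @property
    def center_mask(self) -> np.ndarray:
        """Boolean mask of runs at the coded origin."""
        return np.all(np.abs(self.coded) < 1e-12, axis=1)

    @property
    def has_response(self) -> np.ndarray:
        return ~np.isnan(self.response)

    def with_response(self, response) -> "DesignTable":
        return replace(self, response=np.asarray(response, dtype=float))

    def to_frame(self):
        import pandas as pd

        data = {f.name: self.natural[:, j] for j, f in enumerate(self.factors)}
        data[RESPONSE_COLUMN] = self.response
        return pd.DataFrame(data)

    def validate_bbd(self) -> None:
        """Raise unless this is a 4-factor BBD (24 edge runs + centers)."""
        if len(self.factors) != 4:
            raise UnsupportedDesignError(
                f"expected 4 factors, got {len(self.factors)}"
            )
        nonzero = np.sum(np.abs(self.coded) > 1e-12, axis=1)
        centers = int(np.sum(nonzero == 0))
        edges = int(np.sum(nonzero == 2))
        if centers < 1 or edges != 24 or centers + edges != self.n_runs:
            raise UnsupportedDesignError(
                f"not a 4-factor BBD: {edges} edge runs, {centers} center runs "
                f"of {self.n_runs} total"
            )
        if not np.allclose(self.coded.sum(axis=0), 0.0):
            raise UnsupportedDesignError("coded columns do not sum to zero")


def build_bbd(factors, n_center: int = 5) -> DesignTable:
    """Construct a four-factor, three-level Box-Behnken design.

    Edge runs enumerate unordered factor pairs in lexicographic order, each
    pair taking the sign combinations (-1,-1), (-1,+1), (+1,-1), (+1,+1);
    the ``n_center`` center replicates come last.  Run order is deterministic:
    the artifact never schedules physical experiments, so randomization would
    only hurt reproducibility.
    """
    factors = tuple(factors)
    if len(factors) != 4:
        raise UnsupportedDesignError(
            f"Box-Behnken construction implemented for exactly 4 factors, "
            f"got {len(factors)}"
        )
    if n_center < 1:
        raise UnsupportedDesignError("n_center must be >= 1")
    rows = []
    for i, j in itertools.combinations(range(4), 2):
        for si, sj in itertools.product((-1.0, 1.0), repeat=2):
            row = np.zeros(4)
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend(np.zeros(4) for _ in range(n_center))
    return DesignTable(factors=factors, coded=np.array(rows))


def code_point(natural, factors) -> np.ndarray:
    """Map one natural-unit point to coded units."""
    natural = np.asarray(natural, dtype=float)
    if natural.shape[-1] != len(factors):
        raise ParseError(
            f"point has {natural.shape[-1]} coordinates for {len(factors)} factors"
        )
    return np.stack(
        [f.code(natural[..., j]) for j, f in enumerate(factors)], axis=-1
    )


def decode_point(coded, factors) -> np.ndarray:
    """Inverse of :func:`code_point`."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(factors):
        raise ParseError(
            f"point has {coded.shape[-1]} coordinates for {len(factors)} factors"
        )
    return np.stack(
        [f.decode(coded[..., j]) for j, f in enumerate(factors)], axis=-1
    )


def _infer_factor(name: str, values: np.ndarray) -> FactorSpec:
    levels = np.unique(values)
    lo, hi = float(levels[0]), float(levels[-1])
    if lo == hi:
        raise DegenerateFactorError(f"factor {name!r} is constant in the file")
    if len(levels) == 3:
        return FactorSpec(name=name, unit="", low=lo, center=float(levels[1]), high=hi)
    return FactorSpec.from_range(name, lo, hi)


def read_design(path, factors=None) -> DesignTable:
    """Read a design table from comma-delimited UTF-8 text.

    Header row holds the factor names followed by ``response``; the response
    cell may be empty for unmeasured runs.  When ``factors`` is omitted the
    specs are inferred from the distinct levels found in each column.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if RESPONSE_COLUMN not in header:
            raise ParseError(f"{path}: missing {RESPONSE_COLUMN!r} column")
        resp_idx = header.index(RESPONSE_COLUMN)
        names = [h for k, h in enumerate(header) if k != resp_idx]
        naturals, responses = [], []
        for i, rec in enumerate(reader):
            if not rec or all(not c.strip() for c in rec):
                continue
            if len(rec) != len(header):
                raise ParseError(
                    f"{path}: expected {len(header)} fields, got {len(rec)}", row=i
                )
            try:
                naturals.append(
                    [float(c) for k, c in enumerate(rec) if k != resp_idx]
                )
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric factor level: {exc}", row=i)
            cell = rec[resp_idx].strip()
            if cell in ("", "NA", "nan"):
                responses.append(np.nan)
            else:
                try:
                    responses.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric response {cell!r}", row=i
                    ) from None
    naturals = np.asarray(naturals, dtype=float)
    if factors is None:
        factors = tuple(
            _infer_factor(name, naturals[:, j]) for j, name in enumerate(names)
        )
    else:
        factors = tuple(factors)
        if [f.name for f in factors] != names:
            raise ParseError(
                f"{path}: header {names} does not match factor specs "
                f"{[f.name for f in factors]}"
            )
    coded = code_point(naturals, factors)
    return DesignTable(factors=factors, coded=coded, response=np.asarray(responses))


def write_design(table: DesignTable, path) -> None:
    """Write a design as comma-delimited text; byte-stable for a given table."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(table.factor_names + [RESPONSE_COLUMN])
        for nat, resp in zip(table.natural, table.response):
            writer.writerow(
                [format(v, ".10g") for v in nat]
                + ["" if np.isnan(resp) else format(resp, ".10g")]
            )
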