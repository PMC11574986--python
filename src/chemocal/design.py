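"""Multilevel calibration design for multicomponent calibration.

A five-level, multi-factor cyclic design: every analyte concentration
takes five equally spaced coded levels (-2 ... +2) arranged so that each
level occurs equally often per factor and the first mixture sits at the
center of the design space. The three-factor, 25-run realization with
center levels (11, 15, 12) ug/mL and step sizes (4, 5, 4) ug/mL is the
calibration set used throughout this package; a fixed 10-mixture set
(including two binary mixtures that emulate commercial two-drug tablets)
serves as the independent validation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "ANALYTES",
    "CENTERS",
    "STEPS",
    "CodedDesign",
    "ConcentrationTable",
    "coded_design",
    "realize_design",
    "calibration_table",
    "validation_fixture",
]

#: Analyte labels, in design-column order.
ANALYTES = ("MON", "RUP", "DES")

#: Center concentration levels, ug/mL, one per analyte.
CENTERS = (11.0, 15.0, 12.0)

#: Step between adjacent coded levels, ug/mL, one per analyte.
STEPS = (4.0, 5.0, 4.0)

# Base cyclic sequence of coded levels for runs 2..25 of factor 1.
# Factor j > 1 uses the same sequence rotated left by j-1 positions;
# run 1 is the all-center point. Each level appears 5 times per column.
_BASE_SEQUENCE = (
    0, -2, -2, 2, -1, 2, 0, -1, -1, 1, 2, 1,
    0, 2, 2, -2, 1, -2, 0, 1, 1, -1, -2, -1,
)

_LEVELS = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class CodedDesign:
    """A runs x factors matrix of coded levels in {-2,...,+2}."""

    codes: np.ndarray

    @property
    def runs(self) -> int:
        return self.codes.shape[0]

    @property
    def factors(self) -> int:
        return self.codes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"factor_{j + 1}" for j in range(self.factors)]
        df = pd.DataFrame(self.codes, columns=cols)
        df.insert(0, "mixture_id", np.arange(1, self.runs + 1))
        return df


@dataclass(frozen=True)
class ConcentrationTable:
    """Per-mixture analyte concentrations in ug/mL."""

    mixture_ids: np.ndarray
    concentrations: np.ndarray  # runs x analytes
    analyte_names: tuple[str, ...] = ANALYTES
    centers: np.ndarray | None = None
    steps: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.mixture_ids, dtype=int)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "mixture_ids", ids)
        object.__setattr__(self, "concentrations", conc)
        if conc.ndim != 2 or conc.shape[0] != ids.shape[0]:
            raise InvalidParameterError(
                "concentrations must be runs x analytes, row-matched to mixture_ids"
            )
        if conc.shape[1] != len(self.analyte_names):
            raise InvalidParameterError("one analyte name per concentration column")
        if np.any(conc < 0):
            raise InvalidParameterError("concentrations must be non-negative")

    @property
    def n_mixtures(self) -> int:
        return self.concentrations.shape[0]

    def column(self, analyte: str) -> np.ndarray:
        """Concentration vector for a single analyte."""
        return self.concentrations[:, self.analyte_names.index(analyte)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.concentrations,
            columns=[f"{name}_ugml" for name in self.analyte_names],
        )
        df.insert(0, "mixture_id", self.mixture_ids)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def coded_design(factors: int = 3) -> CodedDesign:
    """Build the 25-run five-level cyclic design for ``factors`` factors.

    Run 1 is all zeros (the center point); runs 2-25 of factor j follow
    the base sequence rotated left by j-1 positions, which keeps every
    factor column balanced (each of the 5 levels exactly 5 times).
    """
    if factors < 1:
        raise InvalidParameterError("factors must be >= 1")
    base = np.array(_BASE_SEQUENCE, dtype=int)
    n = base.size  # 24 cyclic runs + center point
    codes = np.zeros((n + 1, factors), dtype=int)
    for j in range(factors):
        codes[1:, j] = np.roll(base, -j)
    return CodedDesign(codes=codes)


def realize_design(
    design: CodedDesign,
    centers,
    steps,
    first_id: int = 1,
) -> ConcentrationTable:
    """Map coded levels to concentrations: c[i,j] = center[j] + code[i,j]*step[j]."""
    centers = np.asarray(centers, dtype=float)
    steps = np.asarray(steps, dtype=float)
    if centers.shape != (design.factors,) or steps.shape != (design.factors,):
        raise InvalidParameterError("centers and steps must have one entry per factor")
    if np.any(centers <= 0) or np.any(steps < 0):
        raise InvalidParameterError("centers must be positive and steps non-negative")
    conc = centers[None, :] + design.codes * steps[None, :]
    if np.any(conc < 0):
        raise InvalidParameterError(
            "design realization produced a negative concentration; "
            "require centers - 2*steps >= 0"
        )
    ids = np.arange(first_id, first_id + design.runs)
    names = ANALYTES[: design.factors] if design.factors <= 3 else tuple(
        f"analyte_{j + 1}" for j in range(design.factors)
    )
    return ConcentrationTable(
        mixture_ids=ids,
        concentrations=conc,
        analyte_names=names,
        centers=centers,
        steps=steps,
    )


def calibration_table() -> ConcentrationTable:
    """The standard 25-mixture calibration set (mixtures 1-25)."""
    return realize_design(coded_design(3), CENTERS, STEPS)


# Fixed validation mixtures 26-35 (ug/mL). Mixtures 34 and 35 are binary
# (one analyte absent), emulating the two-drug commercial tablets.
_VALIDATION_CONC = (
    (10.0, 10.0, 10.0),
    (11.0, 15.0, 12.0),
    (5.0, 25.0, 5.0),
    (18.0, 5.0, 18.0),
    (3.0, 20.0, 18.0),
    (19.0, 6.0, 6.0),
    (18.0, 22.0, 4.0),
    (6.0, 6.0, 20.0),
    (15.0, 15.0, 0.0),
    (16.0, 0.0, 8.0),
)


def validation_fixture() -> ConcentrationTable:
    """The fixed 10-mixture validation set (mixtures 26-35)."""
    return ConcentrationTable(
        mixture_ids=np.arange(26, 36),
        concentrations=np.array(_VALIDATION_CONC),
        analyte_names=ANALYTES,
    )
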