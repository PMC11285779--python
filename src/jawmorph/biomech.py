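"""Lever-theory biomechanics and the 11-character morphofunctional vector.

The mandible is treated as a third-class lever with the fulcrum at the
articular glenoid, located RPL (retroarticular process length) from the
posterior end of the ramus. All lever arms are straight-line distances along
the jaw's long axis:

* out-levers: anterior tip (``ML - RPL``), posterior end of the tooth row
  (``(ML - RPL) - TRL``; the tooth row is assumed to start at the tip), and
  the largest tooth position (``(ML - RPL) - DLT``) when DLT is measured;
* closing in-lever: the explicit ILc override when present, otherwise the
  adductor insertion length maL;
* opening in-lever: RPL itself.

Closing mechanical advantage (MA) = closing in-lever / out-lever, so aMA
(anterior bite point) <= ltMA (largest tooth) <= pMA (posterior tooth row).
Opening MA = RPL / (ML - RPL); LOW oMA trades force for jaw-opening speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AssemblageTable, RawJawMeasurements


class GeometryError(ValueError):
    """Lever geometry is degenerate (a non-positive lever arm)."""


#: Ordered labels of the 11 ordination characters.
CHARACTER_NAMES: tuple[str, ...] = (
    "ASD/ML", "MSL/ML", "MSD/ML", "TRL/ML", "CPD/ML", "RPL/ML",
    "TI", "maL/ML", "aMA", "pMA", "oMA",
)
#: Auxiliary metrics carried alongside (never entered into the ordination).
AUXILIARY_NAMES: tuple[str, ...] = ("ltMA", "ML")


@dataclass(frozen=True)
class LeverArms:
    """Lever arms (mm) of one jaw; ``out_largest_tooth`` is None without DLT."""

    fulcrum_offset: float
    out_anterior: float
    out_posterior_toothrow: float
    in_closing: float
    in_opening: float
    out_largest_tooth: float | None = None


def derive_lever_arms(m: RawJawMeasurements, specimen_id: str = "?") -> LeverArms:
    out_anterior = m.ML - m.RPL
    out_posterior = out_anterior - m.TRL
    if out_posterior <= 0:
        raise GeometryError(
            f"specimen {specimen_id!r}: tooth row (TRL={m.TRL}) reaches or passes "
            f"the fulcrum (ML-RPL={out_anterior}); posterior out-lever <= 0")
    out_lt = None
    if m.DLT is not None:
        out_lt = out_anterior - m.DLT
        if out_lt <= 0:
            raise GeometryError(
                f"specimen {specimen_id!r}: largest tooth position DLT={m.DLT} "
                f"at or behind the fulcrum")
    in_closing = m.ILc if m.ILc is not None else m.maL
    return LeverArms(
        fulcrum_offset=m.RPL,
        out_anterior=out_anterior,
        out_posterior_toothrow=out_posterior,
        out_largest_tooth=out_lt,
        in_closing=in_closing,
        in_opening=m.RPL,
    )


def compute_characters(m: RawJawMeasurements, specimen_id: str = "?") -> dict[str, float]:
    """The 11 ordination characters plus auxiliary ltMA and ML.

    All are dimensionless ratios except ML (mm), which is kept separately as
    the size metric. ltMA is NaN when DLT was not measured.
    """
    m.validate(specimen_id)
    arms = derive_lever_arms(m, specimen_id)
    chars = {
        "ASD/ML": m.ASD / m.ML,
        "MSL/ML": m.MSL / m.ML,
        "MSD/ML": m.MSD / m.ML,
        "TRL/ML": m.TRL / m.ML,
        "CPD/ML": m.CPD / m.ML,
        "RPL/ML": m.RPL / m.ML,
        "TI": m.LCH / m.ML,
        "maL/ML": m.maL / m.ML,
        "aMA": arms.in_closing / arms.out_anterior,
        "pMA": arms.in_closing / arms.out_posterior_toothrow,
        "oMA": arms.in_opening / arms.out_anterior,
        "ltMA": (arms.in_closing / arms.out_largest_tooth
                 if arms.out_largest_tooth is not None else float("nan")),
        "ML": m.ML,
    }
    return chars


def character_table(table: AssemblageTable) -> pd.DataFrame:
    """Specimens x (11 characters + ltMA + ML) frame, indexed by specimen_id."""
    rows = {r.specimen_id: compute_characters(r.measurements, r.specimen_id)
            for r in table.records}
    cols = list(CHARACTER_NAMES) + list(AUXILIARY_NAMES)
    return pd.DataFrame.from_dict(rows, orient="index")[cols]


# ---------------------------------------------------------------------------
# Z-correction
# ---------------------------------------------------------------------------

class StandardizationError(ValueError):
    """A character column is constant and cannot be z-corrected."""


@dataclass
class StandardizedMatrix:
    """A z-corrected character matrix with the recorded inverse transform.

    Each column of ``values`` has sample mean 0 and sample (ddof=1) standard
    deviation 1.
    """

    values: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def inverse(self) -> pd.DataFrame:
        return self.values * self.column_sds + self.column_means


def zscore_matrix(raw: pd.DataFrame) -> StandardizedMatrix:
    """Z-correct every column (sample mean 0, sample sd 1, ddof=1)."""
    if len(raw) < 2:
        raise StandardizationError("need >= 2 specimens to standardize")
    if raw.isna().any().any():
        bad = sorted(raw.columns[raw.isna().any()])
        raise StandardizationError(f"missing values in columns {bad}")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    scale = raw.abs().max(axis=0).replace(0.0, 1.0)
    constant = sds <= 1e-12 * scale
    if constant.any():
        raise StandardizationError(
            f"constant character column(s): {sorted(raw.columns[constant])}")
    return StandardizedMatrix(values=(raw - means) / sds,
                              column_means=means, column_sds=sds)


def standardized_characters(table: AssemblageTable) -> StandardizedMatrix:
    """Z-corrected 11-character matrix for the ordination (ltMA, ML excluded)."""
    chars = character_table(table)[list(CHARACTER_NAMES)]
    return zscore_matrix(chars)
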