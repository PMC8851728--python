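"""Heart-rate correction formulas for the QT interval.

Six published corrections are provided, in two families:

* power laws, ``QTc = QT / RR**e`` — Bazett (e=0.50), Fridericia (e=0.333),
  Dmitrienko (e=0.413);
* linear laws — Framingham ``QTc = QT + 0.154*(1 - RR)``, Hodges
  ``QTc = QT + 0.00175*(HR - 60)``, Rautaharju
  ``QTc = QT - 0.185*(RR - 1) + k`` with k = 6 ms for men, 0 for women.

Internal units are seconds for QT and RR and bpm for HR.  The published
linear coefficients (0.154 s/s, 0.185 s/s, 0.00175 s/bpm) are only
dimensionally consistent with RR in seconds, so the seconds convention is
used throughout and values are converted to milliseconds only for
reporting.  Every formula is neutral at RR = 1 s (HR = 60 bpm): the
corrected value equals the raw QT there, except for the Rautaharju male
offset of exactly 6 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CorrectionFormula",
    "BAZETT",
    "FRIDERICIA",
    "DMITRIENKO",
    "FRAMINGHAM",
    "HODGES",
    "RAUTAHARJU",
    "SIX_FORMULAS",
    "get_formula",
    "correct_qt",
    "correct_qt_batch",
]

_FAMILIES = ("power", "linear_rr", "linear_hr")


@dataclass(frozen=True)
class CorrectionFormula:
    """A named QT correction law.

    Exactly one family-specific parameter must be set:

    * ``power``: ``exponent`` e, giving QTc = QT / RR**e;
    * ``linear_rr``: ``rr_coeff`` b (s/s), giving QTc = QT + b*(1 - RR);
    * ``linear_hr``: ``hr_coeff`` c (s/bpm), giving QTc = QT + c*(HR - 60),
      with HR derived from RR as 60/RR.

    ``sex_offset_male`` (seconds) is added for male subjects only; it is
    non-zero only for Rautaharju (0.006 s).
    """

    name: str
    family: str
    exponent: float | None = None
    rr_coeff: float | None = None
    hr_coeff: float | None = None
    sex_offset_male: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        params = {
            "power": self.exponent,
            "linear_rr": self.rr_coeff,
            "linear_hr": self.hr_coeff,
        }
        set_params = [fam for fam, val in params.items() if val is not None]
        if set_params != [self.family]:
            raise ValueError(
                f"formula {self.name!r}: exactly the {self.family!r} parameter must be set, "
                f"got parameters for {set_params or 'none'}"
            )
        if self.family == "power" and not (0.0 < self.exponent <= 1.0):
            raise ValueError(f"power exponent must lie in (0, 1], got {self.exponent}")


BAZETT = CorrectionFormula("bazett", "power", exponent=0.50)
FRIDERICIA = CorrectionFormula("fridericia", "power", exponent=0.333)
DMITRIENKO = CorrectionFormula("dmitrienko", "power", exponent=0.413)
FRAMINGHAM = CorrectionFormula("framingham", "linear_rr", rr_coeff=0.154)
HODGES = CorrectionFormula("hodges", "linear_hr", hr_coeff=0.00175)
# QTc = QT - 0.185*(RR - 1) + k  ==  QT + 0.185*(1 - RR) + k
RAUTAHARJU = CorrectionFormula("rautaharju", "linear_rr", rr_coeff=0.185, sex_offset_male=0.006)

SIX_FORMULAS: tuple[CorrectionFormula, ...] = (
    BAZETT,
    FRIDERICIA,
    DMITRIENKO,
    FRAMINGHAM,
    HODGES,
    RAUTAHARJU,
)

_BY_NAME = {f.name: f for f in SIX_FORMULAS}


def get_formula(name: str) -> CorrectionFormula:
    """Look up one of the six published formulas by name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown formula {name!r}; known: {sorted(_BY_NAME)}") from None


def correct_qt(qt, rr, male, formula: CorrectionFormula):
    """Apply ``formula`` to QT/RR pairs.

    Parameters
    ----------
    qt, rr : float or array-like
        QT and RR intervals in seconds; must be strictly positive.
    male : int, bool or array-like
        1/True for male subjects (engages the Rautaharju offset).
    formula : CorrectionFormula

    Returns
    -------
    float or ndarray
        Corrected QT in seconds, scalar if the inputs were scalars.
    """
    qt_arr = np.asarray(qt, dtype=float)
    rr_arr = np.asarray(rr, dtype=float)
    male_arr = np.asarray(male, dtype=float)
    if np.any(~np.isfinite(qt_arr)) or np.any(~np.isfinite(rr_arr)):
        raise ValueError("qt and rr must be finite")
    if np.any(qt_arr <= 0) or np.any(rr_arr <= 0):
        raise ValueError("qt and rr must be strictly positive (seconds)")

    if formula.family == "power":
        qtc = qt_arr / rr_arr**formula.exponent
    elif formula.family == "linear_rr":
        qtc = qt_arr + formula.rr_coeff * (1.0 - rr_arr)
    else:  # linear_hr; HR derived from RR so one (qt, rr) pair determines the value
        hr = 60.0 / rr_arr
        qtc = qt_arr + formula.hr_coeff * (hr - 60.0)
    qtc = qtc + formula.sex_offset_male * male_arr
    if qtc.ndim == 0:
        return float(qtc)
    return qtc


def correct_qt_batch(
    cohort: pd.DataFrame,
    formulas: list[CorrectionFormula] | tuple[CorrectionFormula, ...] = SIX_FORMULAS,
) -> pd.DataFrame:
    """Add one corrected-QT column per formula, in milliseconds.

    Columns are named ``qtc_<name>`` and reported in ms to match the
    conventional presentation of QTc tables; the input ``qt``/``rr``
    columns stay in seconds.  Rows with non-finite or non-positive
    ``qt``/``rr`` are rejected with their subject ids.
    """
    required = {"qt", "rr", "male"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing required columns: {sorted(missing)}")
    out = cohort.copy()
    if len(out):
        bad = ~(
            np.isfinite(out["qt"].to_numpy(dtype=float))
            & np.isfinite(out["rr"].to_numpy(dtype=float))
            & (out["qt"].to_numpy(dtype=float) > 0)
            & (out["rr"].to_numpy(dtype=float) > 0)
        )
        if bad.any():
            ids = (
                out.loc[bad, "subject_id"].tolist()
                if "subject_id" in out.columns
                else out.index[bad].tolist()
            )
            raise ValueError(f"non-finite or non-positive qt/rr for subjects: {ids[:10]}")
    for formula in formulas:
        col = f"qtc_{formula.name}"
        if len(out):
            out[col] = 1000.0 * correct_qt(
                out["qt"].to_numpy(dtype=float),
                out["rr"].to_numpy(dtype=float),
                out["male"].to_numpy(dtype=float),
                formula,
            )
        else:
            out[col] = pd.Series(dtype=float)
    return out
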