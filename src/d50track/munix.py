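"""MUNIX / CMAP / MUSIX measurement processing.

MUNIX (motor unit number index) estimates the number of functioning motor
units in a muscle; CMAP is the supramaximal compound muscle action potential
amplitude in mV; MUSIX (motor unit size index, in µV) is the quotient of
CMAP in µV and MUNIX and rises with compensatory reinnervation.

Measurements failing the guideline inclusion floor (CMAP >= 0.5 mV), with a
MUNIX below the lower limit of 2, or with a CMAP but no obtainable MUNIX,
are replaced by the fixed small-value triple CMAP = 0.5 mV, MUNIX = 2,
MUSIX = 0.5 * 1000 / 2 = 250 µV, so that advanced-stage muscles stay in the
analysis instead of biasing medians upward by drop-out.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, SchemaError

__all__ = [
    "CMAP_FLOOR_MV",
    "MUNIX_FLOOR",
    "IMPUTED_TRIPLE",
    "Muscle",
    "Side",
    "MunixMeasurement",
    "compute_musix",
    "apply_guideline_floor",
    "select_analysis_measurement",
    "process_measurements",
    "select_first_measurements",
    "dropout_rate",
]

#: Guideline inclusion floor for CMAP amplitude (mV).
CMAP_FLOOR_MV = 0.5
#: Lower analyzable limit of the motor unit number index.
MUNIX_FLOOR = 2.0
#: (cmap_mv, munix, musix_uv) assigned to sub-floor measurements.
IMPUTED_TRIPLE = (0.5, 2.0, 250.0)


class Muscle(enum.Enum):
    APB = "APB"  # abductor pollicis brevis (thenar)
    ADM = "ADM"  # abductor digiti minimi (hypothenar)
    TA = "TA"    # tibialis anterior

    def __str__(self):  # pragma: no cover - cosmetic
        return self.value


class Side(enum.Enum):
    LEFT = "left"
    RIGHT = "right"


def _coerce_muscle(muscle):
    if isinstance(muscle, Muscle):
        return muscle
    try:
        return Muscle[str(muscle).upper()]
    except KeyError:
        raise SchemaError(f"unknown muscle label: {muscle!r}") from None


def _coerce_side(side):
    if isinstance(side, Side):
        return side
    try:
        return Side[str(side).upper()]
    except KeyError:
        raise SchemaError(f"unknown side label: {side!r}") from None


@dataclass(frozen=True)
class MunixMeasurement:
    """One muscle's CMAP / MUNIX / MUSIX triple at one visit."""

    patient_id: object
    t: float                 # months since symptom onset
    muscle: Muscle
    side: Side
    cmap_mv: float
    munix: float | None = None
    musix_uv: float | None = None
    imputed: bool = False

    def __post_init__(self):
        object.__setattr__(self, "muscle", _coerce_muscle(self.muscle))
        object.__setattr__(self, "side", _coerce_side(self.side))


def compute_musix(cmap_mv, munix):
    """MUSIX in µV: CMAP (converted mV -> µV) divided by MUNIX."""
    if not (np.isfinite(cmap_mv) and cmap_mv > 0):
        raise InvalidArgumentError(
            f"cmap must be positive (got {cmap_mv}); use the imputation path"
        )
    if not (np.isfinite(munix) and munix > 0):
        raise InvalidArgumentError(
            f"munix must be positive (got {munix}); use the imputation path"
        )
    return cmap_mv * 1000.0 / munix


def _passes_floor(cmap_mv, munix) -> bool:
    cmap_ok = cmap_mv is not None and np.isfinite(cmap_mv) and cmap_mv >= CMAP_FLOOR_MV
    munix_ok = munix is not None and np.isfinite(munix) and munix >= MUNIX_FLOOR
    return bool(cmap_ok and munix_ok)


def apply_guideline_floor(measurement: MunixMeasurement) -> MunixMeasurement:
    """Enforce the guideline floor, imputing the fixed small-value triple.

    A record passes when CMAP >= 0.5 mV and a MUNIX >= 2 is present; it is
    returned unchanged (with MUSIX filled in) and ``imputed=False``.  Any
    other record — CMAP below floor or absent, MUNIX absent or below its
    lower limit of 2 — receives the full triple (0.5 mV, 2, 250 µV) and
    ``imputed=True``.  Idempotent.
    """
    m = measurement
    if m.imputed:
        return m
    if _passes_floor(m.cmap_mv, m.munix):
        return replace(m, musix_uv=compute_musix(m.cmap_mv, m.munix),
                       imputed=False)
    return replace(m, cmap_mv=IMPUTED_TRIPLE[0], munix=IMPUTED_TRIPLE[1],
                   musix_uv=IMPUTED_TRIPLE[2], imputed=True)


def select_analysis_measurement(measurements, less_affected_side=None):
    """Pick the single analysis record per muscle for one patient.

    Only the less affected side is considered and, per muscle, the first
    (earliest) measurement in the disease course.  When no explicit side
    designation is available the side with the higher CMAP at the first
    assessment serves as proxy for "less affected".

    Parameters
    ----------
    measurements : iterable of MunixMeasurement
        All records of one patient (any muscles, sides, visits).
    less_affected_side : Side or mapping {Muscle: Side}, optional
        Clinical designation; a single Side applies to every muscle.

    Returns
    -------
    dict mapping Muscle to the chosen MunixMeasurement (muscles with no
    record are simply absent).
    """
    records = list(measurements)
    chosen: dict[Muscle, MunixMeasurement] = {}
    for muscle in Muscle:
        recs = [m for m in records if m.muscle is muscle]
        if not recs:
            continue
        if less_affected_side is not None:
            side = (less_affected_side.get(muscle)
                    if isinstance(less_affected_side, dict)
                    else less_affected_side)
        else:
            side = None
        if side is not None:
            on_side = [m for m in recs if m.side is _coerce_side(side)]
            if on_side:
                recs = on_side
        else:
            first_t = min(m.t for m in recs)
            at_first = [m for m in recs if m.t == first_t]

            def _cmap(m):
                return m.cmap_mv if m.cmap_mv is not None and math.isfinite(m.cmap_mv) else -1.0

            best = max(at_first, key=_cmap)
            recs = [m for m in recs if m.side is best.side]
        chosen[muscle] = min(recs, key=lambda m: m.t)
    return chosen


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

def process_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the guideline floor to a long-format MUNIX table.

    Input columns: ``patient_id, months_since_onset, muscle, side, cmap_mv,
    munix`` (munix may be empty).  Returns a copy with ``musix_uv`` and
    ``imputed`` columns added; muscle labels are validated.
    """
    bad = set(df["muscle"].astype(str).str.upper()) - {m.name for m in Muscle}
    if bad:
        raise SchemaError(f"unknown muscle label(s): {sorted(bad)}")
    out = df.copy()
    out["muscle"] = out["muscle"].astype(str).str.upper()
    cmap = pd.to_numeric(out["cmap_mv"], errors="coerce")
    munix = pd.to_numeric(out["munix"], errors="coerce")
    passes = (cmap >= CMAP_FLOOR_MV) & (munix >= MUNIX_FLOOR)
    out["imputed"] = ~passes
    out["cmap_mv"] = np.where(passes, cmap, IMPUTED_TRIPLE[0])
    out["munix"] = np.where(passes, munix, IMPUTED_TRIPLE[1])
    out["musix_uv"] = np.where(passes, cmap * 1000.0 / munix, IMPUTED_TRIPLE[2])
    return out


def select_first_measurements(df: pd.DataFrame,
                              side_designation: pd.DataFrame | None = None
                              ) -> pd.DataFrame:
    """Table analogue of :func:`select_analysis_measurement`.

    Keeps, per patient and muscle, the earliest record on the less affected
    side.  ``side_designation`` (optional) has columns ``patient_id,
    muscle, less_affected_side``; otherwise the higher-CMAP side at the
    first visit is used.  Adds an ``analysis_flag`` column to the full
    processed table marking the selected rows.
    """
    df = df.reset_index(drop=True)
    key = ["patient_id", "muscle"]
    cmap_num = pd.to_numeric(df["cmap_mv"], errors="coerce")
    side_low = df["side"].astype(str).str.lower()

    # proxy designation: side with the higher CMAP at the earliest visit
    order = df.assign(_cmap=cmap_num, _side=side_low).sort_values(
        key + ["months_since_onset", "_cmap"],
        ascending=[True, True, True, False], kind="stable")
    proxy = order.drop_duplicates(key).set_index(key)["_side"]

    chosen = proxy.copy()
    if side_designation is not None:
        desig = (side_designation
                 .assign(muscle=side_designation["muscle"].astype(str).str.upper(),
                         _side=side_designation["less_affected_side"]
                         .astype(str).str.lower())
                 .set_index(key)["_side"])
        # an explicit designation wins where records on that side exist
        present = set(zip(df["patient_id"], df["muscle"], side_low))
        for k, s in desig.items():
            if k in chosen.index and (k[0], k[1], s) in present:
                chosen.loc[k] = s

    target = pd.MultiIndex.from_frame(df[key]).map(chosen)
    on_side = df[side_low.to_numpy() == target.to_numpy()]
    keep_idx = (on_side.sort_values(key + ["months_since_onset"], kind="stable")
                .drop_duplicates(key).index)

    out = df.copy()
    out["analysis_flag"] = False
    out.loc[keep_idx, "analysis_flag"] = True
    return out


def dropout_rate(df: pd.DataFrame, stratum_col: str = "stratum") -> pd.DataFrame:
    """Fraction of floor-imputed ("set") values per stratum and muscle.

    Returns a frame with one row per (stratum, muscle): ``n_imputed``,
    ``n_total`` and ``fraction``.  Empty strata simply produce no row.
    """
    if "imputed" not in df.columns:
        raise InvalidArgumentError("measurements must carry an 'imputed' flag")
    grouped = df.groupby([stratum_col, "muscle"], sort=True, observed=True)["imputed"]
    out = grouped.agg(n_imputed="sum", n_total="count").reset_index()
    out["n_imputed"] = out["n_imputed"].astype(int)
    out["fraction"] = out["n_imputed"] / out["n_total"]
    return out
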