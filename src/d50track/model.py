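"""Sigmoidal D50 disease progression model for ALSFRS-R trajectories.

The model describes a patient's functional decline as a falling sigmoid
anchored at the revised ALS Functional Rating Scale ceiling of 48 points::

    F(t) = 48 / (1 + exp((t - D50) / dx))

where ``t`` is time in months since symptom onset, ``D50`` is the time at
which half of baseline functionality is lost (an inverse measure of disease
*aggressiveness*) and ``dx`` is the decline scale in months.  Rescaling
disease time by ``t / (2 * D50)`` yields the relative D50 (rD50), an
open-ended measure of disease *accumulation* on which 0 is onset and 0.5 the
half-functionality time point; rD50 partitions the course into Phase I
(< 0.25), Phase II (0.25-0.5) and Phase III/IV (>= 0.5).

The public surface follows the statsmodels convention: build a
:class:`D50Model` from a patient's observations, call :meth:`D50Model.fit`,
and read estimates, uncertainties and diagnostics off the returned
:class:`D50Results`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .exceptions import (
    IllPosedFitError,
    InsufficientDataError,
    InvalidArgumentError,
    PreOnsetLossWarning,
)

__all__ = [
    "FULL_SCORE",
    "PHASE_BOUNDS",
    "TIER_BOUNDS",
    "Phase",
    "Aggressiveness",
    "D50Model",
    "D50Results",
    "predict_alsfrsr",
    "fit_d50",
    "compute_rd50",
    "classify_phase",
    "classify_aggressiveness",
    "progression_rate",
]

#: Ceiling of the revised ALS Functional Rating Scale (full function).
FULL_SCORE = 48.0

#: rD50 cut points separating Phase I / II / III-IV (half-open intervals).
PHASE_BOUNDS = (0.25, 0.5)

#: D50 cut points (months) separating high / intermediate / low aggressiveness.
TIER_BOUNDS = (20.0, 40.0)


class Phase(enum.Enum):
    """rD50 phase of disease accumulation."""

    I = "I"
    II = "II"
    III_IV = "III/IV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Aggressiveness(enum.Enum):
    """D50 tier of disease aggressiveness (low D50 = aggressive disease)."""

    HIGH = "high"
    INTERMEDIATE = "intermediate"
    LOW = "low"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def predict_alsfrsr(t, d50, dx, full_score=FULL_SCORE):
    """Predicted ALSFRS-R total at time ``t`` months after symptom onset.

    Evaluates ``full_score / (1 + exp((t - d50) / dx))``; strictly
    decreasing in ``t`` and bounded in ``(0, full_score)``.  Negative ``t``
    is permitted and returns the pre-onset near-ceiling region.

    Parameters
    ----------
    t : float or array_like
        Months since symptom onset (may be negative).
    d50 : float
        Months to 50% functionality loss; must be positive.
    dx : float
        Decline scale in months; must be positive.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidArgumentError("t must be finite")
    if not (np.isfinite(d50) and d50 > 0):
        raise InvalidArgumentError(f"d50 must be positive and finite, got {d50}")
    if not (np.isfinite(dx) and dx > 0):
        raise InvalidArgumentError(f"dx must be positive and finite, got {dx}")
    out = full_score * expit(-(t - d50) / dx)
    return float(out) if out.ndim == 0 else out


def compute_rd50(d50, t):
    """Relative D50: disease time rescaled so 0 is onset and 0.5 is D50.

    ``rd50 = t / (2 * d50)``; linear, monotone in ``t`` and unbounded above.
    """
    if not (np.isfinite(d50) and d50 > 0):
        raise InvalidArgumentError(f"d50 must be positive, got {d50}")
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise InvalidArgumentError("t must be finite and non-negative")
    out = t / (2.0 * d50)
    return float(out) if out.ndim == 0 else out


def classify_phase(rd50):
    """Map an rD50 value to Phase I, II or III/IV.

    Half-open intervals; boundary values belong to the later phase
    (0.25 -> II, 0.5 -> III/IV).
    """
    if not np.isfinite(rd50) or rd50 < 0:
        raise InvalidArgumentError(f"rd50 must be finite and >= 0, got {rd50}")
    lo, hi = PHASE_BOUNDS
    if rd50 < lo:
        return Phase.I
    if rd50 < hi:
        return Phase.II
    return Phase.III_IV


def classify_aggressiveness(d50):
    """Map a D50 (months) to the high / intermediate / low aggressiveness tier.

    Boundaries 20 and 40 months belong to the less aggressive tier
    (20 -> intermediate, 40 -> low).
    """
    if not np.isfinite(d50) or d50 <= 0:
        raise InvalidArgumentError(f"d50 must be positive, got {d50}")
    lo, hi = TIER_BOUNDS
    if d50 < lo:
        return Aggressiveness.HIGH
    if d50 < hi:
        return Aggressiveness.INTERMEDIATE
    return Aggressiveness.LOW


def progression_rate(alsfrsr_at_measurement, disease_duration):
    """Classic points-per-month progression rate.

    ``(48 - ALSFRS-R at measurement) / disease duration in months``.
    """
    s = float(alsfrsr_at_measurement)
    d = float(disease_duration)
    if not (0 <= s <= FULL_SCORE):
        raise InvalidArgumentError(f"score must be in [0, 48], got {s}")
    if not (np.isfinite(d) and d > 0):
        raise InvalidArgumentError(f"duration must be positive, got {d}")
    return (FULL_SCORE - s) / d


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

_D50_BOUNDS = (0.1, 300.0)
_DX_BOUNDS = (0.1, 100.0)


@dataclass(frozen=True)
class D50Results:
    """Fitted D50 model for a single patient.

    Attributes
    ----------
    d50, dx : float
        Parameter estimates (months).
    rss : float
        Residual sum of squares of the fit.
    n_obs : int
        Number of ALSFRS-R observations used.
    converged : bool
        False when the optimizer failed to converge; never silent.
    low_information : bool
        True for two-observation fits (the stated minimum); such fits
        interpolate exactly and carry no redundancy.
    bse : tuple of float
        Approximate standard errors of (d50, dx) from the Gauss-Newton
        covariance; ``nan`` when not estimable (n_obs <= 2 or rss == 0).
    """

    d50: float
    dx: float
    rss: float
    n_obs: int
    converged: bool
    low_information: bool = False
    bse: tuple = (np.nan, np.nan)
    model: "D50Model" = field(default=None, repr=False, compare=False)

    @property
    def params(self):
        return np.array([self.d50, self.dx])

    def predict(self, t):
        """Predicted ALSFRS-R at months-since-onset ``t``."""
        return predict_alsfrsr(t, self.d50, self.dx)

    def rd50(self, t):
        """Relative D50 at months-since-onset ``t``."""
        return compute_rd50(self.d50, t)

    def phase_at(self, t):
        """rD50 phase the patient occupies at time ``t``."""
        return classify_phase(self.rd50(t))

    @property
    def aggressiveness(self):
        return classify_aggressiveness(self.d50)

    def conf_int(self, alpha=0.05):
        """Wald confidence intervals for (d50, dx)."""
        from scipy import stats as _st

        z = _st.norm.ppf(1 - alpha / 2)
        est = self.params
        se = np.asarray(self.bse)
        return np.column_stack([est - z * se, est + z * se])

    def summary(self):
        """Plain-text summary of the fit."""
        ci = self.conf_int()
        lines = [
            "D50 disease progression model",
            "=" * 46,
            f"{'n obs':<22}{self.n_obs:>8d}",
            f"{'converged':<22}{str(self.converged):>8}",
            f"{'low information':<22}{str(self.low_information):>8}",
            f"{'RSS':<22}{self.rss:>12.4f}",
            "-" * 46,
            f"{'param':<8}{'estimate':>10}{'std err':>10}{'[0.025':>9}{'0.975]':>9}",
            f"{'D50':<8}{self.d50:>10.3f}{self.bse[0]:>10.3f}"
            f"{ci[0, 0]:>9.2f}{ci[0, 1]:>9.2f}",
            f"{'dx':<8}{self.dx:>10.3f}{self.bse[1]:>10.3f}"
            f"{ci[1, 0]:>9.2f}{ci[1, 1]:>9.2f}",
            "-" * 46,
            f"{'aggressiveness':<22}{self.aggressiveness.value:>10}",
        ]
        return "\n".join(lines)


class D50Model:
    """Sigmoidal decline model for one patient's ALSFRS-R trajectory.

    Parameters
    ----------
    times : array_like
        Months since symptom onset of each assessment; non-negative, finite,
        no duplicates.
    scores : array_like
        ALSFRS-R totals, integers in [0, 48].
    patient_id : hashable, optional
        Carried through to results tables.

    Notes
    -----
    Estimation is bounded nonlinear least squares (trust-region reflective):
    deterministic, derivative-based, with D50 in (0.1, 300] months and dx in
    [0.1, 100] months.  The starting point places D50 where linear
    interpolation of the observations crosses 24 points (falling back to the
    last observation time) and dx at max(D50/4, 1); a second deterministic
    start from a logit-linear regression guards against poor local minima.
    """

    def __init__(self, times, scores, patient_id=None, validate=True):
        t = np.asarray(times, dtype=float)
        y = np.asarray(scores, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise InvalidArgumentError("times and scores must be equal-length 1-D")
        if validate:
            if not np.all(np.isfinite(t)) or np.any(t < 0):
                raise InvalidArgumentError("times must be finite and >= 0")
            if not np.all(np.isfinite(y)) or np.any(y < 0) or np.any(y > FULL_SCORE):
                raise InvalidArgumentError("scores must lie in [0, 48]")
        if t.size < 2:
            raise InsufficientDataError(
                "valid modeling requires at least two ALSFRS-R assessments"
            )
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]
        if np.any(np.diff(t) == 0):
            raise InvalidArgumentError("duplicate assessment times for patient")
        self.times = t
        self.scores = y
        self.patient_id = patient_id

    @classmethod
    def from_dataframe(cls, df, time_col="months_since_onset",
                       score_col="alsfrs_r_total", patient_id=None):
        return cls(df[time_col].to_numpy(), df[score_col].to_numpy(),
                   patient_id=patient_id)

    # -- starting values ---------------------------------------------------

    def _start_interp(self):
        t, y = self.times, self.scores
        half = FULL_SCORE / 2.0
        d50_0 = t[-1]
        below = np.nonzero(y <= half)[0]
        if below.size and below[0] > 0:
            i = below[0]
            t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
            if y1 != y0:
                d50_0 = t0 + (y0 - half) * (t1 - t0) / (y0 - y1)
        elif below.size and below[0] == 0:
            d50_0 = max(t[0] / 2.0, _D50_BOUNDS[0] * 2)
        d50_0 = float(np.clip(d50_0, _D50_BOUNDS[0] * 1.5, _D50_BOUNDS[1]))
        dx_0 = float(np.clip(max(d50_0 / 4.0, 1.0), *_DX_BOUNDS))
        return d50_0, dx_0

    def _start_logit(self):
        # ln(48/y - 1) = (t - D50)/dx is linear in t; least-squares line
        # through interior points gives a second deterministic start.
        t, y = self.times, self.scores
        keep = (y > 0.5) & (y < FULL_SCORE - 0.5)
        if keep.sum() < 2:
            return None
        z = np.log(FULL_SCORE / y[keep] - 1.0)
        slope, intercept = np.polyfit(t[keep], z, 1)
        if slope <= 1e-9:
            return None
        dx_0 = float(np.clip(1.0 / slope, *_DX_BOUNDS))
        d50_0 = float(np.clip(-intercept / slope, *_D50_BOUNDS))
        return d50_0, dx_0

    # -- fitting -----------------------------------------------------------

    def fit(self, on_no_decline="raise", warn_onset=True):
        """Estimate (D50, dx) by bounded nonlinear least squares.

        Parameters
        ----------
        on_no_decline : {"raise", "flag"}
            A trajectory with every score at the ceiling of 48 carries no
            decline signal.  "raise" (default) raises
            :class:`IllPosedFitError`; "flag" returns a non-converged
            result with D50 pinned at its upper bound.
        warn_onset : bool
            Warn when the fitted curve predicts < 46 points at onset,
            implying substantial pre-onset loss.

        Returns
        -------
        D50Results
        """
        t, y = self.times, self.scores
        if np.all(y >= FULL_SCORE):
            if on_no_decline == "raise":
                raise IllPosedFitError(
                    "all scores at ceiling (48): D50 unidentifiable"
                )
            res = D50Results(d50=_D50_BOUNDS[1], dx=_DX_BOUNDS[1],
                             rss=0.0, n_obs=t.size, converged=False,
                             low_information=t.size == 2, model=self)
            return res

        def resid(p):
            return FULL_SCORE * expit(-(t - p[0]) / p[1]) - y

        lower = np.array([_D50_BOUNDS[0], _DX_BOUNDS[0]])
        upper = np.array([_D50_BOUNDS[1], _DX_BOUNDS[1]])
        starts = [self._start_interp()]
        alt = self._start_logit()
        if alt is not None:
            starts.append(alt)

        best = None
        converged = False
        for x0 in starts:
            sol = optimize.least_squares(
                resid, np.clip(x0, lower, upper), bounds=(lower, upper),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=20000,
            )
            if best is None or sol.cost < best.cost:
                best = sol
            converged = converged or sol.success

        d50_hat, dx_hat = map(float, best.x)
        rss = float(2.0 * best.cost)

        bse = (np.nan, np.nan)
        if t.size > 2 and rss > 0:
            jac = best.jac
            try:
                cov = np.linalg.inv(jac.T @ jac) * rss / (t.size - 2)
                bse = tuple(np.sqrt(np.diag(cov)))
            except np.linalg.LinAlgError:
                pass

        res = D50Results(
            d50=d50_hat, dx=dx_hat, rss=rss, n_obs=int(t.size),
            converged=bool(converged), low_information=t.size == 2,
            bse=bse, model=self,
        )
        if warn_onset and res.predict(0.0) < FULL_SCORE - 2.0:
            warnings.warn(
                f"fit implies F(0) = {res.predict(0.0):.1f} < 46: "
                "substantial pre-onset functional loss",
                PreOnsetLossWarning, stacklevel=2,
            )
        return res


def fit_d50(times, scores, patient_id=None, **fit_kwargs):
    """Convenience wrapper: build a :class:`D50Model` and fit it."""
    return D50Model(times, scores, patient_id=patient_id).fit(**fit_kwargs)


def fit_cohort(alsfrs, on_error="record", warn_onset=False):
    """Fit the D50 model to every patient in a long-format table.

    Parameters
    ----------
    alsfrs : pandas.DataFrame
        Columns ``patient_id``, ``months_since_onset``, ``alsfrs_r_total``.
    on_error : {"record", "raise"}
        "record" lists failed patients in the ``excluded`` frame with the
        reason; "raise" propagates the first error.

    Returns
    -------
    fits : pandas.DataFrame
        One row per fitted patient: patient_id, d50, dx, rss, n_obs,
        converged, low_information.
    excluded : pandas.DataFrame
        patient_id and reason for every patient that could not be fitted.
    """
    rows, excluded = [], []
    for pid, grp in alsfrs.groupby("patient_id", sort=True):
        try:
            res = fit_d50(grp["months_since_onset"].to_numpy(),
                          grp["alsfrs_r_total"].to_numpy(),
                          patient_id=pid, warn_onset=warn_onset)
            rows.append({
                "patient_id": pid, "d50": res.d50, "dx": res.dx,
                "rss": res.rss, "n_obs": res.n_obs,
                "converged": res.converged,
                "low_information": res.low_information,
            })
        except Exception as exc:  # noqa: BLE001 - reasons are user-facing
            if on_error == "raise":
                raise
            excluded.append({"patient_id": pid, "reason": str(exc)})
    fits = pd.DataFrame(
        rows, columns=["patient_id", "d50", "dx", "rss", "n_obs",
                       "converged", "low_information"])
    return fits, pd.DataFrame(excluded, columns=["patient_id", "reason"])
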