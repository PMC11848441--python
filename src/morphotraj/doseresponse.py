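"""Four-parameter logistic (variable-slope) dose-response model.

The 4PL curve in log-dose,

    y(d) = bottom + (top - bottom) / (1 + 10^((logEC50 - log10 d) * hill)),

is the standard model for screen validation dose series.  The model object
takes an 8-point (or longer) semi-log dose series with replicate responses;
``fit()`` runs a deterministic multi-start least-squares (9 logEC50 starts
across the tested dose range crossed with hill in {+1, -1}) and returns a
results object carrying the parameter estimates, residual SSE, the
trapezoidal AUC of the mean response over log10 dose, and a flat-data flag
(for responses with no dose structure the hill slope is unidentifiable and
the fit is reported as flat rather than as a spurious curve).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["four_pl", "FourParamLogistic", "FourParamLogisticResults"]


def four_pl(log_dose: np.ndarray, bottom: float, top: float, logec50: float, hill: float) -> np.ndarray:
    """Evaluate the variable-slope 4PL curve at log10 dose values."""
    log_dose = np.asarray(log_dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - log_dose) * hill))


class FourParamLogistic:
    """4PL dose-response model for one readout.

    Parameters
    ----------
    doses
        Dose values (same units throughout, must be > 0), length >= 4
        distinct values; typically an 8-point semi-log series.
    responses
        Array of shape (n_doses,) or (n_doses, n_replicates).
    """

    N_STARTS = 9  # logEC50 grid points spanning the tested dose range

    def __init__(self, doses, responses):
        self.doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if responses.ndim == 1:
            responses = responses[:, None]
        self.responses = responses
        if np.unique(self.doses).size < 4:
            raise ValueError("need at least 4 distinct doses for a 4PL fit")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if responses.shape[0] != self.doses.size:
            raise ValueError("responses must have one row per dose")
        self.log_dose = np.log10(self.doses)
        self.mean_response = self.responses.mean(axis=1)

    def auc(self) -> float:
        """Trapezoidal area under the mean response over log10 dose."""
        order = np.argsort(self.log_dose)
        return float(np.trapezoid(self.mean_response[order], self.log_dose[order]))

    def fit(self, flat_tol: float = 1e-9) -> "FourParamLogisticResults":
        y = self.responses.ravel()
        ld = np.repeat(self.log_dose, self.responses.shape[1])
        span = float(self.mean_response.max() - self.mean_response.min())
        if span <= flat_tol:
            level = float(self.mean_response.mean())
            params = np.array([level, level, float(np.median(self.log_dose)), np.nan])
            sse = float(np.sum((y - level) ** 2))
            return FourParamLogisticResults(self, params, sse, flat=True)

        lo, hi = float(self.log_dose.min()), float(self.log_dose.max())
        b0 = float(self.mean_response.min())
        t0 = float(self.mean_response.max())
        best = None
        for logec50 in np.linspace(lo, hi, self.N_STARTS):
            for hill in (1.0, -1.0):
                x0 = np.array([b0, t0, logec50, hill])
                res = least_squares(
                    lambda p: four_pl(ld, *p) - y, x0, method="lm", max_nfev=2000
                )
                sse = float(np.sum(res.fun**2))
                if best is None or sse < best[1] - 1e-14:
                    best = (res.x, sse)
        params, sse = best
        params = np.asarray(params, dtype=float)
        if params[3] < 0:  # (b, t, L, h) and (t, b, L, -h) trace the same curve
            params = np.array([params[1], params[0], params[2], -params[3]])
        flat = abs(params[1] - params[0]) <= flat_tol * max(1.0, abs(t0 - b0))
        return FourParamLogisticResults(self, params, sse, flat=flat)


@dataclass
class FourParamLogisticResults:
    """Fitted 4PL parameters with fit diagnostics."""

    model: FourParamLogistic
    params: np.ndarray  # bottom, top, logEC50, hill
    sse: float
    flat: bool

    @property
    def bottom(self) -> float:
        return float(self.params[0])

    @property
    def top(self) -> float:
        return float(self.params[1])

    @property
    def logec50(self) -> float:
        return float(self.params[2])

    @property
    def ec50(self) -> float:
        return float(10.0 ** self.params[2])

    @property
    def hill(self) -> float:
        return float(self.params[3])

    @property
    def auc(self) -> float:
        return self.model.auc()

    def predict(self, doses) -> np.ndarray:
        doses = np.asarray(doses, dtype=float)
        if self.flat:
            return np.full(doses.shape, (self.bottom + self.top) / 2.0)
        return four_pl(np.log10(doses), *self.params)

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response",
            "=" * 41,
            f"n doses:    {self.model.doses.size} (x {self.model.responses.shape[1]} replicates)",
            f"bottom:     {self.bottom: .6g}",
            f"top:        {self.top: .6g}",
            f"logEC50:    {self.logec50: .6g}  (EC50 = {self.ec50:.6g})",
            f"hill:       {self.hill: .6g}",
            f"SSE:        {self.sse: .6g}",
            f"AUC:        {self.auc: .6g}",
            f"flat:       {self.flat}",
        ]
        return "\n".join(lines)
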