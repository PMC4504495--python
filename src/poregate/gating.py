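"""The hydration-barrier gating model.

Two linear relations summarize how gate hydration controls ion permeation:
the permeation barrier falls linearly with the gate water count,
dG = a - b * N_wat (kcal/mol), and the mean gate diameter grows linearly
with it, d = c + m * N_wat (nm).  From the fitted coefficients the model
extrapolates the hydration at which the barrier vanishes (the open-state
water count, reported truncated to an integer), predicts barriers at stated
hydration levels, and converts between hydration and diameter.

The model is deliberately linear; it computes the arithmetic consequences
of the fits and makes no claim that the extrapolation identifies the true
open state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .regression import LinearModel, fit_line


@dataclass
class GatingModel:
    """Fitted barrier and diameter relations, with provenance.

    ``provenance`` records which hydration definition the barrier fit used:
    the water count of the initial frame, ``N_wat(t0)``, or the
    during-sampling average while the ion is in the gate, ``N_wat(US)``.
    The model is physically meaningful when the barrier falls (b > 0) and
    the pore dilates (m > 0) with hydration; ``physical`` flags this.
    """

    barrier_fit: LinearModel | None = None
    diameter_fit: LinearModel | None = None
    provenance: str = "N_wat(t0)"

    @property
    def a(self) -> float:
        return self.barrier_fit.intercept

    @property
    def b(self) -> float:
        """Barrier decrease per water (kcal/mol), positive when physical."""
        return -self.barrier_fit.slope

    @property
    def c(self) -> float:
        return self.diameter_fit.intercept

    @property
    def m(self) -> float:
        return self.diameter_fit.slope

    @property
    def physical(self) -> bool:
        ok = True
        if self.barrier_fit is not None:
            ok &= self.b > 0
        if self.diameter_fit is not None:
            ok &= self.m > 0
        return ok


def model_from_coefficients(a: float = None, b: float = None,
                            c: float = None, m: float = None,
                            provenance: str = "N_wat(t0)") -> GatingModel:
    """Build a model directly from printed coefficients (r^2 = 1 stand-ins)."""
    barrier = None if a is None else LinearModel(-b, a, 1.0, 0, 0.0)
    diameter = None if c is None else LinearModel(m, c, 1.0, 0, 0.0)
    return GatingModel(barrier_fit=barrier, diameter_fit=diameter,
                       provenance=provenance)


def fit_barrier_model(n_wat, dg) -> LinearModel:
    """OLS fit of the permeation barrier on the gate water count."""
    return fit_line(n_wat, dg)


def open_state_hydration(model: GatingModel) -> int:
    """Water count at which the extrapolated barrier reaches zero.

    Returns floor(a / b); requires a physically meaningful barrier fit
    (b > 0).
    """
    if model.barrier_fit is None or model.b <= 0:
        raise ValueError("open-state extrapolation requires b > 0")
    return int(math.floor(model.a / model.b))


def predict_barrier(model: GatingModel, n_wat: float) -> float:
    """Barrier a - b * n_wat (kcal/mol) at a stated hydration level."""
    if model.barrier_fit is None:
        raise ValueError("model has no barrier fit")
    return float(model.a - model.b * n_wat)


def diameter_for_hydration(model: GatingModel, n_wat: float) -> float:
    """Mean gate diameter c + m * n_wat (nm)."""
    if model.diameter_fit is None:
        raise ValueError("model has no diameter fit")
    return float(model.c + model.m * n_wat)


def hydration_for_diameter(model: GatingModel, d: float) -> int:
    """Water count whose predicted diameter is ``d``; nearest integer."""
    if model.diameter_fit is None:
        raise ValueError("model has no diameter fit")
    if model.m <= 0:
        raise ValueError("inversion requires m > 0")
    return int(round((d - model.c) / model.m))
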