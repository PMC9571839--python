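"""Linear interaction energy (LIE) binding free-energy formalism.

LIE is an end-point method: the absolute binding free energy of a
non-covalent ligand is estimated from MD ensemble averages of its van der
Waals and electrostatic interaction energies with the environment in two
simulations only -- ligand bound in the solvated protein site (P) and
ligand free in water (W):

    dG_bind = alpha * (<V_vdw>_P - <V_vdw>_W)
            + beta  * (<V_el>_P  - <V_el>_W) + gamma

alpha and beta weight the nonpolar and polar contributions; gamma is a
constant offset used for strongly hydrophobic sites.  The formalism follows
from a thermodynamic cycle through decoupled (non-interacting) ligand
states, with each decoupling leg approximated linearly from the end-point
averages.

Experimental reference values come from inhibition constants via
dG = RT ln Ki at a 1 M standard state.  Uncertainties are propagated to
first order: RT * sigma_Ki / Ki for experiment, and quadrature over the
block-average SDs of the energy differences for the LIE prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .energy_stats import InteractionEnergySummary, MeanSD
from .errors import DegenerateFitError, InvalidInputError
from .util import round_half_away

#: Gas constant in kcal/(mol K).
R_KCAL = 1.987204e-3

#: Default temperature (K) for Ki -> dG conversion.  The assay temperature;
#: it reproduces the tabulated experimental free energies to one decimal.
DEFAULT_TEMPERATURE = 303.15


@dataclass(frozen=True)
class Compound:
    """An inhibitor with its measured inhibition constant.

    ``ki`` and ``ki_err`` are in molar units (1 M standard state).
    """

    id: int
    name: str = ""
    charged: bool = False
    ki: float = 1.0
    ki_err: float = 0.0
    notes: str = ""

    def __post_init__(self):
        if not self.ki > 0:
            raise InvalidInputError(f"compound {self.id}: ki must be > 0, got {self.ki}")
        if self.ki_err < 0:
            raise InvalidInputError(f"compound {self.id}: ki_err must be >= 0")


@dataclass(frozen=True)
class LIECoefficients:
    """Empirical LIE coefficients: alpha (vdW), beta (electrostatic), gamma (offset)."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if not all(np.isfinite([self.alpha, self.beta, self.gamma])):
            raise InvalidInputError("LIE coefficients must be finite")


#: Coefficients calibrated for the MAO-A / beta-carboline series.
MAOA_COEFFICIENTS = LIECoefficients(alpha=0.54, beta=0.26, gamma=-2.65)


@dataclass(frozen=True)
class BindingFreeEnergy:
    """A binding free energy in kcal/mol with its 1-sigma uncertainty."""

    compound_id: int
    value: float
    uncertainty: float
    source: str  # "experimental" or "lie_predicted"

    def __post_init__(self):
        if self.uncertainty < 0:
            raise InvalidInputError("uncertainty must be >= 0")
        if self.source not in ("experimental", "lie_predicted"):
            raise InvalidInputError(f"unknown source {self.source!r}")

    @property
    def rounded(self) -> float:
        return round_half_away(self.value, 1)


@dataclass(frozen=True)
class ThermodynamicCycle:
    """Free-energy legs of the LIE thermodynamic cycle, kcal/mol.

    Closure: dg_binding + dg_decoupling_P - dg_decoupling_W
             - dg_binding_decoupled = 0, with the decoupled-ligand binding
    leg identically zero (a non-interacting ligand binds with zero free
    energy change).
    """

    dg_binding: float
    dg_decoupling_P: float
    dg_decoupling_W: float
    dg_binding_decoupled: float = 0.0

    def closure_residual(self) -> float:
        return (
            self.dg_binding
            + self.dg_decoupling_P
            - self.dg_decoupling_W
            - self.dg_binding_decoupled
        )


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of least-squares calibration of (alpha, beta, gamma)."""

    coefficients: LIECoefficients
    predictions: list[BindingFreeEnergy]
    residuals: np.ndarray  # prediction - experiment, per compound
    mue: float
    pearson_r: float
    compound_ids: list[int] = field(default_factory=list)


def ki_to_dg(
    compound: Compound, temperature: float = DEFAULT_TEMPERATURE
) -> BindingFreeEnergy:
    """Convert an inhibition constant to a binding free energy, RT ln Ki.

    First-order error propagation gives sigma_dG = RT * sigma_Ki / Ki.
    """
    if not temperature > 0:
        raise InvalidInputError(f"temperature must be > 0 K, got {temperature}")
    rt = R_KCAL * temperature
    return BindingFreeEnergy(
        compound_id=compound.id,
        value=rt * float(np.log(compound.ki)),
        uncertainty=rt * compound.ki_err / compound.ki,
        source="experimental",
    )


def lie_predict(
    summary: InteractionEnergySummary, coeffs: LIECoefficients
) -> BindingFreeEnergy:
    """Predict the binding free energy from bound-minus-free energy averages.

    Uncertainty combines the difference-column SDs in quadrature:
    sqrt((alpha*sd_dvdw)^2 + (beta*sd_del)^2).
    """
    value = (
        coeffs.alpha * summary.delta_vdw.mean
        + coeffs.beta * summary.delta_el.mean
        + coeffs.gamma
    )
    unc = float(
        np.hypot(coeffs.alpha * summary.delta_vdw.sd, coeffs.beta * summary.delta_el.sd)
    )
    return BindingFreeEnergy(
        compound_id=summary.compound_id,
        value=float(value),
        uncertainty=abs(unc),
        source="lie_predicted",
    )


def solvation_free_energy(
    vdw_mean: float | MeanSD, el_mean: float | MeanSD, coeffs: LIECoefficients
) -> float:
    """Linear-response solvation free energy of the ligand in one environment.

    ``dG_solv(Q) = alpha*<V_vdw>_Q + beta*<V_el>_Q + gamma`` where Q is either
    the protein site (P) or bulk water (W).  Means may be given as scalars or
    :class:`~maolie.energy_stats.MeanSD` pairs (only the mean is used).
    """
    if isinstance(vdw_mean, tuple):
        vdw_mean = vdw_mean[0]
    if isinstance(el_mean, tuple):
        el_mean = el_mean[0]
    return coeffs.alpha * float(vdw_mean) + coeffs.beta * float(el_mean) + coeffs.gamma


def build_cycle(
    summary: InteractionEnergySummary, coeffs: LIECoefficients
) -> ThermodynamicCycle:
    """Assemble the thermodynamic cycle from one compound's energy averages.

    Each decoupling leg is the negative of the linear-response solvation free
    energy in that environment; the binding leg is their difference (gamma
    cancels), so the cycle closes identically.
    """
    dg_solv_p = solvation_free_energy(summary.vdw_bound, summary.el_bound, coeffs)
    dg_solv_w = solvation_free_energy(summary.vdw_free, summary.el_free, coeffs)
    cycle = ThermodynamicCycle(
        dg_binding=(-dg_solv_w) - (-dg_solv_p),
        dg_decoupling_P=-dg_solv_p,
        dg_decoupling_W=-dg_solv_w,
        dg_binding_decoupled=0.0,
    )
    assert abs(cycle.closure_residual()) < 1e-9
    return cycle


def calibrate(
    summaries: Sequence[InteractionEnergySummary],
    dg_exp: Sequence[BindingFreeEnergy],
    pin_gamma: float | None = None,
) -> CalibrationResult:
    """Fit (alpha, beta, gamma) by ordinary least squares.

    Solves ``dG_exp ~ alpha*dVdW + beta*dEl + gamma`` over compounds present
    in both inputs.  ``pin_gamma`` fixes the offset instead of fitting it.
    """
    exp_by_id = {e.compound_id: e for e in dg_exp}
    matched = [s for s in summaries if s.compound_id in exp_by_id]
    if len(matched) < 4:
        raise InvalidInputError(
            f"need >= 4 matched compounds to calibrate, got {len(matched)}"
        )
    dvdw = np.array([s.delta_vdw.mean for s in matched])
    delE = np.array([s.delta_el.mean for s in matched])
    y = np.array([exp_by_id[s.compound_id].value for s in matched])

    if pin_gamma is None:
        X = np.column_stack([dvdw, delE, np.ones_like(dvdw)])
    else:
        X = np.column_stack([dvdw, delE])
        y = y - pin_gamma
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateFitError(
            "design matrix is rank-deficient (constant or collinear energy differences)"
        )
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    if pin_gamma is None:
        alpha, beta, gamma = (float(t) for t in theta)
    else:
        alpha, beta = (float(t) for t in theta)
        gamma = float(pin_gamma)
        y = y + pin_gamma
    coeffs = LIECoefficients(alpha, beta, gamma)

    predictions = [lie_predict(s, coeffs) for s in matched]
    pred = np.array([p.value for p in predictions])
    residuals = pred - y
    pearson = float(_stats.pearsonr(pred, y).statistic) if len(matched) > 2 else np.nan
    return CalibrationResult(
        coefficients=coeffs,
        predictions=predictions,
        residuals=residuals,
        mue=float(np.mean(np.abs(residuals))),
        pearson_r=pearson,
        compound_ids=[s.compound_id for s in matched],
    )


def correlate_scores(
    scores: Sequence[tuple[int, float]],
    dg_exp: Sequence[BindingFreeEnergy],
) -> tuple[float, float]:
    """Pearson and Spearman correlation of arbitrary scores with dG_exp.

    Used to check external docking scores against experiment.  Compounds are
    matched by id; at least three matched pairs are required.
    """
    exp_by_id = {e.compound_id: e.value for e in dg_exp}
    pairs = [(s, exp_by_id[cid]) for cid, s in scores if cid in exp_by_id]
    if len(pairs) < 3:
        raise InvalidInputError(f"need >= 3 matched (score, dG) pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    return (
        float(_stats.pearsonr(x, y).statistic),
        float(_stats.spearmanr(x, y).statistic),
    )
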