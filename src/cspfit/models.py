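"""Ligand-binding equilibrium models with exact ligand-depletion mass balance.

Five fast-exchange models for a protein P titrated with a ligand L at
concentrations where free ligand cannot be approximated by total ligand
(protein at 200–270 μM, dissociation constants from a few μM to ~1 mM):

``single_site``
    P + L ⇌ PL with dissociation constant K_D.
``two_site_independent``
    Two sites (N-terminal and C-terminal SH3 in the motivating system) that
    bind independently with K_D1 and K_D2; species P, L–P (site 1 bound),
    P–L (site 2 bound) and L–P–L.
``two_site_cooperative``
    Same four species, but occupation of one site rescales the other site's
    affinity by a modulation factor α: K_D3 = α·K_D2 and
    K_D4 = α·K_D2²/K_D1, which closes the thermodynamic cycle
    K_D1·K_D4 = K_D2·K_D3 exactly.  α = 1 recovers independence.
``conformational_selection``
    Free protein pre-equilibrates between an inactive and an active state
    (K_f = [active]/[inactive]); only the active state binds, with K_D.
    Total binding follows a single-site isotherm with apparent
    K_D,app = K_D·(1 + 1/K_f).
``induced_fit``
    Binding (K_D) precedes an intramolecular rearrangement of the complex
    (K_f = [closed]/[open] among bound protein); apparent
    K_D,app = K_D/(1 + K_f).

All solvers conserve protein and ligand mass to better than 1e-9 relative;
free ligand is obtained by bracketed root finding on [0, L_total] (Brent),
except for the single-site model where the numerically stable quadratic root
is closed-form.

Observed CSPs in fast exchange are population-weighted:  ``predict_csp``
maps a solved titration to a per-point Δδ_ave curve given residue-specific
saturation amplitudes.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq

from ._exceptions import InvalidInputError, NumericalError
from .csp import ConcentrationSchedule

__all__ = [
    "SingleSiteParams",
    "TwoSiteIndependentParams",
    "TwoSiteCooperativeParams",
    "TwoStateExchangeParams",
    "ResidueResponse",
    "SpeciesState",
    "solve_single_site",
    "solve_two_site_independent",
    "solve_two_site_cooperative",
    "solve_conformational_selection",
    "solve_induced_fit",
    "solve_state",
    "response_basis",
    "predict_csp",
    "MODEL_NAMES",
    "params_to_dict",
    "params_from_dict",
]

_BAL_RTOL = 1e-9  # relative mass-balance tolerance enforced on every state

# ligand stoichiometry of each protein species
_LIGAND_STOICH = {
    "P": 0,
    "PL": 1,
    "LP": 1,
    "LPL": 2,
    "P_inactive": 0,
    "P_active": 0,
    "PaL": 1,
    "PL_open": 1,
    "PL_close": 1,
}


def _positive(name: str, value: float) -> float:
    value = float(value)
    if not (math.isfinite(value) and value > 0):
        raise InvalidInputError(f"{name} must be finite and > 0, got {value}")
    return value


@dataclass(frozen=True)
class SingleSiteParams:
    """Single binding site: dissociation constant K_D (μM)."""

    kd: float

    def __post_init__(self):
        object.__setattr__(self, "kd", _positive("kd", self.kd))


@dataclass(frozen=True)
class TwoSiteIndependentParams:
    """Independent two-site binding: K_D1 (site 1), K_D2 (site 2), μM."""

    kd1: float
    kd2: float

    def __post_init__(self):
        object.__setattr__(self, "kd1", _positive("kd1", self.kd1))
        object.__setattr__(self, "kd2", _positive("kd2", self.kd2))


@dataclass(frozen=True)
class TwoSiteCooperativeParams:
    """Cooperative two-site binding: K_D1, K_D2 (μM) and modulation factor α.

    The second-binding constants are derived, not free:
    K_D3 = α·K_D2, K_D4 = α·K_D2²/K_D1, so K_D1·K_D4 = K_D2·K_D3 exactly.
    """

    kd1: float
    kd2: float
    alpha: float

    def __post_init__(self):
        object.__setattr__(self, "kd1", _positive("kd1", self.kd1))
        object.__setattr__(self, "kd2", _positive("kd2", self.kd2))
        object.__setattr__(self, "alpha", _positive("alpha", self.alpha))

    @property
    def kd3(self) -> float:
        return self.alpha * self.kd2

    @property
    def kd4(self) -> float:
        return self.alpha * self.kd2**2 / self.kd1


@dataclass(frozen=True)
class TwoStateExchangeParams:
    """Two-state exchange models: K_D (μM) and state equilibrium constant K_f.

    Conformational selection: K_f = [active]/[inactive] among free protein.
    Induced fit: K_f = [closed]/[open] among bound protein.
    """

    kd: float
    kf: float

    def __post_init__(self):
        object.__setattr__(self, "kd", _positive("kd", self.kd))
        object.__setattr__(self, "kf", _positive("kf", self.kf))


@dataclass(frozen=True)
class ResidueResponse:
    """Saturation CSP amplitudes of one residue, ppm; fields are model-specific.

    single site: ``delta_max``; two-site models: ``delta_lp`` (site 1) and
    ``delta_pl`` (site 2); two-state models: ``delta_open`` and ``delta_close``.
    """

    delta_max: float | None = None
    delta_lp: float | None = None
    delta_pl: float | None = None
    delta_open: float | None = None
    delta_close: float | None = None

    def amplitudes(self, model: str) -> np.ndarray:
        names = AMP_NAMES[model]
        vals = []
        for name in names:
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise InvalidInputError(
                    f"model {model!r} requires finite amplitude {name!r}"
                )
            vals.append(float(v))
        return np.array(vals)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium species concentrations (μM) at one titration point."""

    protein_total: float
    ligand_total: float
    free_ligand: float
    species: Mapping[str, float]
    theta1: float
    theta2: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "species", dict(self.species))
        self._check()

    @property
    def bound_ligand(self) -> float:
        return sum(_LIGAND_STOICH[k] * v for k, v in self.species.items())

    def _check(self):
        P, L = self.protein_total, self.ligand_total
        tolP = _BAL_RTOL * max(P, 1.0)
        tolL = _BAL_RTOL * max(L, 1.0)
        for name, c in self.species.items():
            if c < -tolP:
                raise NumericalError(f"negative concentration for {name}: {c}")
        if abs(sum(self.species.values()) - P) > tolP:
            raise NumericalError(
                f"protein mass balance violated at P={P}, L={L}: "
                f"sum={sum(self.species.values())}"
            )
        if abs(self.free_ligand + self.bound_ligand - L) > tolL:
            raise NumericalError(
                f"ligand mass balance violated at P={P}, L={L}: "
                f"free={self.free_ligand}, bound={self.bound_ligand}"
            )
        for th in (self.theta1, self.theta2):
            if not -1e-12 <= th <= 1 + 1e-12:
                raise NumericalError(f"occupancy out of [0,1]: {th}")


def _check_totals(protein_total: float, ligand_total: float):
    if protein_total < 0 or ligand_total < 0:
        raise InvalidInputError("totals must be >= 0")
    if not (math.isfinite(protein_total) and math.isfinite(ligand_total)):
        raise InvalidInputError("totals must be finite")


def _bound_complex(P: float, L: float, kd: float) -> float:
    """Stable closed-form [PL] for one site: the physical quadratic root."""
    b = P + L + kd
    disc = b * b - 4.0 * P * L
    # disc >= kd^2 > 0 analytically; guard tiny negative rounding
    root = math.sqrt(max(disc, 0.0))
    return 2.0 * P * L / (b + root)


def solve_single_site(
    protein_total: float, ligand_total: float, params: SingleSiteParams
) -> SpeciesState:
    """Exact single-site equilibrium via the stable quadratic root."""
    _check_totals(protein_total, ligand_total)
    P, L = float(protein_total), float(ligand_total)
    pl = _bound_complex(P, L, params.kd) if P > 0 and L > 0 else 0.0
    theta = pl / P if P > 0 else 0.0
    return SpeciesState(
        protein_total=P,
        ligand_total=L,
        free_ligand=L - pl,
        species={"P": P - pl, "PL": pl},
        theta1=theta,
    )


def _brent_free_ligand(g: Callable[[float], float], L: float, context: str) -> float:
    """Root of the ligand balance g on [0, L]; g(0) <= 0 <= g(L) by construction."""
    if L == 0.0:
        return 0.0
    try:
        return brentq(g, 0.0, L, xtol=1e-15, rtol=4 * np.finfo(float).eps, maxiter=300)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise NumericalError(f"free-ligand solve failed for {context}") from exc


def solve_two_site_independent(
    protein_total: float, ligand_total: float, params: TwoSiteIndependentParams
) -> SpeciesState:
    """Two independent sites: free ligand from the scalar mass balance.

    L_tot = L_f + P_tot·(L_f/(K_D1+L_f) + L_f/(K_D2+L_f)); occupancies are
    θ_i = L_f/(K_Di+L_f) and the four species follow binomially.
    """
    _check_totals(protein_total, ligand_total)
    P, L = float(protein_total), float(ligand_total)
    kd1, kd2 = params.kd1, params.kd2

    def g(lf: float) -> float:
        return lf + P * (lf / (kd1 + lf) + lf / (kd2 + lf)) - L

    lf = L if P == 0.0 else _brent_free_ligand(
        g, L, f"two_site_independent P={P}, L={L}, kd1={kd1}, kd2={kd2}"
    )
    th1 = lf / (kd1 + lf)
    th2 = lf / (kd2 + lf)
    species = {
        "P": P * (1 - th1) * (1 - th2),
        "LP": P * th1 * (1 - th2),
        "PL": P * (1 - th1) * th2,
        "LPL": P * th1 * th2,
    }
    return SpeciesState(
        protein_total=P,
        ligand_total=L,
        free_ligand=L - P * (th1 + th2),
        species=species,
        theta1=th1,
        theta2=th2,
    )


def solve_two_site_cooperative(
    protein_total: float, ligand_total: float, params: TwoSiteCooperativeParams
) -> SpeciesState:
    """Cooperative two-site equilibrium.

    With free ligand L_f, mass-action ratios give
    [L–P] = [P]·L_f/K_D1, [P–L] = [P]·L_f/K_D2 and
    [L–P–L] = [P]·L_f²/(α·K_D1·K_D2); free protein is eliminated through the
    protein balance and L_f solved from the ligand balance on [0, L_tot].
    """
    _check_totals(protein_total, ligand_total)
    P, L = float(protein_total), float(ligand_total)
    kd1, kd2, alpha = params.kd1, params.kd2, params.alpha
    c12 = 1.0 / (alpha * kd1 * kd2)

    def split(lf: float):
        denom = 1.0 + lf / kd1 + lf / kd2 + lf * lf * c12
        pf = P / denom
        return pf, pf * lf / kd1, pf * lf / kd2, pf * lf * lf * c12

    def g(lf: float) -> float:
        _, lp, pl, lpl = split(lf)
        return lf + lp + pl + 2.0 * lpl - L

    lf = L if P == 0.0 else _brent_free_ligand(
        g, L, f"two_site_cooperative P={P}, L={L}, kd1={kd1}, kd2={kd2}, alpha={alpha}"
    )
    pf, lp, pl, lpl = split(lf)
    return SpeciesState(
        protein_total=P,
        ligand_total=L,
        free_ligand=L - (lp + pl + 2.0 * lpl),
        species={"P": pf, "LP": lp, "PL": pl, "LPL": lpl},
        theta1=(lp + lpl) / P if P > 0 else 0.0,
        theta2=(pl + lpl) / P if P > 0 else 0.0,
    )


def solve_conformational_selection(
    protein_total: float, ligand_total: float, params: TwoStateExchangeParams
) -> SpeciesState:
    """Conformational selection: only the pre-existing active state binds.

    Equivalent to a single-site isotherm on total protein with apparent
    K_D,app = K_D·(1 + 1/K_f); the free pool then splits K_f : 1 between
    active and inactive.
    """
    _check_totals(protein_total, ligand_total)
    P, L = float(protein_total), float(ligand_total)
    kd, kf = params.kd, params.kf
    kd_app = kd * (1.0 + 1.0 / kf)
    bound = _bound_complex(P, L, kd_app) if P > 0 and L > 0 else 0.0
    free_p = P - bound
    species = {
        "P_inactive": free_p / (1.0 + kf),
        "P_active": free_p * kf / (1.0 + kf),
        "PaL": bound,
    }
    return SpeciesState(
        protein_total=P,
        ligand_total=L,
        free_ligand=L - bound,
        species=species,
        theta1=bound / P if P > 0 else 0.0,
    )


def solve_induced_fit(
    protein_total: float, ligand_total: float, params: TwoStateExchangeParams
) -> SpeciesState:
    """Induced fit: binding first (K_D), then rearrangement (K_f) of the complex.

    Equivalent to a single-site isotherm with apparent K_D,app = K_D/(1+K_f);
    the bound pool splits 1 : K_f between open and closed complex.
    """
    _check_totals(protein_total, ligand_total)
    P, L = float(protein_total), float(ligand_total)
    kd, kf = params.kd, params.kf
    kd_app = kd / (1.0 + kf)
    bound = _bound_complex(P, L, kd_app) if P > 0 and L > 0 else 0.0
    species = {
        "P": P - bound,
        "PL_open": bound / (1.0 + kf),
        "PL_close": bound * kf / (1.0 + kf),
    }
    return SpeciesState(
        protein_total=P,
        ligand_total=L,
        free_ligand=L - bound,
        species=species,
        theta1=bound / P if P > 0 else 0.0,
    )


_SOLVERS = {
    "single_site": (solve_single_site, SingleSiteParams),
    "two_site_independent": (solve_two_site_independent, TwoSiteIndependentParams),
    "two_site_cooperative": (solve_two_site_cooperative, TwoSiteCooperativeParams),
    "conformational_selection": (solve_conformational_selection, TwoStateExchangeParams),
    "induced_fit": (solve_induced_fit, TwoStateExchangeParams),
}

MODEL_NAMES = tuple(_SOLVERS)

#: amplitude (response) parameter names per model, in basis-column order
AMP_NAMES = {
    "single_site": ("delta_max",),
    "two_site_independent": ("delta_lp", "delta_pl"),
    "two_site_cooperative": ("delta_lp", "delta_pl"),
    "conformational_selection": ("delta_open", "delta_close"),
    "induced_fit": ("delta_open", "delta_close"),
}

#: thermodynamic (shared) parameter names per model
SHARED_NAMES = {
    "single_site": ("kd",),
    "two_site_independent": ("kd1", "kd2"),
    "two_site_cooperative": ("kd1", "kd2", "alpha"),
    "conformational_selection": ("kd", "kf"),
    "induced_fit": ("kd", "kf"),
}


def solve_state(model: str, protein_total: float, ligand_total: float, params) -> SpeciesState:
    """Dispatch to the solver for ``model``, validating the parameter type."""
    try:
        solver, cls = _SOLVERS[model]
    except KeyError as exc:
        raise InvalidInputError(f"unknown model: {model!r}") from exc
    if not isinstance(params, cls):
        raise InvalidInputError(
            f"model {model!r} expects {cls.__name__}, got {type(params).__name__}"
        )
    return solver(protein_total, ligand_total, params)


def response_basis(model: str, params, schedule: ConcentrationSchedule) -> np.ndarray:
    """Population-fraction basis B (n_points × n_amplitudes).

    The predicted fast-exchange CSP curve of a residue is B @ a where a are
    its saturation amplitudes; every basis column is 0 at the reference point
    by construction, so predicted curves start at exactly 0.
    """
    states = [
        solve_state(model, p, l, params) for p, l in schedule.points
    ]
    if model == "single_site":
        cols = [[s.theta1 for s in states]]
    elif model in ("two_site_independent", "two_site_cooperative"):
        cols = [[s.theta1 for s in states], [s.theta2 for s in states]]
    elif model == "conformational_selection":
        base = params.kf / (1.0 + params.kf)  # active fraction at L=0
        cols = [
            [s.species["P_active"] / s.protein_total - base for s in states],
            [s.species["PaL"] / s.protein_total for s in states],
        ]
    else:  # induced_fit
        cols = [
            [s.species["PL_open"] / s.protein_total for s in states],
            [s.species["PL_close"] / s.protein_total for s in states],
        ]
    return np.column_stack(cols)


def predict_csp(
    model: str,
    params,
    response: ResidueResponse,
    schedule: ConcentrationSchedule,
) -> np.ndarray:
    """Predicted Δδ_obs per titration point (ppm) for one residue.

    single site: Δ_max·θ1; two-site: Δ_LP·θ1 + Δ_PL·θ2; conformational
    selection: population-weighted shift referenced to the ligand-free
    equilibrium (so the curve starts at 0); induced fit: weighted over the
    open/closed complex populations.
    """
    amps = response.amplitudes(model)
    return response_basis(model, params, schedule) @ amps


# --- JSON round-trip for parameter types -----------------------------------

_PARAM_CLS = {
    "single_site": SingleSiteParams,
    "two_site_independent": TwoSiteIndependentParams,
    "two_site_cooperative": TwoSiteCooperativeParams,
    "conformational_selection": TwoStateExchangeParams,
    "induced_fit": TwoStateExchangeParams,
}


def params_to_dict(model: str, params) -> dict:
    if model not in _PARAM_CLS:
        raise InvalidInputError(f"unknown model: {model!r}")
    return {"model": model, **asdict(params)}


def params_from_dict(d: Mapping) -> tuple[str, object]:
    d = dict(d)
    model = d.pop("model")
    if model not in _PARAM_CLS:
        raise InvalidInputError(f"unknown model: {model!r}")
    return model, _PARAM_CLS[model](**d)


def params_to_json(model: str, params) -> str:
    return json.dumps(params_to_dict(model, params))


def params_from_json(s: str) -> tuple[str, object]:
    return params_from_dict(json.loads(s))
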