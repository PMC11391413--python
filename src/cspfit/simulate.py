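"""Synthetic titration generator emulating the GRB2 / SOS1-peptide designs.

Each preset reproduces one experimental design: a ¹⁵N-labelled protein at
200–270 μM titrated stepwise with a proline-rich or phosphopeptide ligand,
HSQC shifts read at every point.  Truth parameters are the fitted constants
reported for that design, so parameter-recovery studies are closed-loop:

========  =========================  ===========  =============================
preset    truth model                protein μM   molar-ratio ladder
========  =========================  ===========  =============================
S4        two-site indep. 38.7/520.5      250     0.25,0.5,1,2,4,6,8,12
S5        two-site indep. 40.9/900.8      250     …,12,18,24,36
S9        two-site indep. 28.4/515.9      250     …,12,18,24,36
S10       two-site indep. 483.1/579.2     250     …,12,18,24
EGFR      single site 4.2                 200     0.25,0.5,0.75,1,1.5,2
========  =========================  ===========  =============================

Only the endpoint ratios of the longer titrations are documented for the
original experiments; the intermediate rungs extend the 1:12 ladder
geometrically and are a convention of this package (see docs/methods.md).

Residue ensemble: site-1 reporters, site-2 reporters, mixed reporters and
null residues.  Each reporter draws a saturation Δδ_ave amplitude and a
nucleus direction φ; the amplitude is realised as (Δ¹H, Δ¹⁵N) =
(A·cosφ, 5·A·sinφ) so the composite CSP equals A.  Both sites of a mixed
reporter share one direction (collinear responses), which makes the σ=0
composite curve exactly Δ_LP·θ1 + Δ_PL·θ2 — the quantity the models fit.
Independent Gaussian noise is added per nucleus per point (reference
included), defaults σ(¹H)=0.002 and σ(¹⁵N)=0.010 ppm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from ._exceptions import InvalidInputError
from .csp import ConcentrationSchedule, ShiftRecord, TitrationSeries
from .models import (
    ResidueResponse,
    SingleSiteParams,
    TwoSiteIndependentParams,
    params_to_dict,
    predict_csp,
)

__all__ = ["ResidueEnsemble", "SimulationDesign", "preset_design", "simulate_titration", "PRESETS"]

_FIG1_LADDER = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0)

# non-proline one-letter/three-letter codes cycled for residue names
_AA_CYCLE = (
    "ALA", "ARG", "ASN", "ASP", "GLN", "GLU", "GLY", "HIS", "ILE", "LEU",
    "LYS", "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass(frozen=True)
class ResidueEnsemble:
    """Counts and amplitude ranges of the simulated residue population."""

    n_site1: int = 20
    n_site2: int = 10
    n_mixed: int = 5
    n_null: int = 15
    amp_range: tuple[float, float] = (0.05, 0.25)  # ppm at saturation
    mixed_amp_range: tuple[float, float] = (0.03, 0.15)

    def __post_init__(self):
        for n in (self.n_site1, self.n_site2, self.n_mixed, self.n_null):
            if n < 0:
                raise InvalidInputError("ensemble counts must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_site1 + self.n_site2 + self.n_mixed + self.n_null


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of one synthetic titration experiment."""

    name: str
    model: str
    truth: object  # parameter object of `model`
    protein_total: float = 250.0  # μM
    ratios: tuple[float, ...] = _FIG1_LADDER  # excludes the 1:0 reference
    ensemble: ResidueEnsemble = field(default_factory=ResidueEnsemble)
    sigma_h: float = 0.002  # ppm
    sigma_n: float = 0.010  # ppm
    seed: int | None = None

    def __post_init__(self):
        errors = []
        if self.protein_total <= 0:
            errors.append("protein_total must be > 0")
        r = self.ratios
        if len(r) == 0 or r[0] <= 0 or any(b <= a for a, b in zip(r, r[1:])):
            errors.append("ratios must be strictly increasing and > 0")
        if self.sigma_h < 0 or self.sigma_n < 0:
            errors.append("noise sigmas must be >= 0")
        if self.ensemble.n_total == 0:
            errors.append("ensemble must contain at least one residue")
        if errors:
            raise InvalidInputError("; ".join(errors))

    @property
    def schedule(self) -> ConcentrationSchedule:
        pts = [(self.protein_total, 0.0)] + [
            (self.protein_total, self.protein_total * r) for r in self.ratios
        ]
        return ConcentrationSchedule(points=tuple(pts))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "model": self.model,
            "truth": params_to_dict(self.model, self.truth),
            "protein_total": self.protein_total,
            "ratios": list(self.ratios),
            "ensemble": {
                "n_site1": self.ensemble.n_site1,
                "n_site2": self.ensemble.n_site2,
                "n_mixed": self.ensemble.n_mixed,
                "n_null": self.ensemble.n_null,
                "amp_range": list(self.ensemble.amp_range),
                "mixed_amp_range": list(self.ensemble.mixed_amp_range),
            },
            "sigma_h": self.sigma_h,
            "sigma_n": self.sigma_n,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


PRESETS: Mapping[str, dict] = {
    "S4": dict(
        model="two_site_independent",
        truth=TwoSiteIndependentParams(kd1=38.7, kd2=520.5),
        protein_total=250.0,
        ratios=_FIG1_LADDER,
    ),
    "S5": dict(
        model="two_site_independent",
        truth=TwoSiteIndependentParams(kd1=40.9, kd2=900.8),
        protein_total=250.0,
        ratios=_FIG1_LADDER + (18.0, 24.0, 36.0),
    ),
    "S9": dict(
        model="two_site_independent",
        truth=TwoSiteIndependentParams(kd1=28.4, kd2=515.9),
        protein_total=250.0,
        ratios=_FIG1_LADDER + (18.0, 24.0, 36.0),
    ),
    "S10": dict(
        model="two_site_independent",
        truth=TwoSiteIndependentParams(kd1=483.1, kd2=579.2),
        protein_total=250.0,
        ratios=_FIG1_LADDER + (18.0, 24.0),
    ),
    "EGFR": dict(
        model="single_site",
        truth=SingleSiteParams(kd=4.2),
        protein_total=200.0,
        ratios=(0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
    ),
}


def preset_design(name: str, seed: int | None = None, **overrides) -> SimulationDesign:
    """Design for a named experimental preset (S4, S5, S9, S10, EGFR)."""
    try:
        base = PRESETS[name]
    except KeyError as exc:
        raise InvalidInputError(
            f"unknown preset: {name!r}; known presets: {', '.join(PRESETS)}"
        ) from exc
    return SimulationDesign(name=name, seed=seed, **{**base, **overrides})


def _draw_responses(design: SimulationDesign, rng: np.random.Generator):
    """Per-residue (role, saturation amplitudes) for the design's truth model."""
    ens = design.ensemble
    two_site = design.model in ("two_site_independent", "two_site_cooperative")
    two_state = design.model in ("conformational_selection", "induced_fit")
    out = []
    roles = (
        ["site1"] * ens.n_site1 + ["site2"] * ens.n_site2 + ["mixed"] * ens.n_mixed
        + ["null"] * ens.n_null
    )
    for role in roles:
        lo, hi = ens.mixed_amp_range if role == "mixed" else ens.amp_range
        if role == "null":
            a1 = a2 = 0.0
        elif two_site:
            a1 = rng.uniform(lo, hi) if role in ("site1", "mixed") else 0.0
            a2 = rng.uniform(lo, hi) if role in ("site2", "mixed") else 0.0
        else:
            a1, a2 = rng.uniform(lo, hi), 0.0
        if two_site:
            resp = ResidueResponse(delta_lp=a1, delta_pl=a2)
        elif two_state:
            resp = ResidueResponse(delta_open=0.0, delta_close=a1)
        else:
            resp = ResidueResponse(delta_max=a1)
        out.append((role, resp))
    return out


def simulate_titration(design: SimulationDesign, seed: int | None = None) -> TitrationSeries:
    """Generate a reproducible synthetic :class:`TitrationSeries`.

    ``seed`` overrides ``design.seed``.  With zero noise the Δδ_ave curves of
    the output are exactly the model-predicted curves.
    """
    rng_seed = seed if seed is not None else design.seed
    rng = np.random.default_rng(rng_seed)
    schedule = design.schedule
    responses = _draw_responses(design, rng)
    records = []
    roles = {}
    for idx, (role, resp) in enumerate(responses):
        rid = idx + 1
        roles[rid] = role
        name = _AA_CYCLE[idx % len(_AA_CYCLE)]
        ref_h = rng.uniform(7.0, 9.5)
        ref_n = rng.uniform(105.0, 130.0)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        curve = predict_csp(design.model, design.truth, resp, schedule)
        h = ref_h + np.cos(phi) * curve
        n = ref_n + 5.0 * np.sin(phi) * curve
        # scale=0 contributes exactly 0 while keeping the draw order fixed,
        # so the noiseless dataset shares reference shifts with its noisy twin
        h = h + rng.normal(0.0, design.sigma_h, size=h.shape)
        n = n + rng.normal(0.0, design.sigma_n, size=n.shape)
        for k in range(schedule.n_points):
            records.append(
                ShiftRecord(
                    residue_id=rid,
                    residue_name=name,
                    point_index=k,
                    h_shift=float(h[k]),
                    n_shift=float(n[k]),
                )
            )
    metadata = {
        "design": design.to_dict(),
        "seed": rng_seed,
        "roles": roles,
        "ligand": design.name,
    }
    return TitrationSeries(schedule=schedule, records=tuple(records), metadata=metadata)
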