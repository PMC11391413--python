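"""Global and residue-specific least-squares fitting of CSP titration curves.

The observed data are per-residue Δδ_ave curves; the model for residue r at
titration point t is

    Δδ_model(r, t) = B(K; t) · a_r

where B is the population-fraction basis of the chosen binding model
(computed from the exact ligand-depletion equilibria in :mod:`cspfit.models`),
K the thermodynamic parameters shared across residues (K_Ds, α or K_f) and
a_r the residue's saturation amplitudes.  The objective is the plain
(unweighted) residual sum of squares over all residues and points.

Because the model is linear in the amplitudes, they are profiled out by an
inner linear least-squares solve (variable projection, optionally
non-negative), and only the shared parameters are optimised — in log10
space, which enforces positivity without active bounds and stabilises
constants spanning several decades.  The outer optimisation is
Levenberg–Marquardt (scipy ``least_squares``, method="lm") started from the
best point of a coarse log-space grid plus a half-saturation heuristic.

Parameter uncertainty uses the residual bootstrap: residuals of the
converged fit are resampled with replacement onto the fitted values and the
model is refit per replicate; confidence bounds are order statistics of the
replicate distribution (for 1000 replicates at 95% coverage, the 25th and
975th smallest values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, lsq_linear, nnls

from ._exceptions import (
    ComparisonError,
    InvalidInputError,
    NumericalError,
    UnderdeterminedError,
)
from .csp import ConcentrationSchedule, CSPProfile
from .models import AMP_NAMES, MODEL_NAMES, SHARED_NAMES, _PARAM_CLS, response_basis

__all__ = [
    "FitSpec",
    "FitResult",
    "BootstrapSummary",
    "ModelComparison",
    "fit",
    "bootstrap",
    "compare_models",
    "residue_kd_map",
    "percentile_ranks",
]

_TWO_SITE_MODELS = ("two_site_independent", "two_site_cooperative")


@dataclass(frozen=True)
class FitSpec:
    """Configuration of one fit."""

    model: str = "two_site_independent"
    scope: str = "global"  # "global" or "residue_specific"
    residues: tuple[int, ...] | None = None  # default: selected residues
    # Amplitudes are unconstrained by default: constraining them to be
    # non-negative truncates noise asymmetrically for residues with a null
    # response on one site, which biases the shared constants (site-1 K_D
    # systematically low).  Set True to enforce physical non-negativity when
    # amplitudes themselves are of interest.
    nonneg_amplitudes: bool = False
    # Physical cap on |amplitude|: amide-proton composite CSPs are far below
    # 1 ppm at saturation, so 5 ppm excludes only degenerate solutions where
    # two nearly collinear occupancy curves cancel with huge +/- amplitudes.
    amp_bound: float = 5.0
    log_kd_bounds: tuple[float, float] = (-1.0, 5.0)  # log10 μM grid for starts
    log_aux_bounds: tuple[float, float] = (-2.0, 2.0)  # log10 grid for α / K_f
    grid_points: int = 13
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 5000
    seed: int | None = None

    def __post_init__(self):
        if self.model not in MODEL_NAMES:
            raise InvalidInputError(f"unknown model: {self.model!r}")
        if self.scope not in ("global", "residue_specific"):
            raise InvalidInputError(f"unknown scope: {self.scope!r}")
        for tol in (self.ftol, self.xtol, self.gtol):
            if not tol > 0:
                raise InvalidInputError("tolerances must be > 0")


@dataclass(frozen=True)
class FitResult:
    """Converged fit: shared parameters, per-residue amplitudes, residuals."""

    model: str
    scope: str
    params: dict[str, float]
    amplitudes: pd.DataFrame  # index residue_id, columns amplitude names
    residue_ids: tuple[int, ...]
    residuals: np.ndarray  # stacked over residues (residue-major), observed points only
    rss: float
    residual_sd: float
    n_obs: int
    n_params: int
    success: bool
    message: str
    nfev: int
    log_params: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)  # (n_res, n_points), NaN = unobserved
    fitted: np.ndarray = field(repr=False)  # same shape, NaN where unobserved
    schedule: ConcentrationSchedule = field(repr=False, default=None)
    spec: FitSpec = field(repr=False, default=None)

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_params

    def params_object(self):
        cls = _PARAM_CLS[self.model]
        return cls(**{k: self.params[k] for k in SHARED_NAMES[self.model]})

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "scope": self.scope,
            "params": self.params,
            "amplitudes": {
                str(i): {c: float(self.amplitudes.loc[i, c]) for c in self.amplitudes.columns}
                for i in self.amplitudes.index
            },
            "rss": self.rss,
            "residual_sd": self.residual_sd,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "success": self.success,
            "nfev": self.nfev,
        }


@dataclass(frozen=True)
class BootstrapSummary:
    """Residual-bootstrap replicate distribution and percentile intervals."""

    n_replicates: int
    n_failed: int
    coverage: float
    seed: int | None
    ranks: tuple[int, int]  # 1-based order statistics used for the bounds
    replicates: pd.DataFrame  # columns: shared params + rss + residual_sd
    intervals: dict[str, tuple[float, float]]
    status: str  # "ok" or "warning" (>5% replicate failures)


@dataclass(frozen=True)
class ModelComparison:
    """Side-by-side fit statistics and an advisory verdict per model."""

    table: pd.DataFrame
    verdicts: dict[str, str]  # model -> "preferred" | "indistinguishable"
    coverage: float


def percentile_ranks(n: int, coverage: float) -> tuple[int, int]:
    """1-based order-statistic ranks of the percentile bootstrap interval.

    For n=1000, coverage=0.95 this is (25, 975): the 25th and 975th smallest
    replicate values bound the 95% interval.
    """
    if not 0 < coverage < 1:
        raise InvalidInputError("coverage must be in (0, 1)")
    lo = int(round(n * (1.0 - coverage) / 2.0))
    hi = int(round(n * (1.0 + coverage) / 2.0))
    return max(lo, 1), min(hi, n)


# --- internal machinery -----------------------------------------------------


def _make_params(model: str, x: np.ndarray):
    cls = _PARAM_CLS[model]
    names = SHARED_NAMES[model]
    # LM probe steps may wander far in log space; clip to a huge but finite
    # range so exponentiation never overflows (1e-15..1e15 μM covers any
    # physically meaningful constant by many orders of magnitude)
    x = np.clip(x, -15.0, 15.0)
    return cls(**{k: 10.0 ** xi for k, xi in zip(names, x)})


def _solve_amplitudes(
    B: np.ndarray, Y: np.ndarray, masks: np.ndarray, nonneg: bool, bound: float = 5.0
):
    """Profiled amplitudes A (n_res, k) minimising ||B a_r − y_r|| per residue.

    Amplitudes are kept inside [lo, bound] with lo = 0 (nonneg) or −bound;
    the box is only binding for degenerate bases (nearly collinear columns),
    where unconstrained least squares would cancel huge +/- amplitudes.
    """
    n_res = Y.shape[0]
    k = B.shape[1]
    lo = 0.0 if nonneg else -bound
    A = np.zeros((n_res, k))

    def _boxed(Bm, ym):
        res = lsq_linear(Bm, ym, bounds=(lo, bound), method="bvls")
        return res.x

    if masks.all():
        sol, *_ = np.linalg.lstsq(B, Y.T, rcond=None)
        A = sol.T
        viol = (A < lo - 1e-14).any(axis=1) | (A > bound + 1e-14).any(axis=1)
        for r in np.where(viol)[0]:
            A[r] = nnls(B, Y[r])[0] if nonneg else _boxed(B, Y[r])
            np.clip(A[r], lo, bound, out=A[r])
        if nonneg:
            np.clip(A, 0.0, None, out=A)
    else:
        for r in range(n_res):
            m = masks[r]
            if not m.any():
                continue
            Bm, ym = B[m], Y[r, m]
            if nonneg:
                a, _ = nnls(Bm, ym)
            else:
                a, *_ = np.linalg.lstsq(Bm, ym, rcond=None)
                if (a < lo).any() or (a > bound).any():
                    a = _boxed(Bm, ym)
            A[r] = np.clip(a, lo, bound)
    return A


def _pack_observations(
    profile: CSPProfile, residue_ids: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Observation matrix Y (n_res, n_points−1) for points ≥ 1, and finite mask."""
    Y = profile.csp_matrix(residue_ids)[:, 1:]
    masks = np.isfinite(Y)
    return np.where(masks, Y, 0.0), masks


class _Objective:
    """Reduced (variable-projection) residual function over log10 shared params."""

    def __init__(self, model, schedule, Y, masks, nonneg, amp_bound=5.0):
        self.model = model
        self.schedule = schedule
        self.Y = Y
        self.masks = masks
        self.nonneg = nonneg
        self.amp_bound = amp_bound
        self.flat = masks.ravel()

    def basis(self, x: np.ndarray) -> np.ndarray:
        params = _make_params(self.model, x)
        return response_basis(self.model, params, self.schedule)[1:, :]

    def residuals(self, x: np.ndarray) -> np.ndarray:
        B = self.basis(x)
        A = _solve_amplitudes(B, self.Y, self.masks, self.nonneg, self.amp_bound)
        R = A @ B.T - self.Y
        return R.ravel()[self.flat]

    def rss(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        return float(r @ r)


def _grid_starts(spec: FitSpec, obj: _Objective, schedule) -> list[np.ndarray]:
    lo, hi = spec.log_kd_bounds
    kd_grid = np.linspace(lo, hi, spec.grid_points)
    alo, ahi = spec.log_aux_bounds
    aux_grid = np.linspace(alo, ahi, 5)
    model = spec.model
    starts: list[np.ndarray] = []
    if model == "single_site":
        starts = [np.array([k]) for k in kd_grid]
    elif model in _TWO_SITE_MODELS:
        pairs = [
            (k1, k2) for i, k1 in enumerate(kd_grid) for k2 in kd_grid[i:]
        ]
        if model == "two_site_independent":
            starts = [np.array(p) for p in pairs]
        else:
            starts = [np.array([k1, k2, a]) for k1, k2 in pairs for a in aux_grid]
    else:  # two-state exchange models
        starts = [np.array([k, a]) for k in kd_grid for a in aux_grid]
    starts.append(_heuristic_start(spec, obj, schedule))
    return starts


def _heuristic_start(spec: FitSpec, obj: _Objective, schedule) -> np.ndarray:
    """K_D guess at the ligand concentration of half-maximal mean CSP."""
    ligand = schedule.ligand_totals[1:]
    with np.errstate(invalid="ignore"):
        mean_curve = np.where(
            obj.masks.any(axis=0),
            np.nansum(np.where(obj.masks, obj.Y, np.nan), axis=0)
            / np.maximum(obj.masks.sum(axis=0), 1),
            0.0,
        )
    top = mean_curve.max() if mean_curve.size else 0.0
    half = 0.5 * top
    idx = np.argmax(mean_curve >= half) if top > 0 else 0
    kd_half = max(ligand[idx], 1e-3)
    lg = float(np.log10(kd_half))
    model = spec.model
    if model == "single_site":
        return np.array([lg])
    if model == "two_site_independent":
        return np.array([lg, lg + 1.0])
    if model == "two_site_cooperative":
        return np.array([lg, lg + 1.0, 0.0])
    return np.array([lg, 0.0])


def _canonicalize(model: str, x: np.ndarray, A: np.ndarray):
    """Resolve the kd1↔kd2 relabelling symmetry: enforce kd1 ≤ kd2."""
    if model in _TWO_SITE_MODELS and x[0] > x[1]:
        x = x.copy()
        x[0], x[1] = x[1], x[0]
        A = A[:, ::-1]
    return x, A


def _fit_arrays(
    Y: np.ndarray,
    masks: np.ndarray,
    schedule: ConcentrationSchedule,
    spec: FitSpec,
    residue_ids: Sequence[int],
    x0: np.ndarray | None = None,
) -> FitResult:
    obj = _Objective(spec.model, schedule, Y, masks, spec.nonneg_amplitudes, spec.amp_bound)
    n_obs = int(masks.sum())
    n_shared = len(SHARED_NAMES[spec.model])
    n_amp = len(AMP_NAMES[spec.model])
    n_params = n_shared + n_amp * len(residue_ids)
    if n_obs < n_params:
        raise UnderdeterminedError(
            f"{n_obs} observations for {n_params} parameters "
            f"({spec.model}, {len(residue_ids)} residues)"
        )
    if x0 is None:
        starts = _grid_starts(spec, obj, schedule)
        x0 = min(starts, key=obj.rss)
    res = least_squares(
        obj.residuals,
        x0,
        method="lm",
        ftol=spec.ftol,
        xtol=spec.xtol,
        gtol=spec.gtol,
        max_nfev=spec.max_nfev,
    )
    if not res.success:
        raise NumericalError(
            f"fit did not converge ({spec.model}): {res.message}; "
            f"best RSS {float(res.fun @ res.fun):.3e} at log10 params {res.x}"
        )
    B = obj.basis(res.x)
    A = _solve_amplitudes(B, Y, masks, spec.nonneg_amplitudes, spec.amp_bound)
    x, A = _canonicalize(spec.model, np.clip(res.x, -15.0, 15.0), A)
    B = obj.basis(x)
    fitted = A @ B.T
    R = fitted - Y
    residuals = R.ravel()[obj.flat]
    rss = float(residuals @ residuals)
    dof = max(n_obs - n_params, 1)
    n_pts = schedule.n_points
    obs_full = np.full((len(residue_ids), n_pts), np.nan)
    fit_full = np.full((len(residue_ids), n_pts), np.nan)
    obs_full[:, 1:] = np.where(masks, Y, np.nan)
    fit_full[:, 1:] = np.where(masks, fitted, np.nan)
    names = SHARED_NAMES[spec.model]
    return FitResult(
        model=spec.model,
        scope=spec.scope,
        params={k: float(10.0 ** xi) for k, xi in zip(names, x)},
        amplitudes=pd.DataFrame(A, index=list(residue_ids), columns=list(AMP_NAMES[spec.model])),
        residue_ids=tuple(residue_ids),
        residuals=residuals,
        rss=rss,
        residual_sd=float(np.sqrt(rss / dof)),
        n_obs=n_obs,
        n_params=n_params,
        success=bool(res.success),
        message=str(res.message),
        nfev=int(res.nfev),
        log_params=x,
        observed=obs_full,
        fitted=fit_full,
        schedule=schedule,
        spec=spec,
    )


# --- public operations ------------------------------------------------------


def fit(profile: CSPProfile, schedule: ConcentrationSchedule, spec: FitSpec):
    """Fit the binding model to the selected residues of a CSP profile.

    scope="global": one :class:`FitResult` with thermodynamic parameters
    shared across residues.  scope="residue_specific": an independent fit per
    residue, returned as ``dict[residue_id, FitResult]``.
    """
    if schedule.n_points != profile.schedule.n_points:
        raise InvalidInputError("schedule length does not match the profile")
    residue_ids = list(spec.residues) if spec.residues else profile.selected_ids
    if not residue_ids:
        raise InvalidInputError("no residues selected for fitting")
    missing = [r for r in residue_ids if r not in profile.residue_ids]
    if missing:
        raise InvalidInputError(f"residues not in profile: {missing}")
    if spec.scope == "residue_specific":
        out = {}
        for rid in residue_ids:
            sub = replace(spec, residues=(rid,), scope="residue_specific")
            Y, masks = _pack_observations(profile, [rid])
            out[rid] = _fit_arrays(Y, masks, schedule, sub, [rid])
        return out
    Y, masks = _pack_observations(profile, residue_ids)
    return _fit_arrays(Y, masks, schedule, spec, residue_ids)


def bootstrap(
    fit_result: FitResult,
    spec: FitSpec | None = None,
    n: int = 1000,
    coverage: float = 0.95,
    seed: int | None = None,
    resample: str = "pooled",
) -> BootstrapSummary:
    """Residual-bootstrap confidence intervals for the shared parameters.

    Residuals of the converged fit are resampled with replacement, added to
    the fitted values, and the model is refit per replicate (warm-started
    from the point estimate).  Bounds are the order statistics given by
    :func:`percentile_ranks` — the 25th and 975th smallest replicate values
    for n=1000 at 95% coverage.
    """
    if spec is None:
        spec = fit_result.spec
    if resample not in ("pooled", "per_curve"):
        raise InvalidInputError(f"unknown resampling scheme: {resample!r}")
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    schedule = fit_result.schedule
    residue_ids = fit_result.residue_ids
    fitted = fit_result.fitted[:, 1:]
    masks = np.isfinite(fitted)
    fitted0 = np.where(masks, fitted, 0.0)
    resid = fit_result.residuals
    # residual positions per residue for per-curve resampling
    counts = masks.sum(axis=1)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    names = list(SHARED_NAMES[fit_result.model])
    rows = []
    n_failed = 0
    for _ in range(n):
        if resample == "pooled":
            draw = rng.choice(resid, size=resid.size, replace=True)
        else:
            draw = np.concatenate(
                [
                    rng.choice(resid[offsets[i]:offsets[i + 1]], size=counts[i], replace=True)
                    if counts[i]
                    else np.empty(0)
                    for i in range(len(residue_ids))
                ]
            )
        Ystar = fitted0.copy()
        Ystar[masks] = fitted0[masks] + draw
        try:
            rep = _fit_arrays(
                Ystar, masks, schedule, spec, residue_ids, x0=fit_result.log_params
            )
        except (NumericalError, UnderdeterminedError):
            n_failed += 1
            continue
        rows.append(
            {**{k: rep.params[k] for k in names}, "rss": rep.rss, "residual_sd": rep.residual_sd}
        )
    reps = pd.DataFrame(rows, columns=names + ["rss", "residual_sd"])
    n_ok = len(reps)
    if n_ok == 0:
        raise NumericalError("all bootstrap replicates failed to refit")
    ranks = percentile_ranks(n_ok, coverage)
    intervals = {}
    for k in names + ["residual_sd"]:
        srt = np.sort(reps[k].to_numpy())
        intervals[k] = (float(srt[ranks[0] - 1]), float(srt[ranks[1] - 1]))
    return BootstrapSummary(
        n_replicates=n_ok,
        n_failed=n_failed,
        coverage=coverage,
        seed=seed,
        ranks=ranks,
        replicates=reps,
        intervals=intervals,
        status="warning" if n_failed > 0.05 * n else "ok",
    )


def _same_observations(a: FitResult, b: FitResult) -> bool:
    if a.residue_ids != b.residue_ids:
        return False
    oa, ob = a.observed, b.observed
    return oa.shape == ob.shape and np.allclose(oa, ob, equal_nan=True)


def compare_models(
    fits: Sequence[tuple[FitResult, BootstrapSummary | None]],
    coverage: float = 0.95,
) -> ModelComparison:
    """Compare models fit to the same observations.

    Models whose residual-SD bootstrap intervals overlap the best model's are
    marked indistinguishable; among those, the advisory "preferred" verdict
    goes to the most parsimonious (fewest parameters, then lowest RSS).
    Models without overlap and with higher residual SD receive no verdict
    flag beyond their recorded statistics.
    """
    if len(fits) < 1:
        raise InvalidInputError("nothing to compare")
    ref = fits[0][0]
    for fr, _ in fits[1:]:
        if not _same_observations(ref, fr):
            raise ComparisonError("fits were made on different observation sets")
    rows = []
    for fr, bs in fits:
        row = {
            "model": fr.model,
            "rss": fr.rss,
            "residual_sd": fr.residual_sd,
            "n_params": fr.n_params,
        }
        if bs is not None:
            ranks = percentile_ranks(bs.n_replicates, coverage)
            srt = np.sort(bs.replicates["residual_sd"].to_numpy())
            row["sd_ci_lower"], row["sd_ci_upper"] = (
                float(srt[ranks[0] - 1]),
                float(srt[ranks[1] - 1]),
            )
            for k in SHARED_NAMES[fr.model]:
                row[f"{k}_sd"] = float(bs.replicates[k].std(ddof=1)) if bs.n_replicates > 1 else 0.0
        else:
            row["sd_ci_lower"] = row["sd_ci_upper"] = float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    best = table.loc[table["residual_sd"].idxmin()]
    overlaps = []
    for _, row in table.iterrows():
        lo, hi = row["sd_ci_lower"], row["sd_ci_upper"]
        blo, bhi = best["sd_ci_lower"], best["sd_ci_upper"]
        if np.isnan(lo) or np.isnan(blo):
            overlap = bool(np.isclose(row["residual_sd"], best["residual_sd"], rtol=1e-9))
        else:
            overlap = bool((lo <= bhi) and (blo <= hi))
        overlaps.append(overlap)
    sub = table[overlaps]
    pref_idx = sub.sort_values(["n_params", "rss"]).index[0]
    table["verdict"] = [
        ("preferred" if i == pref_idx else "indistinguishable" if ov else "")
        for i, ov in zip(table.index, overlaps)
    ]
    verdicts = {
        row["model"]: row["verdict"] for _, row in table.iterrows() if row["verdict"]
    }
    return ModelComparison(table=table, verdicts=verdicts, coverage=coverage)


def residue_kd_map(
    residue_fits: Mapping[int, FitResult],
    bootstraps: Mapping[int, BootstrapSummary] | None = None,
    all_residues: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Tabulate residue-specific dissociation constants for structure mapping.

    One row per residue: the primary K_D (first thermodynamic parameter of
    the residue's fit) with percentile CI when a bootstrap is supplied.
    Residues listed in ``all_residues`` but not fitted (excluded by the
    selection rule) carry null entries.
    """
    bootstraps = bootstraps or {}
    ids = list(all_residues) if all_residues is not None else sorted(residue_fits)
    rows = []
    for rid in ids:
        fr = residue_fits.get(rid)
        if fr is None:
            rows.append({"residue_id": rid, "kd": np.nan, "ci_lower": np.nan, "ci_upper": np.nan})
            continue
        kd_name = SHARED_NAMES[fr.model][0]
        bs = bootstraps.get(rid)
        lo, hi = bs.intervals[kd_name] if bs is not None else (np.nan, np.nan)
        rows.append(
            {"residue_id": rid, "kd": fr.params[kd_name], "ci_lower": lo, "ci_upper": hi}
        )
    return pd.DataFrame(rows, columns=["residue_id", "kd", "ci_lower", "ci_upper"])
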