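"""Chemical-shift perturbation (CSP) computation and residue selection.

A backbone-amide titration series records, per residue and titration point,
the ¹H and ¹⁵N chemical shifts of the ¹H–¹⁵N correlation cross-peak.  In the
fast-exchange regime the peak moves continuously as ligand is added, and the
composite perturbation relative to the ligand-free reference spectrum,

    Δδ_ave = sqrt( (Δδ¹H)² + (Δδ¹⁵N / 5)² )   [ppm],

is the observable fitted by the binding models.  The 1/5 factor compensates
for the wider dispersion of the ¹⁵N dimension.

Residues are selected for global fitting when their maximum CSP across the
titration exceeds a threshold (default 0.03 ppm, strictly); prolines (no
amide proton), overlap-excluded and missing residues are carried with an
exclusion reason rather than dropped, so reports stay complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InvalidInputError

__all__ = [
    "Nucleus",
    "ShiftRecord",
    "ConcentrationSchedule",
    "TitrationSeries",
    "ResidueProfile",
    "CSPProfile",
    "compute_csp",
    "build_csp_profile",
    "select_residues",
    "ppm_to_hz",
    "DEFAULT_CSP_THRESHOLD",
]

#: Selection threshold on the maximum CSP (ppm); residues strictly above pass.
DEFAULT_CSP_THRESHOLD = 0.03

_PROLINE_NAMES = {"PRO", "P"}

#: Exclusion reasons carried in profiles. "below-threshold" is recomputed on
#: every selection pass; the others are sticky properties of the data.
EXCLUSION_REASONS = ("none", "proline", "overlap", "missing", "below-threshold")
_STICKY_REASONS = {"proline", "overlap", "missing"}


class Nucleus(str, Enum):
    """Supported nuclei for ppm → Hz conversion."""

    H1 = "H1"
    N15 = "N15"


#: Spectrometer ¹H frequency context: 1 ppm in Hz for each nucleus.
HZ_PER_PPM: Mapping[Nucleus, float] = {Nucleus.H1: 600.13, Nucleus.N15: 60.81}


def compute_csp(delta_h, delta_n):
    """Composite CSP Δδ_ave = sqrt(Δδ¹H² + (Δδ¹⁵N/5)²) in ppm.

    Accepts scalars or arrays; symmetric in the sign of either input.
    Raises :class:`InvalidInputError` on non-finite input.
    """
    dh = np.asarray(delta_h, dtype=float)
    dn = np.asarray(delta_n, dtype=float)
    if not (np.all(np.isfinite(dh)) and np.all(np.isfinite(dn))):
        raise InvalidInputError("compute_csp requires finite shift differences")
    out = np.hypot(dh, dn / 5.0)
    if out.ndim == 0:
        return float(out)
    return out


def ppm_to_hz(delta: float, nucleus: Nucleus | str) -> float:
    """Convert a shift difference from ppm to Hz for the given nucleus."""
    try:
        nuc = Nucleus(nucleus)
    except ValueError as exc:
        raise InvalidInputError(f"unknown nucleus: {nucleus!r}") from exc
    return float(delta) * HZ_PER_PPM[nuc]


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned amide cross-peak at one titration point."""

    residue_id: int
    residue_name: str
    point_index: int
    h_shift: float  # ppm
    n_shift: float  # ppm

    def __post_init__(self):
        if not (math.isfinite(self.h_shift) and math.isfinite(self.n_shift)):
            raise InvalidInputError(
                f"non-finite shift for residue {self.residue_id} "
                f"at point {self.point_index}"
            )
        if self.point_index < 0:
            raise InvalidInputError("point_index must be >= 0")


@dataclass(frozen=True)
class ConcentrationSchedule:
    """Ordered (protein_total, ligand_total) pairs, μM, one per titration point.

    Point 0 is the ligand-free reference spectrum.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        pts = tuple((float(p), float(l)) for p, l in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) == 0:
            raise InvalidInputError("schedule must contain at least one point")
        if pts[0][1] != 0.0:
            raise InvalidInputError("point 0 must have ligand_total = 0 (reference)")
        lig = [l for _, l in pts]
        for p, l in pts:
            if p <= 0:
                raise InvalidInputError("protein_total must be > 0 at every point")
            if l < 0:
                raise InvalidInputError("ligand_total must be >= 0")
        if any(b < a for a, b in zip(lig, lig[1:])):
            raise InvalidInputError("ligand_total must be non-decreasing")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def protein_totals(self) -> np.ndarray:
        return np.array([p for p, _ in self.points])

    @property
    def ligand_totals(self) -> np.ndarray:
        return np.array([l for _, l in self.points])

    @property
    def molar_ratios(self) -> np.ndarray:
        return self.ligand_totals / self.protein_totals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "point_index": np.arange(self.n_points),
                "protein_total_uM": self.protein_totals,
                "ligand_total_uM": self.ligand_totals,
            }
        )


@dataclass(frozen=True)
class TitrationSeries:
    """A titration dataset: schedule, shift records and free-form metadata."""

    schedule: ConcentrationSchedule
    records: tuple[ShiftRecord, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        recs = tuple(self.records)
        object.__setattr__(self, "records", recs)
        seen = set()
        for r in recs:
            if r.point_index >= self.schedule.n_points:
                raise InvalidInputError(
                    f"record for residue {r.residue_id} has point_index "
                    f"{r.point_index} outside the schedule"
                )
            key = (r.residue_id, r.point_index)
            if key in seen:
                raise InvalidInputError(
                    f"duplicate record for residue {r.residue_id}, point {r.point_index}"
                )
            seen.add(key)

    @property
    def residue_ids(self) -> list[int]:
        return sorted({r.residue_id for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "residue_id": [r.residue_id for r in self.records],
                "residue_name": [r.residue_name for r in self.records],
                "point_index": [r.point_index for r in self.records],
                "h_shift_ppm": [r.h_shift for r in self.records],
                "n_shift_ppm": [r.n_shift for r in self.records],
            }
        )
        return df.sort_values(["residue_id", "point_index"], ignore_index=True)


@dataclass(frozen=True)
class ResidueProfile:
    """Per-residue CSP curve relative to point 0; NaN marks missing points."""

    residue_id: int
    residue_name: str
    csp: np.ndarray  # ppm, length n_points, NaN where the peak was not observed
    excluded_reason: str = "none"
    selected: bool = False

    @property
    def max_csp(self) -> float:
        vals = self.csp[np.isfinite(self.csp)]
        return float(vals.max()) if vals.size else float("nan")


@dataclass(frozen=True)
class CSPProfile:
    """CSP curves for every residue of a series, plus selection state."""

    schedule: ConcentrationSchedule
    residues: tuple[ResidueProfile, ...]
    threshold: float | None = None  # last selection threshold applied, ppm

    @property
    def residue_ids(self) -> list[int]:
        return [r.residue_id for r in self.residues]

    @property
    def selected_ids(self) -> list[int]:
        return [r.residue_id for r in self.residues if r.selected]

    def __getitem__(self, residue_id: int) -> ResidueProfile:
        for r in self.residues:
            if r.residue_id == residue_id:
                return r
        raise KeyError(residue_id)

    def csp_matrix(self, residue_ids: Sequence[int] | None = None) -> np.ndarray:
        """(n_residues, n_points) CSP matrix, NaN for missing observations."""
        ids = list(residue_ids) if residue_ids is not None else self.residue_ids
        return np.vstack([self[i].csp for i in ids])

    def to_frame(self) -> pd.DataFrame:
        n = self.schedule.n_points
        rows = []
        for r in self.residues:
            row = {"residue_id": r.residue_id, "residue_name": r.residue_name}
            row.update({f"csp_point_{k}": r.csp[k] for k in range(n)})
            row["max_csp"] = r.max_csp
            row["selected"] = r.selected
            row["excluded_reason"] = r.excluded_reason
            rows.append(row)
        return pd.DataFrame(rows)


def build_csp_profile(
    series: TitrationSeries,
    exclude: Mapping[int, str] | None = None,
) -> CSPProfile:
    """Compute per-residue CSP curves relative to the point-0 reference.

    ``exclude`` maps residue ids to a sticky exclusion reason (e.g. "overlap")
    applied on top of automatic proline / missing-reference detection.
    Residues without a point-0 record are flagged ``missing``, never dropped.
    """
    exclude = dict(exclude or {})
    for rid, reason in exclude.items():
        if reason not in _STICKY_REASONS:
            raise InvalidInputError(
                f"exclusion reason for residue {rid} must be one of {sorted(_STICKY_REASONS)}"
            )
    n = series.schedule.n_points
    by_residue: dict[int, dict[int, ShiftRecord]] = {}
    names: dict[int, str] = {}
    for rec in series.records:
        by_residue.setdefault(rec.residue_id, {})[rec.point_index] = rec
        names[rec.residue_id] = rec.residue_name

    profiles = []
    for rid in sorted(by_residue):
        pts = by_residue[rid]
        name = names[rid]
        csp = np.full(n, np.nan)
        if 0 not in pts:
            reason = "missing"
        else:
            ref = pts[0]
            for k, rec in pts.items():
                csp[k] = compute_csp(rec.h_shift - ref.h_shift, rec.n_shift - ref.n_shift)
            csp[0] = 0.0  # exact by definition
            if name.upper() in _PROLINE_NAMES:
                reason = "proline"
            else:
                reason = exclude.get(rid, "none")
        profiles.append(
            ResidueProfile(residue_id=rid, residue_name=name, csp=csp, excluded_reason=reason)
        )
    return CSPProfile(schedule=series.schedule, residues=tuple(profiles))


def select_residues(
    profile: CSPProfile, threshold: float = DEFAULT_CSP_THRESHOLD
) -> CSPProfile:
    """Flag residues whose maximum CSP strictly exceeds ``threshold`` (ppm).

    Sticky exclusions (proline, overlap, missing) always disqualify.  The
    soft "below-threshold" reason is recomputed, so repeated application with
    the same threshold is idempotent and raising the threshold never adds
    residues.
    """
    if not threshold > 0:
        raise InvalidInputError("threshold must be > 0")
    out = []
    for r in profile.residues:
        sticky = r.excluded_reason if r.excluded_reason in _STICKY_REASONS else "none"
        if sticky != "none":
            out.append(replace(r, excluded_reason=sticky, selected=False))
            continue
        passes = np.isfinite(r.max_csp) and r.max_csp > threshold
        out.append(
            replace(
                r,
                excluded_reason="none" if passes else "below-threshold",
                selected=bool(passes),
            )
        )
    return CSPProfile(schedule=profile.schedule, residues=tuple(out), threshold=threshold)
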