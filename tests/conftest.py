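import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cspfit as c

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def s4_noiseless():
    """Noiseless S4-design synthetic titration plus its selected profile."""
    design = c.preset_design("S4", seed=42, sigma_h=0.0, sigma_n=0.0)
    series = c.simulate_titration(design)
    profile = c.select_residues(c.build_csp_profile(series))
    return design, series, profile


@pytest.fixture(scope="session")
def s4_noiseless_fit(s4_noiseless):
    design, series, profile = s4_noiseless
    spec = c.FitSpec(model="two_site_independent")
    return c.fit(profile, series.schedule, spec)


def make_series(curves, schedule, names=None):
    """Build a TitrationSeries from per-residue (h, n) shift curves.

    ``curves``: dict residue_id -> (h_array, n_array); NaN entries are
    omitted (missing peak at that point).
    """
    records = []
    for rid, (h, n) in curves.items():
        name = (names or {}).get(rid, "ALA")
        for k, (hh, nn) in enumerate(zip(h, n)):
            if np.isnan(hh) or np.isnan(nn):
                continue
            records.append(
                c.ShiftRecord(residue_id=rid, residue_name=name, point_index=k,
                              h_shift=float(hh), n_shift=float(nn))
            )
    return c.TitrationSeries(schedule=schedule, records=tuple(records))


@pytest.fixture
def simple_schedule():
    return c.ConcentrationSchedule(
        points=tuple((250.0, 250.0 * r) for r in (0.0, 0.25, 0.5, 1, 2, 4, 6, 8, 12))
    )
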