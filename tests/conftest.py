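"""Shared fixtures: single-site IPAP pairs and the three-site demo system."""

from __future__ import annotations

import numpy as np
import pytest

from ipapfesta.fixtures import fluticasone_f6_spec, fluticasone_grid, make_fixtures
from ipapfesta.ipap_core import IPAPPair
from ipapfesta.spin_model import (
    FrequencyGrid,
    ProtonSite,
    SpinSystemSpec,
    simulate_ipap_pair,
)


def make_single_site_pair(
    jhf: float,
    rho: float = 1.0,
    linewidth: float = 1.0,
    jhh: list[tuple[str, float]] | None = None,
    span: float = 30.0,
    step: float = 0.01,
    shift: float = 0.0,
) -> IPAPPair:
    """IP/AP pair for one proton site on a uniform grid of ``step`` Hz."""
    site = ProtonSite(
        label="A", shift=shift, amplitude=1.0, jhh=jhh or [], jhf=jhf, linewidth=linewidth
    )
    spec = SpinSystemSpec(protons=[site], members=["A"], relaxation_attenuation=rho)
    npoints = int(round(2 * span / step)) + 1
    grid = FrequencyGrid(start=shift - span, stop=shift + span, npoints=npoints)
    return simulate_ipap_pair(spec, grid)


def grid_search_displacement(
    sum_y: np.ndarray,
    diff_y: np.ndarray,
    freqs: np.ndarray,
    lo: float,
    hi: float,
    search: tuple[float, float],
    step: float = 0.01,
) -> float:
    """Independent exhaustive-grid oracle for the displacement fit.

    Shifts the difference subspectrum by linear interpolation and minimizes
    the in-region sum of squares over a dense delta grid — deliberately a
    different shifting method from the package's band-limited one.
    """
    mask = (freqs >= lo) & (freqs <= hi)
    target = sum_y[mask]
    f_region = freqs[mask]
    deltas = np.arange(search[0], search[1] + step / 2, step)
    best_delta, best_val = 0.0, np.inf
    for d in deltas:
        shifted = np.interp(f_region - d, freqs, diff_y)
        val = float(np.sum((target - shifted) ** 2))
        if val < best_val:
            best_val, best_delta = val, float(d)
    return best_delta


@pytest.fixture(scope="session")
def fluticasone_pair() -> IPAPPair:
    return simulate_ipap_pair(fluticasone_f6_spec(), fluticasone_grid())


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    make_fixtures(seed=7, out_dir=out)
    return out
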