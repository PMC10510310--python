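"""First-order simulation of in-phase / anti-phase ¹H multiplets.

This module is both the synthetic-data generator and the physics reference
for the rest of the package.  A proton site is split first by all of its
homonuclear (J_HH) couplings and then by its single heteronuclear (J_HF)
coupling into two ¹⁹F-spin-state components at ±J_HF/2.  In an in-phase (IP)
multiplet both components are positive; in an anti-phase (AP) multiplet the
component at −J_HF/2 is negated, which fixes the global sign convention
consumed by the displacement fit: the IP + kAP subspectrum carries the
component at +J_HF/2.

Lineshapes are analytic unit-area Lorentzians evaluated pointwise on the
frequency grid (no FID/FFT step), so simulated intensities are independent
of the grid and exactly integrable — a property the test suite relies on.
Only weak (first-order) coupling is modelled; strongly coupled multiplets
are a documented limitation of the displacement-based analysis itself.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Mode",
    "SpinClass",
    "ProtonSite",
    "SpinSystemSpec",
    "FrequencyGrid",
    "Spectrum1D",
    "simulate_multiplet",
    "simulate_spin_system",
    "simulate_ipap_pair",
    "add_noise",
    "compute_delta",
]

logger = logging.getLogger(__name__)

#: Default spectrometer ¹H frequency in MHz, used for Hz↔ppm presentation.
DEFAULT_SPECTROMETER_MHZ = 500.0


class Mode(str, Enum):
    """Phase structure of a multiplet with respect to the heteronuclear coupling."""

    IP = "IP"
    AP = "AP"


class SpinClass(str, Enum):
    """Multiplicity class of the selected ¹⁹F-coupled proton group (AnX, AnX2, AnX3)."""

    AnX = "AnX"
    AnX2 = "AnX2"
    AnX3 = "AnX3"


class ProtonSite(BaseModel):
    """One proton site of a simulated spin system.

    Parameters
    ----------
    label : str
        Site name, e.g. ``"H4a"`` (``a`` axial, ``b`` equatorial).
    shift : float
        Chemical shift in Hz relative to the carrier.
    amplitude : float
        Multiplet integral in arbitrary units; must be positive.
    jhh : list of (str, float)
        Homonuclear coupling partners as ``(partner_label, J_HH in Hz)``.
    jhf : float
        Signed heteronuclear ¹H–¹⁹F coupling in Hz.
    linewidth : float
        Lorentzian full width at half maximum in Hz; must be positive.
    """

    label: str
    shift: float
    amplitude: float = 1.0
    jhh: list[tuple[str, float]] = Field(default_factory=list)
    jhf: float = 0.0
    linewidth: float = 1.0

    @field_validator("shift", "jhf")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("shift and couplings must be finite")
        return v

    @field_validator("amplitude", "linewidth")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not math.isfinite(v) or v <= 0:
            raise ValueError("amplitude and linewidth must be finite and > 0")
        return v

    @field_validator("jhh")
    @classmethod
    def _finite_jhh(cls, v: list[tuple[str, float]]) -> list[tuple[str, float]]:
        if any(not math.isfinite(j) for _, j in v):
            raise ValueError("J_HH couplings must be finite")
        return v


class SpinSystemSpec(BaseModel):
    """A ¹⁹F-coupled spin system selected by the fluorine-edited experiment.

    Only protons listed in ``members`` belong to the spin system of
    ``fluorine_label`` and survive the spectral editing; everything else is
    assumed perfectly suppressed.  ``relaxation_attenuation`` (ρ) is the
    uniform factor by which AP amplitudes are attenuated relative to IP,
    modelling the faster transverse relaxation of anti-phase coherences.
    """

    fluorine_label: str = "F"
    protons: list[ProtonSite]
    members: list[str] = Field(default_factory=list)
    relaxation_attenuation: float = 1.0

    @field_validator("relaxation_attenuation")
    @classmethod
    def _rho_range(cls, v: float) -> float:
        if not (0.0 < v <= 1.0):
            raise ValueError("relaxation_attenuation must lie in (0, 1]")
        return v

    @model_validator(mode="after")
    def _check_members(self) -> "SpinSystemSpec":
        labels = {p.label for p in self.protons}
        if len(labels) != len(self.protons):
            raise ValueError("duplicate proton labels")
        missing = set(self.members) - labels
        if missing:
            raise ValueError(f"members not among proton labels: {sorted(missing)}")
        # J_HH symmetry when both partners are present
        jmap = {p.label: dict(p.jhh) for p in self.protons}
        for a, partners in jmap.items():
            for b, j in partners.items():
                if b in jmap and a in jmap[b] and not math.isclose(jmap[b][a], j):
                    raise ValueError(f"asymmetric J_HH between {a} and {b}")
        return self

    def member_sites(self) -> list[ProtonSite]:
        return [p for p in self.protons if p.label in self.members]


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform frequency axis: ``npoints`` samples from ``start`` to ``stop`` Hz."""

    start: float
    stop: float
    npoints: int

    def __post_init__(self) -> None:
        if self.npoints < 2:
            raise ValueError("npoints must be >= 2")
        if not (self.stop > self.start):
            raise ValueError("stop must exceed start")

    @property
    def step(self) -> float:
        return (self.stop - self.start) / (self.npoints - 1)

    def frequencies(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.npoints)


@dataclass
class Spectrum1D:
    """A sampled real 1D spectrum on a uniform frequency grid (Hz)."""

    grid: FrequencyGrid
    intensities: np.ndarray
    spectrometer_frequency: float = DEFAULT_SPECTROMETER_MHZ
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.grid.npoints,):
            raise ValueError("intensity array length must equal grid.npoints")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies()

    def ppm(self) -> np.ndarray:
        """Frequency axis in ppm (presentation only; storage stays in Hz)."""
        return self.frequencies / self.spectrometer_frequency

    def integral(self) -> float:
        return float(np.trapezoid(self.intensities, self.frequencies))

    def copy_with(self, intensities: np.ndarray) -> "Spectrum1D":
        return Spectrum1D(
            grid=self.grid,
            intensities=np.asarray(intensities, dtype=float),
            spectrometer_frequency=self.spectrometer_frequency,
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# stick-pattern synthesis


def _stick_pattern(site: ProtonSite, mode: Mode) -> tuple[np.ndarray, np.ndarray]:
    """First-order stick positions (Hz) and signed amplitudes for one site."""
    positions = np.array([site.shift])
    amps = np.array([site.amplitude])
    for _, j in site.jhh:
        positions = np.concatenate([positions - j / 2.0, positions + j / 2.0])
        amps = np.concatenate([amps / 2.0, amps / 2.0])
    # heteronuclear splitting into the two ¹⁹F spin-state components
    lo = positions - site.jhf / 2.0
    hi = positions + site.jhf / 2.0
    if mode is Mode.IP:
        positions = np.concatenate([hi, lo])
        amps = np.concatenate([amps / 2.0, amps / 2.0])
    else:  # AP: the −jhf/2 component is negated
        positions = np.concatenate([hi, lo])
        amps = np.concatenate([amps / 2.0, -amps / 2.0])
    return positions, amps


def _lorentzian_sum(
    freqs: np.ndarray, positions: np.ndarray, amps: np.ndarray, fwhm: float
) -> np.ndarray:
    """Sum of unit-area Lorentzians, scaled by ``amps``, evaluated at ``freqs``."""
    hwhm = fwhm / 2.0
    # (npoints, nsticks) evaluation; stick counts are tiny in practice
    d = freqs[:, None] - positions[None, :]
    shapes = (hwhm / math.pi) / (d * d + hwhm * hwhm)
    return shapes @ amps


def simulate_multiplet(site: ProtonSite, mode: Mode | str, grid: FrequencyGrid) -> Spectrum1D:
    """Simulate one first-order IP or AP multiplet on ``grid``.

    The IP spectrum integrates to ``site.amplitude``; the AP spectrum
    integrates to zero.  A warning is logged when the grid is too narrow to
    contain essentially all (99%) of the multiplet.
    """
    mode = Mode(mode)
    positions, amps = _stick_pattern(site, mode)
    # 99% of a Lorentzian's area lies within ~32 FWHM of its center
    span = 32.0 * site.linewidth
    if positions.min() - span < grid.start or positions.max() + span > grid.stop:
        logger.warning(
            "grid [%g, %g] Hz may clip multiplet %s (sticks %g..%g Hz)",
            grid.start, grid.stop, site.label, positions.min(), positions.max(),
        )
    y = _lorentzian_sum(grid.frequencies(), positions, amps, site.linewidth)
    return Spectrum1D(grid=grid, intensities=y, metadata={"mode": mode.value, "site": site.label})


def simulate_spin_system(
    spec: SpinSystemSpec, mode: Mode | str, grid: FrequencyGrid
) -> Spectrum1D:
    """Simulate the edited subspectrum of a whole spin system.

    Member protons are summed; non-members contribute nothing (suppression is
    assumed perfect).  AP intensities are attenuated by ρ.
    """
    mode = Mode(mode)
    sites = spec.member_sites()
    if not sites:
        warnings.warn("spin system has no member protons; returning zero spectrum")
        return Spectrum1D(grid=grid, intensities=np.zeros(grid.npoints), metadata={"mode": mode.value})
    total = np.zeros(grid.npoints)
    for site in sites:
        total += simulate_multiplet(site, mode, grid).intensities
    if mode is Mode.AP:
        total *= spec.relaxation_attenuation
    return Spectrum1D(
        grid=grid,
        intensities=total,
        metadata={"mode": mode.value, "fluorine": spec.fluorine_label},
    )


def simulate_ipap_pair(spec: SpinSystemSpec, grid: FrequencyGrid):
    """Simulate the matched IP / AP spectrum pair for a spin system.

    Returns an :class:`ipapfesta.ipap_core.IPAPPair` with the AP spectrum
    attenuated by ρ.  Deterministic: add noise separately with
    :func:`add_noise` if required.
    """
    from .ipap_core import IPAPPair  # local import to avoid a cycle

    ip = simulate_spin_system(spec, Mode.IP, grid)
    ap = simulate_spin_system(spec, Mode.AP, grid)
    return IPAPPair(ip=ip, ap=ap)


def add_noise(s: Spectrum1D, sigma: float, seed: int) -> Spectrum1D:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return s.copy_with(s.intensities)
    rng = np.random.default_rng(seed)
    return s.copy_with(s.intensities + rng.normal(0.0, sigma, s.grid.npoints))


def compute_delta(j_hf: float, spin_class: SpinClass | str) -> float:
    """Spin-echo evolution delay Δ in seconds matched to ``j_hf``.

    Δ = 1/(2|J|) for AnX and AnX₃ systems and 1/(4|J|) for AnX₂ systems.
    """
    spin_class = SpinClass(spin_class)
    if j_hf == 0 or not math.isfinite(j_hf):
        raise ValueError("compute_delta requires a nonzero finite J_HF; got %r" % (j_hf,))
    j = abs(j_hf)
    if spin_class is SpinClass.AnX2:
        return 1.0 / (4.0 * j)
    return 1.0 / (2.0 * j)
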