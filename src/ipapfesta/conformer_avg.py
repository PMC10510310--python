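"""Conformational analysis: Boltzmann populations and weighted-average couplings.

A molecule in fast conformational exchange shows a single set of NMR signals
whose couplings are population-weighted averages over the conformers,

    ⟨J⟩ = Σ_i p_i · J_i ,    p_i = exp(−G_i/RT) / Σ_j exp(−G_j/RT),

with G_i the Gibbs energies (kJ/mol) of the conformers.  Conformers that
differ only in a spectroscopically silent degree of freedom (e.g. the OH
rotamer orientation) can be grouped: group populations add, and group
couplings are the population-weighted means of the members, which leaves the
overall average invariant.

Isomer ratios of slowly interconverting species are obtained directly by
integrating a resolved signal of each isomer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spin_model import Spectrum1D
from .j_measure import JEstimate, MultipletRegion

__all__ = [
    "GAS_CONSTANT_KJ",
    "ConformerEnsemble",
    "IsomerRatio",
    "boltzmann_populations",
    "group_populations",
    "weighted_average_j",
    "isomer_ratio_from_integrals",
    "comparison_table",
]

#: Molar gas constant in kJ·mol⁻¹·K⁻¹.
GAS_CONSTANT_KJ = 8.31446e-3

#: Default temperature (K) for population calculations.
DEFAULT_TEMPERATURE = 298.15


def boltzmann_populations(
    gibbs_energies: "list[float] | np.ndarray", temperature: float = DEFAULT_TEMPERATURE
) -> np.ndarray:
    """Boltzmann fractions from relative Gibbs energies (kJ/mol).

    Invariant under adding a constant to all energies (computed with the
    minimum-energy shift for numerical stability).
    """
    g = np.asarray(gibbs_energies, dtype=float)
    if g.size == 0:
        raise ValueError("at least one conformer energy is required")
    if not np.all(np.isfinite(g)):
        raise ValueError("energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    w = np.exp(-(g - g.min()) / (GAS_CONSTANT_KJ * temperature))
    return w / w.sum()


@dataclass
class ConformerEnsemble:
    """Conformer labels with populations and per-site couplings.

    Exactly one of ``gibbs_energies`` / ``populations`` must be supplied;
    populations are derived from energies on construction when absent.
    ``couplings`` maps each site label to one J (Hz) per conformer, in label
    order.  ``group_of`` optionally assigns each conformer to a group (e.g.
    collapsing OH rotamers onto ring conformers).
    """

    labels: list[str]
    gibbs_energies: list[float] | None = None
    populations: list[float] | None = None
    couplings: dict[str, list[float]] = field(default_factory=dict)
    group_of: dict[str, str] | None = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("conformer labels must be unique")
        if (self.gibbs_energies is None) == (self.populations is None):
            raise ValueError("supply exactly one of gibbs_energies or populations")
        if self.gibbs_energies is not None:
            if len(self.gibbs_energies) != n:
                raise ValueError("one Gibbs energy per conformer is required")
            self.populations = list(
                boltzmann_populations(self.gibbs_energies, self.temperature)
            )
        else:
            if len(self.populations) != n:
                raise ValueError("one population per conformer is required")
            p = np.asarray(self.populations, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("populations must be non-negative and sum to 1")
        for site, js in self.couplings.items():
            if len(js) != n:
                raise ValueError(f"site {site!r} must list one J per conformer")

    @property
    def sites(self) -> list[str]:
        return list(self.couplings)

    def site_average(self, site: str) -> float:
        return weighted_average_j(self.populations, self.couplings[site])


def group_populations(ensemble: ConformerEnsemble) -> ConformerEnsemble:
    """Collapse conformers onto their groups.

    Group population = Σ member populations; group coupling per site =
    population-weighted mean of member couplings.  Averaging over the
    grouped ensemble equals averaging over the original one exactly.
    """
    if ensemble.group_of is None:
        raise ValueError("ensemble has no group map")
    missing = [lab for lab in ensemble.labels if lab not in ensemble.group_of]
    if missing:
        raise ValueError(f"labels missing from group_of: {missing}")
    groups: list[str] = []
    for lab in ensemble.labels:
        g = ensemble.group_of[lab]
        if g not in groups:
            groups.append(g)
    p = np.asarray(ensemble.populations)
    gp = np.zeros(len(groups))
    gj = {site: np.zeros(len(groups)) for site in ensemble.couplings}
    for i, lab in enumerate(ensemble.labels):
        gi = groups.index(ensemble.group_of[lab])
        gp[gi] += p[i]
        for site, js in ensemble.couplings.items():
            gj[site][gi] += p[i] * js[i]
    for site in gj:
        nonzero = gp > 0
        gj[site][nonzero] = gj[site][nonzero] / gp[nonzero]
    return ConformerEnsemble(
        labels=groups,
        populations=list(gp / gp.sum()),
        couplings={site: list(js) for site, js in gj.items()},
        temperature=ensemble.temperature,
    )


def weighted_average_j(populations, conformer_js) -> float:
    """Population-weighted average coupling Σ pᵢ·Jᵢ (Hz)."""
    p = np.asarray(populations, dtype=float)
    j = np.asarray(conformer_js, dtype=float)
    if p.shape != j.shape:
        raise ValueError("populations and couplings must have equal length")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("populations must sum to 1")
    return float(np.dot(p, j))


@dataclass
class IsomerRatio:
    """Fractions of two slowly interconverting isomers from signal integrals."""

    labels: tuple[str, str]
    fractions: tuple[float, float]
    integrals: tuple[float, float]

    def __post_init__(self) -> None:
        if min(self.fractions) < 0 or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")


def isomer_ratio_from_integrals(
    spec: Spectrum1D, region_a: MultipletRegion, region_b: MultipletRegion
) -> IsomerRatio:
    """Isomer ratio by trapezoidal integration of one resolved signal each."""
    if not (region_a.hi <= region_b.lo or region_b.hi <= region_a.lo):
        raise ValueError("regions must be disjoint")
    freqs = spec.frequencies

    def area(r: MultipletRegion) -> float:
        if not (freqs[0] <= r.lo and r.hi <= freqs[-1]):
            raise ValueError(f"region {r.label} outside the grid")
        i0 = int(np.searchsorted(freqs, r.lo))
        i1 = int(np.searchsorted(freqs, r.hi, side="right"))
        return float(np.trapezoid(spec.intensities[i0:i1], freqs[i0:i1]))

    a, b = area(region_a), area(region_b)
    total = a + b
    if total <= 0:
        raise ValueError("non-positive total area; cannot form a ratio")
    return IsomerRatio(
        labels=(region_a.label, region_b.label),
        fractions=(a / total, b / total),
        integrals=(a, b),
    )


def comparison_table(
    measured: list[JEstimate], ensemble: ConformerEnsemble
) -> pd.DataFrame:
    """Per-site comparison of conformer-averaged and measured couplings.

    One row per site: the conformer-specific calculated couplings, their
    population-weighted average, the measured J where a matching label
    exists, the difference, and a sign-consistency flag (evaluated only when
    both values exceed 0.1 Hz in magnitude).  Measured estimates with no
    matching site are appended as residual rows.
    """
    rows = []
    meas = {e.label: e for e in measured}
    for site in ensemble.sites:
        avg = ensemble.site_average(site)
        row: dict = {"site": site}
        for i, lab in enumerate(ensemble.labels):
            row[f"J_{lab}"] = ensemble.couplings[site][i]
        row["weighted_average"] = avg
        e = meas.pop(site, None)
        if e is not None:
            row["measured"] = e.j
            row["difference"] = e.j - avg
            if abs(e.j) > 0.1 and abs(avg) > 0.1:
                row["sign_consistent"] = bool(np.sign(e.j) == np.sign(avg))
            else:
                row["sign_consistent"] = None
        else:
            row["measured"] = np.nan
            row["difference"] = np.nan
            row["sign_consistent"] = None
        rows.append(row)
    for label, e in meas.items():  # unmatched measurements: residual section
        rows.append(
            {"site": label, "weighted_average": np.nan, "measured": e.j,
             "difference": np.nan, "sign_consistent": None}
        )
    return pd.DataFrame(rows)
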