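"""Canonical synthetic datasets for tests, demos, and validation.

Two study systems are emulated:

* A three-proton spin system coupled to the F6 fluorine of fluticasone
  propionate, with the couplings measured for that system
  (²J_H6F6 = +48.9 Hz, ³J_H7aF6 = +14.1 Hz, ⁴J_H8F6 = −0.6 Hz) and an AP
  relaxation attenuation ρ = 0.935 chosen so that the compensating AP
  scaling factor is k = 1/ρ ≈ 1.07, matching the value used for the real
  data.

* The cis/trans-fluorohydrin (3-fluorotetrahydro-2H-pyran-2-ol) conformer
  ensembles in water, chloroform, and DMSO: two ring conformers per isomer
  with DFT conformer-specific couplings and populations, plus the
  experimentally integrated isomer ratios.

All numeric values are frozen here as module constants; ``make_fixtures``
writes them to disk (spin-system JSON, IP/AP CSVs, ensemble CSVs, and a
JSON manifest of expected values) deterministically for a given seed.
"""

from __future__ import annotations

import json
from pathlib import Path

from .spin_model import (
    FrequencyGrid,
    ProtonSite,
    SpinSystemSpec,
    add_noise,
    simulate_ipap_pair,
)
from .conformer_avg import ConformerEnsemble

__all__ = [
    "FLUTICASONE_F6_J",
    "FLUTICASONE_RHO",
    "fluticasone_f6_spec",
    "fluticasone_grid",
    "FLUOROHYDRIN_POPULATIONS",
    "FLUOROHYDRIN_COUPLINGS",
    "FLUOROHYDRIN_MEASURED",
    "FLUOROHYDRIN_ISOMER_RATIOS",
    "fluorohydrin_ensemble",
    "make_fixtures",
]

#: Signed ¹H–¹⁹F couplings (Hz) of the three-site F6 spin system.
FLUTICASONE_F6_J = {"H6": 48.9, "H7a": 14.1, "H8": -0.6}

#: Uniform AP relaxation attenuation; k = 1/ρ ≈ 1.07 compensates it.
FLUTICASONE_RHO = 0.935


def fluticasone_f6_spec(rho: float = FLUTICASONE_RHO) -> SpinSystemSpec:
    """Three-site F6-coupled spin system (shifts in Hz relative to carrier)."""
    protons = [
        ProtonSite(label="H6", shift=250.0, amplitude=1.0,
                   jhh=[("H7a", 4.0)], jhf=FLUTICASONE_F6_J["H6"], linewidth=1.0),
        ProtonSite(label="H7a", shift=0.0, amplitude=1.0,
                   jhh=[("H6", 4.0), ("H8", 11.0)], jhf=FLUTICASONE_F6_J["H7a"], linewidth=1.0),
        ProtonSite(label="H8", shift=-250.0, amplitude=1.0,
                   jhh=[("H7a", 11.0), ("H9", 4.5)], jhf=FLUTICASONE_F6_J["H8"], linewidth=1.0),
    ]
    return SpinSystemSpec(
        fluorine_label="F6",
        protons=protons,
        members=["H6", "H7a", "H8"],
        relaxation_attenuation=rho,
    )


def fluticasone_grid(step: float = 0.01) -> FrequencyGrid:
    """Frequency grid covering the three-site system at 0.01 Hz resolution."""
    npoints = int(round(640.0 / step)) + 1
    return FrequencyGrid(start=-320.0, stop=320.0, npoints=npoints)


# --------------------------------------------------------------------------
# fluorohydrin conformer ensembles
#
# Populations are the DFT conformer percentages per solvent; couplings are
# the DFT conformer-specific J_HF values in water; "measured" holds the
# experimental IPAP values in D2O used to parameterize recovery fixtures.

#: DFT conformer fractions per isomer and solvent (grouped over OH rotamers).
FLUOROHYDRIN_POPULATIONS = {
    "cis": {  # (ax-eq, eq-ax)
        "chloroform": (0.39, 0.61),
        "dmso": (0.23, 0.77),
        "water": (0.19, 0.81),
    },
    "trans": {  # (ax-ax, eq-eq)
        "chloroform": (0.61, 0.39),
        "dmso": (0.40, 0.60),
        "water": (0.18, 0.82),
    },
}

#: DFT conformer-specific couplings (Hz) in water, per proton site.
FLUOROHYDRIN_COUPLINGS = {
    "cis": {  # (ax-eq, eq-ax)
        "H3": (54.1, 56.0),
        "H2": (0.9, 18.3),
        "H4a": (6.8, 51.7),
        "H4b": (9.9, 11.5),
        "H5a": (4.5, 0.7),
        "H5b": (-2.2, 0.3),
        "H6a": (4.5, 1.2),
        "H6b": (-0.4, -0.1),
    },
    "trans": {  # (ax-ax, eq-eq)
        "H3": (53.0, 57.6),
        "H2": (10.7, 3.3),
        "H4a": (12.1, 13.7),
        "H4b": (52.0, 5.8),
        "H5a": (-0.1, -2.0),
        "H5b": (0.7, 3.1),
        "H6a": (-0.3, -0.2),
        "H6b": (1.5, 3.7),
    },
}

#: Experimental couplings (Hz) in D2O, used to parameterize fixtures.
FLUOROHYDRIN_MEASURED = {
    "cis": {"H3": 48.5, "H2": 14.7, "H4a": 32.7, "H4b": 10.5,
            "H5a": 1.9, "H5b": -0.8, "H6a": 1.9, "H6b": -0.02},
    "trans": {"H3": 48.5, "H2": 4.9, "H4a": 11.4, "H4b": 23.3,
              "H5a": -0.91, "H5b": 3.6, "H6a": -0.07, "H6b": 2.4},
}

#: cis/trans isomer fractions by H3 integration per solvent.
FLUOROHYDRIN_ISOMER_RATIOS = {
    "chloroform": (0.33, 0.67),
    "dmso": (0.34, 0.66),
    "water": (0.40, 0.60),
}

_CONFORMER_LABELS = {"cis": ("ax-eq", "eq-ax"), "trans": ("ax-ax", "eq-eq")}


def fluorohydrin_ensemble(isomer: str, solvent: str = "water") -> ConformerEnsemble:
    """Conformer ensemble for one isomer/solvent (couplings are for water)."""
    pops = FLUOROHYDRIN_POPULATIONS[isomer][solvent]
    labels = list(_CONFORMER_LABELS[isomer])
    couplings = {site: list(js) for site, js in FLUOROHYDRIN_COUPLINGS[isomer].items()}
    return ConformerEnsemble(labels=labels, populations=list(pops), couplings=couplings)


def make_fixtures(seed: int, out_dir: str | Path, noise_sigma: float = 0.0) -> dict:
    """Write the canonical fixture set to ``out_dir``; returns the manifest.

    Deterministic: the same seed yields a byte-identical file set.  Noise,
    when requested, is derived from the seed.
    """
    from .io import write_ensemble, write_spectrum, write_spin_system

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = fluticasone_f6_spec()
    grid = fluticasone_grid()
    pair = simulate_ipap_pair(spec, grid)
    ip, ap = pair.ip, pair.ap
    if noise_sigma > 0:
        ip = add_noise(ip, noise_sigma, seed)
        ap = add_noise(ap, noise_sigma, seed + 1)
    write_spin_system(out / "fluticasone_f6_spec.json", spec)
    write_spectrum(out / "fluticasone_f6_ip.csv", ip)
    write_spectrum(out / "fluticasone_f6_ap.csv", ap)
    for isomer in ("cis", "trans"):
        write_ensemble(out / f"fluorohydrin_{isomer}_water.csv",
                       fluorohydrin_ensemble(isomer, "water"))
    manifest = {
        "seed": seed,
        "noise_sigma": noise_sigma,
        "fluticasone": {
            "jhf": FLUTICASONE_F6_J,
            "rho": FLUTICASONE_RHO,
            "k_expected": 1.0 / FLUTICASONE_RHO,
            "reference_site": "H6",
        },
        "fluorohydrin": {
            "weighted_averages": {
                isomer: {
                    site: fluorohydrin_ensemble(isomer).site_average(site)
                    for site in FLUOROHYDRIN_COUPLINGS[isomer]
                }
                for isomer in ("cis", "trans")
            },
            "measured": FLUOROHYDRIN_MEASURED,
            "isomer_ratios": FLUOROHYDRIN_ISOMER_RATIOS,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
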