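"""Breast tissue materials and X-ray interaction coefficients.

The breast is modelled as a homogeneous mixture of adipose and glandular
tissue characterised by its glandularity ``G`` (glandular weight fraction,
``G = 0`` fully adipose, ``G = 1`` fully glandular).  Elemental compositions
and densities follow Hammerstein et al.; mixtures combine the two tissues by
mass fraction, with the mixture density given by mass-weighted specific
volumes, ``1/rho_mix = G/rho_g + (1 - G)/rho_a``.

Energy-dependent coefficients (total mass attenuation ``mu/rho``, mass
energy-absorption ``mu_en/rho`` and an approximate coherent-scattering
partition) are packaged as NIST-derived per-element tables and interpolated
log-log; no K-edges fall inside the supported band for these media.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ENERGY_MIN_KEV",
    "ENERGY_MAX_KEV",
    "AIR_DENSITY_G_CM3",
    "ElementalComposition",
    "Material",
    "CoefficientTable",
    "coefficient_table",
    "adipose",
    "glandular",
    "mixture_composition",
    "linear_attenuation",
    "mass_energy_absorption",
    "air_mass_energy_absorption",
    "air_linear_attenuation",
]

#: Energy band (keV) over which the model is specified.
ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 50.0

#: Dry air near sea level, 20 C (g/cm^3).
AIR_DENSITY_G_CM3 = 1.205e-3


@dataclass(frozen=True)
class ElementalComposition:
    """Mass fractions per element symbol plus a bulk density (g/cm^3)."""

    fractions: dict[str, float]
    density: float

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.fractions.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("mass fractions must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1, got {vals.sum()!r}")
        if not self.density > 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class Material:
    """A named homogeneous material with glandularity ``G`` in [0, 1]."""

    name: str
    glandularity: float
    composition: ElementalComposition


def _read_packaged_csv(name: str) -> pd.DataFrame:
    text = resources.files("bctsim.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), comment="#")


def _loglog_interp(energy_keV, grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    e = np.asarray(energy_keV, dtype=float)
    out = np.exp(np.interp(np.log(e), np.log(grid), np.log(values)))
    return out if out.ndim else float(out)


#: electrons per gram, Z/A per element (mol/g); air uses its composition-weighted value
_Z_OVER_A = {
    "H": 1 / 1.008, "C": 6 / 12.011, "N": 7 / 14.007, "O": 8 / 15.999,
    "Na": 11 / 22.9898, "P": 15 / 30.9738, "S": 16 / 32.06,
    "Cl": 17 / 35.45, "K": 19 / 39.0983, "air": 0.49918,
}
_NA_BARN = 0.602214076  # Avogadro / 1e24: barn * mol/g -> cm^2/g
_MEC2_KEV = 510.99895
_SIGMA_T_BARN = 0.66524587


def klein_nishina_total_barn(energy_keV) -> np.ndarray:
    """Total Klein-Nishina cross section per free electron (barn)."""
    k = np.asarray(energy_keV, dtype=float) / _MEC2_KEV
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    t2 = np.log1p(2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return 0.75 * _SIGMA_T_BARN * (t1 + t2 + t3)


def klein_nishina_transfer_barn(energy_keV) -> np.ndarray:
    """Klein-Nishina energy-transfer cross section per free electron (barn)."""
    k = np.asarray(energy_keV, dtype=float) / _MEC2_KEV
    t1 = 2 * (1 + k) ** 2 / (k**2 * (1 + 2 * k))
    t2 = (1 + 3 * k) / (1 + 2 * k) ** 2
    t3 = (1 + k) * (2 * k**2 - 2 * k - 1) / (k**2 * (1 + 2 * k) ** 2)
    t4 = 4 * k**2 / (3 * (1 + 2 * k) ** 3)
    t5 = ((1 + k) / k**3 - 1 / (2 * k) + 1 / (2 * k**3)) * np.log1p(2 * k)
    return 0.75 * _SIGMA_T_BARN * (t1 - t2 - t3 - t4 - t5)


class CoefficientTable:
    """Per-element (and air) interaction coefficients on a common energy grid.

    ``mu_rho`` is the total mass attenuation coefficient (coherent included),
    ``mu_en_rho`` the mass energy-absorption coefficient, and ``mu_coh_rho``
    an approximate coherent partition used by the Monte Carlo transport.
    All in cm^2/g.

    Interpolation is channel-decomposed: the incoherent channel is the exact
    Klein-Nishina closed form (total or energy-transfer), the coherent and
    photoelectric channels are log-log interpolated, with photoelectric taken
    as the node residual of the packaged totals.  Interpolating each channel
    separately avoids the few-percent mid-interval bias that log-log
    interpolation of a *sum* of power laws would introduce on the sparse
    published grid.
    """

    def __init__(self) -> None:
        att = _read_packaged_csv("mass_attenuation.csv")
        en = _read_packaged_csv("mass_energy_absorption.csv")
        coh = _read_packaged_csv("coherent_scattering.csv")
        self.energies_keV = np.sort(att["energy_keV"].unique()).astype(float)
        if not np.all(np.diff(self.energies_keV) > 0):
            raise ValueError("energy grid must be strictly increasing")
        self._mu_rho = self._pivot(att, "mu_over_rho_cm2_g")
        self._mu_en_rho = self._pivot(en, "mu_en_over_rho_cm2_g")
        self._mu_coh_rho = self._pivot(coh, "mu_coh_over_rho_cm2_g")
        for table in (self._mu_rho, self._mu_en_rho, self._mu_coh_rho):
            for v in table.values():
                if np.any(v <= 0):
                    raise ValueError("all packaged coefficients must be positive")
        kn = klein_nishina_total_barn(self.energies_keV)
        kn_tr = klein_nishina_transfer_barn(self.energies_keV)
        self._pe_att: dict[str, np.ndarray] = {}
        self._pe_en: dict[str, np.ndarray] = {}
        for el, tot in self._mu_rho.items():
            epg = _NA_BARN * _Z_OVER_A[el]
            self._pe_att[el] = np.clip(tot - epg * kn - self._mu_coh_rho[el], 1e-8, None)
            self._pe_en[el] = np.clip(self._mu_en_rho[el] - epg * kn_tr, 1e-8, None)

    def _pivot(self, df: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for elem, sub in df.groupby("element"):
            sub = sub.sort_values("energy_keV")
            if not np.array_equal(sub["energy_keV"].to_numpy(dtype=float), self.energies_keV):
                raise ValueError(f"inconsistent energy grid for {elem}")
            out[elem] = sub[col].to_numpy(dtype=float)
        return out

    # Unchecked lookups over the full packaged band (used by the transport code,
    # which follows down-scattered photons slightly outside the 10-50 keV API band).
    def mu_rho(self, element: str, energy_keV) -> np.ndarray:
        epg = _NA_BARN * _Z_OVER_A[element]
        return (
            _loglog_interp(energy_keV, self.energies_keV, self._pe_att[element])
            + epg * klein_nishina_total_barn(energy_keV)
            + _loglog_interp(energy_keV, self.energies_keV, self._mu_coh_rho[element])
        )

    def mu_en_rho(self, element: str, energy_keV) -> np.ndarray:
        epg = _NA_BARN * _Z_OVER_A[element]
        return _loglog_interp(
            energy_keV, self.energies_keV, self._pe_en[element]
        ) + epg * klein_nishina_transfer_barn(energy_keV)

    def mu_coh_rho(self, element: str, energy_keV) -> np.ndarray:
        return _loglog_interp(energy_keV, self.energies_keV, self._mu_coh_rho[element])

    def mixture_mu_rho(self, fractions: dict[str, float], energy_keV) -> np.ndarray:
        return sum(w * self.mu_rho(el, energy_keV) for el, w in fractions.items())

    def mixture_mu_en_rho(self, fractions: dict[str, float], energy_keV) -> np.ndarray:
        return sum(w * self.mu_en_rho(el, energy_keV) for el, w in fractions.items())

    def mixture_mu_coh_rho(self, fractions: dict[str, float], energy_keV) -> np.ndarray:
        return sum(w * self.mu_coh_rho(el, energy_keV) for el, w in fractions.items())


_TABLE: CoefficientTable | None = None
_TISSUES: dict[str, ElementalComposition] | None = None


def coefficient_table() -> CoefficientTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = CoefficientTable()
    return _TABLE


def _tissues() -> dict[str, ElementalComposition]:
    global _TISSUES
    if _TISSUES is None:
        df = _read_packaged_csv("tissues.csv")
        out = {}
        for tissue, sub in df.groupby("tissue"):
            out[tissue] = ElementalComposition(
                fractions=dict(zip(sub["element"], sub["mass_fraction"].astype(float))),
                density=float(sub["density_g_cm3"].iloc[0]),
            )
        _TISSUES = out
    return _TISSUES


def adipose() -> Material:
    return Material("adipose", 0.0, _tissues()["adipose"])


def glandular() -> Material:
    return Material("glandular", 1.0, _tissues()["glandular"])


def mixture_composition(G: float) -> Material:
    """Homogeneous adipose/glandular mixture of glandularity ``G``.

    Mass fractions are the G-weighted combination of the two tissue
    compositions; the density follows mass-weighted specific volumes,
    ``1/rho = G/rho_g + (1-G)/rho_a``.
    """
    if not 0.0 <= G <= 1.0:
        raise ValueError(f"glandularity must be in [0, 1], got {G}")
    a, g = _tissues()["adipose"], _tissues()["glandular"]
    elements = sorted(set(a.fractions) | set(g.fractions))
    fr = {
        el: G * g.fractions.get(el, 0.0) + (1.0 - G) * a.fractions.get(el, 0.0)
        for el in elements
    }
    total = sum(fr.values())
    fr = {el: w / total for el, w in fr.items()}
    density = 1.0 / (G / g.density + (1.0 - G) / a.density)
    if G == 0.0:
        return Material("adipose", 0.0, a)
    if G == 1.0:
        return Material("glandular", 1.0, g)
    return Material(f"breast_G{G:g}", G, ElementalComposition(fr, density))


def _check_energy_range(energy_keV) -> np.ndarray:
    e = np.asarray(energy_keV, dtype=float)
    if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
        raise ValueError(
            f"energy must lie in [{ENERGY_MIN_KEV:g}, {ENERGY_MAX_KEV:g}] keV"
        )
    return e


def linear_attenuation(material: Material, energy_keV) -> np.ndarray:
    """Linear attenuation coefficient mu (1/cm) of ``material`` at ``energy_keV``."""
    e = _check_energy_range(energy_keV)
    t = coefficient_table()
    return material.composition.density * t.mixture_mu_rho(material.composition.fractions, e)


def mass_energy_absorption(material: Material, energy_keV) -> np.ndarray:
    """Mass energy-absorption coefficient mu_en/rho (cm^2/g) of ``material``."""
    e = _check_energy_range(energy_keV)
    return coefficient_table().mixture_mu_en_rho(material.composition.fractions, e)


def air_mass_energy_absorption(energy_keV) -> np.ndarray:
    """(mu_en/rho)_air in cm^2/g, log-log interpolated from the packaged table."""
    e = _check_energy_range(energy_keV)
    return coefficient_table().mu_en_rho("air", e)


def air_linear_attenuation(energy_keV) -> np.ndarray:
    """mu_air (1/cm) for dry air near sea level."""
    e = _check_energy_range(energy_keV)
    return AIR_DENSITY_G_CM3 * coefficient_table().mu_rho("air", e)
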