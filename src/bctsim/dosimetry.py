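"""Dosimetry: from mean glandular dose to photons per pixel, and DgN_CT by Monte Carlo.

The dose prescription chain is

    MGD_t = K * DgN_CT            (air kerma at the isocenter)
    K     = (mu_en/rho)_air * E * phi    (kerma-fluence relation at low energy)
    N_ph  = phi * dx^2            (photons per detector pixel over the whole scan)

``DgN_CT`` (mean glandular dose per unit air kerma at the isocenter, for an
idealized homogeneous cylindrical breast) is estimated by an in-repo photon
Monte Carlo: photoelectric absorption, incoherent (Klein-Nishina) scattering
and, optionally, coherent scattering with a Thomson angular law.  Locally
deposited energy is attributed to the glandular component with the standard
homogeneous-mixture weight

    f_G(E) = G (mu_en/rho)_g / [ G (mu_en/rho)_g + (1-G) (mu_en/rho)_a ]

and divided by the glandular mass ``G * M``; the G -> 0 limit is finite.  The
air kerma in the denominator is computed analytically from the known fluence
at the isocenter (a zero-variance normalization).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bctsim import materials
from bctsim.materials import (
    AIR_DENSITY_G_CM3,
    air_mass_energy_absorption,
    coefficient_table,
    mixture_composition,
)

__all__ = [
    "KEV_TO_J",
    "BeamGeometry",
    "DoseCoefficient",
    "ExposureBudget",
    "kerma_from_mgd",
    "fluence_from_kerma",
    "photons_per_pixel",
    "dgn_ct_monte_carlo",
    "DgnCache",
]

KEV_TO_J = 1.602176634e-16

#: electron rest energy (keV), for Compton kinematics
_MEC2_KEV = 510.99895
#: Thomson cross section (barn)
_SIGMA_THOMSON_BARN = 0.66524587
#: Avogadro constant / 1e24 (so that sigma in barn * N_A/A gives cm^2/g)
_NA_BARN = 0.602214076

#: transport cutoff (keV): photons below this are absorbed on the spot.  The
#: mean free path at 8 keV in breast tissue is ~1 mm and Compton down-scatter
#: from <=50 keV practically never reaches this energy, so the cutoff keeps
#: per-run energy conservation exact at no cost in accuracy.
_CUTOFF_KEV = 8.0


@dataclass(frozen=True)
class BeamGeometry:
    """Irradiation geometry for the DgN_CT Monte Carlo.

    ``mode='full'`` irradiates the whole cylinder height (h = H), emulating a
    complete multi-slab exam; ``mode='laminar'`` restricts the beam to a
    sheet of height ``beam_height_mm`` centred on the cylinder midplane.
    """

    beam_height_mm: float = 3.5
    cylinder_height_cm: float = 9.0
    mode: str = "full"
    odd_cm: float = 185.0

    def __post_init__(self) -> None:
        if self.mode not in ("full", "laminar"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if not 0 < self.beam_height_mm <= self.cylinder_height_cm * 10:
            raise ValueError("beam height must be in (0, cylinder height]")
        if self.odd_cm < 0:
            raise ValueError("ODD must be nonnegative")

    @property
    def irradiated_height_cm(self) -> float:
        if self.mode == "full":
            return self.cylinder_height_cm
        return self.beam_height_mm / 10.0


@dataclass(frozen=True)
class DoseCoefficient:
    """DgN_CT value (mGy per mGy of isocenter air kerma) with MC uncertainty."""

    value: float
    stderr: float
    energy_keV: float
    diameter_cm: float
    glandularity: float
    geometry: BeamGeometry | None = None
    n_photons: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("DgN_CT must be positive")
        if self.stderr < 0:
            raise ValueError("standard error must be nonnegative")


@dataclass(frozen=True)
class ExposureBudget:
    """Resolved exposure quantities for one (d, G, MGD, E, dx) configuration."""

    mgd_mGy: float
    kerma_mGy: float
    fluence_per_mm2: float
    photons_per_pixel: float
    pixel_mm: float


def kerma_from_mgd(mgd_mGy: float, dgn: DoseCoefficient) -> float:
    """Air kerma at the isocenter (mGy) delivering ``mgd_mGy`` of MGD_t."""
    if mgd_mGy < 0:
        raise ValueError("MGD must be nonnegative")
    return mgd_mGy / dgn.value


def fluence_from_kerma(kerma_mGy: float, energy_keV: float) -> float:
    """Photon fluence (photons/mm^2) from air kerma (mGy) at ``energy_keV``.

    Inverts K = (mu_en/rho)_air * E * phi with consistent SI units.
    """
    a_air_m2_kg = float(air_mass_energy_absorption(energy_keV)) * 0.1
    e_joule = energy_keV * KEV_TO_J
    phi_per_m2 = (kerma_mGy * 1e-3) / (a_air_m2_kg * e_joule)
    return phi_per_m2 * 1e-6


def photons_per_pixel(
    mgd_mGy: float, pixel_mm: float, energy_keV: float, dgn: DoseCoefficient
) -> ExposureBudget:
    """Total photons per detector pixel over the scan, N_ph = phi * dx^2."""
    kerma = kerma_from_mgd(mgd_mGy, dgn)
    phi = fluence_from_kerma(kerma, energy_keV)
    return ExposureBudget(
        mgd_mGy=mgd_mGy,
        kerma_mGy=kerma,
        fluence_per_mm2=phi,
        photons_per_pixel=phi * pixel_mm**2,
        pixel_mm=pixel_mm,
    )


# ---------------------------------------------------------------------------
# Monte Carlo transport
# ---------------------------------------------------------------------------


from bctsim.materials import _Z_OVER_A, klein_nishina_total_barn


class _MixtureLookup:
    """Fine-grid interaction coefficients for one glandularity G (all 1/cm)."""

    def __init__(self, G: float) -> None:
        mat = mixture_composition(G)
        table = coefficient_table()
        self.rho = mat.composition.density
        self.grid = np.arange(_CUTOFF_KEV, 55.0 + 0.25, 0.25)
        fr = mat.composition.fractions
        mu_rho = table.mixture_mu_rho(fr, self.grid)
        mu_coh_rho = table.mixture_mu_coh_rho(fr, self.grid)
        # electrons per gram, summed over elements: N_A * sum w_i Z_i / A_i
        electrons_per_g = _NA_BARN * sum(w * _Z_OVER_A[el] for el, w in fr.items())
        mu_incoh_rho = electrons_per_g * klein_nishina_total_barn(self.grid)
        # photoelectric as the residual of the exact packaged total, so the
        # transport attenuation length matches the analytic model exactly
        mu_pe_rho = np.clip(mu_rho - mu_incoh_rho - mu_coh_rho, 1e-6, None)
        self.mu_tot = self.rho * mu_rho
        self.frac_pe = mu_pe_rho / mu_rho
        self.frac_coh = mu_coh_rho / mu_rho
        # glandular attribution weight f_G(E) / G = a_g / (G a_g + (1-G) a_a)
        a_g = table.mixture_mu_en_rho(materials.glandular().composition.fractions, self.grid)
        a_a = table.mixture_mu_en_rho(materials.adipose().composition.fractions, self.grid)
        self.weight = a_g / (G * a_g + (1.0 - G) * a_a)

    def lookup(self, energy_keV: np.ndarray):
        # the grid is uniform, so indices come from arithmetic, not bisection
        step = self.grid[1] - self.grid[0]
        pos = np.clip((energy_keV - self.grid[0]) / step, 0.0, self.grid.size - 1.001)
        i = pos.astype(np.intp)
        frac = pos - i
        j = i + 1
        mu = self.mu_tot[i] * (1 - frac) + self.mu_tot[j] * frac
        f_pe = self.frac_pe[i] * (1 - frac) + self.frac_pe[j] * frac
        f_coh = self.frac_coh[i] * (1 - frac) + self.frac_coh[j] * frac
        w = self.weight[i] * (1 - frac) + self.weight[j] * frac
        return mu, f_pe, f_coh, w


def _rotate_directions(ux, uy, uz, cos_t, phi):
    """Rotate unit vectors by polar angle arccos(cos_t) and azimuth phi.

    Component form of the usual local-frame construction; the helper axis is
    z where the direction is not too axial, x otherwise.
    """
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    c1, c2 = sin_t * np.cos(phi), sin_t * np.sin(phi)
    small_z = np.abs(uz) < 0.9
    hx = np.where(small_z, 0.0, 1.0)
    hz = np.where(small_z, 1.0, 0.0)
    # a = h x u, normalized; b = u x a
    ax = hz * -uy
    ay = hz * ux - hx * uz
    az = hx * uy
    norm = np.sqrt(ax**2 + ay**2 + az**2)
    ax, ay, az = ax / norm, ay / norm, az / norm
    bx = uy * az - uz * ay
    by = uz * ax - ux * az
    bz = ux * ay - uy * ax
    vx = ux * cos_t + ax * c1 + bx * c2
    vy = uy * cos_t + ay * c1 + by * c2
    vz = uz * cos_t + az * c1 + bz * c2
    norm = np.sqrt(vx**2 + vy**2 + vz**2)
    return vx / norm, vy / norm, vz / norm


def _sample_klein_nishina(energy_keV: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample Compton scattering cosines by rejection against a flat envelope."""
    k = energy_keV / _MEC2_KEV
    n = k.size
    cos_t = np.empty(n)
    todo = np.arange(n)
    # envelope: dsigma/dcos is maximal at cos=1 where it equals 2 (in units of
    # re^2/2); a flat envelope of height 2 has acceptance ~2/3 at these energies
    while todo.size:
        c = rng.uniform(-1.0, 1.0, todo.size)
        kk = k[todo]
        r = 1.0 / (1.0 + kk * (1.0 - c))  # E'/E
        f = r**2 * (r + 1.0 / r - (1.0 - c**2))
        accept = rng.uniform(0.0, 2.0, todo.size) < f
        cos_t[todo[accept]] = c[accept]
        todo = todo[~accept]
    return cos_t


def _sample_thomson(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample cosines from the Thomson law, pdf proportional to 1 + cos^2."""
    cos_t = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        c = rng.uniform(-1.0, 1.0, todo.size)
        accept = rng.uniform(0.0, 2.0, todo.size) < 1.0 + c**2
        cos_t[todo[accept]] = c[accept]
        todo = todo[~accept]
    return cos_t


def _exit_distance(x, y, z, ux, uy, uz, R: float, H: float) -> np.ndarray:
    """Distance along (ux,uy,uz) to the surface of the cylinder x^2+y^2=R^2, 0<=z<=H."""
    a = ux**2 + uy**2
    b = 2.0 * (x * ux + y * uy)
    c = x**2 + y**2 - R**2
    disc = np.clip(b**2 - 4.0 * a * c, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_side = np.where(a > 1e-12, (-b + np.sqrt(disc)) / (2.0 * a), np.inf)
    t_side = np.where(t_side > 0, t_side, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_cap = np.where(
            uz > 1e-12, (H - z) / uz, np.where(uz < -1e-12, -z / uz, np.inf)
        )
    t_cap = np.where(t_cap > 0, t_cap, np.inf)
    return np.minimum(t_side, t_cap)


try:  # the JIT kernel is ~10x faster; the numpy path is kept as a cross-check
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _transport_kernel(
        seed, n_photons, R, H, z0, h, E0,
        grid0, gstep, ngrid, mu_tot, frac_pe, frac_coh, weight,
        include_coherent, cutoff, n_batches,
    ):  # pragma: no cover - exercised through dgn_ct_monte_carlo
        np.random.seed(seed)
        dep_w = np.zeros(n_batches)
        dep_total = 0.0
        esc_total = 0.0
        for i in range(n_photons):
            b = i * n_batches // n_photons
            y = np.random.uniform(-R, R)
            x = -np.sqrt(max(R * R - y * y, 0.0))
            z = z0 + np.random.random() * h
            ux, uy, uz = 1.0, 0.0, 0.0
            E = E0
            while True:
                p = (E - grid0) / gstep
                if p < 0.0:
                    p = 0.0
                elif p > ngrid - 1.001:
                    p = ngrid - 1.001
                k = int(p)
                fr = p - k
                mu = mu_tot[k] * (1 - fr) + mu_tot[k + 1] * fr
                fpe = frac_pe[k] * (1 - fr) + frac_pe[k + 1] * fr
                fcoh = frac_coh[k] * (1 - fr) + frac_coh[k + 1] * fr
                w = weight[k] * (1 - fr) + weight[k + 1] * fr

                step = np.random.exponential(1.0) / mu
                a = ux * ux + uy * uy
                bq = 2.0 * (x * ux + y * uy)
                cq = x * x + y * y - R * R
                if a > 1e-12:
                    disc = bq * bq - 4.0 * a * cq
                    if disc < 0.0:
                        disc = 0.0
                    t_side = (-bq + np.sqrt(disc)) / (2.0 * a)
                    if t_side <= 0.0:
                        t_side = 1e30
                else:
                    t_side = 1e30
                if uz > 1e-12:
                    t_cap = (H - z) / uz
                elif uz < -1e-12:
                    t_cap = -z / uz
                else:
                    t_cap = 1e30
                t_exit = min(t_side, t_cap)
                if step >= t_exit:
                    esc_total += E
                    break
                x += ux * step
                y += uy * step
                z += uz * step

                r = np.random.random()
                if not include_coherent:
                    fpe = fpe / (1.0 - fcoh)
                    fcoh = 0.0
                if r < fpe:
                    dep_w[b] += E * w
                    dep_total += E
                    break
                coherent_event = r < fpe + fcoh
                if coherent_event:
                    # Thomson angular law, rejection against a flat envelope
                    while True:
                        c = np.random.uniform(-1.0, 1.0)
                        if np.random.uniform(0.0, 2.0) < 1.0 + c * c:
                            break
                    cos_t = c
                else:
                    kk = E / _MEC2_KEV
                    while True:
                        c = np.random.uniform(-1.0, 1.0)
                        rr = 1.0 / (1.0 + kk * (1.0 - c))
                        f = rr * rr * (rr + 1.0 / rr - (1.0 - c * c))
                        if np.random.uniform(0.0, 2.0) < f:
                            break
                    cos_t = c
                    E_out = E / (1.0 + kk * (1.0 - cos_t))
                    dep_w[b] += (E - E_out) * w
                    dep_total += E - E_out
                    E = E_out

                # rotate direction by (cos_t, random azimuth)
                phi = np.random.uniform(0.0, 2.0 * np.pi)
                sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 0.0))
                c1 = sin_t * np.cos(phi)
                c2 = sin_t * np.sin(phi)
                if abs(uz) < 0.9:
                    ax, ay, az = -uy, ux, 0.0
                else:
                    ax, ay, az = 0.0, uz, -uy
                norm = np.sqrt(ax * ax + ay * ay + az * az)
                ax, ay, az = ax / norm, ay / norm, az / norm
                bx = uy * az - uz * ay
                by = uz * ax - ux * az
                bz = ux * ay - uy * ax
                vx = ux * cos_t + ax * c1 + bx * c2
                vy = uy * cos_t + ay * c1 + by * c2
                vz = uz * cos_t + az * c1 + bz * c2
                norm = np.sqrt(vx * vx + vy * vy + vz * vz)
                ux, uy, uz = vx / norm, vy / norm, vz / norm

                if E < cutoff:
                    dep_w[b] += E * w
                    dep_total += E
                    break
        return dep_w, dep_total, esc_total


def dgn_ct_monte_carlo(
    diameter_cm: float,
    glandularity: float,
    energy_keV: float,
    geometry: BeamGeometry | None = None,
    n_photons: int = 1_000_000,
    seed: int | np.random.SeedSequence = 0,
    include_coherent: bool = True,
    backend: str | None = None,
    _batches: int = 20,
) -> DoseCoefficient:
    """Monte Carlo estimate of DgN_CT for a homogeneous cylindrical breast.

    A monoenergetic parallel beam travels along +x through a cylinder of
    diameter ``diameter_cm`` and height ``geometry.cylinder_height_cm``.
    Deposited energy anywhere in the cylinder (scatter reaches outside the
    irradiated band in laminar mode) is glandular-weighted and normalized by
    the analytic air kerma at the isocenter.  Deterministic given the seed.

    Returns the coefficient with a batch-estimate standard error.
    """
    if n_photons < 10_000:
        raise ValueError("n_photons must be at least 1e4 for a usable estimate")
    if not materials.ENERGY_MIN_KEV <= energy_keV <= materials.ENERGY_MAX_KEV:
        raise ValueError("energy outside the supported 10-50 keV band")
    geom = geometry or BeamGeometry()
    R = diameter_cm / 2.0
    H = geom.cylinder_height_cm
    h = geom.irradiated_height_cm
    lut = _MixtureLookup(glandularity)
    if backend is None:
        backend = "numba" if _HAVE_NUMBA else "numpy"
    if backend not in ("numba", "numpy"):
        raise ValueError(f"unknown backend {backend!r}")
    if backend == "numba" and not _HAVE_NUMBA:
        raise RuntimeError("numba backend requested but numba is not importable")

    z0 = (H - h) / 2.0
    if backend == "numba":
        if isinstance(seed, np.random.SeedSequence):
            seed32 = int(seed.generate_state(1, np.uint32)[0])
        else:
            seed32 = int(seed) % (2**32)
        dep_weighted, dep_total, escaped_total = _transport_kernel(
            seed32, n_photons, R, H, z0, h, float(energy_keV),
            lut.grid[0], lut.grid[1] - lut.grid[0], lut.grid.size,
            lut.mu_tot, lut.frac_pe, lut.frac_coh, lut.weight,
            include_coherent, _CUTOFF_KEV, _batches,
        )
        return _finalize(
            dep_weighted, dep_total, escaped_total, n_photons, energy_keV,
            lut, R, H, h, _batches, diameter_cm, glandularity, geom, seed,
        )
    rng = np.random.default_rng(seed)

    y = rng.uniform(-R, R, n_photons)
    x = -np.sqrt(np.clip(R**2 - y**2, 0.0, None))
    z0 = (H - h) / 2.0
    z = rng.uniform(z0, z0 + h, n_photons)
    ux = np.ones(n_photons)
    uy = np.zeros(n_photons)
    uz = np.zeros(n_photons)
    energy = np.full(n_photons, float(energy_keV))
    edges = np.linspace(0, n_photons, _batches + 1).astype(int)
    batch_id = np.repeat(np.arange(_batches), np.diff(edges))

    dep_weighted = np.zeros(_batches)
    dep_total = 0.0
    escaped_total = 0.0

    while energy.size:
        mu, f_pe, f_coh, w = lut.lookup(energy)
        step = rng.exponential(1.0, energy.size) / mu
        t_exit = _exit_distance(x, y, z, ux, uy, uz, R, H)
        inside = step < t_exit
        escaped_total += energy.sum() - energy[inside].sum()
        x, y, z, ux, uy, uz, energy, batch_id, step = (
            arr[inside] for arr in (x, y, z, ux, uy, uz, energy, batch_id, step)
        )
        f_pe, f_coh, w = f_pe[inside], f_coh[inside], w[inside]
        if not energy.size:
            break
        x = x + ux * step
        y = y + uy * step
        z = z + uz * step

        u = rng.uniform(0.0, 1.0, energy.size)
        if include_coherent:
            is_pe = u < f_pe
            is_coh = (~is_pe) & (u < f_pe + f_coh)
        else:
            # fold the (unused) coherent channel into the scattering decision
            is_pe = u < f_pe / (1.0 - f_coh)
            is_coh = np.zeros_like(is_pe)
        is_inc = ~(is_pe | is_coh)

        # photoelectric: local absorption of the full photon energy
        dep_weighted += np.bincount(
            batch_id[is_pe], weights=(energy * w)[is_pe], minlength=_batches
        )
        dep_total += energy[is_pe].sum()

        # incoherent: deposit the electron recoil energy, follow the photon
        if np.any(is_inc):
            e_inc = energy[is_inc]
            cos_t = _sample_klein_nishina(e_inc, rng)
            e_out = e_inc / (1.0 + (e_inc / _MEC2_KEV) * (1.0 - cos_t))
            dep_weighted += np.bincount(
                batch_id[is_inc], weights=(e_inc - e_out) * w[is_inc], minlength=_batches
            )
            dep_total += (e_inc - e_out).sum()
            phi = rng.uniform(0.0, 2.0 * np.pi, e_inc.size)
            vx, vy, vz = _rotate_directions(
                ux[is_inc], uy[is_inc], uz[is_inc], cos_t, phi
            )
            ux[is_inc], uy[is_inc], uz[is_inc] = vx, vy, vz
            energy[is_inc] = e_out

        # coherent: direction change only
        if np.any(is_coh):
            n_coh = int(is_coh.sum())
            cos_t = _sample_thomson(n_coh, rng)
            phi = rng.uniform(0.0, 2.0 * np.pi, n_coh)
            vx, vy, vz = _rotate_directions(
                ux[is_coh], uy[is_coh], uz[is_coh], cos_t, phi
            )
            ux[is_coh], uy[is_coh], uz[is_coh] = vx, vy, vz

        # cutoff: absorb very soft photons on the spot (see module notes)
        soft = (~is_pe) & (energy < _CUTOFF_KEV)
        if np.any(soft):
            dep_weighted += np.bincount(
                batch_id[soft], weights=(energy * w)[soft], minlength=_batches
            )
            dep_total += energy[soft].sum()
            is_pe = is_pe | soft

        keep = ~is_pe
        x, y, z, ux, uy, uz, energy, batch_id = (
            arr[keep] for arr in (x, y, z, ux, uy, uz, energy, batch_id)
        )

    return _finalize(
        dep_weighted, dep_total, escaped_total, n_photons, energy_keV,
        lut, R, H, h, _batches, diameter_cm, glandularity, geom, seed,
    )


def _finalize(
    dep_weighted, dep_total, escaped_total, n_photons, energy_keV,
    lut, R, H, h, n_batches, diameter_cm, glandularity, geom, seed,
) -> DoseCoefficient:
    injected = n_photons * float(energy_keV)
    balance = abs(injected - dep_total - escaped_total) / injected
    if balance > 1e-6:
        raise RuntimeError(f"energy conservation violated: relative error {balance:.3e}")

    mass_g = lut.rho * np.pi * R**2 * H
    # glandular dose per batch, keV/g
    dose_batches = dep_weighted / mass_g
    # analytic air kerma at the isocenter, keV/g, from the beam fluence
    fluence_per_cm2 = n_photons / (2.0 * R * h)
    a_air = float(air_mass_energy_absorption(energy_keV))
    kerma = fluence_per_cm2 * energy_keV * a_air
    dgn_batches = dose_batches * n_batches / kerma
    value = float(np.mean(dgn_batches))
    stderr = float(np.std(dgn_batches, ddof=1) / np.sqrt(n_batches))
    return DoseCoefficient(
        value=value,
        stderr=stderr,
        energy_keV=float(energy_keV),
        diameter_cm=float(diameter_cm),
        glandularity=float(glandularity),
        geometry=geom,
        n_photons=int(n_photons),
        seed=seed if isinstance(seed, int) else None,
    )


class DgnCache:
    """Delimited-table cache of DgN_CT coefficients keyed by run parameters.

    Users may supply an externally computed table in the same format (for
    example transcribed from a published MC) and it will override new runs.
    """

    COLUMNS = ["E_keV", "d_cm", "G", "mode", "H_cm", "dgn", "stderr", "n_photons", "seed"]

    def __init__(self, path: str | os.PathLike | None = None) -> None:
        self.path = os.fspath(path) if path is not None else None
        if self.path is not None and os.path.exists(self.path):
            self._df = pd.read_csv(self.path, comment="#")
        else:
            self._df = pd.DataFrame(columns=self.COLUMNS)

    def _match(self, E, d, G, geom: BeamGeometry) -> pd.DataFrame:
        df = self._df
        return df[
            np.isclose(df["E_keV"], E)
            & np.isclose(df["d_cm"], d)
            & np.isclose(df["G"], G)
            & (df["mode"] == geom.mode)
            & np.isclose(df["H_cm"], geom.cylinder_height_cm)
        ]

    def get_or_compute(
        self, E, d, G, geometry: BeamGeometry | None = None,
        n_photons: int = 1_000_000, seed: int | np.random.SeedSequence = 0,
    ) -> DoseCoefficient:
        geom = geometry or BeamGeometry()
        hit = self._match(E, d, G, geom)
        if len(hit):
            row = hit.iloc[0]
            return DoseCoefficient(
                value=float(row["dgn"]), stderr=float(row["stderr"]),
                energy_keV=float(E), diameter_cm=float(d), glandularity=float(G),
                geometry=geom, n_photons=int(row["n_photons"]),
                seed=None if pd.isna(row["seed"]) else int(row["seed"]),
            )
        dgn = dgn_ct_monte_carlo(d, G, E, geom, n_photons=n_photons, seed=seed)
        self._df.loc[len(self._df)] = [
            float(E), float(d), float(G), geom.mode, geom.cylinder_height_cm,
            dgn.value, dgn.stderr, dgn.n_photons, dgn.seed,
        ]
        if self.path is not None:
            self._df.to_csv(self.path, index=False)
        return dgn
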