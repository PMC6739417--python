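"""Analytic forward projection of the concentric-cylinder phantom.

The simulated slice is a cylinder of diameter ``d`` made of the homogeneous
glandularity-``G`` mixture, carrying a central glandular disc of 1 cm
diameter surrounded by a concentric adipose annulus of equal area (outer
radius sqrt(2)/2 cm).  Because the three regions are concentric, every
projection row is identical and chord lengths follow from circle geometry,

    chord(r, s) = 2 sqrt(r^2 - s^2),

so expected detector counts for an ideal photon-counting detector are exact,

    c(s) = (N_ph / n_proj) exp(-sum_m mu_m L_m(s)) exp(-mu_air ODD).

Poisson sampling of the expected sinogram gives one noise realization; the
log-normalization back to line integrals uses the noiseless expected blank
as the flat field, so the air-path attenuation divides out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from bctsim import materials

__all__ = [
    "DETAIL_RADIUS_CM",
    "RING_OUTER_RADIUS_CM",
    "ConcentricPhantom",
    "Sinogram",
    "path_lengths",
    "expected_sinogram",
    "sample_sinogram",
    "to_line_integrals",
]

DETAIL_RADIUS_CM = 0.5
RING_OUTER_RADIUS_CM = 0.5 * np.sqrt(2.0)


@dataclass(frozen=True)
class ConcentricPhantom:
    """Cylindrical breast phantom with a glandular detail and adipose ring.

    With ``homogeneous=True`` the detail and ring are removed and the whole
    cylinder is the background mixture (used for noise studies).
    """

    diameter_cm: float
    glandularity: float
    homogeneous: bool = False

    def __post_init__(self) -> None:
        if self.diameter_cm < 2.0:
            raise ValueError("detail and ring must fit inside the cylinder (d >= 2 cm)")
        ring_area = np.pi * (RING_OUTER_RADIUS_CM**2 - DETAIL_RADIUS_CM**2)
        detail_area = np.pi * DETAIL_RADIUS_CM**2
        assert abs(ring_area - detail_area) < 1e-12 * detail_area

    @property
    def background(self) -> materials.Material:
        return materials.mixture_composition(self.glandularity)


@dataclass(frozen=True)
class Sinogram:
    """n_proj x n_det array of counts or line integrals plus scan geometry.

    ``kind`` is one of ``expected`` (mean counts), ``sampled`` (Poisson
    counts), ``line_integral``.  ``flat`` is the noiseless blank counts per
    bin (including the air path), ``mask`` flags photon-starved bins.
    """

    data: np.ndarray
    angles_rad: np.ndarray
    pixel_mm: float
    flat: float
    odd_cm: float
    kind: str
    seed: int | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != self.angles_rad.size:
            raise ValueError("data must be n_proj x n_det with matching angles")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one projection")
        a = self.angles_rad
        if a.size > 1 and not np.all(np.diff(a) > 0):
            raise ValueError("angles must be strictly increasing")
        if a.size and (a[0] < 0 or a[-1] >= np.pi):
            raise ValueError("angles must span [0, pi)")
        if self.kind in ("expected", "sampled") and np.any(self.data < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_det(self) -> int:
        return self.data.shape[1]

    def detector_coords_mm(self) -> np.ndarray:
        k = np.arange(self.n_det)
        return (k - (self.n_det - 1) / 2.0) * self.pixel_mm


def detector_grid(diameter_cm: float, pixel_mm: float) -> np.ndarray:
    """Detector bin centers (mm): ceil(d/dx) bins rounded up to odd, centered."""
    n_det = int(np.ceil(diameter_cm * 10.0 / pixel_mm))
    if n_det % 2 == 0:
        n_det += 1
    k = np.arange(n_det)
    return (k - (n_det - 1) / 2.0) * pixel_mm


def projection_angles(n_proj: int) -> np.ndarray:
    """Uniform angles over the endpoint-exclusive half turn [0, pi)."""
    return np.arange(n_proj) * np.pi / n_proj


def path_lengths(phantom: ConcentricPhantom, s_mm) -> dict[str, np.ndarray]:
    """Per-material chord lengths (cm) for rays at detector coordinate ``s_mm``.

    By concentricity the lengths are the same at every projection angle.
    Returns lengths for 'detail' (glandular), 'ring' (adipose) and
    'background' (the G mixture); they always sum to the outer chord.
    """
    s_cm = np.abs(np.asarray(s_mm, dtype=float)) / 10.0

    def chord(r: float) -> np.ndarray:
        return 2.0 * np.sqrt(np.clip(r**2 - s_cm**2, 0.0, None))

    outer = chord(phantom.diameter_cm / 2.0)
    if phantom.homogeneous:
        zeros = np.zeros_like(outer)
        return {"detail": zeros, "ring": zeros.copy(), "background": outer}
    detail = chord(DETAIL_RADIUS_CM)
    ring = chord(RING_OUTER_RADIUS_CM) - detail
    return {"detail": detail, "ring": ring, "background": outer - ring - detail}


def expected_sinogram(
    phantom: ConcentricPhantom,
    energy_keV: float,
    n_ph: float,
    n_proj: int = 1200,
    pixel_mm: float = 0.12,
    odd_cm: float = 185.0,
) -> Sinogram:
    """Expected (noiseless) counts per bin for an ideal photon counter.

    ``n_ph`` is the photon budget per pixel for the whole scan; each of the
    ``n_proj`` projections receives ``n_ph / n_proj``.  Rays pass through the
    detector-pixel centers.
    """
    if n_ph <= 0 or n_proj < 1:
        raise ValueError("need positive photon budget and at least one projection")
    s = detector_grid(phantom.diameter_cm, pixel_mm)
    lengths = path_lengths(phantom, s)
    mu_g = float(materials.linear_attenuation(materials.glandular(), energy_keV))
    mu_a = float(materials.linear_attenuation(materials.adipose(), energy_keV))
    mu_bg = float(materials.linear_attenuation(phantom.background, energy_keV))
    mu_air = float(materials.air_linear_attenuation(energy_keV))
    line = (
        mu_g * lengths["detail"]
        + mu_a * lengths["ring"]
        + mu_bg * lengths["background"]
    )
    air_t = np.exp(-mu_air * odd_cm)
    row = (n_ph / n_proj) * np.exp(-line) * air_t
    data = np.broadcast_to(row, (n_proj, s.size)).copy()
    return Sinogram(
        data=data,
        angles_rad=projection_angles(n_proj),
        pixel_mm=pixel_mm,
        flat=(n_ph / n_proj) * air_t,
        odd_cm=odd_cm,
        kind="expected",
    )


def sample_sinogram(expected: Sinogram, seed: int | np.random.SeedSequence) -> Sinogram:
    """One Poisson realization of an expected-counts sinogram."""
    if expected.kind != "expected":
        raise ValueError("sample_sinogram needs an expected-counts sinogram")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected.data).astype(np.float64)
    return replace(
        expected,
        data=counts,
        kind="sampled",
        seed=seed if isinstance(seed, int) else None,
        mask=counts == 0,
    )


def write_sinogram(sino: Sinogram, path: str) -> None:
    """Write a sinogram as 32-bit float TIFF plus a text sidecar header.

    The sidecar (``<path>.txt``) records kind, angles, pitch, flat value,
    ODD and seed, enough to rebuild the object with :func:`read_sinogram`.
    """
    import tifffile

    tifffile.imwrite(path, sino.data.astype(np.float32))
    n = sino.angles_rad.size
    with open(str(path) + ".txt", "w") as fh:
        fh.write(f"kind = {sino.kind}\n")
        fh.write(f"n_proj = {n}\n")
        fh.write(f"angle0_rad = {float(sino.angles_rad[0]):.17g}\n")
        fh.write(f"angle_step_rad = {np.pi / n:.17g}\n")
        fh.write(f"pixel_mm = {float(sino.pixel_mm):.17g}\n")
        fh.write(f"flat = {float(sino.flat):.17g}\n")
        fh.write(f"odd_cm = {float(sino.odd_cm):.17g}\n")
        fh.write(f"seed = {sino.seed}\n")


def read_sinogram(path: str) -> Sinogram:
    """Read a sinogram written by :func:`write_sinogram`."""
    import tifffile

    data = tifffile.imread(path).astype(np.float64)
    meta: dict[str, str] = {}
    with open(str(path) + ".txt") as fh:
        for line in fh:
            key, val = (t.strip() for t in line.split("=", 1))
            meta[key] = val
    n = int(meta["n_proj"])
    seed = None if meta["seed"] == "None" else int(meta["seed"])
    sino = Sinogram(
        data=data,
        angles_rad=float(meta["angle0_rad"]) + np.arange(n) * float(meta["angle_step_rad"]),
        pixel_mm=float(meta["pixel_mm"]),
        flat=float(meta["flat"]),
        odd_cm=float(meta["odd_cm"]),
        kind=meta["kind"],
        seed=seed,
    )
    if sino.kind in ("expected", "sampled"):
        sino = replace(sino, mask=data == 0)
    return sino


def to_line_integrals(sampled: Sinogram) -> Sinogram:
    """Log-normalize counts to projections p = -ln(counts / flat).

    Zero-count (photon-starved) bins keep their mask bit and receive the
    finite placeholder p = ln(flat) (i.e. counts clamped to 1); downstream
    correction interpolates them from neighbors instead.
    """
    if sampled.kind not in ("expected", "sampled"):
        raise ValueError("need a counts sinogram")
    if not sampled.flat > 0:
        raise ValueError("flat-field counts must be positive")
    mask = sampled.data == 0
    counts = np.where(mask, 1.0, sampled.data)
    p = -np.log(counts / sampled.flat)
    return replace(sampled, data=p, kind="line_integral", mask=mask)
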