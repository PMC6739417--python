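"""End-to-end studies: optimum-energy tables, normalized-curve analyses,
analytic-vs-simulated comparisons and dose series with starvation correction.

Every experiment is a pure function of its configuration and seeds; runs
write CSV tables (and float-TIFF slices where images are produced) plus a
resolved copy of the configuration next to the outputs.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bctsim import analytic, dosimetry, metrics
from bctsim.analytic import CnrCurve, beta_coefficient, energy_scan, find_optimum
from bctsim.dosimetry import BeamGeometry, DgnCache

__all__ = [
    "ScanConfig",
    "OptimumTable",
    "TABLE_DIAMETERS_CM",
    "TABLE_GLANDULARITIES",
    "make_dgn_provider",
    "run_table1",
    "run_normalized_analysis",
    "run_dose_series",
]

TABLE_DIAMETERS_CM = (8.0, 10.0, 12.0, 14.0, 16.0)
TABLE_GLANDULARITIES = (0.0, 0.143, 0.25, 0.5, 0.75, 1.0)


@dataclass
class ScanConfig:
    """Validated parameters of one acquisition/analysis run."""

    diameter_cm: float = 8.0
    glandularity: float = 0.0
    mgd_mGy: float = 20.0
    pixel_mm: float = 0.12
    energies_keV: np.ndarray = field(default_factory=analytic.default_energy_grid)
    n_proj: int = 1200
    odd_cm: float = 185.0
    algorithm: str = "fbp"
    filter_name: str = "ramlak"
    iterations: int | None = None
    seed: int = 0
    n_replicates: int = 5
    roi_erosion_px: int = 3
    mc_photons: int = 1_000_000
    geometry: BeamGeometry = field(default_factory=BeamGeometry)
    out_dir: str | None = None
    dgn_cache_path: str | None = None

    def __post_init__(self) -> None:
        if not 2.0 <= self.diameter_cm <= 30.0:
            raise ValueError("diameter must be in [2, 30] cm")
        if not 0.0 <= self.glandularity <= 1.0:
            raise ValueError("glandularity must be in [0, 1]")
        if not self.mgd_mGy > 0:
            raise ValueError("MGD must be positive")
        self.energies_keV = np.asarray(self.energies_keV, dtype=float)

    def replicate_seeds(self) -> list[int]:
        """Per-replicate seeds spawned from the master seed by counter."""
        ss = np.random.SeedSequence(self.seed)
        return [int(c.generate_state(1, np.uint32)[0]) for c in ss.spawn(self.n_replicates)]

    def write_resolved(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, np.ndarray):
                    v = ",".join(f"{x:g}" for x in v)
                elif isinstance(v, BeamGeometry):
                    v = f"{v.mode};H={v.cylinder_height_cm};h={v.beam_height_mm};ODD={v.odd_cm}"
                fh.write(f"{f.name} = {v}\n")


@dataclass(frozen=True)
class OptimumTable:
    """Rows of (d, G, E_opt, CNR_max) over the study grid."""

    table: pd.DataFrame

    def optimum(self, d: float, G: float) -> tuple[float, float]:
        row = self.table[
            np.isclose(self.table["d_cm"], d) & np.isclose(self.table["G"], G)
        ]
        if not len(row):
            raise KeyError(f"no row for d={d}, G={G}")
        return float(row["E_opt_keV"].iloc[0]), float(row["cnr_max"].iloc[0])


def make_dgn_provider(config: ScanConfig):
    """DgN_CT provider with caching and a deterministic per-point seed schedule."""
    cache = DgnCache(config.dgn_cache_path)

    def provider(d: float, G: float, E: float) -> dosimetry.DoseCoefficient:
        ss = np.random.SeedSequence(
            [config.seed, int(round(E * 10)), int(round(d * 10)), int(round(G * 1000))]
        )
        return cache.get_or_compute(
            E, d, G, config.geometry, n_photons=config.mc_photons, seed=ss
        )

    return provider


def _scan(config: ScanConfig, d: float, G: float, provider) -> CnrCurve:
    return energy_scan(
        d, G,
        mgd_mGy=config.mgd_mGy,
        pixel_mm=config.pixel_mm,
        filter_name=config.filter_name,
        energies_keV=config.energies_keV,
        dgn_provider=provider,
        odd_cm=config.odd_cm,
    )


def scan_to_frame(curve: CnrCurve, config: ScanConfig, dgn_values=None) -> pd.DataFrame:
    """Per-energy CSV payload of an analytic scan."""
    rows = []
    beta = beta_coefficient(config.filter_name, config.pixel_mm)
    for i, E in enumerate(curve.energies_keV):
        dgn_val = curve.dgn_values[i] if curve.dgn_values is not None else np.nan
        dgn = dosimetry.DoseCoefficient(
            value=dgn_val, stderr=0.0, energy_keV=E,
            diameter_cm=curve.diameter_cm, glandularity=curve.glandularity,
        )
        budget = dosimetry.photons_per_pixel(config.mgd_mGy, config.pixel_mm, E, dgn)
        sigma = analytic.sigma_center(
            curve.diameter_cm, curve.glandularity, config.mgd_mGy,
            config.pixel_mm, E, dgn, beta, config.odd_cm,
        )
        rows.append(
            dict(E_keV=E, dgn=dgn_val, K_mGy=budget.kerma_mGy,
                 N_ph=budget.photons_per_pixel, sigma_center=sigma,
                 cnr=curve.values[i], cnr_normalized=curve.values[i] / curve.values.max())
        )
    return pd.DataFrame(rows)


def run_table1(config: ScanConfig) -> OptimumTable:
    """Analytic optimum energy and CNR maximum for every (d, G) pair."""
    provider = make_dgn_provider(config)
    rows = []
    for d in TABLE_DIAMETERS_CM:
        for G in TABLE_GLANDULARITIES:
            curve = _scan(config, d, G, provider)
            e_opt, cnr_max = find_optimum(curve)
            rows.append(dict(d_cm=d, G=G, E_opt_keV=e_opt, cnr_max=cnr_max))
    table = pd.DataFrame(rows)
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        table.to_csv(os.path.join(config.out_dir, "optima.csv"), index=False)
        config.write_resolved(os.path.join(config.out_dir, "config_resolved.txt"))
    return OptimumTable(table)


def run_normalized_analysis(
    config: ScanConfig,
    d_set,
    G_set,
    e_ref_keV: float,
) -> dict:
    """Minimum over (d, G) of the max-normalized analytic CNR at ``e_ref_keV``."""
    if not len(d_set) or not len(G_set):
        raise ValueError("need nonempty parameter sets")
    provider = make_dgn_provider(config)
    per_curve = []
    for d in d_set:
        for G in G_set:
            curve = _scan(config, d, G, provider).normalize()
            per_curve.append(dict(d_cm=d, G=G, value=curve.at(e_ref_keV)))
    df = pd.DataFrame(per_curve)
    result = dict(e_ref_keV=e_ref_keV, min_normalized_cnr=float(df["value"].min()),
                  per_curve=df)
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        df.to_csv(os.path.join(config.out_dir, f"normalized_{e_ref_keV:g}keV.csv"),
                  index=False)
    return result


def run_dose_series(
    config: ScanConfig,
    mgd_list_mGy=(1.0, 2.0, 5.0, 10.0, 20.0, 200.0),
    energy_keV: float = 28.0,
    write_images: bool = False,
) -> pd.DataFrame:
    """CNR and starved-bin statistics across doses, corrected and uncorrected."""
    from bctsim import projector, reconstruction

    provider = make_dgn_provider(config)
    dgn = provider(config.diameter_cm, config.glandularity, energy_keV)
    rows = []
    masks = None
    for mgd in mgd_list_mGy:
        budget = dosimetry.photons_per_pixel(mgd, config.pixel_mm, energy_keV, dgn)
        phantom = projector.ConcentricPhantom(config.diameter_cm, config.glandularity)
        expected = projector.expected_sinogram(
            phantom, energy_keV, budget.photons_per_pixel,
            n_proj=config.n_proj, pixel_mm=config.pixel_mm, odd_cm=config.odd_cm,
        )
        for corrected in (False, True):
            values, starved = [], []
            for k, sd in enumerate(config.replicate_seeds()):
                sampled = projector.sample_sinogram(expected, sd)
                starved.append(int((sampled.data == 0).sum()))
                sino = (
                    reconstruction.starvation_correct(sampled) if corrected else sampled
                )
                rec = reconstruction.fbp(
                    projector.to_line_integrals(sino), config.filter_name
                )
                if masks is None:
                    masks = metrics.roi_masks(
                        rec.image.shape[0], rec.pixel_mm, config.roi_erosion_px
                    )
                values.append(metrics.cnr_sim(rec, masks).cnr)
                if write_images and config.out_dir and k == 0:
                    os.makedirs(config.out_dir, exist_ok=True)
                    tag = "corr" if corrected else "raw"
                    reconstruction.write_slice(
                        rec,
                        os.path.join(config.out_dir, f"slice_{mgd:g}mGy_{tag}.tif"),
                    )
            rows.append(
                dict(mgd_mGy=mgd, corrected=corrected,
                     cnr_mean=float(np.mean(values)),
                     cnr_std=float(np.std(values, ddof=1)),
                     starved_bins_mean=float(np.mean(starved)),
                     n_rep=len(values))
            )
    df = pd.DataFrame(rows)
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        df.to_csv(os.path.join(config.out_dir, "dose_series.csv"), index=False)
        config.write_resolved(os.path.join(config.out_dir, "config_resolved.txt"))
    return df
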