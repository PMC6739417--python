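"""Shared fixtures.

The expensive object is the DgN_CT(E, d, G) table over the full study grid
(5 diameters x 6 glandularities x 41 energies at 1e6 MC photons per point);
it is computed once per session, lazily, and shared by the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from bctsim import analytic, dosimetry

MASTER_SEED = 1


def dgn_seed(seed: int, d: float, G: float, E: float) -> np.random.SeedSequence:
    """The package's deterministic per-point seed schedule."""
    return np.random.SeedSequence(
        [seed, int(round(E * 10)), int(round(d * 10)), int(round(G * 1000))]
    )


class DgnGrid:
    """Lazily computed, memoized DgN_CT coefficients at study conditions."""

    def __init__(self, n_photons: int = 1_000_000, seed: int = MASTER_SEED) -> None:
        self.n_photons = n_photons
        self.seed = seed
        self._memo: dict[tuple, dosimetry.DoseCoefficient] = {}

    def __call__(self, d: float, G: float, E: float) -> dosimetry.DoseCoefficient:
        key = (round(d, 3), round(G, 4), round(E, 2))
        if key not in self._memo:
            self._memo[key] = dosimetry.dgn_ct_monte_carlo(
                d, G, E, n_photons=self.n_photons, seed=dgn_seed(self.seed, d, G, E)
            )
        return self._memo[key]

    def curve(self, d: float, G: float, filter_name: str = "ramlak") -> analytic.CnrCurve:
        return analytic.energy_scan(d, G, dgn_provider=self)


@pytest.fixture(scope="session")
def dgn_grid() -> DgnGrid:
    return DgnGrid()
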