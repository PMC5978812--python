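"""Deterministic synthetic inputs for tests and examples.

Everything here is generated programmatically: preset experimental summary
tables (the printed per-class means for *Xenopus laevis* stage-10 animal-cap
epithelium), regular lattices and noise-perturbed lattices for off-
equilibrium property tests.  No fixture emulates raw microscopy data.
"""

from __future__ import annotations

import numpy as np

from .fitting import ClassSummaryTable
from .geometry import TissueNetwork, validate_network
from .tessellation import hexagonal_lattice

__all__ = ["EXPERIMENT_PRESETS", "make_experiment_table", "perturbed_lattice"]

#: Published per-class summary vectors (classes 4, 5, 6, 7, 8+).
EXPERIMENT_PRESETS = {
    "xenopus-stage10": {
        "mean_norm_area": (0.59, 0.80, 1.03, 1.20, 1.60),
        "mean_circularity": (0.56, 0.58, 0.58, 0.57, 0.53),
    },
}


def make_experiment_table(profile="xenopus-stage10",
                          mean_circularity=None,
                          counts=None) -> ClassSummaryTable:
    """Experimental summary table from a named preset or explicit vectors.

    ``profile`` is either a preset name or a 5-vector of mean normalised
    areas for classes 4..8+.
    """
    if isinstance(profile, str):
        try:
            preset = EXPERIMENT_PRESETS[profile]
        except KeyError:
            raise KeyError(
                f"unknown preset {profile!r}; available: "
                f"{sorted(EXPERIMENT_PRESETS)}") from None
        return ClassSummaryTable.from_vectors(
            preset["mean_norm_area"], preset["mean_circularity"], counts)
    return ClassSummaryTable.from_vectors(profile, mean_circularity, counts)


def perturbed_lattice(a_cell: float = 1.0, n_x: int = 4, n_y: int = 4,
                      noise_amplitude: float = 0.05, seed: int = 0,
                      max_retries: int = 20) -> TissueNetwork:
    """Honeycomb lattice with i.i.d. uniform vertex displacements.

    A controlled-disorder fixture for gradient and stress property tests
    away from equilibrium.  The displacement amplitude is in units of the
    hexagon side; draws that break polygon simplicity are resampled.
    """
    base = hexagonal_lattice(a_cell, n_x, n_y)
    if noise_amplitude == 0.0:
        return base
    s = np.sqrt(2.0 * a_cell / (3.0 * np.sqrt(3.0)))
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        net = base.copy()
        net.vertices = net.vertices + rng.uniform(
            -noise_amplitude * s, noise_amplitude * s,
            size=net.vertices.shape)
        net.canonicalize()
        report = validate_network(net)
        if report.ok:
            return net
    raise RuntimeError(
        "could not draw a simple perturbed lattice; reduce noise_amplitude")
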