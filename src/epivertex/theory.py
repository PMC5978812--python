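"""Closed-form results for regular polygons and the (Lambda, Gamma) map.

A regular N-gon satisfies L = mu_N sqrt(A) with mu_N = 2 (N tan(pi/N))^{1/2}
(mu_6 ~ 3.72, decreasing to the circle limit 2 sqrt(pi)).  Its effective
pressure is

    P_eff_N(A) = A - 1 + Gamma mu_N^2 / 2 + Lambda mu_N / (4 sqrt(A)),

whose zero-load root A_N* (in x = sqrt(A): x^3 + (Gamma mu_N^2/2 - 1) x +
Lambda mu_N / 4 = 0) fixes the equilibrium cell area.  The structure of
this cubic partitions parameter space (Gamma > 0) into:

* region I   — Lambda < -2 mu_6 Gamma: soft network, no shear resistance;
* region IIa — -2 mu_6 Gamma <= Lambda <= 0: a single stress-free state;
* region IIb — Lambda > 0 below the repeated-root curve
  Lambda = 8/(3^{3/2} mu_6) (1 - Gamma mu_6^2/2)^{3/2}: two equilibria;
* region III — no positive equilibrium area (network collapse).

An isotropic boundary load P_ext > -1 maps onto an equivalent unloaded
problem through the "dagger" rescaling A -> A/(1+P_ext),
Gamma -> Gamma/(1+P_ext), Lambda -> Lambda/(1+P_ext)^{3/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanics import ModelParams

__all__ = [
    "mu_N",
    "MU6",
    "peff_regular",
    "equilibrium_areas",
    "RegionLabel",
    "classify_region",
    "dagger_transform",
    "inverse_dagger",
    "bulk_modulus_hex",
    "bulk_modulus",
    "shear_modulus_hex",
]


def mu_N(n: int) -> float:
    """Perimeter-to-sqrt-area constant of a regular N-gon."""
    if n < 3:
        raise ValueError("polygons have at least 3 sides")
    return float(2.0 * np.sqrt(n * np.tan(np.pi / n)))


MU6 = mu_N(6)


def peff_regular(area: float, n: int, params: ModelParams) -> float:
    """Effective pressure of a regular N-gon of the given area."""
    a = np.asarray(area, dtype=float)
    if np.any(a <= 0):
        raise ValueError("area must be positive")
    mu = mu_N(n)
    out = a - 1.0 + 0.5 * params.gam * mu**2 + params.lam * mu / (4.0 * np.sqrt(a))
    return out if out.ndim else float(out)


def _depressed_cubic_roots(c1: float, c0: float) -> np.ndarray:
    """Real roots of x^3 + c1 x + c0 = 0 via the discriminant (trigonometric
    form for three real roots, Cardano otherwise); repeated roots near the
    discriminant-zero locus are resolved explicitly."""
    if c0 == 0.0:
        roots = [0.0]
        if c1 < 0:
            roots += [np.sqrt(-c1), -np.sqrt(-c1)]
        return np.array(roots)
    disc = -4.0 * c1**3 - 27.0 * c0**2
    scale = max(abs(c1) ** 1.5, abs(c0), 1e-300)
    if abs(disc) <= 1e-12 * scale**2 and c1 < 0:
        # repeated root: x^3 + c1 x + c0 = (x - r)^2 (x + 2r)
        r = -3.0 * c0 / (2.0 * c1)
        return np.array([r, r, -2.0 * r])
    if disc > 0:
        # three distinct real roots
        m = 2.0 * np.sqrt(-c1 / 3.0)
        theta = np.arccos(np.clip(3.0 * c0 / (c1 * m), -1.0, 1.0))
        k = np.arange(3)
        return m * np.cos(theta / 3.0 - 2.0 * np.pi * k / 3.0)
    # one real root (Cardano)
    q = np.sqrt(c0**2 / 4.0 + c1**3 / 27.0)
    u = np.cbrt(-c0 / 2.0 + q)
    v = np.cbrt(-c0 / 2.0 - q)
    return np.array([u + v])


def equilibrium_areas(n: int, params: ModelParams, p_ext: float = 0.0,
                      ) -> np.ndarray:
    """Positive roots A_N* of P_eff_N(A) = p_ext, largest (primary) first.

    Returns an empty array when no positive equilibrium exists (region-III
    behaviour).  In the bistable region IIb two areas are returned; the
    larger is the one used for simulation thresholds.
    """
    if params.gam <= 0:
        raise ValueError("equilibrium areas require Gamma > 0")
    mu = mu_N(n)
    c1 = 0.5 * params.gam * mu**2 - 1.0 - p_ext
    c0 = 0.25 * params.lam * mu
    x = _depressed_cubic_roots(c1, c0)
    x = np.unique(np.round(x[x > 1e-12], 14))
    return np.sort(x**2)[::-1]


@dataclass(frozen=True)
class RegionLabel:
    """Parameter-space region of a (Lambda, Gamma) pair with signed
    distances (in Lambda) to the bounding curves."""

    label: str                      # "I", "IIa", "IIb" or "III"
    lam: float
    gam: float
    dist_soft_boundary: float       # Lambda - (-2 mu_6 Gamma)
    dist_collapse_boundary: float   # repeated-root curve Lambda_c - Lambda
                                    # (nan where the curve does not exist)

    def __str__(self) -> str:
        return self.label


def _lambda_repeated_root(gam: float) -> float:
    """Repeated-root boundary Lambda_c(Gamma) for 0 < Gamma < 2/mu_6^2."""
    return 8.0 / (3.0**1.5 * MU6) * (1.0 - 0.5 * gam * MU6**2) ** 1.5


def classify_region(params: ModelParams) -> RegionLabel:
    """Classify (Lambda, Gamma) into regions I / IIa / IIb / III."""
    lam, gam = params.lam, params.gam
    if gam <= 0:
        raise ValueError("region classification requires Gamma > 0")
    soft = lam - (-2.0 * MU6 * gam)
    if gam < 2.0 / MU6**2:
        lam_c = _lambda_repeated_root(gam)
        collapse = lam_c - lam
    else:
        lam_c = None
        collapse = float("nan")
    if soft < 0:
        label = "I"
    elif lam <= 0:
        label = "III" if (lam == 0 and gam > 2.0 / MU6**2) else "IIa"
    elif lam_c is not None and lam < lam_c:
        label = "IIb"
    else:
        label = "III"
    return RegionLabel(label=label, lam=lam, gam=gam,
                       dist_soft_boundary=soft,
                       dist_collapse_boundary=collapse)


def dagger_transform(params: ModelParams, p_ext: float | None = None,
                     ) -> tuple[ModelParams, float]:
    """Map a loaded problem to its unloaded equivalent.

    Returns ``(params_dagger, area_scale)`` with area_scale = 1/(1+P_ext):
    if P_eff_6(A; Gamma, Lambda) = P_ext then
    P_eff_6(A * area_scale; Gamma^dagger, Lambda^dagger) = 0.
    """
    pe = params.p_ext if p_ext is None else p_ext
    if pe <= -1.0:
        raise ValueError("dagger transform requires P_ext > -1")
    s = 1.0 + pe
    return (ModelParams(lam=params.lam / s**1.5, gam=params.gam / s, p_ext=0.0),
            1.0 / s)


def inverse_dagger(params_dagger: ModelParams, p_ext: float) -> ModelParams:
    """Native (Lambda, Gamma) whose dagger image at load P_ext is the given
    pair."""
    if p_ext <= -1.0:
        raise ValueError("inverse dagger requires P_ext > -1")
    s = 1.0 + p_ext
    return ModelParams(lam=params_dagger.lam * s**1.5,
                       gam=params_dagger.gam * s, p_ext=p_ext)


# ---------------------------------------------------------------------------
# elastic moduli
# ---------------------------------------------------------------------------

def bulk_modulus_hex(params: ModelParams, cell_area: float) -> float:
    """Bulk modulus of a uniform hexagonal monolayer,
    K = A - Lambda mu_6 / (8 sqrt(A)) (dimensionless, units of K A_0)."""
    if cell_area <= 0:
        raise ValueError("cell area must be positive")
    return float(cell_area - params.lam * MU6 / (8.0 * np.sqrt(cell_area)))


def bulk_modulus(network, params: ModelParams, load_tol: float = 1e-2) -> float:
    """Bulk modulus of a disordered monolayer at zero-load equilibrium:
    K = sum_a (A_a / 2A) [2 A_a + Gamma L_0 L_a / (2 A_a)].

    Refuses a network whose area-weighted mean effective pressure is not
    (close to) zero, since the linearisation is about the unloaded state.
    """
    from .mechanics import cell_stress
    geos = network.cell_geometries()
    areas = np.array([g.area for g in geos])
    perims = np.array([g.perimeter for g in geos])
    peff = np.array([cell_stress(g, params).p_eff for g in geos])
    mean_peff = float(np.sum(areas * peff) / np.sum(areas))
    if abs(mean_peff) > load_tol:
        raise ValueError(
            f"network is not at zero-load equilibrium (mean P_eff = "
            f"{mean_peff:.3g}); relax and enforce the load condition first"
        )
    a_tot = areas.sum()
    return float(np.sum(
        (areas / (2.0 * a_tot))
        * (2.0 * areas + params.gam * params.l0 * perims / (2.0 * areas))))


def shear_modulus_hex(params: ModelParams, cell_area: float | None = None,
                      perimeter: float | None = None) -> float:
    """Shear modulus of a uniform hexagonal monolayer,
    G = 3 sqrt(3) Gamma (1 - L_0 / L); positive iff the cell walls are under
    tension (L > L_0).  Provide either the cell area (L = mu_6 sqrt(A)) or
    the perimeter directly."""
    if perimeter is None:
        if cell_area is None or cell_area <= 0:
            raise ValueError("provide cell_area > 0 or perimeter")
        perimeter = MU6 * np.sqrt(cell_area)
    return float(3.0 * np.sqrt(3.0) * params.gam * (1.0 - params.l0 / perimeter))
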