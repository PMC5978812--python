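"""Polygonal-class shape statistics and likelihood fitting.

Segmented epithelia are summarised by the mean normalised cell area per
polygonal class (4-gons, 5-gons, ..., pooled "8+"), areas being normalised
to the population mean of each experiment.  Model parameters (Lambda,
Gamma) are fitted by maximising the log-likelihood

    ln P(Lambda, Gamma | A_exp) = - ln( sum_{i=4}^{8+} |A_i_exp - A_i_sim|^2 )

over a grid of region-II parameter points, each evaluated from several
independent simulated monolayers.  Triangles are never observed
experimentally and are excluded from the sum (reported separately if any
survive in simulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import RelaxationSettings, generate_monolayer
from .geometry import TissueNetwork
from .mechanics import ModelParams
from .theory import classify_region, inverse_dagger

__all__ = [
    "CLASS_LABELS",
    "ClassSummaryTable",
    "class_summary",
    "log_likelihood",
    "FitResult",
    "grid_fit",
    "pext_scan",
]

#: classes entering the likelihood; polygon classes >= 8 pool into "8+"
CLASS_LABELS = ("4", "5", "6", "7", "8+")

_LIKELIHOOD_EPS = 1e-12


@dataclass(frozen=True)
class ClassSummaryTable:
    """Per-polygonal-class summary of a cell population.

    ``table`` is indexed by class label with columns ``count``,
    ``proportion``, ``mean_norm_area``, ``mean_circularity`` and
    ``total_area_fraction``; areas are normalised by the pooled population
    mean, so the count-weighted mean of ``mean_norm_area`` is 1.  Classes
    with no cells keep count 0 and NaN means.  Triangle statistics, when
    present, are carried separately (``n_triangles``) and excluded from
    the likelihood classes.
    """

    table: pd.DataFrame
    mean_area: float            # normalisation constant (population mean)
    n_cells: int
    n_triangles: int = 0

    def area_vector(self) -> np.ndarray:
        """Mean normalised areas over classes 4..8+ (NaN where absent)."""
        return self.table["mean_norm_area"].to_numpy(dtype=float)

    def circularity_vector(self) -> np.ndarray:
        return self.table["mean_circularity"].to_numpy(dtype=float)

    @classmethod
    def from_vectors(cls, mean_norm_area, mean_circularity=None,
                     counts=None) -> "ClassSummaryTable":
        """Build a summary table from explicit per-class vectors
        (classes 4, 5, 6, 7, 8+)."""
        areas = np.asarray(mean_norm_area, dtype=float)
        if areas.size != len(CLASS_LABELS):
            raise ValueError(f"expected {len(CLASS_LABELS)} per-class values")
        circ = (np.full(areas.size, np.nan) if mean_circularity is None
                else np.asarray(mean_circularity, dtype=float))
        if circ.size != areas.size:
            raise ValueError("circularity vector has wrong length")
        n = (np.zeros(areas.size) if counts is None
             else np.asarray(counts, dtype=float))
        total = n.sum()
        prop = n / total if total > 0 else np.full(areas.size, np.nan)
        frac = (n * areas / np.nansum(n * areas) if total > 0
                else np.full(areas.size, np.nan))
        df = pd.DataFrame({
            "count": n.astype(int), "proportion": prop,
            "mean_norm_area": areas, "mean_circularity": circ,
            "total_area_fraction": frac,
        }, index=pd.Index(CLASS_LABELS, name="class"))
        return cls(table=df, mean_area=float("nan"), n_cells=int(total))


def class_summary(networks: TissueNetwork | list[TissueNetwork],
                  ) -> ClassSummaryTable:
    """Pool one or more networks into a per-polygonal-class summary."""
    if isinstance(networks, TissueNetwork):
        networks = [networks]
    if not networks:
        raise ValueError("no networks given")
    rows = []
    for net in networks:
        for a in range(net.n_cells):
            g = net.cell_geometry(a)
            rows.append((g.n_sides, g.area, g.circularity))
    if not rows:
        raise ValueError("networks contain no cells")
    df = pd.DataFrame(rows, columns=["z", "area", "circ"])
    mean_area = float(df["area"].mean())
    df["norm_area"] = df["area"] / mean_area
    n_triangles = int((df["z"] == 3).sum())
    df = df[df["z"] >= 4].copy()
    df["label"] = np.where(df["z"] >= 8, "8+", df["z"].astype(str))
    grouped = df.groupby("label")
    agg = pd.DataFrame({
        "count": grouped.size(),
        "mean_norm_area": grouped["norm_area"].mean(),
        "mean_circularity": grouped["circ"].mean(),
        "total_area": grouped["norm_area"].sum(),
    }).reindex(CLASS_LABELS)
    agg["count"] = agg["count"].fillna(0).astype(int)
    agg["proportion"] = agg["count"] / agg["count"].sum()
    agg["total_area_fraction"] = agg["total_area"] / df["norm_area"].sum()
    out = agg[["count", "proportion", "mean_norm_area", "mean_circularity",
               "total_area_fraction"]]
    out.index.name = "class"
    return ClassSummaryTable(table=out, mean_area=mean_area,
                             n_cells=int(len(df)), n_triangles=n_triangles)


def log_likelihood(sim: ClassSummaryTable, exp: ClassSummaryTable) -> float:
    """Negative log of the summed squared per-class area residuals.

    A simulated class with no cells (NaN mean) contributes the squared
    experimental mean for that class — the maximal penalty, since the
    model then predicts the class absent.  A residual sum of exactly zero
    is capped at ``-ln(1e-12)`` (flagged perfect fit).
    """
    a_sim = sim.area_vector()
    a_exp = exp.area_vector()
    if np.any(np.isnan(a_exp)):
        raise ValueError("experimental table must cover classes 4..8+")
    resid = np.where(np.isnan(a_sim), a_exp, a_exp - a_sim)
    ss = float(np.sum(resid**2))
    return -float(np.log(max(ss, _LIKELIHOOD_EPS)))


@dataclass(frozen=True)
class FitResult:
    """Likelihood surface over a (Lambda, Gamma) grid."""

    lam_values: np.ndarray
    gam_values: np.ndarray
    log_like: np.ndarray        # (n_gam, n_lam), NaN outside region II
    regions: np.ndarray         # (n_gam, n_lam) of region labels
    best: ModelParams
    n_realizations: int
    n_cells: int
    seed: int

    @property
    def argmax_index(self) -> tuple[int, int]:
        flat = np.nanargmax(self.log_like)
        return np.unravel_index(flat, self.log_like.shape)

    def to_frame(self) -> pd.DataFrame:
        ig, il = np.meshgrid(range(self.gam_values.size),
                             range(self.lam_values.size), indexing="ij")
        return pd.DataFrame({
            "lam": self.lam_values[il.ravel()],
            "gam": self.gam_values[ig.ravel()],
            "region": self.regions.ravel(),
            "log_likelihood": self.log_like.ravel(),
        })


def _pooled_summary(params: ModelParams, n_realizations: int, n_cells: int,
                    seeds, settings: RelaxationSettings | None,
                    ) -> ClassSummaryTable:
    nets = [generate_monolayer(params, n_cells, seed=int(s),
                               settings=settings)
            for s in seeds]
    return class_summary(nets)


def grid_fit(exp: ClassSummaryTable, lam_values, gam_values,
             n_realizations: int = 5, n_cells: int = 800, seed: int = 0,
             settings: RelaxationSettings | None = None,
             verbose: bool = False) -> FitResult:
    """Evaluate the likelihood over a parameter grid and locate its peak.

    Grid points outside region II (or on its boundaries in region I / III)
    are skipped.  Each point pools ``n_realizations`` monolayers of
    ``n_cells`` cells; all simulation seeds derive deterministically from
    ``seed``.
    """
    lam_values = np.asarray(lam_values, dtype=float)
    gam_values = np.asarray(gam_values, dtype=float)
    surface = np.full((gam_values.size, lam_values.size), np.nan)
    regions = np.empty(surface.shape, dtype=object)
    ss = np.random.SeedSequence(seed)
    any_ok = False
    best = None
    for ig, gam in enumerate(gam_values):
        for il, lam in enumerate(lam_values):
            params = ModelParams(lam=float(lam), gam=float(gam))
            label = classify_region(params).label
            regions[ig, il] = label
            if label not in ("IIa", "IIb"):
                continue
            child = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(ig, il))
            seeds = child.generate_state(n_realizations) % (2**31)
            try:
                sim = _pooled_summary(params, n_realizations, n_cells,
                                      seeds, settings)
            except (RuntimeError, ValueError):
                continue
            ll = log_likelihood(sim, exp)
            surface[ig, il] = ll
            any_ok = True
            if best is None or ll > best[0]:
                best = (ll, params)
            if verbose:
                print(f"  (Lam, Gam) = ({lam:+.3f}, {gam:.3f}) [{label}]  "
                      f"lnL = {ll:.3f}")
    if not any_ok:
        raise ValueError("no feasible region-II grid point")
    return FitResult(lam_values=lam_values, gam_values=gam_values,
                     log_like=surface, regions=regions, best=best[1],
                     n_realizations=n_realizations, n_cells=n_cells,
                     seed=seed)


def pext_scan(dagger_params: ModelParams, pext_values, n_cells: int = 800,
              n_realizations: int = 1, seed: int = 0,
              settings: RelaxationSettings | None = None,
              ) -> list[tuple[float, ClassSummaryTable]]:
    """Scan boundary pressure at fixed dagger parameters.

    For each P_ext the native parameters are recovered by inverting the
    dagger rescaling (so the system stays at an equivalent point of the
    unloaded parameter map) and a monolayer is equilibrated at that load.
    Returns ``(p_ext, summary)`` pairs; points whose native parameters
    leave region II are skipped with a warning.
    """
    import warnings
    ss = np.random.SeedSequence(seed)
    out = []
    for k, pe in enumerate(pext_values):
        params = inverse_dagger(dagger_params, float(pe))
        label = classify_region(params).label
        if label not in ("IIa", "IIb"):
            warnings.warn(
                f"P_ext = {pe}: native parameters fall in region {label}; "
                "skipped", stacklevel=2)
            continue
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(k,))
        seeds = child.generate_state(n_realizations) % (2**31)
        summary = _pooled_summary(params, n_realizations, n_cells, seeds,
                                  settings)
        out.append((float(pe), summary))
    return out
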