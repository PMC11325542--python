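"""Geometry-space clustering, density maps and census tables.

A full-covariance Gaussian mixture (non-spherical clusters) groups pair
geometries; each component contributes one representative — the member
nearest the component mean by Mahalanobis distance — for downstream export.
Density maps are integer 2-D histograms over fixed half-open bins, with
optional symmetrized counting for homotypic (X–X) pairs where the
reference/partner assignment was arbitrary.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pair_mining import ResiduePair
from .protonation import tautomer_from_deuterium
from .structure_io import Residue, Structure

__all__ = [
    "ClusterModel",
    "DensityMap",
    "cluster_geometries",
    "density_map",
    "tautomer_census",
    "representative_export",
    "aromatic_feature_matrix",
    "cation_feature_matrix",
]

AROMATIC_FEATURES = ("D", "P", "T_theta1", "T_theta2")
CATION_FEATURES = ("D", "theta1", "theta2")


@dataclass
class ClusterModel:
    k: int
    means: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray
    seed: int
    assignments: np.ndarray
    representatives: tuple[int, ...]  # row indices into the input feature matrix
    bic: float
    feature_names: tuple[str, ...] = ()


@dataclass
class DensityMap:
    x_param: str
    y_param: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # integer grid, shape (len(x_edges)-1, len(y_edges)-1)
    symmetrized: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def aromatic_feature_matrix(geoms) -> np.ndarray:
    """(n, 4) matrix of (D, P, Tθ1, Tθ2)."""
    return np.asarray([[g.D, g.P, g.T_theta1, g.T_theta2] for g in geoms], dtype=float)


def cation_feature_matrix(geoms, include_theta2: bool | None = None) -> np.ndarray:
    """(n, 2) or (n, 3) matrix of (D, θ1[, θ2]).

    θ2 is included only when present on every geometry (the dimensionality
    must be fixed within one clustering run).
    """
    if include_theta2 is None:
        include_theta2 = all(g.theta2 is not None for g in geoms)
    if include_theta2:
        return np.asarray([[g.D, g.theta1, g.theta2] for g in geoms], dtype=float)
    return np.asarray([[g.D, g.theta1] for g in geoms], dtype=float)


def cluster_geometries(
    features: np.ndarray,
    k_or_auto: int | str = "auto",
    seed: int = 0,
    k_range: tuple[int, int] = (2, 12),
    standardize: bool = False,
    feature_names: Sequence[str] = (),
) -> ClusterModel:
    """Fit a full-covariance Gaussian mixture and pick representatives.

    ``k_or_auto="auto"`` selects the component count by minimum BIC over
    ``k_range`` (clipped to the sample count).  Refitting with the same seed
    reproduces assignments and representatives exactly.
    """
    from sklearn.mixture import GaussianMixture

    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a non-empty 2-D array")
    n = X.shape[0]
    spans = X.max(axis=0) - X.min(axis=0)
    if np.any(spans == 0.0):
        raise ValueError("degenerate (zero-variance) feature column")
    scale = X.std(axis=0, ddof=0) if standardize else np.ones(X.shape[1])
    Z = X / scale

    def fit(k: int):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=1e-6,
            random_state=seed,
            n_init=1,
        )
        gm.fit(Z)
        return gm

    if k_or_auto == "auto":
        lo, hi = k_range
        candidates = range(max(1, lo), min(hi, n) + 1)
        if not len(list(candidates)):
            raise ValueError(f"no feasible component count in {k_range} for n={n}")
        best, best_bic = None, math.inf
        for k in candidates:
            gm = fit(k)
            bic = gm.bic(Z)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
        gm = best
    else:
        k = int(k_or_auto)
        if k > n:
            raise ValueError(f"k={k} exceeds number of observations n={n}")
        gm = fit(k)

    assignments = gm.predict(Z)
    reps = []
    for j in range(gm.n_components):
        members = np.flatnonzero(assignments == j)
        if members.size == 0:
            members = np.arange(n)
        prec = np.linalg.inv(gm.covariances_[j])
        diffs = Z[members] - gm.means_[j]
        maha = np.einsum("ij,jk,ik->i", diffs, prec, diffs)
        reps.append(int(members[int(np.argmin(maha))]))

    return ClusterModel(
        k=gm.n_components,
        means=gm.means_ * scale,
        covariances=gm.covariances_ * np.outer(scale, scale),
        weights=gm.weights_,
        seed=seed,
        assignments=assignments,
        representatives=tuple(reps),
        bic=float(gm.bic(Z)),
        feature_names=tuple(feature_names),
    )


def _get_param(geom, name: str) -> float:
    if isinstance(geom, Mapping):
        return float(geom[name])
    return float(getattr(geom, name))


def _swapped_param(name: str) -> str:
    return {"T_theta1": "T_theta2", "T_theta2": "T_theta1"}.get(name, name)


def density_map(
    geoms,
    x_param: str,
    y_param: str,
    bin_width_x: float = 5.0,
    bin_width_y: float = 5.0,
    symmetrize_homotypic: bool = False,
) -> DensityMap:
    """2-D count histogram of two descriptors over half-open bins [a, b).

    ``symmetrize_homotypic`` doubles each observation by also counting it
    with the two elevation angles exchanged — used for X–X pairs where the
    reference member was an arbitrary choice.  Default bin widths follow the
    published maps (5° angles / 0.25 Å distances at call sites).
    """
    geoms = list(geoms)
    if not geoms:
        raise ValueError("density_map: empty input")
    obs = [( _get_param(g, x_param), _get_param(g, y_param)) for g in geoms]
    if symmetrize_homotypic:
        obs += [
            (_get_param(g, _swapped_param(x_param)), _get_param(g, _swapped_param(y_param)))
            for g in geoms
        ]
    xs = np.asarray([o[0] for o in obs])
    ys = np.asarray([o[1] for o in obs])
    x0 = math.floor(xs.min() / bin_width_x) * bin_width_x
    y0 = math.floor(ys.min() / bin_width_y) * bin_width_y
    ix = np.floor((xs - x0) / bin_width_x).astype(int)
    iy = np.floor((ys - y0) / bin_width_y).astype(int)
    nx, ny = int(ix.max()) + 1, int(iy.max()) + 1
    counts = np.zeros((nx, ny), dtype=int)
    np.add.at(counts, (ix, iy), 1)
    x_edges = x0 + bin_width_x * np.arange(nx + 1)
    y_edges = y0 + bin_width_y * np.arange(ny + 1)
    return DensityMap(
        x_param=x_param,
        y_param=y_param,
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        symmetrized=symmetrize_homotypic,
    )


def tautomer_census(structures) -> dict[str, int]:
    """Counts of deuterium-assigned His tautomers over all structures.

    Not-determinable His are excluded from the three tautomer counts but
    reported under their own key.
    """
    counts = {"epsilon0": 0, "delta0": 0, "positive": 0, "not_determinable": 0}
    for structure in structures:
        for res in structure.residues:
            if res.name != "HIS":
                continue
            counts[tautomer_from_deuterium(res).state] += 1
    return counts


def representative_export(
    model: ClusterModel,
    pairs: Sequence[ResiduePair],
    structures: Mapping[str, Structure],
    features: np.ndarray | None = None,
) -> list[dict]:
    """Coordinate bundles for the model's representative pairs.

    Each bundle carries the two residues as a standalone two-residue
    :class:`Structure` plus provenance (structure id, residue ids, feature
    vector, component id); write them with :func:`hispi.structure_io.write_pdb`.
    """
    bundles = []
    for component, idx in enumerate(model.representatives):
        pair = pairs[idx]
        source = structures[pair.structure_id]
        residues = [source.find_residue(pair.ref_id), source.find_residue(pair.partner_id)]
        if any(r is None for r in residues):
            raise ValueError(f"representative pair {pair.ref_id}/{pair.partner_id} not found")
        bundles.append(
            {
                "component": component,
                "pair_index": int(idx),
                "structure_id": pair.structure_id,
                "ref_id": pair.ref_id,
                "partner_id": pair.partner_id,
                "family": pair.family,
                "feature_vector": (
                    np.asarray(features[idx], dtype=float).tolist()
                    if features is not None
                    else None
                ),
                "structure": Structure(
                    id=f"{pair.structure_id}_rep{component}",
                    residues=[dataclasses.replace(r) for r in residues],
                ),
            }
        )
    return bundles
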