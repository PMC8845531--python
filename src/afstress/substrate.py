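"""Fibrosis-type substrate variants.

Builds the four substrate compositions probed by the stress-test battery:
``combination`` (interstitial edge decoupling + conductivity scaling +
ionic remodeling), ``conduction_only`` (conductivity + ionic, no
decoupling), ``interstitial`` (decoupling only), and ``none`` (healthy).
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cohort import IIR_THRESHOLD, FibrosisMap, generate_fibers
from .ep import CellModelParams, ConductivityField, SubstrateModel, iir_to_conductivity
from .geometry import SurfaceMesh


class FibrosisType(Enum):
    """Substrate compositions, indexed 1-4 in battery order."""

    COMBINATION = "combination"
    CONDUCTION_ONLY = "conduction_only"
    INTERSTITIAL = "interstitial"
    NONE = "none"


#: apd_scale applied at fibrotic vertices for the ionic-remodeling component
FIBROTIC_APD_SCALE = 0.85


def decouple_interstitial_edges(mesh: SurfaceMesh, fibrosis_map: FibrosisMap,
                                seed: int, p_max: float = 0.5,
                                iir_ceiling: float = 1.6,
                                density_rule=None) -> np.ndarray:
    """Select interior edges to decouple as interstitial fibrosis.

    Each interior edge whose mean endpoint IIR exceeds the fibrosis
    threshold is decoupled with probability ``density_rule(mean_iir)``
    (default: linear 0 -> ``p_max`` over threshold -> ``iir_ceiling``).
    Sampling uses one uniform draw per edge compared against the
    probability, so for a fixed seed the decoupled set is nested
    (monotone) in the density rule. If the selection would split the
    mesh into more than one excitable component, a minimal subset of
    selected edges is re-coupled to restore connectivity (deterministic
    repair). Returns a (k, 2) vertex-pair array.
    """
    if density_rule is None:
        def density_rule(x):
            return np.clip(p_max * (x - IIR_THRESHOLD) / (iir_ceiling - IIR_THRESHOLD),
                           0.0, p_max if p_max <= 1 else 1.0)
    edges = mesh.edges
    mean_iir = fibrosis_map.iir[edges].mean(axis=1)
    p = np.asarray(density_rule(mean_iir), dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("density rule must map iir to probabilities in [0, 1]")
    p = np.where(mean_iir > fibrosis_map.threshold, p, 0.0)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDEC0]))
    sel = rng.random(len(edges)) < p
    if not sel.any():
        return np.empty((0, 2), dtype=np.int64)

    kept = edges[~sel]
    n = mesh.n_vertices
    graph = csr_matrix((np.ones(2 * len(kept)),
                        (np.concatenate([kept[:, 0], kept[:, 1]]),
                         np.concatenate([kept[:, 1], kept[:, 0]]))), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        # repair: re-couple selected edges that bridge components, in
        # seeded random order (index order would carve straight fast paths)
        sel_idx = rng.permutation(np.flatnonzero(sel))
        for ei in sel_idx:
            a, b = edges[ei]
            if labels[a] != labels[b]:
                sel[ei] = False
                labels[labels == labels[b]] = labels[a]
        # labels merging above is a greedy union; verify once more
        kept = edges[~sel]
        graph = csr_matrix((np.ones(2 * len(kept)),
                            (np.concatenate([kept[:, 0], kept[:, 1]]),
                             np.concatenate([kept[:, 1], kept[:, 0]]))), shape=(n, n))
        n_comp, labels = connected_components(graph, directed=False)
        if n_comp > 1:  # pragma: no cover - greedy repair suffices in practice
            sel_idx = rng.permutation(np.flatnonzero(sel))
            for ei in sel_idx:
                a, b = edges[ei]
                if labels[a] != labels[b]:
                    sel[ei] = False
                    lb = labels[b]
                    labels[labels == lb] = labels[a]
    return edges[sel].astype(np.int64)


def build_substrate(mesh: SurfaceMesh, fibrosis_map: FibrosisMap,
                    fiber_variant: str, fibrosis_type: FibrosisType,
                    seed: int, d_long: float = 0.4, d_trans: float = 0.1,
                    cell: CellModelParams = CellModelParams(),
                    global_apd_scale: float = 1.0,
                    conductivity_floor: float = 0.3) -> SubstrateModel:
    """Compose one substrate variant.

    ``d_long``/``d_trans`` are the healthy-tissue diffusion coefficients
    (typically from :func:`afstress.ep.calibrate_cv` at the mesh
    resolution). ``global_apd_scale`` multiplies apd everywhere (patient
    electrical phenotype and ERP stress-test variants); fibrotic ionic
    remodeling multiplies on top of it at vertices with iir > threshold.
    """
    if not isinstance(fibrosis_type, FibrosisType):
        try:
            fibrosis_type = FibrosisType(fibrosis_type)
        except ValueError:
            raise ValueError(f"unknown fibrosis type {fibrosis_type!r}") from None

    fibers = generate_fibers(mesh, fiber_variant)
    m = mesh.n_triangles
    apd = np.full(mesh.n_vertices, float(global_apd_scale))
    excit = np.ones(mesh.n_vertices)

    if fibrosis_type in (FibrosisType.COMBINATION, FibrosisType.CONDUCTION_ONLY):
        scale = iir_to_conductivity(fibrosis_map.iir, mesh.triangles,
                                    floor=conductivity_floor)
        apd[fibrosis_map.fibrotic_vertices()] *= FIBROTIC_APD_SCALE
    else:
        scale = np.ones(m)
    cond = ConductivityField(d_long * scale, d_trans * scale)

    if fibrosis_type in (FibrosisType.COMBINATION, FibrosisType.INTERSTITIAL):
        decoupled = decouple_interstitial_edges(mesh, fibrosis_map, seed)
    else:
        decoupled = np.empty((0, 2), dtype=np.int64)

    return SubstrateModel(
        mesh=mesh, fibers=fibers, conductivity=cond, cell=cell,
        apd_scale=apd, excitability_scale=excit, fibrosis=fibrosis_map,
        decoupled_edges=decoupled,
        provenance={"seed": int(seed), "fibrosis_type": fibrosis_type.value,
                    "fiber_variant": fiber_variant,
                    "d_long": d_long, "d_trans": d_trans,
                    "global_apd_scale": float(global_apd_scale)})
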