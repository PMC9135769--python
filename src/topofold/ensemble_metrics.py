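"""Ensemble and structure scores.

* ``conformational_homogeneity`` — S_h, the average all-against-all
  superposed backbone RMSD over an ensemble's frames, summed over ordered
  pairs i ≠ j and divided by N². Lower S_h means the ensemble stays in one
  conformational basin; it is a proxy for misfolding / basin-hopping
  tendency.
* ``radial_distribution`` / ``rdf_ruggedness`` — the pair-distance
  distribution g(r) of selected atoms and the total variation
  ∫₀⁴ |dg(r)/dr| dr, a score of core-packing idealness (a well-packed core
  gives a smooth, liquid-like g(r); ruggedness penalises spiky profiles).
* ``epitope_rmsd`` — Kabsch superposition restricted to a functional-epitope
  residue set, RMSD over those same atoms.
* ``ensemble_average_deviation`` — mean deviation of frames from the
  ensemble-average structure.
* ``hydropathy_profile`` — Kyte–Doolittle sliding-window hydropathy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .structures import (
    BACKBONE_ATOMS,
    Ensemble,
    Structure,
    StructureError,
    backbone_selection,
    coords_for,
    kabsch_superpose,
    rmsd,
)

__all__ = [
    "EnsembleReport",
    "RDFProfile",
    "EpitopeDefinition",
    "DEFAULT_EPITOPE",
    "conformational_homogeneity",
    "radial_distribution",
    "rdf_ruggedness",
    "epitope_rmsd",
    "ensemble_average_deviation",
    "hydropathy_profile",
    "select_core_sidechains",
]


@dataclass
class EnsembleReport:
    S_h: float
    n_frames: int
    pairwise_rmsd: np.ndarray  # (N, N), symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.pairwise_rmsd = np.asarray(self.pairwise_rmsd, dtype=float)


@dataclass
class RDFProfile:
    r: np.ndarray          # bin centres, Å
    g: np.ndarray          # pair density relative to uniform
    bin_width: float
    ruggedness: float | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")


# The receptor-binding epitope held fixed during refactoring: K16, E19, Q20,
# R22, K23, D27, D109, D112 (author numbering of the template structure).
DEFAULT_EPITOPE_RESIDUES = ((16,), (19,), (20,), (22,), (23,), (27,), (109,), (112,))


@dataclass(frozen=True)
class EpitopeDefinition:
    residues: tuple[tuple[str, int], ...]
    mode: str = "backbone"  # "backbone" (N, CA, C) or "all-atom" (heavy atoms)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("epitope must contain at least one residue")
        if self.mode not in ("backbone", "all-atom"):
            raise ValueError(f"mode must be 'backbone' or 'all-atom', got {self.mode!r}")


DEFAULT_EPITOPE = EpitopeDefinition(
    residues=tuple(("A", n) for (n,) in DEFAULT_EPITOPE_RESIDUES)
)


def _frame_coords(
    ensemble: Ensemble | np.ndarray,
    selection: Sequence[tuple] | None,
) -> np.ndarray:
    """(n_frames, n_atoms, 3) stack from an Ensemble or a raw array."""
    if isinstance(ensemble, Ensemble):
        if selection is None:
            selection = backbone_selection(ensemble.frames[0])
        return ensemble.coords(selection)
    arr = np.asarray(ensemble, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise StructureError(f"expected (n_frames, n_atoms, 3) coordinates, got {arr.shape}")
    return arr


def conformational_homogeneity(
    ensemble: Ensemble | np.ndarray,
    selection: Sequence[tuple] | None = None,
    denominator: str = "n_squared",
) -> EnsembleReport:
    """Conformational homogeneity S_h of an ensemble.

    S_h = Σ_{i≠j} S_RMSD(i, j) / N², where S_RMSD(i, j) is the superposed
    RMSD between frames i and j over ``selection`` (default: all backbone
    N/CA/C atoms). The denominator N² is used literally even though only
    N²−N ordered pairs contribute; ``denominator='pairs'`` divides by
    N(N−1) instead (a plain mean over pairs, clearly a different convention).
    """
    if denominator not in ("n_squared", "pairs"):
        raise ValueError("denominator must be 'n_squared' or 'pairs'")
    coords = _frame_coords(ensemble, selection)
    n = len(coords)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matrix[i, j] = matrix[j, i] = rmsd(coords[i], coords[j], superpose=True)
    if denominator == "n_squared":
        s_h = float(matrix.sum() / n**2)
    else:
        s_h = float(matrix.sum() / (n * (n - 1))) if n > 1 else 0.0
    return EnsembleReport(S_h=s_h, n_frames=n, pairwise_rmsd=matrix)


# ---------------------------------------------------------------------------
# Radial distribution function and packing ruggedness
# ---------------------------------------------------------------------------

def _reference_volume(coords: np.ndarray) -> float:
    """Convex-hull volume of the point cloud (rotation invariant). Degenerate
    clouds fall back to the sphere spanned by the maximum pair distance."""
    try:
        return float(ConvexHull(coords).volume)
    except (QhullError, ValueError):
        from scipy.spatial.distance import pdist

        dmax = float(pdist(coords).max())
        return float(4.0 / 3.0 * np.pi * max(dmax / 2.0, 1.0) ** 3)


def _ball_edge_correction(r: np.ndarray, volume: float) -> np.ndarray:
    """Fraction of a shell at radius r that stays inside a ball of the given
    volume, averaged over uniform centre positions (equivalent-sphere
    boundary correction): 1 − 3r/(4R) + r³/(16R³)."""
    R = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    s = np.clip(r / R, 0.0, 2.0)
    corr = 1.0 - 0.75 * s + s**3 / 16.0
    return np.clip(corr, 1e-12, None)


def radial_distribution(
    structure: Structure | np.ndarray,
    selection: Sequence[tuple] | None = None,
    r_max: float = 4.0,
    bin_width: float = 0.1,
    volume: float | None = None,
) -> RDFProfile:
    """Radial distribution function g(r) of selected atoms.

    The pair-distance histogram is normalised by the uniform-density shell
    expectation ρ·4πr²Δr (ρ = n/V, V the convex-hull volume by default, or
    ``volume`` if given) with an equivalent-sphere boundary correction, so a
    uniform random cloud gives g ≈ 1 and the profile is invariant under
    rigid motion. For packing analysis, select side-chain heavy atoms of
    buried residues (see :func:`select_core_sidechains`).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(structure, Structure):
        coords = (
            structure.all_coords() if selection is None else coords_for(structure, selection)
        )
    else:
        coords = np.asarray(structure, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise StructureError(f"expected (n, 3) coordinates, got {coords.shape}")
    n = len(coords)
    if n < 2:
        raise StructureError("radial distribution needs at least 2 atoms")

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=r_max, output_type="ndarray")
    dists = (
        np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        if len(pairs)
        else np.empty(0)
    )
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts, _ = np.histogram(dists, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])

    vol = _reference_volume(coords) if volume is None else float(volume)
    n_pairs = n * (n - 1) / 2.0
    shell = 4.0 * np.pi * centres**2 * bin_width
    expected = n_pairs * shell / vol * _ball_edge_correction(centres, vol)
    g = counts / expected
    return RDFProfile(r=centres, g=g, bin_width=bin_width)


def rdf_ruggedness(profile: RDFProfile, r_lo: float = 0.0, r_hi: float = 4.0) -> float:
    """Total variation of g(r) over [r_lo, r_hi]: Σ |g_{i+1} − g_i|.

    Over a histogram this is exactly the discretisation of ∫ |dg/dr| dr.
    The profile must cover the requested range.
    """
    half = profile.bin_width / 2.0
    if profile.r[0] > r_lo + half + 1e-9 or profile.r[-1] < r_hi - half - 1e-9:
        raise ValueError(
            f"profile spans [{profile.r[0]:.3g}, {profile.r[-1]:.3g}] Å "
            f"(bin centres) and does not cover [{r_lo}, {r_hi}] Å"
        )
    mask = (profile.r >= r_lo - half) & (profile.r <= r_hi + half)
    g = profile.g[mask]
    value = float(np.sum(np.abs(np.diff(g))))
    profile.ruggedness = value
    return value


def select_core_sidechains(
    structure: Structure,
    neighbor_radius: float = 10.0,
    min_neighbors: int = 16,
) -> list[tuple[str, int, str, str]]:
    """Side-chain heavy atoms of buried residues.

    Burial is decided by a solvent-exposure proxy: a residue is buried when
    its CA has at least ``min_neighbors`` other CA atoms within
    ``neighbor_radius`` Å.
    """
    keys, ca = [], []
    for cid, residues in structure.chains.items():
        for r in residues:
            if r.has_atom("CA"):
                keys.append((cid, r))
                ca.append(r.atom("CA").coords)
    if not keys:
        raise StructureError("no CA atoms in structure")
    tree = cKDTree(np.asarray(ca))
    counts = np.array([len(tree.query_ball_point(p, neighbor_radius)) - 1 for p in ca])
    backbone = set(BACKBONE_ATOMS) | {"O", "OXT"}
    selection = []
    for (cid, res), c in zip(keys, counts):
        if c >= min_neighbors:
            for a in res.atoms:
                if a.name not in backbone:
                    selection.append((cid, res.number, res.icode, a.name))
    return selection


# ---------------------------------------------------------------------------
# Epitope RMSD and ensemble deviation
# ---------------------------------------------------------------------------

def _epitope_coords(
    structure: Structure, epitope: EpitopeDefinition, names_from: Structure | None = None
) -> tuple[np.ndarray, list[tuple]]:
    selection: list[tuple] = []
    for chain, number in epitope.residues:
        res = structure.residue(chain, number)
        if epitope.mode == "backbone":
            names = BACKBONE_ATOMS
        else:
            names = tuple(a.name for a in res.atoms if a.element != "H")
        for name in names:
            if not res.has_atom(name):
                raise StructureError(
                    f"epitope residue {chain}:{number} ({res.name}) missing atom {name}"
                )
            selection.append((chain, number, res.icode, name))
    return coords_for(structure, selection), selection


def epitope_rmsd(
    model: Structure,
    reference: Structure,
    epitope: EpitopeDefinition = DEFAULT_EPITOPE,
) -> float:
    """RMSD over the epitope atoms after Kabsch superposition restricted to
    those same atoms (local alignment, not whole-chain).

    In all-atom mode the residue identities must match between model and
    reference; a mismatch is an error naming the residue.
    """
    model_coords, selection = _epitope_coords(model, epitope)
    if epitope.mode == "all-atom":
        for chain, number in epitope.residues:
            m, r = model.residue(chain, number), reference.residue(chain, number)
            if m.name != r.name:
                raise StructureError(
                    f"epitope residue {chain}:{number} differs: {m.name} vs {r.name}"
                )
    ref_coords = coords_for(reference, selection)
    return rmsd(model_coords, ref_coords, superpose=True)


def ensemble_average_deviation(
    ensemble: Ensemble | np.ndarray,
    selection: Sequence[tuple] | None = None,
    iterations: int = 1,
) -> tuple[float, np.ndarray]:
    """Mean deviation of the frames from the ensemble-average structure.

    Frames are superposed onto frame 1, the coordinate-average structure is
    formed, and the deviation of each superposed frame from that average is
    its plain RMSD. ``iterations=2`` re-superposes onto the evolving mean
    once; the default single pass is deterministic and sufficient for
    compact ensembles. Returns (mean deviation, per-frame deviations).
    """
    coords = _frame_coords(ensemble, selection).copy()
    n = len(coords)
    if n < 2:
        raise StructureError("ensemble deviation needs at least 2 frames")
    reference = coords[0]
    for _ in range(max(1, iterations)):
        for i in range(n):
            R, t, _ = kabsch_superpose(coords[i], reference)
            coords[i] = coords[i] @ R.T + t
        reference = coords.mean(axis=0)
    mean_structure = coords.mean(axis=0)
    deviations = np.array([rmsd(c, mean_structure) for c in coords])
    return float(deviations.mean()), deviations


# ---------------------------------------------------------------------------
# Hydropathy
# ---------------------------------------------------------------------------

def hydropathy_profile(sequence: str, window: int = 9) -> tuple[np.ndarray, np.ndarray]:
    """Kyte–Doolittle sliding-window hydropathy.

    Returns (centre positions, values): the mean of the per-residue
    Kyte–Doolittle constants over each full window, reported at the window's
    centre position (1-based). Positive values are hydrophobic.
    """
    from Bio.SeqUtils.ProtParamData import kd

    sequence = sequence.upper()
    unknown = sorted({c for c in sequence if c not in kd})
    if unknown:
        raise ValueError(f"unknown residue(s) {unknown} in sequence")
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > len(sequence):
        raise ValueError(f"window {window} exceeds sequence length {len(sequence)}")
    values = np.array([kd[c] for c in sequence])
    kernel = np.ones(window) / window
    profile = np.convolve(values, kernel, mode="valid")
    centres = np.arange(window // 2 + 1, window // 2 + 1 + len(profile))
    return centres, profile
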