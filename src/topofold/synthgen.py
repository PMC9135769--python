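"""Synthetic fixtures: ideal helices, helical bundles, perturbed ensembles,
and simulated sensorgram titrations.

These generators stand in for experimental inputs in tests and examples:
ideal α-helix geometry (1.5 Å rise per residue, 100° twist, 2.3 Å Cα
radius) assembled into up/down bundles, i.i.d. Gaussian coordinate
perturbations emulating conformational heterogeneity, and 1:1-model
association titrations with the acquisition defaults of a multi-cycle SPR
run (180 s association window, 900 points, five 2-fold concentration
steps). All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Atom, Ensemble, Residue, Structure, StructureError
from .spr_kinetics import Sensorgram, simulate_association

__all__ = [
    "BundleSpec",
    "build_ideal_helix",
    "build_bundle",
    "perturb_ensemble",
    "make_titration",
    "DEFAULT_CONCENTRATIONS",
]

RISE = 1.5          # Å per residue along the helix axis
TWIST_DEG = 100.0   # ° per residue
CA_RADIUS = 2.3     # Å

# Five 2-fold increasing analyte concentrations, 5 -> 80 nM.
DEFAULT_CONCENTRATIONS = tuple(5e-9 * 2**i for i in range(5))

_CA_C = 1.52   # Å, CA-C bond
_CA_N = 1.46   # Å, N-CA bond
_C_N = 1.33    # Å, peptide bond


@dataclass(frozen=True)
class BundleSpec:
    """An up/down helical bundle on parallel axes.

    ``arrangement`` is one character per helix, 'u' (N terminus at the
    bottom) or 'd' (flipped); ``spacing`` is the distance between adjacent
    helix axes in Å.
    """

    helix_lengths: tuple[int, ...]
    arrangement: str = ""
    spacing: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.helix_lengths) < 2:
            raise ValueError("a bundle needs at least 2 helices")
        if self.spacing <= 0:
            raise ValueError(
                f"spacing must be positive (overlapping axes), got {self.spacing}"
            )
        arrangement = self.arrangement or "ud" * len(self.helix_lengths)
        arrangement = arrangement[: len(self.helix_lengths)]
        if set(arrangement) - {"u", "d"}:
            raise ValueError(f"arrangement may only contain 'u'/'d': {arrangement!r}")
        object.__setattr__(self, "arrangement", arrangement)


def _helix_ca(n_res: int) -> np.ndarray:
    i = np.arange(n_res)
    phi = np.deg2rad(TWIST_DEG) * i
    return np.column_stack(
        [CA_RADIUS * np.cos(phi), CA_RADIUS * np.sin(phi), RISE * i]
    )


def build_ideal_helix(n_res: int) -> list[Residue]:
    """Ideal α-helix backbone (N, CA, C) as a list of residues.

    The Cα trace sits on a cylinder of radius 2.3 Å with 1.5 Å rise and
    100° twist per residue; N and C atoms are placed at standard bond
    lengths so consecutive C(i)–N(i+1) distances reproduce the ~1.33 Å
    peptide bond.
    """
    if n_res < 4:
        raise ValueError(f"helix needs at least 4 residues, got {n_res}")
    ca = _helix_ca(n_res)
    # Per peptide bond j (residues j -> j+1): a unit vector along the bond
    # and one shared outward perpendicular, so C(j) and N(j+1) are tilted
    # symmetrically off the CA-CA line and end up ~1.33 Å apart.
    e = np.diff(ca, axis=0)
    d = np.linalg.norm(e, axis=1)
    e = e / d[:, None]
    mid = 0.5 * (ca[:-1] + ca[1:])
    mid[:, 2] = 0.0
    perp = mid - np.sum(mid * e, axis=1)[:, None] * e
    perp /= np.linalg.norm(perp, axis=1)[:, None]
    cos_t = np.clip((d - _C_N) / (_CA_C + _CA_N), -1.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)

    residues = []
    for i in range(n_res):
        fwd = min(i, n_res - 2)          # bond leaving residue i
        bwd = max(i - 1, 0)              # bond arriving at residue i
        c_pos = ca[i] + _CA_C * (cos_t[fwd] * e[fwd] + sin_t[fwd] * perp[fwd])
        n_pos = ca[i] + _CA_N * (-cos_t[bwd] * e[bwd] + sin_t[bwd] * perp[bwd])
        residues.append(
            Residue(
                number=i + 1,
                name="GLY",
                atoms=[
                    Atom("N", "N", n_pos),
                    Atom("CA", "C", ca[i]),
                    Atom("C", "C", c_pos),
                ],
            )
        )
    return residues


def build_bundle(spec: BundleSpec) -> Structure:
    """Assemble helices on parallel axes at the given spacing, alternating
    direction per the arrangement, residues numbered consecutively in one
    chain. Deterministic for a given spec."""
    residues: list[Residue] = []
    next_number = 1
    max_len = max(spec.helix_lengths)
    for k, (length, direction) in enumerate(zip(spec.helix_lengths, spec.arrangement)):
        helix = build_ideal_helix(length)
        coords = np.array([a.coords for r in helix for a in r.atoms])
        if direction == "d":
            # Flip: rotate 180 degrees about the x axis, then shift the helix
            # back up so it occupies the same z band as the 'u' helices.
            coords = coords * np.array([1.0, -1.0, -1.0])
            coords[:, 2] += RISE * (length - 1)
        coords[:, 0] += k * spec.spacing
        coords[:, 2] += RISE * (max_len - length) / 2.0
        i = 0
        for r in helix:
            atoms = []
            for a in r.atoms:
                atoms.append(Atom(a.name, a.element, coords[i]))
                i += 1
            residues.append(Residue(number=next_number, name=r.name, atoms=atoms))
            next_number += 1
    return Structure(chains={"A": residues})


def perturb_ensemble(
    structure: Structure,
    n_frames: int,
    amplitude: float,
    seed: int | None = None,
) -> Ensemble:
    """Ensemble of i.i.d. Gaussian coordinate perturbations of the input.

    Each frame adds independent N(0, amplitude²) noise to every coordinate
    (no covariance structure); amplitude 0 reproduces the input exactly in
    every frame. Deterministic under a fixed seed.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if n_frames < 1:
        raise ValueError("need at least 1 frame")
    rng = np.random.default_rng(seed)
    base = structure.all_coords()
    frames = []
    for i in range(n_frames):
        frame = structure.copy()
        frame.model_index = i
        noise = rng.normal(0.0, amplitude, size=base.shape) if amplitude > 0 else 0.0
        frame.set_all_coords(base + noise)
        frames.append(frame)
    return Ensemble(frames=frames)


def make_titration(
    k_a: float,
    k_d: float,
    concentrations: tuple[float, ...] | None = None,
    gamma_gg: float = 100.0,
    duration: float = 180.0,
    n: int = 900,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[Sensorgram]:
    """One simulated association curve per concentration.

    Defaults mirror a multi-cycle SPR acquisition: 180 s association
    window, 900 points per curve, and a five-step 2-fold series from 5 to
    80 nM.
    """
    if concentrations is None:
        concentrations = DEFAULT_CONCENTRATIONS
    rng = np.random.default_rng(seed)
    return [
        simulate_association(
            k_a,
            k_d,
            c,
            gamma_gg=gamma_gg,
            duration=duration,
            n=n,
            noise_sd=noise_sd,
            seed=rng,
            label=f"curve_{i + 1}",
        )
        for i, c in enumerate(concentrations)
    ]
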