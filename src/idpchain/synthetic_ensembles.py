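"""Synthetic chain ensembles and paired pseudo-experimental data.

Three coarse-grained homopolymer models with known analytic behaviour serve
as ground truth for the analysis code:

* **Freely jointed chain** (``generate_random_walk``): independent uniform
  bond directions; an ideal Gaussian coil with Flory exponent nu = 0.5 and
  mean squared end-to-end distance (N-1) b^2.
* **Freely rotating chain** (``generate_freely_rotating``): each bond makes
  a fixed angle with its predecessor (uniform azimuth), so the bond-vector
  orientational correlation is exactly C(s) = g^s where g is the cosine of
  the bond angle.  The exponential decay constant is k = -1/ln(g).
* **Self-avoiding walk** (``generate_self_avoiding``): hard-sphere excluded
  volume sampled with the pivot algorithm; a good-solvent chain with
  nu ~ 0.588 at large N.

The default bond length of 0.38 nm is the virtual C-alpha–C-alpha spacing of
a polypeptide backbone, so chain statistics computed from these ensembles are
on the same length scale as protein C-alpha traces.

Two further generators produce paired synthetic "experiment vs model" data
with known ground truth: an affine-transformed, noise-corrupted scattering
curve for exercising the chi-square machinery, and an offset-shifted
chemical-shift table pair for exercising the offset-correction/RMSE
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .ensemble_io import BACKBONE_ATOMS, Ensemble, SAXSProfile, ShiftTable
from .exceptions import IdpChainError
from .scattering_compare import gaussian_chain_intensity

__all__ = [
    "CA_SPACING_NM",
    "ChainModelSpec",
    "generate_random_walk",
    "generate_freely_rotating",
    "generate_self_avoiding",
    "synthesize_saxs_pair",
    "synthesize_shift_pair",
]

#: Distance between consecutive C-alpha atoms in proteins, nm.
CA_SPACING_NM = 0.38


@dataclass
class ChainModelSpec:
    """Parameters shared by the chain generators.

    Parameters
    ----------
    n_residues
        Number of beads (C-alpha sites), >= 2.
    n_frames
        Number of independent (or pivot-decorrelated) conformations.
    bond_length
        Fixed distance between consecutive beads, nm.  Default is the
        0.38 nm C-alpha spacing.
    bond_cos
        Mean cosine g between successive bond vectors for the freely
        rotating model, in (-1, 1).  ``rod=True`` selects the g -> 1
        degenerate straight-chain limit explicitly.
    excluded_diameter
        Hard-core diameter for the self-avoiding model, nm.  Pairs with
        |i - j| >= 2 are kept at least this far apart.  Must be < 2 x
        bond_length so that a chain placement exists at all.
    seed
        Seed for the generator's private RNG; identical (spec, seed)
        always reproduces the ensemble bit for bit.
    """

    n_residues: int
    n_frames: int
    bond_length: float = CA_SPACING_NM
    bond_cos: float = 0.0
    excluded_diameter: float = CA_SPACING_NM
    rod: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise IdpChainError("n_residues must be >= 2")
        if self.n_frames < 1:
            raise IdpChainError("n_frames must be >= 1")
        if self.bond_length <= 0:
            raise IdpChainError("bond_length must be positive")
        if self.excluded_diameter < 0:
            raise IdpChainError("excluded_diameter must be non-negative")
        if self.excluded_diameter >= 2.0 * self.bond_length:
            raise IdpChainError(
                "excluded_diameter must be < 2 x bond_length; no chain "
                "satisfies the |i-j| = 2 constraint otherwise"
            )


def _uniform_directions(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """Unit vectors uniform on the sphere, shape ``shape + (3,)``."""
    v = rng.normal(size=shape + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate_random_walk(spec: ChainModelSpec) -> Ensemble:
    """Freely jointed chains: independent uniform bond directions.

    Each of the ``n_frames`` frames is an independent ideal chain with
    fixed bond length; mean squared end-to-end distance is
    ``(n_residues - 1) * bond_length**2``.
    """
    rng = np.random.default_rng(spec.seed)
    n_bonds = spec.n_residues - 1
    bonds = spec.bond_length * _uniform_directions(
        rng, (spec.n_frames, n_bonds)
    )
    coords = np.zeros((spec.n_frames, spec.n_residues, 3))
    coords[:, 1:] = np.cumsum(bonds, axis=1)
    return Ensemble(coords=coords, label="freely-jointed chain")


def generate_freely_rotating(spec: ChainModelSpec) -> Ensemble:
    """Freely rotating chains with exact successive-bond cosine g.

    Every new bond direction is drawn uniformly on the cone at angle
    arccos(g) around the previous bond, which makes the orientational
    correlation C(s) = g^s exact (not just in expectation of the angle).
    ``spec.rod=True`` returns perfectly straight chains (C(s) = 1) instead
    of sampling; g = +-1 via ``bond_cos`` is rejected.
    """
    if spec.rod:
        coords = np.zeros((spec.n_frames, spec.n_residues, 3))
        coords[..., 0] = spec.bond_length * np.arange(spec.n_residues)
        return Ensemble(coords=coords, label="rod")
    g = spec.bond_cos
    if not -1.0 < g < 1.0:
        raise IdpChainError(
            "bond_cos must lie strictly inside (-1, 1); use rod=True for "
            "the straight-chain limit"
        )
    rng = np.random.default_rng(spec.seed)
    n_bonds = spec.n_residues - 1
    sin_t = np.sqrt(1.0 - g * g)
    u = _uniform_directions(rng, (spec.n_frames,))  # first bond direction
    bonds = np.empty((spec.n_frames, n_bonds, 3))
    bonds[:, 0] = u
    for b in range(1, n_bonds):
        # orthonormal frame (e1, e2) perpendicular to the previous bond;
        # pick the seed axis farthest from u to keep the cross product stable
        seed_axis = np.zeros_like(u)
        seed_axis[np.arange(len(u)), np.argmin(np.abs(u), axis=1)] = 1.0
        e1 = np.cross(u, seed_axis)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(u, e1)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=len(u))
        u = (
            g * u
            + sin_t * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        bonds[:, b] = u
    coords = np.zeros((spec.n_frames, spec.n_residues, 3))
    coords[:, 1:] = spec.bond_length * np.cumsum(bonds, axis=1)
    return Ensemble(coords=coords, label=f"freely-rotating chain g={g}")


# ---------------------------------------------------------------------------
# Self-avoiding walk via the pivot algorithm
# ---------------------------------------------------------------------------

def _self_avoiding_ok(coords: np.ndarray, diameter: float) -> bool:
    """Check min distance >= diameter over all pairs with |i - j| >= 2."""
    n = coords.shape[0]
    d = cdist(coords, coords)
    mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= 2
    return bool(d[mask].min() >= diameter)


def _pivot_once(
    coords: np.ndarray, diameter: float, rng: np.random.Generator
) -> bool:
    """Attempt one pivot move in place; return True if accepted.

    A pivot site p is chosen uniformly in the chain interior and the tail
    (p+1 .. N-1) is rotated rigidly about the pivot bead by a uniform random
    rotation.  Intra-head and intra-tail distances are unchanged, so only
    head-tail pairs need re-checking; the bonded pair (p, p+1) is exempt
    from the |i - j| >= 2 hard-core constraint.
    """
    n = coords.shape[0]
    p = int(rng.integers(1, n - 1))
    quat = rng.normal(size=4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat))
    pivot = coords[p]
    new_tail = rot.apply(coords[p + 1 :] - pivot) + pivot
    d = cdist(coords[: p + 1], new_tail)
    d[p, 0] = np.inf  # bonded neighbours, constraint does not apply
    if d.min() < diameter:
        return False
    coords[p + 1 :] = new_tail
    return True


def generate_self_avoiding(
    spec: ChainModelSpec,
    decorrelation_pivots: int | None = None,
    burn_in_pivots: int | None = None,
    max_attempts_per_accept: int = 100_000,
) -> Ensemble:
    """Self-avoiding chains sampled with the pivot algorithm.

    Starting from a straight chain (always feasible for
    ``excluded_diameter < 2 x bond_length``), pivot moves — rigid rotation
    of the chain tail about a random interior bead — are proposed and
    accepted iff the hard-core constraint (pairwise distance >=
    ``excluded_diameter`` for all |i - j| >= 2) holds.  A frame is emitted
    every ``decorrelation_pivots`` *accepted* pivots (default 2N) after a
    burn-in of 10N accepted pivots.

    Raises if ``max_attempts_per_accept`` consecutive proposals are all
    rejected, which signals a geometrically infeasible diameter.
    """
    if spec.excluded_diameter <= 0:
        raise IdpChainError(
            "self-avoiding model requires excluded_diameter > 0"
        )
    n = spec.n_residues
    b = spec.bond_length
    d = spec.excluded_diameter
    if decorrelation_pivots is None:
        decorrelation_pivots = 2 * n
    if burn_in_pivots is None:
        burn_in_pivots = 10 * n
    rng = np.random.default_rng(spec.seed)

    coords = np.zeros((n, 3))
    coords[:, 0] = b * np.arange(n)
    if not _self_avoiding_ok(coords, d):
        raise IdpChainError(
            f"excluded_diameter {d} nm infeasible for bond length {b} nm"
        )

    def advance(n_accept: int) -> None:
        accepted = 0
        rejected_run = 0
        while accepted < n_accept:
            if _pivot_once(coords, d, rng):
                accepted += 1
                rejected_run = 0
            else:
                rejected_run += 1
                if rejected_run >= max_attempts_per_accept:
                    raise IdpChainError(
                        f"pivot sampler stalled: {rejected_run} consecutive "
                        f"rejections (excluded_diameter {d} nm likely "
                        f"infeasible)"
                    )

    advance(burn_in_pivots)
    frames = np.empty((spec.n_frames, n, 3))
    for t in range(spec.n_frames):
        if t > 0:
            advance(decorrelation_pivots)
        frames[t] = coords
    return Ensemble(coords=frames, label="self-avoiding walk")


# ---------------------------------------------------------------------------
# Paired synthetic experimental data
# ---------------------------------------------------------------------------

def synthesize_saxs_pair(
    model_rg: float,
    q_grid: np.ndarray,
    scale: float = 1.0,
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SAXSProfile, SAXSProfile]:
    """Paired (experimental, simulated) scattering curves with known truth.

    The simulated curve is the Gaussian-chain (Debye) form factor at
    ``model_rg``.  The experimental curve is the affine transform
    ``scale * I_sim + background`` plus Gaussian noise with per-point
    standard deviation ``noise_sd`` times the noise-free value; that same
    standard deviation is stored as the experimental sigma, so the
    chi-square of the pair is ~1 for a correctly specified model.  With
    ``noise_sd = 0`` the pair is exactly affine-related (sigma is set to 1
    so the chi-square remains defined, and evaluates to 0).
    """
    if noise_sd < 0:
        raise IdpChainError("noise_sd must be non-negative")
    if scale <= 0:
        raise IdpChainError("scale must be positive")
    sim = gaussian_chain_intensity(q_grid, model_rg)
    mean = scale * sim.I + background
    if noise_sd == 0:
        expt = SAXSProfile(q=sim.q, I=mean, sigma=np.ones_like(mean),
                           label="synthetic experiment (noise-free)")
        return expt, sim
    sd = noise_sd * np.abs(mean)
    if np.any(sd <= 0):
        raise IdpChainError(
            "scale/background give a zero mean intensity somewhere; "
            "relative noise is undefined there"
        )
    rng = np.random.default_rng(seed)
    noisy = mean + rng.normal(scale=sd)
    expt = SAXSProfile(q=sim.q, I=noisy, sigma=sd,
                       label="synthetic experiment")
    return expt, sim


#: Plausible random-coil shift ranges per atom type, p.p.m.  Centre and
#: half-width chosen to span typical disordered-protein backbone values.
_RC_RANGES = {
    "N": (119.0, 4.0),
    "CA": (56.0, 3.0),
    "CB": (33.0, 5.0),
    "H": (8.2, 0.3),
    "HA": (4.4, 0.3),
}

_AMINO_ACIDS = (
    "ALA ARG ASN ASP GLN GLU GLY HIS ILE LEU "
    "LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def synthesize_shift_pair(
    n_residues: int,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    atoms: tuple[str, ...] = BACKBONE_ATOMS,
) -> tuple[ShiftTable, ShiftTable, ShiftTable]:
    """Paired (expt, calc, random-coil) shift tables with known offset.

    A random hetero-sequence is drawn; random-coil values per (residue
    type, atom) come from fixed plausible backbone ranges.  Experimental
    shifts are the random-coil values plus a smooth structured deviation
    (a low-frequency sinusoid along the sequence, mimicking transient
    secondary-structure propensity); calculated shifts are the experimental
    ones minus ``offset`` plus Gaussian noise of sd ``noise_sd``.  The
    offset-correction pipeline should therefore recover ``offset`` and a
    post-correction RMSE equal to the noise level.
    """
    if n_residues < 3:
        raise IdpChainError("n_residues must be >= 3")
    if noise_sd < 0:
        raise IdpChainError("noise_sd must be non-negative")
    bad = sorted(set(a.upper() for a in atoms) - set(BACKBONE_ATOMS))
    if bad:
        raise IdpChainError(f"unknown atoms {bad}")
    rng = np.random.default_rng(seed)
    sequence = rng.choice(_AMINO_ACIDS, size=n_residues)
    # one random-coil value per residue type actually present
    rc_rows = []
    rc_map: dict[tuple[str, str], float] = {}
    for ri, name in enumerate(sorted(set(sequence)), start=1):
        for atom in atoms:
            centre, half = _RC_RANGES[atom.upper()]
            val = round(rng.uniform(centre - half, centre + half), 4)
            rc_map[(name, atom.upper())] = val
            rc_rows.append((ri, name, atom.upper(), val))

    expt_rows, calc_rows = [], []
    phase = rng.uniform(0, 2 * np.pi)
    for i, name in enumerate(sequence, start=1):
        for atom in atoms:
            atom = atom.upper()
            centre, half = _RC_RANGES[atom]
            structured = 0.3 * half * np.sin(2 * np.pi * i / 11.0 + phase)
            expt_val = rc_map[(name, atom)] + structured
            calc_val = expt_val - offset
            if noise_sd > 0:
                calc_val += rng.normal(scale=noise_sd)
            expt_rows.append((i, name, atom, expt_val))
            calc_rows.append((i, name, atom, calc_val))

    cols = ["res_index", "res_name", "atom", "shift"]
    expt = ShiftTable(pd.DataFrame(expt_rows, columns=cols),
                      label="synthetic experimental shifts")
    calc = ShiftTable(pd.DataFrame(calc_rows, columns=cols),
                      label="synthetic calculated shifts")
    rc = ShiftTable(pd.DataFrame(rc_rows, columns=cols),
                    label="synthetic random-coil reference")
    return expt, calc, rc
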