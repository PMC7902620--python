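"""Agreement scoring between simulated and experimental small-angle
scattering profiles.

Experimental SAXS intensities are in arbitrary units and carry a flat
background from imperfect buffer subtraction, so a simulated curve is
compared through the reduced statistic

    chi^2 = 1/(k-1) * sum_i [ (I_expt(q_i) - (c I_sim(q_i) + bgd))
                              / sigma_expt(q_i) ]^2

with the scale c and background bgd fitted by weighted linear least
squares (closed-form normal equations, no iterative search).  The 1/(k-1)
normalisation is the field's reporting convention for this statistic; the
strict statistical convention 1/(k-3) — two parameters are fitted — is
available via ``dof="k-3"``.

Two intensity calculators are provided for desk-scale work: the analytic
Gaussian-chain (Debye) form factor, and a uniform point-scatterer Debye
sum over C-alpha coordinates.  Both are deliberately simplified models —
no atomic form factors, no hydration-shell contribution — adequate for
method validation on synthetic chains, not for quantitative comparison
with measured protein curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .ensemble_io import Ensemble, SAXSProfile
from .exceptions import FitError, IdpChainError

__all__ = [
    "Chi2Result",
    "chi_squared",
    "gaussian_chain_intensity",
    "debye_intensity_from_coordinates",
    "chi2_convergence",
]


@dataclass
class Chi2Result:
    """Reduced chi-square with the fitted nuisance parameters."""

    chi2: float
    c: float
    bgd: float
    n_points: int
    q_min: float
    q_max: float
    interpolated: bool = False
    background_fitted: bool = True

    def __post_init__(self) -> None:
        if self.chi2 < -1e-12:
            raise FitError("chi2 cannot be negative")
        self.chi2 = max(self.chi2, 0.0)


def _sim_on_expt_grid(expt: SAXSProfile, sim: SAXSProfile):
    """Simulated intensities on the experimental q grid.

    Returns (I_sim, interpolated_flag).  Linear interpolation is used when
    the grids differ; extrapolation outside the simulated q range is
    refused.
    """
    if sim.q.shape == expt.q.shape and np.allclose(sim.q, expt.q):
        return sim.I, False
    if expt.q[0] < sim.q[0] or expt.q[-1] > sim.q[-1]:
        raise IdpChainError(
            f"experimental q range [{expt.q[0]:g}, {expt.q[-1]:g}] nm^-1 "
            f"extends beyond the simulated range [{sim.q[0]:g}, "
            f"{sim.q[-1]:g}]; extrapolation is not supported"
        )
    return np.interp(expt.q, sim.q, sim.I), True


def chi_squared(
    expt: SAXSProfile,
    sim: SAXSProfile,
    q_min: float | None = None,
    q_max: float | None = None,
    fit_background: bool = True,
    dof: str = "k-1",
) -> Chi2Result:
    """Reduced chi-square between profiles, with fitted scale and background.

    The scale c and (optionally) flat background bgd minimising the
    weighted squared deviation are obtained in closed form from the
    1/sigma^2-weighted normal equations.  ``q_min``/``q_max`` restrict the
    comparison range (default: all experimental points).  ``dof`` selects
    the normalisation: ``"k-1"`` (default reporting convention) or
    ``"k-3"`` (accounts for both fitted parameters).
    """
    if expt.sigma is None:
        raise IdpChainError("experimental profile must carry sigma")
    if dof not in ("k-1", "k-3"):
        raise IdpChainError("dof must be 'k-1' or 'k-3'")
    i_sim, interpolated = _sim_on_expt_grid(expt, sim)
    mask = np.ones(len(expt), dtype=bool)
    if q_min is not None:
        mask &= expt.q >= q_min
    if q_max is not None:
        mask &= expt.q <= q_max
    q = expt.q[mask]
    y = expt.I[mask]
    f = i_sim[mask]
    sig = expt.sigma[mask]
    k = int(mask.sum())
    if k < 3:
        raise IdpChainError(
            f"need at least 3 points in the comparison range, have {k}"
        )
    w = 1.0 / sig**2
    if fit_background:
        if np.ptp(f) == 0:
            raise FitError(
                "simulated intensity is constant over the fit range: "
                "collinear with the background term, (c, bgd) not "
                "identifiable"
            )
        # weighted least squares of y on (f, 1)
        sw = w.sum()
        swf = (w * f).sum()
        swy = (w * y).sum()
        swff = (w * f * f).sum()
        swfy = (w * f * y).sum()
        det = sw * swff - swf**2
        c = (sw * swfy - swf * swy) / det
        bgd = (swff * swy - swf * swfy) / det
    else:
        c = (w * f * y).sum() / (w * f * f).sum()
        bgd = 0.0
    resid = (y - (c * f + bgd)) / sig
    denom = k - 1 if dof == "k-1" else k - 3
    if denom < 1:
        raise IdpChainError("too few points for the requested dof")
    return Chi2Result(
        chi2=float((resid**2).sum() / denom),
        c=float(c),
        bgd=float(bgd),
        n_points=k,
        q_min=float(q[0]),
        q_max=float(q[-1]),
        interpolated=interpolated,
        background_fitted=fit_background,
    )


def gaussian_chain_intensity(q_grid: np.ndarray, rg: float) -> SAXSProfile:
    """Debye form factor of an ideal Gaussian chain, normalised to I(0) = 1.

    I(x) = 2 (exp(-x) + x - 1) / x^2 with x = q^2 Rg^2; the x -> 0 limit
    (I = 1) is handled by series expansion for numerical stability.
    """
    if rg <= 0:
        raise IdpChainError("rg must be positive")
    q = np.asarray(q_grid, dtype=float)
    x = (q * rg) ** 2
    small = x < 1e-8
    xs = np.where(small, 1.0, x)  # placeholder to avoid 0/0
    intensity = 2.0 * (np.expm1(-xs) + xs) / xs**2
    intensity = np.where(small, 1.0 - x / 3.0, intensity)
    return SAXSProfile(q=q, I=intensity, sigma=None,
                       label=f"Gaussian chain Rg={rg} nm")


def debye_intensity_from_coordinates(
    ensemble: Ensemble, q_grid: np.ndarray
) -> SAXSProfile:
    """Orientation-averaged point-scatterer Debye sum over C-alpha beads.

    I(q) = < sum_ij sinc(q d_ij) > with unit form factors, averaged over
    frames; I(0) = N^2.  This is an explicit simplification: real protein
    scattering requires atomic form factors and the hydration shell, both
    outside this package's scope.
    """
    q = np.asarray(q_grid, dtype=float)
    per_frame = _debye_per_frame(ensemble, q)
    return SAXSProfile(q=q, I=per_frame.mean(axis=0), sigma=None,
                       label="Debye point-scatterer sum")


def _debye_per_frame(ensemble: Ensemble, q: np.ndarray) -> np.ndarray:
    """Per-frame Debye intensities, shape (n_frames, n_q)."""
    n = ensemble.n_residues
    out = np.empty((ensemble.n_frames, q.size))
    for t in range(ensemble.n_frames):
        d = pdist(ensemble.coords[t])  # upper-triangle distances
        # np.sinc(z) = sin(pi z)/(pi z), so sinc(qd) = np.sinc(qd/pi)
        out[t] = n + 2.0 * np.sinc(np.outer(q, d) / np.pi).sum(axis=1)
    return out


def chi2_convergence(
    ensemble: Ensemble,
    expt: SAXSProfile,
    n_windows: int = 5,
    fit_background: bool = True,
) -> list[tuple[int, float]]:
    """Chi-square of growing trajectory prefixes against an experimental curve.

    The ensemble-average Debye intensity of the first j/n_windows of the
    frames (j = 1..n_windows) is scored with :func:`chi_squared`; a
    plateau in the returned series signals that the simulated observable
    has converged.
    """
    if n_windows < 2:
        raise IdpChainError("n_windows must be >= 2")
    if expt.sigma is None:
        raise IdpChainError("experimental profile must carry sigma")
    per_frame = _debye_per_frame(ensemble, expt.q)
    out: list[tuple[int, float]] = []
    for j in range(1, n_windows + 1):
        n_used = max(1, int(round(j * ensemble.n_frames / n_windows)))
        mean_i = per_frame[:n_used].mean(axis=0)
        sim = SAXSProfile(q=expt.q, I=mean_i)
        res = chi_squared(expt, sim, fit_background=fit_background)
        out.append((n_used, res.chi2))
    return out
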