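"""Global and polymer-physics observables of C-alpha trace ensembles.

The observables implemented here characterise the size and stiffness of a
disordered chain:

* per-frame radius of gyration Rg and its histogram;
* the bond-vector orientational correlation C(s) = <n_i . n_{i+s}>, whose
  initial exponential decay C(s) = exp(-s/k) yields the persistence length
  l_p = k x 0.38 nm (k in C-alpha pair units, 0.38 nm the consecutive
  C-alpha spacing);
* the mean internal distance profile R_s and Flory scaling fits
  R_s = R_0 s^nu, performed separately below and above a residue-separation
  split (default s = 10) because disordered proteins show distinct local
  and global scaling regimes;
* contact counts and contact-frequency maps.

Per-separation uncertainties use the block standard error over five
contiguous frame blocks.  All fits are unweighted log-space linear least
squares by default (straight lines on log plots); inverse-variance
weighting is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .ensemble_io import Ensemble
from .exceptions import FitError, IdpChainError
from .hremd_tools import ScalarSeries

__all__ = [
    "CA_SPACING_NM",
    "CorrelationProfile",
    "PersistenceFit",
    "PowerLawFit",
    "InternalDistanceProfile",
    "FloryRegime",
    "FloryFit",
    "radius_of_gyration",
    "rg_histogram",
    "RgHistogram",
    "orientational_correlation",
    "fit_persistence",
    "fit_power_law_tail",
    "internal_distance_profile",
    "fit_flory",
    "fit_flory_two_regime",
    "contact_count_series",
    "contact_map",
]

#: Distance between consecutive C-alpha atoms in proteins, nm; converts the
#: dimensionless decay constant k of C(s) into a persistence length.
CA_SPACING_NM = 0.38


@dataclass
class CorrelationProfile:
    """A correlation-type function versus integer separation or lag."""

    s: np.ndarray
    value: np.ndarray
    stderr: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if self.s.shape != self.value.shape:
            raise IdpChainError("s and value must have equal length")
        if not np.isfinite(self.value).all():
            raise IdpChainError("correlation values must be finite")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)

    def at(self, s: int) -> float:
        idx = np.flatnonzero(self.s == s)
        if idx.size == 0:
            raise KeyError(f"separation {s} not in profile")
        return float(self.value[idx[0]])


@dataclass
class PersistenceFit:
    """Exponential-decay fit of C(s): k (C-alpha pair units) and l_p (nm)."""

    k: float
    l_p: float
    fit_s_max: int
    residual: float  # sum of squared log-space residuals

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise FitError("decay constant k must be positive")
        assert np.isclose(self.l_p, self.k * CA_SPACING_NM)


@dataclass
class PowerLawFit:
    """Power-law fit C(s) ~ s^exponent over [s_lo, s_hi]."""

    exponent: float
    stderr: float
    s_lo: int
    s_hi: int


@dataclass
class InternalDistanceProfile:
    """Mean C-alpha pair distance R_s (nm) versus residue separation s."""

    s: np.ndarray
    r: np.ndarray
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        if self.s.shape != self.r.shape:
            raise IdpChainError("s and r must have equal length")
        if np.any(self.r <= 0):
            raise IdpChainError("internal distances must be positive")


@dataclass
class FloryRegime:
    """One regime of the scaling fit R_s = R_0 s^nu."""

    s_lo: int
    s_hi: int
    r0: float
    nu: float
    nu_stderr: float


@dataclass
class FloryFit:
    """Two-regime Flory scaling fit; ``tail_fitted`` is False when the
    profile is too short to support the second regime."""

    regimes: list[FloryRegime]
    split: int
    tail_fitted: bool = True


@dataclass
class RgHistogram:
    """Normalised Rg density with bin edges and the ensemble mean."""

    edges: np.ndarray
    density: np.ndarray
    mean: float


# ---------------------------------------------------------------------------
# Global size
# ---------------------------------------------------------------------------

def radius_of_gyration(ensemble: Ensemble) -> ScalarSeries:
    """Per-frame radius of gyration of the C-alpha trace, nm.

    Equal weights on all beads (the C-alpha trace convention), i.e. the
    root-mean-square distance of the beads from their centroid.
    """
    centred = ensemble.coords - ensemble.coords.mean(axis=1, keepdims=True)
    rg = np.sqrt((centred**2).sum(axis=2).mean(axis=1))
    return ScalarSeries(t=np.arange(ensemble.n_frames), value=rg,
                        label="Rg [nm]")


def rg_histogram(
    series: ScalarSeries, n_bins: int = 50,
    range: tuple[float, float] | None = None,
) -> RgHistogram:
    """Normalised histogram of a scalar series plus its mean.

    Densities integrate to 1 over the binned range; the returned mean is
    the plain series mean (the marker conventionally drawn on Rg
    histograms), not the binned approximation.
    """
    if n_bins < 2:
        raise IdpChainError("n_bins must be >= 2")
    if len(series.value) == 0:
        raise IdpChainError("empty series")
    density, edges = np.histogram(series.value, bins=n_bins, range=range,
                                  density=True)
    return RgHistogram(edges=edges, density=density,
                       mean=float(np.mean(series.value)))


# ---------------------------------------------------------------------------
# Orientational correlation and persistence length
# ---------------------------------------------------------------------------

def _unit_bond_vectors(ensemble: Ensemble) -> np.ndarray:
    bonds = ensemble.bond_vectors()
    norms = np.linalg.norm(bonds, axis=2)
    zero = np.argwhere(norms < 1e-12)
    if zero.size:
        t, i = zero[0]
        raise IdpChainError(
            f"zero-length bond between residues {i + 1} and {i + 2} "
            f"in frame {t}"
        )
    return bonds / norms[..., None]


def _block_stderr_over_frames(per_frame: np.ndarray,
                              n_blocks: int = 5) -> float:
    """Block standard error of the mean of a per-frame quantity.

    Returns NaN when fewer than two blocks are available.
    """
    n = per_frame.shape[0]
    nb = min(n_blocks, n)
    if nb < 2:
        return float("nan")
    usable = n - n % nb
    means = per_frame[:usable].reshape(nb, -1).mean(axis=1)
    mbar = means.mean()
    return float(np.sqrt(((means - mbar) ** 2).sum() / (nb * (nb - 1))))


def orientational_correlation(
    ensemble: Ensemble, s_max: int | None = None
) -> CorrelationProfile:
    """Bond-vector orientational correlation C(s) = <n_i . n_{i+s}>.

    n_i is the unit vector joining consecutive C-alpha positions; the
    average pools all valid (i, frame) pairs.  Uncertainties are block
    standard errors over five contiguous frame blocks.
    """
    n_bonds = ensemble.n_residues - 1
    if s_max is None:
        s_max = n_bonds - 1
    if not 1 <= s_max <= n_bonds - 1:
        raise IdpChainError(
            f"s_max must be in [1, {n_bonds - 1}] for {ensemble.n_residues} "
            f"residues"
        )
    u = _unit_bond_vectors(ensemble)
    s_vals = np.arange(1, s_max + 1)
    values = np.empty(s_max)
    errs = np.empty(s_max)
    for j, s in enumerate(s_vals):
        dots = (u[:, :-s, :] * u[:, s:, :]).sum(axis=2)  # (frames, pairs)
        values[j] = dots.mean()
        errs[j] = _block_stderr_over_frames(dots.mean(axis=1))
    return CorrelationProfile(s=s_vals, value=values, stderr=errs,
                              label="C(s)")


def fit_persistence(
    profile: CorrelationProfile, s_fit_max: int = 4
) -> PersistenceFit:
    """Fit C(s) = exp(-s/k) over s in {1..s_fit_max}; l_p = k x 0.38 nm.

    Linear least squares of ln C(s) on s (free intercept); k = -1/slope.
    The short default range reflects that the exponential regime of
    disordered chains holds only at small separations.
    """
    mask = (profile.s >= 1) & (profile.s <= s_fit_max)
    s = profile.s[mask]
    c = profile.value[mask]
    if s.size < 2:
        raise FitError("need at least 2 points with s <= s_fit_max")
    if np.any(c <= 0):
        bad = int(s[np.argmax(c <= 0)])
        raise FitError(
            f"C(s) <= 0 at s = {bad}: log fit undefined; try a shorter "
            f"fit range (s_fit_max < {bad})"
        )
    slope, intercept = np.polyfit(s, np.log(c), 1)
    if slope >= 0:
        raise FitError(
            "C(s) does not decay over the fit range; decay constant "
            "undefined (rod-like input?)"
        )
    k = -1.0 / slope
    resid = float(np.sum((np.log(c) - (slope * s + intercept)) ** 2))
    return PersistenceFit(k=float(k), l_p=float(k) * CA_SPACING_NM,
                          fit_s_max=int(s_fit_max), residual=resid)


def fit_power_law_tail(
    profile: CorrelationProfile, s_lo: int, s_hi: int
) -> PowerLawFit:
    """Fit C(s) ~ s^a over [s_lo, s_hi] by log-log linear regression.

    The exponent is reported with its sign (a decaying tail gives a
    negative exponent, e.g. -3/2 for long-range orientational order in a
    stiff disordered chain).
    """
    if s_hi - s_lo < 2:
        raise IdpChainError("need s_hi - s_lo >= 2")
    mask = (profile.s >= s_lo) & (profile.s <= s_hi)
    s = profile.s[mask]
    c = profile.value[mask]
    if s.size < 3:
        raise FitError("fewer than 3 profile points in [s_lo, s_hi]")
    if np.any(c <= 0):
        raise FitError("non-positive C(s) in fit range: log-log undefined")
    res = stats.linregress(np.log(s), np.log(c))
    return PowerLawFit(exponent=float(res.slope),
                       stderr=float(res.stderr),
                       s_lo=int(s_lo), s_hi=int(s_hi))


# ---------------------------------------------------------------------------
# Internal distances and Flory scaling
# ---------------------------------------------------------------------------

def internal_distance_profile(ensemble: Ensemble) -> InternalDistanceProfile:
    """Mean C-alpha distance R_s over all pairs at separation s, all frames."""
    n = ensemble.n_residues
    s_vals = np.arange(1, n)
    r = np.empty(n - 1)
    errs = np.empty(n - 1)
    for j, s in enumerate(s_vals):
        d = np.linalg.norm(
            ensemble.coords[:, s:, :] - ensemble.coords[:, :-s, :], axis=2
        )  # (frames, n - s)
        r[j] = d.mean()
        errs[j] = _block_stderr_over_frames(d.mean(axis=1))
    return InternalDistanceProfile(s=s_vals, r=r, stderr=errs)


def fit_flory(
    profile: InternalDistanceProfile,
    s_lo: int,
    s_hi: int,
    weighted: bool = False,
) -> FloryRegime:
    """Fit R_s = R_0 s^nu over [s_lo, s_hi] by log-space least squares.

    Unweighted by default; ``weighted=True`` applies inverse-variance
    weights derived from the per-s standard errors.
    """
    mask = (profile.s >= s_lo) & (profile.s <= s_hi)
    s = profile.s[mask].astype(float)
    r = profile.r[mask]
    if s.size < 3:
        raise FitError(
            f"fewer than 3 profile points in [{s_lo}, {s_hi}]"
        )
    x, y = np.log(s), np.log(r)
    if weighted and profile.stderr is not None:
        # d(ln R)/dR = 1/R: propagate linear stderr into log space
        w = (r / profile.stderr[mask]) ** 2
        w = np.where(np.isfinite(w), w, 0.0)
        if w.sum() == 0:
            raise FitError("all weights vanish; refit unweighted")
        xm = np.average(x, weights=w)
        ym = np.average(y, weights=w)
        nu = np.average((x - xm) * (y - ym), weights=w) / np.average(
            (x - xm) ** 2, weights=w
        )
        lnr0 = ym - nu * xm
        dof = max(s.size - 2, 1)
        resid = y - (lnr0 + nu * x)
        var_nu = np.average(resid**2, weights=w) / (
            np.average((x - xm) ** 2, weights=w) * dof
        )
        stderr = float(np.sqrt(var_nu))
    else:
        res = stats.linregress(x, y)
        nu, lnr0, stderr = res.slope, res.intercept, res.stderr
    return FloryRegime(s_lo=int(s_lo), s_hi=int(s_hi),
                       r0=float(np.exp(lnr0)), nu=float(nu),
                       nu_stderr=float(stderr) if stderr is not None else float("nan"))


def fit_flory_two_regime(
    profile: InternalDistanceProfile,
    split: int = 10,
    s_max: int | None = None,
    weighted: bool = False,
) -> FloryFit:
    """Scaling fits in two residue-separation regimes: s <= split, s > split.

    The split (default 10) marks where disordered proteins cross over from
    common, locally stiff statistics to sequence-dependent global scaling.
    If fewer than 3 points lie beyond the split, only the short-range
    regime is fitted and ``tail_fitted`` is False.
    """
    top = int(profile.s.max() if s_max is None else s_max)
    if split < 3:
        raise IdpChainError("split must leave >= 3 points in regime 1")
    regimes = [fit_flory(profile, 1, split, weighted=weighted)]
    tail_points = int(np.sum((profile.s > split) & (profile.s <= top)))
    tail_fitted = tail_points >= 3
    if tail_fitted:
        regimes.append(fit_flory(profile, split + 1, top, weighted=weighted))
    return FloryFit(regimes=regimes, split=int(split), tail_fitted=tail_fitted)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def contact_count_series(
    ensemble: Ensemble, cutoff: float = 0.8, min_separation: int = 3
) -> ScalarSeries:
    """Per-frame count of residue pairs with |i-j| >= min_separation within
    ``cutoff`` nm (C-alpha to C-alpha).

    Defaults (0.8 nm, |i-j| >= 3) are a common coarse contact definition
    for C-alpha traces; both are configurable.
    """
    if cutoff < 0:
        raise IdpChainError("cutoff must be non-negative")
    if min_separation < 1:
        raise IdpChainError("min_separation must be >= 1")
    n = ensemble.n_residues
    idx = np.arange(n)
    pair_mask = squareform(
        np.abs(np.subtract.outer(idx, idx)) >= min_separation, checks=False
    ).astype(bool)
    counts = np.empty(ensemble.n_frames)
    for t in range(ensemble.n_frames):
        d = pdist(ensemble.coords[t])
        counts[t] = np.count_nonzero(pair_mask & (d <= cutoff))
    return ScalarSeries(t=np.arange(ensemble.n_frames), value=counts,
                        label="n_c")


def contact_map(ensemble: Ensemble, cutoff: float = 0.8) -> np.ndarray:
    """Contact frequency matrix: entry (i, j) is the fraction of frames in
    which residues i and j are within ``cutoff`` nm.  Symmetric with unit
    diagonal."""
    if cutoff < 0:
        raise IdpChainError("cutoff must be non-negative")
    n = ensemble.n_residues
    freq = np.zeros((n, n))
    for t in range(ensemble.n_frames):
        d = squareform(pdist(ensemble.coords[t]))
        freq += d <= cutoff
    return freq / ensemble.n_frames
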