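"""Secondary chemical-shift pipeline: random-coil subtraction, offset
correction and per-atom RMSE.

Chemical shifts report the local chemical environment of backbone nuclei.
For a disordered protein the informative quantity is the *secondary* shift

    dCS(x, i) = CS(x, i) - CS_RC(x, i)

the deviation of residue i's shift for atom type x from the random-coil
reference value of that residue type — positive/negative dCS of CA, CB, N
etc. report transient secondary-structure propensity.

Computed shift sets carry a systematic referencing offset relative to the
experiment, so before comparison the calculated shifts are corrected by a
per-atom-type constant O obtained from a slope-fixed-to-1 regression of
experimental on calculated shifts (i.e. O is the mean residual); the
applied correction is CS_calc -> CS_calc + O.  Agreement per atom type is
then the root-mean-square error over the n shared residues

    RMSE(x) = sqrt( 1/n * sum_i (dCS_expt(x,i) - dCS_calc(x,i))^2 )

with an uncertainty from five-block averaging over residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble_io import BACKBONE_ATOMS, ShiftTable
from .exceptions import EmptyInputError, FitError, IdpChainError

__all__ = [
    "SecondaryShiftTable",
    "OffsetFit",
    "AtomRmse",
    "SecondaryShiftResult",
    "secondary_shifts",
    "fit_offset",
    "shift_rmse",
    "secondary_shift_report",
    "SHIFTX2_RMS_FLOOR_PPM",
]

#: Published per-atom RMS prediction floors (p.p.m.) of the SHIFTX2 shift
#: predictor, reported in pipeline output as context for interpreting RMSE
#: magnitudes (an ensemble cannot agree with experiment better than the
#: predictor's own accuracy).  Never asserted against.
SHIFTX2_RMS_FLOOR_PPM = {"N": 1.12, "CA": 0.44, "CB": 0.52,
                         "H": 0.17, "HA": 0.12}


@dataclass
class SecondaryShiftTable:
    """Per-residue secondary shifts dCS = CS - CS_RC for one shift set.

    ``records`` has columns res_index, res_name, atom, delta (p.p.m.);
    ``n_dropped`` counts input records whose (res_name, atom) pair was
    missing from the random-coil reference.
    """

    records: pd.DataFrame
    n_dropped: int = 0

    def atom_series(self, atom: str) -> pd.Series:
        sel = self.records[self.records["atom"] == atom.upper()]
        return sel.set_index("res_index")["delta"]


@dataclass
class OffsetFit:
    """Per-atom referencing offset O (p.p.m.), slope fixed to 1.

    When ``free_slope`` diagnostics are requested the unconstrained
    regression slope and intercept are reported too; the applied
    correction remains the pure offset.
    """

    atom: str
    offset: float
    n: int
    free_slope: float | None = None
    free_intercept: float | None = None


@dataclass
class AtomRmse:
    """RMSE (p.p.m.) between two secondary-shift sets for one atom type."""

    atom: str
    rmse: float
    stderr: float
    n: int


@dataclass
class SecondaryShiftResult:
    """Full per-atom comparison: offsets, RMSEs and bookkeeping."""

    offsets: dict[str, OffsetFit]
    rmse: dict[str, AtomRmse]
    n_dropped_expt: int
    n_dropped_calc: int
    context_floors_ppm: dict[str, float] = field(
        default_factory=lambda: dict(SHIFTX2_RMS_FLOOR_PPM)
    )


def secondary_shifts(cs: ShiftTable, rc: ShiftTable) -> SecondaryShiftTable:
    """Subtract random-coil reference values: dCS(x, i) = CS(x, i) - RC.

    The reference is matched by (residue type, atom); records whose pair
    is absent from the reference are dropped and counted, matching the
    convention of plotting per-residue bars with gaps.
    """
    ref = rc.reference_map()
    rows = []
    dropped = 0
    for row in cs.records.itertuples(index=False):
        key = (row.res_name, row.atom)
        if key not in ref:
            dropped += 1
            continue
        rows.append((row.res_index, row.res_name, row.atom,
                     row.shift - ref[key]))
    if not rows:
        raise EmptyInputError(
            "no shift record has a random-coil reference entry"
        )
    df = pd.DataFrame(rows, columns=["res_index", "res_name", "atom", "delta"])
    return SecondaryShiftTable(records=df, n_dropped=dropped)


def fit_offset(
    calc: ShiftTable,
    expt: ShiftTable,
    atom: str,
    free_slope_diagnostics: bool = False,
) -> OffsetFit:
    """Referencing offset O for one atom type: regression with slope 1.

    With the slope fixed to 1, the least-squares offset is the mean of
    (expt - calc) over residues present in both tables; the corrected
    calculated shifts are calc + O.  ``free_slope_diagnostics=True``
    additionally reports the unconstrained regression slope/intercept (for
    judging whether a pure offset is adequate) without applying them.
    """
    atom = atom.upper()
    if atom not in BACKBONE_ATOMS:
        raise IdpChainError(f"unknown atom {atom!r}")
    c = calc.atom_series(atom)
    e = expt.atom_series(atom)
    shared = c.index.intersection(e.index)
    if len(shared) < 3:
        raise FitError(
            f"only {len(shared)} shared residues for atom {atom}; "
            f"need >= 3 to fit an offset"
        )
    cv = c.loc[shared].to_numpy()
    ev = e.loc[shared].to_numpy()
    fit = OffsetFit(atom=atom, offset=float(np.mean(ev - cv)),
                    n=len(shared))
    if free_slope_diagnostics:
        slope, intercept = np.polyfit(cv, ev, 1)
        fit.free_slope = float(slope)
        fit.free_intercept = float(intercept)
    return fit


def _block_stderr_rmse(sq_dev: np.ndarray, n_blocks: int = 5) -> float:
    """Uncertainty of an RMSE from blockwise RMSEs over residues.

    The squared deviations (in residue order) are split into up to five
    contiguous blocks; the block-mean standard-error formula is applied to
    the per-block RMSEs so the result is on the p.p.m. scale of the RMSE
    itself.  NaN when fewer than two blocks are available.
    """
    nb = min(n_blocks, sq_dev.size)
    if nb < 2:
        return float("nan")
    usable = sq_dev.size - sq_dev.size % nb
    block_rmse = np.sqrt(sq_dev[:usable].reshape(nb, -1).mean(axis=1))
    mbar = block_rmse.mean()
    return float(np.sqrt(((block_rmse - mbar) ** 2).sum() / (nb * (nb - 1))))


def shift_rmse(
    dcs_a: SecondaryShiftTable,
    dcs_b: SecondaryShiftTable,
    atom: str,
) -> AtomRmse:
    """RMSE between two secondary-shift sets for one atom type.

    Computed over residues present in both sets; symmetric in its two
    arguments.
    """
    atom = atom.upper()
    a = dcs_a.atom_series(atom)
    b = dcs_b.atom_series(atom)
    shared = a.index.intersection(b.index).sort_values()
    n = len(shared)
    if n == 0:
        raise EmptyInputError(f"no shared residues for atom {atom}")
    dev = a.loc[shared].to_numpy() - b.loc[shared].to_numpy()
    sq = dev**2
    return AtomRmse(atom=atom, rmse=float(np.sqrt(sq.mean())),
                    stderr=_block_stderr_rmse(sq), n=n)


def secondary_shift_report(
    expt: ShiftTable,
    calc: ShiftTable,
    rc: ShiftTable,
    atoms: tuple[str, ...] | None = None,
    apply_offset: bool = True,
) -> SecondaryShiftResult:
    """End-to-end comparison of calculated against experimental shifts.

    Per atom type: fit the referencing offset on raw shifts, apply it to
    the calculated set (``apply_offset=False`` skips the correction),
    subtract the random-coil reference from both sets and report the
    secondary-shift RMSE.  Atom types with too few shared residues are
    silently omitted from the result dictionaries.
    """
    if atoms is None:
        atoms = tuple(
            sorted(set(expt.records["atom"]) & set(calc.records["atom"]))
        )
    dcs_expt = secondary_shifts(expt, rc)
    dcs_calc_raw = secondary_shifts(calc, rc)
    offsets: dict[str, OffsetFit] = {}
    rmses: dict[str, AtomRmse] = {}
    for atom in atoms:
        try:
            fit = fit_offset(calc, expt, atom)
        except FitError:
            continue
        offsets[atom] = fit
        dcs_calc = dcs_calc_raw
        if apply_offset:
            rec = dcs_calc_raw.records.copy()
            sel = rec["atom"] == atom
            rec.loc[sel, "delta"] = rec.loc[sel, "delta"] + fit.offset
            dcs_calc = SecondaryShiftTable(records=rec,
                                           n_dropped=dcs_calc_raw.n_dropped)
        try:
            rmses[atom] = shift_rmse(dcs_expt, dcs_calc, atom)
        except EmptyInputError:
            offsets.pop(atom)
    if not rmses:
        raise EmptyInputError("no atom type has enough shared residues")
    return SecondaryShiftResult(
        offsets=offsets,
        rmse=rmses,
        n_dropped_expt=dcs_expt.n_dropped,
        n_dropped_calc=dcs_calc_raw.n_dropped,
    )
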