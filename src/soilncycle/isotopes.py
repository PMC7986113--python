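"""Conversions among delta-15N, atom % 15N and atom percent excess.

All isotope abundances are carried in percent (0-100), not fraction, and
delta values in per mil versus atmospheric N2. The standard ratio is the
fractional 15N abundance of the reference (air N2 for nitrogen), exposed
everywhere as a parameter so other reference scales can be used.

These are pure functions accepting scalars or numpy arrays; they are the
arithmetic foundation of the tracer mass balance and pool-dilution modules.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "R_AIR_N2",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "atom_percent_excess",
]

#: Fractional abundance of 15N in atmospheric N2, the delta-scale reference.
R_AIR_N2 = 0.0036765


def _check_std_ratio(std_ratio: float) -> None:
    if not (0.0 < std_ratio < 1.0):
        raise ValueError(f"std_ratio must be in (0, 1), got {std_ratio}")


def delta_to_atom_percent(delta, std_ratio: float = R_AIR_N2):
    """Convert delta-15N (per mil) to atom % 15N.

    atom% = 100 * Std*(d/1000 + 1) / (1 + Std*(d/1000 + 1))

    where ``Std`` is the fractional 15N abundance of the isotopic standard.
    The function is strictly increasing in ``delta``; delta = -1000 (no
    heavy isotope) maps to 0 atom % and delta = 0 to 100*Std/(1+Std).

    Parameters
    ----------
    delta : float or array_like
        delta-15N in per mil; must be >= -1000 (physical lower bound).
    std_ratio : float
        15N/(14N+15N) fractional abundance of the standard, in (0, 1).

    Returns
    -------
    float or ndarray
        atom % 15N in [0, 100).
    """
    _check_std_ratio(std_ratio)
    d = np.asarray(delta, dtype=float)
    if np.any(d < -1000.0):
        raise ValueError("delta-15N below -1000 per mil is physically impossible")
    r = std_ratio * (d / 1000.0 + 1.0)
    out = 100.0 * r / (1.0 + r)
    return out.item() if np.isscalar(delta) else out


def atom_percent_to_delta(atom_percent, std_ratio: float = R_AIR_N2):
    """Convert atom % 15N to delta-15N (per mil); exact algebraic inverse
    of :func:`delta_to_atom_percent`.

    Raises ``ValueError`` for atom % outside [0, 100).
    """
    _check_std_ratio(std_ratio)
    ap = np.asarray(atom_percent, dtype=float)
    if np.any(ap < 0.0) or np.any(ap >= 100.0):
        raise ValueError("atom_percent must lie in [0, 100)")
    f = ap / 100.0
    # f = r/(1+r)  =>  r = f/(1-f);  r = Std*(d/1000+1)
    r = f / (1.0 - f)
    out = (r / std_ratio - 1.0) * 1000.0
    return out.item() if np.isscalar(atom_percent) else out


def atom_percent_excess(sample, background):
    """Atom percent excess: sample atom % 15N minus a matched background.

    No clamping is applied: a sample slightly below background (analytical
    noise at natural abundance) yields a small negative excess, which
    callers flag rather than silently truncate.
    """
    s = np.asarray(sample, dtype=float)
    b = np.asarray(background, dtype=float)
    if np.any((s < 0) | (s > 100)) or np.any((b < 0) | (b > 100)):
        raise ValueError("atom % values must lie in [0, 100]")
    out = s - b
    return out.item() if np.isscalar(sample) and np.isscalar(background) else out
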