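"""FOD-M statistics: divergence entropy, RD, the K-modified profile M,
the optimal-K scan, and unit/fragment analysis.

The micelle-likeness statistic RD (*relative distance*) locates the
observed profile O between the Gaussian ideal T and the featureless
uniform reference R:

    RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R))

RD < 0.5 means O is closer to T than to R — a centric hydrophobic core
is present.  The environment-modified profile

    M_i(K) = [ T_i + K * (T_MAX - T_i)_n ]_n

mixes T with its "inverted" complement; the subscript n denotes
normalisation to unit sum.  K = 0 reproduces T (pure aqueous field);
large K flips the central maximum into a minimum, the signature of a
membrane-like hydrophobic environment.  The optimal K minimises
D_KL(O|M(K)) over a grid, and RD_Kopt re-expresses RD against M_opt
instead of R.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .hydro_field import (
    GaussianField,
    HydroProfile,
    HydroScale,
    observed_hydrophobicity_raw,
    uniform_profile,
)
from .structure_io import EffectiveAtomSet

__all__ = [
    "KGrid",
    "KScanCurve",
    "FodResult",
    "kl_divergence",
    "rd",
    "m_profile",
    "optimize_k",
    "rd_kopt",
    "analyze_profiles",
    "analyze_unit",
    "fragment_status",
    "UndefinedRDError",
]

log = logging.getLogger(__name__)


class UndefinedRDError(ZeroDivisionError):
    """Both divergences vanished (O = T = R); RD is undefined."""


@dataclass(frozen=True)
class KGrid:
    """Search grid for the environment coefficient K.

    Default 0.0 to 5.0 in steps of 0.1.  Reported optimal-K values in
    the FOD-M literature are multiples of 0.1, with K = 3 already an
    extreme membrane-like case; 5.0 leaves headroom.
    """

    k_min: float = 0.0
    k_max: float = 5.0
    step: float = 0.1

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.k_max < self.k_min or self.k_min < 0:
            raise ValueError("need 0 <= k_min <= k_max")

    def points(self) -> np.ndarray:
        n = int(round((self.k_max - self.k_min) / self.step)) + 1
        return np.round(self.k_min + self.step * np.arange(n), 10)


@dataclass
class KScanCurve:
    """D_KL(O|M(K)) along the K grid."""

    k_values: np.ndarray
    dkl_values: np.ndarray  # bits

    def __post_init__(self):
        if len(self.k_values) != len(self.dkl_values):
            raise ValueError("k and dkl arrays misaligned")

    @property
    def k_opt(self) -> float:
        # argmin takes the first minimum: ties break toward the smallest K
        return float(self.k_values[int(np.argmin(self.dkl_values))])


@dataclass
class FodResult:
    """RD, optimal K and the component divergences for one unit/fragment."""

    rd: float
    k_opt: float
    rd_kopt: float
    dkl_ot: float      # D_KL(O|T), bits
    dkl_or: float      # D_KL(O|R), bits
    dkl_om_opt: float  # D_KL(O|M(K_opt)), bits
    n_residues: int
    unit_label: str = ""
    fragment_label: Optional[str] = None
    skipped_residues: list = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "unit": self.unit_label,
            "fragment": self.fragment_label,
            "n_residues": self.n_residues,
            "RD": self.rd,
            "K_opt": self.k_opt,
            "RD_Kopt": self.rd_kopt,
            "DKL_OT_bits": self.dkl_ot,
            "DKL_OR_bits": self.dkl_or,
            "DKL_OM_opt_bits": self.dkl_om_opt,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _aligned(P: HydroProfile, Q: HydroProfile) -> tuple[np.ndarray, np.ndarray]:
    p, q = np.asarray(P.values), np.asarray(Q.values)
    if p.shape != q.shape:
        raise ValueError(
            f"profiles misaligned: {P.role} has {p.shape}, {Q.role} {q.shape}"
        )
    return p, q


def kl_divergence(P: HydroProfile, Q: HydroProfile, base: float = 2.0) -> float:
    """Divergence entropy D_KL(P|Q) = sum P_i log(P_i/Q_i), in bits.

    Zero P entries contribute nothing (0·log 0 = 0); a positive P entry
    facing a zero Q entry makes the divergence infinite and raises.
    The epsilon floor applied when building observed profiles prevents
    that case in normal pipelines.
    """
    p, q = _aligned(P, Q)
    support = p > 0
    if np.any(q[support] <= 0):
        raise ValueError(
            f"infinite divergence: {Q.role} has zero mass where "
            f"{P.role} is positive"
        )
    val = float(np.sum(p[support] * np.log2(p[support] / q[support])))
    if base != 2.0:
        val *= np.log(2.0) / np.log(base)
    return max(val, 0.0)  # clip the tiny negative round-off near P == Q


def rd(O: HydroProfile, T: HydroProfile, R: HydroProfile,
       base: float = 2.0) -> float:
    """Relative distance RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)).

    RD < 0.5 indicates the hydrophobic core (O closer to the Gaussian
    ideal than to uniform).  Independent of the logarithm base.
    """
    d_ot = kl_divergence(O, T, base)
    d_or = kl_divergence(O, R, base)
    denom = d_ot + d_or
    if denom == 0.0:
        raise UndefinedRDError("O coincides with both T and R")
    return d_ot / denom


def m_profile(T: HydroProfile, K: float,
              t_max: Optional[float] = None) -> HydroProfile:
    """Environment-modified profile M(K) = [T + K·(T_MAX - T)_n]_n.

    The complement (T_MAX - T_i) is normalised to unit sum (inner n),
    scaled by K, added to T and the result normalised again (outer n).
    ``t_max`` defaults to max(T) over the profile; a fragment analysis
    passes the fragment-local maximum explicitly.  A flat T (complement
    identically zero) degenerates to M = T for any K.
    """
    if K < 0:
        raise ValueError("K must be nonnegative")
    t = np.asarray(T.values, dtype=float)
    if t_max is None:
        t_max = float(t.max())
    comp = t_max - t
    comp_sum = comp.sum()
    if comp_sum <= 0 or np.allclose(comp, 0.0):
        log.info("flat T profile: M(K) degenerates to T")
        m = t.copy()
    else:
        m = t + K * (comp / comp_sum)
    return HydroProfile("M", m / m.sum(), list(T.residue_ids))


def optimize_k(O: HydroProfile, T: HydroProfile,
               grid: KGrid = KGrid(),
               t_max: Optional[float] = None) -> tuple[float, KScanCurve]:
    """Scan the K grid for the M(K) closest to O in divergence entropy.

    Returns the optimal K (ties broken toward the smallest K) and the
    full scan curve.
    """
    ks = grid.points()
    dkl = np.array([
        kl_divergence(O, m_profile(T, float(k), t_max)) for k in ks
    ])
    curve = KScanCurve(ks, dkl)
    return curve.k_opt, curve


def rd_kopt(O: HydroProfile, T: HydroProfile, M_opt: HydroProfile,
            base: float = 2.0) -> float:
    """RD against the optimal modified profile:
    D_KL(O|T) / (D_KL(O|T) + D_KL(O|M_opt))."""
    d_ot = kl_divergence(O, T, base)
    d_om = kl_divergence(O, M_opt, base)
    denom = d_ot + d_om
    if denom == 0.0:
        raise UndefinedRDError("O coincides with both T and M_opt")
    return d_ot / denom


def analyze_profiles(
    O: HydroProfile,
    T: HydroProfile,
    grid: KGrid = KGrid(),
    t_max: Optional[float] = None,
    unit_label: str = "",
    fragment_label: Optional[str] = None,
) -> tuple[FodResult, KScanCurve]:
    """Full FOD-M readout for one aligned (O, T) pair."""
    R = uniform_profile(T.n, T.residue_ids)
    d_ot = kl_divergence(O, T)
    d_or = kl_divergence(O, R)
    if d_ot + d_or == 0.0:
        raise UndefinedRDError("O coincides with both T and R")
    k_opt, curve = optimize_k(O, T, grid, t_max)
    m_opt = m_profile(T, k_opt, t_max)
    d_om = kl_divergence(O, m_opt)
    res = FodResult(
        rd=d_ot / (d_ot + d_or),
        k_opt=k_opt,
        rd_kopt=d_ot / (d_ot + d_om) if (d_ot + d_om) > 0 else 0.0,
        dkl_ot=d_ot,
        dkl_or=d_or,
        dkl_om_opt=d_om,
        n_residues=T.n,
        unit_label=unit_label,
        fragment_label=fragment_label,
    )
    return res, curve


def analyze_unit(
    atoms: EffectiveAtomSet,
    field: GaussianField,
    scale: Optional[HydroScale] = None,
    hydrophobicity: Optional[np.ndarray] = None,
    cutoff: float = 9.0,
    grid: KGrid = KGrid(),
    unit_label: str = "",
) -> tuple[FodResult, dict[str, HydroProfile], KScanCurve]:
    """FOD-M analysis of a whole structural unit.

    Builds T from the fitted Gaussian field, O from Levitt pairwise
    interactions, R uniform; returns the result, the profiles (including
    M at the optimal K) and the K-scan curve.
    """
    t_raw = field.density(atoms.positions)
    o_raw = observed_hydrophobicity_raw(atoms, scale, hydrophobicity, cutoff)
    T = HydroProfile("T", t_raw / t_raw.sum(), list(atoms.residue_ids))
    O = HydroProfile("O", o_raw / o_raw.sum(), list(atoms.residue_ids))
    result, curve = analyze_profiles(O, T, grid, unit_label=unit_label)
    profiles = {
        "T": T,
        "O": O,
        "R": uniform_profile(atoms.n, list(atoms.residue_ids)),
        "M": m_profile(T, result.k_opt),
    }
    return result, profiles, curve


def fragment_status(
    atoms: EffectiveAtomSet,
    field: GaussianField,
    scale: Optional[HydroScale] = None,
    fragment: Optional[tuple[int, int]] = None,
    grid: KGrid = KGrid(),
    hydrophobicity: Optional[np.ndarray] = None,
    cutoff: float = 9.0,
    chain: Optional[str] = None,
    unit_label: str = "",
    fragment_label: Optional[str] = None,
) -> FodResult:
    """FOD-M status of a fragment (e.g. an IDR) inside its structural unit.

    The parent unit's Gaussian parameters are reused unchanged: T and O
    are evaluated over the whole unit, restricted to the fragment's
    residues and renormalised there; R becomes 1/n_fragment; M uses the
    fragment-local T maximum.  ``fragment`` is an inclusive author-number
    range (optionally limited to ``chain``); None means the whole unit.
    """
    if fragment is None:
        mask = np.ones(atoms.n, dtype=bool)
    else:
        lo, hi = fragment
        mask = np.array([
            lo <= rid.number <= hi and (chain is None or rid.chain == chain)
            for rid in atoms.residue_ids
        ])
    n_frag = int(mask.sum())
    if n_frag < 2:
        raise ValueError(
            f"fragment {fragment} resolves to {n_frag} residue(s); need >= 2"
        )

    t_raw = field.density(atoms.positions)
    o_raw = observed_hydrophobicity_raw(atoms, scale, hydrophobicity, cutoff)

    rids = [atoms.residue_ids[i] for i in np.flatnonzero(mask)]
    T = HydroProfile("T", t_raw[mask] / t_raw[mask].sum(), rids)
    O = HydroProfile("O", o_raw[mask] / o_raw[mask].sum(), rids)

    label = fragment_label
    if label is None and fragment is not None:
        label = f"{fragment[0]}-{fragment[1]}"
    result, _ = analyze_profiles(
        O, T, grid,
        t_max=float(T.values.max()),  # fragment-local T_MAX
        unit_label=unit_label,
        fragment_label=label,
    )
    return result
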