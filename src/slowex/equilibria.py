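"""Mass-action equilibria for a two-site receptor.

The model describes one enzyme E with two independent, non-interacting
ligand-binding sites — an orthosteric (ATP) pocket with dissociation
constant ``KDO`` and an allosteric (myristoyl) pocket with ``KDA`` — and a
single ligand species L shared between them.  Four enzyme states follow:

====  =============================  =========================
E0    apo                            no ligand bound
E1    orthosteric-bound              one ligand in ATP site
E2    allosteric-bound               one ligand in myristoyl site
E3    doubly bound                   ligand in both sites
====  =============================  =========================

The equilibrium conditions are ``E0·L = KDO·E1``, ``E0·L = KDA·E2``,
``E1·L = KDA·E3`` and ``E2·L = KDO·E3`` together with the conservation
laws ``E0+E1+E2+E3 = Et`` and ``L+E1+E2+2·E3 = Lt``.  Because the sites
are independent (the same KDO governs E0→E1 and E2→E3), the site
occupancies factorize in the free-ligand concentration L, and the whole
system reduces to one monotone scalar equation

    g(L) = L + Et·L/(KDO+L) + Et·L/(KDA+L) − Lt = 0,

which is solved by a bracketed root search on [0, Lt].  Monotonicity of g
guarantees a unique physical solution and global convergence, with no
cubic-branch selection logic.

All concentrations are molar.  A dissociation constant at or above
``SITE_DISABLED_KD`` (1 M) is treated as "site absent": the occupancy of
such a site is negligible at any realistic ligand concentration, so the
same code path serves the single-site specializations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError

__all__ = [
    "SITE_DISABLED_KD",
    "BindingConstants",
    "TitrationPoint",
    "EquilibriumState",
    "OccupancyCurve",
    "CompetitionAssay",
    "CompetitionResult",
    "solve_two_site",
    "occupancies",
    "predict_titration_curve",
    "single_site_bound_fraction",
    "solve_competition",
]

#: Dissociation constants at or above this value (molar) mark a site as absent.
SITE_DISABLED_KD = 1.0

#: Default relative tolerance for conservation residuals of a solved state.
DEFAULT_SOLVE_RTOL = 1e-10


def _require_finite_nonnegative(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise DomainError(f"{name} must be finite and non-negative, got {value!r}")
    return value


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise DomainError(f"{name} must be finite and strictly positive, got {value!r}")
    return value


@dataclass(frozen=True)
class BindingConstants:
    """Dissociation constants of the two ligand pockets, in molar.

    Parameters
    ----------
    kd_orthosteric : float
        KD of the orthosteric (ATP) site.
    kd_allosteric : float
        KD of the allosteric (myristoyl) site.

    A value ``>= SITE_DISABLED_KD`` (1 M) acts as a pseudo-infinite
    sentinel that disables the site while keeping a single code path.
    """

    kd_orthosteric: float
    kd_allosteric: float

    def __post_init__(self) -> None:
        _require_positive("kd_orthosteric", self.kd_orthosteric)
        _require_positive("kd_allosteric", self.kd_allosteric)

    def swapped(self) -> "BindingConstants":
        """Constants with the two sites interchanged (KDO ↔ KDA)."""
        return BindingConstants(self.kd_allosteric, self.kd_orthosteric)

    @property
    def orthosteric_disabled(self) -> bool:
        return self.kd_orthosteric >= SITE_DISABLED_KD

    @property
    def allosteric_disabled(self) -> bool:
        return self.kd_allosteric >= SITE_DISABLED_KD


@dataclass(frozen=True)
class TitrationPoint:
    """Total enzyme and total ligand concentration at one titration point (molar)."""

    total_enzyme: float
    total_ligand: float

    def __post_init__(self) -> None:
        _require_positive("total_enzyme", self.total_enzyme)
        _require_finite_nonnegative("total_ligand", self.total_ligand)


@dataclass(frozen=True)
class EquilibriumState:
    """Concentrations of the four enzyme states and free ligand (molar).

    ``e0``..``e3`` are apo, orthosteric-bound, allosteric-bound and doubly
    bound enzyme; ``free_ligand`` is unbound ligand L.
    """

    e0: float
    e1: float
    e2: float
    e3: float
    free_ligand: float

    def __post_init__(self) -> None:
        for name in ("e0", "e1", "e2", "e3", "free_ligand"):
            _require_finite_nonnegative(name, getattr(self, name))

    @property
    def total_enzyme(self) -> float:
        return self.e0 + self.e1 + self.e2 + self.e3

    @property
    def bound_ligand(self) -> float:
        return self.e1 + self.e2 + 2.0 * self.e3


class CompetitionResult(NamedTuple):
    """Outcome of a one-site, two-ligand reporter-displacement calculation."""

    reporter_bound_fraction: float
    competitor_bound_fraction: float
    displacement_fraction: float


@dataclass(frozen=True)
class CompetitionAssay:
    """One shared site, two mutually exclusive ligands (reporter + competitor).

    Models a ¹⁹F reporter-displacement experiment: a labeled reporter ligand
    with known ``kd_reporter`` occupies the site; an unlabeled competitor
    with ``kd_competitor`` displaces it.  All concentrations molar.
    """

    total_enzyme: float
    total_reporter: float
    total_competitor: float
    kd_reporter: float
    kd_competitor: float

    def __post_init__(self) -> None:
        _require_finite_nonnegative("total_enzyme", self.total_enzyme)
        _require_finite_nonnegative("total_reporter", self.total_reporter)
        _require_finite_nonnegative("total_competitor", self.total_competitor)
        _require_positive("kd_reporter", self.kd_reporter)
        _require_positive("kd_competitor", self.kd_competitor)


@dataclass(frozen=True)
class OccupancyCurve:
    """Predicted fractional site occupancies along a ligand series.

    ``occ_orthosteric[i] = (e1+e3)/Et`` and ``occ_allosteric[i] = (e2+e3)/Et``
    at total ligand ``ligand_series[i]``.
    """

    ligand_series: np.ndarray
    occ_orthosteric: np.ndarray
    occ_allosteric: np.ndarray
    states: tuple[EquilibriumState, ...] = field(default=(), repr=False)

    def __len__(self) -> int:
        return len(self.ligand_series)

    def to_frame(self):
        """Curve as a pandas DataFrame (columns Lt_molar, occ_orthosteric, occ_allosteric)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "Lt_molar": self.ligand_series,
                "occ_orthosteric": self.occ_orthosteric,
                "occ_allosteric": self.occ_allosteric,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def _free_ligand_balance(L: float, kdo: float, kda: float, et: float, lt: float) -> float:
    # grouped so the expression is bit-exact under kdo <-> kda exchange
    return (et * L / (kdo + L) + et * L / (kda + L)) + (L - lt)


def solve_two_site(
    constants: BindingConstants,
    point: TitrationPoint,
    *,
    rtol: float = DEFAULT_SOLVE_RTOL,
    max_iter: int = 200,
) -> EquilibriumState:
    """Solve the four-state two-site equilibrium at one titration point.

    Finds the free-ligand concentration L as the unique root of the
    monotone balance ``g(L) = L + Et·L/(KDO+L) + Et·L/(KDA+L) − Lt`` on
    ``[0, Lt]`` and reconstructs the state concentrations from the
    independent-site occupancy factors ``fo = L/(KDO+L)``,
    ``fa = L/(KDA+L)``:

        e0 = Et(1−fo)(1−fa),  e1 = Et·fo(1−fa),
        e2 = Et(1−fo)·fa,     e3 = Et·fo·fa.

    Raises
    ------
    DomainError
        On non-finite or negative inputs.
    ConvergenceError
        If the bracketed search fails or conservation residuals exceed
        ``rtol`` (relative to the larger of Et and Lt).
    """
    kdo, kda = constants.kd_orthosteric, constants.kd_allosteric
    et, lt = point.total_enzyme, point.total_ligand

    if lt == 0.0:
        return EquilibriumState(e0=et, e1=0.0, e2=0.0, e3=0.0, free_ligand=0.0)

    try:
        free_l = brentq(
            _free_ligand_balance,
            0.0,
            lt,
            args=(kdo, kda, et, lt),
            xtol=1e-30,
            rtol=8.9e-16,
            maxiter=max_iter,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise ConvergenceError(
            f"free-ligand root search failed at Et={et:g} M, Lt={lt:g} M: {exc}"
        ) from exc

    fo = free_l / (kdo + free_l)
    fa = free_l / (kda + free_l)
    # products grouped so a kdo <-> kda swap exchanges e1/e2 bit-exactly
    state = EquilibriumState(
        e0=et * ((1.0 - fo) * (1.0 - fa)),
        e1=et * (fo * (1.0 - fa)),
        e2=et * ((1.0 - fo) * fa),
        e3=et * (fo * fa),
        free_ligand=free_l,
    )

    scale = max(et, lt)
    enzyme_resid = abs(state.total_enzyme - et) / et
    ligand_resid = abs(state.free_ligand + state.bound_ligand - lt) / scale
    if enzyme_resid > rtol or ligand_resid > rtol:
        raise ConvergenceError(
            f"conservation residuals exceed tolerance at Et={et:g} M, Lt={lt:g} M: "
            f"enzyme {enzyme_resid:.3e}, ligand {ligand_resid:.3e} (rtol {rtol:g})"
        )
    return state


def occupancies(state: EquilibriumState, total_enzyme: float) -> tuple[float, float]:
    """Fractional occupancies ``((e1+e3)/Et, (e2+e3)/Et)`` of the two sites.

    The state must already be physical: no clamping is applied, and a
    fraction outside [0, 1] (beyond rounding) raises ``DomainError``.
    """
    et = float(total_enzyme)
    if et <= 0.0 or not math.isfinite(et):
        raise DomainError(f"total_enzyme must be positive, got {et!r}")
    occ_o = (state.e1 + state.e3) / et
    occ_a = (state.e2 + state.e3) / et
    eps = 1e-12
    for name, occ in (("orthosteric", occ_o), ("allosteric", occ_a)):
        if occ < -eps or occ > 1.0 + eps:
            raise DomainError(f"{name} occupancy {occ!r} outside [0, 1]; inconsistent state")
    return min(max(occ_o, 0.0), 1.0), min(max(occ_a, 0.0), 1.0)


def predict_titration_curve(
    constants: BindingConstants,
    total_enzyme: float,
    ligand_series: Sequence[float],
    *,
    rtol: float = DEFAULT_SOLVE_RTOL,
) -> OccupancyCurve:
    """Solve the two-site model along an ascending total-ligand series.

    Returns one equilibrium per point plus the two fractional-occupancy
    series, e.g. the dashed theoretical curves of a titration figure
    (Et = 79 µM, KDO = 10 nM, KDA = 10 µM reproduces the reference
    scenario where the orthosteric occupancy rises quasi-linearly to the
    equivalence point while the allosteric occupancy lags far below).
    """
    series = np.asarray(ligand_series, dtype=float)
    if series.ndim != 1 or series.size == 0:
        raise DomainError("ligand_series must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(series)) or np.any(series < 0.0):
        raise DomainError("ligand_series must be finite and non-negative")
    if np.any(np.diff(series) < 0.0):
        raise DomainError("ligand_series must be sorted ascending")

    states = []
    occ_o = np.empty_like(series)
    occ_a = np.empty_like(series)
    for i, lt in enumerate(series):
        try:
            state = solve_two_site(
                constants, TitrationPoint(total_enzyme, lt), rtol=rtol
            )
        except ConvergenceError as exc:
            raise ConvergenceError(f"titration point {i} (Lt={lt:g} M): {exc}") from exc
        states.append(state)
        occ_o[i], occ_a[i] = occupancies(state, total_enzyme)
    return OccupancyCurve(
        ligand_series=series,
        occ_orthosteric=occ_o,
        occ_allosteric=occ_a,
        states=tuple(states),
    )


def single_site_bound_fraction(kd: float, total_enzyme: float, total_ligand: float) -> float:
    """Closed-form bound fraction Eb/Et of a single-site receptor.

    Solves the quadratic conservation system exactly:

        Eb = ((Et+Lt+KD) − sqrt((Et+Lt+KD)² − 4·Et·Lt)) / 2

    evaluated in the numerically stable form ``2·Et·Lt / (b + sqrt(b²−4·Et·Lt))``
    with ``b = Et+Lt+KD``.  This is both the weak/tight-binding oracle for
    the two-site solver with one site disabled and the fitting kernel of
    the one-site model variants.
    """
    kd = _require_positive("kd", kd)
    et = _require_positive("total_enzyme", total_enzyme)
    lt = _require_finite_nonnegative("total_ligand", total_ligand)
    if lt == 0.0:
        return 0.0
    b = et + lt + kd
    disc = b * b - 4.0 * et * lt
    bound = 2.0 * et * lt / (b + math.sqrt(disc))
    return bound / et


def _single_site_bound_fraction_vec(kd: float, et: float, lt: np.ndarray) -> np.ndarray:
    """Vectorized form of :func:`single_site_bound_fraction` (internal fit kernel)."""
    lt = np.asarray(lt, dtype=float)
    b = et + lt + kd
    disc = b * b - 4.0 * et * lt
    return np.where(lt > 0.0, 2.0 * lt / (b + np.sqrt(np.maximum(disc, 0.0))), 0.0)


def solve_competition(
    assay: CompetitionAssay,
    *,
    rtol: float = DEFAULT_SOLVE_RTOL,
    max_iter: int = 200,
) -> CompetitionResult:
    """Solve the one-site, two-ligand competition equilibrium.

    Reporter R and competitor C bind the same site mutually exclusively:
    ``E·R = KdR·ER`` and ``E·C = KdC·EC`` with conservation of enzyme,
    reporter and competitor.  Writing the bound species in terms of free
    enzyme E0, ``ER = Rt·E0/(KdR+E0)`` and ``EC = Ct·E0/(KdC+E0)``, the
    enzyme balance

        f(E0) = E0 + Rt·E0/(KdR+E0) + Ct·E0/(KdC+E0) − Et

    is monotone on [0, Et] and solved by bracketed root search.

    Returns bound fractions normalized to total enzyme (Eb/Et) and the
    displacement fraction ``1 − ER(with C)/ER(without C)``.
    """
    et = assay.total_enzyme
    rt, ct = assay.total_reporter, assay.total_competitor
    kdr, kdc = assay.kd_reporter, assay.kd_competitor

    if et == 0.0:
        return CompetitionResult(0.0, 0.0, 0.0)

    def balance(e0: float, ct_: float) -> float:
        return e0 + rt * e0 / (kdr + e0) + ct_ * e0 / (kdc + e0) - et

    def bound_reporter(ct_: float) -> float:
        if balance(et, ct_) <= 0.0:  # no ligand at all
            return 0.0
        try:
            e0 = brentq(balance, 0.0, et, args=(ct_,), xtol=1e-30,
                        rtol=8.9e-16, maxiter=max_iter)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
            raise ConvergenceError(f"competition root search failed: {exc}") from exc
        return rt * e0 / (kdr + e0)

    if balance(et, ct) <= 0.0:
        return CompetitionResult(0.0, 0.0, 0.0)
    e0 = brentq(balance, 0.0, et, args=(ct,), xtol=1e-30, rtol=8.9e-16, maxiter=max_iter)
    er = rt * e0 / (kdr + e0)
    ec = ct * e0 / (kdc + e0)

    resid = abs(e0 + er + ec - et) / max(et, rt + ct)
    if resid > rtol:
        raise ConvergenceError(f"competition enzyme balance residual {resid:.3e} > {rtol:g}")

    er_baseline = bound_reporter(0.0)
    displacement = 0.0 if er_baseline == 0.0 else 1.0 - er / er_baseline
    return CompetitionResult(er / et, ec / et, displacement)
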