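"""Peak-list I/O and slow-exchange population analysis.

In the slow-exchange NMR regime a residue whose environment differs
between the apo and ligand-bound protein gives two separate amide
resonances whose intensities are proportional to the state populations.
The relative bound population is therefore

    pi = Ii / (Ii + Ia)

with Ia and Ii the apo- and bound-state peak heights.  This assumes equal
per-molecule observability of the two resonances (equal linewidth and
relaxation); an optional per-residue correction factor relaxes it.

Peak lists use the Sparky ``.list`` dialect — whitespace-separated
``assignment  w1  w2  height`` with an optional header line — with the
convention w1 = ¹⁵N (ppm), w2 = ¹H (ppm), stated explicitly because the
dimension order is ambiguous in the wild.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .errors import (
    AmbiguityError,
    DomainError,
    PeakListError,
    UndefinedPopulationError,
)

__all__ = [
    "Peak",
    "PeakPairSeries",
    "ExchangeRegimeInput",
    "read_peak_list",
    "write_peak_list",
    "pair_apo_bound",
    "population_from_intensities",
    "exchange_rate_bound",
    "classify_exchange_regime",
    "residue_of",
]

#: Default pairing tolerances (ppm): a peak matches a reference position if
#: it lies within this box in both dimensions.
DEFAULT_TOL_H = 0.03
DEFAULT_TOL_N = 0.3

_RESIDUE_RE = re.compile(r"^([A-Za-z]{1,3}\d+)")


@dataclass(frozen=True)
class Peak:
    """One cross peak: assignment label, ¹⁵N and ¹H shifts (ppm), height.

    ``artifact`` marks peaks whose height is physically suspect (the reader
    sets it for negative heights); such peaks are excluded from population
    arithmetic.
    """

    assignment: str
    shift_n: float
    shift_h: float
    height: float
    artifact: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.shift_n) and math.isfinite(self.shift_h)):
            raise DomainError(f"peak {self.assignment!r} has non-finite shifts")
        if not math.isfinite(self.height):
            raise DomainError(f"peak {self.assignment!r} has non-finite height")
        if self.height < 0.0 and not self.artifact:
            raise DomainError(
                f"peak {self.assignment!r} has negative height {self.height!r} "
                "but is not flagged as artifact"
            )


def residue_of(assignment: str) -> str:
    """Residue label of an assignment string (``"G149N-H"`` → ``"G149"``)."""
    m = _RESIDUE_RE.match(assignment)
    return m.group(1) if m else assignment


@dataclass
class PeakPairSeries:
    """Apo/bound intensities and bound population of one residue across a titration.

    ``flags[i]`` collects per-point annotations such as ``apo_not_detected``
    (missing peak read as intensity 0) or ``undefined`` (both intensities 0,
    population is NaN).
    """

    residue: str
    state_role: str
    intensity_apo: np.ndarray
    intensity_bound: np.ndarray
    population_bound: np.ndarray
    flags: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.intensity_apo)
        if not (len(self.intensity_bound) == len(self.population_bound) == n):
            raise DomainError("series lengths differ")
        if not self.flags:
            self.flags = [() for _ in range(n)]

    def __len__(self) -> int:
        return len(self.intensity_apo)


@dataclass(frozen=True)
class ExchangeRegimeInput:
    """Chemical-shift separation Δδ (ppm) and nucleus Larmor frequency ν (MHz)."""

    shift_separation: float
    nucleus_frequency: float

    def __post_init__(self) -> None:
        if not (self.shift_separation > 0.0 and math.isfinite(self.shift_separation)):
            raise DomainError("shift_separation must be positive and finite")
        if not (self.nucleus_frequency > 0.0 and math.isfinite(self.nucleus_frequency)):
            raise DomainError("nucleus_frequency must be positive and finite")


# ---------------------------------------------------------------------------
# Sparky-list I/O


def read_peak_list(stream: TextIO | Iterable[str], format_dialect: str = "sparky") -> list[Peak]:
    """Parse a Sparky-style peak list (assignment, w1=¹⁵N ppm, w2=¹H ppm, height).

    Header lines (first token ``Assignment``) and blank lines are skipped.
    A malformed data line raises :class:`PeakListError` naming the line
    number.  An empty list triggers a warning but is returned as ``[]``.
    """
    if format_dialect != "sparky":
        raise PeakListError(f"unsupported peak-list dialect {format_dialect!r}")
    peaks: list[Peak] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if tokens[0].lower() == "assignment":
            continue
        if len(tokens) != 4:
            raise PeakListError(
                f"line {lineno}: expected 4 fields (assignment w1 w2 height), "
                f"got {len(tokens)}: {line!r}"
            )
        try:
            w1, w2, height = float(tokens[1]), float(tokens[2]), float(tokens[3])
        except ValueError:
            raise PeakListError(f"line {lineno}: non-numeric field in {line!r}") from None
        peaks.append(
            Peak(
                assignment=tokens[0],
                shift_n=w1,
                shift_h=w2,
                height=height,
                artifact=height < 0.0,
            )
        )
    if not peaks:
        warnings.warn("peak list contained no peaks", stacklevel=2)
    return peaks


def write_peak_list(peaks: Sequence[Peak], stream: TextIO) -> None:
    """Write peaks in the Sparky dialect; round-trips with :func:`read_peak_list`."""
    stream.write(f"{'Assignment':>17s} {'w1':>10s} {'w2':>9s} {'Height':>16s}\n\n")
    for p in peaks:
        stream.write(
            f"{p.assignment:>17s} {p.shift_n:10.4f} {p.shift_h:9.4f} {p.height:16.10e}\n"
        )


# ---------------------------------------------------------------------------
# Apo/bound pairing and populations


def _matches(peak: Peak, ref: Peak, tol_h: float, tol_n: float) -> bool:
    return abs(peak.shift_n - ref.shift_n) <= tol_n and abs(peak.shift_h - ref.shift_h) <= tol_h


def _pick_candidate(
    peaks: Sequence[Peak],
    ref: Peak,
    other_ref: Peak | None,
    tol_h: float,
    tol_n: float,
    context: str,
) -> Peak | None:
    """Unique peak matching ``ref``; None if absent; AmbiguityError otherwise."""
    hits = [p for p in peaks if _matches(p, ref, tol_h, tol_n)]
    if len(hits) > 1:
        listing = "; ".join(
            f"{p.assignment} ({p.shift_n:.3f}, {p.shift_h:.3f})" for p in hits
        )
        raise AmbiguityError(
            f"{context}: {len(hits)} peaks match reference "
            f"({ref.shift_n:.3f}, {ref.shift_h:.3f}) within tolerance: {listing}"
        )
    if hits and other_ref is not None and _matches(hits[0], other_ref, tol_h, tol_n):
        raise AmbiguityError(
            f"{context}: peak ({hits[0].shift_n:.3f}, {hits[0].shift_h:.3f}) lies "
            "within tolerance of both the apo and the bound reference position; "
            "states cannot be distinguished"
        )
    return hits[0] if hits else None


def pair_apo_bound(
    peaks_per_point: Sequence[Sequence[Peak]],
    reference_apo_list: Sequence[Peak],
    reference_bound_list: Sequence[Peak],
    *,
    tol_h: float = DEFAULT_TOL_H,
    tol_n: float = DEFAULT_TOL_N,
    residue_classes: Mapping[str, str] | None = None,
    observability: Mapping[str, float] | None = None,
) -> list[PeakPairSeries]:
    """Assign each titration point's peaks to apo or bound state per residue.

    For every residue in the apo reference list, the peak nearest the apo
    (resp. bound) reference position within tolerance supplies Ia (resp.
    Ii) at each point; a missing peak contributes intensity 0 with a
    ``*_not_detected`` flag, matching titration endpoints where only one
    state is visible.  Two peaks matching one reference, or one peak
    matching both references, raise :class:`AmbiguityError` — never a
    silent choice.

    ``observability`` maps residue → bound/apo per-molecule intensity
    ratio c (default 1.0): pi = c·Ii / (c·Ii + Ia).
    """
    bound_refs = {residue_of(p.assignment): p for p in reference_bound_list}
    classes = residue_classes or {}
    obs = observability or {}

    series: list[PeakPairSeries] = []
    for apo_ref in reference_apo_list:
        residue = residue_of(apo_ref.assignment)
        bound_ref = bound_refs.get(residue)
        n_points = len(peaks_per_point)
        ia = np.zeros(n_points)
        ii = np.zeros(n_points)
        pi = np.full(n_points, np.nan)
        flags: list[tuple[str, ...]] = []
        c = float(obs.get(residue, 1.0))
        for k, peaks in enumerate(peaks_per_point):
            point_flags: list[str] = []
            ctx = f"residue {residue}, point {k}"
            apo_peak = _pick_candidate(peaks, apo_ref, bound_ref, tol_h, tol_n, ctx)
            bound_peak = (
                _pick_candidate(peaks, bound_ref, apo_ref, tol_h, tol_n, ctx)
                if bound_ref is not None
                else None
            )
            if apo_peak is None:
                point_flags.append("apo_not_detected")
            elif apo_peak.artifact:
                point_flags.append("apo_artifact")
            else:
                ia[k] = apo_peak.height
            if bound_ref is None:
                point_flags.append("no_bound_reference")
            elif bound_peak is None:
                point_flags.append("bound_not_detected")
            elif bound_peak.artifact:
                point_flags.append("bound_artifact")
            else:
                ii[k] = bound_peak.height
            if ia[k] + ii[k] > 0.0:
                pi[k] = c * ii[k] / (c * ii[k] + ia[k])
            else:
                point_flags.append("undefined")
            flags.append(tuple(point_flags))
        series.append(
            PeakPairSeries(
                residue=residue,
                state_role=classes.get(residue, "unknown"),
                intensity_apo=ia,
                intensity_bound=ii,
                population_bound=pi,
                flags=flags,
            )
        )
    return series


def population_from_intensities(intensity_apo: float, intensity_bound: float) -> float:
    """Bound-state population pi = Ii/(Ii+Ia) from two slow-exchange peak heights."""
    ia, ii = float(intensity_apo), float(intensity_bound)
    if not (math.isfinite(ia) and math.isfinite(ii)) or ia < 0.0 or ii < 0.0:
        raise DomainError(f"intensities must be finite and non-negative, got {ia!r}, {ii!r}")
    if ia + ii == 0.0:
        raise UndefinedPopulationError("both intensities are zero; population undefined")
    return ii / (ii + ia)


# ---------------------------------------------------------------------------
# Exchange-regime arithmetic


def exchange_rate_bound(regime: ExchangeRegimeInput) -> float:
    """Angular-frequency separation 2π·Δδ·ν in s⁻¹.

    Two resonances separated by Δδ ppm at Larmor frequency ν MHz are
    resolved (slow exchange) only if the interconversion rate is well
    below this bound; e.g. Δδ = 0.6 ppm of ¹⁵N at 60 MHz gives ≈ 226 s⁻¹
    (≈ 200 s⁻¹ to one significant figure).
    """
    return 2.0 * math.pi * (regime.shift_separation * 1e-6) * (regime.nucleus_frequency * 1e6)


def classify_exchange_regime(k_ex: float, bound: float, *, margin: float = 5.0) -> str:
    """Label exchange as ``slow``, ``intermediate`` or ``fast`` vs. the shift separation.

    ``slow`` if k_ex < bound/margin, ``fast`` if k_ex > margin·bound,
    else ``intermediate`` (default factor-of-5 margins).
    """
    if not (math.isfinite(k_ex) and k_ex >= 0.0):
        raise DomainError(f"k_ex must be finite and non-negative, got {k_ex!r}")
    if not (math.isfinite(bound) and bound > 0.0):
        raise DomainError(f"bound must be finite and positive, got {bound!r}")
    if margin <= 1.0:
        raise DomainError("margin must exceed 1")
    if k_ex < bound / margin:
        return "slow"
    if k_ex > margin * bound:
        return "fast"
    return "intermediate"
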