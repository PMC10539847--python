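"""Synthetic slow-exchange titration data with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
7-point titration (molar ratios 0, 0.1, 0.3, 0.5, 0.7, 1.0, 3.0 by
default) of a ~79 µM two-site receptor, per-residue apo/bound resonance
pairs separated by up to ~0.6 ppm in ¹⁵N, peak heights proportional to
state populations with multiplicative lognormal noise, small Gaussian
shift jitter, and a detection floor that removes peaks of nearly
unpopulated states (emulating endpoint spectra where only one set of
resonances is visible).

A mechanism switch selects which occupancy the core-disassembly reporters
follow: ``orthosteric_opens_core`` ties them to the ATP-site occupancy,
``allosteric_opens_core`` to the myristoyl-site occupancy.  ATP-site and
allosteric-site reporters always follow their own site.  Residue labels
mirror commonly used reporters of the Abl regulatory core; their shifts
are synthetic placeholders, not real assignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .equilibria import (
    BindingConstants,
    CompetitionAssay,
    EquilibriumState,
    SITE_DISABLED_KD,
    TitrationPoint,
    occupancies,
    solve_two_site,
)
from .errors import GenerationError
from .peaks import DEFAULT_TOL_H, DEFAULT_TOL_N, Peak
from .pipeline import TitrationDataset

__all__ = [
    "ResidueSpec",
    "SyntheticSpec",
    "GroundTruth",
    "DEFAULT_RESIDUES",
    "REFERENCE_RATIOS",
    "generate_dataset",
    "generate_edge_cases",
    "make_reporter_panel",
    "write_bundle",
]

#: Default molar-ratio schedule of the reference titration.
REFERENCE_RATIOS: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 0.7, 1.0, 3.0)

MECHANISMS = ("orthosteric_opens_core", "allosteric_opens_core")


@dataclass(frozen=True)
class ResidueSpec:
    """One reporter residue: class, apo and bound peak positions, base intensity."""

    label: str
    reporter_class: str  # atp_site | sh3_sh2_core | allosteric_site
    apo_shift_n: float
    apo_shift_h: float
    bound_shift_n: float
    bound_shift_h: float
    base_intensity: float = 1.0e6


# Reporter labels follow residues commonly used to read out Abl core
# disassembly and ATP-site binding; shift values are synthetic placeholders
# laid out so apo/bound pairs are unambiguous at the default pairing
# tolerances (0.03 ppm 1H, 0.3 ppm 15N).
DEFAULT_RESIDUES: tuple[ResidueSpec, ...] = (
    ResidueSpec("V92", "sh3_sh2_core", 118.60, 8.92, 119.05, 8.94, 1.10e6),
    ResidueSpec("V130", "sh3_sh2_core", 121.40, 9.15, 120.88, 9.12, 0.95e6),
    ResidueSpec("G149", "sh3_sh2_core", 108.20, 8.05, 108.78, 8.06, 1.20e6),
    ResidueSpec("Y283", "sh3_sh2_core", 120.10, 7.64, 119.63, 7.68, 0.80e6),
    ResidueSpec("N316", "atp_site", 115.30, 8.47, 115.85, 8.45, 1.05e6),
    ResidueSpec("D382", "atp_site", 124.90, 8.83, 125.50, 8.86, 1.15e6),
    ResidueSpec("G340", "atp_site", 110.70, 7.92, 110.15, 7.88, 0.90e6),
    ResidueSpec("A384", "atp_site", 123.20, 8.30, 123.68, 8.32, 1.00e6),
    ResidueSpec("F444", "allosteric_site", 117.80, 9.40, 118.30, 9.37, 0.85e6),
    ResidueSpec("G455", "allosteric_site", 106.90, 8.66, 106.32, 8.68, 1.25e6),
    ResidueSpec("F505", "allosteric_site", 119.90, 7.35, 120.42, 7.40, 0.70e6),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic titration dataset.

    Defaults reproduce the reference study conditions: 79 µM receptor,
    the 7-ratio schedule, KDO = 10 nM, KDA = 10 µM, 2 % multiplicative
    intensity noise, 2 % detection floor.
    """

    total_enzyme: float = 79e-6
    molar_ratios: tuple[float, ...] = REFERENCE_RATIOS
    constants: BindingConstants = field(
        default_factory=lambda: BindingConstants(10e-9, 10e-6)
    )
    mechanism: str = "orthosteric_opens_core"
    residues: tuple[ResidueSpec, ...] = DEFAULT_RESIDUES
    noise_sigma: float = 0.02
    detection_floor: float = 0.02
    shift_jitter_h: float = 0.002
    shift_jitter_n: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        ratios = np.asarray(self.molar_ratios, dtype=float)
        if ratios.size == 0 or np.any(ratios < 0.0) or np.any(np.diff(ratios) <= 0.0):
            raise GenerationError("molar_ratios must be non-negative and strictly ascending")
        if self.noise_sigma < 0.0:
            raise GenerationError("noise_sigma must be >= 0")
        if self.mechanism not in MECHANISMS:
            raise GenerationError(f"mechanism must be one of {MECHANISMS}")
        if not self.residues:
            raise GenerationError("at least one residue is required")


@dataclass
class GroundTruth:
    """Everything the generator knows: states, occupancies, true populations."""

    constants: BindingConstants
    mechanism: str
    states: list[EquilibriumState]
    occ_orthosteric: np.ndarray
    occ_allosteric: np.ndarray
    populations: pd.DataFrame  # residue, reporter_class, point, lt_molar, population

    def to_dict(self) -> dict:
        return {
            "kd_orthosteric_molar": self.constants.kd_orthosteric,
            "kd_allosteric_molar": self.constants.kd_allosteric,
            "mechanism": self.mechanism,
            "occ_orthosteric": list(map(float, self.occ_orthosteric)),
            "occ_allosteric": list(map(float, self.occ_allosteric)),
            "states": [
                {"e0": s.e0, "e1": s.e1, "e2": s.e2, "e3": s.e3, "free_ligand": s.free_ligand}
                for s in self.states
            ],
            "populations": self.populations.to_dict(orient="records"),
        }


def _check_reference_collisions(
    residues: Sequence[ResidueSpec],
    tol_h: float,
    tol_n: float,
    jitter_h: float,
    jitter_n: float,
) -> None:
    """Reject panels whose reference peaks could be confused by the pairing step.

    Two reference positions collide when they fall inside one pairing
    tolerance box in both dimensions, widened by 5 sigma of the shift
    jitter.  This covers both apo-vs-bound separation within a residue and
    cross-residue overlap, so generated fixtures are always pairable.
    """
    margin_h = tol_h + 5.0 * jitter_h
    margin_n = tol_n + 5.0 * jitter_n
    refs = []
    for r in residues:
        refs.append((r.label, "apo", r.apo_shift_n, r.apo_shift_h))
        refs.append((r.label, "bound", r.bound_shift_n, r.bound_shift_h))
    for i in range(len(refs)):
        for j in range(i + 1, len(refs)):
            li, si, ni, hi = refs[i]
            lj, sj, nj, hj = refs[j]
            if abs(ni - nj) <= margin_n and abs(hi - hj) <= margin_h:
                raise GenerationError(
                    f"reference peaks collide within pairing tolerance: "
                    f"{li}/{si} ({ni:.3f}, {hi:.3f}) vs {lj}/{sj} ({nj:.3f}, {hj:.3f})"
                )


def _true_population(residue: ResidueSpec, occ_o: float, occ_a: float, mechanism: str) -> float:
    if residue.reporter_class == "atp_site":
        return occ_o
    if residue.reporter_class == "allosteric_site":
        return occ_a
    # core reporters follow whichever site the mechanism couples to opening
    return occ_o if mechanism == "orthosteric_opens_core" else occ_a


def generate_dataset(
    spec: SyntheticSpec,
    *,
    tol_h: float = DEFAULT_TOL_H,
    tol_n: float = DEFAULT_TOL_N,
    validate: bool = True,
) -> tuple[TitrationDataset, GroundTruth]:
    """Generate one titration dataset plus its ground truth.

    For each titration point the four-state equilibrium is solved; each
    residue then contributes an apo peak of height ``base·(1−p)·η`` and a
    bound peak of height ``base·p·η`` with p its class's true population
    and η lognormal multiplicative noise, ``exp(N(0, noise_sigma))``.
    Peaks whose state population falls below ``detection_floor`` are
    omitted.  Peak positions get Gaussian jitter (σ 0.002 ppm ¹H /
    0.02 ppm ¹⁵N by default).  ``validate=False`` skips the reference
    collision check (used to build deliberately ambiguous edge cases).
    """
    if validate:
        _check_reference_collisions(
            spec.residues, tol_h, tol_n, spec.shift_jitter_h, spec.shift_jitter_n
        )
    rng = np.random.default_rng(spec.seed)
    et = spec.total_enzyme
    ligand_totals = np.asarray(spec.molar_ratios, dtype=float) * et

    states, occ_o, occ_a = [], [], []
    for lt in ligand_totals:
        state = solve_two_site(spec.constants, TitrationPoint(et, lt))
        states.append(state)
        o, a = occupancies(state, et)
        occ_o.append(o)
        occ_a.append(a)
    occ_o = np.asarray(occ_o)
    occ_a = np.asarray(occ_a)

    truth_rows = []
    peak_lists: list[list[Peak]] = []
    for k, lt in enumerate(ligand_totals):
        peaks: list[Peak] = []
        for res in spec.residues:
            p = _true_population(res, occ_o[k], occ_a[k], spec.mechanism)
            truth_rows.append(
                {
                    "residue": res.label,
                    "reporter_class": res.reporter_class,
                    "point": k,
                    "lt_molar": lt,
                    "population": p,
                }
            )
            for role, pop, sn, sh in (
                ("apo", 1.0 - p, res.apo_shift_n, res.apo_shift_h),
                ("bound", p, res.bound_shift_n, res.bound_shift_h),
            ):
                if pop < spec.detection_floor:
                    continue  # broadened beyond detection / unpopulated
                noise = float(np.exp(rng.normal(0.0, spec.noise_sigma))) if spec.noise_sigma > 0 else 1.0
                height = res.base_intensity * pop * noise
                peaks.append(
                    Peak(
                        assignment=f"{res.label}N-H",
                        shift_n=sn + float(rng.normal(0.0, spec.shift_jitter_n)),
                        shift_h=sh + float(rng.normal(0.0, spec.shift_jitter_h)),
                        height=height,
                    )
                )
        peak_lists.append(peaks)

    reference_apo = [
        Peak(f"{r.label}N-H", r.apo_shift_n, r.apo_shift_h, r.base_intensity)
        for r in spec.residues
    ]
    reference_bound = [
        Peak(f"{r.label}N-H", r.bound_shift_n, r.bound_shift_h, r.base_intensity)
        for r in spec.residues
    ]
    dataset = TitrationDataset(
        total_enzyme=et,
        ligand_totals=ligand_totals,
        peak_lists=peak_lists,
        residue_classes={r.label: r.reporter_class for r in spec.residues},
        reference_apo=reference_apo,
        reference_bound=reference_bound,
        provenance={
            "generator": "slowex.synth",
            "seed": spec.seed,
            "mechanism": spec.mechanism,
            "noise_sigma": spec.noise_sigma,
            "kd_orthosteric_molar": spec.constants.kd_orthosteric,
            "kd_allosteric_molar": spec.constants.kd_allosteric,
        },
    )
    truth = GroundTruth(
        constants=spec.constants,
        mechanism=spec.mechanism,
        states=states,
        occ_orthosteric=occ_o,
        occ_allosteric=occ_a,
        populations=pd.DataFrame(truth_rows),
    )
    return dataset, truth


def write_bundle(dataset: TitrationDataset, truth: GroundTruth, out_dir: str | Path) -> Path:
    """Persist a dataset directory plus its ground_truth.json."""
    out = dataset.to_directory(out_dir)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def make_reporter_panel(
    n_per_class: int,
    *,
    base_intensity: float = 1.0e6,
    n_start: float = 104.0,
    n_step: float = 1.5,
    bound_offset_n: float = 0.55,
) -> tuple[ResidueSpec, ...]:
    """Regularly spaced synthetic panel with ``n_per_class`` residues per class.

    Used for power studies that need more reporters than the default
    panel; positions are laid on a ¹⁵N grid far coarser than the pairing
    tolerance, so the panel is always unambiguous.
    """
    classes = ("sh3_sh2_core", "atp_site", "allosteric_site")
    residues = []
    i = 0
    for cls in classes:
        for j in range(n_per_class):
            apo_n = n_start + i * n_step
            apo_h = 7.0 + 0.25 * (i % 12)
            residues.append(
                ResidueSpec(
                    label=f"X{100 + i}",
                    reporter_class=cls,
                    apo_shift_n=apo_n,
                    apo_shift_h=apo_h,
                    bound_shift_n=apo_n + bound_offset_n * (1 if i % 2 == 0 else -1),
                    bound_shift_h=apo_h + 0.02,
                    base_intensity=base_intensity * (0.8 + 0.05 * (i % 9)),
                )
            )
            i += 1
    return tuple(residues)


def generate_edge_cases(*, seed: int = 0) -> dict[str, object]:
    """Named fixtures exercising the pipeline's failure and boundary modes.

    Returns a mapping with at least six entries:

    - ``overlapping_peaks``: apo/bound separation below the pairing
      tolerance → pairing must raise an ambiguity error.
    - ``missing_point``: one titration point has an empty peak list.
    - ``all_saturated``: every point at ratio ≥ 3, all populations ≈ 1.
    - ``zero_intensity_residue``: a residue with zero base intensity →
      undefined populations, flagged.
    - ``stoichiometric``: Et ≫ KD single-site series → fits must flag
      upper-bound-only.
    - ``competition_reference``: one-site reporter-displacement scenario
      (4 µM enzyme, 25 µM reporter at KD 43 µM, 25 µM competitor).
    """
    cases: dict[str, object] = {}

    overlap_res = (
        ResidueSpec("G10", "atp_site", 110.00, 8.00, 110.10, 8.005, 1.0e6),
        ResidueSpec("V20", "sh3_sh2_core", 120.00, 9.00, 120.12, 9.004, 1.0e6),
    )
    cases["overlapping_peaks"] = generate_dataset(
        SyntheticSpec(residues=overlap_res, noise_sigma=0.0, seed=seed), validate=False
    )

    ds, truth = generate_dataset(SyntheticSpec(noise_sigma=0.0, seed=seed))
    ds.peak_lists[3] = []
    cases["missing_point"] = (ds, truth)

    cases["all_saturated"] = generate_dataset(
        SyntheticSpec(molar_ratios=(3.0, 4.0, 5.0), noise_sigma=0.0, seed=seed)
    )

    dead = tuple(
        replace(r, base_intensity=0.0) if r.label == "G149" else r for r in DEFAULT_RESIDUES
    )
    cases["zero_intensity_residue"] = generate_dataset(
        SyntheticSpec(residues=dead, noise_sigma=0.0, seed=seed)
    )

    cases["stoichiometric"] = generate_dataset(
        SyntheticSpec(
            constants=BindingConstants(10e-9, SITE_DISABLED_KD),
            mechanism="orthosteric_opens_core",
            noise_sigma=0.0,
            seed=seed,
        )
    )

    cases["competition_reference"] = CompetitionAssay(
        total_enzyme=4e-6,
        total_reporter=25e-6,
        total_competitor=25e-6,
        kd_reporter=43e-6,
        kd_competitor=10e-6,
    )
    return cases
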