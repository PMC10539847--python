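"""End-to-end titration analysis.

Consumes a :class:`TitrationDataset` (totals + per-point peak lists),
derives per-residue bound populations pi = Ii/(Ii+Ia), fits dissociation
constants under competing mechanism variants, and discriminates whether
the core-opening reporters follow the high-affinity orthosteric occupancy
curve or the low-affinity allosteric one.

Fits are least squares in log10(KD) (constants span decades and must stay
positive), pooled across all residues of one reporter class — the residue
curves are treated as reporting a single global binding equilibrium.
Identifiability is handled honestly: when the titration is stoichiometric
(Et >> KD) the RSS profile is flat below some KD, and the fit flags
"upper_bound_only" instead of reporting a spuriously precise constant.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import spearmanr

from . import __version__ as _pkg_version
from .equilibria import (
    BindingConstants,
    SITE_DISABLED_KD,
    _single_site_bound_fraction_vec,
    predict_titration_curve,
)
from .errors import DegenerateDataError, DomainError, FitError
from .peaks import (
    DEFAULT_TOL_H,
    DEFAULT_TOL_N,
    Peak,
    pair_apo_bound,
    read_peak_list,
    write_peak_list,
)
from .units import to_molar

__all__ = [
    "AbsorbanceSpec",
    "TitrationDataset",
    "FitResult",
    "MechanismReport",
    "EPSILON_IMATINIB_255",
    "EPSILON_ABL_CORE_280",
    "beer_lambert_concentration",
    "compute_populations",
    "fit_binding_model",
    "discriminate_mechanism",
    "assemble_report",
]

#: Molar extinction coefficient of imatinib at 255 nm (M^-1 cm^-1).
EPSILON_IMATINIB_255 = 3.3338e4
#: Molar extinction coefficient of the Abl 83-534 regulatory core at 280 nm.
EPSILON_ABL_CORE_280 = 9.5230e4

_REPORTER_CLASSES = ("atp_site", "sh3_sh2_core", "allosteric_site")

_VARIANT_DEFAULT_CLASSES = {
    "orthosteric_only": ("atp_site",),
    "allosteric_only": ("allosteric_site",),
    "two_site": ("atp_site", "allosteric_site"),
}

_DEFAULT_CLASS_OCCUPANCY = {
    "atp_site": "orthosteric",
    "allosteric_site": "allosteric",
}


@dataclass(frozen=True)
class AbsorbanceSpec:
    """One absorbance reading for Beer–Lambert concentration determination."""

    absorbance: float
    wavelength: float  # nm
    extinction_coefficient: float  # M^-1 cm^-1
    path_length: float = 1.0  # cm

    def __post_init__(self) -> None:
        if not (math.isfinite(self.absorbance) and self.absorbance >= 0.0):
            raise DomainError(f"absorbance must be finite and >= 0, got {self.absorbance!r}")
        for name in ("wavelength", "extinction_coefficient", "path_length"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0.0):
                raise DomainError(f"{name} must be finite and positive, got {v!r}")


def beer_lambert_concentration(spec: AbsorbanceSpec) -> float:
    """Concentration (molar) from absorbance: c = A / (ε · l)."""
    return spec.absorbance / (spec.extinction_coefficient * spec.path_length)


@dataclass
class TitrationDataset:
    """A complete titration: totals, per-point peak lists, residue classes.

    ``ligand_totals`` must be strictly increasing; when a zero point is
    present it is the apo reference.  ``reference_apo``/``reference_bound``
    optionally give per-residue reference peak positions; when absent the
    first (apo) and last (bound-dominated) point lists are used.
    """

    total_enzyme: float  # molar
    ligand_totals: np.ndarray  # molar, one per point
    peak_lists: list[list[Peak]]
    residue_classes: dict[str, str]
    reference_apo: list[Peak] | None = None
    reference_bound: list[Peak] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.total_enzyme) and self.total_enzyme > 0.0):
            raise DomainError(f"total_enzyme must be positive, got {self.total_enzyme!r}")
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        if np.any(np.diff(self.ligand_totals) <= 0.0):
            raise DomainError("ligand_totals must be strictly increasing")
        if np.any(self.ligand_totals < 0.0):
            raise DomainError("ligand_totals must be non-negative")
        if len(self.peak_lists) != len(self.ligand_totals):
            raise DomainError(
                f"{len(self.peak_lists)} peak lists for {len(self.ligand_totals)} points"
            )

    @property
    def n_points(self) -> int:
        return len(self.ligand_totals)

    @property
    def molar_ratios(self) -> np.ndarray:
        return self.ligand_totals / self.total_enzyme

    # -- persistence --------------------------------------------------------

    def to_directory(self, out_dir: str | Path) -> Path:
        """Write config.yaml plus one Sparky list per point (and references)."""
        import yaml

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = []
        for k, peaks in enumerate(self.peak_lists):
            name = f"point_{k:02d}.list"
            with open(out / name, "w") as fh:
                write_peak_list(peaks, fh)
            names.append(name)
        config: dict = {
            "enzyme_total": {"value": float(self.total_enzyme * 1e6), "unit": "uM"},
            "ligand_totals": {
                "values": [float(lt * 1e6) for lt in self.ligand_totals],
                "unit": "uM",
            },
            "peak_lists": names,
            "residue_classes": dict(sorted(self.residue_classes.items())),
            "provenance": self.provenance,
        }
        refs = {}
        for role, ref in (("apo", self.reference_apo), ("bound", self.reference_bound)):
            if ref is not None:
                name = f"reference_{role}.list"
                with open(out / name, "w") as fh:
                    write_peak_list(ref, fh)
                refs[role] = name
        if refs:
            config["references"] = refs
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        return out

    @classmethod
    def from_directory(cls, path: str | Path) -> "TitrationDataset":
        """Load a dataset from a directory holding config.yaml and peak lists."""
        import yaml

        root = Path(path)
        cfg_path = root / "config.yaml" if root.is_dir() else root
        root = cfg_path.parent
        with open(cfg_path) as fh:
            cfg = yaml.safe_load(fh)

        et = to_molar(cfg["enzyme_total"]["value"], cfg["enzyme_total"]["unit"])
        if "ligand_totals" in cfg:
            unit = cfg["ligand_totals"]["unit"]
            lts = [to_molar(v, unit) for v in cfg["ligand_totals"]["values"]]
        elif "ratios" in cfg:
            lts = [float(r) * et for r in cfg["ratios"]]
        else:
            raise DomainError("config must define ligand_totals or ratios")

        def load_list(name: str) -> list[Peak]:
            p = root / name
            if not p.exists():
                raise DomainError(f"peak list not found: {p}")
            with open(p) as fh, warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return read_peak_list(fh)

        peak_lists = [load_list(n) for n in cfg["peak_lists"]]
        refs = cfg.get("references") or {}
        return cls(
            total_enzyme=et,
            ligand_totals=np.asarray(lts),
            peak_lists=peak_lists,
            residue_classes=dict(cfg.get("residue_classes") or {}),
            reference_apo=load_list(refs["apo"]) if "apo" in refs else None,
            reference_bound=load_list(refs["bound"]) if "bound" in refs else None,
            provenance=dict(cfg.get("provenance") or {}),
        )

    def config_hash(self) -> str:
        """Stable hash of the scientific configuration (totals + classes)."""
        payload = json.dumps(
            {
                "total_enzyme": self.total_enzyme,
                "ligand_totals": list(map(float, self.ligand_totals)),
                "residue_classes": dict(sorted(self.residue_classes.items())),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def compute_populations(
    dataset: TitrationDataset,
    *,
    tol_h: float = DEFAULT_TOL_H,
    tol_n: float = DEFAULT_TOL_N,
    observability=None,
) -> pd.DataFrame:
    """Per-residue bound populations across the titration.

    Pairs each point's peaks against the apo/bound reference positions and
    returns a tidy table with one row per residue per titration point:
    columns ``residue, reporter_class, point, lt_molar, intensity_apo,
    intensity_bound, population, flags``.  Undefined populations (both
    peaks missing) are flagged and carried as NaN, never dropped silently.
    """
    ref_apo = dataset.reference_apo
    if ref_apo is None:
        if dataset.ligand_totals[0] != 0.0:
            raise DomainError(
                "no apo reference list and first titration point is not ligand-free"
            )
        ref_apo = dataset.peak_lists[0]
    ref_bound = dataset.reference_bound
    if ref_bound is None:
        ref_bound = dataset.peak_lists[-1]

    series = pair_apo_bound(
        dataset.peak_lists,
        ref_apo,
        ref_bound,
        tol_h=tol_h,
        tol_n=tol_n,
        residue_classes=dataset.residue_classes,
        observability=observability,
    )
    rows = []
    for s in series:
        for k in range(len(s)):
            rows.append(
                {
                    "residue": s.residue,
                    "reporter_class": s.state_role,
                    "point": k,
                    "lt_molar": dataset.ligand_totals[k],
                    "intensity_apo": s.intensity_apo[k],
                    "intensity_bound": s.intensity_bound[k],
                    "population": s.population_bound[k],
                    "flags": ";".join(s.flags[k]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# KD fitting


@dataclass
class FitResult:
    """Outcome of a pooled least-squares KD fit.

    ``fitted_kds`` maps parameter name (``kd_orthosteric`` and/or
    ``kd_allosteric``) to the fitted constant in molar.  ``flags`` may
    contain ``upper_bound_only`` (stoichiometric regime: the RSS profile
    is flat below ``kd_upper_bound[param]``, so only an upper bound on the
    KD is supported by the data) or ``lower_bound_only`` (binding too weak
    to saturate).  ``kd_ci`` holds seeded nonparametric-bootstrap 95 %
    intervals over residues; ``log10_kd_se`` the curvature-based standard
    error of log10 KD.  ``aic`` is auxiliary only.
    """

    model_variant: str
    fitted_kds: dict[str, float]
    rss: float
    n_obs: int
    per_residue_rss: dict[str, float]
    success: bool
    message: str
    nfev: int
    flags: list[str] = field(default_factory=list)
    kd_upper_bound: dict[str, float] = field(default_factory=dict)
    log10_kd_se: dict[str, float] = field(default_factory=dict)
    kd_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    aic: float = float("nan")
    profiles: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    @property
    def kd_orthosteric(self) -> float | None:
        return self.fitted_kds.get("kd_orthosteric")

    @property
    def kd_allosteric(self) -> float | None:
        return self.fitted_kds.get("kd_allosteric")

    def to_dict(self) -> dict:
        def clean(x):
            return None if (x is None or (isinstance(x, float) and not math.isfinite(x))) else x

        return {
            "model_variant": self.model_variant,
            "fitted_kds_molar": {k: clean(v) for k, v in self.fitted_kds.items()},
            "rss": clean(self.rss),
            "n_obs": self.n_obs,
            "per_residue_rss": {k: clean(v) for k, v in self.per_residue_rss.items()},
            "success": self.success,
            "message": self.message,
            "nfev": self.nfev,
            "flags": list(self.flags),
            "kd_upper_bound_molar": {k: clean(v) for k, v in self.kd_upper_bound.items()},
            "log10_kd_se": {k: clean(v) for k, v in self.log10_kd_se.items()},
            "kd_ci_molar": {k: [clean(v[0]), clean(v[1])] for k, v in self.kd_ci.items()},
            "aic": clean(self.aic),
        }


def _fit_frame(populations: pd.DataFrame, classes: tuple[str, ...]) -> pd.DataFrame:
    df = populations[populations["reporter_class"].isin(classes)]
    df = df[np.isfinite(df["population"])]
    return df.reset_index(drop=True)


def _predict_populations(
    params_log10: np.ndarray,
    variant: str,
    et: float,
    lt: np.ndarray,
    class_occ: np.ndarray,
) -> np.ndarray:
    """Model populations at each observation row.

    One-site variants use the closed-form quadratic isotherm; the two-site
    variant solves the full four-state model, assigning each row the
    occupancy of the site its reporter class senses (``class_occ`` is 0
    for orthosteric, 1 for allosteric).
    """
    if variant in ("orthosteric_only", "allosteric_only"):
        kd = 10.0 ** params_log10[0]
        return _single_site_bound_fraction_vec(kd, et, lt)
    constants = BindingConstants(10.0 ** params_log10[0], 10.0 ** params_log10[1])
    uniq, inv = np.unique(lt, return_inverse=True)
    curve = predict_titration_curve(constants, et, uniq)
    occ = np.stack([curve.occ_orthosteric, curve.occ_allosteric])
    return occ[class_occ, inv]


def fit_binding_model(
    populations: pd.DataFrame,
    total_enzyme: float,
    variant: str,
    *,
    classes: tuple[str, ...] | None = None,
    class_occupancy: dict[str, str] | None = None,
    log10_bounds: tuple[float, float] = (-12.0, -1.0),
    flat_tol: float = 1e-3,
    n_bootstrap: int = 200,
    seed: int = 0,
    _x0: np.ndarray | None = None,
    _diagnostics: bool = True,
) -> FitResult:
    """Fit dissociation constant(s) to pooled bound-population data.

    Minimizes Σ (pi_observed − occupancy_model(Lt))² over log10(KD),
    pooled across all residues of the relevant reporter class(es)
    (defaults: ``atp_site`` for ``orthosteric_only``, ``allosteric_site``
    for ``allosteric_only``, both for ``two_site``).  A coarse log-grid
    scan seeds a bounded trust-region refinement, and the full RSS profile
    over the grid supplies the identifiability diagnostics: KD values
    whose predicted populations differ from the optimum by less than
    ``flat_tol`` per point are considered indistinguishable, and a flat
    region touching a parameter bound raises the corresponding
    ``*_bound_only`` flag with the edge of the flat region reported as the
    supported bound.

    Raises ``DomainError`` for an unknown variant, ``DegenerateDataError``
    for all-zero populations, ``FitError`` for fewer than 3 informative
    points or optimizer failure.
    """
    if variant not in _VARIANT_DEFAULT_CLASSES:
        raise DomainError(
            f"unknown model variant {variant!r}; expected one of "
            + ", ".join(_VARIANT_DEFAULT_CLASSES)
        )
    classes = tuple(classes) if classes is not None else _VARIANT_DEFAULT_CLASSES[variant]
    class_occ_map = dict(_DEFAULT_CLASS_OCCUPANCY)
    if class_occupancy:
        class_occ_map.update(class_occupancy)

    df = _fit_frame(populations, classes)
    if df.empty:
        raise FitError(f"no populations with defined pi in classes {classes}")
    if df["lt_molar"].nunique() < 3:
        raise FitError(
            f"need >= 3 titration points with defined populations, got {df['lt_molar'].nunique()}"
        )
    if np.all(df["population"].to_numpy() == 0.0):
        raise DegenerateDataError("all observed populations are zero; KD not estimable")

    lt = df["lt_molar"].to_numpy()
    pi_obs = df["population"].to_numpy()
    if variant == "two_site":
        missing = set(df["reporter_class"]) - set(class_occ_map)
        if missing:
            raise DomainError(
                f"no site mapping for reporter class(es) {sorted(missing)}; "
                "pass class_occupancy"
            )
        class_occ = np.array(
            [0 if class_occ_map[c] == "orthosteric" else 1 for c in df["reporter_class"]]
        )
        n_params = 2
    else:
        class_occ = np.zeros(len(df), dtype=int)
        n_params = 1

    lo, hi = log10_bounds

    def residuals(params: np.ndarray) -> np.ndarray:
        return _predict_populations(params, variant, total_enzyme, lt, class_occ) - pi_obs

    def rss_of(params: np.ndarray) -> float:
        r = residuals(params)
        return float(r @ r)

    # coarse grid scan for a global starting point (skipped when a warm
    # start is supplied, e.g. during bootstrap refits)
    grid = np.linspace(lo, hi, int((hi - lo) * 15) + 1)
    if _x0 is not None:
        x0 = np.clip(np.asarray(_x0, dtype=float), lo, hi)
    elif n_params == 1:
        grid_rss = np.array([rss_of(np.array([g])) for g in grid])
        x0 = np.array([grid[int(np.argmin(grid_rss))]])
    else:
        coarse = np.linspace(lo, hi, 23)
        gg = [(rss_of(np.array([a, b])), a, b) for a in coarse for b in coarse]
        _, a0, b0 = min(gg)
        x0 = np.array([a0, b0])

    try:
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
    except Exception as exc:
        raise FitError(f"least-squares refinement failed: {exc}") from exc
    if not sol.success:
        raise FitError(f"fit did not converge: {sol.message}")

    rss = float(sol.fun @ sol.fun)
    param_names = (
        ["kd_orthosteric"]
        if variant == "orthosteric_only"
        else ["kd_allosteric"]
        if variant == "allosteric_only"
        else ["kd_orthosteric", "kd_allosteric"]
    )
    fitted = {name: 10.0 ** x for name, x in zip(param_names, sol.x)}

    # per-residue residuals
    resid = residuals(sol.x)
    per_res = {
        res: float(np.sum(resid[df["residue"].to_numpy() == res] ** 2))
        for res in sorted(df["residue"].unique())
    }

    # identifiability: profile over each parameter with the others held fixed
    n = len(df)
    threshold = rss + max(n * flat_tol**2, 0.05 * rss)
    flags: list[str] = []
    upper_bounds: dict[str, float] = {}
    profiles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, name in enumerate(param_names if _diagnostics else ()):
        prof = np.empty_like(grid)
        p = sol.x.copy()
        for i, g in enumerate(grid):
            p[j] = g
            prof[i] = rss_of(p)
        profiles[name] = (grid, prof)
        flat = prof <= threshold
        i_min = int(np.argmin(np.abs(grid - sol.x[j])))
        # contiguous flat region containing the optimum
        i_lo = i_min
        while i_lo > 0 and flat[i_lo - 1]:
            i_lo -= 1
        i_hi = i_min
        while i_hi < len(grid) - 1 and flat[i_hi + 1]:
            i_hi += 1
        if i_lo == 0:
            flags.append("upper_bound_only" if n_params == 1 else f"upper_bound_only:{name}")
            # interpolate the threshold crossing above the flat region
            if i_hi < len(grid) - 1:
                g0, g1 = grid[i_hi], grid[i_hi + 1]
                r0, r1 = prof[i_hi], prof[i_hi + 1]
                frac = (threshold - r0) / (r1 - r0) if r1 > r0 else 1.0
                upper_bounds[name] = 10.0 ** (g0 + frac * (g1 - g0))
            else:
                upper_bounds[name] = 10.0 ** grid[-1]
        elif i_hi == len(grid) - 1:
            flags.append("lower_bound_only" if n_params == 1 else f"lower_bound_only:{name}")

    # curvature-based SE of log10 KD
    log10_se: dict[str, float] = {}
    dof = max(n - n_params, 1)
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * (rss / dof)
        for name, var in zip(param_names, np.diag(cov)):
            log10_se[name] = float(np.sqrt(var)) if var > 0 else float("nan")
    except np.linalg.LinAlgError:
        log10_se = {name: float("nan") for name in param_names}

    # nonparametric bootstrap over residues
    kd_ci: dict[str, tuple[float, float]] = {}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        residues = sorted(df["residue"].unique())
        boot = {name: [] for name in param_names}
        groups = {res: df[df["residue"] == res] for res in residues}
        for _ in range(n_bootstrap):
            if len(residues) >= 2:
                chosen = rng.choice(residues, size=len(residues), replace=True)
                sample = pd.concat([groups[r] for r in chosen], ignore_index=True)
            else:
                sample = df.sample(n=len(df), replace=True, random_state=rng.integers(2**31))
            try:
                sub = fit_binding_model(
                    sample,
                    total_enzyme,
                    variant,
                    classes=classes,
                    class_occupancy=class_occupancy,
                    log10_bounds=log10_bounds,
                    flat_tol=flat_tol,
                    n_bootstrap=0,
                    _x0=sol.x,
                    _diagnostics=False,
                )
            except (FitError, DegenerateDataError):
                continue
            for name in param_names:
                boot[name].append(sub.fitted_kds[name])
        for name, values in boot.items():
            if len(values) >= 20:
                lo_ci, hi_ci = np.percentile(values, [2.5, 97.5])
                kd_ci[name] = (float(lo_ci), float(hi_ci))

    aic = n * math.log(max(rss, 1e-300) / n) + 2 * n_params
    return FitResult(
        model_variant=variant,
        fitted_kds=fitted,
        rss=rss,
        n_obs=n,
        per_residue_rss=per_res,
        success=bool(sol.success),
        message=str(sol.message),
        nfev=int(sol.nfev),
        flags=flags,
        kd_upper_bound=upper_bounds,
        log10_kd_se=log10_se,
        kd_ci=kd_ci,
        aic=float(aic),
        profiles=profiles,
    )


# ---------------------------------------------------------------------------
# Mechanism discrimination


@dataclass
class MechanismReport:
    """Which candidate occupancy curve the core-opening reporters follow.

    RSS of the pooled ``sh3_sh2_core`` populations against the orthosteric
    and allosteric occupancy curves of the full two-site model at the
    candidate constants, plus concordance statistics between the ATP-site
    and core reporter populations (the orthosteric mechanism predicts they
    change identically with ligand concentration).
    """

    candidate_constants: BindingConstants
    rss_orthosteric: float
    rss_allosteric: float
    preferred_mechanism: str
    rss_ratio: float
    concordance_max_abs_diff: float
    concordance_rank_corr: float
    n_core_obs: int
    n_atp_obs: int

    def to_dict(self) -> dict:
        def clean(x):
            return None if (isinstance(x, float) and not math.isfinite(x)) else x

        return {
            "candidate_kd_orthosteric_molar": self.candidate_constants.kd_orthosteric,
            "candidate_kd_allosteric_molar": self.candidate_constants.kd_allosteric,
            "rss_orthosteric": clean(self.rss_orthosteric),
            "rss_allosteric": clean(self.rss_allosteric),
            "preferred_mechanism": self.preferred_mechanism,
            "rss_ratio_orth_over_allo": clean(self.rss_ratio),
            "concordance_max_abs_diff": clean(self.concordance_max_abs_diff),
            "concordance_rank_corr": clean(self.concordance_rank_corr),
            "n_core_obs": self.n_core_obs,
            "n_atp_obs": self.n_atp_obs,
        }


def discriminate_mechanism(
    populations: pd.DataFrame,
    total_enzyme: float,
    candidate_constants: BindingConstants,
) -> MechanismReport:
    """Test whether core opening tracks orthosteric or allosteric occupancy.

    Compares the observed ``sh3_sh2_core`` populations with both occupancy
    curves of the two-site model at the candidate constants and reports
    the lower-RSS mechanism, the RSS ratio, and the concordance between
    the per-point class means of the core and ATP-site reporters (max
    absolute difference; Spearman rank correlation).
    """
    for cls in ("sh3_sh2_core", "atp_site"):
        if cls not in set(populations["reporter_class"]):
            raise DomainError(
                f"populations lack reporter class {cls!r}; mechanism discrimination "
                "needs both core and ATP-site reporters"
            )
    core = _fit_frame(populations, ("sh3_sh2_core",))
    atp = _fit_frame(populations, ("atp_site",))
    if core.empty or atp.empty:
        raise DegenerateDataError("no defined populations in core or ATP-site class")

    lt = core["lt_molar"].to_numpy()
    pi = core["population"].to_numpy()
    uniq, inv = np.unique(lt, return_inverse=True)
    curve = predict_titration_curve(candidate_constants, total_enzyme, uniq)
    rss_o = float(np.sum((pi - curve.occ_orthosteric[inv]) ** 2))
    rss_a = float(np.sum((pi - curve.occ_allosteric[inv]) ** 2))
    preferred = "orthosteric" if rss_o < rss_a else "allosteric"
    ratio = rss_o / rss_a if rss_a > 0 else float("inf")

    core_mean = core.groupby("lt_molar")["population"].mean()
    atp_mean = atp.groupby("lt_molar")["population"].mean()
    common = core_mean.index.intersection(atp_mean.index)
    diff = (core_mean.loc[common] - atp_mean.loc[common]).to_numpy()
    max_diff = float(np.max(np.abs(diff))) if len(diff) else float("nan")
    if len(common) >= 3:
        rho = spearmanr(core_mean.loc[common], atp_mean.loc[common]).statistic
        rho = float(rho) if rho is not None else float("nan")
    else:
        rho = float("nan")

    return MechanismReport(
        candidate_constants=candidate_constants,
        rss_orthosteric=rss_o,
        rss_allosteric=rss_a,
        preferred_mechanism=preferred,
        rss_ratio=ratio,
        concordance_max_abs_diff=max_diff,
        concordance_rank_corr=rho,
        n_core_obs=len(core),
        n_atp_obs=len(atp),
    )


# ---------------------------------------------------------------------------
# Report assembly


def _plot_report(
    populations: pd.DataFrame,
    total_enzyme: float,
    candidates: BindingConstants | None,
    path: Path,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6.0, 4.2))
    colors = {"sh3_sh2_core": "tab:green", "atp_site": "tab:red",
              "allosteric_site": "tab:blue", "unknown": "tab:gray"}
    for cls, sub in populations.groupby("reporter_class"):
        c = colors.get(cls, "tab:gray")
        ax.plot(sub["lt_molar"] * 1e6, sub["population"], "o", ms=4, alpha=0.45,
                color=c, label=f"{cls} (per residue)")
        mean = sub.groupby("lt_molar")["population"].mean()
        ax.plot(mean.index * 1e6, mean.to_numpy(), "-", lw=1.2, color=c,
                label=f"{cls} (mean)")
    if candidates is not None:
        lt_max = float(populations["lt_molar"].max())
        grid = np.linspace(0.0, max(lt_max, total_enzyme) * 1.05, 200)
        curve = predict_titration_curve(candidates, total_enzyme, grid)
        ax.plot(grid * 1e6, curve.occ_orthosteric, "r--", lw=1.5,
                label="orthosteric occupancy (model)")
        ax.plot(grid * 1e6, curve.occ_allosteric, "b--", lw=1.5,
                label="allosteric occupancy (model)")
    ax.set_xlabel("total ligand (µM)")
    ax.set_ylabel("bound population $p_i$")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def assemble_report(
    dataset: TitrationDataset,
    fits: list[FitResult],
    discrimination: MechanismReport | None,
    out_dir: str | Path,
    *,
    lt_sensitivity: float = 0.15,
    make_plot: bool = True,
    seed: int | None = None,
) -> dict:
    """Write the analysis bundle: populations.csv, summary.json, report plot.

    The JSON summary includes a provenance block (package version, config
    hash, seed) and — because nominal concentrations are only trusted to
    10–20 % — a sensitivity block refitting every model with all ligand
    totals scaled by ``1 ± lt_sensitivity``.  With no fits supplied, a
    populations-only report is written along with a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    populations = compute_populations(dataset)

    csv_path = out / "populations.csv"
    csv_df = populations.rename(columns={"lt_molar": "Lt_molar",
                                         "intensity_apo": "Ia",
                                         "intensity_bound": "Ii",
                                         "population": "pi"})
    csv_df[["residue", "reporter_class", "Lt_molar", "Ia", "Ii", "pi", "flags"]].to_csv(
        csv_path, index=False
    )

    warnings_list: list[str] = []
    if not fits:
        warnings_list.append("no fits supplied; report contains populations only")
        warnings.warn(warnings_list[-1], stacklevel=2)

    sensitivity: dict[str, dict] = {}
    if fits and lt_sensitivity > 0.0:
        for scale in (1.0 - lt_sensitivity, 1.0 + lt_sensitivity):
            scaled = populations.copy()
            scaled["lt_molar"] = scaled["lt_molar"] * scale
            entry: dict[str, dict] = {}
            for f in fits:
                try:
                    refit = fit_binding_model(
                        scaled, dataset.total_enzyme, f.model_variant, n_bootstrap=0
                    )
                    entry[f.model_variant] = {
                        "fitted_kds_molar": refit.fitted_kds,
                        "flags": refit.flags,
                    }
                except (FitError, DegenerateDataError, DomainError) as exc:
                    entry[f.model_variant] = {"error": str(exc)}
            sensitivity[f"lt_scale_{scale:.2f}"] = entry

    summary = {
        "provenance": {
            "package": "slowex",
            "version": _pkg_version,
            "config_hash": dataset.config_hash(),
            "seed": seed if seed is not None else dataset.provenance.get("seed"),
            "dataset": dataset.provenance,
        },
        "total_enzyme_molar": dataset.total_enzyme,
        "ligand_totals_molar": list(map(float, dataset.ligand_totals)),
        "fits": [f.to_dict() for f in fits],
        "discrimination": discrimination.to_dict() if discrimination else None,
        "lt_sensitivity": sensitivity,
        "warnings": warnings_list,
    }
    json_path = out / "summary.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    plot_path = None
    if make_plot:
        candidates = discrimination.candidate_constants if discrimination else None
        if candidates is None and fits:
            kdo = next((f.kd_orthosteric for f in fits if f.kd_orthosteric), None)
            kda = next((f.kd_allosteric for f in fits if f.kd_allosteric), None)
            if kdo or kda:
                candidates = BindingConstants(kdo or SITE_DISABLED_KD, kda or SITE_DISABLED_KD)
        plot_path = out / "report.png"
        _plot_report(populations, dataset.total_enzyme, candidates, plot_path)

    return {
        "populations_csv": str(csv_path),
        "summary_json": str(json_path),
        "plot": str(plot_path) if plot_path else None,
        "summary": summary,
    }
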