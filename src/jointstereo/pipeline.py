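"""Study orchestration: synthetic five-group studies, estimation from counts
tables, group summaries, group comparisons, and the section-reduction
efficiency report.

The default :class:`StudyConfig` encodes a five-group arthritis study
(Arthritis, LNC, Diclofenac, Diclofenac-LNC, No Arthritis; 4 specimens per
group) whose phantom calibration reproduces the published joint-volume
means and between-specimen SDs, sectioned at T = 50 µm with
a/p = 23,470 µm², Af = 2700.28 µm² and six frames per section.
"""
from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, SchemaError, StereologyError
from .estimators import (
    CEFormula,
    CEParameters,
    SpecimenCounts,
    cavalieri_volume,
    counts_to_frame,
    estimate_specimen,
    estimates_to_frame,
    frame_to_specimens,
    predicted_ce,
    subsample_sections,
)
from .phantom import (
    COMPARTMENTS,
    CellFieldParams,
    Villosity,
    group_phantom_params,
)
from .probes import ProbeSet
from .sectioning import SimulatedSpecimen, simulate_specimen

logger = logging.getLogger(__name__)

__all__ = [
    "GroupCalibration",
    "StudyConfig",
    "ComparisonResult",
    "simulate_study",
    "write_study_outputs",
    "run_estimation",
    "summarize_groups",
    "compare_groups",
    "ce_section_reduction_report",
    "DEFAULT_GROUPS",
]

DEFAULT_GROUPS = ("Arthritis", "LNC", "Diclofenac", "Diclofenac-LNC", "No Arthritis")

# Published group means: joint volume (mm³, mean/SD) and per-component
# volumes (mm³) in the order cartilage, bone, capsule, space, membrane.
_TABLE_VOLUMES = {
    "Arthritis": (3.02, 0.08, {"cartilage": 0.50, "bone": 1.20, "capsule": 0.97,
                               "synovial_space": 0.16, "synovial_membrane": 0.08}),
    "LNC": (2.80, 0.32, {"cartilage": 0.36, "bone": 1.08, "capsule": 0.89,
                         "synovial_space": 0.17, "synovial_membrane": 0.04}),
    "Diclofenac": (2.46, 0.12, {"cartilage": 0.34, "bone": 1.02, "capsule": 0.67,
                                "synovial_space": 0.19, "synovial_membrane": 0.03}),
    "Diclofenac-LNC": (2.10, 0.10, {"cartilage": 0.21, "bone": 0.75, "capsule": 0.58,
                                    "synovial_space": 0.26, "synovial_membrane": 0.02}),
    "No Arthritis": (1.95, 0.05, {"cartilage": 0.23, "bone": 0.61, "capsule": 0.52,
                                  "synovial_space": 0.41, "synovial_membrane": 0.01}),
}

# Published chondrocyte profile densities (profiles/mm²): isolated, groups.
_TABLE_CELLS = {
    "Arthritis": (1416.0, 80.55),
    "LNC": (1543.0, 111.5),
    "Diclofenac": (1627.0, 161.1),
    "Diclofenac-LNC": (1894.0, 226.8),
    "No Arthritis": (2208.0, 297.9),
}


@dataclass(frozen=True)
class GroupCalibration:
    """Phantom calibration for one study group.

    ``joint_mean_mm3``/``joint_sd_mm3`` give the between-specimen joint
    volume distribution; ``shares`` split the joint volume over the five
    compartments (normalized on construction).
    """

    joint_mean_mm3: float
    joint_sd_mm3: float
    shares: Mapping[str, float]
    axis_scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    villosity: Villosity | None = None

    def __post_init__(self) -> None:
        if self.joint_mean_mm3 <= 0 or self.joint_sd_mm3 < 0:
            raise InvalidParameterError("joint volume mean must be > 0 and SD >= 0")
        total = sum(self.shares.get(c, 0.0) for c in COMPARTMENTS)
        if total <= 0 or any(self.shares.get(c, 0.0) <= 0 for c in COMPARTMENTS):
            raise InvalidParameterError("every compartment share must be positive")
        object.__setattr__(
            self, "shares", {c: self.shares[c] / total for c in COMPARTMENTS}
        )

    @classmethod
    def from_component_volumes(
        cls,
        joint_mean_mm3: float,
        joint_sd_mm3: float,
        component_means_mm3: Mapping[str, float],
        **kw,
    ) -> "GroupCalibration":
        return cls(joint_mean_mm3, joint_sd_mm3, dict(component_means_mm3), **kw)


def _default_phantoms() -> dict[str, GroupCalibration]:
    return {
        g: GroupCalibration.from_component_volumes(mean, sd, comps)
        for g, (mean, sd, comps) in _TABLE_VOLUMES.items()
    }


def _default_cells() -> dict[str, CellFieldParams]:
    return {
        g: CellFieldParams(lambda_isolated=iso, lambda_parents=grp)
        for g, (iso, grp) in _TABLE_CELLS.items()
    }


@dataclass
class StudyConfig:
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = 4
    t_spacing_um: float = 50.0
    area_per_point_um2: float = 23_470.0
    length_per_point_um: float = 100.0
    frame_area_um2: float = 2700.28
    n_frames: int = 6
    polyline_tolerance_um: float = 0.25
    ce_variant: str = CEFormula.gundersen_noise.value
    shape_coefficient: float = 3.5449077018110318
    master_seed: int = 0
    out_dir: str = "."
    phantoms: dict[str, GroupCalibration] = field(default_factory=_default_phantoms)
    cells: dict[str, CellFieldParams] = field(default_factory=_default_cells)

    def __post_init__(self) -> None:
        if not self.groups or len(set(self.groups)) != len(self.groups):
            raise InvalidParameterError("groups must be non-empty and unique")
        if self.n_per_group < 1:
            raise InvalidParameterError("n_per_group must be >= 1")
        if min(self.t_spacing_um, self.area_per_point_um2, self.length_per_point_um,
               self.frame_area_um2) <= 0:
            raise InvalidParameterError("T and probe constants must be positive")
        self.groups = tuple(self.groups)

    @property
    def probes(self) -> ProbeSet:
        return ProbeSet(
            area_per_point=self.area_per_point_um2,
            length_per_point=self.length_per_point_um,
            frame_area=self.frame_area_um2,
            n_frames=self.n_frames,
            polyline_tolerance=self.polyline_tolerance_um,
        )

    @property
    def ce_params(self) -> CEParameters:
        return CEParameters(
            shape_coefficient=self.shape_coefficient,
            formula_variant=CEFormula(self.ce_variant),
        )

    @classmethod
    def from_dict(cls, raw: Mapping) -> "StudyConfig":
        raw = dict(raw)
        phantoms = raw.pop("phantoms", None)
        cells = raw.pop("cells", None)
        cfg = cls(**raw)
        if phantoms is not None:
            cfg.phantoms = {
                g: GroupCalibration(
                    joint_mean_mm3=p["joint_mean_mm3"],
                    joint_sd_mm3=p.get("joint_sd_mm3", 0.0),
                    shares=p["shares"],
                    axis_scales=tuple(p.get("axis_scales", (1.0, 1.0, 1.0))),
                    villosity=(
                        Villosity(**p["villosity"]) if p.get("villosity") else None
                    ),
                )
                for g, p in phantoms.items()
            }
        if cells is not None:
            cfg.cells = {g: CellFieldParams(**c) for g, c in cells.items()}
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj

        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        return enc(d)


def _specimen_seed(master_seed: int, group_index: int, index: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(group_index, index))
    return int(ss.generate_state(1)[0] % np.uint32(2**31))


def simulate_study(
    config: StudyConfig,
    seed: int | None = None,
    *,
    measure: Sequence[str] = ("points", "surfaces", "cells"),
) -> list[SimulatedSpecimen]:
    """Simulate every specimen of the configured study; fully reproducible
    from the master seed."""
    master = config.master_seed if seed is None else int(seed)
    out = []
    for gi, group in enumerate(config.groups):
        for i in range(config.n_per_group):
            sp_seed = _specimen_seed(master, gi, i)
            phantom = group_phantom_params(group, config, np.random.default_rng(sp_seed))
            out.append(
                simulate_specimen(
                    phantom,
                    config.probes,
                    config.cells.get(group) if "cells" in measure else None,
                    config.t_spacing_um,
                    sp_seed,
                    specimen_id=f"{group.replace(' ', '_')}_{i + 1:02d}",
                    group=group,
                    measure=measure,
                )
            )
    return out


def write_study_outputs(
    specimens: Sequence[SimulatedSpecimen], config: StudyConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write counts.csv, the truth sidecar, estimates.csv, group_summary.csv
    and run_log.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_df = counts_to_frame([s.counts for s in specimens])
    counts_path = out / "counts.csv"
    counts_df.to_csv(counts_path, index=False)
    truth = {
        s.counts.specimen_id: {
            "volumes_mm3": dict(s.truth.volumes),
            "surfaces_mm2": dict(s.truth.surfaces),
            "provenance": s.truth.provenance.value,
            "seed": s.seed,
        }
        for s in specimens
    }
    truth_path = out / "counts_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    est_df = run_estimation(counts_df, config)
    est_path = out / "estimates.csv"
    est_df.to_csv(est_path, index=False)
    summary_path = out / "group_summary.csv"
    summarize_groups(est_df).to_csv(summary_path, index=False)
    comparisons_path = out / "comparisons.csv"
    comparison_rows = []
    if len(config.groups) >= 2 and config.n_per_group >= 2:
        for q in SUMMARY_QUANTITIES:
            if q not in est_df.columns:
                continue
            res = compare_groups(est_df, q, method="auto")
            for (a, b), p in res.pairwise_p.items():
                comparison_rows.append(
                    {
                        "quantity": q,
                        "method": res.method,
                        "group_a": a,
                        "group_b": b,
                        "p_value": p,
                        "statistic": res.pairwise_statistic[(a, b)],
                        "omnibus_p": res.omnibus_p,
                        "levene_p": res.levene_p,
                    }
                )
    else:
        logger.warning("comparisons skipped: need >= 2 groups with >= 2 specimens")
    pd.DataFrame(comparison_rows).to_csv(comparisons_path, index=False)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    log = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "master_seed": config.master_seed,
        "ce_variant": config.ce_variant,
        "n_specimens": len(specimens),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    return {
        "counts": counts_path,
        "truth": truth_path,
        "estimates": est_path,
        "summary": summary_path,
        "comparisons": comparisons_path,
        "run_log": log_path,
    }


def run_estimation(counts: pd.DataFrame | str | Path, config: StudyConfig) -> pd.DataFrame:
    """Estimate every specimen in a counts table (path or DataFrame).

    An empty table yields an empty estimates table with a warning rather
    than an error.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.read_csv(counts)
    if counts.empty:
        logger.warning("empty counts table: no specimens to estimate")
        return pd.DataFrame()
    specimens = frame_to_specimens(
        counts,
        t_spacing=config.t_spacing_um,
        area_per_point=config.area_per_point_um2,
        length_per_point=config.length_per_point_um,
        frame_area=config.frame_area_um2,
    )
    estimates = [estimate_specimen(sp, config.ce_params) for sp in specimens]
    return estimates_to_frame(
        estimates,
        t_spacing=config.t_spacing_um,
        area_per_point=config.area_per_point_um2,
        frame_area=config.frame_area_um2,
    )


#: estimate columns summarized per group, in published-table order
SUMMARY_QUANTITIES = (
    "volume_mm3",
    "volume_cartilage_mm3",
    "volume_bone_mm3",
    "volume_capsule_mm3",
    "volume_synovial_space_mm3",
    "volume_synovial_membrane_mm3",
    "surface_cartilage_mm2",
    "surface_synovial_membrane_mm2",
    "density_isolated_per_mm2",
    "density_isogenous_groups_per_mm2",
    "density_total_per_mm2",
)


def summarize_groups(estimates: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD (n-1 denominator) and n per group and quantity.

    A single-specimen group reports SD as missing (NaN), not zero.
    """
    if estimates.empty:
        return pd.DataFrame()
    rows = []
    for group, sub in estimates.groupby("group", sort=False):
        row: dict = {"group": group, "n": len(sub)}
        for q in SUMMARY_QUANTITIES:
            if q not in sub.columns:
                continue
            row[f"{q}_mean"] = sub[q].mean()
            if len(sub) < 2:
                logger.warning("group %s has one specimen: SD reported missing", group)
                row[f"{q}_sd"] = float("nan")
            else:
                row[f"{q}_sd"] = sub[q].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    quantity: str
    method: str  # test actually used
    omnibus_statistic: float
    omnibus_p: float
    pairwise_p: Mapping[tuple[str, str], float]
    pairwise_statistic: Mapping[tuple[str, str], float]
    levene_p: float  # variance-homogeneity diagnostic (Brown-Forsythe form)

    def __post_init__(self) -> None:
        for p in self.pairwise_p.values():
            if not (math.isnan(p) or 0.0 <= p <= 1.0):
                raise StereologyError(f"p-value {p} outside [0, 1]")


def _sidak(p: float, m: int) -> float:
    return float(1.0 - (1.0 - p) ** m) if not math.isnan(p) else p


def _pairwise_t(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, float]:
    dx = float(np.mean(x) - np.mean(y))
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # degenerate: no within-group variability
        return (0.0, 1.0) if dx == 0 else (math.inf, 0.0)
    with warnings.catch_warnings():
        # nearly identical samples are legitimate (tightly calibrated groups)
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def compare_groups(
    estimates: pd.DataFrame, quantity: str, method: str = "auto"
) -> ComparisonResult:
    """Compare a quantity across all groups.

    ``anova_sidak``: one-way ANOVA omnibus plus pairwise pooled t tests with
    Sidak adjustment.  ``brown_forsythe_dunnett_t3``: Brown-Forsythe
    unequal-variance ANOVA omnibus with pairwise Welch t tests, Sidak
    adjusted (the classical T3 studentized-maximum-modulus reference is
    approximated by the Sidak bound).  ``mann_whitney``: pairwise
    Mann-Whitney U, Sidak adjusted.  ``auto`` picks brown_forsythe_dunnett_t3
    when the Brown-Forsythe (median-centred Levene) homogeneity test rejects
    at alpha = 0.05, else anova_sidak.
    """
    if quantity not in estimates.columns:
        raise KeyError(f"unknown quantity {quantity!r}")
    groups = list(dict.fromkeys(estimates["group"]))
    samples = {g: estimates.loc[estimates["group"] == g, quantity].to_numpy(float) for g in groups}
    small = [g for g, x in samples.items() if x.size < 2]
    if len(groups) < 2 or small:
        raise InvalidParameterError(
            f"insufficient data for comparison: groups {small or groups} need >= 2 specimens"
        )
    xs = list(samples.values())
    degenerate = all(np.ptp(x) == 0 for x in xs)
    if degenerate:
        levene_p = 1.0
    else:
        with warnings.catch_warnings():
            # near-constant groups are legitimate inputs (cloned specimens)
            warnings.simplefilter("ignore", RuntimeWarning)
            levene_p = float(stats.levene(*xs, center="median").pvalue)
    if method == "auto":
        method = "brown_forsythe_dunnett_t3" if levene_p < 0.05 else "anova_sidak"
    m = len(groups) * (len(groups) - 1) // 2
    pairs = list(itertools.combinations(groups, 2))
    pairwise_p: dict[tuple[str, str], float] = {}
    pairwise_t: dict[tuple[str, str], float] = {}
    if method == "anova_sidak":
        if degenerate:
            stat, omnibus_p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                stat, omnibus_p = stats.f_oneway(*xs)
        for a, b in pairs:
            t, p = _pairwise_t(samples[a], samples[b], equal_var=True)
            pairwise_t[(a, b)] = t
            pairwise_p[(a, b)] = _sidak(p, m)
    elif method == "brown_forsythe_dunnett_t3":
        from statsmodels.stats.oneway import anova_oneway

        if degenerate:
            stat, omnibus_p = 0.0, 1.0
        else:
            res = anova_oneway(xs, use_var="bf")
            stat, omnibus_p = float(res.statistic), float(res.pvalue)
        for a, b in pairs:
            t, p = _pairwise_t(samples[a], samples[b], equal_var=False)
            pairwise_t[(a, b)] = t
            pairwise_p[(a, b)] = _sidak(p, m)
    elif method == "mann_whitney":
        stat, omnibus_p = stats.kruskal(*xs)
        for a, b in pairs:
            if np.ptp(samples[a]) == 0 and np.ptp(samples[b]) == 0 and (
                np.mean(samples[a]) == np.mean(samples[b])
            ):
                u, p = float("nan"), 1.0
            else:
                u, p = stats.mannwhitneyu(samples[a], samples[b], alternative="two-sided")
            pairwise_t[(a, b)] = float(u)
            pairwise_p[(a, b)] = _sidak(float(p), m)
    else:
        raise InvalidParameterError(f"unknown comparison method {method!r}")
    if math.isnan(float(omnibus_p)):
        omnibus_p = 1.0  # zero between- and within-group variance
    return ComparisonResult(
        quantity=quantity,
        method=method,
        omnibus_statistic=float(stat) if not math.isnan(float(stat)) else 0.0,
        omnibus_p=float(omnibus_p),
        pairwise_p=pairwise_p,
        pairwise_statistic=pairwise_t,
        levene_p=levene_p,
    )


def ce_section_reduction_report(
    counts: SpecimenCounts,
    steps: Sequence[int],
    ce_params: CEParameters | None = None,
) -> pd.DataFrame:
    """Section-reduction efficiency table for one densely sectioned specimen.

    For each reduction step k the specimen is subsampled at every possible
    start; the table reports the across-start mean of the subsampled
    Cavalieri volume (which equals the full-specimen volume exactly), the
    mean predicted CE, and the empirical CE (across-start SD / mean of the
    subsample volumes).  Steps exceeding the section count are skipped with
    a warning.
    """
    ce_params = ce_params or CEParameters()
    rows = []
    for k in steps:
        if k < 1 or k > counts.n_sections:
            logger.warning("step %d skipped: specimen has %d sections", k, counts.n_sections)
            continue
        vols, ces, n_secs = [], [], []
        for start in range(k):
            sub = subsample_sections(counts, k, start)
            vols.append(cavalieri_volume(sub))
            n_secs.append(sub.n_sections)
            try:
                ces.append(predicted_ce(sub, ce_params))
            except StereologyError:
                ces.append(float("nan"))
        vols_arr = np.asarray(vols)
        mean_v = float(vols_arr.mean())
        emp = float(vols_arr.std(ddof=1) / mean_v) if k > 1 and mean_v > 0 else float("nan")
        rows.append(
            {
                "step": k,
                "n_sections_mean": float(np.mean(n_secs)),
                "volume_mm3": mean_v,
                "predicted_ce": float(np.nanmean(ces)),
                "empirical_ce": emp,
            }
        )
    return pd.DataFrame(rows)
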