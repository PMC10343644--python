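"""Design-based stereological estimators mapping raw section counts to
volumes, volume fractions, surface areas, profile densities, and predicted
coefficients of error (CE).

Formulas (all counts summed over the sections of one specimen):

* Cavalieri volume            V = ΣP · T · (a/p)
* Delesse volume fraction     Vv(comp) = ΣP_comp / ΣP_ref
* absolute component volume   V(comp) = Vv(comp) · V
* surface density             Sv = 2·ΣI / (ΣP · l/p)
* absolute surface            S = Sv · V
* profile density             Nv = ΣQ / (ΣN_frames · Af)
* predicted CE (default)      CE = sqrt(0.0724 · (B/√A) · √n / (ΣP)^{3/2})

Internally everything is computed in µm and converted on output
(volumes mm³, surfaces mm², surface density mm⁻¹, profile density mm⁻²).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SchemaError, UndefinedEstimateError

logger = logging.getLogger(__name__)

__all__ = [
    "COMPONENTS",
    "SURFACES",
    "SectionCounts",
    "SpecimenCounts",
    "CEFormula",
    "CEParameters",
    "SpecimenEstimates",
    "cavalieri_volume",
    "predicted_ce",
    "shape_coefficient_from_profiles",
    "volume_fraction",
    "absolute_volume",
    "surface_density",
    "absolute_surface",
    "profile_density",
    "estimate_specimen",
    "subsample_sections",
    "counts_to_frame",
    "frame_to_specimens",
    "estimates_to_frame",
    "COUNTS_COLUMNS",
]

COMPONENTS = ("cartilage", "bone", "capsule", "synovial_space", "synovial_membrane")
SURFACES = ("cartilage", "synovial_membrane")

UM3_PER_MM3 = 1e9
UM2_PER_MM2 = 1e6
MM_PER_UM_INV = 1e3  # 1 µm⁻¹ = 10³ mm⁻¹


def _check_count(name: str, value: int) -> int:
    v = int(value)
    if v != value or v < 0:
        raise InvalidParameterError(f"{name} must be a non-negative integer, got {value!r}")
    return v


@dataclass(frozen=True)
class SectionCounts:
    """Raw probe counts on one section.

    ``p_ref`` is the number of test points hitting the reference space (the
    whole joint); it serves both the Cavalieri sum ΣPi and the Delesse
    denominator ΣPref.  ``i_component`` are cycloid–interface intersection
    counts; ``q_*`` are counting-frame chondrocyte-profile counts.
    """

    section_index: int
    p_ref: int
    p_component: Mapping[str, int] = field(default_factory=dict)
    i_component: Mapping[str, int] = field(default_factory=dict)
    q_isolated: int = 0
    q_group_cells: int = 0
    q_groups: int = 0
    frames_used: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "section_index", _check_count("section_index", self.section_index))
        object.__setattr__(self, "p_ref", _check_count("p_ref", self.p_ref))
        pc = {}
        for name in COMPONENTS:
            v = _check_count(f"p_{name}", self.p_component.get(name, 0))
            if v > self.p_ref:
                raise InvalidParameterError(
                    f"p_{name} = {v} exceeds p_ref = {self.p_ref} on section {self.section_index}"
                )
            pc[name] = v
        object.__setattr__(self, "p_component", pc)
        ic = {name: _check_count(f"i_{name}", self.i_component.get(name, 0)) for name in SURFACES}
        object.__setattr__(self, "i_component", ic)
        for name in ("q_isolated", "q_group_cells", "q_groups", "frames_used"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        # each counted isogenous group contributes at least one counted cell
        if self.q_group_cells < self.q_groups:
            raise InvalidParameterError(
                f"q_group_cells = {self.q_group_cells} < q_groups = {self.q_groups}"
            )


@dataclass(frozen=True)
class SpecimenCounts:
    """Ordered per-section counts plus probe constants for one specimen."""

    specimen_id: str
    group: str
    sections: tuple[SectionCounts, ...]
    t_spacing: float  # T, µm
    area_per_point: float  # a/p, µm²
    length_per_point: float  # l/p, µm
    frame_area: float  # Af, µm²

    def __post_init__(self) -> None:
        sections = tuple(self.sections)
        if not sections:
            raise InvalidParameterError(f"specimen {self.specimen_id}: no sections")
        idx = [s.section_index for s in sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InvalidParameterError(
                f"specimen {self.specimen_id}: section indices must be strictly increasing"
            )
        if min(self.t_spacing, self.area_per_point, self.length_per_point, self.frame_area) <= 0:
            raise InvalidParameterError(
                f"specimen {self.specimen_id}: T and probe constants must be > 0"
            )
        object.__setattr__(self, "sections", sections)

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def sum_p_ref(self) -> int:
        return sum(s.p_ref for s in self.sections)

    def sum_p_component(self, component: str) -> int:
        if component not in COMPONENTS:
            raise KeyError(f"unknown component {component!r}")
        return sum(s.p_component[component] for s in self.sections)

    def sum_i(self, surface: str) -> int:
        if surface not in SURFACES:
            raise KeyError(f"unknown surface {surface!r}")
        return sum(s.i_component[surface] for s in self.sections)


class CEFormula(str, Enum):
    gundersen_noise = "gundersen_noise"
    sqrt_ratio = "sqrt_ratio"


_MIN_SHAPE = 2.0 * math.sqrt(math.pi)  # the circle minimizes B/√A


@dataclass(frozen=True)
class CEParameters:
    """Shape coefficient B/√A and the CE formula variant.

    B/√A ≥ 2√π (the circle is the minimizer); smaller values indicate an
    input error.  The default is the circle value 2√π, exact for spherical
    phantoms; estimate it from profiles when geometry is available.
    """

    shape_coefficient: float = _MIN_SHAPE
    formula_variant: CEFormula = CEFormula.gundersen_noise

    def __post_init__(self) -> None:
        if self.shape_coefficient < _MIN_SHAPE - 1e-9:
            raise InvalidParameterError(
                f"shape coefficient {self.shape_coefficient} < 2*sqrt(pi); "
                "no planar profile has a smaller boundary/sqrt(area) ratio"
            )


@dataclass(frozen=True)
class SpecimenEstimates:
    """All derived quantities for one specimen."""

    specimen_id: str
    group: str
    n_sections: int
    volume: float  # V, mm³
    ce: float  # predicted CE (NaN when undefined)
    vv: Mapping[str, float]
    absolute_volume: Mapping[str, float]  # mm³
    sv: Mapping[str, float]  # mm⁻¹
    surface_area: Mapping[str, float]  # mm²
    density_isolated: float  # profiles/mm²
    density_group_cells: float
    density_total: float
    density_isogenous_groups: float  # groups/mm²
    ce_variant: str = CEFormula.gundersen_noise.value
    shape_coefficient: float = _MIN_SHAPE
    length_per_point: float = float("nan")  # l/p echoed in outputs


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def cavalieri_volume(counts: SpecimenCounts) -> float:
    """Cavalieri volume V = ΣP · T · (a/p), in mm³."""
    return counts.sum_p_ref * counts.t_spacing * counts.area_per_point / UM3_PER_MM3


def predicted_ce(counts: SpecimenCounts, params: CEParameters | None = None) -> float:
    """Predicted coefficient of error of the Cavalieri estimate.

    ``gundersen_noise`` (default) is the point-counting noise prediction
    CE = sqrt(0.0724 · (B/√A) · √n / (ΣP)^{3/2}), i.e. sqrt(var)/ΣP with
    var = 0.0724 · (B/√A) · sqrt(n · ΣP).  ``sqrt_ratio`` is the alternative
    reading 0.0724 · (B/√A) · sqrt(n / ΣP).
    """
    params = params or CEParameters()
    n = counts.n_sections
    p = counts.sum_p_ref
    if p == 0:
        raise UndefinedEstimateError(f"specimen {counts.specimen_id}: CE undefined for ΣP = 0")
    if n < 2:
        raise UndefinedEstimateError(f"specimen {counts.specimen_id}: CE requires n >= 2 sections")
    b_sqrt_a = params.shape_coefficient
    if params.formula_variant is CEFormula.gundersen_noise:
        return math.sqrt(0.0724 * b_sqrt_a * math.sqrt(n) / p**1.5)
    return 0.0724 * b_sqrt_a * math.sqrt(n / p)


def shape_coefficient_from_profiles(
    boundary_length: Sequence[float], profile_area: Sequence[float]
) -> float:
    """Mean over sections of B_i / sqrt(A_i) from measured profile boundary
    lengths (µm) and areas (µm²); scale invariant."""
    b = np.asarray(boundary_length, dtype=float)
    a = np.asarray(profile_area, dtype=float)
    if b.shape != a.shape or b.size == 0:
        raise InvalidParameterError("boundary_length and profile_area must be equal-length, non-empty")
    if np.any(a <= 0) or np.any(b <= 0):
        raise InvalidParameterError("profile areas and boundary lengths must be > 0")
    return float(np.mean(b / np.sqrt(a)))


def volume_fraction(counts: SpecimenCounts, component: str) -> float:
    """Delesse volume fraction Vv = ΣP_comp / ΣP_ref."""
    p_ref = counts.sum_p_ref
    if p_ref == 0:
        raise UndefinedEstimateError(
            f"specimen {counts.specimen_id}: volume fraction undefined for ΣPref = 0"
        )
    return counts.sum_p_component(component) / p_ref


def absolute_volume(vv: float, cavalieri_volume_mm3: float) -> float:
    """Absolute component volume Vv · V (mm³)."""
    if not 0.0 <= vv <= 1.0:
        raise InvalidParameterError(f"vv must be in [0, 1], got {vv}")
    if cavalieri_volume_mm3 < 0:
        raise InvalidParameterError("volume must be >= 0")
    return vv * cavalieri_volume_mm3


def surface_density(counts: SpecimenCounts, surface: str) -> float:
    """Surface density Sv = 2·ΣI / (ΣP · l/p), in mm⁻¹."""
    p = counts.sum_p_ref
    if p == 0:
        raise UndefinedEstimateError(
            f"specimen {counts.specimen_id}: surface density undefined for ΣP = 0"
        )
    sv_per_um = 2.0 * counts.sum_i(surface) / (p * counts.length_per_point)
    return sv_per_um * MM_PER_UM_INV


def absolute_surface(sv_per_mm: float, cavalieri_volume_mm3: float) -> float:
    """Absolute surface area Sv · V; mm⁻¹ × mm³ = mm²."""
    if sv_per_mm < 0 or cavalieri_volume_mm3 < 0:
        raise InvalidParameterError("sv and volume must be >= 0")
    return sv_per_mm * cavalieri_volume_mm3


def profile_density(counts: SpecimenCounts, which: str) -> float:
    """2-D numerical density ΣQ / (ΣN_frames · Af), in profiles (or groups) per mm²."""
    n_frames = sum(s.frames_used for s in counts.sections)
    if n_frames == 0:
        raise UndefinedEstimateError(
            f"specimen {counts.specimen_id}: profile density undefined without frames"
        )
    sums = {
        "isolated": sum(s.q_isolated for s in counts.sections),
        "group_cells": sum(s.q_group_cells for s in counts.sections),
        "isogenous_groups": sum(s.q_groups for s in counts.sections),
    }
    sums["total"] = sums["isolated"] + sums["group_cells"]
    try:
        q = sums[which]
    except KeyError:
        raise KeyError(f"unknown profile class {which!r}") from None
    return q / (n_frames * counts.frame_area) * UM2_PER_MM2


def estimate_specimen(
    counts: SpecimenCounts, ce_params: CEParameters | None = None
) -> SpecimenEstimates:
    """All estimates for one specimen; deterministic.

    A zero-count specimen yields all-zero estimates with CE reported as
    missing (NaN) rather than an error; CE is likewise NaN when n < 2.
    """
    ce_params = ce_params or CEParameters()
    v = cavalieri_volume(counts)
    p_ref = counts.sum_p_ref
    if p_ref == 0:
        logger.warning("specimen %s: zero reference points; all estimates zero", counts.specimen_id)
        vv = {c: 0.0 for c in COMPONENTS}
        sv = {s: 0.0 for s in SURFACES}
        ce = float("nan")
    else:
        vv = {c: volume_fraction(counts, c) for c in COMPONENTS}
        sv = {s: surface_density(counts, s) for s in SURFACES}
        try:
            ce = predicted_ce(counts, ce_params)
        except UndefinedEstimateError:
            ce = float("nan")
    n_frames = sum(s.frames_used for s in counts.sections)
    if n_frames == 0:
        d_iso = d_grp = d_tot = d_groups = 0.0
    else:
        d_iso = profile_density(counts, "isolated")
        d_grp = profile_density(counts, "group_cells")
        d_tot = d_iso + d_grp
        d_groups = profile_density(counts, "isogenous_groups")
    return SpecimenEstimates(
        specimen_id=counts.specimen_id,
        group=counts.group,
        n_sections=counts.n_sections,
        volume=v,
        ce=ce,
        vv=vv,
        absolute_volume={c: absolute_volume(vv[c], v) for c in COMPONENTS},
        sv=sv,
        surface_area={s: absolute_surface(sv[s], v) for s in SURFACES},
        density_isolated=d_iso,
        density_group_cells=d_grp,
        density_total=d_tot,
        density_isogenous_groups=d_groups,
        ce_variant=ce_params.formula_variant.value,
        shape_coefficient=ce_params.shape_coefficient,
        length_per_point=counts.length_per_point,
    )


def subsample_sections(counts: SpecimenCounts, step: int, start: int = 0) -> SpecimenCounts:
    """Every ``step``-th section beginning at ``start`` with T scaled by
    ``step``; probe constants unchanged.  Averaging the Cavalieri volume of
    the k subsamples over all starts recovers the full-section volume
    exactly."""
    if step < 1:
        raise InvalidParameterError(f"step must be >= 1, got {step}")
    if not 0 <= start < step:
        raise InvalidParameterError(f"start must be in [0, {step}), got {start}")
    if step == 1:
        return counts
    sections = counts.sections[start::step]
    if not sections:
        raise InvalidParameterError(
            f"specimen {counts.specimen_id}: empty subsample (step={step}, start={start})"
        )
    return replace(
        counts,
        specimen_id=f"{counts.specimen_id}:k{step}s{start}",
        sections=sections,
        t_spacing=counts.t_spacing * step,
    )


# ---------------------------------------------------------------------------
# Tabular I/O (counts CSV, estimates CSV)
# ---------------------------------------------------------------------------

COUNTS_COLUMNS = (
    "specimen_id",
    "group",
    "section_index",
    "p_ref",
    *(f"p_{c}" for c in COMPONENTS),
    *(f"i_{s}" for s in SURFACES),
    "q_isolated",
    "q_group_cells",
    "q_groups",
    "frames_used",
)


def counts_to_frame(specimens: Iterable[SpecimenCounts]) -> pd.DataFrame:
    """One row per section; section indices are written 1-based."""
    rows = []
    for sp in specimens:
        for sec in sp.sections:
            row = {
                "specimen_id": sp.specimen_id,
                "group": sp.group,
                "section_index": sec.section_index + 1,
                "p_ref": sec.p_ref,
            }
            row.update({f"p_{c}": sec.p_component[c] for c in COMPONENTS})
            row.update({f"i_{s}": sec.i_component[s] for s in SURFACES})
            row.update(
                q_isolated=sec.q_isolated,
                q_group_cells=sec.q_group_cells,
                q_groups=sec.q_groups,
                frames_used=sec.frames_used,
            )
            rows.append(row)
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def frame_to_specimens(
    df: pd.DataFrame,
    *,
    t_spacing: float,
    area_per_point: float,
    length_per_point: float,
    frame_area: float,
) -> list[SpecimenCounts]:
    """Parse a counts table (schema :data:`COUNTS_COLUMNS`) into specimens.

    Missing count columns are treated as zero with a warning; malformed rows
    and duplicate (specimen, section) pairs raise :class:`SchemaError` with
    row numbers.
    """
    required = {"specimen_id", "group", "section_index", "p_ref"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"counts table missing required columns: {sorted(missing)}")
    for col in COUNTS_COLUMNS:
        if col not in df.columns:
            logger.warning("counts table: column %s absent, treated as 0", col)
    dup = df.duplicated(subset=["specimen_id", "section_index"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based incl. header
        raise SchemaError(f"duplicate (specimen_id, section_index) at file rows {rows}")
    specimens = []
    for sid, sub in df.groupby("specimen_id", sort=True):
        sub = sub.sort_values("section_index")
        sections = []
        for idx, row in sub.iterrows():
            try:
                sections.append(
                    SectionCounts(
                        section_index=int(row["section_index"]) - 1,
                        p_ref=int(row["p_ref"]),
                        p_component={c: int(row.get(f"p_{c}", 0) or 0) for c in COMPONENTS},
                        i_component={s: int(row.get(f"i_{s}", 0) or 0) for s in SURFACES},
                        q_isolated=int(row.get("q_isolated", 0) or 0),
                        q_group_cells=int(row.get("q_group_cells", 0) or 0),
                        q_groups=int(row.get("q_groups", 0) or 0),
                        frames_used=int(row.get("frames_used", 0) or 0),
                    )
                )
            except (ValueError, TypeError, InvalidParameterError) as exc:
                raise SchemaError(f"malformed counts at file row {idx + 2}: {exc}") from exc
        specimens.append(
            SpecimenCounts(
                specimen_id=str(sid),
                group=str(sub["group"].iloc[0]),
                sections=tuple(sections),
                t_spacing=t_spacing,
                area_per_point=area_per_point,
                length_per_point=length_per_point,
                frame_area=frame_area,
            )
        )
    return specimens


def estimates_to_frame(
    estimates: Iterable[SpecimenEstimates],
    *,
    t_spacing: float | None = None,
    area_per_point: float | None = None,
    frame_area: float | None = None,
) -> pd.DataFrame:
    """One row per specimen, probe constants and CE variant echoed."""
    rows = []
    for e in estimates:
        row = {
            "specimen_id": e.specimen_id,
            "group": e.group,
            "n_sections": e.n_sections,
            "volume_mm3": e.volume,
            "ce": e.ce,
        }
        for c in COMPONENTS:
            row[f"vv_{c}"] = e.vv[c]
            row[f"volume_{c}_mm3"] = e.absolute_volume[c]
        for s in SURFACES:
            row[f"sv_{s}_per_mm"] = e.sv[s]
            row[f"surface_{s}_mm2"] = e.surface_area[s]
        row.update(
            density_isolated_per_mm2=e.density_isolated,
            density_group_cells_per_mm2=e.density_group_cells,
            density_total_per_mm2=e.density_total,
            density_isogenous_groups_per_mm2=e.density_isogenous_groups,
            ce_variant=e.ce_variant,
            shape_coefficient=e.shape_coefficient,
            length_per_point_um=e.length_per_point,
        )
        if t_spacing is not None:
            row["t_spacing_um"] = t_spacing
        if area_per_point is not None:
            row["area_per_point_um2"] = area_per_point
        if frame_area is not None:
            row["frame_area_um2"] = frame_area
        rows.append(row)
    return pd.DataFrame(rows)
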