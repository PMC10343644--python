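"""Monte-Carlo validation experiments for every estimator.

Each experiment rebuilds its inputs from the study conditions (phantom
calibrated to the published joint scale, T = 50 µm, a/p = 23,470 µm²,
Af = 2700.28 µm², six frames per section), runs the full virtual workflow
across seeds, and reports recovery of the known ground truth.  The same
functions back the test suite and the acceptance script.
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .estimators import (
    COMPONENTS,
    CEParameters,
    cavalieri_volume,
    counts_to_frame,
    estimate_specimen,
    profile_density,
    subsample_sections,
)
from .phantom import (
    COMPARTMENTS,
    CellFieldParams,
    make_phantom,
    phantom_truth,
    radii_from_volumes,
)
from .pipeline import StudyConfig, compare_groups, run_estimation, simulate_study
from .probes import ProbeSet
from .sectioning import simulate_specimen

__all__ = [
    "study_phantom_radii",
    "cavalieri_unbiasedness",
    "vv_recovery",
    "surface_recovery_anisotropic",
    "profile_density_recovery",
    "section_reduction",
    "ce_adequacy",
    "effect_recovery",
]

#: default probe constants of the study
_PROBES = ProbeSet(
    area_per_point=23_470.0, length_per_point=100.0, frame_area=2700.28, n_frames=6
)
_T = 50.0


def _rep_seed(seed: int, experiment: int, rep: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(experiment, rep))
    return int(ss.generate_state(1)[0] % np.uint32(2**31))


def study_phantom_radii(joint_volume_mm3: float = 3.02) -> tuple[float, ...]:
    """Radii of the study-scale phantom: joint volume at the published
    arthritic-joint mean, compartments split by the published shares."""
    comps = {"cartilage": 0.50, "bone": 1.20, "capsule": 0.97,
             "synovial_space": 0.16, "synovial_membrane": 0.08}
    total = sum(comps.values())
    vols = {c: joint_volume_mm3 * v / total for c, v in comps.items()}
    return radii_from_volumes(vols)


def cavalieri_unbiasedness(n_reps: int = 2000, seed: int = 0) -> dict:
    """Relative bias of the Cavalieri volume over VUR sectioning replicates
    of the study-scale sphere phantom (T = 50 µm, a/p = 23,470 µm²)."""
    phantom = make_phantom(study_phantom_radii())
    truth = phantom_truth(phantom).volumes["joint"]
    vols = np.empty(n_reps)
    for i in range(n_reps):
        sim = simulate_specimen(
            phantom, _PROBES, None, _T, _rep_seed(seed, 1, i), measure=("points",)
        )
        vols[i] = cavalieri_volume(sim.counts)
    mean = float(vols.mean())
    return {
        "truth_mm3": truth,
        "mean_mm3": mean,
        "rel_bias_pct": 100.0 * (mean - truth) / truth,
        "empirical_cv": float(vols.std(ddof=1) / mean),
        "n": n_reps,
    }


def vv_recovery(n_reps: int = 500, seed: int = 0) -> dict:
    """Absolute error of mean estimated volume fractions per compartment on
    the nested-shell study phantom."""
    phantom = make_phantom(study_phantom_radii())
    tr = phantom_truth(phantom)
    frac = {c: tr.volumes[c] / tr.volumes["joint"] for c in COMPARTMENTS}
    vv = np.empty((n_reps, len(COMPONENTS)))
    for i in range(n_reps):
        sim = simulate_specimen(
            phantom, _PROBES, None, _T, _rep_seed(seed, 2, i), measure=("points",)
        )
        est = estimate_specimen(sim.counts)
        vv[i] = [est.vv[c] for c in COMPONENTS]
    errors = {
        c: float(vv[:, j].mean() - frac[c]) for j, c in enumerate(COMPONENTS)
    }
    return {
        "abs_error": errors,
        "max_abs_error": max(abs(e) for e in errors.values()),
        "n": n_reps,
    }


def surface_recovery_anisotropic(n_reps: int = 2000, seed: int = 0) -> dict:
    """Relative error of the mean cartilage surface area on a prolate
    (axis ratio 2) phantom — the decisive check that the cycloid system's
    sine-weighted orientations compensate the vertical design's anisotropy."""
    phantom = make_phantom(study_phantom_radii(), axis_scales=(1.0, 1.0, 2.0))
    truth = phantom_truth(phantom).surfaces["cartilage"]
    surf = np.empty(n_reps)
    for i in range(n_reps):
        sim = simulate_specimen(
            phantom,
            _PROBES,
            None,
            _T,
            _rep_seed(seed, 3, i),
            measure=("points", "surfaces"),
        )
        est = estimate_specimen(sim.counts)
        surf[i] = est.surface_area["cartilage"]
    mean = float(surf.mean())
    return {
        "truth_mm2": truth,
        "mean_mm2": mean,
        "rel_error_pct": 100.0 * (mean - truth) / truth,
        "n": n_reps,
    }


def profile_density_recovery(
    n_reps: int = 1000, seed: int = 0, intensity: float = 1500.0
) -> dict:
    """Relative error of the mean isolated-chondrocyte profile density
    against the generating Poisson intensity (profiles/mm²)."""
    phantom = make_phantom(study_phantom_radii())
    cells = CellFieldParams(lambda_isolated=intensity, lambda_parents=0.0)
    dens = np.empty(n_reps)
    for i in range(n_reps):
        sim = simulate_specimen(
            phantom, _PROBES, cells, _T, _rep_seed(seed, 4, i), measure=("cells",)
        )
        dens[i] = profile_density(sim.counts, "isolated")
    mean = float(dens.mean())
    return {
        "intensity_per_mm2": intensity,
        "mean_per_mm2": mean,
        "rel_error_pct": 100.0 * (mean - intensity) / intensity,
        "n": n_reps,
    }


def section_reduction(n_reps: int = 1000, seed: int = 0) -> dict:
    """Section-reduction efficiency on a ~28-section sphere phantom.

    Reports the across-seed empirical CE of the Cavalieri volume at the
    full sectioning and at reductions to ~14 and ~10 sections (steps 2 and
    3), plus the worst relative error of the exact mean-over-starts
    identity (subsampled volumes averaged over starts equal the full
    volume)."""
    phantom = make_phantom(study_phantom_radii())
    t28 = 2.0 * phantom.horizontal_radius / 28.0
    steps = (1, 2, 3)
    vols = {k: np.empty(n_reps) for k in steps}
    identity_err = 0.0
    for i in range(n_reps):
        rep_seed = _rep_seed(seed, 5, i)
        sim = simulate_specimen(
            phantom, _PROBES, None, t28, rep_seed, measure=("points",)
        )
        full = cavalieri_volume(sim.counts)
        # the retained phase is drawn uniformly so the reduced design has a
        # uniform random start over its full period k*T
        rng = np.random.default_rng(np.random.SeedSequence(rep_seed, spawn_key=(99,)))
        for k in steps:
            start = int(rng.integers(k))
            vols[k][i] = cavalieri_volume(subsample_sections(sim.counts, k, start))
        if i < 50:  # exact identity, checked on a subset (it is deterministic)
            for k in (2, 3):
                mean_over_starts = np.mean(
                    [cavalieri_volume(subsample_sections(sim.counts, k, s)) for s in range(k)]
                )
                identity_err = max(identity_err, abs(mean_over_starts - full) / full)
    ce = {k: float(vols[k].std(ddof=1) / vols[k].mean()) for k in steps}
    return {
        "empirical_ce_28": ce[1],
        "empirical_ce_14": ce[2],
        "empirical_ce_10": ce[3],
        "ce10_over_ce28": ce[3] / ce[1],
        "identity_max_rel_err": identity_err,
        "n": n_reps,
    }


#: (T µm, a/p µm²) regimes spanning the study's sectioning designs:
#: n ≈ 36/18/10 sections at the study grid, and coarser/finer grids at T=50.
CE_REGIMES: tuple[tuple[float, float], ...] = (
    (50.0, 23_470.0),
    (100.0, 23_470.0),
    (180.0, 23_470.0),
    (50.0, 5_867.5),
    (50.0, 93_880.0),
)


def ce_adequacy(
    n_reps: int = 400, seed: int = 0, regimes: Sequence[tuple[float, float]] = CE_REGIMES
) -> dict:
    """Ratio of the predicted CE (point-counting noise formula) to the
    empirical across-seed CV of the volume, per (n, ΣP) regime."""
    phantom = make_phantom(study_phantom_radii())
    ratios = {}
    for j, (t, ap) in enumerate(regimes):
        probes = ProbeSet(ap, 100.0, 2700.28, 6)
        vols = np.empty(n_reps)
        preds = np.empty(n_reps)
        for i in range(n_reps):
            sim = simulate_specimen(
                phantom, probes, None, t, _rep_seed(seed, 6 + j, i), measure=("points",)
            )
            est = estimate_specimen(sim.counts)
            vols[i] = est.volume
            preds[i] = est.ce
        cv = float(vols.std(ddof=1) / vols.mean())
        ratios[f"T{t:g}_ap{ap:g}"] = float(np.nanmean(preds) / cv)
    vals = list(ratios.values())
    return {"ratios": ratios, "min_ratio": min(vals), "max_ratio": max(vals), "n": n_reps}


def effect_recovery(n_studies: int = 500, seed: int = 0) -> dict:
    """End-to-end five-group study replication.

    For each simulated study (published joint-volume means/SDs, 4 specimens
    per group): is the Arthritis vs Diclofenac-LNC joint-volume comparison
    significant at alpha = 0.05 (Sidak-adjusted), and is the group-mean
    ordering Arthritis > Diclofenac > Diclofenac-LNC > No Arthritis
    reproduced?"""
    cfg = StudyConfig()
    significant = 0
    ordered = 0
    pair = ("Arthritis", "Diclofenac-LNC")
    chain = ("Arthritis", "Diclofenac", "Diclofenac-LNC", "No Arthritis")
    for i in range(n_studies):
        sims = simulate_study(cfg, _rep_seed(seed, 20, i), measure=("points",))
        est = run_estimation(counts_to_frame([s.counts for s in sims]), cfg)
        cmp = compare_groups(est, "volume_mm3", method="anova_sidak")
        p = cmp.pairwise_p.get(pair, cmp.pairwise_p.get((pair[1], pair[0])))
        if p < 0.05:
            significant += 1
        means = est.groupby("group")["volume_mm3"].mean()
        if all(means[a] > means[b] for a, b in zip(chain, chain[1:])):
            ordered += 1
    return {
        "significant_fraction": significant / n_studies,
        "ordering_fraction": ordered / n_studies,
        "n": n_studies,
    }
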