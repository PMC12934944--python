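"""End-to-end analyses: ROI RSA, searchlight maps, time-resolved profiles.

Each function consumes a :class:`~socialrsa.geometry.PatternDataset` plus
model RDM sources and returns tidy tables / per-voxel maps, with group
inference by sign-flip permutation tests and Benjamini-Hochberg FDR.
FDR families are explicit: across voxels for searchlight maps, across
(model x ROI x statistic) cells for ROI analyses, and across
(model x window) cells per ROI for time-resolved analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .features import RepresentationSet
from .geometry import PatternDataset, VoxelMask
from .inference import (
    fdr_bh,
    p_to_z,
    rm_anova_2way,
    signed_permutation_test,
    signed_permutation_test_matrix,
)
from .rdm import (
    RDM,
    DegenerateRepresentationError,
    rdm_vector,
    representation_rdm,
    spearman_rsa,
    semipartial_spearman,
)

__all__ = [
    "model_rdm_vectors",
    "subject_roi_statistics",
    "run_roi_analysis",
    "run_searchlight_analysis",
    "run_time_resolved",
    "SearchlightResult",
]

logger = logging.getLogger(__name__)

Z_THRESHOLD = 1.96  # group-map display threshold


def model_rdm_vectors(models: dict) -> dict[str, np.ndarray]:
    """Canonical RDM vectors from RDMs or representation sets."""
    out = {}
    for name, src in models.items():
        if isinstance(src, RDM):
            out[name] = rdm_vector(src)
        elif isinstance(src, RepresentationSet):
            out[name] = rdm_vector(representation_rdm(src))
        else:
            out[name] = src  # already an RDMVector
    return out


def _child_seed(seed: int | None, *tokens: int) -> int | None:
    if seed is None:
        return None
    mix = seed
    for t in tokens:
        mix = (mix * 1000003 + t + 1) % (2**31)
    return mix


def subject_roi_statistics(repeats: list[np.ndarray], voxel_cols: np.ndarray,
                           model_vecs: dict, semipartial: bool,
                           fisher_z: bool = False) -> dict | None:
    """Full (and optionally semi-partial) RSA statistics for one subject/ROI.

    Applies the subject's split-half reliability mask within the ROI,
    normalizes and averages repeats, builds the neural RDM, and correlates
    it with every model.  Returns None when too few voxels survive.
    """
    roi_repeats = [np.asarray(r)[:, voxel_cols] for r in repeats]
    if len(roi_repeats) >= 2:
        _, keep = geometry.split_half_voxel_reliability(roi_repeats)
    else:
        keep = np.ones(len(voxel_cols), dtype=bool)
    if keep.sum() < 2:
        return None
    avg = geometry.normalize_and_average(roi_repeats)[:, keep]
    try:
        neural = rdm_vector(geometry.neural_rdm(avg))
    except (ValueError, DegenerateRepresentationError):
        return None
    stats: dict[str, float] = {}
    names = list(model_vecs)
    for name in names:
        rho = spearman_rsa(neural, model_vecs[name]).rho
        stats[("full", name)] = np.arctanh(rho) if fisher_z else rho
    if semipartial and len(names) >= 2:
        for name in names:
            others = [model_vecs[n] for n in names if n != name]
            rho = semipartial_spearman(neural, model_vecs[name], others).rho
            stats[("semipartial", name)] = np.arctanh(rho) if fisher_z else rho
    if len(roi_repeats) >= 2:
        ceiling = geometry.split_half_rsa_reliability(roi_repeats)
    else:
        ceiling = np.nan
    return {"stats": stats, "ceiling": ceiling, "n_voxels": int(keep.sum())}


def run_roi_analysis(dataset: PatternDataset, rois: dict[str, VoxelMask],
                     models: dict, *, semipartial: bool = True,
                     n_perm: int = 5000, alpha: float = 0.05,
                     tail: str = "one", seed: int | None = 0,
                     fisher_z: bool = False,
                     ceiling_alpha: float = 0.05) -> pd.DataFrame:
    """Group ROI RSA with reliability ceilings and FDR across cells.

    Per subject and ROI the analysis restricts to reliability-passing
    voxels, builds the neural RDM, and computes full plus (optionally)
    semi-partial Spearman statistics against every model.  Group
    significance uses one-tailed sign-flip permutation tests; FDR is
    applied across all (ROI x model x kind) cells of reliable ROIs.  ROIs
    whose Spearman-Brown split-half RSA ceiling is not significantly above
    zero are flagged ``roi_reliable=False`` and excluded from the FDR
    family.
    """
    model_vecs = model_rdm_vectors(models)
    rows = []
    roi_reliable: dict[str, bool] = {}
    roi_ceiling: dict[str, float] = {}
    for r_i, (roi_name, roi_mask) in enumerate(rois.items()):
        inmask = roi_mask.intersect(
            VoxelMask(dataset.grid, dataset.mask.data)
        )
        if inmask.size < 2:
            logger.warning("ROI %s has <2 voxels inside the analysis mask",
                           roi_name)
            roi_reliable[roi_name] = False
            roi_ceiling[roi_name] = np.nan
            continue
        cols = dataset.mask.column_indices(inmask.members)
        per_subject: dict[str, dict] = {}
        for subj in dataset.subject_ids:
            res = subject_roi_statistics(
                dataset.subjects[subj], cols, model_vecs, semipartial,
                fisher_z=fisher_z,
            )
            if res is None:
                logger.warning("subject %s: ROI %s emptied by reliability mask",
                               subj, roi_name)
                continue
            per_subject[subj] = res
        if len(per_subject) < 2:
            roi_reliable[roi_name] = False
            roi_ceiling[roi_name] = np.nan
            continue
        ceilings = np.array([per_subject[s]["ceiling"] for s in per_subject])
        ceilings = ceilings[np.isfinite(ceilings)]
        if len(ceilings) >= 2:
            ceil_test = signed_permutation_test(
                ceilings, tail="one", n_perm=n_perm,
                seed=_child_seed(seed, r_i, 9999),
            )
            reliable = ceil_test.p <= ceiling_alpha
        else:
            reliable = False
        roi_reliable[roi_name] = bool(reliable)
        roi_ceiling[roi_name] = float(np.mean(ceilings)) if len(ceilings) else np.nan
        keys = next(iter(per_subject.values()))["stats"].keys()
        for k_i, (kind, model) in enumerate(keys):
            values = np.array(
                [per_subject[s]["stats"][(kind, model)] for s in per_subject]
            )
            test = signed_permutation_test(
                values, tail=tail, n_perm=n_perm,
                seed=_child_seed(seed, r_i, k_i),
            )
            rows.append(
                {"roi": roi_name, "model": model, "kind": kind,
                 "mean_rho": test.mean, "p": test.p, "z": test.z,
                 "n_subjects": len(values),
                 "ceiling": roi_ceiling[roi_name],
                 "roi_reliable": roi_reliable[roi_name]}
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adj"] = np.nan
    table["significant"] = False
    family = table["roi_reliable"].to_numpy()
    if family.any():
        reject, p_adj = fdr_bh(table.loc[family, "p"].to_numpy(), alpha=alpha)
        table.loc[family, "p_adj"] = p_adj
        table.loc[family, "significant"] = reject
    return table


@dataclass(frozen=True)
class SearchlightResult:
    """Group searchlight maps over the reliability-masked analysis grid."""

    mask: VoxelMask  # group reliability mask; one searchlight per member
    centers: np.ndarray  # (n_centers, 3)
    mean_rho: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    p_adj: dict[str, np.ndarray]
    z: dict[str, np.ndarray]  # signed z from FDR-adjusted p
    z_thresholded: dict[str, np.ndarray]  # zeroed below |z| >= 1.96
    kind: str

    def save_maps(self, outdir, prefix: str = "searchlight") -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for model in self.mean_rho:
            for stem, values in [
                ("rho", self.mean_rho[model]),
                ("z", self.z[model]),
                ("z_thresh", self.z_thresholded[model]),
            ]:
                geometry.save_map_nifti(
                    values, self.mask,
                    outdir / f"{prefix}_{model}_{self.kind}_{stem}.nii.gz",
                )


def run_searchlight_analysis(dataset: PatternDataset, models: dict, *,
                             radius: float = 3.0, semipartial: bool = False,
                             n_perm: int = 5000, alpha: float = 0.05,
                             tail: str = "two", seed: int | None = 0,
                             min_voxels: int = 2) -> SearchlightResult:
    """Whole-volume searchlight RSA with group sign-flip inference.

    The analysis mask is restricted to voxels whose split-half reliability,
    averaged across subjects, is positive.  Per subject and searchlight a
    neural RDM is correlated with every model RDM (semi-partial variant
    controls each model for all others); the group test sign-flips subject
    statistics per voxel with a shared sign schedule, FDR-corrects across
    voxels, and converts adjusted p-values to signed z-maps thresholded at
    |z| >= 1.96.
    """
    rel_maps = []
    for subj in dataset.subject_ids:
        if len(dataset.subjects[subj]) >= 2:
            r, _ = geometry.split_half_voxel_reliability(dataset.subjects[subj])
            rel_maps.append(r)
    if rel_maps:
        group_rel = np.nanmean(np.stack(rel_maps), axis=0)
        keep = np.nan_to_num(group_rel, nan=-1.0) > 0
    else:
        keep = np.ones(dataset.mask.size, dtype=bool)
    rel_mask = VoxelMask.from_indices(
        dataset.grid, dataset.mask.members[keep]
    )
    lights = [
        sl for sl in geometry.define_searchlights(rel_mask, radius)
        if sl.n_voxels >= min_voxels
    ]
    if not lights:
        raise ValueError("no searchlights survive the reliability mask")
    centers = np.array([sl.center for sl in lights])
    model_vecs = model_rdm_vectors(models)
    names = list(model_vecs)
    kind = "semipartial" if semipartial and len(names) >= 2 else "full"

    # per-subject averaged patterns restricted to the reliability mask
    keep_cols = dataset.mask.column_indices(rel_mask.members)
    subj_stats = {name: [] for name in names}
    for subj in dataset.subject_ids:
        avg = geometry.normalize_and_average(dataset.subjects[subj])[:, keep_cols]
        per_model = {name: np.full(len(lights), np.nan) for name in names}
        for i, sl in enumerate(lights):
            try:
                neural = rdm_vector(geometry.neural_rdm(avg[:, sl.member_cols]))
            except (ValueError, DegenerateRepresentationError):
                continue
            for name in names:
                if kind == "semipartial":
                    others = [model_vecs[n] for n in names if n != name]
                    per_model[name][i] = semipartial_spearman(
                        neural, model_vecs[name], others
                    ).rho
                else:
                    per_model[name][i] = spearman_rsa(
                        neural, model_vecs[name]
                    ).rho
        for name in names:
            subj_stats[name].append(per_model[name])

    mean_rho, p_map, p_adj_map, z_map, z_thr = {}, {}, {}, {}, {}
    for m_i, name in enumerate(names):
        values = np.stack(subj_stats[name])  # (n_subj, n_centers)
        valid = ~np.any(np.isnan(values), axis=0)
        obs = np.full(values.shape[1], np.nan)
        p = np.ones(values.shape[1])
        if valid.any():
            obs_v, p_v = signed_permutation_test_matrix(
                values[:, valid], tail=tail, n_perm=n_perm,
                seed=_child_seed(seed, m_i),
            )
            obs[valid] = obs_v
            p[valid] = p_v
        reject, p_adj = fdr_bh(p, alpha=alpha)
        z = np.array(
            [p_to_z(pa, effect_sign=np.sign(o) if np.isfinite(o) and o != 0 else 1.0,
                    tail=tail)
             for pa, o in zip(p_adj, obs)]
        )
        zt = np.where(np.abs(z) >= Z_THRESHOLD, z, 0.0)
        mean_rho[name], p_map[name], p_adj_map[name] = obs, p, p_adj
        z_map[name], z_thr[name] = z, zt
    return SearchlightResult(
        mask=rel_mask, centers=centers, mean_rho=mean_rho, p=p_map,
        p_adj=p_adj_map, z=z_map, z_thresholded=z_thr, kind=kind,
    )


def run_time_resolved(window_datasets: list[PatternDataset],
                      rois: dict[str, VoxelMask], models: dict, *,
                      n_perm: int = 5000, alpha: float = 0.05,
                      seed: int | None = 0,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Time-resolved semi-partial RSA plus model-by-window ANOVA per ROI.

    ``window_datasets`` holds one pattern dataset per time window (the
    published design uses five 2-s windows), sharing subjects and
    conditions.  Exactly two models are compared; each model's unique
    contribution controls for the other.  Returns (per-subject profile
    table, group table with FDR across model x window cells per ROI, and a
    repeated-measures ANOVA table per ROI).
    """
    if len(window_datasets) != 5:
        logger.warning("expected 5 time windows, got %d", len(window_datasets))
    names = list(models)
    if len(names) != 2:
        raise ValueError("time-resolved comparison expects exactly 2 models")
    model_vecs = model_rdm_vectors(models)
    subjects = window_datasets[0].subject_ids
    for ds in window_datasets[1:]:
        if ds.subject_ids != subjects:
            raise ValueError("window datasets must share subjects")

    profile_rows = []
    for roi_name, roi_mask in rois.items():
        for w, ds in enumerate(window_datasets):
            cols = ds.mask.column_indices(
                roi_mask.intersect(VoxelMask(ds.grid, ds.mask.data)).members
            )
            for subj in subjects:
                res = subject_roi_statistics(
                    ds.subjects[subj], cols, model_vecs, semipartial=True
                )
                if res is None:
                    continue
                for name in names:
                    profile_rows.append(
                        {"roi": roi_name, "window": w, "model": name,
                         "subject": subj,
                         "rho": res["stats"][("semipartial", name)]}
                    )
    profiles = pd.DataFrame(profile_rows)

    group_rows = []
    anova_tables: dict[str, pd.DataFrame] = {}
    for r_i, roi_name in enumerate(rois):
        sub = profiles[profiles["roi"] == roi_name]
        cells = []
        for w in sorted(sub["window"].unique()):
            for m_i, name in enumerate(names):
                values = sub[(sub["window"] == w) & (sub["model"] == name)][
                    "rho"
                ].to_numpy()
                if len(values) < 2:
                    continue
                test = signed_permutation_test(
                    values, tail="one", n_perm=n_perm,
                    seed=_child_seed(seed, r_i, w * 10 + m_i),
                )
                cells.append(
                    {"roi": roi_name, "window": w, "model": name,
                     "mean_rho": test.mean, "p": test.p, "z": test.z}
                )
        if cells:
            cdf = pd.DataFrame(cells)
            reject, p_adj = fdr_bh(cdf["p"].to_numpy(), alpha=alpha)
            cdf["p_adj"] = p_adj
            cdf["significant"] = reject
            group_rows.append(cdf)

        # complete subject x model x window grid for the ANOVA
        wide = sub.pivot_table(index="subject", columns=["model", "window"],
                               values="rho")
        if wide.isna().any().any() or wide.shape[0] < 2:
            logger.warning("ROI %s: incomplete grid, ANOVA skipped", roi_name)
            continue
        windows = sorted(sub["window"].unique())
        grid = np.stack(
            [wide[name][windows].to_numpy() for name in names], axis=1
        )  # (n_subj, 2, n_windows)
        anova_tables[roi_name] = rm_anova_2way(grid)
    group = pd.concat(group_rows, ignore_index=True) if group_rows else pd.DataFrame()
    return profiles, group, anova_tables
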