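"""Ground-truth synthetic data for every stage of the pipeline.

The generative assumption mirrors what the analyses infer: a region's
representational geometry is a weighted blend of candidate-model RDMs.
``gen_pattern_dataset`` rank-uniformizes the blend (a monotone transform,
identical information for Spearman-based analyses), factors the
corresponding similarity matrix as a covariance square root (clipping
negative eigenvalues), draws a seeded random voxel realization of that
geometry per subject, and adds independent Gaussian noise per repeat;
voxels outside planted regions receive pure noise.  Companion generators produce multinomial rating
counts, model representations with controlled inter-RDM correlations
(emulating the r = 0.27 / 0.50 / 0.46 structure of the published stimulus
set), time-windowed datasets with per-window weight schedules, and
moving-blob frame stacks for motion-energy tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import CATEGORIES, RepresentationSet
from .geometry import PatternDataset, VolumeGrid, VoxelMask
from .motion import FrameStack
from .rdm import RDM, rdm_vector, representation_rdm, spearman_rsa

__all__ = [
    "MixtureSpec",
    "SyntheticDataset",
    "InfeasibleTargetsError",
    "gen_rating_counts",
    "gen_model_representations",
    "gen_pattern_dataset",
    "gen_windowed_dataset",
    "gen_frame_stack",
]

logger = logging.getLogger(__name__)


class InfeasibleTargetsError(RuntimeError):
    """Requested inter-RDM correlation targets could not be achieved."""


@dataclass(frozen=True)
class MixtureSpec:
    """Planted generative structure for a volumetric pattern dataset.

    ``regions`` maps a region name to ``(mask, weights)`` where weights
    assign each named component RDM its blend weight in that region.
    ``window_schedules``, when given, maps component names to 5 per-window
    weights that override the region weights window by window.
    """

    components: dict[str, RDM]
    regions: dict[str, tuple[VoxelMask, dict[str, float]]]
    sigma: float = 6.5
    n_subjects: int = 25
    n_repeats: int = 5
    window_schedules: dict[str, tuple[float, ...]] | None = None
    subject_jitter: float = 0.5  # fraction of idiosyncratic subject geometry
    jitter_dims: int = 10

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("need at least one component RDM")
        labels = {tuple(c.labels) for c in self.components.values()}
        if len(labels) != 1:
            raise ValueError("component RDMs must share condition labels")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 0.0 <= self.subject_jitter < 1.0:
            raise ValueError("subject_jitter must lie in [0, 1)")
        if self.jitter_dims < 2:
            raise ValueError("jitter_dims must be >= 2")
        if self.n_subjects < 1 or self.n_repeats < 1:
            raise ValueError("need >= 1 subject and repeat")
        for name, (mask, weights) in self.regions.items():
            unknown = set(weights) - set(self.components)
            if unknown:
                raise ValueError(f"region {name}: unknown components {unknown}")
            if any(not np.isfinite(w) or w < 0 for w in weights.values()):
                raise ValueError(f"region {name}: weights must be finite, >= 0")
        if self.window_schedules is not None:
            for comp, sched in self.window_schedules.items():
                if comp not in self.components:
                    raise ValueError(f"schedule for unknown component {comp}")
                if len(sched) != 5:
                    raise ValueError("window schedules must cover all 5 windows")

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return next(iter(self.components.values())).labels


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated pattern dataset together with its ground truth."""

    dataset: PatternDataset
    spec: MixtureSpec
    region_masks: dict[str, VoxelMask]
    seed: int


def gen_rating_counts(n_videos: int, profiles=None, n_raters=10,
                      seed: int | None = None) -> pd.DataFrame:
    """Multinomial rating counts per video.

    ``profiles`` is an (n_videos, 3) array of category probabilities
    (friendly, neutral, adversarial), each row summing to 1; by default
    a random Dirichlet profile per video.  ``n_raters`` may be a scalar
    (default 10, the published median raters-per-video) or per-video array.
    """
    rng = np.random.default_rng(seed)
    if profiles is None:
        profiles = rng.dirichlet(np.ones(3), size=n_videos)
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape != (n_videos, 3):
        raise ValueError("profiles must be (n_videos, 3)")
    if not np.allclose(profiles.sum(axis=1), 1.0):
        raise ValueError("each probability profile must sum to 1")
    raters = np.broadcast_to(np.asarray(n_raters, dtype=int), (n_videos,))
    counts = np.stack(
        [rng.multinomial(raters[i], profiles[i]) for i in range(n_videos)]
    )
    df = pd.DataFrame(counts, columns=list(CATEGORIES))
    df.insert(0, "video", [f"video_{i:03d}" for i in range(n_videos)])
    return df


def _measured_pairwise(sets: dict[str, RepresentationSet]):
    vecs = {k: rdm_vector(representation_rdm(v)) for k, v in sets.items()}
    names = list(sets)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = spearman_rsa(vecs[a], vecs[b]).rho
    return out


def _bisect_noise_scale(latent, eps, target, latent_vec, lo=0.0, hi=64.0,
                        iters=40):
    """Noise scale at which corr(RDM(latent + s*eps), RDM(latent)) = target."""
    def measure(s):
        reps = RepresentationSet(
            tuple(map(str, range(latent.shape[0]))), latent + s * eps
        )
        return spearman_rsa(rdm_vector(representation_rdm(reps)), latent_vec).rho

    if target >= measure(lo):
        return lo
    for _ in range(iters):
        mid = (lo + hi) / 2.0
        if measure(mid) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gen_model_representations(n_conditions: int = 50,
                              targets: tuple[float, float, float] = (0.27, 0.50, 0.46),
                              dims: int = 8,
                              seed: int | None = None,
                              tolerance: float = 0.05,
                              max_attempts: int = 15) -> dict[str, RepresentationSet]:
    """Three representation sets with controlled pairwise RDM correlations.

    ``targets`` are the Spearman correlations (modelA-modelB,
    modelA-behavior, modelB-behavior) between the three sets' RDMs; the
    defaults emulate the published stimulus-set structure.  Construction:
    a shared latent condition embedding plus per-set independent noise
    whose scale is tuned by bisection so that each set's RDM attains a
    prescribed correlation with the latent RDM; under this construction
    the pairwise correlation between two sets is approximately the product
    of their latent couplings, which is refined iteratively until every
    measured pairwise value lies within ``tolerance`` of its target.
    """
    r_ab, r_abeh, r_bbeh = targets
    if any(not -1.0 < t < 1.0 + 1e-12 for t in targets):
        raise ValueError("targets must lie in (-1, 1]")
    labels = tuple(f"video_{i:03d}" for i in range(n_conditions))
    rng = np.random.default_rng(seed)
    names = ("modelA", "modelB", "behavior")
    pairs = {("modelA", "modelB"): r_ab, ("modelA", "behavior"): r_abeh,
             ("modelB", "behavior"): r_bbeh}

    if all(abs(t) <= tolerance / 2 for t in targets):
        sets = {
            n: RepresentationSet(labels, rng.standard_normal((n_conditions, dims)))
            for n in names
        }
        return sets

    if any(t >= 1.0 - 1e-9 for t in targets):  # duplication degenerate case
        base = rng.standard_normal((n_conditions, dims))
        latent = RepresentationSet(labels, base)
        sets = {}
        for n in names:
            sets[n] = RepresentationSet(labels, base.copy())
        # pairs below 1 get fresh noise via the general path is not needed:
        # duplication is only supported when *all* targets are 1
        if not all(t >= 1.0 - 1e-9 for t in targets):
            raise InfeasibleTargetsError(
                "mixing a target of 1 with lower targets is not supported"
            )
        return sets

    clamped = {k: max(v, 0.02) for k, v in pairs.items()}
    g = {
        "modelA": np.sqrt(clamped[("modelA", "modelB")]
                          * clamped[("modelA", "behavior")]
                          / clamped[("modelB", "behavior")]),
        "modelB": np.sqrt(clamped[("modelA", "modelB")]
                          * clamped[("modelB", "behavior")]
                          / clamped[("modelA", "behavior")]),
        "behavior": np.sqrt(clamped[("modelA", "behavior")]
                            * clamped[("modelB", "behavior")]
                            / clamped[("modelA", "modelB")]),
    }
    g = {k: min(v, 0.999) for k, v in g.items()}

    best_err, best_sets, best_meas = np.inf, None, None
    for _ in range(max_attempts):
        latent = rng.standard_normal((n_conditions, dims))
        latent_vec = rdm_vector(
            representation_rdm(RepresentationSet(labels, latent))
        )
        eps = {n: rng.standard_normal((n_conditions, dims)) for n in names}
        g_cur = dict(g)
        for _ in range(4):  # multiplicative refinement of latent couplings
            sets = {}
            for n in names:
                s = _bisect_noise_scale(latent, eps[n], g_cur[n], latent_vec)
                sets[n] = RepresentationSet(labels, latent + s * eps[n])
            measured = _measured_pairwise(sets)
            err = max(abs(measured[p] - pairs[p]) for p in pairs)
            if err < best_err:
                best_err, best_sets, best_meas = err, sets, measured
            if err <= tolerance:
                return sets
            # solve log g corrections from pairwise log ratios
            for n in names:
                ratios = [
                    pairs[p] / measured[p]
                    for p in pairs
                    if n in p and measured[p] > 0.01 and pairs[p] > 0.01
                ]
                if ratios:
                    g_cur[n] = float(
                        np.clip(g_cur[n] * np.prod(ratios) ** (0.5 / len(ratios)),
                                0.01, 0.999)
                    )
    raise InfeasibleTargetsError(
        f"could not reach targets {pairs} within ±{tolerance}; "
        f"best achieved {best_meas}"
    )


def _similarity_factor(dissimilarity: np.ndarray) -> np.ndarray:
    """Factor the blended similarity matrix 1 - D as X X^T.

    Working on the similarity (correlation) scale matches the measurement
    metric of the pipeline's RDMs: condition patterns drawn as X G with a
    random G have expected pattern correlation 1 - D, so the planted
    region's neural RDM is the blend up to zero-mean sampling error.
    Negative eigenvalues (a blend need not be a valid correlation matrix
    after mixing) are clipped and the distortion fraction is logged.
    """
    sim = 1.0 - dissimilarity
    eigval, eigvec = np.linalg.eigh((sim + sim.T) / 2.0)
    neg = eigval[eigval < -1e-10]
    if neg.size:
        distortion = -neg.sum() / np.abs(eigval).sum()
        logger.info(
            "similarity factorization clipped %d negative eigenvalue(s); "
            "distortion fraction %.4f", neg.size, distortion,
        )
    keep = eigval > 1e-10
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def _rank_uniform(dissimilarity: np.ndarray) -> np.ndarray:
    """Monotone transform to uniformly spaced dissimilarities.

    Off-diagonal entries are replaced by their ranks, rescaled to the
    original [min, max] range.  Spearman-based analyses see identical
    information; uniform value spacing makes the re-ranking caused by
    additive noise or jitter linear in rank, so a component absent from
    the blend stays uncorrelated with the planted geometry even through
    the pipeline's rank-transform nonlinearities.
    """
    from scipy import stats as _stats

    n = dissimilarity.shape[0]
    iu = np.triu_indices(n, 1)
    entries = dissimilarity[iu]
    lo, hi = entries.min(), entries.max()
    if hi <= lo:
        return dissimilarity.copy()
    u = (_stats.rankdata(entries) - 1) / (len(entries) - 1) * (hi - lo) + lo
    out = np.zeros_like(dissimilarity)
    out[iu] = u
    return out + out.T


def _region_blend(spec_components: dict[str, RDM], weights: dict[str, float],
                  ) -> tuple[np.ndarray, float] | None:
    """One region's blended dissimilarity and signal amplitude, or None.

    The blend mixes component RDMs by relative weight and is then
    rank-uniformized (see :func:`_rank_uniform`); the summed weight acts
    as the region's signal amplitude in beta units, so window schedules
    modulate signal strength as well as geometry.
    """
    total = sum(weights.values())
    if total <= 0:
        return None
    names = sorted(weights)
    blend = sum(
        (weights[k] / total) * spec_components[k].values for k in names
    )
    return _rank_uniform(blend), float(total)


def _draw_region_signal(factor: np.ndarray, n_vox: int,
                        rng: np.random.Generator) -> np.ndarray:
    """One random voxel realization of the region geometry.

    When the region has enough voxels the random frame is made
    semi-orthogonal with rows orthogonal to the constant vector, so the
    noiseless pattern-correlation matrix equals the blended similarity
    *exactly* for every subject (no sampling distortion that a
    sign-consistent group test could mistake for signal); otherwise a
    plain Gaussian frame is used and the geometry holds in expectation.
    """
    q = factor.shape[1]
    g = rng.standard_normal((n_vox, q))
    if n_vox >= q + 1:
        g = g - g.mean(axis=0)  # frame orthogonal to the constant vector
        qmat, _ = np.linalg.qr(g)
        frame = np.sqrt(n_vox) * qmat.T
    else:
        logger.info(
            "region with %d voxels < geometry rank %d: geometry holds "
            "only in expectation", n_vox, q,
        )
        frame = g.T
    return factor @ frame


def gen_pattern_dataset(spec: MixtureSpec, grid: VolumeGrid,
                        seed: int = 0,
                        analysis_mask: VoxelMask | None = None,
                        _weight_override: dict[str, dict[str, float]] | None = None,
                        _rng_signal: np.random.Generator | None = None,
                        ) -> SyntheticDataset:
    """Generate a multi-subject volumetric dataset with planted geometry.

    Every planted region's noiseless patterns realize the blend of the
    spec's component RDMs at that region's weights; the random voxel
    frame is drawn *per subject*.  With ``subject_jitter`` tau > 0 each
    subject's true similarity matrix is ``(1-tau) * blend + tau * C_s``
    with an independent random correlation matrix ``C_s`` per subject and
    region, emulating idiosyncratic representational geometry across
    participants.  The subject's signal is fixed across repeats;
    independent N(0, sigma^2) noise is added per repeat, and out-of-region
    voxels receive pure unit-variance noise.  Bit-reproducible for a
    fixed seed.
    """
    if analysis_mask is None:
        analysis_mask = VoxelMask(grid, np.ones(grid.shape, dtype=bool))
    for name, (mask, _) in spec.regions.items():
        if mask.difference(analysis_mask).size:
            raise ValueError(f"region {name} extends outside the analysis mask")
    rng_signal = _rng_signal or np.random.default_rng(seed)
    labels = spec.condition_labels
    n_cond = len(labels)
    n_vox = analysis_mask.size

    blends: dict[str, tuple[np.ndarray, float] | None] = {}
    region_cols: dict[str, np.ndarray] = {}
    for name in sorted(spec.regions):
        mask, weights = spec.regions[name]
        if _weight_override and name in _weight_override:
            weights = _weight_override[name]
        region_cols[name] = analysis_mask.column_indices(mask.members)
        blends[name] = _region_blend(spec.components, weights)
    outside = np.ones(n_vox, dtype=bool)
    for cols in region_cols.values():
        outside[cols] = False

    tau = spec.subject_jitter
    rng_noise = np.random.default_rng([seed, 1])
    subjects: dict[str, list[np.ndarray]] = {}
    for s in range(spec.n_subjects):
        signal = np.zeros((n_cond, n_vox))
        for name in sorted(spec.regions):
            if blends[name] is None:
                continue
            dis, amp = blends[name]
            if tau > 0:
                c_s = np.corrcoef(
                    rng_signal.standard_normal((n_cond, spec.jitter_dims))
                )
                dis = (1.0 - tau) * dis + tau * _rank_uniform(1.0 - c_s)
            signal[:, region_cols[name]] = amp * _draw_region_signal(
                _similarity_factor(dis), len(region_cols[name]), rng_signal
            )
        reps = []
        for _ in range(spec.n_repeats):
            noise = rng_noise.standard_normal((n_cond, n_vox))
            pattern = signal + spec.sigma * noise
            pattern[:, outside] = noise[:, outside]
            reps.append(pattern)
        subjects[f"sub-{s + 1:02d}"] = reps
    dataset = PatternDataset(subjects, labels, grid, analysis_mask)
    return SyntheticDataset(
        dataset=dataset, spec=spec,
        region_masks={n: spec.regions[n][0] for n in spec.regions}, seed=seed,
    )


def gen_windowed_dataset(spec: MixtureSpec, grid: VolumeGrid, seed: int = 0,
                         analysis_mask: VoxelMask | None = None,
                         ) -> list[SyntheticDataset]:
    """Five per-window datasets sharing subjects, with scheduled weights.

    Each component listed in ``spec.window_schedules`` takes its scheduled
    weight in each window (in every region that includes the component);
    unscheduled components keep their constant region weight.  The random
    projection map is redrawn per window from the same seed stream while
    noise is independent across windows.
    """
    if spec.window_schedules is None:
        raise ValueError("spec.window_schedules is required")
    out = []
    for w in range(5):
        override: dict[str, dict[str, float]] = {}
        for rname, (_, weights) in spec.regions.items():
            new = dict(weights)
            for comp, sched in spec.window_schedules.items():
                if comp in new:
                    new[comp] = float(sched[w])
            override[rname] = new
        out.append(
            gen_pattern_dataset(
                spec, grid, seed=(seed * 5 + w) % (2**31),
                analysis_mask=analysis_mask, _weight_override=override,
            )
        )
    return out


def gen_frame_stack(start: tuple[float, float], velocity: tuple[float, float],
                    size: tuple[int, int] = (32, 32), n_frames: int = 24,
                    blob_sigma: float = 2.0, amplitude: float = 1.0,
                    frame_rate: float = 10.0,
                    static_distractor: tuple[float, float] | None = None,
                    seed: int | None = None) -> FrameStack:
    """A Gaussian blob translating at constant velocity (pixels/frame).

    The trajectory must stay inside the frame; an optional static
    distractor blob can be added.  Generation is deterministic; ``seed``
    is accepted for interface uniformity with the other generators.
    """
    del seed
    h, w = size
    ys, xs = np.mgrid[0:h, 0:w]
    frames = np.zeros((n_frames, h, w))
    for t in range(n_frames):
        cy = start[0] + velocity[0] * t
        cx = start[1] + velocity[1] * t
        if not (0 <= cy < h and 0 <= cx < w):
            raise ValueError(f"trajectory leaves the frame at t={t}")
        frames[t] = amplitude * np.exp(
            -((ys - cy) ** 2 + (xs - cx) ** 2) / (2 * blob_sigma**2)
        )
        if static_distractor is not None:
            dy, dx = static_distractor
            frames[t] += 0.5 * amplitude * np.exp(
                -((ys - dy) ** 2 + (xs - dx) ** 2) / (2 * blob_sigma**2)
            )
    return FrameStack(frames=frames, frame_rate=frame_rate)
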