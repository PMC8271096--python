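"""Synthetic cohorts: parcellation hierarchies, connectomes, model-grown BOLD.

The generator emulates the statistical shape of a parcellation-level
resting-state dataset without any imaging: a set of "finest units" (stand-ins
for voxel clusters) scattered in a brain-sized box is clustered into nested
parcellations of decreasing granularity; structural connectomes follow a
distance-dependent lognormal count law; and BOLD sessions are grown by
simulating a ground-truth oscillator model on each subject's own network at a
known (tau*, C*), then downsampled to the fMRI repetition time and corrupted
with measurement noise.  Subjects differ through multiplicative lognormal
jitter on their streamline counts and through per-region natural-frequency
jitter, which is what gives the downstream fit statistics their inter-subject
variance.

Every operation is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .derive import RegionalParameters, build_network
from .exceptions import InvalidArgumentError
from .simulate import SimulationConfig, simulate_network

#: brain-like bounding box for the finest-unit coordinates, mm
BOX_EXTENT_MM = (140.0, 180.0, 120.0)

#: emulated fMRI protocol: 4 sessions of 1200 volumes at TR = 0.72 s
N_SESSIONS = 4
VOLUMES_PER_SESSION = 1200
TR_SECONDS = 0.72

#: lognormal spread of streamline counts around the distance-decay trend
COUNT_LOG_SIGMA = 0.8
#: multiplicative noise on path lengths around the centroid distance
LENGTH_LOG_SIGMA = 0.1

#: default grid bounds that ground-truth parameters must respect
GRID_TAU_MAX = 94.0
GRID_C_MAX = 0.945


@dataclass
class Parcellation:
    """One granularity level of a nested parcellation hierarchy."""

    level_id: str
    region_sizes: np.ndarray      # per-region count of finest units
    centroids: np.ndarray         # (n_regions, 3), mm
    parent_map: np.ndarray        # finest unit -> region index at this level

    @property
    def n_regions(self) -> int:
        return len(self.region_sizes)

    @property
    def n_fine(self) -> int:
        return len(self.parent_map)

    def validate(self) -> None:
        sizes = np.asarray(self.region_sizes)
        if np.any(sizes <= 0):
            raise InvalidArgumentError("region sizes must be positive")
        if sizes.sum() != self.n_fine:
            raise InvalidArgumentError(
                "region sizes must sum to the number of finest units")
        counts = np.bincount(self.parent_map, minlength=self.n_regions)
        if not np.array_equal(counts, sizes):
            raise InvalidArgumentError("parent_map inconsistent with sizes")

    @property
    def region_labels(self):
        return [f"{self.level_id}_r{i}" for i in range(self.n_regions)]


@dataclass
class StructuralConnectome:
    """Streamline counts and mean path lengths between regions."""

    counts: np.ndarray    # (N, N), nonnegative, symmetric, zero diagonal
    lengths: np.ndarray   # (N, N), mm, symmetric, zero diagonal

    def validate(self) -> None:
        for name, m in (("counts", self.counts), ("lengths", self.lengths)):
            if not np.allclose(m, m.T):
                raise InvalidArgumentError(f"{name} must be symmetric")
            if np.any(np.diag(m) != 0):
                raise InvalidArgumentError(f"{name} must have zero diagonal")
            if np.any(m < 0):
                raise InvalidArgumentError(f"{name} must be nonnegative")
        if np.any((self.counts > 0) & (self.lengths <= 0)):
            raise InvalidArgumentError(
                "positive counts require positive path lengths")


@dataclass
class BoldDataset:
    """Ordered fMRI-style sessions sharing a repetition time."""

    sessions: list          # list of (T, N) arrays
    tr: float = TR_SECONDS

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.sessions, axis=0)

    @property
    def n_regions(self) -> int:
        return self.sessions[0].shape[1]


@dataclass
class SubjectBundle:
    """One subject's data at one parcellation level.

    ``efc_list`` holds the 4 per-session empirical FC matrices followed by the
    FC of the concatenated sessions (5 matrices in total).
    """

    subject_id: str
    parcellation: Parcellation
    connectome: StructuralConnectome
    bold: BoldDataset
    efc_list: list = field(default=None)
    ground_truth: dict = None

    def __post_init__(self):
        if self.efc_list is None:
            self.efc_list = compute_efc_list(self.bold)

    @property
    def n_regions(self) -> int:
        return self.connectome.counts.shape[0]


def compute_efc_list(bold: BoldDataset) -> list:
    """Per-session plus concatenated FC matrices (Pearson, unit diagonal)."""
    mats = []
    for x in list(bold.sessions) + [bold.concatenated]:
        fc = np.atleast_2d(np.corrcoef(x, rowvar=False))
        np.fill_diagonal(fc, 1.0)
        mats.append(fc)
    return mats


def efc_target_names(n_sessions: int = N_SESSIONS) -> list:
    return [f"session{i + 1}" for i in range(n_sessions)] + ["concatenated"]


def make_parcellation_hierarchy(n_fine: int, granularities, seed: int,
                                box=BOX_EXTENT_MM) -> list:
    """Nested parcellations of ``n_fine`` scattered units, one per granularity.

    Units are placed uniformly in a brain-sized box and merged bottom-up by
    Ward clustering of their coordinates; cutting the single dendrogram at
    each requested granularity guarantees that every coarser region is a union
    of finer ones.  Region labels are assigned in order of first occurrence
    along the unit index, so the level at granularity ``n_fine`` is the
    identity partition.
    """
    granularities = list(granularities)
    for g in granularities:
        if not 1 <= g <= n_fine:
            raise InvalidArgumentError(
                f"granularity {g} outside [1, {n_fine}]")
    rng = np.random.default_rng(seed)
    points = rng.uniform(0.0, 1.0, (n_fine, 3)) * np.asarray(box)
    z = linkage(points, method="ward") if n_fine > 1 else None
    levels = []
    for g in granularities:
        if g == n_fine:
            labels = np.arange(n_fine)
        elif g == 1:
            labels = np.zeros(n_fine, dtype=np.int64)
        else:
            raw = fcluster(z, t=g, criterion="maxclust")
            # relabel clusters by first occurrence for determinism
            order = {}
            labels = np.empty(n_fine, dtype=np.int64)
            for i, c in enumerate(raw):
                if c not in order:
                    order[c] = len(order)
                labels[i] = order[c]
        n_regions = int(labels.max()) + 1
        sizes = np.bincount(labels, minlength=n_regions)
        centroids = np.zeros((n_regions, 3))
        np.add.at(centroids, labels, points)
        centroids /= sizes[:, None]
        parc = Parcellation(level_id=f"L{n_regions}", region_sizes=sizes,
                            centroids=centroids, parent_map=labels)
        parc.validate()
        levels.append(parc)
    return levels


def make_structural_connectome(parcellation: Parcellation,
                               decay_length: float = 30.0,
                               count_scale: float = 500.0,
                               seed: int = 0) -> StructuralConnectome:
    """Distance-decaying lognormal streamline counts plus noisy path lengths.

    Counts follow log k ~ Normal(log(count_scale) - d / decay_length, 0.8)
    with d the centroid Euclidean distance, rounded to integers with floor 0;
    lengths are the centroid distances under multiplicative lognormal noise.
    Both matrices are symmetric with zero diagonal.
    """
    n = parcellation.n_regions
    if n < 2:
        raise InvalidArgumentError("need at least 2 regions")
    if decay_length <= 0:
        raise InvalidArgumentError("decay_length must be positive")
    rng = np.random.default_rng(seed)
    diff = parcellation.centroids[:, None, :] - parcellation.centroids[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    log_mean = np.log(count_scale) - dist[iu] / decay_length
    raw = np.exp(rng.normal(log_mean, COUNT_LOG_SIGMA))
    counts_u = np.maximum(np.round(raw), 0.0)
    lengths_u = dist[iu] * np.exp(rng.normal(0.0, LENGTH_LOG_SIGMA,
                                             size=len(raw)))
    lengths_u = np.where(counts_u > 0, np.maximum(lengths_u, 1e-6), lengths_u)
    counts = np.zeros((n, n))
    lengths = np.zeros((n, n))
    counts[iu] = counts_u
    lengths[iu] = lengths_u
    counts += counts.T
    lengths += lengths.T
    sc = StructuralConnectome(counts=counts, lengths=lengths)
    sc.validate()
    return sc


@dataclass
class NoiseSpec:
    """Sources of subject-level and measurement variability.

    ``subject_sigma``: lognormal sigma of the per-subject multiplicative
    jitter on streamline counts; ``frequency_sigma``: lognormal sigma of the
    per-region natural-frequency jitter; ``measurement``: SD of the additive
    Gaussian BOLD noise relative to each region's signal SD;
    ``sim_noise_amplitude``: amplitude of the dynamical noise in the
    generating model run.
    """

    subject_sigma: float = 0.2
    frequency_sigma: float = 0.1
    measurement: float = 0.5
    sim_noise_amplitude: float = 0.3


def _bold_sim_config(model_kind: str, seed: int,
                     noise_amplitude: float) -> SimulationConfig:
    dt = 0.06
    resample = int(round(TR_SECONDS / dt))          # 12, exact integer ratio
    retained = N_SESSIONS * VOLUMES_PER_SESSION * resample
    n_transient = int(np.ceil(500.0 / dt))
    return SimulationConfig(dt=dt,
                            duration=(n_transient + retained) * dt,
                            transient=n_transient * dt,
                            noise_amplitude=noise_amplitude,
                            seed=seed, model_kind=model_kind)


def make_bold_cohort(n_subjects: int, parcellation: Parcellation,
                     ground_truth: dict, noise_spec: NoiseSpec = None,
                     seed: int = 0, decay_length: float = 30.0,
                     count_scale: float = 500.0,
                     frequency_range=(0.02, 0.09)) -> list:
    """Generate ``n_subjects`` SubjectBundles with known generating dynamics.

    ``ground_truth`` must provide ``model_kind`` ("phase" or "limit_cycle"),
    ``tau`` and ``coupling``, which must lie inside the default fitting grid.
    Each subject gets a jittered copy of a cohort-level connectome and
    frequency profile; BOLD is the ground-truth model's observable simulated
    on that subject's network, downsampled to TR = 0.72 s (every 12th step),
    and corrupted by additive Gaussian noise scaled to the signal SD.
    """
    if n_subjects < 1:
        raise InvalidArgumentError("n_subjects must be >= 1")
    noise_spec = noise_spec or NoiseSpec()
    model_kind = ground_truth["model_kind"]
    tau_star = float(ground_truth["tau"])
    c_star = float(ground_truth["coupling"])
    if not (0 <= tau_star <= GRID_TAU_MAX and 0 <= c_star <= GRID_C_MAX):
        raise InvalidArgumentError(
            f"ground truth (tau={tau_star}, C={c_star}) outside the default "
            f"grid [0, {GRID_TAU_MAX}] x [0, {GRID_C_MAX}]")
    ss = np.random.SeedSequence(seed)
    base_child, freq_child, *subject_children = ss.spawn(2 + n_subjects)
    base_sc = make_structural_connectome(
        parcellation, decay_length=decay_length, count_scale=count_scale,
        seed=int(base_child.generate_state(1)[0]))
    n = parcellation.n_regions
    rng_f = np.random.default_rng(freq_child)
    base_freq = rng_f.uniform(*frequency_range, n)
    iu = np.triu_indices(n, k=1)
    bundles = []
    for i, child in enumerate(subject_children):
        rng = np.random.default_rng(child)
        jitter_u = np.exp(rng.normal(0.0, noise_spec.subject_sigma,
                                     size=len(iu[0])))
        counts = np.zeros((n, n))
        counts[iu] = np.round(base_sc.counts[iu] * jitter_u)
        counts += counts.T
        lengths = base_sc.lengths.copy()
        lengths[(counts > 0) & (lengths <= 0)] = 1e-6
        sc = StructuralConnectome(counts=counts, lengths=lengths)
        freqs = np.clip(base_freq * np.exp(
            rng.normal(0.0, noise_spec.frequency_sigma, n)), 0.011, 0.099)
        amps = rng.normal(0.5, 0.4, n)
        network = build_network(sc)
        params = RegionalParameters(frequencies=freqs, amplitudes=amps)
        sim_seed = int(rng.integers(0, 2 ** 31))
        config = _bold_sim_config(model_kind, sim_seed,
                                  noise_spec.sim_noise_amplitude)
        run = simulate_network(network, params, c_star, tau_star, config)
        resample = int(round(TR_SECONDS / config.dt))
        x = run.observables[::resample]
        sd = x.std(axis=0)
        noisy = x + rng.normal(0.0, 1.0, x.shape) * (
            noise_spec.measurement * sd)
        sessions = [noisy[k * VOLUMES_PER_SESSION:(k + 1) * VOLUMES_PER_SESSION]
                    for k in range(N_SESSIONS)]
        bold = BoldDataset(sessions=sessions, tr=TR_SECONDS)
        bundles.append(SubjectBundle(
            subject_id=f"sub{i:03d}",
            parcellation=parcellation, connectome=sc, bold=bold,
            ground_truth={"model_kind": model_kind, "tau": tau_star,
                          "coupling": c_star, "cohort_seed": seed,
                          "sim_seed": sim_seed,
                          "frequencies": freqs.tolist(),
                          "amplitudes": amps.tolist()}))
    return bundles


def _region_mapping(fine: Parcellation, coarse: Parcellation) -> np.ndarray:
    """fine-region -> coarse-region index; error if levels are not nested."""
    if fine.n_fine != coarse.n_fine:
        raise InvalidArgumentError(
            "parcellations do not share the same finest units")
    mapping = np.full(fine.n_regions, -1, dtype=np.int64)
    for unit in range(fine.n_fine):
        fr = fine.parent_map[unit]
        cr = coarse.parent_map[unit]
        if mapping[fr] == -1:
            mapping[fr] = cr
        elif mapping[fr] != cr:
            raise InvalidArgumentError(
                f"target level {coarse.level_id} is not an ancestor of "
                f"{fine.level_id}: fine region {fr} splits across coarse "
                "regions")
    return mapping


def coarsen_subject(bundle: SubjectBundle,
                    target: Parcellation) -> SubjectBundle:
    """Re-express a subject at a coarser, nested parcellation level.

    Coarse streamline counts sum the fine counts crossing distinct coarse
    regions; coarse path lengths are the count-weighted mean of member
    lengths (plain mean where no streamlines connect the pair); coarse BOLD
    is the region-size-weighted mean of member signals; FC is recomputed.
    """
    fine = bundle.parcellation
    mapping = _region_mapping(fine, target)
    if target.n_regions == fine.n_regions and np.array_equal(
            mapping, np.arange(fine.n_regions)):
        return SubjectBundle(subject_id=bundle.subject_id,
                             parcellation=fine,
                             connectome=StructuralConnectome(
                                 counts=bundle.connectome.counts.copy(),
                                 lengths=bundle.connectome.lengths.copy()),
                             bold=BoldDataset(
                                 [s.copy() for s in bundle.bold.sessions],
                                 tr=bundle.bold.tr),
                             ground_truth=bundle.ground_truth)
    nc = target.n_regions
    # aggregation matrix fine-regions x coarse-regions
    agg = np.zeros((fine.n_regions, nc))
    agg[np.arange(fine.n_regions), mapping] = 1.0
    counts = agg.T @ bundle.connectome.counts @ agg
    weighted_len = agg.T @ (bundle.connectome.counts *
                            bundle.connectome.lengths) @ agg
    pair_n = agg.T @ np.ones_like(bundle.connectome.counts) @ agg
    plain_len = agg.T @ bundle.connectome.lengths @ agg
    with np.errstate(invalid="ignore", divide="ignore"):
        lengths = np.where(counts > 0, weighted_len / np.where(
            counts > 0, counts, 1.0), plain_len / pair_n)
    np.fill_diagonal(counts, 0.0)
    np.fill_diagonal(lengths, 0.0)
    fine_sizes = np.asarray(fine.region_sizes, dtype=float)
    size_w = agg * fine_sizes[:, None]
    size_w = size_w / size_w.sum(axis=0, keepdims=True)
    sessions = [s @ size_w for s in bundle.bold.sessions]
    bold = BoldDataset(sessions=sessions, tr=bundle.bold.tr)
    sc = StructuralConnectome(counts=counts, lengths=lengths)
    sc.validate()
    return SubjectBundle(subject_id=bundle.subject_id, parcellation=target,
                         connectome=sc, bold=bold,
                         ground_truth=bundle.ground_truth)
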