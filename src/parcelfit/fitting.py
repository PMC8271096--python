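"""Grid-search model fitting: similarity planes over (tau, C) and their optima.

For each point of a (global delay, global coupling) grid one model run is
simulated; its simulated FC is compared by Pearson correlation of the upper
triangles against each of the six empirical targets (the 4 session FC
matrices, the concatenated-session FC, and the streamline-count matrix).  The
goodness of fit for a target is the maximum of its similarity plane,

    Fit = max_{(tau, C)} corr(sFC, target),

reported together with the maximizing grid point and the k best points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .derive import derive_subject
from .exceptions import (DivergenceError, InvalidArgumentError,
                         UndefinedCorrelationError)
from .simulate import SimulationConfig, compute_sfc, simulate_network
from .synthetic import efc_target_names

logger = logging.getLogger(__name__)

DEFAULT_TAU_MAX = 94.0
DEFAULT_N_TAU = 48
DEFAULT_C_MAX = 0.945
DEFAULT_N_C = 64

STRUCTURAL_TARGET = "esc"

_MODEL_CODES = {"phase": 0, "limit_cycle": 1}


@dataclass
class FitGrid:
    """Strictly increasing (tau, C) grid values, both starting at 0 by default."""

    tau_values: np.ndarray
    c_values: np.ndarray

    def __post_init__(self):
        self.tau_values = np.asarray(self.tau_values, dtype=float)
        self.c_values = np.asarray(self.c_values, dtype=float)
        for name, v in (("tau_values", self.tau_values),
                        ("c_values", self.c_values)):
            if v.ndim != 1 or len(v) == 0:
                raise InvalidArgumentError(f"{name} must be a 1-d sequence")
            if len(v) > 1 and np.any(np.diff(v) <= 0):
                raise InvalidArgumentError(f"{name} must be strictly increasing")

    @property
    def shape(self):
        return (len(self.tau_values), len(self.c_values))

    @property
    def size(self) -> int:
        return len(self.tau_values) * len(self.c_values)


def default_grid() -> FitGrid:
    """The 48 x 64 grid spanning [0, 94] s x [0, 0.945]."""
    return FitGrid(tau_values=np.linspace(0.0, DEFAULT_TAU_MAX, DEFAULT_N_TAU),
                   c_values=np.linspace(0.0, DEFAULT_C_MAX, DEFAULT_N_C))


def upper_tri_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of the strictly-upper-triangular parts of A and B."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidArgumentError("matrices must be square and equal-shaped")
    n = a.shape[0]
    if n < 3:
        raise InvalidArgumentError("need N >= 3 for a meaningful upper triangle")
    iu = np.triu_indices(n, k=1)
    x, y = a[iu], b[iu]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("constant upper triangle")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class FitResult:
    """Similarity plane and optima for one (subject, model, target)."""

    target: str
    plane: np.ndarray            # (n_tau, n_c); NaN marks diverged runs
    grid: FitGrid
    top_k: list = field(default=None)   # [(tau, C, value, (ti, ci)), ...]

    def __post_init__(self):
        if self.top_k is None:
            self.top_k = extract_optima(self.plane, self.grid)

    @property
    def fit(self) -> float:
        return self.top_k[0][2]

    @property
    def optimum(self):
        return self.top_k[0][:2]

    @property
    def optimum_index(self):
        return self.top_k[0][3]


def extract_optima(plane: np.ndarray, grid: FitGrid, k: int = 5) -> list:
    """The k largest plane entries in descending order.

    Ties are broken by scan order (tau ascending, then C ascending); NaN
    entries (diverged runs) are excluded.
    """
    flat = plane.ravel()
    valid = np.flatnonzero(np.isfinite(flat))
    if valid.size == 0:
        raise InvalidArgumentError("similarity plane has no finite entries")
    order = valid[np.argsort(-flat[valid], kind="stable")][:k]
    n_c = plane.shape[1]
    out = []
    for idx in order:
        ti, ci = divmod(int(idx), n_c)
        out.append((float(grid.tau_values[ti]), float(grid.c_values[ci]),
                    float(flat[idx]), (ti, ci)))
    return out


def point_seed(base_seed: int, subject_index: int, model_kind: str,
               tau_index: int, c_index: int) -> int:
    """Deterministic per-grid-point seed (one stochastic run per point)."""
    ss = np.random.SeedSequence(
        entropy=base_seed,
        spawn_key=(subject_index, _MODEL_CODES[model_kind],
                   tau_index, c_index))
    return int(ss.generate_state(1)[0])


def fit_subject(bundle, model_kind: str, grid: FitGrid = None,
                config: SimulationConfig = None,
                mean_convention: str = "full",
                subject_index: int = 0, top_k: int = 5,
                network=None, params=None) -> dict:
    """Fit one subject: full similarity planes against all six targets.

    One simulation per grid point serves every target.  Returns a dict
    mapping target name (session1..4, concatenated, esc) to FitResult.
    Diverged grid points are logged and left as NaN in the planes.

    By default the model inputs are derived from the bundle itself (the
    personalized-model protocol); pass ``network`` and/or ``params`` to fit
    with externally known inputs, e.g. a generator's recorded ground-truth
    regional parameters in a recovery study.
    """
    grid = grid or default_grid()
    config = config or SimulationConfig(model_kind=model_kind)
    if config.model_kind != model_kind:
        config = replace(config, model_kind=model_kind)
    if network is None or params is None:
        derived_network, derived_params = derive_subject(bundle,
                                                         mean_convention)
        network = network or derived_network
        params = params or derived_params
    targets = {name: fc for name, fc in
               zip(efc_target_names(len(bundle.bold.sessions)),
                   bundle.efc_list)}
    targets[STRUCTURAL_TARGET] = bundle.connectome.counts
    n_tau, n_c = grid.shape
    planes = {name: np.full((n_tau, n_c), np.nan) for name in targets}
    for ti, tau in enumerate(grid.tau_values):
        for ci, c in enumerate(grid.c_values):
            seed = point_seed(config.seed, subject_index, model_kind, ti, ci)
            run_config = replace(config, seed=seed)
            try:
                run = simulate_network(network, params, float(c), float(tau),
                                       run_config)
                sfc = compute_sfc(run)
            except (DivergenceError, UndefinedCorrelationError) as exc:
                logger.warning("run failed at (tau=%g, C=%g): %s", tau, c, exc)
                continue
            for name, target in targets.items():
                planes[name][ti, ci] = upper_tri_similarity(sfc, target)
    return {name: FitResult(target=name, plane=plane, grid=grid,
                            top_k=extract_optima(plane, grid, top_k))
            for name, plane in planes.items()}


def fit_cohort(bundles, model_kind: str, grid: FitGrid = None,
               config: SimulationConfig = None,
               mean_convention: str = "full") -> pd.DataFrame:
    """Long-format fit table over a cohort of bundles.

    One row per (subject, parcellation, model, target) with the Fit value and
    the optimal (tau, C); rows are sorted deterministically, so the table is
    independent of the input order of the bundles.
    """
    rows = []
    order = np.argsort([b.subject_id for b in bundles], kind="stable")
    for rank, idx in enumerate(order):
        bundle = bundles[idx]
        # seed substream keyed by the subject's rank in sorted order, so the
        # result is independent of the input ordering of the bundles
        results = fit_subject(bundle, model_kind, grid, config,
                              mean_convention, subject_index=rank)
        for name, res in results.items():
            tau_opt, c_opt = res.optimum
            rows.append({"subject": bundle.subject_id,
                         "parcellation": bundle.parcellation.level_id,
                         "model": model_kind, "target": name,
                         "fit": res.fit, "tau_opt": tau_opt, "c_opt": c_opt,
                         "seed": config.seed if config else 0})
    df = pd.DataFrame(rows)
    return df.sort_values(["subject", "parcellation", "model", "target"],
                          kind="stable").reset_index(drop=True)


@dataclass
class JobPlan:
    """Bookkeeping of a full fitting campaign."""

    n_runs: int
    n_functional_optima: int   # per parcellation and model
    n_structural_optima: int   # per parcellation and model


def plan_jobs(n_subjects: int, n_parcellations: int, n_models: int,
              grid: FitGrid) -> JobPlan:
    """Run counts of an exhaustive campaign (one run serves all 6 targets)."""
    for name, v in (("n_subjects", n_subjects),
                    ("n_parcellations", n_parcellations),
                    ("n_models", n_models)):
        if v < 1:
            raise InvalidArgumentError(f"{name} must be >= 1")
    return JobPlan(
        n_runs=n_subjects * n_parcellations * n_models * grid.size,
        n_functional_optima=n_subjects * 5,
        n_structural_optima=n_subjects)
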