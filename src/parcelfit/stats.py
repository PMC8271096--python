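"""Variability analyses of fit results across subjects and parcellations.

Covers: Fisher-z averaging of correlation coefficients; pairwise Pearson
correlation of Fit patterns between parcellations with intra-/inter-atlas
summaries; one-sided paired Wilcoxon signed-rank matrices with multiple-
comparison correction and matched-pairs rank-biserial effect sizes;
variable-vs-fit correlation tables with an intra-/inter-parcellation
classification; multiple linear regression of Fit on z-scored data variables;
and normalized distances between optimal parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import InvalidArgumentError

ALPHA = 0.05

_CLIP = 1.0 - 1e-15


def fisher_z(r):
    """atanh of a correlation, clipping |r| >= 1 - 1e-15 first."""
    r = np.clip(np.asarray(r, dtype=float), -_CLIP, _CLIP)
    return np.arctanh(r)


def fisher_z_inv(z):
    return np.tanh(np.asarray(z, dtype=float))


def fisher_mean(rs) -> float:
    """Average correlations on the z scale and transform back."""
    rs = np.asarray(rs, dtype=float)
    return float(fisher_z_inv(fisher_z(rs).mean()))


@dataclass
class FitPatternReport:
    """Pairwise Fit-pattern correlations between parcellations."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame     # boolean, p < alpha
    intra_atlas_mean: float
    inter_atlas_mean: float
    atlas_labels: dict


def fit_pattern_correlations(fit_table: pd.DataFrame,
                             atlas_labels: dict = None,
                             alpha: float = ALPHA) -> FitPatternReport:
    """Correlate Fit vectors (subjects x scans) between every parcellation pair.

    ``fit_table`` is wide: one column per parcellation, rows aligned across
    parcellations (same subject/scan ordering in every column).  Intra- and
    inter-atlas mean correlations are computed on the off-diagonal pairs via
    the Fisher z-transform; ``atlas_labels`` maps parcellation -> atlas name
    (every parcellation its own atlas when omitted).
    """
    cols = list(fit_table.columns)
    if fit_table.isna().any().any():
        raise InvalidArgumentError("fit_table contains missing values")
    atlas_labels = atlas_labels or {c: c for c in cols}
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ri, pi = sps.pearsonr(fit_table[cols[i]], fit_table[cols[j]])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    intra, inter = [], []
    for i in range(k):
        for j in range(i + 1, k):
            same = atlas_labels[cols[i]] == atlas_labels[cols[j]]
            (intra if same else inter).append(r[i, j])
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return FitPatternReport(
        r=rdf, p=pdf, significant=pdf < alpha,
        intra_atlas_mean=fisher_mean(intra) if intra else np.nan,
        inter_atlas_mean=fisher_mean(inter) if inter else np.nan,
        atlas_labels=dict(atlas_labels))


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank


def signed_rank_test(x, y=None, exact_max_n: int = 25):
    """One-sided paired signed-rank test of the alternative x > y.

    Zero differences are dropped.  For n <= ``exact_max_n`` the p-value is
    computed from the exact null distribution of the positive-rank sum
    (enumerated by convolution over the doubled midranks, so ties are
    handled exactly); otherwise a normal approximation with tie correction
    and continuity correction is used.  Returns ``(p, effect)`` where
    ``effect`` is the matched-pairs rank-biserial correlation.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1, effect = 0")
        return 1.0, 0.0
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    effect = (w_pos - w_neg) / (w_pos + w_neg)
    if n <= exact_max_n:
        doubled = np.round(2 * ranks).astype(np.int64)
        total = int(doubled.sum())
        # exact distribution of the doubled positive-rank sum
        poly = np.zeros(total + 1)
        poly[0] = 1.0
        for dr in doubled:
            nxt = poly.copy()
            nxt[dr:] += poly[:total + 1 - dr]
            poly = nxt
        w2 = int(np.round(2 * w_pos))
        p = float(poly[w2:].sum() / 2.0 ** n)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_pos - mean - 0.5) / np.sqrt(var)
        p = float(sps.norm.sf(z))
    return p, effect


@dataclass
class WilcoxonReport:
    """Ordered-pair signed-rank tests between parcellations."""

    p: pd.DataFrame            # raw one-sided p, row > column
    p_corrected: pd.DataFrame
    effect: pd.DataFrame       # rank-biserial, row vs column
    correction: str


def pairwise_wilcoxon(fits: pd.DataFrame, correction: str = "bonferroni",
                      exact_max_n: int = 25) -> WilcoxonReport:
    """Paired one-sided signed-rank tests for every ordered parcellation pair.

    ``fits`` is wide (columns = parcellations, rows = paired observations).
    The alternative for cell (row, column) is Fit(row) > Fit(column).
    Correction is applied across all ordered pairs ("bonferroni" or "holm").
    """
    if correction not in ("bonferroni", "holm"):
        raise InvalidArgumentError(
            f"unknown correction {correction!r}")
    cols = list(fits.columns)
    if len(fits) < 5:
        raise InvalidArgumentError("need at least 5 paired observations")
    k = len(cols)
    p = np.full((k, k), np.nan)
    eff = np.full((k, k), np.nan)
    pairs = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            pij, eij = signed_rank_test(fits[cols[i]].to_numpy(),
                                        fits[cols[j]].to_numpy(),
                                        exact_max_n=exact_max_n)
            p[i, j] = pij
            eff[i, j] = eij
            pairs.append((i, j))
    m = len(pairs)
    pc = np.full((k, k), np.nan)
    if correction == "bonferroni":
        for i, j in pairs:
            pc[i, j] = min(1.0, p[i, j] * m)
    else:
        raw = np.array([p[i, j] for i, j in pairs])
        order = np.argsort(raw, kind="stable")
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx])
            adj[idx] = min(1.0, running)
        for (i, j), a in zip(pairs, adj):
            pc[i, j] = a
    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return WilcoxonReport(p=mk(p), p_corrected=mk(pc), effect=mk(eff),
                          correction=correction)


# ---------------------------------------------------------------------------
# variable-vs-fit correlations and classification


@dataclass
class VariableFitReport:
    """Correlation structure of one or more data variables against Fit."""

    per_parcellation_r: pd.DataFrame    # variables x parcellations
    per_parcellation_p: pd.DataFrame
    summary: pd.DataFrame               # per variable: means, joint, class

    def classification(self, variable: str) -> str:
        return self.summary.loc[variable, "class"]


def variable_fit_regression(table: pd.DataFrame, variables,
                            fit_column: str = "fit",
                            parcellation_column: str = "parcellation",
                            delta: float = 0.1, floor: float = 0.3,
                            alpha: float = ALPHA,
                            min_significant_frac: float = 0.5,
                            ) -> VariableFitReport:
    """Per-parcellation, joint and group-median variable-fit correlations.

    For each variable: r (and p) with Fit within each parcellation; the joint
    r over the rows pooled across parcellations; and the group-median r
    across parcellations (each parcellation reduced to its median variable
    and median Fit first; requires at least 3 parcellations).

    Classification compares the Fisher-z mean of the per-parcellation |r|
    (``mean_abs_individual_r``) with the joint |r|: ``intra`` when the
    individual mean exceeds the joint by ``delta`` and at least
    ``min_significant_frac`` of the individual correlations are significant
    at ``alpha``; ``inter`` when the joint exceeds the individual mean by
    ``delta``; ``both`` when each is at least ``floor`` and they agree within
    ``delta``; otherwise ``neither``.
    """
    parcs = sorted(table[parcellation_column].unique())
    if len(parcs) < 3:
        raise InvalidArgumentError(
            "group-median correlation needs at least 3 parcellations")
    variables = list(variables)
    rmat = pd.DataFrame(index=variables, columns=parcs, dtype=float)
    pmat = pd.DataFrame(index=variables, columns=parcs, dtype=float)
    rows = []
    for var in variables:
        for parc in parcs:
            sub = table[table[parcellation_column] == parc]
            r, p = sps.pearsonr(sub[var], sub[fit_column])
            rmat.loc[var, parc] = r
            pmat.loc[var, parc] = p
        joint_r, joint_p = sps.pearsonr(table[var], table[fit_column])
        med = table.groupby(parcellation_column)[[var, fit_column]].median()
        gm_r, gm_p = sps.pearsonr(med[var], med[fit_column])
        ind = rmat.loc[var].to_numpy(dtype=float)
        mean_abs = fisher_mean(np.abs(ind))
        sig_frac = float((pmat.loc[var] < alpha).mean())
        aj = abs(joint_r)
        if mean_abs > aj + delta and sig_frac >= min_significant_frac:
            cls = "intra"
        elif aj > mean_abs + delta:
            cls = "inter"
        elif mean_abs >= floor and aj >= floor and abs(mean_abs - aj) <= delta:
            cls = "both"
        else:
            cls = "neither"
        rows.append({"variable": var, "mean_abs_individual_r": mean_abs,
                     "significant_frac": sig_frac, "joint_r": joint_r,
                     "joint_p": joint_p, "group_median_r": gm_r,
                     "group_median_p": gm_p, "class": cls})
    summary = pd.DataFrame(rows).set_index("variable")
    return VariableFitReport(per_parcellation_r=rmat, per_parcellation_p=pmat,
                             summary=summary)


# ---------------------------------------------------------------------------
# multiple linear regression


@dataclass
class MLRResult:
    """OLS of Fit on z-scored data variables."""

    coefficients: pd.Series
    p_values: pd.Series
    r_squared: float
    significant: pd.Series = field(default=None)

    def __post_init__(self):
        if self.significant is None:
            self.significant = self.p_values < ALPHA


def mlr_fit(x: pd.DataFrame, y, zscore: bool = True) -> MLRResult:
    """Ordinary least squares with intercept on (optionally z-scored) columns.

    Columns are standardized with the population SD; exactly collinear
    designs raise an error naming the dependent columns.
    """
    x = pd.DataFrame(x).astype(float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n <= p + 1:
        raise InvalidArgumentError(
            f"need more rows ({n}) than columns + 1 ({p + 1})")
    sds = x.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise InvalidArgumentError(f"constant columns: {bad}")
    xz = (x - x.mean(axis=0)) / sds if zscore else x
    design = np.column_stack([np.ones(n), xz.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        _, s, vt = np.linalg.svd(xz.to_numpy() - xz.to_numpy().mean(0))
        null = vt[s.size - 1] if s[-1] < 1e-10 * s[0] else vt[-1]
        dep = [c for c, comp in zip(x.columns, null) if abs(comp) > 1e-8]
        raise InvalidArgumentError(
            f"rank-deficient design; dependent columns: {dep}")
    model = sm.OLS(y, design).fit()
    names = ["intercept"] + list(x.columns)
    return MLRResult(coefficients=pd.Series(model.params, index=names),
                     p_values=pd.Series(model.pvalues, index=names),
                     r_squared=float(model.rsquared))


# ---------------------------------------------------------------------------
# optimal-parameter distances


def optimal_parameter_distances(optima: dict, tau_scale: float = 94.0,
                                c_scale: float = 0.945) -> pd.DataFrame:
    """Mean per-subject distance between grid-normalized optima.

    ``optima`` maps parcellation -> (n_subjects, 2) array of (tau, C) optima,
    aligned by subject.  Each optimum is normalized to (tau/tau_scale,
    C/c_scale); the Euclidean distance between two parcellations' optima is
    averaged over subjects.  Subjects with a missing (NaN) optimum in either
    parcellation of a pair are excluded with a warning.
    """
    names = list(optima)
    arrays = {k: np.asarray(v, dtype=float) / [tau_scale, c_scale]
              for k, v in optima.items()}
    sizes = {len(a) for a in arrays.values()}
    if len(sizes) != 1:
        raise InvalidArgumentError("optima are not aligned across parcellations")
    k = len(names)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ai, aj = arrays[names[i]], arrays[names[j]]
            ok = np.isfinite(ai).all(axis=1) & np.isfinite(aj).all(axis=1)
            if not ok.all():
                warnings.warn(
                    f"excluding {int((~ok).sum())} subject(s) with missing "
                    f"optima for pair ({names[i]}, {names[j]})")
            if not ok.any():
                raise InvalidArgumentError(
                    f"no subjects with complete optima for pair "
                    f"({names[i]}, {names[j]})")
            d = np.linalg.norm(ai[ok] - aj[ok], axis=1).mean()
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=names, columns=names)
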