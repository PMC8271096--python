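"""Per-subject scalar data variables summarizing the empirical-style data.

Seventeen named indices are computed per subject, parcellation and session
scope: regional BOLD fluctuation statistics, column-wise mean/SD statistics of
the FC and (mean-normalized) SC/path-length matrices, the pairwise
correlations between the three connectivity matrices, and the mean/SD of the
natural frequencies.  Column statistics always exclude the diagonal, so
aver(eFC) is a region's average connectivity to the rest of the brain, and
population standard deviations are used throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .derive import extract_natural_frequencies, matrix_mean
from .exceptions import InvalidArgumentError
from .fitting import upper_tri_similarity
from .synthetic import efc_target_names

VARIABLE_NAMES = [
    "aver[std(BOLD)]", "std[std(BOLD)]",
    "aver[aver(eFC)]", "std[aver(eFC)]", "aver[std(eFC)]", "std[std(eFC)]",
    "corr(eFC,eSC)", "corr(eFC,ePL)", "corr(eSC,ePL)",
    "aver[std(eSC)]", "std[aver(eSC)]", "std[std(eSC)]",
    "aver[std(ePL)]", "std[aver(ePL)]", "std[std(ePL)]",
    "aver(fi)", "std(fi)",
]


def _column_stats(m: np.ndarray):
    """Column-wise mean and population SD excluding the diagonal entry."""
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    mask = ~np.eye(n, dtype=bool)
    means = np.empty(n)
    sds = np.empty(n)
    for j in range(n):
        col = m[mask[:, j], j]
        means[j] = col.mean()
        sds[j] = col.std()
    return means, sds


def _matrix_variables(m: np.ndarray, prefix: str) -> dict:
    means, sds = _column_stats(m)
    return {
        f"aver[aver({prefix})]": float(means.mean()),
        f"std[aver({prefix})]": float(means.std()),
        f"aver[std({prefix})]": float(sds.mean()),
        f"std[std({prefix})]": float(sds.std()),
    }


def compute_data_variables(bundle, frequencies: np.ndarray = None,
                           scope: str = "concatenated") -> dict:
    """All data variables of one bundle at one session scope.

    ``scope`` selects the BOLD/FC session: "session1".."session4" or
    "concatenated".  SC-derived variables are session-independent.  The eSC
    and ePL matrices are normalized by their ensemble mean (the same
    convention as in the model derivation) before the column statistics;
    cross-matrix correlations are unaffected by this by Pearson invariance.
    """
    names = efc_target_names(len(bundle.bold.sessions))
    if scope not in names:
        raise InvalidArgumentError(
            f"scope must be one of {names}, got {scope!r}")
    if frequencies is None:
        frequencies = extract_natural_frequencies(bundle.bold)
    idx = names.index(scope)
    efc = bundle.efc_list[idx]
    if scope == "concatenated":
        bold = bundle.bold.concatenated
    else:
        bold = bundle.bold.sessions[idx]
    esc = np.asarray(bundle.connectome.counts, dtype=float)
    epl = np.asarray(bundle.connectome.lengths, dtype=float)
    esc_n = esc / matrix_mean(esc)
    epl_n = epl / matrix_mean(epl)

    bold_sd = bold.std(axis=0)
    out = {
        "aver[std(BOLD)]": float(bold_sd.mean()),
        "std[std(BOLD)]": float(bold_sd.std()),
    }
    efc_stats = _matrix_variables(efc, "eFC")
    out.update(efc_stats)
    out["corr(eFC,eSC)"] = upper_tri_similarity(efc, esc)
    out["corr(eFC,ePL)"] = upper_tri_similarity(efc, epl)
    out["corr(eSC,ePL)"] = upper_tri_similarity(esc, epl)
    esc_stats = _matrix_variables(esc_n, "eSC")
    epl_stats = _matrix_variables(epl_n, "ePL")
    for key in ("aver[std(eSC)]", "std[aver(eSC)]", "std[std(eSC)]"):
        out[key] = esc_stats[key]
    for key in ("aver[std(ePL)]", "std[aver(ePL)]", "std[std(ePL)]"):
        out[key] = epl_stats[key]
    out["aver(fi)"] = float(np.mean(frequencies))
    out["std(fi)"] = float(np.std(frequencies))
    return {name: out[name] for name in VARIABLE_NAMES}


def cohort_variable_table(bundles, scopes=("concatenated",)) -> pd.DataFrame:
    """Data-variable table over a cohort: one row per (subject, level, scope).

    Natural frequencies are extracted per bundle from its own BOLD.  Rows are
    sorted by (subject, parcellation, scope), so the table does not depend on
    the input ordering of the bundles.
    """
    rows = []
    for bundle in bundles:
        freqs = extract_natural_frequencies(bundle.bold)
        for scope in scopes:
            try:
                row = compute_data_variables(bundle, freqs, scope)
            except Exception as exc:
                raise type(exc)(
                    f"subject {bundle.subject_id} at level "
                    f"{bundle.parcellation.level_id}: {exc}") from exc
            rows.append({"subject": bundle.subject_id,
                         "parcellation": bundle.parcellation.level_id,
                         "scope": scope, **row})
    df = pd.DataFrame(rows)
    return df.sort_values(["subject", "parcellation", "scope"],
                          kind="stable").reset_index(drop=True)
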