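"""Text-format persistence: TSV matrices, subject bundles, parcellations.

All artifacts are plain text (tab-delimited tables plus JSON sidecars) so a
run can be inspected and diffed.  Matrices are written with 17 significant
digits, which round-trips IEEE double precision exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .exceptions import FormatError
from .synthetic import (BoldDataset, Parcellation, StructuralConnectome,
                        SubjectBundle)

_FMT = "%.17g"


def write_matrix(matrix: np.ndarray, path, labels=None) -> None:
    """Square numeric matrix as TSV with one header row of region labels."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise FormatError("matrix must be 2-d")
    n_cols = matrix.shape[1]
    labels = labels or [f"r{i}" for i in range(n_cols)]
    if len(labels) != n_cols:
        raise FormatError(
            f"{len(labels)} labels for {n_cols} columns")
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in matrix:
            fh.write("\t".join(_FMT % v for v in row) + "\n")


def read_table(path, square: bool = False):
    """Read a TSV table with a header row; returns (values, labels)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    labels = lines[0].split("\t")
    n_cols = len(labels)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise FormatError(
                f"{path}:{lineno}: expected {n_cols} columns, "
                f"got {len(parts)}")
        try:
            rows.append([float(v) for v in parts])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value "
                              f"({exc})") from exc
    values = np.array(rows, dtype=float)
    if square and values.shape[0] != n_cols:
        raise FormatError(
            f"{path}: expected square matrix, got "
            f"{values.shape[0]} rows x {n_cols} columns")
    return values, labels


def read_matrix(path):
    """Square matrix and its labels from a TSV written by write_matrix."""
    return read_table(path, square=True)


def save_parcellation_hierarchy(levels, path) -> None:
    payload = {"levels": [{
        "level_id": p.level_id,
        "region_sizes": np.asarray(p.region_sizes).tolist(),
        "centroids": np.asarray(p.centroids).tolist(),
        "parent_map": np.asarray(p.parent_map).tolist(),
    } for p in levels]}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_parcellation_hierarchy(path):
    payload = json.loads(Path(path).read_text())
    levels = []
    for entry in payload["levels"]:
        parc = Parcellation(
            level_id=entry["level_id"],
            region_sizes=np.asarray(entry["region_sizes"], dtype=np.int64),
            centroids=np.asarray(entry["centroids"], dtype=float),
            parent_map=np.asarray(entry["parent_map"], dtype=np.int64))
        parc.validate()
        levels.append(parc)
    return levels


def save_bundle(bundle: SubjectBundle, directory) -> None:
    """One directory per subject/level: esc.tsv, epl.tsv, BOLD TSVs, meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = bundle.parcellation.region_labels
    write_matrix(bundle.connectome.counts, directory / "esc.tsv", labels)
    write_matrix(bundle.connectome.lengths, directory / "epl.tsv", labels)
    for i, session in enumerate(bundle.bold.sessions, start=1):
        write_matrix(session, directory / f"bold_session{i}.tsv", labels)
    meta = {"subject_id": bundle.subject_id,
            "tr": bundle.bold.tr,
            "n_sessions": len(bundle.bold.sessions),
            "level_id": bundle.parcellation.level_id,
            "ground_truth": bundle.ground_truth}
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def load_bundle(directory, parcellation: Parcellation) -> SubjectBundle:
    """Rebuild a SubjectBundle from its directory; FC matrices are recomputed."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    if meta["level_id"] != parcellation.level_id:
        raise FormatError(
            f"{directory}: bundle level {meta['level_id']} does not match "
            f"parcellation {parcellation.level_id}")
    counts, labels = read_matrix(directory / "esc.tsv")
    lengths, lab2 = read_matrix(directory / "epl.tsv")
    if labels != lab2:
        raise FormatError(f"{directory}: esc/epl label mismatch")
    sessions = []
    for i in range(1, meta["n_sessions"] + 1):
        x, lab = read_table(directory / f"bold_session{i}.tsv")
        if lab != labels:
            raise FormatError(
                f"{directory}: bold_session{i} label mismatch")
        sessions.append(x)
    return SubjectBundle(
        subject_id=meta["subject_id"], parcellation=parcellation,
        connectome=StructuralConnectome(counts=counts, lengths=lengths),
        bold=BoldDataset(sessions=sessions, tr=meta["tr"]),
        ground_truth=meta.get("ground_truth"))
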