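"""Read-table I/O, technical-replicate filters, and non-detection tabulation.

A read table is a long-format count table keyed by
(sample_id, replicate_id, species_id) with a non-negative ``reads`` column;
technical replicates are independent PCRs of the same DNA extract.  Two
filters flag uninformative replicates: sequencing depth below a threshold
(default 30,000 reads), and high mean Bray-Curtis dissimilarity to sister
replicates of the same sample (default > 0.7, computed on depth-normalized
relative abundances).  Non-detections are tallied within samples: a species
counts as non-detected in a replicate only when a sister replicate of the
same sample did detect it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import distance as _ssd

from .errors import InvalidParameterError, TableValidationError

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_read_table",
    "read_read_table",
    "write_read_table",
    "replicate_depths",
    "bray_curtis",
    "filter_replicates",
    "tabulate_nondetections",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["sample_id", "replicate_id", "species_id", "reads"]
DEFAULT_MIN_DEPTH = 30_000
DEFAULT_MAX_DISSIMILARITY = 0.7


def validate_read_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, non-negative counts and unique keys; return a copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TableValidationError(f"missing required columns: {missing}")
    table = table[REQUIRED_COLUMNS].copy()
    reads = pd.to_numeric(table["reads"], errors="coerce")
    bad = table.index[reads.isna() | (reads < 0) | (reads % 1 != 0)]
    if len(bad):
        raise TableValidationError(
            f"reads must be non-negative integers; offending rows: {list(bad[:10])}"
        )
    table["reads"] = reads.astype(np.int64)
    keys = ["sample_id", "replicate_id", "species_id"]
    dup = table.index[table.duplicated(keys, keep=False)]
    if len(dup):
        raise TableValidationError(
            f"duplicate (sample, replicate, species) keys; offending rows: {list(dup[:10])}"
        )
    return table


def read_read_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV read table; the delimiter is auto-detected unless given.

    ``dialect`` may be an explicit delimiter (``","`` or ``"\\t"``).
    """
    sep = dialect if dialect is not None else None
    table = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return validate_read_table(table)


def write_read_table(table: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a validated read table in canonical key order (round-trip stable)."""
    table = validate_read_table(table)
    table = table.sort_values(["sample_id", "replicate_id", "species_id"],
                              ignore_index=True)
    table.to_csv(path, sep=sep, index=False)


def replicate_depths(table: pd.DataFrame) -> pd.Series:
    """Total reads per (sample_id, replicate_id)."""
    return table.groupby(["sample_id", "replicate_id"])["reads"].sum()


def bray_curtis(u, v, relative: bool = True) -> float:
    """Bray-Curtis dissimilarity between two community count vectors.

    1 - 2*sum(min(u, v)) / (sum(u) + sum(v)); 0 for identical communities,
    1 for disjoint ones.  By default vectors are depth-normalized first, so
    the comparison reflects composition rather than sequencing effort.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InvalidParameterError("vectors must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise InvalidParameterError("counts must be non-negative")
    su, sv = u.sum(), v.sum()
    if su == 0 and sv == 0:
        raise InvalidParameterError("Bray-Curtis undefined for two all-zero vectors")
    if relative:
        u = u / su if su > 0 else u
        v = v / sv if sv > 0 else v
    return float(_ssd.braycurtis(u, v))


def _dissimilarity_to_sisters(mat: pd.DataFrame, relative: bool) -> pd.Series:
    """Mean pairwise Bray-Curtis of each replicate to its sisters.

    ``mat`` is a (replicate x species) count matrix for one sample, species
    zero-filled over the union of sisters' species.
    """
    reps = mat.index
    vals = {}
    for r in reps:
        others = [o for o in reps if o != r]
        vals[r] = float(np.mean([
            bray_curtis(mat.loc[r], mat.loc[o], relative=relative) for o in others
        ]))
    return pd.Series(vals)


def filter_replicates(
    table: pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_dissimilarity: float = DEFAULT_MAX_DISSIMILARITY,
    relative: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove shallow and outlier technical replicates.

    Depth is filtered first (strictly below ``min_depth`` is removed); the
    dissimilarity rule then compares each depth-passing replicate with its
    depth-passing sisters (mean pairwise Bray-Curtis strictly above
    ``max_dissimilarity`` is removed).  Samples left with a single replicate
    skip the dissimilarity rule.  Returns the retained table and a removal
    log with columns sample_id, replicate_id, rule, value.
    """
    table = validate_read_table(table)
    depths = replicate_depths(table)
    log_rows = []

    shallow = depths[depths < min_depth]
    for (s, r), d in shallow.items():
        log_rows.append({"sample_id": s, "replicate_id": r,
                         "rule": "depth", "value": float(d)})
    kept_keys = set(depths[depths >= min_depth].index)

    kept = table[[
        (s, r) in kept_keys
        for s, r in zip(table["sample_id"], table["replicate_id"])
    ]]

    for sample, sub in kept.groupby("sample_id"):
        mat = sub.pivot_table(index="replicate_id", columns="species_id",
                              values="reads", aggfunc="sum", fill_value=0)
        if len(mat) < 2:
            logger.info("sample %s has a single replicate; dissimilarity rule skipped",
                        sample)
            continue
        diss = _dissimilarity_to_sisters(mat, relative=relative)
        for rep, d in diss[diss > max_dissimilarity].items():
            log_rows.append({"sample_id": sample, "replicate_id": rep,
                             "rule": "dissimilarity", "value": float(d)})
            kept_keys.discard((sample, rep))

    retained = table[[
        (s, r) in kept_keys
        for s, r in zip(table["sample_id"], table["replicate_id"])
    ]].reset_index(drop=True)
    removal_log = pd.DataFrame(
        log_rows, columns=["sample_id", "replicate_id", "rule", "value"]
    )
    return retained, removal_log


def tabulate_nondetections(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species non-detection summary from within-sample replicate contrasts.

    For each sample with >= 2 technical replicates and each species detected
    in at least one of them, every replicate of that sample contributes one
    Bernoulli trial: non-detection if the species has zero reads there.
    Species absent from all replicates of a sample contribute nothing for
    that sample (an all-zero species is indistinguishable from a true
    absence).  Returns columns species_id, n_replicates, n_detections,
    n_nondetections, nondetection_rate.
    """
    table = validate_read_table(table)
    rep_counts = table.groupby("sample_id")["replicate_id"].nunique()
    multi = rep_counts[rep_counts >= 2].index
    if len(multi) == 0:
        import warnings

        warnings.warn("no sample has >= 2 technical replicates; nothing to tabulate",
                      stacklevel=2)
        return pd.DataFrame(columns=["species_id", "n_replicates", "n_detections",
                                     "n_nondetections", "nondetection_rate"])

    rows: dict[str, dict[str, int]] = {}
    for sample in multi:
        sub = table[table["sample_id"] == sample]
        mat = sub.pivot_table(index="replicate_id", columns="species_id",
                              values="reads", aggfunc="sum", fill_value=0)
        n_reps = len(mat)
        detected = mat.columns[(mat > 0).any(axis=0)]
        for sp in detected:
            entry = rows.setdefault(str(sp), {"n_replicates": 0, "n_detections": 0,
                                              "n_nondetections": 0})
            nz = int((mat[sp] > 0).sum())
            entry["n_replicates"] += n_reps
            entry["n_detections"] += nz
            entry["n_nondetections"] += n_reps - nz

    out = pd.DataFrame(
        [{"species_id": sp, **v} for sp, v in sorted(rows.items())]
    )
    out["nondetection_rate"] = out["n_nondetections"] / out["n_replicates"]
    return out
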