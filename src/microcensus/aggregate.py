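"""Per-environment novelty-bin fractions.

Two weighting modes:

* **count** — each retained sequence counts once:
  ``fraction(bin) = n(bin) / n(total)`` within each group.
* **depth_weighted** — within each metagenome (sample), bins are weighted
  by summed scaffold read depth (a proxy for cell abundance), then the
  per-metagenome fractions are averaged *unweighted* across the
  metagenomes of an environment. This mean-of-fractions semantics gives
  every metagenome equal say regardless of how many 16S genes it
  contributed, and differs from pooling counts when metagenome sizes
  differ.

Metatranscriptomes carry no scaffold depths and always use count mode.

Observations are rows of a DataFrame with at least ``environment``,
``sample_id``, ``bin`` and (for depth weighting) ``read_depth`` columns;
grouping keys can be extended (e.g. ``["environment", "domain"]``) to keep
bacteria and archaea separate, or reduced to merge them.
"""

from __future__ import annotations

import pandas as pd

from .classify import BIN_LABELS
from .errors import DataError

PROFILE_COLUMNS = ["weighting", "bin", "fraction", "n_sequences", "n_samples"]


def _check_bins(obs: pd.DataFrame) -> None:
    if "bin" not in obs.columns:
        raise DataError("observations need a 'bin' column")
    bad = set(obs["bin"]) - set(BIN_LABELS)
    if bad:
        raise DataError(f"unknown bin labels: {sorted(bad)}")


def _bin_counts(group: pd.DataFrame, weights=None) -> pd.Series:
    if weights is None:
        counts = group["bin"].value_counts()
    else:
        counts = group.groupby("bin", observed=True)[weights].sum()
    return counts.reindex(BIN_LABELS, fill_value=0.0).astype(float)


def count_fractions(observations: pd.DataFrame, by=("environment",)) -> pd.DataFrame:
    """Sequence-count fractions per novelty bin within each group.

    Returns a long table: one row per (group, bin) with columns
    ``fraction``, ``n_sequences`` and ``n_samples``; fractions within a
    group sum to 1. Empty groups are omitted.
    """
    by = list(by)
    _check_bins(observations)
    rows = []
    for keys, group in observations.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        counts = _bin_counts(group)
        total = counts.sum()
        n_samples = group["sample_id"].nunique() if "sample_id" in group else 1
        for bin_label, c in counts.items():
            rows.append((*keys, "count", bin_label, c / total,
                         int(total), int(n_samples)))
    return pd.DataFrame(rows, columns=by + PROFILE_COLUMNS)


def depth_weighted_fractions(observations: pd.DataFrame, by=("environment",)) -> pd.DataFrame:
    """Read-depth-weighted fractions, averaged over metagenomes per group.

    Per metagenome ``m``: ``f_m(bin) = sum(depth | bin) / sum(depth)``;
    per group: the unweighted arithmetic mean of ``f_m`` over its
    metagenomes. Missing or non-positive depths, or a metagenome with zero
    total depth, raise ``DataError``.
    """
    by = list(by)
    _check_bins(observations)
    if "read_depth" not in observations.columns:
        raise DataError("observations need a 'read_depth' column for depth weighting")
    if "sample_id" not in observations.columns:
        raise DataError("observations need a 'sample_id' column for depth weighting")
    depth = observations["read_depth"]
    if depth.isna().any():
        raise DataError("read_depth missing for some observations")
    if (depth <= 0).any():
        raise DataError("read_depth must be positive")
    rows = []
    for keys, group in observations.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        per_sample = []
        for sid, sample in group.groupby("sample_id", sort=True):
            counts = _bin_counts(sample, weights="read_depth")
            total = counts.sum()
            if total <= 0:
                raise DataError(f"zero total read depth in metagenome {sid!r}")
            per_sample.append(counts / total)
        mean = pd.concat(per_sample, axis=1).mean(axis=1)
        for bin_label, f in mean.items():
            rows.append((*keys, "depth_weighted", bin_label, float(f),
                         int(len(group)), len(per_sample)))
    return pd.DataFrame(rows, columns=by + PROFILE_COLUMNS)


def profile_fractions(profiles: pd.DataFrame, **keys) -> dict[str, float]:
    """Extract one group's ``{bin label: fraction}`` map from a profile table."""
    sel = profiles
    for col, val in keys.items():
        sel = sel[sel[col] == val]
    if sel.empty:
        raise DataError(f"no profile rows match {keys!r}")
    return dict(zip(sel["bin"], sel["fraction"]))
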