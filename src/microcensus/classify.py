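"""Novelty-bin assignment from percent identity to the nearest cultured relative.

A query 16S rRNA gene sequence is placed on a three-level novelty ladder from
its percent identity to the single most similar cultured isolate:

* ``CULTURED_SPECIES_TO_GENUS`` — identity strictly above the genus cutoff
  (default 96.6%): the organism belongs to a cultured genus, possibly a
  cultured species.
* ``UNCULTURED_GENUS_TO_CLASS`` — identity between the phylum cutoff
  (inclusive, default 86%) and the genus cutoff (inclusive): a novel genus,
  family, order or class within a phylum that has cultured members.
* ``UNCULTURED_PHYLUM_PLUS`` — identity strictly below the phylum cutoff:
  phylum-level novelty or deeper.

The default cutoffs are the upper 95% confidence bounds of the median within-
rank 16S identity for genus and phylum. Boundary semantics are deliberately
asymmetric — "more than 96.6%" is strict, "at least 86%" is inclusive — so
96.6 and 86.0 both fall in the middle bin.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)

DEFAULT_GENUS_CUTOFF = 96.6
DEFAULT_PHYLUM_CUTOFF = 86.0


class NoveltyBin(enum.IntEnum):
    """Three-level novelty category; larger values are more novel."""

    CULTURED_SPECIES_TO_GENUS = 0
    UNCULTURED_GENUS_TO_CLASS = 1
    UNCULTURED_PHYLUM_PLUS = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "NoveltyBin":
        return cls[label.upper()]


#: Canonical bin ordering for tabular output.
BIN_ORDER = tuple(NoveltyBin)
BIN_LABELS = tuple(b.label for b in BIN_ORDER)


@dataclass(frozen=True)
class CutoffLadder:
    """Identity cutoffs delimiting novelty levels.

    ``genus_cutoff`` and ``phylum_cutoff`` define the normative three-bin
    ladder. ``intermediate`` optionally carries a full rank ladder (finest
    first, e.g. ``{"species": 98.7, "genus": 96.6, ..., "phylum": 86.0}``)
    used by :func:`assign_level`; no default intermediate values ship with
    the package because they are study-specific.
    """

    genus_cutoff: float = DEFAULT_GENUS_CUTOFF
    phylum_cutoff: float = DEFAULT_PHYLUM_CUTOFF
    intermediate: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if not (0.0 < self.phylum_cutoff < self.genus_cutoff <= 100.0):
            raise ParameterError(
                "cutoffs must satisfy 0 < phylum_cutoff < genus_cutoff <= 100, "
                f"got phylum={self.phylum_cutoff}, genus={self.genus_cutoff}"
            )
        if self.intermediate is not None:
            vals = list(self.intermediate.values())
            if any(b >= a for a, b in zip(vals, vals[1:])):
                raise ParameterError(
                    "intermediate cutoffs must strictly decrease with rank breadth"
                )


def assign_bin(identity: float, cutoffs: CutoffLadder | None = None) -> NoveltyBin:
    """Map a percent identity to its novelty bin.

    Raises
    ------
    ParameterError
        If ``identity`` is outside [0, 100] or not finite.
    """
    cutoffs = cutoffs or CutoffLadder()
    if not np.isfinite(identity) or not (0.0 <= identity <= 100.0):
        raise ParameterError(f"identity must be in [0, 100], got {identity!r}")
    if identity > cutoffs.genus_cutoff:
        return NoveltyBin.CULTURED_SPECIES_TO_GENUS
    if identity >= cutoffs.phylum_cutoff:
        return NoveltyBin.UNCULTURED_GENUS_TO_CLASS
    return NoveltyBin.UNCULTURED_PHYLUM_PLUS


def assign_bin_series(identities, cutoffs: CutoffLadder | None = None) -> pd.Series:
    """Vectorised :func:`assign_bin` returning a Series of bin labels."""
    cutoffs = cutoffs or CutoffLadder()
    ident = np.asarray(identities, dtype=float)
    if ident.size and (not np.all(np.isfinite(ident)) or ident.min() < 0 or ident.max() > 100):
        raise ParameterError("identities must all be finite and in [0, 100]")
    out = np.full(ident.shape, NoveltyBin.UNCULTURED_PHYLUM_PLUS.label, dtype=object)
    out[ident >= cutoffs.phylum_cutoff] = NoveltyBin.UNCULTURED_GENUS_TO_CLASS.label
    out[ident > cutoffs.genus_cutoff] = NoveltyBin.CULTURED_SPECIES_TO_GENUS.label
    index = identities.index if isinstance(identities, pd.Series) else None
    return pd.Series(out, index=index, name="bin")


def assign_level(identity: float, cutoffs: CutoffLadder | None = None) -> str:
    """Return the finest taxonomic level at which the query can be placed.

    Scans the configured rank ladder from finest to broadest and returns the
    first level whose cutoff the identity meets; below the broadest cutoff
    the label is ``"above_phylum"``. Comparison is strict (``>``) at every
    level except the broadest, which is inclusive (``>=``), matching the
    asymmetric boundary semantics of the three-bin ladder.

    Falls back to the three-bin assignment (with a logged notice) when no
    intermediate ladder is configured.
    """
    cutoffs = cutoffs or CutoffLadder()
    if not np.isfinite(identity) or not (0.0 <= identity <= 100.0):
        raise ParameterError(f"identity must be in [0, 100], got {identity!r}")
    ladder = cutoffs.intermediate
    if not ladder:
        logger.info("no intermediate cutoff ladder configured; using 3-bin assignment")
        return assign_bin(identity, cutoffs).label
    levels = list(ladder.items())
    for i, (level, cutoff) in enumerate(levels):
        last = i == len(levels) - 1
        if (identity >= cutoff) if last else (identity > cutoff):
            return level
    return "above_phylum"


def identity_histogram(
    identities,
    bin_width: float = 1.0,
    cutoffs: CutoffLadder | None = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Histogram of percent identities plus mass per novelty bin.

    Identity values are grouped into left-closed intervals of ``bin_width``
    labelled by their left edge (100 maps onto its own edge, so a value of
    exactly 100 is labelled 100). Returns ``(counts, novelty_fractions)``;
    counts conserve ``len(identities)`` and the fractions sum to 1 for
    nonempty input.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    cutoffs = cutoffs or CutoffLadder()
    ident = np.asarray(list(identities), dtype=float)
    if ident.size == 0:
        return pd.Series(dtype=int), {}
    edges = np.floor(ident / bin_width).astype(int) * bin_width
    counts = pd.Series(edges).value_counts().sort_index()
    counts.index.name = "identity_bin"
    bins = assign_bin_series(ident, cutoffs)
    frac = bins.value_counts(normalize=True)
    fractions = {label: float(frac.get(label, 0.0)) for label in BIN_LABELS}
    return counts, fractions
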