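"""Global microbial cell census by novelty bin.

Multiplying literature estimates of total microbial cells per environment
(units of 1e26 cells) by the environment's novelty-bin fractions gives the
number of cells per bin; summing over environments gives the global census
and its headline shares (e.g. the percentage of cells on Earth from
uncultured genera or higher).

The default conversion assumes a single 16S rRNA gene copy per genome — a
conservative simplification, since completed genomes average 3.8 copies
(bacteria) and 1.8 copies (archaea) and dividing by the smaller archaeal
number would only increase the estimated share of the (archaea-enriched)
uncultured bins. A ``domain_means`` mode applies those per-domain copy
numbers to domain-resolved fractions instead.

Percentages are rounded to integers (half away from zero); headline cell
counts are reported to 2 significant figures in units of cells.

The module ships three text fixtures: the literature cell totals per
environment, and two reference census tables (metagenome-based and
metatranscriptome-based global estimates) whose per-bin cell counts
regenerate every published percentage. Cell counts in rows whose printed
values were rounded to one decimal are stored at the precision implied by
the published percentages (see ``data/``).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify import BIN_LABELS, NoveltyBin
from .errors import DataError, ParameterError
from .util import round_half_away, round_sigfig

_DATA = importlib.resources.files("microcensus") / "data"

CELLS_COLUMNS = [f"cells_{label}" for label in BIN_LABELS]


@dataclass(frozen=True)
class CopyNumberModel:
    """16S rRNA gene copies per genome used to convert gene to cell fractions."""

    mode: str = "single_copy"  # or "domain_means"
    bacteria_copies: float = 3.8
    archaea_copies: float = 1.8

    def __post_init__(self) -> None:
        if self.mode not in ("single_copy", "domain_means"):
            raise ParameterError(f"unknown copy-number mode {self.mode!r}")
        if min(self.bacteria_copies, self.archaea_copies) < 1:
            raise ParameterError("copies per genome must be >= 1")

    def copies(self, domain: str) -> float:
        return {"bacteria": self.bacteria_copies, "archaea": self.archaea_copies}[domain]


@dataclass
class CellCensusRow:
    """One environment's cells per novelty bin (units of 1e26 cells)."""

    environment: str
    total_1e26: float
    cells: dict[str, float]

    @property
    def row_total(self) -> float:
        return float(sum(self.cells.values()))

    @property
    def percentages(self) -> dict[str, int]:
        denom = self.row_total
        if denom == 0:
            return {label: 0 for label in BIN_LABELS}
        return {label: round_half_away(100.0 * self.cells[label] / denom)
                for label in BIN_LABELS}


@dataclass
class GlobalCensus:
    """Environment rows, their column sums, and headline shares."""

    rows: list[CellCensusRow]
    totals: dict[str, float] = field(init=False)
    grand_total: float = field(init=False)

    def __post_init__(self) -> None:
        self.totals = {
            label: float(sum(r.cells[label] for r in self.rows))
            for label in BIN_LABELS
        }
        self.grand_total = float(sum(self.totals.values()))

    @property
    def percentages(self) -> dict[str, int]:
        return {label: round_half_away(100.0 * c / self.grand_total)
                for label, c in self.totals.items()}

    @property
    def headline(self) -> dict[str, float]:
        """Aggregate shares in percent and cell counts in units of cells."""
        unc = (self.totals[NoveltyBin.UNCULTURED_GENUS_TO_CLASS.label]
               + self.totals[NoveltyBin.UNCULTURED_PHYLUM_PLUS.label])
        phyla = self.totals[NoveltyBin.UNCULTURED_PHYLUM_PLUS.label]
        cult = self.totals[NoveltyBin.CULTURED_SPECIES_TO_GENUS.label]
        return {
            "uncultured_pct": round_half_away(100.0 * unc / self.grand_total),
            "uncultured_cells": round_sigfig(unc * 1e26, 2),
            "uncultured_phyla_pct": round_half_away(100.0 * phyla / self.grand_total),
            "uncultured_phyla_cells": round_sigfig(phyla * 1e26, 2),
            "cultured_pct": round_half_away(100.0 * cult / self.grand_total),
            "genera_to_classes_pct": round_half_away(
                100.0 * self.totals[NoveltyBin.UNCULTURED_GENUS_TO_CLASS.label]
                / self.grand_total),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rows:
            pct = r.percentages
            rows.append([r.environment, r.total_1e26,
                         *(r.cells[label] for label in BIN_LABELS),
                         *(pct[label] for label in BIN_LABELS)])
        pct = self.percentages
        rows.append(["total", self.grand_total,
                     *(self.totals[label] for label in BIN_LABELS),
                     *(pct[label] for label in BIN_LABELS)])
        return pd.DataFrame(
            rows,
            columns=["environment", "total_1e26", *CELLS_COLUMNS,
                     *(f"pct_{label}" for label in BIN_LABELS)],
        )

    def headline_json(self) -> str:
        return json.dumps(self.headline, indent=2, sort_keys=True)


def extrapolate_environment(
    total_cells: float,
    fractions,
    copy_model: CopyNumberModel | None = None,
    environment: str = "",
) -> CellCensusRow:
    """Convert one environment's bin fractions into cell counts.

    ``fractions`` maps bin labels to fractions summing to 1 (single-copy
    mode), or ``(domain, bin label)`` tuples to fractions (domain_means
    mode, which divides each domain's gene fraction by its copies per
    genome and renormalizes before multiplying by ``total_cells``).
    """
    copy_model = copy_model or CopyNumberModel()
    if total_cells < 0:
        raise ParameterError("total_cells must be >= 0")
    items = dict(fractions)
    total_frac = sum(items.values())
    if abs(total_frac - 1.0) > 1e-6:
        raise ParameterError(f"fractions must sum to 1, got {total_frac}")
    domain_resolved = all(isinstance(k, tuple) and len(k) == 2 for k in items)
    if copy_model.mode == "domain_means":
        if not domain_resolved:
            raise ParameterError(
                "domain_means mode needs (domain, bin) resolved fractions; "
                "combined fractions cannot be split without guessing"
            )
        weights = {k: f / copy_model.copies(k[0]) for k, f in items.items()}
        norm = sum(weights.values())
        items = {k: w / norm for k, w in weights.items()}
    if domain_resolved:
        combined = {label: 0.0 for label in BIN_LABELS}
        for (_, label), f in items.items():
            combined[label] += f
        items = combined
    cells = {label: total_cells * items.get(label, 0.0) for label in BIN_LABELS}
    return CellCensusRow(environment=environment, total_1e26=total_cells, cells=cells)


def summarize_global(rows: list[CellCensusRow]) -> GlobalCensus:
    """Column-sum environment rows into the global census with headlines."""
    if not rows:
        raise ParameterError("need at least one census row")
    return GlobalCensus(rows=list(rows))


def load_cell_totals(path=None) -> pd.DataFrame:
    """Load per-environment total cell counts (units 1e26) with sources.

    Defaults to the packaged literature table. Duplicate environments or
    negative totals raise ``DataError``.
    """
    src = Path(path) if path is not None else _DATA / "cell_totals.tsv"
    df = pd.read_csv(src, sep="\t")
    _validate_cell_totals(df)
    return df


def _validate_cell_totals(df: pd.DataFrame) -> None:
    for col in ("environment", "total_1e26"):
        if col not in df.columns:
            raise DataError(f"cell totals table missing column {col!r}")
    if df.empty:
        raise DataError("cell totals table is empty")
    if df["environment"].duplicated().any():
        raise DataError("duplicate environment in cell totals")
    if (df["total_1e26"].astype(float) < 0).any():
        raise DataError("negative cell total")


def write_cell_totals(df: pd.DataFrame, path) -> None:
    _validate_cell_totals(df)
    df.to_csv(path, sep="\t", index=False)


def load_census_fixture(which: str = "metagenome") -> list[CellCensusRow]:
    """Load a packaged reference census table as environment rows.

    ``which`` is ``"metagenome"`` (depth-weighted, 7 environments) or
    ``"metatranscriptome"`` (count-based, 6 environments).
    """
    name = {"metagenome": "census_metagenome.tsv",
            "metatranscriptome": "census_metatranscriptome.tsv"}.get(which)
    if name is None:
        raise ParameterError(f"unknown census fixture {which!r}")
    df = pd.read_csv(_DATA / name, sep="\t")
    rows = []
    for _, rec in df.iterrows():
        cells = {label: float(rec[f"cells_{label}"]) for label in BIN_LABELS}
        rows.append(CellCensusRow(environment=rec["environment"],
                                  total_1e26=float(rec["total_1e26"]),
                                  cells=cells))
    return rows


def census_from_profiles(
    profiles: pd.DataFrame,
    cell_totals: pd.DataFrame,
    copy_model: CopyNumberModel | None = None,
) -> GlobalCensus:
    """Build a global census from an aggregated profile table.

    ``profiles`` must contain one fraction per (environment, bin); only
    environments present in both tables contribute rows.
    """
    copy_model = copy_model or CopyNumberModel()
    totals = dict(zip(cell_totals["environment"], cell_totals["total_1e26"].astype(float)))
    rows = []
    for env, group in profiles.groupby("environment", sort=True):
        if env not in totals:
            continue
        fractions = dict(zip(group["bin"], group["fraction"]))
        if len(fractions) != len(group):
            raise DataError(f"multiple profile rows per bin for {env!r}; "
                            "filter to one weighting/domain first")
        rows.append(extrapolate_environment(totals[env], fractions,
                                            copy_model, environment=env))
    if not rows:
        raise DataError("no overlapping environments between profiles and cell totals")
    return summarize_global(rows)
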