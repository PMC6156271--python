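"""Sequence retention rules for the novelty census.

Five rules are applied in a fixed order, and each record receives exactly
one outcome (the first rule that removes it, else ``retained``):

1. **Minimum length** — primer-amplified (amplicon) sequences must exceed
   900 bp (archaea) or 1,200 bp (bacteria); 16S genes called from
   metagenome or metatranscriptome assemblies must exceed 900 bp. Strict
   inequalities.
2. **No hit** — queries with no database hit are dropped from all further
   denominators.
3. **Short alignment** — top-hit query alignments under 300 bp behave like
   partial hits to small conserved regions (identity inflates as alignment
   length shrinks) and are removed; exactly 300 bp is retained.
4. **Chimera screen** — a record is chimeric iff its alignment spans <90%
   of the query against the best cultured hit AND <90% against the best
   environmental-database hit. Coverage >= 90% to either database retains
   the record.
5. **Non-target taxa** — chloroplast, mitochondrial and eukaryotic
   sequences are removed by taxonomy-string rank match; records without a
   taxonomy pass with a warning.

The retained set is order-independent; the order matters only for which
rule a doubly-failing record is attributed to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

RETAINED = "retained"
REMOVED_LENGTH = "removed_length"
REMOVED_NO_HIT = "removed_no_hit"
REMOVED_SHORT_ALIGNMENT = "removed_short_alignment"
REMOVED_CHIMERA = "removed_chimera"
REMOVED_NONTARGET = "removed_nontarget"

OUTCOMES = (RETAINED, REMOVED_LENGTH, REMOVED_NO_HIT,
            REMOVED_SHORT_ALIGNMENT, REMOVED_CHIMERA, REMOVED_NONTARGET)

_AMPLICON = "amplicon"
_GENE_TYPES = ("metagenome", "metatranscriptome")
_NONTARGET_RANKS = frozenset({"chloroplast", "mitochondria", "eukaryota"})


@dataclass(frozen=True)
class QCThresholds:
    """Retention thresholds (bp and fractions); all inequalities strict."""

    min_len_amplicon_archaea: int = 900
    min_len_amplicon_bacteria: int = 1200
    min_len_gene: int = 900
    min_query_alignment: int = 300
    chimera_alignment_fraction: float = 0.90

    def __post_init__(self) -> None:
        if min(self.min_len_amplicon_archaea, self.min_len_amplicon_bacteria,
               self.min_len_gene, self.min_query_alignment) <= 0:
            raise DataError("length thresholds must be positive")
        if not (0.0 < self.chimera_alignment_fraction <= 1.0):
            raise DataError("chimera_alignment_fraction must be in (0, 1]")


@dataclass
class QCReport:
    """Per-query outcomes plus per-rule removal fractions.

    ``table`` is indexed by query_id with columns ``outcome`` and
    ``rule_value`` (the quantity the removing rule acted on, as a string).
    Rules mark only currently retained records, so outcomes are exclusive
    and counts conserve.
    """

    table: pd.DataFrame
    rules_applied: list[str] = field(default_factory=list)

    @classmethod
    def fresh(cls, query_ids) -> "QCReport":
        table = pd.DataFrame(
            {"outcome": RETAINED, "rule_value": ""},
            index=pd.Index(query_ids, name="query_id"),
        )
        return cls(table=table)

    @property
    def retained_ids(self) -> pd.Index:
        return self.table.index[self.table["outcome"] == RETAINED]

    def mark(self, query_ids, outcome: str, values=None) -> None:
        assert outcome in OUTCOMES
        ids = pd.Index(query_ids)
        still = (self.table.loc[ids, "outcome"] == RETAINED).to_numpy()
        keep = ids[still]
        self.table.loc[keep, "outcome"] = outcome
        if values is not None:
            vals = pd.Series(list(values), index=ids)
            self.table.loc[keep, "rule_value"] = vals.loc[keep].astype(str)

    def removal_fractions(self) -> dict[str, float]:
        n = len(self.table)
        counts = self.table["outcome"].value_counts()
        return {out: float(counts.get(out, 0)) / n if n else 0.0 for out in OUTCOMES}

    def summary(self) -> dict:
        return {
            "n_input": int(len(self.table)),
            "n_retained": int((self.table["outcome"] == RETAINED).sum()),
            "rules_applied": list(self.rules_applied),
            "fractions": self.removal_fractions(),
        }


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{what} is missing columns {missing}")


def filter_min_length(report: QCReport, records: pd.DataFrame,
                      thresholds: QCThresholds | None = None) -> QCReport:
    """Remove records below the domain/dataset-specific minimum length."""
    thresholds = thresholds or QCThresholds()
    _require_columns(records, ["length", "domain", "dataset_type"], "records table")
    rec = records.loc[report.retained_ids]
    unknown = set(rec["dataset_type"]) - ({_AMPLICON} | set(_GENE_TYPES))
    if unknown:
        raise DataError(f"unknown dataset_type values: {sorted(unknown)}")
    limit = np.where(
        rec["dataset_type"].to_numpy() == _AMPLICON,
        np.where(rec["domain"].to_numpy() == "archaea",
                 thresholds.min_len_amplicon_archaea,
                 thresholds.min_len_amplicon_bacteria),
        thresholds.min_len_gene,
    )
    fail = rec.index[rec["length"].to_numpy() <= limit]
    report.mark(fail, REMOVED_LENGTH, values=rec.loc[fail, "length"])
    report.rules_applied.append("min_length")
    logger.info("min_length removed %d of %d", len(fail), len(rec))
    return report


def _hits_by_query(hits: pd.DataFrame) -> pd.DataFrame:
    _require_columns(hits, ["query_id", "qlen_aligned", "no_hit"], "hits table")
    return hits.set_index("query_id")


def remove_no_hit(report: QCReport, hits: pd.DataFrame) -> QCReport:
    """Remove records whose search yielded no hit."""
    h = _hits_by_query(hits)
    retained = report.retained_ids
    missing = retained.difference(h.index)
    if len(missing):
        raise DataError(f"hits missing for {len(missing)} retained records, "
                        f"e.g. {missing[0]!r}")
    fail = retained[h.loc[retained, "no_hit"].to_numpy().astype(bool)]
    report.mark(fail, REMOVED_NO_HIT)
    report.rules_applied.append("no_hit")
    logger.info("no_hit removed %d of %d", len(fail), len(retained))
    return report


def remove_short_alignments(report: QCReport, hits: pd.DataFrame,
                            thresholds: QCThresholds | None = None) -> QCReport:
    """Remove records whose top-hit query alignment is under 300 bp."""
    thresholds = thresholds or QCThresholds()
    h = _hits_by_query(hits)
    retained = report.retained_ids
    qal = h.loc[retained, "qlen_aligned"].astype(float)
    fail = retained[(qal < thresholds.min_query_alignment).to_numpy()]
    report.mark(fail, REMOVED_SHORT_ALIGNMENT, values=qal.loc[fail].astype(int))
    report.rules_applied.append("short_alignment")
    logger.info("short_alignment removed %d of %d", len(fail), len(retained))
    return report


def chimera_screen(report: QCReport, records: pd.DataFrame,
                   hits_cultured: pd.DataFrame,
                   hits_environmental: pd.DataFrame | None,
                   thresholds: QCThresholds | None = None) -> QCReport:
    """Remove records aligning <90% of their length to both databases.

    Only records whose cultured-hit coverage is below the threshold are
    screened; each of those must have an environmental-database hit row or
    a ``DataError`` is raised. An environmental no-hit counts as zero
    coverage (removal side).
    """
    thresholds = thresholds or QCThresholds()
    _require_columns(records, ["length"], "records table")
    hc = _hits_by_query(hits_cultured)
    retained = report.retained_ids
    frac_cult = (hc.loc[retained, "qlen_aligned"].astype(float)
                 / records.loc[retained, "length"].astype(float))
    screened = retained[(frac_cult < thresholds.chimera_alignment_fraction).to_numpy()]
    if len(screened) == 0:
        report.rules_applied.append("chimera")
        return report
    if hits_environmental is None:
        raise DataError("environmental hits required for chimera screen")
    he = _hits_by_query(hits_environmental)
    missing = screened.difference(he.index)
    if len(missing):
        raise DataError(f"environmental hit missing for screened record {missing[0]!r}")
    env_rows = he.loc[screened]
    frac_env = np.where(
        env_rows["no_hit"].to_numpy().astype(bool),
        0.0,
        env_rows["qlen_aligned"].astype(float).to_numpy()
        / records.loc[screened, "length"].astype(float).to_numpy(),
    )
    fail = screened[frac_env < thresholds.chimera_alignment_fraction]
    values = [
        f"{frac_cult.loc[q]:.3f}/{fe:.3f}"
        for q, fe in zip(screened, frac_env)
        if fe < thresholds.chimera_alignment_fraction
    ]
    report.mark(fail, REMOVED_CHIMERA, values=pd.Series(values, index=fail))
    report.rules_applied.append("chimera")
    logger.info("chimera removed %d of %d screened", len(fail), len(screened))
    return report


def remove_nontarget_taxa(report: QCReport, records: pd.DataFrame) -> QCReport:
    """Remove chloroplast, mitochondrial and eukaryotic records.

    A record is non-target when any rank token of its semicolon-separated
    taxonomy equals Chloroplast, Mitochondria or Eukaryota
    (case-insensitive). Records without a taxonomy are retained with a
    logged warning — the filter applies to classified sequences only.
    """
    retained = report.retained_ids
    if "taxonomy" not in records.columns:
        logger.warning("no taxonomy column; non-target filter skipped for all records")
        report.rules_applied.append("nontarget")
        return report
    tax = records.loc[retained, "taxonomy"]
    blank = tax.isna() | (tax.astype(str).str.strip() == "")
    if blank.any():
        logger.warning("%d records lack taxonomy and pass the non-target filter",
                       int(blank.sum()))
    def is_nontarget(t) -> bool:
        if not isinstance(t, str) or not t.strip():
            return False
        return any(r.strip().lower() in _NONTARGET_RANKS for r in t.split(";"))
    fail = retained[tax.map(is_nontarget).to_numpy()]
    report.mark(fail, REMOVED_NONTARGET, values=tax.loc[fail])
    report.rules_applied.append("nontarget")
    logger.info("nontarget removed %d of %d", len(fail), len(retained))
    return report


def run_qc(records: pd.DataFrame,
           hits_cultured: pd.DataFrame,
           hits_environmental: pd.DataFrame | None = None,
           thresholds: QCThresholds | None = None) -> QCReport:
    """Apply all retention rules in the fixed order.

    ``records`` must be indexed by query_id with columns length, domain,
    dataset_type and (optionally) taxonomy.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport.fresh(records.index)
    filter_min_length(report, records, thresholds)
    remove_no_hit(report, hits_cultured)
    remove_short_alignments(report, hits_cultured, thresholds)
    chimera_screen(report, records, hits_cultured, hits_environmental, thresholds)
    remove_nontarget_taxa(report, records)
    return report
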