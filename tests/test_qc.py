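"""Retention rules: boundaries, attribution, conservation, artifact recovery."""

import numpy as np
import pandas as pd
import pytest

import microcensus as mc
from microcensus.errors import DataError
from microcensus.qc import (QCReport, QCThresholds, RETAINED, REMOVED_CHIMERA,
                            REMOVED_LENGTH, REMOVED_NO_HIT,
                            REMOVED_NONTARGET, REMOVED_SHORT_ALIGNMENT,
                            chimera_screen, filter_min_length, remove_no_hit,
                            remove_nontarget_taxa, remove_short_alignments)


def make_records(rows):
    df = pd.DataFrame(rows, columns=["query_id", "domain", "dataset_type",
                                     "length", "taxonomy"])
    return df.set_index("query_id")


def make_hits(rows):
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "pident",
                                       "length", "qlen_aligned", "score",
                                       "no_hit"])


class TestMinLength:
    @pytest.mark.parametrize("domain,dataset,length,kept", [
        ("bacteria", "amplicon", 1200, False),   # boundary excluded (strict >)
        ("bacteria", "amplicon", 1201, True),
        ("archaea", "amplicon", 900, False),
        ("archaea", "amplicon", 901, True),
        ("bacteria", "metagenome", 901, True),   # gene rule: >900 bp
        ("bacteria", "metagenome", 900, False),
        ("archaea", "metatranscriptome", 901, True),
    ])
    def test_boundaries(self, domain, dataset, length, kept):
        records = make_records([("q1", domain, dataset, length, "")])
        report = filter_min_length(QCReport.fresh(records.index), records)
        outcome = report.table.loc["q1", "outcome"]
        assert (outcome == RETAINED) == kept
        if not kept:
            assert outcome == REMOVED_LENGTH

    def test_unknown_dataset_type(self):
        records = make_records([("q1", "bacteria", "isolate", 1500, "")])
        with pytest.raises(DataError):
            filter_min_length(QCReport.fresh(records.index), records)

    def test_empty_input(self):
        records = make_records([])
        report = filter_min_length(QCReport.fresh(records.index), records)
        assert report.table.empty
        assert report.removal_fractions()[REMOVED_LENGTH] == 0.0


class TestNoHitAndShortAlignment:
    def test_no_hit_removed_and_hits_required(self):
        records = make_records([("q1", "bacteria", "metagenome", 1000, ""),
                                ("q2", "bacteria", "metagenome", 1000, "")])
        hits = make_hits([("q1", "", np.nan, np.nan, np.nan, np.nan, True),
                          ("q2", "r1", 95.0, 1000, 1000, 1900.0, False)])
        report = remove_no_hit(QCReport.fresh(records.index), hits)
        assert report.table.loc["q1", "outcome"] == REMOVED_NO_HIT
        assert report.table.loc["q2", "outcome"] == RETAINED
        with pytest.raises(DataError):
            remove_no_hit(QCReport.fresh(pd.Index(["q1", "q3"])), hits)

    @pytest.mark.parametrize("qal,kept", [(299, False), (300, True), (1000, True)])
    def test_short_alignment_boundary(self, qal, kept):
        records = make_records([("q1", "bacteria", "metagenome", 1000, "")])
        hits = make_hits([("q1", "r1", 95.0, qal, qal, 2.0 * qal, False)])
        report = remove_short_alignments(QCReport.fresh(records.index), hits)
        outcome = report.table.loc["q1", "outcome"]
        assert (outcome == RETAINED) == kept
        if not kept:
            assert outcome == REMOVED_SHORT_ALIGNMENT


class TestChimeraScreen:
    def _run(self, frac_cultured, frac_env):
        length = 1000
        records = make_records([("q1", "bacteria", "metagenome", length, "")])
        hits_c = make_hits([("q1", "r1", 95.0, 900, frac_cultured * length,
                             1800.0, False)])
        hits_e = make_hits([("q1", "e1", 95.0, 900, frac_env * length,
                             1800.0, False)])
        report = chimera_screen(QCReport.fresh(records.index), records,
                                hits_c, hits_e)
        return report.table.loc["q1", "outcome"]

    def test_high_env_coverage_rescues(self):
        # removal requires <90% to BOTH databases
        assert self._run(0.85, 0.95) == RETAINED

    def test_low_coverage_to_both_removed(self):
        assert self._run(0.85, 0.85) == REMOVED_CHIMERA

    def test_exact_threshold_retained(self):
        assert self._run(0.90, 0.10) == RETAINED

    def test_env_hits_not_needed_when_coverage_high(self):
        records = make_records([("q1", "bacteria", "metagenome", 1000, "")])
        hits_c = make_hits([("q1", "r1", 95.0, 950, 950, 1900.0, False)])
        report = chimera_screen(QCReport.fresh(records.index), records,
                                hits_c, None)
        assert report.table.loc["q1", "outcome"] == RETAINED

    def test_missing_env_hit_is_data_error(self):
        records = make_records([("q1", "bacteria", "metagenome", 1000, "")])
        hits_c = make_hits([("q1", "r1", 95.0, 500, 500, 1000.0, False)])
        hits_e = make_hits([])
        with pytest.raises(DataError):
            chimera_screen(QCReport.fresh(records.index), records, hits_c, hits_e)

    def test_env_no_hit_counts_as_zero_coverage(self):
        records = make_records([("q1", "bacteria", "metagenome", 1000, "")])
        hits_c = make_hits([("q1", "r1", 95.0, 500, 500, 1000.0, False)])
        hits_e = make_hits([("q1", "", np.nan, np.nan, np.nan, np.nan, True)])
        report = chimera_screen(QCReport.fresh(records.index), records,
                                hits_c, hits_e)
        assert report.table.loc["q1", "outcome"] == REMOVED_CHIMERA


class TestNonTarget:
    @pytest.mark.parametrize("taxonomy,kept", [
        ("Bacteria;Cyanobacteria;Chloroplast;unclassified;unclassified;unclassified;unclassified", False),
        ("Bacteria;Proteobacteria;Alpha;Rickettsiales;Mitochondria;unclassified;unclassified", False),
        ("Eukaryota;Opisthokonta;Fungi;x;y;z;w", False),
        ("Archaea;Euryarchaeota;Class1;Order1;Family1;Genus1;Species1", True),
    ])
    def test_rank_matching(self, taxonomy, kept):
        records = make_records([("q1", "bacteria", "metagenome", 1000, taxonomy)])
        report = remove_nontarget_taxa(QCReport.fresh(records.index), records)
        outcome = report.table.loc["q1", "outcome"]
        assert (outcome == RETAINED) == kept
        if not kept:
            assert outcome == REMOVED_NONTARGET

    def test_missing_taxonomy_passes_with_warning(self, caplog):
        records = make_records([("q1", "bacteria", "metagenome", 1000, "")])
        with caplog.at_level("WARNING", logger="microcensus.qc"):
            report = remove_nontarget_taxa(QCReport.fresh(records.index), records)
        assert report.table.loc["q1", "outcome"] == RETAINED
        assert any("taxonomy" in rec.message for rec in caplog.records)


class TestEndToEnd:
    def test_outcomes_partition_and_conserve(self, qc_dataset):
        dataset, _, report = qc_dataset
        table = report.table
        assert len(table) == len(dataset.sequences)
        fractions = report.removal_fractions()
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert report.rules_applied == ["min_length", "no_hit",
                                        "short_alignment", "chimera",
                                        "nontarget"]

    def test_chimera_recovery_and_no_false_positives(self, qc_dataset):
        """Injected chimeras are flagged at >=90%; clean full-length queries
        are never called chimeric; injected fragments are removed by the
        short-alignment rule at >=95%."""
        dataset, _, report = qc_dataset
        joined = report.table.join(dataset.truth.set_index("query_id"))
        chim = joined[joined["is_chimera"]]
        assert (chim["outcome"] == REMOVED_CHIMERA).mean() >= 0.90
        frag = joined[joined["is_short_fragment"]]
        assert (frag["outcome"] == REMOVED_SHORT_ALIGNMENT).mean() >= 0.95
        clean = joined[~joined["is_chimera"] & ~joined["is_short_fragment"]]
        assert len(clean) == 540
        assert (clean["outcome"] == REMOVED_CHIMERA).sum() == 0
        assert (clean["outcome"] == RETAINED).all()


def test_thresholds_validation():
    with pytest.raises(DataError):
        QCThresholds(min_query_alignment=0)
    with pytest.raises(DataError):
        QCThresholds(chimera_alignment_fraction=1.5)
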