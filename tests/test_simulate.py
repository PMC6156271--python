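"""Generator contracts: determinism, exact identity control, artifact shape."""

import numpy as np
import pandas as pd
import pytest

import microcensus as mc
from microcensus.classify import NoveltyBin, assign_bin
from microcensus.errors import DataError, ParameterError
from microcensus.simulate import achieved_identity


def test_reference_db_counts_and_lengths():
    refs = mc.generate_reference_db(2, 1, 1500, seed=7)
    assert len(refs) == 3
    domains = [r.domain for r in refs]
    assert domains.count("bacteria") == 2 and domains.count("archaea") == 1
    assert all(len(r.sequence) == 1500 for r in refs)
    assert all(len(r.taxonomy.split(";")) == 7 for r in refs)


def test_reference_db_deterministic():
    a = mc.generate_reference_db(3, 2, 600, seed=11)
    b = mc.generate_reference_db(3, 2, 600, seed=11)
    assert a == b
    c = mc.generate_reference_db(3, 2, 600, seed=12)
    assert a != c


@pytest.mark.parametrize("kw", [
    dict(n_bacteria=0, n_archaea=0, length=500),
    dict(n_bacteria=-1, n_archaea=2, length=500),
    dict(n_bacteria=1, n_archaea=0, length=50),
])
def test_reference_db_rejects_bad_parameters(kw):
    with pytest.raises(ParameterError):
        mc.generate_reference_db(**kw, seed=0)


def test_independent_references_are_quarter_identical():
    """Two i.i.d. uniform sequences match at ~25% of positions; the mean
    Hamming identity over 1,000 pairs must sit inside a generous binomial
    band around 0.25."""
    rng = np.random.default_rng(1)
    length, n_pairs = 200, 1000
    draws = rng.integers(0, 4, size=(2 * n_pairs, length))
    ident = (draws[::2] == draws[1::2]).mean(axis=1)
    # sd of the mean ~ sqrt(0.25*0.75/200)/sqrt(1000) ~ 1e-3; allow 5 sd
    assert ident.mean() == pytest.approx(0.25, abs=5e-3)


class TestMutateToIdentity:
    def test_identity_100_returns_input(self):
        seq = "ACGT" * 250
        assert mc.mutate_to_identity(seq, 100.0, seed=3) == seq

    def test_exact_substitution_count(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        out = mc.mutate_to_identity(seq, 90.0, seed=5)
        mismatches = sum(a != b for a, b in zip(seq, out))
        assert mismatches == 100
        assert len(out) == len(seq)

    def test_ends_untouched(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 400))
        out = mc.mutate_to_identity(seq, 75.0, seed=7)
        assert out[:10] == seq[:10] and out[-10:] == seq[-10:]

    def test_rejects_impossible_targets(self):
        with pytest.raises(ParameterError):
            mc.mutate_to_identity("ACGT" * 30, 1.0, seed=0)  # >100 subs, 100 eligible
        with pytest.raises(ParameterError):
            mc.mutate_to_identity("ACGT" * 30, 0.0, seed=0)

    def test_best_hit_recovers_target_identity(self, refs):
        """A query mutated to 86% identity must come back from the search
        with measured identity 86.0 +/- 0.5 against its parent."""
        parent = refs.records[0]
        query = mc.mutate_to_identity(parent.sequence, 86.0, seed=9)
        hit = mc.best_cultured_hit("q", query, refs)
        assert hit.subject_id == parent.id
        assert hit.percent_identity == pytest.approx(86.0, abs=0.5)


class TestApplyIndels:
    def test_length_changes_bounded_and_deterministic(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 500))
        out = mc.apply_indels(seq, 5, seed=3)
        assert abs(len(out) - 500) <= 5
        assert out == mc.apply_indels(seq, 5, seed=3)
        assert mc.apply_indels(seq, 0, seed=3) == seq

    def test_indel_mode_still_recovers_bins(self, refs):
        """With a mild indel rate the measured identity drifts but stays
        within the same novelty bin for well-separated targets."""
        spec = mc.CommunitySpec(environment="soil", n_seqs_per_sample=30,
                                indel_rate=2.0, seed=31)
        data = mc.generate_environment_dataset(spec, refs)
        hits = mc.search_all(data.sequences, refs)
        merged = hits.merge(data.truth, on="query_id")
        err = (merged["pident"] - merged["true_identity"]).abs()
        assert err.max() < 2.0  # approximate, unlike substitution-only mode


class TestMakeChimera:
    def test_construction_midpoint(self):
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list("ACGT"), 1000))
        b = "".join(rng.choice(list("ACGT"), 1000))
        out = mc.make_chimera(a, b, 0.5)
        assert len(out) == 1000
        assert out[:500] == a[:500]
        assert out[500:] == b[500:]

    def test_self_chimera_is_identity(self):
        rng = np.random.default_rng(9)
        a = "".join(rng.choice(list("ACGT"), 800))
        assert mc.make_chimera(a, a, 0.5) == a

    def test_length_near_weighted_mean(self):
        rng = np.random.default_rng(10)
        a = "".join(rng.choice(list("ACGT"), 900))
        b = "".join(rng.choice(list("ACGT"), 1100))
        out = mc.make_chimera(a, b, 0.3)
        expected = 0.3 * 900 + 0.7 * 1100
        assert abs(len(out) - expected) <= 1

    @pytest.mark.parametrize("bp", [0.1, 0.85, -0.2])
    def test_rejects_bad_breakpoint(self, bp):
        a = "A" * 600
        with pytest.raises(ParameterError):
            mc.make_chimera(a, a, bp)

    def test_chimera_low_coverage_to_both_parents(self, refs):
        """Chimeras of two unrelated references align <90% of their length
        to either single parent (20 simulated pairs)."""
        rng = np.random.default_rng(11)
        records = list(refs)
        for _ in range(20):
            ia, ib = rng.choice(len(records), size=2, replace=False)
            a, b = records[ia].sequence, records[ib].sequence
            bp = float(rng.uniform(0.25, 0.75))
            chim = mc.make_chimera(a, b, bp)
            for parent in (a, b):
                res = mc.align_pair(chim, parent)
                assert res.query_alignment_length / len(chim) < 0.90


class TestEnvironmentDataset:
    def test_degenerate_mixture_all_bin_one(self, refs):
        spec = mc.CommunitySpec(environment="pond", n_seqs_per_sample=50,
                                bin_proportions=(1.0, 0.0, 0.0), seed=1)
        data = mc.generate_environment_dataset(spec, refs)
        assert set(data.truth["true_bin"]) == {
            NoveltyBin.CULTURED_SPECIES_TO_GENUS.label}

    def test_exact_largest_remainder_allocation(self, recovery_dataset):
        dataset, _ = recovery_dataset
        counts = dataset.truth["true_bin"].value_counts()
        assert counts[NoveltyBin.CULTURED_SPECIES_TO_GENUS.label] == 60
        assert counts[NoveltyBin.UNCULTURED_GENUS_TO_CLASS.label] == 90
        assert counts[NoveltyBin.UNCULTURED_PHYLUM_PLUS.label] == 150

    def test_deterministic_per_seed(self, refs):
        spec = mc.CommunitySpec(environment="soil", n_seqs_per_sample=20, seed=5)
        d1 = mc.generate_environment_dataset(spec, refs)
        d2 = mc.generate_environment_dataset(spec, refs)
        assert d1.sequences == d2.sequences
        pd.testing.assert_frame_equal(d1.metadata, d2.metadata)
        pd.testing.assert_frame_equal(d1.truth, d2.truth)

    def test_truth_bins_consistent_with_cutoffs(self, qc_dataset):
        dataset, _, _ = qc_dataset
        truth = dataset.truth
        clean = truth[~truth["is_chimera"]]
        for ident, label in zip(clean["true_identity"], clean["true_bin"]):
            assert assign_bin(ident).label == label

    def test_depths_positive_and_metadata_complete(self, qc_dataset):
        dataset, _, _ = qc_dataset
        meta = dataset.metadata
        assert (meta["read_depth"] >= 1.0).all()
        assert meta["query_id"].is_unique
        assert set(meta["query_id"]) == set(dataset.sequences)
        assert set(dataset.truth["query_id"]) == set(dataset.sequences)

    def test_chimeras_have_two_parents(self, qc_dataset):
        dataset, _, _ = qc_dataset
        chim = dataset.truth[dataset.truth["is_chimera"]]
        assert len(chim) == 60
        assert (chim["parent_ref_id"].str.count(";") == 1).all()

    def test_empty_reference_set_rejected(self):
        spec = mc.CommunitySpec(environment="x", n_seqs_per_sample=5)
        with pytest.raises((DataError, ParameterError)):
            mc.generate_environment_dataset(spec, mc.ReferenceSet(()))

    def test_invalid_spec_rejected(self, refs):
        with pytest.raises(ParameterError):
            mc.CommunitySpec(environment="x", bin_proportions=(0.5, 0.5, 0.5)) \
                .validate(mc.CutoffLadder())


def test_achieved_identity_matches_requested_within_rounding():
    for length in (900, 1000, 1500):
        for target in (97.3, 91.0, 86.0, 80.5):
            # inclusive half-step band; epsilon absorbs float ties like
            # 0.195 * 900 = 175.499999...
            assert achieved_identity(length, target) == pytest.approx(
                target, abs=100.0 / (2 * length) + 1e-9)
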