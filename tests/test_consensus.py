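"""MIG grouping, threshold selection, consensus voting, sample collapse."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from bcrnet.consensus import (
    MIG,
    collapse_sample,
    consensus_sequence,
    group_by_umi,
    select_mig_threshold,
)
from bcrnet.io import UsageError
from bcrnet.simulate import SimulationConfig, simulate_repertoire

Q = "I"  # Phred 40


def _reads(*items):
    return [(umi, seq, Q * len(seq)) for umi, seq in items]


class TestGrouping:
    def test_one_mig_per_distinct_umi(self):
        migs = group_by_umi(_reads(("u1", "AAAA"), ("u1", "AAAT"), ("u2", "CCCC")))
        assert sorted(m.size for m in migs) == [1, 2]

    def test_empty_input_gives_empty_list(self):
        assert group_by_umi([]) == []

    def test_sizes_conserve_read_count(self, noisy_sample):
        reads = noisy_sample.umi_reads()
        migs = group_by_umi(reads)
        assert sum(m.size for m in migs) == len(reads)
        assert len(migs) == len({u for u, _, _ in reads})

    def test_unique_umis_fixed_depth_gives_uniform_migs(self):
        config = SimulationConfig(
            seed=3,
            dominant_fractions=(1.0,),
            n_background_clones=0,
            n_molecules=2000,
            shm_rate=0.0,
            seq_error=0.0,
            unique_umis=True,
            pcr_depth_model="fixed",
            pcr_mean_depth=3,
        )
        sim = simulate_repertoire(config)
        migs = group_by_umi(sim.umi_reads())
        assert len(migs) == 2000
        assert all(m.size == 3 for m in migs)


class TestThreshold:
    def test_fixed_strategy_returns_fixed_value(self):
        assert select_mig_threshold({1: 10, 5: 3}, strategy="fixed", fixed_value=2) == 2

    def test_valley_between_error_peak_and_main_mode(self):
        histogram = {1: 10000, 2: 500, 3: 40, 8: 300, 9: 700, 10: 650}
        assert select_mig_threshold(histogram, strategy="histogram_valley") == 4

    def test_unimodal_histogram_falls_back(self):
        assert select_mig_threshold({1: 50}, strategy="histogram_valley", fixed_value=2) == 2

    def test_monotone_decreasing_histogram_falls_back(self):
        # geometric-like histograms have no interior valley
        assert (
            select_mig_threshold({1: 900, 2: 300, 3: 100}, strategy="histogram_valley",
                                 fixed_value=2)
            == 2
        )

    def test_invalid_fixed_value_rejected(self):
        with pytest.raises(UsageError):
            select_mig_threshold({1: 5}, strategy="fixed", fixed_value=0)


class TestConsensus:
    def test_majority_vote(self):
        mig = MIG("u", [("ACGT", Q * 4), ("ACGT", Q * 4), ("ACTT", Q * 4)])
        assert consensus_sequence(mig)[0] == "ACGT"

    def test_single_member_identity(self):
        mig = MIG("u", [("ACGT", Q * 4)])
        assert consensus_sequence(mig)[0] == "ACGT"

    def test_tie_breaks_to_alphabetically_smaller_base(self):
        mig = MIG("u", [("ACGT", Q * 4), ("ACTT", Q * 4)])
        assert consensus_sequence(mig)[0] == "ACGT"

    def test_quality_outvotes_count(self):
        # one high-quality read against two low-quality ones
        mig = MIG("u", [("A", "I"), ("C", "#"), ("C", "#")])
        assert consensus_sequence(mig)[0] == "A"

    def test_members_restricted_to_modal_length(self):
        mig = MIG("u", [("ACGT", Q * 4), ("ACGT", Q * 4), ("ACG", Q * 3)])
        assert consensus_sequence(mig)[0] == "ACGT"

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from(["ACGT", "ACTT", "AGGT", "TCGT"]), min_size=1, max_size=9),
           st.randoms(use_true_random=False))
    def test_order_invariance(self, seqs, rnd):
        members = [(s, Q * len(s)) for s in seqs]
        shuffled = members[:]
        rnd.shuffle(shuffled)
        assert consensus_sequence(MIG("u", members)) == consensus_sequence(
            MIG("u", shuffled)
        )


class TestCollapse:
    def test_threshold_filters_small_migs(self):
        reads = _reads(
            ("u1", "AAAA"),
            ("u2", "CCCC"),
            *[("u3", "GGGG")] * 5,
        )
        cons, stats = collapse_sample(reads, strategy="fixed", fixed_value=2)
        assert len(cons) == 1 and cons[0][1] == "GGGG"
        assert stats.n_migs_kept == 1 and stats.n_migs_dropped == 2
        assert stats.n_migs_kept + stats.n_migs_dropped == 3

    def test_noiseless_consensus_equals_true_molecule(self, noiseless_sample):
        truth = noiseless_sample.truth
        payload_by_umi = {
            row["umi"]: row["cdr3_mut"] for _, row in truth.molecules.iterrows()
        }
        cons, _ = collapse_sample(noiseless_sample.umi_reads(), strategy="fixed",
                                  fixed_value=1)
        assert len(cons) == len(truth.molecules)
        clones = truth.clones.set_index("clone_id")
        mol = truth.molecules.set_index("umi")
        for umi, seq, _q in cons:
            clone = clones.loc[mol.loc[umi, "clone_id"]]
            expected = (
                _full_sequence(clone["v_call"])
                + mol.loc[umi, "cdr3_mut"]
                + _full_sequence(clone["j_call"])
            )
            assert seq == expected

    def test_read_order_does_not_change_output(self, noisy_sample):
        reads = noisy_sample.umi_reads()
        shuffled = reads[:]
        random.Random(0).shuffle(shuffled)
        assert collapse_sample(reads) == collapse_sample(shuffled)

    def test_consensus_error_decreases_with_mig_size(self):
        """Larger MIGs vote away more sequencing errors (monotone in size)."""
        rates = []
        for depth in (1, 3, 5):
            errors = bases = 0
            for seed in range(3):
                config = SimulationConfig(
                    seed=seed,
                    dominant_fractions=(1.0,),
                    n_background_clones=0,
                    n_molecules=300,
                    shm_rate=0.0,
                    seq_error=0.01,
                    unique_umis=True,
                    pcr_depth_model="fixed",
                    pcr_mean_depth=depth,
                )
                sim = simulate_repertoire(config)
                e, b = _consensus_errors(sim, threshold=depth)
                errors += e
                bases += b
            rates.append(errors / bases)
        assert rates[0] >= rates[1] >= rates[2]


def _full_sequence(name):
    from bcrnet.reference import get_default_reference

    return get_default_reference()[name].full_sequence


def _consensus_errors(sim, threshold):
    """Per-base consensus-vs-truth mismatches over MIGs meeting the size cut."""
    truth = sim.truth
    clones = truth.clones.set_index("clone_id")
    mols = truth.molecules.set_index("umi")
    counts = mols.index.value_counts()
    cons, _ = collapse_sample(sim.umi_reads(), strategy="fixed", fixed_value=threshold)
    errors = bases = 0
    for umi, seq, _q in cons:
        if umi not in mols.index or counts[umi] != 1:
            continue  # UMI-error orphan or collision: no unique truth
        row = mols.loc[umi]
        clone = clones.loc[row["clone_id"]]
        expected = (
            _full_sequence(clone["v_call"]) + row["cdr3_mut"] + _full_sequence(clone["j_call"])
        )
        if len(seq) != len(expected):
            continue
        errors += sum(a != b for a, b in zip(seq, expected))
        bases += len(expected)
    return errors, bases
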