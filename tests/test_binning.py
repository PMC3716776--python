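"""Composition models, the TV score, the two-round assignment procedure
and coverage-cluster extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteobin import binning, synthetic
from proteobin.binning import (Bin, BinSet, CompositionModel, Contig,
                               assign_round, count_words, final_classify,
                               merge_or_delete_ambiguous, score, seed_bins,
                               tv_distance)


def _contig(cid, seq, coverage=10.0, markers=()):
    return Contig(id=cid, sequence=seq, coverage=coverage,
                  markers=list(markers))


def _random_seq(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _oracle_fourmer_freq(seq, strand="canonical"):
    """Slow dict-based 4-mer counter, independent of the vectorized path."""
    counts = {}
    windows = [seq[i:i + 4] for i in range(len(seq) - 3)]
    if strand == "canonical":
        windows += [binning.revcomp(seq)[i:i + 4]
                    for i in range(len(seq) - 3)]
    for w in windows:
        if "N" in w:
            continue
        counts[w] = counts.get(w, 0) + 1
    total = sum(counts.values())
    freq = np.zeros(256)
    for w, c in counts.items():
        idx = 0
        for ch in w:
            idx = idx * 4 + "ACGT".index(ch)
        freq[idx] = c / total
    return freq


class TestCompositionModel:
    def test_homopolymer_transitions_and_frequency(self):
        model = CompositionModel.from_sequences(["AAAAAA"], order=3,
                                                strand="single")
        trans = model.transition_matrix(smooth=False)
        assert trans[0, 0] == 1.0  # P(A | AAA) = 1
        assert model.frequencies[0] == 1.0  # 4-mer AAAA

    def test_palindromic_sequence_canonical(self):
        model = CompositionModel.from_sequences(["ACGT"], order=3,
                                                strand="canonical")
        idx = ((0 * 4 + 1) * 4 + 2) * 4 + 3  # "ACGT"
        assert model.frequencies[idx] == 1.0

    def test_recovers_generating_chain(self, rng):
        pop = synthetic.PopulationSpec(label="X", gc_target=0.55,
                                       composition_divergence=0.5)
        trans = synthetic.population_transitions(pop, rng)
        seq = synthetic.sample_chain(trans, 100_000, rng)
        model = CompositionModel.from_sequences([seq], order=3,
                                                strand="single")
        est = model.transition_matrix(smooth=False)
        err = np.abs(est - trans)
        # ~1.5k observations per row at 100 kbp: individual entries can
        # stray by ~3 standard errors (~0.04), the average must be tight
        assert np.nanmean(err) < 0.02
        assert np.nanmax(err) < 0.06

    def test_counts_match_oracle(self, rng):
        seq = _random_seq(rng, 2000)
        fast = count_words(seq, 4, strand="canonical")
        assert np.allclose(fast / fast.sum(), _oracle_fourmer_freq(seq))

    def test_n_windows_skipped(self):
        counts = count_words("ACGTNACGT", 4, strand="single")
        # only ACGT windows at offsets 0 and 5 survive
        assert counts.sum() == 2

    def test_empty_and_bad_order_rejected(self):
        with pytest.raises(ValueError):
            CompositionModel.from_sequences([], order=3)
        with pytest.raises(ValueError):
            CompositionModel.from_sequences(["ACGT"], order=0)

    def test_small_training_set_warns(self):
        with pytest.warns(UserWarning, match="fewer than"):
            CompositionModel.from_sequences(["ACGTACGTACGT"], order=3)


class TestScore:
    def test_identity_gives_zero(self, rng):
        seq = _random_seq(rng, 5000)
        model = CompositionModel.from_sequences([seq])
        assert score(_contig("c", seq), model) == pytest.approx(0.0)

    def test_disjoint_supports_give_one(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = CompositionModel.from_sequences(["C" * 50], order=3,
                                                    strand="single")
            assert score(_contig("a", "A" * 50), model) == pytest.approx(1.0)

    def test_matches_bruteforce_tv(self, rng):
        a = _random_seq(rng, 10_000)
        b = _random_seq(rng, 10_000, p=(0.4, 0.1, 0.1, 0.4))
        model = CompositionModel.from_sequences([a, b])
        expected = 0.5 * np.abs(
            _oracle_fourmer_freq(a)
            - (_oracle_fourmer_freq(a) + _oracle_fourmer_freq(b)) / 2
        ).sum()
        # oracle averages frequencies; model pools counts of equal-length
        # inputs, which is the same thing here
        assert score(_contig("a", a), model) == pytest.approx(expected,
                                                              abs=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        p, q, r = (rng.dirichlet(np.ones(256)) for _ in range(3))
        assert tv_distance(p, q) == pytest.approx(tv_distance(q, p))
        assert tv_distance(p, p) == 0.0
        assert tv_distance(p, r) <= tv_distance(p, q) + tv_distance(q, r) + 1e-12

    def test_too_short_contig_rejected(self):
        model = CompositionModel.from_sequences(["ACGT" * 100])
        with pytest.raises(ValueError):
            score(_contig("tiny", "ACG"), model)

    def test_nll_metric_prefers_generating_model(self, rng):
        pa = synthetic.PopulationSpec(label="A", gc_target=0.65,
                                      composition_divergence=0.6)
        pb = synthetic.PopulationSpec(label="B", gc_target=0.45,
                                      composition_divergence=0.6)
        ta = synthetic.population_transitions(pa, rng)
        tb = synthetic.population_transitions(pb, rng)
        ma = CompositionModel.from_sequences(
            [synthetic.sample_chain(ta, 50_000, rng)], strand="single")
        mb = CompositionModel.from_sequences(
            [synthetic.sample_chain(tb, 50_000, rng)], strand="single")
        probe = _contig("p", synthetic.sample_chain(ta, 10_000, rng))
        assert score(probe, ma, metric="nll") < score(probe, mb, metric="nll")


class TestSeedBins:
    def test_majority_wins(self):
        c = _contig("c1", "ACGT" * 500, markers=[("c1", "Thermus"),
                                                 ("c2", "Thermus"),
                                                 ("c3", "Rhodothermus")])
        bins = seed_bins([c])
        assert [b.label for b in bins.bins] == ["Thermus"]
        assert bins["Thermus"].members == ["c1"]

    def test_tie_excluded(self):
        c = _contig("c1", "ACGT" * 500, markers=[("c1", "A"), ("c2", "B")])
        bins = seed_bins([c])  # markers exist but no strict majority
        assert bins.bins == []
        assert bins.unassigned == ["c1"]

    def test_only_observed_labels_become_bins(self, small_community):
        _, contigs, truth = small_community
        bins = seed_bins(contigs)
        assert set(b.label for b in bins.bins) <= set(truth.values())

    def test_no_markers_error(self):
        with pytest.raises(ValueError, match="markers"):
            seed_bins([_contig("c1", "ACGT" * 300)])


class TestAssignRound:
    def _fake_binset(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            m = CompositionModel.from_sequences(["ACGT" * 30])
        return BinSet(bins=[Bin("X", m, [], 1), Bin("Y", m, [], 1)])

    @pytest.mark.parametrize("best,second,expected", [
        (0.005, 0.009, "assigned"),       # margin: 0.009 >= 1.2 * 0.005
        (0.005, 0.0055, "rejected:ambiguous"),
        (0.02, 0.5, "rejected:score_max"),
    ])
    def test_rule_arithmetic(self, monkeypatch, best, second, expected):
        binset = self._fake_binset()
        contig = _contig("c1", "ACGT" * 300)
        monkeypatch.setattr(binning, "_score_matrix",
                            lambda contigs, bins: np.array([[best, second]]))
        out = assign_round([contig], binset, score_max=0.01, margin=1.2)
        decisions = {r["contig"]: r["decision"] for r in out.round_log}
        assert decisions["c1"] == expected

    def test_member_retained_under_score_max(self, monkeypatch):
        binset = self._fake_binset()
        binset.bins[0].members = ["c1"]
        contig = _contig("c1", "ACGT" * 300)
        monkeypatch.setattr(binning, "_score_matrix",
                            lambda contigs, bins: np.array([[0.5, 0.9]]))
        out = assign_round([contig], binset)
        assert out["X"].members == ["c1"]
        assert out.round_log[0]["decision"] == "retained:member"

    def test_short_contigs_never_assigned(self, monkeypatch):
        binset = self._fake_binset()
        contig = _contig("c1", "ACGT" * 100)  # 400 bp < 1000
        monkeypatch.setattr(binning, "_score_matrix",
                            lambda contigs, bins: np.array([[0.001, 0.9]]))
        out = assign_round([contig], binset, min_len=1000)
        assert out.unassigned == ["c1"]
        assert not out.round_log

    def test_determinism(self, small_community):
        _, contigs, _ = small_community
        seeds = seed_bins(contigs)
        r1 = assign_round(contigs, seeds, score_max=1.0)
        r2 = assign_round(contigs, seeds, score_max=1.0)
        assert r1.round_log == r2.round_log


class TestMergeDelete:
    def test_same_chain_bins_merge(self, rng):
        pop = synthetic.PopulationSpec(label="T", gc_target=0.6,
                                       composition_divergence=0.4)
        trans = synthetic.population_transitions(pop, rng)
        ca = _contig("a", synthetic.sample_chain(trans, 1_000_000, rng))
        cb = _contig("b", synthetic.sample_chain(trans, 1_000_000, rng))
        binset = BinSet(bins=[
            Bin("A", CompositionModel.from_contigs([ca]), ["a"], 1),
            Bin("B", CompositionModel.from_contigs([cb]), ["b"], 1),
        ])
        out = merge_or_delete_ambiguous(binset, [ca, cb],
                                        similarity_max=0.01)
        assert len(out.bins) == 1
        assert out.bins[0].label.endswith("+merged")
        assert sorted(out.bins[0].members) == ["a", "b"]

    def test_distant_bins_untouched(self, small_community):
        _, contigs, _ = small_community
        seeds = seed_bins(contigs)
        out = merge_or_delete_ambiguous(seeds, contigs)
        assert [b.label for b in out.bins] == [b.label for b in seeds.bins]
        assert all(a.members == b.members
                   for a, b in zip(out.bins, seeds.bins))

    def test_shrunken_bin_without_partner_deleted(self, small_community):
        _, contigs, _ = small_community
        seeds = seed_bins(contigs)
        victim = seeds.bins[0]
        victim.seed_size = len(victim.members) + 5  # simulate a round-1 loss
        out = merge_or_delete_ambiguous(seeds, contigs)
        assert victim.label not in [b.label for b in out.bins]
        assert set(victim.members) <= set(out.unassigned)


class TestFinalClassify:
    def test_min_len_boundary(self, small_community, rng):
        _, contigs, _ = small_community
        seeds = seed_bins(contigs)
        seq = contigs[0].sequence
        short = _contig("short", seq[:999])
        exact = _contig("exact", seq[:1000])
        out = final_classify([short, exact], seeds, min_len=1000)
        assert "short" in out.unassigned
        assert any("exact" in b.members for b in out.bins)

    def test_ground_truth_recovery(self, small_community):
        _, contigs, truth = small_community
        final = binning.run_binning(contigs)
        bin_of = final.bin_of()
        eligible = [c for c in contigs if c.length >= 5000]
        correct = sum(1 for c in eligible
                      if bin_of.get(c.id, "").split("+")[0] == truth[c.id])
        assert correct / len(eligible) >= 0.95

    def test_everything_large_is_assigned(self, small_community):
        _, contigs, _ = small_community
        final = binning.run_binning(contigs)
        assigned = {m for b in final.bins for m in b.members}
        for c in contigs:
            if c.length >= 1000:
                assert c.id in assigned
            else:
                assert c.id not in assigned


class TestCoverageClusters:
    def _contigs_at(self, rng, coverages, n_each=30, length=5000):
        out = []
        for k, cov in enumerate(coverages):
            for i in range(n_each):
                seq = _random_seq(rng, length)
                out.append(_contig(f"c{k}_{i}", seq,
                                   coverage=cov * rng.uniform(0.97, 1.03)))
        return out

    def test_unimodal(self, rng):
        contigs = self._contigs_at(rng, [70.0])
        clusters = binning.extract_coverage_clusters("B", contigs)
        assert len(clusters) == 1
        assert clusters[0].coverage_mode == pytest.approx(70, rel=0.06)

    def test_two_separated_modes(self, rng):
        contigs = self._contigs_at(rng, [70.0, 10.0])
        clusters = binning.extract_coverage_clusters("B", contigs)
        assert len(clusters) == 2
        assert clusters[0].coverage_mode == pytest.approx(70, rel=0.1)
        assert clusters[1].coverage_mode == pytest.approx(10, rel=0.1)

    def test_close_modes_unresolved_at_default_bandwidth(self, rng):
        contigs = self._contigs_at(rng, [30.0, 32.0])
        clusters = binning.extract_coverage_clusters("B", contigs,
                                                     bandwidth_log2=0.5)
        assert len(clusters) == 1

    def test_partition_property(self, rng):
        contigs = self._contigs_at(rng, [70.0, 25.0, 5.0])
        clusters = binning.extract_coverage_clusters("B", contigs)
        ids = [cid for cl in clusters for cid in cl.contig_ids]
        assert sorted(ids) == sorted(c.id for c in contigs)
        assert sum(cl.total_bp for cl in clusters) == \
               sum(c.length for c in contigs)
        for cl in clusters:
            lo, hi = cl.coverage_interval
            covs = [c.coverage for c in contigs if c.id in set(cl.contig_ids)]
            assert all(lo <= cv <= hi for cv in covs)

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            binning.extract_coverage_clusters("B", [])
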