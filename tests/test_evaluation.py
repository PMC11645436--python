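import itertools

import numpy as np
import pytest

from ptmct import evaluation as ev
from ptmct.io import PairDataset, PTMPair, PTMSiteRecord


def sites(pid, positions):
    return [PTMSiteRecord(pid, p) for p in positions]


class TestNegativeGeneration:
    def test_all_pairs_without_positives(self):
        negs = ev.generate_negative_pairs(sites("P", [3, 8, 15]), [])
        assert len(negs) == 3
        assert all(n.label == "negative" for n in negs)

    def test_double_membership_rule(self):
        """Only pairs whose BOTH sites belong to the positive-site set are
        removed: with sites {a,b,c} and positive (a,b), (a,c) and (b,c)
        survive."""
        s = sites("P", [1, 2, 3])
        positive = [PTMPair(s[0], s[1], label="positive")]
        negs = ev.generate_negative_pairs(s, positive)
        got = {(n.site_a.position, n.site_b.position) for n in negs}
        assert got == {(1, 3), (2, 3)}

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        all_sites, positives = [], []
        for pid in ("A", "B", "C"):
            positions = sorted(rng.choice(50, size=8, replace=False) + 1)
            s = sites(pid, positions)
            all_sites.extend(s)
            k = rng.integers(0, 4)
            chosen = rng.choice(len(positions), size=(k, 2))
            for a, b in chosen:
                if a != b:
                    positives.append(PTMPair(s[int(a)], s[int(b)],
                                             label="positive"))
        negs = ev.generate_negative_pairs(all_sites, positives)
        # oracle: explicit enumeration
        expected = set()
        for pid in ("A", "B", "C"):
            pos_positions = {p for pr in positives if pr.protein_id == pid
                             for p in pr.positions}
            positions = sorted({s.position for s in all_sites
                                if s.protein_id == pid})
            for a, b in itertools.combinations(positions, 2):
                if not (a in pos_positions and b in pos_positions):
                    expected.add((pid, a, b))
        assert {n.key() for n in negs} == expected


def toy_dataset(n_proteins=12, pairs_per_protein=6, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for k in range(n_proteins):
        pid = f"P{k}"
        positions = sorted(rng.choice(60, size=8, replace=False) + 1)
        for a, b in itertools.combinations(positions, 2):
            if len([p for p in pairs if p.protein_id == pid]) \
                    >= pairs_per_protein:
                break
            label = "positive" if rng.random() < 0.3 else "negative"
            pairs.append(PTMPair(PTMSiteRecord(pid, a), PTMSiteRecord(pid, b),
                                 label=label))
    return PairDataset(pairs=pairs)


class TestFoldAssignment:
    def test_sample_mode_balanced(self):
        ds = toy_dataset()
        fa = ev.make_fold_assignment(ds, "sample", k=10, seed=1)
        counts = np.bincount(fa.folds)[1:]
        assert len(counts) == 10
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == len(ds.pairs)

    def test_protein_mode_no_leakage(self):
        ds = toy_dataset()
        fa = ev.make_fold_assignment(ds, "protein", k=10, seed=2)
        for fold in range(1, 11):
            train, val = fa.split(fold)
            train_p = {ds.pairs[i].protein_id for i in train}
            val_p = {ds.pairs[i].protein_id for i in val}
            assert not (train_p & val_p)

    def test_every_pair_validated_once(self):
        ds = toy_dataset()
        for mode in ("sample", "protein"):
            fa = ev.make_fold_assignment(ds, mode, k=10, seed=3)
            seen = np.concatenate([fa.split(f)[1] for f in range(1, 11)])
            assert sorted(seen) == list(range(len(ds.pairs)))

    def test_seed_reproducible(self):
        ds = toy_dataset()
        a = ev.make_fold_assignment(ds, "sample", seed=4).folds
        b = ev.make_fold_assignment(ds, "sample", seed=4).folds
        np.testing.assert_array_equal(a, b)

    def test_too_few_proteins(self):
        ds = toy_dataset(n_proteins=4)
        with pytest.raises(ValueError):
            ev.make_fold_assignment(ds, "protein", k=10)


def auc_pair_counting(scores, labels):
    """Brute-force AUC: concordant pairs + half ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_ranking(self):
        rep = ev.compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert rep.auc == 1.0
        assert rep.aupr == 1.0

    def test_auc_matches_pair_counting(self):
        scores = [0.9, 0.8, 0.4, 0.2]
        labels = [1, 0, 1, 0]
        rep = ev.compute_metrics(scores, labels)
        assert rep.auc == pytest.approx(auc_pair_counting(scores, labels))

    def test_random_instances_match_oracles(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(6, 51))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 1)   # force ties
            thr = float(rng.random())
            rep = ev.compute_metrics(scores, labels, threshold=thr)
            assert rep.auc == pytest.approx(auc_pair_counting(scores, labels))
            tp = int(np.sum((scores >= thr) & (labels == 1)))
            fn = int(np.sum((scores < thr) & (labels == 1)))
            fp = int(np.sum((scores >= thr) & (labels == 0)))
            tn = int(np.sum((scores < thr) & (labels == 0)))
            m = ev.metrics_from_confusion(tp, fn, fp, tn)
            assert rep.mcc == pytest.approx(m["MCC"])
            assert rep.f1 == pytest.approx(m["F1"])
            assert rep.acc == pytest.approx(m["ACC"])

    def test_histone_confusion_counts(self):
        """Closed-form MCC/F1 from the printed confusion counts
        TP=20, FN=2, FP=6, TN=28."""
        m = ev.metrics_from_confusion(tp=20, fn=2, fp=6, tn=28)
        assert m["recall"] == pytest.approx(20 / 22)
        assert m["precision"] == pytest.approx(20 / 26)
        assert m["F1"] == pytest.approx(2 * (20 / 26) * (20 / 22)
                                        / (20 / 26 + 20 / 22))
        expected_mcc = (20 * 28 - 6 * 2) / np.sqrt(26.0 * 22 * 34 * 30)
        assert m["MCC"] == pytest.approx(expected_mcc)

    def test_single_class_rank_metrics_nan(self):
        with pytest.warns(UserWarning):
            rep = ev.compute_metrics([0.2, 0.9], [1, 1])
        assert np.isnan(rep.auc)
        assert rep.recall == 1.0    # both positives called at cutoff 0.15

    def test_single_class_thresholded_still_computed(self):
        with pytest.warns(UserWarning):
            rep = ev.compute_metrics([0.2, 0.9], [1, 1], threshold=0.5)
        assert rep.recall == 0.5
        assert np.isnan(rep.aupr)


class TestSignificance:
    def test_identical_scores_not_significant(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, size=60)
        scores = rng.random(60)
        rep = ev.significance_test(scores, scores, labels, seed=0)
        assert rep["AUC"]["p_value"] == 1.0

    def test_resample_sizes(self):
        rng = np.random.default_rng(7)
        labels = np.array([1] * 20 + [0] * 40)
        a, b = rng.random(60), rng.random(60)
        rep = ev.significance_test(a, b, labels, n_resamples=10, seed=1)
        assert len(rep["AUC"]["values_a"]) == 10
        assert len(rep["AUPR"]["values_b"]) == 10

    def test_branch_selection(self):
        """Normal samples pass Anderson-Darling, heavy-tailed ones do not."""
        rng = np.random.default_rng(8)
        assert ev._is_normal(rng.normal(size=200))
        heavy = rng.standard_cauchy(size=200)
        assert not ev._is_normal(heavy)

    def test_reports_valid_branch(self):
        rng = np.random.default_rng(9)
        labels = np.array([1] * 15 + [0] * 45)
        a = rng.random(60) + labels * 0.4
        b = rng.random(60)
        rep = ev.significance_test(a, b, labels, seed=2)
        assert rep["AUC"]["test"] in ("paired-t", "wilcoxon-rank-sum")
        assert 0.0 <= rep["AUC"]["p_value"] <= 1.0


class TestControlSets:
    def make_dataset(self, n_pos=30, n_neg=400, seed=0):
        """Positives at short sequence separation, negatives native."""
        rng = np.random.default_rng(seed)
        pairs = []
        for k in range(n_pos):
            a = int(rng.integers(1, 150))
            b = a + int(rng.integers(1, 12))
            pairs.append(PTMPair(PTMSiteRecord(f"P{k % 10}", a),
                                 PTMSiteRecord(f"P{k % 10}", b),
                                 label="positive"))
        while sum(1 for p in pairs if p.label == "negative") < n_neg:
            a, b = sorted(rng.integers(1, 200, size=2).tolist())
            if a == b:
                continue
            pid = f"P{int(rng.integers(10))}"
            pair = PTMPair(PTMSiteRecord(pid, a), PTMSiteRecord(pid, b),
                           label="negative")
            if pair.key() not in {q.key() for q in pairs}:
                pairs.append(pair)
        from ptmct.synthetic import generate_structure
        proteins = {f"P{k}": generate_structure(220, "helix", seed=k,
                                                protein_id=f"P{k}")
                    for k in range(10)}
        return PairDataset(pairs=pairs, proteins=proteins)

    def test_equal_counts_and_positives_kept(self):
        ds = self.make_dataset()
        for mode in ("set_random", "seq_control"):
            ctrl = ev.build_control_sets(ds, mode, seed=1)
            labels = ctrl.labels()
            assert labels.sum() == 30
            assert (1 - labels).sum() == 30
            pos_keys = {p.key() for p in ds.pairs if p.label == "positive"}
            assert {p.key() for p in ctrl.pairs
                    if p.label == "positive"} == pos_keys

    def test_no_duplicate_negatives(self):
        ds = self.make_dataset()
        ctrl = ev.build_control_sets(ds, "seq_control", seed=2)
        keys = [p.key() for p in ctrl.pairs if p.label == "negative"]
        assert len(keys) == len(set(keys))

    def test_seq_control_matches_distance_distribution(self):
        from scipy.stats import ks_2samp
        ds = self.make_dataset(n_pos=60, n_neg=1500, seed=3)
        ctrl = ev.build_control_sets(ds, "seq_control", seed=3)
        pos_d = [ev.sequence_distance(p) for p in ctrl.pairs
                 if p.label == "positive"]
        neg_d = [ev.sequence_distance(p) for p in ctrl.pairs
                 if p.label == "negative"]
        assert ks_2samp(pos_d, neg_d).statistic < 0.2

    def test_set_random_reproducible(self):
        ds = self.make_dataset()
        a = ev.build_control_sets(ds, "set_random", seed=5)
        b = ev.build_control_sets(ds, "set_random", seed=5)
        assert [p.key() for p in a.pairs] == [p.key() for p in b.pairs]


class TestSingleFeatureProbe:
    def test_distance_feature_loses_signal_on_matched_control(self):
        ds = TestControlSets().make_dataset(n_pos=60, n_neg=1500, seed=4)

        def seq_distance_feature(dataset):
            return np.array([[ev.sequence_distance(p)]
                             for p in dataset.pairs])
        reports = ev.single_feature_probe(ds, seq_distance_feature, seed=0)
        # decile-bin matching removes most but not all of the signal
        # (within-bin residual); the drop from the random set is large
        assert reports["set_random"].auc > 0.75
        assert reports["seq_control"].auc < 0.68
        assert (reports["set_random"].auc
                - reports["seq_control"].auc) > 0.15

    def test_distance_independent_feature_is_stable(self):
        ds = TestControlSets().make_dataset(n_pos=250, n_neg=3000, seed=5)
        rng_feature = {}

        def planted_feature(dataset):
            out = []
            for p in dataset.pairs:
                if p.key() not in rng_feature:
                    noise = np.random.default_rng(
                        abs(hash(p.key())) % 2 ** 31).normal()
                    rng_feature[p.key()] = (
                        (1.0 if p.label == "positive" else 0.0) + 0.5 * noise)
                out.append([rng_feature[p.key()]])
            return np.array(out)
        reports = ev.single_feature_probe(ds, planted_feature, seed=0)
        aucs = [reports[m].auc for m in ("set_random", "seq_control",
                                         "str_control")]
        assert max(aucs) - min(aucs) < 0.05

    def test_probe_reproducible(self):
        ds = TestControlSets().make_dataset(n_pos=40, n_neg=600, seed=6)

        def f(dataset):
            return np.array([[ev.sequence_distance(p)] for p in dataset.pairs])
        a = ev.single_feature_probe(ds, f, seed=3)
        b = ev.single_feature_probe(ds, f, seed=3)
        assert a["set_random"].auc == b["set_random"].auc
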