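"""Pose classification, pair-equal weighting, bootstrap CIs, paired tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dockeval.errors import InsufficientDataError
from dockeval.pose_eval import (
    assign_weights,
    bootstrap_ci,
    classify_pose,
    paired_accuracy_test,
    partition_records,
    per_pair_fractions,
    weighted_accuracy,
)


def make_records(rows):
    """rows: (protein, ligand, receptor, kind, pose_rmsd, self_dock, similarity)."""
    return pd.DataFrame(rows, columns=[
        "protein_id", "ligand_id", "receptor_id", "receptor_kind",
        "pose_rmsd", "is_self_dock", "receptor_ligand_similarity"])


def random_manifest(rng, n_pairs=None):
    rows = []
    n_pairs = n_pairs or int(rng.integers(2, 10))
    for p in range(n_pairs):
        kinds = rng.choice(["experimental", "af2", "traditional"],
                           size=int(rng.integers(1, 4)), replace=False)
        for kind in kinds:
            for r in range(int(rng.integers(1, 5))):
                rows.append((f"P{p}", f"L{p}", f"R{kind}{r}", kind,
                             float(rng.uniform(0, 5)), False, np.nan))
    return make_records(rows)


class TestClassifyPose:
    @pytest.mark.parametrize("rmsd,expected", [
        (2.0, True),    # criterion is inclusive
        (0.0, True),
        (2.001, False),
    ])
    def test_threshold_rule(self, rmsd, expected):
        assert classify_pose(rmsd) is expected

    def test_negative_rmsd_rejected(self):
        with pytest.raises(ValueError):
            classify_pose(-0.1)


class TestPartitionRecords:
    BASE = [
        ("P1", "L1", "ref1", "experimental", 1.0, True, 1.0),
        ("P1", "L1", "xtal2", "experimental", 1.5, False, 0.75),
        ("P1", "L1", "af2a", "af2", 3.0, False, np.nan),
    ]

    def test_self_dock_exclusion(self):
        out = partition_records(make_records(self.BASE))
        assert len(out.records) == 2 and out.n_self_excluded == 1

    def test_similar_receptor_ligand_exclusion(self):
        out = partition_records(make_records(self.BASE),
                                exclude_similar_receptor_ligand=True)
        # similarity 0.75 >= 0.5 on an experimental receptor -> dropped
        assert len(out.records) == 1
        assert out.records.iloc[0]["receptor_kind"] == "af2"

    def test_both_filters_off_is_identity(self):
        df = make_records(self.BASE)
        out = partition_records(df, exclude_self_dock=False)
        pd.testing.assert_frame_equal(out.records, df)

    def test_disjoint_accounting(self):
        rng = np.random.default_rng(0)
        df = random_manifest(rng)
        df.loc[df.index[:2], "is_self_dock"] = True
        df["receptor_ligand_similarity"] = rng.uniform(0, 1, len(df))
        out = partition_records(df, exclude_similar_receptor_ligand=True)
        assert len(df) == len(out.records) + out.n_self_excluded + out.n_similar_excluded

    def test_missing_similarity_raises(self):
        df = make_records(self.BASE)
        df["receptor_ligand_similarity"] = np.nan
        with pytest.raises(ValueError):
            partition_records(df, exclude_similar_receptor_ligand=True)


class TestWeights:
    def test_inverse_group_size(self):
        rows = [("P1", "L1", f"T{i}", "traditional", 1.0, False, np.nan) for i in range(3)]
        rows.append(("P1", "L1", "A0", "af2", 1.0, False, np.nan))
        rows.append(("P2", "L2", "T0", "traditional", 1.0, False, np.nan))
        df = assign_weights(make_records(rows))
        trad_p1 = df[(df.protein_id == "P1") & (df.receptor_kind == "traditional")]
        assert np.allclose(trad_p1["weight"], 1 / 3)
        assert df[df.receptor_kind == "af2"]["weight"].iloc[0] == 1.0  # singleton
        assert df[df.protein_id == "P2"]["weight"].iloc[0] == 1.0
        # groups weighted independently per kind; each sums to 1
        sums = df.groupby(["protein_id", "ligand_id", "receptor_kind"])["weight"].sum()
        assert np.allclose(sums, 1.0)


class TestWeightedAccuracy:
    def test_per_pair_mean_worked_example(self):
        rows = [
            ("PA", "LA", "r1", "experimental", 1.0, False, np.nan),   # correct
            ("PA", "LA", "r2", "experimental", 3.0, False, np.nan),   # incorrect
            ("PB", "LB", "r1", "experimental", 0.5, False, np.nan),   # correct
        ]
        assert weighted_accuracy(make_records(rows)) == pytest.approx(0.75)

    def test_single_pair_four_receptors(self):
        rows = [("P", "L", f"r{i}", "af2", 0.5 if i == 0 else 4.0, False, np.nan)
                for i in range(4)]
        assert weighted_accuracy(make_records(rows)) == pytest.approx(0.25)

    def test_all_correct_is_one_and_empty_raises(self):
        rows = [("P", "L", "r", "af2", 0.1, False, np.nan)]
        assert weighted_accuracy(make_records(rows)) == 1.0
        with pytest.raises(InsufficientDataError):
            weighted_accuracy(make_records([]))

    def test_equals_mean_of_per_pair_fractions(self):
        # within a receptor kind each pair's weights sum to 1, so the
        # weighted average is exactly the unweighted mean of per-pair fractions
        rng = np.random.default_rng(5)
        for _ in range(25):
            df = random_manifest(rng)
            for _, group in df.groupby("receptor_kind"):
                want = per_pair_fractions(group).mean()
                assert weighted_accuracy(group) == pytest.approx(want, abs=1e-12)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(8)
        df = random_manifest(rng)
        target_pair = df[["protein_id", "ligand_id"]].iloc[0]
        dup_mask = (df.protein_id == target_pair.protein_id) & (
            df.ligand_id == target_pair.ligand_id)
        doubled = pd.concat([df, df[dup_mask]], ignore_index=True)
        assert weighted_accuracy(doubled) == pytest.approx(weighted_accuracy(df), abs=1e-12)


class TestBootstrapCi:
    def test_all_correct_degenerate_interval(self):
        rows = [(f"P{i}", f"L{i}", "r", "af2", 0.5, False, np.nan) for i in range(5)]
        assert bootstrap_ci(make_records(rows), n_resamples=199, seed=1) == (1.0, 1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        df = random_manifest(rng, n_pairs=12)
        a = bootstrap_ci(df, n_resamples=999, seed=7)
        b = bootstrap_ci(df, n_resamples=999, seed=7)
        assert a == b
        c = bootstrap_ci(df, n_resamples=999, seed=8)
        assert a != c

    def test_single_pair_warns_point_interval(self):
        rows = [("P", "L", f"r{i}", "af2", 1.0 if i else 4.0, False, np.nan)
                for i in range(3)]
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bootstrap_ci(make_records(rows), seed=0)
        assert lo == hi == pytest.approx(2 / 3)

    def test_width_shrinks_with_more_pairs(self):
        """Median CI width at 80 pairs < at 20 pairs over 50 seeded repeats."""
        def widths(n_pairs, seeds):
            out = []
            for s in seeds:
                rng = np.random.default_rng(s)
                rows = [(f"P{i}", f"L{i}", "r", "af2",
                         0.5 if rng.random() < 0.4 else 4.0, False, np.nan)
                        for i in range(n_pairs)]
                lo, hi = bootstrap_ci(make_records(rows), n_resamples=499, seed=s)
                out.append(hi - lo)
            return np.median(out)

        seeds = range(50)
        assert widths(80, seeds) < widths(20, seeds)


class TestPairedAccuracyTest:
    @staticmethod
    def _pair_records(fracs, kind):
        """One pair per fraction; fraction realized as k-correct-of-4 records."""
        rows = []
        for i, f in enumerate(fracs):
            k = int(round(f * 4))
            for r in range(4):
                rows.append((f"P{i}", f"L{i}", f"r{r}", kind,
                             1.0 if r < k else 4.0, False, np.nan))
        return make_records(rows)

    def test_identical_fractions_p_one(self):
        fracs = [0.25, 0.5, 0.75, 1.0]
        a = self._pair_records(fracs, "af2")
        b = self._pair_records(fracs, "traditional")
        with pytest.warns(UserWarning, match="p = 1"):
            assert paired_accuracy_test(a, b) == 1.0

    def test_hand_computed_t_statistic(self):
        """9 pairs differ by +0.5, one by 0: t = 9 on 9 df, textbook formula."""
        fa = [1.0] * 9 + [0.5]
        fb = [0.5] * 9 + [0.5]
        a = self._pair_records(fa, "af2")
        b = self._pair_records(fb, "traditional")
        diffs = np.array(fa) - np.array(fb)
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        expected = 2 * stats.t.sf(abs(t), len(diffs) - 1)
        assert t == pytest.approx(9.0)
        assert paired_accuracy_test(a, b) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        fa = rng.integers(0, 5, size=8) / 4
        fb = rng.integers(0, 5, size=8) / 4
        a = self._pair_records(fa, "af2")
        b = self._pair_records(fb, "traditional")
        assert paired_accuracy_test(a, b) == pytest.approx(paired_accuracy_test(b, a))

    def test_too_few_common_pairs_raises(self):
        a = self._pair_records([1.0], "af2")
        b = self._pair_records([0.5], "traditional")
        with pytest.raises(InsufficientDataError):
            paired_accuracy_test(a, b)
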