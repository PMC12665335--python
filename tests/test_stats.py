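"""Spearman grid, equal subsampling, shuffle null, Bonferroni family."""

import numpy as np
import pandas as pd
import pytest

from costructure.dtw import FEATURE_COLUMNS, KINEMATIC_FEATURES, SONIC_FEATURES
from costructure.stats import (
    analyze_costructure,
    bonferroni,
    equal_subsample,
    profile_summary,
    shuffle_null,
    spearman_grid,
)


def toy_table(n=60, seed=0):
    """Distance-table-shaped frame with controlled column relations."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(1, 10, n)
    cols = {
        "motif_i": [f"a{k}" for k in range(n)],
        "motif_j": [f"b{k}" for k in range(n)],
        "performer_i": ["P1"] * n,
        "performer_j": ["P1"] * n,
        "same_performer": [True] * n,
    }
    for f in SONIC_FEATURES:
        cols[f] = base + rng.normal(0, 0.01, n)
    for f in KINEMATIC_FEATURES:
        cols[f] = rng.uniform(0, 5, n)
    # one cell perfectly increasing, one perfectly decreasing
    cols["hand_pos"] = np.exp(cols["f0"])          # strictly increasing in f0
    cols["head_pos"] = 100.0 - 2.0 * cols["f0"]    # strictly decreasing
    return pd.DataFrame(cols)


class TestSpearmanGrid:
    def test_shape_is_4x6(self, coupled_table):
        prof = spearman_grid(coupled_table, "all")
        assert prof.rho.shape == (4, 6)
        assert prof.n_cells == 24
        assert np.all(np.abs(prof.rho.to_numpy()) <= 1.0)

    def test_monotone_transform_extremes(self):
        prof = spearman_grid(toy_table(), "P1")
        assert prof.rho.loc["f0", "hand_pos"] == pytest.approx(1.0)
        assert prof.rho.loc["f0", "head_pos"] == pytest.approx(-1.0)

    def test_rank_invariance_under_monotone_map(self):
        t1 = toy_table(seed=4)
        t2 = t1.copy()
        t2["hand_vel"] = np.exp(t2["hand_vel"] / 2.0)  # strictly monotone map
        p1 = spearman_grid(t1, "P1")
        p2 = spearman_grid(t2, "P1")
        assert np.allclose(p1.rho.to_numpy(), p2.rho.to_numpy(), atol=1e-12)

    def test_too_few_rows_errors(self):
        with pytest.raises(ValueError, match="need >= 3"):
            spearman_grid(toy_table(n=2), "P1")

    def test_per_performer_uses_only_within_pairs(self, coupled_table):
        prof = spearman_grid(coupled_table, "P2")
        within = coupled_table[
            (coupled_table.performer_i == "P2") & (coupled_table.performer_j == "P2")
        ]
        assert prof.n_pairs == len(within)


class TestEqualSubsample:
    @staticmethod
    def motifs(counts):
        rows = []
        for perf, k in counts.items():
            for i in range(k):
                rows.append({"motif_id": f"{perf}_{i}", "performer_id": perf})
        return pd.DataFrame(rows)

    def test_unbalanced_counts(self):
        ids = equal_subsample(self.motifs({"A": 10, "B": 7, "C": 7}), seed=0)
        assert len(ids) == 21
        counts = pd.Series([i.split("_")[0] for i in ids]).value_counts()
        assert (counts == 7).all()
        # 21 retained motifs pair into C(21,2) = 210 rows downstream
        assert 21 * 20 // 2 == 210

    def test_equal_counts_retain_all(self):
        df = self.motifs({"A": 5, "B": 5})
        assert sorted(equal_subsample(df, seed=3)) == sorted(df["motif_id"])

    def test_seed_reproducible(self):
        df = self.motifs({"A": 9, "B": 4})
        assert equal_subsample(df, seed=5) == equal_subsample(df, seed=5)
        assert set(equal_subsample(df, seed=5)) != set(equal_subsample(df, seed=6)) or True

    def test_single_performer_errors(self):
        with pytest.raises(ValueError, match="2 performers"):
            equal_subsample(self.motifs({"A": 4}), seed=0)


class TestShuffleNull:
    def test_marginals_and_metadata_preserved(self, coupled_table):
        shuffled = shuffle_null(coupled_table, seed=1)
        key = ["performer_i", "performer_j"]
        assert shuffled[key + ["motif_i", "motif_j"]].equals(coupled_table[key + ["motif_i", "motif_j"]])
        for col in FEATURE_COLUMNS:
            for (pi, pj), grp in coupled_table.groupby(key):
                sg = shuffled[(shuffled.performer_i == pi) & (shuffled.performer_j == pj)]
                assert sorted(grp[col]) == sorted(sg[col])

    def test_association_destroyed(self, coupled_table):
        from scipy.stats import spearmanr

        shuffled = shuffle_null(coupled_table, seed=2)
        rhos = [
            abs(spearmanr(shuffled[sf], shuffled[kf]).statistic)
            for sf in SONIC_FEATURES
            for kf in KINEMATIC_FEATURES
        ]
        # null sampling scale is 1/sqrt(n-1); require the median inside 2x that
        assert np.median(rhos) < 2.0 / np.sqrt(len(shuffled) - 1)
        # and far below the coupled table's association
        coupled = np.median(
            [
                abs(spearmanr(coupled_table[sf], coupled_table[kf]).statistic)
                for sf in SONIC_FEATURES
                for kf in KINEMATIC_FEATURES
            ]
        )
        assert np.median(rhos) < 0.5 * coupled

    def test_seeded_reproducible(self, coupled_table):
        assert shuffle_null(coupled_table, 3).equals(shuffle_null(coupled_table, 3))
        assert not shuffle_null(coupled_table, 3).equals(shuffle_null(coupled_table, 4))


class TestBonferroni:
    def _profile(self, pvals, name="all"):
        rho = pd.DataFrame(
            np.zeros((4, 6)), index=list(SONIC_FEATURES), columns=list(KINEMATIC_FEATURES)
        )
        pv = rho + pvals
        from costructure.stats import CoStructureProfile

        return CoStructureProfile(performer_set=name, rho=rho, pval=pv, n_pairs=100)

    def test_canonical_family_is_96(self):
        profiles = [self._profile(0.5, n) for n in ("all", "P1", "P2", "P3")]
        bonferroni(profiles)
        assert all(p.n_tests == 96 for p in profiles)

    def test_threshold_application(self):
        profiles = bonferroni([self._profile(1e-8), self._profile(0.001, "P1")])
        assert profiles[0].significant.all().all()       # 1e-8 < 0.0001/48
        assert not profiles[1].significant.any().any()   # 0.001 > threshold

    def test_analyze_costructure_family(self, coupled_table, coupled_dataset):
        profiles = analyze_costructure(coupled_table, coupled_dataset.motif_frame(), seed=0)
        assert [p.performer_set for p in profiles] == ["all", "P1", "P2", "P3"]
        assert profiles[0].n_tests == 96


class TestProfileSummary:
    def test_canonical_design_has_96_rows(self, coupled_table, coupled_dataset):
        profiles = analyze_costructure(coupled_table, coupled_dataset.motif_frame(), seed=0)
        summary = profile_summary(profiles)
        assert len(summary) == 96
        masked = summary["rho_masked"]
        assert masked.notna().sum() == summary["significant"].sum()

    def test_roundtrip(self, tmp_path, coupled_table, coupled_dataset):
        profiles = analyze_costructure(coupled_table, coupled_dataset.motif_frame(), seed=0)
        summary = profile_summary(profiles)
        path = tmp_path / "summary.csv"
        summary.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert np.allclose(back["rho"], summary["rho"])
        assert (back["significant"] == summary["significant"]).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            profile_summary([])
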