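import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnapipe.crossspecies import (ProjectedProfile, SyntenyBlock, map_position,
                                  project_profile, read_projected,
                                  read_synteny_blocks, resolve_blocks,
                                  similarity_index, similarity_matrix,
                                  write_projected, write_synteny_blocks)

from _oracles import oracle_pearson

FWD = SyntenyBlock("chr1", 100, 200, "h1", 1000, 1100, "forward")
REV = SyntenyBlock("chr1", 100, 200, "h1", 1000, 1100, "reverse")


def projected(values, sample_id="p", group=""):
    values = np.asarray(values, dtype=float)
    grid = pd.DataFrame({"chromosome": "h1",
                         "position": np.arange(len(values)) * 100})
    return ProjectedProfile(sample_id=sample_id, grid=grid, values=values,
                            group=group)


class TestMapPosition:
    def test_forward_linear(self):
        assert map_position("h1", 1050, [FWD]) == ("chr1", 150)

    def test_reverse_reflection(self):
        assert map_position("h1", 1050, [REV]) == ("chr1", 149)

    def test_outside_all_blocks_is_missing(self):
        assert map_position("h1", 5000, [FWD]) is None
        assert map_position("h2", 1050, [FWD]) is None

    def test_length_mismatch_is_proportional(self):
        blk = SyntenyBlock("chr1", 0, 50, "h1", 0, 100, "forward")
        assert map_position("h1", 50, [blk]) == ("chr1", 25)
        assert map_position("h1", 98, [blk]) == ("chr1", 49)

    @given(st.integers(0, 99))
    def test_forward_and_reverse_are_mirror_images(self, offset):
        f = map_position("h1", 1000 + offset, [FWD])[1]
        r = map_position("h1", 1000 + offset, [REV])[1]
        assert f + r == FWD.src_start + FWD.src_end - 1

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            SyntenyBlock("chr1", 10, 10, "h1", 0, 5)

    def test_overlap_resolution_keeps_longer(self):
        short = SyntenyBlock("chr2", 0, 50, "h1", 1020, 1070, "forward")
        with pytest.warns(UserWarning, match="dropping"):
            kept = resolve_blocks([FWD, short])
        assert kept == [FWD]


class TestProjectProfile:
    def _cn(self, segments):
        """Segment-level stand-in for a fitted profile (chr1 coordinates)."""
        from cnapipe.cn_estimation import CopyNumberProfile, TumorModel
        df = pd.DataFrame(segments, columns=["chromosome", "genomic_start",
                                             "genomic_end", "log2_cn_over_ploidy"])
        return CopyNumberProfile(sample_id="x", model=TumorModel(1.0, 2.0),
                                 segments=df)

    def test_neutral_profile_projects_to_zero(self):
        cn = self._cn([("chr1", 0, 1000, 0.0)])
        blocks = [SyntenyBlock("chr1", 0, 1000, "h1", 0, 1000, "forward")]
        grid = pd.DataFrame({"chromosome": "h1", "position": [10, 500, 990]})
        proj = project_profile(cn, blocks, grid)
        assert np.allclose(proj.values, 0.0)

    def test_amplified_segment_value_carried(self):
        cn = self._cn([("chr1", 0, 500, 0.0), ("chr1", 500, 1000, 1.0)])
        blocks = [SyntenyBlock("chr1", 0, 1000, "h1", 0, 1000, "forward")]
        grid = pd.DataFrame({"chromosome": "h1", "position": [100, 700]})
        proj = project_profile(cn, blocks, grid)
        assert proj.values.tolist() == [0.0, 1.0]

    def test_three_block_manual_lookup(self):
        cn = self._cn([("chr1", 0, 300, -1.0), ("chr1", 300, 600, 0.0),
                       ("chr1", 600, 900, 0.585)])
        blocks = [
            SyntenyBlock("chr1", 0, 300, "h1", 0, 300, "forward"),
            SyntenyBlock("chr1", 300, 600, "h1", 600, 900, "reverse"),
            SyntenyBlock("chr1", 600, 900, "h2", 0, 300, "forward"),
        ]
        grid = pd.DataFrame({
            "chromosome": ["h1", "h1", "h1", "h2", "h3"],
            "position": [150, 700, 899, 10, 5],
        })
        proj = project_profile(cn, blocks, grid)
        # manual: h1:150 -> chr1:150 (-1.0); h1:700 reverse -> chr1 in [300,600) (0.0);
        # h1:899 -> chr1:300 (0.0); h2:10 -> chr1:610 (0.585); h3 unmapped
        expected = [-1.0, 0.0, 0.0, 0.585, np.nan]
        assert np.allclose(proj.values, expected, equal_nan=True)

    def test_round_trip_tsv(self, tmp_path):
        prof = projected([0.0, 1.0, np.nan, -0.5], sample_id="s9", group="rat")
        path = tmp_path / "proj.tsv"
        write_projected(prof, path)
        back = read_projected(path)
        assert back.sample_id == "s9" and back.group == "rat"
        assert np.allclose(back.values, prof.values, equal_nan=True)


class TestSimilarityIndex:
    def test_self_similarity_is_1000(self):
        a = projected([0.0, 1.0, -0.5, 0.3, 0.0, 0.2, -1.0, 0.4, 0.1, -0.2])
        assert similarity_index(a, a) == pytest.approx(1000.0)

    def test_negation_gives_minus_1000(self):
        a = projected(np.linspace(-1, 1, 12))
        b = projected(-a.values)
        assert similarity_index(a, b) == pytest.approx(-1000.0)

    def test_sqrt_scaling_of_known_r(self):
        # construct vectors whose Pearson r is exact: y = a*x + b*z with
        # z centered and orthogonal to centered x
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        x -= x.mean()
        z = rng.normal(size=200)
        z -= z.mean()
        z -= z.dot(x) / x.dot(x) * x
        for r, expected in ((0.25, 500.0), (-0.49, -700.0)):
            y = (r / np.linalg.norm(x)) * x \
                + (np.sqrt(1 - r * r) / np.linalg.norm(z)) * z
            s = similarity_index(projected(x), projected(y))
            assert s == pytest.approx(expected, abs=1e-6)

    def test_minimum_overlap_enforced(self):
        a = projected([0.0, 1.0, np.nan, np.nan])
        b = projected([0.0, 1.0, 0.5, np.nan])
        with pytest.raises(ValueError, match="overlap"):
            similarity_index(a, b, min_overlap=10)

    def test_constant_overlap_rejected(self):
        a = projected(np.zeros(20))
        b = projected(np.arange(20.0))
        with pytest.raises(ValueError, match="variance"):
            similarity_index(a, b)

    @given(st.integers(0, 10_000))
    def test_bounded_and_sign_consistent(self, seed):
        rng = np.random.default_rng(seed)
        a = projected(rng.normal(size=15))
        b = projected(rng.normal(size=15))
        s = similarity_index(a, b)
        assert -1000.0 <= s <= 1000.0
        assert np.sign(s) == np.sign(oracle_pearson(a.values, b.values))


class TestSimilarityMatrix:
    def _cohort(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=40)
        return [
            projected(base + rng.normal(0, 0.2, 40), "r1", "rat"),
            projected(base + rng.normal(0, 0.2, 40), "r2", "rat"),
            projected(rng.normal(size=40), "h1", "human"),
            projected(rng.normal(size=40), "h2", "human"),
        ]

    def test_matrix_matches_per_pair_oracle(self):
        profs = self._cohort()
        mat, _ = similarity_matrix(profs)
        for i, a in enumerate(profs):
            for j, b in enumerate(profs):
                if i == j:
                    assert mat.iloc[i, j] == 1000.0
                else:
                    r = oracle_pearson(a.values, b.values)
                    assert mat.iloc[i, j] == pytest.approx(
                        np.sign(r) * np.sqrt(abs(r)) * 1000.0)

    def test_matrix_symmetric(self):
        mat, _ = similarity_matrix(self._cohort())
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_group_summary_is_direct_arithmetic(self):
        profs = self._cohort()
        mat, summary = similarity_matrix(profs)
        m = mat.to_numpy()
        lookup = {(r["group_a"], r["group_b"]): r["mean_similarity"]
                  for _, r in summary.iterrows()}
        assert lookup[("rat", "rat")] == pytest.approx((m[0, 1] + m[1, 0]) / 2)
        cross = [m[0, 2], m[0, 3], m[1, 2], m[1, 3]]
        assert lookup[("rat", "human")] == pytest.approx(np.mean(cross))
        assert lookup[("rat", "human")] == lookup[("human", "rat")]

    def test_identical_groups_of_identical_profiles_score_1000(self):
        v = np.sin(np.arange(20.0))
        profs = [projected(v, f"s{k}", "g") for k in range(3)]
        mat, summary = similarity_matrix(profs)
        assert np.allclose(mat.to_numpy(), 1000.0)
        assert summary["mean_similarity"].tolist() == [pytest.approx(1000.0)]

    def test_synteny_tsv_round_trip(self, tmp_path):
        blocks = [FWD, SyntenyBlock("chr2", 5, 25, "h2", 0, 20, "reverse")]
        path = tmp_path / "blocks.tsv"
        write_synteny_blocks(blocks, path)
        assert read_synteny_blocks(path) == blocks
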