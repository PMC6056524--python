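import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ithshift.profiles import (
    RescueThresholds,
    admit_variants,
    build_profile,
    categorize,
    estimate_tumor_content,
    order_for_heatmap,
    pca_sample_colors,
    rescue_presence,
)
from ithshift.types import CaseTable, MultiregionProfile

from conftest import make_case


def one_sided_fisher_oracle(b, d, nb, nd):
    """P(X >= b) for X ~ Hypergeometric(total=d+nd, successes=b+nb, draws=d),
    by direct enumeration of the tail."""
    total, succ = d + nd, b + nb
    denom = math.comb(total, d)
    p = 0.0
    for k in range(b, min(d, succ) + 1):
        p += math.comb(succ, k) * math.comb(total - succ, d - k) / denom
    return p


class TestAdmission:
    def test_flag_in_one_sample_admits(self):
        table = make_case([[1, 0, 0, 0, 0]], depth=11)
        assert admit_variants(table.counts).tolist() == [True]

    def test_never_flagged_excluded(self):
        table = make_case([[0, 0, 0]], depth=50)
        assert admit_variants(table.counts).tolist() == [False]

    def test_depth_boundary_is_strict(self):
        # coverage of exactly ten reads in any sample excludes the variant
        table = make_case([[1, 1, 1, 0]], depth=11)
        table.counts.depth[0, 3] = 10
        table.counts.alt_reads[0, 3] = 0
        assert admit_variants(table.counts).tolist() == [False]
        table.counts.depth[0, 3] = 11
        assert admit_variants(table.counts).tolist() == [True]

    def test_zero_samples_is_an_error(self):
        table = make_case([[1]])
        table.counts.depth = table.counts.depth[:, :0]
        table.counts.alt_reads = table.counts.alt_reads[:, :0]
        table.counts.caller_flag = table.counts.caller_flag[:, :0]
        with pytest.raises(ValueError, match="zero samples"):
            admit_variants(table.counts)


class TestRescue:
    def _counts(self, b, d, nb=0, nd=100):
        table = make_case([[0, 1]], depth=d)
        table.counts.alt_reads[0, 0] = b
        table.counts.normal_depth[0] = nd
        table.counts.normal_alt_reads[0] = nb
        return table.counts

    def test_clear_signal_is_rescued_and_matches_enumeration(self):
        counts = self._counts(b=8, d=100, nb=0, nd=100)
        p = one_sided_fisher_oracle(8, 100, 0, 100)
        assert p <= 0.05  # oracle agrees the table is significant
        assert rescue_presence(0, 0, counts) is True

    def test_low_tumor_vaf_fails(self):
        assert rescue_presence(0, 0, self._counts(b=4, d=100)) is False

    def test_high_normal_vaf_fails(self):
        assert rescue_presence(0, 0, self._counts(b=8, d=100, nb=2, nd=100)) is False

    def test_zero_depth_fails(self):
        counts = self._counts(b=0, d=100)
        counts.depth[0, 0] = 0
        counts.alt_reads[0, 0] = 0
        assert rescue_presence(0, 0, counts) is False

    @given(st.integers(min_value=5, max_value=60))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_alt_reads(self, b):
        """More variant reads at fixed depth never flips rescued -> not."""
        d = 100
        lo = rescue_presence(0, 0, self._counts(b=b, d=d))
        hi = rescue_presence(0, 0, self._counts(b=b + 5, d=d))
        assert (not lo) or hi

    def test_scipy_one_sided_p_matches_enumeration(self):
        from scipy.stats import fisher_exact

        for b, d, nb, nd in [(8, 100, 0, 100), (6, 80, 1, 120), (12, 50, 2, 60)]:
            _, p = fisher_exact([[b, d - b], [nb, nd - nb]], alternative="greater")
            assert p == pytest.approx(one_sided_fisher_oracle(b, d, nb, nd), abs=1e-12)


class TestCategorize:
    def test_definitions(self):
        table = make_case([[1, 1, 1, 1], [1, 1, 0, 0], [0, 0, 1, 0]])
        prof = build_profile(table)
        assert prof.category.tolist() == ["ubiquitous", "shared", "private"]

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_partition_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        presence = rng.random((rng.integers(1, 12), 6)) < 0.5
        presence[:, rng.integers(6)] = True
        prof = MultiregionProfile(
            case_id="X",
            samples=make_case(np.ones((1, 6))).samples,
            variants=make_case(np.ones((presence.shape[0], 1))).variants,
            presence=presence,
            vaf=presence * 0.4,
            category=np.empty(presence.shape[0], dtype=object),
        )
        categorize(prof)
        for row, cat in zip(presence, prof.category):
            k = int(row.sum())  # brute-force recount by definition
            expect = "ubiquitous" if k == 6 else ("private" if k == 1 else "shared")
            assert cat == expect

    def test_partition_is_exhaustive_and_exclusive(self):
        table = make_case(np.eye(5, dtype=bool) | np.ones((5, 5), bool).cumsum(0) % 2)
        prof = build_profile(table)
        assert set(prof.category) <= {"ubiquitous", "shared", "private"}
        assert (prof.category != None).all()  # noqa: E711


class TestHeatmapOrder:
    def test_all_ubiquitous_is_genomic_sort(self):
        table = make_case(np.ones((4, 3)))
        # variants created on chroms 1..4 at increasing pos: already genomic
        prof = build_profile(table)
        assert order_for_heatmap(prof).tolist() == [0, 1, 2, 3]

    def test_identical_shared_rows_are_adjacent(self):
        presence = np.array(
            [
                [1, 1, 1, 1],  # ubiquitous
                [1, 1, 0, 0],  # shared pattern A
                [0, 0, 1, 1],  # shared pattern B
                [1, 1, 0, 0],  # shared pattern A again
                [0, 1, 0, 0],  # private
            ]
        )
        prof = build_profile(make_case(presence))
        order = order_for_heatmap(prof).tolist()
        shared_block = [i for i in order if prof.category[i] == "shared"]
        pos = {i: shared_block.index(i) for i in (1, 3)}
        assert abs(pos[1] - pos[3]) == 1  # zero-distance pair stays together

    def test_golden_order_on_fixed_fixture(self):
        presence = np.array(
            [
                [1, 1, 1],
                [1, 1, 1],
                [1, 1, 0],
                [0, 1, 1],
                [1, 1, 0],
                [1, 0, 0],
                [0, 1, 0],
                [0, 1, 0],
            ]
        )
        vafs = presence * np.array(
            [[0.5], [0.4], [0.3], [0.3], [0.3], [0.2], [0.45], [0.1]]
        )
        prof = build_profile(make_case(presence, vafs=vafs))
        # blocks: ubiquitous {0,1} genomic; shared {2,3,4} clustered with the
        # identical rows 2 and 4 adjacent; private {5,6,7} by (sample, -VAF)
        order = order_for_heatmap(prof).tolist()
        assert order[:2] == [0, 1]
        shared = order[2:5]
        assert set(shared) == {2, 3, 4} and abs(
            shared.index(2) - shared.index(4)
        ) == 1
        assert order[5:] == [5, 6, 7]  # sample 0 first; within sample 1, VAF desc


class TestPcaColors:
    def test_identical_profiles_share_a_color(self):
        presence = np.tile(np.array([[1], [1], [0], [1]]).T, (4, 1))
        prof = build_profile(make_case(presence))
        colors = pca_sample_colors(prof)
        vals = list(colors.values())
        assert vals[0] == pytest.approx(vals[1], abs=1e-9)
        assert vals[0] == pytest.approx(vals[3], abs=1e-9)

    def test_cluster_separation_exceeds_within_cluster_distance(self):
        presence = np.zeros((10, 6), dtype=bool)
        presence[:5, :3] = True  # variants 0-4 in samples 0-2
        presence[5:, 3:] = True  # variants 5-9 in samples 3-5
        presence[0, :] = True  # one ubiquitous variant keeps admission valid
        prof = build_profile(make_case(presence))
        colors = np.array(list(pca_sample_colors(prof).values()))
        within = max(
            np.linalg.norm(colors[0] - colors[1]),
            np.linalg.norm(colors[3] - colors[4]),
        )
        between = np.linalg.norm(colors[0] - colors[3])
        assert between > within

    def test_invariant_to_variant_order(self):
        rng = np.random.default_rng(5)
        presence = rng.random((12, 4)) < 0.5
        presence[0] = True
        prof = build_profile(make_case(presence))
        colors = pca_sample_colors(prof)
        perm = rng.permutation(len(prof.variants))
        prof2 = MultiregionProfile(
            case_id=prof.case_id,
            samples=prof.samples,
            variants=[prof.variants[i] for i in perm],
            presence=prof.presence[perm],
            vaf=prof.vaf[perm],
            category=prof.category[perm],
        )
        colors2 = pca_sample_colors(prof2)
        for sid in colors:
            assert colors[sid] == pytest.approx(colors2[sid], abs=1e-9)


class TestTumorContent:
    def _profile(self, vafs):
        vafs = np.asarray(vafs, dtype=float)[:, None]
        presence = np.ones_like(vafs, dtype=bool)
        return build_profile(make_case(presence, vafs=vafs))

    def test_doubled_median(self):
        assert estimate_tumor_content(self._profile([0.25, 0.25, 0.25]),
                                      "PCRC01_1C") == pytest.approx(0.5)
        assert estimate_tumor_content(self._profile([0.2, 0.3, 0.4]),
                                      "PCRC01_1C") == pytest.approx(0.6)

    def test_capped_at_one(self):
        assert estimate_tumor_content(self._profile([0.6, 0.6]), "PCRC01_1C") == 1.0

    def test_no_ubiquitous_variants_is_an_error(self):
        table = make_case([[1, 0], [0, 1]])
        prof = build_profile(table)
        with pytest.raises(ValueError, match="supply tumor content"):
            estimate_tumor_content(prof, prof.samples[0].sample_id)


def test_category_recovery_on_clean_deep_synthetic(small_sim):
    """With zero normal error and 1000x coverage, recovered categories match
    the simulated truth for almost all admitted variants."""
    samples, variants, counts, _, truth = small_sim
    prof = build_profile(CaseTable(samples, variants, counts))
    truth_by_key = {
        v.key(): truth.category[i] for i, v in enumerate(variants)
    }
    agree = sum(
        truth_by_key[v.key()] == prof.category[i]
        for i, v in enumerate(prof.variants)
    )
    assert agree / len(prof.variants) > 0.99
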