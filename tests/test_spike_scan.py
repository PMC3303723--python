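"""Conservation profiles, Welch tests, spike detection and BH-FDR."""

import math

import numpy as np
import pytest
from scipy import stats

from esrscan.alignment_io import ExonAlignment, column_match_proportion
from esrscan.phylo_clusters import ALL_SPECIES, build_cluster_set
from esrscan.spike_scan import (
    arcsine,
    bh_fdr,
    conservation_profile,
    correct_all,
    detect_spikes,
    scan_exon,
    welch_t,
)
from esrscan.synthetic_fixtures import AlignmentSimSpec, PlantedMotif, make_alignment


# -- independent oracles ----------------------------------------------------


def welch_oracle(v1, v2):
    """Textbook Welch computation, written directly from the formulas."""
    n1, n2 = len(v1), len(v2)
    m1 = sum(v1) / n1
    m2 = sum(v2) / n2
    s1sq = sum((x - m1) ** 2 for x in v1) / (n1 - 1)
    s2sq = sum((x - m2) ** 2 for x in v2) / (n2 - 1)
    t = (m1 - m2) / math.sqrt(s1sq / n1 + s2sq / n2)
    df = (s1sq / n1 + s2sq / n2) ** 2 / (
        (s1sq / n1) ** 2 / (n1 - 1) + (s2sq / n2) ** 2 / (n2 - 1)
    )
    p = 1.0 - stats.t.cdf(t, df)
    return t, df, p


def bh_oracle(p):
    """Step-up BH: p(i)*n/i, then running minimum from the largest rank."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


# -- profile ----------------------------------------------------------------


class TestConservationProfile:
    def test_fully_conserved_profile_is_one(self, conserved_alignment, all_cluster):
        prof = conservation_profile(conserved_alignment, all_cluster, w=6)
        assert np.allclose(prof.c, 1.0)
        assert len(prof.c) == conserved_alignment.columns - 6 + 1

    def test_window_is_mean_of_columns(self, all_cluster):
        # hand-check c[0] against known per-column proportions [1,1,1,.5,1,1]
        rows = {"dm2": "AAAAAA"}
        for i, sp in enumerate(s for s in ALL_SPECIES if s != "dm2"):
            # at column 3, half the non-reference species mismatch
            seq = list("AAAAAA")
            if i < 7:
                seq[3] = "C"
            rows[sp] = "".join(seq)
        aln = ExonAlignment(gene_id="g", exon_id="e", reference_species="dm2",
                            rows=rows, ref_coords=np.arange(6))
        prof = conservation_profile(aln, all_cluster, w=6)
        assert prof.column_p[3] == pytest.approx(8 / 15)
        assert prof.c[0] == pytest.approx((5 + 8 / 15) / 6)

    def test_window_equal_to_columns_single_score(self, conserved_alignment,
                                                  all_cluster):
        prof = conservation_profile(conserved_alignment, all_cluster,
                                    w=conserved_alignment.columns)
        assert len(prof.c) == 1
        assert prof.c[0] == pytest.approx(prof.column_p.mean())

    def test_fewer_columns_than_window_gives_empty_profile(self, all_cluster):
        spec = AlignmentSimSpec(species=tuple(ALL_SPECIES), length=4, seed=0,
                                match_prob=1.0)
        aln, _ = make_alignment(spec)
        prof = conservation_profile(aln, all_cluster, w=6)
        assert len(prof.c) == 0

    def test_matches_column_match_proportion(self, all_cluster):
        # vectorized per-column scores agree with the scalar definition
        rng = np.random.default_rng(11)
        for trial in range(25):
            spec = AlignmentSimSpec(
                species=tuple(ALL_SPECIES), length=20,
                seed=int(rng.integers(1 << 30)),
                match_prob=float(rng.uniform(0.2, 1.0)),
            )
            aln, _ = make_alignment(spec)
            prof = conservation_profile(aln, all_cluster, w=6)
            col = int(rng.integers(20))
            expected = column_match_proportion(aln, col, list(all_cluster.species))
            assert prof.column_p[col] == pytest.approx(expected)


class TestArcsine:
    def test_endpoints(self):
        assert arcsine(0.0) == 0.0
        assert arcsine(1.0) == pytest.approx(math.pi / 2)

    def test_quarter(self):
        assert arcsine(0.25) == pytest.approx(math.pi / 6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            arcsine(1.5)

    def test_monotone(self):
        p = np.linspace(0, 1, 101)
        assert np.all(np.diff(arcsine(p)) > 0)


class TestWelch:
    def test_identical_windows(self):
        v = [0.5, 0.6, 0.7, 0.5, 0.6, 0.7]
        t, df, p = welch_t(v, v)
        assert t == 0.0 and p == 0.5

    def test_matches_textbook_oracle(self):
        v1 = [0.9, 1.0, 0.8, 0.95, 0.85, 0.9]
        v2 = [0.5, 0.6, 0.4, 0.55, 0.45, 0.5]
        t, df, p = welch_t(v1, v2)
        et, edf, ep = welch_oracle(v1, v2)
        assert t == pytest.approx(et, abs=1e-9)
        assert df == pytest.approx(edf, abs=1e-9)
        assert p == pytest.approx(ep, abs=1e-9)

    def test_oracle_agreement_on_random_windows(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            v1 = rng.uniform(0, math.pi / 2, 6)
            v2 = rng.uniform(0, math.pi / 2, 6)
            t, df, p = welch_t(v1, v2)
            et, edf, ep = welch_oracle(list(v1), list(v2))
            assert t == pytest.approx(et, abs=1e-9)
            assert df == pytest.approx(edf, abs=1e-9)
            assert p == pytest.approx(ep, abs=1e-9)

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(1)
        v1, v2 = rng.uniform(0, 1, 6), rng.uniform(0, 1, 6)
        t, df, p = welch_t(v1, v2, two_sided=True)
        res = stats.ttest_ind(v1, v2, equal_var=False)
        assert t == pytest.approx(res.statistic, abs=1e-12)
        assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_degenerate_zero_variance(self):
        t, _, p = welch_t([1.0] * 6, [0.5] * 6)
        assert t == math.inf and p == 0.0
        t, _, p = welch_t([0.5] * 6, [1.0] * 6)
        assert t == -math.inf and p == 1.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(2)
        v1, v2 = rng.uniform(0, 1, 6), rng.uniform(0, 1, 6)
        t12, _, _ = welch_t(v1, v2)
        t21, _, _ = welch_t(v2, v1)
        assert t12 == pytest.approx(-t21)

    def test_length_checks(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [0.5])
        with pytest.raises(ValueError):
            welch_t([1, 2, 3], [1, 2])


class TestBhFdr:
    def test_single_p(self):
        assert list(bh_fdr([0.01])) == [0.01]

    def test_uniform_grid(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_ties(self):
        assert np.allclose(bh_fdr([0.05, 0.05]), [0.05, 0.05])

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 201))
            p = rng.uniform(0, 1, n)
            assert np.allclose(bh_fdr(p), bh_oracle(list(p)), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDetectSpikes:
    def test_flat_profile_no_candidates(self, conserved_alignment, all_cluster):
        prof = conservation_profile(conserved_alignment, all_cluster, w=6)
        assert detect_spikes(prof, all_cluster) == []

    def test_planted_motif_single_interior_spike(self, planted_alignment):
        # a threshold-1 gate admits only the perfectly conserved window,
        # so the planted hexamer is recovered as exactly one spike
        strict = build_cluster_set(
            [{"name": "strict", "species": list(ALL_SPECIES), "s": 0.039669,
              "override_threshold": 1.0}],
            reference="strict",
        )["strict"]
        aln, truth = planted_alignment
        spikes = scan_exon(aln, [strict], w=6)
        sig = [s for s in spikes if s.significant() and s.boundary == "none"]
        assert [s.x for s in sig] == [truth[0].offset]
        assert sig[0].c_center == pytest.approx(1.0)
        assert sig[0].motif == aln.reference_row()[27:33]

    def test_planted_start_recovered_at_table_threshold(self, planted_alignment,
                                                        all_cluster):
        # at the looser all-species threshold, windows overlapping the plant
        # may also fire, but the planted start itself is always among them
        aln, truth = planted_alignment
        spikes = scan_exon(aln, [all_cluster], w=6)
        sig_x = [s.x for s in spikes if s.significant() and s.boundary == "none"]
        assert truth[0].offset in sig_x

    def test_edge_plant_requires_elevated_threshold(self, all_cluster):
        spec = AlignmentSimSpec(
            species=tuple(ALL_SPECIES), length=40, seed=8, match_prob=0.5,
            planted=(PlantedMotif(offset=0, length=6),),
        )
        aln, _ = make_alignment(spec)
        prof = conservation_profile(aln, all_cluster, w=6)
        spikes = detect_spikes(prof, all_cluster)
        edge = [s for s in spikes if s.x == 0]
        assert edge and edge[0].boundary == "left_edge"
        assert edge[0].c_center >= min(all_cluster.threshold + 0.1, 1.0)
        assert edge[0].p_left is None and edge[0].p_right is not None

    def test_interior_spike_carries_both_tests(self, planted_alignment, all_cluster):
        aln, truth = planted_alignment
        spikes = [s for s in scan_exon(aln, [all_cluster]) if s.x == truth[0].offset]
        s = spikes[0]
        assert s.p_left is not None and s.p_right is not None
        assert s.c_left < s.c_center > s.c_right


class TestCorrectAll:
    def test_pool_sizes_add_across_exons(self, all_cluster):
        spikes = []
        for seed in (21, 22):
            spec = AlignmentSimSpec(
                species=tuple(ALL_SPECIES), length=60, seed=seed, match_prob=0.5,
                planted=(PlantedMotif(offset=27, length=6),),
            )
            aln, _ = make_alignment(spec)
            aln.exon_id = f"e{seed}"
            spikes.extend(scan_exon(aln, [all_cluster]))
        corrected = correct_all(spikes)
        assert len(corrected) == len(spikes)
        lefts = [s for s in corrected if s.p_left is not None]
        assert all(s.q_left is not None for s in lefts)
        # BH over the pooled lefts reproduces the assigned q values
        pooled = bh_oracle([s.p_left for s in lefts])
        assert np.allclose([s.q_left for s in lefts], pooled)

    def test_all_ones_stay_ones(self, planted_alignment, all_cluster):
        aln, _ = planted_alignment
        spikes = scan_exon(aln, [all_cluster])
        forced = [type(s)(**{**s.__dict__, "p_left": 1.0 if s.p_left is not None
                             else None,
                             "p_right": 1.0 if s.p_right is not None else None})
                  for s in spikes]
        corrected = correct_all(forced)
        for s in corrected:
            assert s.q_left in (None, 1.0) and s.q_right in (None, 1.0)
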