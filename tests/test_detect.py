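import numpy as np
import pandas as pd
import pytest

import _oracles
import flagmet as fm
from flagmet.detect import (
    ContigAnnotation,
    MappedCounts,
    ReferenceIndex,
    assign_contig_species,
    call_presence,
    combine_counts,
    estimate_abundance,
    expected_reads_per_cds,
    genome_coverage,
    heat_matrix,
    locus_presence_fraction,
    map_reads,
    normalize_counts,
    pairwise_protein_identity,
)
from flagmet.seqio import GeneFeature
from flagmet.synth import (
    CommunityProfile,
    ConfigError,
    Read,
    ReadSet,
    SimulationConfig,
    make_genome,
    simulate_reads,
)


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


@pytest.fixture(scope="module")
def ref():
    genome, feats = make_genome("sp", 60_000, [("flgB", 900), ("flgC", 600)],
                                seed=21)
    return genome, feats, ReferenceIndex([genome])


class TestMapping:

    def test_exact_read_counted_for_its_cds(self, ref):
        genome, feats, idx = ref
        flgB = feats[0]
        read = genome.sequence[flgB.start + 99:flgB.start + 190]
        rs = ReadSet([Read(read, "sp", flgB.start + 100)])
        mc = map_reads(rs, feats, [genome], index=idx)
        assert mc.counts.loc[flgB.id, "sample"] == 1
        assert mc.counts.loc[feats[1].id, "sample"] == 0

    def test_two_mismatches_map_three_do_not(self, ref):
        genome, feats, idx = ref
        flgB = feats[0]
        read = genome.sequence[flgB.start + 9:flgB.start + 100]
        ok = _mutate(read, [5, 50])
        bad = _mutate(read, [5, 50, 80])
        mc = map_reads(ReadSet([Read(ok, "sp", 0)]), feats, [genome], index=idx)
        assert mc.counts.loc[flgB.id, "sample"] == 1
        mc = map_reads(ReadSet([Read(bad, "sp", 0)]), feats, [genome], index=idx)
        assert int(mc.counts["sample"].sum()) == 0

    def test_read_spanning_two_cdss_counts_for_both(self):
        genome, feats = make_genome("sp", 30_000, [("flgB", 300), ("flgC", 300)],
                                    seed=22)
        boundary = feats[0].end  # locus genes are contiguous
        read = genome.sequence[boundary - 45:boundary + 46]
        mc = map_reads(ReadSet([Read(read, "sp", boundary - 44)]), feats, [genome])
        assert mc.counts.loc[feats[0].id, "sample"] == 1
        assert mc.counts.loc[feats[1].id, "sample"] == 1

    def test_circular_wraparound_read_maps(self, ref):
        genome, feats, idx = ref
        read = genome.sequence[-45:] + genome.sequence[:46]
        placements = idx.place([read])
        assert placements[0] is not None
        assert placements[0].start == genome.size_bp - 45

    def test_simulated_reads_assign_to_true_origin(self, ref):
        """At error rate 0, mapped reads land on their true origin position
        (and hence their true origin gene) essentially always."""
        genome, feats, idx = ref
        profile = CommunityProfile({"sp": 100.0})
        cfg = SimulationConfig(seed=23, depth_bases=91 * 5000)
        rs = simulate_reads([genome], profile, cfg)
        placements = idx.place(r.sequence for r in rs.reads)
        correct = sum(1 for p, r in zip(placements, rs.reads)
                      if p is not None and p.start + 1 == r.origin_start)
        assert correct / len(rs.reads) >= 0.99


class TestNormalizeAndPresence:
    def _mc(self, raw, depth, mean=4.79e9):
        counts = pd.DataFrame({"s1": [raw]}, index=["g1"])
        return MappedCounts(counts, {"s1": depth}, mean_depth=mean)

    def test_identity_at_mean_depth(self):
        dm = normalize_counts(self._mc(20, 4.79e9))
        assert dm.normalized.loc["g1", "s1"] == 20

    def test_half_depth_doubles(self):
        dm = normalize_counts(self._mc(20, 4.79e9 / 2))
        assert dm.normalized.loc["g1", "s1"] == 40

    def test_zero_stays_zero(self):
        dm = normalize_counts(self._mc(0, 1.0))
        assert dm.normalized.loc["g1", "s1"] == 0

    def test_missing_depth_names_sample(self):
        mc = MappedCounts(pd.DataFrame({"s9": [1]}, index=["g"]), {}, 1.0)
        with pytest.raises(ConfigError, match="s9"):
            normalize_counts(mc)

    @pytest.mark.parametrize("value,call", [
        (10.0, "present"), (9.9, "absent"), (40.0, "strong"),
        (10 ** 1.5, "strong"), (31.0, "present"), (0.0, "absent"),
    ])
    def test_threshold_boundaries(self, value, call):
        dm = fm.DetectabilityMatrix(pd.DataFrame({"s": [value]}, index=["g"]))
        assert call_presence(dm).presence.loc["g", "s"] == call

    def test_strong_implies_present(self):
        rng = np.random.default_rng(1)
        dm = fm.DetectabilityMatrix(
            pd.DataFrame(rng.uniform(0, 60, (30, 3)),
                         index=[f"g{i}" for i in range(30)],
                         columns=list("abc")))
        called = call_presence(dm).presence
        norm = dm.normalized
        assert ((called == "strong") <= (norm >= 10)).all().all()


class TestExpectedReads:
    def test_zero_abundance(self):
        assert expected_reads_per_cds(4.79e9, 0.0, 3.5e6, 1000) == 0

    def test_whole_genome_cds_recovers_total_reads(self):
        depth, g = 1e7, 1e5
        n_reads = depth / 100.0 / 91 * 100  # abundance 100%
        e = expected_reads_per_cds(depth, 100.0, g, g, 91)
        assert e == pytest.approx(depth / 91 * (g + 90) / g)
        assert e == pytest.approx(n_reads, rel=0.001)

    def test_stated_magnitude(self):
        # 0.1% of a 4.79 Gb metagenome over a 3.5 Mb genome, 1 kb CDS
        e = expected_reads_per_cds(4.79e9, 0.1, 3.5e6, 1000, 91)
        assert e == pytest.approx(16.4, abs=0.1)

    def test_agrees_with_monte_carlo_placement(self):
        """Uniform circular start positions, overlap >= 1 bp."""
        rng = np.random.default_rng(99)
        g, L, rl = 100_000, 2000, 91
        n = 4_000_000
        starts = rng.integers(0, g, size=n)
        cds_start0 = 30_000
        window = L + rl - 1
        hits = np.count_nonzero((starts - (cds_start0 - rl + 1)) % g < window)
        depth, ab = 91.0 * 1e6, 100.0
        n_reads = depth / rl
        mc_estimate = n_reads * hits / n
        closed = expected_reads_per_cds(depth, ab, g, L, rl)
        assert abs(mc_estimate - closed) / closed < 0.01


class TestCoverage:
    def test_worked_arithmetic(self):
        assert genome_coverage(4000, 1.0, 4.0) == pytest.approx(10.0)

    def test_linear_in_abundance(self):
        assert genome_coverage(4000, 2.0, 4.0) == pytest.approx(
            2 * genome_coverage(4000, 1.0, 4.0))

    def test_more_abundant_species_can_have_less_coverage(self):
        # the published pair: 2.06% on a smaller genome beats 2.23% on a
        # larger one (28.12x vs 26.28x)
        g_rect, g_inul = 3.449, 4.048  # Mb, chosen to match the printed folds
        meta = 28.12 * g_rect / 0.0206
        c_rect = genome_coverage(meta, 2.06, g_rect)
        c_inul = genome_coverage(meta, 2.23, g_inul)
        assert c_rect > c_inul
        ratio = c_rect / c_inul
        assert ratio == pytest.approx((2.06 / 2.23) * (g_inul / g_rect), rel=1e-9)

    def test_coverage_estimate_dataclass(self):
        ce = fm.CoverageEstimate("sp", "s1", 4000.0, 1.0, 4.0)
        assert ce.fold_coverage == pytest.approx(10.0)


@pytest.fixture(scope="module")
def refs():
    ga, fa = make_genome("a", 50_000, [("m1", 900), ("m2", 900)], seed=31)
    gb, fb = make_genome("b", 50_000, [("m1", 900), ("m2", 900)], seed=32)
    markers = {"a": fa, "b": fb}
    return [ga, gb], markers


class TestAbundanceEstimator:

    def test_single_species_is_100(self, refs):
        genomes, markers = refs
        rs = simulate_reads([genomes[0]], CommunityProfile({"a": 100.0}),
                            SimulationConfig(seed=33, depth_bases=91 * 3000))
        prof = estimate_abundance(rs, markers, genomes)
        assert prof.abundances["a"] == pytest.approx(100.0)

    def test_70_30_recovered_within_3sd(self, refs):
        genomes, markers = refs
        n = 30_000
        rs = simulate_reads(genomes, CommunityProfile({"a": 70.0, "b": 30.0}),
                            SimulationConfig(seed=34, depth_bases=91 * n))
        prof = estimate_abundance(rs, markers, genomes)
        # ~ (marker span + rl - 1) * 2 / G of a species' reads hit markers
        p_hit = (900 + 90) * 2 / 50_000
        exp_hits = 0.7 * n * p_hit
        sd_pct = 100 * np.sqrt(exp_hits) / exp_hits * 0.7 * 0.3 / 0.21  # loose
        assert abs(prof.abundances["a"] - 70.0) <= 3 * sd_pct

    def test_zero_reads_uniform_with_warning(self, refs):
        genomes, markers = refs
        rs = ReadSet([], read_length=91)
        with pytest.warns(UserWarning, match="uniform"):
            prof = estimate_abundance(rs, markers, genomes)
        assert prof.abundances == {"a": 50.0, "b": 50.0}

    def test_zero_marker_length_rejected(self, refs):
        genomes, _ = refs
        rs = ReadSet([], read_length=91)
        with pytest.raises(ConfigError, match="zero total marker"):
            estimate_abundance(rs, {"a": [], "b": []}, genomes)


class TestHeatMatrix:
    def _dm(self):
        feats = [
            GeneFeature("g_long", "g", 1, 2100, "+", "flhA", "flgB-fliA"),
            GeneFeature("g_short", "g", 3000, 3299, "+", "flgB", "flgB-fliA"),
            GeneFeature("g_fli", "g", 5000, 5899, "+", "fliC", "none"),
        ]
        dm = fm.DetectabilityMatrix(pd.DataFrame(
            {"s1": [99.0, 0.0, 9.0], "s2": [5.0, 3.0, 1.0]},
            index=["g_long", "g_short", "g_fli"]))
        return dm, feats

    def test_by_length_columns_non_decreasing(self):
        dm, feats = self._dm()
        mat = heat_matrix(dm, feats, order="by_length")
        lengths = {f.id: f.length_bp for f in feats}
        cols = [lengths[c] for c in mat.columns]
        assert cols == sorted(cols)

    def test_by_locus_keeps_locus_members_contiguous(self):
        dm, feats = self._dm()
        mat = heat_matrix(dm, feats, order="by_locus")
        assert list(mat.columns) == ["g_long", "g_short", "g_fli"]

    def test_values_are_log10_1p(self):
        dm, feats = self._dm()
        mat = heat_matrix(dm, feats, order="by_length")
        assert mat.loc["s1", "g_long"] == pytest.approx(np.log10(100))

    def test_single_gene_matrix(self):
        dm, feats = self._dm()
        mat = heat_matrix(dm, feats[:1], order="by_length")
        assert mat.shape == (2, 1)

    def test_unknown_order_rejected(self):
        dm, feats = self._dm()
        with pytest.raises(ValueError, match="by_length or by_locus"):
            heat_matrix(dm, feats, order="alphabetical")

    def test_writes_plot_file(self, tmp_path):
        dm, feats = self._dm()
        out = tmp_path / "hm.png"
        heat_matrix(dm, feats, order="by_length", path=out)
        assert out.stat().st_size > 0


class TestContigAssignment:
    def test_majority_to_one_species(self):
        c = ContigAnnotation("c1", [("x1", "X", 95.0), ("x2", "X", 92.0),
                                    ("x3", "X", 91.0), ("x4", "Y", 50.0)])
        assert assign_contig_species(c) == "X"
        assert c.assigned_species == "X"

    def test_fraction_unmet(self):
        c = ContigAnnotation("c2", [("x1", "X", 95.0), ("x2", "Y", 10.0),
                                    ("x3", "Y", 20.0), ("x4", "Y", 30.0)])
        assert assign_contig_species(c) is None

    def test_split_across_two_species(self):
        c = ContigAnnotation("c3", [("x1", "X", 95.0), ("x2", "X", 95.0),
                                    ("x3", "Y", 95.0), ("x4", "Y", 95.0)])
        assert assign_contig_species(c) is None

    def test_invariant_to_cds_order_and_subthreshold_identity(self):
        base = [("x1", "X", 95.0), ("x2", "X", 92.0), ("x3", "Y", 89.9),
                ("x4", "Z", 10.0)]
        a = assign_contig_species(ContigAnnotation("c", list(base)))
        b = assign_contig_species(ContigAnnotation("c", list(reversed(base))))
        lowered = [(i, s, p if p >= 90 else p / 2) for i, s, p in base]
        c = assign_contig_species(ContigAnnotation("c", lowered))
        assert a == b == c == "X"

    def test_empty_cds_list_rejected(self):
        with pytest.raises(ValueError):
            assign_contig_species(ContigAnnotation("c", []))


class TestProteinIdentity:
    def test_identical_sequences(self):
        assert pairwise_protein_identity("MKVLA" * 20, "MKVLA" * 20) == 100.0

    def test_one_substitution_in_100(self):
        a = "MKVLA" * 20
        b = "W" + a[1:]
        assert pairwise_protein_identity(a, b) == pytest.approx(99.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_alignment_score_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(aa[i] for i in rng.integers(0, 20, 10))
        b = a[::-1]
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        assert aligner.score(a, b) == _oracles.nw_score(a, b)
        # the reported identity is consistent with the alignment's columns
        ident = pairwise_protein_identity(a, b)
        aln = aligner.align(a, b)[0]
        counts = aln.counts()
        assert ident == pytest.approx(100.0 * counts.identities / aln.length)
        assert 0 <= ident <= 100


def test_combine_counts_merges_samples():
    c1 = MappedCounts(pd.DataFrame({"s1": [3]}, index=["g"]), {"s1": 10.0}, 10.0)
    c2 = MappedCounts(pd.DataFrame({"s2": [5]}, index=["g"]), {"s2": 20.0}, 10.0)
    merged = combine_counts([c1, c2])
    assert list(merged.counts.columns) == ["s1", "s2"]
    assert merged.sample_depths == {"s1": 10.0, "s2": 20.0}


def test_locus_presence_fraction():
    feats = [GeneFeature("a", "g", 1, 300, "+", "flgB", "flgB-fliA"),
             GeneFeature("b", "g", 301, 600, "+", "flgC", "flgB-fliA")]
    dm = call_presence(fm.DetectabilityMatrix(
        pd.DataFrame({"s": [50.0, 1.0]}, index=["a", "b"])))
    frac = locus_presence_fraction(dm, feats)
    assert frac.loc["flgB-fliA", "s"] == pytest.approx(0.5)
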