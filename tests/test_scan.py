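import io

import numpy as np
import pytest

from poolscan.differentiation import TripletPbsTrack
from poolscan.io import GeneFeature, write_results
from poolscan.scan import (ScanConfig, SelectionLocus, associate_genes,
                           consensus_loci, empirical_threshold,
                           intersect_gene_sets, loci_to_frame, outlier_mask,
                           read_loci, selected_gene_set, triplet_combinations)


class TestEmpiricalThreshold:
    def test_top_permille_of_1_to_10000(self):
        values = np.arange(1, 10_001)
        thr = empirical_threshold(values, 0.001)
        assert thr == 9990
        assert outlier_mask(values, thr).sum() == 10

    def test_all_equal_no_outliers(self):
        values = np.full(5000, 1.7)
        thr = empirical_threshold(values, 0.001)
        assert outlier_mask(values, thr).sum() == 0

    def test_nan_ignored(self):
        values = np.concatenate([np.arange(1, 10_001), [np.nan] * 50])
        assert empirical_threshold(values, 0.001) == 9990

    def test_no_finite_values_rejected(self):
        with pytest.raises(ValueError):
            empirical_threshold([np.nan, np.nan], 0.001)

    def test_warns_when_poorly_resolved(self):
        with pytest.warns(UserWarning):
            empirical_threshold(np.arange(10), 0.001)

    @pytest.mark.parametrize("n", [100, 999, 10_000, 54_321])
    def test_flagged_fraction_never_exceeds_top_fraction(self, n):
        rng = np.random.default_rng(n)
        values = rng.standard_normal(n)
        for f in (0.001, 0.01, 0.1):
            thr = empirical_threshold(values, f)
            assert outlier_mask(values, thr).sum() <= f * n + 1e-9


def _track(triplet, pbs, chrom="chr1", window=5000, step=4000):
    n = len(pbs)
    starts = np.arange(n) * step
    return TripletPbsTrack(
        triplet=triplet,
        chroms=np.array([chrom] * n, dtype=object),
        starts=starts,
        ends=starts + window,
        t_ab=np.zeros(n), t_ac=np.zeros(n), t_bc=np.zeros(n),
        pbs=np.asarray(pbs, dtype=float),
    )


TRIPLETS = [("S", "A", "B"), ("S", "A", "C"), ("S", "B", "C")]


def _tracks_with_peaks(peaks_per_triplet, n=2000):
    # flat zero background: the nearest-rank threshold is then 0 and the
    # strict ">" rule flags exactly the planted peaks
    tracks = []
    for trip, peaks in zip(TRIPLETS, peaks_per_triplet):
        pbs = np.zeros(n)
        for w in peaks:
            pbs[w] = 5.0
        tracks.append(_track(trip, pbs))
    return tracks


class TestConsensusLoci:
    def test_single_triplet_support_excluded(self):
        loci = consensus_loci(_tracks_with_peaks([[100], [], []]),
                              ScanConfig(TRIPLETS, top_fraction=0.001))
        assert loci == []

    def test_three_triplet_support_single_locus(self):
        loci = consensus_loci(_tracks_with_peaks([[100], [100], [100]]),
                              ScanConfig(TRIPLETS, top_fraction=0.001))
        assert len(loci) == 1
        assert len(loci[0].supporting_triplets) == 3
        assert loci[0].peak_pbs == 5.0

    def test_overlapping_windows_merge(self):
        # windows 100 and 101 overlap (5 kb window, 4 kb step) -> one locus
        loci = consensus_loci(_tracks_with_peaks([[100, 101], [100, 101], []]),
                              ScanConfig(TRIPLETS, top_fraction=0.001))
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100 * 4000, 101 * 4000 + 5000)
        assert loci[0].n_windows == 2

    def test_distant_windows_stay_separate(self):
        loci = consensus_loci(_tracks_with_peaks([[100, 500], [100, 500], []]),
                              ScanConfig(TRIPLETS, top_fraction=0.001))
        assert len(loci) == 2

    def test_consensus_monotone_in_min_support(self):
        tracks = _tracks_with_peaks([[100, 200], [100, 300], [200, 300]])
        covered = {}
        for support in (1, 2, 3):
            loci = consensus_loci(tracks, ScanConfig(TRIPLETS, top_fraction=0.001,
                                                     min_support=support))
            covered[support] = {(l.chrom, w) for l in loci for w in l.window_ids}
        assert covered[3] <= covered[2] <= covered[1]

    def test_mixed_focal_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            ScanConfig([("S", "A", "B"), ("X", "A", "C")])

    def test_book_ended_windows_merge(self):
        # adjacent non-overlapping windows (start == previous end) merge
        tracks = _tracks_with_peaks([[100], [100], []])
        for t in tracks:
            t.starts = np.arange(len(t.pbs)) * 5000
            t.ends = t.starts + 5000
        tracks2 = _tracks_with_peaks([[101], [101], []])
        for a, b in zip(tracks, tracks2):
            a.pbs = np.maximum(a.pbs, b.pbs)
        loci = consensus_loci(tracks, ScanConfig(TRIPLETS, top_fraction=0.001))
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (500_000, 510_000)


class TestGeneAssociation:
    LOCUS = SelectionLocus("chr1", 200_000, 210_000, (("S", "A", "B"),), 1.0, (1,))

    def _genes_of(self, feature, flank=50_000):
        return associate_genes([self.LOCUS], [feature], flank_bp=flank)[0].genes

    def test_gene_49kb_upstream_associates(self):
        g = GeneFeature("g", "chr1", 149_000, 151_000)  # ends 49 kb before
        assert self._genes_of(g) == ("g",)

    def test_gene_51kb_downstream_does_not(self):
        g = GeneFeature("g", "chr1", 261_000, 263_000)  # starts 51 kb after
        assert self._genes_of(g) == ()

    def test_gene_inside_locus(self):
        assert self._genes_of(GeneFeature("g", "chr1", 204_000, 205_000)) == ("g",)

    def test_half_open_boundary_with_zero_flank(self):
        g = GeneFeature("g", "chr1", 210_000, 212_000)  # abuts locus end
        assert self._genes_of(g, flank=0) == ()

    def test_other_chromosome_never_associates(self):
        assert self._genes_of(GeneFeature("g", "chr2", 204_000, 205_000)) == ()

    def test_gene_counted_once_genome_wide(self):
        loci = [self.LOCUS,
                SelectionLocus("chr1", 215_000, 220_000, (("S", "A", "B"),), 1.0, (2,))]
        g = GeneFeature("g", "chr1", 211_000, 213_000)
        out = associate_genes(loci, [g])
        assert out[0].genes == ("g",) and out[1].genes == ("g",)
        assert selected_gene_set(out) == {"g"}


class TestGeneSetIntersections:
    def test_disjoint_sets(self):
        df = intersect_gene_sets({"x": {"a"}, "y": {"b"}})
        both = df[(df["x"]) & (df["y"])]
        assert both["count"].iloc[0] == 0

    def test_identical_sets(self):
        df = intersect_gene_sets({"x": {"a", "b"}, "y": {"a", "b"}})
        both = df[(df["x"]) & (df["y"])]
        assert both["count"].iloc[0] == 2

    def test_partial_overlap(self):
        df = intersect_gene_sets({"x": {"a", "b", "c"}, "y": {"b", "c", "d"}})
        assert df[(df["x"]) & (df["y"])]["count"].iloc[0] == 2
        assert df[(df["x"]) & (~df["y"])]["count"].iloc[0] == 1
        assert df[(~df["x"]) & (df["y"])]["count"].iloc[0] == 1


class TestLociSerialisation:
    def test_round_trip(self):
        loci = [SelectionLocus("chr1", 100, 5100, (("S", "A", "B"), ("S", "A", "C")),
                               2.5, (1, 2), genes=("g1", "g2"))]
        buf = io.StringIO()
        write_results(_Wrap(loci), buf)
        buf.seek(0)
        again = read_loci(buf)
        assert again[0].chrom == "chr1"
        assert (again[0].start, again[0].end) == (100, 5100)
        assert again[0].supporting_triplets == (("S", "A", "B"), ("S", "A", "C"))
        assert again[0].genes == ("g1", "g2")

    def test_support_column(self):
        loci = [SelectionLocus("chr1", 0, 5000, (("S", "A", "B"), ("S", "B", "C")),
                               1.0, (0,))]
        frame = loci_to_frame(loci)
        assert frame["support"].iloc[0] == 2


class _Wrap:
    def __init__(self, loci):
        self.loci = loci

    def to_frame(self):
        return loci_to_frame(self.loci)


def test_triplet_combinations_share_focal():
    trips = triplet_combinations("S", ["A", "B", "C"])
    assert len(trips) == 3
    assert all(t[0] == "S" for t in trips)
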