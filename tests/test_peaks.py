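"""Doppler peak calling: density signal, CWT candidates, pruning,
boundary refinement and annotation."""

import numpy as np
import pytest

from rainstorm import (
    DopplerConfig,
    Hotspot,
    SimCohortConfig,
    amplitude_filter,
    annotate_peaks,
    call_peaks,
    compute_rainstorm,
    detect_wavelet_peaks,
    make_density_signal,
    refine_boundaries,
    simulate_cohort,
    write_peaks,
)
from rainstorm.distance import RainstormPoints
from rainstorm.peaks import DensitySignal, DopplerPeak, GeneModel, WaveletPeak


def make_points(positions, patient_index, R, patients=None):
    positions = np.asarray(positions, dtype=np.int64)
    patients = patients or [f"P{i}" for i in range(int(np.max(patient_index)) + 1)]
    return RainstormPoints(
        chromosome="1",
        positions=positions,
        patient_index=np.asarray(patient_index, dtype=np.int64),
        R=np.asarray(R, dtype=float),
        patients=patients,
    )


def make_signal(D, positions=None, patient_index=None):
    D = np.asarray(D, dtype=float)
    n = len(D)
    return DensitySignal(
        chromosome="1",
        D=D,
        positions=np.asarray(positions if positions is not None else np.arange(1, n + 1) * 100, dtype=np.int64),
        patient_index=np.asarray(
            patient_index if patient_index is not None else np.arange(n) % 5,
            dtype=np.int64,
        ),
        patients=[f"P{i}" for i in range(5)],
    )


class TestDensitySignal:
    def test_negation(self):
        pts = make_points([10, 20, 30], [0, 1, 0], [-1.0, 0.0, 2.0])
        sig = make_density_signal(pts)
        np.testing.assert_array_equal(sig.D, [1.0, 0.0, -2.0])

    def test_positions_recoverable(self):
        pts = make_points([10, 20, 30], [0, 1, 0], [1.0, 2.0, 3.0])
        sig = make_density_signal(pts)
        np.testing.assert_array_equal(sig.positions, pts.positions)

    def test_shuffled_input_gives_same_signal(self, rng):
        n = 50
        pos = np.sort(rng.integers(1, 10_000, size=n))
        pat = rng.integers(0, 4, size=n)
        r = rng.normal(size=n)
        pts = make_points(pos, pat, r)
        perm = rng.permutation(n)
        shuffled = make_points(pos[perm], pat[perm], r[perm], patients=pts.patients)
        a, b = make_density_signal(pts), make_density_signal(shuffled)
        np.testing.assert_array_equal(a.D, b.D)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_empty_points_rejected(self):
        pts = make_points([], np.empty(0, dtype=int), [], patients=["P0"])
        with pytest.raises(ValueError, match="empty"):
            make_density_signal(pts)


def gaussian_bump(n, center, sigma, height=5.0):
    x = np.arange(n)
    return height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


class TestDetectWaveletPeaks:
    kwargs = dict(snr_percentile=0, min_ridge_length=1, min_scale_at_max=1)

    def test_flat_signal_has_no_peaks(self):
        sig = make_signal(np.zeros(1000))
        assert detect_wavelet_peaks(sig, **self.kwargs) == []

    def test_single_gaussian_bump_apex_near_argmax(self):
        sig = make_signal(gaussian_bump(1000, 500, 10))
        peaks = detect_wavelet_peaks(sig, **self.kwargs)
        strong = [p for p in peaks if p.max_coef > 0.5 * max(q.max_coef for q in peaks)]
        assert len(strong) == 1
        assert abs(strong[0].apex_index - 500) <= 3

    def test_two_bumps_found_at_both_maxima(self):
        d = gaussian_bump(1000, 300, 10) + gaussian_bump(1000, 600, 10)
        sig = make_signal(d)
        peaks = detect_wavelet_peaks(sig, **self.kwargs)
        thr = 0.5 * max(p.max_coef for p in peaks)
        apexes = sorted(p.apex_index for p in peaks if p.max_coef > thr)
        assert len(apexes) == 2
        assert abs(apexes[0] - 300) <= 3 and abs(apexes[1] - 600) <= 3

    def test_short_signal_warns_and_returns_empty(self):
        sig = make_signal(np.ones(1))
        with pytest.warns(UserWarning, match="too short"):
            assert detect_wavelet_peaks(sig) == []


class TestAmplitudeFilter:
    def _peaks_at(self, idx):
        return [WaveletPeak(i, 4, 1.0, i - 4, i + 4) for i in idx]

    def test_all_above_phi_unchanged(self, rng):
        d = rng.normal(size=500)
        top = np.argsort(d)[-5:]
        sig = make_signal(d)
        peaks = self._peaks_at(top)
        assert amplitude_filter(peaks, sig, 95.0) == peaks

    def test_apex_exactly_at_phi_kept(self):
        d = np.arange(101, dtype=float)  # 95th percentile lands exactly on 95
        sig = make_signal(d)
        phi = np.percentile(d, 95.0)
        assert phi == int(phi)
        peaks = self._peaks_at([int(phi)])
        assert len(amplitude_filter(peaks, sig, 95.0)) == 1

    def test_survivors_match_percentile_oracle(self, rng):
        d = rng.normal(size=1000)
        sig = make_signal(d)
        peaks = self._peaks_at(rng.integers(10, 990, size=50))
        kept = amplitude_filter(peaks, sig, 90.0)
        phi = np.percentile(d, 90.0)
        expected = [p for p in peaks if d[p.apex_index] >= phi]
        assert kept == expected


class TestRefineBoundaries:
    def test_flanks_below_tau_leave_bounds_unchanged(self):
        d = np.full(100, -10.0)
        d[40:61] = 5.0
        sig = make_signal(d)
        pk = WaveletPeak(50, 10, 5.0, 40, 60)
        out = refine_boundaries(pk, sig, tau=0.0, min_patients=1, min_rate=0.0)
        assert (out.start, out.end) == (sig.positions[40], sig.positions[60])

    def test_left_extension_stops_at_first_below_tau(self):
        # exactly 5 left-flank indices >= tau, then one below it
        d = np.full(100, -10.0)
        d[40:61] = 5.0
        d[35:40] = 1.0   # extension run
        sig = make_signal(d)
        pk = WaveletPeak(50, 10, 5.0, 40, 60)
        out = refine_boundaries(pk, sig, tau=0.0, min_patients=1, min_rate=0.0)
        assert out.start == sig.positions[35]
        assert out.end == sig.positions[60]

    def test_extension_capped_at_max_extend(self):
        d = np.full(100, 1.0)  # everything above tau
        sig = make_signal(d)
        pk = WaveletPeak(50, 5, 5.0, 45, 55)
        out = refine_boundaries(pk, sig, tau=0.0, min_patients=1, min_rate=0.0,
                                max_extend=12)
        assert out.start == sig.positions[45 - 12]
        assert out.end == sig.positions[55 + 12]

    def test_m_rate_formula(self):
        # 6 mutations spanning exactly 1000 bp -> 6.0 mutations/kb
        positions = np.array([1001, 1100, 1300, 1500, 1900, 2000])
        d = np.full(6, 5.0)
        sig = make_signal(d, positions=positions, patient_index=np.arange(6) % 4)
        pk = WaveletPeak(2, 2, 5.0, 0, 5)
        out = refine_boundaries(pk, sig, tau=-1.0, min_patients=1, min_rate=0.0)
        assert out.n_mutations == 6
        assert out.m_rate == pytest.approx(6.0)

    def test_shrinks_to_meet_rate_criterion(self):
        # dense core of 5 mutations inside a wide sparse window
        positions = np.array([1, 50_000, 60_000, 60_100, 60_200, 60_300,
                              60_400, 70_000, 120_000])
        d = np.array([0.1, 0.2, 3.0, 4.0, 5.0, 4.0, 3.0, 0.2, 0.1])
        sig = make_signal(d, positions=positions,
                          patient_index=np.array([0, 1, 0, 1, 2, 3, 0, 2, 3]))
        pk = WaveletPeak(4, 4, 5.0, 0, 8)
        out = refine_boundaries(pk, sig, tau=0.0, min_patients=4, min_rate=6.0)
        assert out.retained
        assert (out.start, out.end) == (60_000, 60_400)
        assert out.g_peak == 4
        assert out.m_rate == pytest.approx(1000 * 5 / 401)

    def test_impossible_criteria_flagged_not_retained(self):
        positions = np.array([100, 200, 300])
        sig = make_signal(np.full(3, 5.0), positions=positions,
                          patient_index=np.array([0, 0, 1]))
        pk = WaveletPeak(1, 1, 5.0, 0, 2)
        out = refine_boundaries(pk, sig, tau=0.0, min_patients=4, min_rate=1.0)
        assert not out.retained

    def test_single_index_peak_has_length_one(self):
        sig = make_signal(np.array([5.0]), positions=np.array([777]),
                          patient_index=np.array([0]))
        pk = WaveletPeak(0, 1, 5.0, 0, 0)
        out = refine_boundaries(pk, sig, tau=10.0, min_patients=1, min_rate=0.0)
        assert (out.start, out.end, out.length) == (777, 777, 1)


def hotspot_points(seed=0, recurrence=0.5):
    cfg = SimCohortConfig(
        seed=seed,
        hotspots=(Hotspot(center=5_000_000, width=2000,
                          rate_multiplier=50, recurrence=recurrence),),
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth, compute_rainstorm(cohort, "1")


class TestCallPeaks:
    def test_three_patient_cohort_yields_nothing(self):
        from rainstorm import build_cohort
        from conftest import snv

        recs = [
            snv(p, "1", int(x))
            for p in ("P1", "P2", "P3")
            for x in np.random.default_rng(1).integers(1, 1_000_000, 200)
        ]
        cohort = build_cohort(recs, {"1": 1_000_000})
        pts = compute_rainstorm(cohort, "1", k=2)
        with pytest.warns(UserWarning, match="fewer than min_patients"):
            assert call_peaks(pts) == []

    def test_recovers_planted_hotspot(self):
        cohort, truth, pts = hotspot_points(seed=5)
        peaks = call_peaks(pts)
        _, lo, hi = truth.hotspot_intervals[0]
        assert any(p.start <= hi and p.end >= lo for p in peaks)

    def test_retained_peaks_satisfy_their_own_criteria(self):
        cohort, truth, pts = hotspot_points(seed=6)
        cfg = DopplerConfig()
        for p in call_peaks(pts, cfg):
            pos, lab = cohort.pooled["1"]
            inside = (pos >= p.start) & (pos <= p.end)
            assert p.n_mutations == int(inside.sum())
            assert p.g_peak == len(np.unique(lab[inside]))
            assert p.m_rate == pytest.approx(1000 * p.n_mutations / p.length)
            assert p.g_peak >= cfg.min_patients
            assert p.m_rate >= cfg.min_rate

    def test_tightening_criteria_never_adds_peaks(self):
        _, _, pts = hotspot_points(seed=7)
        base = len(call_peaks(pts, DopplerConfig()))
        fewer_rate = len(call_peaks(pts, DopplerConfig(min_rate=10.0)))
        fewer_pat = len(call_peaks(pts, DopplerConfig(min_patients=8)))
        assert fewer_rate <= base
        assert fewer_pat <= base

    def test_identical_input_gives_byte_identical_tsv(self, tmp_path):
        _, _, pts = hotspot_points(seed=8)
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_peaks(call_peaks(pts), out1, format="TSV")
        write_peaks(call_peaks(pts), out2, format="TSV")
        assert out1.read_bytes() == out2.read_bytes()


TOY_GFF = """\
##gff-version 3
1\ttest\tgene\t10000\t20000\t.\t+\t.\tID=gene1;Name=GENEA
1\ttest\texon\t10000\t11000\t.\t+\t.\tID=exon1;Parent=gene1
1\ttest\tCDS\t10200\t11000\t.\t+\t.\tID=cds1;Parent=gene1
1\ttest\texon\t19000\t20000\t.\t+\t.\tID=exon2;Parent=gene1
1\ttest\tCDS\t19000\t19800\t.\t+\t.\tID=cds2;Parent=gene1
"""


@pytest.fixture
def gene_model(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF)
    return GeneModel.from_gff3(str(path))


def peak_at(start, end, chrom="1"):
    return DopplerPeak(chrom, start, end, 5, 4, 6.0, 1.0, True)


class TestAnnotatePeaks:
    def test_intronic_peak_labelled(self, gene_model):
        out = annotate_peaks([peak_at(14000, 14500)], gene_model)
        assert out[0].gene == "GENEA" and out[0].region == "Intron"

    def test_cds_peak_labelled(self, gene_model):
        out = annotate_peaks([peak_at(10300, 10400)], gene_model)
        assert out[0].region == "CDS"

    def test_upstream_peak_is_five_prime_flank(self, gene_model):
        out = annotate_peaks([peak_at(8800, 9000)], gene_model)  # 1 kb upstream, + strand
        assert out[0].region == "5'Flank" and out[0].gene == "GENEA"

    def test_downstream_peak_is_three_prime_flank(self, gene_model):
        out = annotate_peaks([peak_at(21000, 21100)], gene_model)
        assert out[0].region == "3'Flank"

    def test_distant_peak_is_intergenic(self, gene_model):
        out = annotate_peaks([peak_at(500_000, 500_100)], gene_model)
        assert out[0].region == "Intergenic" and out[0].gene is None

    def test_missing_gene_model_warns_intergenic(self):
        with pytest.warns(UserWarning, match="no gene model"):
            out = annotate_peaks([peak_at(100, 200)], None)
        assert out[0].region == "Intergenic"

    def test_random_peaks_match_overlap_oracle(self, gene_model, rng):
        peaks = [peak_at(int(s), int(s) + 50) for s in rng.integers(1, 30_000, 40)]
        out = annotate_peaks(peaks, gene_model)
        g = gene_model.genes[0]
        for pk, res in zip(peaks, out):
            overlaps_gene = pk.start <= g["end"] and pk.end >= g["start"]
            assert (res.region in ("CDS", "Intron")) == overlaps_gene
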