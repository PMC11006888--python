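"""pausing: profiles, peak calling vs brute-force oracle, ratios, scan,
tunnel mapping."""

import numpy as np
import pandas as pd
import pytest

from riboplast.errors import ProfileError, RiboplastError
from riboplast.io import OrfRecord
from riboplast.pausing import (
    CoverageProfile,
    NormalizedProfile,
    Peak,
    PeakParams,
    build_profile,
    call_major_peaks,
    genome_wide_scan,
    map_peak_to_tunnel,
    normalize_profile,
    peak_ratio,
    pool_profiles,
    smooth_density,
)
from riboplast.quantify import assign_to_orfs
from riboplast.simulate import (
    SimulationConfig,
    make_toy_annotation,
    simulate_experiment,
    simulate_footprints,
)

from _oracles import call_peaks_oracle, smooth_oracle
from conftest import make_footprints


def norm(density, gene="g", sample="s"):
    density = np.asarray(density, dtype=float)
    return NormalizedProfile(gene_id=gene, sample_id=sample,
                             density=density / density.sum())


def nt_density_from_codons(codon_values):
    """Spread codon-level values into an nt-level density (all on frame 0)."""
    v = np.asarray(codon_values, dtype=float)
    out = np.zeros(3 * v.size)
    out[::3] = v
    return out


class TestBuildProfile:
    def test_plus_strand_position(self, plus_orf):
        fp = make_footprints([(150, 182, "+")])
        prof = build_profile(fp, plus_orf, offset_nt=0)
        assert prof.values[50] == 1 and prof.total == 1

    def test_minus_strand_orientation_flip(self, minus_orf):
        fp = make_footprints([(318, 350, "-")])  # 5' end at 349
        prof = build_profile(fp, minus_orf, offset_nt=0)
        assert prof.values[400 - 1 - 349] == 1

    def test_offset_shifts_and_drops_out_of_range(self, plus_orf):
        fp = make_footprints([(399, 431, "+"), (150, 182, "+")])
        prof = build_profile(fp, plus_orf, offset_nt=12)
        assert prof.values[62] == 1
        assert prof.n_out_of_range == 1  # 299 + 12 >= 300

    def test_profile_total_equals_assigned_count(self, toy_orfs):
        genome, orfs = make_toy_annotation(3, (100, 508, 80), 50, seed=0)
        cfg = SimulationConfig(genome=genome, orfs=orfs, depth_per_gene=1000, seed=6)
        fp = simulate_footprints(cfg, "WT", 1)
        res = assign_to_orfs(fp, orfs)
        for orf in orfs:
            prof = build_profile(fp, orf, offset_nt=0)
            assert prof.total == int((res.gene_id == orf.gene_id).sum())


class TestNormalize:
    def test_simple_density(self):
        prof = CoverageProfile("g", "s", np.array([2, 0, 2]))
        assert np.allclose(normalize_profile(prof).density, [0.5, 0, 0.5])

    def test_density_sums_to_one(self):
        rng = np.random.default_rng(3)
        prof = CoverageProfile("g", "s", rng.integers(0, 50, 300))
        assert normalize_profile(prof).density.sum() == pytest.approx(1, abs=1e-9)

    def test_scale_invariance(self):
        v = np.array([1, 5, 0, 3])
        a = normalize_profile(CoverageProfile("g", "s", v)).density
        b = normalize_profile(CoverageProfile("g", "s", 2 * v)).density
        assert np.allclose(a, b)

    def test_zero_coverage_is_an_error(self):
        with pytest.raises(ProfileError, match="no coverage"):
            normalize_profile(CoverageProfile("g", "s", np.zeros(9, dtype=int)))


class TestSmoothing:
    @pytest.mark.parametrize("window", [1, 3, 5, 9])
    def test_matches_direct_enumeration(self, window):
        rng = np.random.default_rng(window)
        v = rng.random(137)
        assert np.allclose(smooth_density(v, window), smooth_oracle(list(v), window))

    def test_even_window_rejected(self):
        with pytest.raises(ProfileError):
            smooth_density(np.ones(10), 4)


class TestCallMajorPeaks:
    def test_uniform_density_gives_no_peaks(self):
        assert call_major_peaks(norm(np.ones(300))) == []

    def test_single_loaded_codon_is_one_peak_height_one(self):
        dens = np.zeros(300)
        dens[150] = 1.0  # codon 50
        peaks = call_major_peaks(norm(dens), PeakParams(smooth_codons=1))
        assert len(peaks) == 1
        assert peaks[0].codon_index == 51 and peaks[0].height == 1.0
        assert peaks[0].label == "g-I"

    def test_labels_are_positional_roman_numerals(self):
        codons = np.ones(200)
        for c, height in [(20, 5.0), (80, 9.0), (150, 7.0)]:
            codons[c] = height
        peaks = call_major_peaks(
            norm(nt_density_from_codons(codons)),
            PeakParams(smooth_codons=1, min_prominence_frac=0.2),
        )
        assert [p.label for p in peaks] == ["g-I", "g-II", "g-III"]
        assert [p.codon_index for p in peaks] == [21, 81, 151]
        assert [p.rank for p in peaks] == [3, 1, 2]  # by height
        # strictly increasing positions
        pos = [p.position_nt for p in peaks]
        assert pos == sorted(pos) and len(set(pos)) == len(pos)

    def test_min_sep_merges_keeping_higher(self):
        codons = np.ones(100)
        codons[40] = 10.0
        codons[44] = 8.0  # within min_sep of the higher peak
        peaks = call_major_peaks(
            norm(nt_density_from_codons(codons)),
            PeakParams(smooth_codons=1, min_sep_codons=9),
        )
        assert [p.codon_index for p in peaks] == [41]

    def test_top_k_limits_by_height(self):
        codons = np.ones(400)
        for i, c in enumerate(range(20, 380, 40)):
            codons[c] = 20.0 - i
        peaks = call_major_peaks(
            norm(nt_density_from_codons(codons)),
            PeakParams(smooth_codons=1, top_k=3, min_prominence_frac=0.05),
        )
        assert len(peaks) == 3
        assert [p.codon_index for p in peaks] == [21, 61, 101]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle_spot(self, trial):
        rng = np.random.default_rng(trial)
        n_codons = int(rng.integers(100, 600))
        codons = rng.gamma(0.5, 1.0, n_codons)
        params = PeakParams()
        peaks = call_major_peaks(norm(nt_density_from_codons(codons)), params)
        dens = nt_density_from_codons(codons)
        expected = call_peaks_oracle(
            (dens / dens.sum()).reshape(-1, 3).sum(axis=1),
            params.smooth_codons, params.min_prominence_frac,
            params.min_sep_codons, params.top_k,
        )
        assert [p.codon_index - 1 for p in peaks] == [c for c, _ in expected]
        assert [p.height for p in peaks] == pytest.approx(
            [h for _, h in expected], rel=1e-12
        )


class TestPeakRatio:
    def make_peak(self, codon_index, gene="g"):
        return Peak(gene_id=gene, position_nt=3 * (codon_index - 1),
                    codon_index=codon_index, height=0.1, rank=1,
                    label=f"{gene}-I")

    def test_identical_replicates_ratio_one_sd_zero(self):
        dens = np.ones(300)
        dens[150] = 30
        wt = [norm(dens, sample=f"WT_{i}") for i in range(3)]
        mut = [norm(dens, sample=f"m_{i}") for i in range(3)]
        pr = peak_ratio(wt, mut, self.make_peak(51), "mut")
        assert pr.mean == pytest.approx(1.0, rel=1e-12)
        assert pr.sd == pytest.approx(0.0, abs=1e-12)

    def test_single_replicate_arithmetic(self):
        base = np.ones(300)
        wt_d, mut_d = base.copy(), base.copy()
        wt_d[150], mut_d[150] = 10.0, 13.0
        params = PeakParams(smooth_codons=1, match_window_codons=0)
        wt_h = (wt_d / wt_d.sum()).reshape(-1, 3).sum(axis=1)[50]
        mut_h = (mut_d / mut_d.sum()).reshape(-1, 3).sum(axis=1)[50]
        pr = peak_ratio([norm(wt_d)], [norm(mut_d)], self.make_peak(51), "m", params)
        assert pr.mean == pytest.approx(mut_h / wt_h, rel=1e-12)
        assert pr.sd is None and pr.n_replicates == 1

    def test_depth_invariance(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 40, 300)
        wt = [normalize_profile(CoverageProfile("g", "w", counts))]
        mut_counts = counts.copy()
        mut_counts[150] *= 3
        a = peak_ratio(
            wt, [normalize_profile(CoverageProfile("g", "m", mut_counts))],
            self.make_peak(51), "m",
        )
        b = peak_ratio(
            wt, [normalize_profile(CoverageProfile("g", "m", mut_counts * 10))],
            self.make_peak(51), "m",
        )
        assert a.mean == pytest.approx(b.mean, rel=1e-9)

    def test_absent_wt_peak_is_an_error(self):
        wt = [norm(np.concatenate([np.ones(150), np.zeros(150)]))]
        mut = [norm(np.ones(300))]
        with pytest.raises(ProfileError, match="absent in WT"):
            peak_ratio(wt, mut, self.make_peak(91),
                       "m", PeakParams(smooth_codons=1, match_window_codons=0))

    def test_injected_stall_recovered_within_band(self):
        # 2x stall at one codon of the 508-codon gene, 3+3 replicates:
        # recovered ratio within the renormalisation-aware band
        genome, orfs = make_toy_annotation(1, (508,), 50, seed=0, gene_ids=("psbB",))
        cfg = SimulationConfig(
            genome=genome, orfs=orfs, depth_per_gene=50_000,
            pause_map={"psbB": {200: 3.0}},
            genotype_effects={"mut": {("psbB", 200): 2.0}},
            replicate_noise_cv=0.05, seed=21,
        )
        orf = orfs[0]
        wt, mut = [], []
        for rep in (1, 2, 3):
            wt.append(normalize_profile(build_profile(
                simulate_footprints(cfg, "WT", rep), orf, cfg.psite_offset)))
            mut.append(normalize_profile(build_profile(
                simulate_footprints(cfg, "mut", rep), orf, cfg.psite_offset)))
        pooled = pool_profiles([
            build_profile(simulate_footprints(cfg, "WT", r), orf, cfg.psite_offset)
            for r in (1, 2, 3)
        ])
        peaks = call_major_peaks(normalize_profile(pooled))
        assert [p.codon_index for p in peaks] == [201]
        # height measured at codon resolution without smoothing: the stalled
        # window is the single codon, so the renormalisation-corrected truth
        # is ~2 / (1 + 1 * d0) with d0 = 3/510
        pr = peak_ratio(wt, mut, peaks[0], "mut", PeakParams(smooth_codons=1))
        assert 1.7 <= pr.mean <= 2.2


class TestGenomeWideScan:
    def build_inputs(self, seed=13, genotype_effects=None, depth=3000):
        genome, orfs = make_toy_annotation(3, (100, 508, 80), 50, seed=0)
        cfg = SimulationConfig(
            genome=genome, orfs=orfs, depth_per_gene=depth,
            pause_map={"g01": {50: 5.0}, "g02": {250: 6.0}, "g03": {30: 5.0}},
            genotype_effects=genotype_effects or {},
            replicate_noise_cv=0.05, seed=seed,
        )
        fp, sheet = simulate_experiment(cfg, ("WT", "mut"), 3)
        return cfg, fp, sheet

    def test_injected_stall_ranks_first(self):
        cfg, fp, sheet = self.build_inputs(
            genotype_effects={"mut": {("g02", 250): 2.5}}
        )
        scan, excl = genome_wide_scan(
            fp, cfg.orfs, sheet, offset_nt=cfg.psite_offset, min_reads=200
        )
        top = scan.iloc[0]
        assert top.gene_id == "g02" and top.codon_index == 251
        assert top.mean_ratio > 1.5

    def test_output_sorted_by_mean_ratio_within_genotype(self):
        cfg, fp, sheet = self.build_inputs()
        scan, _ = genome_wide_scan(
            fp, cfg.orfs, sheet, offset_nt=cfg.psite_offset, min_reads=200
        )
        for _, grp in scan.groupby("genotype"):
            assert grp["mean_ratio"].is_monotonic_decreasing

    def test_low_count_gene_listed_with_reason(self):
        cfg, fp, sheet = self.build_inputs()
        scan, excl = genome_wide_scan(
            fp, cfg.orfs, sheet, offset_nt=cfg.psite_offset, min_reads=10_000
        )
        assert scan.empty
        assert set(excl["gene_id"]) == {"g01", "g02", "g03"}
        assert excl["reason"].str.contains("below").all()

    def test_empty_mutant_set_gives_empty_table(self, caplog):
        cfg, fp, sheet = self.build_inputs()
        wt_only = sheet[sheet["genotype"] == "WT"]
        fp_wt = fp[fp["sample_id"].isin(wt_only["sample_id"])]
        scan, _ = genome_wide_scan(
            fp_wt, cfg.orfs, wt_only, offset_nt=cfg.psite_offset, min_reads=100
        )
        assert scan.empty


class TestTunnelMapping:
    def peak_at(self, codon):
        return Peak("psbB", 3 * (codon - 1), codon, 0.01, 1, "psbB-V")

    def test_emerging_residue_arithmetic(self):
        tm = map_peak_to_tunnel(self.peak_at(40), tunnel_len_codons=33)
        assert tm.emerging_residue == 7

    def test_no_residue_emerged_yet(self):
        tm = map_peak_to_tunnel(self.peak_at(20), tunnel_len_codons=33)
        assert tm.emerging_residue is None and tm.emerging_feature is None

    def test_tmd_table_interval_containment(self):
        tmds = pd.DataFrame(
            {"tmd_label": ["TMD V", "TMD VI"],
             "start_residue": [280, 420],
             "end_residue": [300, 440]},
        )
        tm = map_peak_to_tunnel(self.peak_at(455), 33, tmds)
        assert tm.emerging_residue == 422 and tm.emerging_feature == "TMD VI"
        tm2 = map_peak_to_tunnel(self.peak_at(350), 33, tmds)
        assert tm2.emerging_feature == "loop"

    def test_overlapping_tmds_fatal(self):
        tmds = pd.DataFrame(
            {"tmd_label": ["a", "b"], "start_residue": [10, 20],
             "end_residue": [25, 40]},
        )
        with pytest.raises(RiboplastError, match="overlap"):
            map_peak_to_tunnel(self.peak_at(100), 33, tmds)

    def test_tmd_past_protein_end_fatal(self):
        tmds = pd.DataFrame(
            {"tmd_label": ["a"], "start_residue": [10], "end_residue": [600]},
        )
        with pytest.raises(RiboplastError, match="past the protein"):
            map_peak_to_tunnel(self.peak_at(100), 33, tmds, protein_length=508)
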