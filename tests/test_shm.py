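"""FR3 mutation profiling, hotspot and polymorphic-site calling."""

import numpy as np
import pytest

from conftest import simulate_to_annotations
from vdjprof import germline as gl
from vdjprof import shm
from vdjprof import simulate as sim
from vdjprof.germline import FR3_START


def make_profile(ref="A" * 115, coverage=None, alt_counts=None):
    """Construct a profile directly: alt_counts maps (offset, base) -> count."""
    n = len(ref)
    prof = shm.MutationProfile(
        gene_name="IGHV1", fr3_start=FR3_START, fr3_end=FR3_START + n - 1,
        ref_bases=ref,
        coverage=np.zeros(n), mismatches=np.zeros(n),
        base_counts=np.zeros((4, n)),
        codon_coverage=np.zeros(n // 3), codon_mismatches=np.zeros(n // 3),
    )
    if coverage is not None:
        prof.coverage[:] = coverage
    for (offset, base), count in (alt_counts or {}).items():
        prof.base_counts[shm._BASE_IDX[base], offset] += count
        prof.mismatches[offset] += count
    ref_idx = np.array([shm._BASE_IDX[b] for b in ref])
    matched = prof.coverage - prof.base_counts.sum(axis=0)
    prof.base_counts[ref_idx, np.arange(n)] += matched
    return prof


@pytest.fixture(scope="module")
def igh_run(igh_db, tmp_path_factory):
    """IGH simulation with SHM 0.05 and one injected heterozygous allele."""
    target = igh_db.v_genes[0]
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[target.sequence[299]]
    weights = {g.gene_name: (0.5 if g is target else 0.5 / (len(igh_db.v_genes) - 1))
               for g in igh_db.v_genes}
    config = sim.SimulationConfig.for_locus(
        "IGH", n_clonotypes=800, seed=71, shm_rate_per_nt=0.05,
        frame_mode="in_frame", v_usage_weights=weights,
        reads_per_clonotype_dispersion=3.0,
        polymorphic_alleles=((target.gene_name, 300, alt, 0.5),),
    )
    tmp = tmp_path_factory.mktemp("igh_run")
    rearr, merged, qc, annotations, summary = simulate_to_annotations(
        igh_db, config, tmp
    )
    profiles = shm.build_profiles(annotations, igh_db)
    return {
        "db": igh_db, "config": config, "rearrangements": rearr,
        "annotations": annotations, "profiles": profiles,
        "target": target.gene_name, "alt": alt,
    }


class TestBuildProfiles:
    def test_tcr_rejected(self, trb_run):
        with pytest.raises(shm.UnsupportedLocusError):
            shm.build_profiles(trb_run["annotations"], trb_run["db"])

    def test_zero_mutation_profiles_clean(self, igh_db, tmp_path):
        config = sim.SimulationConfig.for_locus(
            "IGH", n_clonotypes=60, seed=73, shm_rate_per_nt=0.0,
            per_base_error_rate=0.0, n_rate=0.0, frame_mode="in_frame",
        )
        *_, annotations, _ = simulate_to_annotations(igh_db, config, tmp_path)
        profiles = shm.build_profiles(annotations, igh_db)
        assert profiles
        for prof in profiles.values():
            prof.validate()
            assert prof.mismatches.sum() == 0

    def test_counting_single_substitution(self, igh_db, tmp_path):
        """10 identical reads + 1 carrying a substitution at one position."""
        from vdjprof import annotate as an
        from vdjprof.preprocess import MergedSequence

        gene = igh_db.v_genes[0]
        cfg = sim.SimulationConfig(
            locus="IGH", n_clonotypes=1, deletion_mean=0, insertion_mean=0,
            per_base_error_rate=0, n_rate=0, seed=5, frame_mode="in_frame",
            v_usage_weights={gene.gene_name: 1.0},
        )
        (r,) = sim.simulate_repertoire(cfg, igh_db)
        seq = r.full_sequence[-190:]
        mutated = list(seq)
        pos_in_v = 300  # FR3 position on the V reference
        offset = len(seq) - len(r.full_sequence)  # negative slice start
        idx = pos_in_v - 1 - (len(r.full_sequence) - len(seq))
        mutated[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[idx]]
        reads = [MergedSequence(f"c{i}", seq, 0, 0) for i in range(10)]
        reads.append(MergedSequence("mut", "".join(mutated), 0, 0))
        annotations, _ = an.annotate_repertoire(reads, igh_db)
        profiles = shm.build_profiles(annotations, igh_db, productive_only=False)
        prof = profiles[gene.gene_name]
        i = pos_in_v - prof.fr3_start
        assert prof.coverage[i] == 11
        assert prof.mismatches[i] == 1
        prof.validate()

    def test_uniform_rate_recovered_per_position(self, igh_run):
        """Pooled mismatch frequency matches the configured binomial rate."""
        rate = igh_run["config"].shm_rate_per_nt
        profs = dict(igh_run["profiles"])
        target = igh_run["target"]
        cov = np.sum([p.coverage.sum() for g, p in profs.items() if g != target])
        mm = np.sum([p.mismatches.sum() for g, p in profs.items() if g != target])
        observed = mm / cov
        # mutations can revert to reference and errors add a little noise
        assert observed == pytest.approx(rate, abs=0.01)


class TestRates:
    def test_zero_rate(self):
        prof = make_profile(coverage=100)
        assert shm.overall_rate({"IGHV1": prof}, "nt") == 0.0

    def test_simple_arithmetic(self):
        prof = make_profile(ref="A" * 100 + "C" * 15, coverage=1,
                            alt_counts={(3, "G"): 1})
        # 115 sequenced bases, 1 mutated
        assert shm.overall_rate({"IGHV1": prof}, "nt") == pytest.approx(1 / 115)

    def test_overall_is_coverage_weighted_mean_of_per_gene(self, igh_run):
        profiles = igh_run["profiles"]
        per_gene = shm.per_gene_rate(profiles, "nt")
        weights = {g: p.coverage.sum() for g, p in profiles.items()}
        pooled = sum(per_gene[g] * weights[g] for g in per_gene) / sum(weights.values())
        assert shm.overall_rate(profiles, "nt") == pytest.approx(pooled)

    def test_two_gene_rate_ordering_recovered(self, igh_db, tmp_path):
        g_low, g_high = igh_db.v_genes[1], igh_db.v_genes[2]
        cfg = sim.SimulationConfig.for_locus(
            "IGH", n_clonotypes=400, seed=79, shm_rate_per_nt=0.04,
            frame_mode="in_frame", per_base_error_rate=0.0, n_rate=0.0,
            max_clone_size=1,
            v_usage_weights={g_low.gene_name: 0.5, g_high.gene_name: 0.5},
            shm_hotspots=tuple(
                (g_high.gene_name, pos, 0.13) for pos in range(196, 311)
            ),
        )
        *_, annotations, _ = simulate_to_annotations(igh_db, cfg, tmp_path)
        rates = shm.per_gene_rate(shm.build_profiles(annotations, igh_db), "nt")
        assert rates[g_high.gene_name] > rates[g_low.gene_name]
        assert rates[g_low.gene_name] == pytest.approx(0.04, abs=0.01)
        assert rates[g_high.gene_name] == pytest.approx(0.13, abs=0.015)

    def test_aa_rate_exceeds_nt_rate(self, igh_run):
        nt = shm.overall_rate(igh_run["profiles"], "nt")
        aa = shm.overall_rate(igh_run["profiles"], "aa")
        assert aa > nt

    def test_zero_coverage_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            assert shm.overall_rate([], "nt") is None


class TestHotspots:
    def test_above_threshold_called(self):
        prof = make_profile(coverage=100, alt_counts={(10, "G"): 12})
        hot, _ = shm.call_hotspots(prof)
        assert hot == [FR3_START + 10]

    def test_coverage_30_excluded_regardless_of_level(self):
        prof = make_profile(coverage=30, alt_counts={(10, "G"): 25})
        hot, excluded = shm.call_hotspots(prof)
        assert hot == []
        assert FR3_START + 10 in excluded

    def test_exactly_ten_percent_not_hotspot(self):
        prof = make_profile(coverage=100, alt_counts={(10, "G"): 10})
        hot, _ = shm.call_hotspots(prof)
        assert hot == []

    def test_coverage_31_eligible(self):
        prof = make_profile(coverage=31, alt_counts={(10, "G"): 4})
        hot, excluded = shm.call_hotspots(prof)
        assert hot == [FR3_START + 10]
        assert FR3_START + 10 not in excluded


class TestPolymorphicSites:
    def test_mid_band_single_type_called(self):
        prof = make_profile(coverage=1000, alt_counts={(20, "C"): 544})
        calls = shm.detect_polymorphic_sites(prof)
        (call,) = [c for c in calls if c.verdict == "polymorphic"]
        assert call.position == FR3_START + 20
        assert call.alt_base == "C"
        assert call.alt_fraction == pytest.approx(0.544)

    def test_below_band_not_called(self):
        prof = make_profile(coverage=1000, alt_counts={(20, "C"): 200})
        calls = shm.detect_polymorphic_sites(prof)
        assert all(c.verdict != "polymorphic" for c in calls)
        assert calls[0].reason == "below_band"

    def test_split_alt_types_fail_dominance(self):
        prof = make_profile(coverage=1000,
                            alt_counts={(20, "C"): 250, (20, "G"): 250})
        calls = shm.detect_polymorphic_sites(prof)
        assert calls[0].verdict == "not_polymorphic"
        assert calls[0].reason == "dominance_unmet"

    def test_near_band_reported_as_candidate(self):
        prof = make_profile(coverage=1000, alt_counts={(20, "G"): 361})
        calls = shm.detect_polymorphic_sites(prof)
        assert calls[0].verdict == "candidate"

    def test_shallow_coverage_never_called(self):
        prof = make_profile(coverage=500, alt_counts={(20, "C"): 250})
        assert shm.detect_polymorphic_sites(prof) == []

    def test_injected_allele_recovered_without_false_calls(self, igh_run):
        profiles = igh_run["profiles"]
        target, alt = igh_run["target"], igh_run["alt"]
        found = []
        for gene, prof in profiles.items():
            for call in shm.detect_polymorphic_sites(prof, min_coverage=100):
                if call.verdict == "polymorphic":
                    found.append((gene, call.position, call.alt_base))
        assert found == [(target, 300, alt)]

    def test_hotspots_superset_of_strong_polymorphic_calls(self, igh_run):
        for gene, prof in igh_run["profiles"].items():
            hot, _ = shm.call_hotspots(prof, min_coverage=100)
            for call in shm.detect_polymorphic_sites(prof, min_coverage=100):
                if call.verdict == "polymorphic" and call.alt_fraction > 0.10:
                    assert call.position in hot


class TestSpectrum:
    def test_single_type(self):
        prof = make_profile(ref="T" * 115, coverage=50,
                            alt_counts={(4, "C"): 7, (90, "C"): 3})
        spec = shm.substitution_spectrum({"IGHV1": prof}, "nt")
        assert spec.to_dict() == {"T>C": 1.0}

    def test_normalization(self, igh_run):
        spec = shm.substitution_spectrum(igh_run["profiles"], "nt")
        assert spec.sum() == pytest.approx(1.0)
        aa = shm.substitution_spectrum(igh_run["profiles"], "aa", top=15)
        assert len(aa) <= 15

    def test_transition_bias_recovered(self, igh_db, tmp_path):
        cfg = sim.SimulationConfig.for_locus(
            "IGH", n_clonotypes=600, seed=83, shm_rate_per_nt=0.06,
            frame_mode="in_frame", per_base_error_rate=0.0, n_rate=0.0,
            shm_transition_weight=4.0, max_clone_size=1,
        )
        *_, annotations, _ = simulate_to_annotations(igh_db, cfg, tmp_path)
        profiles = shm.build_profiles(annotations, igh_db)
        spec = shm.substitution_spectrum(profiles, "nt")
        transitions = ["A>G", "G>A", "C>T", "T>C"]
        ts_mass = sum(spec.get(t, 0) for t in transitions)
        # configured transition:transversion odds 4:1 per site -> 2/3 mass
        assert ts_mass == pytest.approx(2 / 3, abs=0.05)

    def test_empty_spectrum_flagged(self, caplog):
        prof = make_profile(coverage=10)
        with caplog.at_level("WARNING"):
            assert shm.substitution_spectrum({"IGHV1": prof}, "nt") is None


def test_heatmap_renders(igh_run, tmp_path):
    out = tmp_path / "heatmap.png"
    shm.plot_mutation_heatmap(igh_run["profiles"], out)
    assert out.stat().st_size > 0
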