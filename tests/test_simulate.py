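"""Synthetic-cohort generator: HWE sampling, ledger fidelity, round trips."""

from __future__ import annotations

import math

import pytest

from pgxstar import io as pgx_io
from pgxstar.calling import match_haplotype
from pgxstar.defs import StructuralKind
from pgxstar.simulate import (
    SimulationConfig,
    simulate_cohort,
    study_frequency_vector,
    write_cohort,
)


def config(**kwargs):
    base = dict(
        gene="CYP2D6",
        allele_freqs={"*1": 1.0},
        n_individuals=10,
        seed=1,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            config(allele_freqs={"*1": 0.6, "*2": 0.5})

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            config(novel_injection_rate=1.5)

    def test_unknown_allele_detected_before_sampling(self, cyp2d6):
        cfg = config(allele_freqs={"*1": 0.5, "*999": 0.5})
        with pytest.raises(KeyError):
            simulate_cohort(cfg, cyp2d6)


class TestDegenerateAndLedger:
    def test_monomorphic_cohort(self, cyp2d6):
        cohort = simulate_cohort(config(), cyp2d6)
        assert len(cohort.observations) == 20
        assert all(not o.variants for o in cohort.observations)
        assert cohort.ledger.true_allele_counts() == {"*1": 20}
        assert not cohort.structural

    def test_study_vector_is_exact(self):
        freqs = study_frequency_vector("CYP2D6")
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)
        assert freqs["*1"] == pytest.approx(92 / 270)
        assert "*1x2" in freqs and "*5" in freqs

    def test_sampled_frequency_within_binomial_error(self):
        freqs = study_frequency_vector("CYP2D6")
        cohort = simulate_cohort(
            config(allele_freqs=freqs, n_individuals=5000, seed=5)
        )
        counts = cohort.ledger.true_allele_counts()
        p = freqs["*1"]
        se = math.sqrt(p * (1 - p) / 10000)
        assert abs(counts["*1"] / 10000 - p) <= 3 * se

    def test_injection_count_within_binomial_error(self):
        rate = 0.05
        cohort = simulate_cohort(
            config(
                allele_freqs={"*1": 0.7, "*2": 0.3},
                n_individuals=1000,
                novel_injection_rate=rate,
                seed=9,
            )
        )
        n = cohort.ledger.n_injections()
        expected = rate * 2000
        se = math.sqrt(2000 * rate * (1 - rate))
        assert abs(n - expected) <= 3 * se

    def test_ledger_covers_every_sample_once(self):
        cohort = simulate_cohort(config(n_individuals=25))
        assert sorted(cohort.ledger.samples) == sorted(
            {o.sample_id for o in cohort.observations}
        )
        assert len(cohort.ledger.samples) == 25


class TestStructuralAlleles:
    def test_deletion_haplotypes_emit_no_variants(self, cyp2d6):
        cohort = simulate_cohort(
            config(allele_freqs={"*5": 0.5, "*2": 0.5}, n_individuals=50, seed=3),
            cyp2d6,
        )
        deleted = cohort.deleted_haps
        assert deleted  # at 50% deletion frequency some carrier must exist
        for sample, haps in deleted.items():
            for obs in cohort.observations:
                if obs.sample_id == sample and obs.hap_index in haps:
                    assert not obs.variants
        kinds = {
            e.kind
            for evts in cohort.structural.values()
            for e in evts
        }
        assert kinds == {StructuralKind.DELETION}

    def test_deletion_carrier_round_trips_via_sidecar(self, tmp_path, cyp2d6):
        cohort = simulate_cohort(
            config(allele_freqs={"*5": 0.4, "*1": 0.6}, n_individuals=30, seed=4),
            cyp2d6,
        )
        paths = write_cohort(cohort, tmp_path)
        events = pgx_io.read_structural_tsv(paths["structural"])
        truth = {
            s: [e for e in evts]
            for s, evts in cohort.structural.items()
        }
        assert events == truth
        # the VCF itself records a missing genotype on the deleted haplotype
        text = paths["vcf"].read_text()
        carrier = next(iter(truth))
        assert carrier in text

    def test_duplication_becomes_structural_event(self, cyp2d6):
        cohort = simulate_cohort(
            config(allele_freqs={"*1x2": 0.5, "*1": 0.5}, n_individuals=40, seed=6),
            cyp2d6,
        )
        dups = [
            e
            for evts in cohort.structural.values()
            for e in evts
            if e.kind is StructuralKind.DUPLICATION
        ]
        assert dups and all(e.multiplicity == 2 for e in dups)


class TestRoundTripsAndReproducibility:
    def test_vcf_round_trip_preserves_variant_sets(self, tmp_path):
        freqs = study_frequency_vector("CYP2D6")
        cohort = simulate_cohort(
            config(allele_freqs=freqs, n_individuals=60, seed=8,
                   novel_injection_rate=0.1)
        )
        paths = write_cohort(cohort, tmp_path)
        observations = pgx_io.read_phased_vcf(
            paths["vcf"], depth_by_sample=cohort.depths
        )
        original = {
            (o.sample_id, o.hap_index): o.variants for o in cohort.observations
        }
        parsed = {(o.sample_id, o.hap_index): o.variants for o in observations}
        assert parsed == original

    def test_haplotype_tsv_round_trip(self, tmp_path):
        cohort = simulate_cohort(
            config(allele_freqs={"*2": 0.5, "*10": 0.5}, n_individuals=15, seed=2)
        )
        path = tmp_path / "haps.tsv"
        pgx_io.write_haplotype_tsv(cohort.observations, path)
        parsed = pgx_io.read_haplotype_tsv(path, depth_by_sample=cohort.depths)
        assert [
            (o.sample_id, o.hap_index, o.variants) for o in parsed
        ] == [
            (o.sample_id, o.hap_index, o.variants) for o in cohort.observations
        ]

    def test_empty_cohort_vcf_is_valid(self, tmp_path):
        path = tmp_path / "empty.vcf"
        pgx_io.write_phased_vcf([], path, gene="CYP2D6", reference_id="NG_008376.4")
        assert pgx_io.read_phased_vcf(path) == []

    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        freqs = study_frequency_vector("CYP2D6")
        for d in ("a", "b"):
            cohort = simulate_cohort(
                config(allele_freqs=freqs, n_individuals=40, seed=11,
                       novel_injection_rate=0.05)
            )
            write_cohort(cohort, tmp_path / d)
        for name in ("cyp2d6.phased.vcf", "cyp2d6.structural.tsv",
                     "cyp2d6.depth.tsv", "cyp2d6.ledger.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        freqs = study_frequency_vector("CYP2D6")
        a = simulate_cohort(config(allele_freqs=freqs, n_individuals=40, seed=1))
        b = simulate_cohort(config(allele_freqs=freqs, n_individuals=40, seed=2))
        assert a.ledger.true_allele_counts() != b.ledger.true_allele_counts()


class TestNovelInjectionDownstream:
    def test_zero_rate_means_zero_novel_flags(self, cyp2d6):
        freqs = study_frequency_vector("CYP2D6")
        cohort = simulate_cohort(
            config(allele_freqs=freqs, n_individuals=200, seed=13,
                   novel_injection_rate=0.0),
            cyp2d6,
        )
        calls = [match_haplotype(o, cyp2d6) for o in cohort.observations]
        assert not any(c.is_novel_suballele for c in calls)

    def test_every_unexplained_variant_traces_to_the_ledger(self, cyp2d6):
        freqs = study_frequency_vector("CYP2D6")
        cohort = simulate_cohort(
            config(allele_freqs=freqs, n_individuals=300, seed=14,
                   novel_injection_rate=0.08),
            cyp2d6,
        )
        injected = {
            (s, int(h)): set(tokens)
            for s, truth in cohort.ledger.samples.items()
            for h, tokens in truth.injected.items()
        }
        for obs in cohort.observations:
            call = match_haplotype(obs, cyp2d6)
            tokens = {v.token for v in call.unexplained}
            assert tokens == injected.get((obs.sample_id, obs.hap_index), set())
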