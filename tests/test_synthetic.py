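"""The synthetic-data generator: determinism, planted truth, noise models."""

import filecmp

import numpy as np
import pytest

from mbhsig.mining import filter_hits_by_coverage, select_hydrogenase_cds
from mbhsig.signature import STANDARD_4C, TOLERANT_6C, classify_collection
from mbhsig.simulate import (
    SimulationConfig,
    evolve_family,
    fragmentize,
    make_dataset,
    make_hit_and_cds_tables,
    make_metadata,
    make_references,
    span_miss_probability,
)


class TestReferences:
    def test_planted_references_classify_to_their_groups(self, references):
        ref6, ref4, _, scheme = references
        calls, counts = classify_collection([ref6, ref4], scheme)
        assert counts[TOLERANT_6C] == 1 and counts[STANDARD_4C] == 1

    def test_signature_residues_planted(self, references):
        ref6, ref4, large, scheme = references
        for p in scheme.positions:
            assert ref6.sequence[p - 1] == "C"
        for p in scheme.discriminating:
            assert ref4.sequence[p - 1] == "G"
        assert large.sequence[scheme.large_position - 1] == "H"

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=42)
        a = make_references(cfg)
        b = make_references(cfg)
        assert a[0].sequence == b[0].sequence
        assert a[2].sequence == b[2].sequence


class TestEvolveFamily:
    def test_zero_rates_yield_copies(self, references):
        ref6, _, _, _ = references
        fam, truth = evolve_family(ref6, 5, 0.0, 0.0, (), seed=1)
        assert all(r.sequence == ref6.sequence for r in fam)
        assert all(t.n_substitutions == 0 for t in truth.values())

    def test_protected_positions_never_touched(self, references):
        ref6, _, _, scheme = references
        fam, _ = evolve_family(ref6, 50, 0.5, 0.0, scheme.positions, seed=2)
        for rec in fam:
            for p in scheme.positions:
                assert rec.sequence[p - 1] == ref6.sequence[p - 1]

    def test_substitution_count_binomial(self, references):
        # mean count within 3 sigma of sub_rate * (length - protected)
        ref6, _, _, scheme = references
        rate, n = 0.1, 100
        fam, truth = evolve_family(ref6, n, rate, 0.0, scheme.positions, seed=3)
        eligible = len(ref6) - len(scheme.positions)
        counts = np.array([t.n_substitutions for t in truth.values()])
        mean_expected = rate * eligible
        sigma = np.sqrt(rate * (1 - rate) * eligible / n)
        assert abs(counts.mean() - mean_expected) <= 3 * sigma

    def test_indels_recorded_and_length_changes(self, references):
        ref6, _, _, scheme = references
        fam, truth = evolve_family(ref6, 30, 0.0, 0.02, scheme.positions, seed=4)
        assert any(t.has_indels for t in truth.values())
        assert any(len(r) != len(ref6) for r in fam)


class TestFragmentize:
    def test_zero_fraction_is_identity(self, references):
        ref6, _, _, _ = references
        cfg = SimulationConfig(seed=5, fragment_fraction=0.0)
        fam, truth = evolve_family(ref6, 10, 0.1, 0.0, cfg.positions, seed=5)
        frags, _ = fragmentize(fam, truth, cfg)
        assert frags == fam

    def test_lengths_within_configured_bounds(self, references):
        ref6, _, _, _ = references
        cfg = SimulationConfig(seed=6, fragment_fraction=1.0,
                               fragment_len_range=(35, 350))
        fam, truth = evolve_family(ref6, 50, 0.0, 0.0, (), seed=6)
        frags, ftruth = fragmentize(fam, truth, cfg)
        for rec in frags:
            assert 35 <= len(rec) <= 350
            s, e = ftruth[rec.id].fragment_span
            assert rec.sequence == fam[0].sequence[s - 1: e]

    def test_miss_rate_matches_closed_form(self, references):
        ref6, _, _, _ = references
        cfg = SimulationConfig(seed=7, fragment_fraction=1.0)
        fam, truth = evolve_family(ref6, 2000, 0.0, 0.0, (), seed=7)
        _, ftruth = fragmentize(fam, truth, cfg)
        missed = sum(
            1 for t in ftruth.values()
            if not any(p in cfg.discriminating for p in t.positions_covered)
        )
        p = span_miss_probability(cfg.ref_length, cfg.fragment_len_range,
                                  cfg.discriminating)
        sigma = np.sqrt(p * (1 - p) / 2000)
        assert abs(missed / 2000 - p) <= 3 * sigma


class TestMetadata:
    def test_degenerate_distribution(self, references):
        cfg = SimulationConfig(
            seed=8,
            metadata_distributions={
                "6C": {"taxon_group": {"CFB": 1.0},
                       "oxygen_class": {"aerobe": 1.0},
                       "env_terms": {"lake": 2.0}},
                "4C": {"taxon_group": {"GNS": 1.0},
                       "oxygen_class": {"anaerobe": 1.0},
                       "env_terms": {"sea": 2.0}},
            },
        )
        bundle = make_dataset(cfg)
        for a in bundle.annotations:
            if a.group == "6C":
                assert a.oxygen_class == "aerobe" and a.taxon_group == "CFB"
            else:
                assert a.oxygen_class == "anaerobe" and a.taxon_group == "GNS"

    def test_invalid_distribution_rejected(self):
        bad = {
            "6C": {"taxon_group": {"a": 0.5}, "oxygen_class": {"aerobe": 1.0},
                   "env_terms": {}},
            "4C": {"taxon_group": {"a": 1.0}, "oxygen_class": {"aerobe": 1.0},
                   "env_terms": {}},
        }
        with pytest.raises(ValueError, match="probability"):
            SimulationConfig(metadata_distributions=bad)

    def test_same_seed_identical_metadata(self, references):
        ref6, _, _, _ = references
        cfg = SimulationConfig(seed=9)
        _, truth = evolve_family(ref6, 10, 0.1, 0.0, (), seed=9,
                                 true_group="6C")
        assert make_metadata(truth, cfg) == make_metadata(truth, cfg)


class TestHitAndCDSTables:
    def test_full_length_coverage_survives_filter(self, references):
        ref6, _, _, _ = references
        cfg = SimulationConfig(seed=10)
        fam, truth = evolve_family(ref6, 5, 0.1, 0.0, (), seed=10)
        hits, cds = make_hit_and_cds_tables(fam, truth, cfg)
        assert all(h.query_coverage == 100.0 for h in hits)
        assert len(filter_hits_by_coverage(hits)) == 5

    def test_short_fragment_eliminated(self, references):
        ref6, _, _, _ = references
        cfg = SimulationConfig(seed=11, fragment_fraction=1.0,
                               fragment_len_range=(35, 36))
        fam, truth = evolve_family(ref6, 5, 0.0, 0.0, (), seed=11)
        frags, ftruth = fragmentize(fam, truth, cfg)
        hits, _ = make_hit_and_cds_tables(frags, ftruth, cfg)
        assert all(h.query_coverage <= 100 * 36 / 350 + 1e-9 for h in hits)
        assert filter_hits_by_coverage(hits) == []

    def test_decoys_excluded_by_ec_filter(self, small_bundle):
        kept = select_hydrogenase_cds(small_bundle.cds)
        assert all(not c.cds_id.startswith("decoy") for c in kept)
        assert len(kept) == len(small_bundle.cds) - small_bundle.config.n_decoy_cds


class TestDataset:
    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=12, n_6C=6, n_4C=6)
        make_dataset(cfg).write(tmp_path / "a")
        make_dataset(cfg).write(tmp_path / "b")
        files = ["database.fasta", "metagenome.fasta", "annotations.tsv",
                 "hits.tsv", "cds.tsv", "truth.tsv", "scheme.cfg"]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", files, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_end_to_end_truth_recovery_without_fragmentation(self):
        cfg = SimulationConfig(seed=13, n_6C=15, n_4C=12, sub_rate=0.1,
                               fragment_fraction=0.0)
        bundle = make_dataset(cfg)
        _, counts = classify_collection(bundle.database, bundle.scheme)
        assert counts[TOLERANT_6C] == 15 and counts[STANDARD_4C] == 12

    def test_accuracy_degrades_when_signature_unprotected(self, references):
        ref6, ref4, _, scheme = references
        rates = [0.0, 0.15, 0.3, 0.45, 0.6]
        accs = []
        for rate in rates:
            fam6, _ = evolve_family(ref6, 40, rate, 0.0, (), seed=14,
                                    id_prefix="a")
            fam4, _ = evolve_family(ref4, 40, rate, 0.0, (), seed=15,
                                    id_prefix="b")
            _, counts = classify_collection(fam6 + fam4, scheme)
            accs.append((counts[TOLERANT_6C] + counts[STANDARD_4C]) / 80)
        assert accs[0] == 1.0
        assert all(b <= a for a, b in zip(accs, accs[1:]))
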