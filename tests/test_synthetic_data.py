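"""Generator properties: determinism, stop-freedom, codon-position bias,
star demography, NUMT structure and the Tpm heterozygote overlay."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from haplomite.seq_core import GAP, translate, iupac_union
from haplomite.synthetic_data import (
    SynthConfig,
    simulate_farm_sample,
    simulate_haplogroup_panel,
    simulate_study,
    simulate_tpm_dataset,
    write_dataset,
)


def _diff_positions(a, b):
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SynthConfig(cds_length_bp=470)  # not a codon multiple
        with pytest.raises(ValueError):
            SynthConfig(third_position_bias=1.5)
        with pytest.raises(ValueError):
            SynthConfig(intergroup_divergence=0.2)
        with pytest.raises(ValueError):
            SynthConfig(tpm_indel_lengths=(2, 3))


class TestPanel:
    def test_pure_third_position_bias(self):
        cfg = SynthConfig(seed=4, third_position_bias=1.0,
                          intergroup_divergence=0.02)
        panel = simulate_haplogroup_panel(cfg)
        for a, b in itertools.combinations(panel.centroids.values(), 2):
            assert all(i % 3 == 2 for i in _diff_positions(a, b))

    def test_centroid_divergence_within_tolerance(self, config, panel):
        L = config.cds_length_bp
        target = config.intergroup_divergence
        for a, b in itertools.combinations(panel.centroids.values(), 2):
            d = len(_diff_positions(a, b)) / L
            assert 0.8 * target <= d <= 1.2 * target
            # intergroup scale far above the 1-2 mutation star scale
            assert d > 2 / L

    def test_deterministic_given_seed(self, config):
        p1 = simulate_haplogroup_panel(config)
        p2 = simulate_haplogroup_panel(config)
        assert p1.centroids == p2.centroids
        assert p1.numt_centroid == p2.numt_centroid

    def test_requested_number_of_haplogroups(self):
        panel = simulate_haplogroup_panel(SynthConfig(seed=2, n_haplogroups=4))
        assert list(panel.centroids) == ["A", "B", "C", "D"]


class TestFarms:
    def test_single_group_star_structure(self, config, panel):
        fs = simulate_farm_sample(
            config, panel, "single_group", rng=np.random.default_rng(7)
        )
        counts = Counter(r.residues for r in fs.records)
        hub, hub_count = counts.most_common(1)[0]
        n = config.farm_size
        assert hub_count >= n * (1 - config.satellite_fraction) - 3
        for seq in counts:
            assert len(_diff_positions(seq, hub)) <= 2

    def test_unknown_profile_rejected(self, config, panel):
        with pytest.raises(ValueError, match="unknown profile"):
            simulate_farm_sample(config, panel, "bogus")

    def test_forced_indel_numts_always_carry_stops(self, config, panel):
        cfg = SynthConfig(seed=config.seed, numt_indel_prob=1.0)
        fs = simulate_farm_sample(
            cfg, panel, "with_numt", rng=np.random.default_rng(9)
        )
        numt_seqs = [
            r.residues
            for r, t in zip(fs.records, fs.truth)
            if t["lineage_class"] == "numt"
        ]
        assert numt_seqs
        for seq in numt_seqs:
            assert GAP in seq
            gap_pos = seq.index(GAP)
            _, stops = translate(seq)
            assert any(s >= gap_pos // 3 for s in stops)

    def test_numt_copy_frequencies_balanced(self, config, panel):
        for seed in range(5):
            fs = simulate_farm_sample(
                config, panel, "with_numt", rng=np.random.default_rng(seed)
            )
            counts = Counter(
                r.residues
                for r, t in zip(fs.records, fs.truth)
                if t["lineage_class"] == "numt"
            )
            assert max(counts.values()) / min(counts.values()) <= 3

    def test_coamplified_mode_emits_ambiguity_consensus(self, config, panel):
        fs = simulate_farm_sample(
            config, panel, "with_numt", rng=np.random.default_rng(21),
            coamplified=True,
        )
        co = [
            r.residues
            for r, t in zip(fs.records, fs.truth)
            if t["lineage_class"] == "numt_coamplified"
        ]
        assert co
        for seq in co:
            amb = sum(1 for c in seq if c not in "ACGTN-")
            assert amb / len(seq) > 0.02  # double-peak density

    def test_truth_table_complete(self, config, panel):
        fs = simulate_farm_sample(
            config, panel, "mixed_with_C", rng=np.random.default_rng(3)
        )
        assert len(fs.truth) == len(fs.records) == config.farm_size
        assert [t["seq_id"] for t in fs.truth] == [r.id for r in fs.records]
        labels = {t["haplogroup_label"] for t in fs.truth}
        assert "C" in labels and len(labels) >= 2


class TestSubstitutionSpectra:
    def test_functional_differences_match_q3_bias(self, config, panel):
        # binomial check on the codon-position spectrum of functional
        # pairwise differences (centroids vs their shared ancestor)
        diffs = []
        for seq in panel.centroids.values():
            diffs += _diff_positions(seq, panel.ancestor)
        n = len(diffs)
        assert n >= 30
        k = sum(1 for i in diffs if i % 3 == 2)
        lo, hi = stats.binom.interval(0.999, n, config.third_position_bias)
        assert lo <= k <= hi

    def test_numt_positions_uniform(self):
        # chi-square goodness of fit over >=300 pseudogene substitutions
        # (each NUMT centroid vs the ancestral haplotype it was copied from)
        diffs = []
        for seed in range(10):
            panel = simulate_haplogroup_panel(SynthConfig(seed=seed))
            diffs += [
                i % 3
                for i in _diff_positions(panel.numt_centroid, panel.numt_source)
            ]
        counts = [diffs.count(0), diffs.count(1), diffs.count(2)]
        assert sum(counts) >= 300
        assert stats.chisquare(counts).pvalue > 0.01


class TestTpm:
    def test_identical_alleles_give_clean_consensus(self):
        from haplomite.synthetic_data import TpmAllele, _het_consensus

        a = TpmAllele("x", "ACGTACGT", None)
        assert _het_consensus(a, a) == "ACGTACGT"

    def test_single_indel_ambiguity_only_downstream(self):
        from haplomite.synthetic_data import TpmAllele, _het_consensus

        rng = np.random.default_rng(0)
        anc = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        p, L = 50, 3
        short = TpmAllele("s", anc[:p] + anc[p + L:], (p, L))
        longa = TpmAllele("l", anc, None)
        cons = _het_consensus(longa, short)
        amb = [i for i, c in enumerate(cons) if c not in "ACGT"]
        assert amb and min(amb) >= p

    def test_truth_indel_lengths_respect_config(self):
        cfg = SynthConfig(seed=8, tpm_indel_lengths=(3, 7))
        ds = simulate_tpm_dataset(cfg)
        lengths = {t["indel_len"] for t in ds.truth if t["indel_len"] > 0}
        assert lengths and lengths <= {3, 7}

    def test_consensus_is_overlay_of_truth_alleles(self):
        ds = simulate_tpm_dataset(SynthConfig(seed=9))
        for rec, t in zip(ds.records, ds.truth):
            a1, a2 = t["allele_1_seq"], t["allele_2_seq"]
            expect = "".join(
                iupac_union(x, y) for x, y in zip(a1, a2)
            )
            assert rec.residues == expect


class TestStudyOutputs:
    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = SynthConfig(seed=42, farm_size=10)
        for d in ("a", "b"):
            study = simulate_study(cfg, {"single_group": 1, "with_numt": 1})
            write_dataset(study, tmp_path / d)
        for name in ("sequences.fasta", "samples.tsv", "truth.tsv",
                     "tpm.fasta", "panel.fasta", "config.txt"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_profile_mix_and_class_counts(self):
        cfg = SynthConfig(seed=5, farm_size=8, n_haplogroups=4)
        study = simulate_study(
            cfg, {"single_group": 2, "mixed_with_C": 1, "with_numt": 1},
            include_cryptic_farms=1,
        )
        farms = {f.farm_id: f.profile for f in study.farms}
        assert len(farms) == 5
        classes = Counter(study.co1_truth.lineage_class)
        assert classes["numt"] > 0 and classes["cryptic"] > 0
        # every emitted sequence appears exactly once in the truth table
        assert study.co1_truth.seq_id.is_unique
        assert len(study.co1_truth) == len(study.co1_records)
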