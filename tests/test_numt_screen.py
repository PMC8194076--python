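"""The five pseudogene warnings and the composite verdict rule."""

import numpy as np
import pytest

from haplomite.numt_screen import (
    W1,
    W2,
    W3,
    W4,
    W5,
    ScreenConfig,
    aa_segregating_vs_panel,
    warning_w1,
    warning_w2,
    warning_w3,
    warning_w4,
    warning_w5_and_verdict,
)
from haplomite.phylo_diag import build_tree
from haplomite.seq_core import GAP


class TestW1:
    def test_frameshifted_numt_fires_with_stops(self, panel):
        from haplomite.synthetic_data import SynthConfig, simulate_farm_sample

        cfg = SynthConfig(seed=11, numt_indel_prob=1.0)
        farm = simulate_farm_sample(
            cfg, panel, "with_numt", rng=np.random.default_rng(13)
        )
        numt_seqs = [
            r.residues
            for r, t in zip(farm.records, farm.truth)
            if t["lineage_class"] == "numt"
        ]
        assert any(GAP in s for s in numt_seqs)
        fired, stops, n_aa = warning_w1(
            numt_seqs, list(panel.centroids.values()), retention=None
        )
        assert fired and stops
        assert n_aa >= 3

    def test_typical_star_does_not_fire(self, panel, star_farm):
        seqs = sorted({r.residues for r in star_farm.records})
        fired, stops, n_aa = warning_w1(
            seqs, list(panel.centroids.values()), retention=None
        )
        assert not fired and not stops
        assert n_aa < 3

    def test_stop_free_numt_fires_via_retention(self, panel):
        # the absence of stop codons is not evidence of functionality: a
        # retained-resolution report fires the warning on its own
        from haplomite.phylo_diag import RetentionRow

        seqs = [panel.centroids["A"]]
        retention = RetentionRow("g", 100, 95, 0.08, 0.07, True)
        fired, stops, _ = warning_w1(
            seqs, list(panel.centroids.values()), retention
        )
        assert fired and not stops

    def test_aa_segregating_counts_states_absent_from_panel(self):
        panel = ["ATGTTTAAAGGG"]  # MFKG
        group = ["ATGTTTAAAGGG", "ATGCTTAAAGGG"]  # L at codon 2 in one member
        assert aa_segregating_vs_panel(group, panel) == 1


@pytest.fixture(scope="module")
def trees(panel):
    from haplomite.synthetic_data import SynthConfig, simulate_farm_sample

    cfg = SynthConfig(seed=11)
    rng = np.random.default_rng(5)
    fs = simulate_farm_sample(cfg, panel, "with_numt", rng=rng)
    numt = sorted(
        {
            r.residues
            for r, t in zip(fs.records, fs.truth)
            if t["lineage_class"] == "numt"
        }
    )
    refs = {f"ref_{k}": v for k, v in panel.centroids.items()}
    ids = [f"X{i}" for i in range(len(numt))] + sorted(refs) + ["OG1", "OG2"]
    seqs = numt + [refs[k] for k in sorted(refs)] + [
        panel.outgroups["OG1"], panel.outgroups["OG2"]
    ]
    tree = build_tree(ids, seqs)
    return tree, {f"X{i}" for i in range(len(numt))}, set(sorted(refs))


class TestW2:
    def test_deep_numt_among_outgroups_fires(self, trees):
        tree, numt_group, refs = trees
        typical = {r for r in refs if r != "ref_D"}
        fired, note = warning_w2(tree, numt_group, typical, {"OG1", "OG2"})
        assert fired, note

    def test_typical_group_inside_species_clade_does_not_fire(self, trees):
        tree, _, refs = trees
        typical = {r for r in refs if r != "ref_D"}
        fired, _ = warning_w2(tree, {"ref_B"}, typical - {"ref_B"}, {"OG1", "OG2"})
        assert not fired

    def test_cryptic_sister_lineage_does_not_fire(self, panel):
        # D sits as sister to the typical clade, not among outgroups
        cfg_panel = panel
        from haplomite.synthetic_data import SynthConfig, simulate_haplogroup_panel

        p4 = simulate_haplogroup_panel(SynthConfig(seed=11, n_haplogroups=4))
        ids = [f"ref_{k}" for k in p4.centroids] + list(p4.outgroups)
        seqs = list(p4.centroids.values()) + list(p4.outgroups.values())
        tree = build_tree(ids, seqs)
        fired, _ = warning_w2(
            tree, {"ref_D"}, {"ref_A", "ref_B", "ref_C"}, {"OG1", "OG2"}
        )
        assert not fired

    def test_requires_two_outgroups(self, trees):
        tree, numt_group, refs = trees
        with pytest.raises(ValueError, match="outgroup"):
            warning_w2(tree, numt_group, refs, {"OG1"})


class TestW3:
    def test_star_farm_hd_below_threshold(self):
        # the {17,1,1,1} star: Hd ~ 0.284, high star score
        fired, low_n = warning_w3(hd=0.2842, star=0.85, n=20)
        assert not fired and not low_n

    def test_balanced_scattered_farm_fires(self):
        # counts {6,5,5,4}: Hd = 20(1 - 102/400)/19 ~ 0.784 > 0.70
        hd = 20 * (1 - (36 + 25 + 25 + 16) / 400) / 19
        assert hd == pytest.approx(0.7842105263157895)
        fired, _ = warning_w3(hd=hd, star=0.3, n=20)
        assert fired

    def test_single_haplotype_never_fires(self):
        fired, _ = warning_w3(hd=0.0, star=1.0, n=20)
        assert not fired

    def test_low_sampling_flagged(self):
        _, low_n = warning_w3(hd=0.9, star=0.2, n=8)
        assert low_n

    def test_balanced_but_star_shaped_does_not_fire(self):
        fired, _ = warning_w3(hd=0.8, star=0.7, n=20)
        assert not fired


class TestW4:
    def test_clean_farm_does_not_fire(self, star_farm):
        assert not warning_w4([r.residues for r in star_farm.records])

    def test_coamplified_farm_fires(self, config, panel):
        from haplomite.synthetic_data import simulate_farm_sample

        fs = simulate_farm_sample(
            config, panel, "with_numt", rng=np.random.default_rng(8),
            coamplified=True,
        )
        assert warning_w4([r.residues for r in fs.records])

    def test_single_ambiguous_base_stays_quiet(self):
        clean = "ACGTACGTAC" * 10
        seqs = [clean] * 19 + ["R" + clean[1:]]
        # one sequence with one double peak: below both thresholds
        assert not warning_w4(seqs)


class TestVerdict:
    def test_stop_codons_override_everything(self):
        v = warning_w5_and_verdict(
            "g", {W1: False, W2: False, W3: False, W4: False},
            stop_codon_present=True, divergent=True, nuclear_shared=None,
        )
        assert v.verdict == "numt_suspect"

    def test_two_warnings_compose_to_suspect(self):
        v = warning_w5_and_verdict(
            "g", {W1: True, W2: False, W3: True, W4: False},
            stop_codon_present=False, divergent=True, nuclear_shared=None,
        )
        assert v.verdict == "numt_suspect"
        assert v.warnings == {W1, W3}

    def test_single_warning_typical_flagged_for_review(self):
        v = warning_w5_and_verdict(
            "g", {W1: False, W2: False, W3: True, W4: False},
            stop_codon_present=False, divergent=False, nuclear_shared=None,
        )
        assert v.verdict == "typical"
        assert any("review" in f for f in v.flags)

    def test_divergent_private_nuclear_is_cryptic_candidate(self):
        v = warning_w5_and_verdict(
            "g", {W1: True, W2: False, W3: False, W4: False},
            stop_codon_present=False, divergent=True, nuclear_shared=False,
        )
        assert v.verdict == "cryptic_candidate"

    def test_divergent_shared_nuclear_is_numt(self):
        v = warning_w5_and_verdict(
            "g", {W1: False, W2: False, W3: False, W4: False},
            stop_codon_present=False, divergent=True, nuclear_shared=True,
        )
        assert v.verdict == "numt_suspect"
        assert W5 in v.warnings

    def test_absent_nuclear_data_flagged(self):
        v = warning_w5_and_verdict(
            "g", {W1: False, W2: False, W3: False, W4: False},
            stop_codon_present=False, divergent=False, nuclear_shared=None,
        )
        assert v.verdict == "typical"
        assert "nuclear data unavailable" in v.flags

    def test_adding_stops_is_monotone_toward_suspect(self):
        # whatever the warning pattern, turning stops on never moves the
        # verdict away from numt_suspect
        import itertools

        for bits in itertools.product([False, True], repeat=4):
            fired = dict(zip((W1, W2, W3, W4), bits))
            for div in (False, True):
                for shared in (None, True, False):
                    base = warning_w5_and_verdict(
                        "g", fired, False, div, shared
                    ).verdict
                    stopped = warning_w5_and_verdict(
                        "g", fired, True, div, shared
                    ).verdict
                    assert stopped == "numt_suspect"
                    order = {"typical": 0, "cryptic_candidate": 1,
                             "numt_suspect": 2}
                    assert order[stopped] >= order[base]

    def test_determinism(self):
        kw = dict(
            fired={W1: True, W2: False, W3: True, W4: False},
            stop_codon_present=False, divergent=True, nuclear_shared=True,
        )
        a = warning_w5_and_verdict("g", **kw)
        b = warning_w5_and_verdict("g", **kw)
        assert (a.verdict, sorted(a.warnings), a.rationale) == (
            b.verdict, sorted(b.warnings), b.rationale
        )


class TestScreenConfig:
    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ScreenConfig(tau_hd=1.5)
        with pytest.raises(ValueError):
            ScreenConfig(tau_aa_seg=0)

    def test_serializable(self):
        import json

        cfg = ScreenConfig()
        assert json.loads(cfg.to_json())["tau_hd"] == 0.70
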