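"""Codon-position partitioning, NJ correctness and resolution retention.

The NJ oracle builds random additive matrices from explicit random trees
(leaf distances = path sums) and checks topology recovery by bipartition
comparison; on additive data NJ provably recovers the unique tree.
"""

import numpy as np
import pytest

from haplomite.phylo_diag import (
    build_tree,
    distance_matrix,
    group_stem_length,
    group_support,
    resolution_retention,
    subset_codon_positions,
)
from haplomite.synthetic_data import (
    SynthConfig,
    simulate_farm_sample,
    simulate_haplogroup_panel,
)


class TestCodonPositions:
    def test_first_positions_of_full_length_window(self):
        seqs = ["A" * 471]
        assert len(subset_codon_positions(seqs, 0, "pos1")[0]) == 157

    def test_direct_indexing_example(self):
        assert subset_codon_positions(["ATGTTTAAA"], 0, "pos3") == ["GTA"]
        assert subset_codon_positions(["ATGTTTAAA"], 0, "pos1") == ["ATA"]

    def test_partition_reassembles_window(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        parts = [
            subset_codon_positions([seq], 0, p)[0]
            for p in ("pos1", "pos2", "pos3")
        ]
        rebuilt = "".join(
            parts[0][i] + parts[1][i] + parts[2][i] for i in range(20)
        )
        assert rebuilt == seq
        assert sum(len(p) for p in parts) == len(seq)

    def test_frame_offset_discards_partial_codon(self):
        assert subset_codon_positions(["XATGTTT".replace("X", "G")], 1, "pos1") == ["AT"]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            subset_codon_positions(["ACGTAC"], 3, "pos1")
        with pytest.raises(ValueError):
            subset_codon_positions(["ACGTAC"], 0, "pos4")


def random_additive_tree(rng, n_leaves):
    """Random binary tree -> (leaf names, distance matrix, bipartitions)."""
    import itertools

    nodes = [(f"L{i}",) for i in range(n_leaves)]
    edges = {}
    children = {}
    nxt = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = (f"N{nxt}",)
        nxt += 1
        children[parent] = (a, b)
        edges[a] = float(rng.integers(1, 20))
        edges[b] = float(rng.integers(1, 20))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]

    def leaves(node):
        if node not in children:
            return [node[0]]
        a, b = children[node]
        return leaves(a) + leaves(b)

    names = [f"L{i}" for i in range(n_leaves)]
    root = nodes[0]

    def depth_map(node, acc):
        out = {}
        if node not in children:
            out[node[0]] = acc
            return out
        a, b = children[node]
        out.update(depth_map(a, acc + edges[a]))
        out.update(depth_map(b, acc + edges[b]))
        return out

    # distances via shared-path subtraction
    dm = np.zeros((n_leaves, n_leaves))
    depths = depth_map(root, 0.0)

    def mrca_depth(x, y, node, acc):
        if node not in children:
            return None
        a, b = children[node]
        la, lb = set(leaves(a)), set(leaves(b))
        if x in la and y in la:
            return mrca_depth(x, y, a, acc + edges[a])
        if x in lb and y in lb:
            return mrca_depth(x, y, b, acc + edges[b])
        return acc

    for x, y in itertools.combinations(range(n_leaves), 2):
        nx_, ny = names[x], names[y]
        m = mrca_depth(nx_, ny, root, 0.0)
        d = depths[nx_] + depths[ny] - 2 * m
        dm[x, y] = dm[y, x] = d

    # internal bipartitions (canonical: the side without the first sorted name)
    anchor = sorted(names)[0]
    bips = set()
    for node in children:
        side = frozenset(leaves(node))
        if 2 <= len(side) <= n_leaves - 2:
            bips.add(side if anchor not in side else frozenset(names) - side)
    return names, dm, bips


class TestNeighborJoining:
    def test_quartet_recovered_from_additive_matrix(self):
        # classic additive quartet: ((a,b),(c,d)) with the four-point
        # condition holding strictly
        dm = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
            dtype=float,
        )
        from skbio import DistanceMatrix
        from skbio.tree import nj

        tree = nj(DistanceMatrix(dm, list("abcd")))
        sides = {
            frozenset(t.name for t in n.tips())
            for n in tree.non_tips(include_self=False)
        }
        assert frozenset({"a", "b"}) in sides or frozenset({"c", "d"}) in sides

    def test_additive_matrices_up_to_eight_leaves(self):
        rng = np.random.default_rng(11)
        from skbio import DistanceMatrix
        from skbio.tree import nj

        for trial in range(30):
            n = int(rng.integers(4, 9))
            names, dm, true_bips = random_additive_tree(rng, n)
            tree = nj(DistanceMatrix(dm, names))
            anchor = sorted(names)[0]
            got = set()
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    got.add(
                        side if anchor not in side else frozenset(names) - side
                    )
            assert got == true_bips, f"trial {trial}"

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="4 taxa"):
            build_tree(["a", "b", "c"], ["ACGT"] * 3)

    def test_no_supports_without_bootstrap(self, panel):
        ids = list(panel.centroids) + list(panel.outgroups)
        seqs = list(panel.centroids.values()) + list(panel.outgroups.values())
        dt = build_tree(ids, seqs, bootstrap=0)
        assert dt.supports == {}
        assert "OG1" in dt.newick()

    def test_deterministic_given_seed(self, panel):
        ids = list(panel.centroids) + list(panel.outgroups)
        seqs = list(panel.centroids.values()) + list(panel.outgroups.values())
        t1 = build_tree(ids, seqs, bootstrap=30, seed=5)
        t2 = build_tree(ids, seqs, bootstrap=30, seed=5)
        assert t1.supports == t2.supports
        assert t1.newick() == t2.newick()

    def test_distance_models(self):
        seqs = ["ACGTACGTAC", "ACGTACGTAT", "TTTTACGTAC", "ACGAACGAAC"]
        p = distance_matrix(seqs, "p")
        jc = distance_matrix(seqs, "JC")
        k2p = distance_matrix(seqs, "K2P")
        assert np.all(jc >= p - 1e-12)  # JC correction expands distances
        assert np.allclose(np.diag(jc), 0)
        assert np.allclose(k2p, k2p.T)

    def test_jc_saturation_falls_back_to_p(self):
        seqs = ["AAAA", "CCCC", "GGGG", "TTTT"]
        with pytest.warns(UserWarning, match="saturation"):
            d = distance_matrix(seqs, "JC")
        assert np.all(np.isfinite(d))


class TestPanelMonophyly:
    def test_synthetic_haplogroups_supported_on_all_positions(self):
        # star samples per group + outgroups: each group monophyletic with
        # high bootstrap support on the full window
        cfg = SynthConfig(seed=1, n_haplogroups=4, farm_size=6)
        panel = simulate_haplogroup_panel(cfg)
        rng = np.random.default_rng(77)
        ids, seqs, groups = [], [], {}
        for label in panel.centroids:
            fs = simulate_farm_sample(
                cfg, panel, "single_group", farm_id=label, rng=rng, group=label
            )
            uniq = sorted(set(r.residues for r in fs.records))
            names = [f"{label}{k}" for k in range(len(uniq))]
            ids += names
            seqs += uniq
            groups[label] = set(names)
        ids += list(panel.outgroups)
        seqs += list(panel.outgroups.values())
        dt = build_tree(ids, seqs, bootstrap=100, seed=1)
        for label, members in groups.items():
            if len(members) < 2:
                continue
            assert group_support(dt, members) >= 90, label
            assert group_stem_length(dt, members) > 0


from _benchmarks import replicate_retention_rows  # noqa: E402


@pytest.fixture(scope="module")
def retention_rows():
    return replicate_retention_rows(seeds=range(4))


class TestRetention:
    def test_typical_groups_lose_pos1_resolution(self, retention_rows):
        typ = [r for r in retention_rows if r.group in "ABC"]
        assert typ
        flagged = sum(r.retained for r in typ)
        assert flagged <= 0.1 * len(typ) + 1

    def test_numt_groups_retain_pos1_resolution(self, retention_rows):
        numt = [r for r in retention_rows if r.group == "X"]
        assert len(numt) == 4
        assert sum(r.retained for r in numt) >= 3
        # the pseudogene signature: long first-position stems
        assert all(r.stem_pos1 > 0.01 for r in numt)

    def test_whole_taxon_group_is_degenerate(self, panel):
        ids = list(panel.centroids) + list(panel.outgroups)
        seqs = list(panel.centroids.values()) + list(panel.outgroups.values())
        rows = resolution_retention(
            ids, seqs, {"all": set(ids)}, bootstrap=10, seed=0
        )
        assert rows[0].degenerate and rows[0].retained
        assert rows[0].support_all == 100.0

    def test_unknown_group_member_rejected(self, panel):
        ids = list(panel.centroids) + list(panel.outgroups)
        seqs = list(panel.centroids.values()) + list(panel.outgroups.values())
        with pytest.raises(ValueError, match="not in tree"):
            resolution_retention(ids, seqs, {"g": {"nope"}}, bootstrap=0, seed=0)
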