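import numpy as np
import pytest

from hogimine.bitsupport import DOMINANT, RECESSIVE, SampleBitset
from hogimine.cmh_stats import chi2_sf
from hogimine.data_io import InteractionSet
from hogimine.fwer_control import TaroneState
from hogimine.miner import (
    MinerConfig,
    Pattern,
    generate_children,
    initial_patterns,
    is_closed,
    mine,
    pattern_support,
)

from conftest import build_dataset, random_tiny_dataset
from _oracles import oracle_mine


class TestInitialPatterns:
    @pytest.mark.parametrize(
        "sizes,mode,expected",
        [
            ((3, 2), "additive", 3 * 2 * 4),
            ((3, 2), "binary", 6),
            ((3,), "additive", 6),
        ],
    )
    def test_counts(self, sizes, mode, expected):
        genes = tuple(f"g{i}" for i in range(len(sizes)))
        pats = initial_patterns(genes, sizes, mode)
        assert len(pats) == expected
        assert len({p.key for p in pats}) == expected
        assert all(p.total_length == len(sizes) for p in pats)


class TestGenerateChildren:
    def _pat(self, intervals, k=2):
        genes = tuple(f"g{i}" for i in range(k))
        return Pattern(genes, intervals, (DOMINANT,) * k)

    def test_root_has_both_extensions(self):
        children = generate_children(self._pat(((0, 1), (0, 1))), (3, 2))
        assert [c.intervals for c, _, _ in children] == [
            ((0, 2), (0, 1)),
            ((0, 1), (0, 2)),
        ]

    def test_grown_first_gene_blocks_later_genes(self):
        children = generate_children(self._pat(((0, 2), (0, 1))), (3, 2))
        assert [c.intervals for c, _, _ in children] == [((0, 3), (0, 1))]

    def test_bounds_and_blocking_give_no_children(self):
        # first gene at its right boundary, second gene already length 2
        children = generate_children(self._pat(((1, 3), (0, 2))), (3, 2))
        assert children == []

    def test_max_interval_len_caps_growth(self):
        children = generate_children(self._pat(((0, 2), (0, 1))), (5, 5), 2)
        assert [c.intervals for c, _, _ in children] == []

    def test_each_pattern_generated_exactly_once(self):
        """BFS from the single-marker roots reaches every interval
        combination exactly once (canonical parent uniqueness)."""
        sizes = (4, 3, 2)
        genes = ("a", "b", "c")
        seen = []
        frontier = [
            Pattern(genes, ivals.intervals, ivals.encodings)
            for ivals in initial_patterns(genes, sizes, "binary")
        ]
        while frontier:
            seen.extend(p.key for p in frontier)
            frontier = [
                c for p in frontier for c, _, _ in generate_children(p, sizes)
            ]
        expected = (4 * 5 // 2) * (3 * 4 // 2) * (2 * 3 // 2)
        assert len(seen) == expected
        assert len(set(seen)) == expected


class TestProcessAndSupport:
    def test_perfect_association_statistic(self):
        """Support equal to the case set gives T = n - 1."""
        rng = np.random.default_rng(0)
        y = np.array([1] * 10 + [0] * 10)
        values = np.vstack([y, rng.integers(0, 3, size=(2, 20))]).astype(np.int8)
        ds = build_dataset(values, y, gene_sizes=[3], mode="additive")
        pat = Pattern(("g0",), ((0, 1),), (DOMINANT,))
        sup = pattern_support(pat, ds)
        assert sup == SampleBitset.from_indicators(y)
        res = mine(
            ds,
            InteractionSet([("g0",)]),
            MinerConfig(mode="additive", fwer="tarone"),
        )
        assert any(s.intervals == ((0, 1),) for s in res.significant)
        top = min(s.p for s in res.significant)
        assert top == pytest.approx(chi2_sf(19.0), rel=1e-12)

    def test_evaluate_pattern_degenerate_supports(self):
        """Full supports are untestable AND prunable; empty supports are
        untestable but must stay expandable (descendants can gain carriers)."""
        from hogimine.miner import evaluate_pattern

        values = np.array([[1] * 8, [0] * 8, [1, 1, 1, 1, 0, 0, 0, 0]], dtype=np.int8)
        y = [1, 1, 0, 0, 1, 1, 0, 0]
        ds = build_dataset(values, y, gene_sizes=[3], mode="binary")
        full, _ = evaluate_pattern(Pattern(("g0",), ((0, 1),), (DOMINANT,)), ds)
        assert full.p_min == 1.0 and full.p_env == 1.0
        empty, _ = evaluate_pattern(Pattern(("g0",), ((1, 2),), (DOMINANT,)), ds)
        assert empty.p_min == 1.0
        assert empty.p_env < 0.05  # descendants can still become testable
        assert empty.p_env <= empty.p_min <= empty.p

    def test_support_consistency_with_recomputation(self):
        """Supports accumulated by OR-extension equal from-scratch ORs."""
        rng = np.random.default_rng(5)
        values = rng.integers(0, 3, size=(7, 30)).astype(np.int8)
        ds = build_dataset(
            values, rng.integers(0, 2, size=30), gene_sizes=[4, 3], mode="additive"
        )
        genes = ("g0", "g1")
        sizes = (4, 3)
        for H in ((DOMINANT, DOMINANT), (DOMINANT, RECESSIVE)):
            frontier = [
                (p, pattern_support(p, ds))
                for p in initial_patterns(genes, sizes, "additive")
                if p.encodings == H
            ]
            while frontier:
                nxt = []
                for parent, sup in frontier:
                    for child, gi, pos in generate_children(parent, sizes):
                        row = ds.genemap[genes[gi]][pos]
                        from hogimine.bitsupport import binarize_marker

                        child_sup = sup | binarize_marker(
                            ds.genotypes.values[row], H[gi]
                        )
                        assert child_sup == pattern_support(child, ds)
                        assert child_sup.popcount() >= sup.popcount()
                        nxt.append((child, child_sup))
                frontier = nxt


class TestIsClosed:
    def test_single_marker_patterns_closed_vacuously(self, tiny_dataset):
        pat = Pattern(("g0",), ((1, 2),), (DOMINANT,))
        assert is_closed(pat, tiny_dataset)

    def test_zero_column_extension_not_closed(self):
        values = np.array([[0, 1, 1, 0], [0, 0, 0, 0]], dtype=np.int8)
        ds = build_dataset(values, [1, 0, 1, 0], gene_sizes=[2], mode="binary")
        assert not is_closed(Pattern(("g0",), ((0, 2),), (DOMINANT,)), ds)

    def test_strictly_growing_support_closed(self):
        values = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]], dtype=np.int8)
        ds = build_dataset(values, [1, 0, 1, 0], gene_sizes=[3], mode="binary")
        assert is_closed(Pattern(("g0",), ((0, 3),), (DOMINANT,)), ds)


class TestMine:
    @pytest.mark.parametrize("mode", ["additive", "binary"])
    def test_pattern_space_size_without_pruning(self, mode):
        """With pruning off, the processed count is the closed-form product
        prod_i l_i(l_i+1)/2, times 2^k in additive mode."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            k = int(rng.integers(1, 4))
            sizes = [int(rng.integers(1, 5)) for _ in range(k)]
            L = sum(sizes)
            values = rng.integers(0, 3 if mode == "additive" else 2, size=(L, 15))
            ds = build_dataset(
                values, rng.integers(0, 2, size=15), gene_sizes=sizes, mode=mode
            )
            inters = InteractionSet([tuple(ds.genemap.genes)])
            res = mine(ds, inters, MinerConfig(mode=mode, prune=False))
            expected = 1
            for l in sizes:
                expected *= l * (l + 1) // 2
            if mode == "additive":
                expected *= 2**k
            assert res.n_processed == expected

    def test_labels_independent_of_genotypes_usually_empty(self):
        rng = np.random.default_rng(100)
        hits = 0
        for rep in range(10):
            ds, inters = random_tiny_dataset(rng, mode="binary")
            res = mine(ds, inters, MinerConfig(mode="binary"))
            hits += bool(res.significant)
        assert hits <= 2

    @pytest.mark.parametrize("fwer", ["tarone", "wy"])
    def test_matches_exhaustive_oracle(self, fwer):
        """Pruned, canonically generated mining returns exactly the
        significant set and threshold of the brute-force enumerator."""
        rng = np.random.default_rng(77)
        for rep in range(8):
            mode = "additive" if rep % 2 else "binary"
            ds, inters = random_tiny_dataset(rng, mode=mode, n_max=40)
            cfg = MinerConfig(
                mode=mode, fwer=fwer, n_permutations=15, seed=rep, alpha=0.2
            )
            res = mine(ds, inters, cfg)
            perms = None
            if fwer == "wy":
                from hogimine.fwer_control import make_permutations

                perms = make_permutations(ds.masks, 15, rep)
            delta_o, sig_o = oracle_mine(
                ds, inters, mode, 0.2, cfg.grid_ratio, fwer=fwer, permutations=perms
            )
            assert res.delta_final == pytest.approx(delta_o, rel=1e-12)
            assert sorted(s.key for s in res.significant) == sig_o

    def test_interaction_with_unknown_gene_skipped(self, tiny_dataset):
        with pytest.warns(UserWarning, match="skipping interaction"):
            res = mine(
                tiny_dataset,
                InteractionSet([("g0", "nope")]),
                MinerConfig(mode="additive"),
            )
        assert res.n_processed == 0
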