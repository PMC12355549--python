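"""SNP-panel construction: merging, masking, site selection, distances, NJ."""

import dendropy
import numpy as np
import pytest

from paleokit import snp_panel as sp
from paleokit.errors import DataError, ParameterError
from paleokit.records import SampleCall, SnpAlignment, VariantCallRecord
from tests._oracles import naive_panel, random_call_table

P = sp.SnpPanelParams()


def _rec(pos, ref, alts, sample, call, contig="c1"):
    return VariantCallRecord(contig=contig, pos=pos, ref=ref, alts=alts,
                             calls={sample: call})


def _call(gt=(1, 1), dp=10, ad=(0, 10), gq=50):
    return SampleCall(gt=gt, dp=dp, ad=ad, gq=gq)


class TestMerge:
    def test_disjoint_sites_union_with_missing(self):
        table = sp.merge_union_sites({
            "a": [_rec(5, "A", ("G",), "a", _call())],
            "b": [_rec(9, "C", ("T",), "b", _call())],
        })
        assert [(s.contig, s.pos) for s in table.sites] == [("c1", 5), ("c1", 9)]
        assert table.sites[0].calls["b"].is_missing
        assert table.sites[1].calls["a"].is_missing

    def test_idempotent_on_identical_sets(self):
        recs = {"a": [_rec(5, "A", ("G",), "a", _call())]}
        t1 = sp.merge_union_sites(recs)
        assert len(t1.sites) == 1
        assert t1.sites[0].calls["a"] == recs["a"][0].calls["a"]

    def test_ad_indices_remapped_hand_merge(self):
        """Three samples with different alt sets at one position: allele depths
        must land on the merged allele list positions."""
        table = sp.merge_union_sites({
            "a": [_rec(7, "A", ("G",), "a", _call(gt=(1, 1), ad=(2, 8)))],
            "b": [_rec(7, "A", ("T",), "b", _call(gt=(1, 1), ad=(1, 9)))],
            "c": [_rec(7, "A", ("G", "T"), "c", _call(gt=(2, 2), ad=(0, 3, 7)))],
        })
        (site,) = table.sites
        assert site.alleles == ("A", "G", "T")
        assert site.calls["a"].ad == (2, 8, 0)
        assert site.calls["b"].ad == (1, 0, 9)
        assert site.calls["c"].ad == (0, 3, 7)
        assert site.calls["b"].gt == (2, 2)  # T remapped from index 1 to 2

    def test_conflicting_ref_rejected(self):
        with pytest.raises(DataError, match="c1:5"):
            sp.merge_union_sites({
                "a": [_rec(5, "A", ("G",), "a", _call())],
                "b": [_rec(5, "C", ("G",), "b", _call())],
            })


class TestGenotypeSite:
    @pytest.mark.parametrize("call,expected", [
        (SampleCall(), "N"),                                    # missing ./.
        (_call(dp=2, ad=(0, 2)), "N"),                          # depth below 3
        (_call(gq=20), "N"),                                    # GQ below 30
        (_call(ad=(9, 1), dp=10, gq=40, gt=(0, 0)), "A"),       # f=0.9 inclusive
        (_call(ad=(7, 3), dp=10, gq=40), "N"),                  # f=0.7 < 0.9
        (_call(ad=(5, 5), dp=10, gq=40), "N"),                  # exact tie
        (_call(ad=(0, 10), dp=10, gq=40), "G"),                 # clean alt call
    ])
    def test_masking_rules(self, call, expected):
        assert sp.genotype_site(call, ("A", "G"), P) == expected

    def test_strict_threshold_masks_boundary(self):
        strict = sp.SnpPanelParams(strict_het_ratio=True)
        call = _call(ad=(9, 1), dp=10, gq=40)
        assert sp.genotype_site(call, ("A", "G"), P) == "A"
        assert sp.genotype_site(call, ("A", "G"), strict) == "N"

    def test_all_zero_ad_with_depth_is_error(self):
        with pytest.raises(DataError):
            sp.genotype_site(_call(ad=(0, 0), dp=10, gq=40), ("A", "G"), P)

    def test_param_invariants(self):
        with pytest.raises(ParameterError):
            sp.SnpPanelParams(het_ratio=0.4)
        with pytest.raises(ParameterError):
            sp.SnpPanelParams(min_presence=0.0)
        with pytest.raises(ParameterError):
            sp.SnpPanelParams(min_spacing=0)


class TestSelectSites:
    def _table(self, site_defs):
        """site_defs: list of (pos, ref, alts, {sample: call})"""
        samples = sorted({s for *_, calls in site_defs for s in calls})
        per_sample = {s: [] for s in samples}
        for pos, ref, alts, calls in site_defs:
            for s, c in calls.items():
                per_sample[s].append(_rec(pos, ref, alts, s, c))
        return sp.merge_union_sites(per_sample)

    def test_all_n_site_dropped(self):
        table = self._table([
            (5, "A", ("G",), {"a": SampleCall(), "b": SampleCall()}),
        ])
        geno = sp.genotype_table(table, P)
        assert sp.select_panel_sites(table, geno, P) == []

    def test_greedy_spacing_hand_trace(self):
        """Positions 100,101,102,105, spacing 3 -> keep {100, 105}."""
        good_a, good_b = _call(gt=(0, 0), ad=(10, 0)), _call(gt=(1, 1), ad=(0, 10))
        site_defs = [(p, "A", ("G",), {"a": good_a, "b": good_b}) for p in (100, 101, 102, 105)]
        table = self._table(site_defs)
        geno = sp.genotype_table(table, P)
        retained = sp.select_panel_sites(table, geno, P)
        assert [table.sites[j].pos for j in retained] == [100, 105]

    def test_each_rule_uniquely_removes_a_site(self):
        """Eight spaced sites; four engineered failures (indel, monomorphic
        after masking, triallelic, presence) plus one spacing casualty."""
        A, G = _call(gt=(0, 0), ad=(10, 0)), _call(gt=(1, 1), ad=(0, 10))
        N = SampleCall()
        t = _call(gt=(1, 1), ad=(0, 10))
        site_defs = [
            (10, "A", ("G",), {"a": A, "b": G, "c": A, "d": G}),      # keep
            (20, "A", ("AT",), {"a": A, "b": t, "c": A, "d": t}),     # indel
            (30, "C", ("T",), {"a": _call(gt=(0, 0), ad=(10, 0)),     # monomorphic
                               "b": _call(gt=(0, 0), ad=(9, 1), dp=10),
                               "c": _call(gt=(0, 0), ad=(10, 0)),
                               "d": N}),
            (40, "A", ("C", "T"), {"a": _call(gt=(0, 0), ad=(10, 0, 0)),  # 3 bases observed
                                   "b": _call(gt=(1, 1), ad=(0, 10, 0)),
                                   "c": _call(gt=(2, 2), ad=(0, 0, 10)),
                                   "d": _call(gt=(0, 0), ad=(10, 0, 0))}),
            (50, "A", ("G",), {"a": A, "b": G, "c": N, "d": N}),      # presence 0.5 < 0.75
            (60, "A", ("G",), {"a": A, "b": G, "c": G, "d": G}),      # keep
            (62, "A", ("G",), {"a": A, "b": G, "c": A, "d": G}),      # spacing < 3 from 60
            (70, "A", ("G",), {"a": G, "b": G, "c": A, "d": G}),      # keep
        ]
        table = self._table(site_defs)
        geno = sp.genotype_table(table, P)
        retained = sp.select_panel_sites(table, geno, P)
        assert [table.sites[j].pos for j in retained] == [10, 60, 70]
        # independent oracle agrees cell for cell
        coords, rows = naive_panel(table)
        assert [p for _, p in coords] == [10, 60, 70]
        aln = sp.build_snp_alignment(table, geno, retained)
        for i, s in enumerate(aln.sample_ids):
            assert "".join(aln.matrix[i]) == rows[s]


class TestOracleEquivalence:
    def test_random_tables_match_naive_reimplementation(self, rng):
        """Full pipeline (genotype -> select -> build) equals the naive
        brute-force route cell for cell on random tables."""
        for _ in range(100):
            per_sample = random_call_table(rng)
            table = sp.merge_union_sites(per_sample)
            geno = sp.genotype_table(table, P)
            retained = sp.select_panel_sites(table, geno, P)
            aln = sp.build_snp_alignment(table, geno, retained)
            coords, rows = naive_panel(table)
            assert aln.site_coords == coords
            for i, s in enumerate(aln.sample_ids):
                assert "".join(aln.matrix[i]) == rows[s]

    def test_masking_presence_spacing_biallelic_invariants(self, rng):
        for _ in range(60):
            per_sample = random_call_table(rng)
            table = sp.merge_union_sites(per_sample)
            geno = sp.genotype_table(table, P)
            retained = sp.select_panel_sites(table, geno, P)
            aln = sp.build_snp_alignment(table, geno, retained)
            n = aln.n_samples
            for k, j in enumerate(retained):
                site = table.sites[j]
                col = aln.matrix[:, k]
                # masking soundness: emitted bases pass every per-call filter
                for i, s in enumerate(aln.sample_ids):
                    if col[i] == "N":
                        continue
                    c = site.calls[s]
                    depth = c.dp if c.dp is not None else sum(c.ad)
                    assert c.gq >= P.min_gq and depth >= P.min_depth
                    assert max(c.ad) / sum(c.ad) >= P.het_ratio
                    assert site.alleles[int(np.argmax(c.ad))] == col[i]
                # presence / biallelic
                assert (col == "N").sum() / n <= 1 - P.min_presence
                assert len(set(col.tolist()) - {"N"}) == 2
            # spacing within contig
            by_contig = {}
            for contig, pos in aln.site_coords:
                by_contig.setdefault(contig, []).append(pos)
            for positions in by_contig.values():
                assert all(b - a >= P.min_spacing for a, b in zip(positions, positions[1:]))


class TestDistances:
    def _aln(self, rows, ids=None):
        ids = ids or [f"s{i}" for i in range(len(rows))]
        return SnpAlignment(
            sample_ids=ids,
            site_coords=[("c", i + 1) for i in range(len(rows[0]))],
            matrix=np.array([list(r) for r in rows]),
        )

    def test_identical_rows(self):
        D, _ = sp.pairwise_p_distance(self._aln(["ACGT", "ACGT"]))
        assert D[0, 1] == 0.0

    def test_quarter_mismatch(self):
        D, _ = sp.pairwise_p_distance(self._aln(["ACGT", "ACGA"]))
        assert D[0, 1] == 0.25

    def test_n_columns_excluded(self):
        D, C = sp.pairwise_p_distance(self._aln(["ANNT", "AGGT"]))
        assert D[0, 1] == 0.0 and C[0, 1] == 2

    def test_no_comparable_columns_is_nan(self):
        D, _ = sp.pairwise_p_distance(self._aln(["NNAA", "GGNN"]))
        assert np.isnan(D[0, 1])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        """Branch lengths solve the three-point equations exactly."""
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        nwk = sp.neighbor_joining(D, ["a", "b", "c"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(3, abs=1e-9)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(4, abs=1e-9)
        assert pdm.distance(taxa["b"], taxa["c"]) == pytest.approx(5, abs=1e-9)

    @staticmethod
    def _rf(nwk1, nwk2):
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns,
                               preserve_underscores=True)
        t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns,
                               preserve_underscores=True)
        t1.encode_bipartitions(), t2.encode_bipartitions()
        return dendropy.calculate.treecompare.symmetric_difference(t1, t2)

    def test_additive_four_taxon_recovery(self):
        """((a,b),(c,d)) with all branch lengths 1: NJ recovers the topology
        and the exact additive distances."""
        true_nwk = "((a:1,b:1):1,(c:1,d:1):1);"
        D = np.array([
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ], dtype=float)
        nwk = sp.neighbor_joining(D, ["a", "b", "c", "d"])
        assert self._rf(nwk, true_nwk) == 0

    def test_label_permutation_invariance(self, rng):
        labels = ["a", "b", "c", "d", "e"]
        # random additive-ish symmetric matrix
        X = rng.uniform(1, 5, size=(5, 5))
        D = (X + X.T) / 2
        np.fill_diagonal(D, 0)
        nwk1 = sp.neighbor_joining(D, labels)
        perm = [3, 1, 4, 0, 2]
        nwk2 = sp.neighbor_joining(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert self._rf(nwk1, nwk2) == 0

    def test_agrees_with_skbio(self, rng):
        """Independent NJ implementation recovers the same topology."""
        import skbio

        n = 7
        X = rng.uniform(1, 10, size=(n, n))
        D = (X + X.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"t{i}" for i in range(n)]
        ours = sp.neighbor_joining(D, labels)
        theirs = str(skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels)))
        assert self._rf(ours, theirs) == 0

    def test_nan_rejected(self):
        D = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(DataError):
            sp.neighbor_joining(D, ["a", "b"])


class TestEndToEndRecovery:
    def test_alignment_matches_truth_where_unmasked(self, strain_set, noise_free_calls):
        """Noise-free simulation: every unmasked alignment cell equals the
        strain's true allele."""
        aln, table, retained = sp.build_panel(noise_free_calls)
        truth = {pos: alleles for pos, _, alleles in strain_set.variant_sites}
        for k, (contig, pos) in enumerate(aln.site_coords):
            for i, s in enumerate(aln.sample_ids):
                base = aln.matrix[i, k]
                if base != "N":
                    assert base == truth[pos][s]

    def test_phylogenetic_recovery(self):
        """8 strains, >=200 true SNPs, 30x noise-free: NJ recovers the true
        topology (RF=0) and p-distances correlate with true patristic."""
        from scipy.stats import spearmanr

        from paleokit.simulate import StrainSimConfig, simulate_sample_calls, simulate_strain_set

        ss = simulate_strain_set(
            StrainSimConfig(n_strains=8, genome_length=50_000, subs_per_branch=30, seed=77)
        )
        assert len(ss.variant_sites) >= 200
        calls = simulate_sample_calls(
            ss, coverage_mean=30, gq_model=lambda rng, n: np.full(n, 99, dtype=int), seed=78
        )
        aln, _, _ = sp.build_panel(calls)
        D, _ = sp.pairwise_p_distance(aln)
        nwk = sp.neighbor_joining(D, aln.sample_ids)
        assert TestNeighborJoining._rf(nwk, ss.tree_newick) == 0
        # Spearman between true patristic and estimated p-distances
        tree = dendropy.Tree.get(data=ss.tree_newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        iu = np.triu_indices(len(aln.sample_ids), 1)
        true_d = [pdm.distance(taxa[aln.sample_ids[i]], taxa[aln.sample_ids[j]])
                  for i, j in zip(*iu)]
        rho = spearmanr(true_d, D[iu]).statistic
        assert rho >= 0.9
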