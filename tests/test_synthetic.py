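"""Synthetic-data generators: determinism, planted structure, null behaviour."""

import numpy as np
import pytest
from scipy import stats

from pollenpref import (GeneSet, ValidationError, conservancy,
                        gen_cross_progeny, gen_expression, gen_go_annotation,
                        gen_ortholog_map)
from pollenpref.enrichment import filter_enriched, fold_enrichment
from pollenpref.synthetic import PanelGroup


def _tiny_panels():
    return {
        "cvA": [PanelGroup("anther", "Me", 0, False, 2),
                PanelGroup("pollen", "MP", 1, True, 2),
                PanelGroup("root", "other", 2, False, 2)],
        "cvB": [PanelGroup("anther", "Me", 0, False, 2),
                PanelGroup("pollen", "MP", 1, True, 2)],
    }


class TestGenExpression:
    def test_same_seed_bit_identical(self):
        a = gen_expression(n_genes=50, n_planted=5, panels=_tiny_panels(),
                           seed=3)
        b = gen_expression(n_genes=50, n_planted=5, panels=_tiny_panels(),
                           seed=3)
        for cv in a.matrices:
            np.testing.assert_array_equal(a.matrices[cv].values,
                                          b.matrices[cv].values)
        assert a.planted == b.planted
        assert a.probe_gene_map.mapping == b.probe_gene_map.mapping

    def test_planted_genes_elevated_on_late_samples_only(self):
        syn = gen_expression(n_genes=100, n_planted=10, panels=_tiny_panels(),
                             effect_size_log2=4.0, noise_sd=0.3, seed=1)
        for cv, matrix in syn.matrices.items():
            meta = syn.metadata[cv].for_samples(matrix.sample_ids)
            late = meta["is_late_pollen"].to_numpy(dtype=bool)
            planted_mask = np.array(
                [syn.probe_gene_map.get(p) in syn.planted[cv]
                 for p in matrix.probe_ids])
            late_gap = (matrix.values[planted_mask][:, late].mean()
                        - matrix.values[~planted_mask][:, late].mean())
            other_gap = (matrix.values[planted_mask][:, ~late].mean()
                         - matrix.values[~planted_mask][:, ~late].mean())
            assert late_gap == pytest.approx(4.0, abs=0.5)
            assert other_gap == pytest.approx(0.0, abs=0.5)

    def test_overlap_fraction_controls_shared_planted(self):
        syn = gen_expression(n_genes=200, n_planted=20, overlap_fraction=0.8,
                             panels=_tiny_panels(), seed=5)
        assert len(syn.planted_shared) == 16
        for cv in syn.planted:
            assert len(syn.planted[cv]) == 20
            assert syn.planted_shared <= syn.planted[cv]

    def test_probe_gene_ratio_near_target(self):
        syn = gen_expression(n_genes=2000, n_planted=10, panels=_tiny_panels(),
                             seed=2)
        ratio = len(syn.probe_gene_map) / len(syn.genes)
        assert ratio == pytest.approx(750 / 627, abs=0.05)

    def test_zero_effect_size_gives_uniform_pvalues(self):
        """With no planted effect, planted and background late-stage means are
        statistically indistinguishable: two-sample p-values are uniform
        across seeds."""
        pvals = []
        for seed in range(200):
            syn = gen_expression(n_genes=40, n_planted=8,
                                 panels={"cv": _tiny_panels()["cvA"]},
                                 effect_size_log2=0.0, seed=seed)
            m = syn.matrices["cv"]
            meta = syn.metadata["cv"].for_samples(m.sample_ids)
            late = meta["is_late_pollen"].to_numpy(dtype=bool)
            planted_mask = np.array(
                [syn.probe_gene_map.get(p) in syn.planted["cv"]
                 for p in m.probe_ids])
            late_means = m.values[:, late].mean(axis=1)
            _, p = stats.ttest_ind(late_means[planted_mask],
                                   late_means[~planted_mask])
            pvals.append(p)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 1e-3

    def test_generated_fixtures_satisfy_reader_invariants(self, tmp_path):
        from pollenpref import read_expression, write_expression, write_metadata
        syn = gen_expression(n_genes=30, n_planted=3, panels=_tiny_panels(),
                             seed=9)
        for cv, matrix in syn.matrices.items():
            write_expression(matrix, tmp_path / f"{cv}.tsv")
            write_metadata(syn.metadata[cv], tmp_path / f"{cv}_meta.tsv")
            back, _ = read_expression(tmp_path / f"{cv}.tsv",
                                      tmp_path / f"{cv}_meta.tsv")
            np.testing.assert_allclose(back.values, matrix.values)

    def test_invalid_parameters_fatal(self):
        with pytest.raises(ValidationError):
            gen_expression(n_genes=5, n_planted=10, panels=_tiny_panels())
        with pytest.raises(ValidationError):
            gen_expression(n_genes=50, n_planted=5, overlap_fraction=1.5,
                           panels=_tiny_panels())
        no_late = {"cv": [PanelGroup("anther", "Me", 0, False, 2)]}
        with pytest.raises(ValidationError):
            gen_expression(n_genes=50, n_planted=5, panels=no_late)


class TestGenGoAnnotation:
    GENES = [f"g{i}" for i in range(500)]
    PLANTED = {f"g{i}" for i in range(40)}

    def test_planted_term_passes_enrichment_filter(self):
        ann, truth = gen_go_annotation(self.GENES, self.PLANTED,
                                       enriched_term_fraction_in_planted=0.5,
                                       background_rate=0.01, seed=7)
        rows = fold_enrichment(self.PLANTED, ann)
        kept = filter_enriched(rows)
        assert truth["enriched_term"] in {r.term_id for r in kept}

    def test_null_fraction_gives_unit_fold(self):
        """When the planted rate equals the background rate the designated
        term's mean fold is ~1 across seeds."""
        folds = []
        for seed in range(100):
            ann, truth = gen_go_annotation(
                self.GENES, self.PLANTED,
                enriched_term_fraction_in_planted=0.05,
                background_rate=0.05, seed=seed)
            rows = fold_enrichment(self.PLANTED, ann)
            for r in rows:
                if r.term_id == truth["enriched_term"]:
                    folds.append(r.fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.3)

    def test_zero_terms_refused_downstream(self):
        ann, truth = gen_go_annotation(self.GENES, self.PLANTED, n_terms=0)
        assert truth["enriched_term"] is None
        with pytest.raises(ValidationError):
            fold_enrichment(self.PLANTED, ann)

    def test_deterministic(self):
        a, _ = gen_go_annotation(self.GENES, self.PLANTED, seed=4)
        b, _ = gen_go_annotation(self.GENES, self.PLANTED, seed=4)
        assert a.term_to_genes == b.term_to_genes
        assert a.genome_term_repeats == b.genome_term_repeats


class TestGenOrthologMap:
    A = [f"a{i}" for i in range(1500)]
    B = [f"b{i}" for i in range(1500)]
    LATE_A = {f"a{i}" for i in range(627)}
    LATE_B = {f"b{i}" for i in range(600)}

    def _measure(self, fraction, seed=7):
        omap, truth = gen_ortholog_map(self.A, self.B, self.LATE_A,
                                       self.LATE_B, fraction, seed=seed)
        r = conservancy(GeneSet.from_loci(self.LATE_A),
                        GeneSet.from_loci(self.LATE_B), omap)
        return r, truth

    def test_conservancy_within_binomial_interval(self):
        r, _ = self._measure(0.21)
        lo, hi = stats.binom.interval(0.95, len(self.LATE_A), 0.21)
        assert lo <= r.n_conserved <= hi

    def test_extreme_fractions(self):
        r0, _ = self._measure(0.0)
        assert r0.percent_conserved == 0.0
        r1, _ = self._measure(1.0)
        assert r1.percent_conserved == 100.0

    def test_truth_matches_measurement(self):
        r, truth = self._measure(0.3)
        assert r.n_conserved == len(truth["conserved_late_a"])


class TestGenCrossProgeny:
    def test_zero_te_all_wild_type(self):
        c = gen_cross_progeny(0.0, 40, seed=1)
        assert (c.n_wild_type, c.n_heterozygote, c.n_homozygote) == (40, 0, 0)

    def test_te_100_gives_half_het(self):
        c = gen_cross_progeny(100.0, 10_000, seed=2)
        frac = c.n_heterozygote / c.total
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 10_000)

    def test_deterministic_and_nonnegative(self):
        a = gen_cross_progeny(85.0, 60, seed=3)
        b = gen_cross_progeny(85.0, 60, seed=3)
        assert a == b
        assert a.n_homozygote == 0 and a.total == 60
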