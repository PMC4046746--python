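"""Simulator: reference generation, expression truth, tag libraries."""

import numpy as np
import pytest
from scipy import stats as sps

from dgetag import (
    build_virtual_tag_db,
    clean_raw_reads,
    gene_counts,
    generate_transcriptome,
    map_tags,
    sample_expression,
    simulate_gene_counts,
    simulate_tag_library,
)
from dgetag.reference import tag_windows
from dgetag.synthetic import READ_LEN, NoTaggableTranscripts


class TestGenerateTranscriptome:
    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            generate_transcriptome(0)
        with pytest.raises(ValueError):
            generate_transcriptome(10, mean_length=10)

    def test_seed_determinism(self):
        a = generate_transcriptome(100, 300, seed=5)
        b = generate_transcriptome(100, 300, seed=5)
        assert [(t.gene_id, t.sequence) for t in a] == [(t.gene_id, t.sequence) for t in b]

    def test_catg_free_fraction_exact(self):
        ts = generate_transcriptome(1000, 200, seed=7, catg_free_fraction=0.1)
        # direct string scan: count genes with zero taggable windows
        free = sum(1 for t in ts if not tag_windows(t.sequence))
        assert free == 100
        # and the guaranteed-free genes contain no CATG at all
        n_no_anchor = sum(1 for t in ts if "CATG" not in t.sequence)
        assert n_no_anchor == 100

    def test_guaranteed_genes_have_windows(self):
        ts = generate_transcriptome(300, 100, seed=8, catg_free_fraction=0.2)
        with_window = sum(1 for t in ts if tag_windows(t.sequence))
        assert with_window == 240


class TestSampleExpression:
    def test_de_fraction_zero_is_null(self, small_reference):
        truth = sample_expression(small_reference, ["a", "b"], de_fraction=0.0, seed=1)
        assert not truth.de_flags("b").any()
        assert np.allclose(truth.abundance["a"], truth.abundance["b"])

    def test_de_count_forced(self, small_reference):
        truth = sample_expression(
            small_reference, ["a", "b"], de_fraction=0.1, effect_log2=2.0, seed=2
        )
        assert int(truth.de_flags("b").sum()) == 20
        effects = truth.log2_effect["b"]
        assert set(np.abs(effects[effects != 0])) == {2.0}

    def test_abundances_normalised(self, small_reference):
        truth = sample_expression(small_reference, ["a", "b"], de_fraction=0.3, seed=3)
        for cond in ("a", "b"):
            assert truth.abundance[cond].sum() == pytest.approx(1.0)

    def test_bad_fraction_rejected(self, small_reference):
        with pytest.raises(ValueError):
            sample_expression(small_reference, ["a"], de_fraction=1.5)

    def test_heavy_tail_most_detected_genes_below_10_copies(self):
        # at 1M tags the default dispersion must reproduce the hallmark
        # shape: the majority of detected genes at fewer than 10 copies
        ts = generate_transcriptome(20_000, 100, seed=21)
        truth = sample_expression(ts, ["c"], seed=22)
        counts = simulate_gene_counts(ts, truth, "c", depth=1_000_000, seed=23)
        detected = counts[counts > 0]
        assert (detected < 10).mean() > 0.5


class TestSimulateTagLibrary:
    def test_noiseless_round_trip_tags_in_db(
        self, small_reference, small_index, noiseless_reads
    ):
        for read in noiseless_reads.reads:
            assert read.category == "tag"
            assert read.sequence[:21] in small_index.exact

    def test_read_length_and_anchor(self, noisy_reads):
        for read in noisy_reads.reads:
            assert len(read.sequence) == READ_LEN
            if read.category == "tag":
                assert read.sequence.startswith("CATG")

    def test_zero_abundance_gene_emits_nothing(self, small_reference):
        truth = sample_expression(small_reference, ["c"], seed=4)
        gene0 = small_reference.gene_ids[0]
        truth.abundance["c"][gene0] = 0.0
        reads = simulate_tag_library(small_reference, truth, "c", depth=5000, seed=5)
        assert all(r.gene_id != gene0 for r in reads.reads)

    def test_adaptor_only_rate_binomial(self, small_reference, two_condition_truth):
        reads = simulate_tag_library(
            small_reference, two_condition_truth, "control", depth=100_000,
            adaptor_only_rate=0.05, n_read_rate=0.0, seed=6,
        )
        n = reads.category_counts().get("adaptor_only", 0)
        sd = (100_000 * 0.05 * 0.95) ** 0.5
        assert abs(n - 5000) <= 3 * sd

    def test_category_counts_multinomial_gof(self, small_reference, two_condition_truth):
        # chi-square goodness of fit over repeated seeds, alpha = 0.001
        rates = {"tag": 0.915, "adaptor_only": 0.06, "n_contaminated": 0.025}
        depth = 20_000
        observed = np.zeros(3)
        for seed in range(5):
            reads = simulate_tag_library(
                small_reference, two_condition_truth, "control", depth=depth,
                adaptor_only_rate=0.06, n_read_rate=0.025, seed=100 + seed,
            )
            cats = reads.category_counts()
            observed += [cats.get(k, 0) for k in rates]
        expected = np.array(list(rates.values())) * depth * 5
        stat = ((observed - expected) ** 2 / expected).sum()
        assert sps.chi2.sf(stat, df=2) > 0.001

    def test_seed_determinism(self, small_reference, two_condition_truth):
        kwargs = dict(depth=2000, error_rate=0.02, seed=9)
        a = simulate_tag_library(small_reference, two_condition_truth, "control", **kwargs)
        b = simulate_tag_library(small_reference, two_condition_truth, "control", **kwargs)
        assert [(r.sequence, r.category, r.gene_id) for r in a.reads] == [
            (r.sequence, r.category, r.gene_id) for r in b.reads
        ]

    def test_no_taggable_transcripts_error(self):
        ts = generate_transcriptome(10, 100, seed=10, catg_free_fraction=1.0)
        truth = sample_expression(ts, ["c"], seed=10)
        with pytest.raises(NoTaggableTranscripts):
            simulate_tag_library(ts, truth, "c", depth=100, seed=10)

    def test_rate_validation(self, small_reference, two_condition_truth):
        with pytest.raises(ValueError):
            simulate_tag_library(
                small_reference, two_condition_truth, "control", depth=10,
                adaptor_only_rate=0.7, n_read_rate=0.4,
            )
        with pytest.raises(ValueError):
            simulate_tag_library(small_reference, two_condition_truth, "control", depth=0)


class TestRoundTripRecovery:
    def test_noiseless_provenance_recovered_exactly(
        self, small_reference, small_index, two_condition_truth, noiseless_reads
    ):
        # clean -> map -> count recovers per-gene read provenance for every
        # gene with a CATG+17 window, with zero unknown tags
        lib = clean_raw_reads(noiseless_reads)
        mapping = map_tags(lib, small_index)
        assert mapping.unknown_total == 0
        counts = gene_counts(mapping, gene_ids=small_reference.gene_ids)
        provenance = noiseless_reads.provenance_counts()
        # ambiguous tags (shared windows) are excluded from gene counts, so
        # compare only genes whose tags all resolved unambiguously
        ambiguous_tags = {
            t for t, (st, _) in mapping.status.items() if st == "ambiguous"
        }
        for gene, n_true in provenance.items():
            gene_tag = None
            for read in noiseless_reads.reads:
                if read.gene_id == gene:
                    gene_tag = read.sequence[:21]
                    break
            if gene_tag in ambiguous_tags:
                continue
            assert counts.counts[gene] == n_true

    def test_gene_counts_match_multinomial_shortcut_in_distribution(
        self, small_reference, two_condition_truth
    ):
        # simulate_gene_counts is the distributional shortcut for the full
        # read-level path with zero noise: same totals, same support
        reads = simulate_tag_library(
            small_reference, two_condition_truth, "control", depth=10_000,
            error_rate=0.0, adaptor_only_rate=0.0, n_read_rate=0.0, seed=31,
        )
        direct = simulate_gene_counts(
            small_reference, two_condition_truth, "control", depth=10_000, seed=31
        )
        assert direct.sum() == len(reads.reads)
        prov = reads.provenance_counts()
        assert sum(prov.values()) == 10_000
        assert set(prov) <= set(direct.index)
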