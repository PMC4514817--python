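"""Background models, binomial probabilities, enrichment, coverage."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatenrich import (
    NeighborhoodSpec,
    Region,
    RepeatIndex,
    background_gene_counts,
    background_repeat_counts,
    background_whole_genome,
    binomial_point_pmf,
    binomial_tail_p,
    coverage_fraction,
    enrich,
    observed_counts,
    observed_counts_regions,
)
from repeatenrich.enrichment import GENE_COUNTS, REPEAT_COUNTS, degenerate_repeats

from conftest import make_gene, make_repeat, random_genes, random_repeats
from oracles import exact_tails

SIZES = {"chr1": 2_000_000}


def place_in_upstream(gene, name="r", cls="DNA", offset=100, length=50):
    """A repeat inside the 10 kb upstream window of a '+' gene."""
    s = gene.tss - offset - length
    return make_repeat(start=s, end=s + length, name=name, cls=cls)


class TestBackgrounds:
    spec = NeighborhoodSpec("upstream_tss", 10_000)

    def genes4(self):
        return [make_gene(f"G{i}", start=100_000 * (i + 1), end=100_000 * (i + 1) + 5_000)
                for i in range(4)]

    def test_gene_counts_fraction(self):
        genes = self.genes4()
        idx = RepeatIndex([place_in_upstream(genes[0], "r")])
        model = background_gene_counts(genes, idx, self.spec, SIZES)
        assert model.p["r"] == 0.25

    def test_gene_counts_at_least_once_rule(self):
        genes = self.genes4()
        idx = RepeatIndex([
            place_in_upstream(genes[0], "r", offset=100),
            place_in_upstream(genes[0], "r", offset=500),
        ])
        model = background_gene_counts(genes, idx, self.spec, SIZES)
        assert model.p["r"] == 0.25

    def test_repeat_counts_shares(self):
        genes = self.genes4()
        idx = RepeatIndex([
            place_in_upstream(genes[0], "r", offset=100),
            place_in_upstream(genes[1], "r", offset=100),
            place_in_upstream(genes[2], "r", offset=100),
            place_in_upstream(genes[3], "s", offset=100),
        ])
        model = background_repeat_counts(genes, idx, self.spec, SIZES)
        assert model.p["r"] == 0.75
        assert model.p["s"] == 0.25
        assert sum(model.p.values()) == pytest.approx(1.0, abs=1e-9)

    def test_whole_genome_shares(self):
        reps = [make_repeat(start=i * 1000, end=i * 1000 + 100, name="r") for i in range(9)]
        reps.append(make_repeat(start=99_000, end=99_100, name="s"))
        model = background_whole_genome(RepeatIndex(reps))
        assert model.p["r"] == 0.9
        assert sum(model.p.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_inputs_rejected(self):
        idx = RepeatIndex([make_repeat()])
        with pytest.raises(ValueError):
            background_gene_counts([], idx, self.spec, SIZES)
        with pytest.raises(ValueError):
            background_whole_genome(RepeatIndex([]))


class TestObservedCounts:
    spec = NeighborhoodSpec("upstream_tss", 10_000)

    def test_gene_counts_k_n(self):
        genes = [make_gene(f"G{i}", start=100_000 * (i + 1), end=100_000 * (i + 1) + 5_000)
                 for i in range(4)]
        idx = RepeatIndex([place_in_upstream(g, "r") for g in genes[:3]])
        obs = observed_counts(genes, idx, self.spec, GENE_COUNTS, SIZES)
        assert (obs.k["r"], obs.n) == (3, 4)

    def test_repeat_counts_in_locus(self):
        reps = [make_repeat(start=1000 * i, end=1000 * i + 100, name="r") for i in range(5)]
        reps += [make_repeat(start=1000 * i + 500, end=1000 * i + 600, name="s") for i in range(5)]
        obs = observed_counts_regions([Region("chr1", 0, 10_000)], RepeatIndex(reps))
        assert (obs.k["r"], obs.n) == (5, 10)

    def test_no_query_genes_is_error(self):
        with pytest.raises(ValueError):
            observed_counts([], RepeatIndex([make_repeat()]), self.spec, GENE_COUNTS, SIZES)


class TestBinomial:
    def test_hand_computed_point_masses(self):
        assert binomial_point_pmf(1, 2, 0.5) == pytest.approx(0.5, rel=1e-12)
        assert binomial_point_pmf(0, 5, 0.1) == pytest.approx(0.9**5, rel=1e-12)

    def test_tail_examples(self):
        # P(X>=9 | n=10, p=1/2) = 11/1024
        assert binomial_tail_p(9, 10, 0.5, "over") == pytest.approx(11 / 1024, rel=1e-12)
        # P(X<=0) = (1-p)^n
        assert binomial_tail_p(0, 7, 0.3, "under") == pytest.approx(0.7**7, rel=1e-12)

    def test_degenerate_p_rejected(self):
        for p in (0.0, 1.0):
            with pytest.raises(ValueError):
                binomial_point_pmf(1, 2, p)
            with pytest.raises(ValueError):
                binomial_tail_p(1, 2, p, "over")

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            binomial_point_pmf(3, 2, 0.5)

    @settings(max_examples=100, derandomize=True)
    @given(n=st.integers(1, 20), data=st.data())
    def test_small_n_matches_rational_oracle(self, n, data):
        k = data.draw(st.integers(0, n))
        num = data.draw(st.integers(1, 99))
        p = num / 100
        row, upper, lower = exact_tails(n, Fraction(p))
        assert binomial_point_pmf(k, n, p) == pytest.approx(float(row[k]), rel=1e-9)
        assert binomial_tail_p(k, n, p, "over") == pytest.approx(float(upper[k]), rel=1e-9)
        assert binomial_tail_p(k, n, p, "under") == pytest.approx(float(lower[k]), rel=1e-9)

    def test_tail_at_least_point_mass_and_monotone_in_k(self):
        n, p = 60, 0.17
        prev = 1.0 + 1e-15
        for k in range(n + 1):
            tail = binomial_tail_p(k, n, p, "over")
            assert tail >= binomial_point_pmf(k, n, p) * (1 - 1e-12)
            assert tail <= prev * (1 + 1e-12)  # P(X>=k) non-increasing in k
            prev = tail


class TestEnrich:
    def small_setup(self):
        genes = [make_gene(f"G{i}", start=100_000 * (i + 1), end=100_000 * (i + 1) + 5_000)
                 for i in range(4)]
        spec = NeighborhoodSpec("upstream_tss", 10_000)
        idx = RepeatIndex(
            [place_in_upstream(g, "r") for g in genes[:3]]
            + [place_in_upstream(g, "s", offset=2000) for g in genes]
        )
        return genes, spec, idx

    def test_ratio_direction_arithmetic(self):
        genes, spec, idx = self.small_setup()
        bg = background_gene_counts(genes, idx, spec, SIZES)
        # query the single gene lacking "r": ratio for r is 0 -> under
        obs = observed_counts(genes[:1] + genes[1:2] + genes[2:3], idx, spec, GENE_COUNTS, SIZES)
        res = {r.repeat_name: r for r in enrich(obs, bg)}
        assert res["r"].k == 3 and res["r"].n == 3
        assert res["r"].observed_freq == 1.0
        assert res["r"].expected_freq == 0.75
        assert res["r"].ratio == pytest.approx(1 / 0.75)
        assert res["r"].direction == "over"

    def test_identity_when_query_is_all_genes(self):
        genes, spec, idx = self.small_setup()
        bg = background_gene_counts(genes, idx, spec, SIZES)
        obs = observed_counts(genes, idx, spec, GENE_COUNTS, SIZES)
        for r in enrich(obs, bg):
            assert r.ratio == 1.0
            assert r.direction == "none"
            assert not r.significant

    def test_degenerate_p_excluded_and_reported(self):
        genes, spec, idx = self.small_setup()
        bg = background_gene_counts(genes, idx, spec, SIZES)
        assert bg.p["s"] == 1.0  # in every gene's neighborhood
        obs = observed_counts(genes[:2], idx, spec, GENE_COUNTS, SIZES)
        names = {r.repeat_name for r in enrich(obs, bg)}
        assert "s" not in names
        assert ("s", "background frequency 1 (present everywhere)") in degenerate_repeats(obs, bg)

    def test_mode_mismatch_rejected(self):
        genes, spec, idx = self.small_setup()
        bg = background_repeat_counts(genes, idx, spec, SIZES)
        obs = observed_counts(genes[:2], idx, spec, GENE_COUNTS, SIZES)
        with pytest.raises(ValueError, match="incompatible"):
            enrich(obs, bg)

    def test_point_mode_uses_point_mass(self):
        genes, spec, idx = self.small_setup()
        bg = background_gene_counts(genes, idx, spec, SIZES)
        obs = observed_counts(genes[:3], idx, spec, GENE_COUNTS, SIZES)
        tail = {r.repeat_name: r.p_value for r in enrich(obs, bg)}
        point = {r.repeat_name: r.p_value for r in enrich(obs, bg, pvalue_mode="point")}
        for name, pv in point.items():
            assert pv == pytest.approx(binomial_point_pmf(
                obs.k.get(name, 0), obs.n, bg.p[name]), rel=1e-12)
            assert tail[name] >= pv * (1 - 1e-12)

    def test_bh_adjustment_controls_significance(self):
        rng = np.random.default_rng(23)
        genes = random_genes(rng, 60)
        reps = random_repeats(rng, 3000, n_names=12)
        idx = RepeatIndex(reps)
        spec = NeighborhoodSpec("around_gene", 10_000)
        bg = background_gene_counts(genes, idx, spec, SIZES)
        obs = observed_counts(genes[:15], idx, spec, GENE_COUNTS, SIZES)
        raw = enrich(obs, bg)
        adj = enrich(obs, bg, adjust="bh")
        by_name = {r.repeat_name: r for r in adj}
        for r in raw:
            a = by_name[r.repeat_name]
            assert a.p_adjusted is not None and a.p_adjusted >= r.p_value - 1e-15
            assert a.significant == (a.p_adjusted < 0.05)


class TestCoverage:
    def test_simple_fraction(self):
        reps = [make_repeat(start=0, end=100)]
        assert coverage_fraction(reps, 1000) == 10.0

    def test_union_semantics(self):
        reps = [make_repeat(start=0, end=100), make_repeat(start=0, end=100)]
        assert coverage_fraction(reps, 1000) == 10.0
        reps.append(make_repeat(start=50, end=150))
        assert coverage_fraction(reps, 1000) == 15.0

    def test_multi_chromosome_union(self):
        reps = [make_repeat(chrom="chr1", start=0, end=100),
                make_repeat(chrom="chr2", start=0, end=300)]
        assert coverage_fraction(reps, 2000) == 20.0
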