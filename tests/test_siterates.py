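import numpy as np
import pytest

import phylorates as pr
from phylorates.exceptions import DomainError
from phylorates.io import bind_partitions
from phylorates.likelihood import SitePattern
from phylorates.optimize import fit_partition
from phylorates.siterates import R_MAX, SiteRateSolver, normalize_rates


@pytest.fixture(scope="module")
def fitted_small():
    """Fitted 10-taxon WAG partition reused across stage-2 tests."""
    tree = pr.random_tree(10, seed=101)
    model = pr.build_model("WAG")
    rd = pr.discrete_gamma(0.4, 20)
    rates = pr.draw_site_rates(rd, 40, seed=102)
    aln = pr.evolve_alignment(tree, model, rates, seed=103)
    pset = bind_partitions(aln, tree)
    fit = fit_partition(aln, pset.partitions[0], model)
    return aln, rates, fit


def _pattern(aln, j):
    return SitePattern.from_characters(list(aln.taxa), aln.column(j), aln.alphabet)


class TestEstimateSiteRate:
    def test_invariant_column_rate_zero_at_lower_bound(self, fitted_small):
        aln, rates, fit = fitted_small
        solver = SiteRateSolver.from_fit(fit)
        pat = SitePattern.from_characters(
            list(aln.taxa), "A" * aln.n_taxa, "protein"
        )
        est = solver.estimate(pat)
        assert est.r_mle == 0.0
        assert est.at_lower_bound

    def test_two_taxon_mismatch_hits_upper_bound(self):
        """A single differing pair has likelihood increasing in r: bound hit."""
        aln = pr.Alignment(taxa=["a", "b"], data=np.array([["A"], ["C"]]),
                           alphabet="nucleotide")
        tree = pr.read_tree("(a:0.05,b:0.05);")
        model = pr.build_model("JC69-nuc")
        solver = SiteRateSolver(tree, model, ["a", "b"], "nucleotide")
        est = solver.estimate(_pattern(aln, 0))
        assert est.r_mle == R_MAX
        assert est.at_upper_bound

    def test_brent_matches_dense_grid_maximizer(self, fitted_small):
        """Brent optimum agrees with a 10,000-point log-grid search."""
        aln, rates, fit = fitted_small
        solver = SiteRateSolver.from_fit(fit)
        grid = np.concatenate([[0.0], np.geomspace(1e-6, R_MAX, 10_000)])
        step = np.log(grid[2] / grid[1])  # relative grid resolution
        for j in (0, 7, 19, 33):
            pat = _pattern(aln, j)
            est = solver.estimate(pat)
            eng = solver._engine(pat)
            lls = np.array([eng.site_log_likelihoods(rate=r)[0] for r in grid])
            r_grid = grid[int(np.argmax(lls))]
            # Brent never loses likelihood to the grid...
            assert est.logl >= lls.max() - 1e-6
            # ...and lands within one grid step (plus 1e-4) of its argmax
            if est.r_mle > 0 and r_grid > 0:
                assert abs(np.log(est.r_mle / r_grid)) < step + 1e-4
            else:
                assert est.r_mle == pytest.approx(r_grid, abs=1e-6)

    def test_deterministic(self, fitted_small):
        aln, rates, fit = fitted_small
        solver = SiteRateSolver.from_fit(fit)
        a = solver.estimate(_pattern(aln, 5))
        b = solver.estimate(_pattern(aln, 5))
        assert (a.r_mle, a.logl) == (b.r_mle, b.logl)

    def test_all_gap_column_reported_not_skipped(self, fitted_small):
        aln, rates, fit = fitted_small
        solver = SiteRateSolver.from_fit(fit)
        pat = SitePattern.from_characters(
            list(aln.taxa), "-" * aln.n_taxa, "protein"
        )
        est = solver.profile_pattern(pat, solver.estimate(pat))
        assert est.uninformative
        assert est.r_mle == 1.0
        assert est.ci_lower == 0.0 and est.ci_upper == R_MAX


class TestProfileCI:
    def test_interior_bounds_satisfy_drop_equation(self, fitted_small):
        """logL at interior CI endpoints sits 1.92073 below the maximum."""
        aln, rates, fit = fitted_small
        solver = SiteRateSolver.from_fit(fit)
        checked = 0
        for j in range(12):
            pat = _pattern(aln, j)
            est = solver.profile_pattern(pat, solver.estimate(pat))
            assert est.ci_lower <= est.r_mle <= est.ci_upper
            for bound, clamped in ((est.ci_lower, est.ci_lower_at_bound),
                                   (est.ci_upper, est.ci_upper_at_bound)):
                if not clamped:
                    ll = solver.loglik(pat, bound)
                    assert ll == pytest.approx(est.logl - 1.92073, abs=1e-3)
                    checked += 1
        assert checked >= 5

    def test_invariant_column_lower_clamp_finite_upper(self, fitted_small):
        aln, rates, fit = fitted_small
        solver = SiteRateSolver.from_fit(fit)
        pat = SitePattern.from_characters(list(aln.taxa), "A" * aln.n_taxa,
                                          "protein")
        est = solver.profile_pattern(pat, solver.estimate(pat))
        assert est.ci_lower == 0.0
        assert 0.0 < est.ci_upper < R_MAX

    def test_narrower_level_gives_nested_interval(self, fitted_small):
        aln, rates, fit = fitted_small
        solver = SiteRateSolver.from_fit(fit)
        pat = _pattern(aln, 3)
        base = solver.estimate(pat)
        wide = solver.profile_pattern(pat, base, level=0.95)
        narrow = solver.profile_pattern(pat, base, level=0.5)
        assert wide.ci_lower <= narrow.ci_lower
        assert narrow.ci_upper <= wide.ci_upper

    def test_bad_level_rejected(self, fitted_small):
        aln, rates, fit = fitted_small
        solver = SiteRateSolver.from_fit(fit)
        pat = _pattern(aln, 0)
        with pytest.raises(DomainError):
            solver.profile_pattern(pat, solver.estimate(pat), level=1.5)


class TestNormalizeRates:
    def _ests(self, rates, partition=0):
        return [
            pr.SiteRateEstimate(site=i + 1, partition=partition, r_mle=r,
                                logl=-1.0, ci_lower=r / 2, ci_upper=r * 2)
            for i, r in enumerate(rates)
        ]

    def test_mean_normalization_arithmetic(self):
        out = normalize_rates(self._ests([2.0, 4.0, 6.0]), "mean")
        assert [e.r_mle for e in out] == [0.5, 1.0, 1.5]
        assert out[0].ci_upper == pytest.approx(1.0)  # CIs share the divisor

    def test_median_already_one(self):
        out = normalize_rates(self._ests([1.0, 1.0, 10.0]), "median")
        assert [e.r_mle for e in out] == [1.0, 1.0, 10.0]

    def test_mean_of_output_exactly_one(self):
        rng = np.random.default_rng(3)
        out = normalize_rates(self._ests(rng.lognormal(0, 1, 17)), "mean")
        assert np.mean([e.r_mle for e in out]) == pytest.approx(1.0, abs=1e-12)

    def test_per_partition_divisors(self):
        ests = self._ests([2.0, 4.0], 0) + self._ests([10.0, 30.0], 1)
        for i, e in enumerate(ests):
            e.site = i + 1
        out = normalize_rates(ests, "mean")
        assert [e.r_mle for e in out] == pytest.approx([2 / 3, 4 / 3, 0.5, 1.5])

    def test_all_zero_rates_error_advises_none(self):
        with pytest.raises(DomainError, match="none"):
            normalize_rates(self._ests([0.0, 0.0]), "mean")


@pytest.fixture(scope="module")
def small_input():
    tree = pr.random_tree(6, seed=201)
    model = pr.build_model("JC69-nuc")
    aln = pr.evolve_alignment(tree, model, np.ones(12), seed=202)
    return aln, tree


class TestRunAnalysis:
    def test_one_row_per_site_with_gap_column(self, tmp_path):
        tree = pr.random_tree(5, seed=210)
        model = pr.build_model("JC69-nuc")
        aln = pr.evolve_alignment(tree, model, np.ones(8), seed=211)
        data = aln.data.copy()
        data[:, 4] = "-"  # force an all-gap column
        aln = pr.Alignment(taxa=list(aln.taxa), data=data, alphabet="nucleotide")
        doc = pr.run_analysis(aln, tree, "JC69-nuc", progress=False)
        assert len(doc.content) == 8
        assert doc.content[4][1] == 1.0  # uninformative column still reported

    def test_worker_count_does_not_change_results(self, small_input):
        aln, tree = small_input
        doc1 = pr.run_analysis(aln, tree, "JC69-nuc", workers=1, progress=False)
        doc4 = pr.run_analysis(aln, tree, "JC69-nuc", workers=4, progress=False)
        assert doc1 == doc4

    def test_identical_reruns_bit_identical(self, small_input, tmp_path):
        aln, tree = small_input
        paths = []
        for i in range(2):
            doc = pr.run_analysis(aln, tree, "JC69-nuc", progress=False)
            p = tmp_path / f"run{i}.fasta"
            paths.append(pr.write_results(doc, p))
        assert open(paths[0], "rb").read() == open(paths[1], "rb").read()

    def test_two_partitions_tag_sites(self, small_input):
        aln, tree = small_input
        pset = pr.PartitionSet([
            pr.Partition(1, 7, tree), pr.Partition(8, 12, tree.clone()),
        ])
        doc = pr.run_analysis(aln, pset, "JC69-nuc", progress=False)
        assert [row[0] for row in doc.content] == [0.0] * 7 + [1.0] * 5

    def test_progress_stream_is_markdown(self, small_input, capsys):
        aln, tree = small_input
        pr.run_analysis(aln, tree, "JC69-nuc", progress=True)
        out = capsys.readouterr().out
        assert out.count("|") > 12 * 6  # one table row per site
        assert "### Fitting" in out
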