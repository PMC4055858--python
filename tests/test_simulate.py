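"""Ground-truth generators: information content, planted sites, correlations."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import photonet as pn
from photonet.simulate import plan_sites, pwm_consensus


def realized_ic(pwm: pn.PWM) -> float:
    freqs = pwm.matrix / pwm.matrix.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return float(np.mean(2.0 + terms.sum(axis=1)))


class TestGeneratePwm:
    def test_maximal_ic_is_one_hot(self):
        pwm = pn.generate_pwm(6, information_content=2.0, seed=0)
        freqs = pwm.matrix / pwm.matrix.sum(axis=1, keepdims=True)
        assert (freqs.max(axis=1) == 1.0).all()

    def test_near_zero_ic_near_uniform(self):
        pwm = pn.generate_pwm(6, information_content=0.001, seed=0)
        freqs = pwm.matrix / pwm.matrix.sum(axis=1, keepdims=True)
        assert np.abs(freqs - 0.25).max() < 0.05

    @pytest.mark.parametrize("target", [0.5, 1.0, 1.5, 1.9])
    def test_realized_ic_matches_target(self, target):
        for seed in range(50):
            pwm = pn.generate_pwm(8, information_content=target, seed=seed)
            assert abs(realized_ic(pwm) - target) < 0.1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="width"):
            pn.generate_pwm(3)
        with pytest.raises(ValueError, match="information"):
            pn.generate_pwm(6, information_content=2.5)

    def test_reproducible_by_seed(self):
        a = pn.generate_pwm(7, seed=5)
        b = pn.generate_pwm(7, seed=5)
        np.testing.assert_array_equal(a.matrix, b.matrix)


class TestGeneratePromoters:
    def test_background_exchangeability(self):
        # without planted sites no gene group is systematically higher-affinity
        pvals = []
        for seed in range(10):
            pwm = pn.generate_pwm(8, 1.5, seed=seed, tf_id="T")
            model = pn.build_energy_model(pwm)
            proms = pn.generate_promoters(
                [f"g{i}" for i in range(40)], length=300, seed=seed + 100
            )
            scores = [pn.affinity_score(model, p) for p in proms]
            pvals.append(mannwhitneyu(scores[:20], scores[20:]).pvalue)
        assert np.median(pvals) > 0.01

    def test_planted_site_strictly_increases_affinity(self):
        pwm = pn.generate_pwm(8, 1.5, seed=1, tf_id="T")
        model = pn.build_energy_model(pwm)
        genes = ["g0"]
        bare = pn.generate_promoters(genes, length=400, seed=7)
        planted = pn.generate_promoters(
            genes, {"T": pwm}, {("T", "g0"): [(100, "+")]}, length=400, seed=7
        )
        assert pn.affinity_score(model, planted[0]) > pn.affinity_score(model, bare[0])

    def test_minus_strand_site_recovered_by_both_strand_scoring(self):
        pwm = pn.generate_pwm(10, 1.8, seed=2, tf_id="T")
        model = pn.build_energy_model(pwm)
        plus = pn.generate_promoters(["g"], {"T": pwm}, {("T", "g"): [(50, "+")]},
                                     length=200, seed=3)
        minus = pn.generate_promoters(["g"], {"T": pwm}, {("T", "g"): [(50, "-")]},
                                      length=200, seed=3)
        assert pn.affinity_score(model, plus[0]) == pytest.approx(
            pn.affinity_score(model, minus[0]), rel=0.5
        )
        for rec in (plus[0], minus[0]):
            assert pn.affinity_score(model, rec) > 0.3

    def test_overlapping_sites_rejected(self):
        pwm = pn.generate_pwm(8, 1.5, seed=4, tf_id="T")
        with pytest.raises(ValueError, match="overlap"):
            pn.generate_promoters(
                ["g"], {"T": pwm}, {("T", "g"): [(10, "+"), (12, "+")]},
                length=100, seed=5,
            )

    def test_site_outside_promoter_rejected(self):
        pwm = pn.generate_pwm(8, 1.5, seed=4, tf_id="T")
        with pytest.raises(ValueError, match="fit"):
            pn.generate_promoters(
                ["g"], {"T": pwm}, {("T", "g"): [(95, "+")]}, length=100, seed=5
            )

    def test_rank_recovery_of_planted_targets(self):
        # 10 planted targets among 200 genes, width-8 1.5-bit motif:
        # planted genes should rank near the top by affinity
        ranks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pwm = pn.generate_pwm(8, 1.5, seed=seed, tf_id="T")
            genes = [f"g{i:03d}" for i in range(200)]
            targets = list(rng.choice(genes, 10, replace=False))
            planted = {("T", g): [(int(rng.integers(0, 1500 - 8)), "+")] for g in targets}
            proms = pn.generate_promoters(genes, {"T": pwm}, planted,
                                          length=1500, seed=seed + 500)
            model = pn.build_energy_model(pwm)
            scores = {p.gene_id: pn.affinity_score(model, p) for p in proms}
            order = sorted(genes, key=lambda g: -scores[g])
            pos = [order.index(g) + 1 for g in targets]
            ranks.append(np.mean(pos))
        assert np.mean(ranks) <= 20

    def test_plan_sites_non_overlapping(self):
        rng = np.random.default_rng(6)
        planted = plan_sites(
            {"g": ["T1", "T2", "T3"]}, {"T1": 10, "T2": 10, "T3": 10},
            length=1500, sites_per_edge=3, rng=rng,
        )
        intervals = sorted(
            (pos, pos + 10) for sites in planted.values() for pos, _ in sites
        )
        assert all(b <= a2 for (_, b), (a2, _) in zip(intervals, intervals[1:]))


class TestGenerateExpression:
    def _truth(self, edges, rho, groups=()):
        return pn.GroundTruth(
            true_edges=frozenset(edges),
            planted_sites={},
            correlation_of_edge={e: rho for e in edges},
            seed=0,
            tf_groups=groups,
        )

    def test_planted_correlation_recovered(self):
        # rho = 0.95 at n = 400: empirical Pearson r in (0.85, 1.0)
        rs = []
        for seed in range(20):
            truth = self._truth({("T", "g1")}, 0.95)
            expr = pn.generate_expression(truth, ["g1", "g2"], n_samples=400, seed=seed)
            r = np.corrcoef(expr.data.loc["T"], expr.data.loc["g1"])[0, 1]
            rs.append(r)
        assert all(0.85 < r < 1.0 for r in rs)

    def test_shared_target_keeps_nominal_correlation(self):
        truth = self._truth({("T1", "g1"), ("T2", "g1")}, 0.9, groups=(("T1", "T2"),))
        expr = pn.generate_expression(truth, ["g1"], n_samples=5000, seed=1)
        for tf in ("T1", "T2"):
            r = np.corrcoef(expr.data.loc[tf], expr.data.loc["g1"])[0, 1]
            assert abs(r - 0.9) < 0.1

    def test_non_target_uncorrelated(self):
        truth = self._truth({("T", "g1")}, 0.9)
        expr = pn.generate_expression(truth, ["g1", "g2"], n_samples=2000, seed=2)
        r = np.corrcoef(expr.data.loc["T"], expr.data.loc["g2"])[0, 1]
        assert abs(r) < 0.1

    def test_experiment_partition_and_positivity(self):
        truth = self._truth({("T", "g1")}, 0.5)
        expr = pn.generate_expression(truth, ["g1"], n_samples=60, n_experiments=3, seed=3)
        assert len(expr.experiments) == 3
        assert (expr.values > 0).all()

    def test_flat_experiment_rejected_by_filter(self):
        truth = self._truth({("T", "g1")}, 0.9)
        expr = pn.generate_expression(
            truth, ["g1", "g2"], n_samples=60, n_experiments=2, seed=4,
            flat_tf_experiments=("E01",),
        )
        _, report = pn.filter_experiments(expr, ["T"])
        kept = report.kept_experiments()
        assert "E01" not in kept and "E02" in kept

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="8 samples"):
            pn.generate_expression(self._truth(set(), 0.9), ["g1"], n_samples=4)


class TestEndToEndFixture:
    def test_zero_tfs_rejected(self):
        with pytest.raises(ValueError, match="n_tfs"):
            pn.make_end_to_end_fixture(pn.FixtureConfig(n_tfs=0))

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            pn.make_end_to_end_fixture(pn.FixtureConfig(n_photoset=500, n_genes=100))

    def test_default_fixture_parses_through_every_reader(self, tmp_path, default_bundle):
        import warnings

        paths = pn.write_bundle(default_bundle, tmp_path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            proms = pn.read_promoter_fasta(paths["promoters"])
            pwms = pn.read_transfac_pwm(paths["pwms"])
            expr = pn.read_expression_tsv(paths["expression"], paths["experiments"])
            ann = pn.read_gene_annotation(paths["annotation"])
            omap = pn.read_ortholog_map(paths["orthologs"])
        assert len(proms) == 200 and len(pwms) == 10
        assert expr.data.shape[0] == 210
        assert len(ann.photoset) == 30
        assert len(omap.pairs) == 10

    def test_every_true_edge_has_site_and_correlation(self, default_bundle):
        gt = default_bundle.ground_truth
        assert len(gt.true_edges) > 0
        for edge in gt.true_edges:
            assert edge in gt.planted_sites and len(gt.planted_sites[edge]) == 3
            assert gt.correlation_of_edge[edge] == 0.9

    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg = pn.FixtureConfig(n_genes=30, n_photoset=8, n_tfs=2, n_samples=20,
                               n_experiments=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        pn.write_bundle(pn.make_end_to_end_fixture(cfg, seed=9), d1)
        pn.write_bundle(pn.make_end_to_end_fixture(cfg, seed=9), d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_recovery_monotone_in_signal_strength(self):
        # promoter evidence: planted-gene affinity percentile grows with the
        # number of planted copies; expression evidence: median MI of true
        # pairs grows with rho
        pctl = []
        for copies in (1, 2, 3):
            vals = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                pwm = pn.generate_pwm(10, 1.5, seed=seed, tf_id="T")
                genes = [f"g{i}" for i in range(50)]
                planted = {("T", "g0"): [(60 * j + 5, "+") for j in range(copies)]}
                proms = pn.generate_promoters(genes, {"T": pwm}, planted,
                                              length=600, seed=seed + 40)
                model = pn.build_energy_model(pwm)
                scores = np.array([pn.affinity_score(model, p) for p in proms])
                vals.append((scores[0] >= scores).mean())
            pctl.append(np.median(vals))
        assert pctl[0] <= pctl[1] <= pctl[2]

        mi_by_rho = []
        for rho in (0.3, 0.6, 0.9):
            vals = []
            for seed in range(5):
                rng = np.random.default_rng(1000 + seed)
                x = rng.standard_normal(200)
                y = rho * x + np.sqrt(1 - rho * rho) * rng.standard_normal(200)
                vals.append(pn.mutual_information(x, y))
            mi_by_rho.append(np.median(vals))
        assert mi_by_rho[0] < mi_by_rho[1] < mi_by_rho[2]
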