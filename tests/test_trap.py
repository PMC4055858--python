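"""Promoter-occupancy model: analytic identities, oracles and invariances."""

import math

import numpy as np
import pytest

import photonet as pn
from photonet.trap import EnergyModel, _encode

RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(RC)[::-1]


def uniform_pwm(width: int, tf_id: str = "U") -> pn.PWM:
    return pn.PWM(tf_id, np.full((width, 4), 5.0))


def random_pwm(width: int, seed: int) -> pn.PWM:
    rng = np.random.default_rng(seed)
    return pn.PWM("R", rng.integers(0, 20, size=(width, 4)).astype(float) + rng.random((width, 4)))


def random_seq(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), length))


def brute_force_affinity(model: EnergyModel, seq: str) -> float:
    """Window-enumeration oracle: explicit per-window energy sums on both
    strands via the closed-form binding probability."""
    total = 0.0
    for strand in (seq, revcomp(seq)):
        for start in range(len(strand) - model.width + 1):
            site = strand[start : start + model.width]
            E = 0.0
            for i, b in enumerate(site):
                if b == "N":
                    E += sum(
                        model.background[j] * model.energy[i, j] for j in range(4)
                    )
                else:
                    E += model.energy[i, "ACGT".index(b)]
            z = model.r0 * math.exp(-E)
            total += z / (1.0 + z)
    return total


class TestEnergyModel:
    def test_uniform_pwm_zero_energies(self):
        m = pn.build_energy_model(uniform_pwm(6))
        np.testing.assert_array_equal(m.energy, np.zeros((6, 4)))
        assert m.consensus == "A" * 6  # tie broken alphabetically

    def test_inverse_lambda_scaling(self):
        pwm = random_pwm(8, 1)
        e05 = pn.build_energy_model(pwm, lam=0.5).energy
        e07 = pn.build_energy_model(pwm, lam=0.7).energy
        np.testing.assert_allclose(e05, (0.7 / 0.5) * e07, rtol=1e-12)

    def test_hand_evaluated_two_position_formula(self):
        # counts (8,0,0,0) and (0,0,0,8); pseudocount 1, uniform background:
        # weights (8.25,.25,.25,.25) so mismatch energy = ln(33)/lambda
        pwm = pn.PWM("H", np.array([[8, 0, 0, 0], [0, 0, 0, 8]], dtype=float))
        m = pn.build_energy_model(pwm, lam=0.7, pseudocount=1.0)
        expected = math.log(8.25 / 0.25) / 0.7
        assert m.consensus == "AT"
        np.testing.assert_allclose(m.energy[0], [0, expected, expected, expected], rtol=1e-12)
        np.testing.assert_allclose(m.energy[1], [expected, expected, expected, 0], rtol=1e-12)

    def test_consensus_energy_always_zero(self):
        for seed in range(5):
            m = pn.build_energy_model(random_pwm(9, seed))
            idx = [_encode(m.consensus)[i] for i in range(m.width)]
            assert all(m.energy[i, j] == 0.0 for i, j in enumerate(idx))

    def test_invalid_lambda_and_zero_rows(self):
        with pytest.raises(ValueError, match="lambda"):
            pn.build_energy_model(uniform_pwm(4), lam=0.0)
        pwm = pn.PWM("Z", np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float))
        with pytest.raises(ValueError, match="zero weight"):
            pn.build_energy_model(pwm, pseudocount=0.0)

    def test_default_r0_published_width_fit(self):
        assert pn.default_r0(10) == pytest.approx(math.exp(0.584 * 10 - 5.66))


class TestSiteProbability:
    def test_consensus_site_r0_one_is_half(self):
        m = pn.build_energy_model(uniform_pwm(5), r0=1.0)
        assert pn.site_probability(m, "ACGTA") == pytest.approx(0.5)

    def test_r0_limits(self):
        pwm = random_pwm(6, 2)
        site = "ACGTAC"
        lo = pn.build_energy_model(pwm, r0=1e-12)
        hi = pn.build_energy_model(pwm, r0=1e12)
        assert pn.site_probability(lo, site) < 1e-10
        assert pn.site_probability(pn.build_energy_model(pwm, r0=1e12), lo.consensus) > 1 - 1e-10
        assert 0.0 < pn.site_probability(hi, site) < 1.0

    def test_matches_closed_form(self):
        for seed in range(10):
            m = pn.build_energy_model(random_pwm(7, seed), r0=0.8)
            site = random_seq(7, seed + 100)
            E = sum(m.energy[i, "ACGT".index(b)] for i, b in enumerate(site))
            expected = 0.8 * math.exp(-E) / (1 + 0.8 * math.exp(-E))
            assert pn.site_probability(m, site) == pytest.approx(expected, rel=1e-12)

    def test_wrong_length_site(self):
        m = pn.build_energy_model(uniform_pwm(5))
        with pytest.raises(ValueError, match="length"):
            pn.site_probability(m, "ACG")


class TestAffinityScore:
    def test_uniform_pwm_analytic_value(self):
        # all energies zero, R0=1: every window contributes 1/2 on each strand
        W, L = 6, 40
        m = pn.build_energy_model(uniform_pwm(W), r0=1.0)
        seq = random_seq(L, 3)
        assert pn.affinity_score(m, seq) == pytest.approx(L - W + 1, rel=1e-12)

    def test_monotone_in_r0(self):
        pwm = random_pwm(8, 4)
        seq = random_seq(60, 5)
        scores = [
            pn.affinity_score(pn.build_energy_model(pwm, r0=r0), seq)
            for r0 in (0.01, 0.1, 1.0, 10.0)
        ]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_window_enumeration_oracle_20bp(self):
        m = pn.build_energy_model(random_pwm(3, 6))
        seq = random_seq(20, 7)
        assert pn.affinity_score(m, seq) == pytest.approx(
            brute_force_affinity(m, seq), rel=1e-10
        )

    def test_strand_symmetry(self):
        for seed in range(5):
            m = pn.build_energy_model(random_pwm(9, seed))
            seq = random_seq(100, seed + 50)
            assert pn.affinity_score(m, seq) == pytest.approx(
                pn.affinity_score(m, revcomp(seq)), rel=1e-12
            )

    def test_gauge_invariance(self):
        # adding c to one position's energies == multiplying R0 by exp(c)
        pwm = random_pwm(7, 8)
        seq = random_seq(80, 9)
        c = 0.37
        base = pn.build_energy_model(pwm, r0=1.0)
        shifted = EnergyModel(
            tf_id=base.tf_id, lam=base.lam,
            energy=base.energy + np.array([c] + [0] * 6)[:, None] * np.ones(4),
            r0=math.exp(c), consensus=base.consensus, background=base.background,
        )
        assert pn.affinity_score(shifted, seq) == pytest.approx(
            pn.affinity_score(base, seq), rel=1e-10
        )

    def test_n_bases_score_background_expectation(self):
        m = pn.build_energy_model(random_pwm(4, 10))
        seq = "ACGTNACGTNAC"
        assert pn.affinity_score(m, seq) == pytest.approx(
            brute_force_affinity(m, seq), rel=1e-10
        )

    def test_consensus_site_maximises_probability(self):
        m = pn.build_energy_model(random_pwm(8, 11))
        p_cons = pn.site_probability(m, m.consensus)
        for seed in range(50):
            assert pn.site_probability(m, random_seq(8, seed)) <= p_cons

    def test_bounds(self):
        m = pn.build_energy_model(random_pwm(5, 12))
        seq = random_seq(30, 13)
        n = pn.affinity_score(m, seq)
        assert 0.0 <= n <= 2 * (30 - 5 + 1)

    def test_short_promoter_error(self):
        m = pn.build_energy_model(uniform_pwm(10))
        with pytest.raises(ValueError, match="shorter"):
            pn.affinity_score(m, "ACGT")


class TestAffinityMatrix:
    def test_single_cell_consistency(self):
        pwm = random_pwm(5, 14)
        prom = pn.PromoterRecord("g1", random_seq(50, 15))
        mat = pn.affinity_matrix([pwm], [prom])
        model = pn.build_energy_model(pwm)
        assert mat.scores[0, 0] == pytest.approx(pn.affinity_score(model, prom))

    def test_gene_permutation_permutes_columns(self):
        pwms = [random_pwm(5, s) for s in (20, 21)]
        proms = [pn.PromoterRecord(f"g{i}", random_seq(40, 30 + i)) for i in range(4)]
        a = pn.affinity_matrix(pwms, proms)
        b = pn.affinity_matrix(pwms, proms[::-1])
        np.testing.assert_allclose(a.scores, b.scores[:, ::-1])

    def test_cellwise_oracle(self):
        pwms = [random_pwm(w, s) for w, s in ((3, 40), (4, 41), (5, 42))]
        proms = [pn.PromoterRecord(f"g{i}", random_seq(25, 60 + i)) for i in range(10)]
        mat = pn.affinity_matrix(pwms, proms)
        for i, pwm in enumerate(pwms):
            model = pn.build_energy_model(pwm)
            for j, prom in enumerate(proms):
                assert mat.scores[i, j] == pytest.approx(
                    brute_force_affinity(model, prom.sequence), rel=1e-10
                )

    def test_short_promoter_flagged_missing_with_warning(self):
        pwms = [random_pwm(10, 50)]
        proms = [
            pn.PromoterRecord("ok", random_seq(30, 51)),
            pn.PromoterRecord("short", random_seq(5, 52)),
        ]
        with pytest.warns(UserWarning, match="shorter"):
            mat = pn.affinity_matrix(pwms, proms)
        assert np.isnan(mat.scores[0, 1]) and not np.isnan(mat.scores[0, 0])


class TestTopNOverlapAndSweep:
    def test_identical_scores(self):
        import pandas as pd

        s = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0})
        assert pn.top_n_overlap(s, s, 2) == 1.0

    def test_reversed_ranking(self):
        import pandas as pd

        genes = [f"g{i}" for i in range(10)]
        a = pd.Series(dict(zip(genes, range(10))))
        b = pd.Series(dict(zip(genes, range(9, -1, -1))))
        assert pn.top_n_overlap(a, b, 5) == 0.0

    def test_set_intersection_oracle(self):
        import pandas as pd

        rng = np.random.default_rng(17)
        genes = [f"g{i:03d}" for i in range(100)]
        a = pd.Series(rng.random(100), index=genes)
        b = pd.Series(rng.random(100), index=genes)
        top = lambda s: set(
            sorted(genes, key=lambda g: (-s[g], g))[:10]
        )
        assert pn.top_n_overlap(a, b, 10) == len(top(a) & top(b)) / 10

    def test_invalid_n(self):
        import pandas as pd

        s = pd.Series({"a": 1.0})
        with pytest.raises(ValueError):
            pn.top_n_overlap(s, s, 0)

    def test_sweep_reference_only(self):
        pwm = random_pwm(5, 70)
        proms = [pn.PromoterRecord(f"g{i}", random_seq(40, 80 + i)) for i in range(20)]
        df = pn.lambda_sweep(pwm, proms, lambdas=[0.7], n=10)
        assert len(df) == 1 and df["top_n_overlap"].iloc[0] == 1.0

    def test_sweep_matches_independent_recomputation(self):
        import pandas as pd

        pwm = random_pwm(6, 71)
        proms = [pn.PromoterRecord(f"g{i}", random_seq(60, 90 + i)) for i in range(60)]
        df = pn.lambda_sweep(pwm, proms, lambdas=[0.5, 0.7, 0.9], n=50)
        assert ((0.0 <= df["top_n_overlap"]) & (df["top_n_overlap"] <= 1.0)).all()

        def scores(lam):
            m = pn.build_energy_model(pwm, lam=lam)
            return pd.Series({p.gene_id: pn.affinity_score(m, p) for p in proms})

        ref = scores(0.7)
        for _, row in df.iterrows():
            expected = pn.top_n_overlap(scores(row["lambda"]), ref, 50)
            assert row["top_n_overlap"] == pytest.approx(expected)
        assert df.loc[df["lambda"] == 0.7, "top_n_overlap"].iloc[0] == 1.0
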