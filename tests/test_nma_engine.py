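import dataclasses

import numpy as np
import pytest

from painnma.exceptions import ConvergenceError, DisconnectedNetworkError, ValidationError
from painnma.nma_engine import ModelSpec, fit, league, split_rhat
from painnma.pairwise_meta import pool_all
from painnma.synthetic_data import Scenario, generate

from conftest import make_continuous_study, make_dataset


class TestModelSpec:
    def test_defaults_follow_protocol(self):
        spec = ModelSpec()
        assert spec.n_chains == 3
        assert spec.burn_in == 50_000
        assert spec.samples == 100_000

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(n_chains=1)
        with pytest.raises(ValidationError):
            ModelSpec(burn_in=0)
        with pytest.raises(ValidationError):
            ModelSpec(tau_prior=("lognormal", (0, 1)))


class TestFit:
    def test_reference_constraint_every_draw(self, two_treatment_ds, quick_spec):
        post = fit(two_treatment_ds, "pain4w", quick_spec)
        ref_col = post.treatment_ids.index(post.reference)
        assert np.all(post.d_draws[:, :, ref_col] == 0.0)
        assert np.all(post.tau_draws > 0)
        assert all(np.isfinite(v) for v in post.rhat.values())

    def test_matches_dl_oracle(self, two_treatment_ds):
        # tau fixed at the DL estimate makes the normal model conjugate, so
        # the posterior must sit on the closed-form pooled estimate
        (pooled,) = pool_all(two_treatment_ds, "pain4w")
        spec = ModelSpec(
            burn_in=1500, samples=6000, seed=11,
            tau_prior=("fixed", float(np.sqrt(pooled.tau2))),
        )
        post = fit(two_treatment_ds, "pain4w", spec)
        draws = post.contrast_draws("drug01", "placebo")
        mce = post.mc_error["d[drug01]"]
        assert abs(float(np.median(draws)) - pooled.value) < 2 * max(mce, 1e-4) + 0.01
        assert float(np.std(draws)) == pytest.approx(pooled.se, rel=0.15)

    def test_tau_point_mass_conjugate_limit(self, quick_spec):
        # single two-arm study, tau == 0: posterior mean of d equals the
        # study's own effect within 2 MC errors
        s = make_continuous_study("s1", [("drug", 50, -2.0, 1.5), ("placebo", 50, -1.0, 1.5)])
        ds = make_dataset([s])
        from painnma.effect_sizes import contrasts

        (e,) = contrasts(s, "pain4w")
        spec = dataclasses.replace(quick_spec, tau_prior=("fixed", 0.0))
        post = fit(ds, "pain4w", spec)
        draws = post.contrast_draws("drug", "placebo")
        mce = post.mc_error["d[drug]"]
        assert abs(float(np.mean(draws)) - e.value) < 2 * max(mce, 1e-3)

    def test_parameter_recovery_tau_zero_large_n(self):
        sc = Scenario(
            n_treatments=3, geometry="triangle", trials_per_edge=2,
            d={"drug01": -0.8, "drug02": -0.3}, tau=0.0, arm_size=(4000, 4000), seed=21,
        )
        post = fit(generate(sc), "pain4w", ModelSpec(burn_in=1500, samples=5000, seed=2))
        d = post.d_pooled()
        for t, truth in sc.d.items():
            med = float(np.median(d[:, post.treatment_ids.index(t)]))
            assert abs(med - truth) < 0.05

    def test_seed_determinism_bitwise(self, two_treatment_ds, quick_spec):
        p1 = fit(two_treatment_ds, "pain4w", quick_spec)
        p2 = fit(two_treatment_ds, "pain4w", quick_spec)
        assert np.array_equal(p1.d_draws, p2.d_draws)
        assert np.array_equal(p1.tau_draws, p2.tau_draws)
        assert p1.dic == p2.dic

    def test_reference_relabeling_invariance(self, triangle_ds):
        spec = ModelSpec(burn_in=1500, samples=6000, seed=5)
        post_a = fit(triangle_ds, "pain4w", spec)
        spec_b = dataclasses.replace(spec, reference="drug01")
        post_b = fit(triangle_ds, "pain4w", spec_b)
        c_a = float(np.median(post_a.contrast_draws("drug02", "drug01")))
        c_b = float(np.median(post_b.contrast_draws("drug02", "drug01")))
        mce = 2 * (post_a.mc_error["d[drug02]"] + post_b.mc_error["d[drug02]"])
        assert abs(c_a - c_b) < 2 * mce + 0.02

    def test_treatment_without_data_dropped(self, quick_spec, caplog):
        s1 = make_continuous_study("s1", [("A", 30, -2.0, 1.0), ("placebo", 30, -1.0, 1.0)])
        s2 = make_continuous_study(
            "s2", [("B", 30, -2.0, 1.0), ("placebo", 30, -1.0, 1.0)],
            outcome_id="pain8w", followup=9.0,
        )
        ds = make_dataset([s1, s2])
        with caplog.at_level("WARNING", logger="painnma"):
            post = fit(ds, "pain4w", quick_spec)
        assert post.dropped_treatments == ("B",)
        assert "B" not in post.treatment_ids
        assert any("dropping treatments" in r.message for r in caplog.records)

    def test_missing_outcome_everywhere_rejected(self, triangle_ds, quick_spec):
        with pytest.raises(ValidationError):
            fit(triangle_ds, "adverse_events", quick_spec)

    def test_disconnected_outcome_rejected(self, quick_spec):
        s1 = make_continuous_study("s1", [("A", 20, -1.0, 1.0), ("B", 20, -0.5, 1.0)])
        s2 = make_continuous_study("s2", [("B", 20, -1.0, 1.0), ("C", 20, -0.5, 1.0)])
        s3 = make_continuous_study("s3", [("C", 20, -1.0, 1.0), ("D", 20, -0.5, 1.0)], outcome_id="pain8w", followup=9.0)
        ds = make_dataset([s1, s2, s3], reference="A")
        # pain8w only connects C-D; the outcome subnetwork lacks the reference
        with pytest.raises((DisconnectedNetworkError, ValidationError)):
            fit(ds, "pain8w", quick_spec)

    def test_strict_convergence_raises(self, two_treatment_ds):
        spec = ModelSpec(
            burn_in=30, samples=60, seed=1, strict_convergence=True, rhat_threshold=1.0001
        )
        with pytest.raises(ConvergenceError) as exc:
            fit(two_treatment_ds, "pain4w", spec)
        assert exc.value.diagnostics


@pytest.fixture(scope="module")
def post(triangle_ds):
    return fit(triangle_ds, "pain4w", ModelSpec(burn_in=1000, samples=3000, seed=7))


class TestLeague:
    def test_diagonal_is_null(self, post):
        df = league(post)
        diag = df[df.row == df.col]
        assert (diag["median"] == 0.0).all()  # SMD null

    def test_antisymmetry_exact(self, post):
        df = league(post).set_index(["row", "col"])
        for a in post.treatment_ids:
            for b in post.treatment_ids:
                if a == b:
                    continue
                ab = df.loc[(a, b)]
                ba = df.loc[(b, a)]
                assert ab["median"] == pytest.approx(-ba["median"], abs=1e-12)
                assert ab["ci95_low"] == pytest.approx(-ba["ci95_high"], abs=1e-12)

    def test_matches_fit_summary(self, post):
        df = league(post).set_index(["row", "col"])
        cell = df.loc[(post.reference, "drug01")]
        draws = post.contrast_draws("drug01", post.reference)
        assert cell["median"] == pytest.approx(float(np.median(draws)), abs=1e-12)

    def test_or_cells_reciprocal(self):
        sc = Scenario(
            n_treatments=3, geometry="triangle", trials_per_edge=2,
            d={"drug01": -0.6, "drug02": 0.2}, tau=0.05,
            outcome_kind="dichotomous", arm_size=(60, 120), seed=13,
        )
        post = fit(generate(sc), "pain4w", ModelSpec(burn_in=1000, samples=3000, seed=3))
        df = league(post).set_index(["row", "col"])
        ab = df.loc[("drug01", "drug02")]["median"]
        ba = df.loc[("drug02", "drug01")]["median"]
        assert ab == pytest.approx(1.0 / ba, rel=1e-9)
        assert (df[df.index.get_level_values(0) == df.index.get_level_values(1)]["median"] == 1.0).all()


class TestDIC:
    def test_pd_close_to_free_parameter_count(self):
        # single two-arm study with tau fixed 0: one free parameter (d);
        # the normal model is conjugate so pD must be ~1
        s = make_continuous_study("s1", [("drug", 40, -2.0, 1.5), ("placebo", 40, -1.0, 1.5)])
        ds = make_dataset([s])
        spec = ModelSpec(burn_in=2000, samples=20000, seed=3, tau_prior=("fixed", 0.0))
        post = fit(ds, "pain4w", spec)
        dbar, pd_, dic_ = post.dic
        assert pd_ == pytest.approx(1.0, abs=0.2)
        assert dic_ == pytest.approx(dbar + pd_)

    def test_dic_deterministic_under_seed(self, two_treatment_ds, quick_spec):
        d1 = fit(two_treatment_ds, "pain4w", quick_spec).dic
        d2 = fit(two_treatment_ds, "pain4w", quick_spec).dic
        assert d1 == d2


def test_split_rhat_detects_disagreement():
    rng = np.random.default_rng(0)
    good = rng.normal(size=(3, 400))
    bad = good + np.array([[0.0], [5.0], [10.0]])
    assert split_rhat(good) < 1.05
    assert split_rhat(bad) > 2.0
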