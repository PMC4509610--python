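"""Mixed-model engine: GLS oracle equivalence, REML, invariances."""

import warnings

import numpy as np
import pandas as pd
import pytest

import pedgwas as pg
from pedgwas.mixed_model import MixedModelEngine, VarianceComponents, reml
from conftest import make_response


def gls_oracle(F, y, V):
    """Explicit V-inversion GLS: the independent reference implementation."""
    Vi = np.linalg.inv(V)
    S = F.T @ Vi @ F
    beta = np.linalg.solve(S, F.T @ Vi @ y)
    cov = np.linalg.inv(S)
    return beta, cov


def small_instance(seed, repeat=2):
    rng = np.random.default_rng(seed)
    cfg = pg.SimulationConfig(
        seed=seed, n_founders=8, n_generations=2,
        n_offspring_per_generation=8, n_cows=None,
    )
    ped, _ = pg.simulate_pedigree(cfg)
    A = pg.build_A(ped)
    animals = np.repeat(ped.ids, repeat)
    idx = np.repeat(np.arange(len(ped.ids)), repeat)
    n = len(animals)
    y = rng.normal(size=n)
    vc = VarianceComponents(0.4, 0.2, 0.7)
    Z = np.zeros((n, len(ped.ids)))
    Z[np.arange(n), idx] = 1.0
    V = (
        vc.sigma_g2 * Z @ A.values @ Z.T
        + vc.sigma_pe2 * Z @ Z.T
        + vc.sigma_e2 * np.eye(n)
    )
    resp = make_response(y, animals)
    return resp, A, vc, V, rng, n


@pytest.mark.parametrize("variant", ["additive", "dominance", "epistasis"])
def test_solver_matches_explicit_gls_oracle(variant):
    """Henderson-absorption solution equals direct V-inversion GLS to 1e-8."""
    resp, A, vc, V, rng, n = small_instance(seed=101)
    assert n <= 50
    codes1 = rng.integers(0, 3, n)
    codes2 = rng.integers(0, 3, n)
    xa1 = pg.code_additive(codes1, 0.4)
    if variant == "additive":
        covs = {"a_j": xa1}
        focal = "a_j"
    elif variant == "dominance":
        covs = {"a_j": xa1, "d_j": pg.code_dominance(codes1, 0.4)}
        focal = "d_j"
    else:
        xa2 = pg.code_additive(codes2, 0.6)
        covs = {"a_j": xa1, "a_k": xa2, "a_jk": pg.code_epistasis(xa1, xa2)}
        focal = "a_jk"
    engine = MixedModelEngine(resp, A, vc)
    res = engine.test_effect(covs, focal, variant=variant)
    F = np.column_stack([np.ones(n), *covs.values()])
    beta, cov = gls_oracle(F, resp["residual"].to_numpy(), V)
    j = 1 + list(covs).index(focal)
    assert res.estimate == pytest.approx(beta[j], rel=1e-8)
    assert res.se == pytest.approx(np.sqrt(cov[j, j]), rel=1e-8)


def test_reduces_to_ols_when_no_random_variance():
    rng = np.random.default_rng(5)
    n = 40
    x = rng.normal(size=n)
    y = 0.7 * x + rng.normal(size=n)
    resp = make_response(y, [f"a{i}" for i in range(n)])
    vc = VarianceComponents(0.0, 0.0, 1.0)
    res = MixedModelEngine(resp, None, vc).test_effect({"b": x}, "b")
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    assert res.estimate == pytest.approx(beta[1], rel=1e-10)


def test_constant_focal_covariate_not_testable():
    resp, A, vc, *_ , n = small_instance(seed=7)
    res = MixedModelEngine(resp, A, vc).test_effect(
        {"b": np.full(n, 1.6)}, "b"
    )
    assert not res.testable


def test_response_shift_moves_only_intercept():
    resp, A, vc, V, rng, n = small_instance(seed=13)
    x = pg.code_additive(rng.integers(0, 3, n), 0.3)
    engine = MixedModelEngine(resp, A, vc)
    r1 = engine.test_effect({"a_j": x}, "a_j")
    shifted = resp.assign(residual=resp["residual"] + 100.0)
    r2 = MixedModelEngine(shifted, A, vc).test_effect({"a_j": x}, "a_j")
    assert r2.estimate == pytest.approx(r1.estimate, rel=1e-9)
    assert r2.p == pytest.approx(r1.p, rel=1e-6)
    assert r2.coefficients["mu"][0] == pytest.approx(
        r1.coefficients["mu"][0] + 100.0, rel=1e-9
    )


def test_allele_relabel_antisymmetry():
    """Swapping A<->a flips the additive estimate's sign; |a|, SE, p and the
    dominance estimate are unchanged."""
    resp, A, vc, V, rng, n = small_instance(seed=23)
    codes = rng.integers(0, 3, n)
    p = 0.35
    engine = MixedModelEngine(resp, A, vc)
    covs = {
        "a_j": pg.code_additive(codes, p),
        "d_j": pg.code_dominance(codes, p),
    }
    covs_sw = {
        "a_j": pg.code_additive(2 - codes, 1 - p),
        "d_j": pg.code_dominance(2 - codes, 1 - p),
    }
    ra = engine.test_effect(covs, "a_j")
    ra_sw = engine.test_effect(covs_sw, "a_j")
    assert ra_sw.estimate == pytest.approx(-ra.estimate, rel=1e-9)
    assert ra_sw.se == pytest.approx(ra.se, rel=1e-9)
    assert ra_sw.p == pytest.approx(ra.p, rel=1e-6)
    rd = engine.test_effect(covs, "d_j")
    rd_sw = engine.test_effect(covs_sw, "d_j")
    assert rd_sw.estimate == pytest.approx(rd.estimate, rel=1e-9)


class TestReml:
    def test_recovers_components_on_repeated_records(self):
        """Mean REML estimates over replicates within 3 empirical SE of the
        generating components (0.3, 0.1, 0.6).

        The response is the raw phenotype (no fixed effects simulated), so
        the check isolates the REML engine from the degrees of freedom the
        two-stage pre-correction absorbs at small n.
        """
        truth = np.array([0.3, 0.1, 0.6])
        ests = []
        for seed in range(6):
            cfg = pg.SimulationConfig(
                seed=seed, n_founders=80, n_generations=2,
                n_offspring_per_generation=280, n_cows=260,
                n_snps=10, n_chromosomes=1, records_min=2, records_max=2,
                fixed_effect_sd=0.0,
            )
            ds = pg.simulate_dataset(cfg)
            resp = make_response(
                ds.phenotypes["value"] - ds.phenotypes["value"].mean(),
                ds.phenotypes["animal"],
            )
            A = pg.build_A(
                pg.prune_to_ancestors(ds.pedigree, ds.panel.animal_ids)
            )
            vc = pg.reml_null(resp, A)
            ests.append([vc.sigma_g2, vc.sigma_pe2, vc.sigma_e2])
        ests = np.array(ests)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        assert (np.abs(ests.mean(axis=0) - truth) < 3 * se + 1e-9).all()

    def test_zero_variance_response_graceful(self):
        resp = make_response(np.zeros(12), [f"a{i}" for i in range(6)] * 2)
        vc = pg.reml_null(resp, None)
        assert vc.sigma_g2 == vc.sigma_pe2 == vc.sigma_e2 == 0.0

    def test_no_repeated_records_warns_and_drops_pe(self):
        rng = np.random.default_rng(2)
        resp = make_response(rng.normal(size=30), [f"a{i}" for i in range(30)])
        with pytest.warns(UserWarning, match="repeated records"):
            vc = pg.reml_null(resp, None)
        assert vc.sigma_pe2 == 0.0

    def test_identity_A_single_records_flags_singular_information(self):
        """With A = I and one record per animal, polygenic and residual
        structures are indistinguishable; the engine must flag it."""
        rng = np.random.default_rng(4)
        n = 60
        y = rng.normal(size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = reml(
                y, np.ones((n, 1)), np.arange(n), np.eye(n), fit_pe=False
            )
        assert vc.ai_singular


def test_per_snp_reml_close_to_fixed_vc():
    """Re-estimating components per marker barely moves the p-values.

    Polygenic-only trait: the fast path's approximation is about ordinary
    markers (a large planted QTL in the fixed part genuinely changes the
    REML polygenic variance, and is not what the fast path is for).
    """
    cfg = pg.SimulationConfig(
        seed=31, n_founders=70, n_generations=2,
        n_offspring_per_generation=230, n_cows=220, n_snps=12,
        n_chromosomes=1, records_min=2, records_max=3,
    )
    ds = pg.simulate_dataset(cfg)
    model = pg.fit_fixed_effects(ds.phenotypes)
    resp = pg.residualize(ds.phenotypes, model, genotyped_ids=ds.panel.animal_ids)
    A = pg.build_A(pg.prune_to_ancestors(ds.pedigree, ds.panel.animal_ids))
    vc = pg.reml_null(resp, A)
    stats = pg.allele_stats(ds.panel)
    sub = ds.panel.subset_animals(
        list(dict.fromkeys(resp["animal"].astype(str)))
    )
    rec_row = (
        resp["animal"].astype(str)
        .map({a: i for i, a in enumerate(sub.animal_ids)})
        .to_numpy()
    )
    checked = 0
    for j in range(sub.n_snps):
        snp = sub.snps["snp"].iloc[j]
        p = float(stats.loc[snp, "p"])
        maf = float(stats.loc[snp, "maf"])
        if not 0.05 < p < 0.95 or maf <= 0.05:
            continue
        covs = {"a_j": pg.code_additive(sub.codes[:, j][rec_row], p)}
        r_fast = pg.fit_snp(covs, "a_j", resp, A, vc, mode="fixed-vc")
        r_full = pg.fit_snp(covs, "a_j", resp, A, vc, mode="per-snp-reml")
        if r_fast.testable and r_full.testable:
            assert abs(r_fast.neglog10p - r_full.neglog10p) < 0.15
            checked += 1
    assert checked >= 5
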