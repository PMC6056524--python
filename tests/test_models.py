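import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.special import expit

from ithshift.models import (
    AlterationCountModel,
    CcfCategoryModel,
    VafCategoryModel,
    expected_vaf_from_ccf,
    posterior_density_summary,
)
from ithshift.types import Hyperparameters, McmcConfig

FAST = McmcConfig(n_chains=2, n_burnin=400, n_total=700, thin=1, seed=1)
RECOVERY_HYPER = Hyperparameters(r0=0.0)
PINNED_HYPER = Hyperparameters()  # the printed constants, r0 = 1


def count_frame(rng, means, n_per_stage=20, n_cases=5):
    rows = []
    for stage, mean in means.items():
        for k in range(n_per_stage):
            rows.append(
                dict(
                    case_id=f"c{k % n_cases}",
                    sample_id=f"{stage}_{k}",
                    stage=stage,
                    n=int(rng.poisson(mean)),
                )
            )
    return pd.DataFrame(rows)


def vaf_frame(rng, truths, n_per_cat=150, tc=(0.4, 0.9), depth=132.0, cn=2):
    rows = []
    for cat, p in truths.items():
        for k in range(n_per_cat):
            t = rng.uniform(*tc)
            d = max(1, int(rng.negative_binomial(8, 8 / (8 + depth))))
            prob = expected_vaf_from_ccf(p, t, cn) if cn != "vaf" else p * t
            rows.append(
                dict(
                    case_id=f"c{k % 4}",
                    sample_id=f"c{k % 4}_s{k % 3}",
                    category=cat,
                    b=int(rng.binomial(d, prob)),
                    d=d,
                    tumor_content=t,
                    copy_number=2,
                    chrom=str(1 + k % 22),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# log-density oracle equivalence


def oracle_count_logpost(data, hyper, params):
    """Independently coded joint density using scipy.stats only."""
    n, stage_idx, case_idx = data
    beta_t = np.asarray(params["beta_t"], float)
    r_ij = np.asarray(params["r_ij"], float)
    r_i = np.asarray(params["r_i"], float)
    t_i = np.asarray(params["t_i"], float)
    beta, tau, t = params["beta"], params["tau"], params["t"]
    mu = np.exp(beta_t[stage_idx] + r_ij)
    lp = sps.poisson.logpmf(n, mu).sum()
    lp += sps.cauchy.logpdf(beta_t, loc=beta, scale=tau).sum()
    lp += sps.cauchy.logpdf(beta, loc=hyper.beta0, scale=hyper.tau0)
    lp += sps.halfcauchy.logpdf(tau, scale=hyper.lambda0)
    lp += sps.cauchy.logpdf(r_ij, loc=r_i[case_idx], scale=t_i[case_idx]).sum()
    lp += sps.cauchy.logpdf(r_i, loc=hyper.r0, scale=t).sum()
    lp += sps.halfcauchy.logpdf(t_i, scale=hyper.l1).sum()
    lp += sps.halfcauchy.logpdf(t, scale=hyper.l0)
    return float(lp)


def oracle_vaf_logpost(df, hyper, params, ccf=False):
    beta_t = np.asarray(params["beta_t"], float)
    r_ijk = np.asarray(params["r_ijk"], float)
    r_ij = np.asarray(params["r_ij"], float)
    r_i = np.asarray(params["r_i"], float)
    t_ij = np.asarray(params["t_ij"], float)
    t_i = np.asarray(params["t_i"], float)
    beta, tau, t = params["beta"], params["tau"], params["t"]

    cats = sorted(df["category"].unique())
    cat_idx = df["category"].map({c: i for i, c in enumerate(cats)}).to_numpy()
    skeys = sorted(set(zip(df["case_id"], df["sample_id"])))
    s_idx = np.array(
        [skeys.index((c, s)) for c, s in zip(df["case_id"], df["sample_id"])]
    )
    ckeys = sorted({c for c, _ in skeys})
    case_of_sample = np.array([ckeys.index(c) for c, _ in skeys])

    eta = beta_t[cat_idx] + r_ijk
    sig = expit(eta)
    tc = df["tumor_content"].to_numpy()
    if ccf:
        p = tc * sig / ((1 - tc) * 2 + tc * df["copy_number"].to_numpy())
    else:
        p = sig * tc
    lp = sps.binom.logpmf(df["b"].to_numpy(), df["d"].to_numpy(), p).sum()
    lp += sps.cauchy.logpdf(beta_t, loc=beta, scale=tau).sum()
    lp += sps.cauchy.logpdf(beta, loc=hyper.beta0, scale=hyper.tau0)
    lp += sps.halfcauchy.logpdf(tau, scale=hyper.lambda0)
    lp += sps.cauchy.logpdf(r_ijk, loc=r_ij[s_idx], scale=t_ij[s_idx]).sum()
    lp += sps.cauchy.logpdf(r_ij, loc=r_i[case_of_sample],
                            scale=t_i[case_of_sample]).sum()
    lp += sps.cauchy.logpdf(r_i, loc=hyper.r0, scale=t).sum()
    lp += sps.halfcauchy.logpdf(t_ij, scale=hyper.l2).sum()
    lp += sps.halfcauchy.logpdf(t_i, scale=hyper.l1).sum()
    lp += sps.halfcauchy.logpdf(t, scale=hyper.l0)
    return float(lp)


def test_count_model_log_density_matches_oracle_at_pinned_points():
    rng = np.random.default_rng(10)
    df = count_frame(rng, {"adenoma": 40, "carcinoma": 90}, n_per_stage=8)
    model = AlterationCountModel(hyper=PINNED_HYPER).prepare(df)
    d = model._oracle_data
    data = (d["n"], d["stage_idx"], d["case_idx"])
    for trial in range(10):
        r = np.random.default_rng(100 + trial)
        params = dict(
            beta_t=r.normal(3, 1, size=2),
            beta=float(r.normal()),
            tau=float(r.uniform(0.2, 2)),
            r_ij=r.normal(0, 1, size=len(d["n"])),
            r_i=r.normal(0, 1, size=d["n_cases"]),
            t_i=r.uniform(0.1, 2, size=d["n_cases"]),
            t=float(r.uniform(0.1, 2)),
        )
        got = model.log_posterior(params)
        want = oracle_count_logpost(data, PINNED_HYPER, params)
        assert got == pytest.approx(want, abs=1e-8)


@pytest.mark.parametrize("cls,ccf", [(VafCategoryModel, False),
                                     (CcfCategoryModel, True)])
def test_binomial_models_log_density_matches_oracle(cls, ccf):
    rng = np.random.default_rng(11)
    df = vaf_frame(rng, {"hi": 0.5, "lo": 0.1}, n_per_cat=25)
    model = cls(hyper=PINNED_HYPER).prepare(df)
    d = model._oracle_data
    for trial in range(10):
        r = np.random.default_rng(200 + trial)
        params = dict(
            beta_t=r.normal(0, 1, size=d["n_groups"]),
            beta=float(r.normal()),
            tau=float(r.uniform(0.2, 2)),
            r_ijk=r.normal(0, 0.5, size=len(d["b"])),
            r_ij=r.normal(0, 0.5, size=d["n_samples"]),
            r_i=r.normal(0, 0.5, size=d["n_cases"]),
            t_ij=r.uniform(0.1, 2, size=d["n_samples"]),
            t_i=r.uniform(0.1, 2, size=d["n_cases"]),
            t=float(r.uniform(0.1, 2)),
        )
        got = model.log_posterior(params)
        want = oracle_vaf_logpost(df, PINNED_HYPER, params, ccf=ccf)
        assert got == pytest.approx(want, abs=1e-8)


# ---------------------------------------------------------------------------
# recovery and behavior


def test_count_model_single_stage_recovery():
    rng = np.random.default_rng(12)
    df = count_frame(rng, {"adenoma": 100}, n_per_stage=60)
    model = AlterationCountModel(hyper=RECOVERY_HYPER, mcmc=FAST).fit(df)
    s = model.summary(kind="adjusted")
    assert s.loc["adenoma", "ci2.5"] < 100 < s.loc["adenoma", "ci97.5"]


def test_count_model_orders_two_stages():
    rng = np.random.default_rng(13)
    df = count_frame(rng, {"adenoma": 50, "carcinoma": 200}, n_per_stage=25)
    model = AlterationCountModel(hyper=RECOVERY_HYPER, mcmc=FAST).fit(df)
    assert model.prob_greater("carcinoma", "adenoma") > 0.99


def test_count_model_zero_count_smoke():
    df = pd.DataFrame(
        [dict(case_id="c0", sample_id="s0", stage="adenoma", n=0)]
    )
    model = AlterationCountModel(mcmc=FAST).fit(df)
    mean_rate = np.exp(model.group_logit_draws(kind="adjusted")).mean()
    assert mean_rate < 5  # posterior mean rate concentrated near zero-to-few


def test_count_model_rejects_bad_inputs():
    base = dict(case_id="c", sample_id="s", stage="adenoma", n=3)
    with pytest.raises(ValueError, match="zero observations"):
        AlterationCountModel(mcmc=FAST, stages=["adenoma", "carcinoma"]).fit(
            pd.DataFrame([base])
        )
    with pytest.raises(ValueError, match="non-negative integers"):
        AlterationCountModel(mcmc=FAST).fit(pd.DataFrame([{**base, "n": 2.5}]))
    with pytest.raises(ValueError, match="exactly once"):
        AlterationCountModel(mcmc=FAST).fit(pd.DataFrame([base, base]))


def test_summary_arithmetic_on_known_draws():
    rng = np.random.default_rng(14)
    df = count_frame(rng, {"adenoma": 30}, n_per_stage=5)
    model = AlterationCountModel(mcmc=FAST).prepare(df)
    draws = np.log(np.arange(1.0, 101.0))  # exp-scale draws are 1..100
    model.draws_ = {
        "beta_t": draws.reshape(2, 50, 1),
        "group_resid_mean": np.zeros((2, 50, 1)),
    }
    s = model.summary()
    assert s.loc["adenoma", "mean"] == pytest.approx(50.5)
    assert s.loc["adenoma", "median"] == pytest.approx(np.median(np.arange(1, 101)))
    lo, hi = np.quantile(np.arange(1.0, 101.0), [0.025, 0.975])
    assert s.loc["adenoma", "ci2.5"] == pytest.approx(lo)
    assert s.loc["adenoma", "ci97.5"] == pytest.approx(hi)
    # constant draws collapse the interval
    model.draws_["beta_t"] = np.full((2, 50, 1), np.log(7.0))
    s = model.summary()
    assert s.loc["adenoma", "ci2.5"] == pytest.approx(7.0)
    assert s.loc["adenoma", "ci97.5"] == pytest.approx(7.0)


def test_seed_determinism():
    rng = np.random.default_rng(15)
    df = count_frame(rng, {"adenoma": 40}, n_per_stage=10)
    cfg = McmcConfig(n_chains=2, n_burnin=100, n_total=200, seed=9)
    a = AlterationCountModel(mcmc=cfg).fit(df)
    b = AlterationCountModel(mcmc=cfg).fit(df)
    np.testing.assert_array_equal(a.draws_["beta_t"], b.draws_["beta_t"])


def test_vaf_model_recovery_and_ordering():
    rng = np.random.default_rng(16)
    hyper = Hyperparameters(r0=0.0, l0=0.05, l1=0.05, l2=0.05)
    rows = []
    for cat, p in {"hi": 0.5, "lo": 0.15}.items():
        for k in range(200):
            t = rng.uniform(0.4, 0.9)
            d = max(1, int(rng.negative_binomial(8, 8 / 140)))
            rows.append(
                dict(case_id=f"c{k % 4}", sample_id=f"c{k % 4}_s{k % 3}",
                     category=cat, b=int(rng.binomial(d, p * t)), d=d,
                     tumor_content=t)
            )
    model = VafCategoryModel(hyper=hyper, mcmc=FAST).fit(pd.DataFrame(rows))
    s = model.summary()
    assert s.loc["hi", "mean"] == pytest.approx(0.5, abs=0.05)
    assert s.loc["lo", "mean"] == pytest.approx(0.15, abs=0.05)
    assert model.prob_greater("hi", "lo", kind="raw") > 0.99


def test_vaf_model_no_signal_sanity():
    rows = [
        dict(case_id="c0", sample_id=f"s{j}", category="only", b=0, d=50,
             tumor_content=0.8)
        for j in range(20)
    ]
    model = VafCategoryModel(
        hyper=Hyperparameters(r0=0.0), mcmc=FAST
    ).fit(pd.DataFrame(rows))
    p = expit(model.group_logit_draws(kind="adjusted"))
    assert np.mean(p < 0.05) > 0.95


def test_vaf_model_requires_tumor_content():
    rows = [dict(case_id="c", sample_id="s", category="x", b=3, d=10,
                 tumor_content=np.nan)]
    with pytest.raises(ValueError, match="tumor content"):
        VafCategoryModel(mcmc=FAST).fit(pd.DataFrame(rows))


def test_ccf_model_filters_sex_chromosomes():
    rng = np.random.default_rng(17)
    df = vaf_frame(rng, {"trunk": 0.9}, n_per_cat=40)
    df.loc[:4, "chrom"] = "X"
    df.loc[5:6, "chrom"] = "chrY"
    model = CcfCategoryModel(mcmc=FAST).prepare(df)
    assert model.n_excluded_sex_ == 7
    assert model.n_obs_ == len(df) - 7


def test_ccf_model_requires_copy_number():
    rows = [dict(case_id="c", sample_id="s", category="x", b=3, d=10,
                 tumor_content=0.8, copy_number=np.nan, chrom="1")]
    with pytest.raises(ValueError, match="copy_number missing"):
        CcfCategoryModel(mcmc=FAST).fit(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# CCF closed form


def test_expected_vaf_closed_form_examples():
    assert expected_vaf_from_ccf(1.0, 1.0, 2) == 0.5
    assert expected_vaf_from_ccf(1.0, 0.5, 2) == pytest.approx(0.25)
    assert expected_vaf_from_ccf(1.0, 0.5, 4) == pytest.approx(1 / 6, abs=5e-5)
    with pytest.raises(ValueError, match="CN=0"):
        expected_vaf_from_ccf(0.5, 0.5, 0)


@given(
    st.floats(min_value=0.05, max_value=0.95),
    st.floats(min_value=0.05, max_value=1.0),
    st.integers(min_value=1, max_value=6),
)
@settings(max_examples=200, deadline=None)
def test_expected_vaf_monotonicity(c, tc, cn):
    eps = 0.02
    base = expected_vaf_from_ccf(c, tc, cn)
    assert 0 < base < 1
    assert expected_vaf_from_ccf(min(c + eps, 0.999), tc, cn) > base
    if tc + eps <= 1 and cn == 2:
        assert expected_vaf_from_ccf(c, tc + eps, cn) > base
    assert expected_vaf_from_ccf(c, tc, cn + 1) < base


def test_ccf_and_vaf_models_agree_at_cn2_tc1():
    """With CN=2 and TC=1 the CCF success probability is C/2 while the VAF
    model's is P: the two fits describe the same data through P = C/2, so the
    transformed posterior means must agree within Monte-Carlo error."""
    rng = np.random.default_rng(18)
    rows = []
    for k in range(300):
        d = max(1, int(rng.negative_binomial(8, 8 / 140)))
        rows.append(
            dict(case_id=f"c{k % 4}", sample_id=f"c{k % 4}_s{k % 3}",
                 category="trunk", b=int(rng.binomial(d, 0.4)), d=d,
                 tumor_content=1.0, copy_number=2, chrom=str(1 + k % 22))
        )
    df = pd.DataFrame(rows)
    hyper = Hyperparameters(r0=0.0, l0=0.05, l1=0.05, l2=0.05)
    cfg = McmcConfig(n_chains=2, n_burnin=500, n_total=900, seed=2)
    vaf = VafCategoryModel(hyper=hyper, mcmc=cfg).fit(df)
    ccf = CcfCategoryModel(hyper=hyper, mcmc=cfg).fit(df)
    p_vaf = expit(vaf.group_logit_draws(kind="adjusted")).mean()
    c_ccf = expit(ccf.group_logit_draws(kind="adjusted")).mean()
    assert p_vaf == pytest.approx(c_ccf / 2.0, abs=0.02)
    assert p_vaf == pytest.approx(0.4, abs=0.03)


def test_posterior_density_summary_wrapper():
    rng = np.random.default_rng(19)
    df = count_frame(rng, {"adenoma": 30}, n_per_stage=10)
    model = AlterationCountModel(mcmc=FAST).fit(df)
    s = posterior_density_summary(model, kind="adjusted")
    assert list(s.columns) == ["mean", "median", "ci2.5", "ci97.5"]
    assert s.loc["adenoma", "ci2.5"] <= s.loc["adenoma", "median"] <= s.loc[
        "adenoma", "ci97.5"
    ]


def test_sklearn_params_round_trip():
    model = VafCategoryModel(random_state=7)
    params = model.get_params()
    assert params["random_state"] == 7
    clone = VafCategoryModel(**params)
    assert clone.get_params() == params
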