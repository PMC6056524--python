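"""Hierarchical Bayesian models of alteration counts, VAFs and CCFs.

Three scikit-learn-style estimators share one architecture:

* ``AlterationCountModel`` — per-sample alteration counts ``n_ij`` are
  Poisson with log-mean ``beta_t(ij) + r_ij``, where ``t`` indexes tumor
  stage. Group means follow a Cauchy hierarchy (``beta_t ~ Cauchy(beta,
  tau)``, ``beta ~ Cauchy(beta0, tau0)``, ``tau ~ Half-Cauchy(lambda0)``)
  and the residual is nested by case then sample: ``r_i ~ Cauchy(r0, t)``,
  ``r_ij ~ Cauchy(r_i, t_i)`` with Half-Cauchy scale hyper-priors.

* ``VafCategoryModel`` — per-mutation variant reads ``b_ijk`` are Binomial
  with success probability ``logistic(beta_t(ijk) + r_ijk) * TC_ij``: the
  logistic term is the tumor-content-free mean VAF of the mutation's
  category, multiplied by sample tumor content. The residual gains a
  mutation level: ``r_ijk ~ Cauchy(r_ij, t_ij)``, ``t_ij ~ Half-Cauchy(l2)``.

* ``CcfCategoryModel`` — identical hierarchy, but the logistic term is the
  cancer cell fraction ``C`` and the success probability is the
  copy-number-adjusted VAF ``TC*C / ((1-TC)*2 + TC*CN)``. Sex-chromosome
  mutations are excluded before fitting.

All models are fitted by slice-within-Gibbs MCMC (:mod:`ithshift.mcmc`) and
report split-R-hat per monitored parameter. Because the group means and the
residual hierarchy are only softly separated by their priors (the likelihood
constrains their sum), each model also monitors the identified combination
``beta_t + mean(residuals of group t)``, reported as the "adjusted" group
mean on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, xlogy
from sklearn.base import BaseEstimator

from .mcmc import cauchy_logpdf, gelman_rubin, half_cauchy_logpdf, slice_sample
from .types import (
    FAST_MCMC,
    Hyperparameters,
    McmcConfig,
    STAGES,
    is_sex_chromosome,
)

__all__ = [
    "CountObservation",
    "VafObservation",
    "AlterationCountModel",
    "VafCategoryModel",
    "CcfCategoryModel",
    "expected_vaf_from_ccf",
    "fit_count_model",
    "fit_vaf_model",
    "fit_ccf_model",
    "posterior_density_summary",
]


@dataclass(frozen=True)
class CountObservation:
    """One sample's alteration count with its stage label."""

    case_id: str
    sample_id: str
    stage: str
    n: int


@dataclass(frozen=True)
class VafObservation:
    """One mutation's read counts in one sample, with category and context."""

    case_id: str
    sample_id: str
    category: str
    b: int
    d: int
    tumor_content: float
    copy_number: Optional[int] = None
    chrom: str = ""


def _as_frame(observations, fields) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations.copy()
    rows = [{f: getattr(o, f) for f in fields} for o in observations]
    return pd.DataFrame(rows)


def expected_vaf_from_ccf(C, TC, CN):
    """Expected VAF of a mutation carried by a fraction ``C`` of tumor cells.

    ``TC*C / ((1-TC)*2 + TC*CN)``: the mutant allele (multiplicity one) is
    read against two normal-cell copies diluting the ``CN`` tumor copies.
    Strictly increasing in ``C`` and ``TC`` and decreasing in ``CN``.
    """
    C = np.asarray(C, dtype=float)
    TC = np.asarray(TC, dtype=float)
    CN = np.asarray(CN)
    if np.any(CN == 0):
        raise ValueError("CN=0 loci must be excluded before CCF conversion")
    return TC * C / ((1.0 - TC) * 2.0 + TC * np.asarray(CN, dtype=float))


# ---------------------------------------------------------------------------
# shared Gibbs driver


def _group_index(values: Sequence, order: Optional[List] = None):
    if order is None:
        order = sorted(set(values))
    lut = {g: i for i, g in enumerate(order)}
    try:
        idx = np.array([lut[v] for v in values], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"value {exc.args[0]!r} not among declared groups {order}")
    return idx, list(order)


class _HierarchicalBase(BaseEstimator):
    """Common chain orchestration, monitoring and diagnostics."""

    def __init__(self, hyper=None, mcmc=None, random_state=None):
        self.hyper = hyper
        self.mcmc = mcmc
        self.random_state = random_state

    # subclasses define: _prepare(X) -> data dict, _init_state(data, rng),
    # _sweep(state, data, rng), _monitor(state, data) -> dict of scalars/arrays

    def _resolved_config(self):
        hyper = self.hyper if self.hyper is not None else Hyperparameters()
        mcmc = self.mcmc if self.mcmc is not None else FAST_MCMC
        if not isinstance(hyper, Hyperparameters):
            hyper = Hyperparameters(**hyper)
        if not isinstance(mcmc, McmcConfig):
            mcmc = McmcConfig(**mcmc)
        if self.random_state is not None:
            mcmc = mcmc.with_seed(self.random_state)
        return hyper, mcmc

    def prepare(self, X):
        """Validate and index the observations without running MCMC; gives
        access to ``log_posterior`` for pinned-parameter evaluation."""
        self._skip_mcmc = True
        try:
            self.fit(X)
        finally:
            self._skip_mcmc = False
        return self

    def _run(self, data) -> None:
        hyper, mcmc = self._resolved_config()
        self.hyper_, self.mcmc_ = hyper, mcmc
        if getattr(self, "_skip_mcmc", False):
            return
        n_keep = mcmc.n_retained
        store: Dict[str, np.ndarray] = {}
        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
        for c, seed in enumerate(seeds):
            rng = np.random.default_rng(seed)
            state = self._init_state(data, rng)
            for _ in range(mcmc.n_burnin):
                self._sweep(state, data, rng)
            kept = 0
            for it in range(mcmc.n_sampling):
                self._sweep(state, data, rng)
                if it % mcmc.thin:
                    continue
                if kept >= n_keep:
                    break
                for name, val in self._monitor(state, data, rng).items():
                    arr = np.asarray(val, dtype=float)
                    if name not in store:
                        store[name] = np.empty(
                            (mcmc.n_chains, n_keep) + arr.shape, dtype=float
                        )
                    store[name][c, kept] = arr
                kept += 1
        self.draws_ = store
        self.rhat_ = self._rhat_table(store)

    def _rhat_table(self, store) -> pd.Series:
        groups = self.groups_
        out = {}
        rh = gelman_rubin(store)
        for name, val in rh.items():
            val = np.atleast_1d(val)
            if name in ("beta_t", "group_resid_mean", "adjusted") and len(val) == len(
                groups
            ):
                for g, v in zip(groups, val):
                    out[f"{name}[{g}]"] = float(v)
            else:
                for i, v in enumerate(val):
                    key = name if len(val) == 1 else f"{name}[{i}]"
                    out[key] = float(v)
        return pd.Series(out, name="rhat")

    # ------------------------------------------------------------------
    # posterior accessors

    def _flat(self, name: str) -> np.ndarray:
        arr = self.draws_[name]
        return arr.reshape(-1, *arr.shape[2:])

    def group_logit_draws(self, kind: str = "raw") -> np.ndarray:
        """Draws of the per-group linear predictor, flattened across chains
        (shape ``(n_draws, n_groups)``).

        ``raw``: beta_t as monitored (the published quantity). ``adjusted``:
        beta_t plus the mean fitted residual of the group's observations —
        the likelihood-identified combination, immune to the prior-anchored
        split between group means and residuals. ``predictive``: beta_t plus
        a residual drawn for a new observation through the fitted hierarchy
        (one per retained iteration), whose spread reflects between-sample
        variability as well as posterior uncertainty.
        """
        if kind == "raw":
            return self._flat("beta_t")
        if kind == "adjusted":
            return self._flat("beta_t") + self._flat("group_resid_mean")
        if kind == "predictive":
            return self._flat("beta_t") + self._flat("pred_resid")[:, None]
        raise ValueError(f"unknown kind {kind!r}")

    def prob_greater(self, a, b, kind: str = "adjusted") -> float:
        """Posterior probability that group ``a``'s mean exceeds ``b``'s."""
        draws = self.group_logit_draws(kind=kind)
        ia, ib = self.groups_.index(a), self.groups_.index(b)
        return float(np.mean(draws[:, ia] > draws[:, ib]))

    def summary(self, kind: str = "raw") -> pd.DataFrame:
        """Per-group posterior summary on the natural scale."""
        nat = self._natural_scale(self.group_logit_draws(kind=kind))
        rows = []
        for g, col in zip(self.groups_, nat.T):
            rows.append(
                {
                    "group": g,
                    "mean": float(np.mean(col)),
                    "median": float(np.median(col)),
                    "ci2.5": float(np.quantile(col, 0.025)),
                    "ci97.5": float(np.quantile(col, 0.975)),
                }
            )
        return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Poisson count model


class AlterationCountModel(_HierarchicalBase):
    """Posterior mean alteration count per tumor stage (Poisson likelihood).

    ``fit`` accepts a DataFrame with columns ``case_id, sample_id, stage, n``
    (or a sequence of :class:`CountObservation`). Each sample appears once.

    Fitted attributes (trailing underscore) include ``groups_`` (stage
    order), ``draws_`` (per-chain monitored draws), ``rhat_`` and the
    config echoes ``hyper_``/``mcmc_``.
    """

    def __init__(self, hyper=None, mcmc=None, random_state=None, stages=None):
        super().__init__(hyper=hyper, mcmc=mcmc, random_state=random_state)
        self.stages = stages

    _natural_scale = staticmethod(np.exp)

    def fit(self, X, y=None):
        df = _as_frame(X, ("case_id", "sample_id", "stage", "n"))
        return self._fit_impl(df)

    # --- Gibbs internals ------------------------------------------------

    def _init_state(self, data, rng):
        h = self.hyper_
        groups_mean = np.array(
            [
                data["n"][data["stage_idx"] == t].mean() + 0.5
                for t in range(data["n_groups"])
            ]
        )

        def jit(k):
            return 0.05 * rng.standard_normal(k)

        return {
            "beta_t": np.log(groups_mean) - h.r0 + jit(data["n_groups"]),
            "beta": np.array([float(np.log(groups_mean.mean()) - h.r0)]),
            "tau": np.array([1.0]),
            "r_ij": np.full(len(data["n"]), h.r0) + jit(len(data["n"])),
            "r_i": np.full(data["n_cases"], h.r0) + jit(data["n_cases"]),
            "t_i": np.full(data["n_cases"], 0.5),
            "t": np.array([0.5]),
        }

    def _sweep(self, st, data, rng):
        h = self.hyper_
        n, stage_idx, case_idx = data["n"], data["stage_idx"], data["case_idx"]
        T, I = data["n_groups"], data["n_cases"]

        # sample-level residuals: Poisson term + Cauchy(parent)
        beta_obs = st["beta_t"][stage_idx]

        def lp_rij(r):
            with np.errstate(over="ignore"):
                mu = np.exp(beta_obs + r)
            return n * r - mu + cauchy_logpdf(r, st["r_i"][case_idx], st["t_i"][case_idx])

        st["r_ij"] = slice_sample(st["r_ij"], lp_rij, rng)

        # case-level residual locations
        def lp_ri(ri):
            child = cauchy_logpdf(st["r_ij"], ri[case_idx], st["t_i"][case_idx])
            return np.bincount(case_idx, child, minlength=I) + cauchy_logpdf(
                ri, h.r0, st["t"][0]
            )

        st["r_i"] = slice_sample(st["r_i"], lp_ri, rng)

        # case-level residual scales (log parameterization)
        def lp_log_ti(theta):
            ti = np.exp(theta)
            child = cauchy_logpdf(st["r_ij"], st["r_i"][case_idx], ti[case_idx])
            return (
                np.bincount(case_idx, child, minlength=I)
                + half_cauchy_logpdf(ti, h.l1)
                + theta
            )

        st["t_i"] = np.exp(slice_sample(np.log(st["t_i"]), lp_log_ti, rng))

        def lp_log_t(theta):
            tt = np.exp(theta)
            return (
                np.sum(cauchy_logpdf(st["r_i"][:, None], h.r0, tt[None, :]), axis=0)
                + half_cauchy_logpdf(tt, h.l0)
                + theta
            )

        st["t"] = np.exp(slice_sample(np.log(st["t"]), lp_log_t, rng))

        # stage means: Poisson sufficient statistics per stage
        s_n = np.bincount(stage_idx, n, minlength=T)
        s_e = np.bincount(stage_idx, np.exp(st["r_ij"]), minlength=T)

        def lp_beta_t(bt):
            with np.errstate(over="ignore"):
                like = bt * s_n - np.exp(bt) * s_e
            return like + cauchy_logpdf(bt, st["beta"][0], st["tau"][0])

        st["beta_t"] = slice_sample(st["beta_t"], lp_beta_t, rng, width=0.5)

        def lp_beta(b):
            prior = np.sum(
                cauchy_logpdf(st["beta_t"][:, None], b[None, :], st["tau"][0]), axis=0
            )
            return prior + cauchy_logpdf(b, h.beta0, h.tau0)

        st["beta"] = slice_sample(st["beta"], lp_beta, rng)

        def lp_log_tau(theta):
            tau = np.exp(theta)
            prior = np.sum(
                cauchy_logpdf(st["beta_t"][:, None], st["beta"][0], tau[None, :]),
                axis=0,
            )
            return prior + half_cauchy_logpdf(tau, h.lambda0) + theta

        st["tau"] = np.exp(slice_sample(np.log(st["tau"]), lp_log_tau, rng))

    def _monitor(self, st, data, rng):
        T = data["n_groups"]
        grp_sum = np.bincount(data["stage_idx"], st["r_ij"], minlength=T)
        grp_n = np.bincount(data["stage_idx"], minlength=T)
        # residual for a hypothetical new sample of a randomly chosen case
        c = int(rng.integers(data["n_cases"]))
        pred = st["r_i"][c] + st["t_i"][c] * rng.standard_cauchy()
        return {
            "beta_t": st["beta_t"],
            "beta": st["beta"][0],
            "tau": st["tau"][0],
            "t": st["t"][0],
            "group_resid_mean": grp_sum / grp_n,
            "pred_resid": pred,
        }

    # --- exact joint density (oracle-checkable) -------------------------

    def log_posterior(self, params: dict) -> float:
        """Unnormalized joint log-density at a pinned parameter point.

        ``params`` carries arrays/scalars: beta_t, beta, tau, r_ij, r_i,
        t_i, t. All likelihood and prior normalization constants are
        included so the value matches an independently coded density.
        """
        h = self.hyper_ if hasattr(self, "hyper_") else self._resolved_config()[0]
        d = self._oracle_data
        beta_t = np.asarray(params["beta_t"], dtype=float)
        r_ij = np.asarray(params["r_ij"], dtype=float)
        r_i = np.asarray(params["r_i"], dtype=float)
        t_i = np.asarray(params["t_i"], dtype=float)
        beta, tau, t = (float(params[k]) for k in ("beta", "tau", "t"))
        log_mu = beta_t[d["stage_idx"]] + r_ij
        lp = float(np.sum(d["n"] * log_mu - np.exp(log_mu) - d["lgamma_n"]))
        lp += float(np.sum(cauchy_logpdf(beta_t, beta, tau)))
        lp += float(cauchy_logpdf(beta, h.beta0, h.tau0))
        lp += float(half_cauchy_logpdf(tau, h.lambda0))
        lp += float(np.sum(cauchy_logpdf(r_ij, r_i[d["case_idx"]], t_i[d["case_idx"]])))
        lp += float(np.sum(cauchy_logpdf(r_i, h.r0, t)))
        lp += float(np.sum(half_cauchy_logpdf(t_i, h.l1)))
        lp += float(half_cauchy_logpdf(t, h.l0))
        return lp

    def _fit_impl(self, df):
        for col in ("case_id", "sample_id", "stage", "n"):
            if col not in df.columns:
                raise ValueError(f"count observations need a {col!r} column")
        n = df["n"].to_numpy()
        if not np.all(np.equal(np.mod(n, 1), 0)) or np.any(n < 0):
            raise ValueError("alteration counts must be non-negative integers")
        n = n.astype(np.int64)
        keys = list(zip(df["case_id"], df["sample_id"]))
        if len(set(keys)) != len(keys):
            raise ValueError("every sample must appear exactly once")

        declared = self.stages
        if declared is None:
            declared = [s for s in STAGES if s in set(df["stage"])]
            if not declared:
                declared = sorted(set(df["stage"]))
        stage_idx, groups = _group_index(df["stage"], list(declared))
        counts_per = np.bincount(stage_idx, minlength=len(groups))
        empty = [g for g, c in zip(groups, counts_per) if c == 0]
        if empty:
            raise ValueError(f"stage {empty[0]!r} has zero observations")
        case_idx, cases = _group_index(df["case_id"])

        data = {
            "n": n,
            "stage_idx": stage_idx,
            "case_idx": case_idx,
            "n_groups": len(groups),
            "n_cases": len(cases),
            "lgamma_n": gammaln(n + 1.0),
        }
        self.groups_ = groups
        self.cases_ = cases
        self.n_obs_ = len(n)
        self._oracle_data = data
        self._run(data)
        return self


# ---------------------------------------------------------------------------
# Binomial VAF / CCF models


class VafCategoryModel(_HierarchicalBase):
    """Posterior mean VAF per mutation category (Binomial likelihood).

    ``fit`` accepts a DataFrame with columns ``case_id, sample_id, category,
    b, d, tumor_content`` (or :class:`VafObservation` records). Tumor content
    must be known for every sample; the fitted per-category quantity is
    ``logistic(beta_t)``, the mean VAF corrected for tumor content and depth.
    """

    _natural_scale = staticmethod(expit)
    _required = ("case_id", "sample_id", "category", "b", "d", "tumor_content")

    def __init__(self, hyper=None, mcmc=None, random_state=None, categories=None):
        super().__init__(hyper=hyper, mcmc=mcmc, random_state=random_state)
        self.categories = categories

    # success probability from the linear predictor; CCF model overrides
    def _success_prob(self, sig, data):
        return sig * data["tc_obs"]

    def _prepare_extra(self, df, data):
        return None

    def fit(self, X, y=None):
        df = _as_frame(X, self._required + ("copy_number", "chrom"))
        for col in self._required:
            if col not in df.columns:
                raise ValueError(f"VAF observations need a {col!r} column")
        df = self._filter(df)
        b = df["b"].to_numpy(dtype=np.int64)
        d = df["d"].to_numpy(dtype=np.int64)
        if np.any(b < 0) or np.any(b > d):
            raise ValueError("need 0 <= b <= d for every mutation")
        tc = df["tumor_content"].to_numpy(dtype=float)
        if np.any(~np.isfinite(tc)) or np.any(tc <= 0) or np.any(tc > 1):
            raise ValueError(
                "tumor content missing or outside (0, 1]; supply TC for every sample"
            )

        cat_idx, groups = _group_index(
            df["category"], list(self.categories) if self.categories else None
        )
        if self.categories:
            present = np.bincount(cat_idx, minlength=len(groups))
            empty = [g for g, c in zip(groups, present) if c == 0]
            if empty:
                raise ValueError(f"category {empty[0]!r} has zero observations")
        sample_keys = list(zip(df["case_id"], df["sample_id"]))
        s_idx, samples = _group_index(sample_keys)
        case_of_sample, cases = _group_index([s[0] for s in samples])
        tc_sample = np.zeros(len(samples))
        tc_sample[s_idx] = tc  # constant within sample by construction

        data = {
            "b": b,
            "d": d,
            "cat_idx": cat_idx,
            "s_idx": s_idx,
            "case_of_sample": case_of_sample,
            "tc_obs": tc,
            "tc_sample": tc_sample,
            "n_groups": len(groups),
            "n_samples": len(samples),
            "n_cases": len(cases),
            "lchoose": gammaln(d + 1.0) - gammaln(b + 1.0) - gammaln(d - b + 1.0),
        }
        self._prepare_extra(df, data)
        self.groups_ = groups
        self.samples_ = samples
        self.cases_ = cases
        self.n_obs_ = len(b)
        self._oracle_data = data
        self._run(data)
        return self

    def _filter(self, df):
        return df

    def _binom_ll(self, eta, data):
        """Per-observation Binomial log-likelihood sans the choose term."""
        p = self._success_prob(expit(eta), data)
        with np.errstate(divide="ignore", invalid="ignore"):
            return xlogy(data["b"], p) + xlogy(data["d"] - data["b"], 1.0 - p)

    def _init_state(self, data, rng):
        h = self.hyper_
        T = data["n_groups"]
        pooled = np.zeros(T)
        for t in range(T):
            sel = data["cat_idx"] == t
            pooled[t] = (data["b"][sel].sum() + 0.5) / (data["d"][sel].sum() + 1.0)
        # crude inverse: divide observed frequency by the mean success-prob
        # scaling the model applies at logistic term == 1
        ones = np.ones(len(data["b"]))
        full_scale = self._success_prob(ones, data)
        mean_scale = np.array(
            [max(full_scale[data["cat_idx"] == t].mean(), 1e-3) for t in range(T)]
        )
        p0 = np.clip(pooled / mean_scale, 1e-3, 1 - 1e-3)

        def jit(k):
            return 0.05 * rng.standard_normal(k)

        return {
            "beta_t": logit(p0) - h.r0 + jit(T),
            "beta": np.array([float(np.mean(logit(p0)) - h.r0)]),
            "tau": np.array([1.0]),
            "r_ijk": np.full(len(data["b"]), h.r0) + jit(len(data["b"])),
            "r_ij": np.full(data["n_samples"], h.r0) + jit(data["n_samples"]),
            "r_i": np.full(data["n_cases"], h.r0) + jit(data["n_cases"]),
            "t_ij": np.full(data["n_samples"], 0.5),
            "t_i": np.full(data["n_cases"], 0.5),
            "t": np.array([0.5]),
        }

    def _sweep(self, st, data, rng):
        h = self.hyper_
        cat_idx, s_idx = data["cat_idx"], data["s_idx"]
        cos = data["case_of_sample"]
        T, S, I = data["n_groups"], data["n_samples"], data["n_cases"]
        beta_obs = st["beta_t"][cat_idx]

        def lp_rijk(r):
            return self._binom_ll(beta_obs + r, data) + cauchy_logpdf(
                r, st["r_ij"][s_idx], st["t_ij"][s_idx]
            )

        st["r_ijk"] = slice_sample(st["r_ijk"], lp_rijk, rng)

        def lp_rij(rij):
            child = cauchy_logpdf(st["r_ijk"], rij[s_idx], st["t_ij"][s_idx])
            return np.bincount(s_idx, child, minlength=S) + cauchy_logpdf(
                rij, st["r_i"][cos], st["t_i"][cos]
            )

        st["r_ij"] = slice_sample(st["r_ij"], lp_rij, rng)

        def lp_log_tij(theta):
            tij = np.exp(theta)
            child = cauchy_logpdf(st["r_ijk"], st["r_ij"][s_idx], tij[s_idx])
            return (
                np.bincount(s_idx, child, minlength=S)
                + half_cauchy_logpdf(tij, h.l2)
                + theta
            )

        st["t_ij"] = np.exp(slice_sample(np.log(st["t_ij"]), lp_log_tij, rng))

        def lp_ri(ri):
            child = cauchy_logpdf(st["r_ij"], ri[cos], st["t_i"][cos])
            return np.bincount(cos, child, minlength=I) + cauchy_logpdf(
                ri, h.r0, st["t"][0]
            )

        st["r_i"] = slice_sample(st["r_i"], lp_ri, rng)

        def lp_log_ti(theta):
            ti = np.exp(theta)
            child = cauchy_logpdf(st["r_ij"], st["r_i"][cos], ti[cos])
            return (
                np.bincount(cos, child, minlength=I)
                + half_cauchy_logpdf(ti, h.l1)
                + theta
            )

        st["t_i"] = np.exp(slice_sample(np.log(st["t_i"]), lp_log_ti, rng))

        def lp_log_t(theta):
            tt = np.exp(theta)
            return (
                np.sum(cauchy_logpdf(st["r_i"][:, None], h.r0, tt[None, :]), axis=0)
                + half_cauchy_logpdf(tt, h.l0)
                + theta
            )

        st["t"] = np.exp(slice_sample(np.log(st["t"]), lp_log_t, rng))

        def lp_beta_t(bt):
            ll = self._binom_ll(bt[cat_idx] + st["r_ijk"], data)
            return np.bincount(cat_idx, ll, minlength=T) + cauchy_logpdf(
                bt, st["beta"][0], st["tau"][0]
            )

        st["beta_t"] = slice_sample(st["beta_t"], lp_beta_t, rng, width=0.5)

        def lp_beta(b):
            prior = np.sum(
                cauchy_logpdf(st["beta_t"][:, None], b[None, :], st["tau"][0]), axis=0
            )
            return prior + cauchy_logpdf(b, h.beta0, h.tau0)

        st["beta"] = slice_sample(st["beta"], lp_beta, rng)

        def lp_log_tau(theta):
            tau = np.exp(theta)
            prior = np.sum(
                cauchy_logpdf(st["beta_t"][:, None], st["beta"][0], tau[None, :]),
                axis=0,
            )
            return prior + half_cauchy_logpdf(tau, h.lambda0) + theta

        st["tau"] = np.exp(slice_sample(np.log(st["tau"]), lp_log_tau, rng))

    def _monitor(self, st, data, rng):
        T = data["n_groups"]
        grp_sum = np.bincount(data["cat_idx"], st["r_ijk"], minlength=T)
        grp_n = np.bincount(data["cat_idx"], minlength=T)
        # residual for a hypothetical new mutation of a randomly chosen sample
        s = int(rng.integers(data["n_samples"]))
        pred = st["r_ij"][s] + st["t_ij"][s] * rng.standard_cauchy()
        return {
            "beta_t": st["beta_t"],
            "beta": st["beta"][0],
            "tau": st["tau"][0],
            "t": st["t"][0],
            "group_resid_mean": grp_sum / grp_n,
            "pred_resid": pred,
        }

    def log_posterior(self, params: dict) -> float:
        """Unnormalized joint log-density (all constants included)."""
        h = self.hyper_ if hasattr(self, "hyper_") else self._resolved_config()[0]
        d = self._oracle_data
        beta_t = np.asarray(params["beta_t"], dtype=float)
        r_ijk = np.asarray(params["r_ijk"], dtype=float)
        r_ij = np.asarray(params["r_ij"], dtype=float)
        r_i = np.asarray(params["r_i"], dtype=float)
        t_ij = np.asarray(params["t_ij"], dtype=float)
        t_i = np.asarray(params["t_i"], dtype=float)
        beta, tau, t = (float(params[k]) for k in ("beta", "tau", "t"))
        eta = beta_t[d["cat_idx"]] + r_ijk
        lp = float(np.sum(self._binom_ll(eta, d) + d["lchoose"]))
        lp += float(np.sum(cauchy_logpdf(beta_t, beta, tau)))
        lp += float(cauchy_logpdf(beta, h.beta0, h.tau0))
        lp += float(half_cauchy_logpdf(tau, h.lambda0))
        s, c = d["s_idx"], d["case_of_sample"]
        lp += float(np.sum(cauchy_logpdf(r_ijk, r_ij[s], t_ij[s])))
        lp += float(np.sum(cauchy_logpdf(r_ij, r_i[c], t_i[c])))
        lp += float(np.sum(cauchy_logpdf(r_i, h.r0, t)))
        lp += float(np.sum(half_cauchy_logpdf(t_ij, h.l2)))
        lp += float(np.sum(half_cauchy_logpdf(t_i, h.l1)))
        lp += float(half_cauchy_logpdf(t, h.l0))
        return lp


class CcfCategoryModel(VafCategoryModel):
    """Posterior mean cancer cell fraction per mutation category.

    Same hierarchy as :class:`VafCategoryModel`, but the logistic term is the
    CCF and the Binomial success probability passes through
    :func:`expected_vaf_from_ccf` using each mutation's local copy number.
    Requires a ``copy_number`` column; rows on sex chromosomes (``chrom``
    column, when present) are removed before fitting, and CN=0 rows are
    excluded with a count kept in ``n_excluded_cn0_``.
    """

    def _filter(self, df):
        if "copy_number" not in df.columns or df["copy_number"].isna().any():
            missing = (
                df.index[df["copy_number"].isna()].tolist()
                if "copy_number" in df.columns
                else "all rows"
            )
            raise ValueError(f"copy_number missing for observations: {missing}")
        if "chrom" in df.columns:
            sex = df["chrom"].astype(str).map(is_sex_chromosome)
            self.n_excluded_sex_ = int(sex.sum())
            df = df[~sex]
        else:
            self.n_excluded_sex_ = 0
        cn0 = df["copy_number"].astype(int) == 0
        self.n_excluded_cn0_ = int(cn0.sum())
        if cn0.any():
            import warnings

            warnings.warn(f"excluded {int(cn0.sum())} CN=0 mutations from CCF fit")
            df = df[~cn0]
        if not len(df):
            raise ValueError("no observations left after CCF filters")
        return df.reset_index(drop=True)

    def _prepare_extra(self, df, data):
        data["cn_obs"] = df["copy_number"].to_numpy(dtype=float)

    def _success_prob(self, sig, data):
        tc = data["tc_obs"]
        return tc * sig / ((1.0 - tc) * 2.0 + tc * data["cn_obs"])


# ---------------------------------------------------------------------------
# functional wrappers (the operation-style surface)


def fit_count_model(observations, hyper=None, mcmc_config=None, stages=None):
    model = AlterationCountModel(hyper=hyper, mcmc=mcmc_config, stages=stages)
    return model.fit(observations)


def fit_vaf_model(observations, hyper=None, mcmc_config=None, categories=None):
    model = VafCategoryModel(hyper=hyper, mcmc=mcmc_config, categories=categories)
    return model.fit(observations)


def fit_ccf_model(observations, hyper=None, mcmc_config=None, categories=None):
    model = CcfCategoryModel(hyper=hyper, mcmc=mcmc_config, categories=categories)
    return model.fit(observations)


def posterior_density_summary(model, kind: str = "raw") -> pd.DataFrame:
    """Per-group posterior mean/median/95% CI on the natural scale
    (exponential for counts, logistic for VAF/CCF)."""
    return model.summary(kind=kind)
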