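"""Bayesian cross-classified Poisson regression of care-deficiency counts.

The outcome is the Total Weighted Health Survey Score discretized to an
integer, modelled as

    y_i ~ Poisson(exp(x_i' beta + u_state[i] + u_hrr[i] + u_fac[i] + e_i))

with additive random intercepts for American state and hospital referral
region (cross-classified: HRRs cross state lines), a facility-level
intercept for the repeated semi-annual measures, and an observation-level
Gaussian residual on the log scale (log-normal Poisson) absorbing
overdispersion.  Fixed effects get a vague Normal(0, 1e8) prior; variance
components get half-Cauchy(0, 5) by default (inverse-gamma(0.001, 0.001)
as a compatibility option).  Continuous covariates are mean-centered over
the analysis sample.

Inference is by an adaptive Metropolis-within-Gibbs sampler:

* fixed effects move in one block, preconditioned by the inverse of the
  Fisher information X'WX (W = diag of current Poisson means) plus the
  prior precision, with a globally adapted step size;
* each random-effect factor (including the observation-level term) gets
  vectorized per-level random-walk proposals with per-level adapted steps,
  accepted against the exact Poisson conditional;
* variances are conjugate inverse-gamma draws, the half-Cauchy prior
  entering through its inverse-gamma scale-mixture representation;
* an exact Gibbs "recentering" sweep moves mass along the degenerate
  direction (all intercepts of a factor up, fixed intercept down), which
  leaves the likelihood untouched and fixes the usual slow mixing between
  the intercept and random-effect means.

Adaptation runs only during burn-in, so the kept draws target the exact
posterior.  Reported effects are prevalence ratios PR = exp(posterior
mean coefficient) with 95% highest-posterior-density intervals on the
exponentiated bounds, two-sided tail probabilities (pMCMC, floored at one
over the kept-draw count), and intraclass correlation coefficients per
variance component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS_TERMS = (
    "staffing_cna_hrd",
    "staffing_lpn_hrd",
    "staffing_rn_hrd",
    "residents",
    "occupancy_pct",
    "years_in_business",
)
BOOLEAN_TERMS = ("hospital_based", "sff", "ccrc", "council", "ownership_changed")
HRR_LEVEL_TERMS = ("prevalence_multiple_pct", "mean_group_size", "delta_hhi")


class DesignError(ValueError):
    """The model frame cannot support the requested design."""


class SettingsError(ValueError):
    """Inconsistent MCMC schedule or prior specification."""


@dataclass
class ModelSpec:
    """Which columns enter the fixed-effect design, and the random terms.

    ``variant`` selects between the quality-measure parameterizations:
    ``model1`` carries the ordinal Five-Star rating as dummies (category 1
    reference); ``model2`` replaces it with the individual MDS measure-code
    prevalences (the rating is derived from those measures, so carrying
    both would be collinear).  Reference levels: for-profit ownership,
    multiple affiliation, and their combination for the interaction.
    """

    variant: str = "model1"
    continuous: tuple[str, ...] = CONTINUOUS_TERMS
    booleans: tuple[str, ...] = BOOLEAN_TERMS
    include_ownership_type: bool = True
    include_affiliation: bool = True
    include_interaction: bool = True
    include_quality: bool = True  # five-star dummies (model1) / MDS columns (model2)
    hrr_level: tuple[str, ...] = HRR_LEVEL_TERMS
    mds_codes: tuple[int, ...] | None = None  # None -> infer from the frame
    random_terms: tuple[str, ...] = ("state", "hrr", "facility", "obs")
    center: bool = True

    def __post_init__(self):
        if self.variant not in ("model1", "model2"):
            raise SettingsError(f"unknown model variant {self.variant!r}")


@dataclass
class MCMCSettings:
    """Chain schedule and priors.

    The default schedule keeps (115,000 - 15,000) / 10 = 10,000 draws.
    ``variance_prior`` is ``halfcauchy`` (scale 5) or ``invgamma``
    (shape/scale 0.001).
    """

    n_iter: int = 115_000
    burn_in: int = 15_000
    thin: int = 10
    seed: int = 20160301
    beta_prior_var: float = 1e8
    variance_prior: str = "halfcauchy"
    halfcauchy_scale: float = 5.0
    invgamma_shape: float = 0.001
    invgamma_scale: float = 0.001
    n_fixed_subiters: int = 1  # fixed-effect block repeats per scan
    u_store_max_levels: int = 400

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise SettingsError("burn-in must be shorter than the chain")
        if (self.n_iter - self.burn_in) % self.thin != 0:
            raise SettingsError("(n_iter - burn_in) must be divisible by thin")
        if self.variance_prior not in ("halfcauchy", "invgamma"):
            raise SettingsError(f"unknown variance prior {self.variance_prior!r}")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class DesignBundle:
    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    factor_codes: dict[str, np.ndarray]   # factor name -> per-row level index
    factor_levels: dict[str, list]        # factor name -> level labels
    centering_means: dict[str, float]
    row_index: pd.DataFrame | None = None  # provider_id/date bookkeeping

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class PosteriorSamples:
    beta: np.ndarray                       # (n_kept, p)
    colnames: list[str]
    sigma2: dict[str, np.ndarray]          # factor -> (n_kept,)
    u_draws: dict[str, np.ndarray]         # small factors -> (n_kept, n_levels)
    u_mean: dict[str, np.ndarray]          # every factor -> posterior-mean intercepts
    factor_levels: dict[str, list]
    settings: MCMCSettings
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return self.beta.shape[0]


@dataclass
class PosteriorSummary:
    fixed: pd.DataFrame
    icc: pd.DataFrame
    variance: pd.DataFrame
    random_pr: dict[str, pd.DataFrame]
    diagnostics: dict


# ---------------------------------------------------------------------------
# Design construction


def assemble_model_frame(panel, networks, metrics) -> pd.DataFrame:
    """Merge the facility panel with network outputs and HRR metrics.

    Adds the per-facility ``affiliation`` class from the network stage and
    the five HRR-level covariates by (hrr, date).  Complete-case rows only.
    """
    from .hrr_aggregation import metrics_frame

    frame = panel.to_frame(complete_only=True)
    if frame.empty:
        return frame
    aff = {}
    for (hrr, date), nw in networks.items():
        for c in nw.classes:
            aff[(c.provider_id, date)] = c.affiliation
    frame["affiliation"] = [
        aff.get((p, d)) for p, d in zip(frame["provider_id"], frame["date"])
    ]
    mf = metrics_frame(metrics)[
        ["hrr", "date", "prevalence_multiple_pct", "mean_group_size", "delta_hhi"]
    ]
    return frame.merge(mf, on=["hrr", "date"], how="left")


def build_design(
    frame: pd.DataFrame, spec: ModelSpec, check_rank: bool = True
) -> DesignBundle:
    """Construct the outcome vector, fixed-effect matrix and grouping codes.

    Rows with any missing required column are dropped (complete-case).
    Continuous columns are centered on their analysis-sample means when
    ``spec.center``; dummies use the fixed reference levels.  A
    rank-deficient design raises :class:`DesignError` naming the aliased
    columns; ``check_rank=False`` skips that (a simulator evaluating a
    given coefficient vector does not need an identifiable design).
    """
    if frame.empty:
        raise DesignError("empty model frame")
    df = frame.copy()

    mds_cols: list[str] = []
    if spec.variant == "model2" and spec.include_quality:
        if spec.mds_codes is not None:
            mds_cols = [f"mds_{c}" for c in spec.mds_codes]
            missing = [c for c in mds_cols if c not in df.columns]
            if missing:
                raise DesignError(f"frame lacks MDS columns {missing}")
        else:
            mds_cols = sorted(
                (c for c in df.columns if c.startswith("mds_")),
                key=lambda c: int(c.split("_")[1]),
            )

    required = ["twhss_int", "state", "hrr", "provider_id"]
    required += list(spec.continuous) + list(spec.booleans)
    if spec.include_ownership_type:
        required.append("ownership_type")
    if spec.include_affiliation or spec.include_interaction:
        required.append("affiliation")
    if spec.variant == "model1" and spec.include_quality:
        required.append("five_star")
    required += [t for t in spec.hrr_level]
    required += mds_cols
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise DesignError(f"model frame lacks columns {missing_cols}")
    df = df.dropna(subset=required)
    if df.empty:
        raise DesignError("no complete rows for the requested design")
    df = df.sort_values(["provider_id", "date"]).reset_index(drop=True)

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    means: dict[str, float] = {}

    def add_continuous(name: str, values: np.ndarray):
        v = values.astype(float)
        if spec.center:
            m = float(v.mean())
            means[name] = m
            v = v - m
        cols[name] = v

    for term in spec.continuous:
        add_continuous(term, df[term].to_numpy())
    for term in spec.booleans:
        cols[term] = df[term].astype(bool).to_numpy().astype(float)
    if spec.include_ownership_type:
        own = df["ownership_type"].to_numpy()
        cols["ownership_government"] = (own == "government").astype(float)
        cols["ownership_nonprofit"] = (own == "non-profit").astype(float)
    if spec.variant == "model1" and spec.include_quality:
        fs = df["five_star"].astype(int).to_numpy()
        for cat in (2, 3, 4, 5):
            cols[f"five_star_{cat}"] = (fs == cat).astype(float)
    for mcol in mds_cols:
        add_continuous(mcol, df[mcol].to_numpy())
    for term in spec.hrr_level:
        add_continuous(term, df[term].to_numpy())
    single = None
    if spec.include_affiliation or spec.include_interaction:
        single = (df["affiliation"].to_numpy() == "single").astype(float)
    if spec.include_affiliation:
        cols["affiliation_single"] = single
    if spec.include_interaction:
        if not spec.include_ownership_type:
            raise DesignError("interaction requires ownership type in the design")
        cols["government_x_single"] = cols["ownership_government"] * single
        cols["nonprofit_x_single"] = cols["ownership_nonprofit"] * single

    colnames = list(cols)
    X = np.column_stack([cols[c] for c in colnames])
    if check_rank:
        _check_rank(X, colnames)

    y = df["twhss_int"].astype(int).to_numpy()
    if (y < 0).any():
        raise DesignError("negative outcome counts")

    factor_codes: dict[str, np.ndarray] = {}
    factor_levels: dict[str, list] = {}
    mapping = {"state": "state", "hrr": "hrr", "facility": "provider_id"}
    for term in spec.random_terms:
        if term == "obs":
            factor_codes["obs"] = np.arange(len(df))
            factor_levels["obs"] = list(range(len(df)))
        else:
            codes, uniques = pd.factorize(df[mapping[term]], sort=True)
            factor_codes[term] = codes.astype(np.int64)
            factor_levels[term] = list(uniques)

    return DesignBundle(
        y=y,
        X=X,
        colnames=colnames,
        factor_codes=factor_codes,
        factor_levels=factor_levels,
        centering_means=means,
        row_index=df[["provider_id", "date"]].copy(),
    )


def _check_rank(X: np.ndarray, colnames: list[str], tol: float = 1e-8) -> None:
    """Greedy aliasing check: each column regressed on its predecessors."""
    n, p = X.shape
    aliased = []
    Q: list[np.ndarray] = []
    for j in range(p):
        v = X[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        if norm0 == 0:
            aliased.append(colnames[j])
            continue
        for q in Q:
            v = v - (q @ X[:, j]) * q
        if np.linalg.norm(v) < tol * norm0:
            aliased.append(colnames[j])
        else:
            Q.append(v / np.linalg.norm(v))
    if aliased:
        raise DesignError(f"design is rank deficient; aliased columns: {aliased}")


# ---------------------------------------------------------------------------
# Sampler


def _safe_exp(x: np.ndarray) -> np.ndarray:
    return np.exp(np.minimum(x, 50.0))


def _sample_invgamma(rng, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape, 1.0)


def fit_poisson_glmm(bundle: DesignBundle, settings: MCMCSettings) -> PosteriorSamples:
    """Run the adaptive Metropolis-within-Gibbs chain.

    Reproducible for a fixed ``settings.seed``.  Emits effective sample
    size and split-R-hat per fixed effect (via arviz); poor diagnostics
    set ``diagnostics['converged'] = False`` but summaries are still
    produced.

    The chain starts at a cheap mode guess (least squares of log(y + 1/2)
    on X, residual level means for the random intercepts) so short
    burn-ins suffice.  Besides the standard block/per-level moves, each
    grouping factor gets an interweaved fixed-effect proposal in its
    sufficient parameterization: beta moves while that factor's
    intercepts absorb the level-mean shift (u'_k = u_k - xbar_k' step),
    so the likelihood only resists through within-level covariate
    variation.  Without this, coefficients of covariates that barely vary
    within a facility mix at a crawl against the facility intercepts.
    """
    rng = np.random.default_rng(settings.seed)
    y = bundle.y.astype(float)
    X = bundle.X
    n, p = X.shape
    tau = settings.beta_prior_var

    factors = [(name, bundle.factor_codes[name]) for name in bundle.factor_codes]
    n_levels = {name: len(bundle.factor_levels[name]) for name, _ in factors}
    has_intercept = bundle.colnames[0] == "intercept"

    # --- initialization at a rough mode
    z = np.log(y + 0.5)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    u = {}
    sigma2 = {}
    for name, codes in factors:
        nl = n_levels[name]
        if name == "obs":
            u[name] = resid.copy()
            sigma2[name] = max(float(np.var(resid)), 0.02)
            resid = np.zeros(n)
        else:
            cnt = np.bincount(codes, minlength=nl).astype(float)
            means = np.bincount(codes, weights=resid, minlength=nl) / np.maximum(cnt, 1)
            means *= cnt / (cnt + 2.0)  # shrink small levels
            u[name] = means
            sigma2[name] = max(float(np.var(means)), 0.02)
            resid = resid - means[codes]
    a_aux = {name: 1.0 for name, _ in factors}

    eta = X @ beta
    for name, codes in factors:
        eta = eta + u[name][codes]
    exp_eta = _safe_exp(eta)

    Xty = X.T @ y
    sum_y = {name: np.bincount(codes, weights=y, minlength=n_levels[name])
             for name, codes in factors}

    # --- interweaving precomputation (all factors except obs)
    iw_names = [name for name, _ in factors if name != "obs"]
    iw_codes = {name: bundle.factor_codes[name] for name in iw_names}
    Xbar: dict[str, np.ndarray] = {}
    Xc: dict[str, np.ndarray] = {}
    Xcty: dict[str, np.ndarray] = {}
    for name in iw_names:
        codes = iw_codes[name]
        nl = n_levels[name]
        cnt = np.bincount(codes, minlength=nl).astype(float)
        xb = np.vstack(
            [np.bincount(codes, weights=X[:, j], minlength=nl) for j in range(p)]
        ).T / np.maximum(cnt, 1)[:, None]
        Xbar[name] = xb
        Xc[name] = X - xb[codes]
        Xcty[name] = Xc[name].T @ y

    # Columns nearly constant within a few-level factor's levels (the
    # HRR-level covariates, typically) get an exact ridge move: holding
    # v = u + xbar'beta_sub fixed, beta_sub has a Gaussian conditional
    # whose prior terms cancel against the proposal, so acceptance reduces
    # to the tiny within-level likelihood change.  This jumps the
    # beta/u ridge in one draw, where random-walk moves crawl.
    ridge_cols: dict[str, list[int]] = {}
    for name in iw_names:
        tot = np.sum(X**2, axis=0)
        within = np.sum(Xc[name] ** 2, axis=0)
        ridge_cols[name] = [
            j
            for j in range(p)
            if tot[j] > 0 and within[j] < 0.05 * tot[j] and bundle.colnames[j] != "intercept"
        ]
    ridge_S = {name: Xbar[name][:, cols] for name, cols in ridge_cols.items() if cols}
    ridge_StS = {name: S.T @ S for name, S in ridge_S.items()}
    ridge_Xc = {name: Xc[name][:, ridge_cols[name]] for name in ridge_S}
    ridge_Xcty = {name: ridge_Xc[name].T @ y for name in ridge_S}

    # Nested-factor degeneracies (every facility sits in one HRR and one
    # state; every observation in one facility) admit exact Gibbs
    # exchange sweeps: shift a coarse level and compensate all its fine
    # levels, leaving eta untouched — only the two priors vote.  These
    # kill the slow collective modes between intercept layers.
    exchange_pairs: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    for a_name, a_codes in factors:
        for b_name, b_codes in factors:
            if a_name == b_name or n_levels[b_name] <= n_levels[a_name]:
                continue
            parent = _nesting_map(a_codes, b_codes, n_levels[b_name])
            if parent is not None:
                counts_b = np.bincount(parent, minlength=n_levels[a_name]).astype(float)
                exchange_pairs.append((a_name, b_name, parent, counts_b))

    # With an observation-level Gaussian term e, beta has an exact Gibbs
    # draw along the likelihood-invariant manifold v = X beta + e: given
    # v and sigma2_obs, beta | v ~ N((X'X/s2 + I/tau)^-1 X'v/s2, inv),
    # and e absorbs the difference, leaving every Poisson mean untouched.
    has_obs_ridge = "obs" in dict(factors)
    XtX = X.T @ X if has_obs_ridge else None

    # proposal state
    beta_scale = 1.0
    chol_prop = _beta_preconditioner(X, exp_eta, tau)
    iw_scale = {name: 1.0 for name in iw_names}
    iw_chol = {
        name: _interweave_preconditioner(
            Xc[name], Xbar[name], exp_eta, sigma2[name], tau
        )
        for name in iw_names
    }
    u_scales = {name: np.full(n_levels[name], 0.3) for name, _ in factors}
    beta_acc = 0
    beta_tries = 0

    n_kept = settings.n_kept
    beta_draws = np.empty((n_kept, p))
    sigma2_draws = {name: np.empty(n_kept) for name, _ in factors}
    store_u = {
        name: n_levels[name] <= settings.u_store_max_levels for name, _ in factors
    }
    u_draws = {
        name: np.empty((n_kept, n_levels[name])) for name, _ in factors if store_u[name]
    }
    u_sum = {name: np.zeros(n_levels[name]) for name, _ in factors}

    kept = 0
    for it in range(settings.n_iter):
        adapting = it < settings.burn_in

        # ---- fixed-effect block
        if adapting and it % 250 == 0 and it > 0:
            chol_prop = _beta_preconditioner(X, exp_eta, tau)
            for name in iw_names:
                iw_chol[name] = _interweave_preconditioner(
                    Xc[name], Xbar[name], exp_eta, sigma2[name], tau
                )
        for _ in range(settings.n_fixed_subiters):
            z = rng.standard_normal(p)
            step = beta_scale * (chol_prop @ z)
            delta_eta = X @ step
            new_eta = eta + delta_eta
            new_exp = _safe_exp(new_eta)
            log_r = (Xty @ step) - (new_exp.sum() - exp_eta.sum())
            log_r += (np.sum(beta**2) - np.sum((beta + step) ** 2)) / (2.0 * tau)
            beta_tries += 1
            if math.log(rng.uniform()) < log_r:
                beta = beta + step
                eta = new_eta
                exp_eta = new_exp
                beta_acc += 1
                accepted = 1.0
            else:
                accepted = 0.0
            if adapting:
                beta_scale *= math.exp(0.02 * (accepted - 0.25))

        # ---- interweaved fixed-effect moves (sufficient parameterization)
        for name in iw_names:
            z2 = rng.standard_normal(p)
            step = iw_scale[name] * (iw_chol[name] @ z2)
            delta_eta = Xc[name] @ step
            new_eta = eta + delta_eta
            new_exp = _safe_exp(new_eta)
            u_new = u[name] - Xbar[name] @ step
            log_r = (Xcty[name] @ step) - (new_exp.sum() - exp_eta.sum())
            log_r += (np.sum(u[name] ** 2) - np.sum(u_new**2)) / (2.0 * sigma2[name])
            log_r += (np.sum(beta**2) - np.sum((beta + step) ** 2)) / (2.0 * tau)
            if math.log(rng.uniform()) < log_r:
                beta = beta + step
                u[name] = u_new
                eta = new_eta
                exp_eta = new_exp
                acc_iw = 1.0
            else:
                acc_iw = 0.0
            if adapting:
                iw_scale[name] *= math.exp(0.02 * (acc_iw - 0.25))

            # exact ridge draw for the level-quasi-constant columns
            if name in ridge_S:
                cols = ridge_cols[name]
                q = len(cols)
                S = ridge_S[name]
                v = u[name] + S @ beta[cols]
                A = ridge_StS[name] / sigma2[name] + np.eye(q) / tau
                L = np.linalg.cholesky(A)
                mean = np.linalg.solve(A, S.T @ v / sigma2[name])
                beta_new = mean + np.linalg.solve(L.T, rng.standard_normal(q))
                d_sub = beta_new - beta[cols]
                delta_eta = ridge_Xc[name] @ d_sub
                new_eta = eta + delta_eta
                new_exp = _safe_exp(new_eta)
                log_r = ridge_Xcty[name] @ d_sub - (new_exp.sum() - exp_eta.sum())
                if math.log(rng.uniform()) < log_r:
                    beta[cols] = beta_new
                    u[name] = v - S @ beta_new
                    eta = new_eta
                    exp_eta = new_exp

        # ---- exact beta Gibbs along the observation-residual manifold
        if has_obs_ridge:
            v = u["obs"] + X @ beta
            A = XtX / sigma2["obs"] + np.eye(p) / tau
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, X.T @ v / sigma2["obs"])
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            u["obs"] = v - X @ beta
            # eta is unchanged by construction

        # ---- random-effect factors: per-level vectorized RW-MH
        for name, codes in factors:
            nl = n_levels[name]
            deltas = u_scales[name] * rng.standard_normal(nl)
            d_row = deltas[codes]
            new_exp_rows = exp_eta * np.exp(np.minimum(d_row, 50.0))
            dll = (
                deltas * sum_y[name]
                - np.bincount(codes, weights=new_exp_rows - exp_eta, minlength=nl)
                + (u[name] ** 2 - (u[name] + deltas) ** 2) / (2.0 * sigma2[name])
            )
            acc = np.log(rng.uniform(size=nl)) < dll
            if acc.any():
                u[name] = np.where(acc, u[name] + deltas, u[name])
                row_acc = acc[codes]
                eta = eta + np.where(row_acc, d_row, 0.0)
                exp_eta = np.where(row_acc, new_exp_rows, exp_eta)
            if adapting:
                u_scales[name] *= np.exp(0.05 * (acc.astype(float) - 0.44))
                np.clip(u_scales[name], 1e-4, 10.0, out=u_scales[name])

            # recentering sweep along the intercept degeneracy
            if has_intercept:
                prec = nl / sigma2[name] + 1.0 / tau
                mean_m = (-u[name].sum() / sigma2[name] + beta[0] / tau) / prec
                m = mean_m + rng.standard_normal() / math.sqrt(prec)
                u[name] = u[name] + m
                beta[0] -= m

            # conjugate variance update
            ssq = float(np.sum(u[name] ** 2))
            if settings.variance_prior == "halfcauchy":
                sigma2[name] = _sample_invgamma(
                    rng, (nl + 1) / 2.0, ssq / 2.0 + 1.0 / a_aux[name]
                )
                a_aux[name] = _sample_invgamma(
                    rng, 1.0, 1.0 / sigma2[name] + 1.0 / settings.halfcauchy_scale**2
                )
            else:
                sigma2[name] = _sample_invgamma(
                    rng,
                    settings.invgamma_shape + nl / 2.0,
                    settings.invgamma_scale + ssq / 2.0,
                )
            sigma2[name] = max(sigma2[name], 1e-12)

        # ---- exchange sweeps along nested degeneracies (exact Gibbs)
        for a_name, b_name, parent, counts_b in exchange_pairs:
            prec = 1.0 / sigma2[a_name] + counts_b / sigma2[b_name]
            mean_m = (
                -u[a_name] / sigma2[a_name]
                + np.bincount(parent, weights=u[b_name], minlength=counts_b.size)
                / sigma2[b_name]
            ) / prec
            m = mean_m + rng.standard_normal(counts_b.size) / np.sqrt(prec)
            u[a_name] = u[a_name] + m
            u[b_name] = u[b_name] - m[parent]

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            beta_draws[kept] = beta
            for name, _ in factors:
                sigma2_draws[name][kept] = sigma2[name]
                u_sum[name] += u[name]
                if store_u[name]:
                    u_draws[name][kept] = u[name]
            kept += 1

    assert kept == n_kept
    u_mean = {name: u_sum[name] / n_kept for name, _ in factors}
    diagnostics = _chain_diagnostics(beta_draws, bundle.colnames)
    diagnostics["beta_acceptance"] = beta_acc / max(beta_tries, 1)
    if not diagnostics["converged"]:
        logger.warning(
            "chain diagnostics poor (min ESS %.0f, max split-Rhat %.3f); "
            "summaries are flagged",
            diagnostics["min_ess"],
            diagnostics["max_rhat"],
        )
    return PosteriorSamples(
        beta=beta_draws,
        colnames=list(bundle.colnames),
        sigma2=sigma2_draws,
        u_draws=u_draws,
        u_mean=u_mean,
        factor_levels=dict(bundle.factor_levels),
        settings=settings,
        diagnostics=diagnostics,
    )


def _nesting_map(
    a_codes: np.ndarray, b_codes: np.ndarray, n_b: int
) -> np.ndarray | None:
    """Map fine-factor level -> coarse level, or None if not nested."""
    parent = np.full(n_b, -1, dtype=np.int64)
    parent[b_codes] = a_codes
    if (parent == -1).any() or not np.array_equal(parent[b_codes], a_codes):
        return None
    return parent


def _beta_preconditioner(X: np.ndarray, exp_eta: np.ndarray, tau: float) -> np.ndarray:
    """Cholesky factor of the inverse Fisher information (plus prior)."""
    p = X.shape[1]
    info = (X * exp_eta[:, None]).T @ X + np.eye(p) / tau
    # scale 2.4/sqrt(p): classic optimal random-walk scaling
    cov = np.linalg.inv(info) * (2.4**2 / p)
    return np.linalg.cholesky(cov)


def _interweave_preconditioner(
    Xc: np.ndarray,
    Xbar: np.ndarray,
    exp_eta: np.ndarray,
    sigma2_f: float,
    tau: float,
) -> np.ndarray:
    """Proposal Cholesky for the sufficient-parameterization beta move.

    Information there is the within-level Poisson curvature plus the
    random-intercept prior acting through the level means.
    """
    p = Xc.shape[1]
    info = (Xc * exp_eta[:, None]).T @ Xc
    info = info + (Xbar.T @ Xbar) / sigma2_f
    info = info + np.eye(p) / tau
    cov = np.linalg.inv(info) * (2.4**2 / p)
    return np.linalg.cholesky(cov)


def _chain_diagnostics(beta_draws: np.ndarray, colnames: list[str]) -> dict:
    import arviz as az

    ess = {}
    rhat = {}
    k = beta_draws.shape[0]
    half = k // 2
    for j, name in enumerate(colnames):
        # single chain split in two: arviz then yields split-ESS / split-Rhat
        chain = beta_draws[: 2 * half, j].reshape(2, half)
        ess[name] = float(az.ess(chain))
        rhat[name] = float(az.rhat(chain))
    min_ess = min(ess.values())
    max_rhat = max(rhat.values())
    return {
        "ess": ess,
        "rhat": rhat,
        "min_ess": min_ess,
        "max_rhat": max_rhat,
        "converged": bool(min_ess >= 100 and max_rhat <= 1.05),
    }


# ---------------------------------------------------------------------------
# Posterior summaries


def hpdi(samples: Sequence[float], prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ``ceil(prob * n)`` sorted draws.

    Ties on width resolve to the first (lowest) window.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 100:
        raise ValueError(f"HPDI needs at least 100 samples, got {n}")
    m = int(math.ceil(prob * n))
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def pmcmc(samples: Sequence[float]) -> float:
    """Two-sided posterior sign probability, floored at 1/n.

    2 * min(fraction of draws > 0, fraction < 0); a coefficient whose
    draws never change sign reports the floor 1/n (printed as a "<" bound
    by the formatter).
    """
    s = np.asarray(samples, dtype=float)
    n = s.size
    if n < 100:
        raise ValueError(f"pMCMC needs at least 100 samples, got {n}")
    frac_pos = float(np.mean(s > 0))
    frac_neg = float(np.mean(s < 0))
    p = 2.0 * min(frac_pos, frac_neg)
    return min(max(p, 1.0 / n), 1.0)


def format_pmcmc(p: float, n: int) -> str:
    if p <= 1.0 / n:
        return f"<{1.0 / n:g}"
    return f"{p:.3f}"


def compute_icc(
    sigma2_draws: Mapping[str, np.ndarray],
    components: Sequence[str] | None = None,
    distribution_variance: float | np.ndarray | None = None,
    prob: float = 0.95,
) -> pd.DataFrame:
    """Per-draw variance shares, summarized by posterior mean and HPDI.

    The denominator is the sum of all supplied variance components; set
    ``distribution_variance`` to additionally include a Poisson-specific
    distributional variance on the latent scale (excluded by default).
    """
    names = list(components) if components is not None else list(sigma2_draws)
    stack = np.column_stack([np.asarray(sigma2_draws[nm]) for nm in names])
    denom = stack.sum(axis=1)
    if distribution_variance is not None:
        denom = denom + distribution_variance
    rows = []
    for j, nm in enumerate(names):
        icc_draws = stack[:, j] / denom
        lo, hi = hpdi(icc_draws, prob)
        rows.append(
            {
                "component": nm,
                "icc": float(icc_draws.mean()),
                "l95_hpdi": lo,
                "u95_hpdi": hi,
            }
        )
    return pd.DataFrame(rows)


def summarize(samples: PosteriorSamples, prob: float = 0.95) -> PosteriorSummary:
    """Prevalence-ratio tables, ICCs and random-intercept PR exports.

    PR is the exponentiated posterior-mean coefficient; the interval is
    the exponentiated coefficient-scale HPDI (exp is monotone, so the
    bounds map through directly).  Random-intercept PRs (per state, per
    HRR) are exponentiated posterior-mean intercepts — the map-ready
    export.
    """
    n = samples.n_kept
    rows = []
    for j, name in enumerate(samples.colnames):
        draws = samples.beta[:, j]
        lo, hi = hpdi(draws, prob)
        p = pmcmc(draws)
        rows.append(
            {
                "term": name,
                "pr": float(np.exp(draws.mean())),
                "l95_hpdi": float(np.exp(lo)),
                "u95_hpdi": float(np.exp(hi)),
                "pmcmc": p,
                "pmcmc_label": format_pmcmc(p, n),
                "ess": samples.diagnostics.get("ess", {}).get(name, np.nan),
                "rhat": samples.diagnostics.get("rhat", {}).get(name, np.nan),
            }
        )
    fixed = pd.DataFrame(rows)

    icc = compute_icc(samples.sigma2)

    var_rows = []
    for name, draws in samples.sigma2.items():
        lo, hi = hpdi(draws, prob)
        var_rows.append(
            {
                "component": name,
                "variance": float(draws.mean()),
                "l95_hpdi": lo,
                "u95_hpdi": hi,
            }
        )
    variance = pd.DataFrame(var_rows)

    random_pr = {}
    for name, means in samples.u_mean.items():
        if name == "obs":
            continue
        levels = samples.factor_levels[name]
        random_pr[name] = pd.DataFrame(
            {"level": levels, "pr": np.exp(means)}
        )
    return PosteriorSummary(
        fixed=fixed,
        icc=icc,
        variance=variance,
        random_pr=random_pr,
        diagnostics=dict(samples.diagnostics),
    )
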