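"""Gene-wise differential expression with linear mixed models.

Each gene is analyzed individually with its normalized Ca value (or the
two-gene index D) as the response. Colony enters as a random intercept
because fragments of one colony are genetically identical; tank enters
as an additional (crossed) random effect where replicate fragments were
distributed over tanks. Fixed effects are the design factors: treatment,
treatment x time, or site.

Inference methods
-----------------
``auto``        exact paired t where the design is a balanced paired
                two-level comparison with colony as the only random
                factor; REML + Wald contrasts otherwise; plain OLS when
                there is no random factor.
``paired_t``    force the paired-difference estimator.
``reml_wald``   force REML mixed model with Wald z contrasts.
``bootstrap``   seeded parametric-bootstrap likelihood-ratio test
                (single-fixed-factor colony designs), a reproducible
                substitute for sampler-based p-values.

Noise-free inputs (zero residual variance, as in analytic test
fixtures) short-circuit to exact arithmetic instead of degenerate fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import VCSpec
from statsmodels.stats.multitest import multipletests

from .datatypes import CaMatrix, EffectEstimate, FoldChange
from .errors import (
    DegenerateDesignError,
    FittingError,
    InvalidArgumentError,
)

logger = logging.getLogger(__name__)

_ZERO_VAR_TOL = 1e-12


@dataclass(frozen=True)
class DesignSpec:
    """Model design: which factors are fixed, which are random.

    ``interaction=True`` adds the interaction of the two fixed factors
    (treatment x time factorial). ``reference`` optionally pins the
    reference level of a factor; by default 'control', 'offshore' and
    'stress' are used as references where present, otherwise the
    alphabetically first level.
    """

    fixed: tuple[str, ...]
    random: tuple[str, ...] = ()
    interaction: bool = False
    reference: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fixed:
            raise InvalidArgumentError("need at least one fixed factor")
        if self.interaction and len(self.fixed) != 2:
            raise InvalidArgumentError("interaction requires exactly 2 fixed factors")


@dataclass(frozen=True)
class InferenceConfig:
    method: str = "auto"   # auto | paired_t | reml_wald | bootstrap
    n_boot: int = 1000
    seed: int | None = None
    alpha: float = 0.05


#: Named designs matching the preset scenarios.
DESIGNS: dict[str, DesignSpec] = {
    "exp1": DesignSpec(fixed=("treatment",), random=("colony",)),
    "exp2": DesignSpec(fixed=("treatment", "timepoint"), random=("colony",),
                       interaction=True),
    "exp4": DesignSpec(fixed=("treatment",), random=("colony", "tank")),
    "field": DesignSpec(fixed=("site",), random=()),
}

_PREFERRED_REFERENCES = ("control", "offshore", "stress")


def design_for(name: str) -> DesignSpec:
    try:
        return DESIGNS[name]
    except KeyError:
        raise KeyError(f"unknown design {name!r}; known: {sorted(DESIGNS)}") from None


def _reference_level(design: DesignSpec, factor: str, levels: list[str]) -> str:
    if factor in design.reference:
        ref = design.reference[factor]
        if ref not in levels:
            raise InvalidArgumentError(
                f"reference level {ref!r} not observed for factor {factor!r}"
            )
        return ref
    for cand in _PREFERRED_REFERENCES:
        if cand in levels:
            return cand
    return sorted(levels)[0]


def _validate(df: pd.DataFrame, design: DesignSpec, response: str) -> None:
    needed = [response, *design.fixed, *design.random]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"data missing column(s): {missing}")
    for f in design.fixed:
        n_levels = df[f].nunique()
        if n_levels < 2:
            raise DegenerateDesignError(
                f"fixed factor {f!r} has {n_levels} observed level(s); need >= 2"
            )


# ---------------------------------------------------------------------------
# Exact paired-difference estimator
# ---------------------------------------------------------------------------

def _is_balanced_paired(df: pd.DataFrame, design: DesignSpec, response: str) -> bool:
    if design.interaction or len(design.fixed) != 1 or design.random != ("colony",):
        return False
    factor = design.fixed[0]
    if df[factor].nunique() != 2:
        return False
    counts = df.groupby(["colony", factor], observed=True)[response].count()
    wide = counts.unstack(factor)
    return bool((wide == 1).all().all())


def _paired_t(df, design, inference, gene_id, response) -> list[EffectEstimate]:
    factor = design.fixed[0]
    levels = sorted(df[factor].unique())
    ref = _reference_level(design, factor, levels)
    other = [l for l in levels if l != ref][0]
    wide = df.pivot_table(index="colony", columns=factor, values=response)
    diffs = (wide[other] - wide[ref]).dropna().to_numpy()
    n = len(diffs)
    b = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1)) if n > 1 else 0.0
    if sd < _ZERO_VAR_TOL:
        return [_exact_estimate(gene_id, factor, b, n, "paired_t_exact")]
    se = sd / np.sqrt(n)
    t = b / se
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    q = stats.t.ppf(1 - inference.alpha / 2, n - 1)
    return [EffectEstimate(
        gene_id=gene_id, term=factor, B=b, se=se,
        ci_low=b - q * se, ci_high=b + q * se, p=p,
        method="paired_t", n_obs=int(2 * n),
    )]


def _exact_estimate(gene_id, term, b, n, method) -> EffectEstimate:
    p = 0.0 if abs(b) > 1e-9 else 1.0
    return EffectEstimate(
        gene_id=gene_id, term=term, B=float(b), se=0.0,
        ci_low=float(b), ci_high=float(b), p=p, method=method, n_obs=n,
    )


# ---------------------------------------------------------------------------
# Design-matrix construction and Wald-type fits
# ---------------------------------------------------------------------------

def _dummy_columns(df: pd.DataFrame, design: DesignSpec):
    """Numeric design columns (reference-level dummy coding) and the
    contrast map term -> coefficient vector."""
    cols: dict[str, np.ndarray] = {}
    info: dict[str, dict] = {}
    for f in design.fixed:
        levels = sorted(df[f].astype(str).unique())
        ref = _reference_level(design, f, levels)
        non_ref = [l for l in levels if l != ref]
        info[f] = {"ref": ref, "levels": levels, "non_ref": non_ref}
        for l in non_ref:
            name = f"{f}[{l}]" if len(non_ref) > 1 else f
            cols[name] = (df[f].astype(str) == l).to_numpy(float)
            info[f].setdefault("colnames", []).append(name)
    if design.interaction:
        f1, f2 = design.fixed
        if len(info[f1]["non_ref"]) != 1 or len(info[f2]["non_ref"]) != 1:
            raise InvalidArgumentError(
                "factorial designs are supported for two-level factors"
            )
        c1 = info[f1]["colnames"][0]
        c2 = info[f2]["colnames"][0]
        cols[f"{f1}:{f2}"] = cols[c1] * cols[c2]
    names = list(cols)
    X = np.column_stack([np.ones(len(df))] + [cols[c] for c in names])
    xnames = ["Intercept", *names]

    contrasts: dict[str, np.ndarray] = {}

    def unit(name: str) -> np.ndarray:
        v = np.zeros(len(xnames))
        v[xnames.index(name)] = 1.0
        return v

    if design.interaction:
        f1, f2 = design.fixed
        c1 = info[f1]["colnames"][0]
        c2 = info[f2]["colnames"][0]
        ref2 = info[f2]["ref"]
        alt2 = info[f2]["non_ref"][0]
        # treatment contrast within each time point
        contrasts[f"{f1}@{ref2}"] = unit(c1)
        contrasts[f"{f1}@{alt2}"] = unit(c1) + unit(f"{f1}:{f2}")
        # time contrast within the reference treatment
        contrasts[f"{f2}@{info[f1]['ref']}"] = unit(c2)
        contrasts[f"{f1}:{f2}"] = unit(f"{f1}:{f2}")
    else:
        for f in design.fixed:
            for name in info[f]["colnames"]:
                contrasts[name] = unit(name)
    return X, xnames, contrasts


def _wald_estimates(gene_id, params, cov, contrasts, inference, n_obs,
                    method, df_resid=None, boundary=False):
    out = []
    for term, c in contrasts.items():
        b = float(c @ params)
        var = float(c @ cov @ c)
        se = float(np.sqrt(max(var, 0.0)))
        if se < _ZERO_VAR_TOL:
            est = _exact_estimate(gene_id, term, b, n_obs, method + "_exact")
            est.boundary = boundary
            out.append(est)
            continue
        z = b / se
        if df_resid is not None:
            p = float(2.0 * stats.t.sf(abs(z), df_resid))
            q = stats.t.ppf(1 - inference.alpha / 2, df_resid)
        else:
            p = float(2.0 * stats.norm.sf(abs(z)))
            q = stats.norm.ppf(1 - inference.alpha / 2)
        out.append(EffectEstimate(
            gene_id=gene_id, term=term, B=b, se=se,
            ci_low=b - q * se, ci_high=b + q * se, p=p,
            method=method, n_obs=n_obs, boundary=boundary,
        ))
    return out


def _residual_sd_within_cells(df, design, response) -> float:
    group_cols = [*design.fixed, *design.random]
    grouped = df.groupby(group_cols, observed=True)[response]
    counts = grouped.count()
    if (counts <= 1).all():
        return np.nan  # no replication within cells; cannot tell
    ss = float((grouped.transform("mean") - df[response]).pow(2).sum())
    dof = int((counts - 1).sum())
    return np.sqrt(ss / dof) if dof > 0 else np.nan


def _exact_fit(df, design, inference, gene_id, response):
    """Noise-free data: read contrasts off the cell means directly."""
    X, xnames, contrasts = _dummy_columns(df, design)
    # absorb random factors with dummy columns; OLS on noise-free data is exact
    extra = []
    for r in design.random:
        d = pd.get_dummies(df[r].astype(str), drop_first=True).to_numpy(float)
        extra.append(d)
    Xfull = np.column_stack([X] + extra) if extra else X
    beta, *_ = np.linalg.lstsq(Xfull, df[response].to_numpy(float), rcond=None)
    out = []
    for term, c in contrasts.items():
        cfull = np.concatenate([c, np.zeros(Xfull.shape[1] - len(c))])
        b = float(cfull @ beta)
        out.append(_exact_estimate(gene_id, term, b, len(df), "exact"))
    return out


def _fit_ols(df, design, inference, gene_id, response):
    X, xnames, contrasts = _dummy_columns(df, design)
    y = df[response].to_numpy(float)
    res = sm.OLS(y, X).fit()
    if np.sqrt(res.scale) < _ZERO_VAR_TOL:
        return _exact_fit(df, design, inference, gene_id, response)
    return _wald_estimates(
        gene_id, res.params, res.cov_params(), contrasts, inference,
        len(df), "ols", df_resid=res.df_resid,
    )


def _profile_reml(y, X, z_list):
    """REML fit of an LMM with arbitrary crossed random intercepts.

    V(lams) = I + sum_k lam_k Z_k Z_k' (in units of the residual
    variance); for fixed lams the GLS coefficients and the residual
    variance are closed-form, leaving a k-dimensional optimization over
    the variance ratios. Dense linear algebra — these designs have tens
    of samples. Used when the general-purpose optimizer fails on
    boundary fits (a variance component estimated at zero).

    Returns (beta, cov_beta, lams, sigma2).
    """
    y = np.asarray(y, float)
    n, p = X.shape
    G = [Z @ Z.T for Z in z_list]
    k = len(G)

    def reml_parts(lams):
        V = np.eye(n)
        for lam, g in zip(lams, G):
            V += lam * g
        W = np.linalg.inv(V)
        XtWX = X.T @ W @ X
        beta = np.linalg.solve(XtWX, X.T @ W @ y)
        r = y - X @ beta
        sigma2 = max(float(r @ W @ r) / (n - p), 1e-300)
        _, logdet_v = np.linalg.slogdet(V)
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        llf = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                      + logdet_v + logdet_xwx)
        return llf, beta, sigma2, XtWX

    from scipy import optimize

    def neg(u):
        return -reml_parts(np.exp(np.clip(u, -20.0, 20.0)))[0]

    best_u, best_val = None, np.inf
    for start in (-2.0, 0.0, 2.0):
        res = optimize.minimize(
            neg, np.full(k, start), method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000},
        )
        if res.fun < best_val:
            best_val, best_u = res.fun, res.x
    lams = np.exp(np.clip(best_u, -20.0, 20.0))
    # compare against the all-boundary candidate (all variance ratios 0)
    if reml_parts(np.zeros(k))[0] >= -best_val:
        lams = np.zeros(k)
    lams = np.where(lams < 1e-8, 0.0, lams)
    _, beta, sigma2, XtWX = reml_parts(lams)
    cov = sigma2 * np.linalg.inv(XtWX)
    return beta, cov, lams, sigma2


def _fit_mixed(df, design, inference, gene_id, response):
    X, xnames, contrasts = _dummy_columns(df, design)
    y = df[response].to_numpy(float)
    k = X.shape[1]
    params = cov = None
    boundary = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if design.random == ("colony",):
                model = sm.MixedLM(y, X, groups=df["colony"].to_numpy())
            else:
                # crossed random effects (e.g. colony and tank) as variance
                # components within a single group
                mats, names = [], []
                for r in design.random:
                    d = pd.get_dummies(df[r].astype(str)).to_numpy(float)
                    mats.append([d])
                    names.append(r)
                vcs = VCSpec(
                    names=names,
                    colnames=[[f"{r}{i}" for i in range(m[0].shape[1])]
                              for r, m in zip(names, mats)],
                    mats=mats,
                )
                model = sm.MixedLM(y, X, groups=np.ones(len(df)), exog_vc=vcs)
            res = model.fit(reml=True, method=["lbfgs", "bfgs", "cg"])
        params = np.asarray(res.fe_params, dtype=float)
        cov = np.asarray(res.cov_params())[:k, :k]
        if not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov))):
            params = cov = None
        else:
            if design.random == ("colony",):
                boundary = bool(float(np.asarray(res.cov_re).ravel()[0]) < 1e-8)
            elif res.vcomp is not None and len(res.vcomp):
                boundary = bool(np.any(np.asarray(res.vcomp) < 1e-8))
    except Exception:
        params = cov = None
    if params is None:
        # boundary fits (variance components at zero) can defeat the
        # general-purpose optimizer; profile REML is exact for these
        # small designs
        z_list = [pd.get_dummies(df[r].astype(str)).to_numpy(float)
                  for r in design.random]
        try:
            params, cov, lams, _ = _profile_reml(y, X, z_list)
        except Exception as exc:  # pragma: no cover - rare numerical failure
            raise FittingError(
                f"mixed model failed for {gene_id!r}: {exc}"
            ) from exc
        boundary = bool(np.any(lams == 0.0))
    return _wald_estimates(
        gene_id, params, cov, contrasts, inference, len(df),
        "reml_wald", boundary=boundary,
    )


# ---------------------------------------------------------------------------
# Parametric bootstrap LRT (single fixed factor, colony random intercept)
# ---------------------------------------------------------------------------

def _ml_profile(y, X, groups):
    """ML fit of a single-random-intercept LMM by profiling.

    For fixed variance ratio lam = var_colony / var_resid the GLS
    coefficients and the residual variance have closed forms (block
    structure: (I + lam*J)^-1 = I - lam/(1 + lam*n_i) * J per group), so
    the log-likelihood reduces to a 1-D optimization over lam >= 0. This
    avoids Hessian inversions that fail on near-boundary fits.

    Returns (llf, beta, var_colony, var_resid).
    """
    y = np.asarray(y, float)
    n = len(y)
    codes, _ = pd.factorize(groups)
    idx_by_group = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]

    def profile(lam):
        XtWX = np.zeros((X.shape[1], X.shape[1]))
        XtWy = np.zeros(X.shape[1])
        logdet = 0.0
        for idx in idx_by_group:
            Xi, yi = X[idx], y[idx]
            ni = len(idx)
            w = lam / (1.0 + lam * ni)
            XtWX += Xi.T @ Xi - w * np.outer(Xi.sum(0), Xi.sum(0))
            XtWy += Xi.T @ yi - w * Xi.sum(0) * yi.sum()
            logdet += np.log1p(lam * ni)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = 0.0
        for idx in idx_by_group:
            ri = y[idx] - X[idx] @ beta
            ni = len(idx)
            w = lam / (1.0 + lam * ni)
            rss += ri @ ri - w * ri.sum() ** 2
        sigma2 = max(rss / n, 1e-300)
        llf = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
        return llf, beta, sigma2

    from scipy import optimize

    def neg(u):
        return -profile(np.exp(u))[0]

    best = optimize.minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded")
    cand = [(profile(0.0)[0], 0.0), (-best.fun, float(np.exp(best.x)))]
    llf, lam = max(cand)
    _, beta, sigma2 = profile(lam)
    return llf, beta, lam * sigma2, sigma2


def parametric_bootstrap_lrt(
    df: pd.DataFrame,
    design: DesignSpec,
    inference: InferenceConfig,
    response: str = "y",
) -> tuple[float, float]:
    """Seeded parametric-bootstrap likelihood-ratio test of the fixed factor.

    Fits the full and the intercept-only model by ML, simulates
    ``n_boot`` datasets from the fitted null (colony intercepts and
    residuals redrawn at their estimated variances) and returns
    (observed LRT statistic, bootstrap p-value with the +1 correction).
    Implemented for single-fixed-factor designs with colony as the only
    random factor.
    """
    if design.interaction or len(design.fixed) != 1 or design.random != ("colony",):
        raise FittingError(
            "bootstrap inference is implemented for single-factor colony designs"
        )
    if inference.seed is None:
        raise InvalidArgumentError("bootstrap inference requires an explicit seed")
    rng = np.random.default_rng(inference.seed)
    X, _, _ = _dummy_columns(df, design)
    X0 = X[:, :1]
    y = df[response].to_numpy(float)
    groups = df["colony"].to_numpy()
    llf_full, _, _, _ = _ml_profile(y, X, groups)
    llf_null, beta0, var_c, var_e = _ml_profile(y, X0, groups)
    lrt_obs = max(0.0, 2.0 * (llf_full - llf_null))

    mu = float(beta0[0])
    colonies = pd.unique(groups)
    pos = {g: np.flatnonzero(groups == g) for g in colonies}
    exceed = 0
    for _ in range(inference.n_boot):
        ystar = mu + rng.normal(0, np.sqrt(var_e), len(y))
        bdraw = rng.normal(0, np.sqrt(var_c), len(colonies))
        for b, g in zip(bdraw, colonies):
            ystar[pos[g]] += b
        f, _, _, _ = _ml_profile(ystar, X, groups)
        n0, _, _, _ = _ml_profile(ystar, X0, groups)
        if max(0.0, 2.0 * (f - n0)) >= lrt_obs:
            exceed += 1
    p = (1.0 + exceed) / (inference.n_boot + 1.0)
    return lrt_obs, float(p)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def fit_gene_model(
    data: pd.DataFrame,
    design: DesignSpec,
    inference: InferenceConfig | None = None,
    response: str = "y",
    gene_id: str = "",
) -> list[EffectEstimate]:
    """Fit the design's model to one gene's responses.

    ``data`` holds one row per sample with the response column plus the
    metadata columns named by the design. Rows with a missing response
    are dropped (unbalanced data are expected and supported). Returns one
    EffectEstimate per reported term; for the factorial design these are
    the treatment contrast at each time point, the time contrast in
    controls, and the interaction.
    """
    inference = inference or InferenceConfig()
    df = data.dropna(subset=[response]).copy()
    _validate(df, design, response)

    if inference.method == "bootstrap":
        ests = _dispatch(df, design, replace(inference, method="auto"),
                         gene_id, response)
        lrt, p = parametric_bootstrap_lrt(df, design, inference, response)
        for e in ests:
            e.p = p
            e.method = "bootstrap_lrt"
            e.extra["lrt"] = lrt
        return ests
    return _dispatch(df, design, inference, gene_id, response)


def _dispatch(df, design, inference, gene_id, response):
    method = inference.method
    if method == "paired_t" or (
        method == "auto" and _is_balanced_paired(df, design, response)
    ):
        if not _is_balanced_paired(df, design, response):
            raise FittingError("paired_t requires a balanced paired design")
        return _paired_t(df, design, inference, gene_id, response)

    # noise-free fixtures short-circuit to exact arithmetic
    resid_sd = _residual_sd_within_cells(df, design, response)
    if np.isfinite(resid_sd) and resid_sd < 1e-9:
        return _exact_fit(df, design, inference, gene_id, response)

    if not design.random:
        return _fit_ols(df, design, inference, gene_id, response)
    return _fit_mixed(df, design, inference, gene_id, response)


def screen_genes(
    ca: CaMatrix,
    metadata: pd.DataFrame,
    design: DesignSpec,
    inference: InferenceConfig | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Gene-wise screen: fit every gene, BH-adjust p per term across genes.

    Returns a tidy frame (gene_id, term, B, fold, se, ci_low, ci_high,
    p, p_adj, method, boundary); ``fold`` is 2**B.
    """
    genes = list(genes) if genes is not None else list(ca.values.columns)
    rows = []
    for g in genes:
        df = metadata.join(ca.values[g].rename("y"), how="inner")
        for est in fit_gene_model(df, design, inference, response="y", gene_id=g):
            rows.append({
                "gene_id": g, "term": est.term, "B": est.B, "fold": est.fold,
                "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "p": est.p, "method": est.method, "boundary": est.boundary,
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for term, idx in out.groupby("term").groups.items():
        out.loc[idx, "p_adj"] = adjust_fdr(out.loc[idx, "p"].to_numpy())
    return out


def adjust_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(B: float) -> FoldChange:
    """Express a log2 effect as a fold change with direction."""
    b = float(B)
    if not np.isfinite(b):
        raise InvalidArgumentError("B must be finite")
    direction = "up" if b > 0 else ("down" if b < 0 else "none")
    return FoldChange(fold=float(2.0**b), magnitude=float(2.0 ** abs(b)),
                      direction=direction)
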