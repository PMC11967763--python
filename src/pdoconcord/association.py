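"""Pharmacogenomic association models.

Mutation-drug association: per-replicate drug z-scores are regressed on a
per-sample binary mutation status with a per-sample random intercept,

    z_ij = beta0 + beta1 * x_i + u_i + e_ij,   u_i ~ N(0, tau^2), e_ij ~ N(0, sigma^2)

fit by maximum likelihood (not REML, so nested log-likelihoods are
comparable) and tested against the null model without the mutation term by a
likelihood-ratio test on chi-square with 1 df.  The effect size is the
estimated beta1, in vehicle-normalized z-score units per mutated allele
status.

Pathway-drug association: a per-sample pathway activity score (e.g. ssGSEA)
is regressed on the sample's normalized drug AUC by ordinary least squares;
the slope is reported (conventionally labelled OR in heatmaps) with its
t-test p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationDesign",
    "AssociationResult",
    "PathwayAssociation",
    "fit_lmm",
    "mutation_drug_matrix",
    "pathway_drug_model",
    "UnidentifiableDesignError",
]


class UnidentifiableDesignError(ValueError):
    """The design cannot identify the requested effect."""


@dataclass(frozen=True)
class AssociationDesign:
    """Replicate-level design: z-scores, mutation status, sample grouping."""

    z: np.ndarray  # one entry per replicate
    x: np.ndarray  # 0/1 mutation status, expanded to replicates
    sample_id: np.ndarray  # grouping factor, one label per replicate

    def __post_init__(self) -> None:
        z = np.asarray(self.z, float)
        x = np.asarray(self.x, float)
        s = np.asarray(self.sample_id)
        if not (z.shape == x.shape == s.shape) or z.ndim != 1:
            raise ValueError("z, x and sample_id must be equal-length 1-d vectors")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "sample_id", s)
        per_sample = pd.Series(x, index=s).groupby(level=0).first()
        if per_sample.nunique() < 2:
            raise UnidentifiableDesignError(
                "mutation status is constant across samples"
            )
        classes = per_sample.value_counts()
        if (classes < 2).any():
            warnings.warn(
                "fewer than 2 samples in a mutation class; the fixed effect is "
                "weakly identified",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AssociationResult:
    beta1: float
    lrt_stat: float
    p: float
    converged: bool
    n_samples: int
    n_replicates: int
    tau2: float = float("nan")  # random-intercept variance
    message: str = ""


@dataclass(frozen=True)
class PathwayAssociation:
    pathway: str
    or_beta: float  # OLS slope of pathway score on drug AUC
    p: float
    n: int


@dataclass(frozen=True)
class _BoundaryFit:
    """ML solution on the tau^2 = 0 boundary, where the LMM reduces to OLS."""

    fe_params: np.ndarray
    llf: float
    cov_re: np.ndarray
    converged: bool = True


def _ols_ml(z: np.ndarray, X: np.ndarray) -> _BoundaryFit:
    fit = sm.OLS(z, X).fit()
    n = z.size
    sigma2 = fit.ssr / n  # ML, not OLS, variance estimate
    llf = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return _BoundaryFit(fe_params=np.asarray(fit.params), llf=float(llf),
                        cov_re=np.array([[0.0]]))


def _ml_fit(z: np.ndarray, X: np.ndarray, groups: np.ndarray):
    # single-optimizer fits can stall on the tau^2 = 0 boundary below the
    # interior maximum, which would bias the LRT; run two optimizers and keep
    # the better likelihood (fit_lmm additionally guards with the exact
    # boundary solution)
    model = MixedLM(z, X, groups=groups)
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "powell", "cg"):
            try:
                res = model.fit(reml=False, method=method)
            except np.linalg.LinAlgError:
                # singular observed information at the boundary
                continue
            if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
                best = res
            if best is not None and method == "powell":
                break
    if best is not None:
        return best
    # every optimizer failed: the ML solution sits on the boundary
    return _ols_ml(z, X)


def fit_lmm(design: AssociationDesign) -> AssociationResult:
    """Random-intercept LMM of z-scores on mutation status, with LRT p-value.

    Both the full model (intercept + mutation + per-sample random intercept)
    and the null (mutation term dropped) are fit by ML; the LRT statistic is
    2 * (llf_full - llf_null) referred to chi-square with 1 df.  When every
    sample has a single replicate the random intercept is not separable from
    the residual; the fit still runs but a warning is emitted.
    """
    z, x, groups = design.z, design.x, design.sample_id
    counts = pd.Series(groups).value_counts()
    if (counts < 2).all():
        warnings.warn(
            "no sample has >=2 replicates; random intercept and residual "
            "variance are confounded",
            stacklevel=2,
        )
    X_full = np.column_stack([np.ones_like(z), x])
    X_null = X_full[:, :1]
    try:
        full = _ml_fit(z, X_full, groups)
        null = _ml_fit(z, X_null, groups)
        converged = bool(full.converged and null.converged)
        message = ""
    except Exception as e:  # optimizer failure
        return AssociationResult(
            beta1=float("nan"), lrt_stat=float("nan"), p=float("nan"),
            converged=False, n_samples=int(counts.size), n_replicates=int(z.size),
            message=str(e),
        )
    # guard against one model stopping short of its maximum: each model's
    # likelihood is at least its tau^2 = 0 boundary value
    full_b, null_b = _ols_ml(z, X_full), _ols_ml(z, X_null)
    if full_b.llf > full.llf:
        full = full_b
    if null_b.llf > null.llf:
        null = null_b
    lrt = 2.0 * (full.llf - null.llf)
    # small negative values are optimizer noise on a true zero
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return AssociationResult(
        beta1=float(np.asarray(full.fe_params)[1]),
        lrt_stat=float(lrt),
        p=p,
        converged=converged,
        n_samples=int(counts.size),
        n_replicates=int(z.size),
        tau2=float(np.asarray(full.cov_re)[0, 0]),
        message=message,
    )


def mutation_drug_matrix(
    mutations: pd.DataFrame,
    zscores: pd.DataFrame,
    min_per_class: int = 2,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Fit the LMM for every (gene, drug) pair.

    ``mutations``: samples x genes 0/1 frame (index = sample ids).
    ``zscores``: long frame with columns sample, drug, replicate, z.
    Pairs with fewer than ``min_per_class`` samples in either mutation class
    are reported with testable=False rather than dropped.  No multiple-testing
    correction is applied unless ``bh_adjust`` (Benjamini-Hochberg) is set.
    """
    need = {"sample", "drug", "z"}
    if not need <= set(zscores.columns):
        raise ValueError(f"zscores needs columns {sorted(need)}")
    samples = mutations.index.intersection(pd.Index(zscores["sample"].unique()))
    if samples.empty:
        raise ValueError("no overlapping samples between mutations and z-scores")
    zs = zscores[zscores["sample"].isin(samples)]
    rows = []
    for drug, zd in zs.groupby("drug", sort=True):
        for gene in mutations.columns:
            status = mutations.loc[samples, gene]
            x = zd["sample"].map(status).to_numpy(float)
            per_sample = status[status.index.isin(zd["sample"])]
            n0 = int((per_sample == 0).sum())
            n1 = int((per_sample == 1).sum())
            base = {"gene": gene, "drug": drug, "n_wt": n0, "n_mut": n1}
            if min(n0, n1) < min_per_class:
                rows.append({**base, "beta1": np.nan, "lrt": np.nan,
                             "p": np.nan, "converged": False, "testable": False})
                continue
            design = AssociationDesign(
                z=zd["z"].to_numpy(float), x=x, sample_id=zd["sample"].to_numpy()
            )
            r = fit_lmm(design)
            rows.append({**base, "beta1": r.beta1, "lrt": r.lrt_stat, "p": r.p,
                         "converged": r.converged, "testable": True})
    out = pd.DataFrame(rows)
    if bh_adjust:
        out["p_bh"] = np.nan
        mask = out["testable"] & out["p"].notna()
        if mask.any():
            out.loc[mask, "p_bh"] = multipletests(
                out.loc[mask, "p"], method="fdr_bh"
            )[1]
    return out


def pathway_drug_model(
    scores: Sequence[float], auc: Sequence[float], pathway: str = ""
) -> PathwayAssociation:
    """OLS of per-sample pathway score on normalized drug AUC.

    Returns the slope (the heatmap's "OR") and its two-sided t-test p-value.
    """
    scores = np.asarray(scores, float)
    auc = np.asarray(auc, float)
    if scores.shape != auc.shape or scores.ndim != 1:
        raise ValueError("scores and auc must be equal-length vectors")
    if scores.size < 3:
        raise ValueError("need >=3 samples for the pathway model")
    if np.ptp(auc) == 0 or np.var(auc) == 0:
        raise UnidentifiableDesignError("AUC has zero variance; slope unidentifiable")
    X = sm.add_constant(auc)
    fit = sm.OLS(scores, X).fit()
    return PathwayAssociation(
        pathway=pathway,
        or_beta=float(fit.params[1]),
        p=float(fit.pvalues[1]),
        n=int(scores.size),
    )
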