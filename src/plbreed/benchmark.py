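"""Centralized genomic-prediction benchmark.

Marker QC, the VanRaden (method 1) additive relationship matrix, GBLUP
variance-component estimation and prediction, a simplified station mixed
model for genotype BLUPs, and heritability on the trial-mean basis.

The mixed models are fitted by profile REML on Henderson's mixed-model
equations: for variance ratios gamma_k = sigma_k^2 / sigma_e^2 the
coefficient matrix C = [[X'X, X'Z], [Z'X, Z'Z + Gamma^-1]] yields the
restricted log-likelihood up to a constant as

    -2 RL = (n - p) log sigma_e^2 + log|C| + sum_k q_k log gamma_k
            + y'Py / sigma_e^2,

with sigma_e^2 profiled out as y'Py/(n-p).  This is exact for
independent random factors; the correlated GBLUP effect u ~ N(0,
sigma_u^2 K) is folded in by the substitution u = L a with K = L L' and
a ~ N(0, sigma_u^2 I).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

__all__ = [
    "GBLUPModel",
    "HeritabilityEstimate",
    "REMLResult",
    "clean_markers",
    "kinship_vanraden",
    "reml_fit",
    "fit_gblup",
    "predict_gblup",
    "station_blup",
    "heritability",
]


# ---------------------------------------------------------------------------
# Marker QC and kinship
# ---------------------------------------------------------------------------

def clean_markers(
    m: pd.DataFrame, max_missing: float = 0.8, max_het: float = 0.5
) -> pd.DataFrame:
    """Filter SNPs and samples whose missing-call rate exceeds
    ``max_missing`` or whose heterozygosity (dosage == 1) exceeds
    ``max_het``, then impute remaining missing dosages with the SNP mean
    computed on observed calls."""
    if not (0 <= max_missing <= 1 and 0 <= max_het <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    x = m.astype(float)
    isna = x.isna()
    snp_keep = (isna.mean(axis=0) <= max_missing) & (
        (x == 1).sum(axis=0) / (~isna).sum(axis=0).clip(lower=1) <= max_het
    )
    x = x.loc[:, snp_keep]
    isna = x.isna()
    sample_keep = (isna.mean(axis=1) <= max_missing) & (
        ((x == 1).sum(axis=1) / (~isna).sum(axis=1).clip(lower=1)) <= max_het
    )
    x = x.loc[sample_keep]
    if x.shape[1] == 0 or x.shape[0] == 0:
        raise ValueError("marker cleaning removed all SNPs or all samples")
    return x.fillna(x.mean(axis=0))


def kinship_vanraden(m: pd.DataFrame) -> pd.DataFrame:
    """VanRaden method-1 additive relationship matrix
    K = ZZ' / (2 * sum p(1-p)) with Z the dosages centred at twice the
    column allele frequency.  Monomorphic SNPs are dropped with a
    warning."""
    x = m.to_numpy(float)
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic SNPs", stacklevel=2)
    x = x[:, poly]
    p = p[poly]
    if x.shape[1] == 0:
        raise ValueError("no polymorphic SNPs left")
    z = x - 2.0 * p[None, :]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    K = z @ z.T / denom
    return pd.DataFrame(K, index=m.index, columns=m.index)


# ---------------------------------------------------------------------------
# Profile REML on Henderson's mixed-model equations
# ---------------------------------------------------------------------------

@dataclass
class REMLResult:
    beta: np.ndarray
    var_e: float
    var_components: dict[str, float]
    blups: dict[str, np.ndarray]
    reml_loglik: float
    converged: bool


def _neg2_reml(log_gamma: np.ndarray, y, X, Zs, XtX, XtZ, ZtZ, Xty, Zty, yty, q_sizes):
    n, p = X.shape
    gammas = np.exp(log_gamma)
    q_total = sum(q_sizes)
    Ginv = np.concatenate(
        [np.full(q, 1.0 / g) for q, g in zip(q_sizes, gammas)]
    )
    C = np.block([[XtX, XtZ], [XtZ.T, ZtZ + np.diag(Ginv)]])
    rhs = np.concatenate([Xty, Zty])
    try:
        cf = scipy.linalg.cho_factor(C)
    except np.linalg.LinAlgError:
        return 1e30, None
    sol = scipy.linalg.cho_solve(cf, rhs)
    resid_ss = float(yty - sol @ rhs)
    resid_ss = max(resid_ss, 1e-12)
    var_e = resid_ss / (n - p)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    neg2 = (n - p) * np.log(var_e) + logdet_C + float(
        np.sum(np.array(q_sizes) * np.log(gammas))
    ) + resid_ss / var_e
    return neg2, (sol, var_e)


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z_blocks: Mapping[str, np.ndarray],
    start_log_gamma: float = 0.0,
    bounds: tuple[float, float] = (-14.0, 14.0),
) -> REMLResult:
    """Profile-REML fit of a Gaussian mixed model with independent random
    factors ``u_k ~ N(0, sigma_k^2 I)`` (columns of Z_k may encode any
    design, including a kinship square root)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    names = list(Z_blocks)
    Zs = [np.asarray(Z_blocks[k], float) for k in names]
    Z = np.concatenate(Zs, axis=1) if Zs else np.empty((y.size, 0))
    q_sizes = [z.shape[1] for z in Zs]
    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty, yty = X.T @ y, Z.T @ y, float(y @ y)

    def obj(lg):
        val, _ = _neg2_reml(lg, y, X, Zs, XtX, XtZ, ZtZ, Xty, Zty, yty, q_sizes)
        return val

    x0 = np.full(len(names), start_log_gamma)
    res = scipy.optimize.minimize(
        obj, x0, method="L-BFGS-B", bounds=[bounds] * len(names),
        options={"maxiter": 200},
    )
    val, aux = _neg2_reml(res.x, y, X, Zs, XtX, XtZ, ZtZ, Xty, Zty, yty, q_sizes)
    sol, var_e = aux
    p = X.shape[1]
    beta = sol[:p]
    gammas = np.exp(res.x)
    blups: dict[str, np.ndarray] = {}
    offset = p
    var_components: dict[str, float] = {}
    for name, q, g in zip(names, q_sizes, gammas):
        blups[name] = sol[offset:offset + q]
        # ratios pinned at the lower bound are effectively zero variance
        var_components[name] = float(g * var_e) if g > 1.5 * np.exp(bounds[0]) else 0.0
        offset += q
    return REMLResult(
        beta=beta,
        var_e=float(var_e),
        var_components=var_components,
        blups=blups,
        reml_loglik=-0.5 * float(val),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

@dataclass
class GBLUPModel:
    """Fitted GBLUP: y = mu + u + e with u ~ N(0, var_u * K)."""

    mu: float
    var_u: float
    var_e: float
    blups: pd.Series
    train_ids: tuple[str, ...]
    y_train: pd.Series

    @property
    def ratio(self) -> float:
        """lambda = var_e / var_u (infinite when var_u is zero)."""
        return np.inf if self.var_u == 0 else self.var_e / self.var_u


def _psd_sqrt(Kv: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(Kv)
    if vals.min() < -1e-8:
        raise ValueError(f"K is not positive semi-definite (min eigenvalue {vals.min():.3g})")
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)[None, :]


def fit_gblup(y: pd.Series, K: pd.DataFrame, rank_transform: bool = False) -> GBLUPModel:
    """REML fit of the GBLUP model on per-genotype phenotypes.

    ``y`` is indexed by a subset of K's genotypes (n >= 3).  With
    ``rank_transform`` the phenotype is replaced by its ordinal rank
    before fitting, mirroring training on rankings derived from absolute
    values."""
    ids = [i for i in y.index if i in K.index]
    if len(ids) < 3:
        raise ValueError("need phenotypes for at least 3 genotypes present in K")
    yv = y.loc[ids].to_numpy(float)
    if rank_transform:
        yv = scipy.stats.rankdata(yv)
    Ktr = K.loc[ids, ids].to_numpy(float)
    L = _psd_sqrt(Ktr)
    X = np.ones((len(ids), 1))
    res = reml_fit(yv, X, {"g": L})
    u = L @ res.blups["g"]
    if res.var_components["g"] == 0.0:
        u = np.zeros_like(u)
    return GBLUPModel(
        mu=float(res.beta[0]),
        var_u=res.var_components["g"],
        var_e=res.var_e,
        blups=pd.Series(u, index=ids, name="blup"),
        train_ids=tuple(ids),
        y_train=pd.Series(yv, index=ids),
    )


def predict_gblup(model: GBLUPModel, targets: Sequence[str], K: pd.DataFrame) -> pd.Series:
    """Genomic predictions mu + u_hat for target genotypes.

    u_hat(target) = K[target, train] (K[train, train] + lambda I)^-1
    (y_train - mu) at the fitted lambda = var_e / var_u.  A target with a
    zero relatedness row is predicted at the grand mean (flagged with a
    warning)."""
    targets = [str(t) for t in targets]
    missing = [t for t in targets if t not in K.index]
    if missing:
        raise KeyError(f"targets missing from K: {missing}")
    train = list(model.train_ids)
    if model.var_u == 0.0:
        return pd.Series(model.mu, index=targets, name="prediction")
    Ktt = K.loc[train, train].to_numpy(float)
    Kxt = K.loc[targets, train].to_numpy(float)
    lam = model.ratio
    rhs = np.linalg.solve(Ktt + lam * np.eye(len(train)), model.y_train.to_numpy() - model.mu)
    u = Kxt @ rhs
    zero_rows = np.all(np.abs(Kxt) < 1e-12, axis=1)
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} target(s) unrelated to training set; predicted at mu",
            stacklevel=2,
        )
    return pd.Series(model.mu + u, index=targets, name="prediction")


# ---------------------------------------------------------------------------
# Station mixed model and heritability
# ---------------------------------------------------------------------------

def _dummies(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    cats = sorted(map(str, set(labels)))
    idx = {c: j for j, c in enumerate(cats)}
    Z = np.zeros((len(labels), len(cats)))
    for i, lab in enumerate(labels.astype(str)):
        Z[i, idx[lab]] = 1.0
    return Z, cats


def station_blup(
    plots: pd.DataFrame, trait: str = "gy"
) -> tuple[pd.Series, dict[str, float]]:
    """Per-genotype BLUPs from station plot data.

    Simplified station model: environment (location x season cell) fixed,
    genotype and replicate-within-environment random (block-within-
    replicate random too when a ``block`` column is present):

        trait = env + genotype + rep(env) [+ block(rep)] + error

    Returns (BLUPs indexed by genotype, variance components with keys
    ``var_g``, ``var_rep``, ``var_e``[, ``var_block``]).
    """
    required = {"location", "genotype", "replicate", trait}
    if not required.issubset(plots.columns):
        raise ValueError(f"plots table needs columns {sorted(required)}")
    env = plots["location"].astype(str)
    if "season" in plots.columns:
        env = env + ":" + plots["season"].astype(str)
    reps_per_geno = plots.groupby("genotype").size()
    if (reps_per_geno < 2).all():
        raise ValueError("need at least 2 replicates for at least one genotype")
    y = plots[trait].to_numpy(float)
    Xe, _ = _dummies(env)
    X = np.column_stack([np.ones(len(plots)), Xe[:, 1:]])  # env fixed, full rank
    Zg, geno_levels = _dummies(plots["genotype"])
    Zr, _ = _dummies(env + "/" + plots["replicate"].astype(str))
    blocks = {"g": Zg, "rep": Zr}
    if "block" in plots.columns:
        Zb, _ = _dummies(
            env + "/" + plots["replicate"].astype(str) + "/" + plots["block"].astype(str)
        )
        blocks["block"] = Zb
    res = reml_fit(y, X, blocks)
    blups = pd.Series(res.blups["g"], index=geno_levels, name=f"{trait}_blup")
    comps = {
        "var_g": res.var_components["g"],
        "var_rep": res.var_components["rep"],
        "var_e": res.var_e,
    }
    if "block" in blocks:
        comps["var_block"] = res.var_components["block"]
    return blups, comps


def station_oa_means(station_oa: pd.DataFrame, gender: str | None = None) -> pd.DataFrame:
    """Average overall-appreciation scores over raters per plot, optionally
    restricted to one gender; genders are combined by pooling records."""
    df = station_oa if gender is None else station_oa[station_oa["gender"] == gender]
    if df.empty:
        raise ValueError("no OA records after gender filter")
    out = (
        df.groupby(["location", "season", "plot_id", "genotype"], as_index=False)["oa"]
        .mean()
        .rename(columns={"oa": "oa_mean"})
    )
    return out


@dataclass(frozen=True)
class HeritabilityEstimate:
    H2: float
    h2: float | None
    var_components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.H2 <= 1.0):
            raise ValueError("H2 must lie in [0, 1]")
        if self.h2 is not None and not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")


def heritability(
    varcomps: Mapping[str, float],
    n_reps: int,
    n_locs: int = 1,
    genomic_var: float | None = None,
) -> HeritabilityEstimate:
    """Heritability on the trial-mean basis.

    Broad sense: H2 = var_g / (var_g + var_gl/l + var_e/(l*r)) across
    ``l`` locations and ``r`` replicates (per-location estimates drop the
    genotype-by-location term).  Narrow sense replaces the genotypic
    variance in the numerator by the additive genomic (kinship-based)
    variance ``genomic_var``, in the same ratio.
    """
    var_g = float(varcomps.get("var_g", 0.0))
    var_e = float(varcomps.get("var_e", 0.0))
    var_gl = float(varcomps.get("var_gl", 0.0))
    if min(var_g, var_e, var_gl) < 0:
        raise ValueError("variance components must be >= 0")
    denom_rest = (var_gl / n_locs if n_locs > 1 else 0.0) + var_e / (n_locs * n_reps)
    total = var_g + denom_rest
    if total <= 0:
        raise ValueError("total variance is zero; heritability undefined")
    H2 = var_g / total
    h2 = None
    if genomic_var is not None:
        ga = float(genomic_var)
        h2 = min(1.0, ga / (ga + denom_rest)) if (ga + denom_rest) > 0 else 0.0
    return HeritabilityEstimate(H2=H2, h2=h2, var_components=dict(varcomps))
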