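"""Phenotype derivations and phylogenetically corrected regressions.

Relative testes mass (RTM) is observed testes mass divided by the mass
predicted from a power-law allometry ``a * body_mass**b``; the constants are
configuration, sourced from the rodent allometric literature, never baked
in. Overall sperm velocity is the first principal component of the seven
standardised CASA descriptors, oriented so the three main velocity measures
(VCL, VSL, VAP) load positively.

Regression uses phylogenetic generalised least squares: the residual
covariance is the Brownian tip covariance from the tree's branch lengths
with off-diagonal elements multiplied by Pagel's lambda. Lambda is
estimated by profile maximum likelihood on [0, 1] and tested against the
boundary values 0 and 1 by likelihood ratio (chi-square, 1 df). With
multiple predictors the stated order is honoured via sequential (Type I)
sums of squares. Effect sizes are Fisher-z transformed correlations,
``atanh(sqrt(F / (F + df_error)))``, with 95% limits ``+- 1.96/sqrt(n-3)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.decomposition import PCA

from .errors import (
    CollinearityError,
    DegenerateVarianceError,
    SampleSizeError,
    UnitError,
)
from .io_formats import VELOCITY_DESCRIPTORS, PhenotypeTable, Phylogeny

# Velocity descriptors whose loadings define the sign of PC1
_PRINCIPAL_VELOCITIES = ("VCL", "VSL", "VAP")


# ---------------------------------------------------------------------------
# Relative testes mass
# ---------------------------------------------------------------------------

@dataclass
class RelativeTestesMass:
    data: pd.DataFrame  # species, body_mass, testes_mass, predicted, RTM
    a: float
    b: float


def relative_testes_mass(
    body: pd.Series, testes: pd.Series, a: float, b: float
) -> RelativeTestesMass:
    """RTM = observed testes mass / (a * body_mass**b)."""
    body = pd.Series(body, dtype=float)
    testes = pd.Series(testes, dtype=float)
    if (body.dropna() <= 0).any() or (testes.dropna() <= 0).any():
        raise UnitError("body and testes masses must be positive")
    if a <= 0:
        raise UnitError("allometric coefficient a must be positive")
    if b == 0:
        warnings.warn("allometric exponent b=0: predicted mass is constant")
    predicted = a * body**b
    rtm = testes / predicted
    df = pd.DataFrame(
        {
            "species": body.index,
            "body_mass": body.values,
            "testes_mass": testes.values,
            "predicted_testes_mass": predicted.values,
            "RTM": rtm.values,
        }
    )
    return RelativeTestesMass(df, a, b)


# ---------------------------------------------------------------------------
# Velocity PCA
# ---------------------------------------------------------------------------

@dataclass
class VelocityPCA:
    loadings: pd.DataFrame  # descriptors x components
    variance_fractions: np.ndarray
    scores: pd.DataFrame  # species x components; PC1 = overall sperm velocity
    correlations: pd.DataFrame  # descriptor-PC Pearson r and p

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def velocity_pca(table: pd.DataFrame) -> VelocityPCA:
    """Correlation-matrix PCA of the seven CASA descriptors.

    ``table`` is species x descriptors with complete rows. PC1 is oriented
    so the main velocity measures (VCL, VSL, VAP) correlate positively with
    it and is interpreted as overall sperm velocity.
    """
    cols = [c for c in VELOCITY_DESCRIPTORS if c in table.columns]
    data = table[cols].dropna()
    if len(data) < 3:
        raise SampleSizeError("PCA needs at least 3 complete species")
    sd = data.std(ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        raise DegenerateVarianceError(f"constant descriptors: {constant}")
    Z = (data - data.mean()) / sd
    n_comp = min(len(data) - 1, len(cols))
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z.values)
    loadings = pca.components_  # (n_comp, n_desc), rows orthonormal
    # orient PC1 by the principal velocity measures
    names = [f"PC{i + 1}" for i in range(n_comp)]
    for k in range(n_comp):
        key = [c for c in _PRINCIPAL_VELOCITIES if c in cols] if k == 0 else cols
        sign = np.sum([loadings[k, cols.index(c)] for c in key])
        if sign < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    corr_rows = []
    for ci, c in enumerate(cols):
        row = {"descriptor": c}
        for k in range(min(2, n_comp)):
            r, p = stats.pearsonr(Z[c].values, scores[:, k])
            row[f"r_PC{k + 1}"] = r
            row[f"p_PC{k + 1}"] = p
        corr_rows.append(row)
    return VelocityPCA(
        loadings=pd.DataFrame(loadings.T, index=cols, columns=names),
        variance_fractions=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=data.index, columns=names),
        correlations=pd.DataFrame(corr_rows),
    )


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    """One phylogenetic GLS regression with Pagel-lambda covariance."""

    response: str
    predictors: list[str]
    n: int
    df_error: int
    intercept: float
    slopes: dict[str, float]
    r_squared: float
    f_statistic: float  # overall model F
    p_value: float
    sequential: pd.DataFrame  # per-predictor Type-I SS, F, p, ES, CLs
    lam: float
    lnl_lambda: float
    p_lambda_zero: float
    p_lambda_one: float
    es: float
    cl_low: float
    cl_high: float
    species: list[str] = field(default_factory=list)
    _whitened: tuple | None = field(default=None, repr=False)


def _pagel_cov(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _gls_profile(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS fit with sigma^2 profiled out; returns (lnL, beta, rss, yw, Xw)."""
    n = len(y)
    V = V + (1e-10 * np.mean(np.diag(V))) * np.eye(n)  # numerical ridge
    L = linalg.cholesky(V, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise CollinearityError("singular design matrix")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * np.log(np.diag(L)).sum()
    lnl = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return lnl, beta, rss, yw, Xw


def pgls_fit(
    y: pd.Series,
    X: pd.DataFrame,
    tree: Phylogeny,
    lam: str | float = "ML",
    *,
    response_name: str | None = None,
) -> PGLSFit:
    """Phylogenetic GLS of ``y`` on the ordered predictors in ``X``.

    ``lam="ML"`` profiles Pagel's lambda over [0, 1]; a float fixes it.
    Predictors enter in column order and per-predictor F tests use
    sequential (Type I) sums of squares. Species are the shared index of
    ``y``, ``X`` and the tree tips (the tree is pruned as needed).
    """
    common = [s for s in y.index if s in X.index and s in tree.tip_labels()]
    y = y.loc[common].astype(float)
    X = X.loc[common].astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    species = list(y.index[keep])
    if len(species) < len(X.columns) + 2:
        raise SampleSizeError(
            f"only {len(species)} complete species for {len(X.columns)} predictors"
        )
    yv = y.loc[species].values
    Xv = X.loc[species].values
    sub = tree.prune_to(species)
    V = sub.brownian_covariance(species).values
    if not np.all(np.isfinite(V)) or np.any(np.diag(V) <= 0):
        raise ValueError("invalid Brownian covariance (check branch lengths)")
    heights = np.diag(V)
    if np.ptp(heights) > 1e-8 * heights.max():
        warnings.warn("tree is not ultrametric; using raw tip heights")

    n = len(species)
    design = np.column_stack([np.ones(n), Xv])

    def lnl_at(l):
        return _gls_profile(yv, design, _pagel_cov(V, l))[0]

    if lam == "ML":
        res = optimize.minimize_scalar(
            lambda l: -lnl_at(l), bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6},
        )
        candidates = [(lnl_at(0.0), 0.0), (lnl_at(1.0), 1.0), (-res.fun, float(res.x))]
        lnl_hat, lam_hat = max(candidates)
    else:
        lam_hat = float(lam)
        lnl_hat = lnl_at(lam_hat)
    p_l0 = float(stats.chi2.sf(max(0.0, 2 * (lnl_hat - lnl_at(0.0))), 1))
    p_l1 = float(stats.chi2.sf(max(0.0, 2 * (lnl_hat - lnl_at(1.0))), 1))

    Vl = _pagel_cov(V, lam_hat)
    _, beta, rss_full, yw, Xw = _gls_profile(yv, design, Vl)
    p_pred = Xv.shape[1]
    df_error = n - (p_pred + 1)
    if df_error <= 0:
        raise SampleSizeError("no error degrees of freedom")
    mse = rss_full / df_error

    # sequential Type-I sums of squares in the whitened space
    rss_seq = []
    for j in range(p_pred + 1):
        Xj = Xw[:, : j + 1]
        bj, _, _, _ = np.linalg.lstsq(Xj, yw, rcond=None)
        r = yw - Xj @ bj
        rss_seq.append(float(r @ r))
    tss = rss_seq[0]  # intercept-only GLS residual SS
    seq_rows = []
    for j, name in enumerate(X.columns):
        ss = rss_seq[j] - rss_seq[j + 1]
        f = ss / mse
        p = float(stats.f.sf(f, 1, df_error))
        es, lo_, hi_ = effect_size(max(f, 0.0), df_error, n)
        seq_rows.append(
            {
                "predictor": name,
                "SS": ss,
                "F": f,
                "p": p,
                "ES": es,
                "CL_low": lo_,
                "CL_high": hi_,
            }
        )
    ss_model = tss - rss_full
    f_overall = (ss_model / p_pred) / mse
    p_overall = float(stats.f.sf(f_overall, p_pred, df_error))
    r2 = 1.0 - rss_full / tss if tss > 0 else 0.0
    es, cl_lo, cl_hi = effect_size(max(f_overall, 0.0), df_error, n)

    return PGLSFit(
        response=response_name or (y.name or "y"),
        predictors=list(X.columns),
        n=n,
        df_error=df_error,
        intercept=float(beta[0]),
        slopes={name: float(b) for name, b in zip(X.columns, beta[1:])},
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        f_statistic=float(f_overall),
        p_value=p_overall,
        sequential=pd.DataFrame(seq_rows),
        lam=lam_hat,
        lnl_lambda=lnl_hat,
        p_lambda_zero=p_l0,
        p_lambda_one=p_l1,
        es=es,
        cl_low=cl_lo,
        cl_high=cl_hi,
        species=species,
        _whitened=(yw, Xw, beta, mse),
    )


def effect_size(f: float, df_error: int, n: int) -> tuple[float, float, float]:
    """Fisher-z effect size from an F statistic with 1 numerator df.

    r = sqrt(F/(F+df_error)); ES = atanh(r); 95% limits ES +- 1.96/sqrt(n-3).
    """
    if n <= 3:
        raise SampleSizeError("effect-size limits need n > 3")
    if f < 0:
        raise ValueError("F must be non-negative")
    r = np.sqrt(f / (f + df_error))
    es = float(np.arctanh(min(r, 1 - 1e-12)))
    half = 1.96 / np.sqrt(n - 3)
    return es, es - half, es + half


@dataclass
class DiagnosticsReport:
    data: pd.DataFrame  # species, residual, studentized, leverage, flags

    @property
    def flagged(self) -> list[str]:
        return list(self.data.loc[self.data["flagged"], "species"])


def regression_diagnostics(
    fit: PGLSFit,
    *,
    studentized_cutoff: float = 3.0,
    leverage_cutoff: float | None = None,
) -> DiagnosticsReport:
    """GLS studentized residuals and leverage, with outlier flags.

    Defaults: |studentized residual| > 3 or leverage > 2(p+1)/n. Flags are
    a function of the fitted model only, so they are invariant to species
    ordering.
    """
    yw, Xw, beta, mse = fit._whitened
    n, p1 = Xw.shape
    if leverage_cutoff is None:
        leverage_cutoff = 2.0 * p1 / n
    H = Xw @ np.linalg.solve(Xw.T @ Xw, Xw.T)
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
    resid = yw - Xw @ beta
    stud = resid / np.sqrt(mse * (1.0 - h))
    df = pd.DataFrame(
        {
            "species": fit.species,
            "residual": resid,
            "studentized": stud,
            "leverage": h,
        }
    )
    df["flagged"] = (df["studentized"].abs() > studentized_cutoff) | (
        df["leverage"] > leverage_cutoff
    )
    return DiagnosticsReport(df)


# ---------------------------------------------------------------------------
# The full comparative suite
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "dependent", "predictor", "n", "d.f.", "slope", "R2", "F", "P",
    "lambda", "P_lambda0", "P_lambda1", "ES", "CL_low", "CL_high",
    "excluded",
]


def _fit_rows(
    dep_name: str,
    y: pd.Series,
    X: pd.DataFrame,
    tree: Phylogeny,
    excluded: list[str],
) -> list[dict]:
    keep = [s for s in y.index if s not in set(excluded)]
    fit = pgls_fit(
        y.loc[keep], X.loc[[s for s in X.index if s in keep]], tree,
        response_name=dep_name,
    )
    rows = []
    single = len(fit.predictors) == 1
    for _, srow in fit.sequential.iterrows():
        name = srow["predictor"]
        rows.append(
            {
                "dependent": dep_name,
                "predictor": name,
                "n": fit.n,
                "d.f.": fit.df_error,
                "slope": fit.slopes[name],
                "R2": fit.r_squared if (single or name == fit.predictors[0]) else np.nan,
                "F": fit.f_statistic if single else srow["F"],
                "P": fit.p_value if single else srow["p"],
                "lambda": fit.lam,
                "P_lambda0": fit.p_lambda_zero,
                "P_lambda1": fit.p_lambda_one,
                "ES": fit.es if single else srow["ES"],
                "CL_low": fit.cl_low if single else srow["CL_low"],
                "CL_high": fit.cl_high if single else srow["CL_high"],
                "excluded": ",".join(sorted(set(excluded) & set(y.index))),
            }
        )
    return rows


def run_comparative_suite(
    lengths: pd.DataFrame,
    omegas: pd.DataFrame,
    histidines: pd.DataFrame,
    phenotypes: PhenotypeTable,
    tree: Phylogeny,
    config: dict | None = None,
) -> dict[str, object]:
    """Run every regression of the study design and return shaped reports.

    Inputs are per-species frames: ``lengths`` (species, nt_length,
    aa_length), ``omegas`` (species, omega_root_to_tip), ``histidines``
    (species, histidine_proportion). ``config`` keys: ``rtm_a``/``rtm_b``
    (allometry constants), ``length_unit`` ("aa" or "nt") and
    ``exclusions`` — a mapping from analysis group ("omega", "length",
    "velocity", "histidine") to species excluded from that group.
    """
    config = dict(config or {})
    a = float(config.get("rtm_a", 1.0))
    b = float(config.get("rtm_b", 0.77))
    unit = config.get("length_unit", "aa")
    excl = {k: list(v) for k, v in (config.get("exclusions") or {}).items()}

    pheno = phenotypes.data.set_index("species")
    rtm = relative_testes_mass(pheno["body_mass"], pheno["testes_mass"], a, b)
    rtm_s = rtm.data.set_index("species")["RTM"]
    body = pheno["body_mass"]
    testes = pheno["testes_mass"]

    length_col = "aa_length" if unit == "aa" else "nt_length"
    length_s = lengths.set_index("species")[length_col].astype(float)
    omega_s = omegas.set_index("species")["omega_root_to_tip"].astype(float)
    hist_s = histidines.set_index("species")["histidine_proportion"].astype(float)

    vel_raw = pheno[[c for c in VELOCITY_DESCRIPTORS if c in pheno.columns]]
    vel_complete = vel_raw.dropna()
    pca = velocity_pca(vel_complete) if len(vel_complete) >= 3 else None

    def xframe(**cols) -> pd.DataFrame:
        return pd.DataFrame(cols)

    t2_rows: list[dict] = []
    t2_rows += _fit_rows(
        "omega", omega_s, xframe(RTM=rtm_s), tree, excl.get("omega", [])
    )
    t2_rows += _fit_rows(
        "omega", omega_s, xframe(body_mass=body, testes_mass=testes), tree,
        excl.get("omega", []),
    )
    t2_rows += _fit_rows(
        "length", length_s, xframe(RTM=rtm_s), tree, excl.get("length", [])
    )
    t2_rows += _fit_rows(
        "length", length_s, xframe(body_mass=body, testes_mass=testes), tree,
        excl.get("length", []),
    )

    t3_rows: list[dict] = []
    vel_excl = excl.get("velocity", [])
    for c in vel_raw.columns:
        t3_rows += _fit_rows(
            c, vel_raw[c], xframe(length=length_s), tree, vel_excl
        )
    if pca is not None:
        t3_rows += _fit_rows(
            "overall_sperm_velocity", pca.pc1, xframe(length=length_s), tree,
            vel_excl,
        )

    hist_rows: list[dict] = []
    hist_rows += _fit_rows(
        "histidine_proportion", hist_s, xframe(RTM=rtm_s), tree,
        excl.get("histidine", []),
    )
    hist_rows += _fit_rows(
        "histidine_proportion", hist_s, xframe(length=length_s), tree,
        excl.get("histidine", []),
    )

    return {
        "rtm": rtm,
        "pca": pca,
        "table2": pd.DataFrame(t2_rows, columns=REPORT_COLUMNS),
        "table3": pd.DataFrame(t3_rows, columns=REPORT_COLUMNS),
        "histidine": pd.DataFrame(hist_rows, columns=REPORT_COLUMNS),
    }
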