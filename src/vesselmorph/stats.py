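"""Inferential statistics for staged shape and size data.

The module collects the study-level inference machinery:

* distance-based permutation tests (PERMANOVA) on normalized Fourier
  coefficient vectors, quantifying among- vs within-potter shape variation;
* growth-curve models of size over normalized time — third-order
  orthogonal-polynomial fixed effects with optional potter random
  intercepts/slopes — compared by likelihood-ratio tests;
* the Stage linear mixed model on shape-space distances with a potter
  random intercept and per-potter residual variances;
* repeated-measures Community ANOVA with generalized eta-squared, a
  one-way ANOVA reconstructor from published summary statistics, and
  Pearson correlations with Fisher-z confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .lmm import FitError, fit_lmm

__all__ = [
    "PermanovaResult",
    "permanova",
    "orthogonal_polynomials",
    "GrowthCurveModel",
    "LRTResult",
    "likelihood_ratio_test",
    "StageLmmResult",
    "stage_lmm",
    "AnovaResult",
    "community_anova",
    "community_anova_from_summary",
    "oneway_anova_from_summary",
    "pearson_ci",
]


# --------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r_squared_among: float
    r_squared_residual: float
    p_value: float
    df_among: int
    df_residual: int
    n_permutations: int
    exhaustive: bool = False


def _ss_within(D2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> float:
    # sum over groups of (1/n_g) * sum_{i<j in g} d_ij^2
    per_group = np.einsum("ig,ij,jg->g", onehot, D2, onehot) / 2.0
    return float(np.sum(per_group / sizes))


def _n_distinct_relabelings(sizes: np.ndarray) -> int:
    total = math.factorial(int(sizes.sum()))
    for s in sizes:
        total //= math.factorial(int(s))
    return total


def _multiset_assignments(labels_sorted: list):
    """Yield all distinct orderings of a multiset of labels."""
    counts = {}
    for lab in labels_sorted:
        counts[lab] = counts.get(lab, 0) + 1
    n = len(labels_sorted)
    out = [None] * n

    def rec(pos):
        if pos == n:
            yield tuple(out)
            return
        for lab in sorted(counts):
            if counts[lab] > 0:
                counts[lab] -= 1
                out[pos] = lab
                yield from rec(pos + 1)
                counts[lab] += 1

    yield from rec(0)


def permanova(
    features: np.ndarray,
    labels,
    n_permutations: int = 9999,
    seed: int | None = None,
    distance_matrix: bool = False,
    exhaustive_limit: int = 100_000,
) -> PermanovaResult:
    """Distance-based permutation test for among-group differences.

    With Euclidean distances ``d_ij`` (computed from the feature rows, or
    supplied directly as a symmetric matrix), the total sum of squares
    ``SS_T = (1/N) sum_{i<j} d_ij^2`` is partitioned into within-group
    ``SS_W = sum_g (1/n_g) sum_{i<j in g} d_ij^2`` and among-group
    ``SS_A = SS_T - SS_W``; the pseudo-F ratio is
    ``(SS_A / (a-1)) / (SS_W / (N-a))`` and ``R^2 = SS_A / SS_T``.
    Significance comes from whole-row relabelings: exhaustively over all
    distinct label arrangements when their number is at most
    ``exhaustive_limit``, otherwise from ``n_permutations`` random
    permutations with ``p = (1 + #{F* >= F}) / (1 + n_permutations)``.
    """
    labels = np.asarray(labels)
    if distance_matrix:
        D = np.asarray(features, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
            raise ValueError("distance input must be a symmetric square matrix")
        D2 = D**2
    else:
        Xf = np.asarray(features, dtype=float)
        if Xf.ndim == 1:
            Xf = Xf[:, None]
        diff = Xf[:, None, :] - Xf[None, :, :]
        D2 = np.einsum("ijk,ijk->ij", diff, diff)
    N = D2.shape[0]
    if labels.size != N:
        raise ValueError("labels length must match number of observations")
    ulabs, inv = np.unique(labels, return_inverse=True)
    a = len(ulabs)
    sizes = np.bincount(inv)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if np.any(sizes < 2):
        raise ValueError("every group needs at least 2 members")

    onehot = np.zeros((N, a))
    onehot[np.arange(N), inv] = 1.0
    ss_total = float(D2.sum()) / (2.0 * N)
    ss_within = _ss_within(D2, onehot, sizes)
    ss_among = ss_total - ss_within
    df_a, df_r = a - 1, N - a
    F_obs = (ss_among / df_a) / (ss_within / df_r)

    n_total = _n_distinct_relabelings(sizes)
    if n_total <= exhaustive_limit:
        count = 0
        for assign in _multiset_assignments(sorted(inv.tolist())):
            av = np.asarray(assign)
            oh = np.zeros((N, a))
            oh[np.arange(N), av] = 1.0
            ssw = _ss_within(D2, oh, sizes)
            Fp = ((ss_total - ssw) / df_a) / (ssw / df_r)
            if Fp >= F_obs - 1e-12:
                count += 1
        p = count / n_total
        n_perm, exhaustive = n_total, True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        chunk = max(1, min(n_permutations, 2_000_000 // (N * N + 1)))
        done = 0
        while done < n_permutations:
            b = min(chunk, n_permutations - done)
            perms = rng.permuted(np.tile(np.arange(N), (b, 1)), axis=1)
            lab_p = inv[perms]  # (b, N)
            oh = np.zeros((b, N, a))
            bidx = np.repeat(np.arange(b), N)
            nidx = np.tile(np.arange(N), b)
            oh[bidx, nidx, lab_p.ravel()] = 1.0
            per_group = np.einsum("big,ij,bjg->bg", oh, D2, oh) / 2.0
            ssw = (per_group / sizes).sum(axis=1)
            Fp = ((ss_total - ssw) / df_a) / (ssw / df_r)
            count += int(np.sum(Fp >= F_obs - 1e-12))
            done += b
        p = (1 + count) / (1 + n_permutations)
        n_perm, exhaustive = n_permutations, False

    return PermanovaResult(
        pseudo_F=float(F_obs),
        r_squared_among=float(ss_among / ss_total),
        r_squared_residual=float(ss_within / ss_total),
        p_value=float(p),
        df_among=df_a,
        df_residual=df_r,
        n_permutations=n_perm,
        exhaustive=exhaustive,
    )


# --------------------------------------------------------------------------
# growth-curve models


def orthogonal_polynomials(values: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis (degrees 1..degree) over observed values.

    Built by QR decomposition of the Vandermonde matrix on the observed
    values (Gram-Schmidt), excluding the constant column; columns have unit
    norm and a deterministic sign (positive leading coefficient).
    """
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) <= degree:
        raise ValueError("degree must be < number of distinct values")
    V = np.vander(v, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    return Q[:, 1:]


@dataclass(frozen=True)
class LRTResult:
    chi_square: float
    df: int
    p_value: float


def likelihood_ratio_test(reduced, full, tol: float = 1e-4) -> LRTResult:
    """Likelihood-ratio test of nested ML fits.

    The change in deviance ``2 (ll_full - ll_reduced)`` is referred to a
    chi-square with df equal to the difference in free parameters.
    """
    ll_r, ll_f = reduced.loglik_, full.loglik_
    df = full.n_params_ - reduced.n_params_
    if df < 1:
        raise ValueError("full model must have more parameters than reduced")
    chi2 = 2.0 * (ll_f - ll_r)
    if chi2 < -tol * (abs(ll_f) + 1.0):
        raise FitError(
            f"full model log-likelihood ({ll_f:.4f}) below reduced ({ll_r:.4f}); "
            "refit with better starting values"
        )
    chi2 = max(chi2, 0.0)
    return LRTResult(chi_square=float(chi2), df=int(df),
                     p_value=float(sps.chi2.sf(chi2, df)))


class GrowthCurveModel(BaseEstimator):
    """Orthogonal-polynomial growth curve of size over normalized time.

    Fits ``value ~ poly(bin, degree)`` by maximum likelihood with optional
    potter-level random effects:

    * ``random_effects='none'`` — ordinary regression;
    * ``'intercept'`` — potter random intercept;
    * ``'slopes'`` — random intercept plus random slopes on all time
      terms with an unstructured covariance.

    ``community=True`` adds a community fixed effect (main effect plus
    interactions with every time term).

    After ``fit``, exposes ``coef_`` (fixed effects), ``loglik_``,
    ``n_params_``, ``psi_`` (random-effect covariance) and ``sigma2_``.
    """

    def __init__(self, degree: int = 3, random_effects: str = "intercept",
                 community: bool = False):
        self.degree = degree
        self.random_effects = random_effects
        self.community = community

    def _design(self, df: pd.DataFrame):
        bins = df["bin"].to_numpy(dtype=float)
        if len(np.unique(bins)) <= self.degree:
            raise ValueError("degree must be < number of distinct bins")
        # Gram-Schmidt over the *observed* bin values (duplicates included),
        # so columns are orthonormal over the data; store the Vandermonde
        # transform for prediction at new bin values
        V = np.vander(bins, self.degree + 1, increasing=True)
        Q, R = np.linalg.qr(V)
        signs = np.sign(np.diag(R))
        signs[signs == 0] = 1.0
        self._poly_transform_ = np.linalg.inv(signs[:, None] * R)
        P = (V @ self._poly_transform_)[:, 1:]
        cols = [np.ones(len(df))] + [P[:, j] for j in range(self.degree)]
        names = ["intercept"] + [f"time^{j + 1}" for j in range(self.degree)]
        if self.community:
            comm = pd.Categorical(df["community"])
            if len(comm.categories) != 2:
                raise ValueError("community effect requires exactly 2 communities")
            ind = (comm.codes == 1).astype(float)
            cols.append(ind)
            names.append("community")
            for j in range(self.degree):
                cols.append(ind * P[:, j])
                names.append(f"community:time^{j + 1}")
        return np.column_stack(cols), names, P

    def fit(self, df: pd.DataFrame, value_col: str = "esa_cm2"):
        if self.random_effects not in ("none", "intercept", "slopes"):
            raise ValueError("random_effects must be 'none', 'intercept' or 'slopes'")
        df = df.reset_index(drop=True)
        y = df[value_col].to_numpy(dtype=float)
        X, names, P = self._design(df)
        groups = df["potter_id"].to_numpy()
        if self.random_effects == "none":
            Z = None
        elif self.random_effects == "intercept":
            Z = np.ones((len(df), 1))
        else:
            Z = np.column_stack([np.ones(len(df)), P])
        scale = np.std(y) or 1.0
        fit = fit_lmm(y / scale, X, groups, re_design=Z)
        self.scale_ = float(scale)
        self.coef_ = fit.beta * scale
        self.coef_names_ = names
        self.loglik_ = fit.loglik - len(y) * np.log(scale)
        self.n_params_ = fit.n_params
        self.sigma2_ = fit.sigma2 * scale**2
        self.psi_ = None if fit.psi is None else fit.psi * scale**2
        self.converged_ = fit.converged
        self.n_obs_ = fit.n_obs
        self._fit = fit
        return self

    def fixed_curve(self, bins: np.ndarray) -> np.ndarray:
        """Population (fixed-effects) curve evaluated at bin values."""
        b = np.asarray(bins, dtype=float)
        V = np.vander(b, self.degree + 1, increasing=True)
        P = (V @ self._poly_transform_)[:, 1:]
        X = np.column_stack([np.ones(len(b))] + [P[:, j] for j in range(self.degree)])
        return X @ self.coef_[: self.degree + 1]


def fit_growth_model(binned: pd.DataFrame, random_effects: str = "intercept",
                     community: bool = False, value_col: str = "esa_cm2",
                     degree: int = 3) -> GrowthCurveModel:
    """Thin functional wrapper over :class:`GrowthCurveModel`."""
    return GrowthCurveModel(
        degree=degree, random_effects=random_effects, community=community
    ).fit(binned, value_col=value_col)


# --------------------------------------------------------------------------
# Stage linear mixed model on shape-space distances


@dataclass(frozen=True)
class StageLmmResult:
    stage_estimate: float
    F: float
    df_num: int
    df_den: int
    p_value: float
    potter_intercept_sd: float
    stratum_sds: dict
    loglik: float
    n_params: int
    converged: bool


class StageDistanceModel(BaseEstimator):
    """LMM for shape-space distances: fixed Stage effect, potter random
    intercept and a free residual SD per potter stratum.

    The Wald F for the two-level Stage factor uses denominator df
    ``N - n_potters - 1`` (within-potter degrees of freedom after the
    grouping level and the Stage term).
    """

    def __init__(self, heteroscedastic: bool = True, random_intercept: bool = True):
        self.heteroscedastic = heteroscedastic
        self.random_intercept = random_intercept

    def fit(self, df: pd.DataFrame, value_col: str = "distance",
            stage_col: str = "stage", potter_col: str = "potter_id"):
        df = df.reset_index(drop=True)
        stages = pd.Categorical(df[stage_col])
        if len(stages.categories) != 2:
            raise ValueError("stage must be a 2-level factor")
        y = df[value_col].to_numpy(dtype=float)
        x = (stages.codes == 1).astype(float)
        X = np.column_stack([np.ones(len(df)), x])
        potters = df[potter_col].to_numpy()
        counts = pd.crosstab(df[potter_col], df[stage_col])
        if (counts == 0).any().any():
            import warnings

            warnings.warn("unbalanced design: some potter lacks a stage",
                          stacklevel=2)
        scale = np.std(y) or 1.0
        fit = fit_lmm(
            y / scale,
            X,
            potters,
            re_design=np.ones((len(df), 1)) if self.random_intercept else None,
            var_groups=potters if self.heteroscedastic else None,
        )
        n_potters = len(np.unique(potters))
        # small-sample covariance adjustment N/(N - p), as used by the
        # reference mixed-model implementations this mirrors
        adj = fit.n_obs / (fit.n_obs - X.shape[1])
        t = fit.wald_t(1) / np.sqrt(adj)
        df_den = fit.n_obs - n_potters - 1
        self.result_ = StageLmmResult(
            stage_estimate=float(fit.beta[1] * scale),
            F=float(t**2),
            df_num=1,
            df_den=int(df_den),
            p_value=float(sps.f.sf(t**2, 1, df_den)),
            potter_intercept_sd=float(np.sqrt(fit.psi[0, 0]) * scale)
            if fit.psi is not None
            else 0.0,
            stratum_sds={k: v * scale for k, v in fit.stratum_sd.items()},
            loglik=float(fit.loglik - len(y) * np.log(scale)),
            n_params=fit.n_params,
            converged=fit.converged,
        )
        self.loglik_ = self.result_.loglik
        self.n_params_ = self.result_.n_params
        return self


def stage_lmm(df: pd.DataFrame, value_col: str = "distance",
              stage_col: str = "stage", potter_col: str = "potter_id",
              heteroscedastic: bool = True) -> StageLmmResult:
    """Fit the Stage LMM and return its result summary."""
    model = StageDistanceModel(heteroscedastic=heteroscedastic)
    model.fit(df, value_col=value_col, stage_col=stage_col, potter_col=potter_col)
    return model.result_


# --------------------------------------------------------------------------
# ANOVA reconstructions and correlations


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p_value: float
    eta_squared_generalized: float | None = None


def community_anova(df: pd.DataFrame, value_col: str,
                    potter_col: str = "potter_id",
                    community_col: str = "community") -> AnovaResult:
    """Community x Trial repeated-measures ANOVA, between-subjects factor.

    Potters are the subjects (nested in community), trials the repeated
    measures.  The Community F uses the potters-within-community mean
    square as its error term.  Generalized eta-squared treats every
    non-effect sum of squares (potters within community and all
    within-potter variation) as error.
    """
    g = df.groupby([community_col, potter_col])[value_col]
    potter_means = g.mean()
    counts = g.count()
    if counts.nunique() != 1:
        import warnings

        warnings.warn("unbalanced trials per potter; using potter means",
                      stacklevel=2)
    n_trials = int(counts.min())
    comm_of = potter_means.index.get_level_values(0)
    communities = comm_of.unique()
    if len(communities) < 2:
        raise ValueError("need at least 2 communities")
    grand = df[value_col].mean()
    comm_means = potter_means.groupby(level=0).mean()
    n_per_comm = potter_means.groupby(level=0).size()

    ss_comm = float(
        n_trials * sum(n_per_comm[c] * (comm_means[c] - grand) ** 2 for c in communities)
    )
    ss_pw = float(
        n_trials
        * sum((potter_means[c, p] - comm_means[c]) ** 2 for c, p in potter_means.index)
    )
    ss_within = float(((df[value_col] - df.groupby(potter_col)[value_col]
                        .transform("mean")) ** 2).sum())
    df1 = len(communities) - 1
    df2 = len(potter_means) - len(communities)
    F = (ss_comm / df1) / (ss_pw / df2)
    eta = ss_comm / (ss_comm + ss_pw + ss_within)
    return AnovaResult(F=float(F), df1=df1, df2=df2,
                       p_value=float(sps.f.sf(F, df1, df2)),
                       eta_squared_generalized=float(eta))


def community_anova_from_summary(means, cvs, communities, n_per_group: int,
                                 dispersion: str = "cv") -> AnovaResult:
    """Community ANOVA reconstructed from per-potter means and CVs (or SDs).

    Mirrors :func:`community_anova` with within-potter sums of squares
    rebuilt as ``(n-1) * SD^2`` per potter.
    """
    means = np.asarray(means, dtype=float)
    disp = np.asarray(cvs, dtype=float)
    communities = np.asarray(communities)
    sds = disp * means / 100.0 if dispersion == "cv" else disp
    n = n_per_group
    ulabs = pd.unique(communities)
    if len(ulabs) < 2:
        raise ValueError("need at least 2 communities")
    grand = means.mean()  # potter-weighted grand mean
    # grand mean over all trials equals potter-weighted mean (balanced n)
    ss_comm = 0.0
    ss_pw = 0.0
    for c in ulabs:
        m = means[communities == c]
        ss_comm += n * len(m) * (m.mean() - grand) ** 2
        ss_pw += n * ((m - m.mean()) ** 2).sum()
    ss_within = float(((n - 1) * sds**2).sum())
    df1 = len(ulabs) - 1
    df2 = len(means) - len(ulabs)
    F = (ss_comm / df1) / (ss_pw / df2)
    eta = ss_comm / (ss_comm + ss_pw + ss_within)
    return AnovaResult(F=float(F), df1=df1, df2=df2,
                       p_value=float(sps.f.sf(F, df1, df2)),
                       eta_squared_generalized=float(eta))


def oneway_anova_from_summary(means, dispersions, n_per_group: int,
                              dispersion: str = "cv") -> AnovaResult:
    """One-way ANOVA reconstructed from group means and CVs or SDs.

    ``SS_between`` comes from the group means (equal group size n);
    ``SS_within = sum (n-1) SD_g^2`` with ``SD = CV * mean / 100`` when
    CVs are supplied.  df = (a - 1, a (n - 1)).
    """
    means = np.asarray(means, dtype=float)
    disp = np.asarray(dispersions, dtype=float)
    if means.size < 2 or n_per_group < 2:
        raise ValueError("need >= 2 groups and n_per_group >= 2")
    sds = disp * means / 100.0 if dispersion == "cv" else disp
    a, n = means.size, n_per_group
    ss_b = n * ((means - means.mean()) ** 2).sum()
    ss_w = ((n - 1) * sds**2).sum()
    df1, df2 = a - 1, a * (n - 1)
    if ss_w == 0:
        return AnovaResult(F=float("inf"), df1=df1, df2=df2, p_value=0.0)
    F = (ss_b / df1) / (ss_w / df2)
    return AnovaResult(F=float(F), df1=df1, df2=df2,
                       p_value=float(sps.f.sf(F, df1, df2)))


def pearson_ci(x, y, conf: float = 0.95) -> tuple[float, float, float, float]:
    """Pearson r, two-sided p, and Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(x.size - 3)
    zc = sps.norm.ppf(0.5 + conf / 2.0)
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    if r >= 1.0 - 1e-12:  # perfectly linear within float precision
        r, hi = 1.0, 1.0
    elif r <= -1.0 + 1e-12:
        r, lo = -1.0, -1.0
    return float(r), float(p), float(lo), float(hi)
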