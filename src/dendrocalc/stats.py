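"""The study's statistical battery, operating on raw data or printed summaries.

Implements two-tailed one-sample, two-sample (pooled/Welch with an automatic
variance pre-test) and paired Student's t tests, Pearson correlation,
one-way and two-way repeated-measures ANOVA with Mauchly's sphericity test
and Greenhouse-Geisser correction, Holm-Sidak step-down multiple-comparison
adjustment, and the Nernst driving-force shift for an extracellular
concentration change.

Every test accepts either raw per-cell observations or a printed
``(mean, SEM, n)`` summary (:class:`~dendrocalc.ephys.StatSummaryPair`), so
worked examples whose inputs are published summary statistics can be
reproduced exactly.  All p-values are two-tailed; scipy supplies only the
t, F and chi-square distribution functions — the statistics themselves are
computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import helmert
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .ephys import StatSummaryPair

__all__ = [
    "StatResult",
    "one_sample_t",
    "two_sample_t",
    "paired_t",
    "pearson_r",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "mauchly",
    "gg_epsilon",
    "holm_sidak",
    "nernst_shift",
    "t_from_summary",
]

ALPHA = 0.05


@dataclass
class StatResult:
    """Outcome of one hypothesis test.

    ``df`` is a float for t-type tests and a ``(df1, df2)`` pair for F
    tests; degrees of freedom may be non-integer after Welch or
    Greenhouse-Geisser correction (reported as e.g. F(1.6, 6.4)).
    """

    statistic: float
    df: float | tuple[float, float]
    p: float
    test: str
    correction: str = "none"
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")


def _summary(data) -> StatSummaryPair:
    if isinstance(data, StatSummaryPair):
        return data
    x = np.asarray(data, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    return StatSummaryPair(mean=float(x.mean()),
                           sem=float(x.std(ddof=1) / np.sqrt(x.size)),
                           n=int(x.size))


def one_sample_t(data, mu0: float = 0.0) -> StatResult:
    """Two-tailed one-sample Student's t test against ``mu0``.

    ``data`` is raw observations or a (mean, SEM, n) summary; the null
    mean is 0 for baseline-subtracted quantities and 1 (or 100%) for
    normalized ones.
    """
    s = _summary(data)
    if s.sem == 0:
        raise ValueError("zero SEM: t statistic undefined")
    t = (s.mean - mu0) / s.sem
    df = s.n - 1
    return StatResult(statistic=t, df=float(df),
                      p=2.0 * t_dist.sf(abs(t), df), test="one-sample t")


def t_from_summary(mean: float, sem: float, n: int,
                   mu0: float = 0.0) -> StatResult:
    """Convenience wrapper: one-sample t from a printed mean/SEM/n triple."""
    return one_sample_t(StatSummaryPair(mean=mean, sem=sem, n=n), mu0=mu0)


def _variance_pretest(s1: StatSummaryPair, s2: StatSummaryPair) -> float:
    """Two-sided F-ratio test of variance equality; returns the p-value."""
    f = s1.var / s2.var
    d1, d2 = s1.n - 1, s2.n - 1
    p = 2.0 * min(f_dist.sf(f, d1, d2), f_dist.cdf(f, d1, d2))
    return min(p, 1.0)


def two_sample_t(group1, group2, force: str = "auto") -> StatResult:
    """Two-tailed unpaired two-sample t test.

    ``force='auto'`` applies Welch's correction when a two-sided F test
    finds the group variances significantly different at alpha = 0.05;
    ``'pooled'`` and ``'welch'`` override the decision rule.
    """
    s1, s2 = _summary(group1), _summary(group2)
    if s1.sem == 0 and s2.sem == 0:
        raise ValueError("both groups have zero variance")
    if force not in ("auto", "pooled", "welch"):
        raise ValueError("force must be 'auto', 'pooled' or 'welch'")
    use_welch = force == "welch" or (
        force == "auto" and _variance_pretest(s1, s2) < ALPHA)
    diff = s1.mean - s2.mean
    if use_welch:
        se = np.sqrt(s1.sem ** 2 + s2.sem ** 2)
        t = diff / se
        df = se ** 4 / (s1.sem ** 4 / (s1.n - 1) + s2.sem ** 4 / (s2.n - 1))
        corr = "welch"
    else:
        sp2 = (((s1.n - 1) * s1.var + (s2.n - 1) * s2.var)
               / (s1.n + s2.n - 2))
        t = diff / np.sqrt(sp2 * (1.0 / s1.n + 1.0 / s2.n))
        df = s1.n + s2.n - 2
        corr = "none"
    return StatResult(statistic=float(t), df=float(df),
                      p=2.0 * t_dist.sf(abs(t), df),
                      test="two-sample t", correction=corr)


def paired_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-tailed paired t test: one-sample t on the differences vs 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t undefined")
    res = one_sample_t(d, 0.0)
    res.test = "paired t"
    return res


def pearson_r(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson correlation with the t-based two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need paired samples of length >= 3")
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    if denom == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.clip((xm * ym).sum() / denom, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        return StatResult(statistic=r, df=float(df), p=0.0, test="pearson r")
    t = r * np.sqrt(df / (1.0 - r ** 2))
    return StatResult(statistic=r, df=float(df),
                      p=2.0 * t_dist.sf(abs(t), df), test="pearson r")


# --------------------------------------------------------------------------
# repeated-measures machinery


def _contrast_cov(X: np.ndarray) -> np.ndarray:
    """Covariance of orthonormal within-subject contrast scores."""
    k = X.shape[1]
    H = helmert(k, full=False)          # (k-1, k), orthonormal rows
    Y = X @ H.T
    return np.cov(Y, rowvar=False, ddof=1).reshape(k - 1, k - 1)


def mauchly(X: np.ndarray) -> StatResult:
    """Mauchly's test of sphericity for a subjects x levels matrix.

    W is the ratio of the determinant of the contrast covariance to its
    arithmetic-mean-eigenvalue bound; the chi-square approximation uses
    the standard Box correction factor.  With k = 2 levels sphericity
    holds trivially (W = 1, p = 1).
    """
    X = _complete_matrix(X)
    n, k = X.shape
    q = k - 1
    if q < 1:
        raise ValueError("need at least 2 levels")
    if q == 1:
        return StatResult(statistic=1.0, df=0.0, p=1.0, test="mauchly")
    if n <= q:
        raise ValueError("need more subjects than contrasts for Mauchly's test")
    S = _contrast_cov(X)
    eig = np.linalg.eigvalsh(S)
    eig = np.maximum(eig, 0.0)
    mean_eig = eig.mean()
    if mean_eig <= 0:
        raise ValueError("degenerate contrast covariance")
    W = float(np.prod(eig / mean_eig))
    df = q * (q + 1) / 2.0 - 1.0
    box = (2.0 * q ** 2 + q + 2.0) / (6.0 * q * (n - 1.0))
    if W <= 0:
        return StatResult(statistic=0.0, df=df, p=0.0, test="mauchly")
    chi2 = -(n - 1.0) * (1.0 - box) * np.log(W)
    return StatResult(statistic=W, df=df, p=float(chi2_dist.sf(chi2, df)),
                      test="mauchly")


def gg_epsilon(X: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor.

    epsilon-hat = tr(S)^2 / ((k-1) tr(S^2)) on the orthonormal-contrast
    covariance S, clipped to its theoretical range [1/(k-1), 1].
    """
    X = _complete_matrix(X)
    k = X.shape[1]
    q = k - 1
    if q == 1:
        return 1.0
    S = _contrast_cov(X)
    eps = np.trace(S) ** 2 / (q * np.trace(S @ S))
    return float(np.clip(eps, 1.0 / q, 1.0))


def _complete_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a subjects x levels matrix")
    if np.isnan(X).any():
        raise ValueError("missing cells: repeated-measures designs require "
                         "complete cases")
    return X


def rm_anova_oneway(X: np.ndarray, gg: str = "auto") -> StatResult:
    """One-way repeated-measures ANOVA on a subjects x levels matrix.

    The within-subject F is SS_level / SS_residual on (k-1), (n-1)(k-1)
    degrees of freedom.  ``gg='auto'`` applies the Greenhouse-Geisser
    df correction when Mauchly's test rejects sphericity at alpha = 0.05;
    ``'always'`` and ``'never'`` override.
    """
    X = _complete_matrix(X)
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    if gg not in ("auto", "always", "never"):
        raise ValueError("gg must be 'auto', 'always' or 'never'")
    grand = X.mean()
    col = X.mean(axis=0)
    row = X.mean(axis=1)
    ss_level = n * ((col - grand) ** 2).sum()
    resid = X - col[None, :] - row[:, None] + grand
    ss_err = (resid ** 2).sum()
    # sums of squares below numerical resolution are exact zeros
    tiny = 1e-12 * max(((X - grand) ** 2).sum(), np.finfo(float).tiny)
    ss_level = 0.0 if ss_level < tiny else ss_level
    ss_err = 0.0 if ss_err < tiny else ss_err
    df1, df2 = k - 1.0, (n - 1.0) * (k - 1.0)
    if ss_level == 0:
        return StatResult(statistic=0.0, df=(df1, df2), p=1.0,
                          test="rm-anova oneway")
    if ss_err == 0:
        return StatResult(statistic=np.inf, df=(df1, df2), p=0.0,
                          test="rm-anova oneway")
    F = (ss_level / df1) / (ss_err / df2)
    correction, eps = "none", None
    apply_gg = gg == "always" or (gg == "auto" and k > 2
                                  and n > k - 1
                                  and mauchly(X).p < ALPHA)
    if apply_gg:
        eps = gg_epsilon(X)
        df1, df2 = df1 * eps, df2 * eps
        correction = "greenhouse-geisser"
    return StatResult(statistic=float(F), df=(df1, df2),
                      p=float(f_dist.sf(F, df1, df2)),
                      test="rm-anova oneway", correction=correction,
                      epsilon=eps)


def _gg_mixed(groups: Sequence[np.ndarray]) -> float:
    """GG epsilon from the pooled within-group contrast covariance."""
    k = groups[0].shape[1]
    q = k - 1
    if q == 1:
        return 1.0
    H = helmert(k, full=False)
    num = np.zeros((q, q))
    dof = 0
    for g in groups:
        Y = g @ H.T
        if g.shape[0] > 1:
            num += (g.shape[0] - 1) * np.cov(Y, rowvar=False, ddof=1)
            dof += g.shape[0] - 1
    S = num / dof
    eps = np.trace(S) ** 2 / (q * np.trace(S @ S))
    return float(np.clip(eps, 1.0 / q, 1.0))


def _apply_gg(result: StatResult, eps: float) -> StatResult:
    d1, d2 = result.df
    result.df = (d1 * eps, d2 * eps)
    result.p = float(f_dist.sf(result.statistic, *result.df))
    result.correction = "greenhouse-geisser"
    result.epsilon = eps
    return result


def rm_anova_twoway(data, design: str = "mixed",
                    gg: str = "auto") -> dict[str, StatResult]:
    """Two-way ANOVA with a repeated measure, three designs:

    ``design='mixed'``
        Split-plot: ``data`` maps each between-subjects group label to a
        subjects x within-levels matrix.  Returns F for the between
        factor, the within factor and their interaction; within-factor
        terms receive the Greenhouse-Geisser correction when Mauchly's
        test on the pooled contrast covariance rejects.  Group sizes may
        differ (weighted-means decomposition, exact when balanced).
    ``design='within'``
        Both factors repeated: ``data`` is a subjects x a x b array; each
        effect is tested against its own subject-interaction error term.
    ``design='between'``
        No repeated measure (e.g. sex x cell-type): ``data`` maps
        (level_a, level_b) to the replicate values of that cell
        (balanced design expected).
    """
    if design == "mixed":
        return _mixed_anova(data, gg=gg)
    if design == "within":
        return _within2_anova(np.asarray(data, dtype=float), gg=gg)
    if design == "between":
        return _between2_anova(data)
    raise ValueError("design must be 'mixed', 'within' or 'between'")


def _mixed_anova(groups: Mapping[object, np.ndarray],
                 gg: str = "auto") -> dict[str, StatResult]:
    mats = [_complete_matrix(groups[key]) for key in groups]
    k = mats[0].shape[1]
    if any(m.shape[1] != k for m in mats):
        raise ValueError("all groups must share the within-factor levels")
    a = len(mats)
    ns = np.asarray([m.shape[0] for m in mats])
    N = int(ns.sum())
    allx = np.concatenate(mats, axis=0)
    grand = allx.mean()
    subj_means = allx.mean(axis=1)
    group_means = np.asarray([m.mean() for m in mats])
    level_means = allx.mean(axis=0)

    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_a = k * (ns * (group_means - grand) ** 2).sum()
    ss_subj = ss_between_subj - ss_a
    df_a, df_subj = a - 1.0, float(N - a)

    ss_b = N * ((level_means - grand) ** 2).sum()
    ss_ab = 0.0
    ss_err = 0.0
    for m, gm in zip(mats, group_means):
        cell = m.mean(axis=0)
        ss_ab += m.shape[0] * ((cell - gm - level_means + grand) ** 2).sum()
        ss_err += ((m - cell[None, :]
                    - m.mean(axis=1)[:, None] + gm) ** 2).sum()
    df_b = k - 1.0
    df_ab = (a - 1.0) * (k - 1.0)
    df_err = (N - a) * (k - 1.0)

    def fres(ss, df1, ss_e, df2, label):
        if ss_e == 0:
            stat = 0.0 if ss == 0 else np.inf
            return StatResult(statistic=stat, df=(df1, df2),
                              p=1.0 if ss == 0 else 0.0, test=label)
        F = (ss / df1) / (ss_e / df2)
        return StatResult(statistic=float(F), df=(df1, df2),
                          p=float(f_dist.sf(F, df1, df2)), test=label)

    out = {
        "between": fres(ss_a, df_a, ss_subj, df_subj, "mixed-anova between"),
    }
    if k > 1:  # a single within level degenerates to a between-only ANOVA
        out["within"] = fres(ss_b, df_b, ss_err, df_err, "mixed-anova within")
        out["interaction"] = fres(ss_ab, df_ab, ss_err, df_err,
                                  "mixed-anova interaction")
    apply_gg = gg == "always"
    if gg == "auto" and k > 2 and N - a > k - 1:
        pooled = np.concatenate(
            [m - m.mean(axis=0)[None, :] for m in mats], axis=0)
        if mauchly(pooled).p < ALPHA:
            apply_gg = True
    if apply_gg:
        eps = _gg_mixed(mats)
        for key in ("within", "interaction"):
            _apply_gg(out[key], eps)
    return out


def _within2_anova(X: np.ndarray, gg: str = "auto") -> dict[str, StatResult]:
    if X.ndim != 3:
        raise ValueError("fully-within design expects subjects x a x b")
    if np.isnan(X).any():
        raise ValueError("missing cells: repeated-measures designs require "
                         "complete cases")
    n, a, b = X.shape
    grand = X.mean()
    m_s = X.mean(axis=(1, 2))
    m_a = X.mean(axis=(0, 2))
    m_b = X.mean(axis=(0, 1))
    m_ab = X.mean(axis=0)
    m_sa = X.mean(axis=2)
    m_sb = X.mean(axis=1)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_as = b * ((m_sa - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (X - m_ab[None, :, :] - m_sa[:, :, None] - m_sb[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None]
             - grand)
    ss_abs = (resid ** 2).sum()

    def fres(ss, df1, ss_e, df2, label):
        if ss_e == 0:
            stat = 0.0 if ss == 0 else np.inf
            return StatResult(statistic=stat, df=(df1, df2),
                              p=1.0 if ss == 0 else 0.0, test=label)
        F = (ss / df1) / (ss_e / df2)
        return StatResult(statistic=float(F), df=(df1, df2),
                          p=float(f_dist.sf(F, df1, df2)), test=label)

    out = {
        "factor_a": fres(ss_a, a - 1.0, ss_as, (n - 1.0) * (a - 1.0),
                         "rm-anova-2w factor A"),
        "factor_b": fres(ss_b, b - 1.0, ss_bs, (n - 1.0) * (b - 1.0),
                         "rm-anova-2w factor B"),
        "interaction": fres(ss_ab, (a - 1.0) * (b - 1.0), ss_abs,
                            (n - 1.0) * (a - 1.0) * (b - 1.0),
                            "rm-anova-2w interaction"),
    }
    if gg in ("auto", "always"):
        # per-effect GG correction from that effect's own contrast space
        for key, mat, q in (("factor_a", m_sa, a - 1),
                            ("factor_b", m_sb, b - 1)):
            if q < 2 or n <= q:
                continue
            if gg == "always" or mauchly(mat).p < ALPHA:
                _apply_gg(out[key], gg_epsilon(mat))
    return out


def _between2_anova(cells: Mapping[tuple, Sequence[float]]
                    ) -> dict[str, StatResult]:
    levels_a = sorted({key[0] for key in cells})
    levels_b = sorted({key[1] for key in cells})
    a, b = len(levels_a), len(levels_b)
    if a < 2 or b < 2:
        raise ValueError("each factor needs >= 2 levels")
    data = {key: np.asarray(cells[key], dtype=float) for key in cells}
    if len(data) != a * b:
        raise ValueError("all factor-level combinations must be present")
    ns = {key: v.size for key, v in data.items()}
    N = sum(ns.values())
    grand = np.concatenate(list(data.values())).mean()
    mean_ab = {key: v.mean() for key, v in data.items()}

    def wmean(keys):
        tot = sum(ns[key] * mean_ab[key] for key in keys)
        return tot / sum(ns[key] for key in keys)

    m_a = {la: wmean([(la, lb) for lb in levels_b]) for la in levels_a}
    m_b = {lb: wmean([(la, lb) for la in levels_a]) for lb in levels_b}

    ss_a = sum(sum(ns[(la, lb)] for lb in levels_b) * (m_a[la] - grand) ** 2
               for la in levels_a)
    ss_b = sum(sum(ns[(la, lb)] for la in levels_a) * (m_b[lb] - grand) ** 2
               for lb in levels_b)
    ss_ab = sum(ns[key] * (mean_ab[key] - m_a[key[0]] - m_b[key[1]]
                           + grand) ** 2 for key in data)
    ss_err = sum(((v - mean_ab[key]) ** 2).sum() for key, v in data.items())
    df_err = float(N - a * b)

    def fres(ss, df1, label):
        if ss_err == 0:
            stat = 0.0 if ss == 0 else np.inf
            return StatResult(statistic=stat, df=(df1, df_err),
                              p=1.0 if ss == 0 else 0.0, test=label)
        F = (ss / df1) / (ss_err / df_err)
        return StatResult(statistic=float(F), df=(df1, df_err),
                          p=float(f_dist.sf(F, df1, df_err)), test=label)

    return {
        "factor_a": fres(ss_a, a - 1.0, "anova-2w factor A"),
        "factor_b": fres(ss_b, b - 1.0, "anova-2w factor B"),
        "interaction": fres(ss_ab, (a - 1.0) * (b - 1.0),
                            "anova-2w interaction"),
    }


# --------------------------------------------------------------------------


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sort ascending; the i-th smallest p (1-based) becomes
    ``1 - (1 - p)^(m - i + 1)``; enforce monotone non-decreasing adjusted
    values; restore the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D array of p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out


GAS_R = 8.31446261815324          # J mol^-1 K^-1
FARADAY = 96485.33212331          # C mol^-1


def nernst_shift(c_out_1_mM: float, c_out_2_mM: float, z: int = 2,
                 temperature_C: float = 28.0) -> float:
    """Magnitude of the equilibrium-potential shift (mV) for an
    extracellular concentration change ``c1 -> c2`` of an ion of valence
    ``z`` at the given bath temperature.

    |dE| = (R T / z F) |ln(c1 / c2)|.  For the ~10% calcium dilution of a
    -30 mOsm hypoosmotic challenge (2.4 -> 2.16 mM at 28 C) this is about
    1.4 mV, i.e. a negligible change in driving force.
    """
    if c_out_1_mM <= 0 or c_out_2_mM <= 0:
        raise ValueError("concentrations must be positive")
    if z == 0:
        raise ValueError("valence must be non-zero")
    t_K = temperature_C + 273.15
    return float(1000.0 * GAS_R * t_K / (abs(z) * FARADAY)
                 * abs(np.log(c_out_1_mM / c_out_2_mM)))
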