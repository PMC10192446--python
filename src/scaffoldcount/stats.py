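"""Accuracy comparison of cell-counting methods.

Given per-scaffold cell-count estimates from several methods (one of which is
the designated reference), the framework decomposes accuracy into

* **bias** -- signed deviation of each estimate from the *theoretical value*
  (tv, the reference method's mean for that seeding density),
* **dispersion** -- absolute and squared deviation from the method's own mean,
* **overall accuracy** -- absolute and squared deviation from the tv.

Group contrasts for the linear measures use generalized least squares with a
group-specific residual variance (for a saturated one-way design the REML
solution is simply the group means with their n-1 sample variances, so the
contrast beta equals the raw difference of group means); p-values come from a
permutational Welch-type t-test.  The squared measures, whose residuals are
strongly right-skewed, are analyzed with a Gamma GLM (log link) and a
permutational log-mean-ratio test.  P-values are not corrected for multiple
comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import AnalysisError

MEASURES = ("bias", "dev_mean", "sq_dev_mean", "dev_tv", "sq_dev_tv")
_LINEAR_MEASURES = ("bias", "dev_mean", "dev_tv")
_SQUARED_MEASURES = ("sq_dev_mean", "sq_dev_tv")


@dataclass(frozen=True)
class MethodSample:
    """Per-scaffold estimates from one method at one seeding density."""

    method: str
    density: str | int | float
    estimates: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float).ravel()
        object.__setattr__(self, "estimates", est)
        if est.size == 0:
            raise AnalysisError("estimates must be non-empty")
        if (est < 0).any():
            raise AnalysisError("estimates must be >= 0")


@dataclass(frozen=True)
class ContrastResult:
    beta: float
    se: float
    df: float
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class ComparisonResult:
    """One Table-style row: a measure, a contrast, its effect, CI and p."""

    density: str | int | float
    measure: str
    contrast: str
    beta: float
    ci_lower: float
    ci_upper: float
    p: float | None
    n_permutations: int | None
    model: str  # "gls" | "gamma_glm"

    def __post_init__(self) -> None:
        if not self.ci_lower - 1e-12 <= self.beta <= self.ci_upper + 1e-12:
            raise AnalysisError("beta must lie within its confidence interval")
        if self.p is not None and not (0.0 < self.p <= 1.0):
            raise AnalysisError("p must lie in (0, 1]")


def theoretical_value(reference: MethodSample) -> float:
    """The reference method's mean estimate: the per-density 'true' count."""
    return float(np.mean(reference.estimates))


def accuracy_measures(
    samples: Sequence[MethodSample], tv: float
) -> pd.DataFrame:
    """Long-format table: one row per observation x measure.

    bias = x - tv (signed); dev_mean = |x - group mean|; dev_tv = |x - tv|;
    sq_* are the elementwise squares of the absolute measures.  The reference
    group's mean bias is 0 by construction when tv is its own mean.
    """
    rows = []
    for s in samples:
        x = s.estimates
        gm = float(x.mean())
        per = {
            "bias": x - tv,
            "dev_mean": np.abs(x - gm),
            "sq_dev_mean": (x - gm) ** 2,
            "dev_tv": np.abs(x - tv),
            "sq_dev_tv": (x - tv) ** 2,
        }
        for measure, vals in per.items():
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "method": s.method,
                        "density": s.density,
                        "observation": i,
                        "estimate": x[i],
                        "measure": measure,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


class GLSFit:
    """Heteroscedastic one-way GLS: group means with group-specific variances.

    Equivalent to a REML fit of `value ~ group` with a per-group residual
    variance; the contrast of two groups is the raw mean difference with
    standard error sqrt(s_a^2/n_a + s_b^2/n_b) and a Satterthwaite-df t
    confidence interval.
    """

    def __init__(self, values, groups):
        values = np.asarray(values, dtype=float).ravel()
        groups = np.asarray(groups).ravel()
        if values.size != groups.size:
            raise AnalysisError("values and groups must have equal length")
        self.group_labels = list(dict.fromkeys(groups.tolist()))
        if len(self.group_labels) < 2:
            raise AnalysisError("need at least two groups")
        self.n = {}
        self.mean = {}
        self.var = {}
        for g in self.group_labels:
            x = values[groups == g]
            if x.size < 2:
                raise AnalysisError(
                    f"group {g!r} has n < 2; its variance is inestimable"
                )
            self.n[g] = int(x.size)
            self.mean[g] = float(x.mean())
            self.var[g] = float(x.var(ddof=1))

    def contrast(self, a, b, conf_level: float = 0.95) -> ContrastResult:
        """Effect of group ``a`` relative to group ``b`` (beta = mean_a - mean_b)."""
        beta = self.mean[a] - self.mean[b]
        va, vb = self.var[a] / self.n[a], self.var[b] / self.n[b]
        se = float(np.sqrt(va + vb))
        if se == 0.0:
            return ContrastResult(beta, 0.0, np.inf, beta, beta)
        df = (va + vb) ** 2 / (
            va**2 / (self.n[a] - 1) + vb**2 / (self.n[b] - 1)
        )
        tcrit = scipy.stats.t.ppf(0.5 + conf_level / 2, df)
        return ContrastResult(beta, se, float(df), beta - tcrit * se, beta + tcrit * se)

    def group_mean_ci(self, g, conf_level: float = 0.95) -> ContrastResult:
        """A group's own mean with its t-based confidence interval."""
        m = self.mean[g]
        se = float(np.sqrt(self.var[g] / self.n[g]))
        df = self.n[g] - 1
        if se == 0.0:
            return ContrastResult(m, 0.0, df, m, m)
        tcrit = scipy.stats.t.ppf(0.5 + conf_level / 2, df)
        return ContrastResult(m, se, float(df), m - tcrit * se, m + tcrit * se)


def gls_heteroscedastic(values, groups) -> GLSFit:
    """Fit the heteroscedastic one-way GLS (see :class:`GLSFit`)."""
    return GLSFit(values, groups)


@dataclass(frozen=True)
class PermutationTestResult:
    p: float
    statistic: float
    n_permutations: int


def _welch_t(mx, my, vx, vy, nx, ny):
    diff = mx - my
    se = np.sqrt(vx / nx + vy / ny)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    return np.where(se == 0, np.where(diff == 0, 0.0, np.inf), t)


def _student_t(mx, my, vx, vy, nx, ny):
    diff = mx - my
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    return np.where(se == 0, np.where(diff == 0, 0.0, np.inf), t)


def permutation_t_test(
    x,
    y,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    statistic: str = "welch",
) -> PermutationTestResult:
    """Two-sided Monte-Carlo permutation test on the (Welch-type) t statistic.

    Group labels are permuted ``n_perm`` times; the p-value uses the
    add-one estimator p = (#{|t*| >= |t_obs|} + 1) / (n_perm + 1), which is
    never exactly zero.  The Welch statistic (group-specific variances)
    mirrors the heteroscedastic GLS; ``statistic="student"`` pools variances.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise AnalysisError("both samples must be non-empty")
    tfun = {"welch": _welch_t, "student": _student_t}.get(statistic)
    if tfun is None:
        raise AnalysisError(f"unknown statistic {statistic!r}")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return PermutationTestResult(p=1.0, statistic=0.0, n_permutations=n_perm)
    nx, ny = x.size, y.size
    t_obs = float(
        tfun(x.mean(), y.mean(), x.var(ddof=1), y.var(ddof=1), nx, ny)
    )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = np.tile(pooled, (n_perm, 1))
    rng.permuted(mat, axis=1, out=mat)
    gx, gy = mat[:, :nx], mat[:, nx:]
    t_star = tfun(
        gx.mean(axis=1), gy.mean(axis=1),
        gx.var(axis=1, ddof=1), gy.var(axis=1, ddof=1),
        nx, ny,
    )
    tol = 1e-12 * max(1.0, abs(t_obs))
    b = int(np.count_nonzero(np.abs(t_star) >= abs(t_obs) - tol))
    return PermutationTestResult(
        p=(b + 1) / (n_perm + 1), statistic=t_obs, n_permutations=n_perm
    )


@dataclass(frozen=True)
class GammaGLMResult:
    beta_log: float
    se: float
    ci_lower: float
    ci_upper: float
    p: float
    n_permutations: int
    zero_offset: float  # 0.0 when no zeros had to be shifted


def gamma_glm_log(
    values,
    groups,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    baseline=None,
) -> GammaGLMResult:
    """Two-group Gamma GLM with log link, fitted by IRLS (statsmodels).

    ``beta_log`` is the log ratio of the non-baseline group's mean to the
    baseline's (default baseline: first label in order of appearance; for the
    saturated two-group model the IRLS fixed point reproduces the sample
    means exactly).  Zero values -- legal for squared deviations -- are
    shifted by the smallest positive observed value times 1e-3 before the
    fit; the applied offset is reported.  The permutational p-value permutes
    group labels and compares |log mean ratio|.
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) != 2:
        raise AnalysisError("gamma_glm_log expects exactly two groups")
    if baseline is not None:
        if baseline not in labels:
            raise AnalysisError(f"baseline {baseline!r} not among group labels")
        labels = [baseline] + [l for l in labels if l != baseline]
    if (values < 0).any():
        raise AnalysisError("values must be >= 0")
    offset = 0.0
    if (values == 0).any():
        positive = values[values > 0]
        if positive.size == 0:
            raise AnalysisError("all values are zero; Gamma GLM undefined")
        offset = float(positive.min() * 1e-3)
        values = np.where(values == 0, offset, values)

    ind = (groups == labels[1]).astype(float)
    X = sm.add_constant(ind)
    fit = sm.GLM(
        values, X, family=sm.families.Gamma(link=sm.families.links.Log())
    ).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    ci = fit.conf_int()
    ci_l, ci_u = float(ci[1][0]), float(ci[1][1])

    # permutation on the closed-form statistic |log(mean ratio)|
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = int(np.count_nonzero(ind == 0))
    obs = abs(np.log(values[ind == 1].mean() / values[ind == 0].mean()))
    order = np.argsort(ind, kind="stable")  # group-0 values first
    pooled = values[order]
    mat = np.tile(pooled, (n_perm, 1))
    rng.permuted(mat, axis=1, out=mat)
    stat = np.abs(np.log(mat[:, n1:].mean(axis=1) / mat[:, :n1].mean(axis=1)))
    tol = 1e-12 * max(1.0, obs)
    b = int(np.count_nonzero(stat >= obs - tol))
    return GammaGLMResult(
        beta_log=beta,
        se=se,
        ci_lower=ci_l,
        ci_upper=ci_u,
        p=(b + 1) / (n_perm + 1),
        n_permutations=n_perm,
        zero_offset=offset,
    )


@dataclass(frozen=True)
class DiagnosticsResult:
    shapiro_statistic: float
    shapiro_p: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray


def residual_diagnostics(residuals) -> DiagnosticsResult:
    """Shapiro-Wilk test and Q-Q data on standardized residuals.

    Accepts a raw residual vector or any fitted model exposing ``resid`` /
    ``resid_response`` (e.g. a statsmodels GLM fit).
    """
    for attr in ("resid_response", "resid"):
        if hasattr(residuals, attr):
            residuals = getattr(residuals, attr)
            break
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size < 3:
        raise AnalysisError("need at least 3 residuals")
    sd = r.std(ddof=1)
    if sd == 0:
        raise AnalysisError("constant residuals: normality is undefined")
    z = (r - r.mean()) / sd
    stat, p = scipy.stats.shapiro(z)
    (osm, osr), _ = scipy.stats.probplot(z, dist="norm")
    return DiagnosticsResult(
        shapiro_statistic=float(stat),
        shapiro_p=float(p),
        qq_theoretical=osm,
        qq_sample=osr,
    )


def compare_methods(
    samples: Sequence[MethodSample],
    reference_label: str,
    n_perm: int = 5000,
    seed: int = 0,
    in_thousands: bool = False,
) -> list[ComparisonResult]:
    """Full per-density accuracy comparison against a reference method.

    For every density: the tv is the reference mean; each measure is compared
    for every candidate-vs-reference and candidate-vs-candidate contrast.
    Linear measures use the heteroscedastic GLS contrast with a permutational
    Welch t p-value; squared measures use the Gamma GLM (log link).  The
    reference's own mean of each measure is reported as a summary row (no p).
    ``in_thousands`` rescales the linear betas/CIs by 1000 for reporting;
    Gamma-GLM effects are log ratios and are never rescaled.
    """
    methods_by_density: dict = {}
    for s in samples:
        methods_by_density.setdefault(s.density, []).append(s)
    rng = np.random.default_rng(seed)
    out: list[ComparisonResult] = []
    for density, group in methods_by_density.items():
        labels = [s.method for s in group]
        if reference_label not in labels:
            raise AnalysisError(
                f"reference {reference_label!r} absent at density {density!r}"
            )
        by_label = {s.method: s for s in group}
        tv = theoretical_value(by_label[reference_label])
        table = accuracy_measures(group, tv)
        others = [m for m in labels if m != reference_label]
        contrasts = [(c, reference_label) for c in others]
        contrasts += list(itertools.combinations(others, 2))
        scale = 1e-3 if in_thousands else 1.0
        for measure in MEASURES:
            sub = table[table.measure == measure]
            vals = sub.value.to_numpy()
            grps = sub.method.to_numpy()
            if measure in _LINEAR_MEASURES:
                fit = gls_heteroscedastic(vals, grps)
                ref_ci = fit.group_mean_ci(reference_label)
                out.append(
                    ComparisonResult(
                        density=density,
                        measure=measure,
                        contrast=f"Reference ({reference_label})",
                        beta=ref_ci.beta * scale,
                        ci_lower=ref_ci.ci_lower * scale,
                        ci_upper=ref_ci.ci_upper * scale,
                        p=None,
                        n_permutations=None,
                        model="gls",
                    )
                )
                for a, b in contrasts:
                    con = fit.contrast(a, b)
                    perm = permutation_t_test(
                        vals[grps == a], vals[grps == b], n_perm=n_perm, seed=rng
                    )
                    out.append(
                        ComparisonResult(
                            density=density,
                            measure=measure,
                            contrast=f"{a} vs. {b}",
                            beta=con.beta * scale,
                            ci_lower=con.ci_lower * scale,
                            ci_upper=con.ci_upper * scale,
                            p=perm.p,
                            n_permutations=n_perm,
                            model="gls",
                        )
                    )
            else:
                for a, b in contrasts:
                    sel = (grps == a) | (grps == b)
                    res = gamma_glm_log(
                        vals[sel],
                        grps[sel],
                        n_perm=n_perm,
                        seed=rng,
                        baseline=b,  # beta_log = log(mean_a / mean_b)
                    )
                    out.append(
                        ComparisonResult(
                            density=density,
                            measure=measure,
                            contrast=f"{a} vs. {b}",
                            beta=res.beta_log,
                            ci_lower=res.ci_lower,
                            ci_upper=res.ci_upper,
                            p=res.p,
                            n_permutations=n_perm,
                            model="gamma_glm",
                        )
                    )
    return out


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "density": [r.density for r in results],
            "measure": [r.measure for r in results],
            "contrast": [r.contrast for r in results],
            "beta": [r.beta for r in results],
            "ci_lower": [r.ci_lower for r in results],
            "ci_upper": [r.ci_upper for r in results],
            "p": [np.nan if r.p is None else r.p for r in results],
            "n_permutations": [r.n_permutations for r in results],
            "model": [r.model for r in results],
        }
    )


def plot_method_estimates(
    samples: Sequence[MethodSample], path, tv: float | None = None
) -> None:
    """Strip-plot of per-scaffold estimates by method (one density)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.5 * len(samples) + 2, 4))
    rng = np.random.default_rng(0)
    for i, s in enumerate(samples):
        jitter = rng.uniform(-0.12, 0.12, s.estimates.size)
        ax.plot(i + jitter, s.estimates / 1e3, "o", alpha=0.6)
        ax.hlines(s.estimates.mean() / 1e3, i - 0.25, i + 0.25, color="k")
    if tv is not None:
        ax.axhline(tv / 1e3, color="r", ls="--", lw=1, label="theoretical value")
        ax.legend(frameon=False)
    ax.set_xticks(range(len(samples)), [s.method for s in samples])
    ax.set_ylabel("estimated cells per scaffold (thousands)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
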