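"""Auxiliary statistics: KS normality, Pearson correlation (ordinary and
through-origin), regression residual diagnostics, and the species × sex
fixed-effects ANOVA on individual body sizes."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from ._errors import DegenerateInputError, InsufficientDataError
from .allometry import RegressionFit


@dataclass(frozen=True)
class TestResult:
    """One named test statistic with its p-value."""

    name: str
    statistic: float
    p_value: float
    n: int
    two_tailed: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def ks_normality(values, lilliefors: bool = False) -> TestResult:
    """One-sample Kolmogorov–Smirnov test against a fitted normal.

    Reports Z = √n · D with the asymptotic two-tailed Kolmogorov p-value,
    the convention of classic statistics packages, with the normal's mean
    and SD estimated from the sample.  Because parameters are estimated,
    this p-value is conservative; ``lilliefors=True`` switches to the
    Lilliefors-corrected p (statsmodels) while still reporting Z.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 5 or not np.all(np.isfinite(values)):
        raise InsufficientDataError(f"need >= 5 finite values, got {n}")
    sd = values.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("sample standard deviation is zero")
    d_stat = stats.kstest(values, "norm", args=(values.mean(), sd)).statistic
    z = float(np.sqrt(n) * d_stat)
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(values, dist="norm")
        note = "Lilliefors-corrected p; Z = sqrt(n)*D"
    else:
        p = float(special.kolmogorov(z))
        note = (
            "asymptotic Kolmogorov p with mean/SD estimated from the sample "
            "(no Lilliefors correction); conservative"
        )
    return TestResult(
        name="ks_normality", statistic=z, p_value=min(float(p), 1.0), n=n, notes=note
    )


def pearson(x, y, through_origin: bool = False) -> TestResult:
    """Pearson correlation with a two-tailed t-test.

    ``through_origin=True`` computes the uncentred correlation
    r₀ = Σxy / √(Σx²·Σy²) with n-1 degrees of freedom — the appropriate
    statistic for independent contrasts, whose signs are arbitrary (the
    statistic is invariant to jointly flipping the sign of any pair).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {n}")
    if through_origin:
        sxx = float(np.dot(x, x))
        syy = float(np.dot(y, y))
        if sxx == 0.0 or syy == 0.0:
            raise DegenerateInputError("zero sum of squares in x or y")
        r = float(np.dot(x, y) / np.sqrt(sxx * syy))
        df = n - 1
        name = "pearson_through_origin"
    else:
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            raise DegenerateInputError("zero variance in x or y")
        r = float(stats.pearsonr(x, y).statistic)
        df = n - 2
        name = "pearson"
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(name=name, statistic=r, p_value=p, n=n)


def residual_diagnostics(fit: RegressionFit, x, y) -> list[TestResult]:
    """Heteroscedasticity screen and residual normality for a fitted line.

    Returns (a) the Pearson correlation between the *absolute* residuals
    and the fitted values — least-squares residuals are orthogonal to
    fitted values by construction, so only their magnitude carries
    heteroscedasticity information — and (b) a KS normality test of the
    residuals.  A residual vector that is numerically zero (perfect fit)
    is reported as a degenerate screen rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fitted = fit.predict(x)
    resid = y - fitted
    out: list[TestResult] = []
    scale = max(float(np.max(np.abs(y))), 1.0)
    if np.ptp(resid) <= 1e-12 * scale or np.ptp(fitted) == 0.0:
        out.append(
            TestResult(
                name="heteroscedasticity_screen",
                statistic=0.0,
                p_value=1.0,
                n=x.size,
                notes="degenerate: residuals (or fitted values) are constant",
            )
        )
    else:
        res = pearson(np.abs(resid), fitted)
        out.append(
            TestResult(
                name="heteroscedasticity_screen",
                statistic=res.statistic,
                p_value=res.p_value,
                n=res.n,
                notes="Pearson r between |residuals| and fitted values",
            )
        )
    try:
        out.append(ks_normality(resid))
    except DegenerateInputError:
        out.append(
            TestResult(
                name="ks_normality",
                statistic=0.0,
                p_value=1.0,
                n=x.size,
                notes="degenerate: residuals constant",
            )
        )
    return out


@dataclass
class AnovaResult:
    """ANOVA table (terms × [sum_sq, df, F, PR(>F)]) plus fitting notes."""

    table: pd.DataFrame
    ss_type: int
    notes: list[str] = field(default_factory=list)


def species_sex_glm(
    individuals: pd.DataFrame, ss_type: int = 1
) -> AnovaResult:
    """Fixed-effects ANOVA of body size on species, sex and their interaction.

    ``individuals`` needs columns ``species``, ``sex``, ``body_size``.
    Unbalanced designs use sequential (Type I) sums of squares by
    default; Type II is available.  If any species was sampled in one sex
    only, the interaction is inestimable and the model is refit without
    it (noted in the result).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    required = {"species", "sex", "body_size"}
    missing = required - set(individuals.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = individuals.copy()
    df["species"] = df["species"].astype(str)
    df["sex"] = df["sex"].astype(str)
    notes: list[str] = []

    n_species = df["species"].nunique()
    if n_species < 2:
        notes.append(
            "single species: species term dropped; reduces to a two-sample "
            "comparison between sexes"
        )
        formula = "body_size ~ C(sex)"
    else:
        cells = df.groupby("species")["sex"].nunique()
        one_sex = sorted(cells[cells < 2].index)
        if one_sex:
            notes.append(
                f"species sampled in one sex only ({one_sex}): interaction "
                "term inestimable, refit without it"
            )
            formula = "body_size ~ C(species) + C(sex)"
        else:
            formula = "body_size ~ C(species) + C(sex) + C(species):C(sex)"
    model = smf.ols(formula, data=df).fit()
    table = anova_lm(model, typ=ss_type)
    return AnovaResult(table=table, ss_type=ss_type, notes=notes)
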