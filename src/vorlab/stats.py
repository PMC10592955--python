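"""Statistical reporting for cohort learning tables.

A cohort table is tidy: one row per (animal, block time) with columns
``animal_id, genotype, block_time_min, delta_pct`` (plus free covariates).
The repeated factor is block time within animal; genotype (or any condition
label) is between animals.  The battery mirrors routine behavioural practice:
Shapiro-Wilk normality screening, a two-factor repeated-measures ANOVA
(between x within, i.e. a mixed ANOVA) with Tukey-adjusted pairwise cell
comparisons, and paired / two-sample t-tests, all at alpha = 0.05.

The ANOVA and posthoc machinery is deliberately delegated to vetted routines
(pingouin, statsmodels); this module's contribution is the harness, the named
contrasts, and its calibration tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "normality_check",
    "validate_cohort",
    "rm_anova_tukey",
    "t_test",
    "format_mean_sem",
    "parse_mean_sem",
    "cell_summary",
    "simulate_cohort",
]

ALPHA = 0.05


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p).  Requires n >= 3."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("Shapiro-Wilk requires a 1-D sample with n >= 3")
    res = scipy.stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def validate_cohort(table: pd.DataFrame,
                    dv: str = "delta_pct",
                    within: str = "block_time_min",
                    between: str = "genotype",
                    subject: str = "animal_id") -> pd.DataFrame:
    """Check the repeated-measures structure of a cohort table."""
    for col in (dv, within, between, subject):
        if col not in table.columns:
            raise ValueError(f"cohort table missing column {col!r}")
    geno_per_animal = table.groupby(subject)[between].nunique()
    if (geno_per_animal > 1).any():
        bad = geno_per_animal[geno_per_animal > 1].index.tolist()
        raise ValueError(f"animals with more than one {between}: {bad}")
    counts = table.groupby([between, within])[subject].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 subjects per genotype x time cell")
    if np.allclose(table[dv].std(ddof=0), 0.0):
        raise ValueError("degenerate input: response has zero variance")
    return table


@dataclass
class AnovaReport:
    anova: pd.DataFrame          # mixed ANOVA table (between, within, interaction)
    tukey: pd.DataFrame          # Tukey HSD over all genotype x time cells
    contrasts: pd.DataFrame      # named contrasts pulled from the Tukey table

    def p_interaction(self) -> float:
        return float(self.anova.loc[self.anova["Source"] == "Interaction", "p_unc"].iloc[0])

    def p_between(self) -> float:
        return float(self.anova.loc[self.anova.index[0], "p_unc"])


def rm_anova_tukey(table: pd.DataFrame,
                   dv: str = "delta_pct",
                   within: str = "block_time_min",
                   between: str = "genotype",
                   subject: str = "animal_id",
                   contrast_times: list[float] | None = None,
                   posthoc: bool = True) -> AnovaReport:
    """Two-factor repeated-measures (mixed) ANOVA with Tukey posthoc.

    ``contrast_times`` selects the named cell contrasts of interest (default:
    the last time point): the between-group difference at that time and the
    within-group first-vs-that-time comparison, both read from the
    Tukey-adjusted table over all genotype x time cells.
    """
    table = validate_cohort(table, dv, within, between, subject)
    aov = pg.mixed_anova(data=table, dv=dv, within=within,
                         subject=subject, between=between, correction=False)
    if not posthoc:
        return AnovaReport(anova=aov, tukey=pd.DataFrame(),
                           contrasts=pd.DataFrame())

    cells = table[between].astype(str) + "@" + table[within].astype(str)
    tk = pairwise_tukeyhsd(table[dv].to_numpy(), cells.to_numpy(), alpha=ALPHA)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])

    times = sorted(table[within].unique())
    groups = sorted(table[between].astype(str).unique())
    if contrast_times is None:
        contrast_times = [times[-1]]

    wanted: list[tuple[str, str, str]] = []
    for t_i in contrast_times:
        if len(groups) == 2:
            wanted.append((f"{between} at {t_i}",
                           f"{groups[0]}@{t_i}", f"{groups[1]}@{t_i}"))
        for g in groups:
            wanted.append((f"{g}: {times[0]} vs {t_i}",
                           f"{g}@{times[0]}", f"{g}@{t_i}"))
    rows = []
    for name, c1, c2 in wanted:
        hit = tukey[((tukey["group1"] == c1) & (tukey["group2"] == c2)) |
                    ((tukey["group1"] == c2) & (tukey["group2"] == c1))]
        if len(hit):
            r = hit.iloc[0]
            rows.append({"contrast": name, "meandiff": float(r["meandiff"]),
                         "p_adj": float(r["p-adj"]), "reject": bool(r["reject"])})
    return AnovaReport(anova=aov, tukey=tukey,
                       contrasts=pd.DataFrame(rows))


def t_test(a: np.ndarray, b: np.ndarray, paired: bool = False) -> tuple[float, float]:
    """Paired or two-sample t-test; returns (t, p).

    A paired comparison of identical vectors has zero variance of the
    differences; the no-effect limit (t = 0, p = 1) is returned rather than
    the 0/0 indeterminate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
            return (0.0, 1.0) if np.allclose(d, 0.0) else (np.inf, 0.0)
        res = scipy.stats.ttest_rel(a, b)
    else:
        res = scipy.stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


_MEAN_SEM_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*±\s*(\d+(?:\.\d+)?)\s*$")


def format_mean_sem(values: np.ndarray, decimals: int = 2) -> str:
    """Render ``mean ± SEM`` at the given precision."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("mean ± SEM needs n >= 2")
    sem = values.std(ddof=1) / np.sqrt(len(values))
    return f"{values.mean():.{decimals}f} ± {sem:.{decimals}f}"


def parse_mean_sem(text: str) -> tuple[float, float]:
    m = _MEAN_SEM_RE.match(text)
    if not m:
        raise ValueError(f"not a mean ± SEM string: {text!r}")
    return float(m.group(1)), float(m.group(2))


def cell_summary(table: pd.DataFrame,
                 dv: str = "delta_pct",
                 within: str = "block_time_min",
                 between: str = "genotype",
                 decimals: int = 2) -> pd.DataFrame:
    """mean ± SEM per genotype x time cell."""
    rows = []
    for (g, t), sub in table.groupby([between, within]):
        rows.append({between: g, within: t, "n": len(sub),
                     "mean_sem": format_mean_sem(sub[dv].to_numpy(), decimals)})
    return pd.DataFrame(rows)


def simulate_cohort(n_per_group: int = 10,
                    times: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0),
                    group_means: dict[str, dict[float, float]] | None = None,
                    sd: float = 10.0,
                    subject_sd: float = 0.0,
                    rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Synthetic cohort table for calibration and power studies.

    ``group_means[genotype][time]`` sets cell means (missing cells default to
    0); ``subject_sd`` adds an animal-level random intercept.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    group_means = group_means or {"WT": {}, "KO": {}}
    rows = []
    for g, means in group_means.items():
        for a in range(n_per_group):
            intercept = gen.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
            for t in times:
                mu = means.get(t, 0.0)
                rows.append({"animal_id": f"{g}_{a}", "genotype": g,
                             "block_time_min": t,
                             "delta_pct": mu + intercept + gen.normal(0.0, sd)})
    return pd.DataFrame(rows)
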