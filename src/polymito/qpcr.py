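"""Relative-expression analysis of RT-qPCR Ct tables.

The pipeline is the standard 2^-ddCt scheme: technical replicates are
collapsed by mean, each sample's target Ct is normalised against a reference
gene (beta-actin by default) to give dCt, relative levels 2^-dCt are screened
for a single outlier per group with Grubbs' test, group means are scaled so
the control mean is exactly 1.0, and groups are compared with a two-tailed
Student's t-test.  Amplification efficiency is fixed at 2 (no efficiency
correction).

Grubbs' critical value uses the Student-t closed form

    GP(n) = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))

with t the upper alpha/n (one-sided, the default) or alpha/(2n) (two-sided)
quantile of Student's t with n-2 degrees of freedom; for n=4, alpha=0.05 the
one-sided value is 1.46.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrubbsResult",
    "ExpressionResult",
    "grubbs_critical",
    "grubbs_test",
    "read_ct_table",
    "relative_expression",
    "expression_frame",
]

CT_COLUMNS = ("sample", "group", "gene", "rep", "ct")
GROUPS = ("control", "stress")


@dataclass(frozen=True)
class GrubbsResult:
    n: int
    alpha: float
    g_statistic: float
    critical_value: float
    outlier_index: int | None


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    control_mean: float  # scaled; exactly 1.0
    control_se: float
    stress_mean: float  # = fold change
    stress_se: float
    fold: float
    p_value: float
    outliers_removed: tuple = ()
    reliable: bool = True
    n_control: int = 0
    n_stress: int = 0
    grubbs: dict = field(default_factory=dict, repr=False, compare=False)


def grubbs_critical(n: int, alpha: float = 0.05, sided: str = "one") -> float:
    """Grubbs critical value GP(n) from the Student-t quantile closed form."""
    if n < 3:
        raise ValueError("Grubbs' test needs n >= 3")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    q = alpha / n if sided == "one" else alpha / (2 * n)
    t = stats.t.ppf(1 - q, n - 2)
    return float(((n - 1) / math.sqrt(n)) * math.sqrt(t * t / (n - 2 + t * t)))


def grubbs_test(values, alpha: float = 0.05, sided: str = "one") -> GrubbsResult:
    """Single-outlier Grubbs test: G = max|x - mean| / s (n-1 denominator).

    Declares the most deviant point an outlier iff G > GP(n).  Zero spread
    yields no outlier with G reported as 0 and a warning.
    """
    x = np.asarray(list(values), dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs' test needs n >= 3")
    crit = grubbs_critical(n, alpha, sided)
    s = x.std(ddof=1)
    if s == 0:
        warnings.warn("zero variance: Grubbs statistic undefined, no outlier", stacklevel=2)
        return GrubbsResult(n, alpha, 0.0, crit, None)
    dev = np.abs(x - x.mean())
    idx = int(dev.argmax())
    g = float(dev[idx] / s)
    return GrubbsResult(n, alpha, g, crit, idx if g > crit else None)


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct CSV with columns sample, group, gene, rep, ct."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    bad = df[~df["group"].isin(GROUPS)]
    if len(bad):
        raise ValueError(f"unknown group labels {sorted(bad['group'].unique())}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df[list(CT_COLUMNS)]


def relative_expression(
    ct: pd.DataFrame,
    reference_gene: str = "ACTIN",
    alpha: float = 0.05,
    equal_var: bool = True,
    apply_grubbs: bool = True,
) -> list[ExpressionResult]:
    """Per-gene relative expression (control mean scaled to 1.0) with stats.

    For each biological sample, technical replicates are averaged, dCt is
    Ct_gene - Ct_reference, and the relative level is 2^-dCt.  Grubbs' test
    (single pass, at most one removal per group) screens each group; surviving
    levels give group means/SEs, the fold change (stress mean after scaling)
    and a two-tailed t-test p-value (Student by default, Welch via
    ``equal_var=False``).  A group left with fewer than 3 samples is flagged
    unreliable.
    """
    df = ct.copy()
    df.columns = [c.strip().lower() for c in df.columns]
    # collapse technical replicates
    mean_ct = (
        df.groupby(["group", "sample", "gene"], sort=False)["ct"].mean().reset_index()
    )
    wide = mean_ct.pivot_table(
        index=["group", "sample"], columns="gene", values="ct", sort=False
    )
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    if wide[reference_gene].isna().any():
        bad = wide[wide[reference_gene].isna()].index.tolist()
        raise ValueError(f"reference gene missing for samples {bad}")

    results = []
    genes = [g for g in wide.columns if g != reference_gene]
    for gene in genes:
        levels: dict[str, pd.Series] = {}
        removed: list[tuple] = []
        gstats: dict[str, GrubbsResult] = {}
        for group in GROUPS:
            if group not in wide.index.get_level_values(0):
                continue
            sub = wide.loc[group]
            dct = sub[gene] - sub[reference_gene]
            rel = np.power(2.0, -dct.astype(float)).dropna()
            if apply_grubbs and len(rel) >= 3:
                gres = grubbs_test(rel.to_numpy(), alpha=alpha)
                gstats[group] = gres
                if gres.outlier_index is not None:
                    removed.append((group, rel.index[gres.outlier_index]))
                    rel = rel.drop(rel.index[gres.outlier_index])
            levels[group] = rel
        if "control" not in levels or len(levels["control"]) == 0:
            raise ValueError(f"no control samples for gene {gene!r}")
        scale = levels["control"].mean()
        ctrl = levels["control"] / scale
        strs = levels.get("stress", pd.Series(dtype=float)) / scale
        n_c, n_s = len(ctrl), len(strs)
        if n_s and (np.ptp(ctrl) > 0 or np.ptp(strs) > 0):
            p = float(stats.ttest_ind(strs, ctrl, equal_var=equal_var).pvalue)
        else:
            p = math.nan if not n_s else 1.0
        results.append(
            ExpressionResult(
                gene=gene,
                control_mean=1.0,
                control_se=float(ctrl.std(ddof=1) / math.sqrt(n_c)) if n_c > 1 else math.nan,
                stress_mean=float(strs.mean()) if n_s else math.nan,
                stress_se=float(strs.std(ddof=1) / math.sqrt(n_s)) if n_s > 1 else math.nan,
                fold=float(strs.mean()) if n_s else math.nan,
                p_value=p,
                outliers_removed=tuple(removed),
                reliable=(n_c >= 3 and (n_s == 0 or n_s >= 3)),
                n_control=n_c,
                n_stress=n_s,
                grubbs={g: r for g, r in gstats.items()},
            )
        )
    return results


def expression_frame(results) -> pd.DataFrame:
    """Tabulate ExpressionResults (one row per gene)."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "fold": r.fold,
                "stress_se": r.stress_se,
                "control_se": r.control_se,
                "p_value": r.p_value,
                "n_control": r.n_control,
                "n_stress": r.n_stress,
                "outliers_removed": ";".join(f"{g}:{s}" for g, s in r.outliers_removed),
                "reliable": r.reliable,
            }
        )
    return pd.DataFrame(rows)
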