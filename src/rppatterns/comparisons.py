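"""Per-protein pairwise group comparisons via a three-level mixed model.

Each protein-instance is analysed with nine biologically motivated pairwise
contrasts between the 8 experimental groups (see :func:`comparison_battery`).
Each contrast is fitted as its own two-group model on log-transformed
normalized intensities:

    log(y) ~ group  +  (1 | mouse)  +  (1 | dilution-series within mouse)  + spot residual

so replicate spots and dilution levels within a mouse are correlated and
mice are the independent units.  The fixed group effect beta is a log ratio;
it is reported on the percent scale as ``100 * (exp(beta) - 1)`` with the
standard error propagated by the delta method.  The p-value uses a t
reference with (n_a + n_b - 2) degrees of freedom — the mouse count, not the
spot count, carries the information.

Significance is family-wise Bonferroni-gated: within one region x fraction,
the per-test threshold is alpha divided by the number of proteins analysed
there (e.g. 0.05 / 73 ~= 7e-4 for a 73-protein family).

When the restricted-likelihood fit cannot converge (degenerate variance,
e.g. noise-free simulations), the estimator falls back to the nested
means-of-means: spot -> dilution mean -> mouse mean, then a two-sample Welch
test on mouse-level means.  On balanced data the mixed-model point estimate
and the fallback coincide exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import usable_mask
from .simulate import GroupSpec

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-24  # below this total within-arm variance the model is degenerate


@dataclass(frozen=True)
class ComparisonDef:
    """One pairwise contrast: group_a vs group_b (percent of group_b)."""

    code: str
    group_a: GroupSpec
    group_b: GroupSpec
    description: str = ""


def _battery() -> tuple[ComparisonDef, ...]:
    g = GroupSpec.from_label
    return (
        ComparisonDef("B", g("t-SC-sal"), g("c-SC-sal"), "baseline genotype difference"),
        ComparisonDef("B-tm", g("t-SC-mem"), g("t-SC-sal"), "memantine effect on trisomic baseline"),
        ComparisonDef("B-cm", g("c-SC-mem"), g("c-SC-sal"), "memantine effect on control baseline"),
        ComparisonDef("B-tm-cs", g("t-SC-mem"), g("c-SC-sal"), "treated trisomic vs control baseline"),
        ComparisonDef("NL", g("c-CS-sal"), g("c-SC-sal"), "normal learning response"),
        ComparisonDef("FL", g("t-CS-sal"), g("t-SC-sal"), "failed learning response"),
        ComparisonDef("RL", g("t-CS-mem"), g("t-SC-mem"), "rescued learning response"),
        ComparisonDef("RL-FL", g("t-CS-mem"), g("t-CS-sal"), "rescued vs failed endpoint"),
        ComparisonDef("RL-NL", g("t-CS-mem"), g("c-CS-sal"), "rescued vs normal endpoint"),
    )


_BATTERY = _battery()
COMPARISON_CODES = tuple(d.code for d in _BATTERY)


def comparison_battery() -> tuple[ComparisonDef, ...]:
    """The nine biologically relevant pairwise group comparisons."""
    return _BATTERY


def get_comparison(code: str) -> ComparisonDef:
    for d in _BATTERY:
        if d.code == code:
            return d
    raise KeyError(f"unknown comparison code {code!r}; valid: {COMPARISON_CODES}")


def percent_difference(mu_a: float, mu_b: float) -> float:
    """100 * (mu_a - mu_b) / mu_b."""
    if mu_b <= 0:
        raise ValueError(f"reference mean must be > 0, got {mu_b!r}")
    return 100.0 * (mu_a - mu_b) / mu_b


@dataclass
class StatsConfig:
    family_alpha: float = 0.05
    transform: str = "log"  # "log" (default) or "linear" sensitivity option
    allow_fallback: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.family_alpha < 1.0:
            raise ValueError("family_alpha must be in (0, 1)")
        if self.transform not in ("log", "linear"):
            raise ValueError("transform must be 'log' or 'linear'")


@dataclass
class ComparisonResult:
    protein: str
    region: str
    fraction: str
    comparison: str
    percent_difference: float
    sem: float
    p_value: float
    n_a: int
    n_b: int
    method: str  # "mixed", "nested_means", or "unestimable"
    status: str  # "ok" or "unestimable"
    m_tests: int | None = None
    significant: bool | None = None

    def to_dict(self) -> dict:
        return {
            "protein": self.protein, "region": self.region, "fraction": self.fraction,
            "comparison": self.comparison,
            "percent_difference": self.percent_difference, "sem": self.sem,
            "p_value": self.p_value, "n_a": self.n_a, "n_b": self.n_b,
            "method": self.method, "status": self.status,
            "m_tests": self.m_tests, "significant": self.significant,
        }


def _mouse_means(arm: pd.DataFrame, value_col: str) -> pd.Series:
    """Nested means-of-means: replicate -> dilution mean -> mouse mean."""
    return (
        arm.groupby(["mouse_id", "dilution_step"])[value_col]
        .mean()
        .groupby(level="mouse_id")
        .mean()
    )


def nested_means_estimate(a: pd.DataFrame, b: pd.DataFrame, value_col: str) -> tuple[float, float, float]:
    """(difference of arm means, SE, p) from mouse-level means (Welch test).

    With zero within-arm variance the p-value degenerates to 0 when the
    means differ and 1 when they do not.
    """
    ma, mb = _mouse_means(a, value_col), _mouse_means(b, value_col)
    diff = float(ma.mean() - mb.mean())
    va, vb = float(ma.var(ddof=1)), float(mb.var(ddof=1))
    na, nb = len(ma), len(mb)
    se2 = va / na + vb / nb
    if se2 <= _VAR_FLOOR:
        return diff, 0.0, (0.0 if diff != 0.0 else 1.0)
    se = float(np.sqrt(se2))
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * sps.t.sf(abs(diff) / se, df))
    return diff, se, p


def _fit_mixed(df: pd.DataFrame, value_col: str) -> tuple[float, float] | None:
    """REML fit of the three-level model; returns (beta, se) or None."""
    import statsmodels.formula.api as smf

    data = df[["mouse_id", "dilution_step", "is_a", value_col]].rename(columns={value_col: "y"})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "y ~ is_a",
                data,
                groups=data["mouse_id"],
                re_formula="1",
                vc_formula={"dilution": "0 + C(dilution_step)"},
            )
            fit = model.fit(reml=True)
        beta = float(fit.params["is_a"])
        se = float(fit.bse["is_a"])
    except Exception as exc:  # pragma: no cover - exercised via degenerate inputs
        logger.info("mixed model failed (%s); falling back to nested means", exc)
        return None
    if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
        return None
    return beta, se


def fit_pairwise(
    measurements: pd.DataFrame,
    comparison: ComparisonDef | str,
    config: StatsConfig | None = None,
) -> ComparisonResult:
    """Fit one contrast for one protein-instance.

    ``measurements`` must be the usable (QC-passing) spots of a single
    protein x region x fraction, with ``normalized_intensity``.  Returns an
    unestimable result (status flag, NaN estimate) when either arm has
    fewer than 2 mice.
    """
    config = config or StatsConfig()
    if isinstance(comparison, str):
        comparison = get_comparison(comparison)
    inst = measurements[["protein", "region", "fraction"]].drop_duplicates()
    if len(inst) != 1:
        raise ValueError("fit_pairwise expects spots from exactly one protein-instance")
    protein, region, fraction = inst.iloc[0]

    a = measurements[measurements["group"] == comparison.group_a.label]
    b = measurements[measurements["group"] == comparison.group_b.label]
    n_a, n_b = a["mouse_id"].nunique(), b["mouse_id"].nunique()

    def unestimable() -> ComparisonResult:
        return ComparisonResult(
            protein, region, fraction, comparison.code,
            np.nan, np.nan, np.nan, n_a, n_b, "unestimable", "unestimable",
        )

    if n_a < 2 or n_b < 2:
        return unestimable()

    df = pd.concat([a, b], ignore_index=True)
    if config.transform == "log":
        if (df["normalized_intensity"] <= 0).any():
            return unestimable()
        df = df.assign(y=np.log(df["normalized_intensity"]))
    else:
        df = df.assign(y=df["normalized_intensity"])
    df["is_a"] = (df["group"] == comparison.group_a.label).astype(float)

    # Degenerate (e.g. noise-free) data: REML has nothing to estimate.
    within_var = df.groupby("group")["y"].var(ddof=0).fillna(0.0).sum()
    method = "mixed"
    est = None if within_var <= _VAR_FLOOR else _fit_mixed(df, "y")
    if est is None:
        if not config.allow_fallback and within_var > _VAR_FLOOR:
            return unestimable()
        method = "nested_means"
        beta, se, p = nested_means_estimate(
            df[df["is_a"] == 1.0], df[df["is_a"] == 0.0], "y"
        )
    else:
        beta, se = est
        tstat = np.inf if se == 0 else abs(beta) / se
        p = float(2.0 * sps.t.sf(tstat, df=n_a + n_b - 2))

    if config.transform == "log":
        pct = 100.0 * float(np.expm1(beta))
        sem = 100.0 * float(np.exp(beta)) * se
    else:
        mu_b = float(df.loc[df["is_a"] == 0.0, "y"].mean())
        if mu_b <= 0:
            return unestimable()
        pct = 100.0 * beta / mu_b
        sem = 100.0 * se / mu_b

    return ComparisonResult(
        protein, region, fraction, comparison.code,
        pct, sem, p, n_a, n_b, method, "ok",
    )


def fit_battery(
    measurements: pd.DataFrame,
    config: StatsConfig | None = None,
    comparisons: Sequence[ComparisonDef | str] | None = None,
    apply_qc: bool = True,
) -> pd.DataFrame:
    """Fit the comparison battery for every protein-instance.

    Returns long-format results (one row per instance x comparison),
    Bonferroni-gated per region x fraction.
    """
    config = config or StatsConfig()
    defs = [get_comparison(c) if isinstance(c, str) else c for c in (comparisons or _BATTERY)]
    df = measurements
    if apply_qc and "qc_invalid" in df.columns:
        df = df.loc[usable_mask(df)]
    rows = []
    for _, inst in df.groupby(["protein", "region", "fraction"], sort=True):
        for d in defs:
            rows.append(fit_pairwise(inst, d, config).to_dict())
    results = pd.DataFrame(rows)
    if results.empty:
        return results
    return bonferroni_gate(results, config)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold controlling the family-wise error at ``alpha``."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def bonferroni_gate(results: pd.DataFrame, config: StatsConfig | None = None) -> pd.DataFrame:
    """Set ``m_tests`` and ``significant`` per region x fraction family.

    The family is the set of proteins analysed in one region x fraction;
    every comparison of every protein in the family is tested at
    ``alpha / m`` where m is the number of proteins.
    """
    config = config or StatsConfig()
    if results.empty:
        raise ValueError("cannot gate an empty result set")
    out = results.copy()
    out["m_tests"] = 0
    out["significant"] = False
    for (_, _), idx in out.groupby(["region", "fraction"], sort=False).groups.items():
        sub = out.loc[idx]
        m = int(sub.loc[sub["status"] == "ok", "protein"].nunique())
        if m == 0:
            continue
        thr = bonferroni_threshold(config.family_alpha, m)
        out.loc[idx, "m_tests"] = m
        out.loc[idx, "significant"] = (sub["status"] == "ok") & (sub["p_value"] < thr)
    return out


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
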