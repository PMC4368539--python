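"""Rule-based classification of per-protein compensation patterns.

The unit of classification is an *instance*: one protein in one subcellular
fraction of one brain region, carrying its estimated percent differences and
Bonferroni-gated significance flags for the five informative contrasts

    NL    normal learning   (control CS vs SC, saline)
    FL    failed learning   (trisomic CS vs SC, saline)
    RL    rescued learning  (trisomic CS vs SC, memantine)
    B     baseline genotype difference (trisomic vs control, SC saline)
    B-tm  memantine effect on the trisomic baseline (SC, mem vs sal)

The classifier asks, for every instance where normal learning produces a
response (NL significant), how the trisomic brain achieves — or fails to
achieve — an equivalent outcome: by the same dynamic response (FL = NL), by
an abnormal baseline level standing in for it (B = NL), by partial
compensation (B + FL = NL), or only with the drug, directly (B-tm = NL) or
indirectly (RL-anchored sums).  Instances with no NL response but an
abnormal baseline are classified by whether anything compensates the
abnormality.  Everything else is a single-comparison responder or stable.

Non-significant terms contribute zero to sums by default: a sum such as
"B + FL" means "the significant baseline abnormality plus the significant
change in failed learning".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Comparisons the classifier requires for every instance.
CLASSIFIER_COMPARISONS = ("NL", "FL", "B", "RL", "B-tm")


class PatternCode(str, enum.Enum):
    """Compensation-pattern codes.

    The first three are adequate without the drug; the next five require
    memantine directly or indirectly; the ``B_ABN_*`` codes cover baseline
    abnormalities with no NL response; the last two are catch-alls.
    """

    FL_EQ_NL = "FL_EQ_NL"                      # same response in failed learning
    B_COMP = "B_COMP"                          # baseline level compensates (FL = 0)
    B_PLUS_FL = "B_PLUS_FL"                    # baseline + partial FL response
    RL_EQ_NL = "RL_EQ_NL"                      # drug induces the response indirectly
    BTM_COMP = "BTM_COMP"                      # drug induces the level directly (RL = 0)
    BTM_PLUS_RL = "BTM_PLUS_RL"                # direct + indirect drug response
    RL_PLUS_B = "RL_PLUS_B"                    # baseline + indirect drug response
    RL_PLUS_B_PLUS_BTM = "RL_PLUS_B_PLUS_BTM"  # baseline + direct + indirect
    NL_UNRESOLVED = "NL_UNRESOLVED"            # NL response, no sum accounts for it
    B_ABN_COMP_FL = "B_ABN_COMP_FL"            # baseline abnormality corrected in FL
    B_ABN_COMP_MEM = "B_ABN_COMP_MEM"          # baseline abnormality corrected by drug
    B_ABN_UNCOMP = "B_ABN_UNCOMP"              # baseline abnormality uncorrected
    SINGLE_RESPONDER = "SINGLE_RESPONDER"      # responds in one comparison only
    STABLE = "STABLE"                          # no significant term anywhere


#: Codes that mean the response is adequate without memantine.
MEMANTINE_NOT_REQUIRED = (PatternCode.FL_EQ_NL, PatternCode.B_COMP, PatternCode.B_PLUS_FL)
#: Codes that mean memantine is required, directly or indirectly.
MEMANTINE_REQUIRED = (
    PatternCode.RL_EQ_NL,
    PatternCode.BTM_COMP,
    PatternCode.BTM_PLUS_RL,
    PatternCode.RL_PLUS_B,
    PatternCode.RL_PLUS_B_PLUS_BTM,
)


@dataclass
class ClassifierConfig:
    """Tolerances for pattern matching.

    tolerance_pp
        absolute percentage-point window for a sum of terms to "match" the
        NL response (or zero, for baseline-abnormality patterns).
    band_threshold_pp
        split reported rosters into residuals within / beyond this window.
    ns_term_policy
        "zero" (default): non-significant terms contribute 0 to sums;
        "point_estimate": sums use every point estimate (sensitivity mode).
    """

    tolerance_pp: float = 10.0
    band_threshold_pp: float = 10.0
    ns_term_policy: str = "zero"

    def __post_init__(self) -> None:
        if self.tolerance_pp <= 0:
            raise ValueError("tolerance_pp must be > 0")
        if self.band_threshold_pp <= 0:
            raise ValueError("band_threshold_pp must be > 0")
        if self.ns_term_policy not in ("zero", "point_estimate"):
            raise ValueError("ns_term_policy must be 'zero' or 'point_estimate'")


@dataclass
class InstanceProfile:
    """Classifier input: one instance's (percent, significant) per comparison."""

    protein: str
    region: str
    fraction: str
    values: Mapping[str, tuple[float, bool]]

    def __post_init__(self) -> None:
        for code in CLASSIFIER_COMPARISONS:
            if code not in self.values:
                raise ValueError(
                    f"profile {self.protein}/{self.region}/{self.fraction} "
                    f"is missing comparison {code!r}"
                )
            pct, _ = self.values[code]
            if not math.isfinite(pct):
                raise ValueError(
                    f"profile {self.protein}/{self.region}/{self.fraction} "
                    f"has non-finite percent for {code!r}"
                )

    def pct(self, code: str) -> float:
        return float(self.values[code][0])

    def sig(self, code: str) -> bool:
        return bool(self.values[code][1])


@dataclass
class PatternAssignment:
    protein: str
    region: str
    fraction: str
    code: PatternCode
    terms_used: tuple[str, ...]
    residual_pp: float  # |sum of terms - target|; NaN when no target applies
    band: str | None    # "within" / "beyond" the band threshold; None if no residual

    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            "region": self.region,
            "fraction": self.fraction,
            "code": self.code.value,
            "terms_used": "+".join(self.terms_used),
            "residual_pp": self.residual_pp,
            "band": self.band if self.band is not None else "",
        }


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def classify(profile: InstanceProfile, config: ClassifierConfig | None = None) -> PatternAssignment:
    """Assign exactly one pattern code to an instance profile.

    Candidate explanations for a significant NL response are evaluated
    simplest-first, never attributing to the drug a response that is already
    adequate without it.  A candidate is admissible only when its dynamic
    terms are significant, and matches when the summed effective value lies
    within ``tolerance_pp`` of NL with the same sign.
    """
    config = config or ClassifierConfig()
    tol = config.tolerance_pp

    def eff(code: str) -> float:
        if config.ns_term_policy == "point_estimate":
            return profile.pct(code)
        return profile.pct(code) if profile.sig(code) else 0.0

    def match(x: float, target: float) -> bool:
        if abs(x - target) > tol:
            return False
        return target == 0 or _sign(x) == _sign(target)

    nl, fl, b, rl, btm = (profile.pct(c) for c in CLASSIFIER_COMPARISONS)
    s = {c: profile.sig(c) for c in CLASSIFIER_COMPARISONS}

    def assign(code: PatternCode, terms: Sequence[str], target: float | None) -> PatternAssignment:
        if target is None:
            residual: float = math.nan
            band = None
        else:
            residual = abs(sum(eff(t) for t in terms) - target)
            band = "within" if residual <= config.band_threshold_pp else "beyond"
        return PatternAssignment(
            profile.protein, profile.region, profile.fraction,
            code, tuple(terms), residual, band,
        )

    if s["NL"]:
        # (code, summed terms, admissibility)
        candidates: list[tuple[PatternCode, tuple[str, ...], bool]] = [
            (PatternCode.FL_EQ_NL, ("FL",), s["FL"]),
            (PatternCode.B_COMP, ("B",), s["B"] and not s["FL"]),
            (PatternCode.B_PLUS_FL, ("B", "FL"), s["B"] and s["FL"]),
            (PatternCode.RL_EQ_NL, ("RL",), s["RL"] and not s["B-tm"]),
            (PatternCode.BTM_COMP, ("B-tm",), s["B-tm"] and not s["RL"]),
            (PatternCode.BTM_COMP, ("B", "B-tm"), s["B-tm"] and not s["RL"]),
            (PatternCode.BTM_PLUS_RL, ("B-tm", "RL"), s["B-tm"] and s["RL"]),
            (PatternCode.RL_PLUS_B, ("B", "RL"), s["B"] and s["RL"] and not s["B-tm"]),
            (PatternCode.RL_PLUS_B_PLUS_BTM, ("B", "B-tm", "RL"), s["RL"] or s["B-tm"]),
        ]
        for code, terms, admissible in candidates:
            if admissible and match(sum(eff(t) for t in terms), nl):
                return assign(code, terms, nl)
        # unresolved: report the closest candidate sum for diagnostics
        best = min(candidates, key=lambda c: abs(sum(eff(t) for t in c[1]) - nl))
        return assign(PatternCode.NL_UNRESOLVED, best[1], nl)

    if s["B"]:
        if s["FL"] and _sign(fl) == -_sign(b) and abs(eff("B") + eff("FL")) <= tol:
            return assign(PatternCode.B_ABN_COMP_FL, ("B", "FL"), 0.0)
        if not s["FL"] and (s["RL"] or s["B-tm"]) and abs(
            eff("B") + eff("B-tm") + eff("RL")
        ) <= tol:
            return assign(PatternCode.B_ABN_COMP_MEM, ("B", "B-tm", "RL"), 0.0)
        return assign(PatternCode.B_ABN_UNCOMP, ("B", "B-tm", "RL"), 0.0)

    responders = tuple(c for c in ("FL", "RL", "B-tm") if s[c])
    if responders:
        return assign(PatternCode.SINGLE_RESPONDER, responders, None)
    return assign(PatternCode.STABLE, (), None)


def classify_all(
    profiles: Iterable[InstanceProfile] | pd.DataFrame,
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Classify a set of instance profiles; one assignment per instance.

    Accepts either an iterable of :class:`InstanceProfile` or a long-format
    DataFrame with columns protein, region, fraction, comparison,
    percent_difference, significant.
    """
    if isinstance(profiles, pd.DataFrame):
        profiles = profiles_from_frame(profiles)
    profiles = list(profiles)
    seen: set[tuple[str, str, str]] = set()
    for p in profiles:
        key = (p.protein, p.region, p.fraction)
        if key in seen:
            raise ValueError(f"duplicate instance {key}")
        seen.add(key)
    rows = [classify(p, config).to_dict() for p in profiles]
    columns = ["protein", "region", "fraction", "code", "terms_used", "residual_pp", "band"]
    return pd.DataFrame(rows, columns=columns)


def profiles_from_frame(df: pd.DataFrame) -> list[InstanceProfile]:
    """Build profiles from long-format comparison results.

    Rows with comparisons beyond the five the classifier uses are ignored.
    """
    needed = df[df["comparison"].isin(CLASSIFIER_COMPARISONS)]
    out = []
    for (protein, region, fraction), g in needed.groupby(
        ["protein", "region", "fraction"], sort=True
    ):
        if g["comparison"].duplicated().any():
            raise ValueError(
                f"duplicate rows for instance {(protein, region, fraction)}"
            )
        values = {
            r.comparison: (float(r.percent_difference), bool(r.significant))
            for r in g.itertuples()
        }
        out.append(InstanceProfile(str(protein), str(region), str(fraction), values))
    return out
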