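"""Simulation studies validating the statistical engine and the classifier.

These routines plant known truths with the synthetic-data generator, run the
full estimation pipeline, and measure how well the truths are recovered:

* :func:`recovery_study` — bias/MAE of percent-difference estimates across a
  grid of planted effect sizes;
* :func:`null_type_one_study` — family-wise false-positive rate under a
  global null with Bonferroni gating;
* :func:`oracle_agreement_study` — equality of the mixed-model fixed effect
  with the nested means-of-means estimator on balanced data;
* :func:`archetype_recovery_study` — end-to-end classification accuracy on
  instances simulated from known pattern archetypes.

All are deterministic given their seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import comparisons, simulate
from .preprocess import preprocess as _preprocess
from .patterns import CLASSIFIER_COMPARISONS, ClassifierConfig, PatternCode, classify_all

#: Archetypes whose planted terms can all be made >= 20 percentage points.
RECOVERABLE_ARCHETYPES: tuple[tuple[PatternCode, float, float | None], ...] = (
    (PatternCode.FL_EQ_NL, 40.0, None),
    (PatternCode.B_COMP, 40.0, 40.0),
    (PatternCode.B_PLUS_FL, 40.0, 20.0),
    (PatternCode.RL_EQ_NL, 40.0, None),
    (PatternCode.BTM_COMP, 40.0, None),
    (PatternCode.BTM_PLUS_RL, 40.0, 20.0),
    (PatternCode.RL_PLUS_B, 40.0, 20.0),
    (PatternCode.RL_PLUS_B_PLUS_BTM, 60.0, 20.0),
)


def _design(n_proteins: int, n_mice: int, seed: int) -> simulate.DesignSpec:
    return simulate.DesignSpec(
        n_mice_per_group=n_mice,
        regions=["hippocampus"],
        fractions=["nuclear"],
        n_proteins=n_proteins,
        seed=seed,
    )


def _fit_nl(measurements: pd.DataFrame) -> pd.DataFrame:
    pre = _preprocess(measurements)
    return comparisons.fit_battery(pre, comparisons=["NL"])


def recovery_study(
    magnitudes: Sequence[float] = (-50.0, -20.0, 0.0, 20.0, 50.0, 120.0),
    n_sims_per_magnitude: int = 34,
    n_mice: int = 8,
    noise: simulate.NoiseSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate each planted NL magnitude repeatedly; return planted vs estimated.

    One simulated protein-instance per (magnitude, replicate), all analysed
    in a single batch so the run shares one design and one preprocessing
    pass.
    """
    noise = noise or simulate.NoiseSpec()
    plants = [m for m in magnitudes for _ in range(n_sims_per_magnitude)]
    design = _design(len(plants), n_mice, seed)
    effects = simulate.effects_table(
        design,
        {
            (p, "hippocampus", "nuclear"): simulate.archetype_to_effects(
                PatternCode.FL_EQ_NL, mag
            )
            for p, mag in zip(design.proteins, plants)
        },
    )
    measurements = simulate.simulate_measurements(design, effects, noise, seed)
    results = _fit_nl(measurements)
    planted = pd.DataFrame({"protein": design.proteins, "planted": plants})
    out = results.merge(planted, on="protein")
    out["error"] = out["percent_difference"] - out["planted"]
    return out[["protein", "planted", "percent_difference", "sem", "p_value", "error", "method"]]


def mean_absolute_error(recovery: pd.DataFrame) -> float:
    return float(recovery["error"].abs().mean())


def null_type_one_study(
    n_instances: int = 1000,
    m_family: int = 73,
    alpha: float = 0.05,
    n_mice: int = 8,
    noise: simulate.NoiseSpec | None = None,
    seed: int = 0,
) -> dict:
    """Fraction of null instances declared significant at the Bonferroni gate.

    All 8 group means are equal; each instance is tested for an NL response
    at the per-test threshold ``alpha / m_family`` (the family size of the
    real data's largest fraction, 73 proteins).
    """
    noise = noise or simulate.NoiseSpec()
    design = _design(n_instances, n_mice, seed)
    effects = simulate.effects_table(design)  # all stable
    measurements = simulate.simulate_measurements(design, effects, noise, seed)
    results = _fit_nl(measurements)
    thr = comparisons.bonferroni_threshold(alpha, m_family)
    ok = results[results["status"] == "ok"]
    frac = float((ok["p_value"] < thr).mean())
    return {
        "fraction_significant": frac,
        "n_instances": int(len(ok)),
        "threshold": thr,
    }


def oracle_agreement_study(
    n_datasets: int = 50,
    n_mice: int = 8,
    noise: simulate.NoiseSpec | None = None,
    seed: int = 0,
) -> dict:
    """Max |mixed-model - nested-means| percent estimate over balanced datasets.

    Each dataset is one protein-instance with a planted +20% NL response.
    The equality of the two estimators holds on *balanced* data, so the
    datasets are kept balanced by construction: no exclusion rule is
    applied (a spot dropped by the k-SD rule would unbalance the nesting
    and the two estimators then weight mice differently).  The number of
    fits that actually used the mixed model is reported alongside.
    """
    noise = noise or simulate.NoiseSpec()
    design = _design(n_datasets, n_mice, seed)
    effects = simulate.effects_table(
        design,
        {
            (p, "hippocampus", "nuclear"): simulate.archetype_to_effects(
                PatternCode.FL_EQ_NL, 20.0
            )
            for p in design.proteins
        },
    )
    measurements = simulate.simulate_measurements(design, effects, noise, seed)
    from .preprocess import normalize_to_total_protein

    usable = normalize_to_total_protein(measurements)
    nl = comparisons.get_comparison("NL")
    diffs = []
    n_mixed = 0
    for _, inst in usable.groupby("protein", sort=True):
        res = comparisons.fit_pairwise(inst, nl)
        if res.method != "mixed":
            continue
        n_mixed += 1
        a = inst[inst.group == nl.group_a.label].assign(y=lambda d: np.log(d.normalized_intensity))
        b = inst[inst.group == nl.group_b.label].assign(y=lambda d: np.log(d.normalized_intensity))
        diff, _, _ = comparisons.nested_means_estimate(a, b, "y")
        oracle_pct = 100.0 * float(np.expm1(diff))
        diffs.append(abs(res.percent_difference - oracle_pct))
    return {
        "max_abs_difference": float(max(diffs)) if diffs else float("nan"),
        "n_mixed": n_mixed,
        "n_datasets": n_datasets,
    }


def archetype_recovery_study(
    archetypes: Sequence[tuple[PatternCode, float, float | None]] = RECOVERABLE_ARCHETYPES,
    n_reps: int = 12,
    n_mice: int = 8,
    noise: simulate.NoiseSpec | None = None,
    classifier: ClassifierConfig | None = None,
    m_family: int = 73,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate instances from known archetypes and classify them back.

    Returns one row per instance with the planted and assigned codes.  With
    ``noise=ZERO_NOISE`` the assignment must be exact; under measurement
    noise it is a recovery-rate study.

    Each simulated instance is a Monte-Carlo replicate of "one protein
    inside the study's family", so significance is gated at
    ``alpha / m_family`` (family size of the real data's largest fraction by
    default) rather than at the replicate count, which is an artifact of
    batching the replicates into one run.
    """
    noise = noise if noise is not None else simulate.NoiseSpec()
    plants = [(code, m, b) for code, m, b in archetypes for _ in range(n_reps)]
    design = _design(len(plants), n_mice, seed)
    effects = simulate.effects_table(
        design,
        {
            (p, "hippocampus", "nuclear"): simulate.archetype_to_effects(code, m, b)
            for p, (code, m, b) in zip(design.proteins, plants)
        },
    )
    measurements = simulate.simulate_measurements(design, effects, noise, seed)
    pre = _preprocess(measurements)
    results = comparisons.fit_battery(pre, comparisons=list(CLASSIFIER_COMPARISONS))
    thr = comparisons.bonferroni_threshold(alpha, m_family)
    results["m_tests"] = m_family
    results["significant"] = (results["status"] == "ok") & (results["p_value"] < thr)
    assignments = classify_all(results, classifier)
    planted = pd.DataFrame(
        {"protein": design.proteins, "planted_code": [c.value for c, _, _ in plants]}
    )
    out = assignments.merge(planted, on="protein")
    out["correct"] = out["code"] == out["planted_code"]
    return out


def accuracy(recovery: pd.DataFrame) -> float:
    return float(recovery["correct"].mean())
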