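"""Synthetic RPPA measurement generator.

Emulates the factorial design of a context-fear-conditioning drug-rescue
study: 2 genotypes (control / trisomic) x 2 training paradigms (SC / CS) x
2 drugs (saline / memantine) = 8 groups of mice, each brain dissected into
regions and subcellular fractions, each lysate spotted as a dilution series
in replicate with a paired total-protein stain (SyproRuby-style) signal.

Noise is multiplicative log-normal at the three nested levels the analysis
model estimates — mouse, dilution-series-within-mouse, and spot residual —
so that with all standard deviations at zero the normalized intensities are
exactly the planted group means and every downstream estimate is exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .patterns import PatternCode

GENOTYPES = ("c", "t")  # control, trisomic (Ts65Dn)
PARADIGMS = ("SC", "CS")  # shock-context (cannot learn), context-shock (learns)
DRUGS = ("sal", "mem")  # saline, memantine


@dataclass(frozen=True)
class GroupSpec:
    """One of the 8 experimental groups, labelled e.g. ``t-CS-mem``."""

    genotype: str
    paradigm: str
    drug: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"paradigm must be one of {PARADIGMS}, got {self.paradigm!r}")
        if self.drug not in DRUGS:
            raise ValueError(f"drug must be one of {DRUGS}, got {self.drug!r}")

    @property
    def label(self) -> str:
        return f"{self.genotype}-{self.paradigm}-{self.drug}"

    @classmethod
    def from_label(cls, label: str) -> "GroupSpec":
        genotype, paradigm, drug = label.split("-")
        return cls(genotype, paradigm, drug)


#: The 8 groups in a fixed canonical order.
ALL_GROUPS: tuple[GroupSpec, ...] = tuple(
    GroupSpec(g, p, d) for g in GENOTYPES for p in PARADIGMS for d in DRUGS
)
GROUP_LABELS: tuple[str, ...] = tuple(g.label for g in ALL_GROUPS)


@dataclass
class DesignSpec:
    """Size and shape of one simulated experiment.

    Defaults are the study conditions the analysis was built for: 8 groups of
    8 mice (midpoint of the 7-10 per group used in practice), two brain
    regions, three subcellular fractions, 85 antibodies, and each sample
    spotted as a five-point two-fold dilution series in three replicates.
    """

    n_mice_per_group: int = 8
    regions: Sequence[str] = ("hippocampus", "cortex")
    fractions: Sequence[str] = ("nuclear", "cytosolic", "membrane")
    n_proteins: int = 85
    n_dilution_steps: int = 5
    n_replicates: int = 3
    dilution_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mice_per_group", "n_proteins", "n_dilution_steps", "n_replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not self.regions or not self.fractions:
            raise ValueError("regions and fractions must each be non-empty")
        if self.dilution_factor <= 0:
            raise ValueError(f"dilution_factor must be > 0, got {self.dilution_factor!r}")

    @property
    def proteins(self) -> list[str]:
        return [f"P{i:03d}" for i in range(1, self.n_proteins + 1)]


@dataclass
class NoiseSpec:
    """Variance components (log scale) and contamination rates.

    The three SDs mirror the three levels of the analysis model. The study
    never reports its variance-component magnitudes, so the defaults are
    moderate values typical of replicate RPPA spots; all are user-tunable.
    Technical outliers are spots whose residual is inflated by
    ``outlier_scale``; low-signal instances have all group means forced to
    ``low_signal_value`` so they trip the downstream reliability floor.
    """

    sd_mouse: float = 0.05
    sd_dilution: float = 0.03
    sd_replicate: float = 0.05
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0
    low_signal_rate: float = 0.0
    low_signal_value: float = 0.05

    def __post_init__(self) -> None:
        for name in ("sd_mouse", "sd_dilution", "sd_replicate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("outlier_rate", "low_signal_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "NoiseSpec":
        return cls(**dict(d))


ZERO_NOISE = NoiseSpec(sd_mouse=0.0, sd_dilution=0.0, sd_replicate=0.0)


def build_design(spec: DesignSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign mice to groups and lay out the full spot grid.

    Returns ``(mice, grid)``: *mice* maps mouse_id -> group; *grid* has one
    row per spot (protein x region x fraction x mouse x dilution x replicate).
    Deterministic given ``spec`` (mouse ids are systematic, not sampled).
    """
    mice = pd.DataFrame(
        [
            {
                "group": g.label,
                "genotype": g.genotype,
                "paradigm": g.paradigm,
                "drug": g.drug,
                "mouse_id": f"{g.label}-m{i:02d}",
            }
            for g in ALL_GROUPS
            for i in range(1, spec.n_mice_per_group + 1)
        ]
    )
    instances = pd.DataFrame(
        itertools.product(spec.proteins, spec.regions, spec.fractions),
        columns=["protein", "region", "fraction"],
    )
    spots = pd.DataFrame(
        itertools.product(
            range(1, spec.n_dilution_steps + 1), range(1, spec.n_replicates + 1)
        ),
        columns=["dilution_step", "replicate"],
    )
    grid = instances.merge(mice, how="cross").merge(spots, how="cross")
    return mice, grid


# ---------------------------------------------------------------------------
# Effect archetypes
# ---------------------------------------------------------------------------

# Percent contrasts (NL, FL, RL, B, B-tm) planted by each archetype, as
# functions of the learning-response magnitude m and baseline magnitude b.
# NL: normal learning (control CS vs SC, saline); FL: failed learning
# (trisomic, saline); RL: rescued learning (trisomic, memantine); B: baseline
# genotype difference; B-tm: memantine effect on the trisomic baseline.
def _archetype_contrasts(code: PatternCode, m: float, b: float) -> dict[str, float]:
    zero = {"NL": 0.0, "FL": 0.0, "RL": 0.0, "B": 0.0, "B-tm": 0.0}
    c = dict(zero)
    if code is PatternCode.STABLE:
        pass
    elif code is PatternCode.FL_EQ_NL:
        c.update(NL=m, FL=m, RL=m)
    elif code is PatternCode.B_COMP:
        c.update(NL=m, B=b)
    elif code is PatternCode.B_PLUS_FL:
        c.update(NL=m, B=b, FL=m - b, RL=m - b)
    elif code is PatternCode.RL_EQ_NL:
        c.update(NL=m, RL=m)
    elif code is PatternCode.BTM_COMP:
        c.update(NL=m, **{"B-tm": m})
    elif code is PatternCode.BTM_PLUS_RL:
        c.update(NL=m, RL=m - b, **{"B-tm": b})
    elif code is PatternCode.RL_PLUS_B:
        c.update(NL=m, B=b, RL=m - b)
    elif code is PatternCode.RL_PLUS_B_PLUS_BTM:
        c.update(NL=m, B=b, RL=m - 2 * b, **{"B-tm": b})
    elif code is PatternCode.B_ABN_COMP_FL:
        c.update(B=b, FL=-b, RL=-b)
    elif code is PatternCode.B_ABN_COMP_MEM:
        c.update(B=b, **{"B-tm": -b})
    elif code is PatternCode.B_ABN_UNCOMP:
        c.update(B=b)
    elif code is PatternCode.NL_UNRESOLVED:
        c.update(NL=m)  # an NL response nothing in the trisomic brain accounts for
    elif code is PatternCode.SINGLE_RESPONDER:
        c.update(FL=m)
    else:  # pragma: no cover - enum is exhaustive
        raise AssertionError(code)
    return c


# Archetypes whose baseline magnitude defaults to a fraction of the NL
# magnitude so that the planted terms sum exactly to NL.
_DEFAULT_BASELINE_FRACTION = {
    PatternCode.B_COMP: 1.0,
    PatternCode.B_PLUS_FL: 0.5,
    PatternCode.BTM_PLUS_RL: 0.5,
    PatternCode.RL_PLUS_B: 0.5,
    PatternCode.RL_PLUS_B_PLUS_BTM: 1.0 / 3.0,
}


def archetype_to_effects(
    archetype: PatternCode | str,
    nl_magnitude: float = 20.0,
    baseline_magnitude: float | None = None,
) -> dict[str, float]:
    """True mean normalized abundance for each of the 8 groups.

    The means are constructed so that recomputing the nine pairwise contrasts
    from them reproduces the planted percent magnitudes exactly: e.g.
    ``B_PLUS_FL`` with ``nl_magnitude=40, baseline_magnitude=20`` yields
    B = +20%, FL = +20%, RL = +20% and NL = +40%.

    Magnitudes are percent differences on the linear scale and must be
    > -100 (a -100% contrast would require a zero mean).
    """
    try:
        code = PatternCode(archetype)
    except ValueError:
        valid = ", ".join(c.value for c in PatternCode)
        raise ValueError(f"unknown archetype {archetype!r}; valid codes: {valid}") from None
    if baseline_magnitude is None:
        baseline_magnitude = nl_magnitude * _DEFAULT_BASELINE_FRACTION.get(code, 0.0)
        if code in (
            PatternCode.B_ABN_COMP_FL,
            PatternCode.B_ABN_COMP_MEM,
            PatternCode.B_ABN_UNCOMP,
        ):
            baseline_magnitude = 20.0
    c = _archetype_contrasts(code, float(nl_magnitude), float(baseline_magnitude))
    for name, pct in c.items():
        if pct <= -100:
            raise ValueError(f"planted {name} contrast must be > -100%, got {pct}")
    r = {k: 1.0 + v / 100.0 for k, v in c.items()}
    means = {
        "c-SC-sal": 1.0,
        "c-CS-sal": r["NL"],
        "c-SC-mem": 1.0,  # no memantine effect planted in controls (B-cm = 0)
        "c-CS-mem": r["NL"],
        "t-SC-sal": r["B"],
        "t-CS-sal": r["B"] * r["FL"],
        "t-SC-mem": r["B"] * r["B-tm"],
        "t-CS-mem": r["B"] * r["B-tm"] * r["RL"],
    }
    return means


def effects_table(
    design: DesignSpec,
    assignments: Mapping[tuple[str, str, str], Mapping[str, float]] | None = None,
    default_archetype: PatternCode | str = PatternCode.STABLE,
) -> pd.DataFrame:
    """Build an effect table (one row per protein-instance, 8 group-mean columns).

    ``assignments`` maps (protein, region, fraction) to its 8 group means,
    e.g. from :func:`archetype_to_effects`; unassigned instances get the
    ``default_archetype`` (stable, all means equal).
    """
    base = archetype_to_effects(default_archetype, 0.0, 0.0)
    rows = []
    for protein in design.proteins:
        for region in design.regions:
            for fraction in design.fractions:
                key = (protein, region, fraction)
                means = dict(assignments[key]) if assignments and key in assignments else dict(base)
                rows.append({"protein": protein, "region": region, "fraction": fraction, **means})
    return pd.DataFrame(rows)


def contrasts_from_effects(means: Mapping[str, float]) -> dict[str, float]:
    """Recompute the nine pairwise percent contrasts implied by 8 group means."""
    from .comparisons import comparison_battery, percent_difference

    return {
        d.code: percent_difference(means[d.group_a.label], means[d.group_b.label])
        for d in comparison_battery()
    }


# ---------------------------------------------------------------------------
# Measurement simulation
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = [
    "protein", "region", "fraction", "genotype", "paradigm", "drug", "group",
    "mouse_id", "dilution_step", "replicate", "raw_intensity", "sypro_intensity",
]


def simulate_measurements(
    design: DesignSpec,
    effects: pd.DataFrame,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one complete measurement table for the design.

    Per spot: ``sypro`` carries the loading (halving down the dilution
    series); ``raw = mean * sypro * exp(e_mouse + e_dilution + e_spot)`` with
    the three log-normal effects drawn independently per protein-instance.
    Hence ``raw / sypro`` has expectation ~= the planted group mean at every
    dilution step, and equals it exactly when all SDs are zero.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    _, grid = build_design(design)

    eff = effects.set_index(["protein", "region", "fraction"])
    missing = [c for c in GROUP_LABELS if c not in eff.columns]
    if missing:
        raise ValueError(f"effects table lacks group columns: {missing}")

    # planted mean per spot, via (instance, group) lookup
    keys = pd.MultiIndex.from_frame(grid[["protein", "region", "fraction"]])
    try:
        inst_means = eff.loc[keys.unique()]
    except KeyError as e:
        raise ValueError(f"effects not defined for instance {e.args[0]}") from None

    long_eff = inst_means[list(GROUP_LABELS)].stack()
    long_eff.index.names = ["protein", "region", "fraction", "group"]
    grid = grid.merge(
        long_eff.rename("true_mean").reset_index(),
        on=["protein", "region", "fraction", "group"],
        how="left",
    )
    if grid["true_mean"].isna().any():
        bad = grid.loc[grid["true_mean"].isna(), ["protein", "region", "fraction"]].iloc[0]
        raise ValueError(f"effects not defined for instance {tuple(bad)}")
    if (grid["true_mean"] <= 0).any():
        raise ValueError("all true group means must be > 0")

    # nested noise, drawn per protein-instance
    inst_mouse = grid[["protein", "region", "fraction", "mouse_id"]]
    im_codes, _ = pd.factorize(pd.MultiIndex.from_frame(inst_mouse), sort=True)
    e_mouse = rng.normal(0.0, noise.sd_mouse, im_codes.max() + 1)[im_codes]

    imd = grid[["protein", "region", "fraction", "mouse_id", "dilution_step"]]
    imd_codes, _ = pd.factorize(pd.MultiIndex.from_frame(imd), sort=True)
    e_dil = rng.normal(0.0, noise.sd_dilution, imd_codes.max() + 1)[imd_codes]

    e_spot = rng.normal(0.0, noise.sd_replicate, len(grid))
    if noise.outlier_rate > 0:
        hit = rng.random(len(grid)) < noise.outlier_rate
        e_spot = np.where(hit, e_spot * noise.outlier_scale, e_spot)

    mean = grid["true_mean"].to_numpy(copy=True)
    if noise.low_signal_rate > 0:
        inst_codes, inst_uniques = pd.factorize(
            pd.MultiIndex.from_frame(grid[["protein", "region", "fraction"]]), sort=True
        )
        low = rng.random(len(inst_uniques)) < noise.low_signal_rate
        mean = np.where(low[inst_codes], noise.low_signal_value, mean)

    sypro = design.dilution_factor ** -(grid["dilution_step"].to_numpy() - 1.0)
    raw = mean * sypro * np.exp(e_mouse + e_dil + e_spot)

    out = grid[[c for c in MEASUREMENT_COLUMNS if c not in ("raw_intensity", "sypro_intensity")]].copy()
    out["raw_intensity"] = raw
    out["sypro_intensity"] = sypro
    return out


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_measurements(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
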