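"""Synthetic aligned-feature-table generator with ground truth.

Every pipeline stage can be exercised without instrument data by emulating
the three study designs the method is built around:

* an S9 incubation time course (0/2/6/24 h, duplicate biological
  replicates) with planted phase I/II products following first-order
  formation kinetics, a slowly declining parent, and time-independent
  nonspecific background features;
* a paired unlabeled/labeled experiment in which every planted metabolite of
  the precursor has a mass-shifted, co-eluting twin in the labeled run
  (with configurable label retention), while background features have no
  twin by construction;
* a cohort of subjects in one or more biofluids where a small exposed
  subgroup carries correlated parent + metabolite signals (a shared
  log-scale subject factor induces the parent–metabolite correlation the
  association networks rely on) and everyone carries background features.

All randomness flows from a single seed; identical configurations give
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import chem
from .chem import (
    ElementalFormula,
    IonSpecies,
    IsotopeLabelSpec,
    TransformationRule,
    ion_mz,
)
from .io import Feature, FeatureTable, LibraryEntry, SampleMeta

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PathwaySpec",
    "simulate_s9",
    "simulate_label_pair",
    "simulate_cohort",
    "library_from_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by all simulators.

    Defaults emulate a well-behaved Orbitrap-class acquisition: sub-ppm mass
    jitter, ~1 s retention-time jitter, log-normal intensities around 1e5
    counts, and the standard 0/2/6/24 h incubation schedule with duplicate
    biological replicates.
    """

    seed: int = 0
    n_background: int = 50
    ppm_jitter_sd: float = 0.5  # ppm on every emitted feature m/z
    rt_jitter_sd: float = 1.0  # s, between runs of the same analyte
    missing_rate: float = 0.0  # extra dropout applied to planted detections
    intensity_log_mean: float = np.log(1e5)
    intensity_log_sd: float = 0.7
    intensity_noise_cv: float = 0.05  # multiplicative per-measurement noise
    time_points_h: tuple[float, ...] = (0.0, 2.0, 6.0, 24.0)
    n_replicates: int = 2
    formation_rate_per_h: float = 0.05  # first-order product formation
    parent_decline_per_h: float = 0.02
    mz_range: tuple[float, float] = (85.0, 1275.0)
    rt_range: tuple[float, float] = (18.0, 300.0)  # void volume → run end
    # cohort-specific
    subject_factor_sd: float = 0.8
    factor_loading: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be a probability")
        for name in ("ppm_jitter_sd", "rt_jitter_sd", "intensity_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: roles, chains, formulas and exposure sets."""

    roles: dict[str, str]  # feature_id -> parent | product | background
    chains: dict[str, tuple[str, ...]]  # feature_id -> rule chain
    formulas: dict[str, ElementalFormula]
    theoretical_mz: dict[str, float]
    rts: dict[str, float]
    exposed: dict[str, frozenset[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)  # feature_id -> label
    precursor_of: dict[str, str] = field(default_factory=dict)

    def planted_ids(self) -> list[str]:
        return [f for f, r in self.roles.items() if r != "background"]

    def product_ids(self) -> list[str]:
        return [f for f, r in self.roles.items() if r == "product"]

    def background_ids(self) -> list[str]:
        return [f for f, r in self.roles.items() if r == "background"]


def _jittered_mz(rng: np.random.Generator, mz: float, ppm_sd: float) -> float:
    return mz * (1.0 + rng.normal(0.0, ppm_sd) * 1e-6) if ppm_sd > 0 else mz


def _noisy(rng: np.random.Generator, value: float, cv: float) -> float:
    if value <= 0:
        return 0.0
    if cv <= 0:
        return value
    return max(0.0, value * (1.0 + rng.normal(0.0, cv)))


def _resolve_chain(
    parent: ElementalFormula,
    chain: Sequence[str],
    rules: Mapping[str, TransformationRule],
) -> ElementalFormula:
    f = parent
    for name in chain:
        f = chem.apply_transformation(f, rules[name])
    return f


def _timecourse_samples(config: SimulationConfig) -> list[SampleMeta]:
    return [
        SampleMeta(sample_id=f"t{t:g}_r{r}", time_h=t, replicate=r)
        for t in config.time_points_h
        for r in range(1, config.n_replicates + 1)
    ]


def simulate_s9(
    parent: ElementalFormula,
    chains: Sequence[Sequence[str]],
    config: SimulationConfig,
    adduct: IonSpecies = chem.M_PLUS_H,
    rules: Sequence[TransformationRule] | None = None,
    method: str = "HILIC+",
    label: IsotopeLabelSpec | None = None,
    labels_retained: Sequence[int] | None = None,
    _rng: np.random.Generator | None = None,
    _shared_rts: Mapping[str, float] | None = None,
) -> tuple[FeatureTable, GroundTruth]:
    """Emulate one S9 incubation time course.

    Each entry of ``chains`` is a sequence of rule names applied to the
    parent; the corresponding product is absent at t = 0 and rises as
    ``1 − exp(−k·t)``.  The parent declines mildly (substrate consumption).
    Background features are time-independent.  With ``label`` set the
    experiment is the isotope-labeled replicate: the parent carries all
    labels and product i retains ``labels_retained[i]`` of them.
    """
    if rules is None:
        rules = chem.default_rules()
    by_name = chem.rules_by_name(rules)
    rng = _rng if _rng is not None else np.random.default_rng(config.seed)
    samples = _timecourse_samples(config)
    shared_rts = _shared_rts if _shared_rts is not None else {}

    def rt_for(key: str) -> float:
        base = shared_rts.get(key)
        if base is None:
            base = float(rng.uniform(*config.rt_range))
            shared_rts[key] = base
        if config.rt_jitter_sd > 0:
            return base + float(rng.normal(0.0, config.rt_jitter_sd))
        return base

    features: list[Feature] = []
    truth = GroundTruth({}, {}, {}, {}, {})

    def plant(fid: str, formula: ElementalFormula, role: str,
              chain: tuple[str, ...], profile: Mapping[str, float]) -> None:
        theo = ion_mz(formula, adduct)
        mz = _jittered_mz(rng, theo, config.ppm_jitter_sd)
        rt = rt_for(fid)
        intens: dict[str, float] = {}
        for s in samples:
            v = profile[s.sample_id]
            if v <= 0:
                continue  # genuinely absent -> missing cell
            if config.missing_rate > 0 and rng.random() < config.missing_rate:
                continue
            intens[s.sample_id] = _noisy(rng, v, config.intensity_noise_cv)
        features.append(Feature(fid, mz, rt, intens))
        truth.roles[fid] = role
        truth.chains[fid] = chain
        truth.formulas[fid] = formula
        truth.theoretical_mz[fid] = theo
        truth.rts[fid] = rt

    # parent
    parent_formula = parent
    if label is not None:
        parent_formula = parent.with_labels(label.heavy_isotope, label.n_labels)
    amp_parent = float(np.exp(rng.normal(config.intensity_log_mean + 2.0,
                                         config.intensity_log_sd)))
    plant(
        "parent",
        parent_formula,
        "parent",
        (),
        {
            s.sample_id: amp_parent * np.exp(-config.parent_decline_per_h * s.time_h)
            for s in samples
        },
    )

    # products
    for i, chain in enumerate(chains):
        chain = tuple(chain)
        formula = _resolve_chain(parent, chain, by_name)
        if label is not None:
            retained = (
                labels_retained[i]
                if labels_retained is not None
                else label.n_labels
            )
            formula = formula.with_labels(label.heavy_isotope, retained)
        amp = float(np.exp(rng.normal(config.intensity_log_mean,
                                      config.intensity_log_sd)))
        k = config.formation_rate_per_h
        plant(
            f"product_{i}_{'+'.join(chain)}",
            formula,
            "product",
            chain,
            {
                s.sample_id: amp * (1.0 - np.exp(-k * s.time_h))
                for s in samples
            },
        )

    # nonspecific background: present at every time point
    for i in range(config.n_background):
        fid = f"bg_{i:04d}"
        mz = float(rng.uniform(*config.mz_range))
        rt = float(rng.uniform(*config.rt_range))
        amp = float(np.exp(rng.normal(config.intensity_log_mean,
                                      config.intensity_log_sd)))
        intens = {
            s.sample_id: _noisy(rng, amp, config.intensity_noise_cv)
            for s in samples
        }
        features.append(Feature(fid, mz, rt, intens))
        truth.roles[fid] = "background"
        truth.rts[fid] = rt
    return FeatureTable(features, samples, method=method), truth


def simulate_label_pair(
    parent: ElementalFormula,
    label: IsotopeLabelSpec,
    chains_with_retention: Sequence[tuple[Sequence[str], int]],
    config: SimulationConfig,
    adduct: IonSpecies = chem.M_PLUS_H,
    rules: Sequence[TransformationRule] | None = None,
    method: str = "HILIC+",
) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Paired unlabeled/labeled incubations of the same precursor.

    Planted products co-elute across the two runs (same base retention time
    up to run-to-run jitter) and the labeled forms are shifted by
    ``retained × per_label_delta``.  Background features are drawn
    independently per run, so none has a mass-shifted twin.
    """
    rng = np.random.default_rng(config.seed)
    chains = [c for c, _ in chains_with_retention]
    retained = [k for _, k in chains_with_retention]
    for k in retained:
        if not 0 <= k <= label.n_labels:
            raise ValueError(f"labels retained {k} outside [0, {label.n_labels}]")
    shared_rts: dict[str, float] = {}
    unlabeled, truth_u = simulate_s9(
        parent, chains, config, adduct=adduct, rules=rules, method=method,
        _rng=rng, _shared_rts=shared_rts,
    )
    labeled, truth_l = simulate_s9(
        parent, chains, config, adduct=adduct, rules=rules, method=method,
        label=label, labels_retained=retained, _rng=rng,
        _shared_rts=shared_rts,
    )
    truth = GroundTruth(
        roles=truth_u.roles,
        chains=truth_u.chains,
        formulas=truth_u.formulas,
        theoretical_mz=truth_u.theoretical_mz,
        rts=truth_u.rts,
    )
    truth.names = {
        fid: f"labeled:{truth_l.theoretical_mz.get(fid, float('nan')):.4f}"
        for fid in truth_l.roles
    }
    # keep the labeled-side truth reachable for assertions
    truth.labeled = truth_l  # type: ignore[attr-defined]
    return unlabeled, labeled, truth


@dataclass(frozen=True)
class PathwaySpec:
    """A xenobiotic exposure pathway to plant in a cohort.

    ``metabolites`` maps metabolite name → chain of transformation-rule
    names applied to the parent formula.
    """

    precursor: str
    parent_formula: ElementalFormula
    metabolites: Mapping[str, tuple[str, ...]]
    n_exposed: int
    adduct: IonSpecies = chem.M_PLUS_H


def simulate_cohort(
    pathways: Sequence[PathwaySpec],
    n_samples: int = 120,
    biofluids: Sequence[str] = ("plasma",),
    config: SimulationConfig = SimulationConfig(),
    rules: Sequence[TransformationRule] | None = None,
    method: str = "HILIC+",
) -> tuple[dict[str, FeatureTable], GroundTruth]:
    """Emulate a cohort with a small exposed subgroup per pathway.

    The exposed sample set for a pathway is drawn once and shared across
    biofluids (a person carrying an exposure carries it in both plasma and
    urine).  Within an exposed sample, parent and metabolite log-intensities
    share a subject-level factor, so pathway members are correlated across
    the cohort; unexposed samples have no signal at all for pathway features.
    """
    if rules is None:
        rules = chem.default_rules()
    by_name = chem.rules_by_name(rules)
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"S{i:03d}" for i in range(1, n_samples + 1)]

    truth = GroundTruth({}, {}, {}, {}, {})
    plan: list[tuple[str, str, ElementalFormula, IonSpecies, str]] = []
    for pw in pathways:
        if pw.n_exposed > n_samples:
            raise ValueError(
                f"{pw.precursor}: n_exposed {pw.n_exposed} > n_samples {n_samples}"
            )
        exposed = rng.choice(n_samples, size=pw.n_exposed, replace=False)
        truth.exposed[pw.precursor] = frozenset(sample_ids[i] for i in exposed)
        members: list[tuple[str, ElementalFormula, tuple[str, ...]]] = [
            (pw.precursor, pw.parent_formula, ())
        ]
        for name, chain in pw.metabolites.items():
            members.append(
                (name, _resolve_chain(pw.parent_formula, tuple(chain), by_name),
                 tuple(chain))
            )
        for name, formula, chain in members:
            fid = f"{pw.precursor}/{name}"
            role = "parent" if name == pw.precursor else "product"
            truth.roles[fid] = role
            truth.chains[fid] = chain
            truth.formulas[fid] = formula
            truth.theoretical_mz[fid] = ion_mz(formula, pw.adduct)
            truth.names[fid] = name
            truth.precursor_of[fid] = pw.precursor
            plan.append((fid, name, formula, pw.adduct, pw.precursor))

    # per-biofluid subject factors: within a fluid, pathway members share it
    tables: dict[str, FeatureTable] = {}
    for fluid in biofluids:
        factors = rng.normal(0.0, config.subject_factor_sd, size=n_samples)
        samples = [
            SampleMeta(sample_id=s, biofluid=fluid) for s in sample_ids
        ]
        features: list[Feature] = []
        for fid, name, formula, adduct, precursor in plan:
            theo = truth.theoretical_mz[fid]
            mz = _jittered_mz(rng, theo, config.ppm_jitter_sd)
            rt = float(rng.uniform(*config.rt_range))
            truth.rts[f"{fluid}:{fid}"] = rt
            base_log = rng.normal(config.intensity_log_mean,
                                  config.intensity_log_sd)
            exposed = truth.exposed[precursor]
            intens: dict[str, float] = {}
            for j, s in enumerate(sample_ids):
                if s not in exposed:
                    continue
                if config.missing_rate > 0 and rng.random() < config.missing_rate:
                    continue
                logv = (
                    base_log
                    + config.factor_loading * factors[j]
                    + rng.normal(0.0, config.intensity_noise_cv + 1e-12)
                )
                intens[s] = float(np.exp(logv))
            features.append(Feature(fid, mz, rt, intens))
        for i in range(config.n_background):
            fid = f"bg_{i:04d}"
            mz = float(rng.uniform(*config.mz_range))
            rt = float(rng.uniform(*config.rt_range))
            amp = float(np.exp(rng.normal(config.intensity_log_mean,
                                          config.intensity_log_sd)))
            intens = {
                s: _noisy(rng, amp, max(config.intensity_noise_cv, 0.3))
                for s in sample_ids
            }
            features.append(Feature(fid, mz, rt, intens))
            truth.roles.setdefault(fid, "background")
        tables[fluid] = FeatureTable(features, samples, method=method)
    return tables, truth


def library_from_truth(
    truth: GroundTruth,
    biofluid: str,
    method: str = "HILIC+",
    adduct: IonSpecies = chem.M_PLUS_H,
    msi_level: int = 2,
) -> list[LibraryEntry]:
    """Library entries for the planted pathway members of a cohort fluid.

    Emulates the S9-derived library the real workflow would carry: theoretical
    m/z from the planted formula, retention time of the planted feature.
    """
    entries = []
    for fid, role in truth.roles.items():
        if role == "background":
            continue
        precursor = truth.precursor_of.get(fid)
        if precursor is None:
            continue
        rt_key = f"{biofluid}:{fid}"
        if rt_key not in truth.rts:
            continue
        entries.append(
            LibraryEntry(
                precursor=precursor,
                metabolite_name=truth.names[fid],
                formula=truth.formulas[fid],
                theoretical_mz=truth.theoretical_mz[fid],
                adduct=adduct,
                method=method,
                rt=truth.rts[rt_key],
                evidence_criteria=frozenset(
                    {"xenobiotic_specific_presence", "mass_match",
                     "time_dependence"}
                ),
                msi_level=msi_level,
            )
        )
    return entries
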