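"""Metabolite discovery from liver-S9 incubation time courses.

An S9 screen incubates a xenobiotic with pooled liver S9 fraction (phase I +
phase II enzyme activities) and samples the reaction at several time points
(default 0/2/6/24 h).  Enzyme-generated products are absent at time zero and
rise with incubation time, so discovery is:

1. a time-trend filter — Pearson correlation of replicate-averaged intensity
   against incubation time, requiring r > 0.9 and no signal at t = 0;
2. annotation of passing features against the accurate masses of
   rule-enumerated expected metabolites of the parent (±3 ppm);
3. conversion of annotated features into library entries carrying their
   satisfied identification criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import chem
from .chem import (
    ElementalFormula,
    IonSpecies,
    ProductCandidate,
    TransformationRule,
    ion_mz,
    ppm_error,
)
from .io import FeatureTable, LibraryEntry, Spectrum

__all__ = [
    "TimecourseResult",
    "ProductAnnotation",
    "CoverageReport",
    "time_trend_filter",
    "annotate_expected",
    "coverage_report",
    "build_library_entries",
]


@dataclass(frozen=True)
class TimecourseResult:
    """Time-trend verdict for one feature."""

    feature_id: str
    pearson_r_vs_time: float  # NaN when intensity variance is zero
    detected_at_t0: bool
    passes: bool


def time_trend_filter(
    table: FeatureTable,
    r_min: float = 0.9,
    t0_threshold: float = 0.0,
) -> list[TimecourseResult]:
    """Flag features whose intensity rises with incubation time.

    Replicates are averaged per time point and missing intensities imputed as
    zero before correlating raw intensity against time in hours.  A feature
    passes iff r > ``r_min`` and its averaged t = 0 intensity is at or below
    ``t0_threshold`` ("not detected at time 0").  Zero-variance features have
    undefined r and fail.
    """
    means = table.mean_by_time()  # features × hours; needs time_h metadata
    times = np.array(sorted(means.columns), dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 distinct time points")
    means = means[list(times)]
    x = times - times.mean()
    sx = np.sqrt((x**2).sum())
    vals = means.to_numpy(dtype=float)
    y = vals - vals.mean(axis=1, keepdims=True)
    sy = np.sqrt((y**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (y @ x) / (sy * sx)
    has_t0 = 0.0 in times
    t0_idx = int(np.where(times == 0.0)[0][0]) if has_t0 else None
    out = []
    for i, fid in enumerate(means.index):
        ri = float(r[i])
        at_t0 = bool(has_t0 and vals[i, t0_idx] > t0_threshold)
        passes = bool(np.isfinite(ri) and ri > r_min and not at_t0)
        out.append(TimecourseResult(str(fid), ri, at_t0, passes))
    return out


@dataclass(frozen=True)
class ProductAnnotation:
    """A passing feature matched to an enumerated expected metabolite."""

    feature_id: str
    observed_mz: float
    rt: float
    product: ProductCandidate
    theoretical_mz: float
    ppm: float

    @property
    def chain(self) -> tuple[str, ...]:
        return self.product.chain


def annotate_expected(
    table: FeatureTable,
    passing: Sequence[TimecourseResult],
    parent: ElementalFormula,
    rules: Sequence[TransformationRule] | None = None,
    depth: int = 2,
    adduct: IonSpecies = chem.M_PLUS_H,
    ppm_tol: float = 3.0,
) -> list[ProductAnnotation]:
    """Match time-trend-passing features to expected metabolite masses.

    Expected products are enumerated by applying up to ``depth`` sequential
    transformation rules to the parent formula; a feature matches a product
    when its m/z is within ``ppm_tol`` of the product's ion m/z.  A feature
    may match several mass-equivalent products; all are reported, sorted by
    absolute ppm error.
    """
    if rules is None:
        rules = chem.default_rules()
    products = chem.enumerate_products(parent, rules, depth)
    theo = [(p, ion_mz(p.formula, adduct)) for p in products]
    out: list[ProductAnnotation] = []
    for res in passing:
        if not res.passes:
            continue
        mz = table.mz(res.feature_id)
        rt = table.rt(res.feature_id)
        hits = []
        for p, t in theo:
            err = ppm_error(mz, t)
            if abs(err) <= ppm_tol:
                hits.append(ProductAnnotation(res.feature_id, mz, rt, p, t, err))
        hits.sort(key=lambda a: abs(a.ppm))
        out.extend(hits)
    return out


@dataclass(frozen=True)
class CoverageReport:
    """Fraction of expected metabolites detected, per parent and pooled."""

    per_parent: Mapping[str, float]
    overall: float
    detected: Mapping[str, tuple[str, ...]]  # parent -> detected product names


def coverage_report(
    expected: Mapping[str, Sequence[tuple[str, float]]],
    annotated_mzs: Mapping[str, Sequence[float]],
    ppm_tol: float = 3.0,
) -> CoverageReport:
    """Detection coverage of literature-expected metabolites.

    ``expected`` maps parent → [(product name, theoretical ion m/z)];
    ``annotated_mzs`` maps parent → observed m/z of annotated features.  A
    product counts as detected when any annotated m/z lies within ``ppm_tol``.
    """
    if not expected or all(len(v) == 0 for v in expected.values()):
        raise ValueError("expected-product list is empty")
    per_parent: dict[str, float] = {}
    detected: dict[str, tuple[str, ...]] = {}
    n_total = n_hit = 0
    for parent, products in expected.items():
        obs = list(annotated_mzs.get(parent, ()))
        hits = [
            name
            for name, mz_t in products
            if any(abs(ppm_error(o, mz_t)) <= ppm_tol for o in obs)
        ]
        detected[parent] = tuple(hits)
        per_parent[parent] = len(hits) / len(products) if products else 0.0
        n_total += len(products)
        n_hit += len(hits)
    return CoverageReport(per_parent, n_hit / n_total, detected)


def build_library_entries(
    annotations: Sequence[ProductAnnotation],
    precursor: str,
    adduct: IonSpecies,
    method: str,
    ms2_store: Mapping[str, Spectrum] | None = None,
    name_by_chain: Mapping[tuple[str, ...], str] | None = None,
) -> list[LibraryEntry]:
    """Turn annotated S9 products into metabolite library entries.

    Every entry carries the S9 evidence criteria it satisfied: presence only
    in xenobiotic-added samples, accurate-mass match, and time-dependent
    formation; an MS2 spectrum, when collected, is a fourth criterion and
    lifts the record to MSI level 2 (spectral match without a purified
    standard).  Without MS2 the entry stays level 3 (tentative).
    """
    ms2_store = ms2_store or {}
    entries = []
    seen: set[tuple[str, tuple[str, ...]]] = set()
    for a in annotations:
        key = (a.feature_id, a.chain)
        if key in seen:
            continue
        seen.add(key)
        criteria = {"xenobiotic_specific_presence", "mass_match",
                    "time_dependence"}
        ms2 = ms2_store.get(a.feature_id)
        if ms2 is not None:
            criteria.add("ms2_match")
        if name_by_chain and a.chain in name_by_chain:
            name = name_by_chain[a.chain]
        else:
            name = f"{precursor} {'+'.join(a.chain)}"
        entries.append(
            LibraryEntry(
                precursor=precursor,
                metabolite_name=name,
                formula=a.product.formula,
                theoretical_mz=a.theoretical_mz,
                adduct=adduct,
                method=method,
                rt=a.rt,
                ms2=ms2,
                evidence_criteria=frozenset(criteria),
                msi_level=2 if ms2 is not None else 3,
            )
        )
    return entries
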