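"""Stable-isotope-assisted confirmation of candidate metabolites.

When the same incubation is run with an unlabeled and an isotopically labeled
precursor (13C3-caffeine, d9-bupropion, ...), every genuine metabolite of the
precursor must appear in the labeled run shifted by the mass of its retained
heavy atoms and co-eluting with the unlabeled form.  Deuterium can be lost
during biotransformation (a d9 precursor can give a d8 hydroxylation
product), so pairing searches over a range of retained-label counts; 13C
skeletons are stable and retain all labels by default.  Time-trend-passing
features without a co-eluting mass-shifted twin are nonspecific reaction
products, not metabolites of the test compound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .chem import IsotopeLabelSpec, ppm_error
from .io import FeatureTable
from .s9 import TimecourseResult

__all__ = [
    "IsotopePair",
    "pair_labeled",
    "filter_nonspecific",
    "isomer_ratio",
]


@dataclass(frozen=True)
class IsotopePair:
    """An unlabeled feature matched to its isotope-labeled counterpart."""

    unlabeled_feature_id: str
    labeled_feature_id: str
    labels_retained: int
    delta_mz_observed: float
    delta_rt: float
    ppm_error_vs_expected: float


def _passing_ids(results: Sequence[TimecourseResult]) -> list[str]:
    return [r.feature_id for r in results if r.passes]


def pair_labeled(
    unlabeled_table: FeatureTable,
    unlabeled_passing: Sequence[TimecourseResult],
    labeled_table: FeatureTable,
    labeled_passing: Sequence[TimecourseResult],
    label: IsotopeLabelSpec,
    max_label_loss: int | None = None,
    rt_tol_s: float = 5.0,
    ppm_tol: float = 3.0,
) -> list[IsotopePair]:
    """Pair unlabeled and labeled time-trend-passing features by mass shift.

    For each unlabeled feature and each plausible retained-label count k
    (``n_labels − max_label_loss`` … ``n_labels``), the labeled run is
    searched for a feature at ``mz + k × per_label_delta`` within ``ppm_tol``
    (evaluated on the labeled m/z) that co-elutes within ``rt_tol_s``.  The
    best match per k (smallest |ppm|) is kept; matches at several k are all
    reported — the ambiguity is chemically meaningful (label position).

    ``max_label_loss`` defaults per isotope: 0 for 13C, ``n_labels`` for 2H.
    """
    if max_label_loss is None:
        max_label_loss = label.default_max_label_loss
    if max_label_loss < 0 or max_label_loss > label.n_labels:
        raise ValueError(
            f"max_label_loss={max_label_loss} outside [0, {label.n_labels}]"
        )
    labeled_ids = _passing_ids(labeled_passing)
    labeled = [
        (fid, labeled_table.mz(fid), labeled_table.rt(fid))
        for fid in labeled_ids
    ]
    pairs: list[IsotopePair] = []
    for res in unlabeled_passing:
        if not res.passes:
            continue
        fid = res.feature_id
        mz_u = unlabeled_table.mz(fid)
        rt_u = unlabeled_table.rt(fid)
        for k in range(label.n_labels - max_label_loss, label.n_labels + 1):
            expected = mz_u + k * label.per_label_delta
            best: IsotopePair | None = None
            for lid, mz_l, rt_l in labeled:
                drt = rt_l - rt_u
                if abs(drt) > rt_tol_s:
                    continue
                err = ppm_error(mz_l, expected)
                if abs(err) > ppm_tol:
                    continue
                cand = IsotopePair(fid, lid, k, mz_l - mz_u, drt, err)
                if best is None or abs(cand.ppm_error_vs_expected) < abs(
                    best.ppm_error_vs_expected
                ):
                    best = cand
            if best is not None:
                pairs.append(best)
    return pairs


def filter_nonspecific(
    unlabeled_passing: Sequence[TimecourseResult],
    pairs: Sequence[IsotopePair],
) -> tuple[list[str], list[str]]:
    """Split passing features into (specific, nonspecific) by label evidence.

    A feature is specific to the test compound iff it appears in at least one
    isotope pair; everything else rose with time for reasons unrelated to the
    precursor.  The partition is exhaustive and disjoint.
    """
    paired = {p.unlabeled_feature_id for p in pairs}
    specific, nonspecific = [], []
    for r in unlabeled_passing:
        if not r.passes:
            continue
        (specific if r.feature_id in paired else nonspecific).append(r.feature_id)
    return specific, nonspecific


def isomer_ratio(
    intensity_a: float, intensity_b: float
) -> tuple[float, bool]:
    """Peak-intensity ratio a/b between two isomeric products.

    Used to compare competing products at a fixed time point (e.g. a major
    heterocyclic hydroxylation product ~10× its ring-hydroxylated isomer).
    Returns ``(ratio, is_infinite)``; a zero denominator is flagged rather
    than raised.
    """
    if intensity_b == 0:
        return math.inf, True
    return intensity_a / intensity_b, False
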