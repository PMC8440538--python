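"""Library matching and confidence-level assignment for study samples.

Study-sample features are matched against the enzyme-generated metabolite
library on accurate mass (±3 ppm) and co-elution (±5 s).  Identification
confidence then follows an orthogonal-criteria scheme extending the MSI
levels to situations where no authentic standard exists:

* accurate-mass match,
* co-elution with the enzyme-generated metabolite,
* detection only in samples with documented exposure (when exposure records
  exist; otherwise this criterion is simply not assessed),
* co-occurrence of at least one other related metabolite of the same
  precursor in the same sample,
* an MS2 spectral match, when spectra could be collected, as a further
  criterion.

Satisfying at least three criteria is level 1 confidence, exactly two is
level 2, and a single criterion is level 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ppm_error
from .io import FeatureTable, LibraryEntry, Spectrum, detection_call

__all__ = [
    "LibraryMatch",
    "CriterionFlags",
    "IdentificationResult",
    "PresenceMatrix",
    "match_library",
    "presence_matrix",
    "assign_confidence",
    "ms2_match",
    "cross_biofluid_concordance",
]


@dataclass(frozen=True)
class LibraryMatch:
    feature_id: str
    entry: LibraryEntry
    ppm_error: float
    delta_rt: float


def match_library(
    table: FeatureTable,
    library: Sequence[LibraryEntry],
    ppm_tol: float = 3.0,
    rt_tol_s: float | None = 5.0,
) -> list[LibraryMatch]:
    """All (feature, library entry) pairs within the mass and RT windows.

    Only entries acquired with the table's chromatographic method are
    compared.  ``rt_tol_s=None`` disables the RT gate (mass-only lookup, e.g.
    against entries from the other method); matches for one entry are ranked
    by |ppm| then |Δrt|.
    """
    mzs = table.features["mz"].to_numpy(dtype=float)
    rts = table.features["rt"].to_numpy(dtype=float)
    fids = list(table.features.index)
    out: list[LibraryMatch] = []
    for entry in library:
        if entry.method != table.method:
            continue
        errs = (mzs - entry.theoretical_mz) / entry.theoretical_mz * 1e6
        drts = rts - entry.rt
        ok = np.abs(errs) <= ppm_tol
        if rt_tol_s is not None:
            ok &= np.abs(drts) <= rt_tol_s
        hits = [
            LibraryMatch(fids[i], entry, float(errs[i]), float(drts[i]))
            for i in np.nonzero(ok)[0]
        ]
        hits.sort(key=lambda m: (abs(m.ppm_error), abs(m.delta_rt)))
        out.extend(hits)
    return out


@dataclass
class PresenceMatrix:
    """Detection calls and min–max scaled relative abundances.

    Rows are (precursor, metabolite name) pairs; columns are samples.
    ``relative`` rescales each row over its detected cells to [0, 1] (max
    intensity → 1); a row with a single distinct intensity maps to 1.
    """

    detected: pd.DataFrame  # bool
    relative: pd.DataFrame  # float, NaN where not detected
    feature_of: Mapping[tuple[str, str], str]
    entry_of: Mapping[tuple[str, str], LibraryEntry]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.detected.columns)

    def pathway_positive(self) -> pd.DataFrame:
        """Precursor × sample: any related metabolite detected."""
        if self.detected.empty:
            return pd.DataFrame()
        return self.detected.groupby(level=0).any()


def presence_matrix(
    matches: Sequence[LibraryMatch],
    table: FeatureTable,
    min_intensity: float = 0.0,
) -> PresenceMatrix:
    """Build the (precursor, metabolite) × sample detection matrix.

    When several features match one entry the best-ranked one (first in
    ``matches``) represents it.
    """
    feature_of: dict[tuple[str, str], str] = {}
    entry_of: dict[tuple[str, str], LibraryEntry] = {}
    for m in matches:
        key = (m.entry.precursor, m.entry.metabolite_name)
        if key not in feature_of:
            feature_of[key] = m.feature_id
            entry_of[key] = m.entry
    if not feature_of:
        empty = pd.DataFrame(columns=table.sample_ids)
        return PresenceMatrix(empty, empty.copy(), {}, {})
    rows = sorted(feature_of)
    det = pd.DataFrame(
        False, index=pd.MultiIndex.from_tuples(rows, names=["precursor", "metabolite"]),
        columns=table.sample_ids,
    )
    rel = pd.DataFrame(np.nan, index=det.index, columns=det.columns)
    for key in rows:
        fid = feature_of[key]
        vals = table.intensities.loc[fid]
        detected = vals.map(lambda v: detection_call(
            None if pd.isna(v) else float(v), min_intensity))
        det.loc[key, :] = detected.to_numpy(dtype=bool)
        pos = vals[detected.to_numpy(dtype=bool)].astype(float)
        if len(pos):
            lo, hi = pos.min(), pos.max()
            scaled = (pos - lo) / (hi - lo) if hi > lo else pos * 0 + 1.0
            rel.loc[key, scaled.index] = scaled
    return PresenceMatrix(det, rel, feature_of, entry_of)


@dataclass(frozen=True)
class CriterionFlags:
    """Orthogonal identification criteria; ``None`` means not assessed."""

    mass_match: bool
    rt_coelution: bool
    exposure_specific_presence: bool | None
    co_occurrence: bool
    ms2_match: bool | None

    @property
    def n_satisfied(self) -> int:
        return sum(
            1
            for v in (
                self.mass_match,
                self.rt_coelution,
                self.exposure_specific_presence,
                self.co_occurrence,
                self.ms2_match,
            )
            if v is True
        )

    @property
    def confidence_level(self) -> int:
        n = self.n_satisfied
        if n >= 3:
            return 1
        if n == 2:
            return 2
        if n == 1:
            return 3
        raise ValueError("no criterion satisfied: not an identification")


@dataclass(frozen=True)
class IdentificationResult:
    entry: LibraryEntry
    sample_id: str
    feature_id: str
    ppm_error: float
    delta_rt: float
    criteria: CriterionFlags

    @property
    def confidence_level(self) -> int:
        return self.criteria.confidence_level


def assign_confidence(
    matches: Sequence[LibraryMatch],
    presence: PresenceMatrix,
    exposures: Mapping[str, set[str]] | None = None,
    ms2_flags: Mapping[tuple[str, str], bool] | None = None,
    ppm_tol: float = 3.0,
    rt_tol_s: float = 5.0,
) -> list[IdentificationResult]:
    """One identification per (matched metabolite, sample where detected).

    Criteria: accurate mass within ``ppm_tol``; co-elution within
    ``rt_tol_s``; exposure-specific presence (assessed only when
    ``exposures`` maps the precursor to its documented-exposure sample set:
    true iff every sample the metabolite is detected in is exposed);
    co-occurrence of ≥1 other related metabolite of the same precursor in the
    same sample; MS2 match where assessed (``ms2_flags`` keyed like presence
    rows).  The criterion count sets the confidence level (≥3 → 1, 2 → 2,
    1 → 3).
    """
    best: dict[tuple[str, str], LibraryMatch] = {}
    for m in matches:
        key = (m.entry.precursor, m.entry.metabolite_name)
        best.setdefault(key, m)
    results: list[IdentificationResult] = []
    det = presence.detected
    for key, m in best.items():
        if key not in det.index:
            continue
        row = det.loc[key]
        detected_samples = [s for s in det.columns if bool(row[s])]
        if exposures is not None and m.entry.precursor in exposures:
            exposed = set(exposures[m.entry.precursor])
            exposure_ok: bool | None = set(detected_samples) <= exposed
        else:
            exposure_ok = None
        siblings = det.loc[det.index.get_level_values(0) == key[0]]
        ms2_flag = None if ms2_flags is None else ms2_flags.get(key)
        for s in detected_samples:
            n_related = int(siblings[s].sum()) - 1  # other metabolites, same sample
            flags = CriterionFlags(
                mass_match=abs(m.ppm_error) <= ppm_tol,
                rt_coelution=abs(m.delta_rt) <= rt_tol_s,
                exposure_specific_presence=exposure_ok,
                co_occurrence=n_related >= 1,
                ms2_match=ms2_flag,
            )
            results.append(
                IdentificationResult(
                    m.entry, s, m.feature_id, m.ppm_error, m.delta_rt, flags
                )
            )
    return results


def ms2_match(
    observed: Spectrum,
    reference: Spectrum,
    fragment_ppm_tol: float = 10.0,
    min_cosine: float = 0.7,
) -> tuple[float, bool]:
    """Cosine similarity between two MS2 peak lists, greedily matched.

    Candidate fragment pairs within ``fragment_ppm_tol`` are accepted
    greedily in order of increasing mass discrepancy, each peak used at most
    once; the score is the cosine of the matched intensity vectors against
    the full spectrum norms.  Returns ``(score, score >= min_cosine)``.
    """
    if not observed.peaks or not reference.peaks:
        raise ValueError("cannot match an empty spectrum")
    a_mz, a_int = observed.mzs, observed.intensities
    b_mz, b_int = reference.mzs, reference.intensities
    cands = []
    for i, ma in enumerate(a_mz):
        for j, mb in enumerate(b_mz):
            err = abs(ppm_error(ma, mb))
            if err <= fragment_ppm_tol:
                cands.append((err, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += a_int[i] * b_int[j]
    denom = math.sqrt((a_int**2).sum()) * math.sqrt((b_int**2).sum())
    score = dot / denom if denom > 0 else 0.0
    return score, score >= min_cosine


def cross_biofluid_concordance(
    matrix_a: PresenceMatrix,
    matrix_b: PresenceMatrix,
) -> pd.DataFrame:
    """Per-precursor sample overlap between two biofluids.

    Both matrices must cover the same samples (paired plasma/urine).  A
    sample is pathway-positive in a fluid when any related metabolite of the
    precursor is detected there.  Returns counts of samples positive in both
    fluids, in either only, and in neither.
    """
    sa, sb = set(matrix_a.sample_ids), set(matrix_b.sample_ids)
    if sa != sb:
        raise ValueError("sample sets differ between biofluids")
    pa, pb = matrix_a.pathway_positive(), matrix_b.pathway_positive()
    precursors = sorted(set(pa.index) | set(pb.index))
    samples = sorted(sa)
    rows = []
    for p in precursors:
        in_a = set(s for s in samples if p in pa.index and bool(pa.loc[p, s]))
        in_b = set(s for s in samples if p in pb.index and bool(pb.loc[p, s]))
        rows.append(
            {
                "precursor": p,
                "both": len(in_a & in_b),
                "only_first": len(in_a - in_b),
                "only_second": len(in_b - in_a),
                "neither": len(samples) - len(in_a | in_b),
            }
        )
    return pd.DataFrame(rows).set_index("precursor")
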