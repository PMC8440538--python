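"""Data model and text I/O for aligned MS1 feature tables, metabolite
libraries, and MS2 peak lists.

A feature table is the standard aligned-LC-MS export shape: one row per
feature (``feature_id, mz, rt``) and one intensity column per sample, with a
companion sample-metadata table keyed by ``sample_id``.  Retention time is in
seconds throughout; readers accept a minutes flag and convert.

Missing intensities (blank cells) and explicit zeros are stored distinctly —
alignment software emits both — but a detection call treats both as "not
detected".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import chem
from .chem import ElementalFormula, IonSpecies, ppm_error

__all__ = [
    "Feature",
    "SampleMeta",
    "FeatureTable",
    "Spectrum",
    "LibraryEntry",
    "read_feature_table",
    "write_feature_table",
    "read_library",
    "write_library",
    "read_spectrum",
    "write_spectrum",
    "qc_check",
    "detection_call",
]

_META_COLUMNS = ["group", "time_h", "label_state", "biofluid", "replicate"]


@dataclass(frozen=True)
class Feature:
    """One aligned MS1 feature: m/z, retention time (s), per-sample intensity."""

    feature_id: str
    mz: float
    rt: float
    intensities: Mapping[str, float]  # missing samples simply absent

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature {self.feature_id}: m/z must be positive")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: rt must be >= 0")
        for s, v in self.intensities.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(
                    f"feature {self.feature_id}, sample {s}: bad intensity {v}"
                )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str | None = None
    time_h: float | None = None
    label_state: str | None = None  # "unlabeled" or "labeled:13C:3" etc.
    biofluid: str | None = None
    replicate: int | None = None


class FeatureTable:
    """An aligned feature table plus its sample metadata.

    Internally two DataFrames: ``features`` (index feature_id; columns mz, rt)
    with ``intensities`` (features × samples, NaN = missing), and ``samples``
    (index sample_id with group/time_h/label_state/biofluid/replicate).
    """

    def __init__(
        self,
        features: Iterable[Feature],
        samples: Iterable[SampleMeta],
        method: str = "HILIC+",
    ) -> None:
        samples = list(samples)
        features = list(features)
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_id in metadata")
        feat_ids = [f.feature_id for f in features]
        if len(set(feat_ids)) != len(feat_ids):
            raise ValueError("duplicate feature_id")
        known = set(sample_ids)
        for f in features:
            unknown = set(f.intensities) - known
            if unknown:
                raise ValueError(
                    f"feature {f.feature_id} has intensities for undeclared "
                    f"samples {sorted(unknown)}"
                )
        self.method = method
        self.features = pd.DataFrame(
            {"mz": [f.mz for f in features], "rt": [f.rt for f in features]},
            index=pd.Index(feat_ids, name="feature_id"),
        )
        inten = np.full((len(features), len(sample_ids)), np.nan)
        col = {s: j for j, s in enumerate(sample_ids)}
        for i, f in enumerate(features):
            for s, v in f.intensities.items():
                inten[i, col[s]] = v
        self.intensities = pd.DataFrame(
            inten, index=self.features.index, columns=pd.Index(sample_ids, name="sample_id")
        )
        self.samples = pd.DataFrame(
            [
                {
                    "group": s.group,
                    "time_h": s.time_h,
                    "label_state": s.label_state,
                    "biofluid": s.biofluid,
                    "replicate": s.replicate,
                }
                for s in samples
            ],
            index=pd.Index(sample_ids, name="sample_id"),
        )

    # -- accessors ---------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def feature(self, feature_id: str) -> Feature:
        row = self.features.loc[feature_id]
        vals = self.intensities.loc[feature_id]
        return Feature(
            feature_id,
            float(row["mz"]),
            float(row["rt"]),
            {s: float(v) for s, v in vals.items() if not pd.isna(v)},
        )

    def mz(self, feature_id: str) -> float:
        return float(self.features.at[feature_id, "mz"])

    def rt(self, feature_id: str) -> float:
        return float(self.features.at[feature_id, "rt"])

    def intensity_matrix(self, fill_missing: float = 0.0) -> pd.DataFrame:
        """Features × samples intensities with missing values imputed."""
        return self.intensities.fillna(fill_missing)

    def mean_by_time(self, fill_missing: float = 0.0) -> pd.DataFrame:
        """Replicate-averaged intensities, features × time points (hours)."""
        t = self.samples["time_h"]
        if t.isna().any():
            raise ValueError("every sample needs time_h metadata")
        mat = self.intensity_matrix(fill_missing)
        out = mat.T.groupby(t.astype(float).values).mean().T
        out.columns = [float(c) for c in out.columns]
        return out

    def __len__(self) -> int:
        return len(self.features)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FeatureTable({len(self.features)} features × "
            f"{len(self.samples)} samples, {self.method})"
        )


# ---------------------------------------------------------------------------
# Feature-table text I/O
# ---------------------------------------------------------------------------


def read_feature_table(
    path,
    sample_metadata_path=None,
    method: str = "HILIC+",
    sep: str = ",",
    rt_in_minutes: bool = False,
) -> FeatureTable:
    """Read a delimited feature table (feature_id, mz, rt, one column per
    sample) and optional sample metadata keyed by sample_id."""
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    expected = ["feature_id", "mz", "rt"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"malformed header: expected columns {expected}, got "
            f"{list(df.columns[:3])}"
        )
    sample_cols = list(df.columns[3:])
    if df["feature_id"].duplicated().any():
        dupes = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate feature_id: {dupes}")

    meta: dict[str, SampleMeta] = {}
    if sample_metadata_path is not None:
        mdf = pd.read_csv(sample_metadata_path, sep=sep, dtype={"sample_id": str})
        if "sample_id" not in mdf.columns:
            raise ValueError("sample metadata needs a sample_id column")
        for _, row in mdf.iterrows():
            sid = str(row["sample_id"])
            meta[sid] = SampleMeta(
                sample_id=sid,
                group=_opt_str(row.get("group")),
                time_h=_opt_float(row.get("time_h")),
                label_state=_opt_str(row.get("label_state")),
                biofluid=_opt_str(row.get("biofluid")),
                replicate=_opt_int(row.get("replicate")),
            )
    samples = [meta.get(s, SampleMeta(sample_id=s)) for s in sample_cols]

    rt_scale = 60.0 if rt_in_minutes else 1.0
    features = []
    for i, row in df.iterrows():
        intens = {}
        for s in sample_cols:
            v = row[s]
            if pd.isna(v):
                continue
            v = float(v)
            if v < 0:
                raise ValueError(
                    f"negative intensity at row {i} (feature "
                    f"{row['feature_id']}), column {s}"
                )
            intens[s] = v
        features.append(
            Feature(str(row["feature_id"]), float(row["mz"]),
                    float(row["rt"]) * rt_scale, intens)
        )
    return FeatureTable(features, samples, method=method)


def write_feature_table(table: FeatureTable, path, sample_metadata_path=None,
                        sep: str = ",") -> None:
    out = pd.concat([table.features, table.intensities], axis=1)
    out.to_csv(path, sep=sep, index=True)
    if sample_metadata_path is not None:
        table.samples.to_csv(sample_metadata_path, sep=sep, index=True)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return str(v)


def _opt_float(v) -> float | None:
    s = _opt_str(v)
    return None if s is None else float(s)


def _opt_int(v) -> int | None:
    f = _opt_float(v)
    return None if f is None else int(f)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """An MS2 peak list, sorted ascending by m/z."""

    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        peaks = tuple((float(m), float(i)) for m, i in self.peaks)
        if any(i < 0 for _, i in peaks):
            raise ValueError("negative peak intensity")
        if list(peaks) != sorted(peaks, key=lambda p: p[0]):
            peaks = tuple(sorted(peaks, key=lambda p: p[0]))
        object.__setattr__(self, "peaks", peaks)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


def read_spectrum(path) -> Spectrum:
    """Read a two-column (mz, intensity) peak list; '# precursor_mz:' header."""
    precursor = 0.0
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "precursor_mz" in line:
                    precursor = float(line.split(":")[1])
                continue
            m, i = line.split()
            peaks.append((float(m), float(i)))
    return Spectrum(precursor, tuple(peaks))


def write_spectrum(spec: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# precursor_mz: {spec.precursor_mz:.6f}\n")
        for m, i in spec.peaks:
            fh.write(f"{m:.6f}\t{i:.6g}\n")


# ---------------------------------------------------------------------------
# Metabolite library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryEntry:
    """An enzyme-generated (or precursor) metabolite library record.

    Metabolite names use broad nomenclature ("hydroxybupropion", not a
    positional isomer) unless orthogonal evidence supports more.  Internal
    consistency is enforced: if a formula is present, the stored theoretical
    m/z must agree with it to within 3 ppm.
    """

    precursor: str
    metabolite_name: str
    theoretical_mz: float
    adduct: IonSpecies
    method: str
    rt: float
    formula: ElementalFormula | None = None
    ms2: Spectrum | None = None
    evidence_criteria: frozenset[str] = frozenset()
    msi_level: int = 3

    def __post_init__(self) -> None:
        if self.formula is not None:
            theo = chem.ion_mz(self.formula, self.adduct)
            err = ppm_error(self.theoretical_mz, theo)
            if abs(err) > 3.0:
                raise ValueError(
                    f"{self.metabolite_name}: theoretical_mz "
                    f"{self.theoretical_mz} is {err:.1f} ppm from its formula "
                    f"{self.formula.to_string()} as {self.adduct.label}"
                )
        object.__setattr__(
            self, "evidence_criteria", frozenset(self.evidence_criteria)
        )


def write_library(entries: Sequence[LibraryEntry], path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "precursor": e.precursor,
                "metabolite_name": e.metabolite_name,
                "formula": e.formula.to_string() if e.formula else "",
                "theoretical_mz": round(e.theoretical_mz, 6),
                "adduct": e.adduct.label,
                "method": e.method,
                "rt": round(e.rt, 3),
                "ms2": _ms2_to_text(e.ms2),
                "evidence_criteria": ";".join(sorted(e.evidence_criteria)),
                "msi_level": e.msi_level,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_library(path) -> list[LibraryEntry]:
    df = pd.read_csv(path, dtype=str)
    if len(df) == 0:
        return []
    entries = []
    for _, row in df.iterrows():
        formula_text = _opt_str(row.get("formula"))
        ms2_text = _opt_str(row.get("ms2"))
        crit_text = _opt_str(row.get("evidence_criteria")) or ""
        entries.append(
            LibraryEntry(
                precursor=str(row["precursor"]),
                metabolite_name=str(row["metabolite_name"]),
                formula=chem.parse_formula(formula_text) if formula_text else None,
                theoretical_mz=float(row["theoretical_mz"]),
                adduct=IonSpecies.from_label(str(row["adduct"])),
                method=str(row["method"]),
                rt=float(row["rt"]),
                ms2=_ms2_from_text(ms2_text),
                evidence_criteria=frozenset(
                    c for c in crit_text.split(";") if c
                ),
                msi_level=int(row["msi_level"]),
            )
        )
    return entries


def _ms2_to_text(spec: Spectrum | None) -> str:
    if spec is None:
        return ""
    peaks = " ".join(f"{m:.5f}:{i:.6g}" for m, i in spec.peaks)
    return f"{spec.precursor_mz:.5f}|{peaks}"


def _ms2_from_text(text: str | None) -> Spectrum | None:
    if not text:
        return None
    prec, _, body = text.partition("|")
    peaks = tuple(
        (float(p.split(":")[0]), float(p.split(":")[1]))
        for p in body.split()
    )
    return Spectrum(float(prec), peaks)


# ---------------------------------------------------------------------------
# QC and detection
# ---------------------------------------------------------------------------


def qc_check(
    qc_features: Sequence[tuple[float, float]],
    reference: Sequence[tuple[float, float]],
    rt_tol_s: float = 8.0,
    ppm_tol: float = 5.0,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-compound QC report against (expected mz, expected rt) references.

    A compound passes iff |Δrt| ≤ rt_tol_s and |ppm error| ≤ ppm_tol.  These
    defaults are the run-level QC windows (±8 s peak quality, ±5 ppm mass
    accuracy).
    """
    if len(qc_features) != len(reference):
        raise ValueError("qc and reference lists must be the same length")
    if names is None:
        names = [f"compound_{i}" for i in range(len(reference))]
    rows = []
    for name, (omz, ort), (emz, ert) in zip(names, qc_features, reference):
        err = ppm_error(omz, emz)
        drt = ort - ert
        mass_ok = abs(err) <= ppm_tol
        rt_ok = abs(drt) <= rt_tol_s
        rows.append(
            {
                "compound": name,
                "ppm_error": err,
                "delta_rt_s": drt,
                "mass_pass": mass_ok,
                "rt_pass": rt_ok,
                "pass": mass_ok and rt_ok,
            }
        )
    return pd.DataFrame(rows).set_index("compound")


def detection_call(value: float | None, min_intensity: float = 0.0) -> bool:
    """Detected iff an intensity is present and strictly above the floor.

    Missing values and zeros are both "not detected"; the default floor of 0
    means any positive signal counts.
    """
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return value > min_intensity
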