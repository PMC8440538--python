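"""Library matching, presence matrices, confidence levels, MS2 cosine."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ebimet import chem, identify
from ebimet.identify import CriterionFlags
from ebimet.io import Feature, FeatureTable, LibraryEntry, SampleMeta, Spectrum
from ebimet.pathways import demo_pathways
from ebimet.simulate import SimulationConfig, library_from_truth, simulate_cohort


def _entry(mz=256.1099, rt=85.0, name="hydroxybupropion", precursor="bupropion"):
    return LibraryEntry(
        precursor=precursor,
        metabolite_name=name,
        theoretical_mz=mz,
        adduct=chem.M_PLUS_H,
        method="HILIC+",
        rt=rt,
    )


def _table(feats, samples=("s1",)):
    metas = [SampleMeta(s) for s in samples]
    return FeatureTable(feats, metas)


# ---------------------------------------------------------------------------
# match_library
# ---------------------------------------------------------------------------


def test_match_within_windows():
    t = _table([Feature("f", 256.1095, 84.0, {"s1": 1e5})])
    (m,) = identify.match_library(t, [_entry()])
    assert m.ppm_error == pytest.approx(-1.56, abs=0.05)
    assert m.delta_rt == -1.0


def test_rt_window_violation_blocks_match():
    t = _table([Feature("f", 256.1099, 95.0, {"s1": 1e5})])
    assert identify.match_library(t, [_entry(rt=85.0)]) == []


def test_ppm_window_violation_blocks_match():
    t = _table([Feature("f", 256.1110, 85.0, {"s1": 1e5})])
    assert identify.match_library(t, [_entry()]) == []


def test_method_mismatch_skipped():
    t = _table([Feature("f", 256.1099, 85.0, {"s1": 1e5})])
    e = LibraryEntry(
        precursor="bupropion", metabolite_name="x", theoretical_mz=256.1099,
        adduct=chem.M_MINUS_H, method="C18-", rt=85.0,
    )
    assert identify.match_library(t, [e]) == []


@pytest.mark.parametrize("ppm_tol, rt_tol", [(5.0, 8.0), (10.0, 20.0)])
def test_widening_tolerances_never_removes_matches(ppm_tol, rt_tol):
    feats = [
        Feature(f"f{i}", 256.1099 * (1 + i * 1e-6), 85.0 + i, {"s1": 1e5})
        for i in range(6)
    ]
    t = _table(feats)
    narrow = {m.feature_id for m in identify.match_library(t, [_entry()])}
    wide = {
        m.feature_id
        for m in identify.match_library(t, [_entry()], ppm_tol=ppm_tol,
                                        rt_tol_s=rt_tol)
    }
    assert narrow <= wide


def test_matches_ranked_by_ppm_then_rt():
    feats = [
        Feature("worse", 256.1099 * (1 + 2e-6), 85.0, {"s1": 1e5}),
        Feature("best", 256.1099, 86.0, {"s1": 1e5}),
    ]
    t = _table(feats)
    ms = identify.match_library(t, [_entry()])
    assert [m.feature_id for m in ms] == ["best", "worse"]


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------


def test_presence_matrix_empty_without_matches():
    t = _table([Feature("f", 100.0, 10.0, {"s1": 1e5})])
    pm = identify.presence_matrix([], t)
    assert pm.detected.empty


def test_presence_matrix_single_cell_relative_is_one():
    t = _table([Feature("f", 256.1099, 85.0, {"s1": 1e5})])
    ms = identify.match_library(t, [_entry()])
    pm = identify.presence_matrix(ms, t)
    key = ("bupropion", "hydroxybupropion")
    assert bool(pm.detected.loc[key, "s1"])
    assert pm.relative.loc[key, "s1"] == 1.0


def test_presence_matrix_minmax_scaling():
    t = _table(
        [Feature("f", 256.1099, 85.0, {"s1": 1e4, "s2": 5e4, "s3": 1e5})],
        samples=("s1", "s2", "s3", "s4"),
    )
    ms = identify.match_library(t, [_entry()])
    pm = identify.presence_matrix(ms, t)
    row = pm.relative.loc[("bupropion", "hydroxybupropion")]
    assert row["s1"] == 0.0 and row["s3"] == 1.0
    assert 0.0 < row["s2"] < 1.0
    assert np.isnan(row["s4"])  # not detected


# ---------------------------------------------------------------------------
# confidence levels
# ---------------------------------------------------------------------------


def test_confidence_level_mapping_exhaustive():
    """Every combination of assessed flags maps by its criterion count."""
    for flags in itertools.product([True, False], repeat=4):
        for ms2 in (True, False, None):
            cf = CriterionFlags(*flags, ms2)
            n = sum(flags) + (1 if ms2 is True else 0)
            if n == 0:
                with pytest.raises(ValueError):
                    cf.confidence_level
            elif n >= 3:
                assert cf.confidence_level == 1
            elif n == 2:
                assert cf.confidence_level == 2
            else:
                assert cf.confidence_level == 3


def test_adding_a_criterion_never_lowers_confidence():
    base = CriterionFlags(True, False, None, False, None)
    more = CriterionFlags(True, True, None, False, None)
    assert more.confidence_level <= base.confidence_level


def test_assign_confidence_criteria_composition():
    # two related bupropion metabolites in s1; only one in s2
    feats = [
        Feature("fp", 240.1150, 80.0, {"s1": 1e6, "s2": 2e6}),
        Feature("fh", 256.1099, 85.0, {"s1": 1e5}),
    ]
    t = _table(feats, samples=("s1", "s2"))
    lib = [
        _entry(mz=240.1150, rt=80.0, name="bupropion"),
        _entry(),
    ]
    ms = identify.match_library(t, lib)
    pm = identify.presence_matrix(ms, t)
    res = identify.assign_confidence(ms, pm)
    by = {(r.entry.metabolite_name, r.sample_id): r for r in res}
    # s1: parent + metabolite co-occur -> 3 criteria -> level 1
    assert by[("bupropion", "s1")].confidence_level == 1
    assert by[("hydroxybupropion", "s1")].criteria.co_occurrence
    # s2: parent alone -> mass + rt only -> level 2
    r2 = by[("bupropion", "s2")]
    assert not r2.criteria.co_occurrence
    assert r2.criteria.exposure_specific_presence is None
    assert r2.confidence_level == 2


def test_exposure_specific_presence_flag():
    feats = [Feature("fp", 240.1150, 80.0, {"s1": 1e6, "s2": 2e6})]
    t = _table(feats, samples=("s1", "s2", "s3"))
    lib = [_entry(mz=240.1150, rt=80.0, name="bupropion")]
    ms = identify.match_library(t, lib)
    pm = identify.presence_matrix(ms, t)
    ok = identify.assign_confidence(
        ms, pm, exposures={"bupropion": {"s1", "s2"}}
    )
    assert all(r.criteria.exposure_specific_presence for r in ok)
    # detected outside the documented set -> criterion false everywhere
    bad = identify.assign_confidence(ms, pm, exposures={"bupropion": {"s1"}})
    assert all(r.criteria.exposure_specific_presence is False for r in bad)


# ---------------------------------------------------------------------------
# MS2 cosine
# ---------------------------------------------------------------------------


def _spec(peaks):
    return Spectrum(256.1099, tuple(peaks))


def test_identical_spectra_score_one():
    s = _spec([(56.0495, 10.0), (123.0427, 100.0), (184.0518, 40.0)])
    score, ok = identify.ms2_match(s, s)
    assert score == pytest.approx(1.0, abs=1e-12)
    assert ok


def test_disjoint_spectra_score_zero():
    a = _spec([(100.0, 50.0), (150.0, 50.0)])
    b = _spec([(120.0, 50.0), (170.0, 50.0)])
    score, ok = identify.ms2_match(a, b)
    assert score == 0.0 and not ok


def test_extra_small_peak_barely_lowers_cosine():
    """Closed form: one unmatched 5%-of-base peak gives cos = 1/sqrt(1+0.05^2)."""
    a = _spec([(100.0, 100.0), (150.0, 60.0)])
    b = _spec([(100.0, 100.0), (150.0, 60.0), (200.0, 5.0)])
    expected = (100.0 * 100 + 60.0 * 60) / (
        np.sqrt(100.0**2 + 60.0**2) * np.sqrt(100.0**2 + 60.0**2 + 5.0**2)
    )
    score, ok = identify.ms2_match(a, b)
    assert score == pytest.approx(expected, abs=1e-9)
    assert score > 0.99 and ok


def test_cosine_agrees_with_matchms():
    """Independent cross-check against matchms CosineGreedy."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import CosineGreedy

    peaks_a = [(56.0495, 10.0), (123.0427, 100.0), (184.0518, 40.0)]
    peaks_b = [(56.0497, 12.0), (123.0426, 90.0), (150.0, 20.0)]
    a, b = _spec(peaks_a), _spec(peaks_b)
    ours, _ = identify.ms2_match(a, b, fragment_ppm_tol=20.0)
    sa = matchms.Spectrum(
        mz=np.array([p[0] for p in peaks_a]),
        intensities=np.array([p[1] for p in peaks_a]),
        metadata={"precursor_mz": 256.1099},
    )
    sb = matchms.Spectrum(
        mz=np.array([p[0] for p in peaks_b]),
        intensities=np.array([p[1] for p in peaks_b]),
        metadata={"precursor_mz": 256.1099},
    )
    theirs = CosineGreedy(tolerance=0.005).pair(sa, sb)
    assert ours == pytest.approx(float(theirs["score"]), abs=1e-6)


def test_empty_spectrum_rejected():
    s = _spec([(100.0, 1.0)])
    with pytest.raises(ValueError):
        identify.ms2_match(s, Spectrum(256.1099, ()))


# ---------------------------------------------------------------------------
# cross-biofluid concordance
# ---------------------------------------------------------------------------


def _presence_from_dict(rows, samples):
    idx = pd.MultiIndex.from_tuples(list(rows), names=["precursor", "metabolite"])
    det = pd.DataFrame(
        [[s in pos for s in samples] for pos in rows.values()],
        index=idx, columns=list(samples),
    )
    return identify.PresenceMatrix(det, det.astype(float), {}, {})


def test_cross_biofluid_overlap_counts():
    samples = [f"S{i}" for i in range(10)]
    plasma = _presence_from_dict(
        {("nicotine", "cotinine"): {"S0", "S1", "S2"},
         ("naphthalene", "naphthol sulfate"): {"S3", "S4"}},
        samples,
    )
    urine = _presence_from_dict(
        {("nicotine", "cotinine"): {"S0", "S1", "S2"},
         ("naphthalene", "naphthol sulfate"): {"S3", "S5", "S6", "S7"}},
        samples,
    )
    rep = identify.cross_biofluid_concordance(plasma, urine)
    assert rep.loc["nicotine", "both"] == 3
    assert rep.loc["naphthalene", "both"] == 1
    assert rep.loc["naphthalene", "only_second"] == 3
    assert rep.loc["nicotine", "neither"] == 7


def test_cross_biofluid_requires_matched_samples():
    a = _presence_from_dict({("x", "y"): {"S0"}}, ["S0", "S1"])
    b = _presence_from_dict({("x", "y"): {"S0"}}, ["S0", "S2"])
    with pytest.raises(ValueError, match="sample sets differ"):
        identify.cross_biofluid_concordance(a, b)


def test_cohort_concordance_same_exposed_set_in_both_fluids():
    cfg = SimulationConfig(seed=5, n_background=20)
    tables, truth = simulate_cohort(
        demo_pathways(), n_samples=60, biofluids=("plasma", "urine"), config=cfg
    )
    mats = {}
    for fluid, t in tables.items():
        lib = library_from_truth(truth, fluid)
        ms = identify.match_library(t, lib)
        mats[fluid] = identify.presence_matrix(ms, t)
    rep = identify.cross_biofluid_concordance(mats["plasma"], mats["urine"])
    assert rep.loc["nicotine", "both"] == len(truth.exposed["nicotine"])
    assert rep.loc["nicotine", "only_first"] == 0
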