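"""Isotope pairing, credentialing, and the ratio matrix."""

import numpy as np
import pandas as pd
import pytest

from isodiel.isotopes import labeled_mz, mz_deprotonated
from isodiel.pairing import (
    Feature,
    build_abundance_matrix,
    credential_features,
    flag_multimers,
    pair_with_internal_standard,
)

D13C = 1.0033548378


def feat(fid, mz, rt, area, sample="s1"):
    return Feature(feature_id=fid, sample_id=sample, mz=mz, rt_min=rt, area=area)


def test_planted_pair_recovered_with_carbon_count_and_ratio():
    features = [
        feat("u", 184.98566, 3.0, 2000.0),
        feat("l", 184.98566 + 3 * D13C, 3.0, 1000.0),
    ]
    pairs = pair_with_internal_standard(features)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.unlabeled_id, p.labeled_id) == ("u", "l")
    assert p.n_carbon == 3
    assert p.ratio == pytest.approx(2.0)
    assert p.observed_shift == pytest.approx(3 * D13C, abs=1e-6)


def test_feature_without_partner_stays_unpaired():
    features = [feat("u", 184.98566, 3.0, 2000.0), feat("x", 400.123, 8.0, 500.0)]
    assert pair_with_internal_standard(features) == []


def test_rt_gate_selects_coeluting_candidate():
    """Of two isobaric labeled candidates only the RT-matched one is taken."""
    features = [
        feat("u", 300.0, 5.0, 900.0),
        feat("far", 300.0 + 6 * D13C, 7.5, 400.0),  # outside rt_tol
        feat("near", 300.0 + 6 * D13C, 5.02, 450.0),
    ]
    pairs = pair_with_internal_standard(features, rt_tol=0.1)
    assert len(pairs) == 1
    assert pairs[0].labeled_id == "near"


def test_assignment_is_one_to_one(default_pairs):
    for pairs in default_pairs.values():
        seen = set()
        for p in pairs:
            assert p.unlabeled_id not in seen and p.labeled_id not in seen
            seen.update((p.unlabeled_id, p.labeled_id))


def test_empty_input_gives_empty_output():
    assert pair_with_internal_standard([]) == []


def test_credentialing_reads_carbon_and_nitrogen_counts():
    """UDP-xylose (C14H22N2O16P2) credentials with nC=14, nN=2."""
    mz_u = mz_deprotonated("C14H22N2O16P2")
    control = [feat("udpx", mz_u, 6.0, 1e5, "CTRL")]
    c13 = [feat("c", labeled_mz("C14H22N2O16P2", "13C")[0], 6.0, 1e5, "C13")]
    n15 = [feat("n", labeled_mz("C14H22N2O16P2", "15N")[0], 6.0, 1e5, "N15")]
    (result,) = credential_features(control, c13, n15)
    assert result.biological
    assert result.n_carbon == 14
    assert result.n_nitrogen == 2


def test_unshifted_contaminant_is_not_biological():
    """A solvent peak at identical m/z in all cultures fails the nC >= 1 gate."""
    control = [feat("cont", 413.2661, 9.1, 5e4, "CTRL")]
    c13 = [feat("c", 413.2661, 9.1, 5e4, "C13")]
    n15 = [feat("n", 413.2661, 9.1, 5e4, "N15")]
    (result,) = credential_features(control, c13, n15)
    assert not result.biological
    assert result.n_carbon is None


def test_nitrogen_free_metabolite_credentials_with_zero_n():
    mz_u = mz_deprotonated("C6H12O6")
    control = [feat("glc", mz_u, 2.0, 1e5, "CTRL")]
    c13 = [feat("c", labeled_mz("C6H12O6", "13C")[0], 2.0, 1e5, "C13")]
    n15 = [feat("n", mz_u, 2.0, 1e5, "N15")]  # no nitrogen, no shift
    (result,) = credential_features(control, c13, n15)
    assert result.biological
    assert result.n_carbon == 6
    assert result.n_nitrogen == 0


def _pair(uid, sample, mz, rt, ratio):
    from isodiel.pairing import IsotopePair

    return IsotopePair(
        unlabeled_id=uid,
        labeled_id=uid + "_is",
        sample_id=sample,
        mz_unlabeled=mz,
        rt_min=rt,
        n_carbon=5,
        observed_shift=5 * D13C,
        ratio=ratio,
    )


def _design(samples):
    return pd.DataFrame(
        {"condition": ["M"] * len(samples), "replicate": range(1, len(samples) + 1)},
        index=pd.Index(samples, name="sample_id"),
    )


def test_matrix_complete_when_pair_present_everywhere():
    samples = ["a", "b", "c"]
    pairs = {s: [_pair("u1", s, 200.0, 4.0, 1.5), _pair("u2", s, 350.0, 6.0, 0.7)]
             for s in samples}
    matrix = build_abundance_matrix(pairs, _design(samples))
    assert matrix.shape == (2, 3)
    assert not matrix.isna().any().any()


def test_matrix_missing_entry_for_absent_metabolite():
    samples = ["a", "b", "c"]
    pairs = {s: [_pair("u1", s, 200.0, 4.0, 1.5)] for s in samples}
    pairs["b"] = []  # metabolite absent in sample b
    matrix = build_abundance_matrix(pairs, _design(samples), max_missing_frac=0.5)
    assert matrix.shape == (1, 3)
    assert matrix.iloc[0].isna().sum() == 1


def test_matrix_rejects_duplicate_entries():
    pairs = {"a": [_pair("u1", "a", 200.0, 4.0, 1.5), _pair("u1b", "a", 200.0, 4.0, 1.6)]}
    with pytest.raises(ValueError, match="duplicate"):
        build_abundance_matrix(pairs, _design(["a"]))


def test_matrix_matches_generator_truth(default_bundle, default_pairs):
    """Recovered ratios agree with planted ratios within the noise level."""
    from isodiel.scoring import match_rows_to_compounds

    matrix = build_abundance_matrix(default_pairs, default_bundle.design)
    row_map = match_rows_to_compounds(matrix.index, default_bundle.truth)
    assert len(row_map) == matrix.shape[0]
    truth = default_bundle.truth.true_ratio
    rel_err = []
    for row_id, name in row_map.items():
        est = matrix.loc[row_id]
        true = truth.loc[name, est.index]
        rel_err.append(np.nanmedian(np.abs(est / true - 1)))
    # multiplicative noise CV is 10% per peak -> ratio errors ~14%
    assert np.median(rel_err) < 0.25


def test_matrix_effect_cancels_in_ratios():
    """Scaling every area in one injection leaves its ratios unchanged."""
    features = [
        feat("u", 184.98566, 3.0, 2000.0),
        feat("l", 184.98566 + 3 * D13C, 3.0, 1000.0),
        feat("u2", 400.2000, 7.0, 300.0),
        feat("l2", 400.2000 + 12 * D13C, 7.0, 600.0),
    ]
    g = 7.3
    scaled = [
        Feature(f.feature_id, f.sample_id, f.mz, f.rt_min, f.area * g) for f in features
    ]
    base = {p.unlabeled_id: p.ratio for p in pair_with_internal_standard(features)}
    after = {p.unlabeled_id: p.ratio for p in pair_with_internal_standard(scaled)}
    assert after == pytest.approx(base)


def test_ratio_cv_far_below_raw_area_cv():
    """Per-sample matrix effects (lognormal sigma 0.3) inflate raw-area CV to
    ~0.3 but cancel in the isotopic area ratio."""
    from isodiel.synthetic import GeneratorConfig, generate_study

    config = GeneratorConfig(
        seed=1, matrix_spread=0.3, noise_cv=0.01, amplitude=1.0,
        n_metabolites=20, n_unknown=0, n_background=0,
    )
    bundle = generate_study(config)
    design = bundle.design
    ratios, raw = {}, {}
    for sample, feats in bundle.mixed_features.items():
        for p in pair_with_internal_standard(feats):
            name = p.unlabeled_id.split("::")[1]
            ratios.setdefault(name, {})[sample] = p.ratio
        for f in feats:
            if f.feature_id.startswith("U::"):
                raw.setdefault(f.feature_id.split("::")[1], {})[f.sample_id] = f.area
    by_cond = design.groupby("condition").groups

    def mean_cv(values):
        cvs = []
        for cols in by_cond.values():
            x = np.array([values[s] for s in cols if s in values])
            if x.size >= 2:
                cvs.append(x.std(ddof=1) / x.mean())
        return float(np.mean(cvs))

    ratio_cvs = [mean_cv(v) for v in ratios.values()]
    raw_cvs = [mean_cv(v) for v in raw.values()]
    assert np.mean(ratio_cvs) < 0.05
    assert np.mean(raw_cvs) > 0.15  # matrix effect dominates raw areas


def test_no_background_decoys_paired_by_default(default_bundle, default_pairs):
    for pairs in default_pairs.values():
        for p in pairs:
            assert not p.unlabeled_id.startswith("BG::")
            assert not p.labeled_id.startswith("BG::")


def test_multimer_flagging():
    from isodiel.isotopes import CONSTANTS, monoisotopic_mass

    m = monoisotopic_mass("C6H12O6")
    dimer_mz = 2 * m - (CONSTANTS.monoisotopic["H"] - CONSTANTS.electron_mass)
    features = [
        feat("dimer", dimer_mz, 2.0, 1e4),
        feat("other", 222.2222, 5.0, 1e4),
    ]
    flagged = flag_multimers(features, {"glucose": "C6H12O6"})
    assert flagged == {"dimer"}
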