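"""Isotope-pair detection, biological credentialing, and ratio quantification.

This is the quantitative heart of the method.  Every sample is spiked with
an equal amount of a fully 13C-labeled whole-cell extract before extraction,
so each genuine metabolite shows up twice in one injection: the unlabeled
(12C, sample) peak and a co-eluting internal-standard peak shifted up by
``nC * (m13C - m12C)``.  The ratio of the two monoisotopic peak areas —
the isotopic area ratio 12C/13C — is the relative abundance measure.
Because numerator and denominator share the injection, any per-sample
multiplicative factor (extraction yield, matrix suppression, source drift)
cancels exactly in the ratio.

Credentialing uses the same arithmetic across *separate* cultures: a feature
is of biological origin iff a 13C-grown culture shows the same retention
time with an m/z shift equal to an integer number of 13C mass differences
(nC >= 1); the matching shift in a 15N-grown culture yields the nitrogen
count (nN = 0 is allowed — nitrogen-free compounds simply do not shift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .isotopes import CONSTANTS, IsotopeConstants, infer_atom_count
from .spectra import Ms2Spectrum

__all__ = [
    "Feature",
    "IsotopePair",
    "CredentialResult",
    "pair_with_internal_standard",
    "credential_features",
    "build_abundance_matrix",
    "flag_multimers",
]


@dataclass(frozen=True)
class Feature:
    """One LC-MS peak: location (m/z, RT), integrated area, provenance."""

    feature_id: str
    sample_id: str
    mz: float
    rt_min: float
    area: float
    spectrum: Ms2Spectrum | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.rt_min < 0:
            raise ValueError("retention time must be >= 0")
        if self.area < 0:
            raise ValueError("area must be >= 0")


@dataclass(frozen=True)
class IsotopePair:
    """Matched unlabeled/13C-IS feature pair with inferred carbon count."""

    unlabeled_id: str
    labeled_id: str
    sample_id: str
    mz_unlabeled: float
    rt_min: float
    n_carbon: int
    observed_shift: float
    ratio: float  # area(unlabeled sample peak) / area(13C internal standard peak)

    def __post_init__(self):
        if self.n_carbon < 1:
            raise ValueError("a credible pair needs at least one carbon")
        if self.ratio < 0:
            raise ValueError("area ratio must be >= 0")


@dataclass(frozen=True)
class CredentialResult:
    feature_id: str
    mz: float
    rt_min: float
    biological: bool
    n_carbon: int | None
    n_nitrogen: int | None


def _candidate_pairs(
    features: Sequence[Feature],
    delta: float,
    rt_tol: float,
    ppm_tol: float,
    n_range: tuple[int, int],
    element: str,
    constants: IsotopeConstants,
):
    """All (i, j, n, ppm deviation, rt deviation) with j a shifted partner of i."""
    mz = np.array([f.mz for f in features])
    rt = np.array([f.rt_min for f in features])
    n_lo, n_hi = n_range
    out = []
    for i in range(len(features)):
        shift_lo = n_lo * delta - ppm_tol * 1e-6 * (mz[i] + n_lo * delta)
        shift_hi = n_hi * delta + ppm_tol * 1e-6 * (mz[i] + n_hi * delta)
        close = np.nonzero(
            (np.abs(rt - rt[i]) <= rt_tol)
            & (mz - mz[i] >= shift_lo)
            & (mz - mz[i] <= shift_hi)
        )[0]
        for j in close:
            if j == i:
                continue
            n = infer_atom_count(mz[i], mz[j], element, 1, ppm_tol, constants)
            if n is None or not n_lo <= n <= n_hi:
                continue
            ppm_dev = abs((mz[j] - mz[i]) - n * delta) / mz[j] * 1e6
            out.append((i, int(j), n, ppm_dev, abs(rt[j] - rt[i])))
    return out


def pair_with_internal_standard(
    features: Sequence[Feature],
    rt_tol: float = 0.1,
    ppm_tol: float = 10.0,
    nc_range: tuple[int, int] = (1, 60),
    constants: IsotopeConstants = CONSTANTS,
) -> list[IsotopePair]:
    """Pair unlabeled peaks with their co-eluting 13C internal-standard peaks.

    All features must come from a single mixed (sample + 13C IS) injection.
    For each feature, partners are features within ``rt_tol`` minutes whose
    m/z sits ``n * delta13C`` higher for some integer ``n`` in ``nc_range``
    within ``ppm_tol`` ppm.  Candidates are ranked by ppm deviation (ties by
    RT deviation) and assigned one-to-one, so no peak serves as both sample
    and internal standard.  The pair's ratio is area(unlabeled)/area(IS).
    """
    if not features:
        return []
    cands = _candidate_pairs(
        features, constants.delta_13c, rt_tol, ppm_tol, nc_range, "C", constants
    )
    cands.sort(key=lambda c: (c[3], c[4]))
    used: set[int] = set()
    pairs: list[IsotopePair] = []
    for i, j, n, _ppm, _drt in cands:
        if i in used or j in used:
            continue
        used.update((i, j))
        u, l = features[i], features[j]
        ratio = u.area / l.area if l.area > 0 else math.inf
        pairs.append(
            IsotopePair(
                unlabeled_id=u.feature_id,
                labeled_id=l.feature_id,
                sample_id=u.sample_id,
                mz_unlabeled=u.mz,
                rt_min=u.rt_min,
                n_carbon=n,
                observed_shift=l.mz - u.mz,
                ratio=ratio,
            )
        )
    return pairs


def _best_shift_match(
    feature: Feature,
    culture: Sequence[Feature],
    element: str,
    rt_tol: float,
    ppm_tol: float,
    n_range: tuple[int, int],
    constants: IsotopeConstants,
) -> int | None:
    """Smallest-ppm-deviation atom count matching ``feature`` in a labeled culture."""
    delta = constants.delta_13c if element == "C" else constants.delta_15n
    best_n, best_dev = None, math.inf
    for other in culture:
        if abs(other.rt_min - feature.rt_min) > rt_tol:
            continue
        n = infer_atom_count(feature.mz, other.mz, element, 1, ppm_tol, constants)
        if n is None or not n_range[0] <= n <= n_range[1]:
            continue
        dev = abs((other.mz - feature.mz) - n * delta) / other.mz * 1e6
        if dev < best_dev:
            best_n, best_dev = n, dev
    return best_n


def credential_features(
    unlabeled_features: Sequence[Feature],
    c13_features: Sequence[Feature],
    n15_features: Sequence[Feature],
    rt_tol: float = 0.1,
    ppm_tol: float = 10.0,
    nc_range: tuple[int, int] = (1, 60),
    constants: IsotopeConstants = CONSTANTS,
) -> list[CredentialResult]:
    """Credential features as biological and infer their C/N composition.

    The three feature lists come from separate injections of a control
    (unlabeled) culture, a fully 13C-fed culture, and a fully 15N-fed
    culture.  A feature is biological iff the 13C culture contains an
    RT-matched peak shifted by ``nC`` 13C mass differences with ``nC >= 1``;
    unshifted ubiquitous peaks (solvent contaminants) fail this gate.  The
    nitrogen count comes from the 15N culture the same way, with ``nN = 0``
    allowed via a zero-shift match for nitrogen-free compounds.
    """
    results: list[CredentialResult] = []
    for feat in unlabeled_features:
        nc = _best_shift_match(feat, c13_features, "C", rt_tol, ppm_tol, nc_range, constants)
        if nc is None or nc < 1:
            results.append(CredentialResult(feat.feature_id, feat.mz, feat.rt_min, False, None, None))
            continue
        nn = _best_shift_match(
            feat, n15_features, "N", rt_tol, ppm_tol, (0, nc_range[1]), constants
        )
        results.append(CredentialResult(feat.feature_id, feat.mz, feat.rt_min, True, nc, nn))
    return results


def build_abundance_matrix(
    pairs_by_sample: Mapping[str, Sequence[IsotopePair]],
    design: pd.DataFrame,
    ppm_tol: float = 10.0,
    rt_tol: float = 0.1,
    max_missing_frac: float = 0.5,
) -> pd.DataFrame:
    """Align isotope pairs across samples into a metabolite x sample matrix.

    Rows are aligned by (m/z, RT): pairs across samples whose unlabeled m/z
    agree within ``ppm_tol`` ppm and RT within ``rt_tol`` minutes share a
    row, labelled ``mz@rt`` from the row's mean coordinates.  Entries are
    the 12C/13C area ratios; a sample lacking the pair leaves a missing
    value, and rows missing in more than ``max_missing_frac`` of samples are
    dropped.  A second pair for the same row and sample is an error.
    """
    unknown = set(pairs_by_sample) - set(design.index)
    if unknown:
        raise ValueError(f"samples not in design: {sorted(unknown)}")
    records = [
        (p.mz_unlabeled, p.rt_min, sample, p.ratio)
        for sample, pairs in pairs_by_sample.items()
        for p in pairs
    ]
    if not records:
        return pd.DataFrame(index=pd.Index([], name="row_id"), columns=list(design.index))
    records.sort()
    # greedy single-linkage clustering along the m/z axis with an RT gate
    clusters: list[dict] = []
    for mz, rt, sample, ratio in records:
        target = None
        for cl in reversed(clusters):
            if (mz - cl["mz_mean"]) > ppm_tol * 1e-6 * mz + 1e-9:
                break
            if abs(rt - cl["rt_mean"]) <= rt_tol:
                target = cl
                break
        if target is None:
            target = {"mz_sum": 0.0, "rt_sum": 0.0, "n": 0, "entries": {},
                      "mz_mean": mz, "rt_mean": rt}
            clusters.append(target)
        if sample in target["entries"]:
            raise ValueError(
                f"duplicate pair for sample {sample!r} near m/z {mz:.4f}, RT {rt:.2f}"
            )
        target["entries"][sample] = ratio
        target["mz_sum"] += mz
        target["rt_sum"] += rt
        target["n"] += 1
        target["mz_mean"] = target["mz_sum"] / target["n"]
        target["rt_mean"] = target["rt_sum"] / target["n"]
        clusters.sort(key=lambda c: c["mz_mean"])
    rows = {}
    n_samples = len(design)
    for cl in clusters:
        if len(cl["entries"]) < (1 - max_missing_frac) * n_samples:
            continue
        row_id = f"{cl['mz_mean']:.4f}@{cl['rt_mean']:.2f}"
        rows[row_id] = cl["entries"]
    matrix = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(design.index))
    matrix.index.name = "row_id"
    return matrix.sort_index()


def flag_multimers(
    features: Sequence[Feature],
    annotated_formulas: Mapping[str, str],
    ppm_tol: float = 10.0,
    constants: IsotopeConstants = CONSTANTS,
) -> set[str]:
    """Feature ids whose m/z matches a [2M-H]- dimer of an annotated compound.

    In negative mode a compound of neutral monoisotopic mass M can also
    appear as the proton-bound dimer ion at ``2M - m_H + m_e``; such peaks
    are chemical echoes of an already-annotated metabolite and are excluded
    from the untargeted (unannotated-feature) list.
    """
    from .isotopes import monoisotopic_mass

    dimer_mz = np.array(
        [
            2 * monoisotopic_mass(f, constants) - (constants.monoisotopic["H"] - constants.electron_mass)
            for f in annotated_formulas.values()
        ]
    )
    flagged = set()
    for feat in features:
        if dimer_mz.size and np.any(np.abs(dimer_mz - feat.mz) <= ppm_tol * 1e-6 * feat.mz):
            flagged.add(feat.feature_id)
    return flagged
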