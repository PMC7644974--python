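"""MS2 spectral matching and feature annotation.

A deliberately small stand-in for a full annotation engine: features that
carry an MS2 spectrum are matched against a reference library by greedy
cosine similarity (square-root intensity weighting,
one-to-one fragment pairing within a fragment m/z tolerance), gated first
on precursor m/z agreement in ppm.  Features without a confident match stay
unannotated and travel through the pipeline as anonymous m/z features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["Ms2Spectrum", "LibraryEntry", "Annotation", "cosine_match", "annotate_features"]


@dataclass(frozen=True)
class Ms2Spectrum:
    """Centroided MS2 spectrum: precursor m/z and fragment peak list."""

    precursor_mz: float
    fragments: tuple[tuple[float, float], ...]  # (fragment m/z, relative intensity)

    def __post_init__(self):
        if not self.fragments:
            raise ValueError("spectrum must contain at least one fragment")
        frag = tuple((float(m), float(i)) for m, i in self.fragments)
        if any(i < 0 for _, i in frag):
            raise ValueError("fragment intensities must be >= 0")
        if any(m > self.precursor_mz + 0.5 for m, _ in frag):
            raise ValueError("fragment m/z above precursor m/z")
        object.__setattr__(self, "fragments", tuple(sorted(frag)))

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.fragments])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.fragments])


@dataclass(frozen=True)
class LibraryEntry:
    """Reference-library record: compound name, formula string, spectrum."""

    name: str
    formula: str
    spectrum: Ms2Spectrum


@dataclass(frozen=True)
class Annotation:
    feature_id: str
    library_name: str | None
    score: float
    accepted: bool


def cosine_match(query: Ms2Spectrum, reference: Ms2Spectrum, frag_tol: float = 0.01) -> float:
    """Greedy one-to-one cosine similarity on square-root intensities.

    Candidate fragment pairs within ``frag_tol`` Da are assigned greedily by
    increasing m/z difference, each fragment used at most once; the score is
    the matched dot product normalized by both spectra's total intensity
    norms, so it lies in [0, 1], equals 1 for identical spectra, and is
    invariant to global intensity scaling of either spectrum.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    q_mz, q_int = query.mz_array, np.sqrt(query.intensity_array)
    r_mz, r_int = reference.mz_array, np.sqrt(reference.intensity_array)
    norm = np.linalg.norm(q_int) * np.linalg.norm(r_int)
    if norm == 0:
        return 0.0
    diffs = np.abs(q_mz[:, None] - r_mz[None, :])
    qi, ri = np.nonzero(diffs <= frag_tol)
    order = np.argsort(diffs[qi, ri], kind="stable")
    used_q: set[int] = set()
    used_r: set[int] = set()
    dot = 0.0
    for idx in order:
        a, b = int(qi[idx]), int(ri[idx])
        if a in used_q or b in used_r:
            continue
        used_q.add(a)
        used_r.add(b)
        dot += q_int[a] * r_int[b]
    return float(dot / norm)


def annotate_features(
    features: Sequence,
    library: Sequence[LibraryEntry],
    precursor_tol: float = 10.0,
    frag_tol: float = 0.01,
    score_min: float = 0.7,
) -> list[Annotation]:
    """Assign each MS2-bearing feature its best-scoring library identity.

    ``features`` are objects with ``feature_id``, ``mz`` and an optional
    ``spectrum`` attribute (see :class:`isodiel.pairing.Feature`).  A library
    entry is a candidate only when its spectrum's precursor m/z matches the
    feature m/z within ``precursor_tol`` ppm; the best cosine score wins and
    is accepted iff it reaches ``score_min``.  Features without a spectrum
    or without an accepted match come back with ``library_name=None``.
    """
    if not library:
        raise ValueError("reference library is empty")
    lib_prec = np.array([entry.spectrum.precursor_mz for entry in library])
    out: list[Annotation] = []
    for feat in features:
        spectrum = getattr(feat, "spectrum", None)
        if spectrum is None:
            out.append(Annotation(feat.feature_id, None, 0.0, False))
            continue
        within = np.abs(lib_prec - feat.mz) <= precursor_tol * 1e-6 * feat.mz
        best_name, best_score = None, 0.0
        for j in np.nonzero(within)[0]:
            score = cosine_match(spectrum, library[j].spectrum, frag_tol)
            if score > best_score:
                best_name, best_score = library[j].name, score
        accepted = best_name is not None and best_score >= score_min
        out.append(
            Annotation(feat.feature_id, best_name if accepted else None, best_score, accepted)
        )
    return out
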