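"""Plain-text readers and writers for every table the pipeline touches.

Formats: feature tables and study designs as CSV/TSV, MS2 spectra as MSP
(NAME / FORMULA / PRECURSORMZ / Num Peaks records), OD720 series as CSV,
abundance matrices as TSV with a commented design header block, ground
truth and screening results as TSV.  All writers use fixed float formats so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .growth import GrowthSeries
from .pairing import Feature, IsotopePair
from .spectra import Annotation, LibraryEntry, Ms2Spectrum
from .stats import StatRecord

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_msp",
    "write_msp",
    "read_design",
    "write_design",
    "read_od_series",
    "write_od_series",
    "write_abundance_matrix",
    "read_abundance_matrix",
    "write_stat_records",
    "write_annotations",
    "write_pairs",
    "load_config",
]


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def write_feature_table(
    features: Sequence[Feature], path: str | Path, spectra_path: str | Path | None = None
) -> None:
    """Write features as CSV/TSV; MS2 spectra go to a side-car MSP keyed by feature id."""
    frame = pd.DataFrame(
        {
            "sample_id": [f.sample_id for f in features],
            "feature_id": [f.feature_id for f in features],
            "mz": [f.mz for f in features],
            "rt_min": [f.rt_min for f in features],
            "area": [f.area for f in features],
        }
    )
    frame.to_csv(path, sep=_sep(path), index=False, float_format="%.6f")
    if spectra_path is not None:
        entries = [
            LibraryEntry(f.feature_id, "", f.spectrum)
            for f in features
            if f.spectrum is not None
        ]
        write_msp(entries, spectra_path)


def read_feature_table(
    path: str | Path, spectra_path: str | Path | None = None
) -> list[Feature]:
    frame = pd.read_csv(path, sep=_sep(path))
    required = {"sample_id", "feature_id", "mz", "rt_min", "area"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    spectra: dict[str, Ms2Spectrum] = {}
    if spectra_path is not None and os.path.exists(spectra_path):
        spectra = {e.name: e.spectrum for e in read_msp(spectra_path)}
    return [
        Feature(
            feature_id=str(r.feature_id),
            sample_id=str(r.sample_id),
            mz=float(r.mz),
            rt_min=float(r.rt_min),
            area=float(r.area),
            spectrum=spectra.get(str(r.feature_id)),
        )
        for r in frame.itertuples(index=False)
    ]


def write_msp(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    """Write an MSP spectral library (NAME/FORMULA/PRECURSORMZ/Num Peaks)."""
    with open(path, "w") as fh:
        for entry in entries:
            spectrum = entry.spectrum
            fh.write(f"NAME: {entry.name}\n")
            if entry.formula:
                fh.write(f"FORMULA: {entry.formula}\n")
            fh.write(f"PRECURSORMZ: {spectrum.precursor_mz:.6f}\n")
            fh.write(f"Num Peaks: {len(spectrum.fragments)}\n")
            for mz, intensity in spectrum.fragments:
                fh.write(f"{mz:.6f}\t{intensity:.6f}\n")
            fh.write("\n")


def read_msp(path: str | Path) -> list[LibraryEntry]:
    """Read an MSP spectral library written by :func:`write_msp` or similar."""
    entries: list[LibraryEntry] = []
    name, formula, precursor = None, "", None
    peaks: list[tuple[float, float]] = []
    n_expected = 0

    def flush():
        nonlocal name, formula, precursor, peaks, n_expected
        if name is not None and peaks:
            if precursor is None:
                raise ValueError(f"{path}: entry {name!r} lacks PRECURSORMZ")
            entries.append(
                LibraryEntry(name, formula, Ms2Spectrum(precursor, tuple(peaks)))
            )
        name, formula, precursor, peaks, n_expected = None, "", None, [], 0

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            upper = line.upper()
            if upper.startswith("NAME:"):
                flush()
                name = line.split(":", 1)[1].strip()
            elif upper.startswith("FORMULA:"):
                formula = line.split(":", 1)[1].strip()
            elif upper.startswith(("PRECURSORMZ:", "PRECURSOR_MZ:")):
                precursor = float(line.split(":", 1)[1])
            elif upper.startswith("NUM PEAKS:"):
                n_expected = int(line.split(":", 1)[1])
            elif line[0].isdigit():
                mz_str, int_str = line.replace("\t", " ").split()[:2]
                peaks.append((float(mz_str), float(int_str)))
    flush()
    return entries


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.reset_index().to_csv(path, sep=_sep(path), index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_sep(path))
    required = {"sample_id", "condition", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame.set_index("sample_id")


def write_od_series(series: GrowthSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_od_series(path: str | Path) -> GrowthSeries:
    frame = pd.read_csv(path)
    if not {"time_h", "od720"} <= set(frame.columns):
        raise ValueError(f"{path}: expected columns time_h, od720")
    mu = frame["mu_per_h"].to_numpy() if "mu_per_h" in frame.columns else None
    return GrowthSeries(
        time_h=frame["time_h"].to_numpy(), od720=frame["od720"].to_numpy(), mu=mu
    )


def write_abundance_matrix(
    matrix: pd.DataFrame, design: pd.DataFrame, path: str | Path
) -> None:
    """TSV matrix preceded by a commented design header block."""
    with open(path, "w") as fh:
        for sample in matrix.columns:
            cond = design.loc[sample, "condition"] if sample in design.index else "?"
            rep = design.loc[sample, "replicate"] if sample in design.index else "?"
            fh.write(f"# sample: {sample}\tcondition: {cond}\treplicate: {rep}\n")
        matrix.to_csv(fh, sep="\t", float_format="%.6f")


def read_abundance_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a matrix written by :func:`write_abundance_matrix`; returns (matrix, design)."""
    design_rows = []
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        fields = dict(
            part.strip().split(": ", 1) for part in line[1:].strip().split("\t")
        )
        design_rows.append(
            {
                "sample_id": fields["sample"],
                "condition": fields["condition"],
                "replicate": fields["replicate"],
            }
        )
    from io import StringIO

    matrix = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col=0)
    design = pd.DataFrame(design_rows).set_index("sample_id") if design_rows else pd.DataFrame()
    return matrix, design


def write_pairs(pairs_by_sample: Mapping[str, Sequence[IsotopePair]], path: str | Path) -> None:
    rows = [
        {
            "sample_id": sample,
            "unlabeled_id": p.unlabeled_id,
            "labeled_id": p.labeled_id,
            "mz_unlabeled": p.mz_unlabeled,
            "rt_min": p.rt_min,
            "n_carbon": p.n_carbon,
            "observed_shift": p.observed_shift,
            "ratio": p.ratio,
        }
        for sample, pairs in pairs_by_sample.items()
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "feature_id": [a.feature_id for a in annotations],
            "library_name": [a.library_name or "" for a in annotations],
            "score": [a.score for a in annotations],
            "accepted": [a.accepted for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_stat_records(records: Sequence[StatRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {
            "row_id": rec.row_id,
            "p_value": rec.p_value,
            "fold_change": rec.fold_change,
            "significant": rec.significant,
            "peaking": rec.peaking or "",
            "tie": rec.tie,
        }
        row.update({f"mean_{c}": v for c, v in sorted(rec.condition_means.items())})
        row.update({f"cv_{c}": v for c, v in sorted(rec.condition_cv.items())})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config
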