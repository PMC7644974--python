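"""End-to-end workflow: annotate, credential, pair/quantify, statistics.

The stages run in the published order of the method they implement:

1. MS2 annotation of features against a reference library;
2. credentialing of biological features via 13C/15N culture mass shifts;
3. isotope pairing against the 13C internal standard and assembly of the
   12C/13C area-ratio abundance matrix;
4. diurnal statistics (ANOVA + fold-change screen, MD-vs-CL t test, CV
   gate for untargeted features, PCA, peaking-time classes) and growth-rate
   estimation from the OD720 series.

Every stage writes its result as a plain-text table so partial reruns are
possible; a JSON manifest records versions, thresholds and the feature
counts entering and surviving each stage.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iom
from . import __version__
from .growth import GrowthSeries, instantaneous_mu
from .pairing import (
    Feature,
    build_abundance_matrix,
    credential_features,
    flag_multimers,
    pair_with_internal_standard,
)
from .spectra import annotate_features
from .stats import (
    anova_screen,
    autoscale_rows,
    cv_gate,
    log2_condition_means,
    pairwise_screen,
    pca_scores,
)
from .synthetic import GeneratorConfig, StudyBundle, generate_study

__all__ = ["PipelineResult", "run_pipeline", "write_bundle_inputs", "read_study_inputs"]

_ROW_ID = re.compile(r"^([0-9.]+)@([0-9.]+)$")


@dataclass(eq=False)
class StudyInputs:
    """The on-disk inputs of one study, loaded into memory."""

    mixed_features: dict
    control_features: list
    c13_features: list
    n15_features: list
    design: pd.DataFrame
    od: GrowthSeries
    msp_library: list


@dataclass(eq=False)
class PipelineResult:
    annotations: dict  # feature id -> accepted library name
    credentials: list
    pairs_by_sample: dict
    matrix: pd.DataFrame  # rows renamed to metabolite where annotated
    row_annotated: pd.Series  # row -> bool
    anova: list
    pairwise: list
    cv_pass: list
    pca: tuple
    mu_series: GrowthSeries
    manifest: dict


def write_bundle_inputs(bundle: StudyBundle, directory: str | Path) -> None:
    """Write a synthetic study to disk in the dialects the pipeline reads."""
    directory = Path(directory)
    (directory / "mixed").mkdir(parents=True, exist_ok=True)
    iom.write_design(bundle.design, directory / "design.csv")
    iom.write_od_series(bundle.od, directory / "od720.csv")
    iom.write_msp(bundle.msp_library, directory / "library.msp")
    iom.write_feature_table(bundle.control_features, directory / "control_culture.tsv")
    iom.write_feature_table(bundle.c13_features, directory / "c13_culture.tsv")
    iom.write_feature_table(bundle.n15_features, directory / "n15_culture.tsv")
    for sample, feats in bundle.mixed_features.items():
        iom.write_feature_table(
            feats, directory / "mixed" / f"{sample}.tsv", directory / "mixed" / f"{sample}.msp"
        )
    # ground truth lives beside the inputs but is never read by the pipeline
    bundle.truth.true_ratio.to_csv(
        directory / "ground_truth_ratios.tsv", sep="\t", float_format="%.6f"
    )
    truth_meta = pd.DataFrame(
        {
            "diurnal_class": bundle.truth.diurnal_class,
            "annotated": bundle.truth.annotated,
        }
    ).join(bundle.truth.compound_location)
    truth_meta.to_csv(directory / "ground_truth_compounds.tsv", sep="\t", float_format="%.6f")


def read_study_inputs(directory: str | Path) -> StudyInputs:
    directory = Path(directory)
    design_path = directory / "design.csv"
    if not design_path.exists():
        raise FileNotFoundError(f"missing design table: {design_path}")
    design = iom.read_design(design_path)
    mixed: dict[str, list[Feature]] = {}
    for sample in design.index:
        table = directory / "mixed" / f"{sample}.tsv"
        if not table.exists():
            raise FileNotFoundError(f"missing mixed-sample feature table: {table}")
        mixed[sample] = iom.read_feature_table(table, table.with_suffix(".msp"))
    return StudyInputs(
        mixed_features=mixed,
        control_features=iom.read_feature_table(directory / "control_culture.tsv"),
        c13_features=iom.read_feature_table(directory / "c13_culture.tsv"),
        n15_features=iom.read_feature_table(directory / "n15_culture.tsv"),
        design=design,
        od=iom.read_od_series(directory / "od720.csv"),
        msp_library=iom.read_msp(directory / "library.msp"),
    )


def _row_coordinates(row_id: str) -> tuple[float, float]:
    match = _ROW_ID.match(str(row_id))
    if not match:
        raise ValueError(f"row id {row_id!r} does not encode m/z@RT")
    return float(match.group(1)), float(match.group(2))


def _assign_row_names(
    matrix: pd.DataFrame,
    accepted: dict[str, str],
    features_by_id: dict[str, Feature],
    ppm_tol: float,
    rt_tol: float,
) -> tuple[pd.DataFrame, pd.Series]:
    """Rename matrix rows to their annotated metabolite where one matches."""
    named: dict[str, str] = {}
    for row_id in matrix.index:
        mz, rt = _row_coordinates(row_id)
        votes: dict[str, int] = {}
        for fid, name in accepted.items():
            feat = features_by_id.get(fid)
            if feat is None:
                continue
            if abs(feat.mz - mz) <= ppm_tol * 1e-6 * mz and abs(feat.rt_min - rt) <= rt_tol:
                votes[name] = votes.get(name, 0) + 1
        if votes:
            named[row_id] = max(votes, key=lambda k: (votes[k], k))
    renamed = matrix.rename(index=named)
    annotated = pd.Series(
        [rid in set(named.values()) for rid in renamed.index], index=renamed.index
    )
    return renamed, annotated


def run_pipeline(config: dict, outdir: str | Path) -> PipelineResult:
    """Run the full workflow described by ``config`` into ``outdir``.

    ``config`` keys (all optional, shown with defaults): ``seed`` (0),
    ``generator`` (mapping of :class:`GeneratorConfig` overrides),
    ``input_dir`` (read an existing study instead of simulating),
    ``tolerances`` (rt_tol 0.1, ppm_tol 10, nc_min 1, nc_max 60),
    ``annotation`` (precursor_tol 10, frag_tol 0.01, score_min 0.7),
    ``stats`` (alpha 0.05, fc_min 1.5, cv_max 0.3, pairwise [MD, CL]),
    ``growth`` (window 3).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    tol = {"rt_tol": 0.1, "ppm_tol": 10.0, "nc_min": 1, "nc_max": 60}
    tol.update(config.get("tolerances", {}))
    ann_cfg = {"precursor_tol": 10.0, "frag_tol": 0.01, "score_min": 0.7}
    ann_cfg.update(config.get("annotation", {}))
    stats_cfg = {"alpha": 0.05, "fc_min": 1.5, "cv_max": 0.3, "pairwise": ["MD", "CL"]}
    stats_cfg.update(config.get("stats", {}))
    growth_cfg = {"window": 3}
    growth_cfg.update(config.get("growth", {}))
    nc_range = (int(tol["nc_min"]), int(tol["nc_max"]))

    if "input_dir" in config:
        inputs = read_study_inputs(config["input_dir"])
    else:
        gen = GeneratorConfig(**{"seed": seed, **config.get("generator", {})})
        bundle = generate_study(gen)
        write_bundle_inputs(bundle, outdir / "inputs")
        inputs = read_study_inputs(outdir / "inputs")

    # stage 1: MS2 annotation
    all_mixed = [f for feats in inputs.mixed_features.values() for f in feats]
    annotations = annotate_features(
        [f for f in all_mixed if f.spectrum is not None],
        inputs.msp_library,
        precursor_tol=ann_cfg["precursor_tol"],
        frag_tol=ann_cfg["frag_tol"],
        score_min=ann_cfg["score_min"],
    )
    accepted = {a.feature_id: a.library_name for a in annotations if a.accepted}
    iom.write_annotations(annotations, outdir / "annotations.tsv")

    # stage 2: credentialing against the labeled cultures
    credentials = credential_features(
        inputs.control_features,
        inputs.c13_features,
        inputs.n15_features,
        rt_tol=tol["rt_tol"],
        ppm_tol=tol["ppm_tol"],
        nc_range=nc_range,
    )
    pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in credentials],
            "mz": [c.mz for c in credentials],
            "rt_min": [c.rt_min for c in credentials],
            "biological": [c.biological for c in credentials],
            "n_carbon": [c.n_carbon if c.n_carbon is not None else "" for c in credentials],
            "n_nitrogen": [c.n_nitrogen if c.n_nitrogen is not None else "" for c in credentials],
        }
    ).to_csv(outdir / "credentials.tsv", sep="\t", index=False, float_format="%.6f")

    # stage 3: isotope pairing and the ratio matrix
    pairs_by_sample = {
        sample: pair_with_internal_standard(
            feats, rt_tol=tol["rt_tol"], ppm_tol=tol["ppm_tol"], nc_range=nc_range
        )
        for sample, feats in inputs.mixed_features.items()
    }
    iom.write_pairs(pairs_by_sample, outdir / "pairs.tsv")
    matrix = build_abundance_matrix(
        pairs_by_sample, inputs.design, ppm_tol=tol["ppm_tol"], rt_tol=tol["rt_tol"]
    )
    features_by_id = {f.feature_id: f for f in all_mixed}
    matrix, row_annotated = _assign_row_names(
        matrix, accepted, features_by_id, tol["ppm_tol"], tol["rt_tol"]
    )
    multimers = flag_multimers(
        [
            f
            for f in all_mixed
            if f.feature_id not in accepted
        ],
        {name: next(e.formula for e in inputs.msp_library if e.name == name)
         for name in set(accepted.values())},
        ppm_tol=tol["ppm_tol"],
    )
    iom.write_abundance_matrix(matrix, inputs.design, outdir / "abundance_matrix.tsv")

    # stage 4: statistics
    anova = anova_screen(matrix, inputs.design, stats_cfg["alpha"], stats_cfg["fc_min"])
    iom.write_stat_records(anova, outdir / "anova.tsv")
    cond_a, cond_b = stats_cfg["pairwise"]
    pairwise = pairwise_screen(
        matrix, inputs.design, cond_a, cond_b, stats_cfg["alpha"], stats_cfg["fc_min"]
    )
    iom.write_stat_records(pairwise, outdir / f"pairwise_{cond_a}_{cond_b}.tsv")
    untargeted = matrix.loc[~row_annotated]
    cv_pass = cv_gate(untargeted, inputs.design, stats_cfg["cv_max"])
    (outdir / "cv_pass_untargeted.txt").write_text("".join(f"{r}\n" for r in cv_pass))
    log2_means = log2_condition_means(matrix, inputs.design)
    scaled_samples, _ = autoscale_rows(np.log2(matrix.where(matrix > 0)))
    scores, explained, ellipses = pca_scores(scaled_samples, inputs.design)
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t", float_format="%.6f")
    log2_means.to_csv(outdir / "log2_condition_means.tsv", sep="\t", float_format="%.6f")

    # growth-rate estimation
    mu_series = instantaneous_mu(inputs.od, window=growth_cfg["window"])
    iom.write_od_series(mu_series, outdir / "growth_mu.csv")

    manifest = {
        "isodiel_version": __version__,
        "seed": seed,
        "thresholds": {**tol, **ann_cfg, **stats_cfg, **growth_cfg},
        "counts": {
            "mixed_features_in": len(all_mixed),
            "ms2_features": sum(1 for f in all_mixed if f.spectrum is not None),
            "annotated_features": len(accepted),
            "credentialed_biological": sum(1 for c in credentials if c.biological),
            "isotope_pairs": sum(len(p) for p in pairs_by_sample.values()),
            "matrix_rows": int(matrix.shape[0]),
            "matrix_rows_annotated": int(row_annotated.sum()),
            "multimer_flagged": len(multimers),
            "anova_significant": sum(1 for r in anova if r.significant),
            f"pairwise_{cond_a}_{cond_b}_significant": sum(
                1 for r in pairwise if r.significant
            ),
            "cv_pass_untargeted": len(cv_pass),
        },
        "pca_explained_variance_ratio": [round(float(v), 6) for v in explained],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        annotations=accepted,
        credentials=credentials,
        pairs_by_sample=pairs_by_sample,
        matrix=matrix,
        row_annotated=row_annotated,
        anova=anova,
        pairwise=pairwise,
        cv_pass=cv_pass,
        pca=(scores, explained, ellipses),
        mu_series=mu_series,
        manifest=manifest,
    )
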