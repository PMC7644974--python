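"""Score pipeline stages against the synthetic ground truth.

The generator's feature ids follow the convention ``ROLE::compound::sample``
(roles ``U`` for the unlabeled sample peak, ``IS`` for the 13C internal
standard, ``BG`` for non-biological background); these helpers parse that
convention and the ground-truth bundle to measure sensitivity, specificity
and classification accuracy of each downstream stage.  Nothing here is ever
used by the pipeline itself.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .stats import StatRecord
from .synthetic import GroundTruth

__all__ = [
    "score_pairing",
    "score_credentialing",
    "match_rows_to_compounds",
    "score_screen",
    "score_peaking",
]


def _role(feature_id: str) -> tuple[str, str]:
    parts = feature_id.split("::")
    return (parts[0], parts[1]) if len(parts) >= 2 else ("?", feature_id)


def score_pairing(pairs_by_sample: Mapping[str, Sequence], truth: GroundTruth) -> dict:
    """Pairing sensitivity and specificity against planted pairs.

    A true positive pairs a compound's U peak with its own IS peak;
    specificity is the fraction of background decoy instances that stay
    unpaired.
    """
    n_compounds = len(truth.diurnal_class)
    n_samples = len(pairs_by_sample)
    tp = 0
    decoy_instances_paired = 0
    for pairs in pairs_by_sample.values():
        for p in pairs:
            role_u, name_u = _role(p.unlabeled_id)
            role_l, name_l = _role(p.labeled_id)
            if role_u == "U" and role_l == "IS" and name_u == name_l:
                tp += 1
            if role_u == "BG":
                decoy_instances_paired += 1
            if role_l == "BG":
                decoy_instances_paired += 1
    n_decoy_instances = len(truth.background_ids) * n_samples
    return {
        "sensitivity": tp / (n_compounds * n_samples),
        "specificity": 1 - decoy_instances_paired / n_decoy_instances
        if n_decoy_instances
        else 1.0,
    }


def score_credentialing(credentials: Sequence, truth: GroundTruth) -> dict:
    """Fraction of compounds credentialed with exact C and N counts, and
    fraction of decoys wrongly called biological."""
    loc = truth.compound_location
    correct = 0
    decoys_called = 0
    for c in credentials:
        _, name = _role(c.feature_id)
        if name in loc.index:
            if (
                c.biological
                and c.n_carbon == loc.loc[name, "n_carbon"]
                and c.n_nitrogen == loc.loc[name, "n_nitrogen"]
            ):
                correct += 1
        elif name in truth.background_ids and c.biological:
            decoys_called += 1
    return {
        "sensitivity": correct / len(loc),
        "false_biological_rate": decoys_called / max(1, len(truth.background_ids)),
    }


def match_rows_to_compounds(
    row_ids: Sequence[str],
    truth: GroundTruth,
    ppm_tol: float = 10.0,
    rt_tol: float = 0.1,
) -> dict[str, str]:
    """Map abundance-matrix row ids to ground-truth compound names.

    Annotated rows already carry the compound name; anonymous ``mz@rt``
    rows are matched to the nearest planted compound location within the
    tolerances.
    """
    loc = truth.compound_location
    mapping: dict[str, str] = {}
    for row_id in row_ids:
        if row_id in loc.index:
            mapping[row_id] = row_id
            continue
        try:
            mz_s, rt_s = str(row_id).split("@")
            mz, rt = float(mz_s), float(rt_s)
        except ValueError:
            continue
        close = loc[
            (np.abs(loc["mz"] - mz) <= ppm_tol * 1e-6 * mz)
            & (np.abs(loc["rt_min"] - rt) <= rt_tol)
        ]
        if len(close):
            mapping[row_id] = str(
                (np.abs(close["mz"] - mz)).idxmin()
            )
    return mapping


def score_screen(
    records: Sequence[StatRecord],
    truth: GroundTruth,
    fc_min: float = 1.5,
    conditions: Sequence[str] | None = None,
) -> dict:
    """Sensitivity/specificity of a significance screen against the truth.

    A row is truly changing when its planted condition multipliers (over
    ``conditions``, default all) span more than ``fc_min``-fold; flat rows
    are true nulls.
    """
    mult = truth.multipliers
    if conditions is not None:
        mult = mult[list(conditions)]
    true_fc = mult.max(axis=1) / mult.min(axis=1)
    row_map = match_rows_to_compounds([r.row_id for r in records], truth)
    tp = fn = tn = fp = 0
    for rec in records:
        name = row_map.get(rec.row_id)
        if name is None:
            continue
        truly_changing = bool(true_fc[name] > fc_min)
        if truly_changing and rec.significant:
            tp += 1
        elif truly_changing:
            fn += 1
        elif rec.significant:
            fp += 1
        else:
            tn += 1
    return {
        "sensitivity": tp / max(1, tp + fn),
        "specificity": tn / max(1, tn + fp),
        "n_true": tp + fn,
        "n_null": tn + fp,
    }


def score_peaking(records: Sequence[StatRecord], truth: GroundTruth) -> float:
    """Accuracy of peaking-condition labels over truly diurnal rows."""
    row_map = match_rows_to_compounds([r.row_id for r in records], truth)
    hits = total = 0
    for rec in records:
        name = row_map.get(rec.row_id)
        if name is None or rec.peaking is None:
            continue
        true_class = truth.diurnal_class[name]
        if true_class == "flat":
            continue
        total += 1
        hits += int(rec.peaking == true_class)
    return hits / max(1, total)
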