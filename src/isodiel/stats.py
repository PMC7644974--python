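"""Statistics for diurnal metabolite rhythms.

Works on an abundance matrix of 12C/13C isotopic area ratios (rows =
metabolites or m/z features, columns = samples) plus a study design mapping
each sample to one of five conditions — morning (M), midday (MD), evening
(E), midnight (MN) sampled across a diurnal cycle, plus continuous light
(CL) — with replicates.

The cascade mirrors common metabolomics practice: ratios are log2
transformed (variance stabilization for multiplicative noise), averaged
over replicates per condition, auto-scaled (row z-score) for heatmaps and
PCA; rhythmic metabolites are screened by one-way ANOVA with a conjunctive
fold-change gate, condition contrasts by Student's t test, and untargeted
features by an intra-condition coefficient-of-variation gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import chi2, gmean
from sklearn.decomposition import PCA

DIURNAL_ORDER = ["M", "MD", "E", "MN"]
CONDITIONS = DIURNAL_ORDER + ["CL"]

__all__ = [
    "DIURNAL_ORDER",
    "CONDITIONS",
    "StatRecord",
    "log2_condition_means",
    "autoscale_rows",
    "geomean_normalize",
    "anova_screen",
    "pairwise_screen",
    "cv_gate",
    "pca_scores",
    "classify_peaking",
]


@dataclass(frozen=True)
class StatRecord:
    """Per-row screening result."""

    row_id: str
    p_value: float
    fold_change: float  # max/min of per-condition geometric means, >= 1
    condition_means: dict  # condition -> geometric mean of ratios
    condition_cv: dict  # condition -> intra-condition CV of ratios
    significant: bool
    peaking: str | None = None
    tie: bool = False


def _groups(matrix: pd.DataFrame, design: pd.DataFrame) -> dict[str, list[str]]:
    """condition -> sample columns present in both matrix and design."""
    cols = [c for c in matrix.columns if c in design.index]
    by_cond: dict[str, list[str]] = {}
    for col in cols:
        by_cond.setdefault(str(design.loc[col, "condition"]), []).append(col)
    return by_cond


def _check_positive(matrix: pd.DataFrame) -> None:
    bad = (matrix <= 0) & matrix.notna()
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise ValueError(f"non-positive abundance at row {row!r}, sample {col!r}")


def log2_condition_means(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean of log2 ratios over the replicates of each condition, per row."""
    _check_positive(matrix)
    groups = _groups(matrix, design)
    out = {
        cond: np.log2(matrix[cols]).mean(axis=1, skipna=True)
        for cond, cols in groups.items()
    }
    order = [c for c in CONDITIONS if c in out] + sorted(set(out) - set(CONDITIONS))
    return pd.DataFrame(out)[order]


def autoscale_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Row z-score (mean 0, sample SD 1).

    Constant rows cannot be scaled; they come back as all zeros and their
    ids are returned alongside as the flagged index.
    """
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    flagged = matrix.index[(sd == 0) | sd.isna()]
    sd_safe = sd.replace(0, np.nan)
    scaled = matrix.sub(mean, axis=0).div(sd_safe, axis=0)
    scaled.loc[flagged] = 0.0
    return scaled, flagged


def geomean_normalize(row: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Divide a row of positive values by its geometric mean (product of output = 1)."""
    values = np.asarray(row, dtype=float)
    if np.any(values <= 0):
        raise ValueError("geometric-mean normalization requires positive values")
    normalized = values / gmean(values)
    if isinstance(row, pd.Series):
        return pd.Series(normalized, index=row.index)
    return normalized


def _row_stats(values: pd.Series, groups: dict[str, list[str]]):
    """Per-condition log2 replicate vectors, geometric means, CVs for one row."""
    log2_by_cond, geo, cv = {}, {}, {}
    for cond, cols in groups.items():
        x = values[cols].dropna().to_numpy(dtype=float)
        if x.size == 0:
            continue
        log2_by_cond[cond] = np.log2(x)
        geo[cond] = float(gmean(x))
        cv[cond] = float(np.std(x, ddof=1) / np.mean(x)) if x.size >= 2 else np.nan
    return log2_by_cond, geo, cv


def anova_screen(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    fc_min: float = 1.5,
) -> list[StatRecord]:
    """One-way ANOVA across conditions with a conjunctive fold-change gate.

    Per row, the ANOVA runs on log2 ratios across all conditions with >= 2
    replicates; the fold change is max/min of the per-condition geometric
    means.  A row is significant iff ``p < alpha`` and ``fold change >
    fc_min`` — both gates must pass, in either order.  Rows with data in
    fewer than two conditions are skipped.
    """
    _check_positive(matrix)
    groups = _groups(matrix, design)
    records: list[StatRecord] = []
    for row_id, values in matrix.iterrows():
        log2_by_cond, geo, cv = _row_stats(values, groups)
        testable = [v for v in log2_by_cond.values() if v.size >= 2]
        if len(testable) < 2 or not geo:
            continue
        p = float(sps.f_oneway(*testable).pvalue)
        fc = max(geo.values()) / min(geo.values())
        peaking, tie = classify_peaking(geo) if set(DIURNAL_ORDER) <= set(geo) else (None, False)
        records.append(
            StatRecord(
                row_id=str(row_id),
                p_value=p,
                fold_change=fc,
                condition_means=geo,
                condition_cv=cv,
                significant=bool(p < alpha and fc > fc_min),
                peaking=peaking,
                tie=tie,
            )
        )
    return records


def pairwise_screen(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    cond_a: str = "MD",
    cond_b: str = "CL",
    alpha: float = 0.05,
    fc_min: float = 1.5,
) -> list[StatRecord]:
    """Two-condition contrast by Student's t test (equal variance) on log2 ratios.

    Fold change is the ratio of the two geometric means, larger over
    smaller; significance requires both ``p < alpha`` and ``fold change >
    fc_min``.  ``peaking`` reports the higher condition.
    """
    _check_positive(matrix)
    groups = _groups(matrix, design)
    for cond in (cond_a, cond_b):
        if len(groups.get(cond, [])) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")
    records: list[StatRecord] = []
    for row_id, values in matrix.iterrows():
        a = np.log2(values[groups[cond_a]].dropna().to_numpy(dtype=float))
        b = np.log2(values[groups[cond_b]].dropna().to_numpy(dtype=float))
        if a.size < 2 or b.size < 2:
            continue
        p = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
        geo = {cond_a: float(2 ** a.mean()), cond_b: float(2 ** b.mean())}
        cv = {
            cond_a: float(np.std(2**a, ddof=1) / np.mean(2**a)),
            cond_b: float(np.std(2**b, ddof=1) / np.mean(2**b)),
        }
        fc = max(geo.values()) / min(geo.values())
        records.append(
            StatRecord(
                row_id=str(row_id),
                p_value=p,
                fold_change=fc,
                condition_means=geo,
                condition_cv=cv,
                significant=bool(p < alpha and fc > fc_min),
                peaking=max(geo, key=geo.get),
            )
        )
    return records


def cv_gate(matrix: pd.DataFrame, design: pd.DataFrame, cv_max: float = 0.3) -> list[str]:
    """Rows whose average intra-condition coefficient of variation is <= cv_max.

    CV is computed per condition on the raw ratios (sample SD over mean) and
    averaged across conditions; rows with a non-positive condition mean are
    dropped.
    """
    groups = _groups(matrix, design)
    survivors: list[str] = []
    for row_id, values in matrix.iterrows():
        cvs = []
        ok = True
        for cols in groups.values():
            x = values[cols].dropna().to_numpy(dtype=float)
            if x.size < 2:
                continue
            m = np.mean(x)
            if m <= 0:
                ok = False
                break
            cvs.append(np.std(x, ddof=1) / m)
        if ok and cvs and float(np.mean(cvs)) <= cv_max:
            survivors.append(str(row_id))
    return survivors


def pca_scores(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    n_components: int = 2,
    coverage: float = 0.95,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """PCA of samples on an autoscaled matrix, with per-condition ellipses.

    ``matrix`` holds autoscaled log2 values (rows = metabolites, columns =
    samples); missing entries are imputed by the row mean before the
    decomposition.  Samples are the observations: scores come from the SVD
    of the column-centered sample x metabolite table.  Each condition gets
    a confidence ellipse from a bivariate normal fitted to its PC1/PC2
    scores, sized by the chi-square quantile with 2 degrees of freedom.

    Returns (scores, explained variance ratio, ellipses) where ellipses maps
    condition -> dict(center, width, height, angle_deg) in score units.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    filled = matrix.apply(lambda r: r.fillna(r.mean()), axis=1).fillna(0.0)
    X = filled.to_numpy(dtype=float).T  # samples x metabolites
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    score_df = pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    ellipses: dict[str, dict] = {}
    if n_components >= 2:
        q = chi2.ppf(coverage, df=2)
        for cond, cols in _groups(score_df.T, design).items():
            pts = score_df.loc[cols, ["PC1", "PC2"]].to_numpy()
            if pts.shape[0] < 3:
                continue
            center = pts.mean(axis=0)
            cov = np.cov(pts, rowvar=False)
            eigval, eigvec = np.linalg.eigh(cov)
            order = np.argsort(eigval)[::-1]
            eigval, eigvec = eigval[order], eigvec[:, order]
            ellipses[cond] = {
                "center": center,
                "width": 2 * np.sqrt(q * max(eigval[0], 0.0)),
                "height": 2 * np.sqrt(q * max(eigval[1], 0.0)),
                "angle_deg": float(np.degrees(np.arctan2(eigvec[1, 0], eigvec[0, 0]))),
            }
    return score_df, pca.explained_variance_ratio_, ellipses


def classify_peaking(condition_means: dict) -> tuple[str, bool]:
    """Diurnal condition with the highest mean; ties take the earliest.

    Requires all four diurnal conditions (M, MD, E, MN).  Returns
    ``(label, tie)`` with ``tie`` set when the maximum is shared.
    """
    missing = [c for c in DIURNAL_ORDER if c not in condition_means]
    if missing:
        raise ValueError(f"missing diurnal conditions: {missing}")
    values = [condition_means[c] for c in DIURNAL_ORDER]
    top = max(values)
    winners = [c for c, v in zip(DIURNAL_ORDER, values) if v == top]
    return winners[0], len(winners) > 1
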