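"""Synthetic study generator with full ground truth.

Emulates the data structure of a dual stable-isotope diurnal metabolomics
study on a cyanobacterial culture:

* a library of named polar metabolites (CBB-cycle intermediates, sugar
  phosphates, amino acids, nucleotides, dipeptides) plus unannotated
  biological compounds, each with an elemental formula, retention time,
  base abundance, and a diurnal abundance class;
* mixed injections — every sample carries, for each compound, an unlabeled
  (12C) peak whose area follows the condition's diurnal multiplier and a
  co-eluting fully 13C-labeled internal-standard peak of constant spike
  amount, both scaled by the same per-sample matrix effect and perturbed by
  multiplicative lognormal noise;
* separate control / fully-13C / fully-15N culture injections for
  credentialing;
* non-biological background features (solvent contaminants) with no
  labeled partner, constructed so they cannot be isotope-paired at the
  default tolerances;
* an OD720 time series from the half-sine light-driven growth model, with
  optional dawn/dusk dips;
* a ground-truth bundle sufficient to score every downstream stage.

Five conditions are simulated: morning (M), midday (MD), evening (E) and
midnight (MN) within a diurnal cycle, plus continuous light (CL).  A
compound of class ``c`` peaking at condition ``k`` has true multiplier
``amplitude ** (1 - d/2)`` where ``d`` is the circular distance between
conditions (so peak : shoulder : trough = 8 : 2.83 : 1 at the default
amplitude of 8); CL sits at the geometric mid-level ``amplitude ** 0.5``;
``flat`` compounds stay at 1 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthSeries, LightProfile, simulate_od
from .isotopes import CONSTANTS, ElementalFormula, labeled_mz, mz_deprotonated
from .pairing import Feature
from .spectra import LibraryEntry, Ms2Spectrum
from .stats import CONDITIONS, DIURNAL_ORDER

__all__ = [
    "NAMED_METABOLITES",
    "MetaboliteSpec",
    "GeneratorConfig",
    "GroundTruth",
    "StudyBundle",
    "class_multiplier",
    "generate_library",
    "generate_study",
]

DIURNAL_CLASSES = DIURNAL_ORDER + ["flat"]

#: Curated (name, Hill formula) pool of polar metabolites spanning the
#: compound classes the study design covers.  The two worked exemplars
#: (3PGA and UDP-xylose) head the list so every library contains them.
NAMED_METABOLITES: tuple[tuple[str, str], ...] = (
    ("3PGA", "C3H7O7P"),
    ("UDP-xylose", "C14H22N2O16P2"),
    ("glucose", "C6H12O6"),
    ("RuBP", "C5H12O11P2"),
    ("FBP", "C6H14O12P2"),
    ("SBP", "C7H16O13P2"),
    ("S7P", "C7H15O10P"),
    ("G6P", "C6H13O9P"),
    ("F6P", "C6H13O9P"),
    ("R5P", "C5H11O8P"),
    ("DHAP", "C3H7O6P"),
    ("2-phosphoglycolate", "C2H5O6P"),
    ("6-phosphogluconate", "C6H13O10P"),
    ("PEP", "C3H5O6P"),
    ("glycerol-3-phosphate", "C3H9O6P"),
    ("sucrose", "C12H22O11"),
    ("glucosylglycerol", "C9H18O8"),
    ("citrate", "C6H8O7"),
    ("2-oxoglutarate", "C5H6O5"),
    ("succinate", "C4H6O4"),
    ("fumarate", "C4H4O4"),
    ("malate", "C4H6O5"),
    ("pyruvate", "C3H4O3"),
    ("lactate", "C3H6O3"),
    ("glycerate", "C3H6O4"),
    ("glycolate", "C2H4O3"),
    ("shikimate", "C7H10O5"),
    ("glycine", "C2H5NO2"),
    ("alanine", "C3H7NO2"),
    ("serine", "C3H7NO3"),
    ("proline", "C5H9NO2"),
    ("valine", "C5H11NO2"),
    ("threonine", "C4H9NO3"),
    ("cysteine", "C3H7NO2S"),
    ("leucine", "C6H13NO2"),
    ("isoleucine", "C6H13NO2"),
    ("asparagine", "C4H8N2O3"),
    ("aspartate", "C4H7NO4"),
    ("glutamine", "C5H10N2O3"),
    ("lysine", "C6H14N2O2"),
    ("glutamate", "C5H9NO4"),
    ("methionine", "C5H11NO2S"),
    ("histidine", "C6H9N3O2"),
    ("phenylalanine", "C9H11NO2"),
    ("arginine", "C6H14N4O2"),
    ("tyrosine", "C9H11NO3"),
    ("tryptophan", "C11H12N2O2"),
    ("citrulline", "C6H13N3O3"),
    ("ornithine", "C5H12N2O2"),
    ("AMP", "C10H14N5O7P"),
    ("ADP", "C10H15N5O10P2"),
    ("ATP", "C10H16N5O13P3"),
    ("GMP", "C10H14N5O8P"),
    ("GDP", "C10H15N5O11P2"),
    ("GTP", "C10H16N5O14P3"),
    ("UMP", "C9H13N2O9P"),
    ("UDP", "C9H14N2O12P2"),
    ("UTP", "C9H15N2O15P3"),
    ("CMP", "C9H14N3O8P"),
    ("ADP-glucose", "C16H25N5O15P2"),
    ("UDP-glucose", "C15H24N2O17P2"),
    ("NAD", "C21H27N7O14P2"),
    ("NADP", "C21H28N7O17P3"),
    ("IMP", "C10H13N4O8P"),
    ("inosine", "C10H12N4O5"),
    ("adenosine", "C10H13N5O4"),
    ("adenine", "C5H5N5"),
    ("guanine", "C5H5N5O"),
    ("uracil", "C4H4N2O2"),
    ("uridine", "C9H12N2O6"),
    ("cytidine", "C9H13N3O5"),
    ("hypoxanthine", "C5H4N4O"),
    ("glutathione", "C10H17N3O6S"),
    ("glutathione-disulfide", "C20H32N6O12S2"),
    ("gamma-Glu-Glu", "C10H16N2O7"),
    ("gamma-Glu-Cys", "C8H14N2O5S"),
    ("Ala-Ala", "C6H12N2O3"),
    ("Gly-Glu", "C7H12N2O5"),
    ("pantothenate", "C9H17NO5"),
    ("nicotinamide", "C6H6N2O"),
    ("cAMP", "C10H12N5O6P"),
)


@dataclass(frozen=True)
class MetaboliteSpec:
    """Ground-truth description of one simulated compound."""

    name: str
    formula: ElementalFormula
    base_abundance: float
    diurnal_class: str  # one of M, MD, E, MN, flat
    amplitude: float
    rt_min: float
    ms2_template: Ms2Spectrum | None = None
    annotated: bool = True

    def __post_init__(self):
        if self.base_abundance <= 0:
            raise ValueError("base abundance must be positive")
        if self.amplitude < 1:
            raise ValueError("class amplitude must be >= 1")
        if self.diurnal_class not in DIURNAL_CLASSES:
            raise ValueError(f"unknown diurnal class {self.diurnal_class!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale and noise settings for the synthetic generator.

    Scale defaults mirror the study design this package emulates: 67
    annotated metabolites plus 47 unannotated biological compounds (114
    credentialable features), five conditions with 3 replicates.  Noise
    defaults are realistic for high-resolution TOF data: 10% multiplicative
    peak-area CV, 20% lognormal per-sample matrix-effect spread, 2 ppm m/z
    jitter.
    """

    n_metabolites: int = 67
    n_unknown: int = 47
    n_background: int = 50
    conditions: tuple[str, ...] = tuple(CONDITIONS)
    n_replicates: int = 3
    noise_cv: float = 0.10
    matrix_spread: float = 0.20
    mz_ppm_noise: float = 2.0
    rt_jitter_min: float = 0.01
    ms2_noise_cv: float = 0.0
    label_purity: float = 1.0
    amplitude: float = 8.0
    heavy_tail_amplitudes: bool = False
    is_spike_ratio: float = 1.0
    # growth-model settings
    light: LightProfile = field(default_factory=LightProfile)
    mu_peak: float = 0.1604
    od0: float = 0.1
    od_dt: float = 0.05
    od_sample_dt: float = 0.25
    od_horizon: float = 96.0
    od_noise_cv: float = 0.003
    dip_depth: float = 0.04
    seed: int = 0

    def __post_init__(self):
        for name in ("noise_cv", "matrix_spread", "ms2_noise_cv", "od_noise_cv"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0 < self.label_purity <= 1:
            raise ValueError("label purity must lie in (0, 1]")
        if self.n_metabolites < 1:
            raise ValueError("need at least one metabolite")
        if self.n_metabolites > len(NAMED_METABOLITES):
            raise ValueError(
                f"at most {len(NAMED_METABOLITES)} named metabolites available"
            )


@dataclass(frozen=True, eq=False)
class GroundTruth:
    """Everything needed to score the pipeline, never read by the pipeline."""

    true_ratio: pd.DataFrame  # compounds x samples: true 12C/13C ratios
    diurnal_class: pd.Series  # compound -> class label
    annotated: pd.Series  # compound -> bool
    multipliers: pd.DataFrame  # compounds x conditions: true condition multipliers
    compound_location: pd.DataFrame  # compound -> (mz, rt_min, n_carbon, n_nitrogen)
    background_ids: frozenset  # base ids of non-biological decoys
    mu_peak: float


@dataclass(frozen=True, eq=False)
class StudyBundle:
    """All generator outputs for one synthetic study."""

    config: GeneratorConfig
    library: list  # MetaboliteSpec, annotated
    unknowns: list  # MetaboliteSpec, unannotated biological compounds
    msp_library: list  # LibraryEntry for the annotation stage
    mixed_features: dict  # sample id -> list[Feature] (sample + 13C IS injection)
    control_features: list  # unlabeled culture injection
    c13_features: list  # fully 13C-fed culture injection
    n15_features: list  # fully 15N-fed culture injection
    design: pd.DataFrame  # sample id -> condition, replicate
    od: GrowthSeries
    truth: GroundTruth


def class_multiplier(diurnal_class: str, condition: str, amplitude: float) -> float:
    """True abundance multiplier for a diurnal class under a condition."""
    if diurnal_class == "flat":
        return 1.0
    if condition == "CL":
        return amplitude**0.5
    i = DIURNAL_ORDER.index(diurnal_class)
    j = DIURNAL_ORDER.index(condition)
    d = min(abs(i - j), len(DIURNAL_ORDER) - abs(i - j))
    return amplitude ** (1 - d / 2)


def _random_ms2(rng: np.random.Generator, precursor_mz: float) -> Ms2Spectrum:
    n_frag = int(rng.integers(4, 9))
    mz = np.sort(rng.uniform(50.0, max(55.0, precursor_mz - 1.0), n_frag))
    intensity = rng.uniform(0.05, 1.0, n_frag)
    intensity /= intensity.max()
    return Ms2Spectrum(precursor_mz, tuple(zip(mz.tolist(), intensity.tolist())))


def _assign_rts(
    rng: np.random.Generator, mzs: list[float], min_sep: float = 0.4, ppm_window: float = 20.0
) -> list[float]:
    """Random retention times, kept apart for near-isobaric compounds.

    Compounds whose m/z agree within ``ppm_window`` ppm get retention times
    at least ``min_sep`` minutes apart so isobars stay chromatographically
    resolved (single-peak-per-compound assumption).
    """
    rts: list[float] = []
    for i, mz in enumerate(mzs):
        for _ in range(1000):
            rt = float(rng.uniform(0.5, 12.0))
            clash = any(
                abs(mz - mzs[j]) <= ppm_window * 1e-6 * mz and abs(rt - rts[j]) < min_sep
                for j in range(i)
            )
            if not clash:
                break
        rts.append(rt)
    return rts


def _make_specs(
    rng: np.random.Generator,
    pool: list[tuple[str, str]],
    config: GeneratorConfig,
    annotated: bool,
) -> list[MetaboliteSpec]:
    formulas = [ElementalFormula(f) for _, f in pool]
    mzs = [mz_deprotonated(f) for f in formulas]
    rts = _assign_rts(rng, mzs)
    specs = []
    for i, ((name, _), formula, rt) in enumerate(zip(pool, formulas, rts)):
        if config.heavy_tail_amplitudes and rng.uniform() < 0.1:
            amplitude = float(np.clip(rng.lognormal(np.log(30.0), 0.5), 8.0, 100.0))
        else:
            amplitude = config.amplitude
        specs.append(
            MetaboliteSpec(
                name=name,
                formula=formula,
                base_abundance=float(rng.lognormal(np.log(1e5), 0.8)),
                diurnal_class=DIURNAL_CLASSES[i % len(DIURNAL_CLASSES)],
                amplitude=amplitude,
                rt_min=rt,
                ms2_template=_random_ms2(rng, mz_deprotonated(formula)),
                annotated=annotated,
            )
        )
    return specs


def _random_formula(rng: np.random.Generator) -> ElementalFormula:
    nc = int(rng.integers(3, 25))
    counts = {
        "C": nc,
        "H": int(rng.integers(max(2, nc // 2), 2 * nc + 3)),
        "N": int(rng.choice([0, 0, 1, 1, 2, 3, 4])),
        "O": int(rng.integers(2, 13)),
        "P": int(rng.choice([0, 0, 0, 1, 1, 2])),
        "S": int(rng.choice([0, 0, 0, 0, 1])),
    }
    return ElementalFormula({k: v for k, v in counts.items() if v})


def generate_library(config: GeneratorConfig) -> list[MetaboliteSpec]:
    """Reproducible library of annotated metabolites (classes round-robin)."""
    rng = np.random.default_rng(config.seed)
    pool = list(NAMED_METABOLITES[: config.n_metabolites])
    return _make_specs(rng, pool, config, annotated=True)


def _noise(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(-(sigma**2) / 2, sigma, size)


def _jitter_mz(rng: np.random.Generator, mz: float, ppm: float) -> float:
    if ppm <= 0:
        return mz
    return mz * (1 + float(rng.uniform(-ppm, ppm)) * 1e-6)


def _noisy_spectrum(
    rng: np.random.Generator, template: Ms2Spectrum, cv: float
) -> Ms2Spectrum:
    if cv <= 0:
        return template
    frags = tuple(
        (m, float(i * _noise(rng, cv))) for m, i in template.fragments
    )
    return Ms2Spectrum(template.precursor_mz, frags)


def _is_pairable(mz_a: float, mz_b: float, delta: float, n_max: int, ppm: float) -> bool:
    shift = abs(mz_b - mz_a)
    n = round(shift / delta)
    if not 1 <= n <= n_max:
        return False
    return abs(shift - n * delta) <= ppm * 1e-6 * max(mz_a, mz_b)


def _background_positions(
    rng: np.random.Generator, config: GeneratorConfig, taken: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Random (m/z, RT) decoy positions that cannot form an isotope pair.

    Rejection-sampled against every existing peak position (and previously
    placed decoys) with widened tolerances, so at the pipeline's default
    tolerances no decoy has a 13C-shift partner: decoy ground truth is
    unambiguous by construction.
    """
    positions: list[tuple[float, float]] = []
    existing = list(taken)
    for _ in range(config.n_background):
        for _ in range(2000):
            mz = float(rng.uniform(100.0, 1000.0))
            rt = float(rng.uniform(0.3, 12.2))
            clash = any(
                abs(rt - rt0) <= 0.3
                and (
                    _is_pairable(mz, mz0, CONSTANTS.delta_13c, 60, 30.0)
                    or abs(mz - mz0) <= 30e-6 * mz
                )
                for mz0, rt0 in existing
            )
            if not clash:
                break
        positions.append((mz, rt))
        existing.append((mz, rt))
    return positions


def generate_study(
    config: GeneratorConfig, library: list[MetaboliteSpec] | None = None
) -> StudyBundle:
    """Generate one full synthetic study with ground truth.

    Deterministic for a fixed config (byte-identical tables when written
    with the writers in :mod:`isodiel.io`).
    """
    if library is None:
        library = generate_library(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    unknown_pool = [(f"unknown{i + 1:03d}", _random_formula(rng).hill())
                    for i in range(config.n_unknown)]
    unknowns = _make_specs(rng, unknown_pool, config, annotated=False)
    compounds = list(library) + list(unknowns)

    design = pd.DataFrame(
        [
            {"sample_id": f"{cond}_{r + 1}", "condition": cond, "replicate": r + 1}
            for cond in config.conditions
            for r in range(config.n_replicates)
        ]
    ).set_index("sample_id")

    mult = pd.DataFrame(
        {
            cond: [class_multiplier(s.diurnal_class, cond, s.amplitude) for s in compounds]
            for cond in config.conditions
        },
        index=[s.name for s in compounds],
    )
    true_ratio = pd.DataFrame(
        {
            sample: mult[design.loc[sample, "condition"]] / config.is_spike_ratio
            for sample in design.index
        }
    )

    # fixed peak positions for decoy rejection sampling
    unl_mz = {s.name: mz_deprotonated(s.formula) for s in compounds}
    lab_mz = {s.name: labeled_mz(s.formula, "13C")[0] for s in compounds}
    taken = [(unl_mz[s.name], s.rt_min) for s in compounds]
    taken += [(lab_mz[s.name], s.rt_min) for s in compounds]
    bg_positions = _background_positions(rng, config, taken)
    bg_ms2 = [
        _random_ms2(rng, mz) if rng.uniform() < 0.5 else None for mz, _ in bg_positions
    ]
    bg_area = rng.lognormal(np.log(2e4), 0.8, config.n_background)

    # per-sample matrix effect: mean-one lognormal with sigma = matrix_spread
    matrix_effect = {
        sample: float(np.exp(rng.normal(-config.matrix_spread**2 / 2, config.matrix_spread)))
        if config.matrix_spread > 0
        else 1.0
        for sample in design.index
    }

    mixed_features: dict[str, list[Feature]] = {}
    for sample in design.index:
        cond = design.loc[sample, "condition"]
        g = matrix_effect[sample]
        feats: list[Feature] = []
        for spec in compounds:
            true_level = spec.base_abundance * mult.loc[spec.name, cond]
            area_u = true_level * g * float(_noise(rng, config.noise_cv))
            spike = spec.base_abundance * config.is_spike_ratio
            area_is = (
                spike
                * g
                * float(_noise(rng, config.noise_cv))
                * config.label_purity**spec.formula.n_carbon
            )
            rt = spec.rt_min + float(rng.uniform(-1, 1)) * config.rt_jitter_min
            spectrum = (
                _noisy_spectrum(rng, spec.ms2_template, config.ms2_noise_cv)
                if spec.ms2_template is not None
                else None
            )
            feats.append(
                Feature(
                    feature_id=f"U::{spec.name}::{sample}",
                    sample_id=sample,
                    mz=_jitter_mz(rng, unl_mz[spec.name], config.mz_ppm_noise),
                    rt_min=rt,
                    area=area_u,
                    spectrum=spectrum,
                )
            )
            feats.append(
                Feature(
                    feature_id=f"IS::{spec.name}::{sample}",
                    sample_id=sample,
                    mz=_jitter_mz(rng, lab_mz[spec.name], config.mz_ppm_noise),
                    rt_min=spec.rt_min + float(rng.uniform(-1, 1)) * config.rt_jitter_min,
                    area=area_is,
                    spectrum=None,
                )
            )
        for k, ((mz, rt), ms2, area) in enumerate(zip(bg_positions, bg_ms2, bg_area)):
            feats.append(
                Feature(
                    feature_id=f"BG::bg{k + 1:03d}::{sample}",
                    sample_id=sample,
                    mz=_jitter_mz(rng, mz, config.mz_ppm_noise),
                    rt_min=rt + float(rng.uniform(-1, 1)) * config.rt_jitter_min,
                    area=float(area * g * _noise(rng, config.noise_cv)),
                    spectrum=ms2,
                )
            )
        mixed_features[sample] = feats

    def culture(tag: str, mz_of) -> list[Feature]:
        feats = []
        for spec in compounds:
            feats.append(
                Feature(
                    feature_id=f"{tag}::{spec.name}",
                    sample_id=tag,
                    mz=_jitter_mz(rng, mz_of(spec), config.mz_ppm_noise),
                    rt_min=spec.rt_min + float(rng.uniform(-1, 1)) * config.rt_jitter_min,
                    area=spec.base_abundance * float(_noise(rng, config.noise_cv)),
                    spectrum=None,
                )
            )
        for k, ((mz, rt), area) in enumerate(zip(bg_positions, bg_area)):
            feats.append(
                Feature(
                    feature_id=f"{tag}::bg{k + 1:03d}",
                    sample_id=tag,
                    mz=_jitter_mz(rng, mz, config.mz_ppm_noise),
                    rt_min=rt + float(rng.uniform(-1, 1)) * config.rt_jitter_min,
                    area=float(area * _noise(rng, config.noise_cv)),
                    spectrum=None,
                )
            )
        return feats

    control_features = culture("CTRL", lambda s: unl_mz[s.name])
    c13_features = culture("C13", lambda s: lab_mz[s.name])
    n15_features = culture("N15", lambda s: labeled_mz(s.formula, "15N")[0])

    od = _simulate_study_od(rng, config)

    truth = GroundTruth(
        true_ratio=true_ratio,
        diurnal_class=pd.Series({s.name: s.diurnal_class for s in compounds}),
        annotated=pd.Series({s.name: s.annotated for s in compounds}),
        multipliers=mult,
        compound_location=pd.DataFrame(
            {
                "mz": {s.name: unl_mz[s.name] for s in compounds},
                "rt_min": {s.name: s.rt_min for s in compounds},
                "n_carbon": {s.name: s.formula.n_carbon for s in compounds},
                "n_nitrogen": {s.name: s.formula.n_nitrogen for s in compounds},
            }
        ),
        background_ids=frozenset(f"bg{k + 1:03d}" for k in range(config.n_background)),
        mu_peak=config.mu_peak,
    )
    msp_library = [
        LibraryEntry(s.name, s.formula.hill(), s.ms2_template)
        for s in library
        if s.ms2_template is not None
    ]
    return StudyBundle(
        config=config,
        library=list(library),
        unknowns=unknowns,
        msp_library=msp_library,
        mixed_features=mixed_features,
        control_features=control_features,
        c13_features=c13_features,
        n15_features=n15_features,
        design=design,
        od=od,
        truth=truth,
    )


def _simulate_study_od(rng: np.random.Generator, config: GeneratorConfig) -> GrowthSeries:
    """OD720 trace over the study horizon with optional dawn/dusk dips."""
    series = simulate_od(
        config.light, config.mu_peak, config.od0, config.od_dt, config.od_horizon
    )
    od = series.od720.copy()
    if config.dip_depth > 0:
        phase = np.mod(series.time_h - config.light.dawn, config.light.cycle)
        for center in (1.0, config.light.photoperiod - 1.0):
            od *= 1 - config.dip_depth * np.exp(-((phase - center) ** 2) / (2 * 0.5**2))
    # turbidity readings come at a coarser cadence than the integrator step
    every = max(1, int(round(config.od_sample_dt / config.od_dt)))
    t, od = series.time_h[::every], od[::every]
    if config.od_noise_cv > 0:
        od = od * _noise(rng, config.od_noise_cv, od.shape)
    return GrowthSeries(time_h=t, od720=od)
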