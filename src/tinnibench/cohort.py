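"""Synthetic mixed-type cohorts with planted endotype structure.

Generates patient tables that emulate a large retrospective tinnitus
case-history database: ~44 quantitative and categorical questionnaire
features, six rare diagnosed endotypes embedded in a mostly-unlabeled
background population, planted per-endotype effect-size vectors, and
injectable MCAR missingness.  Every downstream stage of the pipeline can
therefore be exercised against a known ground truth.

Model assumptions
-----------------
* Endotype membership is mono-label and deterministic in count:
  ``round(prevalence * n_patients)`` members per endotype.
* Quantitative features are independent Gaussians in native units,
  clipped to the declared [min, max] (questionnaire scores are bounded);
  an endotype effect shifts the mean by ``D * sd`` (pooled Cohen's D).
* Categorical features are independent draws from the baseline level
  probabilities, or from a per-endotype override.
* Missingness is MCAR: each patient draws a missing rate from
  ``missing_patient_rates`` and each cell is masked independently at that
  rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    CATEGORICAL,
    NO_DIAGNOSIS,
    QUANTITATIVE,
    ColumnSchema,
    PatientTable,
)

__all__ = [
    "FeatureSpec",
    "EndotypeSpec",
    "CohortSpec",
    "generate_cohort",
    "inject_missingness",
    "make_reference_spec",
    "make_separable_spec",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Baseline distribution of one questionnaire feature.

    For a quantitative feature, ``mean``/``sd``/``minimum``/``maximum``
    describe a clipped Gaussian in native units.  For a categorical
    feature, ``levels`` and ``probs`` give the baseline level
    probabilities.
    """

    name: str
    kind: str
    mean: float | None = None
    sd: float | None = None
    minimum: float | None = None
    maximum: float | None = None
    levels: tuple[str, ...] = ()
    probs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == QUANTITATIVE:
            if self.sd is None or self.sd <= 0:
                raise ValueError(f"{self.name}: sd must be > 0")
            if not (self.minimum <= self.mean <= self.maximum):
                raise ValueError(f"{self.name}: need min <= mean <= max")
        elif self.kind == CATEGORICAL:
            if len(self.levels) != len(self.probs) or not self.levels:
                raise ValueError(f"{self.name}: levels and probs must align")
            p = np.asarray(self.probs, dtype=float)
            if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{self.name}: probs must be >= 0 and sum to 1")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def schema(self) -> ColumnSchema:
        if self.kind == CATEGORICAL:
            return ColumnSchema(kind=CATEGORICAL, levels=self.levels)
        return ColumnSchema(kind=QUANTITATIVE)


@dataclass(frozen=True)
class EndotypeSpec:
    """One planted endotype: prevalence, effects, and labeling rate.

    ``effect`` maps feature name to either a Cohen's-D mean shift
    (quantitative feature) or a level-probability override given as a
    mapping level -> probability (categorical feature).
    ``label_fraction`` is the fraction of the endotype's members whose
    diagnosis is observed in the released label column.
    """

    name: str
    prevalence: float
    effect: dict = field(default_factory=dict)
    label_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{self.name}: prevalence outside [0, 1]")
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ValueError(f"{self.name}: label_fraction outside [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a synthetic cohort.

    ``missing_patient_rates`` is a distribution over per-patient missing
    fractions: either a constant in [0, 1] or a ``(low, high)`` tuple for
    a uniform draw.
    """

    n_patients: int
    features: tuple[FeatureSpec, ...]
    endotypes: tuple[EndotypeSpec, ...]
    missing_patient_rates: float | tuple[float, float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if sum(e.prevalence for e in self.endotypes) > 1.0 + 1e-9:
            raise ValueError("endotype prevalences sum above 1")
        for low, high in [self._rate_bounds()]:
            if not (0.0 <= low <= high <= 1.0):
                raise ValueError("missing_patient_rates outside [0, 1]")

    def _rate_bounds(self) -> tuple[float, float]:
        if isinstance(self.missing_patient_rates, (int, float)):
            r = float(self.missing_patient_rates)
            return r, r
        low, high = self.missing_patient_rates
        return float(low), float(high)

    def endotype_counts(self) -> dict[str, int]:
        """Deterministic member counts: round(prevalence * n_patients)."""
        return {
            e.name: int(round(e.prevalence * self.n_patients))
            for e in self.endotypes
        }

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def _draw_feature(
    rng: np.random.Generator, feat: FeatureSpec, size: int, effect
) -> np.ndarray:
    if feat.kind == QUANTITATIVE:
        shift = 0.0 if effect is None else float(effect) * feat.sd
        x = rng.normal(feat.mean + shift, feat.sd, size=size)
        return np.clip(x, feat.minimum, feat.maximum)
    probs = np.asarray(feat.probs, dtype=float)
    if effect is not None:
        override = dict(effect)
        probs = np.array([override.get(lv, 0.0) for lv in feat.levels], float)
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(
                f"level override for {feat.name!r} must cover all mass"
            )
    codes = rng.choice(len(feat.levels), size=size, p=probs / probs.sum())
    return np.asarray(feat.levels, dtype=object)[codes]


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[PatientTable, pd.Series, pd.Series]:
    """Generate a cohort with planted endotypes and partial labels.

    Returns ``(table, ground_truth, observed)``: the feature table (no
    missing cells yet), the true per-patient endotype assignment, and the
    observed partial label column (a seeded subsample of the truth at each
    endotype's ``label_fraction``; everyone else holds ``NO_DIAGNOSIS``).
    The table's own ``labels`` attribute is the observed column.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = spec.n_patients

    counts = spec.endotype_counts()
    if sum(counts.values()) > n:
        raise ValueError("rounded endotype counts exceed n_patients")

    # Seeded random placement of endotype members among patients.
    order = rng.permutation(n)
    truth = np.full(n, NO_DIAGNOSIS, dtype=object)
    start = 0
    for endo in spec.endotypes:
        k = counts[endo.name]
        truth[order[start : start + k]] = endo.name
        start += k
    effects = {e.name: e.effect for e in spec.endotypes}
    label_fraction = {e.name: e.label_fraction for e in spec.endotypes}

    index = pd.RangeIndex(n, name="patient_id")
    columns: dict[str, np.ndarray] = {}
    for feat in spec.features:
        if feat.kind == QUANTITATIVE:
            col = np.empty(n, dtype=float)
        else:
            col = np.empty(n, dtype=object)
        base_mask = truth == NO_DIAGNOSIS
        col[base_mask] = _draw_feature(rng, feat, int(base_mask.sum()), None)
        for endo in spec.endotypes:
            mask = truth == endo.name
            if not mask.any():
                continue
            col[mask] = _draw_feature(
                rng, feat, int(mask.sum()), effects[endo.name].get(feat.name)
            )
        columns[feat.name] = col

    observed = np.full(n, NO_DIAGNOSIS, dtype=object)
    for endo in spec.endotypes:
        members = np.flatnonzero(truth == endo.name)
        n_labeled = int(round(label_fraction[endo.name] * len(members)))
        chosen = rng.permutation(members)[:n_labeled]
        observed[chosen] = endo.name

    data = pd.DataFrame(columns, index=index)
    schema = {f.name: f.schema() for f in spec.features}
    labels = pd.Series(observed, index=index, name="endotype")
    table = PatientTable(data=data, schema=schema, labels=labels)
    return table, pd.Series(truth, index=index, name="true_endotype"), labels


def inject_missingness(
    table: PatientTable, spec: CohortSpec, seed: int
) -> PatientTable:
    """Mask feature cells MCAR at per-patient rates drawn from the spec.

    Each patient draws one missing rate from ``spec.missing_patient_rates``
    and every feature cell of that patient is masked independently at this
    rate.  The label column is never masked.
    """
    low, high = spec._rate_bounds()
    rng = np.random.default_rng(seed)
    out = table.copy()
    n, p = out.data.shape
    rates = rng.uniform(low, high, size=n) if high > low else np.full(n, low)
    mask = rng.random((n, p)) < rates[:, None]
    values = out.data.to_numpy(dtype=object)
    values[mask] = np.nan
    data = pd.DataFrame(values, index=out.data.index, columns=out.data.columns)
    for col in out.quantitative_columns:
        data[col] = pd.to_numeric(data[col])
    return PatientTable(data=data, schema=out.schema, labels=out.labels)


# ---------------------------------------------------------------------------
# Built-in cohort recipes
# ---------------------------------------------------------------------------

# Quantitative questionnaire features of the reference tinnitus cohort:
# (name, mean, sd, min, max) in native units.
_REFERENCE_QUANTITATIVE = [
    ("age_years", 51.3, 14.74, 18, 95),
    ("thi_score", 50.98, 23.83, 0, 100),
    ("tinnitus_duration_months", 67.79, 93.12, 0, 852),
    ("pct_time_tinnitus_present", 66.34, 28.19, 0, 100),
    ("vas_tinnitus_annoyance", 6.89, 2.17, 0, 10),
    ("vas_anxiety", 4.89, 3.25, 0, 10),
    ("vas_sleep_quality", 5.25, 3.35, 0, 10),
    ("vas_hyperacusis", 5.05, 3.41, 0, 10),
    ("vas_vertigo", 2.36, 2.94, 0, 10),
    ("vas_headache", 2.16, 3.23, 0, 10),
    ("vas_jaw_pain", 1.9, 2.79, 0, 10),
    ("vas_cervical_pain", 2.63, 3.39, 0, 10),
    ("khalfa_hyperacusis", 19.72, 9.73, 0, 42),
    ("had_anxiety", 9.18, 4.24, 0, 21),
    ("had_depression", 6.47, 4.6, 0, 21),
    ("isi_score", 12.39, 6.62, 0, 28),
    ("epworth_score", 7.62, 4.7, 0, 24),
    ("sleep_onset_latency_min", 35.72, 27.23, 0, 121),
]

# Categorical features: (name, {level: occurrence count}).  Counts are the
# observed occurrences in the reference cohort; baseline probabilities are
# their normalisation.
_REFERENCE_CATEGORICAL = [
    ("gender", {"female": 1491, "male": 1226}),
    ("tinnitus_apparition", {"brutal": 1665, "progressive": 1099}),
    ("tinnitus_side", {"left": 1015, "bilateral": 910, "right": 760}),
    ("tinnitus_lateralisation", {"bilateral": 910, "partially_lateral": 743, "lateral": 1032}),
    ("tinnitus_intensity", {"low": 1282, "medium": 990, "elevated": 500}),
    ("acoustic_trauma", {"yes": 460, "no": 2304}),
    ("tinnitus_pulsatile", {"yes": 231, "no": 2533}),
    ("narrow_band_noise", {"yes": 283, "no": 2481}),
    ("somatosensory_modulation", {"yes": 446, "no": 2318}),
    ("jaw_somatosensory_modulation", {"yes": 317, "no": 2447}),
    ("neck_somatosensory_modulation", {"yes": 256, "no": 2508}),
    ("frequent_headaches", {"yes": 826, "no": 1938}),
    ("frequent_cervical_pain", {"yes": 1198, "no": 1566}),
    ("trouble_falling_asleep", {"yes": 972, "sometimes": 505, "no": 1134}),
    ("nocturnal_awakenings", {"yes": 425, "sometimes": 530, "no": 1644}),
    ("tired_when_awake", {"yes": 653, "sometimes": 574, "no": 1360}),
    ("snoring", {"yes": 1152, "no": 1438}),
    ("sleep_apnea", {"yes": 217, "probably": 238, "no": 2102}),
    ("normal_hearing", {"yes": 337, "no": 2427}),
    ("sensorineural_hearing_loss", {"yes": 1563, "no": 656}),
    ("transmissional_hearing_loss", {"yes": 197, "no": 2022}),
    ("notch_hearing_loss", {"yes": 251, "no": 1968}),
    ("high_freq_hearing_loss", {"yes": 146, "no": 2073}),
    ("cophosis", {"yes": 38, "no": 2181}),
]

#: Endotype occurrence counts in the reference cohort of 2772 patients.
REFERENCE_ENDOTYPE_COUNTS = {
    "pulsatile_tinnitus": 231,
    "otosclerosis": 38,
    "menieres_disease": 35,
    "neurinoma": 24,
    "petrous_bone_fracture": 14,
    "eustachian_tube_dysfunction": 7,
}

REFERENCE_N_PATIENTS = 2772

# Clinically-flavoured effect maps for the reference endotypes: each
# endotype over-expresses its hallmark binary finding and shifts a few
# quantitative scales, echoing the differentiation patterns reported for
# diagnosed tinnitus subgroups (e.g. pulsatile tinnitus skews female with
# normal hearing, otosclerosis shows transmissional hearing loss).
_REFERENCE_EFFECTS = {
    "pulsatile_tinnitus": {
        "tinnitus_pulsatile": {"yes": 0.95, "no": 0.05},
        "gender": {"female": 0.75, "male": 0.25},
        "normal_hearing": {"yes": 0.45, "no": 0.55},
        "age_years": -0.5,
    },
    "otosclerosis": {
        "transmissional_hearing_loss": {"yes": 0.9, "no": 0.1},
        "tinnitus_apparition": {"brutal": 0.25, "progressive": 0.75},
        "vas_vertigo": 0.4,
    },
    "menieres_disease": {
        "vas_vertigo": 1.8,
        "tinnitus_lateralisation": {
            "bilateral": 0.1, "partially_lateral": 0.2, "lateral": 0.7,
        },
        "sensorineural_hearing_loss": {"yes": 0.9, "no": 0.1},
    },
    "neurinoma": {
        "cophosis": {"yes": 0.6, "no": 0.4},
        "tinnitus_lateralisation": {
            "bilateral": 0.05, "partially_lateral": 0.15, "lateral": 0.8,
        },
        "sensorineural_hearing_loss": {"yes": 0.95, "no": 0.05},
    },
    "petrous_bone_fracture": {
        "vas_headache": 1.5,
        "vas_vertigo": 1.0,
        "tinnitus_apparition": {"brutal": 0.9, "progressive": 0.1},
    },
    "eustachian_tube_dysfunction": {
        "transmissional_hearing_loss": {"yes": 0.6, "no": 0.4},
        "vas_tinnitus_annoyance": 0.3,
    },
}


def make_reference_spec(
    n_patients: int = REFERENCE_N_PATIENTS,
    missing_patient_rates: float | tuple[float, float] = (0.0, 8.0 / 15.0),
    seed: int = 0,
) -> CohortSpec:
    """Cohort spec emulating the reference tinnitus database.

    42 mixed features with the published summary statistics (means/sds and
    level occurrence counts of the preprocessed 2772-patient cohort), six
    endotypes at their observed prevalences, and full labeling of diagnosed
    endotypes, so the labeled fraction is 349/2772 = 12.59%.

    The default per-patient missing-rate distribution Uniform(0, 8/15) is
    calibrated so that about a quarter of patients exceed the 40% missing
    cut-off, matching the survivor fraction of the reference cohort's
    patient filter (74.9% retained).
    """
    features = [
        FeatureSpec(name, QUANTITATIVE, mean=m, sd=s, minimum=lo, maximum=hi)
        for name, m, s, lo, hi in _REFERENCE_QUANTITATIVE
    ]
    for name, level_counts in _REFERENCE_CATEGORICAL:
        levels = tuple(level_counts)
        total = float(sum(level_counts.values()))
        probs = tuple(c / total for c in level_counts.values())
        features.append(
            FeatureSpec(name, CATEGORICAL, levels=levels, probs=probs)
        )
    endotypes = [
        EndotypeSpec(
            name=name,
            prevalence=count / REFERENCE_N_PATIENTS,
            effect=_REFERENCE_EFFECTS[name],
            label_fraction=1.0,
        )
        for name, count in REFERENCE_ENDOTYPE_COUNTS.items()
    ]
    return CohortSpec(
        n_patients=n_patients,
        features=tuple(features),
        endotypes=tuple(endotypes),
        missing_patient_rates=missing_patient_rates,
        seed=seed,
    )


def make_separable_spec(
    n_patients: int = 2000,
    n_quantitative: int = 16,
    n_categorical: int = 8,
    effects_per_endotype: int = 6,
    effect_low: float = 1.5,
    effect_high: float = 3.0,
    missing_patient_rates: float | tuple[float, float] = 0.0,
    seed: int = 0,
) -> CohortSpec:
    """Cohort spec with strongly separable planted endotypes.

    Six endotypes at the reference prevalences, each shifting a seeded
    random subset of quantitative features by a signed Cohen's D of
    magnitude in ``[effect_low, effect_high]`` and over-expressing one
    hallmark categorical level.  Used as the ground-truth test bed for the
    end-to-end benchmark: with |D| in [1.5, 3] on several features each,
    endotype members form well-separated blobs against the unlabeled
    background.
    """
    rng = np.random.default_rng(seed)
    features = [
        FeatureSpec(
            f"scale_{i:02d}", QUANTITATIVE, mean=50.0, sd=10.0,
            minimum=0.0, maximum=100.0,
        )
        for i in range(n_quantitative)
    ]
    for i in range(n_categorical):
        features.append(
            FeatureSpec(
                f"finding_{i:02d}", CATEGORICAL,
                levels=("yes", "no"), probs=(0.15, 0.85),
            )
        )
    endotypes = []
    names = list(REFERENCE_ENDOTYPE_COUNTS)
    for j, name in enumerate(names):
        chosen = rng.choice(n_quantitative, size=effects_per_endotype, replace=False)
        signs = rng.choice([-1.0, 1.0], size=effects_per_endotype)
        mags = rng.uniform(effect_low, effect_high, size=effects_per_endotype)
        effect: dict = {
            f"scale_{i:02d}": float(s * m)
            for i, s, m in zip(chosen, signs, mags)
        }
        effect[f"finding_{j % n_categorical:02d}"] = {"yes": 0.9, "no": 0.1}
        endotypes.append(
            EndotypeSpec(
                name=name,
                prevalence=REFERENCE_ENDOTYPE_COUNTS[name] / REFERENCE_N_PATIENTS,
                effect=effect,
                label_fraction=1.0,
            )
        )
    return CohortSpec(
        n_patients=n_patients,
        features=tuple(features),
        endotypes=tuple(endotypes),
        missing_patient_rates=missing_patient_rates,
        seed=seed,
    )
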