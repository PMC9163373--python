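"""Synthetic admission-note corpora with known ground truth.

The generator emulates the statistical structure of a psychiatric
mood-disorder cohort: per-patient first diagnosis drawn from the
F31/F32/F33 mix, diagnosis-dependent prevalence of the five
family-history categories (so the true association between family
history and diagnosis group is known by construction), kinship mentions
at first/second/third degree, multiple admissions per patient, and
note lengths following a truncated normal calibrated so the *realized*
mean and sd of character counts match the configured targets.

Each rendered note is a single paragraph that mixes the family-history
sentence with chief-complaint / present-illness / past-history /
personal-history / physical-exam filler, mirroring how admission notes
concatenate those sections.  Notes carry a gold quintet and gold events
with character spans; the per-patient truth equals the bitwise OR of the
patient's note-level quintets by construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np

from .lexicon import Lexicon, load_lexicon
from .types import (
    DIAGNOSIS_CODES,
    DIAGNOSIS_GROUP,
    LABEL_ORDER,
    AdmissionNote,
    FamilyHistoryEvent,
    FamilyHistoryLabel,
    GoldAnnotation,
)


class ConfigError(ValueError):
    """Invalid synthetic-corpus configuration; message names the offending field."""


# --------------------------------------------------------------------------
# Cohort-derived default marginals.
#
# Counts per diagnosis group (F31 / F32 / F33) in the reference cohort of
# 12,006 admission notes; family-history event counts are per disease
# category named in the family history.
_N_BY_DIAG = {"F31": 2123, "F32": 5353, "F33": 4530}

_FH_COUNTS = {  # disease category -> counts in (F31, F32, F33) groups
    "F20": (145, 151, 169),
    "F32": (177, 419, 437),
    "F31": (35, 12, 12),
    "F28": (212, 250, 192),
    "F29": (26, 58, 37),
}

_KINSHIP_COUNTS = {"first": 1593, "second": 342, "third": 63}

_SEX_FEMALE = {"F31": 1263, "F32": 3383, "F33": 3204}

# age-band counts per diagnosis group, band -> (F31, F32, F33)
_AGE_BANDS = {
    (9, 18): (148, 539, 101),
    (19, 40): (949, 1468, 691),
    (41, 60): (707, 1977, 1666),
    (61, 80): (303, 1315, 1937),
    (81, 94): (16, 54, 135),
}

_MARITAL = {  # status -> (F31, F32, F33)
    "married": (1179, 3855, 3660),
    "no_spouse": (940, 1491, 865),
    "not_specified": (4, 7, 5),
}

_RETIREE_SHARE = 0.262
_N_PROFESSIONS = 19


def _default_diagnosis_mix() -> dict[str, float]:
    total = sum(_N_BY_DIAG.values())
    return {k: v / total for k, v in _N_BY_DIAG.items()}


def _default_fh_rates() -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for i, diag in enumerate(("F31", "F32", "F33")):
        out[diag] = {code: _FH_COUNTS[code][i] / _N_BY_DIAG[diag] for code in LABEL_ORDER}
    return out


def _default_kinship_mix() -> dict[str, float]:
    total = sum(_KINSHIP_COUNTS.values())
    return {k: v / total for k, v in _KINSHIP_COUNTS.items()}


def _default_professions() -> tuple[str, ...]:
    return ("retiree",) + tuple(f"profession_{i:02d}" for i in range(1, _N_PROFESSIONS))


@dataclass(frozen=True)
class LengthModel:
    """Truncated-normal model over note character counts.

    ``mean``/``sd`` are the target moments of the *truncated* distribution;
    the parent normal is recalibrated internally so that truncating at
    [min, max] reproduces them.
    """

    mean: float = 204.3
    sd: float = 65.66
    min: int = 60
    max: int = 948

    def validate(self) -> None:
        if self.min < 1:
            raise ConfigError("length_model.min must be >= 1")
        if not (self.min <= self.mean <= self.max):
            raise ConfigError("length_model must satisfy min <= mean <= max")
        if self.sd <= 0:
            raise ConfigError("length_model.sd must be positive")


@lru_cache(maxsize=32)
def _calibrated_parent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent-normal (mu, sigma) whose [lo, hi]-truncation has the given moments."""
    from scipy import optimize
    from scipy.stats import truncnorm

    def residual(params):
        mu, sigma = params
        sigma = abs(sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.fsolve(residual, [mean, sd], xtol=1e-12, full_output=False)
    mu, sigma = float(sol[0]), abs(float(sol[1]))
    return mu, sigma


def sample_lengths(model: LengthModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` integer note lengths from the calibrated truncated normal."""
    mu, sigma = _calibrated_parent(model.mean, model.sd, model.min, model.max)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(mu, sigma, size=max(n - filled, 16))
        keep = draw[(draw >= model.min) & (draw <= model.max)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = np.rint(keep[:take]).astype(np.int64)
        filled += take
    return np.clip(out, model.min, model.max)


@dataclass
class SyntheticCorpusConfig:
    """Configuration of a synthetic cohort; defaults follow the reference cohort."""

    n_patients: int = 1000
    admissions_poisson_rate: float = 0.3  # admissions per patient = 1 + Poisson(rate)
    diagnosis_mix: dict[str, float] = field(default_factory=_default_diagnosis_mix)
    fh_category_rates: dict[str, dict[str, float]] = field(default_factory=_default_fh_rates)
    kinship_mix: dict[str, float] = field(default_factory=_default_kinship_mix)
    negation_rate: float = 0.8
    distractor_rate: float = 0.3
    length_model: LengthModel = field(default_factory=LengthModel)
    lexicon_id: str = "zh"
    profession_classes: tuple[str, ...] = field(default_factory=_default_professions)
    note_share_per_category: float = 0.7  # chance each note voices a patient-positive category
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.admissions_poisson_rate < 0:
            raise ConfigError("admissions_poisson_rate must be >= 0")
        for name, mix, keys in (
            ("diagnosis_mix", self.diagnosis_mix, set(DIAGNOSIS_CODES)),
            ("kinship_mix", self.kinship_mix, {"first", "second", "third"}),
        ):
            if set(mix) != keys:
                raise ConfigError(f"{name} must have keys {sorted(keys)}")
            if any(not (0.0 <= v <= 1.0) for v in mix.values()):
                raise ConfigError(f"{name} proportions must lie in [0, 1]")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 within 1e-9")
        if set(self.fh_category_rates) != set(DIAGNOSIS_CODES):
            raise ConfigError("fh_category_rates must be keyed by diagnosis codes F31/F32/F33")
        for diag, rates in self.fh_category_rates.items():
            if set(rates) != set(LABEL_ORDER):
                raise ConfigError(f"fh_category_rates[{diag}] must have keys {LABEL_ORDER}")
            if any(not (0.0 <= v <= 1.0) for v in rates.values()):
                raise ConfigError(f"fh_category_rates[{diag}] probabilities must lie in [0, 1]")
        for name, v in (
            ("negation_rate", self.negation_rate),
            ("distractor_rate", self.distractor_rate),
            ("note_share_per_category", self.note_share_per_category),
        ):
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if len(self.profession_classes) < 1:
            raise ConfigError("profession_classes must be non-empty")
        self.length_model.validate()


@dataclass
class PatientTruth:
    """Ground truth for one generated patient."""

    patient_id: str
    diagnosis_code: str
    diagnosis_group: str
    label: FamilyHistoryLabel
    kinship_degrees: frozenset[str]
    n_notes: int


# --------------------------------------------------------------------------
# Templates.  Fillers deliberately contain no lexicon term so that rule
# extraction on noise-free corpora is exact; a validation helper below checks
# this and is exercised by the test suite.

_TEMPLATES = {
    "zh": {
        "complaints": [
            "情绪低落伴睡眠差两周",
            "兴趣减退一月余",
            "心境低落伴乏力三月",
            "入睡困难伴早醒半年",
        ],
        "hpi": [
            "患者近期情绪低落，兴趣减退，食欲下降",
            "入睡困难，早醒明显，白天精力差",
            "自觉疲乏无力，注意力不集中，工作效率下降",
            "时有消极观念，未采取行动",
        ],
        "past": [
            "既往体健",
            "既往有高血压病史，规律服药",
            "既往有胃炎病史",
        ],
        "post": [
            "个人史：生长发育正常，适龄入学",
            "月经婚育史：适龄结婚，配偶体健",
            "体格检查：体温正常，脉搏规整，呼吸平稳",
            "神经系统检查阴性，心肺腹查体阴性",
            "神志清，定向力完整，接触交谈合作",
            "情感反应与内心体验协调，智能粗测正常",
            "自知力部分存在，意志活动减退",
        ],
        "fh_positive": ["{kin}患{disease}", "{kin}曾被诊断为{disease}", "患者的{kin}患有{disease}"],
        "fh_header": "家族史：",
        "fh_join": "，",
        "fh_end": "。",
        "fh_negation": [
            "家族史：否认两系三代精神疾病家族史。",
            "家族史：否认家族中有{disease}等精神疾病史。",
        ],
        "fh_empty": "家族史无特殊。",
        "distractor": "曾因{disease}样症状于外院就诊。",
        "pre_headers": ("主诉：", "现病史：", "既往史："),
        "sep": "。",
    },
    "debug": {
        "complaints": [
            "low mood and poor sleep for two weeks",
            "loss of interest for one month",
            "fatigue and low mood for three months",
        ],
        "hpi": [
            "the patient reports reduced appetite and early waking",
            "energy is low during the day and concentration is impaired",
            "there are passive thoughts without intent or plan",
        ],
        "past": [
            "past medical record is unremarkable",
            "hypertension on regular medication",
        ],
        "post": [
            "Social record: normal development and schooling",
            "Physical exam: temperature normal, pulse regular, breathing even",
            "neurological exam negative, cardiopulmonary exam negative",
            "alert, fully oriented, cooperative during interview",
            "affect congruent with reported mood, cognition grossly intact",
            "partial insight, reduced volition",
        ],
        "fh_positive": [
            "the patient's {kin} was diagnosed with {disease}",
            "the {kin} has {disease}",
        ],
        "fh_header": "Family history: ",
        "fh_join": ", and ",
        "fh_end": ".",
        "fh_negation": [
            "Family history: the patient denies any psychiatric illness among relatives.",
            "Family history: denies {disease} among relatives.",
        ],
        "fh_empty": "Family history: unremarkable.",
        "distractor": "Prior outpatient visit for {disease}-like symptoms.",
        "pre_headers": ("Chief complaint: ", "Present illness: ", "Past history: "),
        "sep": ". ",
    },
}


def template_fillers_are_term_free(lexicon: Lexicon) -> bool:
    """True iff no filler/complaint/past/post sentence contains a lexicon term."""
    t = _TEMPLATES[lexicon.lexicon_id]
    pool = t["complaints"] + t["hpi"] + t["past"] + t["post"]
    terms = lexicon.all_terms()
    return not any(term in sentence for sentence in pool for term in terms)


@dataclass
class RenderedNote:
    text: str
    events: list[FamilyHistoryEvent]
    fh_span: tuple[int, int]  # span of the family-history sentence


def render_note(
    rng: np.random.Generator,
    lexicon: Lexicon,
    events_spec: list[tuple[str, str]],  # (disease_code, kinship surface)
    negation: bool,
    distractor_codes: list[str],
    target_length: int,
    length_model: LengthModel,
) -> RenderedNote:
    """Realize one note text of (approximately) ``target_length`` characters.

    The family-history sentence states exactly the given events; when
    ``negation`` is set and no events are given, an explicit-absence phrase is
    used instead.  Disease terms from ``distractor_codes`` are planted in the
    past-history filler, outside the family-history section.  Length is met
    exactly by trimming trailing filler, except in the rare case where the
    mandatory content alone exceeds the target.
    """
    t = _TEMPLATES.get(lexicon.lexicon_id)
    if t is None:
        raise ConfigError(f"no templates for lexicon_id {lexicon.lexicon_id!r}")
    for code, _ in events_spec:
        if code not in LABEL_ORDER:
            raise ConfigError(f"unknown disease category {code!r} in events")

    sep = t["sep"]

    # --- family-history sentence, with local disease-term offsets ----------
    local_events: list[tuple[str, str, int, int]] = []  # code, kin, start, end
    if events_spec:
        parts: list[str] = []
        offset = len(t["fh_header"])
        for i, (code, kin) in enumerate(events_spec):
            template = t["fh_positive"][int(rng.integers(len(t["fh_positive"])))]
            disease = lexicon.disease_surfaces(code)[
                int(rng.integers(len(lexicon.disease_surfaces(code))))
            ]
            part = template.format(kin=kin, disease=disease)
            if i > 0:
                offset += len(t["fh_join"])
            d_start = offset + part.rindex(disease)
            local_events.append((code, kin, d_start, d_start + len(disease)))
            parts.append(part)
            offset += len(part)
        fh = t["fh_header"] + t["fh_join"].join(parts) + t["fh_end"]
    elif negation:
        template = t["fh_negation"][int(rng.integers(len(t["fh_negation"])))]
        if "{disease}" in template:
            all_surfaces = sorted(lexicon.disease_terms)
            template = template.format(
                disease=all_surfaces[int(rng.integers(len(all_surfaces)))]
            )
        fh = template
    else:
        fh = t["fh_empty"]

    # --- pre block: complaint / present illness / past history -------------
    def pick(pool: list[str]) -> str:
        return pool[int(rng.integers(len(pool)))]

    h_cc, h_hpi, h_past = t["pre_headers"]
    past = pick(t["past"]) + sep
    for code in distractor_codes:
        surfaces = lexicon.disease_surfaces(code)
        past += t["distractor"].format(disease=surfaces[int(rng.integers(len(surfaces)))])
        if not past.endswith(t["fh_end"].strip()) and not past.endswith("."):
            past += sep
    pre_variants = [
        h_cc + pick(t["complaints"]) + sep + h_hpi + pick(t["hpi"]) + sep
        + pick(t["hpi"]) + sep + h_past + past,
        h_cc + pick(t["complaints"]) + sep + h_hpi + pick(t["hpi"]) + sep + h_past + past,
        h_hpi + pick(t["hpi"]) + sep + h_past + past,
    ]
    pre = pre_variants[int(rng.integers(len(pre_variants)))]
    # shrink the pre block if the mandatory content would overflow the target
    for candidate in pre_variants[1:]:
        if len(pre) + len(fh) + 1 <= target_length:
            break
        pre = candidate
    target = min(
        max(target_length, len(pre) + len(fh) + 1), length_model.max
    )
    if len(pre) + len(fh) > target:  # pathological: give up on the pre block
        pre = ""
        target = min(max(target_length, len(fh)), max(length_model.max, len(fh)))

    # --- post block: pad with personal-history / exam filler ---------------
    text = pre + fh
    fh_span = (len(pre), len(pre) + len(fh))
    while len(text) < target:
        text += pick(t["post"]) + sep
    text = text[:target] if len(text) > target else text

    events = [
        FamilyHistoryEvent(
            disease_code=code,
            relation_term=kin,
            kinship_degree=lexicon.kinship_terms[kin][1] if kin in lexicon.kinship_terms else "unknown",
            span=(fh_span[0] + s, fh_span[0] + e),
        )
        for code, kin, s, e in local_events
    ]
    return RenderedNote(text=text, events=events, fh_span=fh_span)


def generate_cohort(
    config: SyntheticCorpusConfig,
    lexicon: Optional[Lexicon] = None,
) -> tuple[list[AdmissionNote], dict[str, PatientTruth]]:
    """Generate a cohort of admission notes plus per-patient ground truth.

    Deterministic for a fixed config (including seed).  Every note carries a
    gold quintet and gold events consistent with its text; the per-patient
    truth equals the bitwise OR of the patient's note-level quintets.
    """
    config.validate()
    if lexicon is None:
        lexicon = load_lexicon(config.lexicon_id)
    rng = np.random.default_rng(config.seed)

    diag_codes = list(DIAGNOSIS_CODES)
    diag_p = np.array([config.diagnosis_mix[c] for c in diag_codes])
    kin_degrees = ["first", "second", "third"]
    kin_p = np.array([config.kinship_mix[d] for d in kin_degrees])

    age_bands = list(_AGE_BANDS)
    diag_index = {"F31": 0, "F32": 1, "F33": 2}
    prof = list(config.profession_classes)
    if prof[0] == "retiree" and len(prof) > 1:
        rest = (1.0 - _RETIREE_SHARE) / (len(prof) - 1)
        prof_p = np.array([_RETIREE_SHARE] + [rest] * (len(prof) - 1))
    else:
        prof_p = np.full(len(prof), 1.0 / len(prof))

    notes: list[AdmissionNote] = []
    truths: dict[str, PatientTruth] = {}

    for p_idx in range(config.n_patients):
        pid = f"P{p_idx:06d}"
        diag = diag_codes[int(rng.choice(len(diag_codes), p=diag_p))]
        di = diag_index[diag]
        n_adm = 1 + int(rng.poisson(config.admissions_poisson_rate))

        rates = config.fh_category_rates[diag]
        quintet = tuple(int(rng.random() < rates[c]) for c in LABEL_ORDER)
        positive_codes = [c for c, v in zip(LABEL_ORDER, quintet) if v]

        # one relative per (patient, category), voiced in a random non-empty
        # subset of the patient's notes
        assignments: dict[str, tuple[str, np.ndarray]] = {}
        for code in positive_codes:
            degree = kin_degrees[int(rng.choice(len(kin_degrees), p=kin_p))]
            surfaces = lexicon.kinship_surfaces(degree)
            kin = surfaces[int(rng.integers(len(surfaces)))]
            mask = rng.random(n_adm) < config.note_share_per_category
            if not mask.any():
                mask[int(rng.integers(n_adm))] = True
            assignments[code] = (kin, mask)

        # demographics (held fixed across the patient's admissions)
        band_counts = np.array([_AGE_BANDS[b][di] for b in age_bands], dtype=float)
        band = age_bands[int(rng.choice(len(age_bands), p=band_counts / band_counts.sum()))]
        age = int(rng.integers(band[0], band[1] + 1))
        female_rate = _SEX_FEMALE[diag] / _N_BY_DIAG[diag]
        gender = "female" if rng.random() < female_rate else "male"
        mar_counts = np.array([_MARITAL[m][di] for m in _MARITAL], dtype=float)
        marital = list(_MARITAL)[int(rng.choice(len(_MARITAL), p=mar_counts / mar_counts.sum()))]
        profession = prof[int(rng.choice(len(prof), p=prof_p))]
        years = np.sort(rng.integers(2010, 2020, size=n_adm))

        lengths = sample_lengths(config.length_model, n_adm, rng)
        degrees: set[str] = set()
        for a_idx in range(n_adm):
            events_spec = [
                (code, assignments[code][0])
                for code in positive_codes
                if assignments[code][1][a_idx]
            ]
            negation = (not events_spec) and (rng.random() < config.negation_rate)
            distractors = [LABEL_ORDER[int(rng.integers(5))]] if rng.random() < config.distractor_rate else []
            rendered = render_note(
                rng, lexicon, events_spec, negation, distractors,
                int(lengths[a_idx]), config.length_model,
            )
            degrees.update(e.kinship_degree for e in rendered.events)
            gold = GoldAnnotation(
                label=FamilyHistoryLabel.from_codes([c for c, _ in events_spec]),
                events=rendered.events,
            )
            notes.append(
                AdmissionNote(
                    note_id=f"{pid}-{a_idx:02d}",
                    patient_id=pid,
                    admission_year=int(years[a_idx]),
                    age_years=age,
                    gender=gender,
                    marital_status=marital,
                    profession=profession,
                    first_diagnosis=diag,
                    text=rendered.text,
                    gold=gold,
                )
            )
        truths[pid] = PatientTruth(
            patient_id=pid,
            diagnosis_code=diag,
            diagnosis_group=DIAGNOSIS_GROUP[diag],
            label=FamilyHistoryLabel(quintet),  # type: ignore[arg-type]
            kinship_degrees=frozenset(degrees),
            n_notes=n_adm,
        )

    return notes, truths


def clean_config(**overrides) -> SyntheticCorpusConfig:
    """A noise-free configuration: no negation phrases, no distractors."""
    cfg = SyntheticCorpusConfig(negation_rate=0.0, distractor_rate=0.0)
    return replace(cfg, **overrides)
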