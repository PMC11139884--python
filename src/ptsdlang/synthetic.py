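"""Synthetic trauma-narrative corpora with known ground truth.

The generator emulates the statistical structure the analysis assumes — a
cohort of 148 interview transcripts in two exposure strata (110 directly
exposed / 38 witnesses) and three diagnosis classes (70 full / 42 partial /
36 no PTSD), with roughly log-normal document lengths (target mean 5553,
SD 3628 word tokens, truncated to [200, 20000]) — and plants configurable
group effects whose ground truth is recorded for recovery tests.

Documents are token-stream realistic rather than grammatical prose: a
French function-word skeleton (pronouns, determiners, auxiliaries,
conjugated verb forms) with content slots filled from a Zipf-weighted
vocabulary. This is sufficient for every feature family: category words
come from the generator's own stand-in lexicons, disfluency marks
(fillers, "…" breaks, truncations, repetitions) are inserted at per-
document rates, passive periphrases come from a template bank, a bigram-
recycling knob raises graph repetition measures (PE, L2), and optional
class-exclusive marker tokens support the CNN tests.

Effects are planted as per-document target rates drawn from
``N(p0 + d·σ, σ²)`` with σ = 0.02, so a planted effect size ``d`` is
realised in the extracted feature up to the binomial shrinkage from finite
document length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import LexiconResource, MetadataRecord, Transcript

RATE_SIGMA = 0.02
BASE_CATEGORY_RATE = 0.015

# feature knob -> lexicon category it feeds (rate categories)
KNOB_CATEGORIES = {
    "model_death": "DEATH",
    "model_body": "BODY",
    "model_physical_sensations": "PHYSICAL_SENSATIONS",
    "model_perception": "PERCEPTION",
    "liwc_death": "liwc_death",
    "liwc_body": "liwc_body",
    "liwc_positive_emotion": "liwc_positive_emotion",
    "liwc_negative_emotion": "liwc_negative_emotion",
    **{f"ema_{c}": f"ema_{c}" for c in (
        "positive", "negative", "joy", "sadness", "anger", "fear",
        "disgust", "surprise", "guilt", "shame")},
    **{f"feel_{c}": f"feel_{c}" for c in (
        "positive", "joy", "fear", "sadness", "anger", "disgust")},
    **{f"empath_{c}": f"empath_{c}" for c in (
        "fear", "anger", "sadness", "nervousness")},
}

# behavioural knobs with their base per-word (or per-sentence) rates
BEHAVIOUR_KNOBS = {
    "filler_rate": 0.02,
    "silent_break_rate": 0.02,
    "truncation_rate": 0.01,
    "word_repetition_rate": 0.01,
    "passive_rate": 0.06,       # per sentence
    "bigram_recycling_rate": 0.02,
    "marker_rate": 0.0,         # class-exclusive marker tokens, off by default
}

PTSD_CLASSES = ("full_ptsd", "partial_ptsd")


@dataclass
class PlantedEffect:
    """A group difference planted on one generator knob.

    ``knob`` is a feature name from KNOB_CATEGORIES or a behavioural knob;
    ``affected`` is the set of diagnosis classes shifted by ``d`` effect
    sizes (in units of the between-document rate SD σ = 0.02), or by
    ``delta`` directly on the rate scale.
    """

    knob: str
    affected: tuple = PTSD_CLASSES
    d: float = 0.0
    delta: float | None = None

    def shift(self) -> float:
        return self.delta if self.delta is not None else self.d * RATE_SIGMA


@dataclass
class SyntheticConfig:
    n_docs: int = 148
    exposure_split: tuple = (110, 38)          # A1, A2
    diagnosis_split: tuple = (70, 42, 36)      # full, partial, none
    length_mean: float = 5553.0
    length_sd: float = 3628.0
    length_bounds: tuple = (200, 20000)
    planted_effects: list = field(default_factory=list)
    label_noise: dict = field(default_factory=dict)  # stratum -> flip rate
    marker_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.exposure_split) != self.n_docs:
            raise ValueError("exposure split must sum to n_docs")
        if sum(self.diagnosis_split) != self.n_docs:
            raise ValueError("diagnosis split must sum to n_docs")
        for eff in self.planted_effects:
            if eff.knob not in KNOB_CATEGORIES and eff.knob not in BEHAVIOUR_KNOBS:
                raise ValueError(f"unknown planted knob {eff.knob!r}")


@dataclass
class GroundTruth:
    config: SyntheticConfig
    true_class: dict                 # doc_id -> diagnosis before label noise
    planted: list
    realized_rates: dict             # doc_id -> {knob: realized rate}
    noisy_docs: list = field(default_factory=list)
    marker_tokens: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# vocabulary (deterministic given seed)

_VERB_STEMS = ("march", "parl", "pens", "regard", "cour", "cri", "tremb",
               "rest", "saign", "rappel", "racont", "attend", "avanc")
_PASSIVE_PARTICIPLES = ("blessé", "touché", "frappé", "poussé", "aidé",
                        "soigné", "évacué", "bousculé")
_PROPER_NAMES = ("Marie", "Adrien", "Paris", "Bataclan", "Julien", "Sophie")
_GENERIC_ADVERBS = ("toujours", "jamais", "souvent")
_PAST_ANCHORS = ("hier", "ensuite", "puis", "soudain")

N_BACKGROUND_NOUNS = 240
TERMS_PER_CATEGORY = 22


def _letters(i: int) -> str:
    return chr(97 + i // 26) + chr(97 + i % 26)


def _background_nouns() -> list[str]:
    return [f"mot{_letters(i)}" for i in range(N_BACKGROUND_NOUNS)]


def _category_terms(category: str) -> list[str]:
    slug = category.lower().replace("_", "")
    return [f"{slug}x{_letters(i)}" for i in range(TERMS_PER_CATEGORY)]


def generate_lexicons(seed: int = 0) -> list[LexiconResource]:
    """Stand-in lexicon resources consistent with the generator vocabulary.

    One resource per family: the category-rate lexicon (all sentiment and
    lexical-field categories, ≥20 terms each) and the valence-weighted
    happiness lexicon over the background nouns.
    """
    rng = np.random.default_rng(seed)
    entries: dict = {}
    for category in sorted(set(KNOB_CATEGORIES.values())):
        for term in _category_terms(category):
            entries[(term, category)] = 1.0
    categories = LexiconResource("synthetic_categories", entries,
                                 match_policy="surface")
    hap = {}
    for noun in _background_nouns():
        hap[(noun, "labmt_happiness")] = float(
            np.round(rng.uniform(1.0, 9.0), 3))
    # positive/negative terms carry matching low/high valence
    for term in _category_terms("liwc_positive_emotion"):
        hap[(term, "labmt_happiness")] = 8.0
    for term in _category_terms("liwc_negative_emotion"):
        hap[(term, "labmt_happiness")] = 2.0
    happiness = LexiconResource("synthetic_happiness", hap,
                                match_policy="surface")
    return [categories, happiness]


# ---------------------------------------------------------------------------
# document generation

_SUBJECTS = (("je", 0.28), ("il", 0.14), ("elle", 0.10), ("on", 0.16),
             ("nous", 0.10), ("vous", 0.05), ("tu", 0.05), ("ils", 0.07),
             ("elles", 0.05))
_TENSES = (("present", 0.50), ("imparfait", 0.25), ("future", 0.15),
           ("conditional", 0.10))
_TENSE_SUFFIX = {"present": "e", "imparfait": "ait", "future": "era",
                 "conditional": "erait"}


def _choice(rng, pairs):
    names = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs])
    return names[rng.choice(len(names), p=probs / probs.sum())]


class _DocBuilder:
    """Accumulates tokens with attachment flags and renders raw text."""

    def __init__(self) -> None:
        self.parts: list[tuple[str, bool]] = []  # (text, attach_to_previous)
        self.n_words = 0

    def word(self, w: str) -> None:
        self.parts.append((w, False))
        self.n_words += 1

    def attached_ellipsis(self) -> None:
        self.parts.append(("…", True))

    def free_ellipsis(self) -> None:
        self.parts.append(("…", False))

    def punct(self, p: str = ".") -> None:
        self.parts.append((p, True))

    def render(self) -> str:
        out: list[str] = []
        for text, attach in self.parts:
            if attach and out:
                out[-1] = out[-1] + text
            else:
                out.append(text)
        return " ".join(out)


def _zipf_probs(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


# Fraction of word tokens that are content slots under the sentence
# templates; enters the binomial-noise compensation for planted effects.
SLOT_FRACTION = 0.26


def _gamma_rate(rng, mean: float, sd: float) -> float:
    """Positive per-document rate with exact mean/SD (Gamma draw)."""
    if mean <= 0:
        return 0.0
    shape = (mean / sd) ** 2
    return float(min(0.5, rng.gamma(shape, sd**2 / mean)))


def _effect_shifts(effects, diagnosis: str, inv_len: float) -> dict:
    """Per-knob rate shifts for one document's diagnosis class.

    Effect sizes given as ``d`` are converted to rate shifts against the
    *realised* between-document SD, which combines the planted rate spread
    σ with the binomial sampling noise implied by the document lengths —
    so the extracted feature realises the requested d, not a shrunk one.
    """
    shifts: dict = {}
    for eff in effects:
        if diagnosis not in eff.affected:
            continue
        if eff.delta is not None:
            shift = eff.delta
        elif eff.knob in KNOB_CATEGORIES:
            p_bar = BASE_CATEGORY_RATE + eff.d * RATE_SIGMA / 2.0
            sigma_eff = np.sqrt(
                RATE_SIGMA**2
                + p_bar * (1.0 - p_bar) * inv_len / SLOT_FRACTION
            )
            shift = eff.d * float(sigma_eff)
        else:
            shift = eff.d * RATE_SIGMA
        shifts[eff.knob] = shifts.get(eff.knob, 0.0) + shift
    return shifts


def _draw_rates(rng, diagnosis: str, effects, inv_len: float) -> dict:
    """Per-document knob rates with planted class shifts."""
    rates: dict = {}
    shifts = _effect_shifts(effects, diagnosis, inv_len)
    for knob in KNOB_CATEGORIES:
        base = BASE_CATEGORY_RATE + shifts.get(knob, 0.0)
        rates[knob] = _gamma_rate(rng, base, RATE_SIGMA)
    for knob, base0 in BEHAVIOUR_KNOBS.items():
        base = base0 + shifts.get(knob, 0.0)
        rates[knob] = _gamma_rate(rng, base, RATE_SIGMA) if base0 > 0 else max(
            0.0, base)
    return rates


def _generate_document(rng, n_tokens: int, rates: dict, markers: list,
                       noun_probs, nouns, counters: dict) -> str:
    b = _DocBuilder()
    last_words: list[str] = []

    def emit(w: str) -> None:
        b.word(w)
        last_words.append(w)
        if len(last_words) > 2:
            last_words.pop(0)
        if w in counters:
            counters[w] += 1
        # disfluency insertions after a word
        if rng.random() < rates["silent_break_rate"]:
            if rng.random() < 0.75:
                b.attached_ellipsis()
            else:
                b.free_ellipsis()
        if rng.random() < rates["filler_rate"]:
            b.word("euh")
        if rng.random() < rates["word_repetition_rate"]:
            b.word(w)

    knob_order = list(KNOB_CATEGORIES)

    def content_word() -> str:
        # cumulative-interval draw: each category keeps probability equal to
        # its own rate regardless of shifts planted on other categories
        u = rng.random()
        cum = 0.0
        for knob in knob_order:
            cum += rates[knob]
            if u < cum:
                category = KNOB_CATEGORIES[knob]
                terms = _category_terms(category)
                w = terms[rng.integers(len(terms))]
                counters[knob] = counters.get(knob, 0) + 1
                return w
        if markers and rng.random() < rates["marker_rate"]:
            return markers[rng.integers(len(markers))]
        return nouns[rng.choice(len(nouns), p=noun_probs)]

    def emit_content() -> None:
        w = content_word()
        if len(w) >= 5 and rng.random() < rates["truncation_rate"]:
            b.word(w[:3])
            b.attached_ellipsis()
            counters["truncations"] = counters.get("truncations", 0) + 1
        emit(w)

    while b.n_words < n_tokens:
        if rng.random() < rates["passive_rate"]:
            subj = _choice(rng, (("il", 0.5), ("elle", 0.5)))
            part = _PASSIVE_PARTICIPLES[rng.integers(len(_PASSIVE_PARTICIPLES))]
            for w in (subj, "a", "été", part):
                emit(w)
            if rng.random() < 0.6:
                emit("par")
                emit("une")
                emit_content()
            b.punct(".")
            counters["passives"] = counters.get("passives", 0) + 1
            continue
        subj = _choice(rng, _SUBJECTS)
        tense = _choice(rng, _TENSES)
        verb = _VERB_STEMS[rng.integers(len(_VERB_STEMS))] + _TENSE_SUFFIX[tense]
        emit(subj)
        if subj == "on":
            style = rng.random()
            if style < 0.3:
                emit("m'")
                emit("a")
                emit(_PASSIVE_PARTICIPLES[rng.integers(len(_PASSIVE_PARTICIPLES))])
                b.punct(".")
                continue
            if style < 0.5:
                emit(verb)
                emit(_GENERIC_ADVERBS[rng.integers(len(_GENERIC_ADVERBS))])
            else:
                emit(verb)
        else:
            emit(verb)
        r = rng.random()
        if r < 0.12:
            emit(_GENERIC_ADVERBS[rng.integers(len(_GENERIC_ADVERBS))])
        elif r < 0.24:
            emit(_PAST_ANCHORS[rng.integers(len(_PAST_ANCHORS))])
        emit(_choice(rng, (("le", 0.4), ("la", 0.3), ("une", 0.2), ("un", 0.1))))
        emit_content()
        if rng.random() < 0.3:
            emit("dans")
            emit("la")
            emit_content()
        if rng.random() < 0.08:
            emit(_PROPER_NAMES[rng.integers(len(_PROPER_NAMES))])
        if rng.random() < rates["bigram_recycling_rate"] and len(last_words) == 2:
            emit(last_words[0])
            emit(last_words[1])
        b.punct(".")
    return b.render()


# ---------------------------------------------------------------------------
# cohort generation


def _assign_cohort(rng, cfg: SyntheticConfig):
    diagnoses = (["full_ptsd"] * cfg.diagnosis_split[0]
                 + ["partial_ptsd"] * cfg.diagnosis_split[1]
                 + ["no_ptsd"] * cfg.diagnosis_split[2])
    exposures = ["A1"] * cfg.exposure_split[0] + ["A2"] * cfg.exposure_split[1]
    rng.shuffle(diagnoses)
    rng.shuffle(exposures)
    return diagnoses, exposures


def _criteria_for(rng, diagnosis: str) -> dict:
    if diagnosis == "full_ptsd":
        return {"B": True, "C": rng.random() < 0.85, "D": rng.random() < 0.85,
                "E": rng.random() < 0.85, "G": True}
    if diagnosis == "partial_ptsd":
        return {"B": True, "C": rng.random() < 0.3, "D": rng.random() < 0.3,
                "E": rng.random() < 0.3, "G": True}
    return {"B": False, "C": rng.random() < 0.05, "D": rng.random() < 0.05,
            "E": rng.random() < 0.05, "G": False}


_EDUCATIONS = ("master_or_higher", "bachelor", "highschool_or_less")
_PROFESSIONS = ("executive", "intermediate", "employee", "student", "other")


def _metadata_record(rng, doc_id, diagnosis, exposure) -> MetadataRecord:
    age_mu, age_sd = (37.0, 9.0) if exposure == "A1" else (42.0, 12.0)
    p_female = 0.555 if exposure == "A1" else 0.684
    return MetadataRecord(
        doc_id=doc_id, exposure=exposure, diagnosis=diagnosis,
        criteria=_criteria_for(rng, diagnosis),
        sex="F" if rng.random() < p_female else "M",
        age=float(np.round(np.clip(rng.normal(age_mu, age_sd), 18, 85), 1)),
        education=_EDUCATIONS[rng.choice(3, p=[0.58, 0.27, 0.15])],
        profession=_PROFESSIONS[rng.choice(5, p=[0.5, 0.2, 0.08, 0.05, 0.17])],
        single=bool(rng.random() < 0.62),
        living_alone=bool(rng.random() < 0.55),
    )


def _truncated_lognormal(rng, mean: float, sd: float, bounds) -> int:
    # moment-match a log-normal to the target mean/sd
    var = sd**2
    sigma2 = np.log(1.0 + var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    x = rng.lognormal(mu, np.sqrt(sigma2))
    return int(np.clip(x, bounds[0], bounds[1]))


def generate_corpus(cfg: SyntheticConfig):
    """Generate (corpus, metadata, ground_truth) for a configuration.

    Deterministic: the same (config, seed) yields byte-identical corpora.
    """
    rng = np.random.default_rng(cfg.seed)
    diagnoses, exposures = _assign_cohort(rng, cfg)
    nouns = _background_nouns()
    noun_probs = _zipf_probs(len(nouns))
    markers = {
        "positive": [f"markerpos{_letters(i)}" for i in range(5)],
        "negative": [f"markerneg{_letters(i)}" for i in range(5)],
    }

    corpus: list[Transcript] = []
    metadata: list[MetadataRecord] = []
    true_class: dict = {}
    realized: dict = {}
    noisy: list = []

    lengths = [
        _truncated_lognormal(rng, cfg.length_mean, cfg.length_sd,
                             cfg.length_bounds)
        for _ in range(cfg.n_docs)
    ]
    inv_len = float(np.mean([1.0 / n for n in lengths]))

    width = len(str(cfg.n_docs - 1))
    for i in range(cfg.n_docs):
        doc_id = f"doc{i:0{width}d}"
        diagnosis, exposure = diagnoses[i], exposures[i]
        true_class[doc_id] = diagnosis
        rates = _draw_rates(rng, diagnosis, cfg.planted_effects, inv_len)
        rates["marker_rate"] = cfg.marker_rate
        n_tokens = lengths[i]
        is_ptsd = diagnosis in PTSD_CLASSES
        marker_pool = markers["positive"] if is_ptsd else markers["negative"]
        counters: dict = {}
        text = _generate_document(rng, n_tokens, rates, marker_pool,
                                  noun_probs, nouns, counters)
        corpus.append(Transcript(doc_id, text))
        total_words = max(1, n_tokens)
        realized[doc_id] = {
            knob: counters.get(knob, 0) / total_words
            for knob in KNOB_CATEGORIES
        }

        label = diagnosis
        stratum = exposure
        flip_rate = cfg.label_noise.get(stratum, 0.0)
        if flip_rate and rng.random() < flip_rate:
            label = "no_ptsd" if is_ptsd else "full_ptsd"
            noisy.append(doc_id)
        metadata.append(_metadata_record(rng, doc_id, label, exposure))

    gt = GroundTruth(config=cfg, true_class=true_class,
                     planted=list(cfg.planted_effects),
                     realized_rates=realized, noisy_docs=noisy,
                     marker_tokens=markers)
    return corpus, metadata, gt


def binary_labels(metadata, positive=PTSD_CLASSES) -> dict:
    """doc_id -> 1 for full/partial PTSD, 0 otherwise."""
    return {m.doc_id: int(m.diagnosis in positive) for m in metadata}


def criterion_labels(metadata, criterion: str) -> dict:
    return {m.doc_id: int(m.criteria[criterion]) for m in metadata}


def strata_map(metadata, by=("exposure", "diagnosis")) -> dict:
    return {m.doc_id: tuple(getattr(m, a) for a in by) for m in metadata}
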