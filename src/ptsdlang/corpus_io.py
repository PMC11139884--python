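"""Transcript, metadata and lexicon I/O, plus tokenization.

Transcripts are trauma-narrative interview transcriptions: UTF-8 text in
which transcription conventions are meaningful data. In particular the
ellipsis character "…" marks a silent break and a word glued to "…" may be a
truncated word (a false start, e.g. "par… partir"). The tokenizer therefore
never normalises these marks away; disfluency features depend on them.

Conventions (fixed, deterministic):

* "…" is always its own token.
* A word immediately followed by "…" with no intervening space is flagged
  ``truncated=True`` in its morph map **iff** the next word token strictly
  extends it (case-insensitive proper prefix) — "par… partir" is a truncated
  restart, "Je… je" is a repetition across a silent break, not a truncation.
* Sentences split on terminal punctuation (".", "!", "?").
* Character spans are 0-based half-open into the raw text and the surface
  form always equals the raw-text slice.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

__all__ = [
    "Transcript",
    "Token",
    "TokenizedTranscript",
    "MetadataRecord",
    "LexiconResource",
    "TaggerPlugin",
    "read_corpus",
    "write_corpus",
    "tokenize",
    "read_metadata",
    "write_metadata",
    "read_lexicon",
    "write_lexicon",
    "read_feature_table",
    "write_feature_table",
]

EXPOSURES = ("A1", "A2")
DIAGNOSES = ("full_ptsd", "partial_ptsd", "no_ptsd")
CRITERIA = ("B", "C", "D", "E", "G")

ELLIPSIS = "…"  # …


@dataclass(frozen=True)
class Transcript:
    """One interview narrative; ``raw_text`` round-trips byte-exact."""

    doc_id: str
    raw_text: str


@dataclass
class Token:
    surface: str
    lemma: str
    pos: str  # UPOS coarse tag
    morph: dict
    span: tuple[int, int]  # [start, end) into raw_text

    @property
    def is_word(self) -> bool:
        """Word token for normalisation purposes.

        Punctuation, silent-break marks and truncated fragments are not
        counted as words: a fragment like "par…" is a disfluency event, not a
        lexical word.
        """
        return self.pos != "PUNCT" and not self.morph.get("truncated", False)


@dataclass
class TokenizedTranscript:
    transcript: Transcript
    tokens: list[Token]
    sentences: list[tuple[int, int]]  # token-index ranges, partition tokens

    @property
    def doc_id(self) -> str:
        return self.transcript.doc_id

    @property
    def words(self) -> list[Token]:
        return [t for t in self.tokens if t.is_word]


@dataclass
class MetadataRecord:
    doc_id: str
    exposure: str
    diagnosis: str
    criteria: dict  # {"B": bool, ..., "G": bool}
    sex: str = ""
    age: float = float("nan")
    education: str = ""
    profession: str = ""
    single: bool = False
    living_alone: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exposure not in EXPOSURES:
            raise ValueError(f"invalid exposure {self.exposure!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"invalid diagnosis {self.diagnosis!r}")
        missing = [c for c in CRITERIA if c not in self.criteria]
        if missing:
            raise ValueError(f"missing criterion flags {missing}")
        # Partial PTSD is defined by intrusion symptoms (B) with distress /
        # functional impairment (G); a record violating that is inconsistent.
        if self.diagnosis == "partial_ptsd" and not (
            self.criteria["B"] and self.criteria["G"]
        ):
            raise ValueError(
                f"doc {self.doc_id}: partial_ptsd requires criteria B and G"
            )


@dataclass
class LexiconResource:
    """Term → category lexicon with optional per-term weights.

    ``match_policy`` selects whether terms are matched against lemmas or
    surface forms (lower-cased either way).
    """

    name: str
    entries: dict  # (term, category) -> weight
    match_policy: str = "lemma"

    def __post_init__(self) -> None:
        if self.match_policy not in ("lemma", "surface"):
            raise ValueError(f"invalid match_policy {self.match_policy!r}")
        for (term, cat), w in self.entries.items():
            if term != term.lower():
                raise ValueError(f"lexicon term not lower-cased: {term!r}")
            if not (w == w and abs(w) != float("inf")):
                raise ValueError(f"non-finite weight for ({term}, {cat})")

    @property
    def categories(self) -> list[str]:
        return sorted({cat for (_, cat) in self.entries})

    def terms(self, category: str) -> dict:
        return {t: w for (t, c), w in self.entries.items() if c == category}


class TaggerPlugin(Protocol):
    """Contract for semantic-category taggers over token streams.

    The default implementation is a lexicon/rule tagger; a learned
    contextual tagger may be plugged in. ``tag`` returns non-overlapping
    (start, end) token-index spans per category.
    """

    categories: tuple

    def tag(self, tokens: Sequence[Token]) -> list:  # [(span, category), ...]
        ...


# ---------------------------------------------------------------------------
# corpus I/O


def read_corpus(path: str | Path, format: str = "auto") -> list[Transcript]:
    """Read a corpus from a directory of ``.txt`` files or a JSONL file.

    One transcript per file/record; ``doc_id`` from the filename stem or the
    record field; output sorted lexicographically by Unicode code point.
    """
    path = Path(path)
    if format == "auto":
        format = "jsonl" if path.is_file() else "dir"
    transcripts: list[Transcript] = []
    if format == "dir":
        if not path.is_dir():
            raise FileNotFoundError(f"corpus directory not found: {path}")
        for f in sorted(path.glob("*.txt")):
            try:
                text = f.read_text(encoding="utf-8")
            except UnicodeDecodeError as e:
                raise ValueError(f"file {f} is not valid UTF-8: {e}") from e
            transcripts.append(Transcript(doc_id=f.stem, raw_text=text))
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rec = json.loads(line)
                if "doc_id" not in rec or "text" not in rec:
                    raise ValueError(
                        f"{path}:{lineno}: record missing 'doc_id' or 'text'"
                    )
                transcripts.append(Transcript(rec["doc_id"], rec["text"]))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    seen: set[str] = set()
    for t in transcripts:
        if t.doc_id in seen:
            raise ValueError(f"duplicate doc_id {t.doc_id!r}")
        seen.add(t.doc_id)
    return sorted(transcripts, key=lambda t: t.doc_id)


def write_corpus(corpus: Iterable[Transcript], path: str | Path) -> None:
    """Write one UTF-8 ``.txt`` per transcript into ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for t in corpus:
        (path / f"{t.doc_id}.txt").write_text(t.raw_text, encoding="utf-8")


# ---------------------------------------------------------------------------
# tokenization

# word = letters (incl. apostrophe-final clitics like "j'"), number, or a
# single punctuation / ellipsis character
_TOKEN_RE = re.compile(
    r"[A-Za-zÀ-ÖØ-öø-ÿœŒæÆ]+(?:['’])?"  # word or clitic "j'"
    r"|\d+(?:[.,]\d+)?[hH]?\d*"  # numbers, clock times "20h45"
    r"|…"  # ellipsis
    r"|[^\sA-Za-zÀ-ÖØ-öø-ÿœŒæÆ\d]",  # any other single non-space char
)

_SENT_END = {".", "!", "?"}


def tokenize(transcript: Transcript, tagger=None) -> TokenizedTranscript:
    """Tokenize and annotate a transcript.

    ``tagger`` is a morphosyntactic backend with an
    ``annotate(surface, index, stream) -> (lemma, pos, morph)`` method; the
    default is the rule tagger from :mod:`ptsdlang.tagging`.
    """
    if tagger is None:
        from .tagging import RuleTagger

        tagger = RuleTagger()
    text = transcript.raw_text
    raw: list[tuple[str, int, int]] = [
        (m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)
    ]
    tokens: list[Token] = []
    for i, (surface, start, end) in enumerate(raw):
        lemma, pos, morph = tagger.annotate(surface, i, raw)
        # truncation: word glued to "…" and strictly extended by next word
        if (
            pos != "PUNCT"
            and i + 1 < len(raw)
            and raw[i + 1][0] == ELLIPSIS
            and raw[i + 1][1] == end  # no space before the ellipsis
        ):
            nxt = _next_word_surface(raw, i + 2)
            if (
                nxt is not None
                and len(nxt) > len(surface)
                and nxt.lower().startswith(surface.lower())
            ):
                morph = dict(morph, truncated=True)
        tokens.append(Token(surface, lemma, pos, morph, (start, end)))

    sentences: list[tuple[int, int]] = []
    start_i = 0
    for i, tok in enumerate(tokens):
        if tok.surface in _SENT_END:
            sentences.append((start_i, i + 1))
            start_i = i + 1
    if start_i < len(tokens):
        sentences.append((start_i, len(tokens)))
    return TokenizedTranscript(transcript, tokens, sentences)


def _next_word_surface(raw, i):
    for j in range(i, len(raw)):
        s = raw[j][0]
        if s == ELLIPSIS or (len(s) == 1 and not s.isalnum()):
            continue
        return s
    return None


# ---------------------------------------------------------------------------
# metadata I/O

_META_COLUMNS = [
    "doc_id", "exposure", "diagnosis",
    "crit_B", "crit_C", "crit_D", "crit_E", "crit_G",
    "sex", "age", "education", "profession", "single", "living_alone",
]

_BOOL = {"true": True, "1": True, "false": False, "0": False}


def read_metadata(path: str | Path) -> list[MetadataRecord]:
    """Read the cohort metadata CSV (exposure, diagnosis, criterion flags,
    socio-demographics). Unknown columns are preserved in ``extras``."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = _META_COLUMNS[:8]
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        records = []
        for rowno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_meta_row(row, header))
            except ValueError as e:
                raise ValueError(f"{path}: row {rowno}: {e}") from e
    return records


def _parse_bool(v: str, col: str) -> bool:
    try:
        return _BOOL[v.strip().lower()]
    except KeyError:
        raise ValueError(f"invalid boolean {v!r} in column {col}")


def _parse_meta_row(row: Mapping[str, str], header: Sequence[str]) -> MetadataRecord:
    criteria = {c: _parse_bool(row[f"crit_{c}"], f"crit_{c}") for c in CRITERIA}
    extras = {k: row[k] for k in header if k not in _META_COLUMNS}
    return MetadataRecord(
        doc_id=row["doc_id"],
        exposure=row["exposure"].strip(),
        diagnosis=row["diagnosis"].strip(),
        criteria=criteria,
        sex=row.get("sex", ""),
        age=float(row["age"]) if row.get("age") else float("nan"),
        education=row.get("education", ""),
        profession=row.get("profession", ""),
        single=_parse_bool(row.get("single", "false"), "single"),
        living_alone=_parse_bool(row.get("living_alone", "false"), "living_alone"),
        extras=extras,
    )


def write_metadata(records: Iterable[MetadataRecord], path: str | Path) -> None:
    records = list(records)
    extra_cols = sorted({k for r in records for k in r.extras})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_META_COLUMNS + extra_cols)
        for r in records:
            w.writerow(
                [
                    r.doc_id, r.exposure, r.diagnosis,
                    *[str(r.criteria[c]).lower() for c in CRITERIA],
                    r.sex, r.age, r.education, r.profession,
                    str(r.single).lower(), str(r.living_alone).lower(),
                ]
                + [r.extras.get(k, "") for k in extra_cols]
            )


# ---------------------------------------------------------------------------
# lexicon I/O


def read_lexicon(path: str | Path, name: str | None = None,
                 match_policy: str = "lemma") -> LexiconResource:
    """Read a lexicon CSV with columns ``term,category[,weight]``."""
    path = Path(path)
    entries: dict = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    start = 1 if rows and rows[0][:2] == ["term", "category"] else 0
    for rowno, row in enumerate(rows[start:], start=start + 1):
        if not row or not row[0].strip():
            continue
        term = row[0].strip().lower()
        category = row[1].strip()
        weight = float(row[2]) if len(row) > 2 and row[2].strip() else 1.0
        if (term, category) in entries:
            raise ValueError(
                f"{path}: row {rowno}: duplicate lexicon entry ({term}, {category})"
            )
        entries[(term, category)] = weight
    return LexiconResource(name or path.stem, entries, match_policy)


def write_lexicon(lexicon: LexiconResource, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["term", "category", "weight"])
        for (term, cat), weight in sorted(lexicon.entries.items()):
            w.writerow([term, cat, repr(weight)])


# ---------------------------------------------------------------------------
# feature-table I/O (doc_id + one column per feature; registry order)


def write_feature_table(table, path: str | Path) -> None:
    """Write a FeatureTable to CSV, lossless to 1e-12 relative tolerance."""
    df = table.to_frame()
    df.to_csv(path, index_label="doc_id", float_format="%.17g")


def read_feature_table(path: str | Path, registry=None):
    """Read a feature-table CSV back into a FeatureTable.

    Columns unknown to the registry are kept and a warning is emitted.
    """
    import warnings

    import pandas as pd

    from .registry import FeatureTable, default_registry

    df = pd.read_csv(path, index_col="doc_id")
    df.index = df.index.astype(str)
    if registry is None:
        registry = default_registry()
    known = set(registry.names)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"unknown feature columns kept as-is: {unknown}")
    return FeatureTable.from_frame(df, registry)
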