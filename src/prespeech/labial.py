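"""Labial-constraint coding from the first syllable of the first word.

An utterance is *labially constrained* when its first syllable forces a
small lip area at acoustic onset: either the syllable's initial consonant
is bilabial, labiodental, or rounded — IPA /b, f, m, p, ɹ, v, w/, ARPABET
{B, F, M, P, R, V, W} — or, regardless of initial consonant, its first
nuclear vowel is rounded — IPA /ɔ, o, ʊ, u/, ARPABET {AO, OW, UH, UW}.
Anything else is *labially unconstrained*.

Notes on the phoneme sets:

- Diphthongs are judged on the nucleus: OW (/oʊ/) and OY (/ɔɪ/) count as
  rounded ("no", "oh", "ok" are constrained); AW (/aʊ/) does not, its
  nucleus being unrounded /a/.
- In an onset cluster only the *initial* consonant is tested, so a /sp/
  onset is judged on /s/ and falls through to the vowel check.
- ARPABET stress digits are stripped before membership tests.

Coding is mechanized through a CMU-dict style pronunciation lexicon; a
small built-in lexicon covering the common one-word response vocabulary
ships with the package, and full CMU-dict files load with
:meth:`PronLexicon.from_file`. Out-of-lexicon words raise, and a manual
override table (word -> label) takes precedence over the lexicon.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from prespeech.errors import LexiconLookupError, MissingWordsError
from prespeech.turns import TypedUtterance

#: First-syllable onset consonants forcing lip closure or rounding.
LABIAL_ONSETS = frozenset({"B", "F", "M", "P", "R", "V", "W"})

#: Rounded nuclear vowels (diphthongs judged on the nucleus).
ROUNDED_NUCLEI = frozenset({"AO", "OW", "UH", "UW", "OY"})

_ARPABET_VOWELS = frozenset(
    {
        "AA", "AE", "AH", "AO", "AW", "AY", "EH", "ER", "EY",
        "IH", "IY", "OW", "OY", "UH", "UW",
    }
)

_STRESS_RE = re.compile(r"\d+$")


def _strip_stress(phone: str) -> str:
    return _STRESS_RE.sub("", phone.upper())


def normalize_word(word: str) -> str:
    """Case-fold and strip flanking punctuation, keeping internal
    apostrophes ("That's," -> "that's")."""
    return word.casefold().strip(".,;:!?\"()[]-").strip("'’")


@dataclass(frozen=True)
class ConstraintLabel:
    """A constraint verdict and the rule that produced it.

    ``basis`` is ``onset_consonant`` or ``nuclear_vowel`` when the word is
    constrained, ``neither`` exactly when it is unconstrained.
    """

    value: str  # "constrained" | "unconstrained"
    basis: str  # "onset_consonant" | "nuclear_vowel" | "neither"

    def __post_init__(self):
        assert (self.basis == "neither") == (self.value == "unconstrained")


class PronLexicon:
    """Word -> ARPABET phoneme sequence map (case-folded keys)."""

    def __init__(self, entries: dict[str, list[str]]):
        self.entries = {normalize_word(w): [p.upper() for p in ph] for w, ph in entries.items()}
        no_vowel = [
            w
            for w, ph in self.entries.items()
            if not any(_strip_stress(p) in _ARPABET_VOWELS for p in ph)
        ]
        if no_vowel:
            # Vocalized nasals like "mmhmm" legitimately lack a vowel
            # phoneme; they are judged on the onset consonant alone.
            warnings.warn(
                f"lexicon entries without a vowel phoneme: {', '.join(sorted(no_vowel))}",
                stacklevel=2,
            )

    @classmethod
    def from_file(cls, path) -> "PronLexicon":
        """Load a CMU-dict text dialect file (``WORD  PH1 PH2 ...``;
        ``;;;`` comments; ``WORD(2)`` alternate pronunciations ignored)."""
        entries: dict[str, list[str]] = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith(";;;"):
                continue
            head, *phones = line.split()
            if re.search(r"\(\d+\)$", head):
                continue  # keep the primary pronunciation only
            if phones:
                entries.setdefault(head, phones)
        return cls(entries)

    @classmethod
    def builtin(cls) -> "PronLexicon":
        """The bundled lexicon covering the common response vocabulary."""
        ref = resources.files("prespeech").joinpath("data/builtin_lexicon.dict")
        with resources.as_file(ref) as path:
            with warnings.catch_warnings():
                # the bundled MMHMM entry (vocalized nasal) is intentional
                warnings.simplefilter("ignore")
                return cls.from_file(path)

    def __contains__(self, word: str) -> bool:
        return normalize_word(word) in self.entries

    def lookup(self, word: str) -> list[str]:
        key = normalize_word(word)
        if key not in self.entries:
            raise LexiconLookupError(word)
        return self.entries[key]


def code_constraint(word: str, lexicon: PronLexicon) -> ConstraintLabel:
    """Code one word as labially constrained or unconstrained.

    The onset rule is checked first; the rounded-vowel rule applies
    regardless of the initial consonant; vowel-initial words are judged on
    the vowel alone.
    """
    phones = [_strip_stress(p) for p in lexicon.lookup(word)]
    first_vowel_pos = next(
        (i for i, p in enumerate(phones) if p in _ARPABET_VOWELS), None
    )
    if first_vowel_pos != 0 and phones and phones[0] in LABIAL_ONSETS:
        return ConstraintLabel("constrained", "onset_consonant")
    if first_vowel_pos is not None and phones[first_vowel_pos] in ROUNDED_NUCLEI:
        return ConstraintLabel("constrained", "nuclear_vowel")
    return ConstraintLabel("unconstrained", "neither")


def code_corpus(
    typed: list[TypedUtterance],
    lexicon: PronLexicon,
    overrides: dict[str, str] | None = None,
) -> list[tuple[TypedUtterance, ConstraintLabel]]:
    """Label every retained utterance by its first word.

    ``overrides`` maps word -> {"constrained", "unconstrained"} and takes
    precedence over the lexicon. Unresolvable words are aggregated into a
    single :class:`~prespeech.errors.MissingWordsError`.
    """
    overrides = {normalize_word(w): v for w, v in (overrides or {}).items()}
    missing: list[str] = []
    out: list[tuple[TypedUtterance, ConstraintLabel]] = []
    for t in typed:
        if not t.is_retained:
            continue
        key = normalize_word(t.first_word)
        if key in overrides:
            value = overrides[key]
            label = ConstraintLabel(value, "neither" if value == "unconstrained" else "override")
        elif t.first_word in lexicon:
            label = code_constraint(t.first_word, lexicon)
        else:
            missing.append(key)
            continue
        out.append((t, label))
    if missing:
        raise MissingWordsError(missing)
    return out


def load_overrides(path) -> dict[str, str]:
    """Read a two-column TSV override table (word<TAB>label)."""
    overrides: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("constrained", "unconstrained"):
            raise ValueError(f"overrides line {lineno}: expected 'word<TAB>constrained|unconstrained'")
        overrides[normalize_word(parts[0])] = parts[1]
    return overrides
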