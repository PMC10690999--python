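"""Added-sugar and non-sugar-sweetener detection from ingredient lists.

Label panels rarely declare added sugars separately, so the model's
added-sugar and NSS prohibitions are evaluated by screening the free-text
ingredient list against an editable lexicon. Matching is case-insensitive
and token/phrase aware after punctuation normalization: "sucrose" in
"(sucrose)" matches, "sugar" inside "sugar snap peas" does not, because
negative-context phrases are removed before matching. Parenthetical
sub-ingredients are searched like any other text.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["SweetenerLexicon", "ScreenResult", "load_lexicon", "screen_ingredients"]

_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def _normalize(text: str) -> tuple[str, ...]:
    """Lowercase, strip punctuation/diacritic marks, split into tokens."""
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = _PUNCT_RE.sub(" ", text.casefold())
    return tuple(_WS_RE.sub(" ", text).strip().split())


def _find_phrase(tokens: list[str], phrase: tuple[str, ...]) -> int:
    """Index of the first occurrence of ``phrase`` as a contiguous token run, else -1."""
    n, m = len(tokens), len(phrase)
    for i in range(n - m + 1):
        if tuple(tokens[i : i + m]) == phrase:
            return i
    return -1


@dataclass(frozen=True)
class SweetenerLexicon:
    """Term sets for screening; all entries lowercase and trimmed."""

    added_sugar_terms: frozenset[str]
    nss_terms: frozenset[str]
    negative_contexts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = self.added_sugar_terms & self.nss_terms
        if overlap:
            raise ConfigurationError(
                f"terms listed as both added sugar and NSS: {sorted(overlap)}"
            )
        for term in (*self.added_sugar_terms, *self.nss_terms, *self.negative_contexts):
            if term != term.strip().casefold() or not term:
                raise ConfigurationError(
                    f"lexicon entries must be non-empty, lowercase and trimmed: {term!r}"
                )


@dataclass(frozen=True)
class ScreenResult:
    product_id: str | None
    has_added_sugar: bool
    has_nss: bool
    matched_terms: tuple[str, ...]
    screenable: bool


def default_lexicon_path() -> Path:
    return Path(str(resources.files("foodprofiler").joinpath("data/sweetener_lexicon.yaml")))


def load_lexicon(config_path: str | Path | None = None) -> SweetenerLexicon:
    """Load a lexicon config; with no argument, the packaged default."""
    path = Path(config_path) if config_path is not None else default_lexicon_path()
    if not path.exists():
        raise ConfigurationError(f"lexicon config not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: lexicon config must be a mapping")
    for key in ("added_sugar_terms", "nss_terms"):
        if not isinstance(raw.get(key), list):
            raise ConfigurationError(f"{path}: missing list field {key!r}")
    return SweetenerLexicon(
        added_sugar_terms=frozenset(raw["added_sugar_terms"]),
        nss_terms=frozenset(raw["nss_terms"]),
        negative_contexts=tuple(raw.get("negative_contexts", []) or []),
    )


def screen_ingredients(
    text: str,
    lexicon: SweetenerLexicon,
    product_id: str | None = None,
) -> ScreenResult:
    """Screen one ingredient list for added-sugar and NSS terms.

    Empty (or whitespace-only) text is unscreenable and yields both flags
    false. Negative-context phrases take precedence: they are excised from
    the token stream before term matching, so "no added sugar" or "sugar
    snap peas" cannot trigger the bare "sugar" term.
    """
    tokens = list(_normalize(text))
    if not tokens:
        return ScreenResult(product_id, False, False, (), screenable=False)

    # longest negative context first so overlapping phrases resolve stably
    for phrase in sorted(lexicon.negative_contexts, key=lambda p: -len(p.split())):
        ptoks = _normalize(phrase)
        if not ptoks:
            continue
        i = _find_phrase(tokens, ptoks)
        while i >= 0:
            del tokens[i : i + len(ptoks)]
            i = _find_phrase(tokens, ptoks)

    matched: set[str] = set()
    has_sugar = has_nss = False
    for term in lexicon.added_sugar_terms:
        if _find_phrase(tokens, _normalize(term)) >= 0:
            matched.add(term)
            has_sugar = True
    for term in lexicon.nss_terms:
        if _find_phrase(tokens, _normalize(term)) >= 0:
            matched.add(term)
            has_nss = True
    return ScreenResult(product_id, has_sugar, has_nss, tuple(sorted(matched)), True)
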