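"""Pluggable knowledge sources supplying explanation texts for terms.

A knowledge source answers "what is <term>?" with a short prose
explanation; the scoring stage then looks for body-part names inside
that prose. Two sources are provided:

* :class:`FixtureSource` — a directory of ``.txt`` files (plus an
  optional ``index.tsv``) used for all tests and synthetic benchmarks;
  fully offline and deterministic.
* :class:`LiveSource` — the Wikipedia REST API (lead extract of the
  best-matching article). Page content drifts over time, so live
  results are for interactive use, never for reproducible evaluation.

Explanations are preprocessed with the exact same tokenize/stopword/
stem pipeline as mentions, so in-text matching happens in one shared
token space; scoring offsets are positions in this filtered stream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .normalize import stem_and_clean

__all__ = [
    "Explanation",
    "KnowledgeSource",
    "FixtureSource",
    "LiveSource",
    "TransportError",
    "ConfigurationError",
    "fetch_explanation",
    "preprocess_explanation",
    "slugify",
]


class TransportError(RuntimeError):
    """A live-source network failure (distinct from a simple miss)."""


class ConfigurationError(ValueError):
    """A misconfigured knowledge source (e.g. missing fixture directory)."""


@dataclass
class Explanation:
    """An explanation text for a term, raw and preprocessed."""

    term: str
    raw_text: str
    tokens: tuple[str, ...]
    source: str  # "fixture" | "live"


def preprocess_explanation(
    raw_text: str, stopwords: frozenset[str] | None = None
) -> tuple[str, ...]:
    """Identical pipeline to mention cleaning, over explanation prose."""
    return tuple(stem_and_clean(raw_text, stopwords))


def slugify(term: str) -> str:
    """Lowercase filename slug: spaces and punctuation -> underscores."""
    slug = re.sub(r"[^a-z0-9]+", "_", term.strip().lower())
    return slug.strip("_")


class KnowledgeSource:
    """Base class: subclasses implement :meth:`_lookup`."""

    name = "abstract"

    def __init__(self, stopwords: frozenset[str] | None = None):
        self._stopwords = stopwords
        self._cache: dict[str, Explanation | None] = {}

    def fetch(self, term: str) -> Explanation | None:
        key = term.strip().lower()
        if not key:
            return None
        if key not in self._cache:
            raw = self._lookup(key)
            if raw is None:
                self._cache[key] = None
            else:
                self._cache[key] = Explanation(
                    term=key,
                    raw_text=raw,
                    tokens=preprocess_explanation(raw, self._stopwords),
                    source=self.name,
                )
        return self._cache[key]

    def _lookup(self, term: str) -> str | None:  # pragma: no cover
        raise NotImplementedError


class FixtureSource(KnowledgeSource):
    """Explanations stored as UTF-8 ``.txt`` files in a directory.

    A term resolves to ``<slug>.txt`` (case-insensitive, spaces to
    underscores); an optional ``index.tsv`` (term, filename) covers
    terms whose names are not filename-safe.
    """

    name = "fixture"

    def __init__(
        self,
        directory: str | Path,
        stopwords: frozenset[str] | None = None,
    ):
        super().__init__(stopwords)
        self.directory = Path(directory)
        if not self.directory.is_dir():
            raise ConfigurationError(
                f"fixture KB directory not found: {self.directory}"
            )
        self._index: dict[str, str] = {}
        index_path = self.directory / "index.tsv"
        if index_path.exists():
            for line in index_path.read_text(encoding="utf-8").splitlines():
                if "\t" in line:
                    term, filename = line.split("\t", 1)
                    self._index[term.strip().lower()] = filename.strip()

    def _lookup(self, term: str) -> str | None:
        filename = self._index.get(term, slugify(term) + ".txt")
        path = self.directory / filename
        if not path.is_file():
            return None
        return path.read_text(encoding="utf-8")


class LiveSource(KnowledgeSource):
    """Lead extracts from the Wikipedia REST API (network required).

    Term-to-page resolution tries the exact title first, then the top
    search hit; disambiguation pages count as a miss. ``scope`` may be
    ``lead`` (summary extract, default) or ``full`` (plain-prose page
    text).
    """

    name = "live"

    def __init__(
        self,
        endpoint: str = "https://en.wikipedia.org",
        scope: str = "lead",
        timeout_seconds: float = 10.0,
        stopwords: frozenset[str] | None = None,
    ):
        super().__init__(stopwords)
        if scope not in ("lead", "full"):
            raise ConfigurationError(f"kb.scope must be lead|full, got {scope!r}")
        self.endpoint = endpoint.rstrip("/")
        self.scope = scope
        self.timeout = timeout_seconds

    def _get(self, url: str, **params):
        import requests

        try:
            resp = requests.get(
                url,
                params=params or None,
                timeout=self.timeout,
                headers={"User-Agent": "anatomap/0.1"},
            )
        except requests.RequestException as exc:
            raise TransportError(f"knowledge-base request failed: {exc}") from exc
        return resp

    def _summary(self, title: str) -> dict | None:
        resp = self._get(
            f"{self.endpoint}/api/rest_v1/page/summary/{title.replace(' ', '_')}"
        )
        if resp.status_code != 200:
            return None
        data = resp.json()
        if data.get("type") == "disambiguation":
            return None
        return data

    def _lookup(self, term: str) -> str | None:
        data = self._summary(term)
        if data is None:
            resp = self._get(
                f"{self.endpoint}/w/api.php",
                action="opensearch",
                search=term,
                limit=1,
                format="json",
            )
            if resp.status_code != 200:
                return None
            hits = resp.json()
            titles = hits[1] if len(hits) > 1 else []
            if not titles:
                return None
            data = self._summary(titles[0])
            if data is None:
                return None
        if self.scope == "lead":
            return data.get("extract") or None
        resp = self._get(
            f"{self.endpoint}/w/api.php",
            action="query",
            prop="extracts",
            explaintext=1,
            titles=data.get("title", term),
            format="json",
        )
        if resp.status_code != 200:
            return data.get("extract") or None
        pages = resp.json().get("query", {}).get("pages", {})
        for page in pages.values():
            text = page.get("extract")
            if text:
                return text
        return data.get("extract") or None


def fetch_explanation(source: KnowledgeSource, term: str) -> Explanation | None:
    """Fetch (and cache) the explanation for ``term``; ``None`` on a miss."""
    return source.fetch(term)
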