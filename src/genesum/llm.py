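"""Completion backends: contract, sqlite cache, deterministic mock, live adapter.

The cache is a single sqlite3 file keyed by a stable content hash of
(backend id, model, temperature, prompt); identical requests always return
byte-identical responses, which is what makes the run-to-run stability probe
(changing only the prompt end marker) meaningful.

The mock backend is a pure function of (prompt, behavior, seed). It reads
ONLY the description lines inside the prompt — deliberately ignoring gene
symbols — which mirrors how a real model behaves under the description-swap
control: summaries track the descriptions, not the symbols.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import sqlite3
import time
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol

from .annotations import GeneAnnotationStore
from .errors import FormatError, TransportError

logger = logging.getLogger(__name__)

MOCK_BEHAVIORS = ("faithful", "noisy", "ungroundable")
_DESCRIPTION_HEADER = "Here are the gene summaries:"


@dataclass(frozen=True)
class CompletionRequest:
    prompt: str
    model_name: str = "mock-small"
    temperature: float = 0.0  # lowest supported: maximize determinism
    max_output_tokens: int = 1024

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be nonnegative")
        if self.max_output_tokens <= 0:
            raise ValueError("max_output_tokens must be positive")


@dataclass
class CompletionRecord:
    request: CompletionRequest
    response_text: str
    backend_id: str
    cached: bool
    timestamp: Optional[float] = None
    truncated: bool = False


def cache_key(backend_id: str, req: CompletionRequest) -> str:
    payload = json.dumps(
        [backend_id, req.model_name, f"{req.temperature:.6g}", req.prompt],
        ensure_ascii=False,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


class CompletionCache:
    """Persistent key→response store backed by a single sqlite3 file."""

    def __init__(self, path):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS completions ("
            "key TEXT PRIMARY KEY, response TEXT NOT NULL, "
            "backend_id TEXT, model TEXT, created REAL)"
        )
        self._conn.commit()

    def get(self, key: str) -> Optional[str]:
        row = self._conn.execute(
            "SELECT response FROM completions WHERE key = ?", (key,)
        ).fetchone()
        return row[0] if row else None

    def put(self, key: str, response: str, backend_id: str, model: str) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO completions VALUES (?, ?, ?, ?, ?)",
            (key, response, backend_id, model, time.time()),
        )
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()


class Backend(Protocol):
    backend_id: str

    def generate(self, req: CompletionRequest) -> str: ...

    @property
    def deterministic(self) -> bool: ...


def complete(
    req: CompletionRequest,
    backend: Backend,
    cache: Optional[CompletionCache] = None,
) -> CompletionRecord:
    """Serve the request from cache, else call the backend and store the result."""
    key = cache_key(backend.backend_id, req)
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return CompletionRecord(
                request=req,
                response_text=hit,
                backend_id=backend.backend_id,
                cached=True,
                timestamp=None if backend.deterministic else time.time(),
            )
    try:
        response = backend.generate(req)
    except TransportError:
        raise
    except Exception as exc:
        raise TransportError(f"backend {backend.backend_id} failed: {exc}") from exc
    if cache is not None:
        cache.put(key, response, backend.backend_id, req.model_name)
    return CompletionRecord(
        request=req,
        response_text=response,
        backend_id=backend.backend_id,
        cached=False,
        timestamp=None if backend.deterministic else time.time(),
    )


# -- mock backend ----------------------------------------------------------


def _parse_description_block(prompt: str) -> list[tuple[str, str]]:
    """Recover (symbol, text) pairs from the prompt's description block."""
    if _DESCRIPTION_HEADER not in prompt:
        raise FormatError("prompt has no recognizable description block")
    block = prompt.split(_DESCRIPTION_HEADER, 1)[1]
    lines = [ln.strip() for ln in block.splitlines() if ln.strip()]
    # the final line is the end marker when it carries no word characters
    if lines and not re.search(r"\w", lines[-1]):
        lines = lines[:-1]
    if not lines:
        raise FormatError("prompt description block is empty")
    pairs = []
    for ln in lines:
        if ": " in ln:
            symbol, text = ln.split(": ", 1)
            pairs.append((symbol.strip(), text.strip()))
        else:
            pairs.append((ln, ""))
    return pairs


def mock_complete(
    req: CompletionRequest,
    store: GeneAnnotationStore,
    behavior: str = "faithful",
    seed: int = 0,
) -> str:
    """Deterministic stand-in for a generative model.

    * ``faithful`` — reports every ontology label mentioned in at least two
      description lines (the commonalities actually present in the prompt);
    * ``noisy`` — faithful plus one ontology label unrelated to the prompt;
    * ``ungroundable`` — faithful with one term replaced by a paraphrase
      absent from the ontology's labels and synonyms, emulating a phrase like
      "myelin sheath maintenance" that no exact matcher can ground.

    The output follows the requested Summary / Mechanism / Enriched Terms
    payload format.
    """
    if behavior not in MOCK_BEHAVIORS:
        raise ValueError(f"unknown mock behavior: {behavior!r}")
    pairs = _parse_description_block(req.prompt)
    texts = [text.casefold() for _, text in pairs]

    mentioned: dict[str, int] = {}
    labels = {}
    for term_id, term in store.ontology.terms.items():
        if term.obsolete or not term.label:
            continue
        labels[term_id] = term.label
        needle = term.label.casefold()
        mentioned[term_id] = sum(1 for text in texts if needle in text)
    shared = sorted(
        (labels[t] for t, c in mentioned.items() if c >= 2), key=str.casefold
    )

    terms = list(shared)
    if behavior == "noisy":
        # any label NOT shared across lines is fair game as the off-topic extra
        unrelated = sorted(
            labels[t] for t, c in mentioned.items() if c < 2 and labels[t] not in terms
        )
        if unrelated:
            digest = hashlib.sha256(f"{seed}|{req.prompt}".encode()).hexdigest()
            terms.append(unrelated[int(digest, 16) % len(unrelated)])
    elif behavior == "ungroundable":
        known = {
            s.casefold()
            for term in store.ontology.terms.values()
            for s in {term.label, *term.synonyms}
            if s
        }

        def paraphrase(base: str) -> str:
            candidate = f"{base} maintenance"
            while candidate.casefold() in known:
                candidate += " capacity"
            return candidate

        if terms:
            terms[0] = paraphrase(terms[0])
        else:
            terms.append(paraphrase("uncharacterized cellular process"))

    focus = terms[0] if terms else "no single shared function"
    summary = f"The {len(pairs)} genes share functions centered on {focus}."
    mechanism = f"A common pathway involving {focus} is the most plausible mechanism."
    return (
        f"Summary: {summary}\n"
        f"Mechanism: {mechanism}\n"
        f"Enriched Terms: {'; '.join(terms)}"
    )


@dataclass
class MockBackend:
    """Backend wrapper around :func:`mock_complete` (pure, cache-friendly)."""

    store: GeneAnnotationStore
    behavior: str = "faithful"
    seed: int = 0
    deterministic: bool = True

    @property
    def backend_id(self) -> str:
        return f"mock-{self.behavior}-{self.seed}"

    def generate(self, req: CompletionRequest) -> str:
        return mock_complete(req, self.store, self.behavior, self.seed)


@dataclass
class CachedOnlyBackend:
    """Never generates: a cache miss is a transport error.

    Pair with a cache file of shipped completions to re-run an analysis
    without any model access.
    """

    backend_id: str = "cached-only"
    deterministic: bool = True

    def generate(self, req: CompletionRequest) -> str:
        raise TransportError("cached-only backend has no entry for this prompt", retryable=False)


class OpenAICompatibleBackend:
    """Minimal adapter for an OpenAI-style /v1/completions endpoint.

    Endpoint and API key come from environment variables (never from config
    files). Untested against any specific provider; the test suite runs
    entirely on the mock backend.
    """

    deterministic = False

    def __init__(self, endpoint: str, api_key: str = "", timeout: float = 60.0):
        self.endpoint = endpoint
        self.api_key = api_key
        self.timeout = timeout
        self.backend_id = f"openai-compatible:{endpoint}"

    @classmethod
    def from_env(cls) -> "OpenAICompatibleBackend":
        import os

        endpoint = os.environ.get("GENESUM_LLM_ENDPOINT")
        if not endpoint:
            raise TransportError("GENESUM_LLM_ENDPOINT is not set", retryable=False)
        return cls(endpoint, os.environ.get("GENESUM_LLM_API_KEY", ""))

    def generate(self, req: CompletionRequest) -> str:
        body = json.dumps(
            {
                "model": req.model_name,
                "prompt": req.prompt,
                "temperature": req.temperature,
                "max_tokens": req.max_output_tokens,
            }
        ).encode()
        request = urllib.request.Request(
            self.endpoint,
            data=body,
            headers={
                "Content-Type": "application/json",
                **({"Authorization": f"Bearer {self.api_key}"} if self.api_key else {}),
            },
        )
        try:
            with urllib.request.urlopen(request, timeout=self.timeout) as resp:
                doc = json.loads(resp.read())
        except Exception as exc:
            raise TransportError(f"completion endpoint failed: {exc}") from exc
        try:
            return doc["choices"][0]["text"]
        except (KeyError, IndexError, TypeError) as exc:
            raise TransportError(f"unexpected endpoint response shape: {exc}") from exc
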