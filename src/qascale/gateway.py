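"""Uniform chat-completion gateway.

A single contract (:func:`chat` / :func:`chat_batch`) over any
OpenAI-style chat backend.  Two implementations ship here:

* :class:`HTTPBackend` — a thin client for an OpenAI-compatible
  ``/v1/chat/completions`` endpoint (stdlib ``urllib``; no streaming).
* :class:`MockBackend` — a scripted, fully deterministic stand-in used
  for offline runs, calibration and tests.  Its script is keyed by
  ``(record_id, question_id)`` and it can corrupt its own answers with a
  seeded noise channel (flips, nulls, context-scaled gibberish).

Decoding defaults follow the extraction protocol: greedy decoding
(temperature 0) and a small per-task ``max_tokens`` cap.  Raw completion
text is preserved byte-for-byte; any normalization happens downstream.
"""

from __future__ import annotations

import json
import random
import time
import urllib.error
import urllib.request
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from ._util import stable_seed

__all__ = [
    "ChatMessage",
    "GenerationParams",
    "Completion",
    "BatchFailure",
    "BackendError",
    "BackendUnavailable",
    "TransportError",
    "ProtocolError",
    "Backend",
    "MockBackend",
    "HTTPBackend",
    "chat",
    "chat_batch",
    "load_mock_script",
]

ROLES = ("system", "user", "assistant")

GIBBERISH = "#@&%$!@#"


class BackendError(Exception):
    """Base class for gateway failures."""


class TransportError(BackendError):
    """Retryable failure: network trouble, timeout, 5xx."""


class BackendUnavailable(BackendError):
    """All retry attempts exhausted."""


class ProtocolError(BackendError):
    """The backend replied, but not in the expected wire shape."""


@dataclass(frozen=True)
class ChatMessage:
    role: str
    content: str


@dataclass(frozen=True)
class GenerationParams:
    """Decoding and client-side policy for one task.

    temperature : greedy decoding by default (0.0).
    max_tokens  : per-task output cap (20 for Q&A cells).
    timeout     : per-request wall-clock limit, seconds.
    retries     : extra attempts on transport errors (attempts <= retries+1).
    backoff     : base of the exponential backoff between attempts, seconds.
    """

    temperature: float = 0.0
    max_tokens: int = 20
    timeout: float = 30.0
    retries: int = 3
    backoff: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature <= 1.0:
            raise ValueError("temperature must be in [0, 1]")
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be positive")
        if self.retries < 0:
            raise ValueError("retries must be non-negative")


@dataclass(frozen=True)
class Completion:
    text: str
    latency: float
    backend_id: str
    attempt: int = 1


@dataclass(frozen=True)
class BatchFailure:
    """Per-key error marker in a batch result; never aborts the batch."""

    key: object
    error: str


def validate_messages(messages: Sequence[ChatMessage]) -> None:
    if not messages:
        raise ValueError("empty message list")
    start = 0
    if messages[0].role == "system":
        start = 1
    expected = "user"
    for m in messages[start:]:
        if m.role not in ROLES:
            raise ValueError(f"unknown role {m.role!r}")
        if m.role != expected:
            raise ValueError("roles must alternate user/assistant after an optional system message")
        if m.role == "user" and not m.content:
            raise ValueError("user message content must be non-empty")
        expected = "assistant" if expected == "user" else "user"
    if not any(m.role == "user" for m in messages):
        raise ValueError("at least one user message required")


class Backend:
    """One completion call; retry/latency bookkeeping lives in :func:`chat`."""

    backend_id: str = "backend"

    def complete(
        self,
        messages: Sequence[ChatMessage],
        params: GenerationParams,
        key: object | None = None,
    ) -> tuple[str, float | None]:
        """Return (raw text, scripted latency or None for wall-clock)."""
        raise NotImplementedError


class HTTPBackend(Backend):
    """OpenAI-compatible chat-completions client (non-streaming)."""

    def __init__(self, base_url: str, model: str, api_key: str = "", backend_id: str | None = None):
        self.base_url = base_url.rstrip("/")
        self.model = model
        self.api_key = api_key
        self.backend_id = backend_id or model

    def payload(self, messages: Sequence[ChatMessage], params: GenerationParams) -> dict:
        return {
            "model": self.model,
            "messages": [{"role": m.role, "content": m.content} for m in messages],
            "temperature": params.temperature,
            "max_tokens": params.max_tokens,
        }

    def complete(self, messages, params, key=None):
        req = urllib.request.Request(
            self.base_url + "/v1/chat/completions",
            data=json.dumps(self.payload(messages, params)).encode("utf-8"),
            headers={
                "Content-Type": "application/json",
                **({"Authorization": f"Bearer {self.api_key}"} if self.api_key else {}),
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=params.timeout) as resp:
                body = json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, TimeoutError, OSError) as exc:
            raise TransportError(str(exc)) from exc
        except json.JSONDecodeError as exc:
            raise ProtocolError(f"invalid JSON from backend: {exc}") from exc
        try:
            return body["choices"][0]["message"]["content"], None
        except (KeyError, IndexError, TypeError) as exc:
            raise ProtocolError(f"unexpected response shape: {body!r}") from exc


class MockBackend(Backend):
    """Deterministic scripted backend.

    Parameters
    ----------
    script
        ``(record_id, question_id) -> response`` or ``-> (response,
        flipped_response)``.  The flipped form is what the noise channel
        emits on a corruption draw (for binary cells the opposite answer,
        modeling context/temporal confusion).
    flip_rate, null_rate, gibberish_rate
        Seeded noise channel, drawn once per key from a single uniform so
        results are identical across concurrency settings and run order.
        ``flip_rate`` is the *total* corruption probability; empty-output
        nulls (``null_rate``) and gibberish are realized within it, so the
        expected accuracy of a noisy run is ``1 - max(flip_rate,
        null_rate + gibberish)``.  ``gibberish_rate`` scales with prompt
        length (per 100 characters of the final user message), emulating
        degradation on long contexts.
    fail_times
        ``key -> n``: raise a transport error on the first *n* calls for
        that key (retry-contract testing).  Keys in ``fail_always`` fail
        on every attempt.
    latency
        Scripted per-call latency in seconds, recorded but never slept.
    """

    def __init__(
        self,
        script: Mapping[object, object] | None = None,
        *,
        flip_rate: float = 0.0,
        null_rate: float = 0.0,
        gibberish_rate: float = 0.0,
        seed: int = 0,
        latency: float = 0.05,
        default_response: str | None = None,
        fail_times: Mapping[object, int] | None = None,
        fail_always: Iterable[object] = (),
        backend_id: str = "mock",
    ):
        self.script = dict(script or {})
        self.flip_rate = flip_rate
        self.null_rate = null_rate
        self.gibberish_rate = gibberish_rate
        self.seed = seed
        self.latency = latency
        self.default_response = default_response
        self._fail_remaining = dict(fail_times or {})
        self._fail_always = set(fail_always)
        self.backend_id = backend_id

    def _lookup(self, key: object) -> tuple[str, str]:
        entry = self.script.get(key, self.default_response)
        if entry is None:
            raise ProtocolError(f"mock backend has no script entry for key {key!r}")
        if isinstance(entry, tuple):
            response, flipped = entry
        else:
            response, flipped = entry, entry
        return str(response), str(flipped)

    def complete(self, messages, params, key=None):
        if key in self._fail_always:
            raise TransportError(f"scripted permanent failure for {key!r}")
        left = self._fail_remaining.get(key, 0)
        if left > 0:
            self._fail_remaining[key] = left - 1
            raise TransportError(f"scripted transient failure for {key!r}")

        response, flipped = self._lookup(key)
        context_chars = len(messages[-1].content) if messages else 0
        text = self._corrupt(key, response, flipped, context_chars)
        jitter = stable_seed("latency", self.seed, key) % 1000 / 10000.0
        return text, self.latency + jitter

    def _corrupt(self, key: object, response: str, flipped: str, context_chars: int) -> str:
        g_eff = min(0.95, self.gibberish_rate * context_chars / 100.0)
        bound = max(self.flip_rate, self.null_rate + g_eff)
        if bound <= 0.0:
            return response
        u = random.Random(stable_seed("noise", self.seed, key)).random()
        if u < self.null_rate:
            return ""
        if u < self.null_rate + g_eff:
            return GIBBERISH
        if u < bound:
            return flipped
        return response


def load_mock_script(path) -> dict[tuple[str, str], tuple[str, str]]:
    """Read a JSONL mock script: one object per line with record_id,
    question_id, response and optional flipped."""
    script: dict[tuple[str, str], tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            resp = str(obj["response"])
            script[(obj["record_id"], obj["question_id"])] = (resp, str(obj.get("flipped", resp)))
    return script


def dump_mock_script(script: Mapping[tuple[str, str], tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (rid, qid), entry in script.items():
            resp, flipped = entry if isinstance(entry, tuple) else (entry, entry)
            obj = {"record_id": rid, "question_id": qid, "response": resp}
            if flipped != resp:
                obj["flipped"] = flipped
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def chat(
    backend: Backend,
    messages: Sequence[ChatMessage],
    params: GenerationParams | None = None,
    key: object | None = None,
) -> Completion:
    """One completion with retries on transport errors.

    Raw text is returned unmodified; latency is wall-clock unless the
    backend scripts it.  Raises :class:`BackendUnavailable` once
    ``retries`` extra attempts are exhausted; :class:`ProtocolError`
    surfaces immediately (a malformed reply will not improve on retry).
    """
    params = params or GenerationParams()
    validate_messages(messages)
    last: Exception | None = None
    for attempt in range(1, params.retries + 2):
        t0 = time.perf_counter()
        try:
            text, scripted = backend.complete(messages, params, key=key)
        except TransportError as exc:
            last = exc
            if attempt <= params.retries and params.backoff > 0:
                time.sleep(params.backoff * 2 ** (attempt - 1))
            continue
        latency = scripted if scripted is not None else time.perf_counter() - t0
        return Completion(text=text, latency=latency, backend_id=backend.backend_id, attempt=attempt)
    raise BackendUnavailable(f"backend {backend.backend_id!r} failed after {params.retries + 1} attempts: {last}")


def chat_batch(
    backend: Backend,
    jobs: Sequence[tuple[object, Sequence[ChatMessage]]],
    params: GenerationParams | None = None,
    concurrency: int = 3,
    on_result: Callable[[object, Completion | BatchFailure], None] | None = None,
) -> dict[object, Completion | BatchFailure]:
    """Run many chat jobs with at most `concurrency` requests in flight.

    The result map is complete: every key maps to a :class:`Completion`
    or a :class:`BatchFailure`; one bad job never aborts the batch.  For
    deterministic backends the assembled map is identical across
    concurrency settings (assembly is keyed, not completion-ordered).
    """
    if concurrency < 1:
        raise ValueError("concurrency must be >= 1")
    keys = [k for k, _ in jobs]
    if len(set(keys)) != len(keys):
        raise ValueError("job keys must be unique")
    params = params or GenerationParams()
    results: dict[object, Completion | BatchFailure] = {}

    def one(job: tuple[object, Sequence[ChatMessage]]) -> tuple[object, Completion | BatchFailure]:
        k, msgs = job
        try:
            return k, chat(backend, msgs, params, key=k)
        except BackendError as exc:
            return k, BatchFailure(key=k, error=f"{type(exc).__name__}: {exc}")

    if not jobs:
        return results

    def consume(outcomes) -> None:
        for k, out in outcomes:
            results[k] = out
            if on_result is not None:
                on_result(k, out)

    if concurrency == 1:
        consume(map(one, jobs))
    else:
        with ThreadPoolExecutor(max_workers=concurrency) as pool:
            consume(pool.map(one, jobs))
    return results
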