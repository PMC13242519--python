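"""Knowledge-provider abstraction: live LLM API, offline mock, fixtures.

The pipeline asks three kinds of questions:

* ``suggest_interacting_genes`` — expand a seed gene list with likely
  interaction partners in a stated biological context;
* ``classify_pair`` — one signed integer per ordered gene pair:
  1 direct activation, -1 direct inhibition, 2 indirect activation,
  -2 indirect inhibition (mediated by genes absent from the model),
  0 no known interaction;
* ``suggest_upstream_regulator`` — one HGNC symbol (or the sentinel
  ``EMPTY``) that regulates a poorly fitted target gene in a required
  direction, excluding genes already in the network.

All providers share one contract so the whole pipeline runs offline
against :class:`MockKnowledgeBase`, a deterministic oracle built from a
planted ground-truth network.  Responses are parsed defensively: the
first signed integer after Markdown/bracket cleanup, with both the ASCII
hyphen and the Unicode minus accepted as sign characters.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

EMPTY = "EMPTY"
ALPHABET = (-2, -1, 0, 1, 2)


class ParseError(ValueError):
    """Provider answer could not be interpreted; carries the raw text."""

    def __init__(self, message: str, raw: str = ""):
        super().__init__(f"{message}; raw response: {raw!r}")
        self.raw = raw


class ProviderError(RuntimeError):
    """Provider failed to answer after retries."""


@dataclass
class ProviderConfig:
    """Request settings shared by all providers.

    Temperature and top_p default to 0 so answers are as deterministic
    as the backing model allows; ``context`` is free-text biological
    framing (tissue, phenotype, treatment) inserted into every prompt.
    """

    model: str = "sonar"
    temperature: float = 0.0
    top_p: float = 0.0
    context: str = ""
    timeout: float = 60.0
    max_retries: int = 2

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if not 0 <= self.top_p <= 1:
            raise ValueError("top_p must be in [0, 1]")


@dataclass(frozen=True)
class InteractionVerdict:
    """One signed interaction call for an ordered gene pair."""

    source: str
    target: str
    value: int
    provenance: str = "mock"  # live | mock | fixture

    def __post_init__(self):
        if self.value not in ALPHABET:
            raise ValueError(f"verdict {self.value} outside {{-2,-1,0,1,2}}")


_SIGNED_INT = re.compile(r"[-−–]?\d+")


def _cleanup(text: str) -> str:
    text = re.sub(r"```[a-zA-Z]*", "", text)
    text = re.sub(r"[*_`#>\[\](){}|]", " ", text)
    return text.replace("\n", " ").replace("\r", " ")


def parse_interaction_response(text: str) -> int:
    """First signed integer in the cleaned response, validated.

    Markdown fences and emphasis, brackets and line breaks are stripped
    first; '-', en-dash and the Unicode minus all count as a minus sign.
    """
    m = _SIGNED_INT.search(_cleanup(text))
    if m is None:
        raise ParseError("no integer found in response", text)
    value = int(m.group(0).replace("−", "-").replace("–", "-"))
    if value not in ALPHABET:
        raise ParseError(f"integer {value} outside {{-2,-1,0,1,2}}", text)
    return value


def parse_symbol_response(text: str) -> str:
    """A single gene symbol or ``EMPTY`` from an upstream-regulator answer."""
    cleaned = _cleanup(text).strip()
    tokens = cleaned.split()
    if len(tokens) != 1:
        raise ParseError(f"expected one symbol, got {len(tokens)} tokens", text)
    return tokens[0].upper()


def parse_gene_list_response(text: str) -> list:
    """Comma- or newline-separated gene symbols from a list answer."""
    cleaned = re.sub(r"```[a-zA-Z]*", "", text)
    cleaned = re.sub(r"[*_`#>\[\](){}|]", " ", cleaned)
    parts = re.split(r"[,;\n]+", cleaned)
    symbols = [p.strip().upper() for p in parts if p.strip()]
    if not symbols:
        raise ParseError("no gene symbols found in response", text)
    return symbols


def standardize_symbol(name: str, synonym_map=None, known_genes=None):
    """Map a provider symbol through the user-supplied synonym table.

    Unmapped names are upper-cased and whitespace-trimmed.  When
    ``known_genes`` is given, returns ``(symbol, in_dataset)`` so callers
    can reject symbols absent from the measured gene set; otherwise just
    the symbol.  No gene database is bundled: the synonym map is the
    user's responsibility.
    """
    synonym_map = synonym_map or {}
    raw = name.strip()
    symbol = synonym_map.get(raw, synonym_map.get(raw.upper(), raw.upper()))
    if known_genes is None:
        return symbol
    return symbol, symbol in set(known_genes)


# ---------------------------------------------------------------------------
# Prompt templates (re-authored; users may substitute their own files).
# Each states the output contract the parser expects.
# ---------------------------------------------------------------------------

PROMPT_TEMPLATES = {
    "gene_list": (
        "Context: {context}\n"
        "The following genes are of interest: {genes}.\n"
        "Name exactly {n_new} additional human genes (HGNC symbols) that "
        "directly interact with these genes in this context and are suitable "
        "nodes for a causal regulatory network model. Answer with a "
        "comma-separated list of HGNC symbols only, no prose."
    ),
    "pair_interaction": (
        "Context: {context}\n"
        "Does {gene1} regulate {gene2}? Consider only evidence repeated in "
        "peer-reviewed literature; do not speculate. Answer with a single "
        "integer: 1 direct activation, -1 direct inhibition, 2 indirect "
        "activation (mediated by genes not in the model), -2 indirect "
        "inhibition, 0 no known interaction or insufficient evidence."
    ),
    "upstream_strict": (
        "Context: {context}\n"
        "Which gene is a direct upstream regulator of {target} acting by "
        "{direction}? Exclude downstream targets, co-factors and non-causal "
        "interactors, and exclude these genes: {exclude}. Answer with exactly "
        "one HGNC symbol, or EMPTY if no candidate meets all criteria."
    ),
    "upstream_relaxed": (
        "Context: {context}\n"
        "Name one gene that regulates {target} by {direction} and is not in "
        "this list: {exclude}. Evidence from related tissues or disease "
        "contexts may be used. Answer with exactly one HGNC symbol, or EMPTY."
    ),
}


class KnowledgeProvider:
    """Contract shared by live, mock and fixture providers."""

    config: ProviderConfig

    def complete(self, prompt: str) -> str:  # pragma: no cover - interface
        raise NotImplementedError


class LiveProvider(KnowledgeProvider):
    """Chat-completion HTTPS provider (PerplexityAI-style API).

    Credentials come from an environment variable; requests carry the
    configured model, temperature and top_p.  Every raw response is
    appended to a JSONL transcript for replay.  Network access is never
    exercised by the test suite.
    """

    def __init__(self, config: ProviderConfig = None,
                 api_url: str = "https://api.perplexity.ai/chat/completions",
                 api_key_env: str = "GRNLOOP_API_KEY", transcript_path=None):
        self.config = config or ProviderConfig()
        self.api_url = api_url
        self.api_key_env = api_key_env
        self.transcript_path = transcript_path
        self.n_calls = 0

    def complete(self, prompt: str) -> str:
        import os
        import urllib.request

        key = os.environ.get(self.api_key_env)
        if not key:
            raise ProviderError(
                f"no API key in environment variable {self.api_key_env}")
        payload = json.dumps({
            "model": self.config.model,
            "temperature": self.config.temperature,
            "top_p": self.config.top_p,
            "messages": [{"role": "user", "content": prompt}],
        }).encode()
        req = urllib.request.Request(
            self.api_url, data=payload,
            headers={"Authorization": f"Bearer {key}",
                     "Content-Type": "application/json"})
        last_err = None
        for _ in range(self.config.max_retries + 1):
            try:
                with urllib.request.urlopen(req, timeout=self.config.timeout) as r:
                    body = json.loads(r.read().decode())
                text = body["choices"][0]["message"]["content"]
                self.n_calls += 1
                self._log(prompt, text)
                return text
            except Exception as exc:  # noqa: BLE001 - retried, then surfaced
                last_err = exc
        raise ProviderError(f"provider failed after retries: {last_err}")

    def _log(self, prompt: str, response: str) -> None:
        if self.transcript_path is None:
            return
        with open(self.transcript_path, "a") as fh:
            fh.write(json.dumps({"prompt": prompt, "response": response}) + "\n")


class FixtureProvider(KnowledgeProvider):
    """Replays a recorded transcript keyed by prompt text (byte-for-byte)."""

    def __init__(self, transcript: dict, config: ProviderConfig = None):
        self.transcript = dict(transcript)
        self.config = config or ProviderConfig()

    @classmethod
    def from_jsonl(cls, path) -> "FixtureProvider":
        transcript = {}
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                transcript[rec["prompt"]] = rec["response"]
        return cls(transcript)

    def complete(self, prompt: str) -> str:
        if prompt not in self.transcript:
            raise ProviderError("prompt not in fixture transcript")
        return self.transcript[prompt]


@dataclass
class MockKnowledgeBase:
    """Deterministic offline stand-in for the live provider.

    Built from a planted ground-truth signed network whose gene set may
    include *latent* genes absent from the observed data.  Pair verdicts
    follow the planted graph: +-1 for a true direct edge; +-2 (sign =
    product of the path signs) for pairs connected only through a latent
    gene by a two-hop path; 0 otherwise.  Each answer is corrupted
    independently with probability ``error_rate`` (verdict replaced by a
    random different value) or withheld with probability
    ``abstention_rate`` (verdict 0).  Answers are a pure function of
    (query, seed): per-query RNG streams are derived by hashing the query
    with the seed, so call order never matters.
    """

    edges: dict                      # (source, target) -> sign (+1/-1)
    genes: tuple                     # observed genes
    latent_genes: tuple = ()
    error_rate: float = 0.0
    abstention_rate: float = 0.0
    seed: int = 0
    indirect: dict = field(default_factory=dict, init=False)

    def __post_init__(self):
        if not 0 <= self.error_rate <= 1 or not 0 <= self.abstention_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if set(self.genes) & set(self.latent_genes):
            raise ValueError("latent genes must be disjoint from observed genes")
        self.edges = {(str(a), str(b)): int(s) for (a, b), s in self.edges.items()}
        # Two-hop paths through a latent mediator induce indirect verdicts.
        self.indirect = {}
        for (a, m), s1 in self.edges.items():
            if m not in self.latent_genes:
                continue
            for (m2, b), s2 in self.edges.items():
                if m2 != m or b in self.latent_genes or a in self.latent_genes:
                    continue
                if (a, b) not in self.edges and a != b:
                    self.indirect[(a, b)] = 2 * s1 * s2

    def _rng(self, *query) -> np.random.Generator:
        digest = hashlib.sha256(
            json.dumps([self.seed, *query], sort_keys=True).encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:4], "big"))

    def true_verdict(self, gene1: str, gene2: str) -> int:
        if (gene1, gene2) in self.edges:
            return self.edges[(gene1, gene2)]
        return self.indirect.get((gene1, gene2), 0)

    def pair_verdict(self, gene1: str, gene2: str) -> int:
        truth = self.true_verdict(gene1, gene2)
        rng = self._rng("pair", gene1, gene2)
        if rng.random() < self.abstention_rate:
            return 0
        if rng.random() < self.error_rate:
            choices = [v for v in ALPHABET if v != truth]
            return int(rng.choice(choices))
        return truth

    def neighbors(self, gene: str) -> list:
        """Observed genes sharing a direct edge with ``gene``, sorted."""
        out = set()
        for (a, b) in self.edges:
            if a == gene and b not in self.latent_genes and b != gene:
                out.add(b)
            if b == gene and a not in self.latent_genes and a != gene:
                out.add(a)
        return sorted(out)

    def upstream_regulators(self, target: str, direction: str = None) -> list:
        """Observed direct regulators of ``target``, optionally by sign."""
        want = {"activation": 1, "inhibition": -1}.get(direction)
        out = []
        for (a, b), s in sorted(self.edges.items()):
            if b == target and a != target and a not in self.latent_genes:
                if want is None or s == want:
                    out.append(a)
        return out

    def to_json(self, path) -> None:
        doc = {
            "edges": [[a, b, s] for (a, b), s in sorted(self.edges.items())],
            "genes": list(self.genes),
            "latent_genes": list(self.latent_genes),
            "error_rate": self.error_rate,
            "abstention_rate": self.abstention_rate,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MockKnowledgeBase":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(edges={(a, b): s for a, b, s in doc["edges"]},
                   genes=tuple(doc["genes"]),
                   latent_genes=tuple(doc["latent_genes"]),
                   error_rate=doc["error_rate"],
                   abstention_rate=doc["abstention_rate"],
                   seed=doc["seed"])


class MockProvider(KnowledgeProvider):
    """Answers pipeline queries from a :class:`MockKnowledgeBase`.

    Talks the same high-level protocol as the live provider (the prompt
    text is parsed back into the structured query it encodes), so it is
    a drop-in replacement anywhere a provider is required.
    """

    def __init__(self, kb: MockKnowledgeBase, config: ProviderConfig = None):
        self.kb = kb
        self.config = config or ProviderConfig()

    # Structured entry points used by the pipeline --------------------

    def interacting_genes(self, seed_genes, n_new: int) -> list:
        pool = []
        for g in sorted(set(seed_genes)):
            for nb in self.kb.neighbors(g):
                if nb not in seed_genes and nb not in pool:
                    pool.append(nb)
        return pool[:n_new]

    def pair_verdict(self, gene1: str, gene2: str) -> int:
        return self.kb.pair_verdict(gene1, gene2)

    def upstream(self, target: str, direction: str, exclude,
                 strict: bool = True) -> str:
        regs = self.kb.upstream_regulators(target, direction if strict else None)
        regs = [r for r in regs if r not in set(exclude)]
        return regs[0] if regs else EMPTY

    # Text protocol (keeps MockProvider usable behind `complete`) -----

    def complete(self, prompt: str) -> str:
        raise NotImplementedError(
            "MockProvider answers structured queries, not raw prompts; "
            "use the suggest_*/classify_* functions")


# ---------------------------------------------------------------------------
# Provider-level operations (work with any provider)
# ---------------------------------------------------------------------------


def suggest_interacting_genes(provider, seed_genes, n_new: int,
                              context: str = "") -> list:
    """Ask for ``n_new`` interaction partners of the seed genes.

    Returns new symbols only (never echoes a seed gene); if the provider
    yields fewer than requested the shortfall is flagged with a warning.
    """
    if not seed_genes:
        raise ValueError("seed_genes must be non-empty")
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if n_new == 0:
        return []
    if isinstance(provider, MockProvider):
        symbols = provider.interacting_genes(seed_genes, n_new)
    else:
        prompt = PROMPT_TEMPLATES["gene_list"].format(
            context=context or provider.config.context,
            genes=", ".join(seed_genes), n_new=n_new)
        symbols = parse_gene_list_response(provider.complete(prompt))
    out = []
    seeds = set(seed_genes)
    for s in symbols:
        if s not in seeds and s not in out:
            out.append(s)
    if len(out) < n_new:
        warnings.warn(f"provider returned {len(out)} new genes, "
                      f"{n_new} requested")
    return out[:n_new]


class VerdictStore(dict):
    """Verdict table keyed by ordered pair; earlier entries are immutable."""

    def record(self, verdict: InteractionVerdict) -> InteractionVerdict:
        key = (verdict.source, verdict.target)
        if key in self:
            return self[key]  # interaction values from previous runs persist
        self[key] = verdict
        return verdict


def classify_pair(provider, gene1: str, gene2: str, context: str = "",
                  store: VerdictStore = None) -> InteractionVerdict:
    """One signed verdict for the ordered pair gene1 -> gene2.

    If a ``store`` is supplied and already holds a verdict for the pair,
    that verdict is returned unchanged — the provider is not re-queried
    and previous values are never overwritten.
    """
    if store is not None and (gene1, gene2) in store:
        return store[(gene1, gene2)]
    if isinstance(provider, MockProvider):
        value = provider.pair_verdict(gene1, gene2)
        verdict = InteractionVerdict(gene1, gene2, value, "mock")
    else:
        prompt = PROMPT_TEMPLATES["pair_interaction"].format(
            context=context or provider.config.context, gene1=gene1, gene2=gene2)
        value = parse_interaction_response(provider.complete(prompt))
        provenance = "fixture" if isinstance(provider, FixtureProvider) else "live"
        verdict = InteractionVerdict(gene1, gene2, value, provenance)
    if store is not None:
        verdict = store.record(verdict)
    return verdict


def suggest_upstream_regulator(provider, target: str, direction: str,
                               exclude, strict: bool = True,
                               context: str = "") -> str:
    """One upstream regulator of ``target`` acting by ``direction``.

    Returns a single standardized symbol or ``EMPTY``.  ``exclude`` lists
    genes already in the network; the target must not be in it.
    """
    if direction not in ("activation", "inhibition"):
        raise ValueError("direction must be 'activation' or 'inhibition'")
    if target in set(exclude):
        raise ValueError("target gene must not be in the exclusion list")
    if isinstance(provider, MockProvider):
        return provider.upstream(target, direction, exclude, strict)
    key = "upstream_strict" if strict else "upstream_relaxed"
    prompt = PROMPT_TEMPLATES[key].format(
        context=context or provider.config.context, target=target,
        direction=direction, exclude=", ".join(sorted(exclude)))
    return parse_symbol_response(provider.complete(prompt))


def consistency_check(ask, repeats: int = 10) -> dict:
    """Re-issue one query ``repeats`` times and summarise agreement.

    ``ask`` is a zero-argument callable performing the query.  Returns
    the answer list, the number of distinct answer (sets), and the modal
    answer.  Per-repeat provider errors are recorded and the remaining
    repeats continue.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    answers, errors = [], []
    for i in range(repeats):
        try:
            answers.append(ask())
        except (ProviderError, ParseError) as exc:
            errors.append((i, str(exc)))
    def freeze(a):
        return tuple(sorted(a)) if isinstance(a, (list, set, tuple)) else a
    frozen = [freeze(a) for a in answers]
    distinct = sorted(set(frozen), key=str)
    modal = max(distinct, key=frozen.count) if frozen else None
    return {"answers": answers, "n_distinct": len(distinct),
            "modal": modal, "errors": errors}


def verdicts_to_csv(verdicts, path) -> None:
    """Persist verdicts as the three-column gene1, gene2, interaction table."""
    import pandas as pd

    rows = [(v.source, v.target, v.value) for v in verdicts]
    pd.DataFrame(rows, columns=["gene1", "gene2", "interaction"]).to_csv(
        path, index=False)


def verdicts_from_csv(path, provenance: str = "fixture") -> list:
    import pandas as pd

    df = pd.read_csv(path)
    if list(df.columns) != ["gene1", "gene2", "interaction"]:
        raise ValueError("verdict CSV must have columns gene1, gene2, interaction")
    return [InteractionVerdict(str(r.gene1), str(r.gene2), int(r.interaction),
                               provenance)
            for r in df.itertuples()]
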