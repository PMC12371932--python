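"""Synthetic lexicons, corpora and labeled vectors with known ground truth.

The generator emulates the shape of the study corpus: per-herb documents of
20-130 discourse units whose section headers name one of 9 plant parts,
medicinal EDUs realising (part, property) events through lexicon surface
forms, and up to 88 property concepts whose co-occurrence is structured into
planted correlation blocks.  Pseudo-tokens ("v03", "n217") are used instead
of Thai text so statistical behaviour is tested separately from unicode
handling.  Every function takes an explicit seed or generator and is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus_io import BinaryVector, Document, EDU
from .lexicon import LexiconEntry, WordSets

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "default_path_coefficients",
    "gen_lexicon",
    "gen_corpus",
    "gen_vectors",
]


def default_path_coefficients() -> dict[tuple[int, int], float]:
    """Planted (part index, block index) -> path coefficient.

    Two parts push block 0 up strongly (+0.8) and one pulls it down (-0.4);
    all other paths are null.  Indices are 0-based.
    """
    return {(1, 0): 0.8, (3, 0): 0.8, (5, 0): -0.4}


@dataclass
class GeneratorSpec:
    """Study-condition knobs for the generator.

    Defaults mirror the emulated corpus: 259 documents of 20-130 EDUs,
    9 plant parts, 88 property concepts, 600 direct binary observations,
    three planted correlation blocks.
    """

    seed: int = 0
    n_docs: int = 259
    edus_per_doc_range: tuple[int, int] = (20, 130)
    n_parts: int = 9
    n_properties: int = 88
    n_blocks: int = 3
    block_size: int = 8
    block_within_prob: float = 0.7
    block_loading: float = 0.9
    path_coefficients: dict[tuple[int, int], float] = field(
        default_factory=default_path_coefficients
    )
    distractor_rate: float = 0.5
    noise_property_rate: float = 0.15
    variants_per_property: tuple[int, int] = (1, 3)
    n_symptom_terms: int = 5
    n_obs: int = 600

    def __post_init__(self) -> None:
        if not (0 <= self.block_within_prob <= 1 and 0 <= self.distractor_rate <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_blocks * self.block_size > self.n_properties:
            raise ValueError("planted blocks exceed the property space")

    @property
    def property_labels(self) -> list[str]:
        return [f"mp{j:02d}" for j in range(self.n_properties)]

    @property
    def part_labels(self) -> list[str]:
        return [f"PP{i+1}" for i in range(self.n_parts)]

    def block_of(self) -> dict[str, int]:
        """Planted block membership (properties outside any block absent)."""
        out = {}
        for b in range(self.n_blocks):
            for j in range(b * self.block_size, (b + 1) * self.block_size):
                out[self.property_labels[j]] = b
        return out


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream comparison."""

    events: list[tuple[str, str, frozenset[str]]] = field(default_factory=list)
    block_of: dict[str, int] = field(default_factory=dict)
    path_coefficients: dict[tuple[int, int], float] = field(default_factory=dict)
    parts: Optional[np.ndarray] = None          # per-observation part index
    latents: Optional[np.ndarray] = None        # n_obs x n_blocks latent scores
    pair_labels: dict[tuple[int, int], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Lexicon generation
# ---------------------------------------------------------------------------

def gen_lexicon(
    spec: GeneratorSpec, rng: Optional[np.random.Generator] = None
) -> tuple[list[LexiconEntry], WordSets]:
    """Build a pseudo-token lexicon plus matching word sets.

    Each property concept receives 1-3 surface variants (solving verb +
    one or two nouns); verbs are shared across concepts.  Symptom-term
    entries exercise the solving-verb-prefix rule.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_verbs = max(6, spec.n_properties // 8)
    verbs = [f"v{k:02d}" for k in range(n_verbs)]
    weak_element = ("vw0", "wnoun")  # a weak-verb compound solving element
    svc = [(v,) for v in verbs] + [weak_element]
    svc_sub = [(v,) for v in verbs[: min(3, n_verbs)]]
    stop_words = {"st0", "st1"}
    symptom_word = "xsym"

    entries: list[LexiconEntry] = []
    noun_counter = 0
    lo, hi = spec.variants_per_property
    for j, label in enumerate(spec.property_labels):
        n_var = int(rng.integers(lo, hi + 1))
        for v in range(n_var):
            verb = verbs[int(rng.integers(0, n_verbs))]
            nouns = []
            for _ in range(int(rng.integers(1, 3))):
                nouns.append(f"n{noun_counter:03d}")
                noun_counter += 1
            seg = [(verb, "V_strong", "solve")] + [(nn, "Noun", "thing") for nn in nouns]
            entries.append(
                LexiconEntry(label, tuple(seg), "property_term", entry_id=f"{label}:{v}")
            )
    for k in range(spec.n_symptom_terms):
        seg = [(f"sn{k:02d}", "Noun", "symptom-noun")]
        if rng.random() < 0.5:
            seg.append((f"sa{k:02d}", "Adj", "symptom-adj"))
        entries.append(
            LexiconEntry(f"sym{k:02d}", tuple(seg), "symptom_term", entry_id=f"sym{k:02d}")
        )

    pp_set = [
        {"label": lab, "tokens": [f"part{i}"]}
        for i, lab in enumerate(spec.part_labels)
    ]
    ws = WordSets(
        svc=svc,
        svc_sub=svc_sub,
        stop_words=stop_words,
        symptom_word=symptom_word,
        wrd_set={"patient", "healthy", "illness", "body", "wound"},
        pp_set=pp_set,
    )
    return entries, ws


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def _surface_of(entry: LexiconEntry) -> list[tuple[str, str]]:
    return [(t, p) for t, p, _ in entry.segmented_expression]


def gen_corpus(
    spec: GeneratorSpec,
    lexicon: list[LexiconEntry],
    ws: WordSets,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Document], GroundTruth]:
    """Generate per-herb documents realising planted (part, property) events.

    Properties are sampled blockwise: a document section for a part first
    picks a block, then includes each block member with
    ``block_within_prob``, so block members co-occur far more often than
    properties of different blocks.  Distractor EDUs carry no solving verb
    and are invisible to the extractor.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    by_label: dict[str, list[LexiconEntry]] = {}
    for e in lexicon:
        if e.source_kind == "property_term":
            by_label.setdefault(e.concept_label, []).append(e)
    block_of = spec.block_of()
    blocks: dict[int, list[str]] = {}
    for label, b in block_of.items():
        blocks.setdefault(b, []).append(label)
    loose = [c for c in spec.property_labels if c not in block_of and c in by_label]

    truth = GroundTruth(block_of=block_of, path_coefficients=dict(spec.path_coefficients))
    docs: list[Document] = []
    lo, hi = spec.edus_per_doc_range
    for d in range(spec.n_docs):
        hname = f"herb{d:03d}"
        target_len = int(rng.integers(lo, hi + 1))
        n_sections = int(rng.integers(1, 4))
        part_idx = rng.choice(spec.n_parts, size=n_sections, replace=False)
        edu_lines: list[tuple[bool, list[tuple[str, str]]]] = []
        for i in part_idx:
            label = spec.part_labels[i]
            token = ws.pp_set[i]["tokens"][0]
            edu_lines.append((True, [(token, "Noun")]))
            b = int(rng.integers(0, spec.n_blocks))
            concepts = [
                c for c in blocks.get(b, []) if rng.random() < spec.block_within_prob
            ]
            if loose and rng.random() < 0.5:
                concepts.append(loose[int(rng.integers(0, len(loose)))])
            concepts = [c for c in concepts if c in by_label]
            if not concepts:
                concepts = [blocks[b][0]] if blocks.get(b) else [loose[0]]
            planted = []
            for c in concepts:
                variants = by_label[c]
                entry = variants[int(rng.integers(0, len(variants)))]
                edu_lines.append((False, _surface_of(entry)))
                planted.append(c)
            truth.events.append((hname, label, frozenset(planted)))
            # distractor EDUs: weak verb + noun, no solving verb
            n_distract = rng.binomial(len(planted) + 2, spec.distractor_rate)
            for _ in range(int(n_distract)):
                edu_lines.append(
                    (False, [("dvrb", "V_weak"), (f"dn{int(rng.integers(0, 50)):02d}", "Noun")])
                )
        while len(edu_lines) < min(target_len, lo):
            edu_lines.append(
                (False, [("dvrb", "V_weak"), (f"dn{int(rng.integers(0, 50)):02d}", "Noun")])
            )
        edu_lines = edu_lines[:hi]
        edus = [
            EDU.from_tokens(i + 1, toks, header=hdr)
            for i, (hdr, toks) in enumerate(edu_lines)
        ]
        docs.append(Document(hname, edus))
    return docs, truth


# ---------------------------------------------------------------------------
# Direct vector generation (for factor-recovery and path-recovery studies)
# ---------------------------------------------------------------------------

def gen_vectors(
    spec: GeneratorSpec, rng: Optional[np.random.Generator] = None
) -> tuple[list[BinaryVector], dict[tuple[int, int], int], GroundTruth]:
    """Emit binary vectors with planted blocks and part -> block path effects.

    Per observation: a plant part is drawn uniformly; each block's latent is
    the planted path coefficient of that part plus standard Gaussian noise;
    a block member's underlying value loads on its block latent
    (``block_loading``) plus independent noise and is thresholded at zero.
    Properties outside all blocks are independent background noise.  Pair
    labels mark (part, property) pairs whose block receives a positive
    planted path from that part.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, m = spec.n_obs, spec.n_properties
    lam = spec.block_loading
    block_of = spec.block_of()
    labels = spec.property_labels
    block_idx = np.array([block_of.get(lab, -1) for lab in labels])

    parts = rng.integers(0, spec.n_parts, size=n)
    beta = np.zeros((spec.n_parts, spec.n_blocks))
    for (i, b), coef in spec.path_coefficients.items():
        beta[i, b] = coef
    latents = beta[parts] + rng.standard_normal((n, spec.n_blocks))

    X = np.zeros((n, m), dtype=np.int8)
    for j in range(m):
        b = block_idx[j]
        if b >= 0:
            underlying = lam * latents[:, b] + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            X[:, j] = (underlying > 0).astype(np.int8)
        else:
            X[:, j] = (rng.random(n) < spec.noise_property_rate).astype(np.int8)

    # the one-hot part invariant requires >= 1 property bit per vector
    empty = np.flatnonzero(X.sum(axis=1) == 0)
    for r in empty:
        X[r, int(rng.integers(0, m))] = 1

    pair_labels: dict[tuple[int, int], int] = {}
    for i in range(spec.n_parts):
        for j in range(m):
            b = block_idx[j]
            pair_labels[(i, j)] = int(b >= 0 and beta[i, b] > 0)

    vectors = []
    for r in range(n):
        pp = np.zeros(spec.n_parts, dtype=np.int8)
        pp[parts[r]] = 1
        vectors.append(
            BinaryVector(
                hname=f"obs{r:04d}",
                ppart=spec.part_labels[parts[r]],
                pp_indicators=pp,
                mp_indicators=X[r],
            )
        )
    truth = GroundTruth(
        block_of=block_of,
        path_coefficients=dict(spec.path_coefficients),
        parts=parts,
        latents=latents,
        pair_labels=pair_labels,
    )
    return vectors, pair_labels, truth
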