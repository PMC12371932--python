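"""Corpus, vector-table and plant-table I/O.

The corpus dialect is plain UTF-8 text, one document per file (or per
``#doc`` block):

    #doc <herb name>
    #sec <token>|<POS> ...
    <token>|<POS> <token>|<POS> ...

Regular lines are elementary discourse units (EDUs) with space-separated
``token|POS`` items; ``#sec`` lines are section-header EDUs that carry a noun
phrase only (typically a plant-part name) and no verb phrase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .lexicon import POS_TAGS, _nfc

__all__ = [
    "EDU",
    "Document",
    "SymbolicVector",
    "BinaryVector",
    "PlantRow",
    "read_corpus",
    "parse_document",
    "write_corpus",
    "write_binary_vectors",
    "read_binary_vectors",
    "write_symbolic_vectors",
    "read_symbolic_vectors",
    "write_plant_table",
    "read_plant_table",
    "dedupe_plant_table",
    "binary_matrix",
]

_VERB_POS = {"V_strong", "V_weak"}


@dataclass(frozen=True)
class EDU:
    """One discourse unit: ordered (token, pos) pairs plus noun-phrase info.

    ``np1_noun``/``np2_noun`` are the nouns of the first and second noun
    phrase (here: the first noun before the first verb and the first noun
    after it); section headers have ``has_vp=False``.
    """

    index: int
    tokens: tuple[tuple[str, str], ...]
    has_vp: bool = True
    np1_noun: Optional[str] = None
    np2_noun: Optional[str] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("EDU index must be >= 1")
        for tok, pos in self.tokens:
            if pos not in POS_TAGS:
                raise ValueError(f"unknown POS {pos!r} on token {tok!r}")

    @classmethod
    def from_tokens(
        cls, index: int, tokens: Sequence[tuple[str, str]], header: bool = False
    ) -> "EDU":
        tokens = tuple((_nfc(t), p) for t, p in tokens)
        if header:
            np1 = tokens[0][0] if tokens else None
            return cls(index, tokens, has_vp=False, np1_noun=np1)
        verb_at = next(
            (i for i, (_, p) in enumerate(tokens) if p in _VERB_POS), None
        )
        np1 = next(
            (t for t, p in tokens[: verb_at if verb_at is not None else len(tokens)]
             if p == "Noun"),
            None,
        )
        np2 = None
        if verb_at is not None:
            np2 = next((t for t, p in tokens[verb_at + 1:] if p == "Noun"), None)
        return cls(index, tokens, has_vp=verb_at is not None, np1_noun=np1, np2_noun=np2)


@dataclass
class Document:
    herb_name: str
    edus: list[EDU]

    def __post_init__(self) -> None:
        if not self.herb_name:
            raise ValueError("herb_name must be non-empty")
        if not self.edus:
            raise ValueError("document must contain at least one EDU")


@dataclass
class SymbolicVector:
    """One (herb, plant-part) record with its matched property concepts."""

    hname: str
    ppart: str
    medp_list: list[str] = field(default_factory=list)


@dataclass
class BinaryVector:
    """One-hot plant-part indicators plus binary property indicators."""

    hname: str
    ppart: str
    pp_indicators: np.ndarray
    mp_indicators: np.ndarray

    def __post_init__(self) -> None:
        self.pp_indicators = np.asarray(self.pp_indicators, dtype=np.int8)
        self.mp_indicators = np.asarray(self.mp_indicators, dtype=np.int8)
        if int(self.pp_indicators.sum()) != 1:
            raise ValueError("exactly one plant-part indicator must be set")
        if int(self.mp_indicators.sum()) < 1:
            raise ValueError("at least one property indicator must be set")


@dataclass(frozen=True)
class PlantRow:
    hname: str
    ppart: str
    medp: str


# ---------------------------------------------------------------------------
# Corpus reading
# ---------------------------------------------------------------------------

def parse_document(text: str, herb_name: str = "", source: str = "<string>") -> Document:
    """Parse one document in the corpus dialect from a string."""
    edus: list[EDU] = []
    idx = 0
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#doc"):
            name = line[4:].strip()
            if name:
                herb_name = name
            continue
        header = False
        if line.startswith("#sec"):
            header = True
            line = line[4:].strip()
        try:
            tokens = []
            for item in line.split():
                tok, _, pos = item.partition("|")
                if not pos:
                    raise ValueError(f"token {item!r} lacks a |POS tag")
                tokens.append((tok, pos))
            idx += 1
            edus.append(EDU.from_tokens(idx, tokens, header=header))
        except ValueError as exc:
            raise ValueError(f"{source}:{ln}: {exc}") from exc
    if not herb_name:
        raise ValueError(f"{source}: no herb name (use '#doc <name>' or a file name)")
    return Document(herb_name=herb_name, edus=edus)


def read_corpus(source: str | Path | Iterable[str | Path]) -> list[Document]:
    """Read documents from a directory of ``*.txt`` files, a manifest file
    (one path per line) or an explicit list of paths.

    The herb name defaults to the file-name stem.  Empty files are skipped
    with a warning entry on stderr-free bookkeeping (the returned list simply
    omits them).
    """
    paths: list[Path]
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.is_dir():
            paths = sorted(p.glob("*.txt"))
        else:  # manifest
            base = p.parent
            paths = []
            for line in p.read_text(encoding="utf-8").splitlines():
                line = line.strip()
                if line and not line.startswith("#"):
                    q = Path(line)
                    paths.append(q if q.is_absolute() else base / q)
    else:
        paths = [Path(x) for x in source]

    docs: list[Document] = []
    for path in paths:
        try:
            text = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise OSError(f"cannot read corpus file {path}: {exc}") from exc
        if not text.strip():
            continue
        docs.append(parse_document(text, herb_name=path.stem, source=str(path)))
    return docs


def write_corpus(docs: Iterable[Document], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for doc in docs:
        lines = [f"#doc {doc.herb_name}"]
        for edu in doc.edus:
            body = " ".join(f"{t}|{p}" for t, p in edu.tokens)
            lines.append(f"#sec {body}" if not edu.has_vp else body)
        path = directory / f"{doc.herb_name}.txt"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Vector tables
# ---------------------------------------------------------------------------

def binary_matrix(vectors: Sequence[BinaryVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack vectors into (pp matrix, mp matrix)."""
    pp = np.vstack([v.pp_indicators for v in vectors])
    mp = np.vstack([v.mp_indicators for v in vectors])
    return pp, mp


def write_binary_vectors(
    vectors: Sequence[BinaryVector], path: str | Path, with_metadata: bool = True
) -> None:
    n_pp = len(vectors[0].pp_indicators) if vectors else 9
    n_mp = len(vectors[0].mp_indicators) if vectors else 0
    cols = [f"pp_{i+1}" for i in range(n_pp)] + [f"mp_{j+1}" for j in range(n_mp)]
    rows = []
    for v in vectors:
        row = list(v.pp_indicators) + list(v.mp_indicators)
        if with_metadata:
            row = [v.hname, v.ppart] + row
        rows.append(row)
    if with_metadata:
        cols = ["hname", "ppart"] + cols
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_binary_vectors(path: str | Path) -> list[BinaryVector]:
    df = pd.read_csv(path)
    pp_cols = [c for c in df.columns if c.startswith("pp_")]
    mp_cols = [c for c in df.columns if c.startswith("mp_")]
    if not pp_cols or not mp_cols:
        raise ValueError(f"{path}: header lacks pp_*/mp_* indicator columns")
    out = []
    for _, row in df.iterrows():
        out.append(
            BinaryVector(
                hname=str(row["hname"]) if "hname" in df.columns else "",
                ppart=str(row["ppart"]) if "ppart" in df.columns else "",
                pp_indicators=row[pp_cols].to_numpy(dtype=np.int8),
                mp_indicators=row[mp_cols].to_numpy(dtype=np.int8),
            )
        )
    return out


def write_symbolic_vectors(vectors: Sequence[SymbolicVector], path: str | Path) -> None:
    df = pd.DataFrame(
        [[v.hname, v.ppart, ";".join(v.medp_list)] for v in vectors],
        columns=["hname", "ppart", "medps"],
    )
    df.to_csv(path, index=False)


def read_symbolic_vectors(path: str | Path) -> list[SymbolicVector]:
    df = pd.read_csv(path, keep_default_na=False)
    if list(df.columns) != ["hname", "ppart", "medps"]:
        raise ValueError(f"{path}: unexpected symbolic-vector header {list(df.columns)}")
    return [
        SymbolicVector(r["hname"], r["ppart"], [m for m in r["medps"].split(";") if m])
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Plant table
# ---------------------------------------------------------------------------

def dedupe_plant_table(rows: Iterable[PlantRow]) -> list[PlantRow]:
    """Set-unique triples, first-occurrence order retained."""
    seen: set[PlantRow] = set()
    out: list[PlantRow] = []
    for row in rows:
        if row not in seen:
            seen.add(row)
            out.append(row)
    return out


def write_plant_table(rows: Iterable[PlantRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [[r.hname, r.ppart, r.medp] for r in rows], columns=["hname", "ppart", "medp"]
    )
    df.to_csv(path, index=False)


def read_plant_table(path: str | Path) -> list[PlantRow]:
    df = pd.read_csv(path, keep_default_na=False)
    if list(df.columns) != ["hname", "ppart", "medp"]:
        raise ValueError(f"{path}: unexpected plant-table header {list(df.columns)}")
    return [PlantRow(r["hname"], r["ppart"], r["medp"]) for _, r in df.iterrows()]
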