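"""Corpus curation: keyword frequency ranking, keywords of interest,
triple enumeration, size-bounded subclass selection and the stratified
60/20/20 split.

The curation pipeline mirrors how the three-slot caption corpus is carved
out of a large radiology collection in which every image carries a free-text
caption and a keyword list: rank all keywords by corpus frequency, keep the
frequent ones that belong to one of the three slot categories (exam type,
body part, identified problem), enumerate every category combination, keep
the combinations backed by a moderate number of images, and split the
surviving images into train/validation/test.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "CaptionTriple",
    "KeywordIndex",
    "CategoryMap",
    "ManifestRecord",
    "CorpusManifest",
    "normalize_keyword",
    "compute_keyword_frequencies",
    "select_keywords_of_interest",
    "enumerate_triples",
    "assign_triple",
    "select_subclasses",
    "split_corpus",
    "curate",
    "read_manifest_csv",
    "write_manifest_csv",
    "read_roco_pair",
]

SPLITS = ("train", "val", "test", "unassigned")

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


class CaptionTriple(NamedTuple):
    """Ordered (exam_type, body_part, problem) word triple."""

    exam_type: str
    body_part: str
    problem: str

    def words(self) -> list[str]:
        return [self.exam_type, self.body_part, self.problem]


def normalize_keyword(word: str) -> str:
    """Lowercase and strip punctuation; tokens are otherwise opaque."""
    return word.lower().translate(_PUNCT_TABLE).strip()


@dataclass(frozen=True)
class KeywordIndex:
    """Keyword -> record count, ordered descending by count, ties lexicographic."""

    entries: tuple  # of (keyword, count)

    def __post_init__(self):
        for _, c in self.entries:
            if c < 1:
                raise ValidationError("keyword frequencies must be >= 1")

    def frequency(self, keyword: str) -> int:
        return dict(self.entries).get(keyword, 0)

    def keywords(self) -> list[str]:
        return [k for k, _ in self.entries]

    def __len__(self):
        return len(self.entries)


@dataclass(frozen=True)
class CategoryMap:
    """Ordered keyword lists per slot category; pairwise disjoint."""

    exam_type: tuple
    body_part: tuple
    problem: tuple

    def __post_init__(self):
        e, b, p = set(self.exam_type), set(self.body_part), set(self.problem)
        if e & b or e & p or b & p:
            raise ValidationError("category keyword lists must be pairwise disjoint")

    def category_of(self, keyword: str) -> str | None:
        if keyword in self.exam_type:
            return "exam_type"
        if keyword in self.body_part:
            return "body_part"
        if keyword in self.problem:
            return "problem"
        return None


@dataclass(frozen=True)
class ManifestRecord:
    image_id: str
    image_path: str
    caption: tuple
    keywords: frozenset
    triple: CaptionTriple | None = None
    split: str = "unassigned"


@dataclass
class CorpusManifest:
    records: list = field(default_factory=list)

    def __post_init__(self):
        ids = [r.image_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError("image ids must be unique")

    def __len__(self):
        return len(self.records)

    def subset(self, split: str) -> list:
        return [r for r in self.records if r.split == split]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.image_id,
                    "path": r.image_path,
                    "caption": " ".join(r.caption),
                    "keywords": ";".join(sorted(r.keywords)),
                    "exam_type": r.triple.exam_type if r.triple else "",
                    "body_part": r.triple.body_part if r.triple else "",
                    "problem": r.triple.problem if r.triple else "",
                    "split": r.split,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operations


def compute_keyword_frequencies(records: Iterable[Iterable[str]]) -> KeywordIndex:
    """Count, per keyword, the number of records containing it.

    Keywords are case-normalised before counting; the index is ordered by
    descending count with lexicographic tie-breaking.
    """
    counts: Counter = Counter()
    for rec in records:
        counts.update({normalize_keyword(k) for k in rec} - {""})
    entries = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return KeywordIndex(tuple(entries))


def select_keywords_of_interest(
    index: KeywordIndex, threshold: int, template: CategoryMap
) -> CategoryMap:
    """Keep template keywords whose corpus frequency strictly exceeds
    ``threshold``; keywords outside the template are discarded."""
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")

    def kept(words):
        return tuple(w for w in words if index.frequency(w) > threshold)

    return CategoryMap(
        kept(template.exam_type), kept(template.body_part), kept(template.problem)
    )


def enumerate_triples(categories: CategoryMap) -> list[CaptionTriple]:
    """Cartesian product exam_type x body_part x problem, in category order."""
    return [
        CaptionTriple(e, b, p)
        for e in categories.exam_type
        for b in categories.body_part
        for p in categories.problem
    ]


def assign_triple(keywords: Iterable[str], categories: CategoryMap) -> CaptionTriple | None:
    """Map a record's keyword set to its caption triple.

    A triple is assigned iff the keywords contain exactly one keyword from
    each category; records with zero or several matches in any category are
    ambiguous and excluded (returns None).
    """
    normed = {normalize_keyword(k) for k in keywords} - {""}
    picks = {}
    for cat in ("exam_type", "body_part", "problem"):
        hits = [w for w in getattr(categories, cat) if w in normed]
        if len(hits) != 1:
            return None
        picks[cat] = hits[0]
    return CaptionTriple(picks["exam_type"], picks["body_part"], picks["problem"])


def select_subclasses(triple_to_images: dict, min_size: int, max_size: int) -> dict:
    """Keep triples whose image count lies in [min_size, max_size] inclusive."""
    if min_size > max_size:
        raise ConfigurationError("min_size must be <= max_size")
    return {
        t: imgs
        for t, imgs in triple_to_images.items()
        if min_size <= len(imgs) <= max_size
    }


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_corpus(
    manifest: CorpusManifest,
    fractions: tuple = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> CorpusManifest:
    """Random, seeded 60/20/20 partition into train/val/test.

    Validation and test sizes are the half-up-rounded fractions of n; the
    training set takes the remainder (e.g. n=1419 -> 851/284/284). The
    assignment is a pure function of (manifest order, fractions, seed).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    if len(manifest) == 0:
        raise ValidationError("cannot split an empty manifest")
    n = len(manifest)
    n_val = _round_half_up(fractions[1] * n)
    n_test = _round_half_up(fractions[2] * n)
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ConfigurationError("fractions leave no room for a training set")
    order = np.random.default_rng(seed).permutation(n)
    assignment = {}
    for pos, idx in enumerate(order):
        if pos < n_train:
            assignment[idx] = "train"
        elif pos < n_train + n_val:
            assignment[idx] = "val"
        else:
            assignment[idx] = "test"
    records = [replace(r, split=assignment[i]) for i, r in enumerate(manifest.records)]
    return CorpusManifest(records)


def curate(
    manifest: CorpusManifest,
    template: CategoryMap,
    threshold: int = 500,
    min_size: int = 10,
    max_size: int = 80,
    fractions: tuple = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> CorpusManifest:
    """Full curation pipeline: frequencies -> keywords of interest -> triple
    assignment -> subclass size filter -> split. Returns a manifest holding
    only the retained records, each with a triple and a split."""
    index = compute_keyword_frequencies(r.keywords for r in manifest.records)
    categories = select_keywords_of_interest(index, threshold, template)
    groups: dict = {}
    assigned: dict = {}
    for r in manifest.records:
        t = assign_triple(r.keywords, categories)
        if t is not None:
            assigned[r.image_id] = t
            groups.setdefault(t, set()).add(r.image_id)
    kept_triples = select_subclasses(groups, min_size, max_size)
    kept_ids = set().union(*kept_triples.values()) if kept_triples else set()
    records = [
        replace(r, triple=assigned[r.image_id])
        for r in manifest.records
        if r.image_id in kept_ids
    ]
    if not records:
        return CorpusManifest([])
    return split_corpus(CorpusManifest(records), fractions, seed)


# ---------------------------------------------------------------------------
# I/O


def read_manifest_csv(path) -> CorpusManifest:
    """Read a manifest CSV (columns id,path,caption,keywords[,triple,split])."""
    df = pd.read_csv(path, dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        triple = None
        if row.get("exam_type", ""):
            triple = CaptionTriple(row["exam_type"], row["body_part"], row["problem"])
        records.append(
            ManifestRecord(
                image_id=row["id"],
                image_path=row["path"],
                caption=tuple(row["caption"].split()),
                keywords=frozenset(k for k in row["keywords"].split(";") if k),
                triple=triple,
                split=row.get("split", "") or "unassigned",
            )
        )
    return CorpusManifest(records)


def write_manifest_csv(manifest: CorpusManifest, path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def read_roco_pair(captions_path, keywords_path, image_dir="images") -> CorpusManifest:
    """Read the native per-split text files of a ROCO-style corpus.

    Both files are tab-separated: ``<image id>\\t<caption text>`` and
    ``<image id>\\t<space-separated keyword list>``. Only ids present in
    both files are kept; image paths are ``<image_dir>/<id>.jpg``.
    """

    def read_tsv(p):
        out = {}
        for line in Path(p).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t", 1)
            out[parts[0].strip()] = parts[1].strip() if len(parts) > 1 else ""
        return out

    caps, keys = read_tsv(captions_path), read_tsv(keywords_path)
    records = [
        ManifestRecord(
            image_id=i,
            image_path=str(Path(image_dir) / f"{i}.jpg"),
            caption=tuple(caps[i].lower().split()),
            keywords=frozenset(normalize_keyword(k) for k in keys[i].split()) - frozenset({""}),
        )
        for i in sorted(set(caps) & set(keys))
    ]
    return CorpusManifest(records)
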