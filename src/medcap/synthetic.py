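"""Synthetic ROCO-style corpora whose images encode their own caption.

Each generated image deterministically renders its (exam type, body part,
problem) triple through three independent visual factors:

* exam type  -> background texture (stripes, checks, rings, ...),
* body part  -> centred foreground shape (disc, box, triangle, ...),
* problem    -> small marker glyph in the upper-left quadrant.

Independent factors make each caption slot separately recoverable, so a
partially trained model produces non-trivial slot confusion structure
rather than all-or-nothing captions. Additive Gaussian pixel noise (sd in
0-255 intensity units) controls task difficulty. Output is byte-identical
for identical specs: the per-image noise stream is derived from the spec
seed and the image index only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .corpus import CaptionTriple, CorpusManifest, ManifestRecord, write_manifest_csv
from .errors import ValidationError

__all__ = ["SynthSpec", "DEFAULT_TRIPLES", "generate_corpus", "render_base_image"]

#: three fully distinct triples — the default study condition
DEFAULT_TRIPLES = (
    CaptionTriple("ct", "chest", "tumor"),
    CaptionTriple("radiograph", "bone", "fracture"),
    CaptionTriple("mri", "brain", "cyst"),
)


@dataclass(frozen=True)
class SynthSpec:
    """Conditions for one synthetic corpus."""

    triples: tuple = DEFAULT_TRIPLES
    n_per_triple: int = 60
    image_size: tuple = (64, 64)
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_triple < 1:
            raise ValidationError("n_per_triple must be >= 1")
        if min(self.image_size) < 16:
            raise ValidationError("image sides must be >= 16 pixels")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        object.__setattr__(self, "triples", tuple(CaptionTriple(*t) for t in self.triples))


def _slot_variant(word: str, vocabulary: tuple) -> int:
    """Stable variant index for a slot word within a spec's vocabulary."""
    return sorted(vocabulary).index(word)


def _texture(idx: int, h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    period = 6 + 2 * (idx // 4)
    kind = idx % 4
    if kind == 0:  # horizontal stripes
        img = ((yy // period) % 2) * 60.0 + 40.0
    elif kind == 1:  # vertical stripes
        img = ((xx // period) % 2) * 60.0 + 40.0
    elif kind == 2:  # checkerboard
        img = (((yy // period) + (xx // period)) % 2) * 60.0 + 40.0
    else:  # concentric rings
        r = np.hypot(yy - h / 2, xx - w / 2)
        img = ((r // period) % 2) * 60.0 + 40.0
    return img


def _draw_shape(draw: ImageDraw.ImageDraw, idx: int, h: int, w: int) -> None:
    cy, cx, r = h // 2, w // 2, min(h, w) // 4
    box = (cx - r, cy - r, cx + r, cy + r)
    fill = 200
    kind = idx % 4
    if kind == 0:
        draw.ellipse(box, fill=fill)
    elif kind == 1:
        draw.rectangle(box, fill=fill)
    elif kind == 2:
        draw.polygon([(cx, cy - r), (cx - r, cy + r), (cx + r, cy + r)], fill=fill)
    else:
        t = max(2, r // 2)
        draw.rectangle((cx - r, cy - t, cx + r, cy + t), fill=fill)
        draw.rectangle((cx - t, cy - r, cx + t, cy + r), fill=fill)


def _draw_glyph(draw: ImageDraw.ImageDraw, idx: int, h: int, w: int) -> None:
    g = max(4, min(h, w) // 8)
    ox, oy = w // 8, h // 8
    kind = idx % 4
    if kind == 0:
        draw.ellipse((ox, oy, ox + g, oy + g), fill=255)
    elif kind == 1:
        draw.rectangle((ox, oy, ox + g, oy + g), fill=255)
    elif kind == 2:
        draw.line((ox, oy, ox + g, oy + g), fill=255, width=2)
        draw.line((ox, oy + g, ox + g, oy), fill=255, width=2)
    else:
        draw.ellipse((ox, oy, ox + g, oy + g), outline=255, width=2)


def render_base_image(triple: CaptionTriple, spec: SynthSpec) -> np.ndarray:
    """Noiseless grayscale rendering of a triple, float array in [0, 255]."""
    h, w = spec.image_size
    exams = tuple(t.exam_type for t in spec.triples)
    bodies = tuple(t.body_part for t in spec.triples)
    problems = tuple(t.problem for t in spec.triples)
    base = _texture(_slot_variant(triple.exam_type, exams), h, w)
    img = Image.fromarray(base.astype(np.uint8), mode="L")
    draw = ImageDraw.Draw(img)
    _draw_shape(draw, _slot_variant(triple.body_part, bodies), h, w)
    _draw_glyph(draw, _slot_variant(triple.problem, problems), h, w)
    return np.asarray(img, dtype=np.float64)


def generate_corpus(spec: SynthSpec, out_dir) -> CorpusManifest:
    """Write ``|triples| * n_per_triple`` PNG images plus a manifest CSV.

    The triple serves as both caption and keyword list. Image ids are
    ``syn00000`` onward in (triple, replicate) order.
    """
    out = Path(out_dir)
    img_dir = out / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    records = []
    i = 0
    for triple in spec.triples:
        base = render_base_image(triple, spec)
        for _ in range(spec.n_per_triple):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, i]))
            pixels = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
            arr = np.clip(pixels, 0, 255).astype(np.uint8)
            image_id = f"syn{i:05d}"
            path = img_dir / f"{image_id}.png"
            Image.fromarray(arr, mode="L").save(path, format="PNG")
            records.append(
                ManifestRecord(
                    image_id=image_id,
                    image_path=str(path),
                    caption=tuple(triple.words()),
                    keywords=frozenset(triple.words()),
                    triple=triple,
                )
            )
            i += 1
    manifest = CorpusManifest(records)
    write_manifest_csv(manifest, out / "manifest.csv")
    return manifest
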