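"""End-to-end wiring: corpus directory -> features -> trained caption model
-> slot-wise evaluation. Used by the CLI and by the experiment grid."""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np

from . import nn
from .corpus import CorpusManifest, read_manifest_csv, split_corpus
from .errors import ConfigurationError, ValidationError
from .features import (AugmentSpec, BackboneSpec, FeatureBundle, build_backbone,
                       extract_features, images_as_bundle)
from .metrics import SLOTS, bleu1, build_slot_confusion, token_accuracy
from .training import TrainConfig, train
from .transcoder import (CaptionModel, TranscoderConfig, build_vocabulary,
                         encode_targets, generate_caption)

__all__ = ["load_corpus", "build_caption_model", "EndToEndModel",
           "train_on_corpus", "evaluate_model", "run_experiment"]


def load_corpus(corpus_dir, seed: int = 0) -> CorpusManifest:
    """Read ``<corpus_dir>/manifest.csv`` (curated if available) and ensure
    every record has a split (splitting with ``seed`` if none assigned)."""
    corpus_dir = Path(corpus_dir)
    for name in ("curated.csv", "manifest.csv"):
        path = corpus_dir / name
        if path.exists():
            manifest = read_manifest_csv(path)
            break
    else:
        raise ValidationError(f"no manifest found in {corpus_dir}")
    if any(r.triple is None for r in manifest.records):
        raise ValidationError("corpus manifest must carry caption triples; run curation first")
    if all(r.split == "unassigned" for r in manifest.records):
        manifest = split_corpus(manifest, seed=seed)
    return manifest


def build_caption_model(vocabulary, feature_dim: int, embed_dim: int = 64,
                        n_heads: int = 2, ff_dim: int = 128, max_len: int = 8,
                        seed: int = 0) -> CaptionModel:
    config = TranscoderConfig(
        vocab_size=len(vocabulary), feature_dim=feature_dim, embed_dim=embed_dim,
        n_heads=n_heads, ff_dim=ff_dim, max_len=max_len, seed=seed,
    )
    return CaptionModel(config, vocabulary)


class EndToEndModel(nn.Module):
    """Backbone + transcoder trained jointly (the fine-tuning switch).

    Consumes a pixel bundle of shape (B, H*W, 3) — see
    :func:`medcap.features.images_as_bundle` — reshapes it back into an
    image grid, runs the trainable backbone, then the caption model.
    """

    def __init__(self, backbone, caption_model: CaptionModel, input_size):
        super().__init__()
        self.backbone = backbone
        self.caption = caption_model
        self.input_size = tuple(input_size)

    @property
    def vocabulary(self):
        return self.caption.vocabulary

    @property
    def config(self):
        return self.caption.config

    def _features(self, pixel_tokens):
        x = np.asarray(pixel_tokens)
        h, w = self.input_size
        return self.backbone(x.reshape(x.shape[0], h, w, x.shape[-1]))

    def logits(self, pixel_tokens, tokens):
        return self.caption.decoder.logits(tokens, self.caption.encoder(self._features(pixel_tokens)))


def _bundle_subset(bundle: FeatureBundle, ids) -> FeatureBundle:
    index = {i: k for k, i in enumerate(bundle.image_ids)}
    sel = [index[i] for i in ids]
    return FeatureBundle(list(ids), bundle.features[sel])


def train_on_corpus(corpus_dir, backbone="tiny_cnn", optimizer="adam", tl=False,
                    tr=False, ia=False, config: TrainConfig | None = None,
                    embed_dim: int = 64, n_heads: int = 2, ff_dim: int = 128,
                    max_len: int = 8, seed: int = 0):
    """Train a caption model on a curated corpus directory.

    Returns ``(model, history, parts)`` where parts maps each split to its
    (manifest records, feature bundle, reference triples).
    """
    config = config or TrainConfig(optimizer=optimizer, seed=seed)
    manifest = load_corpus(corpus_dir, seed=seed)
    spec = BackboneSpec(backbone, pretrained=tl, trainable=tr)
    aug = AugmentSpec(seed=seed) if ia else None

    vocab = build_vocabulary([r.triple.words() for r in manifest.records])

    def part(split, augment_spec, net=None):
        records = manifest.subset(split)
        sub = CorpusManifest(records)
        if tr:
            bundle = images_as_bundle(sub, spec.input_size, augment_spec)
        else:
            bundle = extract_features(sub, spec, augment_spec, model=net)
        triples = [r.triple for r in records]
        return records, bundle, triples

    # frozen backbones use a fixed initialization so that a checkpoint can be
    # re-paired with its feature extractor later (caption generation, CLI)
    net = None if tr else build_backbone(spec, seed=0)
    parts = {
        "train": part("train", aug, net),
        "val": part("val", None, net),
        "test": part("test", None, net),
    }
    if tr:
        inner = build_caption_model(
            vocab, feature_dim=build_backbone(spec, seed=seed).feature_dim,
            embed_dim=embed_dim, n_heads=n_heads, ff_dim=ff_dim,
            max_len=max_len, seed=seed,
        )
        model = EndToEndModel(build_backbone(spec, seed=seed), inner, spec.input_size)
    else:
        feature_dim = parts["train"][1].features.shape[-1]
        model = build_caption_model(vocab, feature_dim, embed_dim, n_heads,
                                    ff_dim, max_len, seed)

    targets = {k: encode_targets(vocab, [t.words() for t in v[2]], max_len)
               for k, v in parts.items()}
    model, history = train(
        model, parts["train"][1], targets["train"], config,
        val_bundle=parts["val"][1], val_targets=targets["val"],
    )
    return model, history, parts


def evaluate_model(model, bundle: FeatureBundle, true_triples, max_len: int | None = None):
    """Greedy-decode every image and score the captions slot-wise.

    Returns predictions plus token accuracy, BLEU-1 and the three slot
    confusion matrices. Scoring pads every predicted caption to three slots
    with an out-of-vocabulary filler, so short or empty outputs count as
    errors in all three scores rather than shrinking the denominator.
    """
    caption_model = model.caption if isinstance(model, EndToEndModel) else model
    feats = bundle.features
    if isinstance(model, EndToEndModel):
        feats = model._features(feats).data
    preds = [generate_caption(feats[i], caption_model, max_len) for i in range(feats.shape[0])]
    refs = [t.words() for t in true_triples]
    filled = [p[:3] + ["<none>"] * (3 - min(len(p), 3)) for p in preds]
    confusions = {s: build_slot_confusion(filled, refs, s) for s in SLOTS}
    return {
        "predictions": preds,
        "token_accuracy": token_accuracy(filled, refs),
        "bleu1": bleu1(filled, refs),
        "confusions": confusions,
    }


def run_experiment(corpus_dir, backbone="tiny_cnn", optimizer="adam", tl=False,
                   tr=False, ia=False, config: TrainConfig | None = None,
                   **model_kw) -> dict:
    """One grid cell: train, then time and score generation on the test split."""
    t0 = time.perf_counter()
    model, history, parts = train_on_corpus(
        corpus_dir, backbone=backbone, optimizer=optimizer, tl=tl, tr=tr, ia=ia,
        config=config, **model_kw,
    )
    train_time = time.perf_counter() - t0
    best = int(np.argmin(history["val_loss"]))
    t1 = time.perf_counter()
    test_eval = evaluate_model(model, parts["test"][1], parts["test"][2])
    test_time = time.perf_counter() - t1
    return {
        "val_loss": history["val_loss"][best],
        "val_acc": history["val_acc"][best],
        "epochs": history["epochs"],
        "train_time_s": train_time,
        "test_time_s": test_time,
        "test_token_accuracy": test_eval["token_accuracy"],
        "test_bleu1": test_eval["bleu1"],
        "model": model,
        "history": history,
    }
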