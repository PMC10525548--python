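"""Image preprocessing, seeded augmentation and CNN feature extraction.

A backbone turns a preprocessed image into a fixed-shape sequence of
feature tokens (the final spatial grid flattened to n_tokens positions of
feature_dim channels) for the attention encoder. The registry carries the
classical transfer-learning backbones by name; those require a locally
provisioned weight archive and are never exercised in tests. ``tiny_cnn``,
a three-block convolutional network of a few thousand parameters, is fully
executable and trainable here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from . import nn
from ._tensor import Tensor
from .errors import ConfigurationError, ValidationError

__all__ = [
    "BackboneSpec",
    "AugmentSpec",
    "FeatureBundle",
    "BACKBONES",
    "TinyCNN",
    "build_backbone",
    "preprocess",
    "augment",
    "extract_features",
    "images_as_bundle",
]

#: backbone menu: name -> (input side, requires provisioned weights)
BACKBONES = {
    "tiny_cnn": (32, False),
    "mobilenetv2": (224, True),
    "densenet201": (224, True),
    "resnet152v2": (224, True),
    "nasnetlarge": (331, True),
    "vgg19": (224, True),
    "xception": (299, True),
    "inceptionv3": (299, True),
    "inceptionresnetv2": (299, True),
}


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "tiny_cnn"
    pretrained: bool = False  # TL
    trainable: bool = False  # TR
    input_size: tuple | None = None

    def __post_init__(self):
        if self.name not in BACKBONES:
            raise ConfigurationError(
                f"unknown backbone {self.name!r}; choose from {sorted(BACKBONES)}"
            )
        if self.name == "tiny_cnn" and self.pretrained:
            raise ConfigurationError("tiny_cnn has no pretrained weights")
        if self.input_size is None:
            side = BACKBONES[self.name][0]
            object.__setattr__(self, "input_size", (side, side))


@dataclass(frozen=True)
class AugmentSpec:
    """Seeded rotation / zoom / mirror augmentation (IA)."""

    enabled: bool = True
    max_rotation: float = 15.0  # degrees
    max_zoom: float = 0.1  # fraction
    mirror: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.max_rotation < 0:
            raise ValidationError("max_rotation must be >= 0")
        if not (0 <= self.max_zoom < 1):
            raise ValidationError("max_zoom must lie in [0, 1)")


@dataclass
class FeatureBundle:
    """Per-image feature sequences, first axis aligned with image_ids."""

    image_ids: list
    features: np.ndarray  # (n_images, n_tokens, feature_dim)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 3 or self.features.shape[0] != len(self.image_ids):
            raise ValidationError("features must be (n_images, n_tokens, feature_dim)")
        if not np.isfinite(self.features).all():
            raise ValidationError("features must be finite")

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("ids", data=np.array(self.image_ids, dtype="S"))
            fh.create_dataset("features", data=self.features)

    @classmethod
    def load(cls, path) -> "FeatureBundle":
        with h5py.File(path, "r") as fh:
            ids = [s.decode() for s in fh["ids"][()]]
            return cls(ids, fh["features"][()])


# ---------------------------------------------------------------------------


def preprocess(image, input_size) -> np.ndarray:
    """Decode/resize an image to (H, W, 3) float64 in [0, 1].

    Accepts a path, a PIL image, or a numpy array (grayscale or RGB, uint8
    0-255 or float already in [0, 1]). Idempotent on conforming input.
    """
    if isinstance(image, (str, Path)):
        try:
            image = Image.open(image)
        except OSError as exc:
            raise IOError(f"cannot decode image {image}: {exc}") from exc
    if isinstance(image, Image.Image):
        image = np.asarray(image.convert("L"), dtype=np.float64) / 255.0
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = np.repeat(arr[..., None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise ValidationError("expected a 2-D image or (H, W, 1|3) array")
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.max() > 1.0 + 1e-9:
        arr = arr / 255.0
    h, w = input_size
    if arr.shape[:2] != (h, w):
        im = Image.fromarray(np.clip(arr * 255.0, 0, 255).astype(np.uint8), mode="RGB")
        arr = np.asarray(im.resize((w, h), Image.BILINEAR), dtype=np.float64) / 255.0
    return arr


def augment(image: np.ndarray, spec: AugmentSpec, draw_seed: int) -> np.ndarray:
    """One seeded random draw of rotation, zoom and mirror.

    The draw is a pure function of (spec, draw_seed): rotation uniform in
    [-max_rotation, +max_rotation] degrees, zoom factor uniform in
    [1-max_zoom, 1+max_zoom] about the centre, mirror with probability 1/2.
    """
    if not spec.enabled:
        return image
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, draw_seed]))
    angle = rng.uniform(-spec.max_rotation, spec.max_rotation)
    zoom = rng.uniform(1.0 - spec.max_zoom, 1.0 + spec.max_zoom)
    flip = spec.mirror and rng.random() < 0.5

    arr = np.asarray(image, dtype=np.float64)
    h, w = arr.shape[:2]
    im = Image.fromarray(np.clip(arr * 255.0, 0, 255).astype(np.uint8), mode="RGB")
    if flip:
        im = im.transpose(Image.FLIP_LEFT_RIGHT)
    if angle != 0.0:
        im = im.rotate(angle, resample=Image.BILINEAR)
    if zoom != 1.0:
        zh, zw = max(1, round(h * zoom)), max(1, round(w * zoom))
        im = im.resize((zw, zh), Image.BILINEAR)
        if zoom >= 1.0:  # centre crop back
            top, left = (zh - h) // 2, (zw - w) // 2
            im = im.crop((left, top, left + w, top + h))
        else:  # centre pad back
            canvas = Image.new("RGB", (w, h))
            canvas.paste(im, ((w - zw) // 2, (h - zh) // 2))
            im = canvas
    return np.asarray(im, dtype=np.float64) / 255.0


class TinyCNN(nn.Module):
    """Three conv(3x3)+ReLU+avgpool blocks; final 4x4 grid -> 16 tokens."""

    channels = (8, 16, 32)
    input_side = 32

    def __init__(self, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2d(3, self.channels[0], rng)
        self.conv2 = nn.Conv2d(self.channels[0], self.channels[1], rng)
        self.conv3 = nn.Conv2d(self.channels[1], self.channels[2], rng)

    @property
    def n_tokens(self) -> int:
        return (self.input_side // 8) ** 2

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]

    def __call__(self, images) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(images)
        for conv in (self.conv1, self.conv2, self.conv3):
            x = nn.avg_pool2(conv(x).relu())
        B = x.shape[0]
        return x.reshape(B, self.n_tokens, self.feature_dim)


def build_backbone(spec: BackboneSpec, seed: int = 0, weights_path=None) -> TinyCNN:
    """Instantiate an executable backbone.

    Only ``tiny_cnn`` runs without provisioned weights. For the classical
    backbones a locally downloaded weight archive must be supplied; none is
    fetched here.
    """
    if spec.name == "tiny_cnn":
        return TinyCNN(seed=seed)
    if weights_path is None:
        raise ConfigurationError(
            f"backbone {spec.name!r} requires pretrained weights; download the "
            "weight archive on a connected machine and pass weights_path= "
            "(offline provisioning)"
        )
    raise ConfigurationError(
        f"no loader for {spec.name!r} weight archives is bundled; use tiny_cnn "
        "or register a custom backbone callable"
    )


def _load_images(manifest, input_size, augment_spec=None):
    imgs = []
    for i, rec in enumerate(manifest.records):
        arr = preprocess(rec.image_path, input_size)
        if augment_spec is not None and augment_spec.enabled:
            arr = augment(arr, augment_spec, draw_seed=i)
        imgs.append(arr)
    return np.stack(imgs) if imgs else np.zeros((0,) + tuple(input_size) + (3,))


def extract_features(manifest, backbone, augment_spec=None, model=None) -> FeatureBundle:
    """Run a backbone over every image of a manifest.

    ``backbone`` is a BackboneSpec (``model`` may carry an already-built,
    possibly fine-tuned network; otherwise one is built fresh). With
    ``trainable=False`` the backbone is a frozen pure function: identical
    inputs give identical features.
    """
    spec = backbone if isinstance(backbone, BackboneSpec) else BackboneSpec(backbone)
    net = model if model is not None else build_backbone(spec)
    images = _load_images(manifest, spec.input_size, augment_spec)
    feats = net(images).data
    return FeatureBundle([r.image_id for r in manifest.records], feats)


def images_as_bundle(manifest, input_size, augment_spec=None) -> FeatureBundle:
    """Preprocessed raw pixels viewed as a (H*W, 3) token sequence.

    Used for end-to-end training where the backbone itself is fine-tuned
    inside the model: the 'features' are the pixels, and the model's first
    stage reshapes them back into an image grid.
    """
    images = _load_images(manifest, input_size, augment_spec)
    n, h, w, c = images.shape
    return FeatureBundle([r.image_id for r in manifest.records], images.reshape(n, h * w, c))
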