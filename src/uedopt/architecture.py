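"""Convolutional architecture arithmetic for the LeNet-variant objective.

The optimized network classifies 50x50x3 histopathology patches as
benign or malignant:

    input -> conv1(A filters=B stride=C pad=D) -> ReLU -> maxpool 2x2/2
          -> conv2(E filters=F stride=G pad=H) -> ReLU -> maxpool 2x2/2
          -> conv3(1x1, 120 filters) -> FC 84 -> FC 2

A convolutional layer maps a spatial size w to
``floor((w - k + 2p)/s) + 1`` and "same" padding for odd kernels is
``(k - 1)/2``.  Pooling uses the same formula with k=s=2, p=0, i.e.
``floor(w/2)``.  A factor combination is feasible iff every propagated
spatial size stays a positive integer; feasibility over the whole
discrete factor grid is enumerated deterministically.

Real training on the image dataset is an optional plugin behind
:func:`train_evaluate`; everything else here is pure arithmetic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .allocation import FactorSpec, default_factors
from .exceptions import (
    DatasetUnavailableError,
    InfeasibleArchitectureError,
    ValidationError,
)

__all__ = [
    "ConvLayerSpec",
    "LayerShape",
    "ArchitectureSpec",
    "DatasetManifest",
    "zero_padding",
    "conv_output_size",
    "relu",
    "build_architecture",
    "is_feasible",
    "grid_feasibility",
    "breakhis_manifest",
    "split_counts",
    "train_evaluate",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """Convolution parameters: k x k kernel, filter count, stride, padding."""

    kernel_size: int
    filters: int
    stride: int
    padding: int

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1 or self.padding < 0:
            raise ValidationError("need kernel_size >= 1, stride >= 1, padding >= 0")
        if self.filters < 1:
            raise ValidationError("need at least one filter")


@dataclass(frozen=True)
class LayerShape:
    name: str
    height: int
    width: int
    channels: int


@dataclass(frozen=True)
class ArchitectureSpec:
    """A concrete layer stack with propagated per-layer output shapes."""

    input_size: tuple[int, int, int]
    conv1: ConvLayerSpec
    conv2: ConvLayerSpec
    conv3: ConvLayerSpec
    fc_sizes: tuple[int, ...]
    shapes: tuple[LayerShape, ...]

    @property
    def computed_shapes(self) -> dict[str, tuple[int, int, int]]:
        return {s.name: (s.height, s.width, s.channels) for s in self.shapes}

    def to_dict(self) -> dict:
        return {
            "input_size": list(self.input_size),
            "layers": [
                {
                    "layer": name,
                    "kernel": spec.kernel_size,
                    "stride": spec.stride,
                    "padding": spec.padding,
                    "filters": spec.filters,
                }
                for name, spec in (
                    ("conv1", self.conv1),
                    ("conv2", self.conv2),
                    ("conv3", self.conv3),
                )
            ],
            "fully_connected": list(self.fc_sizes),
            "computed_shapes": {
                s.name: [s.height, s.width, s.channels] for s in self.shapes
            },
        }


def zero_padding(kernel_size: int) -> int:
    """Padding that preserves spatial size at stride 1: (k - 1) / 2, odd k only."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValidationError("same-padding requires an odd kernel size >= 1")
    return (kernel_size - 1) // 2


def conv_output_size(input_size: int, kernel_size: int, padding: int, stride: int) -> int:
    """Spatial output size of a convolution: floor((w - k + 2p)/s) + 1."""
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if input_size < kernel_size - 2 * padding:
        raise InfeasibleArchitectureError(
            f"kernel {kernel_size} with padding {padding} exceeds input {input_size}"
        )
    out = (input_size - kernel_size + 2 * padding) // stride + 1
    if out < 1:
        raise InfeasibleArchitectureError(
            f"non-positive output size for w={input_size}, k={kernel_size}, "
            f"p={padding}, s={stride}"
        )
    return out


def relu(x: float) -> float:
    """Rectified linear activation max(0, x)."""
    return max(0.0, float(x))


def _pool(w: int) -> int:
    # 2x2 max pooling with stride 2 == conv size rule with k=s=2, p=0
    return conv_output_size(w, 2, 0, 2)


def build_architecture(
    settings: Sequence[float],
    input_size: tuple[int, int, int] = (50, 50, 3),
    factors: Sequence[FactorSpec] | None = None,
) -> ArchitectureSpec:
    """Build and shape-check the architecture for one factor combination.

    ``settings`` is (conv1 kernel, conv1 filters, conv1 stride, conv1
    padding, conv2 kernel, conv2 filters, conv2 stride, conv2 padding),
    each value a legal level of the corresponding factor.

    Raises
    ------
    InfeasibleArchitectureError
        If any propagated spatial size is non-positive.
    """
    factors = tuple(factors) if factors is not None else default_factors()
    vals = [float(v) for v in settings]
    if len(vals) != len(factors):
        raise ValidationError("settings length must match the factor count")
    for f, v in zip(factors, vals):
        if v not in f.levels:
            raise ValidationError(f"value {v} is not a level of factor {f.name!r}")
    a, b, c, d, e, f_, g, h = (int(v) for v in vals)
    conv1 = ConvLayerSpec(kernel_size=a, filters=b, stride=c, padding=d)
    conv2 = ConvLayerSpec(kernel_size=e, filters=f_, stride=g, padding=h)
    conv3 = ConvLayerSpec(kernel_size=1, filters=120, stride=1, padding=0)

    hgt, wid, _ = input_size
    shapes: list[LayerShape] = [LayerShape("input", hgt, wid, input_size[2])]
    for name, spec, pool in (("conv1", conv1, True), ("conv2", conv2, True),
                             ("conv3", conv3, False)):
        hgt = conv_output_size(hgt, spec.kernel_size, spec.padding, spec.stride)
        wid = conv_output_size(wid, spec.kernel_size, spec.padding, spec.stride)
        shapes.append(LayerShape(name, hgt, wid, spec.filters))
        if pool:
            hgt, wid = _pool(hgt), _pool(wid)
            shapes.append(LayerShape(f"pool_{name}", hgt, wid, spec.filters))
    # two output units: the task is binary benign/malignant classification
    fc_sizes = (84, 2)
    return ArchitectureSpec(
        input_size=tuple(input_size),
        conv1=conv1,
        conv2=conv2,
        conv3=conv3,
        fc_sizes=fc_sizes,
        shapes=tuple(shapes),
    )


def is_feasible(
    settings: Sequence[float],
    input_size: tuple[int, int, int] = (50, 50, 3),
    factors: Sequence[FactorSpec] | None = None,
) -> bool:
    """True iff the combination propagates to positive sizes throughout."""
    try:
        build_architecture(settings, input_size=input_size, factors=factors)
    except InfeasibleArchitectureError:
        return False
    return True


def grid_feasibility(
    factors: Sequence[FactorSpec] | None = None,
    input_size: tuple[int, int, int] = (50, 50, 3),
) -> dict:
    """Enumerate feasibility of every factor-level combination.

    Returns a dict with ``grid_size``, ``feasible`` and ``infeasible``
    counts and the list of infeasible combinations.
    """
    factors = tuple(factors) if factors is not None else default_factors()
    infeasible = []
    total = 0
    for combo in itertools.product(*(f.levels for f in factors)):
        total += 1
        if not is_feasible(combo, input_size=input_size, factors=factors):
            infeasible.append(tuple(combo))
    return {
        "grid_size": total,
        "feasible": total - len(infeasible),
        "infeasible": len(infeasible),
        "infeasible_combinations": infeasible,
    }


@dataclass(frozen=True)
class DatasetManifest:
    """Image counts per magnification, split into train/validation."""

    per_magnification: tuple[tuple[str, int, int], ...]  # (label, benign, malignant)
    train_fraction: float = 0.7

    @property
    def benign_total(self) -> int:
        return sum(b for _, b, _ in self.per_magnification)

    @property
    def malignant_total(self) -> int:
        return sum(m for _, _, m in self.per_magnification)

    @property
    def total(self) -> int:
        return self.benign_total + self.malignant_total

    @property
    def train_count(self) -> int:
        return split_counts(self.total, self.train_fraction)[0]

    @property
    def validation_count(self) -> int:
        return split_counts(self.total, self.train_fraction)[1]


def breakhis_manifest() -> DatasetManifest:
    """Image counts of the benchmark histopathology collection (four magnifications)."""
    return DatasetManifest(
        per_magnification=(
            ("40x", 625, 1370),
            ("100x", 644, 1437),
            ("200x", 623, 1390),
            ("400x", 588, 1232),
        )
    )


def split_counts(total: int, train_fraction: float = 0.7) -> tuple[int, int]:
    """Deterministic train/validation split sizes: floor for training."""
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    train = int(np.floor(train_fraction * total))
    return train, total - train


def train_evaluate(
    arch: ArchitectureSpec, image_root: str | Path, seed: int = 0
) -> float:
    """Interface for real image training (optional plugin, not packaged).

    Expects ``image_root`` to contain ``benign/`` and ``malignant/``
    subdirectories of PNG images; a concrete trainer fits the
    architecture on the first 70% and returns validation accuracy in
    percent.  The dataset is never simulated: an absent or implausible
    directory raises DatasetUnavailableError, as does a missing torch
    installation.
    """
    root = Path(image_root)
    if not root.is_dir() or not all(
        (root / sub).is_dir() for sub in ("benign", "malignant")
    ):
        raise DatasetUnavailableError(
            f"no benign/ and malignant/ image directories under {root!s}"
        )
    try:  # pragma: no cover - optional heavy dependency
        import torch  # noqa: F401
    except ImportError as exc:  # pragma: no cover
        raise DatasetUnavailableError(
            "real training requires torch, which is not installed"
        ) from exc
    raise NotImplementedError(
        "real image training is an optional plugin; supply your own trainer "
        "via the external-command objective"
    )  # pragma: no cover
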