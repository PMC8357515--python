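"""Segmentation network and patch-classifier baseline.

The segmentation model is an encoder of small convolutions and 2x2 max
poolings whose later feature layers carry dilations (2, 4, 5); the former
fully connected stage is a 1x1 convolution, so any input size >= 32
produces a spatially aligned probability map. The coarse logit map is
decoded back to the input resolution before the output sigmoid —
skip-fused bilinear by default, plain bilinear or learnable transposed
convolution by config.

The baseline shares the convolutional trunk but ends in true fully
connected layers that classify the centre pixel of a fixed-size patch;
dense maps come from sliding the patch over the slice.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ..types import BinaryMask, CTSlice
from .layers import (
    BilinearUpsample,
    Conv2D,
    Dense,
    Flatten,
    Layer,
    MaxPool2,
)
from .ops import sigmoid

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "DilatedFCN",
    "PatchCNN",
    "build_dlfcnn",
    "build_baseline_cnn",
    "predict_mask",
    "save_weights",
    "load_weights",
    "normalize_hu",
    "MIN_INPUT_SIZE",
]

#: Smallest accepted input side for the segmentation model (four poolings).
MIN_INPUT_SIZE = 32

#: Dilation intervals of the stacked feature layers.
DEFAULT_DILATIONS = (2, 4, 5)


def normalize_hu(pixels: np.ndarray) -> np.ndarray:
    """Soft-tissue windowing (centre 40 HU, width 400) into [0, 1].

    A plain full-range rescale leaves only ~0.01 of contrast between the
    soft-tissue classes; windowing is the standard CT preprocessing and
    conditions training far better.
    """
    x = np.asarray(pixels, dtype=np.float64)
    return np.clip((x + 160.0) / 400.0, 0.0, 1.0)


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one layer of the stack."""

    name: str
    kind: str  # conv | downsample | conv_as_fc | dense
    n_maps: int
    kernel_size: int = 1
    stride: int = 1
    padding: int = 0
    dilation: int = 1
    activation: str | None = None


@dataclass(frozen=True)
class NetworkSpec:
    """An ordered layer stack plus the decoding convention."""

    kind: str  # dlfcnn | patch_cnn
    layers: tuple[LayerSpec, ...]
    upsample: str = "bilinear"  # bilinear | transposed_conv
    out_activation: str = "sigmoid"
    patch_size: int = 0  # patch_cnn only

    def feature_map_counts(self) -> tuple[int, ...]:
        return tuple(l.n_maps for l in self.layers if l.name != "OUT")


def _trunk_specs(dilations=DEFAULT_DILATIONS) -> list[LayerSpec]:
    d3, d5, d7 = dilations
    return [
        LayerSpec("C1", "conv", 14, 2, 1, 0, 1, "relu"),
        LayerSpec("S2", "downsample", 14, 2, 2),
        LayerSpec("C3", "conv", 14, 5, 1, 2 * d3, d3, "relu"),
        LayerSpec("S4", "downsample", 14, 2, 2),
        LayerSpec("C5", "conv", 28, 5, 1, 2 * d5, d5, "relu"),
        LayerSpec("S6", "downsample", 28, 2, 2),
        LayerSpec("C7", "conv", 28, 5, 1, 2 * d7, d7, "relu"),
        LayerSpec("S8", "downsample", 28, 2, 2),
    ]


def build_dlfcnn(
    upsample: str = "bilinear_skip", dilations=DEFAULT_DILATIONS
) -> NetworkSpec:
    """Layer stack of the segmentation network.

    Feature-map counts run (14, 14, 14, 14, 28, 28, 28, 28, 52); the former
    fully connected stage F9 and the one-map head are 1x1 convolutions.
    """
    layers = _trunk_specs(dilations) + [
        LayerSpec("F9", "conv_as_fc", 52, 1, 1, 0, 1, "relu"),
        LayerSpec("OUT", "conv_as_fc", 1, 1, 1, 0, 1, "sigmoid"),
    ]
    return NetworkSpec(kind="dlfcnn", layers=tuple(layers), upsample=upsample)


def build_baseline_cnn(patch_size: int = 32) -> NetworkSpec:
    """Patch classifier: the same trunk ending in fully connected layers."""
    if patch_size < 32:
        # four 2x2 poolings after the 2x2 first conv: anything smaller
        # reaches zero spatial size before the fully connected stage
        raise ValueError(f"patch_size must be >= 32, got {patch_size}")
    layers = _trunk_specs(dilations=(1, 1, 1)) + [
        LayerSpec("F9", "dense", 52, activation="relu"),
        LayerSpec("OUT", "dense", 1, activation="sigmoid"),
    ]
    return NetworkSpec(kind="patch_cnn", layers=tuple(layers), patch_size=patch_size)


class _Model:
    """Shared plumbing: a layer list with forward/backward and flat params."""

    spec: NetworkSpec
    layers: list[Layer]

    def __init__(self) -> None:
        self.layers = []
        self.initialized = False

    def init_weights(self, seed: int | np.random.Generator) -> None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        for layer in self.layers:
            layer.init_weights(rng)
        self.initialized = True

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def _require_weights(self) -> None:
        if not self.initialized:
            raise RuntimeError("model has no weights: call init_weights or load_weights")


class DilatedFCN(_Model):
    """Runtime network for a ``dlfcnn`` :class:`NetworkSpec`.

    Decode modes (``spec.upsample``):

    ``bilinear_skip`` (default)
        FCN-style fusion: the coarse head logits are upsampled and summed
        with small-convolution score maps taken from the S4 and S6 stages,
        then upsampled to the input size. Needed because at desk-scale
        inputs the x16-pooled head alone is too coarse to outline a lesion.
    ``bilinear``
        Single bilinear upsample of the coarse head logits.
    ``transposed_conv``
        Four learnable stride-2 transposed convolutions (zero-stuffing +
        4x4 convolution) on the head logits, then an exact-size resize.
    """

    #: trunk indices whose outputs feed the skip score maps (S4, S6)
    _SKIP_TAPS = (3, 5)

    def __init__(self, spec: NetworkSpec | None = None) -> None:
        super().__init__()
        self.spec = spec or build_dlfcnn()
        if self.spec.kind != "dlfcnn":
            raise ValueError("DilatedFCN requires a dlfcnn spec")
        if self.spec.upsample not in ("bilinear", "bilinear_skip", "transposed_conv"):
            raise ValueError(f"unknown upsample mode {self.spec.upsample!r}")
        in_maps = 1
        for ls in self.spec.layers:
            if ls.kind == "downsample":
                self.layers.append(MaxPool2())
            else:
                self.layers.append(
                    Conv2D(
                        in_maps,
                        ls.n_maps,
                        ls.kernel_size,
                        ls.stride,
                        ls.padding,
                        ls.dilation,
                        activation=ls.activation if ls.name != "OUT" else None,
                    )
                )
                in_maps = ls.n_maps
        self._decode: list = []
        if self.spec.upsample == "bilinear_skip":
            tap_maps = [self.spec.layers[i].n_maps for i in self._SKIP_TAPS]
            self.skip_convs = [Conv2D(c, 1, 3, 1, 1, activation=None) for c in tap_maps]
            self.skip_ups = [BilinearUpsample() for _ in tap_maps]
            self.up_main = BilinearUpsample()
            self._decode = list(self.skip_convs)
        elif self.spec.upsample == "transposed_conv":
            for _ in range(4):
                self._decode.append(_ZeroStuff2())
                self._decode.append(Conv2D(1, 1, 4, 1, 2, 1, activation=None))
        self.layers.extend(self._decode)
        self.upsample = BilinearUpsample()

    def init_weights(self, seed) -> None:
        super().init_weights(seed)
        if self.spec.upsample == "bilinear_skip":
            # zero-initialized score maps: decoding starts from the coarse
            # head alone and the skips learn refinements
            for conv in self.skip_convs:
                conv.weight[...] = 0.0
        # start the output near the background base rate instead of 0.5,
        # skipping the initial collapse phase of the MSE/sigmoid pairing
        head = self.layers[len(self.spec.layers) - 1]
        head.bias[...] = -2.0

    def _forward_trunk(self, x: np.ndarray):
        n_named = len(self.spec.layers)
        out = x
        self._layer_out_sizes = []
        taps = {}
        for i, (layer, ls) in enumerate(zip(self.layers[:n_named], self.spec.layers)):
            out = layer.forward(out)
            self._layer_out_sizes.append((ls.name, out.shape[2], out.shape[3]))
            if i in self._SKIP_TAPS:
                taps[i] = out
        return out, taps

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probability maps for a ``(N, 1, H, W)`` normalized batch."""
        if x.ndim != 4:
            raise ValueError("expected (N, 1, H, W) input")
        h, w = x.shape[2], x.shape[3]
        if min(h, w) < MIN_INPUT_SIZE:
            raise ValueError(f"input must be at least {MIN_INPUT_SIZE} px per side")
        self.upsample.set_target((h, w))
        head, taps = self._forward_trunk(x)
        if self.spec.upsample == "bilinear_skip":
            scores = [
                conv.forward(taps[i])
                for conv, i in zip(self.skip_convs, self._SKIP_TAPS)
            ]
            fuse_hw = scores[0].shape[2:]  # finest tap sets the fusion grid
            self.up_main.set_target(fuse_hw)
            fused = self.up_main.forward(head)
            for score, up in zip(scores, self.skip_ups):
                up.set_target(fuse_hw)
                fused = fused + up.forward(score)
            out = self.upsample.forward(fused)
        elif self.spec.upsample == "transposed_conv":
            out = head
            for layer in self._decode:
                out = layer.forward(out)
            out = self.upsample.forward(out)
        else:
            out = self.upsample.forward(head)
        self._logits = out
        self._prob = sigmoid(out)
        return self._prob

    def backward(self, grad_prob: np.ndarray) -> np.ndarray:
        grad = grad_prob * self._prob * (1.0 - self._prob)
        grad = self.upsample.backward(grad)
        n_named = len(self.spec.layers)
        trunk = self.layers[:n_named]
        if self.spec.upsample == "bilinear_skip":
            g_taps = {
                i: conv.backward(up.backward(grad))
                for conv, up, i in zip(self.skip_convs, self.skip_ups, self._SKIP_TAPS)
            }
            grad = self.up_main.backward(grad)
            for i in range(n_named - 1, -1, -1):
                grad = trunk[i].backward(grad)
                if i - 1 in g_taps:
                    grad = grad + g_taps[i - 1]
            return grad
        if self.spec.upsample == "transposed_conv":
            for layer in reversed(self._decode):
                grad = layer.backward(grad)
        for layer in reversed(trunk):
            grad = layer.backward(grad)
        return grad

    def layer_output_sizes(self) -> list[tuple[str, int, int]]:
        """Realized spatial sizes of the named layers in the last forward."""
        return list(self._layer_out_sizes)

    def predict_proba(self, ct: CTSlice) -> np.ndarray:
        self._require_weights()
        x = normalize_hu(ct.pixels)[None, None]
        return self.forward(x)[0, 0]


class _ZeroStuff2(Layer):
    """Insert zeros between pixels (stride-2 transposed-conv front half)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        out = np.zeros((n, c, 2 * h - 1, 2 * w - 1), dtype=np.float64)
        out[:, :, ::2, ::2] = x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, :, ::2, ::2]


class PatchCNN(_Model):
    """Runtime network for a ``patch_cnn`` :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec | None = None) -> None:
        super().__init__()
        self.spec = spec or build_baseline_cnn()
        if self.spec.kind != "patch_cnn":
            raise ValueError("PatchCNN requires a patch_cnn spec")
        self.patch_size = self.spec.patch_size
        in_maps = 1
        size = self.patch_size
        flat = None
        for ls in self.spec.layers:
            if ls.kind == "downsample":
                self.layers.append(MaxPool2())
                size //= 2
            elif ls.kind == "conv":
                conv = Conv2D(
                    in_maps, ls.n_maps, ls.kernel_size, ls.stride,
                    ls.padding, ls.dilation, activation=ls.activation,
                )
                self.layers.append(conv)
                size = conv.out_size(size)
                in_maps = ls.n_maps
            elif ls.kind == "dense":
                if flat is None:
                    self.layers.append(Flatten())
                    flat = in_maps * size * size
                act = ls.activation if ls.name != "OUT" else None
                self.layers.append(Dense(flat, ls.n_maps, activation=act))
                flat = ls.n_maps
        if size < 1:
            raise ValueError("patch too small for the trunk")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Centre-pixel probabilities ``(N, 1)`` for a patch batch."""
        out = x
        for layer in self.layers:
            out = layer.forward(out)
        self._logits = out
        self._prob = sigmoid(out)
        return self._prob

    def backward(self, grad_prob: np.ndarray) -> np.ndarray:
        grad = grad_prob * self._prob * (1.0 - self._prob)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(
        self, ct: CTSlice, stride: int = 1, chunk: int = 1024
    ) -> np.ndarray:
        """Dense probability map via a sliding window over the slice.

        ``stride`` > 1 evaluates a subgrid of centres and bilinearly
        interpolates the rest (documented speed knob).
        """
        self._require_weights()
        from numpy.lib.stride_tricks import sliding_window_view
        from .layers import _interp_matrix

        img = normalize_hu(ct.pixels)
        p = self.patch_size
        half = p // 2
        padded = np.pad(img, ((half, p - 1 - half), (half, p - 1 - half)), mode="reflect")
        h, w = img.shape
        rows = np.arange(0, h, stride)
        cols = np.arange(0, w, stride)
        windows = sliding_window_view(padded, (p, p))
        patches = windows[np.ix_(rows, cols)].reshape(-1, p, p)
        probs = np.empty(patches.shape[0], dtype=np.float64)
        for start in range(0, patches.shape[0], chunk):
            x = np.ascontiguousarray(patches[start : start + chunk])[:, None]
            probs[start : start + x.shape[0]] = self.forward(x)[:, 0]
        probs = probs.reshape(rows.size, cols.size)
        if stride == 1:
            return probs
        a = _interp_matrix(rows.size, h)
        b = _interp_matrix(cols.size, w)
        return a @ probs @ b.T


def predict_mask(
    model: DilatedFCN | PatchCNN,
    ct: CTSlice,
    binarize_threshold: float = 0.5,
    **kwargs,
) -> BinaryMask:
    """Binarize the model's probability map at ``binarize_threshold``."""
    if not 0 < binarize_threshold < 1:
        raise ValueError("binarize_threshold must lie in (0, 1)")
    proba = model.predict_proba(ct, **kwargs)
    return proba > binarize_threshold


def save_weights(model: DilatedFCN | PatchCNN, path) -> None:
    """Serialize weights as an array archive with a JSON layer manifest."""
    manifest = {
        "spec": {
            "kind": model.spec.kind,
            "upsample": model.spec.upsample,
            "out_activation": model.spec.out_activation,
            "patch_size": model.spec.patch_size,
            "layers": [asdict(l) for l in model.spec.layers],
        }
    }
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters())}
    np.savez(path, manifest=json.dumps(manifest), **arrays)


def load_weights(path) -> DilatedFCN | PatchCNN:
    """Rebuild a model from :func:`save_weights` output."""
    with np.load(path, allow_pickle=False) as archive:
        manifest = json.loads(str(archive["manifest"]))
        spec_d = manifest["spec"]
        layers = tuple(LayerSpec(**l) for l in spec_d["layers"])
        spec = NetworkSpec(
            kind=spec_d["kind"],
            layers=layers,
            upsample=spec_d["upsample"],
            out_activation=spec_d["out_activation"],
            patch_size=spec_d["patch_size"],
        )
        model = DilatedFCN(spec) if spec.kind == "dlfcnn" else PatchCNN(spec)
        params = model.parameters()
        for i, p in enumerate(params):
            p[...] = archive[f"param_{i}"]
    model.initialized = True
    return model
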