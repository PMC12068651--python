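"""The interpretable core: a bag-of-local-features network (BagNet).

Each cell of the spatial output is a function of exactly one q x q input
patch (q = 33 for the reference backbone) on a lattice of stride s = 8, so
the spatial output forms a faithful *class evidence map*: the value at
cell (i, j) is the model's evidence that patch (i, j) shows disease.  The
class logit is literally the spatial mean of its evidence map, which makes
the map a complete, non-post-hoc explanation of the prediction.

The architecture is data (`ArchitectureSpec`): the receptive-field /
stride pair (q, s) is *computed* from the layer list by the standard
recursion and verified against a perturbation probe, rather than assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

#: class indices for the binary screening task
CLASS_HEALTHY, CLASS_DR = 0, 1


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor. kind: conv | pool | residual."""

    kind: str
    kernel: int = 1
    stride: int = 1
    out_channels: int = 0
    activation: str | None = None
    norm: bool = False  # batch normalization after the convolution
    bias: bool = True  # class head uses bias-free convolution
    branch: tuple = ()  # for kind == "residual": tuple of LayerSpec (1x1, s=1)


@dataclass(frozen=True)
class ArchitectureSpec:
    layers: tuple
    n_classes: int = 2

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @staticmethod
    def from_json(text: str) -> "ArchitectureSpec":
        raw = json.loads(text)

        def mk(d):
            d = dict(d)
            d["branch"] = tuple(mk(b) for b in d.get("branch", ()))
            return LayerSpec(**d)

        return ArchitectureSpec(
            layers=tuple(mk(d) for d in raw["layers"]), n_classes=raw["n_classes"]
        )


def effective_receptive_field(spec: ArchitectureSpec) -> tuple[int, int]:
    """Analytic (receptive field, stride) of one output cell.

    Standard recursion over layers in order: rf <- rf + (k-1)*jump,
    jump <- jump*stride, where jump is the input-pixel spacing of the
    current layer's lattice.
    """
    rf, jump = 1, 1
    for layer in spec.layers:
        if layer.kind in ("conv", "pool"):
            rf += (layer.kernel - 1) * jump
            jump *= layer.stride
        elif layer.kind == "residual":
            for sub in layer.branch:
                if sub.kind != "conv" or sub.kernel != 1 or sub.stride != 1:
                    raise ValueError("residual branches are restricted to 1x1 s=1 convs")
        else:
            raise ValueError(f"unsupported layer kind: {layer.kind!r}")
    return rf, jump


def map_grid_shape(input_hw: tuple[int, int], q: int, s: int) -> tuple[int, int]:
    """Number of valid q x q patch placements at stride s (no padding)."""
    h, w = input_hw
    if h < q or w < q:
        raise ValueError(f"input {h}x{w} smaller than patch size {q}")
    return ((h - q) // s + 1, (w - q) // s + 1)


@dataclass
class EvidenceMap:
    """Per-class local evidence values on the patch lattice.

    values[i, j, c] is the evidence of class c computed from the single
    image patch covering pixel rows [i*s, i*s+q) and cols [j*s, j*s+q)
    (0-based, half-open).  The spatial mean of slice c is the class logit.
    """

    values: np.ndarray  # (h, w, n_classes)
    input_size: tuple[int, int]
    patch: int  # q
    stride: int  # s

    def __post_init__(self):
        h, w = map_grid_shape(self.input_size, self.patch, self.stride)
        if self.values.shape[:2] != (h, w):
            raise ValueError(
                f"evidence grid {self.values.shape[:2]} inconsistent with "
                f"input {self.input_size}, q={self.patch}, s={self.stride}"
            )

    @property
    def n_classes(self) -> int:
        return self.values.shape[2]

    def logits(self) -> np.ndarray:
        """Spatial mean per class — the model's logits, by definition."""
        return self.values.mean(axis=(0, 1))

    def patch_extent(self, i: int, j: int) -> tuple[int, int, int]:
        """(top row, left col, side) of the patch behind cell (i, j)."""
        return i * self.stride, j * self.stride, self.patch


@dataclass
class ClassificationOutput:
    logits: np.ndarray
    probabilities: np.ndarray
    predicted_label: int
    confidence: float


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def classify_from_logits(logits: np.ndarray) -> ClassificationOutput:
    probs = softmax(logits)
    label = int(np.argmax(logits))
    return ClassificationOutput(
        logits=np.asarray(logits, dtype=np.float64),
        probabilities=probs,
        predicted_label=label,
        confidence=float(probs[label]),
    )


def _build_layers(spec: ArchitectureSpec, in_ch: int = 3) -> nn.Sequential:
    layers: list = []
    ch = in_ch
    for ls in spec.layers:
        if ls.kind == "conv":
            layers.append(nn.Conv2d(ch, ls.out_channels, ls.kernel, ls.stride, use_bias=ls.bias))
            ch = ls.out_channels
            if ls.norm:
                layers.append(nn.BatchNorm2d(ch))
            if ls.activation == "relu":
                layers.append(nn.ReLU())
        elif ls.kind == "residual":
            branch: list = []
            bch = ch
            for sub in ls.branch:
                branch.append(nn.Conv2d(bch, sub.out_channels, 1, 1))
                bch = sub.out_channels
                if sub.norm:
                    branch.append(nn.BatchNorm2d(bch))
                if sub.activation == "relu":
                    branch.append(nn.ReLU())
            if bch != ch:
                raise ValueError("residual branch must end at its input width")
            layers.append(nn.Residual(branch))
        else:
            raise ValueError(f"unsupported layer kind {ls.kind!r}")
    return nn.Sequential(layers)


class SparseBagNet:
    """Bag-of-local-features classifier with evidence-map output.

    The network maps an (H, W, 3) image to an (h, w, n_classes) evidence
    map on the valid patch lattice; `forward` returns the map together with
    the classification derived from its spatial means.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.q, self.s = effective_receptive_field(spec)
        self.net = _build_layers(spec)
        self.net.init_params(np.random.default_rng(seed))
        self.normalization = None  # optional NormalizationStats, carried with checkpoints

    # -- raw tensor path (used by training) ------------------------------
    def evidence_tensor(self, batch_nchw: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 3, H, W) -> (N, n_classes, h, w) evidence maps."""
        h, w = batch_nchw.shape[2:]
        if h < self.q or w < self.q:
            raise ValueError(f"input {h}x{w} smaller than patch size {self.q}")
        return self.net.forward(batch_nchw.astype(np.float32), train=train)

    # -- public single-image API -----------------------------------------
    def forward(self, image_hwc: np.ndarray) -> tuple[EvidenceMap, ClassificationOutput]:
        x = np.ascontiguousarray(image_hwc.transpose(2, 0, 1))[None]
        maps = self.evidence_tensor(x)[0]  # (C, h, w)
        emap = EvidenceMap(
            values=maps.transpose(1, 2, 0).astype(np.float64),
            input_size=image_hwc.shape[:2],
            patch=self.q,
            stride=self.s,
        )
        return emap, classify_from_logits(emap.logits())

    def patchwise_oracle(self, image_hwc: np.ndarray, batch: int = 256) -> EvidenceMap:
        """Definitional oracle: evaluate every q x q patch independently.

        Extracts each patch on the stride-s lattice, runs it through the
        network on its own (yielding a 1x1 spatial output), and assembles
        the map.  Must agree with `forward`, which computes the same thing
        convolutionally — this equality is what makes the evidence map an
        honest patch-local explanation.
        """
        q, s = self.q, self.s
        h, w = image_hwc.shape[:2]
        gh, gw = map_grid_shape((h, w), q, s)
        x = image_hwc.transpose(2, 0, 1)
        win = np.lib.stride_tricks.sliding_window_view(x, (q, q), axis=(1, 2))
        win = win[:, ::s, ::s]  # (3, gh, gw, q, q)
        patches = np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(-1, 3, q, q)
        outs = []
        for start in range(0, len(patches), batch):
            o = self.evidence_tensor(patches[start : start + batch])
            if o.shape[2:] != (1, 1):
                raise AssertionError("a single patch must map to a 1x1 output cell")
            outs.append(o[:, :, 0, 0])
        values = np.concatenate(outs).reshape(gh, gw, -1).astype(np.float64)
        return EvidenceMap(values=values, input_size=(h, w), patch=q, stride=s)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        from .preprocess import NormalizationStats

        payload = {f"w{i}": arr for i, arr in enumerate(self.net.state())}
        payload["spec_json"] = np.frombuffer(self.spec.to_json().encode(), dtype=np.uint8)
        if self.normalization is not None:
            payload["norm_mean"] = np.asarray(self.normalization.mean)
            payload["norm_std"] = np.asarray(self.normalization.std)
        np.savez(path, **payload)

    @staticmethod
    def load(path) -> "SparseBagNet":
        from .preprocess import NormalizationStats

        with np.load(path) as data:
            spec = ArchitectureSpec.from_json(bytes(data["spec_json"]).decode())
            model = SparseBagNet(spec, seed=0)
            n_arrays = sum(1 for key in data.files if key.startswith("w"))
            state = [data[f"w{i}"] for i in range(n_arrays)]
            model.net.load_state(state)
            if "norm_mean" in data:
                model.normalization = NormalizationStats(
                    mean=data["norm_mean"].copy(), std=data["norm_std"].copy()
                )
        return model


def _conv(out_ch, kernel, stride, act="relu"):
    # head convolutions (no activation) are bias-free so the evidence scale
    # is anchored by the patch features alone, not a free global offset
    norm = act == "relu"
    return LayerSpec("conv", kernel=kernel, stride=stride, out_channels=out_ch,
                     activation=act, norm=norm, bias=not norm)


def reference_spec(n_classes: int = 2) -> ArchitectureSpec:
    """Reference backbone: receptive field 33, lattice stride 8.

    Five unpadded 3x3 convolutions (strides 1,2,2,2,1) set (q, s) = (33, 8);
    a residual block of 1x1 convolutions and the 1x1 class head add depth
    without touching patch geometry, so every output cell sees exactly one
    33x33 patch.
    """
    return ArchitectureSpec(
        layers=(
            _conv(16, 3, 1),
            _conv(32, 3, 2),
            _conv(64, 3, 2),
            _conv(64, 3, 2),
            _conv(64, 3, 1),
            LayerSpec(
                "residual",
                branch=(
                    LayerSpec("conv", out_channels=64, activation="relu", norm=True),
                    LayerSpec("conv", out_channels=64, activation=None, norm=True),
                ),
            ),
            _conv(n_classes, 1, 1, act=None),
        ),
        n_classes=n_classes,
    )


def reduced_spec(n_classes: int = 2, width: int = 1) -> ArchitectureSpec:
    """Narrow variant of the reference backbone with identical (33, 8) geometry,
    sized for CPU-scale experiments on 128x128 images."""
    w = width
    return ArchitectureSpec(
        layers=(
            _conv(8 * w, 3, 1),
            _conv(16 * w, 3, 2),
            _conv(24 * w, 3, 2),
            _conv(32 * w, 3, 2),
            _conv(32 * w, 3, 1),
            _conv(n_classes, 1, 1, act=None),
        ),
        n_classes=n_classes,
    )


def build_reference_backbone(n_classes: int = 2, seed: int = 0) -> SparseBagNet:
    model = SparseBagNet(reference_spec(n_classes), seed=seed)
    assert (model.q, model.s) == (33, 8)
    return model


def build_reduced_backbone(n_classes: int = 2, seed: int = 0, width: int = 1) -> SparseBagNet:
    model = SparseBagNet(reduced_spec(n_classes, width), seed=seed)
    assert (model.q, model.s) == (33, 8)
    return model


def probe_receptive_field(model: SparseBagNet, input_hw: tuple[int, int] = (81, 81)) -> tuple[int, int]:
    """Empirical (rf, stride) via single-pixel perturbation probing.

    Perturbs one input pixel at a time along the middle row and records
    which output cells change; the maximal extent of input pixels affecting
    one output cell gives the receptive field, and the pixel offset between
    consecutive output cells' supports gives the stride.
    """
    h, w = input_hw
    rng = np.random.default_rng(12345)
    base_img = rng.normal(0.0, 1.0, (1, 3, h, w)).astype(np.float32)
    base_out = model.evidence_tensor(base_img)
    gh, gw = base_out.shape[2:]
    mid_i = gh // 2
    affected_cols: dict[int, list[int]] = {}
    for col in range(w):
        pert = base_img.copy()
        pert[0, :, :, col] += 10.0
        out = model.evidence_tensor(pert)
        changed = np.nonzero(np.abs(out - base_out).max(axis=(0, 1, 2)) > 1e-6)[0]
        for j in changed:
            affected_cols.setdefault(int(j), []).append(col)
    mid_support = affected_cols[gw // 2]
    rf = max(mid_support) - min(mid_support) + 1
    starts = sorted(min(v) for v in affected_cols.values())
    strides = {b - a for a, b in zip(starts, starts[1:])}
    stride = strides.pop() if len(strides) == 1 else None
    if stride is None:
        raise AssertionError("non-uniform output lattice in perturbation probe")
    return rf, stride
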