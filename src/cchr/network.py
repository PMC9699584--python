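"""Modality-specific hashing networks.

Each modality (infrared video, EEG) gets its own three-layer fully
connected projection from the encoder embedding space to a continuous
"binary-like" code in (-1, 1)^L:

    fc1 (D -> D, ReLU) -> fc2 (D -> H, ReLU) -> BatchNorm(H) -> fc3 (H -> L, tanh)

The two networks are architecturally identical but parameter-independent.
Networks are plain numpy: parameters live in a dict, the forward pass
caches intermediates, and :meth:`HashingNetwork.backward` implements the
exact reverse-mode gradient (including training-mode batch normalisation),
so training needs no autodiff framework. Batch normalisation follows the
standard train/inference contract: batch statistics (and a running-average
update) during training, accumulated running statistics at inference —
which makes code-bank construction deterministic after training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "HashingNetworkSpec",
    "HashingNetwork",
    "build_hashing_network",
    "save_checkpoint",
    "load_checkpoint",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1

#: Fixed activation sequence of the three fully connected layers.
ACTIVATIONS: tuple[str, str, str] = ("relu", "relu", "tanh")


@dataclass(frozen=True)
class HashingNetworkSpec:
    """Architecture of one hashing network.

    ``input_dim`` is the encoder embedding dimension (and the width of the
    first layer's output), ``hidden_dim`` the width of the second layer,
    ``code_length`` the number of hash bits L. The final tanh bounds every
    output strictly inside (-1, 1).
    """

    input_dim: int = 512
    hidden_dim: int = 4096
    code_length: int = 32
    batch_norm_before_output: bool = True
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_dim < 1 or self.code_length < 1:
            raise ValueError("input_dim, hidden_dim and code_length must be >= 1")

    @property
    def activations(self) -> tuple[str, str, str]:
        return ACTIVATIONS


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    # scaled-uniform fan-based initialization: U(-1/sqrt(fan_in), +1/sqrt(fan_in))
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=fan_out)
    return w, b


class HashingNetwork:
    """One modality's hashing function f(.) with explicit backprop.

    Trainable parameters: W1, b1, W2, b2, gamma, beta, W3, b3.
    Buffers (not trained): running_mean, running_var.
    """

    TRAINABLE = ("W1", "b1", "W2", "b2", "gamma", "beta", "W3", "b3")

    def __init__(self, spec: HashingNetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.init_seed)
        d, h, L = spec.input_dim, spec.hidden_dim, spec.code_length
        w1, b1 = _init_linear(rng, d, d)
        w2, b2 = _init_linear(rng, d, h)
        w3, b3 = _init_linear(rng, h, L)
        self.params: dict[str, np.ndarray] = {
            "W1": w1, "b1": b1,
            "W2": w2, "b2": b2,
            "gamma": np.ones(h), "beta": np.zeros(h),
            "W3": w3, "b3": b3,
        }
        self.buffers: dict[str, np.ndarray] = {
            "running_mean": np.zeros(h),
            "running_var": np.ones(h),
        }

    # -- forward ----------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim != 2 or x.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"embedding dimension mismatch: expected D={self.spec.input_dim}, "
                f"got input of shape {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward: [N x D] -> continuous codes [N x L]."""
        x = self._check_input(x)
        p, b = self.params, self.buffers
        h1 = np.maximum(x @ p["W1"] + p["b1"], 0.0)
        h2 = np.maximum(h1 @ p["W2"] + p["b2"], 0.0)
        if self.spec.batch_norm_before_output:
            xhat = (h2 - b["running_mean"]) / np.sqrt(b["running_var"] + _BN_EPS)
            h3 = p["gamma"] * xhat + p["beta"]
        else:
            h3 = h2
        return np.tanh(h3 @ p["W3"] + p["b3"])

    def forward_train(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Training-mode forward; returns (codes, cache) and updates the
        BN running statistics."""
        x = self._check_input(x)
        n = x.shape[0]
        p, b = self.params, self.buffers
        a1 = x @ p["W1"] + p["b1"]
        h1 = np.maximum(a1, 0.0)
        a2 = h1 @ p["W2"] + p["b2"]
        h2 = np.maximum(a2, 0.0)
        cache: dict = {"x": x, "a1": a1, "h1": h1, "a2": a2, "h2": h2}
        if self.spec.batch_norm_before_output:
            mu = h2.mean(axis=0)
            var = h2.var(axis=0)  # biased, used for normalisation
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (h2 - mu) * inv_std
            h3 = p["gamma"] * xhat + p["beta"]
            unbiased = var * (n / max(n - 1, 1))
            b["running_mean"] = (1 - _BN_MOMENTUM) * b["running_mean"] + _BN_MOMENTUM * mu
            b["running_var"] = (1 - _BN_MOMENTUM) * b["running_var"] + _BN_MOMENTUM * unbiased
            cache.update({"xhat": xhat, "inv_std": inv_std})
        else:
            h3 = h2
        a3 = h3 @ p["W3"] + p["b3"]
        f = np.tanh(a3)
        cache.update({"h3": h3, "f": f})
        return f, cache

    # -- backward ---------------------------------------------------------

    def backward(self, cache: dict, df: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss w.r.t. all trainable parameters, given
        dL/dF for the cached training-mode forward."""
        p = self.params
        f = cache["f"]
        da3 = df * (1.0 - f * f)
        grads: dict[str, np.ndarray] = {
            "W3": cache["h3"].T @ da3,
            "b3": da3.sum(axis=0),
        }
        dh3 = da3 @ p["W3"].T
        if self.spec.batch_norm_before_output:
            xhat, inv_std = cache["xhat"], cache["inv_std"]
            n = xhat.shape[0]
            grads["gamma"] = (dh3 * xhat).sum(axis=0)
            grads["beta"] = dh3.sum(axis=0)
            dxhat = dh3 * p["gamma"]
            # standard batch-norm backward (batch statistics are functions
            # of the input, so their gradients must be carried through)
            dh2 = (inv_std / n) * (
                n * dxhat
                - dxhat.sum(axis=0)
                - xhat * (dxhat * xhat).sum(axis=0)
            )
        else:
            grads["gamma"] = np.zeros_like(p["gamma"])
            grads["beta"] = np.zeros_like(p["beta"])
            dh2 = dh3
        da2 = dh2 * (cache["a2"] > 0.0)
        grads["W2"] = cache["h1"].T @ da2
        grads["b2"] = da2.sum(axis=0)
        dh1 = da2 @ p["W2"].T
        da1 = dh1 * (cache["a1"] > 0.0)
        grads["W1"] = cache["x"].T @ da1
        grads["b1"] = da1.sum(axis=0)
        return grads

    # -- state ------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.copy() for k, v in self.params.items()}
        out.update({k: v.copy() for k, v in self.buffers.items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64).copy()
        for k in self.buffers:
            self.buffers[k] = np.asarray(state[k], dtype=np.float64).copy()

    def zero_parameters(self) -> "HashingNetwork":
        """Set every parameter (not the BN buffers) to zero; the forward
        pass then returns tanh(0) = 0 for any input. Returns self."""
        for k in self.params:
            self.params[k] = np.zeros_like(self.params[k])
        return self


def build_hashing_network(spec: HashingNetworkSpec) -> HashingNetwork:
    """Construct a hashing network with deterministic seeded initialisation."""
    return HashingNetwork(spec)


# ---------------------------------------------------------------------------
# Checkpoints: one archive for both modality networks + JSON sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    net_v: HashingNetwork,
    net_e: HashingNetwork,
    meta: dict | None = None,
) -> None:
    """Save both networks to ``<path>`` (npz archive) with a JSON sidecar
    ``<path>.json`` recording architecture and provenance metadata."""
    path = Path(path)
    if net_v.spec.code_length != net_e.spec.code_length:
        raise ValueError("the two networks must share a code length")
    arrays: dict[str, np.ndarray] = {}
    for tag, net in (("v", net_v), ("e", net_e)):
        for k, arr in net.state_dict().items():
            arrays[f"{tag}_{k}"] = arr
    np.savez(path, **arrays)
    if path.suffix != ".npz":
        # np.savez appends .npz; keep the exact path the caller asked for
        path.with_name(path.name + ".npz").replace(path)
    sidecar = {
        "format_version": "1",
        "video_spec": _spec_dict(net_v.spec),
        "eeg_spec": _spec_dict(net_e.spec),
        "meta": meta or {},
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")


def _spec_dict(spec: HashingNetworkSpec) -> dict:
    return {
        "input_dim": spec.input_dim,
        "hidden_dim": spec.hidden_dim,
        "code_length": spec.code_length,
        "batch_norm_before_output": spec.batch_norm_before_output,
        "init_seed": spec.init_seed,
    }


def load_checkpoint(path: str | Path) -> tuple[HashingNetwork, HashingNetwork, dict]:
    """Load ``(net_v, net_e, meta)`` saved by :func:`save_checkpoint`."""
    path = Path(path)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    if sidecar.get("format_version") != "1":
        raise ValueError(
            f"unsupported checkpoint format_version {sidecar.get('format_version')!r}"
        )
    data = np.load(path)
    nets = []
    for tag, key in (("v", "video_spec"), ("e", "eeg_spec")):
        spec = HashingNetworkSpec(**sidecar[key])
        net = HashingNetwork(spec)
        state = {
            k[len(tag) + 1:]: data[k] for k in data.files if k.startswith(tag + "_")
        }
        net.load_state_dict(state)
        nets.append(net)
    return nets[0], nets[1], sidecar.get("meta", {})
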