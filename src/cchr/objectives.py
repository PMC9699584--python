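"""Training objectives for cross-modal contrastive hashing.

Three losses drive the paired hashing networks:

* a cross-modal contrastive loss with in-batch hardest-negative mining:
  for anchor pair k, with similarity S(a,b) = exp(cos(a,b)/tau),

      [alpha - S(fv_k, fe_k) + S(fv_k, fe_m)]_+  +
      [alpha - S(fv_k, fe_k) + S(fv_n, fe_k)]_+

  where m maximises the video-anchor's similarity over non-matching EEG
  rows and n maximises the EEG-anchor's similarity over non-matching
  video rows;
* a quantization loss ||B - Fv||_F^2 + ||B - Fe||_F^2 pulling the
  continuous codes toward the joint binary target B = sign((Fv + Fe)/2),
  which is held constant within a step (no gradient through sign);
* a bit-balance loss penalising per-bit imbalance over the batch so each
  output neuron fires +1/-1 with equal chance.

The total objective is  L = Lc + lambda1 * Lq + lambda2 * Lbb.  All three
losses are reduced as means over the batch by default so the lambda
weights are batch-size independent; per-instance sums are available via
``reduction="sum"``.  Analytic gradients w.r.t. the continuous code
matrices are provided for the numpy training loop; mining indices and B
are treated as piecewise-constant (standard subgradient convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "BatchCodes",
    "cosine_similarity",
    "similarity",
    "cosine_matrix",
    "mine_hard_negatives",
    "contrastive_loss",
    "binarize_joint",
    "quantization_loss",
    "bit_balance_loss",
    "total_loss",
    "loss_components",
    "total_loss_and_grads",
]

_BIT_BALANCE_MODES = ("per_bit_over_batch", "per_sample_over_bits")
_REDUCTIONS = ("mean", "sum")


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters of the combined hashing objective.

    ``margin_alpha`` is the contrastive hinge margin (default 0.25);
    ``temperature_tau`` scales the cosine before exponentiation (the
    similarity is exp(cos/tau)); ``lambda1`` and ``lambda2`` weight the
    quantization and bit-balance terms.
    """

    margin_alpha: float = 0.25
    temperature_tau: float = 1.0
    lambda1: float = 0.001
    lambda2: float = 0.01
    bit_balance_mode: str = "per_bit_over_batch"
    reduction: str = "mean"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.temperature_tau) and self.temperature_tau > 0):
            raise ValueError(f"temperature_tau must be > 0, got {self.temperature_tau}")
        for name in ("margin_alpha", "lambda1", "lambda2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.bit_balance_mode not in _BIT_BALANCE_MODES:
            raise ValueError(
                f"unknown bit_balance_mode {self.bit_balance_mode!r}; "
                f"expected one of {_BIT_BALANCE_MODES}"
            )
        if self.reduction not in _REDUCTIONS:
            raise ValueError(f"reduction must be one of {_REDUCTIONS}")


@dataclass
class BatchCodes:
    """Continuous codes of one synchronized batch plus the joint binary target."""

    Fv: np.ndarray
    Fe: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.Fv = np.asarray(self.Fv, dtype=np.float64)
        self.Fe = np.asarray(self.Fe, dtype=np.float64)
        self.B = np.asarray(self.B)
        if not (self.Fv.shape == self.Fe.shape == self.B.shape):
            raise ValueError("Fv, Fe and B must share a shape")
        if not np.all(np.isin(self.B, (-1, 1))):
            raise ValueError("B entries must be in {-1, +1}")


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a.b / (||a|| ||b||); a zero vector yields 0 with a warning."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("cosine of a zero vector is defined as 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    return float(a @ b / (na * nb))


def similarity(a: np.ndarray, b: np.ndarray, tau: float = 1.0) -> float:
    """S(a, b) = exp(cos(a, b) / tau), strictly increasing in the cosine."""
    if not (math.isfinite(tau) and tau > 0):
        raise ValueError(f"tau must be > 0, got {tau}")
    return float(np.exp(cosine_similarity(a, b) / tau))


def _normalize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    safe = np.where(norms == 0.0, 1.0, norms)
    return x / safe, safe


def cosine_matrix(Fv: np.ndarray, Fe: np.ndarray) -> np.ndarray:
    """Pairwise cosine matrix C[i, j] = cos(Fv[i], Fe[j]); zero rows give 0."""
    Fv = np.asarray(Fv, dtype=np.float64)
    Fe = np.asarray(Fe, dtype=np.float64)
    vn, _ = _normalize_rows(Fv)
    en, _ = _normalize_rows(Fe)
    return vn @ en.T


# ---------------------------------------------------------------------------
# hard-negative mining
# ---------------------------------------------------------------------------

def mine_hard_negatives(Fv: np.ndarray, Fe: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-batch hardest negatives for every anchor.

    Returns ``(m, n)`` where ``m[k] != k`` maximises S(Fv[k], Fe[m]) over
    the batch's EEG rows and ``n[k] != k`` maximises S(Fv[n], Fe[k]) over
    the video rows. S is monotone in the cosine, so the argmax is taken
    over the cosine matrix directly. Ties break to the smallest index.
    """
    c = cosine_matrix(Fv, Fe)
    nb = c.shape[0]
    if nb < 2:
        raise ValueError("hard-negative mining requires a batch of at least 2 pairs")
    masked = c.copy()
    np.fill_diagonal(masked, -np.inf)
    m = np.argmax(masked, axis=1)  # first occurrence == smallest index on ties
    n = np.argmax(masked, axis=0)
    return m, n


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _reduce(total: float, nb: int, reduction: str) -> float:
    return total / nb if reduction == "mean" else total


def contrastive_loss(Fv: np.ndarray, Fe: np.ndarray, cfg: LossConfig) -> float:
    """Cross-modal contrastive loss with in-batch hardest negatives."""
    loss, _, _ = _contrastive_loss_grads(Fv, Fe, cfg, want_grads=False)
    return loss


def binarize_joint(Fv: np.ndarray, Fe: np.ndarray) -> np.ndarray:
    """Joint binary code B = sign((Fv + Fe) / 2), with sign(0) = +1."""
    Fv = np.asarray(Fv, dtype=np.float64)
    Fe = np.asarray(Fe, dtype=np.float64)
    if Fv.shape != Fe.shape:
        raise ValueError(f"shape mismatch: {Fv.shape} vs {Fe.shape}")
    return np.where((Fv + Fe) / 2.0 >= 0.0, 1.0, -1.0)


def quantization_loss(
    Fv: np.ndarray, Fe: np.ndarray, B: np.ndarray, reduction: str = "mean"
) -> float:
    """||B - Fv||_F^2 + ||B - Fe||_F^2, reduced over the batch.

    B is the binarization target and carries no gradient.
    """
    Fv = np.asarray(Fv, dtype=np.float64)
    Fe = np.asarray(Fe, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if not (Fv.shape == Fe.shape == B.shape):
        raise ValueError("Fv, Fe and B must share a shape")
    total = float(np.sum((B - Fv) ** 2) + np.sum((B - Fe) ** 2))
    return _reduce(total, Fv.shape[0], reduction)


def bit_balance_loss(
    Fv: np.ndarray,
    Fe: np.ndarray,
    mode: str = "per_bit_over_batch",
    reduction: str = "mean",
) -> float:
    """Bit-balance penalty: each output neuron should fire with equal chance.

    Default mode penalises the squared per-bit column sums over the batch
    (zero iff every bit position is balanced in both modalities); the
    ``per_sample_over_bits`` alternative penalises per-clip row sums.
    """
    if mode not in _BIT_BALANCE_MODES:
        raise ValueError(
            f"unknown bit_balance_mode {mode!r}; expected one of {_BIT_BALANCE_MODES}"
        )
    Fv = np.asarray(Fv, dtype=np.float64)
    Fe = np.asarray(Fe, dtype=np.float64)
    if Fv.shape != Fe.shape:
        raise ValueError(f"shape mismatch: {Fv.shape} vs {Fe.shape}")
    axis = 0 if mode == "per_bit_over_batch" else 1
    total = float(
        np.sum(Fv.sum(axis=axis) ** 2) + np.sum(Fe.sum(axis=axis) ** 2)
    )
    return _reduce(total, Fv.shape[0], reduction)


def loss_components(
    Fv: np.ndarray, Fe: np.ndarray, cfg: LossConfig
) -> dict[str, float]:
    """Unweighted components and the weighted total for one batch."""
    B = binarize_joint(Fv, Fe)
    lc = contrastive_loss(Fv, Fe, cfg)
    lq = quantization_loss(Fv, Fe, B, reduction=cfg.reduction)
    lbb = bit_balance_loss(Fv, Fe, mode=cfg.bit_balance_mode, reduction=cfg.reduction)
    return {
        "contrastive": lc,
        "quantization": lq,
        "bit_balance": lbb,
        "total": lc + cfg.lambda1 * lq + cfg.lambda2 * lbb,
    }


def total_loss(Fv: np.ndarray, Fe: np.ndarray, cfg: LossConfig) -> float:
    """L = Lc + lambda1 * Lq + lambda2 * Lbb with B recomputed from the batch."""
    return loss_components(Fv, Fe, cfg)["total"]


# ---------------------------------------------------------------------------
# analytic gradients
# ---------------------------------------------------------------------------

def _contrastive_loss_grads(
    Fv: np.ndarray, Fe: np.ndarray, cfg: LossConfig, want_grads: bool = True
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    Fv = np.asarray(Fv, dtype=np.float64)
    Fe = np.asarray(Fe, dtype=np.float64)
    if Fv.shape != Fe.shape:
        raise ValueError(f"shape mismatch: {Fv.shape} vs {Fe.shape}")
    nb = Fv.shape[0]
    if nb < 2:
        raise ValueError("contrastive loss requires a batch of at least 2 pairs")
    tau, alpha = cfg.temperature_tau, cfg.margin_alpha

    vn, vnorm = _normalize_rows(Fv)
    en, enorm = _normalize_rows(Fe)
    c = vn @ en.T
    s = np.exp(c / tau)
    m, n = mine_hard_negatives(Fv, Fe)

    k = np.arange(nb)
    pos = s[k, k]
    h1 = alpha - pos + s[k, m]
    h2 = alpha - pos + s[n, k]
    total = float(np.sum(np.maximum(h1, 0.0) + np.maximum(h2, 0.0)))
    loss = _reduce(total, nb, cfg.reduction)
    if not want_grads:
        return loss, None, None

    # dL/dC accumulated through S = exp(C/tau); mining indices constant
    scale = (1.0 / nb if cfg.reduction == "mean" else 1.0) / tau
    g = np.zeros_like(c)
    act1 = h1 > 0.0
    act2 = h2 > 0.0
    np.add.at(g, (k[act1], k[act1]), -pos[act1] * scale)
    np.add.at(g, (k[act1], m[act1]), s[k, m][act1] * scale)
    np.add.at(g, (k[act2], k[act2]), -pos[act2] * scale)
    np.add.at(g, (n[act2], k[act2]), s[n, k][act2] * scale)

    dvn = g @ en
    den = g.T @ vn
    # back through row normalisation x_n = x / ||x||
    dfv = (dvn - vn * np.sum(dvn * vn, axis=1, keepdims=True)) / vnorm
    dfe = (den - en * np.sum(den * en, axis=1, keepdims=True)) / enorm
    return loss, dfv, dfe


def total_loss_and_grads(
    Fv: np.ndarray, Fe: np.ndarray, cfg: LossConfig
) -> tuple[dict[str, float], np.ndarray, np.ndarray]:
    """Loss components plus dL/dFv and dL/dFe for the weighted total.

    The binary target B and the mining indices are treated as constants of
    the current step.
    """
    Fv = np.asarray(Fv, dtype=np.float64)
    Fe = np.asarray(Fe, dtype=np.float64)
    nb = Fv.shape[0]
    B = binarize_joint(Fv, Fe)
    lc, dfv, dfe = _contrastive_loss_grads(Fv, Fe, cfg, want_grads=True)
    lq = quantization_loss(Fv, Fe, B, reduction=cfg.reduction)
    lbb = bit_balance_loss(Fv, Fe, mode=cfg.bit_balance_mode, reduction=cfg.reduction)

    red = nb if cfg.reduction == "mean" else 1
    dfv = dfv + cfg.lambda1 * 2.0 * (Fv - B) / red
    dfe = dfe + cfg.lambda1 * 2.0 * (Fe - B) / red
    if cfg.bit_balance_mode == "per_bit_over_batch":
        dfv = dfv + cfg.lambda2 * 2.0 * Fv.sum(axis=0)[None, :] / red
        dfe = dfe + cfg.lambda2 * 2.0 * Fe.sum(axis=0)[None, :] / red
    else:
        dfv = dfv + cfg.lambda2 * 2.0 * Fv.sum(axis=1)[:, None] / red
        dfe = dfe + cfg.lambda2 * 2.0 * Fe.sum(axis=1)[:, None] / red

    components = {
        "contrastive": lc,
        "quantization": lq,
        "bit_balance": lbb,
        "total": lc + cfg.lambda1 * lq + cfg.lambda2 * lbb,
    }
    return components, dfv, dfe
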