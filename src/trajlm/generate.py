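"""Autoregressive sampling of synthetic label trajectories.

A trained model defines a conditional next-character law; sampling draws
each character from that categorical distribution at temperature 1 and
feeds it back, so arbitrarily long statistically equivalent trajectories
can be generated from a short training series.  Temperature is fixed at 1:
the Boltzmann and kinetics analyses require unbiased samples of the learned
conditional law, so there is no greedy/argmax mode in the statistics path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import DiscretizationScheme, LabelSeries, decode
from .language_model import TrajLMParams, _sigmoid

__all__ = ["GenConfig", "sample_trajectory", "decode_trajectory"]


@dataclass(frozen=True)
class GenConfig:
    """Sampling settings.

    ``seed_context`` (optional labels) is fed through the model before any
    character is drawn; ``burn_in`` generated symbols are then discarded to
    wash out the zero initial state.  Deterministic given ``rng_seed``.
    """

    length: int
    rng_seed: int = 0
    seed_context: np.ndarray | None = None
    burn_in: int = 1000

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


def sample_trajectory(params: TrajLMParams, cfg: GenConfig) -> np.ndarray:
    """Sample ``cfg.length`` labels autoregressively from the model."""
    dims = params.dims
    N, L = dims.n_labels, dims.hidden_dim
    rng = np.random.default_rng(cfg.rng_seed)

    context = cfg.seed_context
    if context is not None:
        context = np.asarray(
            context.labels if isinstance(context, LabelSeries) else context,
            dtype=np.int64)
        if context.size and (context.min() < 0 or context.max() >= N):
            raise ValueError("seed context labels out of range for the model")
        if context.size == 0:
            context = None
    if context is None:
        context = np.array([rng.integers(N)], dtype=np.int64)

    # per-label input contributions, precomputed once: z_x[k] = W x_k
    zx_table = params.embedding.T @ params.w_x.T  # (N, 4L)
    u_h_T = params.u_h.T
    d_d_T = params.d_d.T
    b, b_d = params.b, params.b_d

    h = np.zeros(L)
    c = np.zeros(L)

    def step(label: int) -> None:
        nonlocal h, c
        z = zx_table[label] + h @ u_h_T + b
        f = _sigmoid(z[0 * L:1 * L])
        i = _sigmoid(z[1 * L:2 * L])
        o = _sigmoid(z[2 * L:3 * L])
        c_tilde = np.tanh(z[3 * L:4 * L])
        c = f * c + i * c_tilde
        h = o * np.tanh(c)

    for lab in context:
        step(int(lab))

    n_draw = cfg.burn_in + cfg.length
    out = np.empty(n_draw, dtype=np.int64)
    uniforms = rng.random(n_draw)
    for k in range(n_draw):
        logits = h @ d_d_T + b_d
        logits -= logits.max()
        p = np.exp(logits)
        cdf = np.cumsum(p)
        lab = int(np.searchsorted(cdf, uniforms[k] * cdf[-1], side="right"))
        lab = min(lab, params.dims.n_labels - 1)
        out[k] = lab
        step(lab)
    return out[cfg.burn_in:]


def decode_trajectory(labels, scheme: DiscretizationScheme) -> np.ndarray:
    """Map generated labels back to order-parameter values (bin midpoints)."""
    if not isinstance(labels, LabelSeries):
        labels = LabelSeries(labels=np.asarray(labels, dtype=np.int64), scheme=scheme)
    return decode(labels)
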