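"""Model / Results interface for the trajectory language model.

``TrajectoryLM`` holds the data (a discretized label series) and the
architecture; ``fit()`` returns a ``TrajectoryLMResults`` carrying the
trained parameters, the loss history, and everything derived from them:
autoregressive sampling, conditional next-character distributions, the
embedding transition-probability ansatz, checkpointing, and a summary table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import language_model as lm
from .encoding import (DiscretizationScheme, LabelSeries, decode, encode,
                       fit_scheme)
from .generate import GenConfig, sample_trajectory

__all__ = ["TrajectoryLM", "TrajectoryLMResults"]


class TrajectoryLM:
    """Character-level LSTM language model of a discretized 1-D trajectory.

    Parameters
    ----------
    endog : LabelSeries or integer array
        The training character sequence.  If a plain integer array is given,
        ``n_labels`` must be provided (or is inferred as ``max + 1``).
    n_labels, embed_dim, hidden_dim :
        Architecture sizes N, M, L.  Defaults M=8, L=64 suit the 2-D model
        potentials; biomolecular series typically need M=128, L=1024.
    """

    def __init__(self, endog, n_labels: int | None = None,
                 embed_dim: int = 8, hidden_dim: int = 64):
        if isinstance(endog, LabelSeries):
            self.labels = endog.labels
            self.scheme: DiscretizationScheme | None = endog.scheme
            n_labels = endog.scheme.n_labels
        else:
            self.labels = np.asarray(endog, dtype=np.int64)
            self.scheme = None
            if n_labels is None:
                n_labels = int(self.labels.max()) + 1
        self.dims = lm.ModelDims(n_labels=int(n_labels), embed_dim=embed_dim,
                                 hidden_dim=hidden_dim)

    @classmethod
    def from_series(cls, series, n_labels: int = 32, *,
                    embed_dim: int = 8, hidden_dim: int = 64,
                    scheme: DiscretizationScheme | None = None) -> "TrajectoryLM":
        """Build from a raw order-parameter series, fitting the
        discretization scheme to its range unless one is supplied."""
        if scheme is None:
            scheme = fit_scheme(series, n_labels)
        return cls(encode(series, scheme), embed_dim=embed_dim,
                   hidden_dim=hidden_dim)

    def fit(self, seq_len: int = 100, batch_size: int = 64, epochs: int = 20,
            learning_rate: float = 2e-3, optimizer: str = "adaptive",
            seed: int = 0, validation_fraction: float = 0.1,
            clip_norm: float = 5.0) -> "TrajectoryLMResults":
        """Train by teacher forcing; see ``language_model.train``."""
        cfg = lm.TrainConfig(seq_len=seq_len, batch_size=batch_size,
                             epochs=epochs, learning_rate=learning_rate,
                             optimizer=optimizer, seed=seed,
                             validation_fraction=validation_fraction,
                             clip_norm=clip_norm)
        params, history = lm.train(self.labels, self.dims, cfg)
        return TrajectoryLMResults(self, params, history, cfg)


class TrajectoryLMResults:
    """Fitted trajectory language model."""

    def __init__(self, model: TrajectoryLM, params: lm.TrajLMParams,
                 history: pd.DataFrame, config: lm.TrainConfig | None = None):
        self.model = model
        self.params = params
        self.loss_history = history
        self.config = config

    # -- diagnostics --------------------------------------------------------

    @property
    def train_loss(self) -> float:
        """Final per-symbol training cross-entropy (nats)."""
        return float(self.loss_history["train_loss"].iloc[-1])

    @property
    def val_loss(self) -> float:
        """Final per-symbol validation cross-entropy (nats)."""
        return float(self.loss_history["val_loss"].iloc[-1])

    def sequence_loss(self, labels) -> lm.SequenceLoss:
        return lm.sequence_loss(self.params, labels)

    # -- derived quantities -------------------------------------------------

    def conditional_probs(self, context) -> np.ndarray:
        return lm.conditional_probs(self.params, context)

    def embedding_transition_matrix(self) -> np.ndarray:
        from .kinetics import embedding_transition_matrix
        return embedding_transition_matrix(self.params.embedding)

    # -- sampling -----------------------------------------------------------

    def _default_context(self, rng_seed: int) -> np.ndarray:
        """A random training subsequence of length seq_len."""
        seq_len = self.config.seq_len if self.config else 100
        labels = self.model.labels
        if labels.size <= seq_len:
            return labels
        rng = np.random.default_rng(rng_seed)
        start = int(rng.integers(labels.size - seq_len))
        return labels[start:start + seq_len]

    def sample(self, length: int, rng_seed: int = 0, burn_in: int = 1000,
               seed_context="train") -> np.ndarray:
        """Autoregressively sample ``length`` labels (temperature 1).

        ``seed_context="train"`` warms the state with a random training
        subsequence; pass an explicit array or None for other protocols.
        """
        if isinstance(seed_context, str) and seed_context == "train":
            seed_context = self._default_context(rng_seed)
        cfg = GenConfig(length=length, rng_seed=rng_seed, burn_in=burn_in,
                        seed_context=seed_context)
        return sample_trajectory(self.params, cfg)

    def sample_series(self, length: int, rng_seed: int = 0,
                      burn_in: int = 1000) -> np.ndarray:
        """Sample and decode back to order-parameter values."""
        if self.model.scheme is None:
            raise ValueError("model was built from labels without a scheme")
        labels = self.sample(length, rng_seed=rng_seed, burn_in=burn_in)
        return decode(LabelSeries(labels=labels, scheme=self.model.scheme))

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        extra = {}
        if self.model.scheme is not None:
            extra.update(lo=self.model.scheme.lo, hi=self.model.scheme.hi)
        if self.config is not None:
            extra.update(seq_len=self.config.seq_len, seed=self.config.seed)
        lm.save_params(self.params, directory, manifest_extra=extra)
        self.loss_history.to_csv(Path(directory) / "loss_history.csv",
                                 index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "TrajectoryLMResults":
        directory = Path(directory)
        params, manifest = lm.load_params(directory)
        hist_path = directory / "loss_history.csv"
        history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
        dummy = TrajectoryLM(np.zeros(2, dtype=np.int64),
                             n_labels=params.dims.n_labels,
                             embed_dim=params.dims.embed_dim,
                             hidden_dim=params.dims.hidden_dim)
        if "lo" in manifest and "hi" in manifest:
            dummy.scheme = DiscretizationScheme(
                n_labels=params.dims.n_labels,
                lo=float(manifest["lo"]), hi=float(manifest["hi"]))
        return cls(dummy, params, history)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        d = self.params.dims
        n_params = sum(v.size for v in self.params.as_dict().values())
        lines = [
            "Trajectory language model (LSTM)",
            "=" * 44,
            f"{'characters (N)':<28}{d.n_labels:>16}",
            f"{'embedding dim (M)':<28}{d.embed_dim:>16}",
            f"{'LSTM units (L)':<28}{d.hidden_dim:>16}",
            f"{'trainable parameters':<28}{n_params:>16}",
            f"{'training symbols':<28}{self.model.labels.size:>16}",
        ]
        if self.config is not None:
            lines += [
                f"{'seq_len / batch / epochs':<28}"
                f"{f'{self.config.seq_len} / {self.config.batch_size} / {self.config.epochs}':>16}",
                f"{'optimizer':<28}{self.config.optimizer:>16}",
            ]
        if len(self.loss_history):
            lines += [
                f"{'final train loss (nats)':<28}{self.train_loss:>16.4f}",
                f"{'final val loss (nats)':<28}{self.val_loss:>16.4f}",
            ]
        lines.append("=" * 44)
        return "\n".join(lines)
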