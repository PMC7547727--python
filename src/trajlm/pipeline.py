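"""End-to-end workflow on the built-in model potentials.

``run_model_system`` chains the full study design for one potential:
Langevin simulation -> x-projection -> discretization -> LSTM training ->
autoregressive generation -> state assignment.  Training and generation are
repeated over ``n_trials`` independent trials (fresh initialization, window
shuffling and sampling streams per trial); generated-side statistics pool
contiguous segments across trials, so their standard errors include
trial-to-trial training variability — the same protocol used to draw error
bars in the reference comparisons — and each trial generates an equal share
of a trajectory as long as the training series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import LabelSeries, encode, fit_scheme
from .kinetics import (CommitCurve, KineticDistanceTable, StateMap,
                       assign_states, counted_commute_time, kinetic_distance,
                       rescale_unit, segment_commit_counts,
                       segment_state_probabilities)
from .langevin import LangevinConfig, project, simulate
from .model import TrajectoryLM, TrajectoryLMResults
from .potentials import ModelPotential, builtin_potential

__all__ = ["SystemRun", "run_model_system", "DEFAULT_BETA",
           "compare_state_probabilities", "compare_commit_curves"]

# inverse temperatures used for the built-in systems
DEFAULT_BETA = {"linear3": 9.5, "triangular3": 9.0, "four_state": 9.5}


@dataclass
class SystemRun:
    """Everything produced by one simulate/train/generate cycle."""

    potential: ModelPotential
    beta: float
    labels_md: LabelSeries            # discretized simulation (x-projection)
    trials: list                      # TrajectoryLMResults per trial
    labels_lm: list                   # generated LabelSeries per trial
    statemap: StateMap

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def _lm_segments_per_trial(self, n_segments: int) -> int:
        if n_segments % self.n_trials:
            raise ValueError(
                f"n_segments ({n_segments}) must be divisible by the "
                f"number of trials ({self.n_trials})")
        return n_segments // self.n_trials

    def state_probabilities(self, which: str = "md",
                            n_segments: int = 20) -> pd.DataFrame:
        if which == "md":
            per_seg = segment_state_probabilities(self.labels_md,
                                                  self.statemap, n_segments)
        else:
            k = self._lm_segments_per_trial(n_segments)
            per_seg = np.vstack([
                segment_state_probabilities(ls, self.statemap, k)
                for ls in self.labels_lm])
        mean = per_seg.mean(axis=0)
        se = per_seg.std(axis=0) / np.sqrt(per_seg.shape[0])
        return pd.DataFrame({"state": np.arange(self.statemap.n_states),
                             "probability": mean, "se": se})

    def commit_curve(self, which: str = "md", commit_times=None,
                     n_segments: int = 20) -> CommitCurve:
        if commit_times is None:
            commit_times = np.arange(1, 201)
        commit_times = np.asarray(commit_times, dtype=np.int64)
        if which == "md":
            per_seg, pairs = segment_commit_counts(
                self.labels_md, self.statemap, commit_times, n_segments)
        else:
            k = self._lm_segments_per_trial(n_segments)
            blocks = [segment_commit_counts(ls, self.statemap, commit_times, k)
                      for ls in self.labels_lm]
            pairs = blocks[0][1]
            per_seg = np.vstack([b[0] for b in blocks])
        mean = per_seg.mean(axis=0)
        se = per_seg.std(axis=0) / np.sqrt(per_seg.shape[0])
        return CommitCurve(
            commit_times=commit_times,
            counts={p: mean[:, i] for i, p in enumerate(pairs)},
            standard_errors={p: se[:, i] for i, p in enumerate(pairs)},
            n_segments=per_seg.shape[0],
        )

    def kinetic_distances(self, commit_times=None, aggregate: str = "weighted",
                          trial: int | None = None) -> KineticDistanceTable:
        """Embedding times (generated series + embedding of one trial, or
        the per-pair median over trials) vs counted commute times from the
        simulated series; both min-max rescaled."""
        if commit_times is None:
            commit_times = np.arange(1, 201)
        t_all = []
        sel = range(self.n_trials) if trial is None else [trial]
        for i in sel:
            q = self.trials[i].embedding_transition_matrix()
            pairs, t = kinetic_distance(q, self.labels_lm[i], self.statemap,
                                        aggregate=aggregate)
            t_all.append(t)
        t = np.median(t_all, axis=0)
        _, tau = counted_commute_time(self.labels_md, self.statemap,
                                      commit_times)
        return KineticDistanceTable(
            pairs=pairs, t_lm=t, tau_lm=tau,
            t_rescaled=rescale_unit(t), tau_rescaled=rescale_unit(tau),
        )


def run_model_system(name: str, *, beta: float | None = None,
                     n_steps: int = 5_000_000, save_stride: int = 10,
                     dt: float = 0.01, n_labels: int = 32,
                     state_radius: float = 0.5,
                     epochs: int = 20, seq_len: int = 100,
                     batch_size: int = 64, learning_rate: float = 2e-3,
                     n_trials: int = 4, gen_length: int | None = None,
                     seed: int = 0) -> SystemRun:
    """Run the full pipeline on a built-in potential.

    ``gen_length=None`` generates as many symbols in total as the training
    series holds, split equally across trials.  All randomness (simulation,
    initialization, window shuffling, sampling) derives from ``seed``.
    """
    p = builtin_potential(name)
    if beta is None:
        beta = DEFAULT_BETA[name]
    cfg = LangevinConfig(beta=beta, dt=dt, n_steps=n_steps,
                         save_stride=save_stride, seed=seed)
    traj = simulate(p, cfg)
    x = project(traj, "x")
    scheme = fit_scheme(x, n_labels)
    labels_md = encode(x, scheme)
    statemap = assign_states(scheme, p.well_projections("x"), state_radius)

    mod = TrajectoryLM(labels_md)
    if gen_length is None:
        gen_length = len(labels_md)
    trials = []
    labels_lm = []
    for i in range(n_trials):
        res = mod.fit(seq_len=seq_len, batch_size=batch_size, epochs=epochs,
                      learning_rate=learning_rate, seed=seed + 1 + 2 * i)
        gen = res.sample(gen_length // n_trials, rng_seed=seed + 2 + 2 * i)
        trials.append(res)
        labels_lm.append(LabelSeries(labels=gen, scheme=scheme))
    return SystemRun(potential=p, beta=beta, labels_md=labels_md,
                     trials=trials, labels_lm=labels_lm, statemap=statemap)


def compare_state_probabilities(run: SystemRun,
                                n_segments: int = 20) -> pd.DataFrame:
    """Per-state comparison of simulated vs generated occupancy.

    The z-score uses the combined standard error
    sqrt(se_md^2 + se_lm^2); agreement within 2 means the generated
    Boltzmann statistics are indistinguishable from the input's at the
    comparison's own noise level (trajectory noise + training-trial
    variability)."""
    a = run.state_probabilities("md", n_segments)
    b = run.state_probabilities("lm", n_segments)
    se = np.sqrt(a["se"] ** 2 + b["se"] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(a["probability"] - b["probability"]) / se,
                     np.where(a["probability"] == b["probability"], 0.0, np.inf))
    return pd.DataFrame({
        "state": a["state"], "p_md": a["probability"], "se_md": a["se"],
        "p_lm": b["probability"], "se_lm": b["se"], "z": z,
    })


def compare_commit_curves(run: SystemRun, commit_times=None,
                          n_segments: int = 20) -> pd.DataFrame:
    """Commit-curve comparison per ordered pair and commit time, with the
    combined-SE z-score; zero-count grid points on both sides count as
    agreeing (z = 0)."""
    if commit_times is None:
        commit_times = np.arange(1, 201)
    ca = run.commit_curve("md", commit_times, n_segments)
    cb = run.commit_curve("lm", commit_times, n_segments)
    rows = []
    for pair in ca.counts:
        ma, sa = ca.counts[pair], ca.standard_errors[pair]
        mb, sb = cb.counts[pair], cb.standard_errors[pair]
        se = np.sqrt(sa**2 + sb**2)
        diff = np.abs(ma - mb)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf))
        for k, ct in enumerate(ca.commit_times):
            rows.append({"pair": f"{pair[0]}->{pair[1]}",
                         "commit_time": int(ct), "count_md": ma[k],
                         "count_lm": mb[k], "z": z[k]})
    return pd.DataFrame(rows)
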