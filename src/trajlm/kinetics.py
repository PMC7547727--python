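"""Trajectory analysis: Boltzmann statistics, commit-time kinetics, and the
embedding-based kinetic distance.

State assignment maps discretization labels onto metastable states (wells);
occupancy counting gives Boltzmann probabilities and free energies with
standard errors over contiguous segments.  Kinetics are characterized by
commit-time transition counting: a trajectory has *committed* to a state
only after spending at least ``commit_time`` consecutive samples there, and
transition counts between committed visits are reported as a function of
commit time.

Two kinetic distances are compared per state pair {l, m}:

* the embedding ansatz ``t_lm = 1 / (Q_l Q_lm + Q_m Q_ml)`` where
  ``Q_lm = softmax_m(x_m . x_l)`` comes from the model's embedding vectors
  and ``Q_l`` is the model's Boltzmann probability of the state, and
* the counted commute time ``tau_lm = T / <N_lm>``, with ``N_lm`` the number
  of transitions between l and m (both directions) averaged over a grid of
  commit times.

Both are min-max rescaled to [0, 1] for comparison; the claim under test is
that the embedding distance reflects connectivity of the underlying 2-D
landscape even when the 1-D projection is kinetically misleading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import DiscretizationScheme

__all__ = [
    "StateMap", "CommitCurve", "KineticDistanceTable",
    "assign_states", "state_probabilities", "free_energy",
    "commit_transitions", "commit_curve",
    "embedding_transition_matrix", "kinetic_distance",
    "counted_commute_time", "rescale_unit",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class StateMap:
    """Label -> metastable-state assignment; UNASSIGNED marks barrier bins."""

    n_states: int
    assignment: np.ndarray  # (n_labels,) ints in {-1, 0..n_states-1}

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.int64)
        if a.max(initial=UNASSIGNED) >= self.n_states:
            raise ValueError("state id out of range")
        for s in range(self.n_states):
            if not np.any(a == s):
                raise ValueError(f"state {s} has no labels assigned")
        object.__setattr__(self, "assignment", a)

    def states_of(self, labels: np.ndarray) -> np.ndarray:
        return self.assignment[np.asarray(labels, dtype=np.int64)]

    def labels_of(self, state: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == state)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(l, m) for l in range(self.n_states)
                for m in range(l + 1, self.n_states)]


@dataclass(frozen=True)
class CommitCurve:
    """Mean transition counts per ordered state pair vs commit time."""

    commit_times: np.ndarray                 # (K,)
    counts: dict                             # (l, m) -> (K,) mean per segment
    standard_errors: dict                    # (l, m) -> (K,)
    n_segments: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (l, m), mean in self.counts.items():
            se = self.standard_errors[(l, m)]
            for k, ct in enumerate(self.commit_times):
                rows.append({"pair": f"{l}->{m}", "commit_time": int(ct),
                             "count_mean": mean[k], "count_se": se[k]})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class KineticDistanceTable:
    """Embedding-ansatz times t_lm and counted commute times tau_lm."""

    pairs: list
    t_lm: np.ndarray
    tau_lm: np.ndarray
    t_rescaled: np.ndarray
    tau_rescaled: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair": [f"{l}-{m}" for l, m in self.pairs],
            "t_lm": self.t_lm, "tau_lm": self.tau_lm,
            "t_rescaled": self.t_rescaled, "tau_rescaled": self.tau_rescaled,
        })


# -- state assignment -------------------------------------------------------

def assign_states(scheme: DiscretizationScheme, minima_projections,
                  radius: float) -> StateMap:
    """Assign each label to the metastable state whose projected minimum is
    within ``radius`` of the label's representative value (nearest wins,
    ties to the lower state id); labels near no minimum stay unassigned."""
    minima = np.asarray(minima_projections, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(np.unique(minima)) != len(minima):
        raise ValueError("minima projections must be distinct")
    reps = scheme.representative_values
    dist = np.abs(reps[:, None] - minima[None, :])  # (n_labels, n_states)
    nearest = np.argmin(dist, axis=1)  # argmin resolves ties to lower id
    assignment = np.where(dist[np.arange(len(reps)), nearest] <= radius,
                          nearest, UNASSIGNED)
    return StateMap(n_states=len(minima), assignment=assignment)


# -- Boltzmann statistics ---------------------------------------------------

def _segments(arr: np.ndarray, n_segments: int) -> list[np.ndarray]:
    return [s for s in np.array_split(arr, n_segments)]


def segment_state_probabilities(labels, statemap: StateMap,
                                n_segments: int) -> np.ndarray:
    """(n_segments, n_states) occupancy fractions among assigned samples,
    one row per contiguous segment."""
    labels = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    states = statemap.states_of(labels)
    per_seg = []
    for k, seg in enumerate(_segments(states, n_segments)):
        assigned = seg[seg != UNASSIGNED]
        if assigned.size == 0:
            raise ValueError(f"segment {k} contains no assigned samples")
        per_seg.append(np.bincount(assigned, minlength=statemap.n_states)
                       / assigned.size)
    return np.array(per_seg)


def state_probabilities(labels, statemap: StateMap,
                        n_segments: int = 20) -> pd.DataFrame:
    """Occupancy fraction per state among assigned samples, with the
    standard error over ``n_segments`` contiguous segments."""
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    per_seg = segment_state_probabilities(labels, statemap, n_segments)
    mean = per_seg.mean(axis=0)
    se = per_seg.std(axis=0) / np.sqrt(n_segments)
    return pd.DataFrame({"state": np.arange(statemap.n_states),
                         "probability": mean, "se": se})


def free_energy(probabilities, beta: float) -> np.ndarray:
    """F_i = -(1/beta) ln P_i; zero probability yields +inf, not an error."""
    p = np.asarray(getattr(probabilities, "probability", probabilities),
                   dtype=float)
    with np.errstate(divide="ignore"):
        return -np.log(p) / beta


# -- commit-time kinetics ---------------------------------------------------

def _committed_runs(states: np.ndarray, commit_time: int) -> np.ndarray:
    """State sequence of committed visits after dropping unassigned samples,
    run-length encoding, keeping runs >= commit_time, and merging repeats."""
    s = states[states != UNASSIGNED]
    if s.size == 0:
        return np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [s.size]]))
    run_states = s[starts]
    committed = run_states[lengths >= commit_time]
    if committed.size == 0:
        return committed
    # skipping uncommitted excursions can leave equal neighbours; merge them
    keep = np.concatenate([[True], np.diff(committed) != 0])
    return committed[keep]


def commit_transitions(labels, statemap: StateMap,
                       commit_time: int) -> dict[tuple[int, int], int]:
    """Count transitions between consecutive committed visits (ordered pairs)."""
    if commit_time < 1:
        raise ValueError("commit_time must be >= 1")
    labels = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    states = statemap.states_of(labels)
    runs = _committed_runs(states, commit_time)
    counts = {(l, m): 0 for l in range(statemap.n_states)
              for m in range(statemap.n_states) if l != m}
    if runs.size >= 2:
        for l, m in zip(runs[:-1], runs[1:]):
            counts[(int(l), int(m))] += 1
    return counts


def segment_commit_counts(labels, statemap: StateMap, commit_times,
                          n_segments: int) -> tuple[np.ndarray, list]:
    """(n_segments, n_commit_times, n_ordered_pairs) committed-transition
    counts per contiguous segment, plus the ordered-pair list."""
    commit_times = np.asarray(commit_times, dtype=np.int64)
    if np.any(np.diff(commit_times) <= 0):
        raise ValueError("commit_times must be strictly increasing")
    labels = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    states = statemap.states_of(labels)
    pairs = [(l, m) for l in range(statemap.n_states)
             for m in range(statemap.n_states) if l != m]
    per_seg = np.zeros((n_segments, len(commit_times), len(pairs)))
    for si, seg in enumerate(_segments(states, n_segments)):
        # run-length encode once per segment; filter per commit time
        s = seg[seg != UNASSIGNED]
        if s.size == 0:
            continue
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate([[0], change])
        lengths = np.diff(np.concatenate([starts, [s.size]]))
        run_states = s[starts]
        for ci, ct in enumerate(commit_times):
            committed = run_states[lengths >= ct]
            if committed.size < 2:
                continue
            keep = np.concatenate([[True], np.diff(committed) != 0])
            committed = committed[keep]
            trans = np.stack([committed[:-1], committed[1:]], axis=1)
            for pi, (l, m) in enumerate(pairs):
                per_seg[si, ci, pi] = np.sum((trans[:, 0] == l) & (trans[:, 1] == m))
    return per_seg, pairs


def commit_curve(labels, statemap: StateMap, commit_times,
                 n_segments: int = 20) -> CommitCurve:
    """Per-segment mean and standard error of commit transition counts over
    a grid of commit times."""
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2 (single segment has no SE)")
    per_seg, pairs = segment_commit_counts(labels, statemap, commit_times,
                                           n_segments)
    commit_times = np.asarray(commit_times, dtype=np.int64)
    mean = per_seg.mean(axis=0)
    se = per_seg.std(axis=0) / np.sqrt(n_segments)
    return CommitCurve(
        commit_times=commit_times,
        counts={p: mean[:, i] for i, p in enumerate(pairs)},
        standard_errors={p: se[:, i] for i, p in enumerate(pairs)},
        n_segments=n_segments,
    )


# -- embedding-based kinetic distance ---------------------------------------

def embedding_transition_matrix(embedding: np.ndarray) -> np.ndarray:
    """Transition-probability ansatz from embedding-vector dot products:
    ``Q[l, m] = exp(x_m . x_l) / sum_k exp(x_k . x_l)``."""
    emb = np.asarray(embedding, dtype=float)  # (M, N), columns are x_k
    dots = emb.T @ emb  # (N, N), dots[l, m] = x_l . x_m
    shifted = dots - dots.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _state_representatives(labels, statemap: StateMap) -> np.ndarray:
    """Most-occupied label of each state in the given label series."""
    labels = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    n_labels = statemap.assignment.size
    occ = np.bincount(labels, minlength=n_labels)
    reps = np.empty(statemap.n_states, dtype=np.int64)
    for s in range(statemap.n_states):
        members = statemap.labels_of(s)
        reps[s] = members[np.argmax(occ[members])]
    return reps


def kinetic_distance(q: np.ndarray, labels, statemap: StateMap,
                     aggregate: str = "weighted") -> tuple[list, np.ndarray]:
    """Embedding-ansatz interconversion times t_lm per unordered state pair.

    ``k_lm = Q_l Q_lm + Q_m Q_ml`` and ``t_lm = 1 / k_lm``, where Q_l is the
    state's Boltzmann probability in the (model-generated) label series and
    Q_lm the ansatz transition probability.  ``aggregate`` controls the
    label->state collapse: "modal" represents each state by its most
    occupied label; "weighted" averages Q over in-state labels with
    occupancy weights.
    """
    q = np.asarray(q, dtype=float)
    labels = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    occ = np.bincount(labels, minlength=statemap.assignment.size).astype(float)
    occ_frac = occ / occ.sum()
    pairs = statemap.pairs
    t = np.empty(len(pairs))
    if aggregate == "modal":
        reps = _state_representatives(labels, statemap)
        for i, (l, m) in enumerate(pairs):
            a, b = reps[l], reps[m]
            k = occ_frac[a] * q[a, b] + occ_frac[b] * q[b, a]
            t[i] = 1.0 / k if k > 0 else np.inf
    elif aggregate == "weighted":
        for i, (l, m) in enumerate(pairs):
            la, lb = statemap.labels_of(l), statemap.labels_of(m)
            wa = occ_frac[la] / max(occ_frac[la].sum(), 1e-300)
            wb = occ_frac[lb] / max(occ_frac[lb].sum(), 1e-300)
            q_lm = wa @ q[np.ix_(la, lb)] @ wb
            q_ml = wb @ q[np.ix_(lb, la)] @ wa
            p_l, p_m = occ_frac[la].sum(), occ_frac[lb].sum()
            k = p_l * q_lm + p_m * q_ml
            t[i] = 1.0 / k if k > 0 else np.inf
    else:
        raise ValueError("aggregate must be 'modal' or 'weighted'")
    return pairs, t


def counted_commute_time(labels, statemap: StateMap,
                         commit_times) -> tuple[list, np.ndarray]:
    """Counted commute times tau_lm = T / <N_lm> per unordered pair, with
    N_lm (both directions summed) averaged over the commit-time grid."""
    labels = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    commit_times = np.asarray(commit_times, dtype=np.int64)
    states = statemap.states_of(labels)
    pairs = statemap.pairs
    totals = np.zeros(len(pairs))
    for ct in commit_times:
        runs = _committed_runs(states, int(ct))
        if runs.size < 2:
            continue
        trans = np.stack([runs[:-1], runs[1:]], axis=1)
        for i, (l, m) in enumerate(pairs):
            fwd = np.sum((trans[:, 0] == l) & (trans[:, 1] == m))
            bwd = np.sum((trans[:, 0] == m) & (trans[:, 1] == l))
            totals[i] += fwd + bwd
    mean_counts = totals / len(commit_times)
    with np.errstate(divide="ignore"):
        tau = np.where(mean_counts > 0, labels.size / mean_counts, np.inf)
    return pairs, tau


def rescale_unit(values) -> np.ndarray:
    """Min-max rescale to [0, 1]; an all-equal input maps to all 0.5.

    Infinite entries (pairs with no observed transitions) map to 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to rescale")
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("no finite values to rescale")
    lo, hi = v[finite].min(), v[finite].max()
    if hi == lo:
        out = np.full_like(v, 0.5)
        out[~finite] = 1.0
        return out
    out = (v - lo) / (hi - lo)
    out[~finite] = 1.0
    return np.clip(out, 0.0, 1.0)


def kinetic_distance_table(q, gen_labels, ref_labels, statemap: StateMap,
                           commit_times, aggregate: str = "weighted"
                           ) -> KineticDistanceTable:
    """Convenience wrapper building the full comparison table: embedding
    times from the generated series, counted commute times from the
    reference series, both min-max rescaled."""
    pairs, t = kinetic_distance(q, gen_labels, statemap, aggregate=aggregate)
    _, tau = counted_commute_time(ref_labels, statemap, commit_times)
    return KineticDistanceTable(
        pairs=pairs, t_lm=t, tau_lm=tau,
        t_rescaled=rescale_unit(t), tau_rescaled=rescale_unit(tau),
    )
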