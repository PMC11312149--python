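"""Chromatin-state transition counting and permutation-null enrichment.

For two conditions A and B sharing a bin grid and a state alphabet, the
observed count ``O[s1, s2]`` is the number of bins in state ``s1`` in A and
``s2`` in B. The null expectation ``E`` is the mean of ``O`` over uniform
genome-wide shuffles of the B state vector (A held fixed); its closed form
is the product of marginals ``E[s1, s2] = n_A(s1) * n_B(s2) / N``.

The enrichment score is ``ES = O / E`` and the directional fold enrichment
``FE(s1->s2) = ES(s1->s2) / ES(s2->s1)``, which controls for the overall
similarity between the two states: a pair of states that simply co-occur a
lot inflates both directions equally and cancels out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import StateTrack


@dataclass
class TransitionCounts:
    states: tuple[str, ...]
    O: np.ndarray = field(repr=False)  # (K, K) int64, rows = state in A
    N: int = 0

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O, dtype=np.int64)
        k = len(self.states)
        if self.O.shape != (k, k):
            raise ValueError(f"O must be {k}x{k}, got {self.O.shape}")
        if (self.O < 0).any():
            raise ValueError("negative transition count")
        if self.O.sum() != self.N:
            raise ValueError(f"sum(O)={self.O.sum()} != N={self.N}")


@dataclass
class TransitionEnrichment:
    states: tuple[str, ...]
    O: np.ndarray = field(repr=False)
    E: np.ndarray = field(repr=False)
    ES: np.ndarray = field(repr=False)
    FE: np.ndarray = field(repr=False)  # NaN where undefined
    n_perm: int | None = None
    seed: int | None = None

    def to_frame(self, min_fe: float = 1.5, min_bins: int = 200) -> pd.DataFrame:
        """Tidy per-transition table (s_from, s_to, O, E, ES, FE, display)."""
        mask = mask_for_display(self, min_fe=min_fe, min_bins=min_bins)
        k = len(self.states)
        i, j = np.divmod(np.arange(k * k), k)
        return pd.DataFrame(
            {
                "s_from": np.asarray(self.states, dtype=object)[i],
                "s_to": np.asarray(self.states, dtype=object)[j],
                "O": self.O.ravel(),
                "E": self.E.ravel(),
                "ES": self.ES.ravel(),
                "FE": self.FE.ravel(),
                "display": mask.ravel(),
            }
        )


def _check_pair(track_a: StateTrack, track_b: StateTrack) -> None:
    if track_a.grid != track_b.grid:
        raise ValueError("tracks are on different grids")
    if track_a.alphabet != track_b.alphabet:
        raise ValueError("tracks use different state alphabets")
    if track_a.codes.size == 0:
        raise ValueError("empty tracks")


def count_transitions(track_a: StateTrack, track_b: StateTrack) -> TransitionCounts:
    """Observed per-bin joint state counts O[s_in_A, s_in_B]."""
    _check_pair(track_a, track_b)
    k = len(track_a.alphabet)
    joint = track_a.codes.astype(np.int64) * k + track_b.codes
    O = np.bincount(joint, minlength=k * k).reshape(k, k)
    return TransitionCounts(states=track_a.alphabet, O=O, N=int(track_a.codes.size))


def expected_counts(
    track_a: StateTrack,
    track_b: StateTrack,
    method: str = "analytic",
    n_perm: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Null-expected transition counts.

    ``analytic`` returns the closed-form product of marginals; ``permutation``
    averages observed counts over ``n_perm`` uniform shuffles of the B state
    vector (requires ``seed``). Both preserve the per-condition marginals, so
    the expectations agree as ``n_perm`` grows.
    """
    _check_pair(track_a, track_b)
    k = len(track_a.alphabet)
    n = track_a.codes.size
    if method == "analytic":
        n_a = np.bincount(track_a.codes, minlength=k).astype(float)
        n_b = np.bincount(track_b.codes, minlength=k).astype(float)
        return np.outer(n_a, n_b) / n
    if method == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if seed is None:
            raise ValueError("permutation mode requires a seed")
        rng = np.random.default_rng(seed)
        base = track_a.codes.astype(np.int64) * k
        acc = np.zeros(k * k, dtype=np.int64)
        b = track_b.codes
        for _ in range(n_perm):
            acc += np.bincount(base + rng.permutation(b), minlength=k * k)
        return (acc / n_perm).reshape(k, k)
    raise ValueError(f"unknown method {method!r}")


def fold_enrichment(counts: TransitionCounts, E: np.ndarray) -> TransitionEnrichment:
    """Enrichment score O/E and opposite-direction fold enrichment.

    FE is NaN where the reverse enrichment score is zero (no observed bins
    in the opposite direction); the diagonal is 1 by construction wherever
    defined.
    """
    E = np.asarray(E, dtype=float)
    if E.shape != counts.O.shape:
        raise ValueError("E shape mismatch")
    if ((E <= 0) & (counts.O > 0)).any():
        raise ValueError("E is zero where O > 0: impossible marginal")
    with np.errstate(divide="ignore", invalid="ignore"):
        ES = np.where(E > 0, counts.O / E, np.nan)
        FE = np.where(ES.T > 0, ES / ES.T, np.nan)
    return TransitionEnrichment(
        states=counts.states, O=counts.O, E=E, ES=ES, FE=FE
    )


def mask_for_display(
    enr: TransitionEnrichment, min_fe: float = 1.5, min_bins: int = 200
) -> np.ndarray:
    """Display category per cell: 'colored', 'uncolored' or 'grey'.

    A cell is colored when FE > ``min_fe`` and O >= ``min_bins``; poorly
    represented transitions (O < ``min_bins``) are greyed out.
    """
    out = np.full(enr.O.shape, "uncolored", dtype=object)
    with np.errstate(invalid="ignore"):
        out[(enr.FE > min_fe) & (enr.O >= min_bins)] = "colored"
    out[enr.O < min_bins] = "grey"
    return out


def transition_enrichment(
    track_a: StateTrack,
    track_b: StateTrack,
    method: str = "permutation",
    n_perm: int = 1000,
    seed: int | None = None,
) -> TransitionEnrichment:
    """Convenience wrapper: count, null expectation, fold enrichment."""
    counts = count_transitions(track_a, track_b)
    E = expected_counts(track_a, track_b, method=method, n_perm=n_perm, seed=seed)
    enr = fold_enrichment(counts, E)
    if method == "permutation":
        enr.n_perm, enr.seed = n_perm, seed
    return enr
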