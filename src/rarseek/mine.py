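"""Predictive association-rule mining over binary genomic markers.

Greedy FOIL-style rule induction in the CPAR family: for each class, rules
are grown literal by literal, choosing the literal with the best weighted
FOIL gain and branching on every literal whose gain comes within
``gain_similarity`` of the best. A rule body is closed when no literal
reaches ``min_gain``. After each rule, the weights of the positive examples
it covers are multiplied by ``decay`` and induction restarts, so later
rules focus on the not-yet-covered examples; the class loop stops when the
remaining positive weight drops below ``min_weight_frac`` of the initial
total.

Reported statistics are exact unweighted recounts on the raw matrix; rules
are ranked by Laplace accuracy (N_c + 1) / (N_total + m), the smoothed
precision with m classes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEAD, ALIVE = 0, 1  # survival-status class coding


def laplace_accuracy(n_c: int, n_total: int, m: int = 2) -> float:
    """Smoothed rule precision (N_c + 1) / (N_total + m)."""
    if n_c > n_total:
        raise ValueError("N_c cannot exceed N_total")
    if n_c < 0 or n_total < 0:
        raise ValueError("counts must be non-negative")
    if m < 2:
        raise ValueError("at least two classes required")
    return (n_c + 1) / (n_total + m)


@dataclass(frozen=True)
class CparParams:
    min_gain: float = 0.7
    decay: float = 2 / 3
    gain_similarity: float = 0.99
    best_k: int = 5
    min_laplace_report: float = 0.75
    min_weight_frac: float = 0.05
    max_literals: int | None = None
    allow_negative_literals: bool = False

    def __post_init__(self):
        if not 0 < self.decay < 1:
            raise ValueError("decay must be in (0, 1)")
        if not 0 < self.gain_similarity <= 1:
            raise ValueError("gain_similarity must be in (0, 1]")


@dataclass(frozen=True)
class AssociationRule:
    """antecedent (marker, value literals) => predicted_class."""

    antecedent: tuple[tuple[str, int], ...]
    predicted_class: int
    n_total: int
    n_c: int
    laplace: float

    def describe(self) -> str:
        body = " AND ".join(f"{m}={v}" for m, v in self.antecedent)
        cls = "dead" if self.predicted_class == DEAD else "alive"
        return f"{body} => {cls}"


def _as_matrix(markers) -> tuple[np.ndarray, list[str]]:
    if isinstance(markers, pd.DataFrame):
        return markers.to_numpy(dtype=np.int8), [str(c) for c in markers.columns]
    arr = np.asarray(markers, dtype=np.int8)
    return arr, [f"M{j}" for j in range(arr.shape[1])]


def _foil_gains(X, w, pos_mask, satisfied, literals, used):
    """Weighted FOIL gain of each candidate literal given the current body.

    gain(l) = P1 * (log2(P1/(P1+N1)) - log2(P0/(P0+N0))), with P/N the
    positive/negative example weight before (0) and after (1) adding l.
    """
    wp = w * (pos_mask & satisfied)
    wn = w * (~pos_mask & satisfied)
    p0, n0 = wp.sum(), wn.sum()
    if p0 <= 0:
        return np.full(len(literals), -np.inf)
    base = math.log2(p0 / (p0 + n0))
    gains = np.full(len(literals), -np.inf)
    for i, (j, v) in enumerate(literals):
        if (j, v) in used or (j, 1 - v) in used:
            continue
        match = X[:, j] == v
        p1 = wp[match].sum()
        n1 = wn[match].sum()
        if p1 <= 0:  # literal kills every positive example
            continue
        gains[i] = p1 * (math.log2(p1 / (p1 + n1)) - base)
    return gains


def mine_rules(markers, classes, params: CparParams = CparParams(),
               seed: int | None = None) -> list[AssociationRule]:
    """Mine class-predictive rules from a binary marker matrix.

    ``markers``: samples x markers DataFrame (or 0/1 array); ``classes``:
    per-sample class labels (0 dead / 1 alive). ``seed`` is accepted for
    interface symmetry; the procedure is deterministic (lexicographic
    tie-breaks). Returns rules sorted by Laplace accuracy (descending),
    ties by smaller antecedent then lexicographic body.
    """
    X, names = _as_matrix(markers)
    y = np.asarray(classes, dtype=int)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("markers and classes must align")
    if np.isnan(X.astype(float)).any():
        raise ValueError("marker matrix may not contain missing entries")
    class_values = sorted(set(y.tolist()))
    if len(class_values) < 2:
        raise ValueError("both classes must be present for rule mining")
    m = len(class_values)
    values = (1,) if not params.allow_negative_literals else (1, 0)
    literals = [(j, v) for j in range(X.shape[1]) for v in values]

    found: set[tuple[tuple[int, int], ...], int] = set()
    raw: list[tuple[tuple[tuple[int, int], ...], int]] = []

    for target in class_values:
        pos_mask = y == target
        w = np.ones(len(y))
        total0 = w[pos_mask].sum()
        guard = 0
        while w[pos_mask].sum() > params.min_weight_frac * total0:
            guard += 1
            if guard > 10 * len(y) * max(1, len(literals)):
                break  # defensive: should be unreachable
            new_rules: list[tuple[tuple[int, int], ...]] = []

            def grow(body: tuple[tuple[int, int], ...], satisfied: np.ndarray) -> None:
                if params.max_literals is not None and len(body) >= params.max_literals:
                    if body:
                        new_rules.append(body)
                    return
                gains = _foil_gains(X, w, pos_mask, satisfied, literals, set(body))
                best = gains.max()
                if not np.isfinite(best) or best < params.min_gain:
                    if body:
                        new_rules.append(body)
                    return
                for i in np.flatnonzero(gains >= params.gain_similarity * best):
                    j, v = literals[i]
                    grow(body + ((j, v),), satisfied & (X[:, j] == v))

            grow((), np.ones(len(y), dtype=bool))
            new_rules = [r for r in new_rules if r]
            progressed = False
            for body in new_rules:
                key = (tuple(sorted(body)), target)
                if key not in found:
                    found.add(key)
                    raw.append((tuple(sorted(body)), target))
                cover = pos_mask.copy()
                for j, v in body:
                    cover &= X[:, j] == v
                if w[cover].sum() > 0:
                    progressed = True
                w[cover] *= params.decay
            if not progressed:
                break

    rules = []
    for body, target in raw:
        sat = np.ones(len(y), dtype=bool)
        for j, v in body:
            sat &= X[:, j] == v
        n_total = int(sat.sum())
        n_c = int((sat & (y == target)).sum())
        rules.append(AssociationRule(
            antecedent=tuple((names[j], v) for j, v in body),
            predicted_class=target,
            n_total=n_total,
            n_c=n_c,
            laplace=laplace_accuracy(n_c, n_total, m),
        ))
    rules.sort(key=lambda r: (-r.laplace, len(r.antecedent), r.antecedent))
    return rules


def report_death_rules(rules: list[AssociationRule],
                       params: CparParams = CparParams()) -> list[AssociationRule]:
    """Rules predicting the death class with Laplace accuracy above the cutoff."""
    return [r for r in rules
            if r.predicted_class == DEAD and r.laplace > params.min_laplace_report]


def brute_force_best_laplace(markers, classes, max_literals: int = 3,
                             target_class: int | None = None) -> float:
    """Exhaustive Laplace optimum over positive-literal antecedents of bounded size.

    Independent of the greedy search; meant as a small-instance oracle.
    """
    X, _names = _as_matrix(markers)
    y = np.asarray(classes, dtype=int)
    m = len(set(y.tolist()))
    best = 0.0
    targets = [target_class] if target_class is not None else sorted(set(y.tolist()))
    for size in range(1, max_literals + 1):
        for combo in itertools.combinations(range(X.shape[1]), size):
            sat = np.all(X[:, combo] == 1, axis=1)
            n_total = int(sat.sum())
            for t in targets:
                n_c = int((sat & (y == t)).sum())
                best = max(best, laplace_accuracy(n_c, n_total, m))
    return best


def rules_table(rules: list[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "rule": r.describe(),
            "predicted_class": "dead" if r.predicted_class == DEAD else "alive",
            "n_total": r.n_total,
            "n_c": r.n_c,
            "laplace": round(r.laplace, 4),
        } for r in rules]
    )
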