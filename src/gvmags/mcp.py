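"""Major-capsid-protein (MCP) lineage survey.

Environmental MCPs are assigned to NCLDV lineages from their profile of
search scores against a panel of lineage-specific MCP models: a one-vs-rest
logistic-regression classifier is trained on lineage-labelled score vectors
and applied to unbinned environmental proteins.  A protein is assigned to
the top lineage only when the classifier's probability exceeds 50 %;
otherwise it is called "novel".  Habitat counts are then corrected for the
lineage's average MCP copy number per genome, so multi-capsid lineages are
not over-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier

__all__ = [
    "NOVEL",
    "LineageAssignment",
    "dedupe_identical",
    "LineageClassifier",
    "train_lineage_classifier",
    "assign",
    "normalize_counts",
]

NOVEL = "novel"
ASSIGNMENT_PROBABILITY = 0.5  # strictly greater than this to assign


def dedupe_identical(sequences: Mapping[str, str]) -> dict[str, str]:
    """Collapse proteins with identical amino-acid sequences.

    Exact string equality; the representative of each duplicate set is the
    lexicographically first protein id.  Case-differing sequences are kept
    distinct (normalize upstream if the inputs mix cases).
    """
    rep: dict[str, str] = {}
    for pid in sorted(sequences):
        seq = sequences[pid]
        if seq not in rep:
            rep[seq] = pid
    return {pid: seq for seq, pid in sorted(rep.items(), key=lambda kv: kv[1])}


@dataclass
class LineageClassifier:
    """One-vs-rest panel of per-lineage logistic models.

    ``normalize`` selects how per-protein probabilities are reported: the
    default uses each lineage's raw (calibrated binary) probability, under
    which the "> 50 % or novel" rule acts as out-of-distribution detection —
    a protein resembling none of the lineages scores low against every
    binary model.  Normalizing the one-vs-rest probabilities to sum to one
    (the alternative reading) is selectable but rescales even uniformly poor
    matches up to 1/k..1, blunting novel detection.
    """

    estimator: OneVsRestClassifier
    lineages: tuple[str, ...]
    model_columns: tuple[str, ...]
    normalize: bool = False

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        if self.normalize:
            return self.estimator.predict_proba(X)
        cols = [est.predict_proba(X)[:, 1] for est in self.estimator.estimators_]
        return np.column_stack(cols)


def train_lineage_classifier(
    scores: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    *,
    min_members: int = 5,
    normalize: bool = False,
) -> LineageClassifier:
    """Train the one-vs-rest logistic-regression lineage classifier.

    ``scores`` is a protein × lineage-model matrix of search scores (bits);
    missing scores should be 0 (no hit ≈ no affinity).  Each lineage needs at
    least ``min_members`` labelled members, mirroring the minimum number of
    MCP copies required to build a lineage model in the first place.
    Deterministic given ``seed``.
    """
    y = np.asarray(labels)
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("training requires at least two lineages")
    starved = uniq[counts < min_members]
    if len(starved):
        raise ValueError(
            f"lineages with fewer than {min_members} members: {list(starved)}"
        )
    est = OneVsRestClassifier(
        LogisticRegression(solver="lbfgs", max_iter=2000, random_state=seed)
    )
    X = scores.to_numpy(dtype=float)
    est.fit(np.nan_to_num(X), y)
    return LineageClassifier(
        estimator=est,
        lineages=tuple(str(c) for c in est.classes_),
        model_columns=tuple(map(str, scores.columns)),
        normalize=normalize,
    )


@dataclass(frozen=True)
class LineageAssignment:
    protein_id: str
    lineage: str  # a lineage name or "novel"
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def assign(
    model: LineageClassifier, scores: pd.DataFrame
) -> list[LineageAssignment]:
    """Assign proteins to lineages; "novel" when the top probability is
    50 % or below (strict > 0.5 required for a lineage call)."""
    if tuple(map(str, scores.columns)) != model.model_columns:
        raise ValueError("score columns do not match the trained model")
    proba = model.probabilities(np.nan_to_num(scores.to_numpy(dtype=float)))
    out = []
    for pid, row in zip(scores.index, proba):
        k = int(np.argmax(row))
        p = float(row[k])
        lineage = model.lineages[k] if p > ASSIGNMENT_PROBABILITY else NOVEL
        out.append(LineageAssignment(protein_id=str(pid), lineage=lineage, probability=p))
    return out


def normalize_counts(
    raw: pd.DataFrame, mean_copy_number: Mapping[str, float]
) -> pd.DataFrame:
    """Correct lineage × habitat MCP counts for per-genome copy number.

    ``corrected = raw / mean_copy_number[lineage]``, where the mean copy
    number is computed over the lineage's bins and reference genomes and is
    at least 1.  Raises if a lineage with counts lacks a copy number.
    """
    missing = [
        lin
        for lin in raw.index
        if lin not in mean_copy_number and raw.loc[lin].abs().sum() > 0
    ]
    if missing:
        raise KeyError(f"no mean copy number for lineages: {missing}")
    bad = [lin for lin, c in mean_copy_number.items() if c < 1]
    if bad:
        raise ValueError(f"mean copy numbers below 1 for: {bad}")
    divisors = pd.Series(
        {lin: mean_copy_number.get(lin, 1.0) for lin in raw.index}, dtype=float
    )
    return raw.div(divisors, axis=0)
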