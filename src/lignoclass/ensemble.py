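"""Voting committee of sparse linear SVMs and majority-weight feature selection.

A single penalty C picked by cross-validation is somewhat arbitrary: several
settings usually perform comparably well.  The committee therefore keeps the
five C values with the best leave-one-out macro-accuracy, retrains one model
per value on the full dataset, and classifies new genomes by majority vote.
Votes are reported with graded confidence symbols:

    positive votes   5     4     3–2    1     0
    symbol           ++    +     0      -     --
    call             degrader (>= 4), ambiguous (2–3), non-degrader (<= 1)

The committee also drives feature discovery: a protein family is called
distinctive of degraders when it receives a strictly positive weight in the
majority (>= 3 of 5) of the member models.  Agreement across differently
regularised models guards against the arbitrariness of any single sparse
solution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import svm
from .annotation import AnnotationProfile
from .evaluation import CGrid, GridPoint, MetricSet, grid_search
from .features import (
    FeatureMatrix,
    FeatureScaler,
    encode_profile,
    scale_apply,
    scale_training,
)

N_MEMBERS = 5

#: symbol per number of positive votes
DEFAULT_VOTE_SYMBOLS: Mapping[int, str] = {5: "++", 4: "+", 3: "0", 2: "0", 1: "-", 0: "--"}

DEGRADER = "degrader"
NON_DEGRADER = "non-degrader"
AMBIGUOUS = "ambiguous"


def call_from_votes(positive_votes: int) -> str:
    if positive_votes >= 4:
        return DEGRADER
    if positive_votes <= 1:
        return NON_DEGRADER
    return AMBIGUOUS


@dataclass(frozen=True)
class VoteResult:
    """Committee verdict for one sample."""

    sample_id: str
    positive_votes: int
    symbol: str
    call: str
    decision_values: tuple


@dataclass(frozen=True)
class SelectedFamily:
    family_id: str
    support: int  # members with strictly positive weight (3..5)
    mean_positive_weight: float


@dataclass(frozen=True)
class FeatureRanking:
    """Families distinctive of degraders, ordered by support then mean weight."""

    selected: tuple

    @property
    def family_ids(self) -> list:
        return [s.family_id for s in self.selected]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.family_id, s.support, s.mean_positive_weight) for s in self.selected],
            columns=["family_id", "support", "mean_positive_weight"],
        )


@dataclass
class EnsembleModel:
    """The five most accurate models, retrained on the full dataset."""

    members: tuple
    grid_ranking: tuple  # GridPoint ranking the members came from
    scaler: Optional[FeatureScaler]
    family_ids: list
    encoding: str
    vote_symbols: dict = field(default_factory=lambda: dict(DEFAULT_VOTE_SYMBOLS))

    def __post_init__(self) -> None:
        if len(self.members) != N_MEMBERS:
            raise ValueError(f"a voting committee has exactly {N_MEMBERS} members")
        for member in self.members:
            if list(member.family_ids) != list(self.family_ids):
                raise ValueError("all members must share the ensemble family universe")
            if member.encoding != self.encoding:
                raise ValueError("all members must share the ensemble encoding")
        if set(self.vote_symbols) != set(range(N_MEMBERS + 1)):
            raise ValueError("vote symbol mapping must cover 0..5 positive votes")

    @property
    def member_cs(self) -> list:
        return [m.C for m in self.members]


def build_ensemble(
    dataset: FeatureMatrix,
    grid: CGrid = CGrid.default(),
    tolerance: float = 1e-6,
) -> EnsembleModel:
    """Rank the C grid by leave-one-out macro-accuracy and train the committee.

    The five top-ranked C values each yield one member trained on all samples
    (ties in the ranking favour the smaller, sparser C).  The scaler, where
    the encoding needs one, is fit on the full dataset.
    """
    if len(grid.values) < N_MEMBERS:
        raise ValueError(
            f"the penalty grid must offer at least {N_MEMBERS} values, got {len(grid.values)}"
        )
    ranking = grid_search(dataset, grid, tolerance)
    scaled, scaler = scale_training(dataset)
    members = tuple(
        svm.train(
            scaled.X, scaled.labels, point.C, tolerance,
            family_ids=scaled.family_ids, encoding=scaled.encoding,
        )
        for point in ranking[:N_MEMBERS]
    )
    return EnsembleModel(
        members=members,
        grid_ranking=tuple(ranking),
        scaler=scaler,
        family_ids=list(dataset.family_ids),
        encoding=dataset.encoding,
    )


def _encode_for_committee(ensemble: EnsembleModel, profile: AnnotationProfile) -> np.ndarray:
    x = encode_profile(profile, ensemble.family_ids, ensemble.encoding)
    row = FeatureMatrix(
        sample_ids=[profile.sample_id],
        family_ids=list(ensemble.family_ids),
        X=x[None, :],
        encoding=ensemble.encoding,
    )
    return scale_apply(ensemble.scaler, row).X[0]


def vote(ensemble: EnsembleModel, profile: AnnotationProfile) -> VoteResult:
    """Classify one annotation profile by committee majority vote."""
    x = _encode_for_committee(ensemble, profile)
    values = tuple(svm.predict(member, x)[1] for member in ensemble.members)
    positive = sum(1 for v in values if v > 0)
    return VoteResult(
        sample_id=profile.sample_id,
        positive_votes=positive,
        symbol=ensemble.vote_symbols[positive],
        call=call_from_votes(positive),
        decision_values=values,
    )


def vote_profiles(
    ensemble: EnsembleModel, profiles: Sequence[AnnotationProfile]
) -> List[VoteResult]:
    return [vote(ensemble, profile) for profile in profiles]


def select_features(ensemble: EnsembleModel, min_support: int = 3) -> FeatureRanking:
    """Families with strictly positive weight in >= *min_support* of 5 members.

    The mean positive weight averages over the supporting members only.
    Ordering: support descending, mean positive weight descending, family id
    ascending (deterministic under member permutation).
    """
    W = np.vstack([m.w for m in ensemble.members])
    positive = W > svm.NONZERO_TOL
    support = positive.sum(axis=0)
    selected = []
    for j, family in enumerate(ensemble.family_ids):
        if support[j] >= min_support:
            # sort before averaging so the result is exactly invariant to
            # member order (float summation is not associative)
            mean_pos = float(np.sort(W[positive[:, j], j]).mean())
            selected.append(
                SelectedFamily(
                    family_id=family, support=int(support[j]), mean_positive_weight=mean_pos
                )
            )
    selected.sort(key=lambda s: (-s.support, -s.mean_positive_weight, s.family_id))
    return FeatureRanking(selected=tuple(selected))


def votes_to_frame(results: Sequence[VoteResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id,
            "positive_votes": r.positive_votes,
            "symbol": r.symbol,
            "call": r.call,
        }
        for k, v in enumerate(r.decision_values, start=1):
            row[f"decision_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# --- serialization ----------------------------------------------------------
# One JSON document holds the committee: member weights are stored sparsely
# (nonzero entries only) since L1 models are mostly zeros.

_FORMAT = "lignoclass-ensemble-v1"


def save_ensemble(ensemble: EnsembleModel, path) -> None:
    doc = {
        "format": _FORMAT,
        "encoding": ensemble.encoding,
        "family_ids": list(ensemble.family_ids),
        "vote_symbols": {str(k): v for k, v in ensemble.vote_symbols.items()},
        "scaler": None
        if ensemble.scaler is None
        else {
            "family_ids": list(ensemble.scaler.family_ids),
            "mins": ensemble.scaler.mins.tolist(),
            "maxs": ensemble.scaler.maxs.tolist(),
        },
        "grid_ranking": [
            {
                "C": p.C,
                "recall": p.metrics.recall,
                "true_negative_rate": p.metrics.true_negative_rate,
                "macro_accuracy": p.metrics.macro_accuracy,
            }
            for p in ensemble.grid_ranking
        ],
        "members": [
            {
                "C": m.C,
                "weights": {
                    fam: float(w)
                    for fam, w in zip(m.family_ids, m.w)
                    if abs(w) > svm.NONZERO_TOL
                },
            }
            for m in ensemble.members
        ],
    }
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=1, sort_keys=True)
        handle.write("\n")


def load_ensemble(path) -> EnsembleModel:
    with open(path) as handle:
        doc = json.load(handle)
    if doc.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a serialized ensemble (format={doc.get('format')!r})")
    family_ids = [str(f) for f in doc["family_ids"]]
    index = {fam: j for j, fam in enumerate(family_ids)}
    members = []
    for entry in doc["members"]:
        w = np.zeros(len(family_ids))
        for fam, weight in entry["weights"].items():
            w[index[fam]] = weight
        members.append(
            svm.SparseLinearModel(
                w=w, C=float(entry["C"]), family_ids=family_ids, encoding=doc["encoding"]
            )
        )
    scaler = None
    if doc["scaler"] is not None:
        scaler = FeatureScaler(
            family_ids=[str(f) for f in doc["scaler"]["family_ids"]],
            mins=np.asarray(doc["scaler"]["mins"], dtype=float),
            maxs=np.asarray(doc["scaler"]["maxs"], dtype=float),
        )
    ranking = tuple(
        GridPoint(
            C=float(p["C"]),
            metrics=MetricSet(
                recall=float(p["recall"]),
                true_negative_rate=float(p["true_negative_rate"]),
                macro_accuracy=float(p["macro_accuracy"]),
            ),
        )
        for p in doc["grid_ranking"]
    )
    return EnsembleModel(
        members=tuple(members),
        grid_ranking=ranking,
        scaler=scaler,
        family_ids=family_ids,
        encoding=doc["encoding"],
        vote_symbols={int(k): v for k, v in doc["vote_symbols"].items()},
    )
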