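"""Feature encodings for annotation profiles.

Two encodings of a sample's protein-family content are supported:

``binary``
    presence/absence indicators — entry 1 iff the family is annotated at
    least once in the sample;
``frequency``
    relative frequencies — each family count divided by the total number of
    annotations in that sample, followed by per-family min–max scaling into
    [0, 1] learned on training rows only.

Binary indicators are already in [0, 1] and are used as-is; sum
normalisation and rescaling apply to the frequency encoding, where raw
relative abundances of individual families are small and unevenly spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import AnnotationProfile

BINARY = "binary"
FREQUENCY = "frequency"
_ENCODINGS = frozenset({BINARY, FREQUENCY})

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Samples × families numeric matrix with encoding metadata.

    ``labels``, when present, holds the phenotype of each sample: +1 for a
    plant-biomass degrader, -1 for a non-degrader.
    """

    sample_ids: list
    family_ids: list
    X: np.ndarray
    labels: Optional[np.ndarray] = None
    encoding: str = BINARY

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.encoding not in _ENCODINGS:
            raise ValueError(f"encoding must be one of {sorted(_ENCODINGS)}")
        if self.X.shape != (len(self.sample_ids), len(self.family_ids)):
            raise ValueError(
                f"X has shape {self.X.shape}, expected "
                f"({len(self.sample_ids)}, {len(self.family_ids)})"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValueError("labels length does not match sample count")
            if not np.isin(self.labels, (-1, 1)).all():
                raise ValueError("labels must be +1 or -1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.family_ids)

    def take(self, indices) -> "FeatureMatrix":
        """Row subset (used by cross-validation folds)."""
        indices = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            sample_ids=[self.sample_ids[i] for i in indices],
            family_ids=list(self.family_ids),
            X=self.X[indices],
            labels=None if self.labels is None else self.labels[indices],
            encoding=self.encoding,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, index=self.sample_ids, columns=self.family_ids)
        frame.index.name = "sample_id"
        return frame

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        if self.labels is not None:
            frame = frame.assign(label=self.labels)
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, encoding: str = BINARY) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        labels = None
        if "label" in frame.columns:
            labels = frame.pop("label").to_numpy(dtype=int)
        return cls(
            sample_ids=[str(s) for s in frame.index],
            family_ids=[str(c) for c in frame.columns],
            X=frame.to_numpy(dtype=float),
            labels=labels,
            encoding=encoding,
        )


def build_matrix(
    profiles: Sequence[AnnotationProfile],
    encoding: str = BINARY,
    labels: Optional[Mapping[str, int]] = None,
) -> FeatureMatrix:
    """Assemble profiles into a feature matrix.

    The family universe is the lexicographically ordered union of families
    over all profiles.  Binary encoding sets an entry to 1 iff the family has
    count >= 1; frequency encoding divides each count by the sample's total
    annotation count.

    Raises ``ValueError`` for an empty profile list, a zero-total profile
    under the frequency encoding (the offending sample is named), or a label
    map missing a sample.
    """
    if not profiles:
        raise ValueError("cannot build a feature matrix from zero profiles")
    if encoding not in _ENCODINGS:
        raise ValueError(f"encoding must be one of {sorted(_ENCODINGS)}")
    universe = sorted(set().union(*(set(p.counts) for p in profiles)))
    index = {fam: j for j, fam in enumerate(universe)}
    X = np.zeros((len(profiles), len(universe)))
    sample_ids = []
    for i, profile in enumerate(profiles):
        sample_ids.append(profile.sample_id)
        if encoding == FREQUENCY:
            total = profile.total
            if total == 0:
                raise ValueError(
                    f"sample {profile.sample_id!r} has no annotations; "
                    "frequency encoding is undefined"
                )
            for fam, count in profile.counts.items():
                X[i, index[fam]] = count / total
        else:
            for fam in profile.counts:
                X[i, index[fam]] = 1.0
    y = None
    if labels is not None:
        missing = [s for s in sample_ids if s not in labels]
        if missing:
            raise ValueError(f"label map is missing samples: {missing}")
        y = np.array([labels[s] for s in sample_ids], dtype=int)
    return FeatureMatrix(sample_ids=sample_ids, family_ids=universe, X=X, labels=y,
                         encoding=encoding)


@dataclass
class FeatureScaler:
    """Per-family min–max statistics learned on a training matrix."""

    family_ids: list
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if not (self.maxs >= self.mins).all():
            raise ValueError("per-family max must be >= min")


def fit_scaler(train: FeatureMatrix) -> FeatureScaler:
    """Learn per-family min and max on training rows only."""
    return FeatureScaler(
        family_ids=list(train.family_ids),
        mins=train.X.min(axis=0),
        maxs=train.X.max(axis=0),
    )


def apply_scaler(scaler: FeatureScaler, matrix: FeatureMatrix) -> FeatureMatrix:
    """Rescale each family as ``(v - min) / (max - min)``.

    A family that was constant on the training rows maps to 0.  Values from
    unseen data may fall outside [0, 1]; they are not clipped.  Families in
    *matrix* unknown to the scaler raise ``ValueError`` listing them.
    """
    known = {fam: j for j, fam in enumerate(scaler.family_ids)}
    unknown = [fam for fam in matrix.family_ids if fam not in known]
    if unknown:
        raise ValueError(f"scaler has no statistics for families: {unknown}")
    cols = np.array([known[fam] for fam in matrix.family_ids], dtype=int)
    mins = scaler.mins[cols]
    span = scaler.maxs[cols] - mins
    scaled = np.zeros_like(matrix.X)
    nonconstant = span > 0
    scaled[:, nonconstant] = (matrix.X[:, nonconstant] - mins[nonconstant]) / span[nonconstant]
    return FeatureMatrix(
        sample_ids=list(matrix.sample_ids),
        family_ids=list(matrix.family_ids),
        X=scaled,
        labels=matrix.labels,
        encoding=matrix.encoding,
    )


def scale_training(matrix: FeatureMatrix) -> Tuple[FeatureMatrix, Optional[FeatureScaler]]:
    """Fit-and-apply scaling appropriate to the encoding.

    Frequency matrices get min–max scaling (scaler returned for reuse on
    held-out rows); binary matrices pass through unchanged with scaler None.
    """
    if matrix.encoding == FREQUENCY:
        scaler = fit_scaler(matrix)
        return apply_scaler(scaler, matrix), scaler
    return matrix, None


def scale_apply(scaler: Optional[FeatureScaler], matrix: FeatureMatrix) -> FeatureMatrix:
    """Apply a previously fit scaler; identity when scaler is None (binary)."""
    if scaler is None:
        return matrix
    return apply_scaler(scaler, matrix)


def encode_profile(
    profile: AnnotationProfile,
    family_ids: Sequence[str],
    encoding: str,
) -> np.ndarray:
    """Project one profile onto a fixed family universe.

    Families absent from the universe are ignored with a logged warning.
    Frequency entries use the profile's full annotation total (including
    families outside the universe) as the denominator.
    """
    if encoding not in _ENCODINGS:
        raise ValueError(f"encoding must be one of {sorted(_ENCODINGS)}")
    index = {fam: j for j, fam in enumerate(family_ids)}
    unseen = sorted(set(profile.counts) - set(index))
    if unseen:
        logger.warning(
            "sample %s: ignoring %d families outside the model universe (e.g. %s)",
            profile.sample_id, len(unseen), ", ".join(unseen[:5]),
        )
    x = np.zeros(len(family_ids))
    if encoding == FREQUENCY:
        total = profile.total
        if total == 0:
            raise ValueError(
                f"sample {profile.sample_id!r} has no annotations; "
                "frequency encoding is undefined"
            )
        for fam, count in profile.counts.items():
            if fam in index:
                x[index[fam]] = count / total
    else:
        for fam in profile.counts:
            if fam in index:
                x[index[fam]] = 1.0
    return x


def export_rescaled_frequencies(
    matrix: FeatureMatrix, selected_families: Sequence[str]
) -> pd.DataFrame:
    """Per-sample relative frequencies of *selected_families*.

    This is the numeric content behind the usual per-genome family heat maps:
    each entry is the family's count rescaled by the sample's total number of
    annotations.  Requires a frequency-encoded matrix; unknown families raise
    ``ValueError``.
    """
    if matrix.encoding != FREQUENCY:
        raise ValueError("rescaled-frequency export requires a frequency-encoded matrix")
    unknown = [fam for fam in selected_families if fam not in matrix.family_ids]
    if unknown:
        raise ValueError(f"unknown families: {unknown}")
    return matrix.to_frame().loc[:, list(selected_families)]


LABEL_HEADER = ("sample_id", "label")


def write_labels(labels: Mapping[str, int], path) -> None:
    """Write a phenotype label table (TSV, labels formatted as +1/-1)."""
    with open(path, "w") as handle:
        handle.write("\t".join(LABEL_HEADER) + "\n")
        for sample in sorted(labels):
            handle.write(f"{sample}\t{labels[sample]:+d}\n")


def read_labels(path) -> dict:
    """Read a phenotype label table; labels must be +1 or -1."""
    labels = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != LABEL_HEADER:
            raise ValueError(f"unexpected label header {header!r} in {path}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: expected 2 columns at line {lineno}")
            sample, label = fields
            value = int(label)
            if value not in (-1, 1):
                raise ValueError(f"{path}: label must be +1 or -1 at line {lineno}")
            labels[sample] = value
    return labels
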