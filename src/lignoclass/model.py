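"""Model/Results front end for degrader classification.

:class:`DegraderModel` bundles a labelled feature matrix with the penalty
grid; ``fit()`` runs the grid search, trains the five-member voting
committee, and returns a :class:`DegraderResults` carrying the committee, the
cross-validated ranking it came from, the selected distinctive families, and
prediction/summary methods.  Unbiased generalisation accuracy is available
separately through :meth:`DegraderModel.nested_cv`, which re-selects C inside
every outer fold instead of reusing the committee's ranking.
"""

from __future__ import annotations

from functools import cached_property
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .annotation import AnnotationProfile
from .ensemble import (
    EnsembleModel,
    FeatureRanking,
    VoteResult,
    build_ensemble,
    load_ensemble,
    save_ensemble,
    select_features,
    vote,
    vote_profiles,
)
from .evaluation import CGrid, CVResult, nested_cv
from .features import BINARY, FeatureMatrix, build_matrix


class DegraderModel:
    """Plant-biomass-degrader classifier over protein-family annotations.

    Parameters
    ----------
    data
        Labelled :class:`FeatureMatrix` (labels +1 degrader / -1 non-degrader).
    grid
        Candidate penalties C = 10^x; defaults to x = -3.0 … 0.0 step 0.25.
    tolerance
        Solver tolerance passed to every SVM fit.
    """

    def __init__(
        self,
        data: FeatureMatrix,
        grid: Optional[CGrid] = None,
        tolerance: float = 1e-6,
    ):
        if data.labels is None:
            raise ValueError("DegraderModel requires a labelled feature matrix")
        self.data = data
        self.grid = grid if grid is not None else CGrid.default()
        self.tolerance = tolerance

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[AnnotationProfile],
        labels: Mapping[str, int],
        encoding: str = BINARY,
        grid: Optional[CGrid] = None,
        tolerance: float = 1e-6,
    ) -> "DegraderModel":
        """Build the model straight from annotation profiles and a label map."""
        return cls(build_matrix(profiles, encoding, labels), grid=grid, tolerance=tolerance)

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        labels: Union[Mapping[str, int], pd.Series],
        encoding: str = BINARY,
        grid: Optional[CGrid] = None,
        tolerance: float = 1e-6,
    ) -> "DegraderModel":
        """Build from a samples × families count table (zeros allowed)."""
        if isinstance(labels, pd.Series):
            labels = labels.to_dict()
        profiles = [
            AnnotationProfile(
                sample_id=str(sample),
                counts={str(f): int(c) for f, c in row.items() if int(c) > 0},
            )
            for sample, row in counts.iterrows()
        ]
        return cls.from_profiles(profiles, labels, encoding=encoding, grid=grid,
                                 tolerance=tolerance)

    def fit(self) -> "DegraderResults":
        """Grid-search C, train the 5-model committee on all samples."""
        ensemble = build_ensemble(self.data, self.grid, self.tolerance)
        return DegraderResults(self, ensemble)

    def nested_cv(self) -> CVResult:
        """Unbiased accuracy: leave-one-out outer loop, inner grid search per fold."""
        return nested_cv(self.data, self.grid, self.tolerance)


class DegraderResults:
    """Fitted committee plus diagnostics and reporting."""

    def __init__(self, model: Optional[DegraderModel], ensemble: EnsembleModel):
        self.model = model
        self.ensemble = ensemble

    @property
    def grid_ranking(self):
        return self.ensemble.grid_ranking

    @property
    def member_cs(self) -> list:
        return self.ensemble.member_cs

    @cached_property
    def selected_features(self) -> FeatureRanking:
        """Families with positive weight in >= 3 of the 5 committee members."""
        return select_features(self.ensemble)

    def predict(
        self, profiles: Union[AnnotationProfile, Sequence[AnnotationProfile]]
    ) -> Union[VoteResult, list]:
        """Committee vote for one profile or a sequence of profiles."""
        if isinstance(profiles, AnnotationProfile):
            return vote(self.ensemble, profiles)
        return vote_profiles(self.ensemble, profiles)

    def save(self, path) -> None:
        save_ensemble(self.ensemble, path)

    @classmethod
    def load(cls, path) -> "DegraderResults":
        """Rehydrate a saved committee (without the training data)."""
        return cls(None, load_ensemble(path))

    def summary(self) -> str:
        """Human-readable fit report."""
        ens = self.ensemble
        lines = []
        title = "Plant-biomass degrader committee (L1-regularized squared-hinge SVM)"
        lines.append(title)
        lines.append("=" * len(title))
        if self.model is not None:
            data = self.model.data
            n_pos = int((data.labels == 1).sum())
            n_neg = int((data.labels == -1).sum())
            lines.append(
                f"Samples: {data.n_samples} ({n_pos} degraders / {n_neg} non-degraders)"
                f"    Families: {data.n_features}"
            )
        lines.append(
            f"Encoding: {ens.encoding}    Penalty grid: {len(ens.grid_ranking)} values"
        )
        lines.append("")
        lines.append("Committee members (top 5 C by leave-one-out macro-accuracy):")
        lines.append(f"{'C':>10}  {'recall':>6}  {'TNR':>6}  {'MACC':>6}  {'nonzero':>7}")
        for member, point in zip(ens.members, ens.grid_ranking[:5]):
            m = point.metrics.rounded()
            lines.append(
                f"{member.C:10.4g}  {m.recall:6.2f}  {m.true_negative_rate:6.2f}  "
                f"{m.macro_accuracy:6.2f}  {member.n_nonzero:7d}"
            )
        ranking = self.selected_features
        lines.append("")
        lines.append(
            f"Distinctive families (positive weight in >=3/5 members): {len(ranking.selected)}"
        )
        if ranking.selected:
            lines.append(f"{'family':<12} {'support':>7}  {'mean +weight':>12}")
            for entry in ranking.selected[:10]:
                lines.append(
                    f"{entry.family_id:<12} {entry.support:>7d}  "
                    f"{entry.mean_positive_weight:12.4f}"
                )
            if len(ranking.selected) > 10:
                lines.append(f"... and {len(ranking.selected) - 10} more")
        return "\n".join(lines)
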