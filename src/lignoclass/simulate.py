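"""Synthetic annotation profiles with planted degradation-associated families.

Real training data for this problem is a curated panel of annotated genomes,
which cannot be bundled.  The generator emulates its co-occurrence structure:
a minority of *planted* protein families is enriched in the positive
(degrader) class and depleted in the negative class — standing in for
degradation-associated families such as the GH5/GH6 glycoside hydrolases —
while background families occur independently of the phenotype.  Counts,
given presence, follow 1 + Poisson(count_mean - 1), so stored counts are
always >= 1.

The generator can also write valid HMMER3 ``--domtblout`` files whose
parse -> filter -> aggregate round trip reproduces a profile exactly.  Those
files deliberately include decoy rows violating each filtering rule (e-value,
bit score, long-CAZy-alignment e-value, and a duplicate protein/family match
for the deduplication rule), so the whole annotation pathway is exercised
without any external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .annotation import CAZY, PFAM, AnnotationProfile


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Defaults give a balanced 20 + 20 panel over 200 families, 15 of them
    planted with presence probability 0.9 in degraders versus 0.1 in
    non-degraders — a strong but noisy class signal.  ``hard_mode``
    additionally correlates blocks of background families within the positive
    class to mimic phylogenetic structure (off by default).
    """

    n_pos: int = 20
    n_neg: int = 20
    n_families: int = 200
    n_planted: int = 15
    p_planted_pos: float = 0.9
    p_planted_neg: float = 0.1
    background_presence: float = 0.5
    count_mean: float = 3.0
    seed: int = 42
    family_db: str = PFAM
    hard_mode: bool = False

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.n_families, self.n_planted) < 1:
            raise ValueError("sample, family and planted counts must be positive")
        if self.n_planted >= self.n_families:
            raise ValueError("n_planted must be smaller than n_families")
        for name in ("p_planted_pos", "p_planted_neg", "background_presence"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.p_planted_pos <= self.p_planted_neg:
            raise ValueError("p_planted_pos must exceed p_planted_neg")
        if self.count_mean < 1.0:
            raise ValueError("count_mean must be >= 1 (counts are at least 1 when present)")


def _family_ids(config: SimulationConfig) -> List[str]:
    # synthetic ids; Pfam-like "PF9xxxx" so database inference lands on pfam
    if config.family_db == PFAM:
        return [f"PF9{j:04d}" for j in range(config.n_families)]
    return [f"GH{900 + j}" for j in range(config.n_families)]


def _draw_counts(rng: np.random.Generator, present: np.ndarray, mean: float) -> np.ndarray:
    counts = np.zeros(present.shape, dtype=int)
    n_present = int(present.sum())
    counts[present] = 1 + rng.poisson(mean - 1.0, size=n_present)
    return counts


def generate_dataset(
    config: SimulationConfig = SimulationConfig(),
) -> Tuple[List[AnnotationProfile], Dict[str, int], List[str]]:
    """Draw a synthetic labelled panel.

    Returns ``(profiles, labels, planted_family_ids)`` where labels map
    sample id to +1 (degrader) or -1 (non-degrader).  Fully reproducible for
    a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    families = _family_ids(config)
    planted_idx = np.sort(rng.choice(config.n_families, size=config.n_planted, replace=False))
    planted = [families[j] for j in planted_idx]
    is_planted = np.zeros(config.n_families, dtype=bool)
    is_planted[planted_idx] = True

    sample_ids = [f"deg{i:03d}" for i in range(config.n_pos)] + [
        f"non{i:03d}" for i in range(config.n_neg)
    ]
    labels = {s: (1 if s.startswith("deg") else -1) for s in sample_ids}

    presence_prob = np.empty((len(sample_ids), config.n_families))
    for i, sample in enumerate(sample_ids):
        positive = labels[sample] == 1
        presence_prob[i, is_planted] = config.p_planted_pos if positive else config.p_planted_neg
        presence_prob[i, ~is_planted] = config.background_presence
    present = rng.random(presence_prob.shape) < presence_prob

    if config.hard_mode:
        # two "clades" of degraders sharing clade-specific background blocks,
        # a crude stand-in for phylogenetic correlation among positives
        background_idx = np.flatnonzero(~is_planted)
        block = rng.choice(background_idx, size=min(20, background_idx.size), replace=False)
        half = block.size // 2
        for i in range(config.n_pos):
            clade_block = block[:half] if i % 2 == 0 else block[half:]
            present[i, clade_block] = rng.random(clade_block.size) < 0.9

    counts = _draw_counts(rng, present, config.count_mean)
    profiles = [
        AnnotationProfile(
            sample_id=sample,
            counts={families[j]: int(counts[i, j]) for j in np.flatnonzero(counts[i])},
            family_db=config.family_db,
        )
        for i, sample in enumerate(sample_ids)
    ]
    return profiles, labels, planted


# --- domtblout emission ------------------------------------------------------

_HEADER = (
    "#                                                                            "
    "--- full sequence --- -------------- this domain -------------   hmm coord   "
    "ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen   "
    "E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  "
    "from    to  from    to  acc description of target\n"
)


def _row(
    family: str,
    accession: str,
    protein: str,
    e_value: float,
    score: float,
    ali_from: int,
    ali_to: int,
    description: str = "-",
) -> str:
    tlen = max(ali_to - ali_from + 1, 50)
    qlen = ali_to + 20
    return (
        f"{family:<20} {accession:<11} {tlen:5d} {protein:<20} {'-':<11} {qlen:5d} "
        f"{e_value:9.2g} {score:6.1f} {0.0:5.1f} {1:3d} {1:3d} {e_value:9.2g} "
        f"{e_value:9.2g} {score:6.1f} {0.0:5.1f} {1:5d} {tlen:5d} {ali_from:5d} "
        f"{ali_to:5d} {max(ali_from - 2, 1):5d} {ali_to + 2:5d} 0.95 {description}\n"
    )


def _accession_for(family: str, db: str) -> str:
    return f"{family}.1" if db == PFAM else "-"


def generate_domtblout(profile: AnnotationProfile, seed: int = 0) -> List[str]:
    """Emit domtblout lines that round-trip to *profile* exactly.

    For a family with count k, k distinct proteins each get one (sometimes a
    duplicated) passing hit.  Decoy rows are appended that must be rejected:
    one failing the e-value rule, one failing the bit-score rule, and one
    long-alignment CAZy hit in the 1e-4 < e <= 1e-2 window; a duplicate row
    exercises the count-once-per-protein rule.
    """
    rng = np.random.default_rng(seed)
    db = profile.family_db
    lines = [_HEADER]
    first_passing_row = None
    for family in sorted(profile.counts):
        accession = _accession_for(family, db)
        for k in range(profile.counts[family]):
            protein = f"{profile.sample_id}_{family}_p{k:03d}"
            e_value = 10.0 ** -float(rng.uniform(5, 20))
            score = float(rng.uniform(30, 300))
            ali_from = int(rng.integers(1, 30))
            ali_to = ali_from + int(rng.integers(20, 90))  # <= 100 aligned positions
            row = _row(family, accession, protein, e_value, score, ali_from, ali_to)
            lines.append(row)
            if first_passing_row is None:
                first_passing_row = row
    if first_passing_row is not None:
        # duplicate match of the same protein against the same family: the
        # deduplication rule must count it only once
        lines.append(first_passing_row)
    decoy_family = "PF99999" if db == PFAM else "GHDECOY"
    decoy_acc = _accession_for(decoy_family, db)
    # fails e-value <= 1e-2
    lines.append(_row(decoy_family, decoy_acc, "decoy_evalue", 5e-2, 80.0, 1, 60))
    # fails bit score >= 25
    lines.append(_row(decoy_family, decoy_acc, "decoy_bitscore", 1e-9, 10.0, 1, 60))
    # CAZy alignment longer than 100 positions with e-value in (1e-4, 1e-2]:
    # passes the base thresholds but must be excluded by the long-alignment rule
    lines.append(_row("GHDECOY2", "-", "decoy_long_cazy", 1e-3, 80.0, 1, 120))
    return lines


def write_domtblout(profile: AnnotationProfile, path, seed: int = 0) -> None:
    with open(path, "w") as handle:
        handle.writelines(generate_domtblout(profile, seed))
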