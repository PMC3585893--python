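"""HMMER3 per-domain hit tables: parsing, filtering, per-sample aggregation.

Genomes and metagenomes are annotated by searching their predicted protein
sequences against the Pfam-A and dbCAN profile-HMM collections.  Each search
writes a ``--domtblout`` table with one row per domain match.  This module
turns those rows into per-sample annotation profiles:

* a match is accepted only if its per-domain independent e-value and bit
  score pass a significance policy, with a stricter e-value required for
  long dbCAN (CAZy) alignments;
* repeated matches of one protein against the same family collapse to a
  single annotation, so a profile counts *proteins carrying a family*, not
  raw domain hits.

Running ``hmmscan``/``hmmsearch`` itself is out of scope; this module only
consumes their tabular output.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, TextIO, Union

PFAM = "pfam"
CAZY = "cazy"
_DBS = frozenset({PFAM, CAZY})

PROFILE_HEADER = ("sample_id", "family_id", "count")


class DomtbloutParseError(ValueError):
    """A malformed row in a HMMER3 per-domain table, reported with its line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"domtblout parse error at line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM match of a protein against a Pfam or CAZy family."""

    sample_id: str
    protein_id: str
    family_id: str
    family_db: str
    e_value: float
    bit_score: float
    alignment_length: int

    def __post_init__(self) -> None:
        if self.family_db not in _DBS:
            raise ValueError(f"family_db must be one of {sorted(_DBS)}, got {self.family_db!r}")
        if self.e_value < 0:
            raise ValueError(f"e_value must be non-negative, got {self.e_value}")
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length must be >= 1, got {self.alignment_length}")


@dataclass(frozen=True)
class FilterPolicy:
    """Significance thresholds applied to domain hits.

    A hit is kept when ``e_value <= max_e_value`` and
    ``bit_score >= min_bit_score``.  CAZy (dbCAN) hits whose alignment spans
    more than ``cazy_long_alignment_length`` positions must additionally
    satisfy the stricter ``e_value <= cazy_long_alignment_max_e``.  Thresholds
    are applied per domain hit; Pfam gathering cutoffs, when wanted, are
    assumed to have been applied upstream by the HMMER run itself.
    """

    max_e_value: float = 1e-2
    min_bit_score: float = 25.0
    cazy_long_alignment_length: int = 100
    cazy_long_alignment_max_e: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_e_value <= 0:
            raise ValueError("max_e_value must be positive")
        if self.cazy_long_alignment_max_e > self.max_e_value:
            raise ValueError("cazy_long_alignment_max_e must not exceed max_e_value")


@dataclass
class AnnotationProfile:
    """Per-sample map from protein family to deduplicated annotation count.

    Only families with at least one annotated protein are stored; absent
    families are implicitly zero.
    """

    sample_id: str
    counts: dict = field(default_factory=dict)
    family_db: str = PFAM

    def __post_init__(self) -> None:
        if self.family_db not in _DBS:
            raise ValueError(f"family_db must be one of {sorted(_DBS)}, got {self.family_db!r}")
        bad = {f: c for f, c in self.counts.items() if int(c) < 1}
        if bad:
            raise ValueError(f"stored counts must be >= 1, offending families: {sorted(bad)}")
        self.counts = {str(f): int(c) for f, c in self.counts.items()}

    @property
    def total(self) -> int:
        """Total number of annotations in the sample."""
        return sum(self.counts.values())

    @property
    def families(self) -> list:
        return sorted(self.counts)


# domtblout: 22 fixed whitespace-separated columns, then a free-text description.
_MIN_FIELDS = 22
_COL_TARGET = 0
_COL_TARGET_ACC = 1
_COL_QUERY = 3
_COL_I_EVALUE = 12  # per-domain independent e-value
_COL_DOM_SCORE = 13  # per-domain bit score
_COL_ALI_FROM = 17
_COL_ALI_TO = 18


def _infer_db(target_acc: str, target_name: str) -> str:
    # Pfam-A rows carry a PFxxxxx accession; dbCAN rows carry "-" and a family name.
    if target_acc.startswith("PF") or target_name.startswith("PF"):
        return PFAM
    return CAZY


def parse_domtblout(
    stream: Union[TextIO, Iterable[str]],
    sample_id: str = "sample",
    family_db: Optional[str] = None,
) -> list:
    """Parse a HMMER3 ``--domtblout`` table into :class:`DomainHit` records.

    Assumes ``hmmscan`` orientation (target = profile HMM, query = protein).
    The per-domain independent e-value and per-domain bit score are used, and
    the alignment length is computed from the alignment coordinate columns as
    ``end - start + 1``.  When *family_db* is None the database is inferred
    per row from the target accession (``PF…`` means Pfam, anything else
    dbCAN/CAZy); trailing ``.hmm`` suffixes on family names are stripped.

    Raises :class:`DomtbloutParseError` naming the offending line on any
    malformed data row.
    """
    if family_db is not None and family_db not in _DBS:
        raise ValueError(f"family_db must be one of {sorted(_DBS)}, got {family_db!r}")
    hits = []
    for lineno, line in enumerate(stream, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < _MIN_FIELDS:
            raise DomtbloutParseError(
                lineno, f"expected at least {_MIN_FIELDS} columns, found {len(parts)}"
            )
        target = parts[_COL_TARGET]
        target_acc = parts[_COL_TARGET_ACC]
        protein = parts[_COL_QUERY]
        try:
            e_value = float(parts[_COL_I_EVALUE])
            bit_score = float(parts[_COL_DOM_SCORE])
            ali_from = int(parts[_COL_ALI_FROM])
            ali_to = int(parts[_COL_ALI_TO])
        except ValueError as exc:
            raise DomtbloutParseError(lineno, f"non-numeric field: {exc}") from exc
        if ali_to < ali_from:
            raise DomtbloutParseError(lineno, f"alignment end {ali_to} before start {ali_from}")
        family = target[:-4] if target.endswith(".hmm") else target
        db = family_db if family_db is not None else _infer_db(target_acc, target)
        try:
            hit = DomainHit(
                sample_id=sample_id,
                protein_id=protein,
                family_id=family,
                family_db=db,
                e_value=e_value,
                bit_score=bit_score,
                alignment_length=ali_to - ali_from + 1,
            )
        except ValueError as exc:
            raise DomtbloutParseError(lineno, str(exc)) from exc
        hits.append(hit)
    return hits


def filter_hits(hits: Sequence[DomainHit], policy: FilterPolicy = FilterPolicy()) -> list:
    """Keep the hits that satisfy *policy*; input order is preserved.

    Idempotent: filtering an already-filtered list is a no-op.
    """
    kept = []
    for hit in hits:
        if hit.e_value > policy.max_e_value:
            continue
        if hit.bit_score < policy.min_bit_score:
            continue
        if (
            hit.family_db == CAZY
            and hit.alignment_length > policy.cazy_long_alignment_length
            and hit.e_value > policy.cazy_long_alignment_max_e
        ):
            continue
        kept.append(hit)
    return kept


def aggregate_profile(
    sample_id: str,
    hits: Sequence[DomainHit],
    family_db: Optional[str] = None,
) -> AnnotationProfile:
    """Collapse filtered hits into a per-sample annotation profile.

    ``counts[f]`` is the number of *distinct proteins* with at least one hit
    against family ``f`` — multiple matches of one protein against the same
    family count as a single annotation.  All hits must share *sample_id* and
    belong to a single database.  For an empty hit list *family_db* (default
    Pfam) labels the resulting empty profile.
    """
    proteins_by_family: defaultdict = defaultdict(set)
    seen_dbs = set()
    for hit in hits:
        if hit.sample_id != sample_id:
            raise ValueError(
                f"mixed sample ids: expected {sample_id!r}, found {hit.sample_id!r}"
            )
        seen_dbs.add(hit.family_db)
        proteins_by_family[hit.family_id].add(hit.protein_id)
    if len(seen_dbs) > 1:
        raise ValueError(f"hits span multiple databases: {sorted(seen_dbs)}")
    if seen_dbs:
        db = seen_dbs.pop()
        if family_db is not None and family_db != db:
            raise ValueError(f"hits are {db} but family_db={family_db!r} was requested")
    else:
        db = family_db if family_db is not None else PFAM
    counts = {fam: len(prots) for fam, prots in proteins_by_family.items()}
    return AnnotationProfile(sample_id=sample_id, counts=counts, family_db=db)


def write_profiles(profiles: Sequence[AnnotationProfile], path) -> None:
    """Write profiles as TSV (``sample_id  family_id  count``), one row per
    nonzero family, in deterministic lexicographic order."""
    rows = []
    for profile in profiles:
        for family in sorted(profile.counts):
            rows.append((profile.sample_id, family, profile.counts[family]))
    rows.sort()
    with open(path, "w") as handle:
        handle.write("\t".join(PROFILE_HEADER) + "\n")
        for sample, family, count in rows:
            handle.write(f"{sample}\t{family}\t{count}\n")


def read_profiles(path, family_db: Optional[str] = None) -> list:
    """Read a profile TSV back into :class:`AnnotationProfile` objects.

    Samples are returned in lexicographic order.  When *family_db* is None it
    is inferred per sample: Pfam if every family id starts with ``PF``,
    otherwise CAZy.
    """
    counts: defaultdict = defaultdict(dict)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != PROFILE_HEADER:
            raise ValueError(f"unexpected profile header {header!r} in {path}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: expected 3 columns at line {lineno}")
            sample, family, count = fields
            counts[sample][family] = int(count)
    profiles = []
    for sample in sorted(counts):
        fam_counts = counts[sample]
        if family_db is None:
            db = PFAM if all(f.startswith("PF") for f in fam_counts) else CAZY
        else:
            db = family_db
        profiles.append(AnnotationProfile(sample_id=sample, counts=fam_counts, family_db=db))
    return profiles
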