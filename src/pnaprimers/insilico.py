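"""TestPrime-style in-silico PCR against a 16S reference collection.

Given degenerate primer pairs and a reference database of 16S-like
sequences with SILVA-style taxonomy paths, this module locates primer
binding sites under a configurable mismatch model and reports per-taxon-
group coverage: the fraction of a group's reference sequences that the
pair would amplify.  Only the forward strand of each record is scanned,
with the reverse primer applied as its reverse complement, matching the
convention that rRNA reference sequences are stored 5'->3'.

Coverage here is the quantity that PNA primer-evaluation studies obtain
from database services such as SILVA TestPrime; the engine makes the
computation reproducible on any FASTA + taxonomy input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .registry import (
    IUPAC_CODES,
    DegeneratePrimer,
    PrimerError,
    PrimerPair,
    normalize_sequence,
    reverse_complement_iupac,
)

__all__ = [
    "ReferenceSequence",
    "ReferenceDB",
    "TaxonGroupDef",
    "MatchParams",
    "CoverageResult",
    "iupac_match_at",
    "find_binding_sites",
    "predict_amplicons",
    "coverage_for_group",
    "coverage_matrix",
    "load_reference_db",
    "write_coverage_tsv",
    "DEFAULT_GROUPS",
]


@dataclass(frozen=True)
class ReferenceSequence:
    """One reference record: id, sequence (A/C/G/T/N), and taxonomy path.

    Taxonomy is an ordered, semicolon-delimited rank path in the SILVA
    style, e.g. ``Bacteria;Planctomycetes;...;Candidatus Brocadia``.
    """

    id: str
    sequence: str
    taxonomy: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.id!r} has an empty sequence")
        if not self.taxonomy:
            raise ValueError(f"reference {self.id!r} has an empty taxonomy path")
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))

    @property
    def taxonomy_string(self) -> str:
        return ";".join(self.taxonomy)


class ReferenceDB:
    """Id-keyed collection of :class:`ReferenceSequence` (a SILVA stand-in)."""

    def __init__(self, records: Iterable[ReferenceSequence] = ()) -> None:
        self._records: dict[str, ReferenceSequence] = {}
        for rec in records:
            if rec.id in self._records:
                raise ValueError(f"duplicate reference id {rec.id!r}")
            self._records[rec.id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __getitem__(self, rec_id: str) -> ReferenceSequence:
        return self._records[rec_id]

    def subset(self, predicate) -> list[ReferenceSequence]:
        return [rec for rec in self if predicate(rec)]


@dataclass(frozen=True)
class TaxonGroupDef:
    """A taxon group decidable from the taxonomy path alone.

    ``patterns`` are substrings matched against individual ranks of the
    path; a sequence belongs to the group when any pattern occurs in any
    rank.  With ``exact_rank`` a pattern must equal a whole rank instead —
    use this when one group label is a substring of another (AOB / AnAOB).
    The universal group EUB matches everything in domain Bacteria (pattern
    on the first rank).
    """

    label: str
    patterns: tuple[str, ...]
    domain_only: bool = False  # match patterns against rank 0 only (EUB)
    exact_rank: bool = False

    def matches(self, ref: ReferenceSequence) -> bool:
        ranks = ref.taxonomy[:1] if self.domain_only else ref.taxonomy
        if self.exact_rank:
            return any(pat == rank for pat in self.patterns for rank in ranks)
        return any(pat in rank for pat in self.patterns for rank in ranks)


# Groups of the PNA consortium; patterns follow SILVA-style rank names.
DEFAULT_GROUPS: tuple[TaxonGroupDef, ...] = (
    TaxonGroupDef("EUB", ("Bacteria",), domain_only=True),
    TaxonGroupDef("AOB", ("Nitrosomonas", "Nitrosospira", "Nitrosococcus")),
    TaxonGroupDef("AnAOB", ("Brocadia", "Kuenenia", "Jettenia", "Scalindua", "Anammoximicrobium")),
    TaxonGroupDef("Nitrobacter", ("Nitrobacter",)),
    TaxonGroupDef("Nitrospira", ("Nitrospira",)),
)


@dataclass(frozen=True)
class MatchParams:
    """Primer-annealing tolerance for the in-silico PCR engine.

    ``max_mismatches`` bounds the total mismatch count per primer;
    ``protected_3prime_len`` positions at the primer's 3' end must match
    exactly (mimicking the elongation-critical terminus).  Product sizes
    outside [min_product, max_product] bp are discarded.  Defaults are the
    most conservative: exact matching, wide product window.
    """

    max_mismatches: int = 0
    protected_3prime_len: int = 0
    min_product: int = 50
    max_product: int = 2000

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.protected_3prime_len < 0:
            raise ValueError("mismatch parameters must be non-negative")
        if self.min_product > self.max_product:
            raise ValueError("min_product must not exceed max_product")


@dataclass(frozen=True)
class CoverageResult:
    """Per (pair, group) coverage: matched / eligible sequences.

    ``coverage`` is None (undefined, not zero) when the group has no
    eligible sequences.
    """

    pair_name: str
    group_label: str
    eligible: int
    matched: int

    def __post_init__(self) -> None:
        if self.matched > self.eligible:
            raise ValueError("matched cannot exceed eligible")

    @property
    def coverage(self) -> Optional[float]:
        return self.matched / self.eligible if self.eligible else None

    @property
    def defined(self) -> bool:
        return self.eligible > 0


def iupac_match_at(
    primer: DegeneratePrimer | str,
    sequence: str,
    offset: int,
    params: MatchParams = MatchParams(),
    three_prime_at_start: bool = False,
) -> tuple[bool, int]:
    """Test primer annealing at a fixed offset on the given strand.

    A position mismatches when the reference base is not in the IUPAC set
    of the primer base (reference ambiguity codes are matched literally, so
    a reference N only matches a primer N).  The site is a match iff the
    total mismatch count is within ``max_mismatches`` and no mismatch lies
    within ``protected_3prime_len`` of the primer's 3' end.

    The primer string is assumed already oriented along the scanned strand,
    so its 3' end is its last character — except for a reverse primer
    scanned as its reverse complement, whose biological 3' terminus maps to
    the *first* characters of the oriented string (``three_prime_at_start``).
    """
    pseq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    n = len(pseq)
    if offset < 0 or offset + n > len(sequence):
        raise ValueError("primer does not fit the sequence at this offset")
    mismatches = 0
    protected_ok = True
    for i, pch in enumerate(pseq):
        ref = sequence[offset + i]
        # reference ambiguity codes are matched literally: ref N matches
        # nothing except a primer N (which matches any reference base)
        if pch != "N" and ref not in IUPAC_CODES[pch]:
            mismatches += 1
            dist_from_3prime = (i + 1) if three_prime_at_start else (n - i)
            if dist_from_3prime <= params.protected_3prime_len:
                protected_ok = False
    return (mismatches <= params.max_mismatches and protected_ok, mismatches)


def find_binding_sites(
    oriented_primer: str,
    sequence: str,
    params: MatchParams = MatchParams(),
    three_prime_at_start: bool = False,
) -> list[int]:
    """All start offsets where the oriented primer anneals on the sequence."""
    pseq = normalize_sequence(oriented_primer)
    n = len(pseq)
    return [
        off
        for off in range(len(sequence) - n + 1)
        if iupac_match_at(pseq, sequence, off, params, three_prime_at_start)[0]
    ]


def predict_amplicons(
    pair: PrimerPair,
    ref: ReferenceSequence | str,
    params: MatchParams = MatchParams(),
) -> list[tuple[int, int, int]]:
    """Predict PCR products of ``pair`` on a reference sequence.

    The forward primer is scanned on the stored strand; the reverse primer
    is scanned as its reverse complement on the same strand.  Each product
    spans the forward site start through the reverse site end in 0-based
    half-open coordinates; only products with
    ``min_product <= length <= max_product`` are returned, sorted by start.
    """
    if not pair.has_sequences:
        raise PrimerError(f"pair {pair.name!r} lacks primer sequences")
    seq = ref.sequence if isinstance(ref, ReferenceSequence) else ref.upper().replace("U", "T")
    fwd_sites = find_binding_sites(pair.forward.sequence, seq, params)
    if not fwd_sites:
        return []
    rev_oriented = reverse_complement_iupac(pair.reverse.sequence)
    rev_sites = find_binding_sites(rev_oriented, seq, params, three_prime_at_start=True)
    if not rev_sites:
        return []
    rev_len = len(rev_oriented)
    amplicons = []
    for fs in fwd_sites:
        for rs in rev_sites:
            end = rs + rev_len
            length = end - fs
            if rs >= fs + len(pair.forward.sequence) and params.min_product <= length <= params.max_product:
                amplicons.append((fs, end, length))
    amplicons.sort()
    return amplicons


def _is_eligible(pair: PrimerPair, ref: ReferenceSequence, matched: bool) -> bool:
    """Full-length test: does the record span both primer loci?

    A record that yields an amplicon is eligible by definition.  Otherwise
    it must at least be long enough to host both primers, and — when the
    pair carries positional labels — long enough to reach the reverse
    locus, so that partial-length records truncated at a primer site are
    excluded from the denominator rather than counted as misses.
    """
    if matched:
        return True
    if len(ref.sequence) < len(pair.forward.sequence) + len(pair.reverse.sequence):
        return False
    rpos = pair.reverse.position_label
    if rpos is not None and len(ref.sequence) < rpos:
        return False
    return True


def coverage_for_group(
    pair: PrimerPair,
    refdb: ReferenceDB,
    group: TaxonGroupDef,
    params: MatchParams = MatchParams(),
) -> CoverageResult:
    """Coverage of ``pair`` over the members of ``group`` in ``refdb``."""
    if len(refdb) == 0:
        raise ValueError("reference database is empty")
    eligible = 0
    matched = 0
    for ref in refdb:
        if not group.matches(ref):
            continue
        hit = bool(predict_amplicons(pair, ref, params))
        if _is_eligible(pair, ref, hit):
            eligible += 1
            matched += hit
    return CoverageResult(pair.name, group.label, eligible, matched)


def coverage_matrix(
    pairs: Sequence[PrimerPair],
    refdb: ReferenceDB,
    groups: Sequence[TaxonGroupDef],
    params: MatchParams = MatchParams(),
) -> pd.DataFrame:
    """Pair x group coverage table (NaN where a group has no eligible members)."""
    data = {}
    for group in groups:
        col = []
        for pair in pairs:
            res = coverage_for_group(pair, refdb, group, params)
            col.append(np.nan if res.coverage is None else res.coverage)
        data[group.label] = col
    return pd.DataFrame(data, index=pd.Index([p.name for p in pairs], name="pair"))


def load_reference_db(fasta_path, taxonomy_path) -> ReferenceDB:
    """Read reference sequences (FASTA) and their taxonomy (TSV).

    The taxonomy file maps ``id<TAB>semicolon-delimited rank path``; a
    header line ``id\ttaxonomy`` is accepted.  Records without a taxonomy
    entry raise a :class:`ValueError`.
    """
    tax = pd.read_csv(taxonomy_path, sep="\t", header=None, names=["id", "taxonomy"], dtype=str)
    if not tax.empty and tax.iloc[0]["id"] == "id":
        tax = tax.iloc[1:]
    tax_map = dict(zip(tax["id"], tax["taxonomy"]))
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in tax_map:
            raise ValueError(f"no taxonomy entry for sequence {rec.id!r}")
        path = tuple(r.strip() for r in tax_map[rec.id].split(";") if r.strip())
        records.append(ReferenceSequence(rec.id, str(rec.seq), path))
    return ReferenceDB(records)


def write_coverage_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
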