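"""Primer registry: degenerate-oligo types, IUPAC algebra, and registry I/O.

Primer pairs used in partial nitritation anammox (PNA) studies are
conventionally named after their annealing positions on the *E. coli* 16S
rRNA gene, e.g. ``1055f-1392r`` for a forward primer at position 1055 and a
reverse primer at 1392.  This module parses those names, validates and
manipulates degenerate IUPAC sequences, and loads tab-separated primer
registries (the packaged registry transcribes the universal eubacterial
pairs and the group-specific pairs reported in the PNA literature).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Optional

import pandas as pd

__all__ = [
    "IUPAC_CODES",
    "IUPAC_COMPLEMENT",
    "DegeneratePrimer",
    "PrimerPair",
    "PrimerRegistry",
    "PrimerError",
    "AmpliconLengthWarning",
    "normalize_sequence",
    "degeneracy",
    "expand_degenerate",
    "reverse_complement_iupac",
    "parse_positional_name",
    "amplicon_length_positional",
    "load_registry",
    "packaged_registry",
    "group_specific_registry",
]

# IUPAC nucleotide ambiguity codes -> set of concrete bases.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class PrimerError(ValueError):
    """Invalid primer sequence, name, or registry content."""


class AmpliconLengthWarning(UserWarning):
    """Positional amplicon length disagrees with the published length."""


def normalize_sequence(sequence: str) -> str:
    """Uppercase, convert U to T, and validate IUPAC characters.

    rRNA-derived primer sequences are sometimes written with uracil; they
    are normalized to the DNA alphabet here.  Raises :class:`PrimerError`
    naming the first invalid position.
    """
    seq = sequence.strip().upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            raise PrimerError(
                f"invalid IUPAC character {ch!r} at position {i} in {sequence!r}"
            )
    return seq


def degeneracy(sequence: str) -> int:
    """Number of concrete oligos encoded by a degenerate sequence."""
    seq = normalize_sequence(sequence)
    n = 1
    for ch in seq:
        n *= len(IUPAC_CODES[ch])
    return n


def expand_degenerate(sequence: str) -> set[str]:
    """Expand a degenerate IUPAC sequence into all concrete A/C/G/T strings.

    The result size equals the product of per-position code cardinalities,
    so e.g. ``"NN"`` expands to 16 strings.
    """
    seq = normalize_sequence(sequence)
    pools = [sorted(IUPAC_CODES[ch]) for ch in seq]
    return {"".join(p) for p in itertools.product(*pools)}


def reverse_complement_iupac(sequence: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes (R<->Y, K<->M, ...)."""
    seq = normalize_sequence(sequence)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq))


_POSITIONAL_RE = re.compile(
    r"^(?P<fprefix>[^-]*?)(?P<fpos>\d+)f-(?P<rprefix>[^-]*?)(?P<rpos>\d+)r$",
    re.IGNORECASE,
)


def parse_positional_name(name: str) -> tuple[int, int]:
    """Parse a positional pair name like ``"1055f-1392r"`` into (1055, 1392).

    Non-digit prefixes are tolerated (``"Amx809f-Amx1066r"`` -> (809, 1066)).
    Raises :class:`PrimerError` for names that do not follow the
    ``<pos>f-<pos>r`` convention or whose positions are not increasing.
    """
    m = _POSITIONAL_RE.match(name.strip())
    if m is None:
        raise PrimerError(f"cannot parse positional primer-pair name {name!r}")
    fpos, rpos = int(m.group("fpos")), int(m.group("rpos"))
    if fpos >= rpos:
        raise PrimerError(
            f"forward position {fpos} not below reverse position {rpos} in {name!r}"
        )
    return fpos, rpos


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named oligonucleotide written 5'->3', possibly degenerate.

    ``sequence`` may be empty when only the primer's name is known from the
    literature (registry rows transcribed from publications that do not
    print sequences).  ``position_label`` is the E. coli 16S position parsed
    from the name, when the name follows the positional convention.
    """

    name: str
    sequence: str = ""
    orientation: str = "forward"
    position_label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise PrimerError(f"orientation must be forward|reverse, got {self.orientation!r}")
        if self.sequence:
            object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence) if self.sequence else 1


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with its target annotation.

    ``target_group`` is the taxon group the pair is specific for (EUB for
    universal eubacterial pairs); ``gene`` is the marker (16S, amoA, hzs,
    nirS, ...).  ``printed_length`` is the published product size in bp and
    is authoritative where present; positional lengths derived from names
    are advisory (see :func:`amplicon_length_positional`).
    """

    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    name: str = ""
    region_label: str = ""
    printed_length: Optional[int] = None
    target_group: str = "EUB"
    gene: str = "16S"

    def __post_init__(self) -> None:
        if not self.name:
            object.__setattr__(self, "name", f"{self.forward.name}-{self.reverse.name}")
        f, r = self.forward.position_label, self.reverse.position_label
        if f is not None and r is not None and r <= f:
            raise PrimerError(
                f"reverse position {r} must exceed forward position {f} for {self.name!r}"
            )

    @property
    def has_sequences(self) -> bool:
        return bool(self.forward.sequence) and bool(self.reverse.sequence)


def amplicon_length_positional(pair: PrimerPair) -> int:
    """Amplicon length implied by the positional labels (reverse - forward).

    Does not overwrite ``printed_length``; emits :class:`AmpliconLengthWarning`
    when the published length exists and differs (e.g. 519f-907r prints
    391 bp but the labels imply 388 bp).  Raises :class:`PrimerError` when
    either label is missing.
    """
    f, r = pair.forward.position_label, pair.reverse.position_label
    if f is None or r is None:
        raise PrimerError(f"pair {pair.name!r} has no positional labels")
    length = r - f
    if pair.printed_length is not None and pair.printed_length != length:
        warnings.warn(
            f"pair {pair.name}: positional length {length} bp differs from "
            f"published length {pair.printed_length} bp",
            AmpliconLengthWarning,
            stacklevel=2,
        )
    return length


class PrimerRegistry:
    """Ordered, name-unique collection of :class:`PrimerPair`."""

    def __init__(self, pairs: Iterator[PrimerPair] | list[PrimerPair] = ()) -> None:
        self._pairs: dict[str, PrimerPair] = {}
        for pair in pairs:
            self.add(pair)

    def add(self, pair: PrimerPair) -> None:
        if pair.name in self._pairs:
            raise PrimerError(f"duplicate primer pair name {pair.name!r}")
        self._pairs[pair.name] = pair

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[PrimerPair]:
        return iter(self._pairs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._pairs

    def __getitem__(self, name: str) -> PrimerPair:
        try:
            return self._pairs[name]
        except KeyError:
            raise KeyError(f"no primer pair named {name!r} in registry") from None

    @property
    def names(self) -> list[str]:
        return list(self._pairs)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view matching the registry TSV dialect."""
        rows = []
        for p in self:
            rows.append(
                {
                    "name": p.name,
                    "forward_seq": p.forward.sequence,
                    "reverse_seq": p.reverse.sequence,
                    "region": p.region_label,
                    "printed_length": p.printed_length,
                    "target_group": p.target_group,
                    "gene": p.gene,
                }
            )
        return pd.DataFrame(rows)


_REQUIRED_COLUMNS = {"name", "forward_seq", "reverse_seq", "region",
                     "printed_length", "target_group", "gene"}


def _split_pair_name(name: str) -> tuple[str, str]:
    # "338f-518r" -> ("338f", "518r"); "hzsA526F/hzsA1829R" uses "/".
    for sep in ("-", "/"):
        if sep in name:
            fwd, _, rev = name.partition(sep)
            return fwd, rev
    return name + "_F", name + "_R"


def load_registry(path) -> PrimerRegistry:
    """Load a primer registry from TSV.

    Required columns: name, forward_seq, reverse_seq, region, printed_length,
    target_group, gene; an optional ``hits`` column (literature usage counts)
    is carried through via :func:`registry_hits`.  Sequence cells may be empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise PrimerError(f"registry file {path} missing columns: {sorted(missing)}")
    registry = PrimerRegistry()
    for _, row in df.iterrows():
        fwd_name, rev_name = _split_pair_name(row["name"])
        try:
            fpos, rpos = parse_positional_name(row["name"])
        except PrimerError:
            fpos = rpos = None
        pair = PrimerPair(
            forward=DegeneratePrimer(fwd_name, row["forward_seq"], "forward", fpos),
            reverse=DegeneratePrimer(rev_name, row["reverse_seq"], "reverse", rpos),
            name=row["name"],
            region_label=row["region"],
            printed_length=int(row["printed_length"]) if row["printed_length"] else None,
            target_group=row["target_group"] or "EUB",
            gene=row["gene"] or "16S",
        )
        registry.add(pair)
    return registry


def registry_hits(path) -> dict[str, int]:
    """Literature hit counts from a registry TSV's ``hits`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "hits" not in df.columns:
        return {}
    return {row["name"]: int(row["hits"]) for _, row in df.iterrows() if row["hits"]}


def _data_path(filename: str):
    return resources.files("pnaprimers.data").joinpath(filename)


def packaged_registry() -> PrimerRegistry:
    """The packaged transcription of the eight universal eubacterial pairs."""
    return load_registry(_data_path("universal_primers.tsv"))


def packaged_registry_hits() -> dict[str, int]:
    return registry_hits(_data_path("universal_primers.tsv"))


def group_specific_registry() -> PrimerRegistry:
    """Group-specific pairs (AOB/AnAOB/NOB/DNB markers) named in the literature."""
    return load_registry(_data_path("group_specific_primers.tsv"))
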