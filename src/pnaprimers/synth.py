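"""Synthetic ground-truth inputs for the primer-evaluation pipeline.

Real primer-coverage studies run against curated 16S databases (SILVA)
whose composition — and hence whose coverage percentages — cannot be
regenerated at desk scale.  This module replaces the database with
synthetic reference collections in which primer-binding-site intactness is
planted at controlled per-group fractions, so every downstream quantity
(coverage, theoretical abundance, dissimilarity) has an exactly known
truth.  It also provides the published inputs of the worked example —
SILVA132 coverage percentages and the hypothetical PNA mock community —
as fixed tables, and simulates qPCR-style replicate measurements with
multiplicative lognormal noise.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bias import MockCommunity
from .insilico import MatchParams, ReferenceDB, ReferenceSequence, TaxonGroupDef
from .registry import IUPAC_CODES, DegeneratePrimer, PrimerPair, reverse_complement_iupac
from .survey import StudyRecord

__all__ = [
    "GroupSpec",
    "ReferenceDBSpec",
    "QPCRSimSpec",
    "generate_reference_db",
    "generate_mock_community",
    "hypothetical_pna_community",
    "silva132_coverage_table",
    "simulate_qpcr_measurements",
    "generate_survey_records",
    "synthetic_primer_pair",
    "write_reference_db",
]

_BASES = np.array(list("ACGT"))

# Published in-silico coverage (SILVA132) of the three most used universal
# eubacterial pairs over the PNA consortium groups; fractions.  These are
# fixed inputs for the worked example, never targets for the engine.
_SILVA132_COVERAGE = {
    "1055f-1392r": {"EUB": 0.445, "AOB": 0.829, "AnAOB": 0.830,
                    "Nitrobacter": 0.857, "Nitrospira": 0.716},
    "338f-518r": {"EUB": 0.700, "AOB": 0.410, "AnAOB": 0.0,
                  "Nitrobacter": 0.360, "Nitrospira": 0.370},
    "341f-543r": {"EUB": 0.512, "AOB": 0.940, "AnAOB": 0.0,
                  "Nitrobacter": 0.860, "Nitrospira": 0.007},
}

# Hypothetical PNA biomass: 16S gene copies/mL per group.
_HYPOTHETICAL_PNA = {
    "EUB": 1.00e10,
    "AnAOB": 4.00e9,
    "AOB": 2.00e9,
    "Nitrobacter": 2.00e9,
    "Nitrospira": 2.00e9,
}


def silva132_coverage_table() -> pd.DataFrame:
    """Published pair x group coverage fractions (fixed worked-example input)."""
    df = pd.DataFrame.from_dict(_SILVA132_COVERAGE, orient="index")
    df.index.name = "pair"
    return df


def hypothetical_pna_community() -> MockCommunity:
    """The hypothetical PNA biomass composition of the worked example."""
    return MockCommunity(_HYPOTHETICAL_PNA)


def generate_mock_community(
    abundances: Optional[Mapping[str, float]] = None,
    preset: Optional[str] = None,
    scale: float = 1.0,
) -> MockCommunity:
    """Build a mock community from explicit abundances or a named preset.

    The ``"hypothetical_pna"`` preset returns the worked-example biomass
    (EUB 1.00e10, AnAOB 4.00e9, AOB/Nitrobacter/Nitrospira 2.00e9
    copies/mL each).  ``scale`` multiplies every abundance.
    """
    if preset is not None:
        if preset != "hypothetical_pna":
            raise ValueError(f"unknown community preset {preset!r}")
        base = _HYPOTHETICAL_PNA
    else:
        base = dict(abundances or {})
    return MockCommunity({g: v * scale for g, v in base.items()})


@dataclass(frozen=True)
class GroupSpec:
    """Synthesis plan for one taxon group's reference sequences.

    ``site_intact_fraction`` maps primer-pair name -> fraction f of the
    group's n sequences generated with fully intact binding sites for that
    pair; exactly round(f*n) sequences amplify under exact matching.
    ``taxonomy`` is the SILVA-style rank path shared by the group.
    """

    label: str
    n: int
    length: int
    site_intact_fraction: Mapping[str, float]
    taxonomy: str

    def __post_init__(self) -> None:
        if self.n < 1 or self.length < 1:
            raise ValueError("n and length must be positive")
        for pair, f in self.site_intact_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"intact fraction {f} for {pair!r} outside [0, 1]")


@dataclass(frozen=True)
class ReferenceDBSpec:
    """Whole-database synthesis plan.

    ``ablation_substitutions`` substitutions are placed inside the
    3'-terminal ``ablation_zone`` positions of each planted site when a
    site is ablated, so ablated sites fail under exact matching and under
    any mismatch model protecting >= 1 terminal base.  ``site_spacing`` is
    the gap in nt between the forward site end and the reverse site start
    (the inter-primer span of the planted amplicon).
    """

    groups: Sequence[GroupSpec]
    ablation_substitutions: int = 2
    ablation_zone: int = 3
    site_spacing: int = 80

    def __post_init__(self) -> None:
        if self.ablation_substitutions < 1:
            raise ValueError("need at least one ablating substitution")
        if self.ablation_substitutions > self.ablation_zone:
            raise ValueError("cannot place more substitutions than zone positions")


def _concrete(rng: np.random.Generator, degenerate: str) -> str:
    """One uniformly drawn concrete realization of a degenerate sequence."""
    return "".join(
        sorted(IUPAC_CODES[ch])[rng.integers(len(IUPAC_CODES[ch]))] for ch in degenerate
    )


def _disrupt(rng: np.random.Generator, site: str, primer: str, zone: int, k: int,
             three_prime_left: bool) -> str:
    """Substitute k bases of a planted site inside the primer's 3' zone.

    ``site`` is the planted concrete site as written on the forward strand;
    for a reverse primer planted as a reverse complement the primer's 3'
    end sits at the left edge (``three_prime_left``).  Each substitution
    replaces the base with one outside the primer's IUPAC set at that
    position, so the position mismatches under every interpretation.
    """
    n = len(primer)
    # candidate positions in primer coordinates (3'-terminal zone), skipping
    # fully degenerate N positions that no base can disrupt
    candidates = [i for i in range(n - zone, n) if len(IUPAC_CODES[primer[i]]) < 4]
    if len(candidates) < k or (n - 1) not in candidates:
        raise ValueError(
            f"cannot ablate site for primer {primer!r}: need {k} disruptable "
            f"positions in the 3'-terminal {zone} nt including the terminal base"
        )
    # the 3'-terminal base is always hit, so the site fails under any model
    # protecting >= 1 terminal position (and under exact matching)
    others = [i for i in candidates if i != n - 1]
    chosen_pos = [n - 1] + [others[int(c)] for c in
                            rng.choice(len(others), size=k - 1, replace=False)]
    site_list = list(site)
    for p in sorted(chosen_pos):
        # forward-strand index of primer position p
        idx = (n - 1 - p) if three_prime_left else p
        allowed = IUPAC_CODES[primer[p]]
        bad = sorted(set("ACGT") - set(_complement(b) for b in allowed)) if three_prime_left \
            else sorted(set("ACGT") - allowed)
        site_list[idx] = bad[rng.integers(len(bad))]
    return "".join(site_list)


def _complement(base: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[base]


def generate_reference_db(
    spec: ReferenceDBSpec,
    pairs: Sequence[PrimerPair],
    seed: int,
) -> tuple[ReferenceDB, pd.DataFrame]:
    """Generate a reference database with planted per-group coverage.

    For each group and primer pair, exactly ``round(f * n)`` of the group's
    sequences carry intact forward and reverse binding sites (one planted
    amplicon of length ``len(fwd) + site_spacing + len(rev)``); the rest
    carry sites ablated by 3'-zone substitutions.  Returns the database and
    the truth table of planted coverages (pair x group), which the
    in-silico engine must recover exactly under exact matching.
    """
    rng = np.random.default_rng(seed)
    by_name = {p.name: p for p in pairs}
    records: list[ReferenceSequence] = []
    truth: dict[str, dict[str, float]] = {}

    for gspec in spec.groups:
        pair_names = list(gspec.site_intact_fraction)
        # fixed, non-overlapping slot per pair along the sequence
        offsets: dict[str, tuple[int, int]] = {}
        cursor = 10
        for name in pair_names:
            pair = by_name[name]
            if not pair.has_sequences:
                raise ValueError(f"pair {name!r} has no sequences to plant")
            flen, rlen = len(pair.forward.sequence), len(pair.reverse.sequence)
            f_start = cursor
            r_start = f_start + flen + spec.site_spacing
            cursor = r_start + rlen + 10
            offsets[name] = (f_start, r_start)
        if cursor > gspec.length:
            raise ValueError(
                f"group {gspec.label!r}: planted sites need {cursor} nt but "
                f"sequences are {gspec.length} nt"
            )

        intact_idx = {
            name: set(
                rng.permutation(gspec.n)[: round(gspec.site_intact_fraction[name] * gspec.n)]
            )
            for name in pair_names
        }
        for name in pair_names:
            truth.setdefault(name, {})[gspec.label] = (
                round(gspec.site_intact_fraction[name] * gspec.n) / gspec.n
            )

        taxonomy = tuple(r.strip() for r in gspec.taxonomy.split(";") if r.strip())
        for i in range(gspec.n):
            seq = rng.choice(_BASES, size=gspec.length)
            for name in pair_names:
                pair = by_name[name]
                f_start, r_start = offsets[name]
                fwd_primer = pair.forward.sequence
                rev_oriented = reverse_complement_iupac(pair.reverse.sequence)
                fwd_site = _concrete(rng, fwd_primer)
                rev_site = _concrete(rng, rev_oriented)
                if i not in intact_idx[name]:
                    fwd_site = _disrupt(rng, fwd_site, fwd_primer,
                                        spec.ablation_zone,
                                        spec.ablation_substitutions,
                                        three_prime_left=False)
                    rev_site = _disrupt(rng, rev_site, pair.reverse.sequence,
                                        spec.ablation_zone,
                                        spec.ablation_substitutions,
                                        three_prime_left=True)
                seq[f_start:f_start + len(fwd_site)] = list(fwd_site)
                seq[r_start:r_start + len(rev_site)] = list(rev_site)
            records.append(
                ReferenceSequence(f"{gspec.label}_{i:05d}", "".join(seq), taxonomy)
            )

    truth_df = pd.DataFrame.from_dict(truth, orient="index")
    truth_df.index.name = "pair"
    return ReferenceDB(records), truth_df


@dataclass(frozen=True)
class QPCRSimSpec:
    """qPCR measurement simulation: noisy replicates of coverage x abundance.

    Noise is multiplicative lognormal with unit mean and coefficient of
    variation ``cv`` (copy-number error is multiplicative on the log
    scale); ``cv = 0`` reduces exactly to the theoretical measurement.
    """

    community: MockCommunity
    coverage: pd.DataFrame  # pair x group fractions
    cv: float = 0.1
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def simulate_qpcr_measurements(spec: QPCRSimSpec, seed: int) -> pd.DataFrame:
    """Tidy replicate table: columns pair, group, replicate, value.

    value(pair, group, r) = coverage x abundance x LN(1, cv); identical
    seeds give identical tables.
    """
    for group in spec.coverage.columns:
        if group not in spec.community:
            raise KeyError(f"community has no abundance for group {group!r}")
    rng = np.random.default_rng(seed)
    if spec.cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.cv**2)))
        mu = -(sigma**2) / 2.0  # unit-mean lognormal
    rows = []
    for pair in spec.coverage.index:
        for group in spec.coverage.columns:
            expected = float(spec.coverage.loc[pair, group]) * spec.community[group]
            for r in range(spec.replicates):
                noise = rng.lognormal(mu, sigma) if spec.cv > 0 else 1.0
                rows.append((pair, group, r, expected * noise))
    return pd.DataFrame(rows, columns=["pair", "group", "replicate", "value"])


def generate_survey_records(
    multiplicities: Mapping[str, Mapping[str, int]],
    system_type: str = "PNA",
    gene_by_pair: Optional[Mapping[str, str]] = None,
) -> list[StudyRecord]:
    """Synthetic survey fixture with planted per-group, per-pair hit counts.

    ``multiplicities`` maps target group -> {pair name -> hits}; the
    summaries in :mod:`pnaprimers.survey` recover the plants exactly.
    """
    records = []
    i = 0
    for group in sorted(multiplicities):
        for pair in sorted(multiplicities[group]):
            for _ in range(multiplicities[group][pair]):
                i += 1
                gene = (gene_by_pair or {}).get(pair, "16S")
                records.append(
                    StudyRecord(f"synthetic-study-{i:03d}", None, system_type,
                                group, pair, gene)
                )
    return records


def synthetic_primer_pair(
    name: str,
    seed: int,
    length: int = 20,
    n_degenerate: int = 2,
    target_group: str = "EUB",
) -> PrimerPair:
    """A random degenerate primer pair with known sequences, for testing."""
    rng = np.random.default_rng(seed)
    degen_codes = "RYSWKM"

    def one(label: str, orientation: str) -> DegeneratePrimer:
        seq = [str(b) for b in rng.choice(_BASES, size=length)]
        # keep the 3'-terminal 3 nt concrete so ablation always has targets
        positions = rng.choice(max(length - 3, 1), size=min(n_degenerate, length - 3),
                               replace=False)
        for p in positions:
            seq[int(p)] = degen_codes[rng.integers(len(degen_codes))]
        return DegeneratePrimer(label, "".join(seq), orientation)

    return PrimerPair(
        forward=one(f"{name}F", "forward"),
        reverse=one(f"{name}R", "reverse"),
        name=name,
        target_group=target_group,
    )


def write_reference_db(refdb: ReferenceDB, fasta_path, taxonomy_path) -> None:
    """Write FASTA + taxonomy TSV readable by :func:`load_reference_db`."""
    with open(fasta_path, "w") as fh:
        for rec in refdb:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    with open(taxonomy_path, "w") as fh:
        for rec in refdb:
            fh.write(f"{rec.id}\t{rec.taxonomy_string}\n")
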