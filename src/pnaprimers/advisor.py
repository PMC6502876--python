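"""Decision-tree advisor for PCR-based PNA study design.

Encodes the study-design framework distilled from the PNA primer
evaluation as an inspectable rule engine: the ecological question
(presence / richness / evenness), the quantification mode (relative via
16S amplicon sequencing vs absolute via qPCR), and the study intent
(cross-study comparison vs within-reactor dynamics) map deterministically
to a method, primer guidance, required quality checks, and warnings.

The tree's wiring is shipped as a JSON rule table (``data/decision_rules.json``)
rather than code branches so it can be reviewed and amended as data;
branches the framework leaves open carry empty guidance lists instead of
guesses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = ["StudyObjective", "Recommendation", "recommend", "enumerate_objectives"]

QUESTIONS = ("presence", "richness", "evenness")
QUANTITIES = ("relative", "absolute")
INTENTS = ("compare_with_other_studies", "characterize_dynamics")


@dataclass(frozen=True)
class StudyObjective:
    """A fully specified study design question.

    All fields are mandatory — the advisor refuses implicit defaults so
    every recommendation is traceable to an explicit objective.
    """

    question: str
    quantity: str
    intent: str
    degenerate_primers: bool
    normalization_to_total_eub_requested: bool

    def __post_init__(self) -> None:
        if self.question not in QUESTIONS:
            raise ValueError(f"question must be one of {QUESTIONS}, got {self.question!r}")
        if self.quantity not in QUANTITIES:
            raise ValueError(f"quantity must be one of {QUANTITIES}, got {self.quantity!r}")
        if self.intent not in INTENTS:
            raise ValueError(f"intent must be one of {INTENTS}, got {self.intent!r}")


@dataclass(frozen=True)
class Recommendation:
    """Deterministic advisor output for one objective."""

    method: str
    guidance: tuple[str, ...]
    required_checks: tuple[str, ...]
    warnings: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "guidance": list(self.guidance),
            "required_checks": list(self.required_checks),
            "warnings": list(self.warnings),
        }


@lru_cache(maxsize=1)
def _rules() -> dict:
    path = resources.files("pnaprimers.data").joinpath("decision_rules.json")
    return json.loads(path.read_text())


def recommend(objective: StudyObjective) -> Recommendation:
    """Apply the rule table to an objective (total, deterministic).

    Absolute quantification routes to qPCR, relative to 16S amplicon
    sequencing; cross-study comparison requires reusing the reference
    study's primer pairs, dynamics studies require an in-silico coverage
    evaluation and interpretation against a same-reactor reference sample;
    gel-electrophoresis product verification is required except for
    degenerate primers (whose multiple products make a single-band check
    uninformative); requesting normalization to total eubacteria always
    draws a warning.
    """
    rules = _rules()
    guidance = list(rules["guidance_by_intent"][objective.intent])
    guidance += rules["guidance_by_question"][objective.question]
    checks = list(rules["always_required_checks"])
    gel = rules["gel_check"]
    if not (objective.degenerate_primers and gel["omit_for_degenerate_primers"]):
        checks.append(gel["code"])
    warns = []
    if objective.normalization_to_total_eub_requested:
        warns.append(rules["warnings"]["normalization_to_total_eub"])
    return Recommendation(
        method=rules["method_by_quantity"][objective.quantity],
        guidance=tuple(guidance),
        required_checks=tuple(checks),
        warnings=tuple(warns),
    )


def enumerate_objectives() -> list[StudyObjective]:
    """All 3 x 2 x 2 x 2 x 2 = 48 objectives in the finite design space."""
    return [
        StudyObjective(q, qty, intent, deg, norm)
        for q in QUESTIONS
        for qty in QUANTITIES
        for intent in INTENTS
        for deg in (False, True)
        for norm in (False, True)
    ]
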