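"""Sequence selection, per-tool routing and dataset accounting.

The modeling campaign starts from the reviewed human reference proteome
(UP000005640, protein-level evidence, no fragments).  Sequences are then
screened for AI-predictor compatibility (length 10-2,700, no ambiguous
residue codes), and each surviving sequence is routed to the prediction
tools whose technical length limits it satisfies.  The accounting helpers
reproduce the arithmetic that relates the per-tool model counts to the
dataset totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from Bio import SeqIO

from .errors import ValidationError

#: Residue letters the AI predictors do not accept.
UNKNOWN_CHARACTERS = frozenset("UOXJBZ")

MIN_AI_LENGTH = 10
MAX_AI_LENGTH = 2700
MAX_OPENFOLD_LENGTH = 2000
MAX_ESM_API_LENGTH = 400
MAX_ESM_BIONEMO_LENGTH = 1024

ALL_TOOLS = ("alphafold2", "openfold", "esmfold_api", "esmfold_bionemo", "homology")


@dataclass
class SequenceRecord:
    accession: str
    sequence: str
    existence_level: int = 1
    is_fragment: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        if not self.sequence.isalpha() or not self.sequence.isupper():
            raise ValidationError(
                f"{self.accession}: sequence must be uppercase alphabetic"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RoutingPlan:
    accession: str
    eligible_tools: frozenset[str]
    exclusion_reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        if {"esmfold_api", "esmfold_bionemo"} <= set(self.eligible_tools):
            raise ValidationError(
                f"{self.accession}: esmfold_api and esmfold_bionemo are mutually exclusive"
            )


def ai_exclusion_reasons(record: SequenceRecord) -> list[str]:
    """Reasons (possibly empty) why a sequence cannot go to any AI predictor."""
    reasons = []
    if len(record) < MIN_AI_LENGTH:
        reasons.append("too_short")
    if len(record) > MAX_AI_LENGTH:
        reasons.append("too_long")
    if set(record.sequence) & UNKNOWN_CHARACTERS:
        reasons.append("unknown_character")
    return reasons


def filter_sequences(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, list[str]]]]:
    """Split records into modeling-eligible and excluded-with-reasons.

    A record is kept (eligible for at least homology modeling) iff its
    existence level is 1 and it is not a fragment.  AI-specific eligibility
    is a further screen, queried via :func:`ai_exclusion_reasons` or
    :func:`route_models`.
    """
    kept: list[SequenceRecord] = []
    excluded: list[tuple[SequenceRecord, list[str]]] = []
    for rec in records:
        reasons = []
        if rec.existence_level != 1:
            reasons.append("not_protein_level_evidence")
        if rec.is_fragment:
            reasons.append("fragment")
        if reasons:
            excluded.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, excluded


def route_models(record: SequenceRecord) -> RoutingPlan:
    """Per-tool routing by the tools' sequence-length limits.

    AlphaFold 2 takes every AI-eligible sequence (<= 2,700 residues by the
    filter); OpenFold is limited to 2,000; ESMFold runs through the public
    API up to 400 residues and through BioNeMo from 401 to 1,024.  Homology
    modeling is always attempted (template availability decided elsewhere).
    """
    ai_reasons = ai_exclusion_reasons(record)
    if ai_reasons:
        raise ValidationError(
            f"{record.accession}: not AI-eligible ({', '.join(ai_reasons)})"
        )
    n = len(record)
    tools = {"alphafold2", "homology"}
    reasons = []
    if n <= MAX_OPENFOLD_LENGTH:
        tools.add("openfold")
    else:
        reasons.append("openfold:too_long")
    if MIN_AI_LENGTH <= n <= MAX_ESM_API_LENGTH:
        tools.add("esmfold_api")
    elif n <= MAX_ESM_BIONEMO_LENGTH:
        tools.add("esmfold_bionemo")
    else:
        reasons.append("esmfold:too_long")
    return RoutingPlan(record.accession, frozenset(tools), reasons)


# ---------------------------------------------------------------------------
# Dataset accounting


def coverage_pct(subset: int, universe: int) -> float:
    """Percentage of ``universe`` covered by ``subset``, half-up to 2 dp."""
    if universe <= 0:
        raise ValidationError("universe must be positive")
    if subset < 0:
        raise ValidationError("subset must be non-negative")
    frac = Decimal(100 * subset) / Decimal(universe)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def dataset_accounting(counts: dict[str, int]) -> dict[str, int]:
    """Derive dataset totals from named component counts.

    Expected keys (missing keys default to 0): ``af2_total`` (all AlphaFold 2
    models), ``af2_from_db`` (retrieved from the public AlphaFold database),
    ``openfold``, ``esmfold``, ``homology``.  Returns ``af2_new`` (newly
    folded AlphaFold 2 models), ``ai_total`` (newly AI-predicted models) and
    ``novel_total`` (AI plus homology).
    """
    for key, val in counts.items():
        if not isinstance(val, int) or val < 0:
            raise ValidationError(f"count {key!r} must be a non-negative integer")
    g = lambda k: counts.get(k, 0)
    af2_new = g("af2_total") - g("af2_from_db")
    if af2_new < 0:
        raise ValidationError("af2_from_db exceeds af2_total")
    ai_total = af2_new + g("openfold") + g("esmfold")
    novel_total = ai_total + g("homology")
    return {"af2_new": af2_new, "ai_total": ai_total, "novel_total": novel_total}


# ---------------------------------------------------------------------------
# FASTA input / report output


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read sequences from FASTA; accession is the UniProt field of
    ``sp|ACC|NAME``-style headers, else the first token of the id."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if "|" in ident:
            parts = ident.split("|")
            ident = parts[1] if len(parts) > 1 and parts[1] else parts[0]
        records.append(SequenceRecord(accession=ident, sequence=str(rec.seq).upper()))
    return records


def routing_table(records: list[SequenceRecord]):
    """Routing plans for a record list as a pandas DataFrame (one row per
    accession, one boolean column per tool plus an exclusion-reason column)."""
    import pandas as pd

    rows = []
    for rec in records:
        ai_reasons = ai_exclusion_reasons(rec)
        if ai_reasons:
            tools: frozenset[str] = frozenset({"homology"})
            reasons = [f"ai:{r}" for r in ai_reasons]
        else:
            plan = route_models(rec)
            tools, reasons = plan.eligible_tools, plan.exclusion_reasons
        row = {"accession": rec.accession, "length": len(rec)}
        for tool in ALL_TOOLS:
            row[tool] = tool in tools
        row["exclusion_reasons"] = ";".join(reasons)
        rows.append(row)
    return pd.DataFrame(rows, columns=["accession", "length", *ALL_TOOLS, "exclusion_reasons"])
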