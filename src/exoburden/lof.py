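"""Variant-class assignment and the NMD-aware loss-of-function curation rule.

A truncating variant (nonsense, frameshift, canonical splice site) counts as
LoF only if its induced premature termination codon (PTC) is predicted to
trigger nonsense-mediated decay (NMD) *and* removes at least 10% of the
protein's C-terminal amino acids. The NMD prediction follows the canonical
last-exon-junction rule: a PTC in the 3'-most exon, or within the 3'-most
50 bp of the penultimate exon, escapes decay.

Damaging missense requires a unanimous deleterious call from all three
in-silico predictors; synonymous variants form the neutral background class.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .types import (
    AnnotatedVariant,
    Consequence,
    TranscriptModel,
    TRUNCATING,
    ValidationError,
    VariantClass,
)


@dataclass(frozen=True)
class NmdRuleParams:
    """Parameters of the NMD-escape / C-terminal-loss curation rule.

    Attributes
    ----------
    penultimate_escape_bp : int
        Width (nt) of the escape zone at the 3' end of the penultimate exon.
    min_cterm_loss_fraction : float
        Minimum fraction of protein length that must be truncated for a
        PTC variant to be retained as LoF.
    """

    penultimate_escape_bp: int = 50
    min_cterm_loss_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.penultimate_escape_bp < 0:
            raise ValidationError("escape_bp must be >= 0")
        if not 0.0 < self.min_cterm_loss_fraction < 1.0:
            raise ValidationError("min_cterm_loss_fraction must be in (0,1)")


DEFAULT_NMD_PARAMS = NmdRuleParams()


def _check_ptc(transcript: TranscriptModel, cds_ptc_position: int) -> None:
    if not 1 <= cds_ptc_position <= transcript.cds_length_nt:
        raise ValidationError(
            f"PTC position {cds_ptc_position} outside CDS of "
            f"{transcript.transcript_id} (length {transcript.cds_length_nt})"
        )


def nmd_predicted(
    transcript: TranscriptModel,
    cds_ptc_position: int,
    params: NmdRuleParams = DEFAULT_NMD_PARAMS,
) -> bool:
    """Whether a PTC at the given CDS coordinate is predicted to trigger NMD.

    The escape zone is the last coding exon plus the 3'-most
    ``params.penultimate_escape_bp`` nucleotides of the penultimate coding
    exon; a PTC strictly 5' of that boundary is NMD-predicted. Single-exon
    transcripts always escape.
    """
    _check_ptc(transcript, cds_ptc_position)
    cds_by_exon = transcript.cds_lengths_by_exon()
    if len(cds_by_exon) < 2:
        return False
    # CDS coordinate of the penultimate coding exon's last base
    pen_end = sum(cds_by_exon[:-1])
    boundary = pen_end - params.penultimate_escape_bp
    return cds_ptc_position < boundary


def cterm_loss_fraction(transcript: TranscriptModel, cds_ptc_position: int) -> float:
    """Fraction of the protein lost C-terminal to the PTC.

    The truncated product retains ``floor((ptc - 1) / 3)`` complete codons.
    """
    _check_ptc(transcript, cds_ptc_position)
    protein = transcript.protein_length_aa
    truncated = (cds_ptc_position - 1) // 3
    truncated = min(truncated, protein)
    return (protein - truncated) / protein


@dataclass
class ClassificationRecord:
    """Outcome of classifying one variant, including NMD-rule bookkeeping."""

    variant_id: str
    variant_class: VariantClass
    nmd_evaluated: bool = False
    nmd_predicted: Optional[bool] = None
    cterm_loss: Optional[float] = None


def classify(
    variant: AnnotatedVariant,
    transcript: Optional[TranscriptModel] = None,
    params: NmdRuleParams = DEFAULT_NMD_PARAMS,
) -> ClassificationRecord:
    """Assign a variant to {LoF, damaging_missense, synonymous, other}.

    Truncating consequences are LoF candidates; when the induced PTC position
    and the transcript model are both available, the NMD and C-terminal-loss
    rules decide whether the candidate is retained (failing either demotes it
    to ``other``). Truncating variants without a resolvable PTC (e.g. splice
    variants) are retained as LoF with ``nmd_evaluated=False``.

    Raises
    ------
    ValidationError
        For a missense variant without predictor flags.
    """
    csq = variant.consequence
    if csq in TRUNCATING:
        if variant.cds_ptc_position is not None and transcript is not None:
            nmd = nmd_predicted(transcript, variant.cds_ptc_position, params)
            loss = cterm_loss_fraction(transcript, variant.cds_ptc_position)
            is_lof = nmd and loss >= params.min_cterm_loss_fraction
            return ClassificationRecord(
                variant.variant_id,
                VariantClass.LOF if is_lof else VariantClass.OTHER,
                nmd_evaluated=True,
                nmd_predicted=nmd,
                cterm_loss=loss,
            )
        return ClassificationRecord(
            variant.variant_id, VariantClass.LOF, nmd_evaluated=False
        )
    if csq is Consequence.MISSENSE:
        if variant.predictor_flags is None:
            raise ValidationError(
                f"missense variant {variant.variant_id} lacks predictor flags"
            )
        cls = (
            VariantClass.DAMAGING_MISSENSE
            if all(variant.predictor_flags)
            else VariantClass.OTHER
        )
        return ClassificationRecord(variant.variant_id, cls)
    if csq is Consequence.SYNONYMOUS:
        return ClassificationRecord(variant.variant_id, VariantClass.SYNONYMOUS)
    return ClassificationRecord(variant.variant_id, VariantClass.OTHER)


def classify_variants(
    variants: Iterable[AnnotatedVariant],
    transcripts: Mapping[str, TranscriptModel],
    params: NmdRuleParams = DEFAULT_NMD_PARAMS,
) -> dict[str, ClassificationRecord]:
    """Classify every variant, looking transcripts up by ``transcript_id``."""
    return {
        v.variant_id: classify(v, transcripts.get(v.transcript_id), params)
        for v in variants
    }


def write_classification_tsv(
    records: Iterable[ClassificationRecord], path: str | os.PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "class", "nmd_evaluated", "nmd_predicted", "cterm_loss"])
        for r in records:
            w.writerow(
                [
                    r.variant_id,
                    r.variant_class.value,
                    int(r.nmd_evaluated),
                    "" if r.nmd_predicted is None else int(r.nmd_predicted),
                    "" if r.cterm_loss is None else "%.12g" % r.cterm_loss,
                ]
            )
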