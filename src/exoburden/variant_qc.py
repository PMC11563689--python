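"""Qualifying-variant selection: sequencing-quality and rarity (MAF) filters.

A qualifying variant (QV) must clear five site-level quality criteria
(DP > 10, carrier alternate-read fraction >= 25%, QD > 10, QUAL > 30,
GQ > 20), be rare (allele frequency < 0.1% in the internal case and control
cohorts separately and in every provided external population database), and
belong to one of the three tested classes (LoF, damaging missense,
synonymous). Attrition is attributed to the first failing criterion in the
fixed order DP -> alt_fraction -> QD -> QUAL -> GQ -> MAF -> class.
"""

from __future__ import annotations

import csv
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .lof import ClassificationRecord
from .types import (
    AnnotatedVariant,
    TESTED_CLASSES,
    ValidationError,
    VariantClass,
)

#: Attribution order for per-filter attrition counts.
CRITERIA_ORDER = ("DP", "alt_fraction", "QD", "QUAL", "GQ", "MAF", "class")


@dataclass(frozen=True)
class QvThresholds:
    """Quality and rarity thresholds for qualifying variants.

    Quality bounds mirror their textual statement exactly: ``>`` thresholds
    are exclusive (a value at the threshold fails), the alternate-read
    fraction bound is inclusive, and the MAF bound is exclusive
    (AF = 0.1% is not rare).
    """

    min_mean_DP: float = 10.0  # exclusive
    min_alt_fraction: float = 0.25  # inclusive
    min_mean_QD: float = 10.0  # exclusive
    min_mean_QUAL: float = 30.0  # exclusive
    min_mean_GQ: float = 20.0  # exclusive
    max_maf: float = 0.001  # exclusive

    def __post_init__(self) -> None:
        for name in (
            "min_mean_DP",
            "min_alt_fraction",
            "min_mean_QD",
            "min_mean_QUAL",
            "min_mean_GQ",
            "max_maf",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


DEFAULT_THRESHOLDS = QvThresholds()


def passes_quality(
    variant: AnnotatedVariant, thresholds: QvThresholds = DEFAULT_THRESHOLDS
) -> tuple[bool, list[str]]:
    """Evaluate the five site-quality criteria.

    Returns ``(passed, failing)`` where ``failing`` lists each violated
    criterion name in attribution order.
    """
    checks = [
        ("DP", variant.mean_DP > thresholds.min_mean_DP),
        ("alt_fraction", variant.mean_alt_fraction() >= thresholds.min_alt_fraction),
        ("QD", variant.mean_QD > thresholds.min_mean_QD),
        ("QUAL", variant.mean_QUAL > thresholds.min_mean_QUAL),
        ("GQ", variant.mean_GQ() > thresholds.min_mean_GQ),
    ]
    failing = [name for name, ok in checks if not ok]
    return (not failing, failing)


def is_rare(
    variant: AnnotatedVariant,
    thresholds: QvThresholds = DEFAULT_THRESHOLDS,
    required_internal: Sequence[str] = ("cases", "controls"),
    pooled_internal: bool = False,
) -> bool:
    """Whether every provided allele frequency is below the rarity bound.

    Internal cohort frequencies are each required to be < ``max_maf``
    separately (the default), or as a carrier-weighted check on each entry
    when ``pooled_internal`` is set the caller must supply a pooled entry.
    External sources the variant is absent from count as frequency 0.
    """
    if not pooled_internal:
        for label in required_internal:
            if label not in variant.internal_af_by_cohort:
                raise ValidationError(
                    f"internal AF for cohort {label!r} missing on {variant.variant_id}"
                )
    for af in variant.internal_af_by_cohort.values():
        if af >= thresholds.max_maf:
            return False
    for af in variant.external_af_by_db.values():
        if af >= thresholds.max_maf:
            return False
    return True


@dataclass
class QvSelection:
    """Output of qualifying-variant selection."""

    qv_sets: dict[tuple[str, VariantClass], list[AnnotatedVariant]]
    gene_universe: set[str]
    attrition: Counter = field(default_factory=Counter)
    n_input: int = 0
    n_qualifying: int = 0

    @property
    def universe_size(self) -> int:
        return len(self.gene_universe)


def select_qualifying_variants(
    variants: Iterable[AnnotatedVariant],
    classifications: Mapping[str, ClassificationRecord],
    thresholds: QvThresholds = DEFAULT_THRESHOLDS,
    required_internal: Sequence[str] = ("cases", "controls"),
) -> QvSelection:
    """Select QVs and tally per-filter attrition.

    ``classifications`` maps variant_id to its class record
    (see :func:`exoburden.lof.classify_variants`). The gene universe is the
    set of genes retaining at least one QV of any tested class.
    """
    sel = QvSelection(qv_sets={}, gene_universe=set())
    for v in variants:
        sel.n_input += 1
        ok, failing = passes_quality(v, thresholds)
        if not ok:
            sel.attrition[failing[0]] += 1
            continue
        if not is_rare(v, thresholds, required_internal):
            sel.attrition["MAF"] += 1
            continue
        record = classifications.get(v.variant_id)
        if record is None:
            raise ValidationError(f"no classification for {v.variant_id}")
        if record.variant_class not in TESTED_CLASSES:
            sel.attrition["class"] += 1
            continue
        sel.n_qualifying += 1
        sel.qv_sets.setdefault((v.gene, record.variant_class), []).append(v)
        sel.gene_universe.add(v.gene)
    return sel


def write_attrition_tsv(selection: QvSelection, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["criterion", "n_excluded"])
        for crit in CRITERIA_ORDER:
            w.writerow([crit, selection.attrition.get(crit, 0)])
        w.writerow(["qualifying", selection.n_qualifying])
        w.writerow(["input", selection.n_input])


def write_qv_sets_tsv(selection: QvSelection, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "class", "variant_id"])
        for (gene, cls), vs in sorted(
            selection.qv_sets.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            for v in vs:
                w.writerow([gene, cls.value, v.variant_id])
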