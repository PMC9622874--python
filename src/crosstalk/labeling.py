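"""Sign logic turning drug-lncRNA effects into therapeutic/exacerbating
labels, and the D+/D- partition.

A lncRNA that is consistently up-regulated in both diseases is restored
toward normal by a drug that decreases it (therapeutic) and pushed further
by one that increases it (exacerbating); symmetrically for a consistently
down-regulated lncRNA.  Drugs whose signable effects disagree are
contradictory and removed; drugs with only unsignable edges (unknown or
disease-discordant lncRNA direction) are excluded rather than guessed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .core_io import (
    Direction,
    DrugEffectRecord,
    Effect,
    LabeledDrugSet,
    RegulationDirection,
    normalize_id,
)

logger = logging.getLogger("crosstalk")

__all__ = [
    "Sign",
    "EffectSign",
    "EFFECT_VERBS",
    "normalize_effect_verb",
    "effect_sign",
    "sign_effects",
    "remove_contradictory",
    "partition_drugs",
    "label_drugs",
]

Sign = str  # 'therapeutic' | 'exacerbating'

THERAPEUTIC: Sign = "therapeutic"
EXACERBATING: Sign = "exacerbating"

# Controlled vocabulary for free-text effect verbs found in drug-lncRNA
# databases.  Extend via the mapping argument of normalize_effect_verb.
EFFECT_VERBS: dict[str, Effect] = {
    "increase": Effect.INCREASE,
    "increases": Effect.INCREASE,
    "overexpress": Effect.INCREASE,
    "overexpression": Effect.INCREASE,
    "elevate": Effect.INCREASE,
    "elevates": Effect.INCREASE,
    "upregulate": Effect.INCREASE,
    "upregulates": Effect.INCREASE,
    "upregulation": Effect.INCREASE,
    "induce": Effect.INCREASE,
    "induces": Effect.INCREASE,
    "decrease": Effect.DECREASE,
    "decreases": Effect.DECREASE,
    "inhibit": Effect.DECREASE,
    "inhibits": Effect.DECREASE,
    "silence": Effect.DECREASE,
    "silences": Effect.DECREASE,
    "suppress": Effect.DECREASE,
    "suppresses": Effect.DECREASE,
    "downregulate": Effect.DECREASE,
    "downregulates": Effect.DECREASE,
    "downregulation": Effect.DECREASE,
}


def normalize_effect_verb(
    verb: str, extra: Mapping[str, Effect] | None = None
) -> Effect:
    """Map a free-text effect verb onto increase/decrease."""
    key = verb.strip().casefold()
    if extra and key in extra:
        return extra[key]
    try:
        return EFFECT_VERBS[key]
    except KeyError:
        raise ValueError(f"unrecognized effect verb {verb!r}") from None


@dataclass(frozen=True)
class EffectSign:
    """The signed (therapeutic/exacerbating) effect of one drug-lncRNA edge."""

    drug_id: str
    lncrna_id: str
    sign: Sign


def effect_sign(direction: Direction, effect: Effect) -> Sign:
    """Therapeutic iff the drug pushes the lncRNA against its disease direction."""
    if direction is Direction.UNKNOWN:
        raise ValueError("sign undefined for unknown regulation direction")
    restores = (direction is Direction.UP) == (effect is Effect.DECREASE)
    return THERAPEUTIC if restores else EXACERBATING


def _direction_index(
    directions: Iterable[RegulationDirection],
) -> dict[str, Direction]:
    return {normalize_id(d.lncrna_id): d.shared_direction for d in directions}


def sign_effects(
    effects: Iterable[DrugEffectRecord],
    directions: Iterable[RegulationDirection],
) -> tuple[list[EffectSign], list[DrugEffectRecord]]:
    """Sign every signable effect record; return (signed, skipped).

    Records pointing at lncRNAs with unknown or disease-discordant
    direction are skipped with a warning, not treated as contradictions.
    Duplicate (drug, lncRNA) pairs with opposite effect verbs are refused —
    they need manual curation upstream.
    """
    index = _direction_index(directions)
    seen: dict[tuple[str, str], Effect] = {}
    signed: list[EffectSign] = []
    skipped: list[DrugEffectRecord] = []
    for rec in effects:
        pair = (normalize_id(rec.drug_id), normalize_id(rec.lncrna_id))
        if pair in seen:
            if seen[pair] is not rec.effect:
                raise ValueError(
                    f"conflicting effect reports for drug {rec.drug_id!r} on "
                    f"lncRNA {rec.lncrna_id!r}: needs manual curation"
                )
            continue
        seen[pair] = rec.effect
        direction = index.get(pair[1], Direction.UNKNOWN)
        if direction is Direction.UNKNOWN:
            logger.warning(
                "skipping unsignable effect %s -> %s (direction unknown/discordant)",
                rec.drug_id, rec.lncrna_id,
            )
            skipped.append(rec)
            continue
        signed.append(EffectSign(rec.drug_id, rec.lncrna_id, effect_sign(direction, rec.effect)))
    return signed, skipped


def remove_contradictory(
    effects: Iterable[DrugEffectRecord],
    directions: Iterable[RegulationDirection],
) -> tuple[list[EffectSign], frozenset[str], frozenset[str]]:
    """Drop drugs whose signable edges disagree in sign.

    Returns ``(retained_signed_effects, removed_contradictory_drugs,
    unsignable_only_drugs)``.  Retained drugs have a uniform sign across all
    their signable edges.  Drug identity is resolved case-insensitively;
    the first-seen spelling is reported.
    """
    signed, skipped = sign_effects(effects, directions)
    if not signed:
        raise ValueError("no signable drug-lncRNA effect records")

    spelling: dict[str, str] = {}
    signs_by_drug: dict[str, set[Sign]] = defaultdict(set)
    for s in signed:
        key = normalize_id(s.drug_id)
        spelling.setdefault(key, s.drug_id)
        signs_by_drug[key].add(s.sign)
    contradictory = {k for k, signs in signs_by_drug.items() if len(signs) > 1}

    unsignable_only = set()
    for rec in skipped:
        key = normalize_id(rec.drug_id)
        spelling.setdefault(key, rec.drug_id)
        if key not in signs_by_drug:
            unsignable_only.add(key)

    retained = [s for s in signed if normalize_id(s.drug_id) not in contradictory]
    logger.info(
        "remove_contradictory: %d drugs retained, %d contradictory removed, "
        "%d unsignable-only dropped",
        len(signs_by_drug) - len(contradictory), len(contradictory), len(unsignable_only),
    )
    return (
        retained,
        frozenset(spelling[k] for k in contradictory),
        frozenset(spelling[k] for k in unsignable_only),
    )


def partition_drugs(
    signed_effects: Iterable[EffectSign],
    removed_contradictory: frozenset[str] = frozenset(),
) -> LabeledDrugSet:
    """Split uniformly-signed drugs into D+ (therapeutic) and D- (exacerbating)."""
    spelling: dict[str, str] = {}
    signs_by_drug: dict[str, set[Sign]] = defaultdict(set)
    for s in signed_effects:
        key = normalize_id(s.drug_id)
        spelling.setdefault(key, s.drug_id)
        signs_by_drug[key].add(s.sign)
    mixed = [spelling[k] for k, v in signs_by_drug.items() if len(v) > 1]
    if mixed:
        raise ValueError(
            f"mixed-sign drugs reached partitioning (run remove_contradictory first): {mixed}"
        )
    positives = frozenset(
        spelling[k] for k, v in signs_by_drug.items() if v == {THERAPEUTIC}
    )
    negatives = frozenset(
        spelling[k] for k, v in signs_by_drug.items() if v == {EXACERBATING}
    )
    logger.info("partition_drugs: |D+|=%d |D-|=%d", len(positives), len(negatives))
    return LabeledDrugSet(positives, negatives, removed_contradictory)


def label_drugs(
    effects: Iterable[DrugEffectRecord],
    directions: Iterable[RegulationDirection],
) -> LabeledDrugSet:
    """remove_contradictory followed by partition_drugs, in one call."""
    retained, removed, _unsignable = remove_contradictory(effects, directions)
    return partition_drugs(retained, removed)


# ---------------------------------------------------------------------------
# Delimited-table carriers for the labeling inputs/outputs
# ---------------------------------------------------------------------------

def read_effect_table(path, extra_verbs: Mapping[str, Effect] | None = None):
    """Read a 3-column (drug, lncRNA, effect verb) delimited table."""
    import csv
    from pathlib import Path

    rows = list(csv.reader(Path(path).read_text().splitlines(), delimiter="\t"))
    records = []
    start = 1 if rows and rows[0][:1] and rows[0][0].casefold() in ("drug", "drug_id") else 0
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or not any(f.strip() for f in row):
            continue
        if len(row) < 3:
            raise ValueError(f"{path}: line {lineno}: expected 3 fields, got {row!r}")
        records.append(
            DrugEffectRecord(row[0].strip(), row[1].strip(),
                             normalize_effect_verb(row[2], extra_verbs))
        )
    return records


def read_direction_table(path):
    """Read a (lncrna, direction_dm, direction_ad) delimited table."""
    import csv
    from pathlib import Path

    rows = list(csv.DictReader(Path(path).read_text().splitlines(), delimiter="\t"))
    return [
        RegulationDirection(
            r["lncrna"].strip(),
            Direction(r["direction_dm"].strip().casefold()),
            Direction(r["direction_ad"].strip().casefold()),
        )
        for r in rows
    ]


def write_labels_tsv(labels: LabeledDrugSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("drug\tlabel\n")
        for d in sorted(labels.positives, key=normalize_id):
            fh.write(f"{d}\tpositive\n")
        for d in sorted(labels.negatives, key=normalize_id):
            fh.write(f"{d}\tnegative\n")
        for d in sorted(labels.removed_contradictory, key=normalize_id):
            fh.write(f"{d}\tremoved_contradictory\n")
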