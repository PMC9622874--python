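"""Data model and tabular I/O for the repurposing pipeline.

Every stage of the pipeline consumes or produces one of a small set of
tabular objects: interaction edge lists (the three network layers), lncRNA
disease-direction tables, drug-effect records, PaDEL-style molecular
descriptor matrices, and labeled drug sets.  This module defines those
types, the delimited-text readers/writers for them, the pipeline
configuration object, and loaders for the small reference tables shipped
with the package (the study's printed node, direction, and drug-class
tables).

Identifiers are case-preserved but compared case-insensitively after
whitespace trimming, because the upstream interaction databases mix cases
freely.  Missing descriptor values are NaN, never zero.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, asdict
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("crosstalk")

__all__ = [
    "LayerTag",
    "Direction",
    "Effect",
    "InteractionEdge",
    "RegulationDirection",
    "DrugEffectRecord",
    "DescriptorMatrix",
    "LabeledDrugSet",
    "PipelineConfig",
    "MalformedTableError",
    "normalize_id",
    "read_edge_list",
    "write_edge_list",
    "read_descriptor_csv",
    "write_descriptor_csv",
    "load_fixture",
]


class LayerTag(str, Enum):
    """Which bipartite layer an interaction edge belongs to."""

    MRNA_MIRNA = "mrna_mirna"
    MIRNA_LNCRNA = "mirna_lncrna"
    DRUG_LNCRNA = "drug_lncrna"


class Direction(str, Enum):
    """Disease regulation direction of a lncRNA."""

    UP = "up"
    DOWN = "down"
    UNKNOWN = "unknown"


class Effect(str, Enum):
    """Directional effect of a drug on a lncRNA's expression."""

    INCREASE = "increase"
    DECREASE = "decrease"


class MalformedTableError(ValueError):
    """A delimited input file violates the expected shape."""


def normalize_id(identifier: str) -> str:
    """Canonical comparison key for an identifier (trimmed, case-folded)."""
    return identifier.strip().casefold()


@dataclass(frozen=True)
class InteractionEdge:
    """One edge of a bipartite interaction layer."""

    source_id: str
    target_id: str
    layer: LayerTag

    def __post_init__(self) -> None:
        if not self.source_id.strip() or not self.target_id.strip():
            raise ValueError("edge endpoints must be non-empty identifiers")

    @property
    def key(self) -> tuple[str, str]:
        return (normalize_id(self.source_id), normalize_id(self.target_id))


@dataclass(frozen=True)
class RegulationDirection:
    """A lncRNA's regulation direction in each of the two diseases.

    Only lncRNAs whose direction is known and identical in both diseases
    take part in drug labeling.
    """

    lncrna_id: str
    direction_dm: Direction
    direction_ad: Direction

    @property
    def shared_direction(self) -> Direction:
        """The direction if consistent and known in both diseases, else UNKNOWN."""
        if (
            self.direction_dm == self.direction_ad
            and self.direction_dm is not Direction.UNKNOWN
        ):
            return self.direction_dm
        return Direction.UNKNOWN


@dataclass(frozen=True)
class DrugEffectRecord:
    """A drug's directional effect (increase/decrease) on one lncRNA."""

    drug_id: str
    lncrna_id: str
    effect: Effect


@dataclass(frozen=True)
class LabeledDrugSet:
    """Partition of the drug set into therapeutic (D+) and exacerbating (D-).

    ``removed_contradictory`` holds drugs dropped because their signable
    lncRNA effects disagreed in sign; the three sets are pairwise disjoint.
    """

    positives: frozenset[str]
    negatives: frozenset[str]
    removed_contradictory: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        sets = [self.positives, self.negatives, self.removed_contradictory]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("labeled drug sets must be pairwise disjoint")

    def label_of(self, drug_id: str) -> str:
        key = normalize_id(drug_id)
        if any(normalize_id(d) == key for d in self.positives):
            return "positive"
        if any(normalize_id(d) == key for d in self.negatives):
            return "negative"
        raise KeyError(drug_id)

    @property
    def all_labeled(self) -> frozenset[str]:
        return self.positives | self.negatives


class DescriptorMatrix:
    """Molecules x numeric-descriptor matrix (PaDEL-style).

    Thin wrapper around a pandas DataFrame whose index holds molecule
    identifiers and whose columns hold 1D-2D descriptor values.  Missing
    values are NaN.  ``natom_column`` names the atom-count descriptor when
    present (used by the small-molecule screening filter).
    """

    def __init__(self, values: pd.DataFrame, natom_column: str | None = None):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].tolist()
            raise MalformedTableError(f"duplicate molecule ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].tolist()
            raise MalformedTableError(f"duplicate descriptor names: {dups}")
        self._df = values.astype(float)
        self._df.index = values.index.astype(str)
        self._df.index.name = None
        if natom_column is not None and natom_column in self._df.columns:
            col = self._df[natom_column]
            if (col.dropna() < 0).any():
                raise MalformedTableError(
                    f"atom-count column {natom_column!r} has negative entries"
                )
        self.natom_column = natom_column

    # -- container protocol -------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def molecule_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self._df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def n_missing(self) -> int:
        return int(self._df.isna().sum().sum())

    def subset_features(self, names: Sequence[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self._df.columns]
        if missing:
            raise KeyError(f"descriptor columns not present: {missing}")
        natom = self.natom_column if self.natom_column in names else None
        return DescriptorMatrix(self._df.loc[:, list(names)].copy(), natom)

    def drop_features(self, names: Iterable[str]) -> "DescriptorMatrix":
        drop = [n for n in names]
        natom = self.natom_column if self.natom_column not in drop else None
        return DescriptorMatrix(self._df.drop(columns=drop), natom)

    def subset_molecules(self, ids: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(self._df.loc[list(ids)].copy(), self.natom_column)

    def equals(self, other: "DescriptorMatrix") -> bool:
        return self._df.equals(other._df) and self.natom_column == other.natom_column

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, w = self.shape
        return f"DescriptorMatrix({n} molecules x {w} descriptors)"


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, in one place.

    Defaults reproduce the study's stated choices: hub tiers accumulated up
    to 15 nodes, correlation cutoff 0.9, entropy threshold 1.5 nats over a
    10-bin histogram, t-test alpha 0.05, atom-count minimum 7, warning
    leverage 3p/n, candidate probability threshold 0.95, 5-fold CV.
    """

    hub_max_nodes: int = 15
    correlation_cutoff: float = 0.9
    entropy_threshold: float = 1.5
    entropy_bins: int = 10
    alpha: float = 0.05
    natom_min: int = 7
    leverage_multiplier: float = 3.0
    probability_threshold: float = 0.95
    n_folds: int = 5
    n_trees: int = 100
    rng_seed: int = 0
    ad_basis: str = "screening"  # or "training"
    ocsvm_nu: float = 0.1
    ocsvm_gamma: float | None = None  # None -> 1 / (n_features * pooled variance)
    welch: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.correlation_cutoff <= 1:
            raise ValueError("correlation_cutoff must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.5 < self.probability_threshold <= 1:
            raise ValueError("probability_threshold must be in (0.5, 1]")
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")
        if self.hub_max_nodes < 1:
            raise ValueError("hub_max_nodes must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.ad_basis not in ("screening", "training"):
            raise ValueError("ad_basis must be 'screening' or 'training'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Delimited-text readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(sample: str) -> str:
    """Tab or comma, whichever splits the first line into more fields."""
    first = sample.splitlines()[0] if sample else ""
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_edge_list(
    path: str | Path,
    layer: LayerTag,
    *,
    delimiter: str | None = None,
    header: str = "auto",
) -> list[InteractionEdge]:
    """Read a 2-column delimited edge list, collapsing duplicate pairs.

    Duplicates are detected case-insensitively; the first-seen spelling is
    kept.  ``header`` may be 'auto' (skip the first row if either field
    repeats a known column word or the file starts with 'source'/'drug'
    style names), 'present', or 'absent'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    delim = delimiter or _sniff_delimiter(text)
    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    if not rows:
        raise MalformedTableError(f"{path}: empty file")

    start = 0
    if header == "present":
        start = 1
    elif header == "auto":
        head = [c.strip().casefold() for c in rows[0][:2]]
        header_words = {
            "source", "target", "mrna", "mirna", "lncrna", "drug",
            "source_id", "target_id", "left", "right",
        }
        if head and set(head) & header_words:
            start = 1

    edges: list[InteractionEdge] = []
    seen: set[tuple[str, str]] = set()
    n_raw = 0
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue  # blank line
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            raise MalformedTableError(
                f"{path}: line {lineno}: expected 2 non-empty fields, got {row!r}"
            )
        edge = InteractionEdge(row[0].strip(), row[1].strip(), layer)
        n_raw += 1
        if edge.key in seen:
            continue
        seen.add(edge.key)
        edges.append(edge)
    if not edges:
        raise MalformedTableError(f"{path}: no edges after parsing")
    logger.info(
        "read_edge_list %s layer=%s raw=%d deduplicated=%d",
        path, layer.value, n_raw, len(edges),
    )
    return edges


def write_edge_list(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["source", "target"])
        for e in edges:
            writer.writerow([e.source_id, e.target_id])


def read_descriptor_csv(
    path: str | Path,
    natom_name: str | None = "nAtom",
    *,
    delimiter: str | None = None,
) -> DescriptorMatrix:
    """Read a PaDEL-style descriptor CSV (first column = molecule name).

    Empty cells become NaN; any other non-numeric cell raises.  Duplicate
    molecule names raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = delimiter or _sniff_delimiter(path.read_text()[:4096])
    df = pd.read_csv(path, sep=delim, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str).str.strip()
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise MalformedTableError(f"{path}: duplicate molecule names {dups}")
    for col in df.columns:  # object dtype <=> at least one non-numeric cell
        if df[col].dtype == object:
            cleaned = df[col].astype("string").str.strip().replace({"": pd.NA})
            converted = pd.to_numeric(cleaned, errors="coerce")
            bad = cleaned.notna() & converted.isna()
            if bad.any():
                where = df.index[bad][0]
                raise MalformedTableError(
                    f"{path}: non-numeric value {df.loc[where, col]!r} "
                    f"in column {col!r}, molecule {where!r}"
                )
            df[col] = converted
    natom = natom_name if natom_name in df.columns else None
    return DescriptorMatrix(df.astype(float), natom)


def write_descriptor_csv(matrix: DescriptorMatrix, path: str | Path) -> None:
    df = matrix.frame.copy()
    df.index.name = "Name"
    df.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# Packaged reference tables (transcribed from the study's printed tables)
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "table1_nodes": "table1_nodes.tsv",
    "table4_directions": "table4_directions.tsv",
    "table5_drug_classes": "table5_drug_classes.tsv",
}


@dataclass(frozen=True)
class NodeTable:
    """The study's selected network nodes with their degrees."""

    mrnas: tuple[str, ...]               # mRNAs with at least one miRNA partner
    isolated_mrnas: tuple[str, ...]      # listed but partnerless (INS, LEP)
    mirna_degrees: dict[str, int]
    lncrna_degrees: dict[str, int]


@dataclass(frozen=True)
class DrugClassRow:
    drug_id: str
    label: str                    # 'positive' | 'negative'
    lncrna_ids: tuple[str, ...]


def _fixture_text(filename: str) -> str:
    return (resources.files("crosstalk.fixtures") / filename).read_text()


def load_fixture(name: str):
    """Load one of the packaged reference tables by name.

    * ``table1_nodes`` -> :class:`NodeTable`
    * ``table4_directions`` -> list of :class:`RegulationDirection`
    * ``table5_drug_classes`` -> list of :class:`DrugClassRow`
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; options: {sorted(_FIXTURE_FILES)}")
    rows = list(csv.DictReader(
        _fixture_text(_FIXTURE_FILES[name]).splitlines(), delimiter="\t"
    ))
    if name == "table1_nodes":
        mrnas = [r["id"] for r in rows if r["layer"] == "mrna" and r["has_partners"] == "true"]
        isolated = [r["id"] for r in rows if r["layer"] == "mrna" and r["has_partners"] == "false"]
        mirna = {r["id"]: int(r["degree"]) for r in rows if r["layer"] == "mirna"}
        lncrna = {r["id"]: int(r["degree"]) for r in rows if r["layer"] == "lncrna"}
        return NodeTable(tuple(mrnas), tuple(isolated), mirna, lncrna)
    if name == "table4_directions":
        return [
            RegulationDirection(
                r["lncrna"], Direction(r["direction_dm"]), Direction(r["direction_ad"])
            )
            for r in rows
        ]
    return [
        DrugClassRow(r["drug"], r["label"], tuple(r["lncrnas"].split(",")))
        for r in rows
    ]


def table5_effect_records() -> list[DrugEffectRecord]:
    """Reconstructed per-edge effects for the packaged drug-class table.

    The printed table reports each drug's lncRNA partners and its final
    class but not the individual effect verbs; the verb is back-filled as
    the unique direction consistent with the class and the lncRNA's shared
    disease direction (a positive drug decreases an up-regulated lncRNA and
    increases a down-regulated one; a negative drug does the opposite).
    """
    directions = {
        normalize_id(d.lncrna_id): d.shared_direction
        for d in load_fixture("table4_directions")
    }
    records = []
    for row in load_fixture("table5_drug_classes"):
        for lnc in row.lncrna_ids:
            direction = directions[normalize_id(lnc)]
            if direction is Direction.UNKNOWN:  # pragma: no cover - fixture invariant
                raise ValueError(f"fixture lncRNA {lnc} has unknown direction")
            therapeutic = row.label == "positive"
            if direction is Direction.UP:
                effect = Effect.DECREASE if therapeutic else Effect.INCREASE
            else:
                effect = Effect.INCREASE if therapeutic else Effect.DECREASE
            records.append(DrugEffectRecord(row.drug_id, lnc, effect))
    return records
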