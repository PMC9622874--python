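"""Synthetic inputs with the statistical structure every pipeline stage
assumes, plus the ground truth needed to score recovery.

Each generator is a pure function of (spec, seed): bipartite interaction
networks with planted high-degree nodes, drug-lncRNA effect tables with a
controllable fraction of sign-contradictory drugs, descriptor matrices
with planted class-separating columns among constant / duplicated /
low-entropy / heavy-tailed nuisance columns, and a screening library mixing
in-domain drugs, planted far outliers, and under-sized molecules.

The default ``study_scale`` preset mirrors the study's dimensions: 40
training drugs in a 16/24 positive/negative split, 6 informative
descriptors in a 1444-column matrix, and a 2474-drug screening library.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    Direction,
    DrugEffectRecord,
    Effect,
    DescriptorMatrix,
    InteractionEdge,
    LayerTag,
    RegulationDirection,
)

__all__ = ["NetworkBlock", "EffectBlock", "DescriptorBlock", "ScreeningBlock",
           "SyntheticSpec", "simulate_bipartite", "simulate_networks",
           "simulate_effect_table", "simulate_descriptors",
           "simulate_screen_library"]

NATOM_COLUMN = "nAtom"


@dataclass
class NetworkBlock:
    n_left: int = 7
    n_right: int = 412
    edge_probability: float = 0.01   # background Bernoulli edge rate
    n_planted_hubs: int = 7
    hub_degree: int = 6              # guaranteed distinct partners per hub
    n_right_second: int | None = None  # second layer's right side (defaults to n_right)


@dataclass
class EffectBlock:
    n_drugs: int = 40
    n_lncrnas: int = 11
    contradiction_rate: float = 0.0
    positive_fraction: float = 0.4   # study split: 16 of 40
    up_fraction: float = 0.8         # share of lncRNAs up-regulated in both diseases
    known_fraction: float = 1.0      # share with a consistent known direction
    max_edges_per_drug: int = 3


@dataclass
class DescriptorBlock:
    n_pos: int = 16
    n_neg: int = 24
    n_informative: int = 6
    separation: float = 3.0          # class mean gap, in pooled SDs
    n_constant: int = 5
    n_correlated_pairs: int = 5
    n_low_entropy: int = 5
    n_noise: int = 50
    missing_rate: float = 0.0        # applied to noise columns only


@dataclass
class ScreeningBlock:
    n_screen: int = 500
    in_domain_fraction: float = 0.9
    outlier_distance: float = 30.0   # in training SDs from the centroid
    small_molecule_fraction: float = 0.05
    positive_fraction: float = 0.5   # class of in-domain screen drugs


@dataclass
class SyntheticSpec:
    """Everything the generators need; generation is pure in (spec, seed)."""

    seed: int = 0
    network: NetworkBlock = field(default_factory=NetworkBlock)
    effects: EffectBlock = field(default_factory=EffectBlock)
    descriptors: DescriptorBlock = field(default_factory=DescriptorBlock)
    screening: ScreeningBlock = field(default_factory=ScreeningBlock)

    @classmethod
    def study_scale(cls, seed: int = 0) -> "SyntheticSpec":
        """Preset mirroring the study's data shapes."""
        return cls(
            seed=seed,
            network=NetworkBlock(7, 412, 0.005, 7, 4, n_right_second=1700),
            effects=EffectBlock(n_drugs=40, n_lncrnas=11, positive_fraction=0.4),
            descriptors=DescriptorBlock(
                n_pos=16, n_neg=24, n_informative=6, separation=3.0,
                n_constant=293, n_correlated_pairs=300, n_low_entropy=100,
                n_noise=1444 - 6 - 293 - 600 - 100 - 1,  # + atom count = 1444
            ),
            screening=ScreeningBlock(
                n_screen=2474, in_domain_fraction=0.9, outlier_distance=30.0,
                small_molecule_fraction=0.06,
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=raw.get("seed", 0),
            network=NetworkBlock(**raw.get("network", {})),
            effects=EffectBlock(**raw.get("effects", {})),
            descriptors=DescriptorBlock(**raw.get("descriptors", {})),
            screening=ScreeningBlock(**raw.get("screening", {})),
        )


def _rng(spec: SyntheticSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def simulate_bipartite(
    block: NetworkBlock,
    layer: LayerTag,
    rng: np.random.Generator,
    *,
    left_prefix: str = "L",
    right_prefix: str = "R",
) -> tuple[list[InteractionEdge], list[str]]:
    """One bipartite layer with hubs planted on the right side.

    Each of the ``n_planted_hubs`` right nodes gets ``hub_degree`` distinct
    left partners outright.  Every other right node gets exactly one
    uniformly-chosen partner — interaction databases only list molecules
    that interact with something — plus Bernoulli(``edge_probability``)
    extras.  With zero background probability hub degrees are exactly
    ``hub_degree`` and non-hub degrees exactly 1 (0 if the layer has a
    single guaranteed edge disabled by ``hub_degree`` covering all nodes).
    Returns (edges, planted hub ids).
    """
    if block.n_planted_hubs > block.n_right:
        raise ValueError("more planted hubs than right-side nodes")
    if block.hub_degree > block.n_left:
        raise ValueError("hub degree exceeds the left-side node count")
    left = [f"{left_prefix}{i}" for i in range(block.n_left)]
    right = [f"{right_prefix}{i}" for i in range(block.n_right)]
    hubs = list(rng.choice(block.n_right, size=block.n_planted_hubs, replace=False))
    hub_set = set(int(h) for h in hubs)
    pairs: set[tuple[int, int]] = set()
    for h in hubs:
        partners = rng.choice(block.n_left, size=block.hub_degree, replace=False)
        pairs.update((int(i), int(h)) for i in partners)
    for j in range(block.n_right):
        if j not in hub_set:
            pairs.add((int(rng.integers(0, block.n_left)), j))
    if block.edge_probability > 0:
        coin = rng.random((block.n_left, block.n_right)) < block.edge_probability
        for i, j in zip(*np.nonzero(coin)):
            if int(j) not in hub_set:
                pairs.add((int(i), int(j)))
    edges = [
        InteractionEdge(left[i], right[j], layer) for i, j in sorted(pairs)
    ]
    return edges, [right[int(h)] for h in sorted(hubs)]


def simulate_networks(
    spec: SyntheticSpec,
) -> tuple[list[InteractionEdge], list[str], list[InteractionEdge], list[str]]:
    """The two upstream layers: (mRNA-miRNA edges, miRNA hubs,
    miRNA-lncRNA edges, lncRNA hubs).

    The second layer's left side is the first layer's planted hubs, so the
    chain composes the way the real pipeline does.
    """
    first, mirna_hubs = simulate_bipartite(
        spec.network, LayerTag.MRNA_MIRNA, _rng(spec, 1),
        left_prefix="mRNA", right_prefix="miR",
    )
    second_block = NetworkBlock(
        n_left=len(mirna_hubs),
        n_right=spec.network.n_right_second or spec.network.n_right,
        edge_probability=spec.network.edge_probability,
        n_planted_hubs=spec.network.n_planted_hubs,
        hub_degree=min(spec.network.hub_degree, len(mirna_hubs)),
    )
    second_raw, lnc_hubs = simulate_bipartite(
        second_block, LayerTag.MIRNA_LNCRNA, _rng(spec, 2),
        left_prefix="hub", right_prefix="lnc",
    )
    # rename the second layer's left side to the actual hub miRNA ids
    second = [
        InteractionEdge(mirna_hubs[int(e.source_id[3:])], e.target_id, e.layer)
        for e in second_raw
    ]
    return first, mirna_hubs, second, lnc_hubs


def simulate_effect_table(
    spec: SyntheticSpec,
) -> tuple[list[DrugEffectRecord], list[RegulationDirection], dict[str, str]]:
    """Drug-lncRNA effects with a planted contradiction fraction.

    Returns (effects, directions, truth) where truth maps each drug to
    'positive', 'negative', or 'contradictory'.  A contradictory drug gets
    one therapeutic and one exacerbating edge; every other drug's edges all
    share the sign implied by its class.
    """
    blk = spec.effects
    rng = _rng(spec, 3)
    n_known = max(2, int(round(blk.known_fraction * blk.n_lncrnas)))
    directions: list[RegulationDirection] = []
    lnc_dir: dict[str, Direction] = {}
    for i in range(blk.n_lncrnas):
        name = f"lnc{i}"
        if i < n_known:
            d = Direction.UP if rng.random() < blk.up_fraction else Direction.DOWN
            directions.append(RegulationDirection(name, d, d))
            lnc_dir[name] = d
        else:  # discordant between the two diseases -> unsignable
            directions.append(RegulationDirection(name, Direction.UP, Direction.DOWN))
    known = list(lnc_dir)
    if len(known) < 2:
        raise ValueError("need >= 2 consistently-directed lncRNAs")

    def edge(drug: str, lnc: str, therapeutic: bool) -> DrugEffectRecord:
        if lnc_dir[lnc] is Direction.UP:
            eff = Effect.DECREASE if therapeutic else Effect.INCREASE
        else:
            eff = Effect.INCREASE if therapeutic else Effect.DECREASE
        return DrugEffectRecord(drug, lnc, eff)

    drugs = [f"drug{d:03d}" for d in range(blk.n_drugs)]
    contradictory = rng.random(blk.n_drugs) < blk.contradiction_rate
    clean = [d for d, c in zip(drugs, contradictory) if not c]
    n_pos = int(round(blk.positive_fraction * len(clean)))
    pos_set = set(rng.permutation(clean)[:n_pos]) if clean else set()

    effects: list[DrugEffectRecord] = []
    truth: dict[str, str] = {}
    for drug, contra in zip(drugs, contradictory):
        if contra:
            a, b = rng.choice(len(known), size=2, replace=False)
            effects.append(edge(drug, known[int(a)], True))
            effects.append(edge(drug, known[int(b)], False))
            truth[drug] = "contradictory"
        else:
            positive = drug in pos_set
            k = int(rng.integers(1, blk.max_edges_per_drug + 1))
            partners = rng.choice(len(known), size=min(k, len(known)), replace=False)
            for p in partners:
                effects.append(edge(drug, known[int(p)], positive))
            truth[drug] = "positive" if positive else "negative"
    return effects, directions, truth


def _descriptor_names(blk: DescriptorBlock) -> dict[str, list[str]]:
    return {
        "informative": [f"inf{i}" for i in range(blk.n_informative)],
        "constant": [f"const{i}" for i in range(blk.n_constant)],
        "correlated": [
            f"dup{i}{suffix}" for i in range(blk.n_correlated_pairs)
            for suffix in ("a", "b")
        ],
        "low_entropy": [f"lowent{i}" for i in range(blk.n_low_entropy)],
        "noise": [f"noise{i}" for i in range(blk.n_noise)],
    }


def simulate_descriptors(
    spec: SyntheticSpec,
    labels: dict[str, str] | None = None,
) -> tuple[DescriptorMatrix, dict[str, str], dict[str, list[str]]]:
    """Training descriptor matrix with planted structure.

    Returns (matrix, labels, truth) where labels maps molecule id ->
    'positive'/'negative' and truth maps column family -> column names.
    When ``labels`` is supplied (e.g. the classes implied by a simulated
    effect table) it fixes the molecule ids and classes; otherwise the
    descriptor block's n_pos/n_neg do.  Informative columns are Gaussian
    with a class mean gap of ``separation`` pooled SDs; duplicated pairs
    differ by tiny jitter (|r| > 0.95 by construction); low-entropy
    columns put ~95% of their mass on a single value; nuisance noise is
    log-normal (heavy-tailed, like real constitutional descriptors); an
    integer atom-count column (>= 7 for all training drugs) is appended.
    """
    blk = spec.descriptors
    rng = _rng(spec, 4)
    if labels is not None:
        ids = list(labels)
        is_pos = np.array([labels[i] == "positive" for i in ids])
        labels = dict(labels)
    else:
        ids = [f"drug{d:03d}" for d in range(blk.n_pos + blk.n_neg)]
        is_pos = np.array([True] * blk.n_pos + [False] * blk.n_neg)
        labels = {i: ("positive" if p else "negative") for i, p in zip(ids, is_pos)}
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 molecules")
    names = _descriptor_names(blk)

    cols: dict[str, np.ndarray] = {}
    for name in names["informative"]:
        shift = np.where(is_pos, blk.separation, 0.0)
        cols[name] = rng.normal(0.0, 1.0, n) + shift
    for name in names["constant"]:
        cols[name] = np.full(n, float(rng.integers(0, 10)))
    for i in range(blk.n_correlated_pairs):
        base = rng.lognormal(0.0, 1.0, n)
        cols[f"dup{i}a"] = base
        cols[f"dup{i}b"] = base + rng.normal(0.0, 1e-3 * max(base.std(), 1e-9), n)
    for name in names["low_entropy"]:
        x = np.full(n, 1.0)
        n_spread = max(1, int(round(0.05 * n)))
        idx = rng.choice(n, size=n_spread, replace=False)
        x[idx] = rng.uniform(2.0, 10.0, n_spread)
        cols[name] = x
    for name in names["noise"]:
        x = rng.lognormal(0.0, 1.0, n)
        if blk.missing_rate > 0:
            mask = rng.random(n) < blk.missing_rate
            x = x.copy()
            x[mask] = np.nan
        cols[name] = x
    cols[NATOM_COLUMN] = rng.integers(10, 80, n).astype(float)

    frame = pd.DataFrame(cols, index=ids)
    # column order shuffled so no stage can key on position
    order = list(frame.columns)
    order.remove(NATOM_COLUMN)
    rng.shuffle(order)
    frame = frame[order + [NATOM_COLUMN]]
    return DescriptorMatrix(frame, NATOM_COLUMN), labels, names


def simulate_screen_library(
    spec: SyntheticSpec,
    train: DescriptorMatrix,
    labels: dict[str, str] | None = None,
) -> tuple[DescriptorMatrix, pd.DataFrame]:
    """A screening library around a training matrix, with planted truth.

    In-domain drugs resample training rows with small Gaussian jitter (0.1
    training SD per column); when ``labels`` is given the source class is
    drawn with ``positive_fraction``, so in-domain screen drugs carry a
    planted class.  Outliers sit ``outlier_distance`` training SDs from
    the centroid in every descriptor (random sign per descriptor), so they
    stay far outside the training cloud in any feature subset; a
    ``small_molecule_fraction`` of drugs gets an atom count below 7.
    Returns (library, flags) where
    flags has boolean columns ``outlier`` and ``small`` and a
    ``planted_class`` column ('positive'/'negative', '' for outliers).
    """
    blk = spec.screening
    rng = _rng(spec, 5)
    feats = list(train.feature_names)
    Xt = train.frame.to_numpy(dtype=float)
    if np.isnan(Xt).any():
        raise ValueError("training matrix must be complete for screen simulation")
    mu = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0

    by_class: dict[str, list[int]] = {}
    if labels is not None:
        for idx, mol in enumerate(train.molecule_ids):
            by_class.setdefault(labels[mol], []).append(idx)

    n = blk.n_screen
    ids = [f"fda{i:04d}" for i in range(n)]
    outlier = rng.random(n) >= blk.in_domain_fraction
    small = rng.random(n) < blk.small_molecule_fraction
    planted: list[str] = []
    rows = np.empty((n, len(feats)))
    for k in range(n):
        if outlier[k]:
            signs = rng.choice([-1.0, 1.0], size=len(feats))
            rows[k] = mu + blk.outlier_distance * sd * signs
            planted.append("")
        else:
            if by_class:
                cls = "positive" if rng.random() < blk.positive_fraction else "negative"
                src = int(rng.choice(by_class[cls]))
            else:
                cls = ""
                src = int(rng.integers(0, Xt.shape[0]))
            rows[k] = Xt[src] + rng.normal(0.0, 0.1, len(feats)) * sd
            planted.append(cls)
    frame = pd.DataFrame(rows, index=ids, columns=feats)
    natom_col = train.natom_column
    if natom_col is not None:
        natom = rng.integers(10, 80, n).astype(float)
        if small.any():
            natom[small] = rng.integers(1, 7, int(small.sum())).astype(float)
        frame[natom_col] = natom
    flags = pd.DataFrame(
        {"outlier": outlier, "small": small, "planted_class": planted}, index=ids
    )
    return DescriptorMatrix(frame, natom_col), flags
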