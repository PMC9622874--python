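"""The run-all chain: networks -> hubs -> labeling -> feature selection ->
forest training/evaluation -> applicability-domain screening -> ranking.

One global seed fans out to per-stage seeds (hashed on the stage name) so
any stage can be re-run in isolation with identical results.  A
:class:`RunManifest` records the configuration snapshot, the seed, and
every stage's input/output counts; two runs with the same inputs, config
and seed produce identical manifests apart from timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .classify import cross_validate, oob_curve, train_classifier
from .core_io import (
    DescriptorMatrix,
    LayerTag,
    PipelineConfig,
    normalize_id,
    read_descriptor_csv,
    read_edge_list,
)
from .features import select_features
from .labeling import label_drugs, read_direction_table, read_effect_table, write_labels_tsv
from .networks import assemble_tripartite, build_network, select_hubs, write_tripartite_tsv
from .screening import run_screening
from .synthetic import SyntheticSpec, simulate_effect_table, simulate_descriptors, \
    simulate_networks, simulate_screen_library

logger = logging.getLogger("crosstalk")

__all__ = ["RunManifest", "stage_seed", "run_all", "write_synthetic_inputs",
           "INPUT_FILES"]

INPUT_FILES = {
    "mrna_mirna": "mrna_mirna.tsv",
    "mirna_lncrna": "mirna_lncrna.tsv",
    "directions": "lncrna_directions.tsv",
    "effects": "drug_effects.tsv",
    "descriptors": "descriptors.csv",
    "screen": "screen_library.csv",
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global one (< 2^31)."""
    return (seed + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    seed: int
    config: dict
    counts: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
        logger.info("manifest written to %s", path)


def write_synthetic_inputs(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate one full synthetic input directory (plus truth files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .core_io import write_descriptor_csv, write_edge_list

    first, mirna_hubs, second, lnc_hubs = simulate_networks(spec)
    write_edge_list(first, out / INPUT_FILES["mrna_mirna"])
    write_edge_list(second, out / INPUT_FILES["mirna_lncrna"])
    (out / "truth_hubs.json").write_text(
        json.dumps({"mirna_hubs": mirna_hubs, "lncrna_hubs": lnc_hubs}, indent=2)
    )

    effects, directions, effect_truth = simulate_effect_table(spec)
    with open(out / INPUT_FILES["effects"], "w") as fh:
        fh.write("drug\tlncrna\teffect\n")
        for r in effects:
            fh.write(f"{r.drug_id}\t{r.lncrna_id}\t{r.effect.value}\n")
    with open(out / INPUT_FILES["directions"], "w") as fh:
        fh.write("lncrna\tdirection_dm\tdirection_ad\n")
        for d in directions:
            fh.write(f"{d.lncrna_id}\t{d.direction_dm.value}\t{d.direction_ad.value}\n")
    (out / "truth_effects.json").write_text(json.dumps(effect_truth, indent=2))

    class_labels = {d: c for d, c in effect_truth.items() if c != "contradictory"}
    matrix, desc_labels, planted = simulate_descriptors(spec, class_labels or None)
    write_descriptor_csv(matrix, out / INPUT_FILES["descriptors"])
    (out / "truth_descriptors.json").write_text(
        json.dumps({"labels": desc_labels, "planted": planted}, indent=2)
    )

    library, flags = simulate_screen_library(spec, matrix, desc_labels)
    write_descriptor_csv(library, out / INPUT_FILES["screen"])
    flags.to_csv(out / "truth_screen.tsv", sep="\t")
    spec.to_yaml(out / "synthetic_spec.yaml")
    return {k: out / v for k, v in INPUT_FILES.items()}


def run_all(
    config: PipelineConfig,
    input_dir: str | Path,
    output_dir: str | Path,
) -> RunManifest:
    """Execute every stage in order, writing all reports to ``output_dir``.

    The descriptor matrix is restricted to drugs that received a label;
    any stage failure aborts with the stage name in the raised error.
    """
    inp, out = Path(input_dir), Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=config.rng_seed,
        config=dataclasses.asdict(config),
        started=datetime.now(timezone.utc).isoformat(),
    )
    counts = manifest.counts

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        return wrap

    # -- networks & hubs ----------------------------------------------------
    def _networks():
        first = read_edge_list(inp / INPUT_FILES["mrna_mirna"], LayerTag.MRNA_MIRNA)
        second = read_edge_list(inp / INPUT_FILES["mirna_lncrna"], LayerTag.MIRNA_LNCRNA)
        p_net = build_network(first)
        l_net = build_network(second)
        m_hubs = select_hubs(p_net, "right", config.hub_max_nodes)
        l_hubs = select_hubs(l_net, "right", config.hub_max_nodes)
        rows = assemble_tripartite(p_net, m_hubs, l_net, l_hubs)
        write_tripartite_tsv(rows, out / "tripartite.tsv")
        counts.update(
            n_mrna=len(p_net.left_ids), n_mirna=len(p_net.right_ids),
            n_lncrna=len(l_net.right_ids),
            n_mirna_hubs=len(m_hubs.selected_ids),
            n_lncrna_hubs=len(l_hubs.selected_ids),
            n_tripartite_edges=len(rows),
        )
    stage("networks")(_networks)

    # -- drug labeling ------------------------------------------------------
    labels_holder = {}

    def _labeling():
        effects = read_effect_table(inp / INPUT_FILES["effects"])
        directions = read_direction_table(inp / INPUT_FILES["directions"])
        labels = label_drugs(effects, directions)
        write_labels_tsv(labels, out / "drug_labels.tsv")
        labels_holder["labels"] = labels
        counts.update(
            n_drugs_labeled=len(labels.all_labeled),
            n_positive=len(labels.positives),
            n_negative=len(labels.negatives),
            n_contradictory_removed=len(labels.removed_contradictory),
        )
    stage("labeling")(_labeling)
    labels = labels_holder["labels"]

    # -- feature selection --------------------------------------------------
    fs_holder = {}

    def _features():
        matrix = read_descriptor_csv(inp / INPUT_FILES["descriptors"])
        labeled_keys = {normalize_id(d) for d in labels.all_labeled}
        keep = [m for m in matrix.molecule_ids if normalize_id(m) in labeled_keys]
        matrix = matrix.subset_molecules(keep)
        selected, report = select_features(matrix, labels)
        report.to_tsv(out / "feature_selection.tsv")
        fs_holder["matrix"] = matrix
        fs_holder["selected"] = selected
        counts.update(
            n_descriptors_input=report.n_input_features,
            n_descriptors_selected=len(report.selected),
        )
    stage("features")(_features)
    selected = fs_holder["selected"]

    # -- model: OOB curve, CV, final fit ------------------------------------
    model_holder = {}

    def _model():
        curve = oob_curve(
            selected, labels, seed=stage_seed(config.rng_seed, "oob"),
            max_trees=max(2 * config.n_trees, 50),
        )
        curve.to_tsv(out / "oob_curve.tsv")
        report = cross_validate(
            selected, labels, n_folds=config.n_folds,
            seed=stage_seed(config.rng_seed, "cv"), n_trees=config.n_trees,
        )
        report.to_tsv(out / "cv_report.tsv")
        model = train_classifier(
            selected, labels, n_trees=config.n_trees,
            seed=stage_seed(config.rng_seed, "train"),
        )
        model.save(out / "model.pkl")
        model_holder["model"] = model
        counts.update(
            n_trees=model.n_trees,
            oob_chosen_n_trees=curve.chosen_n_trees,
            cv_correct=int(round(report.overall_accuracy * len(selected.molecule_ids))),
        )
    stage("model")(_model)
    model = model_holder["model"]

    # -- screening ----------------------------------------------------------
    def _screening():
        library = read_descriptor_csv(inp / INPUT_FILES["screen"])
        report, candidates = run_screening(model, selected, library, config)
        report.to_tsv(out / "screening_report.tsv")
        candidates.to_tsv(out / "candidates.tsv")
        counts.update(
            n_screen_input=report.n_input,
            n_screen_small=len(report.removed_small_molecules),
            n_screen_missing=len(report.removed_missing_features),
            n_screen_high_leverage=len(report.removed_high_leverage),
            n_screen_ocsvm=len(report.removed_ocsvm),
            n_screen_retained=len(report.retained),
            n_candidates_positive=len(candidates.positives),
            n_candidates_negative=len(candidates.negatives),
        )
    stage("screening")(_screening)

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_json(out / "manifest.json")
    return manifest
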