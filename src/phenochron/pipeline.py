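"""End-to-end orchestration: map -> propagate -> bin -> usage -> associate.

Reads the four inputs (ontology, dictionary, encounters, genotypes), runs
every stage of the longitudinal phenotyping analysis, and writes tabular
outputs plus a machine-readable run manifest recording configuration and
every drop/filter count, so the effect of each filter is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, mapping, temporal
from .ontology import DEFAULT_MODIFIER_ROOTS, load_ontology

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and analysis parameters for one pipeline run."""

    ontology: Path
    dictionary: Path
    encounters: Path
    genotypes: Path
    outdir: Path
    bin_width: float = 0.25
    max_age: float = 25.0
    min_carriers: int = 2
    fdr_q: float = 0.05
    modifier_roots: tuple[str, ...] = DEFAULT_MODIFIER_ROOTS
    extra_icd_codes: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for name in ("ontology", "dictionary", "encounters", "genotypes"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")
        temporal.BinGrid(self.bin_width, self.max_age)  # raises if invalid


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def summarize_cohort(windows, tensor: temporal.PresenceTensor) -> dict:
    """Cohort usage summary: patient-years and per-bin informative counts."""
    summary = temporal.summarize_windows(windows)
    per_bin = tensor.informative.sum(axis=0)
    summary.update({
        "n_bins": tensor.n_bins,
        "informative_per_bin_min": int(per_bin.min()),
        "informative_per_bin_median": float(np.median(per_bin)),
        "informative_per_bin_max": int(per_bin.max()),
    })
    return summary


@dataclass
class RunReport:
    summary: dict
    counters: dict
    associations: pd.DataFrame
    outdir: Path = field(default=None)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and write outputs under ``config.outdir``.

    Outputs: ``cohort_summary.json``, ``term_counts.tsv`` (terms x bins
    present-count matrix), ``associations.tsv`` (ranked), one
    ``trajectory_<gene>_<term>.tsv`` per BH-significant pair, and
    ``manifest.json`` (config, input checksums, drop counts).
    Any stage failure aborts with the stage name and cause.
    """
    config.validate()
    stage = "load"
    try:
        graph = load_ontology(config.ontology)
        dictionary = mapping.load_dictionary(config.dictionary, graph)
        raw = pd.read_csv(config.encounters, sep="\t", dtype={"individual_id": str})
        genotypes = pd.read_csv(config.genotypes, sep="\t", dtype=str)

        stage = "map"
        mapped, counters = mapping.map_encounters(
            raw, dictionary, frozenset(config.extra_icd_codes) or None
        )

        stage = "usage"
        windows = temporal.usage_windows(raw)

        stage = "bin"
        grid = temporal.BinGrid(config.bin_width, config.max_age)
        tensor = temporal.build_presence(mapped, graph, grid, windows)

        stage = "associate"
        results = association.run_study(
            tensor, genotypes, graph,
            min_carriers=config.min_carriers,
            fdr_q=config.fdr_q,
            modifier_roots=config.modifier_roots,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = summarize_cohort(windows, tensor)
    summary["n_encounter_rows"] = int(len(raw))
    summary["n_mapped_term_rows"] = int(len(mapped))
    summary["n_propagated_term_instances"] = int(tensor.present.sum())
    summary["n_terms"] = len(tensor.terms)
    summary["n_nominal_associations"] = int(results["nominal_significant"].sum())
    summary["n_bh_significant"] = int(results["bh_significant"].sum())

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "cohort_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    tensor.term_count_matrix().to_csv(outdir / "term_counts.tsv", sep="\t")
    results.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    for _, row in results[results["bh_significant"]].iterrows():
        traj = association.pair_trajectory(row, tensor, genotypes)
        name = f"trajectory_{row['gene']}_{row['hpo_id'].replace(':', '_')}.tsv"
        traj.to_csv(outdir / name, sep="\t", index=False)
    manifest = {
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in vars(config).items()},
        "input_sha256": {name: _sha256(getattr(config, name))
                         for name in ("ontology", "dictionary", "encounters", "genotypes")},
        "drop_counts": counters,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    logger.info("pipeline complete: %d pairs tested, %d BH-significant",
                len(results), summary["n_bh_significant"])
    return RunReport(summary, counters, results, outdir)
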