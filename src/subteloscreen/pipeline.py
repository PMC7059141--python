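"""End-to-end screen driver with a run manifest for reproducibility.

``run_pipeline`` executes scan -> classify -> differential -> associate ->
screen -> report from a flat key/value config.  Identical config and
inputs produce identical outputs.  All outputs are written to a temporary
staging directory and moved into place only on success, so a failed run
never leaves partial results behind.

The manifest records the tool version, every parameter, a SHA-256 of every
input file and the assembly/annotation identifiers supplied by the user —
enough to reproduce the run bit-for-bit given the same inputs.  The paper
trail matters here because no genome build is assumed: the identifiers are
whatever the user declares.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import sys
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .candidate_screen import run_screen, venn_counts, write_report
from .gene_association import write_associations_tsv
from .io_formats import read_chrom_sizes, read_fasta, read_gtf_genes, read_peaks, write_peaks_bed
from .its_scanner import (
    INTERSTITIAL,
    ScanConfig,
    classify_arrays,
    read_arrays_bed,
    scan_arrays,
    write_arrays_bed,
)
from .peak_differential import compare_conditions, label_modulated

__all__ = ["RunManifest", "run_pipeline", "load_config", "CONFIG_KEYS"]

# the flat config schema; every key is optional except the input files
CONFIG_KEYS = {
    "fasta": None,
    "its_bed": None,
    "chrom_sizes": None,
    "peaks_a": None,
    "peaks_b": None,
    "peak_format": "narrowPeak",
    "condition_a": "control",
    "condition_b": "treatment",
    "genes": None,
    "window": 100_000,
    "min_overlap": 1,
    "modulated_mode": "union",
    "anchor": "body",
    "motif": "TTAGGG",
    "min_units": 3,
    "max_spacer": 0,
    "max_mismatches": 0,
    "terminal_margin": 10_000,
    "assembly_id": "unspecified",
    "annotation_id": "unspecified",
}


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    subcommand: str
    params: dict
    input_hashes: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "tool": "subteloscreen",
            "version": self.version or __version__,
            "subcommand": self.subcommand,
            "params": self.params,
            "input_hashes": self.input_hashes,
            "timestamp": self.timestamp,
        }

    def write(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_manifest(subcommand: str, params: dict, input_files: dict) -> RunManifest:
    hashes = {
        name: sha256_file(path) for name, path in input_files.items() if path is not None
    }
    return RunManifest(
        subcommand=subcommand,
        params={k: v for k, v in sorted(params.items())},
        input_hashes=hashes,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    )


def load_config(path) -> dict:
    """Read and validate a flat key/value YAML config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a flat key: value mapping")
    unknown = sorted(set(raw) - set(CONFIG_KEYS))
    if unknown:
        raise ValueError(f"config {path}: unknown keys {unknown}")
    config = dict(CONFIG_KEYS)
    config.update(raw)
    return config


def _log(stage: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    print(f"[subteloscreen] stage={stage} elapsed={time.time() - t0:.2f}s {extras}",
          file=sys.stderr)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full screen; returns a summary dict (counts + paths).

    Validates that every named input exists before any stage runs.
    """
    config = {**CONFIG_KEYS, **config}
    required_inputs = {"peaks_a": config["peaks_a"], "peaks_b": config["peaks_b"],
                       "genes": config["genes"]}
    if config["fasta"] is None and config["its_bed"] is None:
        raise ValueError("config must name either 'fasta' or 'its_bed'")
    if config["its_bed"] is not None and config["fasta"] is None and config["chrom_sizes"] is None:
        raise ValueError("'its_bed' input requires 'chrom_sizes' for classification")
    for key in ("fasta", "its_bed", "chrom_sizes"):
        if config[key] is not None:
            required_inputs[key] = config[key]
    for name, path in required_inputs.items():
        if path is None:
            raise ValueError(f"config is missing required input {name!r}")
        if not Path(path).exists():
            raise ValueError(f"input {name!r} not found: {path}")

    scan_config = ScanConfig(
        motif=config["motif"],
        min_units=int(config["min_units"]),
        max_spacer=int(config["max_spacer"]),
        max_mismatches_per_unit=int(config["max_mismatches"]),
        terminal_margin=int(config["terminal_margin"]),
    )

    out_dir = Path(out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".subteloscreen.", dir=out_dir.parent))
    t0 = time.time()
    try:
        # --- ITS arrays
        if config["fasta"] is not None:
            assembly = read_fasta(config["fasta"])
            chrom_sizes = assembly.chrom_sizes
            arrays = []
            for seq in assembly:
                arrays.extend(scan_arrays(seq, scan_config))
            arrays = classify_arrays(arrays, chrom_sizes, scan_config)
            _log("scan", t0, arrays=len(arrays))
        else:
            chrom_sizes = read_chrom_sizes(config["chrom_sizes"])
            arrays = read_arrays_bed(config["its_bed"])
            arrays = classify_arrays(arrays, chrom_sizes, scan_config)
            _log("load-its", t0, arrays=len(arrays))
        its_arrays = [a for a in arrays if a.array_class == INTERSTITIAL]
        write_arrays_bed(arrays, staging / "its_all.bed", scan_config)
        write_arrays_bed(its_arrays, staging / "its.bed", scan_config)

        # --- differential peaks
        set_a = read_peaks(config["peaks_a"], config["peak_format"], chrom_sizes)
        set_a.condition_label = str(config["condition_a"])
        set_b = read_peaks(config["peaks_b"], config["peak_format"], chrom_sizes)
        set_b.condition_label = str(config["condition_b"])
        diff = compare_conditions(set_a, set_b, int(config["min_overlap"]))
        lost, gained = label_modulated(diff, "A_is_control")
        _log("diff", t0, lost=len(lost), gained=len(gained),
             shared_a=len(diff.shared_A), shared_b=len(diff.shared_B))
        for name, peaks in (
            ("lost", lost), ("gained", gained),
            ("shared_a", diff.shared_A), ("shared_b", diff.shared_B),
        ):
            write_peaks_bed(peaks, staging / f"{name}.bed")

        # --- screen
        genes = read_gtf_genes(config["genes"])
        report = run_screen(
            lost, gained, its_arrays, genes,
            window=int(config["window"]),
            modulated_mode=str(config["modulated_mode"]),
            anchor=str(config["anchor"]),
        )
        report.params["assembly_id"] = config["assembly_id"]
        report.params["annotation_id"] = config["annotation_id"]
        write_report(report, staging / "report.tsv", staging / "report.json")
        _log("screen", t0, genes=len(genes),
             candidates=len(report.final_candidates))

        manifest = build_manifest("run", dict(config), required_inputs)
        manifest.write(staging / "manifest.json")

        out_dir.mkdir(parents=True, exist_ok=True)
        for item in staging.iterdir():
            shutil.move(str(item), str(out_dir / item.name))
    finally:
        shutil.rmtree(staging, ignore_errors=True)

    return {
        "counts": {
            "arrays": len(arrays),
            "interstitial": len(its_arrays),
            "lost_peaks": len(lost),
            "gained_peaks": len(gained),
            "final_candidates": len(report.final_candidates),
            "venn": list(venn_counts(report)),
        },
        "out_dir": str(out_dir),
        "report": report,
    }
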