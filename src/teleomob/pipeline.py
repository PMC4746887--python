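"""Full-pipeline orchestration: simulate or ingest genomes, mask,
summarize, and compare species from a single YAML config with one
global seed.

Stage outputs land in a fixed run-directory layout::

    <outdir>/
      manifest.json
      <species>/genome.fa        (simulated species)
      <species>/truth.tsv
      <species>/library.fa
      <species>/hits.out
      <species>/coverage.tsv
      <species>/landscape.tsv
      compare/merged_coverage.tsv
      compare/size_te.tsv

Deterministic stages are checksum-gated: when a stage's recorded input
checksums match and its outputs are present and unchanged, the stage is
skipped on re-run, so deleting a downstream output regenerates it
without re-running upstream stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import simulate as sim
from .io import (
    read_fasta,
    read_library_fasta,
    read_rm_out,
    write_rm_out,
)
from .landscape import (
    SizeTEPoint,
    coverage_table,
    landscape,
    landscape_to_frame,
    size_te_regression,
)
from .masker import MaskerParams, mask_genome, masked_bp

__all__ = ["validate_config", "run_pipeline", "compare_species", "ConfigError"]


class ConfigError(ValueError):
    """Carries every validation problem at once."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid run config:\n" + "\n".join(f"  - {e}" for e in errors))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(cfg: dict) -> list[str]:
    """Return a list of all validation errors (empty when valid)."""
    errors: list[str] = []
    species = cfg.get("species")
    if not species:
        errors.append("config needs a non-empty 'species' list")
        return errors
    names = [s.get("name") for s in species]
    if len(set(names)) != len(names) or any(not n for n in names):
        errors.append("species names must be present and unique")
    for s in species:
        n = s.get("name", "?")
        if "simulate" not in s and "genome" not in s:
            errors.append(f"species '{n}': needs either 'simulate' or 'genome'")
        for key in ("genome", "rm_out", "library"):
            if key in s and not Path(s[key]).exists():
                errors.append(f"species '{n}': {key} path {s[key]} does not exist")
    if "library" in cfg and not Path(cfg["library"]).exists():
        errors.append(f"library path {cfg['library']} does not exist")
    return errors


def _load_cfg(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


class _Manifest:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.data: dict[str, Any] = {"config_hash": config_hash, "stages": {}}
        self.previous: dict[str, Any] = {}
        if path.exists():
            try:
                prev = json.loads(path.read_text())
                if prev.get("config_hash") == config_hash:
                    self.previous = prev.get("stages", {})
            except json.JSONDecodeError:
                pass

    def stage_fresh(self, key: str, inputs: dict[str, str], outputs: list[Path]) -> bool:
        prev = self.previous.get(key)
        if not prev or prev.get("inputs") != inputs:
            return False
        for p in outputs:
            if not p.exists() or _sha256(p) != prev["outputs"].get(str(p)):
                return False
        self.data["stages"][key] = prev
        return True

    def record(self, key: str, inputs: dict[str, str], outputs: list[Path], seconds: float) -> None:
        self.data["stages"][key] = {
            "inputs": inputs,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def write(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute simulate -> mask -> summarize for every species, then the
    cross-species comparison; returns the run manifest (also written to
    ``<outdir>/manifest.json``).

    All validation errors are raised together before any stage runs;
    stage failures abort with the failing stage named, preserving the
    outputs already written.
    """
    cfg = _load_cfg(config)
    errors = validate_config(cfg)
    if errors:
        raise ConfigError(errors)

    outdir = Path(outdir or cfg.get("outdir", "runs/run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    config_hash = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()
    manifest = _Manifest(outdir / "manifest.json", config_hash)
    mp = MaskerParams(**cfg.get("masker", {}))
    ls_cfg = cfg.get("landscape", {})

    summaries: dict[str, dict] = {}
    for si, sp in enumerate(cfg["species"]):
        name = sp["name"]
        spdir = outdir / name
        spdir.mkdir(exist_ok=True)
        stage = f"{name}:simulate"
        try:
            if "simulate" in sp:
                sim_cfg = sim.config_from_dict({**sp["simulate"], "seed": seed + si,
                                                "genome_id": sp["simulate"].get("genome_id", name)})
                inputs = {"config": config_hash, "seed": str(seed + si)}
                outs = [spdir / "genome.fa", spdir / "truth.tsv", spdir / "library.fa"]
                if not manifest.stage_fresh(stage, inputs, outs):
                    t0 = time.perf_counter()
                    record, truth = sim.simulate_genome(sim_cfg)
                    sim.write_fasta([record], outs[0])
                    sim.write_truth_tsv(truth, outs[1])
                    sim.write_library_fasta(
                        [s.consensus for s in sim_cfg.insertion_specs], outs[2]
                    )
                    manifest.record(stage, inputs, outs, time.perf_counter() - t0)
                genome_path = outs[0]
                library_path = sp.get("library") or cfg.get("library") or outs[2]
            else:
                genome_path = Path(sp["genome"])
                library_path = sp.get("library") or cfg.get("library")

            stage = f"{name}:mask"
            hits_path = spdir / "hits.out"
            if "rm_out" in sp:
                hits_path = Path(sp["rm_out"])
                genome_len = sum(len(r.seq) for r in read_fasta(genome_path))
            else:
                if library_path is None:
                    raise RuntimeError(f"species '{name}': no library available for masking")
                inputs = {"genome": _sha256(Path(genome_path)),
                          "library": _sha256(Path(library_path))}
                if not manifest.stage_fresh(stage, inputs, [hits_path]):
                    t0 = time.perf_counter()
                    genome_recs = read_fasta(genome_path)
                    library = read_library_fasta(library_path)
                    hits = []
                    for rec in genome_recs:
                        hits.extend(mask_genome(rec, library, mp))
                    write_rm_out(hits, hits_path)
                    manifest.record(stage, inputs, [hits_path], time.perf_counter() - t0)
                genome_len = sum(len(r.seq) for r in read_fasta(genome_path))

            stage = f"{name}:summarize"
            cov_path = spdir / "coverage.tsv"
            land_path = spdir / "landscape.tsv"
            inputs = {"hits": _sha256(Path(hits_path))}
            hits = read_rm_out(hits_path)
            if not manifest.stage_fresh(stage, inputs, [cov_path, land_path]):
                t0 = time.perf_counter()
                rows = coverage_table(hits, genome_len,
                                      ls_cfg.get("hierarchy", "superfamily"))
                pd.DataFrame([r.__dict__ for r in rows]).to_csv(cov_path, sep="\t", index=False)
                bins, spill = landscape(
                    hits, genome_len,
                    bin_width=ls_cfg.get("bin_width", 1.0),
                    group_by=ls_cfg.get("group_by", "superfamily"),
                    use_correction=ls_cfg.get("use_correction", True),
                )
                landscape_to_frame(bins).to_csv(land_path, sep="\t", index=False)
                manifest.record(stage, inputs, [cov_path, land_path], time.perf_counter() - t0)

            bp, frac = masked_bp(hits, genome_len)
            summaries[name] = {
                "genome_length": genome_len,
                "masked_bp": bp,
                "te_fraction_pct": 100.0 * frac,
                "coverage": pd.read_csv(cov_path, sep="\t"),
            }
        except ConfigError:
            raise
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if len(summaries) >= 2:
        cmpdir = outdir / "compare"
        cmpdir.mkdir(exist_ok=True)
        report = compare_species(summaries)
        report["merged_coverage"].to_csv(cmpdir / "merged_coverage.tsv", sep="\t", index=True)
        report["points"].to_csv(cmpdir / "size_te.tsv", sep="\t", index=False)
        manifest.data["compare"] = {
            k: report[k] for k in ("slope", "intercept", "pearson_r", "warning") if k in report
        }

    manifest.write()
    return manifest.data


def compare_species(summaries: dict[str, dict]) -> dict:
    """Cross-species report: merged coverage table (one column block per
    species), the genome-size ~ TE-fraction regression, and the points
    behind it.  A degenerate (zero-variance) regression is surfaced as a
    documented warning instead of an error."""
    if len(summaries) < 2:
        raise ValueError("cross-species comparison needs at least 2 species")
    for name, s in summaries.items():
        if not s.get("genome_length"):
            raise ValueError(f"species '{name}' is missing its genome length")

    blocks = []
    for name, s in sorted(summaries.items()):
        cov = s["coverage"].set_index(["level", "group"])[["count", "bp", "pct"]]
        cov.columns = pd.MultiIndex.from_product([[name], cov.columns])
        blocks.append(cov)
    merged = pd.concat(blocks, axis=1).fillna(0)

    points = pd.DataFrame(
        {
            "species": list(sorted(summaries)),
            "genome_size_mb": [summaries[n]["genome_length"] / 1e6 for n in sorted(summaries)],
            "te_fraction_pct": [summaries[n]["te_fraction_pct"] for n in sorted(summaries)],
        }
    )
    out: dict[str, Any] = {"merged_coverage": merged, "points": points}
    try:
        pts = [
            SizeTEPoint(r.species, r.genome_size_mb, r.te_fraction_pct)
            for r in points.itertuples()
        ]
        slope, intercept, r = size_te_regression(pts)
        out.update(slope=slope, intercept=intercept, pearson_r=r)
    except ValueError as exc:
        out["warning"] = f"size~TE regression not computed: {exc}"
    return out
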