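"""End-to-end orchestration of the genomic pipeline.

``run_genomic`` chains the stages -- (optional) simulation, windowed depth,
two-pass DOC-ratio normalization, amplified-segment and internal-deletion
calling, and junction resolution -- and writes per-stage text outputs plus a
consolidated JSON report.  Every output embeds a provenance block (version,
seed, configuration hash) so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from . import coverage, junction as junction_mod, sam, simulate

__all__ = ["RunConfig", "run_genomic", "version_and_provenance", "StageError"]

DEFAULTS: dict[str, Any] = {
    "window": 100,
    "threshold": 1.5,
    "min_run": 20,
    "smooth_window": 21,
    "deletion_step": 0.25,
    "min_clip": 10,
    "min_support": 3,
    "k_sd": 4.0,
    "insert_mean": 250,
    "insert_sd": 25.0,
    "read_length": 100,
    "coverage": 30.0,
    "error_rate": 0.0,
    "seed": 1,
}


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str
    test_sam: str | None = None
    control_sam: str | None = None
    reference_fasta: str | None = None
    simulate: Mapping[str, Any] | None = None  # architecture parameters
    params: dict[str, Any] = dataclass_field(default_factory=dict)

    def resolved(self) -> dict[str, Any]:
        merged = dict(DEFAULTS)
        merged.update(self.params)
        return merged


def version_and_provenance(config: Mapping[str, Any], seed: int) -> dict[str, Any]:
    """Provenance block embedded in every output: version, seed, config hash."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return {
        "tool": "ampliscan",
        "version": __version__,
        "seed": int(seed),
        "config_hash": hashlib.sha256(canon.encode()).hexdigest()[:16],
        "config": dict(config),
    }


def _simulate_pair_of_libraries(cfg: RunConfig, params: Mapping[str, Any]):
    """Build reference + genotypes from the config's simulation block and
    return (reference, test records, control records)."""
    simspec = dict(cfg.simulate or {})
    chrom = simspec.get("chromosome", "chr")
    ref_length = int(simspec.get("reference_length", 1_000_000))
    bp5 = int(simspec.get("bp5", ref_length * 2 // 5))
    bp3 = int(simspec.get("bp3", ref_length * 3 // 5))
    copies = int(simspec.get("copy_count", 2))
    seed = int(params["seed"])

    ref = simulate.build_reference(seed, {chrom: ref_length})
    arch = simulate.AmpliconArchitecture(chrom, bp5, bp3, copies, label="R")
    single = simulate.AmpliconArchitecture(chrom, bp5, bp3, 1, label="S")
    profile = simulate.ReadProfile(
        read_length=int(params["read_length"]),
        insert_mean=int(params["insert_mean"]),
        insert_sd=float(params["insert_sd"]),
        error_rate=float(params["error_rate"]),
        coverage=float(params["coverage"]),
        seed=seed,
    )
    test = list(
        simulate.project_alignments(
            simulate.simulate_read_pairs(simulate.homozygote(ref, arch), profile)
        )
    )
    control_profile = simulate.ReadProfile(
        read_length=profile.read_length,
        insert_mean=profile.insert_mean,
        insert_sd=profile.insert_sd,
        error_rate=profile.error_rate,
        coverage=profile.coverage,
        seed=seed + 1,
    )
    control = list(
        simulate.project_alignments(
            simulate.simulate_read_pairs(simulate.homozygote(ref, single), control_profile)
        )
    )
    return ref, test, control


def run_genomic(cfg: RunConfig) -> dict[str, Any]:
    """Run simulate -> depth -> ratio -> callcnv -> junction and report.

    Returns the report dict (also written to ``report.json`` in the output
    directory).  Any stage failure raises :class:`StageError` naming the
    stage; no partial report is written.
    """
    t0 = time.time()
    params = cfg.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"provenance": version_and_provenance(params, params["seed"])}

    # --- inputs -----------------------------------------------------------
    try:
        if cfg.simulate is not None:
            ref, test_records, control_records = _simulate_pair_of_libraries(cfg, params)
        else:
            if not (cfg.test_sam and cfg.control_sam and cfg.reference_fasta):
                raise ValueError("need test_sam, control_sam and reference_fasta (or a simulate block)")
            ref = simulate.ReferenceGenome(sam.read_fasta(cfg.reference_fasta))
            test_records = list(sam.read_sam(cfg.test_sam))
            control_records = list(sam.read_sam(cfg.control_sam))
        if not test_records or not control_records:
            raise ValueError("empty alignment input")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", exc) from exc

    lengths = ref.lengths
    chrom = next(iter(lengths))

    # --- depth ------------------------------------------------------------
    try:
        window = int(params["window"])
        test_tracks = coverage.window_counts(test_records, lengths, window)
        control_tracks = coverage.window_counts(control_records, lengths, window)
        _write_window_tsv(out / "windows_test.tsv", test_tracks[chrom])
        _write_window_tsv(out / "windows_control.tsv", control_tracks[chrom])
        report["depth"] = {
            "window": window,
            "test_reads": test_tracks[chrom].n_reads,
            "control_reads": control_tracks[chrom].n_reads,
        }
    except Exception as exc:
        raise StageError("depth", exc) from exc

    # --- ratio + segmentation (two-pass normalization) ---------------------
    try:
        ratio_track, segments = coverage.two_pass_ratio(
            test_tracks[chrom],
            control_tracks[chrom],
            threshold=float(params["threshold"]),
            min_run=int(params["min_run"]),
            smooth_window=int(params["smooth_window"]),
        )
        deletions = []
        for seg in segments:
            deletions.extend(
                coverage.call_internal_deletions(
                    ratio_track, seg,
                    step=float(params["deletion_step"]),
                    min_run=int(params["min_run"]),
                    smooth_window=int(params["smooth_window"]),
                )
            )
        _write_ratio_tsv(out / "ratio.tsv", ratio_track)
        _write_segments_bed(out / "segments.bed", chrom, segments + deletions)
        report["cnv"] = {
            "segments": [_segment_dict(s) for s in segments],
            "internal_deletions": [_segment_dict(s) for s in deletions],
        }
    except Exception as exc:
        raise StageError("cnv", exc) from exc

    # --- junction ----------------------------------------------------------
    try:
        evidence = junction_mod.collect_softclipped(test_records, int(params["min_clip"]))
        pairs = junction_mod.collect_discordant_pairs(
            test_records, float(params["insert_mean"]), float(params["insert_sd"]),
            float(params["k_sd"]),
        )
        evidence.pairs = pairs.pairs
        try:
            calls = junction_mod.resolve_junctions(
                evidence, ref, chrom, min_support=int(params["min_support"])
            )
            report["junctions"] = [
                {
                    "bp5": c.bp5,
                    "bp3": c.bp3,
                    "kind": c.kind,
                    "length": c.amplicon_length if c.tandem else c.deletion_length,
                    "clip_support": c.clip_support,
                    "discordant_support": c.discordant_support,
                    "consensus": c.consensus,
                    "note": "orientation requires phased variants",
                }
                for c in calls
            ]
        except junction_mod.NoCallError as exc:
            report["junctions"] = []
            report["junction_no_call"] = str(exc)
        (out / "junctions.json").write_text(
            json.dumps({"provenance": report["provenance"], "junctions": report.get("junctions", [])}, indent=2)
        )
    except Exception as exc:
        raise StageError("junction", exc) from exc

    report["wall_time_s"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _segment_dict(seg: coverage.RatioSegment) -> dict[str, Any]:
    d = {
        "start": seg.start,
        "end": seg.end,
        "mean_ratio": round(seg.mean_ratio, 4),
        "copies": seg.copies,
        "kind": seg.kind,
    }
    if seg.fractional_drop is not None:
        d["fractional_drop"] = round(seg.fractional_drop, 4)
    return d


def _write_window_tsv(path: Path, track: coverage.WindowTrack) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart0\tend0\tcount\n")
        for i, count in enumerate(track.counts):
            fh.write(f"{track.chromosome}\t{i * track.window}\t{(i + 1) * track.window}\t{int(count)}\n")


def _write_ratio_tsv(path: Path, track: coverage.RatioTrack) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart0\tend0\tratio\n")
        for i, r in enumerate(track.ratio):
            value = f"{r:.4f}" if np.isfinite(r) else "NA"
            fh.write(f"{track.chromosome}\t{i * track.window}\t{(i + 1) * track.window}\t{value}\n")


def _write_segments_bed(path: Path, chrom: str, segments: list[coverage.RatioSegment]) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            score = int(round(seg.mean_ratio * 100))
            fh.write(f"{chrom}\t{seg.start - 1}\t{seg.end}\t{seg.kind}\t{score}\n")
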