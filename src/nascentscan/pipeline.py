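"""End-to-end pipeline with provenance.

Stages run in order bin -> (optional amanitin subtraction) -> call ->
classify -> pair -> count -> metagene.  Every run writes a manifest
recording the effective configuration hash, input checksums and output
checksums; re-running with identical inputs and configuration produces a
byte-identical manifest.  No stage mutates its inputs — all intermediates
are files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from . import io as nsio
from .classify import ClassifierConfig, classify_all
from .enhancers import annotate_pairs, pair_ernas
from .hmm import HMMParams, call_transcripts_genome
from .quantify import count_in_intervals, metagene, profile_to_frame
from .tracks import amanitin_subtract, assign_polymerase, bin_reads, normalize_depth

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; defaults are the published parameters.

    shape 5 / negative-log transition 200 for standard calling, 5 / 10 for
    the alpha-amanitin preset; 9 kb eRNA length bound; 1 kb NF-kB radius;
    +/- 4 kb metagene flank; q < 0.001 regulation cutoff.
    """

    bin_width: int = 25
    hmm_shape_n: float = 5.0
    hmm_neg_log_trans: float = 200.0
    amanitin_shape_n: float = 5.0
    amanitin_neg_log_trans: float = 10.0
    subtract_k: int = 3
    min_unit_length: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    erna_max_len: int = 9000
    nfkb_radius: int = 1000
    metagene_flank: int = 4000
    metagene_bin: int = 25
    q_max: float = 0.001
    polymerase_ratio_threshold: float = 1.0
    em_max_iter: int = 30
    em_tol: float = 1e-4
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def hmm_params(self) -> HMMParams:
        return HMMParams(shape_n=self.hmm_shape_n,
                         neg_log_trans_t_to_n=self.hmm_neg_log_trans)

    def amanitin_params(self) -> HMMParams:
        return HMMParams(shape_n=self.amanitin_shape_n,
                         neg_log_trans_t_to_n=self.amanitin_neg_log_trans)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    inputs: Dict[str, str],
    outdir,
) -> Path:
    """Run the full pipeline; returns the path to the written manifest.

    ``inputs`` maps roles to file paths: ``reads`` (control/vehicle BED,
    required), ``sizes`` (chrom sizes TSV, required), ``annotations``
    (GTF), ``repeats`` (BED), ``peaks`` (NF-kB peak BED) and optionally
    ``amanitin_reads`` for the non-Pol II arm.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for role in ("reads", "sizes"):
        if role not in inputs:
            raise StageError("setup", f"missing required input {role!r}")
    for role, path in inputs.items():
        if not Path(path).exists():
            raise StageError("setup", f"input file not found: {path} ({role})")

    artifacts: Dict[str, Path] = {}
    stages: List[str] = []

    # ---- bin -------------------------------------------------------------
    stage = "bin"
    try:
        sizes = nsio.read_chrom_sizes(inputs["sizes"])
        reads = nsio.read_bed(inputs["reads"])
        tracks = {
            s: bin_reads(reads, sizes, config.bin_width, s) for s in ("+", "-")
        }
        track_list = [tracks[s][c] for s in ("+", "-") for c in sorted(sizes)]
        cov = outdir / "coverage.bedgraph"
        with open(cov, "w") as fh:
            for t in track_list:
                nsio.write_bedgraph(t, fh)
        artifacts["coverage"] = cov
        stages.append(stage)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- subtract (optional, alpha-amanitin arm) -------------------------
    corrected_tracks = None
    am_norm = ctrl_norm = None
    if "amanitin_reads" in inputs:
        stage = "subtract"
        try:
            am_reads = nsio.read_bed(inputs["amanitin_reads"])
            am_tracks = {
                s: bin_reads(am_reads, sizes, config.bin_width, s)
                for s in ("+", "-")
            }
            n_ctrl, n_am = len(reads), len(am_reads)
            ctrl_norm = {
                (s, c): normalize_depth(tracks[s][c], n_ctrl)
                for s in ("+", "-") for c in sorted(sizes)
            }
            am_norm = {
                (s, c): normalize_depth(am_tracks[s][c], n_am)
                for s in ("+", "-") for c in sorted(sizes)
            }
            corrected_tracks = [
                amanitin_subtract(am_norm[key], ctrl_norm[key], config.subtract_k)
                for key in sorted(am_norm)
            ]
            sub = outdir / "amanitin_corrected.bedgraph"
            with open(sub, "w") as fh:
                for t in corrected_tracks:
                    nsio.write_bedgraph(t, fh)
            artifacts["amanitin_corrected"] = sub
            stages.append(stage)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # ---- call ------------------------------------------------------------
    stage = "call"
    try:
        units, fitted = call_transcripts_genome(
            track_list, config.hmm_params(),
            min_length=config.min_unit_length,
            max_iter=config.em_max_iter, tol=config.em_tol,
        )
        units_bed = outdir / "units.bed"
        nsio.write_bed([u.interval for u in units], units_bed)
        artifacts["units"] = units_bed
        per_chrom: Dict[str, int] = {}
        for u in units:
            per_chrom[u.chrom] = per_chrom.get(u.chrom, 0) + 1
        log.info("called %d units (%s)", len(units),
                 ", ".join(f"{c}: {n}" for c, n in sorted(per_chrom.items())))
        stages.append(stage)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- classify --------------------------------------------------------
    stage = "classify"
    classified = None
    if "annotations" in inputs:
        try:
            ann = nsio.read_annotations(inputs["annotations"], format="gtf")
            if "repeats" in inputs:
                for iv in nsio.read_bed(inputs["repeats"]):
                    ann.add(iv, "repeat")
            classified, counts = classify_all(units, ann, config.classifier)
            stages.append(stage)
            log.info("class counts: %s", dict(counts))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # ---- pair ------------------------------------------------------------
    stage = "pair"
    pairs = []
    if classified is not None:
        try:
            intergenic = [ct for ct in classified if ct.cls == "intergenic"]
            pairs = pair_ernas(intergenic, max_len=config.erna_max_len)
            peaks = nsio.read_bed(inputs["peaks"]) if "peaks" in inputs else []
            annotate_pairs(pairs, peaks, ann, radius=config.nfkb_radius)
            enh = outdir / "enhancers.tsv"
            with open(enh, "w") as fh:
                fh.write("chrom\tcenter\tplus_id\tminus_id\tnfkb\ttarget_gene\tdistance\n")
                for p in pairs:
                    fh.write(
                        f"{p.chrom}\t{p.center}\t{p.plus_unit.id}\t{p.minus_unit.id}\t"
                        f"{int(bool(p.nfkb))}\t{p.target_gene or '.'}\t"
                        f"{p.target_distance if p.target_distance is not None else '.'}\n"
                    )
            artifacts["enhancers"] = enh
            # classification table is written after pairing so the eRNA
            # relabelling is reflected
            cls_tsv = outdir / "classified.tsv"
            with open(cls_tsv, "w") as fh:
                fh.write("chrom\tstart\tend\tstrand\tid\tclass\trule\t"
                         "evidence\toverlap\n")
                for ct in classified:
                    u = ct.unit
                    ov = "" if ct.overlap is None else f"{ct.overlap:.4f}"
                    fh.write(
                        f"{u.chrom}\t{u.start}\t{u.end}\t{u.strand}\t{u.id}\t"
                        f"{ct.cls}\t{ct.rule}\t{ct.evidence_id or '.'}\t{ov}\n"
                    )
            artifacts["classified"] = cls_tsv
            stages.append(stage)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # ---- count -----------------------------------------------------------
    stage = "count"
    try:
        col = count_in_intervals(reads, units, sample="control")
        counts_tsv = outdir / "counts.tsv"
        col.to_frame().to_csv(counts_tsv, sep="\t", index_label="id")
        artifacts["counts"] = counts_tsv
        stages.append(stage)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- metagene --------------------------------------------------------
    stage = "metagene"
    try:
        if pairs:
            anchors = [(p.chrom, p.center, "+") for p in pairs]
        else:
            anchors = [(u.chrom, u.interval.five_prime, u.strand) for u in units]
        if anchors:
            profiles = metagene(reads, anchors, flank=config.metagene_flank,
                                bin=config.metagene_bin, stranded=True)
            mg_tsv = outdir / "metagene.tsv"
            profile_to_frame(profiles).to_csv(mg_tsv, sep="\t", index=False)
            artifacts["metagene"] = mg_tsv
            stages.append(stage)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- amanitin calling + polymerase assignment ------------------------
    if corrected_tracks is not None:
        stage = "amanitin_call"
        try:
            am_units, _ = call_transcripts_genome(
                corrected_tracks, config.amanitin_params(),
                max_iter=config.em_max_iter, tol=config.em_tol,
            )
            am_bed = outdir / "amanitin_units.bed"
            nsio.write_bed([u.interval for u in am_units], am_bed)
            artifacts["amanitin_units"] = am_bed
            pol_tsv = outdir / "polymerase.tsv"
            with open(pol_tsv, "w") as fh:
                fh.write("id\tchrom\tstart\tend\tstrand\tpolymerase\n")
                for u in units:
                    label = assign_polymerase(
                        u.interval,
                        am_norm[(u.strand, u.chrom)],
                        ctrl_norm[(u.strand, u.chrom)],
                        config.polymerase_ratio_threshold,
                    )
                    fh.write(f"{u.id}\t{u.chrom}\t{u.start}\t{u.end}\t"
                             f"{u.strand}\t{label}\n")
            artifacts["polymerase"] = pol_tsv
            stages.append(stage)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    manifest = {
        "package": "nascentscan",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "inputs": {role: _sha256(Path(p)) for role, p in sorted(inputs.items())},
        "stages": stages,
        "artifacts": {name: {"file": p.name, "sha256": _sha256(p)}
                      for name, p in sorted(artifacts.items())},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
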