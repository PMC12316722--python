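"""End-to-end orchestration and file adapters.

The pipeline runs simulate -> dosage -> junction detection -> contig
validation -> haplotype assignment -> breakpoint enrichment and collects
everything into a :class:`RunReport`.  File formats are deliberately
plain: SAM for alignments, BED (0-based half-open) for feature tracks,
TSV for tables, JSON for the report, FASTA for sequences.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import dosage as dosage_mod
from . import enrichment as enrich_mod
from . import junctions as junc_mod
from . import validate as val_mod
from .intervals import Interval
from .mini import MiniType
from .reference import (
    DEFAULT_CENTROMERE,
    DEFAULT_DELETION,
    DEFAULT_LENGTH,
    DEFAULT_MINI_REGION,
    SCALE_FACTOR,
    ReferenceBundle,
)
from .samio import AlignmentRecord, read_sam

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All numeric knobs of a run.

    Published-scale values are recorded next to their scaled defaults:
    bins of 25 kb (profiles) and 100 kb (clustering) map to 2.5/10 kb at
    the 1:10 toy scale; the >=2000 bp split separation, the 5 kb
    pseudo-junction bins, the 1 kb / 10 kb enrichment windows and the
    10,000 x 1,000 resampling are used as printed.
    """

    scale_factor: int = SCALE_FACTOR
    genome_length: int = DEFAULT_LENGTH
    mini_region: Interval = DEFAULT_MINI_REGION
    centromere_analog: Interval = DEFAULT_CENTROMERE
    deletion_interval: Interval = DEFAULT_DELETION
    profile_bin: int = 25_000 // SCALE_FACTOR  # paper: 25 kb
    cluster_bin: int = 100_000 // SCALE_FACTOR  # paper: 100 kb
    pseudo_junction_bin: int = 5_000  # paper: 5 kb
    min_separation: int = 2_000  # paper: >=2000 bp between split loci
    cluster_tolerance: int = 10
    enrichment_windows: tuple[int, ...] = (1_000, 10_000)  # paper: 1 kb, 10 kb
    enrichment_control_region: Interval = (1_300_001, 2_000_000)  # analog of Chr01 13-20 Mb
    n_pseudo: int = enrich_mod.N_PSEUDO
    reps: int = enrich_mod.N_REPS
    alpha: float = 0.05
    depth: float = 10.0
    read_len: int = 150
    insert_mean: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("profile_bin", "cluster_bin", "pseudo_junction_bin", "min_separation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Machine-readable results of one pipeline run."""

    type_calls: pd.DataFrame  # sample_id, mini_type, distance
    junction_table: pd.DataFrame
    presence_matrix: pd.DataFrame  # samples x junctions, supporting-read counts
    enrichment_table: pd.DataFrame
    gene_disruption: tuple[int, int, float] | None
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "type_calls": self.type_calls.to_dict(orient="records"),
                "junctions": self.junction_table.to_dict(orient="records"),
                "presence_matrix": self.presence_matrix.to_dict(),
                "enrichment": self.enrichment_table.to_dict(orient="records"),
                "gene_disruption": self.gene_disruption,
                "provenance": self.provenance,
            },
            indent=2,
            default=str,
        )


# ---------------------------------------------------------------- file I/O


def read_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED-like file (0-based half-open) into 1-based inclusive tuples.

    Malformed records are skipped with a counted warning; more than 10%
    malformed aborts.
    """
    out: list[tuple[str, int, int]] = []
    bad = total = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        total += 1
        parts = line.split("\t")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError
            out.append((chrom, start + 1, end))
        except (IndexError, ValueError):
            bad += 1
    if bad:
        logger.warning("%d malformed interval records skipped in %s", bad, path)
        if total and bad / total > 0.10:
            raise ValueError(f"more than 10% malformed records in {path}")
    return out


def write_intervals(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s - 1}\t{e}\n")


def write_dosage_tsv(profile: dosage_mod.DosageProfile, path: str | Path) -> None:
    rows = []
    for chrom, vals in profile.values.items():
        bs = profile.bin_size
        for i, v in enumerate(vals):
            rows.append((chrom, i * bs, (i + 1) * bs, "" if not np.isfinite(v) else round(v, 4)))
    pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "dosage"]).to_csv(
        path, sep="\t", index=False
    )


def junctions_to_table(candidates: list[junc_mod.CandidateJunction]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(candidates):
        support = ";".join(f"{s}:{n}" for s, n in sorted(c.support_by_sample().items()))
        rows.append(
            {
                "junction_id": f"J{i + 1}",
                "chromA": c.breakpoint_a.chrom,
                "posA": c.breakpoint_a.pos,
                "sideA": c.breakpoint_a.side,
                "chromB": c.breakpoint_b.chrom,
                "posB": c.breakpoint_b.pos,
                "sideB": c.breakpoint_b.side,
                "orientation": c.orientation,
                "support": c.support,
                "support_by_sample": support,
                "carrier_exclusive": c.carrier_exclusive,
                "above_threshold": c.above_threshold,
                "validated": c.validated,
            }
        )
    return pd.DataFrame(rows)


def write_bedpe(candidates: list[junc_mod.CandidateJunction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(candidates):
            a, b = c.breakpoint_a, c.breakpoint_b
            fh.write(
                f"{a.chrom}\t{a.pos - 1}\t{a.pos}\t{b.chrom}\t{b.pos - 1}\t{b.pos}\t"
                f"J{i + 1}\t{c.support}\t{'+' if a.side == 'left' else '-'}\t"
                f"{'+' if b.side == 'right' else '-'}\n"
            )


def save_reference(ref: ReferenceBundle, outdir: str | Path) -> None:
    """Write a reference bundle as FASTA + BED tracks + SNP TSV + meta JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        [SeqRecord(Seq(s), id=c, description="") for c, s in ref.sequences.items()],
        str(outdir / "reference.fasta"),
        "fasta",
    )
    write_intervals(ref.gene_intervals, outdir / "genes.bed")
    write_intervals(ref.repeat_intervals, outdir / "repeats.bed")
    pd.DataFrame(ref.snp_table, columns=["pos", "background", "mini"]).to_csv(
        outdir / "snps.tsv", sep="\t", index=False
    )
    meta = {
        "mini_chrom": ref.mini_chrom,
        "mini_region": list(ref.mini_region),
        "centromere_analog": list(ref.centromere_analog),
    }
    (outdir / "reference.json").write_text(json.dumps(meta, indent=2))


def load_reference(refdir: str | Path) -> ReferenceBundle:
    refdir = Path(refdir)
    meta = json.loads((refdir / "reference.json").read_text())
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(refdir / "reference.fasta"), "fasta")
    }
    snps = pd.read_csv(refdir / "snps.tsv", sep="\t")
    return ReferenceBundle(
        sequences=seqs,
        mini_chrom=meta["mini_chrom"],
        mini_region=tuple(meta["mini_region"]),
        centromere_analog=tuple(meta["centromere_analog"]),
        gene_intervals=read_intervals(refdir / "genes.bed"),
        repeat_intervals=read_intervals(refdir / "repeats.bed"),
        snp_table=[(int(r.pos), str(r.background), str(r.mini)) for r in snps.itertuples()],
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample_id, sam_path, carrier_status, control."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "sam_path", "carrier_status", "control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------- pipeline


def run_pipeline(
    config: PipelineConfig,
    alignments: dict[str, list[AlignmentRecord]],
    carrier_ids: set[str],
    control_ids: set[str],
    ref: ReferenceBundle,
    control_sample: str | None = None,
) -> RunReport:
    """Run dosage typing, junction calling, validation and enrichment.

    ``control_sample`` anchors dosage normalization (defaults to the first
    control id in sorted order); a run without any control aborts, since
    both normalization and the exclusivity filter require one.
    """
    t0 = time.time()
    if not control_ids:
        raise ValueError("pipeline requires at least one non-carrier control sample")
    control_sample = control_sample or sorted(control_ids)[0]
    chrom_lengths = {c: len(s) for c, s in ref.sequences.items()}

    # --- dosage typing
    coverage = {
        sid: dosage_mod.bin_coverage(recs, config.profile_bin, chrom_lengths)
        for sid, recs in alignments.items()
    }
    control_cov = coverage[control_sample]
    type_rows = []
    for sid in sorted(alignments):
        prof = dosage_mod.normalize_dosage(coverage[sid], control_cov, control_sample)
        mt, dist = dosage_mod.classify_mini_type(
            prof, ref.mini_chrom, ref.mini_region, config.deletion_interval
        )
        type_rows.append(
            {
                "sample_id": sid,
                "mini_type": mt.name if mt is not None else "UNCLASSIFIABLE",
                "distance": round(dist, 4) if np.isfinite(dist) else "",
            }
        )
    type_calls = pd.DataFrame(type_rows)
    logger.info("dosage typing done in %.1fs", time.time() - t0)

    # --- junction detection
    evidence = []
    for sid, recs in alignments.items():
        evidence += junc_mod.extract_split_alignments(recs, config.min_separation, sid)
    candidates = junc_mod.cluster_evidence(evidence, config.cluster_tolerance)
    thresholds = {
        sid: junc_mod.pseudo_junction_threshold(recs, chrom_lengths, config.pseudo_junction_bin)
        for sid, recs in alignments.items()
    }
    accepted = junc_mod.filter_junctions(candidates, carrier_ids, control_ids, thresholds)
    logger.info("junctions: %d candidates, %d accepted", len(candidates), len(accepted))

    # --- validation + haplotype
    hap_calls = {}
    for idx, cand in enumerate(accepted):
        best_sample = max(cand.support_by_sample().items(), key=lambda kv: kv[1])[0]
        reads = val_mod.collect_cross_junction_reads(cand, alignments[best_sample])
        if reads:
            contig = val_mod.assemble_contig(reads)
            val_mod.validate_contig(contig, ref.sequences, cand)
            cand.validated = contig.validated
        else:
            cand.validated = False
        hap = val_mod.assign_haplotype(cand, ref.snp_table, alignments[best_sample])
        hap_calls[idx] = hap.call
    junction_table = junctions_to_table(accepted)
    if len(junction_table):
        junction_table["haplotype"] = [hap_calls[i] for i in range(len(accepted))]

    # --- presence matrix (samples x junctions)
    presence = pd.DataFrame(
        {
            f"J{i + 1}": {
                sid: cand.support_by_sample().get(sid, 0) for sid in sorted(alignments)
            }
            for i, cand in enumerate(accepted)
        },
        dtype=int,
    )

    # --- enrichment around validated breakpoints
    validated = [c for c in accepted if c.validated]
    breakpoints = [c.breakpoint_a.pos for c in validated] + [
        c.breakpoint_b.pos for c in validated
    ]
    enrich_rows = []
    gene_disruption = None
    if len(breakpoints) >= 2:
        L = chrom_lengths[ref.mini_chrom]
        for feature in ("gene", "repeat"):
            track = ref.feature_track(feature)
            for window in config.enrichment_windows:
                null = enrich_mod.resample_null(
                    track,
                    config.enrichment_control_region,
                    L,
                    window,
                    config.n_pseudo,
                    config.reps,
                    seed=config.seed + window,
                )
                res = enrich_mod.enrichment_test(breakpoints, track, window, null, L, feature)
                enrich_rows.append(
                    {
                        "feature": feature,
                        "n_breakpoints": res.n_breakpoints,
                        "window": window,
                        "enrichment_ratio": round(res.ratio, 3),
                        "p_value": round(res.p_value, 4),
                        "significant": "*" if res.p_value < config.alpha else "",
                    }
                )
        gene_disruption = enrich_mod.gene_disruption_test(
            breakpoints, ref.feature_track("gene"), ref.mini_region
        )
    enrichment_table = pd.DataFrame(enrich_rows)

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_samples": len(alignments),
        "control_sample": control_sample,
        "thresholds": {k: round(v, 3) for k, v in thresholds.items()},
    }
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return RunReport(
        type_calls=type_calls,
        junction_table=junction_table,
        presence_matrix=presence,
        enrichment_table=enrichment_table,
        gene_disruption=gene_disruption,
        provenance=provenance,
    )


def run_from_files(
    config: PipelineConfig,
    sample_sheet: str | Path,
    refdir: str | Path,
) -> RunReport:
    """File-level entry: sample sheet TSV + reference directory -> report."""
    sheet = read_sample_sheet(sample_sheet)
    ref = load_reference(refdir)
    alignments = {row.sample_id: read_sam(row.sam_path) for row in sheet.itertuples()}
    carrier_ids = set(sheet.loc[sheet.carrier_status == "carrier", "sample_id"])
    control_ids = set(sheet.loc[sheet.carrier_status == "control", "sample_id"])
    controls = sheet.loc[sheet.control.astype(bool), "sample_id"]
    control_sample = str(controls.iloc[0]) if len(controls) else None
    return run_pipeline(config, alignments, carrier_ids, control_ids, ref, control_sample)
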