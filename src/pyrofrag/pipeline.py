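"""End-to-end orchestration: simulate -> demux -> pileup -> error stats ->
genotyping -> profiles, with a checksummed run manifest.

The pipeline is deterministic under a fixed configuration and seed: two runs
produce byte-identical output trees. Pileups for simulated runs come from
the reads' truth alignments; external FASTQ+SAM+truth inputs bypass the
simulator (``external=...``) and are aligned/ingested instead.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import demux as demux_mod
from . import errorstats as es
from . import genotyping as gt
from . import profiling as pf
from . import pileup as pl
from . import simdata as sd


@dataclass(frozen=True)
class PipelineOptions:
    """Analysis-side knobs (the simulation knobs live in SimulationConfig)."""

    max_mismatch: int = 1
    min_depth: int = 20
    max_alt_freq: float = 0.20
    hp_min_run: int = 5
    het_thresh: float = 0.20
    write_pileups: bool = True
    write_per_sample_fastq: bool = False


@dataclass(frozen=True)
class ExternalInputs:
    """External FASTQ + SAM + Sanger-truth triple replacing the simulator."""

    fastq: Path
    sam: Path
    truth_genotypes: Path | None = None


@dataclass
class RunManifest:
    seed: int
    config_sha256: str
    counters: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)      # name -> sha256
    stages: list = field(default_factory=list)     # {name, inputs, outputs}

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed, "config_sha256": self.config_sha256,
            "counters": self.counters, "files": self.files,
            "stages": self.stages}, indent=2, sort_keys=True)

    def validate_chain(self) -> bool:
        """Every stage input checksum must match the producing stage's
        recorded output checksum."""
        for stage in self.stages:
            for name, sha in stage["inputs"].items():
                if name in self.files and self.files[name] != sha:
                    return False
        return True


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageLogger:
    def __init__(self, quiet: bool = False):
        self.quiet = quiet

    def __call__(self, msg: str) -> None:
        if not self.quiet:
            print(msg, file=sys.stderr)


def truth_entries_from_config(config: sd.SimulationConfig
                              ) -> list[gt.SangerTruthEntry]:
    """Sanger-style truth derived from the simulation's planted het SNPs."""
    region = config.panel.region
    out = []
    for off, alt in config.het_snps:
        ref = region.sequence[off]
        out.append(gt.SangerTruthEntry(
            region.name, (region.abs_pos_1based(off),), ref, "het",
            (ref, alt)))
    return out


def run_pipeline(config: sd.SimulationConfig, outdir,
                 options: PipelineOptions = PipelineOptions(),
                 external: ExternalInputs | None = None,
                 extra_truth: Sequence[gt.SangerTruthEntry] = (),
                 quiet: bool = True) -> RunManifest:
    """Execute the full workflow into ``outdir``; returns the manifest.

    Any stage failure raises with the failing stage named.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLogger(quiet)
    region = config.panel.region
    cfg_json = sd.config_to_json(config)
    manifest = RunManifest(
        seed=config.seed,
        config_sha256=hashlib.sha256(cfg_json.encode()).hexdigest())

    def record(stage: str, inputs: Mapping[str, Path],
               outputs: Mapping[str, Path]) -> None:
        ins = {n: _sha256_file(p) for n, p in inputs.items()}
        outs = {n: _sha256_file(p) for n, p in outputs.items()}
        manifest.files.update(outs)
        manifest.stages.append({"name": stage, "inputs": ins,
                                "outputs": outs})

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            log(f"[{name}] starting")
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}"
                                   ) from exc
            log(f"[{name}] done in {time.time() - t0:.1f}s")
            return result
        return wrap

    (out / "config.json").write_text(cfg_json)

    # -- simulate ----------------------------------------------------------
    if external is None:
        def _simulate():
            sim = sd.simulate_run(config)
            sd.write_fastq(sim.reads, out / "reads.fastq")
            sd.write_truth_tsv(sim.reads, out / "truth.tsv")
            sd.write_panel_bed(config.panel, out / "panel.bed")
            sd.write_region_fasta(region, out / "reference.fasta")
            record("simulate", {"config.json": out / "config.json"},
                   {n: out / n for n in ("reads.fastq", "truth.tsv",
                                         "panel.bed", "reference.fasta")})
            return sim
        sim = stage("simulate")(_simulate)
        reads = sim.reads
        truth_by_id = {r.read_id: r for r in reads}
        manifest.counters["reads_simulated"] = len(reads)
        fastq_path = out / "reads.fastq"
    else:
        reads = sd.read_fastq(external.fastq)
        truth_by_id = None
        fastq_path = Path(external.fastq)
        manifest.counters["reads_input"] = len(reads)

    # -- demultiplex -------------------------------------------------------
    def _demux():
        res = demux_mod.demultiplex(reads, config.mids, options.max_mismatch)
        res.summary_table().to_csv(out / "demux_summary.tsv", sep="\t",
                                   index=False)
        outputs = {"demux_summary.tsv": out / "demux_summary.tsv"}
        if options.write_per_sample_fastq:
            for s, rs in res.assigned.items():
                p = out / f"sample_{s}.fastq"
                sd.write_fastq(rs, p)
                outputs[p.name] = p
        record("demux", {fastq_path.name: fastq_path}, outputs)
        return res
    dres = stage("demux")(_demux)
    manifest.counters["reads_assigned"] = dres.n_total - \
        dres.counts[demux_mod.UNASSIGNED]
    manifest.counters["reads_unassigned"] = dres.counts[demux_mod.UNASSIGNED]

    # -- alignment / pileup ------------------------------------------------
    def _pileups():
        pus: dict[str, pl.Pileup] = {}
        if external is None:
            for s, rs in dres.assigned.items():
                aligned = [pl.from_simulated(truth_by_id[r.read_id])
                           for r in rs]
                pus[s] = pl.build_pileup(aligned, region)
        else:
            aligned, n_unmapped = pl.read_sam(external.sam, region)
            manifest.counters["reads_unmapped"] = n_unmapped
            sample_of = {}
            for s, rs in dres.assigned.items():
                for r in rs:
                    sample_of[r.read_id] = s
            by_sample: dict[str, list] = {s: [] for s in dres.assigned}
            for ar in aligned:
                s = sample_of.get(ar.read_id)
                if s is not None:
                    by_sample[s].append(ar)
            for s, ars in by_sample.items():
                pus[s] = pl.build_pileup(ars, region)
        outputs = {}
        if options.write_pileups:
            for s, pu in pus.items():
                p = out / f"pileup_{s}.tsv"
                pl.write_pileup_tsv(pu, p)
                outputs[p.name] = p
            record("pileup", {fastq_path.name: fastq_path}, outputs)
        return pus
    pileups = stage("pileup")(_pileups)
    manifest.counters["reads_piled"] = sum(pu.n_reads
                                           for pu in pileups.values())

    # -- raw error statistics ---------------------------------------------
    def _errstats():
        params = es.AnalysisParams(min_depth=options.min_depth,
                                   max_alt_freq=options.max_alt_freq)
        stats = {s: es.method1_stats(pu, params)
                 for s, pu in pileups.items()}
        es.stats_table(stats).to_csv(out / "error_stats.tsv", sep="\t",
                                     index=False)
        by_method: dict[str, list] = {}
        for s, st in stats.items():
            by_method.setdefault(config.methods[s], []).append(st)
        es.compare_methods(by_method).to_csv(
            out / "error_comparison.tsv", sep="\t", index=False)
        record("errorstats", {}, {
            "error_stats.tsv": out / "error_stats.tsv",
            "error_comparison.tsv": out / "error_comparison.tsv"})
        return stats
    stats = stage("errorstats")(_errstats)
    manifest.counters["eligible_positions"] = {
        s: st.eligible_positions for s, st in stats.items()}

    # -- genotyping / concordance -----------------------------------------
    def _genotype():
        truth = truth_entries_from_config(config) + list(extra_truth)
        if external is not None and external.truth_genotypes is not None:
            truth += gt.read_truth_genotypes_tsv(external.truth_genotypes)
        if not truth:
            return None
        gt.write_truth_genotypes_tsv(truth, out / "sanger_truth.tsv")
        records, summary = gt.concordance(
            truth, pileups, region, hp_min_run=options.hp_min_run,
            het_thresh=options.het_thresh, methods=config.methods)
        table = make_table1(records, list(pileups))
        table.to_csv(out / "concordance.tsv", sep="\t")
        (out / "concordance_summary.json").write_text(json.dumps({
            "discordant_pairs_by_method": summary.discordant_pairs_by_method,
            "n_loci_any_discordant": summary.n_loci_any_discordant,
            "n_loci": summary.n_loci}, indent=2, sort_keys=True))
        record("genotyping", {}, {
            "sanger_truth.tsv": out / "sanger_truth.tsv",
            "concordance.tsv": out / "concordance.tsv",
            "concordance_summary.json": out / "concordance_summary.json"})
        return records, summary
    conc = stage("genotyping")(_genotype)
    if conc is not None:
        manifest.counters["loci_any_discordant"] = conc[1].n_loci_any_discordant

    # -- profiling ---------------------------------------------------------
    def _profile():
        pooled = None
        for pu in pileups.values():
            pooled = pu if pooled is None else pooled + pu
        cov = pf.coverage_by_amplicon(pooled, config.panel)
        cov.as_table().to_csv(out / "coverage_by_amplicon.tsv", sep="\t",
                              index=False)
        pf.write_coverage_tsv(cov, pooled, out / "coverage_per_position.tsv")
        qual = pf.quality_decay(dres.assigned, window=5)
        pf.write_quality_profile_tsv(qual, out / "quality_profile.tsv")
        hist = pf.readlength_hist(
            [r for rs in dres.assigned.values() for r in rs])
        pf.write_readlength_tsv(hist, out / "readlength_hist.tsv")
        record("profiling", {}, {n: out / n for n in (
            "coverage_by_amplicon.tsv", "coverage_per_position.tsv",
            "quality_profile.tsv", "readlength_hist.tsv")})
        return cov, qual, hist
    stage("profile")(_profile)

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def make_table1(records: Sequence[gt.ConcordanceRecord],
                samples: Sequence[str]):
    """Format concordance records as the Sanger/ALL/per-sample grid.

    Rows are loci (1-based positions); the two leading columns are the
    Sanger genotype and the pooled (ALL) call, followed by one column per
    sample. Each cell shows call, coverage (S) and major-allele percentage;
    discordant cells carry a trailing ``*`` flag.
    """
    import pandas as pd

    def cell(call: gt.LocusCall, flag: bool | None) -> str:
        if call.alleles is None:
            return "no-call"
        s = f"{call.rendered} S{call.depth} {call.major_pct:.0f}%"
        return s + ("*" if flag is False else "")

    rows, index = [], []
    for rec in records:
        index.append("-".join(f"{p:,}".replace(",", ".")
                              for p in rec.truth.positions))
        row = {"Sanger": f"{rec.truth.zygosity} "
                         f"{'/'.join(rec.truth.alleles)}",
               "ALL": cell(rec.pooled, rec.pooled_agrees)}
        for s in samples:
            call = rec.per_sample.get(s)
            row[s] = "no-call" if call is None else \
                cell(call, rec.agreement.get(s))
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(index, name="position"))
    return df
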